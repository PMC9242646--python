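"""Generators: determinism, conservation, and law-of-large-numbers checks."""

import numpy as np
import pytest

from adaptoquant.binding import BindingModel, ITCProtocol
from adaptoquant.core import MicrotubulePath
from adaptoquant.synthetic import (
    SimulationConfig,
    simulate_cell_field,
    simulate_itc,
    simulate_mals_trace,
    simulate_spermatocyte_spread,
    simulate_tirf_movie,
    straight_paths,
)


class TestSimulationConfig:
    def test_state_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            SimulationConfig(state_fractions=(0.5, 0.2, 0.2))

    @pytest.mark.parametrize("kw", [
        {"pixel_size": -0.1}, {"frame_interval": 0.0}, {"landing_rate_true": -1.0},
        {"field_size": (4, 4)},
    ])
    def test_nonphysical_values_rejected(self, kw):
        with pytest.raises(ValueError):
            SimulationConfig(**kw)


class TestSimulateTirfMovie:
    def _cfg(self, **kw):
        base = dict(seed=7, movie_duration=30.0, field_size=(64, 128),
                    landing_rate_true=0.3, run_length_mean=2.0)
        base.update(kw)
        return SimulationConfig(**base)

    def test_degenerate_mixture_yields_only_processive(self):
        cfg = self._cfg(state_fractions=(1.0, 0.0, 0.0))
        _, truth = simulate_tirf_movie(cfg, straight_paths(1, cfg.field_size))
        assert len(truth.events) > 0
        assert (truth.events["class"] == "processive").all()

    def test_zero_landing_rate_gives_background_only(self):
        cfg = self._cfg(landing_rate_true=0.0)
        movie, truth = simulate_tirf_movie(cfg, straight_paths(1, cfg.field_size))
        assert len(truth.events) == 0
        # background only: intensities stay near the configured noise level
        assert movie.frames.max() < cfg.background_mean + 8 * cfg.background_sd

    def test_poisson_event_count_matches_rate_times_length(self):
        # 10 paths totaling 200 µm, 3 min, rate 0.1 -> Poisson mean 60
        cfg = SimulationConfig(seed=0, movie_duration=180.0, field_size=(128, 140),
                               landing_rate_true=0.1)
        paths = [
            MicrotubulePath(f"m{i}", np.array([[5.0, 10.0 + 10 * i], [130.0, 10.0 + 10 * i]]))
            for i in range(10)
        ]
        total_um = sum(p.length_um(cfg.pixel_size) for p in paths)
        assert total_um == pytest.approx(200.0)
        counts = []
        for seed in range(5):
            cfg_s = SimulationConfig(**{**cfg.__dict__, "seed": seed})
            _, truth = simulate_tirf_movie(cfg_s, paths)
            counts.append(len(truth.events))
        assert abs(np.mean(counts) - 60) <= 3 * np.sqrt(60) / np.sqrt(len(counts))

    def test_seed_determinism_bit_for_bit(self):
        cfg = self._cfg()
        paths = straight_paths(2, cfg.field_size)
        m1, t1 = simulate_tirf_movie(cfg, paths)
        m2, t2 = simulate_tirf_movie(cfg, paths)
        np.testing.assert_array_equal(m1.frames, m2.frames)
        assert t1.events.equals(t2.events)

    def test_empty_path_list_rejected(self):
        with pytest.raises(ValueError):
            simulate_tirf_movie(self._cfg(), [])

    def test_every_event_has_exactly_one_truth_record(self):
        cfg = self._cfg(movie_duration=60.0)
        _, truth = simulate_tirf_movie(cfg, straight_paths(3, cfg.field_size))
        ev = truth.events
        assert ev["birth_frame"].le(ev["death_frame"]).all()
        assert ev["class"].isin(["processive", "diffusive", "immotile"]).all()

    def test_speed_mean_converges_to_configured(self):
        cfg = self._cfg(movie_duration=180.0, landing_rate_true=0.5,
                        state_fractions=(1.0, 0, 0),
                        speed_distribution=("normal", 0.5, 0.05))
        _, truth = simulate_tirf_movie(cfg, straight_paths(4, cfg.field_size))
        speeds = truth.events["speed_um_s"].dropna()
        assert len(speeds) > 50
        assert speeds.mean() == pytest.approx(0.5, abs=3 * 0.05 / np.sqrt(len(speeds)))


class TestSimulateCellField:
    def test_enrichment_factor_one_gives_equal_region_means(self):
        cfg = SimulationConfig(seed=2)
        _, truth = simulate_cell_field(cfg, 3, {"dynein": 1.0}, {"dynein": 300.0})
        assert (truth.cells["dynein_band_mean"] == truth.cells["dynein_cyto_mean"]).all()

    def test_noiseless_truth_records_configured_enrichment(self):
        cfg = SimulationConfig(seed=2)
        _, truth = simulate_cell_field(cfg, 2, {"dynein": 2.0}, {"dynein": 250.0})
        assert (truth.cells["dynein_enrichment"] == 2.0).all()
        np.testing.assert_allclose(
            truth.cells["dynein_band_mean"], 2.0 * truth.cells["dynein_cyto_mean"]
        )

    def test_threshold_count_matches_direct_enumeration_of_draws(self):
        cfg = SimulationConfig(seed=9)
        _, truth = simulate_cell_field(
            cfg, 50, {"KASH5": 1.5}, {"KASH5": (150.0, 350.0)}
        )
        for thr in (200.0, 250.0, 300.0):
            n_below = (truth.cells["KASH5_whole_cell_mean"] < thr).sum()
            direct = sum(v < thr for v in truth.cells["KASH5_whole_cell_mean"])
            assert n_below == direct
        # draws actually span the configured range
        assert truth.cells["KASH5_cyto_mean"].between(150, 350).all()

    def test_determinism(self):
        cfg = SimulationConfig(seed=4)
        f1, t1 = simulate_cell_field(cfg, 4, {"d": 2.0}, {"d": 100.0}, noise_sd=3.0)
        f2, t2 = simulate_cell_field(cfg, 4, {"d": 2.0}, {"d": 100.0}, noise_sd=3.0)
        np.testing.assert_array_equal(f1.channels["d"], f2.channels["d"])
        assert t1.cells.equals(t2.cells)


class TestSimulateSpermatocyteSpread:
    def test_seven_cells_twenty_foci_gives_140_truth_records(self):
        cfg = SimulationConfig(seed=3)
        _, truth = simulate_spermatocyte_spread(cfg, 7, 20, 0.73, n_reference_cells=0)
        assert len(truth.foci) == 140

    def test_fraction_one_matches_reference_amplitude_scale(self):
        cfg = SimulationConfig(seed=6)
        _, truth = simulate_spermatocyte_spread(cfg, 2, 4, 1.0, amplitude_cv=0.0)
        mut = truth.foci[~truth.foci["is_reference"]]["p150_amplitude"]
        ref = truth.foci[truth.foci["is_reference"]]["p150_amplitude"]
        assert mut.mean() == pytest.approx(ref.mean())

    def test_fraction_zero_gives_zero_amplitude_foci(self):
        cfg = SimulationConfig(seed=6)
        _, truth = simulate_spermatocyte_spread(cfg, 2, 4, 0.0)
        assert (truth.foci[~truth.foci["is_reference"]]["p150_amplitude"] == 0).all()

    def test_odd_focus_count_rejected(self):
        with pytest.raises(ValueError, match="even"):
            simulate_spermatocyte_spread(SimulationConfig(seed=1), 1, 5, 1.0)

    def test_gfp_negative_cells_carry_no_gfp_foci(self):
        cfg = SimulationConfig(seed=8)
        cells, truth = simulate_spermatocyte_spread(cfg, 1, 4, 0.5, n_reference_cells=1)
        ref_rows = truth.foci[truth.foci["is_reference"]]
        assert (ref_rows["gfp_amplitude"] == 0).all()


class TestSimulateItc:
    def _model(self, dh=-8.0):
        return BindingModel(n_sites=0.5, kd=4.3, dh=dh, baseline=-0.1)

    def _protocol(self):
        return ITCProtocol(cell_concentration=50.0, syringe_concentration=550.0,
                           cell_volume=200.0, injection_volumes=np.full(19, 10.0))

    def test_zero_enthalpy_gives_baseline_heats(self):
        exp = simulate_itc(self._model(dh=0.0), self._protocol(), noise_sd=0.0)
        np.testing.assert_allclose(exp.heats, -0.1)

    def test_stoichiometric_limit_cumulative_heat(self):
        # K_d -> 0 with negligible displacement: total heat = N dH [cell] V0
        model = BindingModel(n_sites=0.5, kd=1e-9, dh=-8.0, baseline=0.0)
        protocol = ITCProtocol(
            cell_concentration=50.0, syringe_concentration=50000.0,
            cell_volume=200.0, injection_volumes=np.full(10, 0.2),
        )
        exp = simulate_itc(model, protocol, noise_sd=0.0)
        expected = 0.5 * -8.0 * 50.0 * 200.0 * 1e-3  # µcal
        assert exp.heats.sum() == pytest.approx(expected, rel=0.02)

    def test_fixed_seed_reproduces_heat_table_exactly(self):
        a = simulate_itc(self._model(), self._protocol(), noise_sd=0.3, seed=5)
        b = simulate_itc(self._model(), self._protocol(), noise_sd=0.3, seed=5)
        np.testing.assert_array_equal(a.heats, b.heats)

    def test_overfilled_cell_rejected(self):
        with pytest.raises(ValueError, match="cell-volume cap"):
            ITCProtocol(cell_concentration=50, syringe_concentration=550,
                        cell_volume=100.0, injection_volumes=np.full(40, 10.0))


class TestSimulateMalsTrace:
    def test_noiseless_round_trip_recovers_mass(self):
        from adaptoquant.binding import mals_mass
        trace = simulate_mals_trace(100.0, noise_sd=0.0)
        assert mals_mass(trace) == pytest.approx(100.0, rel=1e-9)

    def test_scattering_linear_in_concentration(self):
        t1 = simulate_mals_trace(120.0, peak_concentration=0.5, noise_sd=0.0)
        t2 = simulate_mals_trace(120.0, peak_concentration=1.0, noise_sd=0.0)
        np.testing.assert_allclose(t2.scattering, 2.0 * t1.scattering, rtol=1e-12)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            simulate_mals_trace(0.0)
        with pytest.raises(ValueError):
            simulate_mals_trace(100.0, peak_concentration=0.0)
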