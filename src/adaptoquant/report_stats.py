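"""Group-comparison and summary reporting layer.

Two omnibus+posthoc procedures are provided, matching common practice for
single-molecule and imaging datasets:

* rank-based: Kruskal-Wallis omnibus with Dunn's pairwise z-tests
  (tie-corrected rank variance, Bonferroni-adjusted p-values);
* heteroscedastic means: Welch and Brown-Forsythe omnibus ANOVAs with
  Dunnett's T3 pairwise comparisons (Welch t statistics; the studentized
  maximum modulus adjustment is approximated by the Šidák correction).

Significance tiers follow the conventional cutoffs: ns (>0.05), * (<=0.05),
** (<=0.01), *** (<=0.001), **** (<=0.0001), applied to adjusted p-values.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupedSamples",
    "ComparisonResult",
    "PairwiseComparison",
    "compare_groups",
    "summarize_metric",
    "significance_tier",
]

TIER_CUTOFFS = (0.05, 0.01, 0.001, 0.0001)


@dataclass
class GroupedSamples:
    """Named groups of numeric observations for one metric."""

    groups: dict  # label -> 1-D array-like
    metric: str = ""
    units: str = ""

    def __post_init__(self) -> None:
        self.groups = {k: np.asarray(v, dtype=float) for k, v in self.groups.items()}
        for label, vals in self.groups.items():
            if not np.isfinite(vals).all():
                raise ValueError(f"group {label!r} contains non-finite observations")

    @classmethod
    def from_frame(cls, df: pd.DataFrame, group_col: str, value_col: str,
                   metric: str = "", units: str = "") -> "GroupedSamples":
        groups = {str(g): sub[value_col].to_numpy() for g, sub in df.groupby(group_col)}
        return cls(groups=groups, metric=metric or value_col, units=units)


@dataclass
class PairwiseComparison:
    pair: tuple[str, str]
    statistic: float
    p_raw: float
    p_adjusted: float
    tier: str


@dataclass
class ComparisonResult:
    method: str
    omnibus_statistic: float
    omnibus_p: float
    pairwise: list[PairwiseComparison] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "group_a": c.pair[0],
                    "group_b": c.pair[1],
                    "statistic": c.statistic,
                    "p_raw": c.p_raw,
                    "p_adjusted": c.p_adjusted,
                    "tier": c.tier,
                }
                for c in self.pairwise
            ]
        )


def significance_tier(p_adjusted: float) -> str:
    """Map an adjusted p-value onto the ns/*/**/***/**** tiers."""
    if not 0 <= p_adjusted <= 1 + 1e-12:
        raise ValueError("adjusted p must be in [0, 1]")
    if p_adjusted > TIER_CUTOFFS[0]:
        return "ns"
    for stars, cut in enumerate(TIER_CUTOFFS[1:], start=1):
        if p_adjusted > cut:
            return "*" * stars
    return "****"


# ---------------------------------------------------------------------------
# rank-based: Kruskal-Wallis + Dunn
# ---------------------------------------------------------------------------


def _dunn_pairwise(groups: dict) -> list[PairwiseComparison]:
    labels = list(groups)
    pooled = np.concatenate([groups[g] for g in labels])
    n_total = len(pooled)
    ranks = stats.rankdata(pooled)
    offsets = np.cumsum([0] + [len(groups[g]) for g in labels])
    mean_ranks = {
        g: ranks[offsets[i]: offsets[i + 1]].mean() for i, g in enumerate(labels)
    }
    # tie correction to the rank variance
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts**3 - counts) / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term
    m = len(labels) * (len(labels) - 1) // 2
    out = []
    for a, b in itertools.combinations(labels, 2):
        se = np.sqrt(var_base * (1.0 / len(groups[a]) + 1.0 / len(groups[b])))
        z = (mean_ranks[a] - mean_ranks[b]) / se
        p_raw = 2.0 * stats.norm.sf(abs(z))
        p_adj = min(1.0, p_raw * m)  # Bonferroni (Dunn)
        out.append(PairwiseComparison((a, b), float(z), float(p_raw), float(p_adj),
                                      significance_tier(p_adj)))
    return out


# ---------------------------------------------------------------------------
# heteroscedastic means: Welch / Brown-Forsythe ANOVA + Dunnett T3
# ---------------------------------------------------------------------------


def _welch_anova(groups: dict) -> tuple[float, float]:
    ns = np.array([len(v) for v in groups.values()], dtype=float)
    means = np.array([v.mean() for v in groups.values()])
    vars_ = np.array([v.var(ddof=1) for v in groups.values()])
    w = ns / vars_
    grand = np.sum(w * means) / np.sum(w)
    k = len(ns)
    num = np.sum(w * (means - grand) ** 2) / (k - 1)
    lam = 3.0 * np.sum((1.0 - w / np.sum(w)) ** 2 / (ns - 1)) / (k**2 - 1)
    f = num / (1.0 + 2.0 * lam * (k - 2) / 3.0)
    df2 = 1.0 / lam
    return float(f), float(stats.f.sf(f, k - 1, df2))


def _brown_forsythe_anova(groups: dict) -> tuple[float, float]:
    # Brown-Forsythe F* statistic (means version): heteroscedastic one-way F
    ns = np.array([len(v) for v in groups.values()], dtype=float)
    means = np.array([v.mean() for v in groups.values()])
    vars_ = np.array([v.var(ddof=1) for v in groups.values()])
    n = ns.sum()
    grand = np.concatenate(list(groups.values())).mean()
    num = np.sum(ns * (means - grand) ** 2)
    ci = (1.0 - ns / n) * vars_
    denom = np.sum(ci)
    f = num / denom
    df1 = len(ns) - 1
    df2 = denom**2 / np.sum(ci**2 / (ns - 1))
    return float(f), float(stats.f.sf(f, df1, df2))


def _t3_pairwise(groups: dict) -> list[PairwiseComparison]:
    labels = list(groups)
    m = len(labels) * (len(labels) - 1) // 2
    out = []
    for a, b in itertools.combinations(labels, 2):
        va, vb = groups[a], groups[b]
        sa2, sb2 = va.var(ddof=1) / len(va), vb.var(ddof=1) / len(vb)
        t = (va.mean() - vb.mean()) / np.sqrt(sa2 + sb2)
        df = (sa2 + sb2) ** 2 / (sa2**2 / (len(va) - 1) + sb2**2 / (len(vb) - 1))
        p_raw = 2.0 * stats.t.sf(abs(t), df)
        p_adj = 1.0 - (1.0 - p_raw) ** m  # Šidák approximation to the SMM
        p_adj = float(min(1.0, max(p_adj, p_raw)))
        out.append(PairwiseComparison((a, b), float(t), float(p_raw), p_adj,
                                      significance_tier(p_adj)))
    return out


def compare_groups(samples: GroupedSamples, method: str = "kruskal-dunn") -> ComparisonResult:
    """Omnibus test plus adjusted pairwise comparisons.

    ``method`` is ``"kruskal-dunn"`` (rank-based) or ``"welch-t3"``
    (Welch + Brown-Forsythe omnibus ANOVAs with Dunnett T3 pairs; the
    reported omnibus statistic is the Welch F).  Every group needs at least
    three observations and non-constant pooled data.
    """
    groups = samples.groups
    if len(groups) < 2:
        raise ValueError("at least two groups are required")
    for label, vals in groups.items():
        if len(vals) < 3:
            raise ValueError(f"group {label!r} has fewer than 3 observations")
    pooled = np.concatenate(list(groups.values()))
    if np.ptp(pooled) == 0:
        raise ValueError("constant data: comparisons are undefined")

    if method == "kruskal-dunn":
        h, p = stats.kruskal(*groups.values())
        return ComparisonResult("kruskal-dunn", float(h), float(p), _dunn_pairwise(groups))
    if method == "welch-t3":
        f_w, p_w = _welch_anova(groups)
        # Brown-Forsythe computed as a companion omnibus; Welch reported
        _bf_f, _bf_p = _brown_forsythe_anova(groups)
        return ComparisonResult("welch-t3", f_w, p_w, _t3_pairwise(groups))
    raise ValueError(f"unknown method: {method!r}")


def summarize_metric(samples: GroupedSamples, style: str = "median-IQR") -> pd.DataFrame:
    """Figure-legend style per-group summary table.

    ``style`` is one of ``median-IQR``, ``mean-SEM``, ``mean-SD``,
    ``mean-CI95``.  Quantiles use linear interpolation (type 7).  Returns a
    DataFrame with group, n, location, and spread columns (``spread_low`` /
    ``spread_high`` bounds for IQR and CI styles, a symmetric ``spread``
    for SD/SEM).
    """
    rows = []
    for label, vals in samples.groups.items():
        if len(vals) == 0:
            raise ValueError(f"group {label!r} is empty")
        n = len(vals)
        if style == "median-IQR":
            rows.append({"group": label, "n": n, "location": float(np.median(vals)),
                         "spread_low": float(np.percentile(vals, 25)),
                         "spread_high": float(np.percentile(vals, 75))})
        elif style == "mean-SD":
            rows.append({"group": label, "n": n, "location": float(vals.mean()),
                         "spread": float(vals.std(ddof=1)) if n > 1 else 0.0})
        elif style == "mean-SEM":
            sem = float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
            rows.append({"group": label, "n": n, "location": float(vals.mean()),
                         "spread": sem})
        elif style == "mean-CI95":
            sem = vals.std(ddof=1) / np.sqrt(n) if n > 1 else 0.0
            half = float(stats.t.ppf(0.975, n - 1) * sem) if n > 1 else 0.0
            mean = float(vals.mean())
            rows.append({"group": label, "n": n, "location": mean,
                         "spread_low": mean - half, "spread_high": mean + half})
        else:
            raise ValueError(f"unknown style: {style!r}")
    return pd.DataFrame(rows)
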