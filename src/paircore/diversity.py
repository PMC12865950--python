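"""Alpha diversity: SRS depth normalisation and gated group tests.

Counts are normalised by scaling with ranked subsampling (SRS): each
column is scaled to the target depth Cmin, integer parts are kept, and
the remaining reads are allocated one each to the taxa with the largest
fractional parts (ties broken uniformly at random).  Shannon and
Gini-Simpson indices are then compared between groups with a
normality-gated choice between the paired/unpaired t test and its rank
counterpart, mirroring common practice in clinical microbiome studies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Mapping

import numpy as np
from scipy import stats

from .data_model import AbundanceTable, CohortMetadata, PairMap

GATE_ALPHA = 0.05  # Shapiro-Wilk / Levene gate


@dataclass
class SubsampleSpec:
    c_min: int = 1000
    policy: Literal["lowest_sample", "fixed"] = "fixed"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.c_min < 1:
            raise ValueError("c_min must be >= 1")


@dataclass
class AlphaResult:
    index: str
    per_sample: dict[str, float]
    test_used: str
    p_value: float
    ci_95: tuple[float, float] | None
    excluded_samples: list[str] = field(default_factory=list)
    statistic: float | None = None
    gate_shapiro_p: float | None = None
    gate_levene_p: float | None = None


def srs_column(col: np.ndarray, c_min: int,
               rng: np.random.Generator) -> np.ndarray:
    """SRS-normalise one counts column to exactly ``c_min`` reads."""
    depth = int(col.sum())
    if depth == c_min:
        return col.astype(np.int64)
    scaled = col * (c_min / depth)
    base = np.floor(scaled).astype(np.int64)
    remainder = c_min - int(base.sum())
    if remainder:
        frac = scaled - base
        # rank by fractional part, random tie-break: jitter the order
        # by a random permutation then stable-sort on -frac
        order = rng.permutation(len(col))
        by_frac = order[np.argsort(-frac[order], kind="stable")]
        base[by_frac[:remainder]] += 1
    return base


def srs_subsample(t: AbundanceTable, spec: SubsampleSpec,
                  ) -> tuple[AbundanceTable, list[str]]:
    """SRS-normalise every column to Cmin; columns below Cmin are
    dropped and returned in the exclusion list."""
    if t.mode != "counts":
        raise ValueError("srs_subsample requires counts mode")
    depths = t.depths()
    if spec.policy == "lowest_sample":
        c_min = int(depths.min())
    else:
        c_min = int(spec.c_min)
    excluded = [s for s in t.samples if depths[s] < c_min]
    kept = [s for s in t.samples if depths[s] >= c_min]
    if not kept:
        raise ValueError("every sample is below the subsampling depth")
    rng = np.random.default_rng(spec.seed)
    X = t.data[kept].to_numpy(dtype=float)
    out = np.empty_like(X, dtype=np.int64)
    for j in range(X.shape[1]):
        out[:, j] = srs_column(X[:, j], c_min, rng)
    df = t.data[kept].copy()
    df.loc[:, :] = out
    return t.with_data(df), excluded


def shannon(column) -> float:
    """Shannon index, natural log, over positive proportions."""
    x = np.asarray(column, dtype=float)
    total = x.sum()
    if total <= 0:
        raise ValueError("column has no positive entries")
    p = x[x > 0] / total
    return float(-(p * np.log(p)).sum())


def simpson(column) -> float:
    """Gini-Simpson index 1 - sum(p_i^2)."""
    x = np.asarray(column, dtype=float)
    total = x.sum()
    if total <= 0:
        raise ValueError("column has no positive entries")
    p = x[x > 0] / total
    return float(1.0 - (p * p).sum())


_INDEX_FUNCS = {"shannon": shannon, "simpson": simpson}


def alpha_indices(t: AbundanceTable, index: str = "shannon",
                  ) -> dict[str, float]:
    fn = _INDEX_FUNCS[index]
    return {s: fn(t.data[s].to_numpy()) for s in t.samples}


def _paired_t_ci(diff: np.ndarray) -> tuple[float, float]:
    n = len(diff)
    se = diff.std(ddof=1) / math.sqrt(n)
    tcrit = stats.t.ppf(0.975, n - 1)
    m = diff.mean()
    return (float(m - tcrit * se), float(m + tcrit * se))


def _unpaired_t_ci(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    se = math.sqrt(sp2 * (1 / na + 1 / nb))
    tcrit = stats.t.ppf(0.975, na + nb - 2)
    d = a.mean() - b.mean()
    return (float(d - tcrit * se), float(d + tcrit * se))


def gated_group_test(values: Mapping[str, float], meta: CohortMetadata,
                     pm: PairMap,
                     mode: Literal["paired", "unpaired",
                                   "paired_on_complete_pairs"] = "paired",
                     index: str = "alpha") -> AlphaResult:
    """Patient-vs-control test with a normality gate.

    Paired modes test pair differences: Shapiro-Wilk on the differences
    gates between the paired t test (with a 95% CI for the mean
    difference) and the Wilcoxon signed-rank test.  Unpaired mode gates
    on per-group Shapiro plus Levene across groups, choosing between
    the two-sample t test and the Wilcoxon rank-sum test.
    ``paired_on_complete_pairs`` first drops pairs with a missing value,
    emulating re-analysis of depth-filtered data.
    """
    have = {s: v for s, v in values.items() if v is not None
            and not np.isnan(v)}
    excluded = [s for s in values if s not in have]

    if mode in ("paired", "paired_on_complete_pairs"):
        pairs = [(p, c) for p, c in pm.pairs if p in have and c in have]
        if mode == "paired":
            broken = [pc for pc in pm.pairs if pc not in pairs]
            if broken:
                raise ValueError(f"pairs with missing values: {broken}; "
                                 "use mode='paired_on_complete_pairs'")
        if len(pairs) < 3:
            raise ValueError("need at least 3 complete pairs")
        diff = np.array([have[p] - have[c] for p, c in pairs])
        excluded += [s for p, c in pm.pairs if (p, c) not in pairs
                     for s in (p, c) if s in have]
        sw_p = float(stats.shapiro(diff).pvalue) if len(diff) >= 3 else 0.0
        if np.allclose(diff, 0):
            return AlphaResult(index, dict(have), "wilcoxon_signed_rank",
                               1.0, None, excluded,
                               statistic=0.0, gate_shapiro_p=None)
        if sw_p > GATE_ALPHA:
            res = stats.ttest_rel(diff, np.zeros_like(diff))
            return AlphaResult(index, dict(have), "paired_t",
                               float(res.pvalue), _paired_t_ci(diff),
                               excluded, statistic=float(res.statistic),
                               gate_shapiro_p=sw_p)
        res = stats.wilcoxon(diff)
        return AlphaResult(index, dict(have), "wilcoxon_signed_rank",
                           float(res.pvalue), None, excluded,
                           statistic=float(res.statistic),
                           gate_shapiro_p=sw_p)

    if mode != "unpaired":
        raise ValueError(f"unknown mode {mode!r}")
    groups = {s: meta.group_of(s) for s in have}
    a = np.array([v for s, v in have.items() if groups[s] == "patient"])
    b = np.array([v for s, v in have.items() if groups[s] == "control"])
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 samples per group")
    sw_a = float(stats.shapiro(a).pvalue) if len(a) >= 3 else 0.0
    sw_b = float(stats.shapiro(b).pvalue) if len(b) >= 3 else 0.0
    lev = float(stats.levene(a, b).pvalue)
    if min(sw_a, sw_b) > GATE_ALPHA and lev > GATE_ALPHA:
        res = stats.ttest_ind(a, b, equal_var=True)
        return AlphaResult(index, dict(have), "unpaired_t",
                           float(res.pvalue), _unpaired_t_ci(a, b),
                           excluded, statistic=float(res.statistic),
                           gate_shapiro_p=min(sw_a, sw_b), gate_levene_p=lev)
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return AlphaResult(index, dict(have), "wilcoxon_rank_sum",
                       float(res.pvalue), None, excluded,
                       statistic=float(res.statistic),
                       gate_shapiro_p=min(sw_a, sw_b), gate_levene_p=lev)
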