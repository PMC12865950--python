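"""Distance-matrix machinery for beta diversity and platform comparison.

Bray-Curtis dissimilarity, classical PCoA, PERMANOVA with block-
restricted permutations (within-pair patient/control label swaps, the
exchangeable scheme for a paired design), a beta-dispersion test of
within-group spread, Mantel tests between platform distance matrices
and taxon-overlap (Venn) accounting.

PERMANOVA uses sequential (Type I) partitioning of the Gower-centred
distance matrix with the group term entered last after the covariates,
so the group test is covariate-adjusted.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Callable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata

from .data_model import (AbundanceTable, CohortMetadata, PairMap, to_relative,
                         filter_mean_abundance, align_tables)
from .da_engines import bh_adjust


@dataclass
class DistanceMatrix:
    ids: list[str]
    matrix: np.ndarray
    metric: str = "bray_curtis"

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape does not match ids")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValueError("distance matrix not symmetric")
        if np.abs(np.diag(m)).max(initial=0.0) > 1e-12:
            raise ValueError("distance matrix diagonal not zero")
        if m.size and m.min() < 0:
            raise ValueError("negative distances")
        self.matrix = m

    def reorder(self, ids: Sequence[str]) -> "DistanceMatrix":
        idx = [self.ids.index(s) for s in ids]
        return DistanceMatrix(list(ids), self.matrix[np.ix_(idx, idx)],
                              self.metric)

    def condensed(self) -> np.ndarray:
        return squareform(self.matrix, checks=False)


def bray_curtis_matrix(t: AbundanceTable) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity over sample columns,
    d(x, y) = 1 - 2 sum(min(x, y)) / (sum(x) + sum(y))."""
    X = t.data.to_numpy(dtype=float).T
    sums = X.sum(axis=1)
    if (sums <= 0).sum() >= 2:
        raise ValueError("Bray-Curtis undefined between all-zero samples")
    d = squareform(pdist(X, metric="braycurtis"))
    return DistanceMatrix(t.samples, d, "bray_curtis")


# ---------------------------------------------------------------------------
# PCoA


@dataclass
class PCoAResult:
    ids: list[str]
    coordinates: np.ndarray  # samples x axes (positive eigenvalues only)
    eigenvalues: np.ndarray  # all eigenvalues, descending
    negative_eigenvalues: np.ndarray


def _gower_center(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d ** 2
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return j @ a @ j


def pcoa(d: DistanceMatrix, n_axes: int = 2) -> PCoAResult:
    """Classical scaling: eigendecomposition of the double-centred
    squared-distance matrix.  Axes with negative eigenvalues are
    reported but dropped from the coordinates."""
    g = _gower_center(d.matrix)
    evals, evecs = np.linalg.eigh(g)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = max(1e-10, 1e-10 * abs(evals[0]) if len(evals) else 0)
    pos = evals > tol
    n_pos = int(pos.sum())
    if n_axes > n_pos:
        warnings.warn(f"only {n_pos} positive eigenvalues; truncating "
                      f"requested {n_axes} axes", stacklevel=2)
        n_axes = n_pos
    coords = evecs[:, :n_axes] * np.sqrt(evals[:n_axes])
    return PCoAResult(ids=list(d.ids), coordinates=coords,
                      eigenvalues=evals,
                      negative_eigenvalues=evals[evals < -tol])


# ---------------------------------------------------------------------------
# PERMANOVA with block-restricted permutations


@dataclass
class PermanovaTerm:
    name: str
    df: int
    sum_sq: float
    pseudo_f: float
    p_value: float


@dataclass
class PermanovaResult:
    terms: list[PermanovaTerm]
    residual_df: int
    residual_sum_sq: float
    total_sum_sq: float
    n_permutations: int
    permutation_scheme: str
    exhaustive: bool = False

    def term(self, name: str) -> PermanovaTerm:
        for t in self.terms:
            if t.name == name:
                return t
        raise KeyError(name)


def _hat(x: np.ndarray) -> np.ndarray:
    q, _ = np.linalg.qr(x)
    return q @ q.T


def _design_blocks(meta: CohortMetadata, samples: list[str],
                   covariates: Sequence[str]) -> list[tuple[str, np.ndarray]]:
    sub = meta.subset(samples)
    blocks: list[tuple[str, np.ndarray]] = []
    if covariates:
        cov = sub.covariate_frame(list(covariates))
        for name in covariates:
            cols = [c for c in cov.columns if c == name
                    or c.startswith(f"{name}_")]
            blocks.append((name, cov[cols].to_numpy(dtype=float)))
    grp = (sub.data["group"] == "patient").to_numpy(dtype=float)
    blocks.append(("group", grp[:, None]))
    return blocks


def _sequential_stats(g: np.ndarray, hats: list[np.ndarray],
                      dfs: list[int]) -> tuple[np.ndarray, float]:
    """Sequential term F statistics given nested hat matrices."""
    total = float(np.trace(g))
    model_tr = [float(np.sum(h * g)) for h in hats]  # tr(H G), H symmetric
    ss = np.diff([0.0] + model_tr)
    resid = total - model_tr[-1]
    df_res = g.shape[0] - 1 - sum(dfs)
    f = (ss / np.array(dfs)) / (resid / df_res)
    return f, resid


def permanova_blocked(d: DistanceMatrix, meta: CohortMetadata,
                      covariates: Sequence[str] = (),
                      pm: PairMap | None = None,
                      n_permutations: int = 999,
                      seed: int | None = None,
                      scheme: Literal["within_block_swap", "free"]
                      = "within_block_swap") -> PermanovaResult:
    """Distance-based MANOVA with covariates and restricted permutations.

    Terms are partitioned sequentially (covariates first, group last).
    Under ``within_block_swap`` the null distribution swaps the
    patient/control labels independently within each pair — equivalently
    permutes each pair's two samples — sampling the 2^n_pairs space, or
    enumerating it exhaustively when it is no larger than
    ``n_permutations``.  P values use the add-one estimator (exhaustive
    enumeration includes the identity, giving the same guarantee).
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    samples = list(d.ids)
    sub = meta.subset(samples)
    if covariates:
        cov = sub.covariate_frame(list(covariates))
        complete = cov.notna().all(axis=1)
        if not complete.all():
            dropped = list(cov.index[~complete])
            warnings.warn(f"dropping samples with missing covariates: "
                          f"{dropped}", stacklevel=2)
            samples = [s for s in samples if s not in dropped]
    if scheme == "within_block_swap":
        if pm is None:
            raise ValueError("within_block_swap scheme requires a pair map")
        pmr = pm.restrict(samples)
        if pmr.unpaired:
            samples = [s for s in samples if s not in set(pmr.unpaired)]
            pmr = pmr.restrict(samples)
        if pmr.n_pairs < 3:
            raise ValueError("need at least 3 complete pairs")
        samples = pmr.paired_samples()

    dm = d.reorder(samples)
    g = _gower_center(dm.matrix)
    blocks = _design_blocks(meta, samples, covariates)
    n = len(samples)
    ones = np.ones((n, 1))
    hats, dfs, names = [], [], []
    x = ones
    for name, cols in blocks:
        prev_rank = np.linalg.matrix_rank(x)
        x = np.hstack([x, cols])
        rank = np.linalg.matrix_rank(x)
        hats.append(_hat(x))
        dfs.append(rank - prev_rank)
        names.append(name)
    if min(dfs) < 1:
        raise ValueError("collinear model terms: " +
                         ", ".join(n for n, k in zip(names, dfs) if k < 1))
    f_obs, resid = _sequential_stats(g, hats, dfs)
    total = float(np.trace(g))
    df_res = n - 1 - sum(dfs)

    rng = np.random.default_rng(seed)
    idx = np.arange(n)
    exhaustive = False
    if scheme == "within_block_swap":
        n_pairs = n // 2
        if 2 ** n_pairs <= n_permutations:
            masks = list(itertools.product((0, 1), repeat=n_pairs))
            exhaustive = True
        else:
            masks = [tuple(rng.integers(0, 2, n_pairs))
                     for _ in range(n_permutations)]
        perms = []
        for mask in masks:
            p = idx.copy()
            for j, swap in enumerate(mask):
                if swap:
                    p[2 * j], p[2 * j + 1] = p[2 * j + 1], p[2 * j]
            perms.append(p)
    else:
        perms = [rng.permutation(n) for _ in range(n_permutations)]

    count = np.zeros(len(blocks))
    for p in perms:
        gp = g[np.ix_(p, p)]
        f_p, _ = _sequential_stats(gp, hats, dfs)
        count += f_p >= f_obs - 1e-12
    if exhaustive:
        pvals = count / len(perms)  # identity permutation is included
    else:
        pvals = (count + 1) / (len(perms) + 1)

    terms = [PermanovaTerm(name=names[i], df=dfs[i],
                           sum_sq=float(np.diff([0.0] + [
                               float(np.sum(h * g)) for h in hats])[i]),
                           pseudo_f=float(f_obs[i]), p_value=float(pvals[i]))
             for i in range(len(blocks))]
    return PermanovaResult(terms=terms, residual_df=df_res,
                           residual_sum_sq=float(resid),
                           total_sum_sq=total,
                           n_permutations=len(perms),
                           permutation_scheme=scheme, exhaustive=exhaustive)


# ---------------------------------------------------------------------------
# beta dispersion


@dataclass
class BetaDispersionResult:
    distances: dict[str, float]  # sample -> distance to group centroid
    group_means: dict[str, float]
    f_statistic: float
    p_value: float
    n_permutations: int


def betadisper_test(d: DistanceMatrix, groups: Sequence[str],
                    n_permutations: int = 999,
                    seed: int | None = None) -> BetaDispersionResult:
    """Homogeneity of within-group dispersion.

    Samples are embedded by PCoA keeping all axes; squared distances to
    the group centroid subtract the contribution of negative-eigenvalue
    (imaginary) axes, following the standard correction.  The F
    statistic on centroid distances is tested by freely permuting group
    labels.
    """
    groups = list(groups)
    if len(groups) != len(d.ids):
        raise ValueError("one group label per sample required")
    labels = sorted(set(groups))
    counts = {lab: groups.count(lab) for lab in labels}
    if len(labels) != 2 or min(counts.values()) < 2:
        raise ValueError("need two groups with >= 2 samples each")

    g = _gower_center(d.matrix)
    evals, evecs = np.linalg.eigh(g)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = 1e-10 * max(1.0, abs(evals).max(initial=1.0))
    pos = evals > tol
    neg = evals < -tol
    cr = evecs[:, pos] * np.sqrt(evals[pos])
    ci = evecs[:, neg] * np.sqrt(-evals[neg])

    garr = np.array(groups)

    def centroid_dist(labels_arr: np.ndarray) -> np.ndarray:
        out = np.empty(len(labels_arr))
        for lab in labels:
            m = labels_arr == lab
            dr = cr[m] - cr[m].mean(axis=0)
            di = ci[m] - ci[m].mean(axis=0) if ci.size else np.zeros((m.sum(), 0))
            sq = (dr ** 2).sum(axis=1) - (di ** 2).sum(axis=1)
            out[m] = np.sqrt(np.maximum(sq, 0.0))
        return out

    def f_stat(z: np.ndarray, labels_arr: np.ndarray) -> float:
        grand = z.mean()
        ssb = sum(((z[labels_arr == lab].mean() - grand) ** 2)
                  * (labels_arr == lab).sum() for lab in labels)
        ssw = sum(((z[labels_arr == lab] - z[labels_arr == lab].mean()) ** 2).sum()
                  for lab in labels)
        dfb, dfw = len(labels) - 1, len(z) - len(labels)
        if ssw <= 1e-30:
            return 0.0 if ssb <= 1e-30 else np.inf
        return (ssb / dfb) / (ssw / dfw)

    z_obs = centroid_dist(garr)
    f_obs = f_stat(z_obs, garr)
    if not np.isfinite(f_obs) or (f_obs == 0.0 and np.allclose(z_obs, 0)):
        return BetaDispersionResult(
            distances=dict(zip(d.ids, z_obs)),
            group_means={lab: float(z_obs[garr == lab].mean())
                         for lab in labels},
            f_statistic=float(f_obs if np.isfinite(f_obs) else np.inf),
            p_value=1.0 if np.allclose(z_obs, 0) else 0.0,
            n_permutations=0)

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(garr)
        # dispersion residuals are recomputed under permuted membership
        if f_stat(centroid_dist(perm), perm) >= f_obs - 1e-12:
            count += 1
    p = (1 + count) / (1 + n_permutations)
    return BetaDispersionResult(
        distances=dict(zip(d.ids, z_obs)),
        group_means={lab: float(z_obs[garr == lab].mean()) for lab in labels},
        f_statistic=float(f_obs), p_value=p,
        n_permutations=n_permutations)


# ---------------------------------------------------------------------------
# Mantel tests and platform comparison


def _lower(m: np.ndarray) -> np.ndarray:
    i, j = np.tril_indices(m.shape[0], k=-1)
    return m[i, j]


def mantel(d1: DistanceMatrix, d2: DistanceMatrix,
           correlation: Literal["pearson", "spearman"] = "pearson",
           n_permutations: int = 999,
           seed: int | None = None) -> tuple[float, float]:
    """Mantel correlation between two distance matrices over the same
    samples; one-sided (positive association) permutation p value."""
    if set(d1.ids) != set(d2.ids):
        raise ValueError("sample sets differ")
    d2 = d2.reorder(d1.ids)
    x = _lower(d1.matrix)
    m2 = d2.matrix
    if correlation == "spearman":
        x = rankdata(x)

    def corr_with(m: np.ndarray) -> float:
        y = _lower(m)
        if correlation == "spearman":
            y = rankdata(y)
        xc, yc = x - x.mean(), y - y.mean()
        denom = np.sqrt((xc ** 2).sum() * (yc ** 2).sum())
        return float((xc * yc).sum() / denom) if denom > 0 else 0.0

    r_obs = corr_with(m2)
    rng = np.random.default_rng(seed)
    n = m2.shape[0]
    count = 0
    for _ in range(n_permutations):
        p = rng.permutation(n)
        if corr_with(m2[np.ix_(p, p)]) >= r_obs - 1e-12:
            count += 1
    return r_obs, (1 + count) / (1 + n_permutations)


def _prevalence_collapsed(t: AbundanceTable,
                          min_prevalence: float = 0.30) -> AbundanceTable:
    """Prevalence filter with removed taxa summed into an Others row so
    relative columns keep summing to one (as in the platform-comparison
    filtering)."""
    prev = (t.data > 0).mean(axis=1)
    keep = prev >= min_prevalence
    kept = t.data.loc[keep]
    others = t.data.loc[~keep].sum(axis=0)
    df = pd.concat([kept, others.to_frame("Others").T])
    df.index.name = t.data.index.name
    return t.with_data(df)


FILTERS: dict[str, Callable[[AbundanceTable], AbundanceTable]] = {
    "none": lambda t: t,
    "mean_abundance": lambda t: filter_mean_abundance(
        t, 0.001, collapse_others=True),
    "prevalence": _prevalence_collapsed,
}


def mantel_panel(tables: Sequence[AbundanceTable],
                 filters: Sequence[str] = ("none", "mean_abundance",
                                           "prevalence"),
                 correlations: Sequence[str] = ("pearson", "spearman"),
                 n_permutations: int = 999,
                 seed: int | None = None) -> pd.DataFrame:
    """All pairwise platform Mantel tests per filter and correlation,
    BH-adjusted across the whole panel."""
    if len(tables) < 2:
        raise ValueError("need at least 2 platform tables")
    rows = []
    rng = np.random.default_rng(seed)
    for flt in filters:
        rel = [FILTERS[flt](to_relative(t)) for t in tables]
        rel = align_tables(rel, sample_policy="intersect")
        dms = {t.platform: bray_curtis_matrix(t) for t in rel}
        for (pa, da), (pb, db) in itertools.combinations(dms.items(), 2):
            for corr in correlations:
                r, p = mantel(da, db, correlation=corr,
                              n_permutations=n_permutations,
                              seed=int(rng.integers(2 ** 31)))
                rows.append(dict(filter=flt, platform_a=pa, platform_b=pb,
                                 correlation=corr, mantel_r=r, p=p))
    out = pd.DataFrame(rows)
    out["p_adjusted"] = bh_adjust(out["p"].tolist())
    return out


def taxon_overlap(tables: Sequence[AbundanceTable],
                  filter_name: str = "none") -> dict:
    """Venn-region counts of post-filter taxon sets across platforms.

    Regions are keyed by the subset of platforms detecting the taxa;
    ``Others`` rows never enter the sets.  ``shared_fraction`` is the
    share of the union detected by every platform.
    """
    ranks = {t.rank for t in tables}
    if len(ranks) > 1:
        raise ValueError("tables have mixed ranks")
    flt = FILTERS[filter_name]
    sets = {}
    for t in tables:
        ft = flt(to_relative(t)) if filter_name != "none" else t
        sets[t.platform] = {name for name in ft.taxa
                            if (ft.data.loc[name] > 0).any()
                            and not name.startswith("Others")}
    platforms = list(sets)
    union = set().union(*sets.values())
    regions = {}
    for r in range(1, len(platforms) + 1):
        for combo in itertools.combinations(platforms, r):
            inside = set.intersection(*(sets[p] for p in combo))
            outside = set().union(*(sets[p] for p in platforms
                                    if p not in combo)) if r < len(platforms) \
                else set()
            regions[combo] = len(inside - outside)
    full = set.intersection(*sets.values()) if sets else set()
    return {
        "regions": regions,
        "union_size": len(union),
        "all_platforms": len(full),
        "shared_fraction": (len(full) / len(union)) if union else 0.0,
        "per_platform": {p: len(s) for p, s in sets.items()},
    }
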