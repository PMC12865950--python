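"""Intra-pair similarity and the co-housing permutation test.

Partners sharing a household are expected to harbour more similar
microbiota than random patient/control pairings.  The test compares the
mean intra-pair similarity (Pearson or Spearman correlation of relative
abundances, or Bray-Curtis distance) against a null built from random
perfect matchings between the patient and control sets, which keeps the
group structure of the design intact.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from scipy.stats import rankdata

from .data_model import AbundanceTable, PairMap

SIMILARITY_METRICS = ("pearson", "spearman", "bray_curtis")


@dataclass
class PairSimilarityResult:
    metric: str
    per_pair_values: dict[str, float]
    observed_mean: float
    permuted_means: list[float]
    p_value: float
    n_permutations: int
    two_sided: bool = False
    filtered_top_k: int | None = None


def top_k_filter(t: AbundanceTable, k: int = 100) -> AbundanceTable:
    """Keep the k taxa with highest mean relative abundance.

    Ties at the cut are broken by taxon-name order; abundances are not
    renormalised afterwards.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if t.mode != "relative":
        raise ValueError("top_k_filter requires relative mode")
    if t.n_taxa <= k:
        return t
    means = t.data.mean(axis=1)
    order = sorted(t.taxa, key=lambda name: (-means[name], name))
    keep = set(order[:k])
    return t.with_data(t.data.loc[[n for n in t.taxa if n in keep]],
                       strict=False)


def _metric_matrix(t: AbundanceTable, patients: list[str],
                   controls: list[str], metric: str) -> np.ndarray:
    """All patient x control metric values, computed in one shot."""
    X = t.data[patients].to_numpy(dtype=float).T   # n_pat x taxa
    Y = t.data[controls].to_numpy(dtype=float).T
    if metric == "bray_curtis":
        return cdist(X, Y, metric="braycurtis")
    if metric == "spearman":
        X = rankdata(X, axis=1)
        Y = rankdata(Y, axis=1)
    elif metric != "pearson":
        raise ValueError(f"unknown metric {metric!r}")
    Xc = X - X.mean(axis=1, keepdims=True)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    xn = np.linalg.norm(Xc, axis=1)
    yn = np.linalg.norm(Yc, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc @ Yc.T) / np.outer(xn, yn)
    return r


def intra_pair_values(t: AbundanceTable, pm: PairMap,
                      metric: str = "bray_curtis") -> dict[str, float]:
    """One similarity/distance per pair, over the union of taxa
    (zeros included).  Pairs missing a sample are skipped with a warning."""
    if t.mode != "relative":
        raise ValueError("intra_pair_values requires relative mode")
    present = set(t.samples)
    pairs = [(p, c) for p, c in pm.pairs if p in present and c in present]
    skipped = [pc for pc in pm.pairs if pc not in pairs]
    if skipped:
        warnings.warn(f"skipping pairs with missing samples: {skipped}",
                      stacklevel=2)
    if not pairs:
        return {}
    pats = [p for p, _ in pairs]
    ctls = [c for _, c in pairs]
    M = _metric_matrix(t, pats, ctls, metric)
    return {p: float(M[i, i]) for i, (p, _) in enumerate(pairs)}


def pair_permutation_test(t: AbundanceTable, pm: PairMap,
                          metric: str = "bray_curtis",
                          n_permutations: int = 1000,
                          seed: int | None = None,
                          two_sided: bool = False,
                          top_k: int | None = None) -> PairSimilarityResult:
    """Permutation test of intra-pair similarity vs random matchings.

    Each permutation draws a uniform random perfect matching between
    the patient and control sets.  One-sided by default, in the
    co-housing direction: higher correlation / lower distance than the
    permuted matchings counts as extreme.  The add-one estimator
    ``p = (1 + #extreme) / (1 + n_permutations)`` is used.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    if top_k is not None:
        t = top_k_filter(t, top_k)
    present = set(t.samples)
    pairs = [(p, c) for p, c in pm.pairs if p in present and c in present]
    if len(pairs) < 3:
        raise ValueError("need at least 3 complete pairs")
    pats = [p for p, _ in pairs]
    ctls = [c for _, c in pairs]
    M = _metric_matrix(t, pats, ctls, metric)
    n = len(pairs)
    observed = float(np.trace(M) / n)
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(n) for _ in range(n_permutations)])
    permuted = M[np.arange(n)[None, :], perms].mean(axis=1)

    if metric == "bray_curtis":
        extreme = permuted <= observed  # co-housing: smaller distance
    else:
        extreme = permuted >= observed
    if two_sided:
        centred = np.abs(permuted - permuted.mean())
        extreme = centred >= abs(observed - permuted.mean())
    p = (1 + int(extreme.sum())) / (1 + n_permutations)
    return PairSimilarityResult(
        metric=metric,
        per_pair_values={p_: float(M[i, i]) for i, (p_, _) in enumerate(pairs)},
        observed_mean=observed,
        permuted_means=[float(x) for x in permuted],
        p_value=p,
        n_permutations=n_permutations,
        two_sided=two_sided,
        filtered_top_k=top_k,
    )
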