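import itertools

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix as SkbioDM
from skbio.stats.distance import mantel as skbio_mantel, permanova as skbio_permanova

from paircore import (DistanceMatrix, PairMap, betadisper_test,
                      bray_curtis_matrix, mantel, mantel_panel, pcoa,
                      permanova_blocked, taxon_overlap, to_relative)
from paircore.data_model import CohortMetadata

from conftest import table_from

import pandas as pd


class TestBrayCurtis:
    def test_identical_columns_zero(self):
        d = bray_curtis_matrix(table_from([[2, 2], [3, 3]]))
        assert d.matrix[0, 1] == pytest.approx(0.0)

    def test_disjoint_support_one(self):
        d = bray_curtis_matrix(table_from([[2, 0], [0, 3]]))
        assert d.matrix[0, 1] == pytest.approx(1.0)

    def test_hand_value(self):
        # (2,2,0) vs (0,2,2): 1 - 2*2/8 = 0.5
        d = bray_curtis_matrix(table_from([[2, 0], [2, 2], [0, 2]]))
        assert d.matrix[0, 1] == pytest.approx(0.5)

    def test_bounds_and_symmetry(self):
        rng = np.random.default_rng(0)
        t = table_from(rng.integers(0, 20, (10, 6)))
        d = bray_curtis_matrix(t)
        assert (d.matrix <= 1 + 1e-12).all()
        assert np.allclose(d.matrix, d.matrix.T)


class TestPCoA:
    def test_three_equidistant_points(self):
        m = np.ones((3, 3)) - np.eye(3)
        res = pcoa(DistanceMatrix(["a", "b", "c"], m), 2)
        ev = res.eigenvalues
        assert ev[0] == pytest.approx(ev[1])
        assert ev[0] > 0

    def test_two_points_give_plus_minus_half_distance(self):
        m = np.array([[0.0, 2.0], [2.0, 0.0]])
        res = pcoa(DistanceMatrix(["a", "b"], m), 1)
        assert sorted(res.coordinates[:, 0]) == pytest.approx([-1.0, 1.0])

    def test_euclidean_reconstruction(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(6, 3))
        m = squareform(pdist(x))
        res = pcoa(DistanceMatrix([f"s{i}" for i in range(6)], m), 5)
        rec = squareform(pdist(res.coordinates))
        assert np.allclose(rec, m, atol=1e-8)

    def test_axes_truncated_with_warning(self):
        m = np.array([[0.0, 2.0], [2.0, 0.0]])
        with pytest.warns(UserWarning):
            res = pcoa(DistanceMatrix(["a", "b"], m), 5)
        assert res.coordinates.shape[1] == 1


def _paired_setup(n_pairs, seed, effect=0.0):
    rng = np.random.default_rng(seed)
    taxa = 12
    base = rng.normal(0, 1, (n_pairs, taxa))
    rows, ids, pairs = [], [], []
    for i in range(n_pairs):
        pat = base[i] + rng.normal(0, 0.5, taxa)
        pat[:3] += effect
        ctl = base[i] + rng.normal(0, 0.5, taxa)
        rows += [np.exp(pat), np.exp(ctl)]
        ids += [f"p{i}", f"c{i}"]
        pairs.append((f"p{i}", f"c{i}"))
    X = np.vstack(rows)
    X /= X.sum(axis=1, keepdims=True)
    d = DistanceMatrix(ids, squareform(pdist(X, "braycurtis")))
    meta_rows = []
    for i in range(n_pairs):
        meta_rows.append(dict(sample_id=f"p{i}", subject_id=f"p{i}",
                              pair_id=f"q{i}", group="patient",
                              age=60 + i, sex="m",
                              bmi=float(24 + rng.normal(0, 2))))
        meta_rows.append(dict(sample_id=f"c{i}", subject_id=f"c{i}",
                              pair_id=f"q{i}", group="control",
                              age=61 + i, sex="f",
                              bmi=float(24 + rng.normal(0, 2))))
    meta = CohortMetadata(pd.DataFrame(meta_rows).set_index("sample_id"))
    return d, meta, PairMap(pairs)


def brute_force_blocked_p(d, pairs_idx, f_obs_fn):
    """Exhaustively enumerate within-pair swaps and count F >= observed."""
    n_pairs = len(pairs_idx)
    f_obs = f_obs_fn(np.arange(2 * n_pairs))
    count = 0
    total = 0
    for mask in itertools.product((0, 1), repeat=n_pairs):
        idx = np.arange(2 * n_pairs)
        for j, swap in enumerate(mask):
            if swap:
                idx[2 * j], idx[2 * j + 1] = idx[2 * j + 1], idx[2 * j]
        total += 1
        if f_obs_fn(idx) >= f_obs - 1e-12:
            count += 1
    return count / total


class TestPermanova:
    def test_exhaustive_three_pairs_matches_enumeration_oracle(self):
        d, meta, pm = _paired_setup(3, seed=2, effect=1.0)
        res = permanova_blocked(d, meta, covariates=(), pm=pm,
                                n_permutations=999, seed=0)
        assert res.exhaustive
        grp = res.term("group")
        assert grp.p_value * 8 == pytest.approx(round(grp.p_value * 8))

        # independent oracle: direct within/between sum-of-squares formula
        m = d.matrix

        def f_of(idx):
            mm = m[np.ix_(idx, idx)]
            n = mm.shape[0]
            sst = (mm ** 2).sum() / (2 * n)
            pat = np.arange(0, n, 2)
            ctl = np.arange(1, n, 2)
            ssw = 0.0
            for g in (pat, ctl):
                sub = mm[np.ix_(g, g)]
                ssw += (sub ** 2).sum() / (2 * len(g))
            ssa = sst - ssw
            return (ssa / 1) / (ssw / (n - 2))

        oracle_p = brute_force_blocked_p(d, list(range(3)), f_of)
        assert grp.p_value == pytest.approx(oracle_p)

    def test_free_scheme_matches_skbio_pseudo_f(self):
        d, meta, pm = _paired_setup(4, seed=5, effect=1.0)
        res = permanova_blocked(d, meta, covariates=(), pm=pm,
                                n_permutations=99, seed=1, scheme="free")
        sk = skbio_permanova(SkbioDM(d.matrix, ids=d.ids),
                             grouping=[meta.group_of(s) for s in d.ids],
                             permutations=99)
        assert res.term("group").pseudo_f == pytest.approx(
            sk["test statistic"], rel=1e-9)

    def test_sum_of_squares_additivity(self):
        d, meta, pm = _paired_setup(6, seed=7)
        res = permanova_blocked(d, meta, covariates=("age", "bmi"), pm=pm,
                                n_permutations=49, seed=0)
        total = sum(t.sum_sq for t in res.terms) + res.residual_sum_sq
        assert total == pytest.approx(res.total_sum_sq, abs=1e-8)

    def test_too_few_pairs_rejected(self):
        d, meta, pm = _paired_setup(2, seed=0)
        with pytest.raises(ValueError):
            permanova_blocked(d, meta, covariates=(), pm=pm)

    def test_group_effect_detected(self):
        d, meta, pm = _paired_setup(12, seed=9, effect=2.0)
        res = permanova_blocked(d, meta, covariates=(), pm=pm,
                                n_permutations=499, seed=3)
        assert res.term("group").p_value <= 0.05


class TestBetadisper:
    def test_all_identical_samples_degenerate(self):
        m = np.zeros((6, 6))
        d = DistanceMatrix([f"s{i}" for i in range(6)], m)
        res = betadisper_test(d, ["a"] * 3 + ["b"] * 3, 99, seed=0)
        assert res.p_value == 1.0
        assert all(v == 0 for v in res.distances.values())

    def test_unequal_spread_detected(self):
        rng = np.random.default_rng(1)
        tight = rng.normal(0, 0.05, (8, 4))
        loose = rng.normal(0, 2.0, (8, 4))
        x = np.vstack([tight, loose])
        d = DistanceMatrix([f"s{i}" for i in range(16)],
                           squareform(pdist(x)))
        res = betadisper_test(d, ["a"] * 8 + ["b"] * 8, 199, seed=2)
        assert res.p_value <= 0.05
        assert res.group_means["b"] > res.group_means["a"]

    def test_singleton_group_rejected(self):
        m = np.ones((3, 3)) - np.eye(3)
        d = DistanceMatrix(["a", "b", "c"], m)
        with pytest.raises(ValueError):
            betadisper_test(d, ["x", "x", "y"])


class TestMantel:
    def _random_dm(self, seed, n=10):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=(n, 4))
        return DistanceMatrix([f"s{i}" for i in range(n)],
                              squareform(pdist(x)))

    def test_self_correlation_is_one(self):
        d = self._random_dm(0)
        r, p = mantel(d, d, n_permutations=99, seed=0)
        assert r == pytest.approx(1.0)
        assert p == pytest.approx(1 / 100)

    def test_affine_invariance(self):
        d = self._random_dm(1)
        d2 = DistanceMatrix(d.ids, 2.0 * d.matrix)
        r, _ = mantel(d, d2, n_permutations=9, seed=0)
        assert r == pytest.approx(1.0)

    def test_spearman_monotone_invariance(self):
        d = self._random_dm(2)
        d2 = DistanceMatrix(d.ids, d.matrix ** 2)
        r, _ = mantel(d, d2, correlation="spearman", n_permutations=9, seed=0)
        assert r == pytest.approx(1.0)

    def test_agrees_with_skbio_statistic(self):
        a, b = self._random_dm(3), self._random_dm(4)
        r, _ = mantel(a, b, n_permutations=9, seed=0)
        r_sk, _, _ = skbio_mantel(SkbioDM(a.matrix, ids=a.ids),
                                  SkbioDM(b.matrix, ids=b.ids),
                                  permutations=0)
        assert r == pytest.approx(float(r_sk), rel=1e-9)

    def test_mismatched_samples_rejected(self):
        a = self._random_dm(5)
        b = DistanceMatrix([f"x{i}" for i in range(10)], a.matrix)
        with pytest.raises(ValueError):
            mantel(a, b)


class TestMantelPanel:
    def test_identical_platforms_give_unit_correlations(self):
        rng = np.random.default_rng(0)
        x = rng.integers(1, 40, (12, 8))
        a = table_from(x, platform="FL")
        b = table_from(x, platform="SR")
        out = mantel_panel([a, b], filters=("none",), n_permutations=49,
                           seed=1)
        assert np.allclose(out["mantel_r"], 1.0)
        assert set(out.columns) >= {"filter", "platform_a", "platform_b",
                                    "correlation", "mantel_r", "p",
                                    "p_adjusted"}

    def test_schema_constant_across_filters(self):
        rng = np.random.default_rng(1)
        a = table_from(rng.integers(0, 60, (15, 10)), platform="FL")
        b = table_from(rng.integers(0, 60, (15, 10)), platform="SR")
        out = mantel_panel([a, b], n_permutations=19, seed=2)
        assert len(out) == 3 * 2  # filters x correlations for one pair
        assert (out["p_adjusted"] >= out["p"] - 1e-12).all()


class TestTaxonOverlap:
    def _tables(self, sets):
        out = []
        for i, s in enumerate(sets):
            taxa = sorted(s)
            x = np.ones((len(taxa), 2))
            out.append(table_from(x, taxa=taxa, platform=f"P{i}"))
        return out

    def test_hand_example(self):
        res = taxon_overlap(self._tables([{"A", "B", "C"},
                                          {"B", "C", "D"},
                                          {"C", "D", "E"}]))
        assert res["all_platforms"] == 1
        assert res["union_size"] == 5
        assert res["shared_fraction"] == pytest.approx(0.2)

    def test_identical_sets_full_overlap(self):
        res = taxon_overlap(self._tables([{"A", "B"}, {"A", "B"}]))
        assert res["shared_fraction"] == 1.0

    def test_disjoint_sets_zero_overlap(self):
        res = taxon_overlap(self._tables([{"A"}, {"B"}]))
        assert res["all_platforms"] == 0
        assert res["shared_fraction"] == 0.0

    def test_region_counts_sum_to_union(self):
        res = taxon_overlap(self._tables([{"A", "B", "C"},
                                          {"B", "C", "D"},
                                          {"C", "D", "E"}]))
        assert sum(res["regions"].values()) == res["union_size"]
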