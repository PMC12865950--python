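import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import optimize, special, stats
from statsmodels.stats.multitest import multipletests

from paircore import (CohortMetadata, EngineConfig, bh_adjust, ci_from_t,
                      run_bias_corrected, run_clr_paired,
                      run_linear_covariate, to_relative)
from paircore.da_engines import signed_rank_p, tmm_factors

from conftest import make_spec, table_from
from paircore import generate_cohort


def t_quantile_oracle(q, df):
    """Invert the t CDF by root finding; independent of stats.t.ppf."""
    return optimize.brentq(lambda x: special.stdtr(df, x) - q, -1e4, 1e4,
                           xtol=1e-10)


class TestBH:
    def test_hand_example(self):
        assert bh_adjust([0.01, 0.02, 0.2]) == pytest.approx(
            [0.03, 0.03, 0.2])

    def test_single_value_unchanged(self):
        assert bh_adjust([0.42]) == [0.42]

    def test_ties_stay_equal(self):
        out = bh_adjust([0.05, 0.05, 0.05])
        assert len(set(np.round(out, 12))) == 1

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    @settings(max_examples=60, deadline=None)
    def test_matches_reference_implementation(self, ps):
        ours = bh_adjust(ps)
        ref = multipletests(ps, method="fdr_bh")[1]
        assert np.allclose(ours, ref, atol=1e-12)


class TestCI:
    def test_df42_critical_value(self):
        lo, hi = ci_from_t(0.87, 0.17, 42)
        tcrit = (hi - 0.87) / 0.17
        assert tcrit == pytest.approx(2.0181, abs=1e-3)
        assert (lo, hi) == pytest.approx((0.527, 1.213), abs=1e-3)

    def test_df1_wide_interval(self):
        lo, hi = ci_from_t(0.0, 1.0, 1)
        assert hi == pytest.approx(12.706, abs=1e-3)
        assert lo == pytest.approx(-12.706, abs=1e-3)

    @pytest.mark.parametrize("df", [1, 2, 5, 10, 42, 43, 100, 200])
    def test_matches_inverse_cdf_oracle(self, df):
        _, hi = ci_from_t(0.0, 1.0, df)
        assert hi == pytest.approx(t_quantile_oracle(0.975, df), abs=1e-6)

    def test_nonpositive_se_rejected(self):
        with pytest.raises(ValueError):
            ci_from_t(1.0, 0.0, 10)


class TestSignedRank:
    def test_matches_scipy_normal_approximation(self):
        rng = np.random.default_rng(0)
        D = rng.normal(0.3, 1.0, size=(25, 50))
        ours = signed_rank_p(D)
        ref = np.array([stats.wilcoxon(D[:, j], correction=True,
                                       method="approx").pvalue
                        for j in range(D.shape[1])])
        assert np.allclose(ours, ref, atol=1e-9)

    def test_handles_zero_differences(self):
        d = np.array([0.0, 0.0, 1.0, 2.0, -0.5, 3.0, 1.5, 2.5])
        ours = signed_rank_p(d)[0]
        ref = stats.wilcoxon(d, correction=True, method="approx",
                             zero_method="wilcox").pvalue
        assert ours == pytest.approx(ref, abs=1e-9)


def test_tmm_factors_counter_depth_composition():
    # two samples with identical composition but different depth:
    # factors stay near one (depth handled by library size, not factor)
    x = np.array([[100, 1000], [50, 500], [25, 250]], dtype=float)
    f = tmm_factors(x)
    assert np.allclose(f, 1.0, atol=1e-6)


@pytest.fixture(scope="module")
def strong_cohort():
    return generate_cohort(make_spec(seed=3))


def _saliva(c, platform="FL"):
    t = c.tables[("saliva", platform)]
    return t, c.metadata, c.pair_map_for("saliva")


class TestEngines:
    def test_clr_paired_recovers_truth(self, strong_cohort):
        t, meta, pm = _saliva(strong_cohort)
        recs = run_clr_paired(t, meta, pm,
                              EngineConfig(covariates=(), seed=1))
        sig = {r.taxon: r for r in recs if r.significant}
        truth = set(strong_cohort.disease_taxa + strong_cohort.health_taxa)
        assert len(set(sig) & truth) >= 0.8 * len(truth)
        for tx in strong_cohort.disease_taxa:
            if tx in sig:
                assert sig[tx].direction == "patient"
        for tx in strong_cohort.health_taxa:
            if tx in sig:
                assert sig[tx].direction == "control"

    def test_clr_paired_seed_reproducible(self, strong_cohort):
        t, meta, pm = _saliva(strong_cohort)
        cfg = EngineConfig(covariates=(), seed=9, mc_instances=16)
        a = run_clr_paired(t, meta, pm, cfg)
        b = run_clr_paired(t, meta, pm, cfg)
        assert [r.p for r in a] == [r.p for r in b]

    def test_clr_mean_p_stable_in_mc_instances(self, strong_cohort):
        t, meta, pm = _saliva(strong_cohort)
        a = run_clr_paired(t, meta, pm,
                           EngineConfig(covariates=(), seed=2,
                                        mc_instances=128))
        b = run_clr_paired(t, meta, pm,
                           EngineConfig(covariates=(), seed=12,
                                        mc_instances=256))
        pa = np.array([r.p for r in a])
        pb = np.array([r.p for r in b])
        # doubling the Monte-Carlo depth moves the reported mean p only
        # within its stabilised Monte-Carlo error
        assert abs(pa.mean() - pb.mean()) < 0.01
        assert {r.taxon for r in a if r.significant} == \
            {r.taxon for r in b if r.significant}

    def test_constant_taxon_has_no_signal(self):
        rng = np.random.default_rng(0)
        n_pairs = 10
        x = rng.integers(50, 200, size=(8, 2 * n_pairs))
        x[0, :] = 100  # identical counts everywhere
        samples = [f"p{i}" for i in range(n_pairs)] + \
                  [f"c{i}" for i in range(n_pairs)]
        t = table_from(x, samples=samples)
        rows = []
        for i in range(n_pairs):
            rows.append(dict(sample_id=f"p{i}", subject_id=f"p{i}",
                             pair_id=f"q{i}", group="patient"))
            rows.append(dict(sample_id=f"c{i}", subject_id=f"c{i}",
                             pair_id=f"q{i}", group="control"))
        meta = CohortMetadata(pd.DataFrame(rows).set_index("sample_id"))
        from paircore import PairMap
        pm = PairMap([(f"p{i}", f"c{i}") for i in range(n_pairs)])
        recs = run_clr_paired(t, meta, pm,
                              EngineConfig(covariates=(), seed=0,
                                           mc_instances=32, denom="all"))
        r0 = next(r for r in recs if r.taxon == "t0")
        assert abs(r0.effect) < 0.3
        assert not r0.significant

    def test_linear_covariate_recovers_truth(self, strong_cohort):
        t, meta, pm = _saliva(strong_cohort)
        recs = run_linear_covariate(t, meta, pm,
                                    EngineConfig(covariates=(), seed=1))
        sig = {r.taxon for r in recs if r.significant}
        truth = set(strong_cohort.disease_taxa + strong_cohort.health_taxa)
        assert len(sig & truth) >= 0.8 * len(truth)
        fdr = len(sig - truth) / max(len(sig), 1)
        assert fdr <= 0.2

    def test_linear_label_swap_negates_effects(self, strong_cohort):
        t, meta, pm = _saliva(strong_cohort)
        cfg = EngineConfig(covariates=(), seed=0)
        fwd = run_linear_covariate(t, meta, pm, cfg)
        flipped = meta.data.copy()
        flipped["group"] = flipped["group"].map(
            {"patient": "control", "control": "patient"})
        meta2 = CohortMetadata(flipped)
        from paircore import PairMap
        pm2 = PairMap([(c, p) for p, c in pm.pairs], list(pm.unpaired))
        rev = run_linear_covariate(t, meta2, pm2, cfg)
        f = {r.taxon: r for r in fwd}
        for r in rev:
            assert r.effect == pytest.approx(-f[r.taxon].effect, abs=1e-8)
            if r.significant:
                assert r.direction != f[r.taxon].direction

    def test_collinear_covariate_yields_na_records(self, strong_cohort):
        t, meta, pm = _saliva(strong_cohort)
        dup = meta.data.copy()
        dup["dup"] = (dup["group"] == "patient").astype(float)
        meta2 = CohortMetadata(dup)
        with pytest.warns(UserWarning, match="singular"):
            recs = run_linear_covariate(t, meta2, pm,
                                        EngineConfig(covariates=("dup",),
                                                     seed=0))
        assert all(np.isnan(r.p) for r in recs)

    def test_bias_corrected_recovers_truth(self, strong_cohort):
        t, meta, pm = _saliva(strong_cohort)
        recs = run_bias_corrected(t, meta, EngineConfig(covariates=()))
        sig = {r.taxon for r in recs if r.significant}
        truth = set(strong_cohort.disease_taxa + strong_cohort.health_taxa)
        assert len(sig & truth) >= 0.8 * len(truth)
        assert len(sig - truth) / max(len(sig), 1) <= 0.2

    def test_bias_corrected_structural_zero_flagged(self):
        rng = np.random.default_rng(1)
        n = 10
        x = rng.integers(20, 100, size=(6, 2 * n))
        x[0, n:] = 0      # absent from every control, present in patients
        samples = [f"p{i}" for i in range(n)] + [f"c{i}" for i in range(n)]
        t = table_from(x, samples=samples)
        rows = []
        for i in range(n):
            rows.append(dict(sample_id=f"p{i}", subject_id=f"p{i}",
                             pair_id=f"q{i}", group="patient"))
            rows.append(dict(sample_id=f"c{i}", subject_id=f"c{i}",
                             pair_id=f"q{i}", group="control"))
        meta = CohortMetadata(pd.DataFrame(rows).set_index("sample_id"))
        recs = run_bias_corrected(t, meta, EngineConfig(covariates=()))
        r0 = next(r for r in recs if r.taxon == "t0")
        assert r0.structural_zero
        assert not r0.significant
        assert r0.direction == "patient"

    def test_bias_corrected_sensitivity_consistent_with_endpoint_grids(
            self, strong_cohort):
        """The sweep verdict must equal agreement between reruns pinned
        at the grid endpoints and the main analysis."""
        t, meta, _ = _saliva(strong_cohort, "WGS")
        full = run_bias_corrected(t, meta, EngineConfig(covariates=()))
        lo = run_bias_corrected(t, meta, EngineConfig(
            covariates=(), pseudo_count_grid=(0.01,)))
        hi = run_bias_corrected(t, meta, EngineConfig(
            covariates=(), pseudo_count_grid=(0.5,)))
        flags = {r.taxon: r.sensitivity_passed for r in full}
        lo_f = {r.taxon: r.sensitivity_passed for r in lo}
        hi_f = {r.taxon: r.sensitivity_passed for r in hi}
        for tx, flag in flags.items():
            if flag is None:
                continue
            if flag:
                assert lo_f[tx] and hi_f[tx]
            else:
                assert not (lo_f[tx] and hi_f[tx])
        assert any(v is not None for v in flags.values())


class TestNullBehaviour:
    def test_engines_control_fdr_under_null(self):
        """With no designated effect, the mean false-discovery proportion
        at BH 0.1 stays within the Monte-Carlo band of the target rate."""
        from conftest import null_spec
        fdp = {"clr_paired": [], "linear_covariate": [], "bias_corrected": []}
        n_cohorts = 12
        for seed in range(n_cohorts):
            c = generate_cohort(null_spec(seed=100 + seed, n_taxa=40,
                                          n_pairs=15))
            t, meta, pm = _saliva(c)
            cfg = EngineConfig(covariates=(), seed=seed, mc_instances=64)
            recs = {
                "clr_paired": run_clr_paired(t, meta, pm, cfg),
                "linear_covariate": run_linear_covariate(t, meta, pm, cfg),
                "bias_corrected": run_bias_corrected(t, meta, cfg),
            }
            for eng, rs in recs.items():
                n_sig = sum(r.significant for r in rs)
                fdp[eng].append(1.0 if n_sig else 0.0)
        for eng, vals in fdp.items():
            mean = np.mean(vals)
            band = 2.576 * np.sqrt(0.1 * 0.9 / n_cohorts)
            assert mean <= 0.1 + band, (eng, mean)
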