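"""Differential-abundance engines with a common result schema.

Three deliberately simplified engines cover the statistical roles of
the tool stack commonly combined in microbiome studies:

``clr_paired``
    compositional paired testing: Dirichlet Monte-Carlo resampling of
    each sample's proportions, centred log-ratio transform (optionally
    against a low-variance/high-abundance denominator), and a Wilcoxon
    signed-rank test on within-pair CLR differences, aggregated across
    instances (ALDEx2-style).

``linear_covariate``
    covariate linear modelling of log-CPM responses after TMM-style
    normalisation, with the pair as a fixed blocking factor and
    empirical-Bayes variance shrinkage (limma-style).

``bias_corrected``
    sample-offset bias correction of log counts with zeros treated as
    missing, structural-zero flagging and a pseudo-count sensitivity
    sweep (ANCOM-BC-style).

These are reimplementations of the statistical ideas, not of the
published packages; no numerical parity is intended.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import (AbundanceTable, CohortMetadata, PairMap,
                         filter_low_counts, filter_prevalence)

ENGINES = ("clr_paired", "linear_covariate", "bias_corrected")

#: evidence-table codes for each engine (the vocabulary of the
#: published result tables the consensus caller consumes)
ENGINE_CODE = {"clr_paired": "ALDEX",
               "linear_covariate": "LIMMA",
               "bias_corrected": "ANCOM"}

DEFAULT_COVARIATES = ("age", "sex", "bmi", "smoking", "teeth", "sbi")


class SingularDesignError(ValueError):
    """The model design matrix is rank-deficient."""


def _default_grid() -> tuple[float, ...]:
    return (0.01, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5)


@dataclass
class EngineConfig:
    engine: str = "clr_paired"
    mc_instances: int = 128
    denom: Literal["all", "lvha"] = "lvha"
    alpha_adjusted: float = 0.1
    pseudo_count_grid: tuple[float, ...] = field(default_factory=_default_grid)
    covariates: tuple[str, ...] = DEFAULT_COVARIATES
    paired: bool = True
    min_count: int = 10
    max_low_fraction: float = 0.70
    min_prevalence: float = 0.1
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.mc_instances < 2:
            raise ValueError("mc_instances must be >= 2")
        if not 0 < self.alpha_adjusted < 1:
            raise ValueError("alpha_adjusted must be in (0, 1)")
        grid = tuple(self.pseudo_count_grid)
        if any(b <= a for a, b in zip(grid, grid[1:])):
            raise ValueError("pseudo_count_grid must be strictly ascending")


@dataclass
class DAResultRecord:
    taxon: str
    material: str | None
    platform: str | None
    engine: str
    effect: float
    se: float | None
    effect_size: float | None
    p: float
    p_adjusted: float
    ci_95: tuple[float, float] | None
    direction: str              # "patient" | "control"
    significant: bool
    structural_zero: bool = False
    sensitivity_passed: bool | None = None

    @staticmethod
    def columns() -> list[str]:
        return ["taxon", "material", "platform", "engine", "effect", "se",
                "effect_size", "p", "p_adjusted", "ci_low", "ci_high",
                "direction", "significant", "structural_zero",
                "sensitivity_passed"]


def records_frame(records: Sequence[DAResultRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        lo, hi = r.ci_95 if r.ci_95 is not None else (np.nan, np.nan)
        rows.append([r.taxon, r.material, r.platform, r.engine, r.effect,
                     np.nan if r.se is None else r.se,
                     np.nan if r.effect_size is None else r.effect_size,
                     r.p, r.p_adjusted, lo, hi, r.direction, r.significant,
                     r.structural_zero,
                     "" if r.sensitivity_passed is None
                     else r.sensitivity_passed])
    return pd.DataFrame(rows, columns=DAResultRecord.columns())


# ---------------------------------------------------------------------------
# shared utilities


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p values.

    Monotone, capped at one, returned in the original order.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if np.nanmin(p) < 0 or np.nanmax(p) > 1:
        raise ValueError("p values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return [float(x) for x in out]


def ci_from_t(effect: float, se: float, df: int) -> tuple[float, float]:
    """95% confidence interval effect +/- t_{0.975, df} * se."""
    if se <= 0:
        raise ValueError("se must be positive")
    if df < 1:
        raise ValueError("df must be >= 1")
    tcrit = float(stats.t.ppf(0.975, df))
    return (effect - tcrit * se, effect + tcrit * se)


def signed_rank_p(diffs: np.ndarray) -> np.ndarray:
    """Two-sided Wilcoxon signed-rank p values, one per column.

    Normal approximation with tie correction and continuity correction,
    zeros dropped per column; vectorised across columns for use inside
    the Monte-Carlo loop of the CLR engine.
    """
    d = np.asarray(diffs, dtype=float)
    if d.ndim == 1:
        d = d[:, None]
    n_obs, n_col = d.shape
    p_out = np.ones(n_col)
    nz = d != 0
    n_eff = nz.sum(axis=0)
    absd = np.abs(d)
    absd_masked = np.where(nz, absd, np.inf)  # zeros ranked last, excluded
    ranks = stats.rankdata(absd_masked, axis=0)
    wpos = np.where(nz & (d > 0), ranks, 0.0).sum(axis=0)
    n = n_eff.astype(float)
    mu = n * (n + 1) / 4
    var = n * (n + 1) * (2 * n + 1) / 24
    # tie correction on the non-zero ranks
    for j in np.where(n_eff > 0)[0]:
        vals = absd[nz[:, j], j]
        _, counts = np.unique(vals, return_counts=True)
        var[j] -= (counts ** 3 - counts).sum() / 48
    ok = (n_eff >= 1) & (var > 0)
    z = np.zeros(n_col)
    z[ok] = (np.abs(wpos[ok] - mu[ok]) - 0.5) / np.sqrt(var[ok])
    z = np.maximum(z, 0.0)
    p_out[ok] = 2 * stats.norm.sf(z[ok])
    return np.minimum(p_out, 1.0)


# ---------------------------------------------------------------------------
# engine 1: Dirichlet/CLR paired test


def run_clr_paired(t: AbundanceTable, meta: CohortMetadata, pm: PairMap,
                   cfg: EngineConfig) -> list[DAResultRecord]:
    """Compositional paired engine.

    Per Monte-Carlo instance: draw column-wise Dirichlet(counts + 0.5)
    proportions, CLR-transform against the chosen denominator, test
    within-pair differences per taxon with the Wilcoxon signed-rank
    test, and BH-adjust.  Reported p values are means across instances;
    the effect is the across-instance median of the per-instance median
    pair difference on the CLR scale ("diff.btw").
    """
    ft = filter_low_counts(t, cfg.min_count, cfg.max_low_fraction)
    present = set(ft.samples)
    pairs = [(p, c) for p, c in pm.pairs if p in present and c in present]
    if len(pairs) < 3:
        raise ValueError("need at least 3 complete pairs")
    pats = [p for p, _ in pairs]
    ctls = [c for _, c in pairs]
    X = ft.data[pats + ctls].to_numpy(dtype=float)  # taxa x samples
    n_taxa, n_samp = X.shape
    n_pairs = len(pairs)
    rng = np.random.default_rng(cfg.seed)

    p_sum = np.zeros(n_taxa)
    padj_sum = np.zeros(n_taxa)
    effects = np.empty((cfg.mc_instances, n_taxa))
    spreads = np.empty((cfg.mc_instances, n_taxa))
    for it in range(cfg.mc_instances):
        gam = rng.standard_gamma(X + 0.5)
        prop = gam / gam.sum(axis=0, keepdims=True)
        logp = np.log(prop)
        if cfg.denom == "lvha":
            clr_all = logp - logp.mean(axis=0, keepdims=True)
            v = clr_all.var(axis=1)
            a = prop.mean(axis=1)
            denom_idx = (v <= np.median(v)) & (a >= np.median(a))
            if not denom_idx.any():
                denom_idx = np.ones(n_taxa, dtype=bool)
        else:
            denom_idx = np.ones(n_taxa, dtype=bool)
        clr = logp - logp[denom_idx].mean(axis=0, keepdims=True)
        D = clr[:, :n_pairs] - clr[:, n_pairs:]   # taxa x pairs
        pvals = signed_rank_p(D.T)
        p_sum += pvals
        padj_sum += np.asarray(bh_adjust(pvals))
        effects[it] = np.median(D, axis=1)
        mad = np.median(np.abs(D - np.median(D, axis=1, keepdims=True)),
                        axis=1)
        spreads[it] = mad
    p_mean = p_sum / cfg.mc_instances
    padj_mean = padj_sum / cfg.mc_instances
    diff_btw = np.median(effects, axis=0)
    disp = 1.4826 * np.median(spreads, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        eff_size = np.where(disp > 0, diff_btw / disp, np.sign(diff_btw) * np.inf)

    records = []
    for i, taxon in enumerate(ft.taxa):
        sig = bool(padj_mean[i] <= cfg.alpha_adjusted)
        records.append(DAResultRecord(
            taxon=taxon, material=t.material, platform=t.platform,
            engine="clr_paired", effect=float(diff_btw[i]), se=None,
            effect_size=float(eff_size[i]), p=float(p_mean[i]),
            p_adjusted=float(padj_mean[i]), ci_95=None,
            direction="patient" if diff_btw[i] > 0 else "control",
            significant=sig))
    return records


# ---------------------------------------------------------------------------
# engine 2: covariate linear model with pair blocking


def tmm_factors(X: np.ndarray, trim_m: float = 0.30,
                trim_a: float = 0.05) -> np.ndarray:
    """Trimmed-mean-of-M-values normalisation factors.

    The reference is the column whose upper quartile (library-size
    scaled) is closest to the mean upper quartile.  Factors are trimmed
    means of per-taxon log2 ratios to the reference (30% on M, 5% on A);
    when a column shares no positive taxa with the reference the
    singleton fallback factor 1 is used.
    """
    lib = X.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        uq = np.array([np.quantile(X[:, j][X[:, j] > 0] / lib[j], 0.75)
                       if (X[:, j] > 0).any() else 0.0
                       for j in range(X.shape[1])])
    ref = int(np.argmin(np.abs(uq - uq.mean())))
    f = np.ones(X.shape[1])
    xr = X[:, ref] / lib[ref]
    for j in range(X.shape[1]):
        xj = X[:, j] / lib[j]
        both = (xj > 0) & (xr > 0)
        if not both.any():
            continue  # singleton fallback
        m = np.log2(xj[both] / xr[both])
        a = 0.5 * np.log2(xj[both] * xr[both])
        keep = np.ones(m.size, dtype=bool)
        if m.size >= 10:
            lo_m, hi_m = np.quantile(m, [trim_m, 1 - trim_m])
            lo_a, hi_a = np.quantile(a, [trim_a, 1 - trim_a])
            keep = (m >= lo_m) & (m <= hi_m) & (a >= lo_a) & (a <= hi_a)
            if not keep.any():
                keep = np.ones(m.size, dtype=bool)
        f[j] = 2 ** m[keep].mean()
    # factors multiply to one by convention
    f /= np.exp(np.mean(np.log(f)))
    return f


def _eb_shrink(s2: np.ndarray, df: int) -> tuple[np.ndarray, float]:
    """Method-of-moments empirical-Bayes shrinkage of residual variances
    toward their mean; returns posterior variances and the prior df."""
    s2 = np.asarray(s2, dtype=float)
    s0 = s2.mean()
    excess = s2.var(ddof=1) - 2 * s0 ** 2 / df if s2.size > 1 else 0.0
    if excess <= 0:
        d0 = 1e6  # variances consistent with a common value
    else:
        d0 = max(2 * s0 ** 2 / excess * (df + 2) / df, 1.0)
    post = (d0 * s0 + df * s2) / (d0 + df)
    return post, float(d0)


def _design_matrix(meta: CohortMetadata, samples: list[str],
                   covariates: Sequence[str],
                   pair_ids: Sequence[str] | None,
                   extra: pd.DataFrame | None = None,
                   ) -> tuple[np.ndarray, list[str], int, list[str]]:
    """Build [intercept | covariates | extra | pair dummies | group].

    Returns the matrix, its column names, the index of the group
    column and the retained (complete-case) samples.
    """
    sub = meta.subset(samples)
    cov = sub.covariate_frame(list(covariates))
    if extra is not None:
        cov = pd.concat([cov, extra.loc[sub.data.index]], axis=1)
    complete = cov.notna().all(axis=1) if cov.shape[1] else pd.Series(
        True, index=sub.data.index)
    kept = list(cov.index[complete])
    if len(kept) < len(samples):
        warnings.warn("dropping samples with missing covariates: "
                      f"{sorted(set(samples) - set(kept))}", stacklevel=3)
    sub = meta.subset(kept)
    cov = cov.loc[kept]
    cols = [np.ones((len(kept), 1))]
    names = ["intercept"]
    for c in cov.columns:
        cols.append(cov[c].to_numpy(dtype=float)[:, None])
        names.append(str(c))
    if pair_ids is not None:
        pid = pd.Series(pair_ids, index=samples).loc[kept]
        dummies = pd.get_dummies(pid, prefix="pair", drop_first=True,
                                 dtype=float)
        for c in dummies.columns:
            cols.append(dummies[c].to_numpy()[:, None])
            names.append(str(c))
    grp = (sub.data["group"] == "patient").to_numpy(dtype=float)
    cols.append(grp[:, None])
    names.append("group")
    Xd = np.hstack(cols)
    return Xd, names, len(names) - 1, kept


def run_linear_covariate(t: AbundanceTable, meta: CohortMetadata,
                         pm: PairMap | None,
                         cfg: EngineConfig) -> list[DAResultRecord]:
    """Covariate linear-model engine on TMM-normalised log2 CPM.

    Per-taxon OLS of log2 CPM on group + covariates with pair fixed
    effects as the blocking factor; residual variances are shrunk toward
    their mean (method-of-moments empirical Bayes) and the group
    coefficient tested with a moderated t statistic.  A singular design
    yields NA records for every taxon.
    """
    ft = filter_low_counts(t, cfg.min_count, cfg.max_low_fraction)
    if cfg.paired:
        if pm is None:
            raise ValueError("paired engine requires a pair map")
        present = set(ft.samples)
        pairs = [(p, c) for p, c in pm.pairs
                 if p in present and c in present]
        if len(pairs) < 3:
            raise ValueError("need at least 3 complete pairs")
        samples = [s for pc in pairs for s in pc]
        pair_ids = [f"b{i}" for i in range(len(pairs)) for _ in range(2)]
    else:
        samples = list(ft.samples)
        pair_ids = None

    Xd, names, gi, kept = _design_matrix(meta, samples, cfg.covariates,
                                         pair_ids)
    counts = ft.data[kept].to_numpy(dtype=float)
    lib = counts.sum(axis=0)
    eff_lib = lib * tmm_factors(counts)
    Y = np.log2((counts + 0.5) / (eff_lib + 1.0) * 1e6)  # taxa x samples

    n, p_cols = Xd.shape
    rank = np.linalg.matrix_rank(Xd)
    if rank < p_cols:
        warnings.warn("singular design matrix; all taxa reported NA",
                      stacklevel=2)
        return [DAResultRecord(
            taxon=tx, material=t.material, platform=t.platform,
            engine="linear_covariate", effect=float("nan"), se=None,
            effect_size=None, p=float("nan"), p_adjusted=float("nan"),
            ci_95=None, direction="patient", significant=False)
            for tx in ft.taxa]
    df_res = n - p_cols
    if df_res < 1:
        raise SingularDesignError("no residual degrees of freedom")
    pinv = np.linalg.pinv(Xd)
    B = pinv @ Y.T                       # p_cols x taxa
    resid = Y.T - Xd @ B
    s2 = (resid ** 2).sum(axis=0) / df_res
    xtx_inv = np.linalg.inv(Xd.T @ Xd)
    v_g = xtx_inv[gi, gi]
    s2_post, d0 = _eb_shrink(s2, df_res)
    df_mod = df_res + min(d0, 1e6)
    se = np.sqrt(s2_post * v_g)
    beta = B[gi]
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = beta / se
    pvals = 2 * stats.t.sf(np.abs(tstat), df_mod)
    padj = bh_adjust(pvals)
    records = []
    for i, taxon in enumerate(ft.taxa):
        ci = ci_from_t(float(beta[i]), float(se[i]), int(df_res)) \
            if se[i] > 0 else None
        records.append(DAResultRecord(
            taxon=taxon, material=t.material, platform=t.platform,
            engine="linear_covariate", effect=float(beta[i]),
            se=float(se[i]), effect_size=float(tstat[i]),
            p=float(pvals[i]), p_adjusted=float(padj[i]), ci_95=ci,
            direction="patient" if beta[i] > 0 else "control",
            significant=bool(padj[i] <= cfg.alpha_adjusted)))
    return records


# ---------------------------------------------------------------------------
# engine 3: bias-corrected log-linear model


def _ols_group_test(y: np.ndarray, Xd: np.ndarray, gi: int,
                    ) -> tuple[float, float, float, int]:
    """OLS fit returning (beta_group, se, p, df)."""
    n, p_cols = Xd.shape
    df = n - p_cols
    if df < 1:
        return np.nan, np.nan, np.nan, 0
    beta, *_ = np.linalg.lstsq(Xd, y, rcond=None)
    resid = y - Xd @ beta
    s2 = (resid ** 2).sum() / df
    xtx = Xd.T @ Xd
    try:
        v = np.linalg.inv(xtx)[gi, gi]
    except np.linalg.LinAlgError:
        return np.nan, np.nan, np.nan, 0
    se = math.sqrt(max(s2 * v, 0.0))
    if se == 0:
        return float(beta[gi]), 0.0, 1.0, df
    tstat = beta[gi] / se
    return float(beta[gi]), float(se), float(2 * stats.t.sf(abs(tstat), df)), df


def run_bias_corrected(t: AbundanceTable, meta: CohortMetadata,
                       cfg: EngineConfig) -> list[DAResultRecord]:
    """Bias-corrected engine (unpaired; pairing is not modelled).

    After a prevalence filter, structural zeros (taxa absent from one
    whole group) are flagged and excluded from modelling.  Zeros are
    treated as missing on the log scale; per-sample offsets (median
    across taxa of log count minus the taxon's grand mean) absorb
    sequencing-depth and sample-specific bias, and each taxon's
    offset-adjusted log counts are regressed on group + covariates.
    The pseudo-count sensitivity sweep refits with zeros replaced by
    each grid value; a taxon passes when its significance verdict is
    identical across the whole grid.
    """
    ft = filter_prevalence(t, cfg.min_prevalence)
    ft = ft.with_data(ft.data.loc[(ft.data > 0).any(axis=1)])
    Xd, names, gi, kept = _design_matrix(meta, ft.samples, cfg.covariates,
                                         pair_ids=None)
    counts = ft.data[kept].to_numpy(dtype=float)
    groups = np.array([meta.group_of(s) for s in kept])
    pat = groups == "patient"

    zero_pat = (counts[:, pat] == 0).all(axis=1)
    zero_ctl = (counts[:, ~pat] == 0).all(axis=1)
    structural = (zero_pat & ~zero_ctl) | (zero_ctl & ~zero_pat)

    with np.errstate(divide="ignore"):
        L = np.where(counts > 0, np.log(np.maximum(counts, 1e-300)), np.nan)
    grand = np.nanmean(L, axis=1, keepdims=True)
    offsets = np.nanmedian(L - grand, axis=0)
    Z = L - offsets[None, :]

    n_taxa = Z.shape[0]
    beta = np.full(n_taxa, np.nan)
    se = np.full(n_taxa, np.nan)
    pvals = np.full(n_taxa, np.nan)
    dfs = np.zeros(n_taxa, dtype=int)
    model_idx = np.where(~structural)[0]
    for i in model_idx:
        obs = ~np.isnan(Z[i])
        if obs.sum() <= Xd.shape[1]:
            continue
        beta[i], se[i], pvals[i], dfs[i] = _ols_group_test(
            Z[i, obs], Xd[obs], gi)

    tested = ~np.isnan(pvals)
    padj = np.full(n_taxa, np.nan)
    if tested.any():
        padj[tested] = bh_adjust(pvals[tested])
    significant = tested & (padj <= cfg.alpha_adjusted)

    # sensitivity sweep: zeros replaced by each pseudo-count, complete
    # data -> one shared design, vectorised across taxa
    verdicts = np.zeros((len(cfg.pseudo_count_grid), n_taxa), dtype=bool)
    pinv = np.linalg.pinv(Xd)
    xtx_inv = np.linalg.inv(Xd.T @ Xd)
    df_full = Xd.shape[0] - Xd.shape[1]
    for k, pc in enumerate(cfg.pseudo_count_grid):
        Lk = np.log(np.where(counts > 0, counts, pc))
        offk = np.median(Lk - Lk.mean(axis=1, keepdims=True), axis=0)
        Zk = Lk - offk[None, :]
        Bk = pinv @ Zk.T
        residk = Zk.T - Xd @ Bk
        s2k = (residk ** 2).sum(axis=0) / df_full
        sek = np.sqrt(np.maximum(s2k * xtx_inv[gi, gi], 1e-300))
        pk = 2 * stats.t.sf(np.abs(Bk[gi] / sek), df_full)
        padjk = np.full(n_taxa, np.nan)
        padjk[model_idx] = bh_adjust(pk[model_idx])
        verdicts[k] = np.nan_to_num(padjk, nan=1.0) <= cfg.alpha_adjusted
    sens_ok = (verdicts == significant[None, :]).all(axis=0)

    records = []
    for i, taxon in enumerate(ft.taxa):
        if structural[i]:
            records.append(DAResultRecord(
                taxon=taxon, material=t.material, platform=t.platform,
                engine="bias_corrected", effect=float("nan"), se=None,
                effect_size=None, p=float("nan"), p_adjusted=float("nan"),
                ci_95=None,
                direction="patient" if zero_ctl[i] else "control",
                significant=False, structural_zero=True,
                sensitivity_passed=None))
            continue
        ci = None
        if np.isfinite(se[i]) and se[i] > 0 and dfs[i] >= 1:
            ci = ci_from_t(float(beta[i]), float(se[i]), int(dfs[i]))
        records.append(DAResultRecord(
            taxon=taxon, material=t.material, platform=t.platform,
            engine="bias_corrected", effect=float(beta[i]),
            se=None if np.isnan(se[i]) else float(se[i]),
            effect_size=None, p=float(pvals[i]),
            p_adjusted=float(padj[i]), ci_95=ci,
            direction="patient" if (beta[i] if np.isfinite(beta[i]) else 0) > 0
            else "control",
            significant=bool(significant[i]),
            sensitivity_passed=bool(sens_ok[i]) if not np.isnan(pvals[i])
            else None))
    return records


def run_engine(engine: str, t: AbundanceTable, meta: CohortMetadata,
               pm: PairMap | None, cfg: EngineConfig) -> list[DAResultRecord]:
    if engine == "clr_paired":
        if pm is None:
            raise ValueError("clr_paired requires a pair map")
        return run_clr_paired(t, meta, pm, cfg)
    if engine == "linear_covariate":
        return run_linear_covariate(t, meta, pm, cfg)
    if engine == "bias_corrected":
        return run_bias_corrected(t, meta, cfg)
    raise ValueError(f"unknown engine {engine!r}")
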