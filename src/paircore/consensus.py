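"""Core-dysbiosis consensus calling and cross-validation procedures.

A taxon joins the core dysbiosis when it is identified as
differentially abundant at least three times across the
engine x platform x material evidence rows, always in the same
direction (towards patients or towards controls), and by at least two
of the three sequencing platforms.  Evidence rows need not come from
distinct engines.  Structural-zero identifications never enter the
consensus.

Two cross-validations probe the consensus: a re-pairing permutation
(rerunning an analysis under random patient/control matchings) and a
batch-integration analysis that concatenates the platform datasets,
models the platform as a covariate and keeps only taxa whose group
effect survives a stricter threshold without a platform (batch) effect.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from importlib import resources
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model import AbundanceTable, CohortMetadata, PairMap
from .da_engines import (DAResultRecord, EngineConfig, ENGINE_CODE,
                         bh_adjust)

EVIDENCE_COLUMNS = ("taxon", "rank", "material", "platform", "engine",
                    "direction", "lefse_identified", "sensitivity_passed",
                    "education_covariate_passed")


@dataclass(frozen=True)
class EvidenceRecord:
    """One identification of a taxon by one engine on one dataset."""

    taxon: str
    rank: str
    material: str          # saliva | supragingival
    platform: str          # WGS | FL | SR
    engine: str            # ANCOM | LIMMA | ALDEX
    direction: str         # patient | control
    lefse_identified: bool | None = None
    sensitivity_passed: bool | None = None
    education_covariate_passed: bool | None = None

    def key(self) -> tuple[str, str, str, str]:
        return (self.taxon, self.material, self.platform, self.engine)


@dataclass
class CoreCall:
    taxon: str
    rank: str
    direction: str
    n_evidence: int
    engines: frozenset[str]
    platforms: frozenset[str]
    materials: frozenset[str]
    lefse_agreement: float | None
    sensitivity_fraction: float | None
    education_fraction: float | None


def _parse_flag(x) -> bool | None:
    if x is None or (isinstance(x, float) and np.isnan(x)) or x == "":
        return None
    if isinstance(x, (bool, np.bool_)):
        return bool(x)
    s = str(x).strip().upper()
    if s in ("TRUE", "1", "YES"):
        return True
    if s in ("FALSE", "0", "NO"):
        return False
    raise ValueError(f"unparsable flag {x!r}")


def read_evidence(path) -> list[EvidenceRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = set(EVIDENCE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"evidence table missing columns: {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        out.append(EvidenceRecord(
            taxon=row.taxon, rank=row.rank, material=row.material,
            platform=row.platform, engine=row.engine,
            direction=row.direction,
            lefse_identified=_parse_flag(row.lefse_identified),
            sensitivity_passed=_parse_flag(row.sensitivity_passed),
            education_covariate_passed=_parse_flag(
                row.education_covariate_passed)))
    return out


def packaged_evidence(rank: str) -> list[EvidenceRecord]:
    """Evidence fixtures shipped with the package: transcriptions of the
    published species- and genus-level identification tables."""
    name = {"species": "table2_species.tsv",
            "genus": "table3_genera.tsv"}[rank]
    ref = resources.files("paircore.data").joinpath(name)
    with resources.as_file(ref) as path:
        return read_evidence(path)


def records_to_evidence(records: Sequence[DAResultRecord],
                        rank: str = "species",
                        annotations: pd.DataFrame | None = None,
                        ) -> list[EvidenceRecord]:
    """Bridge engine output to the consensus caller.

    One evidence record per significant, non-structural-zero result.
    Optional annotations (columns taxon, material, platform, engine,
    lefse_identified, sensitivity_passed, education_covariate_passed)
    are joined by identification key; duplicate keys are an error.
    """
    ann: dict[tuple, dict] = {}
    if annotations is not None:
        for row in annotations.itertuples(index=False):
            key = (row.taxon, row.material, row.platform, row.engine)
            if key in ann:
                raise ValueError(f"duplicate annotation key {key}")
            ann[key] = {
                "lefse_identified": _parse_flag(
                    getattr(row, "lefse_identified", None)),
                "sensitivity_passed": _parse_flag(
                    getattr(row, "sensitivity_passed", None)),
                "education_covariate_passed": _parse_flag(
                    getattr(row, "education_covariate_passed", None)),
            }
    out = []
    for r in records:
        if not r.significant or r.structural_zero:
            continue
        code = ENGINE_CODE.get(r.engine, r.engine)
        key = (r.taxon, r.material, r.platform, code)
        extra = ann.get(key, {})
        out.append(EvidenceRecord(
            taxon=r.taxon, rank=rank, material=r.material,
            platform=r.platform, engine=code, direction=r.direction,
            lefse_identified=extra.get("lefse_identified"),
            sensitivity_passed=extra.get(
                "sensitivity_passed", r.sensitivity_passed),
            education_covariate_passed=extra.get(
                "education_covariate_passed")))
    return out


def _fraction(flags: list[bool | None]) -> float | None:
    known = [f for f in flags if f is not None]
    if not known:
        return None
    return sum(known) / len(known)


def call_core(records: Sequence[EvidenceRecord], min_evidence: int = 3,
              min_platforms: int = 2,
              direction_rule: str = "all_consistent") -> list[CoreCall]:
    """Apply the three consensus rules to evidence records.

    A taxon is called when (i) it has at least ``min_evidence``
    identification rows (each material x platform x engine row counts
    once; engines need not be distinct), (ii) the direction is
    consistent (unanimous under ``all_consistent``; strict majority
    under ``majority``, where the majority direction is reported), and
    (iii) at least ``min_platforms`` sequencing platforms contributed.
    """
    if direction_rule not in ("all_consistent", "majority"):
        raise ValueError(f"unknown direction rule {direction_rule!r}")
    by_taxon: dict[str, list[EvidenceRecord]] = {}
    for r in records:
        by_taxon.setdefault(r.taxon, []).append(r)
    calls = []
    for taxon in by_taxon:
        rows = by_taxon[taxon]
        ranks = {r.rank for r in rows}
        if len(ranks) > 1:
            raise ValueError(f"taxon {taxon!r} appears at mixed ranks "
                             f"{sorted(ranks)}")
        if len(rows) < min_evidence:
            continue
        platforms = {r.platform for r in rows}
        if len(platforms) < min_platforms:
            continue
        directions = Counter(r.direction for r in rows)
        if direction_rule == "all_consistent":
            if len(directions) != 1:
                continue
            direction = next(iter(directions))
        else:
            direction, top = directions.most_common(1)[0]
            if top * 2 <= len(rows):
                continue
        calls.append(CoreCall(
            taxon=taxon, rank=next(iter(ranks)), direction=direction,
            n_evidence=len(rows),
            engines=frozenset(r.engine for r in rows),
            platforms=frozenset(platforms),
            materials=frozenset(r.material for r in rows),
            lefse_agreement=_fraction([r.lefse_identified for r in rows]),
            sensitivity_fraction=_fraction(
                [r.sensitivity_passed for r in rows]),
            education_fraction=_fraction(
                [r.education_covariate_passed for r in rows])))
    calls.sort(key=lambda c: c.taxon)
    return calls


def summarize_core(calls: Sequence[CoreCall]) -> pd.DataFrame:
    """Counts of called taxa per rank x direction."""
    counts: Counter = Counter((c.rank, c.direction) for c in calls)
    ranks = sorted({c.rank for c in calls})
    rows = []
    for rank in ranks:
        rows.append(dict(rank=rank,
                         patient=counts.get((rank, "patient"), 0),
                         control=counts.get((rank, "control"), 0),
                         total=counts.get((rank, "patient"), 0)
                         + counts.get((rank, "control"), 0)))
    return pd.DataFrame(rows, columns=["rank", "patient", "control", "total"])


def calls_frame(calls: Sequence[CoreCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        rows.append(dict(
            taxon=c.taxon, rank=c.rank, direction=c.direction,
            n_evidence=c.n_evidence,
            engines=",".join(sorted(c.engines)),
            platforms=",".join(sorted(c.platforms)),
            materials=",".join(sorted(c.materials)),
            lefse_agreement=c.lefse_agreement,
            sensitivity_fraction=c.sensitivity_fraction,
            education_fraction=c.education_fraction))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# cross-validation 1: re-pairing permutation


@dataclass
class RepairingResult:
    observed: dict[str, float]
    permuted_mean: dict[str, float]
    permuted_q05: dict[str, float]
    permuted_q95: dict[str, float]
    observed_quantile: dict[str, float]
    n_permutations: int
    n_failed: int


def repairing_permutation(analysis: Callable[[PairMap], Mapping[str, float]],
                          meta: CohortMetadata, pm: PairMap,
                          n_permutations: int = 1000,
                          seed: int | None = None) -> RepairingResult:
    """Rerun an analysis under random patient/control re-pairings.

    ``analysis`` maps a pair map to named numeric outputs (p values,
    statistics...).  Each permutation replaces the pairing with a
    uniform random perfect matching between the patient and control
    sample sets (which may coincide with the true pairing by chance —
    an unbiased null).  Failures on individual permutations are dropped
    and counted.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    observed = dict(analysis(pm))
    pats, ctls = pm.patients, pm.controls
    rng = np.random.default_rng(seed)
    results: dict[str, list[float]] = {k: [] for k in observed}
    n_failed = 0
    for _ in range(n_permutations):
        perm = rng.permutation(len(ctls))
        pm_perm = PairMap(list(zip(pats, [ctls[i] for i in perm])),
                          list(pm.unpaired))
        try:
            out = analysis(pm_perm)
        except Exception as e:  # analysis failure on this permutation
            warnings.warn(f"analysis failed on a permutation: {e}",
                          stacklevel=2)
            n_failed += 1
            continue
        for k in results:
            results[k].append(float(out[k]))
    if any(not v for v in results.values()):
        raise RuntimeError("every permutation failed")
    permuted_mean = {k: float(np.mean(v)) for k, v in results.items()}
    q05 = {k: float(np.quantile(v, 0.05)) for k, v in results.items()}
    q95 = {k: float(np.quantile(v, 0.95)) for k, v in results.items()}
    quantile = {k: float(np.mean(np.asarray(v) <= observed[k]))
                for k, v in results.items()}
    return RepairingResult(observed=observed, permuted_mean=permuted_mean,
                           permuted_q05=q05, permuted_q95=q95,
                           observed_quantile=quantile,
                           n_permutations=n_permutations - n_failed,
                           n_failed=n_failed)


# ---------------------------------------------------------------------------
# cross-validation 2: combined-platform batch integration


@dataclass
class BatchIntegrationResult:
    robust_both: list[str]
    robust_by_engine: dict[str, list[str]]
    records: pd.DataFrame
    alpha_adjusted: float
    platform_alpha: float


def _platform_f_pvalues(Y: np.ndarray, X_full: np.ndarray,
                        platform_cols: list[int]) -> np.ndarray:
    """Joint F-test p values for the platform dummy block, per taxon."""
    from scipy import stats as sstats
    n, p_cols = X_full.shape
    keep = [j for j in range(p_cols) if j not in platform_cols]
    X_red = X_full[:, keep]
    q = len(platform_cols)
    df_full = n - np.linalg.matrix_rank(X_full)
    h_full = X_full @ np.linalg.pinv(X_full)
    h_red = X_red @ np.linalg.pinv(X_red)
    rss_full = ((Y @ (np.eye(n) - h_full)) * Y).sum(axis=1)
    rss_red = ((Y @ (np.eye(n) - h_red)) * Y).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = ((rss_red - rss_full) / q) / (rss_full / df_full)
    return sstats.f.sf(np.maximum(f, 0.0), q, df_full)


def batch_integrate(tables: Mapping[str, AbundanceTable],
                    meta: CohortMetadata,
                    cfg: EngineConfig | None = None,
                    alpha_adjusted: float = 0.01,
                    platform_alpha: float = 0.05) -> BatchIntegrationResult:
    """Combined-platform analysis with the platform as a batch covariate.

    The platform count tables of one material are concatenated (each
    physical sample appears once per platform), low-count filtered, and
    analysed with the linear-covariate and bias-corrected engines with
    platform dummies added to the design and a stricter group threshold
    (adjusted p <= 0.01, compensating the artificially enlarged sample
    number).  A taxon is robust in an engine when its group term is
    significant while its platform block shows no batch effect
    (joint F, BH-adjusted p > ``platform_alpha``).
    """
    if len(tables) < 2:
        raise ValueError("need at least 2 platform tables")
    cfg = cfg or EngineConfig(covariates=(), paired=False)
    from .data_model import align_tables, filter_low_counts, AbundanceTable \
        as AT

    aligned = align_tables(list(tables.values()), sample_policy="intersect")
    frames, meta_rows, platforms = [], [], []
    for t in aligned:
        df = t.data.copy()
        df.columns = [f"{s}@{t.platform}" for s in df.columns]
        frames.append(df)
        for s in t.samples:
            row = meta.data.loc[s].copy()
            meta_rows.append(row.rename(f"{s}@{t.platform}"))
            platforms.append(t.platform)
    combined = AT(pd.concat(frames, axis=1), mode="counts",
                  material=aligned[0].material, rank=aligned[0].rank)
    cmeta = CohortMetadata(pd.DataFrame(meta_rows))
    plat = pd.Series(platforms, index=cmeta.data.index, name="platform")
    plat_dummies = pd.get_dummies(plat, prefix="platform", drop_first=True,
                                  dtype=float)

    ft = filter_low_counts(combined, cfg.min_count, cfg.max_low_fraction)

    results: dict[str, dict[str, tuple[float, float]]] = {}
    frames_out = []

    # engine A: linear covariate model (log2 CPM per column)
    from .da_engines import tmm_factors, _design_matrix
    Xd, names, gi, kept = _design_matrix(cmeta, ft.samples,
                                         cfg.covariates, pair_ids=None,
                                         extra=plat_dummies)
    counts = ft.data[kept].to_numpy(dtype=float)
    lib = counts.sum(axis=0)
    Y = np.log2((counts + 0.5) / (lib * tmm_factors(counts) + 1.0) * 1e6)
    pcols = [j for j, nm in enumerate(names) if nm.startswith("platform_")]
    n, p_cols = Xd.shape
    df_res = n - np.linalg.matrix_rank(Xd)
    pinv = np.linalg.pinv(Xd)
    B = pinv @ Y.T
    resid = Y.T - Xd @ B
    s2 = (resid ** 2).sum(axis=0) / df_res
    v_g = np.linalg.pinv(Xd.T @ Xd)[gi, gi]
    se = np.sqrt(np.maximum(s2 * v_g, 1e-300))
    from scipy import stats as sstats
    p_group = 2 * sstats.t.sf(np.abs(B[gi] / se), df_res)
    p_plat = _platform_f_pvalues(Y, Xd, pcols)
    results["linear_covariate"] = dict(zip(
        ft.taxa, zip(bh_adjust(p_group), bh_adjust(p_plat), B[gi])))

    # engine B: bias-corrected model on offset-adjusted log counts,
    # zeros replaced by the smallest grid pseudo-count for the joint fit
    pc0 = cfg.pseudo_count_grid[0]
    L = np.log(np.where(counts > 0, counts, pc0))
    off = np.median(L - L.mean(axis=1, keepdims=True), axis=0)
    Z = L - off[None, :]
    Bz = pinv @ Z.T
    residz = Z.T - Xd @ Bz
    s2z = (residz ** 2).sum(axis=0) / df_res
    sez = np.sqrt(np.maximum(s2z * v_g, 1e-300))
    pz_group = 2 * sstats.t.sf(np.abs(Bz[gi] / sez), df_res)
    pz_plat = _platform_f_pvalues(Z, Xd, pcols)
    results["bias_corrected"] = dict(zip(
        ft.taxa, zip(bh_adjust(pz_group), bh_adjust(pz_plat), Bz[gi])))

    robust_by_engine = {}
    for eng, res in results.items():
        robust = [tx for tx, (pg, pp, eff) in res.items()
                  if pg <= alpha_adjusted and pp > platform_alpha]
        robust_by_engine[eng] = sorted(robust)
        for tx, (pg, pp, eff) in res.items():
            frames_out.append(dict(
                taxon=tx, engine=eng, effect=float(eff),
                p_group_adjusted=float(pg), p_platform_adjusted=float(pp),
                robust=tx in robust))
    robust_both = sorted(set(robust_by_engine["linear_covariate"])
                         & set(robust_by_engine["bias_corrected"]))
    return BatchIntegrationResult(
        robust_both=robust_both, robust_by_engine=robust_by_engine,
        records=pd.DataFrame(frames_out), alpha_adjusted=alpha_adjusted,
        platform_alpha=platform_alpha)
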