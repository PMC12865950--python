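"""Synthetic paired-cohort generator.

Emulates the statistical structure the downstream analysis assumes:
patient/partner pairs from shared households (a co-housing effect on
community composition), designated disease- and health-enriched taxa,
and three sequencing-platform views of the same underlying community
with platform-specific multiplicative bias and depth regimes — shotgun
bacterial depth heavy-tailed with a tail of samples below 1,000 reads,
amplicon depths orders of magnitude higher.

The model is a hierarchical log-normal–multinomial: per-taxon global
log2 mean, a household random effect shared by both partners, a subject
effect, a fixed +/- effect_log2 shift on the designated taxa in
patients, and a fixed per-(platform, taxon) log2 bias.  Counts are drawn
multinomially at a per-sample drawn depth, so column sums equal depths
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .data_model import AbundanceTable, CohortMetadata, PairMap

SALIVA_PLATFORMS = ("WGS", "FL", "SR")
SUPRA_PLATFORMS = ("FL", "SR")

#: depth below which shotgun samples are considered unreliable
WGS_LOW_DEPTH = 1000


def _default_depths() -> dict[str, float]:
    return {"WGS": 35_000.0, "FL": 100_000.0, "SR": 2_000_000.0}


@dataclass
class CohortSpec:
    """Study conditions for a generated cohort.

    Defaults describe the emulated study: 25 complete patient/partner
    pairs, a strong co-housing effect (household SD twice the subject
    SD on the log2 scale), a 4-fold shift (effect_log2 = 2) on eight
    disease- and eight health-enriched taxa, and platform depth regimes
    with roughly a quarter of shotgun samples under 1,000 bacterial
    reads.
    """

    n_pairs: int = 25
    n_taxa: int = 120
    n_disease_taxa: int = 8
    n_health_taxa: int = 8
    effect_log2: float = 2.0
    household_sd: float = 1.0
    subject_sd: float = 0.5
    platform_bias_sd: float = 0.5
    depth_means: Mapping[str, float] = field(default_factory=_default_depths)
    wgs_low_depth_fraction: float = 0.24
    base_log2_sd: float = 2.0  # spread of global taxon means
    seed: int = 0

    def __post_init__(self) -> None:
        if self.effect_log2 < 0:
            raise ValueError("effect_log2 must be >= 0; direction is "
                             "encoded by the disease/health taxon lists")
        if self.n_disease_taxa + self.n_health_taxa > self.n_taxa:
            raise ValueError("more designated taxa than taxa")
        for name in ("household_sd", "subject_sd", "platform_bias_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0 <= self.wgs_low_depth_fraction <= 1:
            raise ValueError("wgs_low_depth_fraction must be in [0, 1]")


@dataclass
class SyntheticCohort:
    tables: dict[tuple[str, str], AbundanceTable]
    metadata: CohortMetadata
    disease_taxa: list[str]
    health_taxa: list[str]
    pair_map: PairMap

    def pair_map_for(self, material: str) -> PairMap:
        """Pair map restricted to the samples of one material.

        Each pair_id maps to one patient and one control sample per
        material, so the map must be built per material."""
        for key, t in self.tables.items():
            if key[0] == material:
                return PairMap.from_metadata(self.metadata, t.samples)
        raise KeyError(f"no tables for material {material!r}")


def _wgs_depth_params(mean: float, low_fraction: float) -> tuple[float, float]:
    """Log-normal (mu, sigma) with the requested mean and
    P(depth < WGS_LOW_DEPTH) = low_fraction."""
    if low_fraction <= 0:
        return np.log(mean), 0.25
    z = norm.ppf(low_fraction)
    lo = np.log(WGS_LOW_DEPTH)
    # solve sigma^2/2 - z*sigma - log(mean/1000) = 0 for sigma > 0
    disc = z * z + 2 * np.log(mean / WGS_LOW_DEPTH)
    sigma = z + np.sqrt(max(disc, 0.0))
    mu = lo - sigma * z
    return mu, max(sigma, 1e-6)


def _draw_depths(platform: str, n: int, spec: CohortSpec,
                 rng: np.random.Generator) -> np.ndarray:
    mean = float(spec.depth_means[platform])
    if platform == "WGS":
        mu, sigma = _wgs_depth_params(mean, spec.wgs_low_depth_fraction)
        d = np.exp(rng.normal(mu, sigma, size=n))
    else:
        d = np.exp(rng.normal(np.log(mean) - 0.35 ** 2 / 2, 0.35, size=n))
    return np.maximum(np.round(d).astype(np.int64), 10)


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Draw a full paired multi-platform cohort, reproducible from seed."""
    ss = np.random.SeedSequence(spec.seed)
    rng_comm, rng_depth, rng_count, rng_meta = (
        np.random.default_rng(s) for s in ss.spawn(4))

    width = max(2, len(str(spec.n_pairs)))
    taxa = [f"taxon_{i + 1:04d}" for i in range(spec.n_taxa)]
    disease = taxa[: spec.n_disease_taxa]
    health = taxa[spec.n_disease_taxa: spec.n_disease_taxa + spec.n_health_taxa]

    base = rng_comm.normal(0.0, spec.base_log2_sd, size=spec.n_taxa)
    bias = {p: rng_comm.normal(0.0, spec.platform_bias_sd, size=spec.n_taxa)
            for p in ("WGS", "FL", "SR")}

    shift = np.zeros(spec.n_taxa)
    shift[: spec.n_disease_taxa] = spec.effect_log2
    shift[spec.n_disease_taxa: spec.n_disease_taxa + spec.n_health_taxa] = \
        -spec.effect_log2

    subjects = []  # (subject_id, pair_id, group)
    for j in range(spec.n_pairs):
        pid = f"pair{j + 1:0{width}d}"
        subjects.append((f"pat{j + 1:0{width}d}", pid, "patient"))
        subjects.append((f"ctl{j + 1:0{width}d}", pid, "control"))

    materials = {"saliva": SALIVA_PLATFORMS, "supragingival": SUPRA_PLATFORMS}
    # per-material community: household and subject effects are niche-specific
    log2_abun: dict[str, np.ndarray] = {}
    for material in materials:
        H = rng_comm.normal(0.0, spec.household_sd,
                            size=(spec.n_pairs, spec.n_taxa))
        S = rng_comm.normal(0.0, spec.subject_sd,
                            size=(2 * spec.n_pairs, spec.n_taxa))
        A = np.empty((2 * spec.n_pairs, spec.n_taxa))
        for k, (_, _, group) in enumerate(subjects):
            j = k // 2
            A[k] = base + H[j] + S[k] + (shift if group == "patient" else 0.0)
        log2_abun[material] = A

    sample_ids = {m: [f"{sid}_{m[:3]}" for sid, _, _ in subjects]
                  for m in materials}

    tables: dict[tuple[str, str], AbundanceTable] = {}
    for material, platforms in materials.items():
        for platform in platforms:
            depths = _draw_depths(platform, 2 * spec.n_pairs, spec, rng_depth)
            logit = log2_abun[material] + bias[platform]
            # softmax over taxa per sample, in log2 space
            w = np.exp2(logit - logit.max(axis=1, keepdims=True))
            probs = w / w.sum(axis=1, keepdims=True)
            counts = np.empty((2 * spec.n_pairs, spec.n_taxa), dtype=np.int64)
            for k in range(2 * spec.n_pairs):
                counts[k] = rng_count.multinomial(depths[k], probs[k])
            df = pd.DataFrame(counts.T, index=pd.Index(taxa, name="taxon"),
                              columns=sample_ids[material])
            tables[(material, platform)] = AbundanceTable(
                df, mode="counts", material=material, platform=platform,
                rank="species")

    rows = []
    for j in range(spec.n_pairs):
        hh_age = rng_meta.normal(68, 7)
        hh_edu = rng_meta.normal(16, 3)
        for k, off in ((2 * j, 0), (2 * j + 1, 1)):
            sid, pid, group = subjects[k]
            sex = "female" if rng_meta.random() < 0.5 else "male"
            row = dict(
                subject_id=sid, pair_id=pid, group=group,
                age=round(float(np.clip(hh_age + rng_meta.normal(0, 3), 45, 95)), 1),
                sex=sex,
                bmi=round(float(np.clip(rng_meta.normal(25, 3.5), 16, 45)), 1),
                smoking="yes" if rng_meta.random() < 0.15 else "no",
                teeth=int(np.clip(np.round(rng_meta.normal(24, 6)), 0, 32)),
                sbi=int(rng_meta.integers(1, 5)),
                education_years=round(float(np.clip(
                    hh_edu + rng_meta.normal(0, 1.5), 8, 25)), 1),
            )
            for material in materials:
                rows.append(dict(sample_id=f"{sid}_{material[:3]}", **row))
    meta = CohortMetadata(pd.DataFrame(rows).set_index("sample_id"))

    pair_map = PairMap.from_metadata(meta, sample_ids["saliva"])
    return SyntheticCohort(tables=tables, metadata=meta,
                           disease_taxa=disease, health_taxa=health,
                           pair_map=pair_map)


def drop_samples(cohort: SyntheticCohort,
                 rules: Sequence[tuple[str, str]]) -> SyntheticCohort:
    """Apply sample-exclusion rules, keeping every view consistent.

    Rules:
      ``("remove_sample", sample_id)`` — drop one sample from its
      material's tables; its partner becomes unpaired there.
      ``("unpair", subject_id)`` — drop the partner subject entirely,
      leaving the named subject unpaired (a participant who came alone).
    """
    if not rules:
        return cohort
    meta = cohort.metadata.data.copy()
    drop: set[str] = set()
    for kind, target in rules:
        if kind == "remove_sample":
            if target not in meta.index:
                raise KeyError(f"unknown sample {target!r}")
            drop.add(target)
        elif kind == "unpair":
            sub = meta[meta["subject_id"] == target]
            if sub.empty:
                raise KeyError(f"unknown subject {target!r}")
            pid = sub["pair_id"].iloc[0]
            partner = meta[(meta["pair_id"] == pid)
                           & (meta["subject_id"] != target)]
            drop.update(partner.index)
            meta.loc[meta["subject_id"] == target, "pair_id"] = np.nan
        else:
            raise ValueError(f"unknown rule {kind!r}")
    meta = meta.drop(index=list(drop))
    new_meta = CohortMetadata(meta)
    tables = {}
    for key, t in cohort.tables.items():
        keep = [s for s in t.samples if s not in drop]
        tables[key] = t.subset_samples(keep)
    saliva_samples = [s for s in new_meta.samples if s.endswith("_sal")]
    return SyntheticCohort(tables=tables, metadata=new_meta,
                           disease_taxa=list(cohort.disease_taxa),
                           health_taxa=list(cohort.health_taxa),
                           pair_map=PairMap.from_metadata(new_meta,
                                                          saliva_samples))
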