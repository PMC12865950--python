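"""Domain types, TSV I/O and shared filtering rules.

The pipeline operates on taxa-by-sample abundance tables (one per
material x sequencing platform x taxonomic rank), a per-sample cohort
metadata table and a patient/partner pair map.  All downstream stages
consume these three objects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

Mode = Literal["counts", "relative"]
Material = Literal["saliva", "supragingival"]
Platform = Literal["WGS", "FL", "SR"]
Rank = Literal["species", "genus", "family", "order", "class", "phylum"]

MATERIALS: tuple[str, ...] = ("saliva", "supragingival")
PLATFORMS: tuple[str, ...] = ("WGS", "FL", "SR")
RANKS: tuple[str, ...] = ("species", "genus", "family", "order", "class", "phylum")

#: columns of the metadata TSV, in order
METADATA_COLUMNS = (
    "sample_id", "subject_id", "pair_id", "group",
    "age", "sex", "bmi", "smoking", "teeth", "sbi", "education_years",
)

_REL_TOL = 1e-9


class FormatError(ValueError):
    """Malformed table: duplicate names, negative values, bad column sums."""


class DegenerateSampleError(ValueError):
    """A sample column carries no reads where positive depth is required."""


@dataclass
class AbundanceTable:
    """Taxa x samples abundance matrix with provenance tags.

    ``data`` is a DataFrame indexed by taxon name with sample ids as
    columns.  ``mode`` is ``counts`` (non-negative integers) or
    ``relative`` (columns summing to one).
    """

    data: pd.DataFrame
    mode: Mode = "counts"
    material: str | None = None
    platform: str | None = None
    rank: str | None = None
    #: strict relative tables must have unit column sums; tables derived
    #: by non-renormalising filters (top-k, mean-abundance without
    #: collapse) live on a sub-simplex and set this to False
    strict: bool = True

    def __post_init__(self) -> None:
        self.validate()

    # -- basic accessors -------------------------------------------------
    @property
    def taxa(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_taxa(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def depths(self) -> pd.Series:
        """Per-sample column sums (sequencing depth in counts mode)."""
        return self.data.sum(axis=0)

    def with_data(self, data: pd.DataFrame, **kw) -> "AbundanceTable":
        return AbundanceTable(
            data=data,
            mode=kw.get("mode", self.mode),
            material=kw.get("material", self.material),
            platform=kw.get("platform", self.platform),
            rank=kw.get("rank", self.rank),
            strict=kw.get("strict", self.strict),
        )

    def subset_samples(self, samples: Sequence[str]) -> "AbundanceTable":
        missing = [s for s in samples if s not in self.data.columns]
        if missing:
            raise KeyError(f"samples not in table: {missing}")
        return self.with_data(self.data.loc[:, list(samples)])

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate taxon names: {dup}")
        if df.columns.has_duplicates:
            dup = df.columns[df.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample ids: {dup}")
        vals = df.to_numpy(dtype=float)
        if vals.size and np.nanmin(vals) < 0:
            raise FormatError("negative abundance value")
        if self.mode == "counts":
            if vals.size and not np.allclose(vals, np.round(vals)):
                raise FormatError("non-integer value in counts mode")
        elif self.mode == "relative":
            if vals.size and self.strict:
                sums = vals.sum(axis=0)
                bad = ~np.isclose(sums, 1.0, atol=_REL_TOL, rtol=0)
                if bad.any():
                    ids = [df.columns[i] for i in np.where(bad)[0]]
                    raise FormatError(
                        f"relative-mode columns do not sum to 1: {ids}")
        else:
            raise FormatError(f"unknown mode {self.mode!r}")


def read_abundance_table(path, mode: Mode = "counts", material=None,
                         platform=None, rank=None) -> AbundanceTable:
    """Read a tab-separated taxa x samples table.

    First column holds taxon names (header cell ``taxon``), remaining
    columns one sample each.  Validation errors raise :class:`FormatError`.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    df.index = df.index.astype(str)
    df.index.name = "taxon"
    try:
        df = df.astype(float)
    except ValueError as e:
        raise FormatError(f"non-numeric value in abundance table: {e}") from e
    return AbundanceTable(df, mode=mode, material=material,
                          platform=platform, rank=rank)


def write_abundance_table(t: AbundanceTable, path) -> None:
    df = t.data.copy()
    if t.mode == "counts":
        df = df.astype(np.int64)
    df.index.name = "taxon"
    df.to_csv(path, sep="\t")


def to_relative(t: AbundanceTable) -> AbundanceTable:
    """Column-normalise counts to relative abundances."""
    if t.mode == "relative":
        return t
    sums = t.data.sum(axis=0)
    zero = sums[sums <= 0]
    if len(zero):
        raise DegenerateSampleError(
            f"all-zero sample columns: {list(zero.index)}")
    return t.with_data(t.data.div(sums, axis=1), mode="relative")


def filter_low_counts(t: AbundanceTable, min_count: int = 10,
                      max_low_fraction: float = 0.70) -> AbundanceTable:
    """Remove taxa with fewer than ``min_count`` reads in more than
    ``max_low_fraction`` of samples (strict inequalities on both sides)."""
    if t.mode != "counts":
        raise ValueError("filter_low_counts requires counts mode")
    low_frac = (t.data < min_count).mean(axis=1)
    keep = low_frac <= max_low_fraction
    if not keep.any():
        warnings.warn("filter_low_counts removed every taxon", stacklevel=2)
    return t.with_data(t.data.loc[keep])


def filter_prevalence(t: AbundanceTable,
                      min_prevalence: float = 0.1) -> AbundanceTable:
    """Keep taxa present (value > 0) in at least ``min_prevalence`` of samples."""
    prev = (t.data > 0).mean(axis=1)
    keep = prev >= min_prevalence
    strict = t.strict and (t.mode != "relative" or bool(keep.all()))
    return t.with_data(t.data.loc[keep], strict=strict)


def filter_mean_abundance(t: AbundanceTable, min_mean: float = 0.001,
                          collapse_others: bool = False,
                          others_label: str = "Others") -> AbundanceTable:
    """Keep taxa whose mean relative abundance is >= ``min_mean``.

    With ``collapse_others`` the removed mass is summed into a synthetic
    ``Others`` row so every column still sums to one.
    """
    if t.mode != "relative":
        raise ValueError("filter_mean_abundance requires relative mode")
    means = t.data.mean(axis=1)
    keep = means >= min_mean
    kept = t.data.loc[keep]
    if collapse_others:
        others = t.data.loc[~keep].sum(axis=0)
        kept = pd.concat([kept, others.to_frame(others_label).T])
        kept.index.name = t.data.index.name
        return t.with_data(kept)
    return t.with_data(kept, strict=keep.all() and t.strict)


def align_tables(tables: Sequence[AbundanceTable],
                 sample_policy: Literal["intersect", "union"] = "intersect",
                 ) -> list[AbundanceTable]:
    """Reindex tables to the union of taxa (zero-fill) and a common
    sample set (intersection by default, as identical physical samples
    were sequenced on every platform)."""
    if not tables:
        return []
    ranks = {t.rank for t in tables}
    if len(ranks) > 1:
        raise ValueError(f"tables have mixed ranks: {ranks}")
    taxa: list[str] = []
    seen: set[str] = set()
    for t in tables:
        for name in t.taxa:
            if name not in seen:
                seen.add(name)
                taxa.append(name)
    if sample_policy == "intersect":
        common = set(tables[0].samples)
        for t in tables[1:]:
            common &= set(t.samples)
        if not common:
            raise ValueError("empty sample intersection")
        samples = [s for s in tables[0].samples if s in common]
    elif sample_policy == "union":
        samples = []
        sseen: set[str] = set()
        for t in tables:
            for s in t.samples:
                if s not in sseen:
                    sseen.add(s)
                    samples.append(s)
    else:
        raise ValueError(f"unknown sample policy {sample_policy!r}")
    out = []
    for t in tables:
        df = t.data.reindex(index=taxa, columns=samples, fill_value=0.0)
        df = df.fillna(0.0)
        # zero-filling taxa rows leaves column sums intact; a sample a table
        # never measured (union policy) becomes an all-zero column, which the
        # relative-mode invariant rejects — that is deliberate
        out.append(AbundanceTable(df, mode=t.mode, material=t.material,
                                  platform=t.platform, rank=t.rank))
    return out


# ---------------------------------------------------------------------------
# cohort metadata and pair map


@dataclass
class CohortMetadata:
    """Per-sample subject/pair/group records with clinical covariates."""

    data: pd.DataFrame  # indexed by sample_id

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            raise FormatError("duplicate sample ids in metadata")
        bad = set(df["group"]) - {"patient", "control"}
        if bad:
            raise FormatError(f"unknown group labels: {bad}")

    @property
    def samples(self) -> list[str]:
        return list(self.data.index)

    def group_of(self, sample_id: str) -> str:
        return str(self.data.loc[sample_id, "group"])

    def subset(self, samples: Iterable[str]) -> "CohortMetadata":
        keep = [s for s in samples if s in self.data.index]
        return CohortMetadata(self.data.loc[keep])

    def covariate_frame(self, covariates: Sequence[str]) -> pd.DataFrame:
        """Numeric design columns for the requested covariates; categorical
        covariates are dummy-coded, missing values stay NaN for
        complete-case handling downstream."""
        cols = []
        for cov in covariates:
            s = self.data[cov]
            if s.dtype == object or str(s.dtype).startswith("category"):
                s = s.replace("", np.nan)
                dummies = pd.get_dummies(s, prefix=cov, drop_first=True,
                                         dtype=float)
                dummies[s.isna()] = np.nan
                cols.append(dummies)
            else:
                cols.append(pd.to_numeric(s, errors="coerce").to_frame(cov))
        if not cols:
            return pd.DataFrame(index=self.data.index)
        return pd.concat(cols, axis=1)


def read_metadata(path) -> CohortMetadata:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "subject_id": str,
                                            "pair_id": str, "group": str,
                                            "sex": str, "smoking": str})
    missing = set(METADATA_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"metadata missing columns: {sorted(missing)}")
    df = df.set_index("sample_id")
    df["pair_id"] = df["pair_id"].replace("", np.nan)
    return CohortMetadata(df)


def write_metadata(meta: CohortMetadata, path) -> None:
    df = meta.data.copy()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t", na_rep="")


@dataclass
class PairMap:
    """Ordered (patient_sample, control_sample) tuples plus unpaired samples."""

    pairs: list[tuple[str, str]] = field(default_factory=list)
    unpaired: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for p, c in self.pairs:
            for s in (p, c):
                if s in seen:
                    raise FormatError(f"sample {s!r} appears in two pairs")
                seen.add(s)
        overlap = seen & set(self.unpaired)
        if overlap:
            raise FormatError(f"samples both paired and unpaired: {overlap}")

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def patients(self) -> list[str]:
        return [p for p, _ in self.pairs]

    @property
    def controls(self) -> list[str]:
        return [c for _, c in self.pairs]

    def paired_samples(self) -> list[str]:
        out = []
        for p, c in self.pairs:
            out.extend((p, c))
        return out

    def restrict(self, samples: Iterable[str]) -> "PairMap":
        """Keep only pairs whose two members are both in ``samples``; the
        surviving member of a broken pair becomes unpaired."""
        present = set(samples)
        pairs, unpaired = [], []
        for p, c in self.pairs:
            if p in present and c in present:
                pairs.append((p, c))
            elif p in present:
                unpaired.append(p)
            elif c in present:
                unpaired.append(c)
        unpaired.extend(s for s in self.unpaired if s in present)
        return PairMap(pairs, unpaired)

    @classmethod
    def from_metadata(cls, meta: CohortMetadata,
                      samples: Sequence[str] | None = None) -> "PairMap":
        df = meta.data if samples is None else meta.data.loc[
            [s for s in samples if s in meta.data.index]]
        pairs: list[tuple[str, str]] = []
        unpaired: list[str] = []
        for pid, grp in df[df["pair_id"].notna()].groupby("pair_id", sort=True):
            pats = grp.index[grp["group"] == "patient"].tolist()
            ctls = grp.index[grp["group"] == "control"].tolist()
            if len(pats) == 1 and len(ctls) == 1:
                pairs.append((pats[0], ctls[0]))
            else:
                unpaired.extend(pats + ctls)
        unpaired.extend(df.index[df["pair_id"].isna()].tolist())
        return cls(pairs, unpaired)
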