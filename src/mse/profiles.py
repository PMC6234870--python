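"""Reading, normalizing and quality-filtering microbiome profiles.

A profile is one sample's sparse taxon -> relative-abundance map plus the
metadata the database needs: study, habitat, timestamp and the sequencing QC
fields (read count, 16S mapping rate). Tables are plain TSV — samples x taxa
or the transpose, auto-detected from the header sentinel — with one metadata
row per sample.
"""

from __future__ import annotations

import datetime as _dt
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import DuplicateSampleError, MalformedTableError, ValidationError
from .phylogeny import PhylogenyView

logger = logging.getLogger(__name__)

#: header sentinels marking a samples-in-rows table
_SAMPLE_SENTINELS = {"sample_id", "#sampleid", "sampleid", "sample", "sample-id"}
#: header sentinels marking a taxa-in-rows table (classic OTU-table layout)
_TAXON_SENTINELS = {"taxon", "taxon_id", "otu", "otu_id", "#otu id", "#otuid", "feature_id"}

DEFAULT_MIN_READS = 500
DEFAULT_MIN_MAPPING_RATE = 0.80


@dataclass
class MicrobiomeProfile:
    """One sample: sparse relative abundances plus database metadata."""

    sample_id: str
    abundances: dict[str, float]
    study_id: str = ""
    habitat: str = ""
    year: int | None = None
    date: str | None = None  # ISO-8601, used for dedup tie-breaking
    read_count: int = 0
    mapping_rate: float | None = None

    def __post_init__(self) -> None:
        if self.mapping_rate is not None and not (0.0 <= self.mapping_rate <= 1.0):
            raise ValidationError(
                f"mapping_rate of {self.sample_id} must be in [0, 1], got {self.mapping_rate}"
            )
        if self.read_count < 0:
            raise ValidationError(f"read_count of {self.sample_id} must be >= 0")
        if self.date is not None and self.year is None:
            self.year = _dt.date.fromisoformat(self.date).year

    # ------------------------------------------------------------------
    def normalized(self) -> "MicrobiomeProfile":
        """Return a copy with abundances scaled to sum exactly 1."""
        items = {t: float(v) for t, v in self.abundances.items() if v > 0.0}
        for taxon, value in self.abundances.items():
            if value < 0:
                raise MalformedTableError(
                    f"negative abundance for taxon {taxon!r} in sample {self.sample_id!r}"
                )
        total = sum(items.values())
        if total <= 0:
            raise ValidationError(f"sample {self.sample_id!r} has no positive abundances")
        return replace(self, abundances={t: v / total for t, v in items.items()})

    def to_vector(self, phylo: PhylogenyView) -> np.ndarray:
        """Dense abundance vector in the canonical leaf order of `phylo`."""
        vec = np.zeros(phylo.n_leaves)
        for taxon, value in self.abundances.items():
            idx = phylo.leaf_index.get(taxon)
            if idx is None:
                raise ValidationError(
                    f"taxon {taxon!r} of sample {self.sample_id!r} is not a tree leaf; "
                    "align_to_phylogeny() drops unplaced taxa"
                )
            vec[idx] = value
        return vec

    @property
    def sorted_key(self) -> tuple:
        """Chronological ordering key (date beats bare year; id breaks ties)."""
        date = self.date if self.date is not None else f"{self.year}-12-31" if self.year else "9999"
        return (date, self.sample_id)


def align_to_phylogeny(profile: MicrobiomeProfile, phylo: PhylogenyView) -> MicrobiomeProfile:
    """Drop taxa that do not resolve to tree leaves and renormalize.

    Amplicon tables routinely contain unplaced features; these are removed
    with a logged warning rather than raising.
    """
    kept = {t: v for t, v in profile.abundances.items() if t in phylo.leaf_index}
    dropped = set(profile.abundances) - set(kept)
    if dropped:
        logger.warning(
            "sample %s: dropped %d taxa absent from the tree (%.4f abundance mass)",
            profile.sample_id,
            len(dropped),
            sum(profile.abundances[t] for t in dropped),
        )
    return replace(profile, abundances=kept).normalized()


# ----------------------------------------------------------------------
# Table / metadata ingestion
# ----------------------------------------------------------------------

def read_table(path) -> pd.DataFrame:
    """Read a TSV feature table as samples x taxa, auto-detecting orientation.

    The first header cell is the sentinel: a sample-id-like label means
    samples are rows; an OTU/taxon-like label means taxa are rows and the
    table is transposed.
    """
    frame = pd.read_csv(path, sep="\t", index_col=0)
    sentinel = str(frame.index.name or "").strip().lower()
    if sentinel in _TAXON_SENTINELS:
        frame = frame.T
    elif sentinel not in _SAMPLE_SENTINELS:
        logger.info("table %s: unknown header sentinel %r, assuming samples x taxa", path, sentinel)
    frame.index = frame.index.astype(str)
    frame.columns = frame.columns.astype(str)
    if frame.index.duplicated().any():
        dupes = sorted(frame.index[frame.index.duplicated()].unique())
        raise DuplicateSampleError(f"duplicate sample ids in table: {dupes}")
    values = frame.to_numpy(dtype=float)
    if (values < 0).any():
        row, col = np.argwhere(values < 0)[0]
        raise MalformedTableError(
            f"negative entry at sample {frame.index[row]!r}, taxon {frame.columns[col]!r}"
        )
    return frame


def read_metadata(path) -> pd.DataFrame:
    """Read a sample metadata TSV (sample_id, study_id, habitat, year/date, QC)."""
    meta = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "study_id": str}, comment="#")
    required = {"sample_id", "study_id", "habitat", "read_count"}
    missing = required - set(meta.columns)
    if missing:
        raise ValidationError(f"metadata is missing required columns: {sorted(missing)}")
    if "year" not in meta.columns and "date" not in meta.columns:
        raise ValidationError("metadata needs a 'year' or 'date' column")
    if meta["sample_id"].duplicated().any():
        dupes = sorted(meta.loc[meta["sample_id"].duplicated(), "sample_id"].unique())
        raise DuplicateSampleError(f"duplicate sample ids in metadata: {dupes}")
    return meta.set_index("sample_id")


def read_profiles(table_path, metadata_path) -> list[MicrobiomeProfile]:
    """Read a feature table + metadata into normalized profiles.

    Counts (or abundances) are row-normalized per sample. Samples present in
    the table but absent from the metadata are rejected outright.
    """
    table = read_table(table_path)
    meta = read_metadata(metadata_path)
    unknown = [sid for sid in table.index if sid not in meta.index]
    if unknown:
        raise ValidationError(f"samples missing from metadata: {unknown}")

    profiles = []
    for sid, row in table.iterrows():
        info = meta.loc[sid]
        date = info.get("date")
        date = None if (date is None or pd.isna(date)) else str(date)
        year = info.get("year")
        year = None if (year is None or pd.isna(year)) else int(year)
        rate = info.get("mapping_rate")
        rate = None if (rate is None or pd.isna(rate)) else float(rate)
        profile = MicrobiomeProfile(
            sample_id=str(sid),
            abundances={t: float(v) for t, v in row.items() if v > 0},
            study_id=str(info["study_id"]),
            habitat=str(info["habitat"]),
            year=year,
            date=date,
            read_count=int(info["read_count"]),
            mapping_rate=rate,
        ).normalized()
        profiles.append(profile)
    return profiles


# ----------------------------------------------------------------------
# Normalization and quality control
# ----------------------------------------------------------------------

def copy_number_normalize(
    profile: MicrobiomeProfile, copy_numbers: dict[str, float]
) -> MicrobiomeProfile:
    """Correct abundances for 16S rRNA copy-number variation.

    Each abundance is divided by its taxon's copy number and the profile is
    renormalized. Taxa absent from the table default to copy number 1 (with a
    logged warning): multi-copy organisms are otherwise over-counted because
    one cell contributes several amplicons.
    """
    for taxon, cn in copy_numbers.items():
        if not (cn > 0):
            raise ValidationError(f"copy number of taxon {taxon!r} must be > 0, got {cn}")
    missing = [t for t in profile.abundances if t not in copy_numbers]
    if missing:
        logger.warning(
            "sample %s: %d taxa missing from the copy-number table, using copy number 1",
            profile.sample_id,
            len(missing),
        )
    corrected = {
        t: v / copy_numbers.get(t, 1.0) for t, v in profile.abundances.items()
    }
    return replace(profile, abundances=corrected).normalized()


@dataclass
class DroppedSample:
    profile: MicrobiomeProfile
    reason: str


def quality_filter(
    profiles: list[MicrobiomeProfile],
    min_reads: int = DEFAULT_MIN_READS,
    min_mapping_rate: float = DEFAULT_MIN_MAPPING_RATE,
) -> tuple[list[MicrobiomeProfile], list[DroppedSample]]:
    """Keep samples with enough reads and an adequate 16S mapping rate.

    Both thresholds are inclusive (a sample at exactly 500 reads or an 80%
    mapping rate passes). Samples lacking a mapping rate pass that rule, as
    real-world metadata tables often omit it.
    """
    kept: list[MicrobiomeProfile] = []
    dropped: list[DroppedSample] = []
    for profile in profiles:
        if profile.read_count < min_reads:
            dropped.append(DroppedSample(profile, "min_reads"))
        elif profile.mapping_rate is not None and profile.mapping_rate < min_mapping_rate:
            dropped.append(DroppedSample(profile, "mapping_rate"))
        else:
            kept.append(profile)
    if dropped:
        logger.info("quality_filter: kept %d, dropped %d samples", len(kept), len(dropped))
    return kept, dropped
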