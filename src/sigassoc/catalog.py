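"""Somatic mutation tables, trinucleotide contexts and per-sample catalogs.

This module turns MAF-like TSV tables of somatic SNVs into per-sample
96-channel count catalogs and applies the cohort filters used throughout the
pipeline: panel-of-normals exclusion for signature analysis, a minimum
per-sample SNV burden, one sample per patient, cancer-type merges (e.g.
COAD+READ → CRC) and a minimum per-type cohort size.

Coordinates are 1-based fully-closed as in MAF; the context window for a
mutation at ``pos`` is ``[pos-1, pos+1]`` on the forward reference strand.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from ._rng import child_rng
from .channels import BASES, CHANNELS, canonical_channel

__all__ = [
    "MutationRecord",
    "CatalogSet",
    "REQUIRED_COLUMNS",
    "SNV_CLASSES",
    "read_mutations",
    "write_mutations",
    "extract_context",
    "annotate_contexts",
    "is_snv",
    "build_catalogs",
    "filter_cohort",
]

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = (
    "sample_id",
    "patient_id",
    "cancer_type",
    "chrom",
    "pos",
    "ref",
    "alt",
    "variant_class",
)
OPTIONAL_COLUMNS = (
    "gene",
    "protein_change",
    "coding_change",
    "context3",
    "pon_filtered",
)

VARIANT_CLASSES = ("missense", "stop_gain", "indel", "splice", "other")
#: variant classes that can contribute to a 96-channel catalog. Indels have
#: no trinucleotide substitution context and splice calls are unevenly
#: captured by exome baits; every other single-base change counts.
SNV_CLASSES = ("missense", "stop_gain", "other")


@dataclass(frozen=True)
class MutationRecord:
    """One somatic single-nucleotide variant with sample identity.

    ``context3`` is the 3-base forward-strand reference context centred on
    the mutated base; it may be left empty and filled later from a reference
    FASTA. ``pon_filtered`` marks calls flagged by a panel of normals: such
    calls are excluded from signature catalogs but retained when counting
    driver-mutation recurrence.
    """

    sample_id: str
    patient_id: str
    cancer_type: str
    chrom: str
    pos: int
    ref: str
    alt: str
    variant_class: str
    gene: str = ""
    protein_change: str = ""
    coding_change: str = ""
    context3: str = ""
    pon_filtered: bool = False

    def __post_init__(self) -> None:
        if self.variant_class not in VARIANT_CLASSES:
            raise ValueError(f"unknown variant_class {self.variant_class!r}")
        if self.context3 and self.context3[1] != self.ref:
            raise ValueError(
                f"context3 {self.context3!r} middle base != ref {self.ref!r}"
            )


@dataclass
class CatalogSet:
    """Per-sample 96-channel counts plus sample metadata.

    ``counts`` is a samples × 96 integer DataFrame with channel-named
    columns; ``meta`` is indexed identically with columns ``patient_id``,
    ``cancer_type`` and ``total_snvs``.
    """

    counts: pd.DataFrame
    meta: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if list(self.counts.columns) != list(CHANNELS):
            raise ValueError("counts columns must be the 96 channels in order")
        if not self.counts.index.equals(self.meta.index):
            raise ValueError("counts and meta must share a sample index")

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def cancer_types(self) -> pd.Series:
        return self.meta["cancer_type"]

    def subset(self, sample_ids) -> "CatalogSet":
        return CatalogSet(self.counts.loc[sample_ids], self.meta.loc[sample_ids])

    def to_tsv(self, path) -> None:
        out = pd.concat(
            [self.meta[["patient_id", "cancer_type", "total_snvs"]], self.counts],
            axis=1,
        )
        out.to_csv(path, sep="\t", index_label="sample_id")

    @classmethod
    def from_tsv(cls, path) -> "CatalogSet":
        df = pd.read_csv(path, sep="\t", index_col="sample_id")
        meta = df[["patient_id", "cancer_type", "total_snvs"]].copy()
        counts = df[list(CHANNELS)].astype(np.int64)
        return cls(counts, meta)


def read_mutations(path) -> pd.DataFrame:
    """Read a MAF-like mutation TSV, validating required columns."""
    df = pd.read_csv(
        path, sep="\t", dtype={"chrom": str, "sample_id": str, "patient_id": str}
    )
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"mutation table missing columns: {missing}")
    for col in OPTIONAL_COLUMNS:
        if col not in df.columns:
            df[col] = False if col == "pon_filtered" else ""
    df["pos"] = df["pos"].astype(np.int64)
    df["pon_filtered"] = (
        df["pon_filtered"].replace("", False).infer_objects(copy=False).astype(bool)
    )
    df["context3"] = df["context3"].fillna("").astype(str)
    bad = ~df["variant_class"].isin(VARIANT_CLASSES)
    if bad.any():
        raise ValueError(
            f"unknown variant_class values: {sorted(df.loc[bad, 'variant_class'].unique())}"
        )
    return df


def write_mutations(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


class ContextError(ValueError):
    """Raised when a trinucleotide context cannot be read from the reference."""


def extract_context(reference, chrom: str, pos: int) -> str:
    """Forward-strand 3-mer centred on ``pos`` (1-based) from a reference.

    ``reference`` may be a ``pyfaidx.Fasta`` handle or any mapping from
    contig name to sequence string. Windows touching a contig edge, unknown
    contigs and ambiguous bases (anything outside ACGT) raise
    :class:`ContextError`.
    """
    pos = int(pos)
    if isinstance(reference, Mapping):
        if chrom not in reference:
            raise ContextError(f"contig {chrom!r} absent from reference")
        seq = str(reference[chrom])
        if pos < 2 or pos > len(seq) - 1:
            raise ContextError(f"{chrom}:{pos} context window touches contig edge")
        ctx = seq[pos - 2 : pos + 1].upper()
    else:  # pyfaidx.Fasta-like
        if chrom not in reference:
            raise ContextError(f"contig {chrom!r} absent from reference")
        contig = reference[chrom]
        if pos < 2 or pos > len(contig) - 1:
            raise ContextError(f"{chrom}:{pos} context window touches contig edge")
        ctx = str(contig[pos - 2 : pos + 1]).upper()
    if any(b not in BASES for b in ctx):
        raise ContextError(f"ambiguous base in context {ctx!r} at {chrom}:{pos}")
    return ctx


def is_snv(df: pd.DataFrame) -> pd.Series:
    """Boolean mask of rows that are single-base substitutions."""
    ref_ok = df["ref"].isin(BASES)
    alt_ok = df["alt"].isin(BASES)
    return ref_ok & alt_ok & (df["ref"] != df["alt"]) & ~df["variant_class"].isin(
        ("indel", "splice")
    )


def annotate_contexts(df: pd.DataFrame, reference) -> pd.DataFrame:
    """Fill missing ``context3`` values from a reference genome.

    SNV rows whose context cannot be resolved (missing contig, contig edge,
    ambiguous base, or a context that contradicts the ref allele) are dropped
    with a warning; non-SNV rows pass through untouched.
    """
    df = df.copy()
    snv = is_snv(df)
    need = snv & (df["context3"].fillna("") == "")
    drop: list[int] = []
    for idx in df.index[need]:
        row = df.loc[idx]
        try:
            ctx = extract_context(reference, row["chrom"], row["pos"])
        except ContextError as exc:
            logger.warning("excluding %s:%s — %s", row["chrom"], row["pos"], exc)
            drop.append(idx)
            continue
        if ctx[1] != row["ref"]:
            logger.warning(
                "excluding %s:%s — reference middle base %r does not match ref %r",
                row["chrom"],
                row["pos"],
                ctx[1],
                row["ref"],
            )
            drop.append(idx)
            continue
        df.loc[idx, "context3"] = ctx
    if drop:
        warnings.warn(
            f"excluded {len(drop)} SNVs with unresolvable trinucleotide context",
            stacklevel=2,
        )
        df = df.drop(index=drop)
    return df


def build_catalogs(records: pd.DataFrame, include_pon: bool = False) -> CatalogSet:
    """Aggregate SNV records into per-sample 96-channel catalogs.

    Every sample present in ``records`` gets a catalog row, including samples
    whose records are all non-SNV (their counts are zero). Panel-of-normals
    flagged calls are excluded unless ``include_pon`` is set.

    All counted SNVs must carry a ``context3``.
    """
    cols = ["sample_id", "patient_id", "cancer_type"]
    meta = (
        records[cols].drop_duplicates("sample_id").set_index("sample_id")
        if len(records)
        else pd.DataFrame(columns=cols[1:], index=pd.Index([], name="sample_id"))
    )
    counted = records[is_snv(records)]
    if not include_pon:
        counted = counted[~counted["pon_filtered"]]
    if len(counted) and (counted["context3"] == "").any():
        raise ValueError("SNV records without context3; run annotate_contexts first")

    counts = pd.DataFrame(
        0, index=meta.index, columns=list(CHANNELS), dtype=np.int64
    )
    if len(counted):
        chans = [
            canonical_channel(r, a, c)
            for r, a, c in zip(counted["ref"], counted["alt"], counted["context3"])
        ]
        tab = (
            pd.DataFrame({"sample_id": counted["sample_id"].values, "channel": chans})
            .groupby(["sample_id", "channel"])
            .size()
            .unstack(fill_value=0)
        )
        counts.loc[tab.index, tab.columns] = tab
    meta = meta.copy()
    meta["total_snvs"] = counts.sum(axis=1)
    return CatalogSet(counts, meta)


def filter_cohort(
    catalogs: CatalogSet,
    min_snvs: int = 30,
    min_type_size: int = 40,
    merge_map: Mapping[str, str] | None = None,
    seed: int = 0,
) -> CatalogSet:
    """Apply the analysis-cohort filters, in a fixed order.

    1. rename cancer types per ``merge_map`` (e.g. ``{"COAD": "CRC",
       "READ": "CRC"}``);
    2. drop samples with fewer than ``min_snvs`` SNVs;
    3. keep exactly one surviving sample per patient, drawn uniformly from a
       random stream keyed by ``(seed, patient_id)`` — so one patient's draw
       is unaffected by other patients;
    4. drop cancer types left with fewer than ``min_type_size`` samples.

    The operation is idempotent: re-filtering the result with the same
    parameters and seed returns it unchanged.
    """
    meta = catalogs.meta.copy()
    if merge_map:
        meta["cancer_type"] = meta["cancer_type"].replace(dict(merge_map))

    keep = meta["total_snvs"] >= min_snvs
    meta = meta[keep]

    chosen: list[str] = []
    for patient_id, group in meta.groupby("patient_id", sort=True):
        ids = sorted(group.index)
        if len(ids) == 1:
            chosen.append(ids[0])
        else:
            rng = child_rng(seed, "patient", patient_id)
            chosen.append(ids[int(rng.integers(len(ids)))])
    meta = meta.loc[sorted(chosen)]

    sizes = meta["cancer_type"].value_counts()
    big = sizes[sizes >= min_type_size].index
    meta = meta[meta["cancer_type"].isin(big)]

    counts = catalogs.counts.loc[meta.index]
    return CatalogSet(counts, meta)
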