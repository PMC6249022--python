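"""Curation of recurrent somatic driver mutations.

Candidate drivers are recurrent missense/stop-gain SNVs; the final list is
the union of two annotation-supported paths, both requiring recurrence in
the analysis cohort, intersected with an external tumour-driver
designation:

* Path A: within-type recurrence above 3.5% of samples, in a Cancer Gene
  Census Tier-1 gene, and present in more than 10 samples of at least one
  cancer type;
* Path B: catalogued with at least 5 samples in the IntOGen driver
  catalogue (indels and splice variants excluded) and present in more than
  10 samples of at least one cancer type;
* both paths are then filtered to mutations designated tumour drivers by
  the Cancer Genome Interpreter.

Driver identity is genomic — (chrom, pos, ref, alt) — throughout; two
genomic changes producing the same protein change stay distinct.

Recurrence is counted on the un-filtered call stream (no panel-of-normals
exclusion) so that real hotspots shared with normals are not lost.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .channels import CHANNELS, canonical_channel

__all__ = [
    "DriverMutation",
    "AnnotationResources",
    "driver_key",
    "recurrent_candidates",
    "cascade_filter",
    "build_call_matrix",
    "read_cgc_genes",
    "read_intogen_counts",
    "read_cgi_designations",
]


def driver_key(chrom, pos, ref, alt) -> str:
    """Canonical string identity of a genomic change."""
    return f"{chrom}:{int(pos)}:{ref}>{alt}"


@dataclass(frozen=True)
class DriverMutation:
    """One curated driver mutation, identified by its exact genomic change."""

    gene: str
    chrom: str
    pos: int
    ref: str
    alt: str
    coding_change: str = ""
    protein_change: str = ""
    channel: str = ""

    def __post_init__(self) -> None:
        if self.channel and self.channel not in CHANNELS:
            raise ValueError(f"invalid channel {self.channel!r}")

    @property
    def key(self) -> str:
        return driver_key(self.chrom, self.pos, self.ref, self.alt)


@dataclass
class AnnotationResources:
    """External annotation snapshots used by the curation cascade.

    ``cgc_genes``: Cancer Gene Census Tier-1 gene symbols.
    ``intogen_counts``: driver identity (``chrom:pos:ref>alt``) → sample
    count in the IntOGen catalogue.
    ``cgi_drivers``: identities designated tumour drivers by the Cancer
    Genome Interpreter.
    """

    cgc_genes: set[str]
    intogen_counts: dict[str, int]
    cgi_drivers: set[str]


def read_cgc_genes(path) -> set[str]:
    """One gene symbol per line (header optional if named 'gene')."""
    genes = pd.read_csv(path, sep="\t", header=None)[0].astype(str)
    return {g for g in genes if g and g.lower() != "gene"}


def read_intogen_counts(path) -> dict[str, int]:
    """TSV with columns gene, chrom, pos, ref, alt, sample_count."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return {
        driver_key(r.chrom, r.pos, r.ref, r.alt): int(r.sample_count)
        for r in df.itertuples()
    }


def read_cgi_designations(path) -> set[str]:
    """TSV with columns chrom, pos, ref, alt, designation."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    driver = df["designation"].str.lower().str.contains("driver")
    return {
        driver_key(r.chrom, r.pos, r.ref, r.alt)
        for r in df[driver].itertuples()
    }


def _per_type_sample_counts(
    records: pd.DataFrame, cohort_types: pd.Series
) -> pd.DataFrame:
    """Distinct mutated samples per (identity, cancer type).

    ``cohort_types`` maps sample_id → (merged) cancer type and defines the
    sample universe; records from samples outside it are ignored.
    """
    df = records[records["sample_id"].isin(cohort_types.index)].copy()
    df["key"] = [
        driver_key(c, p, r, a)
        for c, p, r, a in zip(df["chrom"], df["pos"], df["ref"], df["alt"])
    ]
    df["ctype"] = df["sample_id"].map(cohort_types)
    return (
        df.drop_duplicates(["key", "sample_id"])
        .groupby(["key", "ctype"])
        .size()
        .unstack(fill_value=0)
    )


def recurrent_candidates(
    records: pd.DataFrame,
    cohort_types: pd.Series,
    min_fraction: float = 0.035,
) -> set[str]:
    """Missense/stop-gain identities recurrent within at least one type.

    Recurrence is the fraction of the cancer type's samples carrying the
    identity; the candidate is kept when that fraction strictly exceeds
    ``min_fraction`` somewhere. ``cohort_types`` maps sample_id → cancer
    type with any COAD/READ-style merges already applied.
    """
    coding = records[records["variant_class"].isin(("missense", "stop_gain"))]
    if len(coding) == 0:
        return set()
    counts = _per_type_sample_counts(coding, cohort_types)
    type_sizes = cohort_types.value_counts()
    fractions = counts.div(type_sizes.reindex(counts.columns), axis=1)
    recurrent = fractions.gt(min_fraction).any(axis=1)
    return set(counts.index[recurrent])


def cascade_filter(
    records: pd.DataFrame,
    candidates: set[str],
    resources: AnnotationResources,
    cohort_types: pd.Series,
    min_cohort_samples: int = 10,
    min_intogen: int = 5,
) -> list[DriverMutation]:
    """Run the two-path annotation cascade and return the final driver list.

    ``candidates`` is the output of :func:`recurrent_candidates`;
    ``cohort_types`` maps the *filtered analysis cohort's* sample_id →
    cancer type (recurrence for the ``> min_cohort_samples`` rule is counted
    there). Indels and splice variants never survive either path. The final
    list is deduplicated by genomic identity and sorted for reproducibility.
    """
    info: dict[str, dict] = {}
    for r in records.itertuples():
        key = driver_key(r.chrom, r.pos, r.ref, r.alt)
        if key not in info:
            info[key] = {
                "gene": r.gene,
                "chrom": str(r.chrom),
                "pos": int(r.pos),
                "ref": r.ref,
                "alt": r.alt,
                "coding_change": r.coding_change,
                "protein_change": r.protein_change,
                "variant_class": r.variant_class,
                "context3": r.context3,
            }

    counts = _per_type_sample_counts(records, cohort_types)
    deep = set(counts.index[(counts > min_cohort_samples).any(axis=1)])

    def usable(key: str) -> bool:
        meta = info.get(key)
        if meta is None:
            return False
        if meta["variant_class"] in ("indel", "splice"):
            return False
        return len(str(meta["ref"])) == 1 and len(str(meta["alt"])) == 1

    path_a = {
        k
        for k in candidates
        if usable(k) and info[k]["gene"] in resources.cgc_genes and k in deep
    }
    path_b = {
        k
        for k, n in resources.intogen_counts.items()
        if n >= min_intogen and usable(k) and k in deep
    }
    final = (path_a | path_b) & resources.cgi_drivers

    drivers = []
    for key in sorted(final):
        meta = info[key]
        ctx = meta["context3"]
        channel = canonical_channel(meta["ref"], meta["alt"], ctx) if ctx else ""
        drivers.append(
            DriverMutation(
                gene=meta["gene"],
                chrom=meta["chrom"],
                pos=meta["pos"],
                ref=meta["ref"],
                alt=meta["alt"],
                coding_change=meta["coding_change"],
                protein_change=meta["protein_change"],
                channel=channel,
            )
        )
    return drivers


def build_call_matrix(
    records: pd.DataFrame,
    drivers: list[DriverMutation],
    cohort_types: pd.Series,
) -> pd.DataFrame:
    """Binary samples × drivers presence matrix over the analysis cohort.

    An entry is 1 when the sample carries at least one record matching the
    driver's genomic identity (duplicates collapse to 1).
    """
    keys = [d.key for d in drivers]
    mat = pd.DataFrame(
        0, index=cohort_types.index, columns=keys, dtype=np.int8
    )
    if len(records) and keys:
        df = records[records["sample_id"].isin(cohort_types.index)]
        rec_keys = [
            driver_key(c, p, r, a)
            for c, p, r, a in zip(df["chrom"], df["pos"], df["ref"], df["alt"])
        ]
        hits = pd.DataFrame({"sample_id": df["sample_id"].values, "key": rec_keys})
        hits = hits[hits["key"].isin(keys)].drop_duplicates()
        for sid, key in zip(hits["sample_id"], hits["key"]):
            mat.loc[sid, key] = 1
    return mat


def frame_to_drivers(df: pd.DataFrame) -> list[DriverMutation]:
    """Rebuild DriverMutation objects from a drivers TSV frame."""
    return [
        DriverMutation(
            gene=str(r.gene),
            chrom=str(r.chrom),
            pos=int(r.pos),
            ref=str(r.ref),
            alt=str(r.alt),
            coding_change="" if pd.isna(r.coding_change) else str(r.coding_change),
            protein_change="" if pd.isna(r.protein_change) else str(r.protein_change),
            channel=str(r.channel),
        )
        for r in df.itertuples()
    ]


def drivers_to_frame(drivers: list[DriverMutation]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene": d.gene,
                "chrom": d.chrom,
                "pos": d.pos,
                "ref": d.ref,
                "alt": d.alt,
                "coding_change": d.coding_change,
                "protein_change": d.protein_change,
                "channel": d.channel,
            }
            for d in drivers
        ]
    )
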