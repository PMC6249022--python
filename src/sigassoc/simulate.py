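"""Synthetic cohorts with known signature mixtures and driver links.

The generator reproduces the statistical structure the analysis assumes,
with full bookkeeping of the truth so every pipeline stage can be tested
without any download:

* per sample, signature exposures drawn from a Dirichlet prior and an SNV
  burden from a rounded lognormal (floored at 30 so no synthetic sample
  trips the cohort filter unintentionally);
* 96-channel counts drawn from a multinomial over the exposure-weighted
  signature mixture;
* per planted driver, presence drawn from the logistic link
  ``P(mutant) = expit(beta0 + beta1 * x_target)`` on the sample's true
  exposure of the driver's target signature (``beta1 = 0`` gives an exact
  null);
* optionally, the whole cohort can be re-expressed as mutation records plus
  a small synthetic reference FASTA, so catalog construction round-trips.

Every draw comes from a stream keyed by (master seed, cancer type, sample,
purpose), so outputs are byte-identical across reruns and insensitive to
the order in which entities are generated.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from ._rng import child_rng
from .catalog import CatalogSet
from .channels import CHANNELS, CHANNEL_INDEX, channel_parts, reverse_complement
from .drivers import DriverMutation
from .signatures import SignatureMatrix

__all__ = [
    "PlantedDriver",
    "CancerTypeConfig",
    "SyntheticCohortConfig",
    "SyntheticTruth",
    "toy_signature_matrix",
    "simulate_cohort",
    "emit_records",
    "write_reference_fasta",
    "preset_config",
]

#: all 64 trinucleotides get a 3-bp contig in the synthetic reference, so
#: any channel (and either strand representation) is realisable at pos 2
_ALL_TRINUCS = tuple(
    a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
)


@dataclass(frozen=True)
class PlantedDriver:
    """A driver mutation planted with a known logistic link.

    Presence is Bernoulli with ``P = expit(beta0 + beta1 * x)`` where ``x``
    is the sample's true exposure of ``target_signature``; ``beta1 = 0``
    plants an exact null. The genomic identity is synthesised from the gene
    name and channel (one private contig per driver, mutation at pos 2).
    """

    gene: str
    channel: str
    target_signature: str
    beta0: float
    beta1: float

    def __post_init__(self) -> None:
        if self.channel not in CHANNEL_INDEX:
            raise ValueError(f"invalid channel {self.channel!r}")

    @property
    def context3(self) -> str:
        _, _, ctx = channel_parts(self.channel)
        return ctx

    @property
    def mutation(self) -> DriverMutation:
        ref, alt, ctx = channel_parts(self.channel)
        chrom = "drv_" + re.sub(r"[^A-Za-z0-9]", "", f"{self.gene}{ctx}{alt}")
        return DriverMutation(
            gene=self.gene,
            chrom=chrom,
            pos=2,
            ref=ref,
            alt=alt,
            coding_change=f"c.2{ref}>{alt}",
            protein_change="",
            channel=self.channel,
        )

    @property
    def key(self) -> str:
        return self.mutation.key


@dataclass
class CancerTypeConfig:
    """Generator settings for one synthetic cancer-type cohort.

    ``dirichlet_alpha`` holds one positive concentration per signature;
    sparse values (< 1) give the skewed, few-signatures-per-sample
    exposures seen in real tumours. Burdens are ``round(lognormal)`` with
    the given log-scale parameters, floored at 30 SNVs.
    """

    name: str
    n_samples: int
    dirichlet_alpha: tuple[float, ...]
    burden_log_mean: float = math.log(100.0)
    burden_log_sd: float = 0.6
    planted_drivers: list[PlantedDriver] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if any(a <= 0 for a in self.dirichlet_alpha):
            raise ValueError("dirichlet_alpha entries must be > 0")


@dataclass
class SyntheticCohortConfig:
    """Full multi-type cohort specification plus the signature matrix."""

    cancer_types: list[CancerTypeConfig]
    signature_matrix: SignatureMatrix

    def __post_init__(self) -> None:
        S = self.signature_matrix.n_signatures
        for ct in self.cancer_types:
            if len(ct.dirichlet_alpha) != S:
                raise ValueError(
                    f"{ct.name}: dirichlet_alpha length {len(ct.dirichlet_alpha)} "
                    f"!= {S} signatures"
                )
            for d in ct.planted_drivers:
                if d.target_signature not in self.signature_matrix.signature_names:
                    raise ValueError(
                        f"unknown target signature {d.target_signature!r}"
                    )

    @property
    def all_drivers(self) -> list[PlantedDriver]:
        seen: dict[str, PlantedDriver] = {}
        for ct in self.cancer_types:
            for d in ct.planted_drivers:
                seen.setdefault(d.key, d)
        return list(seen.values())


@dataclass
class SyntheticTruth:
    """Ground truth recorded by :func:`simulate_cohort`.

    ``exposures`` are the true per-sample Dirichlet draws (not refits);
    ``driver_truth`` has one row per (cancer type, planted driver) with the
    generating ``beta0``/``beta1`` and the realised mutant count;
    ``triple_labels`` marks every (cancer type, driver, signature) triple as
    alternative (the planted link) or null.
    """

    exposures: pd.DataFrame
    burdens: pd.Series
    driver_truth: pd.DataFrame
    triple_labels: pd.DataFrame

    def true_positive_triples(self) -> set[tuple[str, str, str]]:
        alt = self.triple_labels[self.triple_labels["label"] == "alternative"]
        return set(zip(alt["cancer_type"], alt["driver"], alt["signature"]))


def toy_signature_matrix(
    n_signatures: int = 5, seed: int = 0, support: int = 14
) -> SignatureMatrix:
    """Sparse synthetic signatures with partially overlapping support.

    Each signature concentrates on ``support`` channels: a private block
    plus a couple of channels shared with its neighbour, with Dirichlet
    weights — distinct enough for recovery tests, overlapping enough to
    exercise the mixture machinery. As in real signature catalogues, a
    small uniform floor (1% of mass) keeps every channel reachable.
    """
    rng = child_rng(seed, "toy-signatures")
    n_ch = len(CHANNELS)
    probs = np.zeros((n_signatures, n_ch))
    block = n_ch // n_signatures
    for s in range(n_signatures):
        own = np.arange(s * block, s * block + min(block, support))
        shared = np.arange((s + 1) % n_signatures * block,
                           (s + 1) % n_signatures * block + 2)
        idx = np.unique(np.concatenate([own, shared]))[:support]
        probs[s, idx] = rng.dirichlet(np.full(len(idx), 0.8))
    probs = 0.99 * probs + 0.01 / n_ch
    probs /= probs.sum(axis=1, keepdims=True)
    names = [f"SynthSig{j + 1}" for j in range(n_signatures)]
    return SignatureMatrix(names, probs, normalized="exome")


def simulate_cohort(
    config: SyntheticCohortConfig, master_seed: int = 0
) -> tuple[CatalogSet, pd.DataFrame, SyntheticTruth]:
    """Draw a full synthetic cohort.

    Returns per-sample catalogs, the binary driver call matrix and the
    :class:`SyntheticTruth` bookkeeping. When a planted-driver carrier's
    multinomial draw left its driver channel empty, one mutation of that
    channel is added (burden +1) so the driver is always one of the
    sample's counted mutations and record emission round-trips exactly.
    """
    sig = config.signature_matrix
    S = sig.n_signatures
    sample_ids: list[str] = []
    meta_rows: list[dict] = []
    count_rows: list[np.ndarray] = []
    expo_rows: list[np.ndarray] = []
    burdens: list[int] = []
    calls: dict[str, dict[str, int]] = {}
    driver_rows: list[dict] = []
    triple_rows: list[dict] = []

    all_keys = [d.key for d in config.all_drivers]
    for ct in config.cancer_types:
        mutant_counts = {d.key: 0 for d in ct.planted_drivers}
        for i in range(ct.n_samples):
            sid = f"{ct.name}_s{i:04d}"
            expo = child_rng(master_seed, ct.name, i, "exposure").dirichlet(
                np.asarray(ct.dirichlet_alpha, dtype=float)
            )
            burden = max(
                30,
                int(
                    round(
                        child_rng(master_seed, ct.name, i, "burden").lognormal(
                            ct.burden_log_mean, ct.burden_log_sd
                        )
                    )
                ),
            )
            channel_probs = expo @ sig.probs
            counts = child_rng(master_seed, ct.name, i, "counts").multinomial(
                burden, channel_probs
            )
            row_calls = dict.fromkeys(all_keys, 0)
            for d in ct.planted_drivers:
                x = expo[sig.signature_names.index(d.target_signature)]
                p = expit(d.beta0 + d.beta1 * x)
                present = (
                    child_rng(master_seed, ct.name, i, "driver", d.key).random() < p
                )
                if present:
                    row_calls[d.key] = 1
                    mutant_counts[d.key] += 1
                    ch = CHANNEL_INDEX[d.channel]
                    if counts[ch] == 0:  # carrier must hold its own mutation
                        counts[ch] += 1
                        burden += 1
            sample_ids.append(sid)
            meta_rows.append(
                {"patient_id": f"{ct.name}_p{i:04d}", "cancer_type": ct.name}
            )
            count_rows.append(counts)
            expo_rows.append(expo)
            burdens.append(burden)
            calls[sid] = row_calls
        for d in ct.planted_drivers:
            driver_rows.append(
                {
                    "cancer_type": ct.name,
                    "driver": d.key,
                    "gene": d.gene,
                    "channel": d.channel,
                    "target_signature": d.target_signature,
                    "beta0": d.beta0,
                    "beta1": d.beta1,
                    "n_mutant": mutant_counts[d.key],
                }
            )
            for s_name in sig.signature_names:
                is_alt = d.beta1 != 0 and s_name == d.target_signature
                triple_rows.append(
                    {
                        "cancer_type": ct.name,
                        "driver": d.key,
                        "signature": s_name,
                        "label": "alternative" if is_alt else "null",
                    }
                )

    index = pd.Index(sample_ids, name="sample_id")
    stacked = (
        np.vstack(count_rows) if count_rows else np.empty((0, len(CHANNELS)), int)
    )
    counts_df = pd.DataFrame(
        stacked, index=index, columns=list(CHANNELS), dtype=np.int64
    )
    meta = pd.DataFrame(meta_rows, index=index)
    meta["total_snvs"] = counts_df.sum(axis=1)
    catalogs = CatalogSet(counts_df, meta)
    call_matrix = pd.DataFrame(0, index=index, columns=all_keys, dtype=np.int8)
    for sid, row_calls in calls.items():
        for key, carried in row_calls.items():
            if carried:
                call_matrix.loc[sid, key] = 1
    truth = SyntheticTruth(
        exposures=pd.DataFrame(
            np.vstack(expo_rows) if expo_rows else np.empty((0, S)),
            index=index,
            columns=list(sig.signature_names),
        ),
        burdens=pd.Series(burdens, index=index, name="burden"),
        driver_truth=pd.DataFrame(driver_rows),
        triple_labels=pd.DataFrame(triple_rows),
    )
    return catalogs, call_matrix, truth


def emit_records(
    catalogs: CatalogSet,
    call_matrix: pd.DataFrame,
    config: SyntheticCohortConfig,
    purine_fraction: float = 0.0,
    master_seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Re-express catalogs as mutation records plus a synthetic reference.

    Each counted mutation becomes one record placed at position 2 of a
    3-bp contig holding its trinucleotide context; for a sample carrying a
    planted driver, one mutation of the driver's channel is emitted with the
    driver's genomic identity instead. ``build_catalogs`` on the result
    reproduces the input counts exactly.

    ``purine_fraction`` > 0 re-emits that fraction of passenger records in
    the purine-strand representation (complemented alleles, reverse-
    complemented context on the matching contig) — the catalogs must be
    invariant to this.
    """
    drivers = {d.key: d for d in config.all_drivers}
    records: list[dict] = []
    reference = {f"ctx_{t}": t for t in _ALL_TRINUCS}
    for d in drivers.values():
        reference[d.mutation.chrom] = d.context3

    channel_decomp = {ch: channel_parts(ch) for ch in CHANNELS}
    for sid in catalogs.sample_ids:
        patient = catalogs.meta.loc[sid, "patient_id"]
        ctype = catalogs.meta.loc[sid, "cancer_type"]
        counts = catalogs.counts.loc[sid]
        remaining = counts.to_dict()
        if sid in call_matrix.index:
            for key, carried in call_matrix.loc[sid].items():
                if not carried:
                    continue
                d = drivers[key]
                if remaining.get(d.channel, 0) < 1:
                    raise ValueError(
                        f"{sid} carries {key} but has no {d.channel} mutation"
                    )
                remaining[d.channel] -= 1
                m = d.mutation
                records.append(
                    {
                        "sample_id": sid,
                        "patient_id": patient,
                        "cancer_type": ctype,
                        "chrom": m.chrom,
                        "pos": m.pos,
                        "ref": m.ref,
                        "alt": m.alt,
                        "gene": m.gene,
                        "protein_change": m.protein_change,
                        "coding_change": m.coding_change,
                        "variant_class": "missense",
                        "context3": d.context3,
                        "pon_filtered": False,
                    }
                )
        flip_rng = (
            child_rng(master_seed, "strand-flip", sid)
            if purine_fraction > 0
            else None
        )
        for channel, n in remaining.items():
            if n == 0:
                continue
            ref, alt, ctx = channel_decomp[channel]
            for _ in range(int(n)):
                r, a, c = ref, alt, ctx
                if flip_rng is not None and flip_rng.random() < purine_fraction:
                    c = reverse_complement(ctx)
                    r, a = c[1], reverse_complement(alt)
                records.append(
                    {
                        "sample_id": sid,
                        "patient_id": patient,
                        "cancer_type": ctype,
                        "chrom": f"ctx_{c}",
                        "pos": 2,
                        "ref": r,
                        "alt": a,
                        "gene": "",
                        "protein_change": "",
                        "coding_change": "",
                        "variant_class": "other",
                        "context3": c,
                        "pon_filtered": False,
                    }
                )
    columns = [
        "sample_id", "patient_id", "cancer_type", "chrom", "pos", "ref", "alt",
        "gene", "protein_change", "coding_change", "variant_class",
        "context3", "pon_filtered",
    ]
    return pd.DataFrame(records, columns=columns), reference


def write_reference_fasta(reference: dict[str, str], path) -> None:
    """Write the synthetic reference contigs as an uncompressed FASTA."""
    with open(path, "w") as fh:
        for name in sorted(reference):
            fh.write(f">{name}\n{reference[name]}\n")


def preset_config(
    preset: str = "planted",
    n_types: int = 2,
    n_samples: int = 300,
    n_signatures: int = 5,
    n_linked: int = 4,
    n_null: int = 4,
    effect_beta1: float = math.log(6.0),
    baseline_beta0: float = -1.5,
    seed: int = 0,
) -> SyntheticCohortConfig:
    """Ready-made cohort configurations.

    ``"null"`` plants only beta1 = 0 drivers; ``"planted"`` links every
    driver to one signature at ``effect_beta1``; ``"mixed"`` plants
    ``n_linked`` linked plus ``n_null`` null drivers per cancer type.
    Exposure priors are sparse (alpha = 0.3) and burdens lognormal with
    median 100 SNVs, floored at 30.
    """
    if preset not in ("null", "planted", "mixed"):
        raise ValueError(f"unknown preset {preset!r}")
    sig = toy_signature_matrix(n_signatures=n_signatures, seed=seed)
    channels_cycle = [CHANNELS[i] for i in range(0, 96, 7)]
    types = []
    for t in range(n_types):
        name = f"SYN{t + 1}"
        planted: list[PlantedDriver] = []
        k_linked = 0 if preset == "null" else n_linked
        k_null = n_null if preset in ("null", "mixed") else 0
        if preset == "planted":
            k_linked = n_linked + n_null
        for j in range(k_linked):
            planted.append(
                PlantedDriver(
                    gene=f"G{t + 1}L{j + 1}",
                    channel=channels_cycle[(t * 7 + j) % len(channels_cycle)],
                    target_signature=sig.signature_names[j % n_signatures],
                    beta0=baseline_beta0,
                    beta1=effect_beta1,
                )
            )
        for j in range(k_null):
            planted.append(
                PlantedDriver(
                    gene=f"G{t + 1}N{j + 1}",
                    channel=channels_cycle[(t * 7 + n_linked + j + 3) % len(channels_cycle)],
                    target_signature=sig.signature_names[j % n_signatures],
                    beta0=-1.4,
                    beta1=0.0,
                )
            )
        types.append(
            CancerTypeConfig(
                name=name,
                n_samples=n_samples,
                dirichlet_alpha=tuple([0.3] * n_signatures),
                planted_drivers=planted,
            )
        )
    return SyntheticCohortConfig(cancer_types=types, signature_matrix=sig)
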