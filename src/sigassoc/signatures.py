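"""Fixed mutational-signature probability matrices.

A signature is a probability distribution over the 96 substitution channels;
a catalog of S signatures is stored as a row-stochastic S × 96 matrix. The
matrices distributed with COSMIC's "Signatures of Mutational Processes in
Human Cancer" catalogue are derived from whole genomes; refitting exome
catalogs against them first rescales each channel by an exome/genome
trinucleotide-frequency ratio and renormalises ("exome normalisation").
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd

from .channels import (
    CHANNELS,
    CHANNEL_INDEX,
    PYRIMIDINE_TRINUCS,
    channel_parts,
    collapse_trinucleotide,
    parse_channel,
)

__all__ = [
    "SignatureMatrix",
    "read_signature_matrix",
    "read_trinucleotide_weights",
    "default_trinucleotide_weights",
    "exome_normalize",
    "channel_amount",
    "published_channel_probs",
    "published_aetiologies",
]

_ROW_TOL = 1e-9


@dataclass
class SignatureMatrix:
    """S × 96 row-stochastic probability matrix over the channel alphabet.

    ``normalized`` records whether channel probabilities are on the genome
    scale (as distributed) or have been exome-normalised.
    """

    signature_names: list[str]
    probs: np.ndarray
    normalized: str = "genome"

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.shape != (len(self.signature_names), len(CHANNELS)):
            raise ValueError(
                f"probs must be {len(self.signature_names)}x96, got {self.probs.shape}"
            )
        if (self.probs < 0).any():
            raise ValueError("signature probabilities must be non-negative")
        rows = self.probs.sum(axis=1)
        if not np.allclose(rows, 1.0, atol=_ROW_TOL, rtol=0):
            raise ValueError("signature rows must each sum to 1")
        if self.normalized not in ("genome", "exome"):
            raise ValueError(f"unknown normalization flag {self.normalized!r}")

    @property
    def n_signatures(self) -> int:
        return len(self.signature_names)

    def row(self, signature: str) -> np.ndarray:
        return self.probs[self._sig_index(signature)]

    def _sig_index(self, signature: str) -> int:
        try:
            return self.signature_names.index(signature)
        except ValueError:
            raise KeyError(f"unknown signature {signature!r}") from None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.probs.T, index=list(CHANNELS), columns=self.signature_names
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="channel")


def read_signature_matrix(path, normalized: str = "genome") -> SignatureMatrix:
    """Read a signature matrix TSV (channels in rows, signatures in columns).

    Channel labels may use either the ``A[C>A]A`` or the ``ACA>AAA`` dialect,
    in any row order; they are normalised onto the canonical channel set.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = [parse_channel(c) for c in df.index]
    if sorted(df.index) != sorted(CHANNELS):
        missing = set(CHANNELS) - set(df.index)
        raise ValueError(f"signature matrix missing channels: {sorted(missing)[:5]}...")
    df = df.loc[list(CHANNELS)]
    probs = df.to_numpy(dtype=float).T
    probs = probs / probs.sum(axis=1, keepdims=True)
    return SignatureMatrix(list(df.columns), probs, normalized=normalized)


def read_trinucleotide_weights(path) -> dict[str, float]:
    """Read exome/genome frequency ratios, one per pyrimidine trinucleotide.

    TSV with columns ``trinucleotide`` and ``weight``; purine-centred labels
    are collapsed onto their pyrimidine-strand representatives.
    """
    df = pd.read_csv(path, sep="\t")
    weights: dict[str, float] = {}
    for trinuc, w in zip(df.iloc[:, 0], df.iloc[:, 1].astype(float)):
        if w <= 0:
            raise ValueError(f"non-positive weight for {trinuc!r}")
        weights[collapse_trinucleotide(trinuc)] = w
    missing = set(PYRIMIDINE_TRINUCS) - set(weights)
    if missing:
        raise ValueError(f"weights missing trinucleotides: {sorted(missing)}")
    return weights


def default_trinucleotide_weights() -> dict[str, float]:
    """The synthetic exome/genome weight table shipped with the package."""
    ref = resources.files("sigassoc.data") / "exome_trinucleotide_weights_synthetic.tsv"
    with resources.as_file(ref) as path:
        return read_trinucleotide_weights(path)


def exome_normalize(
    sig: SignatureMatrix, weights: Mapping[str, float]
) -> SignatureMatrix:
    """Rescale a genome-form matrix by exome/genome trinucleotide ratios.

    Each channel probability is multiplied by the weight of its (strand-
    collapsed) trinucleotide context, then every row is renormalised to sum
    to 1.
    """
    if sig.normalized != "genome":
        raise ValueError("matrix is already exome-normalised")
    w = np.empty(len(CHANNELS))
    for i, ch in enumerate(CHANNELS):
        _, _, ctx = channel_parts(ch)
        key = collapse_trinucleotide(ctx)
        if key not in weights:
            raise ValueError(f"missing weight for trinucleotide {key!r}")
        w[i] = float(weights[key])
    probs = sig.probs * w[None, :]
    probs = probs / probs.sum(axis=1, keepdims=True)
    return SignatureMatrix(list(sig.signature_names), probs, normalized="exome")


def channel_amount(
    sig: SignatureMatrix, signature: str, channel: str
) -> tuple[float, str]:
    """Percentage of a signature's mutations falling in one channel.

    Returns ``(percent, rank)`` where ``percent`` is 100 × the channel
    probability and ``rank`` is ``"high"`` when the amount exceeds 5% and
    ``"low"`` otherwise — the convention used when annotating how typical a
    driver mutation's trinucleotide context is of an associated signature.
    """
    ch = parse_channel(channel)
    percent = 100.0 * sig.row(signature)[CHANNEL_INDEX[ch]]
    rank = "high" if percent > 5.0 else "low"
    return percent, rank


def published_channel_probs() -> pd.DataFrame:
    """Pinned COSMIC v2 channel probabilities for recurrent driver contexts.

    The full 30-signature COSMIC v2 matrix is a user-supplied input; this
    table pins only the published per-channel probabilities needed to
    annotate the trinucleotide contexts of recurrent driver mutations.
    Columns: ``signature``, ``channel``, ``probability``.
    """
    ref = resources.files("sigassoc.data") / "cosmic_v2_selected_channel_probs.tsv"
    with resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t")
    df["channel"] = [parse_channel(c) for c in df["channel"]]
    return df


def pinned_signature_matrix() -> SignatureMatrix:
    """Signature matrix carrying the pinned published channel probabilities.

    Rows are built from :func:`published_channel_probs`: each pinned channel
    takes its published probability and the remaining mass is spread
    uniformly over the other channels so every row is a valid distribution.
    Only the pinned channels are meaningful — use this matrix solely to
    annotate those contexts (``channel_amount``), never for refitting.
    """
    pinned = published_channel_probs()
    names = list(dict.fromkeys(pinned["signature"]))
    probs = np.zeros((len(names), len(CHANNELS)))
    for i, name in enumerate(names):
        sub = pinned[pinned["signature"] == name]
        idx = [CHANNEL_INDEX[c] for c in sub["channel"]]
        vals = sub["probability"].to_numpy(dtype=float)
        probs[i, idx] = vals
        rest = np.setdiff1d(np.arange(len(CHANNELS)), idx)
        probs[i, rest] = (1.0 - vals.sum()) / len(rest)
    return SignatureMatrix(names, probs, normalized="genome")


def published_aetiologies() -> dict[str, str]:
    """Proposed aetiology strings for COSMIC v2 signatures (annotation only)."""
    ref = resources.files("sigassoc.data") / "signature_aetiology.tsv"
    with resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t")
    return dict(zip(df["signature"], df["aetiology"]))
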