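"""The 96-channel single-base-substitution alphabet.

A somatic SNV is classified by its pyrimidine-strand substitution (C>A, C>G,
C>T, T>A, T>C, T>G) together with its 5' and 3' flanking reference bases.
Mutations reported with a purine reference base (A or G) are reverse-
complemented before classification, collapsing the two strands onto 96
channels named like ``A[C>T]G``.

Channel order follows the COSMIC convention: the six substitution classes in
the order C>A, C>G, C>T, T>A, T>C, T>G, and within each class the 16 flank
pairs alphabetically (A_A, A_C, ..., T_T).
"""

from __future__ import annotations

import re

__all__ = [
    "BASES",
    "CHANNELS",
    "CHANNEL_INDEX",
    "PYRIMIDINE_TRINUCS",
    "SUBSTITUTION_CLASSES",
    "reverse_complement",
    "canonical_channel",
    "channel_parts",
    "parse_channel",
    "collapse_trinucleotide",
]

BASES = ("A", "C", "G", "T")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

SUBSTITUTION_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _build_channels() -> tuple[str, ...]:
    names = []
    for sub in SUBSTITUTION_CLASSES:
        ref = sub[0]
        for five in BASES:
            for three in BASES:
                names.append(f"{five}[{sub}]{three}")
    return tuple(names)


CHANNELS: tuple[str, ...] = _build_channels()
CHANNEL_INDEX: dict[str, int] = {name: i for i, name in enumerate(CHANNELS)}

#: the 32 pyrimidine-centred trinucleotides, in the order they first appear
#: as channel contexts (C-centred then T-centred, flanks alphabetical).
PYRIMIDINE_TRINUCS: tuple[str, ...] = tuple(
    f"{five}{mid}{three}" for mid in "CT" for five in BASES for three in BASES
)

_CHANNEL_RE = re.compile(r"^([ACGT])\[([ACGT])>([ACGT])\]([ACGT])$")
# "ACA>AAA"-style dialect: two trinucleotides differing at the middle base
_TRIPLET_RE = re.compile(r"^([ACGT]{3})>([ACGT]{3})$")


class ChannelError(ValueError):
    """Raised for malformed bases, contexts or channel names."""


def canonical_channel(ref_allele: str, alt_allele: str, context3: str) -> str:
    """Canonical 96-channel name for an SNV in its trinucleotide context.

    Purine-reference mutations are reverse-complemented first, so the result
    always carries a pyrimidine (C/T) reference base; the two strand
    representations of one mutation map to the same channel.

    Parameters
    ----------
    ref_allele, alt_allele : str
        Single reference/alternate bases, A/C/G/T, distinct.
    context3 : str
        Three reference bases centred on the mutated position, forward
        strand; the middle base must equal ``ref_allele``.
    """
    ref = str(ref_allele).upper()
    alt = str(alt_allele).upper()
    ctx = str(context3).upper()
    if ref not in BASES or alt not in BASES:
        raise ChannelError(f"non-ACGT allele in {ref!r}>{alt!r}")
    if ref == alt:
        raise ChannelError(f"ref and alt alleles are identical: {ref!r}")
    if len(ctx) != 3 or any(b not in BASES for b in ctx):
        raise ChannelError(f"context must be 3 ACGT bases, got {ctx!r}")
    if ctx[1] != ref:
        raise ChannelError(
            f"context middle base {ctx[1]!r} does not match ref allele {ref!r}"
        )
    if ref in ("A", "G"):  # purine: flip to the pyrimidine strand
        ref = ref.translate(_COMPLEMENT)
        alt = alt.translate(_COMPLEMENT)
        ctx = reverse_complement(ctx)
    return f"{ctx[0]}[{ref}>{alt}]{ctx[2]}"


def channel_parts(channel: str) -> tuple[str, str, str]:
    """Split a channel name into (ref, alt, pyrimidine-strand context)."""
    m = _CHANNEL_RE.match(channel)
    if not m:
        raise ChannelError(f"malformed channel name {channel!r}")
    five, ref, alt, three = m.groups()
    return ref, alt, f"{five}{ref}{three}"


def parse_channel(name: str) -> str:
    """Normalise a channel label from either supported dialect.

    Accepts ``A[C>A]A`` directly and the ``ACA>AAA`` triplet form used by
    some signature-matrix distributions; either strand representation is
    collapsed onto the canonical pyrimidine-centred name.
    """
    label = str(name).strip().upper()
    m = _CHANNEL_RE.match(label)
    if m:
        five, ref, alt, three = m.groups()
        return canonical_channel(ref, alt, f"{five}{ref}{three}")
    m = _TRIPLET_RE.match(label)
    if m:
        before, after = m.groups()
        if before[0] != after[0] or before[2] != after[2] or before[1] == after[1]:
            raise ChannelError(f"triplet pair {label!r} is not a single substitution")
        return canonical_channel(before[1], after[1], before)
    raise ChannelError(f"unrecognised channel label {name!r}")


def collapse_trinucleotide(trinuc: str) -> str:
    """Pyrimidine-strand representative of a trinucleotide (for weights)."""
    t = str(trinuc).upper()
    if len(t) != 3 or any(b not in BASES for b in t):
        raise ChannelError(f"malformed trinucleotide {trinuc!r}")
    return t if t[1] in ("C", "T") else reverse_complement(t)
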