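"""Trinucleotide substitution channels in the canonical 96-channel layout.

Single-base substitutions are reported with the mutated base normalized to a
pyrimidine (C or T): a G>T call is folded onto the opposite strand and
recorded as C>A with the reverse-complemented flanking context.  The 96
channels are ordered as in the COSMIC SBS catalogs: six substitution classes
(C>A, C>G, C>T, T>A, T>C, T>G), each expanded over the four 5' and four 3'
flanking bases in alphabetical order, e.g. ``A[C>A]A`` ... ``T[T>G]T``.
"""

from __future__ import annotations

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
BASES = ("A", "C", "G", "T")
PYRIMIDINES = ("C", "T")
PURINES = ("A", "G")

#: The six pyrimidine-referenced substitution classes, COSMIC order.
SUB_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

#: The 96 channel labels in canonical COSMIC order.
CHANNELS_96 = tuple(
    f"{five}[{sub}]{three}"
    for sub in SUB_CLASSES
    for five in BASES
    for three in BASES
)

#: The 32 central-pyrimidine trinucleotide contexts, ordered to match the
#: C-channels then T-channels of :data:`CHANNELS_96`.
PYR_CONTEXTS_32 = tuple(
    f"{five}{ref}{three}" for ref in PYRIMIDINES for five in BASES for three in BASES
)

CHANNEL_INDEX = {c: i for i, c in enumerate(CHANNELS_96)}


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (upper-case A/C/G/T only)."""
    try:
        return "".join(COMPLEMENT[b] for b in reversed(seq))
    except KeyError as exc:
        raise ValueError(f"ambiguous or invalid base in {seq!r}") from exc


def pyrimidine_channel(ref: str, alt: str, context: str) -> str:
    """Map a substitution with its trinucleotide context to its channel label.

    Parameters
    ----------
    ref, alt
        Single reference and alternate bases (``ref != alt``).
    context
        The reference trinucleotide centred on the mutated base; its central
        base must equal ``ref``.

    Returns
    -------
    str
        A label of the form ``X[R>A]Y`` with central pyrimidine ``R``.
        Purine-reference calls are reverse-complemented first, so the same
        physical event yields the same channel regardless of reported strand.
    """
    for b in (ref, alt, *context):
        if b not in COMPLEMENT:
            raise ValueError(f"ambiguous base {b!r} in ({ref}>{alt}, {context})")
    if len(ref) != 1 or len(alt) != 1 or len(context) != 3:
        raise ValueError("pyrimidine_channel expects single-base SNVs")
    if ref == alt:
        raise ValueError("ref and alt must differ")
    if context[1] != ref:
        raise ValueError(f"context {context!r} central base != ref {ref!r}")
    if ref in PURINES:
        context = revcomp(context)
        ref = COMPLEMENT[ref]
        alt = COMPLEMENT[alt]
    return f"{context[0]}[{ref}>{alt}]{context[2]}"


def channel_parts(channel: str) -> tuple[str, str, str]:
    """Split ``X[R>A]Y`` into (context ``XRY``, ref, alt)."""
    five, rest = channel[0], channel[2:]
    ref, alt, three = rest[0], rest[2], rest[4]
    return f"{five}{ref}{three}", ref, alt


def channel_sub_class(channel: str) -> str:
    """The 6-class substitution (e.g. ``C>A``) of a 96-channel label."""
    return channel[2:5]
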