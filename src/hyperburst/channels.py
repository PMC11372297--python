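"""SBS96 trinucleotide channel definitions and classification.

Single-base substitutions are reported on the pyrimidine strand: a
substitution whose reference base is a purine (A or G) is reverse
complemented, together with its trinucleotide context, before lookup.
The canonical channel order is the COSMIC convention: six substitution
classes (C>A, C>G, C>T, T>A, T>C, T>G), and within each class the 16
flanking-base pairs in lexicographic order, so "A[C>A]A" is index 0.
"""

from __future__ import annotations

BASES = ("A", "C", "G", "T")
SUBSTITUTION_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (uppercase ACGT only)."""
    try:
        return "".join(_COMPLEMENT[b] for b in reversed(seq))
    except KeyError as exc:
        raise ValueError(f"non-ACGT base in {seq!r}") from exc


def _build_channel_labels() -> tuple[str, ...]:
    labels = []
    for sub in SUBSTITUTION_CLASSES:
        ref, alt = sub[0], sub[2]
        for five in BASES:
            for three in BASES:
                labels.append(f"{five}[{ref}>{alt}]{three}")
    return tuple(labels)


CHANNEL_LABELS: tuple[str, ...] = _build_channel_labels()
N_CHANNELS = len(CHANNEL_LABELS)  # 96
CHANNEL_INDEX: dict[str, int] = {lab: i for i, lab in enumerate(CHANNEL_LABELS)}


def channel_label(ref: str, alt: str, context3: str) -> str:
    """Canonical pyrimidine-strand label for a substitution in context.

    Parameters
    ----------
    ref, alt : str
        Single reference/alternate bases, ``ref != alt``.
    context3 : str
        3-mer whose middle base equals ``ref``.
    """
    if len(context3) != 3 or context3[1] != ref:
        raise ValueError(
            f"context3 {context3!r} must be a 3-mer with middle base {ref!r}"
        )
    if ref not in BASES or alt not in BASES:
        raise ValueError(f"invalid bases ref={ref!r} alt={alt!r}")
    if ref == alt:
        raise ValueError(f"ref == alt ({ref!r})")
    if ref in ("A", "G"):  # purine strand: flip to pyrimidine representation
        context3 = revcomp(context3)
        ref = _COMPLEMENT[ref]
        alt = _COMPLEMENT[alt]
    return f"{context3[0]}[{ref}>{alt}]{context3[2]}"


def classify_channel(ref: str, alt: str, context3: str) -> int:
    """Index in [0, 96) of the canonical channel for a substitution."""
    return CHANNEL_INDEX[channel_label(ref, alt, context3)]


def decode_channel(index: int) -> tuple[str, str, str]:
    """Inverse of :func:`classify_channel` on the pyrimidine strand.

    Returns ``(ref, alt, context3)`` for the canonical representation.
    """
    lab = CHANNEL_LABELS[index]
    five, ref, alt, three = lab[0], lab[2], lab[4], lab[6]
    return ref, alt, five + ref + three
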