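"""96-channel trinucleotide context conventions.

Single-base substitutions are classified into 96 channels: six pyrimidine
substitution types (C>A, C>G, C>T, T>A, T>C, T>G) times the 16 combinations
of 5' and 3' flanking base. Substitutions observed on the purine strand are
reverse-complemented onto the pyrimidine strand before classification, the
standard convention for COSMIC-style mutational-signature catalogs.
"""

from __future__ import annotations

import re

BASES = "ACGT"
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
PYRIMIDINES = frozenset("CT")

SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

#: channel labels in COSMIC order, e.g. "A[C>A]A", "A[C>A]C", ...
CHANNELS: tuple[str, ...] = tuple(
    f"{five}[{sub}]{three}" for sub in SUBSTITUTIONS for five in BASES for three in BASES
)

CHANNEL_INDEX: dict[str, int] = {label: i for i, label in enumerate(CHANNELS)}

_CONTEXT_RE = re.compile(r"^([ACGT])\[([ACGT])>([ACGT])\]([ACGT])$")


def revcomp(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq))


def normalize_context(five: str, ref: str, alt: str, three: str) -> str:
    """Return the pyrimidine-strand context label for a single-base change.

    If ``ref`` is a purine the substitution is mapped onto the opposite
    strand (flanks swap and complement).
    """
    if ref == alt:
        raise ValueError(f"ref and alt are identical: {ref}")
    for b in (five, ref, alt, three):
        if b not in COMPLEMENT:
            raise ValueError(f"invalid base {b!r}")
    if ref not in PYRIMIDINES:
        five, ref, alt, three = (
            COMPLEMENT[three],
            COMPLEMENT[ref],
            COMPLEMENT[alt],
            COMPLEMENT[five],
        )
    return f"{five}[{ref}>{alt}]{three}"


def parse_context(label: str) -> tuple[str, str, str, str]:
    """Split a context label into (5', ref, alt, 3'); validates the format."""
    m = _CONTEXT_RE.match(label)
    if m is None:
        raise ValueError(f"malformed trinucleotide context {label!r}")
    five, ref, alt, three = m.groups()
    if ref not in PYRIMIDINES:
        raise ValueError(f"context {label!r} is not pyrimidine-centred")
    if ref == alt:
        raise ValueError(f"context {label!r} has ref == alt")
    return five, ref, alt, three


def channel_of(label: str) -> int:
    """Index (0..95) of a pyrimidine-centred context label in COSMIC order."""
    try:
        return CHANNEL_INDEX[label]
    except KeyError:
        parse_context(label)  # raise with a precise message
        raise  # pragma: no cover


def is_c_to_t(label: str) -> bool:
    return label[2:5] == "C>T"


def is_dipyrimidine_ct(label: str) -> bool:
    """C>T with a pyrimidine 5' neighbour, the UV photoproduct configuration."""
    return is_c_to_t(label) and label[0] in PYRIMIDINES
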