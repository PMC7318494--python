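"""Small DNA sequence utilities shared across the package.

Primers may use the full IUPAC nucleotide alphabet; templates are strict
A/C/G/T. Matching is asymmetric: a degenerate primer base matches any
compatible template base, never the other way round.
"""

from __future__ import annotations

import numpy as np

# IUPAC code -> set of concrete template bases it hybridizes with
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

IUPAC_ALPHABET = frozenset(IUPAC_SETS)

_COMPLEMENT = str.maketrans(
    "ACGTRYSWKMBDHVN",
    "TGCAYRSWMKVHDBN",
)

_BASES = "ACGT"


def complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)


def revcomp(seq: str) -> str:
    """Reverse complement (IUPAC-aware)."""
    return seq.translate(_COMPLEMENT)[::-1]


def is_iupac(seq: str) -> bool:
    return bool(seq) and set(seq) <= IUPAC_ALPHABET


def is_strict_dna(seq: str) -> bool:
    return bool(seq) and set(seq) <= set(_BASES)


def bases_match(primer_base: str, template_base: str) -> bool:
    """True if a primer base can pair with a concrete template base."""
    return template_base in IUPAC_SETS[primer_base]


def random_dna(rng: np.random.Generator, length: int) -> str:
    """Uniform random A/C/G/T string of the given length."""
    return "".join(rng.choice(list(_BASES), size=length))
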