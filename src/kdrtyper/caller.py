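"""Decode observed band patterns into three-locus genotypes.

The decoder inverts the panel's size code. A lane without the internal
control band cannot be trusted ("no amplification"), so it is a failed call
no matter what else is visible. A band that matches no panel size — or that
matches two panel sizes within tolerance — makes the whole call ambiguous,
because in a multiplex context a stray band cannot be attributed to a locus.
Otherwise each locus reads out directly: one allele band means homozygote,
both mean heterozygote, none means that locus failed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

from .gel import BandPattern
from .panel import MultiLocusGenotype, PrimerPanel

logger = logging.getLogger(__name__)

OK = "ok"
FAILED = "failed"
AMBIGUOUS = "ambiguous"

#: A band within this many bp of a panel size is matched to it.
DEFAULT_SIZE_TOLERANCE = 2


@dataclass(frozen=True)
class SampleCall:
    """The decoded result for one sample under one genotyping method."""

    sample_id: str
    method: str = "multiplex"
    genotype: MultiLocusGenotype | None = None
    status: str = OK
    notes: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if (self.genotype is not None) != (self.status == OK):
            raise ValueError("genotype must be present iff status is ok")

    @property
    def is_ok(self) -> bool:
        return self.status == OK


def _match_bands(
    pattern: BandPattern, panel: PrimerPanel, tolerance: int
) -> tuple[set[int], list[str]]:
    """Map each observed band to at most one panel size.

    Returns the set of matched panel sizes and a list of problems (unmatched
    or ambiguously matched bands).
    """
    matched: set[int] = set()
    problems: list[str] = []
    for band in pattern.sizes:
        hits = [s for s in panel.all_sizes if abs(band - s) <= tolerance]
        if not hits:
            problems.append(f"band {band} bp matches no panel product")
        elif len(hits) > 1:
            problems.append(f"band {band} bp matches several panel products {hits}")
        else:
            matched.add(hits[0])
    return matched, problems


def decode(
    pattern: BandPattern,
    panel: PrimerPanel,
    tolerance: int = DEFAULT_SIZE_TOLERANCE,
    sample_id: str = "",
    method: str = "multiplex",
) -> SampleCall:
    """Decode one lane's band pattern into a genotype call."""
    matched, problems = _match_bands(pattern, panel, tolerance)

    if panel.control_size not in matched:
        return SampleCall(
            sample_id, method, None, FAILED, ("no amplification: control band absent",)
        )
    if problems:
        return SampleCall(sample_id, method, None, AMBIGUOUS, tuple(problems))

    codes: list[str] = []
    locus_failures: list[str] = []
    for locus in panel.loci:
        present = [
            allele
            for allele in locus.alleles
            if panel.product_table[(locus.name, allele)] in matched
        ]
        if not present:
            locus_failures.append(f"locus {locus.name}: no allele band")
        elif len(present) == 1:
            codes.append(present[0] * 2)
        else:  # both alleles: heterozygote, susceptible letter first
            codes.append(locus.susceptible + locus.resistant)

    if locus_failures:
        return SampleCall(sample_id, method, None, FAILED, tuple(locus_failures))

    return SampleCall(sample_id, method, MultiLocusGenotype(tuple(codes)), OK)


def decode_batch(
    patterns: Sequence[BandPattern],
    panel: PrimerPanel,
    sample_ids: Sequence[str] | None = None,
    tolerance: int = DEFAULT_SIZE_TOLERANCE,
    method: str = "multiplex",
) -> list[SampleCall]:
    """Elementwise decode, preserving order; logs a failure/ambiguity summary."""
    ids = list(sample_ids or (f"sample_{i + 1}" for i in range(len(patterns))))
    if len(ids) != len(patterns):
        raise ValueError("sample_ids length must match patterns length")
    calls = [
        decode(p, panel, tolerance, sample_id=i, method=method)
        for p, i in zip(patterns, ids)
    ]
    n_failed = sum(c.status == FAILED for c in calls)
    n_ambig = sum(c.status == AMBIGUOUS for c in calls)
    logger.info(
        "decoded %d patterns: %d ok, %d failed, %d ambiguous",
        len(calls), len(calls) - n_failed - n_ambig, n_failed, n_ambig,
    )
    return calls
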