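"""In-silico PCR: primer binding-site search and amplicon prediction.

The model is an idealized end-point PCR. A primer binds wherever its
templated 3' portion (the sequence minus any 5' non-templated tail) aligns
to either template strand with at most ``max_internal_mismatch`` mismatches;
with ``require_3prime_exact`` (the default) a mismatch at the 3' terminal
base discards the site outright, which is what makes allele-specific primers
discriminate. Every convergent plus/minus site pair within ``max_len`` yields
a product. Amplification is binary — cycle number, efficiency and band
intensity are deliberately not modeled.

Coordinates are 0-based half-open on the plus strand internally.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .dna import bases_match, is_strict_dna, revcomp
from .errors import PanelValidationError, TemplateError
from .panel import Primer, PrimerPanel

PLUS = "+"
MINUS = "-"

#: Shortest templated portion find_binding_sites will search with.
MIN_TEMPLATED_LEN = 12

#: Default ceiling on predicted product length.
DEFAULT_MAX_LEN = 1000


@dataclass(frozen=True)
class Template:
    """A (synthetic) genomic DNA stretch.

    ``tags`` optionally records ground truth such as the locus and allele a
    haplotype template carries; it is carried through FASTA descriptions and
    never consulted by the PCR engine itself.
    """

    id: str
    seq: str
    tags: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.seq or not is_strict_dna(self.seq):
            raise TemplateError(
                f"template {self.id!r}: sequence must be non-empty uppercase A/C/G/T"
            )

    def __len__(self) -> int:
        return len(self.seq)

    def revcomp(self, new_id: str | None = None) -> "Template":
        return Template(new_id or f"{self.id}_rc", revcomp(self.seq), dict(self.tags))


@dataclass(frozen=True)
class BindingSite:
    """One hybridization site of a primer's templated portion.

    ``start`` is the leftmost plus-strand position of the templated match
    (half-open interval ``[start, start + templated_len)``). On the plus
    strand the primer's 3' terminus sits at the right edge of the interval;
    on the minus strand at the left edge. ``mismatches`` counts every
    mismatched position including the 3' terminus.
    """

    primer: Primer
    strand: str
    start: int
    templated_len: int
    mismatches: int
    three_prime_matched: bool

    @property
    def end(self) -> int:
        return self.start + self.templated_len

    @property
    def three_prime_pos(self) -> int:
        """Plus-strand position opposite the primer's 3' terminal base."""
        return self.end - 1 if self.strand == PLUS else self.start


@dataclass(frozen=True)
class Amplicon:
    """A predicted PCR product.

    ``length`` = templated span between the two outermost templated bases
    (inclusive) + both primers' 5' tail lengths.
    """

    template_id: str
    fwd: BindingSite
    rev: BindingSite
    length: int
    locus: str | None
    allele: str | None

    @property
    def is_control(self) -> bool:
        return self.allele is None and self.locus is not None


def _count_mismatches(primer_window: str, template_window: str) -> Iterable[bool]:
    return (not bases_match(p, t) for p, t in zip(primer_window, template_window))


def find_binding_sites(
    template: Template,
    primer: Primer,
    max_internal_mismatch: int = 0,
    require_3prime_exact: bool = True,
    min_templated_len: int = MIN_TEMPLATED_LEN,
) -> list[BindingSite]:
    """All sites on both strands where the primer's templated portion binds.

    Mismatches anywhere count against ``max_internal_mismatch``; with
    ``require_3prime_exact`` a 3'-terminal mismatch discards the site
    regardless of the budget. IUPAC degeneracy in the primer matches any
    compatible template base.
    """
    templated = primer.templated
    m = len(templated)
    if m < min_templated_len:
        raise PanelValidationError(
            f"primer {primer.name}: templated portion ({m} nt) shorter than "
            f"the {min_templated_len} nt minimum"
        )
    seq = template.seq
    n = len(seq)
    sites: list[BindingSite] = []
    if m > n:
        return sites

    # Fast path: with a zero mismatch budget and a non-degenerate primer the
    # search is an exact substring scan.
    if max_internal_mismatch == 0 and is_strict_dna(templated):
        for strand, needle in ((PLUS, templated), (MINUS, revcomp(templated))):
            start = seq.find(needle)
            while start != -1:
                sites.append(BindingSite(primer, strand, start, m, 0, True))
                start = seq.find(needle, start + 1)
        sites.sort(key=lambda s: (s.strand, s.start))
        return sites

    # Plus strand: templated portion read directly; 3' terminus at window end.
    for start in range(n - m + 1):
        window = seq[start : start + m]
        mm = sum(_count_mismatches(templated, window))
        if mm > max_internal_mismatch + 1:
            continue
        three_prime_ok = bases_match(templated[-1], window[-1])
        if require_3prime_exact and not three_prime_ok:
            continue
        if mm > max_internal_mismatch:
            continue
        sites.append(BindingSite(primer, PLUS, start, m, mm, three_prime_ok))

    # Minus strand: the plus strand carries the reverse complement of the
    # templated portion; the primer's 3' terminus maps to the window start.
    rc = revcomp(templated)
    for start in range(n - m + 1):
        window = seq[start : start + m]
        mm = sum(_count_mismatches(rc, window))
        if mm > max_internal_mismatch + 1:
            continue
        three_prime_ok = bases_match(rc[0], window[0])
        if require_3prime_exact and not three_prime_ok:
            continue
        if mm > max_internal_mismatch:
            continue
        sites.append(BindingSite(primer, MINUS, start, m, mm, three_prime_ok))

    return sites


def _label_amplicon(p_plus: Primer, p_minus: Primer) -> tuple[str | None, str | None]:
    """(locus, allele) of a product from its primer pair.

    A pair of common primers at the same locus is the internal control
    (allele None). If exactly one member is allele-specific, the product is
    diagnostic for that primer's locus and allele. Cross-locus or
    doubly-specific discordant pairs are unlabeled off-target products.
    """
    specific = [p for p in (p_plus, p_minus) if p.is_allele_specific]
    if len(specific) == 1:
        return specific[0].locus, specific[0].allele
    if len(specific) == 2:
        if specific[0].locus == specific[1].locus and specific[0].allele == specific[1].allele:
            return specific[0].locus, specific[0].allele
        return None, None
    # both common
    if p_plus.locus == p_minus.locus:
        return p_plus.locus, None
    return None, None


def predict_amplicons(
    template: Template,
    panel: PrimerPanel,
    max_len: int = DEFAULT_MAX_LEN,
    max_internal_mismatch: int = 0,
    require_3prime_exact: bool = True,
) -> list[Amplicon]:
    """Predict every product the panel forms on one template.

    Each pair of a plus-strand site and a minus-strand site in convergent
    orientation (both primers contained in the product, 3' ends pointing
    inward) yields an amplicon of length span + tails, capped at ``max_len``.
    """
    plus_sites: list[BindingSite] = []
    minus_sites: list[BindingSite] = []
    for primer in panel.primers:
        for site in find_binding_sites(
            template, primer, max_internal_mismatch, require_3prime_exact
        ):
            (plus_sites if site.strand == PLUS else minus_sites).append(site)

    amplicons = []
    for f, r in itertools.product(plus_sites, minus_sites):
        if f.start > r.start or f.end > r.end:
            continue  # not convergent
        span = r.end - f.start
        length = span + f.primer.tail_len + r.primer.tail_len
        if length > max_len:
            continue
        locus, allele = _label_amplicon(f.primer, r.primer)
        amplicons.append(Amplicon(template.id, f, r, length, locus, allele))
    amplicons.sort(key=lambda a: (a.length, a.fwd.start))
    return amplicons


def amplify_individual(
    haplotypes: tuple[Sequence[Template], Sequence[Template]],
    panel: PrimerPanel,
    max_len: int = DEFAULT_MAX_LEN,
    max_internal_mismatch: int = 0,
    require_3prime_exact: bool = True,
) -> list[Amplicon]:
    """Pool a diploid individual's two haplotype template sets.

    Returns the union of predictions over both chromosome copies with
    duplicate product sizes collapsed (a homozygote's two identical products
    are one band).
    """
    seen: dict[int, Amplicon] = {}
    for hap in haplotypes:
        for t in hap:
            for amp in predict_amplicons(
                t, panel, max_len, max_internal_mismatch, require_3prime_exact
            ):
                seen.setdefault(amp.length, amp)
    return [seen[k] for k in sorted(seen)]


def amplicon_sizes(amplicons: Iterable[Amplicon]) -> list[int]:
    """Distinct product lengths, ascending."""
    return sorted({a.length for a in amplicons})
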