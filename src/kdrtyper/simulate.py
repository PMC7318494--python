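"""Synthetic data: diploid individuals with known three-locus genotypes and
haplotype template sequences that make the whole assay testable end to end.

Templates are built per locus and per haplotype (three short records per
chromosome copy — inter-locus distance is irrelevant to the assay, so no
contiguous vgsc is emitted). Each record embeds the panel's primer sites as
exact matches with the allele-determining base at the 3' terminus of the
matching allele-specific primer, separated by random spacer DNA that is
screened so it cannot create spurious binding sites. By construction the
predicted amplicon sizes equal the panel's product table exactly, including
the nested 1534 design where the 368 bp outer (control) product contains the
two overlapping inner allele products.

Three sampling modes:

* ``exact_counts`` — emit precisely the requested number of individuals per
  genotype class (used to replay the bundled survey table cell for cell);
* ``haplotype_freqs`` — draw two three-locus haplotypes per individual from
  given haplotype frequencies (models linked resistance haplotypes);
* ``independent_loci`` — draw each locus's alleles independently from
  per-locus resistant-allele frequencies (ignores linkage).

Optional noise drops non-control bands (allele dropout) or the control band
(whole-reaction failure) with given probabilities, for failure-path testing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .dna import random_dna, revcomp
from .errors import PanelValidationError, SimulationConfigError
from .gel import BandPattern
from .panel import (
    FORWARD,
    Locus,
    MultiLocusGenotype,
    Primer,
    PrimerPanel,
    default_panel,
    genotype_from_codes,
    parse_genotype,
)
from .pcr import Template, predict_amplicons

SPACER_LEN = 30  # flanking spacer outside the outermost primer sites
_MAX_SPACER_TRIES = 50


# ---------------------------------------------------------------------------
# Locus layouts derived from the panel
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class _SharedForwardLayout:
    """Two allele-specific forwards over one footprint + a common reverse."""

    locus: Locus
    fwd_by_allele: Mapping[str, Primer]
    rev: Primer
    gap: int  # random bases between forward footprint and reverse site

    def core_len(self) -> int:
        any_fwd = next(iter(self.fwd_by_allele.values()))
        return len(any_fwd.templated) + self.gap + len(self.rev.templated)

    def build(self, allele: str, spacer: str) -> str:
        fwd = self.fwd_by_allele[allele]
        return fwd.templated + spacer + revcomp(self.rev.templated)


@dataclass(frozen=True)
class _NestedLayout:
    """Common outer pair (control product) + overlapping inner AS primers.

    Plus-strand geometry inside the outer product of length ``outer_len``:
    outer forward at 0, inner forward ending on the variant at ``snp_pos``,
    inner reverse starting (3' terminus) at ``snp_pos``, outer reverse ending
    at ``outer_len``.
    """

    locus: Locus
    outer_fwd: Primer
    outer_rev: Primer
    inner_fwd: Primer  # allele-specific, 3' base = its allele's plus base
    inner_rev: Primer  # allele-specific, 3' base pairs the other allele
    outer_len: int
    inner_fwd_start: int
    inner_rev_end: int
    snp_pos: int

    def plus_base(self, allele: str) -> str:
        if allele == self.inner_fwd.allele:
            return self.inner_fwd.three_prime_base
        return revcomp(self.inner_rev.three_prime_base)

    def build(self, allele: str, gap_a: str, gap_b: str) -> str:
        f = self.inner_fwd.templated
        r_plus = revcomp(self.inner_rev.templated)  # covers [snp_pos, inner_rev_end)
        region = (
            self.outer_fwd.templated
            + gap_a
            + f[:-1]
            + self.plus_base(allele)
            + r_plus[1:]
            + gap_b
            + revcomp(self.outer_rev.templated)
        )
        assert len(region) == self.outer_len
        return region

    def gap_lens(self) -> tuple[int, int]:
        a = self.inner_fwd_start - len(self.outer_fwd.templated)
        b = (self.outer_len - len(self.outer_rev.templated)) - self.inner_rev_end
        return a, b


def _locus_layout(panel: PrimerPanel, locus: Locus):
    primers = panel.primers_at(locus.name)
    fwd_as = {p.allele: p for p in primers if p.is_allele_specific and p.orientation == FORWARD}
    rev_as = {p.allele: p for p in primers if p.is_allele_specific and p.orientation != FORWARD}
    fwd_common = [p for p in primers if not p.is_allele_specific and p.orientation == FORWARD]
    rev_common = [p for p in primers if not p.is_allele_specific and p.orientation != FORWARD]

    if len(fwd_as) == 2 and not rev_as and not fwd_common and len(rev_common) == 1:
        rev = rev_common[0]
        fwds = [fwd_as[a] for a in locus.alleles]
        if len({len(p.templated) for p in fwds}) != 1:
            raise PanelValidationError(
                f"locus {locus.name}: allele-specific forwards must share a footprint length"
            )
        if fwds[0].templated[-1] == fwds[1].templated[-1]:
            raise PanelValidationError(
                f"locus {locus.name}: allele-specific forwards must differ at the 3' base"
            )
        spans = {
            a: panel.size_of(locus.name, a) - fwd_as[a].tail_len - rev.tail_len
            for a in locus.alleles
        }
        if len(set(spans.values())) != 1:
            raise PanelValidationError(
                f"locus {locus.name}: product sizes inconsistent with tail lengths "
                f"(templated spans {spans})"
            )
        span = next(iter(spans.values()))
        gap = span - len(fwds[0].templated) - len(rev.templated)
        if gap < 0:
            raise PanelValidationError(
                f"locus {locus.name}: primers longer than the templated span"
            )
        return _SharedForwardLayout(locus, dict(fwd_as), rev, gap)

    if len(fwd_common) == 1 and len(rev_common) == 1 and len(fwd_as) == 1 and len(rev_as) == 1:
        outer_f, outer_r = fwd_common[0], rev_common[0]
        inner_f = next(iter(fwd_as.values()))
        inner_r = next(iter(rev_as.values()))
        if inner_f.allele == inner_r.allele:
            raise PanelValidationError(
                f"locus {locus.name}: nested inner primers must target different alleles"
            )
        outer_len = panel.control_size
        size_f = panel.size_of(locus.name, inner_f.allele)
        size_r = panel.size_of(locus.name, inner_r.allele)
        # inner forward pairs with the outer reverse; inner reverse with the outer forward
        inner_f_start = outer_len - (size_f - inner_f.tail_len - outer_r.tail_len)
        inner_r_end = size_r - outer_f.tail_len - inner_r.tail_len
        snp_f = inner_f_start + len(inner_f.templated) - 1
        snp_r = inner_r_end - len(inner_r.templated)
        if max(size_f, size_r) >= outer_len:
            raise PanelValidationError(
                f"locus {locus.name}: inner product sizes must be smaller than the outer"
            )
        if snp_f != snp_r:
            raise PanelValidationError(
                f"locus {locus.name}: inner primers must overlap exactly at the variant "
                f"base (3' positions {snp_f} vs {snp_r})"
            )
        if inner_f.three_prime_base == revcomp(inner_r.three_prime_base):
            raise PanelValidationError(
                f"locus {locus.name}: the two inner 3' bases read the same plus-strand base"
            )
        gap_a = inner_f_start - len(outer_f.templated)
        gap_b = (outer_len - len(outer_r.templated)) - inner_r_end
        if gap_a < 0 or gap_b < 0:
            raise PanelValidationError(
                f"locus {locus.name}: inner sites collide with the outer primers"
            )
        return _NestedLayout(
            locus, outer_f, outer_r, inner_f, inner_r,
            outer_len, inner_f_start, inner_r_end, snp_f,
        )

    raise PanelValidationError(
        f"locus {locus.name}: unsupported primer configuration "
        f"({len(fwd_as)} AS fwd, {len(rev_as)} AS rev, "
        f"{len(fwd_common)} common fwd, {len(rev_common)} common rev)"
    )


# ---------------------------------------------------------------------------
# Template construction
# ---------------------------------------------------------------------------


def _expected_sizes_for_haplotype(
    panel: PrimerPanel, locus: Locus, allele: str
) -> set[int]:
    layout = _locus_layout(panel, locus)
    sizes = {panel.size_of(locus.name, allele)}
    if isinstance(layout, _NestedLayout):
        sizes.add(panel.control_size)
    return sizes


def _build_locus_template(
    panel: PrimerPanel,
    locus: Locus,
    allele: str,
    rng: np.random.Generator,
    record_id: str,
    tags: Mapping[str, str],
) -> Template:
    """One haplotype template for one locus, with spacers resampled until the
    predicted products are exactly the intended ones (screens out accidental
    primer sites in random spacer)."""
    layout = _locus_layout(panel, locus)
    want = _expected_sizes_for_haplotype(panel, locus, allele)
    for _ in range(_MAX_SPACER_TRIES):
        if isinstance(layout, _SharedForwardLayout):
            core = layout.build(allele, random_dna(rng, layout.gap))
        else:
            ga, gb = layout.gap_lens()
            core = layout.build(allele, random_dna(rng, ga), random_dna(rng, gb))
        seq = random_dna(rng, SPACER_LEN) + core + random_dna(rng, SPACER_LEN)
        t = Template(record_id, seq, dict(tags))
        got = {a.length for a in predict_amplicons(t, panel)}
        if got == want:
            return t
    raise SimulationConfigError(
        f"could not build a clean template for locus {locus.name} allele {allele}"
    )


def build_templates(
    g: MultiLocusGenotype,
    panel: PrimerPanel | None = None,
    seed: int | np.random.Generator = 0,
    individual_id: str = "ind",
) -> tuple[list[Template], list[Template]]:
    """Two haplotype template sets (one per chromosome copy) for a genotype.

    Heterozygous loci put the susceptible allele on haplotype 1 — phase is
    immaterial to the assay. Fully reproducible for a given seed.
    """
    panel = panel or default_panel()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    haplotypes: tuple[list[Template], list[Template]] = ([], [])
    for hap_i in (0, 1):
        for loc_i, locus in enumerate(panel.loci):
            a, b = g.pair(loc_i)
            allele = (a, b)[hap_i]
            tags = {
                "individual": individual_id,
                "hap": str(hap_i + 1),
                "locus": locus.name,
                "allele": allele,
                "genotype": g.render(),
            }
            rec_id = f"{individual_id}|hap{hap_i + 1}|{locus.name}"
            haplotypes[hap_i].append(
                _build_locus_template(panel, locus, allele, rng, rec_id, tags)
            )
    return haplotypes


# ---------------------------------------------------------------------------
# Population simulation
# ---------------------------------------------------------------------------

EXACT_COUNTS = "exact_counts"
HAPLOTYPE_FREQS = "haplotype_freqs"
INDEPENDENT_LOCI = "independent_loci"
_MODES = (EXACT_COUNTS, HAPLOTYPE_FREQS, INDEPENDENT_LOCI)


@dataclass(frozen=True)
class NoiseModel:
    band_dropout_prob: float = 0.0
    control_dropout_prob: float = 0.0

    def __post_init__(self) -> None:
        for p in (self.band_dropout_prob, self.control_dropout_prob):
            if not 0.0 <= p <= 1.0:
                raise SimulationConfigError("dropout probabilities must be in [0, 1]")

    @property
    def is_null(self) -> bool:
        return self.band_dropout_prob == 0.0 and self.control_dropout_prob == 0.0


@dataclass(frozen=True)
class SimulationConfig:
    """One simulation run: mode, per-population composition, noise and seed.

    ``populations`` maps a population label to a mode-dependent spec:
    exact_counts -> {"counts": {genotype class: int}};
    haplotype_freqs -> {"n": int, "freqs": {"LIC": 0.4, ...}} (one allele
    letter per locus, panel order);
    independent_loci -> {"n": int, "resistant_freqs": {locus: f}}.
    """

    mode: str
    populations: Mapping[str, Mapping]
    seed: int = 0
    noise: NoiseModel = field(default_factory=NoiseModel)

    def __post_init__(self) -> None:
        if self.mode not in _MODES:
            raise SimulationConfigError(f"unknown mode {self.mode!r}; pick one of {_MODES}")
        if not self.populations:
            raise SimulationConfigError("at least one population is required")

    @classmethod
    def from_json(cls, path: str | Path) -> "SimulationConfig":
        doc = json.loads(Path(path).read_text(encoding="utf-8"))
        noise = NoiseModel(**doc.get("noise", {}))
        try:
            return cls(
                mode=doc["mode"],
                populations=doc["populations"],
                seed=int(doc.get("seed", 0)),
                noise=noise,
            )
        except KeyError as exc:
            raise SimulationConfigError(f"simulation config missing key {exc}") from exc


@dataclass(frozen=True)
class Individual:
    id: str
    population: str
    genotype: MultiLocusGenotype
    haplotypes: tuple[list[Template], list[Template]]


def _genotypes_exact(spec: Mapping, panel: PrimerPanel, rng) -> list[MultiLocusGenotype]:
    counts = spec.get("counts")
    if not counts:
        raise SimulationConfigError("exact_counts population needs a 'counts' mapping")
    out: list[MultiLocusGenotype] = []
    for cls, k in counts.items():
        if int(k) < 0:
            raise SimulationConfigError("genotype counts must be non-negative")
        out.extend([parse_genotype(cls, panel)] * int(k))
    if "n" in spec and int(spec["n"]) != len(out):
        raise SimulationConfigError(
            f"counts sum to {len(out)} but n={spec['n']} was requested"
        )
    return out


def _hap_to_codes(hap_a: str, hap_b: str, panel: PrimerPanel) -> MultiLocusGenotype:
    codes = [a + b for a, b in zip(hap_a, hap_b)]
    return genotype_from_codes(codes, panel.loci)


def _genotypes_hapfreqs(spec: Mapping, panel: PrimerPanel, rng) -> list[MultiLocusGenotype]:
    n = int(spec.get("n", 0))
    freqs: Mapping[str, float] = spec.get("freqs", {})
    if n <= 0 or not freqs:
        raise SimulationConfigError("haplotype_freqs population needs 'n' and 'freqs'")
    haps = list(freqs)
    probs = np.array([freqs[h] for h in haps], dtype=float)
    if abs(probs.sum() - 1.0) > 1e-9:
        raise SimulationConfigError(f"haplotype frequencies sum to {probs.sum()}, not 1")
    for h in haps:
        if len(h) != len(panel.loci):
            raise SimulationConfigError(f"haplotype {h!r} needs one allele per locus")
    draws = rng.choice(len(haps), size=(n, 2), p=probs)
    return [_hap_to_codes(haps[i], haps[j], panel) for i, j in draws]


def _genotypes_indep(spec: Mapping, panel: PrimerPanel, rng) -> list[MultiLocusGenotype]:
    n = int(spec.get("n", 0))
    rf: Mapping[str, float] = spec.get("resistant_freqs", {})
    if n <= 0:
        raise SimulationConfigError("independent_loci population needs 'n'")
    out = []
    for _ in range(n):
        codes = []
        for locus in panel.loci:
            f = float(rf.get(locus.name, 0.0))
            if not 0.0 <= f <= 1.0:
                raise SimulationConfigError("allele frequencies must be in [0, 1]")
            pair = [locus.resistant if rng.random() < f else locus.susceptible for _ in range(2)]
            codes.append("".join(pair))
        out.append(genotype_from_codes(codes, panel.loci))
    return out


_MODE_SAMPLERS = {
    EXACT_COUNTS: _genotypes_exact,
    HAPLOTYPE_FREQS: _genotypes_hapfreqs,
    INDEPENDENT_LOCI: _genotypes_indep,
}


def simulate_population(
    cfg: SimulationConfig, panel: PrimerPanel | None = None
) -> list[Individual]:
    """Emit the configured individuals with template sequences attached.

    Deterministic for a given config and seed: genotype draws and spacer DNA
    come from one top-level generator.
    """
    panel = panel or default_panel()
    rng = np.random.default_rng(cfg.seed)
    individuals: list[Individual] = []
    for pop, spec in cfg.populations.items():
        genotypes = _MODE_SAMPLERS[cfg.mode](spec, panel, rng)
        for k, g in enumerate(genotypes, start=1):
            iid = f"{pop}_{k}"
            haps = build_templates(g, panel, rng, individual_id=iid)
            individuals.append(Individual(iid, pop, g, haps))
    return individuals


def apply_noise(
    pattern: BandPattern,
    noise: NoiseModel,
    rng: np.random.Generator,
    panel: PrimerPanel | None = None,
) -> BandPattern:
    """Drop each non-control band (and the control) independently."""
    panel = panel or default_panel()
    control = panel.control_size
    kept = []
    for s in pattern.sizes:
        p = noise.control_dropout_prob if s == control else noise.band_dropout_prob
        if rng.random() >= p:
            kept.append(s)
    return BandPattern(tuple(kept), control in kept)
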