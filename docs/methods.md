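# Methods

## Scope and model

`kdrtyper` models a multiplex allele-specific end-point PCR that genotypes
the three *Aedes aegypti* kdr mutations V410L, V1016I and F1534C
simultaneously, together with the virtual gel readout, the band→genotype
decoder, and population summaries. The model is deliberately the *idealized*
assay: amplification is binary (a product exists iff a convergent, valid
primer pair binds), with no thermodynamics, cycle kinetics, primer dimers,
band intensities or migration physics. Thermocycling and reagent settings
are carried as inert metadata on the panel so a configuration documents a
real protocol without influencing any computation.

### Primer binding and allele discrimination

A primer is a 5′→3′ IUPAC string whose first `tail_len` bases are
non-templated (a GC tail used purely to offset product length). Only the
templated 3′ portion is searched, on both template strands, with at most
`max_internal_mismatch` mismatches (default 0); degenerate primer bases
match any compatible template base, never the reverse. With
`require_3prime_exact` (default on), a mismatch at the 3′ terminal base
discards the site regardless of the mismatch budget. This single rule is the
entire allele-discrimination model: each allele-specific primer ends on the
variant base, so it binds one allele's template and is vetoed on the other.
No polymerase-extension or mismatch-penalty model is attempted — nothing in
the assay's published behavior constrains one, and the defaults make the
discriminator exact. The relaxation knobs exist for robustness experiments
only.

A templated portion shorter than 12 nt is rejected as unsearchable (too
unspecific to mean anything at these scales). With the default zero
mismatch budget and a non-degenerate primer the search reduces to exact
substring scanning, which keeps whole-survey replays (≈2,000 templates)
around a second.

### Product length arithmetic

For a convergent plus/minus site pair, `length = templated span (outermost
templated bases, inclusive) + both 5′ tail lengths`. Internally coordinates
are 0-based half-open; TSV output reports 1-based inclusive intervals. The
default panel reproduces the published size code exactly:

* 410 — the two allele-specific forwards share a 25 nt footprint ending on
  the codon-410 variant and differ by a 20 nt tail (V410f 26 nt tail, 51 nt
  total; L410f 6 nt tail, 31 nt), giving 133 vs 113 bp with the common
  reverse. These three sequences are the published domain-I primers,
  carried verbatim; the tail split is the unique one consistent with a
  shared footprint, and the multiplex 410 reverse is assumed identical to
  the published domain-I reverse primer.
* 1016 — same design, 21 nt footprints, 20 nt tail on the susceptible
  primer: 102 vs 82 bp.
* 1534 — nested: common outer pair → 368 bp (doubling as the reaction's
  internal control), inner allele-specific forward (C, 3′ G) → 180 bp with
  the outer reverse, inner allele-specific reverse (F, 3′ A) → 232 bp with
  the outer forward. The two inner primers overlap in exactly one base —
  the variant — so 180 + 232 > 368 is geometrically consistent.

The 1016 and 1534 oligo sequences are synthetic stand-ins designed for this
panel (their docstrings say so): every published surface of the assay —
product sizes, decodability, discrimination — depends on the geometry above,
not on the field sequences, and the panel validator enforces that geometry
for any user-supplied panel (shared footprints, 3′ divergence, consistent
span arithmetic, single-base inner overlap, inner products inside the outer).

### Virtual gel

Two parameters: `size_range = (50, 1000)` bp (fragments outside are
dropped) and `min_resolvable_delta = 8` bp. Fragments are single-linkage
clustered; any run with consecutive gaps below delta merges into one band at
the rounded (half-up) mean, which makes `resolve` idempotent (cluster means
are ≥ delta apart by construction). The true resolution of the published
2.5% agarose / 110 V / 1 h setup is not stated anywhere; 8 bp is an
operational stand-in chosen strictly below the assay's closest size pair
(102 vs 113 bp), so the published design always resolves, while larger
deltas let you explore where the size code would collapse.

### Decoding

A band within ±2 bp of a panel size (configurable) is matched to it; this
tolerance absorbs virtual-gel merge rounding and is safely below half the
minimal panel gap. Decision order: (1) no control band → `failed`
("no amplification" — nothing else in the lane can be trusted); (2) any band
matching no panel size, or two sizes within tolerance → `ambiguous`, for the
whole call, since a multiplex lane cannot attribute a stray band to a locus;
(3) per locus: one allele band → homozygote, both → heterozygote, none →
`failed` with a per-locus note. Statuses are data, never exceptions; the
published survey reports no failed reactions, so the failure paths are
specified here by construction and exercised only by simulation.

### Population summaries

Genotype-count tables are population × 27 canonical classes (per-locus
order hom-susceptible, heterozygote, hom-resistant; heterozygotes rendered
susceptible-letter-first, e.g. `VL`, with the reversed order accepted and
canonicalized on parsing). Marginalization sums classes sharing a one-locus
genotype; allele frequency is `(2·hom_res + het) / 2n` at full precision,
with reporting (and fixation calls) rounded half-up to two decimals —
half-up matches every self-consistent cell of the bundled survey table.
Failed/ambiguous calls are excluded from denominators. Fixation means a
reported frequency ≥ 1 − tol (default tol 0, i.e. 1.00 after rounding).
Concordance between two call sets compares genotypes over shared sample ids,
excluding samples failed/ambiguous under either method. No Hardy–Weinberg,
linkage-disequilibrium or bioassay statistics are computed: the source
survey performs none, and inventing them here would imply analyses the data
were never given.

### Simulator

The generator emits diploid individuals as three separate template records
per haplotype (inter-locus distance is irrelevant to the assay; a contiguous
vgsc model would add realism the assay never sees). Spacer and gap DNA is
uniform random A/C/G/T from a single top-level seeded generator, and each
record is screened by running the in-silico PCR on it and resampling (up to
50 times) if any accidental binding site changes the product set — so
predicted sizes equal the panel's table exactly, by construction, for every
genotype. Sampling modes:

* `exact_counts` — deterministic composition; this is how the bundled
  survey is replayed cell-for-cell (its genotype table fully determines
  the cohort).
* `haplotype_freqs` — two three-locus haplotypes drawn per individual;
  models the strong inter-locus association visible in the survey (the
  modal class is the triple `VL/VI/CC`). True field phase is unknown from
  genotype data, so these runs are illustrative, not reconstructions.
* `independent_loci` — per-locus binomial draws, ignoring linkage.

Noise is two dropout probabilities (non-control bands; the control band)
applied per band after gel resolution, defaulting to 0 — the published
validation observed no failures, so the noiseless generator *is* the study
condition and noise exists for failure-path testing.

What passing tests on this synthetic data do **not** show about real data:
wet-lab failure modes (inhibitors, allele dropout, primer dimers,
heteroduplexes), quantitative band intensity, off-target genomic binding,
and any deviation of the real 1016/1534 primer sequences from the synthetic
stand-ins.

## Numerical and design choices

* Rounding: half-up (away from zero) everywhere a table is printed;
  internal frequencies stay full precision (susceptible + resistant sums to
  exactly 1.0 in floating point because they are computed from the same
  integer counts).
* Tie-breaks: genotype ranking sorts by pooled count descending, then
  canonical class order — deterministic under ties.
* Degenerate inputs: zero genotyped individuals → error (frequency
  undefined); empty call lists → empty tables; empty band lists → empty,
  control-absent patterns that decode to `failed`.
* Seeds: one integer seeds everything (genotype draws, spacers, noise);
  identical config + seed gives byte-identical FASTA and identical calls.
* Exit codes (CLI): 0 success, 1 usage, 2 data/validation; call statuses
  are outputs, not errors.

## Problem sizes

Default test and replay sizes are the survey's own: 12 populations, 352
individuals, 27 genotype classes exhaustively enumerated. Stochastic checks
use n = 500 individuals (allele-frequency recovery within 3 binomial
standard errors) and 10,000 patterns (band-dropout rate), sizes at which the
binomial bands are tight enough to catch real defects while the whole suite
stays interactive.

## Known limitations

* The bundled survey tables are transcribed verbatim from their source, which
  is internally inconsistent in a few cells (one frequency misprint; two
  populations where the per-locus table disagrees with the genotype-class
  table by one individual). The genotype-class table is treated as
  authoritative — its row sums match the stated sample sizes and its
  most/least-frequent classes match the source's own prose. The two tests
  that assert exact cross-table agreement document the discrepancy by
  failing on exactly those cells, and `kdrtyper reproduce` reports 32/36
  matching frequency cells for the same reason.
* The binding model has no mismatch-position weighting beyond the 3′ veto;
  relaxed-matching results should be read qualitatively.
* `find_binding_sites` is an O(n·m) scan per primer (with an exact-search
  fast path); it is meant for amplicon-scale templates, not genome scans.
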