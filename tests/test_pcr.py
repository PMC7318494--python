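"""In-silico PCR: binding-site search, allele discrimination, amplicon sizes."""

import numpy as np
import pytest

from kdrtyper import (
    Template,
    amplicon_sizes,
    amplify_individual,
    build_templates,
    expected_bands,
    find_binding_sites,
    parse_genotype,
    predict_amplicons,
)
from kdrtyper.dna import random_dna, revcomp
from kdrtyper.errors import PanelValidationError, TemplateError
from kdrtyper.panel import Primer
from kdrtyper.pcr import MINUS


def _primer_by_name(panel, name):
    return next(p for p in panel.primers if p.name == name)


def test_exact_site_on_minus_strand(panel):
    rev = _primer_by_name(panel, "410r")
    rng = np.random.default_rng(7)
    seq = random_dna(rng, 40) + revcomp(rev.templated) + random_dna(rng, 40)
    sites = find_binding_sites(Template("t", seq), rev)
    assert len(sites) == 1
    site = sites[0]
    assert (site.strand, site.start, site.mismatches) == (MINUS, 40, 0)
    assert site.three_prime_matched
    assert site.three_prime_pos == 40  # 3' terminus at the left edge on minus


def test_no_occurrence_gives_empty_list(panel):
    t = Template("t", "ACGT" * 30)
    assert find_binding_sites(t, _primer_by_name(panel, "c1534-f")) == []


def test_short_templated_portion_rejected():
    p = Primer("tiny", "ACGTACGTACG", "forward", "410")  # 11 nt templated
    with pytest.raises(PanelValidationError, match="shorter"):
        find_binding_sites(Template("t", "ACGT" * 20), p)


def test_template_must_be_strict_dna():
    with pytest.raises(TemplateError):
        Template("t", "ACGTN")
    with pytest.raises(TemplateError):
        Template("t", "")


def test_3prime_mismatch_discards_site(panel):
    """An allele-specific primer must not bind the other allele's template."""
    v410f = _primer_by_name(panel, "V410f")
    l410f = _primer_by_name(panel, "L410f")
    hap_v, hap_l = build_templates(parse_genotype("VL/VV/FF", panel), panel, seed=3)
    t_v = next(t for t in hap_v if t.tags["locus"] == "410")
    t_l = next(t for t in hap_l if t.tags["locus"] == "410")
    assert len(find_binding_sites(t_v, v410f)) == 1
    assert find_binding_sites(t_v, l410f) == []
    assert len(find_binding_sites(t_l, l410f)) == 1
    assert find_binding_sites(t_l, v410f) == []


def test_3prime_exact_flag_controls_discrimination(panel):
    """Relaxing both the 3' anchor and the mismatch budget re-admits the
    near-matching allele-specific primer (1016 primers differ only at 3')."""
    i1016f = _primer_by_name(panel, "I1016f")
    hap_v, _ = build_templates(parse_genotype("VV/VV/FF", panel), panel, seed=4)
    t_v = next(t for t in hap_v if t.tags["locus"] == "1016")
    assert find_binding_sites(t_v, i1016f) == []
    relaxed = find_binding_sites(
        t_v, i1016f, max_internal_mismatch=1, require_3prime_exact=False
    )
    assert len(relaxed) == 1
    assert relaxed[0].mismatches == 1 and not relaxed[0].three_prime_matched
    # the anchor alone still rejects even with a mismatch budget
    assert (
        find_binding_sites(t_v, i1016f, max_internal_mismatch=1, require_3prime_exact=True)
        == []
    )


def test_internal_mismatch_budget():
    primer = Primer("probe", "ACGTTGCAACGGTCA", "forward", "410")
    seq = "TTTTT" + "ACGTTGCAACGGTCA" + "TTTTT"
    mutated = seq[:8] + ("A" if seq[8] != "A" else "C") + seq[9:]
    t = Template("t", mutated)
    assert find_binding_sites(t, primer) == []
    sites = find_binding_sites(t, primer, max_internal_mismatch=1)
    assert len(sites) == 1 and sites[0].mismatches == 1


def test_iupac_degenerate_primer_matches_compatible_bases():
    primer = Primer("degen", "ACGTRCGTNCGTAY", "forward", "410")
    # R~A/G, N~any, Y~C/T at the 3' terminus
    core = "ACGTACGTGCGTAC"
    t = Template("t", "GGGGG" + core + "GGGGG")
    sites = find_binding_sites(t, primer)
    assert len(sites) == 1 and sites[0].mismatches == 0


@pytest.mark.parametrize(
    "genotype, locus, hap, sizes",
    [
        ("LL/VV/FF", "410", 0, {113}),  # resistant 410 haplotype
        ("VV/VV/FF", "410", 0, {133}),
        ("VV/II/FF", "1016", 0, {82}),
        ("VV/VV/FF", "1016", 0, {102}),
        ("VV/VV/CC", "1534", 0, {368, 180}),  # nested: control + inner product
        ("VV/VV/FF", "1534", 0, {368, 232}),
    ],
)
def test_single_haplotype_product_sizes(panel, genotype, locus, hap, sizes):
    haps = build_templates(parse_genotype(genotype, panel), panel, seed=11)
    t = next(t for t in haps[hap] if t.tags["locus"] == locus)
    amps = predict_amplicons(t, panel)
    assert {a.length for a in amps} == sizes


def test_amplicon_labels(panel):
    haps = build_templates(parse_genotype("LL/VV/CC", panel), panel, seed=5)
    t1534 = next(t for t in haps[0] if t.tags["locus"] == "1534")
    amps = {a.length: a for a in predict_amplicons(t1534, panel)}
    assert (amps[368].locus, amps[368].allele) == ("1534", None)  # common pair
    assert (amps[180].locus, amps[180].allele) == ("1534", "C")
    t410 = next(t for t in haps[0] if t.tags["locus"] == "410")
    (a410,) = predict_amplicons(t410, panel)
    assert (a410.locus, a410.allele, a410.length) == ("410", "L", 113)


def test_random_template_yields_nothing(panel):
    rng = np.random.default_rng(12)
    # screened: resample until no panel primer site occurs by chance
    for _ in range(20):
        t = Template("rand", random_dna(rng, 600))
        if not any(find_binding_sites(t, p) for p in panel.primers):
            assert predict_amplicons(t, panel) == []
            return
    pytest.fail("could not draw a clean random template")


def test_max_len_caps_products(panel):
    haps = build_templates(parse_genotype("VV/VV/FF", panel), panel, seed=6)
    t = next(t for t in haps[0] if t.tags["locus"] == "1534")
    sizes = {a.length for a in predict_amplicons(t, panel, max_len=250)}
    assert sizes == {232}  # the 368 bp outer product is filtered out


def test_strand_symmetry(panel, genotypes27):
    """Reverse-complementing every template leaves product sizes unchanged."""
    for g in genotypes27[::5]:
        haps = build_templates(g, panel, seed=8)
        flipped = tuple([t.revcomp() for t in hap] for hap in haps)
        assert amplicon_sizes(amplify_individual(haps, panel)) == amplicon_sizes(
            amplify_individual(flipped, panel)
        )


def test_heterozygote_pools_both_allele_products(panel):
    haps = build_templates(parse_genotype("VL/VV/FF", panel), panel, seed=9)
    sizes = amplicon_sizes(amplify_individual(haps, panel))
    assert {113, 133} <= set(sizes)


def test_empty_haplotypes_amplify_nothing(panel):
    assert amplify_individual(([], []), panel) == []


def test_end_to_end_identity_all_27_classes(panel, genotypes27):
    """Templates built for any genotype amplify to exactly its expected bands."""
    for g in genotypes27:
        haps = build_templates(g, panel, seed=10)
        sizes = set(amplicon_sizes(amplify_individual(haps, panel)))
        assert sizes == set(expected_bands(g, panel)), g.render()
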