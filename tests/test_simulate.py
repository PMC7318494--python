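"""Simulator: sampling modes, template construction, noise, determinism."""

import numpy as np
import pytest

from kdrtyper import (
    BandPattern,
    NoiseModel,
    SimulationConfig,
    allele_frequencies,
    apply_noise,
    build_templates,
    expected_bands,
    genotype_counts,
    parse_genotype,
    simulate_population,
)
from kdrtyper.caller import FAILED
from kdrtyper.errors import SimulationConfigError
from kdrtyper.pipeline import assay_individual, genotype_individuals
from kdrtyper.simulate import EXACT_COUNTS, HAPLOTYPE_FREQS, INDEPENDENT_LOCI


def test_exact_counts_emits_requested_classes(panel):
    cfg = SimulationConfig(
        EXACT_COUNTS,
        {"Monterrey": {"counts": {"LL/II/CC": 1, "LL/VI/CC": 6, "VL/VI/CC": 9}, "n": 16}},
        seed=1,
    )
    individuals = simulate_population(cfg, panel)
    assert len(individuals) == 16
    tally = {}
    for ind in individuals:
        tally[ind.genotype.render()] = tally.get(ind.genotype.render(), 0) + 1
    assert tally == {"LL/II/CC": 1, "LL/VI/CC": 6, "VL/VI/CC": 9}


def test_exact_counts_must_sum_to_n():
    # construction is lazy; the count/n mismatch surfaces when sampling
    cfg = SimulationConfig(EXACT_COUNTS, {"p": {"counts": {"LL/II/CC": 2}, "n": 5}})
    with pytest.raises(SimulationConfigError, match="sum to"):
        simulate_population(cfg)


def test_independent_loci_extremes(panel):
    all_sus = SimulationConfig(
        INDEPENDENT_LOCI, {"p": {"n": 8, "resistant_freqs": {}}}, seed=2
    )
    assert {i.genotype.render() for i in simulate_population(all_sus, panel)} == {"VV/VV/FF"}
    all_res = SimulationConfig(
        INDEPENDENT_LOCI,
        {"p": {"n": 8, "resistant_freqs": {"410": 1, "1016": 1, "1534": 1}}},
        seed=2,
    )
    assert {i.genotype.render() for i in simulate_population(all_res, panel)} == {"LL/II/CC"}


def test_haplotype_freqs_single_haplotype(panel):
    cfg = SimulationConfig(
        HAPLOTYPE_FREQS, {"p": {"n": 5, "freqs": {"LIC": 1.0}}}, seed=3
    )
    assert {i.genotype.render() for i in simulate_population(cfg, panel)} == {"LL/II/CC"}


def test_config_validation():
    with pytest.raises(SimulationConfigError):
        SimulationConfig("bogus", {"p": {}})
    with pytest.raises(SimulationConfigError):
        SimulationConfig(EXACT_COUNTS, {})
    with pytest.raises(SimulationConfigError):
        NoiseModel(band_dropout_prob=1.5)
    cfg = SimulationConfig(HAPLOTYPE_FREQS, {"p": {"n": 5, "freqs": {"LIC": 0.7}}})
    with pytest.raises(SimulationConfigError, match="sum"):
        simulate_population(cfg)


def test_config_from_json(tmp_path):
    doc = (
        '{"mode": "haplotype_freqs", "seed": 9,'
        ' "populations": {"p": {"n": 4, "freqs": {"LIC": 0.5, "VVF": 0.5}}},'
        ' "noise": {"band_dropout_prob": 0.1}}'
    )
    path = tmp_path / "sim.json"
    path.write_text(doc)
    cfg = SimulationConfig.from_json(path)
    assert cfg.mode == HAPLOTYPE_FREQS and cfg.seed == 9
    assert cfg.noise.band_dropout_prob == 0.1


def test_het_1534_haplotypes_split_nested_products(panel):
    """An F/C heterozygote's two chromosome copies yield 368+232 and 368+180."""
    from kdrtyper import predict_amplicons

    haps = build_templates(parse_genotype("VV/VV/FC", panel), panel, seed=4)
    per_hap = []
    for hap in haps:
        t = next(t for t in hap if t.tags["locus"] == "1534")
        per_hap.append({a.length for a in predict_amplicons(t, panel)})
    # haplotype 1 carries the susceptible F allele, haplotype 2 the C allele
    assert per_hap == [{368, 232}, {368, 180}]


def test_template_tags_consistent_with_genotype(panel, genotypes27):
    g = genotypes27[13]
    haps = build_templates(g, panel, seed=5, individual_id="m1")
    for hap_i, hap in enumerate(haps):
        assert [t.tags["locus"] for t in hap] == ["410", "1016", "1534"]
        for loc_i, t in enumerate(hap):
            assert t.tags["allele"] == g.pair(loc_i)[hap_i]
            assert t.tags["genotype"] == g.render()


def test_simulation_is_deterministic(panel):
    cfg = SimulationConfig(
        HAPLOTYPE_FREQS, {"p": {"n": 6, "freqs": {"LIC": 0.4, "VVF": 0.6}}}, seed=42
    )
    a = simulate_population(cfg, panel)
    b = simulate_population(cfg, panel)
    assert [i.genotype for i in a] == [i.genotype for i in b]
    assert [
        t.seq for i in a for hap in i.haplotypes for t in hap
    ] == [t.seq for i in b for hap in i.haplotypes for t in hap]
    # a different seed changes the spacer sequence
    cfg2 = SimulationConfig(cfg.mode, cfg.populations, seed=43)
    c = simulate_population(cfg2, panel)
    assert [t.seq for hap in a[0].haplotypes for t in hap] != [
        t.seq for hap in c[0].haplotypes for t in hap
    ]


def test_noise_zero_is_identity(panel):
    rng = np.random.default_rng(0)
    pattern = BandPattern((82, 113, 368), True)
    assert apply_noise(pattern, NoiseModel(), rng, panel) == pattern


def test_control_dropout_always_fails_decode(panel):
    rng = np.random.default_rng(0)
    noise = NoiseModel(control_dropout_prob=1.0)
    cfg = SimulationConfig(EXACT_COUNTS, {"p": {"counts": {"VL/VI/FC": 3}}}, seed=6)
    for ind in simulate_population(cfg, panel):
        call = assay_individual(ind, panel, noise=noise, rng=rng)
        assert call.status == FAILED


def test_band_dropout_rate_is_binomial(panel):
    """Each non-control band of 10,000 heterozygote patterns survives with
    probability 0.5, within 3 binomial standard errors."""
    rng = np.random.default_rng(7)
    noise = NoiseModel(band_dropout_prob=0.5)
    pattern = BandPattern((82, 102, 113, 133, 180, 232, 368), True)
    n_trials, n_bands = 10_000, 6
    kept = 0
    for _ in range(n_trials):
        noisy = apply_noise(pattern, noise, rng, panel)
        kept += len([s for s in noisy.sizes if s != 368])
    total = n_trials * n_bands
    se = (0.5 * 0.5 / total) ** 0.5
    assert abs(kept / total - 0.5) < 3 * se


def test_allele_frequency_recovery_through_full_pipeline(panel):
    """Simulate linked haplotypes at known frequencies for n=500, run
    simulate -> pcr -> gel -> decode -> summarize, and recover each locus's
    resistant-allele frequency within 3 binomial standard errors."""
    f = {"LIC": 0.35, "VVC": 0.25, "VVF": 0.40}
    res_freq = {"410": 0.35, "1016": 0.35, "1534": 0.60}
    n = 500
    cfg = SimulationConfig(HAPLOTYPE_FREQS, {"p": {"n": n, "freqs": f}}, seed=2024)
    individuals = simulate_population(cfg, panel)
    calls = genotype_individuals(individuals, panel)
    assert all(c.is_ok for c in calls)
    counts = genotype_counts(calls, {i.id: "p" for i in individuals}, panel)
    est = allele_frequencies(counts, panel).loc["p"]
    for locus, truth in res_freq.items():
        se = (truth * (1 - truth) / (2 * n)) ** 0.5
        assert abs(est[locus] - truth) < 3 * se, locus


def test_simulated_truth_matches_assay_calls(panel):
    cfg = SimulationConfig(
        HAPLOTYPE_FREQS, {"p": {"n": 30, "freqs": {"LIC": 0.5, "VVF": 0.5}}}, seed=11
    )
    individuals = simulate_population(cfg, panel)
    for ind, call in zip(individuals, genotype_individuals(individuals, panel)):
        assert call.genotype == ind.genotype
        assert set(expected_bands(ind.genotype, panel)) >= {panel.control_size}
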