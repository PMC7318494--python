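"""Analyze the bundled 12-population field survey (352 mosquitoes, Mexico
2018): marginal genotype counts, resistant-allele frequencies, fixation and
the most frequent multi-locus genotypes.
"""

from kdrtyper import (
    allele_frequencies,
    concordance,
    fixed_populations,
    load_survey_genotype_counts,
    marginalize,
    rank_genotypes,
    round_half_up,
)
from kdrtyper.popgen import calls_from_counts

counts = load_survey_genotype_counts()
print(f"{len(counts)} populations, {int(counts.values.sum())} mosquitoes, "
      f"{int((counts.sum(axis=0) > 0).sum())} of 27 genotype classes observed\n")

freqs = allele_frequencies(counts)
print("resistant-allele frequency (rounded to 2 decimals):")
print(freqs.map(round_half_up).to_string(), "\n")

fixed = fixed_populations(freqs, "1534")
print(f"C1534 fixed in {len(fixed)}/12 populations: {', '.join(fixed)}\n")

print("Monterrey one-locus marginals (410):",
      marginalize(counts, "410").loc["Monterrey"].to_dict())

top = rank_genotypes(counts)[:2]
print(f"most frequent genotypes: {top[0][0]} ({top[0][1]}), then {top[1][0]} ({top[1][1]})")

multiplex, _ = calls_from_counts(counts, method="multiplex")
aspcr, _ = calls_from_counts(counts, method="aspcr")
result = concordance(multiplex, aspcr)
print(f"multiplex vs simplex concordance: {result.fraction:.2f} "
      f"over {result.n_compared} samples")
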