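"""Population summaries: genotype-count tables, allele frequencies,
fixation, genotype ranking and inter-method concordance.

Tables are plain pandas DataFrames with documented shapes:

* genotype-count table — index: population, columns: the genotype classes in
  canonical order, integer counts; row sums are the per-population sample
  sizes n (successfully genotyped mosquitoes only).
* locus marginal table — index: population, columns: the three one-locus
  genotype codes (hom-susceptible, heterozygote, hom-resistant).
* allele-frequency table — index: population, columns: locus names, values:
  resistant-allele frequency at full precision. Reporting rounds half-up to
  two decimals, which is also how the bundled survey table prints them.

The bundled fixtures transcribe a 2018 survey of 12 Mexican *Ae. aegypti*
field populations (352 mosquitoes) genotyped for V410L/V1016I/F1534C by
three methods that agreed on every sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .caller import OK, SampleCall
from .errors import SampleMismatchError
from .panel import PrimerPanel, default_panel, enumerate_genotypes

logger = logging.getLogger(__name__)


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero, the convention of the survey tables."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def allele_frequency(hom_res: int, het: int, hom_sus: int) -> float:
    """Resistant-allele frequency from one-locus genotype counts.

    f = (2*hom_res + het) / (2*(hom_res + het + hom_sus)), full precision.
    """
    total = hom_res + het + hom_sus
    if total <= 0:
        raise ValueError("allele frequency undefined for zero genotyped individuals")
    if min(hom_res, het, hom_sus) < 0:
        raise ValueError("genotype counts must be non-negative")
    return (2 * hom_res + het) / (2 * total)


def canonical_classes(panel: PrimerPanel | None = None) -> list[str]:
    """The genotype class labels in canonical order (27 for three loci)."""
    return [g.render() for g in enumerate_genotypes(panel or default_panel())]


def genotype_counts(
    calls: Iterable[SampleCall],
    populations: Mapping[str, str],
    panel: PrimerPanel | None = None,
) -> pd.DataFrame:
    """Tally successful calls into a population x genotype-class count table.

    ``populations`` maps sample id -> population label; every successful
    call's sample must be present. Failed/ambiguous calls are excluded from
    the tally (and counted in the log).
    """
    panel = panel or default_panel()
    classes = canonical_classes(panel)
    pop_order: list[str] = []
    for pop in populations.values():
        if pop not in pop_order:
            pop_order.append(pop)
    table = pd.DataFrame(0, index=pd.Index(pop_order, name="population"), columns=classes)

    skipped = 0
    for call in calls:
        if not call.is_ok:
            skipped += 1
            continue
        if call.sample_id not in populations:
            raise KeyError(f"sample {call.sample_id!r} has no population label")
        table.loc[populations[call.sample_id], call.genotype.render()] += 1
    if skipped:
        logger.info("excluded %d failed/ambiguous calls from the count table", skipped)
    return table


def marginalize(
    counts: pd.DataFrame, locus: str, panel: PrimerPanel | None = None
) -> pd.DataFrame:
    """Collapse a genotype-class count table to one-locus genotype counts."""
    panel = panel or default_panel()
    idx = [l.name for l in panel.loci].index(locus)
    codes = panel.loci[idx].genotype_codes()
    out = pd.DataFrame(0, index=counts.index, columns=list(codes))
    for cls in counts.columns:
        out[cls.split("/")[idx]] += counts[cls]
    return out


def allele_frequencies(
    counts: pd.DataFrame, panel: PrimerPanel | None = None
) -> pd.DataFrame:
    """Per-population resistant-allele frequency at each locus (full precision)."""
    panel = panel or default_panel()
    freqs = {}
    for locus in panel.loci:
        marg = marginalize(counts, locus.name, panel)
        ss, sr, rr = locus.genotype_codes()
        freqs[locus.name] = [
            allele_frequency(int(row[rr]), int(row[sr]), int(row[ss]))
            for _, row in marg.iterrows()
        ]
    return pd.DataFrame(freqs, index=counts.index)


def summarize(
    calls: Iterable[SampleCall],
    populations: Mapping[str, str],
    panel: PrimerPanel | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Genotype-count and allele-frequency tables from a batch of calls."""
    counts = genotype_counts(calls, populations, panel)
    return counts, allele_frequencies(counts, panel)


def fixed_populations(
    freqs: pd.DataFrame, locus: str, tol: float = 0.0
) -> list[str]:
    """Populations where the resistant allele is fixed at a locus.

    Fixation means the two-decimal reported frequency is >= 1 - tol; the
    default tol of 0 requires exactly 1.00 after rounding.
    """
    if tol < 0:
        raise ValueError("tol must be >= 0")
    col = freqs[locus]
    return [pop for pop, f in col.items() if round_half_up(float(f)) >= 1.0 - tol]


def rank_genotypes(
    counts: pd.DataFrame, panel: PrimerPanel | None = None
) -> list[tuple[str, int]]:
    """Genotype classes by pooled count, descending; ties break by canonical
    class order (stable)."""
    classes = canonical_classes(panel)
    pooled = counts.sum(axis=0)
    order = sorted(
        ((cls, int(pooled.get(cls, 0))) for cls in classes),
        key=lambda t: (-t[1], classes.index(t[0])),
    )
    return order


@dataclass(frozen=True)
class ConcordanceResult:
    fraction: float
    n_compared: int
    discordant: tuple[str, ...]
    excluded: tuple[str, ...]  # failed/ambiguous in either method


def concordance(
    calls_a: Sequence[SampleCall], calls_b: Sequence[SampleCall]
) -> ConcordanceResult:
    """Agreement between two call sets over shared sample ids.

    Samples failed or ambiguous under either method are excluded from the
    denominator and reported separately.
    """
    a = {c.sample_id: c for c in calls_a}
    b = {c.sample_id: c for c in calls_b}
    if set(a) != set(b):
        raise SampleMismatchError(
            missing_in_a=sorted(set(b) - set(a)),
            missing_in_b=sorted(set(a) - set(b)),
        )
    excluded, discordant, matched = [], [], 0
    for sid in a:
        ca, cb = a[sid], b[sid]
        if ca.status != OK or cb.status != OK:
            excluded.append(sid)
        elif ca.genotype == cb.genotype:
            matched += 1
        else:
            discordant.append(sid)
    n = matched + len(discordant)
    fraction = matched / n if n else float("nan")
    return ConcordanceResult(fraction, n, tuple(sorted(discordant)), tuple(sorted(excluded)))


# ---------------------------------------------------------------------------
# Bundled survey fixtures
# ---------------------------------------------------------------------------


def _data_path(name: str):
    return resources.files("kdrtyper.data").joinpath(name)


def load_survey_genotype_counts(full: bool = True) -> pd.DataFrame:
    """The bundled 12-population genotype-class count table.

    The published table prints only the 15 observed classes; with ``full``
    (default) the remaining 12 classes are added as zero columns and columns
    are put in canonical order. The per-population n column is dropped (it
    equals the row sum, which is asserted on load).
    """
    with resources.as_file(_data_path("survey_genotype_counts.tsv")) as p:
        raw = pd.read_csv(p, sep="\t", index_col="population")
    n = raw.pop("n")
    if not (raw.sum(axis=1) == n).all():
        raise ValueError("survey fixture corrupt: row sums disagree with n")
    if not full:
        return raw
    classes = canonical_classes()
    out = pd.DataFrame(0, index=raw.index, columns=classes)
    out[raw.columns] = raw
    return out


def load_survey_locus_table() -> pd.DataFrame:
    """The bundled per-locus table: one-locus genotype counts and the
    printed two-decimal resistant-allele frequency, long format
    (population, n, locus, hom_susceptible, heterozygote, hom_resistant,
    frequency)."""
    with resources.as_file(_data_path("survey_locus_table.tsv")) as p:
        return pd.read_csv(p, sep="\t", dtype={"locus": str})


def calls_from_counts(
    counts: pd.DataFrame,
    panel: PrimerPanel | None = None,
    method: str = "multiplex",
) -> tuple[list[SampleCall], dict[str, str]]:
    """Expand a count table into per-individual calls (plus the sample ->
    population map), the inverse of ``genotype_counts``. Sample ids are
    deterministic: ``<population>_<k>``."""
    panel = panel or default_panel()
    from .panel import parse_genotype

    calls: list[SampleCall] = []
    pops: dict[str, str] = {}
    for pop, row in counts.iterrows():
        k = 0
        for cls, count in row.items():
            g = parse_genotype(cls, panel)
            for _ in range(int(count)):
                k += 1
                sid = f"{pop}_{k}"
                calls.append(SampleCall(sid, method, g, OK))
                pops[sid] = pop
    return calls, pops
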