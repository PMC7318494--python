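"""Readers and writers binding the modules into shell pipelines.

Conventions: tables are tab-delimited UTF-8 with a header row; FASTA wraps
at 70 columns with ``key=value`` haplotype tags in the description line;
configs are JSON. Every writer's output is re-readable by the matching
reader.
"""

from __future__ import annotations

import hashlib
import logging
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .caller import OK, SampleCall
from .gel import BandPattern
from .panel import MultiLocusGenotype, PrimerPanel, panel_to_json, parse_genotype
from .pcr import Amplicon, Template
from .simulate import Individual

logger = logging.getLogger(__name__)


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )


def panel_hash(panel: PrimerPanel) -> str:
    """Short content hash of a panel, logged with every artifact-writing run."""
    return hashlib.sha256(panel_to_json(panel).encode()).hexdigest()[:12]


# --- FASTA -----------------------------------------------------------------


def _tags_to_description(tags) -> str:
    return " ".join(f"{k}={v}" for k, v in tags.items())


def _description_to_tags(description: str) -> dict[str, str]:
    tags = {}
    for token in description.split():
        if "=" in token:
            k, _, v = token.partition("=")
            tags[k] = v
    return tags


def write_templates_fasta(templates: Iterable[Template], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(t.seq), id=t.id, description=_tags_to_description(t.tags))
        for t in templates
    ]
    with open(path, "w", encoding="utf-8") as fh:
        SeqIO.write(records, fh, "fasta")


def read_templates_fasta(path: str | Path) -> list[Template]:
    templates = []
    for rec in SeqIO.parse(str(path), "fasta"):
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id) :].strip()
        templates.append(Template(rec.id, str(rec.seq).upper(), _description_to_tags(desc)))
    return templates


def write_individuals_fasta(individuals: Iterable[Individual], path: str | Path) -> None:
    """All haplotype templates of a simulated cohort, tags included."""
    flat: list[Template] = []
    for ind in individuals:
        for hap in ind.haplotypes:
            flat.extend(hap)
    write_templates_fasta(flat, path)


# --- TSV tables ------------------------------------------------------------


def write_truth_tsv(individuals: Sequence[Individual], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "sample_id": [i.id for i in individuals],
            "population": [i.population for i in individuals],
            "genotype": [i.genotype.render() for i in individuals],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def write_amplicons_tsv(amplicons: Iterable[Amplicon], path: str | Path) -> None:
    rows = [
        {
            "template": a.template_id,
            "fwd_primer": a.fwd.primer.name,
            "rev_primer": a.rev.primer.name,
            # reported 1-based inclusive on the plus strand
            "start": a.fwd.start + 1,
            "end": a.rev.end,
            "length": a.length,
            "locus": a.locus or "",
            "allele": a.allele or "",
        }
        for a in amplicons
    ]
    pd.DataFrame(
        rows,
        columns=["template", "fwd_primer", "rev_primer", "start", "end", "length", "locus", "allele"],
    ).to_csv(path, sep="\t", index=False)


def write_bands_tsv(
    patterns: Sequence[BandPattern], sample_ids: Sequence[str], path: str | Path
) -> None:
    df = pd.DataFrame(
        {
            "sample_id": list(sample_ids),
            "bands": [",".join(map(str, p.sizes)) for p in patterns],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_bands_tsv(path: str | Path) -> tuple[list[str], list[list[int]]]:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "bands": str})
    ids = df["sample_id"].tolist()
    bands = [
        [int(s) for s in str(row).split(",") if s.strip()] if pd.notna(row) and str(row).strip() else []
        for row in df["bands"]
    ]
    return ids, bands


def write_calls_tsv(calls: Sequence[SampleCall], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "sample_id": [c.sample_id for c in calls],
            "method": [c.method for c in calls],
            "genotype": [c.genotype.render() if c.genotype else "" for c in calls],
            "status": [c.status for c in calls],
            "notes": ["; ".join(c.notes) for c in calls],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_calls_tsv(path: str | Path, panel: PrimerPanel | None = None) -> list[SampleCall]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    calls = []
    for _, row in df.iterrows():
        genotype: MultiLocusGenotype | None = None
        if row["status"] == OK:
            genotype = parse_genotype(row["genotype"], panel)
        notes = tuple(n for n in row.get("notes", "").split("; ") if n)
        calls.append(
            SampleCall(row["sample_id"], row["method"], genotype, row["status"], notes)
        )
    return calls


# --- VCF export ------------------------------------------------------------

# The three kdr sites on a synthetic contig; alleles encoded as the codon's
# discriminating nucleotide (V410L GTA>TTA, V1016I GTA>ATA, F1534C TTC>TGC).
VCF_CONTIG = "vgsc_synth"
VCF_SITES = {
    "410": (1410, "G", "T"),
    "1016": (2016, "G", "A"),
    "1534": (3534, "T", "G"),
}


def write_vcf(calls: Sequence[SampleCall], path: str | Path, panel: PrimerPanel | None = None) -> None:
    """Minimal VCF 4.2 export: three fixed synthetic sites, one sample column
    per call; failed/ambiguous samples get missing genotypes."""
    from .panel import default_panel

    panel = panel or default_panel()
    loci = [l.name for l in panel.loci]
    samples = [c.sample_id for c in calls]
    lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={VCF_CONTIG},length=5000>",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples),
    ]
    for i, locus_name in enumerate(loci):
        pos, ref, alt = VCF_SITES[locus_name]
        locus = panel.loci[i]
        fields = [VCF_CONTIG, str(pos), f"kdr{locus_name}", ref, alt, ".", "PASS", ".", "GT"]
        for c in calls:
            if c.genotype is None:
                fields.append("./.")
            else:
                pair = c.genotype.pair(i)
                gt = "/".join("0" if a == locus.susceptible else "1" for a in pair)
                fields.append(gt)
        lines.append("\t".join(fields))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
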