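"""Primer panel model for the three-locus kdr multiplex assay.

The assay genotypes three voltage-gated sodium channel (vgsc) substitutions
in *Aedes aegypti* — V410L (domain IS6), V1016I (IIS6) and F1534C (IIIS6) —
in a single reaction. Each locus is interrogated by allele-specific primers
whose 3' terminal base sits on the variant, and the two alleles of a locus
are separated on the gel by length: the primer for one allele carries a
non-templated 5' GC tail that lengthens its product by a fixed offset.
Locus 1534 uses a nested design: a common outer pair amplifies a 368 bp
fragment that doubles as the internal control, and two allele-specific inner
primers (one forward, one reverse, overlapping at the variant base) yield
180 bp (C, resistant) or 232 bp (F, susceptible) products inside it.

The genotype -> band-size code of the default panel:

    locus 410:  L (res) 113 bp, V (sus) 133 bp
    locus 1016: I (res)  82 bp, V (sus) 102 bp
    locus 1534: C (res) 180 bp, F (sus) 232 bp
    control: 368 bp in every successful reaction

All seven sizes are pairwise distinct, so every one of the 27 three-locus
diploid genotype classes maps to a unique band pattern.
"""

from __future__ import annotations

import csv
import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from .dna import is_iupac, revcomp
from .errors import PanelConfigError, PanelValidationError

FORWARD = "forward"
REVERSE = "reverse"


@dataclass(frozen=True)
class Locus:
    """A biallelic amino-acid position in vgsc.

    ``name`` is the codon number as text ("410"), ``domain_label`` the
    channel domain ("IS6"), and the two alleles are one-letter amino-acid
    codes with the susceptible (wild-type) residue listed first.
    """

    name: str
    domain_label: str
    susceptible: str
    resistant: str

    def __post_init__(self) -> None:
        if self.susceptible == self.resistant:
            raise PanelValidationError(
                f"locus {self.name}: susceptible and resistant alleles must differ"
            )

    @property
    def alleles(self) -> tuple[str, str]:
        return (self.susceptible, self.resistant)

    def genotype_codes(self) -> tuple[str, str, str]:
        """The three diploid codes in canonical order: hom-sus, het, hom-res."""
        s, r = self.susceptible, self.resistant
        return (s + s, s + r, r + r)


@dataclass(frozen=True)
class Primer:
    """One oligonucleotide of the panel.

    ``seq`` is written 5'->3' in IUPAC letters. ``tail_len`` counts 5' bases
    that are non-templated (the GC tail used to offset product sizes); only
    ``seq[tail_len:]`` is matched against templates. Allele-specific primers
    carry the discriminating base at the 3' terminus. ``concentration`` is
    inert metadata (pmol/ul in the published reaction mix).
    """

    name: str
    seq: str
    orientation: str
    locus: str
    allele: str | None = None
    tail_len: int = 0
    concentration: float | None = None

    def __post_init__(self) -> None:
        if not self.seq or not is_iupac(self.seq):
            raise PanelValidationError(
                f"primer {self.name}: sequence must be non-empty uppercase IUPAC"
            )
        if self.orientation not in (FORWARD, REVERSE):
            raise PanelValidationError(
                f"primer {self.name}: orientation must be forward/reverse"
            )
        if not 0 <= self.tail_len < len(self.seq):
            raise PanelValidationError(
                f"primer {self.name}: tail_len must be < primer length"
            )

    @property
    def templated(self) -> str:
        """The 3' portion that actually hybridizes to the template."""
        return self.seq[self.tail_len :]

    @property
    def three_prime_base(self) -> str:
        return self.seq[-1]

    @property
    def is_allele_specific(self) -> bool:
        return self.allele is not None

    def tm_wallace(self) -> float:
        """Wallace-rule melting temperature of the templated portion."""
        from Bio.SeqUtils import MeltingTemp

        return float(MeltingTemp.Tm_Wallace(self.templated))


@dataclass(frozen=True)
class AssayProtocol:
    """Thermocycling / reaction metadata. Never used in computation."""

    cycles: int = 45
    anneal_temp: float = 58.6
    extras: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.cycles <= 0 or self.anneal_temp <= 0:
            raise PanelValidationError("protocol values must be positive")


@dataclass(frozen=True)
class PrimerPanel:
    """A validated multiplex panel: loci, primers and the size code."""

    loci: tuple[Locus, ...]
    primers: tuple[Primer, ...]
    product_table: Mapping[tuple[str, str], int]  # (locus name, allele) -> bp
    control_size: int
    protocol: AssayProtocol | None = None

    def __post_init__(self) -> None:
        names = [p.name for p in self.primers]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise PanelValidationError(f"duplicate primer names: {dupes}")
        locus_names = {loc.name for loc in self.loci}
        if len(locus_names) != len(self.loci):
            raise PanelValidationError("duplicate locus names")
        allele_sizes = list(self.product_table.values())
        sizes = allele_sizes + [self.control_size]
        if len(set(sizes)) != len(sizes):
            raise PanelValidationError(
                f"product sizes must be pairwise distinct, got {sorted(sizes)}"
            )
        for (locus, allele), size in self.product_table.items():
            loc = self._locus_or_none(locus)
            if loc is None:
                raise PanelValidationError(f"product table references unknown locus {locus}")
            if allele not in loc.alleles:
                raise PanelValidationError(
                    f"product table references unknown allele {allele} at locus {locus}"
                )
            if size <= 0:
                raise PanelValidationError("product sizes must be positive")
        for p in self.primers:
            if p.locus not in locus_names:
                raise PanelValidationError(
                    f"primer {p.name} references unknown locus {p.locus}"
                )
            if p.allele is not None:
                loc = self.locus(p.locus)
                if p.allele not in loc.alleles:
                    raise PanelValidationError(
                        f"primer {p.name}: allele {p.allele} not legal at locus {p.locus}"
                    )

    def _locus_or_none(self, name: str) -> Locus | None:
        for loc in self.loci:
            if loc.name == name:
                return loc
        return None

    def locus(self, name: str) -> Locus:
        loc = self._locus_or_none(name)
        if loc is None:
            raise KeyError(f"no locus named {name}")
        return loc

    def primers_at(self, locus: str) -> list[Primer]:
        return [p for p in self.primers if p.locus == locus]

    def size_of(self, locus: str, allele: str) -> int:
        return self.product_table[(locus, allele)]

    @property
    def all_sizes(self) -> tuple[int, ...]:
        """Every diagnostic size including the control, ascending."""
        return tuple(sorted([*self.product_table.values(), self.control_size]))


@dataclass(frozen=True, order=True)
class MultiLocusGenotype:
    """An unordered diploid allele pair at each panel locus.

    ``codes`` holds one two-letter code per locus in panel order, already
    canonicalized (susceptible letter first in heterozygotes). Rendered as
    e.g. ``"VL/VI/CC"``.
    """

    codes: tuple[str, ...]

    def render(self) -> str:
        return "/".join(self.codes)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.render()

    def pair(self, i: int) -> tuple[str, str]:
        return (self.codes[i][0], self.codes[i][1])

    def alleles_at(self, i: int) -> tuple[str, ...]:
        """Distinct alleles carried at locus index i (1 for hom, 2 for het)."""
        a, b = self.pair(i)
        return (a,) if a == b else (a, b)

    def is_het(self, i: int) -> bool:
        return self.codes[i][0] != self.codes[i][1]

    @property
    def n_het(self) -> int:
        return sum(self.is_het(i) for i in range(len(self.codes)))


def _canonical_code(code: str, locus: Locus) -> str:
    legal = set(locus.alleles)
    if len(code) != 2 or not set(code) <= legal:
        raise ValueError(
            f"'{code}' is not a genotype at locus {locus.name} "
            f"(alleles {locus.susceptible}/{locus.resistant})"
        )
    if code[0] == locus.resistant and code[1] == locus.susceptible:
        return code[1] + code[0]  # accept reversed het and canonicalize
    return code


def genotype_from_codes(codes: Sequence[str], loci: Sequence[Locus]) -> MultiLocusGenotype:
    if len(codes) != len(loci):
        raise ValueError(f"expected {len(loci)} locus codes, got {len(codes)}")
    return MultiLocusGenotype(
        tuple(_canonical_code(c, loc) for c, loc in zip(codes, loci))
    )


def parse_genotype(text: str, panel: "PrimerPanel | None" = None) -> MultiLocusGenotype:
    """Parse a rendering like ``"VL/VI/CC"`` against a panel's loci."""
    loci = (panel or default_panel()).loci
    return genotype_from_codes(text.strip().split("/"), loci)


def enumerate_genotypes(panel: PrimerPanel) -> list[MultiLocusGenotype]:
    """All diploid genotype classes in canonical order (3^n_loci of them).

    Per-locus order is hom-susceptible, heterozygote, hom-resistant, with the
    first panel locus varying slowest.
    """
    per_locus = [loc.genotype_codes() for loc in panel.loci]
    return [MultiLocusGenotype(codes) for codes in itertools.product(*per_locus)]


def expected_bands(g: MultiLocusGenotype, panel: PrimerPanel) -> frozenset[int]:
    """The ideal band-size set for a genotype: one product per allele carried
    at each locus, plus the internal control."""
    sizes = {panel.control_size}
    for i, loc in enumerate(panel.loci):
        for allele in g.alleles_at(i):
            key = (loc.name, allele)
            if key not in panel.product_table:
                raise PanelValidationError(
                    f"panel has no product for allele {allele} at locus {loc.name}"
                )
            sizes.add(panel.product_table[key])
    return frozenset(sizes)


# ---------------------------------------------------------------------------
# Default panel
# ---------------------------------------------------------------------------

DEFAULT_LOCI = (
    Locus("410", "IS6", susceptible="V", resistant="L"),
    Locus("1016", "IIS6", susceptible="V", resistant="I"),
    Locus("1534", "IIIS6", susceptible="F", resistant="C"),
)

# Domain-I primers, published sequences. The susceptible-allele forward
# (V410f) carries a 26 nt GC tail, the resistant-allele forward (L410f) a
# 6 nt tail; both templated portions are 25 nt over the same footprint and
# end on the codon-410 variant, so the two products differ by exactly the
# 20 nt tail difference (133 vs 113 bp).
V410F_SEQ = "GCGGGCAGGGCGGCGGGGGCGGGGCCATCTTCTTGGGTTCGTTCTACCGTG"
L410F_SEQ = "GCGGGCATCTTCTTGGGTTCGTTCTACCATT"
R410_SEQ = "TTCTTCCTCGGCGGCCTCTT"

# Locus 1016/1534 oligos below are synthetic stand-ins: sequences designed
# for this in-silico panel (the published ones live in a supplement that is
# not redistributed here), with tail lengths and footprints chosen so the
# product-size arithmetic reproduces the published 82/102/180/232/368 bp.
_GC_TAIL_20 = "GCGGGCAGGGCGGCGGGGGC"
_CORE_1016 = "CATCGCTTGGAACGTGCTGA"  # shared 20 nt footprint of both 1016 forwards
V1016F_SEQ = _GC_TAIL_20 + _CORE_1016 + "G"
I1016F_SEQ = _CORE_1016 + "A"
I1016R_SEQ = "TCAGGACGTAAGCCTGGTCA"

C1534F_SEQ = "GGATCGCTTCCAAGTGGAAT"
C1534R_SEQ = "TTGACGTGCCATTGAGCAGA"
AE1534C_F_SEQ = "TACGCATGGTCCAGAACTTGT" + "G"  # 3' G = resistant (TGC) variant base
_PLUS_AFTER_SNP_1534 = "ATCGGAGTCAACCTGTGGAGCA"
# Reverse inner primer: 3' terminus on the variant base from the minus strand,
# so its 3' A pairs the susceptible (TTC) plus-strand T.
AE1534F_R_SEQ = revcomp("T" + _PLUS_AFTER_SNP_1534)

DEFAULT_PRODUCT_TABLE: dict[tuple[str, str], int] = {
    ("410", "L"): 113,
    ("410", "V"): 133,
    ("1016", "I"): 82,
    ("1016", "V"): 102,
    ("1534", "C"): 180,
    ("1534", "F"): 232,
}
DEFAULT_CONTROL_SIZE = 368

DEFAULT_PROTOCOL = AssayProtocol(
    cycles=45,
    anneal_temp=58.6,
    extras={
        "initial_denaturation": "95C 2min",
        "denaturation": "95C 30s",
        "extension": "72C 30s",
        "final_extension": "72C 2min",
        "gel": "2.5% agarose, 110V, 1h, 1x SB",
        "ladder": "25 bp",
    },
)


def default_panel() -> PrimerPanel:
    """The built-in three-locus panel with the published size code."""
    primers = (
        Primer("V410f", V410F_SEQ, FORWARD, "410", allele="V", tail_len=26, concentration=1.27),
        Primer("L410f", L410F_SEQ, FORWARD, "410", allele="L", tail_len=6, concentration=1.27),
        Primer("410r", R410_SEQ, REVERSE, "410", concentration=1.27),
        Primer("V1016f", V1016F_SEQ, FORWARD, "1016", allele="V", tail_len=20, concentration=1.02),
        Primer("I1016f", I1016F_SEQ, FORWARD, "1016", allele="I", concentration=1.02),
        Primer("I1016r", I1016R_SEQ, REVERSE, "1016", concentration=1.02),
        Primer("c1534-f", C1534F_SEQ, FORWARD, "1534", concentration=0.82),
        Primer("c1534-r", C1534R_SEQ, REVERSE, "1534", concentration=0.82),
        Primer("Ae1534C-f", AE1534C_F_SEQ, FORWARD, "1534", allele="C", concentration=0.82),
        Primer("Ae1534F-r", AE1534F_R_SEQ, REVERSE, "1534", allele="F", concentration=0.82),
    )
    return PrimerPanel(
        loci=DEFAULT_LOCI,
        primers=primers,
        product_table=dict(DEFAULT_PRODUCT_TABLE),
        control_size=DEFAULT_CONTROL_SIZE,
        protocol=DEFAULT_PROTOCOL,
    )


# ---------------------------------------------------------------------------
# Config I/O
# ---------------------------------------------------------------------------

_REQUIRED_PRIMER_FIELDS = ("name", "seq", "orientation", "locus")


def _primer_from_mapping(d: Mapping) -> Primer:
    missing = [k for k in _REQUIRED_PRIMER_FIELDS if k not in d or d[k] in ("", None)]
    if missing:
        raise PanelConfigError(f"primer entry missing fields {missing}: {dict(d)}")
    try:
        return Primer(
            name=str(d["name"]),
            seq=str(d["seq"]).upper(),
            orientation=str(d["orientation"]),
            locus=str(d["locus"]),
            allele=(str(d["allele"]) if d.get("allele") not in (None, "", "none") else None),
            tail_len=int(d.get("tail_len", 0) or 0),
            concentration=(float(d["conc"]) if d.get("conc") not in (None, "") else None),
        )
    except PanelValidationError:
        raise
    except (TypeError, ValueError) as exc:
        raise PanelConfigError(f"bad primer entry {dict(d)}: {exc}") from exc


def read_primers_tsv(path: str | Path) -> list[Primer]:
    """Read a primer list from a headered TSV (the config's flat alternative)."""
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        return [_primer_from_mapping(row) for row in reader]


def load_panel(config_path: str | Path) -> PrimerPanel:
    """Load and validate a panel from a JSON config.

    Expected keys: ``primers`` (list of objects, or a path to a primer TSV),
    ``loci`` (optional; defaults to the three kdr loci), ``products`` (list
    of {locus, allele, size}), ``control_size``, optional ``protocol``.
    """
    path = Path(config_path)
    if not path.exists():
        raise PanelConfigError(f"panel config not found: {path}")
    try:
        doc = json.loads(path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise PanelConfigError(f"panel config is not valid JSON: {exc}") from exc

    for key in ("primers", "products", "control_size"):
        if key not in doc:
            raise PanelConfigError(f"panel config missing key '{key}'")

    if isinstance(doc["primers"], str):
        primers = read_primers_tsv(path.parent / doc["primers"])
    else:
        primers = [_primer_from_mapping(d) for d in doc["primers"]]

    if "loci" in doc:
        loci = tuple(
            Locus(
                str(d["name"]),
                str(d.get("domain_label", "")),
                str(d["susceptible"]),
                str(d["resistant"]),
            )
            for d in doc["loci"]
        )
    else:
        loci = DEFAULT_LOCI

    try:
        products = {
            (str(d["locus"]), str(d["allele"])): int(d["size"]) for d in doc["products"]
        }
    except (KeyError, TypeError, ValueError) as exc:
        raise PanelConfigError(f"bad 'products' entries: {exc}") from exc

    protocol = None
    if "protocol" in doc:
        p = doc["protocol"]
        protocol = AssayProtocol(
            cycles=int(p.get("cycles", 45)),
            anneal_temp=float(p.get("anneal_temp", 58.6)),
            extras={k: str(v) for k, v in p.items() if k not in ("cycles", "anneal_temp")},
        )

    return PrimerPanel(
        loci=loci,
        primers=tuple(primers),
        product_table=products,
        control_size=int(doc["control_size"]),
        protocol=protocol,
    )


def panel_to_json(panel: PrimerPanel) -> str:
    """Serialize a panel back to the JSON config format."""
    doc = {
        "loci": [
            {
                "name": l.name,
                "domain_label": l.domain_label,
                "susceptible": l.susceptible,
                "resistant": l.resistant,
            }
            for l in panel.loci
        ],
        "primers": [
            {
                "name": p.name,
                "seq": p.seq,
                "orientation": p.orientation,
                "locus": p.locus,
                "allele": p.allele,
                "tail_len": p.tail_len,
                "conc": p.concentration,
            }
            for p in panel.primers
        ],
        "products": [
            {"locus": locus, "allele": allele, "size": size}
            for (locus, allele), size in sorted(panel.product_table.items())
        ],
        "control_size": panel.control_size,
    }
    if panel.protocol is not None:
        doc["protocol"] = {
            "cycles": panel.protocol.cycles,
            "anneal_temp": panel.protocol.anneal_temp,
            **dict(panel.protocol.extras),
        }
    return json.dumps(doc, indent=2)
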