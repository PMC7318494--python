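"""Virtual agarose gel: finite-resolution band formation and lane rendering.

The published assay reads its seven diagnostic sizes (82/102/113/133/180/
232/368 bp) off a 2.5% agarose gel, where the closest pair is 11 bp apart
(102 vs 113). The gel model here keeps only two knobs: fragments whose sizes
differ by less than ``min_resolvable_delta`` co-migrate and merge into one
band at their rounded mean, and fragments outside ``size_range`` run off or
stay in the well. The default delta of 8 bp sits below the assay's closest
pair, so the published design always resolves; raising it lets you explore
when the size code would break down.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

from .panel import PrimerPanel


@dataclass(frozen=True)
class GelModel:
    min_resolvable_delta: int = 8
    size_range: tuple[int, int] = (50, 1000)

    def __post_init__(self) -> None:
        if self.min_resolvable_delta < 0:
            raise ValueError("min_resolvable_delta must be >= 0")
        lo, hi = self.size_range
        if not lo < hi:
            raise ValueError("size_range must satisfy min < max")


@dataclass(frozen=True)
class BandPattern:
    """What one lane shows: unique sorted band sizes plus the control flag."""

    sizes: tuple[int, ...]
    control_present: bool

    def __post_init__(self) -> None:
        object.__setattr__(self, "sizes", tuple(sorted(set(self.sizes))))

    def __contains__(self, size: int) -> bool:
        return size in self.sizes

    def without_control(self, control_size: int) -> "BandPattern":
        return BandPattern(tuple(s for s in self.sizes if s != control_size), False)


def _round_half_up(x: float) -> int:
    return int(Decimal(x).quantize(Decimal("1"), rounding=ROUND_HALF_UP))


def resolve(
    fragments: Iterable[int],
    model: GelModel | None = None,
    panel: PrimerPanel | None = None,
) -> BandPattern:
    """Turn predicted fragment sizes into the observable band pattern.

    Fragments outside the gel's size range are dropped first; the remainder
    are single-linkage clustered, merging any run of sizes with consecutive
    gaps below the resolution delta into one band at the rounded mean. The
    control flag is evaluated after merging against the active panel.
    """
    model = model or GelModel()
    fragments = sorted(f for f in fragments if f > 0)
    lo, hi = model.size_range
    kept = [f for f in fragments if lo <= f <= hi]

    bands: list[int] = []
    i = 0
    while i < len(kept):
        j = i + 1
        while j < len(kept) and kept[j] - kept[j - 1] < model.min_resolvable_delta:
            j += 1
        cluster = kept[i:j]
        bands.append(_round_half_up(sum(cluster) / len(cluster)))
        i = j

    control_size = panel.control_size if panel is not None else None
    control_present = control_size is not None and control_size in bands
    return BandPattern(tuple(bands), control_present)


def render_lanes(
    patterns: Sequence[BandPattern],
    ladder: Sequence[int] | None = None,
    lane_labels: Sequence[str] | None = None,
    mark: str = "==",
) -> str:
    """Fixed-width text gel: a ladder lane plus one column per sample.

    Bands are positioned by size rank (largest at the top, as fragments that
    migrated least), not by physical mobility. Purely presentational.
    """
    all_sizes = sorted({s for p in patterns for s in p.sizes})
    if ladder is None:
        hi = max(all_sizes, default=375)
        top = ((hi + 24) // 25) * 25
        ladder = list(range(top, 49, -25))
    rows = sorted(set(all_sizes) | set(ladder), reverse=True)

    labels = list(lane_labels or [str(i + 1) for i in range(len(patterns))])
    width = max([len(mark), *(len(l) for l in labels)] or [2]) + 2
    header = f"{'bp':>5} {'M':^{width}}" + "".join(f"{l:^{width}}" for l in labels)
    lines = [header]
    for size in rows:
        cells = [f"{size:>5}", f"{'--' if size in ladder else '':^{width}}"]
        for p in patterns:
            cells.append(f"{mark if size in p.sizes else '':^{width}}")
        lines.append(" ".join([cells[0], *cells[1:]]).rstrip())
    return "\n".join(lines)
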