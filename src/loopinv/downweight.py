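"""Single-event down-weighting of called inversions.

A multi-column loop inversion is one molecular event; leaving every column
in the matrix lets tree inference count it as many independent
substitutions.  Down-weighting keeps exactly one (arbitrarily chosen)
column per inversion segment and excludes the rest, alongside any
poor-alignment exclusions, written as a MrBayes-compatible NEXUS command
block.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

from .hairpin import InversionEvent
from .msa import Msa, format_nexus
from .ranges import CoordRange, RangeSet, parse_range_list


class DownweightError(ValueError):
    pass


@dataclass
class ExclusionPlan:
    """Columns to exclude, split by provenance, plus the column kept to
    represent each inversion event."""

    poor_alignment: RangeSet = field(
        default_factory=lambda: RangeSet([], provenance="poor_alignment"))
    inversion_downweight: RangeSet = field(
        default_factory=lambda: RangeSet([], provenance="inversion_downweight"))
    kept_representative: dict[str, int] = field(default_factory=dict)

    def masks(self) -> list[RangeSet]:
        return [m for m in (self.poor_alignment, self.inversion_downweight) if m]

    def combined(self) -> RangeSet:
        return self.poor_alignment.union(self.inversion_downweight,
                                         provenance="user")


def build_downweight_mask(events: list[InversionEvent],
                          keep_policy: str = "first",
                          poor_alignment: RangeSet | None = None) -> ExclusionPlan:
    """Exclude all but one column of each event segment.

    ``keep_policy`` selects the retained column (first, last or middle of
    the segment).  When a segment intersects a poor-alignment range, the
    poor-alignment exclusion wins and the event is excluded entirely (its
    representative is recorded as absent).
    """
    if keep_policy not in ("first", "last", "middle"):
        raise DownweightError(f"unknown keep_policy {keep_policy!r}")
    for i, a in enumerate(events):
        for b in events[i + 1:]:
            if a.segment.overlaps(b.segment):
                raise DownweightError(
                    f"overlapping events {a.event_id} and {b.event_id}")
    poor = poor_alignment or RangeSet([], provenance="poor_alignment")
    ranges: list[CoordRange] = []
    kept: dict[str, int] = {}
    for ev in events:
        cols = list(ev.segment_columns)
        if any(r.overlaps(ev.segment) for r in poor):
            ranges.extend(CoordRange(c, c) for c in cols)
            continue
        if keep_policy == "first":
            keep = cols[0]
        elif keep_policy == "last":
            keep = cols[-1]
        else:
            keep = cols[len(cols) // 2]
        kept[ev.event_id] = keep
        ranges.extend(CoordRange(c, c) for c in cols if c != keep)
    return ExclusionPlan(
        poor_alignment=poor,
        inversion_downweight=RangeSet(ranges, provenance="inversion_downweight"),
        kept_representative=kept)


def write_mrbayes_exclude(msa: Msa, plan: ExclusionPlan, path: str | Path) -> None:
    """Write a NEXUS file with the alignment and a MrBayes command block
    excluding the planned columns ("exclude 3-5 9;" style, singletons
    rendered bare).  Byte-stable for identical inputs."""
    combined = plan.combined()
    combined.check_bounds(msa.length)
    if combined:
        block = ("begin mrbayes;\n"
                 f"    exclude {combined.format_nexus()};\n"
                 "end;\n")
    else:
        block = None
    Path(path).write_text(format_nexus(msa, command_block=block))


_EXCLUDE_RE = re.compile(r"exclude\s+([-0-9\s]+);", re.IGNORECASE)


def read_mrbayes_exclude(path: str | Path,
                         provenance: str = "user") -> RangeSet:
    """Parse the exclude statement back out of a NEXUS command block."""
    text = Path(path).read_text()
    m = _EXCLUDE_RE.search(text)
    if m is None:
        return RangeSet([], provenance=provenance)
    return parse_range_list(",".join(m.group(1).split()), provenance=provenance)
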