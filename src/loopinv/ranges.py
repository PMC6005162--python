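"""1-based inclusive column ranges and range sets.

Coordinates are externally 1-based inclusive, matching the "start-end" style
used for chloroplast alignment site lists (e.g. "54459-54465").  Internally
arithmetic is done 0-based half-open; conversion happens only at the edges.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator


class RangeError(ValueError):
    pass


@dataclass(frozen=True, order=True)
class CoordRange:
    """A 1-based inclusive column range [start, end]."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1:
            raise RangeError(f"range start must be >= 1, got {self.start}")
        if self.start > self.end:
            raise RangeError(f"range start {self.start} > end {self.end}")

    @property
    def size(self) -> int:
        return self.end - self.start + 1

    def columns(self) -> range:
        """0-based column indices covered by this range."""
        return range(self.start - 1, self.end)

    def contains(self, other: "CoordRange") -> bool:
        return self.start <= other.start and other.end <= self.end

    def overlaps(self, other: "CoordRange") -> bool:
        return self.start <= other.end and other.start <= self.end

    def __str__(self) -> str:
        return f"{self.start}-{self.end}" if self.start != self.end else str(self.start)


_TOKEN_RE = re.compile(r"^(\d+)(?:-(\d+))?$")


@dataclass
class RangeSet:
    """A normalized (sorted, merged) set of CoordRanges with a provenance tag.

    Provenance is one of ``poor_alignment``, ``inversion_downweight`` or
    ``user``.
    """

    ranges: list[CoordRange] = field(default_factory=list)
    provenance: str = "user"

    def __post_init__(self) -> None:
        self.ranges = _normalize(self.ranges)

    @property
    def size(self) -> int:
        return sum(r.size for r in self.ranges)

    def columns(self) -> Iterator[int]:
        """Yield 0-based column indices, ascending."""
        for r in self.ranges:
            yield from r.columns()

    def __iter__(self) -> Iterator[CoordRange]:
        return iter(self.ranges)

    def __len__(self) -> int:
        return len(self.ranges)

    def __bool__(self) -> bool:
        return bool(self.ranges)

    def union(self, other: "RangeSet", provenance: str | None = None) -> "RangeSet":
        return RangeSet(self.ranges + other.ranges,
                        provenance=provenance or self.provenance)

    def format(self) -> str:
        """Render in the "start-end, start-end" plain-text style."""
        return ", ".join(str(r) for r in self.ranges)

    def format_nexus(self) -> str:
        """Space-separated ranges for NEXUS exclude statements ("3-5 9")."""
        return " ".join(str(r) for r in self.ranges)

    def check_bounds(self, length: int) -> None:
        for r in self.ranges:
            if r.end > length:
                raise RangeError(
                    f"range {r} exceeds alignment length {length}")


def _normalize(ranges: Iterable[CoordRange]) -> list[CoordRange]:
    """Sort and merge overlapping or adjacent ranges."""
    out: list[CoordRange] = []
    for r in sorted(ranges):
        if out and r.start <= out[-1].end + 1:
            if r.end > out[-1].end:
                out[-1] = CoordRange(out[-1].start, r.end)
        else:
            out.append(r)
    return out


def parse_range_list(text: str, provenance: str = "user") -> RangeSet:
    """Parse a comma-separated list of "start-end" / "start" tokens.

    Semantics are 1-based inclusive; whitespace around tokens is ignored.
    """
    ranges: list[CoordRange] = []
    for token in text.split(","):
        token = token.strip()
        if not token:
            continue
        m = _TOKEN_RE.match(token)
        if m is None:
            raise RangeError(f"malformed range token {token!r}")
        start = int(m.group(1))
        end = int(m.group(2)) if m.group(2) is not None else start
        ranges.append(CoordRange(start, end))
    return RangeSet(ranges, provenance=provenance)
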