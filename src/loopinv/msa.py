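"""Gapped multiple sequence alignments: I/O, masking and summary statistics.

The :class:`Msa` is the universal substrate of the pipeline: an ordered set of
taxa, each with a gapped sequence over the IUPAC DNA alphabet.  FASTA and
NEXUS parsing is delegated to biopython; the NEXUS writer produces a plain
DATA block (optionally followed by a MrBayes command block, see
:mod:`loopinv.downweight`).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Nexus import Nexus

from .ranges import CoordRange, RangeSet

UNAMBIGUOUS = "ACGT"
AMBIGUITY = "RYSWKMBDHVN"
GAP = "-"
ALPHABET = frozenset(UNAMBIGUOUS + AMBIGUITY + GAP + "?")

_BASE_CODES = {c: i for i, c in enumerate(UNAMBIGUOUS)}


class MsaError(ValueError):
    pass


@dataclass
class AlignmentStats:
    """Composition and polymorphism summary of an alignment.

    ``composition`` is the frequency of each unambiguous base among non-gap,
    non-ambiguous characters.  A column is polymorphic when at least two
    distinct unambiguous bases occur in it (gaps and ambiguity codes are
    ignored for that count).
    """

    composition: dict[str, float]
    polymorphic_sites: int
    length: int
    ungapped_lengths: dict[str, int] = field(default_factory=dict)


class Msa:
    """An aligned set of gapped DNA sequences keyed by unique taxon names."""

    def __init__(self, rows: Mapping[str, str] | Iterable[tuple[str, str]]):
        items = list(rows.items()) if isinstance(rows, Mapping) else list(rows)
        self.taxa: list[str] = []
        self.rows: dict[str, str] = {}
        length: int | None = None
        for name, seq in items:
            if name in self.rows:
                raise MsaError(f"duplicate taxon name {name!r}")
            seq = seq.upper()
            if length is None:
                length = len(seq)
            elif len(seq) != length:
                raise MsaError(
                    f"unequal length: taxon {name!r} has {len(seq)} columns, "
                    f"expected {length}")
            bad = set(seq) - ALPHABET
            if bad:
                col = next(i for i, c in enumerate(seq) if c in bad)
                raise MsaError(
                    f"illegal character {seq[col]!r} in taxon {name!r} "
                    f"at column {col + 1}")
            self.taxa.append(name)
            self.rows[name] = seq
        self.length: int = length if length is not None else 0
        self._matrix: np.ndarray | None = None

    # -- container basics -------------------------------------------------
    def __len__(self) -> int:
        return len(self.taxa)

    def __getitem__(self, taxon: str) -> str:
        try:
            return self.rows[taxon]
        except KeyError:
            raise MsaError(f"unknown taxon {taxon!r}") from None

    def __eq__(self, other: object) -> bool:
        return (isinstance(other, Msa) and self.taxa == other.taxa
                and self.rows == other.rows)

    def matrix(self) -> np.ndarray:
        """Byte matrix (n_taxa x L) of the alignment, cached."""
        if self._matrix is None:
            if self.length:
                self._matrix = np.vstack([
                    np.frombuffer(self.rows[t].encode("ascii"), dtype=np.uint8)
                    for t in self.taxa])
            else:
                self._matrix = np.zeros((len(self.taxa), 0), dtype=np.uint8)
        return self._matrix

    def take_columns(self, columns: Sequence[int]) -> "Msa":
        """New Msa keeping the given 0-based columns, in the given order."""
        return Msa((t, "".join(self.rows[t][c] for c in columns))
                   for t in self.taxa)


@dataclass
class ExclusionReport:
    """Bookkeeping from :func:`apply_exclusions`.

    ``kept_to_original`` maps new 1-based columns to original 1-based
    columns.
    """

    removed: int
    kept_to_original: dict[int, int]


def read_alignment(path: str | Path, format: str = "fasta") -> Msa:
    """Read a gapped alignment from multi-FASTA or NEXUS.

    Taxon order follows the file; sequences are case-normalized to upper.
    """
    path = Path(path)
    if format == "fasta":
        records = [(r.id, str(r.seq)) for r in SeqIO.parse(str(path), "fasta")]
        if not records:
            raise MsaError(f"no sequences found in {path}")
        return Msa(records)
    if format == "nexus":
        nex = Nexus.Nexus(str(path))
        return Msa((str(name), str(nex.matrix[name])) for name in nex.taxlabels)
    raise MsaError(f"unknown alignment format {format!r}")


def read_nexus_charsets(path: str | Path) -> dict[str, RangeSet]:
    """Charsets from a NEXUS SETS block, as named 1-based RangeSets."""
    nex = Nexus.Nexus(str(Path(path)))
    out: dict[str, RangeSet] = {}
    for name, positions in (nex.charsets or {}).items():
        cols = sorted(int(p) + 1 for p in positions)  # biopython is 0-based
        ranges: list[CoordRange] = []
        for c in cols:
            if ranges and c == ranges[-1].end + 1:
                ranges[-1] = CoordRange(ranges[-1].start, c)
            else:
                ranges.append(CoordRange(c, c))
        out[str(name)] = RangeSet(ranges, provenance="user")
    return out


def write_alignment(msa: Msa, path: str | Path, format: str = "fasta") -> None:
    path = Path(path)
    if format == "fasta":
        with open(path, "w") as fh:
            for t in msa.taxa:
                fh.write(f">{t}\n{msa.rows[t]}\n")
    elif format == "nexus":
        with open(path, "w") as fh:
            fh.write(format_nexus(msa))
    else:
        raise MsaError(f"unknown alignment format {format!r}")


def format_nexus(msa: Msa, command_block: str | None = None) -> str:
    """Render a NEXUS DATA block, optionally followed by a command block."""
    buf = io.StringIO()
    buf.write("#NEXUS\n\nbegin data;\n")
    buf.write(f"    dimensions ntax={len(msa)} nchar={msa.length};\n")
    buf.write("    format datatype=dna missing=? gap=-;\n")
    buf.write("    matrix\n")
    width = max((len(t) for t in msa.taxa), default=0)
    for t in msa.taxa:
        safe = t.replace(" ", "_")
        buf.write(f"    {safe:<{width}}  {msa.rows[t]}\n")
    buf.write("    ;\nend;\n")
    if command_block:
        buf.write(command_block)
    return buf.getvalue()


def apply_exclusions(msa: Msa, masks: Sequence[RangeSet]) -> tuple[Msa, ExclusionReport]:
    """Remove all columns covered by the union of the masks.

    Returns the reduced alignment plus a report carrying the kept-column to
    original-column map (both 1-based).
    """
    for m in masks:
        m.check_bounds(msa.length)
    drop = np.zeros(msa.length, dtype=bool)
    for m in masks:
        for c in m.columns():
            drop[c] = True
    kept = np.nonzero(~drop)[0]
    out = msa.take_columns(kept.tolist())
    report = ExclusionReport(
        removed=int(drop.sum()),
        kept_to_original={i + 1: int(c) + 1 for i, c in enumerate(kept)})
    return out, report


def extract_region(msa: Msa, region: CoordRange) -> Msa:
    """Sub-alignment of the 1-based inclusive column range."""
    if region.end > msa.length:
        raise MsaError(f"region {region} exceeds alignment length {msa.length}")
    return Msa((t, msa.rows[t][region.start - 1:region.end]) for t in msa.taxa)


def alignment_stats(msa: Msa) -> AlignmentStats:
    """Base composition and polymorphic-site count.

    Composition is computed over unambiguous non-gap characters only; a
    polymorphic column contains >= 2 distinct unambiguous bases.  The
    ungapped length of each row is also reported, since gapped and ungapped
    alignment lengths are both quantities of interest.
    """
    if len(msa) == 0 or msa.length == 0:
        return AlignmentStats({}, 0, msa.length,
                              {t: 0 for t in msa.taxa})
    mat = msa.matrix()
    counts = {b: int((mat == ord(b)).sum()) for b in UNAMBIGUOUS}
    total = sum(counts.values())
    comp = {b: counts[b] / total for b in UNAMBIGUOUS} if total else {}
    poly = 0
    present = np.stack([(mat == ord(b)).any(axis=0) for b in UNAMBIGUOUS])
    poly = int((present.sum(axis=0) >= 2).sum())
    ungapped = {t: msa.length - msa.rows[t].count(GAP) for t in msa.taxa}
    return AlignmentStats(comp, poly, msa.length, ungapped)


def pairwise_identity(msa: Msa, a: str, b: str) -> tuple[float, int]:
    """Fraction of matching columns among columns where both rows carry an
    unambiguous base (gap or ambiguity in either row skips the column).

    Returns (identity, number of compared columns).
    """
    ra, rb = msa[a], msa[b]
    xa = np.frombuffer(ra.encode(), dtype=np.uint8)
    xb = np.frombuffer(rb.encode(), dtype=np.uint8)
    ok_a = np.isin(xa, [ord(c) for c in UNAMBIGUOUS])
    ok_b = np.isin(xb, [ord(c) for c in UNAMBIGUOUS])
    both = ok_a & ok_b
    compared = int(both.sum())
    if compared == 0:
        raise MsaError(f"no comparable sites between {a!r} and {b!r}")
    matches = int((xa[both] == xb[both]).sum())
    return matches / compared, compared
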