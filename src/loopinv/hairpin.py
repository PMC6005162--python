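"""Hairpin stem-loop detection and loop-inversion calling.

Chloroplast non-coding DNA is rich in short stem-loop (hairpin) structures:
two adjacent reverse-complementary segments (the stem) flanking an unpaired
loop.  The loop, or part of it, can be replaced by its reverse complement in
a single intra-molecular event.  Such loop inversions look like clusters of
substitutions in an alignment and can create spurious grouping signal, so
they are detected here and handed to :mod:`loopinv.downweight`.

An inversion is called for a taxon when reverse-complementing a contiguous
loop segment of its sequence brings it close to the majority (consensus)
form: the substitution count drops from ``d_before`` (>= ``min_before``)
to ``d_after`` (<= ``t_after``).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .msa import GAP, Msa, UNAMBIGUOUS
from .ranges import CoordRange

_COMPLEMENT = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
    "-": "-", "?": "?",
}
_COMP_TABLE = str.maketrans(_COMPLEMENT)
_LEGAL = frozenset(_COMPLEMENT)


class HairpinError(ValueError):
    pass


class OrientationError(HairpinError):
    """Raised when minority and majority orientations cannot be separated."""


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC codes; gap maps to gap)."""
    s = seq.upper()
    bad = set(s) - _LEGAL
    if bad:
        raise HairpinError(f"illegal character {bad.pop()!r} in sequence")
    return s.translate(_COMP_TABLE)[::-1]


def segment_distances(majority_seg: str, observed_seg: str) -> tuple[int, int]:
    """Substitutions before/after reverting the observed segment.

    ``d_before`` is the Hamming distance between the observed and majority
    segments; ``d_after`` the distance after reverse-complementing the
    observed segment.  Both strings must be ungapped and of equal length.
    """
    if len(majority_seg) != len(observed_seg):
        raise HairpinError(
            f"segment length mismatch: {len(majority_seg)} vs {len(observed_seg)}")
    maj = majority_seg.upper()
    obs = observed_seg.upper()
    d_before = sum(a != b for a, b in zip(obs, maj))
    d_after = sum(a != b for a, b in zip(revcomp(obs), maj))
    return d_before, d_after


@dataclass
class DetectionParams:
    """Tunable knobs of the detector.

    min_stem
        Minimum number of paired bases per stem (4 bp, the shortest stems in
        group II intron structural models).
    max_loop
        Longest unpaired loop considered, in nt.
    max_stem_search_span
        Longest stem5..stem3 window searched, in alignment columns.
    non_stem_allowance
        Number of unpaired ("subscript") bases tolerated inside a stem; the
        detector admits one only after ``min_stem`` perfect inner pairs.
    t_after
        Maximum residual substitutions after reverting for a taxon to count
        as carrying the inversion.
    min_before
        Minimum substitutions the reversion must explain
        (d_before - d_after) for a taxon to be called.
    majority_fraction
        Strict threshold defining the majority orientation.
    """

    min_stem: int = 4
    max_loop: int = 30
    max_stem_search_span: int = 120
    non_stem_allowance: int = 1
    t_after: int = 2
    min_before: int = 3
    majority_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.min_stem < 1:
            raise HairpinError("min_stem must be >= 1")
        if not (0 <= self.t_after < self.min_before):
            raise HairpinError("need 0 <= t_after < min_before")
        if not (0 < self.majority_fraction < 1):
            raise HairpinError("majority_fraction must be in (0,1)")


@dataclass(frozen=True)
class StemLoop:
    """A located hairpin: 5' stem, loop and 3' stem, in 1-based alignment
    columns.  ``non_stem_positions`` lists stem columns not participating in
    pairing (bulges)."""

    stem5: CoordRange
    loop: CoordRange
    stem3: CoordRange
    non_stem_positions: tuple[int, ...] = ()
    pairing_length: int = 0

    @property
    def span(self) -> CoordRange:
        return CoordRange(self.stem5.start, self.stem3.end)

    def key(self) -> tuple[int, int, int, int]:
        return (self.stem5.start, self.loop.start, self.loop.end, self.stem3.end)


@dataclass
class InversionEvent:
    """A called loop inversion (one per stem-loop).

    ``segment`` is the inverted sub-segment in 1-based alignment columns;
    ``segment_columns`` the exact scored columns (excluding consensus-gap
    columns).  ``per_taxon`` maps each minority taxon to its
    (d_before, d_after) pair; ``not_assessable`` lists taxa with gaps in the
    scored region.
    """

    event_id: str
    stemloop: StemLoop
    segment: CoordRange
    majority_form: str
    minority_form: str
    minority_taxa: frozenset[str]
    d_before: int
    d_after: int
    per_taxon: dict[str, tuple[int, int]] = field(default_factory=dict)
    not_assessable: tuple[str, ...] = ()
    segment_columns: tuple[int, ...] = ()  # 1-based alignment columns
    residual: int = 0  # unexplained mismatches in the stem-loop span

    def __post_init__(self) -> None:
        if self.d_after > self.d_before:
            raise HairpinError("event invariant violated: d_after > d_before")


def majority_consensus(msa: Msa) -> str:
    """Strict majority consensus: per column the most frequent unambiguous
    base among non-gap characters, ties broken alphabetically; all-gap (or
    all-ambiguous) columns yield a gap."""
    if len(msa) == 0:
        raise HairpinError("empty alignment")
    mat = msa.matrix()
    counts = np.stack([(mat == ord(b)).sum(axis=0) for b in UNAMBIGUOUS])
    best = counts.argmax(axis=0)          # argmax is first max -> A<C<G<T ties
    any_base = counts.sum(axis=0) > 0
    out = np.where(any_base,
                   np.array([ord(b) for b in UNAMBIGUOUS])[best],
                   ord(GAP)).astype(np.uint8)
    return out.tobytes().decode("ascii")


# ---------------------------------------------------------------------------
# stem-loop search
# ---------------------------------------------------------------------------

def _encode(seq: str) -> np.ndarray:
    codes = np.full(256, 100, dtype=np.int16)
    for i, b in enumerate(UNAMBIGUOUS):
        codes[ord(b)] = i
    return codes[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def find_stem_loops(seq: str, params: DetectionParams | None = None,
                    column_map: np.ndarray | None = None) -> list[StemLoop]:
    """Scan an ungapped sequence for maximal stem-loops.

    Seed-and-extend over loop centers: for every candidate loop (length 1 to
    ``max_loop``) the innermost flanking pair is tested, then the stem is
    extended outward while bases are perfectly Watson-Crick complementary,
    tolerating up to ``non_stem_allowance`` unpaired bases once at least
    ``min_stem`` inner pairs are in place.  A candidate is suppressed when
    its stem could be extended inward (a tighter stem-loop covers it).

    ``column_map`` maps 0-based sequence positions to 1-based alignment
    columns (identity when omitted).  Results are ranked by stem length,
    then total span.
    """
    params = params or DetectionParams()
    n = len(seq)
    if n == 0:
        return []
    code = _encode(seq.upper())
    if column_map is None:
        column_map = np.arange(1, n + 1)

    found: list[StemLoop] = []
    ms = params.min_stem
    for g in range(1, params.max_loop + 1):
        lmax = n - g - ms - 1
        if lmax < ms - 1:
            continue
        ls = np.arange(ms - 1, lmax + 1)
        js = ls + g + 1
        # min_stem straight pairs, innermost first
        mask = np.ones(len(ls), dtype=bool)
        for k in range(ms):
            mask &= code[ls - k] + code[js + k] == 3
        # inward maximality: a pair just inside the loop means a tighter stem
        if g >= 3:
            mask &= ~(code[ls + 1] + code[js - 1] == 3)
        for idx in np.nonzero(mask)[0]:
            l, j = int(ls[idx]), int(js[idx])
            sl = _extend(code, l, j, g, params, column_map)
            if sl is not None:
                found.append(sl)
    # dedupe identical structures, rank by stem length then span
    uniq: dict[tuple, StemLoop] = {}
    for sl in found:
        uniq.setdefault(sl.key(), sl)
    return sorted(uniq.values(),
                  key=lambda s: (-s.pairing_length, s.span.size, s.span.start))


def _extend(code: np.ndarray, l: int, j: int, g: int,
            params: DetectionParams, column_map: np.ndarray) -> StemLoop | None:
    """Extend a seeded stem outward from innermost pair (l, j)."""
    n = len(code)
    ms = params.min_stem
    i0, j0 = l - ms + 1, j + ms - 1          # outermost paired so far
    # straight extension
    while pair_ok_scalar(code, i0 - 1, j0 + 1, n):
        i0 -= 1
        j0 += 1
    bulge: int | None = None
    if params.non_stem_allowance >= 1:
        # try one unpaired base on either side, keep the better continuation
        best = (0, None, i0, j0)
        for di, dj in ((2, 1), (1, 2)):
            i1, j1 = i0 - di, j0 + dj
            k = 0
            while pair_ok_scalar(code, i1, j1, n):
                k += 1
                i1 -= 1
                j1 += 1
            if k > best[0]:
                skipped = i0 - 1 if di == 2 else j0 + 1
                best = (k, skipped, i1 + 1, j1 - 1)
        if best[1] is not None:
            bulge, i0, j0 = best[1], best[2], best[3]
    span = j0 - i0 + 1
    if span > params.max_stem_search_span:
        return None
    pairing = (l - i0 + 1) - (1 if bulge is not None and bulge < l else 0)
    cm = column_map
    non_stem = (int(cm[bulge]),) if bulge is not None else ()
    return StemLoop(
        stem5=CoordRange(int(cm[i0]), int(cm[l])),
        loop=CoordRange(int(cm[l + 1]), int(cm[j - 1])),
        stem3=CoordRange(int(cm[j]), int(cm[j0])),
        non_stem_positions=non_stem,
        pairing_length=pairing,
    )


def pair_ok_scalar(code: np.ndarray, i: int, j: int, n: int) -> bool:
    return 0 <= i and j < n and int(code[i]) + int(code[j]) == 3


def scan_alignment(msa: Msa, params: DetectionParams | None = None) -> list[StemLoop]:
    """Find stem-loops on the consensus and on every distinct row.

    Row scanning matters when only the inverted (minority) sequences form a
    stem; coordinates are mapped back to alignment columns through each
    row's gap structure.  Duplicate structures are reported once.
    """
    params = params or DetectionParams()
    cons = majority_consensus(msa)
    uniq: dict[tuple, StemLoop] = {}

    def scan(seq: str) -> None:
        keep = [i for i, c in enumerate(seq) if c != GAP]
        ungapped = "".join(seq[i] for i in keep)
        cmap = np.array([i + 1 for i in keep], dtype=np.int64)
        for sl in find_stem_loops(ungapped, params, cmap):
            uniq.setdefault(sl.key(), sl)

    scan(cons)
    for row in set(msa.rows.values()):
        scan(row)
    return sorted(uniq.values(),
                  key=lambda s: (-s.pairing_length, s.span.size, s.span.start))


# ---------------------------------------------------------------------------
# inversion calling
# ---------------------------------------------------------------------------

def _scoring_columns(cons: str, rng: CoordRange) -> list[int]:
    """1-based alignment columns of the range where the consensus has a base."""
    return [c for c in range(rng.start, rng.end + 1) if cons[c - 1] != GAP]


def call_inversions(msa: Msa, stemloops: list[StemLoop],
                    params: DetectionParams | None = None) -> list[InversionEvent]:
    """Call one loop-inversion event per qualifying stem-loop.

    For each stem-loop every contiguous sub-segment of the loop (plus the
    whole stem-loop region, for the case where only inverted sequences form
    the stem) is scored per taxon with :func:`segment_distances` against the
    consensus.  A taxon carries the inversion for a segment when
    ``d_after < d_before``, ``d_after <= t_after`` and
    ``d_before >= min_before``.  Among candidate segments the one minimizing
    the total residual (``d_after`` plus remaining loop mismatches outside
    the segment) is chosen, ties broken by larger total ``d_before`` and
    then by shorter segment — so a whole-loop inversion is preferred over a
    sub-segment that leaves unexplained mismatches next to it.

    Events from overlapping stem-loop candidates at the same locus are
    deduplicated, keeping the one with the longest stem.  Event ids are
    letters assigned in alignment order.
    """
    params = params or DetectionParams()
    if len(msa) == 0:
        return []
    cons = majority_consensus(msa)
    raw: list[InversionEvent] = []
    for sl in stemloops:
        ev = _call_one(msa, cons, sl, params)
        if ev is not None:
            raw.append(ev)
    # dedupe overlapping segments: the explanation leaving the fewest
    # unexplained substitutions in its stem-loop span wins, then the longest
    # stem, then the largest explained signal
    raw.sort(key=lambda e: (
        e.residual,
        -e.stemloop.pairing_length,
        -sum(d[0] for d in e.per_taxon.values()),
        e.segment.start))
    kept: list[InversionEvent] = []
    for ev in raw:
        if any(ev.segment.overlaps(k.segment) for k in kept):
            continue
        kept.append(ev)
    kept.sort(key=lambda e: e.segment.start)
    letters = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    out = []
    for i, ev in enumerate(kept):
        ev.event_id = letters[i % 26] * (i // 26 + 1)
        out.append(ev)
    return out


def _call_one(msa: Msa, cons: str, sl: StemLoop,
              params: DetectionParams) -> InversionEvent | None:
    loop_cols = _scoring_columns(cons, sl.loop)
    if not loop_cols:
        return None
    maj_loop = "".join(cons[c - 1] for c in loop_cols)

    # candidate taxa must carry enough mismatches somewhere in the loop
    rows: dict[str, str] = {}
    mismatch: dict[str, int] = {}
    assessable: list[str] = []
    gapped: list[str] = []
    for t in msa.taxa:
        obs = "".join(msa.rows[t][c - 1] for c in loop_cols)
        if GAP in obs:
            gapped.append(t)
            continue
        assessable.append(t)
        rows[t] = obs
        mismatch[t] = sum(a != b for a, b in zip(obs, maj_loop))
    candidates = [t for t in assessable if mismatch[t] >= params.min_before]
    if not candidates:
        return None

    span_cols = _scoring_columns(cons, sl.span)
    maj_span = "".join(cons[c - 1] for c in span_cols)
    # per-candidate mismatch columns across the whole stem-loop span; the
    # residual of a segment choice is d_after plus the mismatches it leaves
    # unexplained anywhere in the span
    span_mismatch: dict[str, frozenset[int]] = {}
    for t in candidates:
        mm = set()
        for c, mb in zip(span_cols, maj_span):
            rb = msa.rows[t][c - 1]
            if rb != GAP and rb != mb:
                mm.add(c)
        span_mismatch[t] = frozenset(mm)

    m = len(loop_cols)
    segments: list[tuple[list[int], bool]] = []
    for length in range(max(1, params.min_before), m + 1):
        for start in range(0, m - length + 1):
            segments.append(([loop_cols[i] for i in range(start, start + length)],
                             False))
    segments.append((span_cols, True))

    best = None
    for cols, is_region in segments:
        colset = set(cols)
        maj_seg = "".join(cons[c - 1] for c in cols)
        scored: dict[str, tuple[int, int]] = {}
        residual_sum = before_sum = 0
        for t in candidates:
            obs_seg = "".join(msa.rows[t][c - 1] for c in cols)
            if GAP in obs_seg:
                continue
            d_before, d_after = segment_distances(maj_seg, obs_seg)
            # reverting must explain at least min_before substitutions;
            # a marginal fit (e.g. 3 before, 2 after) is not evidence of
            # an inversion
            if not (d_after <= params.t_after
                    and d_before - d_after >= params.min_before):
                continue
            outside = len(span_mismatch[t] - colset)
            scored[t] = (d_before, d_after)
            residual_sum += d_after + outside
            before_sum += d_before
        if not scored:
            continue
        key = (residual_sum, -before_sum, len(cols), cols[0])
        if best is None or key < best[0]:
            best = (key, cols, maj_seg, scored)
    if best is None:
        return None

    (residual_sum, _, _, _), cols, maj_seg, scored = best
    n_scored = len(assessable)
    if 2 * len(scored) >= n_scored:
        raise OrientationError(
            f"inversion at {sl.span} carried by {len(scored)} of {n_scored} "
            "assessable taxa; majority orientation undefined — set "
            "majority_fraction or orient explicitly")
    minority_counts = Counter(
        "".join(msa.rows[t][c - 1] for c in cols) for t in scored)
    minority_form = min(minority_counts,
                        key=lambda s: (-minority_counts[s], s))
    d_before, d_after = segment_distances(maj_seg, minority_form)
    return InversionEvent(
        event_id="?",
        stemloop=sl,
        segment=CoordRange(cols[0], cols[-1]),
        majority_form=maj_seg,
        minority_form=minority_form,
        minority_taxa=frozenset(scored),
        d_before=d_before,
        d_after=d_after,
        per_taxon=dict(scored),
        not_assessable=tuple(gapped),
        segment_columns=tuple(cols),
        residual=residual_sum,
    )


def revert_inversions(msa: Msa, events: list[InversionEvent]) -> Msa:
    """Return a new alignment with each minority segment reverse-complemented.

    Events must not overlap (checked); only minority rows are touched.
    """
    for i, a in enumerate(events):
        for b in events[i + 1:]:
            if a.segment.overlaps(b.segment):
                raise HairpinError(
                    f"overlapping events {a.event_id} and {b.event_id}")
    rows = {t: list(msa.rows[t]) for t in msa.taxa}
    for ev in events:
        for t in ev.minority_taxa:
            obs = "".join(rows[t][c - 1] for c in ev.segment_columns)
            rc = revcomp(obs)
            for c, ch in zip(ev.segment_columns, rc):
                rows[t][c - 1] = ch
    return Msa((t, "".join(rows[t])) for t in msa.taxa)


def events_table(events: list[InversionEvent]):
    """Events as a pandas DataFrame mirroring the standard report columns."""
    import pandas as pd

    rec = []
    for ev in events:
        rec.append({
            "loop": ev.event_id,
            "alignment_coordinates": f"{ev.stemloop.span.start}-{ev.stemloop.span.end}",
            "segment": f"{ev.segment.start}-{ev.segment.end}",
            "sequence_majority": ev.majority_form,
            "sequence_minority": ev.minority_form,
            "substitutions_before_after": f"{ev.d_before}/{ev.d_after}",
            "sequences_minority": ",".join(sorted(ev.minority_taxa)),
        })
    return pd.DataFrame.from_records(
        rec, columns=["loop", "alignment_coordinates", "segment",
                      "sequence_majority", "sequence_minority",
                      "substitutions_before_after", "sequences_minority"])
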