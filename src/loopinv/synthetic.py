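"""Synthetic alignments with the structure the pipeline assumes.

Two generators live here:

* :func:`simulate_alignment` — sequences evolved along a tree under JC or
  HKY, with planted hairpin scaffolds, minority-lineage loop inversions
  (optionally homoplasious), and poorly aligned noise windows; a
  :class:`ScenarioManifest` records the ground truth so detector recall and
  parsimony recovery can be scored.
* :func:`table2_fixture` — a 41-taxon alignment embedding the eight printed
  stem-loop regions of the study's inversion table, each minority list
  carrying its inverted form, in a shared neutral background.

Planted stem-loop columns are invariant by default
(``stemloop_rate = 0``): hairpin stems are structurally constrained, and a
zero rate keeps planted inversions exactly revertible (``d_after = 0``),
the configuration the sensitivity tests assume.  Raising ``stemloop_rate``
adds post-inversion substitutions, which are logged per inversion.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import dendropy
import numpy as np
from scipy.linalg import expm

from .hairpin import segment_distances
from .msa import Msa
from .ranges import CoordRange
from .treekit import parse_newick

_BASES = "ACGT"


class SimulationError(ValueError):
    pass


@dataclass
class PlantedStemLoop:
    """A hairpin scaffold written into the root sequence.

    ``position`` is the 1-based column of the first stem base; the scaffold
    occupies 2*stem_length + len(loop_seq) columns.
    """

    position: int
    stem_length: int
    loop_seq: str

    @property
    def span(self) -> CoordRange:
        return CoordRange(self.position,
                          self.position + 2 * self.stem_length + len(self.loop_seq) - 1)

    @property
    def loop_range(self) -> CoordRange:
        return CoordRange(self.position + self.stem_length,
                          self.position + self.stem_length + len(self.loop_seq) - 1)


@dataclass
class PlantedInversion:
    """A single-event reverse complement of a loop (sub)segment applied on
    one or more branches, each identified by the leaf set of its clade."""

    stemloop_index: int
    branches: list[list[str]]
    segment_offset: int = 0       # 0-based offset within the loop
    segment_length: int | None = None  # None -> whole loop


@dataclass
class ScenarioManifest:
    tree: str
    L: int
    seed: int
    model: str = "JC"
    kappa: float = 2.0
    base_freqs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    stemloop_rate: float = 0.0
    planted_stemloops: list[PlantedStemLoop] = field(default_factory=list)
    planted_inversions: list[PlantedInversion] = field(default_factory=list)
    noise_windows: list[tuple[int, int]] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1)

    @classmethod
    def from_json(cls, text: str) -> "ScenarioManifest":
        d = json.loads(text)
        d["planted_stemloops"] = [PlantedStemLoop(**s)
                                  for s in d.get("planted_stemloops", [])]
        d["planted_inversions"] = [PlantedInversion(**s)
                                   for s in d.get("planted_inversions", [])]
        d["base_freqs"] = tuple(d.get("base_freqs", (0.25,) * 4))
        d["noise_windows"] = [tuple(w) for w in d.get("noise_windows", [])]
        return cls(**d)

    def validate(self) -> None:
        spans = [sl.span for sl in self.planted_stemloops]
        spans += [CoordRange(a, b) for a, b in self.noise_windows]
        for s in spans:
            if s.end > self.L:
                raise SimulationError(f"planted feature {s} exceeds L={self.L}")
        for i, a in enumerate(spans):
            for b in spans[i + 1:]:
                if a.overlaps(b):
                    raise SimulationError(
                        f"planted features overlap: {a} and {b}")
        for inv in self.planted_inversions:
            if not (0 <= inv.stemloop_index < len(self.planted_stemloops)):
                raise SimulationError("inversion references unknown stem-loop")


@dataclass
class SimulationResult:
    msa: Msa
    manifest: ScenarioManifest
    inversion_taxa: list[frozenset[str]] = field(default_factory=list)
    post_inversion_mutations: list[int] = field(default_factory=list)


def _hky_rate_matrix(kappa: float, freqs: np.ndarray) -> np.ndarray:
    Q = np.zeros((4, 4))
    transitions = {(0, 2), (2, 0), (1, 3), (3, 1)}  # A<->G, C<->T
    for i in range(4):
        for j in range(4):
            if i == j:
                continue
            Q[i, j] = freqs[j] * (kappa if (i, j) in transitions else 1.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    scale = -(freqs * np.diag(Q)).sum()
    return Q / scale


def simulate_alignment(manifest: ScenarioManifest) -> SimulationResult:
    """Evolve sequences along the manifest's tree, seeded and reproducible.

    Sites evolve independently; planted scaffolds sit in the root sequence
    and evolve at ``stemloop_rate`` (0 = invariant); each planted inversion
    reverse-complements its segment once on each stated branch, inherited
    by all descendants; noise windows are overwritten with per-taxon
    independent sequence.
    """
    manifest.validate()
    rng = np.random.default_rng(np.random.SeedSequence([manifest.seed, 0xD1CE]))
    tree = parse_newick(manifest.tree, "branch_lengths")
    L = manifest.L
    freqs = np.asarray(manifest.base_freqs, dtype=float)
    if abs(freqs.sum() - 1) > 1e-9:
        raise SimulationError("base frequencies must sum to 1")

    rates = np.ones(L)
    for sl in manifest.planted_stemloops:
        rates[sl.span.start - 1:sl.span.end] = manifest.stemloop_rate

    root = rng.choice(4, size=L, p=freqs)
    for sl in manifest.planted_stemloops:
        stem5 = rng.choice(4, size=sl.stem_length, p=freqs)
        loop = np.array([_BASES.index(b) for b in sl.loop_seq.upper()])
        stem3 = np.array([3 - b for b in stem5[::-1]])
        root[sl.span.start - 1:sl.span.end] = np.concatenate([stem5, loop, stem3])

    # segment columns (0-based) per planted inversion
    segments: list[np.ndarray] = []
    for inv in manifest.planted_inversions:
        sl = manifest.planted_stemloops[inv.stemloop_index]
        lr = sl.loop_range
        length = inv.segment_length if inv.segment_length is not None \
            else lr.size - inv.segment_offset
        start = lr.start - 1 + inv.segment_offset
        segments.append(np.arange(start, start + length))

    clade_of = {}
    for node in tree.postorder_node_iter():
        clade_of[node] = frozenset(l.taxon.label for l in node.leaf_iter())
    inv_branches = []
    for inv in manifest.planted_inversions:
        inv_branches.append([frozenset(b) for b in inv.branches])

    Q = _hky_rate_matrix(manifest.kappa, freqs) if manifest.model == "HKY" else None
    if manifest.model not in ("JC", "HKY"):
        raise SimulationError(f"unknown model {manifest.model!r}")

    rate_values = np.unique(rates)
    site_groups = {r: np.nonzero(rates == r)[0] for r in rate_values}

    seqs: dict[dendropy.Node, np.ndarray] = {tree.seed_node: root}
    inverted_state: dict[dendropy.Node, list[bool]] = {
        tree.seed_node: [False] * len(segments)}
    post_mut = [0] * len(segments)
    inv_taxa: list[set[str]] = [set() for _ in segments]

    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        parent = seqs[node.parent_node]
        t = node.edge.length or 0.0
        child = parent.copy()
        for r, sites in site_groups.items():
            if r <= 0 or t <= 0 or len(sites) == 0:
                continue
            if manifest.model == "JC":
                p = 0.75 * (1.0 - np.exp(-4.0 * t * r / 3.0))
                hit = sites[rng.random(len(sites)) < p]
                child[hit] = (child[hit] + rng.integers(1, 4, size=len(hit))) % 4
            else:
                P = expm(Q * t * r)
                for s in range(4):
                    sel = sites[parent[sites] == s]
                    if len(sel):
                        child[sel] = rng.choice(4, size=len(sel), p=P[s])
        flags = list(inverted_state[node.parent_node])
        for k, seg in enumerate(segments):
            if flags[k]:
                post_mut[k] += int((child[seg] != parent[seg]).sum())
            if clade_of[node] in inv_branches[k]:
                child[seg] = (3 - child[seg])[::-1]
                flags[k] = True
        if node.is_leaf():
            for k, f in enumerate(flags):
                if f:
                    inv_taxa[k].add(node.taxon.label)
        seqs[node] = child
        inverted_state[node] = flags

    rows = []
    for leaf in tree.leaf_node_iter():
        arr = seqs[leaf].copy()
        for a, b in manifest.noise_windows:
            arr[a - 1:b] = rng.choice(4, size=b - a + 1, p=freqs)
        rows.append((leaf.taxon.label, "".join(_BASES[i] for i in arr)))
    return SimulationResult(
        msa=Msa(rows), manifest=manifest,
        inversion_taxa=[frozenset(s) for s in inv_taxa],
        post_inversion_mutations=post_mut)


# ---------------------------------------------------------------------------
# study-shaped scenarios
# ---------------------------------------------------------------------------

def random_tree(n_taxa: int, seed: int, depth: float = 0.008,
                labels: list[str] | None = None) -> str:
    """Random bifurcating ultrametric-ish tree by repeated joins; expected
    root-to-tip path about ``depth`` substitutions/site (so pairwise
    divergence is in the 1-2% range at the default)."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x7EE]))
    labels = labels or [f"t{i + 1}" for i in range(n_taxa)]
    # a root-to-tip path crosses about log2(n)+1 edges in a balanced join
    # tree, so scale per-edge lengths to hit the requested depth
    mean_bl = depth / (np.log2(max(n_taxa, 2)) + 1.0)
    nodes = [f"{lab}:{rng.exponential(mean_bl):.6f}" for lab in labels]
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[i], nodes[j]
        merged = f"({a},{b}):{rng.exponential(mean_bl):.6f}"
        nodes = [x for k, x in enumerate(nodes) if k not in (i, j)] + [merged]
    return f"({nodes[0]},{nodes[1]});"


def study_shape_tree(seed: int, n_ingroup: int = 40,
                     outgroup: str = "outgroup") -> str:
    """Ingroup of ``n_ingroup`` taxa at ~1-2% crown divergence, including a
    short-branch crown clade (the rapid-radiation analogue), plus a more
    distant outgroup."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x0461]))
    n_short = n_ingroup // 2
    short = random_tree(n_short, int(rng.integers(2 ** 31)), depth=0.002,
                        labels=[f"neo{i + 1}" for i in range(n_short)])[:-1]
    grade = random_tree(n_ingroup - n_short, int(rng.integers(2 ** 31)),
                        depth=0.006,
                        labels=[f"afr{i + 1}" for i in range(n_ingroup - n_short)])[:-1]
    return f"(({short}:0.004,{grade}:0.002):0.02,{outgroup}:0.02);"


def inversion_free_scenario(seed: int, n_taxa: int = 40, L: int = 2000,
                            depth: float = 0.008) -> ScenarioManifest:
    """A divergence-only scenario for detector specificity runs."""
    return ScenarioManifest(tree=random_tree(n_taxa, seed, depth=depth),
                            L=L, seed=seed)


def make_benchmark(grid: list[ScenarioManifest], outdir: str | Path) -> list[Path]:
    """Write FASTA + manifest JSON per scenario; deterministic per seed."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for i, manifest in enumerate(grid):
        res = simulate_alignment(manifest)
        stem = outdir / f"scenario_{i:03d}_seed{manifest.seed}"
        fasta = stem.with_suffix(".fasta")
        with open(fasta, "w") as fh:
            for t in res.msa.taxa:
                fh.write(f">{t}\n{res.msa.rows[t]}\n")
        meta = stem.with_suffix(".json")
        meta.write_text(manifest.to_json())
        written += [fasta, meta]
    return written


# ---------------------------------------------------------------------------
# the printed inversion-table fixture
# ---------------------------------------------------------------------------

#: The 40 study samples plus the outgroup.
FIXTURE_TAXA: tuple[str, ...] = tuple(
    ["bicolor"]
    + [f"concreta{i}" for i in range(1, 10)]
    + ["dolichophylla"]
    + [f"estrelensis{i}" for i in range(1, 15)]
    + ["eurychila", "foliosa1", "foliosa2", "golungensis",
       "humbertii1", "humbertii2", "melanantha", "modesta",
       "odorata1", "odorata2", "oreocharis1", "steudneri",
       "tesselata1", "tesselata2", "tsinjoarivensis2", "Phalaenopsis"])

_ESTRELENSIS_CLADE = tuple(f"estrelensis{i}" for i in range(1, 14))


@dataclass(frozen=True)
class Table2Row:
    letter: str
    majority_region: str      # stem5 + loop + stem3, ungapped
    minority_region: str      # same span with the minority (inverted) form
    loop_offset: int          # 0-based offset of the loop within the region
    loop_length: int
    segment_offset: int       # 0-based offset of the inverted segment in the loop
    segment_length: int
    minority_taxa: tuple[str, ...]
    printed_pair: tuple[int, int]
    discrepancy: bool = False

    @property
    def majority_segment(self) -> str:
        a = self.loop_offset + self.segment_offset
        return self.majority_region[a:a + self.segment_length]

    @property
    def minority_segment(self) -> str:
        a = self.loop_offset + self.segment_offset
        return self.minority_region[a:a + self.segment_length]

    @property
    def computed_pair(self) -> tuple[int, int]:
        return segment_distances(self.majority_segment, self.minority_segment)


TABLE2_ROWS: tuple[Table2Row, ...] = (
    Table2Row("A", "TCTATCTA" "GAA" "TAGATAGA",
              "TCTATCTA" "TTC" "TAGATAGA",
              8, 3, 0, 3,
              ("bicolor", "concreta7", "concreta9", "tesselata1",
               "melanantha", "Phalaenopsis"), (3, 0)),
    Table2Row("B", "GGCCCAATCTTTC" "TTTTTTTGAGGA" "AAAGATTGGGCC",
              "GGCCCAATCTTTC" "TCCTCAAAAAAA" "AAAGATTGGGCC",
              13, 12, 0, 12,
              ("humbertii2", "oreocharis1", "tsinjoarivensis2", "melanantha"),
              (8, 0)),
    Table2Row("C", "AGTAAGAACTCAGCG" "GGGTAAGGCCT" "CGCTGAGTTCTTACT",
              "AGTAAGAACTCAGCG" "AGGCCTTACCC" "CGCTGAGTTCTTACT",
              15, 11, 0, 11,
              ("eurychila",), (7, 0)),
    Table2Row("D", "ATTGAAGTAATGAGCCC" "CAAGATGAATATGA" "GGGCTCATTACTTCAAT",
              "ATTGAAGTAATGAGCCC" "TCATATTCATCTTG" "GGGCTCATTACTTCAAT",
              17, 14, 0, 14,
              ("humbertii1", "steudneri"), (8, 0)),
    Table2Row("E", "GTATCTAAGGAAGATCC" "AAAGG" "GGATCTTCCTTAGATAC",
              "GTATCTAAGGAAGATCC" "CTTCT" "GGATCTTCCTTAGATAC",
              17, 5, 0, 5,
              ("estrelensis12", "estrelensis13", "estrelensis14", "eurychila",
               "concreta7", "concreta8", "golungensis", "oreocharis1",
               "melanantha", "humbertii1", "Phalaenopsis"), (5, 2)),
    # Only the minority sequences form the stem here, and the printed
    # before-count (6) is not recovered from the printed strings (we count
    # 5 over the loop) — flagged as a discrepancy.
    Table2Row("F", "AACGTCCAGTG" "CCAAAGT" "CACTGAATGGG",
              "CCCATTCAGTG" "ACTTTGG" "CACTGAATGGG",
              11, 7, 0, 7,
              _ESTRELENSIS_CLADE, (6, 0), discrepancy=True),
    Table2Row("G", "ATTCAATTCTTC" "ATTCTTTCAA" "GAAGAATGAAT",
              "ATTCAATTCTTC" "ATGAAAGAAA" "GAAGAATGAAT",
              12, 10, 2, 6,
              ("foliosa1", "foliosa2", "odorata1", "odorata2", "Phalaenopsis"),
              (6, 0)),
    Table2Row("H", "ATTCATTCTTCAT" "GAAAGA" "ATGAAGAATTGAAT",
              "ATTCATTCTTCAT" "TCTTTC" "ATGAAGAATTGAAT",
              13, 6, 0, 6,
              ("foliosa1", "foliosa2", "odorata1", "odorata2", "Phalaenopsis"),
              (6, 0)),
)

_SPACER = 40  # conserved columns between embedded regions; > max_loop so no
              # stem-loop can bridge two regions


@dataclass
class FixtureExpectation:
    letter: str
    region: CoordRange
    minority_taxa: frozenset[str]
    printed_pair: tuple[int, int]
    computed_pair: tuple[int, int]
    discrepancy: bool


def table2_fixture(seed: int = 0) -> tuple[Msa, list[FixtureExpectation]]:
    """The eight printed stem-loop regions embedded in a shared neutral
    background, 41 taxa.  Absolute coordinates differ from the printed
    alignment (the original gap structure is not reconstructible); relative
    structure, minority taxa and substitution counts are preserved."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xF1B5]))
    taxa = list(FIXTURE_TAXA)
    chunks: dict[str, list[str]] = {t: [] for t in taxa}
    expectations: list[FixtureExpectation] = []
    pos = 1

    def spacer() -> str:
        return "".join(_BASES[i] for i in rng.choice(4, size=_SPACER))

    for row in TABLE2_ROWS:
        sp = spacer()
        for t in taxa:
            chunks[t].append(sp)
        pos += _SPACER
        start = pos
        for t in taxa:
            chunks[t].append(row.minority_region if t in row.minority_taxa
                             else row.majority_region)
        pos += len(row.majority_region)
        expectations.append(FixtureExpectation(
            letter=row.letter,
            region=CoordRange(start, pos - 1),
            minority_taxa=frozenset(row.minority_taxa),
            printed_pair=row.printed_pair,
            computed_pair=row.computed_pair,
            discrepancy=row.discrepancy))
    sp = spacer()
    for t in taxa:
        chunks[t].append(sp)
    msa = Msa((t, "".join(chunks[t])) for t in taxa)
    return msa, expectations
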