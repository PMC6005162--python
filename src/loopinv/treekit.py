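"""Desk-scale tree backend and clade-support bookkeeping.

The original study measured clade support as Bayesian posterior
probabilities; the bookkeeping here (per-replicate support tables,
replicate category rules, supported-node counts) is agnostic to the support
source.  A built-in neighbor-joining + bootstrap engine provides supports at
desk scale, and externally produced newick tree samples can be ingested
instead.

Trees are dendropy objects throughout; node support lives in a ``support``
attribute on internal nodes (float in [0, 1] or None).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import numpy as np
import pandas as pd

from .msa import Msa, UNAMBIGUOUS


class TreeError(ValueError):
    pass


SUPPORT_CONVENTIONS = ("branch_lengths", "post_colon_support", "node_label_support")


# ---------------------------------------------------------------------------
# newick I/O
# ---------------------------------------------------------------------------

def parse_newick(text: str, support_convention: str = "branch_lengths") -> dendropy.Tree:
    """Parse a newick string under one of three support conventions.

    ``post_colon_support``: numbers after ':' on internal nodes are clade
    supports (the style of printed topologies annotated with posterior
    probabilities), not branch lengths.  ``node_label_support``: internal
    node labels are supports.  ``branch_lengths``: plain newick.
    """
    if support_convention not in SUPPORT_CONVENTIONS:
        raise TreeError(f"unknown support convention {support_convention!r}")
    text = text.strip()
    if not text.endswith(";"):
        text += ";"
    try:
        tree = dendropy.Tree.get(data=text, schema="newick",
                                 preserve_underscores=True,
                                 suppress_internal_node_taxa=True)
    except Exception as exc:  # dendropy raises various error types
        raise TreeError(f"newick parse error: {exc}") from exc
    for node in tree:
        node.support = None
    if support_convention == "post_colon_support":
        for node in tree:
            if not node.is_leaf():
                if node.edge.length is not None:
                    node.support = float(node.edge.length)
                node.edge.length = None
            else:
                node.edge.length = None
    elif support_convention == "node_label_support":
        for node in tree:
            if not node.is_leaf() and node.label not in (None, ""):
                node.support = float(node.label)
                node.label = None
    return tree


def write_newick(tree: dendropy.Tree,
                 support_convention: str = "branch_lengths") -> str:
    """Serialize a tree under one of the three support conventions."""
    if support_convention not in SUPPORT_CONVENTIONS:
        raise TreeError(f"unknown support convention {support_convention!r}")

    def fmt(x: float) -> str:
        return f"{x:g}"

    def render(node: dendropy.Node, is_root: bool) -> str:
        if node.is_leaf():
            label = node.taxon.label if node.taxon else (node.label or "")
            out = label
        else:
            inner = ",".join(render(c, False) for c in node.child_nodes())
            out = f"({inner})"
            sup = getattr(node, "support", None)
            if support_convention == "node_label_support" and sup is not None:
                out += fmt(sup)
            if support_convention == "post_colon_support" and sup is not None \
                    and not is_root:
                out += f":{fmt(sup)}"
        if support_convention == "branch_lengths" and node.edge.length is not None \
                and not is_root:
            out += f":{fmt(node.edge.length)}"
        return out

    return render(tree.seed_node, True) + ";"


def read_tree_list(path: str | Path,
                   support_convention: str = "branch_lengths") -> list[dendropy.Tree]:
    """Read a file of newick trees (one per line), e.g. a posterior sample."""
    trees = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            trees.append(parse_newick(line, support_convention))
    return trees


# ---------------------------------------------------------------------------
# leaf sets, clades and splits
# ---------------------------------------------------------------------------

def leaf_labels(tree: dendropy.Tree) -> frozenset[str]:
    return frozenset(l.taxon.label for l in tree.leaf_node_iter())


def clade_sets(tree: dendropy.Tree, include_root: bool = False
               ) -> dict[frozenset[str], dendropy.Node]:
    """Map each internal node (root excluded by default) to its leaf set."""
    out: dict[frozenset[str], dendropy.Node] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            continue
        if node is tree.seed_node and not include_root:
            continue
        out[frozenset(l.taxon.label for l in node.leaf_iter())] = node
    return out


def splits(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Non-trivial bipartitions as canonical leaf-label sets.

    Each split is represented by the side that does not contain the
    alphabetically first leaf label, making the representation
    label-order and rooting invariant.
    """
    labels = leaf_labels(tree)
    anchor = min(labels)
    out: set[frozenset[str]] = set()
    for clade in clade_sets(tree, include_root=False):
        side = frozenset(labels - clade) if anchor in clade else clade
        if 1 < len(side) < len(labels) - 1:
            out.add(side)
    return out


def has_split(tree: dendropy.Tree, side: Iterable[str]) -> bool:
    """True when the bipartition {side, rest} is an edge of the tree."""
    labels = leaf_labels(tree)
    side = frozenset(side)
    anchor = min(labels)
    canonical = frozenset(labels - side) if anchor in side else side
    return canonical in splits(tree)


def incompatible(a: frozenset[str], b: frozenset[str]) -> bool:
    """Rooted-clade incompatibility: intersecting but neither nested."""
    return bool(a & b) and not (a <= b) and not (b <= a)


def root_on_outgroup(tree: dendropy.Tree, outgroup: str) -> dendropy.Tree:
    """Reroot so the named leaf is a child of the root."""
    node = tree.find_node_with_taxon_label(outgroup)
    if node is None:
        raise TreeError(f"outgroup {outgroup!r} not in tree")
    if node.parent_node is not tree.seed_node or len(tree.seed_node.child_nodes()) != 2:
        length = node.edge.length
        halves = (length / 2.0, length / 2.0) if length is not None else (None, None)
        tree.reroot_at_edge(node.edge, length1=halves[0], length2=halves[1])
    tree.is_rooted = True
    return tree


# ---------------------------------------------------------------------------
# distances and neighbor joining
# ---------------------------------------------------------------------------

_SATURATION_P = 0.75


def jc_distance_matrix(msa: Msa) -> pd.DataFrame:
    """Jukes-Cantor distances, d = -(3/4) ln(1 - (4/3) p).

    p is the mismatch fraction over columns where both rows carry an
    unambiguous base.  Saturated pairs (p >= 3/4) are flagged as NaN; a
    pair with no comparable column is an error.
    """
    if len(msa) < 2:
        raise TreeError("need at least two taxa")
    mat = msa.matrix()
    ok = np.isin(mat, [ord(c) for c in UNAMBIGUOUS])
    n = len(msa.taxa)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = ok[i] & ok[j]
            compared = int(both.sum())
            if compared == 0:
                raise TreeError(
                    f"no comparable sites between {msa.taxa[i]!r} and "
                    f"{msa.taxa[j]!r}")
            p = float((mat[i, both] != mat[j, both]).mean())
            if p >= _SATURATION_P:
                D[i, j] = D[j, i] = math.nan
            else:
                D[i, j] = D[j, i] = -0.75 * math.log1p(-4.0 * p / 3.0)
    return pd.DataFrame(D, index=msa.taxa, columns=msa.taxa)


def _as_matrix(matrix) -> tuple[np.ndarray, list[str]]:
    if isinstance(matrix, pd.DataFrame):
        return matrix.to_numpy(dtype=float), [str(c) for c in matrix.columns]
    arr = np.asarray(matrix, dtype=float)
    return arr, [f"T{i}" for i in range(arr.shape[0])]


def nj_tree(matrix, labels: Sequence[str] | None = None) -> dendropy.Tree:
    """Saitou-Nei neighbor joining with deterministic lowest-index
    tie-breaking.  Returns an unrooted dendropy tree; edge lengths as
    computed (may be negative on noisy input)."""
    D0, inferred = _as_matrix(matrix)
    labels = list(labels) if labels is not None else inferred
    n = D0.shape[0]
    if D0.shape != (n, n) or n != len(labels):
        raise TreeError("distance matrix must be square with matching labels")
    if n < 3:
        raise TreeError("need at least three taxa for neighbor joining")
    if np.isnan(D0).any():
        raise TreeError("distance matrix contains saturated (NaN) entries")
    if not np.allclose(D0, D0.T):
        raise TreeError("distance matrix must be symmetric")

    tns = dendropy.TaxonNamespace(labels)
    nodes: list[dendropy.Node] = []
    for lab in labels:
        nd = dendropy.Node()
        nd.taxon = tns.get_taxon(lab)
        nodes.append(nd)
    D = D0.copy()
    active = list(range(n))

    def join(i_pos: int, j_pos: int, li: float, lj: float) -> None:
        """Join active positions i_pos < j_pos into a new node."""
        i, j = active[i_pos], active[j_pos]
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        nodes[i].edge.length = li
        parent.add_child(nodes[j])
        nodes[j].edge.length = lj
        nodes.append(parent)

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        R = sub.sum(axis=1)
        Q = (m - 2) * sub - R[:, None] - R[None, :]
        np.fill_diagonal(Q, np.inf)
        best = None
        for a in range(m):
            for b in range(a + 1, m):
                if best is None or Q[a, b] < Q[best[0], best[1]] - 1e-12:
                    best = (a, b)
        a, b = best
        i, j = active[a], active[b]
        dij = D[i, j]
        li = 0.5 * dij + (R[a] - R[b]) / (2.0 * (m - 2))
        lj = dij - li
        join(a, b, li, lj)
        u = len(nodes) - 1
        newrow = np.zeros(len(nodes))
        D = np.pad(D, ((0, 1), (0, 1)))
        for pos in range(m):
            k = active[pos]
            if k in (i, j):
                continue
            duk = 0.5 * (D[i, k] + D[j, k] - dij)
            D[u, k] = D[k, u] = duk
        active = [k for k in active if k not in (i, j)] + [u]

    x, y, z = active
    center = dendropy.Node()
    lx = 0.5 * (D[x, y] + D[x, z] - D[y, z])
    ly = 0.5 * (D[x, y] + D[y, z] - D[x, z])
    lz = 0.5 * (D[x, z] + D[y, z] - D[x, y])
    for k, lk in ((x, lx), (y, ly), (z, lz)):
        center.add_child(nodes[k])
        nodes[k].edge.length = lk
    tree = dendropy.Tree(seed_node=center, taxon_namespace=tns)
    tree.is_rooted = False
    for node in tree:
        if not hasattr(node, "support"):
            node.support = None
    return tree


def bootstrap_support(msa: Msa, B: int, seed: int = 0) -> dendropy.Tree:
    """NJ tree from the full alignment with bootstrap split frequencies.

    B column resamples with replacement; each replicate is re-joined and
    its splits tallied; supports are the split frequencies mapped onto the
    full-data tree."""
    if B < 1:
        raise TreeError("B must be >= 1")
    full = nj_tree(jc_distance_matrix(msa))
    counts: dict[frozenset[str], int] = {}
    L = msa.length
    for b in range(B):
        rng = np.random.default_rng(np.random.SeedSequence([seed, b]))
        cols = rng.integers(0, L, size=L)
        rep = msa.take_columns(cols.tolist())
        rep_tree = nj_tree(jc_distance_matrix(rep))
        for s in splits(rep_tree):
            counts[s] = counts.get(s, 0) + 1
    labels = leaf_labels(full)
    anchor = min(labels)
    for clade, node in clade_sets(full).items():
        side = frozenset(labels - clade) if anchor in clade else clade
        if 1 < len(side) < len(labels) - 1:
            node.support = counts.get(side, 0) / B
    return full


def count_supported_nodes(tree: dendropy.Tree, threshold: float) -> int:
    """Number of internal nodes (root excluded) with support >= threshold."""
    supports = [getattr(n, "support", None)
                for n in tree.preorder_node_iter()
                if not n.is_leaf() and n is not tree.seed_node]
    if all(s is None for s in supports):
        raise TreeError("tree carries no support values")
    return sum(1 for s in supports if s is not None and s >= threshold)


# ---------------------------------------------------------------------------
# replicate support bookkeeping
# ---------------------------------------------------------------------------

@dataclass
class SupportConfig:
    """Thresholds for the three replicate-support categories.

    A clade is "high" in a replicate at support >= ``high_threshold``; a
    replicate contradicts it when some incompatible clade reaches
    ``high_threshold`` there.  Categories over R replicates:

    * most_high — at least ``replicate_high_count`` replicates high;
    * generally_poor — at most ``low_replicate_count`` high and at least
      ``poor_replicate_count`` replicates with support <= ``poor_threshold``;
    * rarely_high_rarely_contradicted — at most ``low_replicate_count`` high
      and at most one contradicting replicate;
    * intermediate — anything else.
    """

    high_threshold: float = 0.95
    moderate_threshold: float = 0.90
    replicate_high_count: int = 16
    low_replicate_count: int = 5
    poor_threshold: float = 0.05
    poor_replicate_count: int = 6
    burn_in_fraction: float = 0.10

    def __post_init__(self) -> None:
        if not (0 < self.moderate_threshold <= self.high_threshold <= 1):
            raise TreeError("need 0 < moderate <= high <= 1")


@dataclass
class CladeSupport:
    clade: frozenset[str]
    values: list[float]
    contradicted: list[bool]
    category: str

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def min(self) -> float:
        return float(np.min(self.values))

    @property
    def max(self) -> float:
        return float(np.max(self.values))


@dataclass
class CladeSupportTable:
    """Per-clade, per-replicate support values with summary and category."""

    entries: dict[frozenset[str], CladeSupport] = field(default_factory=dict)

    def to_dataframe(self) -> pd.DataFrame:
        rec = []
        for cs in self.entries.values():
            rec.append({
                "clade": "+".join(sorted(cs.clade)),
                "mean": cs.mean, "min": cs.min, "max": cs.max,
                "category": cs.category,
                "values": ",".join(f"{v:.3f}" for v in cs.values),
            })
        return pd.DataFrame.from_records(
            rec, columns=["clade", "mean", "min", "max", "category", "values"])


def _burned_in(sample: Sequence[dendropy.Tree], frac: float) -> list[dendropy.Tree]:
    drop = int(len(sample) * frac)
    return list(sample[drop:])


def _clade_support_in_tree(tree: dendropy.Tree, clade: frozenset[str]) -> float:
    for cl, node in clade_sets(tree, include_root=True).items():
        if cl == clade:
            sup = getattr(node, "support", None)
            return float(sup) if sup is not None else 1.0
    return 0.0


def _tree_contains(tree: dendropy.Tree, clade: frozenset[str]) -> bool:
    return clade in clade_sets(tree, include_root=True)


def _tree_contradicts(tree: dendropy.Tree, clade: frozenset[str]) -> bool:
    return any(incompatible(cl, clade)
               for cl in clade_sets(tree, include_root=True))


def clade_partition_frequencies(sample: Sequence[dendropy.Tree],
                                clade: frozenset[str]
                                ) -> tuple[float, float, float]:
    """(frequency of clade, of contradicting trees, of unresolved trees)
    over a tree sample; the three sum to 1."""
    n = len(sample)
    if n == 0:
        raise TreeError("empty tree sample")
    f_clade = sum(_tree_contains(t, clade) for t in sample) / n
    f_contra = sum((not _tree_contains(t, clade)) and _tree_contradicts(t, clade)
                   for t in sample) / n
    return f_clade, f_contra, 1.0 - f_clade - f_contra


def replicate_support_summary(replicates: Sequence,
                              reference_clades: Iterable[Iterable[str]],
                              config: SupportConfig | None = None
                              ) -> CladeSupportTable:
    """Per-clade support across replicates, each replicate either a
    support-annotated tree or a posterior tree sample (burn-in discarded
    before frequencies are computed)."""
    config = config or SupportConfig()
    clades = [frozenset(c) for c in reference_clades]
    table = CladeSupportTable()
    per_rep: list[tuple[dict[frozenset[str], float], dict[frozenset[str], bool]]] = []
    for ri, rep in enumerate(replicates):
        supports: dict[frozenset[str], float] = {}
        contras: dict[frozenset[str], bool] = {}
        if isinstance(rep, dendropy.Tree):
            for cl in clades:
                supports[cl] = _clade_support_in_tree(rep, cl)
                contras[cl] = any(
                    incompatible(other, cl)
                    and getattr(node, "support", None) is not None
                    and node.support >= config.high_threshold
                    for other, node in clade_sets(rep, include_root=True).items())
        else:
            sample = _burned_in(list(rep), config.burn_in_fraction)
            if not sample:
                raise TreeError(f"replicate {ri} contains no usable trees")
            for cl in clades:
                supports[cl] = sum(_tree_contains(t, cl) for t in sample) / len(sample)
                contra_freqs: dict[frozenset[str], int] = {}
                for t in sample:
                    for other in clade_sets(t, include_root=True):
                        if incompatible(other, cl):
                            contra_freqs[other] = contra_freqs.get(other, 0) + 1
                contras[cl] = any(v / len(sample) >= config.high_threshold
                                  for v in contra_freqs.values())
        per_rep.append((supports, contras))
    for cl in clades:
        values = [s[cl] for s, _ in per_rep]
        contradicted = [c[cl] for _, c in per_rep]
        high = sum(v >= config.high_threshold for v in values)
        poor = sum(v <= config.poor_threshold for v in values)
        if high >= config.replicate_high_count:
            cat = "most_high"
        elif high <= config.low_replicate_count and poor >= config.poor_replicate_count:
            cat = "generally_poor"
        elif high <= config.low_replicate_count and sum(contradicted) <= 1:
            cat = "rarely_high_rarely_contradicted"
        else:
            cat = "intermediate"
        table.entries[cl] = CladeSupport(cl, values, contradicted, cat)
    return table
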