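"""Independent brute-force oracles shared by the unit and acceptance suites."""

import itertools

import numpy as np


# ---------------------------------------------------------------------------
# unrooted topology enumeration + least-squares additive fit (NJ oracle)
# ---------------------------------------------------------------------------

def all_unrooted_topologies(n):
    """All unrooted binary topologies on leaves 0..n-1 as edge sets.

    Nodes are ints: leaves 0..n-1, internal nodes negative.  Built by
    sequential leaf insertion on every edge ((2k-5)!! trees).
    """
    base = frozenset({(0, -1), (1, -1), (2, -1)})
    trees = [base]
    next_internal = -2
    for leaf in range(3, n):
        new_trees = []
        for edges in trees:
            for (u, v) in edges:
                rest = set(edges) - {(u, v)}
                w = next_internal
                rest |= {(u, w), (v, w), (leaf, w)}
                new_trees.append(frozenset(rest))
        trees = new_trees
        next_internal -= 1
    return trees


def _adjacency(edges):
    adj = {}
    for u, v in edges:
        adj.setdefault(u, set()).add(v)
        adj.setdefault(v, set()).add(u)
    return adj


def tree_splits(edges, n):
    """Non-trivial splits of an edge-set topology, anchored away from leaf
    labels' minimum (matching loopinv.treekit.splits conventions)."""
    adj = _adjacency(edges)
    labels = set(range(n))
    out = set()
    for (u, v) in edges:
        # leaves on v's side when edge (u, v) removed
        stack, seen = [v], {u, v}
        side = set()
        while stack:
            x = stack.pop()
            if x >= 0:
                side.add(x)
            for y in adj[x]:
                if y not in seen:
                    seen.add(y)
                    stack.append(y)
        if 0 in side:
            side = labels - side
        if 1 < len(side) < n - 1:
            out.add(frozenset(side))
    return out


def path_edges(edges, n):
    """For each leaf pair, the set of edges on the connecting path."""
    adj = _adjacency(edges)
    edge_index = {e: i for i, e in enumerate(sorted(edges))}

    def find_path(a, b):
        stack = [(a, [])]
        seen = {a}
        while stack:
            x, path = stack.pop()
            if x == b:
                return path
            for y in adj[x]:
                if y not in seen:
                    seen.add(y)
                    e = (x, y) if (x, y) in edge_index else (y, x)
                    stack.append((y, path + [edge_index[e]]))
        raise AssertionError("disconnected tree")

    out = {}
    for a, b in itertools.combinations(range(n), 2):
        out[(a, b)] = find_path(a, b)
    return out, len(edge_index)


def best_additive_topology(D):
    """Exhaustively fit every topology by least squares; return the splits
    of the best-fitting (minimum residual) topology."""
    n = D.shape[0]
    pairs = list(itertools.combinations(range(n), 2))
    d = np.array([D[a, b] for a, b in pairs])
    best = None
    for edges in all_unrooted_topologies(n):
        paths, n_edges = path_edges(edges, n)
        A = np.zeros((len(pairs), n_edges))
        for r, p in enumerate(pairs):
            A[r, paths[p]] = 1.0
        x, *_ = np.linalg.lstsq(A, d, rcond=None)
        resid = float(((A @ x - d) ** 2).sum())
        if best is None or resid < best[0]:
            best = (resid, edges)
    return tree_splits(best[1], n), best[0]


def random_additive_matrix(n, seed, bl_low=0.05, bl_high=0.4):
    """Distance matrix of a random binary topology with random positive
    edge lengths; returns (matrix, true splits)."""
    rng = np.random.default_rng(seed)
    topologies = None
    # build one random topology by sequential insertion
    edges = {(0, -1), (1, -1), (2, -1)}
    next_internal = -2
    for leaf in range(3, n):
        u, v = list(edges)[rng.integers(len(edges))]
        edges.remove((u, v))
        w = next_internal
        edges |= {(u, w), (v, w), (leaf, w)}
        next_internal -= 1
    edges = frozenset(edges)
    lengths = {e: rng.uniform(bl_low, bl_high) for e in sorted(edges)}
    paths, _ = path_edges(edges, n)
    edge_list = sorted(edges)
    D = np.zeros((n, n))
    for (a, b), idx in paths.items():
        D[a, b] = D[b, a] = sum(lengths[edge_list[i]] for i in idx)
    _ = topologies
    return D, tree_splits(edges, n)


# ---------------------------------------------------------------------------
# exhaustive small-parsimony oracle
# ---------------------------------------------------------------------------

def brute_force_parsimony(tree, states):
    """Minimum change count by enumerating all internal-node labelings.

    ``tree`` is a dendropy tree, ``states`` maps leaf label to 0/1/'?'.
    """
    internals = [nd for nd in tree.preorder_node_iter() if not nd.is_leaf()]
    leaves = [nd for nd in tree.leaf_node_iter()]
    best = None
    leaf_choices = []
    for nd in leaves:
        s = states.get(nd.taxon.label, "?")
        leaf_choices.append((0, 1) if s == "?" else (int(s),))
    for assign in itertools.product((0, 1), repeat=len(internals)):
        node_state = {nd: s for nd, s in zip(internals, assign)}
        for leaf_assign in itertools.product(*leaf_choices):
            for nd, s in zip(leaves, leaf_assign):
                node_state[nd] = s
            changes = 0
            for nd in tree.preorder_node_iter():
                if nd.parent_node is not None:
                    changes += node_state[nd] != node_state[nd.parent_node]
            if best is None or changes < best:
                best = changes
    return best
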