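"""Binary-character parsimony on a fixed topology.

Inversion presence/absence characters (one per hairpin loop) are mapped
onto a rooted tree by small parsimony.  The minimum change count comes from
a Sankoff-style dynamic program (exact on multifurcations; "?" is the full
state set).  Among equally parsimonious reconstructions the
accelerated-transformation (ACCTRAN) rule is used: ties in the top-down
state choice are resolved toward a change, placing changes as close to the
root as possible.  The root state defaults to 0, the outgroup form.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy

INF = 10 ** 9


class ParsimonyError(ValueError):
    pass


@dataclass
class BinaryCharacter:
    """taxon -> state in {0, 1, '?'} for one character (e.g. loop A)."""

    char_id: str
    states: dict[str, object]

    def __post_init__(self) -> None:
        if not self.states:
            raise ParsimonyError("character scores no taxa")
        for t, s in self.states.items():
            if s not in (0, 1, "?"):
                raise ParsimonyError(f"bad state {s!r} for taxon {t!r}")

    def state_set(self, taxon: str) -> tuple[int, ...]:
        s = self.states.get(taxon, "?")
        return (0, 1) if s == "?" else (int(s),)


@dataclass
class BranchEvent:
    """A state change on the branch subtending ``clade`` (leaf labels)."""

    clade: frozenset[str]
    kind: str  # "gain" (0->1) or "loss" (1->0)


@dataclass
class EventMapping:
    char_id: str
    events: list[BranchEvent] = field(default_factory=list)
    node_states: dict[frozenset[str], int] = field(default_factory=dict)
    root_state: int = 0
    root_state_forced: bool = True

    @property
    def gains(self) -> int:
        return sum(e.kind == "gain" for e in self.events)

    @property
    def losses(self) -> int:
        return sum(e.kind == "loss" for e in self.events)

    @property
    def length(self) -> int:
        return len(self.events)


def _check_taxa(tree: dendropy.Tree, char: BinaryCharacter) -> None:
    labels = {l.taxon.label for l in tree.leaf_node_iter()}
    missing = set(char.states) - labels
    if missing:
        raise ParsimonyError(
            f"taxa scored in character {char.char_id!r} absent from tree: "
            f"{sorted(missing)}")


def _subtree_costs(tree: dendropy.Tree, char: BinaryCharacter
                   ) -> dict[dendropy.Node, list[int]]:
    """cost[node][s] = min changes in the subtree given the node has state s."""
    cost: dict[dendropy.Node, list[int]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            allowed = char.state_set(node.taxon.label)
            cost[node] = [0 if s in allowed else INF for s in (0, 1)]
        else:
            c = [0, 0]
            for child in node.child_nodes():
                cc = cost[child]
                for s in (0, 1):
                    c[s] += min(cc[t] + (t != s) for t in (0, 1))
            cost[node] = c
    return cost


def fitch_length(tree: dendropy.Tree, char: BinaryCharacter) -> int:
    """Minimum number of state changes on the rooted tree ("?" free)."""
    _check_taxa(tree, char)
    cost = _subtree_costs(tree, char)
    return min(cost[tree.seed_node])


def acctran_map(tree: dendropy.Tree, char: BinaryCharacter,
                ancestral_state: int = 0) -> EventMapping:
    """Accelerated-transformation reconstruction of a binary character.

    The root takes ``ancestral_state`` when that is among its minimum-cost
    states (always true when the tree is rooted on an outgroup fixing that
    state); otherwise the minimum-cost state is used and
    ``root_state_forced`` is False, keeping the mapping length equal to the
    Fitch length.  Going root-to-tips each node takes the state minimizing
    its subtree cost plus the change indicator; on ties the state differing
    from the parent wins (changes accelerate toward the root).
    """
    if ancestral_state not in (0, 1):
        raise ParsimonyError("ancestral_state must be 0 or 1")
    _check_taxa(tree, char)
    cost = _subtree_costs(tree, char)
    root = tree.seed_node
    rc = cost[root]
    forced = rc[ancestral_state] == min(rc)
    root_state = ancestral_state if forced else (0 if rc[0] < rc[1] else 1)

    mapping = EventMapping(char_id=char.char_id, root_state=root_state,
                           root_state_forced=forced)
    state: dict[dendropy.Node, int] = {root: root_state}
    for node in tree.preorder_node_iter():
        if node is root:
            continue
        p = state[node.parent_node]
        cc = cost[node]
        totals = {s: cc[s] + (s != p) for s in (0, 1)}
        best = min(totals.values())
        choices = [s for s in (0, 1) if totals[s] == best]
        s = choices[0] if len(choices) == 1 else next(
            c for c in choices if c != p)  # tie -> accelerate the change
        state[node] = s
        clade = frozenset(l.taxon.label for l in node.leaf_iter())
        mapping.node_states[clade] = s
        if s != p:
            mapping.events.append(
                BranchEvent(clade, "gain" if s == 1 else "loss"))
    return mapping


def mapping_table(mappings: list[EventMapping]):
    """Branch-event report as a pandas DataFrame."""
    import pandas as pd

    rec = []
    for m in mappings:
        for ev in m.events:
            rec.append({
                "character": m.char_id,
                "branch": "+".join(sorted(ev.clade)),
                "event": ev.kind,
            })
    return pd.DataFrame.from_records(rec, columns=["character", "branch", "event"])


def character_matrix_from_events(events, taxa: list[str]) -> list[BinaryCharacter]:
    """Binary characters (one per inversion event): minority taxa are 1,
    assessable majority taxa 0, gapped taxa '?'."""
    chars = []
    for ev in events:
        states: dict[str, object] = {}
        for t in taxa:
            if t in ev.minority_taxa:
                states[t] = 1
            elif t in ev.not_assessable:
                states[t] = "?"
            else:
                states[t] = 0
        chars.append(BinaryCharacter(ev.event_id, states))
    return chars
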