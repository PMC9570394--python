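"""Sex-chromosome turnover counting on a fixed species phylogeny.

Each species carries a categorical sex-chromosome identity (e.g.
``chr5-homologous`` vs ``other``) and a heterogamety state (XY / ZW).  The
minimum number of turnover events (identity changes) and heterogamety shifts
over the tree is the small-parsimony change count, computed by unit-cost
dynamic programming (Sankoff with 0/1 costs, equivalent to Fitch counting).
The species tree is input data from published phylogenies and is never
re-estimated here.

Tips labelled ``unknown`` are wildcards: they can take any state and never
force a change.  Counts are invariant to rerooting (unit-cost parsimony is
unrooted) and to tip order.  Besides the count, branches are classified into
those where *every* most-parsimonious reconstruction places a change
(``change_branches``) and those where only *some* reconstruction does
(``possible_change_branches``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import dendropy

from .io_formats import read_newick

logger = logging.getLogger(__name__)

__all__ = [
    "IdentityPhylogeny",
    "TurnoverReport",
    "fitch_min_changes",
    "count_identities",
    "heterogamety_shifts",
]

UNKNOWN = "unknown"
_INF = float("inf")

Branch = frozenset  # a branch is identified by its child-side tip set


def _as_tree(tree: dendropy.Tree | str) -> dendropy.Tree:
    t = tree if isinstance(tree, dendropy.Tree) else read_newick(tree)
    if not any(t.leaf_node_iter()):
        raise ValueError("empty tree")
    return t


def _check_tips(tree: dendropy.Tree, tip_states: Mapping[str, str]) -> None:
    tips = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    missing = set(tip_states) - tips
    if missing:
        raise ValueError(f"labelled tips not in tree: {sorted(missing)}")


def _observed_states(tip_states: Mapping[str, str]) -> list[str]:
    return sorted({s for s in tip_states.values() if s != UNKNOWN})


def _min_cost(
    tree: dendropy.Tree,
    tip_states: Mapping[str, str],
    states: list[str],
    constrained_edge: frozenset | None = None,
    forbid_change: bool = True,
) -> float:
    """Unit-cost parsimony minimum via postorder DP.

    With ``constrained_edge`` set (child-side tip set), the edge's cost term
    is constrained: ``forbid_change=True`` forces equal states across it,
    ``False`` forces a change.
    """
    k = len(states)
    idx = {s: i for i, s in enumerate(states)}
    cost: dict[dendropy.Node, list[float]] = {}
    leafset: dict[dendropy.Node, frozenset] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            label = node.taxon.label
            leafset[node] = frozenset([label])
            state = tip_states.get(label, UNKNOWN)
            if state == UNKNOWN:
                cost[node] = [0.0] * k
            else:
                cost[node] = [0.0 if i == idx[state] else _INF for i in range(k)]
        else:
            leafset[node] = frozenset().union(
                *(leafset[c] for c in node.child_nodes())
            )
            node_cost = [0.0] * k
            for child in node.child_nodes():
                constrained = leafset[child] == constrained_edge
                for s in range(k):
                    best = _INF
                    for c in range(k):
                        if constrained:
                            if forbid_change and c != s:
                                continue
                            if not forbid_change and c == s:
                                continue
                        step = cost[child][c] + (0.0 if c == s else 1.0)
                        best = min(best, step)
                    node_cost[s] += best
            cost[node] = node_cost
    return min(cost[tree.seed_node])


def fitch_min_changes(
    tree: dendropy.Tree | str,
    tip_states: Mapping[str, str],
) -> tuple[int, set[frozenset], set[frozenset]]:
    """Minimum number of state changes and their branch placements.

    Returns ``(min_changes, change_branches, possible_change_branches)``.
    Branches are identified by the frozenset of tip labels on their child
    side.  ``change_branches`` holds branches where every most-parsimonious
    reconstruction places a change; ``possible_change_branches`` those where
    at least one does (ambiguous placements are in the second set only).
    """
    t = _as_tree(tree)
    _check_tips(t, tip_states)
    # Work on the unrooted shape: collapse a bifurcating root so each
    # unrooted branch is exactly one edge (otherwise the two root-adjacent
    # edges would split one branch's change between them).
    t = t.clone(depth=1)
    if len(t.seed_node.child_nodes()) == 2 and len(t.leaf_nodes()) > 2:
        t.deroot()
    labelled = {k: v for k, v in tip_states.items() if v != UNKNOWN}
    if not labelled:
        raise ValueError("need at least one labelled (non-unknown) tip")
    states = _observed_states(tip_states)
    if len(states) == 1:
        return 0, set(), set()
    baseline = _min_cost(t, tip_states, states)

    all_edges: list[frozenset] = []
    for node in t.postorder_node_iter():
        if node.parent_node is None:
            continue
        tips = frozenset(leaf.taxon.label for leaf in node.leaf_iter())
        all_edges.append(tips)

    necessary: set[frozenset] = set()
    possible: set[frozenset] = set()
    for edge in all_edges:
        no_change = _min_cost(t, tip_states, states, edge, forbid_change=True)
        if no_change > baseline:
            necessary.add(edge)
            possible.add(edge)
        else:
            with_change = _min_cost(t, tip_states, states, edge, forbid_change=False)
            if with_change == baseline:
                possible.add(edge)
    return int(baseline), necessary, possible


def count_identities(tip_states: Mapping[str, str]) -> int:
    """Number of distinct non-unknown sex-chromosome identities."""
    if not tip_states:
        raise ValueError("need at least one labelled tip")
    n = len(_observed_states(tip_states))
    if n == 0:
        logger.warning("all tip identities unknown; identity count is 0")
    return n


def heterogamety_shifts(
    tree: dendropy.Tree | str,
    tip_heterogamety: Mapping[str, str],
) -> tuple[int, set[frozenset], set[frozenset]]:
    """Minimum XY <-> ZW shifts on the tree (two-state parsimony)."""
    bad = {
        t: s for t, s in tip_heterogamety.items() if s not in {"XY", "ZW", UNKNOWN}
    }
    if bad:
        raise ValueError(f"heterogamety states must be XY/ZW/unknown: {bad}")
    return fitch_min_changes(tree, tip_heterogamety)


@dataclass
class TurnoverReport:
    min_turnovers: int
    turnover_branches: set[frozenset]
    possible_turnover_branches: set[frozenset]
    n_identities: int
    min_heterogamety_shifts: int | None
    heterogamety_shift_branches: set[frozenset] = field(default_factory=set)


@dataclass
class IdentityPhylogeny:
    """A species tree with per-tip sex-chromosome identity and heterogamety."""

    tree: dendropy.Tree | str
    identity: dict[str, str] = field(default_factory=dict)
    heterogamety: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.tree = _as_tree(self.tree)
        _check_tips(self.tree, self.identity)
        _check_tips(self.tree, self.heterogamety)

    def report(self) -> TurnoverReport:
        n_changes, branches, possible = fitch_min_changes(self.tree, self.identity)
        if any(s != UNKNOWN for s in self.heterogamety.values()):
            n_shifts, shift_branches, _ = heterogamety_shifts(
                self.tree, self.heterogamety
            )
        else:
            n_shifts, shift_branches = None, set()
        return TurnoverReport(
            min_turnovers=n_changes,
            turnover_branches=branches,
            possible_turnover_branches=possible,
            n_identities=count_identities(self.identity) if self.identity else 0,
            min_heterogamety_shifts=n_shifts,
            heterogamety_shift_branches=shift_branches,
        )

    def render(self) -> str:
        """Text rendering of the tree with identity/heterogamety annotations."""
        lines = []
        for leaf in self.tree.leaf_node_iter():
            name = leaf.taxon.label
            ident = self.identity.get(name, UNKNOWN)
            het = self.heterogamety.get(name, UNKNOWN)
            lines.append(f"{name}\t{ident}\t{het}")
        ascii_plot = self.tree.as_ascii_plot(plot_metric="level")
        return ascii_plot + "\n" + "tip\tidentity\theterogamety\n" + "\n".join(lines)
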