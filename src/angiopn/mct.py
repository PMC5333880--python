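"""Maximal Common Transition (MCT) sets.

An MCT set groups transitions that occur in the supports of exactly the same
t-invariants; the sets partition the covered transitions into the smallest
functional units of the model.  A set of size one is *trivial*.  An MCT set
may induce a disconnected subnet, which is reported but not decomposed
further.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .core_net import PetriNet
from .invariants import SupportMatrix

__all__ = ["MCTPartition", "compute_mct_sets", "mct_subnet_connected"]


def _t_key(label: str) -> tuple:
    """Sort transition labels numerically when they look like t<digits>."""
    if label.startswith("t") and label[1:].isdigit():
        return (0, int(label[1:]), label)
    return (1, 0, label)


@dataclass(frozen=True)
class MCTPartition:
    """Equivalence classes of transitions with identical invariant membership.

    ``sets`` is ordered canonically (size descending, then lexicographic by
    member), with non-trivial sets named m1, m2, ... in that order.
    Transitions in no support at all form ``uncovered_class`` rather than an
    MCT set.
    """

    sets: tuple[tuple[str, ...], ...]
    names: tuple[str, ...]
    trivial_flags: tuple[bool, ...]
    uncovered_class: tuple[str, ...]

    @property
    def nontrivial_sets(self) -> dict[str, tuple[str, ...]]:
        return {
            name: members
            for name, members, triv in zip(self.names, self.sets, self.trivial_flags)
            if not triv
        }

    def set_of(self, transition: str) -> tuple[str, ...]:
        for members in self.sets:
            if transition in members:
                return members
        raise KeyError(transition)


def compute_mct_sets(matrix: SupportMatrix) -> MCTPartition:
    """Group identical nonzero occurrence columns of ``matrix``.

    Hashes column bit patterns (O(N*m)); all-zero columns are collected into
    the uncovered class.  Canonical order: by set size descending, then by the
    smallest member label; names m1, m2, ... go to non-trivial sets first,
    then s1, s2, ... to trivial ones.
    """
    cols = np.asarray(matrix.entries, dtype=np.int8)
    groups: dict[bytes, list[str]] = {}
    uncovered: list[str] = []
    for j, label in enumerate(matrix.col_labels):
        pattern = cols[:, j].tobytes()
        if cols[:, j].sum() == 0:
            uncovered.append(label)
        else:
            groups.setdefault(pattern, []).append(label)
    ordered = sorted(
        (tuple(sorted(members, key=_t_key)) for members in groups.values()),
        key=lambda s: (-len(s), _t_key(s[0])),
    )
    trivial = tuple(len(s) == 1 for s in ordered)
    names = []
    n_nontrivial = n_trivial = 0
    for s in ordered:
        if len(s) > 1:
            n_nontrivial += 1
            names.append(f"m{n_nontrivial}")
        else:
            n_trivial += 1
            names.append(f"s{n_trivial}")
    return MCTPartition(
        sets=tuple(ordered),
        names=tuple(names),
        trivial_flags=trivial,
        uncovered_class=tuple(sorted(uncovered, key=_t_key)),
    )


def mct_subnet_connected(net: PetriNet, mct: set[str] | tuple[str, ...]) -> bool:
    """Is the subnet induced by ``mct`` plus its adjacent places connected?

    Connectivity is undirected.  Places shared with other sets are included
    per-set; a singleton set is always connected.
    """
    members = set(mct)
    unknown = members - set(net.transition_ids)
    if unknown:
        raise KeyError(f"unknown transitions {sorted(unknown)}")
    if not members:
        return True
    g = nx.Graph()
    g.add_nodes_from(members)
    for (src, dst) in net.arcs:
        if src in members or dst in members:
            g.add_edge(src, dst)
    return nx.is_connected(g)
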