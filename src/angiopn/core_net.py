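"""Petri net data model, incidence matrix, token-game firing rule, structural checks.

A Petri net is the 5-tuple Q = (P, T, F, W, M0): a finite bipartite directed
graph of *places* (passive components; compounds, states) and *transitions*
(active components; elementary processes), with positive integer arc weights W
and an initial marking M0 assigning non-negative token counts to places.
Tokens flow from pre-places to post-places when an enabled transition fires.

The incidence matrix A (n places x m transitions) records the net token
effect of each transition on each place and is the algebraic substrate for
invariant analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

__all__ = [
    "NetValidationError",
    "PetriNet",
    "Marking",
    "IncidenceMatrix",
    "StructuralReport",
    "build_incidence_matrix",
    "enabled_transitions",
    "fire_transition",
    "structural_report",
]


class NetValidationError(ValueError):
    """Raised when a net, marking, or firing request violates the model contract."""


def _normalize_nodes(nodes: Iterable) -> tuple[tuple[str, str], ...]:
    out = []
    for item in nodes:
        if isinstance(item, str):
            out.append((item, item))
        else:
            nid, name = item
            out.append((str(nid), str(name)))
    return tuple(out)


@dataclass(frozen=True)
class PetriNet:
    """Immutable place/transition net with weighted arcs and an initial marking.

    Parameters
    ----------
    places, transitions
        Ordered ids, either bare strings or ``(id, name)`` pairs.
    arcs
        Mapping ``(source_id, target_id) -> weight`` or an iterable of
        ``(source, target, weight)`` triples.  Every arc must connect a place
        to a transition or vice versa; duplicate (source, target) pairs are an
        error rather than being weight-summed.
    initial_marking
        ``place_id -> tokens``; unlisted places hold zero tokens.
    """

    places: tuple[tuple[str, str], ...]
    transitions: tuple[tuple[str, str], ...]
    arcs: Mapping[tuple[str, str], int]
    initial_marking: Mapping[str, int] = field(default_factory=dict)

    def __init__(self, places, transitions, arcs, initial_marking=None):
        object.__setattr__(self, "places", _normalize_nodes(places))
        object.__setattr__(self, "transitions", _normalize_nodes(transitions))
        if not isinstance(arcs, Mapping):
            arc_map: dict[tuple[str, str], int] = {}
            for src, dst, w in arcs:
                key = (str(src), str(dst))
                if key in arc_map:
                    raise NetValidationError(f"duplicate arc declaration {key}")
                arc_map[key] = int(w)
            arcs = arc_map
        else:
            arcs = {(str(s), str(d)): int(w) for (s, d), w in arcs.items()}
        object.__setattr__(self, "arcs", dict(arcs))
        object.__setattr__(
            self, "initial_marking", dict(initial_marking or {})
        )
        self._validate()

    # -- contract ---------------------------------------------------------
    def _validate(self) -> None:
        pids = [p for p, _ in self.places]
        tids = [t for t, _ in self.transitions]
        pset, tset = set(pids), set(tids)
        if len(pset) != len(pids) or len(tset) != len(tids):
            raise NetValidationError("duplicate place or transition ids")
        if pset & tset:
            raise NetValidationError(
                f"place and transition ids overlap: {sorted(pset & tset)}"
            )
        if not (pset | tset):
            raise NetValidationError("net must contain at least one vertex")
        for (src, dst), w in self.arcs.items():
            if w < 1:
                raise NetValidationError(f"arc {(src, dst)} has weight {w} < 1")
            p2t = src in pset and dst in tset
            t2p = src in tset and dst in pset
            if not (p2t or t2p):
                raise NetValidationError(
                    f"arc {(src, dst)} does not connect a place and a transition"
                )
        for pid, tok in self.initial_marking.items():
            if pid not in pset:
                raise NetValidationError(f"marking references unknown place {pid!r}")
            if tok < 0:
                raise NetValidationError(f"negative initial tokens at {pid!r}")

    # -- convenience ------------------------------------------------------
    @property
    def place_ids(self) -> tuple[str, ...]:
        return tuple(p for p, _ in self.places)

    @property
    def transition_ids(self) -> tuple[str, ...]:
        return tuple(t for t, _ in self.transitions)

    @property
    def n_places(self) -> int:
        return len(self.places)

    @property
    def n_transitions(self) -> int:
        return len(self.transitions)

    def pre_places(self, t: str) -> dict[str, int]:
        """Weights of arcs place -> ``t``."""
        return {s: w for (s, d), w in self.arcs.items() if d == t}

    def post_places(self, t: str) -> dict[str, int]:
        return {d: w for (s, d), w in self.arcs.items() if s == t}

    def marking_vector(self) -> "Marking":
        return Marking(
            [self.initial_marking.get(p, 0) for p in self.place_ids]
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, PetriNet):
            return NotImplemented
        return (
            self.places == other.places
            and self.transitions == other.transitions
            and self.arcs == other.arcs
            and {p: v for p, v in self.initial_marking.items() if v}
            == {p: v for p, v in other.initial_marking.items() if v}
        )

    def __hash__(self):
        return hash((self.places, self.transitions, tuple(sorted(self.arcs.items()))))


class Marking:
    """Token-count vector indexed by the net's place order (value-semantic)."""

    __slots__ = ("tokens",)

    def __init__(self, tokens: Sequence[int]):
        arr = np.asarray(tokens, dtype=np.int64)
        if arr.ndim != 1:
            raise NetValidationError("marking must be a 1-d vector")
        if (arr < 0).any():
            raise NetValidationError("marking entries must be non-negative")
        self.tokens = arr
        self.tokens.setflags(write=False)

    def __len__(self) -> int:
        return len(self.tokens)

    def __eq__(self, other) -> bool:
        if isinstance(other, Marking):
            other = other.tokens
        return len(self.tokens) == len(other) and bool(
            (self.tokens == np.asarray(other)).all()
        )

    def __repr__(self) -> str:
        return f"Marking({self.tokens.tolist()})"


@dataclass(frozen=True)
class IncidenceMatrix:
    """n x m integer matrix A with a_ij = W(t_j -> p_i) - W(p_i -> t_j)."""

    entries: np.ndarray
    place_ids: tuple[str, ...]
    transition_ids: tuple[str, ...]

    def __post_init__(self):
        arr = np.asarray(self.entries, dtype=np.int64)
        if arr.shape != (len(self.place_ids), len(self.transition_ids)):
            raise NetValidationError("incidence matrix shape/label mismatch")
        arr.setflags(write=False)
        object.__setattr__(self, "entries", arr)

    @property
    def shape(self) -> tuple[int, int]:
        return self.entries.shape


@dataclass(frozen=True)
class StructuralReport:
    ordinary: bool
    homogeneous: bool
    pure: bool
    connected: bool
    strongly_connected: bool
    structurally_conflict_free: bool


def build_incidence_matrix(net: PetriNet) -> IncidenceMatrix:
    """Incidence matrix of ``net``: rows follow place order, columns transition order.

    Entry ``a[i, j]`` is the net token gain of place i when transition j fires
    (production minus consumption); a read-arc-like loop of equal weights
    cancels to zero.
    """
    p_index = {p: i for i, p in enumerate(net.place_ids)}
    t_index = {t: j for j, t in enumerate(net.transition_ids)}
    A = np.zeros((net.n_places, net.n_transitions), dtype=np.int64)
    for (src, dst), w in net.arcs.items():
        if src in p_index:  # place -> transition: consumption
            A[p_index[src], t_index[dst]] -= w
        else:  # transition -> place: production
            A[p_index[dst], t_index[src]] += w
    return IncidenceMatrix(A, net.place_ids, net.transition_ids)


def _check_marking(net: PetriNet, marking: Marking) -> None:
    if len(marking) != net.n_places:
        raise NetValidationError(
            f"marking length {len(marking)} != place count {net.n_places}"
        )


def enabled_transitions(net: PetriNet, marking: Marking) -> set[str]:
    """Transitions whose every pre-place holds at least the connecting arc weight.

    A transition with an empty pre-set is enabled at every marking.
    """
    _check_marking(net, marking)
    p_index = {p: i for i, p in enumerate(net.place_ids)}
    enabled = set(net.transition_ids)
    for (src, dst), w in net.arcs.items():
        if src in p_index and dst in enabled:
            if marking.tokens[p_index[src]] < w:
                enabled.discard(dst)
    return enabled


def fire_transition(net: PetriNet, marking: Marking, t: str) -> Marking:
    """Fire ``t`` at ``marking`` and return the successor marking.

    Raises :class:`NetValidationError` when ``t`` is unknown or not enabled;
    the input marking is never mutated.
    """
    _check_marking(net, marking)
    if t not in set(net.transition_ids):
        raise NetValidationError(f"unknown transition {t!r}")
    p_index = {p: i for i, p in enumerate(net.place_ids)}
    new = marking.tokens.copy()
    for pid, w in net.pre_places(t).items():
        i = p_index[pid]
        if new[i] < w:
            raise NetValidationError(
                f"transition {t!r} not enabled: place {pid!r} holds "
                f"{int(new[i])} < weight {w}"
            )
        new[i] -= w
    for pid, w in net.post_places(t).items():
        new[p_index[pid]] += w
    return Marking(new)


def _as_graphs(net: PetriNet) -> tuple[nx.Graph, nx.DiGraph]:
    dg = nx.DiGraph()
    dg.add_nodes_from(net.place_ids)
    dg.add_nodes_from(net.transition_ids)
    dg.add_edges_from(net.arcs.keys())
    return dg.to_undirected(as_view=False), dg


def structural_report(net: PetriNet) -> StructuralReport:
    """Classify ``net`` by the standard qualitative structural properties.

    ordinary: every arc weight is 1.  homogeneous: for each place all outgoing
    arcs share one weight.  pure: no pair of oppositely directed arcs between
    one place and one transition (no read arcs).  connected / strongly
    connected: on the undirected shadow graph / the directed graph.
    structurally conflict-free: no place feeds two or more transitions.
    """
    pset = set(net.place_ids)
    ordinary = all(w == 1 for w in net.arcs.values())
    out_weights: dict[str, set[int]] = {}
    out_degree: dict[str, int] = {}
    for (src, dst), w in net.arcs.items():
        if src in pset:
            out_weights.setdefault(src, set()).add(w)
            out_degree[src] = out_degree.get(src, 0) + 1
    homogeneous = all(len(ws) == 1 for ws in out_weights.values())
    pure = not any((dst, src) in net.arcs for (src, dst) in net.arcs)
    ug, dg = _as_graphs(net)
    n_nodes = ug.number_of_nodes()
    connected = n_nodes <= 1 or nx.is_connected(ug)
    strongly_connected = n_nodes <= 1 or nx.is_strongly_connected(dg)
    conflict_free = all(d < 2 for d in out_degree.values())
    return StructuralReport(
        ordinary=ordinary,
        homogeneous=homogeneous,
        pure=pure,
        connected=connected,
        strongly_connected=strongly_connected,
        structurally_conflict_free=conflict_free,
    )
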