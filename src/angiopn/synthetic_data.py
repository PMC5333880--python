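"""Generators for structurally well-behaved test nets and support matrices,
plus the packaged angiogenesis-model fixture.

``generate_covered_net`` builds ordinary, pure, connected nets as unions of
directed circuits that share vertices; every circuit is a t-invariant by
construction, so the result is always covered.  ``generate_block_support_matrix``
plants MCT-style block structure (groups of identical columns) into a binary
invariant x transition matrix.  ``load_angiogenesis_fixture`` exposes the
48 x 74 support matrix of the published angiogenesis model, expanded from the
packaged per-invariant composition and MCT-membership tables, together with
the expected structural-knockout ranking.
"""

from __future__ import annotations

import csv
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd

from .core_net import PetriNet
from .invariants import SupportMatrix

__all__ = [
    "generate_covered_net",
    "generate_block_support_matrix",
    "load_angiogenesis_fixture",
]


def _check_feasible(n_places: int, n_transitions: int, n_circuits: int) -> None:
    # circuits partition the transitions and share only places, so each
    # circuit stays a t-invariant of the union net
    if n_transitions < 2 * n_circuits or n_places < 2:
        raise ValueError(
            "need at least two transitions per circuit and two places "
            "(a one-transition circuit would be a read-arc self-loop)"
        )
    if n_places > n_transitions - n_circuits + 1:
        raise ValueError(
            "infeasible: every place needs a fresh cycle slot; require "
            "n_places <= n_transitions - n_circuits + 1"
        )
    if n_transitions > n_circuits * n_places:
        raise ValueError(
            "infeasible: a circuit cannot visit more distinct places than exist; "
            "require n_transitions <= n_circuits * n_places"
        )


def _build_circuits(
    n_places: int, n_transitions: int, n_circuits: int, rng: np.random.Generator
):
    places = [f"p{i}" for i in range(n_places)]
    transitions = [f"t{j}" for j in range(n_transitions)]
    rng.shuffle(places)
    rng.shuffle(transitions)
    # partition transitions into n_circuits parts, each of size 1..n_places
    sizes = [2] * n_circuits
    extra = n_transitions - 2 * n_circuits
    while extra:
        candidates = [c for c in range(n_circuits) if sizes[c] < n_places]
        c = candidates[int(rng.integers(len(candidates)))]
        sizes[c] += 1
        extra -= 1

    fresh = list(places)  # not yet used anywhere
    used: list[str] = []
    arcs: dict[tuple[str, str], int] = {}
    marking: dict[str, int] = {}
    t_cursor = 0
    for c, L in enumerate(sizes):
        ts = transitions[t_cursor : t_cursor + L]
        t_cursor += L
        ps: list[str] = []
        if c > 0:  # anchor to the existing component through a shared place
            ps.append(used[int(rng.integers(len(used)))])
        take = min(L - len(ps), len(fresh))
        ps.extend(fresh[:take])
        del fresh[:take]
        pool = [p for p in used if p not in ps]
        while len(ps) < L:
            if not pool:
                raise ValueError("infeasible parameters: cannot complete circuit")
            ps.append(pool.pop(int(rng.integers(len(pool)))))
        rng.shuffle(ps)
        for i in range(L):
            arcs[(ps[i], ts[i])] = 1
            arcs[(ts[i], ps[(i + 1) % L])] = 1
        marking[ps[0]] = marking.get(ps[0], 0) + 1
        for p in ps:
            if p not in used:
                used.append(p)
    if fresh:
        raise ValueError("infeasible parameters: unused places remain")
    if any((d, s) in arcs for (s, d) in arcs):
        return None  # read arc emerged across circuits; caller retries
    n_order = sorted(places, key=lambda p: int(p[1:]))
    t_order = sorted(transitions, key=lambda t: int(t[1:]))
    return PetriNet(n_order, t_order, arcs, marking)


def generate_covered_net(
    n_places: int,
    n_transitions: int,
    n_circuits: int,
    seed: int,
    max_tries: int = 50,
) -> PetriNet:
    """Random ordinary, pure, connected net covered by t-invariants.

    Built as a union of ``n_circuits`` directed circuits that share vertices;
    each circuit receives one initial token on its entry place so the token
    game is live.  Purity can be violated by chance when circuits overlap, in
    which case generation retries with a derived seed; reproducible for a
    given ``seed``.
    """
    if n_places < 1 or n_transitions < 1 or n_circuits < 1:
        raise ValueError("all parameters must be positive")
    _check_feasible(n_places, n_transitions, n_circuits)
    for attempt in range(max_tries):
        rng = np.random.default_rng([seed, attempt])
        try:
            net = _build_circuits(n_places, n_transitions, n_circuits, rng)
        except ValueError:
            net = None
        if net is not None:
            return net
    raise ValueError(
        f"could not generate a pure covered net for n_places={n_places}, "
        f"n_transitions={n_transitions}, n_circuits={n_circuits}"
    )


def generate_block_support_matrix(
    n_invariants: int,
    block_spec: Sequence[tuple[int, Sequence[int]]],
    noise: float = 0.0,
    seed: int = 0,
) -> tuple[SupportMatrix, tuple[tuple[str, ...], ...]]:
    """Binary matrix with planted MCT blocks.

    ``block_spec`` lists ``(block_size, invariant_row_indices)`` pairs; each
    block contributes ``block_size`` transition columns whose occurrence
    pattern is the indicator of the given row subset.  Two blocks with the
    same row subset would be indistinguishable (one merged MCT set) and are
    rejected.  ``noise`` flips each cell independently with that probability.
    Returns the matrix and the planted partition as column-label groups.
    """
    if not 0 <= noise < 1:
        raise ValueError("noise must be in [0, 1)")
    seen: set[frozenset[int]] = set()
    columns: list[np.ndarray] = []
    planted: list[tuple[str, ...]] = []
    label = 0
    for size, rows_subset in block_spec:
        key = frozenset(int(r) for r in rows_subset)
        if not key:
            raise ValueError("a block must occur in at least one invariant")
        if any(r < 0 or r >= n_invariants for r in key):
            raise ValueError("block invariant index out of range")
        if key in seen:
            raise ValueError("overlapping blocks: two blocks share one row subset")
        if size < 1:
            raise ValueError("block size must be >= 1")
        seen.add(key)
        col = np.zeros(n_invariants, dtype=np.int8)
        col[sorted(key)] = 1
        group = []
        for _ in range(size):
            columns.append(col.copy())
            group.append(f"t{label}")
            label += 1
        planted.append(tuple(group))
    entries = np.stack(columns, axis=1)
    rng = np.random.default_rng(seed)
    if noise > 0:
        flips = rng.random(entries.shape) < noise
        entries = np.where(flips, 1 - entries, entries).astype(np.int8)
    matrix = SupportMatrix(
        entries,
        tuple(f"x{i + 1}" for i in range(n_invariants)),
        tuple(f"t{j}" for j in range(entries.shape[1])),
    )
    return matrix, tuple(planted)


def _read_packaged_csv(name: str) -> list[dict[str, str]]:
    text = resources.files("angiopn.data").joinpath(name).read_text()
    return list(csv.DictReader(text.splitlines()))


def load_angiogenesis_fixture() -> tuple[
    SupportMatrix, dict[str, tuple[str, ...]], pd.DataFrame
]:
    """The published angiogenesis model's t-invariant support data.

    Returns the 48 x 74 binary support matrix (rows x1..x48, columns
    t0..t73), the 11 non-trivial MCT sets (m1..m11 -> member transitions),
    and the 26-row expected structural knockout ranking (unit,
    affected_percent) for cross-checking.
    """
    mct_rows = _read_packaged_csv("mct_sets.csv")
    mct_sets = {
        row["set"]: tuple(row["transitions"].split()) for row in mct_rows
    }
    comp_rows = _read_packaged_csv("t_invariant_composition.csv")
    transitions = tuple(f"t{j}" for j in range(74))
    t_index = {t: j for j, t in enumerate(transitions)}
    entries = np.zeros((len(comp_rows), 74), dtype=np.int8)
    row_labels = []
    for i, row in enumerate(comp_rows):
        row_labels.append(row["invariant"])
        support: set[str] = set()
        for m in row["mct_sets"].split():
            support.update(mct_sets[m])
        support.update(row["single_transitions"].split())
        for t in support:
            entries[i, t_index[t]] = 1
    matrix = SupportMatrix(entries, tuple(row_labels), transitions)
    expected = pd.DataFrame(_read_packaged_csv("knockout_expected.csv"))
    expected["affected_percent"] = expected["affected_percent"].astype(float)
    return matrix, mct_sets, expected
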