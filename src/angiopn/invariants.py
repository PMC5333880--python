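"""Minimal t- and p-invariants of a Petri net, supports, coverage, feasibility.

A t-invariant is a non-negative integer vector x with A*x = 0: firing each
transition t_j the x_j-th number of times reproduces the marking, so the
support supp(x) = {t_j : x_j > 0} delimits a self-contained subprocess.
A p-invariant is a non-negative integer y with A^T*y = 0, a weighted token
conservation law over its place support.  Only *minimal* invariants are
computed — those whose support contains no other invariant's support — since
every invariant is a non-negative combination of minimal ones.

The computation is the classical Fourier-Motzkin / Farkas tableau on
[A^T | I]: place rows are eliminated one at a time by forming all
non-negative combinations of opposite-sign row pairs, with support-superset
pruning after every elimination step and gcd normalisation throughout.
All arithmetic is exact (Python integers); every returned vector is verified
against A before being returned.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import gcd
from typing import Iterable, Sequence

import numpy as np

from .core_net import IncidenceMatrix, PetriNet, build_incidence_matrix

__all__ = [
    "TInvariant",
    "PInvariant",
    "SupportMatrix",
    "InvariantLimitError",
    "minimal_t_invariants",
    "minimal_p_invariants",
    "build_support_matrix",
    "check_coverage",
    "FeasibilityReport",
    "feasibility_preconditions",
]


class InvariantLimitError(RuntimeError):
    """Tableau grew beyond the configured row limit; carries the count reached."""

    def __init__(self, count: int, limit: int):
        super().__init__(
            f"invariant tableau exceeded limit: {count} rows > {limit}"
        )
        self.count = count
        self.limit = limit


@dataclass(frozen=True)
class TInvariant:
    """Minimal transition invariant: A*x = 0, gcd of entries 1."""

    coefficients: tuple[int, ...]
    support: tuple[str, ...]  # transition ids, in column order

    def __len__(self) -> int:
        return len(self.coefficients)


@dataclass(frozen=True)
class PInvariant:
    """Minimal place invariant: A^T*y = 0, gcd of entries 1."""

    coefficients: tuple[int, ...]
    support: tuple[str, ...]  # place ids, in row order


@dataclass(frozen=True)
class SupportMatrix:
    """Binary invariant x transition occurrence matrix (rows = invariants)."""

    entries: np.ndarray
    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]

    def __post_init__(self):
        arr = np.asarray(self.entries, dtype=np.int8)
        if arr.ndim != 2 or arr.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("support matrix shape/label mismatch")
        if not np.isin(arr, (0, 1)).all():
            raise ValueError("support matrix must be binary")
        arr.setflags(write=False)
        object.__setattr__(self, "entries", arr)

    @property
    def shape(self) -> tuple[int, int]:
        return self.entries.shape


# ---------------------------------------------------------------------------
# Fourier-Motzkin / Farkas elimination
# ---------------------------------------------------------------------------

def _vec_gcd(values: Iterable[int]) -> int:
    g = 0
    for v in values:
        g = gcd(g, abs(v))
        if g == 1:
            return 1
    return g or 1


def _prune_supports(rows: list[tuple[list[int], list[int], int]]):
    """Drop rows whose solution-part support strictly contains another's.

    Exact duplicates (same invariant part) collapse to one row.  Masks are
    Python-int bitsets over solution coordinates.
    """
    rows = sorted(rows, key=lambda r: bin(r[2]).count("1"))
    kept: list[tuple[list[int], list[int], int]] = []
    seen: set[tuple[int, ...]] = set()
    for row in rows:
        mask = row[2]
        dominated = False
        for k in kept:
            km = k[2]
            if km & mask == km and km != mask:
                dominated = True
                break
        if dominated:
            continue
        key = tuple(row[1])
        if key in seen:
            continue
        seen.add(key)
        kept.append(row)
    return kept


def _farkas_solve(mat: np.ndarray, limit: int) -> list[list[int]]:
    """All support-minimal non-negative integer solutions of mat @ x = 0.

    ``mat`` is n x m; returns gcd-normalised solution vectors of length m.
    """
    n, m = mat.shape
    # row = (residual over un-eliminated constraints, solution vector, mask)
    rows = [
        ([int(v) for v in mat[:, j]], [1 if i == j else 0 for i in range(m)], 1 << j)
        for j in range(m)
    ]
    remaining = list(range(n))
    while remaining:
        # eliminate the constraint with the fewest pos*neg combinations
        def cost(k: int) -> int:
            pos = sum(1 for r in rows if r[0][k] > 0)
            neg = sum(1 for r in rows if r[0][k] < 0)
            return pos * neg - (pos + neg)

        k = min(remaining, key=cost)
        remaining.remove(k)
        zero = [r for r in rows if r[0][k] == 0]
        pos = [r for r in rows if r[0][k] > 0]
        neg = [r for r in rows if r[0][k] < 0]
        new_rows = zero
        for rp in pos:
            a = rp[0][k]
            for rq in neg:
                b = -rq[0][k]
                res = [b * u + a * v for u, v in zip(rp[0], rq[0])]
                sol = [b * u + a * v for u, v in zip(rp[1], rq[1])]
                g = _vec_gcd(res + sol)
                if g > 1:
                    res = [v // g for v in res]
                    sol = [v // g for v in sol]
                new_rows.append((res, sol, rp[2] | rq[2]))
        rows = _prune_supports(new_rows)
        if len(rows) > limit:
            raise InvariantLimitError(len(rows), limit)
    # all constraints eliminated: every residual is zero by construction
    sols = []
    for res, sol, _mask in rows:
        if any(sol):
            g = _vec_gcd(sol)
            sols.append([v // g for v in sol])
    return sols


def _canonical(sols: list[list[int]]) -> list[list[int]]:
    def key(sol: list[int]):
        supp = tuple(j for j, v in enumerate(sol) if v > 0)
        return (len(supp), supp)

    return sorted(sols, key=key)


def minimal_t_invariants(
    A: IncidenceMatrix, limit: int = 100_000
) -> list[TInvariant]:
    """Complete set of minimal t-invariants of the net with incidence matrix ``A``.

    Output order is canonical: by support size, then lexicographic support
    (column-index order).  Raises :class:`InvariantLimitError` if the
    intermediate tableau exceeds ``limit`` rows.
    """
    sols = _canonical(_farkas_solve(A.entries, limit))
    out = []
    for sol in sols:
        x = np.array(sol, dtype=object)
        if not (A.entries @ x == 0).all():  # exact integer check
            raise AssertionError("computed vector is not a t-invariant")
        support = tuple(
            A.transition_ids[j] for j, v in enumerate(sol) if v > 0
        )
        out.append(TInvariant(tuple(sol), support))
    return out


def minimal_p_invariants(
    A: IncidenceMatrix, limit: int = 100_000
) -> list[PInvariant]:
    """Minimal p-invariants: solutions of A^T*y = 0 via the transposed tableau."""
    sols = _canonical(_farkas_solve(A.entries.T, limit))
    out = []
    for sol in sols:
        y = np.array(sol, dtype=object)
        if not (A.entries.T @ y == 0).all():
            raise AssertionError("computed vector is not a p-invariant")
        support = tuple(A.place_ids[i] for i, v in enumerate(sol) if v > 0)
        out.append(PInvariant(tuple(sol), support))
    return out


# ---------------------------------------------------------------------------
# Supports, coverage, feasibility
# ---------------------------------------------------------------------------

def build_support_matrix(
    invariants: Sequence[TInvariant],
    transition_ids: Sequence[str],
    row_labels: Sequence[str] | None = None,
) -> SupportMatrix:
    """Binary occurrence matrix; rows follow the given invariant order."""
    t_index = {t: j for j, t in enumerate(transition_ids)}
    entries = np.zeros((len(invariants), len(transition_ids)), dtype=np.int8)
    for i, inv in enumerate(invariants):
        if len(inv.coefficients) != len(transition_ids):
            raise ValueError("invariant dimension does not match transition count")
        for t in inv.support:
            entries[i, t_index[t]] = 1
    if row_labels is None:
        row_labels = [f"x{i + 1}" for i in range(len(invariants))]
    return SupportMatrix(entries, tuple(row_labels), tuple(transition_ids))


def check_coverage(matrix: SupportMatrix) -> tuple[bool, set[str]]:
    """Is every transition in at least one invariant support?"""
    col_hits = matrix.entries.sum(axis=0) if matrix.entries.size else np.zeros(
        len(matrix.col_labels)
    )
    uncovered = {
        matrix.col_labels[j] for j in range(len(matrix.col_labels)) if col_hits[j] == 0
    }
    return (not uncovered, uncovered)


@dataclass(frozen=True)
class FeasibilityReport:
    """Preconditions under which every minimal t-invariant is realisable.

    Non-feasible t-invariants can only arise from read arcs (net not pure) or
    from minimal p-invariants that hold too few tokens initially.  When the
    net is pure and has no p-invariants, all t-invariants may be treated as
    feasible; no reachability analysis is attempted.
    """

    has_read_arcs: bool
    empty_p_invariant_set: bool
    p_invariant_token_sums: tuple[int, ...]

    @property
    def all_feasible(self) -> bool:
        return not self.has_read_arcs and self.empty_p_invariant_set


def feasibility_preconditions(
    net: PetriNet, p_invariants: Sequence[PInvariant] | None = None
) -> FeasibilityReport:
    if p_invariants is None:
        p_invariants = minimal_p_invariants(build_incidence_matrix(net))
    has_read_arcs = any((dst, src) in net.arcs for (src, dst) in net.arcs)
    m0 = net.marking_vector().tokens
    sums = tuple(
        int(sum(c * int(m0[i]) for i, c in enumerate(inv.coefficients)))
        for inv in p_invariants
    )
    return FeasibilityReport(
        has_read_arcs=has_read_arcs,
        empty_p_invariant_set=len(p_invariants) == 0,
        p_invariant_token_sums=sums,
    )
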