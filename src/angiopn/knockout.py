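"""Knockout analysis: structural invariant ranking and stochastic token-game simulation.

Two complementary views of what breaks when a functional unit (a non-trivial
MCT set or a single transition) is disabled:

* *structural*: the percentage of minimal t-invariants whose support hits the
  disabled unit — subprocesses that can no longer run to completion; a pure
  ranking over the support matrix, no dynamics involved.
* *dynamic*: repeated stochastic token-game simulation.  In every step each
  enabled, non-disabled transition independently decides to fire with a fixed
  probability (default 50%); willing transitions are then resolved in a
  uniformly random order with enabledness re-checked before each individual
  firing, which guarantees token counts never go negative.  Firing fractions
  and token occupancies are averaged over many independent repetitions, and a
  knockout run is compared with an undisturbed reference run.

Transition statuses: ACTIVE (fired normally), OFFLINE (manually disabled),
KNOCKOUT (never disabled, but starved — zero firings in every repetition).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_net import NetValidationError, PetriNet
from .invariants import SupportMatrix
from .mct import MCTPartition

__all__ = [
    "KnockUnit",
    "knock_units_from_partition",
    "structural_knockout_table",
    "SimulationParams",
    "SimulationDataPackage",
    "run_simulation",
    "simulate_trajectory",
    "compare_simulation_packages",
]


def round_half_up(x: float, ndigits: int = 2) -> float:
    return float(Decimal(repr(x)).quantize(Decimal(10) ** -ndigits, ROUND_HALF_UP))


@dataclass(frozen=True)
class KnockUnit:
    """A named knockable activity: one MCT set or one trivial transition."""

    name: str
    transitions: tuple[str, ...]

    def __post_init__(self):
        if not self.transitions:
            raise ValueError(f"knock unit {self.name!r} has no transitions")


def knock_units_from_partition(partition: MCTPartition) -> list[KnockUnit]:
    """One unit per MCT set: non-trivial sets keep their m-names, trivial sets
    are named after their single transition."""
    units = []
    for name, members, trivial in zip(
        partition.names, partition.sets, partition.trivial_flags
    ):
        units.append(KnockUnit(members[0] if trivial else name, tuple(members)))
    return units


def structural_knockout_table(
    matrix: SupportMatrix, units: Sequence[KnockUnit]
) -> pd.DataFrame:
    """Percent of t-invariants whose support intersects each unit.

    Columns: unit, affected_percent (2 decimals, half-up), affected_count,
    affected_invariants (tuple of row labels).  Rows sorted by percentage
    descending, ties by unit name.  Every member of one MCT set hits exactly
    the same invariants, so listing the set once suffices.
    """
    col_index = {c: j for j, c in enumerate(matrix.col_labels)}
    n = len(matrix.row_labels)
    rows = []
    for unit in units:
        missing = [t for t in unit.transitions if t not in col_index]
        if missing:
            raise KeyError(
                f"unit {unit.name!r} references unknown transitions {missing}"
            )
        cols = [col_index[t] for t in unit.transitions]
        hit = matrix.entries[:, cols].any(axis=1)
        affected = tuple(
            matrix.row_labels[i] for i in range(n) if hit[i]
        )
        percent = 100.0 * len(affected) / n if n else 0.0
        rows.append(
            {
                "unit": unit.name,
                "affected_percent": round_half_up(percent, 2),
                "affected_count": len(affected),
                "affected_invariants": affected,
            }
        )
    df = pd.DataFrame(rows)
    return df.sort_values(
        ["affected_percent", "unit"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Token-game simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimulationParams:
    """Stochastic token-game settings.

    ``mode='sequential'`` resolves each step by firing willing transitions one
    by one in random order, re-checking enabledness on the evolving marking.
    ``mode='maximal'`` is a stricter synchronous variant: consumption is
    checked against the start-of-step marking (minus what earlier transitions
    in the random preference order already consumed) and production only
    becomes visible at the end of the step.
    """

    steps: int = 10_000
    repetitions: int = 4_000
    firing_probability: float = 0.5
    seed: int = 0
    disabled: frozenset[str] = field(default_factory=frozenset)
    mode: str = "sequential"

    def __post_init__(self):
        if self.steps < 1 or self.repetitions < 1:
            raise ValueError("steps and repetitions must be >= 1")
        if not 0 < self.firing_probability <= 1:
            raise ValueError("firing_probability must be in (0, 1]")
        if self.mode not in ("sequential", "maximal"):
            raise ValueError("mode must be 'sequential' or 'maximal'")
        object.__setattr__(self, "disabled", frozenset(self.disabled))


@dataclass(frozen=True)
class SimulationDataPackage:
    """Aggregated firing and token statistics over repeated simulations.

    ``firing_mean[j]`` is the fraction of steps in which transition j fired,
    averaged over repetitions (in [0, 1]); ``firing_std`` the standard
    deviation of that per-repetition fraction.  ``token_mean[i]`` is the mean
    end-of-step token count of place i, averaged over repetitions.
    """

    transition_ids: tuple[str, ...]
    place_ids: tuple[str, ...]
    firing_mean: np.ndarray
    firing_std: np.ndarray
    token_mean: np.ndarray
    token_std: np.ndarray
    statuses: tuple[str, ...]
    params: SimulationParams

    def status_of(self, t: str) -> str:
        return self.statuses[self.transition_ids.index(t)]

    def firing_chance(self, t: str) -> float:
        return float(self.firing_mean[self.transition_ids.index(t)])

    def transitions_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "transition": self.transition_ids,
                "status": self.statuses,
                "firing_mean": self.firing_mean,
                "firing_std": self.firing_std,
            }
        )

    def places_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "place": self.place_ids,
                "token_mean": self.token_mean,
                "token_std": self.token_std,
            }
        )


def _simulate_once(
    rng: np.random.Generator,
    m0: np.ndarray,
    pre: np.ndarray,
    post: np.ndarray,
    steps: int,
    p: float,
    disabled_mask: np.ndarray,
    maximal: bool,
    full_output: bool = False,
):
    """One repetition; returns (per-transition firing fraction, per-place mean tokens)."""
    n, m = pre.shape
    tokens = m0.copy()
    fired = np.zeros(m, dtype=np.int64)
    token_sum = np.zeros(n, dtype=np.float64)
    delta = post - pre
    for _ in range(steps):
        enabled = (tokens[:, None] >= pre).all(axis=0)
        willing = enabled & ~disabled_mask & (rng.random(m) < p)
        idx = np.nonzero(willing)[0]
        if idx.size:
            rng.shuffle(idx)
            if maximal:
                consumed = np.zeros(n, dtype=np.int64)
                produced = np.zeros(n, dtype=np.int64)
                for j in idx:
                    if ((tokens - consumed) >= pre[:, j]).all():
                        consumed += pre[:, j]
                        produced += post[:, j]
                        fired[j] += 1
                tokens = tokens - consumed + produced
            else:
                for j in idx:
                    if (tokens >= pre[:, j]).all():
                        tokens = tokens + delta[:, j]
                        fired[j] += 1
        if (tokens < 0).any():  # defensive; semantics should make this impossible
            raise AssertionError("negative token count during simulation")
        token_sum += tokens
    if full_output:
        return fired / steps, token_sum / steps, fired, tokens
    return fired / steps, token_sum / steps


def _net_matrices(net: PetriNet) -> tuple[np.ndarray, np.ndarray]:
    n, m = net.n_places, net.n_transitions
    p_index = {p: i for i, p in enumerate(net.place_ids)}
    t_index = {t: j for j, t in enumerate(net.transition_ids)}
    pre = np.zeros((n, m), dtype=np.int64)
    post = np.zeros((n, m), dtype=np.int64)
    for (src, dst), w in net.arcs.items():
        if src in p_index:
            pre[p_index[src], t_index[dst]] += w
        else:
            post[p_index[dst], t_index[src]] += w
    return pre, post


def simulate_trajectory(
    net: PetriNet, params: SimulationParams, repetition: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Single repetition at full resolution: (per-transition firing counts,
    final marking).  Useful for verifying the state equation
    ``final = M0 + A @ counts``; uses the same generator derivation as
    :func:`run_simulation`, so repetition ``r`` here reproduces repetition
    ``r`` there.
    """
    pre, post = _net_matrices(net)
    disabled_mask = np.array(
        [t in params.disabled for t in net.transition_ids], dtype=bool
    )
    rng = np.random.default_rng([params.seed, repetition])
    fired_fraction, _token_mean, fired, final = _simulate_once(
        rng,
        net.marking_vector().tokens.copy(),
        pre,
        post,
        params.steps,
        params.firing_probability,
        disabled_mask,
        params.mode == "maximal",
        full_output=True,
    )
    return fired, final


def run_simulation(net: PetriNet, params: SimulationParams) -> SimulationDataPackage:
    """Repeated stochastic token-game runs from the net's initial marking.

    Each repetition uses its own generator derived from ``params.seed`` and
    the repetition index, so results are reproducible and repetitions are
    order-independent.
    """
    unknown = params.disabled - set(net.transition_ids)
    if unknown:
        raise NetValidationError(f"disabled transitions not in net: {sorted(unknown)}")
    n, m = net.n_places, net.n_transitions
    pre, post = _net_matrices(net)
    m0 = net.marking_vector().tokens.copy()
    disabled_mask = np.array(
        [t in params.disabled for t in net.transition_ids], dtype=bool
    )
    firing = np.empty((params.repetitions, m))
    tokens = np.empty((params.repetitions, n))
    for rep in range(params.repetitions):
        rng = np.random.default_rng([params.seed, rep])
        firing[rep], tokens[rep] = _simulate_once(
            rng,
            m0,
            pre,
            post,
            params.steps,
            params.firing_probability,
            disabled_mask,
            params.mode == "maximal",
        )
    statuses = []
    total_fires = firing.sum(axis=0)
    for j, t in enumerate(net.transition_ids):
        if disabled_mask[j]:
            statuses.append("OFFLINE")
        elif total_fires[j] == 0:
            statuses.append("KNOCKOUT")
        else:
            statuses.append("ACTIVE")
    return SimulationDataPackage(
        transition_ids=net.transition_ids,
        place_ids=net.place_ids,
        firing_mean=firing.mean(axis=0),
        firing_std=firing.std(axis=0, ddof=0),
        token_mean=tokens.mean(axis=0),
        token_std=tokens.std(axis=0, ddof=0),
        statuses=tuple(statuses),
        params=params,
    )


def compare_simulation_packages(
    reference: SimulationDataPackage, knockout: SimulationDataPackage
) -> pd.DataFrame:
    """Reference / knockout / difference table per transition.

    Differences (knockout minus reference, in percentage points of firing
    chance) are reported only for transitions that stayed ACTIVE in the
    knockout run; OFFLINE and KNOCKOUT rows carry the status label in the
    ``difference`` column instead, mirroring the usual report layout.
    """
    if reference.transition_ids != knockout.transition_ids:
        raise ValueError("packages describe different transition sets")
    rows = []
    for j, t in enumerate(reference.transition_ids):
        status = knockout.statuses[j]
        ref = 100.0 * float(reference.firing_mean[j])
        ko = 100.0 * float(knockout.firing_mean[j])
        rows.append(
            {
                "transition": t,
                "status": status,
                "reference": round_half_up(ref, 2),
                "knockout": round_half_up(ko, 2),
                "difference": round_half_up(ko - ref, 2)
                if status == "ACTIVE"
                else "disabled",
            }
        )
    return pd.DataFrame(rows)
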