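import numpy as np
import pytest

from angiopn.core_net import PetriNet, build_incidence_matrix
from angiopn.invariants import SupportMatrix
from angiopn.knockout import (
    KnockUnit,
    SimulationParams,
    compare_simulation_packages,
    knock_units_from_partition,
    run_simulation,
    simulate_trajectory,
    structural_knockout_table,
)
from angiopn.mct import compute_mct_sets


def random_support(rng, n=8, m=10):
    return SupportMatrix(
        rng.integers(0, 2, size=(n, m)).astype("int8"),
        tuple(f"x{i}" for i in range(n)),
        tuple(f"t{j}" for j in range(m)),
    )


class TestStructural:
    def test_unit_hitting_no_support_scores_zero(self):
        matrix = SupportMatrix(
            np.array([[1, 0], [1, 0]], dtype="int8"), ("x1", "x2"), ("t0", "t1")
        )
        table = structural_knockout_table(matrix, [KnockUnit("t1", ("t1",))])
        assert table.iloc[0]["affected_percent"] == 0.0

    def test_percent_is_fraction_of_hit_invariants(self):
        matrix = SupportMatrix(
            np.array([[1, 0], [1, 1], [0, 1]], dtype="int8"),
            ("x1", "x2", "x3"),
            ("t0", "t1"),
        )
        table = structural_knockout_table(
            matrix, [KnockUnit("t0", ("t0",)), KnockUnit("t1", ("t1",))]
        )
        by_unit = table.set_index("unit")["affected_percent"]
        assert by_unit["t0"] == pytest.approx(66.67)
        assert by_unit["t1"] == pytest.approx(66.67)

    def test_members_of_one_mct_set_have_identical_impact(self):
        rng = np.random.default_rng(61)
        matrix = random_support(rng)
        partition = compute_mct_sets(matrix)
        for members in partition.sets:
            units = [KnockUnit(t, (t,)) for t in members]
            table = structural_knockout_table(matrix, units)
            assert table["affected_percent"].nunique() == 1

    def test_superset_unit_never_scores_lower(self):
        rng = np.random.default_rng(62)
        matrix = random_support(rng)
        ts = matrix.col_labels
        small = KnockUnit("small", ts[:2])
        large = KnockUnit("large", ts[:5])
        table = structural_knockout_table(matrix, [small, large]).set_index("unit")
        assert (
            table.loc["large", "affected_percent"]
            >= table.loc["small", "affected_percent"]
        )

    def test_rows_sorted_by_impact_then_name(self):
        rng = np.random.default_rng(63)
        matrix = random_support(rng)
        units = [KnockUnit(t, (t,)) for t in matrix.col_labels]
        table = structural_knockout_table(matrix, units)
        keys = list(zip(-table["affected_percent"], table["unit"]))
        assert keys == sorted(keys)

    def test_unknown_transition_in_unit_rejected(self):
        rng = np.random.default_rng(64)
        matrix = random_support(rng)
        with pytest.raises(KeyError, match="ghost"):
            structural_knockout_table(matrix, [KnockUnit("u", ("ghost",))])

    def test_units_from_partition_cover_all_classes(self):
        rng = np.random.default_rng(65)
        matrix = random_support(rng)
        partition = compute_mct_sets(matrix)
        units = knock_units_from_partition(partition)
        covered = {t for u in units for t in u.transitions}
        assert covered == {
            t for s in partition.sets for t in s
        }


@pytest.fixture
def source_chain():
    """t0 (no pre-places) -> p1 -> t1 -> p2 -> t2; t0 is a free source."""
    return PetriNet(
        ["p1", "p2"],
        ["t0", "t1", "t2"],
        [("t0", "p1", 1), ("p1", "t1", 1), ("t1", "p2", 1), ("p2", "t2", 1)],
    )


class TestSimulation:
    def test_same_seed_gives_bit_identical_packages(self, source_chain):
        params = SimulationParams(steps=100, repetitions=10, seed=5)
        a = run_simulation(source_chain, params)
        b = run_simulation(source_chain, params)
        assert (a.firing_mean == b.firing_mean).all()
        assert (a.token_mean == b.token_mean).all()
        assert a.statuses == b.statuses

    def test_disabled_transition_is_offline_with_zero_chance(self, source_chain):
        pkg = run_simulation(
            source_chain,
            SimulationParams(steps=100, repetitions=5, seed=1, disabled={"t1"}),
        )
        assert pkg.status_of("t1") == "OFFLINE"
        assert pkg.firing_chance("t1") == 0.0

    def test_free_source_fires_at_the_firing_probability(self, source_chain):
        """A transition with no pre-places is a Bernoulli(p) per step."""
        pkg = run_simulation(
            source_chain,
            SimulationParams(steps=1000, repetitions=50, seed=2),
        )
        p = 0.5
        se = np.sqrt(p * (1 - p) / (1000 * 50))
        assert abs(pkg.firing_chance("t0") - p) < 3 * se

    def test_disabling_the_source_starves_everything_downstream(self, source_chain):
        pkg = run_simulation(
            source_chain,
            SimulationParams(steps=200, repetitions=10, seed=3, disabled={"t0"}),
        )
        assert pkg.status_of("t0") == "OFFLINE"
        assert pkg.status_of("t1") == "KNOCKOUT"
        assert pkg.status_of("t2") == "KNOCKOUT"
        assert pkg.firing_chance("t1") == 0.0 and pkg.firing_chance("t2") == 0.0

    @pytest.mark.parametrize("mode", ["sequential", "maximal"])
    def test_state_equation_holds_for_full_trajectories(self, random_net, mode):
        params = SimulationParams(steps=300, repetitions=1, seed=9, mode=mode)
        fired, final = simulate_trajectory(random_net, params)
        A = build_incidence_matrix(random_net).entries
        expected = random_net.marking_vector().tokens + A @ fired
        assert final.tolist() == expected.tolist()
        assert (final >= 0).all()

    def test_token_means_never_negative(self, random_net):
        pkg = run_simulation(
            random_net, SimulationParams(steps=100, repetitions=5, seed=4)
        )
        assert (pkg.token_mean >= 0).all()

    def test_std_shrinks_roughly_with_sqrt_repetitions(self, source_chain):
        """Across-repetition SD of the mean is stable; the SE of the package
        mean shrinks ~1/sqrt(reps).  Compare aggregate SD at 100 vs 400 reps."""
        small = run_simulation(
            source_chain, SimulationParams(steps=200, repetitions=100, seed=6)
        )
        large = run_simulation(
            source_chain, SimulationParams(steps=200, repetitions=400, seed=6)
        )
        j = source_chain.transition_ids.index("t0")
        se_small = small.firing_std[j] / np.sqrt(100)
        se_large = large.firing_std[j] / np.sqrt(400)
        assert se_large < se_small
        assert se_small / se_large == pytest.approx(2.0, rel=0.5)

    def test_modes_differ_only_in_within_step_visibility(self, cycle_net):
        """Both conflict semantics are valid token games; with one token the
        loop fires at most one transition per step in either mode."""
        for mode in ("sequential", "maximal"):
            fired, final = simulate_trajectory(
                cycle_net,
                SimulationParams(steps=100, repetitions=1, seed=8, mode=mode),
            )
            assert final.sum() == 1  # token conserved by the loop p-invariant


class TestComparison:
    def test_package_compared_to_itself_is_all_zero(self, source_chain):
        pkg = run_simulation(
            source_chain, SimulationParams(steps=100, repetitions=5, seed=1)
        )
        table = compare_simulation_packages(pkg, pkg)
        assert (table["difference"] == 0.0).all()
        assert (table["status"] == "ACTIVE").all()

    def test_starved_transitions_labeled_not_differenced(self, source_chain):
        ref = run_simulation(
            source_chain, SimulationParams(steps=100, repetitions=5, seed=1)
        )
        ko = run_simulation(
            source_chain,
            SimulationParams(steps=100, repetitions=5, seed=1, disabled={"t0"}),
        )
        table = compare_simulation_packages(ref, ko).set_index("transition")
        assert table.loc["t0", "status"] == "OFFLINE"
        assert table.loc["t1", "status"] == "KNOCKOUT"
        assert table.loc["t1", "difference"] == "disabled"

    def test_mismatched_label_sets_rejected(self, source_chain, cycle_net):
        a = run_simulation(
            source_chain, SimulationParams(steps=10, repetitions=2, seed=1)
        )
        b = run_simulation(
            cycle_net, SimulationParams(steps=10, repetitions=2, seed=1)
        )
        with pytest.raises(ValueError, match="different transition"):
            compare_simulation_packages(a, b)
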