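"""Distance, linkage, silhouette and MSS against literal formula oracles and
scipy/sklearn reference implementations."""

import numpy as np
import pytest
import scipy.cluster.hierarchy as sch
from sklearn.metrics import silhouette_samples

from angiopn.clustering import (
    DistanceMatrix,
    agglomerate,
    cut_dendrogram,
    distance_matrix,
    evaluate_grid,
    mean_split_silhouette,
    silhouette_widths,
)
from angiopn.invariants import SupportMatrix


def literal_distance(x, y, metric, p=3.0):
    """Straight transcription of each metric's formula."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if metric == "binary":
        nz = (x != 0) | (y != 0)
        return 0.0 if not nz.any() else ((x != 0) != (y != 0))[nz].mean()
    if metric == "canberra":
        num, den = np.abs(x - y), np.abs(x) + np.abs(y)
        keep = den != 0
        return float((num[keep] / den[keep]).sum())
    if metric == "correlation":
        xc, yc = x - x.mean(), y - y.mean()
        return 1 - float(xc @ yc / (np.linalg.norm(xc) * np.linalg.norm(yc)))
    if metric == "uncentered":
        return 1 - float(x @ y / (np.linalg.norm(x) * np.linalg.norm(y)))
    if metric == "euclidean":
        return float(np.sqrt(((x - y) ** 2).sum()))
    if metric == "manhattan":
        return float(np.abs(x - y).sum())
    if metric == "maximum":
        return float(np.abs(x - y).max())
    if metric == "minkowski":
        return float((np.abs(x - y) ** p).sum() ** (1 / p))
    raise ValueError(metric)


def binary_support(rng, n=8, m=12):
    entries = rng.integers(0, 2, size=(n, m)).astype("int8")
    entries[:, 0] = 1  # avoid all-zero/constant-zero rows
    return SupportMatrix(
        entries, tuple(f"x{i}" for i in range(n)), tuple(f"t{j}" for j in range(m))
    )


@pytest.mark.parametrize(
    "metric",
    ["binary", "canberra", "correlation", "uncentered", "euclidean",
     "manhattan", "maximum", "minkowski"],
)
def test_each_metric_matches_its_literal_formula(metric):
    rng = np.random.default_rng(31)
    matrix = binary_support(rng)
    d = distance_matrix(matrix, metric, minkowski_p=3.0)
    n = len(matrix.row_labels)
    for i in range(n):
        for j in range(i + 1, n):
            expected = literal_distance(
                matrix.entries[i], matrix.entries[j], metric, p=3.0
            )
            assert d.values[i, j] == pytest.approx(expected, abs=1e-12)


def test_identical_rows_have_zero_distance_under_every_metric():
    entries = np.array([[1, 0, 1, 1], [1, 0, 1, 1], [0, 1, 1, 0]], dtype="int8")
    matrix = SupportMatrix(entries, ("a", "b", "c"), ("t0", "t1", "t2", "t3"))
    for metric in ["binary", "canberra", "correlation", "uncentered",
                   "euclidean", "manhattan", "maximum", "minkowski"]:
        d = distance_matrix(matrix, metric)
        assert d.values[0, 1] == pytest.approx(0.0, abs=1e-12), metric


def test_forced_small_example_values():
    matrix = SupportMatrix(
        np.array([[1, 1, 0, 0], [1, 0, 1, 0]], dtype="int8"),
        ("a", "b"),
        ("t0", "t1", "t2", "t3"),
    )
    assert distance_matrix(matrix, "binary").values[0, 1] == pytest.approx(2 / 3)
    assert distance_matrix(matrix, "manhattan").values[0, 1] == pytest.approx(2)
    assert distance_matrix(matrix, "maximum").values[0, 1] == pytest.approx(1)


def test_constant_row_under_correlation_falls_back_with_warning():
    matrix = SupportMatrix(
        np.array([[1, 1, 1], [1, 1, 1], [1, 0, 1]], dtype="int8"),
        ("a", "b", "c"),
        ("t0", "t1", "t2"),
    )
    with pytest.warns(UserWarning, match="constant"):
        d = distance_matrix(matrix, "correlation")
    assert d.values[0, 1] == 0.0  # identical constant rows
    assert d.values[0, 2] == 1.0  # constant vs anything else


def test_metric_proper_distances_satisfy_triangle_inequality():
    rng = np.random.default_rng(8)
    matrix = binary_support(rng, n=6)
    for metric in ["euclidean", "manhattan", "maximum", "minkowski"]:
        d = distance_matrix(matrix, metric).values
        n = len(d)
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    assert d[i, j] <= d[i, k] + d[k, j] + 1e-9


# ---------------------------------------------------------------------------
# agglomeration
# ---------------------------------------------------------------------------

def random_distance(rng, n):
    """Continuous random distances: ties almost surely absent, so any valid
    implementation must agree exactly."""
    x = rng.random((n, 4))
    from scipy.spatial.distance import pdist, squareform

    return DistanceMatrix(
        squareform(pdist(x)), tuple(f"e{i}" for i in range(n)), "euclidean"
    )


def brute_linkage_partitions(d: DistanceMatrix, kind: str):
    """Independent oracle: agglomerate by recomputing cluster distances from
    the raw pairwise matrix (min for single, max for complete) each round."""
    clusters = [frozenset([i]) for i in range(len(d))]
    partitions = {len(clusters): set(clusters)}
    agg = min if kind == "single" else max
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                val = agg(
                    d.values[i, j] for i in clusters[a] for j in clusters[b]
                )
                if best is None or val < best[0]:
                    best = (val, a, b)
        _, a, b = best
        merged = clusters[a] | clusters[b]
        clusters = [c for idx, c in enumerate(clusters) if idx not in (a, b)]
        clusters.append(merged)
        partitions[len(clusters)] = set(clusters)
    return partitions


def as_partition(assign, labels):
    groups = {}
    for lab in labels:
        groups.setdefault(assign[lab], set()).add(lab)
    return {frozenset(g) for g in groups.values()}


def test_two_points_merge_at_their_distance():
    d = DistanceMatrix(np.array([[0.0, 0.7], [0.7, 0.0]]), ("a", "b"), "test")
    for linkage in ["single", "complete", "average", "ward", "centroid"]:
        dend = agglomerate(d, linkage)
        assert len(dend.merges) == 1
        assert dend.merges[0][2] == pytest.approx(0.7)


@pytest.mark.parametrize("kind", ["single", "complete"])
def test_single_and_complete_match_exhaustive_recomputation(kind):
    rng = np.random.default_rng(41)
    for _ in range(10):
        d = random_distance(rng, 5)
        dend = agglomerate(d, kind)
        oracle = brute_linkage_partitions(d, kind)
        for k in range(1, 6):
            ours = as_partition(cut_dendrogram(dend, k), d.labels)
            expected = {
                frozenset(d.labels[i] for i in c) for c in oracle[k]
            }
            assert ours == expected, (kind, k)


@pytest.mark.parametrize(
    "ours,scipy_name",
    [("single", "single"), ("complete", "complete"), ("average", "average"),
     ("mcquitty", "weighted"), ("centroid", "centroid"), ("median", "median"),
     ("ward", "ward")],
)
def test_linkages_agree_with_scipy_on_tie_free_data(ours, scipy_name):
    from scipy.spatial.distance import squareform

    rng = np.random.default_rng(42)
    for _ in range(5):
        d = random_distance(rng, 8)
        dend = agglomerate(d, ours)
        Z = sch.linkage(squareform(d.values), method=scipy_name)
        assert [tuple(sorted((a, b))) for a, b, _h in dend.merges] == [
            tuple(sorted((int(r[0]), int(r[1])))) for r in Z
        ]
        assert [h for *_ab, h in dend.merges] == pytest.approx(
            list(Z[:, 2]), abs=1e-9
        )
        if ours in ("centroid", "median"):
            # inversions: scipy's cut_tree uses a different flattening rule
            # than undoing the last merges, so only the trees are compared
            continue
        for k in (2, 3, 5):
            flat = sch.cut_tree(Z, n_clusters=k).ravel()
            expected = {
                frozenset(
                    d.labels[i] for i in np.nonzero(flat == c)[0]
                )
                for c in np.unique(flat)
            }
            assert as_partition(cut_dendrogram(dend, k), d.labels) == expected


def test_monotone_linkages_have_nondecreasing_heights():
    rng = np.random.default_rng(43)
    d = random_distance(rng, 10)
    for linkage in ["single", "complete", "average", "mcquitty", "ward"]:
        heights = [h for *_ab, h in agglomerate(d, linkage).merges]
        assert all(a <= b + 1e-12 for a, b in zip(heights, heights[1:]))


class TestCut:
    def test_k_equals_one_and_n(self):
        rng = np.random.default_rng(44)
        d = random_distance(rng, 6)
        dend = agglomerate(d, "average")
        assert set(cut_dendrogram(dend, 1).values()) == {1}
        assert sorted(cut_dendrogram(dend, 6).values()) == [1, 2, 3, 4, 5, 6]

    def test_k_out_of_range_rejected(self):
        rng = np.random.default_rng(45)
        dend = agglomerate(random_distance(rng, 4), "average")
        with pytest.raises(ValueError):
            cut_dendrogram(dend, 0)
        with pytest.raises(ValueError):
            cut_dendrogram(dend, 5)

    def test_cutting_at_k_plus_one_refines_k(self):
        rng = np.random.default_rng(46)
        d = random_distance(rng, 9)
        dend = agglomerate(d, "complete")
        for k in range(1, 9):
            coarse = cut_dendrogram(dend, k)
            fine = cut_dendrogram(dend, k + 1)
            for a in d.labels:
                for b in d.labels:
                    if fine[a] == fine[b]:
                        assert coarse[a] == coarse[b]


# ---------------------------------------------------------------------------
# silhouettes / MSS
# ---------------------------------------------------------------------------

def test_silhouette_matches_sklearn_when_no_singletons():
    rng = np.random.default_rng(51)
    d = random_distance(rng, 12)
    assign = {lab: (i % 3) + 1 for i, lab in enumerate(d.labels)}
    ours = silhouette_widths(assign, d)
    ref = silhouette_samples(
        d.values, np.array([assign[lab] for lab in d.labels]), metric="precomputed"
    )
    for i, lab in enumerate(d.labels):
        assert ours[lab] == pytest.approx(ref[i], abs=1e-12)


def test_two_separated_blocks_score_one():
    vals = np.zeros((4, 4))
    vals[:2, 2:] = 1.0
    vals[2:, :2] = 1.0
    d = DistanceMatrix(vals, ("a", "b", "c", "d"), "test")
    assign = {"a": 1, "b": 1, "c": 2, "d": 2}
    assert all(v == 1.0 for v in silhouette_widths(assign, d).values())


def test_singleton_elements_get_zero():
    rng = np.random.default_rng(52)
    d = random_distance(rng, 5)
    assign = {lab: i + 1 if i < 2 else 3 for i, lab in enumerate(d.labels)}
    widths = silhouette_widths(assign, d)
    assert widths[d.labels[0]] == 0.0 and widths[d.labels[1]] == 0.0


def test_single_cluster_assignment_rejected():
    rng = np.random.default_rng(53)
    d = random_distance(rng, 4)
    with pytest.raises(ValueError, match="single cluster"):
        silhouette_widths({lab: 1 for lab in d.labels}, d)


def test_mss_weighted_mean_identity_and_range():
    rng = np.random.default_rng(54)
    for trial in range(5):
        d = random_distance(rng, 10)
        assign = {
            lab: int(v) + 1
            for lab, v in zip(d.labels, rng.integers(0, 4, size=10))
        }
        if len(set(assign.values())) < 2:
            continue
        mss, per = mean_split_silhouette(assign, d)
        sizes = {c: sum(1 for v in assign.values() if v == c) for c in per}
        weighted = sum(sizes[c] * per[c] for c in per) / sum(sizes.values())
        assert mss == pytest.approx(weighted, abs=1e-12)
        assert -1 <= mss <= 1
        assert all(-1 <= v <= 1 for v in per.values())


def test_all_singletons_score_zero():
    rng = np.random.default_rng(55)
    d = random_distance(rng, 5)
    assign = {lab: i + 1 for i, lab in enumerate(d.labels)}
    mss, per = mean_split_silhouette(assign, d)
    assert mss == 0.0 and all(v == 0.0 for v in per.values())


def test_grid_rows_equal_independent_component_calls():
    rng = np.random.default_rng(56)
    matrix = binary_support(rng, n=6, m=9)
    metrics = ["binary", "euclidean"]
    linkages = ["average", "complete"]
    ks = [2, 3, 4]
    grid = evaluate_grid(matrix, metrics, linkages, ks)
    assert len(grid) == len(metrics) * len(linkages) * len(ks)
    for _, row in grid.iterrows():
        d = distance_matrix(matrix, row["metric"])
        assign = cut_dendrogram(agglomerate(d, row["linkage"]), row["k"])
        mss, _ = mean_split_silhouette(assign, d)
        assert row["mss"] == pytest.approx(mss)
        sizes = {}
        for v in assign.values():
            sizes[v] = sizes.get(v, 0) + 1
        assert row["singletons"] == sum(1 for s in sizes.values() if s == 1)


def test_statistics_invariant_under_label_permutation():
    rng = np.random.default_rng(57)
    d = random_distance(rng, 8)
    assign = {lab: (i % 3) + 1 for i, lab in enumerate(d.labels)}
    relabeled = {lab: {1: 7, 2: 5, 3: 9}[c] for lab, c in assign.items()}
    a, pa = mean_split_silhouette(assign, d)
    b, pb = mean_split_silhouette(relabeled, d)
    assert a == pytest.approx(b)
    assert sorted(pa.values()) == pytest.approx(sorted(pb.values()))
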