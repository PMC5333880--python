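#!/usr/bin/env python
"""Cluster the t-invariants over a metric x linkage x k grid with MSS scoring.

Evaluates every distance metric and linkage over k = 2..20, writes the full
evaluation grid, and reports the two clusterings of interest: binary+UPGMA
cut at 11 (higher global MSS but one giant cluster) and correlation+UPGMA cut
at 13 (the interpretable choice).  Writes the chosen 13-cluster membership.
"""

import json
from collections import Counter
from pathlib import Path

from angiopn.clustering import (
    agglomerate,
    cut_dendrogram,
    distance_matrix,
    evaluate_grid,
    mean_split_silhouette,
)
from angiopn.net_io import read_support_csv

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    matrix = read_support_csv(RESULTS / "support_matrix.csv")
    grid = evaluate_grid(matrix, k_range=range(2, 21))
    grid_out = RESULTS / "clustering_grid.csv"
    grid.to_csv(grid_out, index=False)
    print(f"{len(grid)} (metric, linkage, k) evaluations -> {grid_out}")

    for metric, k in [("binary", 11), ("correlation", 13)]:
        d = distance_matrix(matrix, metric)
        assign = cut_dendrogram(agglomerate(d, "average"), k)
        mss, per = mean_split_silhouette(assign, d)
        sizes = sorted(Counter(assign.values()).values(), reverse=True)
        singletons = sum(1 for s in sizes if s == 1)
        print(f"{metric}+UPGMA k={k}: global MSS {mss:.4f}, "
              f"{singletons} singletons, cluster sizes {sizes}")
        if metric == "correlation":
            out = RESULTS / "clusters_correlation_upgma_k13.json"
            out.write_text(json.dumps(
                {"metric": metric, "linkage": "average", "k": k,
                 "mss_global": round(mss, 4),
                 "mss_per_cluster": {str(c): round(v, 2) for c, v in per.items()},
                 "assignment": assign},
                indent=1) + "\n")
            print(f"chosen clustering membership -> {out}")


if __name__ == "__main__":
    main()
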