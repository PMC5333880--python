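# angiopn — qualitative Petri-net analysis of angiogenesis regulation

`angiopn` re-implements, as a tested Python pipeline, the invariant-based
analysis workflow used to study a qualitative Petri-net model of the
molecular regulation of angiogenesis (HIF-1 oxygen sensing, VEGF, eNOS/NO
and TGF-β1 signalling).  It is aimed at systems biologists who model
processes as place/transition nets and want the standard structural
tool-chain — minimal invariants, functional-unit decomposition, invariant
clustering, and knockout screening — as reproducible library code rather
than a collection of GUI tools.

## The method

A Petri net is a 5-tuple *Q* = (*P*, *T*, *F*, *W*, *M*₀): places *P*
(compounds, states), transitions *T* (elementary processes), weighted arcs,
and an initial token marking.  Its incidence matrix *A* ∈ ℤ^(n×m) holds the
net token effect of each transition on each place.  The pipeline then runs:

1. **Minimal t-invariants** — non-negative integer solutions of *A·x* = 0
   whose supports contain no other solution's support, computed by
   Fourier–Motzkin/Farkas elimination on the tableau [*Aᵀ* | *I*] in exact
   integer arithmetic.  Each t-invariant is a self-contained subprocess;
   p-invariants (*Aᵀ·y* = 0) are token conservation laws and are computed
   dually.  Feasibility of all t-invariants follows when the net is pure (no
   read arcs) and has no p-invariants.
2. **MCT sets** — transitions occurring in exactly the same invariant
   supports form one maximal common transition set, the smallest functional
   unit; computed by hashing occurrence columns of the binary
   invariant × transition support matrix.
3. **t-clusters** — hierarchical clustering of the 0/1 support vectors over
   a grid of eight distance metrics (binary/Jaccard, Canberra, Pearson
   correlation, uncentered Pearson, Euclidean, Manhattan, maximum,
   Minkowski) and seven Lance–Williams linkages (UPGMA, McQuitty, median,
   single, complete, centroid, Ward), each cut scored by singleton count and
   a Mean-Split-Silhouette-style index (classical silhouette widths, with
   singleton clusters contributing 0).
4. **Knockout analysis** — *structural*: the percentage of t-invariants
   whose support hits a disabled unit; *dynamic*: repeated stochastic
   token-game simulation (each enabled transition fires with probability 0.5
   per step; conflicts resolved in uniformly random order) comparing a
   reference run against a run with transitions forced OFFLINE, flagging
   starved transitions as KNOCKOUT.

## Worked example

The 48 × 74 support matrix of the published angiogenesis model ships with
the package, reconstructed from the printed invariant/MCT tables:

```python
>>> from angiopn import (load_angiogenesis_fixture, compute_mct_sets,
...                      knock_units_from_partition, structural_knockout_table)
>>> matrix, mct_sets, expected = load_angiogenesis_fixture()
>>> matrix.shape
(48, 74)
>>> part = compute_mct_sets(matrix)
>>> len(part.nontrivial_sets)
11
>>> table = structural_knockout_table(matrix, knock_units_from_partition(part))
>>> table.head(3)[["unit", "affected_percent"]]
  unit  affected_percent
0  t12             85.42
1   m2             79.17
2  m11             66.67
```

Hypoxia (`t12`) invalidates 85.42 % of all subprocesses, the
mitogen-activated-kinase signalling unit (`m2`, 11 transitions) 79.17 % —
these are the model's most critical activities.  The same workflow is
scripted step by step under `analysis/` (run `01` … `05` in order; outputs
land in `results/`), and is available as a CLI:

```bash
angiopn mct --support results/support_matrix.csv --out mct.json
angiopn cluster --support results/support_matrix.csv \
    --metric correlation --linkage average -k 13 --out clusters.json
angiopn run --config analysis.toml        # full bundle with manifest
```

Nets are read from Snoopy `.spped` (read-only subset, logical places
merged), PNML, a native JSON dialect, or incidence-matrix CSV.  The
supplementary Snoopy file of the original study is not redistributable; when
a copy is placed at `data/external/angiogenesis.spped`, the invariant
computation and the dynamic knockout analysis run on the real net (63
places, 74 transitions) as well.

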