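"""End-to-end analysis orchestration: net -> invariants -> MCT -> clusters -> knockouts.

``run_full_analysis`` sequences the individual modules over a single input
(a net file or a precomputed support-matrix CSV) and writes a reproducible
report bundle: invariants CSV, MCT JSON, clustering-grid CSV, the chosen
clustering's membership JSON, the structural knockout CSV, and — when
simulation is enabled — reference/knockout simulation packages plus their
comparison table.  A manifest records parameters, seeds, and per-stage
status; every stage is a pure function of its inputs and the configuration,
so a rerun with the same config is bit-identical.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict
from pathlib import Path
from typing import Any, Mapping

from . import __version__
from .core_net import build_incidence_matrix, structural_report
from .clustering import agglomerate, cut_dendrogram, distance_matrix, evaluate_grid, mean_split_silhouette
from .invariants import (
    build_support_matrix,
    check_coverage,
    feasibility_preconditions,
    minimal_p_invariants,
    minimal_t_invariants,
)
from .knockout import (
    SimulationParams,
    compare_simulation_packages,
    knock_units_from_partition,
    run_simulation,
    structural_knockout_table,
)
from .mct import compute_mct_sets, mct_subnet_connected
from .net_io import read_net, read_support_csv, write_support_csv

__all__ = ["run_full_analysis", "load_config", "PipelineError"]

log = logging.getLogger(__name__)

DEFAULT_CONFIG: dict[str, Any] = {
    "net": None,  # path to a net file (spped/pnml/json/incidence-csv)
    "support": None,  # or path to a support-matrix CSV
    "outdir": "angiopn_out",
    "clustering": {
        "metric": "correlation",
        "linkage": "average",
        "k": 13,
        "grid": True,
        "k_min": 2,
        "k_max": 20,
    },
    "simulation": {
        "enabled": False,
        "steps": 10_000,
        "repetitions": 4_000,
        "firing_probability": 0.5,
        "seed": 0,
        "disable": [],
        "mode": "sequential",
    },
}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def load_config(path: str | Path) -> dict[str, Any]:
    """TOML configuration mirroring the CLI flags; missing keys take defaults."""
    import tomllib

    with open(path, "rb") as fh:
        user = tomllib.load(fh)
    config = json.loads(json.dumps(DEFAULT_CONFIG))
    for key, val in user.items():
        if isinstance(val, Mapping) and isinstance(config.get(key), dict):
            config[key].update(val)
        else:
            config[key] = val
    return config


def _dump_json(obj: Any, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=1, sort_keys=True) + "\n")


def run_full_analysis(config: Mapping[str, Any] | str | Path) -> dict[str, Any]:
    """Run every configured stage; returns the manifest (also written to disk)."""
    if isinstance(config, (str, Path)):
        config = load_config(config)
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))
    for key, val in config.items():
        if isinstance(val, Mapping) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    if not cfg["net"] and not cfg["support"]:
        raise ValueError("config must name a 'net' file or a 'support' CSV")
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "version": __version__,
        "config": cfg,
        "stages": {},
        "outputs": {},
    }

    def stage(name: str):
        def deco(fn):
            t0 = time.perf_counter()
            try:
                fn()
            except Exception as exc:
                manifest["stages"][name] = "failed"
                _dump_json(manifest, outdir / "manifest.json")
                raise PipelineError(name, exc) from exc
            manifest["stages"][name] = "ok"
            log.info("stage %s done in %.2fs", name, time.perf_counter() - t0)

        return deco

    state: dict[str, Any] = {}

    @stage("input")
    def _input():
        if cfg["net"]:
            net = read_net(cfg["net"])
            state["net"] = net
            rep = structural_report(net)
            manifest["outputs"]["structural_report"] = asdict(rep)
        else:
            state["matrix"] = read_support_csv(cfg["support"])

    if "net" in state:

        @stage("invariants")
        def _invariants():
            net = state["net"]
            A = build_incidence_matrix(net)
            t_invs = minimal_t_invariants(A)
            p_invs = minimal_p_invariants(A)
            matrix = build_support_matrix(t_invs, A.transition_ids)
            state["matrix"] = matrix
            write_support_csv(matrix, outdir / "t_invariants.csv")
            _dump_json(
                {
                    "t_invariants": [list(x.coefficients) for x in t_invs],
                    "p_invariants": [list(y.coefficients) for y in p_invs],
                    "transition_order": list(A.transition_ids),
                    "place_order": list(A.place_ids),
                },
                outdir / "invariant_coefficients.json",
            )
            covered, uncovered = check_coverage(matrix)
            feas = feasibility_preconditions(net, p_invs)
            manifest["outputs"]["invariants"] = {
                "n_t_invariants": len(t_invs),
                "n_p_invariants": len(p_invs),
                "covered": covered,
                "uncovered": sorted(uncovered),
                "all_feasible": feas.all_feasible,
            }

    @stage("mct")
    def _mct():
        matrix = state["matrix"]
        partition = compute_mct_sets(matrix)
        state["partition"] = partition
        payload = []
        for name, members, trivial in zip(
            partition.names, partition.sets, partition.trivial_flags
        ):
            entry = {"name": name, "members": list(members), "trivial": trivial}
            if "net" in state:
                entry["connected"] = mct_subnet_connected(state["net"], members)
            payload.append(entry)
        _dump_json(
            {"sets": payload, "uncovered": list(partition.uncovered_class)},
            outdir / "mct.json",
        )
        manifest["outputs"]["mct"] = {
            "n_sets": len(partition.sets),
            "n_nontrivial": sum(not t for t in partition.trivial_flags),
        }

    @stage("clustering")
    def _clustering():
        matrix = state["matrix"]
        ccfg = cfg["clustering"]
        if ccfg.get("grid", True):
            grid = evaluate_grid(
                matrix, k_range=range(ccfg["k_min"], ccfg["k_max"] + 1)
            )
            grid.to_csv(outdir / "clustering_grid.csv", index=False)
        d = distance_matrix(matrix, ccfg["metric"])
        dend = agglomerate(d, ccfg["linkage"])
        assign = cut_dendrogram(dend, ccfg["k"])
        mss, per_cluster = mean_split_silhouette(assign, d)
        _dump_json(
            {
                "metric": ccfg["metric"],
                "linkage": ccfg["linkage"],
                "k": ccfg["k"],
                "assignment": assign,
                "mss_global": round(mss, 4),
                "mss_per_cluster": {str(c): round(v, 2) for c, v in per_cluster.items()},
            },
            outdir / "clusters.json",
        )
        manifest["outputs"]["clustering"] = {"mss_global": round(mss, 4)}

    @stage("knockout_structural")
    def _knockout():
        units = knock_units_from_partition(state["partition"])
        table = structural_knockout_table(state["matrix"], units)
        table.drop(columns=["affected_invariants"]).to_csv(
            outdir / "knockout_structural.csv", index=False
        )
        manifest["outputs"]["knockout_structural"] = {
            "top_unit": table.iloc[0]["unit"],
            "top_percent": float(table.iloc[0]["affected_percent"]),
        }

    if cfg["simulation"]["enabled"]:
        if "net" not in state:
            raise PipelineError(
                "simulation", ValueError("simulation requires a net input")
            )

        @stage("simulation")
        def _simulation():
            scfg = cfg["simulation"]
            base = dict(
                steps=scfg["steps"],
                repetitions=scfg["repetitions"],
                firing_probability=scfg["firing_probability"],
                seed=scfg["seed"],
                mode=scfg["mode"],
            )
            ref = run_simulation(state["net"], SimulationParams(**base))
            ref.transitions_frame().to_csv(outdir / "sim_reference_transitions.csv", index=False)
            ref.places_frame().to_csv(outdir / "sim_reference_places.csv", index=False)
            if scfg["disable"]:
                ko = run_simulation(
                    state["net"],
                    SimulationParams(**base, disabled=frozenset(scfg["disable"])),
                )
                comparison = compare_simulation_packages(ref, ko)
                comparison.to_csv(outdir / "sim_comparison.csv", index=False)

    _dump_json(manifest, outdir / "manifest.json")
    return manifest
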