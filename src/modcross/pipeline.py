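"""End-to-end orchestration: simulate / DEG / modules / crosstalk / pivots /
enrichment, with one global seed, per-stage derived streams, and a run
manifest (input checksums, parameters, seed, output paths) that suffices to
re-run the pipeline bit-compatibly.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import networkx as nx
import numpy as np
import yaml

from . import crosstalk as ct
from . import degs as dg
from . import enrichment as en
from . import interactome as ia
from . import mcode as mc
from . import regulators as rg
from . import synthetic as syn

logger = logging.getLogger(__name__)

CONTEXTS = syn.CONTEXTS


@dataclass
class PipelineConfig:
    """Paths and thresholds for a full run; defaults follow the study design
    (1% DEG FDR, 0.9 score cutoff, 1000 random networks, 0.05 alphas)."""

    rng_seed: int = 0
    expression: dict[str, list[dict[str, str]]] = field(default_factory=dict)
    edges: str = ""
    regulators: list[dict[str, str]] = field(default_factory=list)
    gmt: str | None = None
    outdir: str = "out"

    fdr_target: float = 0.01
    n_permutations: int = 100
    s0: float | None = None
    score_cutoff: float = 0.9
    mcode: mc.MCODEParams = field(default_factory=mc.MCODEParams)
    n_random: int = 1000
    swaps_per_edge: int = 10
    crosstalk_alpha: float = 0.05
    pivot_min_targets: int = 3
    pivot_alpha: float = 0.05
    enrichment_fdr: float = 0.05

    def validate(self) -> None:
        for alpha in (self.fdr_target, self.crosstalk_alpha, self.pivot_alpha,
                      self.enrichment_fdr):
            if not 0.0 < alpha < 1.0:
                raise ValueError(f"alpha/FDR {alpha} outside (0,1)")
        missing = [p for p in self.input_paths() if not Path(p).exists()]
        if missing:
            raise FileNotFoundError(f"missing input path(s): {missing}")

    def input_paths(self) -> list[str]:
        paths: list[str] = []
        for context in self.expression:
            for entry in self.expression[context]:
                paths += [entry["matrix"], entry["labels"]]
        if self.edges:
            paths.append(self.edges)
        for entry in self.regulators:
            paths.append(entry["path"])
        if self.gmt:
            paths.append(self.gmt)
        return paths

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        paths = raw.get("paths", {})
        params = raw.get("parameters", {})
        mcode_params = mc.MCODEParams(**params.pop("mcode", {}))
        return cls(
            rng_seed=int(raw.get("rng_seed", 0)),
            expression=paths.get("expression", {}),
            edges=paths.get("edges", ""),
            regulators=paths.get("regulators", []),
            gmt=paths.get("gmt"),
            outdir=paths.get("outdir", "out"),
            mcode=mcode_params,
            **params,
        )

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            "rng_seed": self.rng_seed,
            "paths": {
                "expression": self.expression,
                "edges": self.edges,
                "regulators": self.regulators,
                "gmt": self.gmt,
                "outdir": self.outdir,
            },
            "parameters": {
                "fdr_target": self.fdr_target,
                "n_permutations": self.n_permutations,
                "s0": self.s0,
                "score_cutoff": self.score_cutoff,
                "mcode": {
                    "node_score_cutoff": self.mcode.node_score_cutoff,
                    "k_core_min": self.mcode.k_core_min,
                    "haircut": self.mcode.haircut,
                    "fluff": self.mcode.fluff,
                    "fluff_density_cutoff": self.mcode.fluff_density_cutoff,
                    "max_depth": self.mcode.max_depth,
                },
                "n_random": self.n_random,
                "swaps_per_edge": self.swaps_per_edge,
                "crosstalk_alpha": self.crosstalk_alpha,
                "pivot_min_targets": self.pivot_min_targets,
                "pivot_alpha": self.pivot_alpha,
                "enrichment_fdr": self.enrichment_fdr,
            },
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=True)


def _stage_seed(rng_seed: int, stage: int, item: int = 0) -> int:
    return int(np.random.SeedSequence([rng_seed, stage, item]).generate_state(1)[0] % (2**31))


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


# ---------------------------------------------------------------------------
# simulate
# ---------------------------------------------------------------------------

def simulate(config: syn.SyntheticConfig, outdir: str | Path) -> dict[str, Any]:
    """Materialize a synthetic study (expression, edges, regulators, truth)
    plus a ready-to-run pipeline config referencing the artifacts."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    net, truth = syn.generate_interactome(config)
    datasets = syn.generate_expression(config, truth)
    rmap = syn.generate_regulator_map(config, truth)

    expression: dict[str, list[dict[str, str]]] = {c: [] for c in CONTEXTS}
    for ds in datasets:
        matrix = outdir / f"expression_{ds.dataset_id}.tsv"
        labels = outdir / f"labels_{ds.dataset_id}.tsv"
        dg.write_expression(ds, matrix, labels)
        context = ds.dataset_id.rsplit("_", 1)[0]
        expression[context].append({"matrix": str(matrix), "labels": str(labels)})

    edges_path = outdir / "edges.tsv"
    ia.write_edge_table(net, edges_path)
    reg_path = outdir / "regulators.tsv"
    syn.write_regulator_table(rmap, reg_path)
    truth_path = outdir / "truth.json"
    syn.write_truth(truth, truth_path)

    pconfig = PipelineConfig(
        rng_seed=config.rng_seed,
        expression=expression,
        edges=str(edges_path),
        regulators=[{"path": str(reg_path), "type": "mixed"}],
        outdir=str(outdir / "results"),
    )
    config_path = outdir / "pipeline_config.yaml"
    pconfig.to_yaml(config_path)
    return {
        "edges": str(edges_path),
        "regulators": str(reg_path),
        "truth": str(truth_path),
        "pipeline_config": str(config_path),
        "expression": expression,
    }


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_deg(config: PipelineConfig, outdir: Path) -> dict[str, dg.IntegratedDEGSet]:
    integrated = {}
    for ci, (context, entries) in enumerate(sorted(config.expression.items())):
        tables = []
        for i, entry in enumerate(entries):
            ds = dg.read_expression(entry["matrix"], entry["labels"])
            records = dg.call_degs(
                ds,
                fdr_target=config.fdr_target,
                n_permutations=config.n_permutations,
                rng_seed=_stage_seed(config.rng_seed, 1, ci * 1000 + i),
                s0=config.s0,
            )
            dg.write_deg_table(outdir / f"degs_{ds.dataset_id}.tsv", ds.dataset_id, records)
            tables.append((ds.dataset_id, records))
        integrated[context] = dg.integrate_degs(tables, context=context)
        dg.write_integrated_set(outdir / f"integrated_degs_{context}.tsv", integrated[context])
        logger.info("%s: %d integrated DEGs", context, len(integrated[context]))
    return integrated


def stage_modules(
    config: PipelineConfig,
    net: nx.Graph,
    integrated: dict[str, dg.IntegratedDEGSet],
    outdir: Path,
) -> dict[str, list[mc.GeneModule]]:
    modules = {}
    for context, degset in integrated.items():
        mapped = ia.map_degs(net, degset)
        mcc = ia.maximal_connected_component(mapped)
        found = mc.mcode_complexes(mcc, config.mcode, context=context)
        modules[context] = found
        mc.write_modules(outdir / f"modules_{context}.tsv", found)
        mc.write_module_sifs(mcc, found, outdir / "module_sif")
        ia.write_graphml(mcc, outdir / f"mcc_{context}.graphml")
        logger.info("%s: MCC %d nodes / %d edges, %d modules",
                    context, mcc.number_of_nodes(), mcc.number_of_edges(), len(found))
    return modules


def stage_crosstalk(
    config: PipelineConfig,
    net: nx.Graph,
    modules: dict[str, list[mc.GeneModule]],
    outdir: Path,
) -> list[ct.CrosstalkResult]:
    results = ct.crosstalk_test(
        net,
        modules.get(syn.INFLAMMATION, []),
        modules.get(syn.CANCER, []),
        n_random=config.n_random,
        rng_seed=_stage_seed(config.rng_seed, 2),
        swaps_per_edge=config.swaps_per_edge,
        alpha=config.crosstalk_alpha,
    )
    ct.write_crosstalk_table(outdir / "crosstalk.tsv", results)
    sig_graph = ct.significant_pair_graph(
        net, results, modules.get(syn.INFLAMMATION, []), modules.get(syn.CANCER, [])
    )
    ia.write_graphml(sig_graph, outdir / "crosstalk_significant.graphml")
    return results


def stage_pivots(
    config: PipelineConfig,
    net: nx.Graph,
    modules: dict[str, list[mc.GeneModule]],
    results: list[ct.CrosstalkResult],
    outdir: Path,
) -> list[rg.PivotResult]:
    significant = [r for r in results if r.significant]
    if not significant or not config.regulators:
        logger.info("no significant pairs or no regulator tables; pivot stage skipped")
        return []
    paths = [e["path"] for e in config.regulators]
    types = [e.get("type", rg.TF) for e in config.regulators]
    # generator-dialect files are self-labeling; the per-file label is a
    # fallback for 2-column tables
    rmap = rg.read_regulator_map(paths, [t if t in (rg.TF, rg.MIRNA) else rg.TF for t in types])
    all_modules = [m for mods in modules.values() for m in mods]
    background = set(net.nodes)
    pivots = rg.find_pivots(
        rmap, significant, all_modules, background,
        min_targets=config.pivot_min_targets, alpha=config.pivot_alpha,
    )
    rg.write_pivot_table(outdir / "pivots.tsv", pivots)
    layered = rg.pivot_layer_graph(pivots, rmap, all_modules, net)
    ia.write_graphml(layered, outdir / "pivots.graphml")
    return pivots


def stage_enrich(
    config: PipelineConfig,
    net: nx.Graph,
    modules: dict[str, list[mc.GeneModule]],
    outdir: Path,
) -> None:
    if not config.gmt:
        return
    annotations = en.read_gmt(config.gmt)
    background = set(net.nodes)
    with open(outdir / "enrichment.tsv", "w") as fh:
        fh.write("module_id\tterm\tdescription\tk\tK\tn\tN\tp\tq\tsignificant\n")
        for mods in modules.values():
            for m in mods:
                for r in en.enrich(set(m.members), annotations, background,
                                   fdr=config.enrichment_fdr):
                    fh.write(
                        f"{m.module_id[0]}:{m.module_id[1]}\t{r.term}\t{r.description}\t"
                        f"{r.overlap}\t{r.term_size}\t{r.query_size}\t{r.background_size}\t"
                        f"{r.p:.6g}\t{r.q:.6g}\t{int(r.significant)}\n"
                    )


# ---------------------------------------------------------------------------
# run-all
# ---------------------------------------------------------------------------

def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    input_checksums = {p: _sha256(p) for p in config.input_paths()}

    stage = "differential_expression"
    try:
        integrated = stage_deg(config, outdir)
        stage = "interactome"
        net = ia.read_interactions(config.edges, score_cutoff=config.score_cutoff)
        stage = "module_detection"
        modules = stage_modules(config, net, integrated, outdir)
        stage = "crosstalk"
        results = stage_crosstalk(config, net, modules, outdir)
        stage = "pivots"
        pivots = stage_pivots(config, net, modules, results, outdir)
        stage = "enrichment"
        stage_enrich(config, net, modules, outdir)
    except Exception:
        logger.error("pipeline aborted during stage %r; partial artifacts kept in %s",
                     stage, outdir)
        raise

    outputs = sorted(
        str(p) for p in outdir.rglob("*")
        if p.is_file() and p.name not in ("manifest.json", "run.log")
    )
    manifest = {
        "generated_at": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "rng_seed": config.rng_seed,
        "inputs": input_checksums,
        "outputs": {p: _sha256(p) for p in outputs},
        "parameters": {
            "fdr_target": config.fdr_target,
            "n_permutations": config.n_permutations,
            "s0": config.s0,
            "score_cutoff": config.score_cutoff,
            "n_random": config.n_random,
            "swaps_per_edge": config.swaps_per_edge,
            "crosstalk_alpha": config.crosstalk_alpha,
            "pivot_min_targets": config.pivot_min_targets,
            "pivot_alpha": config.pivot_alpha,
            "enrichment_fdr": config.enrichment_fdr,
            "mcode": {
                "node_score_cutoff": config.mcode.node_score_cutoff,
                "k_core_min": config.mcode.k_core_min,
                "haircut": config.mcode.haircut,
                "fluff": config.mcode.fluff,
                "fluff_density_cutoff": config.mcode.fluff_density_cutoff,
                "max_depth": config.mcode.max_depth,
            },
        },
        "summary": {
            "integrated_degs": {c: len(s) for c, s in integrated.items()},
            "modules": {c: len(m) for c, m in modules.items()},
            "crosstalk_pairs_tested": len(results),
            "crosstalk_pairs_significant": sum(r.significant for r in results),
            "pivot_combinations_tested": len(pivots),
            "pivots": len({p.regulator for p in pivots if p.is_pivot}),
        },
    }
    manifest_path = outdir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    manifest["manifest_path"] = str(manifest_path)
    return manifest
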