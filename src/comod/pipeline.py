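"""End-to-end orchestration of the synthetic workflow with provenance.

``run_pipeline`` executes the enabled stages in order — simulate, de,
decompose, modules, network, survival — writing each stage's outputs under
the run directory and a ``manifest.json`` with the echoed config, seeds,
package versions, per-stage wall times and the gene/sample counts at every
filter.  Stages are resumable: a disabled stage's outputs are read back
from a previous run in the same directory.

On real data the decomposition panel would be the consensus DE gene set;
in the synthetic demo the count and FPKM generators are independent
stand-ins, so the decomposition runs on the full simulated FPKM panel and
the DE stage reports its own planted-set recovery instead.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import __version__
from . import de as de_mod
from . import hogsvd, io, modules as mod_mod, network as net_mod
from . import simulate as sim_mod
from . import survival as surv_mod

logger = logging.getLogger("comod")

ALL_STAGES = ("simulate", "de", "decompose", "modules", "network", "survival")


@dataclass
class RunConfig:
    out_dir: str = "comod_run"
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    # stage parameters
    de_alpha: float = 0.05
    de_min_conditions: int = 4
    de_methods: tuple[str, ...] = de_mod.BUILTIN_METHODS
    ridge: float = 1e-6
    center: str = "gene"
    k_eigenvectors: int = 10
    q_cutoff: float = 0.001
    nmf_k: int = 2
    survival_alpha: float = 0.05
    min_hub_degree: int = 10
    use_linkers: bool = True
    sim: sim_mod.SimulationConfig | None = None

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise io.ValidationError(f"unknown stages: {sorted(unknown)}")
        if self.sim is None:
            self.sim = sim_mod.SimulationConfig(seed=self.seed)


def _jaccard(a: set, b: set) -> float:
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


def run_pipeline(config: RunConfig) -> Path:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": _config_dict(config),
        "versions": {"comod": __version__, "numpy": np.__version__},
        "stages": {},
    }
    state: dict = {}
    for stage in ALL_STAGES:
        if stage not in config.stages:
            continue
        t0 = time.perf_counter()
        logger.info("stage %s starting", stage)
        info = _STAGE_FUNCS[stage](config, out, state)
        dt = time.perf_counter() - t0
        manifest["stages"][stage] = {"wall_seconds": round(dt, 3), **(info or {})}
        logger.info("stage %s done in %.2fs", stage, dt)
    io.write_json(manifest, out / "manifest.json")
    return out


def _config_dict(config: RunConfig) -> dict:
    d = asdict(config)
    d["sim"] = asdict(config.sim)
    return d


# ---------------------------------------------------------------------------
# stages


def _stage_simulate(config: RunConfig, out: Path, state: dict) -> dict:
    sim = config.sim
    counts, count_truth = sim_mod.generate_count_panel(sim)
    fpkm, fpkm_truth = sim_mod.generate_fpkm_panel(sim)
    survival = sim_mod.generate_survival(sim, fpkm, fpkm_truth)
    edges = sim_mod.generate_edge_list(fpkm_truth, fpkm[0].gene_ids, seed=sim.seed)
    d = out / "simdata"
    for sub in ("counts", "fpkm", "clinical"):
        (d / sub).mkdir(parents=True, exist_ok=True)
    for m in counts:
        io.write_expression_matrix(m, d / "counts" / f"{m.condition_name}.tsv")
    for m in fpkm:
        io.write_expression_matrix(m, d / "fpkm" / f"{m.condition_name}.tsv")
    for t in survival:
        io.write_survival_table(t, d / "clinical" / f"{t.condition_name}.tsv")
    io.write_edge_list(edges, d / "edges.tsv")
    io.write_json({
        "seed": sim.seed,
        "shared_de_genes": count_truth.shared_de_genes,
        "module_genes": fpkm_truth.module_genes,
        "survival_effects": fpkm_truth.survival_effects,
    }, d / "truth.json")
    state.update(counts=counts, count_truth=count_truth, fpkm=fpkm,
                 fpkm_truth=fpkm_truth, survival=survival, edges=edges)
    return {
        "n_count_conditions": len(counts),
        "n_fpkm_conditions": len(fpkm),
        "p_counts": counts[0].n_genes,
        "p_fpkm": fpkm[0].n_genes,
    }


def _load_sim(config: RunConfig, out: Path, state: dict) -> None:
    if "fpkm" in state:
        return
    d = out / "simdata"
    if not d.exists():
        raise io.ValidationError(
            "no simulated data found; run the 'simulate' stage first"
        )
    state["counts"] = [
        io.read_expression_matrix(p, value_kind="raw_count",
                                  sample_class=None)
        for p in sorted((d / "counts").glob("*.tsv"))
    ]
    state["fpkm"] = [
        io.read_expression_matrix(p, value_kind="log2_fpkm")
        for p in sorted((d / "fpkm").glob("*.tsv"))
    ]
    state["survival"] = [
        io.read_survival_table(p) for p in sorted((d / "clinical").glob("*.tsv"))
    ]
    state["edges"] = io.read_edge_list(d / "edges.tsv")
    truth = json.loads((d / "truth.json").read_text())
    state["truth_json"] = truth


def _truth_modules(state: dict) -> list[list[str]]:
    if "fpkm_truth" in state:
        return state["fpkm_truth"].module_genes
    return state["truth_json"]["module_genes"]


def _truth_shared_de(state: dict) -> list[str]:
    if "count_truth" in state:
        return state["count_truth"].shared_de_genes
    return state["truth_json"]["shared_de_genes"]


def _stage_de(config: RunConfig, out: Path, state: dict) -> dict:
    _load_sim(config, out, state)
    cfg = de_mod.ConsensusConfig(
        alpha=config.de_alpha,
        min_conditions=config.de_min_conditions,
        methods=tuple(config.de_methods),
    )
    results = {
        m: [de_mod.run_builtin_de(mat, method=m) for mat in state["counts"]]
        for m in cfg.methods
    }
    candidate = de_mod.consensus_genes(results, cfg)
    io.write_gene_set(sorted(candidate), out / "candidate_genes.txt")
    truth = set(_truth_shared_de(state))
    jac = _jaccard(candidate, truth)
    logger.info("consensus DE: %d genes (planted-set Jaccard %.3f)",
                len(candidate), jac)
    state["candidate_genes"] = candidate
    return {"n_candidate_genes": len(candidate), "truth_jaccard": round(jac, 4)}


def _stage_decompose(config: RunConfig, out: Path, state: dict) -> dict:
    _load_sim(config, out, state)
    panel = io.align_gene_panels(state["fpkm"], state["fpkm"][0].gene_ids)
    est = hogsvd.HOGSVD(ridge=config.ridge, center=config.center).fit(panel)
    state["hogsvd"] = est.result_
    state["panel_genes"] = panel[0].gene_ids
    d = out / "hogsvd"
    d.mkdir(exist_ok=True)
    np.savetxt(d / "eigenvalues.tsv", est.eigenvalues_, fmt="%.12g")
    np.savetxt(d / "V.tsv", est.V_, fmt="%.12g", delimiter="\t")
    for name, sig in zip(est.condition_names_, est.sigmas_):
        np.savetxt(d / f"sigma_{name}.tsv", sig, fmt="%.12g")
    io.write_gene_set(panel[0].gene_ids, d / "genes.txt")
    io.write_json(est.diagnostics_, d / "diagnostics.json")
    return {"p": est.n_features_in_, "T": len(panel),
            "max_residual": est.diagnostics_["max_reconstruction_residual"]}


def _load_hogsvd(config: RunConfig, out: Path, state: dict) -> None:
    if "hogsvd" in state:
        return
    d = out / "hogsvd"
    if not d.exists():
        raise io.ValidationError("no decomposition found; run 'decompose' first")
    lam = np.loadtxt(d / "eigenvalues.tsv")
    V = np.loadtxt(d / "V.tsv", delimiter="\t")
    state["hogsvd"] = hogsvd.HogsvdResult(
        S=np.empty((0, 0)), eigenvalues=lam, V=V, U=[], sigmas=[], T=0,
    )
    state["panel_genes"] = io.read_gene_set(d / "genes.txt")


def _stage_modules(config: RunConfig, out: Path, state: dict) -> dict:
    _load_sim(config, out, state)
    _load_hogsvd(config, out, state)
    report = mod_mod.call_all_modules(
        state["hogsvd"], state["panel_genes"],
        k=config.k_eigenvectors, q_cutoff=config.q_cutoff, seed=config.seed,
    )
    d = out / "modules"
    d.mkdir(exist_ok=True)
    recovery = []
    truth_modules = [set(g) for g in _truth_modules(state)]
    for m in report.modules:
        io.write_gene_set(m.gene_ids, d / f"module_{m.eigenvector_index:02d}.txt")
        io.write_json(mod_mod.module_to_dict(m),
                      d / f"module_{m.eigenvector_index:02d}.json")
        best = max(
            (_jaccard(set(m.gene_ids), t) for t in truth_modules), default=0.0
        )
        recovery.append({
            "eigenvector_index": m.eigenvector_index,
            "n_genes": len(m),
            "best_truth_jaccard": round(best, 4),
        })
        logger.info("eigenvector %d: %d genes (best planted Jaccard %.3f)",
                    m.eigenvector_index, len(m), best)
    io.write_json({"recovery": recovery,
                   "overlap": report.overlap.tolist()}, d / "recovery.json")
    state["modules"] = report
    return {"n_modules_nonempty": len(report.non_empty()),
            "recovery": recovery}


def _load_modules(config: RunConfig, out: Path, state: dict) -> None:
    if "modules" in state:
        return
    d = out / "modules"
    if not d.exists():
        raise io.ValidationError("no modules found; run 'modules' first")
    state["module_gene_lists"] = {
        p.stem: io.read_gene_set(p) for p in sorted(d.glob("module_*.txt"))
        if p.stat().st_size
    }


def _module_gene_lists(state: dict) -> dict[str, list[str]]:
    if "modules" in state:
        return {
            f"module_{m.eigenvector_index:02d}": m.gene_ids
            for m in state["modules"].non_empty()
        }
    return state.get("module_gene_lists", {})


def _stage_network(config: RunConfig, out: Path, state: dict) -> dict:
    _load_sim(config, out, state)
    _load_modules(config, out, state)
    gene_lists = _module_gene_lists(state)
    d = out / "network"
    d.mkdir(exist_ok=True)
    summary = {}
    for name, genes in sorted(gene_lists.items()):
        net = net_mod.build_fi_subnetwork(genes, state["edges"],
                                          use_linkers=config.use_linkers)
        part = net_mod.cluster_network(net, seed=config.seed)
        hubs = net_mod.hub_genes(net, min_degree=config.min_hub_degree)
        frac = net_mod.connected_fraction(net)
        rows = ["gene\trole\tdegree\tsub_module"]
        for node in sorted(net.graph.nodes):
            rows.append(
                f"{node}\t{net.graph.nodes[node]['role']}\t"
                f"{net.graph.degree(node)}\t{part.labels[node]}"
            )
        (d / f"{name}_nodes.tsv").write_text("\n".join(rows) + "\n")
        io.write_json({
            "connected_fraction": frac,
            "modularity": part.modularity,
            "sub_module_sizes": net_mod.partition_sizes(part),
            "hub_genes": [{"gene": g, "degree": k, "role": r} for g, k, r in hubs],
        }, d / f"{name}_network.json")
        summary[name] = {"connected_fraction": round(frac, 4), "n_hubs": len(hubs)}
        logger.info("network %s: connected fraction %.3f, %d hubs, %d sub-modules",
                    name, frac, len(hubs),
                    len(part.sub_module_labels()))
    return summary


def _stage_survival(config: RunConfig, out: Path, state: dict) -> dict:
    _load_sim(config, out, state)
    _load_modules(config, out, state)
    gene_lists = _module_gene_lists(state)
    expr = {m.condition_name: m for m in state["fpkm"]}
    surv = {t.condition_name: t for t in state["survival"]}
    report = surv_mod.module_prognosis(
        gene_lists, expr, surv,
        k=config.nmf_k, alpha=config.survival_alpha, seed=config.seed,
    )
    d = out / "prognosis"
    d.mkdir(exist_ok=True)
    report.logrank.to_csv(d / "logrank.tsv", sep="\t", index=False)
    if report.cox is not None:
        report.cox.to_csv(d / "cox_scan.tsv", sep="\t", index=False)
    n_sig = int((report.logrank["p"] < config.survival_alpha).sum())
    logger.info("survival: %d/%d (condition, module) pairs significant at %.2g",
                n_sig, len(report.logrank), config.survival_alpha)
    state["prognosis"] = report
    return {"n_pairs": len(report.logrank), "n_significant": n_sig}


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "de": _stage_de,
    "decompose": _stage_decompose,
    "modules": _stage_modules,
    "network": _stage_network,
    "survival": _stage_survival,
}


def run_demo(out_dir: str, seed: int = 0) -> Path:
    """Full synthetic workflow at the default demonstration conditions."""
    return run_pipeline(RunConfig(out_dir=out_dir, seed=seed))
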