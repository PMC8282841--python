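"""End-to-end study workflow: simulate/load -> marker metrics -> diversity ->
distances and trees -> PCA -> admixture -> Evanno -> reports.

Each stage writes its report before the next starts, so a failure aborts
with the stage name while earlier outputs persist.  A run manifest records
the resolved configuration and seed; re-running with the same manifest
reproduces every output.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import admixture as adx
from .bandmatrix import read_band_matrix, write_band_matrix, write_popmap
from .distance import euclidean_matrix, identity_distance_report, pairwise_matrix, upgma, ward_linkage
from .diversity import partition_diversity, per_primer_diversity
from .markers import aggregate_metrics, panel_metrics
from .ordination import accession_shannon, pca
from .reports import round_floats, write_report
from .simulate import SimulationConfig, simulate_dataset
from .trees import write_newick

log = logging.getLogger("issrpop")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Fully serializable description of one pipeline run."""

    outdir: str = "issrpop_out"
    band_matrix: str | None = None          # path; None -> simulate
    popmap: str | None = None
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    seed: int = 0
    precision: int = 4
    distance_level: str = "individual"
    run_metrics: bool = True
    run_diversity: bool = True
    run_distance: bool = True
    run_pca: bool = True
    run_admixture: bool = True
    k_min: int = 1
    k_max: int = 6
    runs_per_k: int = 3
    admixture_config: adx.AdmixtureConfig = field(
        default_factory=lambda: adx.AdmixtureConfig(burnin=500, sweeps=1500)
    )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every enabled stage; returns the manifest dict."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": round_floats(cfg.to_dict()), "stages": {}}
    t0 = time.time()

    def stage(name: str):
        log.info("stage %s", name)
        return time.time()

    def done(name: str, t: float) -> None:
        manifest["stages"][name] = {"seconds": round(time.time() - t, 2)}

    # -- input -------------------------------------------------------------
    t = stage("input")
    if cfg.band_matrix is not None:
        if cfg.popmap is None:
            raise ValueError("a band matrix file needs a popmap")
        m = read_band_matrix(cfg.band_matrix, cfg.popmap)
        truth = None
    else:
        sim_cfg = dataclasses.replace(cfg.simulation, seed=cfg.seed)
        m, truth = simulate_dataset(sim_cfg)
        write_band_matrix(m, out / "band_matrix.csv")
        write_popmap(m.population_of, out / "popmap.csv")
        with open(out / "truth.json", "w") as fh:
            json.dump(
                round_floats(
                    {
                        "Q_true": truth.Q_true,
                        "F_k": truth.F_k,
                        "p_ancestral": truth.p_ancestral,
                        "seed": cfg.seed,
                    }
                ),
                fh,
                indent=1,
            )
    done("input", t)

    # -- marker metrics ----------------------------------------------------
    if cfg.run_metrics:
        t = stage("metrics")
        table = panel_metrics(m)
        table = pd.concat([table, aggregate_metrics(table)])
        write_report(table, out / "marker_metrics", "marker_metrics", cfg.precision)
        done("metrics", t)

    # -- diversity ---------------------------------------------------------
    if cfg.run_diversity:
        t = stage("diversity")
        table = per_primer_diversity(m)
        table = pd.concat([table, aggregate_metrics(table)])
        write_report(table, out / "diversity_per_primer", "diversity", cfg.precision)
        part = partition_diversity(m)
        with open(out / "diversity_partition.json", "w") as fh:
            json.dump(round_floats(part.summary().to_dict(), cfg.precision), fh, indent=1)
        done("diversity", t)

    # -- distance / trees --------------------------------------------------
    if cfg.run_distance:
        t = stage("distance")
        dist, ident = pairwise_matrix(m, cfg.distance_level)
        write_report(
            identity_distance_report(dist, ident),
            out / "nei_identity_distance",
            "nei_identity_distance",
            cfg.precision,
        )
        tree = upgma(dist.capped())
        (out / "upgma.nwk").write_text(write_newick(tree, cfg.precision) + "\n")
        eu = euclidean_matrix(m, "individuals")
        wtree = ward_linkage(eu)
        (out / "ward_rows.nwk").write_text(write_newick(wtree, cfg.precision) + "\n")
        (out / "heatmap_row_order.txt").write_text("\n".join(wtree.leaf_names) + "\n")
        done("distance", t)

    # -- ordination --------------------------------------------------------
    if cfg.run_pca:
        t = stage("pca")
        res = pca(m)
        write_report(res.summary(9), out / "pca_axes", "pca_axes", cfg.precision)
        scores = res.scores.iloc[:, :9].copy()
        scores["H_prime"] = accession_shannon(m)
        write_report(scores, out / "pca_scores", "pca_scores", cfg.precision)
        done("pca", t)

    # -- admixture / Evanno ------------------------------------------------
    if cfg.run_admixture:
        t = stage("admixture")
        runs = adx.fit_k_range(
            m,
            range(cfg.k_min, cfg.k_max + 1),
            runs=cfg.runs_per_k,
            config=cfg.admixture_config,
            seed=cfg.seed,
        )
        lnpds = {k: [r.lnpd for r in rs] for k, rs in runs.items()}
        ev = adx.evanno(lnpds)
        write_report(ev.table, out / "evanno", "evanno", cfg.precision)
        best = ev.best_k
        best_runs = runs[best]
        aligned, mean_q = adx.align_runs([r.Q for r in best_runs])
        qdf = pd.DataFrame(
            mean_q, index=m.individual_ids,
            columns=[f"cluster{k + 1}" for k in range(best)],
        )
        write_report(qdf, out / f"Q_K{best}", f"Q_K{best}", cfg.precision)
        net, het = adx.cluster_divergence(best_runs[0].P)
        div = pd.DataFrame(
            net, index=[f"cluster{k + 1}" for k in range(best)],
            columns=[f"cluster{k + 1}" for k in range(best)],
        )
        div["expected_het"] = het
        div["Fst"] = best_runs[0].F
        write_report(div, out / "cluster_divergence", "cluster_divergence", cfg.precision)
        cls = adx.classify_membership(mean_q, 0.60, m.individual_ids)
        write_report(cls, out / "membership", "membership", cfg.precision)
        manifest["stages"]["admixture"] = {"best_k": best}
        done("admixture", t)

    manifest["seed"] = cfg.seed
    manifest["total_seconds"] = round(time.time() - t0, 2)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return manifest
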