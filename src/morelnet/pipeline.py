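"""End-to-end orchestration of the analysis stages.

A run goes: simulate (or ingest) a genus-level count table -> rare-taxon
filter -> TSS normalization -> alpha diversity per sample -> Bray-Curtis
+ PERMANOVA on plot labels -> two-group differential abundance
(high-yield II vs low/no-yield III) -> per-group top-50 co-occurrence
networks. Every stage writes TSV (networks also GraphML) into the output
directory, and a key-value run report echoes every parameter, row/edge
counts and warnings so a run is auditable and reproducible from the
report alone.
"""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import abundance, alpha, beta, diffabund, io, network, simulate

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Configuration of a full pipeline run.

    Either ``count_table``/``metadata`` paths are given, or
    ``simulation`` (a :class:`~morelnet.simulate.SimulationConfig`) is
    used with the plot/replicate design. Stage toggles skip stages;
    parameters default to the study's settings (rare fraction 1e-5,
    top-N 50, |rho| >= 0.6, q < 0.05, 999/1000 permutations).
    """

    out_dir: str = "morelnet_out"
    count_table: str | None = None
    metadata: str | None = None
    taxonomy: str | None = None
    simulation: simulate.SimulationConfig | None = None
    n_plots: int = 23
    n_replicates: int = 4
    plot_sd: float = 0.5
    seed: int = 0
    rare_fraction: float = 1e-5
    top_n: int = 50
    r_cutoff: float = 0.6
    q_cutoff: float = 0.05
    permanova_permutations: int = 999
    diffabund_permutations: int = 1000
    keep_isolates: bool = False
    group_col: str = "plot"
    network_groups: tuple = ("II", "III")
    run_alpha: bool = True
    run_beta: bool = True
    run_diffabund: bool = True
    run_network: bool = True


def _file_hash(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()[:16]


def _write_report(report: dict, path: Path) -> None:
    with path.open("w", encoding="utf-8") as fh:
        for k, v in report.items():
            fh.write(f"{k}\t{v}\n")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages in dependency order.

    Returns the run report (also written to ``run_report.tsv``); any
    stage failure raises with the stage name. Reruns with the same
    config and seed reproduce all numeric outputs.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed}
    t0 = time.time()

    stage = "ingest"
    try:
        if config.count_table is not None:
            counts = io.read_count_table(config.count_table)
            report["input_hash"] = _file_hash(config.count_table)
            if config.metadata is None:
                raise ValueError("metadata path required with count_table input")
            meta = io.read_metadata(config.metadata)
            if config.taxonomy is not None:
                tax = io.read_taxonomy(config.taxonomy)
                counts = abundance.aggregate_to_genus(counts, tax)
        else:
            sim = config.simulation or simulate.SimulationConfig(seed=config.seed)
            counts, meta, _truth = simulate.emulate_study_design(
                sim, n_plots=config.n_plots, n_replicates=config.n_replicates,
                plot_sd=config.plot_sd, seed=config.seed,
            )
            io.write_count_table(counts, out / "simulated_counts.tsv")
            io.write_metadata(meta, out / "simulated_metadata.tsv")
        missing = [s for s in counts.columns if s not in meta.index]
        if missing:
            raise ValueError(f"samples missing from metadata: {missing}")
        if config.group_col not in meta.columns:
            raise ValueError(f"metadata lacks grouping column {config.group_col!r}")
        report["n_taxa_raw"] = counts.shape[0]
        report["n_samples"] = counts.shape[1]

        stage = "filter"
        counts = abundance.filter_rare(counts, config.rare_fraction)
        report["rare_fraction"] = config.rare_fraction
        report["n_taxa_filtered"] = counts.shape[0]
        report["dropped_taxa"] = ";".join(counts.attrs.get("dropped_taxa", []))

        stage = "normalize"
        abund = abundance.tss_normalize(counts)
        abund.to_csv(out / "relative_abundance.tsv", sep="\t")

        if config.run_alpha:
            stage = "alpha"
            at = alpha.alpha_table(counts)
            at.to_csv(out / "alpha_diversity.tsv", sep="\t")
            report["alpha_rows"] = len(at)

        if config.run_beta:
            stage = "beta"
            dm = beta.bray_curtis_matrix(abund)
            pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids).to_csv(
                out / "bray_curtis.tsv", sep="\t"
            )
            ord_res = beta.pca(abund, n_axes=2)
            ord_res.scores.to_csv(out / "pca_scores.tsv", sep="\t")
            labels = meta.loc[list(counts.columns), config.group_col]
            perm = beta.permanova(
                dm, labels, permutations=config.permanova_permutations,
                seed=config.seed,
            )
            perm.as_table(config.group_col).to_csv(out / "permanova.tsv", sep="\t")
            report["permanova_df_factor"] = perm.df_factor
            report["permanova_df_residual"] = perm.df_residual
            report["permanova_F"] = perm.pseudo_F
            report["permanova_R2"] = perm.R2
            report["permanova_p"] = perm.p_value

        group_samples = {
            g: [s for s in io.samples_in_analysis_group(meta, g) if s in counts.columns]
            for g in config.network_groups
        }

        if config.run_diffabund and all(len(v) >= 2 for v in group_samples.values()):
            stage = "diffabund"
            gII, gIII = config.network_groups
            cols = group_samples[gII] + group_samples[gIII]
            labels = {s: gII for s in group_samples[gII]}
            labels.update({s: gIII for s in group_samples[gIII]})
            da = diffabund.metastats_test(
                counts[cols], labels,
                permutations=config.diffabund_permutations, seed=config.seed,
            )
            da.to_csv(out / f"diffabund_{gII}_vs_{gIII}.tsv", sep="\t")
            report["diffabund_significant_q05"] = int((da["q"] < 0.05).sum())

        if config.run_network:
            stage = "network"
            for g, samples in group_samples.items():
                if len(samples) < 4:
                    log.warning("group %s has %d samples; skipping network", g, len(samples))
                    continue
                top = abundance.top_n_taxa(abund, n=config.top_n, samples=samples)
                sub = abund.loc[top, samples]
                cm = network.spearman_matrix(sub, seed=config.seed)
                net = network.build_network(
                    cm, r_cutoff=config.r_cutoff, q_cutoff=config.q_cutoff,
                    keep_isolates=config.keep_isolates,
                    abundance_means=sub.mean(axis=1).to_dict(),
                )
                assignment, q_mod, modules = network.detect_modules(net)
                for node, mid in assignment.items():
                    net.nodes[node]["module_id"] = mid
                metrics = network.network_metrics(net)
                metrics["modularity"] = q_mod
                metrics["n_modules"] = len(modules)
                io.write_network(net, out / f"network_group_{g}.graphml", "graphml")
                io.write_network(net, out / f"network_group_{g}_edges.tsv", "edge-list")
                hubs = network.hub_ranking(net)
                hubs.to_csv(out / f"network_group_{g}_degrees.tsv", sep="\t", index=False)
                modules.to_csv(out / f"network_group_{g}_modules.tsv", sep="\t", index=False)
                for k, v in metrics.items():
                    report[f"network_{g}_{k}"] = v
    except Exception as exc:
        report["failed_stage"] = stage
        report["error"] = str(exc)
        _write_report(report, out / "run_report.tsv")
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    report["wall_time_s"] = round(time.time() - t0, 3)
    for key in (
        "rare_fraction", "top_n", "r_cutoff", "q_cutoff",
        "permanova_permutations", "diffabund_permutations", "keep_isolates",
    ):
        report.setdefault(key, getattr(config, key))
    _write_report(report, out / "run_report.tsv")
    return report
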