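"""End-to-end orchestration: simulate -> preprocess -> cluster -> correlate ->
screen -> communities -> predict, with one config and one seed.

A single global seed fans out to per-stage seeds by stable hashing so any
stage re-run in isolation reproduces its output bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import communities as comm
from . import comodules, correlate, predict, preprocess, simulate, stats
from .config import AnalysisConfig
from .io import FeatureModuleMap, OmicsMatrix, align_samples, write_manifest, write_matrix

logger = logging.getLogger("trinetomics")


def stage_seed(seed: int, stage: str) -> int:
    """Stable per-stage seed below 2^31 derived from the global seed."""
    digest = hashlib.blake2s(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


@dataclass
class PipelineResult:
    partition: comodules.ModulePartition
    eigenprofiles: comodules.Eigenprofile
    edges: dict[str, pd.DataFrame]
    triangles: correlate.TriangleSet
    network_edges: pd.DataFrame
    communities: comm.CommunityPartition
    community_summaries: list
    permanova: pd.DataFrame
    differential: pd.DataFrame
    reporter: pd.DataFrame
    classification: dict[str, predict.CvResult]
    regression: dict[str, predict.CvResult] = field(default_factory=dict)
    truth: simulate.GroundTruth | None = None


def run_all(config: AnalysisConfig, mgs: OmicsMatrix | None = None,
            metabolites: OmicsMatrix | None = None, phenotype: OmicsMatrix | None = None,
            cohort: simulate.CohortConfig | None = None,
            outdir: str | Path | None = None) -> PipelineResult:
    """Run the full trans-omics analysis.

    Either pass the three sample-aligned matrices, or a
    :class:`~trinetomics.simulate.CohortConfig` to generate them.  When
    ``outdir`` is given every stage output is written as TSV/JSON along
    with a reproducibility manifest.
    """
    truth = None
    if mgs is None or metabolites is None or phenotype is None:
        if cohort is None:
            raise ValueError("matrices missing: pass all three or a CohortConfig to simulate")
        cohort = simulate.CohortConfig(**{**cohort.__dict__,
                                          "seed": stage_seed(config.seed, "simulate")})
        mgs, metabolites, phenotype, truth = simulate.generate_cohort(cohort)
    mgs, metabolites, phenotype = align_samples(mgs, metabolites, phenotype)

    # --- preprocessing -----------------------------------------------------
    mgs_f = preprocess.prevalence_filter(mgs, config.prevalence_min_fraction)
    diversity = pd.DataFrame({
        "shannon": preprocess.shannon_diversity(mgs_f),
        "richness": preprocess.richness(mgs_f),
    })

    # --- metabolite co-abundance modules ----------------------------------
    partition, eigen = comodules.cluster_metabolites(
        metabolites, beta=config.beta, deep_split=config.deep_split,
        min_size=config.min_module_size)
    met_groups = OmicsMatrix(eigen.scores, "metabolite")

    # --- three correlation rounds (metabolite groups, as in the analysis) --
    labels = phenotype.data["disease"] if "disease" in phenotype.data.columns else None
    biomarkers = phenotype
    if labels is not None:
        biomarkers = OmicsMatrix(phenotype.data.drop(columns=["disease"]), "phenotype")
    e_mgs_phe = correlate.all_pairs(mgs_f, biomarkers)
    e_met_phe = correlate.all_pairs(met_groups, biomarkers)
    e_mgs_met = correlate.all_pairs(mgs_f, met_groups)
    edges = {"mgs_phenotype": e_mgs_phe, "metabolite_phenotype": e_met_phe,
             "mgs_metabolite": e_mgs_met}

    triangles = correlate.triangular_retention(
        e_mgs_phe, e_met_phe, e_mgs_met, p_threshold=config.p_threshold)

    network_edges = correlate.filter_for_network(
        [e_mgs_phe, e_met_phe, e_mgs_met],
        q_max=config.q_threshold, rho_min=config.rho_threshold)

    # --- community analysis ------------------------------------------------
    graph = comm.TransOmicsGraph.from_edge_table(network_edges)
    if graph.n_edges():
        partition_c = comm.girvan_newman(graph)
    else:
        partition_c = comm.CommunityPartition({}, 0.0, [])
    summaries = comm.community_summary(graph, partition_c, config.min_community_size)

    # --- covariate screening / differential features ----------------------
    dist = stats.bray_curtis(mgs_f)
    perma = stats.permanova_screen(dist, biomarkers, n_perm=config.n_permutations,
                                   seed=stage_seed(config.seed, "permanova"))

    diff = pd.DataFrame()
    reporter = pd.DataFrame()
    classification: dict[str, predict.CvResult] = {}
    if labels is not None and labels.nunique() == 2:
        diff = stats.differential_abundance(mgs_f, labels)
        met_diff = stats.differential_abundance(
            OmicsMatrix(metabolites.data, "metabolite"), labels)
        if len(met_diff) and len(partition.module_sizes()):
            mod_map = FeatureModuleMap(pd.DataFrame({
                "feature": [f for f, m in partition.labels.items() if m != simulate.UNASSIGNED],
                "module": [m for m in partition.labels.values() if m != simulate.UNASSIGNED],
            }))
            reporter = stats.reporter_scores(
                mod_map, met_diff.set_index("feature")["p"],
                met_diff.set_index("feature")["direction"],
                n_draws=config.reporter_draws,
                seed=stage_seed(config.seed, "reporter"),
                z_threshold=config.reporter_z_threshold)
        scheme = predict.CvScheme(k=config.cv_folds, repeats=config.cv_repeats,
                                  downsample=True, seed=stage_seed(config.seed, "classify"))
        for name, matrix in (("biomarkers", biomarkers), ("microbiome", mgs_f)):
            try:
                classification[name] = predict.repeated_cv(matrix, labels, scheme,
                                                           task="classification")
            except ValueError as exc:
                logger.warning("classification on %s skipped: %s", name, exc)

    result = PipelineResult(partition, eigen, edges, triangles, network_edges,
                            partition_c, summaries, perma, diff, reporter,
                            classification, truth=truth)

    if outdir is not None:
        _write_outputs(Path(outdir), config, result, mgs_f, diversity, met_groups)
    return result


def _write_outputs(outdir: Path, config: AnalysisConfig, res: PipelineResult,
                   mgs_f: OmicsMatrix, diversity: pd.DataFrame,
                   met_groups: OmicsMatrix) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    write_matrix(mgs_f, outdir / "mgs_filtered.tsv")
    write_matrix(met_groups, outdir / "metabolite_groups.tsv")
    diversity.to_csv(outdir / "diversity.tsv", sep="\t")
    res.partition.to_series().to_csv(outdir / "metabolite_modules.tsv", sep="\t",
                                     header=["module"], index_label="feature")
    for name, table in res.edges.items():
        table.to_csv(outdir / f"edges_{name}.tsv", sep="\t", index=False)
    res.triangles.triangles.to_csv(outdir / "triangles.tsv", sep="\t", index=False)
    res.network_edges.to_csv(outdir / "network_edges.tsv", sep="\t", index=False)
    comm.summary_table(res.community_summaries).to_csv(
        outdir / "community_summary.tsv", sep="\t", index=False)
    pd.Series(res.communities.labels, name="community").to_csv(
        outdir / "communities.tsv", sep="\t", index_label="node")
    res.permanova.to_csv(outdir / "permanova.tsv", sep="\t", index=False)
    if len(res.differential):
        res.differential.to_csv(outdir / "differential_mgs.tsv", sep="\t", index=False)
    if len(res.reporter):
        res.reporter.to_csv(outdir / "reporter_scores.tsv", sep="\t", index=False)
    metrics = {name: {"auc_mean": r.aggregate, "auc_per_repeat": r.per_repeat}
               for name, r in res.classification.items()}
    (outdir / "cv_metrics.json").write_text(json.dumps(metrics, indent=2))
    if res.truth is not None:
        (outdir / "ground_truth.json").write_text(json.dumps(res.truth.to_jsonable(), indent=2))
    write_manifest(outdir / "manifest.json", config=config.to_dict(), seed=config.seed,
                   extra={"modularity": res.communities.modularity})
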