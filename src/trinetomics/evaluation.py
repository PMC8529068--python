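"""Calibration and recovery benchmarks run on synthetic cohorts.

These routines quantify how the pipeline behaves under known conditions:
false-discovery control on structure-free cohorts, planted-structure
recovery at strong factor loading, PERMANOVA and reporter-score null
calibration, and the biomarker-vs-microbiome classification contrast.
Both the test suite and the reproduction script call them.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

from . import communities as comm
from .comodules import cluster_metabolites
from .correlate import all_pairs, filter_for_network
from .io import FeatureModuleMap, OmicsMatrix
from .predict import CvScheme, default_classifier, repeated_cv
from .simulate import CohortConfig, generate_cohort, score_recovery
from .stats import bray_curtis, permanova, reporter_scores


def _drop_label(phenotype: OmicsMatrix) -> OmicsMatrix:
    if "disease" in phenotype.data.columns:
        return OmicsMatrix(phenotype.data.drop(columns=["disease"]), "phenotype")
    return phenotype


def fdr_calibration(n_replicates: int = 200, seed: int = 0, q_max: float = 0.1) -> dict:
    """Mean realised false-discovery proportion on structure-free cohorts.

    Every replicate draws a cohort with zero factor loading (50 MGS x 50
    metabolites x 20 biomarkers, n = 150), runs the three all-pairs Spearman
    rounds and BH-adjusts each round as its own family (the unit at which
    the FDR is controlled); with no planted structure every edge at
    q < ``q_max`` is a false discovery, so each round's FDP is
    V / max(R, 1) with V = R, and the replicate's FDP averages the three
    rounds.
    """
    rng = np.random.default_rng(seed)
    fdps = []
    for _ in range(n_replicates):
        cfg = CohortConfig(n_samples=150, n_mgs=50, n_metabolites=50, n_biomarkers=20,
                           n_factors=1, loading=0.0, module_size_range=(3, 5),
                           seed=int(rng.integers(2**31)))
        mgs, met, phe, _ = generate_cohort(cfg)
        bio = _drop_label(phe)
        round_fdps = []
        for a, b in ((mgs, met), (met, bio), (mgs, bio)):
            edges = filter_for_network(all_pairs(a, b), q_max=q_max, rho_min=0.0)
            round_fdps.append(1.0 if len(edges) > 0 else 0.0)
        fdps.append(float(np.mean(round_fdps)))
    return {"mean_fdp": float(np.mean(fdps)), "n_replicates": n_replicates}


def recovery_benchmark(seed: int = 0) -> dict:
    """Planted-structure recovery on a strongly loaded cohort (lambda = 0.8).

    n = 300 samples, 10 metabolite modules of size 5-20, 40 MGS and 15
    biomarkers.  Reports the module adjusted Rand index, the fraction of
    planted cross-domain pairs passing the q < 0.1 & |rho| >= 0.3 network
    filter, and the fraction of same-factor feature pairs that the
    Girvan-Newman decomposition places in one community.
    """
    cfg = CohortConfig(n_samples=300, n_mgs=40, n_metabolites=130, n_biomarkers=15,
                       n_factors=10, loading=0.8, module_size_range=(5, 20), seed=seed)
    mgs, met, phe, truth = generate_cohort(cfg)
    bio = _drop_label(phe)

    partition, _ = cluster_metabolites(met)
    edges = filter_for_network([all_pairs(mgs, met), all_pairs(met, bio),
                                all_pairs(mgs, bio)])
    report = score_recovery(truth, edges, partition)

    graph = comm.TransOmicsGraph.from_edge_table(edges)
    gn = comm.girvan_newman(graph)
    factor_of = {f: fac for f, (fac, _) in truth.factor_loadings.items()}
    in_graph = [n for n in graph.domains if n in factor_of]
    same_factor = [(a, b) for a, b in itertools.combinations(in_graph, 2)
                   if factor_of[a] == factor_of[b]]
    together = sum(1 for a, b in same_factor if gn.labels[a] == gn.labels[b])
    return {
        "module_ari": report.module_ari,
        "edge_sensitivity": report.edge_sensitivity,
        "community_cofactor_fraction": together / len(same_factor) if same_factor else float("nan"),
        "n_planted_edges": report.n_planted,
        "n_network_edges": int(len(edges)),
        "modularity": gn.modularity,
    }


def permanova_calibration(n_replicates: int = 1000, seed: int = 0, n_samples: int = 40,
                          n_features: int = 100, n_perm: int = 999,
                          alpha: float = 0.05) -> dict:
    """Null rejection rate of the continuous-covariate PERMANOVA.

    Each replicate draws log-normal compositional abundances and an
    independent Gaussian covariate; a calibrated test rejects at level
    ``alpha`` with frequency alpha.
    """
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_replicates):
        x = rng.lognormal(0.0, 1.0, size=(n_samples, n_features))
        x /= x.sum(axis=1, keepdims=True)
        v = rng.standard_normal(n_samples)
        d = bray_curtis(x)
        res = permanova(d, v, n_perm=n_perm, seed=int(rng.integers(2**31)))
        rejections += res.p <= alpha
    return {"rejection_rate": rejections / n_replicates, "n_replicates": n_replicates}


def reporter_calibration(n_modules: int = 500, module_size: int = 8,
                         n_background: int = 300, seed: int = 0) -> dict:
    """Corrected reporter Z for random modules drawn from a null background.

    Background features carry uniform p-values; modules are random size-k
    subsets, so the corrected Z should be standard normal (mean 0, sd 1).
    """
    rng = np.random.default_rng(seed)
    p = pd.Series(rng.uniform(size=n_background),
                  index=[f"bg{i}" for i in range(n_background)])
    rows = []
    for m in range(n_modules):
        members = rng.choice(p.index.to_numpy(), size=module_size, replace=False)
        rows.extend((f, f"R{m:04d}") for f in members)
    fmm = FeatureModuleMap(pd.DataFrame(rows, columns=["feature", "module"]))
    res = reporter_scores(fmm, p, n_draws=1000, seed=int(rng.integers(2**31)))
    z = res["corrected_z"].to_numpy()
    return {"mean_z": float(z.mean()), "sd_z": float(z.std(ddof=0)),
            "n_modules": n_modules}


def classification_benchmark(seed: int = 0, n_estimators: int = 300,
                             repeats: int = 5) -> dict:
    """AUC of disease classification from biomarkers vs from MGS abundances.

    Uses the generator defaults, where the disease label is driven by
    factor-free biomarkers: the biomarker model should clearly beat the
    microbiome model, which hovers near chance.
    """
    cfg = CohortConfig(seed=seed)
    mgs, _, phe, _ = generate_cohort(cfg)
    bio = _drop_label(phe)
    y = phe.data["disease"]
    scheme = CvScheme(k=10, repeats=repeats, downsample=True, seed=seed)
    out = {}
    for name, matrix in (("biomarkers", bio), ("microbiome", mgs)):
        res = repeated_cv(matrix, y, scheme, default_classifier(seed, n_estimators))
        out[f"auc_{name}"] = res.aggregate
    return out
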