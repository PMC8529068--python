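"""Synthetic three-domain cohort with planted, recoverable cross-domain structure.

The generative model is a latent-factor Gaussian copula.  Each sample s
draws K independent standard-normal factors f_1..f_K.  A feature that loads
on factor j with loading lambda takes the latent value

    z = lambda * f_j + sqrt(1 - lambda^2) * noise_sd * eps,   eps ~ N(0, 1)

so that with ``noise_sd = 1`` two features sharing a factor have Pearson
(and, being monotone transforms, Spearman) correlation lambda^2 and
features on different factors are independent.  Latent values are mapped to
each domain's observation scale:

* microbiome: exp(b_i + z) with a per-feature baseline b_i, thinned by a
  per-entry presence Bernoulli at the configured prevalence and then
  renormalised per sample, giving compositional zero-inflated relative
  abundances;
* metabolome: exp(mu_i + z) log-normal positive intensities;
* phenotype: z rescaled to biomarker-like units, plus a binary ``disease``
  label drawn from a logistic model on a designated subset of biomarkers.

Factor layout: every factor owns one metabolite module (sizes drawn from
``module_size_range``) and, round-robin, up to two MGS and two biomarkers.
All cross-domain pairs sharing a factor are recorded as planted edges; the
remaining features are pure noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .io import OmicsMatrix

UNASSIGNED = "unassigned"


@dataclass
class CohortConfig:
    """Conditions for one synthetic cohort draw."""

    n_samples: int = 138
    n_mgs: int = 100
    n_metabolites: int = 200
    n_biomarkers: int = 30
    n_factors: int = 10
    loading: float = 0.8
    module_size_range: tuple[int, int] = (5, 20)
    microbiome_prevalence: float = 0.9
    noise_sd: float = 1.0
    disease_effect: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_samples", "n_mgs", "n_metabolites", "n_biomarkers", "n_factors"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0 <= self.loading < 1:
            raise ValueError(f"loading must lie in [0, 1), got {self.loading}")
        lo, hi = self.module_size_range
        if lo < 3 or hi < lo:
            raise ValueError("module_size_range must satisfy 3 <= min <= max")
        if lo * self.n_factors > self.n_metabolites:
            raise ValueError(
                f"module_size_range {self.module_size_range} infeasible: "
                f"{self.n_factors} modules of >= {lo} need more than "
                f"{self.n_metabolites} metabolites")
        if not 0 < self.microbiome_prevalence <= 1:
            raise ValueError("microbiome_prevalence must lie in (0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass
class GroundTruth:
    """Planted structure emitted alongside a synthetic cohort."""

    factor_loadings: dict[str, tuple[int, float]]       # feature -> (factor, lambda)
    metabolite_modules: dict[str, str]                  # metabolite -> module id
    planted_edges: list[tuple[str, str]]                # cross-domain pairs sharing a factor
    disease_drivers: dict[str, float]                   # biomarker -> log-odds effect
    labels: pd.Series = field(default=None)             # per-sample disease label

    def to_jsonable(self) -> dict:
        return {
            "factor_loadings": {k: [int(f), float(l)] for k, (f, l) in self.factor_loadings.items()},
            "metabolite_modules": dict(self.metabolite_modules),
            "planted_edges": [list(e) for e in self.planted_edges],
            "disease_drivers": {k: float(v) for k, v in self.disease_drivers.items()},
        }


def _latent(rng, factors, assign, lam, noise_sd):
    """Latent values for features with factor assignment `assign` (-1 = none)."""
    n, _ = factors.shape
    p = len(assign)
    eps = rng.standard_normal((n, p))
    z = np.sqrt(max(1 - lam**2, 0.0)) * noise_sd * eps
    loaded = assign >= 0
    if loaded.any():
        z[:, loaded] += lam * factors[:, assign[loaded]]
    # unloaded features carry unit-scale noise so every feature varies
    z[:, ~loaded] = noise_sd * eps[:, ~loaded]
    return z


def generate_cohort(config: CohortConfig) -> tuple[OmicsMatrix, OmicsMatrix, OmicsMatrix, GroundTruth]:
    """Draw one cohort; identical config (incl. seed) gives identical output."""
    rng = np.random.default_rng(config.seed)
    n, K, lam = config.n_samples, config.n_factors, config.loading
    samples = [f"S{i:04d}" for i in range(n)]
    mgs_ids = [f"MGS{i:04d}" for i in range(config.n_mgs)]
    met_ids = [f"MET{i:05d}" for i in range(config.n_metabolites)]
    bio_ids = [f"BIO{i:03d}" for i in range(config.n_biomarkers)]

    factors = rng.standard_normal((n, K))

    # metabolite modules: one per factor, contiguous blocks
    lo, hi = config.module_size_range
    sizes = rng.integers(lo, hi + 1, size=K)
    while sizes.sum() > config.n_metabolites:        # shrink feasibly, never below lo
        j = int(np.argmax(sizes))
        if sizes[j] <= lo:
            break
        sizes[j] -= 1
    met_assign = np.full(config.n_metabolites, -1)
    metabolite_modules: dict[str, str] = {}
    pos = 0
    for j in range(K):
        for i in range(pos, pos + int(sizes[j])):
            met_assign[i] = j
            metabolite_modules[met_ids[i]] = f"T{j:02d}"
        pos += int(sizes[j])

    # up to two MGS and two biomarkers per factor, round-robin
    mgs_assign = np.full(config.n_mgs, -1)
    for idx in range(min(config.n_mgs, 2 * K)):
        mgs_assign[idx] = idx % K
    bio_assign = np.full(config.n_biomarkers, -1)
    for idx in range(min(config.n_biomarkers, 2 * K)):
        bio_assign[idx] = idx % K

    z_mgs = _latent(rng, factors, mgs_assign, lam, config.noise_sd)
    z_met = _latent(rng, factors, met_assign, lam, config.noise_sd)
    z_bio = _latent(rng, factors, bio_assign, lam, config.noise_sd)

    # microbiome: heterogeneous baselines, zero-inflation, per-sample closure
    baseline = rng.normal(0.0, 1.5, size=config.n_mgs)
    raw = np.exp(baseline[None, :] + z_mgs)
    present = rng.random((n, config.n_mgs)) < config.microbiome_prevalence
    # keep at least one taxon per sample so closure is well defined
    empty_rows = ~present.any(axis=1)
    if empty_rows.any():
        present[empty_rows, rng.integers(0, config.n_mgs, size=int(empty_rows.sum()))] = True
    raw = raw * present
    mgs = raw / raw.sum(axis=1, keepdims=True)

    met = np.exp(rng.normal(3.0, 1.0, size=config.n_metabolites)[None, :] + z_met)

    bio_scale = np.exp(rng.normal(0.0, 0.5, size=config.n_biomarkers))
    bio = z_bio * bio_scale[None, :]

    # binary label from a logistic model on driver biomarkers; drivers are taken
    # from the tail so that (when n_biomarkers > 2*n_factors + n_drivers) they are
    # factor-free and the microbiome carries no disease signal
    n_drivers = max(1, config.n_biomarkers // 4)
    driver_idx = np.arange(config.n_biomarkers - n_drivers, config.n_biomarkers)
    drivers = {bio_ids[i]: config.disease_effect for i in driver_idx}
    score = z_bio[:, driver_idx].mean(axis=1)
    logit = config.disease_effect * score
    labels = (rng.random(n) < 1.0 / (1.0 + np.exp(-logit))).astype(int)

    phen = np.column_stack([bio, labels])
    phen_ids = bio_ids + ["disease"]

    factor_loadings: dict[str, tuple[int, float]] = {}
    for ids, assign in ((mgs_ids, mgs_assign), (met_ids, met_assign), (bio_ids, bio_assign)):
        for fid, a in zip(ids, assign):
            if a >= 0:
                factor_loadings[fid] = (int(a), lam)

    planted: list[tuple[str, str]] = []
    by_factor: dict[int, dict[str, list[str]]] = {}
    for ids, assign, dom in ((mgs_ids, mgs_assign, "mgs"), (met_ids, met_assign, "met"),
                             (bio_ids, bio_assign, "bio")):
        for fid, a in zip(ids, assign):
            if a >= 0:
                by_factor.setdefault(int(a), {"mgs": [], "met": [], "bio": []})[dom].append(fid)
    for members in by_factor.values():
        for da, db in (("mgs", "met"), ("met", "bio"), ("mgs", "bio")):
            for a in members[da]:
                for b in members[db]:
                    planted.append(tuple(sorted((a, b))))

    truth = GroundTruth(factor_loadings, metabolite_modules, sorted(planted), drivers,
                        labels=pd.Series(labels, index=samples, name="disease"))
    return (
        OmicsMatrix(pd.DataFrame(mgs, index=samples, columns=mgs_ids), "microbiome_mgs"),
        OmicsMatrix(pd.DataFrame(met, index=samples, columns=met_ids), "metabolite"),
        OmicsMatrix(pd.DataFrame(phen, index=samples, columns=phen_ids), "phenotype"),
        truth,
    )


@dataclass
class RecoveryReport:
    edge_sensitivity: float
    edge_precision: float
    module_ari: float
    n_planted: int
    n_recovered: int


def score_recovery(truth: GroundTruth, inferred_edges=None, inferred_modules=None) -> RecoveryReport:
    """Compare inferred edges/modules against the planted truth.

    ``inferred_edges`` is an edge table with ``feature_a``/``feature_b``
    columns (any extra columns ignored); ``inferred_modules`` maps feature id
    to module label (:data:`UNASSIGNED` allowed).  Edge sensitivity is the
    fraction of planted cross-domain pairs recovered; precision the fraction
    of inferred pairs that were planted; the adjusted Rand index compares
    module labels on the features with a planted module.
    """
    planted = {frozenset(e) for e in truth.planted_edges}
    sens = prec = float("nan")
    n_rec = 0
    if inferred_edges is not None:
        if len(inferred_edges):
            pairs = {frozenset((a, b)) for a, b in
                     zip(inferred_edges["feature_a"], inferred_edges["feature_b"])}
        else:
            pairs = set()
        universe = {f for e in planted for f in e}
        if pairs and universe and not (universe & {f for p in pairs for f in p}):
            raise ValueError("inferred edges share no features with the planted truth")
        n_rec = len(pairs & planted)
        sens = n_rec / len(planted) if planted else float("nan")
        prec = n_rec / len(pairs) if pairs else float("nan")
    ari = float("nan")
    if inferred_modules is not None:
        if hasattr(inferred_modules, "labels"):
            inferred_modules = dict(inferred_modules.labels)
        feats = sorted(truth.metabolite_modules)
        if not set(feats) & set(inferred_modules):
            raise ValueError("inferred module labels share no features with the truth")
        true_lab = [truth.metabolite_modules[f] for f in feats]
        inf_lab = [str(inferred_modules.get(f, UNASSIGNED)) for f in feats]
        ari = float(adjusted_rand_score(true_lab, inf_lab))
    return RecoveryReport(sens, prec, ari, len(planted), n_rec)
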