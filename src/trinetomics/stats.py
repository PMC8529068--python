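"""Covariate screening and enrichment statistics.

* PERMANOVA effect sizes: each clinical variable is tested against the MGS
  composition through a Gower-centred distance matrix; r^2 is the fraction
  of distance variance explained and p comes from sample-label permutation.
* Mann–Whitney differential abundance between disease groups.
* Reporter Z-scores: member-feature p-values aggregated to functional
  modules, corrected against a sampled size-matched background;
  |Z| >= 1.96 is called significant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from .correlate import bh_adjust
from .io import FeatureModuleMap, OmicsMatrix


def bray_curtis(matrix: OmicsMatrix | np.ndarray) -> pd.DataFrame:
    """Bray–Curtis distances between samples: d = sum|x - y| / sum(x + y)."""
    if isinstance(matrix, OmicsMatrix):
        x = matrix.values()
        ids = matrix.sample_ids
    else:
        x = np.asarray(matrix, dtype=float)
        ids = list(range(x.shape[0]))
    if (x < 0).any():
        raise ValueError("Bray–Curtis requires non-negative abundances")
    zero = x.sum(axis=1) == 0
    if zero.sum() >= 2:
        raise ValueError(f"distance undefined between all-zero samples: {list(np.array(ids)[zero])}")
    d = squareform(pdist(x, metric="braycurtis"))
    return pd.DataFrame(d, index=ids, columns=ids)


@dataclass
class PermanovaResult:
    variable: str
    r_squared: float
    pseudo_f: float
    p: float
    n_perm: int
    n_samples: int


def _gower_center(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d**2
    row = a.mean(axis=0, keepdims=True)
    col = a.mean(axis=1, keepdims=True)
    return a - row - col + a.mean()


def permanova(distance, variable, n_perm: int = 999, seed: int | None = None,
              name: str = "v") -> PermanovaResult:
    """Single-variable PERMANOVA of a distance matrix against a numeric covariate.

    The Gower-centred inner-product matrix G = -(1/2) J D^2 J is regressed
    on the (centred) covariate: r^2 = SS_model / SS_total with
    SS_model = v'Gv / v'v, SS_total = tr(G).  The permutation p-value uses
    the add-one rule, p = (1 + #{F_perm >= F_obs}) / (n_perm + 1), under
    random relabelling of the covariate.  Binary group labels coded 0/1
    reproduce the classical two-group PERMANOVA.
    """
    d = np.asarray(distance.values if hasattr(distance, "values") else distance, dtype=float)
    v = np.asarray(variable, dtype=float)
    n = d.shape[0]
    if v.shape != (n,):
        raise ValueError("variable must align with the distance matrix")
    ok = np.isfinite(v)
    if not ok.all():
        d = d[np.ix_(ok, ok)]
        v = v[ok]
        n = v.size
    if n < 4:
        raise ValueError("need >= 4 samples with a non-missing covariate")
    if np.ptp(v) == 0:
        raise ValueError(f"constant covariate {name!r}: PERMANOVA undefined")

    g = _gower_center(d)
    ss_total = float(np.trace(g))
    vc = v - v.mean()
    denom = float(vc @ vc)

    def ss_model(vecs: np.ndarray) -> np.ndarray:
        # vecs: (m, n) rows of centred covariates; SS = v G v' / (v v')
        return np.einsum("ij,jk,ik->i", vecs, g, vecs) / denom

    obs = float(ss_model(vc[None, :])[0])
    ss_res = ss_total - obs
    df2 = n - 2
    f_obs = (obs / 1.0) / (ss_res / df2) if ss_res > 0 else np.inf

    rng = np.random.default_rng(seed)
    orders = np.argsort(rng.random((n_perm, n)), axis=1)
    ss_p = ss_model(vc[orders])
    with np.errstate(divide="ignore"):
        f_perm = ss_p / ((ss_total - ss_p) / df2)
    p = (1 + int((f_perm >= f_obs).sum())) / (n_perm + 1)
    return PermanovaResult(name, obs / ss_total if ss_total > 0 else 0.0,
                           float(f_obs), float(p), n_perm, n)


def permanova_screen(distance, phenotype: OmicsMatrix, n_perm: int = 999,
                     seed: int | None = None) -> pd.DataFrame:
    """PERMANOVA of every phenotype variable vs one distance matrix, ranked by r^2.

    Variables that are constant (after dropping missing values) are skipped.
    Adds BH q-values over the tested variables.
    """
    rows = []
    rng = np.random.default_rng(seed)
    for var in phenotype.feature_ids:
        v = phenotype.data[var].to_numpy(dtype=float)
        try:
            res = permanova(distance, v, n_perm=n_perm,
                            seed=int(rng.integers(2**31)), name=var)
        except ValueError:
            continue
        rows.append((res.variable, res.r_squared, res.pseudo_f, res.p, res.n_samples))
    out = pd.DataFrame(rows, columns=["variable", "r_squared", "pseudo_f", "p", "n_samples"])
    if len(out):
        out["q"] = bh_adjust(out["p"].to_numpy())
        out = out.sort_values("r_squared", ascending=False).reset_index(drop=True)
    return out


def mann_whitney(a, b) -> tuple[float, float]:
    """Two-sided Mann–Whitney U (U of the first group; exact when n_a + n_b <= 12).

    Orientation: U counts pairs where a value from ``a`` exceeds one from
    ``b`` (ties half).  U = 0 means every ``a`` is below every ``b``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    method = "exact" if (a.size + b.size <= 12 and
                         np.unique(np.concatenate([a, b])).size == a.size + b.size) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def differential_abundance(matrix: OmicsMatrix, labels) -> pd.DataFrame:
    """Per-feature Mann–Whitney between label 1 and label 0 samples, BH adjusted.

    ``direction`` is the sign of the group-median difference (group 1 minus
    group 0), the signed statistic the reporter score consumes.
    """
    y = np.asarray(labels, dtype=float)
    if set(np.unique(y[np.isfinite(y)])) - {0.0, 1.0}:
        raise ValueError("labels must be binary 0/1")
    x = matrix.values()
    rows = []
    for j, feat in enumerate(matrix.feature_ids):
        g1, g0 = x[y == 1, j], x[y == 0, j]
        try:
            u, p = mann_whitney(g1, g0)
        except ValueError:
            continue
        direction = float(np.sign(np.median(g1) - np.median(g0)))
        rows.append((feat, u, p, direction))
    out = pd.DataFrame(rows, columns=["feature", "u", "p", "direction"])
    if len(out):
        out["q"] = bh_adjust(out["p"].to_numpy())
    return out


@dataclass
class ReporterResult:
    module: str
    k: int
    raw_z: float
    corrected_z: float
    significant: bool


def reporter_scores(module_map: FeatureModuleMap, feature_p: pd.Series,
                    feature_dir: pd.Series | None = None, n_draws: int = 1000,
                    seed: int | None = None, z_threshold: float = 1.96) -> pd.DataFrame:
    """Module-level reporter Z-scores from member-feature p-values.

    Each member feature contributes z_i = Phi^{-1}(1 - p_i), signed by its
    direction of change; the raw module score is Z = sum z_i / sqrt(k).
    The corrected score standardises Z against mu_k, sigma_k estimated from
    ``n_draws`` random size-k draws from the background of all scored
    features; |corrected Z| >= ``z_threshold`` is flagged significant.
    p-values are clipped to [1e-15, 1 - 1e-15] to keep z finite.
    """
    p = pd.Series(feature_p, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    z = pd.Series(stats.norm.ppf(1 - np.clip(p.to_numpy(), 1e-15, 1 - 1e-15)), index=p.index)
    if feature_dir is not None:
        sign = np.sign(pd.Series(feature_dir, dtype=float).reindex(p.index).fillna(1.0))
        sign = sign.replace(0, 1.0)
        z = z * sign
    background = z.to_numpy()
    rng = np.random.default_rng(seed)

    rows = []
    mu_sigma: dict[int, tuple[float, float]] = {}
    for module in module_map.modules():
        members = [m for m in module_map.members(module) if m in z.index]
        missing = set(module_map.members(module)) - set(members)
        if missing:
            raise ValueError(f"module {module}: member(s) without a p-value: {sorted(missing)[:5]}")
        k = len(members)
        if k == 0:
            continue
        raw = float(z[members].sum() / np.sqrt(k))
        if k not in mu_sigma:
            draws = rng.choice(background, size=(n_draws, k), replace=True).sum(axis=1) / np.sqrt(k)
            mu_sigma[k] = (float(draws.mean()), float(draws.std(ddof=0)))
        mu, sigma = mu_sigma[k]
        if sigma == 0:
            raise ValueError(f"degenerate background for module size {k} (sigma = 0)")
        corrected = (raw - mu) / sigma
        rows.append(ReporterResult(module, k, raw, corrected, abs(corrected) >= z_threshold))
    out = pd.DataFrame([r.__dict__ for r in rows],
                       columns=["module", "k", "raw_z", "corrected_z", "significant"])
    if len(out):
        out = out.sort_values("corrected_z", key=np.abs, ascending=False).reset_index(drop=True)
    return out
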