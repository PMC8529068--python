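"""All-pairs Spearman screens, BH adjustment, triangular retention, network filter.

Three rounds of pairwise Spearman correlation are run between the domains
(microbiome vs metabolome, metabolome vs phenotype, microbiome vs
phenotype).  Features significant in all three rounds form retained
triangles (p < 0.05 per leg); for community analysis, edges are instead
kept at BH q < 0.1 and |rho| >= 0.3, inter-omic only, with the q-values
computed within each domain-pair family.

Spearman rho is Pearson on mid-ranks (average ranks for ties); its
two-sided p-value uses the t approximation
t = rho * sqrt((n - 2) / (1 - rho^2)) with n - 2 degrees of freedom, and
|rho| = 1 gives p = 0.  Phenotype missing values are handled by pairwise
deletion with the number of complete pairs recorded per edge.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import OmicsMatrix

logger = logging.getLogger("trinetomics")

EDGE_COLUMNS = ["feature_a", "domain_a", "feature_b", "domain_b", "rho", "p", "n_used"]


def spearman(x, y) -> tuple[float, float]:
    """Spearman rho and two-sided p for one pair, with pairwise NaN deletion."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = x.size
    if n < 4:
        raise ValueError(f"need >= 4 complete paired observations, got {n}")
    rx, ry = stats.rankdata(x), stats.rankdata(y)
    sx, sy = rx.std(), ry.std()
    if sx == 0 or sy == 0:
        raise ValueError("constant vector: Spearman correlation undefined")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    rho = max(-1.0, min(1.0, rho))
    if 1.0 - abs(rho) < 1e-12:          # perfect monotone pair, p = 0 exactly
        rho = float(np.sign(rho))
    return rho, _t_pvalue(np.array([rho]), n)[0]


def _t_pvalue(rho: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p from the t approximation; |rho| = 1 maps to p = 0."""
    rho = np.clip(rho, -1.0, 1.0)
    p = np.zeros_like(rho)
    inner = np.abs(rho) < 1 - 1e-12
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho[inner] * np.sqrt((n - 2) / (1 - rho[inner] ** 2))
    p[inner] = 2 * stats.t.sf(np.abs(t), df=n - 2)
    return p


def _rank_standardise(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column-wise mid-ranks, centred and unit-norm; flags constant columns."""
    r = stats.rankdata(values, axis=0)
    r = r - r.mean(axis=0, keepdims=True)
    norms = np.linalg.norm(r, axis=0)
    constant = norms == 0
    norms[constant] = 1.0
    return r / norms, constant


def all_pairs(a: OmicsMatrix, b: OmicsMatrix | None = None) -> pd.DataFrame:
    """Spearman rho/p for every feature pair between (or within) matrices.

    Within-domain mode (``b`` omitted or identical to ``a``) emits each
    unordered pair once and no self-pairs.  Pairs with fewer than four
    complete observations, or with a constant vector after deletion, are
    skipped and counted in the log.  Returns a tidy edge table with columns
    ``feature_a, domain_a, feature_b, domain_b, rho, p, n_used``.
    """
    within = b is None or b is a
    if within:
        b = a
    if list(a.sample_ids) != list(b.sample_ids):
        raise ValueError("matrices must be sample-aligned (use align_samples)")
    av, bv = a.values(), b.values()
    n = av.shape[0]
    a_has_nan = np.isnan(av).any()
    b_has_nan = np.isnan(bv).any()

    frames: list[pd.DataFrame] = []
    skipped = 0

    def emit(rho, pvals, n_used, ai_idx, bi_idx):
        nonlocal skipped
        ok = np.isfinite(rho)
        skipped += int((~ok).sum())
        frames.append(pd.DataFrame({
            "feature_a": np.asarray(a.feature_ids, object)[ai_idx][ok],
            "domain_a": a.domain,
            "feature_b": np.asarray(b.feature_ids, object)[bi_idx][ok],
            "domain_b": b.domain,
            "rho": rho[ok],
            "p": pvals[ok],
            "n_used": np.asarray(n_used)[ok] if np.ndim(n_used) else np.full(int(ok.sum()), n_used),
        }))

    if not a_has_nan and not b_has_nan:
        ra, const_a = _rank_standardise(av)
        rb, const_b = _rank_standardise(bv)
        rho = ra.T @ rb
        rho[const_a, :] = np.nan
        rho[:, const_b] = np.nan
        pmat = _t_pvalue(np.nan_to_num(rho), n)
        pmat[~np.isfinite(rho)] = np.nan
        if within:
            iu, ju = np.triu_indices(av.shape[1], k=1)
            emit(rho[iu, ju], pmat[iu, ju], n, iu, ju)
        else:
            ii, jj = np.indices(rho.shape)
            emit(rho.ravel(), pmat.ravel(), n, ii.ravel(), jj.ravel())
    elif a_has_nan and b_has_nan:
        # phenotype-vs-phenotype: per-pair deletion
        p_a, p_b = av.shape[1], bv.shape[1]
        for i in range(p_a):
            j_start = i + 1 if within else 0
            for j in range(j_start, p_b):
                try:
                    r, p = spearman(av[:, i], bv[:, j])
                except ValueError:
                    skipped += 1
                    continue
                n_used = int((np.isfinite(av[:, i]) & np.isfinite(bv[:, j])).sum())
                emit(np.array([r]), np.array([p]), n_used, np.array([i]), np.array([j]))
    else:
        # one incomplete matrix (phenotype): delete per incomplete column
        if a_has_nan:   # orient so the complete matrix is ranked in bulk
            swapped = all_pairs(b, a)
            return swapped.rename(columns={
                "feature_a": "feature_b", "domain_a": "domain_b",
                "feature_b": "feature_a", "domain_b": "domain_a"})[EDGE_COLUMNS]
        for j in range(bv.shape[1]):
            col = bv[:, j]
            mask = np.isfinite(col)
            n_used = int(mask.sum())
            if n_used < 4:
                skipped += av.shape[1]
                continue
            ra, const_a = _rank_standardise(av[mask])
            rb, const_b = _rank_standardise(col[mask, None])
            rho = (ra.T @ rb).ravel()
            rho[const_a] = np.nan
            if const_b[0]:
                rho[:] = np.nan
            pv = _t_pvalue(np.nan_to_num(rho), n_used)
            pv[~np.isfinite(rho)] = np.nan
            emit(rho, pv, n_used, np.arange(av.shape[1]), np.full(av.shape[1], j))

    if skipped:
        logger.info("all_pairs(%s, %s): skipped %d pair(s) (too few observations or constant)",
                    a.domain, b.domain, skipped)
    if not frames:
        return pd.DataFrame(columns=EDGE_COLUMNS)
    out = pd.concat(frames, ignore_index=True)
    return out[EDGE_COLUMNS]


def bh_adjust(p) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values: q_i = min_{j>=i} m * p_(j) / j."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def add_q_values(edges: pd.DataFrame) -> pd.DataFrame:
    """BH-adjust p within each domain-pair family (one family per correlation round)."""
    edges = edges.copy()
    edges["q"] = np.nan
    key = edges.apply(lambda r: tuple(sorted((r["domain_a"], r["domain_b"]))), axis=1)
    for _, idx in edges.groupby(key.map(str)).groups.items():
        edges.loc[idx, "q"] = bh_adjust(edges.loc[idx, "p"].to_numpy())
    return edges


@dataclass
class TriangleSet:
    """Feature triples significant in all three correlation rounds."""

    triangles: pd.DataFrame            # columns: microbiome, metabolite, phenotype
    retained: dict[str, set]           # domain -> features in >= 1 retained triangle


def triangular_retention(e_mgs_phe: pd.DataFrame, e_met_phe: pd.DataFrame,
                         e_mgs_met: pd.DataFrame, p_threshold: float = 0.05) -> TriangleSet:
    """Retain (microbe, metabolite, phenotype) triples with all three legs p < threshold."""

    def sig_pairs(edges, dom_first):
        sig = edges[edges["p"] < p_threshold]
        first_is_a = sig["domain_a"] == dom_first
        a = np.where(first_is_a, sig["feature_a"], sig["feature_b"])
        b = np.where(first_is_a, sig["feature_b"], sig["feature_a"])
        return set(zip(a, b))

    mgs_dom = _single_domain(e_mgs_phe, e_mgs_met, exclude={"phenotype", "metabolite"})
    mp = sig_pairs(e_mgs_phe, mgs_dom)
    ep = sig_pairs(e_met_phe, "metabolite")
    me = sig_pairs(e_mgs_met, mgs_dom)

    by_phe_mgs: dict[str, set] = {}
    for m, p in mp:
        by_phe_mgs.setdefault(p, set()).add(m)
    by_phe_met: dict[str, set] = {}
    for e, p in ep:
        by_phe_met.setdefault(p, set()).add(e)

    rows = []
    for phe in sorted(set(by_phe_mgs) & set(by_phe_met)):
        for m in sorted(by_phe_mgs[phe]):
            for e in sorted(by_phe_met[phe]):
                if (m, e) in me:
                    rows.append((m, e, phe))
    tri = pd.DataFrame(rows, columns=["microbiome", "metabolite", "phenotype"])
    retained = {
        "microbiome": set(tri["microbiome"]),
        "metabolite": set(tri["metabolite"]),
        "phenotype": set(tri["phenotype"]),
    }
    return TriangleSet(tri, retained)


def _single_domain(*edge_sets, exclude):
    for edges in edge_sets:
        for col in ("domain_a", "domain_b"):
            doms = set(edges[col].unique()) - set(exclude)
            if doms:
                return doms.pop()
    return "microbiome_mgs"


def filter_for_network(edges, q_max: float = 0.1, rho_min: float = 0.3) -> pd.DataFrame:
    """Edges for community analysis: q < q_max, |rho| >= rho_min, inter-omic only.

    Accepts one edge table or a sequence of them; q-values are computed per
    domain-pair family if not already present.  The boundary |rho| = rho_min
    is kept.
    """
    if isinstance(edges, (list, tuple)):
        edges = pd.concat(list(edges), ignore_index=True)
    if "q" not in edges.columns or edges["q"].isna().any():
        edges = add_q_values(edges)
    keep = (
        (edges["q"] < q_max)
        & (edges["rho"].abs() >= rho_min)
        & (edges["domain_a"] != edges["domain_b"])
    )
    return edges.loc[keep].reset_index(drop=True)
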