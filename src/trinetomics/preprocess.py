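"""Abundance conventions, prevalence filtering, diversity and transforms.

The microbiome convention throughout: the relative abundance of a
metagenomic species (MGS) is the arithmetic mean of the relative abundances
of its constituent genes, and only features present in strictly more than
10% of samples enter downstream analyses.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .io import OmicsMatrix

logger = logging.getLogger("trinetomics")


def mgs_abundance(gene_matrix: OmicsMatrix, gene_to_mgs: dict[str, str]) -> OmicsMatrix:
    """Collapse gene-level relative abundances to MGS level.

    Per sample, an MGS abundance is the arithmetic mean over its constituent
    genes.  Every mapped gene must be present in ``gene_matrix``; an MGS
    whose gene set is empty is a contract violation.
    """
    present = set(gene_matrix.feature_ids)
    missing = sorted(g for g in gene_to_mgs if g not in present)
    if missing:
        raise ValueError(f"mapped gene(s) absent from matrix: {missing[:10]}")
    groups: dict[str, list[str]] = {}
    for gene, mgs in gene_to_mgs.items():
        groups.setdefault(mgs, []).append(gene)
    empty = [m for m, genes in groups.items() if not genes]
    if empty:
        raise ValueError(f"MGS with zero mapped genes: {empty}")
    cols = {mgs: gene_matrix.data[genes].mean(axis=1) for mgs, genes in sorted(groups.items())}
    return OmicsMatrix(pd.DataFrame(cols, index=gene_matrix.data.index), "microbiome_mgs")


def prevalence_filter(matrix: OmicsMatrix, min_fraction: float = 0.10) -> OmicsMatrix:
    """Keep features non-zero in strictly more than ``min_fraction`` of samples."""
    if matrix.n_features == 0 or matrix.n_samples == 0:
        raise ValueError("empty matrix")
    frac = (matrix.values() != 0).mean(axis=0)
    keep = frac > min_fraction
    dropped = int((~keep).sum())
    if dropped:
        logger.info("prevalence_filter: dropped %d/%d features at >%s prevalence",
                    dropped, matrix.n_features, min_fraction)
    return OmicsMatrix(matrix.data.loc[:, keep], matrix.domain)


def shannon_diversity(matrix: OmicsMatrix) -> pd.Series:
    """Per-sample Shannon index H = -sum p_i ln p_i over renormalised non-zero features."""
    x = matrix.values()
    if (x < 0).any():
        raise ValueError("negative abundances")
    totals = x.sum(axis=1)
    if (totals == 0).any():
        bad = [matrix.sample_ids[i] for i in np.flatnonzero(totals == 0)]
        raise ValueError(f"all-zero sample(s): {bad}")
    p = x / totals[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log(p), 0.0)
    return pd.Series(-terms.sum(axis=1), index=matrix.sample_ids, name="shannon")


def richness(matrix: OmicsMatrix) -> pd.Series:
    """Per-sample count of strictly positive features."""
    return pd.Series((matrix.values() > 0).sum(axis=1), index=matrix.sample_ids, name="richness")


def log2_transform(matrix: OmicsMatrix, pseudocount: float | None = None) -> OmicsMatrix:
    """x -> log2(x + pseudocount); default pseudocount is half the smallest non-zero value."""
    x = matrix.values()
    if (x < 0).any():
        raise ValueError("log2_transform requires non-negative values")
    if pseudocount is None:
        nz = x[x > 0]
        pseudocount = float(nz.min()) / 2 if nz.size else 1.0
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    if pseudocount == 0 and (x == 0).any():
        raise ValueError("zero values need a positive pseudocount")
    out = pd.DataFrame(np.log2(x + pseudocount), index=matrix.data.index,
                       columns=matrix.data.columns)
    return OmicsMatrix(out, matrix.domain)
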