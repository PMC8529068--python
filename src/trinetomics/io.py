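"""Shared data model and tab-separated I/O for the three omics domains.

On disk every matrix uses the common abundance-table dialect: features in
rows, samples in columns, a header row of sample identifiers and the feature
identifier in the first column.  In memory matrices are transposed to
samples x features, which is what every statistical routine in this package
expects.

Missing values are permitted only in the ``phenotype`` domain (clinical
tables are sparse); matrices for the other domains must be complete.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("trinetomics")

#: Recognised domain tags, in the order the pipeline treats them.
DOMAINS = ("microbiome_mgs", "microbiome_function", "metabolite", "phenotype")


class ParseError(ValueError):
    """Raised when an on-disk table violates the matrix contract."""


@dataclass
class OmicsMatrix:
    """A samples x features numeric table tagged with its omics domain.

    Parameters
    ----------
    data:
        DataFrame with sample ids as the index and feature ids as columns.
    domain:
        One of :data:`DOMAINS`.
    """

    data: pd.DataFrame
    domain: str

    def __post_init__(self) -> None:
        if self.domain not in DOMAINS:
            raise ValueError(f"unknown domain {self.domain!r}; expected one of {DOMAINS}")
        idx, cols = self.data.index, self.data.columns
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique().tolist()
            raise ParseError(f"duplicated sample id(s): {dups}")
        if cols.has_duplicates:
            dups = cols[cols.duplicated()].unique().tolist()
            raise ParseError(f"duplicated feature id(s): {dups}")
        values = self.data.to_numpy(dtype=float, copy=False)
        all_nan = np.isnan(values).all(axis=0) if values.size else np.array([], bool)
        if all_nan.any():
            bad = list(cols[all_nan])
            raise ParseError(f"all-NaN feature column(s): {bad}")
        if self.domain != "phenotype" and np.isnan(values).any():
            raise ParseError(f"missing values are only allowed in the phenotype domain, not {self.domain}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_features(self) -> int:
        return self.data.shape[1]

    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def subset_features(self, feature_ids) -> "OmicsMatrix":
        return OmicsMatrix(self.data.loc[:, list(feature_ids)], self.domain)


def read_matrix(path, domain: str) -> OmicsMatrix:
    """Read a features-in-rows TSV into a samples x features :class:`OmicsMatrix`."""
    path = Path(path)
    try:
        raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except pd.errors.ParserError as exc:  # ragged rows and friends
        raise ParseError(f"{path}: malformed table ({exc})") from exc
    if raw.index.has_duplicates:
        dups = raw.index[raw.index.duplicated()].unique().tolist()
        raise ParseError(f"{path}: duplicated feature id(s): {dups}")
    if raw.columns.has_duplicates:
        dups = raw.columns[raw.columns.duplicated()].unique().tolist()
        raise ParseError(f"{path}: duplicated sample id(s): {dups}")
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    # a cell that failed conversion is NaN in `numeric` but non-blank in `raw`
    bad = numeric.isna() & raw.notna() & (raw.apply(lambda c: c.str.strip()) != "")
    if bad.to_numpy().any():
        row, col = np.argwhere(bad.to_numpy())[0]
        raise ParseError(
            f"{path}: non-numeric cell {raw.iat[row, col]!r} at feature "
            f"{raw.index[row]!r}, sample {raw.columns[col]!r}"
        )
    return OmicsMatrix(numeric.T.astype(float), domain)


def write_matrix(matrix: OmicsMatrix, path) -> None:
    """Write an :class:`OmicsMatrix` as a features-in-rows TSV (full precision)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = matrix.data.T
    out.index.name = "feature_id"
    out.to_csv(path, sep="\t", float_format="%.17g")


def align_samples(*matrices: OmicsMatrix) -> tuple[OmicsMatrix, ...]:
    """Restrict matrices to their common samples, in the first matrix's order.

    Raises ``ValueError`` when fewer than two matrices are given or the
    intersection of sample ids is empty.  Dropped samples are logged.
    """
    if len(matrices) < 2:
        raise ValueError("align_samples needs at least two matrices")
    common = set(matrices[0].sample_ids)
    for m in matrices[1:]:
        common &= set(m.sample_ids)
    if not common:
        raise ValueError("no samples shared by all matrices")
    order = [s for s in matrices[0].sample_ids if s in common]
    out = []
    for m in matrices:
        dropped = sorted(set(m.sample_ids) - common)
        if dropped:
            logger.info("align_samples: dropping %d sample(s) from %s domain: %s",
                        len(dropped), m.domain, dropped[:10])
        out.append(OmicsMatrix(m.data.loc[order], m.domain))
    return tuple(out)


@dataclass
class FeatureModuleMap:
    """Many-to-many feature -> module assignment (KO -> KEGG module / GMM)."""

    pairs: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=["feature", "module"]))

    def __post_init__(self) -> None:
        self.pairs = pd.DataFrame(self.pairs, columns=["feature", "module"]).astype(str)
        if (self.pairs["feature"].str.len() == 0).any():
            raise ValueError("empty feature id in module map")

    @classmethod
    def from_dict(cls, mapping: dict[str, list[str] | str]) -> "FeatureModuleMap":
        rows = []
        for feat, mods in mapping.items():
            for mod in ([mods] if isinstance(mods, str) else mods):
                rows.append((feat, mod))
        return cls(pd.DataFrame(rows, columns=["feature", "module"]))

    def members(self, module: str) -> list[str]:
        return self.pairs.loc[self.pairs["module"] == module, "feature"].tolist()

    def modules(self) -> list[str]:
        return sorted(self.pairs["module"].unique())

    @classmethod
    def read(cls, path) -> "FeatureModuleMap":
        df = pd.read_csv(path, sep="\t", dtype=str)
        if df.shape[1] < 2:
            raise ParseError(f"{path}: expected two columns (feature, module)")
        df = df.iloc[:, :2]
        df.columns = ["feature", "module"]
        return cls(df)

    def write(self, path) -> None:
        self.pairs.to_csv(path, sep="\t", index=False)


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path, *, config: dict, seed: int, inputs: dict[str, str] | None = None,
                   extra: dict | None = None) -> dict:
    """Write a JSON run manifest (config snapshot + hash, seed, input checksums)."""
    snapshot = json.dumps(config, sort_keys=True, default=str)
    manifest = {
        "config": config,
        "config_sha256": hashlib.sha256(snapshot.encode()).hexdigest(),
        "seed": int(seed),
        "input_sha256": {name: file_sha256(p) for name, p in (inputs or {}).items()},
    }
    if extra:
        manifest.update(extra)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    return manifest
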