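"""Loading, validation and preprocessing of per-layer omics matrices.

Every omics layer (genomic markers, transcript abundances, metabolite
abundances) and the phenotype block is a lines-by-features numeric matrix
with a shared set of line identifiers.  All layers of one dataset are
aligned onto a single canonical (lexicographically sorted) line order before
any kernel is built, so that every kernel and phenotype vector indexes lines
identically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

LAYERS = ("genomic", "transcriptomic", "metabolomic", "phenotype")

#: tokens treated as missing on input (case-insensitive), besides empty cells
MISSING_TOKENS = ("na", "nan", "n/a", "")


class DataValidationError(ValueError):
    """Raised when an input matrix violates a structural invariant."""


@dataclass(frozen=True)
class FeatureMatrix:
    """A lines x features numeric matrix for one omics layer.

    Parameters
    ----------
    line_ids : tuple of str
        Unique ordered line (genotype) identifiers, length ``n``.
    feature_ids : tuple of str
        Unique ordered feature identifiers, length ``p``.
    values : ndarray of shape (n, p)
        Feature values; ``NaN`` marks missing entries prior to imputation.
    layer : str
        One of :data:`LAYERS`.
    """

    line_ids: tuple
    feature_ids: tuple
    values: np.ndarray
    layer: str = "genomic"

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "line_ids", tuple(str(i) for i in self.line_ids))
        object.__setattr__(self, "feature_ids", tuple(str(i) for i in self.feature_ids))
        if values.ndim != 2:
            raise DataValidationError("values must be a 2-D matrix")
        n, p = values.shape
        if len(self.line_ids) != n:
            raise DataValidationError(
                f"{len(self.line_ids)} line ids for {n} rows"
            )
        if len(self.feature_ids) != p:
            raise DataValidationError(
                f"{len(self.feature_ids)} feature ids for {p} columns"
            )
        if len(set(self.line_ids)) != n:
            dup = _first_duplicate(self.line_ids)
            raise DataValidationError(f"duplicate line ID {dup!r}")
        if len(set(self.feature_ids)) != p:
            dup = _first_duplicate(self.feature_ids)
            raise DataValidationError(f"duplicate feature ID {dup!r}")
        if self.layer not in LAYERS:
            raise DataValidationError(
                f"unknown layer {self.layer!r}; expected one of {LAYERS}"
            )

    @property
    def n_lines(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def has_missing(self) -> bool:
        return bool(np.isnan(self.values).any())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.line_ids), columns=list(self.feature_ids)
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, layer: str) -> "FeatureMatrix":
        return cls(
            line_ids=tuple(map(str, frame.index)),
            feature_ids=tuple(map(str, frame.columns)),
            values=frame.to_numpy(dtype=float),
            layer=layer,
        )

    def reindex(self, line_ids: Sequence[str]) -> "FeatureMatrix":
        """Restrict/reorder rows to ``line_ids`` (all must be present)."""
        pos = {lid: i for i, lid in enumerate(self.line_ids)}
        try:
            rows = [pos[str(lid)] for lid in line_ids]
        except KeyError as exc:
            raise DataValidationError(f"line ID {exc.args[0]!r} not in matrix") from exc
        return replace(
            self,
            line_ids=tuple(str(i) for i in line_ids),
            values=self.values[rows, :],
        )


@dataclass(frozen=True)
class Dataset:
    """Aligned multi-omics dataset: three feature layers plus phenotypes."""

    name: str
    genomic: FeatureMatrix
    transcriptomic: FeatureMatrix
    metabolomic: FeatureMatrix
    phenotypes: FeatureMatrix

    def __post_init__(self):
        ids = self.genomic.line_ids
        for block in (self.transcriptomic, self.metabolomic, self.phenotypes):
            if block.line_ids != ids:
                raise DataValidationError(
                    "all blocks of a Dataset must share identical line order"
                )
        if len(ids) < 4:
            raise DataValidationError(
                f"dataset has {len(ids)} lines; at least 4 required for 50/50 CV"
            )

    @property
    def line_ids(self) -> tuple:
        return self.genomic.line_ids

    @property
    def n_lines(self) -> int:
        return self.genomic.n_lines

    @property
    def traits(self) -> tuple:
        return self.phenotypes.feature_ids

    def layer(self, name: str) -> FeatureMatrix:
        if name not in ("genomic", "transcriptomic", "metabolomic", "phenotype"):
            raise KeyError(name)
        return getattr(self, "phenotypes" if name == "phenotype" else name)

    def trait_vector(self, trait: str) -> np.ndarray:
        if trait not in self.phenotypes.feature_ids:
            raise KeyError(f"unknown trait {trait!r}; have {self.phenotypes.feature_ids}")
        j = self.phenotypes.feature_ids.index(trait)
        return self.phenotypes.values[:, j].copy()


def _first_duplicate(items: Iterable) -> object:
    seen = set()
    for x in items:
        if x in seen:
            return x
        seen.add(x)
    return None


def load_matrix(
    path,
    layer: str,
    delimiter: str = "\t",
    has_header: bool = True,
    missing_tokens: Sequence[str] = MISSING_TOKENS,
) -> FeatureMatrix:
    """Read a delimited lines-x-features matrix.

    The first column holds line IDs; remaining cells must be numeric or one
    of ``missing_tokens`` (case-insensitive).  Non-numeric cells raise a
    parse error naming the offending row and column.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(
        path,
        sep=delimiter,
        header=0 if has_header else None,
        index_col=0,
        dtype=str,
        keep_default_na=False,
    )
    lowered = {t.lower() for t in missing_tokens}
    raw = df.to_numpy()
    values = np.empty(raw.shape, dtype=float)
    for i in range(raw.shape[0]):
        for j in range(raw.shape[1]):
            cell = raw[i, j].strip()
            if cell.lower() in lowered:
                values[i, j] = np.nan
                continue
            try:
                values[i, j] = float(cell)
            except ValueError:
                raise DataValidationError(
                    f"non-numeric cell {cell!r} at line {df.index[i]!r}, "
                    f"feature {df.columns[j]!r} in {path.name}"
                ) from None
    fm = FeatureMatrix(
        line_ids=tuple(map(str, df.index)),
        feature_ids=tuple(map(str, df.columns)),
        values=values,
        layer=layer,
    )
    logger.info(
        "loaded %s: %d lines x %d features (%d missing cells)",
        path.name, fm.n_lines, fm.n_features, int(np.isnan(values).sum()),
    )
    return fm


def write_matrix(X: FeatureMatrix, path, delimiter: str = "\t") -> None:
    """Write a matrix in the same dialect :func:`load_matrix` reads."""
    X.to_frame().to_csv(path, sep=delimiter, index_label="line_id", na_rep="NA")


def mean_impute(X: FeatureMatrix) -> FeatureMatrix:
    """Replace each missing entry with its feature's mean over observed lines.

    Raises if any feature has no observed value at all; callers may drop
    such columns beforehand.
    """
    values = X.values
    if not np.isnan(values).any():
        return X
    observed = ~np.isnan(values)
    n_obs = observed.sum(axis=0)
    if (n_obs == 0).any():
        bad = X.feature_ids[int(np.argmax(n_obs == 0))]
        raise DataValidationError(f"feature {bad!r} has no observed values")
    col_means = np.nansum(values, axis=0) / n_obs
    filled = np.where(observed, values, col_means[np.newaxis, :])
    return replace(X, values=filled)


def standardize_features(X: FeatureMatrix, ddof: int = 1) -> FeatureMatrix:
    """Z-score each feature (mean 0, sample sd 1, n-1 denominator).

    Zero-variance features carry no line-discriminating signal and are
    dropped with a warning.  Requires a complete (imputed) matrix.
    """
    if X.has_missing:
        raise DataValidationError("standardize_features requires an imputed matrix")
    values = X.values
    means = values.mean(axis=0)
    sds = values.std(axis=0, ddof=ddof)
    keep = sds > 0
    if not keep.any():
        raise DataValidationError("all features have zero variance")
    n_dropped = int((~keep).sum())
    if n_dropped:
        dropped = [f for f, k in zip(X.feature_ids, keep) if not k]
        logger.warning(
            "dropping %d zero-variance feature(s): %s%s",
            n_dropped, ", ".join(dropped[:5]), "..." if n_dropped > 5 else "",
        )
    z = (values[:, keep] - means[keep]) / sds[keep]
    return replace(
        X,
        feature_ids=tuple(f for f, k in zip(X.feature_ids, keep) if k),
        values=z,
    )


def align_layers(blocks: Sequence[FeatureMatrix], name: str = "dataset") -> Dataset:
    """Intersect line IDs across blocks and reorder all to sorted-ID order.

    ``blocks`` must contain exactly one matrix per layer of :class:`Dataset`
    (genomic, transcriptomic, metabolomic, phenotype), in any order.
    """
    by_layer = {}
    for b in blocks:
        if b.layer in by_layer:
            raise DataValidationError(f"two blocks with layer {b.layer!r}")
        by_layer[b.layer] = b
    missing = set(LAYERS) - set(by_layer)
    if missing:
        raise DataValidationError(f"missing layer(s): {sorted(missing)}")

    common = set(by_layer["genomic"].line_ids)
    for b in by_layer.values():
        common &= set(b.line_ids)
    if not common:
        raise DataValidationError("no line IDs shared by all layers")
    order = tuple(sorted(common))
    total = {lid for b in by_layer.values() for lid in b.line_ids}
    n_dropped = len(total) - len(common)
    if n_dropped:
        logger.info("align_layers: dropped %d line(s) absent from some layer", n_dropped)
    return Dataset(
        name=name,
        genomic=by_layer["genomic"].reindex(order),
        transcriptomic=by_layer["transcriptomic"].reindex(order),
        metabolomic=by_layer["metabolomic"].reindex(order),
        phenotypes=by_layer["phenotype"].reindex(order),
    )


def preprocess_layer(X: FeatureMatrix, standardize: bool = True) -> FeatureMatrix:
    """Impute then (optionally) standardize — the canonical preprocessing order."""
    X = mean_impute(X)
    return standardize_features(X) if standardize else X
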