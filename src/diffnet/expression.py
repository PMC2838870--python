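"""Expression-matrix container, standardization, file I/O and the phenotype z-score filter.

The canonical layout is samples in rows and genes in columns (an ``N x p``
matrix), the convention used throughout the package.  Files with genes in
rows can be loaded with ``orientation="genes"``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "ZeroVarianceError",
    "standardize_expression",
    "read_expression_matrix",
    "write_expression_matrix",
    "zscore_filter",
]


class ZeroVarianceError(ValueError):
    """A gene has zero sample variance, so it cannot be standardized."""


@dataclass
class ExpressionMatrix:
    """An ``N x p`` matrix of expression values with gene and sample labels.

    Parameters
    ----------
    values : ndarray of shape (n_samples, n_genes)
        Numeric expression values; no missing entries allowed.
    gene_ids : sequence of str
        Unique gene identifiers, one per column.
    sample_ids : sequence of str, optional
        Sample identifiers; defaults to ``s1 .. sN``.
    """

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D samples x genes matrix")
        n, p = self.values.shape
        self.gene_ids = [str(g) for g in self.gene_ids]
        if not self.sample_ids:
            self.sample_ids = [f"s{i + 1}" for i in range(n)]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if len(self.gene_ids) != p:
            raise ValueError(f"{len(self.gene_ids)} gene ids for {p} columns")
        if len(self.sample_ids) != n:
            raise ValueError(f"{len(self.sample_ids)} sample ids for {n} rows")
        if len(set(self.gene_ids)) != p:
            dupes = sorted({g for g in self.gene_ids if self.gene_ids.count(g) > 1})
            raise ValueError(f"duplicate gene ids: {', '.join(dupes)}")
        if p < 2:
            raise ValueError("need at least 2 genes")
        if n < 3:
            raise ValueError("need at least 3 samples")
        if not np.isfinite(self.values).all():
            raise ValueError("expression matrix contains missing or non-finite values")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        """Build from a samples x genes DataFrame (index = samples, columns = genes)."""
        return cls(df.to_numpy(dtype=float), list(df.columns), list(df.index.astype(str)))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.gene_ids)

    def subset_genes(self, genes: list[str]) -> "ExpressionMatrix":
        idx = [self.gene_index(g) for g in genes]
        return ExpressionMatrix(self.values[:, idx], list(genes), list(self.sample_ids))

    def gene_index(self, gene: str) -> int:
        try:
            return self.gene_ids.index(gene)
        except ValueError:
            raise KeyError(f"unknown gene id: {gene}") from None


def _standardize_values(values: np.ndarray, gene_ids: list[str] | None = None) -> np.ndarray:
    """Center columns and scale to unit sample standard deviation (n-1 denominator)."""
    values = np.asarray(values, dtype=float)
    mean = values.mean(axis=0)
    sd = values.std(axis=0, ddof=1)
    zero = np.flatnonzero(sd == 0.0)
    if zero.size:
        names = (
            ", ".join(gene_ids[j] for j in zero)
            if gene_ids is not None
            else ", ".join(f"column {j}" for j in zero)
        )
        raise ZeroVarianceError(f"constant expression (zero variance) for: {names}")
    return (values - mean) / sd


def standardize_expression(x: ExpressionMatrix) -> ExpressionMatrix:
    """Return a copy of *x* with each gene centered and scaled to unit variance.

    Uses the sample standard deviation (``ddof=1``).  A constant gene raises
    :class:`ZeroVarianceError` naming the offending gene.
    """
    z = _standardize_values(x.values, x.gene_ids)
    return ExpressionMatrix(z, list(x.gene_ids), list(x.sample_ids))


def _infer_sep(path: str) -> str:
    return "," if str(path).lower().endswith(".csv") else "\t"


def read_expression_matrix(path, orientation: str = "samples") -> ExpressionMatrix:
    """Load a delimited expression matrix (TSV by default, CSV by extension).

    Parameters
    ----------
    orientation : {"samples", "genes"}
        ``"samples"`` (default) means rows are samples and columns are genes;
        ``"genes"`` means the file stores genes in rows and is transposed on
        load.

    Rows (samples) containing missing values are dropped with a warning
    reporting the count; non-numeric cells raise a parse error.
    """
    if orientation not in ("samples", "genes"):
        raise ValueError(f"orientation must be 'samples' or 'genes', got {orientation!r}")
    sep = _infer_sep(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)[1:]
    dupes = sorted({h for h in header if header.count(h) > 1})
    if dupes and orientation == "samples":  # pandas would silently mangle these
        raise ValueError(f"duplicate gene ids in header of {path}: {', '.join(dupes)}")
    df = pd.read_csv(path, sep=sep, index_col=0)
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        bad = [
            (i + 2, str(col))  # +2: header line plus 1-based numbering
            for i, row in enumerate(df.itertuples(index=False))
            for col, val in zip(df.columns, row)
            if not _is_number(val)
        ]
        loc = "; ".join(f"line {ln}, column {col}" for ln, col in bad[:5])
        raise ValueError(f"non-numeric cells in {path} ({loc})") from exc
    if orientation == "genes":
        df = df.T
    n_missing = int(df.isna().any(axis=1).sum())
    if n_missing:
        warnings.warn(
            f"dropped {n_missing} sample(s) with missing values from {path}",
            stacklevel=2,
        )
        df = df.dropna(axis=0)
    return ExpressionMatrix.from_dataframe(df)


def _is_number(val) -> bool:
    try:
        float(val)
        return True
    except (TypeError, ValueError):
        return False


def write_expression_matrix(x: ExpressionMatrix, path) -> None:
    """Write a samples x genes delimited file (TSV, or CSV by extension)."""
    x.to_dataframe().to_csv(path, sep=_infer_sep(path), index_label="sample")


def zscore_filter(
    x: ExpressionMatrix,
    phenotype: np.ndarray,
    threshold: float,
    two_sided: bool = True,
) -> list[str]:
    """Select genes whose univariate regression z-score exceeds *threshold*.

    For each gene, the phenotype is regressed on that gene's expression by
    simple least squares; the z-score is the slope estimate divided by its
    standard error.  Genes with ``|z| > threshold`` (or ``z > threshold`` when
    ``two_sided=False``) are returned.  Zero-variance genes have an undefined
    slope standard error and are excluded with a warning.
    """
    y = np.asarray(phenotype, dtype=float).ravel()
    n = x.n_samples
    if y.shape[0] != n:
        raise ValueError(f"phenotype length {y.shape[0]} != number of samples {n}")
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if n < 4:
        raise ValueError("need at least 4 samples for a slope standard error")

    vals = x.values
    sd = vals.std(axis=0, ddof=1)
    # relative tolerance: a constant column can carry O(eps) rounding residue
    scale = np.maximum(np.abs(vals).max(axis=0), 1.0)
    degenerate = sd <= 1e-12 * scale
    if degenerate.any():
        names = ", ".join(g for g, bad in zip(x.gene_ids, degenerate) if bad)
        warnings.warn(f"excluding zero-variance gene(s) from z-filter: {names}", stacklevel=2)

    with np.errstate(divide="ignore", invalid="ignore"):
        xc = vals - vals.mean(axis=0)
        yc = y - y.mean()
        sxx = (xc**2).sum(axis=0)
        slope = xc.T @ yc / sxx
        rss = (yc**2).sum() - slope**2 * sxx
        rss = np.maximum(rss, 0.0)
        se = np.sqrt(rss / (n - 2) / sxx)
        z = np.where(se > 0, slope / se, np.inf * np.sign(slope))
    z[degenerate] = np.nan

    keep = np.abs(z) > threshold if two_sided else z > threshold
    keep &= ~np.isnan(z)
    return [g for g, k in zip(x.gene_ids, keep) if k]
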