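"""Pairwise gene-gene connectivity scores.

Three families of scores are implemented, all computed on centered and
scaled expression columns:

* **correlation** — the Pearson correlation between two genes' expression
  vectors;
* **partial correlation** — obtained from the inverse of the (optionally
  shrunk) correlation matrix, usable when there are fewer samples than
  genes thanks to shrinkage toward the zero-correlation target;
* **PLS** — each gene is regressed on all remaining genes by partial least
  squares (PLS1 with design-matrix deflation); the connectivity score of a
  pair is the symmetrized regression coefficient expressed on the original
  predictors.

Every score is symmetric; the diagonal carries no information and is never
used by downstream statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix, ZeroVarianceError, _standardize_values

__all__ = [
    "ScoreMatrix",
    "PLSFit",
    "SingularCorrelationError",
    "correlation_scores",
    "partial_correlation_scores",
    "estimate_shrinkage_lambda",
    "pls1_fit",
    "pls_scores",
    "compute_scores",
    "score_values",
]

SCORE_KINDS = ("correlation", "partial_correlation", "pls")

_WEIGHT_TOL = 1e-12  # ||X'y|| below this stops PLS component extraction


class SingularCorrelationError(np.linalg.LinAlgError):
    """The sample correlation matrix is singular; shrinkage is required."""


@dataclass
class ScoreMatrix:
    """A symmetric ``p x p`` matrix of pairwise connectivity scores."""

    values: np.ndarray
    gene_ids: list[str]
    score_kind: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        p = len(self.gene_ids)
        if self.values.shape != (p, p):
            raise ValueError(f"score matrix shape {self.values.shape} != ({p}, {p})")
        if self.score_kind not in SCORE_KINDS:
            raise ValueError(f"unknown score kind {self.score_kind!r}")
        asym = np.abs(self.values - self.values.T).max() if p else 0.0
        if asym > 1e-10:
            raise ValueError(f"score matrix not symmetric (max asymmetry {asym:g})")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def gene_index(self, gene: str) -> int:
        try:
            return self.gene_ids.index(gene)
        except ValueError:
            raise KeyError(f"unknown gene id: {gene}") from None

    def offdiagonal(self) -> np.ndarray:
        """All off-diagonal entries as a flat array (each unordered pair twice)."""
        mask = ~np.eye(self.n_genes, dtype=bool)
        return self.values[mask]

    def to_tsv(self, path) -> None:
        """Square TSV with gene ids as header row and first column.

        Values are written in scientific notation with 17 significant digits
        so that a round-trip is lossless.
        """
        df = pd.DataFrame(self.values, index=self.gene_ids, columns=self.gene_ids)
        df.to_csv(path, sep="\t", float_format="%.16e", index_label="gene")

    @classmethod
    def from_tsv(cls, path, score_kind: str = "correlation", params: dict | None = None) -> "ScoreMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        if list(df.index.astype(str)) != [str(c) for c in df.columns]:
            raise ValueError(f"{path}: row and column gene ids differ; not a score matrix")
        return cls(df.to_numpy(dtype=float), [str(c) for c in df.columns], score_kind, params or {})


@dataclass
class PLSFit:
    """A fitted univariate-response partial least squares model.

    Attributes
    ----------
    weights : ndarray (q, v_eff)
        Unit-norm predictor weight vectors, one column per component.
    scores : ndarray (n, v_eff)
        Latent score vectors ``t``; mutually orthogonal.
    loadings : ndarray (v_eff,)
        Response regression coefficients ``q`` on each latent component.
    x_loadings : ndarray (q, v_eff)
        Predictor loadings used for deflation.
    beta : ndarray (q,)
        Model coefficients mapped back to the original (deflation-free)
        predictors, so that fitted values are ``Z @ beta``.
    n_components : int
        Effective number of components (may be less than requested if weight
        vectors degenerate to zero).
    """

    weights: np.ndarray
    scores: np.ndarray
    loadings: np.ndarray
    x_loadings: np.ndarray
    beta: np.ndarray
    n_components: int
    response_gene: str | None = None


def _corr_from_standardized(z: np.ndarray) -> np.ndarray:
    n = z.shape[0]
    r = z.T @ z / (n - 1)
    np.clip(r, -1.0, 1.0, out=r)
    np.fill_diagonal(r, 1.0)
    return r


def correlation_scores(x: ExpressionMatrix) -> ScoreMatrix:
    """Pearson correlation between every pair of genes."""
    z = _standardize_values(x.values, x.gene_ids)
    return ScoreMatrix(_corr_from_standardized(z), list(x.gene_ids), "correlation")


def estimate_shrinkage_lambda(x: ExpressionMatrix) -> float:
    """Analytic shrinkage intensity for the zero-off-diagonal correlation target.

    Implements the variance-ratio estimator
    ``lambda* = sum_{i<k} Var_hat(r_ik) / sum_{i<k} r_ik^2`` with the
    empirical variance of each correlation coefficient computed from the
    products of standardized observations, clipped to ``[0, 1]``.  Large
    samples with strong true correlations drive the estimate toward 0; pure
    noise drives it toward 1.
    """
    if x.n_samples < 4:
        raise ValueError("need at least 4 samples to estimate the shrinkage intensity")
    z = _standardize_values(x.values, x.gene_ids)
    n = z.shape[0]
    r = z.T @ z / (n - 1)
    # w[s,i,k] = z[s,i]*z[s,k]; Var_hat(r_ik) = n/(n-1)^3 * sum_s (w_sik - mean_s w)^2
    w_mean = r * (n - 1) / n
    sq_sum = (z**2).T @ (z**2)  # sum_s w_sik^2
    var_r = n / (n - 1.0) ** 3 * (sq_sum - n * w_mean**2)
    iu = np.triu_indices(z.shape[1], k=1)
    denom = float((r[iu] ** 2).sum())
    num = float(var_r[iu].sum())
    if denom == 0.0:
        return 1.0
    return float(np.clip(num / denom, 0.0, 1.0))


def partial_correlation_scores(
    x: ExpressionMatrix,
    shrink: bool = False,
    shrinkage_lambda: float | str = "auto",
) -> ScoreMatrix:
    """Partial correlations from the inverse of the (possibly shrunk) correlation matrix.

    With ``shrink=True`` the correlation matrix is replaced by
    ``lambda*T + (1-lambda)*R`` where the target ``T`` is the identity
    (unit variances, zero correlations) and ``lambda`` is either supplied or
    estimated by :func:`estimate_shrinkage_lambda`.  Without shrinkage the
    sample correlation matrix must be invertible, which in practice requires
    more samples than genes.
    """
    z = _standardize_values(x.values, x.gene_ids)
    r = _corr_from_standardized(z)
    params: dict = {"shrink": shrink}
    if shrink:
        lam = estimate_shrinkage_lambda(x) if shrinkage_lambda == "auto" else float(shrinkage_lambda)
        if not 0.0 <= lam <= 1.0:
            raise ValueError(f"shrinkage lambda must be in [0, 1], got {lam}")
        r = (1.0 - lam) * r
        np.fill_diagonal(r, 1.0)
        params["shrinkage_lambda"] = lam
        params["target"] = "identity"
    # reciprocal condition number guards against numerically singular input
    if not shrink:
        if x.n_samples <= x.n_genes or np.linalg.cond(r) > 1e12:
            raise SingularCorrelationError(
                "sample correlation matrix is singular or ill-conditioned "
                f"(N={x.n_samples}, p={x.n_genes}); use shrink=True"
            )
    omega = np.linalg.inv(r)
    d = np.sqrt(np.diag(omega))
    s = -omega / np.outer(d, d)
    s = (s + s.T) / 2.0
    np.clip(s, -1.0, 1.0, out=s)
    np.fill_diagonal(s, 1.0)
    return ScoreMatrix(s, list(x.gene_ids), "partial_correlation", params)


def pls1_fit(y: np.ndarray, z: np.ndarray, v: int, response_gene: str | None = None) -> PLSFit:
    """Fit a single-response PLS model with *v* components by deflation.

    Both *y* and the columns of *z* are expected to be centered and scaled.
    Each iteration extracts a unit-norm weight vector proportional to
    ``X' y``, forms the latent score ``t = X w``, regresses the response on
    ``t`` and deflates the design matrix by the rank-one fit of ``t``.  If
    the weight vector degenerates to numerical zero the iteration stops
    early and the effective number of components is recorded.
    """
    y = np.asarray(y, dtype=float).ravel()
    x_work = np.array(z, dtype=float)
    n, q = x_work.shape
    if y.shape[0] != n:
        raise ValueError("response and predictors have different sample counts")
    if not 1 <= v <= min(n - 1, q):
        raise ValueError(f"v must be in [1, min(N-1, q)] = [1, {min(n - 1, q)}], got {v}")

    weights, t_scores, q_loads, p_loads = [], [], [], []
    for _ in range(v):
        c = x_work.T @ y
        if np.linalg.norm(c) < _WEIGHT_TOL:
            break
        w = c / np.linalg.norm(c)
        t = x_work @ w
        tt = float(t @ t)
        if tt < _WEIGHT_TOL:
            break
        q_l = float(t @ y) / tt
        p_l = x_work.T @ t / tt
        x_work -= np.outer(t, p_l)
        weights.append(w)
        t_scores.append(t)
        q_loads.append(q_l)
        p_loads.append(p_l)

    v_eff = len(weights)
    if v_eff == 0:
        zero = np.zeros(q)
        return PLSFit(
            np.zeros((q, 0)), np.zeros((n, 0)), np.zeros(0), np.zeros((q, 0)),
            zero, 0, response_gene,
        )
    w_mat = np.column_stack(weights)
    p_mat = np.column_stack(p_loads)
    q_vec = np.asarray(q_loads)
    # rotation R = W (P'W)^-1 maps original predictors to latent scores; P'W is
    # unit upper triangular so the solve is well posed
    r_mat = w_mat @ np.linalg.inv(np.triu(p_mat.T @ w_mat))
    beta = r_mat @ q_vec
    return PLSFit(
        w_mat, np.column_stack(t_scores), q_vec, p_mat, beta, v_eff, response_gene
    )


def pls_scores(x: ExpressionMatrix, v: int = 3) -> ScoreMatrix:
    """PLS-based connectivity scores.

    Each gene in turn is taken as the response and regressed on all remaining
    genes with :func:`pls1_fit`; the raw association ``T_ik`` is the
    coefficient of gene *k* in the *v*-component fit of gene *i*, expressed on
    the original predictors.  The reported score is the symmetrized value
    ``(T_ik + T_ki)/2``.  The requested number of components is capped at
    ``min(N-1, p-1)``.
    """
    z = _standardize_values(x.values, x.gene_ids)
    n, p = z.shape
    v_use = int(min(v, n - 1, p - 1))
    if v_use < 1:
        raise ValueError("cannot extract any PLS component from this matrix")
    t_mat = np.zeros((p, p))
    predictors = np.arange(p)
    for i in range(p):
        others = predictors[predictors != i]
        fit = pls1_fit(z[:, i], z[:, others], v_use, response_gene=x.gene_ids[i])
        if fit.n_components == 0:
            warnings.warn(
                f"gene {x.gene_ids[i]}: response orthogonal to all predictors; "
                "score row set to 0",
                stacklevel=2,
            )
        t_mat[i, others] = fit.beta
    s = (t_mat + t_mat.T) / 2.0
    np.fill_diagonal(s, 0.0)
    return ScoreMatrix(s, list(x.gene_ids), "pls", {"v": v_use})


def compute_scores(
    x: ExpressionMatrix,
    score_kind: str = "correlation",
    v: int = 3,
    shrink: bool = False,
    shrinkage_lambda: float | str = "auto",
) -> ScoreMatrix:
    """Dispatch to the requested score family."""
    if score_kind == "correlation":
        return correlation_scores(x)
    if score_kind == "partial_correlation":
        return partial_correlation_scores(x, shrink=shrink, shrinkage_lambda=shrinkage_lambda)
    if score_kind == "pls":
        return pls_scores(x, v=v)
    raise ValueError(f"unknown score kind {score_kind!r}; choose from {SCORE_KINDS}")


def score_values(
    values: np.ndarray,
    score_kind: str = "correlation",
    v: int = 3,
    shrink: bool = False,
    shrinkage_lambda: float | str = "auto",
) -> np.ndarray:
    """Plain-array scoring used in permutation loops.

    Standardizes the columns of *values* and returns the score matrix as an
    ndarray, skipping label bookkeeping.  Semantics are identical to
    :func:`compute_scores`.
    """
    if score_kind == "correlation":
        return _corr_from_standardized(_standardize_values(values))
    n, p = np.asarray(values).shape
    ids = [f"g{j}" for j in range(p)]
    x = ExpressionMatrix(values, ids) if n >= 3 and p >= 2 else None
    if x is None:
        raise ValueError("matrix too small to score")
    return compute_scores(
        x, score_kind=score_kind, v=v, shrink=shrink, shrinkage_lambda=shrinkage_lambda
    ).values
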