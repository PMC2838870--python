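"""Differential-network test statistics and the pooled-row permutation scheme.

Three statistics compare networks built from the same genes under two
conditions:

* the **proportion-of-non-overlap** statistic contrasts the modular
  structures of the two networks (0 = identical, 1 = modules share nothing
  beyond the anchoring gene);
* the **class MDA** statistic ``Delta(F)`` averages ``|s1 - s2|`` over all
  gene pairs inside a designated class ``F`` (an L1-type distance);
* the **single-gene MDA** statistic ``d(g)`` averages ``|s1 - s2|`` over
  all pairs involving gene *g*.

Significance is assessed by pooling the samples of both conditions,
randomly permuting the row labels, re-running the entire analysis
(standardization, scoring, thresholding, module finding) on each permuted
split, and reporting the fraction of permutation statistics at least as
large as the observed one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from statsmodels.stats.multitest import multipletests

from .expression import ExpressionMatrix
from .network_modules import ModuleSet

__all__ = [
    "PooledData",
    "DiffTestResult",
    "nonoverlap_statistic",
    "class_mda",
    "gene_mda",
    "gene_mda_all",
    "pool_rows",
    "permutation_pvalue",
    "bh_adjust",
]


@dataclass
class PooledData:
    """Both conditions' samples stacked, condition 1 rows first."""

    pooled: np.ndarray
    n1: int
    n2: int
    gene_ids: list[str]


@dataclass
class DiffTestResult:
    """Observed statistic(s), permutation replicates and p-value(s).

    ``statistic`` and ``p_value`` are scalars for the modular-structure and
    gene-class tests and per-gene vectors for the single-gene test; in the
    vector case all components share the same ``n_permutations`` random
    permutations.
    """

    statistic: float | np.ndarray
    perm_stats: np.ndarray
    p_value: float | np.ndarray
    n_permutations: int
    seed: int | None = None
    params: dict = field(default_factory=dict)
    gene_ids: list[str] | None = None
    p_adjusted: np.ndarray | None = None

    @property
    def is_vector(self) -> bool:
        return np.ndim(self.statistic) > 0

    def adjust(self) -> np.ndarray:
        """Attach and return BH-adjusted p-values (vector results only)."""
        if not self.is_vector:
            raise ValueError("BH adjustment applies to vector (per-gene) results")
        self.p_adjusted = bh_adjust(np.asarray(self.p_value))
        return self.p_adjusted

    def format_p(self, p: float) -> str:
        return f"< {1.0 / self.n_permutations:g}" if p == 0.0 else f"{p:g}"


def nonoverlap_statistic(m1: ModuleSet, m2: ModuleSet) -> float:
    """Proportion-of-non-overlap between the modular structures of two networks.

    Let G be the genes that belong to some module in *both* networks.  For a
    gene g in G with containing modules F1(g) and F2(g), the per-gene
    non-overlap is ``1 - (|F1 ∩ F2| - 1) / (|F1 ∪ F2| - 1)`` (the anchoring
    gene itself is discounted, so identical modules score 0 and modules
    sharing only g score 1).  The statistic is the mean over G, with an
    empty G yielding 0.
    """
    if set(m1.gene_ids) != set(m2.gene_ids):
        raise ValueError("module sets are defined over different gene universes")
    shared = m1.covered_genes & m2.covered_genes
    if not shared:
        return 0.0
    total = 0.0
    for g in shared:
        f1 = m1.module_of(g)
        f2 = m2.module_of(g)
        union = len(f1 | f2)
        if union == 1:  # both modules are {g}; only possible when m = 1
            continue
        total += 1.0 - (len(f1 & f2) - 1.0) / (union - 1.0)
    return total / len(shared)


def nonoverlap_from_labels(lab1: np.ndarray, lab2: np.ndarray) -> float:
    """Non-overlap statistic from per-gene module labels (-1 = no module).

    Array-level equivalent of :func:`nonoverlap_statistic`, used inside
    permutation loops where building ModuleSet objects would dominate the
    cost.
    """
    lab1 = np.asarray(lab1)
    lab2 = np.asarray(lab2)
    shared = (lab1 >= 0) & (lab2 >= 0)
    if not shared.any():
        return 0.0
    size1 = np.bincount(lab1[lab1 >= 0])
    size2 = np.bincount(lab2[lab2 >= 0])
    # genes sharing both labels form the intersection of the two modules
    pairs = lab1[shared] * (lab2.max() + 1) + lab2[shared]
    _, inverse, counts = np.unique(pairs, return_inverse=True, return_counts=True)
    inter = counts[inverse].astype(float)
    union = size1[lab1[shared]] + size2[lab2[shared]] - inter
    terms = np.where(union > 1, 1.0 - (inter - 1.0) / np.maximum(union - 1.0, 1.0), 0.0)
    return float(terms.mean())


def class_mda(s1, s2, gene_class) -> float:
    """Mean absolute distance of scores over all unordered pairs within a class.

    ``Delta(F) = mean_{i<j in F} |s_ij^(1) - s_ij^(2)|``.
    """
    genes = list(gene_class)
    if len(genes) < 2:
        raise ValueError("gene class must contain at least 2 genes")
    if s1.gene_ids != s2.gene_ids:
        raise ValueError("score matrices are defined over different gene universes")
    unknown = [g for g in genes if g not in s1.gene_ids]
    if unknown:
        raise KeyError(f"unknown gene ids in class: {', '.join(map(str, unknown))}")
    idx = np.array([s1.gene_index(g) for g in genes])
    d = np.abs(s1.values[np.ix_(idx, idx)] - s2.values[np.ix_(idx, idx)])
    iu = np.triu_indices(len(idx), k=1)
    return float(d[iu].mean())


def gene_mda(s1, s2, gene) -> float:
    """Mean absolute score distance between gene *g* and every other gene.

    ``d(g) = mean_{g' != g} |s_{gg'}^(1) - s_{gg'}^(2)|``.
    """
    if s1.gene_ids != s2.gene_ids:
        raise ValueError("score matrices are defined over different gene universes")
    g = s1.gene_index(gene)
    diff = np.abs(s1.values[g] - s2.values[g])
    diff[g] = 0.0
    return float(diff.sum() / (len(s1.gene_ids) - 1))


def gene_mda_all(s1_values: np.ndarray, s2_values: np.ndarray) -> np.ndarray:
    """Vector of d(g) for every gene, from plain score arrays."""
    diff = np.abs(s1_values - s2_values)
    np.fill_diagonal(diff, 0.0)
    return diff.sum(axis=1) / (diff.shape[1] - 1)


def pool_rows(x1: ExpressionMatrix, x2: ExpressionMatrix) -> PooledData:
    """Stack the two conditions' samples, condition 1 first."""
    if x1.gene_ids != x2.gene_ids:
        raise ValueError("expression matrices have different gene ids or ordering")
    return PooledData(
        np.vstack([x1.values, x2.values]), x1.n_samples, x2.n_samples, list(x1.gene_ids)
    )


def permutation_pvalue(
    x1: ExpressionMatrix,
    x2: ExpressionMatrix,
    statistic_fn,
    n_permutations: int = 1000,
    seed: int | None = None,
    params: dict | None = None,
) -> DiffTestResult:
    """Pooled-row permutation p-value for an arbitrary two-sample statistic.

    ``statistic_fn(values1, values2)`` receives raw (unstandardized) group
    matrices and must contain the full analysis recipe — standardization,
    scoring, thresholding, module finding — so the permutation scheme
    re-runs the entire pipeline on each relabelled split.  Permutations are
    drawn uniformly (with replacement, identity included) from the symmetric
    group; ``p = #(permutation statistic >= observed) / P``, computed
    component-wise for vector statistics from the same permutations.  A
    reported p of exactly 0 therefore means "< 1/P".
    """
    if n_permutations < 1:
        raise ValueError("need at least one permutation")
    if isinstance(x1, ExpressionMatrix) and isinstance(x2, ExpressionMatrix):
        pooled = pool_rows(x1, x2)
        gene_ids = list(x1.gene_ids)
        v1, v2 = x1.values, x2.values
    else:  # plain arrays, e.g. for custom statistics on tiny designs
        v1 = np.asarray(x1, dtype=float)
        v2 = np.asarray(x2, dtype=float)
        if v1.shape[1] != v2.shape[1]:
            raise ValueError("the two groups must have the same number of columns")
        pooled = PooledData(np.vstack([v1, v2]), v1.shape[0], v2.shape[0],
                            [f"g{j + 1}" for j in range(v1.shape[1])])
        gene_ids = pooled.gene_ids
    observed = np.asarray(statistic_fn(v1, v2), dtype=float)
    rng = np.random.default_rng(seed)
    n = pooled.n1 + pooled.n2
    perm_stats = np.empty((n_permutations,) + observed.shape)
    for b in range(n_permutations):
        order = rng.permutation(n)
        a = pooled.pooled[order[: pooled.n1]]
        b_rows = pooled.pooled[order[pooled.n1:]]
        perm_stats[b] = statistic_fn(a, b_rows)
    p = (perm_stats >= observed).mean(axis=0)
    scalar = observed.ndim == 0
    return DiffTestResult(
        statistic=float(observed) if scalar else observed,
        perm_stats=perm_stats,
        p_value=float(p) if scalar else p,
        n_permutations=n_permutations,
        seed=seed,
        params=params or {},
        gene_ids=None if scalar else gene_ids,
    )


def bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Step-up Benjamini–Hochberg adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
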