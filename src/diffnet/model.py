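"""Model and results classes for two-condition differential network analysis.

:class:`DifferentialNetworkAnalysis` is constructed from two expression
matrices over the same genes (e.g. control and treatment samples).  Its
three test methods return results objects carrying the observed statistic,
the permutation null replicates, p-values and a ``summary()`` table:

>>> from diffnet import DifferentialNetworkAnalysis, simulate_gaussian_pair
>>> from diffnet.simulation import SimulationDesign
>>> x1, x2 = simulate_gaussian_pair(SimulationDesign(p=20, n=50, rho=0.5, seed=1))
>>> model = DifferentialNetworkAnalysis(x1, x2, score_kind="correlation")
>>> res = model.test_single_genes(n_permutations=500, seed=2)
>>> print(res.summary())              # doctest: +SKIP
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diff_tests import (
    DiffTestResult,
    gene_mda_all,
    nonoverlap_from_labels,
    permutation_pvalue,
)
from .expression import ExpressionMatrix
from .network_modules import ModuleSet, find_modules, module_labels
from .scores import ScoreMatrix, compute_scores, score_values

__all__ = [
    "DifferentialNetworkAnalysis",
    "ModularStructureResults",
    "GeneClassResults",
    "SingleGeneResults",
]


def _as_expression(x) -> ExpressionMatrix:
    if isinstance(x, ExpressionMatrix):
        return x
    if isinstance(x, pd.DataFrame):
        return ExpressionMatrix.from_dataframe(x)
    raise TypeError("expected an ExpressionMatrix or a samples x genes DataFrame")


class DifferentialNetworkAnalysis:
    """Differential network analysis of two gene-expression conditions.

    Parameters
    ----------
    x1, x2 : ExpressionMatrix or DataFrame
        Samples x genes expression data for the two conditions.  Both must
        carry the same genes in the same order; sample counts may differ.
    score_kind : {"correlation", "partial_correlation", "pls"}
        Connectivity score family used to build each network.
    v : int
        Number of PLS components (``score_kind="pls"`` only).
    shrink : bool
        Shrink the correlation matrix toward the identity target before
        inversion (``score_kind="partial_correlation"``; required when
        samples < genes).
    shrinkage_lambda : float or "auto"
        Shrinkage intensity; "auto" uses the analytic variance-ratio
        estimator.

    Notes
    -----
    Standardization (centering and scaling of every gene) happens inside
    the scoring step, so each permuted group in a permutation test is
    re-standardized before scoring, as the pooled-row permutation scheme
    requires.
    """

    def __init__(
        self,
        x1,
        x2,
        score_kind: str = "correlation",
        v: int = 3,
        shrink: bool = False,
        shrinkage_lambda: float | str = "auto",
    ) -> None:
        self.x1 = _as_expression(x1)
        self.x2 = _as_expression(x2)
        if self.x1.gene_ids != self.x2.gene_ids:
            raise ValueError("the two conditions must share the same genes in the same order")
        self.score_kind = score_kind
        self.v = v
        self.shrink = shrink
        self.shrinkage_lambda = shrinkage_lambda
        self._scores: tuple[ScoreMatrix, ScoreMatrix] | None = None

    @classmethod
    def from_dataframes(cls, df1: pd.DataFrame, df2: pd.DataFrame, **kwargs):
        """Build from two samples x genes DataFrames (columns = gene ids)."""
        return cls(df1, df2, **kwargs)

    @property
    def gene_ids(self) -> list[str]:
        return self.x1.gene_ids

    @property
    def score_params(self) -> dict:
        return {
            "score_kind": self.score_kind,
            "v": self.v,
            "shrink": self.shrink,
            "shrinkage_lambda": self.shrinkage_lambda,
        }

    def _score_array(self, values: np.ndarray) -> np.ndarray:
        return score_values(
            values,
            score_kind=self.score_kind,
            v=self.v,
            shrink=self.shrink,
            shrinkage_lambda=self.shrinkage_lambda,
        )

    def scores(self) -> tuple[ScoreMatrix, ScoreMatrix]:
        """Connectivity score matrices of the two networks (cached)."""
        if self._scores is None:
            kw = dict(
                score_kind=self.score_kind,
                v=self.v,
                shrink=self.shrink,
                shrinkage_lambda=self.shrinkage_lambda,
            )
            self._scores = (compute_scores(self.x1, **kw), compute_scores(self.x2, **kw))
        return self._scores

    def modules(self, m: int, epsilon: float) -> tuple[ModuleSet, ModuleSet]:
        """Module sets of the two networks under minimum size *m* and threshold *epsilon*."""
        s1, s2 = self.scores()
        return (
            find_modules(s1, m, epsilon, network_label="network1"),
            find_modules(s2, m, epsilon, network_label="network2"),
        )

    # -- the three permutation tests ------------------------------------

    def test_modular_structure(
        self,
        m: int = 5,
        epsilon: float = 0.5,
        n_permutations: int = 1000,
        seed: int | None = None,
    ) -> "ModularStructureResults":
        """Test whether the modular structures of the two networks differ.

        The observed statistic is the proportion of non-overlap between the
        module memberships of genes present in some module in both
        networks; significance comes from pooled-row permutations that
        re-run scoring and module finding on every relabelled split.
        """
        def stat(a: np.ndarray, b: np.ndarray) -> float:
            lab1 = module_labels(self._score_array(a), m, epsilon)
            lab2 = module_labels(self._score_array(b), m, epsilon)
            return nonoverlap_from_labels(lab1, lab2)

        params = {**self.score_params, "m": m, "epsilon": epsilon}
        raw = permutation_pvalue(self.x1, self.x2, stat, n_permutations, seed, params)
        return ModularStructureResults(self, raw, m, epsilon)

    def test_gene_class(
        self,
        gene_class,
        n_permutations: int = 1000,
        seed: int | None = None,
    ) -> "GeneClassResults":
        """Test whether the connectivity of a class of genes has changed.

        The statistic is the mean absolute score distance Delta(F) over all
        pairs within the class.
        """
        genes = list(gene_class)
        idx = np.array([self.x1.gene_index(g) for g in genes])
        if idx.size < 2:
            raise ValueError("gene class must contain at least 2 genes")
        iu = np.triu_indices(idx.size, k=1)

        def stat(a: np.ndarray, b: np.ndarray) -> float:
            d = np.abs(self._score_array(a) - self._score_array(b))
            return float(d[np.ix_(idx, idx)][iu].mean())

        params = {**self.score_params, "gene_class": genes}
        raw = permutation_pvalue(self.x1, self.x2, stat, n_permutations, seed, params)
        return GeneClassResults(self, raw, genes)

    def test_single_genes(
        self,
        n_permutations: int = 1000,
        seed: int | None = None,
        alpha: float = 0.05,
        adjust: bool = True,
    ) -> "SingleGeneResults":
        """Test every gene for differential connectivity simultaneously.

        The per-gene statistic d(g) is the mean absolute score distance
        between g and all remaining genes; all genes share the same set of
        random permutations.  BH-adjusted p-values are attached when
        ``adjust=True``.
        """
        def stat(a: np.ndarray, b: np.ndarray) -> np.ndarray:
            return gene_mda_all(self._score_array(a), self._score_array(b))

        params = {**self.score_params, "alpha": alpha}
        raw = permutation_pvalue(self.x1, self.x2, stat, n_permutations, seed, params)
        if adjust:
            raw.adjust()
        return SingleGeneResults(self, raw, alpha)


@dataclass
class _BaseResults:
    model: DifferentialNetworkAnalysis
    raw: DiffTestResult

    @property
    def n_permutations(self) -> int:
        return self.raw.n_permutations

    @property
    def seed(self):
        return self.raw.seed

    @property
    def perm_stats(self) -> np.ndarray:
        return self.raw.perm_stats

    def _header(self, title: str) -> list[str]:
        m = self.model
        lines = [
            title,
            "=" * len(title),
            f"score kind:        {m.score_kind}",
            f"genes:             {len(m.gene_ids)}",
            f"samples:           {m.x1.n_samples} + {m.x2.n_samples}",
            f"permutations:      {self.n_permutations}",
        ]
        if self.seed is not None:
            lines.append(f"seed:              {self.seed}")
        return lines

    def to_json(self, path=None) -> str:
        payload = {
            "statistic": np.asarray(self.raw.statistic).tolist(),
            "p_value": np.asarray(self.raw.p_value).tolist(),
            "p_adjusted": None
            if self.raw.p_adjusted is None
            else np.asarray(self.raw.p_adjusted).tolist(),
            "n_permutations": self.n_permutations,
            "seed": self.seed,
            "params": _jsonable(self.raw.params),
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


class ModularStructureResults(_BaseResults):
    """Results of the differential modular-structure test."""

    def __init__(self, model, raw, m: int, epsilon: float) -> None:
        super().__init__(model, raw)
        self.m = m
        self.epsilon = epsilon

    @property
    def statistic(self) -> float:
        return self.raw.statistic

    @property
    def p_value(self) -> float:
        return self.raw.p_value

    def modules(self) -> tuple[ModuleSet, ModuleSet]:
        return self.model.modules(self.m, self.epsilon)

    def summary(self) -> str:
        lines = self._header("Differential modular structure test")
        m1, m2 = self.modules()
        lines += [
            f"min module size m: {self.m}",
            f"threshold epsilon: {self.epsilon:g}",
            f"modules found:     {len(m1)} vs {len(m2)}",
            f"non-overlap stat:  {self.statistic:.4f}",
            f"p-value:           {self.raw.format_p(self.p_value)}",
        ]
        return "\n".join(lines)


class GeneClassResults(_BaseResults):
    """Results of the gene-class differential-connectivity test."""

    def __init__(self, model, raw, gene_class: list[str]) -> None:
        super().__init__(model, raw)
        self.gene_class = gene_class

    @property
    def statistic(self) -> float:
        return self.raw.statistic

    @property
    def p_value(self) -> float:
        return self.raw.p_value

    def summary(self) -> str:
        lines = self._header("Differential connectivity test for a gene class")
        lines += [
            f"class size:        {len(self.gene_class)}",
            f"class MDA Delta:   {self.statistic:.4f}",
            f"p-value:           {self.raw.format_p(self.p_value)}",
        ]
        return "\n".join(lines)


class SingleGeneResults(_BaseResults):
    """Per-gene differential-connectivity test results."""

    def __init__(self, model, raw, alpha: float) -> None:
        super().__init__(model, raw)
        self.alpha = alpha

    @property
    def statistics(self) -> np.ndarray:
        return np.asarray(self.raw.statistic)

    @property
    def p_values(self) -> np.ndarray:
        return np.asarray(self.raw.p_value)

    @property
    def p_adjusted(self) -> np.ndarray:
        if self.raw.p_adjusted is None:
            self.raw.adjust()
        return self.raw.p_adjusted

    def significant(self, adjusted: bool = False) -> list[str]:
        """Genes declared differentially connected at level alpha (strict p < alpha)."""
        p = self.p_adjusted if adjusted else self.p_values
        return [g for g, pv in zip(self.model.gene_ids, p) if pv < self.alpha]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": self.model.gene_ids,
                "d": self.statistics,
                "p": self.p_values,
                "p_BH": self.p_adjusted,
                "significant": self.p_values < self.alpha,
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def summary(self, top: int = 20) -> str:
        lines = self._header("Differential connectivity test for single genes")
        df = self.to_frame().sort_values(["p", "d"], ascending=[True, False])
        n_sig = int((self.p_values < self.alpha).sum())
        n_sig_bh = int((self.p_adjusted < self.alpha).sum())
        lines += [
            f"alpha:             {self.alpha:g}",
            f"significant:       {n_sig} raw, {n_sig_bh} BH-adjusted",
            "",
            df.head(top).to_string(index=False, float_format=lambda x: f"{x:.4f}"),
        ]
        return "\n".join(lines)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
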