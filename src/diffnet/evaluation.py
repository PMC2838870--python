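"""Confusion-based performance measures and Monte-Carlo power studies.

The harness repeatedly simulates a two-network Gaussian experiment, runs
the single-gene (or gene-class) differential-connectivity test on each
replicate, and averages confusion-matrix rates over replicates, treating
the designed "important" genes as ground truth:

* **sensitivity** — proportion of important genes declared significant
  (equals the average power of the test);
* **specificity** — proportion of unimportant genes not declared
  (one minus specificity is the average size);
* **TDR** — proportion of declared genes that are important;
* **TNR** — proportion of non-declared genes that are unimportant.

Rates with an empty denominator in a replicate (e.g. TDR when nothing is
declared) are undefined for that replicate and excluded from the average.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import DifferentialNetworkAnalysis
from .simulation import SimulationDesign, simulate_gaussian_pair

__all__ = [
    "PerformanceSummary",
    "performance_measures",
    "run_power_study",
    "run_class_power_study",
    "PowerStudyResults",
    "replicate_seeds",
]

MEASURES = ("sensitivity", "specificity", "tdr", "tnr")


def replicate_seeds(master_seed: int | None, n: int) -> list[np.random.SeedSequence]:
    """Per-replicate seed sequences spawned from a master seed (fixed rule)."""
    return np.random.SeedSequence(master_seed).spawn(n)


def performance_measures(declared: set, important: set, universe: set) -> dict:
    """The four confusion rates for one replicate; NaN when undefined."""
    declared, important, universe = set(declared), set(important), set(universe)
    if not important <= universe:
        raise ValueError("important genes must be a subset of the universe")
    if not declared <= universe:
        raise ValueError("declared genes must be a subset of the universe")
    unimportant = universe - important
    not_declared = universe - declared
    tp = len(declared & important)
    tn = len(not_declared & unimportant)

    def ratio(num: int, den: int) -> float:
        return num / den if den else float("nan")

    return {
        "sensitivity": ratio(tp, len(important)),
        "specificity": ratio(tn, len(unimportant)),
        "tdr": ratio(tp, len(declared)),
        "tnr": ratio(tn, len(not_declared)),
    }


@dataclass
class PerformanceSummary:
    """Averaged performance of a test across Monte-Carlo replicates."""

    sensitivity: float
    specificity: float
    tdr: float
    tnr: float
    adjusted: bool
    n_replicates: int
    design: SimulationDesign
    alpha: float

    def to_dict(self) -> dict:
        return {m: getattr(self, m) for m in MEASURES}


class PowerStudyResults:
    """Replicate-level and averaged results of a single-gene power study."""

    def __init__(
        self,
        replicates: pd.DataFrame,
        design: SimulationDesign,
        alpha: float,
        n_permutations: int,
        score_kind: str,
        master_seed: int | None,
    ) -> None:
        self.replicates = replicates
        self.design = design
        self.alpha = alpha
        self.n_permutations = n_permutations
        self.score_kind = score_kind
        self.master_seed = master_seed

    def _mean(self, measure: str, adjusted: bool) -> float:
        col = self.replicates[f"{measure}_{'adj' if adjusted else 'raw'}"].dropna()
        return float(col.mean()) if len(col) else float("nan")

    def performance(self, adjusted: bool = False) -> PerformanceSummary:
        return PerformanceSummary(
            *(self._mean(m, adjusted) for m in MEASURES),
            adjusted=adjusted,
            n_replicates=len(self.replicates),
            design=self.design,
            alpha=self.alpha,
        )

    @property
    def unadjusted(self) -> PerformanceSummary:
        return self.performance(adjusted=False)

    @property
    def adjusted(self) -> PerformanceSummary:
        return self.performance(adjusted=True)

    def to_frame(self) -> pd.DataFrame:
        """One-row table shaped like the benchmark power tables."""
        row: dict = {"n": self.design.n, "rho": self.design.rho, "p": self.design.p}
        for m in MEASURES:
            row[f"{m}_unadjusted"] = self._mean(m, False)
            row[f"{m}_adjusted"] = self._mean(m, True)
        return pd.DataFrame([row])

    def provenance(self) -> dict:
        return {
            "design": self.design.to_dict(),
            "alpha": self.alpha,
            "n_permutations": self.n_permutations,
            "n_replicates": len(self.replicates),
            "score_kind": self.score_kind,
            "master_seed": self.master_seed,
            "seed_rule": "numpy SeedSequence(master_seed).spawn(n_replicates)",
        }

    def summary(self) -> str:
        d = self.design
        lines = [
            "Monte-Carlo power study: single-gene differential connectivity",
            "=" * 62,
            f"design:       p={d.p}, n={d.n}, rho={d.rho}, "
            f"important={d.n_important}",
            f"score kind:   {self.score_kind}",
            f"replicates:   {len(self.replicates)}, "
            f"permutations: {self.n_permutations}, alpha: {self.alpha:g}",
            "",
            self.to_frame().to_string(index=False, float_format=lambda x: f"{x:.3f}"),
        ]
        return "\n".join(lines)


def run_power_study(
    design: SimulationDesign,
    score_kind: str = "correlation",
    alpha: float = 0.05,
    n_permutations: int = 500,
    n_replicates: int = 200,
    seed: int | None = None,
    **score_kwargs,
) -> PowerStudyResults:
    """Monte-Carlo power study of the single-gene test under the Gaussian design.

    Each replicate simulates a (control, treatment) pair, runs the
    single-gene permutation test, declares genes with raw (and BH-adjusted)
    p-value strictly below *alpha*, and records the four confusion rates.
    Per-replicate seeds are spawned from *seed* by a fixed rule, so results
    reproduce bit for bit.
    """
    if n_replicates < 1:
        raise ValueError("need at least one replicate")
    important = set(design.important_genes)
    universe = set(design.gene_ids)
    rows = []
    for rep, child in enumerate(replicate_seeds(seed, n_replicates)):
        sim_seed, perm_seed = child.spawn(2)
        rep_design = SimulationDesign(
            design.p, design.n, design.rho, design.n_important, seed=sim_seed
        )
        x1, x2 = simulate_gaussian_pair(rep_design)
        model = DifferentialNetworkAnalysis(x1, x2, score_kind=score_kind, **score_kwargs)
        res = model.test_single_genes(
            n_permutations=n_permutations, seed=perm_seed, alpha=alpha
        )
        row = {"replicate": rep}
        for adjusted, tag in ((False, "raw"), (True, "adj")):
            declared = set(res.significant(adjusted=adjusted))
            rates = performance_measures(declared, important, universe)
            row.update({f"{m}_{tag}": v for m, v in rates.items()})
            row[f"n_declared_{tag}"] = len(declared)
        rows.append(row)
    return PowerStudyResults(
        pd.DataFrame(rows), design, alpha, n_permutations, score_kind, seed
    )


def run_class_power_study(
    design: SimulationDesign,
    gene_class: list[str] | None = None,
    score_kind: str = "correlation",
    alpha: float = 0.05,
    n_permutations: int = 500,
    n_replicates: int = 100,
    seed: int | None = None,
    **score_kwargs,
) -> dict:
    """Rejection rate of the gene-class test across Monte-Carlo replicates.

    By default the tested class is the design's important-gene set.
    Returns the rejection rate together with the replicate p-values and the
    study's provenance.
    """
    if n_replicates < 1:
        raise ValueError("need at least one replicate")
    genes = list(gene_class) if gene_class is not None else design.important_genes
    pvals = []
    for child in replicate_seeds(seed, n_replicates):
        sim_seed, perm_seed = child.spawn(2)
        rep_design = SimulationDesign(
            design.p, design.n, design.rho, design.n_important, seed=sim_seed
        )
        x1, x2 = simulate_gaussian_pair(rep_design)
        model = DifferentialNetworkAnalysis(x1, x2, score_kind=score_kind, **score_kwargs)
        res = model.test_gene_class(genes, n_permutations=n_permutations, seed=perm_seed)
        pvals.append(res.p_value)
    pvals = np.asarray(pvals)
    return {
        "rejection_rate": float((pvals < alpha).mean()),
        "p_values": pvals,
        "gene_class": genes,
        "alpha": alpha,
        "n_replicates": n_replicates,
        "n_permutations": n_permutations,
        "design": design.to_dict(),
        "score_kind": score_kind,
        "master_seed": seed,
    }
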