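"""Gaussian two-network simulators.

Two generators are provided:

* :func:`simulate_gaussian_pair` — the benchmark design for the single-gene
  and gene-class tests: the control network draws from ``N(0, I_p)`` (no
  gene interacts with any other) while the treatment network draws from a
  covariance with unit diagonal and off-diagonals ``+rho`` or ``-rho``
  among the first ``n_important`` genes, the sign set by the parity of the
  1-based index sum; the remaining genes stay independent.  The first
  ``n_important`` genes are thus the "important" genes whose connectivity
  exists only in the treatment network.

* :func:`simulate_modular_pair` — a block-exchangeable design in which the
  two networks carry *different* module partitions (by default five
  10-gene modules versus one 50-gene module), exercising the
  modular-structure test.

Both are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .expression import ExpressionMatrix

__all__ = [
    "SimulationDesign",
    "treatment_covariance",
    "simulate_gaussian_pair",
    "simulate_modular_pair",
]


@dataclass
class SimulationDesign:
    """Parameters of a two-network Gaussian experiment.

    Attributes
    ----------
    p : int
        Number of genes.
    n : int
        Samples per network.
    rho : float
        Association strength among the important genes, in (0, 1).
    n_important : int
        Count of connected ("important") genes; these are genes 1..n_important.
    seed : int or None
        RNG seed; fixing it makes the draw reproducible bit for bit.
    """

    p: int
    n: int
    rho: float
    n_important: int = 10
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_important > self.p:
            raise ValueError("n_important cannot exceed p")
        if self.n_important > 0 and not 0.0 < self.rho < 1.0:
            raise ValueError(f"rho must be in (0, 1), got {self.rho}")

    @property
    def important_genes(self) -> list[str]:
        return [f"g{i + 1}" for i in range(self.n_important)]

    @property
    def gene_ids(self) -> list[str]:
        return [f"g{i + 1}" for i in range(self.p)]

    def to_dict(self) -> dict:
        return asdict(self)


def treatment_covariance(p: int, rho: float, n_important: int = 10) -> np.ndarray:
    """Covariance matrix of the treatment network.

    Unit diagonal; for 1-based indices i != k, both at most ``n_important``,
    the off-diagonal is ``+rho`` when i + k is even and ``-rho`` when odd;
    every other off-diagonal is zero.  The important block equals
    ``(1-rho) I + rho v v'`` with ``v_i = (-1)^i``, so its eigenvalues are
    ``1 + (n_important - 1) rho`` (once) and ``1 - rho``, and the matrix is
    positive definite for all rho in (0, 1).

    Index parity uses 1-based gene indices; an off-by-one here would flip
    every sign.
    """
    if n_important > 0 and not 0.0 < rho < 1.0:
        raise ValueError(f"rho must be in (0, 1), got {rho}")
    if not 0 <= n_important <= p:
        raise ValueError("n_important must be between 0 and p")
    sigma = np.eye(p)
    if n_important > 1:
        ii = np.arange(1, n_important + 1)  # 1-based
        signs = np.where((ii[:, None] + ii[None, :]) % 2 == 0, rho, -rho)
        np.fill_diagonal(signs, 1.0)
        sigma[:n_important, :n_important] = signs
    try:
        np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError as exc:  # unreachable for rho in (0,1)
        raise ValueError("treatment covariance is not positive definite") from exc
    return sigma


def _gaussian_draws(rng: np.random.Generator, n: int, sigma: np.ndarray) -> np.ndarray:
    chol = np.linalg.cholesky(sigma)
    return rng.standard_normal((n, sigma.shape[0])) @ chol.T


def simulate_gaussian_pair(design: SimulationDesign) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Draw (control, treatment) expression matrices under *design*.

    Control samples are iid ``N(0, I_p)``; treatment samples are iid
    ``N(0, treatment_covariance(p, rho, n_important))``, via the Cholesky
    factor applied to standard-normal draws.
    """
    rng = np.random.default_rng(design.seed)
    genes = design.gene_ids
    x1 = rng.standard_normal((design.n, design.p))
    sigma = treatment_covariance(design.p, design.rho, design.n_important)
    x2 = _gaussian_draws(rng, design.n, sigma)
    return (
        ExpressionMatrix(x1, genes, [f"c{i + 1}" for i in range(design.n)]),
        ExpressionMatrix(x2, genes, [f"t{i + 1}" for i in range(design.n)]),
    )


def _block_covariance(p: int, module_sizes, within_rho: float) -> np.ndarray:
    if not 0.0 < within_rho < 1.0:
        raise ValueError(f"within_rho must be in (0, 1), got {within_rho}")
    if sum(module_sizes) > p:
        raise ValueError(
            f"module sizes sum to {sum(module_sizes)} which exceeds p = {p} "
            "(blocks overlap)"
        )
    sigma = np.eye(p)
    start = 0
    for size in module_sizes:
        block = np.full((size, size), within_rho)
        np.fill_diagonal(block, 1.0)
        sigma[start : start + size, start : start + size] = block
        start += size
    return sigma


def simulate_modular_pair(
    p: int = 50,
    n: int = 50,
    module_sizes_a=(10, 10, 10, 10, 10),
    module_sizes_b=(50,),
    within_rho: float = 0.6,
    seed: int | None = None,
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Two Gaussian networks with different block-modular structures.

    Within each block the correlation is exchangeable at ``within_rho``;
    between blocks it is zero.  The defaults give network A five 10-gene
    modules and network B a single 50-gene module, a desk-scale emulation
    of a five-modules-versus-one regulatory-network contrast.  Module
    blocks occupy consecutive gene indices starting at gene 1.
    """
    rng = np.random.default_rng(seed)
    genes = [f"g{i + 1}" for i in range(p)]
    xa = _gaussian_draws(rng, n, _block_covariance(p, module_sizes_a, within_rho))
    xb = _gaussian_draws(rng, n, _block_covariance(p, module_sizes_b, within_rho))
    return (
        ExpressionMatrix(xa, genes, [f"a{i + 1}" for i in range(n)]),
        ExpressionMatrix(xb, genes, [f"b{i + 1}" for i in range(n)]),
    )
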