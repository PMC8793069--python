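"""Random walk with restart (RWR) network diffusion.

The walk iterates

    P_{t+1} = (1 - gamma) * W @ P_t + gamma * P_0

to its fixed point. Column c of the converged matrix is the stationary
visiting distribution of a walker that restarts at P_0[:, c] with
probability ``gamma`` each step; with P_0 = I it is gene c's network
proximity profile, used downstream as that gene's feature vector.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg

from .network import InteractionNetwork, TransitionMatrix, normalize_adjacency

logger = logging.getLogger(__name__)

_NORMS = ("L1", "L2", "Linf")


@dataclass(frozen=True)
class RWRConfig:
    """Diffusion parameters.

    gamma:
        Restart probability in (0, 1]; higher values keep walk mass closer
        to the restart genes. Default 0.5.
    tol:
        Convergence threshold on ||P_{t+1} - P_t|| under ``norm``.
    max_iter:
        Iteration cap; hitting it marks the result non-converged (warned,
        not fatal).
    norm:
        Norm for the convergence test: L1 (sum of absolute differences,
        default), L2 (Frobenius) or Linf (max absolute difference).
    dangling:
        How to treat genes whose transition column is all zero:
        ``teleport`` re-injects their walk mass through the restart
        distribution so column mass is conserved; ``strict`` raises.
    """

    gamma: float = 0.5
    tol: float = 1e-9
    max_iter: int = 1000
    norm: str = "L1"
    dangling: str = "teleport"

    def __post_init__(self) -> None:
        if not 0 < self.gamma <= 1:
            raise ValueError(f"gamma must be in (0, 1], got {self.gamma}")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.norm not in _NORMS:
            raise ValueError(f"norm must be one of {_NORMS}")
        if self.dangling not in ("teleport", "strict"):
            raise ValueError("dangling must be 'teleport' or 'strict'")


@dataclass
class DiffusionMatrix:
    """Converged (or capped) diffusion profiles; column c restarts at P0[:, c]."""

    profiles: np.ndarray
    iterations_used: int
    converged: bool


@dataclass
class FeatureMatrix:
    """Per-gene feature vectors: row g is gene g's diffusion profile."""

    values: np.ndarray
    gene_order: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.isfinite(self.values).all():
            raise ValueError("feature matrix contains non-finite entries")
        if self.gene_order and len(self.gene_order) != self.values.shape[0]:
            raise ValueError("gene_order length does not match row count")

    def write_tsv(self, path: str | os.PathLike, header_lines: list[str] | None = None) -> None:
        """TSV with gene-id header row and row labels; 17-significant-digit floats."""
        df = pd.DataFrame(self.values, index=self.gene_order, columns=self.gene_order or None)
        with open(path, "w") as fh:
            for line in header_lines or []:
                fh.write(f"# {line}\n")
            df.to_csv(fh, sep="\t", float_format="%.17g", index_label="gene")

    @classmethod
    def read_tsv(cls, path: str | os.PathLike) -> "FeatureMatrix":
        df = pd.read_csv(path, sep="\t", comment="#", index_col=0, float_precision="round_trip")
        return cls(values=df.to_numpy(dtype=float), gene_order=[str(g) for g in df.index])


def _diff_norm(delta: np.ndarray, norm: str) -> float:
    if norm == "L1":
        return float(np.abs(delta).sum())
    if norm == "L2":
        return float(np.linalg.norm(delta))
    return float(np.abs(delta).max())


def _as_weights(W: TransitionMatrix | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(W, TransitionMatrix):
        return W.weights, W.isolated
    W = np.asarray(W, dtype=float)
    return W, W.sum(axis=0) == 0


def rwr_iterate(
    W: TransitionMatrix | np.ndarray,
    P0: np.ndarray,
    cfg: RWRConfig = RWRConfig(),
) -> DiffusionMatrix:
    """Iterate the restart walk from P_t = P_0 until convergence.

    Dangling (all-zero) transition columns would leak walk mass; under the
    default ``teleport`` policy the mass sitting on dangling genes is
    re-injected through each column's own restart distribution, so column
    sums are preserved for column-stochastic W.
    """
    W, dangling = _as_weights(W)
    P0 = np.asarray(P0, dtype=float)
    if P0.ndim == 1:
        P0 = P0[:, None]
    if W.shape[0] != W.shape[1] or W.shape[0] != P0.shape[0]:
        raise ValueError(f"dimension mismatch: W {W.shape}, P0 {P0.shape}")
    if dangling.any() and cfg.dangling == "strict":
        raise ValueError(f"{int(dangling.sum())} dangling genes under strict mode")

    has_dangling = bool(dangling.any())
    P = P0.copy()
    for it in range(1, cfg.max_iter + 1):
        P_next = (1 - cfg.gamma) * (W @ P) + cfg.gamma * P0
        if has_dangling:
            lost = P[dangling, :].sum(axis=0)
            P_next += (1 - cfg.gamma) * P0 * lost[None, :]
        delta = _diff_norm(P_next - P, cfg.norm)
        P = P_next
        if delta <= cfg.tol:
            return DiffusionMatrix(profiles=P, iterations_used=it, converged=True)
    logger.warning("RWR did not converge in %d iterations (last delta %.3g)", cfg.max_iter, delta)
    return DiffusionMatrix(profiles=P, iterations_used=cfg.max_iter, converged=False)


def rwr_closed_form(
    W: TransitionMatrix | np.ndarray,
    P0: np.ndarray,
    gamma: float = 0.5,
    dangling: str = "teleport",
) -> DiffusionMatrix:
    """Exact fixed point P = gamma * (I - (1 - gamma) W)^-1 P0.

    Valid whenever the spectral radius of (1-gamma) W is below 1 — always
    the case for column-stochastic W and gamma > 0. Serves as the
    independent check on the iterative solver.
    """
    W, dangling_mask = _as_weights(W)
    P0 = np.asarray(P0, dtype=float)
    if P0.ndim == 1:
        P0 = P0[:, None]
    n = W.shape[0]
    if W.shape != (n, n) or P0.shape[0] != n:
        raise ValueError(f"dimension mismatch: W {W.shape}, P0 {P0.shape}")

    if not dangling_mask.any():
        system = np.eye(n) - (1 - gamma) * W
        try:
            P = scipy.linalg.solve(system, gamma * P0)
        except scipy.linalg.LinAlgError as exc:
            raise ValueError(
                f"singular RWR system (gamma={gamma}): {exc}"
            ) from exc
        return DiffusionMatrix(profiles=P, iterations_used=0, converged=True)

    if dangling == "strict":
        raise ValueError(f"{int(dangling_mask.sum())} dangling genes under strict mode")
    # Teleport makes the effective transition column-dependent:
    # W_c = W + P0[:, c] @ 1_dangling^T, so solve per column.
    d = dangling_mask.astype(float)
    P = np.empty_like(P0)
    for c in range(P0.shape[1]):
        Wc = W + np.outer(P0[:, c], d)
        system = np.eye(n) - (1 - gamma) * Wc
        P[:, c] = scipy.linalg.solve(system, gamma * P0[:, c])
    return DiffusionMatrix(profiles=P, iterations_used=0, converged=True)


def extract_features(
    net: InteractionNetwork,
    cfg: RWRConfig = RWRConfig(),
    normalization: str = "column_stochastic",
) -> FeatureMatrix:
    """Diffuse from every gene (P0 = I) and return profiles as feature rows.

    Gene g's feature vector is its converged diffusion profile over all
    genes — the network-association embedding fed to the classifier.
    """
    W = normalize_adjacency(net, mode=normalization)
    P0 = np.eye(net.n_genes)
    result = rwr_iterate(W, P0, cfg)
    if not result.converged:
        logger.warning("feature extraction used a non-converged diffusion matrix")
    return FeatureMatrix(values=result.profiles.T.copy(), gene_order=list(net.genes))
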