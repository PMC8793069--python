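"""Synthetic gene networks with a planted disease module.

A two-block stochastic block model instantiates the guilt-by-association
premise directly: disease genes interact with each other more densely
(p_within) than background genes do among themselves or with the module
(p_background, p_cross), so network diffusion separates the classes to a
degree controlled by the density contrast. Expected per-block edge counts
are analytic, which makes the generator itself testable.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass

import numpy as np

from .network import InteractionNetwork

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SyntheticSpec:
    """Planted-module network parameters.

    n_disease / n_background:
        Block sizes (counts >= 2).
    p_within:
        Edge probability among disease genes — the module density.
    p_cross / p_background:
        Disease-background and background-background edge probabilities.
    weight_noise:
        (low, high) range of multiplicative Uniform noise on edge weights;
        (1, 1) gives unit weights.
    rewire_isolated:
        Give each isolated node one random edge so every gene participates
        in the walk.
    seed:
        Generator seed; identical specs and seeds give identical edge lists.
    """

    n_disease: int = 60
    n_background: int = 440
    p_within: float = 0.25
    p_cross: float = 0.02
    p_background: float = 0.02
    weight_noise: tuple[float, float] = (0.5, 1.5)
    rewire_isolated: bool = True
    seed: int = 7

    def __post_init__(self) -> None:
        if self.n_disease < 2 or self.n_background < 2:
            raise ValueError("block sizes must be >= 2")
        for name in ("p_within", "p_cross", "p_background"):
            p = getattr(self, name)
            if not 0 <= p <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        lo, hi = self.weight_noise
        if not 0 < lo <= hi:
            raise ValueError("weight_noise must satisfy 0 < low <= high")
        if self.p_within <= self.p_background:
            logger.warning(
                "p_within (%.3g) <= p_background (%.3g): planted module carries "
                "no topological signal", self.p_within, self.p_background,
            )

    @property
    def n_genes(self) -> int:
        return self.n_disease + self.n_background

    def expected_edges(self) -> float:
        nd, nb = self.n_disease, self.n_background
        return (
            nd * (nd - 1) / 2 * self.p_within
            + nd * nb * self.p_cross
            + nb * (nb - 1) / 2 * self.p_background
        )


def _gene_names(spec: SyntheticSpec) -> list[str]:
    width_d = len(str(spec.n_disease))
    width_b = len(str(spec.n_background))
    disease = [f"D{i:0{width_d}d}" for i in range(1, spec.n_disease + 1)]
    background = [f"G{i:0{width_b}d}" for i in range(1, spec.n_background + 1)]
    return disease + background


def generate_planted_module(spec: SyntheticSpec) -> tuple[InteractionNetwork, np.ndarray]:
    """Sample the two-block network; labels are 1 for planted disease genes.

    Disease genes occupy the first ``n_disease`` rows. Edge weights are
    1 times Uniform(weight_noise). Isolated nodes are optionally re-wired
    with one random edge (unit-noise weight) so the network has no
    zero-degree genes.
    """
    if spec.expected_edges() < 1:
        raise ValueError("degenerate spec: fewer than one expected edge")
    rng = np.random.default_rng(spec.seed)
    n, nd = spec.n_genes, spec.n_disease

    prob = np.full((n, n), spec.p_background)
    prob[:nd, :nd] = spec.p_within
    prob[:nd, nd:] = spec.p_cross
    prob[nd:, :nd] = spec.p_cross

    upper = np.triu(rng.random((n, n)) < prob, k=1)
    lo, hi = spec.weight_noise
    weights = rng.uniform(lo, hi, size=(n, n))
    adjacency = np.where(upper, weights, 0.0)
    adjacency = adjacency + adjacency.T

    if spec.rewire_isolated:
        isolated = np.flatnonzero(adjacency.sum(axis=0) == 0)
        for i in isolated:
            j = int(rng.integers(n - 1))
            j += j >= i  # any partner except itself
            w = rng.uniform(lo, hi)
            adjacency[i, j] = adjacency[j, i] = w
        if len(isolated):
            logger.info("re-wired %d isolated genes", len(isolated))

    labels = np.zeros(n, dtype=np.int64)
    labels[:nd] = 1
    net = InteractionNetwork(
        genes=_gene_names(spec),
        adjacency=adjacency,
        seed_flags=labels.astype(bool),
    )
    return net, labels


def paper_scale_fixture(seed: int = 0) -> tuple[InteractionNetwork, np.ndarray]:
    """Planted-module network at the benchmark scale: 435 disease genes
    plus 896 background genes (1331 nodes), default block probabilities."""
    spec = SyntheticSpec(n_disease=435, n_background=896, seed=seed)
    return generate_planted_module(spec)


def write_fixture_files(
    net: InteractionNetwork,
    out_dir: str | os.PathLike,
    prefix: str = "synthetic",
) -> tuple[str, str]:
    """Emit the standard edge-list TSV and seed gene-list consumed by the
    network module, so synthetic runs exercise the real I/O path.

    Returns (edges_path, seeds_path).
    """
    os.makedirs(out_dir, exist_ok=True)
    edges_path = os.path.join(out_dir, f"{prefix}_edges.tsv")
    seeds_path = os.path.join(out_dir, f"{prefix}_seeds.txt")
    with open(edges_path, "w") as fh:
        fh.write("# synthetic planted-module network: geneA\tgeneB\tweight\n")
        for a, b, w in net.to_edges():
            fh.write(f"{a}\t{b}\t{w:.17g}\n")
    with open(seeds_path, "w") as fh:
        fh.write("# synthetic disease (seed) genes\n")
        for gene, flag in zip(net.genes, net.seed_flags):
            if flag:
                fh.write(f"{gene}\n")
    return edges_path, seeds_path
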