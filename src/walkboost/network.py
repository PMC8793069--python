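"""Gene-interaction network assembly.

Reads seed-gene lists and interaction edge lists (HumanNet-style TSV),
builds the seed-restricted interaction network, and produces the normalized
transition matrix consumed by the random walk.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

Edge = tuple[str, str, float]


class NetworkError(ValueError):
    """Raised for structurally invalid networks or inputs."""


def _check_gene_id(symbol: str) -> str:
    if not symbol or any(c.isspace() for c in symbol):
        raise NetworkError(f"invalid gene identifier: {symbol!r}")
    return symbol


@dataclass
class InteractionNetwork:
    """Undirected weighted gene-interaction network.

    Attributes
    ----------
    genes:
        Ordered gene identifiers; row/column ``i`` of ``adjacency``
        corresponds to ``genes[i]``.
    adjacency:
        Symmetric nonnegative weight matrix with zero diagonal
        (unless self-loops were explicitly retained).
    seed_flags:
        Boolean per gene, True for known disease (seed) genes.
    """

    genes: list[str]
    adjacency: np.ndarray
    seed_flags: np.ndarray

    def __post_init__(self) -> None:
        self.adjacency = np.asarray(self.adjacency, dtype=float)
        self.seed_flags = np.asarray(self.seed_flags, dtype=bool)
        n = len(self.genes)
        if self.adjacency.shape != (n, n):
            raise NetworkError(
                f"adjacency shape {self.adjacency.shape} does not match {n} genes"
            )
        if self.seed_flags.shape != (n,):
            raise NetworkError("seed_flags length does not match gene count")
        if len(set(self.genes)) != n:
            raise NetworkError("duplicate gene identifiers in network")
        if (self.adjacency < 0).any():
            raise NetworkError("negative edge weights")
        if not np.array_equal(self.adjacency, self.adjacency.T):
            raise NetworkError("adjacency must be symmetric")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_edges(self) -> int:
        off_diag = int(np.count_nonzero(np.triu(self.adjacency, k=1)))
        return off_diag + int(np.count_nonzero(np.diag(self.adjacency)))

    def index_of(self, gene: str) -> int:
        try:
            return self.genes.index(gene)
        except ValueError:
            raise KeyError(f"gene {gene!r} not in network") from None

    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=0)

    def isolated(self) -> np.ndarray:
        """Boolean mask of genes with no incident edge weight."""
        return self.degrees() == 0

    # ---- persistence -----------------------------------------------------

    def to_edges(self) -> list[Edge]:
        """Upper-triangle edge list (gene order determines direction)."""
        rows, cols = np.nonzero(np.triu(self.adjacency, k=0))
        return [
            (self.genes[i], self.genes[j], float(self.adjacency[i, j]))
            for i, j in zip(rows, cols)
        ]

    def write(self, edges_path: str | os.PathLike, sidecar_path: str | os.PathLike) -> None:
        """Write the TSV edge list plus a JSON sidecar (node order, seed flags)."""
        with open(edges_path, "w") as fh:
            fh.write("# walkboost network edge list: geneA\tgeneB\tweight\n")
            for a, b, w in self.to_edges():
                fh.write(f"{a}\t{b}\t{w:.17g}\n")
        sidecar = {
            "genes": self.genes,
            "seed_flags": [bool(f) for f in self.seed_flags],
            "n_genes": self.n_genes,
            "n_edges": self.n_edges,
        }
        with open(sidecar_path, "w") as fh:
            json.dump(sidecar, fh, indent=1)
            fh.write("\n")

    @classmethod
    def read(
        cls, edges_path: str | os.PathLike, sidecar_path: str | os.PathLike
    ) -> "InteractionNetwork":
        with open(sidecar_path) as fh:
            sidecar = json.load(fh)
        genes = list(sidecar["genes"])
        seed_flags = np.array(sidecar["seed_flags"], dtype=bool)
        index = {g: i for i, g in enumerate(genes)}
        adjacency = np.zeros((len(genes), len(genes)))
        for a, b, w in read_edge_list(edges_path, keep_self_loops=True):
            i, j = index[a], index[b]
            adjacency[i, j] = w
            adjacency[j, i] = w
        return cls(genes=genes, adjacency=adjacency, seed_flags=seed_flags)


@dataclass
class TransitionMatrix:
    """Normalized walk matrix W plus bookkeeping for isolated genes."""

    weights: np.ndarray
    normalization: str
    isolated: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.isolated is None:
            self.isolated = self.weights.sum(axis=0) == 0
        self.isolated = np.asarray(self.isolated, dtype=bool)


def read_gene_list(path: str | os.PathLike) -> list[str]:
    """Read one gene symbol per line; '#' lines are comments.

    Returns the de-duplicated, order-preserving list. Duplicates are
    counted and reported through logging.
    """
    seen: dict[str, None] = {}
    duplicates = 0
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            symbol = _check_gene_id(line.split()[0])
            if symbol in seen:
                duplicates += 1
            else:
                seen[symbol] = None
    if duplicates:
        logger.info("%d duplicate gene identifiers dropped from %s", duplicates, path)
    if not seen:
        raise NetworkError(f"no genes in {path}")
    return list(seen)


def read_edge_list(
    path: str | os.PathLike, keep_self_loops: bool = False
) -> list[Edge]:
    """Parse a whitespace/tab-separated edge list: geneA geneB [weight].

    Missing weights default to 1.0; self-loop rows are dropped (and counted)
    unless ``keep_self_loops``; negative weights are rejected.
    """
    edges: list[Edge] = []
    self_loops = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 2:
                raise NetworkError(
                    f"{path}:{lineno}: malformed edge row (need geneA geneB [weight])"
                )
            a, b = _check_gene_id(fields[0]), _check_gene_id(fields[1])
            if len(fields) >= 3:
                try:
                    w = float(fields[2])
                except ValueError:
                    raise NetworkError(
                        f"{path}:{lineno}: weight {fields[2]!r} is not a number"
                    ) from None
            else:
                w = 1.0
            if w < 0:
                raise NetworkError(f"{path}:{lineno}: negative weight {w}")
            if a == b and not keep_self_loops:
                self_loops += 1
                continue
            edges.append((a, b, w))
    if self_loops:
        logger.info("%d self-loop rows dropped from %s", self_loops, path)
    return edges


def build_network(
    edges: Iterable[Edge],
    seeds: Sequence[str],
    restrict: bool = True,
    binarize: bool = False,
    keep_self_loops: bool = False,
) -> InteractionNetwork:
    """Assemble the interaction network from edges and disease seed genes.

    With ``restrict`` (the default) only seeds and their direct interactors
    are kept — the seed-plus-one-hop construction used to define the
    candidate gene universe. Directed duplicates are symmetrized by the
    maximum of the two weights. Genes are ordered seeds-first, each group
    alphabetically, so downstream feature columns are reproducible.
    """
    if not seeds:
        raise NetworkError("seed list is empty")
    seed_set = {_check_gene_id(s) for s in seeds}

    edges = list(edges)
    touched = {a for a, _, _ in edges} | {b for _, b, _ in edges}
    if not (seed_set & touched):
        raise NetworkError("seeds disconnected from interactome: no seed appears in any edge")

    if restrict:
        keep = set(seed_set)
        for a, b, _ in edges:
            if a in seed_set:
                keep.add(b)
            if b in seed_set:
                keep.add(a)
        edges = [(a, b, w) for a, b, w in edges if a in keep and b in keep]
    else:
        keep = seed_set | touched

    seeds_sorted = sorted(g for g in keep if g in seed_set)
    others_sorted = sorted(g for g in keep if g not in seed_set)
    genes = seeds_sorted + others_sorted
    index = {g: i for i, g in enumerate(genes)}

    n = len(genes)
    adjacency = np.zeros((n, n))
    for a, b, w in edges:
        if a == b and not keep_self_loops:
            continue
        i, j = index[a], index[b]
        value = 1.0 if (binarize and w > 0) else w
        adjacency[i, j] = max(adjacency[i, j], value)
        adjacency[j, i] = max(adjacency[j, i], value)

    seed_flags = np.array([g in seed_set for g in genes])
    net = InteractionNetwork(genes=genes, adjacency=adjacency, seed_flags=seed_flags)
    logger.info(
        "built network: %d genes (%d seeds), %d edges",
        net.n_genes, int(seed_flags.sum()), net.n_edges,
    )
    return net


def normalize_adjacency(
    net: InteractionNetwork | np.ndarray, mode: str = "column_stochastic"
) -> TransitionMatrix:
    """Turn the adjacency matrix into a walk transition matrix.

    ``column_stochastic`` divides each nonzero column by its sum (the walk
    is a proper Markov chain); ``symmetric`` applies D^(-1/2) A D^(-1/2);
    ``none`` passes A through untouched. Columns of isolated genes stay
    all-zero and are flagged rather than treated as an error.
    """
    A = net.adjacency if isinstance(net, InteractionNetwork) else np.asarray(net, float)
    if (A < 0).any():
        raise NetworkError("adjacency must be nonnegative")
    colsum = A.sum(axis=0)
    isolated = colsum == 0
    if mode == "column_stochastic":
        denom = np.where(isolated, 1.0, colsum)
        W = A / denom
    elif mode == "symmetric":
        d = np.where(isolated, 1.0, colsum)
        inv_sqrt = 1.0 / np.sqrt(d)
        W = inv_sqrt[:, None] * A * inv_sqrt[None, :]
    elif mode == "none":
        W = A.copy()
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    if isolated.any():
        logger.warning("%d isolated genes have all-zero transition columns", int(isolated.sum()))
    return TransitionMatrix(weights=W, normalization=mode, isolated=isolated)
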