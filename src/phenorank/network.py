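"""Protein-protein interaction network, random walk with restart, ranking.

The network is an undirected, unweighted gene graph G = (V, E).  Scores are
diffused over it with the random walk with restart (RWR) iteration

    Q^{t+1} = (1 - r) A Q^t + r Q^0

where A is the column-normalized adjacency matrix and r the restart
probability.  A fixed number of iterations is run — no convergence test —
so that score vectors are directly comparable between the query run and the
simulated-null runs; scores are then converted to descending ranks (ties
share the average rank).
"""

from __future__ import annotations

import csv
import logging
from typing import IO, Iterable, Union

import numpy as np
from scipy import sparse
from scipy.stats import rankdata

logger = logging.getLogger(__name__)

__all__ = [
    "PPINetwork",
    "load_ppi_edges",
    "column_normalize",
    "rwr_propagate",
    "rank_scores",
    "convergence_profile",
]


class PPINetwork:
    """Undirected gene graph with no self-loops and no duplicate edges."""

    def __init__(
        self, gene_ids: Iterable[str], edges: Iterable[tuple[str, str]] = ()
    ):
        self.gene_ids: list[str] = list(dict.fromkeys(gene_ids))
        self.index: dict[str, int] = {g: i for i, g in enumerate(self.gene_ids)}
        self.edges: set[tuple[str, str]] = set()
        for a, b in edges:
            self.add_edge(a, b)

    def add_edge(self, a: str, b: str) -> bool:
        """Add an undirected edge; returns False for self-loops/duplicates."""
        if a not in self.index or b not in self.index:
            raise KeyError(f"edge endpoint not in network: {(a, b)!r}")
        if a == b:
            return False
        key = (a, b) if a < b else (b, a)
        if key in self.edges:
            return False
        self.edges.add(key)
        return True

    @property
    def n(self) -> int:
        return len(self.gene_ids)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.index

    def degree(self, gene_id: str) -> int:
        return int(self.degrees()[self.index[gene_id]])

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n, dtype=np.int64)
        for a, b in self.edges:
            deg[self.index[a]] += 1
            deg[self.index[b]] += 1
        return deg

    def adjacency(self) -> sparse.csr_matrix:
        """Symmetric 0/1 adjacency matrix in node order."""
        rows, cols = [], []
        for a, b in self.edges:
            ia, ib = self.index[a], self.index[b]
            rows += [ia, ib]
            cols += [ib, ia]
        data = np.ones(len(rows), dtype=float)
        return sparse.csr_matrix((data, (rows, cols)), shape=(self.n, self.n))

    def with_edges(
        self, extra_edges: Iterable[tuple[str, str]]
    ) -> "PPINetwork":
        """Copy of the network with extra edges added (used to wire modules)."""
        return PPINetwork(self.gene_ids, list(self.edges) + list(extra_edges))


def load_ppi_edges(stream: Union[str, IO[str]]) -> PPINetwork:
    """Read a two-column TSV edge list.

    Self-loops and duplicate edges (in either orientation) are dropped with
    logged counts; node order is first-appearance order in the file.
    """

    def parse(handle: IO[str]) -> PPINetwork:
        gene_ids: dict[str, None] = {}
        raw_edges = []
        for lineno, row in enumerate(csv.reader(handle, delimiter="\t"), start=1):
            if not row or row[0].startswith("#"):
                continue
            if len(row) != 2 or not row[0] or not row[1]:
                raise ValueError(
                    f"ppi_edges: malformed row at line {lineno}: expected 2 "
                    f"tab-separated columns, got {len(row)}"
                )
            gene_ids.setdefault(row[0])
            gene_ids.setdefault(row[1])
            raw_edges.append((row[0], row[1]))
        network = PPINetwork(gene_ids)
        n_loops = n_dups = 0
        for a, b in raw_edges:
            if a == b:
                n_loops += 1
            elif not network.add_edge(a, b):
                n_dups += 1
        if n_loops or n_dups:
            logger.info(
                "dropped %d self-loop(s) and %d duplicate edge(s)", n_loops, n_dups
            )
        return network

    if isinstance(stream, str):
        with open(stream, encoding="utf-8") as handle:
            return parse(handle)
    return parse(stream)


def column_normalize(network: PPINetwork) -> sparse.csr_matrix:
    """Column-normalized adjacency: each nonzero column sums to 1.

    Columns of zero-degree (isolated) genes are left all-zero; walker mass at
    such nodes is not redistributed and decays to the restart term alone.
    """
    adj = network.adjacency().tocsc()
    colsums = np.asarray(adj.sum(axis=0)).ravel()
    scale = np.divide(
        1.0, colsums, out=np.zeros_like(colsums, dtype=float), where=colsums > 0
    )
    return (adj @ sparse.diags(scale)).tocsr()


def rwr_propagate(
    a_norm: sparse.spmatrix,
    q0: np.ndarray,
    r: float,
    n_iter: int,
    return_trajectory: bool = False,
) -> np.ndarray:
    """Run exactly ``n_iter`` RWR iterations Q^{t+1} = (1-r) A Q^t + r Q^0.

    With ``return_trajectory`` the full (n_iter + 1, n) array of score
    vectors Q^0 .. Q^{n_iter} is returned instead of the final vector.
    """
    if not 0.0 <= r <= 1.0:
        raise ValueError(f"restart probability must be in [0, 1], got {r}")
    if n_iter < 0:
        raise ValueError("n_iter must be >= 0")
    q0 = np.asarray(q0, dtype=float)
    if a_norm.shape[0] != q0.shape[0]:
        raise ValueError(
            f"dimension mismatch: matrix {a_norm.shape} vs scores {q0.shape}"
        )
    trajectory = [q0]
    q = q0
    for _ in range(n_iter):
        q = (1.0 - r) * (a_norm @ q) + r * q0
        if return_trajectory:
            trajectory.append(q)
    return np.vstack(trajectory) if return_trajectory else q


def rank_scores(scores: np.ndarray) -> np.ndarray:
    """Descending ranks (1 = highest score); exact ties share the average."""
    scores = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    return rankdata(-scores, method="average")


def convergence_profile(
    a_norm: sparse.spmatrix,
    q0: np.ndarray,
    r: float,
    max_iter: int = 30,
) -> np.ndarray:
    """Mean absolute score difference at t = 1..max_iter-1 vs t = max_iter.

    Diagnostic for choosing the iteration count: the profile is
    monotonically non-increasing and shows when the walk has effectively
    reached its steady state.
    """
    traj = rwr_propagate(a_norm, q0, r, max_iter, return_trajectory=True)
    final = traj[-1]
    return np.array(
        [np.mean(np.abs(traj[t] - final)) for t in range(1, max_iter)]
    )
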