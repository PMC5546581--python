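"""Weighted protein-protein interaction networks in the STRING dialect.

The STRING ``protein.links`` flavour is a whitespace-separated table with
three columns — ``protein1 protein2 combined_score`` — where the combined
score is an integer confidence on a 0-1000 scale and every undirected
interaction is listed once per direction.  This module reads that dialect
into an ordered, symmetric :class:`PPINetwork` and derives the
column-stochastic :class:`TransitionMatrix` that network propagation
operates on.

Node order is the order of first appearance in the input, recorded on the
network, so every downstream matrix and vector is reproducible bit for bit.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import scipy.sparse as sp

from .exceptions import DataIntegrityError, LookupError_, ParseError

logger = logging.getLogger(__name__)

__all__ = [
    "InteractionRecord",
    "PPINetwork",
    "TransitionMatrix",
    "load_string_links",
    "write_edge_list",
    "build_transition_matrix",
]


@dataclass(frozen=True)
class InteractionRecord:
    """One undirected, scored interaction between two distinct proteins."""

    protein_a: str
    protein_b: str
    score: int

    def __post_init__(self):
        if not (0 < self.score <= 1000):
            raise ValueError(
                f"interaction score must be in (0, 1000], got {self.score!r}"
            )
        if self.protein_a == self.protein_b:
            raise ValueError(f"self-interaction not allowed: {self.protein_a!r}")

    @property
    def key(self) -> tuple[str, str]:
        """Order-independent identity of the pair."""
        a, b = self.protein_a, self.protein_b
        return (a, b) if a < b else (b, a)


class PPINetwork:
    """An undirected, weighted PPI graph with a fixed node ordering.

    Parameters
    ----------
    records
        Interaction records; duplicate unordered pairs with equal scores
        collapse to one, conflicting scores raise
        :class:`~walkscreen.exceptions.DataIntegrityError`.
    extra_nodes
        Identifiers to include even if they take part in no interaction
        (isolated nodes).  Mainly used by synthetic generators and tests.
    """

    def __init__(
        self,
        records: Iterable[InteractionRecord],
        extra_nodes: Sequence[str] = (),
    ):
        nodes: list[str] = []
        index: dict[str, int] = {}

        def intern(name: str) -> int:
            pos = index.get(name)
            if pos is None:
                pos = len(nodes)
                index[name] = pos
                nodes.append(name)
            return pos

        edges: dict[tuple[str, str], int] = {}
        for rec in records:
            intern(rec.protein_a)
            intern(rec.protein_b)
            prev = edges.get(rec.key)
            if prev is None:
                edges[rec.key] = rec.score
            elif prev != rec.score:
                raise DataIntegrityError(
                    f"conflicting scores for pair {rec.key}: {prev} vs {rec.score}"
                )
        for name in extra_nodes:
            intern(name)

        self.nodes: list[str] = nodes
        self.node_index: dict[str, int] = index
        self._edges: dict[tuple[str, str], int] = edges
        self.adjacency: sp.csr_array = self._build_adjacency()

    def _build_adjacency(self) -> sp.csr_array:
        n = len(self.nodes)
        if not self._edges:
            return sp.csr_array((n, n), dtype=np.float64)
        rows, cols, vals = [], [], []
        for (a, b), s in self._edges.items():
            i, j = self.node_index[a], self.node_index[b]
            rows += [i, j]
            cols += [j, i]
            vals += [s, s]
        return sp.csr_array(
            (np.asarray(vals, dtype=np.float64), (rows, cols)), shape=(n, n)
        )

    # -- basic queries ----------------------------------------------------

    def __len__(self) -> int:
        return len(self.nodes)

    def __contains__(self, node: str) -> bool:
        return node in self.node_index

    @property
    def n_edges(self) -> int:
        """Number of undirected edges."""
        return len(self._edges)

    @property
    def edges(self) -> dict[tuple[str, str], int]:
        """Mapping (a, b) with a < b -> score.  Do not mutate."""
        return self._edges

    def edge_score(self, a: str, b: str) -> int:
        """Stored score of the undirected edge a-b, or 0 if absent."""
        if a not in self.node_index or b not in self.node_index:
            raise LookupError_(f"unknown node in pair ({a!r}, {b!r})")
        key = (a, b) if a < b else (b, a)
        return self._edges.get(key, 0)

    def neighbors(self, node: str) -> list[str]:
        i = self.node_index.get(node)
        if i is None:
            raise LookupError_(node)
        row = self.adjacency[[i], :].tocoo()
        return [self.nodes[j] for j in row.coords[1]]

    def weighted_degree(self) -> np.ndarray:
        """Per-node sum of incident edge scores, in node order."""
        return np.asarray(self.adjacency.sum(axis=0)).ravel()

    @property
    def isolated_nodes(self) -> list[str]:
        deg = self.weighted_degree()
        return [self.nodes[i] for i in np.flatnonzero(deg == 0)]


@dataclass
class TransitionMatrix:
    """Column-stochastic walk operator derived from a :class:`PPINetwork`.

    ``matrix[v, u]`` is the probability of stepping from node ``u`` to node
    ``v``, proportional to the edge score S(u, v).  Columns of isolated
    (zero-out-weight) nodes are all-zero and their positions are listed in
    ``dangling_nodes``; the walk re-injects their mass as restart mass.
    """

    matrix: sp.csr_array
    dangling_nodes: list[int]
    nodes: list[str] = field(repr=False)

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


def build_transition_matrix(network: PPINetwork) -> TransitionMatrix:
    """Column-normalize the weighted adjacency of ``network``.

    Entry (v, u) becomes S(u, v) / sum_x S(u, x).  Isolated nodes yield
    zero columns, recorded in ``dangling_nodes`` — not an error.
    """
    if len(network) == 0:
        raise ValueError("cannot build a transition matrix for an empty network")
    colsum = network.weighted_degree()
    dangling = np.flatnonzero(colsum == 0)
    inv = np.zeros_like(colsum)
    nz = colsum > 0
    inv[nz] = 1.0 / colsum[nz]
    # right-multiplying by diag(1/colsum) rescales each column u
    matrix = (network.adjacency @ sp.diags_array(inv)).tocsr()
    return TransitionMatrix(
        matrix=matrix, dangling_nodes=dangling.tolist(), nodes=network.nodes
    )


# -- STRING dialect I/O ---------------------------------------------------


def _open_text(path: Path):
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def load_string_links(
    path: str | Path,
    species_prefix: str | None = None,
) -> PPINetwork:
    """Read a ``protein.links``-style edge list into a :class:`PPINetwork`.

    Parameters
    ----------
    path
        Plain or gzip-compressed whitespace-separated file with columns
        ``protein1 protein2 combined_score``.  A single header line
        beginning with ``protein1`` is skipped.
    species_prefix
        When given (e.g. ``"9606."``), only records where *both*
        identifiers carry the prefix are kept, and the prefix is stripped
        ("9606.ENSP00000258743" -> "ENSP00000258743").

    Notes
    -----
    Self-loops are dropped with a warning.  STRING lists each pair once per
    direction; the two directed records collapse to one undirected edge,
    and a score conflict between them is treated as corrupt input.  The
    loader records ``n_directed_records`` (kept lines) on the returned
    network alongside the undirected edge count.
    """
    path = Path(path)
    records: list[InteractionRecord] = []
    n_directed = 0
    n_self_loops = 0
    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if lineno == 1 and line.startswith("protein1"):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise ParseError(
                    f"expected >= 3 whitespace-separated fields, got {len(fields)}",
                    line_number=lineno,
                )
            a, b, raw_score = fields[0], fields[1], fields[2]
            try:
                score = int(raw_score)
            except ValueError:
                raise ParseError(
                    f"combined_score is not an integer: {raw_score!r}",
                    line_number=lineno,
                ) from None
            if species_prefix is not None:
                if not (a.startswith(species_prefix) and b.startswith(species_prefix)):
                    continue
                a = a[len(species_prefix):]
                b = b[len(species_prefix):]
            if a == b:
                n_self_loops += 1
                continue
            if not (0 < score <= 1000):
                raise ParseError(
                    f"combined_score out of (0, 1000]: {score}", line_number=lineno
                )
            n_directed += 1
            records.append(InteractionRecord(a, b, score))
    if n_self_loops:
        logger.warning("dropped %d self-loop record(s) from %s", n_self_loops, path)
    network = PPINetwork(records)
    network.n_directed_records = n_directed  # type: ignore[attr-defined]
    logger.info(
        "loaded %s: %d nodes, %d directed records, %d undirected edges",
        path, len(network), n_directed, network.n_edges,
    )
    return network


def write_edge_list(network: PPINetwork, path: str | Path) -> None:
    """Write the canonical TSV edge list: ``node_a node_b score`` with
    ``node_a < node_b`` lexicographically, sorted by pair."""
    with open(path, "wt") as fh:
        fh.write("protein1\tprotein2\tcombined_score\n")
        for (a, b) in sorted(network.edges):
            fh.write(f"{a}\t{b}\t{network.edges[(a, b)]}\n")
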