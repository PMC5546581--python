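"""Random walk with restart (RWR) over a PPI network.

The walk iterates

    P_{i+1} = (1 - c) * T @ P_i + c * P0

where ``T`` is the column-stochastic transition operator, ``c`` the
restart probability, and ``P0`` the restart distribution (uniform over the
seed genes).  The fixed point scores every node's network proximity to the
seed set.  Mass that would vanish at dangling (zero-out-weight) columns is
re-injected through the restart term, so P stays a probability
distribution at every iteration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .exceptions import ConfigurationError, ConvergenceError
from .network import PPINetwork, TransitionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "SeedSet",
    "PropagationResult",
    "RWRGeneSet",
    "load_seed_list",
    "map_seeds",
    "make_initial_vector",
    "rwr_propagate",
    "select_rwr_genes",
]

#: supported convergence norms for the update difference
_NORMS: dict[str, Callable[[np.ndarray], float]] = {
    "l1": lambda d: float(np.abs(d).sum()),
    "l2": lambda d: float(np.sqrt((d * d).sum())),
    "linf": lambda d: float(np.abs(d).max()),
}


@dataclass(frozen=True)
class SeedSet:
    """Seed genes restricted to the network.

    ``members`` are the seeds actually present in the network (the walk's
    restart support); ``requested`` is the original list as given;
    ``dropped`` are requested seeds absent from the network.
    """

    members: tuple[str, ...]
    requested: tuple[str, ...]
    dropped: tuple[str, ...]

    def __post_init__(self):
        if len(self.members) < 1:
            raise ConfigurationError("seed set is empty after mapping to the network")
        if set(self.members) & set(self.dropped):
            raise ConfigurationError("seed mapped and dropped at the same time")

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, node: str) -> bool:
        return node in set(self.members)


def load_seed_list(path: str | Path) -> list[str]:
    """Read a one-identifier-per-line seed file, ignoring blanks and '#' comments."""
    out: list[str] = []
    for line in Path(path).read_text().splitlines():
        tok = line.strip()
        if tok and not tok.startswith("#"):
            out.append(tok)
    return out


def map_seeds(requested: Sequence[str], network: PPINetwork) -> SeedSet:
    """Intersect a requested seed list with the network's nodes.

    Seeds missing from the network are dropped with a warning; the restart
    distribution built later is renormalized over the mapped seeds so it
    stays a probability distribution.
    """
    seen: set[str] = set()
    members, dropped = [], []
    for s in requested:
        if s in seen:
            continue
        seen.add(s)
        (members if s in network else dropped).append(s)
    if dropped:
        logger.warning(
            "%d of %d seed(s) not in the network and dropped: %s",
            len(dropped), len(seen), ", ".join(dropped[:5]) + ("..." if len(dropped) > 5 else ""),
        )
    return SeedSet(tuple(members), tuple(dict.fromkeys(requested)), tuple(dropped))


def make_initial_vector(seeds: SeedSet, network: PPINetwork) -> np.ndarray:
    """Uniform restart distribution: 1/|seeds| on each seed, 0 elsewhere."""
    p0 = np.zeros(len(network))
    idx = [network.node_index[s] for s in seeds.members]
    p0[idx] = 1.0 / len(idx)
    return p0


@dataclass
class PropagationResult:
    """Converged (or truncated) propagation state plus metadata."""

    probabilities: np.ndarray
    iterations: int
    final_delta: float
    restart_prob: float
    converged: bool
    tolerance: float = 1e-6
    norm: str = "l1"


def rwr_propagate(
    transition: TransitionMatrix,
    p0: np.ndarray,
    restart_prob: float = 0.8,
    tolerance: float = 1e-6,
    max_iter: int = 10_000,
    norm: str = "l1",
    on_iteration: Callable[[int, np.ndarray], None] | None = None,
) -> PropagationResult:
    """Iterate the restart walk to its fixed point.

    Stops when ``norm(P_{i+1} - P_i) < tolerance`` (L1 by default) and
    raises :class:`~walkscreen.exceptions.ConvergenceError` if ``max_iter``
    updates were not enough.  ``on_iteration(i, P_i)``, when given, is
    called after every update (used for conservation diagnostics).
    """
    if not (0.0 < restart_prob <= 1.0):
        raise ConfigurationError(f"restart_prob must be in (0, 1], got {restart_prob}")
    if tolerance <= 0:
        raise ConfigurationError("tolerance must be positive")
    if norm not in _NORMS:
        raise ConfigurationError(f"unknown norm {norm!r}; choose from {sorted(_NORMS)}")
    if abs(p0.sum() - 1.0) > 1e-9:
        raise ConfigurationError("initial vector must sum to 1")
    norm_fn = _NORMS[norm]
    T = transition.matrix
    dangling = np.asarray(transition.dangling_nodes, dtype=np.intp)
    c = restart_prob

    p = p0.copy()
    for i in range(1, max_iter + 1):
        lost = float(p[dangling].sum()) if dangling.size else 0.0
        p_next = (1.0 - c) * (T @ p) + (c + (1.0 - c) * lost) * p0
        delta = norm_fn(p_next - p)
        p = p_next
        if on_iteration is not None:
            on_iteration(i, p)
        if delta < tolerance:
            return PropagationResult(
                probabilities=p, iterations=i, final_delta=delta,
                restart_prob=c, converged=True, tolerance=tolerance, norm=norm,
            )
    raise ConvergenceError(
        f"no convergence after {max_iter} iterations (last delta {delta:.3e})",
        final_delta=delta, iterations=max_iter,
    )


@dataclass
class RWRGeneSet:
    """Non-seed nodes whose propagated probability exceeds a threshold.

    ``entries`` is sorted by probability descending, ties broken by node
    identifier ascending, so ranked reports are reproducible.
    """

    entries: list[tuple[str, float]]
    threshold: float

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def gene_ids(self) -> list[str]:
        return [g for g, _ in self.entries]

    def probability(self, gene: str) -> float:
        return dict(self.entries)[gene]


def select_rwr_genes(
    result: PropagationResult,
    seeds: SeedSet,
    network: PPINetwork,
    threshold: float = 1e-5,
) -> RWRGeneSet:
    """Pick non-seed genes with probability strictly above ``threshold``.

    Seeds are excluded: they are known genes by definition, so they cannot
    be novel candidates.
    """
    if not result.converged:
        raise ConfigurationError("refusing to select genes from a non-converged run")
    seed_set = set(seeds.members)
    entries = [
        (node, float(p))
        for node, p in zip(network.nodes, result.probabilities)
        if node not in seed_set and p > threshold
    ]
    entries.sort(key=lambda e: (-e[1], e[0]))
    return RWRGeneSet(entries=entries, threshold=threshold)
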