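"""The three-stage screening cascade applied to propagated candidate genes.

Stage 1 — permutation test.  Re-runs the identical restart walk from many
random seed sets of the same size and reports, per candidate, the fraction
of permutations whose propagated probability strictly exceeds the real
one: an empirical p-value with granularity 1/n_permutations.  Candidates
with p >= 0.05 are attributable to network topology alone.

Stage 2 — interaction test.  The maximum interaction score (MIS) is the
candidate's largest stored edge score with any seed gene; the cutoff 900
is STRING's highest-confidence threshold.

Stage 3 — enrichment test.  The maximum enrichment score (MES) is the
candidate's largest direction cosine between its annotation feature
vector and any seed's; the cutoff is 0.8.

A gene passing all three stages is an *inferred* gene.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .exceptions import ConfigurationError, ConsistencyError, ConvergenceError, LookupError_
from .network import PPINetwork, TransitionMatrix
from .rwr import PropagationResult, RWRGeneSet, SeedSet, rwr_propagate

logger = logging.getLogger(__name__)

__all__ = [
    "PermutationConfig",
    "ScreenThresholds",
    "GeneScreenRecord",
    "direction_cosine",
    "permutation_pvalues",
    "max_interaction_score",
    "max_enrichment_score",
    "apply_screens",
]


@dataclass(frozen=True)
class PermutationConfig:
    """How the permutation null is drawn.

    Random seed sets are sampled uniformly without replacement from all
    network nodes (no degree matching); the real seeds stay in the pool
    unless ``exclude_real_seeds`` is set.  ``conservative`` switches the
    p-value estimator from Theta/n to (Theta+1)/(n+1), which can never
    return an exact zero.
    """

    n_permutations: int = 1000
    seed_set_size: int = 106
    rng_seed: int = 0
    sampling: str = "uniform_without_replacement"
    exclude_real_seeds: bool = False
    conservative: bool = False

    def __post_init__(self):
        if self.n_permutations < 1:
            raise ConfigurationError("n_permutations must be >= 1")
        if self.seed_set_size < 1:
            raise ConfigurationError("seed_set_size must be >= 1")
        if self.sampling != "uniform_without_replacement":
            raise ConfigurationError(f"unsupported sampling {self.sampling!r}")


@dataclass(frozen=True)
class ScreenThresholds:
    """Stage cutoffs with their boundary semantics.

    probability strictly > ``probability_min``; p-value strictly <
    ``p_value_max``; MIS >= ``mis_min`` (inclusive); MES strictly >
    ``mes_min``.
    """

    p_value_max: float = 0.05
    mis_min: float = 900.0
    mes_min: float = 0.8
    probability_min: float = 1e-5

    def __post_init__(self):
        if not (0 <= self.mis_min <= 1000):
            raise ConfigurationError("mis_min must lie in [0, 1000]")
        if not (0 <= self.mes_min <= 1):
            raise ConfigurationError("mes_min must lie in [0, 1]")


@dataclass
class GeneScreenRecord:
    """One candidate's scores and pass/fail flags across all three stages."""

    node_id: str
    probability: float
    p_value: float
    mis: float
    mis_partner: str | None
    mes: float
    mes_partner: str | None
    passed_permutation: bool
    passed_mis: bool
    passed_mes: bool
    inferred: bool


def permutation_pvalues(
    transition: TransitionMatrix,
    network: PPINetwork,
    real_result: PropagationResult,
    rwr_genes: RWRGeneSet,
    config: PermutationConfig,
    seeds: SeedSet | None = None,
    max_iter: int = 10_000,
    progress_every: int = 100,
) -> dict[str, float]:
    """Empirical per-gene p-values against random same-size seed sets.

    Every permutation runs the walk with the same restart probability,
    tolerance and norm as the real run.  Exceedance is strict: a permuted
    probability equal to the real one does not count against the gene.
    Memory stays proportional to N plus the number of candidates — the
    permutation probability vectors are streamed, never stacked.
    """
    if not real_result.converged:
        raise ConfigurationError("real propagation result did not converge")
    n = len(network)
    if config.seed_set_size > n:
        raise ConfigurationError("seed_set_size exceeds the network size")
    if config.exclude_real_seeds:
        if seeds is None:
            raise ConfigurationError("exclude_real_seeds requires the real seed set")
        seed_idx = {network.node_index[s] for s in seeds.members}
        pool = np.array([i for i in range(n) if i not in seed_idx], dtype=np.intp)
    else:
        pool = np.arange(n, dtype=np.intp)
    if config.seed_set_size > pool.size:
        raise ConfigurationError("sampling pool smaller than seed_set_size")

    gene_idx = np.array([network.node_index[g] for g in rwr_genes.gene_ids], dtype=np.intp)
    real_probs = real_result.probabilities[gene_idx]
    exceed = np.zeros(gene_idx.size, dtype=np.int64)

    rng = np.random.default_rng(config.rng_seed)
    uniform = 1.0 / config.seed_set_size
    for j in range(config.n_permutations):
        chosen = rng.choice(pool, size=config.seed_set_size, replace=False)
        p0 = np.zeros(n)
        p0[chosen] = uniform
        try:
            perm = rwr_propagate(
                transition, p0,
                restart_prob=real_result.restart_prob,
                tolerance=real_result.tolerance,
                max_iter=max_iter,
                norm=real_result.norm,
            )
        except ConvergenceError as err:
            raise ConvergenceError(
                f"permutation {j} failed to converge: {err}",
                final_delta=err.final_delta, iterations=err.iterations,
            ) from err
        exceed += perm.probabilities[gene_idx] > real_probs
        if progress_every and (j + 1) % progress_every == 0:
            logger.info("permutations: %d / %d", j + 1, config.n_permutations)

    if config.conservative:
        pvals = (exceed + 1) / (config.n_permutations + 1)
    else:
        pvals = exceed / config.n_permutations
    return dict(zip(rwr_genes.gene_ids, pvals.tolist()))


def max_interaction_score(
    gene: str, seeds: SeedSet, network: PPINetwork
) -> tuple[float, str | None]:
    """Largest stored edge score between ``gene`` and any seed.

    Seed pairs with no edge contribute 0.  Returns (0, None) when the gene
    touches no seed at all; argmax ties resolve to the lexicographically
    smallest seed identifier.
    """
    if gene not in network:
        raise LookupError_(gene)
    best_score, best_partner = 0.0, None
    for s in sorted(seeds.members):
        if s == gene:
            continue
        score = network.edge_score(gene, s)
        if score > best_score:
            best_score, best_partner = float(score), s
    return best_score, best_partner


def direction_cosine(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine of the angle between two vectors; 0 when either is zero."""
    nu = float(np.linalg.norm(u))
    nv = float(np.linalg.norm(v))
    if nu == 0.0 or nv == 0.0:
        return 0.0
    return float(np.dot(u, v) / (nu * nv))


def max_enrichment_score(
    gene: str,
    seeds: SeedSet,
    vectors: Mapping[str, np.ndarray],
) -> tuple[float, str | None]:
    """Largest direction cosine between the gene's feature vector and any
    seed's.

    A gene with no annotation vector (or a zero vector) scores 0 with a
    logged warning rather than an error; argmax ties resolve to the
    lexicographically smallest seed identifier.
    """
    fv = vectors.get(gene)
    if fv is None or not np.any(fv):
        logger.warning("gene %s has no annotations; MES set to 0", gene)
        return 0.0, None
    best_score, best_partner = 0.0, None
    for s in sorted(seeds.members):
        sv = vectors.get(s)
        if sv is None:
            continue
        cos = direction_cosine(fv, sv)
        if cos > best_score:
            best_score, best_partner = cos, s
    return best_score, best_partner


def apply_screens(
    rwr_genes: RWRGeneSet,
    p_values: Mapping[str, float],
    mis_results: Mapping[str, tuple[float, str | None]],
    mes_results: Mapping[str, tuple[float, str | None]],
    thresholds: ScreenThresholds = ScreenThresholds(),
) -> list[GeneScreenRecord]:
    """Combine the three score maps into per-gene records with pass flags.

    Records are returned for *every* candidate (not only passers) so each
    filtering stage stays auditable; the inferred flag is the conjunction
    of the three stage flags.
    """
    records: list[GeneScreenRecord] = []
    for gene, prob in rwr_genes.entries:
        try:
            p = p_values[gene]
            mis, mis_partner = mis_results[gene]
            mes, mes_partner = mes_results[gene]
        except KeyError as missing:
            raise ConsistencyError(
                f"candidate {gene} missing from score map: {missing}"
            ) from None
        passed_p = p < thresholds.p_value_max
        passed_mis = mis >= thresholds.mis_min
        passed_mes = mes > thresholds.mes_min
        records.append(
            GeneScreenRecord(
                node_id=gene, probability=prob, p_value=float(p),
                mis=float(mis), mis_partner=mis_partner,
                mes=float(mes), mes_partner=mes_partner,
                passed_permutation=passed_p, passed_mis=passed_mis,
                passed_mes=passed_mes,
                inferred=passed_p and passed_mis and passed_mes,
            )
        )
    return records
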