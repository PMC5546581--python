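"""End-to-end orchestration: load -> propagate -> screen -> report.

The pipeline mirrors how the method is applied in practice: build the
weighted interactome, run the restart walk from the known disease genes,
keep candidates above the probability threshold, then pass them through
the permutation / interaction / enrichment cascade and write auditable
plain-TSV tables plus a YAML run manifest (config, input checksums,
library versions, per-stage counts and timings).

All result tables are computed in memory and written at the very end, so
a failing stage leaves no partial output behind.
"""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy
import yaml

from . import __version__
from .annotations import (
    build_feature_vectors,
    load_gmt,
    load_obo,
    merge_catalogs,
    propagate_ancestors,
    prune_empty_terms,
)
from .exceptions import ConfigurationError, PipelineStageError
from .network import PPINetwork, build_transition_matrix, load_string_links
from .rwr import (
    SeedSet,
    load_seed_list,
    make_initial_vector,
    map_seeds,
    rwr_propagate,
    select_rwr_genes,
)
from .screening import (
    GeneScreenRecord,
    PermutationConfig,
    ScreenThresholds,
    apply_screens,
    max_enrichment_score,
    max_interaction_score,
    permutation_pvalues,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "BipartiteEdge", "RunSummary", "run_pipeline", "export_bipartite_subgraph"]


@dataclass
class RunConfig:
    """Everything a pipeline run needs; defaults are the method's standard
    settings (restart probability 0.8, tolerance 1e-6, probability
    threshold 1e-5, 1000 permutations, cutoffs p < 0.05 / MIS >= 900 /
    MES > 0.8)."""

    network_path: str
    seed_path: str
    out_dir: str
    gmt_paths: list[str] = field(default_factory=list)
    obo_path: str | None = None
    species_prefix: str | None = None
    restart_prob: float = 0.8
    tolerance: float = 1e-6
    norm: str = "l1"
    prob_threshold: float = 1e-5
    n_permutations: int = 1000
    thresholds: ScreenThresholds = field(default_factory=ScreenThresholds)
    fv_encoding: str = "binary"
    rng_seed: int = 0
    min_bipartite_score: int | None = None  # default: thresholds.mis_min

    def validate(self) -> None:
        if self.n_permutations < 1:
            raise ConfigurationError("n_permutations must be >= 1")
        if not (0.0 < self.restart_prob <= 1.0):
            raise ConfigurationError("restart_prob must be in (0, 1]")
        if self.tolerance <= 0:
            raise ConfigurationError("tolerance must be positive")
        if self.prob_threshold < 0:
            raise ConfigurationError("prob_threshold must be non-negative")
        if not self.gmt_paths:
            raise ConfigurationError("at least one GMT annotation file is required")


@dataclass(frozen=True)
class BipartiteEdge:
    """One inferred-gene / known-gene interaction for the subgraph export."""

    inferred_gene: str
    known_gene: str
    score: int


@dataclass
class RunSummary:
    """Stage counts plus paths of the written tables."""

    n_nodes: int
    n_edges: int
    n_seeds: int
    n_rwr_genes: int
    n_candidates: int
    n_inferred: int
    iterations: int
    out_files: dict[str, str]


def export_bipartite_subgraph(
    inferred: list[str],
    seeds: SeedSet,
    network: PPINetwork,
    min_score: int = 900,
) -> list[BipartiteEdge]:
    """All network edges joining an inferred gene to a seed with score >=
    ``min_score``, sorted for reproducible output.

    Every gene that passed the interaction screen at the same cutoff is
    guaranteed at least one edge here.
    """
    inferred_set = set(inferred)
    if inferred_set & set(seeds.members):
        raise ConfigurationError("inferred genes and seeds must be disjoint")
    edges: list[BipartiteEdge] = []
    for gene in sorted(inferred_set):
        for s in sorted(seeds.members):
            score = network.edge_score(gene, s)
            if score >= min_score:
                edges.append(BipartiteEdge(gene, s, score))
    return edges


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage(name: str, timings: dict[str, float]):
    class _Ctx:
        def __enter__(self):
            logger.info("stage %s: start", name)
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            timings[name] = round(dt, 3)
            if exc is None:
                logger.info("stage %s: done in %.2fs", name, dt)
                return False
            if isinstance(exc, PipelineStageError):
                return False
            raise PipelineStageError(name, exc) from exc

    return _Ctx()


def run_pipeline(config: RunConfig) -> RunSummary:
    """Execute the full cascade and write the report tables.

    Outputs in ``config.out_dir``: ``rwr_genes.tsv`` (ranked propagation
    table, seeds flagged), ``screening.tsv`` (every candidate with all
    scores and flags), ``inferred_genes.tsv``, ``bipartite_edges.tsv`` and
    ``manifest.yaml``.
    """
    config.validate()
    timings: dict[str, float] = {}

    with _stage("network", timings):
        network = load_string_links(config.network_path, config.species_prefix)
        transition = build_transition_matrix(network)

    with _stage("seeds", timings):
        requested = load_seed_list(config.seed_path)
        seeds = map_seeds(requested, network)

    with _stage("rwr", timings):
        p0 = make_initial_vector(seeds, network)
        result = rwr_propagate(
            transition, p0,
            restart_prob=config.restart_prob,
            tolerance=config.tolerance,
            norm=config.norm,
        )
        rwr_genes = select_rwr_genes(result, seeds, network, config.prob_threshold)
    logger.info("RWR genes above %.1e: %d", config.prob_threshold, len(rwr_genes))

    with _stage("permutation", timings):
        perm_cfg = PermutationConfig(
            n_permutations=config.n_permutations,
            seed_set_size=len(seeds),
            rng_seed=config.rng_seed,
        )
        pvals = permutation_pvalues(
            transition, network, result, rwr_genes, perm_cfg, seeds=seeds
        )

    with _stage("annotations", timings):
        catalog = merge_catalogs([load_gmt(p) for p in config.gmt_paths])
        if config.obo_path:
            catalog = propagate_ancestors(catalog, load_obo(config.obo_path))
        catalog = prune_empty_terms(catalog)
        fv_net = network if config.fv_encoding == "neighbor_enrichment" else None
        vectors = build_feature_vectors(
            list(rwr_genes.gene_ids) + list(seeds.members),
            catalog, encoding=config.fv_encoding, network=fv_net,
        )

    with _stage("screening", timings):
        mis = {g: max_interaction_score(g, seeds, network) for g in rwr_genes.gene_ids}
        mes = {g: max_enrichment_score(g, seeds, vectors) for g in rwr_genes.gene_ids}
        records = apply_screens(rwr_genes, pvals, mis, mes, config.thresholds)
        candidates = [r for r in records if r.passed_permutation]
        inferred = [r for r in records if r.inferred]

    with _stage("bipartite", timings):
        min_score = (
            config.min_bipartite_score
            if config.min_bipartite_score is not None
            else int(config.thresholds.mis_min)
        )
        bip = export_bipartite_subgraph(
            [r.node_id for r in inferred], seeds, network, min_score
        )

    with _stage("write", timings):
        out_files = _write_outputs(
            config, network, seeds, result, rwr_genes, records, inferred, bip, timings
        )

    logger.info(
        "stage counts: RWR genes %d -> candidates %d -> inferred %d",
        len(rwr_genes), len(candidates), len(inferred),
    )
    return RunSummary(
        n_nodes=len(network), n_edges=network.n_edges, n_seeds=len(seeds),
        n_rwr_genes=len(rwr_genes), n_candidates=len(candidates),
        n_inferred=len(inferred), iterations=result.iterations,
        out_files={k: str(v) for k, v in out_files.items()},
    )


def _records_frame(records: list[GeneScreenRecord]) -> pd.DataFrame:
    df = pd.DataFrame([asdict(r) for r in records])
    if df.empty:
        df = pd.DataFrame(
            columns=[
                "node_id", "probability", "p_value", "mis", "mis_partner",
                "mes", "mes_partner", "passed_permutation", "passed_mis",
                "passed_mes", "inferred",
            ]
        )
    return df


def _write_outputs(
    config, network, seeds, result, rwr_genes, records, inferred, bip, timings
) -> dict[str, Path]:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: dict[str, Path] = {}

    # ranked propagation table: candidates plus seeds, probability descending
    seed_set = set(seeds.members)
    ranked = [
        (node, float(p), node in seed_set)
        for node, p in zip(network.nodes, result.probabilities)
        if node in seed_set or p > config.prob_threshold
    ]
    ranked.sort(key=lambda e: (-e[1], e[0]))
    files["rwr_genes"] = out / "rwr_genes.tsv"
    with open(files["rwr_genes"], "wt") as fh:
        fh.write("rank\tnode_id\tprobability\tis_seed\n")
        for rank, (node, p, is_seed) in enumerate(ranked, start=1):
            fh.write(f"{rank}\t{node}\t{p:.10e}\t{int(is_seed)}\n")

    df = _records_frame(records)
    float_fmt = {"probability": "{:.10e}", "p_value": "{:.6g}", "mis": "{:.0f}", "mes": "{:.6f}"}
    for col, fmt in float_fmt.items():
        df[col] = df[col].map(lambda v: fmt.format(v))
    for col in ("passed_permutation", "passed_mis", "passed_mes", "inferred"):
        df[col] = df[col].astype(int)
    files["screening"] = out / "screening.tsv"
    df.to_csv(files["screening"], sep="\t", index=False)

    files["inferred_genes"] = out / "inferred_genes.tsv"
    df[df["inferred"] == 1].to_csv(files["inferred_genes"], sep="\t", index=False)

    files["bipartite_edges"] = out / "bipartite_edges.tsv"
    with open(files["bipartite_edges"], "wt") as fh:
        fh.write("inferred_gene\tknown_gene\tscore\n")
        for e in bip:
            fh.write(f"{e.inferred_gene}\t{e.known_gene}\t{e.score}\n")

    manifest = {
        "walkscreen_version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S%z"),
        "config": {
            **{
                k: v for k, v in asdict(config).items() if k != "thresholds"
            },
            "thresholds": asdict(config.thresholds),
        },
        "inputs": {
            "network": {"path": str(config.network_path), "sha256": _sha256(config.network_path)},
            "seeds": {"path": str(config.seed_path), "sha256": _sha256(config.seed_path)},
            "gmt": [{"path": str(p), "sha256": _sha256(p)} for p in config.gmt_paths],
        },
        "library_versions": {
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
        },
        "counts": {
            "nodes": len(network),
            "undirected_edges": network.n_edges,
            "seeds_mapped": len(seeds),
            "seeds_dropped": len(seeds.dropped),
            "rwr_genes": len(rwr_genes),
            "candidates": int((df["passed_permutation"] == 1).sum()),
            "inferred": len(inferred),
            "bipartite_edges": len(bip),
        },
        "rwr": {
            "iterations": result.iterations,
            "final_delta": float(result.final_delta),
            "converged": bool(result.converged),
        },
        "stage_seconds": timings,
    }
    files["manifest"] = out / "manifest.yaml"
    with open(files["manifest"], "wt") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return files
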