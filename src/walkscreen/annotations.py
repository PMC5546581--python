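"""Gene annotation catalogs and the feature vectors the enrichment screen uses.

A candidate's functional proximity to a seed gene is the direction cosine
of two feature vectors FV(g) defined over a fixed dictionary of annotation
terms (GO terms and/or KEGG pathways, read from GMT files).  Two encodings
are available:

``binary``
    entry t is 1 iff the gene is annotated to term t.  Deterministic and
    the package default; optionally preceded by GO ancestor propagation
    (true-path rule) so that annotation to a child implies annotation to
    all its is_a/part_of ancestors.

``neighbor_enrichment``
    entry t is max(0, -log10 p), where p is the exact hypergeometric
    upper-tail probability of the overlap between the gene's direct
    network neighbors and term t's gene set, against the universe of all
    network nodes.  Captures guilt-by-association annotation signal for
    sparsely annotated genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
from scipy.stats import hypergeom

from .exceptions import OntologyError, ParseError
from .network import PPINetwork

logger = logging.getLogger(__name__)

__all__ = [
    "SourceKind",
    "AnnotationCatalog",
    "FeatureVector",
    "load_gmt",
    "load_obo",
    "merge_catalogs",
    "prune_empty_terms",
    "propagate_ancestors",
    "build_feature_vector",
    "build_feature_vectors",
]


class SourceKind(str, Enum):
    GO = "GO"
    KEGG = "KEGG"
    MIXED = "mixed"


@dataclass
class AnnotationCatalog:
    """Ordered term -> gene-set mapping; the feature-vector dictionary.

    Term order is fixed at construction and defines the vector dimension
    assignment, so vectors built from the same catalog are comparable.
    """

    terms: list[str]
    term_to_genes: dict[str, set[str]]
    source_kind: SourceKind = SourceKind.MIXED
    ontology: nx.MultiDiGraph | None = field(default=None, repr=False)

    def __post_init__(self):
        if set(self.terms) != set(self.term_to_genes):
            raise ValueError("terms and term_to_genes must cover the same term IDs")

    def __len__(self) -> int:
        return len(self.terms)

    @property
    def genes(self) -> set[str]:
        out: set[str] = set()
        for gs in self.term_to_genes.values():
            out |= gs
        return out

    def terms_of(self, gene: str) -> set[str]:
        return {t for t, gs in self.term_to_genes.items() if gene in gs}


def load_gmt(path: str | Path, source_kind: SourceKind | str = SourceKind.MIXED) -> AnnotationCatalog:
    """Read a GMT gene-set file (term, description, then >= 1 gene, tab-separated).

    Duplicate term IDs across lines merge by union with a warning.
    """
    terms: list[str] = []
    term_to_genes: dict[str, set[str]] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        if not raw.strip():
            continue
        fields = [f for f in raw.rstrip("\n").split("\t")]
        if len(fields) < 3 or not any(f.strip() for f in fields[2:]):
            raise ParseError(
                "GMT line needs term, description and >= 1 gene", line_number=lineno
            )
        term = fields[0].strip()
        genes = {f.strip() for f in fields[2:] if f.strip()}
        if term in term_to_genes:
            logger.warning("duplicate term %r in %s merged by union", term, path)
            term_to_genes[term] |= genes
        else:
            terms.append(term)
            term_to_genes[term] = genes
    return AnnotationCatalog(terms, term_to_genes, SourceKind(source_kind))


def load_obo(path: str | Path) -> nx.MultiDiGraph:
    """Read an OBO ontology into a child -> parent multigraph (obonet layout:
    an edge (u, v, key='is_a') means u is_a v)."""
    import obonet

    return obonet.read_obo(str(path))


def merge_catalogs(catalogs: Sequence[AnnotationCatalog]) -> AnnotationCatalog:
    """Concatenate catalogs into one joint term dictionary.

    GO and pathway vectors are deliberately kept in one concatenated space:
    the enrichment screen treats both annotation sources jointly.
    """
    if not catalogs:
        raise ValueError("need at least one catalog")
    if len(catalogs) == 1:
        return catalogs[0]
    terms: list[str] = []
    term_to_genes: dict[str, set[str]] = {}
    kinds = {c.source_kind for c in catalogs}
    for cat in catalogs:
        for t in cat.terms:
            if t in term_to_genes:
                term_to_genes[t] |= cat.term_to_genes[t]
            else:
                terms.append(t)
                term_to_genes[t] = set(cat.term_to_genes[t])
    kind = kinds.pop() if len(kinds) == 1 else SourceKind.MIXED
    return AnnotationCatalog(terms, term_to_genes, kind)


def prune_empty_terms(
    catalog: AnnotationCatalog, universe: set[str] | None = None
) -> AnnotationCatalog:
    """Drop terms annotating no gene (optionally: no gene in ``universe``).

    Empty terms only pad vector dimensions and never change a cosine.
    """
    terms, t2g = [], {}
    for t in catalog.terms:
        gs = catalog.term_to_genes[t]
        if universe is not None:
            gs = gs & universe
        if gs:
            terms.append(t)
            t2g[t] = set(gs)
    return AnnotationCatalog(terms, t2g, catalog.source_kind, catalog.ontology)


def propagate_ancestors(
    catalog: AnnotationCatalog,
    ontology: nx.MultiDiGraph | nx.DiGraph,
    relations: tuple[str, ...] = ("is_a", "part_of"),
) -> AnnotationCatalog:
    """Apply the true-path rule: a gene annotated to a term is annotated to
    every ancestor along the chosen relations.

    The ontology uses the obonet layout (edges point child -> parent).
    Ancestor terms missing from the catalog are appended, sorted, after the
    original term order.  Gene sets in the result are supersets of the
    input's.
    """
    if isinstance(ontology, nx.MultiDiGraph):
        parent_graph = nx.DiGraph()
        parent_graph.add_nodes_from(ontology.nodes)
        for u, v, rel in ontology.edges(keys=True):
            if rel in relations:
                parent_graph.add_edge(u, v)
    else:
        parent_graph = ontology
    if not nx.is_directed_acyclic_graph(parent_graph):
        raise OntologyError("ontology contains a cycle along the chosen relations")

    t2g = {t: set(gs) for t, gs in catalog.term_to_genes.items()}
    missing = [t for t in catalog.terms if t not in parent_graph]
    if missing:
        logger.warning(
            "%d catalog term(s) absent from the ontology; left unpropagated", len(missing)
        )
    new_terms: set[str] = set()
    for term in catalog.terms:
        if term not in parent_graph:
            continue
        # edges point child -> parent, so graph-descendants are ancestors
        for anc in nx.descendants(parent_graph, term):
            if anc not in t2g:
                t2g[anc] = set()
                new_terms.add(anc)
            t2g[anc] |= catalog.term_to_genes[term]
    terms = list(catalog.terms) + sorted(new_terms)
    return AnnotationCatalog(terms, t2g, catalog.source_kind, catalog.ontology)


@dataclass
class FeatureVector:
    """A gene's non-negative annotation profile over the catalog's terms."""

    values: np.ndarray
    gene: str
    encoding: str = "binary"

    def __post_init__(self):
        if np.any(self.values < 0):
            raise ValueError("feature vector entries must be non-negative")


def build_feature_vector(
    gene: str,
    catalog: AnnotationCatalog,
    encoding: str = "binary",
    network: PPINetwork | None = None,
) -> FeatureVector:
    """Encode one gene's annotation profile as a vector over catalog terms.

    An unannotated gene yields the zero vector; downstream that gene's
    enrichment score is 0 by the zero-vector cosine convention.
    """
    T = len(catalog)
    values = np.zeros(T)
    if encoding == "binary":
        for k, term in enumerate(catalog.terms):
            if gene in catalog.term_to_genes[term]:
                values[k] = 1.0
    elif encoding == "neighbor_enrichment":
        if network is None:
            raise ValueError("neighbor_enrichment encoding requires the network")
        universe = set(network.nodes)
        M = len(universe)
        neigh = set(network.neighbors(gene))
        n_draw = len(neigh)
        for k, term in enumerate(catalog.terms):
            term_genes = catalog.term_to_genes[term] & universe
            K = len(term_genes)
            overlap = len(neigh & term_genes)
            if overlap == 0 or K == 0 or n_draw == 0:
                continue
            # P(X >= overlap) for X ~ Hypergeom(M, K, n_draw)
            p = float(hypergeom.sf(overlap - 1, M, K, n_draw))
            values[k] = max(0.0, -np.log10(max(p, 1e-300)))
    else:
        raise ValueError(f"unknown encoding {encoding!r}")
    return FeatureVector(values=values, gene=gene, encoding=encoding)


def build_feature_vectors(
    genes: Iterable[str],
    catalog: AnnotationCatalog,
    encoding: str = "binary",
    network: PPINetwork | None = None,
) -> dict[str, np.ndarray]:
    """Vectorize many genes at once; returns gene -> values array."""
    return {
        g: build_feature_vector(g, catalog, encoding=encoding, network=network).values
        for g in genes
    }
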