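"""HPO ontology handling: is-a DAG, annotation propagation, information
content, and Resnik most-informative-common-ancestor similarity.

Information content of a term t is estimated from gene annotation
frequencies: IC(t) = -ln(n_t / n_root), where n_t counts genes annotated to
t or any of its descendants and n_root counts all annotated genes. The root
therefore has IC 0, and terms annotated to no gene have undefined IC and are
skipped as match anchors.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, Mapping, Optional

import networkx as nx
import obonet

logger = logging.getLogger(__name__)


class Ontology:
    """A rooted acyclic is-a ontology with gene annotations.

    Parameters
    ----------
    graph:
        Directed graph with child -> parent ("is_a") edges and a single root.
    """

    def __init__(self, graph: nx.DiGraph):
        if not nx.is_directed_acyclic_graph(graph):
            raise ValueError("ontology graph must be acyclic")
        roots = [n for n in graph.nodes if graph.out_degree(n) == 0]
        if len(roots) != 1:
            raise ValueError(f"ontology must have exactly one root, found {roots}")
        self.graph = graph
        self.root: str = roots[0]
        self._ancestors: dict[str, frozenset[str]] = {}
        self._term_genes: Optional[dict[str, frozenset[str]]] = None
        self._n_total: int = 0
        self.gene_annotations: dict[str, frozenset[str]] = {}

    @classmethod
    def from_obo(cls, path) -> "Ontology":
        multigraph = obonet.read_obo(path)
        g = nx.DiGraph()
        g.add_nodes_from(multigraph.nodes)
        for child, parent, key in multigraph.edges(keys=True):
            if key == "is_a":
                g.add_edge(child, parent)
        # drop terms disconnected by non-is_a-only linkage
        return cls(g)

    def __contains__(self, term: str) -> bool:
        return term in self.graph

    def __len__(self) -> int:
        return self.graph.number_of_nodes()

    def validate_terms(self, terms: Iterable[str]) -> None:
        unknown = sorted(t for t in terms if t not in self.graph)
        if unknown:
            raise KeyError(f"HPO terms absent from the ontology: {unknown}")

    def ancestors(self, term: str) -> frozenset[str]:
        """All ancestors of ``term`` including the term itself."""
        cached = self._ancestors.get(term)
        if cached is None:
            if term not in self.graph:
                raise KeyError(f"unknown term {term!r}")
            cached = frozenset(nx.descendants(self.graph, term)) | {term}
            self._ancestors[term] = cached
        return cached

    def set_annotations(self, gene_to_terms: Mapping[str, Iterable[str]]) -> None:
        """Attach gene -> term annotations, propagated to all ancestors."""
        term_genes: dict[str, set[str]] = {}
        clean: dict[str, frozenset[str]] = {}
        for gene, terms in gene_to_terms.items():
            terms = frozenset(terms)
            self.validate_terms(terms)
            clean[gene] = terms
            for t in terms:
                for anc in self.ancestors(t):
                    term_genes.setdefault(anc, set()).add(gene)
        if not term_genes:
            raise ValueError("no gene annotations provided")
        self.gene_annotations = clean
        self._term_genes = {t: frozenset(g) for t, g in term_genes.items()}
        self._n_total = len(self._term_genes.get(self.root, frozenset()))

    def _require_annotations(self) -> None:
        if self._term_genes is None:
            raise RuntimeError("call set_annotations() before scoring")

    def annotation_count(self, term: str) -> int:
        """Number of genes annotated to ``term`` or any descendant."""
        self._require_annotations()
        return len(self._term_genes.get(term, frozenset()))

    def information_content(self, term: str) -> Optional[float]:
        """IC(t) = -ln(n_t / n_root); None when no gene reaches the term."""
        self._require_annotations()
        if term not in self.graph:
            raise KeyError(f"unknown term {term!r}")
        n = self.annotation_count(term)
        if n == 0:
            logger.debug("term %s has no annotated genes; IC undefined", term)
            return None
        return -math.log(n / self._n_total)

    def term_similarity(self, t1: str, t2: str) -> float:
        """Resnik similarity: max IC over the common ancestors of t1 and t2.

        The root is always a common ancestor, so the score is >= 0.
        """
        common = self.ancestors(t1) & self.ancestors(t2)
        best = 0.0
        for term in common:
            ic = self.information_content(term)
            if ic is not None and ic > best:
                best = ic
        return best
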