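"""Ontology DAG handling and parent-child overrepresentation testing.

The enrichment test implemented here is the *parent-child* variant of the
classic hypergeometric gene-set test: instead of asking whether a term's
annotated genes are overrepresented in the study set relative to the whole
gene universe, each term is conditioned on the genes annotated to its
parent terms.  This corrects the inheritance bias of term-by-term Fisher
tests on a DAG-structured vocabulary, where a significant child otherwise
drags all of its ancestors to significance.

Terms and annotations follow the true-path rule: a gene directly annotated
to a term is implicitly annotated to every ancestor of that term.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx
from scipy.stats import hypergeom

__all__ = [
    "OntologyDAG",
    "AnnotationMap",
    "EnrichmentResult",
    "propagate",
    "parent_child_test",
    "n_testable_terms",
    "bonferroni_select",
    "cross_species_overlap",
    "map_to_phenotype_terms",
]


class OntologyDAG:
    """A rooted, acyclic ``is_a`` hierarchy of ontology terms.

    Edges point child -> parent.  Roots are terms with no parents.
    Both the Gene Ontology (biological process branch) and the Mammalian
    Phenotype ontology are represented with this class.
    """

    def __init__(self, graph: nx.DiGraph, names: Mapping[str, str] | None = None):
        if not nx.is_directed_acyclic_graph(graph):
            raise ValueError("ontology graph contains a cycle")
        self._g = graph
        self.names = dict(names or {})
        self._roots = frozenset(t for t in graph.nodes if graph.out_degree(t) == 0)
        if graph.number_of_nodes() and not self._roots:
            raise ValueError("ontology has no root term")
        # every non-root term must reach a root (guaranteed acyclic + finite,
        # but check connectivity of orphan components anyway)
        for t in graph.nodes:
            if t not in self._roots and not nx.descendants(graph, t) & self._roots:
                raise ValueError(f"term {t} does not reach a root")
        self._ancestor_cache: dict[str, frozenset[str]] = {}

    @classmethod
    def from_edges(
        cls,
        terms: Iterable[str],
        child_parent_edges: Iterable[tuple[str, str]],
        names: Mapping[str, str] | None = None,
    ) -> "OntologyDAG":
        g = nx.DiGraph()
        g.add_nodes_from(terms)
        g.add_edges_from(child_parent_edges)
        return cls(g, names)

    @property
    def terms(self) -> frozenset[str]:
        return frozenset(self._g.nodes)

    @property
    def roots(self) -> frozenset[str]:
        return self._roots

    def __contains__(self, term: str) -> bool:
        return term in self._g

    def __len__(self) -> int:
        return self._g.number_of_nodes()

    def parents(self, term: str) -> frozenset[str]:
        return frozenset(self._g.successors(term))

    def children(self, term: str) -> frozenset[str]:
        return frozenset(self._g.predecessors(term))

    def ancestors(self, term: str) -> frozenset[str]:
        """All proper ancestors of ``term`` (excluding the term itself)."""
        cached = self._ancestor_cache.get(term)
        if cached is None:
            cached = frozenset(nx.descendants(self._g, term))
            self._ancestor_cache[term] = cached
        return cached

    def descendants(self, term: str) -> frozenset[str]:
        return frozenset(nx.ancestors(self._g, term))

    def top_level_terms(self) -> frozenset[str]:
        """Direct children of the root(s)."""
        out: set[str] = set()
        for r in self._roots:
            out |= self.children(r)
        return frozenset(out)

    def edges(self) -> list[tuple[str, str]]:
        return sorted(self._g.edges())

    def equals(self, other: "OntologyDAG") -> bool:
        return (
            self.terms == other.terms
            and set(self._g.edges()) == set(other._g.edges())
            and self.names == other.names
        )


@dataclass
class AnnotationMap:
    """Direct and ancestor-closed (true-path) gene -> term annotations."""

    direct: dict[str, frozenset[str]]
    propagated: dict[str, frozenset[str]]

    def genes(self) -> frozenset[str]:
        return frozenset(self.propagated)


@dataclass
class EnrichmentResult:
    """One term's parent-child test.

    ``k`` study genes out of ``m`` study genes annotated to the parents;
    ``K`` genes annotated to the term out of ``M`` annotated to the parents.
    """

    term: str
    k: int
    K: int
    m: int
    M: int
    p_value: float
    significant: bool = False
    name: str = ""


def propagate(dag: OntologyDAG, direct: Mapping[str, Iterable[str]]) -> AnnotationMap:
    """Close a direct annotation map under ancestors (true-path rule).

    Raises if any annotated term is missing from the DAG.
    """
    direct_fs: dict[str, frozenset[str]] = {}
    propagated: dict[str, frozenset[str]] = {}
    for gene, terms in direct.items():
        ts = frozenset(terms)
        for t in ts:
            if t not in dag:
                raise ValueError(f"annotation term {t!r} not in ontology")
        closed: set[str] = set(ts)
        for t in ts:
            closed |= dag.ancestors(t)
        direct_fs[gene] = ts
        propagated[gene] = frozenset(closed)
    return AnnotationMap(direct=direct_fs, propagated=propagated)


def _term_gene_index(
    ann: AnnotationMap, universe: frozenset[str]
) -> dict[str, frozenset[str]]:
    idx: dict[str, set[str]] = {}
    for gene, terms in ann.propagated.items():
        if gene not in universe:
            continue
        for t in terms:
            idx.setdefault(t, set()).add(gene)
    return {t: frozenset(gs) for t, gs in idx.items()}


def parent_child_test(
    study: Iterable[str],
    universe: Iterable[str],
    dag: OntologyDAG,
    ann: AnnotationMap,
    min_term_size: int = 1,
    parent_join: str = "union",
) -> list[EnrichmentResult]:
    """Parent-child overrepresentation over every testable term.

    For each term ``t`` with at least ``min_term_size`` annotated genes and
    at least one study gene, the reference population is the set of genes
    annotated (after propagation) to the parents of ``t`` — joined by union
    (default) or intersection — and the p-value is the upper hypergeometric
    tail P(X >= k).  Root terms are conditioned on the whole universe.

    Results are sorted by term id.  Terms with zero study genes are not
    returned; use :func:`n_testable_terms` to count every term that met
    ``min_term_size`` when defining the Bonferroni divisor that way.
    """
    study_set = frozenset(study)
    universe_set = frozenset(universe)
    if not study_set <= universe_set:
        missing = sorted(study_set - universe_set)[:5]
        raise ValueError(f"study genes not in universe: {missing}")
    if min_term_size < 1:
        raise ValueError("min_term_size must be >= 1")
    if parent_join not in ("union", "intersection"):
        raise ValueError("parent_join must be 'union' or 'intersection'")

    term_genes = _term_gene_index(ann, universe_set)
    results: list[EnrichmentResult] = []
    for t in sorted(dag.terms):
        genes_t = term_genes.get(t, frozenset())
        if len(genes_t) < min_term_size:
            continue
        k = len(study_set & genes_t)
        if k < 1:
            continue
        parents = dag.parents(t)
        if not parents:
            pop = universe_set
        else:
            parent_sets = [term_genes.get(p, frozenset()) for p in parents]
            if parent_join == "union":
                pop = frozenset().union(*parent_sets)
            else:
                pop = frozenset.intersection(*parent_sets)
        M = len(pop)
        K = len(genes_t & pop)
        m = len(study_set & pop)
        p = float(hypergeom.sf(k - 1, M, K, m))
        results.append(
            EnrichmentResult(
                term=t, k=k, K=K, m=m, M=M, p_value=min(p, 1.0),
                name=dag.names.get(t, ""),
            )
        )
    return results


def n_testable_terms(
    universe: Iterable[str],
    dag: OntologyDAG,
    ann: AnnotationMap,
    min_term_size: int = 1,
) -> int:
    """Number of terms with >= min_term_size annotated genes in the universe."""
    term_genes = _term_gene_index(ann, frozenset(universe))
    return sum(1 for gs in term_genes.values() if len(gs) >= min_term_size)


def bonferroni_select(
    results: list[EnrichmentResult],
    alpha: float = 0.05,
    n_tested: int | None = None,
) -> frozenset[str]:
    """Terms with p <= alpha / n_tested (boundary inclusive).

    ``n_tested`` defaults to the number of results; pass the count of all
    minimum-size terms to divide by every node evaluated instead.  Marks the
    ``significant`` flag on the selected results.
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    if not results:
        return frozenset()
    n = n_tested if n_tested is not None else len(results)
    threshold = alpha / n
    selected = set()
    for r in results:
        r.significant = r.p_value <= threshold
        if r.significant:
            selected.add(r.term)
    return frozenset(selected)


def cross_species_overlap(
    human_sig: Iterable[str], mouse_sig: Iterable[str]
) -> frozenset[str]:
    """Terms overrepresented in both species (shared term namespace)."""
    return frozenset(human_sig) & frozenset(mouse_sig)


def map_to_phenotype_terms(
    sig_terms: Iterable[str],
    xmap,
    mp_dag: OntologyDAG,
) -> tuple[frozenset[str], frozenset[str]]:
    """Map overrepresented process terms to phenotype terms and roll up.

    ``xmap`` is a DataFrame with columns (source_term, target_term, distance);
    only distance-1 (direct) mappings are used.  Returns the mapped phenotype
    terms and the top-level phenotype terms (direct children of the root)
    that they roll up to; a mapped term that is itself top-level is its own
    rollup.
    """
    sig = frozenset(sig_terms)
    direct = xmap[xmap["distance"] == 1]
    mp_terms = frozenset(
        direct.loc[direct["source_term"].isin(sig), "target_term"]
    )
    top_children = mp_dag.top_level_terms()
    top_level: set[str] = set()
    for t in mp_terms:
        if t not in mp_dag:
            raise ValueError(f"mapped phenotype term {t!r} not in phenotype ontology")
        top_level |= (mp_dag.ancestors(t) | {t}) & top_children
    return mp_terms, frozenset(top_level)
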