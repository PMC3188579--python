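"""GO-term enrichment of a significant gene list.

Three tests over an is_a/part_of DAG with annotations propagated to all
ancestors (the annotation closure):

* term-for-term — upper-tail hypergeometric per term against the whole
  population;
* parent-child — the hypergeometric test conditioned on the parents'
  annotation set (intersection variant: the conditioning population is the
  genes annotated to *all* parents of the term), which discounts enrichment
  a term merely inherits from its parents;
* permutation — an empirical null built by redrawing the study set uniformly
  without replacement from the population.

No multiple-testing correction is applied by default; a Benjamini-Hochberg
option is available on each method.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import obonet
import pandas as pd
from scipy.stats import hypergeom

_PARENT_EDGES = {"is_a", "part_of"}


@dataclass
class GoDag:
    """Term DAG plus gene annotations and their ancestor closure."""

    graph: nx.DiGraph  # edge term -> parent
    annotations: dict[str, set[str]]  # gene -> direct term set
    closure: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not nx.is_directed_acyclic_graph(self.graph):
            raise ValueError("term parent graph must be acyclic")
        if not self.closure:
            self.closure = {
                g: self.propagate(terms) for g, terms in self.annotations.items()
            }

    def propagate(self, terms: set[str]) -> set[str]:
        """A term set plus every ancestor reachable along parent edges."""
        out = set()
        for t in terms:
            if t not in self.graph:
                continue
            out.add(t)
            out |= nx.descendants(self.graph, t)  # edges point child -> parent
        return out

    def parents(self, term: str) -> set[str]:
        return set(self.graph.successors(term))

    def roots(self) -> set[str]:
        return {t for t in self.graph.nodes if not self.parents(t)}

    def genes_of(self, term: str, universe: set[str]) -> set[str]:
        return {g for g in universe if term in self.closure.get(g, ())}

    # -- construction --------------------------------------------------------

    @classmethod
    def from_obo(cls, obo_path, annotation_path) -> "GoDag":
        """Read an OBO term file and a 2-column gene<TAB>term annotation file."""
        multi = obonet.read_obo(obo_path)
        graph = nx.DiGraph()
        graph.add_nodes_from(multi.nodes(data=True))
        for child, parent, key in multi.edges(keys=True):
            if key in _PARENT_EDGES:
                graph.add_edge(child, parent)
        annotations: dict[str, set[str]] = {}
        with open(annotation_path) as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                gene, term = line.rstrip("\n").split("\t")[:2]
                if term in graph:
                    annotations.setdefault(gene, set()).add(term)
        return cls(graph=graph, annotations=annotations)

    @classmethod
    def from_edges(
        cls,
        edges: list[tuple[str, str]],
        annotations: dict[str, set[str]],
        names: dict[str, str] | None = None,
    ) -> "GoDag":
        """Build from (child, parent) pairs; isolated terms allowed via names."""
        graph = nx.DiGraph()
        if names:
            graph.add_nodes_from(names)
        graph.add_edges_from(edges)
        for g, terms in annotations.items():
            graph.add_nodes_from(terms)
        return cls(graph=graph, annotations=dict(annotations))


@dataclass(frozen=True)
class EnrichmentRow:
    term: str
    study_hits: int
    study_size: int
    population_hits: int
    population_size: int
    p_value: float
    method: str


def _prepare(study: set[str], population: set[str], dag: GoDag):
    """Drop unannotated genes from study and population; returns the counts."""
    annotated = set(dag.closure)
    pop = {g for g in population if g in annotated}
    stu = {g for g in study if g in annotated}
    dropped = (len(population) - len(pop)) + (len(study) - len(stu))
    if not stu <= pop:
        raise ValueError("study set must be a subset of the population")
    return stu, pop, dropped


def _terms_of(pop: set[str], dag: GoDag) -> dict[str, set[str]]:
    """term -> population genes annotated (via closure) to it."""
    by_term: dict[str, set[str]] = {}
    for g in pop:
        for t in dag.closure[g]:
            by_term.setdefault(t, set()).add(g)
    return by_term


def _maybe_bh(rows: list[EnrichmentRow], adjust: bool) -> pd.DataFrame:
    df = pd.DataFrame(rows).sort_values(["p_value", "term"]).reset_index(drop=True)
    if adjust and len(df):
        p = df["p_value"].values
        m = len(p)
        order = np.argsort(p, kind="mergesort")
        adj = p[order] * m / np.arange(1, m + 1)
        adj = np.minimum(np.minimum.accumulate(adj[::-1])[::-1], 1.0)
        out = np.empty(m)
        out[order] = adj
        df["p_adjusted"] = out
    return df


def term_for_term(
    study: set[str], population: set[str], dag: GoDag, adjust: bool = False
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment, one row per annotated term.

    p = P(X >= m_t) with X ~ Hypergeom(N, M_t, n): N the population size,
    M_t the term's population annotations, n the study size. Terms with no
    population annotation are skipped.
    """
    stu, pop, _ = _prepare(study, population, dag)
    by_term = _terms_of(pop, dag)
    rows = []
    for term in sorted(by_term):
        M = len(by_term[term])
        m = len(by_term[term] & stu)
        p = float(hypergeom.sf(m - 1, len(pop), M, len(stu)))
        rows.append(
            EnrichmentRow(term, m, len(stu), M, len(pop), min(p, 1.0),
                          "term_for_term")
        )
    return _maybe_bh(rows, adjust)


def parent_child(
    study: set[str], population: set[str], dag: GoDag, adjust: bool = False
) -> pd.DataFrame:
    """Parent-child-intersection enrichment.

    Each term is tested inside the sub-population annotated to *all* of its
    parents: p = P(X >= m_t), X ~ Hypergeom(|pa(t) ∩ pop|, M_t within,
    |pa(t) ∩ study|). Root terms (no parents) get p = 1 by convention; so
    does a term whose annotation set equals its parents' intersection (no
    refinement is possible).
    """
    stu, pop, _ = _prepare(study, population, dag)
    by_term = _terms_of(pop, dag)
    rows = []
    for term in sorted(by_term):
        parents = dag.parents(term)
        if not parents:
            rows.append(
                EnrichmentRow(term, len(by_term[term] & stu), len(stu),
                              len(by_term[term]), len(pop), 1.0, "parent_child")
            )
            continue
        cond_pop = set(pop)
        for par in parents:
            cond_pop &= by_term.get(par, set())
        cond_stu = cond_pop & stu
        M = len(by_term[term] & cond_pop)
        m = len(by_term[term] & cond_stu)
        p = float(hypergeom.sf(m - 1, len(cond_pop), M, len(cond_stu)))
        rows.append(
            EnrichmentRow(term, m, len(cond_stu), M, len(cond_pop),
                          min(p, 1.0), "parent_child")
        )
    return _maybe_bh(rows, adjust)


def perm_enrichment(
    study: set[str],
    population: set[str],
    dag: GoDag,
    n_perm: int = 1000,
    seed: int = 0,
    adjust: bool = False,
) -> pd.DataFrame:
    """Permutation enrichment: redraw the study set uniformly from the
    population ``n_perm`` times; p = (1 + #{m* >= m_t}) / (n_perm + 1)."""
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    stu, pop, _ = _prepare(study, population, dag)
    by_term = _terms_of(pop, dag)
    terms = sorted(by_term)
    pop_list = sorted(pop)
    term_index = {t: i for i, t in enumerate(terms)}
    # gene -> term index list for fast permutation tallies
    gene_terms = {
        g: np.array([term_index[t] for t in dag.closure[g] if t in term_index])
        for g in pop_list
    }
    observed = np.zeros(len(terms), dtype=np.int64)
    for g in stu:
        observed[gene_terms[g]] += 1
    exceed = np.zeros(len(terms), dtype=np.int64)
    rng = np.random.default_rng(seed)
    n = len(stu)
    for _ in range(n_perm):
        draw = rng.choice(len(pop_list), size=n, replace=False)
        counts = np.zeros(len(terms), dtype=np.int64)
        for gi in draw:
            counts[gene_terms[pop_list[gi]]] += 1
        exceed += counts >= observed
    rows = [
        EnrichmentRow(
            t, int(observed[i]), n, len(by_term[t]), len(pop),
            float((1 + exceed[i]) / (n_perm + 1)), "permutation",
        )
        for i, t in enumerate(terms)
    ]
    return _maybe_bh(rows, adjust)
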