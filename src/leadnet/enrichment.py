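"""Ontology over-representation analysis in the BinGO style.

A study set (typically the leader genes) is tested term-by-term against a
background population with the exact upper-tail hypergeometric probability
P(X >= k), X ~ Hypergeom(N, K, n), followed by Benjamini-Hochberg FDR
correction (Bonferroni available).  When an ontology edge table is supplied,
annotations are first propagated along the true-path rule: a gene annotated
to a term is annotated to every ancestor of that term.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Mapping

import networkx as nx
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .network import normalize_symbol

logger = logging.getLogger("leadnet")


class AnnotationTable:
    """Set of (gene, term) annotation pairs with optional term names."""

    def __init__(self, pairs: Iterable[tuple[str, str]] = (),
                 term_names: Mapping[str, str] | None = None):
        self.pairs: set[tuple[str, str]] = set()
        self.term_names: dict[str, str] = dict(term_names or {})
        for gene, term in pairs:
            self.add(gene, term)

    def add(self, gene: str, term: str, name: str | None = None) -> None:
        term = str(term).strip()
        if not term:
            raise ValidationError("empty term id in annotation table")
        self.pairs.add((normalize_symbol(gene), term))
        if name:
            self.term_names[term] = name

    @property
    def genes(self) -> set[str]:
        return {g for g, _ in self.pairs}

    @property
    def terms(self) -> set[str]:
        return {t for _, t in self.pairs}

    def genes_for_term(self, term: str) -> set[str]:
        return {g for g, t in self.pairs if t == term}

    def terms_for_gene(self, gene: str) -> set[str]:
        gene = normalize_symbol(gene)
        return {t for g, t in self.pairs if g == gene}

    def __len__(self) -> int:
        return len(self.pairs)

    def __eq__(self, other) -> bool:
        return isinstance(other, AnnotationTable) and self.pairs == other.pairs


class OntologyEdges:
    """Directed child -> parent term relations; must form a DAG."""

    def __init__(self, edges: Iterable[tuple[str, str]] = ()):
        self.edges: list[tuple[str, str]] = [
            (str(c).strip(), str(p).strip()) for c, p in edges
        ]
        for c, p in self.edges:
            if not c or not p:
                raise ValidationError("empty term id in ontology edge table")

    def digraph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_edges_from(self.edges)
        return g

    def validate_dag(self) -> None:
        g = self.digraph()
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise ValidationError(
                f"ontology contains a directed cycle through term {cycle[0][0]!r}"
            )

    def __len__(self) -> int:
        return len(self.edges)


def propagate_annotations(annot: AnnotationTable, ontology: OntologyEdges) -> AnnotationTable:
    """Apply the true-path rule: annotate each gene to all ancestor terms.

    Idempotent; raises :class:`ValidationError` naming a cycle member if the
    ontology is not a DAG.
    """
    ontology.validate_dag()
    g = ontology.digraph()
    ancestors: dict[str, set[str]] = {}

    def anc(term: str) -> set[str]:
        if term not in ancestors:
            ancestors[term] = set(nx.descendants(g, term)) if term in g else set()
        return ancestors[term]

    out = AnnotationTable(term_names=annot.term_names)
    for gene, term in annot.pairs:
        out.add(gene, term)
        for parent in anc(term):
            out.add(gene, parent)
    return out


def hypergeom_overrep(k: int, n: int, K: int, N: int) -> float:
    """Exact upper-tail hypergeometric probability P(X >= k).

    ``k`` study genes carry the term, out of a study set of ``n`` drawn from
    a population of ``N`` genes of which ``K`` carry the term.
    """
    k, n, K, N = int(k), int(n), int(K), int(N)
    if not (0 <= k <= min(n, K) and K <= N and n <= N and n >= 0 and K >= 0):
        raise ValidationError(
            f"inconsistent counts k={k}, n={n}, K={K}, N={N}: "
            "require 0 <= k <= min(n, K), K <= N, n <= N"
        )
    # sf(k-1) = P(X >= k); exact within scipy's hypergeometric pmf accuracy
    return float(hypergeom.sf(k - 1, N, K, n))


def bh_correct(p_values: Mapping[str, float], method: str = "bh") -> dict[str, float]:
    """Benjamini-Hochberg step-up q-values (or Bonferroni with method="bonferroni").

    Monotone-enforced and capped at 1; stable under input permutation and
    under tied p-values.
    """
    terms = list(p_values)
    ps = [float(p_values[t]) for t in terms]
    for t, p in zip(terms, ps):
        if not (0.0 < p <= 1.0):
            raise ValidationError(f"p-value {p} for term {t!r} outside (0, 1]")
    if not terms:
        return {}
    sm_method = {"bh": "fdr_bh", "bonferroni": "bonferroni"}.get(method)
    if sm_method is None:
        raise ValidationError(f"unknown correction method {method!r}")
    _, q, _, _ = multipletests(ps, method=sm_method)
    return dict(zip(terms, (float(v) for v in q)))


def run_enrichment(study, annot: AnnotationTable,
                   ontology: OntologyEdges | None = None,
                   background=None,
                   correction: str = "bh") -> pd.DataFrame:
    """Term-by-term over-representation of a study gene set.

    Parameters
    ----------
    study : iterable of str or GeneList
        Study gene symbols (e.g. the leader genes).
    annot : AnnotationTable
        Gene -> term annotations defining the population terms.
    ontology : OntologyEdges, optional
        If given, annotations are true-path propagated first.
    background : iterable of str, optional
        Population gene set; defaults to all annotated genes.  The study set
        must be contained in the background.
    correction : {"bh", "bonferroni"}

    Returns
    -------
    pandas.DataFrame
        Columns term, term_name, k, n, K, N, p_value, q_value; terms with
        k = 0 excluded; sorted ascending by (p_value, term).
    """
    symbols = getattr(study, "symbols", study)
    study_set = {normalize_symbol(s) for s in symbols}
    if ontology is not None:
        annot = propagate_annotations(annot, ontology)
    if background is None:
        bg = set(annot.genes)
    else:
        bg_symbols = getattr(background, "symbols", background)
        bg = {normalize_symbol(s) for s in bg_symbols}
        missing = study_set - bg
        if missing:
            raise ValidationError(
                f"study genes not in background: {sorted(missing)[:5]}"
            )
    study_set &= bg
    annotated_study = {g for g in study_set if annot.terms_for_gene(g)}
    if not annotated_study:
        raise ValidationError("no annotated study genes after background intersection")

    N, n = len(bg), len(study_set)
    rows = []
    for term in sorted(annot.terms):
        term_genes = annot.genes_for_term(term) & bg
        K = len(term_genes)
        k = len(term_genes & study_set)
        if k == 0 or K == 0:
            continue
        p = hypergeom_overrep(k, n, K, N)
        rows.append({"term": term, "term_name": annot.term_names.get(term, ""),
                     "k": k, "n": n, "K": K, "N": N, "p_value": p})
    if not rows:
        return pd.DataFrame(columns=["term", "term_name", "k", "n", "K", "N",
                                     "p_value", "q_value"])
    df = pd.DataFrame(rows)
    qmap = bh_correct(dict(zip(df["term"], df["p_value"])), method=correction)
    df["q_value"] = df["term"].map(qmap)
    df = df.sort_values(["p_value", "term"], kind="mergesort").reset_index(drop=True)
    return df
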