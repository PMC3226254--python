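"""Hypergeometric GO term enrichment with DAG-propagated counts.

For a query gene list of size k drawn from a background of t genes, a term
with m annotated background genes of which q fall in the query has the
upper-tail enrichment probability

    P = sum_{i=q}^{min(m, k)} C(m, i) * C(t - m, k - i) / C(t, k),

the chance of seeing at least q annotated query genes under random
sampling.  Annotations are propagated to ancestors first, so "annotated"
means directly or through any descendant term ("q/m|t/k" convention).
Counts are namespace-specific: t and k count genes with at least one
annotation in the tested term's namespace, keeping q <= min(m, k) <= t.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from scipy.stats import hypergeom

from ._errors import DataError
from .gosim import AnnotationCorpus, OntologyDAG, propagate_annotations

__all__ = ["TermEnrichment", "hypergeom_tail", "enrich"]


@dataclass(frozen=True)
class TermEnrichment:
    """One term's enrichment counts and p-value ("q/m|t/k(p)")."""

    term: str
    namespace: str
    q: int
    m: int
    k: int
    t: int
    p_value: float
    annotated_query_genes: tuple[str, ...]
    fdr: float | None = None

    def format_counts(self) -> str:
        return f"{self.q}/{self.m}|{self.t}/{self.k}({self.p_value:.6g})"


def hypergeom_tail(q: int, m: int, k: int, t: int) -> float:
    """Upper-tail hypergeometric probability P(X >= q).

    X counts annotated genes in a size-k draw from t genes of which m are
    annotated.  Computed through the survival function of the
    hypergeometric distribution (log-space stable).
    """
    if not (0 <= m <= t and 0 <= k <= t):
        raise DataError(f"need 0 <= m <= t and 0 <= k <= t, got "
                        f"q={q}, m={m}, k={k}, t={t}")
    if not 0 <= q <= min(m, k):
        raise DataError(f"need 0 <= q <= min(m, k), got q={q}, m={m}, k={k}")
    if q == 0:
        return 1.0
    return float(hypergeom.sf(q - 1, t, m, k))


def enrich(
    query: list[str],
    background: list[str],
    dag: OntologyDAG,
    corpus: AnnotationCorpus,
    p_threshold: float | None = None,
    compute_fdr: bool = False,
) -> list[TermEnrichment]:
    """Test every term with >= 1 annotated query gene for over-representation.

    ``query`` must be a subset of ``background``; both are restricted, per
    namespace, to genes carrying at least one annotation there.  The
    returned list keeps terms with raw p-value < ``p_threshold`` (all terms
    when None), sorted ascending by p-value then term id.  With
    ``compute_fdr`` a Benjamini-Hochberg column over *all* tested terms is
    attached (the p-value filter still applies to the raw values).
    """
    query = sorted(set(query))
    background_set = set(background)
    for g in query:
        if g not in background_set:
            raise DataError(f"query gene {g!r} is not in the background")
    if p_threshold is not None and not 0.0 < p_threshold <= 1.0:
        raise DataError("p_threshold must lie in (0, 1]")

    propagated = propagate_annotations(dag, corpus)
    # Restrict to the supplied background.
    propagated = {g: ts for g, ts in propagated.items() if g in background_set}

    ns_of = dag.namespace
    # Per-namespace annotated gene universes.
    ns_background: dict[str, set[str]] = {}
    ns_query: dict[str, set[str]] = {}
    term_genes: dict[str, set[str]] = {}
    for gene, terms in propagated.items():
        in_query = gene in set(query)
        for t in terms:
            ns = ns_of[t]
            ns_background.setdefault(ns, set()).add(gene)
            if in_query:
                ns_query.setdefault(ns, set()).add(gene)
            term_genes.setdefault(t, set()).add(gene)

    results: list[TermEnrichment] = []
    query_set = set(query)
    for term, genes in term_genes.items():
        ns = ns_of[term]
        q_genes = genes & query_set
        if not q_genes:
            continue
        q = len(q_genes)
        m = len(genes)
        k = len(ns_query.get(ns, ()))
        t = len(ns_background.get(ns, ()))
        results.append(TermEnrichment(
            term=term, namespace=ns, q=q, m=m, k=k, t=t,
            p_value=hypergeom_tail(q, m, k, t),
            annotated_query_genes=tuple(sorted(q_genes)),
        ))

    results.sort(key=lambda r: (r.p_value, r.term))
    if compute_fdr and results:
        n = len(results)
        # Benjamini-Hochberg over the already p-sorted list.
        adj = [r.p_value * n / (i + 1) for i, r in enumerate(results)]
        for i in range(n - 2, -1, -1):
            adj[i] = min(adj[i], adj[i + 1])
        results = [replace(r, fdr=min(a, 1.0)) for r, a in zip(results, adj)]
    if p_threshold is None:
        return results
    return [r for r in results if r.p_value < p_threshold]
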