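"""GO semantic similarity of genes by Schlicker's relevance (Rel) measure.

Each Gene Ontology term t gets an annotation probability p(t) — the
fraction of genes in the corpus annotated to t directly or through any
descendant, normalized within the term's namespace — and an information
content ic(t) = -ln p(t).  Two terms' Rel similarity is taken over their
common ancestors c,

    sim(t1, t2) = max_c [ 2*ic(c) / (ic(t1) + ic(t2)) ] * (1 - p(c)),

the Lin ratio weighted by how non-generic the shared ancestor is; a pair
whose only common ancestor is the namespace root scores 0.  Gene-level
similarity aggregates term similarities over the two genes' direct
annotation sets, by default with the best-match average (BMA), separately
for molecular function and biological process, and averages the available
namespaces.  Gene pairs exceeding a similarity threshold form the edges of
gene networks (connected components of size > 1).
"""

from __future__ import annotations

import csv
import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import obonet

from ._errors import DataError, ModelError
from .networks import NetworkComponent, _components

__all__ = [
    "NAMESPACES",
    "OntologyDAG",
    "AnnotationCorpus",
    "TermIC",
    "GeneNetwork",
    "propagate_annotations",
    "term_ic",
    "rel_term_sim",
    "gene_sim",
    "gene_network",
]

NAMESPACES = ("molecular_function", "biological_process", "cellular_component")
#: GAF aspect code -> namespace.
ASPECT_TO_NAMESPACE = {"F": "molecular_function", "P": "biological_process",
                       "C": "cellular_component"}


class OntologyDAG:
    """Directed acyclic GO term graph with one root per namespace.

    ``parents`` maps each term to its direct parents (is_a and, optionally,
    part_of); every non-root term must reach its namespace root.
    """

    def __init__(self, parents: dict[str, set[str]],
                 namespace: dict[str, str]):
        self.parents = {t: frozenset(ps) for t, ps in parents.items()}
        self.namespace = dict(namespace)
        unknown_ns = set(self.namespace.values()) - set(NAMESPACES)
        if unknown_ns:
            raise ModelError(f"unknown namespace(s): {sorted(unknown_ns)}")
        for t, ps in self.parents.items():
            for p in ps:
                if p not in self.namespace:
                    raise ModelError(f"parent {p!r} of {t!r} is not a term")
                if self.namespace[p] != self.namespace[t]:
                    raise ModelError(
                        f"edge {t!r} -> {p!r} crosses namespaces")
        g = nx.DiGraph()
        g.add_nodes_from(self.namespace)
        g.add_edges_from((t, p) for t, ps in self.parents.items() for p in ps)
        if not nx.is_directed_acyclic_graph(g):
            raise ModelError("ontology graph contains a cycle")
        self._graph = g
        self.roots: dict[str, str] = {}
        for ns in sorted(set(self.namespace.values())):
            roots = [t for t in self.namespace
                     if self.namespace[t] == ns and not self.parents.get(t)]
            if len(roots) != 1:
                raise ModelError(
                    f"namespace {ns} must have exactly one root, "
                    f"found {len(roots)}")
            self.roots[ns] = roots[0]
        for t in self.namespace:
            root = self.roots[self.namespace[t]]
            if t != root and not nx.has_path(g, t, root):
                raise ModelError(f"term {t!r} does not reach its root")
        self._ancestor_cache: dict[str, frozenset[str]] = {}

    @classmethod
    def from_obo(cls, path, include_part_of: bool = False) -> "OntologyDAG":
        """Read an OBO 1.2 file (is_a edges; part_of optionally included)."""
        graph = obonet.read_obo(path)
        parents: dict[str, set[str]] = {}
        namespace: dict[str, str] = {}
        wanted = {"is_a"} | ({"part_of"} if include_part_of else set())
        for term, data in graph.nodes(data=True):
            ns = data.get("namespace")
            if ns not in NAMESPACES:
                continue
            namespace[term] = ns
            parents.setdefault(term, set())
        for child, parent, key in graph.edges(keys=True):
            if key in wanted and child in namespace and parent in namespace:
                parents[child].add(parent)
        return cls(parents, namespace)

    @property
    def terms(self) -> set[str]:
        return set(self.namespace)

    def __contains__(self, term: str) -> bool:
        return term in self.namespace

    def ancestors(self, term: str) -> frozenset[str]:
        """All (strict) ancestors of ``term``."""
        if term not in self.namespace:
            raise DataError(f"unknown term {term!r}")
        cached = self._ancestor_cache.get(term)
        if cached is None:
            cached = frozenset(nx.descendants(self._graph, term))
            self._ancestor_cache[term] = cached
        return cached

    def ancestors_or_self(self, term: str) -> frozenset[str]:
        return self.ancestors(term) | {term}


@dataclass
class AnnotationCorpus:
    """Direct gene -> GO term annotations plus the background gene universe."""

    annotations: dict[str, frozenset[str]]
    universe: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.annotations = {g: frozenset(ts)
                            for g, ts in self.annotations.items()}
        self.universe = frozenset(self.universe) | set(self.annotations)

    @classmethod
    def from_gaf(cls, path, exclude_evidence: set[str] | None = None
                 ) -> "AnnotationCorpus":
        """Read GAF 2.x: column 2 = gene id, 5 = GO id, 7 = evidence,
        9 = aspect.  All evidence codes are kept unless excluded."""
        exclude = exclude_evidence or set()
        annotations: dict[str, set[str]] = {}
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith("!"):
                    continue
                cols = line.rstrip("\n").split("\t")
                if len(cols) < 9:
                    raise DataError("GAF line has fewer than 9 columns")
                gene, go_id, evidence = cols[1], cols[4], cols[6]
                if cols[3].lower().startswith("not"):
                    continue
                if evidence in exclude:
                    continue
                annotations.setdefault(gene, set()).add(go_id)
        return cls(annotations={g: frozenset(t)
                                for g, t in annotations.items()})

    @classmethod
    def from_tsv(cls, path) -> "AnnotationCorpus":
        """Read the minimal 2-column dialect: gene <TAB> term."""
        annotations: dict[str, set[str]] = {}
        with open(path) as fh:
            for row in csv.reader(fh, delimiter="\t"):
                if not row or row[0].startswith("#"):
                    continue
                if len(row) != 2:
                    raise DataError("annotation TSV rows must be gene<TAB>term")
                annotations.setdefault(row[0], set()).add(row[1])
        return cls(annotations={g: frozenset(t)
                                for g, t in annotations.items()})

    def validate_terms(self, dag: OntologyDAG) -> None:
        for gene, terms in self.annotations.items():
            for t in terms:
                if t not in dag:
                    raise DataError(
                        f"gene {gene!r} annotated to unknown term {t!r}")


@dataclass(frozen=True)
class TermIC:
    """Per-term annotation probability and information content.

    Only terms with at least one (propagated) annotation appear; a
    namespace with no annotated genes is dropped entirely.
    """

    p: dict[str, float]
    ic: dict[str, float]
    genes_per_namespace: dict[str, int]

    def __contains__(self, term: str) -> bool:
        return term in self.p


def propagate_annotations(
    dag: OntologyDAG, corpus: AnnotationCorpus
) -> dict[str, frozenset[str]]:
    """Each gene's term set closed under the ancestor relation (idempotent)."""
    corpus.validate_terms(dag)
    out = {}
    for gene, terms in corpus.annotations.items():
        closed: set[str] = set()
        for t in terms:
            closed |= dag.ancestors_or_self(t)
        out[gene] = frozenset(closed)
    return out


def term_ic(dag: OntologyDAG, corpus: AnnotationCorpus) -> TermIC:
    """Annotation probability p(t) and information content -ln p(t).

    p(t) = (# genes annotated to t or any descendant) / (# genes with any
    annotation in t's namespace); the namespace root always has p = 1.
    """
    propagated = propagate_annotations(dag, corpus)
    counts: dict[str, int] = {}
    ns_genes: dict[str, set[str]] = {ns: set() for ns in NAMESPACES}
    for gene, terms in propagated.items():
        for t in terms:
            counts[t] = counts.get(t, 0) + 1
            ns_genes[dag.namespace[t]].add(gene)
    p: dict[str, float] = {}
    ic: dict[str, float] = {}
    genes_per_ns = {ns: len(g) for ns, g in ns_genes.items() if g}
    for t, c in counts.items():
        total = genes_per_ns.get(dag.namespace[t])
        if not total:
            continue
        p[t] = c / total
        ic[t] = -np.log(p[t])
    return TermIC(p=p, ic=ic, genes_per_namespace=genes_per_ns)


def rel_term_sim(t1: str, t2: str, tic: TermIC, dag: OntologyDAG) -> float:
    """Schlicker relevance similarity of two same-namespace terms.

    max over common ancestors c (including the terms themselves) of
    [2*ic(c) / (ic(t1) + ic(t2))] * (1 - p(c)); 0 when ic(t1) + ic(t2) = 0.
    Ancestors without an annotation (hence without an IC) are skipped.
    """
    for t in (t1, t2):
        if t not in dag:
            raise DataError(f"unknown term {t!r}")
        if t not in tic:
            raise DataError(f"term {t!r} has no annotation in the corpus")
    if dag.namespace[t1] != dag.namespace[t2]:
        raise DataError(
            f"cross-namespace pair: {t1!r} ({dag.namespace[t1]}) vs "
            f"{t2!r} ({dag.namespace[t2]})")
    denom = tic.ic[t1] + tic.ic[t2]
    if denom == 0.0:
        return 0.0
    common = dag.ancestors_or_self(t1) & dag.ancestors_or_self(t2)
    best = 0.0
    for c in common:
        if c not in tic:
            continue
        val = (2.0 * tic.ic[c] / denom) * (1.0 - tic.p[c])
        if val > best:
            best = val
    return best


def _bma(sim_matrix: np.ndarray) -> float:
    """Best-match average of an n1 x n2 term-similarity matrix."""
    n1, n2 = sim_matrix.shape
    return float((sim_matrix.max(axis=1).sum() + sim_matrix.max(axis=0).sum())
                 / (n1 + n2))


def gene_sim(
    g1: str,
    g2: str,
    dag: OntologyDAG,
    tic: TermIC,
    corpus: AnnotationCorpus,
    namespaces: tuple[str, ...] = ("molecular_function", "biological_process"),
    combine: str = "bma",
) -> float | None:
    """Gene-level semantic similarity over the requested namespaces.

    Per namespace the two genes' *direct* term sets are compared with the
    ``combine`` rule (``"bma"`` best-match average, ``"max"``, or
    ``"avg"``); the final value is the arithmetic mean of the namespaces
    where both genes are annotated.  Returns None when no namespace is
    shared.
    """
    if combine not in ("bma", "max", "avg"):
        raise DataError("combine must be 'bma', 'max' or 'avg'")
    for g in (g1, g2):
        if g not in corpus.annotations:
            raise DataError(f"unknown gene {g!r}")
    per_ns: list[float] = []
    for ns in namespaces:
        t1 = [t for t in corpus.annotations[g1]
              if dag.namespace.get(t) == ns and t in tic]
        t2 = [t for t in corpus.annotations[g2]
              if dag.namespace.get(t) == ns and t in tic]
        if not t1 or not t2:
            continue
        mat = np.array([[rel_term_sim(a, b, tic, dag) for b in t2]
                        for a in t1])
        if combine == "bma":
            per_ns.append(_bma(mat))
        elif combine == "max":
            per_ns.append(float(mat.max()))
        else:
            per_ns.append(float(mat.mean()))
    if not per_ns:
        return None
    return float(np.mean(per_ns))


def gene_sim_matrix(
    genes: list[str],
    dag: OntologyDAG,
    tic: TermIC,
    corpus: AnnotationCorpus,
    namespaces: tuple[str, ...] = ("molecular_function", "biological_process"),
    combine: str = "bma",
) -> dict[tuple[str, str], float]:
    """All-pairs gene similarity; pairs without a shared namespace omitted."""
    out = {}
    for g1, g2 in itertools.combinations(sorted(set(genes)), 2):
        s = gene_sim(g1, g2, dag, tic, corpus, namespaces, combine)
        if s is not None:
            out[(g1, g2)] = s
    return out


@dataclass(frozen=True)
class GeneNetwork:
    """Gene networks at one similarity threshold (Table-style summary)."""

    threshold: float
    components: tuple[NetworkComponent, ...]

    @property
    def n_networks(self) -> int:
        return len(self.components)

    @property
    def n_pairs(self) -> int:
        return sum(c.edge_count for c in self.components)

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(sorted(g for c in self.components for g in c.member_snps))


def gene_network(
    similarities: dict[tuple[str, str], float], threshold: float
) -> GeneNetwork:
    """Connected components of gene pairs with similarity strictly above
    ``threshold``; single-gene components are dropped."""
    if not 0.0 <= threshold <= 1.0:
        raise DataError("threshold must lie in [0, 1]")
    edges = [(a, b) for (a, b), s in similarities.items() if s > threshold]
    comps = _components([], edges)
    return GeneNetwork(threshold=float(threshold), components=tuple(comps))
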