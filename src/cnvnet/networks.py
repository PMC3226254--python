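"""SNP interaction networks and their resampling-based significance.

SNP pairs whose interaction P-value falls below a threshold become edges;
the connected components of size > 1 are the SNP networks.  A selected
network's coherence is judged against a null built by repeatedly drawing
the same number of SNPs at random from a pool, averaging all pairwise
P-values within each draw, and comparing the network's observed mean
pairwise P to the null sample's mean and standard deviation through the
standard-normal lower tail,

    significance = Phi((observed_mean - null_mean) / null_sd).

An empirical rank p-value (r + 1) / (n_reps + 1) over the null sample is
reported alongside.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.stats import norm

from ._errors import DataError
from .epistasis import EpistasisTest

__all__ = [
    "NetworkComponent",
    "NetworkSummary",
    "NullDistribution",
    "NetworkSignificance",
    "PLookup",
    "build_interaction_graph",
    "summarize_networks",
    "mean_pairwise_p",
    "random_network_null",
    "network_significance",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class NetworkComponent:
    """One connected component of the thresholded interaction graph."""

    member_snps: tuple[str, ...]  # sorted
    edge_count: int

    @property
    def size(self) -> int:
        return len(self.member_snps)


@dataclass(frozen=True)
class NetworkSummary:
    """Per-component size/edge counts plus totals (one threshold)."""

    threshold: float
    sizes: tuple[int, ...]
    edge_counts: tuple[int, ...]

    @property
    def n_networks(self) -> int:
        return len(self.sizes)

    @property
    def total_snps(self) -> int:
        return sum(self.sizes)

    @property
    def total_edges(self) -> int:
        return sum(self.edge_counts)

    def format_counts(self) -> tuple[str, str]:
        """"k(count)" strings for SNPs and pairs, e.g. "1(2), 2(49)"."""
        snps = ", ".join(f"{i}({s})" for i, s in enumerate(self.sizes, 1))
        pairs = ", ".join(f"{i}({e})" for i, e in enumerate(self.edge_counts, 1))
        return snps, pairs


@dataclass(frozen=True)
class NullDistribution:
    """Random same-size network null: sample mean, SD and the raw sample."""

    mean: float
    sd: float
    samples: np.ndarray


@dataclass(frozen=True)
class NetworkSignificance:
    """Gaussian-tail significance of an observed mean pairwise P."""

    observed_mean: float
    null_mean: float
    null_sd: float
    n_reps: int
    significance: float
    empirical_p: float | None = None


class PLookup:
    """All-pairs P-value source backed by a dict of canonical pairs.

    Keys are lexicographically ordered (snp_a, snp_b) tuples; values may be
    NaN for degenerate tests, which are skipped (and counted) by
    :func:`mean_pairwise_p`.
    """

    def __init__(self, pvalues: dict[tuple[str, str], float]):
        self._p = {self._key(a, b): float(p) for (a, b), p in pvalues.items()}

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        if a == b:
            raise DataError(f"self-pair ({a!r}, {a!r}) has no interaction test")
        return (a, b) if a < b else (b, a)

    @classmethod
    def from_tests(cls, tests: list[EpistasisTest]) -> "PLookup":
        return cls({
            (t.snp_a, t.snp_b): (t.p_value if t.available else math.nan)
            for t in tests
        })

    def __call__(self, a: str, b: str) -> float:
        key = self._key(a, b)
        try:
            return self._p[key]
        except KeyError:
            raise DataError(f"no interaction test for pair {key}") from None


def _components(nodes, edges) -> list[NetworkComponent]:
    """Size->1 components, ordered by descending size then smallest member."""
    g = nx.Graph()
    g.add_nodes_from(nodes)
    g.add_edges_from(edges)
    comps = []
    for members in nx.connected_components(g):
        if len(members) < 2:
            continue
        sub = g.subgraph(members)
        comps.append(NetworkComponent(member_snps=tuple(sorted(members)),
                                      edge_count=sub.number_of_edges()))
    comps.sort(key=lambda c: (-c.size, c.member_snps[0]))
    return comps


def build_interaction_graph(
    tests: list[EpistasisTest], threshold: float
) -> list[NetworkComponent]:
    """Connected components of the graph of pairs with P < threshold.

    Degenerate tests never contribute edges; components of a single SNP
    are discarded.  An empty test list yields an empty component list.
    """
    if not 0.0 < threshold < 1.0:
        raise DataError("threshold must lie strictly between 0 and 1")
    edges = [
        (t.snp_a, t.snp_b)
        for t in tests
        if t.available and t.snp_a != t.snp_b and t.p_value < threshold
    ]
    return _components([], edges)


def summarize_networks(
    components: list[NetworkComponent], threshold: float = float("nan")
) -> NetworkSummary:
    """Per-component SNP and edge counts with totals."""
    return NetworkSummary(
        threshold=threshold,
        sizes=tuple(c.size for c in components),
        edge_counts=tuple(c.edge_count for c in components),
    )


@dataclass(frozen=True)
class MeanPairwiseP:
    mean: float  # NaN when every pair is degenerate
    n_used: int
    n_excluded: int

    @property
    def available(self) -> bool:
        return not math.isnan(self.mean)


def mean_pairwise_p(snps, p_lookup) -> MeanPairwiseP:
    """Arithmetic mean of P over all unordered pairs of ``snps``.

    ``p_lookup`` is a callable ``(snp_a, snp_b) -> p`` (NaN marks a
    degenerate pair, excluded from numerator and denominator alike).
    """
    snps = sorted(set(snps))
    if len(snps) < 2:
        raise DataError("need at least 2 SNPs for a mean pairwise P")
    total, used, excluded = 0.0, 0, 0
    for a, b in itertools.combinations(snps, 2):
        p = p_lookup(a, b)
        if math.isnan(p):
            excluded += 1
        else:
            total += p
            used += 1
    if excluded:
        logger.info("mean_pairwise_p: excluded %d degenerate pair(s)", excluded)
    mean = total / used if used else math.nan
    return MeanPairwiseP(mean=mean, n_used=used, n_excluded=excluded)


def random_network_null(
    pool, size: int, n_reps: int, seed: int, p_lookup
) -> NullDistribution:
    """Null distribution of the mean pairwise P over random SNP draws.

    Each of ``n_reps`` draws picks ``size`` SNPs from ``pool`` without
    replacement (draws are independent of each other) and averages all
    pairwise P-values within the draw.
    """
    pool = sorted(set(pool))
    if size > len(pool):
        raise DataError(f"cannot draw {size} SNPs from a pool of {len(pool)}")
    if size < 2:
        raise DataError("network size must be at least 2")
    if n_reps < 2:
        raise DataError("n_reps must be at least 2")
    rng = np.random.default_rng(seed)
    samples = np.empty(n_reps)
    for r in range(n_reps):
        draw = rng.choice(len(pool), size=size, replace=False)
        samples[r] = mean_pairwise_p([pool[i] for i in draw], p_lookup).mean
    return NullDistribution(mean=float(np.mean(samples)),
                            sd=float(np.std(samples, ddof=1)),
                            samples=samples)


def network_significance(
    observed_mean: float,
    null_mean: float,
    null_sd: float,
    samples: np.ndarray | None = None,
) -> NetworkSignificance:
    """Gaussian lower-tail significance of the observed mean pairwise P.

    significance = Phi((observed_mean - null_mean) / null_sd).  When the
    raw null sample is supplied, the empirical rank p-value
    (r + 1) / (n_reps + 1) with r = #{null means <= observed} is added.
    """
    if null_sd < 0:
        raise DataError("null_sd must be non-negative")
    if null_sd == 0:
        warnings.warn("null SD is zero; significance degenerates to 0/1",
                      stacklevel=2)
        sig = 0.0 if observed_mean < null_mean else 1.0
    else:
        sig = float(norm.cdf((observed_mean - null_mean) / null_sd))
    emp = None
    n_reps = 0
    if samples is not None:
        samples = np.asarray(samples, dtype=float)
        n_reps = len(samples)
        r = int((samples <= observed_mean).sum())
        emp = (r + 1) / (n_reps + 1)
    return NetworkSignificance(observed_mean=float(observed_mean),
                               null_mean=float(null_mean),
                               null_sd=float(null_sd), n_reps=n_reps,
                               significance=sig, empirical_p=emp)
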