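"""Synthetic case/control SNP-array cohorts with planted signals.

The generator emulates the raw material of a copy-number association
study at desk scale:

* per-SNP canonical genotype clusters at theta ~ 0.05 / 0.5 / 0.95
  (AA / AB / BB) around a common diploid total intensity R ~ 2;
* per-sample (X, Y) allele intensities scattered around the cluster of
  the sample's genotype, drawn under Hardy-Weinberg at a minor-allele
  frequency sampled per SNP from a configurable range;
* a multiplicative copy-number effect at a planted set of "relevant"
  SNPs in cases only, scaling R by 2**lrr_shift so the case-minus-control
  mean LRR difference equals ``lrr_shift`` in expectation;
* case/control status drawn from a logistic model whose linear predictor
  carries planted genotype-interaction (epistasis) terms, with the
  intercept calibrated so the expected case count matches the request and
  a latent-utility draw enforcing the exact group sizes.

Everything is deterministic given the seed, and the planted truth
(relevant SNP ids, epistatic pairs) is recorded for recovery checks.
A companion generator builds a toy ontology and gene annotations so the
downstream gene-network and enrichment stages are exercisable end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from ._errors import ConfigError
from .gosim import ASPECT_TO_NAMESPACE, AnnotationCorpus, OntologyDAG
from .lrr import CLUSTER_COLUMNS, ClusterModel

__all__ = [
    "CohortConfig",
    "TruthSet",
    "SyntheticCohort",
    "SyntheticAnnotation",
    "simulate_cohort",
    "simulate_annotation",
    "write_fixture",
]

#: Canonical theta centers for the AA / AB / BB genotype clusters.
THETA_CENTERS = np.array([0.05, 0.5, 0.95])
#: Common diploid total-intensity baseline.
R_BASELINE = 2.0
#: SD of per-sample theta scatter around its cluster center.
THETA_NOISE_SD = 0.02
#: SD of the per-SNP log-normal jitter of cluster R centers.
CLUSTER_R_JITTER_SD = 0.05


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for one synthetic cohort."""

    n_cases: int = 100
    n_controls: int = 100
    n_snps: int = 300
    n_relevant: int = 10
    lrr_shift: float = 0.2
    lrr_noise_sd: float = 0.15
    n_epistatic_pairs: int = 0
    epistasis_log_odds: float = 0.0
    minor_allele_freq_range: tuple[float, float] = (0.1, 0.5)
    missing_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_cases", "n_controls", "n_snps", "n_relevant",
                     "n_epistatic_pairs"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        if self.n_relevant > self.n_snps:
            raise ConfigError("n_relevant cannot exceed n_snps")
        if 2 * self.n_epistatic_pairs > self.n_snps:
            raise ConfigError(
                "n_epistatic_pairs too large: 2*n_epistatic_pairs must not "
                "exceed n_snps")
        if self.lrr_noise_sd <= 0:
            raise ConfigError("lrr_noise_sd must be positive")
        lo, hi = self.minor_allele_freq_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigError(
                "minor_allele_freq_range must be an interval within (0, 0.5]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ConfigError("missing_rate must lie in [0, 1)")


@dataclass(frozen=True)
class TruthSet:
    """Planted signal: which SNPs carry a shift, which pairs interact."""

    relevant_snps: tuple[str, ...]
    epistatic_pairs: tuple[tuple[str, str], ...]


@dataclass
class SyntheticCohort:
    """One generated cohort with its ground truth."""

    config: CohortConfig
    sample_ids: list[str]
    snp_ids: list[str]
    x: np.ndarray            # (n, p) allele-A intensities
    y: np.ndarray            # (n, p) allele-B intensities
    clusters: ClusterModel
    genotypes: np.ndarray    # (n, p) dosage 0/1/2, NaN = missing
    phenotype: np.ndarray    # (n,) 1 = control, 2 = case
    truth: TruthSet
    maf: np.ndarray = field(default=None)  # (p,) simulated MAFs

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def intensity_frame(self) -> pd.DataFrame:
        """Long-form (sample_id, snp_id, X, Y) intensity table."""
        return pd.DataFrame({
            "sample_id": np.repeat(self.sample_ids, len(self.snp_ids)),
            "snp_id": np.tile(self.snp_ids, len(self.sample_ids)),
            "X": self.x.ravel(),
            "Y": self.y.ravel(),
        })

    def to_lrr_matrix(self):
        """LRR matrix recovered through the canonical-cluster interpolation."""
        from .lrr import build_lrr_matrix

        phenotype = dict(zip(self.sample_ids, self.phenotype))
        return build_lrr_matrix(self.intensity_frame(), self.clusters,
                                phenotype)

    def to_genotype_matrix(self):
        from .epistasis import GenotypeMatrix

        return GenotypeMatrix(dosages=self.genotypes,
                              phenotype=self.phenotype,
                              snp_ids=list(self.snp_ids),
                              sample_ids=list(self.sample_ids))


@dataclass
class SyntheticAnnotation:
    """Toy ontology, annotations and SNP-to-gene map for a cohort."""

    dag: OntologyDAG
    corpus: AnnotationCorpus
    snp_to_gene: dict[str, str]  # value "intergenic" for unmapped SNPs
    term_names: dict[str, str]


def _intensities_from_polar(theta: np.ndarray, r: np.ndarray):
    """Invert theta = (2/pi) arctan(Y/X), R = X + Y."""
    ang = theta * np.pi / 2.0
    x = r * np.cos(ang) / (np.cos(ang) + np.sin(ang))
    y = r * np.sin(ang) / (np.cos(ang) + np.sin(ang))
    return x, y


def simulate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate one cohort under ``config``; deterministic given the seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_cases + config.n_controls
    p = config.n_snps
    sample_ids = [f"s{i:04d}" for i in range(n)]
    snp_ids = [f"rs{i + 1:06d}" for i in range(p)]

    lo, hi = config.minor_allele_freq_range
    maf = rng.uniform(lo, hi, size=p)
    genotypes = rng.binomial(2, maf[None, :], size=(n, p)).astype(float)

    # Planted truth: relevant (shifted) SNPs, then epistatic pairs drawn
    # from the remaining SNPs where room allows.
    relevant_idx = np.sort(rng.choice(p, size=config.n_relevant,
                                      replace=False))
    remaining = np.setdiff1d(np.arange(p), relevant_idx)
    need = 2 * config.n_epistatic_pairs
    pool = remaining if len(remaining) >= need else np.arange(p)
    pair_idx = rng.choice(pool, size=need, replace=False)
    pairs = [(int(pair_idx[2 * i]), int(pair_idx[2 * i + 1]))
             for i in range(config.n_epistatic_pairs)]

    # Phenotype from the generative logit with planted interactions; the
    # intercept is calibrated to the requested case fraction and a latent
    # logistic draw enforces exact group sizes.
    eta = np.zeros(n)
    for i, j in pairs:
        eta += config.epistasis_log_odds * genotypes[:, i] * genotypes[:, j]
    target = config.n_cases / n if n else 0.0
    if n and 0.0 < target < 1.0 and np.ptp(eta) > 0:
        b0 = brentq(lambda b: expit(b + eta).mean() - target, -60.0, 60.0)
    else:
        # Constant eta: closed-form intercept (or degenerate all-one-class).
        b0 = 0.0
    latent = b0 + eta + rng.logistic(size=n)
    phenotype = np.ones(n, dtype=int)
    if config.n_cases:
        case_rows = np.argsort(latent, kind="stable")[-config.n_cases:]
        phenotype[case_rows] = 2

    # Canonical clusters: fixed theta centers, jittered R per cluster.
    r_centers = R_BASELINE * np.exp(
        rng.normal(0.0, CLUSTER_R_JITTER_SD, size=(p, 3)))
    cluster_table = pd.DataFrame(
        {
            "theta_AA": THETA_CENTERS[0], "R_AA": r_centers[:, 0],
            "theta_AB": THETA_CENTERS[1], "R_AB": r_centers[:, 1],
            "theta_BB": THETA_CENTERS[2], "R_BB": r_centers[:, 2],
        },
        index=pd.Index(snp_ids, name="snp_id"),
    )[CLUSTER_COLUMNS]
    clusters = ClusterModel(cluster_table)

    # Intensities: theta scatters around the genotype's cluster center;
    # R follows the cluster interpolation at the sample's theta times
    # 2**(true LRR), so the matrix recovered downstream equals the planted
    # LRR field exactly.
    geno_int = genotypes.astype(int)
    theta = np.clip(
        THETA_CENTERS[geno_int] + rng.normal(0.0, THETA_NOISE_SD, size=(n, p)),
        0.0, 1.0)
    lrr_true = rng.normal(0.0, config.lrr_noise_sd, size=(n, p))
    case_mask = phenotype == 2
    lrr_true[np.ix_(case_mask, relevant_idx)] += config.lrr_shift

    thetas_knots = cluster_table[["theta_AA", "theta_AB", "theta_BB"]].to_numpy()
    r_knots = cluster_table[["R_AA", "R_AB", "R_BB"]].to_numpy()
    r_expected = np.empty((n, p))
    for j in range(p):
        r_expected[:, j] = np.interp(theta[:, j], thetas_knots[j], r_knots[j])
    r_observed = r_expected * np.power(2.0, lrr_true)
    x, y = _intensities_from_polar(theta, r_observed)

    if config.missing_rate > 0:
        miss = rng.random(size=(n, p)) < config.missing_rate
        genotypes[miss] = np.nan

    truth = TruthSet(
        relevant_snps=tuple(snp_ids[i] for i in relevant_idx),
        epistatic_pairs=tuple(
            tuple(sorted((snp_ids[i], snp_ids[j])))  # type: ignore[misc]
            for i, j in pairs),
    )
    return SyntheticCohort(config=config, sample_ids=sample_ids,
                           snp_ids=snp_ids, x=x, y=y, clusters=clusters,
                           genotypes=genotypes, phenotype=phenotype,
                           truth=truth, maf=maf)


def simulate_annotation(
    snp_ids: list[str],
    seed: int = 0,
    genic_fraction: float = 0.6,
    snps_per_gene: int = 2,
    terms_per_namespace: int = 12,
) -> SyntheticAnnotation:
    """Toy GO ontology, gene annotations and SNP-to-gene map.

    A fraction of SNPs is assigned to genes (about ``snps_per_gene`` SNPs
    each); the rest are "intergenic".  Each namespace gets a small two-level
    DAG (root, a few mid-level terms, leaves) and every gene draws 1-3
    direct terms in MF and BP (and occasionally CC).
    """
    rng = np.random.default_rng(seed)
    n_snps = len(snp_ids)
    n_genic = int(round(genic_fraction * n_snps))
    genic = sorted(rng.choice(n_snps, size=n_genic, replace=False).tolist())
    n_genes = max(3, n_genic // max(snps_per_gene, 1)) if n_genic else 0
    gene_ids = [f"GENE{g + 1:03d}" for g in range(n_genes)]

    snp_to_gene = {s: "intergenic" for s in snp_ids}
    for pos, snp_idx in enumerate(genic):
        snp_to_gene[snp_ids[snp_idx]] = gene_ids[pos % n_genes]

    parents: dict[str, set[str]] = {}
    namespace: dict[str, str] = {}
    term_names: dict[str, str] = {}
    leaves_by_ns: dict[str, list[str]] = {}
    tid = 0

    def new_term(ns: str, name: str) -> str:
        nonlocal tid
        tid += 1
        term = f"GO:{tid:07d}"
        namespace[term] = ns
        term_names[term] = name
        parents[term] = set()
        return term

    for ns in sorted(ASPECT_TO_NAMESPACE.values()):
        root = new_term(ns, f"{ns} root")
        n_mid = max(2, terms_per_namespace // 4)
        mids = []
        for i in range(n_mid):
            mid = new_term(ns, f"{ns} branch {i + 1}")
            parents[mid] = {root}
            mids.append(mid)
        leaves = []
        for i in range(terms_per_namespace - n_mid - 1):
            leaf = new_term(ns, f"{ns} leaf {i + 1}")
            # Leaves hang off 1-2 mid-level terms (diamonds exercise the
            # common-ancestor scan).
            k = 1 + int(rng.random() < 0.3)
            chosen = rng.choice(len(mids), size=min(k, len(mids)),
                                replace=False)
            parents[leaf] = {mids[c] for c in chosen}
            leaves.append(leaf)
        leaves_by_ns[ns] = leaves or mids

    annotations: dict[str, set[str]] = {}
    for gene in gene_ids:
        terms: set[str] = set()
        for ns in ("molecular_function", "biological_process"):
            pool = leaves_by_ns[ns]
            k = 1 + int(rng.integers(0, 3))
            chosen = rng.choice(len(pool), size=min(k, len(pool)),
                                replace=False)
            terms |= {pool[c] for c in chosen}
        if rng.random() < 0.5:
            pool = leaves_by_ns["cellular_component"]
            terms.add(pool[int(rng.integers(0, len(pool)))])
        annotations[gene] = terms

    dag = OntologyDAG(parents, namespace)
    corpus = AnnotationCorpus(
        annotations={g: frozenset(t) for g, t in annotations.items()})
    return SyntheticAnnotation(dag=dag, corpus=corpus,
                               snp_to_gene=snp_to_gene,
                               term_names=term_names)


def write_fixture(cohort: SyntheticCohort, directory,
                  annotation: SyntheticAnnotation | None = None) -> dict:
    """Write the cohort (and optional annotation) as plain-text fixtures.

    Emits the TSV dialects consumed by the reader functions in
    :mod:`cnvnet.io` plus, when an annotation is given, an OBO 1.2
    ontology, a GAF 2.1 annotation file and the SNP-to-gene map.  Returns
    a manifest of written paths.
    """
    from pathlib import Path

    from . import io as cio
    from .lrr import build_lrr_matrix

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {}

    intensities = pd.DataFrame({
        "sample_id": np.repeat(cohort.sample_ids, len(cohort.snp_ids)),
        "snp_id": np.tile(cohort.snp_ids, len(cohort.sample_ids)),
        "X": cohort.x.ravel(),
        "Y": cohort.y.ravel(),
    })
    manifest["intensities"] = cio.write_intensity_tsv(
        intensities, directory / "intensities.tsv")
    manifest["clusters"] = cio.write_clusters_tsv(
        cohort.clusters, directory / "clusters.tsv")
    manifest["phenotype"] = cio.write_phenotype_tsv(
        cohort.sample_ids, cohort.phenotype, directory / "phenotype.tsv")

    phenotype_map = dict(zip(cohort.sample_ids, cohort.phenotype))
    matrix = build_lrr_matrix(intensities, cohort.clusters, phenotype_map)
    manifest["lrr"] = cio.write_lrr_tsv(matrix, directory / "lrr.tsv")
    manifest["genotypes"] = cio.write_genotype_tsv(
        cohort.genotypes, cohort.phenotype, cohort.sample_ids,
        cohort.snp_ids, directory / "genotypes.tsv")
    manifest["truth"] = cio.write_truth_json(
        cohort.truth, directory / "truth.json")

    if annotation is not None:
        manifest["snp_to_gene"] = cio.write_snp_gene_map(
            annotation.snp_to_gene, directory / "snp_to_gene.tsv")
        manifest["ontology"] = cio.write_obo(
            annotation.dag, annotation.term_names,
            directory / "ontology.obo")
        manifest["annotations"] = cio.write_gaf(
            annotation.corpus, annotation.dag,
            directory / "annotations.gaf")
    return manifest
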