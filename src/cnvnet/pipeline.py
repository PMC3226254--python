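"""End-to-end orchestration: LRR -> classification -> SNP networks -> genes.

The workflow chains every stage of the framework behind one configuration:

1. build (or load) the samples x SNPs LRR matrix;
2. tune the shrinkage threshold Delta by stratified cross-validation, fit
   the shrunken-centroid model on the full data, and rank the selected
   SNPs;
3. run pairwise logistic interaction tests on the selected SNPs;
4. build SNP networks at each P threshold and score each against the
   random same-size-network null;
5. map selected SNPs to genes (intergenic SNPs stay in SNP networks but
   leave the gene stage), compute pairwise GO semantic similarities and
   gene networks;
6. run hypergeometric GO enrichment on the gene-network genes.

Every stage writes self-describing TSV outputs plus a JSON manifest
recording the seed, stage parameters and filter counts; a rerun with the
same configuration is byte-identical.
"""

from __future__ import annotations

import configparser
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as cio
from ._errors import ConfigError, PipelineError
from .centroid import cross_validate, fit_centroids, rank_features, shrink
from .enrichment import enrich
from .epistasis import pairwise_epistasis
from .gosim import (AnnotationCorpus, OntologyDAG, gene_network,
                    gene_sim_matrix, term_ic)
from .lrr import build_lrr_matrix
from .networks import (PLookup, build_interaction_graph, mean_pairwise_p,
                       network_significance, random_network_null,
                       summarize_networks)

__all__ = ["PipelineConfig", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All inputs, thresholds and tuning knobs for one pipeline run."""

    out_dir: str
    # Either a precomputed LRR matrix...
    lrr: str | None = None
    # ...or raw intensities plus clusters plus phenotype.
    intensities: str | None = None
    clusters: str | None = None
    phenotype: str | None = None
    genotypes: str | None = None
    snp_gene_map: str | None = None
    obo: str | None = None
    gaf: str | None = None
    cv_folds: int = 10
    delta_grid: str = "auto"      # "auto" or comma-separated values
    n_grid: int = 30
    s0_quantile: float = 0.5
    network_thresholds: tuple[float, ...] = (0.1, 0.05, 0.01, 0.005, 0.001)
    null_reps: int = 500
    gene_sim_threshold: float = 0.15
    enrichment_threshold: float = 0.001
    epistasis_method: str = "wald"
    seed: int = 0

    def validate(self) -> None:
        if self.lrr is None and not (self.intensities and self.clusters
                                     and self.phenotype):
            raise ConfigError(
                "either 'lrr' or all of 'intensities', 'clusters', "
                "'phenotype' must be set")
        for name in ("network_thresholds",):
            for v in getattr(self, name):
                if not 0.0 < v < 1.0:
                    raise ConfigError(f"{name} values must lie in (0, 1)")
        if not 0.0 < self.enrichment_threshold <= 1.0:
            raise ConfigError("enrichment_threshold must lie in (0, 1]")
        if not 0.0 <= self.gene_sim_threshold <= 1.0:
            raise ConfigError("gene_sim_threshold must lie in [0, 1]")
        if self.cv_folds < 2:
            raise ConfigError("cv_folds must be at least 2")
        for name in ("lrr", "intensities", "clusters", "phenotype",
                     "genotypes", "snp_gene_map", "obo", "gaf"):
            value = getattr(self, name)
            if value is not None and not Path(value).exists():
                raise ConfigError(f"{name} file not found: {value}")

    @classmethod
    def from_ini(cls, path) -> "PipelineConfig":
        """Read a key = value config with [inputs], [classify], [network],
        [genes] and [run] sections (all optional except inputs/out_dir)."""
        cp = configparser.ConfigParser()
        if not cp.read(path):
            raise ConfigError(f"config file not found: {path}")

        def get(section, key, default=None):
            return cp.get(section, key, fallback=default)

        thresholds = get("network", "thresholds")
        kwargs = dict(
            out_dir=get("run", "out_dir", "cnvnet_out"),
            lrr=get("inputs", "lrr"),
            intensities=get("inputs", "intensities"),
            clusters=get("inputs", "clusters"),
            phenotype=get("inputs", "phenotype"),
            genotypes=get("inputs", "genotypes"),
            snp_gene_map=get("inputs", "snp_gene_map"),
            obo=get("inputs", "obo"),
            gaf=get("inputs", "gaf"),
            cv_folds=int(get("classify", "cv_folds", "10")),
            delta_grid=get("classify", "delta_grid", "auto"),
            n_grid=int(get("classify", "n_grid", "30")),
            s0_quantile=float(get("classify", "s0_quantile", "0.5")),
            null_reps=int(get("network", "null_reps", "500")),
            gene_sim_threshold=float(get("genes", "sim_threshold", "0.15")),
            enrichment_threshold=float(
                get("genes", "enrichment_threshold", "0.001")),
            epistasis_method=get("network", "epistasis_method", "wald"),
            seed=int(get("run", "seed", "0")),
        )
        if thresholds:
            kwargs["network_thresholds"] = tuple(
                float(v) for v in thresholds.replace(",", " ").split())
        return cls(**kwargs)


def _stage(name):
    """Decorator-free stage wrapper: re-raise with the stage name."""
    class _Ctx:
        def __enter__(self):
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            logger.info("stage %s: done", name)
            return False
    return _Ctx()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all configured stages; returns (and writes) the manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}, "counts": {}}

    # ---- stage: lrr ----
    with _stage("lrr"):
        if config.lrr:
            matrix = cio.read_lrr_tsv(config.lrr)
        else:
            intensities = cio.read_intensity_tsv(config.intensities)
            clusters = cio.read_clusters_tsv(config.clusters)
            phenotype = cio.read_phenotype_tsv(config.phenotype)
            matrix = build_lrr_matrix(intensities, clusters, phenotype)
            cio.write_lrr_tsv(matrix, out / "lrr.tsv")
            manifest["stages"]["lrr"] = {"out": "lrr.tsv"}
        manifest["counts"]["n_samples"] = matrix.n_samples
        manifest["counts"]["n_snps"] = matrix.n_features

    # ---- stage: classify ----
    with _stage("classify"):
        grid = None
        if config.delta_grid != "auto":
            grid = np.array([float(v) for v in
                             config.delta_grid.replace(",", " ").split()])
        curve = cross_validate(matrix, n_folds=config.cv_folds,
                               delta_grid=grid, seed=config.seed,
                               n_grid=config.n_grid,
                               s0_quantile=config.s0_quantile)
        pd.DataFrame({"delta": curve.delta_grid,
                      "accuracy": curve.accuracy,
                      "n_selected": curve.n_selected}).to_csv(
            out / "cv_curve.tsv", sep="\t", index=False,
            float_format="%.17g")
        fit = fit_centroids(matrix, s0_quantile=config.s0_quantile)
        sfit = shrink(fit, curve.best_delta)
        ranking = rank_features(sfit)
        _write_ranking(matrix, ranking, out / "ranking.tsv")
        selected = [snp for snp, _ in ranking]
        (out / "selected_snps.txt").write_text(
            "".join(f"{s}\n" for s in selected))
        manifest["stages"]["classify"] = {
            "best_delta": curve.best_delta,
            "peak_accuracy": float(curve.accuracy.max()),
            "out": ["cv_curve.tsv", "ranking.tsv", "selected_snps.txt"],
        }
        manifest["counts"]["n_selected_snps"] = len(selected)
        if not selected:
            manifest["stages"]["classify"]["note"] = "no SNPs selected"

    # ---- stage: epistasis ----
    tests = []
    if config.genotypes and len(selected) >= 2:
        with _stage("epistasis"):
            genotypes = cio.read_genotype_tsv(config.genotypes)
            testable = [s for s in selected if s in genotypes.snp_ids]
            manifest["counts"]["n_selected_with_genotypes"] = len(testable)
            if len(testable) >= 2:
                tests = pairwise_epistasis(genotypes, testable,
                                           method=config.epistasis_method)
                cio.write_epistasis_tsv(tests, out / "epistasis.tsv")
                manifest["stages"]["epistasis"] = {
                    "n_pairs": len(tests),
                    "n_degenerate": sum(not t.available for t in tests),
                    "out": "epistasis.tsv",
                }

    # ---- stage: snp networks ----
    if tests:
        with _stage("snp_network"):
            lookup = PLookup.from_tests(tests)
            pool = sorted({t.snp_a for t in tests} | {t.snp_b for t in tests})
            summaries, sig_rows, all_edges = [], [], []
            for thr in config.network_thresholds:
                comps = build_interaction_graph(tests, thr)
                summaries.append(summarize_networks(comps, thr))
                for idx, comp in enumerate(comps, 1):
                    obs = mean_pairwise_p(comp.member_snps, lookup)
                    if not obs.available:
                        continue
                    null = random_network_null(pool, comp.size,
                                               config.null_reps,
                                               config.seed, lookup)
                    sig = network_significance(obs.mean, null.mean, null.sd,
                                               null.samples)
                    sig_rows.append({
                        "threshold": thr, "network": idx, "size": comp.size,
                        "selected_mean": obs.mean, "random_mean": null.mean,
                        "random_sd": null.sd,
                        "significance": sig.significance,
                        "empirical_p": sig.empirical_p,
                    })
                all_edges.extend(
                    (t.snp_a, t.snp_b) for t in tests
                    if t.available and t.p_value < thr)
            cio.write_network_summary_tsv(summaries,
                                          out / "snp_network_summary.tsv")
            cio.write_significance_tsv(sig_rows,
                                       out / "snp_network_significance.tsv")
            cio.write_edge_list_tsv(tests, max(config.network_thresholds),
                                    out / "snp_edges.tsv")
            cio.write_sif(sorted(set(all_edges)), out / "snp_network.sif")
            manifest["stages"]["snp_network"] = {
                "thresholds": list(config.network_thresholds),
                "null_reps": config.null_reps,
                "out": ["snp_network_summary.tsv",
                        "snp_network_significance.tsv", "snp_edges.tsv",
                        "snp_network.sif"],
            }

    # ---- stage: genes ----
    genes: list[str] = []
    if config.snp_gene_map and selected:
        with _stage("gene_map"):
            mapping = cio.read_snp_gene_map(config.snp_gene_map)
            genes = sorted({
                mapping[s] for s in selected
                if mapping.get(s, "intergenic") != "intergenic"})
            manifest["counts"]["n_genic_selected_snps"] = sum(
                1 for s in selected
                if mapping.get(s, "intergenic") != "intergenic")
            manifest["counts"]["n_unique_genes"] = len(genes)
            (out / "selected_genes.txt").write_text(
                "".join(f"{g}\n" for g in genes))
            manifest["stages"]["gene_map"] = {"out": "selected_genes.txt"}

    # ---- stage: gene networks + enrichment ----
    if config.obo and config.gaf and len(genes) >= 2:
        with _stage("gene_network"):
            dag = OntologyDAG.from_obo(config.obo)
            corpus = AnnotationCorpus.from_gaf(config.gaf)
            tic = term_ic(dag, corpus)
            annotated = [g for g in genes if g in corpus.annotations]
            manifest["counts"]["n_annotated_genes"] = len(annotated)
            sims = gene_sim_matrix(annotated, dag, tic, corpus)
            cio.write_gene_sim_tsv(sims, out / "gene_similarity.tsv")
            net = gene_network(sims, config.gene_sim_threshold)
            cio.write_sif([(a, b) for (a, b), s in sorted(sims.items())
                           if s > config.gene_sim_threshold],
                          out / "gene_network.sif")
            manifest["stages"]["gene_network"] = {
                "threshold": config.gene_sim_threshold,
                "n_networks": net.n_networks,
                "n_pairs": net.n_pairs,
                "genes": list(net.genes),
                "out": ["gene_similarity.tsv", "gene_network.sif"],
            }

        query = list(net.genes)
        if query:
            with _stage("enrichment"):
                background = sorted(corpus.annotations)
                results = enrich(query, background, dag, corpus,
                                 p_threshold=config.enrichment_threshold)
                pd.DataFrame([{
                    "category": r.namespace, "term": r.term,
                    "q": r.q, "m": r.m, "t": r.t, "k": r.k,
                    "genes": ",".join(r.annotated_query_genes),
                    "p_value": r.p_value,
                } for r in results]).to_csv(out / "enrichment.tsv", sep="\t",
                                            index=False,
                                            float_format="%.17g")
                manifest["stages"]["enrichment"] = {
                    "p_threshold": config.enrichment_threshold,
                    "n_significant": len(results),
                    "out": "enrichment.tsv",
                }

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def _write_ranking(matrix, ranking, path) -> None:
    """Ranking table: snp_id, score, per-class mean and variance."""
    classes = np.unique(matrix.labels)
    rows = []
    idx = {f: j for j, f in enumerate(matrix.feature_ids)}
    for snp, score in ranking:
        row = {"snp_id": snp, "score": score}
        for c in classes:
            vals = matrix.values[matrix.labels == c, idx[snp]]
            name = {1: "control", 2: "case"}.get(int(c), f"class{c}")
            row[f"{name}_mean"] = float(vals.mean())
            row[f"{name}_variance"] = float(vals.var(ddof=1))
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False,
                              float_format="%.17g")
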