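"""Plain-text readers and writers for every file dialect the package uses.

All tabular files are TSV with a header row.  Phenotype codes are
1 = control, 2 = case throughout.  Floating-point values are written with
``repr``-level precision so write/read round trips are lossless.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from ._errors import DataError
from .epistasis import EpistasisTest, GenotypeMatrix
from .gosim import AnnotationCorpus, OntologyDAG
from .lrr import CLUSTER_COLUMNS, ClusterModel, LRRMatrix

__all__ = [
    "read_intensity_tsv", "write_intensity_tsv",
    "read_clusters_tsv", "write_clusters_tsv",
    "read_phenotype_tsv", "write_phenotype_tsv",
    "read_lrr_tsv", "write_lrr_tsv",
    "read_genotype_tsv", "write_genotype_tsv",
    "read_ped_map",
    "write_epistasis_tsv", "read_epistasis_tsv",
    "write_edge_list_tsv", "write_sif",
    "write_network_summary_tsv", "write_significance_tsv",
    "read_gene_list", "read_snp_gene_map", "write_snp_gene_map",
    "write_obo", "write_gaf",
    "write_truth_json", "read_truth_json",
    "write_gene_sim_tsv", "read_gene_sim_tsv",
]

_FLOAT_FMT = "%.17g"


def _to_path(path) -> Path:
    return Path(path)


# -- intensities --------------------------------------------------------

def write_intensity_tsv(intensities: pd.DataFrame, path) -> Path:
    """Long-form intensity table: sample_id, snp_id, X, Y."""
    path = _to_path(path)
    intensities[["sample_id", "snp_id", "X", "Y"]].to_csv(
        path, sep="\t", index=False, float_format=_FLOAT_FMT)
    return path


def read_intensity_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "snp_id", "X", "Y"}
    if not required.issubset(df.columns):
        raise DataError(f"intensity TSV needs columns {sorted(required)}")
    return df


# -- canonical clusters -------------------------------------------------

def write_clusters_tsv(clusters: ClusterModel, path) -> Path:
    path = _to_path(path)
    clusters.table.to_csv(path, sep="\t", index_label="snp_id",
                          float_format=_FLOAT_FMT)
    return path


def read_clusters_tsv(path) -> ClusterModel:
    df = pd.read_csv(path, sep="\t", index_col="snp_id")
    missing = [c for c in CLUSTER_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"cluster TSV missing columns: {missing}")
    return ClusterModel(df[CLUSTER_COLUMNS])


# -- phenotype ----------------------------------------------------------

def write_phenotype_tsv(sample_ids, phenotype, path) -> Path:
    path = _to_path(path)
    pd.DataFrame({"sample_id": sample_ids,
                  "phenotype": np.asarray(phenotype, int)}).to_csv(
        path, sep="\t", index=False)
    return path


def read_phenotype_tsv(path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t")
    if not {"sample_id", "phenotype"}.issubset(df.columns):
        raise DataError("phenotype TSV needs columns sample_id, phenotype")
    return dict(zip(df["sample_id"], df["phenotype"].astype(int)))


# -- LRR matrix ---------------------------------------------------------

def write_lrr_tsv(matrix: LRRMatrix, path) -> Path:
    """sample_id, phenotype, then one LRR column per SNP."""
    path = _to_path(path)
    df = pd.DataFrame(matrix.values, columns=matrix.feature_ids)
    df.insert(0, "phenotype", matrix.labels)
    df.insert(0, "sample_id", matrix.sample_ids)
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
    return path


def read_lrr_tsv(path) -> LRRMatrix:
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "sample_id" or df.columns[1] != "phenotype":
        raise DataError(
            "LRR TSV must start with columns sample_id, phenotype")
    values = df.iloc[:, 2:].to_numpy(float)
    if np.isnan(values).any():
        raise DataError("LRR matrix contains missing values")
    return LRRMatrix(values=values,
                     labels=df["phenotype"].to_numpy(int),
                     sample_ids=df["sample_id"].astype(str).tolist(),
                     feature_ids=list(df.columns[2:]))


# -- genotypes ----------------------------------------------------------

def write_genotype_tsv(dosages, phenotype, sample_ids, snp_ids, path) -> Path:
    """sample_id, phenotype, then one dosage column per SNP (NA = missing)."""
    path = _to_path(path)
    dosages = np.asarray(dosages, float)
    df = pd.DataFrame(dosages, columns=snp_ids)
    # Integral dosages; keep NA cells empty-free as literal "NA".
    df = df.map(lambda v: "NA" if np.isnan(v) else str(int(v)))
    df.insert(0, "phenotype", np.asarray(phenotype, int))
    df.insert(0, "sample_id", sample_ids)
    df.to_csv(path, sep="\t", index=False)
    return path


def read_genotype_tsv(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    if df.columns[0] != "sample_id" or df.columns[1] != "phenotype":
        raise DataError(
            "genotype TSV must start with columns sample_id, phenotype")
    return GenotypeMatrix(
        dosages=df.iloc[:, 2:].to_numpy(float),
        phenotype=df["phenotype"].to_numpy(int),
        snp_ids=list(df.columns[2:]),
        sample_ids=df["sample_id"].astype(str).tolist(),
    )


def read_ped_map(ped_path, map_path) -> GenotypeMatrix:
    """Minimal PED/MAP text reader.

    MAP: chrom, snp_id, genetic distance, position (1-based), one SNP per
    line.  PED: FID IID PAT MAT SEX PHENOTYPE then two allele columns per
    SNP ('0' = missing).  Dosage counts the sample minor allele per SNP;
    phenotype uses the 1 = control / 2 = case convention.
    """
    snp_ids = []
    with open(map_path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) < 4:
                raise DataError("MAP lines need 4 columns")
            snp_ids.append(parts[1])

    sample_ids, phenotype, allele_rows = [], [], []
    with open(ped_path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * len(snp_ids):
                raise DataError(
                    f"PED line for {parts[1] if len(parts) > 1 else '?'} has "
                    f"{len(parts)} fields, expected {6 + 2 * len(snp_ids)}")
            sample_ids.append(parts[1])
            phenotype.append(int(parts[5]))
            allele_rows.append(parts[6:])

    n, p = len(sample_ids), len(snp_ids)
    dosages = np.full((n, p), np.nan)
    for j in range(p):
        a1 = [row[2 * j] for row in allele_rows]
        a2 = [row[2 * j + 1] for row in allele_rows]
        observed = [a for a in a1 + a2 if a != "0"]
        if not observed:
            continue
        alleles, counts = np.unique(observed, return_counts=True)
        minor = alleles[np.argmin(counts)] if len(alleles) > 1 else alleles[0]
        for i in range(n):
            if a1[i] == "0" or a2[i] == "0":
                continue
            dosages[i, j] = (a1[i] == minor) + (a2[i] == minor)
    return GenotypeMatrix(dosages=dosages, phenotype=np.array(phenotype),
                          snp_ids=snp_ids, sample_ids=sample_ids)


# -- epistasis report ---------------------------------------------------

def write_epistasis_tsv(tests: list[EpistasisTest], path) -> Path:
    """Interaction report: SNP1, SNP2, OR_INT, CHISQ, P (+ N, STATUS)."""
    path = _to_path(path)
    pd.DataFrame([{
        "SNP1": t.snp_a, "SNP2": t.snp_b, "OR_INT": t.odds_ratio,
        "CHISQ": t.chi2, "P": t.p_value, "N": t.n_used, "STATUS": t.status,
    } for t in tests]).to_csv(path, sep="\t", index=False,
                              float_format=_FLOAT_FMT)
    return path


def read_epistasis_tsv(path) -> list[EpistasisTest]:
    df = pd.read_csv(path, sep="\t")
    required = {"SNP1", "SNP2", "OR_INT", "CHISQ", "P"}
    if not required.issubset(df.columns):
        raise DataError(f"epistasis TSV needs columns {sorted(required)}")
    tests = []
    for row in df.itertuples(index=False):
        status = getattr(row, "STATUS", "converged")
        orr = float(row.OR_INT)
        tests.append(EpistasisTest(
            snp_a=str(row.SNP1), snp_b=str(row.SNP2),
            b3=float(np.log(orr)) if orr > 0 else np.nan,
            odds_ratio=orr, chi2=float(row.CHISQ), p_value=float(row.P),
            n_used=int(getattr(row, "N", 0)), status=str(status)))
    return tests


# -- network exports ----------------------------------------------------

def write_edge_list_tsv(tests: list[EpistasisTest], threshold: float,
                        path) -> Path:
    """Edges (snp_a, snp_b, p_value) with P < threshold."""
    path = _to_path(path)
    rows = [{"snp_a": t.snp_a, "snp_b": t.snp_b, "p_value": t.p_value}
            for t in tests if t.available and t.p_value < threshold]
    pd.DataFrame(rows, columns=["snp_a", "snp_b", "p_value"]).to_csv(
        path, sep="\t", index=False, float_format=_FLOAT_FMT)
    return path


def write_sif(edges: list[tuple[str, str]], path,
              relation: str = "pp") -> Path:
    """Cytoscape SIF export: "<a> pp <b>" per edge."""
    path = _to_path(path)
    with open(path, "w") as fh:
        for a, b in edges:
            fh.write(f"{a}\t{relation}\t{b}\n")
    return path


def write_network_summary_tsv(summaries, path) -> Path:
    """Per-threshold network counts in the "k(count)" convention."""
    path = _to_path(path)
    rows = []
    for s in summaries:
        snps, pairs = s.format_counts()
        rows.append({"threshold": s.threshold, "n_networks": s.n_networks,
                     "snps": snps, "snp_pairs": pairs})
    pd.DataFrame(rows, columns=["threshold", "n_networks", "snps",
                                "snp_pairs"]).to_csv(path, sep="\t",
                                                     index=False)
    return path


def write_significance_tsv(rows, path) -> Path:
    """Threshold/network significance table (mirrors the selected-vs-random
    comparison): threshold, network, size, selected_mean, random_mean,
    random_sd, significance, empirical_p."""
    path = _to_path(path)
    pd.DataFrame(rows, columns=[
        "threshold", "network", "size", "selected_mean", "random_mean",
        "random_sd", "significance", "empirical_p",
    ]).to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
    return path


# -- gene-level files ---------------------------------------------------

def read_gene_list(path) -> list[str]:
    """One gene id per line; blank lines and #-comments skipped."""
    genes = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                genes.append(line)
    return genes


def read_snp_gene_map(path) -> dict[str, str]:
    """Two columns snp_id, gene; gene "intergenic" marks unmapped SNPs."""
    df = pd.read_csv(path, sep="\t")
    if not {"snp_id", "gene"}.issubset(df.columns):
        raise DataError("SNP-gene map needs columns snp_id, gene")
    return dict(zip(df["snp_id"].astype(str), df["gene"].astype(str)))


def write_snp_gene_map(mapping: dict[str, str], path) -> Path:
    path = _to_path(path)
    pd.DataFrame(sorted(mapping.items()),
                 columns=["snp_id", "gene"]).to_csv(path, sep="\t",
                                                    index=False)
    return path


def write_gene_sim_tsv(similarities: dict[tuple[str, str], float],
                       path) -> Path:
    path = _to_path(path)
    rows = [{"gene_a": a, "gene_b": b, "similarity": s}
            for (a, b), s in sorted(similarities.items())]
    pd.DataFrame(rows, columns=["gene_a", "gene_b", "similarity"]).to_csv(
        path, sep="\t", index=False, float_format=_FLOAT_FMT)
    return path


def read_gene_sim_tsv(path) -> dict[tuple[str, str], float]:
    df = pd.read_csv(path, sep="\t")
    return {(str(r.gene_a), str(r.gene_b)): float(r.similarity)
            for r in df.itertuples(index=False)}


# -- ontology / annotations --------------------------------------------

def write_obo(dag: OntologyDAG, term_names: dict[str, str], path) -> Path:
    """Minimal OBO 1.2 writer (round-trips through obonet)."""
    path = _to_path(path)
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\nontology: go\n")
        for term in sorted(dag.namespace):
            fh.write("\n[Term]\n")
            fh.write(f"id: {term}\n")
            fh.write(f"name: {term_names.get(term, term)}\n")
            fh.write(f"namespace: {dag.namespace[term]}\n")
            for parent in sorted(dag.parents.get(term, ())):
                fh.write(f"is_a: {parent} ! {term_names.get(parent, parent)}\n")
    return path


def write_gaf(corpus: AnnotationCorpus, dag: OntologyDAG, path,
              evidence: str = "IEA") -> Path:
    """Minimal GAF 2.1 writer (columns 2/5/7/9 meaningful)."""
    ns_to_aspect = {"molecular_function": "F", "biological_process": "P",
                    "cellular_component": "C"}
    path = _to_path(path)
    with open(path, "w") as fh:
        fh.write("!gaf-version: 2.1\n")
        for gene in sorted(corpus.annotations):
            for term in sorted(corpus.annotations[gene]):
                aspect = ns_to_aspect[dag.namespace[term]]
                cols = ["CNVNET", gene, gene, "", term, "CNVNET:0000001",
                        evidence, "", aspect, gene, "", "gene_product",
                        "taxon:9606", "20110101", "CNVNET", "", ""]
                fh.write("\t".join(cols) + "\n")
    return path


# -- truth --------------------------------------------------------------

def write_truth_json(truth, path) -> Path:
    path = _to_path(path)
    with open(path, "w") as fh:
        json.dump({"relevant_snps": list(truth.relevant_snps),
                   "epistatic_pairs": [list(p)
                                       for p in truth.epistatic_pairs]},
                  fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path


def read_truth_json(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
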