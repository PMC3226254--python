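import numpy as np
import pandas as pd
import pytest

from cnvnet import (AnnotationCorpus, CohortConfig, ClusterModel,
                    OntologyDAG, simulate_cohort)


@pytest.fixture
def simple_clusters() -> ClusterModel:
    """One well-behaved SNP with asymmetric cluster intensities."""
    return ClusterModel(pd.DataFrame(
        {"theta_AA": [0.05], "R_AA": [1.8], "theta_AB": [0.5],
         "R_AB": [2.0], "theta_BB": [0.95], "R_BB": [2.2]},
        index=pd.Index(["rs1"], name="snp_id")))


@pytest.fixture(scope="session")
def strong_cohort():
    """Planted-signal cohort: shift/noise = 2, the classifier's test bed."""
    return simulate_cohort(CohortConfig(
        n_cases=100, n_controls=100, n_snps=300, n_relevant=10,
        lrr_shift=0.3, lrr_noise_sd=0.15, seed=11))


@pytest.fixture(scope="session")
def null_cohort():
    """No planted signal at all: shift 0, no epistasis."""
    return simulate_cohort(CohortConfig(
        n_cases=60, n_controls=60, n_snps=80, n_relevant=0,
        lrr_shift=0.0, lrr_noise_sd=0.15, seed=5))


def _toy_terms():
    r"""Two-namespace toy ontology.

    molecular_function:          biological_process:
        MF:root                      BP:root
        /      \                       |
      MF:a     MF:b                  BP:a
      /   \    /                       |
    MF:a1  MF:ab  (MF:ab under both)  BP:a1
    """
    parents = {
        "MF:root": set(),
        "MF:a": {"MF:root"},
        "MF:b": {"MF:root"},
        "MF:a1": {"MF:a"},
        "MF:ab": {"MF:a", "MF:b"},
        "BP:root": set(),
        "BP:a": {"BP:root"},
        "BP:a1": {"BP:a"},
    }
    namespace = {t: ("molecular_function" if t.startswith("MF")
                     else "biological_process") for t in parents}
    return parents, namespace


@pytest.fixture
def toy_dag() -> OntologyDAG:
    return OntologyDAG(*_toy_terms())


@pytest.fixture
def toy_corpus() -> AnnotationCorpus:
    """Ten genes with hand-placed annotations over the toy DAG.

    Propagated per-term gene counts (MF namespace, 10 annotated genes):
      MF:a1 -> g1, g2          (p = 0.2)
      MF:ab -> g2, g3          (p = 0.2)
      MF:a  -> g1..g4          (p = 0.4)
      MF:b  -> g2, g3, g5      (p = 0.3)
      MF:root -> all 10        (p = 1.0)
    """
    annotations = {
        "g1": {"MF:a1", "BP:a1"},
        "g2": {"MF:a1", "MF:ab"},
        "g3": {"MF:ab", "BP:a"},
        "g4": {"MF:a", "BP:a1"},
        "g5": {"MF:b"},
        "g6": {"MF:root", "BP:root"},
        "g7": {"MF:root"},
        "g8": {"MF:root", "BP:a"},
        "g9": {"MF:root"},
        "g10": {"MF:root"},
    }
    return AnnotationCorpus(annotations={g: frozenset(t)
                                         for g, t in annotations.items()})


@pytest.fixture
def toy_lrr_frame():
    """4-sample, 2-feature matrix with hand-checkable statistics."""
    from cnvnet import LRRMatrix

    values = np.array([[0.0, 1.0],
                       [0.0, 3.0],
                       [1.0, 2.0],
                       [1.0, 0.0]])
    return LRRMatrix(values=values, labels=np.array([1, 1, 2, 2]),
                     sample_ids=["a", "b", "c", "d"],
                     feature_ids=["f1", "f2"])
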