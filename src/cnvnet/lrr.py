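"""Log R Ratio (LRR) computation from normalized allele intensities.

A SNP array reports, for every marker, a pair of normalized intensities
``(X, Y)`` for the two alleles.  Total intensity ``R = X + Y`` tracks DNA
copy number: a diploid locus yields an R close to the canonical value for
its genotype cluster, a deletion or duplication scales R down or up.  The
Log R Ratio normalizes the observed R against the R *expected* for the
sample's position along the allelic axis,

    LRR = log2(R_observed / R_expected),

where R_expected is read off a piecewise-linear interpolation of the
per-SNP canonical genotype cluster centers (AA, AB, BB) in polar
coordinates (theta, R).  For normal diploid genotypes LRR fluctuates
around zero; systematic shifts indicate copy-number change.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._errors import DataError, ModelError

__all__ = [
    "ClusterModel",
    "LRRMatrix",
    "polar_transform",
    "expected_r",
    "compute_lrr",
    "build_lrr_matrix",
]

#: Column order of the canonical-cluster table.
CLUSTER_COLUMNS = ["theta_AA", "R_AA", "theta_AB", "R_AB", "theta_BB", "R_BB"]


@dataclass(frozen=True)
class ClusterModel:
    """Per-SNP canonical genotype cluster centers in polar coordinates.

    ``table`` is indexed by SNP id with columns ``theta_AA, R_AA, theta_AB,
    R_AB, theta_BB, R_BB``.  Thetas must be strictly increasing AA < AB < BB
    within [0, 1] and every R strictly positive.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in CLUSTER_COLUMNS if c not in self.table.columns]
        if missing:
            raise ModelError(f"cluster table missing columns: {missing}")
        t = self.table
        thetas = t[["theta_AA", "theta_AB", "theta_BB"]].to_numpy(float)
        rs = t[["R_AA", "R_AB", "R_BB"]].to_numpy(float)
        bad = ~(np.diff(thetas, axis=1) > 0).all(axis=1)
        if bad.any():
            snp = t.index[bad][0]
            raise ModelError(f"non-monotone cluster thetas for SNP {snp!r}")
        if (thetas < 0).any() or (thetas > 1).any():
            raise ModelError("cluster thetas must lie in [0, 1]")
        if (rs <= 0).any():
            snp = t.index[(rs <= 0).any(axis=1)][0]
            raise ModelError(f"non-positive cluster R for SNP {snp!r}")

    @property
    def snp_ids(self) -> list[str]:
        return list(self.table.index)

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self.table.index

    def knots(self, snp_id: str) -> tuple[np.ndarray, np.ndarray]:
        """(thetas, Rs) of the three cluster centers for one SNP."""
        try:
            row = self.table.loc[snp_id]
        except KeyError:
            raise DataError(f"no cluster entry for SNP {snp_id!r}") from None
        thetas = row[["theta_AA", "theta_AB", "theta_BB"]].to_numpy(float)
        rs = row[["R_AA", "R_AB", "R_BB"]].to_numpy(float)
        return thetas, rs


@dataclass
class LRRMatrix:
    """Samples x SNPs matrix of LRR values with case/control labels.

    ``labels`` follow the file convention 1 = control, 2 = case, but any
    set of >= 1 integer class codes is accepted (the classifier is K-class).
    """

    values: np.ndarray  # (n, p) float
    labels: np.ndarray  # (n,) int class codes
    sample_ids: list[str]
    feature_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.values.ndim != 2:
            raise DataError("LRR values must be a 2-D samples x SNPs array")
        n, p = self.values.shape
        if len(self.labels) != n or len(self.sample_ids) != n:
            raise DataError("labels/sample_ids length must match the sample count")
        if not self.feature_ids:
            self.feature_ids = [f"snp{i}" for i in range(p)]
        if len(self.feature_ids) != p:
            raise DataError("feature_ids length must match the SNP count")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def validate_for_fit(self) -> None:
        """Classifier preconditions: finite values, p >= 1, >= 2 samples/class."""
        if self.n_features < 1:
            raise DataError("at least one feature required")
        if not np.isfinite(self.values).all():
            raise DataError("LRR matrix contains missing or non-finite values")
        _, counts = np.unique(self.labels, return_counts=True)
        if (counts < 2).any():
            small = np.unique(self.labels)[counts < 2][0]
            raise DataError(f"class {small} has fewer than 2 samples")


def polar_transform(x, y):
    """Map allele intensities (X, Y) to polar coordinates (theta, R).

    R = X + Y; theta = (2/pi) * arctan(Y/X), so theta is 0 for a pure-A
    signal and 1 for a pure-B signal.  Accepts scalars or arrays.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if (x < 0).any() or (y < 0).any():
        raise DataError("intensities must be non-negative")
    r = x + y
    if (r <= 0).any():
        raise DataError("degenerate intensity: X + Y must be positive")
    theta = (2.0 / np.pi) * np.arctan2(y, x)
    if theta.ndim == 0:
        return float(theta), float(r)
    return theta, r


def expected_r(theta, thetas: np.ndarray, rs: np.ndarray):
    """Expected total intensity at ``theta`` for one SNP's cluster centers.

    Piecewise-linear interpolation of R against theta through the AA/AB/BB
    knots; theta outside [theta_AA, theta_BB] is clamped to the nearest
    knot (no extrapolation, which could go negative).
    """
    thetas = np.asarray(thetas, dtype=float)
    rs = np.asarray(rs, dtype=float)
    if thetas.shape != (3,) or rs.shape != (3,):
        raise ModelError("cluster entry must have exactly three (theta, R) knots")
    if not (np.diff(thetas) > 0).all():
        raise ModelError("cluster thetas must be strictly increasing")
    if (rs <= 0).any():
        raise ModelError("cluster R values must be positive")
    out = np.interp(theta, thetas, rs)  # np.interp clamps outside the knots
    return float(out) if np.ndim(theta) == 0 else out


def compute_lrr(r_observed, r_expected):
    """LRR = log2(R_observed / R_expected); both inputs strictly positive."""
    r_observed = np.asarray(r_observed, dtype=float)
    r_expected = np.asarray(r_expected, dtype=float)
    if (r_observed <= 0).any() or (r_expected <= 0).any():
        raise DataError("R_observed and R_expected must be strictly positive")
    out = np.log2(r_observed / r_expected)
    return float(out) if out.ndim == 0 else out


def build_lrr_matrix(
    intensities: pd.DataFrame,
    clusters: ClusterModel,
    phenotype: dict[str, int] | pd.Series,
) -> LRRMatrix:
    """Assemble the samples x SNPs LRR matrix from long-form intensities.

    Parameters
    ----------
    intensities
        Long-form table with columns ``sample_id, snp_id, X, Y``.
    clusters
        Canonical cluster model; every SNP in ``intensities`` must have an
        entry (a missing one is reported with its SNP id).
    phenotype
        Mapping sample_id -> class label (1 = control, 2 = case).

    SNP order follows first appearance in the input; sample order likewise.
    """
    required = {"sample_id", "snp_id", "X", "Y"}
    if not required.issubset(intensities.columns):
        raise DataError(f"intensity table needs columns {sorted(required)}")
    snp_ids = list(pd.unique(intensities["snp_id"]))
    sample_ids = list(pd.unique(intensities["sample_id"]))
    for snp in snp_ids:
        if snp not in clusters:
            raise DataError(f"no cluster entry for SNP {snp!r}")

    wide_x = intensities.pivot(index="sample_id", columns="snp_id", values="X")
    wide_y = intensities.pivot(index="sample_id", columns="snp_id", values="Y")
    wide_x = wide_x.reindex(index=sample_ids, columns=snp_ids)
    wide_y = wide_y.reindex(index=sample_ids, columns=snp_ids)
    if wide_x.isna().any().any() or wide_y.isna().any().any():
        raise DataError("intensity table is not a complete sample x SNP grid")

    n, p = len(sample_ids), len(snp_ids)
    values = np.empty((n, p), dtype=float)
    if p:
        theta, r_obs = polar_transform(wide_x.to_numpy(), wide_y.to_numpy())
        for j, snp in enumerate(snp_ids):
            knots_t, knots_r = clusters.knots(snp)
            r_exp = expected_r(theta[:, j], knots_t, knots_r)
            values[:, j] = compute_lrr(r_obs[:, j], r_exp)

    pheno = pd.Series(phenotype)
    missing = [s for s in sample_ids if s not in pheno.index]
    if missing:
        raise DataError(f"no phenotype for sample {missing[0]!r}")
    labels = pheno.loc[sample_ids].to_numpy(int)
    return LRRMatrix(values=values, labels=labels, sample_ids=sample_ids,
                     feature_ids=snp_ids)
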