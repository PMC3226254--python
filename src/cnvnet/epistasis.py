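"""Pairwise SNP-SNP interaction (epistasis) testing.

For a SNP pair with allele dosages A and B (0/1/2 copies of the minor
allele) and binary case/control outcome Y, fit the logistic model

    logit P(Y = case) = b0 + b1*A + b2*B + b3*(A*B)

by iteratively reweighted least squares (IRLS).  The interaction test is
on b3: the Wald statistic (b3 / SE(b3))^2 is referred to a chi-square
distribution with 1 degree of freedom, and exp(b3) is the interaction odds
ratio (1.0 = no interaction).  A likelihood-ratio variant refits the model
without the product term.  Pairs whose design is rank-deficient (e.g. a
constant product column) or whose fit diverges are marked degenerate and
excluded from downstream network construction.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2

from ._errors import DataError

__all__ = [
    "GenotypeMatrix",
    "LogisticFit",
    "EpistasisTest",
    "fit_logistic_interaction",
    "interaction_test",
    "test_pair",
    "minor_allele_dosage",
    "pairwise_epistasis",
]

MAX_ITER = 50
LOGLIK_RTOL = 1e-10
#: |coefficient| beyond this is treated as quasi-separation.
SEPARATION_BOUND = 15.0


@dataclass
class GenotypeMatrix:
    """Samples x SNPs allele-dosage matrix with case/control phenotype.

    Dosages are 0/1/2 (NaN for missing); phenotype codes 1 = control,
    2 = case.
    """

    dosages: np.ndarray       # (n, p) float, NaN = missing
    phenotype: np.ndarray     # (n,) in {1, 2}
    snp_ids: list[str]
    sample_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.phenotype = np.asarray(self.phenotype, dtype=int)
        n, p = self.dosages.shape
        if len(self.phenotype) != n:
            raise DataError("phenotype length must match the sample count")
        if len(self.snp_ids) != p:
            raise DataError("snp_ids length must match the SNP count")
        observed = self.dosages[~np.isnan(self.dosages)]
        if not np.isin(observed, (0.0, 1.0, 2.0)).all():
            raise DataError("dosages must be 0, 1, 2 or missing")
        if set(np.unique(self.phenotype)) - {1, 2}:
            raise DataError("phenotype codes must be 1 (control) or 2 (case)")
        if len(np.unique(self.phenotype)) < 2:
            raise DataError("phenotype must contain both cases and controls")

    @property
    def y(self) -> np.ndarray:
        """Binary outcome: 1 for cases, 0 for controls."""
        return (self.phenotype == 2).astype(float)

    def column(self, snp_id: str) -> np.ndarray:
        try:
            j = self.snp_ids.index(snp_id)
        except ValueError:
            raise DataError(f"unknown SNP {snp_id!r}") from None
        return self.dosages[:, j]


@dataclass(frozen=True)
class LogisticFit:
    """Result of one IRLS fit of the four-parameter interaction model."""

    coef: np.ndarray | None       # (4,): b0, b1, b2, b3
    cov: np.ndarray | None        # (4, 4) inverse observed information
    loglik: float
    n_used: int
    status: str                   # "converged" | "degenerate"
    n_iter: int = 0


@dataclass(frozen=True)
class EpistasisTest:
    """One SNP pair's interaction coefficient, odds ratio and chi-square test."""

    snp_a: str
    snp_b: str
    b3: float
    odds_ratio: float
    chi2: float
    p_value: float
    n_used: int
    status: str  # "converged" | "degenerate"

    @property
    def available(self) -> bool:
        return self.status == "converged"


def _loglik(y: np.ndarray, eta: np.ndarray) -> float:
    # log L = sum y*eta - log(1 + e^eta), stable via logaddexp
    return float((y * eta - np.logaddexp(0.0, eta)).sum())


def fit_logistic_interaction(y, a, b) -> LogisticFit:
    """Maximum-likelihood fit of logit(P) = b0 + b1*A + b2*B + b3*A*B.

    Inputs must be complete cases (no NaN).  Returns a degenerate fit
    (without a usable test) when the outcome does not vary, the design is
    rank-deficient, the iteration fails to converge within ``MAX_ITER``
    steps, or a coefficient runs away (quasi-separation).
    """
    y = np.asarray(y, dtype=float)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n = len(y)
    if len(a) != n or len(b) != n:
        raise DataError("y, a, b must have equal length")
    if np.isnan(y).any() or np.isnan(a).any() or np.isnan(b).any():
        raise DataError("complete cases required: remove missing values first")
    if n < 5:
        raise DataError(f"need at least 5 complete cases, got {n}")

    x = np.column_stack([np.ones(n), a, b, a * b])
    if len(np.unique(y)) < 2 or np.linalg.matrix_rank(x) < 4:
        return LogisticFit(coef=None, cov=None, loglik=np.nan, n_used=n,
                           status="degenerate")

    beta = np.zeros(4)
    ll_old = _loglik(y, x @ beta)
    for it in range(1, MAX_ITER + 1):
        eta = x @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        w = p * (1.0 - p)
        xtwx = (x * w[:, None]).T @ x
        grad = x.T @ (y - p)
        try:
            step = np.linalg.solve(xtwx, grad)
        except np.linalg.LinAlgError:
            return LogisticFit(coef=None, cov=None, loglik=np.nan, n_used=n,
                               status="degenerate", n_iter=it)
        beta = beta + step
        if np.abs(beta).max() > SEPARATION_BOUND:
            return LogisticFit(coef=None, cov=None, loglik=np.nan, n_used=n,
                               status="degenerate", n_iter=it)
        ll = _loglik(y, x @ beta)
        if abs(ll - ll_old) <= LOGLIK_RTOL * (abs(ll_old) + 1.0):
            eta = x @ beta
            p = 1.0 / (1.0 + np.exp(-eta))
            w = p * (1.0 - p)
            xtwx = (x * w[:, None]).T @ x
            try:
                cov = np.linalg.inv(xtwx)
            except np.linalg.LinAlgError:
                return LogisticFit(coef=None, cov=None, loglik=np.nan,
                                   n_used=n, status="degenerate", n_iter=it)
            return LogisticFit(coef=beta, cov=cov, loglik=ll, n_used=n,
                               status="converged", n_iter=it)
        ll_old = ll
    return LogisticFit(coef=None, cov=None, loglik=np.nan, n_used=n,
                       status="degenerate", n_iter=MAX_ITER)


def _fit_reduced(y, a, b) -> LogisticFit:
    """Fit without the product term, for the likelihood-ratio variant."""
    y = np.asarray(y, dtype=float)
    x = np.column_stack([np.ones(len(y)), np.asarray(a, float),
                         np.asarray(b, float)])
    if len(np.unique(y)) < 2 or np.linalg.matrix_rank(x) < 3:
        return LogisticFit(coef=None, cov=None, loglik=np.nan, n_used=len(y),
                           status="degenerate")
    beta = np.zeros(3)
    ll_old = _loglik(y, x @ beta)
    for it in range(1, MAX_ITER + 1):
        eta = x @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        w = p * (1.0 - p)
        try:
            beta = beta + np.linalg.solve((x * w[:, None]).T @ x, x.T @ (y - p))
        except np.linalg.LinAlgError:
            return LogisticFit(coef=None, cov=None, loglik=np.nan,
                               n_used=len(y), status="degenerate", n_iter=it)
        if np.abs(beta).max() > SEPARATION_BOUND:
            return LogisticFit(coef=None, cov=None, loglik=np.nan,
                               n_used=len(y), status="degenerate", n_iter=it)
        ll = _loglik(y, x @ beta)
        if abs(ll - ll_old) <= LOGLIK_RTOL * (abs(ll_old) + 1.0):
            return LogisticFit(coef=beta, cov=None, loglik=ll, n_used=len(y),
                               status="converged", n_iter=it)
        ll_old = ll
    return LogisticFit(coef=None, cov=None, loglik=np.nan, n_used=len(y),
                       status="degenerate", n_iter=MAX_ITER)


def interaction_test(
    fit: LogisticFit,
    snp_a: str = "A",
    snp_b: str = "B",
    reduced_loglik: float | None = None,
) -> EpistasisTest:
    """Chi-square test on the interaction coefficient b3.

    Default is the 1-df Wald statistic (b3/SE)^2; when ``reduced_loglik``
    (log-likelihood of the no-interaction model) is supplied, the 1-df
    likelihood-ratio statistic 2*(llfull - llreduced) is used instead.
    Degenerate fits yield a test marked unavailable.
    """
    if fit.status != "converged":
        return EpistasisTest(snp_a=snp_a, snp_b=snp_b, b3=np.nan,
                             odds_ratio=np.nan, chi2=np.nan, p_value=np.nan,
                             n_used=fit.n_used, status="degenerate")
    b3 = float(fit.coef[3])
    if reduced_loglik is None:
        se = float(np.sqrt(fit.cov[3, 3]))
        stat = (b3 / se) ** 2 if se > 0 else np.inf
    else:
        stat = max(2.0 * (fit.loglik - reduced_loglik), 0.0)
    p = float(chi2.sf(stat, df=1))
    return EpistasisTest(snp_a=snp_a, snp_b=snp_b, b3=b3,
                         odds_ratio=float(np.exp(b3)), chi2=float(stat),
                         p_value=p, n_used=fit.n_used, status="converged")


def minor_allele_dosage(dosage: np.ndarray) -> np.ndarray:
    """Recode so dosage counts the minor allele of the observed sample.

    If the mean observed dosage exceeds 1 (the coded allele is the major
    one), flip d -> 2 - d.  Missing values pass through.
    """
    observed = dosage[~np.isnan(dosage)]
    if observed.size and observed.mean() > 1.0:
        return np.where(np.isnan(dosage), np.nan, 2.0 - dosage)
    return dosage


def test_pair(y, a, b, snp_a="A", snp_b="B", method="wald") -> EpistasisTest:
    """Fit and test one complete-case pair."""
    fit = fit_logistic_interaction(y, a, b)
    if method == "wald" or fit.status != "converged":
        return interaction_test(fit, snp_a, snp_b)
    if method == "lrt":
        reduced = _fit_reduced(y, a, b)
        if reduced.status != "converged":
            return interaction_test(
                LogisticFit(coef=None, cov=None, loglik=np.nan,
                            n_used=fit.n_used, status="degenerate"),
                snp_a, snp_b)
        return interaction_test(fit, snp_a, snp_b,
                                reduced_loglik=reduced.loglik)
    raise DataError("method must be 'wald' or 'lrt'")


def pairwise_epistasis(
    genotypes: GenotypeMatrix,
    snp_subset: list[str] | None = None,
    method: str = "wald",
    recode_minor: bool = True,
) -> list[EpistasisTest]:
    """Interaction tests for every unique SNP pair in ``snp_subset``.

    Pairs are canonicalized lexicographically (snp_a < snp_b) and each is
    tested once, on its complete cases (samples missing either dosage are
    dropped pairwise; ``n_used`` records how many remain).  With
    ``recode_minor`` each SNP's dosage is flipped, if needed, to count the
    sample minor allele.
    """
    subset = list(genotypes.snp_ids) if snp_subset is None else list(snp_subset)
    unknown = [s for s in subset if s not in genotypes.snp_ids]
    if unknown:
        raise DataError(f"unknown SNP {unknown[0]!r}")
    if len(subset) < 2:
        raise DataError("need at least 2 SNPs for pairwise testing")

    cols: dict[str, np.ndarray] = {}
    for snp in subset:
        col = genotypes.column(snp)
        cols[snp] = minor_allele_dosage(col) if recode_minor else col

    y_all = genotypes.y
    tests = []
    for snp_a, snp_b in itertools.combinations(sorted(subset), 2):
        a, b = cols[snp_a], cols[snp_b]
        keep = ~(np.isnan(a) | np.isnan(b))
        n_used = int(keep.sum())
        if n_used < 5:
            tests.append(EpistasisTest(snp_a=snp_a, snp_b=snp_b, b3=np.nan,
                                       odds_ratio=np.nan, chi2=np.nan,
                                       p_value=np.nan, n_used=n_used,
                                       status="degenerate"))
            continue
        tests.append(test_pair(y_all[keep], a[keep], b[keep],
                               snp_a=snp_a, snp_b=snp_b, method=method))
    return tests
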