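"""Case-control association statistics and inverse-variance meta-analysis.

Implements the replication-cohort statistics used to validate a GWAS hit:
Hardy-Weinberg goodness of fit, allelic odds ratio with Woolf standard
error, covariate-adjusted logistic regression on allele dosage, and
fixed-effect inverse-variance-weighted (IVW) combination of per-cohort
log-odds ratios. Printed odds ratios with 95% confidence intervals can be
converted back to (log-OR, SE) pairs for meta-analysis of summary tables.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Z95",
    "AlleleTable",
    "AssocResult",
    "MetaResult",
    "hwe_test",
    "counts_from_maf",
    "allele_table_from_maf",
    "allelic_or",
    "logistic_assoc",
    "se_from_ci",
    "ivw_meta",
]

# z for a 95% CI; enough digits that CI -> SE -> CI round-trips printed values
Z95 = 1.959964


@dataclass
class AlleleTable:
    """2x2 allele-count table: minor/major alleles in cases and controls."""

    minor_cases: int
    major_cases: int
    minor_controls: int
    major_controls: int

    def __post_init__(self):
        counts = (self.minor_cases, self.major_cases, self.minor_controls, self.major_controls)
        if any(c < 0 for c in counts):
            raise ValueError("allele counts must be non-negative")
        if self.minor_cases + self.major_cases == 0 or self.minor_controls + self.major_controls == 0:
            raise ValueError("empty margin: a group has no alleles")


@dataclass
class AssocResult:
    beta: float          # log-OR
    se: float
    or_: float
    ci95: tuple
    p: float
    method: str          # "allelic" or "logistic"
    converged: bool = True


@dataclass
class MetaResult:
    studies: list        # of (beta_i, se_i, w_i)
    beta: float
    se: float
    or_: float
    ci95: tuple
    p: float
    q_stat: float        # Cochran's Q (reported, not used for random effects)
    i2: float


def hwe_test(genotype_counts) -> tuple:
    """Goodness-of-fit chi-square test for Hardy-Weinberg equilibrium.

    Parameters
    ----------
    genotype_counts : (n_AA, n_Aa, n_aa) observed genotype counts.

    Returns
    -------
    (chi2, p) with 1 degree of freedom. A monomorphic sample is trivially
    in equilibrium; it returns (0.0, 1.0) with a warning.
    """
    n_aa, n_ab, n_bb = (int(c) for c in genotype_counts)
    n = n_aa + n_ab + n_bb
    if n <= 0:
        raise ValueError("total genotype count must be positive")
    p = (2 * n_aa + n_ab) / (2 * n)
    if p in (0.0, 1.0):
        warnings.warn("monomorphic sample: HWE trivially satisfied", stacklevel=2)
        return 0.0, 1.0
    expected = np.array([n * p * p, 2 * n * p * (1 - p), n * (1 - p) ** 2])
    observed = np.array([n_aa, n_ab, n_bb], dtype=float)
    chi2 = float(np.sum((observed - expected) ** 2 / expected))
    return chi2, float(stats.chi2.sf(chi2, df=1))


def counts_from_maf(maf: float, n_subjects: int) -> tuple:
    """Reconstruct (minor, major) allele counts from a printed MAF and N.

    Counts are rounded to the nearest integer among the 2N chromosomes;
    rounding is the source of last-digit differences versus published ORs.
    """
    if not 0 <= maf <= 1:
        raise ValueError("MAF must lie in [0, 1]")
    if n_subjects <= 0:
        raise ValueError("N must be positive")
    minor = round(2 * n_subjects * maf)
    return minor, 2 * n_subjects - minor


def allele_table_from_maf(maf_cases, n_cases, maf_controls, n_controls) -> AlleleTable:
    a, b = counts_from_maf(maf_cases, n_cases)
    c, d = counts_from_maf(maf_controls, n_controls)
    return AlleleTable(a, b, c, d)


def allelic_or(table: AlleleTable) -> AssocResult:
    """Allelic odds ratio with Woolf SE and a Wald two-sided p-value.

    OR = (minor_cases * major_controls) / (major_cases * minor_controls).
    If any cell is zero the Haldane-Anscombe correction (+0.5 on every
    cell) is applied before computing the OR and its SE.
    """
    a, b, c, d = (float(table.minor_cases), float(table.major_cases),
                  float(table.minor_controls), float(table.major_controls))
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    or_ = (a * d) / (b * c)
    beta = math.log(or_)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    p = 2 * stats.norm.sf(abs(beta) / se)
    ci = (math.exp(beta - Z95 * se), math.exp(beta + Z95 * se))
    return AssocResult(beta=beta, se=se, or_=or_, ci95=ci, p=float(p), method="allelic")


def logistic_assoc(genotypes, status, covariates=None, tol: float = 1e-8,
                   max_iter: int = 100) -> AssocResult:
    """Logistic regression of case status on allele dosage with covariates.

    Fits ``status ~ dosage (+ covariates)`` by Newton-type iterations via
    statsmodels and returns the Wald statistics for the dosage term.
    Complete separation yields a flagged (converged=False) result rather
    than an exception; collinear covariate columns are dropped with a
    warning.
    """
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

    dosage = np.asarray(genotypes, dtype=float)
    y = np.asarray(status, dtype=float)
    cols = {"dosage": dosage}
    if covariates is not None:
        cov = pd.DataFrame(covariates).reset_index(drop=True)
        for name in cov.columns:
            cols[str(name)] = cov[name].to_numpy(dtype=float)
    x = pd.DataFrame(cols)
    # drop collinear covariate columns (never the dosage term)
    keep = ["dosage"]
    for name in x.columns:
        if name == "dosage":
            continue
        trial = x[keep + [name]].to_numpy()
        if np.linalg.matrix_rank(trial) == trial.shape[1] and x[name].nunique() > 1:
            keep.append(name)
        else:
            warnings.warn(f"covariate {name!r} is constant or collinear; dropped", stacklevel=2)
    x = sm.add_constant(x[keep], has_constant="add")

    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("error", PerfectSeparationWarning)
        try:
            fit = sm.Logit(y, x).fit(disp=0, tol=tol, maxiter=max_iter)
            converged = bool(fit.mle_retvals.get("converged", True))
        except Exception:
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, x).fit(disp=0, tol=tol, maxiter=max_iter, method="bfgs")
            converged = False
    beta = float(fit.params["dosage"])
    se = float(fit.bse["dosage"])
    p = float(fit.pvalues["dosage"])
    # np.exp: diverged estimates (separation) give inf rather than raising
    ci = (float(np.exp(beta - Z95 * se)), float(np.exp(beta + Z95 * se)))
    return AssocResult(beta=beta, se=se, or_=float(np.exp(beta)), ci95=ci, p=p,
                       method="logistic", converged=converged)


def se_from_ci(or_: float, low: float, high: float) -> float:
    """SE of the log-OR recovered from a printed OR and 95% CI."""
    if not (0 < low <= or_ <= high):
        raise ValueError("require 0 < low <= OR <= high")
    return (math.log(high) - math.log(low)) / (2 * Z95)


def ivw_meta(studies) -> MetaResult:
    """Fixed-effect inverse-variance-weighted meta-analysis.

    Parameters
    ----------
    studies : iterable of (beta, se) per cohort, on the log-OR scale.

    The combined estimate is ``sum(w_i * beta_i) / sum(w_i)`` with
    ``w_i = 1/se_i^2`` and ``SE = 1/sqrt(sum(w_i))``; Cochran's Q and I²
    are reported for heterogeneity inspection but a fixed-effect model is
    always used.
    """
    studies = [(float(b), float(s)) for b, s in studies]
    if any(s <= 0 for _, s in studies):
        raise ValueError("all standard errors must be positive")
    if len(studies) < 2:
        warnings.warn("single study: meta-analysis is a pass-through", stacklevel=2)
    w = np.array([1 / s**2 for _, s in studies])
    b = np.array([b for b, _ in studies])
    beta = float(np.sum(w * b) / np.sum(w))
    se = float(1 / math.sqrt(np.sum(w)))
    q = float(np.sum(w * (b - beta) ** 2))
    dfree = max(len(studies) - 1, 1)
    i2 = max(0.0, (q - dfree) / q) if q > 0 else 0.0
    p = 2 * stats.norm.sf(abs(beta) / se)
    ci = (math.exp(beta - Z95 * se), math.exp(beta + Z95 * se))
    return MetaResult(studies=[(bi, si, wi) for (bi, si), wi in zip(studies, w)],
                      beta=beta, se=se, or_=math.exp(beta), ci95=ci, p=float(p),
                      q_stat=q, i2=i2)
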