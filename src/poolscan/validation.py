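"""Validation statistics: homogeneity tests, estimate-vs-truth agreement,
and allele/trait association tests.

Pooled allele-frequency estimates are validated against individual
genotypes in two ways: per-marker Pearson chi-squared homogeneity tests of
the allele-by-set line-count table, and agreement of estimated with true
reference allele frequencies summarised by the identity-line R^2 (residuals
about y = x).  Marker-trait associations are re-tested in a wider panel by
a one-sided pooled-variance t-test of the trait between carriers of the
high and low allele.

The counting unit for 2x2 tables is lines (one allele call per fully
homozygous inbred line), not 2n chromosomes: in homozygous material the 2n
convention merely doubles every cell and inflates the statistic.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats

log = logging.getLogger(__name__)


class ChisqResult(NamedTuple):
    chi2: float
    p: float
    neglog10p: float
    degenerate: bool


@dataclass
class MarkerGenotypeContrast:
    """One validated marker: line counts by set, true AFD and the pooled estimate."""

    marker_id: str
    counts: np.ndarray  # 2x2, rows = (high set, low set), cols = (ref, alt)
    true_afd: float
    est_afd: float


@dataclass
class AlleleTraitTest:
    """One-sided pooled-t comparison of trait means by carried allele."""

    marker_id: str
    n_high: int
    n_low: int
    mean_high: float
    mean_low: float
    sem_high: float
    sem_low: float
    t: float
    df: int
    p: float


def chisq_homogeneity(counts, correction: bool = False) -> ChisqResult:
    """Pearson chi-squared test of homogeneity on a 2x2 count table.

    1 df, no continuity correction by default (``correction=True`` applies
    Yates); two-sided p from the upper tail of the chi-squared
    distribution.  A zero row or column marginal makes the statistic 0 and
    flags the result degenerate.
    """
    t = np.asarray(counts, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("counts must be a 2x2 table")
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    n = t.sum()
    if n <= 0:
        raise ValueError("table must have a positive grand total")
    a, b, c, d = t.ravel()
    den = (a + b) * (c + d) * (a + c) * (b + d)
    if den == 0:
        return ChisqResult(0.0, 1.0, 0.0, True)
    diff = abs(a * d - b * c)
    if correction:
        diff = max(diff - n / 2.0, 0.0)
    chi2 = n * diff**2 / den
    p = float(stats.chi2.sf(chi2, df=1))
    return ChisqResult(float(chi2), p, chisq_to_neglog10p(chi2), False)


def chisq_to_neglog10p(chi2: float, df: int = 1) -> float:
    """-log10 of the upper-tail chi-squared probability."""
    if chi2 < 0:
        raise ValueError("chi2 must be >= 0")
    if df == 1:
        # exact squared-normal identity; norm.logsf stays finite far beyond
        # where the chi-squared survival function underflows
        logp = np.log(2.0) + stats.norm.logsf(np.sqrt(chi2))
    else:
        logp = stats.chi2.logsf(chi2, df=df)
    return float(-logp / np.log(10))


def _ref_calls(genotypes) -> np.ndarray:
    """Recode homozygous calls to 0/1 reference indicators with NaN missing."""
    x = np.asarray(genotypes, dtype=float).copy()
    x[x < 0] = np.nan
    finite = x[np.isfinite(x)]
    if finite.size and finite.max() > 1:
        x = x / 2.0
    return x


def true_afd_from_genotypes(high_genotypes, low_genotypes) -> float:
    """Reference allele frequency difference (high - low) from individual calls.

    Accepts {0,2} or {0,1} homozygote codes with -1/NaN missing; missing
    calls are dropped per set.  NaN (with a warning) when a set has no
    non-missing call.
    """
    freqs = []
    for calls in (high_genotypes, low_genotypes):
        x = _ref_calls(calls)
        n = np.isfinite(x).sum()
        if n == 0:
            warnings.warn("a set has no non-missing genotype call; true AFD undefined",
                          RuntimeWarning)
            return float("nan")
        freqs.append(np.nansum(x) / n)
    return float(freqs[0] - freqs[1])


def marker_contrast(
    marker_id: str, high_genotypes, low_genotypes, est_afd: float
) -> MarkerGenotypeContrast:
    """Build the line-count table and true AFD for one validated marker."""
    rows = []
    for calls in (high_genotypes, low_genotypes):
        x = _ref_calls(calls)
        ref = int(np.nansum(x))
        rows.append([ref, int(np.isfinite(x).sum()) - ref])
    return MarkerGenotypeContrast(
        marker_id=marker_id,
        counts=np.array(rows),
        true_afd=true_afd_from_genotypes(high_genotypes, low_genotypes),
        est_afd=est_afd,
    )


def compare_estimated_true(est, true) -> tuple[float, float]:
    """Agreement of estimated with true values: identity-line R^2 and |.|-correlation.

    ``identity_r2 = 1 - sum((est - true)^2) / sum((est - mean(est))^2)`` —
    residuals about the y = x line, variance about the estimate mean.
    ``abs_correlation`` is the Pearson correlation of |est| with |true|.
    NaN with a warning when the estimates have zero variance.
    """
    e = np.asarray(est, dtype=float)
    t = np.asarray(true, dtype=float)
    if e.shape != t.shape or e.size < 3:
        raise ValueError("need at least 3 matched (est, true) pairs")
    ss_var = ((e - e.mean()) ** 2).sum()
    if ss_var == 0:
        warnings.warn("estimates have zero variance; identity R^2 undefined", RuntimeWarning)
        return float("nan"), float("nan")
    identity_r2 = 1.0 - ((e - t) ** 2).sum() / ss_var
    abs_corr = float(stats.pearsonr(np.abs(e), np.abs(t)).statistic)
    return float(identity_r2), abs_corr


def allele_trait_ttest(
    trait,
    allele_labels,
    high_label,
    marker_id: str = "",
    alternative: str = "greater",
) -> AlleleTraitTest:
    """Pooled-variance two-sample t-test of the trait by carried allele.

    ``alternative='greater'`` (default) tests mean(high-allele carriers) >
    mean(low-allele carriers), the one-sided direction implied by the
    discovery contrast; 'two-sided' is available.  df = n1 + n2 - 2.
    """
    y = np.asarray(trait, dtype=float)
    lab = np.asarray(allele_labels)
    hi = y[lab == high_label]
    lo = y[lab != high_label]
    if hi.size < 2 or lo.size < 2:
        raise ValueError("both allele groups need at least 2 observations")
    if (hi.size >= 2 and np.ptp(hi) == 0) or (lo.size >= 2 and np.ptp(lo) == 0):
        log.info("allele_trait_ttest %s: a group has zero variance", marker_id or "<marker>")
    res = stats.ttest_ind(hi, lo, equal_var=True, alternative=alternative)
    return AlleleTraitTest(
        marker_id=marker_id,
        n_high=int(hi.size),
        n_low=int(lo.size),
        mean_high=float(hi.mean()),
        mean_low=float(lo.mean()),
        sem_high=float(stats.sem(hi)),
        sem_low=float(stats.sem(lo)),
        t=float(res.statistic),
        df=int(hi.size + lo.size - 2),
        p=float(res.pvalue),
    )


def kasp_validation_table(contrasts: Sequence[MarkerGenotypeContrast]):
    """Per-marker validation report: est/true AFD, chi-squared and -log10 p."""
    import pandas as pd

    rows = []
    for mc in contrasts:
        res = chisq_homogeneity(mc.counts)
        rows.append(
            {
                "marker_id": mc.marker_id,
                "est_afd": mc.est_afd,
                "true_afd": mc.true_afd,
                "chi2": res.chi2,
                "neglog10p": res.neglog10p,
                "degenerate": res.degenerate,
            }
        )
    return pd.DataFrame(rows)
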