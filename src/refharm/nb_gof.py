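"""Per-gene negative-binomial goodness-of-fit screen.

Sequencing counts (and floored microarray intensities treated as
pseudo-counts) are screened gene by gene: a negative binomial NB(mu, size)
is fitted by maximum likelihood, then a Pearson chi-squared test compares
the observed count histogram with the fitted law.  The reported fraction
of genes consistent with the NB law indicates whether count-model
normalization (median-of-ratios) is formally applicable to a dataset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .core_io import ExpressionMatrix

__all__ = ["NBFit", "GofResult", "fit_nb", "pearson_chisq_gof", "nb_gof_matrix"]

_SIZE_LO = 1e-4
_SIZE_HI = 1e6
_MIN_SAMPLES = 8


@dataclass(frozen=True)
class NBFit:
    """Maximum-likelihood NB(mu, size) fit for one gene's counts."""

    mu: float
    size: float
    loglik: float
    poisson_like: bool = False  # variance <= mean; size capped at the bracket top


@dataclass(frozen=True)
class GofResult:
    """Pearson chi-squared goodness-of-fit outcome."""

    p_value: float
    statistic: float
    df: int
    n_bins: int
    skipped: bool = False  # too few bins after merging to test anything


def _nb_loglik(counts: np.ndarray, mu: float, size: float) -> float:
    p = size / (size + mu)
    return float(stats.nbinom.logpmf(counts, size, p).sum())


def fit_nb(counts: np.ndarray) -> NBFit:
    """Fit NB(mu, size) by maximum likelihood.

    ``mu`` is the sample mean (its MLE for fixed size); ``size`` maximizes
    the profile log-likelihood over log(size) in [1e-4, 1e6].  When the
    sample variance does not exceed the mean there is no over-dispersion
    to estimate: size is capped at the top of the bracket and the fit is
    flagged Poisson-like.
    """
    counts = np.asarray(counts)
    if len(counts) < _MIN_SAMPLES:
        raise ValueError(f"need >= {_MIN_SAMPLES} observations, got {len(counts)}")
    if np.any(counts < 0) or not np.allclose(counts, np.round(counts)):
        raise ValueError("counts must be non-negative integers")
    counts = counts.astype(np.int64)
    if not counts.any():
        raise ValueError("all-zero count vector: NB fit undefined")
    mu = float(counts.mean())
    var = float(counts.var())
    if var <= mu:
        size = _SIZE_HI
        return NBFit(mu, size, _nb_loglik(counts, mu, size), poisson_like=True)
    size0 = mu**2 / (var - mu)  # moment estimate
    res = optimize.minimize_scalar(
        lambda log_size: -_nb_loglik(counts, mu, float(np.exp(log_size))),
        bounds=(np.log(_SIZE_LO), np.log(_SIZE_HI)),
        method="bounded",
        options={"xatol": 1e-8},
    )
    size = float(np.exp(res.x))
    loglik = -float(res.fun)
    ll_moment = _nb_loglik(counts, mu, float(np.clip(size0, _SIZE_LO, _SIZE_HI)))
    if ll_moment > loglik:  # optimizer must never do worse than its start
        size = float(np.clip(size0, _SIZE_LO, _SIZE_HI))
        loglik = ll_moment
    return NBFit(mu, size, loglik, poisson_like=size >= _SIZE_HI * 0.999)


def _merge_bins(observed: np.ndarray, expected: np.ndarray, min_expected: float):
    """Merge adjacent count categories until every expected count is large.

    The sparse right tail is collapsed first (rightward sweep), then the
    left edge; any interior shortfall left over is merged into its right
    neighbour.
    """
    obs = list(observed.astype(float))
    exp = list(expected.astype(float))
    # rightward: collapse the tail
    while len(exp) > 1 and exp[-1] < min_expected:
        exp[-2] += exp[-1]
        obs[-2] += obs[-1]
        del exp[-1], obs[-1]
    # leftward: collapse the head
    while len(exp) > 1 and exp[0] < min_expected:
        exp[1] += exp[0]
        obs[1] += obs[0]
        del exp[0], obs[0]
    # interior
    i = 0
    while i < len(exp):
        if exp[i] < min_expected and len(exp) > 1:
            j = i + 1 if i + 1 < len(exp) else i - 1
            exp[j] += exp[i]
            obs[j] += obs[i]
            del exp[i], obs[i]
            i = 0
        else:
            i += 1
    return np.array(obs), np.array(exp)


def pearson_chisq_gof(
    counts: np.ndarray, fit: NBFit, min_expected: float = 5.0
) -> GofResult:
    """Pearson chi-squared test of the fitted NB law on count categories.

    Categories 0..max(counts) plus an open right tail; adjacent categories
    are merged until every expected count is >= ``min_expected``.  Degrees
    of freedom = bins - 1 - 2 (two estimated parameters); when fewer than
    one degree of freedom remains the test is skipped with p = 1.
    """
    counts = np.asarray(counts).astype(np.int64)
    n = len(counts)
    top = int(counts.max())
    p = fit.size / (fit.size + fit.mu)
    cats = np.arange(top + 1)
    probs = stats.nbinom.pmf(cats, fit.size, p)
    tail = float(stats.nbinom.sf(top, fit.size, p))
    probs = np.append(probs, tail)
    expected = probs * n
    observed = np.append(np.bincount(counts, minlength=top + 1), 0.0)
    obs, exp = _merge_bins(observed, expected, min_expected)
    df = len(obs) - 1 - 2
    if df < 1:
        return GofResult(1.0, 0.0, df, len(obs), skipped=True)
    stat = float(((obs - exp) ** 2 / exp).sum())
    return GofResult(float(stats.chi2.sf(stat, df)), stat, df, len(obs))


def nb_gof_matrix(
    matrix: ExpressionMatrix, alpha: float = 0.05, min_expected: float = 5.0
) -> pd.DataFrame:
    """Run the NB fit + chi-squared screen on every gene of a count matrix.

    Returns a per-gene table (p_value, mu, size, status); genes that
    cannot be fitted (all zeros, non-integer) get status strings and NA
    p-values instead of raising.  The table's ``attrs['fraction_consistent']``
    holds the fraction of testable genes with p >= alpha.
    """
    arr = matrix.values.to_numpy()
    rows = []
    for g, gene in enumerate(matrix.gene_ids):
        counts = arr[g]
        try:
            fit = fit_nb(counts)
            gof = pearson_chisq_gof(counts, fit, min_expected)
            rows.append(
                {
                    "gene": gene,
                    "p_value": gof.p_value,
                    "mu": fit.mu,
                    "size": fit.size,
                    "status": "skipped" if gof.skipped else "ok",
                }
            )
        except ValueError as exc:
            rows.append(
                {"gene": gene, "p_value": np.nan, "mu": np.nan, "size": np.nan,
                 "status": str(exc)}
            )
    table = pd.DataFrame(rows).set_index("gene")
    tested = table["p_value"].notna()
    frac = float((table.loc[tested, "p_value"] >= alpha).mean()) if tested.any() else np.nan
    table.attrs["fraction_consistent"] = frac
    table.attrs["alpha"] = alpha
    return table
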