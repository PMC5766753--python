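"""Method-comparison statistics for count validation.

Implements, at formula level, the agreement machinery used to validate an
automated count against a reference count:

* Bland-Altman analysis — mean difference, SD of differences and the
  1.96-SD limits of agreement, plus a one-sample t-test of zero bias;
* intraclass correlation, two-way random effects, absolute agreement —
  ICC(2,1) single measures and ICC(2,k) average measures from the two-way
  ANOVA mean squares;
* Spearman rank correlation — Pearson correlation of mid-ranks with a
  t-approximation p-value (exact permutation p for tiny samples);
* forward stepwise multiple regression — incremental predictor entry by
  partial-F p-value, reporting the R² path, for finding which spatial bins
  best predict a total count.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _sps

logger = logging.getLogger(__name__)

__all__ = [
    "AgreementStats",
    "ICCResult",
    "SpearmanResult",
    "StepwiseModel",
    "bland_altman",
    "icc_two_way_random_absolute",
    "spearman",
    "stepwise_regression",
]


def _paired(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("paired vectors must have equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    dropped = int(x.size - keep.sum())
    if dropped:
        logger.info("dropped %d pair(s) with missing values", dropped)
    return x[keep], y[keep]


# ---------------------------------------------------------------------------
# Bland-Altman
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AgreementStats:
    """Bland-Altman summary of paired differences d = x - y."""

    n: int
    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    loa_multiplier: float
    t_stat: float
    p_value: float

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "mean_diff": self.mean_diff,
            "sd_diff": self.sd_diff,
            "loa_low": self.loa_low,
            "loa_high": self.loa_high,
            "loa_multiplier": self.loa_multiplier,
            "t_stat": self.t_stat,
            "p_value": self.p_value,
        }


def bland_altman(x, y, loa_multiplier: float = 1.96) -> AgreementStats:
    """Bland-Altman agreement between two paired measurement methods.

    d = x - y; limits of agreement are mean(d) ± ``loa_multiplier`` · SD(d)
    with the sample (n−1) SD.  The t-test is the conventional one-sample
    test of mean difference = 0 (a measure of systematic bias).
    """
    x, y = _paired(x, y)
    n = x.size
    if n < 3:
        raise ValueError("Bland-Altman needs at least 3 pairs")
    d = x - y
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd > 0:
        t = mean / (sd / math.sqrt(n))
        p = float(2.0 * _sps.t.sf(abs(t), n - 1))
    else:
        t = math.inf if mean > 0 else (-math.inf if mean < 0 else 0.0)
        p = 0.0 if mean != 0 else 1.0
    return AgreementStats(
        n=n,
        mean_diff=mean,
        sd_diff=sd,
        loa_low=mean - loa_multiplier * sd,
        loa_high=mean + loa_multiplier * sd,
        loa_multiplier=loa_multiplier,
        t_stat=float(t),
        p_value=p,
    )


# ---------------------------------------------------------------------------
# ICC (two-way random, absolute agreement)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ICCResult:
    icc_single: float      # ICC(2,1)
    icc_average: float     # ICC(2,k)
    n_subjects: int
    k_raters: int
    ms_rows: float
    ms_cols: float
    ms_error: float

    def to_dict(self) -> dict:
        return {
            "icc_single": self.icc_single,
            "icc_average": self.icc_average,
            "n_subjects": self.n_subjects,
            "k_raters": self.k_raters,
        }


def icc_two_way_random_absolute(m) -> ICCResult:
    """ICC(2,1) and ICC(2,k): two-way random effects, absolute agreement.

    ``m`` is a complete n_subjects × k_raters matrix (raters may be
    assessors or repeated images of the same tongue).  From the two-way
    ANOVA mean squares (MSR between subjects, MSC between raters, MSE
    residual)::

        ICC(2,1) = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)
        ICC(2,k) = (MSR - MSE) / (MSR + (MSC - MSE) / n)
    """
    m = np.asarray(m, dtype=float)
    if m.ndim != 2:
        raise ValueError("ratings must be a 2-D matrix")
    if np.isnan(m).any():
        raise ValueError("ratings matrix must be complete (no missing values)")
    n, k = m.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 subjects and 2 raters")

    grand = m.mean()
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    ssr = k * ((row_means - grand) ** 2).sum()
    ssc = n * ((col_means - grand) ** 2).sum()
    sst = ((m - grand) ** 2).sum()
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = max(sse / ((n - 1) * (k - 1)), 0.0)  # clamp tiny negative round-off

    denom_single = msr + (k - 1) * mse + k * (msc - mse) / n
    denom_avg = msr + (msc - mse) / n
    if denom_single == 0 or denom_avg == 0:
        raise ValueError("degenerate ratings matrix (zero total variance)")
    return ICCResult(
        icc_single=float((msr - mse) / denom_single),
        icc_average=float((msr - mse) / denom_avg),
        n_subjects=n,
        k_raters=k,
        ms_rows=float(msr),
        ms_cols=float(msc),
        ms_error=float(mse),
    )


# ---------------------------------------------------------------------------
# Spearman correlation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpearmanResult:
    r: float
    p_value: float
    n: int

    def __iter__(self):
        return iter((self.r, self.p_value))


def spearman(x, y, method: str = "t") -> SpearmanResult:
    """Spearman rank correlation with mid-ranks for ties.

    r is the Pearson correlation of the rank vectors.  ``method="t"`` gives
    the usual t approximation with n−2 degrees of freedom (adequate at study
    scale); ``method="permutation"`` enumerates all permutations of one
    vector (factorial cost — intended for n ≤ 10).
    """
    x, y = _paired(x, y)
    n = x.size
    if n < 3:
        raise ValueError("Spearman needs at least 3 pairs")
    rx = _sps.rankdata(x)
    ry = _sps.rankdata(y)
    if rx.std() == 0 or ry.std() == 0:
        raise ValueError("zero rank variance (constant input vector)")
    r = float(np.corrcoef(rx, ry)[0, 1])

    if method == "t":
        if abs(r) >= 1.0:
            p = 0.0
        else:
            t = r * math.sqrt((n - 2) / (1.0 - r * r))
            p = float(2.0 * _sps.t.sf(abs(t), n - 2))
    elif method == "permutation":
        if n > 10:
            raise ValueError("exact permutation p-value is limited to n <= 10")
        # |r| comparisons reduce to |dot| comparisons: the rank variances
        # are permutation-invariant
        rx_c = rx - rx.mean()
        ry_c = ry - ry.mean()
        observed = abs(rx_c @ ry_c)
        count = 0
        total = 0
        for perm in itertools.permutations(ry_c):
            if abs(rx_c @ np.asarray(perm)) >= observed - 1e-12:
                count += 1
            total += 1
        p = count / total
    else:
        raise ValueError("method must be 't' or 'permutation'")
    return SpearmanResult(r=r, p_value=p, n=n)


# ---------------------------------------------------------------------------
# forward stepwise regression
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StepwiseModel:
    """A forward-selection path: predictors in entry order plus final fit."""

    predictors: tuple[str, ...]
    coefficients: dict[str, float]
    intercept: float
    r2_path: tuple[float, ...]
    p_enter: float
    candidate_names: tuple[str, ...] = field(default=())

    @property
    def r2(self) -> float:
        return self.r2_path[-1] if self.r2_path else 0.0

    def to_dict(self) -> dict:
        return {
            "predictors": list(self.predictors),
            "coefficients": dict(self.coefficients),
            "intercept": self.intercept,
            "r2_path": list(self.r2_path),
            "p_enter": self.p_enter,
        }


def _ols_rss(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    """Least-squares fit with intercept; returns (coefs incl. intercept, RSS)."""
    A = np.column_stack([X, np.ones(len(y))])
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ beta
    return beta, float(resid @ resid)


def stepwise_regression(X, y, p_enter: float = 0.05, names=None) -> StepwiseModel:
    """Forward stepwise selection of predictors of a total count.

    At each step the candidate giving the largest R² increase enters if its
    partial-F p-value is below ``p_enter``; selection stops when no
    candidate qualifies (no removal step).  Exact ties (e.g. duplicated
    columns) break deterministically by column order.

    ``X`` may be a pandas DataFrame (column names are used) or a 2-D array.
    """
    try:
        import pandas as pd

        if isinstance(X, pd.DataFrame):
            if names is None:
                names = list(X.columns)
            X = X.to_numpy(dtype=float)
    except ImportError:  # pragma: no cover
        pass
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("X must be (n, p) with n matching y")
    n, p = X.shape
    if names is None:
        names = [f"x{j + 1}" for j in range(p)]
    names = [str(nm) for nm in names]

    tss = float(((y - y.mean()) ** 2).sum())
    if tss == 0:
        raise ValueError("y has zero variance")

    selected: list[int] = []
    r2_path: list[float] = []
    rss_current = tss
    while len(selected) < p:
        n_params_new = len(selected) + 1 + 1  # predictors + candidate + intercept
        df_resid = n - n_params_new
        if df_resid < 1:
            logger.info("stopping: no residual degrees of freedom left")
            break
        best = None
        for j in range(p):
            if j in selected:
                continue
            _, rss_j = _ols_rss(X[:, selected + [j]], y)
            if best is None or rss_j < best[1] - 1e-12:
                best = (j, rss_j)
        j, rss_new = best
        # partial F for adding one predictor
        improvement = rss_current - rss_new
        if improvement <= 1e-12 * tss:
            p_val = 1.0                      # no gain (incl. already-perfect fit)
        elif rss_new <= 1e-12 * tss:
            p_val = 0.0                      # candidate completes a perfect fit
        else:
            f_stat = improvement / (rss_new / df_resid)
            p_val = float(_sps.f.sf(f_stat, 1, df_resid)) if f_stat > 0 else 1.0
        if p_val >= p_enter:
            break
        selected.append(j)
        rss_current = rss_new
        r2_path.append(1.0 - rss_current / tss)

    if selected:
        beta, _ = _ols_rss(X[:, selected], y)
        coefs = {names[j]: float(b) for j, b in zip(selected, beta[:-1])}
        intercept = float(beta[-1])
    else:
        coefs, intercept = {}, float(y.mean())
    return StepwiseModel(
        predictors=tuple(names[j] for j in selected),
        coefficients=coefs,
        intercept=intercept,
        r2_path=tuple(r2_path),
        p_enter=p_enter,
        candidate_names=tuple(names),
    )
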