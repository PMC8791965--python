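"""Agreement and error statistics for age regression.

Implements the full reporting stack: coefficient of determination (R²),
mean absolute error in days, Lin's concordance correlation coefficient
(CCC) with a 95% confidence interval and a qualitative strength-of-
agreement class, and the modified Bland–Altman analysis in which
prediction-minus-truth differences are summarized by locally estimated
quantile curves along the true-age axis.

Lin's CCC combines precision (Pearson correlation) and accuracy (location
and scale bias):

    rho_c = 2 cov(y, yhat) / (var(y) + var(yhat) + (mean(y) - mean(yhat))^2)

with population (1/n) moments, as in Lin's original definition; sample
(1/(n-1)) moments are available as an option. The confidence interval uses
the Fisher z transform with Lin's asymptotic variance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.ndimage import gaussian_filter1d

__all__ = ["EvaluationReport", "QuantileCurves", "r2_score", "mae_days",
           "lin_ccc", "mcbride_class", "bland_altman_quantiles", "evaluate"]

QUANTILE_LEVELS = (0.05, 0.10, 0.25, 0.50, 0.75, 0.90, 0.95)


@dataclass
class EvaluationReport:
    r2: float
    mae: float          # days
    ccc: float
    ccc_ci: tuple[float, float]
    mcbride: str
    n: int

    def to_dict(self) -> dict:
        return {"r2": self.r2, "mae_days": self.mae, "ccc": self.ccc,
                "ccc_ci_low": self.ccc_ci[0], "ccc_ci_high": self.ccc_ci[1],
                "mcbride": self.mcbride, "n": self.n}


@dataclass
class QuantileCurves:
    """Smoothed local quantile curves of (prediction - truth) vs truth."""

    levels: tuple[float, ...]
    x: np.ndarray             # window-median true age, days
    curves: np.ndarray        # (len(levels), len(x)) differences, days
    window: int = 15
    overlap: float = 0.95


def _check_pair(y_true, y_pred, min_n: int = 1):
    y_true = np.asarray(y_true, dtype=np.float64).ravel()
    y_pred = np.asarray(y_pred, dtype=np.float64).ravel()
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    if y_true.size < min_n:
        raise ValueError(f"need at least {min_n} observations")
    return y_true, y_pred


def r2_score(y_true, y_pred) -> float:
    """1 - SS_res / SS_tot."""
    y_true, y_pred = _check_pair(y_true, y_pred, min_n=2)
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("R^2 undefined for constant y_true")
    ss_res = float(np.sum((y_true - y_pred) ** 2))
    return 1.0 - ss_res / ss_tot


def mae_days(y_true, y_pred) -> float:
    y_true, y_pred = _check_pair(y_true, y_pred, min_n=1)
    return float(np.mean(np.abs(y_true - y_pred)))


def lin_ccc(y_true, y_pred, ddof: int = 0,
            confidence: float = 0.95) -> tuple[float, float, float]:
    """Lin's concordance correlation coefficient with its CI.

    Returns (rho_c, ci_low, ci_high). ``ddof=0`` (population moments) is
    the canonical definition; ``ddof=1`` uses sample moments.
    """
    y_true, y_pred = _check_pair(y_true, y_pred, min_n=3)
    n = y_true.size
    m1, m2 = y_true.mean(), y_pred.mean()
    v1 = y_true.var(ddof=ddof)
    v2 = y_pred.var(ddof=ddof)
    if v1 == 0 or v2 == 0:
        raise ValueError("CCC undefined for a constant vector")
    cov = float(((y_true - m1) * (y_pred - m2)).sum()) / (n - ddof)
    ccc = 2.0 * cov / (v1 + v2 + (m1 - m2) ** 2)

    # Fisher z CI with Lin's asymptotic variance of the transformed estimate
    r = cov / np.sqrt(v1 * v2)
    u = (m1 - m2) / (v1 * v2) ** 0.25
    eps = 1e-12
    ccc_c = np.clip(ccc, -1 + eps, 1 - eps)
    r_c = np.sign(r) * max(abs(r), eps)
    one_m = 1.0 - ccc_c ** 2
    var_z = ((1 - r_c ** 2) * ccc_c ** 2 / (one_m * r_c ** 2)
             + 2 * ccc_c ** 3 * (1 - ccc_c) * u ** 2 / (r_c * one_m ** 2)
             - ccc_c ** 4 * u ** 4 / (2 * r_c ** 2 * one_m ** 2)) / (n - 2)
    var_z = max(var_z, 0.0)
    z = np.arctanh(ccc_c)
    zcrit = stats.norm.ppf(0.5 + confidence / 2.0)
    lo = float(np.tanh(z - zcrit * np.sqrt(var_z)))
    hi = float(np.tanh(z + zcrit * np.sqrt(var_z)))
    # the interval always brackets the point estimate (degenerate at |ccc|=1)
    return float(ccc), min(lo, float(ccc)), max(hi, float(ccc))


def mcbride_class(ccc: float) -> str:
    """Strength-of-agreement class: poor < 0.90; moderate 0.90-0.95;
    substantial 0.95-0.99; almost perfect > 0.99."""
    if not -1.0 <= ccc <= 1.0:
        raise ValueError("CCC must lie in [-1, 1]")
    if ccc < 0.90:
        return "poor"
    if ccc < 0.95:
        return "moderate"
    if ccc <= 0.99:
        return "substantial"
    return "almost_perfect"


def bland_altman_quantiles(y_true, y_pred, window: int = 15,
                           overlap: float = 0.95,
                           smoothing_sigma: float = 2.0) -> QuantileCurves:
    """Local piecewise quantile curves for the modified Bland–Altman plot.

    Pairs are sorted by true age; a ``window``-point window slides with the
    stated fractional overlap (rounded to an integer stride of at least 1);
    within each window the seven empirical quantiles of (prediction -
    truth) are taken at the window's median true age, and each quantile
    series is smoothed with a Gaussian kernel. Smoothing is a positive
    linear combination shared across levels, so the curves stay monotone in
    quantile level at every evaluation point.
    """
    y_true, y_pred = _check_pair(y_true, y_pred, min_n=window)
    if not 0.0 <= overlap < 1.0:
        raise ValueError("overlap must lie in [0, 1)")
    order = np.argsort(y_true, kind="stable")
    yt = y_true[order]
    diff = (y_pred - y_true)[order]
    stride = max(1, int(round((1.0 - overlap) * window)))
    starts = list(range(0, yt.size - window + 1, stride))
    if starts[-1] != yt.size - window:
        starts.append(yt.size - window)
    x = np.empty(len(starts))
    curves = np.empty((len(QUANTILE_LEVELS), len(starts)))
    for j, s in enumerate(starts):
        w_true = yt[s:s + window]
        w_diff = diff[s:s + window]
        x[j] = np.median(w_true)
        curves[:, j] = np.quantile(w_diff, QUANTILE_LEVELS)
    if smoothing_sigma > 0 and len(starts) > 1:
        curves = gaussian_filter1d(curves, sigma=smoothing_sigma, axis=1,
                                   mode="nearest")
    return QuantileCurves(QUANTILE_LEVELS, x, curves,
                          window=window, overlap=overlap)


def evaluate(y_true, y_pred) -> EvaluationReport:
    """Full report: R², MAE (days), CCC with 95% CI, and agreement class."""
    y_true, y_pred = _check_pair(y_true, y_pred, min_n=3)
    ccc, lo, hi = lin_ccc(y_true, y_pred)
    return EvaluationReport(
        r2=r2_score(y_true, y_pred),
        mae=mae_days(y_true, y_pred),
        ccc=ccc, ccc_ci=(lo, hi),
        mcbride=mcbride_class(ccc),
        n=int(y_true.size))
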