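"""Likelihood-ratio tests and false-discovery-rate control.

Two null hypotheses are of biological interest per gene: no gene-dosage
effect (beta = 0) and no temporal differential expression (all spline
coefficients zero, i.e. a flat spline).  Both are evaluated by a likelihood
ratio computed at the shrunken posterior-mean parameters of nested fits; the
use of shrunken estimates makes the tests somewhat conservative, which is
accepted.  The temporal test uses real-valued degrees of freedom equal to the
effective spline df (hat-matrix trace); the dosage test uses 1 df.  Raw
p-values come from the upper tail of the chi-square distribution and are
adjusted by the Benjamini-Hochberg step-up procedure (Benjamini-Yekutieli
available behind a flag).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
from scipy import stats
from scipy.special import gammaln

from .gene_model import GeneFit, hat_trace

__all__ = [
    "TestResult",
    "lrt_copy_number",
    "lrt_temporal",
    "lrt_line_difference",
    "adjust_bh",
    "summarize_tests",
    "data_loglik",
]

_DF_FLOOR = 0.5


@dataclass
class TestResult:
    feature_id: Optional[str]
    statistic: float
    df: float
    p_value: float
    test: str
    p_adjusted: float = np.nan
    significant: Optional[bool] = None


def data_loglik(fit: GeneFit) -> float:
    """Data log-likelihood at the posterior-mean parameters of a fit."""
    y = fit._y
    if fit.family == "gaussian":
        s2 = fit.sigma2_eps_mean
        return float(np.sum(stats.norm.logpdf(y, loc=fit.fitted, scale=np.sqrt(s2))))
    r = fit.dispersion
    mu = np.maximum(fit.fitted, 1e-12)
    base = (gammaln(y + r) - gammaln(r) - gammaln(y + 1.0)
            + r * (np.log(r) - np.log(r + mu)) + y * (np.log(mu) - np.log(r + mu)))
    pi = fit.zero_inflation
    if pi > 0:
        logq = r * (np.log(r) - np.log(r + mu))
        l0 = np.logaddexp(np.log(pi), np.log1p(-pi) + logq)
        base = np.where(y == 0, l0, base + np.log1p(-pi))
    return float(base.sum())


def _check_same_hyper(fit_a: GeneFit, fit_b: GeneFit) -> None:
    if fit_a._priors.shared() != fit_b._priors.shared():
        raise ValueError("fits were obtained under different shared hyperparameters")


def _lrt(fit_full: GeneFit, fit_reduced: GeneFit, df: float, test: str) -> TestResult:
    stat = 2.0 * (data_loglik(fit_full) - data_loglik(fit_reduced))
    stat = max(stat, 0.0)  # shrinkage can push the ratio slightly negative
    p = 1.0 if stat == 0.0 else float(stats.chi2.sf(stat, df))
    return TestResult(feature_id=fit_full.feature_id, statistic=float(stat),
                      df=float(df), p_value=p, test=test)


def lrt_copy_number(fit_full: GeneFit, fit_reduced: GeneFit) -> TestResult:
    """LRT of H0: beta = 0 (reduced fit omits the copy-number covariate), 1 df."""
    _check_same_hyper(fit_full, fit_reduced)
    return _lrt(fit_full, fit_reduced, 1.0, "cn_effect")


def lrt_temporal(fit_full: GeneFit, fit_reduced: GeneFit) -> TestResult:
    """LRT of a flat spline (reduced fit omits the spline columns).

    Degrees of freedom are the effective spline df of the full fit, i.e. the
    trace of the spline block of the hat matrix, floored at 0.5.
    """
    _check_same_hyper(fit_full, fit_reduced)
    df = max(hat_trace(fit_full, "spline"), _DF_FLOOR)
    return _lrt(fit_full, fit_reduced, df, "temporal")


def lrt_line_difference(fit_perline: GeneFit, fit_common: GeneFit) -> TestResult:
    """LRT comparing per-line splines against a single common spline.

    Both fits must use the same knots; df is the difference in effective
    spline df between the two fits, floored at 0.5.
    """
    _check_same_hyper(fit_perline, fit_common)
    if fit_perline.basis_knots is None or fit_common.basis_knots is None or \
            not np.array_equal(fit_perline.basis_knots, fit_common.basis_knots):
        raise ValueError("per-line and common fits use different knots")
    df = max(hat_trace(fit_perline, "spline") - hat_trace(fit_common, "spline"), _DF_FLOOR)
    return _lrt(fit_perline, fit_common, df, "line_difference")


def adjust_bh(p_values: Sequence[float], method: str = "bh") -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in the input order.

    NaNs are passed through untouched and excluded from the number of tests.
    ``method='by'`` applies the Benjamini-Yekutieli correction instead.
    """
    p = np.asarray(p_values, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    if np.any((pv < 0) | (pv > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order]
    scale = m / np.arange(1, m + 1)
    if method == "by":
        scale = scale * np.sum(1.0 / np.arange(1, m + 1))
    elif method != "bh":
        raise ValueError("method must be 'bh' or 'by'")
    q = np.minimum.accumulate((ranked * scale)[::-1])[::-1]
    q = np.minimum(q, 1.0)
    adj = np.empty(m)
    adj[order] = q
    out[ok] = adj
    return out


def summarize_tests(results: List[TestResult], fdr_level: float = 0.05,
                    method: str = "bh") -> List[TestResult]:
    """Fill in BH-adjusted p-values and significance flags for one test family."""
    p = [r.p_value for r in results]
    adj = adjust_bh(p, method=method)
    for r, q in zip(results, adj):
        r.p_adjusted = float(q) if np.isfinite(q) else np.nan
        r.significant = bool(q <= fdr_level) if np.isfinite(q) else None
    return results
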