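"""Empirical-Bayes estimation of shared prior hyperparameters.

The hyperparameters of the spike-and-slab prior on the gene-dosage effect
(pi0, tau^2) and of the Gamma priors on the spline and error precisions are
shared by all genes and estimated by maximizing the product of per-gene
marginal likelihoods.  The maximization is approximated by alternating
(i) per-gene posterior fits at the current hyperparameters with (ii) EM /
moment-matching updates of the hyperparameters:

* the mixture weights are updated from posterior inclusion probabilities
  (E-step) and the slab variance by a 1-d search on the inclusion-weighted
  slab evidence (M-step);
* each precision Gamma prior is moment-matched to the across-gene
  distribution of posterior precision means.

Initialization uses a very flat prior on the precisions, which corresponds to
a narrow prior on the spline variance: splines start flat and gain
flexibility only if the data ask for it.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import minimize_scalar

from .data_model import TimeCourseExperiment
from .gene_model import (GeneFit, GenePriors, estimate_dispersion,
                         fit_gaussian, fit_negbin, moderate_dispersions)
from .spline_basis import SplineBasis, orthogonalize

logger = logging.getLogger(__name__)

__all__ = ["EBState", "estimate_hyperparameters", "update_mixture", "update_gamma_prior"]

_SHAPE_FLOOR = 0.01
_RATE_FLOOR = 1e-6
_SHAPE_CAP = 1e4  # numerical guard against degenerate moment-matched priors
_DAMPING = 0.5    # log-space relaxation of precision-prior updates


def _damp(old: float, new: float, w: float = _DAMPING) -> float:
    """Geometric interpolation between successive prior values (stabilizes the
    moment-matching fixed point, which can otherwise oscillate)."""
    return float(np.exp((1.0 - w) * np.log(old) + w * np.log(new)))


@dataclass
class EBState:
    """State of the iterative hyperparameter estimation."""

    iteration: int
    priors: GenePriors
    log_total_marglik: float
    converged: bool
    history: List[dict] = field(default_factory=list)
    fits: Optional[List[GeneFit]] = None

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.history)


def update_mixture(
    evidences: Sequence[Tuple[float, Callable[[float], float]]],
    current: Tuple[float, float],
    tau2_bounds: Tuple[float, float] = (1e-6, 1e3),
) -> Tuple[float, float]:
    """One EM update of the Dirac-Gaussian mixture hyperparameters.

    ``evidences`` holds per-gene ``(log E0, log_E1_fn)`` pairs: the spike
    evidence and the slab evidence as a (cheap) function of the slab variance.
    The E-step computes posterior inclusion probabilities at the current
    values; the M-step sets ``pi0 = 1 - mean(inclusion)`` and maximizes the
    inclusion-weighted slab log-evidence over ``tau^2`` within
    ``tau2_bounds`` (default [1e-6, 1e3]).  Callers may raise the lower
    bound to the measurement-noise floor of the beta estimates: a slab
    narrower than that floor is unidentifiable from the spike, and letting
    tau^2 collapse there freezes pi0 at an arbitrary value.
    """
    pi0, tau2 = current
    if not evidences:
        return pi0, tau2
    log_e0 = np.array([e0 for e0, _ in evidences])
    log_e1 = np.array([fn(tau2) for _, fn in evidences])

    def respons(p0):
        with np.errstate(over="ignore"):
            if p0 >= 1.0:
                return np.zeros_like(log_e0)
            if p0 <= 0.0:
                return np.ones_like(log_e0)
            logit = np.log1p(-p0) + log_e1 - np.log(p0) - log_e0
            return 1.0 / (1.0 + np.exp(-logit))

    # run the inner weight problem (fixed evidences) to its fixed point:
    # a single mean-rule step converges only geometrically near pi0 = 1
    incl = respons(pi0)
    pi0_new = float(1.0 - incl.mean())
    for _ in range(500):
        incl = respons(pi0_new)
        nxt = float(1.0 - incl.mean())
        if abs(nxt - pi0_new) < 1e-10:
            pi0_new = nxt
            break
        pi0_new = nxt
    if incl.mean() < 1e-6:
        warnings.warn("all inclusion probabilities are zero; tau^2 kept at current value")
        return pi0_new, tau2

    fns = [fn for _, fn in evidences]

    def neg(log_tau2):
        t2 = np.exp(log_tau2)
        return -float(sum(w * fn(t2) for w, fn in zip(incl, fns) if w > 1e-8))

    lo, hi = tau2_bounds
    res = minimize_scalar(neg, bounds=(np.log(lo), np.log(hi)), method="bounded",
                          options={"xatol": 1e-4})
    return pi0_new, float(np.exp(res.x))


def update_gamma_prior(
    precision_posteriors: Sequence[Tuple[float, float]],
    current: Optional[Tuple[float, float]] = None,
) -> Tuple[float, float]:
    """Moment-match a Gamma prior to the across-gene posterior precision means.

    With ``m`` and ``v`` the across-gene mean and variance of the per-gene
    posterior precision means, returns ``(shape, rate) = (m^2/v, m/v)``
    (floored at shape >= 0.01, rate >= 1e-6; shape capped at 1e4 to avoid a
    numerically degenerate prior when the means are nearly constant).
    """
    means = np.array([m for m, _ in precision_posteriors], dtype=float)
    if means.size < 2:
        if current is not None:
            return current
        raise ValueError("need at least 2 genes to update the precision prior")
    m = float(means.mean())
    v = float(means.var())
    v = max(v, 1e-12)
    shape = m**2 / v
    if shape > _SHAPE_CAP:
        shape = _SHAPE_CAP
    rate = shape / max(m, 1e-12)
    return max(shape, _SHAPE_FLOOR), max(rate, _RATE_FLOOR)


def _gene_inputs(experiment: TimeCourseExperiment, basis: SplineBasis,
                 use_cn: bool, do_orthogonalize: bool):
    """Per-gene designs: fixed effects, CN covariate, (orthogonalized) basis."""
    X = experiment.line_design()
    cn_mat = experiment.copy_number if use_cn else None
    base_no_cn = None
    inputs = []
    for j in range(experiment.p):
        y = experiment.expression[j]
        cn = None if cn_mat is None else cn_mat[j]
        if cn is not None and np.std(cn) < 1e-12:
            cn = None
        if do_orthogonalize:
            if cn is None:
                if base_no_cn is None:
                    base_no_cn = orthogonalize(basis, X)
                b = base_no_cn
            else:
                b = orthogonalize(basis, np.column_stack([X, cn]))
        else:
            b = basis
        inputs.append((y, X, cn, b))
    return inputs


def estimate_hyperparameters(
    experiment: TimeCourseExperiment,
    basis: Optional[SplineBasis],
    init: Optional[GenePriors] = None,
    max_iter: int = 25,
    tol: float = 1e-4,
    grid_size: int = 7,
    use_cn: bool = True,
    orthogonalize_basis: bool = False,
    dispersions: Optional[np.ndarray] = None,
    offsets: Optional[np.ndarray] = None,
    zero_inflation: Optional[float] = None,
    log_path=None,
) -> EBState:
    """Estimate shared hyperparameters by iterating per-gene fits and updates.

    Returns an :class:`EBState` whose ``priors`` field holds the estimated
    hyperparameters and whose ``fits`` field holds the per-gene fits of the
    final iteration.  ``log_total_marglik`` is the sum of per-gene log
    marginal likelihoods, the objective of the empirical-Bayes procedure; it
    is asserted to be non-decreasing across iterations up to tolerance, with
    violations logged (the updates are EM-style approximations).
    """
    if experiment.p < 50:
        warnings.warn("fewer than 50 genes: hyperparameter estimates may be unstable")
    priors = init or GenePriors()
    gaussian = experiment.family == "gaussian"
    inputs = _gene_inputs(experiment, basis, use_cn, orthogonalize_basis)
    alpha_vars = np.maximum(100.0 * experiment.expression.var(axis=1), 1e-6)
    if not gaussian and dispersions is None:
        lines = experiment.lines
        cn_mat = experiment.copy_number if use_cn else None
        dispersions = np.array([
            estimate_dispersion(experiment.expression[j], lines,
                                cn=None if cn_mat is None else cn_mat[j],
                                offsets=offsets)
            for j in range(experiment.p)
        ])
        dispersions = moderate_dispersions(dispersions)

    history: List[dict] = []
    prev = None
    converged = False
    fits: List[GeneFit] = []
    iteration = 0
    for iteration in range(1, max_iter + 1):
        fits = []
        for j, (y, X, cn, b) in enumerate(inputs):
            pj = replace(priors, alpha_var=float(alpha_vars[j]))
            if gaussian:
                fit = fit_gaussian(y, X, cn=cn, basis=b, priors=pj,
                                   grid_size=grid_size, feature_id=experiment.features[j].feature_id)
            else:
                fit = fit_negbin(y, X, cn=cn, basis=b, priors=pj,
                                 dispersion=float(dispersions[j]),
                                 offsets=offsets, zero_inflation=zero_inflation,
                                 grid_size=grid_size,
                                 feature_id=experiment.features[j].feature_id)
            fits.append(fit)
        log_total = float(sum(f.log_marglik for f in fits))
        if prev is not None and log_total < prev - 1e-4 * (abs(prev) + 1.0):
            logger.warning(
                "EB objective decreased at iteration %d (%.6g -> %.6g)",
                iteration, prev, log_total)
        history.append({
            "iteration": iteration, "log_total_marglik": log_total,
            "beta_pi0": priors.beta_pi0, "beta_tau2": priors.beta_tau2,
            "gamma_prec_shape": priors.gamma_prec_shape,
            "gamma_prec_rate": priors.gamma_prec_rate,
            "eps_prec_shape": priors.eps_prec_shape,
            "eps_prec_rate": priors.eps_prec_rate,
        })
        if prev is not None and abs(log_total - prev) / (abs(prev) + 1.0) < tol:
            converged = True
            break
        prev = log_total

        # ---- hyperparameter updates -----------------------------------
        beta_fits = [f for f in fits if len(f._groups["beta"]) > 0]
        mix_ev = [f.mixture_evidence() for f in beta_fits]
        if mix_ev:
            noise_floor = np.nanmedian([f.beta_likelihood_variance() for f in beta_fits])
            lo = max(1e-6, 0.5 * noise_floor) if np.isfinite(noise_floor) else 1e-6
            pi0, tau2 = update_mixture(mix_ev, (priors.beta_pi0, priors.beta_tau2),
                                       tau2_bounds=(min(lo, 1e3 / 2), 1e3))
            priors = replace(priors, beta_pi0=min(max(pi0, 0.0), 1.0), beta_tau2=tau2)
        gpost = [p for p in (f.gamma_precision_posterior() for f in fits) if p is not None]
        if len(gpost) >= 2:
            shape, rate = update_gamma_prior(
                gpost, (priors.gamma_prec_shape, priors.gamma_prec_rate))
            priors = replace(priors,
                             gamma_prec_shape=_damp(priors.gamma_prec_shape, shape),
                             gamma_prec_rate=_damp(priors.gamma_prec_rate, rate))
        if gaussian:
            epost = [f.eps_precision_posterior() for f in fits]
            shape, rate = update_gamma_prior(
                epost, (priors.eps_prec_shape, priors.eps_prec_rate))
            priors = replace(priors,
                             eps_prec_shape=_damp(priors.eps_prec_shape, shape),
                             eps_prec_rate=_damp(priors.eps_prec_rate, rate))

    if not converged:
        if max_iter > 1:
            warnings.warn(f"EB did not converge in {max_iter} iterations")
        # the loop exited after an update: refit once so the returned fits are
        # consistent with the returned (updated) hyperparameters
        fits = []
        for j, (y, X, cn, b) in enumerate(inputs):
            pj = replace(priors, alpha_var=float(alpha_vars[j]))
            if gaussian:
                fits.append(fit_gaussian(y, X, cn=cn, basis=b, priors=pj,
                                         grid_size=grid_size,
                                         feature_id=experiment.features[j].feature_id))
            else:
                fits.append(fit_negbin(y, X, cn=cn, basis=b, priors=pj,
                                       dispersion=float(dispersions[j]),
                                       offsets=offsets, zero_inflation=zero_inflation,
                                       grid_size=grid_size,
                                       feature_id=experiment.features[j].feature_id))
    state = EBState(iteration=iteration, priors=priors,
                    log_total_marglik=history[-1]["log_total_marglik"] if history else np.nan,
                    converged=converged, history=history, fits=fits)
    if log_path is not None:
        state.to_frame().to_csv(log_path, sep="\t", index=False)
    return state
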