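"""AR(1) spatial prior on gene-dosage effects along the genome.

Copy-number aberrations span regions harbouring many genes, so the dosage
effects of genomically adjacent genes are correlated.  This is modelled by a
first-order autoregressive process beta_j = rho * beta_{j-1} + e_j along each
chromosome.  ``rho`` is estimated by regressing beta_j on beta_{j-1} (pooled
across chromosomes, pairs never straddling a boundary).  The model is then
refitted per triplet of neighbouring genes with a trivariate Gaussian prior
N(0, tau^2 R), R_ab = rho^{|a-b|}, on the three dosage effects; only the
middle gene's estimate is kept.  Chromosome-edge genes use the analogous
doublet prior.  Refits condition on each gene's posterior-mean variance
components from the univariate pass, and the spike component is dropped
inside the joint prior (pure Gaussian AR(1) slab).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .data_model import TimeCourseExperiment
from .gene_model import GeneFit, GenePriors
from .inference import TestResult, summarize_tests

logger = logging.getLogger(__name__)

__all__ = ["SpatialModel", "estimate_rho", "refit_triplets", "cn_tests_after_spatial"]

_RHO_CLAMP = 0.99


@dataclass
class SpatialModel:
    rho: float
    per_chromosome: bool
    beta_updated: np.ndarray
    lag1_partial_correlation_before: float
    lag1_partial_correlation_after: float
    gene_indices: List[int] = field(default_factory=list)
    fitted_updated: Dict[int, np.ndarray] = field(default_factory=dict)
    sigma2_eps: Dict[int, float] = field(default_factory=dict)


def _lag1_pairs(beta: np.ndarray, chromosomes: np.ndarray,
                center: bool = False) -> Tuple[np.ndarray, np.ndarray]:
    """Consecutive (beta_{j-1}, beta_j) pairs, never straddling a chromosome.

    With ``center=True`` each chromosome's series is mean-centred first, so a
    chromosome-level offset cannot masquerade as lag-1 dependence."""
    prev, nxt = [], []
    for c in pd_unique(chromosomes):
        idx = np.flatnonzero(chromosomes == c)
        if idx.size < 2:
            continue
        b = beta[idx]
        if center:
            b = b - b.mean()
        prev.append(b[:-1])
        nxt.append(b[1:])
    if not prev:
        return np.array([]), np.array([])
    return np.concatenate(prev), np.concatenate(nxt)


def pd_unique(values: np.ndarray) -> np.ndarray:
    """Unique values in order of first appearance."""
    _, idx = np.unique(values, return_index=True)
    return values[np.sort(idx)]


def lag1_correlation(beta: np.ndarray, chromosomes: np.ndarray) -> float:
    """Lag-1 correlation of the beta series (for an AR(1) series this equals
    the lag-1 partial autocorrelation)."""
    x, y = _lag1_pairs(np.asarray(beta, float), np.asarray(chromosomes))
    if x.size < 3 or np.std(x) == 0 or np.std(y) == 0:
        return np.nan
    return float(stats.pearsonr(x, y)[0])


def estimate_rho(beta_hat: np.ndarray, chromosome_ids: np.ndarray) -> float:
    """OLS slope of beta_j on beta_{j-1}, pooled within chromosomes.

    The result is clamped to (-0.99, 0.99) so the AR(1) prior correlation
    matrix stays positive definite.
    """
    beta_hat = np.asarray(beta_hat, dtype=float)
    if beta_hat.size < 10:
        raise ValueError("need at least 10 features with beta estimates")
    x, y = _lag1_pairs(beta_hat, np.asarray(chromosome_ids), center=True)
    if x.size < 2 or np.var(x) == 0:
        raise ValueError("zero variance of lagged beta; rho undefined")
    xc = x - x.mean()
    slope = float(np.sum(xc * (y - y.mean())) / np.sum(xc**2))
    return float(np.clip(slope, -_RHO_CLAMP, _RHO_CLAMP))


def _gene_blocks(fit: GeneFit):
    """Design, response and fixed prior precisions of one gene's slab model."""
    W = fit._W
    groups = fit._groups
    d = W.shape[1]
    prior_prec = np.zeros(d)  # beta entries stay 0; the AR(1) precision is added jointly
    prior_prec[np.array(groups["alpha"], dtype=int)] = 1.0 / fit._priors.alpha_var
    if groups["gamma"]:
        s2g = fit.sigma2_gamma_mean
        if not np.isfinite(s2g) or s2g <= 0:
            s2g = 1e-8
        prior_prec[np.array(groups["gamma"], dtype=int)] = 1.0 / s2g
    beta_pos = groups["beta"][0] if groups["beta"] else None
    return W, fit._y, prior_prec, beta_pos, fit.sigma2_eps_mean


def _joint_refit(fits: Sequence[GeneFit], rho: float, tau2: float):
    """Joint Gaussian refit of 1-3 genes with an AR(1) prior on their betas.

    Conditions on each gene's posterior-mean sigma^2_eps and sigma^2_gamma.
    Returns the stacked posterior mean split per gene.
    """
    k = len(fits)
    blocks = [_gene_blocks(f) for f in fits]
    dims = [b[0].shape[1] for b in blocks]
    offsets = np.concatenate([[0], np.cumsum(dims)])
    D = offsets[-1]
    A = np.zeros((D, D))
    rhs = np.zeros(D)
    beta_pos_global = []
    for g, (W, y, prior_prec, beta_pos, s2e) in enumerate(blocks):
        sl = slice(offsets[g], offsets[g + 1])
        A[sl, sl] = W.T @ W / s2e + np.diag(prior_prec)
        rhs[offsets[g]:offsets[g + 1]] = W.T @ y / s2e
        if beta_pos is None:
            raise ValueError("spatial refit requires a copy-number effect in every gene")
        beta_pos_global.append(offsets[g] + beta_pos)
    R = rho ** np.abs(np.subtract.outer(np.arange(k), np.arange(k)))
    Rinv = np.linalg.inv(R) / tau2
    for a in range(k):
        for b in range(k):
            A[beta_pos_global[a], beta_pos_global[b]] += Rinv[a, b]
    mean = np.linalg.solve(A, rhs)
    return [mean[offsets[g]:offsets[g + 1]] for g in range(k)], beta_pos_global, offsets


def refit_triplets(
    experiment: TimeCourseExperiment,
    fits: Sequence[GeneFit],
    rho: float,
    hyper: GenePriors,
) -> SpatialModel:
    """Refit dosage effects triplet-wise under the AR(1) prior.

    ``fits`` must be the univariate (per-gene) fits, in the experiment's
    genome order.  Genes without a usable copy-number covariate keep their
    univariate estimate.  Returns a :class:`SpatialModel` with the updated
    beta vector and the lag-1 correlation of the series before and after.
    """
    if experiment.family != "gaussian":
        raise NotImplementedError("spatial refitting is implemented for the gaussian family")
    p = len(fits)
    if p != experiment.p:
        raise ValueError("one fit per experiment feature required")
    chroms = np.array([f.chromosome for f in experiment.features])
    has_beta = np.array([len(f._groups["beta"]) > 0 for f in fits])
    beta_in = np.array([f.beta_mean for f in fits], dtype=float)
    beta_out = beta_in.copy()
    tau2 = hyper.beta_tau2
    model = SpatialModel(
        rho=float(rho), per_chromosome=False, beta_updated=beta_out,
        lag1_partial_correlation_before=np.nan, lag1_partial_correlation_after=np.nan,
    )
    for c in pd_unique(chroms):
        idx = np.flatnonzero((chroms == c) & has_beta)
        if idx.size < 3:
            if idx.size:
                logger.info("chromosome %s has %d usable genes; univariate estimates kept",
                            c, idx.size)
            continue
        for pos in range(idx.size):
            if pos == 0:
                members, keep = idx[[0, 1]], 0
            elif pos == idx.size - 1:
                members, keep = idx[[-2, -1]], 1
            else:
                members, keep = idx[[pos - 1, pos, pos + 1]], 1
            means, beta_pos, offsets = _joint_refit([fits[m] for m in members], rho, tau2)
            j = members[keep]
            mean_j = means[keep]
            beta_out[j] = mean_j[fits[j]._groups["beta"][0]]
            fitted = fits[j]._W @ mean_j
            model.fitted_updated[int(j)] = fitted
            model.sigma2_eps[int(j)] = fits[j].sigma2_eps_mean
            model.gene_indices.append(int(j))
    usable = has_beta
    model.lag1_partial_correlation_before = lag1_correlation(beta_in[usable], chroms[usable])
    model.lag1_partial_correlation_after = lag1_correlation(beta_out[usable], chroms[usable])
    model.beta_updated = beta_out
    return model


def cn_tests_after_spatial(
    model: SpatialModel,
    fits_full: Sequence[GeneFit],
    fits_reduced: Sequence[GeneFit],
    fdr_level: float = 0.05,
) -> List[TestResult]:
    """Re-evaluate the copy-number LRT using the spatially refitted parameters.

    The full-model likelihood is computed at the triplet-refit posterior mean
    (with each gene's univariate sigma^2_eps); the reduced model is the
    beta-free fit from the univariate pass.
    """
    from .inference import data_loglik

    results = []
    for j, (ff, fr) in enumerate(zip(fits_full, fits_reduced)):
        if j in model.fitted_updated:
            y = ff._y
            s2 = model.sigma2_eps[j]
            resid = y - model.fitted_updated[j]
            ll_full = float(np.sum(stats.norm.logpdf(resid, scale=np.sqrt(s2))))
        else:
            ll_full = data_loglik(ff)
        stat = max(2.0 * (ll_full - data_loglik(fr)), 0.0)
        p = 1.0 if stat == 0.0 else float(stats.chi2.sf(stat, 1.0))
        results.append(TestResult(feature_id=ff.feature_id, statistic=stat, df=1.0,
                                  p_value=p, test="cn_effect"))
    return summarize_tests(results, fdr_level=fdr_level)
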