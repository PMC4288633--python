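"""End-to-end analysis: basis construction, EB estimation, tests, spatial refit.

This is the library-level orchestration the command-line interface wraps:
build the (optionally per-line, optionally orthogonalized) spline basis,
estimate shared hyperparameters by empirical Bayes on the full model, refit
every gene and its reduced counterparts under those hyperparameters, run the
likelihood-ratio tests with BH-FDR control, and optionally apply the AR(1)
spatial refit of the dosage effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional

import numpy as np
import pandas as pd

from .data_model import TimeCourseExperiment
from .empirical_bayes import EBState, estimate_hyperparameters, _gene_inputs
from .gene_model import (GeneFit, GenePriors, estimate_dispersion,
                         fit_gaussian, fit_negbin, moderate_dispersions)
from .inference import TestResult, lrt_copy_number, lrt_temporal, summarize_tests
from .spatial_prior import SpatialModel, cn_tests_after_spatial, estimate_rho, refit_triplets
from .spline_basis import SplineBasis, build_basis, expand_per_line, place_knots

__all__ = ["PipelineResult", "run_pipeline", "no_shrinkage_priors"]


def no_shrinkage_priors() -> GenePriors:
    """Fixed, weakly informative priors used when EB information borrowing is off."""
    return GenePriors(beta_pi0=0.5, beta_tau2=1.0,
                      gamma_prec_shape=0.01, gamma_prec_rate=0.01,
                      eps_prec_shape=0.01, eps_prec_rate=0.01)


@dataclass
class PipelineResult:
    table: pd.DataFrame
    eb_state: EBState
    fits_full: List[GeneFit]
    fits_no_spline: Optional[List[GeneFit]] = None
    fits_no_cn: Optional[List[GeneFit]] = None
    temporal: Optional[List[TestResult]] = None
    cn_effect: Optional[List[TestResult]] = None
    spatial: Optional[SpatialModel] = None
    cn_effect_spatial: Optional[List[TestResult]] = None
    basis: Optional[SplineBasis] = None


def _refit(experiment, basis, priors, grid_size, use_cn, orthogonalize_basis,
           dispersions, offsets, zero_inflation, drop_spline=False):
    """Fit every gene under fixed shared priors (full or reduced design)."""
    gaussian = experiment.family == "gaussian"
    inputs = _gene_inputs(experiment, basis, use_cn, orthogonalize_basis and not drop_spline)
    alpha_vars = np.maximum(100.0 * experiment.expression.var(axis=1), 1e-6)
    fits = []
    for j, (y, X, cn, b) in enumerate(inputs):
        pj = replace(priors, alpha_var=float(alpha_vars[j]))
        fid = experiment.features[j].feature_id
        b_use = None if drop_spline else b
        if gaussian:
            fits.append(fit_gaussian(y, X, cn=cn, basis=b_use, priors=pj,
                                     grid_size=grid_size, feature_id=fid))
        else:
            fits.append(fit_negbin(y, X, cn=cn, basis=b_use, priors=pj,
                                   dispersion=float(dispersions[j]), offsets=offsets,
                                   zero_inflation=zero_inflation, grid_size=grid_size,
                                   feature_id=fid))
    return fits


def run_pipeline(
    experiment: TimeCourseExperiment,
    K: int = 2,
    per_line: bool = False,
    orthogonalize: bool = False,
    spatial: bool = False,
    fdr_level: float = 0.05,
    eb: bool = True,
    eb_max_iter: int = 8,
    eb_tol: float = 1e-4,
    grid_size: int = 7,
    use_cn: bool = True,
    zero_inflation: Optional[float] = None,
    seed: int = 0,
) -> PipelineResult:
    """Run the full analysis on a loaded experiment.

    With ``eb=False`` the shared priors stay at their weakly informative
    initial values (no borrowing of information across genes); this is mainly
    useful for reproducibility comparisons.
    """
    use_cn = use_cn and experiment.copy_number is not None
    if spatial and not use_cn:
        raise ValueError("spatial refitting requires copy number data")
    times = experiment.times
    knots = place_knots(times, K)
    basis = build_basis(times, knots)
    if per_line:
        basis = expand_per_line(basis, experiment.n_lines)

    gaussian = experiment.family == "gaussian"
    dispersions = None
    if not gaussian:
        lines = experiment.lines
        cn_mat = experiment.copy_number if use_cn else None
        dispersions = np.array([
            estimate_dispersion(experiment.expression[j], lines,
                                cn=None if cn_mat is None else cn_mat[j])
            for j in range(experiment.p)])
        dispersions = moderate_dispersions(dispersions)

    init = no_shrinkage_priors()
    if eb:
        state = estimate_hyperparameters(
            experiment, basis, init=init, max_iter=eb_max_iter, tol=eb_tol,
            grid_size=grid_size, use_cn=use_cn, orthogonalize_basis=orthogonalize,
            dispersions=dispersions, zero_inflation=zero_inflation)
        priors = state.priors
        fits_full = state.fits
    else:
        priors = init
        fits_full = _refit(experiment, basis, priors, grid_size, use_cn,
                           orthogonalize, dispersions, None, zero_inflation)
        state = EBState(iteration=0, priors=priors, log_total_marglik=float(
            sum(f.log_marglik for f in fits_full)), converged=True, fits=fits_full)

    fits_no_spline = _refit(experiment, basis, priors, grid_size, use_cn,
                            orthogonalize, dispersions, None, zero_inflation,
                            drop_spline=True)
    temporal = summarize_tests(
        [lrt_temporal(f, r) for f, r in zip(fits_full, fits_no_spline)],
        fdr_level=fdr_level)

    fits_no_cn = None
    cn_tests = None
    spatial_model = None
    cn_tests_spatial = None
    if use_cn:
        fits_no_cn = _refit(experiment, basis, priors, grid_size, False,
                            orthogonalize, dispersions, None, zero_inflation)
        cn_tests = summarize_tests(
            [lrt_copy_number(f, r) for f, r in zip(fits_full, fits_no_cn)],
            fdr_level=fdr_level)
        if spatial:
            beta = np.array([f.beta_mean for f in fits_full])
            chroms = np.array([f.chromosome for f in experiment.features])
            rho = estimate_rho(beta, chroms)
            spatial_model = refit_triplets(experiment, fits_full, rho, priors)
            cn_tests_spatial = cn_tests_after_spatial(
                spatial_model, fits_full, fits_no_cn, fdr_level=fdr_level)

    rows = []
    for j in range(experiment.p):
        row = {
            "feature_id": experiment.features[j].feature_id,
            "chromosome": experiment.features[j].chromosome,
            "beta_mean": fits_full[j].beta_mean,
            "beta_inclusion": fits_full[j].beta_inclusion,
            "temporal_stat": temporal[j].statistic,
            "temporal_df": temporal[j].df,
            "temporal_p": temporal[j].p_value,
            "temporal_p_adj": temporal[j].p_adjusted,
            "temporal_significant": temporal[j].significant,
        }
        if cn_tests is not None:
            row.update({
                "cn_stat": cn_tests[j].statistic,
                "cn_p": cn_tests[j].p_value,
                "cn_p_adj": cn_tests[j].p_adjusted,
                "cn_significant": cn_tests[j].significant,
            })
        if spatial_model is not None:
            row["beta_spatial"] = spatial_model.beta_updated[j]
            row["cn_spatial_p_adj"] = cn_tests_spatial[j].p_adjusted
            row["cn_spatial_significant"] = cn_tests_spatial[j].significant
        rows.append(row)

    return PipelineResult(
        table=pd.DataFrame(rows), eb_state=state, fits_full=fits_full,
        fits_no_spline=fits_no_spline, fits_no_cn=fits_no_cn,
        temporal=temporal, cn_effect=cn_tests, spatial=spatial_model,
        cn_effect_spatial=cn_tests_spatial, basis=basis)
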