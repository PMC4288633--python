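"""Synthetic matched copy-number / expression time courses with known truth.

The generator emulates the two study designs the method targets: a
microarray-style design (four cell lines assayed at eight time points, with a
matched segmented copy-number profile and a minority of genes whose
expression is truly dosage-driven) and an RNA-seq-style count design (two
conditions at six time points).

Copy number is simulated segment-wise along a synthetic genome: segment
lengths are geometric, each (segment, line) pair acquires an aberration level
at a random change-point in time, and levels are AR(1)-correlated across
adjacent segments.  All genes in a segment share the segment's copy-number
signature, which induces the spatial correlation of estimated dosage effects
that the AR(1) prior exploits.  Dosage effects are spike-and-slab by default
(or an explicit AR(1) series via ``beta_ar1_rho``); temporal signal is drawn
from the model's own thin-plate basis family (or out-of-family sinusoids for
robustness checks).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
from scipy import stats

from .data_model import FeatureAnnotation, SampleAnnotation, TimeCourseExperiment
from .spline_basis import build_basis, place_knots

__all__ = ["SimulationConfig", "GroundTruth", "simulate_experiment", "split_half"]


@dataclass
class SimulationConfig:
    """Parameters of the generator; the defaults emulate the four-line,
    eight-time-point matched microarray design."""

    n_lines: int = 4
    n_times: int = 8
    n_genes: int = 1000
    frac_cn_effect: float = 0.1
    beta_slab_sd: float = 1.0
    cn_ar1_rho: float = 0.3
    cn_segment_length_mean: float = 10.0
    spline_signal_sd: float = 1.0
    frac_temporal: float = 0.2
    noise_sd: float = 0.5
    alpha_sd: float = 1.0
    family: str = "gaussian"
    nb_dispersion: float = 3.0
    nb_log_baseline: Tuple[float, float] = (4.0, 0.7)
    per_line_splines: bool = False
    K: int = 2
    beta_ar1_rho: Optional[float] = None
    out_of_family_temporal: bool = False
    with_cn: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in ("n_lines", "n_times", "n_genes"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0.0 <= self.frac_cn_effect <= 1.0:
            raise ValueError("frac_cn_effect must be in [0, 1]")
        if not 0.0 <= self.frac_temporal <= 1.0:
            raise ValueError("frac_temporal must be in [0, 1]")


@dataclass
class GroundTruth:
    beta_true: np.ndarray
    temporal_true: np.ndarray
    gamma_true: np.ndarray
    family: str
    segment_of_gene: np.ndarray = None


def _simulate_cn(cfg: SimulationConfig, rng: np.random.Generator,
                 times: np.ndarray, lines: np.ndarray):
    """Segment-wise piecewise-constant copy number with temporal change-points."""
    p = cfg.n_genes
    seg_of_gene = np.empty(p, dtype=int)
    g = 0
    seg = 0
    while g < p:
        length = rng.geometric(1.0 / cfg.cn_segment_length_mean)
        seg_of_gene[g:g + length] = seg
        g += length
        seg += 1
    n_seg = seg
    N = times.size
    x_seg = np.zeros((n_seg, N))
    uniq_lines = np.unique(lines)
    for li in uniq_lines:
        cols = np.flatnonzero(lines == li)
        t_line = times[cols]
        # AR(1) levels across adjacent segments within a line
        innov = rng.standard_normal(n_seg)
        level = np.empty(n_seg)
        level[0] = innov[0]
        for s in range(1, n_seg):
            level[s] = cfg.cn_ar1_rho * level[s - 1] + \
                np.sqrt(1.0 - cfg.cn_ar1_rho**2) * innov[s]
        t_sorted = np.unique(t_line)
        for s in range(n_seg):
            # aberration acquired at a random change-point (never the first time)
            t0 = t_sorted[rng.integers(1, t_sorted.size)] if t_sorted.size > 1 else t_sorted[0]
            x_seg[s, cols] = np.where(t_line >= t0, level[s], 0.0)
    return x_seg[seg_of_gene], seg_of_gene


def simulate_experiment(cfg: SimulationConfig) -> Tuple[TimeCourseExperiment, GroundTruth]:
    """Generate a matched experiment and its ground truth, reproducibly from seed."""
    rng = np.random.default_rng(cfg.seed)
    n, T, p = cfg.n_lines, cfg.n_times, cfg.n_genes
    N = n * T
    time_grid = np.arange(1.0, T + 1.0)
    lines = np.repeat(np.arange(n), T)
    times = np.tile(time_grid, n)
    samples = [
        SampleAnnotation(f"L{li + 1}_t{int(t)}", f"line{li + 1}", float(t))
        for li, t in zip(lines, times)
    ]
    features = [
        FeatureAnnotation(f"gene{j + 1:05d}", "chr1", j * 1000, j * 1000 + 500, j)
        for j in range(p)
    ]

    cn = None
    seg_of_gene = np.zeros(p, dtype=int)
    if cfg.with_cn:
        cn, seg_of_gene = _simulate_cn(cfg, rng, times, lines)

    # dosage effects
    if cfg.beta_ar1_rho is not None:
        rho = cfg.beta_ar1_rho
        innov = rng.standard_normal(p)
        beta = np.empty(p)
        beta[0] = innov[0] * cfg.beta_slab_sd
        for j in range(1, p):
            beta[j] = rho * beta[j - 1] + \
                cfg.beta_slab_sd * np.sqrt(1.0 - rho**2) * innov[j]
    else:
        nonzero = rng.random(p) < cfg.frac_cn_effect
        beta = np.where(nonzero, rng.normal(0.0, cfg.beta_slab_sd, size=p), 0.0)
    if not cfg.with_cn:
        beta = np.zeros(p)

    # temporal signal from the model's own basis family (or sinusoids)
    temporal = rng.random(p) < cfg.frac_temporal
    knots = place_knots(time_grid, cfg.K)
    basis = build_basis(times, knots)
    n_curves = n if cfg.per_line_splines else 1
    gamma_true = np.zeros((p, n_curves, cfg.K))
    curves = np.zeros((p, N))
    for j in np.flatnonzero(temporal):
        if cfg.out_of_family_temporal:
            for c in range(n_curves):
                amp = rng.normal(0.0, cfg.spline_signal_sd)
                phase = rng.uniform(0, 2 * np.pi)
                wave = amp * np.sin(2 * np.pi * times / T + phase)
                rows = slice(None) if n_curves == 1 else (lines == c)
                curves[j, rows] = wave[rows]
        else:
            scale = cfg.spline_signal_sd / max(np.std(basis.design), 1e-12)
            for c in range(n_curves):
                g = rng.normal(0.0, scale, size=basis.design.shape[1])
                gamma_true[j, c] = g
                wave = basis.design @ g
                rows = slice(None) if n_curves == 1 else (lines == c)
                curves[j, rows] = wave[rows]

    alpha = rng.normal(0.0, cfg.alpha_sd, size=(p, n))
    eta = alpha[:, lines] + curves
    if cfg.with_cn:
        eta = eta + beta[:, None] * cn

    if cfg.family == "gaussian":
        expr = eta + rng.normal(0.0, cfg.noise_sd, size=eta.shape)
        family = "gaussian"
    else:
        mu0, sd0 = cfg.nb_log_baseline
        baseline = rng.normal(mu0, sd0, size=p)
        # alpha plays the role of a modest condition effect on the log scale
        log_mu = baseline[:, None] + 0.3 * alpha[:, lines] + curves
        if cfg.with_cn:
            log_mu = log_mu + beta[:, None] * cn
        mu = np.exp(np.clip(log_mu, -20, 20))
        r = cfg.nb_dispersion
        expr = rng.negative_binomial(r, r / (r + mu)).astype(float)
        family = "negative_binomial"

    exp = TimeCourseExperiment(
        expression=expr, copy_number=cn, samples=samples, features=features,
        family=family)
    truth = GroundTruth(beta_true=beta, temporal_true=temporal,
                        gamma_true=gamma_true, family=family,
                        segment_of_gene=seg_of_gene)
    return exp, truth


def split_half(experiment: TimeCourseExperiment, seed: int = 0):
    """Randomly partition the cell lines into two balanced halves.

    Supports the reproducibility protocol: the same analysis is run on both
    halves and the overlap of significant features is compared.
    """
    labels = sorted(set(s.line for s in experiment.samples))
    if len(labels) < 2:
        raise ValueError("need at least 2 lines to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(labels))
    half = len(labels) // 2
    set_a = {labels[i] for i in perm[:half]}
    idx_a = [i for i, s in enumerate(experiment.samples) if s.line in set_a]
    idx_b = [i for i, s in enumerate(experiment.samples) if s.line not in set_a]
    return experiment.subset_samples(idx_a), experiment.subset_samples(idx_b)
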