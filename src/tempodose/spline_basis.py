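"""Low-rank thin-plate spline bases for time-course mixed models.

The temporal random effect of each gene is modelled with the radial basis
``|t - kappa_k|^3`` at a small set of fixed, equally spaced interior knots
``kappa_1 < ... < kappa_K``.  The raw basis is penalized through the matrix
``Omega`` of cubed inter-knot distances; multiplying the raw basis by
``Omega^{-1/2}`` (via SVD) re-parameterizes the spline so its coefficients can
be treated as exchangeable iid Gaussian random effects, which is the form the
per-gene mixed model consumes.

Two design-time variants are supported: a block-diagonal expansion giving each
cell line its own spline (Kronecker structure over lines), and an
orthogonalized variant in which the spline design is projected onto the
orthocomplement of the fixed-effect columns (cell-line indicators and,
per gene, the copy-number profile) so that copy number is given precedence
over the spline in explaining expression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = [
    "SplineBasis",
    "place_knots",
    "build_basis",
    "omega_half_inverse",
    "expand_per_line",
    "orthogonalize",
]

# relative singular-value cutoff below which directions are dropped, not amplified
_SV_RTOL = 1e-10


@dataclass
class SplineBasis:
    """A reparameterized low-rank thin-plate spline design.

    Attributes
    ----------
    knots : (K,) array
        Strictly increasing interior knots.
    times : (N,) array
        Observation times, one per sample row of the design.
    Z_raw : (N, K) array
        Raw radial basis, ``Z_raw[s, k] = |t_s - kappa_k|^3``.
    omega : (K, K) array
        Penalty matrix, ``omega[k, l] = |kappa_k - kappa_l|^3``.
    Z_reparam : (N, K') array
        Design after multiplication by ``omega^{-1/2}`` (and, possibly,
        per-line expansion / orthogonalization).  ``K'`` equals ``K`` for the
        plain basis and ``n_lines * K`` after per-line expansion.
    per_line : bool
        Whether the design is the block-diagonal per-line expansion.
    n_lines : int
        Number of line blocks (1 unless ``per_line``).
    orthogonalized_against : (N, q) array or None
        The fixed design used for projection, if any.
    """

    knots: np.ndarray
    times: np.ndarray
    Z_raw: np.ndarray
    omega: np.ndarray
    Z_reparam: np.ndarray
    per_line: bool = False
    n_lines: int = 1
    orthogonalized_against: Optional[np.ndarray] = None

    @property
    def K(self) -> int:
        return len(self.knots)

    @property
    def n_columns(self) -> int:
        return self.Z_reparam.shape[1]

    @property
    def design(self) -> np.ndarray:
        """The (N, K') design matrix entering the mixed model."""
        return self.Z_reparam


def place_knots(times: np.ndarray, K: int) -> np.ndarray:
    """Place ``K`` equally spaced interior knots on [min(times), max(times)].

    ``kappa_k = t_min + k * (t_max - t_min) / (K + 1)`` for ``k = 1..K``, so
    the knots are strictly interior to the observed time range.
    """
    times = np.asarray(times, dtype=float)
    distinct = np.unique(times)
    if distinct.size < 2:
        raise ValueError("need at least 2 distinct time points to place knots")
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > distinct.size - 1:
        raise ValueError(
            f"K={K} too large for {distinct.size} distinct time points; "
            f"use K <= {distinct.size - 1}"
        )
    t_min, t_max = distinct[0], distinct[-1]
    k = np.arange(1, K + 1, dtype=float)
    return t_min + k * (t_max - t_min) / (K + 1)


def omega_half_inverse(omega: np.ndarray) -> np.ndarray:
    """Inverse square root of the penalty matrix via SVD.

    With ``omega = U D V^T``, returns ``V D^{-1/2} U^T``; singular values below
    ``1e-10 * max(D)`` are pseudo-inverted to zero (directions dropped rather
    than amplified).
    """
    omega = np.asarray(omega, dtype=float)
    if omega.ndim != 2 or omega.shape[0] != omega.shape[1]:
        raise ValueError("omega must be square")
    if not np.allclose(omega, omega.T, atol=1e-12):
        raise ValueError("omega must be symmetric")
    U, s, Vt = np.linalg.svd(omega)
    smax = s.max() if s.size else 0.0
    inv_sqrt = np.where(s > _SV_RTOL * smax, 1.0 / np.sqrt(np.maximum(s, 1e-300)), 0.0)
    return Vt.T @ np.diag(inv_sqrt) @ U.T


def build_basis(times: np.ndarray, knots: np.ndarray) -> SplineBasis:
    """Build the reparameterized thin-plate basis at the given knots.

    For ``K = 1`` the penalty matrix ``|kappa - kappa|^3`` degenerates to the
    1x1 zero matrix; it is replaced by ``[[1.]]`` so that the single basis
    column is simply the raw ``|t - kappa|^3`` profile.
    """
    times = np.asarray(times, dtype=float)
    knots = np.asarray(knots, dtype=float)
    if knots.ndim != 1 or knots.size < 1:
        raise ValueError("knots must be a non-empty 1-d array")
    if np.any(np.diff(knots) <= 0):
        raise ValueError("knots must be strictly increasing (no duplicates)")
    Z_raw = np.abs(times[:, None] - knots[None, :]) ** 3
    if knots.size == 1:
        omega = np.array([[1.0]])
    else:
        omega = np.abs(knots[:, None] - knots[None, :]) ** 3
    M = omega_half_inverse(omega)
    Z_reparam = Z_raw @ M
    # numerical full-column-rank check on the retained span
    rank = np.linalg.matrix_rank(Z_reparam, tol=1e-10 * max(1.0, np.abs(Z_reparam).max()))
    if rank < min(Z_reparam.shape):
        warnings.warn(
            "reparameterized spline design is numerically rank deficient; "
            "consider fewer knots",
            stacklevel=2,
        )
    return SplineBasis(knots=knots, times=times, Z_raw=Z_raw, omega=omega, Z_reparam=Z_reparam)


def expand_per_line(
    basis: SplineBasis, n_lines: int, lines: Optional[np.ndarray] = None
) -> SplineBasis:
    """Give each cell line its own copy of the spline (block-diagonal design).

    Samples must be ordered line-major (all samples of line 1, then line 2,
    ...), matching the likelihood ordering of the per-gene response vector.
    ``lines`` may be passed explicitly; by default ``N`` is split into
    ``n_lines`` contiguous equal blocks.
    """
    if basis.per_line:
        raise ValueError("basis is already expanded per line")
    N, K = basis.Z_reparam.shape
    if n_lines == 1:
        return replace(basis)
    if lines is None:
        if N % n_lines != 0:
            raise ValueError(
                f"N={N} not divisible by n_lines={n_lines}; pass explicit line labels"
            )
        T = N // n_lines
        lines = np.repeat(np.arange(n_lines), T)
    else:
        lines = np.asarray(lines)
        codes = np.unique(lines)
        if codes.size != n_lines:
            raise ValueError("number of distinct line labels does not match n_lines")
        # line-major check: labels must form contiguous runs
        change = np.flatnonzero(lines[1:] != lines[:-1]).size
        if change != n_lines - 1:
            raise ValueError("samples are not ordered line-major; sort by (line, time) first")
        lines = np.searchsorted(codes, lines)
    Z = np.zeros((N, n_lines * K))
    for i in range(n_lines):
        rows = lines == i
        Z[rows, i * K : (i + 1) * K] = basis.Z_reparam[rows]
    return replace(basis, Z_reparam=Z, per_line=True, n_lines=n_lines)


def orthogonalize(basis: SplineBasis, fixed_design: np.ndarray) -> SplineBasis:
    """Project the spline design onto the orthocomplement of the fixed design.

    ``Z <- (I - P) Z`` with ``P`` the orthogonal projector onto the column
    span of ``fixed_design``.  The span of ``[fixed_design, Z]`` (and hence
    the saturated fit) is preserved, but the spline can no longer absorb
    variation explainable by the fixed effects (in particular copy number).
    """
    F = np.asarray(fixed_design, dtype=float)
    if F.ndim != 2 or F.shape[0] != basis.Z_reparam.shape[0]:
        raise ValueError("fixed_design must be a matrix with one row per sample")
    Q, R = np.linalg.qr(F)
    diag = np.abs(np.diag(R))
    tol = 1e-10 * max(1.0, diag.max() if diag.size else 0.0)
    bad = np.flatnonzero(diag < tol)
    if bad.size:
        raise ValueError(f"fixed_design is rank deficient; collinear columns: {bad.tolist()}")
    Z_new = basis.Z_reparam - Q @ (Q.T @ basis.Z_reparam)
    if np.abs(Z_new).max() < 1e-10 * max(1.0, np.abs(basis.Z_reparam).max()):
        warnings.warn(
            "spline design entirely within the fixed-design span; "
            "spline fully absorbed by fixed effects",
            stacklevel=2,
        )
    return replace(basis, Z_reparam=Z_new, orthogonalized_against=F)
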