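"""Spatio-temporal receptive-field estimation from shifted-dense-noise
responses.

The response variable is the positive part of the temporal gradient of the
detrended calcium trace, ``cdot = max(0, d/dt r_detrend)``, upsampled to ten
times the 5 Hz stimulus rate. The RF ``F(x, y, tau) = S b`` lives on a
(32, 20, 15) grid (fine pixels x lags) and is parameterised by a cubic
B-spline tensor basis with (10, 12, 9) coefficients; the weights ``b`` and an
intercept ``y0`` minimise

    L = (1/T) sum_t (cdot(t) - y0 - X(t) S b)^2 + beta * |b|_1

with Adam (learning rate 0.1, 100-2000 steps, stopping after five steps
without improvement and keeping the lowest-loss parameters). Internally the
quadratic part is preconditioned by Cholesky-whitening the centred Gram
matrix of the projected features; the loss, its minimiser and the Adam
update rule are unchanged, only the coordinate system is better conditioned.

Fitted RFs are smoothed per lag frame (5 x 5 Gaussian, sigma = 1 px), split
into a temporal and a spatial component by a rank-1 SVD, the spatial
component is fit with an elliptical 2D Gaussian, and the RF size is the area
covered by two standard deviations of that fit. Quality gates: QI_SVD > 0.5,
QI_sRF > 0.5 and a main temporal peak lag between 0 and 0.3 s.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
from scipy.interpolate import BSpline
from scipy.linalg import cholesky, solve_triangular
from scipy.ndimage import gaussian_filter
from scipy.optimize import least_squares
from scipy.signal import find_peaks

from . import RECORDING_RATE_HZ

__all__ = [
    "SplineBasis",
    "RFModel",
    "GaussianFit",
    "FitResult",
    "LAGS_S",
    "PIXEL_SIZE_UM",
    "clipped_gradient",
    "upsample_pair",
    "build_design",
    "fit_rf",
    "closed_form_lstsq",
    "assemble_rf",
    "smooth_rf",
    "svd_split",
    "fit_spatial_gaussian",
    "rf_size",
    "corrected_sigmas_um",
    "temporal_peaks",
    "rf_quality_gate",
    "estimate_rf",
]

PIXEL_SIZE_UM = 12.5
"""Fine-grid pixel size for the (32, 20) spatial RF window (400 x 250 um)."""

GRID_SHAPE = (32, 20, 15)
N_KNOTS = (10, 12, 9)
LAGS_S = np.linspace(-0.20, 1.35, GRID_SHAPE[2])
"""Lag axis, ascending; positive lags = stimulus preceding the response."""

UPSAMPLED_RATE_HZ = 50.0
SMOOTH_SIGMA_PX = 1.0


# ---------------------------------------------------------------------------
# basis
# ---------------------------------------------------------------------------

def _bspline_design(n_points: int, n_coef: int, degree: int = 3) -> np.ndarray:
    """Clamped uniform cubic B-spline design matrix (n_points x n_coef)."""
    if n_coef < degree + 1:
        raise ValueError(f"need at least {degree + 1} coefficients for degree {degree}")
    n_interior = n_coef - degree - 1
    knots = np.concatenate([
        np.zeros(degree + 1),
        np.linspace(0, n_points - 1, n_interior + 2)[1:-1],
        np.full(degree + 1, n_points - 1),
    ])
    x = np.arange(n_points, dtype=np.float64)
    return BSpline.design_matrix(x, knots, degree).toarray()


@dataclass(frozen=True)
class SplineBasis:
    """Tensor-product basis mapping (kx*ky*ktau) coefficients to RF voxels."""

    grid_shape: Tuple[int, int, int]
    n_knots: Tuple[int, int, int]
    Sx: np.ndarray
    Sy: np.ndarray
    St: np.ndarray

    @classmethod
    def make(
        cls,
        grid_shape: Tuple[int, int, int] = GRID_SHAPE,
        n_knots: Tuple[int, int, int] = N_KNOTS,
    ) -> "SplineBasis":
        return cls(
            grid_shape=grid_shape,
            n_knots=n_knots,
            Sx=_bspline_design(grid_shape[0], n_knots[0]),
            Sy=_bspline_design(grid_shape[1], n_knots[1]),
            St=_bspline_design(grid_shape[2], n_knots[2]),
        )

    @classmethod
    def identity(cls, grid_shape: Tuple[int, int, int]) -> "SplineBasis":
        """Identity basis (coefficients are voxels) for small test grids."""
        return cls(
            grid_shape=grid_shape,
            n_knots=grid_shape,
            Sx=np.eye(grid_shape[0]),
            Sy=np.eye(grid_shape[1]),
            St=np.eye(grid_shape[2]),
        )

    @property
    def n_features(self) -> int:
        return self.n_knots[0] * self.n_knots[1] * self.n_knots[2]


# ---------------------------------------------------------------------------
# response variable and design
# ---------------------------------------------------------------------------

def clipped_gradient(detrended_trace: np.ndarray, sample_rate: float = RECORDING_RATE_HZ) -> np.ndarray:
    """Forward-difference temporal gradient with negative values clipped to 0.

    The last difference is repeated so the output matches the input length.
    """
    trace = np.asarray(detrended_trace, dtype=np.float64)
    if len(trace) < 2:
        raise ValueError("trace must have at least 2 samples")
    d = np.diff(trace) * sample_rate
    d = np.concatenate([d, d[-1:]])
    return np.maximum(d, 0.0)


def upsample_pair(
    n_frames: int,
    cdot: np.ndarray,
    trigger_s: float,
    trace_rate: float = RECORDING_RATE_HZ,
    stim_rate: float = 5.0,
    factor: int = 10,
) -> Tuple[np.ndarray, np.ndarray, int]:
    """Align stimulus frames and clipped gradient on the upsampled clock.

    The stimulus is zero-order-held (each frame repeated ``factor`` times);
    the gradient is linearly interpolated onto the same grid. Returns
    ``(frame_index, cdot_up, n_trimmed)`` where ``frame_index[t]`` is the
    stimulus frame shown at upsampled sample ``t``.
    """
    cdot = np.asarray(cdot, dtype=np.float64)
    up_rate = stim_rate * factor
    frame_index = np.repeat(np.arange(n_frames), factor)
    t_up = trigger_s + np.arange(n_frames * factor) / up_rate
    # the forward difference between samples i and i+1 estimates the
    # derivative at the interval midpoint, hence the half-sample offset
    t_trace = (np.arange(len(cdot)) + 0.5) / trace_rate
    n_trimmed = 0
    if t_up[-1] > t_trace[-1]:
        keep = t_up <= t_trace[-1]
        n_trimmed = int(np.sum(~keep))
        warnings.warn(f"trace shorter than stimulus: trimmed {n_trimmed} upsampled samples")
        t_up, frame_index = t_up[keep], frame_index[keep]
    cdot_up = np.interp(t_up, t_trace, cdot)
    return frame_index, cdot_up, n_trimmed


def build_design(
    frames_fine: np.ndarray,
    frame_index: np.ndarray,
    basis: SplineBasis,
    lags_s: np.ndarray = LAGS_S,
    up_rate: float = UPSAMPLED_RATE_HZ,
) -> Tuple[np.ndarray, np.ndarray]:
    """Spline-projected lagged-stimulus features X(t)*S.

    Each fine frame is first projected on the spatial basis once; per time
    sample the 15 lagged projections are combined through the temporal basis.
    Samples whose lag window leaves the recording are dropped.

    Returns ``(features, valid)`` where ``features`` has one row per retained
    sample and ``valid`` holds the retained sample indices.
    """
    frames_fine = np.asarray(frames_fine, dtype=np.float64)
    nf, dx, dy = frames_fine.shape
    if (dx, dy) != basis.grid_shape[:2]:
        raise ValueError("frame shape does not match the basis spatial grid")
    kx, ky, kt = basis.n_knots
    lag_samples = np.rint(np.asarray(lags_s) * up_rate).astype(int)

    # spatial projection of each unique frame: (nf, kx*ky)
    proj = np.einsum("xi,fxy,yj->fij", basis.Sx, frames_fine, basis.Sy).reshape(nf, kx * ky)

    T = len(frame_index)
    lo, hi = lag_samples.min(), lag_samples.max()
    valid = np.arange(max(0, hi), T + min(0, lo))
    if valid.size == 0:
        raise ValueError("no samples with a complete lag window")
    feats = np.zeros((valid.size, kx * ky, kt))
    for l, dt in enumerate(lag_samples):
        rows = proj[frame_index[valid - dt]]
        feats += rows[:, :, None] * basis.St[l, None, :]
    return feats.reshape(valid.size, basis.n_features), valid


# ---------------------------------------------------------------------------
# penalised fit
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FitResult:
    y0: float
    b: np.ndarray
    loss_history: np.ndarray
    n_steps: int
    best_loss: float


def fit_rf(
    features: np.ndarray,
    cdot: np.ndarray,
    beta: float = 0.01,
    lr: float = 0.1,
    min_steps: int = 100,
    max_steps: int = 2000,
    patience: int = 5,
    seed: Optional[int] = None,
) -> FitResult:
    """Minimise the L1-penalised mean-squared error with Adam.

    Full-batch first-order steps (Adam moments beta1 = 0.9, beta2 = 0.999,
    eps = 1e-8); training stops after ``patience`` consecutive steps whose
    loss did not drop below the preceding step's, and the lowest-loss
    parameters are returned. Deterministic: the initialisation is b = 0,
    y0 = mean(cdot); ``seed`` is accepted for interface uniformity.
    """
    del seed
    X = np.asarray(features, dtype=np.float64)
    y = np.asarray(cdot, dtype=np.float64)
    if X.shape[0] != y.shape[0]:
        raise ValueError("features and target must have equal length")
    if beta < 0:
        raise ValueError("beta must be nonnegative")
    T, p = X.shape

    xbar = X.mean(axis=0)
    ybar = y.mean()
    G = X.T @ X / T - np.outer(xbar, xbar)
    Xy = X.T @ y / T - xbar * ybar
    yy = float(np.mean((y - ybar) ** 2))

    # precondition: G = L L^T, optimise u = L^T b (same loss, same minimiser)
    ridge = 1e-10 * np.trace(G) / p
    L = cholesky(G + ridge * np.eye(p), lower=True)
    u_target = solve_triangular(L, Xy, lower=True)

    u = np.zeros(p)
    a = 0.0  # intercept offset in centred coordinates
    m = np.zeros(p + 1)
    v = np.zeros(p + 1)
    b1, b2, eps = 0.9, 0.999, 1e-8

    best = np.inf
    best_u, best_a = u.copy(), a
    prev = np.inf
    run = 0
    losses = []
    n_steps = 0
    for step in range(1, max_steps + 1):
        n_steps = step
        b_cur = solve_triangular(L.T, u, lower=False)
        loss = yy + a * a - 2 * u @ u_target + u @ u + beta * np.abs(b_cur).sum()
        if not np.isfinite(loss):
            raise RuntimeError(
                "non-finite loss during RF fitting; consider lowering the learning rate"
            )
        losses.append(loss)
        if loss < best:
            best = loss
            best_u, best_a = u.copy(), a
        run = run + 1 if loss >= prev else 0
        prev = loss
        if run >= patience and step >= min_steps:
            break
        g = np.empty(p + 1)
        g[0] = 2 * a
        g[1:] = 2 * (u - u_target)
        if beta:
            g[1:] += beta * solve_triangular(L, np.sign(b_cur), lower=True)
        m = b1 * m + (1 - b1) * g
        v = b2 * v + (1 - b2) * g * g
        mhat = m / (1 - b1**step)
        vhat = v / (1 - b2**step)
        a -= lr * mhat[0] / (np.sqrt(vhat[0]) + eps)
        u -= lr * mhat[1:] / (np.sqrt(vhat[1:]) + eps)

    b_best = solve_triangular(L.T, best_u, lower=False)
    y0 = float(ybar + best_a - xbar @ b_best)
    return FitResult(y0=y0, b=b_best, loss_history=np.array(losses), n_steps=n_steps, best_loss=float(best))


def closed_form_lstsq(features: np.ndarray, cdot: np.ndarray) -> Tuple[float, np.ndarray]:
    """Unpenalised least-squares solution (y0, b); reference for beta = 0."""
    X = np.asarray(features, dtype=np.float64)
    y = np.asarray(cdot, dtype=np.float64)
    A = np.column_stack([np.ones(len(y)), X])
    sol = np.linalg.lstsq(A, y, rcond=None)[0]
    return float(sol[0]), sol[1:]


# ---------------------------------------------------------------------------
# RF assembly, decomposition and measurement
# ---------------------------------------------------------------------------

def assemble_rf(b: np.ndarray, basis: SplineBasis) -> np.ndarray:
    """Evaluate F = S b on the (dx, dy, dtau) grid."""
    kx, ky, kt = basis.n_knots
    coef = np.asarray(b, dtype=np.float64).reshape(kx, ky, kt)
    return np.einsum("xi,yj,tk,ijk->xyt", basis.Sx, basis.Sy, basis.St, coef)


def smooth_rf(F: np.ndarray, sigma_px: float = SMOOTH_SIGMA_PX) -> np.ndarray:
    """Smooth each lag frame with a truncated 5x5 Gaussian (sigma = 1 px),
    reflective borders."""
    out = np.empty_like(F, dtype=np.float64)
    for k in range(F.shape[2]):
        out[:, :, k] = gaussian_filter(F[:, :, k], sigma=sigma_px, mode="reflect", truncate=2.0)
    return out


def svd_split(F: np.ndarray) -> Tuple[np.ndarray, np.ndarray, float]:
    """Rank-1 decomposition into temporal and spatial components.

    Scaling follows the reporting convention max|Ft| = 1 and
    max|Fs| = max|F|; the sign is anchored so the spatial component is
    positive at its absolute maximum (polarity is carried by Ft).
    QI_SVD = 1 - Var[F - Ft x Fs] / Var[F].
    """
    F = np.asarray(F, dtype=np.float64)
    dx, dy, dt = F.shape
    if not F.any():
        return np.zeros(dt), np.zeros((dx, dy)), 0.0
    M = F.reshape(dx * dy, dt)
    u, s, vt = np.linalg.svd(M, full_matrices=False)
    rank1 = s[0] * np.outer(u[:, 0], vt[0])
    qi = 1.0 - np.var(M - rank1) / np.var(M)
    qi = float(np.clip(qi, 0.0, 1.0))

    Ft = vt[0].copy()
    Fs = (s[0] * u[:, 0]).reshape(dx, dy)
    if Fs.flat[np.argmax(np.abs(Fs))] < 0:
        Fs, Ft = -Fs, -Ft
    Ft = Ft / np.max(np.abs(Ft))
    Fs = Fs * (np.max(np.abs(F)) / np.max(np.abs(Fs)))
    return Ft, Fs, qi


@dataclass(frozen=True)
class GaussianFit:
    amplitude: float
    x0_px: float
    y0_px: float
    sigma_x_px: float
    sigma_y_px: float
    theta_rad: float
    converged: bool

    def model(self, shape: Tuple[int, int]) -> np.ndarray:
        xx, yy = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
        return _gauss2d(
            xx, yy, self.amplitude, self.x0_px, self.y0_px,
            self.sigma_x_px, self.sigma_y_px, self.theta_rad,
        )


def _gauss2d(xx, yy, A, x0, y0, sx, sy, th):
    ct, st = np.cos(th), np.sin(th)
    xr = (xx - x0) * ct + (yy - y0) * st
    yr = -(xx - x0) * st + (yy - y0) * ct
    return A * np.exp(-0.5 * ((xr / sx) ** 2 + (yr / sy) ** 2))


def fit_spatial_gaussian(Fs: np.ndarray) -> Tuple[Optional[GaussianFit], float]:
    """Elliptical 2D Gaussian fit to the spatial RF by nonlinear least
    squares; QI_sRF = 1 - Var[Fs - F_Gauss] / Var[Fs].

    Returns ``(fit, qi_srf)``; a failed fit gives ``(None, 0.0)``.
    """
    Fs = np.asarray(Fs, dtype=np.float64)
    if np.ptp(Fs) == 0:
        return None, 0.0
    dx, dy = Fs.shape
    xx, yy = np.meshgrid(np.arange(dx), np.arange(dy), indexing="ij")
    peak = np.unravel_index(np.argmax(np.abs(Fs)), Fs.shape)
    p0 = [Fs[peak], float(peak[0]), float(peak[1]), 2.0, 2.0, 0.0]

    def resid(p):
        return (_gauss2d(xx, yy, *p) - Fs).ravel()

    try:
        res = least_squares(
            resid, p0,
            bounds=([-np.inf, -dx, -dy, 0.3, 0.3, -np.pi], [np.inf, 2 * dx, 2 * dy, dx, dy, np.pi]),
            max_nfev=2000,
        )
    except Exception:
        return None, 0.0
    if not res.success:
        return None, 0.0
    A, x0, y0, sx, sy, th = res.x
    fit = GaussianFit(A, x0, y0, sx, sy, th, converged=True)
    qi = 1.0 - np.var(Fs - fit.model(Fs.shape)) / np.var(Fs)
    return fit, float(np.clip(qi, 0.0, 1.0))


def corrected_sigmas_um(
    fit: GaussianFit,
    pixel_size_um: float = PIXEL_SIZE_UM,
    smooth_sigma_px: float = SMOOTH_SIGMA_PX,
) -> Tuple[float, float]:
    """Gaussian SDs in um, deconvolving the explicit per-frame smoothing
    (variance subtraction); floored at a tenth of a pixel."""
    floor = (0.1 * pixel_size_um) ** 2
    sx2 = max((fit.sigma_x_px**2 - smooth_sigma_px**2), 0.0) * pixel_size_um**2
    sy2 = max((fit.sigma_y_px**2 - smooth_sigma_px**2), 0.0) * pixel_size_um**2
    return float(np.sqrt(max(sx2, floor))), float(np.sqrt(max(sy2, floor)))


def rf_size(sigma_x_um: float, sigma_y_um: float) -> Tuple[float, float]:
    """RF size from the 2-SD ellipse of the Gaussian fit.

    Returns ``(area_um2, equivalent_diameter_um)`` with
    area = pi * (2 sx) * (2 sy) and d = 2 sqrt(area/pi) = 4 sqrt(sx sy).
    """
    if sigma_x_um <= 0 or sigma_y_um <= 0:
        raise ValueError("Gaussian SDs must be positive")
    area = np.pi * (2 * sigma_x_um) * (2 * sigma_y_um)
    return float(area), float(2 * np.sqrt(area / np.pi))


def temporal_peaks(Ft: np.ndarray, lags_s: np.ndarray = LAGS_S) -> Optional[float]:
    """Lag (s) of the main temporal peak: among local maxima of |Ft| above
    0.65 population SDs of Ft, the one with the smallest lag. ``None`` when
    no peak qualifies."""
    Ft = np.asarray(Ft, dtype=np.float64)
    height = 0.65 * np.std(Ft)
    idx, _ = find_peaks(np.abs(Ft), height=height)
    if idx.size == 0:
        return None
    return float(np.min(np.asarray(lags_s)[idx]))


def rf_quality_gate(
    qi_svd: float,
    qi_srf: float,
    main_peak_lag_s: Optional[float],
    lag_window_s: Tuple[float, float] = (0.0, 0.3),
    qi_trf: Optional[float] = None,
    qi_trf_threshold: Optional[float] = None,
) -> bool:
    """Strict QI gates (> 0.5) and the main-peak-lag window (inclusive).

    An undefined lag fails the gate. The optional temporal-fit gate
    (``qi_trf_threshold``) is disabled unless both arguments are given.
    """
    if main_peak_lag_s is None:
        return False
    ok = qi_svd > 0.5 and qi_srf > 0.5 and lag_window_s[0] <= main_peak_lag_s <= lag_window_s[1]
    if ok and qi_trf_threshold is not None and qi_trf is not None:
        ok = qi_trf > qi_trf_threshold
    return bool(ok)


# ---------------------------------------------------------------------------
# end-to-end estimator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RFModel:
    """Fitted spatio-temporal receptive field and derived measurements."""

    y0: float
    b: np.ndarray
    F: np.ndarray                 # (32, 20, 15) smoothed RF
    Ft: np.ndarray                # temporal component, max|Ft| = 1
    Fs: np.ndarray                # spatial component, max|Fs| = max|F|
    gauss_fit: Optional[GaussianFit]
    sigma_x_um: float             # smoothing-corrected, um
    sigma_y_um: float
    rf_area_um2: float
    rf_diameter_um: float
    main_peak_lag_s: Optional[float]
    qi_svd: float
    qi_srf: float
    passes_quality: bool
    lags_s: np.ndarray = field(default_factory=lambda: LAGS_S.copy())


def estimate_rf(
    detrended_trace: np.ndarray,
    frames_fine: np.ndarray,
    trigger_s: float,
    basis: Optional[SplineBasis] = None,
    beta: float = 0.01,
    sample_rate: float = RECORDING_RATE_HZ,
    pixel_size_um: float = PIXEL_SIZE_UM,
) -> RFModel:
    """Full RF pipeline for one cell: clipped gradient, upsampling, spline
    design, penalised fit, smoothing, SVD split, Gaussian fit and gates."""
    basis = basis or SplineBasis.make()
    cdot = clipped_gradient(detrended_trace, sample_rate)
    frame_index, cdot_up, _ = upsample_pair(frames_fine.shape[0], cdot, trigger_s, trace_rate=sample_rate)
    features, valid = build_design(frames_fine, frame_index, basis)
    fit = fit_rf(features, cdot_up[valid], beta=beta)
    F = smooth_rf(assemble_rf(fit.b, basis))
    Ft, Fs, qi_svd = svd_split(F)
    gfit, qi_srf = fit_spatial_gaussian(Fs)
    if gfit is not None:
        sx_um, sy_um = corrected_sigmas_um(gfit, pixel_size_um)
        area, diam = rf_size(sx_um, sy_um)
    else:
        sx_um = sy_um = area = diam = np.nan
    lag = temporal_peaks(Ft) if F.any() else None
    return RFModel(
        y0=fit.y0, b=fit.b, F=F, Ft=Ft, Fs=Fs, gauss_fit=gfit,
        sigma_x_um=sx_um, sigma_y_um=sy_um, rf_area_um2=area, rf_diameter_um=diam,
        main_peak_lag_s=lag, qi_svd=qi_svd, qi_srf=qi_srf,
        passes_quality=rf_quality_gate(qi_svd, qi_srf, lag),
    )
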