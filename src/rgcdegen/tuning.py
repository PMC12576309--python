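"""Direction and orientation selectivity from moving-bar responses.

The per-direction mean snippets are stacked into a time x direction matrix
and decomposed by a rank-1 SVD; the direction singular vector (times the
singular value) is the tuning curve. The direction selectivity index is the
modulus of the amplitude-weighted mean unit vector,

    DSI = |sum_k r_k e^{i theta_k}| / sum_k r_k,

and the orientation index uses doubled angles (e^{2 i theta_k}). Significance
is assessed by shuffling direction labels across trials (add-one permutation
p-value).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = ["TuningResult", "tuning_curve", "dsi", "osi", "permutation_test", "analyze_tuning"]


@dataclass(frozen=True)
class TuningResult:
    directions: np.ndarray    # degrees
    tuning_curve: np.ndarray  # nonnegative amplitude per direction
    dsi: float
    osi: float
    p_ds: float
    p_os: float


def tuning_curve(C_by_direction: Sequence[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Rank-1 SVD tuning curve.

    Parameters
    ----------
    C_by_direction
        One T x R snippet matrix per direction (common T, R >= 2).

    Returns
    -------
    curve, time_component
        ``curve[k] = |v_k| * s`` with the sign chosen so the peak of the time
        component is positive; ``time_component`` is the unit-norm left
        singular vector.
    """
    mats = [np.asarray(c, dtype=np.float64) for c in C_by_direction]
    T = mats[0].shape[0]
    if any(m.shape[0] != T for m in mats):
        raise ValueError("all directions must share the same snippet length")
    if any(m.shape[1] < 2 for m in mats):
        raise ValueError("at least 2 trials per direction are required")
    M = np.stack([m.mean(axis=1) for m in mats], axis=1)  # T x n_dir
    if not M.any():
        return np.zeros(M.shape[1]), np.zeros(T)
    u, s, vt = np.linalg.svd(M, full_matrices=False)
    time_comp, dir_comp = u[:, 0], vt[0]
    if time_comp[np.argmax(np.abs(time_comp))] < 0:
        time_comp, dir_comp = -time_comp, -dir_comp
    return np.abs(dir_comp) * s[0], time_comp


def _vector_sum_index(tuning: np.ndarray, directions_deg: np.ndarray, angle_factor: int) -> float:
    r = np.asarray(tuning, dtype=np.float64)
    if np.any(r < 0):
        raise ValueError("tuning amplitudes must be nonnegative")
    total = r.sum()
    if total == 0.0:
        return 0.0
    theta = np.deg2rad(np.asarray(directions_deg, dtype=np.float64))
    return float(np.abs(np.sum(r * np.exp(1j * angle_factor * theta))) / total)


def dsi(tuning: np.ndarray, directions_deg: np.ndarray) -> float:
    """Direction selectivity: length of the normalised complex vector sum."""
    return _vector_sum_index(tuning, directions_deg, 1)


def osi(tuning: np.ndarray, directions_deg: np.ndarray) -> float:
    """Orientation selectivity: as :func:`dsi` with doubled angles."""
    return _vector_sum_index(tuning, directions_deg, 2)


def permutation_test(
    trial_amplitudes: np.ndarray,
    trial_directions_deg: np.ndarray,
    n_perm: int = 1000,
    seed: int = 0,
    mode: str = "ds",
) -> float:
    """Add-one permutation p-value for DSI (``mode='ds'``) or OSI (``'os'``).

    Direction labels are shuffled across trials; p = (1 + #{perm >= obs}) /
    (1 + n_perm). Degenerate inputs (a single direction) give p = 1.
    """
    if mode not in ("ds", "os"):
        raise ValueError("mode must be 'ds' or 'os'")
    index = dsi if mode == "ds" else osi
    amps = np.asarray(trial_amplitudes, dtype=np.float64)
    dirs = np.asarray(trial_directions_deg, dtype=np.float64)
    if amps.shape != dirs.shape:
        raise ValueError("amplitudes and direction labels must align")
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    uniq, inv = np.unique(dirs, return_inverse=True)
    if uniq.size < 2:
        return 1.0
    onehot = np.zeros((amps.size, uniq.size))
    onehot[np.arange(amps.size), inv] = 1.0
    onehot /= onehot.sum(axis=0, keepdims=True)  # column k averages trials of direction k

    obs = index(np.maximum(amps @ onehot, 0.0), uniq)

    # permuting labels over trials == permuting the amplitude vector
    rng = np.random.default_rng(seed)
    perm = rng.permuted(np.tile(amps, (n_perm, 1)), axis=1)
    curves = np.maximum(perm @ onehot, 0.0)
    factor = 1 if mode == "ds" else 2
    phases = np.exp(1j * factor * np.deg2rad(uniq))
    totals = curves.sum(axis=1)
    vals = np.zeros(n_perm)
    nonzero = totals > 0
    vals[nonzero] = np.abs(curves[nonzero] @ phases) / totals[nonzero]
    count = int(np.sum(vals >= obs))
    return (1 + count) / (1 + n_perm)


def analyze_tuning(
    C_by_direction: Sequence[np.ndarray],
    directions_deg: np.ndarray,
    n_perm: int = 1000,
    seed: int = 0,
) -> TuningResult:
    """Tuning curve, DSI/OSI and their permutation p-values for one cell.

    Per-trial amplitudes for the permutation test are the magnitudes of the
    projections of each trial snippet onto the SVD time component, keeping
    the test consistent with the SVD construction of the tuning curve.
    """
    directions_deg = np.asarray(directions_deg, dtype=np.float64)
    curve, time_comp = tuning_curve(C_by_direction)
    d = dsi(curve, directions_deg)
    o = osi(curve, directions_deg)
    amps, labels = [], []
    for k, mat in enumerate(C_by_direction):
        proj = np.abs(time_comp @ np.asarray(mat, dtype=np.float64))
        amps.append(proj)
        labels.append(np.full(proj.shape, directions_deg[k]))
    amps_arr = np.concatenate(amps)
    labels_arr = np.concatenate(labels)
    p_ds = permutation_test(amps_arr, labels_arr, n_perm=n_perm, seed=seed, mode="ds")
    p_os = permutation_test(amps_arr, labels_arr, n_perm=n_perm, seed=seed + 1, mode="os")
    return TuningResult(
        directions=directions_deg, tuning_curve=curve, dsi=d, osi=o, p_ds=p_ds, p_os=p_os
    )
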