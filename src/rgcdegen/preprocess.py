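"""Trace preprocessing and response-quality filtering.

Raw fluorescence traces are detrended by subtracting a Savitzky-Golay
smoothed copy (3rd order, 60 s window), baseline-subtracted (mean of the
first 8 samples) and peak-normalised so that ``max_t r(t) = 1``. Responses
are cut into a T x R snippet matrix ``C`` (time samples x repetitions) from
which the repeatability quality index

    QI = Var_t[<C>_r] / <Var_t[C]>_r

is computed: the temporal variance of the trial-mean response over the mean
within-trial variance. QI = 1 for perfectly repeatable responses and tends
to 1/R for independent noise. A cell counts as responsive if
``QI_chirp >= 0.35`` or ``QI_mb >= 0.6``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from . import RECORDING_RATE_HZ

__all__ = [
    "ResponseMatrix",
    "QualityIndices",
    "NormalizedTrace",
    "detrend",
    "baseline_normalize",
    "snippet",
    "quality_index",
    "gate_responsive",
    "QI_CHIRP_THRESHOLD",
    "QI_MB_THRESHOLD",
]

QI_CHIRP_THRESHOLD = 0.35
QI_MB_THRESHOLD = 0.6
N_BASELINE_SAMPLES = 8


@dataclass(frozen=True)
class ResponseMatrix:
    """T x R snippet matrix for one cell and one stimulus."""

    data: np.ndarray
    sample_rate: float
    stimulus_id: str = ""

    def __post_init__(self) -> None:
        if self.data.ndim != 2:
            raise ValueError("response matrix must be 2-D (time x repetitions)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("response matrix contains non-finite entries")

    @property
    def n_time(self) -> int:
        return self.data.shape[0]

    @property
    def n_reps(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class QualityIndices:
    qi_chirp: float
    qi_mb: float

    @property
    def responsive(self) -> bool:
        return gate_responsive(self.qi_chirp, self.qi_mb)


@dataclass(frozen=True)
class NormalizedTrace:
    trace: np.ndarray
    scale: float
    valid: bool


def detrend(
    raw_trace: np.ndarray,
    sample_rate: float = RECORDING_RATE_HZ,
    window_s: float = 60.0,
    order: int = 3,
) -> np.ndarray:
    """Subtract a Savitzky-Golay smoothed copy to remove slow drift.

    The window is ``window_s`` converted to the nearest odd sample count
    (469 samples at 7.8125 Hz); edges are mirror-padded.
    """
    trace = np.asarray(raw_trace, dtype=np.float64)
    window = int(round(window_s * sample_rate))
    if window % 2 == 0:
        window += 1
    if len(trace) <= window:
        raise ValueError(
            f"trace has {len(trace)} samples but the detrending filter needs "
            f"more than {window} (= {window_s} s at {sample_rate} Hz)"
        )
    smooth = savgol_filter(trace, window_length=window, polyorder=order, mode="mirror")
    return trace - smooth


def baseline_normalize(trace: np.ndarray) -> NormalizedTrace:
    """Subtract the mean of the first 8 samples, then scale the peak to 1.

    Cells whose baseline-subtracted maximum is non-positive (or numerically
    zero) cannot be normalised and are flagged invalid rather than raising.
    """
    trace = np.asarray(trace, dtype=np.float64)
    if len(trace) < N_BASELINE_SAMPLES:
        raise ValueError(f"trace needs at least {N_BASELINE_SAMPLES} samples")
    shifted = trace - trace[:N_BASELINE_SAMPLES].mean()
    peak = shifted.max()
    if peak <= 1e-12:
        return NormalizedTrace(trace=shifted, scale=np.nan, valid=False)
    return NormalizedTrace(trace=shifted / peak, scale=peak, valid=True)


def snippet(
    trace: np.ndarray,
    triggers_s: np.ndarray,
    snippet_len: int,
    sample_rate: float = RECORDING_RATE_HZ,
    stimulus_id: str = "",
) -> ResponseMatrix:
    """Cut trigger-aligned columns of ``snippet_len`` samples from a trace.

    Triggers are rounded to the nearest sample.
    """
    trace = np.asarray(trace, dtype=np.float64)
    triggers_s = np.atleast_1d(np.asarray(triggers_s, dtype=np.float64))
    if len(triggers_s) < 2:
        raise ValueError("at least 2 triggers are required to form a response matrix")
    starts = np.rint(triggers_s * sample_rate).astype(int)
    bad = np.nonzero((starts < 0) | (starts + snippet_len > len(trace)))[0]
    if bad.size:
        raise ValueError(
            f"trigger(s) at {triggers_s[bad].tolist()} s fall outside the trace "
            f"(length {len(trace)} samples, snippet {snippet_len})"
        )
    cols = np.stack([trace[s : s + snippet_len] for s in starts], axis=1)
    return ResponseMatrix(data=cols, sample_rate=sample_rate, stimulus_id=stimulus_id)


def quality_index(C: ResponseMatrix | np.ndarray) -> float:
    """Repeatability index: Var_t of the repetition mean over the mean
    within-repetition variance (population variance, ddof 0), clipped to [0,1].
    """
    data = C.data if isinstance(C, ResponseMatrix) else np.asarray(C, dtype=np.float64)
    if data.ndim != 2 or data.shape[0] < 2 or data.shape[1] < 2:
        raise ValueError("quality_index needs a T x R matrix with T >= 2 and R >= 2")
    denom = data.var(axis=0, ddof=0).mean()
    if denom == 0.0:
        return 0.0
    num = data.mean(axis=1).var(ddof=0)
    return float(np.clip(num / denom, 0.0, 1.0))


def gate_responsive(
    qi_chirp: float,
    qi_mb: float,
    chirp_threshold: float = QI_CHIRP_THRESHOLD,
    mb_threshold: float = QI_MB_THRESHOLD,
) -> bool:
    """A cell is responsive if either stimulus passes its QI threshold
    (inclusive)."""
    return bool(qi_chirp >= chirp_threshold or qi_mb >= mb_threshold)
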