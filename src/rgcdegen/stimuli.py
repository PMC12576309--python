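"""Light-stimulus generators.

Three protocols are used to fingerprint RGC function:

* a full-field *chirp* (steps, an accelerating frequency sweep and a growing
  contrast sweep) probing temporal dynamics and contrast sensitivity,
* a bright *moving bar* (0.3 x 1 mm at 1 mm/s) swept in eight directions,
* *shifted dense noise*: a 20 x 15 binary checkerboard (40 um checks) at 5 Hz
  for 5 min, with every frame jittered on a 10 um grid so receptive fields
  can be resolved below the check size.

All generators are pure functions of ``(config, seed)``; intensities are
unitless in [0, 1] with 0 = dark, 0.5 = background, 1 = bright.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Tuple

import numpy as np

__all__ = [
    "ChirpConfig",
    "ChirpStimulus",
    "BarConfig",
    "MovingBarStimulus",
    "NoiseConfig",
    "ShiftedDenseNoise",
    "make_chirp",
    "make_moving_bar",
    "make_shifted_dense_noise",
    "rasterize_noise",
]

BACKGROUND = 0.5


# ---------------------------------------------------------------------------
# chirp
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChirpConfig:
    """Segment layout of the full-field chirp, durations in seconds."""

    sample_rate: float = 62.5
    baseline_s: float = 2.0
    step_on_s: float = 3.0
    step_off_s: float = 3.0
    pre_sweep_s: float = 2.0
    freq_sweep_s: float = 8.0
    freq_start_hz: float = 0.5
    freq_end_hz: float = 8.0
    inter_s: float = 2.0
    amp_sweep_s: float = 8.0
    amp_freq_hz: float = 2.0
    tail_s: float = 2.0

    def validate(self) -> None:
        durations = (
            self.baseline_s, self.step_on_s, self.step_off_s, self.pre_sweep_s,
            self.freq_sweep_s, self.inter_s, self.amp_sweep_s, self.tail_s,
        )
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if any(d <= 0 for d in durations):
            raise ValueError("all chirp segment durations must be positive")


@dataclass(frozen=True)
class ChirpStimulus:
    sample_rate: float
    trace: np.ndarray            # full trace, n_reps identical repetitions
    trigger_times: np.ndarray    # repetition starts, s
    n_reps: int
    segments: Dict[str, Tuple[float, float]]  # name -> (start_s, end_s) within one rep

    @property
    def rep_duration_s(self) -> float:
        return len(self.trace) / self.sample_rate / self.n_reps


def _chirp_one_rep(cfg: ChirpConfig) -> Tuple[np.ndarray, Dict[str, Tuple[float, float]]]:
    fs = cfg.sample_rate
    pieces = []
    segments: Dict[str, Tuple[float, float]] = {}
    t0 = 0.0

    def add(name: str, dur: float, values: np.ndarray) -> None:
        nonlocal t0
        segments[name] = (t0, t0 + dur)
        pieces.append(values)
        t0 += dur

    def const(dur: float, level: float) -> np.ndarray:
        return np.full(int(round(dur * fs)), level)

    add("baseline", cfg.baseline_s, const(cfg.baseline_s, BACKGROUND))
    add("step_on", cfg.step_on_s, const(cfg.step_on_s, 1.0))
    add("step_off", cfg.step_off_s, const(cfg.step_off_s, 0.0))
    add("pre_sweep", cfg.pre_sweep_s, const(cfg.pre_sweep_s, BACKGROUND))

    n = int(round(cfg.freq_sweep_s * fs))
    t = np.arange(n) / fs
    # instantaneous frequency rises linearly f0 -> f1; phase is its integral
    phase = cfg.freq_start_hz * t + (cfg.freq_end_hz - cfg.freq_start_hz) * t**2 / (2 * cfg.freq_sweep_s)
    add("freq_sweep", cfg.freq_sweep_s, BACKGROUND + 0.5 * np.sin(2 * np.pi * phase))

    add("inter", cfg.inter_s, const(cfg.inter_s, BACKGROUND))

    n = int(round(cfg.amp_sweep_s * fs))
    t = np.arange(n) / fs
    env = t / cfg.amp_sweep_s
    add("amp_sweep", cfg.amp_sweep_s, BACKGROUND + 0.5 * env * np.sin(2 * np.pi * cfg.amp_freq_hz * t))

    add("tail", cfg.tail_s, const(cfg.tail_s, BACKGROUND))

    trace = np.clip(np.concatenate(pieces), 0.0, 1.0)
    return trace, segments


def make_chirp(config: ChirpConfig | None = None, n_reps: int = 5) -> ChirpStimulus:
    """Render the chirp; repetitions are bit-identical copies of one cycle."""
    cfg = config or ChirpConfig()
    cfg.validate()
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rep, segments = _chirp_one_rep(cfg)
    rep_dur = len(rep) / cfg.sample_rate
    return ChirpStimulus(
        sample_rate=cfg.sample_rate,
        trace=np.tile(rep, n_reps),
        trigger_times=np.arange(n_reps) * rep_dur,
        n_reps=n_reps,
        segments=segments,
    )


# ---------------------------------------------------------------------------
# moving bar
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BarConfig:
    speed_um_s: float = 1000.0
    bar_width_um: float = 300.0    # extent along the direction of motion
    bar_length_um: float = 1000.0  # extent orthogonal to motion
    n_directions: int = 8
    gap_s: float = 1.0             # inter-trial background interval

    def validate(self) -> None:
        if self.n_directions < 8:
            raise ValueError("at least 8 directions are required")
        if self.speed_um_s <= 0 or self.bar_width_um <= 0 or self.bar_length_um <= 0:
            raise ValueError("bar geometry and speed must be positive")


@dataclass(frozen=True)
class MovingBarStimulus:
    directions: np.ndarray        # degrees, length 8, spaced 45
    speed_um_s: float
    bar_size_um: Tuple[float, float]
    trial_order: np.ndarray       # (n_reps, 8) direction indices
    trigger_times: np.ndarray     # trial starts, s, flattened over reps
    sweep_duration_s: float
    gap_s: float

    @property
    def n_reps(self) -> int:
        return self.trial_order.shape[0]

    @property
    def trial_duration_s(self) -> float:
        return self.sweep_duration_s + self.gap_s

    def trial_directions(self) -> np.ndarray:
        """Direction (degrees) of every trial in presentation order."""
        return self.directions[self.trial_order.ravel()]


def make_moving_bar(
    config: BarConfig | None = None,
    field_extent_um: float = 1000.0,
    n_reps: int = 3,
    seed: int = 0,
) -> MovingBarStimulus:
    """Schedule one sweep per direction per repetition, order shuffled per rep.

    The sweep duration is the time for the bar to fully traverse the field
    plus its own width along the motion axis.
    """
    cfg = config or BarConfig()
    cfg.validate()
    if field_extent_um <= 0:
        raise ValueError("field_extent_um must be positive")
    rng = np.random.default_rng(seed)
    directions = np.arange(cfg.n_directions) * (360.0 / cfg.n_directions)
    sweep = (field_extent_um + cfg.bar_width_um) / cfg.speed_um_s
    trial_order = np.stack([rng.permutation(cfg.n_directions) for _ in range(n_reps)])
    n_trials = n_reps * cfg.n_directions
    triggers = np.arange(n_trials) * (sweep + cfg.gap_s)
    return MovingBarStimulus(
        directions=directions,
        speed_um_s=cfg.speed_um_s,
        bar_size_um=(cfg.bar_width_um, cfg.bar_length_um),
        trial_order=trial_order,
        trigger_times=triggers,
        sweep_duration_s=sweep,
        gap_s=cfg.gap_s,
    )


# ---------------------------------------------------------------------------
# shifted dense noise
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NoiseConfig:
    n_checks_x: int = 20
    n_checks_y: int = 15
    check_size_um: float = 40.0
    frame_rate_hz: float = 5.0
    duration_s: float = 300.0
    shift_grid_um: float = 10.0

    def validate(self) -> None:
        if min(self.n_checks_x, self.n_checks_y) <= 0:
            raise ValueError("check grid must be positive")
        if min(self.check_size_um, self.frame_rate_hz, self.duration_s, self.shift_grid_um) <= 0:
            raise ValueError("check size, frame rate, duration and shift grid must be positive")


@dataclass(frozen=True)
class ShiftedDenseNoise:
    config: NoiseConfig
    frames: np.ndarray        # (n_frames, n_checks_x, n_checks_y) uint8 in {0,1}
    shift_offsets: np.ndarray  # (n_frames, 2) um, multiples of shift_grid_um
    seed: int

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def extent_um(self) -> Tuple[float, float]:
        c = self.config
        return (c.n_checks_x * c.check_size_um, c.n_checks_y * c.check_size_um)


def make_shifted_dense_noise(config: NoiseConfig | None = None, seed: int = 0) -> ShiftedDenseNoise:
    """Balanced binary frames (exactly half the checks bright) with a random
    whole-frame shift drawn uniformly on the shift grid within one check."""
    cfg = config or NoiseConfig()
    cfg.validate()
    rng = np.random.default_rng(seed)
    n_frames = int(round(cfg.duration_s * cfg.frame_rate_hz))
    n_checks = cfg.n_checks_x * cfg.n_checks_y
    base = np.zeros(n_checks, dtype=np.uint8)
    base[: n_checks // 2] = 1

    frames = np.empty((n_frames, cfg.n_checks_x, cfg.n_checks_y), dtype=np.uint8)
    for i in range(n_frames):
        frames[i] = rng.permutation(base).reshape(cfg.n_checks_x, cfg.n_checks_y)

    n_sub = int(round(cfg.check_size_um / cfg.shift_grid_um))
    offsets = rng.integers(0, n_sub, size=(n_frames, 2)) * cfg.shift_grid_um
    return ShiftedDenseNoise(config=cfg, frames=frames, shift_offsets=offsets.astype(np.int16), seed=seed)


def rasterize_noise(
    stim: ShiftedDenseNoise,
    target_shape: Tuple[int, int] = (32, 20),
    pixel_size_um: float = 12.5,
) -> np.ndarray:
    """Sample the shifted checkerboard onto a fine pixel grid.

    The target window is centred on the stimulus; each fine pixel takes the
    intensity of the check covering its centre after the frame's shift.
    Returns a float array of shape ``(n_frames, nx, ny)``.
    """
    cfg = stim.config
    nx, ny = target_shape
    ext_x, ext_y = stim.extent_um
    win_x, win_y = nx * pixel_size_um, ny * pixel_size_um
    if win_x > ext_x + cfg.check_size_um or win_y > ext_y + cfg.check_size_um:
        raise ValueError("target grid does not fit inside the stimulus extent")
    x0 = (ext_x - win_x) / 2.0
    y0 = (ext_y - win_y) / 2.0
    px = x0 + (np.arange(nx) + 0.5) * pixel_size_um  # pixel-centre positions, um
    py = y0 + (np.arange(ny) + 0.5) * pixel_size_um

    out = np.empty((stim.n_frames, nx, ny), dtype=np.float64)
    for i in range(stim.n_frames):
        ox, oy = stim.shift_offsets[i]
        ix = np.clip(np.floor((px - ox) / cfg.check_size_um).astype(int), 0, cfg.n_checks_x - 1)
        iy = np.clip(np.floor((py - oy) / cfg.check_size_um).astype(int), 0, cfg.n_checks_y - 1)
        out[i] = stim.frames[i][np.ix_(ix, iy)]
    return out
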