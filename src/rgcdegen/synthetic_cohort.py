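"""Forward simulation of wild-type and degenerating (rd10) GCL populations.

The simulator provides ground-truth-labelled stand-ins for two-photon
calcium recordings: a library of 32 functional type templates spanning the
five super-groups, each with a chirp/moving-bar response fingerprint, a
separable spatio-temporal receptive field, direction/orientation tuning and
a soma-size distribution. Cells are simulated as linear-nonlinear-calcium
encoders: rate(t) = max(0, RF * stimulus), fluorescence = rate convolved
with a single-exponential calcium-indicator kernel (tau = 0.5 s) plus slow
drift and white noise, sampled at the 7.8125 Hz recording rate.

A recording field holds 100-120 cells of which ~60% respond in wild type;
an rd10 degeneration schedule scales per-super-group responsiveness down
with age (Off first, then On-Off, Slow On, Fast On, with 'Uncertain' cells
most resilient) and perturbs RF size and kinetics.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.ndimage import gaussian_filter1d

from . import AGES, RECORDING_RATE_HZ
from .classify import supergroup
from .stimuli import (
    BarConfig,
    ChirpConfig,
    ChirpStimulus,
    MovingBarStimulus,
    NoiseConfig,
    ShiftedDenseNoise,
    make_chirp,
    make_moving_bar,
    make_shifted_dense_noise,
    rasterize_noise,
)

__all__ = [
    "TypeTemplate",
    "DegenerationSchedule",
    "CellRecord",
    "CohortStimuli",
    "make_type_library",
    "make_cohort_stimuli",
    "simulate_cell",
    "simulate_cohort",
    "wildtype_schedule",
    "default_rd10_schedule",
    "CALCIUM_TAU_S",
    "BASE_RESPONSIVE_FRACTION",
]

SIM_RATE_HZ = 62.5        # internal simulation clock, 8x the recording rate
DECIMATE = 8
CALCIUM_TAU_S = 0.5       # OGB-1-like indicator decay
BASE_RESPONSIVE_FRACTION = 0.6
PRE_STIMULUS_S = 20.0     # baseline recorded before each stimulus

DS_GROUPS = (2, 12, 13, 16)
OS_GROUPS = (1, 6)
ALPHA_GROUPS = (5, 8, 18)  # large-soma templates so the alpha filter is exercised


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TypeTemplate:
    group_id: int
    super_group: str
    chirp_template: np.ndarray      # one repetition at 7.8125 Hz, peak = 1
    bar_template: np.ndarray        # one trial window at 7.8125 Hz, peak = 1
    ds_flag: bool
    os_flag: bool
    preferred_angle_deg: float
    tuning_exponent: float
    rf_sigma_um: Tuple[float, float]
    rf_polarity: int                # +1 On-dominant, -1 Off-dominant
    temporal_peak_lag_s: float
    soma_mean_um2: float
    soma_log_sd: float
    baseline_abundance: float

    def tuning_gain(self, direction_deg: float) -> float:
        """Response gain for a bar moving in ``direction_deg``."""
        d = np.deg2rad(direction_deg - self.preferred_angle_deg)
        if self.ds_flag:
            return float(((1 + np.cos(d)) / 2) ** self.tuning_exponent)
        if self.os_flag:
            return float(((1 + np.cos(2 * d)) / 2) ** self.tuning_exponent)
        return 1.0


@dataclass(frozen=True)
class DegenerationSchedule:
    """Per-(super-group, age) responsiveness multipliers plus per-age RF
    perturbations. The wild-type schedule is identically 1."""

    responsiveness: Dict[Tuple[str, str], float]
    rf_size_scale: Dict[str, float]
    kinetics_scale: Dict[str, float]
    noise_scale: Dict[str, float]

    def multiplier(self, super_group: str, age: str) -> float:
        try:
            return self.responsiveness[(super_group, age)]
        except KeyError:
            raise ValueError(f"schedule undefined for {(super_group, age)!r}") from None


@dataclass
class CellRecord:
    cell_id: str
    field_id: str
    genotype: str
    age: str
    soma_size_um2: float
    traces: Dict[str, np.ndarray]
    triggers: Dict[str, np.ndarray]
    sample_rate: float = RECORDING_RATE_HZ
    ground_truth: Dict[str, object] = field(default_factory=dict)


@dataclass(frozen=True)
class CohortStimuli:
    chirp: ChirpStimulus
    bar: MovingBarStimulus
    noise: Optional[ShiftedDenseNoise] = None
    noise_fine: Optional[np.ndarray] = None  # rasterized frames (T, 32, 20)


def wildtype_schedule() -> DegenerationSchedule:
    ones = {(sg, age): 1.0 for sg in ("Off", "On-Off", "Fast On", "Slow On", "Uncertain") for age in AGES}
    unit = {age: 1.0 for age in AGES}
    return DegenerationSchedule(ones, dict(unit), dict(unit), dict(unit))


def default_rd10_schedule() -> DegenerationSchedule:
    """Default rd10 schedule: Off types decline first, then On-Off, Slow On
    (from P45), Fast On (from P90); 'Uncertain' cells are most resilient;
    responsiveness is near zero for everyone by P180. RFs are ~5% smaller at
    P30/P45 and kinetics ~15% faster at P45."""
    resp = {
        "Off":       {"P30": 0.45, "P45": 0.22, "P90": 0.08, "P180": 0.010},
        "On-Off":    {"P30": 0.62, "P45": 0.35, "P90": 0.12, "P180": 0.010},
        "Slow On":   {"P30": 0.88, "P45": 0.50, "P90": 0.18, "P180": 0.010},
        "Fast On":   {"P30": 1.00, "P45": 0.72, "P90": 0.28, "P180": 0.015},
        "Uncertain": {"P30": 1.00, "P45": 0.92, "P90": 0.55, "P180": 0.020},
    }
    return DegenerationSchedule(
        responsiveness={(sg, age): v for sg, by_age in resp.items() for age, v in by_age.items()},
        rf_size_scale={"P30": 0.95, "P45": 0.95, "P90": 1.0, "P180": 1.0},
        kinetics_scale={"P30": 1.0, "P45": 0.85, "P90": 0.90, "P180": 0.90},
        noise_scale={"P30": 1.0, "P45": 1.1, "P90": 1.25, "P180": 1.5},
    )


# ---------------------------------------------------------------------------
# template library
# ---------------------------------------------------------------------------

def _calcium_kernel(rate_hz: float, tau_s: float = CALCIUM_TAU_S) -> np.ndarray:
    t = np.arange(0, 4 * tau_s, 1 / rate_hz)
    k = np.exp(-t / tau_s)
    return k / k.sum()


def _temporal_kernel(peak_lag_s: float, polarity: int, rate_hz: float = 50.0,
                     biphasic_weight: float = 0.45) -> np.ndarray:
    """Biphasic unit-peak temporal RF kernel with its (absolute) main peak at
    ``peak_lag_s``."""
    t = np.arange(0, 0.8, 1 / rate_hz)
    tp = peak_lag_s
    main = (t / tp) * np.exp(1 - t / tp)
    t2 = 2.2 * tp
    rebound = (t / t2) * np.exp(1 - t / t2)
    k = main - biphasic_weight * rebound
    k = k / np.max(np.abs(k))
    return polarity * k


def _group_params(g: int, rng: np.random.Generator) -> dict:
    """Deterministic per-group response parameters; systematic within-super-
    group spread keeps the 32 chirp fingerprints mutually distinguishable."""
    sg = supergroup(g)
    u = rng.uniform  # consumed in a fixed order per group
    if sg == "Off":
        i = g - 1
        p = dict(w_on=0.0, w_off=1.0, w_sus_on=0.0, w_sus_off=0.12 + 0.22 * (i % 3),
                 tau=0.18 + 0.16 * (i % 5), cutoff_hz=8.0 - 1.4 * (i % 4), polarity=-1)
    elif sg == "On-Off":
        i = g - 10
        p = dict(w_on=1.0, w_off=0.55 + 0.4 * (i % 2), w_sus_on=0.05 * i, w_sus_off=0.0,
                 tau=0.2 + 0.12 * i, cutoff_hz=7.0 - 0.9 * (i % 3), polarity=1)
    elif sg == "Fast On":
        i = g - 15
        p = dict(w_on=1.0, w_off=0.0, w_sus_on=0.05 + 0.1 * (i % 2), w_sus_off=0.0,
                 tau=0.14 + 0.05 * i, cutoff_hz=9.0 - 0.8 * i, polarity=1)
    elif sg == "Slow On":
        i = g - 21
        p = dict(w_on=0.5 + 0.07 * i, w_off=0.0, w_sus_on=0.45 + 0.18 * (i % 3), w_sus_off=0.0,
                 tau=0.8 + 0.28 * i, cutoff_hz=3.0 - 0.25 * (i % 4), polarity=1)
    else:  # Uncertain
        i = g - 29
        p = dict(w_on=0.35 + 0.25 * (i % 2), w_off=0.35 + 0.25 * ((i + 1) % 2),
                 w_sus_on=0.3 * (i % 2), w_sus_off=0.3 * ((i + 1) % 2),
                 tau=0.4 + 0.5 * i, cutoff_hz=2.0 + 1.0 * i, polarity=1 if i % 2 else -1)
    # segment signatures: frequency-sweep attenuation cutoff and contrast
    # threshold in the amplitude sweep, spread systematically within each
    # super-group so fingerprints separate even after calcium-kernel blur
    if sg == "Fast On":
        p["fc_hz"] = 4.0 + 2.2 * (g - 15)
        p["c_thr"] = 0.10 * ((g - 15) % 3)
    elif sg == "Slow On":
        p["fc_hz"] = 0.7 + 0.45 * (g - 21)
        p["c_thr"] = 0.16 * ((g - 21) % 4)
    elif sg == "Off":
        p["fc_hz"] = 1.2 + 1.1 * ((g - 1) % 5)
        p["c_thr"] = 0.22 * ((g - 1) % 3)
    elif sg == "On-Off":
        p["fc_hz"] = 2.0 + 1.8 * (g - 10)
        p["c_thr"] = 0.14 * ((g - 10) % 3)
    else:
        p["fc_hz"] = 1.0 + 2.0 * (g - 29)
        p["c_thr"] = 0.2 * ((g - 29) % 2)
    # relative segment dominance (step- vs sweep-driven types); coprime
    # index strides decorrelate the pattern from the other parameter cycles
    p["step_gain"] = 0.35 + 1.15 * ((g * 7) % 5) / 4
    p["freq_gain"] = 0.25 + 0.95 * ((g * 3) % 5) / 4
    p["amp_gain"] = 0.25 + 0.95 * ((g * 5) % 4) / 3
    p["jitter"] = u(0.9, 1.1)
    return p


def _chirp_response(chirp: ChirpStimulus, cfg: ChirpConfig, p: dict) -> np.ndarray:
    """LN response of one template to the chirp, with calcium kernel."""
    rate_hz = cfg.sample_rate
    stim_trace = chirp.trace
    sigma = rate_hz / (2 * np.pi * max(p["cutoff_hz"], 0.1))
    s = gaussian_filter1d(stim_trace, sigma=sigma, mode="nearest")
    ds = np.gradient(s) * rate_hz
    drive = (
        p["w_on"] * np.maximum(ds, 0)
        + p["w_off"] * np.maximum(-ds, 0)
        + 4.0 * p["w_sus_on"] * np.maximum(s - 0.5, 0)
        + 4.0 * p["w_sus_off"] * np.maximum(0.5 - s, 0)
    )
    # segment-specific gain: high-frequency attenuation over the frequency
    # sweep, contrast threshold over the amplitude sweep
    gain = np.ones_like(drive)
    for seg in ("step_on", "step_off"):
        t0, t1 = chirp.segments[seg]
        gain[int(t0 * rate_hz):int(t1 * rate_hz) + int(rate_hz)] = p["step_gain"]
    t0, t1 = chirp.segments["freq_sweep"]
    i0, i1 = int(t0 * rate_hz), int(t1 * rate_hz)
    tt = np.arange(i1 - i0) / rate_hz
    f_inst = cfg.freq_start_hz + (cfg.freq_end_hz - cfg.freq_start_hz) * tt / cfg.freq_sweep_s
    gain[i0:i1] = p["freq_gain"] * np.exp(-(f_inst - cfg.freq_start_hz) / p["fc_hz"])
    t0, t1 = chirp.segments["amp_sweep"]
    i0, i1 = int(t0 * rate_hz), int(t1 * rate_hz)
    env = np.arange(i1 - i0) / rate_hz / cfg.amp_sweep_s
    gain[i0:i1] = p["amp_gain"] * np.clip((env - p["c_thr"]) / (1 - p["c_thr"]), 0.0, 1.0)
    drive = drive * gain
    kin = np.exp(-np.arange(0, 4 * p["tau"], 1 / rate_hz) / p["tau"])
    resp = np.convolve(drive, kin / kin.sum())[: len(drive)]
    resp = np.convolve(resp, _calcium_kernel(rate_hz))[: len(drive)]
    return resp * p["jitter"]


def _bar_response(bar: MovingBarStimulus, rate_hz: float, p: dict, rf_sigma_um: float) -> np.ndarray:
    """Template response to one bar sweep (leading and trailing edge)."""
    n = int(round((bar.sweep_duration_s + bar.gap_s) * rate_hz))
    t = np.arange(n) / rate_hz
    travel_mid = bar.sweep_duration_s / 2
    edge_dt = bar.bar_size_um[0] / bar.speed_um_s  # leading-to-trailing delay
    width = (rf_sigma_um * 2) / bar.speed_um_s + 0.05
    lead = np.exp(-0.5 * ((t - travel_mid) / width) ** 2)
    trail = np.exp(-0.5 * ((t - travel_mid - edge_dt) / width) ** 2)
    on_amp = p["w_on"] + p["w_sus_on"]
    off_amp = p["w_off"] + p["w_sus_off"]
    drive = on_amp * lead + off_amp * trail
    kin = np.exp(-np.arange(0, 4 * p["tau"], 1 / rate_hz) / p["tau"])
    resp = np.convolve(drive, kin / kin.sum())[:n]
    return np.convolve(resp, _calcium_kernel(rate_hz))[:n]


def make_type_library(
    seed: int = 0,
    chirp_config: Optional[ChirpConfig] = None,
    bar_config: Optional[BarConfig] = None,
) -> List[TypeTemplate]:
    """Deterministic 32-template library spanning the five super-groups.

    Chirp templates are pairwise distinguishable (Pearson r < 0.95) and
    baseline abundances sum to 1.
    """
    rng = np.random.default_rng(seed)
    chirp_cfg = chirp_config or ChirpConfig(sample_rate=SIM_RATE_HZ)
    chirp = make_chirp(chirp_cfg, n_reps=1)
    bar = make_moving_bar(bar_config, n_reps=1, seed=0)

    raw_abund = 0.5 + rng.random(32)
    abund = raw_abund / raw_abund.sum()

    templates: List[TypeTemplate] = []
    for g in range(1, 33):
        p = _group_params(g, rng)
        rf_sig = (float(rng.uniform(22, 45)), float(rng.uniform(22, 45)))
        chirp_resp = _chirp_response(chirp, chirp_cfg, p)[::DECIMATE]
        # idiosyncratic smooth component: real types differ in ways the
        # coarse LN parameterisation cannot express; this also keeps the 32
        # fingerprints mutually distinguishable
        idio = gaussian_filter1d(rng.normal(size=chirp_resp.shape), sigma=3.0, mode="reflect")
        idio = idio / idio.std() * 0.35 * chirp_resp.std()
        active = chirp_resp > 0.02 * chirp_resp.max()
        chirp_resp = np.maximum(chirp_resp + idio * active, 0.0)
        chirp_resp = chirp_resp / np.max(np.abs(chirp_resp))
        bar_resp = _bar_response(bar, chirp_cfg.sample_rate, p, np.mean(rf_sig))[::DECIMATE]
        bar_resp = bar_resp / np.max(np.abs(bar_resp))
        templates.append(TypeTemplate(
            group_id=g,
            super_group=supergroup(g),
            chirp_template=chirp_resp,
            bar_template=bar_resp,
            ds_flag=g in DS_GROUPS,
            os_flag=g in OS_GROUPS,
            preferred_angle_deg=float(rng.choice(np.arange(8) * 45.0)),
            tuning_exponent=3.0,
            rf_sigma_um=rf_sig,
            rf_polarity=p["polarity"],
            temporal_peak_lag_s=float(rng.uniform(0.08, 0.18)),
            soma_mean_um2=170.0 if g in ALPHA_GROUPS else float(rng.uniform(60, 115)),
            soma_log_sd=0.15 if g in ALPHA_GROUPS else 0.25,
            baseline_abundance=float(abund[g - 1]),
        ))
    return templates


def make_cohort_stimuli(
    seed: int = 0,
    n_chirp_reps: int = 5,
    n_bar_reps: int = 3,
    include_noise: bool = False,
) -> CohortStimuli:
    """The shared stimulus set for one simulated cohort."""
    chirp = make_chirp(ChirpConfig(sample_rate=SIM_RATE_HZ), n_reps=n_chirp_reps)
    bar = make_moving_bar(n_reps=n_bar_reps, seed=seed)
    noise = noise_fine = None
    if include_noise:
        noise = make_shifted_dense_noise(NoiseConfig(), seed=seed)
        noise_fine = rasterize_noise(noise)
    return CohortStimuli(chirp=chirp, bar=bar, noise=noise, noise_fine=noise_fine)


# ---------------------------------------------------------------------------
# single-cell simulation
# ---------------------------------------------------------------------------

def _place(trace: np.ndarray, start_s: float, chunk: np.ndarray, rate: float) -> None:
    i0 = int(np.rint(start_s * rate))
    i1 = min(i0 + len(chunk), len(trace))
    trace[i0:i1] += chunk[: i1 - i0]


def _noise_background(n: int, rng: np.random.Generator, noise_scale: float,
                      rate: float) -> np.ndarray:
    """White noise plus slow drift (time constant >= 30 s), both scaled by
    ``noise_scale`` so a noiseless cell is exactly repeatable."""
    if noise_scale == 0:
        return np.zeros(n)
    white = rng.normal(0.0, 0.12 * noise_scale, size=n)
    t = np.arange(n) / rate
    slow = np.zeros(n)
    for _ in range(2):  # two slow sinusoids, periods 60-300 s
        period = rng.uniform(60.0, 300.0)
        slow += rng.uniform(0.5, 1.0) * np.sin(2 * np.pi * t / period + rng.uniform(0, 2 * np.pi))
    sd = slow.std()
    if sd > 0:
        slow = slow / sd * 0.30 * noise_scale
    return white + slow


def _simulate_noise_response(
    template: TypeTemplate,
    noise_fine: np.ndarray,
    rf_center_px: Tuple[float, float],
    rf_size_scale: float,
    kinetics_scale: float,
    pixel_size_um: float,
    stim_rate: float,
    out_rate: float,
    duration_s: float,
    response_sd: float = 1.0,
    t_offset_s: float = 0.0,
) -> np.ndarray:
    """Linear-nonlinear-calcium response to the rasterized shifted noise.

    The fluorescence is scaled to a fixed standard deviation so simulated
    dF/F stays on the same O(1) scale as the chirp/bar responses.
    """
    nf, dx, dy = noise_fine.shape
    xx, yy = np.meshgrid(np.arange(dx), np.arange(dy), indexing="ij")
    sx = template.rf_sigma_um[0] * rf_size_scale / pixel_size_um
    sy = template.rf_sigma_um[1] * rf_size_scale / pixel_size_um
    spatial = np.exp(-0.5 * (((xx - rf_center_px[0]) / sx) ** 2 + ((yy - rf_center_px[1]) / sy) ** 2))
    spatial = template.rf_polarity * spatial / np.abs(spatial).sum()

    sim_rate = 50.0
    factor = int(round(sim_rate / stim_rate))
    proj = np.tensordot(noise_fine - 0.5, spatial, axes=([1, 2], [0, 1]))
    proj_up = np.repeat(proj, factor)
    kt = _temporal_kernel(template.temporal_peak_lag_s * kinetics_scale, +1, rate_hz=sim_rate)
    g = np.convolve(proj_up, kt)[: len(proj_up)]
    rate_sig = np.maximum(g, 0.0)
    fluor = np.convolve(rate_sig, _calcium_kernel(sim_rate))[: len(rate_sig)]
    sd = fluor.std()
    if sd > 0:
        fluor = fluor * (response_sd / sd)
    t_out = np.arange(int(round(duration_s * out_rate))) / out_rate + t_offset_s
    t_sim = np.arange(len(fluor)) / sim_rate
    return np.interp(t_out, t_sim, fluor)


def simulate_cell(
    template: TypeTemplate,
    stimuli: CohortStimuli,
    noise_scale: float = 1.0,
    seed: int | np.random.SeedSequence = 0,
    responsive: bool = True,
    amplitude: Optional[float] = None,
    rf_size_scale: float = 1.0,
    kinetics_scale: float = 1.0,
    soma_size_um2: Optional[float] = None,
    cell_id: str = "cell",
    field_id: str = "field",
    genotype: str = "wt",
    age: str = "P30",
    pixel_size_um: float = 12.5,
) -> CellRecord:
    """Simulate one GCL cell's recordings for the cohort stimulus set.

    Chirp and bar responses follow the template across repetitions up to
    noise; the shifted-noise response is generated from the template's
    ground-truth separable RF through the LN-calcium cascade.
    """
    rng = np.random.default_rng(seed)
    fs = RECORDING_RATE_HZ
    amp = amplitude if amplitude is not None else float(rng.lognormal(0.0, 0.2))
    if not responsive:
        amp = 0.0
    soma = soma_size_um2 if soma_size_um2 is not None else float(
        np.exp(rng.normal(np.log(template.soma_mean_um2), template.soma_log_sd))
    )

    traces: Dict[str, np.ndarray] = {}
    triggers: Dict[str, np.ndarray] = {}

    # chirp
    chirp = stimuli.chirp
    rep_dur = chirp.rep_duration_s
    total_s = PRE_STIMULUS_S + chirp.n_reps * rep_dur + 2.0
    n = int(round(total_s * fs))
    tr = np.zeros(n)
    trig = PRE_STIMULUS_S + chirp.trigger_times
    for t0 in trig:
        _place(tr, t0, amp * template.chirp_template, fs)
    tr += _noise_background(n, rng, noise_scale, fs)
    traces["chirp"] = tr
    triggers["chirp"] = trig

    # moving bar
    bar = stimuli.bar
    dirs = bar.trial_directions()
    total_s = PRE_STIMULUS_S + len(dirs) * bar.trial_duration_s + 2.0
    n = int(round(total_s * fs))
    tr = np.zeros(n)
    trig = PRE_STIMULUS_S + bar.trigger_times
    for t0, d in zip(trig, dirs):
        _place(tr, t0, amp * template.tuning_gain(d) * template.bar_template, fs)
    tr += _noise_background(n, rng, noise_scale, fs)
    traces["bar"] = tr
    triggers["bar"] = trig

    gt_rf_center = None
    if stimuli.noise_fine is not None:
        nf = stimuli.noise_fine
        cx = nf.shape[1] / 2 - 0.5 + rng.uniform(-3, 3)
        cy = nf.shape[2] / 2 - 0.5 + rng.uniform(-3, 3)
        gt_rf_center = (float(cx), float(cy))
        dur = PRE_STIMULUS_S + nf.shape[0] / stimuli.noise.config.frame_rate_hz + 2.0
        n = int(round(dur * fs))
        tr = np.zeros(n)
        if responsive:
            # the placement index rounds the trigger to the sample grid;
            # generate the response on exactly that (slightly offset) grid
            i0 = int(np.rint(PRE_STIMULUS_S * fs))
            resp = _simulate_noise_response(
                template, nf, gt_rf_center, rf_size_scale, kinetics_scale,
                pixel_size_um, stimuli.noise.config.frame_rate_hz, fs,
                dur - PRE_STIMULUS_S, t_offset_s=i0 / fs - PRE_STIMULUS_S,
            )
            _place(tr, PRE_STIMULUS_S, amp * resp, fs)
        tr += _noise_background(n, rng, noise_scale, fs)
        traces["noise"] = tr
        triggers["noise"] = np.array([PRE_STIMULUS_S])

    return CellRecord(
        cell_id=cell_id,
        field_id=field_id,
        genotype=genotype,
        age=age,
        soma_size_um2=soma,
        traces=traces,
        triggers=triggers,
        ground_truth={
            "group_id": template.group_id,
            "super_group": template.super_group,
            "responsive": bool(responsive),
            "amplitude": amp,
            "rf_sigma_um": tuple(s * rf_size_scale for s in template.rf_sigma_um),
            "rf_center_px": gt_rf_center,
            "temporal_peak_lag_s": template.temporal_peak_lag_s * kinetics_scale,
        },
    )


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

def simulate_cohort(
    genotype: str,
    age: str,
    schedule: Optional[DegenerationSchedule] = None,
    n_fields: int = 4,
    seed: int = 0,
    library: Optional[Sequence[TypeTemplate]] = None,
    stimuli: Optional[CohortStimuli] = None,
    include_noise: bool = False,
    base_responsive: float = BASE_RESPONSIVE_FRACTION,
) -> List[CellRecord]:
    """Simulate ``n_fields`` recording fields of one (genotype, age) cohort.

    Cell counts are drawn uniformly in [100, 120]; each cell draws a type
    from the baseline abundances and is responsive with probability
    ``base_responsive`` times the schedule's (super-group, age) multiplier.
    Non-responsive cells carry noise-only traces.
    """
    if genotype not in ("wt", "rd10"):
        raise ValueError(f"unknown genotype {genotype!r}")
    if age not in AGES:
        raise ValueError(f"unknown age {age!r}")
    if schedule is None:
        schedule = wildtype_schedule() if genotype == "wt" else default_rd10_schedule()
    library = list(library) if library is not None else make_type_library(seed=0)
    stimuli = stimuli or make_cohort_stimuli(seed=0, include_noise=include_noise)

    abund = np.array([t.baseline_abundance for t in library])
    abund = abund / abund.sum()
    tag = zlib.crc32(f"{genotype}|{age}".encode())
    ss = np.random.SeedSequence([seed & 0x7FFFFFFF, tag & 0x7FFFFFFF])
    field_seeds = ss.spawn(n_fields)

    cells: List[CellRecord] = []
    for f, fseed in enumerate(field_seeds):
        frng = np.random.default_rng(fseed)
        n_cells = int(frng.integers(100, 121))
        cell_seeds = fseed.spawn(n_cells)
        field_id = f"{genotype}_{age}_f{f:02d}"
        for c in range(n_cells):
            crng = np.random.default_rng(cell_seeds[c])
            tpl = library[int(crng.choice(len(library), p=abund))]
            p_resp = base_responsive * schedule.multiplier(tpl.super_group, age)
            responsive = bool(crng.random() < p_resp)
            cells.append(simulate_cell(
                tpl, stimuli,
                noise_scale=schedule.noise_scale[age],
                seed=cell_seeds[c].spawn(1)[0],
                responsive=responsive,
                rf_size_scale=schedule.rf_size_scale[age],
                kinetics_scale=schedule.kinetics_scale[age],
                cell_id=f"{field_id}_c{c:03d}",
                field_id=field_id,
                genotype=genotype,
                age=age,
            ))
    return cells
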