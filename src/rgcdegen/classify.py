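"""Functional type assignment and derived cell-level indices.

Responsive cells are mapped to one of 32 functional RGC groups (G1-G32,
aggregated into the five super-groups 'Off', 'On-Off', 'Fast On', 'Slow On'
and 'Uncertain') by a nearest-template classifier: chirp and moving-bar mean
snippets are projected onto a fixed low-dimensional basis built from the
template library, combined with the direction-selectivity permutation
p-value and the soma size into a similarity per template. The confidence
score (CS) is a squashed top-two similarity margin; only cells with
CS >= 0.25 enter type-resolved analyses.

This classifier is a self-contained surrogate for the published
random-forest classifier (external prior work trained on a reference
dataset); it is calibrated only on the synthetic template library.

Also here: the On-Off index (OOi) with its three reporting bins, and the
large-soma alpha-RGC flag (soma area > 136 um^2).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "SUPER_GROUP_NAMES",
    "TypeAssignment",
    "CellFeatures",
    "TemplateClassifier",
    "supergroup",
    "on_off_index",
    "alpha_flag",
    "type_mean_responses",
    "CS_THRESHOLD",
    "ALPHA_SOMA_UM2",
]

CS_THRESHOLD = 0.25
ALPHA_SOMA_UM2 = 136.0

SUPER_GROUP_NAMES = ("Off", "On-Off", "Fast On", "Slow On", "Uncertain")

# Fixed group -> super-group lookup following the reference functional
# taxonomy (G1 'Off local, OS' ... G17 'On local transient' ... G27 'On slow'
# ... G32 uncertain). Groups 1-9 Off, 10-14 On-Off, 15-20 Fast On,
# 21-28 Slow On, 29-32 Uncertain.
_SUPER_GROUP_OF: Dict[int, str] = {}
for _g in range(1, 33):
    if _g <= 9:
        _SUPER_GROUP_OF[_g] = "Off"
    elif _g <= 14:
        _SUPER_GROUP_OF[_g] = "On-Off"
    elif _g <= 20:
        _SUPER_GROUP_OF[_g] = "Fast On"
    elif _g <= 28:
        _SUPER_GROUP_OF[_g] = "Slow On"
    else:
        _SUPER_GROUP_OF[_g] = "Uncertain"


def supergroup(group_id: int) -> str:
    """Super-group label for a functional group id (1-32)."""
    try:
        return _SUPER_GROUP_OF[int(group_id)]
    except (KeyError, TypeError, ValueError):
        raise ValueError(f"unknown functional group id: {group_id!r}") from None


@dataclass(frozen=True)
class TypeAssignment:
    group_id: Optional[int]       # 1-32 or None when unassigned
    confidence: float             # CS in [0, 1]
    super_group: Optional[str]
    similarities: np.ndarray      # per-template similarity, length 32

    @property
    def included(self) -> bool:
        return self.group_id is not None and self.confidence >= CS_THRESHOLD


@dataclass(frozen=True)
class CellFeatures:
    chirp: np.ndarray    # projection on the chirp basis
    bar: np.ndarray      # projection on the bar basis
    p_ds: float
    soma_size_um2: float


def _pca_basis(traces: np.ndarray, n_components: int) -> Tuple[np.ndarray, np.ndarray]:
    """Principal directions of the (centred) template trace matrix."""
    mean = traces.mean(axis=0)
    _, _, vt = np.linalg.svd(traces - mean, full_matrices=False)
    return mean, vt[:n_components]


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


class TemplateClassifier:
    """Nearest-template classifier over the 32-group library.

    Parameters
    ----------
    chirp_templates, bar_templates
        Arrays (32, T) of reference mean snippets, processed identically to
        the cell snippets they will be compared against.
    ds_flags
        Boolean per template: whether the group is direction selective.
    soma_means_um2
        Mean soma area per template, um^2.
    """

    W_CHIRP, W_BAR, W_DS, W_SOMA = 0.70, 0.30, 0.05, 0.05
    SOMA_LOG_SD = 0.35
    P_DS_CUTOFF = 0.05

    def __init__(
        self,
        chirp_templates: np.ndarray,
        bar_templates: np.ndarray,
        ds_flags: Sequence[bool],
        soma_means_um2: Sequence[float],
        n_chirp_components: int = 20,
        n_bar_components: int = 8,
    ) -> None:
        self.chirp_templates = np.asarray(chirp_templates, dtype=np.float64)
        self.bar_templates = np.asarray(bar_templates, dtype=np.float64)
        self.ds_flags = np.asarray(ds_flags, dtype=bool)
        self.soma_means = np.asarray(soma_means_um2, dtype=np.float64)
        self.n_templates = self.chirp_templates.shape[0]

        self.chirp_mean, self.chirp_basis = _pca_basis(self.chirp_templates, n_chirp_components)
        self.bar_mean, self.bar_basis = _pca_basis(self.bar_templates, n_bar_components)
        self._template_features = [
            self._project(self.chirp_templates[i], self.bar_templates[i])
            for i in range(self.n_templates)
        ]
        self.margin_scale = self._calibrate_margin_scale()

    # -- features ----------------------------------------------------------

    def _project(self, chirp_snippet: np.ndarray, bar_snippet: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        c = self.chirp_basis @ (chirp_snippet - self.chirp_mean)
        b = self.bar_basis @ (bar_snippet - self.bar_mean)
        return c, b

    def extract_features(
        self,
        chirp_snippet: Optional[np.ndarray],
        bar_snippet: Optional[np.ndarray],
        p_ds: float,
        soma_size_um2: float,
    ) -> Optional[CellFeatures]:
        """Fixed-length feature vector; ``None`` if a stimulus is missing
        (the cell is then excluded from typing)."""
        if chirp_snippet is None or bar_snippet is None:
            return None
        c, b = self._project(np.asarray(chirp_snippet), np.asarray(bar_snippet))
        return CellFeatures(chirp=c, bar=b, p_ds=float(p_ds), soma_size_um2=float(soma_size_um2))

    def reconstruct_chirp(self, features: CellFeatures) -> np.ndarray:
        return self.chirp_mean + features.chirp @ self.chirp_basis

    # -- assignment --------------------------------------------------------

    def _similarities(self, features: CellFeatures) -> np.ndarray:
        sims = np.empty(self.n_templates)
        cell_ds = features.p_ds < self.P_DS_CUTOFF
        for i, (tc, tb) in enumerate(self._template_features):
            rc = _safe_corr(features.chirp, tc)
            rb = _safe_corr(features.bar, tb)
            if np.isnan(rc):
                sims[i] = np.nan
                continue
            rb = 0.0 if np.isnan(rb) else rb
            soma_aff = np.exp(
                -0.5 * (np.log(max(features.soma_size_um2, 1.0) / self.soma_means[i]) / self.SOMA_LOG_SD) ** 2
            )
            sims[i] = (
                self.W_CHIRP * rc
                + self.W_BAR * rb
                + self.W_DS * (1.0 if cell_ds == self.ds_flags[i] else 0.0)
                + self.W_SOMA * soma_aff
            )
        return sims

    def _calibrate_margin_scale(self) -> float:
        """Map the smallest noiseless template margin to CS = 0.8."""
        margins = []
        for i in range(self.n_templates):
            feats = CellFeatures(
                chirp=self._template_features[i][0],
                bar=self._template_features[i][1],
                p_ds=0.0 if self.ds_flags[i] else 1.0,
                soma_size_um2=self.soma_means[i],
            )
            sims = self._similarities(feats)
            order = np.argsort(sims)
            margins.append(sims[order[-1]] - sims[order[-2]])
        min_margin = max(min(margins), 1e-3)
        return float(np.clip(np.arctanh(0.8) / min_margin, 1.0, 200.0))

    def assign_type(self, features: Optional[CellFeatures]) -> TypeAssignment:
        """Best-matching group with a squashed top-two-margin confidence."""
        empty = np.full(self.n_templates, np.nan)
        if features is None:
            return TypeAssignment(None, 0.0, None, empty)
        sims = self._similarities(features)
        if np.all(np.isnan(sims)):
            return TypeAssignment(None, 0.0, None, sims)
        order = np.argsort(np.nan_to_num(sims, nan=-np.inf))
        top1, top2 = order[-1], order[-2]
        margin = sims[top1] - sims[top2]
        cs = float(np.tanh(self.margin_scale * margin))
        group = int(top1) + 1
        return TypeAssignment(group, cs, supergroup(group), sims)


# ---------------------------------------------------------------------------
# cell-level indices
# ---------------------------------------------------------------------------

def on_off_index(a_on: float, a_off: float) -> Tuple[Optional[float], Optional[str]]:
    """On-Off index (a_on - a_off) / (a_on + a_off) with its reporting bin.

    Bins (right-inclusive): Off (-1, -0.2], On-Off (-0.2, 0.2], On (0.2, 1].
    Both amplitudes zero -> undefined, the cell is excluded.
    """
    if a_on < 0 or a_off < 0:
        raise ValueError("phase amplitudes must be nonnegative")
    total = a_on + a_off
    if total == 0:
        return None, None
    ooi = (a_on - a_off) / total
    eps = 1e-12  # keep exact bin edges stable against float rounding
    if ooi <= -0.2 + eps:
        return float(ooi), "Off"
    if ooi <= 0.2 + eps:
        return float(ooi), "On-Off"
    return float(ooi), "On"


def step_amplitudes(
    chirp_mean_snippet: np.ndarray,
    sample_rate: float,
    on_window_s: Tuple[float, float],
    off_window_s: Tuple[float, float],
    baseline_window_s: Tuple[float, float],
) -> Tuple[float, float]:
    """On/Off phase amplitudes: peak above the pre-step baseline within
    windows locked to the chirp's light step onset and offset."""
    snip = np.asarray(chirp_mean_snippet, dtype=np.float64)

    def window(w):
        i0, i1 = int(w[0] * sample_rate), int(w[1] * sample_rate)
        return snip[i0:max(i1, i0 + 1)]

    base = window(baseline_window_s).mean()
    a_on = max(0.0, float(window(on_window_s).max() - base))
    a_off = max(0.0, float(window(off_window_s).max() - base))
    return a_on, a_off


def alpha_flag(soma_size_um2: float) -> bool:
    """Alpha-RGC flag: soma area strictly greater than 136 um^2."""
    if soma_size_um2 <= 0:
        raise ValueError("soma size must be positive")
    return bool(soma_size_um2 > ALPHA_SOMA_UM2)


def type_mean_responses(
    group_ids: Sequence[Optional[int]],
    snippets: Sequence[np.ndarray],
    included: Sequence[bool],
) -> Dict[int, Optional[np.ndarray]]:
    """Per-type mean of normalised snippets over included cells.

    Types without any included cell map to ``None`` (missing).
    """
    sums: Dict[int, np.ndarray] = {}
    counts: Dict[int, int] = {}
    for gid, snip, inc in zip(group_ids, snippets, included):
        if gid is None or not inc:
            continue
        arr = np.asarray(snip, dtype=np.float64)
        if gid in sums:
            sums[gid] = sums[gid] + arr
            counts[gid] += 1
        else:
            sums[gid] = arr.copy()
            counts[gid] = 1
    return {g: (sums[g] / counts[g] if g in sums else None) for g in range(1, 33)}
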