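"""End-to-end cohort analysis: simulate or load cell records, preprocess,
gate responsiveness, compute tuning, assign functional types and build the
cohort-level statistics tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from . import AGES, RECORDING_RATE_HZ
from . import classify, cohort_stats, preprocess, tuning
from .classify import TemplateClassifier, supergroup
from .synthetic_cohort import (
    CellRecord,
    CohortStimuli,
    DegenerationSchedule,
    TypeTemplate,
    default_rd10_schedule,
    make_cohort_stimuli,
    make_type_library,
    simulate_cell,
    simulate_cohort,
    wildtype_schedule,
)

__all__ = [
    "PreprocessedCell",
    "preprocess_cell",
    "build_classifier",
    "analyze_cells",
    "run_cohort_analysis",
    "CohortAnalysis",
]


@dataclass
class PreprocessedCell:
    qi_chirp: float
    qi_mb: float
    responsive: bool
    chirp_mean: Optional[np.ndarray]
    bar_mean: Optional[np.ndarray]
    bar_by_direction: Optional[Dict[float, np.ndarray]]
    chirp_matrix: Optional[np.ndarray]


def _snippet_len(duration_s: float, fs: float) -> int:
    return int(np.floor(duration_s * fs))


def preprocess_cell(record: CellRecord, stimuli: CohortStimuli) -> PreprocessedCell:
    """Detrend, normalise and snippet one cell; compute both QIs."""
    fs = record.sample_rate
    out: Dict[str, Optional[np.ndarray]] = {"chirp": None, "bar": None}
    mats: Dict[str, Optional[np.ndarray]] = {"chirp": None, "bar": None}
    qis = {"chirp": 0.0, "bar": 0.0}
    durations = {
        "chirp": stimuli.chirp.rep_duration_s,
        "bar": stimuli.bar.trial_duration_s,
    }
    for stim_name in ("chirp", "bar"):
        trace = record.traces.get(stim_name)
        if trace is None:
            continue
        det = preprocess.detrend(trace, fs)
        norm = preprocess.baseline_normalize(det)
        if not norm.valid:
            continue
        mat = preprocess.snippet(
            norm.trace, record.triggers[stim_name],
            _snippet_len(durations[stim_name], fs), fs, stimulus_id=stim_name,
        )
        qis[stim_name] = preprocess.quality_index(mat)
        out[stim_name] = mat.data.mean(axis=1)
        mats[stim_name] = mat.data

    bar_by_dir = None
    if mats["bar"] is not None:
        dirs = stimuli.bar.trial_directions()
        bar_by_dir = {
            d: mats["bar"][:, dirs == d] for d in np.unique(dirs)
        }
    return PreprocessedCell(
        qi_chirp=qis["chirp"],
        qi_mb=qis["bar"],
        responsive=preprocess.gate_responsive(qis["chirp"], qis["bar"]),
        chirp_mean=out["chirp"],
        bar_mean=out["bar"],
        bar_by_direction=bar_by_dir,
        chirp_matrix=mats["chirp"],
    )


def build_classifier(
    library: Sequence[TypeTemplate],
    stimuli: CohortStimuli,
    n_chirp_components: int = 20,
    n_bar_components: int = 8,
) -> TemplateClassifier:
    """Template classifier whose reference snippets are noiseless simulated
    cells passed through the identical preprocessing as real cells."""
    chirp_refs, bar_refs = [], []
    for tpl in library:
        rec = simulate_cell(tpl, stimuli, noise_scale=0.0, seed=0, amplitude=1.0)
        pre = preprocess_cell(rec, stimuli)
        if pre.chirp_mean is None or pre.bar_mean is None:
            raise RuntimeError(f"template G{tpl.group_id} produced no usable reference snippet")
        chirp_refs.append(pre.chirp_mean)
        bar_refs.append(pre.bar_mean)
    return TemplateClassifier(
        np.stack(chirp_refs), np.stack(bar_refs),
        ds_flags=[t.ds_flag for t in library],
        soma_means_um2=[t.soma_mean_um2 for t in library],
        n_chirp_components=n_chirp_components,
        n_bar_components=n_bar_components,
    )


def analyze_cells(
    records: Sequence[CellRecord],
    stimuli: CohortStimuli,
    classifier: TemplateClassifier,
    n_perm: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-cell table: QIs, responsiveness, DS/OS, type assignment, OOi and
    the alpha flag. Tuning and typing are computed for responsive cells."""
    chirp_segments = stimuli.chirp.segments
    on_w = chirp_segments["step_on"]
    off_w = chirp_segments["step_off"]
    base_w = chirp_segments["baseline"]
    rows = []
    for i, rec in enumerate(records):
        pre = preprocess_cell(rec, stimuli)
        row = {
            "cell_id": rec.cell_id, "field_id": rec.field_id,
            "genotype": rec.genotype, "age": rec.age,
            "soma_size_um2": rec.soma_size_um2,
            "qi_chirp": pre.qi_chirp, "qi_mb": pre.qi_mb,
            "responsive": pre.responsive,
            "dsi": np.nan, "osi": np.nan, "p_ds": np.nan, "p_os": np.nan,
            "group_id": None, "confidence": 0.0, "super_group": None,
            "included": False, "ooi": np.nan, "ooi_bin": None,
            "is_alpha": classify.alpha_flag(rec.soma_size_um2),
            "gt_group": rec.ground_truth.get("group_id"),
            "gt_responsive": rec.ground_truth.get("responsive"),
        }
        if pre.responsive and pre.bar_by_direction is not None:
            dirs = sorted(pre.bar_by_direction)
            tun = tuning.analyze_tuning(
                [pre.bar_by_direction[d] for d in dirs], np.array(dirs),
                n_perm=n_perm, seed=seed + i,
            )
            row.update(dsi=tun.dsi, osi=tun.osi, p_ds=tun.p_ds, p_os=tun.p_os)
            feats = classifier.extract_features(
                pre.chirp_mean, pre.bar_mean, tun.p_ds, rec.soma_size_um2
            )
            assign = classifier.assign_type(feats)
            row.update(
                group_id=assign.group_id, confidence=assign.confidence,
                super_group=assign.super_group, included=assign.included,
            )
            if pre.chirp_mean is not None:
                a_on, a_off = classify.step_amplitudes(
                    pre.chirp_mean, RECORDING_RATE_HZ, on_w, off_w, base_w
                )
                ooi, ooi_bin = classify.on_off_index(a_on, a_off)
                row.update(ooi=ooi, ooi_bin=ooi_bin)
        row["_chirp_mean"] = pre.chirp_mean
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class CohortAnalysis:
    cells: pd.DataFrame
    responsive_fractions: pd.DataFrame     # per (genotype, age): mean, sd across fields
    abundance_by_age: Dict[str, pd.DataFrame]
    supergroup_abundance: pd.Series        # mean relative abundance, descending
    resilience_ranking: List[str]


def run_cohort_analysis(
    seed: int = 0,
    ages: Sequence[str] = AGES,
    n_fields: int = 4,
    schedule_rd10: Optional[DegenerationSchedule] = None,
    library: Optional[Sequence[TypeTemplate]] = None,
    n_perm: int = 200,
    abundance_ages: Sequence[str] = ("P30", "P45", "P90"),
) -> CohortAnalysis:
    """Simulate wild-type and rd10 cohorts at the given ages and run the full
    chirp/bar analysis: responsiveness, typing and abundance statistics."""
    library = list(library) if library is not None else make_type_library(seed=0)
    stimuli = make_cohort_stimuli(seed=0)
    classifier = build_classifier(library, stimuli)
    schedule_rd10 = schedule_rd10 or default_rd10_schedule()
    schedules = {"wt": wildtype_schedule(), "rd10": schedule_rd10}

    frames = []
    for genotype in ("wt", "rd10"):
        for age in ages:
            records = simulate_cohort(
                genotype, age, schedules[genotype], n_fields=n_fields,
                seed=seed, library=library, stimuli=stimuli,
            )
            frames.append(analyze_cells(records, stimuli, classifier, n_perm=n_perm, seed=seed))
    cells = pd.concat(frames, ignore_index=True)

    rf_rows = []
    for (genotype, age), sub in cells.groupby(["genotype", "age"]):
        per_field, mean, sd = cohort_stats.responsive_fraction(sub["field_id"], sub["responsive"])
        rf_rows.append({"genotype": genotype, "age": age, "mean": mean, "sd": sd,
                        "n_fields": len(per_field), "n_cells": len(sub)})
    responsive_fractions = pd.DataFrame(rf_rows)

    # abundance statistics follow the binomial-test design: computed for the
    # ages with usable rd10 cohorts (by P180 almost no rd10 cell responds)
    abundance_by_age: Dict[str, pd.DataFrame] = {}
    for age in [a for a in ages if a in abundance_ages]:
        inc = cells[(cells["age"] == age) & cells["included"]]
        counts = {
            gt: inc[inc["genotype"] == gt].groupby("group_id").size().to_dict()
            for gt in ("wt", "rd10")
        }
        if counts["wt"] and counts["rd10"]:
            abundance_by_age[age] = cohort_stats.abundance_table(counts["wt"], counts["rd10"])

    sg_of = {g: supergroup(g) for g in range(1, 33)}
    supergroup_abundance = cohort_stats.supergroup_mean_abundance(abundance_by_age, sg_of)
    return CohortAnalysis(
        cells=cells,
        responsive_fractions=responsive_fractions,
        abundance_by_age=abundance_by_age,
        supergroup_abundance=supergroup_abundance,
        resilience_ranking=list(supergroup_abundance.index),
    )
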