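"""HDF5 / CSV persistence for stimuli, cohorts and result tables."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import h5py
import numpy as np
import pandas as pd

from .stimuli import NoiseConfig, ShiftedDenseNoise
from .synthetic_cohort import CellRecord

__all__ = [
    "load_stimulus_config",
    "save_noise_stimulus",
    "load_noise_stimulus",
    "save_cohort",
    "load_cohort",
    "save_rf_models",
    "cohort_manifest",
    "write_manifest",
]

def load_stimulus_config(path: str | Path):
    """Read stimulus configs from a YAML (or JSON) file.

    The file maps section names (``chirp``, ``bar``, ``noise``) to keyword
    fields of the corresponding config dataclass; missing sections keep
    their defaults.
    """
    import yaml

    from .stimuli import BarConfig, ChirpConfig

    data = yaml.safe_load(Path(path).read_text()) or {}
    types = {"chirp": ChirpConfig, "bar": BarConfig, "noise": NoiseConfig}
    out = {}
    for section, cls in types.items():
        out[section] = cls(**data.get(section, {}))
    return out


def save_noise_stimulus(stim: ShiftedDenseNoise, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("frames", data=stim.frames, dtype="uint8")
        f.create_dataset("shift_offsets", data=stim.shift_offsets, dtype="int16")
        f.attrs["seed"] = stim.seed
        for key, value in vars(stim.config).items():
            f.attrs[key] = value


def load_noise_stimulus(path: str | Path) -> ShiftedDenseNoise:
    with h5py.File(path, "r") as f:
        cfg = NoiseConfig(
            n_checks_x=int(f.attrs["n_checks_x"]),
            n_checks_y=int(f.attrs["n_checks_y"]),
            check_size_um=float(f.attrs["check_size_um"]),
            frame_rate_hz=float(f.attrs["frame_rate_hz"]),
            duration_s=float(f.attrs["duration_s"]),
            shift_grid_um=float(f.attrs["shift_grid_um"]),
        )
        return ShiftedDenseNoise(
            config=cfg,
            frames=f["frames"][()],
            shift_offsets=f["shift_offsets"][()],
            seed=int(f.attrs["seed"]),
        )


def save_cohort(cells: Sequence[CellRecord], path: str | Path) -> None:
    """One HDF5 group per cell: traces/<stimulus>, triggers/<stimulus> and
    scalar attributes; ground truth in a subgroup."""
    with h5py.File(path, "w") as f:
        for cell in cells:
            g = f.create_group(cell.cell_id)
            g.attrs.update({
                "field_id": cell.field_id, "genotype": cell.genotype,
                "age": cell.age, "soma_size_um2": cell.soma_size_um2,
                "sample_rate": cell.sample_rate,
            })
            tg = g.create_group("traces")
            for name, trace in cell.traces.items():
                tg.create_dataset(name, data=trace)
            rg = g.create_group("triggers")
            for name, trig in cell.triggers.items():
                rg.create_dataset(name, data=trig)
            gt = g.create_group("ground_truth")
            for key, value in cell.ground_truth.items():
                if value is None:
                    continue
                gt.attrs[key] = value


def load_cohort(path: str | Path) -> List[CellRecord]:
    cells = []
    with h5py.File(path, "r") as f:
        for cell_id in f:
            g = f[cell_id]
            cells.append(CellRecord(
                cell_id=cell_id,
                field_id=str(g.attrs["field_id"]),
                genotype=str(g.attrs["genotype"]),
                age=str(g.attrs["age"]),
                soma_size_um2=float(g.attrs["soma_size_um2"]),
                traces={k: g["traces"][k][()] for k in g["traces"]},
                triggers={k: g["triggers"][k][()] for k in g["triggers"]},
                sample_rate=float(g.attrs["sample_rate"]),
                ground_truth=dict(g["ground_truth"].attrs),
            ))
    return cells


def save_rf_models(models: Dict[str, "object"], path: str | Path) -> None:
    """Write fitted RF models to HDF5: per cell a group with datasets
    ``rf/F``, ``rf/Ft``, ``rf/Fs`` and the scalar metrics as attributes."""
    with h5py.File(path, "w") as f:
        for cell_id, model in models.items():
            g = f.create_group(cell_id).create_group("rf")
            g.create_dataset("F", data=model.F)
            g.create_dataset("Ft", data=model.Ft)
            g.create_dataset("Fs", data=model.Fs)
            g.attrs.update({
                "qi_svd": model.qi_svd,
                "qi_srf": model.qi_srf,
                "rf_area_um2": model.rf_area_um2,
                "rf_diameter_um": model.rf_diameter_um,
                "main_peak_lag_s": np.nan if model.main_peak_lag_s is None else model.main_peak_lag_s,
                "passes_quality": model.passes_quality,
            })


def cohort_manifest(cells: Sequence[CellRecord]) -> pd.DataFrame:
    """One row per cell: identity, cohort labels and soma size."""
    return pd.DataFrame([
        {
            "cell_id": c.cell_id, "field_id": c.field_id,
            "genotype": c.genotype, "age": c.age,
            "soma_size_um2": c.soma_size_um2,
            "gt_group": c.ground_truth.get("group_id"),
            "gt_responsive": c.ground_truth.get("responsive"),
        }
        for c in cells
    ])


def write_manifest(path: str | Path, seed: int, config: Optional[Dict] = None) -> None:
    """Run manifest: seed, package and library versions, free-form config."""
    import scipy

    from . import __version__

    manifest = {
        "package_version": __version__,
        "seed": seed,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "config": config or {},
    }
    Path(path).write_text(json.dumps(manifest, indent=2, default=str))
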