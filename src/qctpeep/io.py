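"""File-format adapters: NIfTI volumes, CSV tables, JSON reports.

Conventions: pressures in cmH2O everywhere (mmHg converted on read when
flagged), CSV files UTF-8 with a header row and dot decimals, HU assumed
already rescaled.  All writers emit byte-stable output for identical
inputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .aeration import DEFAULT_BIN_EDGES, CTVolume, LungMask
from .pv_model import PVDataset

__all__ = [
    "CMH2O_PER_MMHG",
    "mmhg_to_cmh2o",
    "RunConfig",
    "read_ct",
    "read_mask",
    "write_nifti",
    "read_pv_table",
    "write_pv_table",
    "read_titration_table",
    "write_titration_table",
    "load_reference_medians",
    "write_json",
]

#: Pressure unit conversion.
CMH2O_PER_MMHG = 1.36

PV_COLUMNS = ["pressure_cmH2O", "volume", "compartment", "condition", "phase"]
TITRATION_COLUMNS = ["subject", "condition", "phase", "peep_cmH2O", "endpoint", "value"]


def mmhg_to_cmh2o(pressure_mmhg: float) -> float:
    return pressure_mmhg * CMH2O_PER_MMHG


@dataclass(frozen=True)
class RunConfig:
    """Pipeline configuration shared by the CLI commands."""

    bin_edges: tuple[float, ...] = DEFAULT_BIN_EDGES
    n_segments: int = 3
    peep_levels: tuple[float, ...] = (5.0, 12.0, 17.0, 22.0, 27.0)
    fit_families: tuple[str, ...] = ("venegas", "exponential", "linear")
    seed: int = 0
    output_dir: Path = field(default_factory=lambda: Path("."))

    def __post_init__(self) -> None:
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")


def read_ct(path: str | Path, dependent_axis: int = 2) -> CTVolume:
    """Load a NIfTI CT volume (rescaled HU) as a :class:`CTVolume`."""
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=float)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return CTVolume(hu=data, spacing=spacing, dependent_axis=dependent_axis)


def read_mask(path: str | Path) -> LungMask:
    """Load a NIfTI binary mask (non-zero = lung)."""
    img = nib.load(str(path))
    return LungMask(inside=np.asarray(img.get_fdata()) > 0.5)


def write_nifti(path: str | Path, array: np.ndarray, spacing: tuple[float, ...]) -> None:
    affine = np.diag(list(spacing) + [1.0])
    img = nib.Nifti1Image(np.asarray(array, dtype=np.float32), affine)
    img.header.set_zooms(spacing)
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# PV tables


def read_pv_table(path: str | Path, pressure_unit: str = "cmH2O") -> list[PVDataset]:
    """Parse a PV CSV into one dataset per (compartment, condition, phase).

    Expected columns: ``pressure_cmH2O, volume, compartment, condition,
    phase``.  With ``pressure_unit="mmHg"`` the pressure column is converted
    on read.
    """
    df = pd.read_csv(path, comment="#")
    missing = [c for c in PV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"PV table {path} lacks columns {missing}")
    if pressure_unit == "mmHg":
        df["pressure_cmH2O"] = df["pressure_cmH2O"].map(mmhg_to_cmh2o)
    elif pressure_unit != "cmH2O":
        raise ValueError(f"unknown pressure unit {pressure_unit!r}")
    out = []
    for (compartment, condition, phase), grp in df.groupby(
        ["compartment", "condition", "phase"], sort=True
    ):
        out.append(
            PVDataset(
                pressures=grp["pressure_cmH2O"].to_numpy(float),
                volumes=grp["volume"].to_numpy(float),
                compartment=str(compartment),
                condition=str(condition),
                phase=str(phase),
            )
        )
    return out


def write_pv_table(path: str | Path, datasets: list[PVDataset]) -> None:
    rows = []
    for ds in datasets:
        for p, v in zip(ds.pressures, ds.volumes):
            rows.append(
                {
                    "pressure_cmH2O": p,
                    "volume": v,
                    "compartment": ds.compartment,
                    "condition": ds.condition,
                    "phase": ds.phase,
                }
            )
    pd.DataFrame(rows, columns=PV_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Titration tables


def read_titration_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    missing = [c for c in TITRATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"titration table {path} lacks columns {missing}")
    df["peep_cmH2O"] = df["peep_cmH2O"].astype(float)
    return df[TITRATION_COLUMNS]


def write_titration_table(path: str | Path, table: pd.DataFrame) -> None:
    table[TITRATION_COLUMNS].to_csv(path, index=False)


def load_reference_medians() -> pd.DataFrame:
    """Packaged descending-phase median endpoints per PEEP level.

    Transcribed from the summary tables of a published porcine
    intra-abdominal-hypertension PEEP-titration experiment (healthy and
    oleic-acid-injured conditions); serves as the offline worked-example
    input for :func:`qctpeep.mechanics.best_peep`.
    """
    with resources.files("qctpeep.data").joinpath("titration_medians.csv").open("rb") as fh:
        df = pd.read_csv(fh, comment="#")
    df["peep_cmH2O"] = df["peep_cmH2O"].astype(float)
    return df[TITRATION_COLUMNS]


def write_json(path: str | Path, payload: dict) -> None:
    """Byte-stable JSON report (sorted keys, fixed separators)."""
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
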