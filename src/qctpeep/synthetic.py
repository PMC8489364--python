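"""Synthetic fixtures: CT phantoms, sigmoid PEEP-volume data, physiology tables.

The phantom emulates a supine lung under intra-abdominal hypertension (IAH):
an ellipsoidal lung whose voxels aerate along a logistic recruitment curve.
A voxel at normalized depth ``h`` (0 = ventral, 1 = dorsal) held at airway
pressure ``P`` (cmH2O) has noiseless gas fraction

    g(h, P) = g_min + (g_max - g_min) * sigmoid((P - P_open(h)) / w)

with opening pressure

    P_open(h) = theta0 + theta1 * h + k_iap * IAP

so dependent (dorsal) tissue needs more pressure to aerate, and raised
intra-abdominal pressure shifts the whole curve rightward.  HU are the
linear mixture value ``-1000 * g`` plus optional Gaussian noise.  Oleic-acid
type injury lowers the achievable gas fraction and steepens the opening
pressure gradient in the dependent half (h > 0.5) only.

The default parameters describe a severe-IAH phantom: dependent atelectasis
shrinking monotonically as PEEP rises 5 -> 27 cmH2O while ventral
overdistension grows.  The magnitudes are not calibrated to any animal; only
the directions and the functional form matter for testing the analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .aeration import CTVolume, LungMask

__all__ = [
    "PhantomConfig",
    "SigmoidTruth",
    "generate_phantom",
    "gas_fraction",
    "venegas",
    "generate_pv_dataset",
    "generate_physiology_table",
]

#: Fraction of intra-abdominal pressure transmitted to the opening pressure.
IAP_TRANSMISSION = 0.5

#: Injury effect on the dependent half: achievable gas fraction drop and
#: extra opening-pressure slope (cmH2O per unit depth beyond h = 0.5).
INJURY_GMAX_DROP = 0.15
INJURY_THETA1_BOOST = 40.0

#: Ellipsoid semi-axes as a fraction of each half-extent of the grid.
_ELLIPSOID_FRACTION = 0.84


@dataclass(frozen=True)
class PhantomConfig:
    """Parameters of the CT phantom.

    Defaults reproduce the experimental conditions the analysis targets:
    PEEP steps 5/12/17/22/27 cmH2O under an intra-abdominal pressure of
    27 cmH2O.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size: tuple[float, float, float] = (2.5, 2.5, 2.5)  # mm
    peep_levels: tuple[float, ...] = (5.0, 12.0, 17.0, 22.0, 27.0)
    iap: float = 27.0  # cmH2O
    injury: bool = False
    gas_frac_range: tuple[float, float] = (0.02, 0.95)
    opening_intercept: float = -41.0  # theta0, cmH2O
    opening_depth_slope: float = 85.0  # theta1, cmH2O per unit depth
    sigmoid_width: float = 9.0  # w, cmH2O
    hu_noise_sd: float = 30.0  # HU
    seed: int = 0

    def __post_init__(self) -> None:
        g_min, g_max = self.gas_frac_range
        if not (0.0 <= g_min < g_max <= 1.0):
            raise ValueError(f"need 0 <= g_min < g_max <= 1, got {self.gas_frac_range}")
        if self.sigmoid_width <= 0:
            raise ValueError("sigmoid_width must be > 0")
        if self.hu_noise_sd < 0:
            raise ValueError("hu_noise_sd must be >= 0")
        peeps = np.asarray(self.peep_levels, dtype=float)
        if len(peeps) == 0 or np.any(peeps < 0) or np.any(np.diff(peeps) <= 0):
            raise ValueError("peep_levels must be strictly increasing and >= 0")
        if len(self.grid_shape) != 3 or any(int(n) != n for n in self.grid_shape):
            raise ValueError("grid_shape must be three integers")
        if any(s <= 0 for s in self.voxel_size):
            raise ValueError("voxel_size must be positive")


def _logistic(x: np.ndarray) -> np.ndarray:
    # overflow in exp saturates to the correct limit (0 or 1); keep it silent
    with np.errstate(over="ignore"):
        return 1.0 / (1.0 + np.exp(-x))


def _ellipsoid_mask(shape: tuple[int, int, int]) -> np.ndarray:
    if min(shape) < 8:
        raise ValueError(
            f"grid {shape} too small to contain the ellipsoidal lung; "
            "every axis needs at least 8 voxels"
        )
    center = [(n - 1) / 2.0 for n in shape]
    semi = [_ELLIPSOID_FRACTION * n / 2.0 for n in shape]
    grids = np.ogrid[tuple(slice(0, n) for n in shape)]
    r2 = sum(((g - c) / s) ** 2 for g, c, s in zip(grids, center, semi))
    mask = r2 <= 1.0
    if not mask.any():
        raise ValueError(f"grid {shape} too small to contain the ellipsoidal lung")
    return mask


def gas_fraction(config: PhantomConfig, depth: np.ndarray, peep: float) -> np.ndarray:
    """Noiseless gas fraction g(h, P) for normalized depth(s) ``depth``.

    This closed form is the ground truth that phantom-based oracles evaluate
    directly; :func:`generate_phantom` uses exactly this function.
    """
    h = np.asarray(depth, dtype=float)
    g_min, g_max = config.gas_frac_range
    p_open = (
        config.opening_intercept
        + config.opening_depth_slope * h
        + IAP_TRANSMISSION * config.iap
    )
    g_max_eff = np.full_like(h, g_max)
    if config.injury:
        dependent = h > 0.5
        p_open = p_open + np.where(dependent, INJURY_THETA1_BOOST * (h - 0.5), 0.0)
        g_max_eff = np.where(dependent, max(g_min + 1e-6, g_max - INJURY_GMAX_DROP), g_max_eff)
    return g_min + (g_max_eff - g_min) * _logistic((peep - p_open) / config.sigmoid_width)


def generate_phantom(
    config: PhantomConfig,
) -> list[tuple[float, CTVolume, LungMask]]:
    """Generate one (CT, mask) pair per PEEP level.

    The ellipsoidal mask geometry is identical across PEEP levels (no
    registration is needed downstream); only the HU field responds to
    pressure.  Output is bit-reproducible for a fixed config.
    """
    shape = tuple(int(n) for n in config.grid_shape)
    mask_arr = _ellipsoid_mask(shape)
    mask = LungMask(inside=mask_arr)

    dep = 2  # dependent axis: last array axis, index 0 = ventral
    idx_dep = np.nonzero(mask_arr.any(axis=(0, 1)))[0]
    lo, hi = int(idx_dep.min()), int(idx_dep.max())
    coords = np.arange(shape[dep], dtype=float)
    h_axis = np.clip((coords - lo) / max(hi - lo, 1), 0.0, 1.0)
    depth = np.broadcast_to(h_axis.reshape(1, 1, -1), shape)

    rng = np.random.default_rng(config.seed)
    out: list[tuple[float, CTVolume, LungMask]] = []
    for peep in config.peep_levels:
        g = gas_fraction(config, depth, float(peep))
        hu = -1000.0 * g
        if config.hu_noise_sd > 0:
            hu = hu + rng.normal(0.0, config.hu_noise_sd, size=shape)
        hu = np.where(mask_arr, hu, 50.0)  # soft tissue outside the lung
        ct = CTVolume(hu=hu, spacing=tuple(config.voxel_size), dependent_axis=dep)
        out.append((float(peep), ct, mask))
    return out


# ---------------------------------------------------------------------------
# Sigmoid PEEP-volume datasets


@dataclass(frozen=True)
class SigmoidTruth:
    """Ground-truth sigmoid V(P) = a + b / (1 + exp(-(P - c)/d)).

    ``a`` is the baseline volume (L), ``b`` the signed volume span (L,
    negative for de-recruiting compartments such as atelectasis), ``c`` the
    pressure of the inflection (cmH2O), ``d`` the width (cmH2O) and
    ``noise_sd`` the additive volume noise (L).
    """

    a: float
    b: float
    c: float
    d: float
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.d <= 0:
            raise ValueError("width d must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def venegas(p: np.ndarray, a: float, b: float, c: float, d: float) -> np.ndarray:
    """Four-parameter sigmoid V = a + b / (1 + e^{-(P-c)/d})."""
    return a + b * _logistic((np.asarray(p, dtype=float) - c) / d)


def generate_pv_dataset(
    truth: SigmoidTruth,
    peep_levels: Sequence[float],
    seed: int = 0,
    compartment: str = "volume",
    condition: str = "healthy",
    phase: str = "descending",
) -> "PVDataset":
    """Sample V_i = sigmoid(P_i) + Normal(0, noise_sd), seeded."""
    from .pv_model import PVDataset  # local import to avoid a cycle

    p = np.asarray(peep_levels, dtype=float)
    if len(p) < 2:
        raise ValueError("need at least 2 PEEP levels")
    v = venegas(p, truth.a, truth.b, truth.c, truth.d)
    if truth.noise_sd > 0:
        v = v + np.random.default_rng(seed).normal(0.0, truth.noise_sd, size=len(p))
    return PVDataset(
        pressures=p, volumes=v, compartment=compartment, condition=condition, phase=phase
    )


# ---------------------------------------------------------------------------
# Physiology tables

TITRATION_COLUMNS = ["subject", "condition", "phase", "peep_cmH2O", "endpoint", "value"]


def generate_physiology_table(
    medians_per_peep: Mapping[str, Mapping[float, float]] | pd.DataFrame,
    n_subjects: int = 5,
    noise_cv: float = 0.1,
    missing_spec: Iterable[tuple[str, str, float]] = (),
    seed: int = 0,
    condition: str = "healthy",
    phases: Sequence[str] = ("descending",),
    phase_offset: float = 0.0,
) -> pd.DataFrame:
    """Per-subject titration tables around endpoint x PEEP medians.

    Each subject's value is ``median * exp(Normal(0, noise_cv))``
    (multiplicative lognormal noise); cells named in ``missing_spec`` —
    tuples ``(subject, endpoint, peep)`` with subjects ``"s1".."sN"`` — are
    blanked to NaN.  When an ``"ascending"`` phase is requested its values
    are shifted so that descending minus ascending equals ``phase_offset``
    (before noise), giving a known hysteresis.

    Returns a long-format table with columns
    ``subject, condition, phase, peep_cmH2O, endpoint, value``.
    """
    if isinstance(medians_per_peep, pd.DataFrame):
        medians: dict[str, dict[float, float]] = {}
        for _, row in medians_per_peep.iterrows():
            medians.setdefault(str(row["endpoint"]), {})[float(row["peep_cmH2O"])] = float(
                row["value"]
            )
    else:
        medians = {
            e: {float(p): float(v) for p, v in per_peep.items()}
            for e, per_peep in medians_per_peep.items()
        }
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")

    subjects = [f"s{i + 1}" for i in range(n_subjects)]
    rng = np.random.default_rng(seed)
    rows = []
    for subject in subjects:
        for endpoint, per_peep in medians.items():
            for peep in sorted(per_peep):
                base = per_peep[peep]
                noise = rng.normal(0.0, noise_cv) if noise_cv > 0 else 0.0
                for phase in phases:
                    value = base - (phase_offset if phase == "ascending" else 0.0)
                    rows.append(
                        {
                            "subject": subject,
                            "condition": condition,
                            "phase": phase,
                            "peep_cmH2O": peep,
                            "endpoint": endpoint,
                            "value": value * float(np.exp(noise)),
                        }
                    )
    table = pd.DataFrame(rows, columns=TITRATION_COLUMNS)

    for subject, endpoint, peep in missing_spec:
        hit = (
            (table["subject"] == subject)
            & (table["endpoint"] == endpoint)
            & (table["peep_cmH2O"] == float(peep))
        )
        if not hit.any():
            raise ValueError(
                f"missing_spec cell ({subject!r}, {endpoint!r}, {peep}) does not exist"
            )
        table.loc[hit, "value"] = np.nan
    return table
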