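"""Pressure-volume modeling of CT compartment volumes across PEEP.

Three candidate model families describe a compartment's volume as a
function of end-expiratory pressure P:

* sigmoid (Venegas form):  V = a + b / (1 + e^{-(P-c)/d}),  d > 0
* saturating exponential:  V = a + b (1 - e^{-P/tau}),      tau > 0
* linear:                  V = a + b P

The best model is the converged fit with the smallest root-mean-square
residual.  For a sigmoid fit the lower and upper inflection (corner)
points are P = c - 2d and P = c + 2d: the pressures where the tangent at
the midpoint (c, a + b/2), whose slope is b/(4d), meets the asymptotes
V = a and V = a + b.  The *optimal CT inflation PEEP range* runs from the
lower inflection point of the atelectatic compartment (above it, little
recruitable lung remains collapsed) to the lower inflection point of the
overdistended compartment (below it, overdistension has not yet taken
off).

The four-parameter sigmoid is weakly identified on a five-point PEEP
ladder, so fitting uses a deterministic multi-start: c on a grid spanning
the observed pressures, d in {1, 3, 6} cmH2O, with a and b solved exactly
by linear least squares at each start (the model is linear in them), then
a bounded trust-region refinement.  No degrees-of-freedom penalty is
applied in model selection — raw RMS, which is biased toward the sigmoid;
ties break toward the more expressive family.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import least_squares

from .synthetic import venegas

__all__ = [
    "PVDataset",
    "ModelFitResult",
    "InflectionPoints",
    "OptimalPEEPRange",
    "fit_venegas",
    "fit_exponential",
    "fit_linear",
    "select_best_model",
    "inflection_points",
    "optimal_peep_range",
    "to_fractional",
    "bootstrap_lower_inflection",
]

#: Bounds on the sigmoid width (cmH2O): excludes step-function degeneracies.
D_BOUNDS = (0.1, 50.0)

#: Deterministic multi-start grids.
N_C_STARTS = 5
D_STARTS = (1.0, 3.0, 6.0)
TAU_STARTS = (2.0, 5.0, 10.0, 20.0, 40.0)

_FAMILY_RANK = {"venegas": 0, "exponential": 1, "linear": 2}


@dataclass(frozen=True)
class PVDataset:
    """Volumes of one compartment observed across PEEP levels."""

    pressures: np.ndarray
    volumes: np.ndarray
    compartment: str = "volume"
    condition: str = "healthy"
    phase: str = "descending"

    def __post_init__(self) -> None:
        p = np.asarray(self.pressures, dtype=float)
        v = np.asarray(self.volumes, dtype=float)
        if p.ndim != 1 or v.shape != p.shape:
            raise ValueError("pressures and volumes must be 1-D arrays of equal length")
        if not (np.all(np.isfinite(p)) and np.all(np.isfinite(v))):
            raise ValueError("pressures and volumes must be finite")
        if len(np.unique(p)) < 2:
            raise ValueError("need at least 2 distinct pressures")
        object.__setattr__(self, "pressures", p)
        object.__setattr__(self, "volumes", v)

    @property
    def n_distinct_pressures(self) -> int:
        return len(np.unique(self.pressures))


@dataclass(frozen=True)
class ModelFitResult:
    """One fitted PV model: parameters, fit quality and diagnostics."""

    family: str
    params: dict[str, float]
    rms: float
    fitted: np.ndarray
    converged: bool
    degenerate: bool = False
    message: str = ""
    dataset: PVDataset | None = field(default=None, repr=False, compare=False)

    def predict(self, pressures: np.ndarray) -> np.ndarray:
        p = np.asarray(pressures, dtype=float)
        q = self.params
        if self.family == "venegas":
            return venegas(p, q["a"], q["b"], q["c"], q["d"])
        if self.family == "exponential":
            return q["a"] + q["b"] * (1.0 - np.exp(-p / q["tau"]))
        if self.family == "linear":
            return q["a"] + q["b"] * p
        raise ValueError(f"unknown family {self.family!r}")


@dataclass(frozen=True)
class InflectionPoints:
    """Corner pressures of a sigmoid fit: c - 2d, c, c + 2d (cmH2O)."""

    lower: float
    true_inflection: float
    upper: float


@dataclass(frozen=True)
class OptimalPEEPRange:
    """PEEP window between recruitment and overdistension corner pressures."""

    low: float
    high: float

    @property
    def well_formed(self) -> bool:
        return self.low <= self.high


def _rms(residuals: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.square(residuals))))


def _linear_ab(basis: np.ndarray, v: np.ndarray) -> tuple[float, float]:
    """Exact least squares for V ~ a + b * basis."""
    design = np.column_stack([np.ones_like(basis), basis])
    coef, *_ = np.linalg.lstsq(design, v, rcond=None)
    return float(coef[0]), float(coef[1])


def fit_venegas(
    data: PVDataset,
    init: Sequence[float] | None = None,
    bounds: tuple[float, float] = D_BOUNDS,
) -> ModelFitResult:
    """Fit the four-parameter sigmoid by bounded multi-start least squares.

    ``init`` optionally supplies a single (a, b, c, d) start replacing the
    deterministic grid.  ``bounds`` constrain d.  b is free-signed so
    decreasing compartments (atelectasis) fit with b < 0.  The result is
    deterministic for fixed inputs; non-convergence and degenerate fits
    (vanishing span or width pinned at a bound) are flagged, never silent.
    """
    p, v = data.pressures, data.volumes
    if data.n_distinct_pressures < 4:
        return ModelFitResult(
            family="venegas",
            params={},
            rms=float("inf"),
            fitted=np.full_like(v, np.nan),
            converged=False,
            message=f"under-determined: {data.n_distinct_pressures} distinct pressures < 4",
            dataset=data,
        )
    d_lo, d_hi = bounds

    def residuals(theta: np.ndarray) -> np.ndarray:
        return venegas(p, *theta) - v

    def jacobian(theta: np.ndarray) -> np.ndarray:
        _, b, c, d = theta
        with np.errstate(over="ignore"):
            s = 1.0 / (1.0 + np.exp(-(p - c) / d))
        ds = s * (1.0 - s)
        return np.column_stack([np.ones_like(p), s, -b * ds / d, -b * ds * (p - c) / d**2])

    if init is not None:
        starts = [np.asarray(init, dtype=float)]
    else:
        starts = []
        for c0 in np.linspace(p.min(), p.max(), N_C_STARTS):
            for d0 in D_STARTS:
                d0 = float(np.clip(d0, d_lo, d_hi))
                s = 1.0 / (1.0 + np.exp(-(p - c0) / d0))
                a0, b0 = _linear_ab(s, v)
                starts.append(np.array([a0, b0, c0, d0]))

    span = p.max() - p.min()
    lo = np.array([-np.inf, -np.inf, p.min() - 2 * span, d_lo])
    hi = np.array([np.inf, np.inf, p.max() + 2 * span, d_hi])
    best = None
    for x0 in starts:
        x0 = np.clip(x0, lo, hi)
        try:
            sol = least_squares(
                residuals, x0, jac=jacobian, bounds=(lo, hi), xtol=1e-14, ftol=1e-14, gtol=1e-14
            )
        except Exception as exc:  # pragma: no cover - scipy raises rarely here
            sol = None
            err = str(exc)
        if sol is not None and sol.success and (best is None or sol.cost < best.cost):
            best = sol
    if best is None:
        return ModelFitResult(
            family="venegas",
            params={},
            rms=float("inf"),
            fitted=np.full_like(v, np.nan),
            converged=False,
            message="no start converged",
            dataset=data,
        )
    a, b, c, d = (float(x) for x in best.x)
    v_scale = max(float(np.max(np.abs(v))), 1e-12)
    degenerate = abs(b) < 1e-6 * v_scale or d <= d_lo * (1 + 1e-9) or d >= d_hi * (1 - 1e-9)
    return ModelFitResult(
        family="venegas",
        params={"a": a, "b": b, "c": c, "d": d},
        rms=_rms(best.fun),
        fitted=venegas(p, a, b, c, d),
        converged=True,
        degenerate=degenerate,
        message="degenerate sigmoid (span ~ 0 or width at bound)" if degenerate else "",
        dataset=data,
    )


def fit_exponential(data: PVDataset) -> ModelFitResult:
    """Fit the saturating exponential V = a + b (1 - e^{-P/tau}), tau > 0."""
    p, v = data.pressures, data.volumes
    if data.n_distinct_pressures < 3:
        return ModelFitResult(
            family="exponential",
            params={},
            rms=float("inf"),
            fitted=np.full_like(v, np.nan),
            converged=False,
            message=f"under-determined: {data.n_distinct_pressures} distinct pressures < 3",
            dataset=data,
        )

    def residuals(theta: np.ndarray) -> np.ndarray:
        a, b, tau = theta
        return a + b * (1.0 - np.exp(-p / tau)) - v

    tau_lo, tau_hi = 1e-3, 1e3
    lo = np.array([-np.inf, -np.inf, tau_lo])
    hi = np.array([np.inf, np.inf, tau_hi])
    best = None
    for tau0 in TAU_STARTS:
        s = 1.0 - np.exp(-p / tau0)
        a0, b0 = _linear_ab(s, v)
        sol = least_squares(
            residuals,
            np.array([a0, b0, tau0]),
            bounds=(lo, hi),
            xtol=1e-14,
            ftol=1e-14,
            gtol=1e-14,
        )
        if sol.success and (best is None or sol.cost < best.cost):
            best = sol
    if best is None:
        return ModelFitResult(
            family="exponential",
            params={},
            rms=float("inf"),
            fitted=np.full_like(v, np.nan),
            converged=False,
            message="no start converged",
            dataset=data,
        )
    a, b, tau = (float(x) for x in best.x)
    v_scale = max(float(np.max(np.abs(v))), 1e-12)
    degenerate = abs(b) < 1e-6 * v_scale or tau <= tau_lo * (1 + 1e-6) or tau >= tau_hi * (1 - 1e-6)
    return ModelFitResult(
        family="exponential",
        params={"a": a, "b": b, "tau": tau},
        rms=_rms(best.fun),
        fitted=a + b * (1.0 - np.exp(-p / tau)),
        converged=True,
        degenerate=degenerate,
        message="degenerate exponential (span ~ 0 or tau at bound)" if degenerate else "",
        dataset=data,
    )


def fit_linear(data: PVDataset) -> ModelFitResult:
    """Fit V = a + b P by ordinary least squares (closed form)."""
    p, v = data.pressures, data.volumes
    a, b = _linear_ab(p, v)
    fitted = a + b * p
    return ModelFitResult(
        family="linear",
        params={"a": a, "b": b},
        rms=_rms(fitted - v),
        fitted=fitted,
        converged=True,
        dataset=data,
    )


def select_best_model(data: PVDataset) -> ModelFitResult:
    """Fit all three families; return the smallest-RMS converged fit.

    Non-converged and degenerate fits are excluded.  Exact RMS ties break
    toward the more expressive family (sigmoid > exponential > linear).
    """
    fits = [fit_venegas(data), fit_exponential(data), fit_linear(data)]
    candidates = [f for f in fits if f.converged and not f.degenerate]
    if not candidates:
        detail = "; ".join(f"{f.family}: {f.message or 'failed'}" for f in fits)
        raise RuntimeError(f"no PV model could be fitted ({detail})")
    best = candidates[0]
    for f in candidates[1:]:
        if f.rms < best.rms - 1e-12 * (1.0 + best.rms):
            best = f
    return best


def inflection_points(fit: ModelFitResult) -> InflectionPoints:
    """Corner pressures c - 2d and c + 2d of a converged sigmoid fit."""
    if fit.family != "venegas":
        raise ValueError(
            f"inflection points are defined for the sigmoid family only, got {fit.family!r}"
        )
    if not fit.converged:
        raise ValueError("cannot derive inflection points from a non-converged fit")
    c, d = fit.params["c"], fit.params["d"]
    return InflectionPoints(lower=c - 2.0 * d, true_inflection=c, upper=c + 2.0 * d)


def optimal_peep_range(
    atelectatic_fit: ModelFitResult, overdistended_fit: ModelFitResult
) -> OptimalPEEPRange:
    """PEEP window between the two compartments' lower inflection points.

    The low end comes from the atelectatic fit, the high end from the
    overdistended fit; endpoints are never reordered, so an inverted
    (ill-formed) window is visible via ``well_formed``.
    """
    low = inflection_points(atelectatic_fit).lower
    high = inflection_points(overdistended_fit).lower
    return OptimalPEEPRange(low=low, high=high)


def to_fractional(data: PVDataset) -> PVDataset:
    """Rescale volumes to fractions of the change across the pressure range.

    V -> (V - V(P_min)) / (V(P_max) - V(P_min)), so the observed trajectory
    runs from 0 at the lowest to 1 at the highest PEEP.  Affine rescaling
    leaves c and d (hence the inflection points) of a sigmoid fit unchanged.
    """
    p, v = data.pressures, data.volumes
    v0 = float(v[np.argmin(p)])
    v1 = float(v[np.argmax(p)])
    if v1 == v0:
        raise ValueError("volume change across the pressure range is zero")
    return replace(data, volumes=(v - v0) / (v1 - v0))


def bootstrap_lower_inflection(
    data: PVDataset,
    n_boot: int = 200,
    seed: int = 0,
    fitter: Callable[[PVDataset], ModelFitResult] = fit_venegas,
) -> np.ndarray:
    """Residual-bootstrap sample of the lower inflection point (optional CI).

    Refits on data with resampled residuals added to the fitted curve;
    returns the array of bootstrap ``c - 2d`` values (non-converged
    replicates dropped).
    """
    base = fitter(data)
    if not base.converged:
        raise RuntimeError("base fit did not converge")
    res = data.volumes - base.fitted
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_boot):
        v_star = base.fitted + rng.choice(res, size=len(res), replace=True)
        fit = fitter(replace(data, volumes=v_star))
        if fit.converged and not fit.degenerate:
            out.append(fit.params["c"] - 2.0 * fit.params["d"])
    return np.asarray(out)
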