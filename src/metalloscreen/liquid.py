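"""Liquid CAS assay quantification.

Chelators strip Fe(III) from the blue Fe-CAS dye; the loss of absorbance at
630 nm relative to an untreated Fe-CAS blank is the percentage CAS response.
A dilution series of the reference siderophore desferrioxamine B (DFOB)
calibrates that response through a saturating exponential decolourisation
model,

    response(c) = ceiling * (1 - exp(-k * c)),    ceiling = 100 % by default,

whose inverse converts sample responses into uM DFOB equivalents.  Kinetic
traces (absorbance vs time) yield an initial decolourisation velocity, and a
unit-conversion helper turns extract concentrations into practical yields in
mg per liter of culture.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "ExtrapolationWarning",
    "CalibrationModel",
    "VelocityResult",
    "CASResult",
    "cas_response",
    "transmission_to_absorbance",
    "decolourisation_velocity",
    "fit_calibration",
    "to_dfob_equivalents",
    "yield_mg_per_l",
    "DFOB_MOLAR_MASS",
]

#: molar mass of desferrioxamine B free base, g/mol
DFOB_MOLAR_MASS = 560.68


class ExtrapolationWarning(UserWarning):
    """Inverse prediction outside the calibrated concentration range."""


class VelocityResult(NamedTuple):
    rate_per_h: float  # decolourisation velocity, absorbance units per hour
    stderr_per_h: float
    n_points: int


@dataclass(frozen=True)
class CASResult:
    response_pct: float
    dilution: float
    dfob_equivalents_uM: float
    extrapolated: bool
    yield_mg_per_l: float | None = None


@dataclass(frozen=True)
class CalibrationModel:
    """Fitted exponential decolourisation calibration."""

    k: float  # decolourisation rate per uM DFOB
    ceiling: float = 100.0  # % response at saturation
    residual_sd: float = float("nan")
    conc_range: tuple[float, float] = (0.0, float("inf"))
    n_points: int = 0

    def predict(self, conc_uM: float | np.ndarray) -> float | np.ndarray:
        """Forward model: % CAS response at a DFOB concentration (uM)."""
        return self.ceiling * (1.0 - np.exp(-self.k * np.asarray(conc_uM, dtype=float)))

    def to_dict(self) -> dict:
        return {
            "k_per_uM": self.k,
            "ceiling_pct": self.ceiling,
            "residual_sd_pct": self.residual_sd,
            "conc_range_uM": list(self.conc_range),
            "n_points": self.n_points,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationModel":
        return cls(
            k=float(d["k_per_uM"]),
            ceiling=float(d.get("ceiling_pct", 100.0)),
            residual_sd=float(d.get("residual_sd_pct", float("nan"))),
            conc_range=tuple(d.get("conc_range_uM", (0.0, float("inf")))),
            n_points=int(d.get("n_points", 0)),
        )


def cas_response(a_sample: float, a_reference: float) -> float:
    """Percentage CAS response from sample and Fe-CAS blank absorbances.

    100 * (A_ref - A_sample) / A_ref, clipped to [0, 100]; small negative
    differences from read noise clip to 0 rather than erroring.
    """
    if a_reference <= 0:
        raise ValueError("reference absorbance must be positive")
    if a_sample < 0:
        raise ValueError("sample absorbance must be nonnegative")
    response = 100.0 * (a_reference - a_sample) / a_reference
    return float(np.clip(response, 0.0, 100.0))


def transmission_to_absorbance(t_pct: float | np.ndarray) -> float | np.ndarray:
    """A = -log10(T/100) for plate readers that export percent transmission."""
    t = np.asarray(t_pct, dtype=float)
    if np.any(t <= 0):
        raise ValueError("transmission must be positive")
    out = -np.log10(t / 100.0)
    return float(out) if out.ndim == 0 else out


def decolourisation_velocity(
    times_s: Sequence[float],
    readings: Sequence[float],
    window_s: float = 3600.0,
) -> VelocityResult:
    """Initial decolourisation velocity from a kinetic 630 nm trace.

    Least-squares slope of reading vs time over the first ``window_s``
    seconds from the trace start, sign-flipped so that decolourisation
    (falling absorbance) is positive, in reading units per hour.
    """
    t = np.asarray(times_s, dtype=float)
    y = np.asarray(readings, dtype=float)
    if t.shape != y.shape or t.ndim != 1 or t.size < 2:
        raise ValueError("need matched 1-D time/reading vectors with >= 2 points")
    if np.any(np.diff(t) <= 0):
        raise ValueError("time points must be strictly increasing")
    if np.any(y < 0):
        raise ValueError("readings must be nonnegative")
    mask = t <= t[0] + window_s
    if mask.sum() < 2:
        raise ValueError("fewer than 2 points inside the window")
    fit = stats.linregress(t[mask], y[mask])
    stderr = fit.stderr if np.isfinite(fit.stderr) else 0.0
    return VelocityResult(
        rate_per_h=-fit.slope * 3600.0,
        stderr_per_h=stderr * 3600.0,
        n_points=int(mask.sum()),
    )


def fit_calibration(
    conc_uM: Sequence[float],
    response_pct: Sequence[float],
    free_ceiling: bool = False,
) -> CalibrationModel:
    """Fit the exponential decolourisation model to DFOB standards.

    Nonlinear least squares of ``ceiling * (1 - exp(-k c))`` with the ceiling
    fixed at 100 % (optionally estimated with ``free_ceiling=True``).  The
    starting value for k comes from the through-origin regression of
    ``-ln(1 - response/100)`` on concentration.  Points at or above the
    ceiling are excluded with a warning (the log transform is undefined
    there); at least 3 usable points at distinct concentrations are
    required.
    """
    c = np.asarray(conc_uM, dtype=float)
    r = np.asarray(response_pct, dtype=float)
    if c.shape != r.shape or c.ndim != 1:
        raise ValueError("conc and response must be matched 1-D vectors")
    if np.any(c < 0):
        raise ValueError("concentrations must be nonnegative")
    usable = r < 100.0
    if not np.all(usable):
        warnings.warn(
            f"excluding {int((~usable).sum())} point(s) with response >= 100 %",
            UserWarning,
            stacklevel=2,
        )
    c, r = c[usable], r[usable]
    if np.unique(c).size < 3:
        raise ValueError("need >= 3 usable points at distinct concentrations")

    y = -np.log1p(-r / 100.0)
    denom = float(np.sum(c * c))
    k0 = float(np.sum(c * y)) / denom if denom > 0 else 0.01
    k0 = max(k0, 1e-9)

    if free_ceiling:
        def model(x, k, ceiling):
            return ceiling * (1.0 - np.exp(-k * x))

        popt, _ = optimize.curve_fit(
            model, c, r, p0=(k0, 100.0), bounds=([1e-12, 1.0], [np.inf, np.inf]), maxfev=10000
        )
        k_hat, ceiling = float(popt[0]), float(popt[1])
        n_param = 2
    else:
        def model(x, k):
            return 100.0 * (1.0 - np.exp(-k * x))

        popt, _ = optimize.curve_fit(
            model, c, r, p0=(k0,), bounds=(1e-12, np.inf), maxfev=10000
        )
        k_hat, ceiling = float(popt[0]), 100.0
        n_param = 1

    resid = r - ceiling * (1.0 - np.exp(-k_hat * c))
    dof = max(c.size - n_param, 1)
    return CalibrationModel(
        k=k_hat,
        ceiling=ceiling,
        residual_sd=float(np.sqrt(np.sum(resid**2) / dof)),
        conc_range=(float(c.min()), float(c.max())),
        n_points=int(c.size),
    )


def to_dfob_equivalents(
    response_pct: float,
    model: CalibrationModel,
    dilution: float = 1.0,
) -> float:
    """Invert the calibration: % CAS response -> uM DFOB equivalents.

    c = -ln(1 - response/ceiling) / k, multiplied by the dilution factor.
    Emits an :class:`ExtrapolationWarning` when the inverse-predicted
    concentration falls outside the model's calibrated range.
    """
    if dilution < 1:
        raise ValueError("dilution factor must be >= 1")
    if not 0 <= response_pct < model.ceiling:
        raise ValueError(
            f"response must be in [0, {model.ceiling}) to be invertible"
        )
    conc = -math.log1p(-response_pct / model.ceiling) / model.k
    lo, hi = model.conc_range
    tol = 1e-9 * max(abs(lo), abs(hi), 1.0)  # ignore round-off at the boundary
    if not lo - tol <= conc <= hi + tol:
        warnings.warn(
            f"inverse prediction {conc:.4g} uM lies outside the calibrated "
            f"range [{lo:.4g}, {hi:.4g}] uM",
            ExtrapolationWarning,
            stacklevel=2,
        )
    return conc * dilution


def yield_mg_per_l(
    conc_uM: float,
    extract_volume_l: float,
    culture_volume_l: float,
    molar_mass: float = DFOB_MOLAR_MASS,
) -> float:
    """Practical yield (mg per liter of culture) from an extract concentration.

    conc [uM] * 1e-6 [mol/L/uM] * extract volume [L] * molar mass [g/mol]
    * 1e3 [mg/g] / culture volume [L].
    """
    if conc_uM < 0:
        raise ValueError("concentration must be nonnegative")
    if extract_volume_l <= 0 or culture_volume_l <= 0 or molar_mass <= 0:
        raise ValueError("volumes and molar mass must be positive")
    return conc_uM * 1e-6 * extract_volume_l * molar_mass * 1e3 / culture_volume_l
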