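"""Insulin-sensitivity (KITT) estimation and caloric-intake accounting.

KITT is the constant rate of blood glucose disappearance during an
insulin tolerance test, in %/min.  Under first-order kinetics
G(t) = G0*exp(-k*t); the glucose half-life is t1/2 = ln(2)/k and
KITT = 100*k = 0.693/t1/2 * 100.  k is estimated from the slope of a
least-squares fit to the glucose decline over the linear phase
(default window 4-16 min after the insulin bolus, excluding the
pre-action baseline).

Caloric intake combines chow (2.89 kcal/g) with fructose dissolved in
the drinking fluid (4.0 kcal/g).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "KCAL_PER_G_CHOW",
    "KCAL_PER_G_FRUCTOSE",
    "ITTCurve",
    "ITTResult",
    "IntakeRecord",
    "IntakeResult",
    "compute_kitt",
    "caloric_intake",
]

KCAL_PER_G_CHOW = 2.89
KCAL_PER_G_FRUCTOSE = 4.0


@dataclass(frozen=True)
class ITTCurve:
    """Glucose (mg/dL) at minute marks after the insulin bolus."""

    times: np.ndarray
    glucose: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "glucose", np.asarray(self.glucose, dtype=float))
        if len(self.times) != len(self.glucose):
            raise ValueError("times and glucose must have equal length")
        if self.times[0] != 0 or np.any(np.diff(self.times) <= 0):
            raise ValueError("times must start at 0 and be strictly increasing")
        if np.any(self.glucose <= 0):
            raise ValueError("glucose values must be positive")


@dataclass(frozen=True)
class ITTResult:
    """KITT (%/min) with the half-life and the underlying fit.

    ``declining`` is False when the fitted slope is non-negative; KITT
    is then reported as 0 and ``t_half`` is NaN.  ``log_fit`` records
    whether the regression was on ln(glucose) (first-order kinetics,
    the default) or on raw glucose.
    """

    kitt: float
    t_half: float
    slope: float
    intercept: float
    window: tuple[float, float]
    declining: bool
    log_fit: bool = True


@dataclass(frozen=True)
class IntakeRecord:
    """Daily consumption: chow (g/day), fluid (mL/day) and the fructose
    concentration of the fluid (g/L; 0 for plain water)."""

    chow: float
    fluid: float
    fructose_conc: float = 0.0

    def __post_init__(self) -> None:
        if self.chow < 0 or self.fluid < 0 or self.fructose_conc < 0:
            raise ValueError("intake quantities must be non-negative")


@dataclass(frozen=True)
class IntakeResult:
    chow_kcal: float
    fructose_kcal: float
    total_kcal: float


def compute_kitt(
    curve: ITTCurve,
    window: tuple[float, float] = (4.0, 16.0),
    log_fit: bool = True,
) -> ITTResult:
    """Estimate KITT from the glucose decline inside ``window`` minutes.

    Default: least-squares fit of ln(glucose) vs time; the decay
    constant is k = -slope, t1/2 = ln(2)/k and KITT = 100*k %/min.
    With ``log_fit=False`` the fit is on raw glucose and k is the
    fitted fractional decline -slope / fitted-glucose-at-window-start.
    Exact on noiseless exponentials (log fit) for any k > 0.
    """
    lo, hi = window
    mask = (curve.times >= lo) & (curve.times <= hi)
    if mask.sum() < 3:
        raise ValueError(f"need >= 3 samples inside window {window}")
    t = curve.times[mask]
    g = curve.glucose[mask]
    if log_fit:
        intercept, slope = np.polynomial.polynomial.polyfit(t, np.log(g), 1)
        k = -slope
    else:
        intercept, slope = np.polynomial.polynomial.polyfit(t, g, 1)
        g_start = intercept + slope * lo
        k = -slope / g_start if g_start > 0 else -np.inf
    declining = k > 1e-12  # numerically flat fits count as non-declining
    return ITTResult(
        kitt=100.0 * k if declining else 0.0,
        t_half=float(np.log(2) / k) if declining else float("nan"),
        slope=float(slope),
        intercept=float(intercept),
        window=(lo, hi),
        declining=bool(declining),
        log_fit=log_fit,
    )


def caloric_intake(rec: IntakeRecord) -> IntakeResult:
    """Total daily energy intake from chow and fructose-sweetened fluid.

    chow_kcal = chow * 2.89; fructose grams = fluid(mL) * conc(g/L) / 1000,
    at 4.0 kcal/g.
    """
    chow_kcal = rec.chow * KCAL_PER_G_CHOW
    fructose_g = rec.fluid * rec.fructose_conc / 1000.0
    fructose_kcal = fructose_g * KCAL_PER_G_FRUCTOSE
    return IntakeResult(
        chow_kcal=chow_kcal,
        fructose_kcal=fructose_kcal,
        total_kcal=chow_kcal + fructose_kcal,
    )
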