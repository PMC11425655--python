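"""Batch adsorption modelling: adsorbed quantity, kinetic and isotherm fits.

The adsorbed quantity per gram of adsorbent is the mass-balance

    Q_t = (C0 - C_t) * V / M        [mg/g]

with C0 the initial solute concentration (mg/L), C_t the solution
concentration at time t (mg/L), V the solution volume (L) and M the
adsorbent mass (g).  Three kinetic laws and two isotherms are fitted by
ordinary least squares on their standard linearised forms:

* pseudo-second-order (PKE):   t/Qt = 1/(k*Qe^2) + t/Qe
* Elovich:                     Qt   = a + b*ln(t)
* intra-particle diffusion:    Qt   = kp*sqrt(t) + c
* Langmuir:                    Ce/Qe = Ce/Qmax + 1/(Qmax*KL)
* Freundlich:                  ln(Qe) = ln(KF) + (1/n)*ln(Ce)

R-squared is reported on the linearised regression's own scale (the scale
on which the parameters are estimated) together with a native-scale
R-squared of the back-transformed curve; an optional nonlinear
least-squares refinement is available but off by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

KINETIC_MODELS = ("pke", "elovich", "idm")
ISOTHERM_MODELS = ("langmuir", "freundlich")


class AdsorptionValidationError(ValueError):
    """Raised when an adsorption series violates its physical constraints."""


@dataclass
class AdsorptionSeries:
    """Timed (kinetic) or equilibrium (isotherm) concentration measurements.

    Parameters
    ----------
    mode:
        ``"kinetic"`` (a single batch sampled over time) or ``"isotherm"``
        (one equilibrium point per initial concentration).
    t:
        Sampling times in minutes (kinetic mode only).
    c0:
        Initial concentration(s), mg/L — a scalar in kinetic mode, one value
        per point in isotherm mode.
    conc:
        Measured solution concentration, mg/L: C_t in kinetic mode, C_e in
        isotherm mode.
    volume_l, mass_g:
        Batch geometry: solution volume (L) and adsorbent mass (g).
    q_measured:
        Optional directly measured adsorbed quantity (mg/g); when present it
        takes precedence over the mass-balance value in model fits.
    """

    mode: str
    c0: np.ndarray | float
    conc: np.ndarray
    volume_l: float
    mass_g: float
    t: np.ndarray | None = None
    q_measured: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("kinetic", "isotherm"):
            raise AdsorptionValidationError(
                f"mode must be 'kinetic' or 'isotherm', got {self.mode!r}"
            )
        self.conc = np.asarray(self.conc, dtype=float)
        if self.volume_l <= 0 or self.mass_g <= 0:
            raise AdsorptionValidationError("V and M must be positive")
        if self.mode == "kinetic":
            if self.t is None:
                raise AdsorptionValidationError("kinetic series requires times t")
            self.t = np.asarray(self.t, dtype=float)
            if self.t.shape != self.conc.shape:
                raise AdsorptionValidationError("t and concentrations differ in length")
            if np.any(np.diff(self.t) <= 0):
                raise AdsorptionValidationError("times must be strictly increasing")
        else:
            self.c0 = np.asarray(self.c0, dtype=float)
            if self.c0.shape != self.conc.shape:
                raise AdsorptionValidationError("c0 and Ce differ in length")

    @property
    def q(self) -> np.ndarray:
        """Adsorbed quantity per point (Qt or Qe), mg/g."""
        if self.q_measured is not None:
            return np.asarray(self.q_measured, dtype=float)
        return compute_qt(self)


def compute_qt(series: AdsorptionSeries) -> np.ndarray:
    """Adsorbed quantity Q = (C0 - C) * V / M for each point, mg/g.

    Raises :class:`AdsorptionValidationError` if any measured concentration
    exceeds its initial concentration (negative adsorption).
    """
    c0 = np.asarray(series.c0, dtype=float)
    if np.any(series.conc > c0 + 1e-12):
        raise AdsorptionValidationError(
            "measured concentration exceeds C0 (negative adsorption)"
        )
    return (c0 - series.conc) * series.volume_l / series.mass_g


# ---------------------------------------------------------------------------
# model curves (native forms)

def pke_curve(t, qe, k):
    return k * qe**2 * t / (1.0 + k * qe * t)


def elovich_curve(t, a, b):
    return a + b * np.log(t)


def idm_curve(t, kp, c):
    return kp * np.sqrt(t) + c


def langmuir_curve(ce, qmax, kl):
    return qmax * kl * ce / (1.0 + kl * ce)


def freundlich_curve(ce, kf, n):
    return kf * ce ** (1.0 / n)


_CURVES = {
    "pke": pke_curve,
    "elovich": elovich_curve,
    "idm": idm_curve,
    "langmuir": langmuir_curve,
    "freundlich": freundlich_curve,
}


@dataclass
class FitResult:
    model: str
    mode: str
    params: dict[str, float]
    r_squared: float
    r_squared_native: float
    fitted: np.ndarray
    valid: bool = True
    message: str = ""
    x: np.ndarray = field(default_factory=lambda: np.array([]))


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Slope, intercept and R^2 of a simple linear regression."""
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def _native_r2(observed: np.ndarray, fitted: np.ndarray) -> float:
    ss_res = float(np.sum((observed - fitted) ** 2))
    ss_tot = float(np.sum((observed - observed.mean()) ** 2))
    if ss_tot == 0:
        return 1.0 if ss_res == 0 else 0.0
    return 1.0 - ss_res / ss_tot


def fit_kinetics(
    series: AdsorptionSeries, model: str, nonlinear_refine: bool = False
) -> FitResult:
    """Fit one kinetic model to a timed series by linearised OLS.

    Points with t <= 0 or Qt <= 0 are excluded (the PKE and Elovich
    linearisations are undefined there).  A non-positive PKE slope is flagged
    as an invalid fit rather than raised.
    """
    model = model.lower()
    if model not in KINETIC_MODELS:
        raise ValueError(f"unknown kinetic model {model!r}; choose from {KINETIC_MODELS}")
    if series.mode != "kinetic":
        raise AdsorptionValidationError("kinetic fit requires a kinetic-mode series")
    qt = series.q
    keep = (series.t > 0) & (qt > 0)
    t, qt = series.t[keep], qt[keep]
    if t.size < 3:
        raise AdsorptionValidationError("need at least 3 usable (t>0, Qt>0) points")

    if model == "pke":
        slope, intercept, r2 = _ols(t, t / qt)
        if slope <= 0 or intercept <= 0:
            return FitResult(
                model, "kinetic", {"Qe": np.nan, "k": np.nan}, r2, np.nan,
                np.full_like(t, np.nan), valid=False,
                message="non-positive PKE linearisation slope/intercept", x=t,
            )
        qe = 1.0 / slope
        k = slope**2 / intercept
        params = {"Qe": qe, "k": k}
    elif model == "elovich":
        slope, intercept, r2 = _ols(np.log(t), qt)
        params = {"a": intercept, "b": slope}
    else:  # idm
        slope, intercept, r2 = _ols(np.sqrt(t), qt)
        params = {"kp": slope, "c": intercept}

    curve = _CURVES[model]
    if nonlinear_refine:
        p0 = list(params.values())
        try:
            popt, _ = optimize.curve_fit(curve, t, qt, p0=p0, maxfev=10000)
            params = dict(zip(params.keys(), map(float, popt)))
        except RuntimeError:
            pass
    fitted = curve(t, *params.values())
    return FitResult(model, "kinetic", params, r2, _native_r2(qt, fitted), fitted, x=t)


def fit_isotherm(
    series: AdsorptionSeries, model: str, nonlinear_refine: bool = False
) -> FitResult:
    """Fit Langmuir or Freundlich isotherms by linearised OLS."""
    model = model.lower()
    if model not in ISOTHERM_MODELS:
        raise ValueError(
            f"unknown isotherm model {model!r}; choose from {ISOTHERM_MODELS}"
        )
    if series.mode != "isotherm":
        raise AdsorptionValidationError("isotherm fit requires an isotherm-mode series")
    qe = series.q
    ce = series.conc
    if np.any(ce <= 0) or np.any(qe <= 0):
        raise AdsorptionValidationError("isotherm fit requires positive Ce and Qe")
    if ce.size < 3:
        raise AdsorptionValidationError("need at least 3 (Ce, Qe) pairs")

    if model == "langmuir":
        slope, intercept, r2 = _ols(ce, ce / qe)
        if slope <= 0 or intercept <= 0:
            return FitResult(
                model, "isotherm", {"Qmax": np.nan, "KL": np.nan}, r2, np.nan,
                np.full_like(ce, np.nan), valid=False,
                message="non-positive Langmuir linearisation slope/intercept", x=ce,
            )
        qmax = 1.0 / slope
        kl = slope / intercept
        params = {"Qmax": qmax, "KL": kl}
    else:
        slope, intercept, r2 = _ols(np.log(ce), np.log(qe))
        params = {"KF": float(np.exp(intercept)), "n": 1.0 / slope}

    curve = _CURVES[model]
    if nonlinear_refine:
        try:
            popt, _ = optimize.curve_fit(
                curve, ce, qe, p0=list(params.values()), maxfev=10000
            )
            params = dict(zip(params.keys(), map(float, popt)))
        except RuntimeError:
            pass
    fitted = curve(ce, *params.values())
    return FitResult(model, "isotherm", params, r2, _native_r2(qe, fitted), fitted, x=ce)


def model_compare(results: list[FitResult]) -> tuple[list[FitResult], bool]:
    """Rank fit results by descending R-squared.

    Ties are broken alphabetically by model name and flagged.  Mixing kinetic
    and isotherm results is an error.  Returns ``(ranked, tie_flag)``.
    """
    if not results:
        raise ValueError("no fit results to compare")
    modes = {r.mode for r in results}
    if len(modes) > 1:
        raise ValueError("cannot rank kinetic and isotherm fits together")
    ranked = sorted(results, key=lambda r: (-r.r_squared, r.model))
    tie = len({round(r.r_squared, 12) for r in ranked}) < len(ranked)
    return ranked, tie
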