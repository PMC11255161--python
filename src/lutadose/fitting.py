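"""Time-activity curve (TAC) fitting and time-integrated activity (TIA).

The reference dosimetry method fits each measured TAC with a
mono-exponential ``A0 * exp(-lam*t)`` or an uptake bi-exponential
``A0 * (exp(-lam_eff*t) - exp(-lam_up*t))`` and integrates the fitted
curve analytically to infinity.  Where no exponential describes the data
(long uptake phases, non-monotone washout) the TIA falls back to
trapezoidal integration of the samples with a mono-exponential tail
fitted to the last 2 or 3 points.

Fits are least squares on untransformed activities; a log-linear fit is
used for initialisation and for the exact 2-point case.  The clearance
rate is bounded to effective half-lives between 0.5 h and 1000 h; a fit
pinned at a bound is flagged rather than rejected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import curve_fit

from .errors import DomainError, FitError
from .physics import sorted_unique

LAMBDA_MIN = math.log(2.0) / 1000.0  # h^-1, T_eff = 1000 h
LAMBDA_MAX = math.log(2.0) / 0.5  # h^-1, T_eff = 0.5 h
#: residual RMS above this fraction of the peak activity triggers the
#: trapezoid-with-tail fallback in :func:`select_fit`
RESIDUAL_FRACTION_LIMIT = 0.20
#: minimum ratio lam_up / lam_eff for an accepted uptake bi-exponential
BIEXP_RATE_SEPARATION = 1.05


@dataclass(frozen=True)
class TAC:
    """Measured time-activity samples for one region in one cycle."""

    times_h: np.ndarray
    activities_MBq: np.ndarray
    region_id: str = ""
    patient: str = ""
    cycle: int = 0

    def __post_init__(self) -> None:
        t = np.asarray(self.times_h, dtype=float)
        a = np.asarray(self.activities_MBq, dtype=float)
        if t.ndim != 1 or t.shape != a.shape or t.size < 1:
            raise DomainError("times and activities must be equal-length 1-D arrays")
        if np.any(t <= 0):
            raise DomainError("measurement times must be positive")
        if np.any(a < 0):
            raise DomainError("activities must be non-negative")
        order = np.argsort(t)
        t, a = t[order], a[order]
        sorted_unique(t)  # reject duplicate times
        object.__setattr__(self, "times_h", t)
        object.__setattr__(self, "activities_MBq", a)

    def __len__(self) -> int:
        return int(self.times_h.size)


@dataclass(frozen=True)
class TACFit:
    """A fitted kinetic model for a TAC.

    ``model`` is one of ``monoexp``, ``uptake_biexp``, ``trapezoid_tail``
    (the latter records the tail mono-exponential used for extrapolation).
    """

    model: str
    amplitude_MBq: float
    clearance_rate_h: float
    uptake_rate_h: float | None = None
    tail_points_used: int | None = None
    fit_residual_rms: float = 0.0
    flagged: bool = False

    def __post_init__(self) -> None:
        if not self.clearance_rate_h > 0:
            raise DomainError("clearance rate must be positive")
        if self.model == "uptake_biexp":
            if self.uptake_rate_h is None or self.uptake_rate_h <= self.clearance_rate_h:
                raise DomainError("uptake rate must exceed clearance rate")

    @property
    def t_eff_h(self) -> float:
        """Effective half-life of the terminal clearance phase, hours."""
        return math.log(2.0) / self.clearance_rate_h

    def predict(self, t):
        """Model activity at time(s) t (hours).

        For ``trapezoid_tail`` this is the tail mono-exponential, which is
        only meaningful at/after the start of the excretion phase.
        """
        t = np.asarray(t, dtype=float)
        if self.model == "uptake_biexp":
            return self.amplitude_MBq * (
                np.exp(-self.clearance_rate_h * t) - np.exp(-self.uptake_rate_h * t)
            )
        return self.amplitude_MBq * np.exp(-self.clearance_rate_h * t)


def _residual_rms(fit: TACFit, tac: TAC) -> float:
    resid = tac.activities_MBq - fit.predict(tac.times_h)
    return float(np.sqrt(np.mean(resid**2)))


def _loglinear(times: np.ndarray, acts: np.ndarray) -> tuple[float, float]:
    """Log-linear (A0, lam) estimate from positive samples."""
    slope, intercept = np.polyfit(times, np.log(acts), 1)
    lam = float(np.clip(-slope, LAMBDA_MIN, LAMBDA_MAX))
    return float(np.exp(intercept)), lam


def fit_monoexp(tac: TAC) -> TACFit:
    """Least-squares mono-exponential fit ``A0 * exp(-lam*t)``.

    Two points are fitted exactly (log-linear); three or more via
    nonlinear least squares on untransformed activities, initialised
    log-linearly.  A clearance rate pinned at a bound (non-decaying or
    implausibly fast data) yields a *flagged* fit.
    """
    pos = tac.activities_MBq > 0
    if int(pos.sum()) < 2:
        raise FitError("mono-exponential fit needs at least 2 positive activities")
    t, a = tac.times_h[pos], tac.activities_MBq[pos]
    a0, lam = _loglinear(t, a)
    if len(t) > 2:
        try:
            popt, _ = curve_fit(
                lambda tt, A, L: A * np.exp(-L * tt),
                t,
                a,
                p0=[max(a0, 1e-12), lam],
                bounds=([0.0, LAMBDA_MIN], [np.inf, LAMBDA_MAX]),
                maxfev=10000,
            )
        except RuntimeError as exc:  # pragma: no cover - scipy non-convergence
            raise FitError(f"mono-exponential fit did not converge: {exc}") from exc
        a0, lam = float(popt[0]), float(popt[1])
    flagged = lam <= LAMBDA_MIN * (1 + 1e-9) or lam >= LAMBDA_MAX * (1 - 1e-9)
    fit = TACFit("monoexp", a0, lam, flagged=flagged)
    return replace(fit, fit_residual_rms=_residual_rms(fit, tac))


def fit_uptake_biexp(tac: TAC) -> TACFit:
    """Least-squares uptake bi-exponential ``A0*(exp(-lam_eff*t) - exp(-lam_up*t))``.

    Requires >= 4 points with the peak after the first sample.  Initialised
    from a mono-exponential fit of the post-peak points and an uptake
    half-life of 1 h.  Raises :class:`FitError` when the two rates do not
    separate (ratio < 1.05) so the caller can fall back.
    """
    if len(tac) < 4:
        raise FitError("uptake bi-exponential fit needs at least 4 points")
    peak = int(np.argmax(tac.activities_MBq))
    if peak == 0:
        raise FitError("peak at first sample: no observable uptake phase")
    tail = TAC(tac.times_h[peak:], tac.activities_MBq[peak:])
    try:
        mono = fit_monoexp(tail)
    except FitError:
        mono = TACFit("monoexp", float(tac.activities_MBq[peak]), math.log(2) / 48.0)
    lam_up0 = max(math.log(2.0) / 1.0, mono.clearance_rate_h * 2)

    def model(tt, A, lam_eff, lam_up):
        return A * (np.exp(-lam_eff * tt) - np.exp(-lam_up * tt))

    try:
        popt, _ = curve_fit(
            model,
            tac.times_h,
            tac.activities_MBq,
            p0=[mono.amplitude_MBq, mono.clearance_rate_h, lam_up0],
            bounds=([0.0, LAMBDA_MIN, LAMBDA_MIN], [np.inf, LAMBDA_MAX, 100.0]),
            maxfev=20000,
        )
    except RuntimeError as exc:
        raise FitError(f"uptake bi-exponential fit did not converge: {exc}") from exc
    a0, lam_eff, lam_up = (float(v) for v in popt)
    if lam_up < lam_eff * BIEXP_RATE_SEPARATION:
        raise FitError("uptake and clearance rates did not separate")
    fit = TACFit("uptake_biexp", a0, lam_eff, uptake_rate_h=lam_up)
    return replace(fit, fit_residual_rms=_residual_rms(fit, tac))


def select_fit(tac: TAC) -> TACFit:
    """Reference-method fit cascade.

    1. If the first sample is below the second and there are >= 4 points,
       try the uptake bi-exponential.
    2. Otherwise (or on failure) fit a mono-exponential: to all points if
       the TAC is monotone decreasing, else to the points from the peak on.
    3. If fitting fails or the residual RMS exceeds 20% of the peak
       activity, fall back to trapezoidal integration with a tail fit
       (:func:`tia_trapezoid_tail`).
    """
    if len(tac) < 2:
        raise FitError("need at least 2 samples")
    a = tac.activities_MBq
    peak_act = float(np.max(a))
    fit: TACFit | None = None
    if len(tac) >= 4 and a[0] < a[1]:
        try:
            fit = fit_uptake_biexp(tac)
        except FitError:
            fit = None
    if fit is None:
        try:
            if np.all(np.diff(a) <= 0):
                fit = fit_monoexp(tac)
            else:
                peak = int(np.argmax(a))
                sub = TAC(tac.times_h[peak:], a[peak:]) if peak > 0 else tac
                fit = fit_monoexp(sub)
                fit = replace(fit, fit_residual_rms=_residual_rms(fit, tac))
        except FitError:
            fit = None
    if fit is None or fit.fit_residual_rms > RESIDUAL_FRACTION_LIMIT * peak_act:
        _, fit = tia_trapezoid_tail(tac)
    return fit


def tia_analytic(fit: TACFit) -> float:
    """Analytic integral of the fitted curve from t=0 to infinity, MBq*h."""
    if fit.model == "monoexp":
        return fit.amplitude_MBq / fit.clearance_rate_h
    if fit.model == "uptake_biexp":
        return fit.amplitude_MBq * (1.0 / fit.clearance_rate_h - 1.0 / fit.uptake_rate_h)
    raise DomainError(
        "analytic TIA is defined for exponential fits only; "
        "use tia_trapezoid_tail for trapezoid models"
    )


def tia_trapezoid_tail(tac: TAC, tail_points: int | None = None) -> tuple[float, TACFit]:
    """Trapezoidal TIA with mono-exponential tail extrapolation.

    The integral is a linear rise from (0, 0) to the first sample, the
    trapezoid rule between samples, and an analytic tail ``A_last/lam``
    with ``lam`` from a mono-exponential fit of the last ``tail_points``
    samples.  ``tail_points`` defaults to 3 when the last three samples
    are monotone decreasing (excretion phase already established), else 2.
    """
    if len(tac) < 3 and tail_points is None:
        if len(tac) < 2:
            raise FitError("trapezoid integration needs at least 2 samples")
        tail_points = 2
    t, a = tac.times_h, tac.activities_MBq
    if tail_points is None:
        last3 = a[-3:]
        tail_points = 3 if np.all(np.diff(last3) < 0) else 2
    if tail_points not in (2, 3):
        raise DomainError("tail_points must be 2 or 3")
    if tail_points > len(tac):
        raise FitError("not enough samples for the requested tail")
    tail_a = a[-tail_points:]
    if np.any(tail_a <= 0) or np.any(np.diff(tail_a) >= 0):
        raise FitError("tail activities must be positive and strictly decreasing")
    tail_fit = fit_monoexp(TAC(t[-tail_points:], tail_a))
    triangle = 0.5 * t[0] * a[0]
    body = float(np.trapezoid(a, t)) if len(tac) > 1 else 0.0
    tail = float(a[-1]) / tail_fit.clearance_rate_h
    fit = TACFit(
        "trapezoid_tail",
        tail_fit.amplitude_MBq,
        tail_fit.clearance_rate_h,
        tail_points_used=tail_points,
        fit_residual_rms=0.0,
    )
    return triangle + body + tail, fit


def tia_of(tac: TAC, fit: TACFit) -> float:
    """TIA for a fit produced by :func:`select_fit` (dispatches on model)."""
    if fit.model == "trapezoid_tail":
        tia, _ = tia_trapezoid_tail(tac, fit.tail_points_used)
        return tia
    return tia_analytic(fit)
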