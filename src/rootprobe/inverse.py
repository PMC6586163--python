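"""Inverse analysis of pressure-probe traces.

Estimates the probe elastic coefficient β from volume-step calibrations, the
half-times of water and solute exchange from relaxation traces, and from them
the root transport triple (Lpr, Psr, σsr):

    Lpr = ln 2 / (t½w · Ar · β)
    Psr = ln 2 · Vx / (t½s · Ar)
    σsr = (ΔPr / Δπ°s) · exp(ksr · tmin)

Exponential phases are fitted by nonlinear least squares seeded from a
log-linear fit of the envelope; the biphasic osmotic response is split at the
pressure minimum (optionally after moving-average smoothing), the water phase
fitted on [0, tmin] with a free asymptote and the solute phase on [tmin, end]
with the asymptote pinned to the pre-step pressure P(0), since under the
composite transport model the pressure recovers fully.

A cut test applied at the end of each measurement provides quality control:
cutting the root close to the seal must collapse the root pressure to near
zero and accelerate the relaxation by about an order of magnitude; otherwise
the seal was overtightened (blocked xylem) and the root is discarded.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

from .forward import LN2, PressureTrace, ProbeSystem, RootGeometry, xylem_volume

__all__ = [
    "FitError",
    "CalibrationError",
    "NoMinimumError",
    "RelaxationFit",
    "BiphasicDecomposition",
    "calibrate_beta",
    "fit_exponential_phase",
    "split_biphasic",
    "hydraulic_conductivity",
    "solute_permeability",
    "reflection_coefficient",
    "analyze_osmotic_trace",
    "qc_cut_test",
]


class FitError(RuntimeError):
    """An exponential phase could not be fitted (no decay, k ≤ 0, …)."""


class CalibrationError(RuntimeError):
    """β calibration failed (no elastic response, inconsistent signs)."""


class NoMinimumError(RuntimeError):
    """The trace has no interior pressure minimum (impermeant-solute case)."""


@dataclass(frozen=True)
class RelaxationFit:
    """Fitted single-exponential phase P(t) = asymptote + amplitude·e^(−k·t)."""

    rate_constant: float  # s⁻¹
    half_time: float  # s, = ln2 / rate_constant
    asymptote: float  # MPa
    amplitude: float  # MPa
    rss: float  # MPa²
    n_points: int

    def __post_init__(self) -> None:
        if self.rate_constant <= 0:
            raise ValueError("rate_constant must be > 0")
        if not math.isclose(self.half_time, LN2 / self.rate_constant, rel_tol=1e-9):
            raise ValueError("half_time must equal ln2/rate_constant")
        if self.n_points < 5:
            raise ValueError("a relaxation fit needs ≥ 5 points")


@dataclass(frozen=True)
class BiphasicDecomposition:
    """Water + solute phases of one osmotic experiment.

    ``deltaPr`` is the depth of the pressure minimum below the pre-step
    pressure (positive, MPa); ``tmin`` the time of the minimum (s).
    """

    water_fit: RelaxationFit
    solute_fit: RelaxationFit
    deltaPr: float
    tmin: float

    def __post_init__(self) -> None:
        if self.deltaPr <= 0 or self.tmin <= 0:
            raise ValueError("deltaPr and tmin must be > 0")


def calibrate_beta(
    volume_steps: Sequence[float],
    pressure_responses: Sequence[float],
) -> tuple[float, np.ndarray]:
    """Elastic coefficient β from paired (ΔV, ΔP) calibration steps.

    Least-squares slope of ΔP against ΔV through the origin:
    β = Σ ΔV·ΔP / Σ ΔV².  Returns (β, per-step residuals ΔP − β·ΔV).
    """
    dv = np.asarray(volume_steps, dtype=float)
    dp = np.asarray(pressure_responses, dtype=float)
    if dv.size != dp.size or dv.size < 1:
        raise CalibrationError("need ≥ 1 paired (ΔV, ΔP) step")
    if np.any(dv == 0):
        raise CalibrationError("volume steps must be nonzero")
    if np.all(dp == 0):
        raise CalibrationError("no elastic response: all ΔP are zero")
    ratios = dp / dv
    nonzero = ratios[dp != 0]
    if nonzero.size and (np.any(nonzero > 0) and np.any(nonzero < 0)):
        raise CalibrationError("inconsistent ΔP/ΔV signs across calibration steps")
    beta = float(np.dot(dv, dp) / np.dot(dv, dv))
    residuals = dp - beta * dv
    return beta, residuals


def _seed_from_loglinear(t: np.ndarray, p: np.ndarray, asymptote: float) -> tuple[float, float]:
    """Initial (amplitude, k) from a log-linear fit of |P − asymptote|."""
    dev = p - asymptote
    sign = 1.0 if dev[np.argmax(np.abs(dev))] >= 0 else -1.0
    mag = np.abs(dev)
    mask = mag > 1e-4 * mag.max()
    if mask.sum() < 2:
        raise FitError("pressure is constant in the fit window")
    slope, intercept = np.polyfit(t[mask], np.log(mag[mask]), 1)
    return sign * math.exp(intercept), -slope


def fit_exponential_phase(
    trace: PressureTrace,
    window: tuple[float, float] | None = None,
    fixed_asymptote: float | None = None,
) -> RelaxationFit:
    """Fit P(t) = P∞ + A·e^(−k·t) over a time window by nonlinear least squares.

    The fit is seeded from a log-linear regression of ln|P − P̂∞| on t, with
    P̂∞ taken from the tail mean (or ``fixed_asymptote`` when given, in which
    case P∞ is held fixed during the fit — used for the solute phase, whose
    asymptote is the pre-step pressure).  Time is re-based to the window start
    internally; the returned rate constant is origin-independent.

    Raises
    ------
    FitError
        if the window holds < 5 samples, the pressure is constant, or the
        fitted rate constant is not positive (no exponential decay).
    """
    sub = trace if window is None else trace.window(*window)
    t = sub.time - sub.time[0]
    p = sub.pressure
    if t.size < 5:
        raise FitError(f"need ≥ 5 samples in the fit window, got {t.size}")
    if np.ptp(p) == 0:
        raise FitError("pressure is constant in the fit window")

    if fixed_asymptote is None:
        # tail mean over the last ~10% of samples as the asymptote seed
        tail = max(2, t.size // 10)
        p_inf0 = float(p[-tail:].mean())
    else:
        p_inf0 = float(fixed_asymptote)

    try:
        a0, k0 = _seed_from_loglinear(t, p, p_inf0)
    except FitError:
        raise
    if not np.isfinite(k0) or k0 <= 0:
        k0 = LN2 / max(t[-1] / 2.0, t[1])
        a0 = p[0] - p_inf0

    try:
        if fixed_asymptote is None:
            popt, _ = curve_fit(
                lambda tt, pinf, a, k: pinf + a * np.exp(-k * tt),
                t, p, p0=[p_inf0, a0, k0], maxfev=20000,
            )
            p_inf, amp, k = (float(v) for v in popt)
        else:
            popt, _ = curve_fit(
                lambda tt, a, k: p_inf0 + a * np.exp(-k * tt),
                t, p, p0=[a0, k0], maxfev=20000,
            )
            amp, k = (float(v) for v in popt)
            p_inf = p_inf0
    except RuntimeError as exc:  # pragma: no cover - pathological inputs
        raise FitError(f"exponential fit did not converge: {exc}") from exc

    if k <= 0 or not np.isfinite(k):
        raise FitError(f"fitted rate constant not positive (k = {k:g} s⁻¹)")
    resid = p - (p_inf + amp * np.exp(-k * t))
    return RelaxationFit(
        rate_constant=k,
        half_time=LN2 / k,
        asymptote=p_inf,
        amplitude=amp,
        rss=float(np.dot(resid, resid)),
        n_points=int(t.size),
    )


def _smooth(p: np.ndarray, window: int) -> np.ndarray:
    """Centred moving average with edge shrinkage (window forced odd)."""
    if window <= 1:
        return p
    w = window + 1 if window % 2 == 0 else window
    half = w // 2
    padded = np.pad(p, half, mode="edge")
    kernel = np.ones(w) / w
    return np.convolve(padded, kernel, mode="valid")


def split_biphasic(
    trace: PressureTrace,
    smooth_window: int = 5,
    solute_onset_efolds: float = 3.0,
) -> BiphasicDecomposition:
    """Split a biphasic osmotic trace at its pressure minimum.

    The minimum is located on the (moving-average smoothed) trace; the water
    phase is fitted on [0, tmin] with a free asymptote and the solute phase on
    [tmin, end] with the asymptote pinned at the pre-step pressure P(0).  The
    solute-phase window actually starts ``solute_onset_efolds`` water-phase
    time constants after tmin (when possible), where the residual water-phase
    transient has decayed to < e⁻³ of its value at the minimum; near the
    minimum the two phases overlap and would bias the solute rate constant
    upward.  Set ``solute_onset_efolds=0`` to fit from tmin exactly.

    Raises
    ------
    NoMinimumError
        if the trace is monotone (flat σ = 0 trace, or impermeant solute with
        no recovery phase).
    """
    p_s = _smooth(trace.pressure, smooth_window)
    idx = int(np.argmin(p_s))
    if idx == 0 or idx >= trace.n - 1:
        raise NoMinimumError(
            "no interior pressure minimum: trace is monotone "
            "(flat response or impermeant solute)"
        )
    # guard against a noise dimple: require a real recovery after the minimum
    depth = trace.pressure[0] - p_s[idx]
    recovery = p_s[-1] - p_s[idx]
    if depth <= 0 or recovery < 0.02 * depth:
        raise NoMinimumError(
            "no solute-phase recovery after the minimum (impermeant-solute plateau?)"
        )

    tmin = float(trace.time[idx])
    delta_pr = float(trace.pressure[0] - p_s[idx])
    water = fit_exponential_phase(trace, window=(trace.time[0], tmin))
    t_end = float(trace.time[-1])
    onset = tmin + solute_onset_efolds / water.rate_constant
    if onset > tmin + 0.5 * (t_end - tmin):  # keep most of the solute phase
        onset = tmin
    solute = fit_exponential_phase(
        trace, window=(onset, t_end), fixed_asymptote=float(trace.pressure[0])
    )
    return BiphasicDecomposition(water_fit=water, solute_fit=solute, deltaPr=delta_pr, tmin=tmin)


def hydraulic_conductivity(half_time_w: float, Ar: float, beta: float) -> float:
    """Lpr = ln 2 / (t½w · Ar · β), m s⁻¹ MPa⁻¹."""
    if half_time_w <= 0 or Ar <= 0 or beta <= 0:
        raise ValueError("half_time_w, Ar and beta must all be > 0")
    return LN2 / (half_time_w * Ar * beta)


def solute_permeability(half_time_s: float, Ar: float, Vx: float) -> float:
    """Psr = ln 2 · Vx / (t½s · Ar), m s⁻¹."""
    if half_time_s <= 0 or Ar <= 0 or Vx <= 0:
        raise ValueError("half_time_s, Ar and Vx must all be > 0")
    return LN2 * Vx / (half_time_s * Ar)


def reflection_coefficient(deltaPr: float, delta_pi: float, ksr: float, tmin: float) -> float:
    """σsr = (ΔPr/Δπ°s)·e^(ksr·tmin); warns when the estimate exceeds 1."""
    if delta_pi <= 0:
        raise ValueError("delta_pi must be > 0")
    if deltaPr < 0 or tmin < 0:
        raise ValueError("deltaPr and tmin must be ≥ 0")
    sigma = (deltaPr / delta_pi) * math.exp(ksr * tmin)
    if sigma > 1.0:
        warnings.warn(
            f"reflection coefficient estimate {sigma:.3f} exceeds 1; "
            "check ΔPr, Δπ and the solute-phase fit",
            stacklevel=2,
        )
    return sigma


def analyze_osmotic_trace(
    trace: PressureTrace,
    probe: ProbeSystem,
    geom: RootGeometry,
    delta_pi: float | None = None,
    smooth_window: int = 5,
) -> dict:
    """Full inverse analysis of one biphasic osmotic trace.

    Returns a dict with the biphasic decomposition plus derived osmotic Lpr
    (from the water-phase half-time), Psr (solute phase) and σsr.  The osmotic
    step Δπ°s defaults to the trace's event magnitude.
    """
    dpi = trace.event_magnitude if delta_pi is None else delta_pi
    decomp = split_biphasic(trace, smooth_window=smooth_window)
    ksr = decomp.solute_fit.rate_constant
    vx = xylem_volume(geom)
    return {
        "decomposition": decomp,
        "Lpr_osmotic": hydraulic_conductivity(decomp.water_fit.half_time, probe.Ar, probe.beta),
        "Psr": solute_permeability(decomp.solute_fit.half_time, probe.Ar, vx),
        "sigma": reflection_coefficient(decomp.deltaPr, dpi, ksr, decomp.tmin),
        "ksr": ksr,
        "tmin": decomp.tmin,
        "deltaPr": decomp.deltaPr,
    }


def qc_cut_test(
    pre_cut: RelaxationFit,
    post_cut_trace: PressureTrace | None,
    pre_cut_steady_pressure: float | None = None,
    pressure_drop_fraction: float = 0.10,
    half_time_speedup: float = 10.0,
) -> tuple[str, list[str]]:
    """Cut-test quality control on a mounted root.

    After cutting the root close to the seal, a properly mounted root must
    (a) lose its root pressure to below ``pressure_drop_fraction`` of the
    pre-cut steady pressure and (b) relax about ``half_time_speedup`` times
    faster than during hydrostatic relaxations; a seal that was overtightened
    blocks the xylem vessels and fails both.

    Returns (verdict, reasons) with verdict in {"pass", "fail",
    "indeterminate"}.
    """
    if post_cut_trace is None or post_cut_trace.n < 5:
        return "indeterminate", ["missing or too-short post-cut trace"]
    steady = pre_cut.asymptote if pre_cut_steady_pressure is None else pre_cut_steady_pressure
    if steady <= 0:
        return "indeterminate", ["non-positive pre-cut steady pressure"]

    reasons: list[str] = []
    final_pressure = float(post_cut_trace.pressure[-1])
    if final_pressure > pressure_drop_fraction * steady:
        reasons.append(
            f"root pressure did not collapse: final {final_pressure:.3f} MPa "
            f"> {pressure_drop_fraction:.0%} of steady {steady:.3f} MPa "
            "(overtightened seal blocking the xylem?)"
        )
    try:
        post_fit = fit_exponential_phase(post_cut_trace)
        if post_fit.half_time > pre_cut.half_time / half_time_speedup:
            reasons.append(
                f"post-cut t½ = {post_fit.half_time:.2f} s not ≥ "
                f"{half_time_speedup:g}× faster than pre-cut {pre_cut.half_time:.2f} s"
            )
    except FitError as exc:
        reasons.append(f"post-cut relaxation not fittable: {exc}")
    return ("pass" if not reasons else "fail"), reasons
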