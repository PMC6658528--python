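"""Patch-clamp photocurrent analysis.

Implements the standard whole-cell analysis rules for strongly desensitizing
channelrhodopsin photocurrents:

* peak current = signed extremum within the light window,
* stationary current = mean of the last 50 ms of illumination,
* desensitization extent = 1 - |I_stationary / I_peak|,
* mono/bi-exponential kinetic fits with amplitude-weighted apparent time
  constants (tau_des, tau_off),
* reversal potentials by interpolation of the zero crossing (or extrapolation
  from the two smallest-|I| adjacent points when the series does not cross),
* double-pulse recovery fits R(dt) = 1 - exp(-dt/tau_rec),
* three-parameter Weibull fits of normalized action spectra for lambda_max.

Nernst, permeability-ratio and Henderson liquid-junction computations live in
:mod:`mermaidkin.solutions` and are re-exported here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import lmfit
import numpy as np

from .kinetics import PhotocurrentTrace
from .solutions import (  # noqa: F401  (re-exported module surface)
    SolutionComposition,
    henderson_ljp,
    nernst_potential,
    permeability_ratio,
)

__all__ = [
    "IVSeries",
    "ActionSpectrum",
    "RecoverySeries",
    "ExpFitResult",
    "WeibullFitResult",
    "extract_peak",
    "extract_stationary",
    "desensitization_extent",
    "ExponentialDecayModel",
    "fit_exponentials",
    "reversal_potential",
    "RecoveryModel",
    "recovery_fit",
    "WeibullActionModel",
    "weibull_action_fit",
    "SolutionComposition",
    "nernst_potential",
    "permeability_ratio",
    "henderson_ljp",
]

STATIONARY_WINDOW_S = 0.050  # average the last 50 ms of illumination


@dataclass
class IVSeries:
    """Current-voltage relationship at one ionic condition."""

    voltages: np.ndarray  # mV, LJP-corrected, strictly increasing
    currents: np.ndarray  # pA
    condition_label: str = ""

    def __post_init__(self):
        self.voltages = np.asarray(self.voltages, dtype=float)
        self.currents = np.asarray(self.currents, dtype=float)
        if self.voltages.size != self.currents.size:
            raise ValueError("voltages and currents must have equal length")
        if self.voltages.size < 2:
            raise ValueError("need at least two IV points")
        if np.any(np.diff(self.voltages) <= 0):
            raise ValueError("voltages must be strictly increasing")


@dataclass
class ActionSpectrum:
    """Wavelength dependence of the photocurrent, normalized to max = 1."""

    wavelengths: np.ndarray  # nm, increasing
    responses: np.ndarray

    def __post_init__(self):
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if self.wavelengths.size != self.responses.size:
            raise ValueError("length mismatch")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        m = np.max(np.abs(self.responses))
        if m == 0:
            raise ValueError("all-zero action spectrum")
        self.responses = self.responses / m


@dataclass
class RecoverySeries:
    """Paired-pulse peak ratios versus dark interval."""

    intervals: np.ndarray  # s
    peak_ratios: np.ndarray  # in (0, 1]

    def __post_init__(self):
        self.intervals = np.asarray(self.intervals, dtype=float)
        self.peak_ratios = np.asarray(self.peak_ratios, dtype=float)
        if self.intervals.size != self.peak_ratios.size:
            raise ValueError("length mismatch")
        if np.any(self.intervals <= 0):
            raise ValueError("intervals must be positive")


@dataclass
class ExpFitResult:
    """Multi-exponential fit: offset + sum_i a_i exp(-t/tau_i).

    ``apparent_tau`` is the amplitude-weighted mean sum|a_i| tau_i / sum|a_i|,
    the convention behind apparent desensitization/closing constants of
    biphasic fits.
    """

    amplitudes: np.ndarray
    taus: np.ndarray  # s, ascending
    offset: float
    model_order: int
    residual_rms: float
    aic: float
    converged: bool
    degenerate: bool = False

    def __post_init__(self):
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        self.taus = np.asarray(self.taus, dtype=float)

    @property
    def apparent_tau(self) -> float:
        w = np.abs(self.amplitudes)
        if w.sum() == 0:
            return float("nan")
        return float(np.sum(w * self.taus) / w.sum())

    def summary(self) -> str:
        lines = [f"{self.model_order}-exponential fit", "=" * 24]
        for a, tau in zip(self.amplitudes, self.taus):
            lines.append(f"  a = {a:+.4g}, tau = {tau:.4g} s")
        lines.append(f"  offset        {self.offset:+.4g}")
        lines.append(f"  apparent tau  {self.apparent_tau:.4g} s")
        lines.append(f"  residual RMS  {self.residual_rms:.3g}  AIC {self.aic:.1f}")
        if self.degenerate:
            lines.append("  [degenerate: amplitude ~ 0, taus unreliable]")
        return "\n".join(lines)


@dataclass
class WeibullFitResult:
    """Three-parameter Weibull action-spectrum fit."""

    location: float  # lambda_0, nm
    scale: float  # beta, nm
    shape: float  # k (> 1 for a peaked curve)
    lambda_max: float  # nm
    residual_rms: float
    converged: bool
    monotone_flag: bool = False  # k <= 1: no interior peak

    def curve(self, wavelengths) -> np.ndarray:
        return _weibull_shape(np.asarray(wavelengths, dtype=float), self.location, self.scale, self.shape)

    def summary(self) -> str:
        return (
            "Weibull action-spectrum fit\n"
            f"  lambda_0 = {self.location:.2f} nm, beta = {self.scale:.2f} nm, "
            f"k = {self.shape:.3f}\n"
            f"  lambda_max = {self.lambda_max:.2f} nm (residual RMS {self.residual_rms:.3g})"
        )


def extract_peak(trace: PhotocurrentTrace) -> float:
    """Signed extremum of the current within the light window (pA)."""
    on, off = trace.light_window
    sel = (trace.times >= on) & (trace.times <= off)
    if not np.any(sel):
        raise ValueError("light window contains no samples")
    window = trace.current[sel]
    return float(window[np.argmax(np.abs(window))])


def extract_stationary(trace: PhotocurrentTrace) -> float:
    """Mean current over the last 50 ms of illumination (pA).

    Uses trapezoidal averaging so the result is exact for linear drifts
    regardless of sample spacing.
    """
    on, off = trace.light_window
    if off - on < STATIONARY_WINDOW_S:
        raise ValueError(
            "stationary-current rule needs a light window of at least 50 ms "
            f"(got {(off - on) * 1e3:.1f} ms)"
        )
    start = off - STATIONARY_WINDOW_S
    sel = (trace.times >= start - 1e-12) & (trace.times <= off + 1e-12)
    t = trace.times[sel]
    i = trace.current[sel]
    if t.size < 2:
        raise ValueError("fewer than two samples in the stationary window")
    return float(np.trapezoid(i, t) / (t[-1] - t[0]))


def desensitization_extent(peak: float, stationary: float) -> float:
    """Fractional current decline 1 - |I_stationary / I_peak| in [0, 1]."""
    if peak == 0:
        raise ValueError("zero peak current")
    frac = 1.0 - abs(stationary / peak)
    return float(min(max(frac, 0.0), 1.0))


class ExponentialDecayModel:
    """Mono- or bi-exponential model for a monotone-trending segment.

    The caller crops the trace to the decaying (or recovering) segment;
    ``fit`` runs lmfit least squares from heuristic initial values.
    """

    def __init__(self, times, values, model_order: int = 1):
        self.times = np.asarray(times, dtype=float)
        self.values = np.asarray(values, dtype=float)
        if model_order not in (1, 2):
            raise ValueError("model_order must be 1 or 2")
        if self.times.size < 5 * model_order:
            raise ValueError(f"need at least {5 * model_order} points for order {model_order}")
        self.model_order = model_order

    def fit(self, tau_init=None) -> ExpFitResult:
        t = self.times - self.times[0]
        y = self.values
        span = y.max() - y.min()
        degenerate_input = span < 1e-12 * max(1.0, np.abs(y).max())
        if tau_init is None:
            t_range = max(t[-1], 1e-9)
            tau_init = [t_range / 5.0] if self.model_order == 1 else [t_range / 20.0, t_range / 3.0]
        params = lmfit.Parameters()
        params.add("offset", value=float(y[-1]))
        for i, tau0 in enumerate(tau_init, start=1):
            params.add(f"a{i}", value=float((y[0] - y[-1]) / len(tau_init)))
            params.add(f"tau{i}", value=float(tau0), min=1e-12)

        def model(p):
            out = np.full_like(t, p["offset"].value)
            for i in range(1, self.model_order + 1):
                out = out + p[f"a{i}"].value * np.exp(-t / p[f"tau{i}"].value)
            return out

        out = lmfit.minimize(lambda p: model(p) - y, params)
        p = out.params
        amps = np.array([p[f"a{i}"].value for i in range(1, self.model_order + 1)])
        taus = np.array([p[f"tau{i}"].value for i in range(1, self.model_order + 1)])
        order = np.argsort(taus)
        amps, taus = amps[order], taus[order]
        resid = model(p) - y
        rms = float(np.sqrt(np.mean(resid**2)))
        degenerate = degenerate_input or np.abs(amps).sum() < 1e-9 * max(1.0, np.abs(y).max())
        return ExpFitResult(
            amplitudes=amps,
            taus=taus,
            offset=float(p["offset"].value),
            model_order=self.model_order,
            residual_rms=rms,
            aic=float(out.aic),
            converged=bool(out.success),
            degenerate=bool(degenerate),
        )


def fit_exponentials(times, values, model_order: int = 1, tau_init=None) -> ExpFitResult:
    """Least-squares fit of offset + sum a_i exp(-t/tau_i); taus ascending."""
    return ExponentialDecayModel(times, values, model_order).fit(tau_init)


def reversal_potential(iv: IVSeries) -> float:
    """Zero-current voltage from an IV series (mV).

    If consecutive points bracket a sign change, interpolate linearly within
    the first such pair (scanning from the most negative voltage).  If all
    currents share one sign, extrapolate the line through the two
    voltage-adjacent points of smallest |I| (ties broken toward the pair
    containing the global minimum |I|).
    """
    v, i = iv.voltages, iv.currents
    for j in range(v.size - 1):
        if i[j] == 0.0 and i[j + 1] == 0.0:
            raise ValueError("two consecutive zero currents: reversal undefined")
        if i[j] == 0.0:
            return float(v[j])
        if i[j] * i[j + 1] < 0:
            return float(v[j] - i[j] * (v[j + 1] - v[j]) / (i[j + 1] - i[j]))
    if i[-1] == 0.0:
        return float(v[-1])
    # no crossing: extrapolate from adjacent pair with smallest currents
    j_min = int(np.argmin(np.abs(i)))
    candidates = [j for j in (j_min - 1, j_min) if 0 <= j < v.size - 1]
    j = min(candidates, key=lambda j: np.abs(i[j]) + np.abs(i[j + 1]))
    di = i[j + 1] - i[j]
    if di == 0:
        raise ValueError("flat IV segment: cannot extrapolate a crossing")
    return float(v[j] - i[j] * (v[j + 1] - v[j]) / di)


class RecoveryModel:
    """Dark-recovery model R(dt) = 1 - exp(-dt/tau_rec) for paired pulses."""

    def __init__(self, series: RecoverySeries):
        if series.intervals.size < 4:
            raise ValueError("need at least four intervals for a recovery fit")
        self.series = series

    def fit(self) -> ExpFitResult:
        dt = self.series.intervals
        r = self.series.peak_ratios
        degenerate = np.all(r > 0.99)
        params = lmfit.Parameters()
        params.add("tau", value=float(np.median(dt)), min=1e-9)
        out = lmfit.minimize(lambda p: 1.0 - np.exp(-dt / p["tau"].value) - r, params)
        tau = float(out.params["tau"].value)
        resid = 1.0 - np.exp(-dt / tau) - r
        return ExpFitResult(
            amplitudes=np.array([-1.0]),
            taus=np.array([tau]),
            offset=1.0,
            model_order=1,
            residual_rms=float(np.sqrt(np.mean(resid**2))),
            aic=float(out.aic),
            converged=bool(out.success),
            degenerate=bool(degenerate),
        )


def recovery_fit(series: RecoverySeries) -> ExpFitResult:
    """Fit the paired-pulse recovery time constant tau_rec."""
    return RecoveryModel(series).fit()


def _weibull_shape(x, location, scale, shape):
    """Weibull density shape normalized to unit maximum (zero below location)."""
    z = (np.asarray(x, dtype=float) - location) / scale
    out = np.zeros_like(z)
    pos = z > 0
    out[pos] = z[pos] ** (shape - 1.0) * np.exp(-(z[pos] ** shape))
    if shape > 1.0:
        zmax = ((shape - 1.0) / shape) ** (1.0 / shape)
        peak = zmax ** (shape - 1.0) * np.exp(-(zmax**shape))
        out /= peak
    return out


class WeibullActionModel:
    """Three-parameter Weibull model for a normalized action spectrum.

    The fitted curve is the Weibull density shape in wavelength with location
    lambda_0, scale beta and shape k, max-normalized; the peak wavelength is
    analytic: lambda_max = lambda_0 + beta * ((k-1)/k)^(1/k).
    """

    def __init__(self, spectrum: ActionSpectrum):
        if spectrum.wavelengths.size < 6:
            raise ValueError("need at least six wavelengths spanning the peak")
        self.spectrum = spectrum

    def fit(self) -> WeibullFitResult:
        wl = self.spectrum.wavelengths
        resp = self.spectrum.responses
        wl_peak = wl[np.argmax(resp)]
        span = wl[-1] - wl[0]

        def resid(p):
            return (
                _weibull_shape(wl, p["location"].value, p["scale"].value, p["shape"].value) - resp
            )

        # the (location, scale, shape) surface has long degenerate valleys
        # (large shape + large scale mimics a Gaussian), so start from a small
        # grid of shapes/locations and keep the best least-squares solution
        out = None
        for shape0 in (1.5, 2.0, 3.0, 5.0):
            for loc_frac in (0.3, 0.8):
                params = lmfit.Parameters()
                params.add(
                    "location",
                    value=float(wl_peak - loc_frac * span),
                    min=float(wl[0] - 5.0 * span),
                    max=float(wl_peak - 1e-6),
                )
                params.add("scale", value=float(span), min=1.0, max=float(10.0 * span))
                params.add("shape", value=shape0, min=1.01, max=50.0)
                cand = lmfit.minimize(resid, params)
                if out is None or cand.chisqr < out.chisqr:
                    out = cand
        loc = float(out.params["location"].value)
        beta = float(out.params["scale"].value)
        k = float(out.params["shape"].value)
        monotone = k <= 1.0
        lam_max = loc + beta * ((k - 1.0) / k) ** (1.0 / k) if k > 1.0 else float("nan")
        rms = float(np.sqrt(np.mean(resid(out.params) ** 2)))
        return WeibullFitResult(
            location=loc,
            scale=beta,
            shape=k,
            lambda_max=lam_max,
            residual_rms=rms,
            converged=bool(out.success),
            monotone_flag=monotone,
        )


def weibull_action_fit(spectrum: ActionSpectrum) -> WeibullFitResult:
    """Fit the three-parameter Weibull curve and return lambda_max."""
    return WeibullActionModel(spectrum).fit()
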