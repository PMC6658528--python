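"""Steady-state UV/vis spectrum processing and pH-titration analysis.

Covers the routine operations on dark/illuminated rhodopsin absorption
spectra: normalization (to the 280 nm protein band or the chromophore
maximum), Savitzky-Golay smoothing, light-minus-dark difference spectra,
detection of the fine-structured sub-maxima of the deprotonated M-like
species, and base-10 Boltzmann fitting of absorbance-versus-pH titrations
to extract the pK of the Schiff-base deprotonation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import lmfit
import numpy as np
from scipy.signal import savgol_filter

__all__ = [
    "Spectrum",
    "TitrationSeries",
    "BoltzmannFitResult",
    "normalize",
    "smooth_sg",
    "difference_spectrum",
    "find_submaxima",
    "BoltzmannTitrationModel",
    "boltzmann_pk_fit",
]

CHROMOPHORE_WINDOW = (330.0, 650.0)  # nm, retinal absorption search window


@dataclass
class Spectrum:
    """An absorbance spectrum on a strictly increasing wavelength grid."""

    wavelengths: np.ndarray  # nm
    absorbance: np.ndarray  # AU
    label: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.wavelengths.size != self.absorbance.size:
            raise ValueError("length mismatch")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly increasing")

    def value_at(self, wavelength: float) -> float:
        lo, hi = self.wavelengths[0], self.wavelengths[-1]
        if not lo <= wavelength <= hi:
            raise ValueError(f"{wavelength} nm outside spectral range [{lo}, {hi}]")
        return float(np.interp(wavelength, self.wavelengths, self.absorbance))


@dataclass
class TitrationSeries:
    """Absorbance amplitude at one wavelength across a pH series."""

    ph_values: np.ndarray
    amplitudes: np.ndarray
    wavelength: float = float("nan")

    def __post_init__(self):
        self.ph_values = np.asarray(self.ph_values, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if self.ph_values.size != self.amplitudes.size:
            raise ValueError("length mismatch")
        if self.ph_values.size < 4:
            raise ValueError("need at least four pH points spanning the transition")


@dataclass
class BoltzmannFitResult:
    """Base-10 Boltzmann (Henderson-Hasselbalch-type) titration fit."""

    pk: float
    hill_slope: float
    plateau_low: float  # amplitude at low pH
    plateau_high: float  # amplitude at high pH
    residual_rms: float
    converged: bool
    pk_in_span: bool

    def curve(self, ph) -> np.ndarray:
        ph = np.asarray(ph, dtype=float)
        return self.plateau_low + (self.plateau_high - self.plateau_low) / (
            1.0 + 10.0 ** (self.hill_slope * (self.pk - ph))
        )

    def summary(self) -> str:
        flag = "" if self.pk_in_span else "  [pK outside sampled span]"
        return (
            "Boltzmann titration fit\n"
            f"  pK = {self.pk:.3f}, Hill slope = {self.hill_slope:.3f}{flag}\n"
            f"  plateaus: {self.plateau_low:.4g} -> {self.plateau_high:.4g} "
            f"(residual RMS {self.residual_rms:.3g})"
        )


def normalize(spec: Spectrum, mode: str = "chromophore_max") -> Spectrum:
    """Scale a spectrum so a reference value equals one.

    ``at_280`` anchors at the 280 nm protein band; ``chromophore_max`` at the
    absolute maximum inside the 330-650 nm retinal window.
    """
    if mode == "at_280":
        ref = spec.value_at(280.0)
    elif mode == "chromophore_max":
        lo, hi = CHROMOPHORE_WINDOW
        sel = (spec.wavelengths >= lo) & (spec.wavelengths <= hi)
        if not np.any(sel):
            raise ValueError("no points inside the chromophore window")
        ref = float(np.max(spec.absorbance[sel]))
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    if ref == 0:
        raise ValueError("zero reference absorbance")
    return Spectrum(
        wavelengths=spec.wavelengths,
        absorbance=spec.absorbance / ref,
        label=spec.label,
        metadata={**spec.metadata, "normalized": mode},
    )


def smooth_sg(spec: Spectrum, window_points: int = 11, poly_order: int = 5) -> Spectrum:
    """Savitzky-Golay smoothing; polynomials up to poly_order are fixed points.

    A symmetric odd window is required, so the traditional even 10-point
    window is used here as its next odd size (11).
    """
    if window_points % 2 == 0 or window_points <= poly_order:
        raise ValueError("window must be odd and greater than poly_order")
    if spec.wavelengths.size < window_points:
        raise ValueError("spectrum shorter than the smoothing window")
    return Spectrum(
        wavelengths=spec.wavelengths,
        absorbance=savgol_filter(spec.absorbance, window_points, poly_order),
        label=spec.label,
        metadata={**spec.metadata, "smoothed": f"sg{window_points}/{poly_order}"},
    )


def difference_spectrum(a: Spectrum, b: Spectrum) -> Spectrum:
    """Pointwise a - b; both spectra must share the exact wavelength grid."""
    if a.wavelengths.size != b.wavelengths.size or np.any(a.wavelengths != b.wavelengths):
        raise ValueError("wavelength grids differ; resample before subtracting")
    return Spectrum(
        wavelengths=a.wavelengths,
        absorbance=a.absorbance - b.absorbance,
        label=f"{a.label} - {b.label}".strip(" -"),
        metadata={"difference_of": (a.label, b.label)},
    )


def find_submaxima(spec: Spectrum, window: tuple | None = None) -> np.ndarray:
    """Local maxima (strict neighbor comparison) with parabolic refinement.

    Returns sub-grid wavelength positions in nm inside ``window``; an empty
    array when the segment is monotone.  Intended for locating the
    fine-structured UV sub-bands of the M-like state on smoothed spectra.
    """
    wl, ab = spec.wavelengths, spec.absorbance
    if window is not None:
        sel = (wl >= window[0]) & (wl <= window[1])
        wl, ab = wl[sel], ab[sel]
    peaks = []
    for j in range(1, wl.size - 1):
        if ab[j] > ab[j - 1] and ab[j] > ab[j + 1]:
            # parabola through the three points around the sample maximum
            denom = ab[j - 1] - 2 * ab[j] + ab[j + 1]
            shift = 0.0 if denom == 0 else 0.5 * (ab[j - 1] - ab[j + 1]) / denom
            step = 0.5 * (wl[j + 1] - wl[j - 1])
            peaks.append(wl[j] + shift * step)
    return np.asarray(peaks)


class BoltzmannTitrationModel:
    """Boltzmann model A(pH) = A1 + (A2 - A1) / (1 + 10^(h (pK - pH)))."""

    def __init__(self, series: TitrationSeries):
        self.series = series

    def fit(self, hill: float = 1.0, vary_hill: bool = False) -> BoltzmannFitResult:
        """Fit pK and plateaus; the Hill slope stays fixed at ``hill`` (a
        single-site protonation) unless ``vary_hill`` is set."""
        ph = self.series.ph_values
        amp = self.series.amplitudes
        params = lmfit.Parameters()
        params.add("a1", value=float(amp[np.argmin(ph)]))
        params.add("a2", value=float(amp[np.argmax(ph)]))
        params.add("pk", value=float(np.median(ph)))
        params.add("h", value=float(hill), min=0.05, max=20.0, vary=vary_hill)

        def resid(p):
            return (
                p["a1"].value
                + (p["a2"].value - p["a1"].value)
                / (1.0 + 10.0 ** (p["h"].value * (p["pk"].value - ph)))
                - amp
            )

        out = lmfit.minimize(resid, params)
        pk = float(out.params["pk"].value)
        in_span = bool(ph.min() <= pk <= ph.max())
        return BoltzmannFitResult(
            pk=pk,
            hill_slope=float(out.params["h"].value),
            plateau_low=float(out.params["a1"].value),
            plateau_high=float(out.params["a2"].value),
            residual_rms=float(np.sqrt(np.mean(resid(out.params) ** 2))),
            converged=bool(out.success),
            pk_in_span=in_span,
        )


def boltzmann_pk_fit(
    series: TitrationSeries, hill: float = 1.0, vary_hill: bool = False
) -> BoltzmannFitResult:
    """Fit the base-10 Boltzmann titration model; see BoltzmannTitrationModel."""
    return BoltzmannTitrationModel(series).fit(hill, vary_hill)
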