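"""Global lifetime analysis of time-resolved difference spectra.

Flash-photolysis and rapid-scan FTIR datasets are wavelength (or wavenumber)
by time matrices of absorbance changes.  This module implements the standard
global-analysis toolchain:

* isologarithmic time grids (fixed number of points per decade),
* closed-form concentration profiles of the unidirectional sequential scheme
  A1 -> A2 -> ... -> An -> ground (Bateman equations),
* SVD truncation with an automatic rank rule,
* variable-projection global fitting of the lifetimes, where the
  conditionally linear amplitude spectra are solved exactly by linear least
  squares at every candidate lifetime set,
* the exact linear transform between decay-associated (DADS) and
  evolution-associated (EADS) difference spectra, and
* the SVD-plus-rotation kinetic decomposition used for FTIR series.

Lifetimes are optimized in log10 space because photocycles span ten decades
(nanoseconds to hundreds of seconds).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "TimeResolvedSpectra",
    "SequentialFitResult",
    "make_isolog_grid",
    "bateman_coefficients",
    "bateman_concentrations",
    "svd_truncate",
    "SequentialSpectralModel",
    "global_fit_sequential",
    "eads_dads_transform",
    "ftir_kinetic_decomposition",
]

#: relative rate gap below which two sequential rates are considered
#: degenerate and the later one is jittered (avoids the confluent Bateman
#: closed form; the induced lifetime error is far below fit tolerances)
DEGENERACY_RTOL = 1e-9
DEGENERACY_JITTER = 1e-6


@dataclass
class TimeResolvedSpectra:
    """A wavelength/wavenumber x time matrix of absorbance changes."""

    axis_values: np.ndarray  # nm or cm^-1, strictly increasing
    times: np.ndarray  # s, strictly increasing
    delta_a: np.ndarray  # (n_axis, n_times)
    axis_kind: str = "wavelength"  # or "wavenumber"
    excluded_ranges: tuple = ()  # ((lo, hi), ...) axis intervals to mask
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.axis_values = np.asarray(self.axis_values, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.delta_a = np.asarray(self.delta_a, dtype=float)
        if self.axis_kind not in ("wavelength", "wavenumber"):
            raise ValueError(f"unknown axis kind {self.axis_kind!r}")
        if np.any(np.diff(self.axis_values) <= 0):
            raise ValueError("axis_values must be strictly increasing")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.delta_a.shape != (self.axis_values.size, self.times.size):
            raise ValueError("delta_a shape must be (n_axis, n_times)")
        lo, hi = self.axis_values[0], self.axis_values[-1]
        for a, b in self.excluded_ranges:
            if b < a or b < lo or a > hi:
                raise ValueError(f"excluded range ({a}, {b}) outside axis span")

    def mask(self) -> np.ndarray:
        """Boolean keep-mask over the axis after applying excluded ranges."""
        keep = np.ones(self.axis_values.size, dtype=bool)
        for a, b in self.excluded_ranges:
            keep &= ~((self.axis_values >= a) & (self.axis_values <= b))
        return keep


@dataclass
class SequentialFitResult:
    """Result of a sequential-model global fit.

    ``eads`` are the spectra of the sequentially evolving compartments;
    ``dads`` the amplitudes of the corresponding pure exponentials.  Both
    reconstruct the data identically: ``eads @ C(t) == dads @ exp(-t/tau)``.
    """

    lifetimes: np.ndarray  # s, ascending
    dads: np.ndarray  # (n_axis, n_components)
    eads: np.ndarray  # (n_axis, n_components)
    residual_rms: float
    n_svd_components: int
    converged: bool
    axis_values: np.ndarray | None = None
    model: "SequentialSpectralModel | None" = None

    def __post_init__(self):
        self.lifetimes = np.asarray(self.lifetimes, dtype=float)
        if np.any(self.lifetimes <= 0):
            raise ValueError("lifetimes must be positive")
        if np.any(np.diff(self.lifetimes) < 0):
            raise ValueError("lifetimes must be sorted ascending")

    def reconstruct(self, times) -> np.ndarray:
        """Model data matrix EADS @ C(t) on the given times."""
        c = bateman_concentrations(self.lifetimes, times)
        return self.eads @ c

    def summary(self) -> str:
        lines = ["Sequential global lifetime analysis", "=" * 36]
        lines.append(f"components:     {self.lifetimes.size}")
        lines.append(f"converged:      {self.converged}")
        lines.append(f"residual RMS:   {self.residual_rms:.3e}")
        lines.append(f"SVD components: {self.n_svd_components}")
        for i, tau in enumerate(self.lifetimes, start=1):
            lines.append(f"  tau_{i}: {_format_time(tau)}")
        return "\n".join(lines)

    def plot(self, ax=None):
        """EADS vs axis; requires matplotlib."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        x = self.axis_values if self.axis_values is not None else np.arange(self.eads.shape[0])
        for i, tau in enumerate(self.lifetimes):
            ax.plot(x, self.eads[:, i], label=f"EADS {i + 1} ({_format_time(tau)})")
        ax.axhline(0.0, color="0.6", lw=0.5)
        ax.set_ylabel("ΔA")
        ax.legend()
        return ax


def _format_time(t: float) -> str:
    for scale, unit in ((1.0, "s"), (1e-3, "ms"), (1e-6, "µs"), (1e-9, "ns")):
        if t >= scale:
            return f"{t / scale:.3g} {unit}"
    return f"{t:.3g} s"


def make_isolog_grid(t_start: float, t_end: float, points_per_decade: int) -> np.ndarray:
    """Geometric time grid with a fixed number of points per decade.

    Both endpoints are included; for decade-aligned endpoints the grid holds
    ``round(log10(t_end/t_start)) * points_per_decade + 1`` points (101 for
    10 ns to 100 s at 10 per decade).
    """
    if t_start <= 0 or t_end <= t_start:
        raise ValueError("need 0 < t_start < t_end")
    if points_per_decade < 1:
        raise ValueError("points_per_decade must be >= 1")
    n_dec = np.log10(t_end / t_start)
    n = int(round(n_dec * points_per_decade)) + 1
    grid = np.geomspace(t_start, t_end, n)
    grid[0], grid[-1] = t_start, t_end
    return grid


def _rates_from_lifetimes(lifetimes) -> np.ndarray:
    tau = np.asarray(lifetimes, dtype=float)
    if np.any(tau <= 0):
        raise ValueError("lifetimes must be positive")
    k = 1.0 / tau
    # jitter near-degenerate rates so the distinct-rate Bateman form applies
    for i in range(1, k.size):
        for j in range(i):
            if abs(k[i] - k[j]) < DEGENERACY_RTOL * max(abs(k[i]), abs(k[j])):
                k[i] *= 1.0 + DEGENERACY_JITTER
    return k


def bateman_coefficients(lifetimes) -> np.ndarray:
    """Lower-triangular matrix A with c_m(t) = sum_l A[m, l] exp(-k_l t).

    Closed-form coefficients of the unidirectional chain with unit initial
    population in the first compartment and terminal decay to ground.
    """
    k = _rates_from_lifetimes(lifetimes)
    n = k.size
    a = np.zeros((n, n))
    for m in range(n):
        prefactor = np.prod(k[:m])
        for l in range(m + 1):
            denom = np.prod([k[j] - k[l] for j in range(m + 1) if j != l])
            a[m, l] = prefactor / denom if m else 1.0
    return a


def bateman_concentrations(lifetimes, times) -> np.ndarray:
    """Sequential-scheme concentration profiles, shape (n_components, n_times)."""
    t = np.asarray(times, dtype=float)
    k = _rates_from_lifetimes(lifetimes)
    a = bateman_coefficients(1.0 / k)
    decays = np.exp(-np.outer(k, t))
    return a @ decays


def svd_truncate(data: TimeResolvedSpectra, n: int | None = None):
    """Best rank-n approximation of the (masked) data matrix.

    With ``n=None`` the rank is chosen automatically: the smallest n that
    either captures 99.9% of the squared singular values or whose first
    discarded temporal vector already looks like noise (lag-1 autocorrelation
    below 0.5) — under measurement noise the cumulative-energy criterion
    alone would absorb arbitrarily many noise components.

    Returns ``(u, s, vt, rank_estimate)`` for the truncated decomposition.
    """
    m = data.delta_a[data.mask()]
    if not np.all(np.isfinite(m)):
        raise ValueError("data matrix contains non-finite values")
    u, s, vt = np.linalg.svd(m, full_matrices=False)
    max_rank = int(np.sum(s > s[0] * 1e-12)) if s.size else 0
    if n is not None:
        if n > max_rank:
            raise ValueError(f"requested rank {n} exceeds matrix rank {max_rank}")
        rank = n
    else:
        total = np.sum(s**2)
        cum = np.cumsum(s**2) / total
        rank = max_rank
        for i in range(1, max_rank + 1):
            if cum[i - 1] >= 0.999 or (i < s.size and _lag1_autocorr(vt[i]) < 0.5):
                rank = i
                break
    return u[:, :rank], s[:rank], vt[:rank], rank


def _lag1_autocorr(v: np.ndarray) -> float:
    v = v - v.mean()
    denom = np.dot(v, v)
    if denom == 0:
        return 0.0
    return float(np.dot(v[:-1], v[1:]) / denom)


class SequentialSpectralModel:
    """Sequential (unidirectional chain) global model for a spectral dataset.

    The model is ``dA(x, t) = sum_i EADS_i(x) * c_i(t; tau)`` with c the
    Bateman concentrations.  ``fit`` optimizes the lifetimes by trust-region
    least squares in log10-lifetime space; the EADS are projected out exactly
    at each iterate (variable projection).
    """

    def __init__(self, data: TimeResolvedSpectra, n_components: int):
        if n_components < 1:
            raise ValueError("n_components must be >= 1")
        self.data = data
        self.n_components = n_components
        keep = data.mask()
        self._matrix = data.delta_a[keep]
        self._axis = data.axis_values[keep]
        _, _, _, self._svd_rank = svd_truncate(data)
        if n_components > self._svd_rank:
            import warnings

            warnings.warn(
                f"n_components={n_components} exceeds the estimated SVD rank "
                f"{self._svd_rank}; amplitudes may be ill-determined",
                stacklevel=2,
            )

    def _amplitudes(self, log10_tau: np.ndarray):
        """Exact linear solve for EADS given lifetimes; returns (eads, resid)."""
        c = bateman_concentrations(10.0**log10_tau, self.data.times)
        # least squares over the time dimension for all axis rows at once
        eads, *_ = np.linalg.lstsq(c.T, self._matrix.T, rcond=None)
        resid = self._matrix - eads.T @ c
        return eads.T, resid

    def fit(self, tau_init, xtol: float = 1e-14, ftol: float = 1e-14) -> SequentialFitResult:
        tau_init = np.sort(np.asarray(tau_init, dtype=float))
        if tau_init.size != self.n_components:
            raise ValueError("tau_init length must equal n_components")
        if np.any(tau_init <= 0):
            raise ValueError("tau_init must be positive")
        x0 = np.log10(tau_init)

        def residual(x):
            return self._amplitudes(x)[1].ravel()

        sol = least_squares(residual, x0, method="trf", xtol=xtol, ftol=ftol, gtol=1e-14)
        order = np.argsort(sol.x)
        tau = np.sort(10.0**sol.x)
        eads, resid = self._amplitudes(np.log10(tau))
        rms = float(np.sqrt(np.mean(resid**2)))
        rms0 = float(np.sqrt(np.mean(self._amplitudes(x0)[1] ** 2)))
        converged = bool(sol.status > 0) and rms <= rms0 + 1e-15
        dads = eads_dads_transform(eads, tau, direction="eads->dads")
        del order
        return SequentialFitResult(
            lifetimes=tau,
            dads=dads,
            eads=eads,
            residual_rms=rms,
            n_svd_components=self._svd_rank,
            converged=converged,
            axis_values=self._axis,
            model=self,
        )


def global_fit_sequential(
    data: TimeResolvedSpectra, n_components: int, tau_init
) -> SequentialFitResult:
    """Sequential-model global lifetime fit (see SequentialSpectralModel)."""
    return SequentialSpectralModel(data, n_components).fit(tau_init)


def eads_dads_transform(spectra: np.ndarray, lifetimes, direction: str) -> np.ndarray:
    """Convert between EADS and DADS amplitude representations.

    The sequential concentrations are linear combinations of pure
    exponentials, ``C(t) = A @ exp(-k t)`` with A the Bateman coefficient
    matrix, so ``DADS = EADS @ A`` and ``EADS = DADS @ inv(A)``.  The round
    trip is the identity.
    """
    spectra = np.asarray(spectra, dtype=float)
    lifetimes = np.asarray(lifetimes, dtype=float)
    if spectra.shape[1] != lifetimes.size:
        raise ValueError("component count must match lifetime count")
    a = bateman_coefficients(lifetimes)
    if direction in ("eads->dads", "eads→dads"):
        return spectra @ a
    if direction in ("dads->eads", "dads→eads"):
        return spectra @ np.linalg.inv(a)
    raise ValueError(f"unknown direction {direction!r}")


def ftir_kinetic_decomposition(
    data: TimeResolvedSpectra,
    n: int = 2,
    tau_init=None,
    with_offset: bool = False,
):
    """SVD-plus-rotation kinetic decomposition of an FTIR difference series.

    The data matrix is truncated to rank ``n``; the retained temporal right
    vectors are fitted globally with a shared sum of ``n`` exponentials
    (optionally plus a constant for continuous-illumination plateaus), and
    the spectral left vectors are rotated by the fitted amplitude matrix into
    kinetic component spectra (fast component first).

    Returns ``(component_spectra, time_constants, amplitudes)`` where
    ``component_spectra`` has shape (n_axis_kept, n) and
    ``data ~= component_spectra @ exp(-t / tau)``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    try:
        u, s, vt, _ = svd_truncate(data, n)
    except ValueError:
        # deficient data (e.g. rank-1 input with n=2): keep what exists; the
        # surplus exponentials fit with near-zero amplitude
        u, s, vt, _ = svd_truncate(data, None)
    t = data.times
    if tau_init is None:
        # spread initial guesses over the observed decades
        tau_init = np.geomspace(max(t[t > 0].min(), 1e-12) * 3, t.max() / 3, n)
    tau_init = np.asarray(tau_init, dtype=float)

    n_basis = n + (1 if with_offset else 0)

    def basis(log10_tau):
        b = np.exp(-np.outer(1.0 / (10.0**log10_tau), t))
        if with_offset:
            b = np.vstack([b, np.ones_like(t)])
        return b

    sv = (s[:, None]) * vt  # weighted temporal vectors, shape (n, n_times)

    def residual(x):
        b = basis(x)
        amps, *_ = np.linalg.lstsq(b.T, sv.T, rcond=None)
        return (sv - amps.T @ b).ravel()

    sol = least_squares(residual, np.log10(tau_init), method="trf", xtol=1e-14, ftol=1e-14)
    tau = 10.0**sol.x
    order = np.argsort(tau)
    tau = tau[order]
    b = basis(np.log10(tau) if not with_offset else sol.x[np.argsort(sol.x)])
    # rebuild basis with sorted taus (offset column stays last)
    b = np.exp(-np.outer(1.0 / tau, t))
    if with_offset:
        b = np.vstack([b, np.ones_like(t)])
    amps, *_ = np.linalg.lstsq(b.T, sv.T, rcond=None)  # (n_basis, n_svd)
    component_spectra = u @ amps.T  # (n_axis_kept, n_basis)
    del n_basis
    return component_spectra, tau, amps.T
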