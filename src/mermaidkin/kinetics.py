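"""Single-photocycle kinetic model for light-gated ion channels.

A channelrhodopsin photocycle is modelled as a continuous-time Markov chain
over a small set of spectroscopic states (dark state D, early K intermediate,
conducting L state, desensitized M state).  Light drives the ground state into
the cycle with a rate proportional to intensity; all other transitions are
thermal and first order.  Under a piecewise-constant light protocol the master
equation is linear with a piecewise-constant generator, so occupancies are
propagated exactly by matrix exponentials segment by segment.

Photocurrent follows ohmically from the occupancy of the conducting state(s):
``I(t) = g * f_open(t) * (V - E_rev)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm, null_space

__all__ = [
    "KineticScheme",
    "LightProtocol",
    "OccupancyTrajectory",
    "PhotocurrentTrace",
    "propagate",
    "steady_state",
    "current_from_occupancy",
    "double_pulse_recovery",
    "discretize_ramp",
]


@dataclass(frozen=True)
class KineticScheme:
    """States and rate constants of a photocycle.

    Parameters
    ----------
    state_names : tuple of str
        Ordered state labels, e.g. ``("D", "K", "L", "M")``.
    conducting_mask : tuple of bool
        Which states carry current (the open state L in the canonical cycle).
    ground_state : str
        The dark-adapted state that absorbs light.
    photo_rates : dict
        ``(from, to) -> sigma`` light-driven coefficients; the transition rate
        is ``sigma * intensity`` (intensity in arbitrary units).
    thermal_rates : dict
        ``(from, to) -> k`` first-order thermal rates in 1/s.
    """

    state_names: tuple
    conducting_mask: tuple
    ground_state: str
    photo_rates: dict = field(default_factory=dict)
    thermal_rates: dict = field(default_factory=dict)

    def __post_init__(self):
        names = tuple(self.state_names)
        object.__setattr__(self, "state_names", names)
        object.__setattr__(self, "conducting_mask", tuple(bool(c) for c in self.conducting_mask))
        if len(names) != len(set(names)):
            raise ValueError("duplicate state names")
        if len(self.conducting_mask) != len(names):
            raise ValueError("conducting_mask length must match state_names")
        if self.ground_state not in names:
            raise ValueError(f"unknown ground state {self.ground_state!r}")
        for rates, kind in ((self.photo_rates, "photo"), (self.thermal_rates, "thermal")):
            for (a, b), k in rates.items():
                if a not in names or b not in names:
                    raise ValueError(f"unknown state in {kind} rate {a!r}->{b!r}")
                if a == b:
                    raise ValueError(f"self-transition {a!r}->{b!r}")
                if k < 0:
                    raise ValueError(f"negative {kind} rate {a!r}->{b!r}")

    @property
    def n_states(self) -> int:
        return len(self.state_names)

    def index(self, name: str) -> int:
        return self.state_names.index(name)

    def generator(self, intensity: float) -> np.ndarray:
        """Master-equation generator G at the given light intensity.

        ``dp/dt = G p`` with ``G[i, j]`` the rate j -> i for i != j; columns
        sum to zero so total population is conserved.
        """
        if intensity < 0:
            raise ValueError("negative light intensity")
        n = self.n_states
        g = np.zeros((n, n))
        for (a, b), k in self.thermal_rates.items():
            g[self.index(b), self.index(a)] += k
        for (a, b), s in self.photo_rates.items():
            g[self.index(b), self.index(a)] += s * intensity
        g[np.diag_indices(n)] -= g.sum(axis=0)
        return g

    def photo_target(self) -> str:
        """The state populated directly from the ground state by light."""
        targets = [b for (a, b) in self.photo_rates if a == self.ground_state]
        if len(targets) != 1:
            raise ValueError("ground state must have exactly one photo transition")
        return targets[0]

    @property
    def conducting_indices(self) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.conducting_mask))


@dataclass(frozen=True)
class LightProtocol:
    """Piecewise-constant illumination plus an optional instantaneous flash.

    ``segments`` is an ordered list of ``(t_start, t_end, intensity)`` with
    non-overlapping intervals; intensity is zero outside all segments.
    ``delta_flash`` is ``(time, excited_fraction)``: at that instant the given
    fraction of the ground-state population is promoted to the first
    post-excitation state (single-turnover ns-laser idealization).
    """

    segments: tuple = ()
    delta_flash: tuple | None = None

    def __post_init__(self):
        segs = tuple((float(a), float(b), float(i)) for a, b, i in self.segments)
        object.__setattr__(self, "segments", segs)
        prev_end = -np.inf
        for a, b, i in segs:
            if b <= a:
                raise ValueError(f"segment ({a}, {b}) has t_end <= t_start")
            if a < prev_end:
                raise ValueError("segments overlap or are out of order")
            if i < 0:
                raise ValueError("negative light intensity")
            prev_end = b
        if self.delta_flash is not None:
            t, f = self.delta_flash
            if not 0.0 <= f <= 1.0:
                raise ValueError("excited_fraction must lie in [0, 1]")
            object.__setattr__(self, "delta_flash", (float(t), float(f)))

    def intensity_at(self, t: float) -> float:
        for a, b, i in self.segments:
            if a <= t < b:
                return i
        return 0.0

    def breakpoints(self) -> list:
        pts = set()
        for a, b, _ in self.segments:
            pts.update((a, b))
        if self.delta_flash is not None:
            pts.add(self.delta_flash[0])
        return sorted(pts)


@dataclass(frozen=True)
class OccupancyTrajectory:
    """State occupancies over time; rows of ``occupancy`` sum to one."""

    times: np.ndarray
    occupancy: np.ndarray  # (n_times, n_states)
    state_names: tuple

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        p = np.asarray(self.occupancy, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "occupancy", p)
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if p.shape != (t.size, len(self.state_names)):
            raise ValueError("occupancy shape mismatch")
        if np.any(p < -1e-9) or np.any(np.abs(p.sum(axis=1) - 1.0) > 1e-9):
            raise ValueError("occupancies must be non-negative and sum to 1")

    def state(self, name: str) -> np.ndarray:
        return self.occupancy[:, self.state_names.index(name)]

    def conducting(self, scheme: KineticScheme) -> np.ndarray:
        return self.occupancy[:, scheme.conducting_indices].sum(axis=1)


@dataclass
class PhotocurrentTrace:
    """A voltage-clamp photocurrent recording (or simulation thereof).

    Inward current is negative, matching standard whole-cell convention.
    """

    times: np.ndarray  # s
    current: np.ndarray  # pA
    voltage: float  # mV, command potential (LJP-corrected)
    e_rev: float  # mV
    light_window: tuple  # (on, off) in s
    conductance_scale: float = 1.0  # pA/mV, lumped N*g
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.current = np.asarray(self.current, dtype=float)
        if self.times.shape != self.current.shape:
            raise ValueError("times and current must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        on, off = self.light_window
        if not (self.times[0] <= on < off <= self.times[-1] + 1e-12):
            raise ValueError("light_window must lie inside the time range")


def _segment_bounds(protocol: LightProtocol, t0: float, t1: float) -> list:
    """Split [t0, t1] at every protocol breakpoint."""
    cuts = [t0] + [b for b in protocol.breakpoints() if t0 < b < t1] + [t1]
    return [(cuts[i], cuts[i + 1]) for i in range(len(cuts) - 1)]


def _propagate_constant(g: np.ndarray, p0: np.ndarray, dts: np.ndarray) -> np.ndarray:
    """Propagate p0 under constant generator g for each dt (exactly).

    Uses the eigendecomposition when well conditioned, otherwise falls back to
    scipy's expm per time point (generators of small photocycles are rarely
    defective, but degenerate rates can make them so).
    """
    out = np.empty((dts.size, p0.size))
    try:
        w, v = np.linalg.eig(g)
        vinv = np.linalg.inv(v)
        if np.linalg.cond(v) < 1e10:
            c = vinv @ p0
            out[:] = np.real((np.exp(np.outer(dts, w)) * c) @ v.T)
            return out
    except np.linalg.LinAlgError:
        pass
    for i, dt in enumerate(dts):
        out[i] = expm(g * dt) @ p0
    return out


def propagate(scheme: KineticScheme, protocol: LightProtocol, grid) -> OccupancyTrajectory:
    """Solve the master equation on ``grid`` under the given light protocol.

    The initial condition places all population in the ground state at the
    first grid time; a ``delta_flash`` instantaneously moves its
    ``excited_fraction`` of the ground-state population to the photo target.
    Within each constant-intensity interval the solution is the exact
    matrix-exponential propagation of that interval's generator.
    """
    t = np.asarray(grid, dtype=float)
    if t.ndim != 1 or t.size < 1 or np.any(np.diff(t) <= 0):
        raise ValueError("grid must be 1-D and strictly increasing")
    n = scheme.n_states
    p = np.zeros(n)
    p[scheme.index(scheme.ground_state)] = 1.0

    flash = protocol.delta_flash
    out = np.empty((t.size, n))
    if flash is not None and flash[0] <= t[0]:
        p = _apply_flash(scheme, p, flash[1])
        flash = None
    out[0] = p
    # constant-generator spans: one eigendecomposition each, all grid times
    # inside a span propagated in a single vectorized call
    for a, b in _segment_bounds(protocol, t[0], t[-1]):
        if flash is not None and a >= flash[0]:
            p = _apply_flash(scheme, p, flash[1])
            flash = None
        g = scheme.generator(protocol.intensity_at(a))
        lo = np.searchsorted(t, a, side="right")
        hi = np.searchsorted(t, b, side="right")
        if hi > lo:
            out[lo:hi] = _propagate_constant(g, p, t[lo:hi] - a)
        p = out[hi - 1] if hi > lo and t[hi - 1] == b else _propagate_constant(
            g, p, np.array([b - a])
        )[0]
    # clip tiny negative round-off before invariant checks
    out = np.clip(out, 0.0, None)
    out /= out.sum(axis=1, keepdims=True)
    return OccupancyTrajectory(times=t, occupancy=out, state_names=scheme.state_names)


def _apply_flash(scheme: KineticScheme, p: np.ndarray, fraction: float) -> np.ndarray:
    p = p.copy()
    ig = scheme.index(scheme.ground_state)
    it = scheme.index(scheme.photo_target())
    moved = fraction * p[ig]
    p[ig] -= moved
    p[it] += moved
    return p


def steady_state(scheme: KineticScheme, intensity: float) -> np.ndarray:
    """Stationary occupancy under constant light: the null space of G.

    At zero intensity the ground state is absorbing for the packaged cycles
    and the stationary distribution is the ground-state point mass.
    """
    g = scheme.generator(intensity)
    ns = null_space(g, rcond=1e-12)
    if ns.shape[1] == 0:
        raise ValueError("generator has no stationary distribution")
    if ns.shape[1] > 1:
        # reducible chain (e.g. dark, no photoactivation): the reachable
        # stationary state from the ground state is the ground point mass
        # when the ground state itself is absorbing.
        col = g[:, scheme.index(scheme.ground_state)]
        if np.allclose(col, 0.0):
            p = np.zeros(scheme.n_states)
            p[scheme.index(scheme.ground_state)] = 1.0
            return p
        raise ValueError("stationary distribution is not unique")
    p = ns[:, 0]
    if p.sum() < 0:
        p = -p
    if np.any(p < -1e-10):
        raise ValueError("null-space vector is not a probability distribution")
    p = np.clip(p, 0.0, None)
    return p / p.sum()


def current_from_occupancy(
    traj: OccupancyTrajectory,
    scheme: KineticScheme,
    voltage: float,
    e_rev: float,
    conductance_scale: float,
    light_window: tuple | None = None,
) -> PhotocurrentTrace:
    """Ohmic conversion of conducting-state occupancy to photocurrent.

    ``I(t) = conductance_scale * f_open(t) * (V - E_rev)`` in pA for V, E_rev
    in mV and conductance_scale in pA/mV.
    """
    if conductance_scale < 0:
        raise ValueError("conductance_scale must be >= 0")
    f_open = traj.conducting(scheme)
    current = conductance_scale * f_open * (voltage - e_rev)
    if light_window is None:
        light_window = (traj.times[0], traj.times[-1])
    return PhotocurrentTrace(
        times=traj.times,
        current=current,
        voltage=voltage,
        e_rev=e_rev,
        light_window=light_window,
        conductance_scale=conductance_scale,
        metadata={
            "voltage_mV": voltage,
            "e_rev_mV": e_rev,
            "conductance_scale_pA_per_mV": conductance_scale,
            "light_on_s": light_window[0],
            "light_off_s": light_window[1],
        },
    )


def double_pulse_recovery(
    scheme: KineticScheme,
    pulse_duration: float,
    intensity: float,
    intervals,
    dt: float = 1e-4,
) -> tuple:
    """Peak-recovery ratios from a paired-pulse protocol.

    Two identical light pulses separated by a dark interval; returns for each
    interval the ratio (second conducting-occupancy peak)/(first peak).  Full
    dark recovery drives the ratio to one; the time course of the ratio is
    dominated by repopulation of the dark state from the desensitized state.
    """
    intervals = np.asarray(intervals, dtype=float)
    if intervals.size == 0:
        raise ValueError("empty interval list")
    if np.any(intervals <= 0):
        raise ValueError("intervals must be positive")
    ratios = []
    n_pulse = max(int(round(pulse_duration / dt)), 50)
    for gap in intervals:
        protocol = LightProtocol(
            segments=(
                (0.0, pulse_duration, intensity),
                (pulse_duration + gap, 2 * pulse_duration + gap, intensity),
            )
        )
        pulse_grid_1 = np.linspace(0.0, pulse_duration, n_pulse + 1)
        pulse_grid_2 = pulse_duration + gap + np.linspace(0.0, pulse_duration, n_pulse + 1)
        grid = np.concatenate([pulse_grid_1, [pulse_duration + gap * 0.5], pulse_grid_2])
        traj = propagate(scheme, protocol, grid)
        f = traj.conducting(scheme)
        first = f[: n_pulse + 1].max()
        second = f[n_pulse + 2 :].max()
        ratios.append(second / first)
    return intervals, np.asarray(ratios)


def discretize_ramp(t_start: float, t_end: float, intensity_fn, step: float = 1e-4) -> LightProtocol:
    """Approximate a smooth intensity ramp by 0.1 ms piecewise-constant steps.

    ``intensity_fn`` is evaluated at each step midpoint.  Exact propagation
    applies to the discretized protocol, not the underlying ramp.
    """
    edges = np.arange(t_start, t_end, step)
    edges = np.append(edges, t_end)
    segs = []
    for a, b in zip(edges[:-1], edges[1:]):
        segs.append((a, b, float(intensity_fn(0.5 * (a + b)))))
    return LightProtocol(segments=tuple(segs))
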