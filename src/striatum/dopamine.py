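"""Mean-field extracellular dopamine dynamics in a striatal subvolume.

Dopamine in a mesoscopic subvolume (~10^3 model volume units holding ~100
terminals when innervation is healthy) follows a deterministic mean-field
balance between impulse-driven release and Michaelis-Menten reuptake:

    dM/dt = Delta * nu * N  -  V_M * N * M / (K_M + M)

where ``M`` is the extracellular DA concentration (uM), ``Delta`` the DA
released per impulse per terminal, ``nu`` the firing frequency (Hz), ``N``
the number of terminals in the subvolume and ``V_M``/``K_M`` the uptake
parameters.  Enzymatic degradation (epsilon) and diffusion between
subvolumes are negligible wherever terminals are present; a subvolume with
``N = 0`` keeps only the degradation term, dM/dt = -epsilon*M, and receives
no dopamine at all.

Firing switches between three regimes: pauses (0 Hz), tonic (4 Hz) and
phasic bursts (20 Hz).  The closed-form steady state

    M* = K_M * Delta*nu / (V_M - Delta*nu)

is independent of N; denervation therefore leaves the tonic plateau intact
and instead slows the *transients* (relaxation rate scales with N), which is
what degrades phasic peaks and pause clearance downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .geometry import ArborNetwork

__all__ = [
    "TERMINAL_DENSITY_PER_MM3",
    "SUBVOLUME_MM3",
    "HEALTHY_TERMINAL_COUNT",
    "DAParams",
    "FiringProtocol",
    "DATrace",
    "default_protocol",
    "steady_state_da",
    "simulate_da",
    "local_terminal_count",
    "healthy_mean_cover",
]

# Mean-field bookkeeping: ~0.1 terminals per unit volume times a 10^3-unit
# subvolume gives 100 terminals per healthy subvolume.
TERMINAL_DENSITY_PER_MM3 = 0.1
SUBVOLUME_MM3 = 1.0e3
HEALTHY_TERMINAL_COUNT = TERMINAL_DENSITY_PER_MM3 * SUBVOLUME_MM3

TONIC_HZ = 4.0
PHASIC_HZ = 20.0
PAUSE_HZ = 0.0
ALLOWED_FREQUENCIES = (PAUSE_HZ, TONIC_HZ, PHASIC_HZ)


@dataclass(frozen=True)
class DAParams:
    """Kinetic constants of the mean-field DA equation.

    Defaults are calibrated to standard physiological plateaus (tonic
    ~37 nM, phasic ~0.63 uM): delta_release 1.5e-3 uM per impulse per
    terminal, v_uptake 0.04 uM/s per terminal, k_m 0.21 uM, epsilon 0.05 /s.
    """

    delta_release: float = 1.5e-3  # uM per impulse per terminal
    v_uptake: float = 0.04  # uM/s per terminal
    k_m: float = 0.21  # uM
    epsilon: float = 0.05  # 1/s
    diffusion: float = 0.0  # mm^2/s; dropped in well-innervated regions

    def __post_init__(self) -> None:
        for name in ("delta_release", "v_uptake", "k_m", "epsilon", "diffusion"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class FiringProtocol:
    """Ordered (duration_s, frequency_Hz) segments of SNc firing."""

    segments: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("protocol needs at least one segment")
        for dur, freq in self.segments:
            if dur <= 0:
                raise ValueError("segment durations must be > 0")
            if freq not in ALLOWED_FREQUENCIES:
                raise ValueError(
                    f"frequency {freq} Hz not in the pause/tonic/phasic set "
                    f"{ALLOWED_FREQUENCIES}"
                )

    @property
    def total_duration(self) -> float:
        return sum(d for d, _ in self.segments)

    @property
    def boundaries(self) -> np.ndarray:
        return np.concatenate([[0.0], np.cumsum([d for d, _ in self.segments])])

    def frequency_at(self, t: float) -> float:
        edges = self.boundaries
        i = int(np.clip(np.searchsorted(edges, t, side="right") - 1, 0, len(self.segments) - 1))
        return self.segments[i][1]

    def _window(self, freq: float) -> tuple[float, float]:
        edges = self.boundaries
        for i, (_, f) in enumerate(self.segments):
            if f == freq:
                return float(edges[i]), float(edges[i + 1])
        raise ValueError(f"protocol has no {freq} Hz segment")

    def phasic_window(self) -> tuple[float, float]:
        """(t0, t1) of the first 20 Hz segment."""
        return self._window(PHASIC_HZ)

    def pause_window(self) -> tuple[float, float]:
        """(t0, t1) of the first 0 Hz segment."""
        return self._window(PAUSE_HZ)


def default_protocol(
    tonic_s: float = 3.0, phasic_s: float = 0.5, pause_s: float = 0.5
) -> FiringProtocol:
    """Tonic -> phasic burst -> tonic -> pause -> tonic (10 s total with the
    default durations)."""
    return FiringProtocol(
        (
            (tonic_s, TONIC_HZ),
            (phasic_s, PHASIC_HZ),
            (tonic_s, TONIC_HZ),
            (pause_s, PAUSE_HZ),
            (tonic_s, TONIC_HZ),
        )
    )


def steady_state_da(params: DAParams, frequency: float) -> float:
    """Closed-form steady state K_M * Delta*nu / (V_M - Delta*nu).

    Independent of the terminal count N (N multiplies release and uptake
    alike).  Requires Delta*nu < V_M; beyond that release outpaces the
    maximal uptake and no finite steady state exists.
    """
    drive = params.delta_release * frequency
    if drive >= params.v_uptake:
        raise ValueError(
            "uptake capacity exceeded: delta_release * frequency >= v_uptake"
        )
    return params.k_m * drive / (params.v_uptake - drive)


@dataclass
class DATrace:
    """DA concentration time course for one subvolume."""

    times: np.ndarray  # s
    m: np.ndarray  # uM
    protocol: FiringProtocol
    n_terminals: float

    def interp(self, t: np.ndarray) -> np.ndarray:
        return np.interp(t, self.times, self.m)


def _initial_da(params: DAParams, protocol: FiringProtocol, n_terminals: float) -> float:
    """Steady state of the first protocol segment; if release exceeds uptake
    capacity there (possible under strong release compensation) fall back to
    a long pre-equilibration integration."""
    if n_terminals <= 0:
        return 0.0
    freq = protocol.segments[0][1]
    try:
        return steady_state_da(params, freq)
    except ValueError:
        warm = FiringProtocol(((30.0, freq),))
        trace = simulate_da(params, warm, n_terminals, m0=0.0)
        return float(trace.m[-1])


def simulate_da(
    params: DAParams,
    protocol: FiringProtocol,
    n_terminals: float,
    m0: float | None = None,
    dt_out: float = 1.0e-3,
    rtol: float = 1.0e-8,
) -> DATrace:
    """Integrate the mean-field DA equation through a firing protocol.

    Output on a uniform grid of ``dt_out`` seconds.  ``m0`` defaults to the
    steady state of the first segment (0 for a terminal-free subvolume,
    which then evolves by pure epsilon-decay).
    """
    if n_terminals < 0:
        raise ValueError("n_terminals must be >= 0")
    if m0 is None:
        m0 = _initial_da(params, protocol, n_terminals)
    if m0 < 0:
        raise ValueError("m0 must be >= 0")

    times_all = [np.array([0.0])]
    m_all = [np.array([m0])]
    edges = protocol.boundaries
    m_cur = float(m0)
    for (dur, freq), t0 in zip(protocol.segments, edges[:-1]):
        n_pts = max(2, int(round(dur / dt_out)) + 1)
        t_eval = np.linspace(0.0, dur, n_pts)
        if n_terminals > 0:
            drive = params.delta_release * freq * n_terminals
            vn = params.v_uptake * n_terminals

            def rhs(_t, y, drive=drive, vn=vn):
                m = max(y[0], 0.0)
                return [drive - vn * m / (params.k_m + m)]

        else:

            def rhs(_t, y):
                return [-params.epsilon * max(y[0], 0.0)]

        sol = solve_ivp(
            rhs,
            (0.0, dur),
            [m_cur],
            method="LSODA",
            t_eval=t_eval,
            rtol=rtol,
            atol=1.0e-12,
        )
        if not sol.success:  # pragma: no cover
            raise RuntimeError(f"DA integration failed: {sol.message}")
        m_seg = np.clip(sol.y[0], 0.0, None)
        times_all.append(t0 + t_eval[1:])
        m_all.append(m_seg[1:])
        m_cur = float(m_seg[-1])
    return DATrace(
        np.concatenate(times_all), np.concatenate(m_all), protocol, n_terminals
    )


def healthy_mean_cover(
    network: ArborNetwork, n_points: int = 10_000, seed: int | None = 0
) -> float:
    """Mean number of arbors (alive or dead) covering a uniform random point
    of the striatum — the healthy-state coverage used to convert arbor cover
    into terminal counts."""
    rng = np.random.default_rng(seed)
    pts = network.config.ellipsoid.sample_points(n_points, rng)
    counts = _cover_counts(network, pts, use_all=True)
    return float(counts.mean())


def _cover_counts(
    network: ArborNetwork, points: np.ndarray, use_all: bool = False
) -> np.ndarray:
    """Number of (live) arbors whose sphere contains each point."""
    from scipy.spatial import cKDTree

    pts = np.atleast_2d(np.asarray(points, dtype=float))
    ids = np.arange(network.n_arbors) if use_all else network.live_ids
    if len(ids) == 0:
        return np.zeros(len(pts), dtype=np.int64)
    centers = network.centers[ids]
    radii = network.radii[ids]
    tree = cKDTree(centers)
    r_max = radii.max()
    counts = np.zeros(len(pts), dtype=np.int64)
    if np.ptp(radii) == 0:
        neigh = tree.query_ball_point(pts, r_max, return_length=True)
        counts[:] = neigh
    else:
        for i, p in enumerate(pts):
            idx = tree.query_ball_point(p, r_max)
            if idx:
                d = np.linalg.norm(centers[idx] - p, axis=1)
                counts[i] = int(np.sum(d < radii[idx]))
    return counts


def local_terminal_count(
    network: ArborNetwork,
    points: np.ndarray,
    mean_cover: float | None = None,
) -> np.ndarray:
    """Effective terminal count N at each point.

    N = (live arbors covering the point) * (100 / healthy mean arbor cover),
    calibrated so the healthy-network spatial mean is the bookkeeping value
    of 100 terminals per subvolume.  ``mean_cover`` may be precomputed with
    :func:`healthy_mean_cover` to avoid resampling.
    """
    if mean_cover is None:
        mean_cover = healthy_mean_cover(network)
    counts = _cover_counts(network, points)
    return counts * (HEALTHY_TERMINAL_COUNT / mean_cover)
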