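"""Stochastic denervation of the arbor network via the Gillespie algorithm.

Three mechanisms of progressive dopaminergic neuron loss are simulated as
continuous-time death processes:

RD (random denervation)
    Every live neuron dies at the same rate; deaths are spatially uniform.

PLD (prion-like denervation)
    One neuron is initially infected.  Only infected neurons can die; when
    one dies (picked uniformly, since all infected share the same rate) it
    first infects the two nearest living uninfected neurons whose arbors are
    in physical contact with its own (center distance below the sum of the
    two arbor radii), modeling the cell-to-cell spread of pathological
    protein aggregates through overlapping axonal territories.  The
    infection therefore advances as a compact wave.  If the infected set
    ever burns out while neurons remain, a fresh random neuron is seeded.

SID (stress-induced denervation)
    Neuron i dies at rate base_rate / (1 + exp((k_i - midpoint)/slope)),
    where k_i is its number of overlapping neighbors in the healthy network.
    Sparse neurons, presumed to fire harder to compensate for weak local
    coverage, die fast; densely embedded neurons are strongly protected.
    The resulting survival curve is a mixture of exponentials, hence
    decelerating (stretching exponent c < 1).

All three yield a :class:`DenervationTrajectory` — an ordered record of
Gillespie event times — from which survival curves, stretched-exponential
fits N(t) = N0*exp(-b t^c), largest-CAC breakdown curves and tipping points
are extracted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from scipy.spatial import cKDTree

from .geometry import ArborNetwork, contiguous_arbor_classes, overlap_pairs

__all__ = [
    "DenervationParams",
    "DenervationTrajectory",
    "StretchedExpFit",
    "simulate_denervation",
    "snapshot",
    "survival_curve",
    "fit_stretched_exponential",
    "largest_cac_curve",
    "tipping_point",
    "sid_rate",
]

CAUSE_DEATH = 0
CAUSE_INFECTION = 1


@dataclass(frozen=True)
class DenervationParams:
    """Parameters of a denervation mechanism.

    Time is in arbitrary units; ``base_rate`` = 1 defines the clock.  The SID
    sigmoid midpoint/slope are calibrated so that, with the default geometry
    (healthy mean neighbor count ~11), sparse neurons die near the base rate
    while densely embedded neurons are strongly protected.
    """

    model: str = "rd"  # rd | pld | sid
    base_rate: float = 1.0
    sid_midpoint: float = 9.0
    sid_slope: float = 1.0
    pld_branching: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in ("rd", "pld", "sid"):
            raise ValueError(f"unknown denervation model {self.model!r}")
        if self.base_rate <= 0:
            raise ValueError("base_rate must be > 0")
        if self.sid_slope <= 0:
            raise ValueError("sid_slope must be > 0")


def sid_rate(
    n_neighbors: np.ndarray | float, params: DenervationParams
) -> np.ndarray | float:
    """Sigmoidal death rate: ~base_rate with no neighbors, ~0 when densely
    embedded."""
    k = np.asarray(n_neighbors, dtype=float)
    return params.base_rate / (1.0 + np.exp((k - params.sid_midpoint) / params.sid_slope))


@dataclass
class DenervationTrajectory:
    """Ordered Gillespie events on a network.

    ``times``/``ids``/``causes`` cover death and (for PLD) infection events.
    Death times are strictly increasing; an infection shares the Gillespie
    time of the death event that triggered it.
    """

    network: ArborNetwork
    times: np.ndarray
    ids: np.ndarray
    causes: np.ndarray
    params: DenervationParams

    @property
    def death_mask(self) -> np.ndarray:
        return self.causes == CAUSE_DEATH

    @property
    def death_times(self) -> np.ndarray:
        return self.times[self.death_mask]

    @property
    def death_order(self) -> np.ndarray:
        return self.ids[self.death_mask]

    @property
    def n_deaths(self) -> int:
        return int(self.death_mask.sum())


def _simulate_rd(network: ArborNetwork, params: DenervationParams, n_target: int, rng):
    live = network.live_ids
    order = rng.permutation(live)[:n_target]
    n_alive = np.arange(len(live), len(live) - n_target, -1)
    dt = rng.exponential(1.0, size=n_target) / (n_alive * params.base_rate)
    return np.cumsum(dt), order


def _csr_from_pairs(
    n: int, pairs: np.ndarray, dists: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Symmetric CSR adjacency (indptr, indices) with each neighbor list
    sorted by increasing distance."""
    if len(pairs) == 0:
        return np.zeros(n + 1, dtype=np.int64), np.empty(0, dtype=np.int64)
    src = np.concatenate([pairs[:, 0], pairs[:, 1]])
    dst = np.concatenate([pairs[:, 1], pairs[:, 0]])
    dd = np.concatenate([dists, dists])
    order = np.lexsort((dd, src))
    indptr = np.zeros(n + 1, dtype=np.int64)
    np.cumsum(np.bincount(src, minlength=n), out=indptr[1:])
    return indptr, dst[order]


def _overlap_csr(network: ArborNetwork) -> tuple[np.ndarray, np.ndarray]:
    """CSR adjacency of the live <overlap_threshold proximity graph."""
    pairs = overlap_pairs(network)
    d = (
        np.linalg.norm(network.centers[pairs[:, 0]] - network.centers[pairs[:, 1]], axis=1)
        if len(pairs)
        else np.empty(0)
    )
    return _csr_from_pairs(network.n_arbors, pairs, d)


def _contact_csr(network: ArborNetwork) -> tuple[np.ndarray, np.ndarray]:
    """CSR adjacency of the live arbor *contact* graph: arbors touch when
    their center distance is below the sum of their radii."""
    live = network.live_ids
    if len(live) < 2:
        return np.zeros(network.n_arbors + 1, dtype=np.int64), np.empty(0, dtype=np.int64)
    radii = network.radii[live]
    tree = cKDTree(network.centers[live])
    pairs = tree.query_pairs(2.0 * radii.max(), output_type="ndarray")
    d = np.linalg.norm(
        network.centers[live[pairs[:, 0]]] - network.centers[live[pairs[:, 1]]], axis=1
    )
    keep = d < radii[pairs[:, 0]] + radii[pairs[:, 1]]
    return _csr_from_pairs(network.n_arbors, live[pairs[keep]], d[keep])


def _simulate_pld(network: ArborNetwork, params: DenervationParams, n_target: int, rng):
    """Prion-like denervation.

    Only infected neurons die; the dying neuron passes the infection to its
    two nearest living uninfected contacts (arbors physically touching its
    own).  The infection therefore advances as a compact wave, and regions
    swallowed early are almost completely cleared before the front reaches
    distant regions.  If the infected set burns out while uninfected neurons
    remain, a fresh random neuron is seeded.
    """
    indptr, indices = _contact_csr(network)
    live = network.live_ids
    status = np.full(network.n_arbors, 2, dtype=np.int8)  # 0 uninf, 1 inf, 2 dead
    status[live] = 0
    n_uninf = len(live)
    infected: list[int] = []

    times: list[float] = []
    ids: list[int] = []
    causes: list[int] = []
    t = 0.0
    n_dead = 0

    def seed_infection():
        nonlocal n_uninf
        pool = np.flatnonzero(status == 0)
        j = int(pool[rng.integers(len(pool))])
        status[j] = 1
        infected.append(j)
        n_uninf -= 1

    seed_infection()
    while n_dead < n_target:
        if not infected:
            if n_uninf == 0:
                break
            seed_infection()
            continue
        # Gillespie step: all infected share the base death rate
        t += rng.exponential(1.0) / (len(infected) * params.base_rate)
        pick = int(rng.integers(len(infected)))
        j = infected[pick]
        # infect up to `branching` nearest uninfected neighbors (pre-sorted by
        # distance)
        n_found = 0
        for c in indices[indptr[j] : indptr[j + 1]]:
            if status[c] == 0:
                status[c] = 1
                infected.append(int(c))
                n_uninf -= 1
                times.append(t)
                ids.append(int(c))
                causes.append(CAUSE_INFECTION)
                n_found += 1
                if n_found == params.pld_branching:
                    break
        # the chosen neuron dies
        infected[pick] = infected[-1]
        infected.pop()
        status[j] = 2
        n_dead += 1
        times.append(t)
        ids.append(j)
        causes.append(CAUSE_DEATH)
    return np.array(times), np.array(ids, dtype=np.int64), np.array(causes, dtype=np.int8)


def _simulate_sid(network: ArborNetwork, params: DenervationParams, n_target: int, rng):
    """Stress-induced denervation: independent deaths at static rates set by
    the healthy neighbor count.

    With constant per-neuron rates the Gillespie realization is exactly
    equivalent to drawing one exponential death time per neuron and sorting,
    which is how it is sampled here.
    """
    indptr, _ = _overlap_csr(network)
    live = network.live_ids
    k_healthy = np.diff(indptr)[live].astype(float)
    rates = np.asarray(sid_rate(k_healthy, params), dtype=float)
    t_death = rng.exponential(1.0 / rates)
    order = np.argsort(t_death, kind="stable")[:n_target]
    return t_death[order], live[order]


def simulate_denervation(
    network: ArborNetwork,
    params: DenervationParams,
    until_fraction: float = 1.0,
) -> DenervationTrajectory:
    """Run a Gillespie denervation simulation until ``until_fraction`` of the
    initially live neurons are dead (or the network is exhausted)."""
    if network.n_live == 0:
        raise ValueError("network has no live arbors")
    if not 0.0 <= until_fraction <= 1.0:
        raise ValueError("until_fraction must be in [0, 1]")
    rng = np.random.default_rng(params.seed)
    n_target = int(np.floor(until_fraction * network.n_live))
    if params.model == "rd":
        times, order = _simulate_rd(network, params, n_target, rng)
        causes = np.zeros(n_target, dtype=np.int8)
    elif params.model == "sid":
        times, order = _simulate_sid(network, params, n_target, rng)
        causes = np.zeros(n_target, dtype=np.int8)
    else:
        times, order, causes = _simulate_pld(network, params, n_target, rng)
    return DenervationTrajectory(network.copy(), times, order, causes, params)


def snapshot(trajectory: DenervationTrajectory, denervation_fraction: float) -> ArborNetwork:
    """Network state after the first ``floor(fraction * n_live)`` deaths."""
    if not 0.0 <= denervation_fraction <= 1.0:
        raise ValueError("denervation_fraction must be in [0, 1]")
    net = trajectory.network
    n_kill = int(np.floor(denervation_fraction * net.n_live))
    if n_kill > trajectory.n_deaths:
        raise ValueError(
            f"trajectory only reaches {trajectory.n_deaths / net.n_live:.0%} denervation"
        )
    alive = net.alive.copy()
    alive[trajectory.death_order[:n_kill]] = False
    return net.with_alive(alive)


def survival_curve(trajectory: DenervationTrajectory) -> tuple[np.ndarray, np.ndarray]:
    """Stepwise fraction of remaining arbors vs Gillespie time, starting at
    (0, 1.0)."""
    if trajectory.n_deaths == 0:
        raise ValueError("trajectory has no death events")
    n0 = trajectory.network.n_live
    dt = trajectory.death_times
    frac = 1.0 - np.arange(1, len(dt) + 1) / n0
    return np.concatenate([[0.0], dt]), np.concatenate([[1.0], frac])


@dataclass
class StretchedExpFit:
    """Least-squares fit of ln N(t) = ln N0 - b t^c."""

    b: float
    c: float
    log_n0: float
    rss: float

    def predict(self, t: np.ndarray) -> np.ndarray:
        return np.exp(self.log_n0 - self.b * np.asarray(t) ** self.c)


def fit_stretched_exponential(
    times: np.ndarray,
    fraction_remaining: np.ndarray,
    fit_range: tuple[float, float] = (0.02, 0.98),
) -> StretchedExpFit:
    """Fit N(t) = N0 exp(-b t^c) over the part of the survival curve with
    fraction remaining inside ``fit_range`` (end-of-run and t=0 artifacts
    excluded).  Deterministic given the curve."""
    t = np.asarray(times, dtype=float)
    f = np.asarray(fraction_remaining, dtype=float)
    lo, hi = fit_range
    mask = (f > lo) & (f < hi) & (t > 0)
    if mask.sum() < 10:
        raise ValueError("survival curve has fewer than 10 usable points")
    t, f = t[mask], f[mask]
    ln_f = np.log(f)

    def model(tt, log_n0, b, c):
        return log_n0 - b * tt**c

    # initial c from the log-log slope of -ln N vs t
    pos = ln_f < 0
    if pos.sum() >= 2:
        slope, icept = np.polyfit(np.log(t[pos]), np.log(-ln_f[pos]), 1)
        p0 = [0.0, float(np.exp(icept)), float(np.clip(slope, 0.1, 5.0))]
    else:
        p0 = [0.0, 1.0, 1.0]
    popt, _ = curve_fit(
        model,
        t,
        ln_f,
        p0=p0,
        bounds=([-1.0, 1e-12, 1e-3], [1.0, np.inf, 20.0]),
        maxfev=20_000,
    )
    resid = ln_f - model(t, *popt)
    return StretchedExpFit(b=popt[1], c=popt[2], log_n0=popt[0], rss=float(resid @ resid))


def largest_cac_curve(
    trajectory: DenervationTrajectory, levels: np.ndarray
) -> np.ndarray:
    """Fraction of surviving arbors in the largest CAC at each denervation
    level.  An exhausted network contributes 0."""
    levels = np.asarray(levels, dtype=float)
    net = trajectory.network
    n0 = net.n_live
    # precompute healthy proximity pairs once; each level only masks them
    pairs = overlap_pairs(net)
    death_rank = np.full(net.n_arbors, np.iinfo(np.int64).max, dtype=np.int64)
    death_rank[trajectory.death_order] = np.arange(trajectory.n_deaths)
    out = np.empty(len(levels))
    from scipy import sparse
    from scipy.sparse.csgraph import connected_components

    live0 = net.live_ids
    for i, lev in enumerate(levels):
        n_kill = int(np.floor(lev * n0))
        alive_rank = death_rank >= n_kill
        live = live0[alive_rank[live0]]
        n_live = len(live)
        if n_live == 0:
            out[i] = 0.0
            continue
        keep = alive_rank[pairs[:, 0]] & alive_rank[pairs[:, 1]] if len(pairs) else np.empty(0, bool)
        pos = np.full(net.n_arbors, -1, dtype=np.int64)
        pos[live] = np.arange(n_live)
        pp = pairs[keep] if len(pairs) else pairs
        if len(pp):
            g = sparse.coo_matrix(
                (np.ones(len(pp), dtype=np.int8), (pos[pp[:, 0]], pos[pp[:, 1]])),
                shape=(n_live, n_live),
            )
            _, comp = connected_components(g, directed=False)
            out[i] = np.bincount(comp).max() / n_live
        else:
            out[i] = 1.0 / n_live
    return out


def tipping_point(
    levels: np.ndarray, largest_fracs: np.ndarray, threshold: float = 0.5
) -> float | None:
    """Smallest denervation level at which the largest-CAC fraction first
    drops below ``threshold``; None if it never does."""
    levels = np.asarray(levels, dtype=float)
    fr = np.asarray(largest_fracs, dtype=float)
    below = np.flatnonzero(fr < threshold)
    if len(below) == 0:
        return None
    return float(levels[below[0]])
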