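"""End-to-end spatial mapping of SPN activity over the striatum.

The expensive neuron simulations are decoupled from the spatial map: for a
grid of local terminal counts N, the DA -> cAMP -> SPN-firing chain is run
once per grid value (100 noise seeds per neuron model), producing a firing
lookup table.  An activity map then samples 10,000 random points of the
striatum, converts local arbor cover into terminal counts, and interpolates
the lookup — so maps over any denervation snapshot or compensation
mechanism reuse the same per-N simulations.

Compensation enters through the local coverage: each grid N maps to an
arbor cover, the cover to a compensation strength delta, and delta rescales
the DA parameters before the DA/cAMP simulation for that grid value.
"""

from __future__ import annotations

import warnings
from collections import namedtuple
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .camp import (
    CAMPParams,
    d1_phasic_max,
    d2_pause_max,
    simulate_camp,
)
from .compensation import CompensationSpec, apply_presynaptic, delta_of_coverage
from .denervation import DenervationTrajectory, snapshot
from .dopamine import (
    DAParams,
    FiringProtocol,
    HEALTHY_TERMINAL_COUNT,
    default_protocol,
    healthy_mean_cover,
    local_terminal_count,
    simulate_da,
)
from .geometry import ArborNetwork
from .spn import BarrageSpec, IzhikevichParams, ModulationSpec, SPNChannelSet, firing_lookup

__all__ = [
    "DEFAULT_N_GRID",
    "SpatialActivityMap",
    "MapStats",
    "make_camp_source",
    "build_firing_table",
    "activity_map",
    "map_stats",
    "denervation_sweep",
]

# Terminal-count grid for the firing lookup; 0 is the isolated-area row and
# the upper end leaves headroom for compensation-boosted effective counts.
DEFAULT_N_GRID = (0.0, 5.0, 10.0, 15.0, 25.0, 40.0, 60.0, 80.0, 100.0, 125.0, 150.0, 200.0)

MapStats = namedtuple("MapStats", ["mean_d1", "sd_d1", "mean_d2", "sd_d2"])


def make_camp_source(
    da_params: DAParams | None = None,
    camp_params: CAMPParams | None = None,
    protocol: FiringProtocol | None = None,
    compensation: CompensationSpec | None = None,
    mean_cover: float = 11.0,
):
    """Return ``source(receptor, n) -> max cAMP`` for the firing lookup.

    For a presynaptic compensation mechanism, the DA parameters used at
    terminal count ``n`` are rescaled by delta evaluated at the arbor cover
    corresponding to ``n`` (cover = n * mean_cover / 100).  Results are
    cached per (receptor, n).
    """
    da_params = da_params or DAParams()
    camp_params = camp_params or CAMPParams()
    protocol = protocol or default_protocol()
    cache: dict[tuple[str, float], float] = {}

    def source(receptor: str, n: float) -> float:
        key = (receptor, float(n))
        if key in cache:
            return cache[key]
        p = da_params
        if compensation is not None and compensation.mechanism != "nc":
            cover = n * mean_cover / HEALTHY_TERMINAL_COUNT
            delta = float(delta_of_coverage(cover, compensation))
            p = apply_presynaptic(da_params, compensation.mechanism, delta)
        da = simulate_da(p, protocol, n)
        trace = simulate_camp(camp_params, da, receptor)
        value = d1_phasic_max(trace) if receptor == "d1" else d2_pause_max(trace)
        cache[key] = value
        return value

    return source


def build_firing_table(
    model: str = "hh",
    compensation: CompensationSpec | None = None,
    n_grid=DEFAULT_N_GRID,
    n_neurons: int = 100,
    seed: int = 0,
    da_params: DAParams | None = None,
    camp_params: CAMPParams | None = None,
    protocol: FiringProtocol | None = None,
    mean_cover: float = 11.0,
    channels: SPNChannelSet | None = None,
    modulation: ModulationSpec | None = None,
    izh: IzhikevichParams | None = None,
    barrage: BarrageSpec | None = None,
) -> pd.DataFrame:
    """Firing lookup for both receptors over the terminal-count grid.

    Returns the concatenated D1/D2 table from
    :func:`striatum.spn.firing_lookup`, with compensation (if any) baked
    into the cAMP levels.
    """
    source = make_camp_source(da_params, camp_params, protocol, compensation, mean_cover)
    parts = [
        firing_lookup(
            model,
            receptor,
            n_grid,
            source,
            n_neurons=n_neurons,
            seed=seed,
            channels=channels,
            modulation=modulation,
            izh=izh,
            barrage=barrage,
        )
        for receptor in ("d1", "d2")
    ]
    return pd.concat(parts, ignore_index=True)


@dataclass
class SpatialActivityMap:
    """Maximal D1/D2 firing interpolated at random striatal points."""

    points: np.ndarray  # (n, 3) mm
    n_local: np.ndarray  # effective terminal counts
    d1: np.ndarray  # mean spikes per analysis window
    d2: np.ndarray
    provenance: dict = field(default_factory=dict)


def _interp_column(table: pd.DataFrame, receptor: str, n_values: np.ndarray, drop_zero=False):
    sub = table[table.receptor == receptor].sort_values("n_terminals")
    if drop_zero:
        sub = sub[sub.n_terminals > 0]
    grid = sub.n_terminals.to_numpy()
    vals = sub.mean_spikes.to_numpy()
    outside = np.mean((n_values > grid.max()) | (n_values < grid.min()))
    if outside > 0.01:
        warnings.warn(
            f"{outside:.1%} of terminal counts fall outside the lookup grid "
            f"[{grid.min():g}, {grid.max():g}] and are clamped",
            stacklevel=3,
        )
    return np.interp(n_values, grid, vals)


def activity_map(
    network: ArborNetwork,
    table: pd.DataFrame,
    n_points: int = 10_000,
    seed: int | None = 0,
    mean_cover: float | None = None,
    d2_homeostasis: bool = False,
    provenance: dict | None = None,
) -> SpatialActivityMap:
    """Sample the striatum and look up maximal D1/D2 firing per point.

    ``mean_cover`` is the healthy-network calibration constant (computed
    from the network's full arbor set when omitted).  With
    ``d2_homeostasis`` the isolated-area D2 row (N = 0) is excluded,
    emulating D2-SPNs that downregulate their excitability when deprived of
    DA instead of firing maximally.
    """
    rng = np.random.default_rng(seed)
    pts = network.config.ellipsoid.sample_points(n_points, rng)
    if mean_cover is None:
        mean_cover = healthy_mean_cover(network)
    n_local = local_terminal_count(network, pts, mean_cover=mean_cover)
    d1 = _interp_column(table, "d1", n_local)
    d2 = _interp_column(table, "d2", n_local, drop_zero=d2_homeostasis)
    prov = {"n_points": n_points, "seed": seed, "d2_homeostasis": d2_homeostasis}
    if provenance:
        prov.update(provenance)
    return SpatialActivityMap(pts, n_local, d1, d2, prov)


def map_stats(amap: SpatialActivityMap) -> MapStats:
    """Unweighted spatial mean and SD of the D1/D2 firing map."""
    if len(amap.d1) == 0:
        raise ValueError("activity map is empty")
    return MapStats(
        float(amap.d1.mean()),
        float(amap.d1.std()),
        float(amap.d2.mean()),
        float(amap.d2.std()),
    )


def denervation_sweep(
    trajectory: DenervationTrajectory,
    levels,
    table: pd.DataFrame,
    n_points: int = 10_000,
    seed: int | None = 0,
    mean_cover: float | None = None,
    d2_homeostasis: bool = False,
) -> pd.DataFrame:
    """Spatial mean/SD of D1 and D2 firing at each denervation level.

    Snapshots the trajectory at each level, maps it and summarizes.  The
    healthy calibration ``mean_cover`` is computed once from the initial
    network.  Returns a DataFrame (level, mean_d1, sd_d1, mean_d2, sd_d2).
    """
    levels = np.asarray(sorted(levels), dtype=float)
    if mean_cover is None:
        mean_cover = healthy_mean_cover(trajectory.network)
    rows = []
    for lev in levels:
        net = snapshot(trajectory, float(lev))
        amap = activity_map(
            net,
            table,
            n_points=n_points,
            seed=seed,
            mean_cover=mean_cover,
            d2_homeostasis=d2_homeostasis,
        )
        st = map_stats(amap)
        rows.append(
            {
                "level": float(lev),
                "mean_d1": st.mean_d1,
                "sd_d1": st.sd_d1,
                "mean_d2": st.mean_d2,
                "sd_d2": st.sd_d2,
            }
        )
    return pd.DataFrame(rows)
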