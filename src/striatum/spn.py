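"""Spiny-projection-neuron membrane dynamics under barrages and cAMP.

Two single-compartment models of the striatal SPN are provided:

* a Hodgkin-Huxley-inspired model with the SPN's characteristic channel
  complement — fast and persistent Na+, delayed-rectifier, inward-rectifier
  (KIR), fast A-type, slowly inactivating (K_SI) and Ca2+-dependent (K_Ca)
  K+ channels, high-threshold N-/P-type Ca2+ channels and a leak.  KIR
  anchors the hyperpolarized down-state near -80 mV; sustained synaptic
  drive switches KIR off and produces a depolarized up-state near -55 mV
  from which spikes are fired.

* the two-variable Izhikevich quadratic model with a published spiny-neuron
  parameter set, used to check that the results do not depend on the
  biophysical detail of the first model.

Dopamine acts through cAMP: rising cAMP *reduces* the conductances of the
Ca_V(N), Ca_V(P), K_SI and K_Ca channels (HH model), or equivalently scales
up the effective drive (Izhikevich model).  Since three of the four targets
are potassium brakes, cAMP is net excitatory.  cAMP enters as a static
level per simulation — the maximal concentration reached in the relevant
protocol window — mirroring a pipeline in which the neuron is stimulated at
the recorded cAMP maximum.

Synaptic barrages are an Ornstein-Uhlenbeck current (correlation time 5 ms)
with a mean component, ramped up 4-fold inside the barrage window.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from numba import njit

__all__ = [
    "SPNChannelSet",
    "ModulationSpec",
    "BarrageSpec",
    "SpikeResult",
    "IzhikevichParams",
    "simulate_spn_hh",
    "simulate_spn_izhikevich",
    "firing_lookup",
]

SPIKE_THRESHOLD_MV = -20.0
REFRACTORY_MS = 2.0
DT_MS = 0.025


@dataclass(frozen=True)
class SPNChannelSet:
    """Maximal conductances (mS/cm^2) and membrane constants of the
    HH-inspired SPN.  Defaults are calibrated to the SPN behavioral
    contract: down-state -80+-5 mV, barrage-evoked up-state -55+-5 mV with
    spiking, silence without barrage."""

    g_naf: float = 35.0
    g_nap: float = 0.06
    g_kdr: float = 4.0
    g_kir: float = 1.8
    g_ka: float = 1.0
    g_ksi: float = 0.8
    g_kca: float = 0.8
    g_can: float = 0.25
    g_cap: float = 0.15
    g_leak: float = 0.1
    c_m: float = 1.0  # uF/cm^2
    e_na: float = 55.0
    e_k: float = -90.0
    e_ca: float = 100.0
    e_leak: float = -70.0
    ca_phi: float = 0.01  # uM per (uA/cm^2 * ms) of Ca current
    ca_tau: float = 80.0  # ms
    ca_kd: float = 0.5  # uM, K_Ca half-activation

    def __post_init__(self) -> None:
        for name in (
            "g_naf",
            "g_nap",
            "g_kdr",
            "g_kir",
            "g_ka",
            "g_ksi",
            "g_kca",
            "g_can",
            "g_cap",
            "g_leak",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class ModulationSpec:
    """cAMP modulation of the DA-sensitive channels.

    Each targeted conductance scales as g0 * (1 - depth * c/(c + k_c)) with
    c the cAMP level, so the effective conductance stays in
    (g0*(1-depth), g0].  ``k_c`` defaults to roughly half the healthy D1
    phasic cAMP maximum.
    """

    depth_ca_n: float = 0.7
    depth_ca_p: float = 0.7
    depth_k_si: float = 0.7
    depth_k_ca: float = 0.7
    k_c: float = 0.08  # uM cAMP

    def __post_init__(self) -> None:
        for name in ("depth_ca_n", "depth_ca_p", "depth_k_si", "depth_k_ca"):
            d = getattr(self, name)
            if not 0.0 <= d <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.k_c <= 0:
            raise ValueError("k_c must be > 0")

    def factor(self, camp: float) -> float:
        """Saturating modulation factor c/(c + k_c) in [0, 1)."""
        if camp < 0:
            raise ValueError("camp must be >= 0")
        return camp / (camp + self.k_c)


@dataclass(frozen=True)
class BarrageSpec:
    """Stochastic synaptic drive: an OU current (uA/cm^2) with correlation
    time ``tau_ms`` plus a proportional mean component; the amplitude is
    ``barrage_amplitude`` inside [t0, t1] and ``baseline_amplitude``
    outside."""

    baseline_amplitude: float = 1.375
    barrage_amplitude: float = 5.5  # 4x baseline
    window: tuple[float, float] = (100.0, 600.0)  # ms
    tau_ms: float = 5.0
    mean_ratio: float = 1.5  # mean drive = mean_ratio * amplitude
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_amplitude < 0 or self.barrage_amplitude < 0:
            raise ValueError("amplitudes must be >= 0")
        if self.window[1] <= self.window[0]:
            raise ValueError("barrage window must have t1 > t0")


@dataclass
class SpikeResult:
    """Membrane-potential trace and detected spikes."""

    times: np.ndarray  # ms
    v: np.ndarray  # mV
    spike_times: np.ndarray  # ms
    window: tuple[float, float]

    @property
    def n_spikes(self) -> int:
        """Spike count inside the analysis (barrage) window."""
        t0, t1 = self.window
        return int(np.sum((self.spike_times >= t0) & (self.spike_times <= t1)))

    def time_above(self, v_thresh: float = -60.0) -> float:
        """Total time (ms) with Vm above ``v_thresh`` inside the window."""
        t0, t1 = self.window
        mask = (self.times >= t0) & (self.times <= t1)
        return float(np.sum(self.v[mask] > v_thresh)) * DT_MS


@njit(cache=True)
def _sig(v, vh, k):
    return 1.0 / (1.0 + np.exp(-(v - vh) / k))


@njit(cache=True)
def _hh_core(
    n_steps,
    dt,
    g_naf,
    g_nap,
    g_kdr,
    g_kir,
    g_ka,
    g_ksi,
    g_kca,
    g_can,
    g_cap,
    g_leak,
    c_m,
    e_na,
    e_k,
    e_ca,
    e_leak,
    ca_phi,
    ca_tau,
    ca_kd,
    drive_mean,
    drive_sigma,
    noise,
):
    v_out = np.empty(n_steps)
    v = -80.0
    h = 1.0
    n = 0.0
    a = _sig(v, -45.0, 10.0)
    b = _sig(v, -80.0, -10.0)
    s = _sig(v, -40.0, 10.0)
    ca = 0.05
    i_ou = 0.0
    tau_ou = 5.0
    for t in range(n_steps):
        # OU synaptic current
        sig_t = drive_sigma[t]
        i_ou += (-i_ou / tau_ou) * dt + sig_t * np.sqrt(2.0 * dt / tau_ou) * noise[t]
        i_in = drive_mean[t] + i_ou

        m = _sig(v, -32.0, 6.0)
        i_naf = g_naf * m * m * m * h * (v - e_na)
        i_nap = g_nap * _sig(v, -50.0, 4.0) * (v - e_na)
        i_kdr = g_kdr * n * n * (v - e_k)
        i_kir = g_kir * _sig(v, -90.0, -10.0) * (v - e_k)
        i_ka = g_ka * a * b * (v - e_k)
        i_ksi = g_ksi * s * (v - e_k)
        can = _sig(v, -20.0, 7.0)
        cap = _sig(v, -15.0, 6.0)
        i_can = g_can * can * can * (v - e_ca)
        i_cap = g_cap * cap * cap * (v - e_ca)
        i_kca = g_kca * (ca / (ca + ca_kd)) * (v - e_k)
        i_leak = g_leak * (v - e_leak)

        dv = (
            -(i_naf + i_nap + i_kdr + i_kir + i_ka + i_ksi + i_kca + i_can + i_cap + i_leak)
            + i_in
        ) / c_m
        v = v + dv * dt
        if v > 60.0:
            v = 60.0
        if v < -110.0:
            v = -110.0

        # gates (exponential Euler)
        h_inf = _sig(v, -55.0, -6.0)
        h += (h_inf - h) * (1.0 - np.exp(-dt / 1.0))
        n_inf = _sig(v, -30.0, 9.0)
        n += (n_inf - n) * (1.0 - np.exp(-dt / 3.0))
        a_inf = _sig(v, -45.0, 10.0)
        a += (a_inf - a) * (1.0 - np.exp(-dt / 1.0))
        b_inf = _sig(v, -80.0, -10.0)
        b += (b_inf - b) * (1.0 - np.exp(-dt / 25.0))
        s_inf = _sig(v, -40.0, 10.0)
        s += (s_inf - s) * (1.0 - np.exp(-dt / 15.0))
        ca += (-ca_phi * (i_can + i_cap) - ca / ca_tau) * dt
        if ca < 0.0:
            ca = 0.0
        v_out[t] = v
    return v_out


@njit(cache=True)
def _izh_core(n_steps, dt, C, k, vr, vt, a, b, c, d, v_peak, drive, noise, sigma):
    v_out = np.empty(n_steps)
    v = vr
    u = 0.0
    i_ou = 0.0
    tau_ou = 5.0
    for t in range(n_steps):
        i_ou += (-i_ou / tau_ou) * dt + sigma[t] * np.sqrt(2.0 * dt / tau_ou) * noise[t]
        i_in = drive[t] + i_ou
        v += dt * (k * (v - vr) * (v - vt) - u + i_in) / C
        u += dt * a * (b * (v - vr) - u)
        if v >= v_peak:
            v = c
            u += d
            v_out[t] = v_peak
        else:
            v_out[t] = v
    return v_out


def _detect_spikes(times: np.ndarray, v: np.ndarray) -> np.ndarray:
    above = v >= SPIKE_THRESHOLD_MV
    crossings = np.flatnonzero(~above[:-1] & above[1:]) + 1
    spikes = []
    last = -np.inf
    for i in crossings:
        if times[i] - last >= REFRACTORY_MS:
            spikes.append(times[i])
            last = times[i]
    return np.array(spikes)


def _drive_arrays(barrage: BarrageSpec, n_steps: int, dt: float):
    t = np.arange(n_steps) * dt
    amp = np.where(
        (t >= barrage.window[0]) & (t < barrage.window[1]),
        barrage.barrage_amplitude,
        barrage.baseline_amplitude,
    )
    mean = barrage.mean_ratio * amp
    return mean, amp


def simulate_spn_hh(
    channels: SPNChannelSet | None = None,
    modulation: ModulationSpec | None = None,
    camp_level: float = 0.0,
    barrage: BarrageSpec | None = None,
    duration_ms: float = 700.0,
    dt: float = DT_MS,
) -> SpikeResult:
    """Simulate the HH-inspired SPN at a static cAMP level.

    cAMP scales the Ca_N, Ca_P, K_SI and K_Ca conductances down by their
    modulation depths; the synaptic barrage is seeded OU noise.  Raises on a
    numerically diverged (NaN) trace.
    """
    channels = channels or SPNChannelSet()
    modulation = modulation or ModulationSpec()
    barrage = barrage or BarrageSpec()
    f = modulation.factor(camp_level)
    n_steps = int(round(duration_ms / dt))
    mean, sigma = _drive_arrays(barrage, n_steps, dt)
    rng = np.random.default_rng(barrage.seed)
    noise = rng.standard_normal(n_steps)
    v = _hh_core(
        n_steps,
        dt,
        channels.g_naf,
        channels.g_nap,
        channels.g_kdr,
        channels.g_kir,
        channels.g_ka,
        channels.g_ksi * (1.0 - modulation.depth_k_si * f),
        channels.g_kca * (1.0 - modulation.depth_k_ca * f),
        channels.g_can * (1.0 - modulation.depth_ca_n * f),
        channels.g_cap * (1.0 - modulation.depth_ca_p * f),
        channels.g_leak,
        channels.c_m,
        channels.e_na,
        channels.e_k,
        channels.e_ca,
        channels.e_leak,
        channels.ca_phi,
        channels.ca_tau,
        channels.ca_kd,
        mean,
        sigma,
        noise,
    )
    if not np.isfinite(v).all():
        raise FloatingPointError("SPN membrane-potential integration diverged")
    times = np.arange(n_steps) * dt
    return SpikeResult(times, v, _detect_spikes(times, v), barrage.window)


@dataclass(frozen=True)
class IzhikevichParams:
    """Published spiny-neuron parameter set for the quadratic model."""

    C: float = 50.0
    k: float = 1.0
    v_r: float = -80.0
    v_t: float = -25.0
    a: float = 0.01
    b: float = -20.0
    c: float = -55.0
    d: float = 150.0
    v_peak: float = 40.0
    camp_gain: float = 1.0  # excitability gain at cAMP saturation
    drive_scale: float = 35.0  # converts barrage amplitude to pA-scale drive


def simulate_spn_izhikevich(
    params: IzhikevichParams | None = None,
    modulation: ModulationSpec | None = None,
    camp_level: float = 0.0,
    barrage: BarrageSpec | None = None,
    duration_ms: float = 700.0,
    dt: float = DT_MS,
) -> SpikeResult:
    """Simulate the Izhikevich SPN; cAMP multiplies the input drive by
    (1 + camp_gain * c/(c + k_c))."""
    params = params or IzhikevichParams()
    modulation = modulation or ModulationSpec()
    barrage = barrage or BarrageSpec()
    gain = 1.0 + params.camp_gain * modulation.factor(camp_level)
    n_steps = int(round(duration_ms / dt))
    mean, sigma = _drive_arrays(barrage, n_steps, dt)
    mean = mean * params.drive_scale * gain
    sigma = sigma * params.drive_scale * gain
    rng = np.random.default_rng(barrage.seed)
    noise = rng.standard_normal(n_steps)
    v = _izh_core(
        n_steps,
        dt,
        params.C,
        params.k,
        params.v_r,
        params.v_t,
        params.a,
        params.b,
        params.c,
        params.d,
        params.v_peak,
        mean,
        noise,
        sigma,
    )
    if not np.isfinite(v).all():
        raise FloatingPointError("Izhikevich integration diverged")
    times = np.arange(n_steps) * dt
    return SpikeResult(times, v, _detect_spikes(times, v), barrage.window)


def firing_lookup(
    model: str,
    receptor: str,
    n_grid,
    camp_source,
    n_neurons: int = 100,
    seed: int = 0,
    channels: SPNChannelSet | None = None,
    modulation: ModulationSpec | None = None,
    izh: IzhikevichParams | None = None,
    barrage: BarrageSpec | None = None,
):
    """Mean +- SD spike count over ``n_neurons`` noise realizations, per
    terminal count N.

    ``camp_source(receptor, n)`` must return the maximal cAMP level for the
    given terminal count (D1: phasic window; D2: pause window) — see
    :func:`striatum.camp.camp_vs_terminals`.  The same seed vector is reused
    for every N (common random numbers), so the table is deterministic given
    ``seed`` and differences across N reflect cAMP alone.  Returns a pandas
    DataFrame (n_terminals, receptor, model, camp, mean_spikes, sd_spikes,
    n_seeds).
    """
    import pandas as pd

    if model not in ("hh", "izh"):
        raise ValueError(f"unknown model {model!r} (expected 'hh' or 'izh')")
    if receptor not in ("d1", "d2"):
        raise ValueError(f"unknown receptor {receptor!r}")
    base_barrage = barrage or BarrageSpec()
    seeds = np.random.SeedSequence(seed).generate_state(n_neurons)
    rows = []
    for n in n_grid:
        camp = float(camp_source(receptor, n))
        counts = np.empty(n_neurons)
        for i, s in enumerate(seeds):
            bar = replace(base_barrage, seed=int(s))
            if model == "hh":
                res = simulate_spn_hh(channels, modulation, camp, bar)
            else:
                res = simulate_spn_izhikevich(izh, modulation, camp, bar)
            counts[i] = res.n_spikes
        rows.append(
            {
                "n_terminals": float(n),
                "receptor": receptor,
                "model": model,
                "camp": camp,
                "mean_spikes": counts.mean(),
                "sd_spikes": counts.std(),
                "n_seeds": n_neurons,
            }
        )
    return pd.DataFrame(rows)
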