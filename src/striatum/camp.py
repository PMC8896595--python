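"""Intracellular cAMP dynamics in D1- and D2-SPNs driven by dopamine.

Dopamine regulates spiny-projection-neuron excitability through cAMP.  D1
receptors (low DA affinity) *stimulate* cAMP production, so D1-SPN cAMP
peaks during phasic DA bursts; D2 receptors (high DA affinity) *inhibit*
production, so D2-SPN cAMP peaks when DA is cleared during firing pauses:

    d[cAMP]_D1/dt = alpha + lambda1 * DA^h / (DA^h + kappa1^h) - delta1 * cAMP
    d[cAMP]_D2/dt = alpha + lambda2 * kappa2^h / (DA^h + kappa2^h) - delta2 * cAMP

``alpha`` is basal production, ``lambda`` the receptor-driven production,
``kappa`` the receptor half-activation DA concentration (kappa2 << kappa1),
``h`` a Hill coefficient and ``delta`` the spontaneous decay rate.  The
defaults place tonic DA (~37 nM) below D1 activation and around the D2
transition, reproducing the regime in which D1 cells read out phasic peaks
and D2 cells read out pauses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .dopamine import DAParams, DATrace, FiringProtocol, simulate_da

__all__ = [
    "CAMPParams",
    "CAMPTrace",
    "simulate_camp",
    "max_camp",
    "camp_steady_state",
    "d1_phasic_max",
    "d2_pause_max",
    "camp_vs_terminals",
    "D2_PAUSE_EXTENSION_S",
]

# Optional extension of the D2 readout window past the firing pause.  Kept at
# zero by default: the post-pause DA-recovery transient is faster at high
# terminal counts, and folding it into the readout breaks the monotone
# dependence of the D2 pause response on innervation.
D2_PAUSE_EXTENSION_S = 0.0


@dataclass(frozen=True)
class CAMPParams:
    """Parameters of the D1/D2 cAMP equations (concentrations in uM DA or
    uM cAMP, rates in 1/s)."""

    alpha: float = 0.1  # basal production, uM/s
    lambda1: float = 1.0  # D1 receptor-driven production, uM/s
    lambda2: float = 1.0  # D2 disinhibited production, uM/s
    kappa1: float = 0.5  # D1 half-activation DA, uM
    kappa2: float = 0.03  # D2 half-activation DA, uM
    hill: float = 4.0
    decay1: float = 1.0  # D1 cAMP decay, 1/s
    decay2: float = 1.0  # D2 cAMP decay, 1/s

    def __post_init__(self) -> None:
        for name in (
            "alpha",
            "lambda1",
            "lambda2",
            "kappa1",
            "kappa2",
            "hill",
            "decay1",
            "decay2",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.kappa2 >= self.kappa1:
            raise ValueError("kappa2 must be < kappa1 (D2 has the higher affinity)")


@dataclass
class CAMPTrace:
    """cAMP time course for one SPN type."""

    times: np.ndarray  # s
    camp: np.ndarray  # uM
    receptor: str  # "d1" | "d2"
    da: DATrace

    def interp(self, t: np.ndarray) -> np.ndarray:
        return np.interp(t, self.times, self.camp)


def _production(params: CAMPParams, da: np.ndarray, receptor: str) -> np.ndarray:
    da = np.clip(np.asarray(da, dtype=float), 0.0, None)
    h = params.hill
    if receptor == "d1":
        act = da**h / (da**h + params.kappa1**h)
        return params.alpha + params.lambda1 * act
    if receptor == "d2":
        act = params.kappa2**h / (da**h + params.kappa2**h)
        return params.alpha + params.lambda2 * act
    raise ValueError(f"unknown receptor {receptor!r} (expected 'd1' or 'd2')")


def camp_steady_state(params: CAMPParams, da: float, receptor: str) -> float:
    """Fixed point of the cAMP equation at constant DA."""
    decay = params.decay1 if receptor == "d1" else params.decay2
    return float(_production(params, np.array(da), receptor) / decay)


def simulate_camp(params: CAMPParams, da: DATrace, receptor: str) -> CAMPTrace:
    """Integrate the cAMP equation along a DA trace.

    The initial condition is the receptor's steady state at the trace's
    initial DA level, so a constant-DA trace yields a constant cAMP level.
    """
    decay = params.decay1 if receptor == "d1" else params.decay2
    prod = _production(params, da.m, receptor)  # validates receptor
    c0 = camp_steady_state(params, float(da.m[0]), receptor)

    def rhs(t, y):
        p = np.interp(t, da.times, prod)
        return [p - decay * y[0]]

    sol = solve_ivp(
        rhs,
        (da.times[0], da.times[-1]),
        [c0],
        method="LSODA",
        t_eval=da.times,
        rtol=1.0e-8,
        atol=1.0e-12,
        max_step=0.05,
    )
    if not sol.success:  # pragma: no cover
        raise RuntimeError(f"cAMP integration failed: {sol.message}")
    return CAMPTrace(da.times.copy(), np.clip(sol.y[0], 0.0, None), receptor, da)


def max_camp(trace: CAMPTrace, window: tuple[float, float]) -> float:
    """Maximum cAMP inside a time window (inclusive)."""
    t0, t1 = window
    mask = (trace.times >= t0) & (trace.times <= t1)
    if not mask.any():
        raise ValueError(f"window ({t0}, {t1}) contains no trace samples")
    return float(trace.camp[mask].max())


def d1_phasic_max(trace: CAMPTrace) -> float:
    """Maximal D1 cAMP during the phasic burst of the driving protocol."""
    return max_camp(trace, trace.da.protocol.phasic_window())


def d2_pause_max(trace: CAMPTrace, extension: float = D2_PAUSE_EXTENSION_S) -> float:
    """Maximal D2 cAMP during the firing pause (optionally extended)."""
    t0, t1 = trace.da.protocol.pause_window()
    t1 = min(t1 + extension, float(trace.times[-1]))
    return max_camp(trace, (t0, t1))


def camp_vs_terminals(
    da_params: DAParams,
    camp_params: CAMPParams,
    protocol: FiringProtocol,
    n_values,
    da_params_for_n=None,
):
    """D1 phasic and D2 pause cAMP maxima as a function of terminal count.

    Runs the full DA -> cAMP pipeline per N.  ``da_params_for_n`` optionally
    maps N to (possibly compensation-adjusted) DA parameters.  Returns a
    pandas DataFrame with columns ``n_terminals``, ``d1_phasic_max``,
    ``d2_pause_max``.
    """
    import pandas as pd

    rows = []
    for n in n_values:
        if n < 0:
            raise ValueError("terminal counts must be >= 0")
        p = da_params if da_params_for_n is None else da_params_for_n(n)
        da = simulate_da(p, protocol, n)
        d1 = simulate_camp(camp_params, da, "d1")
        d2 = simulate_camp(camp_params, da, "d2")
        rows.append(
            {
                "n_terminals": float(n),
                "d1_phasic_max": d1_phasic_max(d1),
                "d2_pause_max": d2_pause_max(d2),
            }
        )
    return pd.DataFrame(rows)
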