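"""Compensatory mechanisms against dopaminergic denervation.

Presynaptic compensation rescales the release and uptake parameters of the
surviving terminals by a coverage-dependent factor delta in [0, 1): the
fewer arbors cover a subvolume, the harder its remaining terminals
compensate.

    ERC  (enhanced release):       Delta -> Delta0 / (1 - delta)
    DUC  (decreased uptake):       V_M   -> V0 * (1 - delta)
    DEC  (dual enhancement):       Delta -> Delta0 / (1 - delta)
                                   V_M   -> V0 / (1 - delta)

DEC is algebraically special: scaling release *and* uptake by the same
factor is equivalent to restoring the local terminal count N -> N/(1-delta)
in the mean-field DA equation, so the full DA time course — tonic plateau,
phasic peaks *and* pause clearance — is preserved.  ERC and DUC both raise
the tonic plateau and DUC additionally leaves pause clearance incomplete.

Postsynaptic variants act on the cAMP parameters instead: increased D2
receptor expression (D2X: lambda2 * s), enhanced receptor sensitivity
(SENS: kappa1, kappa2 / s) and suppressed cAMP degradation, e.g. by a
phosphodiesterase inhibitor (PDEI: delta1, delta2 / s).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .camp import CAMPParams
from .dopamine import DAParams

__all__ = [
    "CompensationSpec",
    "delta_of_coverage",
    "apply_presynaptic",
    "apply_postsynaptic",
    "PRESYNAPTIC_MECHANISMS",
    "POSTSYNAPTIC_MECHANISMS",
]

PRESYNAPTIC_MECHANISMS = ("nc", "erc", "duc", "dec")
POSTSYNAPTIC_MECHANISMS = ("d2x", "sens", "pdei")


@dataclass(frozen=True)
class CompensationSpec:
    """Coverage-dependent compensation strength.

    delta follows a sigmoid of the local arbor cover n: delta_max at zero
    cover, delta_max/2 at ``n_half`` (default half of the healthy mean
    cover ~11), ~0 at healthy cover.  ``delta_max`` < 1 bounds the release
    amplification (a delta of exactly 1 would diverge).
    ``exact_recovery_mode`` replaces the sigmoid by the linear form
    delta = clip(1 - n/n_healthy, 0, delta_max), under which DEC restores
    the healthy terminal count exactly — used to exercise the DEC identity.
    """

    mechanism: str = "nc"
    delta_max: float = 0.9
    n_half: float = 5.5
    slope: float = 2.0
    exact_recovery_mode: bool = False
    n_healthy: float = 11.0  # healthy mean arbor cover, for exact-recovery mode

    def __post_init__(self) -> None:
        if self.mechanism not in PRESYNAPTIC_MECHANISMS + POSTSYNAPTIC_MECHANISMS:
            raise ValueError(f"unknown compensation mechanism {self.mechanism!r}")
        if not 0.0 <= self.delta_max < 1.0:
            raise ValueError("delta_max must be in [0, 1)")
        if self.slope <= 0:
            raise ValueError("slope must be > 0")


def delta_of_coverage(n_cover, spec: CompensationSpec):
    """Compensation strength delta for a local arbor cover count.

    Sigmoidal by default; linear in exact-recovery mode.  Vectorized over
    ``n_cover``.
    """
    n = np.asarray(n_cover, dtype=float)
    if np.any(n < 0):
        raise ValueError("n_cover must be >= 0")
    if spec.exact_recovery_mode:
        delta = np.clip(1.0 - n / spec.n_healthy, 0.0, spec.delta_max)
    else:
        delta = spec.delta_max / (1.0 + np.exp((n - spec.n_half) / spec.slope))
    return float(delta) if np.isscalar(n_cover) else delta


def apply_presynaptic(params: DAParams, mechanism: str, delta: float) -> DAParams:
    """Return DA parameters rescaled by a presynaptic compensation mechanism.

    NC returns the input unchanged.  Requires delta < 1.
    """
    if mechanism not in PRESYNAPTIC_MECHANISMS:
        raise ValueError(f"unknown presynaptic mechanism {mechanism!r}")
    if not 0.0 <= delta < 1.0:
        raise ValueError("delta must be in [0, 1)")
    if mechanism == "nc" or delta == 0.0:
        return params
    scale = 1.0 / (1.0 - delta)
    if mechanism == "erc":
        return replace(params, delta_release=params.delta_release * scale)
    if mechanism == "duc":
        return replace(params, v_uptake=params.v_uptake / scale)
    # dec
    return replace(
        params,
        delta_release=params.delta_release * scale,
        v_uptake=params.v_uptake * scale,
    )


def apply_postsynaptic(params: CAMPParams, mechanism: str, strength: float) -> CAMPParams:
    """Return cAMP parameters rescaled by a postsynaptic mechanism.

    ``strength`` = 1 is a no-op; larger values strengthen the mechanism.
    """
    if mechanism not in POSTSYNAPTIC_MECHANISMS:
        raise ValueError(f"unknown postsynaptic mechanism {mechanism!r}")
    if strength <= 0:
        raise ValueError("strength must be > 0")
    if mechanism == "d2x":
        return replace(params, lambda2=params.lambda2 * strength)
    if mechanism == "sens":
        return replace(
            params, kappa1=params.kappa1 / strength, kappa2=params.kappa2 / strength
        )
    # pdei
    return replace(
        params, decay1=params.decay1 / strength, decay2=params.decay2 / strength
    )
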