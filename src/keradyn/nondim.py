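"""Nondimensionalization of a fitted Michaelis-Menten scenario.

With characteristic length ``l = 2L`` (the full cell cross-section),
time ``l/u`` and concentration scale ``k_S``, the dimensionless system is
governed by two numbers:

* Péclet number ``Pe = tau_diffusion_I / tau_drift = u l / (eps D_S)``
  — drift vs diffusion for the insoluble pool;
* Damköhler number ``Da = tau_drift / tau_reaction = l k_ass / (u k_S)``
  — drift vs turnover, with reaction time ``tau = k_S / k_ass``.

``Pe >> 1`` and ``Da >> 1`` mean the insoluble-pool dynamics are
controlled by the active transport.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .profiles import FixedParameters, L_DEFAULT
from .scenarios import TurnoverParameters

__all__ = ["DimensionlessSummary", "characteristic_scales",
           "timescale_ordering"]

_TIMESCALE_FIELDS = (
    ("reaction", "tau_reaction"),
    ("diffusion_S", "tau_diff_S"),
    ("drift", "tau_drift"),
    ("diffusion_I", "tau_diff_I"),
)


@dataclass(frozen=True)
class DimensionlessSummary:
    """Characteristic scales and dimensionless numbers of a scenario."""

    ell: float           # characteristic length, 2L (um)
    tau_diff_S: float    # l^2 / D_S (s)
    tau_diff_I: float    # l^2 / (eps D_S) (s)
    tau_drift: float     # l / u (s)
    tau_reaction: float  # k_S / k_ass (s)
    Pe: float
    Da: float
    kdis_over_kass: float
    kI_over_kS: float

    def as_dict(self) -> dict[str, float]:
        from dataclasses import asdict

        return asdict(self)


def characteristic_scales(params: TurnoverParameters,
                          fixed: FixedParameters | None = None,
                          L: float = L_DEFAULT) -> DimensionlessSummary:
    """Compute timescales, Pe and Da from fitted turnover parameters and
    the fixed transport parameters.

    Requires Michaelis-Menten parameters (the reaction time is
    ``k_S / k_ass``); the disassembly level used in the ratio
    ``k_dis / k_ass`` is the constant-equivalent level of the fitted
    profile.
    """
    fixed = fixed or FixedParameters()
    if params.k_S is None or params.k_I is None:
        raise ValueError("nondimensionalization requires the "
                         "Michaelis-Menten half-saturations k_S and k_I")
    ell = 2.0 * L
    tau_diff_S = ell ** 2 / fixed.D_S
    tau_diff_I = ell ** 2 / (fixed.eps * fixed.D_S)
    tau_drift = ell / fixed.u
    tau_reaction = params.k_S / params.k_ass
    return DimensionlessSummary(
        ell=ell,
        tau_diff_S=tau_diff_S,
        tau_diff_I=tau_diff_I,
        tau_drift=tau_drift,
        tau_reaction=tau_reaction,
        Pe=fixed.u * ell / (fixed.eps * fixed.D_S),
        Da=ell * params.k_ass / (fixed.u * params.k_S),
        kdis_over_kass=params.k_dis / params.k_ass,
        kI_over_kS=params.k_I / params.k_S,
    )


def timescale_ordering(summary: DimensionlessSummary
                       ) -> list[tuple[str, int]]:
    """Process labels sorted by ascending timescale, each annotated with
    its order of magnitude (nearest power of ten of the time in seconds,
    so 61 s reads as 10^2 s).  Ties keep the declaration order
    (reaction, diffusion_S, drift, diffusion_I)."""
    labelled = [(label, getattr(summary, attr))
                for label, attr in _TIMESCALE_FIELDS]
    labelled.sort(key=lambda lv: lv[1])  # stable: ties keep declaration order
    return [(label, round(math.log10(value)))
            for label, value in labelled]
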