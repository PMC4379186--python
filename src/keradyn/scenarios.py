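"""The 36-scenario model collection.

Each scenario is one combination of four modelling choices for the
soluble/insoluble keratin system:

* transport of the insoluble pool: no drift, inward drift at almost
  constant speed ``v(x)``, or inward drift at the measured variable speed
  ``u(x)`` (the soluble pool always diffuses);
* turnover kinetics: linear mass-action exchange or Michaelis-Menten
  ("nonlinear") exchange;
* assembly-rate profile: constant or localized of type Sources;
* disassembly-rate profile: constant, localized of type Sinks, or
  localized of type Mollify.

The scenario index is ``12*drift + 6*turnover + 3*assembly + disassembly
+ 1`` over the ordered option lists below, so indices 1-12 have no drift,
13-24 constant-speed drift and 25-36 variable-speed drift, and within
each drift block the first six scenarios are linear.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
from numpy.typing import ArrayLike, NDArray

from .profiles import (
    L_DEFAULT,
    eval_kass_sources,
    eval_kdis_mollify,
    eval_kdis_sinks,
)

__all__ = [
    "DRIFT_MODES",
    "TURNOVER_KINDS",
    "ASSEMBLY_PROFILES",
    "DISASSEMBLY_PROFILES",
    "ScenarioSpec",
    "TurnoverParameters",
    "build_scenario",
    "all_scenarios",
    "assembly_rate_profile",
    "disassembly_rate_profile",
    "turnover_rhs",
    "n_estimated_parameters",
    "scenario_table",
]

DRIFT_MODES = ("none", "const_speed", "var_speed")
TURNOVER_KINDS = ("linear", "nonlinear")
ASSEMBLY_PROFILES = ("constant", "sources")
DISASSEMBLY_PROFILES = ("constant", "sinks", "mollify")

N_SCENARIOS = 36


@dataclass(frozen=True)
class ScenarioSpec:
    """One model of the collection, identified by its feature flags."""

    index: int
    drift: str
    turnover: str
    assembly: str
    disassembly: str

    def __post_init__(self) -> None:
        if self.drift not in DRIFT_MODES:
            raise ValueError(f"unknown drift mode {self.drift!r}")
        if self.turnover not in TURNOVER_KINDS:
            raise ValueError(f"unknown turnover kind {self.turnover!r}")
        if self.assembly not in ASSEMBLY_PROFILES:
            raise ValueError(f"unknown assembly profile {self.assembly!r}")
        if self.disassembly not in DISASSEMBLY_PROFILES:
            raise ValueError(
                f"unknown disassembly profile {self.disassembly!r}")
        expected = (12 * DRIFT_MODES.index(self.drift)
                    + 6 * TURNOVER_KINDS.index(self.turnover)
                    + 3 * ASSEMBLY_PROFILES.index(self.assembly)
                    + DISASSEMBLY_PROFILES.index(self.disassembly) + 1)
        if self.index != expected:
            raise ValueError(
                f"index {self.index} inconsistent with flags (expected "
                f"{expected})")

    @property
    def n_free(self) -> int:
        """Number of fitted turnover parameters (2 linear, 4 nonlinear)."""
        return 2 if self.turnover == "linear" else 4

    @property
    def free_parameter_names(self) -> tuple[str, ...]:
        if self.turnover == "linear":
            return ("k_ass", "k_dis")
        return ("k_ass", "k_S", "k_dis", "k_I")


@dataclass(frozen=True)
class TurnoverParameters:
    """Turnover rate levels and, for Michaelis-Menten kinetics, the
    half-saturation concentrations.

    Units: ``k_ass``/``k_dis`` are 1/s for linear kinetics and uM/s for
    nonlinear kinetics (where they are maximal rates); ``k_S``/``k_I`` are
    concentrations (uM) and must be absent for linear kinetics.
    """

    k_ass: float
    k_dis: float
    k_S: float | None = None
    k_I: float | None = None

    def __post_init__(self) -> None:
        for name in ("k_ass", "k_dis", "k_S", "k_I"):
            value = getattr(self, name)
            if value is not None and value <= 0:
                raise ValueError(f"{name} must be strictly positive, "
                                 f"got {value}")

    @property
    def is_nonlinear(self) -> bool:
        return self.k_S is not None and self.k_I is not None

    def require_for(self, spec: ScenarioSpec) -> None:
        if spec.turnover == "nonlinear" and not self.is_nonlinear:
            raise ValueError(
                "nonlinear turnover requires half-saturations k_S and k_I")

    def as_dict(self) -> dict[str, float]:
        out = {"k_ass": self.k_ass, "k_dis": self.k_dis}
        if self.k_S is not None:
            out["k_S"] = self.k_S
        if self.k_I is not None:
            out["k_I"] = self.k_I
        return out


def build_scenario(index: int) -> ScenarioSpec:
    """Return the scenario with the given index (1..36)."""
    if not 1 <= index <= N_SCENARIOS:
        raise ValueError(f"scenario index must be in 1..{N_SCENARIOS}, "
                         f"got {index}")
    rem = index - 1
    drift_idx, rem = divmod(rem, 12)
    turnover_idx, rem = divmod(rem, 6)
    assembly_idx, disassembly_idx = divmod(rem, 3)
    return ScenarioSpec(
        index=index,
        drift=DRIFT_MODES[drift_idx],
        turnover=TURNOVER_KINDS[turnover_idx],
        assembly=ASSEMBLY_PROFILES[assembly_idx],
        disassembly=DISASSEMBLY_PROFILES[disassembly_idx],
    )


def all_scenarios() -> list[ScenarioSpec]:
    return [build_scenario(i) for i in range(1, N_SCENARIOS + 1)]


# ----------------------------------------------------------------------
# Turnover right-hand side
# ----------------------------------------------------------------------

def assembly_rate_profile(spec: ScenarioSpec, k_ass: float, x: ArrayLike,
                          L: float = L_DEFAULT) -> NDArray[np.float64]:
    """Spatial assembly-rate field ``k_ass(x)`` for the scenario.

    The fitted level is always the ``k_ass`` entering the area
    normalization, so the total assembly over the cell is comparable
    between constant and localized profiles.
    """
    x = np.asarray(x, dtype=float)
    if spec.assembly == "constant":
        return np.full_like(x, k_ass)
    return eval_kass_sources(x, k_ass, L=L)


def disassembly_rate_profile(spec: ScenarioSpec, k_dis: float, x: ArrayLike,
                             L: float = L_DEFAULT) -> NDArray[np.float64]:
    """Spatial disassembly-rate field ``k_dis(x)`` for the scenario.

    Sinks-type evaluations are clamped at zero: the signed Gaussian fit
    can dip below zero between peaks and a negative disassembly rate is
    unphysical.
    """
    x = np.asarray(x, dtype=float)
    if spec.disassembly == "constant":
        return np.full_like(x, k_dis)
    if spec.disassembly == "sinks":
        return eval_kdis_sinks(x, k_dis, L=L, clamp=True)
    return eval_kdis_mollify(x, k_dis)


def turnover_rhs(spec: ScenarioSpec, params: TurnoverParameters,
                 S: ArrayLike, I: ArrayLike, x: ArrayLike,
                 L: float = L_DEFAULT) -> NDArray[np.float64]:
    """Net soluble-to-insoluble conversion rate (uM/s) at positions ``x``.

    Applied with opposite signs in the two pool equations:
    ``dS/dt`` gains ``-rate`` and ``dI/dt`` gains ``+rate``.  Linear
    kinetics give ``k_ass(x) S - k_dis(x) I``; Michaelis-Menten kinetics
    ``k_ass(x) S/(k_S + S) - k_dis(x) I/(k_I + I)``.
    """
    params.require_for(spec)
    S = np.asarray(S, dtype=float)
    I = np.asarray(I, dtype=float)
    if np.any(S < 0) or np.any(I < 0):
        raise ValueError("concentrations must be nonnegative")
    kass_x = assembly_rate_profile(spec, params.k_ass, x, L=L)
    kdis_x = disassembly_rate_profile(spec, params.k_dis, x, L=L)
    if spec.turnover == "linear":
        return kass_x * S - kdis_x * I
    return (kass_x * S / (params.k_S + S)
            - kdis_x * I / (params.k_I + I))


def n_estimated_parameters(spec: ScenarioSpec) -> int:
    """Parameter count ``K`` entering the AIC: the free turnover
    parameters plus one for the residual-variance estimate."""
    return spec.n_free + 1


def scenario_table(specs: Iterable[ScenarioSpec] | None = None):
    """Design matrix of the collection as a pandas DataFrame with columns
    (index, drift, turnover, assembly, disassembly, n_free, K)."""
    import pandas as pd

    specs = list(specs) if specs is not None else all_scenarios()
    return pd.DataFrame({
        "index": [s.index for s in specs],
        "drift": [s.drift for s in specs],
        "turnover": [s.turnover for s in specs],
        "assembly": [s.assembly for s in specs],
        "disassembly": [s.disassembly for s in specs],
        "n_free": [s.n_free for s in specs],
        "K": [n_estimated_parameters(s) for s in specs],
    })
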