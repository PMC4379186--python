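"""Empirical spatial profiles for the 1-D keratin cell cross-section.

The cell is represented as a symmetric one-dimensional domain
``Omega = [-L, L]`` with ``L = 22.5`` micrometres: the plasma membrane sits
at ``x = +/-L``, the nuclear envelope at ``x = +/-7.5`` and the cell centre
at ``x = 0``.  Every function in this module evaluates one of the fitted
profiles that drive the models:

* active-transport speeds ``v(x)`` (almost constant) and ``u(x)``
  (variable, a two-Gaussian fit of measured speeds),
* spatially localized turnover-rate shapes: assembly of type *Sources*
  (three-Gaussian fit), disassembly of type *Sinks* (eight-Gaussian signed
  fit) and of type *Mollify* (a smoothed trapezoid localizing disassembly
  to the perinuclear band),
* the measured insoluble-pool concentration profiles at 24 h (``f0``, a
  mollified degree-8 polynomial) and 48 h (``f_final``, a quartic),
* the linear fluorescence-to-concentration calibration.

All localized rate profiles are area-normalized: with level ``k`` the
integral over the domain equals ``2*L*k``, so a localized profile injects
the same total turnover as a constant rate of the same level.

Coefficients below are exact decimal literals from the published fits;
they are the single source of truth for the whole package.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np
from numpy.typing import ArrayLike, NDArray

__all__ = [
    "L_DEFAULT",
    "N_POINTS_DEFAULT",
    "SpatialGrid",
    "GaussianSum",
    "MollifiedStep",
    "FixedParameters",
    "eval_drift_speed_const",
    "eval_drift_speed_var",
    "smooth_sgn",
    "eval_kass_sources",
    "eval_kdis_sinks",
    "eval_kdis_mollify",
    "eval_f0",
    "eval_ffinal",
    "fluorescence_to_concentration",
    "export_profile_csv",
]

# ----------------------------------------------------------------------
# Domain constants
# ----------------------------------------------------------------------

L_DEFAULT = 22.5        # half-length of the cell cross-section (um)
N_POINTS_DEFAULT = 200  # sample locations on [-L, L]

# Decay coefficient of the almost-constant speed v(x) = u*(1 - exp(-a x^2))
A_SPEED = 0.05

# Smoothing length (um) of the logistic analogue of sgn(x)
SGN_SMOOTHING = 1.0

# Variable speed u(x): two-Gaussian fit of the measured speed profile
U_VAR_AMPLITUDES = (0.003372, 0.003378)
U_VAR_CENTERS = (17.39, -17.41)
U_VAR_WIDTHS = (7.577, 7.546)

# Assembly profile of type Sources: three-Gaussian fit
SOURCES_AMPLITUDES = (1.684e5, 8.493e4, 1.333e5)
SOURCES_CENTERS = (20.13, -19.04, -20.74)
SOURCES_WIDTHS = (2.105, 1.374, 1.734)

# Disassembly profile of type Sinks: eight-Gaussian signed fit
SINKS_AMPLITUDES = (-3.383e5, -1.004e5, 2.445e5, -2.032e4,
                    -2.058e4, 3.793e5, -1.008e5, -4.742e5)
SINKS_CENTERS = (-11.51, -14.03, -11.39, 5.922, -6.077, 11.37, 14.03, 11.46)
SINKS_WIDTHS = (4.158, 2.236, 4.339, 5.385, 5.778, 4.322, 2.238, 4.196)

# Disassembly profile of type Mollify: trapezoid knots (um) and half-width
MOLLIFY_KNOTS = (-15.0, -7.5, 7.5, 15.0)
MOLLIFY_EPS = 1.0

# Initial insoluble profile f0: degree-8 polynomial P(x) (highest first for
# numpy.polyval), mollification knots and floor concentration
F0_POLY_COEFFS = (5.441e-8, 3.397e-21, -5.379e-5, -2.077e-18,
                  0.01062, 2.801e-16, 0.4104, 1.4e-14, 506.5)
F0_KNOT = 21.0   # a2 = 21, a1 = -21
F0_EPS = 1.0
F0_FLOOR = 50.0  # c (uM)

# Target insoluble profile at 48 h: quartic (highest first)
FFINAL_POLY_COEFFS = (-0.003255, 2.61e-17, 0.4899, 1.558e-15, 604.1)

# Mean keratin concentration used in the fluorescence calibration (uM)
MEAN_CONCENTRATION = 520.0


# ----------------------------------------------------------------------
# Domain types
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class SpatialGrid:
    """Uniform symmetric grid of sample locations on ``[-L, L]``."""

    L: float = L_DEFAULT
    n_points: int = N_POINTS_DEFAULT
    x: NDArray[np.float64] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.L <= 0:
            raise ValueError(f"half-length L must be positive, got {self.L}")
        if self.n_points < 3 or self.n_points % 2:
            raise ValueError("n_points must be an even integer >= 4 so the "
                             "grid is symmetric about 0 without a centre node")
        object.__setattr__(
            self, "x", np.linspace(-self.L, self.L, self.n_points))

    @property
    def dx(self) -> float:
        return 2.0 * self.L / (self.n_points - 1)


@dataclass(frozen=True)
class GaussianSum:
    """Sum of Gaussians ``sum_i a_i exp(-((x - b_i)/c_i)^2)`` with optional
    overall scale and additive baseline."""

    amplitudes: tuple[float, ...]
    centers: tuple[float, ...]
    widths: tuple[float, ...]
    scale: float = 1.0
    baseline: float = 0.0

    def __post_init__(self) -> None:
        if not (len(self.amplitudes) == len(self.centers) == len(self.widths)):
            raise ValueError("coefficient lists must have equal length")
        if any(c == 0 for c in self.widths):
            raise ValueError("Gaussian widths must be nonzero")

    def __call__(self, x: ArrayLike) -> NDArray[np.float64]:
        x = np.asarray(x, dtype=float)
        total = np.zeros_like(x)
        for a, b, c in zip(self.amplitudes, self.centers, self.widths):
            total += a * np.exp(-(((x - b) / c) ** 2))
        return self.scale * total + self.baseline

    def signed_width_sum(self) -> float:
        """``sum_i a_i |c_i|`` — the signed area factor used by the
        area-normalizing ``k_max``."""
        return float(sum(a * abs(c) for a, c in
                         zip(self.amplitudes, self.widths)))


@dataclass(frozen=True)
class MollifiedStep:
    """Trapezoidal plateau with parabolically smoothed corners.

    Piecewise-linear skeleton: ``baseline`` outside ``[a1, a4]``, rising to
    ``baseline + k_max`` on ``[a2, a3]``; each corner knot is replaced on
    ``[knot - eps, knot + eps]`` by the unique quadratic matching the two
    adjacent linear pieces in value and slope (C1 mollification).
    """

    knots: tuple[float, float, float, float] = MOLLIFY_KNOTS
    eps: float = MOLLIFY_EPS
    baseline: float = 0.0
    k_max: float = 1.0

    def __post_init__(self) -> None:
        a1, a2, a3, a4 = self.knots
        if not (a1 < a2 < a3 < a4):
            raise ValueError("knots must be strictly increasing")
        if self.eps <= 0:
            raise ValueError("mollification half-width eps must be positive")

    def __call__(self, x: ArrayLike) -> NDArray[np.float64]:
        x = np.asarray(x, dtype=float)
        a1, a2, a3, a4 = self.knots
        eps, kb, km = self.eps, self.baseline, self.k_max
        s_up = km / (a2 - a1)    # slope of the rising edge
        s_dn = -km / (a4 - a3)   # slope of the falling edge

        def corner(xv, knot, left_line, slope_jump):
            # C1 parabolic smoothing of a slope discontinuity at `knot`
            return left_line(xv) + slope_jump / (4 * eps) * (xv - knot + eps) ** 2

        pieces = [
            lambda xv: np.full_like(xv, kb),
            lambda xv: corner(xv, a1, lambda t: np.full_like(t, kb), s_up),
            lambda xv: kb + s_up * (xv - a1),
            lambda xv: corner(xv, a2, lambda t: kb + s_up * (t - a1), -s_up),
            lambda xv: np.full_like(xv, kb + km),
            lambda xv: corner(xv, a3, lambda t: np.full_like(t, kb + km), s_dn),
            lambda xv: kb + km + s_dn * (xv - a3),
            lambda xv: corner(xv, a4, lambda t: kb + km + s_dn * (t - a3), -s_dn),
            lambda xv: np.full_like(xv, kb),
        ]
        # half-open branches, lower bound inclusive
        edges = [a1 - eps, a1 + eps, a2 - eps, a2 + eps,
                 a3 - eps, a3 + eps, a4 - eps, a4 + eps]
        conds = [x < edges[0]]
        conds += [(x >= lo) & (x < hi) for lo, hi in zip(edges[:-1], edges[1:])]
        conds += [x >= edges[-1]]
        out = np.empty_like(x)
        for cond, piece in zip(conds, pieces):
            out[cond] = piece(x[cond])
        return out


@dataclass(frozen=True)
class FixedParameters:
    """Measured parameters held fixed in every scenario fit.

    D_S : soluble-pool diffusion coefficient (um^2/s)
    eps : D_I / D_S ratio of the insoluble to soluble diffusivity
    u : scale of the active-transport speed (um/s)
    a_speed : decay coefficient of the almost-constant speed v(x)
    mean_concentration : fluorescence-calibration constant (uM)
    """

    D_S: float = 0.88
    eps: float = 9.5e-4
    u: float = 0.0025
    a_speed: float = A_SPEED
    mean_concentration: float = MEAN_CONCENTRATION

    def __post_init__(self) -> None:
        for name in ("D_S", "eps", "u", "a_speed", "mean_concentration"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.eps > 1e-3:
            raise ValueError("insoluble/soluble diffusivity ratio eps must "
                             "not exceed 1e-3")

    @property
    def D_I(self) -> float:
        """Insoluble-pool diffusion coefficient (um^2/s)."""
        return self.eps * self.D_S


# prebuilt fitted shapes (unit scale; callers apply k_max / baseline)
_U_VAR = GaussianSum(U_VAR_AMPLITUDES, U_VAR_CENTERS, U_VAR_WIDTHS)
_SOURCES = GaussianSum(SOURCES_AMPLITUDES, SOURCES_CENTERS, SOURCES_WIDTHS)
_SINKS = GaussianSum(SINKS_AMPLITUDES, SINKS_CENTERS, SINKS_WIDTHS)


# ----------------------------------------------------------------------
# Transport speeds and the smooth sign
# ----------------------------------------------------------------------

def eval_drift_speed_const(x: ArrayLike,
                           fixed: FixedParameters | None = None
                           ) -> NDArray[np.float64]:
    """Almost-constant inward-drift speed ``v(x) = u (1 - exp(-a x^2))``.

    Equal to ``u`` away from the cell centre and decaying to zero at the
    nucleus, mirroring the observed stalling of assembled keratin there.
    """
    fixed = fixed or FixedParameters()
    x = np.asarray(x, dtype=float)
    return fixed.u * (1.0 - np.exp(-fixed.a_speed * x ** 2))


def eval_drift_speed_var(x: ArrayLike) -> NDArray[np.float64]:
    """Variable drift speed ``u(x)``: two-Gaussian fit of measured speeds,
    nearly zero over the nucleus and peaking near the cell periphery."""
    return _U_VAR(x)


def smooth_sgn(x: ArrayLike, a: float = SGN_SMOOTHING) -> NDArray[np.float64]:
    """Smooth odd analogue of ``sgn(x)``: ``2 / (1 + exp(-x/a)) - 1``."""
    if a <= 0:
        raise ValueError("smoothing length a must be positive")
    x = np.asarray(x, dtype=float)
    return 2.0 / (1.0 + np.exp(-x / a)) - 1.0


# ----------------------------------------------------------------------
# Localized turnover-rate profiles
# ----------------------------------------------------------------------

def _require_positive_level(value: float, name: str) -> None:
    if value <= 0:
        raise ValueError(f"rate level {name} must be strictly positive, "
                         f"got {value}")


def eval_kass_sources(x: ArrayLike, k_ass: float,
                      L: float = L_DEFAULT) -> NDArray[np.float64]:
    """Localized assembly rate of type Sources (peripheral peaks).

    ``k_max * sum_i a_i exp(-((x-b_i)/c_i)^2) + k_baseline`` with
    ``k_baseline = 0.01 k_ass`` and ``k_max`` chosen so that the integral
    over ``[-L, L]`` equals ``2 L k_ass`` (same total assembly as a
    constant rate of level ``k_ass``, up to clipped Gaussian tails).
    """
    _require_positive_level(k_ass, "k_ass")
    k_baseline = 1e-2 * k_ass
    k_max = (2.0 * L * (k_ass - k_baseline)
             / (np.sqrt(np.pi) * _SOURCES.signed_width_sum()))
    return k_max * _SOURCES(x) + k_baseline


def eval_kdis_sinks(x: ArrayLike, k_dis: float, L: float = L_DEFAULT,
                    clamp: bool = False) -> NDArray[np.float64]:
    """Localized disassembly rate of type Sinks (mid-cytoplasmic band).

    Signed eight-Gaussian fit scaled by ``k_max = 2 L k_dis /
    (sqrt(pi) * sum_i a_i |c_i|)``; the signed sum makes the profile dip
    slightly negative between fitted Gaussians.  With ``clamp=True`` the
    evaluation is floored at zero, as required when it is used as a rate.
    """
    _require_positive_level(k_dis, "k_dis")
    k_max = (2.0 * L * k_dis
             / (np.sqrt(np.pi) * _SINKS.signed_width_sum()))
    out = k_max * _SINKS(x)
    if clamp:
        out = np.maximum(out, 0.0)
    return out


def eval_kdis_mollify(x: ArrayLike, k_dis: float) -> NDArray[np.float64]:
    """Localized disassembly rate of type Mollify (perinuclear trapezoid).

    Smoothed step with plateau over the nucleus flanks, baseline
    ``0.01 k_dis`` and plateau increment ``k_max = 2 (k_dis - k_baseline)``
    so the domain integral matches a constant rate of level ``k_dis``.
    """
    _require_positive_level(k_dis, "k_dis")
    k_baseline = 1e-2 * k_dis
    step = MollifiedStep(baseline=k_baseline,
                         k_max=2.0 * (k_dis - k_baseline))
    return step(x)


# ----------------------------------------------------------------------
# Measured concentration profiles
# ----------------------------------------------------------------------

def _f0_poly(x: ArrayLike) -> NDArray[np.float64]:
    return np.polyval(F0_POLY_COEFFS, np.asarray(x, dtype=float))


def _f0_poly_deriv(x: ArrayLike) -> NDArray[np.float64]:
    return np.polyval(np.polyder(np.asarray(F0_POLY_COEFFS)),
                      np.asarray(x, dtype=float))


def eval_f0(x: ArrayLike) -> NDArray[np.float64]:
    """Insoluble-pool concentration profile at 24 h (uM).

    A degree-8 polynomial fit ``P(x)`` of the measured profile, mollified
    near ``x = +/-21`` so it meets the floor concentration ``c = 50 uM``
    continuously and satisfies no-flux-compatible flat tails at the
    membrane.  Branch boundaries are half-open with the lower bound
    inclusive.
    """
    x = np.asarray(x, dtype=float)
    a2 = F0_KNOT
    a1 = -a2
    eps, c = F0_EPS, F0_FLOOR

    p_a1 = float(_f0_poly(a1 + eps))
    p_a2 = float(_f0_poly(a2 - eps))
    d_a2 = float(_f0_poly_deriv(a2 - eps))

    def left_junction(xv):
        # quadratic through (a1-eps, c) with zero slope there, reaching
        # P(a1+eps) at a1+eps
        return c + (p_a1 - c) * (xv - a1 + eps) ** 2 / (4 * eps ** 2)

    def right_junction(xv):
        # quadratic matching P and P' at a2-eps and the floor c at a2+eps
        t = xv - a2 + eps
        curv = (c - p_a2 - 2 * eps * d_a2) / (4 * eps ** 2)
        return p_a2 + d_a2 * t + curv * t ** 2

    conds = [x < a1 - eps,
             (x >= a1 - eps) & (x < a1 + eps),
             (x >= a1 + eps) & (x < a2 - eps),
             (x >= a2 - eps) & (x < a2 + eps),
             x >= a2 + eps]
    pieces = [lambda xv: np.full_like(xv, c),
              left_junction,
              _f0_poly,
              right_junction,
              lambda xv: np.full_like(xv, c)]
    out = np.empty_like(x)
    for cond, piece in zip(conds, pieces):
        out[cond] = piece(x[cond])
    return out


def eval_ffinal(x: ArrayLike) -> NDArray[np.float64]:
    """Insoluble-pool concentration profile at 48 h (uM): quartic fit of
    the measured 48-hour profile — the fitting target."""
    return np.polyval(FFINAL_POLY_COEFFS, np.asarray(x, dtype=float))


# ----------------------------------------------------------------------
# Fluorescence calibration
# ----------------------------------------------------------------------

def fluorescence_to_concentration(fluor: ArrayLike, mean_fluor: float,
                                  mean_conc: float = MEAN_CONCENTRATION
                                  ) -> NDArray[np.float64]:
    """Convert fluorescence intensity to concentration (uM) by the linear
    calibration ``conc = fluor * mean_conc / mean_fluor``."""
    if mean_fluor <= 0:
        raise ValueError("mean fluorescence must be strictly positive")
    return np.asarray(fluor, dtype=float) * (mean_conc / mean_fluor)


# ----------------------------------------------------------------------
# Export
# ----------------------------------------------------------------------

def export_profile_csv(path, x: ArrayLike, values: ArrayLike,
                       value_name: str = "value") -> None:
    """Write a profile as two-column CSV ``(x_um, <value_name>)``."""
    x = np.asarray(x, dtype=float)
    values = np.asarray(values, dtype=float)
    if x.shape != values.shape:
        raise ValueError("x and values must have the same shape")
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["x_um", value_name])
        writer.writerows(zip(x, values))
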