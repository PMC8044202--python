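"""Closed-form kinetics of the kinesin-8 walk/slip model.

The motor alternates between processive hand-over-hand walking and brief
slip episodes in a weak-binding state in which both heads carry ADP
("Period II").  All quantities here are analytic functions of a
:class:`~kip3slip.parameters.MotorParameters` set and an operating point
(load ``F`` in pN, forward positive; ATP/ADP in uM).

Walking: the detached ADP-head moves from the intermediate (INT)
position to the front binding site with probability

    P_E(F) = e^(E_NL) e^(beta F d+) / (e^(E_NL) e^(beta F d+) + 1),

a Boltzmann split biased by the neck-linker docking energy ``E_NL``
(in kBT units) and the load acting over the distance parameter ``d+``.
The per-head ATPase rates ``k_T`` (trailing) and ``k_L`` (leading)
combine hydrolysis (k+, k-) and ADP release (k_D); at finite ATP the
second-order ATP binding step (k_bT [ATP]) adds a serial waiting time.
The no-slip velocity is v0 = [P_E k_T - (1 - P_E) k_L] d.

Slipping: during Period II the dimer hops between binding sites at
rates v_II0 e^(+-beta F delta) with delta = d/2, giving the slip
velocity v_II = v_II0 [e^(beta F delta) - e^(-beta F delta)] d and a
total velocity v = v0 + P_II F_II v_II, where P_II is the per-cycle
occurrence probability of Period II and F_II its fraction of the cycle
lifetime.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit

from .parameters import SATURATING, Condition, MotorParameters, _is_saturating

__all__ = [
    "ZeroATPError",
    "RateBreakdown",
    "VelocityResult",
    "binding_probability",
    "atpase_rates",
    "total_atpase_rate",
    "velocity_no_slip",
    "velocity_no_slip_simple",
    "period2_probability",
    "period2_fraction",
    "slip_velocity",
    "total_velocity",
    "rate_breakdown",
    "slipping_time",
    "stepping_ratio_no_slip",
    "stepping_ratio_with_slip",
    "stepping_ratio_adp_only",
    "stall_force",
    "stall_force_closed_form",
    "slip_diffusion_constant",
]


class ZeroATPError(ValueError):
    """Raised when a walking-mode quantity is requested at [ATP] = 0.

    With no ATP there is no turnover: the ATPase rates vanish and the
    slipping time diverges.  That regime is the slip-only mode (pure
    biased hopping), handled separately.
    """


@dataclasses.dataclass(frozen=True)
class RateBreakdown:
    """All intermediate fluxes at one operating point.

    ``P_E`` front-binding probability; ``k_T``/``k_L`` overall ATPase
    rates of the trailing/leading head (s^-1); ``k_total`` their sum;
    ``P_II`` per-cycle Period-II occurrence probability; ``F_II``
    Period-II fraction of the cycle lifetime.
    """

    P_E: float
    k_T: float
    k_L: float
    k_total: float
    P_II: float
    F_II: float


@dataclasses.dataclass(frozen=True)
class VelocityResult:
    """Velocity components at one operating point (nm/s, forward positive).

    ``v_total = v0 + v_slip`` with ``v_slip = P_II F_II v_II``.
    """

    v0: float
    v_slip: float
    v_total: float
    breakdown: RateBreakdown


def binding_probability(params: MotorParameters, F: float) -> float:
    """Probability P_E that the detached head binds the front site.

    Computed as a logistic function of ``E_NL + beta F d+`` (log-domain
    safe: large |F| saturates to exactly 1.0 or a tiny positive number
    without overflow).  Strictly increasing in F.
    """
    return float(expit(params.E_NL + params.beta * F * params.d_plus))


def _harmonic(*rates: float) -> float:
    """Rate of a series of first-order steps: inverse sum of inverse rates."""
    return 1.0 / sum(1.0 / r for r in rates)


def atpase_rates(params: MotorParameters, cond: Condition) -> tuple[float, float]:
    """Overall ATPase rates (k_T, k_L) of the trailing and leading head.

    At saturating ATP the trailing head turns over at k+ directly after a
    front binding (probability P_E) and through the serial ADP-release +
    hydrolysis path otherwise; the leading head mirrors this with k-.
    At finite ATP the second-order binding step 1/(k_bT [ATP]) is added
    in series; the finite branch converges to the saturating one as
    [ATP] -> infinity.
    """
    p = binding_probability(params, cond.F)
    kD, kp, km = params.k_D, params.k_plus, params.k_minus
    if cond.is_saturating:
        k_T = kp * p + _harmonic(kD, kp) * (1.0 - p)
        k_L = _harmonic(kD, km) * p + km * (1.0 - p)
        return k_T, k_L
    atp = float(cond.atp)
    if atp == 0.0:
        raise ZeroATPError(
            "[ATP] = 0 gives zero ATPase turnover; walking-mode quantities are "
            "undefined (use the slip-only mode for the no-ATP regime)"
        )
    kb = params.k_bT * atp
    k_T = p * _harmonic(kp, kb) + (1.0 - p) * _harmonic(kD, kb, kp)
    k_L = p * _harmonic(kD, kb, km) + (1.0 - p) * _harmonic(km, kb)
    return k_T, k_L


def total_atpase_rate(params: MotorParameters, cond: Condition) -> float:
    """Overall ATPase rate of the motor, k = k_T + k_L (s^-1)."""
    k_T, k_L = atpase_rates(params, cond)
    return k_T + k_L


def velocity_no_slip(params: MotorParameters, cond: Condition) -> float:
    """Walking velocity without the slip contribution (nm/s, signed).

    v0 = [P_E k_T - (1 - P_E) k_L] d with the branch-appropriate rates.
    """
    p = binding_probability(params, cond.F)
    k_T, k_L = atpase_rates(params, cond)
    return (p * k_T - (1.0 - p) * k_L) * params.d


def velocity_no_slip_simple(
    r0: float,
    F_S: float,
    k_plus: float,
    k_minus: float,
    F: float,
    d: float = 8.0,
) -> float:
    """Simplified four-parameter force-velocity relation (nm/s).

    Valid when ADP release is much faster than hydrolysis (k_D >> k+-):

        v0(F) = (r^x - 1) / (r^x + k+/k-) * k+ * d,   x = 1 + F/F_S,

    where ``r0`` is the unloaded stepping ratio and ``F_S`` the stall
    force.  The exponent makes v0 vanish exactly at F = -F_S (forward-
    positive load convention) and approach k+ d under large forward load.
    """
    if not r0 > 1:
        raise ValueError(f"r0 must exceed 1, got {r0}")
    if not F_S > 0:
        raise ValueError(f"F_S must be positive, got {F_S}")
    exponent = (1.0 + F / F_S) * math.log(r0)
    with np.errstate(over="ignore"):
        rx = float(np.exp(exponent))
    ratio = k_plus / k_minus
    if math.isinf(rx):
        return k_plus * d
    return (rx - 1.0) / (rx + ratio) * k_plus * d


def period2_probability(params: MotorParameters, F: float) -> float:
    """Occurrence probability P_II of Period II in one ATPase cycle.

    Period II (both heads ADP, weak binding) is entered when hydrolysis +
    Pi release (k+ or k-, by branch) wins the race against ADP release
    (k_D) in the partner head:

        P_II = P_E k+/(k+ + k_D) + (1 - P_E) k-/(k- + k_D).
    """
    p = binding_probability(params, F)
    kD, kp, km = params.k_D, params.k_plus, params.k_minus
    return p * kp / (kp + kD) + (1.0 - p) * km / (km + kD)


def period2_fraction(params: MotorParameters, cond: Condition) -> float:
    """Fraction F_II of the ATPase-cycle lifetime spent in Period II.

    At saturating ATP this coincides with :func:`period2_probability`
    (the Period-II dwell 1/k_D over a per-branch cycle time
    1/k+- + 1/k_D).  At finite ATP the ATP-binding waiting time
    1/(k_bT [ATP]) lengthens the cycle:

        F_II = P_E (1/k_D)/(1/(k_bT[ATP]) + 1/k+ + 1/k_D)
             + (1 - P_E) (1/k_D)/(1/(k_bT[ATP]) + 1/k- + 1/k_D),

    which converges to the saturating form as [ATP] -> infinity.
    """
    if cond.is_saturating:
        return period2_probability(params, cond.F)
    atp = float(cond.atp)
    if atp == 0.0:
        raise ZeroATPError("Period-II fraction is undefined at [ATP] = 0")
    p = binding_probability(params, cond.F)
    kD, kp, km = params.k_D, params.k_plus, params.k_minus
    t_bind = 1.0 / (params.k_bT * atp)
    t_D = 1.0 / kD
    return p * t_D / (t_bind + 1.0 / kp + t_D) + (1.0 - p) * t_D / (t_bind + 1.0 / km + t_D)


def slip_velocity(params: MotorParameters, F: float) -> float:
    """Slipping velocity in Period II (nm/s, signed): odd in F, zero at F=0.

    v_II = v_II0 [exp(beta F delta) - exp(-beta F delta)] d, from biased
    hopping over a symmetric weak-binding potential with delta = d/2.
    """
    x = params.beta * F * params.delta
    with np.errstate(over="ignore"):
        return float(2.0 * params.v_II0 * np.sinh(x) * params.d)


def rate_breakdown(params: MotorParameters, cond: Condition) -> RateBreakdown:
    """Assemble every intermediate flux at one operating point."""
    p = binding_probability(params, cond.F)
    k_T, k_L = atpase_rates(params, cond)
    return RateBreakdown(
        P_E=p,
        k_T=k_T,
        k_L=k_L,
        k_total=k_T + k_L,
        P_II=period2_probability(params, cond.F),
        F_II=period2_fraction(params, cond),
    )


def total_velocity(params: MotorParameters, cond: Condition) -> VelocityResult:
    """Total velocity with the slip contribution: v = v0 + P_II F_II v_II."""
    bd = rate_breakdown(params, cond)
    v0 = (bd.P_E * bd.k_T - (1.0 - bd.P_E) * bd.k_L) * params.d
    v_slip = bd.P_II * bd.F_II * slip_velocity(params, cond.F)
    return VelocityResult(v0=v0, v_slip=v_slip, v_total=v0 + v_slip, breakdown=bd)


def slipping_time(
    params: MotorParameters,
    atp: float | str = SATURATING,
    adp: float = 0.0,
) -> float:
    """Mean slip-episode duration tau_S (s).

    tau_S is the lifetime of ADP on the microtubule-bound head in the
    INT state: ADP release (k_D) followed by nucleotide rebinding,

        tau_S = (k_D + k_bD [ADP] + k_bT [ATP]) / (k_D k_bT [ATP]),

    which tends to 1/k_D at saturating ATP.  Diverges at [ATP] = 0.
    """
    if _is_saturating(atp):
        return 1.0 / params.k_D
    atp = float(atp)
    if atp <= 0.0:
        raise ZeroATPError("slipping time diverges at [ATP] = 0 (slip-only regime)")
    if adp < 0:
        raise ValueError(f"adp must be non-negative, got {adp}")
    return (params.k_D + params.k_bD * adp + params.k_bT * atp) / (
        params.k_D * params.k_bT * atp
    )


def _walking_fluxes(params: MotorParameters, F: float) -> tuple[float, float]:
    """Forward and backward walking step fluxes at saturating ATP (s^-1)."""
    cond = Condition.saturating(F)
    p = binding_probability(params, F)
    k_T, k_L = atpase_rates(params, cond)
    return p * k_T, (1.0 - p) * k_L


def stepping_ratio_no_slip(params: MotorParameters, F: float) -> float:
    """Forward-to-backward stepping ratio r0 without slip (saturating ATP).

    r0 = P_E k_T / [(1 - P_E) k_L]; exceeds 1 exactly when the no-slip
    velocity is forward.  Returns ``inf`` when P_E reaches 1 exactly.
    """
    fwd, bwd = _walking_fluxes(params, F)
    if bwd == 0.0:
        return math.inf
    return fwd / bwd


def stepping_ratio_with_slip(params: MotorParameters, F: float) -> float:
    """Stepping ratio r with slip hops included (saturating ATP).

    Augments the walking fluxes with the slip hop fluxes
    P_II F_II v_II0 exp(+-beta F delta).  Returns ``inf`` when the
    denominator vanishes or underflows to zero.
    """
    fwd, bwd = _walking_fluxes(params, F)
    cond = Condition.saturating(F)
    w = period2_probability(params, F) * period2_fraction(params, cond) * params.v_II0
    x = params.beta * F * params.delta
    with np.errstate(over="ignore"):
        num = fwd + w * float(np.exp(x))
        den = bwd + w * float(np.exp(-x))
    if den == 0.0:
        return math.inf
    return num / den


def stepping_ratio_adp_only(params: MotorParameters, F: float) -> float:
    """Stepping ratio at saturating ADP and no ATP: r_II = exp(2 beta F delta).

    Pure biased hopping; equals 1 at zero load and satisfies
    r(F) r(-F) = 1.  Overflow returns the ``inf`` sentinel.
    """
    with np.errstate(over="ignore"):
        return float(np.exp(2.0 * params.beta * F * params.delta))


def stall_force(
    params: MotorParameters,
    include_slip: bool = False,
    bracket: tuple[float, float] = (-3.0, 0.0),
    wide_bracket: tuple[float, float] = (-20.0, 0.0),
    vtol: float = 1e-6,
) -> float:
    """Stall force magnitude F_S (pN): backward load at which velocity is zero.

    Root-solves the no-slip velocity (or the total velocity when
    ``include_slip``) over backward loads, seeded by the closed-form
    relation exp(beta E_NL) exp(-beta F_S d+) k+ = k-.  Converged until
    |v| < ``vtol`` nm/s.
    """

    def vel(F: float) -> float:
        cond = Condition.saturating(F)
        if include_slip:
            return total_velocity(params, cond).v_total
        return velocity_no_slip(params, cond)

    if not vel(0.0) > 0:
        raise ValueError("unloaded velocity is not forward; no stall force exists")
    lo, hi = bracket
    if not vel(lo) < 0:
        lo, hi = wide_bracket
        if not vel(lo) < 0:
            raise ValueError(
                f"velocity does not change sign over {wide_bracket}; cannot bracket stall"
            )
    root = brentq(vel, lo, hi, xtol=1e-12, rtol=8.9e-16)
    if abs(vel(root)) >= vtol:
        raise RuntimeError("stall-force root did not converge below velocity tolerance")
    return abs(root)


def stall_force_closed_form(params: MotorParameters) -> float:
    """Closed-form stall-force seed: F_S = kBT [E_NL + ln(k+/k-)] / d+.

    Exact under the approximation k_D >> k+-; the full root solve of the
    no-slip velocity shifts it slightly.
    """
    numerator = params.E_NL + math.log(params.k_plus / params.k_minus)
    return params.kBT * numerator / params.d_plus


def slip_diffusion_constant(params: MotorParameters) -> float:
    """Diffusion constant of unloaded slipping: D = v_II0 d^2 / 2 (nm^2/s).

    From hop steps of size d at total unloaded rate set by v_II0, via
    d^2 = 2 D t0 with t0 the mean time per hop step.
    """
    return params.v_II0 * params.d**2 / 2.0
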