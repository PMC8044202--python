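"""Parameter-estimation recipe from force-velocity data.

With the ADP-release rate k_D fixed independently (from the mean slip
duration), four parameters determine the no-slip force-velocity curve:
k+, k-, E_NL and d+.  Each is pinned by one feature of the data:

* k+ and k-: the velocity plateaus under large forward/backward load,
  where v0 -> +k+ d and -> -k- d respectively;
* E_NL: the unloaded velocity, through the closed form
  v0(0) = [exp(E_NL) k+ - k-] / [exp(E_NL) + 1] * d;
* d+: the stall force, through
  exp(E_NL) exp(-F_S d+ / kBT) k+ = k-.

The second-order ATP-binding rate k_bT is calibrated separately from
the ATP concentration at which the unloaded velocity halves, and the
slip hop rate v_II0 from pure slip-velocity data.  An optional
least-squares refinement polishes the four recipe estimates against the
full no-slip expression.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Any

import numpy as np
from scipy.optimize import brentq, least_squares

from .data import FVDataset
from .kinetics import slip_velocity, velocity_no_slip
from .parameters import Condition, MotorParameters

__all__ = [
    "EstimatedParameters",
    "estimate_rate_constants",
    "estimate_E_NL",
    "estimate_d_plus",
    "estimate_stall_force_from_data",
    "calibrate_k_bT",
    "estimate_v_II0",
    "refine_parameters",
]


@dataclasses.dataclass(frozen=True)
class EstimatedParameters:
    """Recipe output: parameter values plus per-parameter provenance.

    ``provenance`` maps each parameter name to the data feature that
    determined it (plateau mean, unloaded velocity, stall force, ...).
    """

    k_plus: float
    k_minus: float
    E_NL: float
    d_plus: float
    k_bT: float | None = None
    v_II0: float | None = None
    provenance: dict[str, Any] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("k_plus", "k_minus", "E_NL", "d_plus"):
            value = getattr(self, name)
            if not (math.isfinite(value) and value > 0):
                raise ValueError(f"estimated {name} must be finite and positive, got {value}")

    def to_motor_parameters(self, k_D: float = 400.0, **extra: Any) -> MotorParameters:
        """Assemble a full parameter set (k_D supplied independently)."""
        kwargs: dict[str, Any] = dict(
            k_D=k_D,
            k_plus=self.k_plus,
            k_minus=self.k_minus,
            E_NL=self.E_NL,
            d_plus=self.d_plus,
        )
        if self.k_bT is not None:
            kwargs["k_bT"] = self.k_bT
        if self.v_II0 is not None:
            kwargs["v_II0"] = self.v_II0
        kwargs.update(extra)
        return MotorParameters(**kwargs)


def _plateau_masks(force: np.ndarray, fraction: float) -> tuple[np.ndarray, np.ndarray]:
    span = force.max() - force.min()
    width = fraction * span
    return force >= force.max() - width, force <= force.min() + width


def estimate_rate_constants(
    data: FVDataset,
    plateau_fraction: float = 0.10,
    d: float = 8.0,
) -> tuple[float, float]:
    """Estimate (k+, k-) from the large-load velocity plateaus.

    The plateau is the extreme ``plateau_fraction`` of the sampled load
    range on each side; k+ = <v>/d over the forward plateau,
    k- = |<v>|/d over the backward plateau.  Requires forward loads
    reaching at least twice the apparent stall force and backward loads
    likewise (asymptote coverage).
    """
    force, velocity = data.force, data.velocity
    fwd, bwd = _plateau_masks(force, plateau_fraction)
    v_fwd = velocity[fwd].mean()
    v_bwd = velocity[bwd].mean()
    if not v_fwd > 0:
        raise ValueError(
            "forward plateau velocity is not positive: dataset lacks sufficient "
            "forward-load coverage for the k_plus asymptote"
        )
    if not v_bwd < 0:
        raise ValueError(
            "backward plateau velocity is not negative: dataset lacks sufficient "
            "backward-load coverage for the k_minus asymptote"
        )
    return v_fwd / d, abs(v_bwd) / d


def estimate_E_NL(v0_unloaded: float, k_plus: float, k_minus: float, d: float = 8.0) -> float:
    """Invert the unloaded-velocity closed form for E_NL (kBT units).

    v0(0) = [exp(E_NL) k+ - k-] / [exp(E_NL) + 1] * d has a finite
    solution only for -k- d < v0 < k+ d:

        exp(E_NL) = (k- + v0/d) / (k+ - v0/d).
    """
    v = v0_unloaded / d
    if not (-k_minus < v < k_plus):
        raise ValueError(
            f"unloaded velocity {v0_unloaded} nm/s lies outside the open interval "
            f"({-k_minus * d}, {k_plus * d}) nm/s: no finite E_NL exists"
        )
    value = math.log((k_minus + v) / (k_plus - v))
    if value < 0:
        # A backward-biased unloaded velocity would need a negative docking
        # energy; the model constrains E_NL >= 0.
        raise ValueError(
            f"unloaded velocity {v0_unloaded} nm/s implies negative E_NL ({value:.3g})"
        )
    return value


def estimate_d_plus(
    F_S_observed: float,
    E_NL: float,
    k_plus: float,
    k_minus: float,
    kBT: float = 4.1,
) -> float:
    """Invert the stall relation for the distance parameter d+ (nm).

    From exp(E_NL) exp(-F_S d+/kBT) k+ = k-:
    d+ = kBT [E_NL + ln(k+/k-)] / F_S.
    """
    if not F_S_observed > 0:
        raise ValueError(f"stall force must be positive, got {F_S_observed}")
    numerator = E_NL + math.log(k_plus / k_minus)
    if numerator <= 0:
        raise ValueError(
            "E_NL + ln(k+/k-) is not positive: the model cannot stall at a "
            "positive backward load with these rates"
        )
    return kBT * numerator / F_S_observed


def estimate_stall_force_from_data(data: FVDataset) -> float:
    """Stall-force magnitude from the data's zero crossing at backward load.

    Linear interpolation between the two load points bracketing the
    sign change of velocity on the backward-load side.
    """
    force, velocity = data.force, data.velocity
    sign_change = np.flatnonzero(np.diff(np.sign(velocity)) > 0)
    candidates = [i for i in sign_change if force[i] < 0 or force[i + 1] <= 0]
    if not candidates:
        raise ValueError("no zero crossing at backward load found in the dataset")
    i = candidates[-1]
    f0, f1 = force[i], force[i + 1]
    v0, v1 = velocity[i], velocity[i + 1]
    root = f0 - v0 * (f1 - f0) / (v1 - v0)
    return abs(root)


def calibrate_k_bT(
    params: MotorParameters,
    half_velocity_atp: float,
    bounds: tuple[float, float] = (1e-3, 1e3),
    rtol: float = 1e-3,
) -> float:
    """ATP-binding rate k_bT (uM^-1 s^-1) from the half-velocity ATP level.

    Solves for the k_bT at which the unloaded walking velocity at
    ``half_velocity_atp`` uM equals half the saturating-ATP value.
    """
    if not half_velocity_atp > 0:
        raise ValueError(f"half_velocity_atp must be positive, got {half_velocity_atp}")
    v_sat = velocity_no_slip(params, Condition.saturating(0.0))

    def gap(k_bT: float) -> float:
        trial = params.replace(k_bT=k_bT)
        return velocity_no_slip(trial, Condition(0.0, half_velocity_atp)) - 0.5 * v_sat

    lo, hi = bounds
    if gap(lo) * gap(hi) > 0:
        raise ValueError(
            f"no k_bT in [{lo}, {hi}] uM^-1 s^-1 yields half-velocity at "
            f"{half_velocity_atp} uM ATP"
        )
    return float(brentq(gap, lo, hi, rtol=rtol))


def estimate_v_II0(data: FVDataset, params: MotorParameters) -> float:
    """Slip hop rate v_II0 (s^-1) by least squares against slip-velocity data.

    The slip velocity is linear in v_II0, so the least-squares solution
    is the ratio of cross- and auto-correlations of the unit curve.
    """
    unit = np.array([slip_velocity(params.replace(v_II0=1.0), F) for F in data.force])
    denom = float(unit @ unit)
    if denom == 0.0:
        raise ValueError("slip-velocity basis vanishes on this load grid (all F = 0?)")
    value = float(unit @ data.velocity) / denom
    if value < 0:
        raise ValueError(f"fitted v_II0 is negative ({value:.3g}); data are not slip-like")
    return value


def refine_parameters(
    data: FVDataset,
    initial: EstimatedParameters,
    k_D: float = 400.0,
    d: float = 8.0,
    kBT: float = 4.1,
) -> EstimatedParameters:
    """Least-squares polish of (k+, k-, E_NL, d+) against the no-slip curve.

    Seeded by the recipe estimates; parameters stay positive via log
    reparameterisation.  The residual is the no-slip velocity at
    saturating ATP evaluated on the dataset's load grid.
    """
    force, velocity = data.force, data.velocity

    def residuals(log_theta: np.ndarray) -> np.ndarray:
        kp, km, enl, dp = np.exp(log_theta)
        params = MotorParameters(
            k_D=k_D, k_plus=kp, k_minus=km, E_NL=enl, d_plus=dp, d=d, kBT=kBT
        )
        model = np.array(
            [velocity_no_slip(params, Condition.saturating(F)) for F in force]
        )
        return model - velocity

    x0 = np.log([initial.k_plus, initial.k_minus, initial.E_NL, initial.d_plus])
    fit = least_squares(residuals, x0, method="lm")
    kp, km, enl, dp = np.exp(fit.x)
    provenance = dict(initial.provenance)
    provenance["refinement"] = {
        "objective": "least squares of no-slip velocity over the dataset",
        "cost": float(fit.cost),
        "seeded_by": {
            "k_plus": initial.k_plus,
            "k_minus": initial.k_minus,
            "E_NL": initial.E_NL,
            "d_plus": initial.d_plus,
        },
    }
    return dataclasses.replace(
        initial, k_plus=float(kp), k_minus=float(km), E_NL=float(enl),
        d_plus=float(dp), provenance=provenance,
    )
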