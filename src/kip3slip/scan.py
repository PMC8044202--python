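"""Curve scans: analytic quantities evaluated over load/ATP grids.

A :class:`ScanSpec` names a load grid, a list of ATP conditions and the
quantities to evaluate; :func:`run_scan` returns a long-format table
with one row per (load, ATP, quantity).  Scans are deterministic:
re-running an identical spec reproduces the table byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import json
import pathlib
from typing import Any, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .kinetics import (
    slip_velocity,
    slipping_time,
    stepping_ratio_adp_only,
    stepping_ratio_no_slip,
    stepping_ratio_with_slip,
    total_velocity,
    velocity_no_slip,
)
from .parameters import SATURATING, Condition, MotorParameters, load_parameters

#: Quantities a scan can request, keyed by their field name.
QUANTITIES = ("v0", "v_total", "v_slip", "r0", "r", "r_II", "v_II", "tau_S")


@dataclasses.dataclass(frozen=True)
class ScanSpec:
    """Grid specification for a curve scan.

    ``F_start``/``F_stop``/``F_step`` define the load grid (pN,
    inclusive of the endpoint up to rounding); ``atp`` lists ATP
    concentrations in uM or the ``saturating`` sentinel; ``quantities``
    come from :data:`QUANTITIES`.
    """

    F_start: float
    F_stop: float
    F_step: float
    atp: tuple[Any, ...] = (SATURATING,)
    quantities: tuple[str, ...] = ("v0", "v_total")

    def __post_init__(self) -> None:
        if not self.F_step > 0:
            raise ValueError(f"F_step must be positive, got {self.F_step}")
        if self.F_stop < self.F_start:
            raise ValueError("F_stop must not precede F_start")
        if not self.atp:
            raise ValueError("at least one ATP condition is required")
        if not self.quantities:
            raise ValueError("at least one quantity is required")
        unknown = set(self.quantities) - set(QUANTITIES)
        if unknown:
            raise ValueError(
                f"unknown quantity name(s) {sorted(unknown)}; valid names: {list(QUANTITIES)}"
            )

    @property
    def grid(self) -> np.ndarray:
        n = int(round((self.F_stop - self.F_start) / self.F_step)) + 1
        return self.F_start + self.F_step * np.arange(n)


def _evaluate(params: MotorParameters, quantity: str, F: float, atp: Any, adp: float) -> float:
    cond = Condition(F=F, atp=atp, adp=adp)
    if quantity == "v0":
        return velocity_no_slip(params, cond)
    if quantity == "v_total":
        return total_velocity(params, cond).v_total
    if quantity == "v_slip":
        return total_velocity(params, cond).v_slip
    if quantity == "r0":
        return stepping_ratio_no_slip(params, F)
    if quantity == "r":
        return stepping_ratio_with_slip(params, F)
    if quantity == "r_II":
        return stepping_ratio_adp_only(params, F)
    if quantity == "v_II":
        return slip_velocity(params, F)
    if quantity == "tau_S":
        return slipping_time(params, atp, adp)
    raise ValueError(f"unknown quantity {quantity!r}")  # pragma: no cover


def run_scan(
    spec: ScanSpec,
    params: str | MotorParameters = "kip3_table1",
    adp: float = 0.0,
) -> pd.DataFrame:
    """Evaluate the requested quantities on the spec's grid.

    Returns a long-format DataFrame with columns ``force_pN``,
    ``atp_uM``, ``quantity`` and ``value`` (units fixed per quantity:
    velocities nm/s, ratios dimensionless, tau_S seconds).
    """
    p = load_parameters(params)
    rows = []
    for atp in spec.atp:
        for F in spec.grid:
            for quantity in spec.quantities:
                rows.append(
                    {
                        "force_pN": float(F),
                        "atp_uM": atp,
                        "quantity": quantity,
                        "value": _evaluate(p, quantity, float(F), atp, adp),
                    }
                )
    return pd.DataFrame(rows)


def write_scan(
    table: pd.DataFrame,
    path: str | pathlib.Path,
    params: str | MotorParameters = "kip3_table1",
    sep: str = "\t",
) -> None:
    """Write a scan table with parameter provenance as a header comment."""
    p = load_parameters(params)
    meta = {
        "kip3slip_version": __version__,
        "parameters": p.to_dict(),
    }
    path = pathlib.Path(path)
    with path.open("w") as fh:
        fh.write("# " + json.dumps(meta, sort_keys=True) + "\n")
        table.to_csv(fh, sep=sep, index=False)
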