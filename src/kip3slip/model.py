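"""Model/Results interface for fitting the walk/slip model to data.

:class:`ForceVelocityModel` wraps a force-velocity dataset and fits the
four free parameters of the no-slip force-velocity relation (k+, k-,
E_NL, d+) by the feature-based recipe (large-load plateaus, unloaded
velocity, stall force), optionally polished by least squares.
:meth:`ForceVelocityModel.fit` returns a
:class:`ForceVelocityResults` carrying the estimates, provenance,
residual diagnostics and a ``summary()`` table; prediction, simulation
and plotting hang off the results object.

Example
-------
>>> from kip3slip import ForceVelocityModel, generate_fixture
>>> data = generate_fixture("kip3_table1")          # noiseless synthetic
>>> res = ForceVelocityModel.from_dataset(data).fit()
>>> print(res.summary())                            # doctest: +SKIP
"""

from __future__ import annotations

import dataclasses
import json
import pathlib
from typing import Any

import numpy as np
import pandas as pd

from .data import FVDataset
from .estimate import (
    EstimatedParameters,
    estimate_E_NL,
    estimate_d_plus,
    estimate_rate_constants,
    estimate_stall_force_from_data,
    refine_parameters,
)
from .kinetics import velocity_no_slip
from .parameters import Condition, MotorParameters

__all__ = ["ForceVelocityModel", "ForceVelocityResults"]


class ForceVelocityModel:
    """No-slip force-velocity model bound to a dataset.

    Parameters
    ----------
    data : FVDataset
        Observations with columns ``force_pN`` and ``velocity_nm_per_s``.
    k_D : float
        ADP-release rate (s^-1), fixed independently of the
        force-velocity data (it is set by the mean slip duration).
    d, kBT : float
        Binding-site spacing (nm) and thermal energy (pN nm).
    plateau_fraction : float
        Extreme fraction of the load range used for the asymptote
        plateaus.
    """

    def __init__(
        self,
        data: FVDataset,
        k_D: float = 400.0,
        d: float = 8.0,
        kBT: float = 4.1,
        plateau_fraction: float = 0.10,
    ) -> None:
        if len(data) < 5:
            raise ValueError("need at least five force-velocity rows to run the recipe")
        self.data = data
        self.k_D = k_D
        self.d = d
        self.kBT = kBT
        self.plateau_fraction = plateau_fraction

    @classmethod
    def from_dataset(cls, data: FVDataset, **kwargs: Any) -> "ForceVelocityModel":
        return cls(data, **kwargs)

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, **kwargs: Any) -> "ForceVelocityModel":
        return cls(FVDataset(frame.copy()), **kwargs)

    @classmethod
    def from_csv(cls, path: str | pathlib.Path, **kwargs: Any) -> "ForceVelocityModel":
        return cls(FVDataset.read(path), **kwargs)

    def _check_coverage(self, F_S: float) -> None:
        force = self.data.force
        missing = []
        if force.max() < 2.0 * F_S:
            missing.append(f"forward loads up to {2 * F_S:.2f} pN (have {force.max():.2f})")
        if force.min() > -2.0 * F_S:
            missing.append(f"backward loads down to {-2 * F_S:.2f} pN (have {force.min():.2f})")
        if missing:
            raise ValueError("insufficient load range for asymptote estimation: "
                             + "; ".join(missing))

    def fit(self, refine: bool = True) -> "ForceVelocityResults":
        """Run the estimation recipe; optionally polish by least squares.

        The recipe estimates are always recorded in the provenance; with
        ``refine=True`` (default, mirroring the adjust-slightly step of
        the original analysis) the returned values are the least-squares
        polish seeded by them.
        """
        data = self.data
        F_S_obs = estimate_stall_force_from_data(data)
        self._check_coverage(F_S_obs)
        k_plus, k_minus = estimate_rate_constants(data, self.plateau_fraction, self.d)
        # Unloaded velocity: observation nearest F = 0.
        idx0 = int(np.argmin(np.abs(data.force)))
        v0_unloaded = float(data.velocity[idx0])
        E_NL = estimate_E_NL(v0_unloaded, k_plus, k_minus, self.d)
        d_plus = estimate_d_plus(F_S_obs, E_NL, k_plus, k_minus, self.kBT)
        provenance = {
            "k_plus": f"forward-plateau mean velocity / d (top {self.plateau_fraction:.0%} of load range)",
            "k_minus": f"backward-plateau |mean velocity| / d (bottom {self.plateau_fraction:.0%} of load range)",
            "E_NL": f"unloaded velocity {v0_unloaded:.3g} nm/s at F = {data.force[idx0]:.3g} pN",
            "d_plus": f"stall force {F_S_obs:.4g} pN from the zero crossing",
            "recipe": {
                "k_plus": k_plus, "k_minus": k_minus, "E_NL": E_NL, "d_plus": d_plus,
            },
        }
        estimates = EstimatedParameters(
            k_plus=k_plus, k_minus=k_minus, E_NL=E_NL, d_plus=d_plus,
            provenance=provenance,
        )
        if refine:
            estimates = refine_parameters(data, estimates, self.k_D, self.d, self.kBT)
        return ForceVelocityResults(self, estimates, F_S_obs, v0_unloaded)


@dataclasses.dataclass
class ForceVelocityResults:
    """Fit results: estimates, provenance, diagnostics, prediction."""

    model: ForceVelocityModel
    estimates: EstimatedParameters
    stall_force_observed: float
    v0_unloaded_observed: float

    @property
    def params(self) -> MotorParameters:
        """Full parameter set assembled from the estimates (k_D fixed)."""
        return self.estimates.to_motor_parameters(
            k_D=self.model.k_D, d=self.model.d, kBT=self.model.kBT
        )

    def predict(self, force: np.ndarray | float) -> np.ndarray:
        """No-slip velocity (saturating ATP) at the given load(s)."""
        force = np.atleast_1d(np.asarray(force, dtype=float))
        params = self.params
        return np.array(
            [velocity_no_slip(params, Condition.saturating(F)) for F in force]
        )

    @property
    def fittedvalues(self) -> np.ndarray:
        return self.predict(self.model.data.force)

    @property
    def resid(self) -> np.ndarray:
        return self.model.data.velocity - self.fittedvalues

    @property
    def rmse(self) -> float:
        return float(np.sqrt(np.mean(self.resid**2)))

    def simulate(self, cond: Condition | None = None, seed: int = 0, duration: float = 100.0):
        """Stochastic trajectory under the fitted parameters (flux mode)."""
        from .simulate import SimConfig, simulate

        if cond is None:
            cond = Condition.saturating(0.0)
        return simulate(self.params, cond, SimConfig(seed=seed, duration=duration))

    def summary(self) -> str:
        """Plain-text summary table of the fit."""
        e = self.estimates
        recipe = e.provenance.get("recipe", {})
        lines = [
            "Kinesin-8 walk/slip force-velocity fit",
            "=" * 54,
            f"Observations: {len(self.model.data):>4d}    "
            f"k_D (fixed): {self.model.k_D:g} 1/s    kBT: {self.model.kBT:g} pN nm",
            f"Observed stall force: {self.stall_force_observed:.3f} pN    "
            f"unloaded velocity: {self.v0_unloaded_observed:.2f} nm/s",
            "-" * 54,
            f"{'parameter':<10}{'estimate':>12}{'recipe seed':>14}  units",
        ]
        rows = [
            ("k_plus", e.k_plus, recipe.get("k_plus"), "1/s"),
            ("k_minus", e.k_minus, recipe.get("k_minus"), "1/s"),
            ("E_NL", e.E_NL, recipe.get("E_NL"), "kBT"),
            ("d_plus", e.d_plus, recipe.get("d_plus"), "nm"),
        ]
        for name, value, seed_val, units in rows:
            seed_txt = f"{seed_val:>14.4g}" if seed_val is not None else " " * 14
            lines.append(f"{name:<10}{value:>12.4g}{seed_txt}  {units}")
        lines += ["-" * 54, f"RMSE: {self.rmse:.4g} nm/s"]
        return "\n".join(lines)

    def to_json(self) -> str:
        """JSON estimation report: values, provenance, fit residual scale."""
        e = self.estimates
        payload = {
            "estimates": {
                "k_plus": e.k_plus, "k_minus": e.k_minus,
                "E_NL": e.E_NL, "d_plus": e.d_plus,
            },
            "fixed": {"k_D": self.model.k_D, "d": self.model.d, "kBT": self.model.kBT},
            "observed": {
                "stall_force_pN": self.stall_force_observed,
                "v0_unloaded_nm_per_s": self.v0_unloaded_observed,
            },
            "provenance": e.provenance,
            "rmse_nm_per_s": self.rmse,
        }
        if e.k_bT is not None:
            payload["estimates"]["k_bT"] = e.k_bT
        if e.v_II0 is not None:
            payload["estimates"]["v_II0"] = e.v_II0
        return json.dumps(payload, indent=2, sort_keys=True)

    def plot_fit(self, ax=None):
        """Data vs fitted no-slip force-velocity curve (matplotlib axes)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        data = self.model.data
        ax.plot(data.force, data.velocity, "o", ms=4, label="data")
        grid = np.linspace(data.force.min(), data.force.max(), 200)
        ax.plot(grid, self.predict(grid), "-", label="fit")
        ax.axhline(0.0, color="0.7", lw=0.8)
        ax.set_xlabel("load (pN, forward positive)")
        ax.set_ylabel("velocity (nm/s)")
        ax.legend()
        return ax
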