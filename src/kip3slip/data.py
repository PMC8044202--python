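"""Force-velocity datasets: the estimation module's input format.

An :class:`FVDataset` holds single-molecule-style force-velocity
observations as a pandas DataFrame with columns ``force_pN`` and
``velocity_nm_per_s`` (optionally ``sd_nm_per_s``), plus metadata (ATP
condition, whether the slip contribution is included, generating preset
for synthetic data).  Files are delimited text (comma or tab) with a
required header row; metadata travel as ``#``-prefixed header comments.

No experimental dataset ships with the package: :func:`generate_fixture`
produces synthetic equivalents from known parameters for round-trip
testing of the estimation recipe.
"""

from __future__ import annotations

import dataclasses
import io
import json
import pathlib
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .kinetics import slip_velocity, total_velocity, velocity_no_slip
from .parameters import SATURATING, Condition, MotorParameters, load_parameters

FORCE_COL = "force_pN"
VELOCITY_COL = "velocity_nm_per_s"
SD_COL = "sd_nm_per_s"


@dataclasses.dataclass
class FVDataset:
    """Force-velocity observations plus provenance metadata."""

    table: pd.DataFrame
    metadata: dict[str, Any] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = {FORCE_COL, VELOCITY_COL} - set(self.table.columns)
        if missing:
            raise ValueError(f"dataset is missing required column(s) {sorted(missing)}")
        numeric = self.table[[c for c in (FORCE_COL, VELOCITY_COL, SD_COL) if c in self.table]]
        if not np.all(np.isfinite(numeric.to_numpy(dtype=float))):
            raise ValueError("dataset contains non-finite values")
        self.table = self.table.sort_values(FORCE_COL, kind="stable").reset_index(drop=True)

    @property
    def force(self) -> np.ndarray:
        return self.table[FORCE_COL].to_numpy(dtype=float)

    @property
    def velocity(self) -> np.ndarray:
        return self.table[VELOCITY_COL].to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.table)

    @classmethod
    def from_arrays(
        cls,
        force: np.ndarray,
        velocity: np.ndarray,
        sd: np.ndarray | None = None,
        **metadata: Any,
    ) -> "FVDataset":
        data = {FORCE_COL: np.asarray(force, dtype=float),
                VELOCITY_COL: np.asarray(velocity, dtype=float)}
        if sd is not None:
            data[SD_COL] = np.asarray(sd, dtype=float)
        return cls(pd.DataFrame(data), dict(metadata))

    @classmethod
    def read(cls, path: str | pathlib.Path) -> "FVDataset":
        """Read a delimited-text dataset (comma or tab, sniffed)."""
        path = pathlib.Path(path)
        metadata: dict[str, Any] = {}
        body_lines: list[str] = []
        for line in path.read_text().splitlines():
            if line.startswith("#"):
                stripped = line.lstrip("#").strip()
                if stripped.startswith("{"):
                    metadata.update(json.loads(stripped))
            else:
                body_lines.append(line)
        body = "\n".join(body_lines)
        sep = "\t" if "\t" in body_lines[0] else ","
        table = pd.read_csv(io.StringIO(body), sep=sep)
        return cls(table, metadata)

    def write(self, path: str | pathlib.Path, sep: str = ",") -> None:
        """Write as delimited text with metadata as a ``#`` JSON comment."""
        path = pathlib.Path(path)
        meta = dict(self.metadata)
        meta.setdefault("kip3slip_version", __version__)
        with path.open("w") as fh:
            fh.write("# " + json.dumps(meta, sort_keys=True) + "\n")
            self.table.to_csv(fh, sep=sep, index=False)


def generate_fixture(
    preset: str | MotorParameters,
    noise_sd: float = 0.0,
    seed: int | None = None,
    grid: np.ndarray | None = None,
    atp: float | str = SATURATING,
    quantity: str = "v0",
) -> FVDataset:
    """Generate a synthetic force-velocity dataset from known parameters.

    ``quantity`` selects the generating curve: ``v0`` (walking velocity
    without slip), ``v_total`` (with slip) or ``v_II`` (pure slip
    velocity).  Gaussian noise of standard deviation ``noise_sd`` (nm/s)
    is added with the given seed; metadata record the generating preset,
    condition and seed.
    """
    if noise_sd < 0:
        raise ValueError(f"noise_sd must be non-negative, got {noise_sd}")
    params = load_parameters(preset)
    if grid is None:
        grid = np.arange(-10.0, 10.0 + 1e-9, 0.25)
    grid = np.asarray(grid, dtype=float)
    if quantity == "v0":
        values = np.array([velocity_no_slip(params, Condition(F, atp)) for F in grid])
    elif quantity == "v_total":
        values = np.array([total_velocity(params, Condition(F, atp)).v_total for F in grid])
    elif quantity == "v_II":
        values = np.array([slip_velocity(params, F) for F in grid])
    else:
        raise ValueError(f"unknown quantity {quantity!r}; expected v0, v_total or v_II")
    if noise_sd > 0:
        if seed is None:
            raise ValueError("a seed is required when noise_sd > 0")
        rng = np.random.default_rng(seed)
        values = values + rng.normal(0.0, noise_sd, size=values.shape)
    sd = np.full(grid.shape, noise_sd) if noise_sd > 0 else None
    meta: dict[str, Any] = {
        "preset": preset if isinstance(preset, str) else "custom",
        "parameters": params.to_dict(),
        "atp": atp,
        "quantity": quantity,
        "noise_sd": noise_sd,
        "includes_slip": quantity != "v0",
    }
    if seed is not None:
        meta["seed"] = int(seed)
    return FVDataset.from_arrays(grid, values, sd, **meta)
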