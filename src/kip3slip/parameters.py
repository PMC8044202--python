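"""Motor parameter sets and operating conditions.

The model describes a dimeric kinesin-8 walking hand-over-hand on a
microtubule (binding sites every ``d`` = 8 nm) whose processive runs are
interrupted by brief slip episodes in a weak-binding (both-heads-ADP)
state.  A :class:`MotorParameters` instance carries the full kinetic and
energetic parameter set; a :class:`Condition` fixes one operating point
(external load and nucleotide concentrations).

Saturating ATP is a symbolic limit selected with the :data:`SATURATING`
sentinel, never approximated by a large finite concentration.
"""

from __future__ import annotations

import dataclasses
import json
import math
import pathlib
from typing import Any, Mapping, Union

import yaml

#: Sentinel for the [ATP] -> infinity limit.  Compared with ``is`` or ``==``;
#: the string spelling is what the CLI and config files use.
SATURATING = "saturating"

AtpLike = Union[float, int, str]


def _is_saturating(atp: AtpLike) -> bool:
    return isinstance(atp, str) and atp.lower() == SATURATING


@dataclasses.dataclass(frozen=True)
class MotorParameters:
    """Full kinetic/energetic parameter set of the walk/slip model.

    Parameters
    ----------
    k_D : float
        Rate of ADP release from the microtubule-bound head (s^-1).
    k_plus : float
        Rate of ATP hydrolysis + Pi release in the trailing head, i.e.
        with the neck linker in the forward orientation (s^-1).
    k_minus : float
        Same rate for the leading head (backward neck-linker
        orientation) (s^-1).
    E_NL : float
        Free-energy change of neck-linker docking plus the ATP-induced
        conformational change, as a dimensionless multiple of kBT.
    d_plus : float
        Distance parameter (nm) for the detached head's movement from
        the intermediate (INT) position to the front binding site.
    d_minus : float, optional
        Distance parameter (nm) for movement to the rear binding site.
        Defaults to ``d_plus`` (the model treats the two as equal; the
        value enters no closed-form expression and is kept only for
        forward compatibility).
    v_II0 : float
        Unloaded slip hop rate in the weak-binding state (s^-1).
    k_bT : float
        Second-order ATP binding rate (uM^-1 s^-1).
    k_bD : float
        Second-order ADP binding rate (uM^-1 s^-1).  No measured value
        exists (only that it is much smaller than ``k_bT``); defaults
        to 0 so the slipping time reduces correctly when ADP is absent.
    d : float
        Binding-site spacing along a protofilament (nm), default 8.
    kBT : float
        Thermal energy (pN nm), default 4.1 (about 24 C).

    The slip characteristic distance ``delta`` is defined as ``d/2`` and
    is exposed as a read-only property, never set independently.
    """

    k_D: float
    k_plus: float
    k_minus: float
    E_NL: float
    d_plus: float
    v_II0: float = 0.0
    k_bT: float = 1.0
    k_bD: float = 0.0
    d_minus: float | None = None
    d: float = 8.0
    kBT: float = 4.1

    def __post_init__(self) -> None:
        if self.d_minus is None:
            object.__setattr__(self, "d_minus", self.d_plus)
        for name in ("k_D", "k_plus", "k_minus", "k_bT", "d_plus", "d_minus", "d", "kBT"):
            value = getattr(self, name)
            if not (isinstance(value, (int, float)) and math.isfinite(value) and value > 0):
                raise ValueError(f"{name} must be a finite positive number, got {value!r}")
        for name in ("v_II0", "k_bD", "E_NL"):
            value = getattr(self, name)
            if not (isinstance(value, (int, float)) and math.isfinite(value) and value >= 0):
                raise ValueError(f"{name} must be finite and non-negative, got {value!r}")

    @property
    def delta(self) -> float:
        """Slip characteristic distance delta = d/2 (nm)."""
        return self.d / 2.0

    @property
    def beta(self) -> float:
        """Inverse thermal energy beta = 1/kBT (pN^-1 nm^-1)."""
        return 1.0 / self.kBT

    def replace(self, **changes: Any) -> "MotorParameters":
        """Return a copy with the given fields replaced."""
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, mapping: Mapping[str, Any]) -> "MotorParameters":
        data = dict(mapping)
        delta = data.pop("delta", None)
        params = cls(**data)
        if delta is not None and not math.isclose(delta, params.delta):
            raise ValueError(
                f"delta is defined as d/2 = {params.delta}; got inconsistent value {delta}"
            )
        return params

    @classmethod
    def from_file(cls, path: str | pathlib.Path) -> "MotorParameters":
        """Load a parameter set from a JSON or YAML mapping."""
        path = pathlib.Path(path)
        text = path.read_text()
        if path.suffix.lower() == ".json":
            data = json.loads(text)
        else:
            data = yaml.safe_load(text)
        if not isinstance(data, Mapping):
            raise ValueError(f"{path} does not contain a parameter mapping")
        return cls.from_dict(data)


#: Kip3 parameter values (ADP release 400 s^-1, hydrolysis+Pi 22/45 s^-1
#: for trailing/leading head, neck-linker energy 1.1 kBT, distance
#: parameter 1.7 nm, unloaded slip rate 45 s^-1, ATP binding 1 uM^-1 s^-1).
KIP3_TABLE1 = MotorParameters(
    k_D=400.0,
    k_plus=22.0,
    k_minus=45.0,
    E_NL=1.1,
    d_plus=1.7,
    v_II0=45.0,
    k_bT=1.0,
)


@dataclasses.dataclass(frozen=True)
class SimpleFVParameters:
    """Parameters of the simplified four-parameter force-velocity form.

    ``r0`` is the unloaded stepping ratio, ``F_S`` the stall force (pN);
    ``k_plus``/``k_minus`` as in :class:`MotorParameters`.
    """

    r0: float
    F_S: float
    k_plus: float
    k_minus: float
    d: float = 8.0

    def __post_init__(self) -> None:
        if not self.r0 > 1:
            raise ValueError(f"r0 must exceed 1, got {self.r0}")
        if not self.F_S > 0:
            raise ValueError(f"F_S must be positive, got {self.F_S}")


#: The fitted simplified-form parameter set used alongside the full model
#: (its values are close to, but not exactly, those implied by the full
#: Kip3 set through the closed forms; both are kept as distinct presets).
KIP3_FIG2A_SIMPLE = SimpleFVParameters(r0=1.5, F_S=1.1, k_plus=23.0, k_minus=2.3 * 23.0)

PRESETS: dict[str, MotorParameters] = {"kip3_table1": KIP3_TABLE1}
SIMPLE_PRESETS: dict[str, SimpleFVParameters] = {"kip3_fig2a_simple": KIP3_FIG2A_SIMPLE}


def get_preset(name: str) -> MotorParameters:
    """Look up a named full-model parameter preset."""
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        ) from None


def load_parameters(source: str | pathlib.Path | Mapping[str, Any] | MotorParameters) -> MotorParameters:
    """Resolve a preset name, file path, mapping or instance to parameters."""
    if isinstance(source, MotorParameters):
        return source
    if isinstance(source, Mapping):
        return MotorParameters.from_dict(source)
    if isinstance(source, str) and source in PRESETS:
        return PRESETS[source]
    return MotorParameters.from_file(source)


@dataclasses.dataclass(frozen=True)
class Condition:
    """One operating point: external load and nucleotide concentrations.

    ``F`` is the signed external load in pN, positive in the forward
    direction (toward the microtubule plus end).  ``atp`` is the ATP
    concentration in uM or the :data:`SATURATING` sentinel; ``adp``
    the ADP concentration in uM.
    """

    F: float
    atp: AtpLike = SATURATING
    adp: float = 0.0

    def __post_init__(self) -> None:
        if not math.isfinite(self.F):
            raise ValueError(f"F must be finite, got {self.F!r}")
        if _is_saturating(self.atp):
            object.__setattr__(self, "atp", SATURATING)
        else:
            try:
                atp = float(self.atp)  # type: ignore[arg-type]
            except (TypeError, ValueError):
                raise ValueError(
                    f"atp must be a concentration in uM or {SATURATING!r}, got {self.atp!r}"
                ) from None
            if not (math.isfinite(atp) and atp >= 0):
                raise ValueError(f"atp must be non-negative and finite, got {atp}")
            object.__setattr__(self, "atp", atp)
        if not (math.isfinite(self.adp) and self.adp >= 0):
            raise ValueError(f"adp must be non-negative and finite, got {self.adp!r}")

    @property
    def is_saturating(self) -> bool:
        return _is_saturating(self.atp)

    @classmethod
    def saturating(cls, F: float, adp: float = 0.0) -> "Condition":
        return cls(F=F, atp=SATURATING, adp=adp)
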