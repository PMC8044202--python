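"""Seeded stochastic trajectory simulation of the walk/slip pathway.

Three modes:

``flux``
    The canonical Monte-Carlo oracle for the analytic expressions.
    Forward/backward walking steps are Poisson processes at the analytic
    step fluxes P_E k_T and (1 - P_E) k_L; slip episodes (Period II) are
    a renewal process with exponential durations of mean tau_S (the
    slipping time) whose initiation rate is chosen so that the long-run
    fraction of time spent slipping equals P_II F_II; within an episode
    the motor hops at v_II0 exp(+-beta F delta).  Mean velocity,
    stepping ratio, episode duration and slip displacement therefore
    match the closed forms in expectation by construction.  The walking
    point process is superposed on (not gated by) the slip occupancy
    process, which is what keeps the expectation exact.

``mechanistic``
    An explicit continuous-time Markov chain over the coupling pathway
    sub-states: the INT branch (probability P_E), the ADP-release vs
    hydrolysis races (k_D vs k+-) that open Period II, second-order ATP
    binding at finite [ATP], and slip episodes terminated by ADP release
    plus nucleotide rebinding.  A physical cross-check of the analytic
    approximations; agreement with the closed forms is at the ~10%
    level, not exact.

``slip_only``
    Pure biased hopping at rates v_II0 exp(+-beta F delta): the
    saturating-ADP / no-ATP regime.

All randomness flows from the mandatory seed; identical configurations
produce bit-identical trajectories.
"""

from __future__ import annotations

import dataclasses
import json
import math
import pathlib
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .kinetics import ZeroATPError, rate_breakdown, slipping_time
from .parameters import Condition, MotorParameters

__all__ = [
    "SimConfig",
    "Trajectory",
    "TrajectorySummary",
    "simulate",
    "simulate_slip_only",
    "summarize",
]

WALK_FWD = "walk_forward"
WALK_BWD = "walk_backward"
PII_ENTRY = "periodII_entry"
PII_EXIT = "periodII_exit"
HOP_FWD = "slip_hop_forward"
HOP_BWD = "slip_hop_backward"

MODES = ("flux", "mechanistic", "slip_only")


@dataclasses.dataclass(frozen=True)
class SimConfig:
    """Simulation run configuration.

    Exactly one of ``duration`` (simulated seconds) or ``n_cycles``
    (target ATPase-cycle count, converted through the mean cycle rate)
    must be given.  The seed is mandatory: there is no silent clock
    seeding.
    """

    seed: int
    duration: float | None = None
    n_cycles: int | None = None
    mode: str = "flux"
    record_states: bool = True
    block_count: int = 20

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        if (self.duration is None) == (self.n_cycles is None):
            raise ValueError("give exactly one of duration or n_cycles")
        if self.duration is not None and not self.duration > 0:
            raise ValueError(f"duration must be positive, got {self.duration}")
        if self.n_cycles is not None and not self.n_cycles > 0:
            raise ValueError(f"n_cycles must be positive, got {self.n_cycles}")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")


@dataclasses.dataclass
class Trajectory:
    """Simulated position-time path with state labels.

    ``times`` are strictly increasing event times (s); ``positions`` the
    motor position (nm, integer multiple of the site spacing d) after
    each event; ``events`` the label of each event.  Slip hops occur
    only between a Period-II entry and its closure.
    """

    times: np.ndarray
    positions: np.ndarray
    events: np.ndarray
    duration: float
    metadata: dict[str, Any] = dataclasses.field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.times)

    @property
    def net_displacement(self) -> float:
        return float(self.positions[-1]) if len(self.positions) else 0.0

    def position_at(self, t: np.ndarray | float) -> np.ndarray:
        """Piecewise-constant position sampled at time(s) t."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        idx = np.searchsorted(self.times, t, side="right")
        padded = np.concatenate([[0.0], self.positions])
        return padded[idx]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_s": self.times, "position_nm": self.positions, "event": self.events}
        )

    def write(self, path: str | pathlib.Path) -> None:
        """Export as tab-delimited text with a JSON metadata comment."""
        path = pathlib.Path(path)
        meta = dict(self.metadata)
        meta.setdefault("kip3slip_version", __version__)
        meta["duration_s"] = self.duration
        with path.open("w") as fh:
            fh.write("# " + json.dumps(meta, sort_keys=True) + "\n")
            self.to_dataframe().to_csv(fh, sep="\t", index=False)


@dataclasses.dataclass(frozen=True)
class TrajectorySummary:
    """Stepping and slip statistics of one trajectory.

    ``mean_velocity`` is net displacement over duration (nm/s) with a
    block-averaging standard error; ``stepping_ratio`` counts forward
    over backward position changes (walking steps plus slip hops).
    ``mean_slip_duration`` is NaN when no completed episode exists.
    """

    mean_velocity: float
    velocity_se: float
    n_forward_steps: int
    n_backward_steps: int
    n_slip_episodes: int
    mean_slip_duration: float
    net_slip_displacement: float
    stepping_ratio: float
    duration: float

    def to_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)


def _merge_events(
    times: list[np.ndarray], deltas: list[np.ndarray], labels: list[np.ndarray]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    t = np.concatenate(times) if times else np.empty(0)
    dx = np.concatenate(deltas) if deltas else np.empty(0)
    lab = np.concatenate(labels) if labels else np.empty(0, dtype=object)
    order = np.argsort(t, kind="stable")
    return t[order], dx[order], lab[order]


def _hop_rates(params: MotorParameters, F: float) -> tuple[float, float]:
    x = params.beta * F * params.delta
    with np.errstate(over="ignore"):
        return params.v_II0 * math.exp(x), params.v_II0 * math.exp(-x)


def _poisson_times(rng: np.random.Generator, rate: float, t0: float, t1: float) -> np.ndarray:
    """Event times of a homogeneous Poisson process on [t0, t1)."""
    if rate <= 0 or t1 <= t0:
        return np.empty(0)
    n = rng.poisson(rate * (t1 - t0))
    return np.sort(rng.uniform(t0, t1, size=n))


def _simulate_flux(
    params: MotorParameters, cond: Condition, config: SimConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    bd = rate_breakdown(params, cond)
    a_fwd = bd.P_E * bd.k_T
    a_bwd = (1.0 - bd.P_E) * bd.k_L
    tau_S = slipping_time(params, cond.atp, cond.adp)
    phi = bd.P_II * bd.F_II  # long-run fraction of time in Period II
    # Renewal initiation rate during the non-slipping phase such that the
    # stationary slip occupancy equals phi with mean episode length tau_S.
    lam_ep = 0.0 if phi == 0.0 else phi / ((1.0 - phi) * tau_S)
    h_fwd, h_bwd = _hop_rates(params, cond.F)

    T = config.duration
    if T is None:
        T = config.n_cycles / bd.k_total

    times: list[np.ndarray] = []
    deltas: list[np.ndarray] = []
    labels: list[np.ndarray] = []

    # Walking steps: two independent Poisson processes over the full run.
    for rate, delta, label in ((a_fwd, params.d, WALK_FWD), (a_bwd, -params.d, WALK_BWD)):
        t = _poisson_times(rng, rate, 0.0, T)
        times.append(t)
        deltas.append(np.full(t.shape, delta))
        labels.append(np.full(t.shape, label, dtype=object))

    # Slip episodes: renewal process, episodes never overlap.
    t = 0.0
    while lam_ep > 0.0:
        t += rng.exponential(1.0 / lam_ep)
        if t >= T:
            break
        dur = rng.exponential(tau_S)
        end = min(t + dur, T)
        hop_t = _poisson_times(rng, h_fwd + h_bwd, t, end)
        hop_sign = np.where(
            rng.random(hop_t.shape) < h_fwd / (h_fwd + h_bwd), 1.0, -1.0
        ) if len(hop_t) else np.empty(0)
        ep_times = [np.array([t]), hop_t]
        ep_deltas = [np.array([0.0]), hop_sign * params.d]
        ep_labels = [
            np.array([PII_ENTRY], dtype=object),
            np.where(hop_sign > 0, HOP_FWD, HOP_BWD).astype(object),
        ]
        if t + dur < T:  # completed episode: record its closure
            ep_times.append(np.array([t + dur]))
            ep_deltas.append(np.array([0.0]))
            ep_labels.append(np.array([PII_EXIT], dtype=object))
        times += ep_times
        deltas += ep_deltas
        labels += ep_labels
        t += dur

    t_all, dx_all, lab_all = _merge_events(times, deltas, labels)
    return t_all, dx_all, lab_all, T


def _simulate_slip_only(
    params: MotorParameters, F: float, config: SimConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    h_fwd, h_bwd = _hop_rates(params, F)
    h_tot = h_fwd + h_bwd
    T = config.duration
    if T is None:
        if h_tot <= 0:
            raise ValueError("cannot target a hop count with zero hop rate")
        T = config.n_cycles / h_tot
    t = _poisson_times(rng, h_tot, 0.0, T)
    sign = np.where(rng.random(t.shape) < (h_fwd / h_tot if h_tot > 0 else 0.5), 1.0, -1.0)
    labels = np.where(sign > 0, HOP_FWD, HOP_BWD).astype(object)
    return t, sign * params.d, labels, T


def _simulate_mechanistic(
    params: MotorParameters, cond: Condition, config: SimConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Stage-resolved chain over the coupling-pathway sub-states.

    Each head runs a renewal process of explicit exponential stages
    mirroring its serial turnover sequences: per turnover the
    neck-linker branch is drawn with probability P_E, and the dwell is
    the corresponding stage chain (trailing head after a front binding:
    hydrolysis k+ [plus ATP binding 1/(k_bT [ATP]) at finite ATP];
    after a rear binding: ADP release k_D, ATP binding, hydrolysis k+;
    the leading head mirrors this with k-).  A trailing turnover on the
    front branch advances the motor +d; a leading turnover on the rear
    branch moves it -d; the other two turnover kinds rebind the same
    site and move nothing.

    Period II is entered when hydrolysis + Pi release outruns the
    partner head's ADP release (the k+- vs k_D race) on a stepping
    turnover; an episode has the ADP-lifetime structure of the slipping
    time (hop window of mean 1/k_D, then nucleotide rebinding with ADP
    able to re-open the window) and pauses both heads' clocks.

    The construction makes the walking fluxes and Period-II statistics
    track the closed forms at the ~few-percent level while resolving
    every kinetic stage; the two heads' cycles are treated as
    independent, which is the same idealization the analytic rate
    expressions make.
    """
    kD, kp, km = params.k_D, params.k_plus, params.k_minus
    p_E = rate_breakdown(params, cond).P_E
    h_fwd, h_bwd = _hop_rates(params, cond.F)
    h_tot = h_fwd + h_bwd
    saturating = cond.is_saturating
    if not saturating and float(cond.atp) == 0.0:
        raise ZeroATPError("mechanistic walking mode requires ATP")
    kb_atp = math.inf if saturating else params.k_bT * float(cond.atp)
    kb_adp = 0.0 if saturating else params.k_bD * cond.adp

    T = config.duration
    target_cycles = config.n_cycles
    if T is None:
        T = math.inf

    ev_t: list[float] = []
    ev_dx: list[float] = []
    ev_lab: list[str] = []

    def record(t: float, dx: float, label: str) -> None:
        ev_t.append(t)
        ev_dx.append(dx)
        ev_lab.append(label)

    def atp_stage() -> float:
        return 0.0 if saturating else rng.exponential(1.0 / kb_atp)

    def turnover(head: str) -> tuple[float, bool, bool]:
        """Draw one turnover: (dwell, steps, may_enter_period2)."""
        front = rng.random() < p_E
        if head == "trailing":
            if front:
                return rng.exponential(1.0 / kp) + atp_stage(), True, True
            return (
                rng.exponential(1.0 / kD) + atp_stage() + rng.exponential(1.0 / kp),
                False,
                False,
            )
        if front:
            return (
                rng.exponential(1.0 / kD) + atp_stage() + rng.exponential(1.0 / km),
                False,
                False,
            )
        return rng.exponential(1.0 / km) + atp_stage(), True, True

    def run_episode(t: float) -> float:
        """Slip episode: weak-binding hop windows of mean 1/k_D closed by
        the ATP-vs-ADP rebinding competition (ADP re-opens the window)."""
        record(t, 0.0, PII_ENTRY)
        while True:
            window = rng.exponential(1.0 / kD)
            for ht in _poisson_times(rng, h_tot, t, t + window):
                fwd = rng.random() < (h_fwd / h_tot if h_tot > 0 else 0.5)
                record(ht, params.d if fwd else -params.d, HOP_FWD if fwd else HOP_BWD)
            t += window
            if saturating:
                break
            kb_tot = kb_atp + kb_adp
            t += rng.exponential(1.0 / kb_tot)
            if rng.random() < kb_atp / kb_tot:
                break
        record(t, 0.0, PII_EXIT)
        return t

    t = 0.0
    cycles = 0
    race_prob = {"trailing": kp / (kp + kD), "leading": km / (km + kD)}
    step_delta = {"trailing": params.d, "leading": -params.d}
    step_label = {"trailing": WALK_FWD, "leading": WALK_BWD}
    dwell_t, step_t, pii_t = turnover("trailing")
    dwell_l, step_l, pii_l = turnover("leading")
    next_done = {"trailing": dwell_t, "leading": dwell_l}
    pending = {"trailing": (step_t, pii_t), "leading": (step_l, pii_l)}
    while t < T and (target_cycles is None or cycles < target_cycles):
        head = min(next_done, key=lambda h: next_done[h])
        t = next_done[head]
        if t >= T:
            break
        steps, may_pii = pending[head]
        if steps:
            record(t, step_delta[head], step_label[head])
            if may_pii and rng.random() < race_prob[head]:
                t_end = run_episode(t)
                pause = t_end - t
                t = t_end
                other = "leading" if head == "trailing" else "trailing"
                next_done[other] += pause
        cycles += 1
        dwell, steps, may_pii = turnover(head)
        next_done[head] = t + dwell
        pending[head] = (steps, may_pii)

    T_end = t if math.isinf(T) else T
    t_arr = np.array(ev_t)
    keep = t_arr <= T_end
    dx = np.array(ev_dx)[keep]
    lab = np.array(ev_lab, dtype=object)[keep]
    return t_arr[keep], dx, lab, float(T_end)


def simulate(params: MotorParameters, cond: Condition, config: SimConfig) -> Trajectory:
    """Simulate one trajectory under the given operating point.

    Walking modes (``flux``, ``mechanistic``) require ATP; the no-ATP
    regime is served by ``slip_only`` (see
    :func:`simulate_slip_only`).
    """
    rng = np.random.default_rng(config.seed)
    if config.mode == "flux":
        t, dx, lab, T = _simulate_flux(params, cond, config, rng)
    elif config.mode == "mechanistic":
        t, dx, lab, T = _simulate_mechanistic(params, cond, config, rng)
    elif config.mode == "slip_only":
        t, dx, lab, T = _simulate_slip_only(params, cond.F, config, rng)
    else:  # pragma: no cover - guarded by SimConfig
        raise ValueError(f"unknown mode {config.mode!r}")
    positions = np.cumsum(dx)
    metadata = {
        "mode": config.mode,
        "seed": int(config.seed),
        "F_pN": cond.F,
        "atp_uM": cond.atp,
        "adp_uM": cond.adp,
        "parameters": params.to_dict(),
    }
    if not config.record_states:
        moved = dx != 0.0
        t, positions, lab = t[moved], positions[moved], lab[moved]
    return Trajectory(times=t, positions=positions, events=lab, duration=T, metadata=metadata)


def simulate_slip_only(params: MotorParameters, F: float, config: SimConfig) -> Trajectory:
    """Pure biased hopping at rates v_II0 exp(+-beta F delta).

    The saturating-ADP / no-ATP regime: the empirical hop ratio
    converges to exp(2 beta F delta) and the velocity to the slip
    velocity closed form.
    """
    config = dataclasses.replace(config, mode="slip_only")
    return simulate(params, Condition(F=F, atp=0.0), config)


def summarize(trajectory: Trajectory, block_count: int | None = None) -> TrajectorySummary:
    """Stepping/slip statistics with a block-averaged velocity SE."""
    if len(trajectory) == 0:
        raise ValueError("cannot summarize an empty trajectory")
    T = trajectory.duration
    n_blocks = block_count or 20
    edges = np.linspace(0.0, T, n_blocks + 1)
    samples = trajectory.position_at(edges)
    block_v = np.diff(samples) / np.diff(edges)
    se = float(np.std(block_v, ddof=1) / math.sqrt(n_blocks))
    mean_v = trajectory.net_displacement / T

    events = trajectory.events
    n_wf = int(np.sum(events == WALK_FWD))
    n_wb = int(np.sum(events == WALK_BWD))
    n_hf = int(np.sum(events == HOP_FWD))
    n_hb = int(np.sum(events == HOP_BWD))
    entries = trajectory.times[events == PII_ENTRY]
    exits = trajectory.times[events == PII_EXIT]
    n_completed = min(len(entries), len(exits))
    mean_slip = (
        float(np.mean(exits[:n_completed] - entries[:n_completed]))
        if n_completed
        else math.nan
    )
    d = trajectory.metadata.get("parameters", {}).get("d", 8.0)
    fwd, bwd = n_wf + n_hf, n_wb + n_hb
    ratio = math.inf if bwd == 0 else fwd / bwd
    return TrajectorySummary(
        mean_velocity=mean_v,
        velocity_se=se,
        n_forward_steps=n_wf,
        n_backward_steps=n_wb,
        n_slip_episodes=int(len(entries)),
        mean_slip_duration=mean_slip,
        net_slip_displacement=(n_hf - n_hb) * d,
        stepping_ratio=ratio,
        duration=T,
    )
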