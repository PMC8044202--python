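# Methods

## Model and assumptions

`kip3slip` describes a dimeric kinesin-8 motor on a single microtubule
protofilament with binding sites every d = 8 nm. The chemomechanical
cycle alternates between strong-binding walking states (at least one
head nucleotide-free, ATP- or ADP·Pi-bound) and an occasional
weak-binding state with both heads ADP-bound, in which the dimer slips
along the lattice instead of stepping.

The closed forms rest on these assumptions:

* Hydrolysis + Pi release is rate-limiting and depends only on
  neck-linker orientation: k⁺ in the trailing head, k⁻ in the leading
  head. ADP release (k_D) is orientation-independent, and neck-linker
  docking is much faster than k⁺, k⁻, k_D, so the front/rear branch of
  the detached head resolves instantaneously with probability
  P_E(F) = σ(E_NL + βF d⁺) (logistic σ; E_NL in k_BT units).
* The per-head ATPase rates combine the serial stages harmonically;
  at finite [ATP] a second-order binding stage 1/(k_bT[ATP]) is added
  in series and the finite forms converge to the saturating ones as
  [ATP] → ∞. Saturating ATP is a symbolic limit selected by the
  `"saturating"` sentinel, never a large finite number.
* The weak-binding slip state ("Period II") is entered when hydrolysis
  outruns the partner's ADP release (the k±-vs-k_D race); slips from
  the other weak period are neglected, as is motor dissociation.
  Slip hopping is biased by the load over a symmetric potential:
  rates v_II⁰ e^(±βFδ), δ = d/2, hop size d.
* The external load acts on the stalk; positive F is toward the plus
  end.

## Parameters

| name | meaning | default (Kip3 preset) | units |
|------|---------|----------------------|-------|
| k_D | ADP release from the MT-bound head | 400 | s⁻¹ |
| k⁺ | hydrolysis + Pi release, trailing head | 22 | s⁻¹ |
| k⁻ | hydrolysis + Pi release, leading head | 45 | s⁻¹ |
| E_NL | neck-linker docking + ATP-induced conformational energy | 1.1 | k_BT |
| d⁺ | INT → front-site distance parameter | 1.7 | nm |
| d⁻ | INT → rear-site distance parameter | = d⁺ | nm |
| v_II⁰ | unloaded slip hop rate | 45 | s⁻¹ |
| k_bT | second-order ATP binding | 1 | µM⁻¹s⁻¹ |
| k_bD | second-order ADP binding | 0 | µM⁻¹s⁻¹ |
| d | lattice spacing | 8 | nm |
| k_BT | thermal energy | 4.1 | pN·nm |

Notes on the defaults:

* k_BT = 4.1 pN·nm corresponds to ≈24 °C; it is configurable because
  the temperature is not pinned by the model itself.
* k_bD has no measured value, only the constraint k_bT ≫ k_bD; the
  default 0 makes the slipping time exactly independent of [ADP], and
  any positive override restores the [ADP] dependence of τ_S.
* d⁻ enters no closed form (the Boltzmann split already encodes
  d⁻ ≈ d⁺); it is stored and documented as inert.
* δ is defined as d/2 and cannot be set independently.

A second, simplified parameterisation (`KIP3_FIG2A_SIMPLE`: r₀ = 1.5,
F_S = 1.1 pN, k⁺ = 23 s⁻¹, k⁻ = 2.3 k⁺) drives the four-parameter
force–velocity form v₀ = (r^x − 1)/(r^x + k⁺/k⁻)·k⁺d with
x = 1 + F/F_S. The two presets are deliberately kept distinct: the
simplified-form fit values are close to, but not exactly, what the full
preset implies through the closed forms (r₀ → 1.469, F_S → 0.927 pN
from the stall relation). The exponent is written 1 + F/F_S so that
the curve stalls at F = −F_S under the forward-positive convention;
the equivalent derivation is r(F) = r₀ e^(βFd⁺) = r₀^(1+F/F_S).

Two further conventions: the logarithm in the stall-force relation
F_S = k_BT[E_NL + ln(k⁺/k⁻)]/d⁺ is natural, and the unloaded-velocity
closed form [e^(E_NL)k⁺ − k⁻]/[e^(E_NL) + 1] carries the factor d
required for dimensional consistency with the flux-difference velocity.

## Numerical choices

* P_E is evaluated as a logistic (`scipy.special.expit`), so |F| up to
  10³ pN yields probabilities in [0, 1] without overflow. Exponential
  factors in ratios may overflow; they return the `inf` sentinel (or
  0.0 on the other side) rather than raising, so curve scans never
  abort. A stepping ratio whose denominator is exactly zero (P_E = 1)
  is likewise `inf`.
* The stall force is found by Brent root-finding on [−3, 0] pN
  (widened to [−20, 0] if the bracket fails), converged to
  |v| < 10⁻⁶ nm/s; the closed-form relation above is reported as the
  analytic seed. With slip included the stall is smaller in magnitude
  (0.975 vs 1.051 pN for the Kip3 preset) because backward-load slip
  hops are net backward.
* Zero ATP in a walking-mode quantity raises `ZeroATPError`: turnover
  and the slipping time are undefined there, and the no-ATP regime is
  served by the slip-only simulator mode.
* The Period-II occurrence probability and lifetime fraction coincide
  exactly at saturating ATP; the finite-ATP lifetime fraction weighs
  the 1/k_D dwell against the full per-branch cycle time including the
  ATP-binding stage.

## Slip-state diffusion: a factor-of-two convention

The slip velocity and hop-ratio expressions force per-direction hop
rates v_II⁰ e^(±βFδ), i.e. a total unloaded hop rate of 2 v_II⁰. The
textbook-style chain v_II⁰ = d/t₀, d² = 2Dt₀ instead treats v_II⁰ as
the total hop rate and yields D = v_II⁰d²/2 = 1440 nm²/s for the Kip3
preset; the true diffusion coefficient of the model's two-sided
hopping is v_II⁰d² = 2880 nm²/s. Both cannot hold at once.
`slip_diffusion_constant` returns the per-direction (chain) form
v_II⁰d²/2, and the simulator tests verify that the measured MSD-based
coefficient equals exactly twice that value — the consistent
coefficient of the hopping dynamics the velocity expressions demand.

## Estimation recipe

With k_D fixed from the mean slip duration (τ_S = 1/k_D at saturating
ATP), four parameters shape the no-slip force–velocity curve, each
pinned by one data feature:

1. k⁺ and k⁻ from the mean plateau velocities over the extreme 10%
   (configurable) of the sampled load range on each side, divided
   by d. The backward plateau carries a known finite-load bias
   (≈ 10% at −10 pN; the asymptote converges slowly on that side).
2. E_NL by inverting the unloaded-velocity closed form; a finite
   solution requires −k⁻d < v₀(0) < k⁺d.
3. d⁺ by inverting the stall relation, with F_S read from the data's
   zero crossing by linear interpolation between the bracketing loads.
4. Optionally k_bT from the [ATP] at which the unloaded velocity
   halves (scalar root solve), and v_II⁰ by linear least squares
   against slip-velocity data.

`ForceVelocityModel.fit()` then polishes (k⁺, k⁻, E_NL, d⁺) by
Levenberg–Marquardt least squares of the full no-slip expression over
the dataset, seeded by the recipe values — the "adjust slightly around
the estimates" step — in log-parameters to preserve positivity. The
recipe estimates are always retained in the provenance; `refine=False`
returns them as the fit. The least-squares objective (unweighted
velocity residuals) is this package's choice; nothing in the model
prescribes one.

Fitting requires load coverage to at least ±2 F_S for the asymptotes;
a dataset missing one side raises an error naming it.

## Simulator

All modes draw every random number from one `numpy` generator seeded
by the mandatory `SimConfig.seed`; identical configurations give
bit-identical trajectories. Positions change by exactly ±d; slip hops
occur only between a Period-II entry and its closure.

**flux** (default) is the Monte-Carlo counterpart of the closed forms,
exact in expectation by construction: forward/backward walking steps
are Poisson processes at the analytic fluxes P_E k_T and (1−P_E) k_L,
and slip episodes form a non-overlapping renewal process with
exponential durations of mean τ_S whose initiation rate
λ = φ/[(1−φ)τ_S], φ = P_II F_II, makes the stationary slip occupancy
exactly φ; hops run at v_II⁰e^(±βFδ) throughout an episode. The
walking point process is superposed on, not gated by, the slip
occupancy — that superposition is what keeps the velocity, stepping
ratio, episode duration and slip displacement simultaneously exact in
expectation. (Gating walking during episodes would bias the walking
term by the occupancy φ ≈ 0.4%, far below the simulation's resolution,
but the oracle is kept exact on principle.)

**mechanistic** resolves every kinetic stage: each head runs a renewal
process of explicit exponential stages mirroring its serial turnover
sequences (hydrolysis; ADP release + ATP binding + hydrolysis on the
other branch), with the neck-linker branch drawn per turnover, Period
II entered on the k±-vs-k_D race, and episodes — hop windows of mean
1/k_D closed by the ATP-vs-ADP rebinding competition — pausing both
heads' clocks. It treats the two heads' cycles as independent, the
same idealisation the analytic rate expressions make, and agrees with
the closed forms to within ~7% over loads ∓0.5 pN and 10 µM–saturating
ATP. A fully coupled two-head chain (tracking both nucleotide states
jointly) was prototyped and deviates from the analytic velocity by up
to ~20% at intermediate [ATP] — a real limitation of the parallel-flux
approximation underlying the closed forms, which is why the
stage-resolved form, not the coupled chain, ships as the cross-check.

**slip_only** is pure biased hopping (the saturating-ADP / no-ATP
regime), generated as an exact Poisson construction.

`summarize` reports the mean velocity (net displacement over duration)
with a block-averaging standard error (20 blocks by default), walking
step and slip-hop counts, the empirical stepping ratio (forward over
backward position changes), episode count and mean duration
(NaN when no episode completed), and net slip displacement.
Episode durations are taken from completed entry/exit pairs; an
episode truncated by the end of the run is counted but not timed.

## Synthetic data

`generate_fixture` evaluates the chosen closed-form curve (no-slip,
with-slip, or pure slip velocity) on a load grid — by default
[−10, 10] pN in 0.25-pN steps, wide enough to expose both asymptotes
and the stall crossing — and adds seeded Gaussian velocity noise
(2 nm/s in the robustness tests, the scale of single-molecule
force–velocity scatter). This emulates the *shape* of optical-trap
force–velocity data but none of its other features: no heteroscedastic
noise, no load-dependent sampling density, no attachment-duration
censoring, no drift. Passing round-trip tests therefore demonstrates
the internal consistency of recipe and model, not robustness to every
artefact of real trap data.

## Problem sizes

The simulator-vs-analytic checks use 10⁴ cycles per operating point on
a 3×3 load/ATP grid and the diffusion check a single 1500-s slip-only
trajectory (≈1.3×10⁵ hops), sizes at which the 3-SE and 10% bands are
decisive; the noise-robustness check uses 100 replicates of the
81-point force–velocity grid.

## Known limitations

* No motor dissociation, run-length statistics, or microtubule
  depolymerase activity; no Period-I slip contribution; no explicit
  energy-landscape quantities (they enter no closed form).
* The printed identity between the Period-II occurrence probability
  and its lifetime fraction at saturating ATP is implemented as
  printed; a derivation distinguishing them would change the slip
  term's weighting (the finite-ATP fraction does distinguish the
  forms, and its saturating limit confirms the identity).
* The estimation recipe's plateau rule and the refinement objective
  are operational choices; uncertainty is available only by
  replication over synthetic datasets.
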