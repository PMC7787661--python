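# Methods

## Overview

`reachopt` studies how the speed-accuracy tradeoff (Fitts' law) can arise
from *motor planning variability* — the run-to-run scatter of a stochastic
trajectory optimizer — rather than from signal-dependent execution noise.
There is no noise anywhere in the forward dynamics: every source of
variability is the optimizer's random search.  The package contains two
largely independent pipelines:

1. a biomechanical pipeline: a planar two-joint arm driven by lumped
   Hill-type muscles, controlled by B-spline excitation plans found with
   CMA-ES under a gated accuracy/effort/time cost; and
2. a neural-analysis pipeline: variance measures of a preparatory
   population state and its coupling to movement duration, exercised on
   synthetic trial sets with closed-form ground truth.

## The plant

The arm is a desk-scale stand-in for a 47-muscle, 5-degree-of-freedom
upper-extremity model: two rigid links (lengths 0.30/0.33 m, masses
2.0/1.5 kg, rod inertias, COM at mid-link) moving in a horizontal plane
(gravity off by default; a flag enables it), with viscous joint damping
1.5 N·m·s/rad and joint-limit box (−1.0, 3.0) × (0.0, 2.9) rad.  Dynamics
are the standard two-link manipulator equations (mass matrix,
Coriolis/centrifugal terms, damping, optional gravity); generalized torques
are clipped to ±50 N·m before use, which also defines the torque-actuated
model variant.

Six lumped muscles actuate the arm: shoulder flexor/extensor, elbow
flexor/extensor, and a biarticular flexor/extensor pair, with constant
moment arms (0.025–0.04 m, signed per joint).  Muscle tension is

    F = a · Fmax · fl(l̃) · fv(ṽ) + Fmax · fp(l̃)

with activation `a` following first-order dynamics (τ_act 15 ms,
τ_deact 50 ms), a Gaussian active force–length curve `fl` (width 0.45,
peak 1 at optimal length), a Hill force–velocity curve `fv` (zero at the
maximal shortening velocity of 10 optimal lengths/s, eccentric branch
saturating at 1.5× isometric), and a passive quadratic term above optimal
length (coefficient 0.5).  Fiber length is an affine function of joint
angles through the constant moment arms, with optimal length at the
reference posture (shoulder 45°, elbow 90°), which is also the start pose
for all reaches.  Ablation flags freeze `fl` ≡ 1 ("unrealistic
force–length"), `fv` ≡ 1, remove the biarticular pair, or switch to direct
torque actuation.

Integration is fixed-step semi-explicit Euler (velocity before position)
at dt = 1 ms.  A compiled kernel (numba) runs the step loop; a pure-Python
reference built from the public per-step functions is asserted equivalent
in the test suite, and step-halving convergence is checked against dt/2 and
dt/4.

Why damping 1.5: at light damping (~0.3) reduced-budget solutions wobble
through the target region repeatedly, while very heavy damping (≥3)
suppresses the force–velocity braking signature that produces the
velocity-profile asymmetry.  1.5 N·m·s/rad gives overdamped settling
without erasing that signature; it was fixed once, before the acceptance
suite was frozen, and is configuration rather than contract.

## Control plans and cost

Excitations are clamped cubic B-splines with knots every 0.1 s (the last
segment is shortened when the horizon is not a multiple of 0.1 s), one knot
row per actuator; spline outputs are clipped to [0, 1] (muscle) or [−1, 1]
scaled by ±50 N·m (torque).  The optimizer searches the unbounded knot
space; clipping is the only bound mechanism.

A rollout is scored by

    F = w1·‖h_N − h*‖² + w2·δ(Σᵢ‖aᵢ‖², ζ) + w3·Σᵢ l(qᵢ)
        + w4·δ(‖q̇_N‖², ζ) + w5·ρ(q_N) + w_time·Σᵢ [‖hᵢ − h*‖ ≥ κ]

with w1..w5 = 5, 1e−3, 1e−5, 0.15, 0.5, gate tolerance ζ = 0.025 m, gate
constant C = 1e6, and target radius κ = W/2.  δ(x, ζ) returns x if the
final miss distance is below ζ and C otherwise, for both gated terms: any
trajectory that fails to end near the target costs ≥ 151,000, far above
any hit, so accuracy is optimized before effort or terminal stillness.
`l` is a quadratic joint-limit penalty; ρ, a squared deviation of one
designated terminal joint coordinate, generalizes a terminal-posture
(pronation) term that has no coordinate in a planar arm and is disabled by
default.  In "hit-radius" mode w1 is zeroed once the hand ends inside κ.

The per-step out-of-target weight `w_time` = 0.2 is not printed anywhere in
the source material; it was calibrated once so the duration term dominates
the effort term for realistic reaches (tens of units vs. <1) while staying
orders of magnitude under the C-gates, and it is recorded in every run
record.

Movement duration is read out as the time the hand *first* enters the
target region.  A hold-at-target reading (first entry after which the hand
never exits) was tried and rejected: because the δ-gates act on the final
time step, reduced-budget solutions organize themselves to arrive by t = T,
which pins the hold-reading MD to the horizon (≈0.95 s at every width,
with variance *decreasing* for smaller targets) and destroys the very
statistics under study.  First entry matches the protocol sentence the
cost function implements (a per-step penalty until the target is reached)
and yields the expected pattern.

## Optimization

CMA-ES is implemented in-package (standard (μ/μ_w, λ) strategy with
cumulative step-size adaptation and rank-one + rank-μ covariance updates;
`cma` is not a dependency).  Defaults: population 20, σ0 = 0.2 in knot
units, all knots initialized at 0.1.  The *reduced* preset runs 40
iterations (800 rollouts); the *standard* preset 500 iterations (10,000
rollouts, 12.5× more).  The reduced preset is the package default — the
speed-accuracy results survive it, and it keeps the full protocol suite in
minutes on one core.  Ensembles derive run seeds as
`base + i·10007`; everything downstream is reproducible from (config,
base seed).

## Experiments

**Fitts protocol.** Amplitude fixed at A = 0.15 m (target due +x of the
start hand position — the coordination this demands proved well
conditioned for the lumped muscle set), 10 log-spaced widths from 0.16 m
to 0.0141 m (index of difficulty 0.9–4.41 bits), horizon T = 1.0 s,
duration penalty on, 10 runs per width.  Runs whose hand never enters the
target are excluded from MD statistics but counted against the hit rate;
widths with <2 entering runs are excluded from the fit.  MD = a + b·ID is
fit by ordinary least squares on per-width means.

Typical desk-scale outcomes (reduced preset): b ≈ 0.11–0.18 s/bit (inside
the published human range 0.0393–0.1987), R² ≈ 0.74–0.95, MD SD at the
smallest width ≈ 0.35–0.39 s versus ≈ 0.02–0.05 s at the widest.  Note a
statistical consequence of that variability: with adjacent-width mean MD
gaps of b·0.39 ≤ 0.08 s and hard-width mean standard errors of ~0.11 s at
10 runs, *strictly* monotone per-width means are not a reliable event at
this ensemble size — rank correlations of 0.92–0.99 are the expected
regime, not exactly +1.

**Velocity-profile asymmetry.** Fixed-horizon reaches (duration term off,
hit-radius mode on) at prescribed MDs 0.18/0.22/0.26 s to a 4 cm target,
20 runs each; the lowest-cost solution per MD is summarized by its
normalized speed profile (speed/peak vs. time/MD), the relative peak time,
and the count of interior local minima after a 5%-window moving-average
smooth restricted to 5–95% of the movement.  With muscles the peak time
decreases from fast to slow (≈0.68/0.55/0.30 at the default seed; published
values 0.66/0.51/0.40); the torque and fv ≡ 1 variants lose the ordering —
the eccentric force–velocity branch is the mechanism, since late braking
is cheap only when lengthening antagonists gain force with speed.

**Ablation grid.** Under the Fitts protocol the muscle-based ablations
(fl ≡ 1, biarticular pair removed, no-effort cost) retain a Fitts-like
fit — positive slopes of 0.10–0.16 s/bit with R² ≈ 0.54–0.66 at 5
runs/width.  The torque variant does *not* reproduce a Fitts fit at desk
scale (R² ≈ 0.2 at either optimizer budget): ±50 N·m of raw, un-filtered
torque on a two-link arm of total inertia ~0.25 kg·m² is powerful enough
that even the smallest target is acquired directly once the optimizer is
given a standard budget, so no difficulty gradient survives.  This is a
known divergence of the desk-scale plant from full-scale results, where
the same torque limit is a modest actuation level; it is documented rather
than hidden by re-scaling the printed torque limit.

**Reference correlation.** If a behavioral CSV
(subject, index_of_difficulty, movement_duration) is supplied, model
means/SDs are interpolated onto the reference ID grid and Pearson
correlations reported.  No such dataset ships with the package.

## Synthetic neural data and the preparatory pipeline

Each trial draws a latent preparatory state z ~ N(μ_c, s_c²·I_d) (d = 3),
observed as 192 channel rates `max(0, baseline + L·z + ε_obs)` with a
shared random-orthonormal loading matrix scaled to 60 Hz per latent unit,
channel baselines uniform in 12–42 Hz, and Gaussian observation noise of
2 Hz on the 200-ms-window rates (a Poisson spike-count option exists
behind a flag).  MD couples linearly to the latent state plus execution
noise: MD = m_c + βᵀz + ε.  The true explained fraction
Var(βᵀz)/(Var(βᵀz)+σ_ε²) is available in closed form, which is what the
parameter-recovery tests exercise (median estimate within ±0.1 of
0.2/0.4/0.6/0.8 at 200 trials).

The two-condition generator targets the published MD moments — large
target 461 ± 234 ms with true explained fraction 0.45, small target
661 ± 258 ms with 0.60 — with the small condition's latent covariance
scaled to 0.6× the large one's.  Matching those first and second moments
while keeping the latent covariance *smaller* for the small target forces
the latent→MD coupling gain to differ by condition; that is a deliberate
generator property, not an estimate from data.

Pipeline estimators: preparatory variability is the volume (4/3)π·σ1σ2σ3
of the error ellipsoid spanned by the top-3 principal components (a warning
— not an error — fires if they capture <80% of variance; rank-deficient
clouds return volume 0); volumes are reported normalized by the maximum
across conditions.  The proportion of MD variance explained by the
preparatory state projects trials onto the top-k PCs (smallest k capturing
≥80%, capped at 10) and uses leave-one-out cross-validated linear
regression (closed form via the hat matrix), reporting
max(0, 1 − PRESS/TSS) — a reimplementation choice validated by parameter
recovery rather than by matching any animal's numbers.  MD variances are
compared with a two-sided two-sample F-test.

## Numerical choices and degenerate inputs

- Spline evaluation is clamped-uniform cubic; constant knots reproduce a
  constant exactly (partition of unity) and evaluation outside [0, T]
  raises.
- Ties in `best_of` go to the smaller seed; ensembles share no state.
- A diverged rollout (non-finite state) raises with the step index during
  simulation and is scored 10·C inside the optimizer (flagged, not fatal).
- Zero-variance MDs, rank-<3 state clouds, all-zero volumes, and
  empty ensembles raise informative errors rather than returning NaNs.
- All randomness flows through `numpy.random.default_rng` seeds; repeated
  calls are bit-identical.

## What the synthetic data does and does not show

The generators reproduce the *statistical structure* the analyses assume —
low-dimensional latent states, linear MD coupling, condition differences in
covariance scale — so green tests demonstrate estimator correctness and
the pipeline's ability to recover known ground truth.  They do not
demonstrate anything about real motor cortex: temporal dynamics within the
preparatory window, non-Gaussian rate statistics, behavioral confounds,
and electrode nonstationarities are all absent.  Likewise the planar
two-muscle-per-joint arm preserves the mechanisms credited for the
behavioral effects (redundancy, force–length/velocity, biarticularity) but
not the geometry or scale of a human arm, so quantitative agreement with
published human coefficients is expected only at the order-of-magnitude
level; the package's claims are about patterns (slopes within human range,
orderings, variance directions), not digits.

## Problem sizes

Default protocol sizes were chosen so the complete test suite runs in
roughly ten minutes on one core: 10 widths × 10 runs × 800 rollouts of
1000 steps for the Fitts grid, 3 MDs × 20 runs for the asymmetry protocol,
200–500 trials × 192 channels for the neural analyses.  All sizes are
configuration.
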