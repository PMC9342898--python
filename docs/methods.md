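# Methods

This note documents the models behind each module, the parameters that
matter (units, defaults, rationale), the numerical choices, and what the
synthetic-data generators do and do not emulate. Nothing here states an
empirical result beyond what the test suite and `scripts/acceptance.py`
themselves compute.

## Activation scheme (`kinetic_model`)

Species: back-folded tail `F`, free partner `P`, bound-folded encounter
complex `FP`, bound-unfolded tail `UP`, tail dimer `D2` (concentrations in
µM, time in s). Induced fit:

    F + P ⇌ FP   (k_on, k_off)        FP → UP   (k_unfold)
    UP + UP → D2 (k_dimer)

Conformational selection replaces the first step with spontaneous opening
`F ⇌ U` (`k_open`, `k_close`) followed by capture `U + P ⇌ UP`.

Assumptions: unfolding is irreversible (observed transients plateau, and
the activated state is treated as committed); one partner per tail
protomer, so a dimer carries two partners; partner concentrations are
those of the functional (dimeric) species in the mixing chamber;
calcium–calmodulin regulation and the motor's ATPase cycle are outside
the model.

Defaults `k_on = 1.65 µM⁻¹s⁻¹`, `k_off = 3.2 s⁻¹`, `k_unfold = 2.2 s⁻¹`
are the measured binding rate law and unfolding rate of the NDP52·tail
system; `K_d = k_off/k_on ≈ 1.94 µM`. `k_dimer` (default 10 µM⁻¹s⁻¹) and
the conformational-selection rates are not measured quantities; the
conformational-selection default `k_close = 10 k_open` keeps the folded
state favored, which is all the qualitative mechanism discrimination
needs.

Under pseudo-first-order conditions (P in excess) the linearized
binding/unfolding system relaxes with eigen-rates

    λ_fast + λ_slow = k_on[P] + k_off + k_unfold
    λ_fast · λ_slow = k_on[P] · k_unfold

computed in closed form (stable quadratic evaluation: the product
identity holds to machine precision). The discriminating signature:
induced fit predicts λ_fast linear in [P] and λ_slow rising toward
`k_unfold`; conformational selection predicts a slow phase
`k_open + k_close·K_d/(K_d + [P])` that *falls* toward `k_open`.

A subtlety the tests respect: the dimer-FRET observable relaxes at
λ_slow, not at `k_unfold` itself, and λ_slow → `k_unfold` only at
saturating partner. The concentration-independent single-exponential
dimer signal therefore emerges in the regime `[P] ≫ K_d` *and*
`k_dimer·[tail] ≫ k_unfold`; at 1 µM tail this needs `k_dimer` well above
the default (the dimerization-rate test uses 1000 µM⁻¹s⁻¹ and 20–80 µM
partner). At the default `k_dimer = 10` the second-order dimer flux is
itself rate-limiting at micromolar tail.

Integration: LSODA (stiff-capable, adaptive) with `rtol = 1e-10`,
outputs interpolated onto the caller's grid; mass conservation of tail
and partner is verified to a relative drift below 1e-6. Probe models map
species to fluorescence linearly: partner-FRET weights `FP > UP` (rise
then partial fall), the calmodulin-environment probe distinguishes only
folded vs unfolded, and tail-tail FRET reports `D2` alone.

## Stopped-flow phase analysis (`transient_fit`)

Each phase is modelled as `y = offset + A(1 − e^{−k t'})` and fitted by
Levenberg–Marquardt with deterministic initial guesses (rate from a
log-linear fit of the residual-to-plateau, amplitude/offset from the
window endpoints). Points before the 2 ms instrument dead time are always
excluded; fits whose realized signal change is under twice the residual
RMS are rejected as noise; windows shorter than `3/k_obs` carry a flag.

Biphasic traces are split at the peak of a 5-sample moving-average
smoothed copy. Fitting each phase on its literal window alone is biased
by cross-phase leakage (the slow phase's early tail is nearly linear
inside the rise window), so `analyze_biphasic` subtracts the currently
fitted counterpart exponential before each phase fit and iterates the
pair (3 rounds). Both phases belong to the same exponential family, so on
a clean two-exponential trace this coordinate iteration converges to the
exact decomposition while each rate is still estimated on its own time
scale. The fall window starts three fast-phase time constants past the
peak.

`kobs_regression` averages replicates at the `k_obs` level, fits the
straight line to per-concentration means by weighted least squares
(weights `1/SEM²` when every concentration has ≥2 replicates and a
nonzero SEM, unweighted otherwise), and propagates
`K_d = intercept/slope` errors by the delta method including the
parameter covariance. A phase is called concentration independent when
the 95% slope CI contains zero *or* the slope accounts for under 10% of
the mean `k_obs` across the range — a dual criterion because a shallow
but significant slope on a large offset is still, operationally, an
independent rate.

## Equilibrium titrations (`equilibrium_titration`)

The donor-labelled tail (fixed total `D`) is titrated with
acceptor-labelled CBD (total `A`); at totals comparable to K_d the
complex follows the tight-binding root

    [C] = (S − √(S² − 4DA))/2,  S = D + A + K_d,

evaluated in the cancellation-free form `2DA/(S + √(S² − 4DA))` — exact
at `K_d = 0` (stoichiometric limit) and accurate for K_d far above the
totals. Only this root respects `[C] ≤ min(D, A)`; the other violates
mass balance.

Direct-excitation correction subtracts a linear fit of the acceptor-only
control versus acceptor total; without a control, the slope of the three
highest-acceptor points of the saturated titration is used and the result
flagged. Fits report standard errors, and a K_d pinned at the working
bounds (1e-3, 1e3 µM) is flagged unidentifiable.

Competition (partner sequestering the CBD) solves the scalar mass balance
`a + D_t a/(a+K_p) + C_t a/(a+K_c) = A_t` for free acceptor by bracketed
root finding (Brent, machine-precision tolerances); at zero competitor it
reduces exactly to the quadratic isotherm. The competitor affinity
defaults to 1.94 µM (the kinetically determined NDP52·CBD K_d) and is a
configuration value, not a fitted one.

## Steady-state ATPase (`atpase`)

NADH-coupled assay: turnover `= |dOD340/dt| / (ε·l) / [myosin]` with
`ε = 6220 M⁻¹cm⁻¹` and 1 cm path (standard coupled-assay constants,
overridable). The slope is taken on the longest window with linear R² ≥
0.99 and ≥ 60 s. Activation series are fitted to
`Rate = V₀ + k_cat[Actin]/(K_actin + [Actin])`; the zero-actin point
anchors `V₀`, and a grid that does not reach `K_actin/2` flags the
half-saturation constant unidentifiable. The gating ratio
`k_cat(dimer)/k_cat(monomer)` is annotated gating-consistent at ≤ 0.7 —
between the ideal one-head-at-a-time value of 0.5 and unity.

The generator's `K_actin = 8 µM` and `V₀ = 0.2 s⁻¹` are fixture values
chosen so a 0–30 µM actin grid identifies all three parameters; only
`k_cat` carries measured per-construct values (4.1 full-length, 4.4 for
the 1–814 motor, 2.79 for the 1–1060 constitutive dimer, 2.11 with
NDP52, 2.55 with tDab2, all s⁻¹).

## SMLM point patterns (`smlm_cluster`)

Coordinates in nm, 2D, channels symmetric. Edge handling is by guard
margin rather than analytic correction: Ripley's K accumulates ordered
pairs whose first point lies at least `r_max` inside the ROI boundary,

    K(r) = A · n_pairs(r) / (n_interior · (n − 1)),   L = √(K/π),

which keeps the estimator exactly reproducible by a brute-force double
loop (asserted in the tests) at the cost of discarding a margin the
synthetic ROIs are generated to afford. `L(r) − r` is zero in expectation
under CSR; a simulation envelope (max-|L−r| quantile over seeded CSR
draws) provides the null band.

Cluster maps use DBSCAN with a minimum cluster size of five molecules;
the neighborhood radius defaults to the mean localization precision, but
the analysis pipeline derives it from the data as **half the radius of
the L(r) − r peak**. Rationale: the peak radius tracks the cluster
*domain* scale (roughly the diameter for Gaussian clusters); used
directly it over-merges dense background, while at half the peak radius
intra-cluster neighbors dominate. This Ripley-informed radius is what
makes the planted in-cluster fraction recoverable within ±5 points across
sparse and dense patterns — at a fixed 20 nm radius, clusters with an
effective 36 nm spread are mostly invisible to a five-point density
criterion. Cluster area is the convex hull of members (degenerate hulls
score zero); a contour-density area would be display-oriented and is not
implemented.

DoC scoring: for every localization, the local densities of both channels
are evaluated at radii 20, 40, …, 500 nm (counts/πr², self excluded in
the point's own channel); the score is the Spearman rank correlation of
the two density profiles damped by `exp(−d/r_max)`, with `d` the distance
to the nearest other-channel localization. Constant profiles (e.g. an
empty neighborhood) get score 0. A point is colocalized above 0.4; a
cluster is colocalized when ≥ 10 of its members are — published defaults
of the reference colocalization workflow.

## 3D single-particle tracking (`spt_msd`)

Time-averaged MSD over overlapping windows, lags up to a quarter of the
track length (≥ 3 lags); the anomalous model is fitted as a log-log
linear regression, `α` the slope and `D = e^{intercept}/(2·dim)` with
`dim = 3`. No offset term by default: the model statement is bare
anomalous diffusion, and an optional constant-offset fit would trade bias
for variance on 50-frame tracks. Interpretation: `α < 1` confined,
`α ≈ 1` Brownian, `α > 1` directed. Localization noise adds `2·dim·σ²`
to every lag (verified analytically on stationary tracks); at the study
conditions (σ = 20 nm against ~0.17 µm² first-lag MSD) this is a ~1%
perturbation.

Mobility classes bin per-track D at 0.1 and 2 µm²s⁻¹; the outer classes
use strict inequalities, so boundary values fall in the middle class.
Turning angles are signed 2D angles on the xy projection in [0°, 360°)
(planar roseplot convention; straight = 0°, reversal = 180°), with an
unsigned 3D variant available; zero-length displacements are skipped.

Track import (`filter_tracks`) splits at frame gaps and at consecutive
displacements above 0.4 µm (the linking limit of the upstream tracking
software) and drops segments under 10 frames. Generated ensembles are
analysed with the step split disabled: a synthetic track is a single
particle by construction, and re-splitting a D ≈ 0.3 µm²s⁻¹ ensemble at
0.4 µm selects small-step segments and biases α upward.

## Synthetic data (`synthetic_data`)

All generators draw from one `numpy` Generator seeded by the config;
identical configs give bit-identical outputs, and every emitted file
carries its generating truth in a JSON sidecar.

* **Stopped flow** — empirical mode: two-exponential rise-then-fall
  traces, fast rate `1.65[P] + 3.2 s⁻¹`, slow rate 2.2 s⁻¹, amplitudes
  1.0/0.4, sampled at 0.5 ms (resolving the fast phase at the highest
  concentration) to 2.5 s (> 5 slow time constants), truncated at the
  2 ms dead time, Gaussian noise 2% of the rise amplitude; default
  concentrations {2.5, 5, 10, 20} µM × 3 replicates. Mechanistic mode
  integrates the ODE scheme and maps species through a probe model. The
  two modes exist because exponential-phase rates of the coupled system
  deviate from the asymptotic linear law at low [P]; their agreement at
  `[P] ≥ 10 K_d` is a cross-model property test.
* **Titrations** — acceptor grid 0–30 µM at 1 µM donor; K_d 5.98 µM (LI
  isoform) and 4.8 µM (NI); a linear direct-excitation background is
  added to the raw channel and removed by the control-based correction;
  noise is relative (sd proportional to each point's intensity, default
  5%).
* **ATPase** — actin 0–30 µM including 0; per-construct k_cat as above;
  noise 5% of k_cat, clipped at zero. OD340 time courses can be
  forward-generated for the raw-conversion path.
* **SMLM** — square 5 µm ROI; Gaussian clusters (default 20 clusters ×
  40 molecules, σ = 30 nm, centers ≥ 500 nm from the edge so the Ripley
  guard margin is available) plus CSR background sized so the planted
  in-cluster fraction is exact; per-channel localization jitter 20/30 nm;
  a configurable fraction of channel-2 cluster centers coincides with
  channel-1 centers. Background density at these defaults is far below
  the DBSCAN core threshold. One localization per molecule: blinking,
  camera noise and PSF shape are not simulated, so tests validate the
  point-pattern statistics, not image-level robustness.
* **Tracks** — mixtures of Brownian, fractional-Brownian (exact
  covariance via Cholesky of the fGn autocovariance, Hurst `H = α/2`,
  scaled so per-axis MSD `= 2Dτ^α`; O(N³) is irrelevant at ≤ 200
  frames), reflected-sphere confined, and directed-plus-Brownian modes;
  50 frames at 32 ms; isotropic 20 nm localization noise. The default is
  a single anomalous mode at the wild-type ensemble means
  `(D, α) = (0.3 µm²s⁻¹, 0.69)`.

What passing tests show — and do not. Closed-loop recovery on these
generators demonstrates that each estimator is unbiased and correctly
implemented under the stated noise models. It does not certify behavior
under unmodelled experimental pathology: photobleaching and blinking,
drift residuals, anisotropic localization error, baseline drifts in the
coupled assay, or motion-model switching within a track.

## Problem sizes

Default analysis and acceptance runs use 12 traces of 5,000 points,
16-point titrations, 10-point ATPase series, ~2,500-localization fields
(20 replicate fields for the in-cluster fraction), and 200 tracks of 50
frames — sizes chosen to keep every stage's sampling error comfortably
inside the tolerances its estimator is tested at.
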