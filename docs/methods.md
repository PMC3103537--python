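# Methods

## Model and assumptions

A trap is modelled as a two-state relaxation oscillator.  Between
firings, active pumping against Darcy leakage through the porous wall
drives the transmural pressure difference along
ΔP(t) = ΔP_max(1 − e^{−t/τ}); the door is an elastic shell that buckles
at ΔP_c, resetting ΔP to zero.  The only timing-relevant parameter is
the threshold ratio x = ΔP_c/ΔP_max: the firing interval is
T = −τ ln(1−x) for x < 1, and x ≥ 1 is a genuine physical regime
(*waiting*), represented by a typed `WAITING` sentinel rather than an
exception.

Assumptions inherited by everything downstream:

* pressure–volume and volume–width relations are linear, so the lateral
  width relaxes with the same exponential time constant τ as the
  pressure and can stand in for it;
* τ is a trap constant — it depends on wall permeability and elasticity
  (τ = V₀K/k with K = ηe/(κS)), not on the pumping rate — so interval
  fluctuations must originate in the threshold ratio;
* threshold fluctuations are gaussian, symmetric and independent between
  cycles (the draw is renewed at each firing);
* millisecond-scale door dynamics are outside scope; a firing is an
  instantaneous reset.

The buckling pressure uses the classical thin spherical-shell result
2Ed²/(R²√(3(1−ν²))) with ν = 0.5 (incompressible tissue) by default.
Because the true prefactor is shape-dependent, it is exposed as an
override parameter rather than hard-coded.

## Fluctuation propagation

For x ~ N(x̄, σ_x) truncated to (0, 1), leading-order Taylor expansion
gives ⟨T⟩ = −τ ln(1−x̄) and σ_T = τσ_x/(1−x̄).  The validity of the
expansion is tracked by the single proxy σ_x/(1−x̄) ≤ 0.1 (default,
configurable): the neglected second-order terms are controlled by powers
of exactly this ratio, and the variance condition is the more
restrictive one.  The full density follows by change of variables,
p_T(T) = φ(1−e^{−T/τ}; x̄, σ_x)·e^{−T/τ}/τ, and is increasingly
right-skewed as x̄ → 1.  The gaussian mass at x ≥ 1 is reported as a
separate waiting probability and never renormalized away — a trap with
x̄ near 1 genuinely alternates between waiting and firing.  The mass at
x ≤ 0 is negligible for every parameter set used here (x̄/σ_x ≥ 30) and
is redrawn in sampling contexts to avoid a point mass at T = 0.

Note one subtlety: the coefficient of variation
σ_T/⟨T⟩ = σ_x/((1−x̄)|ln(1−x̄)|) is U-shaped in x̄ with a minimum at
x̄ = 1−1/e ≈ 0.63.  The "longer mean interval ⇒ proportionally noisier"
trend therefore holds above that point, which is where all random and
bursting parameter sets live; the property tests assert monotonicity on
that branch only.

## Stochastic simulator

After each firing a fresh ratio is drawn (redrawn while ≤ 0).  A draw
≥ 1 advances the clock by `waiting_redraw` (default τ, the natural time
unit — the pressure is saturated, so only threshold fluctuations can end
the wait) and redraws.  Bursting adds a non-retriggerable excitation: a
firing with no active excitation opens a window of exactly τ_r during
which draws use the lowered (x_intra, x_intra_sd); a candidate firing is
part of the burst only if it lands inside the window — if the lowered
threshold would be crossed after the window closes, the ambient
threshold takes over from the same firing time, since the pressure rose
continuously throughout.  This makes the noiseless burst size exactly
N = 1 + ⌊τ_r/T_intra⌋ (initiator counted).  A spontaneous firing inside
the window does not reset the τ_r clock; re-arming happens at the first
firing after full relaxation.

Width traces are rendered as w(t) = w_def + (w_inf−w_def)e^{−(t−t_f)/τ}
between firings with an instantaneous jump to w_inf at each firing
(defaults 600/480 µm), sampled uniformly with dt required to be finer
than one fifth of the shortest interval.  Measurement noise is additive
gaussian with sd defaulting to 1% of the inflation range, truncated at
±5 sd so the container's physical-band invariant holds for arbitrarily
long traces (the truncation discards ~6·10⁻⁷ of the mass and is
irrelevant to every statistic computed here).

What the generator emulates: piecewise-exponential width decay with
instantaneous recovery jumps, firing intervals from tens of minutes to
days, waiting spells, and bursts of 2–7 fast regular firings.  What it
does *not* emulate: slow secular drift of the period within a trap,
prey-triggered firings, air-bubble aspiration, trap rotation
(projection) artefacts, and pixel-quantization noise.  Passing tests
therefore validate the pipeline's statistical machinery under the
model's own idealized conditions, not its robustness to every artefact
of real imaging data.

Per-regime default ranges (drawn uniformly per trap): metronomic
τ ∈ [1.5, 2.5] h, x̄ ∈ [0.45, 0.6], σ_x = 0.01 (mean intervals 1–3 h);
random τ ∈ [1, 2] h, x̄ ∈ [0.95, 0.99], σ_x = 0.04 (mean intervals
> 3 h, inflated further by waiting spells); waiting x̄ ∈ [1.05, 1.2];
bursting τ ∈ [0.8, 1.2] h, ambient x̄ ∈ [0.95, 0.99], x_intra ∈
[0.35, 0.6] (intra intervals ≈ 20–60 min), τ_r ∈ [1.2, 2.4] h.  Horizons
are 72 h (metronomic, waiting), 120 h (bursting) and 240 h (random) —
long enough for ≥ 30 events or ≥ 5τ of silence per trap while keeping a
full cohort simulation under a second.

## Measurement pipeline

**Firing detection.**  An event is a one-step width increase exceeding
`jump_frac` (default 0.15) of the robust range (2.5–97.5 percentile
span), with a refractory period of 3 samples.  The threshold is floored
at 6× the MAD-based robust step-to-step scatter: on plateau-dominated
traces (waiting traps) the percentile span collapses to the noise scale
and, without the floor, measurement noise itself gets called as
firings.  The event time is the first inflated sample, so detection is
accurate to one sampling step.

**Randomness index.**  r = ⟨|T_{i+1}−T_i|⟩/⟨T⟩ over the sample.
Successive differencing makes r insensitive to the slow period drift
metronomic traps exhibit, which would corrupt a plain coefficient of
variation.  Calibration: r < 0.1 metronomic, r ≈ 1 for i.i.d.
exponential intervals (E|X−Y| = 1/λ).

**Deflation fitting.**  Each inter-firing segment (plus the tail after
the last firing; the whole trace when there are no events) is fitted by
nonlinear least squares to w_def + (w_inf−w_def)e^{−t/τ} with all three
parameters free — the deflated plateau is never actually reached, so
w_def is estimated jointly rather than adjusted by hand, for
reproducibility.  Initialization: w_inf = segment max, w_def = segment
min, τ = time to 1/e of the range.  Degenerate (constant) or
non-convergent segments are skipped with a warning; the pooled τ̂ is the
per-segment mean with a standard error from the per-segment scatter.
Segments need ≥ 10 samples.

**Classification.**  Waiting: zero events over ≥ 5τ̂ (shorter eventless
horizons are "insufficient-data", as are records with < 2 intervals).
Bursting: ≥ 2 bursts of ≥ 2 firings, pooled intra-burst randomness
index < 0.2 and mean gap > 3× mean intra interval.  Otherwise r < 0.1 is
metronomic, r ≥ 0.5 random, and the in-between is reported as random
with an `intermediate` flag — the regimes form a continuum and only the
0.1 cutoff is empirically anchored; 0.5 and the 5τ window are exposed in
the configuration.

**Burst segmentation.**  The intra-burst time scale is the median of the
intervals at or below the overall median (the lower mode of the bimodal
interval distribution); a new burst starts at any interval exceeding
`gap_factor` (default 3) times that scale.  Intra-burst (15 min–1 h) and
inter-burst (many hours) intervals are far enough apart that the result
is insensitive to the factor.  Singleton bursts are kept in the tables
but excluded from the τ_r fit — one firing is no burst.

**τ_r recovery.**  Through-origin least squares of N against
f = 1/⟨T_intra⟩ pooled over bursts, slope in hours.  Through the origin
because the prediction is N ≈ τ_r·f with no intercept.  Counting the
initiating firing biases the recovered slope above τ_r by roughly
⟨f⟩/⟨f²⟩ (≈ 0.25 h for the sweep cohort); whether the initiator should
be counted is left open by the excitation model itself, and the recovery
is judged against the 1.1–2.4 h spread observed across real traps rather
than a point value.

## Numerical choices

* Deflation ODE: LSODA with rtol 10⁻⁹ and atol 10⁻¹² × ΔP_max; the
  closed-form exponential is the accuracy oracle (agreement < 10⁻⁶
  relative).  The zero-pumping limit is handled with a tiny absolute
  floor on atol.
* firing_time uses `log1p` for accuracy near x = 0; its inverse
  (pressure-ratio inference) uses `expm1`.
* Interval-density quadrature in tests passes the deterministic firing
  time as a `points=` hint: for small σ_x the density is a near-delta
  spike that adaptive quadrature otherwise misses.
* Ties in the burst gap rule (`interval == threshold`) stay inside the
  burst; the boundary case T_intra dividing τ_r exactly keeps the firing
  at the window edge inside the burst.
* All randomness flows through `numpy.random.Generator` seeded per trap;
  cohorts derive per-trap seeds from one master seed, so identical
  (spec, seed) give bit-identical cohorts, and the full
  simulate→write→read→analyze chain is byte-deterministic.

## Problem sizes

Test and reproduction runs use cohorts of up to 40 traps over horizons
of 120–240 h (≈ 10²–10³ events per regime), 10⁴-event trains for
moment checks and 10⁵ draws for Monte-Carlo/KS comparisons — sizes at
which every Monte-Carlo tolerance asserted (5% on σ_T, 0.02 KS distance,
binomial 3σ on the waiting mass) has comfortable margin, while the whole
suite runs in a few seconds.

## Known limitations

* The waiting-state re-test cadence (`waiting_redraw`) is a modelling
  choice; nothing observable pins it down, and waiting-interval
  statistics (though not the waiting/firing split itself) depend on it.
* The classifier's bursting criteria assume several bursts per record;
  a trap observed over a single burst is labelled by its overall r.
* The τ_r estimator inherits the initiator-counting bias discussed
  above; with few bursts or a narrow frequency range the slope is
  correspondingly less constrained.
* The exponential pressure law is itself a model reduction; all
  downstream formulas (and the pressure-ratio inversion in particular)
  are exact only under it.
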