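# utrap — mechanical-oscillator model of spontaneous *Utricularia* trap firing

Aquatic bladderworts (*Utricularia*) catch prey with millimetre-scale
suction traps that can also fire *spontaneously*, over and over, with
temporal patterns ranging from clockwork-regular ("metronomic") through
scattered ("random") to trains of fast regular firings separated by long
gaps ("bursting"); some traps simply stop ("waiting").  This package
implements the relaxation-oscillator model that explains this continuum,
together with the full measurement pipeline needed to analyse firing
records, for biophysicists and plant-biomechanics researchers working
with time-lapse trap recordings (real or simulated).

## The model

Continuous pumping of water out of the trap makes the inside/outside
pressure difference rise exponentially towards a saturation value,

&nbsp;&nbsp;ΔP(t) = ΔP_max (1 − e^{−t/τ}),

and the elastic trap door buckles (fires) when ΔP reaches a critical
value ΔP_c, after which the cycle restarts.  Only the threshold ratio
x = ΔP_c/ΔP_max matters for timing:

&nbsp;&nbsp;T = −τ ln(1 − x) for x < 1;  x ≥ 1 → no firing (*waiting*).

Gaussian fluctuations of x (sd σ_x) propagate to the firing intervals as

&nbsp;&nbsp;⟨T⟩ = −τ ln(1 − x̄),  σ_T = τ σ_x / (1 − x̄),

so the same threshold noise is amplified without bound as x̄ → 1: traps
firing early in the deflation are metronomic, traps firing near full
deflation are random, and the interval distribution grows a long right
tail.  Bursting arises from a post-firing excitation that lowers the
threshold to x_intra for a relaxation time τ_r and cannot re-arm until it
has fully relaxed, bounding a noiseless burst at
N = 1 + ⌊τ_r/T_intra⌋ firings and predicting N ≈ τ_r·f for the burst
size versus the intra-burst frequency f = 1/⟨T_intra⟩.

The library covers: the deterministic mechanics including the spherical
shell buckling pressure 2Ed²/(R²√(3(1−ν²))), the Darcy poroelastic
deflation ODE and the permeability / equivalent-hole-radius / Reynolds
estimates (`core_model`); a seeded stochastic simulator of all four
regimes plus realistic noisy width traces (`simulator`); firing
detection, the drift-robust randomness index r = ⟨|ΔT|⟩/⟨T⟩, exponential
deflation fitting and regime classification (`trace_analysis`); burst
segmentation and through-origin recovery of τ_r (`burst_analysis`); the
analytic interval pdf with Monte-Carlo oracles (`fluctuation_theory`);
and strict CSV formats, configuration and orchestration (`pipeline_io`,
`cli`).

## Worked example

The numbered scripts under `analysis/` run the whole study on simulated
data and write their tables under `results/`.  For instance, recovering
the excitation relaxation time from a 40-trap bursting cohort:

```sh
$ python analysis/04_burst_relaxation.py --seed 1
862 multi-firing bursts from 40 traps
burst sizes span 2-6
through-origin slope of N vs f: 1.949 h (generator tau_r = 1.7 h, observed spread 1.1-2.4 h)
```

The slope sits slightly above the generating τ_r because the initiating
firing is counted in N; it stays well inside the 1.1–2.4 h spread seen
across real traps.  The classification pipeline
(`analysis/01_simulate_cohort.py` then `analysis/02_interval_statistics.py`)
simulates a labelled four-regime cohort, renders each trap as a noisy
width trace, reads everything back from CSV, re-detects the firings and
recovers every generating label:

```text
trap_id label_true  n_events  T_mean_h     r  tau_hat_h  ratio      label
trap000 metronomic        39     1.817 0.033      2.001  0.908 metronomic
trap003     random        58     4.082 0.313      1.029  3.966     random
trap006   bursting        81     1.461 1.095      0.891  1.638   bursting
trap009    waiting         0       NaN   NaN      1.782    NaN    waiting
...
label agreement: 100%
```

Here `r` is the randomness index (≈0.03 for the metronomic trap, ≈1 for
bursting traps whose gaps scatter), `tau_hat_h` the deflation time fitted
from the width trace, and `ratio = T_mean/τ̂` the depth of deflation at
which the trap fires — small for metronomic traps, ≫1 for random ones.
Analytic theory versus Monte-Carlo (`analysis/05_fluctuation_theory.py`)
agrees to 0.3% in σ_T where the Taylor expansion is valid and flags the
near-threshold regime where part of the gaussian mass spills into
waiting.

A thin CLI wraps the same pipeline: `utrap simulate`, `utrap analyze`,
`utrap bursts`, `utrap theory`, `utrap report` (see `utrap --help`).

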