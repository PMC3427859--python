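# Methods

This note records the models, the parameter choices that matter, and what
the synthetic generators do and do not emulate.

## DamID binding analysis

### Signal model and conventions

The unit of analysis is a per-probe log2(Dam-fusion / Dam-only) ratio on a
tiling array. All genomic intervals are 0-based half-open (BED
convention); GFF3 is converted at the I/O boundary. Probe identity is
(arm, start); probe length is carried for interval output but all peak
arithmetic is in probe counts, matching an analysis designed around "runs
of consecutive probes".

Replicate preparation: the dye-swapped replicate is negated first, then
each replicate is median-centred using the median over the whole array
(all arms pooled). Orientation must precede centring because medians do
not commute with sign flips; array-wide rather than per-arm centring keeps
the per-arm permutation null from interacting with the normalization.

### Peak calling

A peak is a maximal run of ≥ `min_width` consecutive probes with value ≥
`height_threshold` (defaults 8 probes and 1.0 log2 = 2-fold). Ties at the
threshold are included; a single sub-threshold probe terminates a run; only
enrichment (positive) runs are called. **Peak height is the minimum probe
value in the run.** This is the one definition under which "a peak of
height h and width w" and "a run of ≥ w probes ≥ h" are the same event, so
observed peaks and null-grid counts are commensurable; max- or mean-based
heights would break that correspondence.

### Permutation-null FDR

For each (arm, replicate), probe values are permuted uniformly within the
arm — the null hypothesis is probe exchangeability — and run counts are
averaged over 20 permutations on a grid of heights 0.10–1.25 log2 and
widths 6–15 probes. The height step of 0.05 (24 levels) is a choice:
dense enough to constrain a 3-parameter surface, cheap to compute.
Empirical FDR per cell is mean-null-count / observed-count capped at 1
(the ratio form is what makes the quantity a rate). Cells with zero
observed count carry no rate; cells with zero null count have undefined
log-FDR; both are excluded from the fit rather than pseudocounted. The
surface ln FDR = a + b·h + c·w is fitted by ordinary least squares over
the remaining cells (≥ 6 required) and evaluated — extrapolated, for
peaks beyond the grid — as FDR = min(1, exp(a + b·h + c·w)).

Null grids are per (arm, replicate), and each replicate's peaks are scored
by their own model; grids are built lazily, only where that replicate has
observed peaks to score. Permutation streams are derived by counter from
the master seed per (arm, replicate, iteration), so changing the iteration
count never reshuffles earlier draws.

### Consensus and targets

Peaks from different replicates whose intervals overlap by ≥ 1 bp are
chained into clusters; a cluster represented in every replicate (the
default; 2-of-3 is available as configuration) becomes a consensus peak
spanning the union interval with the **largest** member FDR — a peak is
only as credible as its weakest replicate. A gene is a target when a
consensus peak with FDR strictly < 0.001 lies within 5,000 bp of its
transcription unit (tx start to tx end, strand-independent). Distances
are gaps between half-open intervals: a peak ending exactly where a gene
starts has distance 0, and a 5,000 bp gap is inside the window while
5,001 bp is outside. All genes within the window are called — an
intergenic peak between divergently transcribed neighbours supports both —
with a nearest-gene-only mode off by default.

### The array simulator

The generator emulates the study design the analysis was built for: probes
of 50–75 bp at 55 ± 10 bp spacing, three replicates with the third
dye-swapped (modelled as sign inversion of the stored ratios), i.i.d.
Gaussian probe noise in log2 space with sd 0.3 (a realistic two-colour
ratio spread), rectangular planted peaks, and synthetic transcription
units tiled with gaps drawn from 1–8 kb so the 5 kb window has non-trivial
known answers. Gaussian noise is a stand-in — the noise law of real
probes is not known — chosen because it satisfies the exchangeability the
permutation null assumes; passing calibration tests therefore validate
the machinery under the null's own assumptions, not the exchangeability
of real arrays (probe GC, spatial artifacts and restriction-fragment
structure are deliberately not simulated). The standard recovery
experiment plants 20 peaks per dataset with heights 1.5–2.5 log2 paired
inversely with widths 48 down to 10 probes; the pairing comes from an
a-priori longest-run power calculation so that each peak presents a
called run in all three replicates with probability > 99.9% at noise 0.3.

Problem sizes throughout (2 arms × 5,000 probes; 50 calibration runs;
20-iteration nulls) are desk scale by design: the full recovery
experiment runs in well under a minute.

## Electrophysiology

### Voltage clamp is closed form

A space-clamped cell under voltage clamp needs no ODE solver: per
constant-voltage segment the current is the exact sum of a capacity
transient (ΔV/R_a)·exp(−t/τ_a) with τ_a = R_a·C, ohmic leak
g_leak·(V−E_leak), a fast component g_f·a∞(V)·h∞(V_prev)·exp(−t/τ_inact)·
(V−E_K), and a slow component g_s·s∞(V)·(1−exp(−t/τ_act))·(V−E_K).
Samples are emitted as exact averages of the analytic current over each
50 µs sampling bin — emulating the integrating anti-alias stage of
acquisition — which makes the discrete area of the capacity transient
equal C·ΔV exactly and lets every extractor be validated against analytic
values. Fast-current inactivation enters each segment at its steady state
for the previous segment's voltage (this carries the prepulse effect);
slow activation restarts from zero at each voltage change, so the slow
read-out is prepulse-independent by construction. The optional 2 kHz
Bessel stage of real acquisition is not modelled; extractors are tested
on unfiltered analytic traces.

Kinetic constants are minimal stand-ins for a phenotype, not fitted
channel kinetics: Boltzmann activations (fast: V½ −30 mV, k 10; slow:
V½ −20 mV, k 8), fast inactivation V½ −60 mV, k 8 (h∞ ≈ 0.98 at −90 mV,
≈ 0.007 at −20 mV), τ_inact 10 ms, τ_act 50 ms, E_K −90 mV (approximate
Nernst for the recording solutions), R_a 10 MΩ. All recovery tests are
parameter-recovery tests; nothing asserts these kinetics match a real
channel.

### Feature extraction

Capacitance integrates the baseline-subtracted transient over 10 ms after
the −60→−90 mV jump and divides by 30 mV; input resistance uses the
steady currents at −60 and −90 mV, where every modelled conductance is
essentially closed; acceptance requires R_in strictly > 1 GΩ. Off-line
leak subtraction removes g_leak·(V_cmd(t)−V_hold); P/4 subtracts four
quarter-amplitude subsweeps scaled by 4, which cancels all linear
components identically. The fast current is the maximum within
**[0.5, 5] ms** of test-step onset and the slow current the mean over the
last 20% of the 50 ms step; both are configuration keys because the
original windows are known only graphically. The fast window's upper
bound matters: with a slowly activating sustained current, a window
reaching 10 ms reads ~25% of the slow steady level even when the fast
current is fully inactivated by a −20 mV prepulse, defeating the
isolation the prepulse exists to provide; at 5 ms the residual is ~13%
and the > 80% suppression criterion is met with margin. Group IV curves
report mean ± SEM with Welch (unequal-variance) two-sample t-tests — the
analysis specifies only "nonpaired", and Welch is the safer default.
Spikes are upward 0 mV crossings with a 2 ms lockout; both values are
configuration keys, as no spike criterion is stated for the original
recordings.

Density planting inverts the analytic component formulas only — the fast
target is the fast component's value 0.5 ms after step onset (the
earliest instant the window can read), the slow target the late-window
mean of the slow component — never the measurement pipeline, so pipeline
recovery of the planted 60.1/49.0 and 42.6/33.3 pA/pF pairs within 5% is
a genuine end-to-end test (observed error ≲ 1%).

### Current clamp

The membrane equation adds an instantaneous-activation Na conductance
with first-order inactivation (V½ −50 mV, k 3, τ 1 ms — deep enough that
no persistent window current can sustain a depolarized plateau), a
delayed rectifier (V½ −15 mV, k 5, τ 1 ms), the A-type and slow K⁺
currents above, and leak; it is integrated by fixed-step forward Euler on
the 20 kHz grid with 5 substeps (spike counts are unchanged at 10 or 20
substeps) and a non-finite-state abort. The spiking pair (g_Na 400 nS,
g_KDR 100 nS) was chosen once so the model cell fires repetitively across
the 1–10 pA step family; with the dorsal-like A-type conductance present
the cell fires fewer spikes at every step than without it, which is the
qualitative relationship the current-clamp arm is designed to test. The
simulator is single-compartment (the recorded cells are treated as
isopotential) and contains no synaptic input or Ca²⁺ currents;
pharmacological block is represented as setting a conductance to zero.

## Known limitations

* The permutation null assumes probe exchangeability within an arm; real
  tiling arrays violate this (GC trends, fragment structure), and the
  calibration results here do not speak to that violation.
* The FDR surface is log-linear by construction of the fit; real decay
  need not be exactly log-linear, and extrapolated FDRs far beyond the
  grid inherit that model error.
* Clamp kinetics are placeholders; only planted-parameter recovery and
  qualitative direction (prepulse inactivation, firing suppression) are
  claimed.
* Bin-averaged sampling idealises acquisition; estimator behaviour under
  real filter ringing and point sampling is untested.
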