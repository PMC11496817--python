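# Methods

`thetashift` implements an analysis pipeline for theta phase-shift coding in
hippocampal CA1 population recordings: the observation that a place cell's
preferred firing phase relative to the local theta rhythm is not a fixed
property of the cell but shifts with the functional context in which it
fires — the cell assembly it is recruited into, the place field it is
traversing, or the trial type being performed. This note documents the models
and procedures, the parameters that matter, what the synthetic data do and do
not emulate, and the numerically delicate choices.

## Session model

A session bundles sorted spike trains, one continuous LFP channel (nominally
2 kHz), the animal's tracked position on a 170 × 130 cm end-to-end T-maze,
and a trial table. Six trial categories are distinguished: free-choice runs
G→C ending in a left or right turn at the open T-junction (correct when the
exit turn matches the entry turn), and four guided runs C→G labeled by their
forced entry/exit turns (LL, LR, RL, RR). Time is float64 seconds from
session start; intervals are half-open `[t0, t1)`.

Putative place cells are units with an on-maze mean rate between 0.2 and
4 Hz and spatial information above 0.5 bit/s. "On-maze" means within any
trial interval. Speed is estimated by central differences on positions
smoothed with a 0.25 s boxcar; the boxcar width trades tracker jitter against
lag at turns. Linearized position is the arc-length projection of the 2D
position onto the trial category's ordered segment chain (nearest point on
the chain, 5 cm off-path tolerance); the maze geometry is a configurable set
of polylines with a built-in default.

## LFP processing

Theta phase is the angle of the analytic (Hilbert) signal of the 4–10 Hz
zero-phase band-passed LFP, interpolated (on the unwrapped phase) at spike
times. Filters are least-squares linear-phase FIRs applied with group-delay
compensation; orders give ≥ 40 dB of rejection one octave outside the band.
Under this convention the positive peaks of a sinusoid sit at phase 0.

High-theta epochs use a two-pass rule that resolves the circularity of
defining artifacts and power thresholds from the same trace: σ₀ is the SD of
the full filtered trace; samples with |LFP_θ| > 2σ₀ (padded by 0.25 s to
cover filter ringing) are artifacts; σ is then recomputed on the artifact-free
remainder and high-theta epochs are where the analytic envelope exceeds 1σ.

Sharp-wave ripples: down-sample to 1 kHz, 50 Hz notch, band-pass 120–220 Hz,
z-score the analytic envelope; candidate events cross 3.5 SD with boundaries
at 2 SD; events shorter than 50 ms are rejected, then events separated by
gaps under 50 ms are merged, then events longer than 500 ms are rejected.
Rejecting short events *before* merging is deliberate: merging first welds
pairs of sub-50 ms noise excursions into spurious events (measured ~10% of
100 s noise traces with more than one false event; the implemented order
yields ≤ 1 false event per 100 s in 50/50 noise seeds while recovering
planted 100 ms ripples within 20 ms).

## Assembly detection

The detector searches parallel binned spike trains for recurring lagged
coincidence patterns at a ladder of temporal resolutions (31 bin widths,
0.0058–5.0 s, each with its own maximum lag). For a unit pair with counts
n_A, n_B, the joint activation count at lag ℓ is Σ_t min(n_A(t), n_B(t+ℓ));
the candidate lag maximizes this count (ties broken toward smaller |lag|).
Slow behavioral comodulation inflates the joint count at *every* lag, so the
test is conditional: the candidate count is contrasted with the mean count at
the reference-shifted lags ℓ ± 2 bins via a binomial test at probability 1/2,
Sidak-corrected for the best-lag search, with Benjamini–Hochberg control
across pairs. Significant pairs are agglomerated one unit at a time by
applying the same test between the pattern's activation series (the min over
lag-aligned member counts) and each remaining unit, accepting the
lowest-p Benjamini–Hochberg survivor until no extension is significant.
Patterns detected at several resolutions are pruned to the lowest-p
resolution per member set, independently within the spike-timescale window
(0.005–0.06 s) and the rate-timescale window (0.07–5 s), so the same member
set may survive once in each window.

An assembly has an activation of strength n at origin bin t when every
member fires at least n spikes in its lag-aligned bin; a member's spike is an
*assembly-spike* when its bin matches the member's lag position within an
occurrence. Occurrence bins are not exclusive between patterns.

Type-I behavior is calibrated against independent Poisson pairs
(false-detection ≤ α over seeds) and the best-lag/count selection is verified
against exhaustive enumeration on small instances.

## Circular statistics

* **Hodges–Ajne** tests non-uniformity without assuming unimodality; the
  statistic m is the minimum count in any closed half circle (computed by an
  exhaustive sweep over data-anchored boundaries) with the standard large-n
  tail approximation. Sets of ≤ 50 spikes are marked *not testable* — a
  distinct state from non-significant — and are excluded from every
  denominator downstream.
* **Enhanced locking** compares the resultant length R of a context's spikes
  with 1000 same-size replicas drawn without replacement from all the unit's
  spikes; p is the fraction of replicas with strictly larger R (ties count
  against significance).
* **Phase-shift tests** use the multi-sample common-median test (the
  circular analog of the Kruskal–Wallis test): observations are counted on
  each side of the pooled circular median and the statistic is referred to
  χ²(k−1). The pooled median is found by an O(n log n) prefix-sum scan. Note
  a structural property: an *exactly antipodal* shift leaves both groups
  split 50/50 by every diameter and is invisible to this statistic; power is
  excellent for the quarter-cycle shifts the analyses target.
* **Circular–linear correlation** (phase precession): the precession slope
  maximizes the resultant length of phase − 2πs·x (grid plus bounded
  refinement); the coefficient is the circular correlation between measured
  and fitted phases carrying the slope's sign, with the usual normal
  approximation for the two-sided p.
* **Hartigan's dip** measures bimodality of the detected assembly-timescale
  distribution. The statistic is computed exactly over continuous unimodal
  cdfs: for every candidate mode interval, the minimal sup-norm tube radius
  admitting a cdf convex left / concave right of the mode is a small linear
  program; a greatest-convex-minorant feasibility bound prunes the splits so
  only a few programs are solved. Distributions with an atom at the mode are
  excluded, a conservative restriction of at most (max tie mass)/(2n) that is
  irrelevant for continuous data. The p-value is a bootstrap against uniform
  samples (the least-favorable unimodal null), cached per sample size.

All multiple-comparison control is Benjamini–Hochberg at α = 0.05; NaN
(not-testable) p-values never count as tests.

## Phase-shift coding analyses

Spike-phase sets are grouped per unit by assembly, by place field, or by
(field, trial type). Eligibility everywhere: > 50 spikes per set, and for
by-assembly comparisons each set must itself be phase-locked. Units with
fewer than two eligible sets are not tested and do not enter denominators;
session-level fractions are combined across sessions weighted by the number
of tested units (or assemblies).

Place fields are isolated by five methods sharing a 12 cm/s speed floor:
rate-map thresholding at μ+σ with a μ+2σ peak requirement (the conservative
variant), at 0.7μ (recovers low-rate fields), at μ followed by
Gaussian-mixture refinement, DBSCAN on spike positions (ε = 0.05 on
per-axis min-max normalized coordinates, MinPts = 15), and DBSCAN followed
by mixture refinement. Mixture refinement fits full-covariance 2D Gaussians
initialized from first-stage memberships, on first-stage member spikes only,
then classifies all of the unit's spikes by maximum posterior, discarding
spikes with mixture log-density < −20 and components left with fewer than
MinPts members. Rate maps use 2 cm bins and a 10 cm Gaussian kernel; field
regions are 8-connected; fields shorter than 15 cm in maximal axis-aligned
extent are discarded (the maze is quasi-1D, so axis extent matches
path-length extent on the arms). Spatial information is the standard
occupancy-weighted form I = Σ p_i λ_i log2(λ_i/λ̄) in bits/s.

Instantaneous rate is a Gaussian-kernel intensity estimate with SD equal to
half the unit's mean ISI, evaluated at spike times. Rate differences between
spike sets use a two-sided rank-sum on these per-spike rates, and the
co-occurrence of phase and rate differences is tested by a χ² independence
test (no continuity correction) on the 2×2 table of (phase p < .05) ×
(rate p < .05) per comparison family.

Trial-type decoding trains a linear SVM (C = 1) per field on per-spike
features — phase passed as [cos θ, sin θ], instantaneous rate, and optional
speed/theta-power covariates — with stratified k-fold cross-validation
(nominally 50-fold, reduced with a log entry when a class is smaller). The
null shuffles labels at the trial level; because shuffling also destroys
label autocorrelation, the original fit uses a jointly shuffled sample order
for a like-for-like comparison.

Theta-cycle lag changes: per trial, the lag (20 ms bins, ±3 bins) maximizing
the two units' cross-correlogram; lags are compared across trial types with
a two-sided rank-sum test (groups are unpaired and unequal in size, so the
unpaired test is the coherent choice), separately per place field of the
reference unit.

Sensitivity reruns re-execute any analysis on spike sets with SWR and/or
low-theta epochs removed; removal can only shrink spike sets.

## AdEx simulation of assembly recruitment

Membrane dynamics per unit:

    C dV/dt = −g_L(V−E_L) + g_L Δ_T exp((V−V_T)/Δ_T)
              − g_e(t)(V−E_e) − g_i(t)(V−E_i) − w + ε
    τ_w dw/dt = a(V−E_L) − w

with a spike when V reaches 0 mV, then V → V_r and w → w + b. The drive is

    g_i(t) = k_i (sin(2πθt − π) + 1)
    g_e(t) = k_e (sin(2πθt) + 4) exp(−(t−c)²/(2σ²))

with θ = 7 Hz, k_i = 17 nS for every unit and assembly, c = 2.5 s,
σ = 0.4 s, and a fixed π offset between excitation and inhibition. Each
assembly assigns its members individual gains k_e: assembly A uses
(2.7, 1.7, 0.7) nS and assembly B (1.0, 2.0, 3.0) nS over the same three
units.

Integration is forward Euler–Maruyama (default step 0.05 ms for single-unit
work, 0.1 ms for the experiment harness, both convergence-checked: halving
the step moves noise-free spike times by < 0.5 ms). The per-step current
noise has variance 1.6 × 10⁻¹⁹ A² at the 0.05 ms reference step and is
rescaled with √dt so the diffusion is step-size consistent. The exponential
term's argument is capped at 30 before the spike test to avoid overflow in
the step before reset.

**Cell parameters.** The published regular-spiking AdEx set (g_L = 30 nS,
E_L = −70.6 mV, V_T = −50.4 mV, …) cannot express this experiment: with
those values a unit driven at k_e = 0.7 nS peaks ~13 mV below threshold and
never fires, so no 3-unit sequence exists to detect. The defaults are
therefore calibrated for the recruitment regime the experiment requires —
a slow, near-threshold cell: C = 0.8 nF, g_L = 5 nS, E_L = −54 mV,
Δ_T = 2 mV, V_T = −50 mV, V_r = −62 mV, E_e = 0, E_i = −60 mV, a = 0,
b = 1.2 nA, τ_w = 1 s. Strong spike-triggered adaptation makes each unit
fire essentially one phase-locked spike per retrieval, at a time ordered by
its gain: stronger k_e → recruitment in an earlier theta cycle of the
retrieval envelope. In this regime the multi-resolution detector recovers
the gain-descending activation order of both assemblies in ~100% of
realizations, with the second and third units detected ≈ 0.13 s and ≈ 0.45 s
(one and three theta cycles) after the first.

A structural limitation worth stating: with the printed drive (k_i = 17 nS
inhibition gating roughly half of each theta cycle), the *within-cycle*
firing-phase separation attainable between the strongest and weakest gains
saturates near 0.8 rad (≈ 20 ms) across every parameter regime explored,
while across-cycle separations are quantized at ≥ 1 theta period (≈ 143 ms).
Inter-unit lags in the 0.04–0.1 s range (a large fraction of a cycle between
phase-locked units) are therefore not expressible by this model family as
parameterized here; the reported lags are the ones the calibrated model
actually produces.

The experiment harness concatenates 400 retrievals per assembly
(5 s each; 5 s × 7 Hz is an integer, so theta is cycle-continuous across the
concatenation), runs detection separately on each assembly's concatenation
at the spike-timescale resolutions with wide lag ranges
(bins 0.0058–0.055 s, max lags 18–11), prunes to the best resolution, and
scores a realization as a recovery when both assemblies' 3-unit patterns are
ordered by descending gain. Integration is restricted to c ± 4.3σ of each
retrieval, where the envelope exceeds 10⁻⁴ of its peak; outside it the cell
is inhibition-clamped and cannot spike.

## Synthetic sessions

The generator emulates the structure of a real session: an interleaved
choice/guided trial schedule (default 10+10 choice, 4×5 guided, ~500 s),
constant-speed runs along the category paths with stationary inter-trial
gaps, ~10 place cells with 3–5 Gaussian place fields (8 cm SD, 4 Hz peak
over a 0.05 Hz floor) at random path locations, spiking as an inhomogeneous
Poisson process thinned by a von Mises phase-acceptance profile normalized
by I₀(κ) to preserve the marginal rate (κ = 2 by default), an LFP built from
amplitude-modulated 7 Hz theta plus 1/f noise with planted 150 Hz ripple
bursts in the gaps, and optional planted coincidence assemblies (spike
timescale: jittered lagged spike injections; rate timescale: lagged
multi-spike co-activations). Configurable fractions of units carry planted
phase shifts across fields or trial types; shifted fields alternate by the
planted π/2 (shifts are not stacked across fields, which would create
antipodal pairs that the common-median statistic cannot see).

What the generator does *not* emulate: spike-sorting noise and unit
contamination, theta frequency drift and asymmetric (sawtooth) theta,
phase precession within fields (phase preference is constant per field
unless planted otherwise), behavioral variability in running speed, and
inter-unit synaptic structure beyond the planted motifs. Passing the
recovery tests therefore demonstrates correctness of the pipeline's
inference under its own statistical assumptions, not robustness to every
property of real recordings.

Note one property of realistic synthetic sessions: with theta-modulated
units (κ > 0) the detector legitimately finds fine-timescale coordination
*without* planted motifs, because shared theta drive is genuine coincidence
structure. Detector false-positive calibration therefore uses sessions with
κ = 0, where only behavior-driven slow comodulation remains (and is removed
by the reference-lag contrast).

## Problem sizes used by the tests and the acceptance script

The test suite scales simulations to keep the default run short: the
assembly-recruitment experiment uses a 20-realization smoke run (the
acceptance script runs 100 realizations at the full 400 retrievals per
assembly); detector calibration and planted-motif recovery use 50 seeds;
circular-test calibration uses 300–500 simulations per test; the end-to-end
fraction recovery uses 14 sessions per planted proportion q ∈ {0, 0.3, 0.5}.
These sizes are the package's own choices for routine verification; every
property can be re-run at larger n through the same functions.
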