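# Methods

This note documents the models, parameters and numerical choices behind
`lfpseize`, and what the synthetic validation does and does not establish.

## Recording model and epochs

A recording is a single-channel voltage trace with a drug-free **baseline**
epoch and a drug **exposure** epoch. Default epoch positions follow the
acquisition protocol: baseline 0–450 s; exposure 1050–1500 s, leaving 10 min
after compound addition for equilibration. All quantities reported per
animal are baseline-normalized, so absolute amplitude calibration is never
required.

Preprocessing decimates 10 kHz acquisitions to 2 kHz (order-8 Butterworth
anti-alias low-pass at 0.8× the new Nyquist, forward–backward, then keep
every 5th sample) and band-passes 1–500 Hz with an order-4 Butterworth
filter applied forward–backward. The acquisition protocol fixes only the
corner frequencies; order 4 and zero-phase application are this package's
choices — zero phase preserves the timing of 1-s event windows, at the cost
of squaring the magnitude response (the effective roll-off is order 8).
The 1-Hz high-pass has an edge transient of roughly 2–3 s; epoch-level
statistics are unaffected, but single-trace comparisons near the record
edges should exclude that region.

## Morse-wavelet time–frequency analysis

The CWT uses the analytic generalized Morse family. In the frequency domain
the unit-scale window is

    Ψ(ω) = a · ω^β · e^(−ω^γ),   ω > 0;    Ψ(ω) = 0, ω ≤ 0,

with symmetry γ = 3 and time-bandwidth product P² = βγ = 60 (so β = 20),
following the convention in which "time-bandwidth" names βγ. The window
peaks at ω_p = (β/γ)^(1/γ) and is normalized to peak value 2
(analytic-signal convention), so a unit-amplitude tone yields magnitude ≈ 1
at its own scale and magnitudes are directly comparable across scales.
Absolute magnitudes under other CWT normalizations differ by a scale
factor; every downstream quantity (band ratios, distances relative to a
baseline threshold) is invariant to that factor.

Frequencies are laid out geometrically at 10 voices per octave over
1–500 Hz (90 grid points; adjacent frequencies differ by 2^(1/10)).
Coefficients are computed by frequency-domain multiplication with a
zero-padded FFT of the input, one inverse transform per scale; padding is
one wavelet footprint at the lowest analyzed frequency, taken as
P/f_min ≈ 7.7 s. The same footprint defines the cone-of-influence region
excluded from baseline statistics at each epoch edge. For long traces the
transform is streamed scale-by-scale directly into band averages
(`banded_cwt`) so the full time × 90 matrix is never materialized; the full
spectrogram path stores magnitudes in float32, which leaves ~1e-4 relative
noise in averaged quantities.

Band binning takes the unweighted mean of the magnitudes of all grid
frequencies inside each band. Bands are half-open [low, high) except HFO,
closed at 500 Hz; frequencies in the deliberate 7–8 and 13–15 Hz gaps
belong to no band.

## Event detection

First pass: the per-sample Euclidean distance between the 7-band magnitude
vector and the baseline-mean vector is thresholded at baseline mean +
2 SD (mean and SD over the baseline epoch, cone-of-influence edges
excluded). Local maxima above threshold with ≥ 1 s separation become
candidate events; each event window is 1 s centered on its peak, shifted
inward (not truncated) at epoch edges so all band vectors average the same
window length. Peak selection uses height and spacing only — no prominence
or width constraints.

Second pass: baseline candidates are detected with the identical procedure
and threshold; the centroid of their band vectors and the radius r_max of
the farthest baseline event define the rejection region. Exposure events
strictly inside r_max are discarded. If the baseline produced no events,
all exposure candidates are retained (r_max is undefined; in practice the
stimulus deflections guarantee baseline events). By construction, running
the detector with the exposure epoch equal to the baseline epoch refines to
zero events.

The event vector used in both passes is the time-mean of the 7 band
magnitudes over the 1-s window. A sustained spectral change (e.g. a
suppressor-like compound) keeps the whole exposure epoch far from the
baseline profile, so such groups legitimately produce many events — the
event count measures departure from baseline, not burstiness per se.

## Hilbert-envelope AUC

The envelope is |analytic signal| of the full 1–500 Hz filtered trace,
computed per epoch (FFT length padded to the next fast size; the padding
perturbs only a short edge region). AUC is the trapezoidal integral on the
sample grid — at 2 kHz the difference from a rectangle rule is negligible,
and the closed forms for constant and linear envelopes are exact. Binned
series use fixed 30-s bins with partial trailing bins dropped; binned
traces are normalized by the mean baseline bin, and the scalar endpoint is
total exposure AUC / total baseline AUC.

## Statistics

`rank_sum_test` and `signed_rank_test` are self-contained. Exact two-sided
p-values come from dynamic programming over rank-subset sums (rank-sum:
distribution of the first sample's rank total over all subsets; signed
rank: distribution of W⁺ over all sign patterns, on a half-integer grid so
tied ranks stay exact) and are used automatically when the combined sample
size is ≤ 12 (rank-sum additionally requires no ties). Otherwise the normal
approximation applies the standard tie-adjusted variance and a 0.5
continuity correction; p = 2Φ(−|z|). The reported rank-sum statistic is W,
the rank total of the treatment sample (U = W − n_x(n_x+1)/2).

`bh_adjust` implements the step-up adjustment q_(i) = min_{j≥i} p_(j)·m/j,
capped at 1, optionally within families. Note that BH adjustment is not
idempotent (re-adjusting adjusted values inflates them further); callers
should adjust raw p-values exactly once. The family for band comparisons is
configurable (`per_band`, `global`, `per_compound`): with many treatment
groups, correcting across treatments within each band (`per_band`) mirrors
the study design, while with a single treatment group only `global`
(all bands in one family) performs a real correction — the validation
scenarios use `global` for that reason.

`classical_mds` double-centers the squared-distance matrix,
eigendecomposes, and scales the top-k eigenvectors by √λ. Negative
eigenvalues from non-Euclidean inputs are dropped from the
explained-fraction denominator (positive-part convention); if fewer than k
positive eigenvalues exist, fewer columns are returned with a `truncated`
flag. The sign of each coordinate axis is arbitrary; only relative geometry
is meaningful.

Welch spectra use 2-s Hann segments with 50% overlap (a configuration
knob), and amplitude (√ of the averaged periodogram) rather than power is
ratioed and reported, matching the band-summary convention; squaring the
ratios converts to power.

## Synthetic cohorts

The generator emulates the salient structure of the study recordings:

* **Background**: Gaussian 1/f noise (exponent 1.0, RMS 1.0 arbitrary
  units), shaped in the frequency domain and rescaled; the study gives no
  amplitude calibration, and all endpoints are ratios.
* **Stimulus artifacts**: the acquisition protocol flashes paired blue-light
  stimuli (2 × 100 ms, 500-ms gap) every 4.5 s throughout recording. Each
  flash evokes a biphasic 20-ms deflection at 2.0× background RMS — evoked
  responses are visible above, but comparable to, ongoing activity. They
  appear in both epochs, which is what lets the second detection pass
  reject them.
* **Band gains**: group-specific amplitude modulation during exposure is
  implemented by decomposing the background into band-limited components
  (order-6 Butterworth band-passes, forward–backward; the steep transition
  keeps the injected gain localized to the named band) and re-mixing with a
  0.25-s cosine ramp at the epoch edges.
* **Bursts**: 1-s Hann-enveloped sinusoids at the geometric-mean frequency
  of the target band, default 6× background RMS, placed on a jittered grid
  inside the exposure epoch with guaranteed separation; every burst is
  recorded in a ground-truth annotation.
* **Reproducibility**: per-animal seeds derive from
  (master seed, CRC32(group label), animal index); cohorts are pure
  functions of their arguments.

What the generator does **not** model: biophysically realistic neural-mass
dynamics, non-stationary drift, pharmacokinetic onset ramps, electrode or
movement artifacts beyond the periodic stimulus template, and line noise.
Passing the simulation-based checks therefore demonstrates that the
pipeline recovers known injected structure under LFP-like 1/f statistics —
not that it would match any particular real recording.

## Validation problem sizes

Simulation studies run at desk scale: 120-s baseline (0–120 s) and 120-s
exposure (130–250 s) epochs at 2 kHz instead of the protocol's 450-s
epochs; epoch length only sets the amount of averaging. The bundled demo
uses 150-s epochs and n = 4 per group. Measured on these conditions (fixed
seeds, reported by `scripts/acceptance.py` and asserted in
`tests/test_acceptance.py`):

* CWT tone recovery: 20/20 tones within one voice over 2–400 Hz.
* Detector on 20 annotated 6×-RMS γ bursts per recording (10 recordings):
  mean recall 1.00, precision ≥ 0.97 at ±0.25 s matching.
* Stationary controls (10 recordings): median refined count ≤ 2; the
  exposure≡baseline construction refines to exactly 0.
* Injected 2.0× γ gain (n = 8): recovered mean 1.80–1.85 (the Butterworth
  decomposition's band-edge roll-off accounts for the shortfall from 2.0);
  all other bands within 1.00 ± 0.05.
* Suppressor cohorts (0.5× gain on the four >15 Hz bands, n = 8 vs 8,
  10 replicates): every suppressed band flagged in 10/10 replicates,
  untouched bands rarely flagged; relabeled-control nulls clean in ≥ 9/10.
* Full pipeline on the demo config: byte-identical artifacts across
  re-runs (the run report's wall-clock timings are the only exception).

## Known limitations

* The detector's event count conflates transient bursts with sustained
  spectral change (see above); distinguishing them requires inspecting the
  binned AUC traces and representative events.
* Exact MATLAB-toolbox CWT normalization is not reproduced; absolute
  magnitudes may differ from other implementations by a scale factor.
* The ABF acquisition format is not read directly; convert to the raw
  float32 + JSON sidecar or TSV format.
* With a single treatment group, `per_band` BH families degenerate to no
  correction; choose the family to match the comparison structure.
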