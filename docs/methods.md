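# Methods

## The measure

Phase-amplitude coupling (PAC) quantifies how the amplitude envelope of a
fast oscillation varies with the phase of a slow oscillation. For a window
of one channel, a complex Morlet continuous wavelet transform extracts the
instantaneous phase Φ(t) at a low analysis frequency f_P and the
instantaneous amplitude A(t) at a high frequency f_A. Phases are binned
into N = 18 bins tiling [−π, π) (width π/9) and the mean amplitude per bin
is normalised:

    P(j) = ⟨A⟩_j / Σ_k ⟨A⟩_k ,    Σ_j P(j) = 1 .

The coupling strength is the modulation index — the Kullback–Leibler
divergence of P from the uniform distribution U(j) = 1/N, normalised to
[0, 1]:

    S = D_KL(P, U) / log N ,   D_KL(P, U) = Σ_j P(j) log(P(j)·N) .

S = 0 for a flat profile and S = 1 when all amplitude mass falls in one
bin; it is invariant to the base of the logarithm and to amplitude
rescaling. The coupled phase ψ is the centre angle of the arg-max bin of
P(j), reported in [−π, π) (ties break to the lowest bin index). Strength
and phase are combined into one complex pixel

    C = S·cos ψ + i·S·sin ψ ,

so a comodulogram over a 10 × 10 grid of frequency pairs (low 1–10 Hz,
high 30–160 Hz, both split into 10 intervals with equal steps in log
frequency; analysis at the geometric-mean centre of each interval) is a
10 × 10 complex image: modulus = coupling strength, argument = coupled
phase.

### Conventions and edge cases

- Phase-bin convention: the bin grid tiles [−π, π) and ψ is a bin
  *centre* in [−π, π), matching the complex-argument convention of the
  pixel. (An equivalent formulation indexes bins over (0, 2π]; the choice
  only relabels angles.)
- An empty phase bin (possible in 10 s windows at ~1 Hz) contributes a
  mean amplitude of 0 and the window is flagged in provenance; a strict
  mode rejects such windows instead.
- A zero-amplitude window has no preferred phase; its profile is defined
  as uniform, giving S = 0.
- A zero-strength pixel is stored as exactly 0 (its argument is
  unconstrained).

### Wavelet choice

The transform is a complex Morlet (`cmor` in PyWavelets) with one
coefficient series per interval centre. The bandwidth parameter defaults
to fb = 3.0, chosen so that the frequency response at a neighbouring grid
centre stays below 50% in both grids (centre ratios 1.26 and 1.18) while
the modulation sidebands of slow rhythms around high-frequency carriers
(f_A ± f_P) are still passed. Windows are analysed together with up to 2 s
of recorded context on each side (zero-padded where unavailable) and the
pads are trimmed after the transform to control wavelet edge effects; at
1 Hz the wavelet's temporal e-folding half-width is ≈ 1.2 s, so 2 s of
context covers the bulk of it.

## Surrogate screening (ST-CV-PAC)

Chance-level coupling is screened per pixel: the phase series is shuffled
`n_shuffles` (default 100) times, the strength recomputed against the
amplitude envelope each time, and the pixel zeroed unless its strength
reaches the smallest of the top ⌊α·n⌋ surrogate strengths (α = 0.05). If
the original is exchangeable with the surrogates under the null, a pixel
survives with probability ⌊α·n⌋/(n+1) ≈ α.

The default shuffle is a *block permutation*: the phase series is
circularly rolled by a random offset, cut into 1 s blocks and the blocks
permuted. This preserves the short-range autocorrelation that CWT-filtered
series necessarily carry — a full sample-wise permutation destroys it,
which makes the surrogate strengths systematically too small on
band-limited data and inflates the null retention far beyond α — while
still scrambling the long-range phase-amplitude alignment that genuine
coupling lives on. A plain circular shift is also calibrated but has no
power against strictly stationary periodic modulation (a shift only
rotates the coupled phase without changing the strength), so it is offered
as an option rather than the default; the full permutation is likewise
available for comparison.

## Synthetic signals

The generator emulates the signal structure the measure assumes: per
coupled component,

    x(t) = cos(ω_P t + φ₀) + [1 − d + d·(1 + cos(ω_P t + φ₀ − ψ))/2]·sin(ω_A t) + σ·n(t)

with modulation depth d ∈ [0, 1], coupled phase ψ, random initial phase
φ₀, and white (optionally pink) noise. The slow carrier is a cosine so
its wavelet phase equals the envelope's phase argument and the recovered ψ
matches the specification directly. The measured S grows monotonically
with d but is not numerically equal to it (for this envelope shape,
S ≈ 0.04 at d = 0.8 — KL-based modulation indices are small numbers).

Defaults: 10 s windows at 1000 Hz with 2 s of generated context per side,
noise σ = 0.3 relative to unit oscillation amplitude. Labelled datasets
draw per-window coupling parameters from class specifications: one coupled
component per low band (slow delta 1–2, fast delta 2–4, theta 4–8, alpha
8–10 Hz), phases from von Mises distributions (κ = 8) and depths from
truncated Gaussians. The default two classes mimic the qualitative
pattern of pathological vs. normal coupling — separable phases in slow
delta, fast delta and alpha, overlapping theta phases with deeper
pathological theta coupling; the numbers are package choices, not
measurements. A phase-only pair of specs (identical depth statistics,
different phases in every band) isolates the information carried by the
coupled phase. Windows are grouped into synthetic channels and patients so
that channel-level aggregation and leave-one-patient-out protocols are
exercised end to end; an optional class imbalance (≈ 1 : 2.77
pathological : normal) mirrors a realistic ictal dataset.

What the generator does *not* emulate: seizure dynamics and
non-stationarity, spikes and artifacts, volume conduction, inter-channel
correlation, or realistic 1/f spectra (unless pink noise is enabled).
Passing tests therefore demonstrate that the pipeline recovers the
structure it is designed to detect, not clinical performance on real SEEG.

## The complex-valued network

Inputs are the complex 10 × 10 images (one complex channel). The network
has three complex convolutional layers (3 × 3 kernels, 'same' padding)
and four complex fully connected layers. Complex multiplication is carried
through convolution and dense products; ReLU applies to real and imaginary
feature maps separately; complex batch normalisation standardises each
part per channel (batch mean 0, variance 1) with an independent learned
affine per part. A whitening variant normalises by the inverse principal
square root of the 2 × 2 real/imaginary covariance; its backward pass
treats the batch statistics as constants (the default per-part mode has
exact gradients, verified by finite differences). Dropout zeroes real and
imaginary parts together with one mask, on the first fully connected layer
only. The final complex activations become real logits through their
modulus (phase-invariant at the readout; a real-part mode exists), and the
loss is softmax cross-entropy.

Training: plain SGD, 800 epochs, batch size 128, learning rate 0.0025
halved at every multiple of 250 epochs, dropout 0.2, and L2 regularisation
with λ = 0.004 applied to the convolution weights only. Layer widths are
implementation choices (defaults 16/32/64 channels, FC 128/64/32/2; a
`small` preset with 4/8/8 and 32/16/8 at 200 epochs serves desk-scale
experiments). Everything is implemented in NumPy with hand-derived
backpropagation in the real/imaginary parameterisation (for the C-linear
layers: grad_W = G·conj(x), grad_x = conj(W)·G), and is deterministic
given the config seed. The same machinery with real dtype provides the
real-valued CNN baseline consuming two-layer (real/imaginary) or
strength-only images.

Class imbalance is not reweighted by default. Gradient checks compare
analytic and central-difference gradients at 1e−4 on small instances.

## Evaluation

A trained classifier labels windows; a channel's score is the fraction of
its windows predicted pathological (arg-max class by default; a
probability-threshold rule is available). Channels are thresholded on that
fraction, giving an ROC curve (threshold sweep over observed fractions,
trapezoidal AUC). The reported operating point maximises Youden's J =
sensitivity + specificity − 1, breaking ties toward the lower threshold.
Cross-validation is leave-one-patient-out with unweighted averaging of
per-patient AUCs; a held-out patient whose channels are single-class is
excluded from the average with a warning.

Band experiments: clinical bands are mapped to grid rows/columns by
interval centre (log-spaced edges do not align exactly with band
boundaries). Ablation replaces a band's pixels with Gaussian noise matched
to the per-part mean and variance of that region — statistics estimated on
the training split only, then applied to both splits of each
cross-validation round; a circularly-symmetric variant is available.
Row restriction cuts images to the gamma (30–80 Hz) or HFO (80–160 Hz)
rows for low-frequency–band-specific experiments.

Baselines: an RBF-SVM (default C = 2¹⁸, γ = 2², with a grid search over
C ∈ {2², 2⁶, …, 2¹⁸} and γ ∈ {2⁻¹⁰, 2⁻⁸, …, 2¹⁰} on a validation split)
and a 100-tree random forest, both on flattened per-part pixel features,
plus the real-valued CNN above.

## Problem sizes used by the test suite and acceptance script

Chosen as the package's desk-scale defaults: surrogate calibration uses
200 white-noise windows (20,000 pixels); phase recovery uses 8 target
phases × 50 seeded runs at d = 0.8, noise 0.3; the phase-information
experiment trains the small network for 200 epochs on 400 images per class
(20 channels per class) and evaluates on an independent 200 per class
spread over 100 channels per class; the cohort scaffolding run uses nine
synthetic patients with the example seizure-duration table (23 seizures,
2 channels per class per patient) and a deliberately tiny network (3
epochs), since it checks the protocol plumbing rather than accuracy.

## Known limitations

- The surrogate block length (1 s) is a fixed default; extremely slow
  rhythms (< 1 Hz) would need longer blocks for exact null calibration.
- The whitening batch-norm gradient approximation (statistics as
  constants) can slow convergence in that mode.
- The EDF writer covers the subset of EDF needed for fixtures (16-bit,
  integer rate, 1 s records); reading arbitrary clinical EDF goes through
  `mne` and inherits its handling of units and annotations.
- Modulation depth d and measured S are related monotonically but
  nonlinearly; no closed-form inverse is provided, only the empirical
  relation exercised in tests.
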