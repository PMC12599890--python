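# Methods

This note records the modelling conventions, parameter defaults and numerical
choices behind `ecgssm`, and what the synthetic-data tests do and do not
establish about real ECG corpora.

## Data model and I/O

A record is a `12 × n` matrix in millivolts with a sampling rate in
{257, 500, 1000} Hz on ingest (any positive rate is accepted from synthetic
fixtures), a set of diagnosis-code strings, and free-form header metadata.
On disk we support the challenge-style WFDB-like dialect (text `.hea` header
with per-lead gain and a `# Dx:` comment line; `.mat` companion holding the
integer matrix under `val`) and a portable `.dat` companion of little-endian
int16 frames. Leads are canonicalized to the standard order
I, II, III, aVR, aVL, aVF, V1–V6 on read by name; records without exactly
the twelve standard leads are rejected — no imputation, because any fill-in
policy would silently change the montage the model sees. Diagnosis codes
absent from the active vocabulary are dropped with a warning rather than
failing: the 2020 and 2021 challenge vocabularies differ and a reader must
tolerate both. Storage quantizes at the per-lead gain (default 1000 units/mV),
so round trips are exact to 0.5 µV.

## Preprocessing

Every record is brought to `12 × 8192` at 500 Hz:

* **1000 → 500 Hz**: polyphase decimation. The anti-aliasing FIR is a
  kaiser-windowed design (β = 8, 40·max(up,down) taps per side) rather than
  the short library default; this keeps passband ripple below 10⁻⁵ so that
  downsampling an upsampled band-limited signal round-trips to ~4·10⁻⁶
  relative RMS (the contract tested is 10⁻⁴).
* **257 → 500 Hz**: Fourier-domain resampling; content below 128.5 Hz is
  preserved.
* **Length**: shorter signals are zero-padded (end-padding by default,
  center optional); longer signals are cropped to one contiguous window
  whose start is uniform over valid positions, drawn once from
  `truncation_seed` and shared by all leads. Whether the window should be
  redrawn every epoch is an open reading; we fix it at preprocessing time
  for reproducibility.
* **Z-score**: population standard deviation (divide by n), per lead by
  default (per record available); constant leads map to zeros via an ε
  guard (ε = 10⁻¹⁰). Statistics are computed on the pre-pad support and the
  zeros are appended afterwards, so padding neither shrinks amplitudes nor
  shifts the mean — the padded zeros coincide with the standardized mean.
  Z-scoring has an off switch because preserved absolute amplitude can
  itself be diagnostic; the end-to-end synthetic training test runs with it
  off for exactly that reason (its class signal *is* an amplitude).

Output length under resampling is `floor(n · fs_out/fs_in + 0.5)`
(round half up), matching the polyphase implementation's ceiling behaviour
at exact halves.

## Non-uniform mixing

`participation_fraction(e)` = `min(0.2·e, 0.8)` for the default ramp — 20%
of the training set at epoch 1, +20 points per epoch, constant at 80% from
epoch 4 onward — plus `cycle` mode (an explicit per-epoch pattern with
repeat-last semantics, e.g. `(0, 0.6, 0.8, 0)`) and `constant` mode
(including the deliberately non-default 100% setting, which is known to hurt
this architecture). Exactly `round(f·N)` participants are drawn uniformly
without replacement; each partner is drawn uniformly from the entire
training set, and a sample may be participant and partner in the same epoch
(no exclusion). λ ~ Beta(α=10, β=10), one scalar per mixed pair (not per
lead or per time point), applied identically to signals and labels, so label
mass is conserved to machine precision and every mixed label entry is convex
in its parents. Whether the Beta distribution should also govern *partner
selection* is ambiguous in the source lineage of this scheme; we read it as
governing λ only, with uniform partner choice. CutMix swaps one contiguous
time segment (same position in all 12 leads, length `round(f·n)` clipped to
[1, n−1]) and mixes labels by the swapped fraction.

Augmentation operates on preprocessed arrays and rewrites the scheduled
samples in place for that epoch; `apply_epoch` returns an instrumentation
report (participants, partners, λ draws) that the acceptance machinery uses
to verify counts rather than trusting the formula.

## Architecture

* **Stem**: 8192 samples are right-padded with zeros to 8748 = 729·12, then
  stage 1 (kernel 8, stride 4) and stage 2 (kernel 6, stride 3), each with
  "same"-style padding, batch norm and ReLU, give exactly 729 tokens.
  Channel plan 12 → 192 → 384 at full scale. The reference configuration
  fixes the (729, 384) token geometry but not the kernel plan; this geometry
  is our choice, config-overridable, and pinned by a shape-contract test
  plus an interior translation-covariance test (a shift by one full stem
  stride shifts tokens by one position away from boundaries).
* **Blocks**: pre-norm residual. `h = LayerNorm(x)`; a forward selective
  scan over tokens 1..L and a backward scan over L..1 use separate parameter
  sets (whether the original blocks share them is unstated; separate is the
  more general choice); outputs are summed, gated by `sigmoid(affine(h))`,
  and projected by a zero-initialized output matrix, so every block starts
  as the identity and the reversal-equivariance contract (reverse input +
  swap direction parameters ⇒ reversed output) holds by construction.
* **Selective parameters**: Δt = softplus(affine(h)) per token and channel
  (bias initialized so initial steps are log-uniform in [10⁻³, 10⁻¹]);
  B, C affine in h; A diagonal-real, A = −exp(log_a) with log_a initialized
  to log(1..N) per channel — stability (|A_d| < 1) is guaranteed by the
  parameterization, not by clipping. D = 0 throughout.
* **Scan convention**: each output reads the state *after* absorbing its own
  input (h[n] = A_d h[n−1] + B_d u[n]; y[n] = C h[n]). The literal variant
  in which y[n] reads the pre-update state (so y[0] ignores u[0]) is
  available via `ssm_scan(..., convention="literal")`.
* **Head**: mean pooling over tokens, one linear layer to 26 logits.
* **Loss**: binary cross-entropy with logits against soft multilabel
  targets — the only standard choice compatible with mixed labels in [0,1].

Sizes: full scale 24 blocks / embed 384 / state 16 (≈15.6 M parameters); the
5-block ablation variant has ≈3.6 M (< ¼, dominated by the per-block cost);
the desk-scale test variant is 2 blocks / embed 16 / state 4 (≈6 k).

## Autodiff

Torch-free by design: a ~400-line reverse-mode core over numpy with exactly
the primitives the model needs. The selective scan is a fused primitive with
a hand-derived backpropagation-through-time backward; the ZOH factor
`(e^{AΔ}−1)/A` uses the exact identities d/dΔ = e^{AΔ} and
d/dA = (Δ e^{AΔ} A − (e^{AΔ}−1))/A², with the Δ²/2 limit below |A| < 10⁻⁸.
All primitive gradients (scan, strided conv1d, composed nonlinearities, the
BCE-with-logits reduction) are checked against central finite differences at
small sizes in the test suite.

## Training

Adam (β₁ = 0.9, β₂ = 0.999, ε = 10⁻⁸ — unstated upstream, library defaults
exposed in config) with either schedule:

* **Noam**: `lr(t) = d_model^{−1/2} min(t^{−1/2}, t ω^{−3/2})`, ω = 4000,
  and `d_model = 729` — the token-sequence length, not the embedding width,
  kept per the reference configuration. Both branches meet at t = ω (the
  global maximum), verified to 10⁻¹⁵.
* **StepLR**: 10⁻³ decayed by 0.1 every 20 epochs.

Batching drops the last incomplete batch, the convention under which 70,602
training records at batch 30 give exactly 2,353 steps per epoch. The
augmentation hook rewrites the scheduled fraction at each epoch start;
a NaN loss aborts with a diagnostic. Runs are deterministic for a given seed
on one device.

**Splits.** Single holdouts use train = `floor(0.8·n + 0.5)`: this one
round-half-up rule reproduces both challenge-corpus pairs (88,253 → 70,602/17,651
and 43,101 → 34,481/8,620, which differ in rounding direction). The 5-fold
assignment sizes fold 0 as `n − floor(0.8n + 0.5)` so holding out fold 0
matches the same arithmetic, and distributes the remainder over the other
folds. Stratification is iterative multilabel stratification: labels are
processed rarest-first and each positive record goes to the fold with the
greatest remaining demand for that label (ties by remaining capacity, then
seeded choice); label-free records fill remaining capacity.

## Evaluation

AUROC is the normalized Mann–Whitney U (ties count half); AUPRC is average
precision — the step integral of the PR curve, the mean of precision at each
positive in stable score-descending order (not trapezoidal interpolation;
the two differ and the convention must be fixed). A class enters the macro
averages only when the evaluation set contains at least one positive *and*
one negative for it; excluded classes are reported by name. Both metrics are
cross-checked against scikit-learn on tie-free random data to 10⁻⁶, and
against brute-force pair counting / rank enumeration oracles at n ≤ 20. The
Challenge Score is not computed (it depends on the official class-similarity
weight matrix, an external artifact); the report schema reserves a field.

## Synthetic data: what it shows and what it does not

Records are sums of five Gaussian bumps per beat (P, Q, R, S, T amplitudes,
widths and offsets), projected to the 12 leads by a fixed scaling vector,
with jittered RR intervals and white noise. Defaults: RR 1.0 s, noise
0.05 mV, durations 8–12 s, and an fs mixture matching the challenge corpus
proportions (≈99.3% at 500 Hz, small 1000/257 Hz minorities). Multilabel
structure: a primary class drawn from configured prevalences plus, at the
`multilabel_rate`, one secondary class. One root `SeedSequence` is split per
record, so generation is order-independent and byte-reproducible.

The two-class end-to-end fixture differs only in R amplitude (1.40 vs
0.35 mV against a 0.05 mV noise floor), making it separable by a bare peak
threshold — by design, so that the training smoke test isolates pipeline
correctness (gradients flow, the scheduler mixes the right counts, metrics
compute) from modelling power. Passing it says nothing about performance on
real cardiac abnormalities: the generator has no pathology-accurate
morphologies, no baseline wander, powerline or muscle artifact, no
vectorcardiographic lead physics, and its class structure is far easier than
the challenge's 26-way imbalanced task.

## Problem sizes

The test suite and acceptance checks run at desk scale as the package's own
configuration: the 2-block/embed-16 model, 200 training + 60 held-out
synthetic records, 5 epochs at batch 10 (100 Adam steps), StepLR 10⁻³, and
z-scoring off for the amplitude-separable fixture. Oracle equivalences use
L ≤ 64, state ≤ 8 for scans and n ≤ 20 for metric enumeration; scheduler
percentages are measured on N = 1000.

## Known limitations

* The scan is a sequential reference implementation; full-scale (24-block)
  training is impractical on CPU and out of scope — full-scale code paths
  are exercised forward-only (shape and parameter-count contracts).
* Diagonal-real A; complex or structured state matrices are not implemented.
* No denoising or artifact handling in preprocessing (none is applied
  upstream either).
* `make_splits` balances best-effort when a class has fewer positives than
  folds; exact ±1 proportionality is only guaranteed when feasible.
* The portable `.dat` dialect stores int16 only; very large amplitudes
  require lowering the gain.
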