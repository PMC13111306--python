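# Methods

This note documents the models, parameters and design choices behind
`kerasym`, in the spirit of a methods appendix: what is computed, under
which assumptions, and what the synthetic benchmarks do and do not show.

## Biometry model

A per-eye record carries seven quantities: K1 and K2 (flat/steep
keratometry, diopters), Kmax (maximum keratometry, D), CCT (central corneal
thickness, µm), axial length and anterior chamber depth (mm), and
astigmatism magnitude. Astigmatism is defined as `K2 − K1` with no axis
(magnitude-only); Kmax is treated as an opaque maximum-keratometry scalar
without committing to anterior-axial vs. total power, since devices differ.

A measurement session is a set of repeat scans (three by default).
Aggregation takes the **median per parameter independently** across the
scans where the parameter is present; astigmatism is the median of the
per-scan `K2 − K1` differences so both keratometry values always come from
the same acquisition. The median suppresses single-scan outliers and, for
odd scan counts, always equals an observed value.

Missing values are explicit sentinels and never imputed: quality control
excludes records rather than repairing them. QC reasons are `incomplete`
(any parameter missing), `implausible_range` (outside configurable windows,
defaults K ∈ [35, 60] D, CCT ∈ [350, 700] µm, AL ∈ [19, 32] mm,
ACD ∈ [1.5, 5.0] mm — generous physiologic ranges) and `inconsistent`
(K2 < K1, Kmax < K2 − 0.5 D, negative astigmatism). The 0.5 D Kmax
tolerance acknowledges that a point maximum estimated from a map can sit
slightly below the fitted steep meridian.

One record is one eye. Inter-eye correlation (patients contribute two
correlated eyes) is the caller's responsibility; the generator emits
independent eyes and real studies typically select one eye per patient.

## Knowledge graph and evidence activation

The graph is a three-layer DAG: parameter nodes (K1, K2, Kmax, CCT, AL,
ACD, astigmatism, I-S asymmetry), diagnosis nodes (`early_keratoconus`,
`normal_cornea`), decision nodes (`surgery_candidate`,
`surgery_contraindicated`). Edges point parameter→diagnosis,
diagnosis→decision or parameter→decision; each parameter-source edge
carries a threshold rule `(feature, direction, τ, s)` and a weight
`w ∈ [0, 1]`.

Evidence activation is logistic, `a = σ((x − τ)/s)` for direction `above`
(mirrored for `below`); `s = 0` degenerates to a hard step with `a = 0.5`
exactly at the threshold. Soft activations were chosen as the default
because they give continuous scores (needed for ROC analysis) while
recovering rule-book behavior as `s → 0`. Activation is monotone in the
feature by construction.

Shipped default rules (configuration values, not clinically validated):

| rule | feature | direction | τ | s | w | target |
|------|---------|-----------|---|---|---|--------|
| R1 | Kmax | above | 47.0 D | 0.5 | 0.60 | early_keratoconus |
| R2 | CCT | below | 500 µm | 10 | 0.45 | early_keratoconus |
| R3 | K2−K1 | above | 2.0 D | 0.3 | 0.25 | early_keratoconus |
| R4 | I-S asymmetry | above | 1.4 D | 0.3 | 0.50 | early_keratoconus |
| R5 | CCT | below | 480 µm | 0 (hard) | 1.0 | surgery_contraindicated |

R1/R2 encode the steep-Kmax/thin-cornea ectasia signature; R3/R4
operationalize irregular astigmatism via magnitude and the classical
inferior-superior index. All of them, and the diagnosis prior, live in the
graph data file and can be overridden without code changes — the package
is deliberately config-first because real clinical thresholds are
site-specific.

## Inference

The posterior of early keratoconus is a **noisy-OR with leak**:

    P(KC) = 1 − (1 − p₀) · ∏ᵢ (1 − wᵢ·aᵢ)

where the product runs over rule edges into the diagnosis node, `p₀` is
the screening prior (default 0.05) acting as the leak, and each weight is
interpretable as the link probability of an independent risk factor. This
is the standard Bayesian-network combiner for independent causes; it is
exactly reproduced by brute-force enumeration over cause-activation
outcomes (a property the test suite checks to 1e−12), monotone in every
`wᵢ` and `aᵢ`, and bounded in `[p₀, 1]`. The normal-cornea hypothesis is
the complement `1 − P(KC)` — the task is binary screening, so no
multi-diagnosis normalization machinery is introduced.

Eligibility: contraindicated iff `P(KC) ≥ τ_d` (default τ_d = 0.30,
favoring sensitivity in a screening setting) or any hard parameter→decision
rule reached activation 1. A hard pachymetry veto therefore overrides a low
posterior.

Neural–symbolic fusion is a logit-linear pool,
`logit(p) = (1−α)·logit(p_sym) + α·logit(p_neur)`, with probabilities
clamped to [1e−6, 1−1e−6] before the logit for numerical safety. Default
α = 0 (recommended α = 0.3 when an encoder is trained): the out-of-box
pipeline is purely symbolic and bit-identical whether or not an encoder
exists.

Every run assembles a four-stage reasoning trace — measured parameters,
rule evaluations, posterior terms, decision rationale — whose numbers are
exact (unrounded) copies of the values the combiner used. A rule is
reported as "fired" when its activation exceeds 0.5, i.e. the feature is
strictly past its threshold.

## Curvature maps, indices, encoder

Rendered axial maps live on a square grid (default 64 px over 9 mm),
apex-centered, +y superior; inside the corneal disc the power is

    K(x, y) = mean_k + (astig/2)·cos(2(θ − axis)) + A·exp(−d²/(2σ²))

— a with-the-rule bowtie (steep axis 90° by default) plus a Gaussian cone
bump; pixels outside the disc carry a defined background value (0 D).
For early-KC eyes the cone amplitude is set so the map maximum matches the
eye's Kmax; normal eyes have no cone, so their map maximum is mean_k +
astig/2, slightly below the recorded Kmax — the rendered map deliberately
does not fake focal steepening that is not in the latent cone.

The I-S asymmetry index is the mean power over the inferior half
(angle ∈ (180°, 360°)) of a 2–3 mm annulus minus the superior counterpart,
the classical keratoconus screening formula; it is invariant to adding a
constant to the map, zero for a pure vertical bowtie by mirror symmetry,
and positive for inferior cones. Maps must cover ≥ 6 mm diameter.

The encoder is a compact CNN→transformer: two stride-2 3×3 conv layers
(8, 16 channels), 4×4 patching into 16 tokens, linear projection to
dimension 64 with learned positional embeddings, two pre-norm transformer
blocks (4 heads, MLP 128), token mean-pooling and a unit-norm projection.
Training aligns map embeddings with two *learned* diagnosis-node
embeddings via symmetric InfoNCE at temperature 0.1 (map→node cross-entropy
plus node→map, uniform over the class's batch members), optimized by SGD
with momentum 0.9 under a cosine learning-rate schedule (0.05 → 0.0005,
≤ 40 epochs), early-stopped on a stratified 20% validation split with
patience 8 and best-validation parameters returned. The validation fold's
labels are read only through the early-stopping loss. The neural score of
a map is the softmax over cosine similarities to the two node embeddings
(training temperature), reported as the early-keratoconus component.

The whole stack runs in float64 on a small reverse-mode autodiff engine
written for this package (broadcasting arithmetic, batched matmul, im2col
convolution, softmax/log-softmax, shape ops), gradient-checked against
central finite differences to ~1e−10 relative error. Seeded,
single-threaded training is bit-reproducible and is the tested mode; sizes
were chosen so the 200-map benchmark trains in seconds on one CPU.

## Synthetic cohorts

Two modes serve two different purposes.

**Marginal mode** draws each of the seven parameters independently from an
untruncated normal at the published cohort calibration statistics
(K1 43.21 ± 1.18 D, K2 44.36 ± 1.42 D, Kmax 46.02 ± 2.15 D,
CCT 532.6 ± 28.4 µm, AL 24.18 ± 1.12 mm, ACD 3.21 ± 0.38 mm,
astigmatism 1.15 ± 0.72 D). Printed cohort min/max values are treated as
observed extremes, not truncation bounds, which keeps mean recovery
unbiased. Because the draws are independent, individual marginal-mode eyes
can violate the clinical ordering K1 ≤ K2 ≤ Kmax (the joint distribution
is not modeled — the published source gives no covariances); this mode is
for distribution-level calibration checks, not for eye-level pipeline runs.

**Labeled mode** (the default) generates a two-class benchmark with
class-conditional effect sizes chosen to produce the canonical early-KC
signature (all values are package choices, documented here, not published
values): both classes draw K1 ~ N(43.0, 1.0); the normal class has
astigmatism |N(0.9, 0.5)|, Kmax excess |N(0.8, 0.4)| and CCT N(545, 25);
the early-KC class has astigmatism |N(1.8, 0.8)|, Kmax excess N(4.5, 1.5)
floored at 2.5 D and CCT N(495, 25); AL and ACD follow the calibration
values in both classes. The Kmax excess is additionally floored at
astig/2 (a map maximum cannot sit below the steep meridian), and draws are
clipped just inside the QC windows (≥ 4σ tails, negligible distortion), so
every labeled eye satisfies the record invariants and passes default QC.
Early-KC eyes carry an inferior paracentral cone: center radius U(1, 2) mm,
angle N(270°, 20°), width σ U(0.8, 1.4) mm, amplitude set to hit Kmax at
the cone apex — the canonical early-KC morphology.

Repeat-scan noise is zero-mean Gaussian per parameter (defaults 0.10 D for
keratometry, 3 µm CCT, 0.02 mm AL, 0.03 mm ACD — repeatability-scale
values; true device noise is not published, so these are explicit config).
After adding noise each scan is relabeled with device semantics: K1/K2 are
sorted (they are meridian labels, a device never reports K2 < K1) and Kmax
is floored at K2 (it is a map maximum). For a consistent eye this is the
identity unless noise crosses the labels; it is what guarantees that every
default-configuration eye survives QC after aggregation.

What the synthetic data does *not* emulate: inter-eye/patient correlation,
parameter covariances within an eye, posterior-surface and elevation data,
device artifacts (tear film, eyelid shadow), and any realistic overlap
structure between classes — the labeled benchmark is deliberately
well-separated. Benchmark results (pooled symbolic AUC ≈ 0.99, encoder
held-out AUC ≈ 0.99) therefore demonstrate that the pipeline is correctly
wired and that its components rank the intended signal; they say nothing
about clinical performance on real corneas.

## Evaluation choices

- AUC uses the Mann-Whitney rank statistic with half-credit ties (so
  all-tied scores give exactly 0.5); the test suite cross-checks it against
  exhaustive pair enumeration and an independent library implementation.
- Bootstrap CIs: case resampling of (label, score) pairs, default 1,000
  replicates, percentile 2.5/97.5; replicates that lose a class are
  skipped.
- Cross-validation: seeded shuffle + round-robin assignment, stratified by
  label; fold sizes and per-fold class counts differ by at most one. A
  leakage guard errors if an eye appears on both sides of a fold, and the
  scoring path receives records only (never held-out labels).
- Both pooled and fold-averaged metrics are reported; pooled is primary.
  Confusion metrics are reported at τ_d and at the pooled Youden-optimal
  threshold, both labeled as such.
- Undefined metrics (no positives, constant raters) return NaN sentinels
  with warnings, never silent zeros.
- Benchmark sizes (10,000 eyes for calibration, 1,000 for the symbolic CV
  benchmark, 200 maps for the encoder) were chosen as the smallest sizes at
  which the quantities of interest are statistically stable on a single
  CPU in seconds to minutes.

## Reporting

Reports are pure functions of (trace, catalog, audience, language).
Catalogs are versioned JSON data files; English and Simplified Chinese
ship with the package (the bilingual clinical setting this targets), and
any language can be added by supplying a catalog with the same keys —
section structure is identical across languages by construction.
Physician reports render every fired rule with its observed value,
threshold and direction, and print probabilities to three decimals; the
full-precision trace is embedded as a JSON appendix so every printed
number is auditable. Patient summaries map the posterior to
low (< 0.1) / moderate / elevated (≥ τ_d) bands — the elevated band starts
exactly at the decision threshold so patient wording can never contradict
the decision — and are linted against a jargon blocklist at render time.
The external-generator adapter passes the trace and deterministic report
as grounding context and falls back to the deterministic report on any
failure, so the core pipeline never depends on a network service.

## Known limitations

- All thresholds/weights/priors are placeholders pending site-specific
  calibration; the package enforces this by keeping them config-first.
- Astigmatism is magnitude-only; meridian/axis handling is out of scope.
- The marginal generator models marginals only (no covariance), and the
  labeled benchmark is easier than real screening populations.
- The encoder is desk-scale by design; it is not a pretrained clinical
  model and its scores are calibrated only through the softmax temperature.
- Multi-threaded numerics may not be bit-reproducible; the determinism
  contract covers single-threaded execution.
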