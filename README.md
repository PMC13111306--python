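# kerasym

Explainable neuro-symbolic screening of **early keratoconus** from ocular
biometry and axial curvature maps, with structured bilingual report
generation and a fully synthetic, seeded test bed.

Keratoconus is a progressive corneal ectasia: the cornea thins and steepens
focally, usually infero-paracentrally. Catching it early matters most in
refractive-surgery screening, because operating on an ectatic cornea risks
post-operative ectasia. Screening relies on a handful of biometric
parameters per eye — flat/steep keratometry (K1/K2, diopters), maximum
keratometry (Kmax), central corneal thickness (CCT, µm), axial length and
anterior chamber depth (mm), astigmatism magnitude (K2−K1) — plus the
spatial pattern of the axial curvature map (regular "bowtie" astigmatism
vs. an inferior cone).

`kerasym` is for researchers and tool builders who want a *transparent*
screening pipeline: every probability it reports can be traced to named
clinical rules with explicit thresholds, and every artifact is reproducible
from a seed.

## What it computes

1. **Biometry handling** — parses per-eye scan sets (JSON/CSV, schema in
   `src/kerasym/data/record_schema.json`), aggregates triplicate scans by
   per-parameter medians, applies quality control (incomplete, implausible,
   inconsistent), and derives the features rules consume
   (mean K, K2−K1, Kmax excess).
2. **Knowledge graph** — a layered DAG of parameter → diagnosis → decision
   nodes. Each parameter edge carries a threshold rule with a logistic
   softness; evidence activation is `a = σ((x − τ)/s)` (a hard step as
   `s → 0`). The default graph ships as a data file; every threshold,
   weight and prior is config-overridable.
3. **Bayesian inference** — a noisy-OR combiner over the activated rules:

       P(KC) = 1 − (1 − p₀) · ∏ᵢ (1 − wᵢ·aᵢ)

   with leak `p₀` = screening prior (default 0.05). Surgery eligibility is
   decided by the posterior against a threshold τ_d (default 0.30) plus
   hard contraindication rules (e.g. CCT < 480 µm). Each step is recorded
   in a machine-readable **reasoning trace**.
4. **Map features & encoder** — deterministic morphology indices
   (inferior–superior asymmetry over a 2–3 mm annulus, map maximum), and a
   compact convolutional + transformer encoder trained with symmetric
   InfoNCE to align map embeddings with the two diagnosis-node embeddings.
   Its score can be fused with the symbolic posterior by a logit-linear
   pool (weight α; α = 0, the default, is purely symbolic).
5. **Reports** — deterministic physician and patient reports in English and
   Simplified Chinese, rendered from the trace; patient wording is banded
   (low / moderate / elevated, aligned with τ_d) and jargon-linted. An
   adapter hook lets you plug in an external text generator with the trace
   as grounding; failures fall back to the deterministic report.
6. **Evaluation** — stratified k-fold plans with a leakage guard, confusion
   metrics, Mann-Whitney AUC with bootstrap CIs, Cohen's κ, and an
   end-to-end cross-validated benchmark over a cohort directory.
7. **Synthetic cohorts** — a seeded generator with two modes: *marginal*
   (each parameter drawn from a normal calibrated to published cohort
   summary statistics, e.g. K1 43.21 ± 1.18 D) and *labeled* (a two-class
   benchmark with the early-KC signature: steep Kmax, thin cornea, inferior
   cone), plus triplicate-scan device noise and rendered curvature maps.

## Worked example

```python
import kerasym as ks

eye = next(e for e in ks.sample_cohort(ks.CohortSpec(n_eyes=10, seed=21))
           if e.label == "early_kc")
record = ks.aggregate_scans(ks.simulate_repeat_scans(eye, seed=1))
feats = ks.derive_features(record)
indices = ks.compute_map_indices(ks.render_curvature_map(eye))

graph = ks.build_default_graph()
evidence = ks.activate_evidence(record, feats, indices, graph)
diagnosis = ks.infer_posterior(evidence, graph)
decision = ks.decide_eligibility(diagnosis, evidence, graph)
print(f"P(early keratoconus) = {diagnosis.p_kc:.3f}  ->  {decision.eligibility}")
```

prints

```
P(early keratoconus) = 0.419  ->  contraindicated
```

Here the eye's thin cornea (490.3 µm, below the 500 µm rule threshold)
contributes `w·a = 0.326`, lifting the posterior from the 0.05 prior to
0.419 — above the 0.30 decision threshold, so the eye is flagged as a
surgery contraindication. `ks.build_trace(...)` packages the whole chain,
and `ks.generate_physician_report(trace, "en")` /
`ks.generate_patient_summary(trace, "zh")` render it. Run
`python examples/02_symbolic_inference_and_report.py` for the full output;
the other `examples/` scripts cover cohort simulation, map indices, encoder
training (held-out AUC 0.988 in ~15 s on one CPU) and the five-fold
benchmark (pooled AUC 0.995 on the default 1,000-eye cohort).

There is also a thin CLI:

```bash
kerasym simulate --n 50 --seed 7 --out cohort/
kerasym infer --records cohort/records.json --maps cohort/maps --graph default --out traces/
kerasym report --traces traces/ --audience physician --lang en --out reports/
kerasym evaluate --cohort cohort/ --mode symbolic --k 5 --seed 7
kerasym validate-graph mygraph.json
```

## Caveats

The shipped rule thresholds, weights and priors are documented
configuration defaults, not clinically validated values — substitute
site-specific values via the graph file or config before drawing any
clinical conclusion. See `docs/methods.md` for the model, the synthetic
data's assumptions, and known limitations.
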