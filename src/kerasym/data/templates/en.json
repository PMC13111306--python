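{
 "language": "en",
 "param_labels": {
  "k1_D": ["Flat keratometry (K1)", "D"],
  "k2_D": ["Steep keratometry (K2)", "D"],
  "kmax_D": ["Maximum keratometry (Kmax)", "D"],
  "cct_um": ["Central corneal thickness", "µm"],
  "axial_length_mm": ["Axial length", "mm"],
  "acd_mm": ["Anterior chamber depth", "mm"],
  "astigmatism_D": ["Corneal astigmatism", "D"],
  "mean_k_D": ["Mean keratometry", "D"],
  "astig_kdiff_D": ["Keratometric cylinder (K2−K1)", "D"],
  "kmax_excess_D": ["Kmax excess over mean K", "D"],
  "is_asymmetry_D": ["Inferior-superior asymmetry", "D"],
  "max_power_D": ["Map maximum power", "D"]
 },
 "physician": {
  "title": "Corneal biometry interpretation — physician report (eye {eye_id}, {laterality})",
  "measurements_header": "Measured and derived parameters",
  "measurement_row": "- {label}: {value} {units}",
  "evidence_header": "Diagnostic evidence",
  "evidence_row": "- [{rule_id}] {label} = {observed} {units} ({direction} threshold {threshold} {units}); evidence activation {activation}",
  "evidence_none": "No diagnostic criteria were met by the measured parameters.",
  "skipped_note": "Note: rules {rules} were not evaluated (no curvature-map indices supplied).",
  "probability_header": "Probability assessment",
  "probability": "Estimated probability of early keratoconus: {p_kc} (screening prior {prior}).",
  "decision_header": "Surgical eligibility",
  "decision_candidate": "The eye is a refractive-surgery candidate at decision threshold {threshold}.",
  "decision_contraindicated": "Refractive surgery is contraindicated at decision threshold {threshold}.",
  "hard_rule_note": "Absolute contraindication triggered by rule(s): {rules}.",
  "caveats_header": "Caveats",
  "caveats": "This automated interpretation supports, but does not replace, clinical judgement. Thresholds and weights are configuration values and must be locally validated before clinical use."
 },
 "patient": {
  "title": "Your corneal examination summary",
  "summary": "We measured the shape and thickness of the front surface of your eye ({laterality}).",
  "risk_low": "The measurements look reassuring: the likelihood of an early corneal shape condition (keratoconus) is low.",
  "risk_moderate": "Some measurements deserve a follow-up look: the likelihood of an early corneal shape condition (keratoconus) is moderate.",
  "risk_elevated": "Several measurements stand out: the likelihood of an early corneal shape condition (keratoconus) is elevated, and your doctor will discuss next steps with you.",
  "advice_candidate": "Based on these measurements, laser vision correction remains an option to discuss with your doctor.",
  "advice_contraindicated": "Based on these measurements, laser vision correction is not advisable at this time; your doctor will explain the alternatives.",
  "caveats": "This summary is generated automatically from your measurements. Please discuss any questions with your eye doctor."
 }
}
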