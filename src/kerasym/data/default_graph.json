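{
 "version": "1",
 "priors": {
  "early_keratoconus": 0.05,
  "normal_cornea": 0.95
 },
 "nodes": [
  {"node_id": "k1", "category": "parameter", "label": "Flat keratometry (K1)", "labels": {"en": "Flat keratometry (K1)", "zh": "平坦角膜曲率 (K1)"}},
  {"node_id": "k2", "category": "parameter", "label": "Steep keratometry (K2)", "labels": {"en": "Steep keratometry (K2)", "zh": "陡峭角膜曲率 (K2)"}},
  {"node_id": "kmax", "category": "parameter", "label": "Maximum keratometry (Kmax)", "labels": {"en": "Maximum keratometry (Kmax)", "zh": "最大角膜曲率 (Kmax)"}},
  {"node_id": "cct", "category": "parameter", "label": "Central corneal thickness", "labels": {"en": "Central corneal thickness", "zh": "中央角膜厚度"}},
  {"node_id": "axial_length", "category": "parameter", "label": "Axial length", "labels": {"en": "Axial length", "zh": "眼轴长度"}},
  {"node_id": "acd", "category": "parameter", "label": "Anterior chamber depth", "labels": {"en": "Anterior chamber depth", "zh": "前房深度"}},
  {"node_id": "astigmatism", "category": "parameter", "label": "Corneal astigmatism", "labels": {"en": "Corneal astigmatism", "zh": "角膜散光"}},
  {"node_id": "is_asymmetry", "category": "parameter", "label": "Inferior-superior asymmetry", "labels": {"en": "Inferior-superior asymmetry", "zh": "下上方不对称指数"}},
  {"node_id": "early_keratoconus", "category": "diagnosis", "label": "Early keratoconus", "labels": {"en": "Early keratoconus", "zh": "早期圆锥角膜"}},
  {"node_id": "normal_cornea", "category": "diagnosis", "label": "Normal cornea", "labels": {"en": "Normal cornea", "zh": "正常角膜"}},
  {"node_id": "surgery_candidate", "category": "decision", "label": "Refractive surgery candidate", "labels": {"en": "Refractive surgery candidate", "zh": "适合屈光手术"}},
  {"node_id": "surgery_contraindicated", "category": "decision", "label": "Refractive surgery contraindicated", "labels": {"en": "Refractive surgery contraindicated", "zh": "屈光手术禁忌"}}
 ],
 "edges": [
  {"source": "kmax", "target": "early_keratoconus", "weight": 0.60,
   "rule": {"rule_id": "R1", "parameter": "kmax_D", "direction": "above", "threshold": 47.0, "softness": 0.5}},
  {"source": "cct", "target": "early_keratoconus", "weight": 0.45,
   "rule": {"rule_id": "R2", "parameter": "cct_um", "direction": "below", "threshold": 500.0, "softness": 10.0}},
  {"source": "astigmatism", "target": "early_keratoconus", "weight": 0.25,
   "rule": {"rule_id": "R3", "parameter": "astig_kdiff_D", "direction": "above", "threshold": 2.0, "softness": 0.3}},
  {"source": "is_asymmetry", "target": "early_keratoconus", "weight": 0.50,
   "rule": {"rule_id": "R4", "parameter": "is_asymmetry_D", "direction": "above", "threshold": 1.4, "softness": 0.3}},
  {"source": "cct", "target": "surgery_contraindicated", "weight": 1.0,
   "rule": {"rule_id": "R5", "parameter": "cct_um", "direction": "below", "threshold": 480.0, "softness": 0.0}},
  {"source": "early_keratoconus", "target": "surgery_contraindicated", "weight": 0.9, "rule": null},
  {"source": "normal_cornea", "target": "surgery_candidate", "weight": 0.9, "rule": null}
 ]
}
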