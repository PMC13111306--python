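{
 "language": "zh",
 "param_labels": {
  "k1_D": ["平坦角膜曲率 (K1)", "D"],
  "k2_D": ["陡峭角膜曲率 (K2)", "D"],
  "kmax_D": ["最大角膜曲率 (Kmax)", "D"],
  "cct_um": ["中央角膜厚度", "µm"],
  "axial_length_mm": ["眼轴长度", "mm"],
  "acd_mm": ["前房深度", "mm"],
  "astigmatism_D": ["角膜散光", "D"],
  "mean_k_D": ["平均角膜曲率", "D"],
  "astig_kdiff_D": ["角膜柱镜 (K2−K1)", "D"],
  "kmax_excess_D": ["Kmax 相对平均曲率的增量", "D"],
  "is_asymmetry_D": ["下上方不对称指数", "D"],
  "max_power_D": ["地形图最大屈光力", "D"]
 },
 "physician": {
  "title": "角膜生物测量解读 — 医师报告（眼 {eye_id}，{laterality}）",
  "measurements_header": "测量及衍生参数",
  "measurement_row": "- {label}：{value} {units}",
  "evidence_header": "诊断证据",
  "evidence_row": "- [{rule_id}] {label} = {observed} {units}（{direction} 阈值 {threshold} {units}）；证据激活度 {activation}",
  "evidence_none": "所测参数未满足任何诊断标准。",
  "skipped_note": "注：规则 {rules} 未被评估（未提供角膜地形图指数）。",
  "probability_header": "概率评估",
  "probability": "早期圆锥角膜的估计概率：{p_kc}（筛查先验 {prior}）。",
  "decision_header": "手术适应性",
  "decision_candidate": "在决策阈值 {threshold} 下，该眼适合屈光手术。",
  "decision_contraindicated": "在决策阈值 {threshold} 下，屈光手术为禁忌。",
  "hard_rule_note": "绝对禁忌由以下规则触发：{rules}。",
  "caveats_header": "注意事项",
  "caveats": "本自动解读仅辅助而不能替代临床判断。阈值与权重均为配置值，临床使用前须经本地验证。"
 },
 "patient": {
  "title": "您的角膜检查小结",
  "summary": "我们测量了您（{laterality}）眼睛前表面的形状和厚度。",
  "risk_low": "各项测量结果令人放心：出现早期角膜形状异常（圆锥角膜）的可能性较低。",
  "risk_moderate": "部分测量结果值得随访复查：出现早期角膜形状异常（圆锥角膜）的可能性为中等。",
  "risk_elevated": "多项测量结果较为突出：出现早期角膜形状异常（圆锥角膜）的可能性偏高，医生会与您讨论后续安排。",
  "advice_candidate": "根据这些测量结果，激光视力矫正仍是可与医生讨论的选择。",
  "advice_contraindicated": "根据这些测量结果，目前不建议进行激光视力矫正；医生会为您说明其他方案。",
  "caveats": "本小结由测量数据自动生成。如有任何疑问，请咨询您的眼科医生。"
 }
}
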