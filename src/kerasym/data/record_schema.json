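{
 "title": "Per-eye biometry record schema",
 "description": "Schema of the JSON and CSV record formats accepted by kerasym.biometry.parse_records. Units: keratometry in diopters (D), central corneal thickness in micrometers (um), axial length and anterior chamber depth in millimeters (mm). Decimal separator '.', encoding UTF-8. Missing measurements are null (JSON) or empty cells (CSV), never zero.",
 "json_format": {
  "type": "array",
  "items": {
   "type": "object",
   "required": ["eye_id", "laterality", "scans"],
   "properties": {
    "eye_id": {"type": "string", "description": "opaque per-eye identifier, unique within a file"},
    "laterality": {"enum": ["OD", "OS"]},
    "scans": {
     "type": "array",
     "minItems": 1,
     "description": "repeat acquisitions from one session; 'order' must be unique per eye",
     "items": {
      "type": "object",
      "required": ["order"],
      "properties": {
       "order": {"type": "integer"},
       "k1_D": {"type": ["number", "null"], "description": "flat keratometry, D"},
       "k2_D": {"type": ["number", "null"], "description": "steep keratometry, D"},
       "kmax_D": {"type": ["number", "null"], "description": "maximum keratometry, D"},
       "cct_um": {"type": ["number", "null"], "description": "central corneal thickness, um"},
       "axial_length_mm": {"type": ["number", "null"]},
       "acd_mm": {"type": ["number", "null"], "description": "anterior chamber depth, mm"}
      }
     }
    }
   },
   "additionalProperties": "preserved as opaque metadata"
  }
 },
 "csv_format": {
  "description": "One row per scan. Header required.",
  "columns": ["eye_id", "laterality", "order", "k1_D", "k2_D", "kmax_D", "cct_um", "axial_length_mm", "acd_mm"]
 }
}
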