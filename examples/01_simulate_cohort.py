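"""Simulate a labeled synthetic cohort and write it to disk.

Builds 50 eyes (half normal, half early keratoconus), simulates the
triplicate scans with device noise, renders axial curvature maps, and
writes the schema-conformant cohort directory with a checksummed manifest.
"""

from pathlib import Path

import kerasym as ks

out = Path("scratch/example_cohort")
spec = ks.CohortSpec(n_eyes=50, seed=7)
eyes = ks.sample_cohort(spec)
scans = [ks.simulate_repeat_scans(e, seed=ks.derive_seed(7, e.eye_id)) for e in eyes]
maps = [ks.render_curvature_map(e) for e in eyes]
manifest = ks.write_cohort(eyes, scans, maps, out, write_png=True)

n_kc = sum(1 for e in eyes if e.label == "early_kc")
print(f"wrote {manifest['n_eyes']} eyes ({n_kc} early keratoconus) to {out}")
print(f"files in manifest: {len(manifest['files'])}")
example = eyes[0]
print(f"example truth {example.eye_id} [{example.label}]: "
      f"K1={example.true_params.k1_D:.2f} D, Kmax={example.true_params.kmax_D:.2f} D, "
      f"CCT={example.true_params.cct_um:.0f} um")
# The manifest checksums let you verify byte-identical regeneration from the same seed.
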