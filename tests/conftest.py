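import numpy as np
import pytest

import kerasym as ks


@pytest.fixture(scope="session")
def default_graph():
    return ks.build_default_graph()


@pytest.fixture(scope="session")
def labeled_cohort():
    """Small default-configuration labeled cohort with scans and maps."""
    eyes = ks.sample_cohort(ks.CohortSpec(n_eyes=20, seed=123))
    scan_sets = [ks.simulate_repeat_scans(e, seed=ks.derive_seed(123, e.eye_id)) for e in eyes]
    maps = [ks.render_curvature_map(e) for e in eyes]
    return eyes, scan_sets, maps


@pytest.fixture(scope="session")
def example_trace(default_graph, labeled_cohort):
    """A full reasoning trace for the first eye of the small cohort."""
    eyes, scan_sets, maps = labeled_cohort
    record = ks.aggregate_scans(scan_sets[0])
    feats = ks.derive_features(record)
    indices = ks.compute_map_indices(maps[0])
    evidence = ks.activate_evidence(record, feats, indices, default_graph)
    diagnosis = ks.infer_posterior(evidence, default_graph)
    decision = ks.decide_eligibility(diagnosis, evidence, default_graph)
    return ks.build_trace(record, feats, evidence, diagnosis, decision)


def make_two_eye_json(tmp_path, name="records.json"):
    import json

    records = [
        {
            "eye_id": "A",
            "laterality": "OD",
            "site": "clinic-1",
            "scans": [
                {"order": 1, "k1_D": 43.0, "k2_D": 44.0, "kmax_D": 45.0, "cct_um": 540.0, "axial_length_mm": 24.0, "acd_mm": 3.2},
                {"order": 2, "k1_D": 43.2, "k2_D": 44.1, "kmax_D": 45.2, "cct_um": 542.0, "axial_length_mm": 24.1, "acd_mm": 3.1},
                {"order": 3, "k1_D": 43.1, "k2_D": 43.9, "kmax_D": 45.1, "cct_um": 538.0, "axial_length_mm": 23.9, "acd_mm": 3.3},
            ],
        },
        {
            "eye_id": "B",
            "laterality": "OS",
            "scans": [
                {"order": 1, "k1_D": 44.0, "k2_D": 46.5, "kmax_D": 49.0, "cct_um": 492.0, "axial_length_mm": 24.5, "acd_mm": 3.4},
                {"order": 2, "k1_D": 44.1, "k2_D": 46.6, "kmax_D": 49.2, "cct_um": 490.0, "axial_length_mm": 24.4, "acd_mm": 3.5},
                {"order": 3, "k1_D": 43.9, "k2_D": 46.4, "kmax_D": 48.9, "cct_um": 494.0, "axial_length_mm": 24.6, "acd_mm": 3.3},
            ],
        },
    ]
    path = tmp_path / name
    path.write_text(json.dumps(records))
    return path
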