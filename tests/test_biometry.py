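"""Record parsing, median aggregation and quality control."""

import json

import pytest
from hypothesis import given, settings, strategies as st

import kerasym as ks
from kerasym.biometry import PARAMETERS, Scan, ScanSet, SchemaError

from conftest import make_two_eye_json


def make_scanset(k1_values, **overrides):
    scans = []
    for i, k1 in enumerate(k1_values, start=1):
        values = {
            "k1_D": k1,
            "k2_D": k1 + 1.0,
            "kmax_D": k1 + 2.0,
            "cct_um": 540.0,
            "axial_length_mm": 24.0,
            "acd_mm": 3.2,
        }
        values.update(overrides)
        scans.append(Scan(order=i, **values))
    return ScanSet(eye_id="X", laterality="OD", scans=tuple(scans))


class TestParseRecords:
    def test_json_fixture_roundtrip(self, tmp_path):
        path = make_two_eye_json(tmp_path)
        scan_sets = ks.parse_records(path)
        assert len(scan_sets) == 2
        assert all(len(ss.scans) == 3 for ss in scan_sets)
        assert scan_sets[0].metadata == {"site": "clinic-1"}

    def test_csv_missing_cell_flagged_not_crash(self, tmp_path):
        path = tmp_path / "records.csv"
        path.write_text(
            "eye_id,laterality,order,k1_D,k2_D,kmax_D,cct_um,axial_length_mm,acd_mm\n"
            "A,OD,1,43.0,44.0,45.0,,24.0,3.2\n"
            "A,OD,2,43.1,44.1,45.1,540,24.1,3.1\n"
        )
        (scan_set,) = ks.parse_records(path)
        assert scan_set.scans[0].cct_um is None
        assert scan_set.scans[1].cct_um == 540.0

    def test_duplicate_acquisition_order_names_eye(self, tmp_path):
        records = [
            {"eye_id": "DUP", "laterality": "OD", "scans": [{"order": 1, "k1_D": 43.0}, {"order": 1, "k1_D": 43.1}]}
        ]
        path = tmp_path / "bad.json"
        path.write_text(json.dumps(records))
        with pytest.raises(SchemaError, match="DUP"):
            ks.parse_records(path)

    def test_malformed_field_names_record_and_field(self, tmp_path):
        records = [{"eye_id": "E1", "laterality": "OD", "scans": [{"order": 1, "k1_D": "steep"}]}]
        path = tmp_path / "bad.json"
        path.write_text(json.dumps(records))
        with pytest.raises(SchemaError, match="E1.*k1_D"):
            ks.parse_records(path)


class TestAggregateScans:
    @pytest.mark.parametrize(
        "k1_values, expected",
        [
            ((43.0, 43.2, 43.1), 43.1),  # median of three
            ((43.0, 43.1, 49.0), 43.1),  # outlier rejected by the median
        ],
    )
    def test_median_of_three(self, k1_values, expected):
        record = ks.aggregate_scans(make_scanset(k1_values))
        assert record.k1_D == pytest.approx(expected)

    def test_identical_scans_idempotent(self):
        record = ks.aggregate_scans(make_scanset((43.0, 43.0, 43.0)))
        assert record.k1_D == 43.0 and record.k2_D == 44.0 and record.kmax_D == 45.0
        assert record.astigmatism_D == pytest.approx(1.0)

    def test_astigmatism_is_median_of_per_scan_differences(self):
        scans = (
            Scan(order=1, k1_D=43.0, k2_D=44.0),
            Scan(order=2, k1_D=42.0, k2_D=44.5),
            Scan(order=3, k1_D=43.5, k2_D=44.0),
        )
        record = ks.aggregate_scans(ScanSet(eye_id="X", laterality="OD", scans=scans))
        assert record.astigmatism_D == pytest.approx(1.0)  # median of (1.0, 2.5, 0.5)

    def test_parameter_missing_everywhere_propagates(self):
        record = ks.aggregate_scans(make_scanset((43.0, 43.1, 43.2), cct_um=None))
        assert record.cct_um is None

    @given(st.permutations(range(5)))
    @settings(max_examples=20, deadline=None)
    def test_permutation_invariance(self, perm):
        base = [43.0, 43.3, 42.8, 44.0, 43.1]
        record_a = ks.aggregate_scans(make_scanset(base))
        record_b = ks.aggregate_scans(make_scanset([base[i] for i in perm]))
        assert record_a.k1_D == record_b.k1_D

    @given(st.lists(st.floats(min_value=40, max_value=48), min_size=3, max_size=7).filter(lambda v: len(v) % 2 == 1))
    @settings(max_examples=30, deadline=None)
    def test_odd_count_median_is_an_observed_value(self, k1_values):
        record = ks.aggregate_scans(make_scanset(k1_values))
        assert record.k1_D in k1_values


class TestValidateRecord:
    def _record(self, **overrides):
        values = dict(
            eye_id="X", laterality="OD",
            k1_D=43.21, k2_D=44.36, kmax_D=46.02, cct_um=532.6,
            axial_length_mm=24.18, acd_mm=3.21, astigmatism_D=1.15,
        )
        values.update(overrides)
        return ks.BiometricRecord(**values)

    def test_cohort_mean_record_passes(self):
        # record built from the published cohort mean values
        assert ks.validate_record(self._record()).status == "pass"

    def test_missing_cct_excluded_incomplete(self):
        result = ks.validate_record(self._record(cct_um=None))
        assert result.status == "excluded" and "incomplete" in result.reasons

    def test_cct_100_implausible(self):
        result = ks.validate_record(self._record(cct_um=100.0))
        assert "implausible_range" in result.reasons

    def test_k2_below_k1_inconsistent(self):
        result = ks.validate_record(self._record(k1_D=45.0, k2_D=44.0))
        assert "inconsistent" in result.reasons

    def test_kmax_tolerance_half_diopter(self):
        assert ks.validate_record(self._record(kmax_D=44.0)).status == "pass"  # K2 - 0.36
        assert "inconsistent" in ks.validate_record(self._record(kmax_D=43.5)).reasons

    def test_custom_windows_override(self):
        qc = ks.QCConfig(cct_window_um=(520.0, 560.0))
        assert "implausible_range" in ks.validate_record(self._record(cct_um=500.0), qc).reasons


class TestDeriveFeatures:
    def test_cohort_mean_astigmatism_identity(self):
        # the published K1/K2 means reproduce the published mean astigmatism
        record = ks.BiometricRecord(
            eye_id="X", laterality="OD", k1_D=43.21, k2_D=44.36, kmax_D=46.02,
            cct_um=532.6, axial_length_mm=24.18, acd_mm=3.21, astigmatism_D=1.15,
        )
        feats = ks.derive_features(record)
        assert feats.astig_kdiff_D == pytest.approx(1.15)

    @pytest.mark.parametrize(
        "k1, k2, kmax, mean_k, astig, excess",
        [
            (44.0, 44.0, 44.5, 44.0, 0.0, 0.5),
            (43.0, 45.0, 48.0, 44.0, 2.0, 4.0),
        ],
    )
    def test_formulas(self, k1, k2, kmax, mean_k, astig, excess):
        record = ks.BiometricRecord(
            eye_id="X", laterality="OD", k1_D=k1, k2_D=k2, kmax_D=kmax,
            cct_um=540.0, axial_length_mm=24.0, acd_mm=3.2, astigmatism_D=astig,
        )
        feats = ks.derive_features(record)
        assert (feats.mean_k_D, feats.astig_kdiff_D, feats.kmax_excess_D) == pytest.approx(
            (mean_k, astig, excess)
        )

    def test_missing_input_errors(self):
        record = ks.BiometricRecord(
            eye_id="X", laterality="OD", k1_D=43.0, k2_D=None, kmax_D=45.0,
            cct_um=540.0, axial_length_mm=24.0, acd_mm=3.2, astigmatism_D=None,
        )
        with pytest.raises(ValueError, match="k2_D"):
            ks.derive_features(record)

    def test_pipeline_deterministic(self):
        ss = make_scanset((43.0, 43.2, 43.1))
        a = ks.derive_features(ks.aggregate_scans(ss))
        b = ks.derive_features(ks.aggregate_scans(ss))
        assert a == b
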