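"""Noisy-OR posterior, score fusion, eligibility and trace assembly."""

import itertools
import json

import numpy as np
import pytest

import kerasym as ks
from kerasym.graph import ActivationEntry, EvidenceActivation


def noisy_or_oracle(prior, rules):
    """Brute-force enumeration of the noisy-OR causal model.

    Each cause i is active with probability a_i; an active cause triggers
    the effect with probability w_i; an always-on leak triggers it with
    probability ``prior``.  Sums over all 2^n activation outcomes.
    """
    total = 0.0
    n = len(rules)
    for outcome in itertools.product((0, 1), repeat=n):
        p_outcome = 1.0
        p_no_effect = 1.0 - prior
        for active, (w, a) in zip(outcome, rules):
            p_outcome *= a if active else (1.0 - a)
            if active:
                p_no_effect *= 1.0 - w
        total += p_outcome * (1.0 - p_no_effect)
    return total


def make_evidence(rules, target="early_keratoconus", eye_id="E"):
    entries = tuple(
        ActivationEntry(
            rule_id=rule_id, feature="kmax_D", observed=48.0, threshold=47.0,
            direction="above", activation=a, weight=w, target=target, hard=False,
        )
        for rule_id, w, a in rules
    )
    return EvidenceActivation(eye_id=eye_id, entries=entries)


class TestInferPosterior:
    def test_no_rules_fired_returns_prior(self, default_graph):
        evidence = make_evidence([("R1", 0.6, 0.0), ("R2", 0.45, 0.0)])
        result = ks.infer_posterior(evidence, default_graph, ks.InferenceConfig(prior=0.05))
        assert result.p_kc == pytest.approx(0.05)

    def test_single_rule_closed_form(self, default_graph):
        evidence = make_evidence([("R1", 0.6, 1.0)])
        result = ks.infer_posterior(evidence, default_graph, ks.InferenceConfig(prior=0.05))
        assert result.p_kc == pytest.approx(1 - 0.95 * 0.4)  # 0.62

    def test_two_rule_closed_form(self, default_graph):
        evidence = make_evidence([("R1", 0.6, 1.0), ("R2", 0.5, 0.5)])
        result = ks.infer_posterior(evidence, default_graph, ks.InferenceConfig(prior=0.05))
        assert result.p_kc == pytest.approx(1 - 0.95 * 0.4 * 0.75)  # 0.715

    def test_matches_enumeration_oracle(self, default_graph):
        grid = (0.0, 0.25, 0.6, 1.0)
        config = ks.InferenceConfig(prior=0.05)
        rule_ids = ("R1", "R2", "R3")
        for n in (1, 2, 3):
            for weights in itertools.product(grid, repeat=n):
                for acts in itertools.product(grid, repeat=n):
                    rules = [(rule_ids[i], weights[i], acts[i]) for i in range(n)]
                    got = ks.infer_posterior(make_evidence(rules), default_graph, config).p_kc
                    assert got == pytest.approx(noisy_or_oracle(0.05, [(w, a) for _, w, a in rules]), abs=1e-12)

    def test_monotone_in_activation_and_weight(self, default_graph):
        config = ks.InferenceConfig(prior=0.05)
        base = ks.infer_posterior(make_evidence([("R1", 0.5, 0.5)]), default_graph, config).p_kc
        for a in np.linspace(0.5, 1.0, 11):
            p = ks.infer_posterior(make_evidence([("R1", 0.5, float(a))]), default_graph, config).p_kc
            assert p >= base - 1e-15
            base = p
        base = ks.infer_posterior(make_evidence([("R1", 0.0, 0.7)]), default_graph, config).p_kc
        for w in np.linspace(0.0, 1.0, 11):
            p = ks.infer_posterior(make_evidence([("R1", float(w), 0.7)]), default_graph, config).p_kc
            assert p >= base - 1e-15
            base = p

    def test_bounds_prior_to_one(self, default_graph):
        rng = np.random.default_rng(0)
        config = ks.InferenceConfig(prior=0.05)
        for _ in range(100):
            n = rng.integers(0, 4)
            rules = [(f"R{i+1}", rng.uniform(), rng.uniform()) for i in range(n)]
            p = ks.infer_posterior(make_evidence(rules), default_graph, config).p_kc
            assert 0.05 - 1e-15 <= p <= 1.0

    def test_unknown_rule_rejected(self, default_graph):
        with pytest.raises(KeyError, match="R99"):
            ks.infer_posterior(make_evidence([("R99", 0.5, 1.0)]), default_graph)

    def test_contributions_sorted(self, default_graph):
        evidence = make_evidence([("R1", 0.6, 0.1), ("R2", 0.45, 1.0)])
        result = ks.infer_posterior(evidence, default_graph)
        assert result.contributions[0][0] == "R2"


class TestFuseScores:
    def test_endpoints_and_fixed_point(self):
        assert ks.fuse_scores(0.3, 0.8, 0.0) == pytest.approx(0.3, abs=1e-9)
        assert ks.fuse_scores(0.3, 0.8, 1.0) == pytest.approx(0.8, abs=1e-9)
        for alpha in (0.0, 0.3, 0.7, 1.0):
            assert ks.fuse_scores(0.4, 0.4, alpha) == pytest.approx(0.4, abs=1e-9)

    def test_symmetry_under_swap(self):
        assert ks.fuse_scores(0.2, 0.9, 0.3) == pytest.approx(ks.fuse_scores(0.9, 0.2, 0.7))

    def test_monotone_in_both_arguments(self):
        grid = np.linspace(0.05, 0.95, 10)
        fused_sym = [ks.fuse_scores(p, 0.5, 0.3) for p in grid]
        fused_neur = [ks.fuse_scores(0.5, p, 0.3) for p in grid]
        assert fused_sym == sorted(fused_sym)
        assert fused_neur == sorted(fused_neur)

    def test_alpha_out_of_range(self):
        with pytest.raises(ValueError):
            ks.fuse_scores(0.5, 0.5, 1.2)


class TestDecideEligibility:
    def _diagnosis(self, p, eye_id="E"):
        return ks.DiagnosisResult(eye_id=eye_id, p_kc=p, p_source="symbolic", prior=0.05, contributions=())

    def test_high_posterior_contraindicates(self, default_graph):
        decision = ks.decide_eligibility(self._diagnosis(0.9), make_evidence([]), default_graph,
                                         ks.InferenceConfig(decision_threshold=0.3))
        assert decision.eligibility == "contraindicated"

    def test_low_posterior_candidate(self, default_graph):
        decision = ks.decide_eligibility(self._diagnosis(0.01), make_evidence([]), default_graph)
        assert decision.eligibility == "candidate"

    def test_hard_pachymetry_veto_overrides_low_posterior(self, default_graph):
        # cct 470 µm < 480 µm fires the hard contraindication regardless of posterior
        record = ks.BiometricRecord(
            eye_id="E", laterality="OD", k1_D=43.0, k2_D=43.5, kmax_D=44.0,
            cct_um=470.0, axial_length_mm=24.0, acd_mm=3.2, astigmatism_D=0.5,
        )
        evidence = ks.activate_evidence(record, ks.derive_features(record), None, default_graph)
        diagnosis = ks.infer_posterior(evidence, default_graph)
        decision = ks.decide_eligibility(diagnosis, evidence, default_graph)
        assert decision.eligibility == "contraindicated"
        assert decision.triggered_hard_rules == ("R5",)


class TestBuildTrace:
    def test_posterior_copied_exactly(self, example_trace, default_graph):
        assert isinstance(example_trace.p_kc, float)
        terms = example_trace.posterior["terms"]
        survival = 1.0 - example_trace.posterior["prior"]
        for term in terms.values():
            survival *= 1.0 - term
        assert example_trace.p_kc == 1.0 - survival  # bit-for-bit

    def test_each_fired_rule_once(self, example_trace):
        fired = [r["rule_id"] for r in example_trace.rules if r["fired"]]
        assert len(fired) == len(set(fired))

    def test_json_roundtrip_identity(self, example_trace):
        text = example_trace.to_json()
        assert ks.ReasoningTrace.from_json(text).to_json() == text
        assert json.loads(text)["posterior"]["p_kc"] == example_trace.p_kc

    def test_stage_mismatch_rejected(self, default_graph, example_trace):
        record = ks.BiometricRecord(
            eye_id="OTHER", laterality="OD", k1_D=43.0, k2_D=44.0, kmax_D=45.0,
            cct_um=540.0, axial_length_mm=24.0, acd_mm=3.2, astigmatism_D=1.0,
        )
        feats = ks.derive_features(record)
        evidence = ks.activate_evidence(record, feats, None, default_graph)
        diagnosis = ks.infer_posterior(evidence, default_graph)
        other_decision = ks.decide_eligibility(diagnosis, evidence, default_graph)
        with pytest.raises(ValueError, match="stage mismatch"):
            ks.build_trace(record, feats, evidence, diagnosis,
                           ks.DecisionResult(eye_id="E", eligibility="candidate",
                                             triggered_hard_rules=(), threshold=0.3, posterior=0.1))
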