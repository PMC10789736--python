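import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dermxai.decision import (
    DetectionSet,
    TemperatureVector,
    assemble_explanation,
    calibrate_scores,
    detect_characteristics,
    evidence_level,
    extract_explanation_region,
    fit_temperatures,
    infer_diagnosis,
)
from dermxai.ontology import DiagnosisClass


def _grid_search_temperature(logits, labels):
    """Independent oracle: brute-force NLL minimisation over a fine grid."""
    grid = np.linspace(0.05, 20.0, 4000)
    z = logits[:, None] / grid[None, :]
    nll = np.mean(
        np.maximum(z, 0) - z * labels[:, None] + np.log1p(np.exp(-np.abs(z))), axis=0
    )
    return grid[np.argmin(nll)]


class TestTemperatureScaling:
    def test_already_calibrated_logits_give_unit_temperature(self):
        rng = np.random.default_rng(0)
        z = rng.normal(0, 2, size=5000)
        y = (rng.uniform(size=z.size) < 1 / (1 + np.exp(-z))).astype(float)
        T = fit_temperatures(z[:, None], y[:, None])
        oracle = _grid_search_temperature(z, y)
        assert T.temperatures[0] == pytest.approx(1.0, abs=0.1)
        assert T.temperatures[0] == pytest.approx(oracle, abs=0.05)

    def test_scale_equivariance_doubled_logits_double_temperature(self):
        rng = np.random.default_rng(1)
        z = rng.normal(0, 1.5, size=5000)
        y = (rng.uniform(size=z.size) < 1 / (1 + np.exp(-z))).astype(float)
        t1 = fit_temperatures(z[:, None], y[:, None]).temperatures[0]
        t2 = fit_temperatures(2 * z[:, None], y[:, None]).temperatures[0]
        assert t2 == pytest.approx(2 * t1, rel=0.05)
        assert t2 == pytest.approx(_grid_search_temperature(2 * z, y), abs=0.05)

    def test_nll_never_worse_than_identity(self):
        rng = np.random.default_rng(2)
        z = rng.normal(0, 3, size=2000)
        y = (rng.uniform(size=z.size) < 1 / (1 + np.exp(-z / 3))).astype(float)
        T = fit_temperatures(z[:, None], y[:, None])
        from dermxai.decision import _binary_nll

        assert _binary_nll(z, y, T.temperatures[0]) <= _binary_nll(z, y, 1.0)

    def test_empty_validation_set_rejected(self):
        with pytest.raises(ValueError):
            fit_temperatures(np.empty((0, 2)), np.empty((0, 2)))

    def test_degenerate_class_keeps_unit_temperature_with_warning(self):
        z = np.random.default_rng(3).normal(size=(50, 2))
        y = np.zeros((50, 2))
        y[:, 1] = (z[:, 1] > 0).astype(float)
        with pytest.warns(UserWarning):
            T = fit_temperatures(z, y)
        assert T.temperatures[0] == 1.0

    def test_non_positive_temperature_rejected(self):
        with pytest.raises(ValueError):
            TemperatureVector(np.array([1.0, 0.0]))


class TestCalibrateScores:
    def test_identity_temperature_preserves_scores(self):
        z = np.random.default_rng(0).normal(size=10)
        T = TemperatureVector.identity(10)
        assert np.allclose(calibrate_scores(z, T), 1 / (1 + np.exp(-z)))

    def test_zero_logit_maps_to_half_for_any_temperature(self):
        for t in (0.1, 1.0, 7.5):
            assert calibrate_scores(np.zeros(1), TemperatureVector([t]))[0] == 0.5

    def test_within_class_ranking_preserved(self):
        rng = np.random.default_rng(4)
        T = TemperatureVector(rng.uniform(0.2, 5.0, size=6))
        for _ in range(1000):
            z = rng.normal(0, 3, size=(10, 6))
            s = calibrate_scores(z, T)
            for c in range(6):
                assert np.array_equal(np.argsort(z[:, c]), np.argsort(s[:, c]))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            calibrate_scores(np.zeros(3), TemperatureVector(np.ones(2)))


class TestEvidenceAndDetection:
    @pytest.mark.parametrize("score,level", [(0.71, "strong"), (0.70, "some"), (0.0, "some"), (1.0, "strong")])
    def test_strict_above_seven_tenths(self, score, level):
        assert evidence_level(score) == level

    def test_out_of_range_score_rejected(self):
        with pytest.raises(ValueError):
            evidence_level(1.2)

    def test_all_zero_scores_detect_nothing(self, ontology):
        assert detect_characteristics(np.zeros(18), ontology).detected == set()

    def test_threshold_equality_is_included(self, ontology):
        scores = np.full(18, 0.5)
        assert detect_characteristics(scores, ontology, 0.5).detected == set(ontology.ids)

    def test_matches_elementwise_oracle_on_random_vectors(self, ontology):
        rng = np.random.default_rng(5)
        for _ in range(200):
            scores = rng.uniform(size=18)
            thr = rng.uniform(0.1, 0.9)
            got = detect_characteristics(scores, ontology, thr).detected
            expected = {ontology.ids[i] for i in range(18) if scores[i] >= thr}
            assert got == expected

    def test_invalid_threshold_rejected(self, ontology):
        with pytest.raises(ValueError):
            detect_characteristics(np.zeros(18), ontology, 1.0)


class TestInferDiagnosis:
    def test_two_melanoma_detections_mean_melanoma(self, ontology):
        det = DetectionSet({"grey_patterns", "white_lines"})
        assert infer_diagnosis(det, ontology) is DiagnosisClass.MELANOMA

    def test_single_melanoma_detection_means_nevus(self, ontology):
        assert infer_diagnosis(DetectionSet({"grey_patterns"}), ontology) is DiagnosisClass.NEVUS

    def test_nevus_detections_never_count_toward_melanoma(self, ontology):
        det = DetectionSet(
            {"grey_patterns", "one_pattern_one_colour", "symmetric_patterns", "melanoma_simulator"}
        )
        assert infer_diagnosis(det, ontology) is DiagnosisClass.NEVUS


class TestExplanationRegion:
    def test_distinct_values_select_exactly_top_fifth(self):
        rng = np.random.default_rng(6)
        vals = rng.permutation(100).reshape(10, 10) / 100.0
        mask, _ = extract_explanation_region(vals, 0.20)
        assert mask.sum() == 20
        assert vals[mask].min() > vals[~mask].max()

    def test_constant_map_uses_stable_raster_tie_break(self):
        mask, _ = extract_explanation_region(np.full((10, 10), 0.5), 0.20)
        assert mask.sum() == 20
        expected = np.zeros(100, dtype=bool)
        expected[:20] = True
        assert np.array_equal(mask.ravel(), expected)

    def test_single_bright_blob_yields_one_component_one_polygon(self):
        vals = np.zeros((20, 20))
        vals[8:12, 8:12] = 1.0
        from skimage import measure

        mask, polys = extract_explanation_region(vals, 0.04)
        assert measure.label(mask, connectivity=2).max() == 1
        assert len(polys) == 1

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_region_cardinality_always_floor_fraction(self, seed):
        vals = np.random.default_rng(seed).uniform(size=(13, 17))
        mask, _ = extract_explanation_region(vals, 0.20)
        assert mask.sum() == int(np.floor(0.2 * 13 * 17))

    def test_absolute_mode_thresholds_at_value(self):
        vals = np.linspace(0, 1, 100).reshape(10, 10)
        mask, _ = extract_explanation_region(vals, mode="absolute", absolute_threshold=0.7)
        assert np.array_equal(mask, vals >= 0.7)

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            extract_explanation_region(np.zeros((4, 4)), 1.0)


def _fake_prediction(scores, hw=(24, 24), seed=0):
    from dermxai.model import AttentionMap, RawPrediction

    scores = np.asarray(scores, dtype=float)
    logits = np.log(scores / (1 - scores))
    rng = np.random.default_rng(seed)
    attention = [
        AttentionMap(values=rng.uniform(0, 1, hw), class_id=c) for c in range(len(scores))
    ]
    return RawPrediction(scores=scores, logits=logits, attention=attention)


class TestAssembleExplanation:
    def test_two_strong_melanoma_scores_give_melanoma_with_regions(self, ontology):
        scores = np.full(18, 0.05)
        scores[ontology.index_of("grey_patterns")] = 0.9
        scores[ontology.index_of("white_lines")] = 0.8
        expl = assemble_explanation(
            _fake_prediction(scores), TemperatureVector.identity(18), ontology
        )
        assert expl.diagnosis is DiagnosisClass.MELANOMA
        assert expl.findings.strong == {"grey_patterns", "white_lines"}
        assert expl.classifier_certain
        assert set(expl.regions) == {"grey_patterns", "white_lines"}
        assert all(len(r["polygons"]) >= 1 for r in expl.regions.values())

    def test_no_strong_score_falls_back_to_most_certain(self, ontology):
        scores = np.full(18, 0.1)
        scores[ontology.index_of("monomorphic_vessels")] = 0.6
        expl = assemble_explanation(
            _fake_prediction(scores), TemperatureVector.identity(18), ontology
        )
        assert not expl.classifier_certain
        assert expl.findings.strong == set()
        assert expl.findings.some == {"monomorphic_vessels"}
        assert set(expl.regions) == {"monomorphic_vessels"}
        assert "some evidence" in expl.text

    def test_all_equal_scores_pick_first_criterion_in_order(self, ontology):
        expl = assemble_explanation(
            _fake_prediction(np.full(18, 0.3)), TemperatureVector.identity(18), ontology
        )
        assert expl.findings.some == {ontology.ids[0]}

    def test_output_size_mismatch_rejected(self, ontology):
        with pytest.raises(ValueError):
            assemble_explanation(
                _fake_prediction(np.full(5, 0.3)), TemperatureVector.identity(5), ontology
            )

    def test_explanation_never_empty_on_random_scores(self, ontology):
        rng = np.random.default_rng(9)
        for _ in range(50):
            scores = np.clip(rng.uniform(0.01, 0.99, 18), 0.01, 0.99)
            expl = assemble_explanation(
                _fake_prediction(scores), TemperatureVector.identity(18), ontology
            )
            assert expl.findings.all_ids()
            assert expl.regions
            assert expl.classifier_certain == bool(expl.findings.strong)

    def test_serialises_to_json(self, ontology):
        scores = np.full(18, 0.2)
        scores[0] = 0.95
        expl = assemble_explanation(
            _fake_prediction(scores), TemperatureVector.identity(18), ontology
        )
        import json

        payload = json.loads(expl.to_json())
        assert payload["diagnosis"] == "nevus"
        assert payload["findings"]["strong"] == [ontology.ids[0]]
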