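"""Held-out prediction protocols, error metrics and the profile runner."""

import math

import numpy as np
import pytest

from anodet import (
    GeneratorConfig,
    HealthTensor,
    HeldOutEntry,
    IndexTable,
    ValidationError,
    generate_cohort,
    mae,
    mask_entries,
    predict_heldout_anodet,
    predict_heldout_ucf,
    reports_to_frame,
    rmse,
    run_profile,
)
from anodet.evaluation import student_correlations


class TestErrorMetrics:
    def test_perfect_predictions_score_zero(self):
        assert mae([1.0, 2.0], [1.0, 2.0]) == 0.0
        assert rmse([1.0, 2.0], [1.0, 2.0]) == 0.0

    def test_symmetric_unit_errors(self):
        assert mae([1.0, -1.0], [0.0, 0.0]) == 1.0
        assert rmse([1.0, -1.0], [0.0, 0.0]) == 1.0

    def test_rmse_exceeds_mae_for_uneven_errors(self):
        preds, truths = [0.0, 2.0], [0.0, 0.0]
        assert mae(preds, truths) == 1.0
        assert rmse(preds, truths) == pytest.approx(math.sqrt(2.0))

    def test_empty_and_mismatched_inputs_rejected(self):
        with pytest.raises(ValidationError):
            mae([], [])
        with pytest.raises(ValidationError):
            rmse([1.0], [1.0, 2.0])


def _hand_setup():
    """3 students, 1 criterion, K=2; s1 and s2 similar, s3 isolated."""
    values = np.array([[[70.0, 75.0]], [[80.0, 81.0]], [[10.0, 11.0]]])
    mask = np.ones_like(values, dtype=bool)
    mask[0, 0, 0] = False  # hide s1's first reading
    mask[2, 0, 1] = False  # hide isolated s3's second reading
    tensor = HealthTensor(["s1", "s2", "s3"], ["c1"], values, mask)
    index = IndexTable(
        student_ids=["s1", "s2", "s3"],
        pi=[[[1, 1], [1, 1], [2, 3]]],  # p=1, q=2
        p=1, q=2, M=2, seed=0,
    )
    heldout = [
        HeldOutEntry("s1", "c1", 0, 70.0),
        HeldOutEntry("s3", "c1", 1, 11.0),
    ]
    return tensor, index, heldout


class TestAnodetPredictor:
    def test_single_neighbor_mean(self):
        tensor, index, heldout = _hand_setup()
        preds = predict_heldout_anodet(tensor, index, T=2, heldout=heldout)
        assert preds[0] == 80.0  # s2 is s1's only neighbor

    def test_isolated_student_falls_back_to_cohort_mean(self):
        tensor, index, heldout = _hand_setup()
        preds = predict_heldout_anodet(tensor, index, T=2, heldout=heldout)
        assert preds[1] == pytest.approx((75.0 + 81.0) / 2)  # observed at (c1, k=1)

    def test_observed_heldout_triple_rejected(self):
        tensor, index, _ = _hand_setup()
        with pytest.raises(ValidationError):
            predict_heldout_anodet(
                tensor, index, T=2, heldout=[HeldOutEntry("s2", "c1", 0, 80.0)]
            )

    def test_matches_plain_loop_oracle_on_random_cohort(self):
        cohort = generate_cohort(GeneratorConfig(N=10, M=4, K=8, seed=31))
        masked, heldout = mask_entries(cohort, 0.1, seed=31)
        from anodet import RunConfig, build_index, similarity_matrix, threshold_graph

        index = build_index(masked, RunConfig(p=2, q=3, T=2, seed=31))
        preds = predict_heldout_anodet(masked, index, T=2, heldout=heldout)

        graph = threshold_graph(similarity_matrix(index), 2)
        mask = masked.observed_mask()
        s_pos = {s: i for i, s in enumerate(masked.student_ids)}
        c_pos = {c: j for j, c in enumerate(masked.criterion_ids)}
        global_mean = masked.values[mask].mean()
        for pred, h in zip(preds, heldout):
            i, j, k = s_pos[h.student_id], c_pos[h.criterion_id], h.time_index
            vals = [
                masked.values[s_pos[nb], j, k]
                for nb in graph.graph.neighbors(h.student_id)
                if mask[s_pos[nb], j, k]
            ]
            if not vals:
                vals = [masked.values[i2, j, k] for i2 in range(10) if mask[i2, j, k]]
            expected = np.mean(vals) if vals else global_mean
            assert pred == pytest.approx(expected, rel=1e-12)


class TestUcfPredictor:
    def test_perfectly_correlated_neighbor_is_copied(self):
        values = np.array(
            [[[1.0, 2.0, 3.0, 4.0]], [[2.0, 4.0, 6.0, 8.0]]]
        )  # s2 = 2 * s1, correlation exactly 1
        mask = np.ones_like(values, dtype=bool)
        mask[0, 0, 3] = False
        tensor = HealthTensor(["s1", "s2"], ["c1"], values, mask)
        preds = predict_heldout_ucf(tensor, [HeldOutEntry("s1", "c1", 3, 4.0)])
        assert preds[0] == pytest.approx(8.0)  # the neighbor's raw value

    def test_constant_cohort_predicts_the_constant(self):
        values = np.full((3, 2, 4), 5.0)
        mask = np.ones_like(values, dtype=bool)
        mask[1, 0, 2] = False
        tensor = HealthTensor(["s1", "s2", "s3"], ["c1", "c2"], values, mask)
        preds = predict_heldout_ucf(tensor, [HeldOutEntry("s2", "c1", 2, 5.0)])
        assert preds[0] == 5.0

    def test_correlations_match_pairwise_oracle(self):
        cohort = generate_cohort(GeneratorConfig(N=8, M=3, K=10, seed=17))
        masked, _ = mask_entries(cohort, 0.2, seed=17)
        r = student_correlations(masked)
        mask = masked.observed_mask().reshape(8, -1)
        flat = masked.values.reshape(8, -1)
        for a in range(8):
            for b in range(a + 1, 8):
                co = mask[a] & mask[b]
                if co.sum() >= 2 and flat[a, co].std() > 0 and flat[b, co].std() > 0:
                    expected = np.corrcoef(flat[a, co], flat[b, co])[0, 1]
                    assert r[a, b] == pytest.approx(expected, abs=1e-9)
                else:
                    assert r[a, b] == 0.0

    def test_matches_direct_weighted_mean_oracle(self):
        cohort = generate_cohort(GeneratorConfig(N=12, M=4, K=6, seed=23))
        masked, heldout = mask_entries(cohort, 0.15, seed=23)
        preds = predict_heldout_ucf(masked, heldout, k_neighbors=5)

        r = student_correlations(masked)
        mask = masked.observed_mask()
        s_pos = {s: i for i, s in enumerate(masked.student_ids)}
        c_pos = {c: j for j, c in enumerate(masked.criterion_ids)}
        for pred, h in zip(preds, heldout):
            i, j, k = s_pos[h.student_id], c_pos[h.criterion_id], h.time_index
            cands = [
                (r[i, v], masked.values[v, j, k])
                for v in range(12)
                if v != i and mask[v, j, k] and r[i, v] > 0
            ]
            cands.sort(key=lambda t: t[0], reverse=True)
            cands = cands[:5]
            if cands:
                w = np.array([c[0] for c in cands])
                x = np.array([c[1] for c in cands])
                expected = float(np.dot(w, x) / w.sum())
            else:
                col = [masked.values[v, j, k] for v in range(12) if mask[v, j, k]]
                expected = float(np.mean(col))
            assert pred == pytest.approx(expected, rel=1e-10)


class TestRunProfile:
    GEN = GeneratorConfig(N=24, M=6, K=12, n_groups=3, seed=40)

    def test_one_point_one_seed_yields_one_report_per_method(self):
        reports = run_profile([(2, 3, 2)], self.GEN, 0.1, seeds=[0])
        assert sorted(r.method for r in reports) == ["ano-det", "ucf"]

    def test_fully_seeded_anodet_reports_are_reproducible(self):
        a = run_profile([(2, 3, 2)], self.GEN, 0.1, seeds=[1], methods=("ano-det",))
        b = run_profile([(2, 3, 2)], self.GEN, 0.1, seeds=[1], methods=("ano-det",))
        assert a[0].mae == b[0].mae and a[0].rmse == b[0].rmse

    def test_rmse_dominates_mae_on_every_report(self):
        reports = run_profile(
            [(1, 2, 1), (2, 3, 2)], self.GEN, 0.1, seeds=[0, 1],
            methods=("ano-det", "ucf", "brute-lsh"),
        )
        assert len(reports) == 2 * 2 * 3
        for rep in reports:
            assert rep.rmse >= rep.mae >= 0.0

    def test_tidy_frame_has_declared_columns(self):
        reports = run_profile([(2, 2, 1)], self.GEN, 0.1, seeds=[0])
        frame = reports_to_frame(reports)
        assert list(frame.columns) == [
            "method", "p", "q", "T", "seed", "mae", "rmse", "n_heldout",
            "index_seconds", "predict_seconds", "n_anomalies",
        ]

    def test_invalid_grid_point_rejected(self):
        with pytest.raises(ValidationError):
            run_profile([(2, 3, 4)], self.GEN, 0.1, seeds=[0])  # T > q
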