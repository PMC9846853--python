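import numpy as np
import pytest
from scipy import stats

import voicerep as vr
from voicerep.errors import (
    InvalidArgumentError,
    UndefinedCorrelationError,
)
from voicerep.patterns import ActivityPattern
from voicerep.rsa import RDM, within_between_cells


def _rdm_from_rows(rows, labels=None):
    rows = np.asarray(rows, float)
    labels = labels or [f"s{i}" for i in range(rows.shape[0])]
    return vr.compute_rdm(ActivityPattern(values=rows, row_labels=labels))


def _symmetric_rdm(vals, n, labels=None):
    m = np.zeros((n, n))
    m[np.triu_indices(n, 1)] = vals
    m += m.T
    return RDM(condition_labels=labels or [f"s{i}" for i in range(n)], matrix=m)


class TestComputeRDM:
    def test_three_four_five_triangle(self):
        rdm = _rdm_from_rows([[0.0, 0.0], [3.0, 4.0]])
        assert rdm.matrix[0, 1] == pytest.approx(5.0)

    def test_identical_rows_give_zero(self):
        rdm = _rdm_from_rows([[1.0, 2.0, 3.0]] * 2)
        assert rdm.matrix[0, 1] == 0.0

    @pytest.mark.parametrize("shape,seed", [((6, 4), 0), ((8, 5), 1), ((8, 5), 2)])
    def test_matches_brute_force_oracle(self, shape, seed):
        rows = np.random.default_rng(seed).normal(size=shape)
        rdm = _rdm_from_rows(rows)
        n = shape[0]
        # independent double-loop oracle
        for i in range(n):
            for j in range(n):
                expected = np.sqrt(np.sum((rows[i] - rows[j]) ** 2))
                assert rdm.matrix[i, j] == pytest.approx(expected, abs=1e-12)

    def test_event_rows_averaged_per_stimulus(self, stim48):
        pat = vr.generate_beta_patterns(stim48, vr.GenerativeConfig(seed=0))
        rdm = vr.compute_rdm(pat)
        assert rdm.n_conditions == 48
        direct = vr.compute_rdm(pat.mean_by_stimulus())
        np.testing.assert_allclose(rdm.matrix, direct.matrix)

    def test_duplicate_condition_labels_rejected(self):
        with pytest.raises(InvalidArgumentError):
            RDM(condition_labels=["a", "a"], matrix=np.zeros((2, 2)))


class TestPercentileTransform:
    def test_distinct_entries_give_uniform_grid(self):
        rdm = _symmetric_rdm([1.0, 2.0, 3.0, 4.0, 5.0, 6.0], 4)
        perc = vr.percentile_transform(rdm)
        vals = np.sort(perc.upper_values())
        np.testing.assert_allclose(vals, 100 * (np.arange(1, 7) - 0.5) / 6)

    def test_all_equal_entries_map_to_median_percentile(self):
        rdm = _symmetric_rdm([2.0] * 6, 4)
        perc = vr.percentile_transform(rdm)
        np.testing.assert_allclose(perc.upper_values(), 50.0)

    def test_rank_order_preserved(self):
        vals = np.random.default_rng(3).uniform(1, 9, size=15)
        rdm = _symmetric_rdm(vals, 6)
        perc = vr.percentile_transform(rdm)
        a, b = rdm.upper_values(), perc.upper_values()
        np.testing.assert_array_equal(np.argsort(a), np.argsort(b))


class TestModelRDMs:
    def test_human_model_groups_speech_with_nonspeech_vocal(self, stim48):
        rdm = vr.make_model_rdm(stim48, "human")
        by_id = {s.stimulus_id: s for s in stim48}
        ids = rdm.condition_labels
        sp = next(i for i, x in enumerate(ids) if by_id[x].subcategory == "speech")
        nsv = next(
            i for i, x in enumerate(ids) if by_id[x].subcategory == "nonspeech_vocal"
        )
        nat = next(i for i, x in enumerate(ids) if by_id[x].subcategory == "natural")
        assert rdm.matrix[sp, nsv] == 0.0  # same main category
        assert rdm.matrix[sp, nat] == 1.0

    def test_speech_model_separates_speech_from_other_vocal(self, stim48):
        rdm = vr.make_model_rdm(stim48, "speech")
        by_id = {s.stimulus_id: s for s in stim48}
        ids = rdm.condition_labels
        sp = [i for i, x in enumerate(ids) if by_id[x].subcategory == "speech"]
        nsv = [i for i, x in enumerate(ids) if by_id[x].subcategory == "nonspeech_vocal"]
        assert rdm.matrix[sp[0], nsv[0]] == 1.0
        assert rdm.matrix[sp[0], sp[1]] == 0.0

    @pytest.mark.parametrize("model", ["human", "speech", "nonspeech"])
    def test_model_rdms_are_valid_binary_rdms(self, stim48, model):
        rdm = vr.make_model_rdm(stim48, model)
        assert set(np.unique(rdm.matrix)) <= {0.0, 1.0}
        np.testing.assert_array_equal(rdm.matrix, rdm.matrix.T)
        np.testing.assert_array_equal(np.diag(rdm.matrix), 0.0)

    def test_unknown_model_rejected(self, stim48):
        with pytest.raises(InvalidArgumentError):
            vr.make_model_rdm(stim48, "syntax")


class TestCorrelateRDMs:
    def test_self_correlation_is_one(self):
        rdm = _symmetric_rdm([1, 2, 3, 4, 5, 6], 4)
        assert vr.correlate_rdms(rdm, rdm).spearman_rho == pytest.approx(1.0)

    def test_monotone_transform_invariance(self):
        vals = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        a = _symmetric_rdm(vals, 4)
        b = _symmetric_rdm(np.exp(vals), 4)
        assert vr.correlate_rdms(a, b).spearman_rho == pytest.approx(1.0)

    def test_hand_computed_four_condition_example(self):
        # upper triangles (1..6) vs (2,1,4,3,6,5): six rank differences of
        # +-1 each -> rho = 1 - 6*6/(6*35) = 0.82857142857...
        a = _symmetric_rdm([1, 2, 3, 4, 5, 6], 4)
        b = _symmetric_rdm([2, 1, 4, 3, 6, 5], 4)
        assert vr.correlate_rdms(a, b).spearman_rho == pytest.approx(1 - 36 / 210)

    def test_label_mismatch_rejected(self):
        a = _symmetric_rdm([1, 2, 3, 4, 5, 6], 4)
        b = _symmetric_rdm([1, 2, 3, 4, 5, 6], 4, labels=list("wxyz"))
        with pytest.raises(InvalidArgumentError):
            vr.correlate_rdms(a, b)

    def test_constant_rdm_signals_undefined(self):
        a = _symmetric_rdm([1, 2, 3, 4, 5, 6], 4)
        const = _symmetric_rdm([2.0] * 6, 4)
        with pytest.raises(UndefinedCorrelationError):
            vr.correlate_rdms(a, const)


class TestMDS:
    def _rdms_with_structure(self):
        # A and B perfectly rank-correlated, C uncorrelated with both
        rng = np.random.default_rng(0)
        base = rng.uniform(1, 2, 15)
        other = rng.permutation(base)
        a = _symmetric_rdm(base, 6)
        b = _symmetric_rdm(2 * base, 6)  # monotone transform of A
        c = _symmetric_rdm(other, 6)
        return a, b, c

    def test_correlated_rdms_coincide(self):
        coords = vr.mds_embed(self._rdms_with_structure())
        d_ab = np.linalg.norm(coords[0] - coords[1])
        d_ac = np.linalg.norm(coords[0] - coords[2])
        assert d_ab < 1e-8
        assert d_ac > 0.1

    def test_exact_triangle_distances_reproduced(self):
        # 1 - rho is proportional to the squared distance between rank
        # vectors, so two orthogonal single-swap perturbations of a base
        # ranking give an exactly collinear (hence embeddable) 3-point
        # configuration: classical MDS must reproduce its distances
        labels = [f"s{i}" for i in range(4)]
        base = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        swap01 = [2.0, 1.0, 3.0, 4.0, 5.0, 6.0]
        swap45 = [1.0, 2.0, 3.0, 4.0, 6.0, 5.0]
        rdms = [
            _symmetric_rdm(v, 4, labels=labels) for v in (swap01, base, swap45)
        ]
        d = np.zeros((3, 3))
        for i in range(3):
            for j in range(i + 1, 3):
                d[i, j] = d[j, i] = 1 - vr.correlate_rdms(rdms[i], rdms[j]).spearman_rho
        coords = vr.mds_embed(rdms)
        for i in range(3):
            for j in range(3):
                assert np.linalg.norm(coords[i] - coords[j]) == pytest.approx(
                    d[i, j], abs=1e-8
                )

    def test_output_centered_at_origin(self):
        coords = vr.mds_embed(self._rdms_with_structure())
        np.testing.assert_allclose(coords.mean(axis=0), 0.0, atol=1e-10)

    def test_fewer_than_three_rdms_rejected(self):
        a, b, _ = self._rdms_with_structure()
        with pytest.raises(InvalidArgumentError):
            vr.mds_embed([a, b])


class TestWithinBetweenTest:
    def test_separated_pools_give_minimal_p(self):
        n = 10
        part = [True] * 5 + [False] * 5
        iu, ju = np.triu_indices(n, 1)
        vals = np.where(
            np.array(part)[iu] == np.array(part)[ju],
            np.random.default_rng(0).uniform(1.0, 1.1, len(iu)),
            np.random.default_rng(1).uniform(5.0, 5.1, len(iu)),
        )
        rdm = _symmetric_rdm(vals, n)
        res = vr.within_between_test(rdm, part, n_iter=1000, seed=0)
        assert res.t_stat > 0
        assert res.p_boot <= 1 / 1000

    def test_single_iteration_p_is_binary(self):
        rdm = _symmetric_rdm(np.random.default_rng(2).uniform(1, 2, 45), 10)
        res = vr.within_between_test(
            rdm, [True] * 5 + [False] * 5, n_iter=1, seed=0
        )
        assert res.p_boot in (0.0, 1.0)

    def test_empty_pool_rejected(self):
        rdm = _symmetric_rdm([1, 2, 3, 4, 5, 6], 4)
        with pytest.raises(InvalidArgumentError):
            vr.within_between_test(rdm, [True] * 4, n_iter=10, seed=0)

    def test_within_between_split_counts(self, stim48):
        rdm = vr.make_model_rdm(stim48, "human")
        part = [s.main_category == "vocal" for s in stim48]
        within, between = within_between_cells(rdm, part)
        assert len(within) == 2 * 24 * 23 // 2
        assert len(between) == 24 * 24

    @pytest.mark.parametrize("resample", ["cells", "conditions"])
    def test_null_p_values_are_uniform(self, resample):
        # within and between drawn from one distribution -> p ~ U(0,1)
        rng = np.random.default_rng(42)
        n, part = 16, [True] * 8 + [False] * 8
        ps = []
        for rep in range(200):
            vals = rng.uniform(1.0, 2.0, n * (n - 1) // 2)
            rdm = _symmetric_rdm(vals, n)
            ps.append(
                vr.within_between_test(
                    rdm, part, n_iter=200, seed=rep, resample=resample
                ).p_boot
            )
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_condition_permutation_controls_dependent_cells(self, stim48):
        # group-averaged RDMs of pure-noise patterns: cells sharing a
        # condition are dependent; the condition-label permutation null
        # must not declare categorical structure
        part = [s.subcategory == "nonspeech_vocal" for s in stim48]
        worst = 0.0
        for rep in range(5):
            mats = [
                vr.compute_rdm(
                    vr.standardize(
                        vr.generate_beta_patterns(
                            stim48,
                            vr.GenerativeConfig(
                                vocal_effect=0, speech_gain=0, seed=500 + 10 * rep + p
                            ),
                        ),
                        "along_stimuli",
                    )
                ).matrix
                for p in range(5)
            ]
            rdm = RDM(condition_labels=stim48.ids, matrix=np.mean(mats, axis=0))
            res = vr.within_between_test(
                rdm, part, n_iter=400, seed=rep, resample="conditions"
            )
            worst = max(worst, 1.0 - res.p_boot)
        assert worst < 1.0 - 0.01 / 24  # never close to corrected significance


class TestPlannedComparisonEnumeration:
    def test_standard_factorial_yields_24(self):
        specs, m = vr.enumerate_planned_comparisons(
            rois=["A1", "TVA"],
            standardizations=["along_stimuli", "along_voxels"],
            models=["human", "speech", "nonspeech"],
        )
        assert m == 24
        assert len(specs) == 24
        assert len({tuple(s.values()) for s in specs}) == 24

    def test_degenerate_factorial(self):
        specs, m = vr.enumerate_planned_comparisons(
            ["A1"], ["none"], ["human"], hemispheres=["left"]
        )
        assert m == 1

    def test_bonferroni_correction_caps_at_one(self):
        res = vr.PlannedComparisonResult(
            roi_name="A1", hemisphere="left", standardization="none",
            model_name="human", t_stat=0.0, p_boot=0.2, n_iter=10,
        )
        assert res.correct(24).p_corrected == 1.0
        res2 = vr.PlannedComparisonResult(
            roi_name="A1", hemisphere="left", standardization="none",
            model_name="human", t_stat=2.0, p_boot=0.001, n_iter=1000,
        )
        assert res2.correct(24).p_corrected == pytest.approx(0.024)

    def test_empty_factor_rejected(self):
        with pytest.raises(InvalidArgumentError):
            vr.enumerate_planned_comparisons([], ["none"], ["human"])


def test_rdm_tsv_round_trip(tmp_path, stim48):
    rdm = vr.make_model_rdm(stim48, "human")
    path = tmp_path / "rdm.tsv"
    rdm.to_tsv(path)
    back = RDM.from_tsv(path, metric_tag="binary_model")
    np.testing.assert_allclose(back.matrix, rdm.matrix)
    assert back.condition_labels == rdm.condition_labels
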