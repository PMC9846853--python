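import numpy as np
import pytest

import voicerep as vr
from voicerep.decoding import DecodingResult, _dummy_null_scores, exceedance_rate
from voicerep.errors import DegenerateComparisonError, InvalidArgumentError


class TestBalancedSelection:
    @pytest.mark.parametrize("subset", ["speech", "nonspeech_vocal"])
    def test_24_stimuli_12_per_class(self, stim48, subset):
        chosen = vr.select_balanced_events(stim48, subset, seed=0)
        assert len(chosen) == 24
        by_id = {s.stimulus_id: s for s in stim48}
        subs = [by_id[c].subcategory for c in chosen]
        assert subs.count(subset) == 12
        assert subs.count("natural") == 6
        assert subs.count("artificial") == 6

    def test_seeded_draw_is_deterministic(self, stim48):
        assert vr.select_balanced_events(stim48, "speech", seed=5) == \
            vr.select_balanced_events(stim48, "speech", seed=5)

    def test_insufficient_vocal_stimuli_rejected(self):
        small = vr.generate_stimulus_set(11, seed=0)
        with pytest.raises(InvalidArgumentError):
            vr.select_balanced_events(small, "speech", seed=0)


class TestTwofoldDecoding:
    def test_separable_patterns_decode_perfectly(self, clean_pattern, stim48):
        for subset in ("speech", "nonspeech_vocal"):
            res = vr.decode_vocal_vs_nonvocal(
                clean_pattern, stim48, subset, scheme="none", seed=0
            )
            assert res.mean_accuracy == 1.0
            assert res.fold_accuracies == (1.0, 1.0)

    def test_noise_patterns_hover_at_chance(self, stim48):
        accs = []
        for seed in range(8):
            pat = vr.generate_beta_patterns(
                stim48,
                vr.GenerativeConfig(vocal_effect=0.0, speech_gain=0.0, seed=100 + seed),
            )
            accs.append(
                vr.decode_vocal_vs_nonvocal(pat, stim48, "speech", seed=0).mean_accuracy
            )
        # binomial error band around chance for 8 x 48 held-out events
        assert abs(np.mean(accs) - 0.5) < 3 * 0.5 / np.sqrt(8 * 48)

    def test_fold_swap_permutes_folds_mean_invariant(self, clean_pattern, stim48):
        pat = clean_pattern
        swapped = vr.ActivityPattern(
            values=pat.values,
            row_labels=pat.row_labels,
            run_labels=1 - np.asarray(pat.run_labels),
            participant_id=pat.participant_id,
        )
        vocal = {s.stimulus_id for s in stim48.by_main_category("vocal")}
        y = np.array([lab in vocal for lab in pat.row_labels], int)
        a = vr.run_twofold_decoding(pat, y)
        b = vr.run_twofold_decoding(swapped, y)
        assert a.fold_accuracies == b.fold_accuracies[::-1]
        assert a.mean_accuracy == b.mean_accuracy

    def test_single_run_rejected(self, clean_pattern):
        y = np.tile([0, 1], 48)
        with pytest.raises(InvalidArgumentError):
            vr.run_twofold_decoding(clean_pattern, y, run_labels=np.zeros(96))

    def test_single_class_training_fold_rejected(self, clean_pattern):
        y = (np.asarray(clean_pattern.run_labels) == 1).astype(int)
        with pytest.raises(InvalidArgumentError):
            vr.run_twofold_decoding(clean_pattern, y)


class TestDummyNull:
    def test_null_centered_at_half(self):
        null = vr.bootstrap_null_threshold(24, n_iter=20_000, seed=0)
        assert abs(null.mean - 0.5) < 0.01

    def test_median_threshold_near_half(self):
        null = vr.bootstrap_null_threshold(24, n_iter=20_000, quantile=0.5, seed=1)
        assert abs(null.threshold - 0.5) < 0.05

    def test_single_iteration_threshold_is_the_single_score(self):
        rng = np.random.default_rng(3)
        score = _dummy_null_scores(24, 1, np.random.default_rng(3))[0]
        null = vr.bootstrap_null_threshold(24, n_iter=1, quantile=0.9, seed=3)
        assert null.threshold == score

    def test_tie_aware_exceedance_calibrates_near_alpha(self):
        null = vr.bootstrap_null_threshold(24, n_iter=20_000, quantile=0.95, seed=4)
        exc = exceedance_rate(null.threshold, 24, n_iter=20_000, seed=5)
        assert abs(exc - 0.05) < 0.012
        strict = exceedance_rate(null.threshold, 24, n_iter=20_000, seed=5, tie_aware=False)
        assert strict <= exc  # strict exceedance is conservative on a lattice

    @pytest.mark.parametrize("kw", [{"quantile": 0.0}, {"quantile": 1.5}, {"n_iter": 0}])
    def test_invalid_parameters_rejected(self, kw):
        with pytest.raises(InvalidArgumentError):
            vr.bootstrap_null_threshold(24, **{"n_iter": 100, "quantile": 0.95, **kw})

    def test_svc_permutation_null_agrees_with_dummy(self, noise_pattern, stim48):
        chosen = vr.select_balanced_events(stim48, "speech", seed=0)
        mask = np.isin(np.asarray(noise_pattern.row_labels), chosen)
        sub = noise_pattern.select_rows(mask)
        vocal = {s.stimulus_id for s in stim48.by_main_category("vocal")}
        y = np.array([lab in vocal for lab in sub.row_labels], int)
        svc_null = vr.svc_permutation_threshold(sub, y, n_iter=200, seed=0)
        assert abs(svc_null.mean - 0.5) < 0.05


class TestAccuracyComparison:
    def _results(self, accs, tag="a"):
        return [
            DecodingResult(
                participant_id=f"p{i}",
                roi_name=tag,
                vocal_subset="speech",
                standardization="none",
                fold_accuracies=(acc, acc),
                mean_accuracy=acc,
            )
            for i, acc in enumerate(accs)
        ]

    def test_uniform_shift_gives_exact_signed_rank_p(self):
        # n=5 uniform positive differences: two-sided exact p = 2/2^5
        a = self._results([0.5, 0.55, 0.6, 0.65, 0.7])
        b = self._results([0.6, 0.65, 0.7, 0.75, 0.8], tag="b")
        stat, p = vr.compare_accuracy_sets(a, b)
        assert p == pytest.approx(2 / 32)

    def test_identical_accuracies_signal_degenerate(self):
        a = self._results([0.5, 0.6, 0.7])
        with pytest.raises(DegenerateComparisonError):
            vr.compare_accuracy_sets(a, self._results([0.5, 0.6, 0.7], tag="b"))

    def test_single_pair_rejected(self):
        with pytest.raises(InvalidArgumentError):
            vr.compare_accuracy_sets(self._results([0.5]), self._results([0.6]))

    def test_unpaired_participants_rejected(self):
        a = self._results([0.5, 0.6])
        b = self._results([0.5, 0.6, 0.7], tag="b")
        with pytest.raises(InvalidArgumentError):
            vr.compare_accuracy_sets(a, b)
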