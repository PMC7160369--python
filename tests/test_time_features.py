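import math

import numpy as np
import pytest

from vfforage.errors import EmptySequenceError, ValidationError
from vfforage.lexicon import classify_tokens
from vfforage.segmentation import segment_from_adjacency
from vfforage.time_features import (SwitchTiming, aggregate_timing,
                                    compute_switch_timing,
                                    intra_cluster_retrieval_times,
                                    optimal_switch_rates, switching_durations,
                                    trim_and_renormalize)
from vfforage.vf_io import ANIMAL, EXAMINER, NON_ANIMAL, PARTICIPANT, \
    Response, Token


def tok(word, onset, duration, speaker=PARTICIPANT, cls=ANIMAL):
    return Token(word=word, onset=onset, duration=duration, speaker=speaker,
                 token_class=cls)


class TestTrimAndRenormalize:
    def test_no_non_animal_tokens_identity(self, worked_example):
        response, _ = worked_example
        seq = trim_and_renormalize(response)
        np.testing.assert_allclose(seq.onsets,
                                   [1.0, 1.5, 2.2, 2.4, 2.9, 3.8, 4.2])
        assert seq.shortened_duration == seq.original_duration

    def test_removed_durations_shorten_the_recording(self):
        # 58 s recording with 8 s of non-animal speech -> 50 s shortened
        tokens = [
            tok("cat", 1.0, 0.3),
            tok("you", 3.0, 4.0, speaker=EXAMINER, cls=NON_ANIMAL),
            tok("um", 8.0, 4.0, cls=NON_ANIMAL),
            tok("dog", 13.0, 0.3),
        ]
        resp = Response(subject_id="s", tokens=tokens, total_duration=58.0)
        seq = trim_and_renormalize(resp)
        assert seq.shortened_duration == pytest.approx(50.0)
        # conservation: removed + shortened == original
        assert seq.original_duration - seq.shortened_duration == \
            pytest.approx(8.0)

    def test_interval_collapse_shifts_later_onsets(self):
        # animal at 10.0 s preceded by a 2.0 s examiner utterance -> 8.0 s
        tokens = [
            tok("cat", 1.0, 0.3),
            tok("good", 4.0, 2.0, speaker=EXAMINER, cls=NON_ANIMAL),
            tok("dog", 10.0, 0.3),
        ]
        resp = Response(subject_id="s", tokens=tokens, total_duration=60.0)
        seq = trim_and_renormalize(resp)
        assert seq.onsets[1] == pytest.approx(8.0)

    def test_gaps_without_interruptions_preserved(self):
        tokens = [
            tok("hum", 0.2, 0.5, cls=NON_ANIMAL),
            tok("cat", 1.0, 0.3),
            tok("dog", 2.5, 0.3),     # 1.5 s gap, nothing removed inside
            tok("good", 3.5, 1.0, speaker=EXAMINER, cls=NON_ANIMAL),
            tok("owl", 6.0, 0.3),
        ]
        resp = Response(subject_id="s", tokens=tokens, total_duration=60.0)
        seq = trim_and_renormalize(resp)
        assert seq.onsets[1] - seq.onsets[0] == pytest.approx(1.5)
        assert seq.onsets[2] - seq.onsets[1] == pytest.approx(2.5)  # 3.5 - 1.0

    def test_fraction_mode_divides_by_shortened_duration(self):
        tokens = [tok("cat", 1.0, 0.5), tok("dog", 31.0, 0.5)]
        resp = Response(subject_id="s", tokens=tokens, total_duration=60.0)
        seq = trim_and_renormalize(resp, mode="fraction")
        np.testing.assert_allclose(seq.onsets, [1.0 / 60, 31.0 / 60])

    def test_no_animals_raises(self):
        resp = Response(subject_id="s",
                        tokens=[tok("um", 1.0, 0.3, cls=NON_ANIMAL)],
                        total_duration=60.0)
        with pytest.raises(EmptySequenceError):
            trim_and_renormalize(resp)

    def test_unclassified_tokens_rejected(self):
        resp = Response(subject_id="s",
                        tokens=[Token(word="cat", onset=1.0, duration=0.3)],
                        total_duration=60.0)
        with pytest.raises(ValidationError, match="classify"):
            trim_and_renormalize(resp)

    def test_classify_then_trim_round_trip_on_generated_subject(
            self, small_cohort, lexicon):
        """Inserted interruptions collapse away exactly (conservation)."""
        for resp in small_cohort[:5]:
            classified = classify_tokens(resp, lexicon)
            seq = trim_and_renormalize(classified)
            removed = sum(t.duration for t in classified.tokens
                          if t.token_class == NON_ANIMAL)
            assert removed + seq.shortened_duration == \
                pytest.approx(seq.original_duration)


class TestSwitchTimingValues:
    def test_worked_example_sd(self, example_sequence, example_segmentation):
        np.testing.assert_allclose(
            switching_durations(example_sequence, example_segmentation),
            [0.7, 0.9])

    def test_worked_example_icrt(self, example_sequence, example_segmentation):
        np.testing.assert_allclose(
            intra_cluster_retrieval_times(example_sequence, example_segmentation),
            [0.2, 0.4])

    def test_worked_example_osr_follows_absolute_difference(self, example_sequence,
                                                  example_segmentation):
        timing = compute_switch_timing(example_sequence, example_segmentation)
        np.testing.assert_allclose(timing.osr,
                                   np.abs(timing.sd - timing.icrt))
        np.testing.assert_allclose(timing.osr, [0.5, 0.5])

    def test_no_switches_empty_lists(self, example_sequence):
        seg = segment_from_adjacency([True] * 6)
        timing = compute_switch_timing(example_sequence, seg)
        assert timing.sd.size == timing.icrt.size == timing.osr.size == 0

    def test_singleton_cluster_gives_missing_icrt_and_osr(self):
        from vfforage.time_features import AnimalSequence
        seq = AnimalSequence(subject_id="s", names=["a", "b", "c"],
                             onsets=np.array([1.0, 2.0, 4.0]),
                             original_duration=60, shortened_duration=60)
        seg = segment_from_adjacency([False, False])  # 3 singletons
        timing = compute_switch_timing(seq, seg)
        np.testing.assert_allclose(timing.sd, [1.0, 2.0])
        assert np.isnan(timing.icrt).all()
        assert np.isnan(timing.osr).all()

    def test_osr_properties(self):
        sd = np.array([1.0, 2.0, 0.5])
        icrt = np.array([1.0, np.nan, 0.9])
        osr = optimal_switch_rates(sd, icrt)
        assert osr[0] == 0.0            # sd == icrt -> perfectly matched
        assert np.isnan(osr[1])         # missing icrt -> missing osr
        assert osr[2] == pytest.approx(0.4)
        assert np.all((osr >= 0) | np.isnan(osr))


class TestAggregateTiming:
    def test_hand_arithmetic(self):
        timing = SwitchTiming(sd=np.array([1.0, 1.0]),
                              icrt=np.array([0.5, 0.4]),
                              osr=np.array([0.5, 0.6]))
        agg = aggregate_timing(timing)
        assert agg["osr_mean"] == pytest.approx(0.55)
        assert agg["osr_median"] == pytest.approx(0.55)
        assert agg["osr_min"] == pytest.approx(0.5)
        assert agg["osr_max"] == pytest.approx(0.6)
        assert agg["osr_var"] == pytest.approx(0.0025)  # population variance

    def test_single_value(self):
        timing = SwitchTiming(sd=np.array([0.7]), icrt=np.array([0.2]),
                              osr=np.array([0.5]))
        agg = aggregate_timing(timing)
        for stat in ("mean", "median", "min", "max"):
            assert agg[f"sd_{stat}"] == pytest.approx(0.7)
        assert agg["sd_var"] == 0.0

    def test_empty_all_missing(self):
        timing = SwitchTiming(sd=np.array([]), icrt=np.array([]),
                              osr=np.array([]))
        agg = aggregate_timing(timing)
        assert len(agg) == 15
        assert all(math.isnan(v) for v in agg.values())

    def test_missing_values_excluded_from_aggregates(self):
        timing = SwitchTiming(sd=np.array([1.0, 3.0]),
                              icrt=np.array([np.nan, 2.0]),
                              osr=np.array([np.nan, 1.0]))
        agg = aggregate_timing(timing)
        assert agg["icrt_mean"] == pytest.approx(2.0)
        assert agg["osr_mean"] == pytest.approx(1.0)
        assert agg["sd_mean"] == pytest.approx(2.0)
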