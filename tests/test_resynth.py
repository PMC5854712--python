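"""Profile building, average-rhythm synthesis, and deviation series."""

import numpy as np
import pytest

from songfractal.envelope import Envelope, NoteAnnotation, SongRecord, zero_pauses
from songfractal.resynth import (NoteInstance, build_note_profiles,
                                 build_pause_profiles, collect_instances,
                                 deviation_series, synthesize_average_song)


def make_instance(label, duration_ms, height, song_id="s0", onset=0.0):
    n = int(duration_ms)
    return NoteInstance(song_id=song_id, type_label=label, onset_ms=onset,
                        duration_ms=float(duration_ms),
                        course=np.full(n, float(height)), rate=1000.0)


class TestCollectInstances:
    def test_counts_match_annotations(self, clean_corpus):
        songs, _ = clean_corpus
        instances = collect_instances(songs)
        assert len(instances) == sum(len(s.notes) for s in songs)
        per_type = {}
        for inst in instances:
            per_type[inst.type_label] = per_type.get(inst.type_label, 0) + 1
        ann_per_type = {}
        for s in songs:
            for n in s.notes:
                ann_per_type[n.type_label] = ann_per_type.get(n.type_label, 0) + 1
        assert per_type == ann_per_type

    def test_empty_corpus(self):
        assert collect_instances([]) == []

    def test_unlabeled_note_rejected(self):
        song = SongRecord(envelope=Envelope(values=np.ones(100)),
                          notes=[NoteAnnotation(0, 50, "")])
        with pytest.raises(ValueError, match="unlabeled"):
            collect_instances([song])


class TestBuildNoteProfiles:
    def test_identical_instances_reproduced_exactly(self):
        insts = [make_instance("a", 80, 0.5) for _ in range(4)]
        prof = build_note_profiles(insts)["a"]
        assert prof.mean_duration_ms == 80.0
        np.testing.assert_array_equal(prof.course, insts[0].course)
        assert prof.n_instances == 4

    def test_mean_duration_of_two_instances(self):
        insts = [make_instance("a", 80, 0.5), make_instance("a", 120, 0.5)]
        assert build_note_profiles(insts)["a"].mean_duration_ms == 100.0

    def test_pointwise_mean_of_heights(self):
        insts = [make_instance("a", 100, 0.4), make_instance("a", 100, 0.8)]
        prof = build_note_profiles(insts)["a"]
        np.testing.assert_allclose(prof.course, 0.6, rtol=1e-12)


class TestBuildPauseProfiles:
    def make_corpus(self, pauses, labels=("a", "b")):
        songs = []
        for i, p in enumerate(pauses):
            vals = np.zeros(300 + int(p))
            vals[0:100] = 0.5
            vals[100 + int(p):200 + int(p)] = 0.5
            notes = [NoteAnnotation(0, 100, labels[0]),
                     NoteAnnotation(100 + p, 200 + p, labels[1])]
            songs.append(SongRecord(envelope=Envelope(values=vals,
                                                      song_id=f"s{i}"),
                                    notes=notes))
        return songs

    def test_mean_statistic(self):
        pp = build_pause_profiles(self.make_corpus([20, 40]), "mean")
        assert pp[("a", "b")].duration_ms == 30.0
        assert pp[("a", "b")].n_instances == 2

    def test_median_on_skewed_durations(self):
        pp = build_pause_profiles(self.make_corpus([10, 10, 100]), "median")
        assert pp[("a", "b")].duration_ms == 10.0

    def test_single_observation_either_statistic(self):
        for stat in ("mean", "median"):
            pp = build_pause_profiles(self.make_corpus([35]), stat)
            assert pp[("a", "b")].duration_ms == 35.0

    def test_unknown_statistic_rejected(self):
        with pytest.raises(ValueError):
            build_pause_profiles([], statistic="mode")


class TestSynthesizeAverageSong:
    def test_identity_on_zero_deviation_corpus(self, clean_corpus):
        songs, _ = clean_corpus
        profiles = build_note_profiles(collect_instances(songs))
        pauses = build_pause_profiles(songs)
        for song in songs:
            target = zero_pauses(song)
            avg = synthesize_average_song(song, profiles, pauses)
            assert len(avg.envelope) == len(target.envelope)
            np.testing.assert_allclose(avg.envelope.values,
                                       target.envelope.values, atol=1e-9)
            assert avg.provenance == "average_rhythm"

    def test_label_sequence_preserved(self, mixed_corpus):
        songs, _ = mixed_corpus
        profiles = build_note_profiles(collect_instances(songs))
        pauses = build_pause_profiles(songs)
        for song in songs:
            avg = synthesize_average_song(song, profiles, pauses)
            assert [n.type_label for n in avg.notes] == \
                [n.type_label for n in song.notes]

    def test_total_duration_is_sum_of_profiles(self, mixed_corpus):
        songs, _ = mixed_corpus
        profiles = build_note_profiles(collect_instances(songs))
        pauses = build_pause_profiles(songs)
        song = songs[0]
        avg = synthesize_average_song(song, profiles, pauses)
        n_expected = sum(profiles[n.type_label].course.size
                         for n in song.notes)
        n_expected += sum(int(round(pauses[(a.type_label, b.type_label)
                                           ].duration_ms))
                          for a, b in zip(song.notes[:-1], song.notes[1:]))
        assert len(avg.envelope) == n_expected

    def test_missing_profile_error_names_the_type(self, mixed_corpus):
        songs, _ = mixed_corpus
        profiles = build_note_profiles(collect_instances(songs))
        pauses = build_pause_profiles(songs)
        label = songs[0].notes[0].type_label
        del profiles[label]
        with pytest.raises(KeyError, match=label):
            synthesize_average_song(songs[0], profiles, pauses)


class TestDeviationSeries:
    def test_zero_on_zero_deviation_corpus(self, clean_corpus):
        songs, _ = clean_corpus
        profiles = build_note_profiles(collect_instances(songs))
        pauses = build_pause_profiles(songs)
        for song in songs:
            dev = deviation_series(song, profiles, pauses)
            np.testing.assert_allclose(dev.onset_to_onset_deviation_ms, 0.0,
                                       atol=1e-9)
            np.testing.assert_allclose(dev.intensity_deviation, 0.0, atol=1e-9)
            assert dev.onset_to_onset_deviation_ms.size == len(song.notes) - 1
            assert dev.intensity_deviation.size == len(song.notes)

    def test_single_late_note_detected(self, clean_corpus):
        songs, _ = clean_corpus
        profiles = build_note_profiles(collect_instances(songs))
        pauses = build_pause_profiles(songs)
        song = songs[0]
        # push the second note 15 ms later by inserting pause samples
        v = song.envelope.values
        idx = int(song.notes[1].onset_ms) - 1
        shifted = np.insert(v, idx, np.zeros(15))
        notes = [song.notes[0]] + [
            NoteAnnotation(n.onset_ms + 15, n.offset_ms + 15, n.type_label)
            for n in song.notes[1:]]
        late = SongRecord(envelope=Envelope(values=shifted,
                                            song_id=song.envelope.song_id),
                          notes=notes)
        dev = deviation_series(late, profiles, pauses)
        assert dev.onset_to_onset_deviation_ms[0] == pytest.approx(15.0,
                                                                   abs=1e-9)
        np.testing.assert_allclose(dev.onset_to_onset_deviation_ms[1:], 0.0,
                                   atol=1e-9)

    def test_drift_slope_recovered_within_10pct(self):
        from songfractal.simulate import SongConfig, gen_song_corpus
        cfg = SongConfig(n_songs=12, notes_per_song=(12, 16), seed=21,
                         deviation="drift")
        songs, _ = gen_song_corpus(cfg)
        profiles = build_note_profiles(collect_instances(songs))
        pauses = build_pause_profiles(songs)
        slopes = []
        for song in songs:
            dev = deviation_series(song, profiles, pauses)
            k = np.arange(dev.onset_to_onset_deviation_ms.size)
            slopes.append(np.polyfit(k, dev.onset_to_onset_deviation_ms, 1)[0])
        mean_abs = np.mean(np.abs(slopes))
        assert mean_abs == pytest.approx(cfg.drift_ms_per_transition, rel=0.10)
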