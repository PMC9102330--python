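"""Sliding-correlation nucleosome mapping and accuracy evaluation."""

import warnings

import numpy as np
import pytest
from scipy import stats

import nucpatterns as npx
from nucpatterns.mapping import MappingTrack
from nucpatterns.pattern import NucleosomePattern

from conftest import random_dna


def make_pattern(values, code="AA"):
    return NucleosomePattern(
        np.asarray(values, dtype=float), code, start=1, window=len(values),
        smoothing_window=1, trim=0,
    )


def test_cc_track_matches_naive_pearson():
    rng = np.random.default_rng(21)
    seq = random_dna(rng, 80)
    pat = make_pattern(rng.random(21), "WW")
    track = npx.cc_track(seq, pat)
    ind = npx.encode_occurrences(seq, "WW").astype(float)
    m = len(pat.values)
    for t in range(len(ind) - m + 1):
        b = ind[t : t + m]
        if b.std() == 0:
            assert np.isnan(track.cc[t + m // 2])
        else:
            expected = stats.pearsonr(pat.values, b).statistic
            assert track.cc[t + m // 2] == pytest.approx(expected, abs=1e-10)


def test_planted_indicator_match_gives_cc_one_at_dyad():
    """A sequence whose class indicator equals the pattern scores CC=1 there."""
    rng = np.random.default_rng(22)
    core = "ACAA" * 10  # AA indicator: 0,0,1,0 repeating
    seq = "GCGC" * 10 + core + "GCGC" * 10
    ind = npx.encode_occurrences(core, "AA").astype(float)
    pat = make_pattern(ind, "AA")
    track = npx.cc_track(seq, pat)
    t_true = 40  # 0-based placement of the core
    dyad_idx = t_true + len(pat) // 2
    assert track.cc[dyad_idx] == pytest.approx(1.0, abs=1e-12)
    assert np.nanargmax(track.cc) == dyad_idx


def test_zero_variance_segment_is_missing():
    pat = make_pattern(np.linspace(0, 1, 11), "CC")
    seq = "AT" * 20  # no CC anywhere
    track = npx.cc_track(seq, pat)
    assert np.all(np.isnan(track.cc))


def test_sequence_too_short_errors():
    pat = make_pattern(np.linspace(0, 1, 30))
    with pytest.raises(ValueError):
        npx.cc_track("ACGTACGT", pat)


def test_translation_equivariance():
    """Prepending background shifts the predicted dyad by exactly that much."""
    rng = np.random.default_rng(23)
    core = "ACAA" * 12
    pat = make_pattern(npx.encode_occurrences(core, "AA").astype(float), "AA")
    tail = random_dna(rng, 40)
    seq = "GC" * 20 + core + tail
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        base = npx.predict_dyad([npx.cc_track(seq, pat)]).predicted_dyad
        for n in (1, 7, 13):
            shifted = npx.predict_dyad([npx.cc_track("CG" * (n // 2) + "G" * (n % 2) + seq, pat)])
            assert shifted.predicted_dyad == base + n


def test_palindromic_class_mirrors_under_reverse_complement():
    """WW mapping of the rc'd sequence is the mirrored WW track (odd m)."""
    rng = np.random.default_rng(24)
    seq = random_dna(rng, 90)
    vals = rng.random(21)
    sym = (vals + vals[::-1]) / 2  # mirror-symmetric pattern, odd length
    pat = make_pattern(sym, "WW")
    fw = npx.cc_track(seq, pat).cc
    rc = npx.cc_track(npx.reverse_complement(seq), pat).cc
    m = len(sym)
    L = len(seq)
    for t in range(L - 1 - m + 1):
        d = t + m // 2
        d_rc = (L - 1 - m - t) + m // 2
        np.testing.assert_allclose(rc[d_rc], fw[d], atol=1e-12, equal_nan=True)


class TestPredictDyad:
    def test_single_track_positive_max(self):
        cc = np.full(250, np.nan)
        cc[50:240] = 0.1
        cc[199] = 0.8  # 1-based position 200
        res = npx.predict_dyad([MappingTrack(cc, "p1", "AA")])
        assert (res.predicted_dyad, res.no_call) == (200, False)
        assert res.max_cc == pytest.approx(0.8)

    def test_mean_of_two_tracks(self):
        a = np.array([np.nan, 0.2, 0.6, 0.1, np.nan])
        b = np.array([np.nan, 0.5, 0.3, 0.1, np.nan])
        res = npx.predict_dyad([MappingTrack(a, "p1", "AA"), MappingTrack(b, "p2", "TT")])
        assert res.predicted_dyad == 3  # mean 0.45 at position 3 beats 0.35
        assert res.aggregation == "mean"

    def test_all_negative_is_no_call(self):
        cc = np.full(100, -0.2)
        res = npx.predict_dyad([MappingTrack(cc, "p1", "AA")])
        assert res.no_call and res.predicted_dyad is None

    def test_long_sequence_warns_about_nonuniqueness(self):
        cc = np.zeros(300)
        cc[100] = 0.5
        with pytest.warns(UserWarning, match="two nucleosome lengths"):
            npx.predict_dyad([MappingTrack(cc, "p1", "AA")])


class TestEvaluateAccuracy:
    @staticmethod
    def result(seq_id, calls):
        """calls: pattern_id -> predicted position (cc fixed positive)."""
        tracks = []
        for pid, pos in calls.items():
            cc = np.full(400, np.nan)
            cc[100:350] = 0.05
            cc[pos - 1] = 0.9
            tracks.append(MappingTrack(cc, pid, "AA"))
        res = npx.predict_dyad(tracks) if tracks else None
        res.seq_id = seq_id
        return res

    def test_distance_and_hit_flag(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            results = {
                "s1": self.result("s1", {"aa": 199}),
                "s2": self.result("s2", {"aa": 200}),
                "s3": self.result("s3", {"aa": 250}),
            }
        table, rate = npx.evaluate_accuracy(results, {"s1": 200, "s2": 200, "s3": 200})
        by_id = table.set_index("seq_id")
        assert by_id.loc["s1", "distance"] == 1 and by_id.loc["s1", "hit"]
        assert by_id.loc["s2", "distance"] == 0
        assert not by_id.loc["s3", "hit"]
        assert rate == pytest.approx(2 / 3)

    def test_best_pattern_minimal_distance_ties_lexicographic(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = self.result("s1", {"b": 203, "a": 197, "c": 210})
        table, _ = npx.evaluate_accuracy({"s1": res}, {"s1": 200})
        assert table.loc[0, "best_pattern"] == "a"  # 197 and 203 tie at distance 3

    def test_missing_truth_errors(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = self.result("s1", {"a": 200})
        with pytest.raises(KeyError):
            npx.evaluate_accuracy({"s1": res}, {"other": 200})
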