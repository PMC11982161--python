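import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from speechcoord import (
    ConfigurationError,
    FormatError,
    IntervalAnnotation,
    SpeechSeries,
    align_dyad,
    binarize,
    read_annotation,
    read_series_csv,
    series_to_intervals,
    write_series_csv,
)

SPEECH_MAP = {"speech": 1, "silence": 0}


def ann(intervals, total=None, label_map=SPEECH_MAP):
    total = total if total is not None else intervals[-1][1]
    return IntervalAnnotation(tuple(intervals), total, "p1", label_map)


class TestReadAnnotation:
    def test_interval_csv(self, tmp_path):
        f = tmp_path / "p1.csv"
        f.write_text("onset,offset,label\n0.0,1.6,sounding\n1.6,3.0,silent\n")
        a = read_annotation(f)
        assert len(a.intervals) == 2
        assert a.total_duration == 3.0
        assert a.intervals[0] == (0.0, 1.6, "sounding")

    def test_csv_missing_columns(self, tmp_path):
        f = tmp_path / "bad.csv"
        f.write_text("start,stop\n0,1\n")
        with pytest.raises(ConfigurationError):
            read_annotation(f)

    def test_overlapping_intervals_name_the_pair(self, tmp_path):
        f = tmp_path / "p1.csv"
        f.write_text("onset,offset,label\n0.0,2.0,sounding\n1.5,3.0,sounding\n")
        with pytest.raises(FormatError, match="overlap"):
            read_annotation(f)

    def test_textgrid_tier_selection(self, tmp_path):
        tg = tmp_path / "p1.TextGrid"
        tg.write_text(
            'File type = "ooTextFile"\n'
            'Object class = "TextGrid"\n'
            "xmin = 0\nxmax = 3\ntiers? <exists>\nsize = 2\nitem []:\n"
            "    item [1]:\n"
            '        class = "IntervalTier"\n'
            '        name = "silences"\n'
            "        xmin = 0\n        xmax = 3\n        intervals: size = 2\n"
            "        intervals [1]:\n"
            "            xmin = 0\n            xmax = 1.6\n"
            '            text = "sounding"\n'
            "        intervals [2]:\n"
            "            xmin = 1.6\n            xmax = 3\n"
            '            text = "silent"\n'
            "    item [2]:\n"
            '        class = "IntervalTier"\n'
            '        name = "words"\n'
            "        xmin = 0\n        xmax = 3\n        intervals: size = 1\n"
            "        intervals [1]:\n"
            "            xmin = 0\n            xmax = 3\n"
            '            text = "hello"\n'
        )
        a = read_annotation(tg, "silences")
        assert [iv[2] for iv in a.intervals] == ["sounding", "silent"]
        with pytest.raises(ConfigurationError):
            read_annotation(tg)  # ambiguous: two tiers, no selector
        with pytest.raises(ConfigurationError):
            read_annotation(tg, "nonexistent")


class TestBinarize:
    @pytest.mark.parametrize(
        "intervals,total,rule,expected",
        [
            # bin [1,2) holds 0.6 s of speech -> majority speech
            ([(0.0, 1.6, "speech"), (1.6, 3.0, "silence")], 3.0, "majority", [1, 1, 0]),
            ([(0.0, 5.0, "silence")], 5.0, "majority", [0, 0, 0, 0, 0]),
            # 0.4 s < 0.5 s majority threshold, but any overlap counts for any_speech
            ([(0.0, 0.4, "speech"), (0.4, 2.0, "silence")], 2.0, "majority", [0, 0]),
            ([(0.0, 0.4, "speech"), (0.4, 2.0, "silence")], 2.0, "any_speech", [1, 0]),
            # exactly 0.5 s ties to speech
            ([(0.0, 0.5, "speech"), (0.5, 2.0, "silence")], 2.0, "majority", [1, 0]),
        ],
    )
    def test_rules(self, intervals, total, rule, expected):
        s = binarize(ann(intervals, total), rule)
        assert s.values.tolist() == expected

    def test_partial_trailing_bin_dropped(self):
        s = binarize(ann([(0.0, 3.7, "speech")], 3.7))
        assert len(s) == 3

    def test_too_short(self):
        with pytest.raises(FormatError):
            binarize(ann([(0.0, 0.9, "speech")], 0.9))

    def test_unknown_label(self):
        with pytest.raises(ConfigurationError):
            binarize(ann([(0.0, 2.0, "mumble")], 2.0))

    def test_idempotent_on_reexported_intervals(self):
        s = binarize(ann([(0.0, 1.6, "speech"), (1.6, 4.0, "silence"), (4.0, 6.2, "speech")], 6.2))
        again = binarize(series_to_intervals(s))
        assert np.array_equal(s.values, again.values)

    @given(
        cuts=st.lists(st.floats(0.1, 9.9), min_size=1, max_size=8, unique=True),
        labels=st.integers(0, 255),
    )
    @settings(max_examples=50, deadline=None)
    def test_majority_never_exceeds_any_speech(self, cuts, labels):
        bounds = [0.0] + sorted(cuts) + [10.0]
        intervals = [
            (bounds[i], bounds[i + 1], "speech" if (labels >> i) & 1 else "silence")
            for i in range(len(bounds) - 1)
        ]
        a = ann(intervals, 10.0)
        maj = binarize(a, "majority").values
        any_ = binarize(a, "any_speech").values
        assert np.all(maj <= any_)


class TestAlignAndRoundTrip:
    def mk(self, n, pid):
        return SpeechSeries(np.resize([1, 0], n), "d1", pid, "introduction")

    def test_truncates_to_shorter(self):
        d = align_dyad(self.mk(299, "p1"), self.mk(301, "p2"))
        assert d.n == 299

    def test_equal_lengths_unchanged(self):
        d = align_dyad(self.mk(300, "p1"), self.mk(300, "p2"))
        assert d.n == 300

    def test_mismatched_dyad(self):
        a = SpeechSeries([1, 0], "d1", "p1", "introduction")
        b = SpeechSeries([1, 0], "d2", "p2", "introduction")
        with pytest.raises(FormatError):
            align_dyad(a, b)

    def test_csv_round_trip(self, tmp_path):
        rng = np.random.default_rng(5)
        s = SpeechSeries((rng.random(120) < 0.4).astype(int), "d1", "p1", "argumentative")
        f = tmp_path / "s.csv"
        write_series_csv(s, f)
        back = read_series_csv(f, dyad_id="d1", participant_id="p1", task="argumentative")
        assert np.array_equal(s.values, back.values)


def test_speech_series_rejects_nonbinary():
    with pytest.raises(FormatError):
        SpeechSeries([0, 2, 1], "d", "p", "introduction")
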