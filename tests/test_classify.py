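"""Profile coding, region calling, class summaries and candidate ranking."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from posrnaseq import (
    CountMatrix,
    NestedDesign,
    call_region,
    classify_all,
    encode_profile,
    format_code,
    parse_code,
    rank_candidates,
    summarize_class_sizes,
    summarize_classes,
)

from conftest import random_count_matrix


class TestEncodeProfile:
    @pytest.mark.parametrize(
        "diffs,expected",
        [
            ((5.17, -0.03, -0.39), ("+", "0", "0")),
            ((2.00, 5.35, 0.88), ("0", "+", "0")),  # exactly 2.00 codes as 0
            ((0.0, 0.0, 0.0), ("0", "0", "0")),
            ((-2.5, 2.5, 0.0), ("-", "+", "0")),
            ((-2.0, 2.0, 1.99), ("0", "0", "0")),   # strict at both signs
        ],
    )
    def test_coding_rule(self, diffs, expected):
        assert encode_profile(diffs) == expected

    def test_per_comparison_thresholds(self):
        # a laxer C-B cut-off recovers gonad transcripts below the global one
        assert encode_profile((0.5, 1.5, 0.5), thresholds=2.0) == ("0", "0", "0")
        assert encode_profile((0.5, 1.5, 0.5), thresholds=[2.0, 1.0, 2.0]) == (
            "0", "+", "0",
        )

    def test_non_finite_difference_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            encode_profile((np.nan, 0.0, 0.0))

    def test_code_formatting_round_trip(self):
        assert format_code(("+", "0", "0")) == "[+,0,0]"
        assert parse_code("[+,0,-]") == ("+", "0", "-")
        with pytest.raises(ValueError):
            parse_code("[+,x,0]")

    @given(
        diffs=st.lists(st.floats(-10, 10), min_size=3, max_size=3),
        t1=st.floats(0.5, 4.0),
        t2=st.floats(0.5, 4.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_raising_threshold_never_creates_a_symbol(self, diffs, t1, t2):
        lo, hi = sorted([t1, t2])
        code_lo = encode_profile(diffs, lo)
        code_hi = encode_profile(diffs, hi)
        for a, b in zip(code_lo, code_hi):
            if a == "0":
                assert b == "0"


class TestCallRegion:
    @pytest.mark.parametrize(
        "code,expected",
        [
            (("0", "0", "0"), "non-differential"),
            (("+", "0", "0"), "testis region"),
            (("0", "+", "0"), "ovary region"),
            (("+", "+", "0"), "ovary region"),   # leading contamination
            (("0", "0", "+"), "tail region"),
            (("+", "0", "+"), "other"),
            (("0", "+", "+"), "other"),          # trailing ++ is not honoured
            (("-", "+", "0"), "other"),          # any − is dilution, not location
            (("+", "+", "+"), "other"),
            (("0", "-", "0"), "other"),
        ],
    )
    def test_canonical_mapping(self, design, code, expected):
        assert call_region(code, design) == expected

    def test_length_mismatch(self, design):
        with pytest.raises(ValueError, match="length"):
            call_region(("+", "0"), design)

    def test_contamination_pattern_needs_a_flagged_pair(self):
        plain = NestedDesign(
            samples=[("A", {"r1"}), ("B", {"r1", "r2"}), ("C", {"r1", "r2", "r3"}),
                     ("D", {"r1", "r2", "r3", "r4"})],
            region_order=["r1", "r2", "r3", "r4"],
        )
        # no pair flagged: only the simple one-plus rule applies
        assert call_region(("+", "+", "0"), plain) == "other"
        assert call_region(("0", "+", "0"), plain) == "r3 region"
        # explicitly flagging the later pair moves the honoured pattern
        assert call_region(("0", "+", "+"), plain,
                           contamination_pair=("C-B", "D-C")) == "r4 region"


class TestClassifyAll:
    def test_each_class_once_on_a_crafted_matrix(self, design):
        total = 1e6
        base = 100.0

        def counts_for(levels):
            # invert the level formula at fixed totals (pseudo-count removed)
            return [total * (2.0**lv) / 100.0 for lv in levels]

        rows = {
            "t_nd":    counts_for([2, 2, 2, 2]),
            "t_test":  counts_for([0, 3, 3, 3]),
            "t_ov1":   counts_for([0, 0, 3, 3]),
            "t_ov2":   counts_for([0, 3, 6, 6]),
            "t_tail":  counts_for([0, 0, 0, 3]),
            "t_other": counts_for([6, 3, 0, 0]),
        }
        frame = pd.DataFrame.from_dict(rows, orient="index",
                                       columns=design.sample_names)
        # fix totals explicitly so the designed levels are (almost) exact
        cm = CountMatrix(frame, totals={s: total for s in design.sample_names})
        table = classify_all(cm, design)
        assert table["region_call"].tolist() == [
            "non-differential", "testis region", "ovary region", "ovary region",
            "tail region", "other",
        ]

    def test_empty_matrix_gives_empty_table(self, design):
        cm = CountMatrix(
            pd.DataFrame(columns=design.sample_names, dtype=float),
            totals={s: 1.0 for s in design.sample_names},
        )
        table = classify_all(cm, design)
        assert len(table) == 0
        assert "region_call" in table.columns

    def test_partition_and_determinism(self, design, rng):
        cm = random_count_matrix(rng, 300)
        t1 = classify_all(cm, design)
        t2 = classify_all(cm, design)
        pd.testing.assert_frame_equal(t1, t2)
        assert t1["region_call"].notna().all()
        summary = summarize_classes(t1, design)
        assert summary.per_class["n"].sum() == len(t1)
        assert summary.total == len(t1)


class TestSummaries:
    def test_published_class_sizes_arithmetic(self):
        sizes = {"[0,0,0]": 70064, "[+,0,0]": 3360, "[+,+,0]": 127,
                 "[0,+,0]": 323, "[0,0,+]": 366, "other": 468}
        summary = summarize_class_sizes(sizes)
        assert summary.total == 74708
        assert summary.n_differential == 4644
        share = summary.per_class.loc["[+,0,0]", "share_of_differential"]
        assert share == pytest.approx(100 * 3360 / 4644)
        assert round(share, 1) == 72.4

    def test_single_class_input_is_100_percent(self, design):
        table = pd.DataFrame(
            {"profile_code": ["[0,0,0]"] * 5, "region_call": ["non-differential"] * 5},
            index=[f"t{i}" for i in range(5)],
        )
        summary = summarize_classes(table, design)
        assert summary.per_class.loc["[0,0,0]", "percent"] == 100.0
        assert summary.n_differential == 0


class TestRankCandidates:
    def make_table(self):
        return pd.DataFrame(
            {
                "B-A": [5.2, 3.1, 4.0, 4.0, 0.1],
                "C-B": [0.0, 0.0, 0.0, 0.0, 5.0],
                "D-C": [0.0, 0.0, 0.0, 0.0, 0.2],
                "region_call": ["testis region"] * 4 + ["ovary region"],
            },
            index=["tx_b", "tx_a", "tx_d", "tx_c", "tx_ov"],
        )

    def test_descending_defining_difference(self):
        # 5.2 first; the 4.0 tie resolves lexicographically to tx_c
        assert rank_candidates(self.make_table(), "testis region", 2) == [
            "tx_b", "tx_c",
        ]

    def test_tie_breaks_lexicographically(self):
        assert rank_candidates(self.make_table(), "testis region", 4) == [
            "tx_b", "tx_c", "tx_d", "tx_a",
        ]

    def test_top_n_larger_than_matches(self):
        assert rank_candidates(self.make_table(), "ovary region", 10) == ["tx_ov"]

    def test_no_matches_is_empty(self):
        assert rank_candidates(self.make_table(), "tail region", 3) == []
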