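"""Percentage-of-total, percentage-change, pattern classification and the
full dynamics table against the published reference cells."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import bindyn as bd
from .conftest import REFERENCE_CELLS, REFERENCE_MEANS, REFERENCE_TOTALS

TRANSITIONS = [("R2", "R3"), ("R3", "R4"), ("R2", "R4")]


class TestPctChange:
    @pytest.mark.parametrize(
        ("baseline", "later", "expected"),
        [
            (3, 19, 533),     # photosynthesis pwd->wd
            (15, 28, 87),     # 86.67 rounds away from zero
            (19, 16, -16),    # -15.79
            (58, 165, 184),   # 184.48
            (139, 151, 9),    # 8.63
            (0, 1, None),     # zero baseline undefined
            (0, 0, None),
            (7, 7, 0),
        ],
    )
    def test_examples(self, baseline, later, expected):
        assert bd.pct_change(baseline, later) == expected

    def test_negative_counts_are_a_contract_violation(self):
        with pytest.raises(bd.IntegrityError):
            bd.pct_change(-1, 3)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.integers(0, 500), st.integers(0, 500))
    def test_defined_iff_baseline_positive_and_sign_matches_pattern(self, a, b):
        pc = bd.pct_change(a, b)
        assert (pc is not None) == (a > 0)
        if pc is not None:
            label = bd.classify_transition(a, b)
            if pc != 0:
                assert {1: "up", -1: "down"}[int(np.sign(pc))] == label
            else:
                # sub-half-percent changes round to 0 but the pattern label
                # still reflects the raw count direction
                assert label == "nc" if a == b else abs(b - a) / a < 0.005

    def test_baseline_asymmetry(self):
        # pct_change is relative to its own baseline: (4,1) -> -75 but
        # (1,4) -> +300, not +75.
        assert bd.pct_change(4, 1) == -75
        assert bd.pct_change(1, 4) == 300


class TestPatterns:
    @pytest.mark.parametrize(
        ("baseline", "later", "label"),
        [(0, 1, "up"), (1, 1, "nc"), (4, 1, "down"), (0, 0, "nc")],
    )
    def test_transition_labels_derive_from_raw_counts(self, baseline, later, label):
        assert bd.classify_transition(baseline, later) == label

    @pytest.mark.parametrize(
        ("labels", "composite"),
        [
            (("up", "up"), "up-pattern"),
            (("down", "down"), "down-pattern"),
            (("nc", "nc"), "unchanged-pattern"),
            (("up", "down"), "mixed-pattern(up/down)"),
            (("down", "up"), "mixed-pattern(down/up)"),
            (("nc", "up"), "mixed-pattern(unchanged/up)"),
            (("nc", "down"), "mixed-pattern(unchanged/down)"),
            (("up",), "up-pattern"),
        ],
    )
    def test_trajectory_composites(self, labels, composite):
        assert bd.classify_trajectory(labels) == composite

    def test_empty_trajectory_is_a_contract_violation(self):
        with pytest.raises(bd.IntegrityError):
            bd.classify_trajectory([])


class TestCountByBin:
    def test_counts_unmapped_to_not_assigned_and_conserves_columns(
        self, small_binmap
    ):
        degs = {
            "R2": [
                bd.DEGRecord("gPS1", 2.0, 0.01, "up"),
                bd.DEGRecord("gPS2", 2.0, 0.01, "up"),
                bd.DEGRecord("mystery", -2.0, 0.01, "down"),
            ],
            "R3": [],
        }
        m = bd.count_by_bin(degs, small_binmap)
        assert m["PS.lightreaction", "R2"] == 2
        assert m[bd.NOT_ASSIGNED, "R2"] == 1
        assert int(m.column_totals()["R2"]) == 3
        assert int(m.column_totals()["R3"]) == 0

    def test_bins_ordered_by_code_with_not_assigned_last(self, small_binmap):
        degs = {
            "R2": [
                bd.DEGRecord("gCHO2", 2.0, 0.01, "up"),
                bd.DEGRecord("gPS1", 2.0, 0.01, "up"),
                bd.DEGRecord("x", 2.0, 0.01, "up"),
            ]
        }
        m = bd.count_by_bin(degs, small_binmap)
        assert m.bins == [
            "PS.lightreaction",
            "major CHO.degradation.starch",
            bd.NOT_ASSIGNED,
        ]

    def test_recovered_matrix_from_simulation_sums_to_published_totals(
        self, reference_sim_degs
    ):
        degs, binmap, _ = reference_sim_degs
        m = bd.count_by_bin(degs, binmap)
        assert dict(m.column_totals()) == REFERENCE_TOTALS


class TestPctOfTotal:
    def test_single_bin_is_100_percent(self):
        m = bd.CountMatrix(counts=pd.DataFrame({"R2": [5]}, index=["protein"]))
        assert bd.pct_of_total(m).at["protein", "R2"] == 100.0

    def test_two_equal_bins_split_50_50(self):
        m = bd.CountMatrix(counts=pd.DataFrame({"R2": [3, 3]}, index=["a", "b"]))
        assert list(bd.pct_of_total(m)["R2"]) == [50.0, 50.0]

    def test_reference_photosynthesis_share_at_water_deficit(
        self, reference_matrix
    ):
        # 19 of 2980 DEGs -> 0.64% (2 d.p.)
        share = bd.pct_of_total(reference_matrix).at["photosynthesis", "R3"]
        assert round(share, 2) == 0.64

    def test_columns_sum_to_100_and_zero_total_flagged_nan(self, reference_matrix):
        pct = bd.pct_of_total(reference_matrix)
        assert np.allclose(pct.sum(axis=0), 100.0)
        empty = bd.CountMatrix(counts=pd.DataFrame({"R2": [0]}, index=["a"]))
        assert bd.pct_of_total(empty)["R2"].isna().all()


class TestMeanPctChange:
    def test_single_bin(self):
        m = bd.CountMatrix(counts=pd.DataFrame({"R2": [2], "R3": [3]}, index=["a"]))
        assert bd.mean_pct_change(m, ("R2", "R3")) == 50

    def test_all_undefined_returns_none(self):
        m = bd.CountMatrix(counts=pd.DataFrame({"R2": [0], "R3": [3]}, index=["a"]))
        assert bd.mean_pct_change(m, ("R2", "R3")) is None

    @pytest.mark.parametrize(("transition", "expected"), list(REFERENCE_MEANS.items()))
    def test_reference_means(self, reference_matrix, transition, expected):
        assert bd.mean_pct_change(reference_matrix, transition) == expected

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.randoms(use_true_random=False))
    def test_invariant_to_bin_ordering(self, reference_matrix, rnd):
        order = list(reference_matrix.counts.index)
        rnd.shuffle(order)
        shuffled = bd.CountMatrix(counts=reference_matrix.counts.loc[order])
        for t in TRANSITIONS:
            assert bd.mean_pct_change(shuffled, t) == bd.mean_pct_change(
                reference_matrix, t
            )


def test_timepoint_modification():
    a = {"photosynthesis": 5, "protein": 5, "RNA": 0}
    b = {"photosynthesis": 5, "protein": 7, "RNA": 0}
    assert bd.timepoint_modification(a, b) == {
        "photosynthesis": "unchanged",
        "protein": "modified",
        "RNA": "unchanged",
    }
    with pytest.raises(bd.IntegrityError):
        bd.timepoint_modification(a, {"photosynthesis": 5})


class TestDynamicsTable:
    def test_reproduces_every_published_cell(self, reference_matrix):
        """Full-matrix check: every percent-change and pattern cell of the
        published three-stage table, including all na/nc cells."""
        table = bd.dynamics_table(reference_matrix).set_index("bin")
        for bin_name, cells in REFERENCE_CELLS.items():
            for k, (base, later) in enumerate(TRANSITIONS):
                pc_expected, pat_expected = cells[2 * k], cells[2 * k + 1]
                pc = table.at[bin_name, f"pct_change:{base}/{later}"]
                if pc_expected is None:
                    assert pc is pd.NA or pc != pc
                else:
                    assert pc == pc_expected
                assert table.at[bin_name, f"pattern:{base}/{later}"] == pat_expected

    def test_total_and_mean_rows(self, reference_matrix):
        table = bd.dynamics_table(reference_matrix).set_index("bin")
        for stage, total in REFERENCE_TOTALS.items():
            assert table.at["Total", f"count:{stage}"] == total
        for (base, later), mean in REFERENCE_MEANS.items():
            assert table.at["% mean", f"pct_change:{base}/{later}"] == mean

    def test_default_transitions_consecutive_plus_span(self):
        assert bd.default_transitions(["R2", "R3", "R4"]) == TRANSITIONS
        assert bd.default_transitions(["R2", "R3"]) == [("R2", "R3")]
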