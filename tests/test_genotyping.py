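"""Genotype calling thresholds, run filtering, marker QC and coverage windows."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rtgrecomb.genotypes import (
    DEFAULT_THRESHOLDS,
    GenotypingThresholds,
    HET,
    HOM_P1,
    HOM_P2,
    NO_CALL,
    call_genotype,
    call_genotypes,
    cnv_marker_mask,
    coverage_windows,
    filter_short_runs,
    frame_to_genotypes,
    genotypes_to_frame,
    qc_marker_set,
)


class TestCallGenotype:
    @pytest.mark.parametrize(
        "n_p1,n_p2,expected",
        [
            (48, 2, HOM_P1),  # 96% reference-parent reads
            (3, 2, NO_CALL),  # depth 5 is not greater than 5
            (30, 70, HET),  # 70% P2 does not exceed the 75% cutoff
            (100, 0, HOM_P1),
            (0, 100, HOM_P2),
            (24, 76, HOM_P2),  # 76% P2 exceeds the cutoff
            (95, 5, HET),  # exactly 95% P1 stays heterozygous (strict cutoff)
            (25, 75, HET),  # boundary of the het range is inclusive
            (0, 0, NO_CALL),
        ],
    )
    def test_threshold_table(self, n_p1, n_p2, expected):
        assert call_genotype(n_p1, n_p2) == expected

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            call_genotype(-1, 10)

    def test_parental_fraction_rule(self):
        # 12 parental reads of 20 total: below the 2/3 parental-read minimum
        assert call_genotype(6, 6, n_other=8) == NO_CALL
        # 16 of 20 parental reads passes
        assert call_genotype(8, 8, n_other=4) == HET

    def test_exactly_one_label_fires_on_grid(self):
        """Brute-force: every depth combination maps to exactly one label."""
        t = DEFAULT_THRESHOLDS
        for n1, n2 in itertools.product(range(0, 61, 3), repeat=2):
            call = call_genotype(n1, n2)
            total = n1 + n2
            if total <= t.min_depth_exclusive:
                assert call == NO_CALL
                continue
            f1 = n1 / total
            labels = []
            if f1 > t.p1_hom_min:
                labels.append(HOM_P1)
            if (1 - f1) > t.p2_hom_min:
                labels.append(HOM_P2)
            if (
                t.het_p1_range[0] <= f1 <= t.het_p1_range[1]
                and t.het_p2_range[0] <= 1 - f1 <= t.het_p2_range[1]
            ):
                labels.append(HET)
            assert len(labels) == 1, (n1, n2, labels)
            assert call == labels[0]

    def test_vectorised_matches_scalar(self):
        rng = np.random.default_rng(0)
        n1 = rng.integers(0, 80, size=200)
        n2 = rng.integers(0, 80, size=200)
        vec = call_genotypes(n1, n2)
        assert all(vec[i] == call_genotype(int(n1[i]), int(n2[i])) for i in range(200))

    def test_threshold_validation(self):
        with pytest.raises(ValueError):
            GenotypingThresholds(p1_hom_min=0.5, p2_hom_min=0.75)


class TestFilterShortRuns:
    def test_single_marker_island_removed(self):
        calls = np.array([HET, HOM_P2, HET], dtype=np.int8)
        out, log = filter_short_runs(calls, 3)
        assert list(out) == [HET, HET, HET]
        assert len(log) == 1 and log[0]["n_markers"] == 1

    def test_run_of_three_retained(self):
        calls = np.array([HET, HOM_P2, HOM_P2, HOM_P2, HET], dtype=np.int8)
        out, log = filter_short_runs(calls, 3)
        assert np.array_equal(out, calls)
        assert log == []

    def test_all_het_identity(self):
        calls = np.full(10, HET, dtype=np.int8)
        out, _ = filter_short_runs(calls, 3)
        assert np.array_equal(out, calls)

    def test_no_call_markers_are_transparent(self):
        # two HOM_P2 calls separated by NO_CALL form one run of two -> removed
        calls = np.array([HET, HOM_P2, NO_CALL, HOM_P2, HET], dtype=np.int8)
        out, _ = filter_short_runs(calls, 3)
        assert list(out) == [HET, HET, NO_CALL, HET, HET]
        # three HOM_P2 calls spanning a NO_CALL survive
        calls = np.array([HET, HOM_P2, NO_CALL, HOM_P2, HOM_P2, HET], dtype=np.int8)
        out, _ = filter_short_runs(calls, 3)
        assert list(out) == [HET, HOM_P2, NO_CALL, HOM_P2, HOM_P2, HET]

    def test_short_run_at_chromosome_end_removed(self):
        calls = np.array([HOM_P1, HOM_P1, HET, HET, HET], dtype=np.int8)
        out, _ = filter_short_runs(calls, 3)
        assert list(out) == [HET] * 5

    def test_hom_context_is_not_het_context(self):
        # a short P1 run flanked by P2 on one side is kept (asymmetric rule)
        calls = np.array(
            [HOM_P2, HOM_P2, HOM_P2, HOM_P1, HET, HET, HET], dtype=np.int8
        )
        out, _ = filter_short_runs(calls, 3)
        assert np.array_equal(out, calls)

    def test_symmetric_option_fills_het_islands(self):
        calls = np.array([HOM_P2] * 3 + [HET] + [HOM_P2] * 3, dtype=np.int8)
        out, _ = filter_short_runs(calls, 3, symmetric=True)
        assert list(out) == [HOM_P2] * 7
        out_default, _ = filter_short_runs(calls, 3)
        assert np.array_equal(out_default, calls)

    @given(
        st.lists(
            st.sampled_from([NO_CALL, HOM_P1, HET, HOM_P2]), min_size=0, max_size=40
        ),
        st.integers(min_value=1, max_value=5),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_idempotent_and_never_creates_hom_runs(self, calls, min_run):
        calls = np.array(calls, dtype=np.int8)
        out1, _ = filter_short_runs(calls, min_run)
        out2, _ = filter_short_runs(out1, min_run)
        assert np.array_equal(out1, out2)
        # reassignment only ever turns homozygous calls into HET
        changed = out1 != calls
        assert np.all(np.isin(calls[changed], [HOM_P1, HOM_P2]))
        assert np.all(out1[changed] == HET)


class TestMarkerQc:
    def test_all_genotype_combinations(self):
        """Exactly the (P1-hom, P2-hom, het) triple is retained."""
        codes = [NO_CALL, HOM_P1, HET, HOM_P2]
        for p1, p2, hyb in itertools.product(codes, repeat=3):
            keep, reasons = qc_marker_set(
                np.array([p1], dtype=np.int8),
                np.array([p2], dtype=np.int8),
                np.array([hyb], dtype=np.int8),
            )
            expected = p1 == HOM_P1 and p2 == HOM_P2 and hyb == HET
            assert keep[0] == expected

    def test_reason_codes(self):
        p1 = np.array([HOM_P1, HOM_P1, HOM_P1], dtype=np.int8)
        p2 = np.array([HOM_P2, HOM_P1, HOM_P2], dtype=np.int8)
        hyb = np.array([HET, HET, HOM_P1], dtype=np.int8)
        keep, reasons = qc_marker_set(p1, p2, hyb)
        assert list(keep) == [True, False, False]
        assert reasons[1] == "shared_allele"
        assert reasons[2] == "hybrid_not_het"

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            qc_marker_set(np.zeros(3, np.int8), np.zeros(2, np.int8), np.zeros(3, np.int8))


class TestCoverageWindows:
    @staticmethod
    def _track(depths_by_chrom, window=10_000):
        rows = []
        for chrom, depths in depths_by_chrom.items():
            for w, d in enumerate(depths):
                for p in range(0, window, 2500):
                    rows.append({"chrom": chrom, "pos": w * window + p + 1, "depth": d})
        return pd.DataFrame(rows)

    def test_uniform_depth_unflagged(self):
        win = coverage_windows(self._track({"chr1": [30] * 8}))
        assert np.allclose(win["ratio"], 1.0)
        assert not win["flagged"].any()

    def test_half_depth_deletion_flagged(self):
        win = coverage_windows(self._track({"chr1": [30] * 8, "chr2": [15] * 2}))
        chr2 = win[win["chrom"] == "chr2"]
        assert np.allclose(chr2["ratio"], 0.5)
        assert chr2["flagged"].all()

    def test_duplication_flagged(self):
        win = coverage_windows(self._track({"chr1": [30] * 8 + [45] * 2}))
        assert win["flagged"].sum() == 2
        assert np.allclose(win.loc[win["flagged"], "ratio"], 1.5)

    def test_empty_track_rejected(self):
        with pytest.raises(ValueError):
            coverage_windows(pd.DataFrame(columns=["chrom", "pos", "depth"]))

    def test_marker_mask(self, toy_map):
        win = coverage_windows(self._track({"chrT": [30, 15, 30]}, window=5_000), window=5_000)
        mask = cnv_marker_mask(win, toy_map)
        # the half-depth window (5001-10000) is flagged; markers 6500..9500 fall in it
        assert list(np.flatnonzero(mask)) == [5, 6, 7, 8]


def test_genotype_matrix_round_trip(toy_map):
    rng = np.random.default_rng(3)
    calls = {
        "s1": rng.choice([NO_CALL, HOM_P1, HET, HOM_P2], 10).astype(np.int8),
        "s2": rng.choice([NO_CALL, HOM_P1, HET, HOM_P2], 10).astype(np.int8),
    }
    frame = genotypes_to_frame(toy_map, calls)
    back = frame_to_genotypes(frame)
    assert set(back) == {"s1", "s2"}
    for k in calls:
        assert np.array_equal(back[k], calls[k])
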