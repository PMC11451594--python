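"""Interval filters, reference scaling, and Ward clustering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from nucleomech import SimConfig
from nucleomech.genomics import (
    PeakTable,
    classify_tss,
    exclude_blacklist,
    merge_within,
    reproducibility_filter,
    scale_and_log,
    size_signal_filter,
    ward_cluster,
)
from nucleomech.simulate import OccupancyTruth, gen_peak_table


def small_table(intervals, signal=None, called=None, conditions=("a", "b"),
                n_rep=2):
    iv = pd.DataFrame(intervals, columns=["chrom", "start", "end", "name"])
    samples = [f"{c}_r{r+1}" for c in conditions for r in range(n_rep)]
    meta = pd.DataFrame(
        {"condition": [c for c in conditions for _ in range(n_rep)],
         "replicate": [r + 1 for _ in conditions for r in range(n_rep)]},
        index=pd.Index(samples, name="sample"))
    names = pd.Index(iv["name"], name="name")
    if signal is None:
        signal = pd.DataFrame(1.0, index=names, columns=samples)
    else:
        signal = pd.DataFrame(signal, index=names, columns=samples)
    if called is not None:
        called = pd.DataFrame(called, index=names, columns=samples)
    return PeakTable(iv, signal, meta, called)


class TestMergeWithin:
    def test_exact_gap_boundary_not_merged(self):
        t = small_table([("chr1", 0, 100, "p1"), ("chr1", 1100, 1200, "p2")])
        out = merge_within(t, gap=1000)
        assert len(out.intervals) == 2

    def test_transitive_merge(self):
        t = small_table([("chr1", 0, 100, "p1"), ("chr1", 1050, 1200, "p2"),
                         ("chr1", 1300, 1400, "p3")])
        out = merge_within(t, gap=1000)
        assert len(out.intervals) == 1
        row = out.intervals.iloc[0]
        assert (row["start"], row["end"]) == (0, 1400)

    def test_single_interval_unchanged(self):
        t = small_table([("chr1", 5, 50, "p1")])
        out = merge_within(t)
        assert out.intervals[["chrom", "start", "end"]].equals(
            t.intervals[["chrom", "start", "end"]])

    def test_merged_signal_is_length_weighted_mean(self):
        sig = np.array([[1.0, 1.0, 1.0, 1.0], [4.0, 4.0, 4.0, 4.0]])
        t = small_table([("chr1", 0, 100, "p1"), ("chr1", 150, 550, "p2")],
                        signal=sig)
        out = merge_within(t, gap=1000)
        # widths 100 and 400: weighted mean = (1*100 + 4*400)/500 = 3.4
        assert np.allclose(out.signal.iloc[0], 3.4)

    @given(st.lists(st.tuples(st.integers(0, 5000), st.integers(1, 400)),
                    min_size=1, max_size=20))
    def test_idempotent(self, raw):
        iv = [("chr1", s, s + w, f"p{i}") for i, (s, w) in enumerate(raw)]
        # drop overlapping intervals to respect the non-overlap contract
        iv.sort(key=lambda r: r[1])
        kept, last_end = [], -1
        for r in iv:
            if r[1] >= last_end:
                kept.append(r)
                last_end = r[2]
        t = small_table(kept)
        once = merge_within(t, gap=500)
        twice = merge_within(once, gap=500)
        assert once.intervals[["chrom", "start", "end"]].equals(
            twice.intervals[["chrom", "start", "end"]])


class TestBlacklist:
    def test_no_overlap_identity(self):
        t = small_table([("chr1", 0, 100, "p1"), ("chr2", 0, 100, "p2")])
        bl = pd.DataFrame({"chrom": ["chr1"], "start": [500], "end": [600]})
        assert len(exclude_blacklist(t, bl).intervals) == 2

    def test_one_bp_overlap_removed(self):
        t = small_table([("chr1", 0, 100, "p1")])
        bl = pd.DataFrame({"chrom": ["chr1"], "start": [99], "end": [200]})
        assert len(exclude_blacklist(t, bl).intervals) == 0

    def test_peak_containing_blacklist_removed(self):
        t = small_table([("chr1", 0, 1000, "p1")])
        bl = pd.DataFrame({"chrom": ["chr1"], "start": [400], "end": [410]})
        assert len(exclude_blacklist(t, bl).intervals) == 0

    def test_output_never_overlaps_blacklist(self):
        truth = OccupancyTruth(condition_means=[[1.0, 0.5]])
        table = gen_peak_table(SimConfig(seed=8), 100, ["a", "b"], 2, truth)
        rng = np.random.default_rng(0)
        starts = rng.integers(0, 9_000_000, 30)
        bl = pd.DataFrame({"chrom": "chr1", "start": starts,
                           "end": starts + 2000})
        out = exclude_blacklist(table, bl)
        for p in out.intervals.itertuples():
            overlap = (bl["start"] < p.end) & (p.start < bl["end"])
            assert not overlap.any()


class TestReproducibility:
    def test_two_of_two_same_condition_kept(self):
        t = small_table([("chr1", 0, 100, "p1")],
                        called=[[True, True, False, False]])
        assert len(reproducibility_filter(t, 2).intervals) == 1

    def test_split_across_conditions_dropped(self):
        t = small_table([("chr1", 0, 100, "p1")],
                        called=[[True, False, True, False]])
        assert len(reproducibility_filter(t, 2, "same_condition").intervals) == 0
        assert len(reproducibility_filter(t, 2, "any").intervals) == 1

    def test_min_one_is_identity(self):
        t = small_table([("chr1", 0, 100, "p1"), ("chr1", 500, 700, "p2")],
                        called=[[True, False, False, False]] * 2)
        assert len(reproducibility_filter(t, 1).intervals) == 2

    def test_min_above_sample_count_rejected(self):
        t = small_table([("chr1", 0, 100, "p1")],
                        called=[[True, True, True, True]])
        with pytest.raises(ValueError):
            reproducibility_filter(t, 5)


class TestSizeSignal:
    def test_exact_width_boundary_dropped(self):
        t = small_table([("chr1", 0, 1000, "p1"), ("chr1", 5000, 6001, "p2")])
        out = size_signal_filter(t, min_size=1000, min_mean_signal=0.5)
        assert list(out.intervals["name"]) == ["p2"]

    def test_exact_signal_boundary_dropped(self):
        sig = np.array([[0.075, 0.075, 0.05, 0.05],
                        [0.076, 0.076, 0.05, 0.05]])
        t = small_table([("chr1", 0, 2000, "p1"), ("chr1", 5000, 7000, "p2")],
                        signal=sig)
        out = size_signal_filter(t)
        assert list(out.intervals["name"]) == ["p2"]

    def test_planted_violations_match_brute_force(self):
        truth = OccupancyTruth(
            condition_means=np.array([[1.0, 0.3], [0.3, 1.0]]),
            replicate_cv=0.15)
        table = gen_peak_table(SimConfig(seed=9), 400, ["a", "b"], 3, truth,
                               frac_short=0.15, frac_weak=0.15,
                               frac_nonreproducible=0.15)
        out = size_signal_filter(reproducibility_filter(table, 2), 1000, 0.075)
        survivors = set(out.intervals["name"])
        # brute-force enumeration over every peak
        expected = set()
        meta = table.sample_meta
        for row in table.intervals.itertuples():
            width_ok = (row.end - row.start) > 1000
            sig_ok = False
            rep_ok = False
            for cond in ("a", "b"):
                cols = meta.index[meta["condition"] == cond]
                if table.signal.loc[row.name, cols].mean() > 0.075:
                    sig_ok = True
                if table.called_in.loc[row.name, cols].sum() >= 2:
                    rep_ok = True
            if width_ok and sig_ok and rep_ok:
                expected.add(row.name)
        assert survivors == expected

    def test_filters_commute(self):
        truth = OccupancyTruth(condition_means=[[1.0, 0.3]],
                               replicate_cv=0.2)
        table = gen_peak_table(SimConfig(seed=10), 200, ["a", "b"], 2, truth,
                               frac_short=0.2, frac_nonreproducible=0.2)
        a = size_signal_filter(reproducibility_filter(table))
        b = reproducibility_filter(size_signal_filter(table))
        assert set(a.intervals["name"]) == set(b.intervals["name"])


class TestClassifyTSS:
    TSS = pd.DataFrame({"chrom": ["chr1", "chr1"],
                        "position": [1500, 10000],
                        "gene": ["G1", "G2"]})

    def test_window_overlap_is_promoter(self):
        iv = pd.DataFrame([("chr1", 500, 900, "p1")],
                          columns=["chrom", "start", "end", "name"])
        out = classify_tss(iv, self.TSS, window=1000)
        assert out.loc[0, "class"] == "promoter"

    def test_distal_peak_is_enhancer_with_nearest_gene(self):
        iv = pd.DataFrame([("chr1", 5000, 5100, "p1")],
                          columns=["chrom", "start", "end", "name"])
        out = classify_tss(iv, self.TSS, window=1000)
        assert out.loc[0, "class"] == "enhancer"
        assert out.loc[0, "nearest_gene"] == "G1"

    def test_nearest_gene_tie_lexicographic(self):
        tss = pd.DataFrame({"chrom": ["chr1", "chr1"],
                            "position": [0, 10000],
                            "gene": ["Gb", "Ga"]})
        iv = pd.DataFrame([("chr1", 4500, 5501, "p1")],
                          columns=["chrom", "start", "end", "name"])
        out = classify_tss(iv, tss, window=1000)
        # equidistant: distance 4500 to Gb, 10000-5501+1=4500 to Ga
        assert out.loc[0, "nearest_gene"] == "Ga"

    def test_empty_tss_rejected(self):
        iv = pd.DataFrame([("chr1", 0, 10, "p1")],
                          columns=["chrom", "start", "end", "name"])
        with pytest.raises(ValueError):
            classify_tss(iv, self.TSS.iloc[:0])


class TestScaleAndLog:
    def test_equal_conditions_all_zero(self):
        t = small_table([("chr1", 0, 100, "p1"), ("chr1", 500, 900, "p2")])
        mat = scale_and_log(t, "a")
        assert np.allclose(mat.values.to_numpy(), 0.0)

    def test_log2_closed_forms(self):
        sig = np.array([[1.0, 1.0, 2.0, 2.0], [1.0, 1.0, 0.25, 0.25]])
        t = small_table([("chr1", 0, 100, "p1"), ("chr1", 500, 900, "p2")],
                        signal=sig)
        mat = scale_and_log(t, "a")
        assert mat.values.loc["p1", "b"] == pytest.approx(1.0)
        assert mat.values.loc["p2", "b"] == pytest.approx(-2.0)
        assert np.allclose(mat.values["a"], 0.0)

    def test_zero_reference_dropped_with_count(self):
        sig = np.array([[0.0, 0.0, 2.0, 2.0], [1.0, 1.0, 0.5, 0.5]])
        t = small_table([("chr1", 0, 100, "p1"), ("chr1", 500, 900, "p2")],
                        signal=sig)
        mat = scale_and_log(t, "a")
        assert mat.n_dropped == 1
        assert list(mat.values.index) == ["p2"]

    def test_bijective_off_dropped_set(self):
        truth = OccupancyTruth(condition_means=[[1.0, 0.4]],
                               replicate_cv=0.1)
        table = gen_peak_table(SimConfig(seed=11), 50, ["a", "b"], 2, truth)
        means = table.condition_means()
        mat = scale_and_log(table, "a")
        recovered = (2.0 ** mat.values).mul(means["a"], axis=0)
        assert np.allclose(recovered.to_numpy(), means.to_numpy())


class TestWardCluster:
    def test_identical_rows_single_cluster(self):
        vals = pd.DataFrame([[1.0, 2.0], [1.0, 2.0]], index=["p1", "p2"])
        from nucleomech.genomics import ConditionMatrix

        res = ward_cluster(ConditionMatrix(vals, "a"), cutoff=0.1)
        assert res.linkage[0, 2] == 0.0
        assert res.assignment.max() == 1

    def test_cutoff_above_root_single_cluster(self):
        from nucleomech.genomics import ConditionMatrix

        rng = np.random.default_rng(1)
        vals = pd.DataFrame(rng.normal(size=(20, 3)))
        res = ward_cluster(ConditionMatrix(vals, "a"), cutoff=1e9)
        assert res.assignment.max() == 1

    def test_planted_clusters_recovered(self):
        from sklearn.metrics import adjusted_rand_score

        truth = OccupancyTruth(
            condition_means=np.array([[1.0, 0.25, 0.25],
                                      [0.25, 1.0, 0.25],
                                      [0.25, 0.25, 1.0]]),
            replicate_cv=0.1)
        table = gen_peak_table(SimConfig(seed=12), 300, ["a", "b", "c"], 2,
                               truth)
        mat = scale_and_log(table, "a")
        res = ward_cluster(mat, cutoff=7.0)
        ari = adjusted_rand_score(truth.flags.loc[mat.values.index, "cluster"],
                                  res.assignment)
        assert ari > 0.95

    def test_non_finite_rejected(self):
        from nucleomech.genomics import ConditionMatrix

        vals = pd.DataFrame([[0.0, np.nan], [1.0, 2.0]])
        with pytest.raises(ValueError):
            ward_cluster(ConditionMatrix(vals, "a"))
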