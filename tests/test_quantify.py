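import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import sdpmark as sm
from sdpmark.quantify import UNASSIGNED, percent_identity


def sheet2():
    return [
        sm.SampleSheet("s1", "AAAAAA", "TTTTTT"),
        sm.SampleSheet("s2", "CCCCCC", "GGGGGG"),
    ]


class TestDemultiplex:
    def test_forward_barcode_assignment_and_trim(self):
        batch = sm.ReadBatch([("r1", "AAAAAA" + "ACGTACGT")])
        out, un = sm.demultiplex(batch, sheet2())
        assert un == 0
        assert out["s1"].reads == [("r1", "ACGTACGT")]

    def test_reverse_barcode_reverse_complements(self):
        batch = sm.ReadBatch([("r1", "TTTTTT" + sm.revcomp("ACGTTGCA"))])
        out, _ = sm.demultiplex(batch, sheet2())
        assert out["s1"].reads == [("r1", "ACGTTGCA")]

    def test_unmatched_reads_counted(self):
        batch = sm.ReadBatch([("r1", "GTGTGT" + "ACGT")])
        out, un = sm.demultiplex(batch, sheet2())
        assert un == 1
        assert all(len(b) == 0 for b in out.values())

    def test_barcode_collision_rejected(self):
        bad = [
            sm.SampleSheet("s1", "AAAAAA", "TTTTTT"),
            sm.SampleSheet("s2", "AAAAAA", "GGGGGG"),
        ]
        with pytest.raises(ValueError, match="collides"):
            sm.demultiplex(sm.ReadBatch([("r", "AAAAAAA")]), bad)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_conservation_law(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 60))
        reads = [
            (f"r{i}", "".join(rng.choice(list("ACGT"), 7 + int(rng.integers(0, 12)))))
            for i in range(n)
        ]
        out, un = sm.demultiplex(sm.ReadBatch(reads), sheet2())
        assert sum(len(b) for b in out.values()) + un == n


class TestDereplicate:
    def test_counts_are_multiplicities(self):
        reads = [(f"r{i}", "AAAA") for i in range(5)] + [
            (f"q{i}", "CCCC") for i in range(3)
        ]
        ft = sm.dereplicate(sm.ReadBatch(reads))
        assert sorted(ft.counts.iloc[0].tolist(), reverse=True) == [5, 3]
        assert ft.sequences[ft.feature_ids[0]] == "AAAA"  # abundance-sorted

    def test_all_distinct(self):
        reads = [("r1", "AAAA"), ("r2", "CCCC"), ("r3", "GGGG")]
        ft = sm.dereplicate(sm.ReadBatch(reads))
        assert len(ft.feature_ids) == 3
        assert set(ft.counts.iloc[0]) == {1}

    def test_empty_batch(self):
        ft = sm.dereplicate(sm.ReadBatch([]))
        assert ft.feature_ids == []

    def test_abundance_tie_broken_lexicographically(self):
        reads = [("r1", "TTTT"), ("r2", "AAAA")]
        ft = sm.dereplicate(sm.ReadBatch(reads))
        assert ft.sequences[ft.feature_ids[0]] == "AAAA"


def feature_table(seqs_counts, sample="s"):
    counts = pd.DataFrame(
        {f"F{i:06d}": [c] for i, (_, c) in enumerate(seqs_counts, 1)},
        index=[sample],
    )
    seqs = {f"F{i:06d}": s for i, (s, _) in enumerate(seqs_counts, 1)}
    return sm.FeatureTable(counts, seqs)


class TestClassify:
    REF = "ACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGT"  # 52 nt

    def refs(self):
        other = "TGCA" * 13
        return [
            sm.GeneRecord("a", self.REF, sdp="SDP_1"),
            sm.GeneRecord("b", other, sdp="SDP_2"),
        ]

    def test_identical_sequence_assigned(self):
        ft = feature_table([(self.REF, 10)])
        assert sm.classify(ft, self.refs()) == {"F000001": "SDP_1"}

    def test_below_threshold_unassigned(self):
        query = self.REF[:40] + "TTTTTTTTTTTT"  # ~77% identity
        ft = feature_table([(query, 10)])
        assert sm.classify(ft, self.refs()) == {"F000001": UNASSIGNED}

    def test_equal_best_conflicting_hits_unassigned(self):
        refs = [
            sm.GeneRecord("a", self.REF, sdp="SDP_1"),
            sm.GeneRecord("b", self.REF, sdp="SDP_2"),
        ]
        ft = feature_table([(self.REF, 10)])
        assert sm.classify(ft, refs) == {"F000001": UNASSIGNED}

    def test_reference_order_invariant(self):
        ft = feature_table([(self.REF, 10)])
        fwd = sm.classify(ft, self.refs())
        rev = sm.classify(ft, list(reversed(self.refs())))
        assert fwd == rev

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            sm.classify(feature_table([(self.REF, 1)]), [])

    def test_one_mismatch_in_52_still_assigned(self):
        query = "T" + self.REF[1:]
        ft = feature_table([(query, 10)])
        assert sm.classify(ft, self.refs()) == {"F000001": "SDP_1"}


class TestPercentIdentity:
    def test_identical(self):
        assert percent_identity("ACGTACGT", "ACGTACGT") == 1.0

    def test_one_substitution(self):
        assert percent_identity("ACGTACGT", "ACGTACGA") == pytest.approx(7 / 8)

    def test_terminal_gaps_excluded(self):
        # query is an internal fragment: terminal gaps must not count
        assert percent_identity("GTAC", "ACGTACGT") == 1.0


class TestAbundance:
    def test_ra_formula(self):
        ft = feature_table([("AAAA", 50), ("CCCC", 150)])
        tab = sm.abundance(ft, {"F000001": "S1", "F000002": "S2"})
        assert tab.relative.at["s", "S1"] == pytest.approx(25.0)
        assert tab.relative.at["s", "S2"] == pytest.approx(75.0)
        assert tab.counts.at["s", "S1"] == 50

    def test_single_sdp_is_100(self):
        ft = feature_table([("AAAA", 7)])
        tab = sm.abundance(ft, {"F000001": "S1"})
        assert tab.relative.at["s", "S1"] == 100.0

    def test_unassigned_excluded_from_denominator(self):
        ft = feature_table([("AAAA", 50), ("CCCC", 50)])
        tab = sm.abundance(ft, {"F000001": "S1", "F000002": UNASSIGNED})
        assert tab.relative.at["s", "S1"] == 100.0
        assert tab.n_unassigned["s"] == 50

    def test_zero_assigned_flagged_not_propagated(self):
        ft = feature_table([("AAAA", 50)])
        tab = sm.abundance(ft, {"F000001": UNASSIGNED})
        assert tab.empty_samples == ["s"]

    def test_rows_sum_to_100(self):
        rng = np.random.default_rng(0)
        ft = feature_table([("AAAA", 11), ("CCCC", 23), ("GGGG", 5)])
        tab = sm.abundance(ft, {"F000001": "S1", "F000002": "S2", "F000003": "S3"})
        assert tab.relative.loc["s"].sum() == pytest.approx(100.0, abs=1e-9)


class TestFilterLowAbundance:
    def table(self):
        counts = pd.DataFrame(
            {"F000001": [99, 500], "F000002": [100, 0], "F000003": [3, 7]},
            index=["s1", "s2"],
        )
        return sm.FeatureTable(counts, {f: "ACGT" for f in counts.columns})

    def test_below_100_zeroed_per_sample(self):
        out = sm.filter_low_abundance(self.table())
        assert out.counts.at["s1", "F000001"] == 0
        assert out.counts.at["s2", "F000001"] == 500

    def test_exactly_100_retained(self):
        out = sm.filter_low_abundance(self.table())
        assert out.counts.at["s1", "F000002"] == 100

    def test_everywhere_empty_features_dropped(self):
        out = sm.filter_low_abundance(self.table())
        assert "F000003" not in out.counts.columns

    def test_min_count_zero_is_identity(self):
        out = sm.filter_low_abundance(self.table(), min_count=0)
        pd.testing.assert_frame_equal(out.counts, self.table().counts)


class TestClusterOtus:
    def seq(self, n_diff, L=100):
        # isolated substitutions (A->T at positions 0, 4, 8, ...) so the edit
        # distance is exactly n_diff and cannot be shortcut by indels
        base = list(("ACGT" * 25)[:L])
        for i in range(n_diff):
            base[4 * i] = "T"
        return "".join(base)

    def test_pair_98pct_merges_at_97(self):
        ft = feature_table([(self.seq(0), 10), (self.seq(2), 5)])
        out = sm.cluster_otus(ft, identity=0.97)
        assert len(out.feature_ids) == 1
        assert out.counts.iloc[0, 0] == 15

    def test_same_pair_splits_at_99(self):
        ft = feature_table([(self.seq(0), 10), (self.seq(2), 5)])
        out = sm.cluster_otus(ft, identity=0.99)
        assert len(out.feature_ids) == 2

    def test_greedy_chain_follows_abundance_order(self):
        # A (most abundant) ~ B at 98%, B ~ C at 98%, A ~ C at 96%:
        # greedy puts B with A, then C matches neither centroid A (96%) -> own OTU
        a = self.seq(0)
        b = self.seq(2)
        c = self.seq(4)
        ft = feature_table([(a, 10), (b, 5), (c, 2)])
        out = sm.cluster_otus(ft, identity=0.97)
        assert len(out.feature_ids) == 2
        assert sorted(out.counts.iloc[0].tolist(), reverse=True) == [15, 2]


class TestRarefyDetection:
    def test_sole_sdp_always_detected(self):
        res = sm.rarefy_detection({"S1": 500}, depths=[1, 10, 100], reps=50, seed=0)
        assert all(p == 1.0 for p in res.detection_prob.values())

    def test_full_depth_without_replacement_is_deterministic(self):
        counts = {"S1": 90, "S2": 10}
        res = sm.rarefy_detection(counts, depths=[100], reps=20, seed=1)
        assert res.detection_prob[("S2", 100)] == 1.0

    def test_with_replacement_matches_binomial_closed_form(self):
        # 1% member, depth 300: P(detect) = 1 - 0.99^300 ~ 0.951
        counts = {"rare": 100, "common": 9900}
        reps = 1000
        res = sm.rarefy_detection(
            counts, depths=[300], reps=reps, seed=5, with_replacement=True
        )
        expect = 1 - 0.99**300
        se = np.sqrt(expect * (1 - expect) / reps)
        assert abs(res.detection_prob[("rare", 300)] - expect) <= 3 * se

    def test_seed_reproducibility(self):
        counts = {"S1": 50, "S2": 950}
        a = sm.rarefy_detection(counts, [20, 40], reps=30, seed=9)
        b = sm.rarefy_detection(counts, [20, 40], reps=30, seed=9)
        assert a.detection_prob == b.detection_prob


class TestMinReadsForDetection:
    def test_always_detected_gives_smallest_depth(self):
        res = sm.rarefy_detection({"S1": 100}, depths=[50, 10, 80], reps=10, seed=0)
        assert sm.min_reads_for_detection(res) == {"S1": 10}

    def test_target_zero_gives_smallest_depth(self):
        res = sm.rarefy_detection({"S1": 10, "S2": 990}, [5, 50], reps=10, seed=0)
        assert sm.min_reads_for_detection(res, target_prob=0.0) == {"S1": 5, "S2": 5}

    def test_closed_form_crossing_near_299(self):
        # analytic minimum for f=1%, >=1 read, 95%: ceil(ln .05 / ln .99) = 299
        counts = {"rare": 10_000, "common": 990_000}
        depths = list(range(280, 321))
        res = sm.rarefy_detection(
            counts, depths, reps=1000, seed=3, with_replacement=True
        )
        got = sm.min_reads_for_detection(res, 0.95)["rare"]
        assert got is not None and abs(got - 299) <= 10  # Monte-Carlo wiggle near the crossing

    def test_monotone_in_target_prob(self):
        counts = {"rare": 100, "common": 9900}
        res = sm.rarefy_detection(counts, list(range(50, 500, 50)), reps=400, seed=2,
                                  with_replacement=True)
        d_low = sm.min_reads_for_detection(res, 0.5)["rare"]
        d_high = sm.min_reads_for_detection(res, 0.95)["rare"]
        assert d_low <= d_high


class TestIcc:
    def test_identical_replicates_distinct_subjects(self):
        x = np.array([[1.0, 1.0], [2.0, 2.0], [5.0, 5.0]])
        assert sm.icc_c1(x).icc_c1 == pytest.approx(1.0)

    def test_consistency_with_rater_offsets_is_one(self):
        x = np.array([[1, 2, 3], [2, 3, 4], [3, 4, 5]], float)
        res = sm.icc_c1(x)
        assert res.icc_c1 == pytest.approx(1.0, abs=1e-12)
        assert res.ms_error == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_anova(self):
        # 3 subjects x 2 raters; mean squares computed by hand:
        # rows means (1.5, 3.5, 3.0), grand 8/3 -> SS_rows = 2*(...)=4.334
        x = np.array([[1.0, 2.0], [3.0, 4.0], [4.0, 2.0]])
        n, k = 3, 2
        grand = x.mean()
        ms_bs = k * ((x.mean(1) - grand) ** 2).sum() / (n - 1)
        ms_e = (
            ((x - grand) ** 2).sum()
            - k * ((x.mean(1) - grand) ** 2).sum()
            - n * ((x.mean(0) - grand) ** 2).sum()
        ) / ((n - 1) * (k - 1))
        expect = (ms_bs - ms_e) / (ms_bs + (k - 1) * ms_e)
        assert sm.icc_c1(x).icc_c1 == pytest.approx(expect, abs=1e-12)

    def test_all_equal_is_nan(self):
        res = sm.icc_c1(np.full((3, 3), 2.0))
        assert np.isnan(res.icc_c1)

    def test_small_matrices_rejected(self):
        with pytest.raises(ValueError):
            sm.icc_c1(np.array([[1.0, 2.0]]))

    def test_matches_pingouin_icc3(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(12)
        x = rng.normal(size=(8, 3)) + rng.normal(size=(8, 1)) * 2
        df = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(8), 3),
                "rater": np.tile(np.arange(3), 8),
                "score": x.ravel(),
            }
        )
        ref = pingouin.intraclass_corr(
            data=df, targets="subject", raters="rater", ratings="score"
        )
        mask = ref["Type"].isin(["ICC(C,1)", "ICC3"])
        icc3 = float(ref.loc[mask, "ICC"].iloc[0])
        assert sm.icc_c1(x).icc_c1 == pytest.approx(icc3, abs=1e-10)


class TestDiversity:
    def test_uniform_shannon(self):
        assert sm.shannon_diversity([0.2] * 5) == pytest.approx(np.log(5))

    def test_zeros_ignored(self):
        assert sm.shannon_diversity([0.5, 0.5, 0.0]) == pytest.approx(np.log(2))

    def test_bray_curtis_extremes(self):
        # identical samples -> 0; disjoint supports -> 1
        identical = pd.DataFrame([[10, 5], [10, 5]], index=["a", "b"])
        assert sm.bray_curtis(identical).at["a", "b"] == pytest.approx(0.0)
        disjoint = pd.DataFrame([[10, 0], [0, 4]], index=["a", "b"])
        assert sm.bray_curtis(disjoint).at["a", "b"] == pytest.approx(1.0)

    def test_two_point_pcoa_separation(self):
        d = 0.6
        dissim = pd.DataFrame([[0, d], [d, 0]], index=["a", "b"], columns=["a", "b"])
        coords, eig = sm.pcoa(dissim, n_axes=1)
        sep = abs(coords.iloc[0, 0] - coords.iloc[1, 0])
        assert sep == pytest.approx(d, abs=1e-9)
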