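"""Usage tables, combinations, rarefaction, convergence, assignment rates."""

import numpy as np
import pandas as pd
import pytest

from finrep.stats import (
    ConvergenceSummary,
    assignment_rates,
    convergence_counts,
    expected_distinct,
    junction_distributions,
    rarefaction,
    round_half_up,
    summarize_across_individuals,
    truncate_rate,
    usage_frequencies,
    vdj_combinations,
)


def frame(rows, **defaults):
    base = {
        "read_id": "r", "isotype": "IgM", "v_id": None, "d_id": None,
        "j_id": None, "cdr3_nt": None, "cdr3_aa": None,
        "cdr3_aa_length": None, "productive": False, "v3_del": None,
        "d5_del": None, "d3_del": None, "j5_del": None, "vd_ins": None,
        "dj_ins": None, "vj_ins": None,
    }
    out = []
    for i, r in enumerate(rows):
        d = dict(base, **defaults, **r)
        d["read_id"] = f"r{i}"
        out.append(d)
    return pd.DataFrame(out)


class TestUsageFrequencies:
    def test_point_mass_on_single_segment(self, small_germline):
        vid = small_germline.v_segments[0].id
        df = frame([{"v_id": vid}] * 100)
        table = usage_frequencies(df, small_germline, "V")
        assert table.loc[table.segment_id == vid, "frequency"].item() == 1.0
        assert table["count"].sum() == 100
        assert (table.frequency >= 0).all()
        assert table.frequency.sum() == pytest.approx(1.0, abs=1e-9)

    def test_zero_count_segments_included(self, small_germline):
        df = frame([{"v_id": small_germline.v_segments[0].id}])
        table = usage_frequencies(df, small_germline, "V")
        assert len(table) == len(small_germline.v_segments)

    def test_empty_input_flagged(self, small_germline):
        table = usage_frequencies(frame([]), small_germline, "V")
        assert table.attrs["empty_input"]
        assert (table["count"] == 0).all()
        assert (table["frequency"] == 0).all()

    def test_unknown_segment_id_rejected(self, small_germline):
        with pytest.raises(ValueError, match="V99"):
            usage_frequencies(frame([{"v_id": "V99.9"}]), small_germline, "V")

    def test_d_frequencies_over_identified_reads_only(self, small_germline):
        did = small_germline.d_segments[0].id
        df = frame([{"d_id": did}, {"d_id": "AMBIGUOUS"}, {"d_id": None}])
        table = usage_frequencies(df, small_germline, "D")
        assert table["count"].sum() == 1
        assert table.loc[table.segment_id == did, "frequency"].item() == 1.0

    def test_simulated_usage_within_sampling_error(self, small_germline):
        rng = np.random.default_rng(3)
        weights = np.array([0.5, 0.3, 0.2])
        ids = [s.id for s in small_germline.v_segments[:3]]
        n = 50_000
        picks = rng.choice(ids, size=n, p=weights)
        table = usage_frequencies(
            frame([{"v_id": v} for v in picks]), small_germline, "V"
        )
        for vid, w in zip(ids, weights):
            freq = table.loc[table.segment_id == vid, "frequency"].item()
            se = np.sqrt(w * (1 - w) / n)
            assert abs(freq - w) < 3 * se


class TestVdjCombinations:
    def test_single_read(self, small_germline):
        df = frame([{
            "v_id": small_germline.v_segments[0].id,
            "d_id": small_germline.d_segments[0].id,
            "j_id": small_germline.j_segments[0].id,
        }])
        table = vdj_combinations(df, small_germline)
        assert table.observed == 1
        assert table.theoretical == small_germline.theoretical_combinations
        assert table.coverage == 1 / table.theoretical

    def test_full_saturation_reaches_coverage_one(self, small_germline):
        rows = [
            {"v_id": v.id, "d_id": d.id, "j_id": j.id}
            for v in small_germline.v_segments
            for d in small_germline.d_segments
            for j in small_germline.j_segments
        ]
        table = vdj_combinations(frame(rows), small_germline)
        assert table.observed == table.theoretical
        assert table.coverage == 1.0

    def test_ambiguous_stratum_excluded_from_coverage(self, small_germline):
        rows = [
            {"v_id": small_germline.v_segments[0].id, "d_id": "AMBIGUOUS",
             "j_id": small_germline.j_segments[0].id},
        ]
        table = vdj_combinations(frame(rows), small_germline)
        assert table.observed == 0
        assert table.counts["count"].sum() == 1

    def test_counts_match_truth_enumeration(self, noise_free_repertoire):
        """Observed distinct triples equal a direct truth-table enumeration."""
        _, truths = noise_free_repertoire
        igm = [t for t in truths if t.isotype == "IgM"]
        from finrep.simulate import make_germline

        gs = make_germline(32, 6, 5, seed=1)
        rows = [
            {
                "v_id": t.v_id,
                "d_id": t.d_id if t.d_remnant_len >= 4 else "AMBIGUOUS",
                "j_id": t.j_id,
            }
            for t in igm
        ]
        table = vdj_combinations(frame(rows), gs)
        oracle = len(
            {(t.v_id, t.d_id, t.j_id) for t in igm if t.d_remnant_len >= 4}
        )
        assert table.observed == oracle
        assert table.counts["count"].sum() == len(igm)


class TestRarefaction:
    @staticmethod
    def toy_frame(rng, n=600, n_combos=40):
        combos = [(f"V1.{i%8+1}", f"Dm{i%4+1}", f"Jm{i%3+1}", i)
                  for i in range(n_combos)]
        picks = [combos[rng.integers(0, n_combos)] for _ in range(n)]
        return frame(
            [{"v_id": v, "d_id": f"{d}_{k}", "j_id": j}
             for v, d, j, k in picks]
        )

    def test_full_depth_equals_observed_exactly(self):
        rng = np.random.default_rng(5)
        df = self.toy_frame(rng)
        curve = rarefaction(df, [len(df)], n_resamples=50, seed=1)
        assert curve["std"].iloc[0] == 0.0
        assert curve["mean"].iloc[0] == curve.attrs["observed_distinct"]

    def test_depth_one_always_yields_one(self):
        rng = np.random.default_rng(6)
        df = self.toy_frame(rng)
        curve = rarefaction(df, [1], n_resamples=100, seed=2)
        assert curve["mean"].iloc[0] == 1.0

    def test_depth_exceeding_dataset_rejected(self):
        rng = np.random.default_rng(7)
        df = self.toy_frame(rng, n=50)
        with pytest.raises(ValueError, match="51"):
            rarefaction(df, [51], seed=0)

    def test_half_depth_mean_matches_hypergeometric_expectation(self):
        """Monte-Carlo mean vs the closed form sum_i 1 - C(N-n_i,k)/C(N,k)."""
        rng = np.random.default_rng(8)
        df = self.toy_frame(rng, n=800)
        labels = df[["v_id", "d_id", "j_id"]].apply(tuple, axis=1)
        counts = labels.value_counts().to_numpy()
        k = 400
        curve = rarefaction(df, [k], n_resamples=1000, seed=3)
        closed = expected_distinct(counts, k)
        mc_se = curve["std"].iloc[0] / np.sqrt(1000)
        assert abs(curve["mean"].iloc[0] - closed) < 4 * mc_se

    def test_means_monotone_in_depth(self):
        rng = np.random.default_rng(9)
        df = self.toy_frame(rng)
        depths = [10, 100, 300, len(df)]
        curve = rarefaction(df, depths, n_resamples=400, seed=4)
        assert curve["mean"].is_monotonic_increasing

    def test_deterministic_under_fixed_seed(self):
        rng = np.random.default_rng(10)
        df = self.toy_frame(rng)
        a = rarefaction(df, [100, 200], n_resamples=50, seed=5)
        b = rarefaction(df, [100, 200], n_resamples=50, seed=5)
        pd.testing.assert_frame_equal(a, b)


class TestJunctionDistributions:
    def test_all_zero_junctions_concentrate_at_zero(self):
        df = frame(
            [{"v_id": "V1.1", "d_id": "Dm1", "j_id": "Jm1", "v3_del": 0,
              "d5_del": 0, "d3_del": 0, "j5_del": 0, "vd_ins": 0,
              "dj_ins": 0, "cdr3_aa_length": 10}] * 5
        )
        hists = junction_distributions(df)["IgM"]
        for metric in ("vd_del", "dj_del", "vd_ins", "dj_ins"):
            sub = hists[hists.metric == metric]
            assert list(sub["value"]) == [0]
            assert list(sub["count"]) == [5]

    def test_histograms_conserve_record_counts(self, noise_free_repertoire):
        _, truths = noise_free_repertoire
        rows = [
            {"v_id": t.v_id, "d_id": t.d_id, "j_id": t.j_id,
             "isotype": t.isotype,
             "v3_del": t.v3_del, "d5_del": t.d5_del, "d3_del": t.d3_del,
             "j5_del": t.j5_del, "vd_ins": t.vd_ins, "dj_ins": t.dj_ins,
             "cdr3_aa_length": len(t.cdr3_aa) if t.cdr3_aa else None}
            for t in truths
        ]
        df = frame(rows)
        df["isotype"] = [t.isotype for t in truths]
        for isotype, hists in junction_distributions(df).items():
            n = (df.isotype == isotype).sum()
            assert hists[hists.metric == "vd_del"]["count"].sum() == n

    def test_uniform_lengths_give_flat_histogram(self):
        rows = [{"cdr3_aa_length": L, "v_id": "V1.1", "j_id": "Jm1"}
                for L in range(8, 17) for _ in range(3)]
        hists = junction_distributions(frame(rows))["IgM"]
        sub = hists[hists.metric == "aa_length"]
        assert list(sub["value"]) == list(range(8, 17))
        assert set(sub["count"]) == {3}


class TestConvergence:
    def test_hand_enumeration(self):
        df = frame([
            {"cdr3_aa": "ARD", "cdr3_nt": "GCTCGTGAT", "v_id": "V1",
             "j_id": "J1", "productive": True},
            {"cdr3_aa": "ARD", "cdr3_nt": "GCACGAGAC", "v_id": "V1",
             "j_id": "J1", "productive": True},
            {"cdr3_aa": "ARW", "cdr3_nt": "GCTCGTTGG", "v_id": "V1",
             "j_id": "J1", "productive": True},
        ])
        summary = convergence_counts(df)
        assert summary.unique_aa == 2
        assert summary.multi_coding == 1
        assert summary.one_coding == 1
        assert summary.ratio == 0.5

    def test_every_aa_coded_once_gives_zero_ratio(self):
        df = frame([
            {"cdr3_aa": aa, "cdr3_nt": nt, "productive": True}
            for aa, nt in [("ARD", "GCTCGTGAT"), ("ARW", "GCTCGTTGG")]
        ])
        summary = convergence_counts(df)
        assert summary.multi_coding == 0
        assert summary.ratio == 0.0

    def test_partition_property(self, noise_free_repertoire):
        _, truths = noise_free_repertoire
        df = pd.DataFrame([
            {"cdr3_aa": t.cdr3_aa, "cdr3_nt": t.cdr3_nt, "v_id": t.v_id,
             "j_id": t.j_id}
            for t in truths if t.productive
        ])
        summary = convergence_counts(df)
        assert summary.one_coding + summary.multi_coding == summary.unique_aa

    def test_fish1_scale_ratio_truncates(self):
        summary = ConvergenceSummary(
            unique_aa=363_728, one_coding=330_174, multi_coding=33_554,
            nt_multi_vj=0,
        )
        assert summary.ratio_reported == 0.092

    def test_nt_with_multiple_vj_pairings_counted(self):
        df = frame([
            {"cdr3_aa": "ARD", "cdr3_nt": "GCTCGTGAT", "v_id": "V1",
             "j_id": "J1", "productive": True},
            {"cdr3_aa": "ARD", "cdr3_nt": "GCTCGTGAT", "v_id": "V2",
             "j_id": "J1", "productive": True},
        ])
        assert convergence_counts(df).nt_multi_vj == 1


class TestAssignmentRates:
    # printed-table cells: (total, vj, vdj) -> (vj_rate, vdj_rate)
    TABLE_CELLS = [
        ((1_798_717, 1_684_225, 251_746), (0.936, 0.149)),
        ((2_337_015, 2_215_821, 320_638), (0.948, 0.144)),
        ((2_029_082, 1_915_237, 244_172), (0.943, 0.127)),
        ((2_160_668, 2_096_641, 1_462_606), (0.970, 0.697)),
        ((1_516_736, 1_483_036, 545_230), (0.977, 0.367)),
        ((1_905_817, 1_876_739, 306_943), (0.984, 0.163)),
    ]

    @pytest.mark.parametrize("counts,expected", TABLE_CELLS)
    def test_truncation_convention_reproduces_printed_rates(
        self, counts, expected
    ):
        total, vj, vdj = counts
        rates = assignment_rates({"total": total, "vj": vj, "vdj": vdj})
        assert rates["vj_rate"] == expected[0]
        assert rates["vdj_rate"] == expected[1]

    def test_equal_numerator_denominator_gives_one(self):
        rates = assignment_rates({"total": 10, "vj": 10, "vdj": 10})
        assert rates == {"vj_rate": 1.0, "vdj_rate": 1.0}

    def test_zero_denominator_flagged_as_nan(self):
        rates = assignment_rates({"total": 0, "vj": 0, "vdj": 0})
        assert np.isnan(rates["vj_rate"]) and np.isnan(rates["vdj_rate"])

    def test_truncation_not_rounding(self):
        assert truncate_rate(1_876_739, 1_905_817) == 0.984  # 0.98474 floors
        assert truncate_rate(320_638, 2_215_821) == 0.144  # 0.14470 floors


class TestCrossIndividualAverages:
    def test_unique_aa_average(self):
        out = summarize_across_individuals(
            {"unique_aa": [363_728, 479_043, 393_180]}
        )
        assert out["unique_aa"] == 411_984  # 411,983.67 rounds half-up

    def test_multi_coding_average(self):
        out = summarize_across_individuals(
            {"multi_coding": [33_554, 43_049, 34_967]}
        )
        assert out["multi_coding"] == 37_190

    def test_single_individual_returns_itself(self):
        assert summarize_across_individuals({"x": [42]}) == {"x": 42}

    def test_non_count_metric_stays_float(self):
        out = summarize_across_individuals(
            {"rate": [0.25, 0.5]}, count_metrics=set()
        )
        assert out["rate"] == 0.375

    def test_round_half_up_behaviour(self):
        assert round_half_up(2.5) == 3
        assert round_half_up(2.49) == 2
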