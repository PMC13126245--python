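"""Synthetic cohort, intensity and junction generators."""

import numpy as np
import pandas as pd
import pytest

from bcl3meth import junctions, stats_core, synth


class TestAnnotation:
    def test_seed_determinism(self):
        a = synth.generate_annotation(1000, seed=1)
        b = synth.generate_annotation(1000, seed=1)
        pd.testing.assert_frame_equal(a, b)

    def test_cardinality_and_unique_ids(self):
        ann = synth.generate_annotation(1000, seed=1)
        assert len(ann) == 1000
        assert ann["cpg_id"].is_unique

    def test_module_state_rule_table(self):
        ann = synth.generate_annotation(1000, seed=1)
        for module, state in synth.MODULE_STATE_RULES.items():
            sub = ann[ann["module"] == str(module)]
            assert (sub["state"] == state).all()

    def test_minimum_size_enforced(self):
        with pytest.raises(ValueError):
            synth.generate_annotation(50, seed=0)

    def test_positions_sorted_within_chromosome(self):
        ann = synth.generate_annotation(500, seed=2)
        for _, sub in ann.groupby("chrom"):
            assert sub["start"].is_monotonic_increasing


class TestCohort:
    def test_noiseless_purity_one_reproduces_means(self, annotation_small):
        cfg = synth.CohortConfig(
            n_cases=4, n_controls=3, n_cpgs=500, n_hypo=40, n_hyper=2,
            precision=float("inf"), purity_range=(1.0, 1.0), seed=5,
        )
        beta, sheet, truth = synth.generate_cohort(cfg, annotation_small)
        cases = sheet.loc[sheet["group"] == "BCL3", "sample_id"]
        # all case columns identical (no noise), ditto controls per group
        assert beta[list(cases)].std(axis=1).max() == 0.0
        ctrl = sheet.loc[sheet["group"] == "CLL_U", "sample_id"]
        delta = beta[list(cases)].mean(1) - beta[list(ctrl)].mean(1)
        np.testing.assert_allclose(
            delta.loc[truth["cpg_id"]], truth["planted_delta"], atol=1e-12
        )

    def test_planted_delta_recovered_within_tolerance(self, annotation_small):
        cfg = synth.CohortConfig(
            n_cases=80, n_controls=32, n_cpgs=2000, n_hypo=196, n_hyper=4,
            delta_beta=0.35, precision=100.0, purity_range=(1.0, 1.0), seed=7,
        )
        beta, sheet, truth = synth.generate_cohort(cfg, annotation_small)
        cases = sheet.loc[sheet["group"] == "BCL3", "sample_id"]
        ctrl = sheet.loc[sheet["group"] == "CLL_U", "sample_id"]
        delta = beta[list(cases)].mean(1) - beta[list(ctrl)].mean(1)
        err = (delta.loc[truth["cpg_id"]] - truth["planted_delta"]).abs()
        assert err.max() < 0.05
        assert err.mean() < 0.02

    def test_purity_linear_mixing(self, annotation_small):
        cfg = synth.CohortConfig(
            n_cases=3, n_controls=3, n_cpgs=500, n_hypo=40, n_hyper=2,
            delta_beta=0.4, precision=float("inf"), purity_range=(0.5, 0.5), seed=9,
        )
        beta, sheet, truth = synth.generate_cohort(cfg, annotation_small)
        cases = sheet.loc[sheet["group"] == "BCL3", "sample_id"]
        ctrl = sheet.loc[sheet["group"] == "CLL_U", "sample_id"]
        delta = beta[list(cases)].mean(1) - beta[list(ctrl)].mean(1)
        np.testing.assert_allclose(
            delta.loc[truth["cpg_id"]], 0.5 * truth["planted_delta"], atol=1e-12
        )

    def test_values_bounded_and_complete(self, cohort_small):
        _, beta, _, _ = cohort_small
        assert not beta.isna().any().any()
        assert beta.values.min() >= 0.0 and beta.values.max() <= 1.0

    def test_hypo_hyper_ratio_exact(self, cohort_small):
        cfg, _, _, truth = cohort_small
        assert (truth["direction"] == "hypo").sum() == cfg.n_hypo
        assert (truth["direction"] == "hyper").sum() == cfg.n_hyper

    def test_seed_determinism(self, annotation_small):
        cfg = synth.CohortConfig(n_cases=5, n_controls=4, n_cpgs=300, n_hypo=20,
                                 n_hyper=2, seed=11)
        b1, s1, t1 = synth.generate_cohort(cfg, annotation_small)
        b2, s2, t2 = synth.generate_cohort(cfg, annotation_small)
        pd.testing.assert_frame_equal(b1, b2)
        pd.testing.assert_frame_equal(s1, s2)
        pd.testing.assert_frame_equal(t1, t2)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            synth.CohortConfig(n_hypo=900, n_hyper=200, n_cpgs=1000)
        with pytest.raises(ValueError):
            synth.CohortConfig(delta_beta=1.5)
        with pytest.raises(ValueError):
            synth.CohortConfig(purity_range=(0.5, 1.2))


class TestFollowups:
    def test_zero_noise_gives_identical_profiles(self, cohort_small):
        _, beta, sheet, _ = cohort_small
        b2, s2 = synth.generate_followups(beta, sheet, n_pairs=3, within_noise=0.0, seed=1)
        pairs = [(p, c) for c, p in zip(s2["sample_id"], s2["followup_of"]) if p]
        assert len(pairs) == 3
        for parent, child in pairs:
            np.testing.assert_array_equal(b2[parent], b2[child])
            assert stats_core.pairwise_corr(b2, [(parent, child)])[0] == pytest.approx(1.0)

    def test_within_exceeds_between_correlation(self, cohort_small):
        _, beta, sheet, _ = cohort_small
        b2, s2 = synth.generate_followups(beta, sheet, n_pairs=5, within_noise=0.02, seed=2)
        pairs = [(p, c) for c, p in zip(s2["sample_id"], s2["followup_of"]) if p]
        within = np.mean(stats_core.pairwise_corr(b2, pairs))
        cases = s2.loc[(s2["group"] == "BCL3") & (s2["followup_of"] == ""), "sample_id"].tolist()
        between_pairs = [(cases[i], cases[j]) for i in range(8) for j in range(i + 1, 8)]
        between = np.mean(stats_core.pairwise_corr(b2, between_pairs))
        assert within > between

    def test_determinism_and_pair_limit(self, cohort_small):
        _, beta, sheet, _ = cohort_small
        a = synth.generate_followups(beta, sheet, 2, 0.02, seed=5)[0]
        b = synth.generate_followups(beta, sheet, 2, 0.02, seed=5)[0]
        pd.testing.assert_frame_equal(a, b)
        with pytest.raises(ValueError):
            synth.generate_followups(beta, sheet, 10_000, 0.02, seed=5)


class TestIntensity:
    def test_no_cnv_zero_noise_all_zero(self, annotation_small):
        m = synth.generate_intensity(annotation_small, ["s1", "s2"], [], noise_sd=0.0, seed=1)
        assert (m.values == 0).all()

    def test_planted_shift_mean(self, annotation_small):
        m = synth.generate_intensity(annotation_small, ["s"], [("chr12", 0.15)],
                                     noise_sd=0.03, seed=2)
        on = annotation_small["chrom"] == "chr12"
        chr12 = m.loc[annotation_small.loc[on, "cpg_id"], "s"]
        se = 0.03 / np.sqrt(len(chr12))
        assert abs(chr12.mean() - 0.15) < 3 * se

    def test_negative_shift_sign(self, annotation_small):
        m = synth.generate_intensity(annotation_small, ["s"], [("chr13", -0.2)],
                                     noise_sd=0.03, seed=3)
        on = annotation_small["chrom"] == "chr13"
        assert m.loc[annotation_small.loc[on, "cpg_id"], "s"].mean() < 0

    def test_unknown_chromosome_rejected(self, annotation_small):
        with pytest.raises(ValueError):
            synth.generate_intensity(annotation_small, ["s"], [("chr99", 0.1)], seed=0)


class TestJunctionGeneration:
    def test_csr_breakpoint_inside_switch_region(self, loci):
        cfg = synth.JunctionSimConfig(mechanism="CSR", switch_region="IGHA1", n_insert=0, seed=1)
        rec = synth.generate_junction(cfg, loci)
        sw = loci.feature("IGHA1")
        assert sw["start"] <= rec.pos14 <= sw["end"]
        assert junctions.assign_igh_segment(rec.pos14, loci) == "IGHA1"

    def test_vdj_junction_contains_heptamer_near_breakpoint(self, loci):
        cfg = synth.JunctionSimConfig(mechanism="VDJ", rss_spacer=12, n_insert=11, seed=2)
        rec = synth.generate_junction(cfg, loci)
        boundary = len(rec.left_flank) + rec.insert_len
        assert rec.junction_seq[boundary + 12 : boundary + 19] == synth.RSS_HEPTAMER

    @pytest.mark.parametrize("n_insert", [0, 1, 6, 11, 30])
    def test_insert_lengths_round_trip(self, loci, n_insert):
        cfg = synth.JunctionSimConfig(mechanism="CSR", switch_region="IGHM",
                                      n_insert=n_insert, seed=3 + n_insert)
        rec = synth.generate_junction(cfg, loci)
        ins, mh = junctions.junction_inserts(rec.junction_seq, rec.left_flank, rec.right_flank)
        assert (ins, mh) == (n_insert, 0)

    @pytest.mark.parametrize("mh", [1, 4, 10])
    def test_microhomology_round_trip(self, loci, mh):
        cfg = synth.JunctionSimConfig(mechanism="CSR", switch_region="IGHG3",
                                      microhomology=mh, seed=17 + mh)
        rec = synth.generate_junction(cfg, loci)
        ins, got = junctions.junction_inserts(rec.junction_seq, rec.left_flank, rec.right_flank)
        assert (ins, got) == (0, mh)

    def test_unknown_switch_region_rejected(self, loci):
        with pytest.raises(ValueError):
            synth.generate_junction(
                synth.JunctionSimConfig(mechanism="CSR", switch_region="IGHX"), loci
            )

    def test_insert_and_microhomology_exclusive(self):
        with pytest.raises(ValueError):
            synth.JunctionSimConfig(mechanism="CSR", n_insert=3, microhomology=2)

    def test_seed_determinism(self, loci):
        cfg = synth.JunctionSimConfig(mechanism="VDJ", n_insert=5, seed=9)
        r1 = synth.generate_junction(cfg, loci)
        r2 = synth.generate_junction(cfg, loci)
        assert r1 == r2
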