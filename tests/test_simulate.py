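import numpy as np
import pandas as pd
import pytest

from circsponge import sites
from circsponge.annotate import cpm_normalize
from circsponge.model import PipelineError
from circsponge.simulate import (
    CohortConfig,
    SyntheticTruth,
    simulate_cohort,
    simulate_knockdown,
)


class TestDeterminism:
    def test_same_seed_same_cohort(self, small_config):
        a = simulate_cohort(small_config, seed=9)
        b = simulate_cohort(small_config, seed=9)
        pd.testing.assert_frame_equal(a.circ_matrix.counts, b.circ_matrix.counts)
        pd.testing.assert_frame_equal(a.mrna_matrix.counts, b.mrna_matrix.counts)
        assert a.genome == b.genome
        assert a.truth.to_json() == b.truth.to_json()

    def test_different_seed_differs(self, small_config):
        a = simulate_cohort(small_config, seed=9)
        b = simulate_cohort(small_config, seed=10)
        assert not a.circ_matrix.counts.equals(b.circ_matrix.counts)

    def test_same_seed_same_knockdown(self, default_cohort):
        a, _ = simulate_knockdown(default_cohort.truth, CohortConfig(), seed=3)
        b, _ = simulate_knockdown(default_cohort.truth, CohortConfig(), seed=3)
        pd.testing.assert_frame_equal(a.counts, b.counts)


class TestShapes:
    def test_requested_feature_counts(self, small_config):
        cohort = simulate_cohort(small_config, seed=1)
        assert len(cohort.junctions) == small_config.n_circ
        assert cohort.circ_matrix.counts.shape == (small_config.n_circ,
                                                   2 * small_config.n_subjects)
        assert cohort.mrna_matrix.counts.shape == (small_config.n_mrna,
                                                   2 * small_config.n_subjects)
        assert len(cohort.mirnas) == small_config.n_mirna
        assert len(cohort.truth.planted_triplets) == small_config.n_planted_triplets

    def test_infeasible_config_is_error(self):
        with pytest.raises(PipelineError, match="infeasible"):
            simulate_cohort(CohortConfig(n_circ=40, n_mrna=45), seed=0)

    def test_truth_json_round_trip(self, default_cohort):
        truth2 = SyntheticTruth.from_json(default_cohort.truth.to_json())
        assert truth2 == default_cohort.truth


class TestNbMeanLaw:
    def test_planted_fold_change_reproduced_in_mean_cpm(self):
        """Monte-Carlo check of the NB mean law: with low dispersion and
        little biological noise, the tumor/normal mean-CPM ratio of a planted
        circRNA approaches its planted fold change."""
        cfg = CohortConfig(
            n_subjects=200, n_circ=150, n_mrna=170, n_mirna=5,
            n_planted_triplets=1, n_planted_dec_extra=1,
            n_decoy_pos=5, n_decoy_neg=5, n_kd_pos=2, n_kd_neg=1,
            nb_dispersion=0.01, bio_sd=0.1)
        cohort = simulate_cohort(cfg, seed=4)
        cpm = cpm_normalize(cohort.circ_matrix)
        meta = cohort.circ_matrix.sample_meta
        tumor = meta.index[meta["condition"] == "tumor"]
        normal = meta.index[meta["condition"] == "normal"]
        for circ, lfc in cohort.truth.planted_dec.items():
            ratio = cpm.loc[circ, tumor].mean() / cpm.loc[circ, normal].mean()
            assert ratio == pytest.approx(2.0 ** lfc, rel=0.05)

    def test_null_features_have_unit_ratio(self):
        cfg = CohortConfig(
            n_subjects=200, n_circ=150, n_mrna=170, n_mirna=5,
            n_planted_triplets=1, n_planted_dec_extra=1,
            n_decoy_pos=5, n_decoy_neg=5, n_kd_pos=2, n_kd_neg=1,
            nb_dispersion=0.01, bio_sd=0.1)
        cohort = simulate_cohort(cfg, seed=4)
        cpm = cpm_normalize(cohort.circ_matrix)
        meta = cohort.circ_matrix.sample_meta
        tumor = meta.index[meta["condition"] == "tumor"]
        normal = meta.index[meta["condition"] == "normal"]
        nulls = [c for c in cohort.truth.circ_ids if c not in cohort.truth.planted_dec]
        ratios = cpm.loc[nulls, tumor].mean(axis=1) / cpm.loc[nulls, normal].mean(axis=1)
        assert ratios.median() == pytest.approx(1.0, rel=0.05)


class TestPlantedSites:
    def test_every_planted_triplet_is_redetected(self, default_cohort):
        """The scanner must find >= 2 circRNA sites and >= 1 UTR site for
        every planted triplet (site-planting postcondition)."""
        cohort = default_cohort
        mirnas = {m.mirna_id: m for m in cohort.mirnas}
        for circ_id, mirna_id, mrna_id in cohort.truth.planted_triplets:
            m = mirnas[mirna_id]
            circ_hits = sites.scan_circular(cohort.circ_seqs[circ_id], m, circ_id)
            utr_hits = sites.scan_linear(cohort.utr_seqs[mrna_id], m, mrna_id)
            assert len(circ_hits) >= 2
            assert len(utr_hits) >= 1

    def test_no_accidental_sites_anywhere(self, default_cohort):
        """Scrubbing guarantee: outside planted (target, miRNA) pairs, no
        scanned sequence carries any seed site for any simulated miRNA."""
        cohort = default_cohort
        planted = {(c, m) for c, m, _ in cohort.truth.planted_triplets} \
            | {(g, m) for _, m, g in cohort.truth.planted_triplets}
        table = sites.site_count_table(
            {**{c: ("circ", s) for c, s in cohort.circ_seqs.items()},
             **{g: ("utr3", s) for g, s in cohort.utr_seqs.items()}},
            cohort.mirnas)
        extra = [(r.target_id, r.mirna_id) for r in table.itertuples()
                 if (r.target_id, r.mirna_id) not in planted]
        assert extra == []

    def test_junction_spanning_sites_do_occur(self):
        """With certain junction-site placement every triplet circ carries one."""
        cfg = CohortConfig(n_circ=40, n_mrna=70, n_mirna=5, n_planted_triplets=3,
                           n_planted_dec_extra=2, n_decoy_pos=8, n_decoy_neg=8,
                           n_kd_pos=3, n_kd_neg=2, p_junction_site=1.0)
        cohort = simulate_cohort(cfg, seed=2)
        mirnas = {m.mirna_id: m for m in cohort.mirnas}
        for circ_id, mirna_id, _ in cohort.truth.planted_triplets:
            hits = sites.scan_circular(cohort.circ_seqs[circ_id], mirnas[mirna_id])
            assert any(h.spans_junction for h in hits)


class TestCorrelationPlanting:
    def test_max_strength_zero_dispersion_gives_near_perfect_r(self):
        cfg = CohortConfig(
            n_circ=40, n_mrna=70, n_mirna=5, n_planted_triplets=3,
            n_planted_dec_extra=2, n_decoy_pos=8, n_decoy_neg=8,
            n_kd_pos=3, n_kd_neg=2,
            rho=1.0, host_rho=1.0, nb_dispersion=0.0, bio_sd=2.0,
            circ_mean=(2000, 4000), mrna_mean=(2000, 4000))
        cohort = simulate_cohort(cfg, seed=6)
        lc = np.log2(cpm_normalize(cohort.circ_matrix) + 1)
        lm = np.log2(cpm_normalize(cohort.mrna_matrix) + 1)
        for (circ, gene), (sign, _rho) in cohort.truth.planted_corr.items():
            if circ in cohort.truth.planted_dec:
                continue  # DE shift adds variance unrelated to the latent
            r = np.corrcoef(lc.loc[circ], lm.loc[gene])[0, 1]
            assert sign * r > 0.9


class TestKnockdown:
    def test_positive_targets_go_down(self, default_cohort):
        kd, directions = simulate_knockdown(default_cohort.truth, CohortConfig(), seed=2)
        meta = kd.sample_meta
        ctrl = meta.index[meta["condition"] == "control"]
        down = [g for g, d in directions.items() if d == "down"]
        up = [g for g, d in directions.items() if d == "up"]
        kd_samples = meta.index[meta["condition"] == "knockdown"]
        ratios = kd.counts[kd_samples].mean(axis=1) / kd.counts[ctrl].mean(axis=1)
        assert (ratios.loc[down] < 1).all()
        assert (ratios.loc[up] > 1).all()

    def test_other_circ_has_no_planted_targets(self, default_cohort):
        other = default_cohort.truth.circ_ids[-1]
        _, directions = simulate_knockdown(default_cohort.truth, CohortConfig(),
                                           seed=2, circ_id=other)
        assert directions == {}

    def test_unknown_circ_is_error(self, default_cohort):
        with pytest.raises(PipelineError):
            simulate_knockdown(default_cohort.truth, CohortConfig(), seed=2,
                               circ_id="not-a-circ")
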