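"""Allele-specific copy-number estimation: QC, segmentation, grid fit."""

import numpy as np
import pandas as pd
import pytest

import cnaloss as cl
from cnaloss.ascn import (AscnSolution, SegmentedTrack, average_ploidy,
                          fit_purity_ploidy, goodness_at, qc_sample,
                          segment_track, select_solution,
                          UnassessableSampleError)

from conftest import diploid_profile


def _track(genome, truth, lrr_sd=0.25, baf_sd=0.03, seed=0):
    return cl.render_snp_track(truth, genome, lrr_sd=lrr_sd, baf_sd=baf_sd,
                               seed=seed)


def _three_state_truth(genome, rho):
    """One chromosome with (1,1) / (1,0) / (2,1) blocks, rest diploid."""
    rows = []
    for i, (chrom, size) in enumerate(genome.chromosomes):
        if i == 0:
            third = size // 3
            rows += [(chrom, 0, third, 1, 1),
                     (chrom, third, 2 * third, 1, 0),
                     (chrom, 2 * third, size, 2, 1)]
        else:
            rows.append((chrom, 0, size, 1, 1))
    segs = pd.DataFrame(rows, columns=["chrom", "start", "end", "nA", "nB"])
    return cl.TruthProfile(sample_id="T3", rho=rho, segments=segs)


class TestQC:
    def test_zero_content_is_flat_baf(self, genome_small, sets_small):
        t = cl.simulate_cohort_truth(genome_small, sets_small, 1,
                                     rho_range=(0.0, 0.0), seed=1)[0]
        flags = qc_sample(_track(genome_small, t, seed=2))
        assert flags.flat_baf and not flags.noisy_lrr
        assert flags.reason == "flat_baf"

    def test_excessive_lrr_noise_flagged(self, genome_small, sets_small):
        t = cl.simulate_cohort_truth(genome_small, sets_small, 1,
                                     rho_range=(0.8, 0.8), seed=1)[0]
        flags = qc_sample(_track(genome_small, t, lrr_sd=1.5, seed=3))
        assert flags.noisy_lrr
        assert flags.metrics["lrr_successive_mad"] > 0.5

    def test_clean_high_purity_track_passes(self, genome_small, sets_small):
        t = cl.simulate_cohort_truth(genome_small, sets_small, 1,
                                     rho_range=(0.8, 0.8), seed=1)[0]
        flags = qc_sample(_track(genome_small, t, seed=4))
        assert flags.passed

    def test_empty_track_rejected(self):
        track = cl.SnpTrack("E", pd.DataFrame(
            columns=["chrom", "pos", "lrr", "baf", "is_het"]))
        with pytest.raises(ValueError):
            qc_sample(track)


class TestSegmentation:
    def test_noise_free_three_segments_exact(self, genome_small):
        t = _three_state_truth(genome_small, rho=0.8)
        seg = segment_track(_track(genome_small, t, 0.0, 0.0, seed=5))
        chr1 = seg.segments[seg.segments.chrom == "chr1"]
        assert len(chr1) == 3
        size = genome_small.chrom_size("chr1")
        spacing = 10_000
        for found, true_bp in zip(sorted(chr1.start)[1:],
                                  [size // 3, 2 * (size // 3)]):
            # boundary within one SNP spacing of the truth (het SNPs are
            # a 0.3 subsample, so allow the inter-het gap)
            assert abs(found - true_bp) < 8 * spacing

    def test_constant_track_one_segment_per_chromosome(self, genome_small):
        t = diploid_profile(genome_small, rho=0.6)
        seg = segment_track(_track(genome_small, t, 0.0, 0.0, seed=6))
        assert len(seg.segments) == len(genome_small.chromosomes)

    def test_noisy_breakpoint_recovery(self, genome_small):
        """>= 90 % of true breakpoints within 5 het SNPs at default noise."""
        hits = total = 0
        for seed in range(10):
            t = _three_state_truth(genome_small, rho=0.8)
            track = _track(genome_small, t, seed=seed)
            seg = segment_track(track)
            het = track.df[(track.df.is_het) & (track.df.chrom == "chr1")]
            hp = het.pos.to_numpy()
            size = genome_small.chrom_size("chr1")
            found = seg.segments[seg.segments.chrom == "chr1"].start.to_numpy()
            for true_bp in (size // 3, 2 * (size // 3)):
                total += 1
                iref = np.searchsorted(hp, true_bp)
                near = [abs(np.searchsorted(hp, f) - iref) for f in found]
                if near and min(near) <= 5:
                    hits += 1
        assert hits / total >= 0.9

    def test_no_het_chromosome_marked_unassessable(self, genome_small):
        t = diploid_profile(genome_small, rho=0.8)
        track = _track(genome_small, t, seed=7)
        df = track.df.copy()
        df.loc[df.chrom == "chr2", "is_het"] = False
        seg = segment_track(cl.SnpTrack("U", df))
        assert "chr2" in seg.unassessable_chroms
        assert not (seg.segments.chrom == "chr2").any()

    def test_mirrored_baf_in_range(self, genome_small, sets_small):
        t = cl.simulate_cohort_truth(genome_small, sets_small, 1,
                                     rho_range=(0.7, 0.7), seed=9)[0]
        seg = segment_track(_track(genome_small, t, seed=9))
        assert (seg.segments.mean_mirrored_baf >= 0.5).all()
        assert (seg.segments.mean_mirrored_baf <= 1.0).all()


def _contrived_segments(rho, psi_t, states, gamma=0.55, n_snps=200):
    """Exact segment summaries from the forward model for given states."""
    states = np.array(states, float)
    tot = states.sum(1)
    n_mix = 2 * (1 - rho) + rho * tot
    psi_mix = 2 * (1 - rho) + rho * psi_t
    lrr = gamma * np.log2(n_mix / psi_mix)
    baf = (1 - rho + rho * states[:, 0]) / n_mix
    mb = 1_000_000
    return SegmentedTrack("C", pd.DataFrame({
        "chrom": "chr1", "start": np.arange(len(states)) * 10 * mb,
        "end": (np.arange(len(states)) + 1) * 10 * mb,
        "mean_lrr": lrr, "mean_mirrored_baf": baf,
        "n_informative_snps": n_snps}))


class TestFitPurityPloidy:
    def test_truth_grid_point_is_global_optimum(self):
        states = [(1, 1), (1, 0), (2, 1), (2, 2), (1, 1), (2, 0)]
        rho, psi_t = 0.6, np.mean([2, 1, 3, 4, 2, 2])
        seg = _contrived_segments(rho, psi_t, states)
        g_truth = goodness_at(seg, rho, psi_t)
        assert g_truth < 1e-12
        rng = np.random.default_rng(0)
        for _ in range(200):
            r2 = rng.uniform(0.1, 1.0)
            p2 = rng.uniform(1.0, 5.5)
            assert g_truth <= goodness_at(seg, r2, p2) + 1e-12

    def test_noise_free_recovery_diploidish(self, genome_dense, sets_dense):
        cohort = cl.simulate_cohort_truth(
            genome_dense, sets_dense, 1, rho_range=(0.6, 0.6),
            ploidy_choices=[2.0], seed=31)
        t = cohort[0]
        fit = cl.AllelicCopyNumberModel(
            _track(genome_dense, t, 0.0, 0.0, seed=31)).fit(skip_qc=True)
        assert abs(fit.rho - t.rho) <= 0.011
        assert abs(fit.psi - t.psi_true) <= 0.06

    def test_noise_free_recovery_aneuploid(self, genome_dense, sets_dense):
        cohort = cl.simulate_cohort_truth(
            genome_dense, sets_dense, 1, rho_range=(0.3, 0.3),
            ploidy_choices=[3.6], seed=32)
        t = cohort[0]
        fit = cl.AllelicCopyNumberModel(
            _track(genome_dense, t, 0.0, 0.0, seed=32)).fit(skip_qc=True)
        assert abs(fit.rho - t.rho) <= 0.011
        assert abs(fit.psi - t.psi_true) <= 0.06

    def test_pure_balanced_genome_unidentifiable(self, genome_small):
        t = diploid_profile(genome_small, rho=1.0)
        seg = segment_track(_track(genome_small, t, 0.0, 0.0, seed=33))
        assert fit_purity_ploidy(seg) == []
        with pytest.raises(UnassessableSampleError):
            cl.AllelicCopyNumberModel(
                _track(genome_small, t, 0.0, 0.0, seed=33)).fit(skip_qc=True)

    def test_inversion_consistency_on_candidates(self):
        """Applying the generative equations to the fitted integers at the
        reported (rho, psi_t) reproduces the observed segment summaries."""
        states = [(1, 1), (1, 0), (2, 1), (2, 2), (2, 0), (1, 1)]
        rho, psi_t = 0.45, np.mean([2, 1, 3, 4, 2, 2])
        seg = _contrived_segments(rho, psi_t, states)
        best = fit_purity_ploidy(seg)[0]
        gamma = 0.55
        psi_mix = 2 * (1 - best.rho) + best.rho * best.psi_t_grid
        tot = (best.segments.nA + best.segments.nB).to_numpy(float)
        n_mix = 2 * (1 - best.rho) + best.rho * tot
        lrr_model = gamma * np.log2(n_mix / psi_mix)
        baf_model = (1 - best.rho + best.rho * best.segments.nA.to_numpy()) \
            / n_mix
        np.testing.assert_allclose(lrr_model, seg.segments.mean_lrr,
                                   atol=1e-6)
        np.testing.assert_allclose(baf_model, seg.segments.mean_mirrored_baf,
                                   atol=1e-6)


def _toy_solution(rho, psi, homdel_mb, goodness):
    segs = pd.DataFrame({"chrom": ["chr1"], "start": [0],
                         "end": [int(100e6)], "nA": [1], "nB": [1],
                         "n_snps": [100]})
    sol = AscnSolution(sample_id="X", rho=rho, psi=psi, psi_t_grid=psi,
                       segments=segs, goodness=goodness)
    sol.homdel_mb = homdel_mb
    return sol


class TestSelectSolution:
    def test_clean_best_returned(self):
        cands = [_toy_solution(0.8, 2.0, 0.0, 0.01),
                 _toy_solution(0.6, 4.0, 0.0, 0.02)]
        assert select_solution(cands) is cands[0]

    def test_large_homdel_triggers_higher_ploidy_pick(self):
        cands = [_toy_solution(0.8, 2.0, 15.0, 0.01),
                 _toy_solution(0.6, 4.0, 0.0, 0.02)]
        chosen = select_solution(cands, max_homdel_mb=10.0)
        assert chosen is cands[1]
        assert chosen.psi > cands[0].psi

    def test_higher_ploidy_required_not_just_next(self):
        # next-best is at LOWER ploidy -> skipped; third (higher) wins
        cands = [_toy_solution(0.8, 3.0, 15.0, 0.01),
                 _toy_solution(0.9, 2.0, 0.0, 0.02),
                 _toy_solution(0.6, 4.0, 0.0, 0.03)]
        assert select_solution(cands, 10.0) is cands[2]

    def test_all_exceed_returns_best_with_warning(self):
        cands = [_toy_solution(0.8, 2.0, 15.0, 0.01),
                 _toy_solution(0.6, 4.0, 30.0, 0.02)]
        chosen = select_solution(cands, 10.0)
        assert chosen is cands[0]
        assert chosen.warning is not None

    def test_empty_candidates_error(self):
        with pytest.raises(UnassessableSampleError):
            select_solution([])


class TestAveragePloidy:
    @pytest.mark.parametrize("totals,weights,expected", [
        ([(1, 1), (1, 1)], [10, 10], 2.0),
        ([(1, 1), (2, 2)], [10, 10], 3.0),
        ([(1, 1), (3, 3)], [30, 10], 3.0),
    ])
    def test_weighted_mean(self, totals, weights, expected):
        segs = pd.DataFrame({
            "chrom": "chr1",
            "start": np.arange(len(totals)) * 10,
            "end": (np.arange(len(totals)) + 1) * 10,
            "nA": [t[0] for t in totals], "nB": [t[1] for t in totals],
            "n_snps": weights})
        sol = AscnSolution(sample_id="P", rho=0.5, psi=expected,
                           psi_t_grid=expected, segments=segs, goodness=0.0)
        assert average_ploidy(sol) == pytest.approx(expected)

    def test_zero_informative_snps_error(self):
        segs = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [10],
                             "nA": [1], "nB": [1], "n_snps": [0]})
        sol = AscnSolution(sample_id="Z", rho=0.5, psi=2.0, psi_t_grid=2.0,
                           segments=segs, goodness=0.0)
        with pytest.raises(ValueError):
            average_ploidy(sol)


class TestParameterRecovery:
    def test_default_noise_recovery_multi_seed(self, genome_dense,
                                               sets_dense):
        """rho within 0.05 and psi within 0.1 at default noise, rho >= 0.3."""
        n_ok = n = 0
        for seed in range(8):
            t = cl.simulate_cohort_truth(
                genome_dense, sets_dense, 1, rho_range=(0.3, 1.0),
                ploidy_choices=[2.0, 1.7, 3.6], seed=600 + seed)[0]
            fit = cl.AllelicCopyNumberModel(
                _track(genome_dense, t, seed=seed)).fit(skip_qc=True)
            n += 1
            n_ok += (abs(fit.rho - t.rho) <= 0.05
                     and abs(fit.psi - t.psi_true) <= 0.1)
        assert n_ok == n
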