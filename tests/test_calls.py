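"""Loss/LOH calling, genome fractions, frequency tracks, regions."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import cnaloss as cl
from cnaloss.calls import (annotate_regions, call_loh, call_losses,
                           cohort_gene_calls, gene_copy_number,
                           genome_fractions, loss_frequency,
                           recurrent_loss_regions)

from conftest import truth_cohort_dict


def _genes(*rows):
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end"])


def _segs(*rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "nA", "nB"])


class TestGeneCopyNumber:
    def test_gene_inside_single_segment(self):
        segs = _segs(("chr1", 0, 1000, 2, 1))
        genes = _genes(("G1", "chr1", 100, 200))
        gc = gene_copy_number(segs, genes)
        assert gc.loc["G1", "total_cn"] == 3
        assert gc.loc["G1", "minor_cn"] == 1

    def test_gene_straddling_two_segments_weighted(self):
        segs = _segs(("chr1", 0, 100, 2, 2), ("chr1", 100, 200, 1, 0))
        genes = _genes(("G1", "chr1", 50, 150))
        gc = gene_copy_number(segs, genes)
        assert gc.loc["G1", "total_cn"] == pytest.approx(0.5 * 4 + 0.5 * 1)
        assert gc.loc["G1", "minor_cn"] == 0

    def test_gene_in_gap_unassessable(self):
        segs = _segs(("chr1", 0, 100, 1, 1))
        genes = _genes(("G1", "chr1", 500, 600))
        gc = gene_copy_number(segs, genes)
        assert np.isnan(gc.loc["G1", "total_cn"])
        assert np.isnan(gc.loc["G1", "minor_cn"])


class TestCallLosses:
    def test_worked_threshold_psi_2_31(self):
        # 0.7 x 2.31 = 1.617: total 1 is a loss, total 2 is not
        assert call_losses([1.0], psi=2.31, factor=0.7)[0]
        assert not call_losses([2.0], psi=2.31, factor=0.7)[0]

    def test_boundary_is_strict(self):
        psi, factor = 2.0, 0.7
        assert not call_losses([factor * psi], psi, factor)[0]
        assert call_losses([factor * psi - 1e-9], psi, factor)[0]

    def test_invalid_factor_or_psi(self):
        with pytest.raises(ValueError):
            call_losses([1.0], psi=2.0, factor=1.5)
        with pytest.raises(ValueError):
            call_losses([1.0], psi=0.0)

    def test_monotone_in_factor(self, genome_small, sets_small):
        cohort = cl.simulate_cohort_truth(genome_small, sets_small, 5,
                                          seed=41)
        prev = None
        for factor in (0.9, 0.7, 0.5, 0.3):
            n = 0
            for t in cohort:
                tot = (t.segments.nA + t.segments.nB).to_numpy(float)
                n += int(call_losses(tot, t.psi_true, factor).sum())
            if prev is not None:
                assert n <= prev
            prev = n


class TestCallLoh:
    @pytest.mark.parametrize("nA,nB,expected", [
        (2, 0, True),    # copy-neutral LOH
        (1, 1, False),
        (1, 0, True),
        (0, 0, True),    # homozygous deletion counts as LOH (and loss)
    ])
    def test_loh_definition(self, nA, nB, expected):
        assert call_loh([nB])[0] is np.bool_(expected)

    def test_homdel_is_both_loss_and_loh(self):
        assert call_losses([0.0], psi=2.0)[0]
        assert call_loh([0.0])[0]


class TestGenomeFractions:
    def test_diploid_zero_fractions(self):
        segs = _segs(("chr1", 0, 10_000_000, 1, 1))
        assert genome_fractions(segs, psi=2.0) == (0.0, 0.0)

    def test_one_tenth_lost_and_loh(self):
        # 10 equal chromosomes, one fully (1,0): psi = 1.95
        rows = [(f"chr{i+1}", 0, 10_000_000, 1, 1) for i in range(9)]
        rows.append(("chr10", 0, 10_000_000, 1, 0))
        segs = _segs(*rows)
        psi = 1.95
        lost, loh = genome_fractions(segs, psi)
        assert lost == pytest.approx(0.1)
        assert loh == pytest.approx(0.1)

    def test_whole_genome_copy_neutral_loh(self):
        segs = _segs(("chr1", 0, 10_000_000, 2, 0))
        lost, loh = genome_fractions(segs, psi=2.0)
        assert (lost, loh) == (0.0, 1.0)

    def test_sex_chromosomes_excluded(self):
        segs = _segs(("chr1", 0, 10_000_000, 1, 1),
                     ("chrX", 0, 10_000_000, 1, 0))
        lost, loh = genome_fractions(segs, psi=2.0)
        assert (lost, loh) == (0.0, 0.0)


class TestLossFrequency:
    def _mini_genome(self):
        return cl.make_genome(seed=5, chrom_sizes=[10_000_000],
                              snp_spacing=100_000, n_genes=10)

    def test_no_losses_all_zero(self):
        g = self._mini_genome()
        cohort = {f"S{i}": (_segs(("chr1", 0, 10_000_000, 1, 1)), 2.0)
                  for i in range(5)}
        track = loss_frequency(cohort, g)
        assert (track.frequency == 0).all()

    def test_shared_arm_loss_counted(self):
        g = self._mini_genome()
        cohort = {}
        for i in range(10):
            if i < 3:
                segs = _segs(("chr1", 0, 5_000_000, 1, 0),
                             ("chr1", 5_000_000, 10_000_000, 1, 1))
            else:
                segs = _segs(("chr1", 0, 10_000_000, 1, 1))
            cohort[f"S{i}"] = (segs, 2.0)
        track = loss_frequency(cohort, g)
        left = track[track.pos < 5_000_000]
        right = track[track.pos >= 5_000_000]
        np.testing.assert_allclose(left.frequency, 0.3)
        assert (right.frequency == 0).all()

    def test_unassessable_tumor_excluded_from_denominator(self):
        g = self._mini_genome()
        cohort = {}
        for i in range(10):
            if i < 3:
                segs = _segs(("chr1", 0, 10_000_000, 1, 0))
            elif i == 9:  # no segments on the first half
                segs = _segs(("chr1", 5_000_000, 10_000_000, 1, 1))
            else:
                segs = _segs(("chr1", 0, 10_000_000, 1, 1))
            cohort[f"S{i}"] = (segs, 2.0)
        track = loss_frequency(cohort, g)
        left = track[track.pos < 5_000_000]
        assert (left.n_assessable == 9).all()
        np.testing.assert_allclose(left.frequency, 3 / 9)


def _uniform_track(freqs, spacing=100_000):
    pos = np.arange(len(freqs)) * spacing + spacing // 2
    return pd.DataFrame({"chrom": "chr1", "pos": pos,
                         "n_loss": 0, "n_assessable": 10,
                         "frequency": freqs})


class TestRecurrentRegions:
    def test_uniform_low_track_empty(self):
        track = _uniform_track([0.1] * 100)
        assert recurrent_loss_regions(track) == []

    def test_two_mb_run_reported_with_max(self):
        freqs = [0.05] * 20 + [0.25] * 21 + [0.05] * 20
        track = _uniform_track(freqs)
        regions = recurrent_loss_regions(track)
        assert len(regions) == 1
        assert regions[0].max_frequency == pytest.approx(0.25)
        assert regions[0].size_mb > 2.0

    def test_exactly_one_mb_excluded_strictly(self):
        # run spanning exactly 1.0 Mb: excluded ("larger than" is strict)
        freqs = [0.0] * 20 + [0.3] * 10 + [0.0] * 20
        track = _uniform_track(freqs, spacing=100_000)
        # span = last - first + 1 = 9 * 100 kb + 1 -> 0.9 Mb; widen to 1.0:
        freqs = [0.0] * 20 + [0.3] * 11 + [0.0] * 20
        track = _uniform_track(freqs, spacing=100_000)
        regions = recurrent_loss_regions(track, min_freq=0.2, min_size_mb=1.0)
        spans = [r.size_mb for r in regions]
        assert all(s > 1.0 for s in spans)

    def test_gap_merging(self):
        # two hot runs separated by a 0.3 Mb cold gap -> merged
        freqs = [0.3] * 10 + [0.05] * 3 + [0.3] * 10
        track = _uniform_track(freqs, spacing=100_000)
        regions = recurrent_loss_regions(track, gap_mb=0.5)
        assert len(regions) == 1

    def test_raising_min_freq_shrinks_coverage(self):
        """Regions at a stricter threshold are contained in the union of
        regions at a looser one (gap merging can fragment a region, so
        the count itself is not monotone — coverage is)."""
        rng = np.random.default_rng(3)
        freqs = rng.uniform(0, 0.5, 500)
        track = _uniform_track(freqs)
        prev_union = None
        for mf in (0.1, 0.2, 0.3, 0.4):
            regions = recurrent_loss_regions(track, min_freq=mf)
            union = set()
            for r in regions:
                union |= set(range(r.start // 100_000, r.end // 100_000 + 1))
            if prev_union is not None:
                assert union <= prev_union
            prev_union = union


class TestAnnotateRegions:
    def test_membership_and_straddle(self):
        from cnaloss.calls import RegionSummary
        genes = _genes(("G1", "chr1", 100, 200),
                       ("G2", "chr1", 950, 1100),   # straddles the boundary
                       ("G3", "chr1", 2000, 2100))  # outside
        regions = [RegionSummary("chr1", 0, 1000, 0.001, 0.3)]
        table = annotate_regions(regions, genes,
                                 {"stop_like": ["G1", "G2", "G3"]})
        assert table.loc[0, "n_stop_like"] == 2
        assert table.loc[0, "stop_like"] == "G1,G2"

    def test_region_without_members_empty(self):
        from cnaloss.calls import RegionSummary
        genes = _genes(("G1", "chr1", 100, 200))
        regions = [RegionSummary("chr2", 0, 1000, 0.001, 0.3)]
        table = annotate_regions(regions, genes, {"stop_like": ["G1"]})
        assert table.loc[0, "n_stop_like"] == 0


class TestCohortCalls:
    def test_conservation_gene_vs_segment_fraction(self, genome_small,
                                                   sets_small):
        """Fraction lost from a dense gene tiling matches the segment-based
        value within tiling resolution."""
        t = cl.simulate_cohort_truth(genome_small, sets_small, 1,
                                     rho_range=(1.0, 1.0), seed=51)[0]
        lost_seg, _ = genome_fractions(t.segments, t.psi_true)
        # tile the genome with 200-kb pseudo-genes
        tiles = []
        for chrom, size in genome_small.chromosomes:
            edges = np.arange(0, size, 200_000)
            for i, s in enumerate(edges[:-1]):
                tiles.append((f"{chrom}_t{i}", chrom, int(s),
                              int(edges[i + 1])))
        tiles = _genes(*tiles)
        gc = gene_copy_number(t.segments, tiles)
        lost_tiles = float(np.mean(
            call_losses(gc.total_cn.to_numpy(), t.psi_true)))
        assert abs(lost_tiles - lost_seg) < 0.02

    def test_stop_like_enriched_in_calls(self, genome_small, sets_small):
        """With in-set rate 0.4 vs background 0.1 over 50 tumors, stop-like
        genes are lost significantly more often (one-sided, p < 0.01)."""
        cohort = cl.simulate_cohort_truth(
            genome_small, sets_small, 50, rho_range=(1.0, 1.0),
            loss_rate_in_set=0.4, loss_rate_background=0.1, seed=52)
        gene_calls = cohort_gene_calls(truth_cohort_dict(cohort),
                                       genome_small)
        freq = gene_calls.groupby("gene")["is_loss"].mean()
        f_stop = freq.loc[list(sets_small.stop_like)].astype(float)
        f_bg = freq.loc[list(sets_small.neutral)].astype(float)
        res = stats.mannwhitneyu(f_stop, f_bg, alternative="greater")
        assert res.pvalue < 0.01

    def test_unassessable_propagates_as_na(self):
        segs = _segs(("chr1", 0, 1000, 1, 1))
        genome = cl.make_genome(seed=6, chrom_sizes=[1_000_000],
                                snp_spacing=10_000, n_genes=5)
        calls_df = cohort_gene_calls({"S1": (segs, 2.0)}, genome)
        outside = genome.genes[genome.genes.start >= 1000].gene_id
        sub = calls_df[calls_df.gene.isin(outside)]
        assert sub.total_cn.isna().all()
        assert sub.is_loss.isna().all()
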