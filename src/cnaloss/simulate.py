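"""Synthetic cohorts with known ground truth.

This module generates everything the rest of the package consumes:
a genome backbone (chromosomes, SNP probe positions, gene intervals),
gene-set collections with designated roles, per-tumor ground-truth
allele-specific copy-number profiles, raw LRR/BAF SNP tracks rendered
from those profiles, and gene-by-sample expression matrices coupled to
copy number for a labelled subset of genes.

The generative model for a tumor sample is a two-population mixture: a
fraction ``rho`` of cells carry the aberrant genome (integer allele
copy numbers ``nA >= nB >= 0`` per segment) and the remaining
``1 - rho`` are diploid. At a SNP inside a segment with total tumor
copy number ``n = nA + nB`` the mixture copy number is
``n_mix = 2 (1 - rho) + rho n``, and

* ``LRR  = gamma * log2(n_mix / psi_mix)`` where ``psi_mix`` is the
  SNP-averaged mixture copy number of the whole sample (centering the
  track the way tumor-vs-matched-normal ratios are centered), and
  ``gamma`` is a platform compression factor;
* for a germline-heterozygous SNP,
  ``BAF = (1 - rho + rho nB') / n_mix`` with ``nB'`` equal to ``nB``
  or ``nA`` depending on a per-segment random phase, so BAF is
  symmetric about 0.5;
* germline-homozygous SNPs have BAF near 0 or 1.

Gaussian noise is added to both signals and BAF is clipped to [0, 1].
All randomness is driven by explicit integer seeds.

Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenomeModel",
    "TruthProfile",
    "GeneSetCollection",
    "SnpTrack",
    "make_genome",
    "make_gene_sets",
    "simulate_cohort_truth",
    "render_snp_track",
    "simulate_expression",
]

#: Total-copy-number threshold factor defining a loss, relative to ploidy.
LOSS_FACTOR = 0.7


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomeModel:
    """Chromosomes, SNP probe positions and gene intervals.

    chromosomes: list of (name, length_bp).
    snp_positions: chrom -> sorted int array of probe positions (bp).
    genes: DataFrame with columns gene_id, chrom, start, end
        (0-based half-open), one row per gene, unique gene_ids.
    """

    chromosomes: tuple
    snp_positions: dict
    genes: pd.DataFrame

    def __post_init__(self):
        sizes = dict(self.chromosomes)
        for chrom, pos in self.snp_positions.items():
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"SNP positions not strictly increasing on {chrom}")
            if len(pos) and (pos[0] < 0 or pos[-1] >= sizes[chrom]):
                raise ValueError(f"SNP positions outside chromosome {chrom}")
        g = self.genes
        if g["gene_id"].duplicated().any():
            raise ValueError("duplicate gene_ids")
        for _, row in g.iterrows():
            if not (0 <= row.start < row.end <= sizes[row.chrom]):
                raise ValueError(f"gene {row.gene_id} outside chromosome {row.chrom}")

    @property
    def chrom_names(self):
        return [c for c, _ in self.chromosomes]

    def chrom_size(self, chrom: str) -> int:
        return dict(self.chromosomes)[chrom]

    @property
    def total_bp(self) -> int:
        return sum(s for _, s in self.chromosomes)

    @property
    def n_snps(self) -> int:
        return sum(len(p) for p in self.snp_positions.values())


@dataclass
class TruthProfile:
    """Ground-truth allele-specific profile of one simulated tumor.

    segments tile [0, chrom_length) on every chromosome, sorted and
    non-overlapping, with integer nA >= nB >= 0.
    """

    sample_id: str
    rho: float
    segments: pd.DataFrame  # chrom, start, end, nA, nB
    psi_true: float = field(default=np.nan)

    def __post_init__(self):
        s = self.segments
        if ((s.nA < s.nB) | (s.nB < 0)).any():
            raise ValueError("segments must satisfy nA >= nB >= 0")
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError("rho must be in [0, 1]")
        if np.isnan(self.psi_true):
            self.psi_true = self.recompute_psi()

    def recompute_psi(self) -> float:
        """Length-weighted mean total copy number over all segments."""
        s = self.segments
        length = (s.end - s.start).to_numpy(float)
        total = (s.nA + s.nB).to_numpy(float)
        return float((length * total).sum() / length.sum())


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets plus the designated simulation roles."""

    sets: dict  # name -> list of gene_ids
    stop_like: tuple
    cyclops_like: tuple
    neutral: tuple

    def __post_init__(self):
        if set(self.stop_like) & set(self.cyclops_like):
            raise ValueError("stop_like and cyclops_like must be disjoint")


@dataclass
class SnpTrack:
    """Per-SNP LRR/BAF observations for one tumor/normal pair.

    df columns: chrom, pos, lrr, baf, is_het; sorted by (chrom, pos).
    """

    sample_id: str
    df: pd.DataFrame

    def __post_init__(self):
        d = self.df
        if ((d.baf < 0) | (d.baf > 1)).any():
            raise ValueError("BAF outside [0, 1]")

    @property
    def n_snps(self) -> int:
        return len(self.df)


# ---------------------------------------------------------------------------
# genome and gene sets
# ---------------------------------------------------------------------------

def make_genome(seed: int, chrom_sizes, snp_spacing: int, n_genes: int,
                gene_length: int | None = None) -> GenomeModel:
    """Build a genome backbone with evenly spaced SNPs and random genes.

    SNPs are placed every ``snp_spacing`` bp starting at ``snp_spacing/2``.
    Genes are placed uniformly without overlap; each gene spans at least
    one SNP (gene length defaults to 3x the SNP spacing).
    """
    if snp_spacing <= 0:
        raise ValueError("snp_spacing must be positive")
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = np.random.default_rng(seed)
    chromosomes = tuple((f"chr{i + 1}", int(s)) for i, s in enumerate(chrom_sizes))
    snp_positions = {
        name: np.arange(snp_spacing // 2, size, snp_spacing, dtype=np.int64)
        for name, size in chromosomes
    }
    total = sum(s for _, s in chromosomes)
    # genes per chromosome proportional to length
    quota = [int(round(n_genes * s / total)) for _, s in chromosomes]
    while sum(quota) < n_genes:
        quota[int(np.argmax([s for _, s in chromosomes]))] += 1
    while sum(quota) > n_genes:
        quota[int(np.argmax(quota))] -= 1
    if gene_length is not None:
        glen = int(gene_length)
    else:
        # 3x the SNP spacing, shrunk when gene slots are tight
        slot_min = min(size // k for (_, size), k in zip(chromosomes, quota)
                       if k > 0)
        glen = max(min(3 * snp_spacing, slot_min // 2), snp_spacing // 2, 1)
    rows = []
    gi = 0
    for (name, size), k in zip(chromosomes, quota):
        if k == 0:
            continue
        slot = size // k
        if slot < glen:
            raise ValueError(
                f"chromosome {name} ({size} bp) too small for {k} genes of {glen} bp")
        for j in range(k):
            lo, hi = j * slot, (j + 1) * slot - glen
            start = int(rng.integers(lo, max(lo + 1, hi)))
            # shift so the gene covers >= 1 SNP probe
            pos = snp_positions[name]
            i0 = np.searchsorted(pos, start, "left")
            if i0 == len(pos) or pos[i0] >= start + glen:
                target = pos[min(i0, len(pos) - 1)]
                start = int(min(max(0, target - glen // 2), size - glen))
            rows.append((f"G{gi:05d}", name, start, start + glen))
            gi += 1
    genes = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end"])
    return GenomeModel(chromosomes, snp_positions, genes)


def make_gene_sets(genome: GenomeModel, stop_size: int = 878,
                   cyclops_size: int = 55, seed: int = 0) -> GeneSetCollection:
    """Sample disjoint stop-like and cyclops-like sets without replacement."""
    ids = genome.genes["gene_id"].to_numpy()
    if stop_size + cyclops_size > len(ids):
        raise ValueError("requested set sizes exceed the number of genes")
    rng = np.random.default_rng(seed)
    pick = rng.choice(len(ids), size=stop_size + cyclops_size, replace=False)
    stop = tuple(ids[pick[:stop_size]])
    cyc = tuple(ids[pick[stop_size:]])
    neutral = tuple(np.setdiff1d(ids, np.concatenate([stop, cyc])))
    return GeneSetCollection(
        sets={"stop_like": list(stop), "cyclops_like": list(cyc)},
        stop_like=stop, cyclops_like=cyc, neutral=neutral)


# ---------------------------------------------------------------------------
# cohort truth
# ---------------------------------------------------------------------------

def _apply_interval(segs, chrom, lo, hi, delta_minor, delta_major):
    """Overlay a +/- copy change on [lo, hi) of one chromosome's tiling."""
    out = []
    for (c, s, e, nA, nB) in segs:
        if c != chrom or e <= lo or s >= hi:
            out.append((c, s, e, nA, nB))
            continue
        if s < lo:
            out.append((c, s, lo, nA, nB))
        a, b = max(s, lo), min(e, hi)
        nB2 = nB + delta_minor
        nA2 = nA + delta_major
        if nB2 < 0:          # minor exhausted: take the copy from the major,
            nA2 += nB2       # but never drive the segment to homozygous
            nB2 = 0          # deletion (total 0), which is lethal at scale
        if nA2 < 1 and delta_minor < 0:
            nA2 = 1
        nA2 = max(nA2, 0)
        if nA2 < nB2:
            nA2, nB2 = nB2, nA2
        out.append((c, a, b, nA2, nB2))
        if e > hi:
            out.append((c, hi, e, nA, nB))
    return out


def _coalesce(segs):
    out = []
    for seg in segs:
        if out and out[-1][0] == seg[0] and out[-1][2] == seg[1] \
                and out[-1][3:] == seg[3:]:
            prev = out.pop()
            out.append((prev[0], prev[1], seg[2], seg[3], seg[4]))
        else:
            out.append(seg)
    return out


def _draw_segment(rng, genome, min_len=1_000_000, max_len=None,
                  center_gene=None):
    """A contiguous interval with log-uniform length between min_len and
    max_len (default: half the chromosome, i.e. arm scale), optionally
    covering a given gene."""
    if center_gene is not None:
        chrom = center_gene.chrom
    else:
        sizes = np.array([s for _, s in genome.chromosomes], float)
        chrom = genome.chrom_names[rng.choice(len(sizes), p=sizes / sizes.sum())]
    size = genome.chrom_size(chrom)
    hi = max(min_len + 1, size // 2 if max_len is None else min(max_len, size))
    length = int(np.exp(rng.uniform(np.log(min_len), np.log(hi))))
    length = min(length, size)
    if center_gene is not None:
        glo, ghi = int(center_gene.start), int(center_gene.end)
        lo_min = max(0, ghi - length)
        lo_max = min(size - length, glo)
        lo = int(rng.integers(lo_min, max(lo_min + 1, lo_max + 1)))
    else:
        lo = int(rng.integers(0, max(1, size - length + 1)))
    return chrom, lo, lo + length


def simulate_cohort_truth(genome: GenomeModel, sets: GeneSetCollection,
                          n_tumors: int, rho_range=(0.3, 1.0),
                          ploidy_choices=(2.0,), loss_rate_in_set=0.4,
                          loss_rate_background=0.1, seed: int = 0,
                          min_seg_len: int = 1_000_000,
                          anchor_max_len: int = 5_000_000):
    """Simulate ground-truth profiles for a cohort.

    Losses are contiguous multi-megabase single-copy deletions. Background
    segments are arm-scale (log-uniform between ``min_seg_len`` and half a
    chromosome) and placed uniformly so each gene is covered with
    probability ``loss_rate_background`` in expectation; stop-like genes
    additionally receive focal gene-anchored loss segments (log-uniform
    between ``min_seg_len`` and ``anchor_max_len``) so their total
    per-tumor loss probability is ``loss_rate_in_set`` without flooding
    the rest of the genome. Ploidy targets other than 2 are met by extra
    gains (psi > 2.8 starts from a tetraploid base) or losses spread over
    the genome.
    """
    if not (0 < loss_rate_background <= loss_rate_in_set <= 1):
        raise ValueError("need 0 < loss_rate_background <= loss_rate_in_set <= 1")
    if len(ploidy_choices) == 0:
        raise ValueError("ploidy_choices must be nonempty")
    rng = np.random.default_rng(seed)
    genes = genome.genes.set_index("gene_id")
    stop_genes = genes.loc[list(sets.stop_like)]
    G = genome.total_bp
    # expected background-segment length: mean of log-uniform(a, b_c) per
    # chromosome, (b - a) / ln(b / a), weighted by chromosome size
    sizes = np.array([s for _, s in genome.chromosomes], float)
    a = float(min_seg_len)
    bs = np.maximum(a + 1, sizes / 2)
    e_len = (bs - a) / np.log(bs / a)
    mean_len = float((sizes / sizes.sum() * e_len).sum())
    p_bg = loss_rate_background
    p_extra = (loss_rate_in_set - p_bg) / (1 - p_bg) if p_bg < 1 else 0.0

    profiles = []
    for t in range(n_tumors):
        rho = float(rng.uniform(*rho_range))
        target = float(rng.choice(list(ploidy_choices)))
        base = 2 if target <= 2.8 else 4
        segs = [(c, 0, s, base // 2, base // 2) for c, s in genome.chromosomes]
        # ploidy drift toward the target: +/-1-copy segments covering |delta| of genome
        delta = target - base
        budget = abs(delta) * G
        covered = 0.0
        while covered < budget:
            chrom, lo, hi = _draw_segment(rng, genome, min_seg_len)
            if delta > 0:
                segs = _apply_interval(segs, chrom, lo, hi, 0, +1)
            else:
                segs = _apply_interval(segs, chrom, lo, hi, -1, 0)
            covered += hi - lo
        # background losses
        n_bg = rng.poisson(p_bg * G / mean_len)
        for _ in range(n_bg):
            chrom, lo, hi = _draw_segment(rng, genome, min_seg_len)
            segs = _apply_interval(segs, chrom, lo, hi, -1, 0)
        # focal stop-anchored losses
        for gid, grow in stop_genes.iterrows():
            if rng.random() < p_extra:
                chrom, lo, hi = _draw_segment(
                    rng, genome, min_seg_len, anchor_max_len, center_gene=grow)
                segs = _apply_interval(segs, chrom, lo, hi, -1, 0)
        segs = _coalesce(sorted(segs, key=lambda x: (x[0], x[1])))
        df = pd.DataFrame(segs, columns=["chrom", "start", "end", "nA", "nB"])
        # keep chromosome order stable
        order = {c: i for i, c in enumerate(genome.chrom_names)}
        df = df.sort_values(["chrom", "start"], key=lambda col: col.map(order)
                            if col.name == "chrom" else col).reset_index(drop=True)
        profiles.append(TruthProfile(sample_id=f"T{t:03d}", rho=rho, segments=df))
    return profiles


# ---------------------------------------------------------------------------
# SNP-track rendering
# ---------------------------------------------------------------------------

def render_snp_track(truth: TruthProfile, genome: GenomeModel,
                     gamma: float = 0.55, lrr_sd: float = 0.25,
                     baf_sd: float = 0.03, het_fraction: float = 0.3,
                     seed: int = 0) -> SnpTrack:
    """Render noisy LRR/BAF observations from a ground-truth profile."""
    if not 0 < gamma <= 1:
        raise ValueError("gamma must be in (0, 1]")
    if lrr_sd < 0 or baf_sd < 0:
        raise ValueError("noise SDs must be >= 0")
    if not 0.0 <= truth.rho <= 1.0:
        raise ValueError("rho must be in [0, 1]")
    rng = np.random.default_rng(seed)
    rho = truth.rho
    frames = []
    for chrom in genome.chrom_names:
        pos = genome.snp_positions[chrom]
        segs = truth.segments[truth.segments.chrom == chrom]
        starts = segs.start.to_numpy()
        idx = np.searchsorted(starts, pos, "right") - 1
        nA = segs.nA.to_numpy()[idx].astype(float)
        nB = segs.nB.to_numpy()[idx].astype(float)
        phase = rng.random(len(segs)) < 0.5
        b_is_major = phase[idx]
        n_mix = 2 * (1 - rho) + rho * (nA + nB)
        frames.append(pd.DataFrame({
            "chrom": chrom, "pos": pos, "n_mix": n_mix,
            "nb_prime": np.where(b_is_major, nA, nB)}))
    df = pd.concat(frames, ignore_index=True)
    psi_mix = float(df.n_mix.mean())
    n_mix = df.n_mix.to_numpy()
    lrr = gamma * (np.log2(np.maximum(n_mix, 1e-2)) - np.log2(psi_mix))
    is_het = rng.random(len(df)) < het_fraction
    baf_mean = np.where(is_het,
                        np.where(n_mix > 0,
                                 (1 - rho + rho * df.nb_prime.to_numpy())
                                 / np.maximum(n_mix, 1e-12), 0.5),
                        np.where(rng.random(len(df)) < 0.5, 0.0, 1.0))
    lrr = lrr + rng.normal(0, lrr_sd, len(df)) if lrr_sd > 0 else lrr
    baf = baf_mean + (rng.normal(0, baf_sd, len(df)) if baf_sd > 0 else 0.0)
    out = pd.DataFrame({
        "chrom": df.chrom, "pos": df.pos, "lrr": lrr,
        "baf": np.clip(baf, 0.0, 1.0), "is_het": is_het})
    return SnpTrack(sample_id=truth.sample_id, df=out)


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def simulate_expression(truth_cohort, genome: GenomeModel,
                        coupled_fraction: float = 0.8, slope: float = 1.0,
                        noise_sd: float = 0.5, seed: int = 0):
    """Simulate a gene x sample expression matrix.

    A labelled ``coupled_fraction`` of genes follow
    ``expr = baseline + slope * relative_cn + noise`` where
    ``relative_cn = gene total CN / psi_true``; the rest are
    copy-number-independent. Returns ``(expr_df, coupled)`` where
    ``coupled`` is a boolean Series indexed by gene_id.
    """
    if not 0 <= coupled_fraction <= 1:
        raise ValueError("coupled_fraction must be in [0, 1]")
    from .calls import gene_total_cn_matrix  # local import to avoid cycle
    rng = np.random.default_rng(seed)
    genes = genome.genes
    n_genes = len(genes)
    coupled = pd.Series(rng.random(n_genes) < coupled_fraction,
                        index=genes.gene_id, name="coupled")
    baseline = pd.Series(rng.normal(7.0, 1.0, n_genes), index=genes.gene_id)
    total = gene_total_cn_matrix(
        {p.sample_id: (p.segments, p.psi_true) for p in truth_cohort}, genome)
    rel = total / pd.Series({p.sample_id: p.psi_true for p in truth_cohort})
    expr = pd.DataFrame(
        np.add.outer(baseline.to_numpy(), np.zeros(rel.shape[1])),
        index=rel.index, columns=rel.columns)
    expr[:] += np.where(coupled.to_numpy()[:, None], slope * rel.to_numpy(), 0.0)
    if noise_sd > 0:
        expr[:] += rng.normal(0, noise_sd, expr.shape)
    return expr, coupled
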