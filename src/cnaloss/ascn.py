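"""Allele-specific copy-number estimation from LRR/BAF SNP tracks.

The estimator inverts the two-population mixture model documented in
:mod:`cnaloss.simulate`. Given segment summaries (mean LRR, mean
mirrored BAF over germline-heterozygous SNPs) it scans a grid of
candidate aberrant-cell fractions ``rho`` and tumor ploidies
``psi_t``. At a grid point the mixture ploidy is
``psi_mix = 2 (1 - rho) + rho psi_t`` and the continuous allele copy
numbers of a segment with summaries ``(r, b)`` are::

    n_mix = psi_mix * 2 ** (r / gamma)
    n_tot = (n_mix - 2 (1 - rho)) / rho
    nA    = (b * n_mix - (1 - rho)) / rho        # b folded to [0.5, 1]
    nB    = n_tot - nA

The goodness of a grid point is the informative-SNP-weighted mean
squared distance of ``(nA, nB)`` to the nearest nonnegative integers;
candidate solutions are the local minima of this surface. The usual
whole-genome-doubling degeneracy (doubling every copy number while
moving ``rho`` to ``rho / (2 - rho)`` reproduces the data exactly) is
resolved by preferring the lower-ploidy solution on ties, with an
explicit escape hatch: if the best solution implies more than
``max_homdel_mb`` megabases of homozygous deletion — biologically
implausible — the next-best solution at strictly higher ploidy is
taken instead.

Sample-level quality control mirrors the exclusion taxonomy used for
real arrays: excessively variable LRR, flat BAF (no allelic imbalance
anywhere, as seen with very low tumor content), and low-signal samples
with neither LRR nor BAF divergence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, optimize
from scipy.stats import norm as _norm

from .simulate import SnpTrack

__all__ = [
    "QCThresholds", "QCFlags", "SegmentedTrack", "AscnSolution",
    "qc_sample", "segment_track", "fit_purity_ploidy", "select_solution",
    "average_ploidy", "AllelicCopyNumberModel", "AscnFit",
    "UnassessableSampleError",
]

AUTOSOMES = None  # placeholder: chromosomes named chrX/chrY are dropped


class UnassessableSampleError(RuntimeError):
    """Raised when no allele-specific solution can be produced."""


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class QCThresholds:
    """Thresholds for the three sample-exclusion reasons.

    flat_baf_min_divergent: minimum fraction of het SNPs with
        |BAF - 0.5| > flat_baf_delta for the sample to show imbalance.
    noisy_lrr_max_mad: maximum median absolute successive LRR difference.
    low_lrr_var / low_baf_div: minimal-signal thresholds on the
        segmented track (variance of segment LRR means; weighted mean
        |mirrored BAF - 0.5|).
    """

    flat_baf_delta: float = 0.1
    flat_baf_min_divergent: float = 0.005
    noisy_lrr_max_mad: float = 0.5
    low_lrr_var: float = 0.003
    low_baf_div: float = 0.015


@dataclass(frozen=True)
class QCFlags:
    flat_baf: bool
    noisy_lrr: bool
    low_content: bool
    metrics: dict

    @property
    def passed(self) -> bool:
        return not (self.flat_baf or self.noisy_lrr or self.low_content)

    @property
    def reason(self) -> str | None:
        for name in ("noisy_lrr", "flat_baf", "low_content"):
            if getattr(self, name):
                return name
        return None


def qc_sample(track: SnpTrack, thresholds: QCThresholds | None = None) -> QCFlags:
    """Classify a sample against the three exclusion reasons.

    ``noisy_lrr`` takes precedence (a track that cannot be segmented is
    not interpretable); ``flat_baf`` marks tracks whose heterozygous
    BAFs never diverge from 0.5; ``low_content`` marks tracks that are
    neither but show essentially no segmented LRR variance and no BAF
    divergence.
    """
    th = thresholds or QCThresholds()
    d = track.df
    if len(d) == 0:
        raise ValueError("empty SNP track")
    het = d[d.is_het]
    frac_div = float((np.abs(het.baf - 0.5) > th.flat_baf_delta).mean()) \
        if len(het) else 0.0
    lrr_mad = float(np.median(np.abs(np.diff(d.lrr.to_numpy()))))
    noisy = lrr_mad > th.noisy_lrr_max_mad
    flat = (not noisy) and frac_div < th.flat_baf_min_divergent
    low = False
    metrics = {"frac_divergent_baf": frac_div, "lrr_successive_mad": lrr_mad}
    if not noisy and not flat:
        seg = segment_track(track)
        s = seg.segments
        w = s.n_informative_snps.to_numpy(float)
        w = w / w.sum()
        mu = float((w * s.mean_lrr).sum())
        lrr_var = float((w * (s.mean_lrr - mu) ** 2).sum())
        baf_div = float((w * (s.mean_mirrored_baf - 0.5)).sum())
        metrics.update({"segmented_lrr_var": lrr_var, "segmented_baf_div": baf_div})
        low = lrr_var < th.low_lrr_var and baf_div < th.low_baf_div
    return QCFlags(flat_baf=flat, noisy_lrr=noisy, low_content=low, metrics=metrics)


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

@dataclass
class SegmentedTrack:
    """Piecewise-constant summary of one sample's informative SNPs.

    segments columns: chrom, start, end, mean_lrr, mean_mirrored_baf,
    n_informative_snps. Segments tile the SNP extent of each assessable
    chromosome; mirrored BAF is folded into [0.5, 1].
    """

    sample_id: str
    segments: pd.DataFrame
    unassessable_chroms: tuple = ()


def _binary_segment(z: np.ndarray, min_size: int, threshold: float):
    """Greedy binary segmentation of a (n, d) standardized signal.

    Returns sorted interior changepoint indices. A split is accepted when
    the within-segment SSE reduction exceeds ``threshold``.
    """
    n = z.shape[0]
    breaks = []

    def gain_and_split(lo, hi):
        seg = z[lo:hi]
        m = hi - lo
        if m < 2 * min_size:
            return 0.0, None
        c1 = np.cumsum(seg, axis=0)
        c2 = np.cumsum(seg ** 2, axis=0)
        tot1, tot2 = c1[-1], c2[-1]
        k = np.arange(1, m)  # left sizes
        sse_left = (c2[:-1] - c1[:-1] ** 2 / k[:, None]).sum(axis=1)
        right1 = tot1 - c1[:-1]
        right2 = tot2 - c2[:-1]
        sse_right = (right2 - right1 ** 2 / (m - k)[:, None]).sum(axis=1)
        sse_full = (tot2 - tot1 ** 2 / m).sum()
        gains = sse_full - (sse_left + sse_right)
        valid = (k >= min_size) & (m - k >= min_size)
        gains = np.where(valid, gains, -np.inf)
        s = int(np.argmax(gains))
        return float(gains[s]), lo + s + 1

    stack = [(0, n)]
    while stack:
        lo, hi = stack.pop()
        g, s = gain_and_split(lo, hi)
        if s is not None and g > threshold:
            breaks.append(s)
            stack.append((lo, s))
            stack.append((s, hi))
    return sorted(breaks)


def _folded_baf_mean(baf: np.ndarray, sigma: float) -> float:
    """Unbiased segment BAF divergence from folded per-SNP values.

    The mean of ``|BAF - 0.5|`` is robust to the phase of the imbalance
    (unlike the folded mean, which cancels when a segment mixes
    opposite phases of the same allelic state) but is biased upward by
    noise: for noise SD ``sigma`` and true divergence ``delta``,
    ``E|N(delta, sigma)| = sigma sqrt(2/pi) exp(-delta^2 / 2 sigma^2)
    + delta (1 - 2 Phi(-delta / sigma))``. This inverts that relation.
    """
    m2 = float(np.mean(np.abs(baf - 0.5)))
    if sigma <= 0 or m2 <= 0:
        return 0.5 + m2

    def mean_abs(delta):
        return (sigma * np.sqrt(2 / np.pi) * np.exp(-delta ** 2 / (2 * sigma ** 2))
                + delta * (1 - 2 * _norm.cdf(-delta / sigma)))

    if m2 <= mean_abs(0.0):
        return 0.5
    hi = m2 + 4 * sigma
    try:
        delta = optimize.brentq(lambda d: mean_abs(d) - m2, 0.0, hi,
                                xtol=1e-9)
    except ValueError:  # degenerate bracket: bias negligible
        delta = m2
    return 0.5 + float(min(delta, m2))


def _robust_sd(x: np.ndarray) -> float:
    """Noise SD from successive differences, immune to segment steps."""
    d = np.diff(x)
    if len(d) == 0:
        return 0.0
    return float(1.4826 * np.median(np.abs(d)) / np.sqrt(2))


def segment_track(track: SnpTrack, penalty: float = 10.0,
                  min_snps: int = 5, drop_sex_chroms: bool = True) -> SegmentedTrack:
    """Joint changepoint segmentation of (LRR, mirrored BAF).

    Both signals are evaluated at germline-heterozygous SNPs only,
    standardized by a robust successive-difference noise estimate, and
    segmented per chromosome with greedy binary splitting; the
    acceptance threshold for a split is ``penalty * log(n_het)``.
    Chromosome boundaries are always changepoints. Chromosomes without
    heterozygous SNPs are reported as unassessable.
    """
    rows = []
    unassessable = []
    d = track.df
    for chrom, sub in d.groupby("chrom", sort=False):
        if drop_sex_chroms and str(chrom).lstrip("chr") in ("X", "Y"):
            continue
        het = sub[sub.is_het]
        if len(het) < max(1, min_snps):
            unassessable.append(chrom)
            continue
        lrr = het.lrr.to_numpy()
        mbaf = 0.5 + np.abs(het.baf.to_numpy() - 0.5)
        pos = het.pos.to_numpy()
        all_pos = sub.pos.to_numpy()
        all_lrr = sub.lrr.to_numpy()
        sd_l = max(_robust_sd(lrr), 1e-4)
        sd_b = max(_robust_sd(mbaf), 1e-4)
        sd_raw_baf = _robust_sd(het.baf.to_numpy())
        z = np.column_stack([lrr / sd_l, mbaf / sd_b])
        thr = penalty * np.log(max(len(het), 3))
        breaks = _binary_segment(z, min_snps, thr) if len(het) >= 2 * min_snps else []
        bounds = [0] + breaks + [len(het)]
        ext_lo = int(sub.pos.min())
        ext_hi = int(sub.pos.max()) + 1
        for i in range(len(bounds) - 1):
            a, b = bounds[i], bounds[i + 1]
            start = ext_lo if i == 0 else int((pos[a - 1] + pos[a]) // 2)
            end = ext_hi if i == len(bounds) - 2 else int((pos[b - 1] + pos[b]) // 2)
            seg_baf = het.baf.to_numpy()[a:b]
            # total-copy signal is carried by every probe, so the segment
            # LRR mean uses all SNPs — but only between the segment's first
            # and last het SNP, where assignment is unambiguous
            j0 = np.searchsorted(all_pos, pos[a])
            j1 = np.searchsorted(all_pos, pos[b - 1], "right")
            mean_lrr = float(np.mean(all_lrr[j0:j1])) if j1 > j0 \
                else float(np.mean(lrr[a:b]))
            rows.append((chrom, start, end, mean_lrr,
                         _folded_baf_mean(seg_baf, sd_raw_baf),
                         b - a))
    segments = pd.DataFrame(rows, columns=[
        "chrom", "start", "end", "mean_lrr", "mean_mirrored_baf",
        "n_informative_snps"])
    return SegmentedTrack(sample_id=track.sample_id, segments=segments,
                          unassessable_chroms=tuple(unassessable))


# ---------------------------------------------------------------------------
# purity/ploidy fit
# ---------------------------------------------------------------------------

@dataclass
class AscnSolution:
    """One candidate allele-specific solution for a sample."""

    sample_id: str
    rho: float
    psi: float            # SNP-weighted mean total copy number of the fit
    psi_t_grid: float     # the grid tumor-ploidy at which it was found
    segments: pd.DataFrame  # chrom, start, end, nA, nB, n_snps
    goodness: float
    reliability: np.ndarray = field(repr=False, default=None)
    homdel_mb: float = 0.0
    warning: str | None = None

    def __post_init__(self):
        s = self.segments
        if ((s.nA < s.nB) | (s.nB < 0)).any():
            raise ValueError("solution segments must satisfy nA >= nB >= 0")
        if not 0 < self.rho <= 1:
            raise ValueError("rho must be in (0, 1]")


def _continuous_copy_numbers(r, b, rho, psi_t, gamma):
    psi_mix = 2 * (1 - rho) + rho * psi_t
    n_mix = psi_mix * np.exp2(r / gamma)
    n_tot = (n_mix - 2 * (1 - rho)) / rho
    nA = (b * n_mix - (1 - rho)) / rho
    nB = n_tot - nA
    return nA, nB


def _trimmed_goodness(dA, dB, W, frac_trim: float):
    """Weighted mean squared residual, dropping the worst-fitting
    segments up to a ``frac_trim`` weight budget.

    Broadcasts over leading grid axes. Trimming makes the surface
    robust to the few segments that straddle a sub-resolution true
    breakpoint; because it is applied identically at every grid point
    it cannot favor one solution family over another.
    """
    d2 = dA ** 2 + dB ** 2
    order = np.argsort(-d2, axis=-1)
    d2s = np.take_along_axis(d2, order, axis=-1)
    Ws = np.broadcast_to(W, d2.shape)
    Ws = np.take_along_axis(Ws, order, axis=-1)
    cumw = np.cumsum(Ws, axis=-1)
    dropped = cumw <= frac_trim
    keep_w = (Ws * ~dropped).sum(axis=-1)
    kept = (Ws * d2s * ~dropped).sum(axis=-1)
    return kept / keep_w


def goodness_at(seg: SegmentedTrack, rho: float, psi_t: float,
                gamma: float = 0.55, min_fit_snps: int = 10,
                frac_trim: float = 0.03) -> float:
    """Weighted mean squared distance of the continuous allele copy
    numbers to the nearest nonnegative integers at one (rho, psi_t).

    Segments with fewer than ``min_fit_snps`` informative SNPs are
    excluded: such segments often straddle a true breakpoint the
    segmentation could not place at this resolution, and their mixture
    means would otherwise bias the surface toward genome-doubled
    aliases of the true solution.
    """
    s = seg.segments
    keep = s.n_informative_snps.to_numpy() >= min_fit_snps
    if not keep.any():
        keep = np.ones(len(s), bool)
    r = s.mean_lrr.to_numpy(float)[keep]
    b = s.mean_mirrored_baf.to_numpy(float)[keep]
    w = s.n_informative_snps.to_numpy(float)[keep]
    w = w / w.sum()
    nA, nB = _continuous_copy_numbers(r, b, rho, psi_t, gamma)
    dA = nA - np.clip(np.round(nA), 0, None)
    dB = nB - np.clip(np.round(nB), 0, None)
    return float(_trimmed_goodness(dA, dB, w, frac_trim))


def fit_purity_ploidy(seg: SegmentedTrack, rho_grid=None, psi_grid=None,
                      gamma: float = 0.55, min_fit_snps: int = 10,
                      frac_trim: float = 0.03):
    """Grid-scan (rho, psi_t) and return candidate solutions.

    Candidates are grid points whose goodness is a local minimum
    (strictly below all 8 neighbors; equal-valued plateaus are
    represented by their lowest-psi, highest-rho cell), sorted by
    ascending goodness with ties broken toward lower ploidy. Returns an
    empty list with no error when the genome shows no aberration signal
    at all (every segment balanced and flat), which makes the two
    parameters unidentifiable.
    """
    s = seg.segments
    if len(s) == 0:
        raise ValueError("empty segmented track")
    all_r = s.mean_lrr.to_numpy(float)
    all_b = s.mean_mirrored_baf.to_numpy(float)
    all_w = s.n_informative_snps.to_numpy(float)
    length_mb = (s.end - s.start).to_numpy(float) / 1e6
    keep = s.n_informative_snps.to_numpy() >= min_fit_snps
    if not keep.any():
        keep = np.ones(len(s), bool)
    r, b, w = all_r[keep], all_b[keep], all_w[keep]
    if np.all(np.abs(b - 0.5) < 5e-3) and (r.max() - r.min()) < 1e-2:
        return []  # all-balanced, flat: (rho, psi) unidentifiable
    rho_grid = np.round(np.arange(0.10, 1.0001, 0.01), 10) \
        if rho_grid is None else np.asarray(rho_grid, float)
    psi_grid = np.round(np.arange(1.0, 5.5001, 0.05), 10) \
        if psi_grid is None else np.asarray(psi_grid, float)
    W = w / w.sum()
    R, P = np.meshgrid(rho_grid, psi_grid, indexing="ij")
    # goodness surface, vectorized over the grid x segments
    nA, nB = _continuous_copy_numbers(
        r[None, None, :], b[None, None, :], R[:, :, None], P[:, :, None], gamma)
    dA = nA - np.clip(np.round(nA), 0, None)
    dB = nB - np.clip(np.round(nB), 0, None)
    goodness = _trimmed_goodness(dA, dB, W[None, None, :], frac_trim)

    # local minima of the surface (8-neighborhood)
    neigh_min = ndimage.minimum_filter(goodness, size=3, mode="nearest")
    is_min = goodness <= neigh_min + 1e-15
    # collapse equal-valued plateaus to one representative cell
    lab, nlab = ndimage.label(is_min)
    candidates = []
    for li in range(1, nlab + 1):
        cells = np.argwhere(lab == li)
        vals = goodness[cells[:, 0], cells[:, 1]]
        cells = cells[vals <= vals.min() + 1e-15]
        # lower psi first, then higher rho
        order = np.lexsort((-cells[:, 0], cells[:, 1]))
        i, j = cells[order[0]]
        candidates.append((float(goodness[i, j]), float(rho_grid[i]),
                           float(psi_grid[j])))

    # refine each grid minimum locally so that the exact whole-genome-
    # doubling degeneracy is decided by noise, not by which alias happens
    # to sit closer to a grid node
    drho = float(np.median(np.diff(rho_grid))) if len(rho_grid) > 1 else 0.01
    dpsi = float(np.median(np.diff(psi_grid))) if len(psi_grid) > 1 else 0.05
    refined = []
    for g, rho, psi_t in candidates:
        # zoom grid around the node, then simplex-polish the best cell
        rz = np.linspace(max(rho - drho, 0.02), min(rho + drho, 1.0), 11)
        pz = np.linspace(max(psi_t - dpsi, 0.5), psi_t + dpsi, 11)
        zoom = [(goodness_at(seg, rr, pp, gamma, min_fit_snps, frac_trim),
                 rr, pp) for rr in rz for pp in pz]
        g0, r0, p0 = min(zoom)
        res = optimize.minimize(
            lambda x: goodness_at(seg, x[0], x[1], gamma, min_fit_snps,
                                  frac_trim),
            x0=[r0, p0], method="Nelder-Mead",
            bounds=[(max(rho - 2 * drho, 0.02), min(rho + 2 * drho, 1.0)),
                    (max(psi_t - 2 * dpsi, 0.5), psi_t + 2 * dpsi)],
            options={"xatol": 1e-6, "fatol": 1e-16, "maxiter": 400})
        best = min((g, rho, psi_t), (g0, r0, p0),
                   (float(res.fun), float(res.x[0]), float(res.x[1])))
        refined.append(best)

    sols = []
    for g, rho, psi_t in refined:
        cnA, cnB = _continuous_copy_numbers(all_r, all_b, rho, psi_t, gamma)
        iA = np.clip(np.round(cnA), 0, None).astype(int)
        iB = np.clip(np.round(cnB), 0, None).astype(int)
        swap = iA < iB
        iA2 = np.where(swap, iB, iA)
        iB2 = np.where(swap, iA, iB)
        resid = np.sqrt((cnA - iA) ** 2 + (cnB - iB) ** 2)
        reliability = 1.0 - np.minimum(resid / np.sqrt(0.5), 1.0)
        segments = pd.DataFrame({
            "chrom": s.chrom, "start": s.start, "end": s.end,
            "nA": iA2, "nB": iB2, "n_snps": s.n_informative_snps})
        psi = float((all_w * (iA2 + iB2)).sum() / all_w.sum())
        homdel = float(length_mb[(iA2 + iB2) == 0].sum())
        sols.append(AscnSolution(
            sample_id=seg.sample_id, rho=rho, psi=psi, psi_t_grid=psi_t,
            segments=segments, goodness=g, reliability=reliability,
            homdel_mb=homdel))
    # ascending goodness; then, because a genome-doubled alias of the true
    # solution fits almost as well when some segments straddle missed
    # breakpoints (while a genuinely distinct solution fits far worse),
    # candidates within 1.5x of the best goodness are treated as ties and
    # resolved toward lower ploidy, then higher rho
    sols.sort(key=lambda x: x.goodness)
    if sols:
        gmin = sols[0].goodness
        cut = max(1.5 * gmin, gmin + 1e-9)
        near = [s for s in sols if s.goodness <= cut]
        winner = min(near, key=lambda x: (x.psi, -x.rho))
        sols.remove(winner)
        sols.insert(0, winner)
    return sols


def select_solution(candidates, max_homdel_mb: float = 10.0) -> AscnSolution:
    """Pick the reported solution, applying the homozygous-deletion rule.

    The best-goodness candidate wins unless it implies more than
    ``max_homdel_mb`` Mb of homozygous deletion, in which case the next
    best candidate at strictly higher average ploidy and admissible
    homozygous-deletion load is taken. If no such candidate exists the
    best is returned with a warning recorded on the solution.
    """
    if not candidates:
        raise UnassessableSampleError("no candidate solutions")
    best = candidates[0]
    if best.homdel_mb <= max_homdel_mb:
        return best
    for cand in candidates[1:]:
        if cand.psi > best.psi and cand.homdel_mb <= max_homdel_mb:
            return cand
    best.warning = (f"all candidates exceed {max_homdel_mb} Mb of "
                    "homozygous deletion; best kept")
    return best


def average_ploidy(solution: AscnSolution) -> float:
    """Informative-SNP-weighted mean total copy number of a solution."""
    s = solution.segments
    w = s.n_snps.to_numpy(float)
    if w.sum() == 0:
        raise ValueError("solution has no informative SNPs")
    return float((w * (s.nA + s.nB)).sum() / w.sum())


# ---------------------------------------------------------------------------
# model / results facade
# ---------------------------------------------------------------------------

class AllelicCopyNumberModel:
    """Purity/ploidy/copy-number model for one LRR/BAF SNP track.

    Parameters
    ----------
    track : SnpTrack
        Observed per-SNP LRR/BAF with germline-heterozygosity flags.
    gamma : float
        Platform compression factor of the LRR response.
    qc_thresholds, penalty, min_snps, rho_grid, psi_grid, max_homdel_mb :
        Passed through to :func:`qc_sample`, :func:`segment_track`,
        :func:`fit_purity_ploidy` and :func:`select_solution`.
    """

    def __init__(self, track: SnpTrack, gamma: float = 0.55,
                 qc_thresholds: QCThresholds | None = None,
                 penalty: float = 10.0, min_snps: int = 5,
                 rho_grid=None, psi_grid=None, max_homdel_mb: float = 10.0):
        self.track = track
        self.gamma = gamma
        self.qc_thresholds = qc_thresholds or QCThresholds()
        self.penalty = penalty
        self.min_snps = min_snps
        self.rho_grid = rho_grid
        self.psi_grid = psi_grid
        self.max_homdel_mb = max_homdel_mb

    def qc(self) -> QCFlags:
        return qc_sample(self.track, self.qc_thresholds)

    def fit(self, skip_qc: bool = False) -> "AscnFit":
        """Run QC, segmentation, the grid fit, and solution selection."""
        flags = None
        if not skip_qc:
            flags = self.qc()
            if not flags.passed:
                raise UnassessableSampleError(
                    f"sample {self.track.sample_id} failed QC: {flags.reason}")
        seg = segment_track(self.track, self.penalty, self.min_snps)
        candidates = fit_purity_ploidy(seg, self.rho_grid, self.psi_grid,
                                       self.gamma)
        if not candidates:
            raise UnassessableSampleError(
                f"sample {self.track.sample_id}: no aberration signal, "
                "(rho, psi) unidentifiable")
        chosen = select_solution(candidates, self.max_homdel_mb)
        return AscnFit(self, seg, candidates, chosen, flags)


class AscnFit:
    """Results of :meth:`AllelicCopyNumberModel.fit`.

    Exposes the chosen solution's parameters plus the full candidate
    list, the segmented track, and QC flags.
    """

    def __init__(self, model, segmented, candidates, solution, qc_flags):
        self.model = model
        self.segmented = segmented
        self.candidates = candidates
        self.solution = solution
        self.qc_flags = qc_flags

    @property
    def rho(self) -> float:
        return self.solution.rho

    @property
    def psi(self) -> float:
        return self.solution.psi

    @property
    def segments(self) -> pd.DataFrame:
        return self.solution.segments

    def summary(self) -> str:
        s = self.solution
        lines = [
            f"Allele-specific copy-number fit: sample {s.sample_id}",
            f"  aberrant cell fraction rho  {s.rho:6.2f}",
            f"  average ploidy psi          {s.psi:6.3f}",
            f"  goodness of fit             {s.goodness:9.3e}",
            f"  homozygous deletion (Mb)    {s.homdel_mb:6.1f}",
            f"  segments                    {len(s.segments):4d}",
            f"  candidate solutions         {len(self.candidates):4d}",
        ]
        if s.warning:
            lines.append(f"  warning: {s.warning}")
        return "\n".join(lines)
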