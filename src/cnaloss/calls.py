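"""Loss/LOH calling, genome fractions, frequency tracks, recurrent regions.

A *loss* is any gene or segment whose total copy number is strictly
below ``factor * psi`` (default factor 0.7), i.e. the threshold scales
with each sample's average ploidy so that, for example, a single-copy
deletion in a near-triploid tumor is still recognized. *LOH* is a
minor-allele copy number of zero, which deliberately includes both
copy-neutral LOH and homozygous deletions.

Gene-level total copy number is the length-weighted mean of the
overlapping segments (a sliver of loss inside a gene should not call
the whole gene lost); minor copy number is the minimum over overlapping
segments (any overlapping LOH segment confers LOH). Genes falling in a
segment-free gap are unassessable and propagate as missing values.

All cohort summaries are computed over autosomes, and frequency tracks
are evaluated at SNP positions, the native resolution of the data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "gene_copy_number", "gene_total_cn_matrix", "call_losses", "call_loh",
    "genome_fractions", "loss_frequency", "recurrent_loss_regions",
    "annotate_regions", "cohort_gene_calls", "RegionSummary",
]


def _is_autosome(chrom: str) -> bool:
    return str(chrom).lstrip("chr") not in ("X", "Y")


# ---------------------------------------------------------------------------
# segment -> gene projection
# ---------------------------------------------------------------------------

def _chrom_arrays(segments: pd.DataFrame):
    """Per-chromosome sorted arrays for fast interval queries."""
    out = {}
    for chrom, sub in segments.groupby("chrom", sort=False):
        sub = sub.sort_values("start")
        out[chrom] = (sub.start.to_numpy(np.int64), sub.end.to_numpy(np.int64),
                      (sub.nA + sub.nB).to_numpy(float), sub.nB.to_numpy(float))
    return out


def gene_copy_number(segments: pd.DataFrame, genes: pd.DataFrame) -> pd.DataFrame:
    """Project segmental (nA, nB) onto genes.

    Returns a DataFrame indexed by gene_id with columns ``total_cn``
    (overlap-length-weighted mean of segment totals) and ``minor_cn``
    (minimum minor copy number over overlapping segments). Genes with
    no overlapping segment get NaN in both.
    """
    arrays = _chrom_arrays(segments)
    total = np.full(len(genes), np.nan)
    minor = np.full(len(genes), np.nan)
    for k, (gid, chrom, gs, ge) in enumerate(
            genes[["gene_id", "chrom", "start", "end"]].itertuples(index=False)):
        if chrom not in arrays:
            continue
        starts, ends, tot, nb = arrays[chrom]
        i0 = np.searchsorted(ends, gs, "right")
        i1 = np.searchsorted(starts, ge, "left")
        if i1 <= i0:
            continue
        ov = np.minimum(ends[i0:i1], ge) - np.maximum(starts[i0:i1], gs)
        ov = np.clip(ov, 0, None).astype(float)
        if ov.sum() <= 0:
            continue
        total[k] = float((ov * tot[i0:i1]).sum() / ov.sum())
        minor[k] = float(nb[i0:i1].min())
    return pd.DataFrame({"total_cn": total, "minor_cn": minor},
                        index=pd.Index(genes.gene_id, name="gene_id"))


def gene_total_cn_matrix(cohort: dict, genome) -> pd.DataFrame:
    """Gene x sample matrix of total copy number.

    ``cohort`` maps sample_id -> (segments DataFrame, psi); only the
    segments are used here. Fully vectorized through cumulative
    length-weighted copy sums, which is exact because segments tile
    each chromosome.
    """
    genes = genome.genes
    cols = {}
    for sample, (segments, _psi) in cohort.items():
        vals = np.full(len(genes), np.nan)
        for chrom, sub in segments.groupby("chrom", sort=False):
            sub = sub.sort_values("start")
            gsel = genes.chrom == chrom
            if not gsel.any():
                continue
            edges = np.append(sub.start.to_numpy(np.int64),
                              sub.end.to_numpy(np.int64)[-1])
            tot = (sub.nA + sub.nB).to_numpy(float)
            cum = np.concatenate([[0.0], np.cumsum(np.diff(edges) * tot)])

            def integral(x):
                i = np.clip(np.searchsorted(edges, x, "right") - 1, 0, len(tot) - 1)
                return cum[i] + (np.clip(x, edges[0], edges[-1]) - edges[i]) * tot[i]

            gs = genes.start.to_numpy(np.int64)[gsel.to_numpy()]
            ge = genes.end.to_numpy(np.int64)[gsel.to_numpy()]
            covered = (np.minimum(ge, edges[-1]) - np.maximum(gs, edges[0]))
            with np.errstate(invalid="ignore"):
                v = (integral(ge) - integral(gs)) / covered
            v = np.where(covered > 0, v, np.nan)
            vals[gsel.to_numpy()] = v
        cols[sample] = vals
    return pd.DataFrame(cols, index=pd.Index(genes.gene_id, name="gene_id"))


# ---------------------------------------------------------------------------
# calls
# ---------------------------------------------------------------------------

def call_losses(total_cn, psi: float, factor: float = 0.7):
    """Loss calls: total copy number strictly below ``factor * psi``."""
    if not 0 < factor <= 1:
        raise ValueError("factor must be in (0, 1]")
    if psi <= 0:
        raise ValueError("psi must be positive")
    return np.asarray(total_cn, float) < factor * psi


def call_loh(minor_cn):
    """LOH calls: minor copy number zero (includes homozygous deletion)."""
    return np.asarray(minor_cn, float) == 0


def cohort_gene_calls(cohort: dict, genome, factor: float = 0.7) -> pd.DataFrame:
    """Long-format gene x sample calls for a cohort.

    ``cohort`` maps sample_id -> (segments DataFrame, psi). Columns:
    gene, sample, total_cn, minor_cn, relative_cn, is_loss, is_loh.
    Unassessable gene/sample pairs carry NaN copy numbers and <NA>
    booleans.
    """
    frames = []
    for sample, (segments, psi) in cohort.items():
        gc = gene_copy_number(segments, genome.genes)
        rel = gc.total_cn / psi
        loss = pd.array(call_losses(gc.total_cn, psi, factor), dtype="boolean")
        loh = pd.array(call_loh(gc.minor_cn), dtype="boolean")
        na = gc.total_cn.isna().to_numpy()
        loss[na] = pd.NA
        loh[na] = pd.NA
        frames.append(pd.DataFrame({
            "gene": gc.index, "sample": sample,
            "total_cn": gc.total_cn.to_numpy(),
            "minor_cn": gc.minor_cn.to_numpy(),
            "relative_cn": rel.to_numpy(),
            "is_loss": loss, "is_loh": loh}))
    return pd.concat(frames, ignore_index=True)


def genome_fractions(segments: pd.DataFrame, psi: float,
                     factor: float = 0.7) -> tuple:
    """(fraction_lost, fraction_loh) over the assessable autosomal extent,
    weighted by base-pair length."""
    s = segments[segments.chrom.map(_is_autosome)]
    length = (s.end - s.start).to_numpy(float)
    if length.sum() <= 0:
        raise ValueError("no assessable autosomal extent")
    total = (s.nA + s.nB).to_numpy(float)
    minor = s.nB.to_numpy(float)
    lost = float(length[call_losses(total, psi, factor)].sum() / length.sum())
    loh = float(length[call_loh(minor)].sum() / length.sum())
    return lost, loh


# ---------------------------------------------------------------------------
# cohort frequency track and recurrent regions
# ---------------------------------------------------------------------------

def loss_frequency(cohort: dict, genome, factor: float = 0.7) -> pd.DataFrame:
    """Per-SNP-position cohort loss frequency.

    ``cohort`` maps sample_id -> (segments, psi). At each autosomal SNP
    position the frequency is (tumors with loss) / (tumors assessable
    there); positions where no tumor is assessable get NaN frequency.
    Columns: chrom, pos, n_loss, n_assessable, frequency.
    """
    if not cohort:
        raise ValueError("empty cohort")
    frames = []
    for chrom in genome.chrom_names:
        if not _is_autosome(chrom):
            continue
        pos = genome.snp_positions[chrom]
        n_loss = np.zeros(len(pos), int)
        n_ok = np.zeros(len(pos), int)
        for sample, (segments, psi) in cohort.items():
            sub = segments[segments.chrom == chrom].sort_values("start")
            if len(sub) == 0:
                continue
            starts = sub.start.to_numpy(np.int64)
            ends = sub.end.to_numpy(np.int64)
            tot = (sub.nA + sub.nB).to_numpy(float)
            idx = np.searchsorted(starts, pos, "right") - 1
            inside = (idx >= 0) & (pos < ends[np.clip(idx, 0, None)])
            n_ok += inside
            lossseg = call_losses(tot, psi, factor)
            n_loss += inside & lossseg[np.clip(idx, 0, None)]
        with np.errstate(invalid="ignore"):
            freq = np.where(n_ok > 0, n_loss / np.maximum(n_ok, 1), np.nan)
        frames.append(pd.DataFrame({"chrom": chrom, "pos": pos,
                                    "n_loss": n_loss, "n_assessable": n_ok,
                                    "frequency": freq}))
    return pd.concat(frames, ignore_index=True)


@dataclass(frozen=True)
class RegionSummary:
    chrom: str
    start: int
    end: int
    size_mb: float
    max_frequency: float


def recurrent_loss_regions(freq_track: pd.DataFrame, min_freq: float = 0.2,
                           min_size_mb: float = 1.0,
                           gap_mb: float = 0.5) -> list:
    """Maximal runs of positions with loss frequency >= ``min_freq``.

    Runs separated by less than ``gap_mb`` megabases are merged; only
    regions spanning strictly more than ``min_size_mb`` are reported,
    each with the maximum frequency attained inside it.
    """
    if len(freq_track) == 0:
        raise ValueError("empty frequency track")
    regions = []
    for chrom, sub in freq_track.groupby("chrom", sort=False):
        sub = sub.sort_values("pos")
        pos = sub.pos.to_numpy(np.int64)
        freq = sub.frequency.to_numpy(float)
        hot = np.where(~np.isnan(freq) & (freq >= min_freq))[0]
        if len(hot) == 0:
            continue
        # split where consecutive hot positions are >= gap_mb apart
        gaps = np.where(np.diff(pos[hot]) >= gap_mb * 1e6)[0]
        for block in np.split(hot, gaps + 1):
            start, end = int(pos[block[0]]), int(pos[block[-1]]) + 1
            size_mb = (end - start) / 1e6
            if size_mb > min_size_mb:
                regions.append(RegionSummary(
                    chrom=str(chrom), start=start, end=end, size_mb=size_mb,
                    max_frequency=float(np.nanmax(freq[block]))))
    return regions


def annotate_regions(regions, genes: pd.DataFrame, gene_sets: dict) -> pd.DataFrame:
    """Attach member genes of each named set to each region.

    A gene belongs to a region iff its interval intersects it. Returns
    one row per region with a comma-separated member column and a count
    column per set name.
    """
    rows = []
    for reg in regions:
        row = {"chrom": reg.chrom, "start": reg.start, "end": reg.end,
               "size_mb": round(reg.size_mb, 3),
               "max_frequency": round(reg.max_frequency, 4)}
        inside = genes[(genes.chrom == reg.chrom) & (genes.start < reg.end)
                       & (genes.end > reg.start)]
        members = set(inside.gene_id)
        for name, ids in gene_sets.items():
            hits = sorted(members & set(ids))
            row[f"n_{name}"] = len(hits)
            row[name] = ",".join(hits)
        rows.append(row)
    cols = ["chrom", "start", "end", "size_mb", "max_frequency"] + \
        [c for name in gene_sets for c in (f"n_{name}", name)]
    return pd.DataFrame(rows, columns=cols)
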