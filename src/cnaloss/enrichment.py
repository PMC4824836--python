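"""Ranked gene-set enrichment of copy-number loss.

The question: do the genes of a candidate set (e.g. suppressors of
proliferation) sit disproportionately at the low-copy-number end of
the genome? Genes are ranked in *increasing* order of their cohort-mean
relative copy number (gene total copy number divided by the sample's
average ploidy), after restricting to genes whose relative copy number
correlates positively with their mRNA expression (Spearman). Ties are
broken by descending Spearman correlation, and residual ties by a
seeded random ordering. A set concentrated at the top of this list
(lowest relative copy number) attains a positive enrichment score.

The enrichment score is the classic, unweighted running-sum statistic:
walking down the ranking, set members add ``1/n_hit`` and non-members
subtract ``1/(N - n_hit)``; the score is the running sum at its point
of maximum absolute deviation (signed). Significance comes from two
resampling routes:

* a permutation null of random same-size gene sets, yielding a
  sign-matched normalized enrichment score (NES) and permutation p;
* an empirical p — the fraction of random same-size sets whose NES
  strictly exceeds the observed NES — reported as ``k / n`` so that,
  e.g., 4 exceedances in 1000 draws gives p = 0.004.

Because residual ties are broken at random, the whole analysis can be
repeated over several orderings and the maximum p reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RankedGeneList", "EnrichmentResult", "mean_relative_cn",
    "cn_expression_correlation", "build_ranked_list",
    "enrichment_score_classic", "permutation_nes",
    "random_set_empirical_p", "enrich", "max_p_over_orderings",
]


# ---------------------------------------------------------------------------
# ranking inputs
# ---------------------------------------------------------------------------

def mean_relative_cn(gene_calls: pd.DataFrame) -> pd.Series:
    """Per-gene mean of relative copy number over assessable samples.

    ``gene_calls`` is the long-format table from
    :func:`cnaloss.calls.cohort_gene_calls`. Genes assessable in no
    sample are excluded.
    """
    m = gene_calls.groupby("gene")["relative_cn"].mean()
    return m.dropna()


def relative_cn_matrix(gene_calls: pd.DataFrame) -> pd.DataFrame:
    """Gene x sample matrix of relative copy number."""
    return gene_calls.pivot(index="gene", columns="sample",
                            values="relative_cn")


def cn_expression_correlation(relative_cn: pd.DataFrame,
                              expression: pd.DataFrame,
                              min_samples: int = 8) -> pd.DataFrame:
    """Per-gene Spearman correlation between copy number and expression.

    Both inputs are gene x sample; samples are aligned by name and an
    alignment error is raised when they do not overlap. Genes with a
    constant copy-number or expression vector (or fewer than
    ``min_samples`` complete pairs) get NaN rho and p, which fails the
    downstream positive-correlation filter.

    The p-value is the usual t-approximation on the rank correlation,
    matching ``scipy.stats.spearmanr``.
    """
    common = relative_cn.columns.intersection(expression.columns)
    if len(common) == 0:
        raise ValueError("no shared samples between copy-number and "
                         "expression matrices")
    genes = relative_cn.index.intersection(expression.index)
    cn = relative_cn.loc[genes, common]
    ex = expression.loc[genes, common]
    valid = cn.notna() & ex.notna()
    n = valid.sum(axis=1).to_numpy()
    # rank within each gene over its valid samples
    cn_r = cn.where(valid).rank(axis=1)
    ex_r = ex.where(valid).rank(axis=1)
    cn_z = cn_r.sub(cn_r.mean(axis=1), axis=0)
    ex_z = ex_r.sub(ex_r.mean(axis=1), axis=0)
    num = (cn_z * ex_z).sum(axis=1)
    den = np.sqrt((cn_z ** 2).sum(axis=1) * (ex_z ** 2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (num / den).to_numpy()
    rho = np.where(den.to_numpy() > 0, rho, np.nan)
    rho = np.where(n >= min_samples, rho, np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = rho * np.sqrt((n - 2) / np.clip(1 - rho ** 2, 1e-300, None))
        p = 2 * stats.t.sf(np.abs(t), np.clip(n - 2, 1, None))
    p = np.where(np.isnan(rho), np.nan, p)
    return pd.DataFrame({"rho": rho, "p": p, "n": n}, index=genes)


@dataclass
class RankedGeneList:
    """Genes ordered for enrichment testing."""

    genes: list
    table: pd.DataFrame  # mean_relative_cn, spearman_rho, spearman_p per gene
    ordering_seed: int

    def __len__(self):
        return len(self.genes)


def build_ranked_list(mean_rel_cn: pd.Series, correlations: pd.DataFrame,
                      filter_alpha: float | None = 0.05,
                      seed: int = 0) -> RankedGeneList:
    """Order genes by ascending mean relative copy number.

    Only genes passing the positive-correlation filter (rho > 0 and
    two-sided Spearman p < ``filter_alpha``) are kept; pass
    ``filter_alpha=None`` to disable the filter entirely. Ties in the
    primary key are broken by descending rho; residual ties by a seeded
    random permutation.
    """
    df = pd.DataFrame({"mean_relative_cn": mean_rel_cn})
    df = df.join(correlations[["rho", "p"]], how="inner")
    if filter_alpha is not None:
        df = df[(df.rho > 0) & (df.p < filter_alpha)]
    if len(df) == 0:
        raise ValueError("no genes pass the positive-correlation filter")
    rng = np.random.default_rng(seed)
    df = df.assign(_jitter=rng.permutation(len(df)))
    df = df.sort_values(["mean_relative_cn", "rho", "_jitter"],
                        ascending=[True, False, True], kind="mergesort")
    table = df.rename(columns={"rho": "spearman_rho", "p": "spearman_p"}) \
        .drop(columns="_jitter")
    return RankedGeneList(genes=list(df.index), table=table,
                          ordering_seed=seed)


# ---------------------------------------------------------------------------
# enrichment statistic
# ---------------------------------------------------------------------------

def enrichment_score_classic(ranked, gene_set) -> tuple:
    """Classic (unweighted) enrichment score and its running-sum trace.

    Hits add ``1/n_hit``; misses subtract ``1/(N - n_hit)``. Returns
    ``(es, running_sum)`` where ``es`` is the signed value of the
    running sum at its maximum absolute deviation.
    """
    genes = ranked.genes if isinstance(ranked, RankedGeneList) else list(ranked)
    members = set(gene_set)
    hits = np.fromiter((g in members for g in genes), bool, len(genes))
    n = len(genes)
    n_hit = int(hits.sum())
    if n_hit == 0 or n_hit == n:
        raise ValueError("gene set intersection with the ranking is empty "
                         "or complete; enrichment undefined")
    step = np.where(hits, 1.0 / n_hit, -1.0 / (n - n_hit))
    running = np.cumsum(step)
    es = float(running[np.argmax(np.abs(running))])
    return es, running


def _es_many(hit_rank_matrix: np.ndarray, n_total: int) -> np.ndarray:
    """Vectorized ES for many same-size sets (rows of sorted hit ranks)."""
    m, n_hit = hit_rank_matrix.shape
    n_miss = n_total - n_hit
    i = np.arange(1, n_hit + 1)[None, :]
    after = i / n_hit - (hit_rank_matrix + 1 - i) / n_miss
    before = (i - 1) / n_hit - (hit_rank_matrix - (i - 1)) / n_miss
    both = np.concatenate([after, before], axis=1)
    idx = np.argmax(np.abs(both), axis=1)
    return both[np.arange(m), idx]


@dataclass
class EnrichmentResult:
    """Enrichment of one gene set against one ranking."""

    set_name: str
    es: float
    nes: float
    perm_p: float
    empirical_p: float | None
    n_perm: int
    n_resample: int
    running_sum: np.ndarray = field(repr=False, default=None)
    n_genes: int = 0
    n_hits: int = 0

    def summary(self) -> str:
        lines = [
            f"Gene-set enrichment: {self.set_name}",
            f"  ranked genes              {self.n_genes:6d}",
            f"  set members in ranking    {self.n_hits:6d}",
            f"  enrichment score (ES)     {self.es:8.4f}",
            f"  normalized ES (NES)       {self.nes:8.4f}",
            f"  permutation p ({self.n_perm} perms)  {self.perm_p:.4g}",
        ]
        if self.empirical_p is not None:
            lines.append(
                f"  random-set empirical p ({self.n_resample} draws)  "
                f"{self.empirical_p:.4g}")
        return "\n".join(lines)


def _null_es(n_total: int, n_hit: int, n_draws: int, rng) -> np.ndarray:
    ranks = np.empty((n_draws, n_hit), dtype=np.int64)
    for j in range(n_draws):
        ranks[j] = np.sort(rng.choice(n_total, size=n_hit, replace=False))
    return _es_many(ranks, n_total)


def permutation_nes(ranked, gene_set, n_perm: int = 1000, seed: int = 0,
                    _es: float | None = None) -> tuple:
    """Normalized enrichment score and permutation p.

    The null is the ES of ``n_perm`` random same-size gene sets drawn
    from the ranked universe. NES = ES / mean(|null ES| of matching
    sign); the permutation p is the fraction of matching-sign null ES
    at least as extreme as the observed one.
    """
    import warnings as _warnings
    if n_perm < 100:
        _warnings.warn("n_perm < 100 gives a very coarse permutation null")
    genes = ranked.genes if isinstance(ranked, RankedGeneList) else list(ranked)
    members = set(gene_set)
    n = len(genes)
    n_hit = sum(g in members for g in genes)
    if _es is None:
        _es, _ = enrichment_score_classic(ranked, gene_set)
    rng = np.random.default_rng(seed)
    null = _null_es(n, n_hit, n_perm, rng)
    same = null >= 0 if _es >= 0 else null < 0
    if same.sum() == 0:
        return float(np.sign(_es)), 1.0 / n_perm
    denom = float(np.abs(null[same]).mean())
    nes = _es / denom if denom > 0 else 0.0
    perm_p = float((np.abs(null[same]) >= abs(_es)).sum() / same.sum())
    return float(nes), perm_p


def random_set_empirical_p(ranked, gene_set, n_resample: int = 1000,
                           seed: int = 0, n_perm: int = 1000) -> float:
    """Empirical p from random same-size gene sets.

    Draws ``n_resample`` uniform same-size sets from the ranked
    universe, computes each one's NES against a shared permutation
    null, and returns ``k / n_resample`` where ``k`` counts resampled
    sets with NES strictly greater than the observed set's NES.
    """
    genes = ranked.genes if isinstance(ranked, RankedGeneList) else list(ranked)
    members = set(gene_set)
    n = len(genes)
    n_hit = sum(g in members for g in genes)
    if n_hit > n:
        raise ValueError("gene set larger than the ranked universe")
    es, _ = enrichment_score_classic(ranked, gene_set)
    rng = np.random.default_rng(seed)
    null = _null_es(n, n_hit, n_perm, rng)
    pos_mean = np.abs(null[null >= 0]).mean() if (null >= 0).any() else 1.0
    neg_mean = np.abs(null[null < 0]).mean() if (null < 0).any() else 1.0

    def nes_of(e):
        return e / pos_mean if e >= 0 else e / neg_mean

    obs_nes = nes_of(es)
    res = _null_es(n, n_hit, n_resample, rng)
    res_nes = np.where(res >= 0, res / pos_mean, res / neg_mean)
    k = int((res_nes > obs_nes).sum())
    return k / n_resample


def enrich(ranked: RankedGeneList, gene_set, set_name: str = "gene_set",
           n_perm: int = 1000, n_resample: int = 1000,
           seed: int = 0) -> EnrichmentResult:
    """Full single-set analysis: ES, NES, permutation p, empirical p."""
    es, running = enrichment_score_classic(ranked, gene_set)
    nes, perm_p = permutation_nes(ranked, gene_set, n_perm, seed, _es=es)
    emp = random_set_empirical_p(ranked, gene_set, n_resample, seed + 1, n_perm)
    members = set(gene_set)
    return EnrichmentResult(
        set_name=set_name, es=es, nes=nes, perm_p=perm_p, empirical_p=emp,
        n_perm=n_perm, n_resample=n_resample, running_sum=running,
        n_genes=len(ranked), n_hits=sum(g in members for g in ranked.genes))


def max_p_over_orderings(mean_rel_cn: pd.Series, correlations: pd.DataFrame,
                         gene_set, ordering_seeds, filter_alpha=0.05,
                         n_perm: int = 1000, n_resample: int = 1000,
                         stat: str = "empirical_p") -> dict:
    """Repeat the analysis over several residual-tie orderings.

    Returns the maximum p over orderings (the conservative report when
    ties are broken at random) together with all per-seed results.
    """
    seeds = list(ordering_seeds)
    if len(seeds) < 2:
        raise ValueError("need at least two orderings")
    results = []
    for s in seeds:
        ranked = build_ranked_list(mean_rel_cn, correlations, filter_alpha, s)
        results.append(enrich(ranked, gene_set, n_perm=n_perm,
                              n_resample=n_resample, seed=s))
    ps = [getattr(r, stat) for r in results]
    return {"max_p": max(ps), "p_values": ps, "results": results,
            "spread": max(ps) - min(ps)}
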