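"""CYCLOPS-gene accounting.

CYCLOPS genes are candidate therapeutic vulnerabilities: genes whose
partial copy-number loss — assumed to be an incidental bystander event,
not a selected one — may sensitize the tumor to further suppression of
that gene. The practical questions for a cohort are bookkeeping ones:
how many candidate genes are deleted per tumor; which candidates are
actually *downregulated* when deleted (without that, the putative
vulnerability is absent); what fraction of tumors carry at least one
such qualifying gene; and how deletion frequencies compare with other
cohorts.

"Deleted" uses the same ploidy-relative call as everywhere else in the
package (total copy number < 0.7 x sample ploidy). Downregulation is a
one-sided Wilcoxon rank-sum test (deleted < intact) at a nominal alpha
with a minimum group size, below which a gene is "untestable" rather
than silently negative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "per_tumor_set_loss_counts", "deletion_downregulation_test",
    "qualifying_genes", "tumors_with_any", "deletion_frequency_fisher",
    "CyclopsReport", "cyclops_report",
]


def _loss_matrix(gene_calls: pd.DataFrame, genes) -> pd.DataFrame:
    sub = gene_calls[gene_calls.gene.isin(set(genes))]
    return sub.pivot(index="gene", columns="sample", values="is_loss")


def per_tumor_set_loss_counts(gene_calls: pd.DataFrame, gene_set) -> dict:
    """Count set genes lost per tumor; summary over tumors.

    Unassessable gene/sample pairs are excluded from that tumor's count
    (tracked in ``n_unassessable``). Returns counts (Series indexed by
    sample), mean, median, range.
    """
    m = _loss_matrix(gene_calls, gene_set)
    if m.empty:
        raise ValueError("gene set disjoint from the call universe")
    counts = m.fillna(False).astype(bool).sum(axis=0)
    return {
        "counts": counts,
        "mean": float(counts.mean()),
        "median": float(counts.median()),
        "range": (int(counts.min()), int(counts.max())),
        "n_unassessable": m.isna().sum(axis=0),
    }


def deletion_downregulation_test(gene: str, gene_calls: pd.DataFrame,
                                 expression: pd.DataFrame,
                                 alpha: float = 0.05,
                                 min_group: int = 3) -> dict:
    """Is this gene's expression lower in tumors where it is deleted?

    One-sided Wilcoxon rank-sum (Mann-Whitney U, asymptotic), deleted
    group vs intact group. Returns a dict with keys ``downregulated``
    (True / False / None for untestable), ``statistic``, ``p``,
    ``n_deleted``, ``n_intact``.
    """
    sub = gene_calls[gene_calls.gene == gene].set_index("sample")
    if gene not in expression.index:
        return {"downregulated": None, "statistic": np.nan, "p": np.nan,
                "n_deleted": 0, "n_intact": 0}
    expr = expression.loc[gene]
    common = sub.index.intersection(expr.index)
    loss = sub.loc[common, "is_loss"]
    ok = loss.notna() & expr[common].notna()
    loss = loss[ok].astype(bool)
    vals = expr[common][ok].astype(float)
    deleted = vals[loss.to_numpy()]
    intact = vals[~loss.to_numpy()]
    if len(deleted) < min_group or len(intact) < min_group:
        return {"downregulated": None, "statistic": np.nan, "p": np.nan,
                "n_deleted": len(deleted), "n_intact": len(intact)}
    res = stats.mannwhitneyu(deleted, intact, alternative="less",
                             method="asymptotic")
    return {"downregulated": bool(res.pvalue < alpha),
            "statistic": float(res.statistic), "p": float(res.pvalue),
            "n_deleted": len(deleted), "n_intact": len(intact)}


def qualifying_genes(cyclops_set, gene_calls: pd.DataFrame,
                     expression: pd.DataFrame, alpha: float = 0.05,
                     min_group: int = 3) -> dict:
    """Candidates deleted in >= 1 tumor AND downregulated when deleted.

    Returns the qualifying subset, the per-gene test table, and the
    percentage of the candidate set (rounded to the nearest integer for
    reporting, e.g. 9 of 55 -> 16 %).
    """
    rows = []
    qualifying = []
    m = _loss_matrix(gene_calls, cyclops_set)
    for gene in cyclops_set:
        if gene in m.index:
            n_del = int(m.loc[gene].fillna(False).astype(bool).sum())
            n_ok = int(m.loc[gene].notna().sum())
        else:
            n_del, n_ok = 0, 0
        test = deletion_downregulation_test(gene, gene_calls, expression,
                                            alpha, min_group)
        freq = n_del / n_ok if n_ok else np.nan
        qualifies = n_del >= 1 and test["downregulated"] is True
        if qualifies:
            qualifying.append(gene)
        rows.append({"gene": gene, "n_deleted": n_del,
                     "deletion_frequency": freq,
                     "downregulated": test["downregulated"],
                     "p": test["p"], "qualifies": qualifies})
    table = pd.DataFrame(rows).set_index("gene")
    pct = int(round(100.0 * len(qualifying) / len(cyclops_set))) \
        if len(cyclops_set) else 0
    return {"qualifying": qualifying, "table": table, "percentage": pct}


def tumors_with_any(gene_calls: pd.DataFrame, qualifying) -> tuple:
    """Tumors with >= 1 qualifying gene lost: (count, percentage).

    Percentage is over assessable tumors, reported to one decimal.
    """
    if len(qualifying) == 0:
        raise ValueError("qualifying set is empty")
    m = _loss_matrix(gene_calls, qualifying)
    any_loss = m.fillna(False).astype(bool).any(axis=0)
    n_tumors = gene_calls["sample"].nunique()
    count = int(any_loss.sum())
    return count, round(100.0 * count / n_tumors, 1)


def deletion_frequency_fisher(k1: int, n1: int, k2: int, n2: int) -> tuple:
    """Two-sided Fisher's exact test comparing k1/n1 with k2/n2.

    The two-sided p sums the probabilities of all 2x2 tables (at the
    observed margins) whose probability does not exceed the observed
    table's. Returns (odds_ratio, p).
    """
    if k1 > n1 or k2 > n2 or min(k1, k2) < 0:
        raise ValueError("need 0 <= k <= n in both cohorts")
    table = [[k1, n1 - k1], [k2, n2 - k2]]
    res = stats.fisher_exact(table, alternative="two-sided")
    return float(res[0]), float(res[1])


@dataclass
class CyclopsReport:
    """Cohort-level CYCLOPS summary."""

    per_gene: pd.DataFrame
    per_tumor: pd.DataFrame
    qualifying: list
    percentage_qualifying: int
    n_tumors_with_any_qualifying: int
    pct_tumors_with_any_qualifying: float
    count_summary: dict
    qualifying_count_summary: dict

    def summary(self) -> str:
        cs, qs = self.count_summary, self.qualifying_count_summary
        lines = [
            "CYCLOPS-gene report",
            f"  candidate genes                    {len(self.per_gene):4d}",
            f"  qualifying (deleted+downregulated) {len(self.qualifying):4d}"
            f"  ({self.percentage_qualifying} %)",
            f"  candidate losses per tumor: mean {cs['mean']:.2f}, "
            f"median {cs['median']:.0f}, range {cs['range'][0]}-{cs['range'][1]}",
        ]
        if self.qualifying:
            lines += [
                f"  qualifying losses per tumor: mean {qs['mean']:.2f}, "
                f"median {qs['median']:.0f}, range {qs['range'][0]}-{qs['range'][1]}",
                f"  tumors with >= 1 qualifying gene   "
                f"{self.n_tumors_with_any_qualifying:4d} "
                f"({self.pct_tumors_with_any_qualifying} %)",
            ]
        return "\n".join(lines)


def cyclops_report(cyclops_set, gene_calls: pd.DataFrame,
                   expression: pd.DataFrame, alpha: float = 0.05,
                   min_group: int = 3) -> CyclopsReport:
    """Assemble the full per-gene / per-tumor CYCLOPS report."""
    counts = per_tumor_set_loss_counts(gene_calls, cyclops_set)
    qual = qualifying_genes(cyclops_set, gene_calls, expression, alpha,
                            min_group)
    if qual["qualifying"]:
        qcounts = per_tumor_set_loss_counts(gene_calls, qual["qualifying"])
        n_any, pct_any = tumors_with_any(gene_calls, qual["qualifying"])
    else:
        idx = counts["counts"].index
        qcounts = {"counts": pd.Series(0, index=idx), "mean": 0.0,
                   "median": 0.0, "range": (0, 0)}
        n_any, pct_any = 0, 0.0
    per_tumor = pd.DataFrame({
        "n_cyclops_deleted": counts["counts"],
        "n_qualifying_deleted": qcounts["counts"]}).fillna(0).astype(int)
    return CyclopsReport(
        per_gene=qual["table"], per_tumor=per_tumor,
        qualifying=qual["qualifying"],
        percentage_qualifying=qual["percentage"],
        n_tumors_with_any_qualifying=n_any,
        pct_tumors_with_any_qualifying=pct_any,
        count_summary={k: counts[k] for k in ("mean", "median", "range")},
        qualifying_count_summary={k: qcounts[k] for k in
                                  ("mean", "median", "range")})
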