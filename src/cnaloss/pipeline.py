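"""End-to-end orchestration: simulate/ingest -> fit -> call -> analyze.

Three input modes:

* ``synthetic``        — generate a cohort with known ground truth;
* ``snp-tracks``       — read per-sample LRR/BAF tracks and fit them;
* ``segment-profiles`` — read already-fitted allele-specific profiles
                         and skip the fitting stage entirely.

Whatever the entry point, downstream stages are identical: per-gene
loss/LOH calls, genome fractions, the cohort loss-frequency track,
recurrent-loss regions, gene-set enrichment of the ranked (filtered)
gene list, and the CYCLOPS report. Samples failing QC are excluded
before fitting and listed with their reason; the run manifest records
the sample funnel. Reruns with identical configuration and seeds
produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import ascn, calls, cyclops, enrichment, io as cio, simulate

__all__ = ["PipelineConfig", "ReportBundle", "read_inputs", "run_pipeline",
           "write_reports"]

log = logging.getLogger("cnaloss")


@dataclass
class PipelineConfig:
    """All knobs of the pipeline, with their standard defaults.

    Thresholds mirror the analysis conventions used throughout the
    package: loss factor 0.7 (relative to average ploidy), recurrent
    regions at >= 20 % cohort frequency and > 1 Mb, positive-correlation
    filter at two-sided alpha 0.05, >10 Mb homozygous-deletion solution
    adjustment.
    """

    mode: str = "synthetic"              # synthetic | snp-tracks | segment-profiles
    outdir: str = "cnaloss_out"
    seed: int = 0

    # synthetic cohort
    n_tumors: int = 20
    chrom_sizes: list = field(default_factory=lambda: [40_000_000] * 3)
    snp_spacing: int = 10_000
    n_genes: int = 300
    stop_size: int = 30
    cyclops_size: int = 10
    rho_range: list = field(default_factory=lambda: [0.3, 1.0])
    ploidy_choices: list = field(default_factory=lambda: [2.0])
    loss_rate_in_set: float = 0.4
    loss_rate_background: float = 0.1
    gamma: float = 0.55
    lrr_sd: float = 0.25
    baf_sd: float = 0.03
    het_fraction: float = 0.3
    coupled_fraction: float = 0.8
    expr_slope: float = 1.0
    expr_noise_sd: float = 0.5

    # file inputs (snp-tracks / segment-profiles modes)
    snp_tracks: dict = field(default_factory=dict)   # sample_id -> path
    segment_profiles: str | None = None
    genes_bed: str | None = None
    gene_sets_gmt: str | None = None
    expression_tsv: str | None = None
    chrom_sizes_from_bed_margin: int = 0

    # analysis thresholds
    loss_factor: float = 0.7
    min_freq: float = 0.2
    min_size_mb: float = 1.0
    gap_mb: float = 0.5
    filter_alpha: float | None = 0.05
    min_corr_samples: int = 8
    penalty: float = 10.0
    min_snps: int = 5
    max_homdel_mb: float = 10.0
    n_perm: int = 1000
    n_resample: int = 1000
    stop_set_name: str = "stop_like"
    cyclops_set_name: str = "cyclops_like"
    downreg_alpha: float = 0.05
    downreg_min_group: int = 3

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


@dataclass
class ReportBundle:
    """Everything a pipeline run produced, ready to write."""

    config: PipelineConfig
    funnel: dict
    qc_table: pd.DataFrame
    solutions: dict                     # sample -> AscnSolution-like
    gene_calls: pd.DataFrame
    fractions: pd.DataFrame
    freq_track: pd.DataFrame
    regions: pd.DataFrame
    ranked: "enrichment.RankedGeneList | None"
    enrichment_results: dict
    cyclops_report: "cyclops.CyclopsReport | None"
    genome: simulate.GenomeModel
    gene_sets: dict
    truth: list = field(default_factory=list)
    expression: pd.DataFrame | None = None


# ---------------------------------------------------------------------------
# input assembly
# ---------------------------------------------------------------------------

def _genome_from_bed(genes: pd.DataFrame, spacing: int) -> simulate.GenomeModel:
    """Build a genome backbone from gene extents when no SNP platform is
    given: chromosome length is the max gene end (+margin), positions a
    uniform grid. Only used to anchor frequency tracks in file modes."""
    chroms = []
    pos = {}
    for chrom, sub in genes.groupby("chrom", sort=True):
        size = int(sub.end.max())
        chroms.append((chrom, size))
        pos[chrom] = np.arange(spacing // 2, size, spacing, dtype=np.int64)
    return simulate.GenomeModel(tuple(chroms), pos, genes.reset_index(drop=True))


def read_inputs(config: PipelineConfig) -> dict:
    """Load and validate the file inputs for non-synthetic modes.

    Checks coordinate sanity (via the io readers) and sample-name
    consistency between the segment/track inputs and the expression
    matrix; mismatches raise with the offending names listed.
    """
    if config.genes_bed is None:
        raise ValueError("genes_bed is required in file modes")
    genes = cio.read_bed(config.genes_bed)
    genome = _genome_from_bed(genes, config.snp_spacing)
    gene_sets = cio.read_gmt(config.gene_sets_gmt) if config.gene_sets_gmt else {}
    expression = (cio.read_expression(config.expression_tsv)
                  if config.expression_tsv else None)
    data = {"genome": genome, "gene_sets": gene_sets, "expression": expression}
    if config.mode == "segment-profiles":
        if not config.segment_profiles:
            raise ValueError("segment_profiles path required")
        profiles = cio.read_segment_profiles(config.segment_profiles)
        data["profiles"] = profiles
        samples = set(profiles)
    elif config.mode == "snp-tracks":
        if not config.snp_tracks:
            raise ValueError("snp_tracks mapping required")
        data["tracks"] = {s: cio.read_snp_track(p, s)
                          for s, p in sorted(config.snp_tracks.items())}
        samples = set(data["tracks"])
    else:
        raise ValueError(f"read_inputs not applicable to mode {config.mode}")
    if expression is not None:
        extra = set(expression.columns) - samples
        if extra:
            raise ValueError("expression samples absent from copy-number "
                             f"inputs: {sorted(extra)}")
    return data


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def _fit_cohort(tracks: dict, config: PipelineConfig):
    """QC + fit every track; returns (solutions, qc_rows, funnel)."""
    solutions = {}
    qc_rows = []
    excluded = {"noisy_lrr": 0, "flat_baf": 0, "low_content": 0,
                "unidentifiable": 0}
    for sample in sorted(tracks):
        track = tracks[sample]
        model = ascn.AllelicCopyNumberModel(
            track, gamma=config.gamma, penalty=config.penalty,
            min_snps=config.min_snps, max_homdel_mb=config.max_homdel_mb)
        flags = model.qc()
        qc_rows.append({"sample": sample, "passed": flags.passed,
                        "reason": flags.reason or "", **flags.metrics})
        if not flags.passed:
            excluded[flags.reason] += 1
            log.info("sample %s excluded: %s", sample, flags.reason)
            continue
        try:
            fit = model.fit(skip_qc=True)
        except ascn.UnassessableSampleError:
            excluded["unidentifiable"] += 1
            log.info("sample %s excluded: unidentifiable", sample)
            continue
        solutions[sample] = fit.solution
    funnel = {"n_input": len(tracks), "n_passed": len(solutions),
              **{f"excluded_{k}": v for k, v in excluded.items()}}
    return solutions, pd.DataFrame(qc_rows), funnel


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Run every stage appropriate to the configured input mode."""
    rng_seed = config.seed
    truth = []
    expression = None
    if config.mode == "synthetic":
        genome = simulate.make_genome(
            rng_seed, config.chrom_sizes, config.snp_spacing, config.n_genes)
        sets = simulate.make_gene_sets(
            genome, config.stop_size, config.cyclops_size, rng_seed + 1)
        gene_sets = dict(sets.sets)
        truth = simulate.simulate_cohort_truth(
            genome, sets, config.n_tumors, tuple(config.rho_range),
            tuple(config.ploidy_choices), config.loss_rate_in_set,
            config.loss_rate_background, rng_seed + 2)
        tracks = {t.sample_id: simulate.render_snp_track(
            t, genome, config.gamma, config.lrr_sd, config.baf_sd,
            config.het_fraction, rng_seed + 10 + i)
            for i, t in enumerate(truth)}
        expression, _ = simulate.simulate_expression(
            truth, genome, config.coupled_fraction, config.expr_slope,
            config.expr_noise_sd, rng_seed + 3)
        solutions, qc_table, funnel = _fit_cohort(tracks, config)
    elif config.mode == "snp-tracks":
        data = read_inputs(config)
        genome, gene_sets = data["genome"], data["gene_sets"]
        expression = data["expression"]
        solutions, qc_table, funnel = _fit_cohort(data["tracks"], config)
    elif config.mode == "segment-profiles":
        data = read_inputs(config)
        genome, gene_sets = data["genome"], data["gene_sets"]
        expression = data["expression"]
        solutions = {
            s: ascn.AscnSolution(
                sample_id=s, rho=p["rho"], psi=p["psi"], psi_t_grid=p["psi"],
                segments=p["segments"].assign(n_snps=1),
                goodness=p.get("goodness") or 0.0)
            for s, p in data["profiles"].items()}
        qc_table = pd.DataFrame(
            {"sample": sorted(solutions), "passed": True, "reason": ""})
        funnel = {"n_input": len(solutions), "n_passed": len(solutions)}
    else:
        raise ValueError(f"unknown mode {config.mode}")

    if not solutions:
        raise RuntimeError("no samples passed QC/fitting; empty cohort")
    log.info("sample funnel: %s", funnel)

    cohort = {s: (sol.segments, sol.psi) for s, sol in solutions.items()}
    gene_calls = calls.cohort_gene_calls(cohort, genome, config.loss_factor)
    fractions = pd.DataFrame([
        {"sample": s, "rho": sol.rho, "psi": sol.psi,
         "fraction_lost": calls.genome_fractions(
             sol.segments, sol.psi, config.loss_factor)[0],
         "fraction_loh": calls.genome_fractions(
             sol.segments, sol.psi, config.loss_factor)[1]}
        for s, sol in solutions.items()])
    freq_track = calls.loss_frequency(cohort, genome, config.loss_factor)
    regions = calls.annotate_regions(
        calls.recurrent_loss_regions(freq_track, config.min_freq,
                                     config.min_size_mb, config.gap_mb),
        genome.genes, gene_sets)

    ranked = None
    enrichment_results = {}
    cyc_report = None
    if expression is not None and len(gene_sets):
        rel = enrichment.relative_cn_matrix(gene_calls)
        corr = enrichment.cn_expression_correlation(
            rel, expression, config.min_corr_samples)
        mean_rel = enrichment.mean_relative_cn(gene_calls)
        try:
            ranked = enrichment.build_ranked_list(
                mean_rel, corr, config.filter_alpha, rng_seed + 4)
        except ValueError:
            log.warning("no genes pass the correlation filter; "
                        "enrichment skipped")
        if ranked is not None:
            for name, members in sorted(gene_sets.items()):
                inset = set(members) & set(ranked.genes)
                if 0 < len(inset) < len(ranked):
                    enrichment_results[name] = enrichment.enrich(
                        ranked, members, name, config.n_perm,
                        config.n_resample, rng_seed + 5)
        cyc_members = gene_sets.get(config.cyclops_set_name, [])
        if cyc_members:
            cyc_report = cyclops.cyclops_report(
                list(cyc_members), gene_calls, expression,
                config.downreg_alpha, config.downreg_min_group)

    return ReportBundle(
        config=config, funnel=funnel, qc_table=qc_table, solutions=solutions,
        gene_calls=gene_calls, fractions=fractions, freq_track=freq_track,
        regions=regions, ranked=ranked,
        enrichment_results=enrichment_results, cyclops_report=cyc_report,
        genome=genome, gene_sets=gene_sets, truth=truth,
        expression=expression)


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_reports(bundle: ReportBundle, outdir=None) -> dict:
    """Write every report as TSV (+ GMT + manifest); returns the manifest.

    Empty tables produce header-only files, never absent ones. The
    manifest lists each output with its sha256 checksum, plus the run
    seed and the sample funnel.
    """
    out = Path(outdir or bundle.config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    files = {}

    _write_tsv(bundle.qc_table, out / "qc.tsv")
    files["qc.tsv"] = None
    cio.write_segment_profiles(bundle.solutions, out / "solutions.tsv")
    files["solutions.tsv"] = None
    gc = bundle.gene_calls.copy()
    gc["is_loss"] = gc.is_loss.map({True: 1, False: 0, pd.NA: ""})
    gc["is_loh"] = gc.is_loh.map({True: 1, False: 0, pd.NA: ""})
    _write_tsv(gc, out / "gene_calls.tsv")
    files["gene_calls.tsv"] = None
    _write_tsv(bundle.fractions, out / "fractions.tsv")
    files["fractions.tsv"] = None
    _write_tsv(bundle.freq_track, out / "loss_frequency.tsv")
    files["loss_frequency.tsv"] = None
    _write_tsv(bundle.regions, out / "regions.tsv")
    files["regions.tsv"] = None
    if bundle.gene_sets:
        cio.write_gmt(bundle.gene_sets, out / "gene_sets.gmt")
        files["gene_sets.gmt"] = None
    if bundle.ranked is not None:
        rt = bundle.ranked.table.reset_index(names="gene")
        _write_tsv(rt, out / "ranked_list.tsv")
        files["ranked_list.tsv"] = None
    if bundle.enrichment_results:
        rows = []
        for name, res in sorted(bundle.enrichment_results.items()):
            rows.append({"set": name, "n_genes": res.n_genes,
                         "n_hits": res.n_hits, "es": res.es, "nes": res.nes,
                         "perm_p": res.perm_p, "empirical_p": res.empirical_p,
                         "n_perm": res.n_perm, "n_resample": res.n_resample})
            trace = pd.DataFrame({"rank": np.arange(1, len(res.running_sum) + 1),
                                  "running_sum": res.running_sum})
            _write_tsv(trace, out / f"running_sum_{name}.tsv")
            files[f"running_sum_{name}.tsv"] = None
            _plot_running_sum(res, out / f"running_sum_{name}.png")
            files[f"running_sum_{name}.png"] = None
        _write_tsv(pd.DataFrame(rows), out / "enrichment.tsv")
        files["enrichment.tsv"] = None
    if bundle.cyclops_report is not None:
        _write_tsv(bundle.cyclops_report.per_gene.reset_index(),
                   out / "cyclops_per_gene.tsv")
        _write_tsv(bundle.cyclops_report.per_tumor.reset_index(names="sample"),
                   out / "cyclops_per_tumor.tsv")
        files["cyclops_per_gene.tsv"] = None
        files["cyclops_per_tumor.tsv"] = None

    manifest_rows = []
    for name in sorted(files):
        digest = hashlib.sha256((out / name).read_bytes()).hexdigest()
        manifest_rows.append({"file": name, "sha256": digest})
    manifest = pd.DataFrame(manifest_rows)
    with open(out / "manifest.tsv", "w") as fh:
        fh.write(f"# seed={bundle.config.seed} mode={bundle.config.mode}\n")
        for k, v in bundle.funnel.items():
            fh.write(f"# funnel {k}={v}\n")
        manifest.to_csv(fh, sep="\t", index=False)
    return {r["file"]: r["sha256"] for r in manifest_rows}


def _plot_running_sum(res, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    fig, ax = plt.subplots(figsize=(6, 3))
    ax.plot(np.arange(1, len(res.running_sum) + 1), res.running_sum, lw=1)
    ax.axhline(0, color="gray", lw=0.5)
    ax.set_xlabel("rank in gene list (ascending relative copy number)")
    ax.set_ylabel("running enrichment score")
    ax.set_title(f"{res.set_name}: ES={res.es:.3f}, NES={res.nes:.2f}, "
                 f"empirical p={res.empirical_p}")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
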