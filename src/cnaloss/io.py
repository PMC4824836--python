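"""Readers and writers for the package's plain-text formats.

All genomic coordinates are 0-based half-open, including BED input,
which is taken as-is; files that look 1-based (end < start, or
intervals running off the chromosome) are rejected rather than
silently shifted. All writers are deterministic: column order, float
formatting and row order are fixed so that identical inputs produce
byte-identical files.

Formats
-------
SNP track TSV   chrom, pos, lrr, baf, is_het (is_het written as 0/1)
segment TSV     sample, chrom, start, end, nA, nB preceded by one
                ``#sample <id> rho=<r> psi=<p> [goodness=<g>]`` comment
                line per sample
BED             chrom, start, end, gene_id (standard 4-column BED)
GMT             set name, description, member genes (tab-separated)
expression TSV  genes in rows, samples in columns
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .simulate import SnpTrack

__all__ = [
    "write_snp_track", "read_snp_track", "write_segment_profiles",
    "read_segment_profiles", "write_bed", "read_bed", "write_gmt",
    "read_gmt", "write_expression", "read_expression", "FormatError",
]

_FLOAT_FMT = "%.6g"


class FormatError(ValueError):
    """A file violated its documented format; message names the line."""


def write_snp_track(track: SnpTrack, path) -> None:
    d = track.df.copy()
    d["is_het"] = d.is_het.astype(int)
    d.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_snp_track(path, sample_id: str = "sample") -> SnpTrack:
    d = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"chrom", "pos", "lrr", "baf", "is_het"}
    missing = required - set(d.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    d["is_het"] = d.is_het.astype(bool)
    return SnpTrack(sample_id=sample_id, df=d)


def write_segment_profiles(solutions: dict, path) -> None:
    """``solutions`` maps sample_id -> object with .rho, .psi, .segments
    (chrom, start, end, nA, nB) and optionally .goodness."""
    with open(path, "w") as fh:
        fh.write("sample\tchrom\tstart\tend\tnA\tnB\n")
        for sample in sorted(solutions):
            sol = solutions[sample]
            g = getattr(sol, "goodness", None)
            extra = f" goodness={g:.6g}" if g is not None else ""
            fh.write(f"#sample {sample} rho={sol.rho:.6g} "
                     f"psi={sol.psi:.6g}{extra}\n")
            for row in sol.segments.itertuples(index=False):
                fh.write(f"{sample}\t{row.chrom}\t{int(row.start)}\t"
                         f"{int(row.end)}\t{int(row.nA)}\t{int(row.nB)}\n")


def read_segment_profiles(path) -> dict:
    """Returns sample_id -> dict(rho=..., psi=..., goodness=...,
    segments=DataFrame(chrom, start, end, nA, nB))."""
    meta = {}
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#sample"):
                parts = line.split()
                if len(parts) < 4:
                    raise FormatError(f"{path}:{ln}: malformed sample header")
                sample = parts[1]
                kv = dict(p.split("=", 1) for p in parts[2:])
                meta[sample] = {k: float(v) for k, v in kv.items()}
                continue
            if line.startswith("sample\t"):
                continue
            parts = line.split("\t")
            if len(parts) != 6:
                raise FormatError(f"{path}:{ln}: expected 6 columns, "
                                  f"got {len(parts)}")
            sample, chrom, start, end, nA, nB = parts
            try:
                start, end, nA, nB = int(start), int(end), int(nA), int(nB)
            except ValueError as exc:
                raise FormatError(f"{path}:{ln}: non-integer field") from exc
            if end <= start:
                raise FormatError(f"{path}:{ln}: end <= start")
            rows.append((sample, chrom, start, end, nA, nB))
    df = pd.DataFrame(rows, columns=["sample", "chrom", "start", "end",
                                     "nA", "nB"])
    out = {}
    for sample, sub in df.groupby("sample", sort=True):
        m = meta.get(sample)
        if m is None or "rho" not in m or "psi" not in m:
            raise FormatError(f"{path}: sample {sample} lacks a "
                              "#sample header with rho and psi")
        out[sample] = {
            "rho": m["rho"], "psi": m["psi"],
            "goodness": m.get("goodness"),
            "segments": sub.drop(columns="sample").reset_index(drop=True)}
    return out


def write_bed(genes: pd.DataFrame, path) -> None:
    genes[["chrom", "start", "end", "gene_id"]].to_csv(
        path, sep="\t", index=False, header=False)


def read_bed(path, chrom_sizes: dict | None = None) -> pd.DataFrame:
    """4-column BED -> DataFrame(gene_id, chrom, start, end).

    Validates 0-based half-open intervals: end must exceed start, and
    when chromosome sizes are supplied, intervals must lie inside them
    (a 1-based file typically ends exactly at the chromosome length
    plus one and is rejected here rather than guessed at).
    """
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise FormatError(f"{path}:{ln}: expected >= 4 BED columns")
            chrom, start, end, name = parts[0], parts[1], parts[2], parts[3]
            try:
                start, end = int(start), int(end)
            except ValueError as exc:
                raise FormatError(f"{path}:{ln}: non-integer coordinates") from exc
            if end <= start or start < 0:
                raise FormatError(f"{path}:{ln}: invalid interval "
                                  f"[{start}, {end})")
            if chrom_sizes is not None:
                if chrom not in chrom_sizes:
                    raise FormatError(f"{path}:{ln}: unknown chromosome {chrom}")
                if end > chrom_sizes[chrom]:
                    raise FormatError(
                        f"{path}:{ln}: interval end {end} beyond chromosome "
                        f"{chrom} ({chrom_sizes[chrom]} bp); is this file "
                        "1-based?")
            rows.append((name, chrom, start, end))
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end"])


def write_gmt(gene_sets: dict, path, descriptions: dict | None = None) -> None:
    with open(path, "w") as fh:
        for name in sorted(gene_sets):
            desc = (descriptions or {}).get(name, "na")
            fh.write("\t".join([name, desc] + list(gene_sets[name])) + "\n")


def read_gmt(path) -> dict:
    sets = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{ln}: GMT line needs name, "
                                  "description and >= 1 gene")
            sets[parts[0]] = parts[2:]
    return sets


def write_expression(expr: pd.DataFrame, path) -> None:
    expr.sort_index().to_csv(path, sep="\t", float_format=_FLOAT_FMT,
                             index_label="gene_id")


def read_expression(path) -> pd.DataFrame:
    d = pd.read_csv(path, sep="\t", index_col=0)
    if d.index.has_duplicates:
        raise FormatError(f"{path}: duplicate gene ids")
    return d
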