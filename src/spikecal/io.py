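"""Text-format readers and writers: BED, bedGraph, TSV interchange tables.

Everything is plain text with deterministic column and line order. bedGraph
values are signal per bp over the record's span; tracks are rebinned on read
to a fixed bin size by length-weighted accumulation, which conserves total
signal exactly.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd

from .counts import TaggedCounts
from .errors import ValidationError
from .tracks import CoverageTrack, GeneModel

BED6_COLUMNS = ["contig", "start", "end", "name", "score", "strand"]


# ---------------------------------------------------------------------------
# BED


def read_bed(path) -> pd.DataFrame:
    """Read BED3/BED6 (plus extra columns) with per-line validation.

    Returns a DataFrame with contig/start/end and, when present, name,
    score, strand and any additional columns (bed7, bed8, ...).
    """
    rows = []
    ncols = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValidationError(f"{path}:{lineno}: fewer than 3 BED fields")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValidationError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start < 0 or end <= start:
                raise ValidationError(
                    f"{path}:{lineno}: invalid interval [{start}, {end})"
                )
            if len(parts) >= 6 and parts[5] not in ("+", "-", "."):
                raise ValidationError(f"{path}:{lineno}: bad strand {parts[5]!r}")
            ncols = max(ncols or 0, len(parts))
            rows.append(parts)
    cols = BED6_COLUMNS + [f"bed{i + 1}" for i in range(6, ncols or 3)]
    cols = cols[: ncols or 3]
    df = pd.DataFrame([r + [None] * (len(cols) - len(r)) for r in rows], columns=cols)
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    if "score" in df.columns:
        df["score"] = pd.to_numeric(df["score"], errors="coerce")
    return df


def write_bed(intervals: pd.DataFrame, path) -> None:
    """Write intervals as BED; emits exactly the BED columns present."""
    df = intervals
    cols = [c for c in BED6_COLUMNS if c in df.columns]
    extra = [c for c in df.columns if c.startswith("bed")]
    out = df[cols + extra].copy()
    if "score" in out.columns:
        out["score"] = out["score"].fillna(0)
    if "name" in out.columns:
        out["name"] = out["name"].fillna(".")
    out.to_csv(path, sep="\t", header=False, index=False)


def genes_to_bed_frame(genes: list[GeneModel]) -> pd.DataFrame:
    """BED6 + cgi + polycomb flag columns for a gene list."""
    return pd.DataFrame(
        {
            "contig": [g.contig for g in genes],
            "start": [g.start for g in genes],
            "end": [g.end for g in genes],
            "name": [g.gene_id for g in genes],
            "score": 0,
            "strand": [g.strand for g in genes],
            "bed7": [int(g.cgi) for g in genes],
            "bed8": [int(g.polycomb) for g in genes],
        }
    )


def write_genes_bed(genes: list[GeneModel], path) -> None:
    genes_to_bed_frame(genes).to_csv(path, sep="\t", header=False, index=False)


def read_genes_bed(path) -> list[GeneModel]:
    """Read a BED6(+2 flag columns) gene annotation into GeneModel objects."""
    df = read_bed(path)
    for col in ("name", "strand"):
        if col not in df.columns:
            raise ValidationError(f"{path}: gene annotation needs BED6 ({col} missing)")
    genes = []
    for _, row in df.iterrows():
        strand = row["strand"]
        if strand not in ("+", "-"):
            raise ValidationError(f"{path}: gene {row['name']} lacks a strand")
        start, end = int(row["start"]), int(row["end"])
        tss, tes = (start, end) if strand == "+" else (end - 1, start - 1)
        genes.append(
            GeneModel(
                gene_id=str(row["name"]),
                contig=str(row["contig"]),
                strand=strand,
                tss=tss,
                tes=tes,
                cgi=bool(int(row["bed7"])) if "bed7" in df.columns and row["bed7"] is not None else False,
                polycomb=bool(int(row["bed8"])) if "bed8" in df.columns and row["bed8"] is not None else False,
            )
        )
    return genes


# ---------------------------------------------------------------------------
# bedGraph


def read_bedgraph(path, bin_size: int) -> CoverageTrack:
    """Read a bedGraph into a fixed-bin track (length-weighted accumulation).

    Records must be sorted and non-overlapping within each contig. The value
    of a record is signal per bp; bin k of the output accumulates
    value * overlap([k*bin, (k+1)*bin)). Total signal is conserved exactly.
    """
    if bin_size <= 0:
        raise ValidationError("bin_size must be positive")
    per_contig: dict[str, list[tuple[int, int, float]]] = {}
    last: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValidationError(f"{path}:{lineno}: bedGraph needs 4 fields")
            contig = parts[0]
            try:
                start, end, value = int(parts[1]), int(parts[2]), float(parts[3])
            except ValueError as exc:
                raise ValidationError(f"{path}:{lineno}: malformed record") from exc
            if start < 0 or end <= start:
                raise ValidationError(f"{path}:{lineno}: invalid interval")
            if not math.isfinite(value) or value < 0:
                raise ValidationError(f"{path}:{lineno}: bad value {parts[3]}")
            if contig in last and start < last[contig]:
                raise ValidationError(
                    f"{path}:{lineno}: unsorted or overlapping record on {contig}"
                )
            last[contig] = end
            per_contig.setdefault(contig, []).append((start, end, value))
    data = {}
    for contig, recs in per_contig.items():
        length = recs[-1][1]
        nbins = -(-length // bin_size)  # ceil
        bins = np.zeros(nbins)
        for start, end, value in recs:
            if value == 0:
                continue
            first, lastbin = start // bin_size, (end - 1) // bin_size
            if first == lastbin:
                bins[first] += value * (end - start)
                continue
            bins[first] += value * ((first + 1) * bin_size - start)
            if lastbin > first + 1:
                bins[first + 1 : lastbin] += value * bin_size
            bins[lastbin] += value * (end - lastbin * bin_size)
        data[contig] = bins
    return CoverageTrack(data, bin_size)


def write_bedgraph(track: CoverageTrack, path) -> None:
    """Write a track as bedGraph; adjacent equal-density bins are merged."""
    with open(path, "w") as fh:
        for contig in sorted(track.data):
            vals = track.data[contig] / track.bin_size  # back to per-bp density
            if len(vals) == 0:
                continue
            # run-length encode equal adjacent densities
            change = np.flatnonzero(np.diff(vals)) + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [len(vals)]])
            for s, e in zip(starts, ends):
                v = vals[s]
                if v != 0:
                    fh.write(
                        f"{contig}\t{s * track.bin_size}"
                        f"\t{e * track.bin_size}\t{v:.10g}\n"
                    )


# ---------------------------------------------------------------------------
# TSV interchange


def write_tagged_counts(tc: TaggedCounts, counts_path, samples_path=None) -> None:
    """Counts TSV: gene_id, genome_tag, one column per sample (+ samples TSV)."""
    out = pd.concat([tc.genome.rename("genome_tag"), tc.counts], axis=1)
    out.to_csv(counts_path, sep="\t", index_label="gene_id")
    if samples_path is not None and len(tc.samples):
        tc.samples.to_csv(samples_path, sep="\t", index_label="sample")


def read_tagged_counts(counts_path, samples_path=None) -> TaggedCounts:
    df = pd.read_csv(counts_path, sep="\t", index_col="gene_id")
    if "genome_tag" not in df.columns:
        raise ValidationError(f"{counts_path}: missing genome_tag column")
    genome = df["genome_tag"]
    counts = df.drop(columns=["genome_tag"])
    samples = (
        pd.read_csv(samples_path, sep="\t", index_col="sample")
        if samples_path is not None and Path(samples_path).exists()
        else pd.DataFrame()
    )
    return TaggedCounts(counts, genome, samples)


def write_table(df: pd.DataFrame, path, index_label: str | None = None) -> None:
    df.to_csv(path, sep="\t", index=index_label is not None, index_label=index_label)


def read_table(path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)
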