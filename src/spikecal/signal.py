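"""Interval counting, RPKM, TSS metaprofiles, ratio tracks and stratification.

All interval arithmetic is 0-based half-open. Partial bin overlaps are
weighted by overlap length, which makes the quantities conservative: the sum
of a TSS-matrix row equals the interval count over the same window.
"""

from __future__ import annotations

import logging
import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .tracks import CoverageTrack, GeneModel, SignalMatrix, window_sums

log = logging.getLogger(__name__)


def _intervals_frame(intervals) -> pd.DataFrame:
    if isinstance(intervals, pd.DataFrame):
        need = {"contig", "start", "end"}
        if len(intervals) and not need <= set(intervals.columns):
            raise ValidationError(f"interval table needs columns {sorted(need)}")
        if not need <= set(intervals.columns):  # empty frame without columns
            return pd.DataFrame(columns=["contig", "start", "end"])
        return intervals
    rows = [{"contig": c, "start": s, "end": e} for c, s, e in intervals]
    return pd.DataFrame(rows, columns=["contig", "start", "end"])


def count_in_intervals(track: CoverageTrack, intervals) -> pd.Series:
    """Signal sum per interval, fractional bins weighted by overlap length.

    Intervals extending past the contig are clipped with a warning; unknown
    contigs yield NaN entries (reported once per contig).
    """
    ivals = _intervals_frame(intervals)
    out = np.full(len(ivals), np.nan)
    unknown: set[str] = set()
    clipped = 0
    for contig, grp in ivals.groupby("contig", sort=False):
        if contig not in track.data:
            unknown.add(str(contig))
            continue
        length = track.contig_length(contig)
        start = grp["start"].to_numpy(dtype=float)
        end = grp["end"].to_numpy(dtype=float)
        if (end <= start).any():
            raise ValidationError(f"interval with end <= start on {contig}")
        clipped += int(((start < 0) | (end > length)).sum())
        cum_end = track.signal_at(contig, end)
        cum_start = track.signal_at(contig, start)
        out[ivals.index.get_indexer(grp.index)] = cum_end - cum_start
    if unknown:
        warnings.warn(f"unknown contigs in intervals: {sorted(unknown)}", stacklevel=2)
    if clipped:
        warnings.warn(f"{clipped} intervals clipped to contig bounds", stacklevel=2)
    name = ivals["name"] if "name" in ivals.columns else ivals.index
    return pd.Series(out, index=name, name="count")


def rpkm(counts, interval_lengths, library_total: float) -> np.ndarray:
    """Reads per kilobase per million: count / (length_kb * total_millions)."""
    counts = np.asarray(counts, dtype=float)
    lengths = np.asarray(interval_lengths, dtype=float)
    if (lengths <= 0).any():
        raise ValidationError("interval lengths must be positive")
    if not library_total > 0:
        raise ValidationError("library total must be positive")
    return counts / (lengths / 1e3) / (library_total / 1e6)


def _gene_window_sums(
    track: CoverageTrack, gene: GeneModel, rel_start: int, rel_end: int, nbins: int
) -> np.ndarray:
    """Per-bin sums over a TSS-relative window, oriented 5'->3'."""
    lo, hi = gene.window(rel_start, rel_end)
    vals = window_sums(track, gene.contig, lo, hi, nbins)
    return vals if gene.strand == "+" else vals[::-1]


def tss_matrix(
    track: CoverageTrack,
    genes: Sequence[GeneModel],
    flank_bp: int = 2000,
    bin_bp: int = 50,
) -> SignalMatrix:
    """Signal matrix anchored at TSSs, transcription left-to-right.

    Each row covers TSS-relative offsets [-flank_bp, +flank_bp) in bins of
    ``bin_bp`` (flank must be a multiple of the bin). Minus-strand rows are
    reversed so downstream is rightward; off-contig bins are NaN.
    """
    if flank_bp <= 0 or bin_bp <= 0 or flank_bp % bin_bp:
        raise ValidationError("flank_bp must be a positive multiple of bin_bp")
    nbins = 2 * flank_bp // bin_bp
    rows, ids = [], []
    for g in genes:
        if g.contig not in track.data:
            rows.append(np.full(nbins, np.nan))
        else:
            rows.append(_gene_window_sums(track, g, -flank_bp, flank_bp, nbins))
        ids.append(g.gene_id)
    return SignalMatrix(
        np.vstack(rows) if rows else np.empty((0, nbins)),
        ids,
        anchor="TSS",
        bin_size=float(bin_bp),
        meta={"flank_bp": flank_bp},
    )


def scaled_body_matrix(
    track: CoverageTrack,
    genes: Sequence[GeneModel],
    nbins: int = 100,
    flank_bp: int = 2000,
    flank_bins: int = 20,
) -> SignalMatrix:
    """Gene bodies rescaled to ``nbins``, flanks unscaled, rows are densities.

    Each body (TSS to TES) is resampled to ``nbins`` equal slices by
    length-weighted averaging, so two genes with the same relative signal
    shape give identical rows regardless of length. Values are mean signal
    per bp. Genes shorter than ``nbins`` bp are excluded (count reported in
    ``meta['n_excluded']``).
    """
    if nbins < 1 or flank_bins < 1 or flank_bp <= 0:
        raise ValidationError("nbins, flank_bins and flank_bp must be positive")
    rows, ids = [], []
    excluded = 0
    flank_bin_bp = flank_bp / flank_bins
    for g in genes:
        if g.length < nbins:
            excluded += 1
            continue
        if g.contig not in track.data:
            rows.append(np.full(2 * flank_bins + nbins, np.nan))
            ids.append(g.gene_id)
            continue
        up = _gene_window_sums(track, g, -flank_bp, 0, flank_bins) / flank_bin_bp
        body = _gene_window_sums(track, g, 0, g.length, nbins) / (g.length / nbins)
        down = (
            _gene_window_sums(track, g, g.length, g.length + flank_bp, flank_bins)
            / flank_bin_bp
        )
        rows.append(np.concatenate([up, body, down]))
        ids.append(g.gene_id)
    if excluded:
        log.warning("scaled_body_matrix: %d genes shorter than %d bp excluded", excluded, nbins)
    width = 2 * flank_bins + nbins
    return SignalMatrix(
        np.vstack(rows) if rows else np.empty((0, width)),
        ids,
        anchor="scaled",
        bin_size=None,
        meta={"nbins": nbins, "flank_bp": flank_bp, "flank_bins": flank_bins,
              "n_excluded": excluded},
    )


def ratio_track(
    numerator: CoverageTrack,
    denominator: CoverageTrack,
    pseudocount: float = 1.0,
) -> CoverageTrack:
    """Per-bin (num + pc) / (den + pc); used e.g. for H3K36me2 over H3.

    The pseudocount (default 1 signal unit) bounds ratios at empty bins.
    Requires identical binning and contigs.
    """
    if numerator.bin_size != denominator.bin_size:
        raise ValidationError("ratio_track: bin sizes differ")
    if set(numerator.data) != set(denominator.data):
        raise ValidationError("ratio_track: contig sets differ")
    if pseudocount < 0:
        raise ValidationError("pseudocount must be >= 0")
    out = {}
    for contig, num in numerator.data.items():
        den = denominator.data[contig]
        if len(num) != len(den):
            raise ValidationError(f"ratio_track: contig {contig} lengths differ")
        with np.errstate(divide="ignore", invalid="ignore"):
            r = (num + pseudocount) / (den + pseudocount)
        if not np.isfinite(r).all():
            raise ValidationError(
                f"ratio undefined on {contig}: zero denominator with pseudocount 0"
            )
        out[contig] = r
    return CoverageTrack(out, numerator.bin_size)


def filter_blacklist(records, blacklist) -> pd.DataFrame:
    """Drop records overlapping any blacklist interval by >= 1 bp (half-open).

    Records abutting a blacklist interval (record end == blacklist start)
    are retained. The number removed is logged.
    """
    recs = _intervals_frame(records)
    bl = _intervals_frame(blacklist)
    if len(bl) == 0 or len(recs) == 0:
        log.info("blacklist filter removed 0 records")
        return recs.copy()
    keep = np.ones(len(recs), dtype=bool)
    by_contig = {c: g for c, g in bl.groupby("contig", sort=False)}
    for contig, grp in recs.groupby("contig", sort=False):
        b = by_contig.get(contig)
        if b is None:
            continue
        bs = b["start"].to_numpy()
        be = b["end"].to_numpy()
        order = np.argsort(bs)
        bs, be = bs[order], be[order]
        rs = grp["start"].to_numpy()[:, None]
        re_ = grp["end"].to_numpy()[:, None]
        hit = ((rs < be[None, :]) & (bs[None, :] < re_)).any(axis=1)
        keep[recs.index.get_indexer(grp.index)] = ~hit
    removed = int((~keep).sum())
    log.info("blacklist filter removed %d records", removed)
    return recs.loc[keep]


def replicate_correlation(
    replicates: pd.DataFrame, threshold: float = 0.95
) -> tuple[pd.DataFrame, bool]:
    """Pairwise Pearson r between replicate count vectors and a merge gate.

    ``replicates`` is features x replicates. The gate is True when every
    off-diagonal r exceeds ``threshold`` (the merge criterion). Zero-variance
    replicates give NaN with a warning and fail the gate.
    """
    if replicates.shape[1] < 2:
        raise ValidationError("need at least 2 replicates")
    mat = replicates.to_numpy(dtype=float)
    sd = mat.std(axis=0)
    if (sd == 0).any():
        warnings.warn("zero-variance replicate; correlation undefined", stacklevel=2)
    with np.errstate(invalid="ignore"):
        r = np.corrcoef(mat, rowvar=False)
    r[np.isnan(r)] = np.nan
    rmat = pd.DataFrame(r, index=replicates.columns, columns=replicates.columns)
    off = r[~np.eye(len(r), dtype=bool)]
    gate = bool(np.all(np.nan_to_num(off, nan=-np.inf) > threshold))
    return rmat, gate


def expression_quartiles(expression: pd.Series) -> pd.Series:
    """Rank-based quartile labels Q1 (lowest) .. Q4 (highest).

    Ties are broken by stable input order, so quartile sizes differ by at
    most one even when all values are equal.
    """
    if len(expression) < 4:
        raise ValidationError("need at least 4 genes for quartiles")
    vals = expression.to_numpy(dtype=float)
    order = np.argsort(vals, kind="stable")
    n = len(vals)
    labels = np.empty(n, dtype=object)
    for rank, idx in enumerate(order):
        labels[idx] = f"Q{1 + (rank * 4) // n}"
    return pd.Series(labels, index=expression.index, name="quartile")
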