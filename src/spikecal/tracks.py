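"""Genomic containers: binned coverage tracks, gene models, signal matrices.

Coordinates are 0-based half-open (BED convention) throughout. A coverage
track stores, per contig, the TOTAL signal falling in each fixed-width bin;
signal is treated as uniformly distributed within a bin, so any sub-bin
interval receives a length-proportional share. The TSS of a minus-strand
gene is the last base of its interval (interval end - 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .errors import ValidationError


@dataclass
class CoverageTrack:
    """Binned non-negative signal over named contigs with fixed bin size."""

    data: dict[str, np.ndarray]
    bin_size: int

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValidationError("bin_size must be positive")
        clean: dict[str, np.ndarray] = {}
        for contig, vals in self.data.items():
            arr = np.asarray(vals, dtype=float)
            if arr.ndim != 1:
                raise ValidationError(f"track for {contig} is not 1-D")
            if not np.isfinite(arr).all():
                raise ValidationError(f"non-finite signal on {contig}")
            if (arr < 0).any():
                raise ValidationError(f"negative signal on {contig}")
            clean[contig] = arr
        self.data = clean

    @property
    def total(self) -> float:
        return float(sum(arr.sum() for arr in self.data.values()))

    def contig_length(self, contig: str) -> int:
        return len(self.data[contig]) * self.bin_size

    def scaled(self, factor: float) -> "CoverageTrack":
        return CoverageTrack(
            {c: v * factor for c, v in self.data.items()}, self.bin_size
        )

    def cumulative(self, contig: str) -> np.ndarray:
        """Cumulative signal at bin edges: F[k] = total signal in [0, k*bin).

        Cached per contig; tracks are treated as immutable after creation.
        """
        cache = self.__dict__.setdefault("_cum_cache", {})
        if contig not in cache:
            arr = self.data[contig]
            out = np.empty(len(arr) + 1)
            out[0] = 0.0
            np.cumsum(arr, out=out[1:])
            cache[contig] = out
        return cache[contig]

    def signal_at(self, contig: str, positions: np.ndarray) -> np.ndarray:
        """Cumulative signal F(x) at arbitrary bp positions (clipped to contig).

        Signal is uniform within a bin, so F is piecewise linear between bin
        edges.
        """
        cum = self.cumulative(contig)
        arr = self.data[contig]
        length = len(arr) * float(self.bin_size)
        x = np.clip(np.asarray(positions, dtype=float), 0.0, length)
        k = np.minimum((x // self.bin_size).astype(np.int64), len(arr) - 1)
        frac = (x - k * self.bin_size) / self.bin_size
        return cum[k] + frac * arr[k]


@dataclass(frozen=True)
class GeneModel:
    """One gene: contig, strand, TSS/TES coordinates and annotation flags.

    For a minus-strand gene TSS > TES in genomic coordinates; the occupied
    half-open interval is [tes + 1, tss + 1) so that the TSS base is the
    interval end - 1.
    """

    gene_id: str
    contig: str
    strand: str
    tss: int
    tes: int
    cgi: bool = False
    polycomb: bool = False
    class_label: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"{self.gene_id}: strand must be + or -")
        if self.tes == self.tss:
            raise ValidationError(f"{self.gene_id}: TES == TSS")
        if self.strand == "+" and self.tes < self.tss:
            raise ValidationError(f"{self.gene_id}: + strand needs TES > TSS")
        if self.strand == "-" and self.tes > self.tss:
            raise ValidationError(f"{self.gene_id}: - strand needs TSS > TES")

    @property
    def length(self) -> int:
        return abs(self.tes - self.tss)

    @property
    def start(self) -> int:
        return self.tss if self.strand == "+" else self.tes + 1

    @property
    def end(self) -> int:
        return self.tes if self.strand == "+" else self.tss + 1

    def window(self, rel_start: int, rel_end: int) -> tuple[int, int]:
        """Genomic half-open interval for TSS-relative offsets [rel_start, rel_end).

        Offsets increase in the direction of transcription. For the minus
        strand the genomic interval is reflected about the TSS base.
        """
        if rel_end <= rel_start:
            raise ValidationError("window requires rel_end > rel_start")
        if self.strand == "+":
            return self.tss + rel_start, self.tss + rel_end
        return self.tss - rel_end + 1, self.tss - rel_start + 1


@dataclass
class SignalMatrix:
    """Regions x bins real matrix with an anchor scheme.

    ``anchor`` is one of ``"TSS"`` (fixed-width windows centred on the TSS),
    ``"scaled"`` (gene bodies resampled to a fixed bin count, flanks
    unscaled) or ``"center"``. Rows are oriented so transcription runs left
    to right.
    """

    values: np.ndarray
    region_ids: list[str]
    anchor: str
    bin_size: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("SignalMatrix values must be 2-D")
        if self.values.shape[0] != len(self.region_ids):
            raise ValidationError("row count != number of region ids")

    @property
    def profile(self) -> np.ndarray:
        """Column means ignoring NaN padding (the metaplot)."""
        return np.nanmean(self.values, axis=0)


def window_sums(
    track: CoverageTrack,
    contig: str,
    start: float,
    end: float,
    nbins: int,
) -> np.ndarray:
    """Length-weighted signal sums over ``nbins`` equal sub-windows of [start, end).

    Sub-windows that lie entirely outside the contig are NaN; partial
    overlaps count only the in-bounds portion. Unknown contig raises KeyError.
    """
    if end <= start:
        raise ValidationError("window requires end > start")
    if nbins < 1:
        raise ValidationError("nbins must be >= 1")
    edges = np.linspace(float(start), float(end), nbins + 1)
    cum = track.signal_at(contig, edges)
    out = np.diff(cum)
    length = track.contig_length(contig)
    fully_outside = (edges[1:] <= 0) | (edges[:-1] >= length)
    out[fully_outside] = np.nan
    return out


def genes_to_frame(genes: Iterable[GeneModel]):
    """Tabulate gene models (useful for BED export and joins)."""
    import pandas as pd

    rows = [
        {
            "gene_id": g.gene_id,
            "contig": g.contig,
            "start": g.start,
            "end": g.end,
            "strand": g.strand,
            "tss": g.tss,
            "tes": g.tes,
            "cgi": g.cgi,
            "polycomb": g.polycomb,
        }
        for g in genes
    ]
    return pd.DataFrame(rows)
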