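"""RNAPII pausing index, ECDF summaries and phospho-isoform ratios.

The pausing index PI of a gene is the RNAPII signal density (signal per bp)
in a promoter-proximal window divided by the density over the gene body; a
drop in PI between conditions indicates increased pause release. Default
windows follow the common convention: promoter TSS-30..TSS+300, body
TSS+300..TES, both strand-aware and configurable; genes shorter than 1 kb
are excluded so the windows cannot overlap.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .signal import count_in_intervals
from .tracks import CoverageTrack, GeneModel

PROMOTER_WINDOW = (-30, 300)
MIN_GENE_LENGTH = 1000


@dataclass
class PausingRecord:
    gene_id: str
    promoter_density: float
    body_density: float
    pausing_index: float
    valid: bool
    reason: str = ""


def pausing_index(
    track: CoverageTrack,
    gene: GeneModel,
    promoter_window: tuple[int, int] = PROMOTER_WINDOW,
    body_window: tuple[int, int | None] = (PROMOTER_WINDOW[1], None),
    min_gene_length: int = MIN_GENE_LENGTH,
) -> PausingRecord:
    """PI = promoter signal density / body signal density for one gene.

    Windows are TSS-relative (offsets increase with transcription); a body
    end of None means the TES. Genes shorter than ``min_gene_length`` or with
    zero body density yield an invalid record rather than an infinite PI.
    """
    p0, p1 = promoter_window
    b0 = body_window[0]
    b1 = gene.length if body_window[1] is None else body_window[1]
    if p1 <= p0 or b1 <= b0:
        raise ValidationError("windows must have positive length")
    if b0 < p1:
        raise ValidationError("promoter and body windows overlap")
    if gene.length < min_gene_length:
        return PausingRecord(gene.gene_id, np.nan, np.nan, np.nan, False, "short_gene")
    if b1 > gene.length:
        return PausingRecord(
            gene.gene_id, np.nan, np.nan, np.nan, False, "body_outside_gene"
        )
    lo_p, hi_p = gene.window(p0, p1)
    lo_b, hi_b = gene.window(b0, b1)
    counts = count_in_intervals(
        track,
        pd.DataFrame(
            {
                "contig": [gene.contig, gene.contig],
                "start": [lo_p, lo_b],
                "end": [hi_p, hi_b],
            }
        ),
    ).to_numpy()
    prom_density = counts[0] / (p1 - p0)
    body_density = counts[1] / (b1 - b0)
    if not np.isfinite(prom_density) or not np.isfinite(body_density):
        return PausingRecord(gene.gene_id, np.nan, np.nan, np.nan, False, "off_contig")
    if body_density == 0:
        return PausingRecord(
            gene.gene_id, prom_density, 0.0, np.nan, False, "zero_body_signal"
        )
    return PausingRecord(
        gene.gene_id, prom_density, body_density, prom_density / body_density, True
    )


def pausing_table(
    track: CoverageTrack, genes: Sequence[GeneModel], **kwargs
) -> pd.DataFrame:
    """Pausing records for a gene set as a DataFrame (one row per gene)."""
    recs = [pausing_index(track, g, **kwargs) for g in genes]
    return pd.DataFrame([r.__dict__ for r in recs]).set_index("gene_id")


def pausing_ecdf(records) -> pd.DataFrame:
    """ECDF of pausing indices; accepts records or a {condition: records} map.

    Returns a long table (pausing_index, ecdf[, condition]) with one row per
    valid record, sorted ascending; the ECDF at the k-th sorted value is k/n.
    Invalid records are excluded (their count is in ``attrs['n_invalid']``).
    """
    if isinstance(records, Mapping):
        parts = []
        for cond, recs in records.items():
            t = pausing_ecdf(recs)
            t["condition"] = cond
            parts.append(t)
        out = pd.concat(parts, ignore_index=True)
        out.attrs["n_invalid"] = sum(p.attrs.get("n_invalid", 0) for p in parts)
        return out
    vals, n_invalid = [], 0
    for r in records:
        pi = r.pausing_index if isinstance(r, PausingRecord) else float(r)
        if np.isfinite(pi):
            vals.append(pi)
        else:
            n_invalid += 1
    if not vals:
        raise ValidationError("no valid pausing records")
    vals = np.sort(np.asarray(vals, dtype=float))
    out = pd.DataFrame(
        {"pausing_index": vals, "ecdf": np.arange(1, len(vals) + 1) / len(vals)}
    )
    out.attrs["n_invalid"] = n_invalid
    return out


def ecdf_at(table: pd.DataFrame, x: float) -> float:
    """Evaluate an ECDF table at x: fraction of values <= x."""
    return float((table["pausing_index"].to_numpy() <= x).mean())


def phospho_ratio_change(
    ser_track_unt: CoverageTrack,
    ser_track_oht: CoverageTrack,
    ntd_track_unt: CoverageTrack,
    ntd_track_oht: CoverageTrack,
    intervals,
) -> pd.DataFrame:
    """Per-interval fold change of phospho-RNAPII normalized to total RNAPII.

    fold = (Ser_OHT / NTD_OHT) / (Ser_UNT / NTD_UNT); intervals with a
    non-positive NTD count in either condition are invalid with a reason.
    """
    tracks = [ser_track_unt, ser_track_oht, ntd_track_unt, ntd_track_oht]
    bins = {t.bin_size for t in tracks}
    if len(bins) != 1:
        raise ValidationError("all four tracks must share one bin size")
    counts = [count_in_intervals(t, intervals) for t in tracks]
    su, so, nu, no = (c.to_numpy() for c in counts)
    fold = np.full(len(su), np.nan)
    reason = np.full(len(su), "", dtype=object)
    bad_ntd = ~(np.isfinite(nu) & np.isfinite(no)) | (nu <= 0) | (no <= 0)
    reason[bad_ntd] = "zero_ntd_signal"
    bad_ser = ~bad_ntd & (~(np.isfinite(su) & np.isfinite(so)) | (su <= 0))
    reason[bad_ser] = "zero_or_missing_ser_unt_signal"
    ok = ~bad_ntd & ~bad_ser
    with np.errstate(divide="ignore", invalid="ignore"):
        fold[ok] = (so[ok] / no[ok]) / (su[ok] / nu[ok])
    return pd.DataFrame(
        {"fold_change": fold, "valid": ok, "reason": reason}, index=counts[0].index
    )
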