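"""Promoter-based gene classification: non-CGI / PRC / non-PRC.

A gene is CGI-associated when its promoter window overlaps a (non-methylated)
CpG-island interval. Among CGI-associated genes, those whose promoter
overlaps BOTH a RING1B and a SUZ12 interval are polycomb-occupied (PRC);
the rest are non-PRC. Everything else is non-CGI, regardless of polycomb
overlap. The three classes partition the gene set.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .signal import _intervals_frame
from .tracks import GeneModel

log = logging.getLogger(__name__)

PROMOTER_HALF_WINDOW = 1000

NON_CGI = "non-CGI"
PRC = "PRC"
NON_PRC = "non-PRC"


def _overlap_index(intervals) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-contig merged, sorted interval arrays for fast overlap queries."""
    df = _intervals_frame(intervals)
    out = {}
    for contig, grp in df.groupby("contig", sort=False):
        s = grp["start"].to_numpy(dtype=np.int64)
        e = grp["end"].to_numpy(dtype=np.int64)
        if (e <= s).any():
            raise ValidationError(f"interval with end <= start on {contig}")
        order = np.argsort(s)
        s, e = s[order], e[order]
        # merge overlapping/adjacent so a single searchsorted answers queries
        ms, me = [s[0]], [e[0]]
        for a, b in zip(s[1:], e[1:]):
            if a <= me[-1]:
                me[-1] = max(me[-1], b)
            else:
                ms.append(a)
                me.append(b)
        out[str(contig)] = (np.asarray(ms), np.asarray(me))
    return out


def _overlaps(index, contig: str, start: int, end: int) -> bool:
    """Half-open overlap of [start, end) with any indexed interval."""
    if contig not in index:
        return False
    ms, me = index[contig]
    i = int(np.searchsorted(ms, end))  # intervals starting before `end`
    return i > 0 and me[i - 1] > start


def classify_genes(
    genes: Sequence[GeneModel],
    cgi_intervals,
    ring1b_intervals,
    suz12_intervals,
    promoter_window: int = PROMOTER_HALF_WINDOW,
) -> pd.DataFrame:
    """Classify genes by promoter (TSS +/- window) overlap with CGI and polycomb peaks.

    Returns a table with the supporting flags (cgi_overlap, ring1b_bound,
    suz12_bound) and the class label; genes whose contig appears in none of
    the interval sets are reported (logged) and classified non-CGI.
    """
    if promoter_window <= 0:
        raise ValidationError("promoter_window must be positive")
    cgi = _overlap_index(cgi_intervals)
    r1b = _overlap_index(ring1b_intervals)
    suz = _overlap_index(suz12_intervals)
    known_contigs = set(cgi) | set(r1b) | set(suz)
    rows = []
    unknown = set()
    for g in genes:
        if g.contig not in known_contigs:
            unknown.add(g.contig)
        lo = g.tss - promoter_window
        hi = g.tss + promoter_window
        has_cgi = _overlaps(cgi, g.contig, lo, hi)
        has_r1b = _overlaps(r1b, g.contig, lo, hi)
        has_suz = _overlaps(suz, g.contig, lo, hi)
        if not has_cgi:
            label = NON_CGI
        elif has_r1b and has_suz:
            label = PRC
        else:
            label = NON_PRC
        rows.append(
            {
                "gene_id": g.gene_id,
                "cgi_overlap": has_cgi,
                "ring1b_bound": has_r1b,
                "suz12_bound": has_suz,
                "gene_class": label,
            }
        )
    if unknown:
        log.warning("gene contigs absent from all interval sets: %s", sorted(unknown))
    return pd.DataFrame(rows).set_index("gene_id")


def class_composition(classes: pd.DataFrame, gene_subset=None) -> pd.DataFrame:
    """Fraction of each class within a gene subset (counts alongside).

    ``gene_subset=None`` uses all classified genes. An empty subset or one
    containing unclassified genes is an error.
    """
    if gene_subset is None:
        sub = classes
    else:
        subset = list(gene_subset)
        if len(subset) == 0:
            raise ValidationError("empty gene subset")
        missing = [g for g in subset if g not in classes.index]
        if missing:
            raise ValidationError(f"subset contains unclassified genes: {missing[:5]}")
        sub = classes.loc[subset]
    counts = sub["gene_class"].value_counts()
    out = pd.DataFrame(
        {
            "count": [int(counts.get(c, 0)) for c in (NON_CGI, PRC, NON_PRC)],
        },
        index=pd.Index([NON_CGI, PRC, NON_PRC], name="gene_class"),
    )
    out["fraction"] = out["count"] / out["count"].sum()
    return out
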