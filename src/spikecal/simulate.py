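"""Synthetic dual-genome data with known ground truth.

Emulates a two-condition (UNT vs OHT) spike-in calibrated experiment: a
fixed fraction of spike-in cells is mixed into every sample (with a small
random mixing error between replicates), gene counts are negative-binomial,
a condition-dependent shift affects a chosen fraction of target genes, and
spike-in genes are condition-invariant. Matched input-gDNA samples measure
the realized genome mixing without assay enrichment.

The nominal mixing fraction default (0.25) corresponds to mixing 2.5e6
spike-in cells into 1e7 target cells.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from .counts import SPIKE, TARGET, TaggedCounts
from .errors import SizingError, ValidationError
from .tracks import CoverageTrack, GeneModel

log = logging.getLogger(__name__)

UNT = "UNT"
OHT = "OHT"


@dataclass
class SimConfig:
    """Generative parameters for the synthetic experiment.

    Counts follow NB(mean mu, variance mu + dispersion * mu^2); dispersion 0
    degenerates to Poisson. ``mean_depth`` is the expected target-genome
    read total of an untreated sample; shifted genes raise the treated
    totals above it, exactly the situation total-count normalization cannot
    see. ``spike_cell_fraction`` is the nominal spike/target cell ratio; the
    realized per-sample ratio is log-normal around it with coefficient of
    variation ``mixing_cv``.
    """

    n_target_genes: int = 2000
    n_spike_genes: int = 500
    n_replicates_per_condition: int = 3
    spike_cell_fraction: float = 0.25
    mixing_cv: float = 0.05
    frac_shifted: float = 0.3
    shift_log2fc: float = 1.0
    dispersion: float = 0.05
    mean_depth: float = 2e6
    seed: int = 0
    # secondary knobs (documented defaults, rarely moved)
    baseline_sigma: float = 1.5   # log-sd of the log-normal baseline means
    frac_low: float = 0.2         # fraction of target genes forced lowly expressed
    low_scale: float = 0.05       # baseline multiplier for that fraction
    depth_cv: float = 0.1         # CV of the per-sample library depth factor
    input_depth: float | None = None  # expected input target total (default mean_depth)

    def __post_init__(self) -> None:
        for name in ("n_target_genes", "n_spike_genes", "n_replicates_per_condition"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 1:
                raise ValidationError(f"{name} must be a positive integer, got {v!r}")
        for name in ("spike_cell_fraction", "frac_low", "low_scale"):
            v = float(getattr(self, name))
            if not math.isfinite(v) or not (0.0 < v < 1.0):
                raise ValidationError(f"{name} must lie in (0, 1), got {v!r}")
        if not (0.0 <= float(self.frac_shifted) <= 1.0):
            raise ValidationError("frac_shifted must lie in [0, 1]")
        for name in ("mixing_cv", "dispersion", "depth_cv", "baseline_sigma"):
            v = float(getattr(self, name))
            if not math.isfinite(v) or v < 0:
                raise ValidationError(f"{name} must be finite and >= 0, got {v!r}")
        if not math.isfinite(float(self.mean_depth)) or self.mean_depth <= 0:
            raise ValidationError("mean_depth must be finite and > 0")
        if not math.isfinite(float(self.shift_log2fc)):
            raise ValidationError("shift_log2fc must be finite")
        if self.input_depth is not None and (
            not math.isfinite(float(self.input_depth)) or self.input_depth <= 0
        ):
            raise ValidationError("input_depth must be finite and > 0")


@dataclass
class SimTruth:
    """Ground truth of one simulation.

    ``genes``: gene_id, genome, baseline_mean, true_log2fc (0 for spike-in
    and unshifted genes). ``samples``: condition, realized mixing ratio,
    realized depth factor, matched input name.
    """

    genes: pd.DataFrame
    samples: pd.DataFrame


class SimulatedCounts(NamedTuple):
    assay: TaggedCounts
    inputs: TaggedCounts
    truth: SimTruth


def _lognormal_about(rng: np.random.Generator, mean: float, cv: float, size: int):
    """Log-normal draws with the requested arithmetic mean and CV (cv=0 -> constant)."""
    if cv == 0:
        return np.full(size, float(mean))
    sigma2 = math.log1p(cv * cv)
    mu = math.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, math.sqrt(sigma2), size)


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float):
    """NB(mu, mu + a*mu^2) counts; Poisson when the dispersion is zero."""
    mean = np.asarray(mean, dtype=float)
    if dispersion == 0:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    # negative_binomial(r, p) has mean r(1-p)/p = mu for p = r/(r+mu)
    p = r / (r + mean)
    return rng.negative_binomial(r, np.clip(p, 1e-12, 1.0))


def _sample_names(cfg: SimConfig) -> tuple[list[str], np.ndarray]:
    names, cond = [], []
    for c in (UNT, OHT):
        for r in range(1, cfg.n_replicates_per_condition + 1):
            names.append(f"{c}_rep{r}")
            cond.append(c)
    return names, np.array(cond)


def simulate_counts(cfg: SimConfig) -> SimulatedCounts:
    """Draw assay and matched-input count matrices plus the truth table.

    Target gene s-mean: baseline * 2^(log2FC * [condition==OHT]) * depth_s.
    Spike gene s-mean: spike_baseline * mean_depth * mixing_s * depth_s,
    i.e. spike material scales with the realized cell-mixing ratio and the
    library depth but never with condition. Inputs have uniform per-gene
    means within each genome so their spike/target total ratio estimates the
    realized mixing ratio.
    """
    if not isinstance(cfg, SimConfig):
        cfg = SimConfig(**cfg) if isinstance(cfg, dict) else cfg
    ss = np.random.SeedSequence(cfg.seed)
    r_base, r_mix, r_depth, r_assay, r_input = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )

    names, cond = _sample_names(cfg)
    n_samp = len(names)
    is_oht = (cond == OHT).astype(float)

    # per-gene baselines
    p = r_base.lognormal(0.0, cfg.baseline_sigma, cfg.n_target_genes)
    n_low = int(round(cfg.frac_low * cfg.n_target_genes))
    low_idx = r_base.choice(cfg.n_target_genes, size=n_low, replace=False)
    p[low_idx] *= cfg.low_scale
    p *= cfg.mean_depth / p.sum()

    q = r_base.lognormal(0.0, cfg.baseline_sigma, cfg.n_spike_genes)
    q /= q.sum()

    lfc = np.zeros(cfg.n_target_genes)
    n_shift = int(round(cfg.frac_shifted * cfg.n_target_genes))
    shift_idx = r_base.choice(cfg.n_target_genes, size=n_shift, replace=False)
    lfc[shift_idx] = cfg.shift_log2fc

    # per-sample factors
    mixing = _lognormal_about(r_mix, cfg.spike_cell_fraction, cfg.mixing_cv, n_samp)
    depth = _lognormal_about(r_depth, 1.0, cfg.depth_cv, n_samp)
    depth_in = _lognormal_about(r_depth, 1.0, cfg.depth_cv, n_samp)

    mu_target = p[:, None] * np.exp2(lfc[:, None] * is_oht[None, :]) * depth[None, :]
    mu_spike = q[:, None] * cfg.mean_depth * (mixing * depth)[None, :]
    assay_mat = np.vstack(
        [_nb_draw(r_assay, mu_target, cfg.dispersion),
         _nb_draw(r_assay, mu_spike, cfg.dispersion)]
    )

    d_in = cfg.mean_depth if cfg.input_depth is None else float(cfg.input_depth)
    mu_t_in = np.full((cfg.n_target_genes, n_samp), d_in / cfg.n_target_genes)
    mu_t_in = mu_t_in * depth_in[None, :]
    mu_s_in = (d_in / cfg.n_spike_genes) * (mixing * depth_in)[None, :]
    mu_s_in = np.broadcast_to(mu_s_in, (cfg.n_spike_genes, n_samp))
    input_mat = np.vstack(
        [_nb_draw(r_input, mu_t_in, cfg.dispersion),
         _nb_draw(r_input, mu_s_in, cfg.dispersion)]
    )

    gene_ids = [f"tgene_{i:05d}" for i in range(cfg.n_target_genes)] + [
        f"sgene_{i:05d}" for i in range(cfg.n_spike_genes)
    ]
    genome = pd.Series(
        [TARGET] * cfg.n_target_genes + [SPIKE] * cfg.n_spike_genes,
        index=gene_ids,
        name="genome_tag",
    )
    input_names = [f"input_{s}" for s in names]
    assay_meta = pd.DataFrame(
        {"condition": cond, "assay": "assay", "matched_input": input_names},
        index=names,
    )
    input_meta = pd.DataFrame({"condition": cond, "assay": "input"}, index=input_names)

    assay = TaggedCounts(
        pd.DataFrame(assay_mat, index=gene_ids, columns=names), genome, assay_meta
    )
    inputs = TaggedCounts(
        pd.DataFrame(input_mat, index=gene_ids, columns=input_names),
        genome,
        input_meta,
    )
    truth = SimTruth(
        genes=pd.DataFrame(
            {
                "genome": genome.to_numpy(),
                "baseline_mean": np.concatenate([p, q * cfg.mean_depth]),
                "true_log2fc": np.concatenate([lfc, np.zeros(cfg.n_spike_genes)]),
            },
            index=gene_ids,
        ),
        samples=pd.DataFrame(
            {
                "condition": cond,
                "mixing_ratio": mixing,
                "depth_factor": depth,
                "input_depth_factor": depth_in,
                "matched_input": input_names,
            },
            index=names,
        ),
    )
    return SimulatedCounts(assay, inputs, truth)


# ---------------------------------------------------------------------------
# toy coverage tracks


@dataclass
class TrackShape:
    """Generative shape of the toy coverage tracks.

    Every gene gets a promoter peak over its first ``promoter_bp`` and a
    gene-body plateau; densities are signal units per bp. Setting
    ``promoter_density < body_density`` produces a promoter-dip profile
    (H3K36me2-like); the default 5' bias emulates paused-polymerase tracks.
    In the treated condition the body density of shifted genes is multiplied
    by 2^shift_log2fc.
    """

    contig: str = "chrT"
    contig_bp: int = 6_100_000  # fits the default 2000-gene layout
    bin_bp: int = 10
    gene_length_bp: int = 2_000
    gap_bp: int = 1_000
    promoter_bp: int = 300
    promoter_density: float = 10.0
    body_density: float = 2.0
    background_density: float = 0.0
    noise_cv: float = 0.0

    def __post_init__(self) -> None:
        for name in ("contig_bp", "bin_bp", "gene_length_bp", "gap_bp", "promoter_bp"):
            if getattr(self, name) < (1 if name != "gap_bp" else 0):
                raise ValidationError(f"{name} out of range")
        if self.contig_bp % self.bin_bp:
            raise ValidationError("contig_bp must be a multiple of bin_bp")
        if self.promoter_bp >= self.gene_length_bp:
            raise ValidationError("promoter_bp must be smaller than gene_length_bp")
        for name in ("promoter_density", "body_density", "background_density", "noise_cv"):
            v = float(getattr(self, name))
            if not math.isfinite(v) or v < 0:
                raise ValidationError(f"{name} must be finite and >= 0")


class SimulatedTracks(NamedTuple):
    tracks: dict[str, CoverageTrack]
    genes: list[GeneModel]
    shape: TrackShape


def _place_genes(cfg: SimConfig, shape: TrackShape) -> list[GeneModel]:
    """Non-overlapping alternating-strand genes; CGI on even, polycomb on 1 in 4."""
    span = shape.gene_length_bp + shape.gap_bp
    needed = shape.gap_bp + cfg.n_target_genes * span
    if needed > shape.contig_bp:
        raise SizingError(
            f"{cfg.n_target_genes} genes of {shape.gene_length_bp} bp with "
            f"{shape.gap_bp} bp gaps need {needed} bp; contig is {shape.contig_bp} bp"
        )
    genes = []
    for i in range(cfg.n_target_genes):
        start = shape.gap_bp + i * span
        end = start + shape.gene_length_bp
        strand = "+" if i % 2 == 0 else "-"
        tss, tes = (start, end) if strand == "+" else (end - 1, start - 1)
        genes.append(
            GeneModel(
                gene_id=f"tgene_{i:05d}",
                contig=shape.contig,
                strand=strand,
                tss=tss,
                tes=tes,
                cgi=(i % 2 == 0),
                polycomb=(i % 4 == 0),
            )
        )
    return genes


def simulate_tracks(cfg: SimConfig, shape: TrackShape | None = None) -> SimulatedTracks:
    """Toy per-sample coverage tracks with known promoter/body densities.

    Tracks are built per bp (promoter peak + body plateau on a uniform
    background) and summed into fixed-size bins, so expected pausing indices
    and metaprofiles are known exactly from ``shape``.
    """
    shape = shape or TrackShape()
    genes = _place_genes(cfg, shape)
    names, cond = _sample_names(cfg)
    n_shift = int(round(cfg.frac_shifted * cfg.n_target_genes))
    shifted = {g.gene_id for g in genes[:n_shift]}

    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(6)[5])
    tracks: dict[str, CoverageTrack] = {}
    for name, c in zip(names, cond):
        dens = np.full(shape.contig_bp, shape.background_density)
        for g in genes:
            body_density = shape.body_density
            if c == OHT and g.gene_id in shifted:
                body_density *= 2.0 ** cfg.shift_log2fc
            lo, hi = g.window(0, shape.promoter_bp)
            dens[lo:hi] = shape.promoter_density
            lo, hi = g.window(shape.promoter_bp, g.length)
            dens[lo:hi] = body_density
        binned = dens.reshape(-1, shape.bin_bp).sum(axis=1)
        if shape.noise_cv > 0:
            binned = binned * _lognormal_about(rng, 1.0, shape.noise_cv, len(binned))
        tracks[name] = CoverageTrack({shape.contig: binned}, shape.bin_bp)
    return SimulatedTracks(tracks, genes, shape)


def simulate_annotation(genes: list[GeneModel], window_bp: int = 500) -> dict[str, pd.DataFrame]:
    """Toy CGI / RING1B / SUZ12 interval sets consistent with the gene flags.

    CGI intervals cover the promoters of CGI-flagged genes; RING1B and SUZ12
    intervals cover the promoters of polycomb-flagged genes, so downstream
    classification has an exact expected answer.
    """
    def promoters(flag: str) -> pd.DataFrame:
        rows = [
            {
                "contig": g.contig,
                "start": max(0, min(g.window(-window_bp, window_bp))),
                "end": max(g.window(-window_bp, window_bp)),
                "name": f"{flag}_{g.gene_id}",
            }
            for g in genes
            if getattr(g, flag)
        ]
        return pd.DataFrame(rows, columns=["contig", "start", "end", "name"])

    return {
        "cgi": promoters("cgi"),
        "ring1b": promoters("polycomb"),
        "suz12": promoters("polycomb"),
    }
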