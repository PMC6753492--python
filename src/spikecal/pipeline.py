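"""End-to-end pipeline: simulate -> calibrate -> test -> profile -> pause -> classify.

Every stage writes deterministic TSV/BED/bedGraph artifacts into the output
directory; ``run.json`` stamps the configuration hash and seed, and the log
records the calibration factors and call counts.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .calibration import SpikeInCalibrator
from .config import RunConfig
from .differential import NegativeBinomialWaldDE
from .errors import PipelineError, SpikecalError
from .gene_classes import class_composition, classify_genes
from .pausing import pausing_ecdf, pausing_table
from .signal import replicate_correlation, tss_matrix
from .simulate import simulate_annotation, simulate_counts, simulate_tracks

log = logging.getLogger(__name__)


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except SpikecalError as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return wrapped

    return deco


def run_pipeline(config: RunConfig, outdir) -> Path:
    """Execute all stages on synthetic data; returns the artifact directory."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)

    # simulate
    sim = _stage("simulate")(simulate_counts)(config.sim)
    tracks = _stage("simulate")(simulate_tracks)(config.sim, config.track_shape)
    io.write_tagged_counts(sim.assay, out / "counts.tsv", out / "samples.tsv")
    io.write_tagged_counts(sim.inputs, out / "input_counts.tsv", out / "input_samples.tsv")
    io.write_table(sim.truth.genes, out / "truth_genes.tsv", index_label="gene_id")
    io.write_table(sim.truth.samples, out / "truth_samples.tsv", index_label="sample")
    io.write_genes_bed(tracks.genes, out / "genes.bed")
    for name, track in tracks.tracks.items():
        io.write_bedgraph(track, out / f"track_{name}.bedgraph")

    # calibrate
    cal = _stage("calibrate")(SpikeInCalibrator().fit)(sim.assay, sim.inputs)
    io.write_table(cal.report_, out / "factors.tsv", index_label="sample")

    # replicate correlation gate (per condition, on target counts)
    target = sim.assay.target_counts
    cond = sim.assay.samples["condition"]
    gates = {}
    for level in pd.unique(cond):
        cols = cond.index[cond == level]
        _, gate = _stage("correlate")(replicate_correlation)(
            target[list(cols)], threshold=config.correlation_gate
        )
        gates[str(level)] = bool(gate)

    # differential test
    de = NegativeBinomialWaldDE(
        padj_threshold=config.padj_threshold, fold_threshold=config.fold_threshold
    )
    _stage("diffexp")(de.fit)(sim.assay, cond, size_factors=cal.size_factor_)
    io.write_table(de.results_, out / "diffexp.tsv", index_label="gene_id")

    # TSS profile of the first sample's track
    first = next(iter(tracks.tracks))
    mat = _stage("profile")(tss_matrix)(
        tracks.tracks[first], tracks.genes, config.flank_bp, config.profile_bin_bp
    )
    offs = (np.arange(mat.values.shape[1]) - mat.values.shape[1] / 2) * mat.bin_size
    io.write_table(
        pd.DataFrame({"offset_bp": offs, "mean_signal": mat.profile}),
        out / "tss_profile.tsv",
    )

    # pausing
    pi_unt = _stage("pausing")(pausing_table)(
        tracks.tracks[first], tracks.genes, promoter_window=config.pausing_promoter
    )
    io.write_table(pi_unt, out / "pausing.tsv", index_label="gene_id")
    ecdf = pausing_ecdf(list(pi_unt["pausing_index"].dropna()))
    io.write_table(ecdf, out / "pausing_ecdf.tsv")

    # classification against the toy annotation
    ann = simulate_annotation(tracks.genes, window_bp=config.flank_bp)
    classes = _stage("classify")(classify_genes)(
        tracks.genes,
        ann["cgi"],
        ann["ring1b"],
        ann["suz12"],
        promoter_window=config.promoter_window,
    )
    io.write_table(classes, out / "gene_classes.tsv", index_label="gene_id")
    comp = class_composition(classes)
    io.write_table(comp, out / "class_composition.tsv", index_label="gene_class")

    stamp = {
        "config_digest": config.digest,
        "seed": config.seed,
        "replicate_gates": gates,
        "n_up": de.n_up_,
        "n_down": de.n_down_,
    }
    with open(out / "run.json", "w") as fh:
        json.dump(stamp, fh, indent=2, sort_keys=True)
    log.info("pipeline complete: %s", stamp)
    return out
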