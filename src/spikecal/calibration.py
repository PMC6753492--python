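"""Spike-in calibration factors.

Four quantities per sample, all anchored on the exogenous spike-in genome:

* ``input_ratio`` r_s — spike/target read ratio in the matched input-gDNA
  sample, the realized cell-mixing proportion;
* ``track_scale`` f_s in (0, 1] — random-subsampling factor for track
  visualization, computed from the input-corrected spike depth
  a_s = spike_total_s / r_s as f_s = min(a) / a_s, so the lowest-spike-depth
  sample is untouched and no library is up-sampled;
* ``size_factor`` sigma_s — median-of-ratios size factor computed on spike
  genes only, after pre-normalizing each sample's spike counts by its input
  mixing ratio (relative to the median ratio). These size factors normalize
  the TARGET-gene counts in the differential test;
* equal-depth downsampling to the minimum library total, used for histone
  ChIP libraries that carry no spike-in.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .counts import SPIKE, TARGET, TaggedCounts
from .errors import CalibrationError, ValidationError
from .tracks import CoverageTrack

log = logging.getLogger(__name__)


@dataclass
class CalibrationFactors:
    """Per-sample calibration triple (plus the intermediate spike depth)."""

    input_ratio: pd.Series
    track_scale: pd.Series
    size_factor: pd.Series
    adjusted_spike_depth: pd.Series | None = None

    @property
    def frame(self) -> pd.DataFrame:
        cols = {
            "input_ratio": self.input_ratio,
            "track_scale": self.track_scale,
            "size_factor": self.size_factor,
        }
        if self.adjusted_spike_depth is not None:
            cols["adjusted_spike_depth"] = self.adjusted_spike_depth
        return pd.DataFrame(cols)


def compute_input_mixing_ratio(input_counts: TaggedCounts, sample: str) -> float:
    """Spike/target total read ratio of one input-gDNA sample.

    A zero target total is an error; a zero spike total yields ratio 0 with
    a warning (unusable for calibration).
    """
    if sample not in input_counts.counts.columns:
        raise ValidationError(f"sample {sample!r} not found in input counts")
    target_total = float(input_counts.totals(TARGET)[sample])
    spike_total = float(input_counts.totals(SPIKE)[sample])
    if target_total == 0:
        raise CalibrationError(f"input sample {sample!r} has zero target reads")
    if spike_total == 0:
        warnings.warn(
            f"input sample {sample!r} has zero spike reads; ratio 0 is unusable",
            stacklevel=2,
        )
        return 0.0
    return spike_total / target_total


def compute_input_mixing_ratios(
    assay_counts: TaggedCounts, input_counts: TaggedCounts
) -> pd.Series:
    """Input mixing ratio per ASSAY sample, via its matched input sample."""
    ratios = {}
    for s in assay_counts.sample_names:
        ratios[s] = compute_input_mixing_ratio(
            input_counts, assay_counts.matched_input_of(s)
        )
    return pd.Series(ratios, name="input_ratio")


def _check_ratios(samples, input_ratios: pd.Series) -> pd.Series:
    input_ratios = pd.Series(input_ratios)
    missing = [s for s in samples if s not in input_ratios.index]
    if missing:
        raise ValidationError(f"no input ratio for samples: {missing}")
    r = input_ratios.loc[list(samples)].astype(float)
    if not np.isfinite(r).all() or (r <= 0).any():
        bad = list(r.index[~(np.isfinite(r) & (r > 0))])
        raise CalibrationError(f"unusable input ratios (<= 0 or non-finite): {bad}")
    return r


def compute_track_scale_factors(
    assay_counts: TaggedCounts, input_ratios: pd.Series
) -> pd.Series:
    """Subsampling factor per sample from input-corrected spike depth.

    a_s = spike_total_s / r_s; f_s = min(a) / a_s. The sample with the
    smallest corrected spike depth keeps all reads (f = 1); deeper-spike
    samples are thinned harder.
    """
    samples = assay_counts.sample_names
    r = _check_ratios(samples, input_ratios)
    spike_tot = assay_counts.totals(SPIKE).astype(float)
    zero = list(spike_tot.index[spike_tot == 0])
    if zero:
        raise CalibrationError(f"zero spike reads in assay samples: {zero}")
    adjusted = spike_tot / r
    f = adjusted.min() / adjusted
    f.name = "track_scale"
    return f


def adjusted_spike_depth(
    assay_counts: TaggedCounts, input_ratios: pd.Series
) -> pd.Series:
    r = _check_ratios(assay_counts.sample_names, input_ratios)
    out = assay_counts.totals(SPIKE).astype(float) / r
    out.name = "adjusted_spike_depth"
    return out


def compute_spikein_size_factors(
    assay_counts: TaggedCounts, input_ratios: pd.Series
) -> pd.Series:
    """Median-of-ratios size factors over spike genes, input-ratio corrected.

    Each sample's spike counts are first divided by r_s / median(r) (keeping
    the factors near 1), genes with any zero are dropped from the geometric
    mean reference, and sigma_s is the median ratio to that reference. The
    returned factors normalize target-gene counts downstream.
    """
    samples = assay_counts.sample_names
    r = _check_ratios(samples, input_ratios)
    spike = assay_counts.spike_counts.astype(float)
    if spike.shape[0] < 2:
        raise CalibrationError("need at least 2 spike-tagged genes")
    pre = spike / (r / r.median())
    keep = (pre > 0).all(axis=1)
    if keep.sum() < 2:
        raise CalibrationError(
            "fewer than 2 spike genes with non-zero counts in all samples"
        )
    pre = pre.loc[keep]
    log_ref = np.log(pre).mean(axis=1)
    ratios = pre / np.exp(log_ref).to_numpy()[:, None]
    sigma = ratios.median(axis=0)
    sigma.name = "size_factor"
    if not np.isfinite(sigma).all() or (sigma <= 0).any():
        raise CalibrationError("non-positive or non-finite size factor computed")
    return sigma


def total_count_size_factors(assay_counts: TaggedCounts) -> pd.Series:
    """Conventional size factors from target-genome read totals.

    Geometric-mean-centred library totals — the normalization that a global
    shift silently defeats; provided for the calibrated-vs-naive contrast.
    """
    tot = assay_counts.totals(TARGET).astype(float)
    if (tot <= 0).any():
        raise CalibrationError("zero target totals; cannot form total-count factors")
    sigma = tot / np.exp(np.log(tot).mean())
    sigma.name = "size_factor"
    return sigma


# ---------------------------------------------------------------------------
# subsampling


def subsample_counts(
    counts: np.ndarray | CoverageTrack, factor: float, seed: int
) -> np.ndarray | CoverageTrack:
    """Binomial thinning: each read kept independently with probability ``factor``.

    Accepts an integer count array or a CoverageTrack with integer-valued
    bins; spike-in material is never passed through this function.
    """
    if not (0 < factor <= 1):
        raise ValidationError(f"subsampling factor must be in (0, 1], got {factor}")
    rng = np.random.default_rng(seed)
    if isinstance(counts, CoverageTrack):
        out = {}
        for contig, vals in counts.data.items():
            ints = np.rint(vals).astype(np.int64)
            if not np.allclose(ints, vals):
                raise ValidationError(
                    f"binomial thinning needs integer bin counts (contig {contig})"
                )
            out[contig] = ints if factor == 1.0 else rng.binomial(ints, factor)
        return CoverageTrack(out, counts.bin_size)
    arr = np.asarray(counts)
    if not np.issubdtype(arr.dtype, np.integer):
        ints = np.rint(arr).astype(np.int64)
        if not np.allclose(ints, arr):
            raise ValidationError("binomial thinning needs integer counts")
        arr = ints
    return arr.copy() if factor == 1.0 else rng.binomial(arr, factor)


def subsample_reads(reads: pd.DataFrame, factor: float, seed: int) -> pd.DataFrame:
    """Thin a read table: each row retained independently with probability ``factor``."""
    if not (0 < factor <= 1):
        raise ValidationError(f"subsampling factor must be in (0, 1], got {factor}")
    if factor == 1.0:
        return reads.copy()
    rng = np.random.default_rng(seed)
    keep = rng.random(len(reads)) < factor
    return reads.loc[keep]


def equal_depth_downsample(libraries: list, seed: int) -> list:
    """Exact downsampling of every library to the minimum total, without replacement.

    Libraries are integer count vectors (per-gene or per-bin) or read tables;
    the common total is the smallest input total.
    """
    if len(libraries) < 2:
        raise ValidationError("need at least 2 libraries to equalize depth")
    totals = []
    for i, lib in enumerate(libraries):
        t = len(lib) if isinstance(lib, pd.DataFrame) else int(np.asarray(lib).sum())
        if t == 0:
            raise ValidationError(f"library {i} is empty")
        totals.append(t)
    target = min(totals)
    rng = np.random.default_rng(seed)
    out = []
    for lib, t in zip(libraries, totals):
        if isinstance(lib, pd.DataFrame):
            if t == target:
                out.append(lib.copy())
            else:
                idx = rng.choice(t, size=target, replace=False)
                out.append(lib.iloc[np.sort(idx)])
        else:
            arr = np.asarray(lib)
            ints = np.rint(arr).astype(np.int64)
            if not np.allclose(ints, arr):
                raise ValidationError("equal-depth downsampling needs integer counts")
            if t == target:
                out.append(ints.copy())
            else:
                out.append(
                    rng.multivariate_hypergeometric(ints, target, method="marginals")
                )
    return out


# ---------------------------------------------------------------------------
# estimator


class SpikeInCalibrator(BaseEstimator, TransformerMixin):
    """Fit spike-in calibration factors; transform divides counts by them.

    Parameters
    ----------
    use_input_ratios
        Correct spike depths by the matched-input mixing ratio (the
        recommended, default behaviour). With False all ratios are taken
        as 1 (no input correction).
    reference
        Reference for the track-scale factors; only ``"min"`` (the
        minimum-corrected-spike-depth sample keeps all reads) is supported.

    Attributes (after ``fit``)
    --------------------------
    input_ratio_, adjusted_spike_depth_, track_scale_, size_factor_ : Series
    factors_ : CalibrationFactors
    report_ : DataFrame, one row per sample.
    """

    def __init__(self, use_input_ratios: bool = True, reference: str = "min"):
        self.use_input_ratios = use_input_ratios
        self.reference = reference

    def fit(self, X: TaggedCounts, y: TaggedCounts | None = None):
        """X: assay TaggedCounts; y: matched input TaggedCounts (required
        when ``use_input_ratios``)."""
        if self.reference != "min":
            raise ValidationError("only reference='min' is supported")
        if self.use_input_ratios:
            if y is None:
                raise ValidationError("input counts required when use_input_ratios")
            ratios = compute_input_mixing_ratios(X, y)
        else:
            ratios = pd.Series(1.0, index=X.sample_names, name="input_ratio")
        self.input_ratio_ = ratios
        self.adjusted_spike_depth_ = adjusted_spike_depth(X, ratios)
        self.track_scale_ = compute_track_scale_factors(X, ratios)
        self.size_factor_ = compute_spikein_size_factors(X, ratios)
        self.factors_ = CalibrationFactors(
            self.input_ratio_,
            self.track_scale_,
            self.size_factor_,
            self.adjusted_spike_depth_,
        )
        self.report_ = self.factors_.frame
        log.info("calibration factors:\n%s", self.report_)
        return self

    def transform(self, X: TaggedCounts) -> pd.DataFrame:
        """Size-factor-normalized TARGET-gene counts (genes x samples)."""
        if not hasattr(self, "size_factor_"):
            raise ValidationError("calibrator is not fitted")
        missing = [s for s in X.sample_names if s not in self.size_factor_.index]
        if missing:
            raise ValidationError(f"no size factor for samples: {missing}")
        return X.target_counts / self.size_factor_.loc[X.sample_names]
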