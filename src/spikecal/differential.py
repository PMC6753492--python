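"""Two-condition negative-binomial differential test with external size factors.

A deliberately transparent NB pipeline: per-gene method-of-moments
dispersion pooled within condition, a log-link NB fit per condition with the
size factors entering as offsets, and a Wald test on the condition contrast.
There is no dispersion or fold-change shrinkage and no independent
filtering; the size factors are supplied externally (from the spike-in
calibration), which is the point of the method — a genuinely global shift in
the target genome is invisible to total-count normalization but not to a
condition-invariant spike-in anchor.

Small-sample calibration: with a handful of replicates the plug-in
dispersion makes the usual normal reference for the Wald statistic
anti-conservative (empirically ~0.10 at nominal 0.05 with n=4 per group),
so the statistic is compared against a t distribution with the residual
degrees of freedom n1 + n2 - 2, which restores the nominal level. Pass
``wald_reference="normal"`` for the plain asymptotic test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .counts import TaggedCounts
from .errors import ValidationError

log = logging.getLogger(__name__)

LOG2 = np.log(2.0)

PADJ_THRESHOLD = 0.05
FOLD_THRESHOLD = 1.4


def _as_matrix(counts) -> tuple[np.ndarray, pd.Index, pd.Index]:
    if isinstance(counts, TaggedCounts):
        counts = counts.target_counts
    if not isinstance(counts, pd.DataFrame):
        raise ValidationError("counts must be a DataFrame or TaggedCounts")
    return counts.to_numpy(dtype=float), counts.index, counts.columns


def _group_masks(conditions, columns) -> tuple[np.ndarray, np.ndarray, list[str]]:
    if isinstance(conditions, pd.Series):
        cond = conditions.reindex(columns)
        if cond.isna().any():
            raise ValidationError("conditions missing for some samples")
    else:
        arr = np.asarray(conditions)
        if len(arr) != len(columns):
            raise ValidationError("conditions length != number of samples")
        cond = pd.Series(arr, index=columns)
    levels = list(pd.unique(cond))
    if len(levels) != 2:
        raise ValidationError(f"exactly two conditions required, got {levels}")
    return (cond == levels[0]).to_numpy(), (cond == levels[1]).to_numpy(), levels


def _align_sf(size_factors, cols) -> np.ndarray:
    if isinstance(size_factors, pd.Series):
        sf = size_factors.reindex(cols)
        if sf.isna().any():
            raise ValidationError("size factors missing for some samples")
        return sf.to_numpy(dtype=float)
    arr = np.asarray(size_factors, dtype=float)
    if len(arr) != len(cols):
        raise ValidationError("size factors length != number of samples")
    return arr


def estimate_dispersions(
    counts,
    size_factors: pd.Series,
    conditions,
    floor: float = 1e-8,
) -> pd.Series:
    """Per-gene NB dispersion by method of moments on normalized counts.

    Variances are pooled within condition (so a real condition effect does
    not inflate the estimate); alpha-hat = max(floor, (var - mean) / mean^2).
    Requires >= 2 replicates per condition.
    """
    mat, genes, cols = _as_matrix(counts)
    m0, m1, _ = _group_masks(conditions, cols)
    if m0.sum() < 2 or m1.sum() < 2:
        raise ValidationError(
            "dispersion cannot be estimated with a single-replicate condition"
        )
    sf = _align_sf(size_factors, cols)
    norm = mat / sf
    n0, n1 = int(m0.sum()), int(m1.sum())
    v0 = norm[:, m0].var(axis=1, ddof=1)
    v1 = norm[:, m1].var(axis=1, ddof=1)
    pooled = ((n0 - 1) * v0 + (n1 - 1) * v1) / (n0 + n1 - 2)
    mean = norm.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (pooled - mean) / mean**2
    alpha = np.where(np.isfinite(alpha), alpha, floor)
    return pd.Series(np.maximum(alpha, floor), index=genes, name="dispersion")


def _fit_group(y: np.ndarray, sf: np.ndarray, alpha: np.ndarray):
    """Vectorized per-gene NB log-link fit of one group mean.

    Solves sum_i (y_i - mu_i)/(1 + alpha*mu_i) = 0 with mu_i = sf_i*exp(beta)
    by Fisher scoring. Groups with zero total get a 0.5 continuity adjustment
    so beta stays finite (flagged by the caller). Returns (beta, information,
    converged).
    """
    tot = y.sum(axis=1)
    adj = np.where(tot > 0, tot, 0.5)
    beta = np.log(adj / sf.sum())
    zero_group = tot == 0
    converged = np.zeros(len(y), dtype=bool)
    active = ~zero_group
    for _ in range(60):
        if not active.any():
            break
        mu = sf[None, :] * np.exp(beta)[:, None]
        w = 1.0 + alpha[:, None] * mu
        score = ((y - mu) / w).sum(axis=1)
        info = (mu / w).sum(axis=1)
        step = np.where(active, score / np.maximum(info, 1e-300), 0.0)
        step = np.clip(step, -5.0, 5.0)
        beta = beta + step
        newly = active & (np.abs(step) < 1e-12)
        converged |= newly
        active &= ~newly
    mu = sf[None, :] * np.exp(beta)[:, None]
    info = (mu / (1.0 + alpha[:, None] * mu)).sum(axis=1)
    converged |= zero_group  # continuity-adjusted estimate, accepted as-is
    return beta, info, converged, zero_group


def nb_wald_test(
    counts,
    size_factors: pd.Series,
    dispersions: pd.Series,
    conditions,
    wald_reference: str = "t",
) -> pd.DataFrame:
    """Per-gene Wald test of the condition contrast in an NB log-link model.

    log2FoldChange is condition2 vs condition1 (by order of appearance in
    ``conditions``); size factors enter as offsets. Genes with all-zero
    counts get NaN statistics; genes whose fit failed are flagged in the
    ``converged`` column and should be excluded from calls.
    """
    mat, genes, cols = _as_matrix(counts)
    m0, m1, levels = _group_masks(conditions, cols)
    sf = _align_sf(size_factors, cols)
    if (sf <= 0).any() or not np.isfinite(sf).all():
        raise ValidationError("size factors must be finite and positive")
    alpha = (
        dispersions.reindex(genes).to_numpy(dtype=float)
        if isinstance(dispersions, pd.Series)
        else np.asarray(dispersions, dtype=float)
    )
    if (alpha < 0).any():
        raise ValidationError("dispersions must be >= 0")

    b0, i0, c0, z0 = _fit_group(mat[:, m0], sf[m0], alpha)
    b1, i1, c1, z1 = _fit_group(mat[:, m1], sf[m1], alpha)

    lfc = (b1 - b0) / LOG2
    se = np.sqrt(1.0 / i0 + 1.0 / i1) / LOG2
    with np.errstate(divide="ignore", invalid="ignore"):
        wald = lfc / se
    if wald_reference == "t":
        df = int(m0.sum() + m1.sum() - 2)
        if df < 1:
            raise ValidationError("need more than one replicate in total per group")
        pvals = 2.0 * stats.t.sf(np.abs(wald), df=df)
    elif wald_reference == "normal":
        pvals = 2.0 * stats.norm.sf(np.abs(wald))
    else:
        raise ValidationError("wald_reference must be 't' or 'normal'")

    all_zero = z0 & z1
    converged = c0 & c1
    for arr in (lfc, se, wald, pvals):
        arr[all_zero] = np.nan
    pvals[~converged] = np.nan
    if (~converged & ~all_zero).any():
        log.warning(
            "%d genes failed to converge and were excluded from calls",
            int((~converged & ~all_zero).sum()),
        )

    base_mean = (mat / sf).mean(axis=1)
    return pd.DataFrame(
        {
            "baseMean": base_mean,
            "log2FoldChange": lfc,
            "lfcSE": se,
            "stat": wald,
            "pvalue": pvals,
            "converged": converged,
        },
        index=genes,
    ).assign(contrast=f"{levels[1]}_vs_{levels[0]}")


def adjust_bh(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment; NaNs are ignored and propagated."""
    p = np.asarray(pd.Series(pvalues), dtype=float)
    ok = ~np.isnan(p)
    if ((p[ok] < 0) | (p[ok] > 1)).any():
        raise ValidationError("p-values must lie in [0, 1]")
    out = np.full_like(p, np.nan)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def call_significant(
    results: pd.DataFrame,
    padj_threshold: float = PADJ_THRESHOLD,
    fold_threshold: float = FOLD_THRESHOLD,
) -> pd.DataFrame:
    """Apply the significance rule: adjusted p < 0.05 AND fold change > 1.4.

    ``up`` when padj < threshold and 2^lfc > fold_threshold, ``down`` when
    padj < threshold and 2^(-lfc) > fold_threshold, else ``ns``; NaN -> ns.
    Adds ``padj`` if absent and a ``call`` column.
    """
    res = results.copy()
    if "padj" not in res.columns:
        res["padj"] = adjust_bh(res["pvalue"])
    lfc = res["log2FoldChange"].to_numpy(dtype=float)
    padj = res["padj"].to_numpy(dtype=float)
    conv = (
        res["converged"].to_numpy(dtype=bool)
        if "converged" in res.columns
        else np.ones(len(res), dtype=bool)
    )
    with np.errstate(invalid="ignore", over="ignore"):
        sig = (padj < padj_threshold) & conv
        up = sig & (np.exp2(lfc) > fold_threshold)
        down = sig & (np.exp2(-lfc) > fold_threshold)
    call = np.where(up, "up", np.where(down, "down", "ns"))
    call[np.isnan(padj) | np.isnan(lfc)] = "ns"
    res["call"] = call
    return res


def summarize_ma(results: pd.DataFrame, density_bins: int = 60):
    """MA table, log2FC density table and up/down call counts.

    Returns ``(ma, density, counts)`` where ``ma`` has (baseMean,
    log2FoldChange, call) per gene, ``density`` is a binned log2FC density
    (columns bin_mid, density) over finite values, and ``counts`` is a dict
    with keys up/down/ns.
    """
    if len(results) == 0:
        ma = pd.DataFrame(columns=["baseMean", "log2FoldChange", "call"])
        density = pd.DataFrame(columns=["bin_mid", "density"])
        return ma, density, {"up": 0, "down": 0, "ns": 0}
    res = results if "call" in results.columns else call_significant(results)
    ma = res[["baseMean", "log2FoldChange", "call"]].copy()
    vals = res["log2FoldChange"].to_numpy(dtype=float)
    vals = vals[np.isfinite(vals)]
    if len(vals):
        hist, edges = np.histogram(vals, bins=density_bins, density=True)
        density = pd.DataFrame(
            {"bin_mid": 0.5 * (edges[:-1] + edges[1:]), "density": hist}
        )
    else:
        density = pd.DataFrame(columns=["bin_mid", "density"])
    counts = res["call"].value_counts().to_dict()
    counts = {k: int(counts.get(k, 0)) for k in ("up", "down", "ns")}
    return ma, density, counts


@dataclass
class DiffResult:
    """Full differential-test output: the per-gene table plus call counts."""

    table: pd.DataFrame
    n_up: int
    n_down: int
    contrast: str


class NegativeBinomialWaldDE(BaseEstimator):
    """Spike-calibrated NB Wald differential test as an estimator.

    ``fit(X, y)`` takes target-gene counts (DataFrame or TaggedCounts) and
    the per-sample condition labels ``y``; size factors are passed to
    ``fit`` (keyword) and would normally come from
    :class:`~spikecal.calibration.SpikeInCalibrator`.

    Attributes after fit: ``dispersions_``, ``results_`` (table with call
    column), ``n_up_``, ``n_down_``.
    """

    def __init__(
        self,
        padj_threshold: float = PADJ_THRESHOLD,
        fold_threshold: float = FOLD_THRESHOLD,
        dispersion_floor: float = 1e-8,
        wald_reference: str = "t",
    ):
        self.padj_threshold = padj_threshold
        self.fold_threshold = fold_threshold
        self.dispersion_floor = dispersion_floor
        self.wald_reference = wald_reference

    def fit(self, X, y, size_factors: pd.Series | None = None):
        if size_factors is None:
            raise ValidationError(
                "size_factors are required (spike-in calibrated or otherwise)"
            )
        self.dispersions_ = estimate_dispersions(
            X, size_factors, y, floor=self.dispersion_floor
        )
        res = nb_wald_test(
            X, size_factors, self.dispersions_, y, wald_reference=self.wald_reference
        )
        res = call_significant(res, self.padj_threshold, self.fold_threshold)
        self.results_ = res
        counts = res["call"].value_counts()
        self.n_up_ = int(counts.get("up", 0))
        self.n_down_ = int(counts.get("down", 0))
        log.info("calls: %d up, %d down of %d genes", self.n_up_, self.n_down_, len(res))
        return self

    def summarize_ma(self, density_bins: int = 60):
        if not hasattr(self, "results_"):
            raise ValidationError("estimator is not fitted")
        return summarize_ma(self.results_, density_bins=density_bins)
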