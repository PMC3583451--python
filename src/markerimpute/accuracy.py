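"""Imputation-accuracy statistics.

Accuracy is the coefficient of determination between true and imputed values
at the cells that were hidden by simulation:

    R^2 = 1 - sum_j (x_j,true - x_j,imputed)^2 / sum_j (x_j,true - mean(x_true))^2

evaluated per marker (Rm^2, over that marker's hidden cells) and per
individual (Ri^2, over that individual's hidden cells). R^2 is at most 1 and
can be negative; markers/individuals whose hidden truth values are constant
have an undefined R^2 and are excluded from aggregates.

Replicate aggregation follows the study design: element-wise means across
missing-data replicates give Rm2-bar / Ri2-bar; a median across markers or
individuals gives a scalar summary; a further mean across missingness levels
gives the overall Rm2-double-bar used in factor analyses.

``equivalent_percent_correct`` converts an (MAF, R^2) pair into the percent
of calls that would be correct after rounding continuous imputations back to
legal genotype codes, by simulation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .imputers import ImputationResult
from .simulate import MaskedDataset


@dataclass
class AccuracyReport:
    rm2: Optional[np.ndarray] = None  # NaN where no masked cells / undefined
    ri2: Optional[np.ndarray] = None
    marker_ids: Optional[np.ndarray] = None
    individual_ids: Optional[np.ndarray] = None
    replicate_id: int = 0
    method: str = ""
    level: str = ""
    dataset: str = ""
    n_undefined_markers: int = 0
    n_undefined_individuals: int = 0


def imputation_r2(truth, imputed) -> float:
    """The accuracy formula on a pair of aligned value vectors.

    Returns NaN (flagged undefined) when the truth vector is constant.
    """
    t = np.asarray(truth, dtype=float).ravel()
    p = np.asarray(imputed, dtype=float).ravel()
    if t.size != p.size or t.size == 0:
        raise ValueError("truth and imputed must be non-empty and equal-length")
    sst = float(((t - t.mean()) ** 2).sum())
    if sst == 0.0:
        return np.nan
    sse = float(((t - p) ** 2).sum())
    return 1.0 - sse / sst


def _labels(md: MaskedDataset, res: ImputationResult, replicate_id, method, level, dataset):
    return dict(
        replicate_id=replicate_id,
        method=method or res.method,
        level=level,
        dataset=dataset,
    )


def per_marker_accuracy(
    md: MaskedDataset,
    res: ImputationResult,
    replicate_id: int = 0,
    method: str = "",
    level: str = "",
    dataset: str = "",
) -> AccuracyReport:
    """Rm^2 for every marker with at least one simulated-missing cell."""
    truth, imp = md.truth.values, res.completed.values
    if truth.shape != imp.shape:
        raise ValueError("truth and imputed matrices differ in shape")
    n = truth.shape[1]
    rm2 = np.full(n, np.nan)
    undefined = 0
    for j in range(n):
        cells = md.simulated_mask[:, j]
        if not cells.any():
            continue
        val = imputation_r2(truth[cells, j], imp[cells, j])
        if np.isnan(val):
            undefined += 1
        rm2[j] = val
    return AccuracyReport(
        rm2=rm2,
        marker_ids=md.truth.marker_ids,
        n_undefined_markers=undefined,
        **_labels(md, res, replicate_id, method, level, dataset),
    )


def per_individual_accuracy(
    md: MaskedDataset,
    res: ImputationResult,
    replicate_id: int = 0,
    method: str = "",
    level: str = "",
    dataset: str = "",
) -> AccuracyReport:
    """Ri^2 for every individual with at least one simulated-missing cell."""
    truth, imp = md.truth.values, res.completed.values
    if truth.shape != imp.shape:
        raise ValueError("truth and imputed matrices differ in shape")
    m = truth.shape[0]
    ri2 = np.full(m, np.nan)
    undefined = 0
    for i in range(m):
        cells = md.simulated_mask[i, :]
        if not cells.any():
            continue
        val = imputation_r2(truth[i, cells], imp[i, cells])
        if np.isnan(val):
            undefined += 1
        ri2[i] = val
    return AccuracyReport(
        ri2=ri2,
        individual_ids=md.truth.individual_ids,
        n_undefined_individuals=undefined,
        **_labels(md, res, replicate_id, method, level, dataset),
    )


def mean_across_replicates(reports: Sequence[AccuracyReport], which: str = "rm2") -> np.ndarray:
    """Element-wise mean over replicates (undefined entries excluded)."""
    if not reports:
        raise ValueError("no reports")
    labels = {(r.method, r.level, r.dataset) for r in reports}
    if len(labels) > 1:
        raise ValueError(f"reports carry inconsistent labels: {sorted(labels)}")
    stack = np.vstack([getattr(r, which) for r in reports])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns stay NaN
        return np.nanmean(stack, axis=0)


def median_accuracy(values: np.ndarray) -> float:
    """Median over the defined entries of an accuracy vector."""
    values = np.asarray(values, dtype=float)
    good = values[~np.isnan(values)]
    if good.size == 0:
        raise ValueError("no defined accuracy values to summarise")
    return float(np.median(good))


def aggregate(reports: Sequence[AccuracyReport], stat: str = "median", which: str = "rm2"):
    """Replicate-mean vector, optionally reduced to a scalar summary.

    ``stat='mean'`` returns the element-wise replicate mean (Rm2-bar);
    ``stat='median'`` additionally reduces it to the Table-2-style scalar.
    """
    bar = mean_across_replicates(reports, which=which)
    if stat == "mean":
        return bar
    if stat == "median":
        return median_accuracy(bar)
    raise ValueError("stat must be 'mean' or 'median'")


def mean_across_levels(bars: Iterable[np.ndarray]) -> np.ndarray:
    """Average replicate-mean vectors across missingness levels (Rm2-bar-bar)."""
    stack = np.vstack(list(bars))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(stack, axis=0)


def equivalent_percent_correct(
    maf: float,
    r2: float,
    n_sims: int = 10000,
    seed: int = 0,
    levels: Sequence[float] = (-1.0, 1.0),
) -> float:
    """Percent of calls recovered correctly at a given MAF and accuracy.

    Simulates ``n_sims`` biallelic truth codes at the given MAF, generates
    continuous imputations whose realised accuracy equals ``r2`` under the
    shrink-to-mean model imputed = mean + r2*(truth - mean) + e with
    var(e) = r2*(1 - r2)*var(truth), rounds each imputation to the nearest
    legal code, and returns the percent matching the truth. At r2 = 0 the
    imputation collapses to the marker mean, so the percent correct tends to
    100*(1 - MAF) for two-state codes; at r2 = 1 it is exactly 100.
    """
    if not 0.0 <= maf <= 0.5:
        raise ValueError("maf must be in [0, 0.5]")
    if r2 > 1.0:
        raise ValueError("r2 cannot exceed 1")
    r2 = max(0.0, float(r2))  # negative accuracies behave like the mean predictor
    rng = np.random.default_rng(seed)
    levels = np.asarray(sorted(levels), dtype=float)
    major, minor = levels[-1], levels[0]
    truth = np.where(rng.random(n_sims) < maf, minor, major)
    mu = truth.mean()
    sd = truth.std()
    noise = rng.standard_normal(n_sims) * np.sqrt(r2 * (1.0 - r2)) * sd
    imputed = mu + r2 * (truth - mu) + noise
    # round to nearest legal code
    idx = np.abs(imputed[:, None] - levels[None, :]).argmin(axis=1)
    called = levels[idx]
    return float(100.0 * np.mean(called == truth))
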