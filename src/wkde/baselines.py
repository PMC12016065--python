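"""Linear-regression comparator clocks and the shared evaluation metrics.

Two conventional clocks built on the same CpG signature serve as
baselines: (1) a multivariable ordinary-least-squares regression of age on
all signature CpGs jointly, and (2) the average of independent single-CpG
regressions (each CpG predicts age on its own; the clock reports the
mean).  Performance throughout is summarized by the squared Pearson
correlation between predicted and chronological age and by the MEDIAN
absolute error in years (MAE here is the median, not the mean).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from wkde.core_io import MethylationMatrix

logger = logging.getLogger("wkde")


@dataclass
class LinearClock:
    """Either a joint OLS clock or an averaged single-CpG clock.

    multivariable: ``intercept`` + ``slopes`` (one per CpG, aligned with
    ``cpg_ids``).  single_cpg_average: per-CpG ``intercepts``/``slopes``
    pairs; prediction is the mean of the per-CpG predictions over CpGs
    available for the sample.
    """

    kind: str
    cpg_ids: list[str]
    intercept: float | None = None
    slopes: np.ndarray | None = None
    intercepts: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.kind == "multivariable":
            if self.intercept is None or len(self.slopes) != len(self.cpg_ids):
                raise ValueError("multivariable clock needs 1 + n coefficients")
        elif self.kind == "single_cpg_average":
            if (self.intercepts is None or self.slopes is None
                    or len(self.intercepts) != len(self.cpg_ids)
                    or len(self.slopes) != len(self.cpg_ids)):
                raise ValueError("average clock needs n (intercept, slope) pairs")
        else:
            raise ValueError(f"unknown clock kind {self.kind!r}")

    def predict(self, matrix: MethylationMatrix) -> pd.Series:
        sub = matrix.subset_cpgs(self.cpg_ids)
        X = sub.values.to_numpy(dtype=float).T  # (n_samples, n_cpgs)
        if self.kind == "multivariable":
            if np.any(~np.isfinite(X)):
                raise ValueError(
                    "multivariable clock needs complete signature DNAm")
            pred = self.intercept + X @ self.slopes
        else:
            per_cpg = self.intercepts[None, :] + X * self.slopes[None, :]
            pred = np.nanmean(per_cpg, axis=1)
        return pd.Series(pred, index=sub.sample_ids, name="predicted_age")


def _aligned_ages(matrix: MethylationMatrix, samples: pd.DataFrame) -> np.ndarray:
    return (samples.set_index("sample_id").loc[matrix.sample_ids, "age"]
            .to_numpy(dtype=float))


def fit_multivariable_clock(matrix: MethylationMatrix, samples: pd.DataFrame,
                            signature: list[str]) -> LinearClock:
    """OLS of age on all signature CpGs jointly (complete cases only)."""
    sub = matrix.subset_cpgs(signature)
    X = sub.values.to_numpy(dtype=float).T
    ages = _aligned_ages(sub, samples)
    complete = np.all(np.isfinite(X), axis=1) & np.isfinite(ages)
    X, ages = X[complete], ages[complete]
    n, p = X.shape
    if n < p + 1:
        raise ValueError(f"need >= {p + 1} complete samples, have {n}")
    design = np.column_stack([np.ones(n), X])
    rank = np.linalg.matrix_rank(design)
    if rank < p + 1:
        # identify offending columns via QR pivoting on the centered design
        _, r = np.linalg.qr(design)
        small = np.abs(np.diag(r)) < 1e-8 * np.abs(np.diag(r)).max()
        bad = [signature[i - 1] for i in np.flatnonzero(small) if i > 0]
        raise ValueError(f"design is rank-deficient; collinear CpGs: {bad}")
    coef, *_ = np.linalg.lstsq(design, ages, rcond=None)
    return LinearClock(kind="multivariable", cpg_ids=list(signature),
                       intercept=float(coef[0]), slopes=coef[1:])


def fit_single_cpg_average_clock(matrix: MethylationMatrix,
                                 samples: pd.DataFrame,
                                 signature: list[str]) -> LinearClock:
    """Per-CpG simple regressions age = a_k + b_k * DNAm_k; the clock
    averages the per-CpG predictions.  Zero-variance CpGs are excluded."""
    sub = matrix.subset_cpgs(signature)
    ages = _aligned_ages(sub, samples)
    intercepts, slopes, kept = [], [], []
    for cpg in signature:
        x = sub.values.loc[cpg].to_numpy(dtype=float)
        ok = np.isfinite(x) & np.isfinite(ages)
        if ok.sum() < 3:
            raise ValueError(f"{cpg}: fewer than 3 complete (age, DNAm) pairs")
        if np.ptp(x[ok]) == 0:
            logger.warning("%s has zero DNAm variance; excluded from the "
                           "average clock", cpg)
            continue
        b, a = np.polyfit(x[ok], ages[ok], 1)
        intercepts.append(a)
        slopes.append(b)
        kept.append(cpg)
    if not kept:
        raise ValueError("every signature CpG had zero variance")
    return LinearClock(kind="single_cpg_average", cpg_ids=kept,
                       intercepts=np.asarray(intercepts),
                       slopes=np.asarray(slopes))


def pearson_r2(pred: np.ndarray, truth: np.ndarray) -> float:
    """Squared Pearson correlation between predictions and truth."""
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if pred.size != truth.size or pred.size < 3:
        raise ValueError("need >= 3 aligned pairs")
    if np.ptp(pred) == 0 or np.ptp(truth) == 0:
        raise ValueError("correlation undefined for a constant vector")
    r = stats.pearsonr(pred, truth).statistic
    return float(r * r)


def median_abs_error(pred: np.ndarray, truth: np.ndarray) -> float:
    """Median of |pred - truth| in years (even counts: mean of the two
    central values)."""
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if pred.size == 0 or pred.size != truth.size:
        raise ValueError("need equal-length, non-empty vectors")
    return float(np.median(np.abs(pred - truth)))


def benchmark_row(name: str, dataset: str, pred: np.ndarray,
                  truth: np.ndarray) -> dict:
    """One row of the standard benchmark report."""
    return {"model": name, "dataset": dataset,
            "r2": pearson_r2(pred, truth),
            "mae": median_abs_error(pred, truth),
            "n": int(np.asarray(pred).size)}
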