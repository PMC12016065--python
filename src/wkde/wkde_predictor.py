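"""Probabilistic age prediction from a fitted kernel model.

A sample's measured DNAm percentage at each signature CpG selects one row
of that CpG's density matrix — a vector of densities over all grid ages.
The (optionally weighted) elementwise sum of these rows is the sample's
age profile; its argmax is the predicted age, and normalizing it yields an
age-probability vector.  The *variation score* is the standard deviation
of the unweighted probability distribution after linear interpolation onto
a 0.1-year grid: it measures how much the signature CpGs disagree about
the sample's age, not the error of the point prediction — although in
practice chronological age falls inside predicted age +/- score for the
vast majority of samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from wkde.core_io import DensityKernel, GridSpec, KernelModel, MethylationMatrix

FINE_STEPS_PER_YEAR = 10


@dataclass(frozen=True)
class VariationResult:
    """Moments of a sample's age-probability distribution."""

    predicted_age: float
    mean: float
    variance: float
    variation_score: float

    @property
    def interval(self) -> tuple[float, float]:
        return (self.predicted_age - self.variation_score,
                self.predicted_age + self.variation_score)


@dataclass(frozen=True)
class PredictionResult:
    sample_id: str
    predicted_age: int
    delta_age: float | None
    probability: np.ndarray
    variation: VariationResult
    n_cpgs_used: int
    floored: bool


def dnam_to_row(grid: GridSpec, dnam: float) -> int:
    """Map a DNAm percentage to its nearest grid row (round half up)."""
    step = (grid.dnam_max - grid.dnam_min) / (grid.n_points - 1)
    pos = (dnam - grid.dnam_min) / step
    if not -0.5 < pos < grid.n_points - 0.5:
        raise ValueError(f"DNAm value {dnam} outside the grid")
    return int(np.floor(pos + 0.5))


def density_row(kernel: DensityKernel, dnam: float,
                grid: GridSpec | None = None) -> np.ndarray:
    """The kernel row at the grid node nearest to ``dnam``: densities over
    all grid ages.  NaN DNAm signals "skip this CpG" via KeyError."""
    if not np.isfinite(dnam):
        raise KeyError(f"missing DNAm for CpG {kernel.cpg_id}")
    grid = grid or GridSpec()
    return kernel.density[dnam_to_row(grid, dnam)]


def joint_density_profile(model: KernelModel,
                          sample_dnam: Mapping[str, float],
                          use_weights: bool = True
                          ) -> tuple[np.ndarray, int]:
    """Sum of per-CpG density rows for one sample.

    ``sample_dnam`` maps cpg_id -> DNAm percent (NaN or absent = missing;
    such CpGs are skipped).  Returns the profile over grid ages and the
    number of CpGs actually used.
    """
    profile = np.zeros(model.grid.n_points)
    n_used = 0
    for kernel, w in zip(model.kernels, model.weights):
        dnam = sample_dnam.get(kernel.cpg_id, np.nan)
        if dnam is None or not np.isfinite(dnam):
            continue
        row = density_row(kernel, dnam, model.grid)
        profile += (w * row) if use_weights else row
        n_used += 1
    if n_used == 0:
        raise ValueError("no signature CpG has a DNAm value for this sample")
    return profile, n_used


def predict_age(model: KernelModel, sample_dnam: Mapping[str, float],
                use_weights: bool = True) -> int:
    """Grid age with the maximum summed density; ties go to the youngest age.

    The argmax is taken on the raw (possibly signed) weighted profile, so a
    negative weight genuinely pushes density away from its CpG's peak.
    """
    profile, _ = joint_density_profile(model, sample_dnam, use_weights)
    if np.all(profile == 0):
        raise ValueError("age profile is identically zero")
    return int(np.argmax(profile))  # argmax returns the first (youngest) tie


def probability_vector(model: KernelModel, sample_dnam: Mapping[str, float],
                       use_weights: bool = True
                       ) -> tuple[np.ndarray, bool]:
    """Normalize the profile to an age-probability vector summing to 1.

    Negative entries (possible only with negative weights) are floored at
    zero before renormalization; the returned flag reports whether any
    flooring occurred.
    """
    profile, _ = joint_density_profile(model, sample_dnam, use_weights)
    floored = bool(np.any(profile < 0))
    if floored:
        profile = np.clip(profile, 0.0, None)
    total = profile.sum()
    if total <= 0:
        raise ValueError("profile has no positive mass to normalize")
    return profile / total, floored


def fine_probability(p: np.ndarray, mode: str = "consistent") -> np.ndarray:
    """Linear interpolation of a 101-point probability vector onto a
    0.1-year grid (1001 points, ages 0.0, 0.1, ..., 100.0).

    ``"consistent"`` renormalizes the interpolated values to a proper pmf
    (sum 1).  ``"literal"`` returns the raw interpolated values, whose sum
    is close to 10; the companion literal moment formulas carry explicit
    0.1 prefactors instead.
    """
    p = np.asarray(p, dtype=float)
    knots = np.arange(p.size) * FINE_STEPS_PER_YEAR
    x = np.arange(knots[-1] + 1)
    f = np.interp(x, knots, p)
    if mode == "literal":
        return f
    if mode != "consistent":
        raise ValueError(f"unknown mode {mode!r}")
    return f / f.sum()


def variation_score(p: np.ndarray, predicted_age: float | None = None,
                    mode: str = "consistent") -> VariationResult:
    """Mean, variance and standard deviation of the age-probability
    distribution on the fine 0.1-year grid.

    ``p`` must be an *unweighted* probability vector: the score measures
    heterogeneity among the signature CpGs themselves, and CpG weights
    tuned for point prediction would distort that.  (``predict_samples``
    enforces this by always recomputing ``p`` without weights.)

    In the default ``"consistent"`` mode the interpolated fine vector is
    renormalized to a pmf f and
        mean     = sum_x f(x) * (x/10)
        variance = sum_x f(x) * (x/10 - mean)^2 ,
    so both are in years / years^2.  ``"literal"`` mode instead evaluates
    mean = 0.1 * sum f(x) * x and variance = 0.1 * sum f(x) * (0.1 x -
    mean)^2 on the unnormalized fine vector — a historical variant kept
    for comparison; its two moments are not on mutually consistent scales.
    """
    if mode == "consistent":
        f = fine_probability(p, "consistent")
        ages = np.arange(f.size) / FINE_STEPS_PER_YEAR
        mean = float(np.sum(f * ages))
        variance = float(np.sum(f * (ages - mean) ** 2))
    elif mode == "literal":
        f = fine_probability(p, "literal")
        x = np.arange(f.size, dtype=float)
        mean = 0.1 * float(np.sum(f * x))
        variance = 0.1 * float(np.sum(f * (0.1 * x - mean) ** 2))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if predicted_age is None:
        predicted_age = mean
    return VariationResult(predicted_age=float(predicted_age), mean=mean,
                           variance=variance,
                           variation_score=float(np.sqrt(max(variance, 0.0))))


def predict_sample(model: KernelModel, sample_dnam: Mapping[str, float],
                   sample_id: str = "sample",
                   chronological_age: float | None = None,
                   use_weights: bool = True) -> PredictionResult:
    """Full prediction for one sample: age, probabilities, variation score."""
    age = predict_age(model, sample_dnam, use_weights)
    prob, floored = probability_vector(model, sample_dnam, use_weights)
    unweighted_prob, _ = probability_vector(model, sample_dnam,
                                            use_weights=False)
    _, n_used = joint_density_profile(model, sample_dnam, use_weights)
    variation = variation_score(unweighted_prob, predicted_age=age)
    delta = None if chronological_age is None else float(age - chronological_age)
    return PredictionResult(sample_id=sample_id, predicted_age=age,
                            delta_age=delta, probability=prob,
                            variation=variation, n_cpgs_used=n_used,
                            floored=floored)


def predict_samples(model: KernelModel, matrix: MethylationMatrix,
                    samples: pd.DataFrame | None = None,
                    use_weights: bool = True) -> pd.DataFrame:
    """Predict every sample of a matrix; returns the standard output table.

    Columns: sample_id, predicted_age, chronological_age, delta_age,
    variation_score, interval_lo, interval_hi, n_cpgs_used, floored.
    """
    ages = None
    if samples is not None:
        ages = samples.set_index("sample_id")["age"]
    sub = matrix.subset_cpgs([c for c in model.cpg_ids
                              if c in matrix.values.index])
    if sub.shape[0] < model.n_cpgs:
        missing = sorted(set(model.cpg_ids) - set(sub.cpg_ids))
        raise KeyError(f"signature CpGs absent from input: {missing[:5]}")
    rows = []
    for sid in sub.sample_ids:
        dnam = sub.values[sid].to_dict()
        chron = float(ages[sid]) if ages is not None and sid in ages.index else None
        res = predict_sample(model, dnam, sample_id=sid,
                             chronological_age=chron, use_weights=use_weights)
        lo, hi = res.variation.interval
        rows.append({
            "sample_id": sid,
            "predicted_age": res.predicted_age,
            "chronological_age": chron,
            "delta_age": res.delta_age,
            "variation_score": res.variation.variation_score,
            "interval_lo": lo,
            "interval_hi": hi,
            "n_cpgs_used": res.n_cpgs_used,
            "floored": res.floored,
        })
    return pd.DataFrame(rows)


def coverage_fraction(results: pd.DataFrame) -> float:
    """Fraction of samples whose chronological age falls inside
    predicted age +/- variation score."""
    if len(results) == 0:
        raise ValueError("no predictions to evaluate")
    delta = results["delta_age"].to_numpy(dtype=float)
    if np.any(~np.isfinite(delta)):
        raise ValueError("coverage needs chronological ages for all samples")
    score = results["variation_score"].to_numpy(dtype=float)
    return float(np.mean(np.abs(delta) <= score))
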