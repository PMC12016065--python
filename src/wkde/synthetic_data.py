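"""Synthetic DNAm cohorts with the statistical structure the clock assumes.

The generator emulates blood-methylation aging data: each age-associated
CpG follows a smooth trajectory in age — logarithmic, mu(age) = beta0 +/-
beta1 * log(age + 1), the shape most strongly age-correlated CpGs show
because childhood changes are much faster than adult ones, or linear —
plus homoscedastic Gaussian noise, a per-study x per-CpG batch offset, and
clipping to [0, 100] percent (which reproduces the saturation plateaus of
real beta values near 0 and 100).  A disease mode adds an independent
per-sample, per-CpG shift to a fraction of the CpGs, decoupling their
apparent ages from one another — exactly the heterogeneity the variation
score is designed to detect.

What it does not emulate: cell-type composition shifts, probe-specific
technical error structure, or age-dependent noise; conclusions drawn from
these cohorts are about the algorithm, not about real 450K data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from wkde.core_io import MethylationMatrix, write_beta_matrix, write_sample_table


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort generator settings (percent units throughout).

    Defaults give the "paper-like" scenario: 1000 samples, 30 CpGs of which
    27 carry a strong age signal and 3 are pure noise, a skewed
    (middle-age-heavy) age mixture, two studies with 2% batch-offset SD, and
    per-CpG noise SDs between 2 and 5%.
    """

    n_samples: int = 1000
    n_cpgs: int = 30
    n_signal_cpgs: int = 27
    age_distribution: str = "skewed"  # or "uniform"
    frac_logarithmic: float = 0.7
    log_slope_range: tuple[float, float] = (12.0, 20.0)
    linear_slope_range: tuple[float, float] = (0.4, 0.8)
    noise_sd_range: tuple[float, float] = (2.0, 5.0)
    n_studies: int = 2
    batch_offset_sd: float = 2.0
    disease_sigma: float = 0.0
    disease_frac_cpgs: float = 0.5
    seed: int = 0
    trajectory_seed: int | None = None  # share trajectories across cohorts

    def __post_init__(self) -> None:
        if self.n_samples < 1 or self.n_cpgs < 1:
            raise ValueError("n_samples and n_cpgs must be >= 1")
        if not 0 <= self.n_signal_cpgs <= self.n_cpgs:
            raise ValueError("n_signal_cpgs must not exceed n_cpgs")
        if self.batch_offset_sd < 0 or self.disease_sigma < 0:
            raise ValueError("standard deviations must be >= 0")
        if min(self.noise_sd_range) < 0:
            raise ValueError("noise SDs must be >= 0")
        if self.age_distribution not in ("skewed", "uniform"):
            raise ValueError(f"unknown age_distribution "
                             f"{self.age_distribution!r}")


def paper_like_config(seed: int = 0, **overrides) -> SimulationConfig:
    """The default scenario sized like a pooled blood training set."""
    return SimulationConfig(seed=seed, **overrides)


@dataclass
class TrajectorySet:
    """Per-CpG trajectory parameters drawn once per trajectory seed."""

    shape: np.ndarray       # "log" or "linear" per CpG
    beta0: np.ndarray       # baseline DNAm percent
    beta1: np.ndarray       # slope magnitude (0 for noise CpGs)
    direction: np.ndarray   # +1 gain / -1 loss of methylation with age
    noise_sd: np.ndarray    # percent
    is_signal: np.ndarray   # bool
    disease_affected: np.ndarray  # bool

    def mean_dnam(self, ages: np.ndarray) -> np.ndarray:
        """Noise-free mu_k(age) for every CpG: (n_cpgs, n_samples)."""
        ages = np.asarray(ages, dtype=float)
        f = np.where(self.shape[:, None] == "log",
                     np.log(ages[None, :] + 1.0), ages[None, :])
        return (self.beta0[:, None]
                + self.direction[:, None] * self.beta1[:, None] * f)

    def to_jsonable(self) -> dict:
        return {k: v.tolist() for k, v in asdict(self).items()}


def draw_trajectories(cfg: SimulationConfig) -> TrajectorySet:
    seed = cfg.trajectory_seed if cfg.trajectory_seed is not None else cfg.seed
    rng = np.random.default_rng([seed, 17])  # distinct stream from sampling
    n = cfg.n_cpgs
    is_signal = np.zeros(n, dtype=bool)
    is_signal[: cfg.n_signal_cpgs] = True
    shape = np.where(rng.uniform(size=n) < cfg.frac_logarithmic,
                     "log", "linear").astype(object)
    direction = np.where(rng.uniform(size=n) < 0.5, 1.0, -1.0)
    beta1 = np.where(
        shape == "log",
        rng.uniform(*cfg.log_slope_range, size=n),
        rng.uniform(*cfg.linear_slope_range, size=n),
    )
    beta1[~is_signal] = 0.0
    # pick baselines so the noise-free trajectory stays inside [0, 100]
    span = np.where(shape == "log", np.log(101.0), 100.0) * beta1
    margin = rng.uniform(2, 8, size=n)
    low = np.where(direction > 0,
                   np.minimum(margin, 100.0 - span),
                   np.minimum(span + margin, 100.0))
    beta0 = np.where(is_signal, low, rng.uniform(20, 80, size=n))
    noise_sd = rng.uniform(*cfg.noise_sd_range, size=n)
    affected = np.zeros(n, dtype=bool)
    n_affected = int(round(cfg.disease_frac_cpgs * cfg.n_signal_cpgs))
    affected[rng.choice(np.flatnonzero(is_signal), size=n_affected,
                        replace=False)] = True
    return TrajectorySet(shape=shape, beta0=beta0, beta1=beta1,
                         direction=direction, noise_sd=noise_sd,
                         is_signal=is_signal, disease_affected=affected)


def _draw_ages(cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    if cfg.age_distribution == "uniform":
        return rng.uniform(0.0, 100.0, size=cfg.n_samples)
    # skewed mixture: young uniform block + middle-age bulk + elderly bump
    comp = rng.choice(3, size=cfg.n_samples, p=[0.30, 0.45, 0.25])
    ages = np.empty(cfg.n_samples)
    ages[comp == 0] = rng.uniform(0.0, 25.0, size=int((comp == 0).sum()))
    ages[comp == 1] = rng.normal(50.0, 15.0, size=int((comp == 1).sum()))
    ages[comp == 2] = rng.normal(75.0, 8.0, size=int((comp == 2).sum()))
    return np.clip(ages, 0.0, 100.0)


def simulate_cohort(cfg: SimulationConfig,
                    trajectories: TrajectorySet | None = None
                    ) -> tuple[MethylationMatrix, pd.DataFrame, dict]:
    """Generate one cohort; deterministic per ``cfg.seed``.

    Returns (matrix, sample table, params), where ``params`` records every
    drawn quantity (trajectories, study offsets, disease shifts applied)
    so tests can check the generator against its own bookkeeping.
    """
    traj = trajectories if trajectories is not None else draw_trajectories(cfg)
    rng = np.random.default_rng([cfg.seed, 23])
    ages = _draw_ages(cfg, rng)
    study_idx = rng.integers(0, cfg.n_studies, size=cfg.n_samples)
    sex = rng.choice(["female", "male"], size=cfg.n_samples)
    offsets = rng.normal(0.0, cfg.batch_offset_sd,
                         size=(cfg.n_studies, cfg.n_cpgs))

    mu = traj.mean_dnam(ages)  # (n_cpgs, n_samples)
    if np.any(mu < 0) or np.any(mu > 100):
        import logging
        logging.getLogger("wkde").warning(
            "noise-free trajectories leave [0, 100]; clipping will saturate")
    values = (mu + offsets[study_idx, :].T
              + rng.normal(0.0, 1.0, size=mu.shape) * traj.noise_sd[:, None])
    diseased = cfg.disease_sigma > 0
    if diseased:
        shift = np.zeros_like(values)
        aff = traj.disease_affected
        shift[aff, :] = rng.normal(0.0, cfg.disease_sigma,
                                   size=(int(aff.sum()), cfg.n_samples))
        values = values + shift
    values = np.clip(values, 0.0, 100.0)

    cpg_ids = [f"cg{str(i).zfill(8)}" for i in range(cfg.n_cpgs)]
    sample_ids = [f"s{str(i).zfill(5)}" for i in range(cfg.n_samples)]
    matrix = MethylationMatrix(pd.DataFrame(values, index=cpg_ids,
                                            columns=sample_ids))
    samples = pd.DataFrame({
        "sample_id": sample_ids,
        "age": ages,
        "sex": sex,
        "study": [f"study{i + 1}" for i in study_idx],
        "group": "diseased" if diseased else "healthy",
    })
    params = {
        "config": asdict(cfg),
        "trajectories": traj.to_jsonable(),
        "study_offsets": offsets.tolist(),
        "cpg_ids": cpg_ids,
    }
    return matrix, samples, params


def simulate_disease_cohort(cfg: SimulationConfig,
                            trajectories: TrajectorySet | None = None
                            ) -> tuple[MethylationMatrix, pd.DataFrame, dict]:
    """Disease-mode cohort: per-sample heterogeneity shifts on the affected
    CpG fraction; chronological ages and trajectories are untouched."""
    if cfg.disease_sigma <= 0:
        raise ValueError("disease cohort needs disease_sigma > 0")
    return simulate_cohort(cfg, trajectories)


def write_cohort(matrix: MethylationMatrix, samples: pd.DataFrame,
                 params: dict, out_dir: str | Path) -> None:
    """Emit the standard TSV pair plus a JSON sidecar of drawn parameters."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_beta_matrix(matrix, out / "betas.tsv")
    write_sample_table(samples, out / "samples.tsv")
    with open(out / "simulation_params.json", "w") as fh:
        json.dump(params, fh, indent=2)
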