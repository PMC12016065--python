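import numpy as np
import pandas as pd
import pytest

from wkde.core_io import DensityKernel, GridSpec, KernelModel, MethylationMatrix
from wkde.kde_engine import KernelFitConfig, fit_kernel_model


def make_matrix(values: np.ndarray, cpg_ids=None, sample_ids=None) -> MethylationMatrix:
    values = np.asarray(values, dtype=float)
    cpg_ids = cpg_ids or [f"cg{i:08d}" for i in range(values.shape[0])]
    sample_ids = sample_ids or [f"s{i:05d}" for i in range(values.shape[1])]
    return MethylationMatrix(pd.DataFrame(values, index=cpg_ids,
                                          columns=sample_ids))


def make_samples(ages, sample_ids=None, **cols) -> pd.DataFrame:
    ages = np.asarray(ages, dtype=float)
    sample_ids = sample_ids or [f"s{i:05d}" for i in range(ages.size)]
    df = pd.DataFrame({"sample_id": sample_ids, "age": ages})
    for k, v in cols.items():
        df[k] = v
    return df


@pytest.fixture
def linear_cohort():
    """20 samples, 3 CpGs exactly linear in age (one decreasing), no noise."""
    ages = np.linspace(0.0, 95.0, 20)
    values = np.vstack([
        10.0 + 0.8 * ages,
        90.0 - 0.7 * ages,
        5.0 + 0.5 * ages,
    ])
    return make_matrix(values), make_samples(ages)


@pytest.fixture
def toy_model(linear_cohort):
    """3-CpG kernel model with fixed bandwidths on the default 101-grid."""
    matrix, samples = linear_cohort
    cfg = KernelFitConfig(bandwidth_mode="fixed", fixed_bandwidths=(16.0, 16.0))
    return fit_kernel_model(matrix, samples, matrix.cpg_ids, cfg)


def brute_force_kernel(ages, dnam, grid: GridSpec, s_age: float,
                       s_dnam: float) -> np.ndarray:
    """Independent double-loop Gaussian-sum density (oracle)."""
    ages = np.asarray(ages, float)
    dnam = np.asarray(dnam, float)
    n = ages.size
    out = np.zeros((grid.n_points, grid.n_points))
    for j, g_d in enumerate(grid.dnam_grid):
        for i, g_a in enumerate(grid.age_grid):
            total = 0.0
            for l in range(n):
                pa = np.exp(-0.5 * ((g_a - ages[l]) / s_age) ** 2) / (
                    s_age * np.sqrt(2 * np.pi))
                pd_ = np.exp(-0.5 * ((g_d - dnam[l]) / s_dnam) ** 2) / (
                    s_dnam * np.sqrt(2 * np.pi))
                total += pa * pd_
            out[j, i] = total / n
    return out


def single_kernel_model(density: np.ndarray, grid: GridSpec | None = None,
                        weight: float = 1.0) -> KernelModel:
    grid = grid or GridSpec()
    k = DensityKernel("cgTOY00001", density, (1.0, 1.0))
    return KernelModel(grid, [k], np.array([weight]))
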