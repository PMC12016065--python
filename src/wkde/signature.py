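"""CpG signature selection and uniform-age subsampling of the training set.

Signature CpGs are chosen by squared Pearson correlation of DNAm with
chronological age (e.g. r^2 > 0.7 yields signatures of a few dozen CpGs on
blood 450K data).  Because donor ages in pooled cohorts are far from
uniform, the kernel training set is first reduced to a fixed number of
samples per 5-year age bin, which flattens the age histogram the kernels
would otherwise inherit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from wkde.core_io import MethylationMatrix

logger = logging.getLogger("wkde")

_SEX_CHROMOSOMES = {"X", "Y", "chrX", "chrY", "x", "y"}


def filter_probes(matrix: MethylationMatrix,
                  annotation: pd.DataFrame) -> MethylationMatrix:
    """Drop CpGs on sex chromosomes or flagged as SNP probes.

    ``annotation`` has columns cpg_id, chromosome, is_snp_probe.  CpGs not
    covered by the annotation are kept with a warning; survivor order is
    preserved.
    """
    ann = annotation.set_index(annotation["cpg_id"].astype(str))
    if ann.index.has_duplicates:
        raise ValueError("duplicate cpg_id in probe annotation")
    keep = []
    uncovered = 0
    for cpg in matrix.cpg_ids:
        if cpg not in ann.index:
            uncovered += 1
            keep.append(cpg)
            continue
        row = ann.loc[cpg]
        if str(row["chromosome"]) in _SEX_CHROMOSOMES or bool(row["is_snp_probe"]):
            continue
        keep.append(cpg)
    if uncovered:
        logger.warning("%d CpGs lack annotation; kept unfiltered", uncovered)
    if not keep:
        raise ValueError("probe filtering removed every CpG")
    return matrix.subset_cpgs(keep)


def age_correlation(matrix: MethylationMatrix,
                    samples: pd.DataFrame) -> pd.DataFrame:
    """Per-CpG squared Pearson correlation of DNAm with age.

    Uses pairwise-complete observations per CpG.  Returns a DataFrame
    indexed by cpg_id with columns ``r2`` (NaN when undefined: fewer than
    3 complete pairs or zero DNAm variance), ``slope_sign``, ``n_used``
    and ``missing_frac``.
    """
    order = samples.set_index("sample_id").loc[matrix.sample_ids]
    ages = order["age"].to_numpy(dtype=float)
    values = matrix.values.to_numpy(dtype=float)  # (n_cpgs, n_samples)
    ok = np.isfinite(values)
    n_used = ok.sum(axis=1)
    missing_frac = 1.0 - n_used / values.shape[1]

    # Masked pairwise-complete moments, vectorized over CpGs.
    v = np.where(ok, values, 0.0)
    a = np.where(ok, ages[None, :], 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        n = n_used.astype(float)
        mv = v.sum(axis=1) / n
        ma = a.sum(axis=1) / n
        sv = (np.where(ok, (values - mv[:, None]) ** 2, 0.0)).sum(axis=1)
        sa = (np.where(ok, (ages[None, :] - ma[:, None]) ** 2, 0.0)).sum(axis=1)
        cov = (np.where(ok, (values - mv[:, None]) * (ages[None, :] - ma[:, None]),
                        0.0)).sum(axis=1)
        r2 = cov ** 2 / (sv * sa)
        slope = cov / sv
    undefined = (n_used < 3) | ~np.isfinite(r2)
    r2 = np.where(undefined, np.nan, np.clip(r2, 0.0, 1.0))
    return pd.DataFrame(
        {
            "r2": r2,
            "slope_sign": np.where(undefined, 0, np.sign(slope)).astype(int),
            "n_used": n_used,
            "missing_frac": missing_frac,
        },
        index=pd.Index(matrix.cpg_ids, name="cpg_id"),
    )


def select_signature(correlations: pd.DataFrame, threshold: float,
                     max_missing_frac: float = 0.2) -> list[str]:
    """CpGs with r^2 strictly above ``threshold``.

    Sorted by descending r^2, ties broken lexicographically by cpg_id so
    the signature order is deterministic and independent of input order.
    CpGs with undefined r^2 or more than ``max_missing_frac`` missing
    values never enter the signature.
    """
    if not 0 <= threshold < 1:
        raise ValueError("threshold must lie in [0, 1)")
    ok = correlations[
        correlations["r2"].notna()
        & (correlations["r2"] > threshold)
        & (correlations["missing_frac"] <= max_missing_frac)
    ]
    if ok.empty:
        raise ValueError(
            f"no CpG exceeds r^2 > {threshold}; lower the threshold")
    ordered = ok.sort_index().sort_values("r2", ascending=False,
                                          kind="stable")
    return [str(c) for c in ordered.index]


@dataclass(frozen=True)
class BinningSpec:
    """Uniform-age subsampling: 18 five-year bins on [0, 90] plus an
    overflow bin for ages strictly above 90, with ``per_bin`` samples drawn
    from each."""

    bin_width: float = 5.0
    age_cap: float = 90.0
    per_bin: int = 15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.bin_width <= 0 or self.per_bin < 1:
            raise ValueError("bin_width and per_bin must be positive")

    @property
    def n_regular_bins(self) -> int:
        return int(round(self.age_cap / self.bin_width))

    @property
    def n_bins(self) -> int:
        return self.n_regular_bins + 1

    def bin_index(self, age: float) -> int:
        # age exactly at the cap goes to the last regular bin; the overflow
        # bin takes ages strictly above the cap
        if age > self.age_cap:
            return self.n_regular_bins
        return min(int(age // self.bin_width), self.n_regular_bins - 1)


def uniform_age_subsample(samples: pd.DataFrame,
                          spec: BinningSpec) -> pd.DataFrame:
    """Draw ``spec.per_bin`` samples without replacement from each age bin.

    Bins holding fewer than ``per_bin`` samples contribute everything they
    have ("take-all"); empty bins contribute nothing.  Deterministic given
    ``spec.seed``; the returned table preserves the input row order.
    """
    rng = np.random.default_rng(spec.seed)
    ages = samples["age"].to_numpy(dtype=float)
    bins = np.array([spec.bin_index(a) for a in ages])
    chosen: list[int] = []
    for b in range(spec.n_bins):
        members = np.flatnonzero(bins == b)
        if members.size == 0:
            logger.warning("age bin %d is empty", b)
            continue
        if members.size < spec.per_bin:
            logger.info("age bin %d holds %d < %d samples; taking all",
                        b, members.size, spec.per_bin)
            chosen.extend(members.tolist())
        else:
            chosen.extend(rng.choice(members, size=spec.per_bin,
                                     replace=False).tolist())
    return samples.iloc[sorted(chosen)].reset_index(drop=True)
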