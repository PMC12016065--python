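# Methods

## The model

The clock predicts donor age from DNA-methylation (DNAm) beta values at a
small signature of age-associated CpG sites, without assuming any
parametric age trajectory. For each signature CpG *k* a bivariate kernel
density estimate is evaluated on a fixed grid of ages *i* ∈ {0,…,100}
years and DNAm levels *j* ∈ {0,…,100}% (101 points per axis, step 1),
giving a matrix *K<sub>i,j,k</sub>*. Given a sample with measured DNAm(k)
percent at each CpG, the row of each kernel nearest to DNAm(k) is a
101-vector of densities over ages, and the predicted age is

  predicted age = argmax<sub>i∈[0,100]</sub> Σ<sub>k</sub> w<sub>k</sub> · K<sub>i,DNAm(k),k</sub>

with per-CpG weights w<sub>k</sub> ∈ [−10, 10] (all 1 before
optimization). Normalizing the same weighted sum over ages yields an
age-probability vector,

  probability(age) = Σ<sub>k</sub> w<sub>k</sub>·K<sub>age,DNAm(k),k</sub> / Σ<sub>i</sub> Σ<sub>k</sub> w<sub>k</sub>·K<sub>i,DNAm(k),k</sub>.

Ties in the argmax go to the youngest age (deterministic). Negative
entries of a weighted profile — possible only with negative weights — are
floored at zero in the probability view and flagged; the argmax is always
taken on the raw signed profile so the point prediction is unaffected by
the flooring.

### Kernel fitting

Each kernel is a product-Gaussian KDE: density(age g<sub>i</sub>, DNAm
g<sub>j</sub>) = (1/n) Σ<sub>l</sub> φ<sub>sa</sub>(g<sub>i</sub> −
age<sub>l</sub>) φ<sub>sd</sub>(g<sub>j</sub> − dnam<sub>l</sub>), with
per-axis bandwidths from the normal-reference rule h = 4 · 1.06 ·
min(sd, IQR/1.34) · n<sup>−1/5</sup> (sample sd, type-7 quartiles) and
component scale s = h/4. This reproduces the classical bivariate `kde2d`
convention, including its internal quartering of the bandwidth argument,
so fitted grids match that routine to numerical precision. Kernels are not
renormalized after fitting: prediction consumes relative magnitudes across
DNAm rows. A fixed-bandwidth mode exists for testing; the bandwidth rule
errors on degenerate (zero-spread) inputs rather than guessing, since an
invariant CpG carries no age information.

### Handling the skewed age distribution

Pooled cohorts are concentrated at middle ages, which biases raw kernels
toward overrepresented ages. Two mutually exclusive corrections are
provided: (a) the default, uniform-age subsampling — the training set is
split into 18 five-year bins covering [0, 90] plus one overflow bin for
ages strictly above 90 (age exactly 90 falls in the last regular bin) and
15 samples are drawn per bin without replacement, 285 when every bin is
full; bins holding fewer than 15 contribute all their samples (take-all,
logged); (b) age-histogram normalization — each age column of a kernel is
divided by the count of donors of that rounded age, considering only
donors ≤ 85 years because very sparse old-age columns would otherwise blow
up; unpopulated columns are zeroed so they can never win the argmax.

### Signature selection

Per-CpG squared Pearson correlation (r²) between DNAm and age, computed on
pairwise-complete observations; CpGs with r² strictly above the threshold
(default 0.7) enter the signature, ordered by descending r² with
lexicographic tie-breaks so the result is independent of input order. CpGs
with undefined r² (fewer than 3 complete pairs, zero variance) or more
than 20% missing values are excluded — the missingness cut is this
package's conservative default and is configurable. Probes on sex
chromosomes or flagged as SNP probes are removed beforehand when an
annotation is supplied.

### Weight optimization

A genetic algorithm minimizes the total absolute training error
Σ<sub>l</sub> |age<sub>l</sub> − argmax<sub>i</sub> Σ<sub>k</sub>
w<sub>k</sub> K<sub>i,DNAm_l(k),k</sub>|. The objective is piecewise
constant in w, so a derivative-free population search is appropriate.
Defaults: population 150, 100 generations, keep fraction 0.4, mutation
rate 0.1, genes bounded to [−10, 10]. Operators: truncation selection,
arithmetic (per-gene blend) crossover between two distinct survivors,
uniform-reset mutation, and elitism. Two deliberate design choices: the
unit vector (1,…,1) is injected into the initial population, so the
optimized clock can never underperform the unweighted clock on training
data, and because survivors are exactly the generation's best, the
best-fitness trace is non-increasing by construction. All randomness flows
from one seeded generator; runs are bit-reproducible. Objective
evaluations use a precomputed cache of per-sample density rows (its
equality with full-model recomputation is itself a tested contract), which
makes the full 150 × 100 run a few seconds of matrix products.

### Variation score

The score quantifies how much the signature CpGs disagree about a sample's
age. It is always computed from the *unweighted* probability vector —
weights are tuned for point prediction and would distort the
heterogeneity measure. The 101-point vector is linearly interpolated onto
a 0.1-year grid (1001 points, ages 0.0–100.0), renormalized to a pmf f,
and summarized by mean = Σ f(x)·(x/10), variance = Σ f(x)·(x/10 − mean)²,
score = √variance (years). The reported interval is predicted age ±
score. A "literal" mode evaluates the historical variant with explicit 0.1
prefactors on the unnormalized interpolated vector; its two moments are
not on mutually consistent scales and it is kept only for comparison.
Note one numerical consequence of the interpolation: a distribution
concentrated on a single year is broadened into a ±1-year tent, so the
smallest achievable score is ≈0.41 years rather than 0.

### Baseline clocks and metrics

Two conventional comparators on the same signature: a multivariable OLS
regression of age on all CpGs jointly (requires complete cases, ≥ p+1
samples, and a full-rank design — exactly collinear CpGs are rejected by
name), and the average of independent single-CpG regressions (zero-
variance CpGs excluded; prediction averages over CpGs available for the
sample). Accuracy is summarized by squared Pearson correlation (R²) and
the MEDIAN absolute error (MAE) in years — median, not mean, a detail
worth pinning because the two differ substantially on heavy-tailed error
distributions.

## Synthetic cohorts

The generator produces beta matrices with the structure the method
assumes. Per CpG, the mean trajectory is β0 ± β1·log(age+1)
(logarithmic; 70% of signal CpGs by default, reflecting that strongly
age-correlated CpGs change fastest in childhood) or β0 ± β1·age (linear),
with slopes drawn so the trajectory spans roughly 40–92 DNAm percentage
points over 0–100 years and baselines chosen to keep the noise-free curve
inside [0, 100]. Observed values add a per-study × per-CpG batch offset
~N(0, τ), per-CpG Gaussian noise, and are clipped to [0, 100] — clipping
rather than truncation, which is simpler and reproduces the saturation
plateaus of real beta values. The default scenario has 1000 samples,
30 CpGs (27 signal, 3 pure noise), a skewed age mixture (30% uniform
0–25 yr, 45% N(50, 15), 25% N(75, 8), clipped), two studies, τ = 2%, and
noise SDs uniform in [2, 5]% — sized after pooled blood training sets of
order 10³ samples and a few dozen signature CpGs. Disease mode adds an
independent per-sample, per-CpG shift ~N(0, σ_d) to a configurable
fraction (default 50%) of the signal CpGs before clipping, decoupling
their apparent ages — the heterogeneity signature the variation score
detects — while leaving chronological ages untouched. All draws are
reproducible per seed, trajectories can be shared across cohorts via a
separate trajectory seed, and every drawn parameter is logged to a sidecar
JSON for oracle checks.

What the generator does not emulate: cell-type composition and its age
drift, probe-specific technical error, age-dependent noise, and non-
Gaussian batch structure. Tests passing on these cohorts validate the
algorithmic contracts, not performance on real 450K data.

## Numerical and interface choices

- DNAm is held internally in percent [0, 100]; fraction-scaled inputs are
  detected (max ≤ 1.5) and rescaled on read. Missing values are never
  imputed; each operation declares its policy (kernel fits drop incomplete
  pairs, prediction skips missing CpGs and reports the count used, the
  multivariable baseline refuses incomplete samples, the GA drops them).
- A sample's DNAm is mapped to the nearest grid row by round-half-up;
  values within half a grid step outside [0, 100] clamp to the boundary
  rows, anything further errors at read time.
- The model bundle is human-readable JSON (grid, CpG ids, weights,
  bandwidths, provenance) plus an HDF5 payload with one float64 dataset
  per kernel, so other languages can read it; loading re-validates weights
  bounds, version, and metadata/payload consistency, and round-trips are
  bit-exact.
- Evaluation problem sizes in the test suite and acceptance script —
  1000-sample cohorts, 27-CpG signatures, the full 150 × 100 GA — mirror
  the default scenario and complete in seconds on one core.

## Known limitations

Predictions are confined to the kernel grid (0–100 years); samples older
than the training range cannot be predicted reliably. The argmax returns
integer years. The GA operators are one reasonable instantiation of a
bounded real-valued GA, not a bit-level reproduction of any particular
library, so optimized weights are seed- and implementation-specific even
though the contract (never worse than unweighted, monotone trace) is
guaranteed. The variation score inherits a floor of ≈0.41 years from the
fine-grid interpolation and depends on kernel bandwidths; comparisons are
meaningful within a model, not across models with different bandwidths.
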