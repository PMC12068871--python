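# Methods

This note records the models, parameter choices and numerical
conventions behind `reprophys`, and what the synthetic generators do and
do not emulate.

## Data model

A session is one probe insertion: a list of sorted units (spike times in
seconds from session start, one amplitude in µV per spike, an (x, y, z)
template position in µm in a right-handed atlas frame with DV increasing
with depth, a peak-to-trough duration in ms, and a region label from
{VISa/am, CA1, DG, LP, PO, other}), per-channel AP-band RMS and LFP
power spectra in dB, a trial table, planned/micromanipulator/histology
trajectories, and an ordered QC ledger. On disk a session is one
directory: columnar tables (CSV or Parquet) for units, spikes, channels,
LFP spectra and trials, plus a JSON metadata file. All indexing is
0-based; round-trips are lossless.

## Unit quality metrics

**Sliding refractory-period confidence.** Violations are counted over
consecutive inter-spike intervals only. Under the contamination model —
an independent Poisson process of contaminating spikes superimposed on a
refractory-respecting train — a contaminating spike can violate against
either neighbour, giving the expected count
`lambda(t_r) = 2 * t_r * c_max * N * r` at contamination `c_max = 0.1`,
with `N` the spike count and `r = N/duration`. Confidence is the strict
survival probability `P[Poisson(lambda) > k]`; the refractory grid is 50
logarithmically spaced lengths in [0.5, 10] ms (log spacing resolves the
short end where contamination discriminates best). The same
contamination model drives the synthetic generator, so metric and
simulator share one set of assumptions, and the metric is validated
against brute-force Poisson-CDF summation.

**Amplitude cutoff.** 100 equal-width histogram bins over the observed
amplitude range; the comparison set is the top quarter (by bin index) of
bins above the histogram peak. The unit fails when the lowest bin sits
≥ 5 SDs above the mean of those high-tail bins or exceeds 10% of the
peak bin. If the high-tail bins are exactly flat (SD 0), the distance is
defined as +∞ unless the low bin equals their mean, in which case 0. No
Gaussian assumption is made; the test detects the missing left tail that
thresholded spike detection produces.

**Median amplitude** must strictly exceed 50 µV.

## Recording quality metrics

Yield is QC-passing units per channel, computed per region from the
channel→region map, threshold 0.1 (pass at ≥). Median AP-band RMS must
be strictly below 40 µV. LFP spectra use Welch's method (Hann windows of
1024 samples, 50% overlap) with `dB = 10 log10(PSD)`; the decibel
conversion uses log base 10 by convention. Band power is the **mean** dB
over 20–80 Hz (median would differ little on smooth spectra; mean was
fixed once). The depth derivative uses central finite differences in the
interior and one-sided differences at the probe ends, and takes the
absolute value, since the gradient's sign reflects only probe
orientation; its median must be strictly below 0.05 dB/µm. All-zero
channels get a −∞ dB sentinel and are flagged rather than raised.

## Session exclusion cascade

Criteria apply in a fixed order — hardware failure, missing histology,
drift, noisy channels, artefacts, epileptiform activity, low yield,
noise level, behavior (≥ 400 completed trials), and finally a minimum of
3 sessions per lab for across-lab tests — and each session is tallied
against the first criterion it fails, so the tallies plus survivors
partition the input. Visually assessed criteria (drift, noisy channels,
artefacts, epileptiform) are ingested as precomputed boolean flags
because they are manual judgements, not computations. The per-lab
session minimum is applied last; analysis-specific filters (e.g. ≥ 4
good units per region) live with their analyses.

## Task-modulation tests

Trials are filtered to correct (rewarded), non-zero-contrast trials.
Per-trial firing rates use half-open windows `[event + w0, event + w1)`.
The six tests and their default windows (seconds, config-overridable):

| test | comparison | windows | statistic |
|---|---|---|---|
| stimulus | pre vs post stimulus | [−0.2, 0) vs [0, 0.4) | signed-rank |
| movement initiation | pre vs post movement | [−0.2, 0) vs [0, 0.2) | signed-rank |
| left vs right movement | post-movement by choice | [0, 0.2) | rank-sum |
| feedback | pre vs post feedback | [−0.2, 0) vs [0, 0.2) | signed-rank |
| stimulus left vs right | post-stimulus by side | [0, 0.4) | rank-sum |
| movement vs baseline | pre-stimulus vs post-movement | [−0.2, 0) vs [0, 0.4) | signed-rank |

α = 0.05 per test with no unit-level multiple-test correction (the
modulated-proportion summaries inherit this convention). Signed-rank
tests drop zero differences (Wilcoxon convention) and fall back to the
normal approximation with continuity correction when exact enumeration
is unavailable (ties or larger n, following scipy's switch). A test
needs ≥ 5 usable trials per side, else it is undetermined and excluded
from proportions. The Fano factor uses counts in [0.04, 0.2) s after
movement onset on correct full-contrast right-stimulus trials, with the
unbiased (n−1) variance estimator; mean-zero counts give NaN.
Modulated-proportion summaries require ≥ 4 good units in the region.

## Permutation framework

The statistic is the maximum over labs of the sup-distance between the
lab's empirical CDF and the pooled CDF of all other labs; it is
rank-based and thus invariant to monotone transforms. The null permutes
lab assignments 50,000 times by default (2,000 in calibration studies),
keeping per-lab counts intact; the permutation unit is the mouse when a
grouping is supplied, otherwise the individual value. The p-value uses
the add-one estimator `(1 + #{null ≥ observed}) / (1 + n_perm)`: it
differs from the plain proportion by at most `1/n_perm`, can never be
exactly zero, and counts ties against rejection (the conservative
reading of "more extreme"). Significance calls use α = 0.01, a
stringency chosen in lieu of explicit multiple-testing correction.

**Power analysis.** For a target lab, all of its values are shifted
additively; a single frozen set of relabelings (drawn once from the
seed) is reused for every shift evaluated, making the p-value landscape
deterministic. The bracket expands geometrically from one pooled SD
until significant, then bisects to a tolerance of 0.1% of the pooled
value range (20 expansion, 200 refinement iterations). Because the
statistic is not globally monotone in the shift, the search finishes by
explicitly enforcing the defining property `p(shift) < α ≤ p(shift −
tol·sign)`. Shifts are reported in feature units; the acceptance script
additionally reports them in pooled-SD units.

**Decoding test.** A 200-tree random forest with stratified 5-fold
cross-validation predicts the group from five per-recording markers
(yield, firing rate, LFP band power, AP-band RMS, spike amplitude); the
null shuffles labels 500 times and p is the add-one fraction of shuffled
accuracies at least as high as the observed one. Tree count, fold count
and shuffle count are arbitrary but fixed; classes with fewer than two
members are dropped with a warning.

## PETH embedding

Each cell contributes two PETHs aligned to first-movement onset — fast
(< 0.15 s) and slow (> 0.15 s) reaction-time trials, the split point
being the population mean reaction time — with 20 ms bins spanning
[−0.5, 1.5) s (T = 100), concatenated to a 2T row. Normalization is
`(PETH − b) / (b + ε)` with `b` the mean baseline rate over [−0.5, −0.2)
s pre-movement (pooled across trials) and `ε = 0.5` spikes/s, a small
positive offset that keeps near-silent cells from amplifying noise; both
are configurable. PCA removes column means before the SVD so that PC1
captures variance (an uncentered SVD is available by flag). Per-cell
goodness of fit is `1 − ||row − reconstruction||² / ||row − mean row||²`.

Lab/region comparisons: two-sample KS tests of a target subset's first
PCs against the remaining cells, a permutation test on the 2D distance
between a group's mean embedding and the remainder's mean, and a
cell-number-controlled variant that samples the minimum group size from
both sides and combines KS p-values with Fisher's method (χ² with
2 × n_samplings df, n_samplings = 100 by default). Fisher's method
assumes independent p-values but the repeated subsamples overlap, so the
combination is conservative in practice rather than exactly calibrated;
the implementation follows the stated procedure verbatim and the test
suite measures its behaviour on identical-group and separated-group
inputs rather than assuming uniformity.

## Variance regression and outliers

Outlier neurons deviate from the median firing rate by more than 15% of
the rate range; the rule is scale-equivariant, degenerate for two-point
inputs (both flagged), and applied per region with rates pooled across
sessions. Group comparisons use two-sample KS tests per feature (x, y,
z, amplitude, peak-to-trough duration) with Bonferroni correction over
the five features. The variance model is OLS of session-averaged rate on
the five features plus intercept, without regularization; predictors are
standardized internally for conditioning and coefficients reported back
in original units (numerically identical to raw OLS), with t-based
p-values and the unadjusted R².

## Probe geometry

Traced tracks are fitted by total least squares (first principal axis
through the centroid); the entry point is the line's intersection with
the brain surface, modeled as the plane DV = 0 in the synthetic atlas
frame with an injectable surface function for other conventions. Angles
use the absolute dot product because traced directions carry a sign
ambiguity; per-plane components come from projections onto the coronal
and sagittal planes. The planned repeated-site insertion enters at AP
+2.0 mm, ML −2.24 mm at a 15° angle from vertical.

## Synthetic generators

The generators reproduce the statistical structure the analyses assume,
not the biophysics. Spike trains are homogeneous Poisson thinned to an
absolute refractory period (2 ms default), with contamination injected
as an independent unconstrained Poisson process at rate
`c/(1−c) × rate` — exactly the model under which the refractory metric's
expected-count algebra holds. Event-locked modulation superimposes a
per-region template (step, Gaussian transient, ramp; a minimal basis
that makes the five regions separable in the embedding) via thinning.
Amplitudes are Gaussian per unit; a truncation bound discards (does not
redraw) sub-threshold draws, emulating a detection floor. Trial tables
start with 90 unbiased trials then alternate 20:80 / 80:20 blocks of
20–100 trials; reaction times are log-normal (σ = 0.6) with mean 0.15 s,
chosen so both fast and slow trials occur — the distributional family is
an assumption, as only the empirical mean is constrained. The multi-lab
generator nests lab → mouse → session with defaults mirroring the study
design (10 labs × 4 mice × 1 session, ~20 units per region, 400 trials);
per-mouse values are exchangeable across labs unless `lab_effects`
injects additive shifts, and per-session random streams are spawned from
the configured seed, making output bit-identical across runs. Per-mouse
feature variability is Gaussian in the alternative-hypothesis generator,
another assumption the real data do not pin down.

What the generators do **not** emulate: raw voltage waveforms, drift,
non-stationary rates, correlated noise across units, realistic LFP
spectra beyond a flat floor with an elevated dentate-gyrus band, video
or histology images. Passing tests therefore certify the statistical
machinery (calibration, power, invariances, bookkeeping) on data
satisfying the model assumptions, not performance on violated
assumptions.

## Problem sizes and numerical choices

Calibration studies use 200 replicate null datasets with 2,000
permutations each; metric calibrations use 200 seeds at ≥ 10⁴ spikes per
train; embedding studies use 10 labs × 5 units per region × 120 trials;
regression recoveries use 1,000–4,000 synthetic neurons. These sizes
give binomial/SE margins comfortably inside the asserted bands while
keeping the full suite and the acceptance script to a couple of minutes.
Degenerate inputs never raise inside QC metrics (they fail with
reasons); they raise `ValueError` in statistics where no answer exists
(single lab, empty group, zero-width window) and `FormatError` in I/O.

## Known limitations

- The max-CDF permutation test is conservative at very small per-lab
  counts because the statistic's null support is coarse; calibration at
  α = 0.01 with 4 mice per lab sits at or below the nominal level.
- The Fisher-combined subsampling test inherits the dependence problem
  noted above.
- Discrete spike counts make the signed-rank tests' size deviate from
  nominal by a few percent at low rates.
- The session exclusion cascade applies the per-lab session minimum
  after all quality criteria; orderings interleaving it earlier would
  attribute exclusions differently.
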