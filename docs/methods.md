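# Methods

## The tuning model

A voxel's aggregate numerosity tuning is modelled as a Gaussian in
log-numerosity space:

    r(n) = exp( -(ln n - ln p)² / (2 σ²) ),   n, p > 0, σ > 0

with preferred numerosity `p` (linear units) and tuning width `σ`
(log units). Natural logarithms are used throughout; a different log
base only rescales σ, so nothing is lost. The width is also reported as
the linear full width at half maximum,
`FWHM = exp(ln p + cσ) - exp(ln p - cσ)` with `c = √(2 ln 2)`, which is
the width a tuning curve plot shows.

The predicted BOLD series is the tuning response evaluated on the
stimulus sequence (zero where no stimulus is present, with the
20-item baseline included as an ordinary stimulus — for preferences well
below 20 it drives a near-zero response and acts as an effective rest
condition), convolved with a double-gamma HRF and sampled at the frame
times. The HRF is the difference of two gamma densities (peak delay 6 s,
undershoot delay 16 s, unit dispersions, undershoot ratio 1/6, unit
peak); its functional form is the field standard, and the
participant-level refit re-estimates exactly the two parameters the data
can constrain, peak delay and undershoot ratio, by maximizing summed
variance explained over voxels with initial R² > 0.3, followed by one
pRF refit with the new kernel.

Time zero is the first retained frame; frames discarded for steady-state
magnetization are represented only by a count. Stimulus intervals are
half-open `[onset, onset + duration)`. The design is sampled at dt =
0.1 s for the haptic protocol and 0.05 s for the visual protocol (the
coarsest steps that divide both the TR and all event boundaries
exactly); predictions use a dt-scaled kernel so their scale is
independent of the dt choice.

## Fitting

Fitting is an exhaustive grid search over 60 log-spaced preferences in
[0.5, 40] × 40 log-spaced widths in [0.05, 3] — deliberately far beyond
the presented 1–7 range, so estimates inside the range are not an
artifact of a truncated search — followed by bounded Nelder–Mead
refinement of (ln p, ln σ) at tolerance 1e-6. Per candidate, amplitude
and baseline are solved by OLS, so the grid score reduces to the
correlation between candidate prediction and data, and training
R² = 1 − RSS/TSS equals that correlation squared.

Tuned responses are modelled positive-going: candidates that correlate
negatively with the data lose to any positively correlating candidate.
When *no* candidate correlates positively (which happens for a few
percent of pure-noise series), the least-negative candidate is refined
and the fit is reported with its variance explained plus a `degenerate`
flag rather than a forced R² of 0. This keeps the null distribution of
R² continuous — an atom at zero would make empirical-null p-values
non-uniform by exactly the atom's mass — while downstream selection
still treats flagged fits as non-tuned. Grid candidates whose prediction
is numerically flat (centered norm < 1e-6; very narrow tuning placed
between presented numerosities) are excluded as models: they respond to
nothing that was shown. Constant input series return R² = 0 with the
degenerate flag.

## Selection

Two filters separate tuned voxels from merely responsive or noisy ones.

*Cross-validated model comparison.* Runs are split by 1-based index
(odd = runs 1, 3, …), each half averaged. The pRF model is fit per half
and its prediction — tuning shape fixed, amplitude/baseline refit, i.e.
held-out R² is the squared correlation — evaluated on the other half;
the two held-out R² values are averaged. An "on–off" GLM (stimulus
presence convolved with the HRF, plus constant) is fit on each half and
its training R² averaged. A voxel is excluded when the GLM beats the
cross-validated pRF: its response tracks presence, not numerosity. Note
the asymmetry (training GLM vs held-out pRF) is intentional and slightly
favors exclusion; calibration shows on–off voxels are excluded and tuned
voxels retained in ≥ 95% of replicates at the default noise level.

*Empirical null.* The same fitting procedure is run on signal-free
voxels; the p-value of an observed R² is the fraction of null fits at
least as large. The null here is built from synthetic pure-noise voxels
— white-matter voxels, which the original approach used, require scan
data. Inclusion threshold: R² > 0.30. On 1,000 synthetic null voxels no
fit reaches that threshold, and p-values of fresh null voxels are
uniform (KS test).

## Map statistics

Geodesic distances from each recording site to the low- and high-
preference map borders are multi-source Dijkstra shortest paths on the
mesh edge graph with Euclidean weights — an approximation to exact
polyhedral geodesics that is adequate at 2 mm binning. The normalized
progression distance is `d_low / (d_low + d_high)` scaled by the mean
map length.

Sites are binned every 2 mm (half-open bins; empty bins dropped, bins
with one site kept). A logarithmic model `pref = a + b ln(d + ε)` with
`ε = bin_width/2` (so a hypothetical zero-distance bin center stays
finite) is fit to bin means by least squares. Inference:

- **Bootstrap** (default unit: bins). Bin means are resampled with
  replacement; the median slope/intercept is the reported progression
  and the 2.5/97.5 percentiles give the 95% CI. A second unit,
  `boot_unit="vertices"`, keeps bin positions fixed and resamples the
  member sites within each bin. Calibration against an independently
  coded oracle shows the bin-unit percentile CI undercovers by a few
  percent at realistic map sizes (~91–93% at 10–40 bins — a known
  small-sample property of pairs resampling), while the vertex-unit CI,
  which tracks the sampling noise of each bin mean directly, holds
  ~94% coverage down to small maps. Coverage calibration therefore
  exercises the vertex unit; both are available.
- **Permutation.** The assignment of bin means to bin positions is
  shuffled; p is the plain fraction of shuffled slopes ≥ the observed
  slope (an add-one smoothed variant is not used, matching the
  plain-proportion definition). Under scrambled preferences these
  p-values are uniform (KS over 500 maps).

Tuning-width progression uses the same machinery with preference on the
abscissa (0.25-wide bins) and a linear fit. Cortical magnification
counts preferences (masked to [1, 7]) into unit-width bins centered on
the integers, expresses them as % of the map, applies a centered
linearly decreasing contrast (+3 … −3), and tests the per-map scores
> 0 with a one-sided t-test; across map groups, Benjamini–Hochberg FDR.
The contrast weights are the standard centered ramp; the exact weights
used elsewhere are not published, so this is a package choice.

Simulation sizes in the validation suite (500 permutation-null maps,
300 coverage replicates, resampling depth 2,000) are chosen to estimate
rates to ~1–1.5% Monte-Carlo error; the analysis default for real data
remains 10,000 resamples.

## Cross-modal comparison

Overlap between two thresholded maps (R² > 0.30 in both) is reported
relative to each map and as the mean of the two, since group summaries
average across maps of both modalities. Preference agreement over shared
vertices is Pearson r, Fisher z-transformed (`z = atanh r`) before any
group statistic; overlap percentages are arcsine-square-root transformed
before ANOVA. Group comparisons: one-way ANOVA on z with all-pairs
Bonferroni post hocs (raw p × number of pairs, capped at 1) and
per-group one-sample t vs 0; |r| = 1 values (infinite z) are excluded
with a warning. Each map instance is treated as one observation —
whether hemispheres count as independent is a design question the
package does not decide. Test–retest splits fit the model independently
per run half and correlate preferences over vertices above threshold in
the odd (reference) half.

## Controls

*Motion.* Glove traces are cut into exploration epochs. Per epoch and
finger: peak count with prominence ≥ 10% of the epoch's signal range;
signal STD; motion duration = time between the first and last absolute
successive difference exceeding 3× the median absolute successive
difference of the quiescent (inter-epoch) signal. Both thresholds are
config-exposed; no smoothing is applied by default (a window is
available). Metrics are averaged across fingers, then cell means enter a
two-way repeated-measures ANOVA (condition × numerosity, statsmodels
AnovaRM). Evidence for the null is summarized by BF01 =
exp((BIC_full − BIC_null)/2) comparing OLS models with and without the
numerosity factor — a BIC approximation, explicitly *not* equivalent to
a default-prior Bayesian ANOVA. Under the null motion generator
(constant per-epoch Poisson bump counts) the numerosity effect rejects
at ~5%.

*Behavior.* Error rate is computed per participant then averaged;
reaction times are summarized by per-participant medians. Friedman tests
compare median RTs across numerosities within each condition; pairwise
error-rate chi-squares use participant-pooled 2×2 counts (no continuity
correction, Bonferroni ×(number of pairs)); Spearman correlations
compare concatenated per-participant per-numerosity profiles between
modalities. Rank ties are handled by average ranks; a fully tied
Friedman table (zero statistic in the limit) is reported as χ² = 0,
p = 1.

## Synthetic data: what it does and does not emulate

Generators are pure functions of parameters and an explicit seed. Tuned
voxels follow the forward model exactly, with white Gaussian noise
(optional AR(1)); the default noise SD (0.75) equals the SD of the
unit-amplitude noiseless prediction on the haptic protocol, putting
tuned voxels at R² ≈ 0.5 — the regime of well-fitting map voxels. No
reported SNR exists to anchor this, so it is a convenience choice.
Surface patches are regular triangulated strips with a log-spaced
preference gradient between the first (low-border) and last
(high-border) columns and σ = 0.35 + 0.25 ln p, emulating the
widening-with-preference organization of numerosity maps. Glove traces
place Poisson numbers of smooth half-sine bumps inside epochs (constant
mean across numerosities = the null of the motion control). Behavior
tables are error-free up to the subitizing limit (3) with linearly
increasing error probability above it (slope 0.15/item, misses by one
item) and log-normally scattered RTs increasing with numerosity.

None of this emulates draining veins, physiological noise spectra,
cortical folding, head motion, or realistic exploration kinematics.
Passing tests therefore establish that the analysis recovers known
parameters from data generated by its own forward model and that its
inferential machinery is calibrated (type-I rates, p-value uniformity,
CI coverage) — not that it is robust to every artifact of real fMRI.

## Numerical choices and degenerate inputs

- Grid bounds double as refinement bounds; Nelder–Mead tolerance 1e-6
  on (ln p, ln σ); noiseless parameter recovery is exact to <1e-3
  relative.
- dt must divide the TR (to 1e-9) so frame times land on design
  samples; dt coarser than the shortest event is rejected.
- Preference range mask is the closed interval [1, 7]; whether the
  20-item baseline counts as "presented" is debatable, but map figures
  span 1–7, so 7 is the default upper bound.
- Disconnected mesh vertices get infinite geodesic distance with a
  warning; a vertex on both borders (zero total distance) is an error.
- Empty map bins are dropped; fewer than 3 non-empty bins is an error;
  constant preferences give slope 0 with permutation p = 1.
- Correlation of a zero-variance preference map is an error, not NaN.

## Known limitations

- Held-out R² is defined as squared correlation after amplitude/baseline
  refit; alternatives (1 − RSS/TSS with transferred scale) differ
  out-of-sample and would be slightly stricter.
- The bin-unit percentile bootstrap undercovers by ~2–4% at realistic
  bin counts (see above); analyses that need calibrated slope CIs at
  small map sizes should use the vertex unit.
- The BF01 is a BIC approximation; it shows direction and order of
  magnitude of evidence, not prior-sensitive Bayes factors.
- Geodesics are graph shortest paths, which overestimate true surface
  distance by the mesh detour factor; at 2 mm bins on ~1–2 mm meshes
  this does not move bin assignments much, but exact polyhedral
  geodesics would be needed for finer work.
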