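# Methods notes

## The model problem

Two overlapping dot fields move at speeds v_s < v_f with a fixed ratio
(2x or 4x).  A population of ~100 speed-tuned neurons, each recorded with
the stimulus centered on its receptive field, responds to each bi-speed
stimulus, to each component alone, and to the single log-mean speed
√(v_s·v_f).  The package asks two questions of such data: how the
bi-speed response relates to the component responses (encoding), and
whether one or two speeds can be read back out of the population
response (decoding).

## Synthetic populations

The generator produces the study conditions so every stage runs without
recorded data.

- **Speed tuning** is log-Gaussian with additive baseline:
  r(v) = b + (p − b)·exp(−(ln v − ln v_pref)² / 2w²).  Recorded MT speed
  tuning is well described by a Gaussian on a logarithmic speed axis, and
  the analyses all operate in ln speed, so this is the natural smooth
  unimodal form.  Default widths w ~ Uniform(1.0, 1.6) (ln-speed units)
  and baselines ~ Uniform(0, 8) spikes/s are typical MT values.
- **Preferred speeds** are drawn from a truncated normal in ln speed,
  μ = ln 20, σ = 1.6, truncated to [ln 1.25, ln 80].  A ln-uniform
  distribution was considered but rejected: it centers the
  population-average tuning at exactly √(1.25·80) = 10 °/s, whereas the
  population-average tuning of recorded MT samples peaks near 20 °/s.
  The truncated normal puts the synthetic population-average peak at
  ~15–20 °/s and yields preferred-speed group proportions
  (<2.5 / 2.5–25 / >25 °/s) of roughly 7/60/33%, close to the recorded
  10/61/29 split.  This default is a stand-in for the unreported full
  empirical distribution, not a fit to it.
- **Peak rates** ~ Uniform(40, 120) spikes/s.  This range is calibrated
  so the synthetic population-averaged responses to single speeds of 2.5
  and 10 °/s land near the recorded population averages of 36.7 and
  62.5 spikes/s (the weighting-pool values); a 100-neuron draw gives
  ~37 and ~58 spikes/s.
- **Direction tuning** is von Mises (κ ~ Uniform(1.5, 3)); the recorded
  analyses use only empirical direction curves, so the form is a free
  modeling choice.
- **Trials** are independent Poisson counts with mean rate × 0.5 s (the
  coherent-motion period).  No inter-neuron noise correlations are
  simulated; the trial-resampling analyses in the original study are
  likewise independent-Poisson.

What passing tests on these populations show: the estimators recover
generative parameters, the decoder inverts its own forward model, and
qualitative orderings (4x vs 2x) hold under realistic rates and Poisson
noise.  What they do not show: quantitative agreement with recorded d′
magnitudes or fitted weights, which depend on the actual MT data.

## Smoothing splines

All tuning-curve and population-response smoothing uses a natural cubic
smoothing spline minimizing p·Σw_i(y_i − f(x_i))² + (1 − p)·∫f″², the
parameterization of MATLAB's `csaps` (p = 1 interpolates, p = 0 is the
least-squares line).  The implementation (`splines.py`) solves the
Reinsch equations directly; it exists because the analyses need n ≥ 4
sites, per-site weights, and the explicit linear-smoother matrix.  For
n ≥ 5 it agrees with `scipy.interpolate.make_smoothing_spline` at
λ = (1 − p)/p to ~1e-13, which the tests use as an independent oracle.
p = 0.93 is used throughout, the value found to track speed tuning
without overfitting in the source analyses; duplicate sites (tied
preferred speeds) are averaged with multiplicity weights, which is
exactly equivalent to weighting each neuron once.

## Estimators and fits

- **Weight regression**: OLS with intercept of (R − R_s) on (R_f − R_s);
  the t-based 95% CI is reported for the measured slope (the CI method
  for measured slopes is not otherwise specified), while the
  random-weight control reports percentile (2.5/97.5) intervals over its
  1000 repetitions.  Per-neuron weights w_f = (R − R_s)/(R_f − R_s) are
  exposed for diagnostics only and are flagged undefined when
  |R_f − R_s| < 1e-9 spikes/s; the population regression is the primary
  estimator because per-neuron denominators near zero inflate weights.
- **Bootstrap comparison** uses (k + 1)/(n + 1) smoothing so a measured
  slope above all n simulated slopes reports p < 1/n rather than 0.
- **Split-trial control**: one random half-split of the slower-component
  trials per repeat, shared by both regression orientations; 50 repeats
  by default.
- **LWS fit**: linear least squares in (w_s, w_f, c); the unconstrained
  solution is used when c already lies in [0, 100] spikes/s (then it is
  exact), otherwise bounded linear least squares.  Weights are not
  constrained to sum to one — the full direction curves identify them.
- **Normalization fit**: SSE minimization over n ∈ [0.01, 100],
  σ ∈ [0, 500], α ∈ [0.01, 100], c ∈ [0, 100], with n and α optimized on
  a log10 scale, via L-BFGS-B from 20 seeded random interior starts (the
  original work names only constrained minimization; restart count and
  tolerances are this package's defaults).  (n, σ, α) are jointly
  under-determined — many triples give the same implied weights — so the
  contract is recovery of the implied weights, not the raw parameters.

## Classifier

SGDClassifier with logistic loss and L1 penalty; 200 Poisson trials per
class; stratified 40-fold cross-validation so each trial is tested
exactly once.  The regularization strength is not specified in the
source analyses; the default is the weak 1/n_train.  Consequently the
tested contract is the ordering of d′ across conditions (4x > 2x at
matched log-mean speed), not d′ magnitudes.  Features are normalized
per-neuron trial responses; counts are generated through each neuron's
maximum rate and the 0.5 s window, then rescaled back to normalized
units.

## Decoder

The candidate space is all distributions over the 121-point ln-uniform
grid (step 0.0347) with at most two support points and probabilities on
a 0.01 lattice summing to 1.  The search reproduces the published
algorithm: exhaustive single-speed stage; then for each separation of
2–96 grid steps (ln-separation 0.0693–3.3271, ratio up to 27.86x) a
center walk starting at the grid middle, moving while OF strictly
improves, then looking ahead up to 30 further intervals and jumping to
the first improvement, stopping at a border or when none is found; the
walk runs leftward and rightward.  Ties: an exactly equal neighbor stops
the walk (the published rule moves only on strict improvement), and an
exact tie between the best single- and two-speed solutions returns the
single-speed solution (parsimony) with the tie flagged.

Implementation note: for fixed sites, weights and p the smoothing spline
is a linear operator, so spEP(φ) is linear in φ.  The decoder
precomputes the grid response of every point-mass distribution and
evaluates each candidate's OF from the resulting Gram matrix.  This is
algebraically identical to building spEP per candidate — the tests
assert equality with brute-force enumeration on a reduced grid — but
makes per-trial decoding run in milliseconds.

Per-trial decoding normalizes Poisson-resampled counts and spline-fits
each trial's population response before decoding.  Readouts are
classified 'single' when the weight gap exceeds 0.7 (strictly); a
support point at a grid boundary or at the maximum searched separation
with weight < 0.15 is flagged as a likely boundary artifact.
Decode-based discrimination thresholds the readout ln-separation at
ln 1.3 ≈ 0.26 (choices in 1.1x–1.7x do not change conclusions
qualitatively), counting 'single'-class readouts as zero separation.

## d′ conventions

Standard d′ = Φ⁻¹(hit) − Φ⁻¹(fa).  The finite-d′ modified formula maps
both rates through (100r + 1)/102 and is available in two trigger modes:
`extremes` (only when a rate is exactly 0 or 1) and `always`.  The
classifier and decode-based discrimination stages use `always`: their
rates routinely sit at ceiling, and applying the correction to every
rate keeps d′ monotone in (hit, fa) there, whereas exact-extreme
triggering scores (1, 0.005) above (1, 0).  The 3AFC "no two speeds"
(NTC) option splits NTC counts evenly into the hit and false-alarm
tallies (fractional halves for odd counts), so NTC responses never aid
discrimination.

## Problem sizes

Default analyses use 100 neurons, 1000 control repetitions, 200 trials
per class for the classifier, and 200 decoded trials per condition; the
qualitative-ordering tests aggregate 10 seeds with 25 decoded trials per
class per seed.  These match the study conditions except for the decode
trial count per seed, reduced because the ordering statistic stabilizes
well below 200 trials.

## Known limitations

- No noise correlations, attention states, or temporal dynamics; the
  synthetic populations are stationary rate models.
- The empirical preferred-speed distribution beyond the three-group
  split is unknown; conclusions that depend on its fine structure are
  out of reach of the synthetic stand-in.
- The decoder's hill-climbing stage is heuristic on the full grid; the
  exhaustive-equivalence guarantee is established on reduced grids.
- Same-direction five-pair datasets cannot constrain the normalization
  model fit (under-constrained) and are not fit here.
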