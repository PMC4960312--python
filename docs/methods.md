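# Methods

## Generative model

The simulator produces the statistical structure that quantal analysis
assumes, nothing more.

**Evoked release.** Each NMJ carries a readily releasable pool of `n_rrp`
vesicles. A stimulus releases Binomial(`n_rrp`, *p*) of them, with

*p*(Ca) = `p_max` · Ca^`hill` / (`ca_half`^`hill` + Ca^`hill`).

A Hill dependence was chosen because vesicular release probability depends
cooperatively on calcium influx; the defaults (`p_max` 0.7, `ca_half`
1.5 mM, `hill` 3.0) put the experimentally used 0.5–3 mM range on the
steep-through-saturating part of the curve, giving strong growth of quantal
content between 0.5 and 1.0 mM. The curve is a simulator convenience, not a
biophysical claim: none of the estimators see it.

**Quantal amplitudes.** Each released vesicle contributes a current drawn
from a Gamma distribution with mean `q_mean` (default 0.8 nA) and CV `q_cv`
(default 0.3) — strictly positive and right-skewed, like measured mini
amplitude histograms. A sum of *k* such draws is drawn directly as
Gamma(*k*·shape, scale). Measured evoked amplitudes add Gaussian noise of
s.d. `noise_sd` (default 0.1 nA) and clip at zero (amplitudes are reported
as positive magnitudes of inward currents at −80 mV holding). Mini
amplitudes are pure quantal draws arriving as a Poisson process
(`mini_rate`, default 2 Hz).

**Between-NMJ heterogeneity.** A lognormal multiplier with unit mean and CV
`nmj_cv` (default 0.2) scales `n_rrp` and `q_mean` once per NMJ and is
shared across that NMJ's protocols, as it would be across recordings from
one physical junction.

**Trains.** During 60 Hz trains the pool depletes: release_t =
Binomial(⌊pool⌋, *p*) (pool·*p* in expectation mode), then a fraction
`replenish_frac` (default 0.05) of the deficit refills before the next
stimulus. Replenishment is deterministic and release stochastic, which
keeps the conservation bound — cumulative release never exceeds the initial
pool plus cumulative replenishment — exact rather than in expectation. The
pool never leaves [0, `n_rrp`]. This is the simplest discrete-time
refilling scheme; no facilitation, calcium-channel kinetics or receptor
desensitization is modeled.

**Trace rendering.** Events convolve with a biexponential waveform
(defaults: rise 1 ms, decay 6 ms, stimulus-to-peak latency 1.5 ms with
0.2 ms Gaussian jitter — typical larval-muscle mEJC kinetics), scaled so
the *filtered* peak equals the event amplitude (the filter is linear, so a
single unit-kernel calibration suffices). Gaussian baseline noise is added
and the whole trace passes a 4-pole Butterworth low-pass at 1 kHz applied
forward only, modeling acquisition filtering; the default sampling rate is
10 kHz (≥10× the cutoff). When the pipeline renders low-frequency evoked
protocols it compacts the inter-stimulus interval to 0.5 s — two orders of
magnitude longer than the response decay, so amplitude statistics are
unchanged while sweeps stay tractable.

## Detection layer

**Noise.** Baseline noise is summarized from 30-ms quiescent windows (at
least eight): prestimulus intervals on evoked sweeps, tiled segments on
spontaneous sweeps. Two statistics are kept: the mean and s.d. of the
per-window peak-to-trough range (`mean_na`, `sd_na` — the failure-analysis
statistic; a per-window s.d. variant is available by config), and the
pooled per-sample s.d. (`sample_sd_na`), which is the natural scale for
detection thresholds. On spontaneous sweeps a robust mode first discards
windows whose range exceeds twice the median window range, so sparse events
do not inflate the estimate.

**Minis.** Detection runs on a 1-ms boxcar-smoothed trace: negative-going
peaks with prominence ≥ `threshold_k` × `sample_sd_na`, a 5-ms refractory
merge (larger peak kept), amplitude measured from the unsmoothed trace
against the median of the 10 ms preceding the peak. `threshold_k` defaults
to 4.5: on synthetic sweeps at quantal-SNR 5 and 2 Hz this yields recall
≥ 0.98 and precision ≥ 0.99 against the simulator's event list, whereas 3–4
sample-s.d. thresholds admit bare noise crossings (measured precision
0.94–0.96). With a degenerate (zero-s.d.) noise model an absolute 0.05 nA
floor applies with a logged warning.

**Evoked amplitudes.** One row per stimulus: |trace minimum in the 30 ms
post-stimulus window − median of the 10 ms pre-stimulus baseline|; exact on
noise-free rendered responses across 0.5–100 nA. Stimuli whose window runs
past the sweep end are excluded with a warning. All window lengths are
config-exposed; none is a measured property of real recordings.

## Estimators

**Direct QC** uses arithmetic means. **Failure analysis** classifies a
stimulus as a failure iff its amplitude ≤ noise mean + `k_noise` (default
2) × noise s.d. **and** below the 5th percentile of that NMJ's mini
amplitudes (both constants config-exposed; both sub-criterion counts
logged), then QC = ln(m/n₀). Zero failures raise an error advising lower
calcium — the Poisson estimator is undefined there.

**Variance–mean.** Per calcium level: mean, unbiased (n−1) variance, CV² =
Var/mean². The parabola is fitted as Var = A·I − B·I² through the origin
with A, B ≥ 0 (non-negative least squares). The variance–mean relation is
implemented in this downward form: the binomial model gives Var =
qI(1+q_cv²) − I²/N, which has the maximum that motivates "parabolic" fits
and a finite N from curvature; a monotone increasing sign convention cannot
yield either. Weighting defaults to inverse squared variance: the sampling
variance of a sample variance scales with Var², so this is the
generalized-least-squares choice, and it matters — with unweighted fitting
the per-NMJ N = 1/B has sampling CV ≈ 1 even at 100 EJCs per level, too
noisy to resolve a 1.7-fold pool difference at n = 10 NMJs (measured power
14% unweighted vs 92% weighted). Unweighted and count-weighted variants
remain available by config. When B is positive but its 95% CI (from the
unconstrained fit) includes zero, the estimate is flagged imprecise but
still reported; refusing it would silently select for small-N fits and bias
cohort medians. N is withheld (NaN + flag) only when the fit finds no
curvature at all (B at the boundary). Per level, Pvr = I(B/A)(1+CV²) and
q = A/(1+CV²), using that level's *amplitude* CV² exactly as defined —
note this differs from conventional fluctuation analysis, which uses the
quantal CV; both q readings (per-level and the coefficient A itself) are
reported. A minimum of three calcium levels is required so the two-parameter
fit has residual degrees of freedom.

**Cumulative train.** OLS line through cumulative points 21–30 against
stimulus index, intercept at index zero divided by the mean mEJC. A
negative intercept (facilitation-dominated train, no depletion-defined
pool) is floored at zero and flagged. With 5% replenishment the estimate
runs ~15% below the true pool — replenished vesicles released early in the
train steepen the tail fit — which is an inherent property of
back-extrapolation, shared by the experimental method.

## Cohort statistics and pipeline

Groups are summarized as mean ± s.e.m. (s.d./√n, n = NMJs). Two groups:
two-tailed Student's t-test, pooled variance by default (Welch by flag);
both groups constant and equal is reported as p = 1. Three or more: a
Brown–Forsythe screen (median-centered Levene, α = 0.05, Bartlett not used
because per-NMJ estimates are not reliably normal) routes to one-way
ANOVA + Tukey HSD, or, on rejection, to a Welch omnibus with Games–Howell
(Welch–Satterthwaite df, studentized-range quantiles). The branch taken is
always recorded. Standard tests come from scipy and pingouin; only the
quantal estimators and the simulator are bespoke.

The pipeline is a pure function of (config, seed): per-genotype seeds are
spawned from the master seed, every exclusion (holding current > 10 nA,
skipped estimator, unconstrained fit) is logged, and identical configs
yield byte-identical tables. The holding-current gate rejects strictly
above 10 nA (exactly 10 nA is accepted) and flags |holding| < 5 nA as
"low-holding" for reporting only. The recording-QC calcium level (0.5 mM),
failure protocol (0.25 mM, 300 stimuli at 1 Hz), train protocol (3 mM,
60 Hz, 30 stimuli) and variance–mean grid ({0.5, 1, 1.5, 2, 2.5, 3} mM)
are config defaults. The variance–mean protocol defaults to 100 EJCs per
level: 20 per level (the protocol minimum, below which a warning fires)
bounds what a level contributes to a cohort median but leaves single-NMJ
pool estimates with CV > 1, which no per-NMJ comparison can carry.

## Problem sizes and what the tests show

The test suite validates parameter recovery at desk scale: 100–200
simulated NMJs for estimator calibration, 50 replicate cohorts of 10 NMJs
for power, 1,000 replicates for type-I error, 20 rendered 10-s sweeps for
detection. Passing these shows the estimators are correct *for data obeying
the generative model*. Real recordings violate it in known ways the
simulator deliberately omits: short-term facilitation and receptor
desensitization, baseline drift and stimulus artifacts, non-stationary
release probability, space-clamp error, and manual curation of ambiguous
events. Results on real data inherit none of the guarantees demonstrated
here beyond the algebraic identities.

## Known limitations

- The failure criterion needs ≥ 20 minis per NMJ and a noise model; in
  amplitude-only mode the noise model comes from the configured noise s.d.
  rather than from windows of a real trace.
- Back-extrapolated pool sizes are biased low under replenishment (above);
  variance–mean N is unbiased in median but heavy-tailed per NMJ.
- Per-level CV² in the Pvr/q equations mixes quantal and binomial
  variability; the conventional quantal-CV variant is available by config
  switch for sensitivity analysis.
- The renderer does not model pool depletion within rendered sweeps, muscle
  geometry or electrode artifacts; full-trace mode re-measures only the
  spontaneous and quantal-content protocols through the detection layer.
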