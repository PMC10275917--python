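# Methods

This note documents the models, conventions and numerical choices behind the
package, in the order the pipeline runs.

## Audio and annotations

Audio is PCM WAV (16/24-bit integer or float), read through
`scipy.io.wavfile` and scaled to [−1, 1] by the full-scale integer (2¹⁵ for
int16, 2³¹ for left-justified 24/32-bit data).  Stereo is averaged to mono:
field recorders vary, and the analysis is single-channel.  Note annotations
are 3-column tab-separated label tracks (`start<TAB>end<TAB>label`, seconds),
the export format of common spectrogram editors.  Time-to-sample conversion
is round-half-up with half-open intervals `[round(start·rate),
round(end·rate))`, chosen so that slicing a clip by any partition of its
duration and concatenating reproduces the sample sequence exactly.

A song's trill is the trailing run of notes labelled with the trill class;
intro/trill distinction is taken from the labels, never inferred from
acoustics.  Songs whose trill has fewer than 2 notes are *flagged* excluded
rather than dropped (pairwise consistency is undefined below one pair, and
keeping the rows makes totals auditable); the same screening motivates the
generator's minimum of 3 trill notes.

## Spectrograms and SPCC

Spectrograms are linear magnitude (not power, not dB), 512-sample Hann
window, 90% overlap, no boundary padding, so the hop is 51 samples and the
frame count is `floor((N−512)/51)+1`.  At 48 kHz the native frame step is
~1.06 ms; the ±20 ms lag search at 1 ms nominal resolution is realised as
the deduplicated set of native-frame lags covering ±20 ms — the closest grid
the windowing admits.

At each lag the two spectrograms are compared by Pearson correlation over
the flattened frequency × overlapping-time cells, with two refinements:

* **Both-zero columns are dropped** before the correlation.  Silent padding
  carries no information, and without this step padding shifts the cell
  means and the score would depend on how much silence surrounds a note;
  with it, shifting a note inside its silent margins permutes the lag set
  one-to-one and the maximum is exactly invariant (verified to 1e−9).
* **A minimum overlap of 3 frames** is required, else the lag is skipped.

Correlation on linear magnitude with mean subtraction is the common SPCC
convention and gives the contract the score needs: bounded in [−1, 1],
symmetric, and exactly 1 for a self-comparison.  If every lag has
zero-variance overlap (silence vs silence) the score is defined as 0 with a
warning rather than NaN.  Notes shorter than one FFT window are zero-padded
to a single window.  All notes are resampled to one analysis rate (default
48 kHz) so frequency and frame grids match.  The full band is used; no
band-limit is applied by default (none is part of the measurement's
definition here).

Per-note consistency is the mean SPCC of that note against every other
trill note (row mean of the pair matrix, diagonal excluded); song-level
consistency is the mean over notes, which by symmetry equals the mean over
unordered pairs — the tests assert both identities against brute-force
enumeration.

## Bout segmentation and the warm-up model

Songs are time-stamped; the silent pause between songs is measured from one
song's end to the next song's start.  A new bout starts at the session
start, at a type switch, or after a pause > 60 s; a pause starts a new bout
even without a switch, and takes precedence when both occur at once.  Runs
of fewer than 3 songs are emitted flagged `sub_minimal` and excluded from
warm-up analysis.  Segmentation partitions its input: every song lands in
exactly one run.

Warm-up series take the first 15 repetitions of a bout, subtract the
first-song consistency (position 1 is exactly 0 by construction), and drop
songs without a consistency value while preserving repetition numbers; a
bout whose first song is missing has no baseline and is skipped with a
warning.  The trend model is a linear mixed model, `std_consistency ~
repetition + (1 | individual)`, REML-fitted via statsmodels MixedLM — a
random intercept per individual only, matching the single reported variance
component.  With one individual the model degenerates and the code falls
back to OLS with a warning.

The warm-up simulator draws raw song-level consistencies `baseline + b_i +
slope·p + ε` (individual SD 0.028, slope 0.002/repetition, song noise SD
0.074 — the published estimates at 18 individuals × 4 bouts × 15 positions)
and pushes them through the same standardisation the measurement path uses.
Differencing by the first song inflates the std-scale residual (≈ √2 × the
song noise) and induces within-bout correlation; the slope stays unbiased
and its CI is, if anything, conservative — recovery tests require ≥90%
coverage over 50 seeded replicates and observe ~100%.

Seasonal summaries bin weeks by floor division so the first-egg date falls
in week 0, and centre consistency within individual (mean 0 per male).
Spline/GAMM fitting of the seasonal curve is out of scope; only the
normalisation feeding it is provided.

## Playback construction

A song-type bout repeats one exemplar song verbatim at the male's measured
song rate: onsets at `0, 60/rate, 120/rate, …` while the complete song still
fits in the 75 s bout; the remainder is silence.  Twelve 5-minute rounds
each hold one 150 s song section (two bouts, one per song type) and one
150 s silence section, order drawn per round from a seeded generator; the
schedule is a pure function of (types, seed, lead silence).  One open design
point was how the two types are ordered when two song sections abut: the
package forces the later section to open with the *other* type, so every
bout is cleanly preceded by either silence (>60 s) or a genuine type switch
— the two levels the habituation model contrasts.  Rendering replaces
speaker SPL calibration with digital peak normalisation (default −3 dBFS),
which is hardware-independent and cannot clip.

## Female-response models

Response scoring counts only the three call classes associated with
copulation solicitation (copulation, twittering, chattering); churring,
screaming and unclassified calls are ignored.  A song position scores 1 if
at least one such call falls in its onset-to-next-onset window; a bout's
response is the OR over positions; bouts played while the female was absent
(occupancy fraction below a threshold, default: any presence retains the
bout) are removed.

The song-vs-silence comparison is a paired Wilcoxon signed-rank test on
per-female proportions: zero differences dropped, V = sum of positive-
difference ranks, exact permutation p-value for n ≤ 25 without ties (normal
approximation with continuity correction otherwise), and a Hodges–Lehmann
CI from Walsh averages with exact (dynamic-programming) or approximate null
quantiles.

Both GLMMs are binomial logistic models with a single random intercept
(female identity), the only variance component the reported models carry.
statsmodels has no frequentist GLMM, so the package fits them by maximum
likelihood with **adaptive Gauss–Hermite quadrature** (15 nodes): per
cluster, Newton steps locate the integrand's mode and curvature and the
Hermite nodes are recentred there — the lme4 `nAGQ` approach, accurate even
for large clusters where naive quadrature fails.  The fit agrees with
lme4::glmer (nAGQ = 9) to ~1e−3 on test data (asserted in the suite at 0.02
absolute).  Standard errors are Wald from a finite-difference Hessian; CIs
are Wald on the logit scale and back-transformed endpoint-wise, matching
the published table layout (the original CI method is not stated).  The
variance component is optimised as log-SD; complete separation is flagged,
not silently "fixed".

Habituation design conventions, shared by the simulator and the fitter
through one utility: `log(position)` is the natural log of the 1-based song
position, *uncentred*, and the switch indicator is raw 0/1 with
silence-preceded as the reference — so the intercept is the response at the
first song of a silence-preceded bout (inverse-logit 0.513 at the reference
coefficients, which is how the published intercept reads).  The preference
model's continuous predictors (vocal consistency, song rate, trill length)
are z-scored; song rate is exposed as a predictor even though the published
final model retains only consistency and trill length — model selection is
allowed to drop it.

Model selection follows the information-theoretic workflow: AICc
(−2ℓ + 2k + 2k(k+1)/(n−k−1)), candidate ranking, Akaike weights renormalised
within the ΔAICc < 2 set, **full** model averaging (a coefficient is 0 in
models that omit the term — the "full average" convention, not conditional
averaging), relative importance as the summed weight of models containing a
term, and a report listing all candidates with ΔAICc < 7.  Collinearity is
screened by VIF (regression of each predictor on the others plus an
intercept), flagged above 3.

## Synthetic data: what it does and does not emulate

Notes are frequency-swept sinusoids (trill default 6 kHz with a downward
sweep; intro notes a configurable factor higher) with raised-cosine ramps,
note-to-note Gaussian jitter in frequency (default SD 50 Hz), duration
(3 ms, clamped at 25% of nominal) and amplitude (5%), plus white noise
(1% RMS).  Defaults describe a realistic singer: 2 intro + 8 trill notes of
60 ms at 100 ms spacing, song rates 12–14/min so a 75 s bout holds 15–18
songs.  Consistency responds monotonically to each jitter dose — the
generator's core realism property, asserted over 100 seeded trills per
level.

The warm-up effect is injected by *shrinking the frequency jitter* across
repetitions, not by setting consistency directly (consistency is a derived
measurement, not a dial); a calibration routine maps a Monte-Carlo
jitter→consistency curve to the per-position jitter schedule achieving a
target slope, stored with its seed.  Response simulation draws per-female
intercepts and Bernoulli outcomes from the logistic habituation process
using the fitter's own design matrix, so recovery tests are exact in
expectation.

What the generator does **not** emulate: real blue tit timbre, syntax
learning, reverberation or coloured environmental noise, competing singers,
or movement of the bird relative to the microphone.  Passing tests
demonstrate that the measurement and inference machinery is correct under
the stated statistical structure — not that field recordings of comparable
SNR would yield identical scores.

## Problem sizes and numerical details

Recovery suites use the published generating-process parameters at their
published sample sizes (warm-up: 18 individuals × 4 bouts; habituation: 100
females × 8 bouts × 15 positions) with 50 seeded replicates, sizes chosen to
keep the full suite comfortably runnable on a laptop while leaving the
coverage criterion (≥90%) well-resolved.  Habituation rows are aggregated
to binomial counts per (female, switch, position) before fitting — the
likelihood depends only on those cells, and the aggregation cuts fit time
several-fold.  Optimisation is L-BFGS-B from a GLM warm start; quadrature
mode-finding runs 25 vectorised Newton steps with step clamping at ±4.
Degenerate inputs raise informative errors rather than returning NaN:
zero-variance predictors are named, all-zero signed-rank differences are
rejected, AICc refuses n ≤ k+1, and sub-window clips are zero-padded only
where the contract says so.
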