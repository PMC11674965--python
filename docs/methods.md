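# Methods

## Scope and model class

The package analyses region-to-region connectivity in the two visual
streams from sampled BOLD-like time series. All directed-connectivity
machinery assumes the data are well described by a stationary vector
autoregression (VAR): x(t) = Σₖ Aₖ x(t−k) + ε(t), ε ~ N(0, Σ). This is the
model class that frequency-domain Granger causality presumes, and it is
also the generative model of the synthetic cohort, so parameter recovery
and calibration are testable end to end.

## Directed connectivity (spectral Granger causality)

For a bivariate VAR(p) with sampling rate fs, the transfer function is
H(f) = (I − Σₖ Aₖ e^(−i2πfk/fs))⁻¹ and the spectral matrix S(f) = H Σ H*.
The causality from channel 2 to channel 1 is

    I₂→₁(f) = ln [ S₁₁(f) / (S₁₁(f) − (Σ₂₂ − Σ₁₂²/Σ₁₁) |H₁₂(f)|²) ]

where Σ₂₂ − Σ₁₂²/Σ₁₁ is the partial innovation variance of the source.
The band-integrated ("time-domain equivalent") value is the
bandwidth-normalized trapezoid integral over [f₁, f₂]. Over the full band
[0, fs/2] this equals Geweke's residual-variance log-ratio
ln(σ²_reduced/σ²_full) when Σ₁₂ = 0; the test suite verifies this identity
against an independent reduced-model refit on T = 10⁵ simulations (within
5%). With Σ₁₂ ≠ 0 the formula above (which uses the raw H₁₂ rather than a
rotated transfer function) is no longer exactly the Geweke decomposition;
finite-sample or Σ₁₂-induced negative values of the ln argument are clamped
to zero and counted in a diagnostics dict.

Numerical choices: 513-point frequency grid on [0, fs/2]; analysis band
0.05–0.9 Hz (Nyquist is 0.935 Hz at TR = 535 ms); VAR estimation by
multivariate least squares on demeaned segments with residual-covariance
divisor T − p; a regressor condition number above 1e10 raises an error
rather than returning a silently unstable fit. Multi-run recordings are fit
per run and the spectral GC curves averaged with run lengths as weights —
concatenation across run boundaries would manufacture spurious cross-
boundary lags. FC is likewise computed per run and averaged.

## Model-order selection

The order is chosen from candidates 2–20 by minimizing a spectral
difference between the fitted VAR's parametric spectral density and a
nonparametric (Welch, segment-averaged) cross-spectral estimate, summed as
a squared Frobenius norm over the Welch grid. Two refinements make this
criterion identifiable in practice:

* **Held-out reference.** The series is split in half; each half's VAR fit
  is scored against the *other* half's Welch estimate and the two scores
  summed. Scoring a fit against a spectrum estimated from the same samples
  lets high orders chase shared periodogram noise, which flattens the
  criterion and destroys order recovery.
* **DC exclusion.** Per-segment demeaning biases the Welch estimate at the
  lowest bin, and these spectra peak at low frequency; the DC bin is
  excluded from the distance. Welch settings: nperseg 256, 87.5% overlap.

With these choices the criterion recovers a true order 2 and the packaged
order 6 modally over 50 simulations at T = 3440. Ties break toward the
smaller order.

## Group statistics

Group differences use the Wilcoxon rank-sum test: exact enumeration when
the pooled sample is ≤ 12 without ties, otherwise the normal approximation
with midrank tie correction and continuity correction (the exact path can
be forced where feasible). Family-wise error is controlled per subsystem
family (DVS, VVS, VS — four connections each) by Holm–Bonferroni. For the
directed metric both directions of every connection enter the family
(family size 8), a conservative choice that is configurable. Tests are
two-sided by default. Subject exclusion is metric-local: a subject missing
one connection's value is dropped only from that connection's test.

Brain–behavior association is Spearman's rank correlation (midranks,
two-sided t-approximation p) between a connectivity metric and response
time; an ordinary least-squares line is fitted for display only and plays
no inferential role.

## ROI geometry

ROIs are spheres at MNI millimetre coordinates (6 mm radius functional,
12 mm structural). A voxel belongs to a sphere iff its center's mm
coordinates lie within the radius (voxel-center convention, not
any-overlap). The default grid is 2 mm isotropic MNI-like (configurable
affine). Extraction is voxel-average → per-run linear detrend → per-run
z-normalization; a zero-variance averaged segment is an error rather than
a silent NaN.

## Synthetic cohort: what it emulates and what it does not

The generator reproduces the statistical skeleton the analysis assumes:
47 subjects (28/19), four 860-sample runs at fs = 1/0.535 s, a designated
dorsal pair (L SOG → L SPL) carrying a group-dependent directed coupling,
response times monotonically and negatively linked to that coupling, and
per-connection FA/QA tables with a gamer-side shift on the designated
dorsal connection. The remaining 12 ROIs are independent AR(1) channels:
they keep the 14-ROI table shape at negligible cost and carry no designed
effect, so every non-designated connection is a built-in negative control.

Per-subject dynamics (bivariate VAR(6), channel 0 = source):

* diagonal memory at lags 1 (0.30 ± 0.005 jitter) and 6 (0.25) — the lag-6
  term makes the true order 6, matching the packaged analysis order;
* directed coupling c at lag 1, c ~ N(0.345, 0.011) for gamers and
  N(0.255, 0.011) for nongamers;
* a zero-DC nuisance cross-coupling (equal-and-opposite coefficients at
  lags 2 and 3, SD 0.17, truncated at 2.5 SD for stationarity margin).
  Because its transfer gain vanishes at f = 0, it perturbs directed
  predictability (TGC) while leaving the low-frequency covariance that
  dominates FC nearly untouched — subject-level "temporal profile"
  heterogeneity orthogonal to connection strength;
* unit innovation covariance (an optional innovation-correlation jitter
  exists but defaults to zero, which also keeps the GC formula exactly in
  its Geweke form).

Every emitted system passes a companion-spectral-radius < 1 gate. Seeding
is counter-based — generators derive from (seed, stage, subject index) —
so enlarging the cohort never perturbs existing subjects' draws.

Response times follow RT = rt_mean_nongamer + s·(z̄_non − z) + noise, with
z the coupling standardized by its theoretical pooled moments and slope
s = behavior_link_strength · rt_gap / Δz̄. The group gap is therefore
mediated entirely through the coupling separation: its expectation equals
behavior_link_strength × rt_gap (190 ms at defaults), the noise-free map is
globally strictly monotone (Spearman exactly −1), and zero link strength
removes both gap and association. RT noise SD is 15 ms.

Calibration: the defaults above were set by a one-off Monte-Carlo sweep so
that, at packaged defaults, the designated connection's group effect sizes
land near d ≈ 1 on both FC and TGC and the brain–behavior Spearman
correlations center near −0.45 (TGC) and −0.41 (FC) over the 44-subject
complete-data subset, with a group RT gap of 190 ± ~9 ms. A single seed's
rho scatters with the sampling error of a rank correlation at n = 44
(SD ≈ 0.10), so individual seeds occasionally land outside ±0.15 of the
center; the tests therefore pin a fixed seed panel.

What the generator does **not** emulate: hemodynamic response convolution,
physiological noise and motion artifacts, spatial correlation between
ROIs beyond the designated pair, condition structure within runs, and any
dependence of FA/QA on the functional coupling (structural metrics are
drawn independently, so the packaged cohort shows no structural
brain–behavior correlation — matching the analysis expectation, but by
construction). Passing tests demonstrate the statistical machinery and its
calibration, not fidelity to real BOLD physiology.

Completeness flags reproduce the cohort bookkeeping (one gamer missing
tractography, one nongamer missing fMRI, one of each missing response
time), giving effective sample sizes 46 (functional), 44 (functional
brain–behavior), 46 (structural), 44 (structural brain–behavior).

Structural tables draw FA ~ N(0.45, 0.06) clipped to (0, 1) and
QA ~ N(0.35, 0.08) floored at zero, with gamer shifts +0.055 (FA) and
+0.07 (QA) on the designated dorsal connection (L SOG–L IPL); the shift
corresponds to a rank-sum rejection rate above 80% uncorrected at the
packaged group sizes.

## Known limitations

* Pairwise (bivariate) GC only — no conditional/multivariate GC, no
  spectral-factorization or state-space variants, no hemodynamic
  deconvolution. Directed estimates can reflect common input.
* The GC formula follows the plain-H₁₂ form above; with correlated
  innovations it deviates from the exact Geweke decomposition (defaults
  keep Σ₁₂ = 0).
* Order selection needs enough samples for a meaningful half-split
  (roughly T > 20·p_max); at short T the criterion degrades gracefully but
  noisily.
* Real-data p-values from any particular cohort are not reproducible from
  the packaged generator; only the calibrated summary statistics are.
* A pipeline run at the packaged sizes (47 subjects × 12 connections ×
  4 runs) takes on the order of a minute on one core; the test suite uses
  reduced cohort sizes for end-to-end round trips and the packaged sizes
  for the calibration checks.
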