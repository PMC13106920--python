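# Methods

This note records the models, the numerical choices, and the design
decisions behind the package, together with what the synthetic cohorts
do and do not establish about real song data.

## From onsets to ratios

The unit of analysis is the *individual contribution*: one animal's
part in a group song, as a strictly increasing sequence of note-onset
times in seconds. Onsets come from a Praat TextGrid interval tier
(long text format, UTF-8 or UTF-16; the short format is rejected with
an explicit message to keep the parser small and auditable) or from
the canonical onset CSV. A note is any interval with a non-empty,
non-whitespace label; times are taken verbatim, with no rounding, so
downstream ratios are as exact as the annotations.

Inter-onset intervals `t_k` above the 5 s cap are treated as
between-part silences: the interval is discarded and a sequence break
recorded, so by default no ratio `r_k = t_k/(t_k + t_{k+1})` and no
interval triple spans the gap. Rationale: a ratio formed across a
discarded interval would smuggle the excluded duration back into the
analysis. The alternative reading — drop only the interval and treat
its neighbours as adjacent — is available as `bridge_gaps=True` on
`compute_iois`.

Age classes partition the age axis at 2.5 and 4.5 years (0–2 years:
age ≤ 2.5; 3–4 years: 2.5 < age ≤ 4.5; adult: age > 4.5). The verbal
class definitions leave (2.5, 2.6) unassigned; the boundary is taken
at exactly 2.5 so membership is a half-open partition and
`assign_age_class` is monotone.

## The bin scheme

On/off-integer ranges are stored as exact `Fraction` boundaries:
1/3.5, 1/3.25, 1/2.75, 1/2.5, 1/2.25 and their complements. The
decimal forms in circulation are inconsistently rounded (1/3.5 appears
as 0.285, 0.286 and 0.287 depending on the source); exact fractions
remove the ambiguity and make the six ranges tile
[1/3.5, 1 − 1/3.5] with no gaps or overlaps. Membership is half-open
`[lo, hi)` with the single global maximum closed (assigned to the last
off-range), guaranteeing a partition. The on and off ranges have
unequal widths — on: 8/143 (1:2 and 2:1) and 1/9 (1:1); off: 2/91+2/55
and 4/45 — which is exactly why the count model needs an offset.

## Peak-significance model

Per age class, the number of ratios per bin per contribution is
modelled as

    count ~ bin * sex + offset(log width) + (1 | individual),  Poisson, log link.

The offset is `log(bin width in ratio units)`, the standard exposure
construction: coefficients are then log densities (counts per unit
ratio width), making on and off bins directly comparable. The
companion null model keeps only the offset and the random intercept.

Inference chain, mirroring standard mixed-model practice:

1. **Likelihood-ratio test** of full vs null, `2Δℓ` against chi-square
   with df = the difference in fixed-parameter count (11 for the 6 × 2
   interaction design).
2. **Estimated marginal means** per bin (within sex), averaging the
   reference grid with equal weights over the companion factor on the
   link scale — the conventional default of contrast machinery.
3. **Tukey-adjusted pairwise contrasts** using the studentized-range
   distribution with family size k = number of bin levels, asymptotic
   (infinite-df) to match the Wald z statistics; with k = 2 this
   reduces exactly to the two-sided normal p-value.
4. **Zero-inflation check**: observed zeros vs `Σ exp(−μ̂_i)` with
   conditional fitted means; a ratio above 1.05 raises a flag (no
   zero-inflated model is fitted — the check is diagnostic only).

A category is reported as significantly on-integer for a sex when the
LRT passes at α and the within-sex on-minus-off contrast is positive
with adjusted p < α (α = 0.05 by default). Sex-pooled contrasts are
available through the same machinery (`by=None`), but within-sex is
the default because the results are reported per sex. When a cohort
contains a single sex, the sex factor is dropped from the design (a
one-level factor is not estimable) and contrasts run over bins alone.

## Estimation: Laplace-approximated ML

No installed Python library fits maximum-likelihood random-intercept
Poisson or beta GLMMs, so the fitter is implemented here. For a scalar
random intercept per group the marginal likelihood factorises over
groups; each group's integral is approximated by Laplace's method
around the penalised-likelihood mode, found by a vectorised scalar
Newton iteration across all groups simultaneously (Fisher curvature
for the beta family, where the observed curvature can lose
definiteness). The outer optimisation (L-BFGS-B over fixed effects,
log random-effect SD, and log precision for beta) uses the profiled
objective; adaptive Gauss–Hermite quadrature with a configurable node
count is available where Laplace accuracy is in doubt.

Key numerical choices:

* With σ pinned at 0 the objective reduces *exactly* to the ordinary
  GLM likelihood; the test suite verifies agreement with plain Poisson
  regression to 1e-6 in coefficients and log-likelihood. σ is bounded
  below at 1e-5, so boundary (σ² → 0) fits are reported as ≈ 0 rather
  than failing.
* Standard errors come from a central-difference Hessian of the
  marginal negative log-likelihood, fixed-effect block inverted.
  Quasi-separated cells (a bin with essentially no counts) leave the
  Hessian singular in that direction; the affected coefficient gets an
  infinite SE, so its contrasts report z = 0, p → 1 — the honest
  statement that the direction is not identified.
* Convergence: L-BFGS-B with relative tolerance 1e-10, max 500
  iterations; non-convergence sets a flag on the fit and is recorded
  in the pipeline manifest, never raised as an exception, so a run can
  finish and report it.
* All-zero count responses (the Poisson supremum sits on the boundary
  λ → 0) return a flagged degenerate fit; the significance map then
  reports nothing significant with LRT p = 1.
* The implementation is cross-checked in the test suite against
  glmmTMB's Laplace fit of the same Poisson model on a small simulated
  dataset (log-likelihood, coefficients and σ² to 1e-3).

## Regularity model

Per contribution and category, regularity is the width-weighted
on-share `(n_on·w_on)/(n_on·w_on + n_off·w_off)`, missing when no
ratio fell near the category. The weighting reading — each bin's
count multiplied by its own bin width in both numerator and
denominator — preserves the stated endpoints (1 = all on-integer,
0 = all off-integer) and reduces to the plain proportion when widths
are equal. An alternative reading (weighting by the density mass over
the bin rather than its width) cannot be excluded from the verbal
description; it is noted here and not implemented.

Because the beta likelihood has open support, exact 0/1 responses are
compressed on request by `y' = (y(n−1) + 0.5)/n` (n = number of
non-missing rows), applied to the whole column in the standard
Smithson–Verkuilen fashion. The model is

    regularity ~ sex * age_class + (1 | group),  beta, logit link, precision φ.

The grouping factor defaults to the contribution. With one regularity
value per contribution × category this leaves σ² weakly identified
against φ; the fitter emits an identifiability warning and
individual-level grouping is available as a config option
(`regularity_group: individual_id`). The categories modelled default
to 1:2 and 1:1 — those detected as significant in at least two age
classes of both sexes — and the set is a configuration knob.

## Densities and peaks

Gaussian-kernel density estimates use Silverman's rule
`0.9·min(sd, IQR/1.34)·n^(−1/5)` on a 512-point grid spanning the data
± 3 bandwidths — the common density-plot convention, since no single
bandwidth is canonical for these curves. Peaks are interior local
maxima with prominence ≥ 1% of the curve maximum (suppressing
floating-point ripple), reported in increasing location order; for the
IOI distribution the lower mode is the intra-phrase interval and the
upper mode the inter-phrase interval. Peak *locations* from kernel
densities are bandwidth-dependent; published peak values from real
data cannot anchor the estimator without the original bandwidth, so
the package treats peak finding as descriptive machinery, validated on
simulated mixtures with known modes.

## Synthetic cohorts: what they emulate, what they do not

The generator produces phrase-structured contributions: per phrase a
shifted-Poisson number of units separated by gamma-distributed
within-phrase intervals (mean ~2 s, preset CV), phrases separated
either by a gamma between-phrase interval (mean = multiplier × within
mean, multiplier 2.0 for adults) or, with probability `p_long_pause`,
by an over-cap silence; single notes (probability `p_single_note`) are
always followed by a long pause. A lognormal per-individual tempo
multiplier (SD 0.1) induces the random-intercept structure. Gamma
noise was chosen as the simplest positive, CV-parameterised family; no
field estimate of interval dispersion exists for any class, so preset
CVs are calibration knobs, not estimates.

Presets are invented and tuned only to reproduce the *qualitative*
ontogenetic pattern: adults (low CV, rapid phrase alternation) yield
all three categories; young classes (high `p_long_pause`, noisy
between-phrase intervals, and for young females frequent single notes)
yield only isochrony. In the zero-noise limit every generated ratio is
exactly 1/3, 1/2 or 2/3, which pins classification and regularity
end-to-end.

Consequently, passing tests establish that the pipeline's machinery is
correct — exact binning, calibrated tests, recoverable parameters,
reproducible tables — under a data-generating process with the assumed
architecture. They do not establish anything about real indri song:
the generator has no phrase-final lengthening (so it does not
reproduce the right-shifted 2:1 peak or the 1:2/2:1 asymmetry real
females show at 3–4 years), no chorus overlap, no recording noise, and
its preset rates are not field estimates.

## Problem sizes and defaults

Default analysis cohort: 20 individuals × 5 contributions per age ×
sex cell (600 contributions, ~12,000 ratios), chosen as a realistic
multi-year field-campaign scale for this species. The acceptance
script runs exactly this cohort. Simulation-based tests use 20–200
groups per fit and 500 replicates for the likelihood-ratio
calibration check on a deliberately small design (20 groups × 4
observations, one 2-level factor), sizes at which the asymptotic
chi-square reference is already adequate.

## Known limitations

* The random-intercept structure is scalar (no random slopes, no
  crossed effects); the study design needs nothing more.
* Tukey adjustment is asymptotic (infinite df), consistent with Wald
  z contrasts from ML fits; small-sample df corrections are not
  implemented.
* The beta model's default contribution-level grouping is weakly
  identified by construction (see above); it is kept as the default
  deliberately, with a warning, because it matches the described
  design.
* Ternary plots are rendered with a minimal built-in simplex
  projection (no dedicated ternary-plot dependency): scatter only, no
  density shading on the simplex.
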