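# Methods

## The validation model

The package models an automated bone age reading as 21 per-bone estimates
of a common underlying skeletal maturity. Redundancy is the safety
mechanism: because all tubular bones mature under the same endocrine
control, any subset gives an unbiased consensus, so individual bones can be
discarded freely and the image as a whole can be rejected when too little
reliable evidence remains.

**Rule A (appearance).** In deployment this decision comes from a learned
model of normal bone appearance; here it is deliberately a pluggable
contract — a score in [0, 1] with a threshold (default 0.5, strict
inequality) — so any anomaly detector can drive it. The simulator draws
scores from U(0, 0.3) for normal and U(0.7, 1) for anomalous bones, which
makes the default threshold uninformative about calibration in between;
real detectors need their own calibration.

**Rule B (deviation).** The deployed description says only that a bone is
rejected when it deviates "by more than some threshold" from the average of
the tubular bones; it does not say whether the average excludes the
candidate or whether rejection iterates. We use iterative worst-first
removal against the leave-one-out mean, recomputed each round:

1. For each accepted bone, compute the mean of the *other* accepted bones
   and the absolute deviation from it.
2. Take the bone with the largest deviation (ties: lowest roster index).
3. If that deviation exceeds T(leave-one-out mean), reject it and repeat;
   stop otherwise, or when two bones remain (a deviation between two
   remaining bones cannot attribute blame).

The leave-one-out mean keeps a gross outlier from dragging the consensus
toward itself and masking its own deviation; iterating handles multiple
outliers. The procedure is deterministic, idempotent, and lands on a fixed
point of the one-round rule (verified against exhaustive subset enumeration
for small bone sets). A `single_pass` mode (one sweep against the
contaminated grand mean) is available for comparison; it is cheaper but can
both under-reject (masking) and over-reject (swamping) with multiple
outliers.

The threshold T is piecewise linear: 2.4 y at and above a consensus of
7 y, falling linearly to 1.2 y at birth — younger hands mature faster, so
equal age deviations mean more there.

**Image gates.** Gate order is fixed: bone count, then sharpness, then
radius-at-maturity. *Hand not found* (fewer than 8 accepted bones) is never
bypassable: below that the consensus itself is untrustworthy, so a
downgraded warning would report a number built on nothing. Gates 2–4
protect accuracy rather than validity and may be bypassed into
*accepted with warning* (useful in retrospective studies where every image
must yield a number). All gate comparisons are strict inequalities; a value
exactly at a threshold passes. With the sharpness gates active an image
without a sharpness value is an input error; with bypass on it is
tolerated, since the gates could not reject anyway.

## The sharpness statistic

Only the contract of the deployed measure is public: dimensionless,
invariant under linear brightness/contrast maps, film images around 5–6.5,
rejection outside (4, 13]. The functional form here is this package's own
convention:

    s = κ · max|∇I along profile| · (1 mm) / (p95 − p5 of profile intensity)

with profiles of 8 mm sampled every 0.25 mm perpendicular to segments laid
along the metacarpal shaft edges (five stations per segment, bilinear
interpolation, pixel centres at integer coordinates, default pixel spacing
0.1 mm). Percentile range rather than min/max resists noise; the median
over profiles rather than the mean resists occluded or unusable edges.
Gradient and range both scale with contrast, so the ratio is exactly
invariant; flat profiles (range below a 1e-9 relative floor) are discarded,
and fewer than two usable profiles is an error.

κ is fixed once by scoring the analytic reference edge — a unit step
convolved with a 0.6 mm Gaussian, i.e. Φ(x/0.6 mm), on the default grid —
and solving for the factor that makes it score 5.75, the midpoint of the
film interval. Since max|∇| of a blurred step is proportional to 1/σ, the
statistic is strictly decreasing in blur over the gated range; it flattens
once σ approaches the 4 mm profile half-length (far below the "too blurred"
gate already). The calibration is exposed (`calibration_constant`) for
users who need to re-anchor against their own modality.

## The simulator

The error model is the one implied by quadrature decomposition: truth
drawn uniformly over the observed study range (0–17 y males, 0–15 y
females), independent additive Gaussian method error (σ_auto, reference
0.33 y) and rater errors (σ_rater, 0.52 y hospital-like / 0.68 y
challenge-like), and a contamination mixture for manual ratings — with
probability 0.01 a rating's error is drawn from N(0, 1.5 y) instead —
giving the fat tails that drive disputed-case audits. Case-level ratings
are *not* truncated at zero: truncation would break the variance-addition
identities the evaluation rests on; per-bone ages are truncated (no
negative maturity), which matters only within ~1.5 y of birth. Per-bone
scatter defaults to 0.5 y and the anomaly rate to 0.02 — at that rate about
99% of images keep 19–21 bones, matching the deployment regime where
multi-bone rejection is rare. No published per-bone scatter exists; 0.5 y
is a convention chosen once.

Each case owns a spawned `SeedSequence` stream, so cohorts are bitwise
reproducible and a case's data do not depend on draw order.

Edge-test images are three vertical bright bands (background 50, bands 200
on a 32 mm field at 0.1 mm pixels) with Poisson noise, Gaussian acquisition
blur, optional unsharp masking, then an affine intensity map. The unsharp
mask (radius 0.6 mm) clips to the pre-enhancement range, as display
pipelines do; clipping is what lets strong boosts raise the normalised
gradient past the too-sharp gate instead of inflating the intensity range
in step with it. ROI segments run along all six band edges.

What the simulator does **not** emulate: real hand anatomy and per-bone
maturation ordering, disorder-specific patterns, rater bias or
heteroscedasticity across age, scanner-specific post-processing beyond
unsharp masking, and the true (unknown) shape of manual gross-error tails
beyond a two-component Gaussian mixture. Passing tests therefore show the
cascade and statistics behave correctly under the stated error model, not
that the deployed thresholds are optimal for any particular scanner fleet.

## Statistics

RMS is reported in years, MAD in months (12 × mean |error|); MAD/12 ≤ RMS
always (Jensen), with equality only for constant-magnitude errors. The
quadrature decomposition assumes independent additive errors; when the
observed RMS falls below the reference error the decomposition raises
rather than clamping — a negative variance estimate is a model
contradiction the caller should see. `reference_error_sd` always computes
σ/√k rather than quoting any published value; published decomposition
chains that used a differently rounded reference error are reproduced by
passing that value explicitly. Bland–Altman tables put the mean of the two
methods on the x-axis and use bias ± 1.96·SD limits. The disputed-case
audit uses strict thresholds (defaults 1.8 y dispute, 1.5 y grave) and is
symmetric in the two methods by construction.

Bootstrap uncertainty for the recovered true accuracy resamples cases (200
replicates by default) with a percentile CI; inside this estimator negative
variance estimates are floored at zero, since a resampled replicate is not
a user-facing decomposition.

## Problem sizes and numerical choices

Simulated evaluations in the tests and the acceptance script use cohorts
of 8,250 cases (the hospital-study scale) and 10,000 where a moment check
wants tighter Monte-Carlo error; stochastic assertions use 3-standard-error
bands around closed-form values. Report rounding: years to 2 decimals,
months to 1, variance fractions to the nearest percent, rates to 1 decimal.
Final bone ages are stored at full precision and rounded only at the report
boundary.

## Known limitations

- The appearance rule's mathematical form is a stand-in contract; no
  attempt is made to reproduce the learned appearance model.
- The sharpness statistic matches the public contract, not the deployed
  implementation; absolute values are comparable only through the (4, 13]
  gates and the 5.75 anchor.
- "Short bones" in gate 4 is interpreted as all tubular bones except radius
  and ulna; a radius-only exclusion would shift the gate marginally for
  near-mature hands.
- The simulator's uniform truth distribution overweights extreme ages
  relative to real referral populations; rates that depend on the age mix
  (e.g. near-maturity gate firings) should not be read as clinical rates.
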