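"""Accuracy and agreement statistics for rating comparisons.

Tools for evaluating an automated rater against human rater panels:

* RMS error (years) and MAD (months) of a set of rating errors.
* Reference construction: the mean of a k-rater panel, whose own error
  about the truth has SD ``sigma_rater / sqrt(k)``.
* Quadrature decomposition: with independent additive errors, the
  observed RMS against a reference splits as
  ``observed^2 = true_accuracy^2 + reference_error^2``, so the method's
  accuracy with respect to the (unobservable) truth is
  ``sqrt(observed^2 - reference_error^2)``.
* Variance fractions: an error SD expressed as a percentage of the
  natural population variance of bone age at fixed age (1.0 y^2).
* Bland-Altman agreement tables and limits of agreement.
* The disputed-case audit: cases where two methods disagree by more than
  a dispute threshold are re-rated by a blinded panel; each method's
  distance to the panel mean decides who was right, and "grave" errors
  (beyond a second threshold from the panel mean) are counted per method.

Rounding conventions for reports: years to 2 decimals, months to 1
decimal, variance fractions to the nearest percent, rates to 1 decimal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd


class DecompositionError(ValueError):
    """Observed RMS smaller than the reference error: quadrature
    subtraction is infeasible (never silently clamped)."""


# --- elementary error metrics ---------------------------------------------

def rms_error(errors: Sequence[float]) -> float:
    """Root-mean-square of rating errors, in years."""
    e = np.asarray(errors, dtype=float)
    if e.size == 0:
        raise ValueError("empty error vector")
    return float(np.sqrt(np.mean(e**2)))


def mad(errors: Sequence[float]) -> float:
    """Mean absolute deviation of rating errors given in years, in months."""
    e = np.asarray(errors, dtype=float)
    if e.size == 0:
        raise ValueError("empty error vector")
    return float(12.0 * np.mean(np.abs(e)))


def panel_reference(ratings: Sequence[float]) -> float:
    """Reference rating: the arithmetic mean of a rater panel."""
    r = np.asarray(ratings, dtype=float)
    if r.size == 0:
        raise ValueError("empty rater panel")
    return float(np.mean(r))


def reference_error_sd(sigma_rater: float, k: int) -> float:
    """SD of a k-rater panel mean about the truth: sigma / sqrt(k)."""
    if k < 1:
        raise ValueError("panel size k must be >= 1")
    if sigma_rater < 0:
        raise ValueError("sigma_rater must be >= 0")
    return sigma_rater / math.sqrt(k)


# --- quadrature decomposition ---------------------------------------------

def true_accuracy(observed_rms: float, reference_error: float) -> float:
    """Method accuracy w.r.t. the truth, from the observed RMS against an
    imperfect reference: sqrt(observed^2 - reference_error^2)."""
    if reference_error < 0 or observed_rms < 0:
        raise ValueError("RMS inputs must be >= 0")
    if observed_rms < reference_error:
        raise DecompositionError(
            f"observed RMS {observed_rms} < reference error {reference_error}"
        )
    return math.sqrt(observed_rms**2 - reference_error**2)


def rater_variability(observed_rms: float, true_acc: float) -> float:
    """Single-rater SD implied by an observed RMS against that rater and a
    known method accuracy: sqrt(observed^2 - true_accuracy^2)."""
    if true_acc < 0 or observed_rms < 0:
        raise ValueError("RMS inputs must be >= 0")
    if observed_rms < true_acc:
        raise DecompositionError(
            f"observed RMS {observed_rms} < true accuracy {true_acc}"
        )
    return math.sqrt(observed_rms**2 - true_acc**2)


def variance_fraction(error_sd: float, natural_sd: float = 1.0) -> float:
    """Error variance as a percentage of the natural bone age variance at
    fixed age (default natural SD 1.0 y)."""
    if natural_sd <= 0:
        raise ValueError("natural_sd must be > 0")
    return 100.0 * error_sd**2 / natural_sd**2


def single_case_sensitivity(
    n: int, rms: float, mad_months: float, err_old: float, err_new: float
) -> tuple[float, float]:
    """Relative change (%) of RMS and MAD when one case's absolute error
    moves from ``err_old`` to ``err_new`` (both in months).

    MAD responds linearly, RMS quadratically, so a single gross error
    moves the RMS far more — the reason RMS is the safer accuracy metric
    for risk assessment.  Returns ``(delta_rms_pct, delta_mad_pct)``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if err_old < 0 or err_new < 0:
        raise ValueError("errors must be >= 0")
    delta_mad = 100.0 * (err_new - err_old) / (n * mad_months)
    if rms == 0.0:
        if err_new != err_old:
            raise ValueError("relative RMS change undefined for rms == 0")
        return 0.0, delta_mad
    new_rms = math.sqrt(rms**2 + (err_new**2 - err_old**2) / (144.0 * n))
    delta_rms = 100.0 * (new_rms / rms - 1.0)
    return delta_rms, delta_mad


# --- report-level rounding helpers ----------------------------------------

def rate_percent(count: int, total: int) -> float:
    """Share of cases as a percentage, 1 decimal (e.g. 59/14036 -> 0.4)."""
    if total < 1:
        raise ValueError("total must be >= 1")
    return round(100.0 * count / total, 1)


def fold_ratio(a: float, b: float) -> int:
    """Ratio between two counts, reported to the nearest integer fold."""
    if b == 0:
        raise ValueError("denominator count is zero")
    return round(a / b)


# --- Bland-Altman -----------------------------------------------------------

def bland_altman(
    auto: Sequence[float], manual: Sequence[float]
) -> tuple[pd.DataFrame, float, tuple[float, float]]:
    """Bland-Altman agreement analysis of two raters.

    Returns a table with per-case ``mean`` (of the two ratings, the
    x-axis) and ``diff`` (auto - manual), the bias (mean difference) and
    the 95% limits of agreement ``bias +- 1.96 * SD(diff)``.
    """
    a = np.asarray(auto, dtype=float)
    m = np.asarray(manual, dtype=float)
    if a.shape != m.shape or a.ndim != 1:
        raise ValueError("auto and manual must be 1-D and equally long")
    if a.size < 2:
        raise ValueError("need at least 2 paired ratings")
    diff = a - m
    table = pd.DataFrame({"mean": (a + m) / 2.0, "diff": diff})
    bias = float(np.mean(diff))
    sd = float(np.std(diff, ddof=1))
    return table, bias, (bias - 1.96 * sd, bias + 1.96 * sd)


# --- cohort-level report ----------------------------------------------------

@dataclass
class AgreementReport:
    """Summary of an automated-vs-reference comparison."""

    n: int
    rms: float  # years, vs the reference
    mad: float  # months, vs the reference
    ref_error: float | None  # years, reference's own error SD
    true_accuracy: float | None  # years, method error vs the truth
    rater_sd: float | None  # years, single-rater SD (panel estimate)
    variance_fraction: float | None  # percent of natural variance
    bias: float  # years, mean(auto - reference)
    loa: tuple[float, float]  # 95% limits of agreement


def agreement_report(
    auto: Sequence[float],
    manual: Sequence[float] | np.ndarray,
    reference_error: float | None = None,
    natural_sd: float = 1.0,
) -> AgreementReport:
    """Full agreement summary of automated ratings against manual ones.

    ``manual`` may be a vector of single ratings or an (n, k) panel; with
    a panel the reference is the per-case panel mean, the single-rater SD
    is estimated from the within-panel scatter, and the reference error
    is that SD over sqrt(k).  An explicit ``reference_error`` overrides
    the panel estimate (use this to reproduce printed decompositions).
    When a reference error is available, the true accuracy and its
    variance fraction are decomposed by quadrature subtraction.
    """
    a = np.asarray(auto, dtype=float)
    m = np.asarray(manual, dtype=float)
    rater_sd = None
    if m.ndim == 2 and m.shape[1] > 1:
        k = m.shape[1]
        rater_sd = float(np.sqrt(np.mean(np.var(m, axis=1, ddof=1))))
        if reference_error is None:
            reference_error = reference_error_sd(rater_sd, k)
        reference = np.mean(m, axis=1)
    else:
        reference = m.reshape(-1)
    errors = a - reference
    _, bias, loa = bland_altman(a, reference)
    rms = rms_error(errors)
    acc = frac = None
    if reference_error is not None:
        acc = true_accuracy(rms, reference_error)
        frac = variance_fraction(acc, natural_sd)
    return AgreementReport(
        n=int(a.size),
        rms=rms,
        mad=mad(errors),
        ref_error=reference_error,
        true_accuracy=acc,
        rater_sd=rater_sd,
        variance_fraction=frac,
        bias=bias,
        loa=loa,
    )


def estimate_true_accuracy(
    auto: Sequence[float],
    panel: np.ndarray,
    n_boot: int = 200,
    seed: int = 0,
) -> dict:
    """Point estimate and bootstrap CI of the method's true accuracy.

    The estimate subtracts the panel mean's own error (within-panel SD
    over sqrt(k)) from the observed RMS in quadrature; the uncertainty is
    a case-resampling bootstrap (percentile 95% CI and SE).
    """
    a = np.asarray(auto, dtype=float)
    p = np.asarray(panel, dtype=float)
    if p.ndim != 2 or p.shape[0] != a.size or p.shape[1] < 2:
        raise ValueError("panel must be (n_cases, k>=2)")

    def _estimate(a_s: np.ndarray, p_s: np.ndarray) -> float:
        k = p_s.shape[1]
        rater_sd = np.sqrt(np.mean(np.var(p_s, axis=1, ddof=1)))
        obs = np.sqrt(np.mean((a_s - np.mean(p_s, axis=1)) ** 2))
        return math.sqrt(max(obs**2 - rater_sd**2 / k, 0.0))

    est = _estimate(a, p)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, a.size, a.size)
        boots[b] = _estimate(a[idx], p[idx])
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return {
        "estimate": est,
        "se": float(np.std(boots, ddof=1)),
        "ci_low": float(lo),
        "ci_high": float(hi),
        "n_boot": n_boot,
    }


# --- disputed cases ----------------------------------------------------------

@dataclass
class DisputedAnalysis:
    """Outcome of a blinded re-rating audit of disagreeing cases."""

    dispute_threshold: float  # years
    grave_threshold: float  # years
    n_total: int
    n_disputed: int
    n_auto_closer: int
    n_manual_grave: int
    n_auto_grave: int

    @property
    def disputed_rate_percent(self) -> float:
        return rate_percent(self.n_disputed, self.n_total)

    @property
    def grave_fold(self) -> int:
        return fold_ratio(self.n_manual_grave, self.n_auto_grave)


def disputed_case_analysis(
    auto: Sequence[float],
    manual: Sequence[float],
    panel: np.ndarray,
    dispute_threshold: float = 1.8,
    grave_threshold: float = 1.5,
) -> DisputedAnalysis:
    """Audit the cases where automated and manual ratings disagree.

    Cases with ``|auto - manual| > dispute_threshold`` are the disputed
    cases; for each, the mean of the blinded re-rating panel is the
    reference.  A method is "closer" when its distance to the reference
    is strictly smaller than the other's; a "grave" error deviates from
    the reference by more than ``grave_threshold``.  The analysis treats
    both methods on an equal footing: swapping the two rating columns
    swaps the output counts.

    ``panel`` is an (n, k) array of re-ratings; rows may be NaN for
    non-disputed cases, but every disputed case must have a complete
    panel.
    """
    a = np.asarray(auto, dtype=float)
    m = np.asarray(manual, dtype=float)
    p = np.asarray(panel, dtype=float)
    if a.shape != m.shape or a.ndim != 1 or p.shape[0] != a.size or p.ndim != 2:
        raise ValueError("auto, manual must be 1-D; panel must be (n, k)")
    disputed = np.abs(a - m) > dispute_threshold
    if np.isnan(p[disputed]).any():
        raise ValueError("missing re-rating panel for a disputed case")
    ref = np.mean(p[disputed], axis=1)
    d_auto = np.abs(a[disputed] - ref)
    d_manual = np.abs(m[disputed] - ref)
    return DisputedAnalysis(
        dispute_threshold=dispute_threshold,
        grave_threshold=grave_threshold,
        n_total=int(a.size),
        n_disputed=int(disputed.sum()),
        n_auto_closer=int(np.sum(d_auto < d_manual)),
        n_manual_grave=int(np.sum(d_manual > grave_threshold)),
        n_auto_grave=int(np.sum(d_auto > grave_threshold)),
    )
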