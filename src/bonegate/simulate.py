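"""Synthetic cohorts, bone sets and edge-test images.

No study data ship with this package; instead the simulator reproduces the
statistical structure the evaluations assume: true bone ages spread over
the paediatric range, an automated method whose error about the truth is
additive Gaussian (reference SD 0.33 y), human raters with a larger SD
(0.52 y for careful hospital raters, 0.68 y for the challenge panel), a
rare gross-error contamination of manual ratings producing fat tails, 21
per-bone estimates scattered around the case truth with occasional
anomalous bones, and radiograph-like test images with controllable blur
and edge enhancement.

Reproducibility: one spawned RNG stream per case, so a cohort is bitwise
reproducible under its seed and individual cases do not depend on the
order in which they are drawn.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from skimage.filters import gaussian as _gaussian_filter

from .validation import BONE_ROSTER, BoneAssessment

#: Observed bone age ranges: 0-17 y for males, 0-15 y for females.
DEFAULT_TRUTH_RANGE = {"male": (0.0, 17.0), "female": (0.0, 15.0)}


@dataclass(frozen=True)
class SimulationSpec:
    """Generative parameters for a synthetic cohort.

    Parameters
    ----------
    n_cases
        Number of cases (images) to simulate.
    truth_distribution
        ``("uniform", lo, hi)`` in years, or None for the sex-specific
        default uniform ranges (0-17 y male, 0-15 y female).
    sigma_auto
        SD of the automated method's error about the truth (years).
    sigma_rater
        SD of a single manual rating about the truth (years).
    n_raters
        Number of independent manual ratings per case.
    bone_sd
        SD of a single bone's estimate about the case truth (years).
    anomaly_rate
        Probability that a bone is anomalous: its appearance score is
        drawn from U(0.7, 1) and its bone age receives an extra
        N(0, 3*bone_sd) shift.
    gross_error_rate, gross_error_sd
        Contamination mixture for manual ratings: with this probability a
        rating's error is drawn from N(0, gross_error_sd) instead of
        N(0, sigma_rater), producing the fat tails seen in real manual
        rating audits.
    seed
        Fixes every output exactly.
    """

    n_cases: int = 1000
    truth_distribution: tuple | None = None
    sigma_auto: float = 0.33
    sigma_rater: float = 0.52
    n_raters: int = 1
    bone_sd: float = 0.5
    anomaly_rate: float = 0.02
    gross_error_rate: float = 0.01
    gross_error_sd: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sigma_auto", "sigma_rater", "bone_sd", "gross_error_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("anomaly_rate", "gross_error_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_cases < 1 or self.n_raters < 1:
            raise ValueError("n_cases and n_raters must be >= 1")
        if self.truth_distribution is not None:
            kind, lo, hi = self.truth_distribution
            if kind != "uniform" or not lo <= hi:
                raise ValueError(
                    "truth_distribution must be ('uniform', lo, hi) with lo <= hi"
                )


@dataclass
class SimulatedCase:
    image_id: str
    true_ba: float
    sex: str
    auto_ba: float
    manual_ratings: list[float]
    bones: list[BoneAssessment] = field(default_factory=list)


def _draw_truth(spec: SimulationSpec, sex: str, rng: np.random.Generator) -> float:
    if spec.truth_distribution is not None:
        _, lo, hi = spec.truth_distribution
    else:
        lo, hi = DEFAULT_TRUTH_RANGE[sex]
    return float(rng.uniform(lo, hi))


def simulate_bone_set(
    true_ba: float,
    spec: SimulationSpec,
    rng: np.random.Generator | int | None = None,
) -> list[BoneAssessment]:
    """Draw the 21 per-bone assessments of one case.

    The 21 tubular bones mature under the same endocrine control, so each
    bone's estimate scatters around the case truth with SD ``bone_sd``
    (truncated at 0: no negative maturity).  Anomalous bones (probability
    ``anomaly_rate``) carry a high appearance score and an extra bone-age
    shift, emulating malformed, occluded or wrongly posed bones.
    """
    if true_ba < 0:
        raise ValueError("true_ba must be >= 0")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(spec.seed if rng is None else rng)
    bones = []
    for bone_id in BONE_ROSTER:
        anomalous = rng.random() < spec.anomaly_rate
        age = true_ba + rng.normal(0.0, spec.bone_sd) if spec.bone_sd else true_ba
        if anomalous:
            if spec.bone_sd:
                age += rng.normal(0.0, 3.0 * spec.bone_sd)
            score = rng.uniform(0.7, 1.0)
        else:
            score = rng.uniform(0.0, 0.3)
        bones.append(
            BoneAssessment(
                bone_id=bone_id,
                bone_age=max(0.0, float(age)),
                appearance_score=float(score),
            )
        )
    return bones


def simulate_cohort(
    spec: SimulationSpec, with_bones: bool = True
) -> list[SimulatedCase]:
    """Generate a synthetic cohort of rated cases.

    Per case: truth from the truth distribution; automated rating
    ``truth + N(0, sigma_auto)``; each of ``n_raters`` manual ratings
    ``truth + N(0, sigma_rater)``, replaced with probability
    ``gross_error_rate`` by ``truth + N(0, gross_error_sd)``.  Ratings are
    not truncated: the additive error model is kept exact so that
    variance-addition identities hold.  Set ``with_bones=False`` to skip
    the per-bone simulation when only case-level ratings are needed.
    """
    root = np.random.SeedSequence(spec.seed)
    cases: list[SimulatedCase] = []
    for i, child in enumerate(root.spawn(spec.n_cases)):
        rng = np.random.default_rng(child)
        sex = "male" if rng.random() < 0.5 else "female"
        truth = _draw_truth(spec, sex, rng)
        auto = truth + rng.normal(0.0, spec.sigma_auto)
        ratings = []
        for _ in range(spec.n_raters):
            if rng.random() < spec.gross_error_rate:
                ratings.append(truth + rng.normal(0.0, spec.gross_error_sd))
            else:
                ratings.append(truth + rng.normal(0.0, spec.sigma_rater))
        bones = simulate_bone_set(truth, spec, rng) if with_bones else []
        cases.append(
            SimulatedCase(
                image_id=f"case_{i:05d}",
                true_ba=truth,
                sex=sex,
                auto_ba=float(auto),
                manual_ratings=[float(r) for r in ratings],
                bones=bones,
            )
        )
    return cases


def cohort_to_frame(cases: Sequence[SimulatedCase]) -> pd.DataFrame:
    """Case-level table: image_id, sex, true_ba, auto_ba, rating_1..k."""
    k = len(cases[0].manual_ratings) if cases else 0
    rows = []
    for c in cases:
        row = {
            "image_id": c.image_id,
            "sex": c.sex,
            "true_ba": c.true_ba,
            "auto_ba": c.auto_ba,
        }
        row.update({f"rating_{j + 1}": r for j, r in enumerate(c.manual_ratings)})
        rows.append(row)
    columns = ["image_id", "sex", "true_ba", "auto_ba"] + [
        f"rating_{j + 1}" for j in range(k)
    ]
    return pd.DataFrame(rows, columns=columns)


def bone_table(cases: Sequence[SimulatedCase]) -> pd.DataFrame:
    """Per-bone table in the case-table schema consumed by validation."""
    rows = [
        {
            "image_id": c.image_id,
            "sex": c.sex,
            "bone_id": b.bone_id,
            "bone_age_y": b.bone_age,
            "appearance_score": b.appearance_score,
        }
        for c in cases
        for b in c.bones
    ]
    return pd.DataFrame(
        rows,
        columns=["image_id", "sex", "bone_id", "bone_age_y", "appearance_score"],
    )


# --- synthetic edge-test images -------------------------------------------

_IMAGE_SIZE = 320  # pixels
_BAND_EDGES_PX = [(64.5, 94.5), (144.5, 174.5), (224.5, 254.5)]
_BACKGROUND = 50.0
_BAND_INTENSITY = 200.0
_UNSHARP_SIGMA_MM = 0.6


def simulate_edge_image(
    blur_sigma_mm: float = 0.6,
    enhance_gain: float = 0.0,
    contrast_a: float = 1.0,
    contrast_b: float = 0.0,
    seed: int = 0,
    pixel_spacing_mm: float = 0.1,
    noise: bool = True,
) -> tuple[np.ndarray, list[tuple[float, float, float, float]]]:
    """Render a radiograph-like test image for the sharpness metric.

    Three vertical bright bands stand in for the middle metacarpals on a
    darker background.  Poisson noise emulates quantum mottle; the image
    is then Gaussian-blurred (``blur_sigma_mm``, the acquisition blur),
    optionally unsharp-masked with overshoot ``enhance_gain`` (emulating
    aggressive post-processing), and finally mapped through
    ``contrast_a * I + contrast_b``.

    Returns the float image and ROI segments running along both shaft
    edges of each band (six segments), as consumed by
    :func:`bonegate.sharpness.image_sharpness`.
    """
    if blur_sigma_mm < 0:
        raise ValueError("blur_sigma_mm must be >= 0")
    rng = np.random.default_rng(seed)
    img = np.full((_IMAGE_SIZE, _IMAGE_SIZE), _BACKGROUND)
    for left, right in _BAND_EDGES_PX:
        img[:, int(np.ceil(left)) : int(np.ceil(right))] = _BAND_INTENSITY
    if noise:
        img = rng.poisson(img).astype(float)
    if blur_sigma_mm > 0:
        img = _gaussian_filter(
            img, sigma=blur_sigma_mm / pixel_spacing_mm, preserve_range=True
        )
    if enhance_gain > 0:
        smooth = _gaussian_filter(
            img, sigma=_UNSHARP_SIGMA_MM / pixel_spacing_mm, preserve_range=True
        )
        # display pipelines clip the boosted image to the original range
        img = np.clip(img + enhance_gain * (img - smooth), img.min(), img.max())
    img = contrast_a * img + contrast_b

    y0, y1 = 100.0, 220.0
    rois = [
        (x, y0, x, y1) for left, right in _BAND_EDGES_PX for x in (left, right)
    ]
    return img, rois
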