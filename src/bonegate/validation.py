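"""Self-validation cascade for automated bone age assessment.

The cascade mirrors the quality-control architecture of an automated hand
radiograph method.  Six steps: the first two validate individual bone
contributions (appearance, deviation from the consensus bone age), the last
four validate the entire image (minimum bone count, sharpness window,
radius availability near maturity).

Per-bone bone ages come from up to 21 tubular bones; the consensus is their
mean over accepted bones.  All thresholds live in :class:`ValidationConfig`
and default to the clinically deployed values.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

logger = logging.getLogger("bonegate.validation")

#: Fixed roster of the 21 tubular bones of the hand and wrist, in canonical
#: order.  Metacarpals 1-5, proximal phalanges 1-5, middle phalanges 2-4
#: plus 5 (the thumb has no middle phalanx), distal phalanges 1-5.
BONE_ROSTER: tuple[str, ...] = (
    "radius",
    "ulna",
    "metacarpal_1",
    "metacarpal_2",
    "metacarpal_3",
    "metacarpal_4",
    "metacarpal_5",
    "proximal_phalanx_1",
    "proximal_phalanx_2",
    "proximal_phalanx_3",
    "proximal_phalanx_4",
    "proximal_phalanx_5",
    "middle_phalanx_2",
    "middle_phalanx_3",
    "middle_phalanx_4",
    "middle_phalanx_5",
    "distal_phalanx_1",
    "distal_phalanx_2",
    "distal_phalanx_3",
    "distal_phalanx_4",
    "distal_phalanx_5",
)

_ROSTER_INDEX = {b: i for i, b in enumerate(BONE_ROSTER)}

#: Long bones excluded from the "short bones" used by the maturity gate.
LONG_BONES = frozenset({"radius", "ulna"})

STATUSES = (
    "accepted",
    "hand_not_found",
    "too_sharp",
    "too_blurred",
    "no_radius_mature",
    "accepted_with_warning",
)

REJECTION_REASONS = ("none", "appearance", "deviation")


class ValidationError(ValueError):
    """Invalid input to the validation cascade."""


class NoAcceptedBonesError(ValidationError):
    """Deviation validation called with no appearance-accepted bones."""


class MissingSharpnessError(ValidationError):
    """Sharpness gates enabled but no sharpness value supplied."""


@dataclass(frozen=True)
class BoneAssessment:
    """One tubular bone's contribution to the image-level bone age.

    Parameters
    ----------
    bone_id
        Identifier from :data:`BONE_ROSTER`.
    bone_age
        Estimated bone age of this bone in years (>= 0).
    appearance_score
        Anomaly score in [0, 1]; higher means the bone's shape or density
        distribution looks more unlike a normally maturing bone.
    accepted
        Whether the bone currently contributes to the consensus.
    rejection_reason
        "none", "appearance" or "deviation"; "none" iff ``accepted``.
    """

    bone_id: str
    bone_age: float
    appearance_score: float = 0.0
    accepted: bool = True
    rejection_reason: str = "none"

    def __post_init__(self) -> None:
        if self.bone_id not in _ROSTER_INDEX:
            raise ValidationError(f"unknown bone_id {self.bone_id!r}")
        if not math.isfinite(self.bone_age) or self.bone_age < 0:
            raise ValidationError(
                f"bone_age must be finite and >= 0, got {self.bone_age!r} "
                f"for {self.bone_id}"
            )
        if self.rejection_reason not in REJECTION_REASONS:
            raise ValidationError(
                f"invalid rejection_reason {self.rejection_reason!r}"
            )
        if (self.rejection_reason == "none") != self.accepted:
            raise ValidationError(
                "rejection_reason must be 'none' iff the bone is accepted"
            )

    @property
    def roster_index(self) -> int:
        return _ROSTER_INDEX[self.bone_id]


@dataclass
class ImageAssessment:
    """A fully or partially validated case (one hand radiograph)."""

    image_id: str
    sex: str
    bones: list[BoneAssessment]
    sharpness: float | None = None
    status: str = "accepted"
    final_bone_age: float | None = None

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValidationError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if self.status not in STATUSES:
            raise ValidationError(f"invalid status {self.status!r}")
        ids = [b.bone_id for b in self.bones]
        if len(ids) != len(set(ids)):
            raise ValidationError(f"duplicate bone_id in image {self.image_id!r}")

    @property
    def accepted_bones(self) -> list[BoneAssessment]:
        return [b for b in self.bones if b.accepted]


@dataclass
class ValidationConfig:
    """All thresholds of the self-validation cascade.

    Defaults are the deployed clinical values: the deviation threshold is
    2.4 y at and above a consensus of 7 y, ramping linearly down to 1.2 y
    at birth; at least 8 accepted bones are required; the sharpness window
    is (4, 13]; near maturity (above 17 y for boys, 15 y for girls in the
    short bones) the radius must be among the accepted bones.
    """

    dev_threshold_high: float = 2.4  # years, plateau above ramp_end
    dev_threshold_birth: float = 1.2  # years, at consensus 0
    ramp_end: float = 7.0  # years
    min_bones: int = 8
    sharp_max: float = 13.0
    sharp_min: float = 4.0
    mature_ba_male: float = 17.0  # years
    mature_ba_female: float = 15.0  # years
    appearance_threshold: float = 0.5
    bypass_quality_gates: bool = False
    # "iterative": worst-first leave-one-out removal, recomputed each round.
    # "single_pass": one sweep against the contaminated grand mean.
    deviation_mode: str = "iterative"

    def __post_init__(self) -> None:
        if self.dev_threshold_birth > self.dev_threshold_high:
            raise ValidationError("dev_threshold_birth must be <= dev_threshold_high")
        if self.sharp_min >= self.sharp_max:
            raise ValidationError("sharp_min must be < sharp_max")
        if self.min_bones < 1:
            raise ValidationError("min_bones must be >= 1")
        if self.deviation_mode not in ("iterative", "single_pass"):
            raise ValidationError(f"invalid deviation_mode {self.deviation_mode!r}")

    def mature_ba(self, sex: str) -> float:
        return self.mature_ba_male if sex == "male" else self.mature_ba_female


def deviation_threshold(
    consensus_ba: float, config: ValidationConfig | None = None
) -> float:
    """Maximum allowed deviation of a bone from the consensus bone age.

    Piecewise linear: ``dev_threshold_high`` at and above ``ramp_end``,
    decreasing linearly to ``dev_threshold_birth`` at birth.  Continuous
    and non-decreasing in the consensus.
    """
    config = config or ValidationConfig()
    if not math.isfinite(consensus_ba) or consensus_ba < 0:
        raise ValidationError(
            f"consensus bone age must be finite and >= 0, got {consensus_ba!r}"
        )
    if consensus_ba >= config.ramp_end:
        return config.dev_threshold_high
    slope = (config.dev_threshold_high - config.dev_threshold_birth) / config.ramp_end
    return config.dev_threshold_birth + slope * consensus_ba


def reject_by_appearance(
    bones: Iterable[BoneAssessment], config: ValidationConfig | None = None
) -> list[BoneAssessment]:
    """Step A: reject bones whose appearance score exceeds the threshold.

    A bone whose shape or density distribution is at odds with normal
    maturation carries a high anomaly score; scores strictly above
    ``appearance_threshold`` are rejected.  Already-rejected bones are
    left untouched.
    """
    config = config or ValidationConfig()
    out: list[BoneAssessment] = []
    for bone in bones:
        if not (0.0 <= bone.appearance_score <= 1.0):
            raise ValidationError(
                f"appearance_score must be in [0, 1], got "
                f"{bone.appearance_score!r} for {bone.bone_id}"
            )
        if bone.accepted and bone.appearance_score > config.appearance_threshold:
            logger.info(
                "bone %s rejected: appearance score %.3f > threshold %.3f",
                bone.bone_id,
                bone.appearance_score,
                config.appearance_threshold,
            )
            bone = replace(bone, accepted=False, rejection_reason="appearance")
        out.append(bone)
    return out


def _loo_means(ages: Sequence[float]) -> list[float]:
    total = sum(ages)
    n = len(ages)
    return [(total - a) / (n - 1) for a in ages]


def reject_by_deviation(
    bones: Iterable[BoneAssessment], config: ValidationConfig | None = None
) -> tuple[list[BoneAssessment], float]:
    """Step B: reject bones deviating too far from the consensus bone age.

    Default mode is iterative worst-first removal: in each round the
    leave-one-out mean of the currently accepted bones is computed for
    every accepted bone; the bone with the largest absolute deviation from
    its leave-one-out mean is rejected if that deviation exceeds
    :func:`deviation_threshold` evaluated at the leave-one-out mean.
    Repeats until no bone exceeds its threshold or only two bones remain.
    Ties break on roster order.  Deterministic and idempotent.

    ``single_pass`` mode instead sweeps once against the grand mean of all
    appearance-accepted bones (which still contains any outliers).

    Returns the updated bone list and the consensus (mean over accepted).
    """
    config = config or ValidationConfig()
    bones = list(bones)
    active = {b.bone_id for b in bones if b.accepted}
    if not active:
        raise NoAcceptedBonesError("no accepted bones to compute a consensus from")

    by_id = {b.bone_id: b for b in bones}

    def _reject(bone_id: str, dev: float, thr: float) -> None:
        logger.info(
            "bone %s rejected: deviation %.3f y > threshold %.3f y",
            bone_id,
            dev,
            thr,
        )
        by_id[bone_id] = replace(
            by_id[bone_id], accepted=False, rejection_reason="deviation"
        )
        active.discard(bone_id)

    if config.deviation_mode == "single_pass":
        ages = [by_id[i].bone_age for i in active]
        grand_mean = sum(ages) / len(ages)
        thr = deviation_threshold(grand_mean, config)
        for bone_id in sorted(active, key=lambda i: _ROSTER_INDEX[i]):
            dev = abs(by_id[bone_id].bone_age - grand_mean)
            if dev > thr:
                _reject(bone_id, dev, thr)
    else:
        while len(active) > 2:
            ordered = sorted(active, key=lambda i: _ROSTER_INDEX[i])
            ages = [by_id[i].bone_age for i in ordered]
            loo = _loo_means(ages)
            devs = [abs(a - m) for a, m in zip(ages, loo)]
            worst = max(range(len(ordered)), key=lambda k: (devs[k], -k))
            thr = deviation_threshold(loo[worst], config)
            if devs[worst] > thr:
                _reject(ordered[worst], devs[worst], thr)
            else:
                break

    consensus = sum(by_id[i].bone_age for i in active) / len(active)
    return [by_id[b.bone_id] for b in bones], consensus


def gate_image(
    assessment: ImageAssessment, config: ValidationConfig | None = None
) -> ImageAssessment:
    """Apply the four image-level gates, in order.

    1. Fewer than ``min_bones`` accepted bones -> ``hand_not_found``
       (never bypassable: too few bones means no reliable consensus).
    2. Sharpness above ``sharp_max`` -> ``too_sharp`` (excessive edge
       enhancement by image post-processing).
    3. Sharpness below ``sharp_min`` -> ``too_blurred``.
    4. Mean bone age of the accepted short bones (all tubular bones except
       radius and ulna) above the sex-specific maturity limit while the
       radius is rejected -> ``no_radius_mature`` (the radius is the only
       bone still maturing at those ages).

    With ``bypass_quality_gates`` set, gates 2-4 downgrade to
    ``accepted_with_warning`` instead of rejecting.  On acceptance the
    final bone age is the mean over all accepted tubular bones.
    """
    config = config or ValidationConfig()
    accepted = assessment.accepted_bones
    status = "accepted"

    if len(accepted) < config.min_bones:
        logger.info(
            "image %s rejected: %d accepted bones < minimum %d",
            assessment.image_id,
            len(accepted),
            config.min_bones,
        )
        return replace(assessment, status="hand_not_found", final_bone_age=None)

    def _soft_reject(new_status: str, msg: str, *args) -> str | None:
        if config.bypass_quality_gates:
            logger.warning("image %s bypassed gate: " + msg, assessment.image_id, *args)
            return "accepted_with_warning"
        logger.info("image %s rejected: " + msg, assessment.image_id, *args)
        return None

    if assessment.sharpness is None:
        if not config.bypass_quality_gates:
            raise MissingSharpnessError(
                f"image {assessment.image_id!r}: sharpness required while "
                "sharpness gates are enabled"
            )
    else:
        if assessment.sharpness > config.sharp_max:
            s = _soft_reject(
                "too_sharp", "sharpness %.2f > %.2f", assessment.sharpness,
                config.sharp_max,
            )
            if s is None:
                return replace(assessment, status="too_sharp", final_bone_age=None)
            status = s
        elif assessment.sharpness < config.sharp_min:
            s = _soft_reject(
                "too_blurred", "sharpness %.2f < %.2f", assessment.sharpness,
                config.sharp_min,
            )
            if s is None:
                return replace(assessment, status="too_blurred", final_bone_age=None)
            status = s

    short = [b for b in accepted if b.bone_id not in LONG_BONES]
    radius_ok = any(b.bone_id == "radius" for b in accepted)
    limit = config.mature_ba(assessment.sex)
    if short and not radius_ok:
        short_mean = sum(b.bone_age for b in short) / len(short)
        if short_mean > limit:
            s = _soft_reject(
                "no_radius_mature",
                "short-bone mean %.2f y > %.1f y with radius rejected",
                short_mean,
                limit,
            )
            if s is None:
                return replace(
                    assessment, status="no_radius_mature", final_bone_age=None
                )
            status = s

    final = sum(b.bone_age for b in accepted) / len(accepted)
    return replace(assessment, status=status, final_bone_age=final)


def run_cascade(
    bones: Iterable[BoneAssessment],
    sharpness: float | None,
    sex: str,
    config: ValidationConfig | None = None,
    image_id: str = "",
) -> ImageAssessment:
    """Run the full six-step self-validation on one image.

    Composition of :func:`reject_by_appearance`, :func:`reject_by_deviation`
    and :func:`gate_image`.  Bone input order never affects the result:
    bones are canonically sorted by roster order first.  If every bone is
    rejected at the appearance step the image is ``hand_not_found``.
    """
    config = config or ValidationConfig()
    bones = sorted(bones, key=lambda b: b.roster_index)
    if not bones:
        raise ValidationError("at least one bone must be supplied")
    ids = [b.bone_id for b in bones]
    if len(ids) != len(set(ids)):
        raise ValidationError("duplicate bone_id in input")

    bones = reject_by_appearance(bones, config)
    try:
        bones, _ = reject_by_deviation(bones, config)
    except NoAcceptedBonesError:
        return ImageAssessment(
            image_id=image_id,
            sex=sex,
            bones=bones,
            sharpness=sharpness,
            status="hand_not_found",
            final_bone_age=None,
        )
    assessment = ImageAssessment(
        image_id=image_id, sex=sex, bones=bones, sharpness=sharpness
    )
    return gate_image(assessment, config)
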