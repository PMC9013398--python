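"""Self-validation cascade: per-bone rejection rules and image gates."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from bonegate import (
    BONE_ROSTER,
    BoneAssessment,
    ImageAssessment,
    ValidationConfig,
    deviation_threshold,
    gate_image,
    reject_by_appearance,
    reject_by_deviation,
    run_cascade,
)
from bonegate.validation import (
    NoAcceptedBonesError,
    MissingSharpnessError,
    ValidationError,
)

from conftest import make_bones


class TestDeviationThreshold:
    @pytest.mark.parametrize(
        "consensus, expected",
        [
            (0.0, 1.2),  # at birth
            (7.0, 2.4),  # ramp end
            (12.0, 2.4),  # plateau
            (3.5, 1.8),  # midpoint of the linear ramp
        ],
    )
    def test_printed_endpoints_and_interpolation(self, consensus, expected):
        assert deviation_threshold(consensus) == pytest.approx(expected)

    @pytest.mark.parametrize("bad", [-0.1, float("nan"), float("inf")])
    def test_invalid_consensus_rejected(self, bad):
        with pytest.raises(ValidationError):
            deviation_threshold(bad)

    @given(st.floats(min_value=0.0, max_value=25.0))
    def test_piecewise_linear_monotone_bounded(self, ba):
        cfg = ValidationConfig()
        t = deviation_threshold(ba, cfg)
        assert cfg.dev_threshold_birth <= t <= cfg.dev_threshold_high
        # non-decreasing
        assert deviation_threshold(min(ba + 0.5, 25.0), cfg) >= t - 1e-12
        # linear below the ramp end: slope matches the endpoint chord
        if ba < cfg.ramp_end:
            chord = cfg.dev_threshold_birth + (
                cfg.dev_threshold_high - cfg.dev_threshold_birth
            ) * ba / cfg.ramp_end
            assert t == pytest.approx(chord)


class TestAppearanceRejection:
    def test_no_anomaly_keeps_all(self):
        bones = reject_by_appearance(make_bones([10.0] * 21))
        assert all(b.accepted for b in bones)

    def test_single_high_score_rejected(self):
        scores = [0.1] * 21
        scores[4] = 0.9
        bones = reject_by_appearance(make_bones([10.0] * 21, scores))
        rejected = [b for b in bones if not b.accepted]
        assert [b.bone_id for b in rejected] == [BONE_ROSTER[4]]
        assert rejected[0].rejection_reason == "appearance"

    def test_score_exactly_at_threshold_is_kept(self):
        bones = reject_by_appearance(make_bones([10.0] * 5, [0.5] * 5))
        assert all(b.accepted for b in bones)

    def test_score_outside_unit_interval_rejected(self):
        bones = make_bones([10.0] * 3, [1.5, 0.0, 0.0])
        with pytest.raises(ValidationError):
            reject_by_appearance(bones)


class TestDeviationRejection:
    def test_identical_ages_keep_everything(self):
        bones, consensus = reject_by_deviation(make_bones([10.0] * 21))
        assert all(b.accepted for b in bones)
        assert consensus == pytest.approx(10.0)

    def test_outlier_beyond_plateau_threshold_rejected(self):
        # leave-one-out mean 10.0, deviation 3.0 > 2.4
        bones, consensus = reject_by_deviation(make_bones([10.0] * 20 + [13.0]))
        assert [b.bone_id for b in bones if not b.accepted] == [BONE_ROSTER[20]]
        assert bones[-1].rejection_reason == "deviation"
        assert consensus == pytest.approx(10.0)

    def test_deviation_within_threshold_kept(self):
        bones, consensus = reject_by_deviation(make_bones([10.0] * 20 + [12.0]))
        assert all(b.accepted for b in bones)
        assert consensus == pytest.approx((20 * 10.0 + 12.0) / 21)

    def test_ramp_lowers_threshold_at_young_ages(self):
        # at consensus 1.0 the threshold is 1.2 + 1.2/7 ~ 1.371 < 1.5
        bones, _ = reject_by_deviation(make_bones([1.0] * 10 + [2.5]))
        assert [b.bone_id for b in bones if not b.accepted] == [BONE_ROSTER[10]]

    def test_no_accepted_bones_is_an_error(self):
        bones = reject_by_appearance(make_bones([10.0] * 3, [0.9] * 3))
        with pytest.raises(NoAcceptedBonesError):
            reject_by_deviation(bones)

    def test_idempotent(self):
        bones, c1 = reject_by_deviation(
            make_bones([10.0] * 15 + [13.0, 14.0, 9.0, 10.5, 8.0, 12.9])
        )
        again, c2 = reject_by_deviation(bones)
        assert again == bones
        assert c1 == c2

    def test_single_pass_mode_uses_contaminated_grand_mean(self):
        # two opposite outliers inflate nothing in the grand mean but are
        # both caught; a borderline bone close to the grand mean survives
        cfg = ValidationConfig(deviation_mode="single_pass")
        ages = [10.0] * 10 + [14.0, 6.0]
        bones, consensus = reject_by_deviation(make_bones(ages), cfg)
        rejected = {b.bone_id for b in bones if not b.accepted}
        assert rejected == {BONE_ROSTER[10], BONE_ROSTER[11]}
        assert consensus == pytest.approx(10.0)

    def test_minimum_two_bones_survive(self):
        bones, _ = reject_by_deviation(make_bones([0.0, 19.0]))
        assert all(b.accepted for b in bones)


def _rule_b_fixed_points(ages, cfg):
    """All accept-subsets (>=2 bones) stable under one worst-first round."""
    n = len(ages)
    fixed = []
    for r in range(2, n + 1):
        for subset in itertools.combinations(range(n), r):
            sub_ages = [ages[i] for i in subset]
            total = sum(sub_ages)
            if len(subset) <= 2:
                fixed.append(frozenset(subset))
                continue
            devs = [
                abs(a - (total - a) / (r - 1)) for a in sub_ages
            ]
            worst = max(range(r), key=lambda k: (devs[k], -k))
            loo = (total - sub_ages[worst]) / (r - 1)
            if devs[worst] <= deviation_threshold(max(loo, 0.0), cfg):
                fixed.append(frozenset(subset))
    return fixed


@given(
    st.lists(
        st.floats(min_value=0.0, max_value=19.0), min_size=2, max_size=6
    )
)
def test_cascade_subset_matches_brute_force_fixed_points(ages):
    """The iterative cascade must land on a rule-B fixed point found by
    exhaustive subset enumeration."""
    cfg = ValidationConfig()
    bones, _ = reject_by_deviation(make_bones(ages), cfg)
    survivors = frozenset(
        i for i, b in enumerate(bones) if b.accepted
    )
    assert survivors in _rule_b_fixed_points(ages, cfg)


class TestGateImage:
    def _assessment(self, bones, sharpness=5.5, sex="male"):
        return ImageAssessment(
            image_id="img", sex=sex, bones=bones, sharpness=sharpness
        )

    def test_too_few_bones_is_hand_not_found(self, config):
        out = gate_image(self._assessment(make_bones([10.0] * 7)))
        assert out.status == "hand_not_found"
        assert out.final_bone_age is None

    def test_hand_not_found_is_never_bypassable(self):
        cfg = ValidationConfig(bypass_quality_gates=True)
        out = gate_image(self._assessment(make_bones([10.0] * 7)), cfg)
        assert out.status == "hand_not_found"

    @pytest.mark.parametrize(
        "sharpness, status", [(14.0, "too_sharp"), (3.0, "too_blurred")]
    )
    def test_sharpness_window(self, sharpness, status):
        out = gate_image(self._assessment(make_bones([10.0] * 21), sharpness))
        assert out.status == status
        assert out.final_bone_age is None

    @pytest.mark.parametrize("sharpness", [13.0, 4.0, 5.5])
    def test_values_at_gate_boundaries_accepted(self, sharpness):
        out = gate_image(self._assessment(make_bones([10.0] * 21), sharpness))
        assert out.status == "accepted"

    def test_bypass_downgrades_to_warning(self):
        cfg = ValidationConfig(bypass_quality_gates=True)
        out = gate_image(self._assessment(make_bones([10.0] * 21), 14.0), cfg)
        assert out.status == "accepted_with_warning"
        assert out.final_bone_age == pytest.approx(10.0)

    def test_mature_without_radius_rejected(self):
        bones = make_bones([17.5] * 21)
        bones[0] = BoneAssessment(
            "radius", 17.5, 0.9, accepted=False, rejection_reason="appearance"
        )
        out = gate_image(self._assessment(bones, sex="male"))
        assert out.status == "no_radius_mature"

    def test_mature_with_radius_accepted(self):
        out = gate_image(
            self._assessment(make_bones([15.5] * 21), sex="female")
        )
        assert out.status == "accepted"

    def test_female_maturity_limit_lower(self):
        bones = make_bones([15.5] * 21)
        bones[0] = BoneAssessment(
            "radius", 15.5, 0.9, accepted=False, rejection_reason="appearance"
        )
        assert gate_image(self._assessment(bones, sex="female")).status == \
            "no_radius_mature"
        assert gate_image(self._assessment(bones, sex="male")).status == \
            "accepted"

    def test_missing_sharpness_errors_unless_bypassed(self):
        with pytest.raises(MissingSharpnessError):
            gate_image(self._assessment(make_bones([10.0] * 21), None))
        cfg = ValidationConfig(bypass_quality_gates=True)
        out = gate_image(self._assessment(make_bones([10.0] * 21), None), cfg)
        assert out.status == "accepted"


class TestRunCascade:
    def test_clean_image_accepted(self):
        out = run_cascade(make_bones([8.0] * 21), 5.5, "male")
        assert out.status == "accepted"
        assert out.final_bone_age == pytest.approx(8.0)
        assert len(out.accepted_bones) == 21

    def test_survives_with_nine_clean_bones(self):
        scores = [0.0] * 9 + [1.0] * 12
        out = run_cascade(make_bones([8.0] * 21, scores), 5.5, "male")
        assert out.status == "accepted"
        assert len(out.accepted_bones) == 9

    def test_seven_clean_bones_is_hand_not_found(self):
        scores = [0.0] * 7 + [1.0] * 14
        out = run_cascade(make_bones([8.0] * 21, scores), 5.5, "male")
        assert out.status == "hand_not_found"

    def test_all_bones_anomalous_is_hand_not_found(self):
        out = run_cascade(make_bones([8.0] * 21, [1.0] * 21), 5.5, "male")
        assert out.status == "hand_not_found"

    def test_empty_input_is_an_error(self):
        with pytest.raises(ValidationError):
            run_cascade([], 5.5, "male")

    def test_duplicate_bone_id_is_an_error(self):
        bones = [
            BoneAssessment("radius", 10.0),
            BoneAssessment("radius", 11.0),
        ]
        with pytest.raises(ValidationError):
            run_cascade(bones, 5.5, "male")

    @given(st.randoms(use_true_random=False))
    def test_permutation_invariance(self, rnd):
        ages = [10.0] * 15 + [13.5, 6.2, 9.1, 10.4, 12.9, 0.4]
        scores = [0.0] * 18 + [0.8, 0.2, 0.9]
        bones = make_bones(ages, scores)
        shuffled = bones[:]
        rnd.shuffle(shuffled)
        a = run_cascade(bones, 5.5, "male")
        b = run_cascade(shuffled, 5.5, "male")
        assert a == b

    def test_idempotence_on_survivors(self):
        """Re-running the cascade on an accepted image's surviving bones
        rejects nothing further."""
        ages = [10.0] * 15 + [13.5, 6.2, 9.1, 10.4, 12.9, 10.2]
        first = run_cascade(make_bones(ages), 5.5, "male")
        assert first.status == "accepted"
        second = run_cascade(first.accepted_bones, 5.5, "male")
        assert second.status == "accepted"
        assert len(second.accepted_bones) == len(first.accepted_bones)
        assert second.final_bone_age == pytest.approx(first.final_bone_age)


class TestInvariants:
    def test_rejection_reason_consistency_enforced(self):
        with pytest.raises(ValidationError):
            BoneAssessment("radius", 10.0, accepted=True,
                           rejection_reason="deviation")
        with pytest.raises(ValidationError):
            BoneAssessment("radius", 10.0, accepted=False,
                           rejection_reason="none")

    def test_negative_or_nonfinite_age_rejected(self):
        for bad in (-1.0, float("nan")):
            with pytest.raises(ValidationError):
                BoneAssessment("radius", bad)

    def test_config_invariants_enforced(self):
        with pytest.raises(ValidationError):
            ValidationConfig(dev_threshold_birth=3.0, dev_threshold_high=2.4)
        with pytest.raises(ValidationError):
            ValidationConfig(sharp_min=13.0, sharp_max=4.0)
        with pytest.raises(ValidationError):
            ValidationConfig(min_bones=0)

    @pytest.mark.parametrize("bypass", [False, True])
    @pytest.mark.parametrize("n_clean", [6, 7, 8, 9])
    def test_hand_not_found_iff_below_min_bones(self, bypass, n_clean):
        cfg = ValidationConfig(bypass_quality_gates=bypass)
        scores = [0.0] * n_clean + [1.0] * (21 - n_clean)
        out = run_cascade(make_bones([9.0] * 21, scores), 5.5, "male", cfg)
        if n_clean < cfg.min_bones:
            assert out.status == "hand_not_found"
        else:
            assert out.status == "accepted"
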