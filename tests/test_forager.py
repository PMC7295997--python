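import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from foragesim import (
    AssociativeStrengths,
    ComputationError,
    ForagerParams,
    ForagerState,
    OdorFields,
    PainParams,
    PreyItem,
    SensorParams,
    SensorReading,
    compute_appetitive_state,
    compute_incentive,
    decide_turn,
    default_species_params,
    sense,
    somatic_map,
    step_and_consume,
    update_satiation,
)
from foragesim.forager import S_FLOOR, SomaticMap, _log_scale, _torus_delta


def reading_with(left_total=0.0, right_total=0.0, signature="hermi"):
    zero = {s: 0.0 for s in ("betaine", "hermi", "flab", "drug")}
    left = dict(zero)
    right = dict(zero)
    left[signature] = left_total
    right[signature] = right_total
    return SensorReading(left=left, right=right)


class TestSensing:
    def test_log_scale_floor_and_value(self):
        sp = SensorParams()
        assert _log_scale(0.0, sp) == 0.0
        assert _log_scale(1.0, sp) == pytest.approx(
            sp.k_log + math.log10(1.0 + sp.c_floor)
        )

    def test_log_scale_monotone(self):
        sp = SensorParams()
        values = [_log_scale(c, sp) for c in (0.0, 1e-6, 1e-3, 0.1, 1.0, 10.0)]
        assert all(b >= a for a, b in zip(values, values[1:]))

    def test_sensors_straddle_odor_source(self):
        # Forager at centre heading +x; source ahead-left should excite the
        # left sensor more than the right one.
        fields = OdorFields(40)
        forager = ForagerState(x=20.0, y=20.0, heading=0.0)
        sp = SensorParams()
        # left sensor sits at reach 3, +40 deg -> patch (22, 21)
        fields["hermi"][22, 21] = 5.0
        reading = sense(fields, forager, sp)
        assert reading.left["hermi"] > reading.right["hermi"]

    def test_side_sum_and_totals(self):
        r = reading_with(left_total=2.0, right_total=1.0)
        assert r.side_sum("hermi") == pytest.approx(3.0)
        assert r.totals() == (pytest.approx(2.0), pytest.approx(1.0))


class TestSomaticMap:
    def test_side_from_dominant_input(self):
        p = ForagerParams()
        assert somatic_map(reading_with(2.0, 1.0), p).stimulus_side == "left"
        assert somatic_map(reading_with(1.0, 2.0), p).stimulus_side == "right"
        assert somatic_map(reading_with(1.0, 1.0), p).stimulus_side == "center"

    def test_amplitude_scales_and_caps(self):
        p = ForagerParams(gain_turn=5.0, max_turn=20.0)
        assert somatic_map(reading_with(3.0, 1.0), p).amplitude == pytest.approx(10.0)
        assert somatic_map(reading_with(30.0, 0.0), p).amplitude == pytest.approx(20.0)

    def test_extra_inputs_route_pain_to_a_side(self):
        p = ForagerParams()
        smap = somatic_map(reading_with(1.0, 1.0), p, extra_right=4.0)
        assert smap.stimulus_side == "right"
        assert smap.amplitude == pytest.approx(20.0)


class TestIncentive:
    def test_naive_forager_follows_betaine_only(self):
        V = AssociativeStrengths.naive()
        r = reading_with(left_total=2.0, right_total=2.0, signature="betaine")
        assert compute_incentive(r, V, w_betaine=0.05) == pytest.approx(0.2)

    def test_learned_values_add_and_subtract(self):
        V = AssociativeStrengths.naive()
        V.pos["hermi"] = 1.0
        V.neg["flab"] = 0.5
        r = reading_with(left_total=3.0, right_total=0.0, signature="hermi")
        r.left["flab"] = 2.0
        assert compute_incentive(r, V, w_betaine=0.0) == pytest.approx(3.0 - 1.0)

    def test_drug_signature_carries_no_innate_pull(self):
        V = AssociativeStrengths.naive()
        r = reading_with(left_total=5.0, right_total=5.0, signature="drug")
        assert compute_incentive(r, V, w_betaine=0.05) == 0.0


class TestAppetitiveState:
    def test_hunger_raises_and_satiation_lowers(self):
        p, pp = ForagerParams(), PainParams()
        hungry = compute_appetitive_state(0.0, 0.01, 0.0, 0.0, p, pp)
        sated = compute_appetitive_state(0.0, 1.0, 0.0, 0.0, p, pp)
        assert hungry > 0.5 > sated

    def test_monotone_decreasing_in_satiation(self):
        p, pp = ForagerParams(), PainParams()
        values = [
            compute_appetitive_state(2.0, s, 0.0, 0.0, p, pp)
            for s in np.linspace(0.01, 1.0, 12)
        ]
        assert all(b < a for a, b in zip(values, values[1:]))

    def test_withdrawal_amplifies_hunger(self):
        p, pp = ForagerParams(), PainParams()
        base = compute_appetitive_state(0.0, 0.5, 0.0, 0.0, p, pp)
        withdrawn = compute_appetitive_state(0.0, 0.5, -5.0, 0.0, p, pp)
        assert withdrawn > base

    def test_positive_re_deepens_satiation_suppression(self):
        p, pp = ForagerParams(c_re=0.1), PainParams()
        base = compute_appetitive_state(0.0, 1.0, 0.0, 0.0, p, pp)
        rewarded = compute_appetitive_state(0.0, 1.0, 10.0, 0.0, p, pp)
        assert rewarded < base

    def test_pain_suppresses_unless_cancelled_by_reward(self):
        p, pp = ForagerParams(), PainParams(k_pr=1.0)
        hurt = compute_appetitive_state(0.0, 0.5, 0.0, 10.0, p, pp)
        relieved = compute_appetitive_state(0.0, 0.5, 10.0, 10.0, p, pp)
        no_pain = compute_appetitive_state(0.0, 0.5, 0.0, 0.0, p, pp)
        assert hurt < no_pain
        assert relieved > hurt

    def test_nonfinite_inputs_rejected(self):
        with pytest.raises(ComputationError):
            compute_appetitive_state(
                float("nan"), 0.5, 0.0, 0.0, ForagerParams(), PainParams()
            )

    @given(
        I=st.floats(-20, 20),
        S=st.floats(0.01, 1.0),
        RE=st.floats(-20, 20),
        P=st.floats(0, 20),
    )
    @settings(max_examples=200, deadline=None)
    def test_always_a_probability(self, I, S, RE, P):
        AS = compute_appetitive_state(I, S, RE, P, ForagerParams(), PainParams())
        assert 0.0 <= AS <= 1.0


class TestTurnDecision:
    def test_approach_turns_toward_stimulus(self):
        smap = SomaticMap("left", 12.0)
        assert decide_turn(0.7, smap, 0.5) == pytest.approx(12.0)
        smap = SomaticMap("right", 12.0)
        assert decide_turn(0.7, smap, 0.5) == pytest.approx(-12.0)

    def test_low_appetitive_state_inverts_to_avoidance(self):
        smap = SomaticMap("left", 12.0)
        assert decide_turn(0.3, smap, 0.5) == pytest.approx(-12.0)

    def test_centered_or_silent_stimulus_gives_no_turn(self):
        assert decide_turn(0.9, SomaticMap("center", 5.0), 0.5) == 0.0
        assert decide_turn(0.9, SomaticMap("left", 0.0), 0.5) == 0.0


class TestLocomotionAndConsumption:
    def test_torus_delta_shortest_path(self):
        assert _torus_delta(50.0, 60.0) == pytest.approx(-10.0)
        assert _torus_delta(-50.0, 60.0) == pytest.approx(10.0)
        assert _torus_delta(10.0, 60.0) == pytest.approx(10.0)

    @given(d=st.floats(-300, 300), size=st.floats(20, 200))
    @settings(max_examples=100, deadline=None)
    def test_torus_delta_bounded_by_half_size(self, d, size):
        assert abs(_torus_delta(d, size)) <= size / 2 + 1e-9

    def test_movement_follows_heading_and_wraps(self):
        f = ForagerState(x=59.9, y=10.0, heading=0.0, appetitive_state=0.0)
        step_and_consume(f, [], 0.0, True, default_species_params(), ForagerParams(), 60)
        assert f.x == pytest.approx((59.9 + ForagerParams().speed) % 60)

    def test_turn_applied_before_motion(self):
        f = ForagerState(x=10.0, y=10.0, heading=0.0, appetitive_state=0.0)
        step_and_consume(
            f, [], 90.0, True, default_species_params(), ForagerParams(), 60
        )
        assert f.heading == pytest.approx(90.0)
        assert f.y > 10.0

    def test_immobile_forager_only_turns(self):
        f = ForagerState(x=10.0, y=10.0, heading=0.0, appetitive_state=0.9)
        step_and_consume(
            f, [], 15.0, False, default_species_params(), ForagerParams(), 60
        )
        assert (f.x, f.y) == (10.0, 10.0)
        assert f.heading == pytest.approx(15.0)

    def test_consumption_requires_bite_threshold(self):
        params = ForagerParams()
        item = PreyItem("hermi", 10.5, 10.0)
        f = ForagerState(x=10.0, y=10.0, appetitive_state=params.bite_threshold - 0.01)
        events = step_and_consume(
            f, [item], 0.0, False, default_species_params(), params, 60
        )
        assert events == [] and item.alive
        f.appetitive_state = params.bite_threshold
        events = step_and_consume(
            f, [item], 0.0, False, default_species_params(), params, 60
        )
        assert len(events) == 1 and not item.alive
        assert events[0].species == "hermi"
        assert events[0].reward_magnitude == pytest.approx(0.5)
        assert events[0].nutrition_value == pytest.approx(0.3)

    def test_capture_radius_respects_torus(self):
        params = ForagerParams(capture_radius=1.5)
        item = PreyItem("hermi", 59.5, 10.0)
        f = ForagerState(x=0.5, y=10.0, appetitive_state=1.0)
        events = step_and_consume(
            f, [item], 0.0, False, default_species_params(), params, 60
        )
        assert len(events) == 1

    def test_reward_override_changes_event_not_species(self):
        params = ForagerParams()
        item = PreyItem("drug", 10.5, 10.0)
        f = ForagerState(x=10.0, y=10.0, appetitive_state=1.0)
        events = step_and_consume(
            f,
            [item],
            0.0,
            False,
            default_species_params(),
            params,
            60,
            reward_overrides={"drug": 0.0},
        )
        assert events[0].reward_magnitude == 0.0
        assert events[0].species == "drug"


class TestSatiation:
    def test_nutrition_decays_and_meals_add(self):
        params = ForagerParams(k_N=0.01)
        f = ForagerState(nutrition=1.0)
        update_satiation(f, [], params)
        assert f.nutrition == pytest.approx(0.99)
        from foragesim import ConsumptionEvent

        update_satiation(f, [ConsumptionEvent("hermi", 0.5, 0.3)], params)
        assert f.nutrition == pytest.approx(0.99 * 0.99 + 0.3)

    def test_satiation_saturates_and_clamps(self):
        params = ForagerParams()
        f = ForagerState(nutrition=0.0)
        update_satiation(f, [], params)
        assert f.satiation == S_FLOOR
        f.nutrition = 1e6
        update_satiation(f, [], params)
        assert f.satiation <= 1.0

    def test_half_saturation_constant(self):
        params = ForagerParams(K_half=0.3, k_N=0.0)
        f = ForagerState(nutrition=0.3)
        update_satiation(f, [], params)
        assert f.satiation == pytest.approx(0.5)

    def test_drug_meal_adds_no_nutrition(self):
        from foragesim import ConsumptionEvent

        params = ForagerParams(k_N=0.0)
        f = ForagerState(nutrition=0.5)
        update_satiation(f, [ConsumptionEvent("drug", 4.0, 0.0)], params)
        assert f.nutrition == pytest.approx(0.5)
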