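"""Solving the sequential game: thresholds, outcomes, losses, zones, winners."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kinconflict import (
    ATOL,
    Action,
    GameParams,
    Role,
    Winner,
    best_response,
    bruteforce_solve,
    classify_zone,
    critical_youth_benefit,
    loss_to_second,
    predict_winner,
    sequential_outcome,
    thresholds,
)
from conftest import random_params


class TestThresholds:
    def test_symmetric_case(self):
        thr = thresholds(GameParams(s=0.5, c=0.0, y=1.0))
        assert thr.adolescent_adds_second == pytest.approx(1 / 3, abs=1e-15)
        assert thr.parent_adds_second == pytest.approx(1 / 3, abs=1e-15)

    def test_full_continuity(self):
        thr = thresholds(GameParams(s=0.5, c=1.0, y=1.0))
        assert thr.adolescent_adds_second == pytest.approx(0.5, abs=1e-15)
        assert thr.parent_adds_second == pytest.approx(1 / 3, abs=1e-15)
        assert thr.parent_wants_adolescent_second == pytest.approx(2 / 3, abs=1e-15)
        assert thr.adolescent_wants_parent_second == pytest.approx(0.5, abs=1e-15)

    def test_large_youth_benefit_limit(self):
        for c in (0.0, 0.5, 1.0):
            assert thresholds(GameParams(s=0.5, c=c, y=1e6)).adolescent_adds_second < 1e-5

    @settings(derandomize=True, max_examples=200)
    @given(st.floats(0.0, 1.0), st.floats(0.01, 20.0))
    def test_all_thresholds_in_unit_interval(self, c, y):
        thr = thresholds(GameParams(s=0.5, c=c, y=y))
        for v in vars(thr).values():
            assert 0.0 < v < 1.0

    @settings(derandomize=True, max_examples=100)
    @given(st.floats(0.0, 0.9), st.floats(0.001, 0.1), st.floats(0.1, 10.0), st.floats(0.001, 1.0))
    def test_adolescent_threshold_increasing_in_c_decreasing_in_y(self, c, dc, y, dy):
        base = thresholds(GameParams(s=0.5, c=c, y=y)).adolescent_adds_second
        assert thresholds(GameParams(s=0.5, c=c + dc, y=y)).adolescent_adds_second > base
        assert thresholds(GameParams(s=0.5, c=c, y=y + dy)).adolescent_adds_second < base

    def test_best_response_flips_exactly_at_closed_form(self, rng):
        # bisection on s over the payoff comparison brackets each closed form
        for p in random_params(rng, 50):
            thr = thresholds(p)
            for role, other, crit in [
                (Role.ADOLESCENT, Action.R, thr.adolescent_adds_second),
                (Role.PARENT, Action.R, thr.parent_adds_second),
            ]:
                lo, hi = 0.0, 1.0
                for _ in range(60):
                    mid = (lo + hi) / 2
                    act, _ = best_response(role, other, GameParams(s=mid, c=p.c, y=p.y))
                    if act is Action.R:
                        hi = mid
                    else:
                        lo = mid
                # flip point sits within the ATOL-wide indifference band
                # around the closed form (ties resolve to N inside the band)
                assert hi == pytest.approx(crit, abs=1e-7)


class TestBestResponse:
    @pytest.mark.parametrize(
        "role, other, kw, expected",
        [
            (Role.ADOLESCENT, Action.R, dict(s=0.9, c=0.0, y=1.0), Action.R),
            (Role.ADOLESCENT, Action.R, dict(s=0.2, c=0.0, y=1.0), Action.N),
            (Role.PARENT, Action.R, dict(s=0.9, c=0.0, y=1.0), Action.R),
            (Role.PARENT, Action.N, dict(s=0.1, c=0.5, y=0.3), Action.R),
            (Role.ADOLESCENT, Action.N, dict(s=0.1, c=0.5, y=0.3), Action.R),
        ],
    )
    def test_examples(self, role, other, kw, expected):
        act, tie = best_response(role, other, GameParams(**kw))
        assert act is expected and not tie

    def test_exact_indifference_resolves_to_n_with_flag(self):
        # at s exactly 1/3 with c=0, y=1 the adolescent is indifferent
        act, tie = best_response(Role.ADOLESCENT, Action.R, GameParams(s=1 / 3, c=0.0, y=1.0))
        assert act is Action.N and tie


class TestSequentialOutcome:
    def test_parent_first_low_survival(self):
        out = sequential_outcome(Role.PARENT, GameParams(s=0.2, c=0.0, y=1.0))
        assert (out.first_action, out.second_action) == (Action.R, Action.N)
        assert out.n_infants == 1
        assert out.payoff_parent == pytest.approx(0.5)
        assert out.payoff_adolescent == pytest.approx(0.25)

    def test_adolescent_first_low_survival(self):
        out = sequential_outcome(Role.ADOLESCENT, GameParams(s=0.2, c=0.0, y=1.0))
        assert out.second_action is Action.N
        assert out.payoff_adolescent == pytest.approx(0.5)
        assert out.payoff_parent == pytest.approx(0.25)

    @pytest.mark.parametrize("first", list(Role))
    def test_high_survival_both_reproduce(self, first):
        p = GameParams(s=0.9, c=0.0, y=1.0)
        out = sequential_outcome(first, p)
        assert out.n_infants == 2
        assert out.payoff_parent == pytest.approx(0.5 * 0.9 + 0.25 * 0.9)
        assert out.payoff_adolescent == pytest.approx(0.5 * 0.9 + 0.25 * 0.9)

    def test_matches_piecewise_first_mover_payoffs(self, rng):
        # branch-for-branch against the piecewise closed forms
        for p in random_params(rng, 200):
            thr = thresholds(p)
            out_p = sequential_outcome(Role.PARENT, p)
            if abs(p.s - thr.adolescent_adds_second) <= 1e-9:
                continue
            if p.s > thr.adolescent_adds_second:
                assert out_p.payoff_parent == pytest.approx(0.5 * p.s + 0.25 * p.s * p.y)
                assert out_p.payoff_adolescent == pytest.approx(
                    0.5 * p.s * p.y + 0.25 * p.s * (1 + p.c)
                )
            else:
                assert out_p.payoff_parent == pytest.approx(0.5)
                assert out_p.payoff_adolescent == pytest.approx(0.25 * (1 + p.c))
            out_a = sequential_outcome(Role.ADOLESCENT, p)
            if abs(p.s - thr.parent_adds_second) <= 1e-9:
                continue
            if p.s > thr.parent_adds_second:
                assert out_a.payoff_parent == pytest.approx(0.5 * p.s + 0.25 * p.s * p.y)
            else:
                assert out_a.payoff_parent == pytest.approx(0.25 * p.y)
                assert out_a.payoff_adolescent == pytest.approx(0.5 * p.y)


class TestBruteForceOracle:
    def test_oracle_equivalence_random_draws(self, rng):
        # backward induction from the payoff table alone reproduces the
        # closed-form sequential outcomes away from threshold boundaries
        n_checked = 0
        for p in random_params(rng, 10_000):
            thr = thresholds(p)
            if min(
                abs(p.s - thr.adolescent_adds_second), abs(p.s - thr.parent_adds_second)
            ) < 1e-6:
                continue
            for first in Role:
                closed = sequential_outcome(first, p)
                brute = bruteforce_solve(first, p, optimize_first=False)
                assert brute.second_action is closed.second_action
                assert brute.payoff_parent == pytest.approx(closed.payoff_parent, abs=1e-12)
                assert brute.payoff_adolescent == pytest.approx(
                    closed.payoff_adolescent, abs=1e-12
                )
            n_checked += 1
        assert n_checked > 9_000

    def test_parent_abstains_for_large_youth_benefit(self):
        out = bruteforce_solve(Role.PARENT, GameParams(s=0.2, c=0.0, y=3.0))
        assert out.first_action is Action.N
        assert out.second_action is Action.R
        assert out.n_infants == 1

    def test_parent_reproduces_just_below_indifference(self):
        out = bruteforce_solve(Role.PARENT, GameParams(s=0.2, c=0.0, y=1.9))
        assert out.first_action is Action.R

    def test_first_mover_tie_at_indifference_keeps_r_with_flag(self):
        out = bruteforce_solve(Role.PARENT, GameParams(s=0.2, c=0.0, y=2.0))
        assert out.first_action is Action.R and out.first_tie


class TestLossToSecond:
    def test_symmetric_loss(self):
        p = GameParams(s=0.2, c=0.0, y=1.0)
        assert loss_to_second(Role.PARENT, p) == pytest.approx(0.25)
        assert loss_to_second(Role.ADOLESCENT, p) == pytest.approx(0.25)

    def test_adolescent_indifferent_at_full_continuity(self):
        assert loss_to_second(Role.ADOLESCENT, GameParams(s=0.2, c=1.0, y=1.0)) == pytest.approx(
            0.0, abs=1e-12
        )

    @pytest.mark.parametrize("role", list(Role))
    def test_zero_loss_when_both_always_reproduce(self, role):
        assert loss_to_second(role, GameParams(s=0.9, c=0.0, y=1.0)) == pytest.approx(0.0)

    def test_symmetry_across_s_grid(self):
        for s in np.linspace(0.0, 1.0, 101):
            p = GameParams(s=float(s), c=0.0, y=1.0)
            assert loss_to_second(Role.PARENT, p) == pytest.approx(
                loss_to_second(Role.ADOLESCENT, p), abs=1e-12
            )

    def test_negative_loss_is_endogenous_timing(self):
        # intermediate s, y=1: the adolescent prefers to respond to the parent
        p = GameParams(s=0.35, c=0.25, y=1.0)
        assert classify_zone(p)[0] == 2
        assert loss_to_second(Role.ADOLESCENT, p) < 0
        assert loss_to_second(Role.PARENT, p) > 0
        assert predict_winner(p).endogenous_timing


class TestZones:
    def test_zone2_with_bounds(self):
        zone, bounds, flagged = classify_zone(GameParams(s=0.4, c=1.0, y=1.0))
        assert zone == 2 and not flagged
        assert bounds == pytest.approx((1 / 3, 0.5))

    def test_zone2_collapses_at_critical_youth_benefit(self):
        for c in (0.0, 0.25, 0.5, 1.0):
            _, (lo, hi), _ = classify_zone(GameParams(s=0.5, c=c, y=math.sqrt(1 + c)))
            assert hi - lo == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("c", [0.0, 0.5, 1.0])
    def test_high_survival_is_zone3(self, c):
        assert classify_zone(GameParams(s=0.9, c=c, y=1.0))[0] == 3

    def test_boundary_point_assigned_down_and_flagged(self):
        zone, (lo, hi), flagged = classify_zone(GameParams(s=1 / 3, c=1.0, y=1.0))
        assert zone == 1 and flagged
        zone, _, flagged = classify_zone(GameParams(s=0.5, c=1.0, y=1.0))
        assert zone == 2 and flagged

    def test_bound_ordering_flips_at_sqrt_one_plus_c(self):
        for c in (0.0, 0.3, 0.7, 1.0):
            ycrit = math.sqrt(1 + c)
            below = thresholds(GameParams(s=0.5, c=c, y=ycrit * 0.99))
            above = thresholds(GameParams(s=0.5, c=c, y=ycrit * 1.01))
            assert below.adolescent_adds_second > below.parent_adds_second
            assert above.adolescent_adds_second < above.parent_adds_second

    def test_zone1_exactly_one_reproduces_zone3_losses_zero(self, rng):
        for p in random_params(rng, 500):
            zone, _, flagged = classify_zone(p)
            if flagged:
                continue
            if zone == 1:
                for first in Role:
                    assert sequential_outcome(first, p).n_infants == 1
            elif zone == 3:
                assert loss_to_second(Role.PARENT, p) == pytest.approx(0.0, abs=1e-12)
                assert loss_to_second(Role.ADOLESCENT, p) == pytest.approx(0.0, abs=1e-12)


class TestWinner:
    @pytest.mark.parametrize(
        "kw, expected",
        [
            (dict(s=0.2, c=1.0, y=1.0), Winner.PARENT),
            (dict(s=0.2, c=0.0, y=1.0), Winner.TIE),
            (dict(s=0.2, c=0.0, y=3.0), Winner.ADOLESCENT),
            (dict(s=0.9, c=0.5, y=1.0), Winner.NO_CONFLICT),
        ],
    )
    def test_examples(self, kw, expected):
        assert predict_winner(GameParams(**kw)).winner is expected

    def test_analysis_consistency(self):
        res = predict_winner(GameParams(s=0.2, c=1.0, y=1.0))
        assert res.zone == 1
        assert res.loss_parent == pytest.approx(0.25)
        assert res.loss_adolescent == pytest.approx(0.0, abs=1e-12)
        assert not res.parent_abstains_first

    def test_abstention_flag_exposed(self):
        res = predict_winner(GameParams(s=0.2, c=0.0, y=3.0))
        assert res.parent_abstains_first and not res.adolescent_abstains_first
        assert res.endogenous_timing  # parent's loss is negative

    def test_parent_margin_nondecreasing_in_c(self):
        margins = []
        for c in np.linspace(0.0, 1.0, 21):
            res = predict_winner(GameParams(s=0.2, c=float(c), y=1.0))
            margins.append(res.loss_parent - res.loss_adolescent)
        assert all(b >= a - ATOL for a, b in zip(margins, margins[1:]))

    def test_adolescent_margin_nondecreasing_in_y(self):
        margins = []
        for y in np.linspace(0.5, 3.0, 26):
            res = predict_winner(GameParams(s=0.05, c=0.5, y=float(y)))
            margins.append(res.loss_adolescent - res.loss_parent)
        assert all(b >= a - ATOL for a, b in zip(margins, margins[1:]))

    def test_adolescent_wins_zone1_above_y_threshold(self):
        # the adolescent loses more than the parent once y > (3 + c) / 3
        for c in (0.0, 0.6, 1.0):
            ycrit = (3 + c) / 3
            lo = predict_winner(GameParams(s=0.05, c=c, y=ycrit - 0.05))
            hi = predict_winner(GameParams(s=0.05, c=c, y=ycrit + 0.05))
            assert lo.loss_parent > lo.loss_adolescent
            assert hi.loss_adolescent > hi.loss_parent


def test_critical_youth_benefit_closed_forms():
    assert critical_youth_benefit(Role.PARENT) == pytest.approx(2.0, abs=1e-9)
    assert critical_youth_benefit(Role.ADOLESCENT, c=0.0) == pytest.approx(0.5, abs=1e-9)
    assert critical_youth_benefit(Role.ADOLESCENT, c=1.0) == pytest.approx(1.0, abs=1e-9)
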