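import pytest

from crnctrl.crn import build_crn, compile_crn, simulate, steady_state
from crnctrl.operators import (
    REACTION_COUNTS,
    OperatorSpec,
    make_division,
    make_dualrail,
    make_gain,
    make_integrator,
    make_proportional,
    make_subtraction_onesided,
    make_summation3,
)

N_RANDOM_CASES = 50
REL_TOL = 1e-6


def clamp_inputs(crn, names):
    return build_crn(crn.reactions, clamped=set(names), allow_higher_order=True)


def equilibrium(crn, inputs, outputs, gamma=1.0, horizon=None):
    horizon = horizon if horizon is not None else 20.0 / gamma
    res = steady_state(compile_crn(clamp_inputs(crn, inputs)), inputs=inputs,
                       horizon=horizon)
    return res, {s: res[s] for s in outputs}


class TestReactionCounts:
    @pytest.mark.parametrize(
        "kind, expected",
        [
            ("gain", 2),
            ("summation3", 3),
            ("subtraction_onesided", 4),
            ("division", 2),
            ("integrator", 1),
            ("proportional", 2),
            ("summation_dualrail", 9),
            ("subtraction_dualrail", 9),
        ],
    )
    def test_count_table(self, kind, expected):
        assert REACTION_COUNTS[kind] == expected

    def test_built_counts_match_table(self):
        built = {
            "gain": make_gain(1.0, 1.0, "a", "b"),
            "summation3": make_summation3(1.0, "a", "b", "c"),
            "subtraction_onesided": make_subtraction_onesided(1.0, "a", "b", "c", "i"),
            "division": make_division(1.0, "a", "b", "c"),
            "integrator": make_integrator(1.0, "a", "b"),
            "proportional": make_proportional(1.0, 1.0, "a", "b"),
            "summation_dualrail": make_dualrail(
                "summation", 1.0, 1000.0, "ap", "am", "bp", "bm", "op", "om"
            ),
            "subtraction_dualrail": make_dualrail(
                "subtraction", 1.0, 1000.0, "ap", "am", "bp", "bm", "op", "om"
            ),
        }
        for kind, crn in built.items():
            assert crn.n_reactions == REACTION_COUNTS[kind], kind


class TestGain:
    def test_alpha_gain_example(self):
        # alpha = kr2*kr3 from the nominal process rates
        crn = make_gain(0.00128, 1.0, "r", "x1")
        _, out = equilibrium(crn, {"r": 4.0}, ["x1"])
        assert out["x1"] == pytest.approx(0.00512, rel=REL_TOL)

    def test_identity_and_zero(self):
        crn = make_gain(1.0, 2.0, "r", "y")
        _, out = equilibrium(crn, {"r": 3.0}, ["y"], gamma=2.0)
        assert out["y"] == pytest.approx(3.0, rel=REL_TOL)
        crn = make_gain(0.0, 1.0, "r", "y")
        _, out = equilibrium(crn, {"r": 3.0}, ["y"])
        assert out["y"] == pytest.approx(0.0, abs=1e-9)

    def test_negative_gain_rejected(self):
        with pytest.raises(ValueError):
            make_gain(-0.5, 1.0, "r", "y")

    def test_random_cases(self, rng):
        for _ in range(N_RANDOM_CASES):
            k, gamma, r = rng.uniform(0.1, 5), rng.uniform(0.5, 3), rng.uniform(0, 10)
            crn = make_gain(k, gamma, "r", "y")
            _, out = equilibrium(crn, {"r": r}, ["y"], gamma=gamma)
            assert out["y"] == pytest.approx(k * r, rel=REL_TOL, abs=1e-9)


class TestSummation3:
    def test_examples(self):
        crn = make_summation3(1.0, "a", "b", "c")
        assert crn.n_reactions == 3
        _, out = equilibrium(crn, {"a": 2.0, "b": 3.0}, ["c"])
        assert out["c"] == pytest.approx(5.0, rel=REL_TOL)
        _, out = equilibrium(crn, {"a": 0.0, "b": 0.0}, ["c"])
        assert out["c"] == pytest.approx(0.0, abs=1e-9)

    def test_random_cases(self, rng):
        for _ in range(N_RANDOM_CASES):
            a, b = rng.uniform(0, 10, 2)
            gamma = rng.uniform(0.5, 3)
            crn = make_summation3(gamma, "a", "b", "c")
            _, out = equilibrium(crn, {"a": a, "b": b}, ["c"], gamma=gamma)
            assert out["c"] == pytest.approx(a + b, rel=REL_TOL, abs=1e-9)


class TestSubtractionOnesided:
    def test_positive_difference(self):
        crn = make_subtraction_onesided(1.0, "a", "b", "o", "i")
        res, out = equilibrium(crn, {"a": 5.0, "b": 3.0}, ["o"], horizon=400.0)
        assert out["o"] == pytest.approx(2.0, rel=1e-4)
        assert res.converged

    def test_negative_difference_clips_to_zero(self):
        crn = make_subtraction_onesided(1.0, "a", "b", "o", "i")
        res, out = equilibrium(crn, {"a": 3.0, "b": 5.0}, ["o"], horizon=400.0)
        # output decays like a / ((b-a) t) toward zero; no finite fixed point
        assert out["o"] <= 2 * 3.0 / (2.0 * 400.0)
        assert not res.converged

    def test_equal_inputs_no_fixed_point(self):
        crn = make_subtraction_onesided(1.0, "a", "b", "o", "i")
        res, out = equilibrium(crn, {"a": 4.0, "b": 4.0}, ["o"], horizon=2000.0)
        assert out["o"] == pytest.approx(0.0, abs=0.1)
        assert not res.converged

    def test_output_nonnegative_at_all_times(self, rng):
        crn = clamp_inputs(make_subtraction_onesided(1.0, "a", "b", "o", "i"),
                           {"a", "b"})
        for _ in range(5):
            a, b = rng.uniform(0, 8, 2)
            traj = simulate(compile_crn(crn), inputs={"a": a, "b": b}, t_end=100.0)
            assert traj["o"].min() >= 0

    def test_random_cases(self, rng):
        crn = make_subtraction_onesided(1.0, "a", "b", "o", "i")
        for _ in range(N_RANDOM_CASES):
            a, b = rng.uniform(0, 10, 2)
            horizon = 3000.0
            _, out = equilibrium(crn, {"a": a, "b": b}, ["o"], horizon=horizon)
            if a > b + 0.05:
                assert out["o"] == pytest.approx(a - b, rel=1e-4, abs=1e-6)
            else:
                # saturated branch settles only algebraically (~1/t)
                envelope = 2 * a / (max(b - a, 1.0 / horizon) * horizon)
                assert out["o"] <= max(envelope, 1e-4)


class TestDivision:
    def test_examples(self):
        crn = make_division(1.0, "n", "d", "q")
        _, out = equilibrium(crn, {"n": 6.0, "d": 3.0}, ["q"])
        assert out["q"] == pytest.approx(2.0, rel=REL_TOL)
        _, out = equilibrium(crn, {"n": 0.0, "d": 3.0}, ["q"])
        assert out["q"] == pytest.approx(0.0, abs=1e-9)

    def test_vanishing_denominator_flagged(self):
        crn = make_division(1.0, "n", "d", "q")
        res, out = equilibrium(crn, {"n": 1.0, "d": 1e-8}, ["q"], horizon=100.0)
        assert not res.converged
        assert out["q"] > 10

    def test_random_cases(self, rng):
        crn = make_division(1.0, "n", "d", "q")
        for _ in range(N_RANDOM_CASES):
            n, d = rng.uniform(0.5, 10), rng.uniform(0.5, 10)
            _, out = equilibrium(crn, {"n": n, "d": d}, ["q"], horizon=400.0)
            assert out["q"] == pytest.approx(n / d, rel=1e-5)


class TestIntegrator:
    def test_linear_growth(self):
        crn = clamp_inputs(make_integrator(1.0, "u", "y"), {"u"})
        traj = simulate(compile_crn(crn), inputs={"u": 3.0}, t_end=10.0)
        assert traj.final("y") == pytest.approx(30.0, rel=1e-8)

    def test_zero_input_holds(self):
        crn = clamp_inputs(make_integrator(1.0, "u", "y"), {"u"})
        traj = simulate(compile_crn(crn), {"y": 2.0}, inputs={"u": 0.0}, t_end=10.0)
        assert traj.final("y") == pytest.approx(2.0, rel=1e-9)

    def test_small_gain_long_horizon(self):
        crn = clamp_inputs(make_integrator(2.5e-8, "u", "y"), {"u"})
        traj = simulate(compile_crn(crn), inputs={"u": 1.0}, t_end=1e4)
        assert traj.final("y") == pytest.approx(2.5e-4, rel=1e-8)


class TestDualRail:
    @staticmethod
    def signed_equilibrium(kind, in1, in2, gamma=1.0, eta=1000.0, horizon=None):
        crn = make_dualrail(kind, gamma, eta, "a_p", "a_m", "b_p", "b_m", "o_p", "o_m")
        inputs = {
            "a_p": max(in1, 0.0), "a_m": max(-in1, 0.0),
            "b_p": max(in2, 0.0), "b_m": max(-in2, 0.0),
        }
        res, out = equilibrium(crn, inputs, ["o_p", "o_m"], gamma=gamma,
                               horizon=horizon or 40.0 / gamma)
        return out["o_p"] - out["o_m"], out

    def test_subtraction_negative_result(self):
        value, _ = self.signed_equilibrium("subtraction", 2.0, 5.0)
        assert value == pytest.approx(-3.0, rel=1e-5)

    def test_summation(self):
        value, _ = self.signed_equilibrium("summation", 2.0, 3.0)
        assert value == pytest.approx(5.0, rel=1e-5)

    def test_random_cases(self, rng):
        for _ in range(N_RANDOM_CASES):
            a, b = rng.uniform(-5, 5, 2)
            value, _ = self.signed_equilibrium("subtraction", a, b)
            assert value == pytest.approx(a - b, rel=1e-4, abs=1e-3)

    def test_annihilation_improves_with_eta(self):
        leaks = []
        for eta in (10.0, 100.0, 1000.0):
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                _, out = self.signed_equilibrium("subtraction", 2.0, 5.0, eta=eta)
            leaks.append(min(out["o_p"], out["o_m"]))
        assert leaks[0] > leaks[1] > leaks[2]

    def test_low_eta_warns(self):
        with pytest.warns(UserWarning, match="dual-rail"):
            make_dualrail("subtraction", 1.0, 0.5, "ap", "am", "bp", "bm", "op", "om")


class TestNoNegativeSingleRailEquilibrium:
    """Library-level restatement of the impossibility of two-sided
    subtraction with standard motifs: no single-rail operator output can
    settle below zero."""

    def test_all_single_rail_outputs_nonnegative(self, rng):
        cases = []
        for _ in range(10):
            a, b = rng.uniform(0, 6, 2)
            cases += [
                (make_gain(rng.uniform(0, 2), 1.0, "a", "o"), {"a": a}),
                (make_summation3(1.0, "a", "b", "o"), {"a": a, "b": b}),
                (make_subtraction_onesided(1.0, "a", "b", "o", "i"), {"a": a, "b": b}),
                (make_division(1.0, "a", "b", "o"), {"a": a, "b": max(b, 0.2)}),
            ]
        for crn, inputs in cases:
            _, out = equilibrium(crn, inputs, ["o"], horizon=300.0)
            assert out["o"] >= 0


class TestOperatorSpec:
    def test_build_matches_factory(self):
        spec = OperatorSpec(kind="summation3", gamma=2.0, inputs=("a", "b"), output="c")
        assert spec.build().n_reactions == 3
        assert spec.n_reactions == 3

    def test_dualrail_defaults_eta(self):
        spec = OperatorSpec(
            kind="subtraction_dualrail", gamma=2.0,
            inputs=("ap", "am", "bp", "bm"), output=("op", "om"),
        )
        assert spec.eta == pytest.approx(2000.0)

    def test_unknown_kind(self):
        with pytest.raises(ValueError):
            OperatorSpec(kind="multiplication")
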