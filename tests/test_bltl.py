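"""BLTL parsing, trace semantics, and statistical estimation."""

import numpy as np
import pytest

from modex.bltl import (
    BltlSyntaxError,
    EvaluationError,
    Property,
    estimate_probability,
    evaluate_on_trace,
    hoeffding_half_width,
    parse_formula,
    parse_property,
    required_horizon,
)
from modex.simulate import SimulationConfig

from conftest import make_model


def test_parse_nested_temporal():
    ast = parse_formula("F[10]G[5](x = 1 and y = 2)")
    assert ast == ("F", 10, ("G", 5, ("and", ("atom", "x", "=", 1),
                                      ("atom", "y", "=", 2))))


def test_parse_single_atom_and_comparators():
    assert parse_formula("x = 1") == ("atom", "x", "=", 1)
    assert parse_formula("x >= 2") == ("atom", "x", ">=", 2)
    assert parse_formula("x < 1") == ("atom", "x", "<", 1)


def test_parse_until_and_precedence():
    ast = parse_formula("a = 1 U[4] b = 1 or c = 1")
    # U binds loosest: (a=1) U[4] ((b=1) or (c=1))
    assert ast[0] == "U" and ast[1] == 4
    assert ast[3][0] == "or"


def test_negative_bound_rejected():
    with pytest.raises(BltlSyntaxError, match="negative bound"):
        parse_formula("F[-1](x = 1)")


@pytest.mark.parametrize("bad", ["F[2]", "x =", "x 1", "(x = 1", "F[2)x=1"])
def test_syntax_errors(bad):
    with pytest.raises(BltlSyntaxError):
        parse_formula(bad)


def test_goal_probability_validated():
    with pytest.raises(ValueError):
        parse_property("x = 1", 1.5)
    p = parse_property("x = 1", 0.25, "t1")
    assert p.goal_probability == 0.25 and p.id == "t1"


@pytest.mark.parametrize(
    "text,expected",
    [
        ("F[10]G[5](x = 1)", 15),
        ("x = 1", 0),
        ("F[3](x = 1) and G[7](y = 1)", 7),
        ("not G[4](x = 0)", 4),
        ("x = 1 U[6] F[2](y = 1)", 8),
    ],
)
def test_required_horizon(text, expected):
    assert required_horizon(parse_formula(text)) == expected


def trace_of(**series):
    return {k: np.array(v) for k, v in series.items()}


def test_eventually_globally_witness():
    tr = trace_of(x=[0, 0, 1, 1, 1])
    assert evaluate_on_trace(parse_formula("F[2]G[1](x = 1)"), tr, 0)


def test_eventually_false_on_all_zero():
    tr = trace_of(x=[0, 0, 0, 0, 0])
    assert not evaluate_on_trace(parse_formula("F[4](x = 1)"), tr, 0)
    assert evaluate_on_trace(parse_formula("G[4](x = 0)"), tr, 0)


def test_until_semantics():
    phi_until_psi = parse_formula("x = 1 U[3] y = 1")
    assert evaluate_on_trace(phi_until_psi, trace_of(x=[1, 1, 0, 0], y=[0, 0, 1, 0]), 0)
    # phi fails before psi arrives
    assert not evaluate_on_trace(phi_until_psi, trace_of(x=[1, 0, 0, 0], y=[0, 0, 1, 0]), 0)
    # psi never arrives in the bound
    assert not evaluate_on_trace(phi_until_psi, trace_of(x=[1, 1, 1, 1], y=[0, 0, 0, 0]), 0)
    # psi immediately: phi irrelevant
    assert evaluate_on_trace(phi_until_psi, trace_of(x=[0, 0, 0, 0], y=[1, 0, 0, 0]), 0)


def test_too_short_trace_is_an_error_not_truncation():
    tr = trace_of(x=[0, 1])
    with pytest.raises(EvaluationError, match="too short"):
        evaluate_on_trace(parse_formula("F[5](x = 1)"), tr, 0)


def test_position_offset():
    tr = trace_of(x=[0, 0, 0, 1, 1])
    f = parse_formula("F[1](x = 1)")
    assert not evaluate_on_trace(f, tr, 0)
    assert evaluate_on_trace(f, tr, 2)


def _random_traces(n, length, seed):
    rng = np.random.default_rng(seed)
    return [trace_of(x=rng.integers(0, 2, size=length), y=rng.integers(0, 2, size=length))
            for _ in range(n)]


@pytest.mark.parametrize("formula", ["x = 1", "x = 1 and y = 0", "x = 1 or y = 1"])
@pytest.mark.parametrize("k", [0, 1, 3, 5])
def test_fg_duality_on_random_traces(formula, k):
    f_version = parse_formula(f"F[{k}]({formula})")
    g_version = parse_formula(f"not G[{k}](not ({formula}))")
    for tr in _random_traces(60, 10, seed=k + 17):
        assert evaluate_on_trace(f_version, tr, 0) == evaluate_on_trace(g_version, tr, 0)


def test_zero_bound_temporal_is_present_tense():
    phi = "x = 1"
    for tr in _random_traces(40, 6, seed=2):
        now = evaluate_on_trace(parse_formula(phi), tr, 0)
        assert evaluate_on_trace(parse_formula(f"F[0]({phi})"), tr, 0) == now
        assert evaluate_on_trace(parse_formula(f"G[0]({phi})"), tr, 0) == now


def test_bound_monotonicity_on_random_traces():
    for tr in _random_traces(60, 12, seed=3):
        for k in range(0, 8):
            g_k = evaluate_on_trace(parse_formula(f"G[{k + 1}](x = 1)"), tr, 0)
            if g_k:  # G is monotone decreasing in the bound
                assert evaluate_on_trace(parse_formula(f"G[{k}](x = 1)"), tr, 0)
            f_k = evaluate_on_trace(parse_formula(f"F[{k}](x = 1)"), tr, 0)
            if f_k:  # F is monotone increasing in the bound
                assert evaluate_on_trace(parse_formula(f"F[{k + 1}](x = 1)"), tr, 0)


def test_estimate_tautology_and_contradiction(chain_model):
    cfg = SimulationConfig(scheme="synchronous", steps=6, runs=20, seed=0)
    taut = parse_property("F[3](C = 1)", 1.0, "t")
    assert estimate_probability(chain_model, taut, cfg).estimate == 1.0
    contra = parse_property("G[3](C = 1)", 1.0, "t")
    assert estimate_probability(chain_model, contra, cfg).estimate == 0.0


def test_estimate_refuses_short_horizon(chain_model):
    cfg = SimulationConfig(steps=3, runs=5, seed=0)
    prop = parse_property("F[10](C = 1)", 1.0, "t")
    with pytest.raises(ValueError, match="10"):
        estimate_probability(chain_model, prop, cfg)


def test_estimate_race_matches_enumeration():
    # mutual repression: A wins iff it updates first; p = 1/2 exactly
    m = make_model([("A", "", "B", 0), ("B", "", "A", 0)])
    runs = 2000
    cfg = SimulationConfig(steps=6, runs=runs, seed=11)
    prop = parse_property("F[6](A = 1)", 0.5, "t")
    res = estimate_probability(m, prop, cfg)
    se = np.sqrt(0.25 / runs)
    assert abs(res.estimate - 0.5) <= 3 * se
    assert res.runs == runs
    assert res.half_width == pytest.approx(hoeffding_half_width(runs, 0.05))


def test_half_width_formula():
    # runs >= ln(2/alpha) / (2 eps^2)  <=>  eps = sqrt(ln(2/alpha)/(2 runs))
    assert hoeffding_half_width(1000, 0.05) == pytest.approx(
        np.sqrt(np.log(2 / 0.05) / 2000.0)
    )
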