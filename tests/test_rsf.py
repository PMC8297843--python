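"""Logistic RSF fitting, screens, backward selection and prediction."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from habsel import rsf
from habsel.grids import Grid, LandscapeStack
from habsel.rsf import (RankDeficiencyError, RSFModel, SelectionLedger,
                        SeparationError, backward_select, design_matrix,
                        dependents_of, fit_logistic, pearson_screen,
                        predict_rsf, term_column, vif)

from conftest import make_table


# ---------------------------------------------------------------------------
# fitting

def test_logistic_2x2_closed_form(binary_2x2_table):
    m = fit_logistic(binary_2x2_table, ["x"])
    assert m.coef("intercept") == pytest.approx(np.log(40 / 400), abs=1e-6)
    assert m.coef("x") == pytest.approx(np.log(6.0), abs=1e-6)
    assert m.n_used == 100 and m.n_available == 500


def test_logistic_intercept_only():
    df = pd.DataFrame({"response": np.r_[np.ones(100), np.zeros(500)],
                       "x": np.r_[np.zeros(300), np.ones(300)]})
    m = fit_logistic(make_table(df), [])
    assert m.coef("intercept") == pytest.approx(np.log(1 / 5), abs=1e-8)


def test_logistic_matches_scipy_oracle():
    rng = np.random.default_rng(42)
    n = 800
    x1 = rng.standard_normal(n)
    x2 = rng.standard_normal(n)
    eta = -1.0 + 0.8 * x1 - 0.5 * x2
    y = (rng.uniform(size=n) < 1 / (1 + np.exp(-eta))).astype(float)
    table = make_table(pd.DataFrame({"response": y, "x1": x1, "x2": x2}))
    m = fit_logistic(table, ["x1", "x2"])

    X = design_matrix(table, ["x1", "x2"])

    def negloglik(beta):
        e = X @ beta
        return -(y @ e - np.logaddexp(0.0, e).sum())

    res = optimize.minimize(negloglik, np.zeros(3), method="BFGS")
    assert np.allclose(m.beta, res.x, atol=1e-4)
    assert m.llf == pytest.approx(-res.fun, abs=1e-6)
    assert m.aic == pytest.approx(2 * res.fun + 6, abs=1e-5)


def test_logistic_errors():
    df = pd.DataFrame({"response": np.r_[np.ones(20), np.zeros(100)],
                       "x": np.r_[np.ones(20), np.zeros(100)],
                       "x2": 2 * np.r_[np.ones(20), np.zeros(100)]})
    with pytest.raises(RankDeficiencyError) as exc:
        fit_logistic(make_table(df), ["x", "x2"])
    assert "x2" in exc.value.aliased
    with pytest.raises(SeparationError):
        fit_logistic(make_table(df), ["x"])  # x perfectly predicts response
    empty = pd.DataFrame({"response": np.ones(5), "x": np.arange(5.0)})
    with pytest.raises(ValueError):
        fit_logistic(make_table(empty), ["x"])


def test_model_json_round_trip(tmp_path, binary_2x2_table):
    m = fit_logistic(binary_2x2_table, ["x"])
    p = tmp_path / "m.json"
    m.to_json(p)
    back = RSFModel.from_json(p)
    assert back.terms == m.terms
    assert np.allclose(back.beta, m.beta)
    assert np.allclose(back.cov, m.cov)
    assert back.aic == m.aic


def test_conf_int_closed_form(binary_2x2_table):
    m = fit_logistic(binary_2x2_table, ["x"])
    lo, hi = m.conf_int(0.95)["x"]
    assert lo == pytest.approx(m.coef("x") - 1.959963985 * m.se_of("x"),
                               abs=1e-6)
    assert hi == pytest.approx(m.coef("x") + 1.959963985 * m.se_of("x"),
                               abs=1e-6)


# ---------------------------------------------------------------------------
# term columns

def test_term_column_interaction_and_quadratic():
    df = pd.DataFrame({"response": [1, 0, 1], "a": [1.0, 2.0, 3.0],
                       "b": [2.0, 0.5, -1.0]})
    t = make_table(df)
    assert np.allclose(term_column(t, "a:b"), [2.0, 1.0, -3.0])
    assert np.allclose(term_column(t, "a^2"), [1.0, 4.0, 9.0])
    with pytest.raises(KeyError):
        term_column(t, "zzz")


# ---------------------------------------------------------------------------
# screens

def _correlated_table(r=0.8, n=2000, seed=0, beta=(1.0, 0.0)):
    rng = np.random.default_rng(seed)
    a = rng.standard_normal(n)
    b = r * a + np.sqrt(1 - r * r) * rng.standard_normal(n)
    c = rng.standard_normal(n)
    eta = -1.5 + beta[0] * a + beta[1] * b
    y = (rng.uniform(size=n) < 1 / (1 + np.exp(-eta))).astype(float)
    return make_table(pd.DataFrame({"response": y, "a": a, "b": b, "c": c}))


def test_pearson_screen_drops_higher_aic():
    table = _correlated_table()
    retained, ledger = pearson_screen(table, ["a", "b", "c"], 0.5)
    # a drives the response, so b (higher single-variable AIC) is dropped
    assert retained == ["a", "c"]
    assert ledger.dropped_terms() == ["b"]
    assert ledger.steps[0]["action"] == "corr-screen-drop"


def test_pearson_screen_no_pairs():
    table = _correlated_table(r=0.1)
    retained, _ = pearson_screen(table, ["a", "b", "c"], 0.5)
    assert retained == ["a", "b", "c"]


def test_pearson_screen_needs_two():
    table = _correlated_table()
    with pytest.raises(ValueError):
        pearson_screen(table, ["a"], 0.5)


def test_vif_closed_form():
    rng = np.random.default_rng(1)
    n = 200000
    a = rng.standard_normal(n)
    b = 0.8 * a + 0.6 * rng.standard_normal(n)  # corr = 0.8 exactly in law
    v = vif(np.column_stack([a, b]))
    # VIF = 1 / (1 - r^2) = 1 / 0.36 = 2.778 with two columns
    assert np.allclose(v, 1.0 / (1.0 - 0.64), atol=0.05)


def test_vif_infinite_for_duplicates():
    a = np.arange(100.0)
    v = vif(np.column_stack([a, 2 * a, np.random.default_rng(0)
                             .standard_normal(100)]))
    assert np.isinf(v[0]) and np.isinf(v[1]) and np.isfinite(v[2])


def test_vif_errors():
    with pytest.raises(ValueError):
        vif(np.ones((10, 1)))
    with pytest.raises(ValueError):
        vif(np.column_stack([np.ones(10), np.arange(10.0)]))


def test_dependents_of():
    terms = ["a", "b", "a:b", "a^2", "c"]
    assert dependents_of("a", terms) == ["a:b", "a^2"]
    assert dependents_of("b", terms) == ["a:b"]
    assert dependents_of("c", terms) == []


# ---------------------------------------------------------------------------
# backward selection

def _selection_table(n=4000, seed=3):
    rng = np.random.default_rng(seed)
    a = rng.standard_normal(n)
    b = rng.standard_normal(n)
    noise = rng.standard_normal(n)
    eta = -1.5 + 1.0 * a - 0.7 * b
    y = (rng.uniform(size=n) < 1 / (1 + np.exp(-eta))).astype(float)
    return make_table(pd.DataFrame({"response": y, "a": a, "b": b,
                                    "noise": noise}))


def test_backward_select_drops_noise_keeps_signal():
    table = _selection_table()
    model, ledger = backward_select(table, ["a", "b", "noise"])
    assert set(model.terms) == {"a", "b"}
    assert "noise" in ledger.dropped_terms()
    # the final model is replayable from the ledger
    assert set(ledger.replay(["a", "b", "noise"])) == {"a", "b"}


def test_backward_select_removes_dependents_with_main_effect():
    table = _selection_table()
    model, ledger = backward_select(table, ["a", "b", "noise", "noise^2"])
    assert "noise" not in model.terms and "noise^2" not in model.terms


def test_backward_select_interaction_retention():
    # main effect near zero but a strong interaction built on it
    rng = np.random.default_rng(9)
    n = 6000
    a = rng.standard_normal(n)
    b = rng.standard_normal(n)
    eta = -1.5 + 0.9 * a + 0.9 * a * b  # b main effect truly zero
    y = (rng.uniform(size=n) < 1 / (1 + np.exp(-eta))).astype(float)
    table = make_table(pd.DataFrame({"response": y, "a": a, "b": b}))
    model, ledger = backward_select(table, ["a", "b", "a:b"])
    # the interaction is significant, so b is retained alongside it
    assert set(model.terms) == {"a", "b", "a:b"}
    assert any(s["action"] == "ci-retain-interaction" for s in ledger.steps)


def test_ledger_round_trip(tmp_path):
    ledger = SelectionLedger()
    ledger.add("importance-drop", "x", {"aic": 1.0}, "why")
    ledger.add("ci-retain-interaction", "y", {"ci": (0, 1)}, "why not")
    p = tmp_path / "ledger.csv"
    ledger.to_csv(p)
    back = pd.read_csv(p)
    assert list(back["action"]) == ["importance-drop", "ci-retain-interaction"]
    assert ledger.replay(["x", "y"]) == ["y"]


# ---------------------------------------------------------------------------
# prediction

def test_predict_rsf_closed_form():
    slope = np.array([[10.0, 20.0], [30.0, 40.0]])
    land = LandscapeStack(layers={"slope": Grid(slope, cell_size=30.0)})
    model = RSFModel(terms=["slope"], beta=np.array([-5.0, 1.1]),
                     se=np.zeros(2), cov=np.zeros((2, 2)), llf=0.0, aic=0.0,
                     n_used=1, n_available=1,
                     scaling={"slope": (10.0, 10.0)})
    w = predict_rsf(model, land).values
    # cell (0,1): scaled value (20-10)/10 = 1 -> w = e^1.1
    assert w[0, 1] == pytest.approx(np.exp(1.1), abs=1e-12)
    assert w[0, 1] == pytest.approx(3.0041660239, abs=1e-6)
    # intercept is omitted: a different intercept gives the same surface
    model2 = RSFModel(terms=["slope"], beta=np.array([3.0, 1.1]),
                      se=np.zeros(2), cov=np.zeros((2, 2)), llf=0.0, aic=0.0,
                      n_used=1, n_available=1,
                      scaling={"slope": (10.0, 10.0)})
    assert np.allclose(predict_rsf(model2, land).values, w)


def test_predict_rsf_missing_propagates():
    slope = np.array([[10.0, np.nan], [30.0, 40.0]])
    land = LandscapeStack(layers={"slope": Grid(slope, cell_size=30.0)})
    model = RSFModel(terms=["slope"], beta=np.array([0.0, 1.0]),
                     se=np.zeros(2), cov=np.zeros((2, 2)), llf=0.0, aic=0.0,
                     n_used=1, n_available=1, scaling={"slope": (0.0, 1.0)})
    w = predict_rsf(model, land).values
    assert np.isnan(w[0, 1]) and np.isfinite(w[1, 1])


def test_predict_rsf_requires_scaling():
    land = LandscapeStack(layers={"slope": Grid(np.ones((3, 3)))})
    model = RSFModel(terms=["slope"], beta=np.array([0.0, 1.0]),
                     se=np.zeros(2), cov=np.zeros((2, 2)), llf=0.0, aic=0.0,
                     n_used=1, n_available=1, scaling={})
    with pytest.raises(ValueError, match="scaling"):
        predict_rsf(model, land)
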