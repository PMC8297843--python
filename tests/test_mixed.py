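"""Mixed-effects RSF (random pack intercept + road slope) and the
road functional-response trend."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from habsel import preprocess, synthetic
from habsel.mixed import (MixedRSFModel, fit_mixed_logistic,
                          functional_response, pack_road_odds)
from habsel.preprocess import UsedAvailableTable
from habsel.rsf import design_matrix

from conftest import make_table


def _scenario_table(seed, n_packs=6, a=-0.5, b=0.6, n_per=600,
                    floor=0.25):
    """Functional-response scenario telemetry assembled into a table."""
    rng = np.random.default_rng(seed)
    landscape, _ = synthetic.gen_landscape(seed=int(rng.integers(2 ** 31)),
                                           n_roads=16)
    telemetry, truth = synthetic.gen_functional_response_scenario(
        landscape, n_packs=n_packs, a=a, b=b,
        config=synthetic.SimConfig(seed=int(rng.integers(2 ** 31)),
                                   n_locations_per_animal=n_per),
        min_mean_road_density=floor)
    avail = []
    for pid, sub in telemetry.groupby("pack_id"):
        row = truth[truth.pack_id == pid].iloc[0]
        pack = synthetic.PackSpec(
            pack_id=str(pid),
            territory_center=(row["center_x"], row["center_y"]),
            territory_radius=float(row["territory_radius"]))
        av = synthetic.sample_territory_uniform(landscape, pack,
                                                5 * len(sub), rng)
        av["animal_id"] = f"{pid}-pooled"
        avail.append(av)
    table = preprocess.assemble_table(
        telemetry, pd.concat(avail, ignore_index=True), landscape)
    return table, truth


TERMS = ["slope", "tpi", "road_density"]


# ---------------------------------------------------------------------------
# odds rescaling and the trend regression (closed forms)

def _toy_model(modes, scaling_sd=2.0):
    return MixedRSFModel(
        fixed_terms=["road_density"], beta=np.array([-2.0, 0.2]),
        se=np.zeros(2), var_intercept=0.0, var_road=0.01,
        pack_ids=["p1", "p2"], modes=np.asarray(modes, dtype=float),
        scaling={"road_density": (1.0, scaling_sd)})


def test_pack_road_odds_rescales_to_raw_units():
    m = _toy_model([[0.0, 0.0], [0.0, 0.2]])
    odds = pack_road_odds(m)
    # p1: scaled coef 0.2, sd 2 -> per-raw-unit 0.1 -> odds e^0.1
    assert odds["p1"] == pytest.approx(np.exp(0.1), abs=1e-12)
    # p2 adds its conditional mode: (0.2 + 0.2)/2 = 0.2
    assert odds["p2"] == pytest.approx(np.exp(0.2), abs=1e-12)


def test_pack_road_odds_requires_scaling():
    m = _toy_model([[0.0, 0.0], [0.0, 0.0]])
    m.scaling = {}
    with pytest.raises(ValueError, match="scaling"):
        pack_road_odds(m)


def test_functional_response_closed_form():
    odds = pd.Series([1.0, 1.2, 1.4], index=["p1", "p2", "p3"])
    avail = pd.Series([1.0, 2.0, 3.0], index=["p1", "p2", "p3"])
    fr = functional_response(odds, avail)
    assert fr.slope == pytest.approx(0.2, abs=1e-12)
    assert fr.intercept == pytest.approx(0.8, abs=1e-12)
    assert fr.percent_change_per_unit == pytest.approx(20.0, abs=1e-10)
    assert np.allclose(fr.per_pack["road_beta_per_unit"],
                       np.log(odds.to_numpy()))


def test_functional_response_aligns_on_index():
    odds = pd.Series([1.4, 1.0, 1.2], index=["p3", "p1", "p2"])
    avail = pd.Series([2.0, 3.0, 1.0], index=["p2", "p3", "p1"])
    fr = functional_response(odds, avail)
    assert fr.slope == pytest.approx(0.2, abs=1e-12)


def test_functional_response_errors():
    with pytest.raises(ValueError, match="at least 3"):
        functional_response(pd.Series([1.0, 1.2], index=["a", "b"]),
                            pd.Series([1.0, 2.0], index=["a", "b"]))
    odds = pd.Series([1.0, 1.2, 1.4], index=["a", "b", "c"])
    flat = pd.Series([1.0, 1.0, 1.0], index=["a", "b", "c"])
    with pytest.raises(ValueError, match="gradient"):
        functional_response(odds, flat)


# ---------------------------------------------------------------------------
# fit validation

def _hand_table(n_packs):
    rng = np.random.default_rng(0)
    n = 200 * n_packs
    road = rng.standard_normal(n)
    y = (rng.uniform(size=n) < 0.2).astype(float)
    df = pd.DataFrame({"response": y, "road_density": road,
                       "pack_id": np.repeat([f"p{i}" for i in range(n_packs)],
                                            200)})
    return make_table(df, scaling={"road_density": (0.0, 1.0)})


def test_fit_mixed_requires_random_term_in_fixed():
    with pytest.raises(ValueError, match="fixed terms"):
        fit_mixed_logistic(_hand_table(4), ["slope"])


def test_fit_mixed_requires_enough_packs():
    with pytest.raises(ValueError, match="more than one pack"):
        fit_mixed_logistic(_hand_table(1), ["road_density"])
    with pytest.raises(ValueError, match="at least 3"):
        fit_mixed_logistic(_hand_table(2), ["road_density"])


# ---------------------------------------------------------------------------
# linear predictor

def test_linear_predictor_closed_form():
    df = pd.DataFrame({"response": [1.0, 0.0, 1.0, 0.0],
                       "road_density": [0.5, -0.5, 1.0, -1.0],
                       "pack_id": ["p1", "p1", "p2", "p2"]})
    table = make_table(df, scaling={"road_density": (0.0, 1.0)})
    m = MixedRSFModel(
        fixed_terms=["road_density"], beta=np.array([-1.0, 0.4]),
        se=np.zeros(2), var_intercept=0.1, var_road=0.1,
        pack_ids=["p1", "p2"],
        modes=np.array([[0.3, -0.2], [0.0, 0.0]]),
        scaling={"road_density": (0.0, 1.0)})
    eta = m.linear_predictor(table)
    # p1 rows: -1 + 0.4 z + 0.3 - 0.2 z; p2 rows: fixed only
    assert eta == pytest.approx([-1 + 0.4 * 0.5 + 0.3 - 0.2 * 0.5,
                                 -1 - 0.4 * 0.5 + 0.3 + 0.2 * 0.5,
                                 -1 + 0.4, -1 - 0.4], abs=1e-12)


def test_zero_modes_give_fixed_effects_predictions():
    table, _ = _scenario_table(seed=11, n_packs=4, n_per=200)
    mm = fit_mixed_logistic(table, TERMS, method="two-stage")
    mm.modes = np.zeros_like(mm.modes)
    eta = mm.linear_predictor(table)
    fixed = design_matrix(table, mm.fixed_terms) @ mm.beta
    assert np.allclose(eta, fixed, atol=1e-6)


# ---------------------------------------------------------------------------
# estimator behaviour on simulated scenarios

def test_identical_packs_have_near_zero_modes():
    table, _ = _scenario_table(seed=5, n_packs=4, n_per=300)
    one = table.df[table.df["pack_id"] == table.df["pack_id"].iloc[0]]
    copies = pd.concat([one.assign(pack_id=f"copy{i}") for i in range(4)],
                       ignore_index=True)
    big = UsedAvailableTable(df=copies, scaling=table.scaling,
                             reference_level=table.reference_level,
                             cover_levels=table.cover_levels)
    mm = fit_mixed_logistic(big, TERMS, method="laplace")
    assert np.max(np.abs(mm.modes)) < 0.05


def test_zero_between_pack_variance_recovered(landscape):
    # 10 packs drawn independently from one shared territory and one
    # shared selection model: the true between-pack variances are exactly
    # zero (distinct territories would differ in their availability
    # normalisation, i.e. a genuine intercept variance), so both fitted
    # variances should collapse (10 packs x ~2,000 rows each)
    rng = np.random.default_rng(21)
    model = synthetic.TrueModel(TERMS, [-0.05, -0.006, -0.4])
    center = (3000.0, 3000.0)
    packs = [synthetic.PackSpec(f"p{i:02d}", center, 1500.0)
             for i in range(10)]
    telemetry = synthetic.gen_tracks(
        landscape, packs, model,
        synthetic.SimConfig(seed=21, n_locations_per_animal=333))
    avail = []
    for p in packs:
        av = synthetic.sample_territory_uniform(landscape, p, 5 * 333, rng)
        av["animal_id"] = f"{p.pack_id}-pooled"
        avail.append(av)
    table = preprocess.assemble_table(
        telemetry, pd.concat(avail, ignore_index=True), landscape)
    mm = fit_mixed_logistic(table, TERMS, method="laplace")
    assert mm.var_intercept < 0.05
    assert mm.var_road < 0.05


def test_laplace_and_two_stage_agree_on_road_effect():
    table, _ = _scenario_table(seed=7, n_packs=6, n_per=600)
    la = fit_mixed_logistic(table, TERMS, method="laplace")
    ts = fit_mixed_logistic(table, TERMS, method="two-stage")
    assert la.method == "laplace" and ts.method == "two-stage"
    assert abs(la.coef("road_density") - ts.coef("road_density")) < 0.1


def test_unshrunk_modes_are_raw_per_pack_estimates():
    table, _ = _scenario_table(seed=13, n_packs=5, n_per=400)
    shrunk = fit_mixed_logistic(table, TERMS, method="two-stage")
    raw = fit_mixed_logistic(table, TERMS, method="two-stage-unshrunk")
    assert raw.method == "two-stage-unshrunk"
    # shrinkage pulls every pack toward the mean, so the unshrunk
    # coefficients have at least the shrunk coefficients' spread
    spread_raw = np.ptp(raw.pack_road_coef().to_numpy())
    spread_shrunk = np.ptp(shrunk.pack_road_coef().to_numpy())
    assert spread_raw >= spread_shrunk - 1e-12
    # both center on the same random-effects mean
    assert abs(raw.coef("road_density") - shrunk.coef("road_density")) < 1e-9


def test_conditional_modes_track_true_coefficients():
    """Per-pack road coefficients rank-correlate with the generating
    coefficients (mean Spearman r over 20 seeds)."""
    rs = []
    for seed in range(20):
        table, truth = _scenario_table(seed=seed, n_packs=13, n_per=600)
        mm = fit_mixed_logistic(table, TERMS, method="laplace")
        est = mm.pack_road_coef(scaled=False).sort_index()
        tr = truth.set_index("pack_id")["true_road_beta"].sort_index()
        rs.append(spearmanr(est.to_numpy(), tr.to_numpy()).statistic)
    assert np.mean(rs) > 0.8
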