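"""Microscopic chain: contacts, travel time, speed model, limit flow."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from anttraffic.exceptions import ConfigurationError, DataFormatError
from anttraffic.microscopic import (
    MicroParams,
    SpeedModelRegressor,
    fit_contact_rate,
    fit_microscopic,
    fit_speed_model,
    fit_travel_time,
    free_flow_speed,
    limit_flow,
    pheromone_factor,
    predict_flow,
    speed_model,
    travel_time_curves,
)
from anttraffic.synthetic_data import GeneratorConfig, generate_tracked


# ---------------------------------------------------------------------------
# closed forms


def test_speed_at_zero_density(params):
    assert speed_model(0.0, params) == pytest.approx(2 * 0.812 / 0.95, rel=1e-9)


def test_limit_flow_closed_form(params):
    assert round(limit_flow(params), 2) == 11.09
    half = MicroParams(alpha=params.alpha / 2)
    assert limit_flow(half) == pytest.approx(limit_flow(params) / 2)


def test_flow_plateau_value(params):
    """The predicted flow on the plateau rounds to 10 ants/cm/s."""
    assert round(predict_flow(14.0, params)) == 10


def test_limit_flow_is_numeric_limit_of_predicted_flow(params):
    assert predict_flow(1e6, params) == pytest.approx(limit_flow(params), rel=1e-3)
    k = np.linspace(50, 200, 16)
    gap = np.abs(predict_flow(k, params) - limit_flow(params))
    assert np.all(np.diff(gap) < 0)  # sup gap shrinks as k grows


def test_flow_rises_then_plateaus(params):
    k = np.linspace(0, 8, 200)
    assert np.all(np.diff(predict_flow(k, params)) > 0)
    plateau = predict_flow(np.linspace(10, 18, 100), params)
    assert np.ptp(plateau) / plateau.mean() < 0.10


@given(gamma=st.floats(0.02, 1.0))
@settings(max_examples=50, deadline=None)
def test_pheromone_factor_peaks_at_inverse_gamma(gamma):
    """k*exp(-gamma*k) is maximal at exactly k = 1/gamma."""
    p = MicroParams(gamma=gamma)
    k = np.linspace(0, 5 / gamma, 2000)
    assert np.all(pheromone_factor(1 / gamma, p) >= pheromone_factor(k, p))


def test_beta_zero_reduces_to_pure_contact_friction(params):
    p = MicroParams(beta=1e-12)
    k = np.linspace(0, 40, 400)
    assert np.all(np.diff(speed_model(k, p)) < 0)
    q = predict_flow(k, p)
    assert np.all(np.diff(q) > 0)
    assert predict_flow(1e6, p) == pytest.approx(
        2 * 0.812 / (0.24 * 0.61), rel=1e-3
    )


def test_free_flow_speed_cases():
    assert free_flow_speed(0.95, 0) == pytest.approx(2 / 0.95)
    # contact-corrected crossing equals the contact-free one
    assert free_flow_speed(1.43, 2) == pytest.approx(2 / 0.95)
    assert np.isnan(free_flow_speed(0.4, 2))  # overcorrected: invalid record
    v = free_flow_speed([0.95, 0.4], [0, 2])
    assert np.isnan(v).sum() == 1


# ---------------------------------------------------------------------------
# regressions: planted-parameter oracles


def test_noiseless_contact_rate_recovered_exactly(tracked_noiseless):
    fit = fit_contact_rate(tracked_noiseless)
    assert fit.slope_ == pytest.approx(0.61, rel=1e-9)


def test_all_zero_contacts_give_zero_slope():
    df = pd.DataFrame(
        {"k_local": np.linspace(0.1, 10, 50), "C": 0.0, "T": 1.0, "uturn": False}
    )
    assert fit_contact_rate(df).slope_ == pytest.approx(0.0)


def test_noiseless_travel_time_recovered_exactly(params):
    cfg = GeneratorConfig(
        seed=2, travel_noise_sd=0.0, pheromone=False, uturn_prob=0.0
    )
    df = generate_tracked(2000, params=params, config=cfg)
    fit = fit_travel_time(df)
    assert fit.intercept_ == pytest.approx(0.95, rel=1e-9)
    assert fit.slope_ == pytest.approx(0.24, rel=1e-9)
    assert fit.r2_ == pytest.approx(1.0)


def test_noiseless_speed_model_recovered_to_1e6(tracked_noiseless):
    fit = fit_speed_model(tracked_noiseless)
    assert fit.alpha_ == pytest.approx(0.812, rel=1e-6)
    assert fit.beta_ == pytest.approx(0.160, rel=1e-6)
    assert fit.gamma_ == pytest.approx(0.156, rel=1e-6)


def test_noisy_recovery_within_three_se(tracked_noisy, params):
    cr = fit_contact_rate(tracked_noisy)
    assert abs(cr.slope_ - params.c) < 3 * cr.se_

    cfg = GeneratorConfig(seed=1, pheromone=False)
    df = generate_tracked(8000, params=params, config=cfg)
    tt = fit_travel_time(df)
    assert abs(tt.intercept_ - params.T0) < 3 * tt.se_intercept_
    assert abs(tt.slope_ - params.dT) < 3 * tt.se_slope_

    sp = fit_speed_model(tracked_noisy)
    for est, truth, se in zip(
        (sp.alpha_, sp.beta_, sp.gamma_),
        (params.alpha, params.beta, params.gamma),
        sp.se_,
    ):
        assert abs(est - truth) < 3 * se


def test_end_to_end_recovery_of_all_planted_constants(params):
    """generate -> contact fit + travel fit + speed fit reproduces the
    seven planted constants from one synthetic campaign."""
    cr = fit_contact_rate(
        generate_tracked(8000, params=params, config=GeneratorConfig(seed=21))
    )
    tt = fit_travel_time(
        generate_tracked(
            8000, params=params, config=GeneratorConfig(seed=22, pheromone=False)
        )
    )
    sp = fit_speed_model(
        generate_tracked(8000, params=params, config=GeneratorConfig(seed=23)),
        fixed=params,
    )
    assert abs(cr.slope_ - params.c) < 3 * cr.se_
    assert abs(tt.intercept_ - params.T0) < 3 * tt.se_intercept_
    assert abs(tt.slope_ - params.dT) < 3 * tt.se_slope_
    for est, truth, se in zip(
        (sp.alpha_, sp.beta_, sp.gamma_),
        (params.alpha, params.beta, params.gamma),
        sp.se_,
    ):
        assert abs(est - truth) < 3 * se


def test_uturn_records_are_excluded(tracked_noiseless):
    poisoned = tracked_noiseless.copy()
    extra = poisoned.iloc[:100].copy()
    extra["T"] = 1e6
    extra["uturn"] = True
    poisoned = pd.concat([poisoned, extra], ignore_index=True)
    assert fit_travel_time(poisoned).intercept_ == pytest.approx(
        fit_travel_time(tracked_noiseless).intercept_
    )


def test_degenerate_regression_inputs_raise():
    df = pd.DataFrame(
        {"k_local": np.zeros(50), "C": np.zeros(50), "T": 1.0, "uturn": False}
    )
    with pytest.raises(DataFormatError):
        fit_contact_rate(df)
    with pytest.raises(DataFormatError):
        fit_travel_time(df)  # constant C: slope unidentifiable
    with pytest.raises(DataFormatError):
        fit_speed_model(df)  # no density spread
    with pytest.raises(DataFormatError):
        SpeedModelRegressor().fit(np.linspace(0, 16, 10), np.ones(10))


def test_invalid_params_rejected():
    with pytest.raises(ConfigurationError):
        MicroParams(T0=-1.0)
    with pytest.raises(ConfigurationError):
        speed_model(-1.0)


# ---------------------------------------------------------------------------
# stratified travel-time curves


def test_travel_time_curve_minimum_near_inverse_gamma(params):
    cfg = GeneratorConfig(seed=9, travel_noise_sd=0.0, uturn_prob=0.0)
    df = generate_tracked(30000, params=params, config=cfg)
    curves = travel_time_curves(df, contact_levels=[1, 2, 3])
    for _, grp in curves.groupby("C"):
        k_min = grp.loc[grp["T_fit"].idxmin(), "k"]
        assert abs(k_min - 1 / params.gamma) < 1.0


def test_travel_time_curves_ordered_by_contact_level(params):
    cfg = GeneratorConfig(seed=9, travel_noise_sd=0.0, uturn_prob=0.0)
    df = generate_tracked(30000, params=params, config=cfg)
    grid = None
    curves = travel_time_curves(df, contact_levels=[1, 2], n_grid=25)
    c1 = curves[curves["C"] == 1].set_index("k")["T_fit"]
    c2 = curves[curves["C"] == 2].set_index("k")["T_fit"]
    shared = np.linspace(max(c1.index.min(), c2.index.min()) + 0.5,
                         min(c1.index.max(), c2.index.max()) - 0.5, 10)
    hi = np.interp(shared, c2.index, c2.values)
    lo = np.interp(shared, c1.index, c1.values)
    assert np.all(hi > lo)


def test_flat_stratum_yields_flat_curve():
    rng = np.random.default_rng(0)
    df = pd.DataFrame(
        {
            "k_local": rng.uniform(0, 10, 200),
            "C": 2.0,
            "T": 1.43,
            "uturn": False,
        }
    )
    curves = travel_time_curves(df, contact_levels=[2])
    np.testing.assert_allclose(curves["T_fit"], 1.43, rtol=1e-8)


def test_sparse_stratum_skipped_with_warning(tracked_noisy):
    with pytest.warns(UserWarning, match="skipped"):
        curves = travel_time_curves(tracked_noisy, contact_levels=[0, 200])
    assert set(curves["C"]) == {0}
    with pytest.raises(DataFormatError):
        travel_time_curves(tracked_noisy, contact_levels=[999])


def test_fit_microscopic_bundles_all_estimates(tracked_noisy):
    mf = fit_microscopic(tracked_noisy)
    assert mf.n == (~tracked_noisy["uturn"]).sum()
    assert 0 <= mf.c_r2 <= 1 and 0 <= mf.tt_r2 <= 1
    d = mf.to_dict()
    assert {"c_hat", "T0_hat", "dT_hat", "alpha_hat"} <= set(d)
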