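"""Gamma meta-regression of CRPS: null recovery, marginal effects, prob-best."""

import math

import numpy as np
import pandas as pd
import pytest

from gagrowth.errors import GagrowthError
from gagrowth.inference import SamplerConfig
from gagrowth.metareg import (
    MetaPosterior,
    MetaRegressionSpec,
    fit_crps_regression,
    marginal_effect,
    probability_best,
)

FAST = SamplerConfig(warmup=300, draws=250, max_store_draws=800)


def _null_records(seed, n_pat=20, mean_crps=0.5):
    rng = np.random.default_rng(seed)
    rows = []
    for p in range(n_pat):
        for t in range(2):
            h = rng.gamma(2.0, 0.35)
            v = 5 + int(rng.poisson(2))
            for m in ("gompertz", "linear"):
                rows.append(
                    dict(
                        patient_id=f"P{p}",
                        eye_id="OD",
                        model=m,
                        horizon=h,
                        n_prior_visits=v,
                        crps=float(rng.gamma(2.0, mean_crps / 2.0)),
                    )
                )
    return pd.DataFrame(rows)


def _point_posterior(beta0_rows, beta_h=None, models=("a", "b")):
    """MetaPosterior with hand-set coefficient draws (no fitting)."""
    b0 = np.asarray(beta0_rows, dtype=float)
    S, M = b0.shape
    bh = np.zeros((S, M)) if beta_h is None else np.asarray(beta_h, dtype=float)
    return MetaPosterior(
        models=tuple(models),
        draws={
            "beta0": b0,
            "beta_h": bh,
            "beta_v": np.zeros((S, M)),
            "tau_patient": np.full(S, 0.1),
            "tau_eye": np.full(S, 0.1),
            "alpha": np.full(S, 2.0),
        },
        horizon_sd=0.66,
        visits_sd=2.0,
        chain=np.zeros((1, 2, 1)),
        meta={"chains": 2},
    )


def test_null_data_intercept_matches_sample_mean():
    df = _null_records(0)
    post = fit_crps_regression(df, sampler_config=FAST, seed=4)
    target = math.log(df["crps"].mean())
    for i in range(len(post.models)):
        assert np.mean(post.draws["beta0"][:, i]) == pytest.approx(target, abs=0.25)
    # slopes centered near zero when nothing was planted
    assert abs(np.mean(post.draws["beta_h"])) < 0.15
    assert abs(np.mean(post.draws["beta_v"])) < 0.15


def test_fit_reproducible_given_seed():
    df = _null_records(1, n_pat=10)
    p1 = fit_crps_regression(df, sampler_config=FAST, seed=7)
    p2 = fit_crps_regression(df, sampler_config=FAST, seed=7)
    assert np.array_equal(p1.chain, p2.chain)


def test_marginal_effect_inverts_point_coefficients_exactly():
    post = _point_posterior(
        beta0_rows=np.zeros((5, 2)),
        beta_h=np.full((5, 2), math.log(1.46)),
    )
    eff = marginal_effect(post, "horizon")
    assert np.allclose(eff["pct_change_mean"], 46.0, atol=1e-9)
    zero = marginal_effect(
        _point_posterior(np.zeros((5, 2))), "horizon"
    )
    assert np.allclose(zero["pct_change_mean"], 0.0, atol=1e-12)
    # exp-linearity in delta: effect(2 SD) = (1 + effect(1 SD))^2 - 1
    one = marginal_effect(post, "horizon", delta_in_sd=1.0)["pct_change_mean"].iloc[0]
    two = marginal_effect(post, "horizon", delta_in_sd=2.0)["pct_change_mean"].iloc[0]
    assert two / 100.0 == pytest.approx((1 + one / 100.0) ** 2 - 1, rel=1e-12)
    with pytest.raises(GagrowthError):
        marginal_effect(post, "age")


def test_probability_best_ties_sum_and_scale_invariance():
    tied = _point_posterior(np.zeros((50, 2)))
    probs = probability_best(tied)
    assert probs["a"] == pytest.approx(0.5) and probs["b"] == pytest.approx(0.5)
    rng = np.random.default_rng(0)
    b0 = rng.normal(0.0, 0.3, size=(200, 3))
    post = _point_posterior(b0, models=("x", "y", "z"))
    probs = probability_best(post)
    assert sum(probs.values()) == pytest.approx(1.0, abs=1e-12)
    # common multiplicative rescaling of CRPS shifts all intercepts equally
    shifted = _point_posterior(b0 + math.log(3.7), models=("x", "y", "z"))
    assert probability_best(shifted) == probs


def test_planted_advantage_wins_decisively():
    rng = np.random.default_rng(1)
    b0 = np.column_stack(
        [rng.normal(math.log(0.35), 0.03, 400), rng.normal(math.log(0.5), 0.03, 400)]
    )
    probs = probability_best(_point_posterior(b0))
    assert probs["a"] > 0.99


def test_input_validation():
    df = _null_records(2)
    single = df[df.model == "gompertz"]
    with pytest.raises(GagrowthError):
        fit_crps_regression(single, sampler_config=FAST, seed=0)
    neg = df.copy()
    neg.loc[neg.index[0], "crps"] = -0.1
    with pytest.raises(GagrowthError, match="negative CRPS"):
        fit_crps_regression(neg, sampler_config=FAST, seed=0)
    with pytest.raises(GagrowthError):
        fit_crps_regression(df.drop(columns=["horizon"]), sampler_config=FAST, seed=0)


def test_zero_crps_floored_into_gamma_support():
    df = _null_records(3, n_pat=8)
    df.loc[df.index[0], "crps"] = 0.0
    post = fit_crps_regression(df, sampler_config=FAST, seed=2)
    assert np.all(post.draws["alpha"] > 0)
    assert MetaRegressionSpec().crps_floor == 1e-6
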