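"""Growth laws: mean/rate identities, derivative oracles, landmarks, priors."""

import math

import numpy as np
import pytest

from gagrowth.errors import ConfigError, DomainError
from gagrowth.models import (
    MODELS,
    default_priors,
    get_model,
    growth_rate,
    landmarks,
    mean_area,
)

GOMP = {"K": 10.0, "b": 3.0, "c": 0.5}
LOGI = {"K": 8.0, "r": 1.0, "t0": 2.0}

CASES = {
    "gompertz": GOMP,
    "logistic": LOGI,
    "linear": {"a": 1.0, "s": 2.0},
    "effective_radius": {"a": 1.0, "s": 0.5},
    "von_bertalanffy": {"K": 10.0, "k": 0.5, "t0": -1.0},
    "mitscherlich": {"K": 10.0, "k": 0.4, "t0": -0.5},
}


def test_mean_examples():
    g = get_model("gompertz")
    assert mean_area(g, GOMP, 200.0) == pytest.approx(10.0, rel=1e-12)
    assert mean_area(g, GOMP, 0.0) == pytest.approx(10.0 * math.exp(-3.0), rel=1e-12)
    lo = get_model("logistic")
    assert mean_area(lo, LOGI, 2.0) == pytest.approx(4.0, rel=1e-12)
    er = get_model("effective_radius")
    assert mean_area(er, {"a": 1.0, "s": 0.5}, 2.0) == pytest.approx(4.0, rel=1e-12)
    li = get_model("linear")
    assert np.allclose(mean_area(li, {"a": 1.0, "s": 2.0}, [0, 1, 2]), [1, 3, 5])
    # clipped at zero before onset
    assert mean_area(li, {"a": -1.0, "s": 2.0}, 0.0) == 0.0


def test_rate_closed_form_examples():
    g = get_model("gompertz")
    t_peak = math.log(GOMP["b"]) / GOMP["c"]
    assert growth_rate(g, GOMP, t_peak) == pytest.approx(
        GOMP["K"] * GOMP["c"] / math.e, rel=1e-12
    )
    lo = get_model("logistic")
    assert growth_rate(lo, LOGI, LOGI["t0"]) == pytest.approx(
        LOGI["K"] * LOGI["r"] / 4.0, rel=1e-12
    )
    li = get_model("linear")
    assert growth_rate(li, {"a": 1.0, "s": 2.0}, 17.3) == 2.0


@pytest.mark.parametrize("name", sorted(MODELS))
def test_rate_matches_finite_difference(name):
    """The declared rate is the derivative of the mean everywhere tested."""
    spec = get_model(name)
    params = CASES[name]
    h = 1e-6
    for t in np.linspace(0.3, 9.7, 23):
        fd = (spec.mean(t + h, params) - spec.mean(t - h, params)) / (2 * h)
        assert spec.rate(t, params) == pytest.approx(fd, rel=1e-5, abs=1e-7)


@pytest.mark.parametrize("name", sorted(MODELS))
def test_fit_scale_gradients_match_finite_difference(name):
    """Analytic parameter gradients of the fit-scale mean (used by HMC)."""
    spec = get_model(name)
    params = {k: float(v) for k, v in CASES[name].items()}
    t = np.linspace(0.2, 8.0, 9)
    m0, grads = spec.fit_mean_and_grad(t, params)
    assert np.allclose(m0, spec.fit_mean(t, params))
    for j, (nat, tr) in enumerate(zip(spec.natural_params, spec.transformed_params)):
        h = 1e-6
        pp = dict(params)
        pm = dict(params)
        if tr.startswith("log"):
            pp[nat] = params[nat] * math.exp(h)
            pm[nat] = params[nat] * math.exp(-h)
        else:
            pp[nat] = params[nat] + h
            pm[nat] = params[nat] - h
        fd = (spec.fit_mean(t, pp) - spec.fit_mean(t, pm)) / (2 * h)
        assert np.allclose(np.broadcast_to(grads[j], t.shape), fd, rtol=1e-4, atol=1e-6)


def test_gompertz_landmark_closed_forms():
    g = get_model("gompertz")
    lm = landmarks(g, GOMP)
    b, c = GOMP["b"], GOMP["c"]
    assert lm.t_peak_rate == pytest.approx(math.log(b) / c, abs=1e-10)
    # rate-curve inflections solve u^2 - 3u + 1 = 0 with u = b e^{-ct}
    u_hi = (3 + math.sqrt(5)) / 2
    u_lo = (3 - math.sqrt(5)) / 2
    assert lm.t_accel == pytest.approx(math.log(b / u_hi) / c, abs=1e-6)
    assert lm.t_decel == pytest.approx(math.log(b / u_lo) / c, abs=1e-6)
    assert lm.t_accel < lm.t_peak_rate < lm.t_decel
    # area at peak growth equals K / e (analytic identity)
    assert mean_area(g, GOMP, lm.t_peak_rate) == pytest.approx(
        GOMP["K"] / math.e, rel=1e-10
    )


def test_logistic_landmark_closed_forms():
    lo = get_model("logistic")
    lm = landmarks(lo, LOGI)
    assert lm.t_peak_rate == pytest.approx(LOGI["t0"], abs=1e-10)
    offset = math.log(2 + math.sqrt(3)) / LOGI["r"]
    assert lm.t_accel == pytest.approx(LOGI["t0"] - offset, abs=1e-6)
    assert lm.t_decel == pytest.approx(LOGI["t0"] + offset, abs=1e-6)
    assert mean_area(lo, LOGI, lm.t_peak_rate) == pytest.approx(
        LOGI["K"] / 2.0, rel=1e-10
    )


def test_von_bertalanffy_numeric_peak_matches_closed_form():
    vb = get_model("von_bertalanffy")
    p = CASES["von_bertalanffy"]
    lm = landmarks(vb, p)
    assert lm.t_peak_rate == pytest.approx(p["t0"] + math.log(3) / p["k"], abs=1e-6)


def test_unbounded_models_have_no_landmarks():
    for name in ("linear", "effective_radius"):
        lm = landmarks(get_model(name), CASES[name])
        assert lm.t_peak_rate is None and lm.t_accel is None and lm.t_decel is None
        assert lm.asymptote == math.inf


def test_gompertz_mean_increasing_and_rate_unimodal():
    g = get_model("gompertz")
    t = np.linspace(-2, 30, 600)
    m = g.mean(t, GOMP)
    assert np.all(np.diff(m) > 0)
    r = g.rate(t, GOMP)
    peak = int(np.argmax(r))
    assert np.all(np.diff(r[: peak + 1]) > 0) and np.all(np.diff(r[peak:]) < 0)


def test_domain_errors():
    g = get_model("gompertz")
    with pytest.raises(DomainError):
        mean_area(g, {"K": -1.0, "b": 3.0, "c": 0.5}, 1.0)
    with pytest.raises(DomainError):
        growth_rate(g, {"K": 10.0, "b": 3.0}, 1.0)
    with pytest.raises(ConfigError):
        get_model("spline")


def test_default_priors_cover_every_parameter():
    summary = {"max_area": 20.0, "t_span": 8.0}
    for name, spec in MODELS.items():
        ps = default_priors(spec, summary)
        assert set(ps.params) == set(spec.transformed_params)
        assert ps.noise_sd.family == "halfnormal" and ps.noise_sd.scale == 1.0
    # asymptote prior truncated at 4x the largest observed lesion
    gp = default_priors(get_model("gompertz"), summary)
    assert gp.params["logK"].upper == pytest.approx(math.log(80.0))
    lp = default_priors(get_model("linear"), summary)
    assert lp.params["s"].loc == 0.0 and lp.params["s"].scale == 5.0
    # serialization round-trip stays plain data
    d = gp.to_dict()
    assert d["params"]["logK"]["upper"] == pytest.approx(math.log(80.0))
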