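"""Hierarchical fits: exact recovery, determinism, predictive draws, diagnostics."""

import numpy as np
import pytest
from scipy import stats

from gagrowth.errors import GagrowthError
from gagrowth.inference import (
    HierarchySpec,
    PosteriorDraws,
    SamplerConfig,
    convergence_check,
    fit_hierarchical,
    posterior_predictive,
)
from gagrowth.models import get_model

from conftest import make_linear_cohort

FAST = SamplerConfig(warmup=200, draws=150, path_factor_max=6.0, max_store_draws=400)


@pytest.fixture(scope="module")
def linear_fit():
    cohort = make_linear_cohort(seed=0, n_eyes=1, n_visits=7, sigma=0.0)
    spec = get_model("linear")
    post = fit_hierarchical(cohort, spec, sampler_config=FAST, seed=3)
    return cohort, spec, post


def test_single_eye_noiseless_linear_recovery(linear_fit):
    """A noiseless a=1, s=2 series is recovered almost exactly."""
    _, _, post = linear_fit
    eye = post.draws["eye_transformed"][:, 0, :]  # (S, [a, s])
    assert abs(np.mean(eye[:, 0]) - 1.0) < 0.05
    assert abs(np.mean(eye[:, 1]) - 2.0) < 0.05
    assert np.mean(post.draws["sigma"]) < 0.1


def test_fit_is_deterministic_given_seed():
    cohort = make_linear_cohort(seed=1, n_eyes=1, n_visits=6, sigma=0.1)
    spec = get_model("linear")
    p1 = fit_hierarchical(cohort, spec, sampler_config=FAST, seed=9)
    p2 = fit_hierarchical(cohort, spec, sampler_config=FAST, seed=9)
    assert np.array_equal(p1.chain, p2.chain)
    assert np.array_equal(p1.loglik, p2.loglik)


def test_posterior_predictive_tracks_truth_and_noise(linear_fit):
    _, spec, post = linear_fit
    times = np.array([0.0, 1.0, 2.0])
    pred = posterior_predictive(post, spec, ("P00", "OD"), times, seed=1)
    assert pred.shape == (post.n_draws, 3)
    med = np.median(pred, axis=0)
    assert np.allclose(med, 1.0 + 2.0 * times, atol=0.1)
    # without observation noise the draws collapse onto the fitted mean curve
    mean_only = posterior_predictive(
        post, spec, ("P00", "OD"), times, seed=1, include_noise=False
    )
    assert np.std(mean_only, axis=0).max() < np.std(pred, axis=0).max()
    assert np.all(pred >= 0)


def test_posterior_predictive_unknown_eye_requires_flag(linear_fit):
    _, spec, post = linear_fit
    with pytest.raises(KeyError):
        posterior_predictive(post, spec, ("PX", "OD"), [1.0])
    new = posterior_predictive(post, spec, None, [1.0], seed=2, new_eye=True)
    assert new.shape == (post.n_draws, 1) and np.all(new >= 0)


def test_effective_radius_predictive_nonnegative():
    cohort = make_linear_cohort(seed=2, n_eyes=2, n_visits=6, sigma=0.1)
    spec = get_model("effective_radius")
    post = fit_hierarchical(cohort, spec, sampler_config=FAST, seed=4)
    pred = posterior_predictive(post, spec, ("P00", "OD"), [0.0, 3.0], seed=0)
    assert np.all(pred >= 0)


def test_pointwise_loglik_matches_direct_density(linear_fit):
    """Columns of the stored log-likelihood reproduce scipy's normal density
    and sum to the joint data log-likelihood draw by draw."""
    cohort, spec, post = linear_fit
    s = 0  # first stored draw
    a, slope = post.draws["eye_transformed"][s, 0, :]
    sigma = post.draws["sigma"][s]
    mean = np.maximum(0.0, a + slope * post.train_t)
    direct = stats.norm.logpdf(post.train_area, mean, sigma)
    assert np.allclose(post.loglik[s], direct, rtol=1e-10)
    assert post.loglik.shape[1] == len(cohort.df)


def _dummy_posterior(chain: np.ndarray) -> PosteriorDraws:
    """Pseudo-draws with the layout of a 1-parameter, 0-group fit: the chain's
    last dim must be 4 (mu, tau_patient, tau_eye, log_sigma)."""
    draws, chains, ndim = chain.shape
    assert ndim == 4
    return PosteriorDraws(
        model="gompertz",
        param_names=("logK",),
        re_params=("logK",),
        patients=[],
        eye_keys=[],
        pat_of_eye=np.array([], dtype=int),
        chain=chain,
        draws={"sigma": np.ones(draws)},
        loglik=np.zeros((draws, 1)),
        train_t=np.array([0.0]),
        train_area=np.array([0.0]),
        train_eye_idx=np.array([0]),
        priors=None,
        meta={"chains": chains},
    )


def test_convergence_check_on_iid_draws_passes():
    rng = np.random.default_rng(0)
    post = _dummy_posterior(rng.standard_normal((800, 4, 4)))
    rep = convergence_check(post)
    assert rep.passed
    assert rep.table["rhat"].between(0.99, 1.01).all()
    assert (rep.table["ess_bulk"] > 1000).all()


def test_convergence_check_flags_disagreeing_chains():
    rng = np.random.default_rng(1)
    chain = 0.001 * rng.standard_normal((400, 4, 4))
    chain[:, 2:, :] += 10.0  # two chains at a different constant
    rep = convergence_check(_dummy_posterior(chain))
    assert not rep.passed
    assert (rep.table["rhat"] > 1.5).all()


def test_convergence_report_lists_each_parameter_once():
    rng = np.random.default_rng(2)
    cohort = make_linear_cohort(seed=3, n_eyes=2, n_visits=6, sigma=0.1)
    post = fit_hierarchical(cohort, get_model("linear"), sampler_config=FAST, seed=1)
    rep = convergence_check(post)
    names = rep.table["parameter"]
    assert len(names) == post.meta["ndim"]
    assert names.is_unique


def test_single_chain_is_an_error():
    rng = np.random.default_rng(3)
    post = _dummy_posterior(rng.standard_normal((100, 1, 4)))
    with pytest.raises(GagrowthError):
        convergence_check(post)


def test_hierarchy_spec_rejects_unknown_parameters():
    with pytest.raises(GagrowthError):
        HierarchySpec(re_params=("not_a_param",)).resolve(get_model("gompertz"))
    sub = HierarchySpec(re_params=("logK",)).resolve(get_model("gompertz"))
    assert sub == ("logK",)
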