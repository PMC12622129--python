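"""Scoring: CRPS estimator, MAE, intervals, PSIS-LOO and pseudo-BMA+ weights."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gagrowth.errors import GagrowthError
from gagrowth.scoring import (
    crps_sample,
    interval_score,
    mae_from_median,
    pseudo_bma_plus,
    psis_loo,
)


def crps_by_integration(draws: np.ndarray, y: float) -> float:
    """Independent oracle: exact integral of (F_hat(x) - 1{x >= y})^2 dx.

    The empirical CDF is a step function, so the Brier integral is a finite
    sum over the intervals between consecutive breakpoints.  This evaluates
    the S^2-denominator variant; callers convert if they need the unbiased
    S(S-1) form.
    """
    x = np.sort(np.asarray(draws, dtype=float))
    S = x.size
    pts = np.unique(np.concatenate([x, [y]]))
    total = 0.0
    for lo, hi in zip(pts[:-1], pts[1:]):
        F = np.searchsorted(x, lo, side="right") / S
        H = 1.0 if lo >= y else 0.0
        total += (hi - lo) * (F - H) ** 2
    return total


def fair_from_integral(draws, y):
    x = np.asarray(draws, dtype=float)
    S = x.size
    A = np.mean(np.abs(x - y))
    I = crps_by_integration(x, y)
    return A - S / (S - 1) * (A - I)


def test_crps_hand_evaluated_examples():
    # draws {0, 2}, y = 1: mean|X-y| = 1; unbiased pairwise term = 1 -> CRPS 0
    assert crps_sample([0.0, 2.0], 1.0) == pytest.approx(0.0, abs=1e-12)
    assert crps_sample([3.0, 3.0, 3.0], 3.0) == pytest.approx(0.0, abs=1e-12)
    # a point mass reduces to absolute error
    assert crps_sample([2.5] * 10, 4.0) == pytest.approx(1.5, abs=1e-12)


def test_crps_matches_integration_oracle():
    rng = np.random.default_rng(42)
    for _ in range(8):
        draws = rng.gamma(2.0, 1.5, size=50)
        y = float(rng.uniform(0, 8))
        assert crps_sample(draws, y) == pytest.approx(
            fair_from_integral(draws, y), abs=1e-6
        )


def test_crps_errors():
    with pytest.raises(GagrowthError):
        crps_sample([1.0], 1.0)
    with pytest.raises(GagrowthError):
        crps_sample([1.0, np.nan], 1.0)


@settings(max_examples=40, deadline=None)
@given(
    draws=st.lists(st.floats(-50, 50), min_size=2, max_size=30),
    y=st.floats(-50, 50),
    c=st.floats(0.1, 10),
)
def test_crps_order_invariance_and_homogeneity(draws, y, c):
    x = np.array(draws)
    base = crps_sample(x, y)
    rng = np.random.default_rng(0)
    assert crps_sample(rng.permutation(x), y) == pytest.approx(base, abs=1e-9)
    assert crps_sample(c * x, c * y) == pytest.approx(c * base, rel=1e-9, abs=1e-9)


def test_mae_from_median():
    assert mae_from_median([3.0, 3.0, 3.0], 5.0) == 2.0
    assert mae_from_median([1.0, 2.0, 9.0], 2.0) == 0.0
    assert mae_from_median(np.linspace(-1, 1, 101) + 4.0, 4.0) == pytest.approx(0.0)
    with pytest.raises(GagrowthError):
        mae_from_median([], 1.0)


def test_interval_score_quantile_oracle():
    draws = np.arange(1.0, 101.0)
    low, high, width, covered = interval_score(draws, 50.0, level=0.90)
    # type-7 interpolated quantiles of 1..100
    assert low == pytest.approx(np.quantile(draws, 0.05))
    assert low == pytest.approx(5.95)
    assert high == pytest.approx(95.05)
    assert width == pytest.approx(high - low)
    assert covered
    assert not interval_score(draws, 200.0, level=0.90)[3]
    with pytest.raises(GagrowthError):
        interval_score(draws, 50.0, level=1.5)
    with pytest.raises(GagrowthError):
        interval_score(draws[:5], 3.0)


def test_psis_loo_constant_likelihood_reduces_to_pointwise():
    ll = np.tile(np.array([-1.3, -0.7, -2.2]), (200, 1))
    elpd, k = psis_loo(ll)
    assert np.allclose(elpd, [-1.3, -0.7, -2.2])
    assert np.all(k <= 0.0 + 1e-12)


def test_psis_loo_pareto_k_bookkeeping():
    rng = np.random.default_rng(1)
    ll = rng.normal(-1.0, 0.5, size=(500, 12))
    elpd, k = psis_loo(ll)
    assert elpd.shape == (12,) and k.shape == (12,)
    assert int((k > 0.7).sum()) >= 0  # reported, finite
    assert np.all(np.isfinite(elpd))
    with pytest.raises(GagrowthError):
        psis_loo(np.full((10, 3), np.nan))


def test_pseudo_bma_symmetry_and_dominance():
    rng = np.random.default_rng(0)
    base = rng.normal(-1.0, 0.3, size=40)
    equal = np.vstack([base, base])
    w = pseudo_bma_plus(equal, ["a", "b"], seed=3)
    assert w.weights == pytest.approx([0.5, 0.5], abs=1e-9)
    dom = np.vstack([base + 10.0, base])
    w2 = pseudo_bma_plus(dom, ["a", "b"], seed=3)
    assert w2.weights[0] > 0.999
    rnd = rng.normal(size=(4, 25))
    w3 = pseudo_bma_plus(rnd, seed=1)
    assert w3.weights.sum() == pytest.approx(1.0, abs=1e-9)
    assert np.all(w3.weights >= 0)


def test_pseudo_bma_input_validation():
    with pytest.raises(GagrowthError):
        pseudo_bma_plus(np.ones((1, 5)))
    with pytest.raises(GagrowthError):
        pseudo_bma_plus(np.ones((2, 5)), ["only_one"])
    with pytest.raises(GagrowthError):
        pseudo_bma_plus(np.array([[1.0, np.inf], [0.0, 1.0]]))
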