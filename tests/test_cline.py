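"""Cline model evaluation, likelihood, AICc bookkeeping and MCMC fitting."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from _oracles import bernoulli_loglik_naive, gaussian_loglik_naive
from hzkit.cline import (
    ClineDataset,
    ClineFit,
    ClineModelSpec,
    ClineParams,
    MCMCSettings,
    aicc,
    cline_eval,
    enumerate_models,
    fit_mcmc,
    loglik,
    observed_trait_interval,
    select_best,
)
from hzkit.errors import DataError, ParameterError, SelectionError

B_NONE = ClineModelSpec(scaling="fixed01", tails="none", likelihood="bernoulli")


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def test_sigmoid_midpoint_and_quarter():
    p = ClineParams(center=0, width=30)
    assert cline_eval(p, B_NONE, 0.0) == pytest.approx(0.5)
    assert cline_eval(p, B_NONE, 15.0) == pytest.approx(1 / (1 + math.exp(-2)))
    assert cline_eval(p, B_NONE, 15.0) == pytest.approx(0.88080, abs=1e-5)


def test_sigmoid_symmetry_without_tails():
    p = ClineParams(center=12.0, width=40.0)
    for d in (0.5, 5, 33, 90):
        s = cline_eval(p, B_NONE, 12.0 + d) + cline_eval(p, B_NONE, 12.0 - d)
        assert s == pytest.approx(1.0, abs=1e-12)


@pytest.mark.parametrize("tails", ["left", "right", "mirror", "both"])
def test_tail_continuity_at_junctions(tails):
    """p(x) is continuous across both tail junctions over a parameter sweep."""
    spec = ClineModelSpec(scaling="fixed01", tails=tails, likelihood="bernoulli")
    for w in (5.0, 30.0, 120.0):
        for delta in (0.0, 3.0, 40.0):
            for tau in (0.0, 0.3, 1.0):
                p = ClineParams(center=-7.0, width=w, delta_l=delta, tau_l=tau,
                                delta_r=delta, tau_r=tau)
                for junction in (-7.0 - delta, -7.0 + delta):
                    lo = cline_eval(p, spec, junction - 1e-9)
                    hi = cline_eval(p, spec, junction + 1e-9)
                    assert abs(hi - lo) < 1e-8


def test_tau_one_matches_sigmoid_log_slope():
    """With tau = 1 the one-sided derivative of log f matches across the
    left junction to 1e-9 (the tail continues the sigmoid's log-scale slope)."""
    spec = ClineModelSpec(scaling="fixed01", tails="left", likelihood="bernoulli")
    p = ClineParams(center=0.0, width=30.0, delta_l=20.0, tau_l=1.0)
    xj = -20.0
    h = 1e-6
    inner = (math.log(cline_eval(p, spec, xj + 2 * h))
             - math.log(cline_eval(p, spec, xj + h))) / h
    outer = (math.log(cline_eval(p, spec, xj - h))
             - math.log(cline_eval(p, spec, xj - 2 * h))) / h
    assert abs(inner - outer) < 1e-4  # finite-difference resolution
    # analytic check to full precision: slope of log tail = tau (4/w)(1 - g_L)
    from scipy.special import expit

    gl = expit(-4 * 20 / 30)
    assert (4 / 30) * (1 - gl) == pytest.approx(
        (math.log(cline_eval(p, spec, xj)) - math.log(cline_eval(p, spec, xj - 1e-3)))
        / 1e-3, rel=1e-3)


@settings(deadline=None, derandomize=True, max_examples=60)
@given(
    c=st.floats(-100, 100), w=st.floats(0.1, 300),
    dl=st.floats(0, 100), tl=st.floats(0, 1),
    dr=st.floats(0, 100), tr=st.floats(0, 1),
    tails=st.sampled_from(["none", "left", "right", "mirror", "both"]),
)
def test_cline_monotone_nondecreasing(c, w, dl, tl, dr, tr, tails):
    spec = ClineModelSpec(scaling="fixed01", tails=tails, likelihood="bernoulli")
    p = ClineParams(center=c, width=w, delta_l=dl, tau_l=tl, delta_r=dr, tau_r=tr)
    x = np.linspace(c - 400, c + 400, 801)
    y = cline_eval(p, spec, x)
    assert np.all(np.diff(y) >= -1e-12)


def test_scaling_modes():
    p = ClineParams(center=0, width=30, p_min=0.2, p_max=0.6)
    spec = ClineModelSpec(scaling="free", tails="none", likelihood="gaussian")
    assert cline_eval(p, spec, 0.0) == pytest.approx(0.4)
    assert cline_eval(p, spec, 1e6) == pytest.approx(0.6)
    assert cline_eval(p, spec, -1e6) == pytest.approx(0.2)


def test_invalid_params_raise():
    with pytest.raises(ParameterError):
        cline_eval(ClineParams(width=-1), B_NONE, 0.0)
    with pytest.raises(ParameterError):
        cline_eval(ClineParams(p_min=0.8, p_max=0.2), B_NONE, 0.0)
    with pytest.raises(ParameterError):
        cline_eval(ClineParams(tau_l=1.5), B_NONE, 0.0)


# ---------------------------------------------------------------------------
# model space and AICc
# ---------------------------------------------------------------------------

def test_enumerate_fifteen_plus_null():
    models = enumerate_models("gaussian")
    assert len(models) == 16
    assert sum(m.is_null for m in models) == 1
    assert len({(m.scaling, m.tails) for m in models if not m.is_null}) == 15


@pytest.mark.parametrize("spec,k", [
    (ClineModelSpec("fixed01", "none", "bernoulli"), 2),
    (ClineModelSpec("free", "both", "gaussian"), 9),
    (ClineModelSpec("observed", "mirror", "bernoulli"), 4),
    (ClineModelSpec("free", "left", "bernoulli"), 6),
    (ClineModelSpec(likelihood="bernoulli", is_null=True), 1),
    (ClineModelSpec(likelihood="gaussian", is_null=True), 2),
])
def test_free_parameter_counts(spec, k):
    assert spec.k == k


def test_aicc_arithmetic():
    assert aicc(-5, 2, 10) == pytest.approx(10 + 4 + 12 / 7)
    assert aicc(-3.7, 0, 50) == pytest.approx(7.4)
    # approaches plain AIC for large n
    assert abs(aicc(-10, 3, 10**8) - (20 + 6)) < 1e-6
    with pytest.raises(ParameterError):
        aicc(-5, 4, 5)


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------

def test_bernoulli_single_observation():
    ds = ClineDataset(np.array([0.0]), np.array([1.0]), trait_type="haplogroup")
    p = ClineParams(center=0, width=30)
    assert loglik(ds, B_NONE, p) == pytest.approx(math.log(0.5))


def test_loglik_matches_naive_summation():
    """Vectorised likelihood equals an independently coded summation, 1e-12."""
    x = np.array([-40.0, -10.0, 0.0, 5.0, 60.0])
    yb = np.array([0.0, 0.0, 1.0, 1.0, 1.0])
    p = ClineParams(center=2.0, width=25.0)
    ds = ClineDataset(x, yb, trait_type="haplogroup")
    naive = bernoulli_loglik_naive(x, yb, lambda xi: cline_eval(p, B_NONE, xi))
    assert loglik(ds, B_NONE, p) == pytest.approx(naive, abs=1e-12)

    yg = np.array([0.05, 0.2, 0.55, 0.6, 0.97])
    gspec = ClineModelSpec("fixed01", "none", "gaussian")
    pg = ClineParams(center=2.0, width=25.0, residual_sd=0.1)
    dsg = ClineDataset(x, yg, trait_type="ancestry")
    naive_g = gaussian_loglik_naive(x, yg, lambda xi: cline_eval(pg, gspec, xi), 0.1)
    assert loglik(dsg, gspec, pg) == pytest.approx(naive_g, abs=1e-12)


def test_gaussian_sd_floor_guards_degenerate_limit():
    x = np.linspace(-50, 50, 9)
    p = ClineParams(center=0, width=30, residual_sd=1e-12)
    y = cline_eval(p, ClineModelSpec("fixed01", "none", "gaussian"), x)
    ds = ClineDataset(x, y, trait_type="ancestry")
    ll = loglik(ds, ClineModelSpec("fixed01", "none", "gaussian"), p)
    assert math.isfinite(ll)  # sd floored at 1e-4 instead of diverging


def test_scale_equivariance_of_bernoulli_loglik():
    """Doubling all x together with c, w, delta leaves the likelihood unchanged."""
    rng = np.random.default_rng(0)
    x = rng.uniform(-100, 100, 60)
    spec = ClineModelSpec("fixed01", "both", "bernoulli")
    p1 = ClineParams(center=5, width=40, delta_l=10, tau_l=0.4, delta_r=25, tau_r=0.7)
    y = (rng.random(60) < cline_eval(p1, spec, x)).astype(float)
    p2 = ClineParams(center=10, width=80, delta_l=20, tau_l=0.4, delta_r=50, tau_r=0.7)
    ll1 = loglik(ClineDataset(x, y, trait_type="haplogroup"), spec, p1)
    ll2 = loglik(ClineDataset(2 * x, y, trait_type="haplogroup"), spec, p2)
    assert ll1 == pytest.approx(ll2, abs=1e-10)


def test_empty_dataset_raises():
    empty = ClineDataset(np.array([]), np.array([]), trait_type="haplogroup")
    with pytest.raises(DataError):
        loglik(empty, B_NONE, ClineParams(width=1))


def test_observed_interval_from_locality_means():
    x = np.array([-25.0, -22.0, 3.0, 6.0, 31.0, 34.0])
    y = np.array([0.1, 0.3, 0.5, 0.7, 0.8, 1.0])
    lo, hi = observed_trait_interval(ClineDataset(x, y), bin_km=10.0)
    assert lo == pytest.approx(0.2)   # mean of the (-30,-20] bin
    assert hi == pytest.approx(0.9)   # mean of the (30,40] bin


# ---------------------------------------------------------------------------
# fitting and selection
# ---------------------------------------------------------------------------

def _bernoulli_zone(seed, n=120, width=30.0):
    rng = np.random.default_rng(seed)
    x = rng.uniform(-150, 150, n)
    p = cline_eval(ClineParams(center=0, width=width), B_NONE, x)
    y = (rng.random(n) < p).astype(float)
    return ClineDataset(x, y, trait_type="haplogroup")


def test_fit_mcmc_seeded_determinism():
    ds = _bernoulli_zone(5)
    s = MCMCSettings(iterations=3000)
    f1 = fit_mcmc(ds, B_NONE, s, seed=42)
    f2 = fit_mcmc(ds, B_NONE, s, seed=42)
    assert f1.loglik == f2.loglik
    assert f1.aicc == f2.aicc
    assert np.array_equal(f1.samples, f2.samples)
    assert f1.params.width == f2.params.width


def test_fit_recovers_width_roughly():
    ds = _bernoulli_zone(9, n=150)
    fit = fit_mcmc(ds, B_NONE, MCMCSettings(iterations=20000), seed=3)
    assert fit.ci_width[0] <= fit.params.width <= fit.ci_width[1]
    assert 10 < fit.params.width < 90
    assert abs(fit.params.center) < 25
    assert fit.envelope_x is not None
    assert np.all(fit.envelope_low <= fit.envelope_high + 1e-12)
    assert np.all(fit.envelope_low >= 0) and np.all(fit.envelope_high <= 1)


def test_fit_rejects_mismatched_likelihood():
    ds = _bernoulli_zone(1)
    with pytest.raises(DataError):
        fit_mcmc(ds, ClineModelSpec("fixed01", "none", "gaussian"),
                 MCMCSettings(iterations=100), seed=0)


def test_fit_requires_enough_observations():
    ds = ClineDataset(np.array([0.0, 1.0, 2.0]), np.array([0.0, 1.0, 1.0]),
                      trait_type="haplogroup")
    with pytest.raises(DataError):
        fit_mcmc(ds, B_NONE, MCMCSettings(iterations=100), seed=0)


def _dummy_fit(aicc_value, k, spec=None):
    spec = spec or B_NONE
    return ClineFit(spec=spec, params=ClineParams(width=1), loglik=0.0, k=k,
                    n=50, aicc=aicc_value, param_names=[], samples=np.empty((0, 0)),
                    sample_logliks=np.empty(0), ci_center=None, ci_width=None,
                    envelope_x=None, envelope_low=None, envelope_high=None,
                    acceptance_rate=0.3, seed=0)


def test_select_best_minimum_and_tiebreaks():
    fits = [_dummy_fit(12.1, 2), _dummy_fit(11.9, 4), _dummy_fit(30.0, 2)]
    assert select_best(fits).aicc == 11.9
    # tie broken by smaller k
    tie = [_dummy_fit(10.0, 4), _dummy_fit(10.0, 2)]
    assert select_best(tie).k == 2
    # then by enumeration (input) order
    tie2 = [_dummy_fit(10.0, 2), _dummy_fit(10.0, 2, ClineModelSpec("free", "none", "bernoulli"))]
    assert select_best(tie2) is tie2[0]
    with pytest.raises(SelectionError):
        select_best([_dummy_fit(float("nan"), 2)])
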