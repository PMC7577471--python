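"""Model core: logit-linear layers, marginal likelihood, priors.

The key oracle is explicit enumeration over the latent occupancy state:
P(history) = sum_z P(z) P(history | z), computed from first principles for
every random instance and compared with the closed-form marginal.
"""

import numpy as np
import pytest
from scipy.stats import norm, uniform

import msom
from msom.core import LOGIT_CLIP


def _state(u=0.0, v=0.0, alpha=(), beta=(), **kw):
    n = np.atleast_1d(u).shape[0]
    return msom.ParameterState(
        u=np.atleast_1d(u),
        v=np.atleast_1d(v),
        alpha=np.tile(np.asarray(alpha, float), (n, 1)),
        beta=np.tile(np.asarray(beta, float), (n, 1)),
        mu_alpha=np.zeros(len(alpha)),
        mu_beta=np.zeros(len(beta)),
        sigma_alpha=np.ones(len(alpha)),
        sigma_beta=np.ones(len(beta)),
        **kw,
    )


def enumeration_marginal(history, mask, psi, p):
    """Brute-force sum over z in {0, 1} of P(z) * P(history | z)."""
    total = 0.0
    obs = np.asarray(mask, bool)
    for z in (0, 1):
        pz = psi if z else 1.0 - psi
        lik = 1.0
        for k in np.nonzero(obs)[0]:
            pk = p[k] * z
            lik *= pk if history[k] else 1.0 - pk
        total += pz * lik
    return total


# ---------------------------------------------------------------------------
# probability layers
# ---------------------------------------------------------------------------


def test_occupancy_probability_closed_forms():
    st = _state(u=[0.0], alpha=[1.0, 0.0, 0.0])
    X = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0]])
    psi = msom.occupancy_probability(st, X)
    assert psi[0, 0] == pytest.approx(0.5)
    assert psi[0, 1] == pytest.approx(1.0 / (1.0 + np.exp(-1.0)))  # ~0.7311


def test_occupancy_probability_saturates_without_overflow():
    st = _state(u=[30.0])
    with np.errstate(over="raise"):
        psi = msom.occupancy_probability(st, np.zeros((1, 0)))
    assert psi[0, 0] == pytest.approx(1.0, abs=1e-9)
    assert psi[0, 0] < 1.0  # never an exact 1 from a finite predictor


def test_probabilities_stay_in_open_interval():
    st = _state(u=[1e6])
    psi = msom.occupancy_probability(st, np.zeros((1, 0)))
    assert 0.0 < psi[0, 0] < 1.0
    st2 = _state(u=[-1e6])
    assert msom.occupancy_probability(st2, np.zeros((1, 0)))[0, 0] > 0.0


def test_occupancy_rejects_nonfinite_covariate():
    st = _state(u=[0.0], alpha=[1.0])
    with pytest.raises(ValueError, match="non-finite"):
        msom.occupancy_probability(st, np.array([[np.nan]]))


def test_detection_probability_with_reported_date_coefficient():
    # the community date effect reported for reptiles, used as a test input
    st = _state(v=[0.0], beta=[-0.472])
    X = np.array([[[1.0]]])  # one site, one occasion, date = +1 sd
    p = msom.detection_probability(st, X)
    assert p[0, 0, 0] == pytest.approx(1.0 / (1.0 + np.exp(0.472)))


def test_detection_probability_requires_matching_columns():
    st = _state(v=[0.0], beta=[0.5, 0.5])
    with pytest.raises(ValueError, match="covariate count"):
        msom.detection_probability(st, np.zeros((2, 3, 1)))


def test_build_design_broadcasts_site_level_detection_covariates():
    site = msom.CovariateTable(
        names=["elev", "understory"],
        level="site",
        values=np.array([[1.0, 2.0], [-1.0, -2.0]]),
        standardized=True,
    )
    occ = msom.CovariateTable(
        names=["date"],
        level="site_occasion",
        values=np.arange(6, dtype=float).reshape(2, 3, 1),
        standardized=True,
    )
    spec = msom.ModelSpec(("elev",), ("date", "understory"))
    Xocc, Xdet = msom.build_design(spec, site, occ)
    assert Xocc.shape == (2, 1) and Xdet.shape == (2, 3, 2)
    np.testing.assert_array_equal(Xdet[:, :, 1], [[2.0] * 3, [-2.0] * 3])
    with pytest.raises(KeyError, match="absent"):
        msom.build_design(msom.ModelSpec((), ("humidity",)), site, occ)


# ---------------------------------------------------------------------------
# marginal likelihood
# ---------------------------------------------------------------------------


def test_marginal_likelihood_hand_values():
    mask = np.ones(2, bool)
    p = np.array([0.5, 0.5])
    assert msom.species_site_marginal_lik([0, 0], mask, 0.5, p) == pytest.approx(0.625)
    assert msom.species_site_marginal_lik([1, 0], mask, 0.5, p) == pytest.approx(0.125)


def test_marginal_likelihood_fully_missing_is_one():
    assert msom.species_site_marginal_lik(
        [0, 0], np.zeros(2, bool), 0.3, np.array([0.4, 0.4])
    ) == pytest.approx(1.0)


def test_marginal_likelihood_rejects_detection_outside_mask():
    with pytest.raises(ValueError, match="unsurveyed"):
        msom.species_site_marginal_lik(
            [1, 0], np.array([False, True]), 0.5, np.array([0.5, 0.5])
        )


def test_marginal_likelihood_equals_enumeration_on_random_instances():
    rng = np.random.default_rng(2024)
    for _ in range(300):
        K = rng.integers(1, 6)
        psi = rng.uniform(0.02, 0.98)
        p = rng.uniform(0.02, 0.98, K)
        mask = rng.random(K) < 0.8
        history = ((rng.random(K) < p) & mask).astype(int)
        ours = msom.species_site_marginal_lik(history, mask, psi, p)
        oracle = enumeration_marginal(history, mask, psi, p)
        assert ours == pytest.approx(oracle, abs=1e-12)


def test_total_loglik_composition_and_permutation_invariance():
    x = np.array([[[0, 0]]], dtype=np.int8)
    data = msom.DetectionData(["a"], ["s"], ["o1", "o2"], x, np.ones((1, 2), np.int8))
    lat = msom.LatentProbabilities(
        psi=np.array([[0.5]]), p=np.array([[[0.5, 0.5]]])
    )
    assert msom.total_loglik(data, lat) == pytest.approx(np.log(0.625))

    rng = np.random.default_rng(3)
    N, J, K = 3, 4, 2
    psi = rng.uniform(0.1, 0.9, (N, J))
    p = rng.uniform(0.1, 0.9, (N, J, K))
    mask = (rng.random((J, K)) < 0.85).astype(np.int8)
    x = ((rng.random((N, J, K)) < 0.4) & mask.astype(bool)).astype(np.int8)
    data = msom.DetectionData(
        [f"sp{i}" for i in range(N)], [f"s{j}" for j in range(J)],
        [f"o{k}" for k in range(K)], x, mask,
    )
    total = msom.total_loglik(data, msom.LatentProbabilities(psi, p))
    oracle = sum(
        np.log(enumeration_marginal(x[i, j], mask[j].astype(bool), psi[i, j], p[i, j]))
        for i in range(N)
        for j in range(J)
    )
    assert total == pytest.approx(oracle, abs=1e-10)

    perm_i = rng.permutation(N)
    perm_j = rng.permutation(J)
    data_perm = msom.DetectionData(
        [data.species_ids[i] for i in perm_i],
        [data.site_ids[j] for j in perm_j],
        data.occasion_ids,
        x[np.ix_(perm_i, perm_j)],
        mask[perm_j],
    )
    lat_perm = msom.LatentProbabilities(
        psi[np.ix_(perm_i, perm_j)], p[np.ix_(perm_i, perm_j)]
    )
    assert msom.total_loglik(data_perm, lat_perm) == pytest.approx(total, abs=1e-10)


def test_total_loglik_all_missing_is_zero():
    x = np.zeros((2, 2, 2), dtype=np.int8)
    data = msom.DetectionData(
        ["a", "b"], ["s1", "s2"], ["o1", "o2"], x, np.zeros((2, 2), np.int8)
    )
    lat = msom.LatentProbabilities(np.full((2, 2), 0.3), np.full((2, 2, 2), 0.4))
    assert msom.total_loglik(data, lat) == 0.0


# ---------------------------------------------------------------------------
# prior
# ---------------------------------------------------------------------------


def test_log_prior_matches_term_by_term_oracle():
    rng = np.random.default_rng(9)
    n, co, cd = 4, 2, 3
    state = msom.ParameterState(
        u=rng.normal(size=n),
        v=rng.normal(size=n),
        alpha=rng.normal(size=(n, co)),
        beta=rng.normal(size=(n, cd)),
        mu_u=rng.normal(),
        mu_v=rng.normal(),
        mu_alpha=rng.normal(size=co),
        mu_beta=rng.normal(size=cd),
        sigma_u=1.3,
        sigma_v=0.7,
        sigma_alpha=rng.uniform(0.5, 2.0, co),
        sigma_beta=rng.uniform(0.5, 2.0, cd),
    )
    spec = msom.ModelSpec(("a", "b"), ("c", "d", "e"))
    expected = 0.0
    expected += norm.logpdf(state.u, state.mu_u, state.sigma_u).sum()
    expected += norm.logpdf(state.v, state.mu_v, state.sigma_v).sum()
    for c in range(co):
        expected += norm.logpdf(state.alpha[:, c], state.mu_alpha[c], state.sigma_alpha[c]).sum()
    for c in range(cd):
        expected += norm.logpdf(state.beta[:, c], state.mu_beta[c], state.sigma_beta[c]).sum()
    for m in [state.mu_u, state.mu_v, *state.mu_alpha, *state.mu_beta]:
        expected += norm.logpdf(m, 0, 2.25)
    for s in [state.sigma_u, state.sigma_v, *state.sigma_alpha, *state.sigma_beta]:
        expected += uniform.logpdf(s, 0, 5)
    assert msom.log_prior(state, spec) == pytest.approx(expected, abs=1e-10)


def test_log_prior_rejects_out_of_support_hyper_sd():
    state = msom.ParameterState(
        u=[0.0], v=[0.0], alpha=np.zeros((1, 0)), beta=np.zeros((1, 0)), sigma_u=6.0
    )
    assert msom.log_prior(state, msom.ModelSpec()) == -np.inf


def test_log_prior_mode_contribution():
    state = msom.ParameterState(
        u=[0.0, 0.0], v=[0.0, 0.0], alpha=np.zeros((2, 0)), beta=np.zeros((2, 0))
    )
    lp = msom.log_prior(state, msom.ModelSpec())
    # species effects at their hyper-means each contribute the Normal mode density
    mode = norm.logpdf(0.0, 0.0, 1.0)
    expected = 4 * mode + 2 * norm.logpdf(0.0, 0.0, 2.25) + 2 * uniform.logpdf(1.0, 0, 5)
    assert lp == pytest.approx(expected, abs=1e-12)


# ---------------------------------------------------------------------------
# z full conditional
# ---------------------------------------------------------------------------


def test_z_full_conditional_hand_values():
    mask1 = np.ones(1, bool)
    assert msom.z_full_conditional([1], mask1, 0.5, np.array([0.5])) == 1.0
    assert msom.z_full_conditional([0], mask1, 0.5, np.array([0.5])) == pytest.approx(1 / 3)
    mask2 = np.ones(2, bool)
    assert msom.z_full_conditional(
        [0, 0], mask2, 0.5, np.array([0.5, 0.5])
    ) == pytest.approx(0.2)


def test_z_full_conditional_limits():
    mask = np.ones(3, bool)
    # no information: p -> 0 leaves the prior psi
    assert msom.z_full_conditional(
        [0, 0, 0], mask, 0.37, np.full(3, 1e-12)
    ) == pytest.approx(0.37, abs=1e-9)
    # many high-p misses drive occupancy towards zero
    assert msom.z_full_conditional([0, 0, 0], mask, 0.5, np.full(3, 0.999)) < 1e-8
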