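"""The hierarchical multi-species occupancy model (MSOM).

Latent occupancy of species i at site j is Bernoulli,
``z(i,j) ~ Bern(psi_ij)``, and detections on surveyed occasions are
Bernoulli conditional on presence, ``x(i,j,k) ~ Bern(p_ijk * z(i,j))``.
Both probabilities are logit-linear in standardized covariates:

    logit(psi_ij)  = u_i + sum_c alpha[c,i] * occupancy_cov[c,j]
    logit(p_ijk)   = v_i + sum_c beta[c,i]  * detection_cov[c,j,k]

Species-level coefficients are tied together by community hyper-
distributions: each coefficient family (intercepts u, v and every
covariate's alpha or beta) is Normal(hyper-mean, hyper-sd) across species.
Hyper-means get weakly informative Normal(0, sd 2.25) priors on the logit
scale (near-uniform after inverse-logit) and hyper-sds Uniform(0, 5);
both are configurable through :class:`ModelSpec`.

All likelihood computation is in log space, and linear predictors are
clipped to +/-35 before the inverse logit so probabilities never reach an
exact 0 or 1 from finite inputs (the clip perturbs results below 1e-15).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import yaml
from scipy.special import expit
from scipy.stats import norm

from .data_model import CovariateTable, DetectionData

__all__ = [
    "LOGIT_CLIP",
    "ModelSpec",
    "ParameterState",
    "LatentProbabilities",
    "inverse_logit",
    "build_design",
    "occupancy_probability",
    "detection_probability",
    "latent_probabilities",
    "species_site_marginal_lik",
    "total_loglik",
    "log_prior",
    "z_full_conditional",
]

LOGIT_CLIP = 35.0


def inverse_logit(eta: np.ndarray | float) -> np.ndarray | float:
    """Inverse logit with the linear predictor clipped to +/-LOGIT_CLIP."""
    return expit(np.clip(eta, -LOGIT_CLIP, LOGIT_CLIP))


@dataclass(frozen=True)
class ModelSpec:
    """Which covariates enter each submodel, plus hyper-prior settings.

    Detection covariate sets legitimately differ between datasets (e.g.
    humidity only for amphibians, temperature only for reptiles); that is
    configuration, not code.
    """

    occupancy_covariates: tuple[str, ...] = ()
    detection_covariates: tuple[str, ...] = ()
    hyper_mean_sd: float = 2.25
    hyper_sd_upper: float = 5.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "occupancy_covariates", tuple(self.occupancy_covariates))
        object.__setattr__(self, "detection_covariates", tuple(self.detection_covariates))
        if self.hyper_mean_sd <= 0 or self.hyper_sd_upper <= 0:
            raise ValueError("hyper-prior scales must be positive")

    @property
    def families(self) -> list[str]:
        """Coefficient families in sampler order: u, v, alphas, betas."""
        return (
            ["u", "v"]
            + [f"alpha[{c}]" for c in self.occupancy_covariates]
            + [f"beta[{c}]" for c in self.detection_covariates]
        )

    def to_yaml(self, path) -> None:
        payload = {
            "occupancy_covariates": list(self.occupancy_covariates),
            "detection_covariates": list(self.detection_covariates),
            "hyper_mean_sd": self.hyper_mean_sd,
            "hyper_sd_upper": self.hyper_sd_upper,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh)

    @classmethod
    def from_yaml(cls, path) -> "ModelSpec":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        return cls(
            occupancy_covariates=tuple(payload.get("occupancy_covariates", ())),
            detection_covariates=tuple(payload.get("detection_covariates", ())),
            hyper_mean_sd=float(payload.get("hyper_mean_sd", 2.25)),
            hyper_sd_upper=float(payload.get("hyper_sd_upper", 5.0)),
        )


@dataclass
class ParameterState:
    """All latent quantities of one MCMC state.

    ``u``/``v`` are species-level intercepts (N,), ``alpha`` (N, Co) and
    ``beta`` (N, Cd) the species-level covariate coefficients, and the
    ``mu_*``/``sigma_*`` fields the community hyper-means and hyper-sds.
    """

    u: np.ndarray
    v: np.ndarray
    alpha: np.ndarray
    beta: np.ndarray
    mu_u: float = 0.0
    mu_v: float = 0.0
    mu_alpha: np.ndarray = field(default_factory=lambda: np.zeros(0))
    mu_beta: np.ndarray = field(default_factory=lambda: np.zeros(0))
    sigma_u: float = 1.0
    sigma_v: float = 1.0
    sigma_alpha: np.ndarray = field(default_factory=lambda: np.zeros(0))
    sigma_beta: np.ndarray = field(default_factory=lambda: np.zeros(0))
    z: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.u = np.atleast_1d(np.asarray(self.u, dtype=float))
        self.v = np.atleast_1d(np.asarray(self.v, dtype=float))
        n = self.u.shape[0]
        self.alpha = np.asarray(self.alpha, dtype=float).reshape(n, -1)
        self.beta = np.asarray(self.beta, dtype=float).reshape(n, -1)
        self.mu_alpha = np.atleast_1d(np.asarray(self.mu_alpha, dtype=float))
        self.mu_beta = np.atleast_1d(np.asarray(self.mu_beta, dtype=float))
        self.sigma_alpha = np.atleast_1d(np.asarray(self.sigma_alpha, dtype=float))
        self.sigma_beta = np.atleast_1d(np.asarray(self.sigma_beta, dtype=float))
        sds = np.concatenate(
            [[self.sigma_u, self.sigma_v], self.sigma_alpha, self.sigma_beta]
        )
        if (sds <= 0).any():
            raise ValueError("all hyper-sds must be strictly positive")

    @property
    def n_species(self) -> int:
        return self.u.shape[0]


@dataclass
class LatentProbabilities:
    """Realized occupancy (psi, N x J) and detection (p, N x J x K) probabilities."""

    psi: np.ndarray
    p: np.ndarray


def _covariate_matrix(covs, expected_ndim: int) -> np.ndarray:
    values = covs.values if isinstance(covs, CovariateTable) else np.asarray(covs, float)
    if isinstance(covs, CovariateTable) and not covs.standardized:
        raise ValueError("covariates must be standardized before entering the model")
    if values.ndim != expected_ndim:
        raise ValueError(f"expected {expected_ndim}-d covariate array, got {values.ndim}-d")
    return values


def build_design(
    spec: ModelSpec,
    site_covs: CovariateTable,
    occasion_covs: CovariateTable | None = None,
    n_occasions: int | None = None,
    observed_mask: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Resolve the named covariates into design arrays Xocc (J, Co), Xdet (J, K, Cd).

    Detection covariates are looked up in the occasion-level table first and
    fall back to the site-level table (broadcast over occasions) — understory
    height and wood stem density are measured once per site.  With an
    ``observed_mask``, covariate values at unsurveyed occasions are zeroed
    (they never enter a likelihood) and NaNs at surveyed occasions are
    rejected.
    """
    if not site_covs.standardized:
        raise ValueError("site covariates must be standardized")
    if occasion_covs is not None and not occasion_covs.standardized:
        raise ValueError("occasion covariates must be standardized")
    J = site_covs.values.shape[0]
    if occasion_covs is not None:
        K = occasion_covs.values.shape[1]
        if occasion_covs.values.shape[0] != J:
            raise ValueError("site and occasion tables disagree on the number of sites")
    elif n_occasions is not None:
        K = int(n_occasions)
    else:
        raise ValueError("need occasion_covs or n_occasions to size the detection design")

    if spec.occupancy_covariates:
        Xocc = np.column_stack([site_covs.column(c) for c in spec.occupancy_covariates])
    else:
        Xocc = np.zeros((J, 0))

    det_cols = []
    for name in spec.detection_covariates:
        if occasion_covs is not None and name in occasion_covs.names:
            det_cols.append(occasion_covs.column(name))
        elif name in site_covs.names:
            det_cols.append(np.broadcast_to(site_covs.column(name)[:, None], (J, K)))
        else:
            raise KeyError(f"detection covariate {name!r} absent from supplied tables")
    Xdet = np.stack(det_cols, axis=-1) if det_cols else np.zeros((J, K, 0))

    if not np.isfinite(Xocc).all():
        raise ValueError("non-finite occupancy covariate value")
    if observed_mask is not None and Xdet.shape[-1]:
        obs = np.asarray(observed_mask, bool)
        if not np.isfinite(Xdet[obs]).all():
            raise ValueError("non-finite detection covariate at a surveyed occasion")
        Xdet = np.where(obs[:, :, None], Xdet, 0.0)
    elif not np.isfinite(Xdet).all():
        raise ValueError("non-finite detection covariate value")
    return np.ascontiguousarray(Xocc), np.ascontiguousarray(Xdet)


def occupancy_probability(state: ParameterState, site_covs) -> np.ndarray:
    """psi[i, j] = inverse-logit(u_i + sum_c alpha[i, c] * cov[j, c])."""
    X = _covariate_matrix(site_covs, 2)
    if not np.isfinite(X).all():
        raise ValueError("non-finite occupancy covariate value")
    if X.shape[1] != state.alpha.shape[1]:
        raise ValueError("covariate count does not match alpha coefficients")
    eta = state.u[:, None] + state.alpha @ X.T
    return inverse_logit(eta)


def detection_probability(state: ParameterState, occasion_design) -> np.ndarray:
    """p[i, j, k] = inverse-logit(v_i + sum_c beta[i, c] * cov[j, k, c]).

    ``occasion_design`` is the (J, K, Cd) array from :func:`build_design`
    (site-level detection covariates already broadcast over occasions).
    """
    X = _covariate_matrix(occasion_design, 3)
    if X.shape[2] != state.beta.shape[1]:
        raise ValueError("covariate count does not match beta coefficients")
    eta = state.v[:, None, None] + np.einsum("ic,jkc->ijk", state.beta, X)
    return inverse_logit(eta)


def latent_probabilities(
    state: ParameterState, Xocc: np.ndarray, Xdet: np.ndarray
) -> LatentProbabilities:
    return LatentProbabilities(
        psi=occupancy_probability(state, Xocc),
        p=detection_probability(state, Xdet),
    )


def species_site_marginal_lik(
    history: np.ndarray,
    mask: np.ndarray,
    psi: float,
    p: np.ndarray,
) -> float:
    """Likelihood of one species-site detection history, z marginalized out.

    With at least one detection the site is certainly occupied:
    ``psi * prod_k p^x (1-p)^(1-x)``.  With none, presence and absence both
    contribute: ``psi * prod_k (1-p) + (1-psi)``.  A fully missing history
    carries no information (likelihood 1).
    """
    history = np.asarray(history)
    obs = np.asarray(mask, bool)
    p = np.asarray(p, dtype=float)
    if (history[~obs] == 1).any():
        raise ValueError("detection recorded on an unsurveyed occasion")
    if not obs.any():
        return 1.0
    h = history[obs].astype(float)
    po = p[obs]
    cond = float(np.prod(np.where(h == 1, po, 1.0 - po)))
    if h.any():
        return psi * cond
    return psi * cond + (1.0 - psi)


def total_loglik(data: DetectionData, lat: LatentProbabilities) -> float:
    """Sum over species and sites of the log marginal likelihood."""
    psi, p = lat.psi, lat.p
    if psi.shape != (data.n_species, data.n_sites) or p.shape != data.x.shape:
        raise ValueError("latent probability dimensions do not match the data")
    obs = data.observed_mask.astype(bool)[None, :, :]
    x = data.x.astype(float)
    # per-cell log Bernoulli terms, zeroed at unsurveyed occasions
    with np.errstate(divide="ignore"):
        term = np.where(x == 1, np.log(p), np.log1p(-p))
    cond = np.where(obs, term, 0.0).sum(axis=2)  # (N, J): log prod over observed k
    detected = data.detected_anywhere
    log_psi = np.log(psi)
    occupied_branch = log_psi + cond
    ll = np.where(
        detected, occupied_branch, np.logaddexp(occupied_branch, np.log1p(-psi))
    )
    return float(ll.sum())


def log_prior(state: ParameterState, spec: ModelSpec) -> float:
    """Log density of the hierarchical prior at ``state``.

    Species effects ~ Normal(hyper-mean, hyper-sd); hyper-means ~
    Normal(0, spec.hyper_mean_sd); hyper-sds ~ Uniform(0, spec.hyper_sd_upper).
    Any hyper-sd outside (0, upper] makes the state impossible (-inf).
    """
    sds = np.concatenate([[state.sigma_u, state.sigma_v], state.sigma_alpha, state.sigma_beta])
    if (sds <= 0).any() or (sds > spec.hyper_sd_upper).any():
        return -np.inf
    total = 0.0
    total += norm.logpdf(state.u, state.mu_u, state.sigma_u).sum()
    total += norm.logpdf(state.v, state.mu_v, state.sigma_v).sum()
    for c in range(state.alpha.shape[1]):
        total += norm.logpdf(state.alpha[:, c], state.mu_alpha[c], state.sigma_alpha[c]).sum()
    for c in range(state.beta.shape[1]):
        total += norm.logpdf(state.beta[:, c], state.mu_beta[c], state.sigma_beta[c]).sum()
    mus = np.concatenate([[state.mu_u, state.mu_v], state.mu_alpha, state.mu_beta])
    total += norm.logpdf(mus, 0.0, spec.hyper_mean_sd).sum()
    total += -len(sds) * np.log(spec.hyper_sd_upper)  # Uniform(0, upper) densities
    return float(total)


def z_full_conditional(
    history: np.ndarray, mask: np.ndarray, psi: float, p: np.ndarray
) -> float:
    """P(z = 1 | history): 1 with any detection, otherwise the Bayes ratio
    psi * prod(1-p) / (psi * prod(1-p) + 1 - psi)."""
    history = np.asarray(history)
    obs = np.asarray(mask, bool)
    p = np.asarray(p, dtype=float)
    if (history[~obs] == 1).any():
        raise ValueError("detection recorded on an unsurveyed occasion")
    if history[obs].any():
        return 1.0
    q = psi * float(np.prod(1.0 - p[obs]))
    return q / (q + 1.0 - psi)
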