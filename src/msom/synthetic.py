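"""Synthetic communities with the exact generative structure the model assumes.

Species-level coefficients are drawn from Normal community
hyper-distributions, latent occupancy from z ~ Bern(psi), and detections
from x ~ Bern(p * z) on surveyed occasions — the same two Bernoulli layers
the inference machinery fits, so parameter-recovery and calibration tests
run without any field data.

Preset scenarios pin the community hyper-means at the values estimated for
each vertebrate group in the Mumbai Metropolitan Region study (35 sampling
grids; occupancy covariates elevation, forest cover, anthropogenic habitat
cover; detection covariate sets differing by taxon).  Community hyper-sds
were not reported and default to 1.0; intercept hyper-means (mu_u = 0,
mu_v = -1) are likewise choices of this package, documented in the methods
note — recovery difficulty depends on them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .core import ModelSpec, build_design, inverse_logit
from .data_model import CovariateTable, DetectionData, standardize

__all__ = [
    "Scenario",
    "SyntheticTruth",
    "PRESETS",
    "preset_scenario",
    "gen_covariates",
    "simulate_community",
]


@dataclass(frozen=True)
class Scenario:
    """Community hyper-parameter values plus the covariates they attach to.

    ``site_detection_covariates`` names the detection covariates measured
    once per site (broadcast over occasions); the rest vary by occasion.
    """

    name: str
    occupancy_covariates: tuple[str, ...]
    detection_covariates: tuple[str, ...]
    site_detection_covariates: tuple[str, ...]
    mu_u: float
    mu_v: float
    mu_alpha: tuple[float, ...]
    mu_beta: tuple[float, ...]
    sigma_u: float = 1.0
    sigma_v: float = 1.0
    sigma_alpha: tuple[float, ...] | None = None
    sigma_beta: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if len(self.mu_alpha) != len(self.occupancy_covariates):
            raise ValueError("one mu_alpha per occupancy covariate")
        if len(self.mu_beta) != len(self.detection_covariates):
            raise ValueError("one mu_beta per detection covariate")
        if self.sigma_alpha is None:
            object.__setattr__(self, "sigma_alpha", (1.0,) * len(self.mu_alpha))
        if self.sigma_beta is None:
            object.__setattr__(self, "sigma_beta", (1.0,) * len(self.mu_beta))

    @property
    def model_spec(self) -> ModelSpec:
        return ModelSpec(self.occupancy_covariates, self.detection_covariates)

    @property
    def hyper_means(self) -> dict[str, float]:
        out = {"mu_u": self.mu_u, "mu_v": self.mu_v}
        for c, m in zip(self.occupancy_covariates, self.mu_alpha):
            out[f"mu_alpha[{c}]"] = m
        for c, m in zip(self.detection_covariates, self.mu_beta):
            out[f"mu_beta[{c}]"] = m
        return out

    @property
    def hyper_sds(self) -> dict[str, float]:
        out = {"sigma_u": self.sigma_u, "sigma_v": self.sigma_v}
        for c, s in zip(self.occupancy_covariates, self.sigma_alpha):
            out[f"sigma_alpha[{c}]"] = s
        for c, s in zip(self.detection_covariates, self.sigma_beta):
            out[f"sigma_beta[{c}]"] = s
        return out


_OCC = ("elevation", "forest_cover", "anthropogenic_cover")

PRESETS: dict[str, Scenario] = {
    # hyper-means from the community-level estimates for each taxon
    "mmr_mammals": Scenario(
        name="mmr_mammals",
        occupancy_covariates=_OCC,
        detection_covariates=("date", "time", "understory_height", "wood_stem_density"),
        site_detection_covariates=("understory_height", "wood_stem_density"),
        mu_u=0.0,
        mu_v=-1.0,
        mu_alpha=(-0.404, 2.404, -1.812),
        mu_beta=(0.009, -0.018, -0.071, 0.080),
    ),
    "mmr_birds": Scenario(
        name="mmr_birds",
        occupancy_covariates=_OCC,
        detection_covariates=("date", "time", "understory_height", "wood_stem_density"),
        site_detection_covariates=("understory_height", "wood_stem_density"),
        mu_u=0.0,
        mu_v=-1.0,
        mu_alpha=(-0.572, 0.172, -0.693),
        mu_beta=(0.027, 0.043, -0.251, 0.038),
    ),
    "mmr_amphibians": Scenario(
        name="mmr_amphibians",
        occupancy_covariates=_OCC,
        detection_covariates=("date", "time", "humidity", "understory_height"),
        site_detection_covariates=("understory_height",),
        mu_u=0.0,
        mu_v=-1.0,
        mu_alpha=(0.484, 1.311, -0.773),
        mu_beta=(-0.532, 0.124, 0.023, 0.239),
    ),
    "mmr_reptiles": Scenario(
        name="mmr_reptiles",
        occupancy_covariates=_OCC,
        detection_covariates=("date", "time", "temperature", "understory_height"),
        site_detection_covariates=("understory_height",),
        mu_u=0.0,
        mu_v=-1.0,
        mu_alpha=(0.689, -0.703, -2.375),
        mu_beta=(-0.472, 0.213, -0.121, 0.421),
    ),
    "null": Scenario(
        name="null",
        occupancy_covariates=_OCC,
        detection_covariates=("date", "time"),
        site_detection_covariates=(),
        mu_u=0.0,
        mu_v=0.0,
        mu_alpha=(0.0, 0.0, 0.0),
        mu_beta=(0.0, 0.0),
    ),
}


def preset_scenario(name: str) -> Scenario:
    """Look up a preset community scenario by name."""
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown scenario {name!r}; available: {sorted(PRESETS)}"
        ) from None


@dataclass
class SyntheticTruth:
    """Everything the generator realized, for recovery checks.

    Regenerating with the same seed reproduces every field bit-exactly, and
    the generated detections satisfy x <= z_true everywhere.
    """

    scenario: Scenario
    seed: int
    u: np.ndarray  # (N,)
    v: np.ndarray  # (N,)
    alpha: np.ndarray  # (N, Co)
    beta: np.ndarray  # (N, Cd)
    z_true: np.ndarray  # (N, J)
    psi_true: np.ndarray  # (N, J)
    p_true: np.ndarray  # (N, J, K)
    site_covs: CovariateTable
    occasion_covs: CovariateTable | None

    @property
    def hyper_means(self) -> dict[str, float]:
        return self.scenario.hyper_means


def gen_covariates(
    n_sites: int,
    n_occasions: int,
    site_names: tuple[str, ...],
    occasion_names: tuple[str, ...] = (),
    seed: int = 0,
    corr: np.ndarray | None = None,
) -> tuple[CovariateTable, CovariateTable | None]:
    """Independent (optionally correlated) normal covariates, standardized exactly.

    ``corr`` applies a correlation structure to the site-level covariates
    (must be positive definite); occasion-level covariates are always
    independent.  Returns (site table, occasion table or None).
    """
    if n_sites < 1 or n_occasions < 1:
        raise ValueError("need n_sites, n_occasions >= 1")
    rng = np.random.default_rng(seed)
    Cs = len(site_names)
    raw = rng.standard_normal((n_sites, Cs)) if Cs else np.zeros((n_sites, 0))
    if corr is not None:
        corr = np.asarray(corr, dtype=float)
        if corr.shape != (Cs, Cs):
            raise ValueError("correlation matrix shape must match site covariates")
        try:
            L = np.linalg.cholesky(corr)
        except np.linalg.LinAlgError:
            raise ValueError("requested correlation matrix is not positive definite")
        raw = raw @ L.T
    site_ids = [f"site{j + 1:02d}" for j in range(n_sites)]
    occ_ids = [f"occ{k + 1}" for k in range(n_occasions)]
    site = CovariateTable(
        names=list(site_names), level="site", values=raw, site_ids=site_ids
    )
    site = standardize(site) if Cs else replace(site, standardized=True)

    occ = None
    if occasion_names:
        raw_o = rng.standard_normal((n_sites, n_occasions, len(occasion_names)))
        occ = CovariateTable(
            names=list(occasion_names),
            level="site_occasion",
            values=raw_o,
            site_ids=site_ids,
            occasion_ids=occ_ids,
        )
        occ = standardize(occ)
    return site, occ


def simulate_community(
    scenario: Scenario,
    n_species: int,
    n_sites: int = 35,
    n_occasions: int = 6,
    site_covs: CovariateTable | None = None,
    occasion_covs: CovariateTable | None = None,
    seed: int = 0,
    missing_rate: float = 0.0,
    missing_mask: np.ndarray | None = None,
) -> tuple[DetectionData, SyntheticTruth]:
    """Draw a community, its occupancy states, and a detection history.

    Covariates are generated on the fly unless supplied.  Occasion
    missingness is independent Bernoulli dropout per (site, occasion) at
    ``missing_rate`` (default 0), or an explicit ``missing_mask`` (J, K with
    1 = surveyed).
    """
    if n_species < 1:
        raise ValueError("need at least one species")
    rng = np.random.default_rng(seed)
    occ_level = tuple(
        c for c in scenario.detection_covariates
        if c not in scenario.site_detection_covariates
    )
    if site_covs is None and occasion_covs is None:
        site_covs, occasion_covs = gen_covariates(
            n_sites,
            n_occasions,
            scenario.occupancy_covariates + scenario.site_detection_covariates,
            occ_level,
            seed=int(rng.integers(2**31)),
        )
    elif site_covs is None:
        raise ValueError("supply both covariate tables or neither")
    J = site_covs.values.shape[0]
    K = n_occasions if occasion_covs is None else occasion_covs.values.shape[1]

    spec = scenario.model_spec
    Xocc, Xdet = build_design(spec, site_covs, occasion_covs, n_occasions=K)

    Co = len(scenario.occupancy_covariates)
    Cd = len(scenario.detection_covariates)
    u = rng.normal(scenario.mu_u, scenario.sigma_u, n_species)
    v = rng.normal(scenario.mu_v, scenario.sigma_v, n_species)
    alpha = rng.normal(scenario.mu_alpha, scenario.sigma_alpha, (n_species, Co))
    beta = rng.normal(scenario.mu_beta, scenario.sigma_beta, (n_species, Cd))

    psi = inverse_logit(u[:, None] + alpha @ Xocc.T)  # (N, J)
    p = inverse_logit(v[:, None, None] + np.einsum("ic,jkc->ijk", beta, Xdet))

    z = (rng.random((n_species, J)) < psi).astype(np.int8)

    if missing_mask is not None:
        mask = np.asarray(missing_mask, dtype=np.int8)
        if mask.shape != (J, K):
            raise ValueError("missing_mask must be J x K")
    elif missing_rate > 0:
        mask = (rng.random((J, K)) >= missing_rate).astype(np.int8)
    else:
        mask = np.ones((J, K), dtype=np.int8)

    x = (rng.random((n_species, J, K)) < p).astype(np.int8)
    x *= z[:, :, None]
    x *= mask[None, :, :]

    species_ids = [f"sp{i + 1:03d}" for i in range(n_species)]
    site_ids = site_covs.site_ids or [f"site{j + 1:02d}" for j in range(J)]
    occasion_ids = (
        occasion_covs.occasion_ids
        if occasion_covs is not None and occasion_covs.occasion_ids
        else [f"occ{k + 1}" for k in range(K)]
    )
    data = DetectionData(species_ids, list(site_ids), list(occasion_ids), x, mask)
    truth = SyntheticTruth(
        scenario=scenario,
        seed=seed,
        u=u,
        v=v,
        alpha=alpha,
        beta=beta,
        z_true=z,
        psi_true=psi,
        p_true=p,
        site_covs=site_covs,
        occasion_covs=occasion_covs,
    )
    return data, truth
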