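"""Posterior sampling, convergence diagnostics, and goodness of fit.

The sampler is Metropolis-within-Gibbs with data augmentation on the latent
occupancy matrix z:

* z(i, j) has a closed-form Bernoulli full conditional (forced to 1 at any
  detection), sampled exactly each sweep;
* community hyper-means are conjugate Normal updates given the species
  effects and hyper-sds;
* species-level coefficients and the log hyper-sds move by adaptive
  random-walk Metropolis, one scalar coordinate at a time, with
  Robbins–Monro step-size adaptation toward 0.44 acceptance.  Adaptation is
  frozen at the end of burn-in so the retained draws come from a fixed,
  detailed-balance-preserving kernel.

The per-iteration sweep is compiled with numba; chains are seeded
deterministically from the base seed, so identical configurations yield
bit-identical output.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import arviz as az
import numpy as np
import pandas as pd
from numba import njit

from .core import LOGIT_CLIP, ModelSpec, build_design, inverse_logit
from .data_model import CovariateTable, DetectionData

__all__ = [
    "McmcConfig",
    "PosteriorSamples",
    "GofResult",
    "run_mcmc",
    "gelman_rubin",
    "bayesian_p_value",
]

TARGET_ACCEPTANCE = 0.44


@dataclass(frozen=True)
class McmcConfig:
    """Chain-length and seeding configuration.

    The field study's protocol — 3 chains of 150,000 iterations, burn-in
    50,000, thinning 100 — retains (150000-50000)/100 = 1000 draws per chain,
    3000 in total.  ``adapt_until`` bounds proposal adaptation and defaults
    to the burn-in.
    """

    chains: int = 3
    iterations: int = 150_000
    burn_in: int = 50_000
    thin: int = 100
    base_seed: int = 0
    adapt_until: int | None = None

    def __post_init__(self) -> None:
        if self.chains < 1:
            raise ValueError("need at least one chain")
        if not (0 <= self.burn_in < self.iterations):
            raise ValueError("burn_in must satisfy 0 <= burn_in < iterations")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.adapt_until is not None and self.adapt_until > self.iterations:
            raise ValueError("adapt_until cannot exceed iterations")

    @property
    def retained_per_chain(self) -> int:
        span = self.iterations - self.burn_in
        return (span + self.thin - 1) // self.thin

    @property
    def effective_adapt_until(self) -> int:
        return self.burn_in if self.adapt_until is None else self.adapt_until


# ---------------------------------------------------------------------------
# compiled sampler sweep
# ---------------------------------------------------------------------------


@njit(cache=False)
def _sig(x):
    if x > 35.0:
        x = 35.0
    elif x < -35.0:
        x = -35.0
    return 1.0 / (1.0 + np.exp(-x))


@njit(cache=False)
def _run_chain(
    x,  # (N, J, K) float64 in {0, 1}
    mask,  # (J, K) float64 in {0, 1}
    detij,  # (N, J) int8 — any detection at the species-site
    Xocc,  # (J, Co)
    Xdet,  # (J, K, Cd)
    W,  # (N, H) species coefficients, modified in place
    mu,  # (H,) hyper-means
    sig,  # (H,) hyper-sds
    hyper_mean_sd,
    sig_upper,
    fix_hypers,  # 0/1
    n_iter,
    burn,
    thin,
    adapt_until,
    seed,
):
    N, J, K = x.shape
    Co = Xocc.shape[1]
    Cd = Xdet.shape[2]
    H = 2 + Co + Cd
    np.random.seed(seed)

    # cached linear predictors
    eta_occ = np.empty((N, J))
    for i in range(N):
        for j in range(J):
            e = W[i, 0]
            for c in range(Co):
                e += W[i, 2 + c] * Xocc[j, c]
            eta_occ[i, j] = e
    eta_det = np.empty((N, J, K))
    for i in range(N):
        for j in range(J):
            for k in range(K):
                e = W[i, 1]
                for c in range(Cd):
                    e += W[i, 2 + Co + c] * Xdet[j, k, c]
                eta_det[i, j, k] = e

    z = np.empty((N, J), np.int8)
    for i in range(N):
        for j in range(J):
            z[i, j] = detij[i, j]

    lstep = np.full((N, H), np.log(0.5))
    lstep_sig = np.full(H, np.log(0.5))
    acc = np.zeros(H)
    tries = np.zeros(H)
    acc_sig = np.zeros(H)
    tries_sig = np.zeros(H)

    span = n_iter - burn
    n_ret = (span + thin - 1) // thin
    P = N * H + 2 * H
    draws = np.empty((n_ret, P))
    zdraws = np.empty((n_ret, N, J), np.int8)
    r = 0

    for t in range(n_iter):
        gain = (t + 1.0) ** (-0.6)
        if gain > 0.05:
            gain = 0.05

        # --- latent occupancy: exact Bernoulli full conditional -----------
        for i in range(N):
            for j in range(J):
                if detij[i, j] == 1:
                    z[i, j] = 1
                else:
                    psi = _sig(eta_occ[i, j])
                    lp0 = 0.0
                    for k in range(K):
                        if mask[j, k] == 1.0:
                            lp0 += np.log(1.0 - _sig(eta_det[i, j, k]))
                    q1 = psi * np.exp(lp0)
                    pz = q1 / (q1 + 1.0 - psi)
                    z[i, j] = 1 if np.random.random() < pz else 0

        # --- species coefficients: scalar random-walk Metropolis ----------
        for h in range(H):
            occ_fam = h == 0 or (2 <= h < 2 + Co)
            for i in range(N):
                d = np.exp(lstep[i, h]) * np.random.normal()
                wold = W[i, h]
                wnew = wold + d
                s2 = sig[h] * sig[h]
                dlp = -0.5 * ((wnew - mu[h]) ** 2 - (wold - mu[h]) ** 2) / s2
                if occ_fam:
                    for j in range(J):
                        xc = 1.0 if h == 0 else Xocc[j, h - 2]
                        if xc == 0.0:
                            continue
                        pn = _sig(eta_occ[i, j] + d * xc)
                        po = _sig(eta_occ[i, j])
                        if z[i, j] == 1:
                            dlp += np.log(pn) - np.log(po)
                        else:
                            dlp += np.log(1.0 - pn) - np.log(1.0 - po)
                else:
                    c = -1 if h == 1 else h - 2 - Co
                    for j in range(J):
                        if z[i, j] == 1:
                            for k in range(K):
                                if mask[j, k] == 1.0:
                                    xc = 1.0 if h == 1 else Xdet[j, k, c]
                                    if xc == 0.0:
                                        continue
                                    pn = _sig(eta_det[i, j, k] + d * xc)
                                    po = _sig(eta_det[i, j, k])
                                    if x[i, j, k] == 1.0:
                                        dlp += np.log(pn) - np.log(po)
                                    else:
                                        dlp += np.log(1.0 - pn) - np.log(1.0 - po)
                ap = 1.0 if dlp >= 0.0 else np.exp(dlp)
                if np.random.random() < ap:
                    W[i, h] = wnew
                    if occ_fam:
                        for j in range(J):
                            xc = 1.0 if h == 0 else Xocc[j, h - 2]
                            eta_occ[i, j] += d * xc
                    else:
                        c = -1 if h == 1 else h - 2 - Co
                        for j in range(J):
                            for k in range(K):
                                xc = 1.0 if h == 1 else Xdet[j, k, c]
                                eta_det[i, j, k] += d * xc
                    if t >= burn:
                        acc[h] += 1.0
                if t < adapt_until:
                    lstep[i, h] += gain * (ap - 0.44)
                if t >= burn:
                    tries[h] += 1.0

        # --- community hyper-parameters ------------------------------------
        if fix_hypers == 0:
            for h in range(H):
                # conjugate Normal update for the hyper-mean
                s2 = sig[h] * sig[h]
                prec = N / s2 + 1.0 / (hyper_mean_sd * hyper_mean_sd)
                tot = 0.0
                for i in range(N):
                    tot += W[i, h]
                mean = (tot / s2) / prec
                mu[h] = mean + np.random.normal() / np.sqrt(prec)

                # random walk on log hyper-sd, Uniform(0, upper) prior
                tcur = np.log(sig[h])
                tprop = tcur + np.exp(lstep_sig[h]) * np.random.normal()
                signew = np.exp(tprop)
                if signew < sig_upper:
                    ss = 0.0
                    for i in range(N):
                        ss += (W[i, h] - mu[h]) ** 2
                    lp_new = -N * tprop - 0.5 * ss * np.exp(-2.0 * tprop) + tprop
                    lp_old = -N * tcur - 0.5 * ss * np.exp(-2.0 * tcur) + tcur
                    dlp = lp_new - lp_old
                    ap = 1.0 if dlp >= 0.0 else np.exp(dlp)
                else:
                    ap = 0.0
                if np.random.random() < ap:
                    sig[h] = signew
                    if t >= burn:
                        acc_sig[h] += 1.0
                if t < adapt_until:
                    lstep_sig[h] += gain * (ap - 0.44)
                if t >= burn:
                    tries_sig[h] += 1.0

        # --- store ---------------------------------------------------------
        if t >= burn and (t - burn) % thin == 0:
            for i in range(N):
                for h in range(H):
                    draws[r, i * H + h] = W[i, h]
            for h in range(H):
                draws[r, N * H + h] = mu[h]
                draws[r, N * H + H + h] = sig[h]
            for i in range(N):
                for j in range(J):
                    zdraws[r, i, j] = z[i, j]
            r += 1

    return draws, zdraws, acc, tries, acc_sig, tries_sig


# ---------------------------------------------------------------------------
# posterior container
# ---------------------------------------------------------------------------


class PosteriorSamples:
    """Retained MCMC draws across chains with full provenance.

    ``draws`` is (chains, retained, P) with ``param_names`` naming the last
    axis: species-level coefficients first (``u[sp]``, ``alpha[cov][sp]``,
    ...), then hyper-means (``mu_u``, ``mu_alpha[cov]``, ...) and hyper-sds.
    ``z_draws`` (chains, retained, N, J) holds the thinned latent occupancy
    states when stored.
    """

    def __init__(
        self,
        draws: np.ndarray,
        param_names: list[str],
        families: list[str],
        species_ids: list[str],
        site_ids: list[str],
        occ_cov_names: list[str],
        det_cov_names: list[str],
        z_draws: np.ndarray | None = None,
        acceptance: dict[str, float] | None = None,
        config: McmcConfig | None = None,
        model_spec: ModelSpec | None = None,
        site_scaling: pd.DataFrame | None = None,
        chain_seeds: list[int] | None = None,
    ) -> None:
        self.draws = np.asarray(draws, dtype=float)
        if self.draws.ndim != 3:
            raise ValueError("draws must be (chains, retained, parameters)")
        if self.draws.shape[2] != len(param_names):
            raise ValueError("param_names must match the parameter axis")
        self.param_names = list(param_names)
        self.families = list(families)
        self.species_ids = list(species_ids)
        self.site_ids = list(site_ids)
        self.occ_cov_names = list(occ_cov_names)
        self.det_cov_names = list(det_cov_names)
        self.z_draws = None if z_draws is None else np.asarray(z_draws, dtype=np.int8)
        self.acceptance = dict(acceptance or {})
        self.config = config
        self.model_spec = model_spec
        self.site_scaling = site_scaling
        self.chain_seeds = list(chain_seeds or [])
        self._index = {name: p for p, name in enumerate(self.param_names)}

    # -- shapes ------------------------------------------------------------
    @property
    def n_chains(self) -> int:
        return self.draws.shape[0]

    @property
    def n_retained(self) -> int:
        return self.draws.shape[1]

    @property
    def n_species(self) -> int:
        return len(self.species_ids)

    @property
    def n_families(self) -> int:
        return len(self.families)

    @property
    def hyper_names(self) -> list[str]:
        return [n for n in self.param_names if n.startswith(("mu_", "sigma_"))]

    # -- access ------------------------------------------------------------
    def get(self, name: str) -> np.ndarray:
        """(chains, retained) draws of one scalar parameter."""
        try:
            p = self._index[name]
        except KeyError:
            raise KeyError(f"unknown parameter {name!r}") from None
        return self.draws[:, :, p]

    def pooled(self, name: str) -> np.ndarray:
        return self.get(name).reshape(-1)

    def species_draws(self, family: str) -> np.ndarray:
        """(pooled draws, N) array of one coefficient family across species."""
        try:
            h = self.families.index(family)
        except ValueError:
            raise KeyError(f"unknown family {family!r} ({self.families})") from None
        H = self.n_families
        cols = [i * H + h for i in range(self.n_species)]
        return self.draws[:, :, cols].reshape(-1, self.n_species)

    def pooled_z(self) -> np.ndarray:
        if self.z_draws is None:
            raise ValueError(
                "no latent-occupancy draws stored; re-run the fit with store_z=True"
            )
        C, T, N, J = self.z_draws.shape
        return self.z_draws.reshape(C * T, N, J)

    def to_inference_data(self) -> az.InferenceData:
        data = {name: self.get(name) for name in self.param_names}
        return az.from_dict(posterior={k: v for k, v in data.items()})

    # -- persistence ---------------------------------------------------------
    def save(self, directory) -> None:
        """One delimited table per chain plus a JSON manifest; loads bit-exactly."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for c in range(self.n_chains):
            # default float formatting is the shortest round-trip repr
            pd.DataFrame(self.draws[c], columns=self.param_names).to_csv(
                directory / f"chain_{c}.csv", index=False
            )
            if self.z_draws is not None:
                np.savetxt(
                    directory / f"chain_{c}_z.csv",
                    self.z_draws[c].reshape(self.n_retained, -1),
                    fmt="%d",
                    delimiter=",",
                )
        manifest = {
            "param_names": self.param_names,
            "families": self.families,
            "species_ids": self.species_ids,
            "site_ids": self.site_ids,
            "occ_cov_names": self.occ_cov_names,
            "det_cov_names": self.det_cov_names,
            "acceptance": self.acceptance,
            "chain_seeds": self.chain_seeds,
            "n_chains": self.n_chains,
            "has_z": self.z_draws is not None,
            "config": None if self.config is None else asdict(self.config),
            "model_spec": None
            if self.model_spec is None
            else {
                "occupancy_covariates": list(self.model_spec.occupancy_covariates),
                "detection_covariates": list(self.model_spec.detection_covariates),
                "hyper_mean_sd": self.model_spec.hyper_mean_sd,
                "hyper_sd_upper": self.model_spec.hyper_sd_upper,
            },
            "site_scaling": None
            if self.site_scaling is None
            else {
                "index": list(self.site_scaling.index),
                "mean": [float(v) for v in self.site_scaling["mean"]],
                "sd": [float(v) for v in self.site_scaling["sd"]],
            },
        }
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))

    @classmethod
    def load(cls, directory) -> "PosteriorSamples":
        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text())
        chains = []
        zchains = []
        for c in range(manifest["n_chains"]):
            chains.append(
                pd.read_csv(
                    directory / f"chain_{c}.csv", float_precision="round_trip"
                ).to_numpy(dtype=float)
            )
            if manifest["has_z"]:
                zc = np.loadtxt(directory / f"chain_{c}_z.csv", dtype=np.int8, delimiter=",")
                zc = zc.reshape(
                    chains[-1].shape[0],
                    len(manifest["species_ids"]),
                    len(manifest["site_ids"]),
                )
                zchains.append(zc)
        cfg = manifest["config"]
        spec = manifest["model_spec"]
        sc = manifest["site_scaling"]
        return cls(
            draws=np.stack(chains),
            param_names=manifest["param_names"],
            families=manifest["families"],
            species_ids=manifest["species_ids"],
            site_ids=manifest["site_ids"],
            occ_cov_names=manifest["occ_cov_names"],
            det_cov_names=manifest["det_cov_names"],
            z_draws=np.stack(zchains) if zchains else None,
            acceptance=manifest["acceptance"],
            config=None if cfg is None else McmcConfig(**cfg),
            model_spec=None
            if spec is None
            else ModelSpec(
                occupancy_covariates=tuple(spec["occupancy_covariates"]),
                detection_covariates=tuple(spec["detection_covariates"]),
                hyper_mean_sd=spec["hyper_mean_sd"],
                hyper_sd_upper=spec["hyper_sd_upper"],
            ),
            site_scaling=None
            if sc is None
            else pd.DataFrame({"mean": sc["mean"], "sd": sc["sd"]}, index=sc["index"]),
            chain_seeds=manifest["chain_seeds"],
        )


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def _param_names(families: list[str], species_ids: list[str]) -> list[str]:
    names = []
    for sp in species_ids:
        for fam in families:
            names.append(f"{fam}[{sp}]")
    for fam in families:
        names.append(f"mu_{fam}")
    for fam in families:
        names.append(f"sigma_{fam}")
    return names


def run_mcmc(
    data: DetectionData,
    site_covs: CovariateTable,
    occasion_covs: CovariateTable | None,
    spec: ModelSpec,
    cfg: McmcConfig,
    fixed_hypers: dict[str, tuple[float, float]] | None = None,
    store_z: bool = True,
) -> PosteriorSamples:
    """Sample the posterior of the MSOM by Metropolis-within-Gibbs.

    ``fixed_hypers`` maps family labels (``"u"``, ``"alpha[forest_cover]"``,
    ...) to fixed (mean, sd) values; when given for all families the
    community layer is held constant (used for exact-posterior checks on toy
    models).  Chains are initialized overdispersed from per-chain seeds
    derived from ``cfg.base_seed``.
    """
    if data.x.sum() == 0:
        raise ValueError(
            "no detections anywhere: the detection layer is unidentified"
        )
    Xocc, Xdet = build_design(
        spec,
        site_covs,
        occasion_covs,
        n_occasions=data.n_occasions,
        observed_mask=data.observed_mask,
    )
    if Xocc.shape[0] != data.n_sites:
        raise ValueError("covariate tables and detection data disagree on J")
    families = spec.families
    H = len(families)
    N, J, K = data.x.shape

    fix_all = False
    mu_fix = np.zeros(H)
    sig_fix = np.ones(H)
    if fixed_hypers is not None:
        unknown = set(fixed_hypers) - set(families)
        if unknown:
            raise KeyError(f"fixed_hypers names unknown families: {sorted(unknown)}")
        if set(fixed_hypers) != set(families):
            raise ValueError("fixed_hypers must cover every family or be None")
        for h, fam in enumerate(families):
            m, s = fixed_hypers[fam]
            if s <= 0:
                raise ValueError("fixed hyper-sd must be positive")
            mu_fix[h] = m
            sig_fix[h] = s
        fix_all = True

    x64 = np.ascontiguousarray(data.x, dtype=np.float64)
    mask64 = np.ascontiguousarray(data.observed_mask, dtype=np.float64)
    detij = np.ascontiguousarray(data.detected_anywhere, dtype=np.int8)

    all_draws = []
    all_z = []
    acc_tot = np.zeros(H)
    tries_tot = np.zeros(H)
    accs_tot = np.zeros(H)
    triess_tot = np.zeros(H)
    chain_seeds = []
    for chain in range(cfg.chains):
        ss = np.random.SeedSequence([int(cfg.base_seed), chain])
        init_rng = np.random.default_rng(ss)
        kernel_seed = int(ss.generate_state(1, np.uint32)[0]) % (2**31)
        chain_seeds.append(kernel_seed)

        if fix_all:
            mu0 = mu_fix.copy()
            sig0 = sig_fix.copy()
        else:
            mu0 = init_rng.normal(0.0, 1.0, H)
            sig0 = init_rng.uniform(0.5, 2.0, H)
        W0 = mu0 + sig0 * init_rng.normal(0.0, 0.5, (N, H))

        # guard: the initial state must have a finite (log) posterior
        eta0 = W0[:, 0:1] + W0[:, 2 : 2 + Xocc.shape[1]] @ Xocc.T
        if not np.isfinite(eta0).all():
            raise ValueError("non-finite initial log posterior: check covariates")

        draws, zdraws, acc, tries, acc_sig, tries_sig = _run_chain(
            x64,
            mask64,
            detij,
            Xocc,
            Xdet,
            W0,
            mu0,
            sig0,
            float(spec.hyper_mean_sd),
            float(spec.hyper_sd_upper),
            1 if fix_all else 0,
            int(cfg.iterations),
            int(cfg.burn_in),
            int(cfg.thin),
            int(cfg.effective_adapt_until),
            kernel_seed,
        )
        all_draws.append(draws)
        all_z.append(zdraws)
        acc_tot += acc
        tries_tot += tries
        accs_tot += acc_sig
        triess_tot += tries_sig

    acceptance = {}
    for h, fam in enumerate(families):
        if tries_tot[h] > 0:
            acceptance[f"coef[{fam}]"] = float(acc_tot[h] / tries_tot[h])
        if not fix_all and triess_tot[h] > 0:
            acceptance[f"sigma[{fam}]"] = float(accs_tot[h] / triess_tot[h])

    return PosteriorSamples(
        draws=np.stack(all_draws),
        param_names=_param_names(families, data.species_ids),
        families=families,
        species_ids=data.species_ids,
        site_ids=data.site_ids,
        occ_cov_names=list(spec.occupancy_covariates),
        det_cov_names=list(spec.detection_covariates),
        z_draws=np.stack(all_z) if store_z else None,
        acceptance=acceptance,
        config=cfg,
        model_spec=spec,
        site_scaling=site_covs.scaling,
        chain_seeds=chain_seeds,
    )


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------


def gelman_rubin(samples: PosteriorSamples, parameters: list[str] | None = None) -> pd.Series:
    """Split-chain rank-normalized R-hat per scalar parameter.

    Values near 1 indicate the chains agree; the conventional flag is 1.1.
    Requires >= 2 chains and >= 4 retained draws per chain.
    """
    if samples.n_chains < 2:
        raise ValueError("R-hat needs at least two chains")
    if samples.n_retained < 4:
        raise ValueError("R-hat needs at least four retained draws per chain")
    names = parameters if parameters is not None else samples.param_names
    out = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for name in names:
            arr = samples.get(name)
            if np.allclose(arr, arr.flat[0]):
                out[name] = 1.0  # degenerate (constant) parameter
            else:
                out[name] = float(az.rhat(arr, method="rank"))
    return pd.Series(out, name="rhat")


# ---------------------------------------------------------------------------
# posterior-predictive goodness of fit
# ---------------------------------------------------------------------------


@dataclass
class GofResult:
    """Bayesian p-value with the per-draw discrepancies behind it."""

    bayes_p: float
    chi2_obs: np.ndarray
    chi2_sim: np.ndarray


def _expected_counts(samples, Xocc, Xdet, mask, chunk):
    """Yield (slice, psi, p) per chunk of pooled draws."""
    H = samples.n_families
    N = samples.n_species
    Co = Xocc.shape[1]
    D = samples.n_chains * samples.n_retained
    flat = samples.draws.reshape(D, -1)
    W = flat[:, : N * H].reshape(D, N, H)
    for start in range(0, D, chunk):
        sl = slice(start, min(start + chunk, D))
        Wc = W[sl]
        eta_occ = Wc[:, :, 0][:, :, None] + np.einsum("dic,jc->dij", Wc[:, :, 2 : 2 + Co], Xocc)
        eta_det = Wc[:, :, 1][:, :, None, None] + np.einsum(
            "dic,jkc->dijk", Wc[:, :, 2 + Co :], Xdet
        )
        yield sl, inverse_logit(eta_occ), inverse_logit(eta_det)


def bayesian_p_value(
    samples: PosteriorSamples,
    data: DetectionData,
    site_covs: CovariateTable,
    occasion_covs: CovariateTable | None = None,
    seed: int = 0,
    conditional: bool = False,
    chunk: int = 200,
) -> GofResult:
    """Posterior-predictive check: Pr(chi2_obs > chi2_sim) over retained draws.

    Discrepancy is a Pearson-style chi-square on species-by-site detection
    totals, ``sum_ij (O_ij - E_ij)^2 / (E_ij + 0.5)``, with expected counts
    marginal over occupancy, ``E_ij = psi_ij * sum_k p_ijk`` over surveyed
    occasions (``conditional=True`` instead conditions on the stored z draw).
    For each retained draw a replicate dataset is simulated from the model
    at that draw and scored identically.  Values above 0.95 or below 0.05
    indicate lack of fit.
    """
    if samples.model_spec is None:
        raise ValueError("samples carry no model spec")
    Xocc, Xdet = build_design(
        samples.model_spec,
        site_covs,
        occasion_covs,
        n_occasions=data.n_occasions,
        observed_mask=data.observed_mask,
    )
    mask = data.observed_mask.astype(float)
    O = (data.x * data.observed_mask[None, :, :]).sum(axis=2).astype(float)  # (N, J)
    D = samples.n_chains * samples.n_retained
    chi2_obs = np.empty(D)
    chi2_sim = np.empty(D)
    rng = np.random.default_rng(seed)
    zpool = samples.pooled_z() if conditional else None
    for sl, psi, p in _expected_counts(samples, Xocc, Xdet, mask, chunk):
        psum = (p * mask[None, None, :, :]).sum(axis=3)  # (d, N, J)
        if conditional:
            E = zpool[sl].astype(float) * psum
        else:
            E = psi * psum
        chi2_obs[sl] = ((O[None] - E) ** 2 / (E + 0.5)).sum(axis=(1, 2))
        # replicate data simulated from the model at each draw
        z_rep = rng.random(psi.shape) < psi
        x_rep = (rng.random(p.shape) < p) & z_rep[:, :, :, None] & (
            mask[None, None, :, :] > 0
        )
        O_rep = x_rep.sum(axis=3).astype(float)
        chi2_sim[sl] = ((O_rep - E) ** 2 / (E + 0.5)).sum(axis=(1, 2))
    return GofResult(
        bayes_p=float((chi2_obs > chi2_sim).mean()),
        chi2_obs=chi2_obs,
        chi2_sim=chi2_sim,
    )
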