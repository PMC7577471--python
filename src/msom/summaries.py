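"""Posterior summarization: credible intervals, effect strength, richness.

Summaries follow the JAGS-era conventions of community occupancy studies:
pooled-chain posterior means with equal-tailed 95% credible intervals
(linear-interpolation percentiles).  Covariate effects are classed as
*strong* when the 95% CI excludes zero; otherwise the posterior mass on the
dominant side of zero decides between *moderate* (>= 0.80 by default) and
*weak*.  Detection-corrected species richness comes from the latent
occupancy draws (estimated richness can never fall below the observed count
because z is forced to 1 wherever a species was detected), and richness
over a covariate grid is the posterior mean of the summed occupancy
probabilities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import inverse_logit
from .data_model import CovariateTable, DetectionData, observed_richness
from .inference import PosteriorSamples

__all__ = [
    "SummaryRow",
    "EffectClass",
    "EffectTally",
    "summarize",
    "hyper_summary",
    "species_summary",
    "classify_effect",
    "estimated_richness",
    "predict_richness",
    "effect_tally",
]

CI_LEVEL = 0.95


@dataclass(frozen=True)
class SummaryRow:
    parameter: str
    mean: float
    ci_low: float
    ci_high: float


@dataclass(frozen=True)
class EffectClass:
    """Strength class of one covariate effect: strong / moderate / weak."""

    label: str  # strong | moderate | weak
    sign: str  # positive | negative
    side_mass: float  # max posterior mass on one side of zero


@dataclass
class EffectTally:
    """Counts of effect classes across species plus headline percentages."""

    counts: pd.DataFrame  # index strong/moderate/weak, columns positive/negative
    n_species: int
    pct_negative: float  # % of species with a negative posterior-mean effect

    def pct(self, label: str) -> float:
        """Percentage of species in one strength class (e.g. 13 of 25 -> 52.0)."""
        if self.n_species == 0:
            return 0.0
        return float(self.counts.loc[label].sum()) / self.n_species * 100.0


def _ci(draws: np.ndarray, level: float = CI_LEVEL) -> tuple[float, float]:
    lo = (1.0 - level) / 2.0 * 100.0
    lo_v, hi_v = np.percentile(draws, [lo, 100.0 - lo])  # linear interpolation
    return float(lo_v), float(hi_v)


def summarize(
    samples: PosteriorSamples,
    parameters: Sequence[str] | None = None,
    level: float = CI_LEVEL,
) -> pd.DataFrame:
    """Pooled-chain mean and equal-tailed credible bounds per parameter."""
    names = list(parameters) if parameters is not None else samples.param_names
    total = samples.n_chains * samples.n_retained
    if total < 100:
        warnings.warn(
            f"only {total} pooled draws; summaries will be noisy", stacklevel=2
        )
    rows = []
    for name in names:
        d = samples.pooled(name)  # raises KeyError for unknown names
        lo, hi = _ci(d, level)
        mean = float(d.mean())
        if lo == hi:
            warnings.warn(f"degenerate credible interval for {name!r}", stacklevel=2)
        elif not (lo <= mean <= hi):
            warnings.warn(
                f"posterior mean of {name!r} falls outside its percentile CI",
                stacklevel=2,
            )
        rows.append((name, mean, lo, hi))
    return pd.DataFrame(rows, columns=["parameter", "mean", "ci_low", "ci_high"])


def hyper_summary(samples: PosteriorSamples, level: float = CI_LEVEL) -> pd.DataFrame:
    """Community-level (hyper-parameter) summary table."""
    return summarize(samples, samples.hyper_names, level)


def classify_effect(
    draws: np.ndarray, level: float = CI_LEVEL, moderate_mass: float = 0.80
) -> EffectClass:
    """Class a coefficient by its posterior: strong iff the CI excludes zero,
    else moderate when >= ``moderate_mass`` of the posterior sits on one side
    of zero, weak otherwise (mass near 0.5 means the CI is centred on zero)."""
    draws = np.asarray(draws, dtype=float)
    if draws.size < 2:
        raise ValueError("need at least two draws to classify an effect")
    lo, hi = _ci(draws, level)
    sign = "positive" if draws.mean() >= 0 else "negative"
    side_mass = float(max((draws > 0).mean(), (draws < 0).mean()))
    if lo > 0 or hi < 0:
        return EffectClass("strong", sign, side_mass)
    if side_mass >= moderate_mass:
        return EffectClass("moderate", sign, side_mass)
    return EffectClass("weak", sign, side_mass)


def species_summary(
    samples: PosteriorSamples, family: str, level: float = CI_LEVEL
) -> pd.DataFrame:
    """Per-species posterior summary and effect class for one coefficient family."""
    draws = samples.species_draws(family)
    rows = []
    for i, sp in enumerate(samples.species_ids):
        d = draws[:, i]
        lo, hi = _ci(d, level)
        cls = classify_effect(d, level)
        rows.append((sp, float(d.mean()), lo, hi, cls.label, cls.sign, cls.side_mass))
    return pd.DataFrame(
        rows,
        columns=["species", "mean", "ci_low", "ci_high", "effect", "sign", "side_mass"],
    )


def estimated_richness(
    samples: PosteriorSamples,
    data: DetectionData,
    grouping: Mapping[str, str] | None = None,
    level: float = CI_LEVEL,
) -> pd.DataFrame:
    """Detection-corrected species richness per site (or per site group).

    Per retained draw, site richness is the number of species with z = 1;
    group richness counts species with z = 1 anywhere in the group.  Observed
    richness (raw detections) is attached for comparison and is a lower
    bound by construction.
    """
    z = samples.pooled_z()  # (D, N, J) — raises if not stored
    obs = observed_richness(data, grouping)
    if grouping is None:
        rich = z.sum(axis=1)  # (D, J)
        labels = data.site_ids
    else:
        missing = [s for s in data.site_ids if s not in grouping]
        if missing:
            raise ValueError(f"sites missing from grouping: {missing}")
        labels = list(obs.index)
        cols = []
        for g in labels:
            idx = [j for j, s in enumerate(data.site_ids) if grouping[s] == g]
            cols.append(z[:, :, idx].any(axis=2).sum(axis=1))
        rich = np.column_stack(cols)
    rows = []
    for col, label in enumerate(labels):
        d = rich[:, col].astype(float)
        lo, hi = _ci(d, level)
        rows.append((label, int(obs.loc[label]), float(d.mean()), lo, hi))
    key = "site" if grouping is None else "group"
    return pd.DataFrame(
        rows, columns=[key, "observed", "posterior_mean", "ci_low", "ci_high"]
    )


def predict_richness(
    samples: PosteriorSamples,
    grid: CovariateTable,
    ci: bool = False,
    level: float = CI_LEVEL,
) -> pd.DataFrame:
    """Expected species richness sum_i psi_i(x) over a covariate grid.

    The grid must carry the same occupancy covariates as the fit and be
    standardized with the fit's scaling (see
    :func:`msom.data_model.standardize_like`).  Expected richness, not a
    thresholded z, is used: the posterior mean of the summed occupancy
    probabilities is an unbiased estimate of richness at covariate value x.
    """
    if list(grid.names) != list(samples.occ_cov_names):
        raise ValueError(
            f"grid covariates {grid.names} do not match the fit's occupancy "
            f"covariates {samples.occ_cov_names}"
        )
    if not grid.standardized:
        raise ValueError("grid must be standardized with the fit's covariate scaling")
    X = grid.values  # (G, Co)
    u = samples.species_draws("u")  # (D, N)
    alphas = [samples.species_draws(f"alpha[{c}]") for c in samples.occ_cov_names]
    eta = u[:, :, None] + sum(
        a[:, :, None] * X[None, None, :, c] for c, a in enumerate(alphas)
    ) if alphas else np.repeat(u[:, :, None], X.shape[0], axis=2)
    rich = inverse_logit(eta).sum(axis=1)  # (D, G)
    out = pd.DataFrame({"expected_richness": rich.mean(axis=0)})
    if ci:
        lo = (1.0 - level) / 2.0 * 100.0
        qs = np.percentile(rich, [lo, 100.0 - lo], axis=0)
        out["ci_low"] = qs[0]
        out["ci_high"] = qs[1]
    return out


def effect_tally(classes: Mapping[str, EffectClass]) -> EffectTally:
    """Tabulate effect classes across species for one covariate."""
    counts = pd.DataFrame(
        0,
        index=pd.Index(["strong", "moderate", "weak"], name="effect"),
        columns=["positive", "negative"],
    )
    n_negative = 0
    for cls in classes.values():
        counts.loc[cls.label, cls.sign] += 1
        if cls.sign == "negative":
            n_negative += 1
    n = len(classes)
    pct_neg = 0.0 if n == 0 else n_negative / n * 100.0
    return EffectTally(counts=counts, n_species=n, pct_negative=pct_neg)
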