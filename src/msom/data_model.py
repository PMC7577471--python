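"""Detection histories, covariates, and covariate-preparation rules.

The raw material of a multi-species occupancy analysis is the detection
history x(i, j, k): a binary record of whether species *i* was detected at
site *j* on survey occasion *k*.  Because field designs mix methods (camera
nights, transects, point counts, quadrats) and seasons, occasion counts are
unequal across sites, so an explicit occasion manifest marks which (site,
occasion) cells were actually surveyed; unsurveyed cells carry no
information and are excluded from every likelihood and count.

This module houses the containers (:class:`DetectionData`,
:class:`CovariateTable`), delimited-text I/O, and the standard covariate
preparation steps: z-score standardization, pooling of the seven land-cover
classes into forest / degraded forest / anthropogenic habitat, and
collinearity screening by pairwise correlation and variance inflation
factors.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DetectionData",
    "CovariateTable",
    "HabitatClassTable",
    "ScreeningReport",
    "SEVEN_COVER_CLASSES",
    "POOLED_CLASSES",
    "read_detection_records",
    "write_detection_records",
    "read_site_covariates",
    "write_site_covariates",
    "read_occasion_covariates",
    "write_occasion_covariates",
    "read_supplementary_workbook",
    "standardize",
    "unstandardize",
    "standardize_like",
    "screen_collinearity",
    "pool_habitat_covers",
    "assign_habitat_classes",
    "detection_counts",
    "naive_occupancy",
    "observed_richness",
]


def _natural_key(value) -> tuple:
    """Sort key treating embedded integers numerically (site2 < site10)."""
    parts = re.split(r"(\d+)", str(value))
    return tuple((0, int(p)) if p.isdigit() else (1, p) for p in parts if p != "")


def _sorted_ids(values: Iterable) -> list[str]:
    return sorted({str(v) for v in values}, key=_natural_key)


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class DetectionData:
    """Dense binary detection array with an explicit surveyed-occasion mask.

    ``x[i, j, k]`` is 1 when species ``species_ids[i]`` was detected at site
    ``site_ids[j]`` on occasion ``occasion_ids[k]``.  ``observed_mask[j, k]``
    is 1 where the occasion was actually surveyed; ``x`` is defined only
    there and must be 0 elsewhere.
    """

    species_ids: list[str]
    site_ids: list[str]
    occasion_ids: list[str]
    x: np.ndarray  # (N, J, K) int8
    observed_mask: np.ndarray  # (J, K) int8

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=np.int8)
        self.observed_mask = np.asarray(self.observed_mask, dtype=np.int8)
        n, j, k = self.x.shape
        if n < 1 or j < 1 or k < 1:
            raise ValueError("DetectionData requires N, J, K >= 1")
        if (len(self.species_ids), len(self.site_ids), len(self.occasion_ids)) != (n, j, k):
            raise ValueError("axis labels do not match array shape")
        for name, ids in (
            ("species", self.species_ids),
            ("site", self.site_ids),
            ("occasion", self.occasion_ids),
        ):
            if len(set(ids)) != len(ids):
                raise ValueError(f"duplicate {name} ids")
        if self.observed_mask.shape != (j, k):
            raise ValueError("observed_mask must be J x K")
        if not np.isin(self.x, (0, 1)).all() or not np.isin(self.observed_mask, (0, 1)).all():
            raise ValueError("x and observed_mask must be binary")
        if (self.x * (1 - self.observed_mask)[None, :, :]).any():
            raise ValueError("detection recorded on an unsurveyed occasion")

    @property
    def n_species(self) -> int:
        return self.x.shape[0]

    @property
    def n_sites(self) -> int:
        return self.x.shape[1]

    @property
    def n_occasions(self) -> int:
        return self.x.shape[2]

    @property
    def detected_anywhere(self) -> np.ndarray:
        """(N, J) boolean: species detected at least once at the site."""
        return self.x.any(axis=2)

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format table with one row per surveyed (species, site, occasion)."""
        jj, kk = np.nonzero(self.observed_mask)
        rows = []
        for i, sp in enumerate(self.species_ids):
            rows.append(
                pd.DataFrame(
                    {
                        "species": sp,
                        "site": [self.site_ids[j] for j in jj],
                        "occasion": [self.occasion_ids[k] for k in kk],
                        "detected": self.x[i, jj, kk].astype(int),
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


@dataclass
class CovariateTable:
    """Named covariates at site level (J x C) or site-occasion level (J x K x C).

    When ``standardized`` is set, ``scaling`` records the raw mean and sample
    standard deviation (ddof=1) of each covariate so raw values remain
    recoverable and new data (e.g. prediction grids) can be put on the same
    scale.
    """

    names: list[str]
    level: str  # "site" | "site_occasion"
    values: np.ndarray
    standardized: bool = False
    scaling: pd.DataFrame | None = None  # index = names, columns = mean, sd
    site_ids: list[str] | None = None
    occasion_ids: list[str] | None = None

    def __post_init__(self) -> None:
        if self.level not in ("site", "site_occasion"):
            raise ValueError(f"unknown covariate level {self.level!r}")
        self.values = np.asarray(self.values, dtype=float)
        expected_ndim = 2 if self.level == "site" else 3
        if self.values.ndim != expected_ndim:
            raise ValueError(
                f"{self.level} covariates must be {expected_ndim}-d, got {self.values.ndim}-d"
            )
        if self.values.shape[-1] != len(self.names):
            raise ValueError("last axis must match number of covariate names")
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate covariate names")
        if self.standardized and self.scaling is not None:
            if (self.scaling["sd"] <= 0).any():
                raise ValueError("scaling sd must be positive")

    @property
    def n_covariates(self) -> int:
        return len(self.names)

    def column(self, name: str) -> np.ndarray:
        try:
            c = self.names.index(name)
        except ValueError:
            raise KeyError(f"covariate {name!r} not in table ({self.names})") from None
        return self.values[..., c]


@dataclass
class HabitatClassTable:
    """One pooled habitat class per site, optionally with the source fractions."""

    site_ids: list[str]
    habitat_class: list[str]  # "forest" | "degraded_forest" | "anthropogenic"
    source_fractions: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        valid = {"forest", "degraded_forest", "anthropogenic"}
        if len(self.site_ids) != len(self.habitat_class):
            raise ValueError("one class per site required")
        bad = set(self.habitat_class) - valid
        if bad:
            raise ValueError(f"unknown habitat classes: {sorted(bad)}")
        if self.source_fractions is not None:
            vals = self.source_fractions.to_numpy(dtype=float)
            if ((vals < 0) | (vals > 1)).any():
                raise ValueError("source fractions must lie in [0, 1]")

    def as_mapping(self) -> dict[str, str]:
        return dict(zip(self.site_ids, self.habitat_class))


@dataclass
class ScreeningReport:
    """Outcome of correlation/VIF screening: what was kept, what was dropped, why."""

    pairwise_r: pd.DataFrame
    vif: pd.Series
    retained: list[str]
    dropped: list[tuple[str, str]]  # (name, reason)


# ---------------------------------------------------------------------------
# detection-record I/O
# ---------------------------------------------------------------------------

_RECORD_COLUMNS = ("species", "site", "occasion", "detected")


def _validate_records(df: pd.DataFrame) -> pd.DataFrame:
    missing = set(_RECORD_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"detection records missing columns: {sorted(missing)}")
    df = df.loc[:, list(_RECORD_COLUMNS)].copy()
    for col in ("species", "site", "occasion"):
        df[col] = df[col].astype(str)
    det = pd.to_numeric(df["detected"], errors="coerce")
    if det.isna().any() or not det.isin((0, 1)).all():
        bad = df.loc[~det.isin((0, 1)) | det.isna(), "detected"].iloc[0]
        raise ValueError(f"detected values must be 0 or 1, got {bad!r}")
    df["detected"] = det.astype(int)
    keys = ["species", "site", "occasion"]
    conflicts = df.groupby(keys)["detected"].nunique()
    if (conflicts > 1).any():
        key = conflicts[conflicts > 1].index[0]
        raise ValueError(f"conflicting duplicate records for {key}")
    return df.drop_duplicates(keys)


def _build_detection(
    df: pd.DataFrame, surveyed: set[tuple[str, str]] | None
) -> DetectionData:
    record_pairs = set(zip(df["site"], df["occasion"]))
    if surveyed is None:
        surveyed = record_pairs
    species_ids = _sorted_ids(df["species"])
    site_ids = _sorted_ids(list(df["site"]) + [s for s, _ in surveyed])
    occasion_ids = _sorted_ids(list(df["occasion"]) + [o for _, o in surveyed])
    j_index = {s: j for j, s in enumerate(site_ids)}
    k_index = {o: k for k, o in enumerate(occasion_ids)}
    i_index = {s: i for i, s in enumerate(species_ids)}

    mask = np.zeros((len(site_ids), len(occasion_ids)), dtype=np.int8)
    for s, o in surveyed:
        mask[j_index[s], k_index[o]] = 1

    x = np.zeros((len(species_ids), len(site_ids), len(occasion_ids)), dtype=np.int8)
    for sp, s, o, d in df.itertuples(index=False):
        j, k = j_index[s], k_index[o]
        if mask[j, k]:  # records outside the manifest are ignored (occasion missing)
            x[i_index[sp], j, k] = d
    return DetectionData(species_ids, site_ids, occasion_ids, x, mask)


def read_detection_records(path, manifest_path=None) -> DetectionData:
    """Read long-format detection records (columns species,site,occasion,detected).

    With a manifest (columns site,occasion) listing surveyed occasions, absent
    rows at surveyed occasions mean non-detection and occasions outside the
    manifest are treated as missing.  Without one, the surveyed set is the set
    of (site, occasion) pairs appearing in the records.
    """
    df = _validate_records(pd.read_csv(path, dtype=str))
    surveyed = None
    if manifest_path is not None:
        mdf = pd.read_csv(manifest_path, dtype=str)
        missing = {"site", "occasion"} - set(mdf.columns)
        if missing:
            raise ValueError(f"occasion manifest missing columns: {sorted(missing)}")
        surveyed = set(zip(mdf["site"].astype(str), mdf["occasion"].astype(str)))
    return _build_detection(df, surveyed)


def write_detection_records(data: DetectionData, path, manifest_path=None) -> None:
    """Write records (explicit 0/1 for every surveyed cell) and optionally a manifest."""
    data.to_dataframe().to_csv(path, index=False)
    if manifest_path is not None:
        jj, kk = np.nonzero(data.observed_mask)
        pd.DataFrame(
            {
                "site": [data.site_ids[j] for j in jj],
                "occasion": [data.occasion_ids[k] for k in kk],
            }
        ).to_csv(manifest_path, index=False)


_SUPP_COLUMN_SYNONYMS = {
    "species": ("species", "species name", "scientific name", "sp"),
    "site": ("site", "grid", "grid id", "site id"),
    "occasion": ("occasion", "replicate", "survey", "sample", "occasion id"),
    "detected": ("detected", "detection", "presence", "obs", "value"),
}


def read_supplementary_workbook(path, sheet=0, column_map: Mapping[str, str] | None = None,
                                manifest_path=None) -> DetectionData:
    """Import a detection-history spreadsheet (one long sheet per taxon).

    ``column_map`` maps the canonical names (species/site/occasion/detected)
    to the workbook's column headers; without it, a small set of common
    synonyms is tried (case-insensitive).
    """
    raw = pd.read_excel(path, sheet_name=sheet)
    lower = {str(c).strip().lower(): c for c in raw.columns}
    resolved: dict[str, str] = {}
    for canon in _RECORD_COLUMNS:
        if column_map and canon in column_map:
            resolved[canon] = column_map[canon]
        else:
            for syn in _SUPP_COLUMN_SYNONYMS[canon]:
                if syn in lower:
                    resolved[canon] = lower[syn]
                    break
            else:
                raise ValueError(
                    f"cannot locate a column for {canon!r} in {list(raw.columns)}; "
                    "pass column_map"
                )
    df = raw.rename(columns={v: k for k, v in resolved.items()})
    df = _validate_records(df.astype({c: str for c in ("species", "site", "occasion")}))
    surveyed = None
    if manifest_path is not None:
        mdf = pd.read_csv(manifest_path, dtype=str)
        surveyed = set(zip(mdf["site"], mdf["occasion"]))
    return _build_detection(df, surveyed)


# ---------------------------------------------------------------------------
# covariate I/O
# ---------------------------------------------------------------------------


def read_site_covariates(path) -> CovariateTable:
    """CSV keyed by a ``site`` column; remaining columns are covariates."""
    df = pd.read_csv(path)
    if "site" not in df.columns:
        raise ValueError("site covariate file needs a 'site' column")
    df["site"] = df["site"].astype(str)
    df = df.sort_values("site", key=lambda s: s.map(_natural_key)).reset_index(drop=True)
    names = [c for c in df.columns if c != "site"]
    return CovariateTable(
        names=names,
        level="site",
        values=df[names].to_numpy(dtype=float),
        site_ids=list(df["site"]),
    )


def write_site_covariates(table: CovariateTable, path) -> None:
    if table.level != "site":
        raise ValueError("expected a site-level table")
    site = table.site_ids or [str(j) for j in range(table.values.shape[0])]
    out = pd.DataFrame(table.values, columns=table.names)
    out.insert(0, "site", site)
    out.to_csv(path, index=False)


def read_occasion_covariates(path) -> CovariateTable:
    """CSV keyed by site,occasion columns; remaining columns are covariates.

    Unlisted (site, occasion) combinations become NaN (unsurveyed occasions).
    """
    df = pd.read_csv(path)
    missing = {"site", "occasion"} - set(df.columns)
    if missing:
        raise ValueError(f"occasion covariate file missing columns: {sorted(missing)}")
    df["site"] = df["site"].astype(str)
    df["occasion"] = df["occasion"].astype(str)
    names = [c for c in df.columns if c not in ("site", "occasion")]
    site_ids = _sorted_ids(df["site"])
    occasion_ids = _sorted_ids(df["occasion"])
    values = np.full((len(site_ids), len(occasion_ids), len(names)), np.nan)
    j_index = {s: j for j, s in enumerate(site_ids)}
    k_index = {o: k for k, o in enumerate(occasion_ids)}
    for row in df.itertuples(index=False):
        values[j_index[row.site], k_index[row.occasion], :] = [
            getattr(row, n) for n in names
        ]
    return CovariateTable(
        names=names,
        level="site_occasion",
        values=values,
        site_ids=site_ids,
        occasion_ids=occasion_ids,
    )


def write_occasion_covariates(table: CovariateTable, path) -> None:
    if table.level != "site_occasion":
        raise ValueError("expected a site-occasion-level table")
    J, K, _ = table.values.shape
    site = table.site_ids or [str(j) for j in range(J)]
    occ = table.occasion_ids or [str(k) for k in range(K)]
    rows = []
    for j in range(J):
        for k in range(K):
            if np.isnan(table.values[j, k]).all():
                continue
            rows.append([site[j], occ[k], *table.values[j, k]])
    pd.DataFrame(rows, columns=["site", "occasion", *table.names]).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# covariate preparation
# ---------------------------------------------------------------------------


def standardize(table: CovariateTable) -> CovariateTable:
    """Z-score each covariate to mean 0, sample sd 1 (ddof=1), recording scaling.

    Standardizing an already-standardized table is a no-op (the recorded raw
    scaling is preserved so the inverse transform still recovers raw values).
    """
    if table.standardized:
        return replace(table, values=table.values.copy())
    flat = table.values.reshape(-1, table.n_covariates)
    means = np.nanmean(flat, axis=0)
    sds = np.nanstd(flat, axis=0, ddof=1)
    for name, sd in zip(table.names, sds):
        if not np.isfinite(sd) or sd <= 0:
            raise ValueError(f"covariate {name!r} is constant (sd = 0); cannot standardize")
    scaling = pd.DataFrame({"mean": means, "sd": sds}, index=table.names)
    return replace(
        table,
        values=(table.values - means) / sds,
        standardized=True,
        scaling=scaling,
    )


def unstandardize(table: CovariateTable) -> CovariateTable:
    """Invert :func:`standardize` using the recorded scaling."""
    if not table.standardized or table.scaling is None:
        raise ValueError("table is not standardized or has no recorded scaling")
    means = table.scaling["mean"].to_numpy()
    sds = table.scaling["sd"].to_numpy()
    return replace(table, values=table.values * sds + means, standardized=False, scaling=None)


def standardize_like(table: CovariateTable, reference: CovariateTable) -> CovariateTable:
    """Scale raw values with another table's recorded (mean, sd) — e.g. a
    prediction grid put on the scale of the covariates used in a fit."""
    if reference.scaling is None:
        raise ValueError("reference table carries no scaling")
    if table.standardized:
        raise ValueError("table is already standardized")
    try:
        sc = reference.scaling.loc[table.names]
    except KeyError as exc:
        raise KeyError(f"reference scaling lacks covariate: {exc}") from None
    means = sc["mean"].to_numpy()
    sds = sc["sd"].to_numpy()
    return replace(
        table, values=(table.values - means) / sds, standardized=True, scaling=sc.copy()
    )


def _vif(X: np.ndarray, names: Sequence[str]) -> pd.Series:
    """VIF_m = 1/(1-R^2_m) from OLS of covariate m on the others plus intercept."""
    n, m = X.shape
    out = {}
    for c in range(m):
        y = X[:, c]
        others = np.delete(X, c, axis=1)
        design = np.column_stack([np.ones(n), others])
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        resid = y - design @ coef
        ss_tot = np.sum((y - y.mean()) ** 2)
        if ss_tot == 0:
            out[names[c]] = np.inf
            continue
        r2 = 1.0 - np.sum(resid**2) / ss_tot
        out[names[c]] = np.inf if r2 >= 1.0 else 1.0 / (1.0 - r2)
    return pd.Series(out)


def screen_collinearity(
    table: CovariateTable, r_max: float = 0.60, vif_max: float = 3.0
) -> ScreeningReport:
    """Iteratively discard collinear covariates until |r| <= r_max and VIF <= vif_max.

    Correlation is Pearson on complete pairs.  At each step the covariate with
    the most |r|-threshold partners is dropped (ties broken by higher VIF,
    then by later covariate name); with no correlation violations, the highest
    VIF above threshold is dropped.
    """
    flat = table.values.reshape(-1, table.n_covariates)
    n_rows = flat.shape[0]
    if table.n_covariates < 2:
        raise ValueError("screening needs at least two covariates")
    if n_rows < 3:
        raise ValueError("screening needs at least three observations")
    if n_rows < table.n_covariates:
        raise ValueError("fewer rows than covariates: VIF undefined")

    full = pd.DataFrame(flat, columns=table.names)
    pairwise_r = full.corr(method="pearson")
    complete = full.dropna()
    vif_full = _vif(complete.to_numpy(), list(full.columns))

    active = list(table.names)
    dropped: list[tuple[str, str]] = []
    while len(active) >= 2:
        sub = full[active].dropna()
        r = full[active].corr(method="pearson").to_numpy()
        np.fill_diagonal(r, 0.0)
        partners = (np.abs(r) > r_max).sum(axis=0)
        vif = _vif(sub.to_numpy(), active)
        if partners.max() > 0:
            worst = max(
                range(len(active)),
                key=lambda c: (partners[c], vif.iloc[c], _natural_key(active[c])),
            )
            dropped.append((active[worst], "r-rule"))
            del active[worst]
        elif (vif > vif_max).any():
            worst = max(
                range(len(active)),
                key=lambda c: (vif.iloc[c], _natural_key(active[c])),
            )
            dropped.append((active[worst], "VIF-rule"))
            del active[worst]
        else:
            break
    return ScreeningReport(
        pairwise_r=pairwise_r, vif=vif_full, retained=active, dropped=dropped
    )


SEVEN_COVER_CLASSES = (
    "semi_evergreen_forest",
    "moist_deciduous_forest",
    "mangrove",
    "scrub_forest",
    "grassland",
    "settlement",
    "agriculture",
)

POOLED_CLASSES: dict[str, tuple[str, ...]] = {
    "forest": ("semi_evergreen_forest", "moist_deciduous_forest", "mangrove"),
    "degraded_forest": ("scrub_forest", "grassland"),
    "anthropogenic": ("settlement", "agriculture"),
}


def pool_habitat_covers(seven_class: CovariateTable) -> CovariateTable:
    """Pool the seven cover fractions into forest / degraded forest / anthropogenic.

    Additive pooling: the total cover at each site is conserved.
    """
    missing = [c for c in SEVEN_COVER_CLASSES if c not in seven_class.names]
    if missing:
        raise ValueError(f"missing required cover columns: {missing}")
    cols = {}
    for pooled, sources in POOLED_CLASSES.items():
        cols[pooled] = sum(seven_class.column(s) for s in sources)
    values = np.column_stack([cols[p] for p in POOLED_CLASSES])
    return CovariateTable(
        names=list(POOLED_CLASSES),
        level="site",
        values=values,
        site_ids=seven_class.site_ids,
    )


def assign_habitat_classes(pooled: CovariateTable) -> HabitatClassTable:
    """Dominant pooled class per site (ties favour forest, then degraded forest)."""
    for name in POOLED_CLASSES:
        if name not in pooled.names:
            raise ValueError(f"pooled table missing {name!r} column")
    frac = np.column_stack([pooled.column(n) for n in POOLED_CLASSES])
    classes = [list(POOLED_CLASSES)[c] for c in np.argmax(frac, axis=1)]
    site_ids = pooled.site_ids or [str(j) for j in range(frac.shape[0])]
    return HabitatClassTable(
        site_ids=list(site_ids),
        habitat_class=classes,
        source_fractions=pd.DataFrame(frac, index=site_ids, columns=list(POOLED_CLASSES)),
    )


# ---------------------------------------------------------------------------
# descriptive summaries
# ---------------------------------------------------------------------------


def detection_counts(data: DetectionData) -> pd.DataFrame:
    """Per-species total detections and number of sites with >= 1 detection."""
    totals = data.x.sum(axis=(1, 2))
    sites = data.detected_anywhere.sum(axis=1)
    return pd.DataFrame(
        {"n_detections": totals.astype(int), "n_sites_detected": sites.astype(int)},
        index=pd.Index(data.species_ids, name="species"),
    )


def naive_occupancy(data: DetectionData) -> pd.Series:
    """Fraction of sites with at least one detection, per species (uncorrected)."""
    counts = detection_counts(data)
    return (counts["n_sites_detected"] / data.n_sites).rename("naive_occupancy")


def observed_richness(
    data: DetectionData, grouping: Mapping[str, str] | None = None
) -> pd.Series:
    """Number of species with >= 1 detection per site, or per group of sites.

    ``grouping`` maps every site id to a group label (e.g. habitat class).
    """
    det = data.detected_anywhere  # (N, J)
    if grouping is None:
        rich = det.sum(axis=0)
        return pd.Series(rich.astype(int), index=pd.Index(data.site_ids, name="site"))
    missing = [s for s in data.site_ids if s not in grouping]
    if missing:
        raise ValueError(f"sites missing from grouping: {missing}")
    groups = sorted({grouping[s] for s in data.site_ids}, key=_natural_key)
    out = {}
    for g in groups:
        idx = [j for j, s in enumerate(data.site_ids) if grouping[s] == g]
        out[g] = int(det[:, idx].any(axis=1).sum())
    return pd.Series(out, name="observed_richness").rename_axis("group")
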