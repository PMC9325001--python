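"""Synthetic monitoring-network generator.

Emulates a national arable-soil monitoring network resampled after a decade:
385 plots with paired topsoil SOC measurements nine years apart, per-year crop
records, and two gridded monthly summer climate products whose change signals
agree roughly 1:1 (temperature slope 0.90, precipitation slope 0.98).

The response follows the generative model the analysis assumes: a shared-mean
two-Gaussian mixture (a narrow component for well-relocated plots, a wide one
for plots whose resampling location drifted) around a linear predictor with
climate, farm-type, rotation-class and SOC-to-fine-ratio effects plus a
measurement-group random effect. Coefficient defaults are on the per-year
g kg⁻¹ scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .covariates import (
    CROP_GROUPS,
    PERENNIAL_GROUPS,
    assign_grid_points,
    classify_rotation,
    climate_deltas_for_grid,
)

__all__ = ["SynthConfig", "SyntheticDataset", "generate_network", "emulate_second_grid", "write_csvs"]

#: Default per-year truth for the linear predictor (g kg⁻¹ yr⁻¹ per unit covariate).
DEFAULT_COEFFICIENTS: Mapping[str, float] = {
    "nu": 0.048,
    "beta_p": -0.003,
    "beta_t": -0.404,
    "beta_ft": 0.011,
    "beta_fine": -0.193,
    "beta_per": 0.152,
    "beta_div": 0.081,
    "beta_rot": 0.137,
}

ROTATION_LABELS = ("Annual", "Perennial", "Diverse", "Rotation")

# Candidate 9-year crop-group count patterns per rotation class; each pattern
# is validated against the classifier at generation time.
_PATTERNS: Mapping[str, tuple[Mapping[str, int], ...]] = {
    "Annual": (
        {"cereals": 9},
        {"cereals": 8, "oilseeds": 1},
        {"cereals": 7, "oilseeds": 2},
    ),
    "Perennial": (
        {"grasses": 9},
        {"grasses": 8, "green fallow": 1},
    ),
    "Diverse": (
        {"cereals": 3, "legumes": 2, "oilseeds": 2, "grasses": 2},
        {"cereals": 4, "grasses": 3, "legumes": 2},
        {"cereals": 3, "grasses": 3, "oilseeds": 3},
    ),
    "Rotation": (
        {"cereals": 5, "grasses": 4},
        {"cereals": 6, "grasses": 3},
        {"cereals": 4, "grasses": 5},
    ),
}


@dataclass
class SynthConfig:
    """Conditions for one synthetic monitoring network.

    Noise parameters (sigma_narrow, sigma_wide_extra, sigma_group) and the
    true coefficients are on the per-year scale; the SD of the wide mixture
    component is sigma_narrow + sigma_wide_extra. Climate deltas are the
    change in mean summertime (May-Sep) temperature (°C) and precipitation
    sum (mm) between the 1998-2018 and 1989-2009 windows.
    """

    n_plots: int = 385
    n_groups: int = 20
    interval_years: int = 9
    true_coefficients: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COEFFICIENTS)
    )
    pi_narrow: float = 0.734
    sigma_narrow: float = 0.267
    sigma_wide_extra: float = 0.911
    sigma_group: float = 0.112
    climate_delta_means: tuple[float, float] = (0.46, 14.0)  # (ΔT °C, ΔP mm)
    climate_delta_sds: tuple[float, float] = (0.12, 5.0)
    delta_t_range: tuple[float, float] = (0.2, 0.7)
    climate_grid_slopes: tuple[float, float] = (0.90, 0.98)
    climate_grid_noise: tuple[float, float] = (0.03, 1.0)
    rotation_mix: Mapping[str, float] = field(
        default_factory=lambda: {"Annual": 0.45, "Perennial": 0.20, "Diverse": 0.10, "Rotation": 0.25}
    )
    soc2009_mean: float = 34.1
    soc2009_log_sd: float = 0.45
    log_ratio_mean: float = -3.0
    log_ratio_sd: float = 0.6
    livestock_share: float = 0.35
    n_grid_points: int = 400
    domain_size: float = 500_000.0
    crop_groups: tuple[str, ...] = CROP_GROUPS
    center_log_ratio: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.pi_narrow < 1.0:
            raise ValueError("pi_narrow must lie in (0, 1)")
        for name in ("sigma_narrow", "sigma_wide_extra", "sigma_group"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.interval_years < 1:
            raise ValueError("interval_years must be >= 1")
        mix = dict(self.rotation_mix)
        if set(mix) - set(ROTATION_LABELS):
            raise ValueError(f"unknown rotation labels: {set(mix) - set(ROTATION_LABELS)}")
        if abs(sum(mix.values()) - 1.0) > 1e-9:
            raise ValueError("rotation_mix must sum to 1")
        if any(v < 0 for v in mix.values()):
            raise ValueError("rotation_mix proportions must be non-negative")
        groups = set(self.crop_groups)
        perennial_avail = groups & PERENNIAL_GROUPS
        annual_avail = groups - PERENNIAL_GROUPS
        if mix.get("Diverse", 0) > 0 and len(groups) < 3:
            raise ValueError("Diverse rotations need at least 3 crop groups")
        if mix.get("Perennial", 0) > 0 and not perennial_avail:
            raise ValueError("Perennial rotations need a perennial crop group")
        if mix.get("Rotation", 0) > 0 and not (perennial_avail and annual_avail):
            raise ValueError("Rotation mixes need both annual and perennial crop groups")
        if mix.get("Annual", 0) > 0 and not annual_avail:
            raise ValueError("Annual rotations need an annual crop group")


@dataclass
class SyntheticDataset:
    """One generated network plus the latent truth used to create it."""

    plots: pd.DataFrame
    crop_records: pd.DataFrame
    climate: dict[str, pd.DataFrame]
    truth: SynthConfig
    latent_wide_flags: np.ndarray
    group_effects: np.ndarray
    per_year_change: np.ndarray


def _truncated_normal(rng, mean, sd, low, high, size):
    out = rng.normal(mean, sd, size)
    bad = (out < low) | (out > high)
    while bad.any():
        out[bad] = rng.normal(mean, sd, bad.sum())
        bad = (out < low) | (out > high)
    return out


def _make_grid_a(cfg: SynthConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Monthly May-Sep series 1989-2018 whose window deltas hit per-point targets.

    Each grid point carries a linear year trend sized so that the 21-year
    window difference equals the drawn target delta exactly (a linear trend of
    b per year shifts the window means by 9·b).
    """
    m = cfg.n_grid_points
    east = rng.uniform(0, cfg.domain_size, m)
    north = rng.uniform(0, cfg.domain_size, m)
    dt = _truncated_normal(
        rng, cfg.climate_delta_means[0], cfg.climate_delta_sds[0], *cfg.delta_t_range, size=m
    )
    dp = rng.normal(cfg.climate_delta_means[1], cfg.climate_delta_sds[1], m)

    years = np.arange(1989, 2019)
    months = np.array([5, 6, 7, 8, 9])
    month_base_t = np.array([9.0, 14.0, 17.0, 15.0, 9.0])
    month_base_p = np.array([40.0, 55.0, 70.0, 75.0, 60.0])
    point_offset_t = rng.normal(0.0, 1.5, m)
    point_offset_p = rng.normal(0.0, 8.0, m)

    gid = np.repeat(np.arange(m), years.size * months.size)
    yy = np.tile(np.repeat(years, months.size), m)
    mm = np.tile(months, m * years.size)
    elapsed = yy - years[0]
    trend_t = np.repeat(dt, years.size * months.size) / 9.0
    trend_p = np.repeat(dp, years.size * months.size) / (9.0 * months.size)
    temp = (
        month_base_t[mm - 5]
        + np.repeat(point_offset_t, years.size * months.size)
        + trend_t * elapsed
    )
    precip = np.clip(
        month_base_p[mm - 5]
        + np.repeat(point_offset_p, years.size * months.size)
        + trend_p * elapsed,
        0.0,
        None,
    )
    return pd.DataFrame(
        {
            "grid_point_id": gid,
            "easting": np.repeat(east, years.size * months.size),
            "northing": np.repeat(north, years.size * months.size),
            "year": yy,
            "month": mm,
            "temperature": temp,
            "precipitation": precip,
        }
    )


def emulate_second_grid(
    grid_a: pd.DataFrame,
    slope_t: float = 0.90,
    slope_p: float = 0.98,
    noise_sd_t: float = 0.03,
    noise_sd_p: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Derive a second climate grid whose deltas regress on the first's.

    Per grid point the second grid's window delta equals slope × (first
    grid's delta) plus Normal(0, noise_sd) error, realised by an affine
    transform of the monthly series plus a small extra linear trend. With
    zero noise and unit slopes the deltas are identical by construction.
    """
    if noise_sd_t < 0 or noise_sd_p < 0:
        raise ValueError("noise SDs must be non-negative")
    if grid_a.empty:
        raise ValueError("grid_a is empty")
    rng = np.random.default_rng(seed)
    out = grid_a.copy()
    pts = out["grid_point_id"].drop_duplicates().to_numpy()
    n_months = out["month"].nunique()
    eps_t = pd.Series(rng.normal(0, noise_sd_t, pts.size), index=pts)
    eps_p = pd.Series(rng.normal(0, noise_sd_p, pts.size), index=pts)
    off_t = pd.Series(rng.normal(0, 0.5, pts.size), index=pts)
    elapsed = out["year"] - out["year"].min()
    out["temperature"] = (
        off_t.loc[out["grid_point_id"]].to_numpy()
        + slope_t * out["temperature"]
        + eps_t.loc[out["grid_point_id"]].to_numpy() / 9.0 * elapsed
    )
    out["precipitation"] = np.clip(
        slope_p * out["precipitation"]
        + eps_p.loc[out["grid_point_id"]].to_numpy() / (9.0 * n_months) * elapsed,
        0.0,
        None,
    )
    return out


def _draw_crop_records(
    cfg: SynthConfig, labels: np.ndarray, rng: np.random.Generator
) -> pd.DataFrame:
    """Per-plot yearly crop-group records realizing the requested classes."""
    y0 = 2010
    years = np.arange(y0, y0 + 9)
    avail = set(cfg.crop_groups)
    recs: list[tuple[int, int, str]] = []
    for pid, label in enumerate(labels):
        candidates = [p for p in _PATTERNS[label] if set(p) <= avail]
        if not candidates:
            raise ValueError(f"no crop pattern for class {label!r} under crop_groups")
        pattern = candidates[rng.integers(len(candidates))]
        seq = [g for g, c in pattern.items() for _ in range(c)]
        rng.shuffle(seq)
        got = classify_rotation(seq).label
        if got != label:  # patterns are pre-vetted; guard against config edits
            raise AssertionError(f"pattern classified as {got}, wanted {label}")
        recs.extend((pid, y, g) for y, g in zip(years, seq))
    return pd.DataFrame(recs, columns=["plot_id", "year", "crop_group"])


def generate_network(config: SynthConfig) -> SyntheticDataset:
    """Generate one complete synthetic monitoring network.

    All randomness flows from ``config.seed`` through a splittable
    SeedSequence, so equal configs give bit-identical datasets.
    """
    ss = np.random.SeedSequence(config.seed)
    r_plot, r_clim, r_crop, r_resp, r_gridb = [np.random.default_rng(s) for s in ss.spawn(5)]
    n = config.n_plots

    east = r_plot.uniform(0, config.domain_size, n)
    north = r_plot.uniform(0, config.domain_size, n)
    # contiguous geographic blocks: equal-size slices of the easting order
    order = np.argsort(east, kind="stable")
    group = np.empty(n, dtype=int)
    group[order] = (np.arange(n) * config.n_groups) // n

    mu_log = np.log(config.soc2009_mean) - 0.5 * config.soc2009_log_sd**2
    soc_cap = 200.0 / 1.724  # stay below the organic-soil exclusion
    soc0 = np.exp(
        _truncated_normal(r_plot, mu_log, config.soc2009_log_sd, -np.inf, np.log(soc_cap), n)
    )
    # fine fraction via the log ratio, kept physical (fine <= 1000 g/kg)
    lr_floor = np.log(soc0 / 1000.0)
    log_ratio = np.maximum(
        _truncated_normal(r_plot, config.log_ratio_mean, config.log_ratio_sd, -np.inf, 0.0, n),
        lr_floor + 1e-9,
    )
    fine = soc0 / np.exp(log_ratio)
    farm = np.where(r_plot.random(n) < config.livestock_share, "livestock", "plant")

    mix_labels = np.array(ROTATION_LABELS)
    mix_p = np.array([dict(config.rotation_mix).get(l, 0.0) for l in mix_labels])
    labels = r_crop.choice(mix_labels, size=n, p=mix_p)
    crops = _draw_crop_records(config, labels, r_crop)

    grid_a = _make_grid_a(config, r_clim)
    grid_b = emulate_second_grid(
        grid_a,
        config.climate_grid_slopes[0],
        config.climate_grid_slopes[1],
        config.climate_grid_noise[0],
        config.climate_grid_noise[1],
        seed=int(r_gridb.integers(2**31)),
    )

    plots = pd.DataFrame(
        {
            "plot_id": np.arange(n),
            "group_id": group,
            "easting": east,
            "northing": north,
            "soc_t0": soc0,
            "soc_t1": np.nan,
            "fine_fraction": fine,
            "farm_type": farm,
        }
    )

    deltas = climate_deltas_for_grid(grid_a)
    gids = assign_grid_points(plots, grid_a)
    dmap = deltas.set_index("grid_point_id")
    dt = dmap.loc[gids, "delta_t"].to_numpy()
    dp = dmap.loc[gids, "delta_p"].to_numpy()

    beta = dict(config.true_coefficients)
    lr_term = log_ratio - log_ratio.mean() if config.center_log_ratio else log_ratio
    mu = (
        beta["nu"]
        + beta["beta_p"] * dp
        + beta["beta_t"] * dt
        + beta["beta_ft"] * (farm == "livestock")
        + beta["beta_fine"] * lr_term
        + beta["beta_per"] * (labels == "Perennial")
        + beta["beta_div"] * (labels == "Diverse")
        + beta["beta_rot"] * (labels == "Rotation")
    )
    u = r_resp.normal(0.0, config.sigma_group, config.n_groups)
    mu = mu + u[group]

    wide = r_resp.random(n) >= config.pi_narrow
    sd = np.where(wide, config.sigma_narrow + config.sigma_wide_extra, config.sigma_narrow)
    change = r_resp.normal(mu, sd)
    soc1 = soc0 + config.interval_years * change
    # keep SOC physically positive; redraw the rare deep-negative tails
    bad = soc1 <= 1.0
    while bad.any():
        change[bad] = r_resp.normal(mu[bad], sd[bad])
        soc1 = soc0 + config.interval_years * change
        bad = soc1 <= 1.0
    plots["soc_t1"] = soc1

    return SyntheticDataset(
        plots=plots,
        crop_records=crops,
        climate={"grid_a": grid_a, "grid_b": grid_b},
        truth=replace(config),
        latent_wide_flags=wide,
        group_effects=u,
        per_year_change=change,
    )


def write_csvs(dataset: SyntheticDataset, directory: str | Path) -> dict[str, Path]:
    """Write plots.csv, crops.csv and climate_<grid>.csv into a directory."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}
    paths["plots"] = directory / "plots.csv"
    dataset.plots.to_csv(paths["plots"], index=False)
    paths["crops"] = directory / "crops.csv"
    dataset.crop_records.to_csv(paths["crops"], index=False)
    for name, grid in dataset.climate.items():
        p = directory / f"climate_{name}.csv"
        grid.to_csv(p, index=False)
        paths[f"climate_{name}"] = p
    return paths
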