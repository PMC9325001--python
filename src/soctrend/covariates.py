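"""Design-matrix construction for the SOC-change regression.

Raw inputs are three tables: per-plot soil records (paired SOC measurements,
fine-fraction content, farm type), per-plot crop records by year, and a gridded
monthly climate series. This module turns them into one covariate row per plot:

* crop-rotation class (Annual / Perennial / Diverse / Rotation) from the
  Shannon diversity of the recorded crop groups and the share of perennials,
* summertime (May-Sep) climate deltas between two 21-year averaging windows,
* the log SOC-to-fine-fraction ratio, centered to the analysis-set mean,
* exclusion of organic soils (organic matter > 20 %) and plots without crop
  history, with an explicit exclusion log.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple

import numpy as np
import pandas as pd

__all__ = [
    "CROP_GROUPS",
    "PERENNIAL_GROUPS",
    "AnalysisConfig",
    "RotationClass",
    "shannon_index",
    "classify_rotation",
    "nearest_grid_point",
    "assign_grid_points",
    "climate_delta",
    "climate_deltas_for_grid",
    "soc_fine_log_ratio",
    "build_design",
]

#: The seven crop groups used for rotation classification.
CROP_GROUPS = (
    "cereals",
    "legumes",
    "vegetables",
    "oilseeds",
    "grasses",
    "green fallow",
    "others",
)

#: Crop groups counted as perennial cover; the rest are annuals.
PERENNIAL_GROUPS = frozenset({"grasses", "green fallow"})

#: Biologically active season in the boreal zone.
SUMMER_MONTHS = (5, 6, 7, 8, 9)


class RotationClass(NamedTuple):
    """Result of the rotation classifier for one plot."""

    label: str
    shannon_h: float
    perennial_share: float
    annual_share: float


def shannon_index(crop_year_counts: Mapping[str, float]) -> float:
    """Shannon diversity H = -sum p_i ln p_i of crop-group year counts.

    Parameters
    ----------
    crop_year_counts
        Mapping crop group -> number of recorded years. Groups with zero
        count contribute nothing.

    Returns
    -------
    float
        H in nats; 0 for a single group, ln(s) for s equally frequent groups.
    """
    counts = np.asarray([c for c in crop_year_counts.values() if c > 0], dtype=float)
    if counts.size == 0:
        raise ValueError("shannon_index requires at least one positive count")
    p = counts / counts.sum()
    return float(-(p * np.log(p)).sum())


def classify_rotation(
    crop_labels: Iterable[str],
    *,
    perennial_groups: frozenset[str] | set[str] = PERENNIAL_GROUPS,
    group_map: Mapping[str, str] | None = None,
    h_threshold: float = 0.8,
    share_threshold: float = 0.8,
) -> RotationClass:
    """Classify one plot's crop rotation from its recorded per-year crops.

    The rule is applied in order: Diverse if the Shannon index of the crop
    groups exceeds ``h_threshold``; otherwise Annual (Perennial) if annual
    (perennial) crops cover strictly more than ``share_threshold`` of the
    recorded years; otherwise Rotation. All thresholds are strict, so a plot
    sitting exactly on a boundary falls through to the next rule.

    Parameters
    ----------
    crop_labels
        One crop label per recorded year (order irrelevant).
    group_map
        Optional mapping from raw crop labels to the seven crop groups;
        by default labels must already be group names.
    """
    labels = list(crop_labels)
    if not labels:
        raise ValueError("classify_rotation requires at least one recorded year")
    groups = []
    for lab in labels:
        g = group_map.get(lab, lab) if group_map is not None else lab
        if g not in CROP_GROUPS:
            raise ValueError(f"unmapped crop label: {lab!r}")
        groups.append(g)

    n_years = len(groups)
    counts: dict[str, int] = {}
    for g in groups:
        counts[g] = counts.get(g, 0) + 1
    h = shannon_index(counts)
    perennial_share = sum(c for g, c in counts.items() if g in perennial_groups) / n_years
    annual_share = 1.0 - perennial_share

    if h > h_threshold:
        label = "Diverse"
    elif annual_share > share_threshold:
        label = "Annual"
    elif perennial_share > share_threshold:
        label = "Perennial"
    else:
        label = "Rotation"
    return RotationClass(label, h, perennial_share, annual_share)


def _grid_points(grid: pd.DataFrame) -> pd.DataFrame:
    pts = (
        grid[["grid_point_id", "easting", "northing"]]
        .drop_duplicates("grid_point_id")
        .sort_values("grid_point_id")
        .reset_index(drop=True)
    )
    if pts.empty:
        raise ValueError("climate grid is empty")
    return pts

def nearest_grid_point(easting: float, northing: float, grid: pd.DataFrame) -> int:
    """Id of the grid point closest (planar Euclidean) to the location.

    Ties are broken toward the lowest grid_point_id.
    """
    pts = _grid_points(grid)
    d2 = (pts["easting"].to_numpy() - easting) ** 2 + (pts["northing"].to_numpy() - northing) ** 2
    return int(pts["grid_point_id"].to_numpy()[np.argmin(d2)])

def assign_grid_points(plots: pd.DataFrame, grid: pd.DataFrame) -> pd.Series:
    """Vectorised nearest-grid-point lookup for a table of plots.

    Returns a Series of grid_point_id indexed like ``plots``. Equidistant
    points resolve to the lowest id (grid points are scanned in id order and
    argmin keeps the first minimum).
    """
    pts = _grid_points(grid)
    pe = plots["easting"].to_numpy()[:, None]
    pn = plots["northing"].to_numpy()[:, None]
    d2 = (pts["easting"].to_numpy()[None, :] - pe) ** 2 + (
        pts["northing"].to_numpy()[None, :] - pn
    ) ** 2
    idx = np.argmin(d2, axis=1)
    return pd.Series(pts["grid_point_id"].to_numpy()[idx], index=plots.index, name="grid_point_id")


def _window_stat(
    series: pd.DataFrame,
    variable: str,
    years: range,
    months: tuple[int, ...],
) -> float:
    """Mean over years of the May-Sep summary (mean for T, sum for P)."""
    sub = series[series["year"].isin(years) & series["month"].isin(months)]
    missing = []
    for y in years:
        have = set(sub.loc[sub["year"] == y, "month"])
        gaps = [m for m in months if m not in have]
        missing.extend((y, m) for m in gaps)
    if missing:
        raise ValueError(f"incomplete climate series; missing (year, month): {missing}")
    per_year = sub.groupby("year")[variable]
    yearly = per_year.sum() if variable == "precipitation" else per_year.mean()
    return float(yearly.mean())


def climate_delta(
    series: pd.DataFrame,
    variable: str,
    window_new: tuple[int, int] = (1998, 2018),
    window_old: tuple[int, int] = (1989, 2009),
    months: tuple[int, ...] = SUMMER_MONTHS,
) -> float:
    """Change in the summertime climate between two averaging windows.

    For temperature, each year is summarised by the mean of the May-Sep
    monthly means; for precipitation the May-Sep monthly sums are summed per
    year first. The delta is the mean over the new window (inclusive) minus
    the mean over the old window.

    Parameters
    ----------
    series
        Rows (year, month, temperature, precipitation) for one grid point.
    variable
        ``"temperature"`` or ``"precipitation"``.
    """
    if variable not in ("temperature", "precipitation"):
        raise ValueError(f"unknown climate variable: {variable!r}")
    new = _window_stat(series, variable, range(window_new[0], window_new[1] + 1), months)
    old = _window_stat(series, variable, range(window_old[0], window_old[1] + 1), months)
    return new - old


def climate_deltas_for_grid(
    grid: pd.DataFrame,
    window_new: tuple[int, int] = (1998, 2018),
    window_old: tuple[int, int] = (1989, 2009),
    months: tuple[int, ...] = SUMMER_MONTHS,
) -> pd.DataFrame:
    """climate_delta for every grid point; columns (grid_point_id, delta_t, delta_p).

    Vectorised equivalent of calling :func:`climate_delta` per grid point,
    with the same completeness requirement over both windows.
    """
    years = sorted(
        set(range(window_old[0], window_old[1] + 1)) | set(range(window_new[0], window_new[1] + 1))
    )
    sub = grid[grid["year"].isin(years) & grid["month"].isin(months)]
    counts = sub.groupby(["grid_point_id", "year"])["month"].count()
    full = counts.unstack("year")
    if full.isna().any().any() or (full != len(months)).any().any() or set(full.columns) != set(years):
        raise ValueError("incomplete climate series in at least one grid point/window")
    yearly = sub.groupby(["grid_point_id", "year"]).agg(
        t=("temperature", "mean"), p=("precipitation", "sum")
    )
    t = yearly["t"].unstack("year")
    p = yearly["p"].unstack("year")
    new = list(range(window_new[0], window_new[1] + 1))
    old = list(range(window_old[0], window_old[1] + 1))
    out = pd.DataFrame(
        {
            "grid_point_id": t.index,
            "delta_t": (t[new].mean(axis=1) - t[old].mean(axis=1)).to_numpy(),
            "delta_p": (p[new].mean(axis=1) - p[old].mean(axis=1)).to_numpy(),
        }
    ).reset_index(drop=True)
    return out


def soc_fine_log_ratio(soc_t0, fine_fraction):
    """Natural log of the SOC-to-fine-fraction ratio (both g kg⁻¹).

    A ratio of 1 (log 0) is the intercept reference point of the uncentered
    model parameterisation; typical mineral-soil values are 0.03-0.18.
    """
    soc = np.asarray(soc_t0, dtype=float)
    fine = np.asarray(fine_fraction, dtype=float)
    if np.any(soc <= 0) or np.any(fine <= 0):
        raise ValueError("soc_t0 and fine_fraction must be strictly positive")
    out = np.log(soc / fine)
    return float(out) if out.ndim == 0 else out


@dataclass
class AnalysisConfig:
    """Settings for design-matrix construction.

    om_factor is the conventional Van Bemmelen conversion from organic carbon
    to organic matter; plots with OM ≥ om_threshold (g kg⁻¹, i.e. 20 % of dry
    mass) at either sampling are treated as organic soils and excluded.
    """

    window_new: tuple[int, int] = (1998, 2018)
    window_old: tuple[int, int] = (1989, 2009)
    months: tuple[int, ...] = SUMMER_MONTHS
    crop_window: tuple[int, int] = (2010, 2018)
    om_factor: float = 1.724
    om_threshold: float = 200.0
    center_log_ratio: bool = True
    h_threshold: float = 0.8
    share_threshold: float = 0.8
    perennial_groups: frozenset = PERENNIAL_GROUPS
    group_map: Mapping[str, str] | None = None


def build_design(
    plots: pd.DataFrame,
    crop_records: pd.DataFrame,
    grid: pd.DataFrame,
    config: AnalysisConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assemble the regression design: one row per retained plot.

    Applies the exclusion rules (organic soils, missing crop history), joins
    the nearest-grid-point climate deltas, classifies rotations and centers
    the log SOC-to-fine ratio on the post-exclusion sample.

    Returns
    -------
    (design, exclusions)
        ``design`` has columns plot_id, group_id, delta_soc_total, delta_p,
        delta_t, farm_livestock, log_ratio_centered, rot_per, rot_div,
        rot_rot, rotation_label; ``exclusions`` has (plot_id, reason).
    """
    config = config or AnalysisConfig()
    plots = plots.reset_index(drop=True)
    exclusions: list[dict] = []

    om_t0 = config.om_factor * plots["soc_t0"]
    om_t1 = config.om_factor * plots["soc_t1"]
    organic = (om_t0 >= config.om_threshold) | (om_t1 >= config.om_threshold)
    for pid in plots.loc[organic, "plot_id"]:
        exclusions.append({"plot_id": pid, "reason": "organic_soil"})

    y0, y1 = config.crop_window
    crops_in_window = crop_records[(crop_records["year"] >= y0) & (crop_records["year"] <= y1)]
    plots_with_crops = set(crops_in_window["plot_id"])
    no_history = ~plots["plot_id"].isin(plots_with_crops)
    for pid in plots.loc[no_history & ~organic, "plot_id"]:
        exclusions.append({"plot_id": pid, "reason": "missing_crop_history"})

    keep = plots[~organic & ~no_history].copy()
    if keep.empty:
        raise ValueError("all plots excluded; nothing to analyse")

    deltas = climate_deltas_for_grid(
        grid, window_new=config.window_new, window_old=config.window_old, months=config.months
    )
    keep["grid_point_id"] = assign_grid_points(keep, grid)
    keep = keep.merge(deltas, on="grid_point_id", how="left", validate="many_to_one")

    crop_lists = crops_in_window.groupby("plot_id")["crop_group"].apply(list)
    rot = {
        pid: classify_rotation(
            crop_lists[pid],
            perennial_groups=config.perennial_groups,
            group_map=config.group_map,
            h_threshold=config.h_threshold,
            share_threshold=config.share_threshold,
        )
        for pid in keep["plot_id"]
    }
    labels = keep["plot_id"].map(lambda pid: rot[pid].label)

    log_ratio = soc_fine_log_ratio(keep["soc_t0"].to_numpy(), keep["fine_fraction"].to_numpy())
    if config.center_log_ratio:
        log_ratio = log_ratio - log_ratio.mean()

    design = pd.DataFrame(
        {
            "plot_id": keep["plot_id"].to_numpy(),
            "group_id": keep["group_id"].to_numpy(),
            "delta_soc_total": (keep["soc_t1"] - keep["soc_t0"]).to_numpy(),
            "delta_p": keep["delta_p"].to_numpy(),
            "delta_t": keep["delta_t"].to_numpy(),
            "farm_livestock": (keep["farm_type"] == "livestock").astype(int).to_numpy(),
            "log_ratio_centered": log_ratio,
            "rot_per": (labels == "Perennial").astype(int).to_numpy(),
            "rot_div": (labels == "Diverse").astype(int).to_numpy(),
            "rot_rot": (labels == "Rotation").astype(int).to_numpy(),
            "rotation_label": labels.to_numpy(),
        }
    )
    return design, pd.DataFrame(exclusions, columns=["plot_id", "reason"])
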