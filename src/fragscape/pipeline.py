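"""Orchestration of the two analyses: island-wide and large-cell.

`run_island_wide` reproduces the scenario bookkeeping: the four indices
per class per year, forest metrics outside the urban-union mask, the
deforestation-only / reforestation-only counterfactuals with their
percent changes relative to the first year, and the mean distances of
change sites to unchanged forest.

`run_grid_analysis` runs the large-cell stage: tile + filter +
summarise into the cell table, intercept-only spatial-error tests of
the index increments, minimum-AIC spatial-error models of the indices
on biophysical/socioeconomic drivers (distance to urban D and D^2,
slope s and s^2, slope SD and its square, population density), the
increment-on-area-change regressions, and the peak locations / shift
rates of the distance-to-urban quadratics.

Every report carries the configuration hash and seed so reruns are
reproducible and traceable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .change import (
    SCENARIO_TAGS,
    build_scenario,
    apply_urban_mask,
    classify_forest_change,
    mean_distance_to_unchanged,
    relative_change,
)
from .metrics import all_class_metrics, class_metrics, label_patches
from .peaks import peak_shift, quadratic_extremum, slope_extrema_report
from .raster import CovariateGrid, LandCoverGrid, TargetClass, require_aligned
from .sem import aic_select, build_knn_weights, fit_increment_models, fit_intercept_only
from .tiling import build_cell_table

__all__ = ["RunConfig", "run_island_wide", "run_grid_analysis"]

METRIC_NAMES = ("AREA_MN", "LPI", "ED", "EDGE_AREA")

#: index-class responses modelled against the drivers
DRIVER_RESPONSES = ("EDGE_AREA_U", "ED_U", "ED_F", "AREA_MN_F")

#: candidate driver terms (squares spelled with a trailing 2)
DRIVER_TERMS = ("D", "D2", "s", "s2", "sigma_s", "sigma_s2", "d_p")


@dataclass
class RunConfig:
    """Settings of one pipeline run; defaults are the reference setting
    (3 km x 3 km cells of 100 x 100 thirty-meter pixels, 2,500-land-pixel
    filter, eight nearest neighbours, row-standardized weights)."""

    connectivity: int = 8
    boundary_policy: str = "exclude"
    cell_pixels: int = 100
    min_land_pixels: int = 2500
    k_neighbours: int = 8
    standardize_weights: bool = True
    edge_area_per: str = "hectare"
    seed: int = 0

    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def provenance(self) -> dict:
        return {"config_hash": self.hash(), "seed": self.seed, **asdict(self)}


def _metrics_row(grid: LandCoverGrid, focal_class: int, cfg: RunConfig) -> dict:
    ps = label_patches(grid, focal_class, cfg.connectivity, cfg.boundary_policy)
    cm = class_metrics(ps, cfg.edge_area_per)
    return {m: v for m, v in zip(
        METRIC_NAMES, (cm.area_mn, cm.lpi, cm.ed, cm.edge_area)
    )} | {"n_patches": cm.n, "defined": cm.defined}


def run_island_wide(
    grids_by_year: dict[int, LandCoverGrid],
    config: RunConfig | None = None,
    classes: dict[str, int] | None = None,
) -> dict:
    """Island-wide metrics, urban-masked forest metrics, change scenarios.

    Requires at least two aligned yearly grids; the first and last year
    define the change period. Returns a dict with the metrics table
    (rows per class/scenario per year), the relative-change table of the
    forest scenarios, the change-site distance statistics, and run
    provenance.
    """
    cfg = config or RunConfig()
    years = sorted(grids_by_year)
    if len(years) < 2:
        raise ValueError("island-wide analysis needs at least two years")
    require_aligned(*[grids_by_year[y] for y in years])
    if classes is None:
        classes = {"urban": TargetClass.URBAN, "forest": TargetClass.FOREST,
                   "wetland": TargetClass.WETLAND}

    rows = []
    for y in years:
        for label, cls in classes.items():
            rows.append(
                {"scenario": label, "year": y}
                | _metrics_row(grids_by_year[y], cls, cfg)
            )

    y1, y2 = years[0], years[-1]
    g1, g2 = grids_by_year[y1], grids_by_year[y2]

    # forest outside the union of both years' urban areas
    u1 = g1.class_mask(TargetClass.URBAN)
    u2 = g2.class_mask(TargetClass.URBAN)
    for y, g in ((y1, g1), (y2, g2)):
        masked = apply_urban_mask(g, u1, u2)
        rows.append(
            {"scenario": "forest_outside_urban", "year": y}
            | _metrics_row(masked, TargetClass.FOREST, cfg)
        )

    # counterfactual forest scenarios
    change = classify_forest_change(g1, g2)
    scenario_metrics: dict[str, dict] = {}
    for tag in SCENARIO_TAGS:
        sg = build_scenario(change, tag)
        m = _metrics_row(sg.grid, TargetClass.FOREST, cfg)
        scenario_metrics[tag] = m
        rows.append({"scenario": tag.lower(), "year": None} | m)

    rel_rows = []
    ref = scenario_metrics["TRUE_T1"]
    for tag in ("DEFORESTATION_ONLY", "REFORESTATION_ONLY", "TRUE_T2"):
        for metric in METRIC_NAMES:
            rel_rows.append(
                {
                    "scenario": tag.lower(),
                    "metric": metric,
                    "reference": ref[metric],
                    "value": scenario_metrics[tag][metric],
                    "percent_change": relative_change(
                        ref[metric], scenario_metrics[tag][metric]
                    ),
                }
            )

    distances = {}
    counts = change.counts()
    if counts["unchanged_forest"]:
        for cat in ("DEFORESTED", "REFORESTED"):
            if counts[cat.lower()]:
                distances[cat.lower() + "_mean_distance_m"] = (
                    mean_distance_to_unchanged(change, cat)
                )
    if len(distances) == 2:
        d_def = distances["deforested_mean_distance_m"]
        d_ref = distances["reforested_mean_distance_m"]
        distances["deforested_closer_percent"] = relative_change(d_ref, d_def) * -1

    return {
        "metrics": pd.DataFrame(rows),
        "relative_changes": pd.DataFrame(rel_rows),
        "distances": distances,
        "change_counts": counts,
        "provenance": cfg.provenance(),
    }


def _driver_design(cells: pd.DataFrame) -> pd.DataFrame:
    """Candidate driver terms from cell-table covariate summaries.

    Distance to urban enters in kilometers; slope terms in degrees;
    population density in persons per km^2.
    """
    out = pd.DataFrame(index=cells.index)
    out["D"] = cells["D_mean"] / 1000.0
    out["D2"] = out["D"] ** 2
    out["s"] = cells["slope_mean"]
    out["s2"] = out["s"] ** 2
    out["sigma_s"] = cells["slope_sd"]
    out["sigma_s2"] = out["sigma_s"] ** 2
    out["d_p"] = cells["popden_mean"]
    return out


def run_grid_analysis(
    grids_by_year: dict[int, LandCoverGrid],
    covariates: dict[str, CovariateGrid],
    config: RunConfig | None = None,
    driver_responses: tuple[str, ...] = DRIVER_RESPONSES,
    driver_terms: tuple[str, ...] = DRIVER_TERMS,
    fit_drivers: bool = True,
    fit_increments: bool = True,
) -> dict:
    """Large-cell stage: cell table, intercept tests, driver models, peaks.

    ``covariates`` must include ``D`` (distance to urban, m), ``slope``
    (degrees) and ``popden``; ``elev`` is summarised when present.
    Responses are spelled ``<INDEX>_<classletter>`` (e.g. ``ED_F``) and
    resolved per year against the cell-table columns.
    """
    cfg = config or RunConfig()
    years = sorted(grids_by_year)
    y1, y2 = years[0], years[-1]
    cells = build_cell_table(
        grids_by_year,
        covariates,
        cell_pixels=cfg.cell_pixels,
        min_land_pixels=cfg.min_land_pixels,
        increment_years=(y1, y2),
        connectivity=cfg.connectivity,
        boundary_policy=cfg.boundary_policy,
    )
    if len(cells) <= cfg.k_neighbours + 2:
        raise ValueError(
            f"only {len(cells)} cells retained; too few for spatial regression"
        )
    results: dict = {"cells": cells, "provenance": cfg.provenance()}

    # ---- intercept-only tests of index increments (Table-3 shape) ----
    intercept_rows = []
    for metric in METRIC_NAMES:
        for short in ("U", "F", "W"):
            c1, c2 = f"{metric}_{short}_{y1}", f"{metric}_{short}_{y2}"
            if c1 not in cells.columns:
                continue
            sub = cells[[c1, c2, "centroid_x", "centroid_y"]].dropna()
            if len(sub) <= cfg.k_neighbours + 2:
                continue
            dy = (sub[c2] - sub[c1]).to_numpy()
            w = build_knn_weights(
                sub[["centroid_x", "centroid_y"]].to_numpy(),
                k=cfg.k_neighbours, standardize=cfg.standardize_weights,
            )
            fit = fit_intercept_only(dy, w, response=f"d{metric}_{short}")
            mean_level = float(np.nanmean([sub[c1].mean(), sub[c2].mean()]))
            icpt = float(fit.params["intercept"])
            intercept_rows.append(
                {
                    "index": metric, "class": short, "n": fit.n,
                    "intercept": icpt,
                    "p": float(fit.pvalues["intercept"]),
                    "stars": fit.stars["intercept"],
                    "relative_change": icpt / mean_level if mean_level else np.nan,
                    "lambda": fit.lam,
                }
            )
    results["increment_intercepts"] = pd.DataFrame(intercept_rows)

    # ---- driver models per response per year (Table-4 shape) ----
    driver_fits: dict[str, object] = {}
    coef_rows = []
    if fit_drivers:
        design_all = _driver_design(cells)
        for resp in driver_responses:
            for y in years:
                col = f"{resp}_{y}"
                if col not in cells.columns:
                    continue
                keep = cells[col].notna() & design_all.notna().all(axis=1)
                sub = cells[keep]
                if len(sub) <= cfg.k_neighbours + 2:
                    continue
                w = build_knn_weights(
                    sub[["centroid_x", "centroid_y"]].to_numpy(),
                    k=cfg.k_neighbours, standardize=cfg.standardize_weights,
                )
                fit = aic_select(
                    sub[col].to_numpy(),
                    design_all.loc[keep, list(driver_terms)],
                    w,
                    include_intercept="search",
                    response=f"{resp}_{y}",
                )
                driver_fits[f"{resp}_{y}"] = fit
                row = {"response": resp, "year": y, "aic": fit.aic,
                       "lambda": fit.lam, "n": fit.n}
                row |= dict(zip(fit.term_names, fit.params.values))
                coef_rows.append(row)
        results["driver_models"] = driver_fits
        results["driver_coefficients"] = pd.DataFrame(coef_rows)

        # ---- peak locations along D and shift rates between years ----
        peak_rows, shift_rows = [], []
        for resp in driver_responses:
            extrema = {}
            for y in years:
                fit = driver_fits.get(f"{resp}_{y}")
                if fit is None:
                    continue
                has = {"D", "D2"} <= set(fit.term_names)
                if not has or fit.params["D2"] == 0:
                    peak_rows.append(
                        {"response": resp, "year": y, "predictor": "D",
                         "location_km": np.nan, "kind": "no interior peak"}
                    )
                    continue
                ext = quadratic_extremum(
                    float(fit.params["D"]), float(fit.params["D2"]),
                    float(fit.params.get("intercept", 0.0)),
                    predictor="D", source=f"{resp}_{y}",
                )
                extrema[y] = ext
                peak_rows.append(
                    {"response": resp, "year": y, "predictor": "D",
                     "location_km": ext.location_rounded, "kind": ext.kind}
                )
            ys = sorted(extrema)
            for a, b in zip(ys[:-1], ys[1:]):
                if extrema[a].kind != extrema[b].kind:
                    continue
                sh = peak_shift(extrema[a], extrema[b], years=b - a)
                shift_rows.append(
                    {"response": resp, "from": a, "to": b,
                     "absolute_rate": round(sh.absolute_rate, 2),
                     "relative_rate_percent": round(sh.relative_rate, 2)}
                )
        results["peaks"] = pd.DataFrame(peak_rows)
        results["peak_shifts"] = pd.DataFrame(shift_rows)
        if driver_fits:
            results["slope_extrema"] = slope_extrema_report(driver_fits)

    # ---- increment-on-area-change regressions ----
    if fit_increments:
        inc = cells.copy()
        inc["D"] = cells["D_mean"] / 1000.0
        for resp_combo in (("EDGE_AREA", "U"), ("ED", "U"), ("ED", "F"),
                           ("AREA_MN", "F"), ("EDGE_AREA", "W")):
            metric, short = resp_combo
            c1, c2 = f"{metric}_{short}_{y1}", f"{metric}_{short}_{y2}"
            if c1 in inc.columns:
                inc[f"d{metric}_{short}"] = inc[c2] - inc[c1]
        needed = [c for c in ("dEDGE_AREA_U", "dED_U", "dED_F",
                              "dAREA_MN_F", "dEDGE_AREA_W") if c in inc.columns]
        keep = inc[needed].notna().all(axis=1)
        sub = inc[keep]
        if len(sub) > cfg.k_neighbours + 2:
            w = build_knn_weights(
                sub[["centroid_x", "centroid_y"]].to_numpy(),
                k=cfg.k_neighbours, standardize=cfg.standardize_weights,
            )
            results["increment_models"] = fit_increment_models(sub, w)
    return results
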