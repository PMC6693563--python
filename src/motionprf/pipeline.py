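"""End-to-end orchestration: simulate -> preprocess -> fit -> summarise.

These functions are the programmatic counterparts of the CLI subcommands:
each takes and returns in-memory objects (bundles, DataFrames) and optionally
writes tidy TSV outputs plus a JSON manifest with content hashes.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ValidationError
from .map_metrics import (attach_polar_coords, circ_corr, selection_control,
                          summarize_by_area)
from .prf_core import HRFSpec, preprocess
from .prf_fit import build_grid, fit_population
from .synthetic_cortex import make_dataset
from .sweep_design import SweepDesign, render_apertures

__all__ = [
    "simulate", "preprocess_bundle", "fit_bundle", "report_bundle",
    "load_bundle", "write_manifest",
]

logger = logging.getLogger(__name__)


def simulate(config: dict | None = None, seed: int = 0,
             out_dir: str | Path | None = None, force: bool = False) -> dict:
    """Generate a dataset bundle (wraps :func:`synthetic_cortex.make_dataset`)."""
    if out_dir is not None:
        out_dir = Path(out_dir)
        if out_dir.exists() and any(out_dir.iterdir()) and not force:
            raise ValidationError(f"output directory {out_dir} is not empty "
                                  "(use force=True / --force to overwrite)")
    bundle = make_dataset(config, seed=seed, out_dir=out_dir)
    if out_dir is not None:
        write_manifest(out_dir, {"command": "simulate", "seed": seed,
                                 "config": _jsonable(config or {})})
    return bundle


def load_bundle(bundle_dir: str | Path) -> dict:
    """Reload a simulated bundle written by :func:`simulate` from disk."""
    bundle_dir = Path(bundle_dir)
    manifest = json.loads((bundle_dir / "manifest.json").read_text())
    scenario = yaml.safe_load((bundle_dir / "scenario.yaml").read_text())
    design = SweepDesign.from_yaml(bundle_dir / "design.yaml")
    stack = render_apertures(design, grid_pixels=scenario["grid_pixels"])
    truth = pd.read_csv(bundle_dir / "truth.tsv", sep="\t")
    runs = {}
    for condition in manifest["conditions"]:
        run_list = []
        for r in range(manifest["runs_per_condition"]):
            df = pd.read_csv(bundle_dir / f"series_{condition}_run{r}.tsv", sep="\t")
            run_list.append(df.drop(columns="vertex_id").to_numpy())
        runs[condition] = run_list
    from .synthetic_cortex import VertexPopulation, default_areas
    areas = {a.name: a for a in default_areas()}
    pop = VertexPopulation(truth=truth, areas=areas,
                           noise_sd=scenario["noise_sd"], ar1=scenario["ar1"],
                           seed=manifest["seed"])
    return {"population": pop, "stack": stack, "design": design, "runs": runs,
            "scenario": scenario, "seed": manifest["seed"]}


def preprocess_bundle(bundle: dict, discard: int = 0) -> dict:
    """Detrend, z-standardise and average each condition's runs per vertex."""
    out = {}
    for condition, run_list in bundle["runs"].items():
        n_vertices = run_list[0].shape[0]
        series = np.empty((n_vertices, run_list[0].shape[1] - discard))
        for v in range(n_vertices):
            series[v] = preprocess([run[v] for run in run_list], discard=discard).values
        out[condition] = series
    return out


def fit_bundle(bundle: dict, grid_ranges: dict | None = None,
               threshold: float = 0.05, fine: bool = True,
               hrf: HRFSpec = HRFSpec(), discard: int = 0,
               out_dir: str | Path | None = None) -> dict:
    """Fit every vertex in every condition; returns condition -> fit table."""
    stack = bundle["stack"]
    truth = bundle["population"].truth
    grid = build_grid(grid_ranges, stack, hrf)
    observed = preprocess_bundle(bundle, discard=discard)

    tables = {}
    for condition, series in observed.items():
        results, responsive = fit_population(series, grid, threshold=threshold,
                                             fine=fine)
        rows = []
        for vid, res, resp in zip(truth["vertex_id"], results, responsive):
            if res is None:
                rows.append({"vertex_id": vid, "x0": np.nan, "y0": np.nan,
                             "sigma": np.nan, "beta": np.nan, "baseline": np.nan,
                             "r2": np.nan, "stage": "failed", "converged": False,
                             "responsive": False})
                continue
            p = res.params
            rows.append({"vertex_id": vid, "x0": p.x0, "y0": p.y0,
                         "sigma": p.sigma, "beta": p.beta, "baseline": p.baseline,
                         "r2": res.r2, "stage": res.stage,
                         "converged": res.converged, "responsive": bool(resp)})
        table = attach_polar_coords(pd.DataFrame(rows))
        table["area"] = truth["area"].to_numpy()
        table["condition"] = condition
        tables[condition] = table
        logger.info("fitted condition %s: %d/%d responsive", condition,
                    int(responsive.sum()), len(responsive))
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for condition, table in tables.items():
            table.to_csv(out_dir / f"fits_{condition}.tsv", sep="\t", index=False)
        write_manifest(out_dir, {"command": "fit", "threshold": threshold,
                                 "fine": fine})
    return tables


def report_bundle(fit_tables: dict, truth: pd.DataFrame | None = None,
                  threshold: float = 0.05, reference: str = "bar_only",
                  out_dir: str | Path | None = None) -> dict:
    """Area summaries, polar-angle correlations, selection control, recovery."""
    summaries = []
    for condition, table in fit_tables.items():
        s = summarize_by_area(table, threshold=threshold)
        s.insert(0, "condition", condition)
        summaries.append(s)
    summary = pd.concat(summaries, ignore_index=True)

    # pairwise polar-angle circular correlations over jointly responsive vertices
    conditions = list(fit_tables)
    corr_rows = []
    for i, a in enumerate(conditions):
        for b in conditions[i + 1:]:
            ta = fit_tables[a]
            tb = fit_tables[b]
            for area in sorted(ta["area"].unique()):
                ids = (set(ta.loc[(ta["area"] == area) & ta["responsive"], "vertex_id"])
                       & set(tb.loc[(tb["area"] == area) & tb["responsive"], "vertex_id"]))
                row = {"condition_a": a, "condition_b": b, "area": area,
                       "n_shared": len(ids), "r": np.nan}
                if len(ids) >= 3:
                    sa = ta[ta["vertex_id"].isin(ids)].sort_values("vertex_id")
                    sb = tb[tb["vertex_id"].isin(ids)].sort_values("vertex_id")
                    try:
                        row["r"] = circ_corr(sa["polar_angle"].to_numpy(),
                                             sb["polar_angle"].to_numpy())
                    except Exception:
                        pass
                corr_rows.append(row)
    correlations = pd.DataFrame(corr_rows)

    selection = None
    if reference in fit_tables and len(fit_tables) > 1:
        survivors = {c: set(t.loc[t["responsive"], "vertex_id"])
                     for c, t in fit_tables.items() if c != reference}
        selection = selection_control(fit_tables[reference], survivors,
                                      threshold=threshold)

    recovery = None
    if truth is not None:
        rec_rows = []
        for condition, table in fit_tables.items():
            joined = table.merge(truth, on="vertex_id", suffixes=("_fit", "_true"))
            joined = joined[joined["responsive"]]
            for area, g in joined.groupby("area_true"):
                ex = g["x0_fit"] - g["x0_true"]
                ey = g["y0_fit"] - g["y0_true"]
                es = g["sigma_fit"] - g["sigma_true"]
                rec_rows.append({
                    "condition": condition, "area": area, "n": len(g),
                    "bias_x0": ex.mean(), "rmse_x0": np.sqrt((ex**2).mean()),
                    "bias_y0": ey.mean(), "rmse_y0": np.sqrt((ey**2).mean()),
                    "bias_sigma": es.mean(), "rmse_sigma": np.sqrt((es**2).mean()),
                    "median_abs_x0_err": ex.abs().median(),
                    "median_rel_sigma_err": (es.abs() / g["sigma_true"]).median()})
        recovery = pd.DataFrame(rec_rows)

    report = {"summary": summary, "correlations": correlations,
              "selection_control": selection, "recovery": recovery}
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for name, df in report.items():
            if df is not None:
                df.to_csv(out_dir / f"{name}.tsv", sep="\t", index=False)
        write_manifest(out_dir, {"command": "report", "threshold": threshold})
    return report


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def write_manifest(out_dir: str | Path, meta: dict) -> None:
    """Write run metadata plus a content hash for every file in ``out_dir``."""
    out_dir = Path(out_dir)
    hashes = {}
    for path in sorted(out_dir.rglob("*")):
        if path.is_file() and path.name != "run_manifest.json":
            hashes[str(path.relative_to(out_dir))] = hashlib.sha256(
                path.read_bytes()).hexdigest()
    (out_dir / "run_manifest.json").write_text(
        json.dumps({**meta, "files": hashes}, indent=2, sort_keys=True))
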