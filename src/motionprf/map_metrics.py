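"""Map-level statistics: responsivity, fit quality, pRF size, polar-angle
circular correlations, selection-control analysis, gaze stability and
observer-task (localisation) scoring.

All tabular inputs and outputs are tidy pandas DataFrames; the fit table is
expected to carry at least ``vertex_id``, ``x0``, ``y0``, ``sigma``, ``r2``
columns (as produced by the pipeline), with visual-area labels supplied as a
``vertex_id -> area`` mapping or an aligned column.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import InsufficientDataError, ValidationError

__all__ = [
    "attach_polar_coords",
    "summarize_by_area",
    "circ_corr",
    "group_circ_corr",
    "selection_control",
    "sigma_vs_ecc",
    "r2_sigma_association",
    "gaze_mad",
    "GazeResult",
    "localisation_design",
    "score_localisation",
]


def attach_polar_coords(fits: pd.DataFrame) -> pd.DataFrame:
    """Add polar_angle (radians, atan2(y0, x0)) and eccentricity columns."""
    out = fits.copy()
    out["polar_angle"] = np.arctan2(out["y0"], out["x0"])
    out["eccentricity"] = np.hypot(out["x0"], out["y0"])
    return out


def _with_area(fits: pd.DataFrame, labels) -> pd.DataFrame:
    fits = fits.copy()
    if labels is None:
        if "area" not in fits.columns:
            raise ValidationError("no area labels supplied and no 'area' column present")
        return fits
    if isinstance(labels, pd.Series) or isinstance(labels, dict):
        labels = pd.Series(labels)
        fits["area"] = fits["vertex_id"].map(labels)
        if fits["area"].isna().any():
            raise ValidationError("area labels do not cover all vertices")
        return fits
    raise ValidationError("labels must be a vertex_id -> area mapping")


def summarize_by_area(fits: pd.DataFrame, labels=None, threshold: float = 0.05,
                      by: tuple[str, ...] = ("area",)) -> pd.DataFrame:
    """Per-area (and optionally per-condition) responsivity and fit summaries.

    ``prop_responsive`` counts vertices with ``r2 > threshold``; the medians
    of r2 and sigma are over responsive vertices only.  Areas with no
    responsive vertex get NaN medians (flagged rows, kept for accounting).
    """
    fits = _with_area(fits, labels)
    rows = []
    for keys, g in fits.groupby(list(by), sort=True):
        keys = (keys,) if not isinstance(keys, tuple) else keys
        resp = g[g["r2"] > threshold]
        rows.append({**dict(zip(by, keys)),
                     "n_vertices": len(g),
                     "n_responsive": len(resp),
                     "prop_responsive": len(resp) / len(g) if len(g) else np.nan,
                     "median_r2": resp["r2"].median() if len(resp) else np.nan,
                     "median_sigma": resp["sigma"].median() if len(resp) else np.nan})
    return pd.DataFrame(rows)


def circ_corr(a: np.ndarray, b: np.ndarray) -> float:
    """Circular correlation of paired angles (Jammalamadaka--SenGupta).

    ``rho = sum sin(a - abar) sin(b - bbar) / sqrt(sum sin^2(a - abar) *
    sum sin^2(b - bbar))`` with circular means ``abar``, ``bbar``.
    Requires at least 3 pairs.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValidationError("angle vectors must be 1-D and the same length")
    if a.size < 3:
        raise InsufficientDataError(f"need >= 3 angle pairs, got {a.size}")
    abar = np.arctan2(np.sin(a).sum(), np.cos(a).sum())
    bbar = np.arctan2(np.sin(b).sum(), np.cos(b).sum())
    sa, sb = np.sin(a - abar), np.sin(b - bbar)
    denom = np.sqrt((sa**2).sum() * (sb**2).sum())
    if denom == 0:
        raise InsufficientDataError("degenerate angular spread (all angles equal)")
    return float((sa * sb).sum() / denom)


def group_circ_corr(per_subject: np.ndarray) -> dict:
    """Fisher-z average of per-subject correlations with a one-sample test.

    Returns mean z, the back-transformed mean correlation, and the two-sided
    one-sample t-test p-value against zero (uncorrected).  Correlations at
    exactly +-1 are clipped (with a warning) before the z transform; a
    zero-variance set of z values flags the t test as degenerate.
    """
    r = np.asarray(per_subject, dtype=float)
    if r.size < 2:
        raise InsufficientDataError("need >= 2 subjects")
    if (np.abs(r) >= 1).any():
        warnings.warn("correlation(s) at |r| = 1 clipped before Fisher z",
                      stacklevel=2)
        r = np.clip(r, -1 + 1e-6, 1 - 1e-6)
    z = np.arctanh(r)
    mean_z = float(z.mean())
    if np.allclose(z, z[0]):
        return {"mean_z": mean_z, "mean_r": float(np.tanh(mean_z)),
                "t": np.nan, "p": np.nan, "n": r.size, "degenerate": True}
    t, p = stats.ttest_1samp(z, 0.0)
    return {"mean_z": mean_z, "mean_r": float(np.tanh(mean_z)),
            "t": float(t), "p": float(p), "n": r.size, "degenerate": False}


def selection_control(fits_ref: pd.DataFrame, survivors_other: dict,
                      labels=None, threshold: float = 0.05) -> pd.DataFrame:
    """Reference-condition summaries restricted to other conditions' survivors.

    ``survivors_other`` maps a condition name to the set of vertex_ids that
    survived that condition's threshold; the reference fits are re-summarised
    on each such subset.  Rows where the restriction leaves an area empty
    keep NaN medians (and are the analogue of dropped zero-value points).
    """
    fits_ref = _with_area(fits_ref, labels)
    known = set(fits_ref["vertex_id"])
    out = []
    for name, ids in survivors_other.items():
        ids = set(ids)
        if not ids <= known:
            raise ValidationError(f"survivor set {name!r} contains unknown vertex ids")
        sub = fits_ref[fits_ref["vertex_id"].isin(ids)]
        summary = summarize_by_area(sub, threshold=threshold)
        summary.insert(0, "survivors_of", name)
        out.append(summary)
    return pd.concat(out, ignore_index=True)


def sigma_vs_ecc(fits: pd.DataFrame, labels=None, threshold: float = 0.05,
                 min_n: int = 10) -> pd.DataFrame:
    """Per-area OLS fit of pRF size on eccentricity (responsive vertices only)."""
    fits = _with_area(attach_polar_coords(fits), labels)
    rows = []
    for area, g in fits.groupby("area", sort=True):
        g = g[g["r2"] > threshold]
        if len(g) < min_n:
            rows.append({"area": area, "n": len(g), "slope": np.nan,
                         "intercept": np.nan, "flagged": True})
            continue
        model = sm.OLS(g["sigma"], sm.add_constant(g["eccentricity"])).fit()
        rows.append({"area": area, "n": len(g),
                     "slope": float(model.params["eccentricity"]),
                     "intercept": float(model.params["const"]), "flagged": False})
    return pd.DataFrame(rows)


def r2_sigma_association(fits: pd.DataFrame, area: str | None = None,
                         labels=None, threshold: float = 0.05,
                         min_n: int = 10) -> tuple[float, float]:
    """Spearman rank correlation between R^2 and sigma among responsive vertices."""
    if area is not None:
        fits = _with_area(fits, labels)
        fits = fits[fits["area"] == area]
    g = fits[fits["r2"] > threshold]
    if len(g) < min_n:
        raise InsufficientDataError(f"need >= {min_n} responsive vertices, got {len(g)}")
    if g["r2"].nunique() == 1 or g["sigma"].nunique() == 1:
        raise ValidationError("degenerate input: a variable is constant")
    rho, p = stats.spearmanr(g["r2"], g["sigma"])
    return float(rho), float(p)


@dataclass
class GazeResult:
    """Per-run gaze stability: MAD per axis, or an exclusion sentinel."""

    mad_x: float | None
    mad_y: float | None
    n_valid: int
    excluded: bool
    reason: str | None = None


def gaze_mad(x: np.ndarray, y: np.ndarray, valid: np.ndarray | None = None,
             min_valid: int = 10) -> GazeResult:
    """Median absolute deviation of gaze position along each axis.

    Runs with fewer than ``min_valid`` valid samples are excluded (sentinel
    result, not an exception), mirroring the run-rejection rule of the gaze
    stability analysis.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if valid is None:
        valid = np.isfinite(x) & np.isfinite(y)
    valid = np.asarray(valid, dtype=bool)
    n_valid = int(valid.sum())
    if n_valid < min_valid:
        return GazeResult(None, None, n_valid, True,
                          f"only {n_valid} valid samples (< {min_valid})")
    xv, yv = x[valid], y[valid]
    mad_x = float(np.median(np.abs(xv - np.median(xv))))
    mad_y = float(np.median(np.abs(yv - np.median(yv))))
    return GazeResult(mad_x, mad_y, n_valid, False)


# ---------------------------------------------------------------------------
# Observer localisation task (bar-visibility psychophysics)
# ---------------------------------------------------------------------------

#: 4AFC response categories: bar above / below / left / right of fixation.
RESPONSES = ("above", "below", "left", "right")


def localisation_design(conditions=("bar_only", "kinetic", "global",
                                    "transparent", "size_defined"),
                        step_size: float = 0.7, steps_per_trial: int = 25,
                        n_excluded_centre: int = 3, repeats: int = 5
                        ) -> pd.DataFrame:
    """Enumerate the observer-task trials for one block per condition.

    Bar positions are the sweep steps minus the ``n_excluded_centre`` middle
    positions (whose side relative to fixation is ambiguous), each shown in
    two orientations (horizontal and vertical) with ``repeats`` repeats:
    22 positions x 2 orientations x 5 repeats = 220 trials per block.
    Eccentricity is recorded as the absolute bar-centre offset from fixation.
    """
    centre = (steps_per_trial - 1) / 2.0
    offsets = [(s - centre) * step_size for s in range(steps_per_trial)]
    offsets.sort(key=abs)
    offsets = sorted(offsets[n_excluded_centre:])
    rows = []
    for cond in conditions:
        for orientation in ("horizontal", "vertical"):
            for off in offsets:
                if orientation == "horizontal":  # horizontal bar: above or below
                    truth = "above" if off > 0 else "below"
                else:
                    truth = "right" if off > 0 else "left"
                for rep in range(repeats):
                    rows.append({"condition": cond, "orientation": orientation,
                                 "offset": off, "eccentricity": abs(off),
                                 "truth": truth, "repeat": rep})
    return pd.DataFrame(rows)


def score_localisation(responses: pd.DataFrame, reference: str = "bar_only"
                       ) -> dict:
    """Proportion correct by eccentricity with per-condition linear fits.

    ``responses`` must carry condition, orientation, offset, truth and
    response columns.  Trials whose response is not one of the four
    alternatives are rejected (counted, not fatal).  Responses are collated
    by eccentricity (collapsing hemifield and orientation), scored as
    proportion correct per bin, and an OLS line is fitted per condition over
    the binned points; slopes are contrasted against ``reference`` through
    an interaction model on the binned data.
    """
    required = {"condition", "orientation", "offset", "truth", "response"}
    missing = required - set(responses.columns)
    if missing:
        raise ValidationError(f"response table is missing column(s): {sorted(missing)}")
    ok = responses["response"].isin(RESPONSES)
    n_rejected = int((~ok).sum())
    trials = responses[ok].copy()
    trials["eccentricity"] = trials["offset"].abs()
    trials["correct"] = (trials["response"] == trials["truth"]).astype(float)

    binned = (trials.groupby(["condition", "eccentricity"], sort=True)
              .agg(prop_correct=("correct", "mean"), n=("correct", "size"))
              .reset_index())

    fits = {}
    for cond, g in binned.groupby("condition"):
        model = sm.OLS(g["prop_correct"], sm.add_constant(g["eccentricity"])).fit()
        fits[cond] = {"slope": float(model.params["eccentricity"]),
                      "intercept": float(model.params["const"])}

    contrasts = {}
    if reference in fits:
        for cond in fits:
            if cond == reference:
                continue
            sub = binned[binned["condition"].isin([cond, reference])].copy()
            sub["is_other"] = (sub["condition"] == cond).astype(float)
            X = sub[["eccentricity", "is_other"]].copy()
            X["interaction"] = sub["eccentricity"] * sub["is_other"]
            model = sm.OLS(sub["prop_correct"], sm.add_constant(X)).fit()
            contrasts[cond] = {"slope_diff": float(model.params["interaction"]),
                               "t": float(model.tvalues["interaction"]),
                               "p": float(model.pvalues["interaction"])}
    return {"by_eccentricity": binned, "linear_fits": fits,
            "slope_contrasts": contrasts, "n_rejected": n_rejected,
            "eccentricity_convention": "absolute bar-centre offset from fixation"}
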