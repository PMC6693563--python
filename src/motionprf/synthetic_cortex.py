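"""Synthetic cortical data with known ground-truth pRFs.

Emulates the structure of the study data this pipeline analyses: populations
of vertices across visual areas V1, V2, V3, V3A, V3B and MT+, each vertex
carrying a ground-truth 2D-Gaussian pRF whose spread grows linearly with
eccentricity, responding to the bar-sweep stimulus through two channels:

* a *bar* response -- overlap of the pRF with the bar aperture, weighted by a
  per-area, per-condition ``bar_gain``; and
* a *background* response -- overlap with the rest of the stimulus disc,
  weighted by ``background_gain``.

Conditions whose background carries its own signal (moving or flickering
dots outside the bar) have ``background_gain > 0``, which shrinks the
bar-locked modulation of the total drive: the "neural visibility" of the bar
is the bar/background response contrast, not the bar response alone.  On
null trials the background drive follows the condition's rule: a blank
screen for ``bar_only``, full-field background drive for every other
condition.

Drives are normalised by each pRF's full-field overlap so that a vertex's
signal amplitude is governed by its ``beta`` (in the z-units of the
preprocessed data) rather than by its spread, convolved with the HRF, and
summed with Gaussian noise (optionally AR(1)).

The per-area gain defaults are illustrative calibration knobs chosen so the
qualitative responsivity pattern of interest emerges (strong early-area
responses to the plain bar; suppressed V1 and a V3A/V3B peak for the
global-motion-like conditions); they are not estimates of any measured
quantity.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.signal import lfilter

from .errors import ValidationError
from .prf_core import HRFSpec, hrf_kernel
from .sweep_design import ApertureStack, build_sweep_design, render_apertures

__all__ = [
    "AreaModel",
    "VertexPopulation",
    "CONDITIONS",
    "default_areas",
    "sample_vertices",
    "simulate_run",
    "make_dataset",
]

CONDITIONS = ("bar_only", "kinetic", "global", "transparent", "size_defined")

#: Background-to-bar response ratios per (area, condition); bar gain is 1.
#: Chosen once as plausible "neural visibility" levels: the plain bar has no
#: background signal anywhere; the global-like conditions drive the V1
#: background almost as strongly as the bar (suppressing its bar-locked
#: modulation) but leave a clear bar/background contrast in V3A/V3B.
_DEFAULT_BACKGROUND_GAIN = {
    "V1":  {"bar_only": 0.0, "kinetic": 0.75, "global": 0.95, "transparent": 0.95, "size_defined": 0.92},
    "V2":  {"bar_only": 0.0, "kinetic": 0.65, "global": 0.88, "transparent": 0.92, "size_defined": 0.88},
    "V3":  {"bar_only": 0.0, "kinetic": 0.55, "global": 0.78, "transparent": 0.85, "size_defined": 0.82},
    "V3A": {"bar_only": 0.0, "kinetic": 0.45, "global": 0.62, "transparent": 0.70, "size_defined": 0.72},
    "V3B": {"bar_only": 0.0, "kinetic": 0.45, "global": 0.62, "transparent": 0.70, "size_defined": 0.68},
    "MT+": {"bar_only": 0.0, "kinetic": 0.65, "global": 0.80, "transparent": 0.85, "size_defined": 0.82},
}

#: pRF size vs eccentricity laws per area (degrees; sigma = a + b * ecc),
#: ordered so that median size increases up the hierarchy.
_DEFAULT_SIZE_LAW = {
    "V1": (0.50, 0.15), "V2": (0.60, 0.20), "V3": (0.80, 0.25),
    "V3A": (1.20, 0.35), "V3B": (1.40, 0.35), "MT+": (2.00, 0.50),
}


@dataclass
class AreaModel:
    """One visual area's vertex count, size law and condition gains."""

    name: str
    n_vertices: int
    sigma_intercept: float
    sigma_slope: float
    bar_gain: dict = field(default_factory=dict)  # condition -> gain (default 1)
    background_gain: dict = field(default_factory=dict)  # condition -> gain

    def __post_init__(self) -> None:
        if self.sigma_intercept <= 0:
            raise ValidationError("sigma_intercept must be positive")
        if self.sigma_slope < 0:
            raise ValidationError("sigma_slope must be non-negative")
        if self.n_vertices < 1:
            raise ValidationError("n_vertices must be >= 1")
        for gains in (self.bar_gain, self.background_gain):
            if any(g < 0 for g in gains.values()):
                raise ValidationError("gains must be non-negative")

    def gains(self, condition: str) -> tuple[float, float]:
        return (float(self.bar_gain.get(condition, 1.0)),
                float(self.background_gain.get(condition, 0.0)))


def default_areas(n_vertices: int = 100) -> list[AreaModel]:
    """The default six-area layout with illustrative condition gains."""
    return [AreaModel(name=name, n_vertices=n_vertices,
                      sigma_intercept=_DEFAULT_SIZE_LAW[name][0],
                      sigma_slope=_DEFAULT_SIZE_LAW[name][1],
                      background_gain=dict(_DEFAULT_BACKGROUND_GAIN[name]))
            for name in _DEFAULT_SIZE_LAW]


@dataclass
class VertexPopulation:
    """Simulated cortex: per-vertex area label and ground-truth pRF."""

    truth: pd.DataFrame  # vertex_id, area, x0, y0, sigma, ecc, polar_angle, beta, baseline
    areas: dict  # name -> AreaModel
    noise_sd: float = 1.0
    ar1: float = 0.0
    seed: int | None = None

    @property
    def n_vertices(self) -> int:
        return len(self.truth)


def sample_vertices(areas: Sequence[AreaModel], seed: int,
                    field_radius: float = 8.0, sigma_jitter: float = 0.10,
                    beta_jitter: float = 0.2,
                    noise_sd: float = 1.5, ar1: float = 0.3) -> VertexPopulation:
    """Draw a vertex population with ground-truth pRFs.

    Polar angles are uniform; eccentricities are drawn with density
    proportional to radius (uniform over the disc area) up to
    ``field_radius``; sigma follows the area's linear eccentricity law with
    multiplicative lognormal jitter (sd ~``sigma_jitter``).  Response
    amplitudes are lognormal with median 1 and log-sd ``beta_jitter``:
    vertices vary widely in how strongly they respond, which is what makes a
    responsivity *fraction* (rather than all-or-none areas) possible.
    """
    if len(areas) == 0:
        raise ValidationError("at least one AreaModel is required")
    rng = np.random.default_rng(seed)
    rows = []
    vid = 0
    for area in areas:
        n = area.n_vertices
        ecc = field_radius * np.sqrt(rng.uniform(size=n))
        ang = rng.uniform(-np.pi, np.pi, size=n)
        sigma = ((area.sigma_intercept + area.sigma_slope * ecc)
                 * np.exp(rng.normal(0.0, sigma_jitter, size=n)))
        beta = np.exp(rng.normal(0.0, beta_jitter, size=n))
        for i in range(n):
            rows.append({"vertex_id": vid, "area": area.name,
                         "x0": ecc[i] * np.cos(ang[i]), "y0": ecc[i] * np.sin(ang[i]),
                         "sigma": sigma[i], "ecc": ecc[i], "polar_angle": ang[i],
                         "beta": beta[i], "baseline": 0.0})
            vid += 1
    truth = pd.DataFrame(rows)
    return VertexPopulation(truth=truth, areas={a.name: a for a in areas},
                            noise_sd=noise_sd, ar1=ar1, seed=seed)


def _background_frames(stack: ApertureStack, condition: str) -> np.ndarray:
    """Per-volume background region: disc minus bar, with the condition's null rule.

    ``bar_only`` shows a blank screen outside the bar (and on null trials),
    so its background drive is identically zero; every other condition fills
    the rest of the disc with moving/flickering dots, and its null trials
    drive the full disc.
    """
    frames = stack.frames_matrix()
    if condition == "bar_only":
        return np.zeros_like(frames)
    disc = stack.disc_mask().ravel().astype(float)
    return np.clip(disc[None, :] - frames, 0.0, 1.0)


def _gauss_matrix(truth: pd.DataFrame, stack: ApertureStack) -> np.ndarray:
    X, Y = stack.pixel_centres()
    px, py = X.ravel(), Y.ravel()
    dx = truth["x0"].to_numpy()[:, None] - px[None, :]
    dy = truth["y0"].to_numpy()[:, None] - py[None, :]
    s2 = truth["sigma"].to_numpy()[:, None] ** 2
    return np.exp(-(dx**2 + dy**2) / (2.0 * s2))


def simulate_run(pop: VertexPopulation, condition: str, stack: ApertureStack,
                 hrf: HRFSpec = HRFSpec(), seed: int = 0,
                 noise_sd: float | None = None) -> np.ndarray:
    """One run of noisy BOLD series, shape (n_vertices, T).

    drive = (bar_gain * overlap(pRF, bar) + background_gain * overlap(pRF,
    background region)) / overlap(pRF, full disc); the series is the
    HRF-convolved drive scaled by beta, plus baseline and Gaussian noise.
    """
    if condition not in CONDITIONS:
        raise ValidationError(f"unknown condition {condition!r}; expected one of {CONDITIONS}")
    truth = pop.truth
    noise_sd = pop.noise_sd if noise_sd is None else noise_sd

    frames = stack.frames_matrix()
    bg_frames = _background_frames(stack, condition)
    disc = stack.disc_mask().ravel().astype(float)

    W = _gauss_matrix(truth, stack)  # (N, P)
    ovl_bar = W @ frames.T
    ovl_bg = W @ bg_frames.T
    norm = W @ disc
    del W

    bar_g = np.array([pop.areas[a].gains(condition)[0] for a in truth["area"]])
    bg_g = np.array([pop.areas[a].gains(condition)[1] for a in truth["area"]])
    drive = (bar_g[:, None] * ovl_bar + bg_g[:, None] * ovl_bg) / norm[:, None]

    TR = stack.design.TR if stack.design is not None else 1.0
    kernel = hrf_kernel(hrf, TR)
    T = stack.n_volumes
    # The background is already on before the first analysed volume (the run
    # starts with a pre-equilibrium period), so pad the drive with its
    # steady-state background level to avoid a spurious onset transient.
    pad = kernel.size
    steady = np.repeat(bg_g[:, None], pad, axis=1)
    padded = np.concatenate([steady, drive], axis=1)
    conv = np.apply_along_axis(
        lambda d: np.convolve(d, kernel)[pad: pad + T], 1, padded)
    signal = (truth["baseline"].to_numpy()[:, None]
              + truth["beta"].to_numpy()[:, None] * conv)

    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, 1.0, size=signal.shape)
    if pop.ar1:
        # AR(1) innovations scaled to keep the stationary sd at 1
        noise = lfilter([np.sqrt(1.0 - pop.ar1**2)], [1.0, -pop.ar1], noise, axis=1)
    return signal + noise_sd * noise


DEFAULT_SCENARIO = {
    "conditions": list(CONDITIONS),
    "runs_per_condition": 4,
    "n_vertices_per_area": 100,
    "noise_sd": 1.5,
    "ar1": 0.3,
    "grid_pixels": 100,
    "sigma_jitter": 0.10,
    "beta_jitter": 0.2,
}


def make_dataset(scenario: dict | None = None, seed: int = 0,
                 out_dir: str | Path | None = None) -> dict:
    """Generate a full dataset bundle: population, apertures, per-condition runs.

    Returns a dict with keys ``population``, ``stack``, ``design``, ``runs``
    (condition -> list of (N, T) arrays) and ``scenario``; if ``out_dir`` is
    given the truth table (TSV), per-run series (TSV), scenario YAML and a
    seed manifest (JSON) are written there as well.
    """
    scenario = {**DEFAULT_SCENARIO, **(scenario or {})}
    unknown = set(scenario) - set(DEFAULT_SCENARIO) - {"areas", "design"}
    if unknown:
        raise ValidationError(f"unknown scenario key(s): {sorted(unknown)}")
    design = build_sweep_design(scenario.get("design"))
    stack = render_apertures(design, grid_pixels=scenario["grid_pixels"])
    areas = scenario.get("areas") or default_areas(scenario["n_vertices_per_area"])
    pop = sample_vertices(areas, seed=seed, sigma_jitter=scenario["sigma_jitter"],
                          beta_jitter=scenario["beta_jitter"],
                          noise_sd=scenario["noise_sd"], ar1=scenario["ar1"])

    runs: dict[str, list[np.ndarray]] = {}
    for c_idx, condition in enumerate(scenario["conditions"]):
        runs[condition] = [
            simulate_run(pop, condition, stack,
                         seed=_subseed(seed, c_idx, r))
            for r in range(scenario["runs_per_condition"])
        ]

    bundle = {"population": pop, "stack": stack, "design": design,
              "runs": runs, "scenario": scenario, "seed": seed}
    if out_dir is not None:
        _write_bundle(bundle, Path(out_dir))
    return bundle


def _subseed(seed: int, condition_index: int, run_index: int) -> int:
    """Stable per-run seed below 2**31, derived by hashing the master seed."""
    key = f"{seed}:{condition_index}:{run_index}".encode()
    return int.from_bytes(hashlib.sha256(key).digest()[:4], "big") % (2**31)


def _write_bundle(bundle: dict, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    pop: VertexPopulation = bundle["population"]
    pop.truth.to_csv(out_dir / "truth.tsv", sep="\t", index=False)
    for condition, run_list in bundle["runs"].items():
        for r, series in enumerate(run_list):
            df = pd.DataFrame(series)
            df.insert(0, "vertex_id", pop.truth["vertex_id"].to_numpy())
            df.to_csv(out_dir / f"series_{condition}_run{r}.tsv", sep="\t", index=False)
    (out_dir / "scenario.yaml").write_text(yaml.safe_dump(bundle["scenario"]))
    manifest = {"seed": bundle["seed"],
                "n_vertices": pop.n_vertices,
                "conditions": list(bundle["runs"]),
                "runs_per_condition": bundle["scenario"]["runs_per_condition"]}
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    bundle["design"].to_yaml(out_dir / "design.yaml")
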