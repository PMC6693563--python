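"""Forward model: 2D-Gaussian pRF, aperture overlap, HRF, preprocessing.

A vertex's population receptive field (pRF) is an isotropic 2D Gaussian in
the visual field with centre ``(x0, y0)`` and spread ``sigma`` (both in
degrees of visual angle).  The neural drive at volume ``t`` is the overlap of
that Gaussian with the binary bar aperture at ``t``; convolving the drive
with a canonical haemodynamic response function (HRF), scaling by a response
amplitude ``beta`` and adding a ``baseline`` gives the predicted BOLD series.

Observed runs are prepared for fitting by discarding the leading
pre-equilibrium volumes, linearly detrending each run, z-standardising it,
and averaging runs of the same condition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal as sp_signal
from scipy.stats import gamma as gamma_dist

from .errors import DegenerateSeriesError, GeometryError, ValidationError
from .sweep_design import ApertureStack

__all__ = [
    "PRFParams",
    "HRFSpec",
    "TimeSeries",
    "gaussian_field",
    "neural_drive",
    "hrf_kernel",
    "predict_timeseries",
    "preprocess",
    "detrend_zscore",
]


@dataclass(frozen=True)
class PRFParams:
    """One vertex's pRF model: centre, spread, amplitude, baseline."""

    x0: float
    y0: float
    sigma: float
    beta: float = 1.0
    baseline: float = 0.0

    def __post_init__(self) -> None:
        if not np.isfinite([self.x0, self.y0, self.sigma]).all():
            raise ValidationError("pRF centre and spread must be finite")
        if self.sigma <= 0:
            raise ValidationError(f"sigma must be positive, got {self.sigma}")

    @property
    def eccentricity(self) -> float:
        return float(np.hypot(self.x0, self.y0))

    @property
    def polar_angle(self) -> float:
        """Radians; 0 at the right horizontal meridian, counterclockwise positive."""
        return float(np.arctan2(self.y0, self.x0))


@dataclass(frozen=True)
class HRFSpec:
    """Canonical double-gamma HRF (peak minus scaled undershoot), peak-normalised.

    Defaults are the standard canonical shape: peak at ~6 s, undershoot at
    ~16 s, unit dispersions, peak:undershoot ratio 6, evaluated on a 0.1-s
    lattice and truncated at 32 s.  A measured HRF can be substituted by
    adjusting the parameters.
    """

    peak_delay: float = 6.0
    undershoot_delay: float = 16.0
    peak_disp: float = 1.0
    undershoot_disp: float = 1.0
    p_u_ratio: float = 6.0
    dt: float = 0.1
    duration: float = 32.0

    def __post_init__(self) -> None:
        if min(self.peak_delay, self.undershoot_delay, self.peak_disp,
               self.undershoot_disp, self.p_u_ratio, self.dt) <= 0:
            raise ValidationError("all HRF parameters must be positive")


@dataclass
class TimeSeries:
    """A single vertex/voxel BOLD series sampled at TR."""

    values: np.ndarray
    TR: float = 1.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValidationError("TimeSeries values must be 1-D")
        if not np.isfinite(self.values).all():
            raise ValidationError("TimeSeries values must be finite")

    def __len__(self) -> int:
        return self.values.size


def gaussian_field(params: PRFParams, grid: ApertureStack | tuple[np.ndarray, np.ndarray]
                   ) -> np.ndarray:
    """Unnormalised Gaussian pRF profile sampled at pixel centres (peak 1)."""
    if isinstance(grid, ApertureStack):
        X, Y = grid.pixel_centres()
    else:
        X, Y = grid
    return np.exp(-((X - params.x0) ** 2 + (Y - params.y0) ** 2)
                  / (2.0 * params.sigma ** 2))


def neural_drive(params: PRFParams, stack: ApertureStack) -> np.ndarray:
    """Overlap of the pRF profile with the binary aperture, per volume."""
    w = gaussian_field(params, stack)
    if w.shape != stack.frames.shape[1:]:
        raise GeometryError("pRF grid does not match aperture frames")
    return stack.frames_matrix() @ w.ravel()


def hrf_kernel(spec: HRFSpec, TR: float) -> np.ndarray:
    """HRF sampled at TR, truncated at ``spec.duration``, peak normalised to 1.

    Built as the difference of two gamma densities (shape = delay/dispersion,
    scale = dispersion) on the fine ``spec.dt`` lattice, then decimated to TR
    (``TR`` must be a multiple of ``dt``).
    """
    n_fine = int(round(spec.duration / spec.dt)) + 1
    t = np.arange(n_fine) * spec.dt
    h = (gamma_dist.pdf(t, spec.peak_delay / spec.peak_disp, scale=spec.peak_disp)
         - gamma_dist.pdf(t, spec.undershoot_delay / spec.undershoot_disp,
                          scale=spec.undershoot_disp) / spec.p_u_ratio)
    h = h / h.max()
    stride = TR / spec.dt
    if abs(stride - round(stride)) > 1e-9:
        raise ValidationError(f"TR={TR} is not a multiple of HRF dt={spec.dt}")
    return h[:: int(round(stride))]


def predict_timeseries(params: PRFParams, stack: ApertureStack,
                       hrf: HRFSpec = HRFSpec()) -> TimeSeries:
    """Predicted BOLD series: baseline + beta * (drive (*) HRF), causal, length T."""
    d = neural_drive(params, stack)
    kernel = hrf_kernel(hrf, stack.design.TR if stack.design else 1.0)
    T = d.size
    conv = np.convolve(d, kernel)[:T]
    TR = stack.design.TR if stack.design else 1.0
    return TimeSeries(values=params.baseline + params.beta * conv, TR=TR,
                      meta={"model": "gaussian_prf"})


def detrend_zscore(values: np.ndarray) -> np.ndarray:
    """Remove the best-fit line, then standardise to mean 0 and sd 1."""
    values = np.asarray(values, dtype=float)
    detrended = sp_signal.detrend(values, type="linear")
    sd = detrended.std()
    # tolerance relative to the raw scale: a pure line detrends to rounding noise
    if sd <= 1e-10 * max(1.0, float(np.abs(values).max())):
        raise DegenerateSeriesError("series is constant (or a pure line) after detrending")
    return detrended / sd


def preprocess(series: Sequence[TimeSeries] | Sequence[np.ndarray],
               discard: int = 0, TR: float | None = None) -> TimeSeries:
    """Discard leading volumes, detrend + z-standardise each run, average runs.

    All runs must have equal length after the discard.  Raises
    :class:`DegenerateSeriesError` if any run is constant.
    """
    if len(series) == 0:
        raise ValidationError("preprocess requires at least one run")
    runs = []
    for s in series:
        v = s.values if isinstance(s, TimeSeries) else np.asarray(s, dtype=float)
        if TR is None and isinstance(s, TimeSeries):
            TR = s.TR
        runs.append(detrend_zscore(v[discard:]))
    lengths = {r.size for r in runs}
    if len(lengths) != 1:
        raise GeometryError(f"runs have unequal lengths after discard: {sorted(lengths)}")
    return TimeSeries(values=np.mean(runs, axis=0), TR=TR or 1.0,
                      meta={"n_runs": len(runs), "discard": discard})
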