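"""Bar-sweep experimental design and binary aperture rendering.

The mapping stimulus is a bar (a straight strip 2.4 degrees wide) that sweeps
across a circular stimulus region of radius 8 degrees in 25 discrete steps of
0.7 degrees, one step per second.  A run consists of eight bar trials -- one
per sweep direction (four cardinal, four oblique) -- plus two null trials with
no bar, always in trial positions 5 and 10.  At TR = 1 s this yields 250
analysis volumes per run.

The aperture of the bar (bar region intersected with the stimulus disc,
rendered as a binary image per volume) is the only stimulus description the
pRF model needs; it is identical across the dot-motion conditions, which
differ only in dot content.

Conventions
-----------
* Angles are in degrees, math convention: 0 = rightward, counterclockwise
  positive.  A trial's ``direction`` is the direction of bar *travel*; the
  bar strip itself is perpendicular to it.
* Pixel centres lie on a uniform lattice over the aperture square; a pixel
  belongs to a region iff its centre does (strict inequalities).
* The 25-step sweep path is centred on the visual field, so the strip starts
  and ends partly outside the disc (the 17.5-degree path slightly exceeds the
  16-degree square).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
import yaml

from .errors import ConfigError, ResolutionError, ValidationError

__all__ = [
    "SweepDesign",
    "ApertureStack",
    "build_sweep_design",
    "render_apertures",
    "trial_volume_count",
    "bar_geometry",
    "visual_angle_deg",
    "EXP1_DIRECTIONS",
]

#: Experiment-1 fixed trial order: anticlockwise from the horizontal bar at the
#: top of the screen moving downwards (travel angle 270 deg), in 45-deg steps.
EXP1_DIRECTIONS: tuple[float, ...] = tuple((270.0 + 45.0 * k) % 360.0 for k in range(8))


@dataclass(frozen=True)
class SweepDesign:
    """Geometry and timing of one bar-sweep run."""

    bar_width: float = 2.4
    step_size: float = 0.7
    steps_per_trial: int = 25
    step_duration: float = 1.0
    directions: tuple[float, ...] = EXP1_DIRECTIONS
    null_trial_positions: tuple[int, ...] = (5, 10)  # 1-based trial order
    field_halfwidth: float = 8.0
    aperture_halfwidth: float = 8.0  # half-side of the 16 x 16 deg dot square
    TR: float = 1.0

    def __post_init__(self) -> None:
        for name in ("bar_width", "step_size", "step_duration", "field_halfwidth",
                     "aperture_halfwidth", "TR"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive, got {getattr(self, name)}")
        if self.steps_per_trial < 1:
            raise ValidationError("steps_per_trial must be >= 1")
        n_trials = len(self.directions) + len(self.null_trial_positions)
        for pos in self.null_trial_positions:
            if not 1 <= pos <= n_trials:
                raise ValidationError(f"null trial position {pos} outside 1..{n_trials}")

    @property
    def n_trials(self) -> int:
        return len(self.directions) + len(self.null_trial_positions)

    @property
    def trial_duration(self) -> float:
        return self.steps_per_trial * self.step_duration

    @property
    def frames_per_trial(self) -> int:
        return int(round(self.trial_duration / self.TR))

    @property
    def total_volumes(self) -> int:
        return self.n_trials * self.frames_per_trial

    def trial_sequence(self) -> list[float | None]:
        """Trial-ordered list of travel directions, ``None`` for null trials."""
        seq: list[float | None] = []
        directions = iter(self.directions)
        for trial in range(1, self.n_trials + 1):
            if trial in self.null_trial_positions:
                seq.append(None)
            else:
                seq.append(next(directions))
        return seq

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["directions"] = list(self.directions)
        d["null_trial_positions"] = list(self.null_trial_positions)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SweepDesign":
        return build_sweep_design(yaml.safe_load(Path(path).read_text()))


@dataclass
class ApertureStack:
    """Time-ordered binary visual-field masks of the bar, one frame per volume."""

    frames: np.ndarray  # (T, H, W) uint8, values in {0, 1}
    grid_extent: float  # side of the square field of view, degrees
    pixel_size: float  # degrees per pixel
    frame_times: np.ndarray  # (T,) seconds
    design: SweepDesign | None = field(default=None, repr=False)

    @property
    def n_volumes(self) -> int:
        return self.frames.shape[0]

    @property
    def grid_pixels(self) -> int:
        return self.frames.shape[1]

    def pixel_centres(self) -> tuple[np.ndarray, np.ndarray]:
        """(X, Y) coordinate images of pixel centres, degrees; y increases upward."""
        n = self.grid_pixels
        half = self.grid_extent / 2.0
        coords = -half + (np.arange(n) + 0.5) * self.pixel_size
        X, Y = np.meshgrid(coords, coords)
        # row 0 is the top of the visual field
        return X, Y[::-1]

    def frames_matrix(self, dtype=np.float64) -> np.ndarray:
        """Frames flattened to (T, n_pixels)."""
        return self.frames.reshape(self.n_volumes, -1).astype(dtype)

    def disc_mask(self, radius: float | None = None) -> np.ndarray:
        """Boolean image of pixels whose centre lies strictly inside the disc."""
        if radius is None:
            radius = (self.design.field_halfwidth if self.design is not None
                      else self.grid_extent / 2.0)
        X, Y = self.pixel_centres()
        return X**2 + Y**2 < radius**2

    def save_npz(self, path: str | Path) -> None:
        path = Path(path)
        np.savez_compressed(path, frames=self.frames, frame_times=self.frame_times)
        meta = {"grid_extent": self.grid_extent, "pixel_size": self.pixel_size}
        path.with_suffix(".json").write_text(json.dumps(meta))

    @classmethod
    def load_npz(cls, path: str | Path) -> "ApertureStack":
        path = Path(path)
        with np.load(path) as z:
            frames, frame_times = z["frames"], z["frame_times"]
        meta = json.loads(path.with_suffix(".json").read_text())
        return cls(frames=frames, frame_times=frame_times, **meta)


def build_sweep_design(overrides: dict | None = None, *, experiment: int = 1,
                       seed: int | None = None) -> SweepDesign:
    """Construct and validate a :class:`SweepDesign`.

    Parameters
    ----------
    overrides
        Mapping of :class:`SweepDesign` field names to values; unknown keys
        raise :class:`ConfigError`.
    experiment
        1 gives the fixed anticlockwise direction order starting with the
        horizontal bar moving downwards.  2 randomises the starting
        orientation and the rotation sense (clockwise/anticlockwise) of the
        direction sequence, deterministically from ``seed``.
    seed
        Required when ``experiment == 2``.
    """
    overrides = dict(overrides or {})
    known = {f.name for f in dataclasses.fields(SweepDesign)}
    unknown = set(overrides) - known
    if unknown:
        raise ConfigError(f"unknown design key(s): {sorted(unknown)}")
    for key in ("directions", "null_trial_positions"):
        if key in overrides:
            overrides[key] = tuple(overrides[key])

    if experiment == 2 and "directions" not in overrides:
        if seed is None:
            raise ConfigError("experiment 2 randomises the sweep order; a seed is required")
        rng = np.random.default_rng(seed)
        start = float(rng.integers(8)) * 45.0
        sense = 1.0 if rng.integers(2) else -1.0  # anticlockwise vs clockwise shifts
        overrides["directions"] = tuple((start + sense * 45.0 * k) % 360.0
                                        for k in range(8))
    elif experiment not in (1, 2):
        raise ConfigError(f"experiment must be 1 or 2, got {experiment}")
    return SweepDesign(**overrides)


def trial_volume_count(design: SweepDesign) -> tuple[int, int]:
    """(frames per trial, total frames in the analysed run) at the design TR."""
    return design.frames_per_trial, design.total_volumes


def _unit_vector(direction: float) -> np.ndarray:
    """Unit vector of a travel direction, exact at multiples of 45 degrees.

    Exactness matters: it makes opposite directions exactly antiparallel, so
    reversing a sweep reproduces the time-reversed frames bit for bit.
    """
    d = direction % 360.0
    if d % 45.0 == 0.0:
        c = np.sqrt(0.5)
        exact = {0.0: (1.0, 0.0), 45.0: (c, c), 90.0: (0.0, 1.0), 135.0: (-c, c),
                 180.0: (-1.0, 0.0), 225.0: (-c, -c), 270.0: (0.0, -1.0),
                 315.0: (c, -c)}
        return np.array(exact[d])
    theta = np.deg2rad(d)
    return np.array([np.cos(theta), np.sin(theta)])


def bar_geometry(design: SweepDesign, direction: float, step: int
                 ) -> tuple[np.ndarray, float]:
    """Travel unit vector and signed bar-centre offset for one sweep step.

    The bar strip at step ``s`` is the set of points ``p`` with
    ``|p . u - offset| < bar_width / 2`` where ``u`` is the travel direction;
    the sweep path is centred on fixation.
    """
    u = _unit_vector(direction)
    offset = (step - (design.steps_per_trial - 1) / 2.0) * design.step_size
    return u, offset


def render_apertures(design: SweepDesign, grid_pixels: int = 100) -> ApertureStack:
    """Render the binary bar apertures, one frame per scanning volume.

    A pixel is set iff its centre lies strictly inside the bar strip at that
    volume's sweep position *and* strictly inside the stimulus disc.  Null
    trials render as all-zero frames.
    """
    if grid_pixels < 16:
        raise ValidationError(f"grid_pixels must be >= 16, got {grid_pixels}")
    extent = 2.0 * design.aperture_halfwidth
    pixel_size = extent / grid_pixels
    if design.bar_width < 2.0 * pixel_size:
        raise ResolutionError(
            f"bar width {design.bar_width} deg spans fewer than 2 pixels at "
            f"{pixel_size:.3f} deg/pixel")

    T = design.total_volumes
    frames = np.zeros((T, grid_pixels, grid_pixels), dtype=np.uint8)
    stack = ApertureStack(frames=frames, grid_extent=extent, pixel_size=pixel_size,
                          frame_times=np.arange(T, dtype=float) * design.TR,
                          design=design)
    X, Y = stack.pixel_centres()
    in_disc = X**2 + Y**2 < design.field_halfwidth**2

    fpt = design.frames_per_trial
    for i, direction in enumerate(design.trial_sequence()):
        if direction is None:
            continue
        for f in range(fpt):
            step = int(f * design.TR // design.step_duration)
            u, offset = bar_geometry(design, direction, step)
            in_strip = np.abs(X * u[0] + Y * u[1] - offset) < design.bar_width / 2.0
            frames[i * fpt + f] = (in_strip & in_disc).astype(np.uint8)
    return stack


def visual_angle_deg(size_cm: float, distance_cm: float) -> float:
    """Visual angle subtended by an object of ``size_cm`` at ``distance_cm``."""
    if size_cm <= 0 or distance_cm <= 0:
        raise ValidationError("size and distance must be positive")
    return float(np.rad2deg(2.0 * np.arctan2(size_cm / 2.0, distance_cm)))
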