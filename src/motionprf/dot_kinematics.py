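"""Random-dot kinematics for the five bar-visibility conditions.

The mapping bar is always a region of coherent dot motion (or, in one
condition, of slightly larger dots); what distinguishes the conditions is
the *background*:

* ``bar_only`` -- only the dots inside the bar are visible (bar on a blank
  field).
* ``kinetic`` -- background dots always move opposite to the bar dots
  (a shearing, kinetic boundary).
* ``global`` -- background dots oscillate along their own random axes; the
  bar is a patch of 100%-coherent global motion amid noise.
* ``transparent`` -- all dots are locally paired; bar pairs move coherently
  with half the pairs in each of two opposed directions (two transparent
  sheets), background pair members move in opposite directions (locally
  balanced, no transparency percept).
* ``size_defined`` -- all dots oscillate along random axes; bar dots are
  0.10 degrees in diameter against a 0.09-degree background.

All dots reverse direction by 180 degrees every ``reversal_period`` (0.5 s)
to prevent motion adaptation; in the paired (transparent-family) conditions
the reversal clock is desynchronised across pairs.  Dots inside the bar move
along the bar's length (perpendicular to the sweep travel direction).  Dots
leaving the 16 x 16-degree square are wrapped back one aperture width.

This module exists for stimulus fixture generation, documentation and the
observer (localisation) experiment; the pRF analysis itself needs only the
binary apertures, which are identical across conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .sweep_design import SweepDesign, bar_geometry

__all__ = [
    "ConditionSpec",
    "DotField",
    "BarRegion",
    "condition_spec",
    "init_dots",
    "step_dots",
    "classify_bar_membership",
    "visible_dots",
    "export_frame",
]

_CONDITION_DEFAULTS = {
    # name: (speed deg/s, paired, bar dot diameter)
    "bar_only": (0.8, False, 0.09),
    "kinetic": (0.8, False, 0.09),
    "global": (0.8, False, 0.09),
    "transparent": (0.34, True, 0.09),
    "size_defined": (0.34, False, 0.10),
}


@dataclass(frozen=True)
class ConditionSpec:
    """Dot-kinematics parameters of one stimulus condition."""

    name: str
    n_dots: int = 2000
    dot_diameter: float = 0.09
    bar_dot_diameter: float = 0.09
    speed: float = 0.8
    reversal_period: float = 0.5
    paired: bool = False
    frame_rate: float = 60.0
    aperture_halfwidth: float = 8.0
    field_radius: float = 8.0
    fixation_mask_radius: float = 0.4

    def __post_init__(self) -> None:
        if self.name not in _CONDITION_DEFAULTS:
            raise ValidationError(f"unknown condition {self.name!r}")
        if self.speed < 0:
            raise ValidationError("speed must be >= 0")
        if self.reversal_period <= 0:
            raise ValidationError("reversal_period must be positive")
        if self.frame_rate <= 0:
            raise ValidationError("frame_rate must be positive")
        if self.paired and self.n_dots % 2:
            raise ValidationError("paired conditions need an even dot count")


def condition_spec(name: str, **overrides) -> ConditionSpec:
    """The named condition with its published defaults (overridable)."""
    if name not in _CONDITION_DEFAULTS:
        raise ValidationError(f"unknown condition {name!r}")
    speed, paired, bar_diam = _CONDITION_DEFAULTS[name]
    kwargs = dict(name=name, speed=speed, paired=paired, bar_dot_diameter=bar_diam)
    kwargs.update(overrides)
    return ConditionSpec(**kwargs)


@dataclass
class BarRegion:
    """The bar strip at one sweep step: travel direction, offset, width."""

    u: np.ndarray  # travel unit vector
    offset: float  # signed bar-centre position along u
    width: float  # bar width, degrees
    disc_radius: float = 8.0

    @classmethod
    def from_design(cls, design: SweepDesign, direction: float, step: int) -> "BarRegion":
        u, offset = bar_geometry(design, direction, step)
        return cls(u=u, offset=offset, width=design.bar_width,
                   disc_radius=design.field_halfwidth)

    def bar_axis(self) -> np.ndarray:
        """Unit vector along the bar's length (dots move along this)."""
        return np.array([-self.u[1], self.u[0]])

    def contains(self, positions: np.ndarray) -> np.ndarray:
        """Strict membership: |p.u - offset| < width/2 and inside the disc."""
        proj = positions @ self.u
        in_strip = np.abs(proj - self.offset) < self.width / 2.0
        in_disc = (positions**2).sum(axis=1) < self.disc_radius**2
        return in_strip & in_disc


@dataclass
class DotField:
    """State of the dot field at one instant."""

    positions: np.ndarray  # (n, 2) degrees
    headings: np.ndarray  # (n, 2) unit vectors (current direction of motion)
    polarity: np.ndarray  # (n,) "white" | "black"
    diameters: np.ndarray  # (n,) degrees
    pair_id: np.ndarray  # (n,) int; -1 when unpaired
    in_bar: np.ndarray  # (n,) bool
    phase: np.ndarray  # (n,) reversal-clock offset, seconds
    bg_axis: np.ndarray  # (n, 2) home oscillation axis (background rule)
    sheet_sign: np.ndarray  # (n,) +-1: direction taken along the bar axis when in the bar

    @property
    def n_dots(self) -> int:
        return self.positions.shape[0]


def _random_unit(rng: np.random.Generator, n: int) -> np.ndarray:
    ang = rng.uniform(0.0, 2.0 * np.pi, size=n)
    return np.column_stack([np.cos(ang), np.sin(ang)])


#: Initial pair separation; the periodic reversals then cap each member's
#: excursion about the pair midpoint at +-(speed * reversal_period / 2).
PAIR_SEPARATION = 0.2


def init_dots(spec: ConditionSpec, seed: int) -> DotField:
    """Random initial dot field: uniform positions, exact half/half polarity."""
    rng = np.random.default_rng(seed)
    n = spec.n_dots
    half = spec.aperture_halfwidth

    if spec.paired:
        n_pairs = n // 2
        mid = rng.uniform(-half, half, size=(n_pairs, 2))
        sep_dir = _random_unit(rng, n_pairs)
        positions = np.empty((n, 2))
        positions[0::2] = mid + sep_dir * PAIR_SEPARATION / 2.0
        positions[1::2] = mid - sep_dir * PAIR_SEPARATION / 2.0
        pair_id = np.repeat(np.arange(n_pairs), 2)
        # background rule: locally balanced -- members oscillate in antiphase
        pair_axis = _random_unit(rng, n_pairs)
        member_sign = np.tile([1.0, -1.0], n_pairs)
        bg_axis = np.repeat(pair_axis, 2, axis=0) * member_sign[:, None]
        # bar rule: two opposed coherent sheets, assigned per pair
        sheet_sign = np.repeat(np.where(rng.uniform(size=n_pairs) < 0.5, 1.0, -1.0), 2)
        phase = np.repeat(rng.uniform(0.0, spec.reversal_period, size=n_pairs), 2)
    else:
        positions = rng.uniform(-half, half, size=(n, 2))
        pair_id = np.full(n, -1, dtype=int)
        bg_axis = _random_unit(rng, n)  # used by the random-motion conditions
        sheet_sign = np.ones(n)
        phase = np.zeros(n)

    polarity = np.array(["white"] * (n // 2) + ["black"] * (n - n // 2))
    rng.shuffle(polarity)
    # positions are wrapped into the square, exactly as during stepping
    positions = _wrap(positions, half)
    return DotField(positions=positions, headings=bg_axis.copy(), polarity=polarity,
                    diameters=np.full(n, spec.dot_diameter), pair_id=pair_id,
                    in_bar=np.zeros(n, dtype=bool), phase=phase, bg_axis=bg_axis,
                    sheet_sign=sheet_sign)


def classify_bar_membership(field_: DotField, bar_region: BarRegion | None
                            ) -> np.ndarray:
    """Bar-membership flags; paired dots are classified by their pair midpoint."""
    if bar_region is None:
        return np.zeros(field_.n_dots, dtype=bool)
    if (field_.pair_id >= 0).any():
        paired = field_.pair_id >= 0
        member = np.zeros(field_.n_dots, dtype=bool)
        member[~paired] = bar_region.contains(field_.positions[~paired])
        if paired.any():
            order = np.argsort(field_.pair_id[paired], kind="stable")
            idx = np.where(paired)[0][order]
            mids = 0.5 * (field_.positions[idx[0::2]] + field_.positions[idx[1::2]])
            pair_member = bar_region.contains(mids)
            member[idx[0::2]] = pair_member
            member[idx[1::2]] = pair_member
        return member
    return bar_region.contains(field_.positions)


def _reversal_parity(t: float, phase: np.ndarray, period: float) -> np.ndarray:
    """+1 or -1 per dot: sign of the oscillation at time t."""
    k = np.floor((t + phase) / period).astype(int)
    return np.where(k % 2 == 0, 1.0, -1.0)


def _wrap(positions: np.ndarray, half: float) -> np.ndarray:
    """Dots crossing the square boundary move back one aperture width."""
    width = 2.0 * half
    out = positions.copy()
    out[out > half] -= width
    out[out < -half] += width
    return out


def step_dots(field_: DotField, spec: ConditionSpec,
              bar_region: BarRegion | None, t: float) -> DotField:
    """Advance the dot field by one frame (1/frame_rate s) starting at time t.

    Membership is re-evaluated first: dots inside the bar adopt the coherent
    bar direction (along the bar's length, reversing with the clock); dots
    outside follow the condition's background rule.
    """
    member = classify_bar_membership(field_, bar_region)
    parity = _reversal_parity(t, field_.phase, spec.reversal_period)

    axis = field_.bg_axis.copy()
    if bar_region is not None:
        bar_ax = bar_region.bar_axis()
        if spec.name in ("bar_only", "kinetic"):
            # coherent background axis tied to the bar: same for bar-only
            # (invisible anyway), opposite for kinetic
            sign = -1.0 if spec.name == "kinetic" else 1.0
            axis[~member] = sign * bar_ax
        if spec.name != "size_defined":
            axis[member] = bar_ax[None, :] * field_.sheet_sign[member, None]
    elif spec.name == "kinetic":
        # kinetic null trials: full-field coherent motion (no bar to oppose)
        axis[:] = np.array([0.0, 1.0])

    headings = axis * parity[:, None]
    positions = field_.positions + headings * (spec.speed / spec.frame_rate)
    positions = _wrap(positions, spec.aperture_halfwidth)

    diameters = np.where(member, spec.bar_dot_diameter, spec.dot_diameter) \
        if spec.name == "size_defined" else field_.diameters
    return replace(field_, positions=positions, headings=headings,
                   in_bar=member, diameters=np.asarray(diameters, dtype=float))


def visible_dots(field_: DotField, spec: ConditionSpec) -> np.ndarray:
    """Visibility flags after the circular and fixation masks.

    In ``bar_only`` only the bar dots are visible; in every other condition
    all dots inside the stimulus disc (and outside the fixation mask) are.
    """
    r2 = (field_.positions**2).sum(axis=1)
    in_disc = (r2 < spec.field_radius**2) & (r2 > spec.fixation_mask_radius**2)
    if spec.name == "bar_only":
        return field_.in_bar & in_disc
    return in_disc


def export_frame(field_: DotField, spec: ConditionSpec, path: str | Path | None = None
                 ) -> pd.DataFrame:
    """One frame as a tidy table (x, y, polarity, diameter, visible)."""
    df = pd.DataFrame({
        "x": field_.positions[:, 0], "y": field_.positions[:, 1],
        "polarity": field_.polarity, "diameter": field_.diameters,
        "in_bar": field_.in_bar, "visible": visible_dots(field_, spec),
    })
    if path is not None:
        df.to_csv(path, sep="\t", index=False)
    return df
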