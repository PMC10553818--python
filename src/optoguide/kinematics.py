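"""Trajectory kinematics: smoothing, heading series, outcome classification.

Cell-guidance assays reduce to questions about the *direction* of migration:
did the cell move ≥ 20 µm toward a stimulus, did it reverse between two
stimuli, how fast is it turning (rpm)?  All of these are computed from a
centroid trajectory via a common recipe: Savitzky–Golay smoothing of x and
y, per-step headings gated at 2 µm/min (sub-threshold steps inherit the last
confident heading), and 2π-unwrapping into a cumulative angle series.

Angles follow the mathematical convention: radians, counterclockwise
positive, 0 along +x.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
from scipy.signal import savgol_filter
from scipy.stats import linregress

from .errors import InvalidArgumentError, UndefinedHeadingError

__all__ = [
    "Track",
    "HeadingSeries",
    "wrap_angle",
    "smooth_track",
    "heading_series",
    "classify_two_spot",
    "detect_reversal",
    "angular_velocity",
    "alignment_cosine",
    "normalize_track_frame",
    "initial_heading",
]

SG_WINDOW = 9
SG_ORDER = 3
MIN_SPEED_UM_MIN = 2.0
ALIGN_TOL_RAD = 0.4
TWO_SPOT_THRESHOLD_UM = 20.0


@dataclass
class Track:
    """Per-cell centroid time series in physical units (µm, s)."""

    cell_id: str
    t_s: np.ndarray
    x_um: np.ndarray
    y_um: np.ndarray

    def __post_init__(self):
        self.t_s = np.asarray(self.t_s, dtype=float)
        self.x_um = np.asarray(self.x_um, dtype=float)
        self.y_um = np.asarray(self.y_um, dtype=float)
        if not (len(self.t_s) == len(self.x_um) == len(self.y_um)):
            raise InvalidArgumentError("t, x, y must have equal length")
        if np.any(np.diff(self.t_s) <= 0):
            raise InvalidArgumentError("timestamps must be strictly increasing")
        if not (np.all(np.isfinite(self.x_um)) and np.all(np.isfinite(self.y_um))):
            raise InvalidArgumentError("coordinates must be finite")

    def __len__(self) -> int:
        return len(self.t_s)

    @property
    def positions(self) -> np.ndarray:
        return np.column_stack([self.x_um, self.y_um])


@dataclass
class HeadingSeries:
    """Unwrapped (cumulative) heading per step, with confidence flags.

    ``angle_rad[i]`` is the direction of motion over the step ending at
    ``t_s[i]``; steps slower than the gate carry the last confident value
    and are flagged ``confident=False``.  Steps before the first confident
    measurement are flagged undefined (NaN) and excluded from downstream
    alignment logic.
    """

    t_s: np.ndarray
    angle_rad: np.ndarray  # unwrapped, may start with NaNs
    confident: np.ndarray  # bool per step
    n_confident: int = field(init=False)

    def __post_init__(self):
        self.t_s = np.asarray(self.t_s, dtype=float)
        self.angle_rad = np.asarray(self.angle_rad, dtype=float)
        self.confident = np.asarray(self.confident, dtype=bool)
        self.n_confident = int(self.confident.sum())


def wrap_angle(a):
    """Wrap angle(s) into (−π, π]."""
    a = np.asarray(a, dtype=float)
    out = -((-a + np.pi) % (2 * np.pi) - np.pi)
    return out if out.ndim else float(out)


def smooth_track(track: Track, window: int = SG_WINDOW, order: int = SG_ORDER) -> Track:
    """Savitzky–Golay smoothing of x and y independently.

    Endpoints use a same-order polynomial fit on the truncated one-sided
    windows (scipy's ``mode='interp'``), so an order-3 filter reproduces any
    cubic trajectory exactly, endpoints included.
    """
    if len(track) < window:
        raise InvalidArgumentError(
            f"track has {len(track)} samples; Savitzky–Golay window is {window}"
        )
    x = savgol_filter(track.x_um, window, order, mode="interp")
    y = savgol_filter(track.y_um, window, order, mode="interp")
    return replace(track, x_um=x, y_um=y)


def heading_series(track: Track, min_speed_um_min: float = MIN_SPEED_UM_MIN) -> HeadingSeries:
    """Per-step headings, speed-gated and unwrapped.

    Headings from steps with displacement below ``min_speed_um_min`` are
    unreliable; they inherit the last confidently measured heading.  The
    gated series is then unwrapped into a cumulative angle by adding or
    subtracting multiples of 2π so that no confident increment exceeds π in
    magnitude.
    """
    if len(track) < 2:
        raise InvalidArgumentError("need at least 2 samples for headings")
    dt = np.diff(track.t_s)
    dx = np.diff(track.x_um)
    dy = np.diff(track.y_um)
    speed_um_min = np.hypot(dx, dy) / dt * 60.0
    raw = np.arctan2(dy, dx)
    confident = speed_um_min >= min_speed_um_min

    angles = np.full(len(raw), np.nan)
    last = np.nan
    for i in range(len(raw)):
        if confident[i]:
            last = raw[i]
        angles[i] = last  # NaN until the first confident step

    defined = ~np.isnan(angles)
    unwrapped = angles.copy()
    if defined.any():
        unwrapped[defined] = np.unwrap(angles[defined])
    return HeadingSeries(t_s=track.t_s[1:], angle_rad=unwrapped, confident=confident)


def classify_two_spot(
    track: Track,
    stim_axes: Sequence[Sequence[float]],
    threshold_um: float = TWO_SPOT_THRESHOLD_UM,
    start_time_s: float = 0.0,
) -> Literal["frontward", "rearward", "nonresponder"]:
    """Classify a two-spot assay outcome by net displacement projection.

    ``stim_axes`` is ``(frontward, rearward)`` direction vectors.  The net
    displacement from ``start_time_s`` to the end of the track is projected
    onto each stimulus direction; the cell is labelled by whichever
    projection reaches ``threshold_um`` (larger projection wins when both
    do), else ``nonresponder``.
    """
    axes = np.asarray(stim_axes, dtype=float)
    if axes.shape != (2, 2):
        raise InvalidArgumentError("stim_axes must be two 2-vectors")
    norms = np.linalg.norm(axes, axis=1)
    if np.any(norms == 0):
        raise InvalidArgumentError("stimulus direction must be nonzero")
    units = axes / norms[:, None]
    i0 = int(np.searchsorted(track.t_s, start_time_s))
    i0 = min(i0, len(track) - 1)
    net = track.positions[-1] - track.positions[i0]
    proj = units @ net
    hit = proj >= threshold_um
    if hit[0] and hit[1]:  # both exceed: larger projection wins
        return "frontward" if proj[0] >= proj[1] else "rearward"
    if hit[0]:
        return "frontward"
    if hit[1]:
        return "rearward"
    return "nonresponder"


def detect_reversal(
    heading: HeadingSeries,
    stim_angles: Sequence[float],
    epochs: Sequence[tuple[float, float]],
    tol_rad: float = ALIGN_TOL_RAD,
) -> bool:
    """Flag a reverser: within one continuous stimulation epoch the heading
    is at some time within ``tol_rad`` of one stimulus *and* at some time
    within ``tol_rad`` of the other.

    Alignment is judged on the wrapped angular distance (either direction
    around the circle).  Epochs must not overlap; a dwell at stimulus A in
    one epoch and at B in another does not count.
    """
    if len(stim_angles) != 2:
        raise InvalidArgumentError("exactly two stimulus angles expected")
    eps = sorted((float(a), float(b)) for a, b in epochs)
    for (a0, b0), (a1, _) in zip(eps, eps[1:]):
        if a1 < b0:
            raise InvalidArgumentError("epochs overlap")
    defined = ~np.isnan(heading.angle_rad)
    for t0, t1 in eps:
        sel = defined & (heading.t_s >= t0) & (heading.t_s <= t1)
        if not sel.any():
            continue
        ang = heading.angle_rad[sel]
        aligned = [
            np.abs(wrap_angle(ang - sa)) <= tol_rad for sa in stim_angles
        ]
        if aligned[0].any() and aligned[1].any():
            return True
    return False


def angular_velocity(heading: HeadingSeries, window: tuple[float, float]) -> float:
    """Angular velocity in revolutions per minute over a time window.

    A line is fit to the unwrapped angle versus time; the slope (rad/s) is
    converted to rpm.  Counterclockwise is positive.
    """
    t0, t1 = window
    sel = (
        (heading.t_s >= t0)
        & (heading.t_s <= t1)
        & ~np.isnan(heading.angle_rad)
        & heading.confident
    )
    if sel.sum() < 3:
        raise InvalidArgumentError(
            f"need >= 3 confident points in window [{t0}, {t1}], got {int(sel.sum())}"
        )
    slope = linregress(heading.t_s[sel], heading.angle_rad[sel]).slope
    return slope * 60.0 / (2 * np.pi)


def alignment_cosine(heading: HeadingSeries, stim_angle_rad: float) -> np.ndarray:
    """cos(heading − stimulus angle) per step; NaN where heading undefined."""
    return np.cos(heading.angle_rad - stim_angle_rad)


def initial_heading(track: Track, window_s: float = 60.0) -> float:
    """Direction of the net displacement over the first ``window_s``."""
    sel = track.t_s <= track.t_s[0] + window_s
    if sel.sum() < 2:
        raise InvalidArgumentError("not enough samples in the initial window")
    i1 = int(np.nonzero(sel)[0][-1])
    dx = track.x_um[i1] - track.x_um[0]
    dy = track.y_um[i1] - track.y_um[0]
    if dx == 0 and dy == 0:
        raise UndefinedHeadingError("zero displacement in the initial window")
    return float(np.arctan2(dy, dx))


def normalize_track_frame(track: Track, window_s: float = 60.0) -> Track:
    """Rotate and translate a track into the assay's standard frame.

    The position at the end of the initial window maps to the origin and
    the initial-window displacement maps to +y, so cohorts of tracks can be
    overlaid with "initial direction up".
    """
    if track.t_s[-1] - track.t_s[0] < window_s:
        raise InvalidArgumentError(f"track must span at least {window_s} s")
    theta = initial_heading(track, window_s)
    sel = track.t_s <= track.t_s[0] + window_s
    i1 = int(np.nonzero(sel)[0][-1])
    # rotate heading -> +y (i.e. by pi/2 - theta), then translate mark -> origin
    rot = np.pi / 2 - theta
    c, s = np.cos(rot), np.sin(rot)
    x = track.x_um - track.x_um[i1]
    y = track.y_um - track.y_um[i1]
    return replace(track, x_um=c * x - s * y, y_um=s * x + c * y)
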