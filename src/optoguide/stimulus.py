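"""Controller-side stimulus geometry: protocols, qualification, spot placement.

The automated guidance pipeline scans for candidate objects, verifies for
30 s that a candidate moves like a migrating cell, then runs a phased
stimulation protocol.  Each protocol phase is either dark, a global
illumination of the cell footprint, or a set of edge spots whose angles are
given relative to the cell's heading or in the lab frame.  At every control
step the spot is re-centered on the boundary point of the current mask at
the requested bearing from the centroid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import yaml
from scipy import ndimage
from skimage import morphology

from .errors import InvalidArgumentError, UndefinedHeadingError
from .image_prep import pixel_angles
from .kinematics import wrap_angle

__all__ = [
    "SpotSpec",
    "ProtocolPhase",
    "StimulusProtocol",
    "StimulusMask",
    "qualify_candidate",
    "place_stimulus",
    "schedule_protocol",
    "load_protocol",
]

DEFAULT_SPOT_RADIUS_UM = 5.0


@dataclass
class SpotSpec:
    """One edge-centered stimulation spot."""

    angle_deg: float
    frame: Literal["heading", "lab"] = "heading"
    radius_um: float = DEFAULT_SPOT_RADIUS_UM
    intensity: float = 1.0

    def __post_init__(self):
        if not -180.0 < self.angle_deg <= 180.0:
            raise InvalidArgumentError("spot angle must lie in (−180, 180]")
        if self.radius_um <= 0:
            raise InvalidArgumentError("spot radius must be positive")


@dataclass
class ProtocolPhase:
    duration_s: float
    pattern: Literal["none", "global", "spots"]
    spots: list[SpotSpec] = field(default_factory=list)
    intensity: float = 1.0

    def __post_init__(self):
        if self.duration_s <= 0:
            raise InvalidArgumentError("phase duration must be positive")
        if self.pattern == "spots" and not self.spots:
            raise InvalidArgumentError("spots pattern requires at least one spot")


@dataclass
class StimulusProtocol:
    """Ordered stimulation phases; time 0 is the start of phase 1."""

    phases: list[ProtocolPhase]

    @property
    def total_duration_s(self) -> float:
        return sum(p.duration_s for p in self.phases)

    def phase_boundaries_s(self) -> np.ndarray:
        return np.concatenate([[0.0], np.cumsum([p.duration_s for p in self.phases])])


@dataclass
class StimulusMask:
    """A realized stimulation pattern for one control step, with provenance."""

    mask: np.ndarray
    phase_index: int | None = None
    spot: SpotSpec | None = None
    centroid_px: tuple[float, float] | None = None
    heading_rad: float | None = None
    nearest_boundary_fallback: bool = False


def qualify_candidate(
    area_px: float,
    mean_intensity: float,
    speed_um_min: float,
    area_range_px: tuple[float, float] = (200.0, 5000.0),
    intensity_range: tuple[float, float] = (50.0, 1e6),
    speed_range_um_min: tuple[float, float] = (3.0, 30.0),
) -> dict:
    """Accept a candidate object iff its size, intensity and 30-s motility
    speed all fall within the configured gates.  Returns the decision and
    each gate's evaluation for logging."""
    gates = {
        "area_px": (area_px, area_range_px),
        "mean_intensity": (mean_intensity, intensity_range),
        "speed_um_min": (speed_um_min, speed_range_um_min),
    }
    results = {
        name: bool(lo <= value <= hi) for name, (value, (lo, hi)) in gates.items()
    }
    return {
        "accept": all(results.values()),
        "gates": results,
        "values": {name: value for name, (value, _) in gates.items()},
    }


def _boundary_points(mask: np.ndarray) -> np.ndarray:
    boundary = mask & ~ndimage.binary_erosion(mask)
    return np.column_stack(np.nonzero(boundary))  # (N, 2) rows, cols


def place_stimulus(
    cell_mask: np.ndarray,
    spot: SpotSpec | Literal["global"],
    heading_rad: float | None = None,
    pixel_size_um: float = 1.0,
    global_margin_px: int = 3,
) -> StimulusMask:
    """Realize a stimulus pattern on the current cell mask.

    A spot is centered on the boundary point of the mask whose bearing from
    the centroid is closest to the requested angle (heading-frame angles
    are offset by the current heading); for star-convex masks that bearing
    always exists, otherwise the nearest boundary point is used and
    flagged.  ``"global"`` returns the footprint dilated by a margin.
    """
    cell_mask = np.asarray(cell_mask, dtype=bool)
    if not cell_mask.any():
        raise InvalidArgumentError("empty cell mask")
    rows, cols = np.nonzero(cell_mask)
    centroid = (float(rows.mean()), float(cols.mean()))

    if spot == "global":
        dilated = ndimage.binary_dilation(
            cell_mask, structure=morphology.disk(global_margin_px)
        )
        return StimulusMask(mask=dilated, centroid_px=centroid, heading_rad=heading_rad)

    if spot.frame == "heading":
        if heading_rad is None:
            raise UndefinedHeadingError("heading-frame spot before heading is defined")
        target = heading_rad + np.radians(spot.angle_deg)
    else:
        target = np.radians(spot.angle_deg)

    pts = _boundary_points(cell_mask)
    angles = pixel_angles(cell_mask.shape, centroid)[pts[:, 0], pts[:, 1]]
    diff = np.abs(wrap_angle(angles - target))
    best = int(np.argmin(diff))
    # > half a pixel of angular slack at the boundary radius means the ray
    # truly misses the boundary (non-star-convex mask)
    radius = np.hypot(pts[best, 0] - centroid[0], pts[best, 1] - centroid[1])
    fallback = bool(diff[best] > 2.0 / max(radius, 1.0))
    center = pts[best]

    radius_px = max(1, int(round(spot.radius_um / pixel_size_um)))
    rr, cc = np.mgrid[0 : cell_mask.shape[0], 0 : cell_mask.shape[1]]
    mask = (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius_px**2
    return StimulusMask(
        mask=mask, spot=spot, centroid_px=centroid, heading_rad=heading_rad,
        nearest_boundary_fallback=fallback,
    )


def schedule_protocol(protocol: StimulusProtocol, t_s: float) -> tuple[int, ProtocolPhase]:
    """Active phase at time ``t_s``; phase boundaries are half-open
    [start, end), so a time exactly on a boundary belongs to the next phase."""
    if not protocol.phases:
        raise InvalidArgumentError("empty protocol")
    edges = protocol.phase_boundaries_s()
    if not 0.0 <= t_s < edges[-1]:
        raise InvalidArgumentError(
            f"t={t_s} outside protocol span [0, {edges[-1]})"
        )
    idx = int(np.searchsorted(edges, t_s, side="right") - 1)
    return idx, protocol.phases[idx]


def load_protocol(source) -> StimulusProtocol:
    """Load a :class:`StimulusProtocol` from a YAML file path or string."""
    import os

    if hasattr(source, "read"):
        data = yaml.safe_load(source)
    elif isinstance(source, (str, os.PathLike)) and os.path.exists(source):
        with open(source) as fh:
            data = yaml.safe_load(fh)
    else:
        data = yaml.safe_load(str(source))
    phases = []
    for ph in data["phases"]:
        spots = [SpotSpec(**s) for s in ph.get("spots", [])]
        phases.append(
            ProtocolPhase(
                duration_s=float(ph["duration_s"]),
                pattern=ph["pattern"],
                spots=spots,
                intensity=float(ph.get("intensity", 1.0)),
            )
        )
    return StimulusProtocol(phases=phases)
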