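"""Peripheral biosensor quantification: ring masks, angular profiles, kymographs.

A migrating cell signals at its edge.  To quantify a biosensor around the
periphery, the segmentation mask is contracted by a fixed number of pixels
(default 14 px = 3.0 µm at the default scale) and the remaining center is
subtracted, leaving a ring.  Ring-pixel intensities are binned by their
angle to the centroid (minus a reference angle, normally the cell's initial
heading), giving a 1-D angular profile per frame; profiles stacked over time
form an angular kymograph.  Kymographs from many cells are averaged, after
optionally reflecting each cell so that its "winning side" is positive.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage import morphology

from .errors import InvalidArgumentError, ThinCellError
from .image_prep import pixel_angles
from .kinematics import Track, initial_heading

__all__ = [
    "AngularProfile",
    "AngularKymograph",
    "ring_mask",
    "angular_profile",
    "build_kymograph",
    "average_kymographs",
    "align_winning_side",
    "fold_change_profile",
]

RING_CONTRACTION_PX = 14
DEFAULT_N_BINS = 72


def bin_edges_deg(n_bins: int) -> np.ndarray:
    """Uniform bin edges covering (−180°, 180°]."""
    return np.linspace(-180.0, 180.0, n_bins + 1)


@dataclass
class AngularProfile:
    """Mean peripheral intensity per angular bin for one frame.

    Empty bins (possible for concave masks) hold NaN and zero occupancy;
    they are excluded from averages rather than zero-filled.
    """

    bin_centers_deg: np.ndarray
    mean_intensity: np.ndarray  # NaN where occupancy == 0
    occupancy: np.ndarray  # pixel count per bin

    def __post_init__(self):
        self.bin_centers_deg = np.asarray(self.bin_centers_deg, dtype=float)
        self.mean_intensity = np.asarray(self.mean_intensity, dtype=float)
        self.occupancy = np.asarray(self.occupancy, dtype=int)
        widths = np.diff(self.bin_centers_deg)
        if widths.size and not np.allclose(widths, widths[0]):
            raise InvalidArgumentError("bins must be uniform")

    @property
    def n_bins(self) -> int:
        return len(self.bin_centers_deg)


@dataclass
class AngularKymograph:
    """Time × angular-bin matrix of peripheral intensity.

    ``values[i, j]`` is the mean intensity in bin ``j`` at ``timestamps_s[i]``,
    referenced to the cell's initial heading (bin 0° = initial front).
    """

    timestamps_s: np.ndarray
    bin_centers_deg: np.ndarray
    values: np.ndarray  # (T, n_bins), NaN for empty bins

    def __post_init__(self):
        self.timestamps_s = np.asarray(self.timestamps_s, dtype=float)
        self.bin_centers_deg = np.asarray(self.bin_centers_deg, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.timestamps_s), len(self.bin_centers_deg)):
            raise InvalidArgumentError("values shape must be (n_times, n_bins)")


def ring_mask(cell_mask: np.ndarray, contraction_px: int = RING_CONTRACTION_PX) -> np.ndarray:
    """Peripheral ring: the mask minus its erosion by ``contraction_px``.

    At the default pixel scale (3.0/14 µm/px) the 14-px contraction gives a
    ring 3.0 µm wide.  Raises :class:`ThinCellError` when erosion empties
    the mask (the cell is too thin for the requested ring width).
    """
    cell_mask = np.asarray(cell_mask, dtype=bool)
    if not cell_mask.any():
        raise InvalidArgumentError("empty cell mask")
    eroded = ndimage.binary_erosion(
        cell_mask, structure=morphology.disk(contraction_px)
    )
    if not eroded.any():
        raise ThinCellError(
            f"erosion by {contraction_px} px empties the mask; cell too thin"
        )
    return cell_mask & ~eroded


def angular_profile(
    corrected_frame: np.ndarray,
    ring: np.ndarray,
    centroid_px: tuple[float, float],
    reference_angle_rad: float = 0.0,
    n_bins: int = DEFAULT_N_BINS,
) -> AngularProfile:
    """Bin ring-pixel intensities by centroid angle relative to a reference.

    The reference (normally the initial heading) is subtracted so that bin
    0° is the cell's initial front.
    """
    if n_bins < 8:
        raise InvalidArgumentError("n_bins must be >= 8")
    ring = np.asarray(ring, dtype=bool)
    if not ring.any():
        raise InvalidArgumentError("empty ring mask")
    shape = ring.shape
    if not (0 <= centroid_px[0] < shape[0] and 0 <= centroid_px[1] < shape[1]):
        raise InvalidArgumentError("centroid outside frame")
    angles = pixel_angles(shape, centroid_px)[ring] - reference_angle_rad
    rel_deg = np.degrees(angles)
    rel_deg = -((-rel_deg + 180.0) % 360.0 - 180.0)  # wrap into (−180, 180]
    vals = np.asarray(corrected_frame, dtype=float)[ring]

    edges = bin_edges_deg(n_bins)
    # right-closed bins so 180 lands in the last bin
    idx = np.clip(np.searchsorted(edges, rel_deg, side="left") - 1, 0, n_bins - 1)
    occupancy = np.bincount(idx, minlength=n_bins)
    sums = np.bincount(idx, weights=vals, minlength=n_bins)
    with np.errstate(invalid="ignore"):
        means = np.where(occupancy > 0, sums / np.maximum(occupancy, 1), np.nan)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return AngularProfile(bin_centers_deg=centers, mean_intensity=means, occupancy=occupancy)


def build_kymograph(
    profiles: Sequence[AngularProfile], timestamps_s: Sequence[float]
) -> AngularKymograph:
    """Stack per-frame angular profiles into a time × bin kymograph."""
    if len(profiles) != len(timestamps_s):
        raise InvalidArgumentError("one profile per timestamp required")
    if not profiles:
        raise InvalidArgumentError("no profiles")
    centers = profiles[0].bin_centers_deg
    for p in profiles[1:]:
        if not np.array_equal(p.bin_centers_deg, centers):
            raise InvalidArgumentError("profiles must share binning")
    values = np.vstack([p.mean_intensity for p in profiles])
    return AngularKymograph(
        timestamps_s=np.asarray(timestamps_s, dtype=float),
        bin_centers_deg=centers,
        values=values,
    )


def average_kymographs(kymographs: Sequence[AngularKymograph]) -> AngularKymograph:
    """Unweighted per-(time, bin) mean across cells.

    Cells on different time grids are linearly interpolated onto the first
    kymograph's grid (no extrapolation: times outside a cell's span stay
    missing).  Missing bins propagate as missing only where no cell has
    data.
    """
    if not kymographs:
        raise InvalidArgumentError("no kymographs")
    ref = kymographs[0]
    for k in kymographs[1:]:
        if not np.array_equal(k.bin_centers_deg, ref.bin_centers_deg):
            raise InvalidArgumentError("kymographs must share binning")
    t = ref.timestamps_s
    stack = []
    for k in kymographs:
        if np.array_equal(k.timestamps_s, t):
            stack.append(k.values)
            continue
        resampled = np.full((len(t), len(ref.bin_centers_deg)), np.nan)
        inside = (t >= k.timestamps_s[0]) & (t <= k.timestamps_s[-1])
        for j in range(k.values.shape[1]):
            col = k.values[:, j]
            ok = ~np.isnan(col)
            if ok.sum() >= 2:
                resampled[inside, j] = np.interp(
                    t[inside], k.timestamps_s[ok], col[ok]
                )
        stack.append(resampled)
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(np.stack(stack), axis=0)
    return AngularKymograph(timestamps_s=t, bin_centers_deg=ref.bin_centers_deg, values=mean)


def reflect_kymograph(kym: AngularKymograph) -> AngularKymograph:
    """Map bin at +θ to −θ (mirror about the 0° axis)."""
    return replace(kym, values=kym.values[:, ::-1].copy())


def align_winning_side(kym: AngularKymograph, track: Track) -> AngularKymograph:
    """Reflect a single-cell kymograph when the cell's final x position, in
    the frame where the initial heading points +y, is negative.

    After alignment the "winning" (final-turn) side of every cell lies at
    positive angles, so cohort averages do not cancel left- and
    right-turners.
    """
    if track.t_s[0] > kym.timestamps_s[0] or track.t_s[-1] < kym.timestamps_s[-1]:
        raise InvalidArgumentError("track must cover the kymograph time span")
    theta = initial_heading(track)
    # rotate so initial heading -> +y, then check final x
    rot = np.pi / 2 - theta
    xf = track.x_um[-1] - track.x_um[0]
    yf = track.y_um[-1] - track.y_um[0]
    final_x = np.cos(rot) * xf - np.sin(rot) * yf
    if final_x < 0:
        return reflect_kymograph(kym)
    return kym


def fold_change_profile(
    kym: AngularKymograph, stim_time_s: float, window_s: float = 60.0
) -> np.ndarray:
    """Per-bin ratio of the post-stimulus window mean to the pre-stimulus
    window mean.  Bins whose pre-stimulus mean is ≤ 0 (or empty) are NaN,
    never infinite.
    """
    t = kym.timestamps_s
    pre = (t >= stim_time_s - window_s) & (t < stim_time_s)
    post = (t >= stim_time_s) & (t < stim_time_s + window_s)
    if not pre.any() or not post.any():
        raise InvalidArgumentError(
            f"need data within {window_s} s on both sides of stim_time"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        pre_mean = np.nanmean(kym.values[pre], axis=0)
        post_mean = np.nanmean(kym.values[post], axis=0)
        ratio = np.where(pre_mean > 0, post_mean / np.where(pre_mean > 0, pre_mean, 1), np.nan)
    return ratio
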