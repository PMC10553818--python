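"""Segmentation, background-model fitting and subtraction, and intensity QC.

TIRF frames carry a smooth illumination background (well modelled by a plane
on cropped fields or a full 2-D quadratic on full-size frames) on top of
which the cell footprint sits.  The pipeline segments the cell from the
PIP3-biosensor channel, fits the background model to non-cell pixels, and
subtracts it per pixel before any intensity quantification.  Cells whose
background-subtracted baseline is too dim for reliable normalization are
excluded.

Coordinate conventions
----------------------
Pixel arrays are indexed ``[row, col]`` with the origin at the top-left.
``x`` increases with column and ``y`` increases *downward* with row in pixel
space.  All angular quantities use the mathematical convention
(counterclockwise positive, ``+x`` = 0), obtained by flipping the pixel
``y`` axis; :func:`pixel_angles` is the single source of that conversion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import ndimage
from skimage import filters, measure, morphology

from .errors import DegenerateFitError, InvalidArgumentError

BackgroundKind = Literal["plane", "quadratic"]

__all__ = [
    "Movie",
    "BackgroundModel",
    "CellMask",
    "pixel_angles",
    "segment_cell",
    "fit_background",
    "subtract_background",
    "baseline_qc",
    "make_background_mask",
]


@dataclass
class Movie:
    """Time-ordered multi-channel 2-D intensity grids.

    Parameters
    ----------
    frames : dict[str, np.ndarray]
        One ``(T, H, W)`` float array per named channel.
    pixel_size_um : float
        Physical size of one pixel, µm.
    timestamps_s : np.ndarray
        Frame acquisition times in seconds, strictly increasing.
    """

    frames: dict[str, np.ndarray]
    pixel_size_um: float
    timestamps_s: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.timestamps_s = np.asarray(self.timestamps_s, dtype=float)
        if self.pixel_size_um <= 0:
            raise InvalidArgumentError("pixel_size_um must be > 0")
        if np.any(np.diff(self.timestamps_s) <= 0):
            raise InvalidArgumentError("timestamps must be strictly increasing")
        shapes = {ch: arr.shape for ch, arr in self.frames.items()}
        ref = next(iter(shapes.values()), None)
        for ch, shp in shapes.items():
            if shp != ref:
                raise InvalidArgumentError(f"channel {ch!r} shape {shp} != {ref}")
            if shp[0] != len(self.timestamps_s):
                raise InvalidArgumentError(
                    f"channel {ch!r} has {shp[0]} frames but {len(self.timestamps_s)} timestamps"
                )

    @property
    def n_frames(self) -> int:
        return len(self.timestamps_s)

    @property
    def shape(self) -> tuple[int, int]:
        arr = next(iter(self.frames.values()))
        return arr.shape[1:]

    def channel(self, name: str) -> np.ndarray:
        return self.frames[name]


@dataclass
class BackgroundModel:
    """Smooth background model: plane ``z = a·x + b·y + c`` or quadratic
    ``z = a·x² + b·y² + c·x·y + d·x + e·y + f`` over pixel coordinates.

    The two families reuse the letters a, b, c with different roles; mapping
    between them is by monomial, with the plane's (a, b, c) corresponding to
    the quadratic's (d, e, f).
    """

    kind: BackgroundKind
    coefficients: np.ndarray  # (3,) for plane, (6,) for quadratic

    N_COEF = {"plane": 3, "quadratic": 6}

    def __post_init__(self):
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        expect = self.N_COEF.get(self.kind)
        if expect is None:
            raise InvalidArgumentError(f"unknown background kind {self.kind!r}")
        if self.coefficients.shape != (expect,):
            raise InvalidArgumentError(
                f"{self.kind} background needs {expect} coefficients, got {self.coefficients.shape}"
            )

    def evaluate(self, shape: tuple[int, int]) -> np.ndarray:
        """Evaluate the model on every pixel of a ``(H, W)`` grid."""
        rows, cols = np.mgrid[0 : shape[0], 0 : shape[1]]
        x = cols.astype(float)
        y = rows.astype(float)
        return self.evaluate_at(x, y)

    def evaluate_at(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        c = self.coefficients
        if self.kind == "plane":
            return c[0] * x + c[1] * y + c[2]
        return c[0] * x**2 + c[1] * y**2 + c[2] * x * y + c[3] * x + c[4] * y + c[5]


@dataclass
class CellMask:
    """A single cell's segmentation on one frame."""

    mask: np.ndarray  # boolean (H, W)
    frame_index: int
    centroid_px: tuple[float, float]  # (row, col)
    area_px: int
    pixel_size_um: float = 1.0

    @property
    def centroid_um(self) -> tuple[float, float]:
        r, c = self.centroid_px
        return (r * self.pixel_size_um, c * self.pixel_size_um)


def pixel_angles(shape: tuple[int, int], centroid_px: tuple[float, float]) -> np.ndarray:
    """Angle of every pixel as seen from ``centroid_px`` (row, col).

    Returns angles in radians in (−π, π], counterclockwise positive with 0
    along +x (rightward); image "up" is +90° because the pixel y axis is
    flipped to the mathematical convention.
    """
    rows, cols = np.mgrid[0 : shape[0], 0 : shape[1]]
    dy = centroid_px[0] - rows  # flip: up is positive
    dx = cols - centroid_px[1]
    return np.arctan2(dy, dx)


def segment_cell(
    frame: np.ndarray,
    *,
    blur_sigma_px: float = 2.0,
    min_area_px: int = 200,
    frame_index: int = 0,
    pixel_size_um: float = 1.0,
) -> CellMask | None:
    """Segment the brightest cell from a biosensor-channel frame.

    Otsu threshold on a lightly blurred frame, then the largest connected
    component with holes filled.  Returns ``None`` (a no-cell signal, not an
    exception) when the frame is constant or no component passes the
    ``min_area_px`` gate.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.size == 0:
        raise InvalidArgumentError("empty frame")
    blurred = filters.gaussian(frame, sigma=blur_sigma_px, preserve_range=True)
    if np.ptp(blurred) == 0:
        return None
    thresh = filters.threshold_otsu(blurred)
    fg = blurred > thresh
    labels = measure.label(fg)
    if labels.max() == 0:
        return None
    areas = np.bincount(labels.ravel())[1:]
    best = int(np.argmax(areas)) + 1  # ties: lowest label (top-most component)
    if areas[best - 1] < min_area_px:
        return None
    mask = ndimage.binary_fill_holes(labels == best)
    rows, cols = np.nonzero(mask)
    centroid = (float(rows.mean()), float(cols.mean()))
    return CellMask(
        mask=mask,
        frame_index=frame_index,
        centroid_px=centroid,
        area_px=int(mask.sum()),
        pixel_size_um=pixel_size_um,
    )


def _design_matrix(x: np.ndarray, y: np.ndarray, kind: BackgroundKind) -> np.ndarray:
    if kind == "plane":
        return np.column_stack([x, y, np.ones_like(x)])
    if kind == "quadratic":
        return np.column_stack([x**2, y**2, x * y, x, y, np.ones_like(x)])
    raise InvalidArgumentError(f"unknown background kind {kind!r}")


def fit_background(
    frame: np.ndarray, background_mask: np.ndarray, kind: BackgroundKind = "plane"
) -> BackgroundModel:
    """Least-squares fit of the background model to non-cell pixels.

    Raises :class:`DegenerateFitError` when the design matrix is
    rank-deficient (e.g. all background pixels collinear for a quadratic).
    """
    frame = np.asarray(frame, dtype=float)
    background_mask = np.asarray(background_mask, dtype=bool)
    n_coef = BackgroundModel.N_COEF[kind]
    rows, cols = np.nonzero(background_mask)
    if rows.size < n_coef:
        raise InvalidArgumentError(
            f"background mask has {rows.size} pixels; need >= {n_coef} for {kind}"
        )
    X = _design_matrix(cols.astype(float), rows.astype(float), kind)
    z = frame[rows, cols]
    coef, _, rank, _ = np.linalg.lstsq(X, z, rcond=None)
    if rank < n_coef:
        raise DegenerateFitError(
            f"rank-deficient {kind} background fit (rank {rank} < {n_coef})"
        )
    return BackgroundModel(kind=kind, coefficients=coef)


def subtract_background(frame: np.ndarray, model: BackgroundModel) -> np.ndarray:
    """Per-pixel subtraction of an evaluated background model."""
    frame = np.asarray(frame, dtype=float)
    return frame - model.evaluate(frame.shape)


def baseline_qc(
    mean_trace: Sequence[float],
    timestamps_s: Sequence[float],
    stim_time_s: float,
    threshold_units: float = 100.0,
) -> bool:
    """Return ``True`` (include) unless the pre-stimulus mean intensity is
    strictly below ``threshold_units``.

    Cells with a dim background-subtracted baseline make baseline
    normalization a division by a small, noisy number; they are dropped.
    The threshold defaults to 100 units and is meaningful in [100, 200].
    """
    trace = np.asarray(mean_trace, dtype=float)
    t = np.asarray(timestamps_s, dtype=float)
    pre = trace[t < stim_time_s]
    if pre.size == 0:
        raise InvalidArgumentError("empty pre-stimulus window")
    return not (pre.mean() < threshold_units)


def make_background_mask(
    frame_shape: tuple[int, int],
    cell_masks: Sequence[np.ndarray],
    guard_band_px: int = 10,
    min_coverage: float = 0.20,
) -> np.ndarray:
    """Pixels usable for background fitting: everything outside every cell
    mask dilated by ``guard_band_px``.

    Raises when less than ``min_coverage`` of the frame survives.
    """
    bg = np.ones(frame_shape, dtype=bool)
    if cell_masks:
        footprint = morphology.disk(guard_band_px)
        for m in cell_masks:
            m = np.asarray(m, dtype=bool)
            if m.shape != tuple(frame_shape):
                raise InvalidArgumentError("cell mask shape does not match frame")
            bg &= ~ndimage.binary_dilation(m, structure=footprint)
    if bg.mean() < min_coverage:
        raise InvalidArgumentError(
            f"background covers {bg.mean():.1%} of frame; need >= {min_coverage:.0%}"
        )
    return bg
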