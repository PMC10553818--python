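"""Synthetic microscope: movies, trajectories and virtual guidance assays
with planted ground truth.

Every downstream stage of the pipeline (segmentation, background fitting,
peripheral kymographs, kinematics, kinetics, statistics) is exercised on
data from this module, which returns the planted quantities — masks,
background coefficients, heading series, kinetic parameters — alongside the
rendered data so recovery can be asserted exactly.

Three generators:

* :func:`make_trajectory` — centroid tracks for persistent, turning
  (fixed rpm), u-turning, reversing and stationary cells.
* :func:`make_cell_movie` — a moving bright disk with an optionally
  polarized (von Mises-shaped) peripheral signal on a sloped or curved
  background plus Gaussian read noise.
* :func:`simulate_adaptive_response` — an invented incoherent feed-forward
  /negative-feedback ODE producing transient (adaptive) responses to step
  inputs and attenuated responses to slow ramps; the feedback strength dial
  moves the response continuously from transient to sustained.  This is
  synthetic ground truth only, not a fitted model of any real signaling
  circuit.

:func:`run_virtual_assay` closes the loop: a behavioral cell model whose
heading turns toward membrane sectors experiencing a local *rate of
increase* of input (with an insensitive rear sector and a saturated front
sector) is driven by the stimulus-placement controller, reproducing
winner-take-all side choice, front/back persistence and the
local-to-global turning reversal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .errors import InvalidArgumentError, OutOfFieldError, UndefinedHeadingError
from .image_prep import BackgroundModel, Movie
from .kinematics import Track, wrap_angle
from .stimulus import ProtocolPhase, SpotSpec, StimulusProtocol, schedule_protocol

__all__ = [
    "SyntheticCellSpec",
    "BackgroundSpec",
    "AdaptiveResponseSpec",
    "GuidanceCellModel",
    "ControllerRules",
    "MovieGroundTruth",
    "VirtualAssayResult",
    "DEFAULT_PIXEL_SIZE_UM",
    "DEFAULT_FRAME_DT_S",
    "make_trajectory",
    "make_cell_movie",
    "simulate_adaptive_response",
    "run_virtual_assay",
]

# 14 px of mask contraction correspond to 3.0 µm at this scale
DEFAULT_PIXEL_SIZE_UM = 3.0 / 14.0
DEFAULT_FRAME_DT_S = 5.0

CellMode = Literal["persistent", "turn", "u_turn", "reverser", "stationary"]


@dataclass
class SyntheticCellSpec:
    """Kinematic and photometric description of one synthetic cell."""

    radius_um: float = 8.0
    speed_um_min: float = 10.0
    mode: CellMode = "persistent"
    turn_rpm: float = 0.0
    peak_intensity: float = 500.0
    polarity_kappa: float = 0.0
    heading0_rad: float = 0.0
    switch_time_s: float | None = None  # reverser: time of the 180° switch
    u_turn_duration_s: float = 60.0  # u_turn: time spent rotating by π

    def __post_init__(self):
        if self.radius_um <= 0:
            raise InvalidArgumentError("radius_um must be > 0")
        if self.speed_um_min < 0:
            raise InvalidArgumentError("speed_um_min must be >= 0")
        if self.peak_intensity <= 0:
            raise InvalidArgumentError("peak_intensity must be > 0")
        if self.polarity_kappa < 0:
            raise InvalidArgumentError("polarity_kappa must be >= 0")


@dataclass
class BackgroundSpec:
    """Planted illumination background: plane (a, b, c) or quadratic
    (a, b, c, d, e, f), plus Gaussian read noise."""

    kind: Literal["plane", "quadratic"] = "plane"
    coefficients: Sequence[float] = (0.0, 0.0, 10.0)
    noise_sd: float = 0.0

    def __post_init__(self):
        n = BackgroundModel.N_COEF[self.kind]
        if len(self.coefficients) != n:
            raise InvalidArgumentError(
                f"{self.kind} background needs {n} coefficients"
            )
        if self.noise_sd < 0:
            raise InvalidArgumentError("noise_sd must be >= 0")

    def model(self) -> BackgroundModel:
        return BackgroundModel(kind=self.kind, coefficients=np.asarray(self.coefficients))


@dataclass
class AdaptiveResponseSpec:
    """Parameters of the invented adaptive response circuit.

    The response R integrates the input P and is degraded by an inhibitor I
    that is itself produced by R — activity-dependent negative feedback:

        dR/dt = gain_activation · P − inhibitor_decay · feedback_strength · I · R
        dI/dt = gain_feedback · R − inhibitor_decay · I

    ``feedback_strength`` = 1 is the intact circuit (transient, adaptive
    step response); 0 removes the feedback entirely (sustained, monotone
    response), emulating titration of a feedback inhibitor.  Defaults give
    a step-response peak-to-plateau ratio of about 2–3.
    """

    gain_activation: float = 0.5
    gain_feedback: float = 0.05
    inhibitor_decay: float = 0.01
    feedback_strength: float = 1.0

    def __post_init__(self):
        for name in ("gain_activation", "gain_feedback", "inhibitor_decay"):
            if getattr(self, name) < 0:
                raise InvalidArgumentError(f"{name} must be >= 0")
        if not 0.0 <= self.feedback_strength <= 1.0:
            raise InvalidArgumentError("feedback_strength must lie in [0, 1]")


def _heading_profile(spec: SyntheticCellSpec, t: np.ndarray, duration_s: float) -> np.ndarray:
    """Planted heading at each time point for the requested mode."""
    h0 = spec.heading0_rad
    if spec.mode in ("persistent", "stationary"):
        return np.full_like(t, h0)
    if spec.mode == "turn":
        omega = 2 * np.pi * spec.turn_rpm / 60.0  # rad/s, CCW positive
        return h0 + omega * t
    if spec.mode == "reverser":
        switch = spec.switch_time_s if spec.switch_time_s is not None else duration_s / 2
        return np.where(t < switch, h0, h0 + np.pi)
    if spec.mode == "u_turn":
        start = (duration_s - spec.u_turn_duration_s) / 2
        frac = np.clip((t - start) / spec.u_turn_duration_s, 0.0, 1.0)
        return h0 + np.pi * frac
    raise InvalidArgumentError(f"unknown mode {spec.mode!r}")


def make_trajectory(
    spec: SyntheticCellSpec,
    duration_s: float,
    dt_s: float,
    noise_sd_um: float = 0.0,
    seed: int | None = None,
    cell_id: str = "cell",
) -> tuple[Track, np.ndarray]:
    """Generate a centroid track plus its planted heading series.

    The cell moves at constant speed along a heading profile set by its
    mode; Gaussian positional noise of ``noise_sd_um`` is added per sample.
    Identical ``(spec, seed)`` give identical output.
    """
    if duration_s <= 0 or dt_s <= 0:
        raise InvalidArgumentError("duration_s and dt_s must be > 0")
    n = int(round(duration_s / dt_s)) + 1
    t = np.arange(n) * dt_s
    headings = _heading_profile(spec, t, duration_s)
    v = spec.speed_um_min / 60.0  # µm/s
    if spec.mode == "stationary":
        v = 0.0
    # step directions use the mid-step heading so a fixed-rpm turner traces
    # an exact circle whose chord directions advance at the planted rate
    mid = _heading_profile(spec, t[:-1] + dt_s / 2, duration_s)
    dx = v * dt_s * np.cos(mid)
    dy = v * dt_s * np.sin(mid)
    x = np.concatenate([[0.0], np.cumsum(dx)])
    y = np.concatenate([[0.0], np.cumsum(dy)])
    if noise_sd_um > 0:
        rng = np.random.default_rng(seed)
        x = x + rng.normal(0.0, noise_sd_um, n)
        y = y + rng.normal(0.0, noise_sd_um, n)
    return Track(cell_id=cell_id, t_s=t, x_um=x, y_um=y), headings


@dataclass
class MovieGroundTruth:
    """Planted quantities behind a synthetic movie."""

    masks: np.ndarray  # (T, H, W) bool
    centroids_px: np.ndarray  # (T, 2) row, col
    background: np.ndarray  # (H, W) noiseless background grid
    background_model: BackgroundModel
    headings_rad: np.ndarray
    track: Track


def _paint_cell(
    frame: np.ndarray,
    center_px: tuple[float, float],
    radius_px: float,
    peak: float,
    kappa: float,
    heading_rad: float,
) -> np.ndarray:
    """Paint a disk with a von Mises-shaped angular intensity modulation.

    Intensity is peak·(0.5 + 0.5·exp(κ(cos(θ−heading) − 1))): uniform for
    κ = 0, peaked at the heading for κ > 0, never below half peak so the
    interior stays bright relative to background.
    """
    h, w = frame.shape
    rr, cc = np.mgrid[0:h, 0:w]
    d2 = (rr - center_px[0]) ** 2 + (cc - center_px[1]) ** 2
    mask = d2 <= radius_px**2
    if kappa > 0:
        ang = np.arctan2(center_px[0] - rr, cc - center_px[1])  # math convention
        modulation = 0.5 + 0.5 * np.exp(kappa * (np.cos(ang - heading_rad) - 1.0))
    else:
        modulation = 1.0
    frame = frame.copy()
    frame[mask] += (peak * np.asarray(modulation))[mask] if kappa > 0 else peak
    return frame, mask


def make_cell_movie(
    cell: SyntheticCellSpec,
    bg: BackgroundSpec,
    field_px: int = 160,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
    duration_s: float = 60.0,
    dt_s: float = DEFAULT_FRAME_DT_S,
    seed: int | None = None,
    channel: str = "PHAkt",
    track: Track | None = None,
    headings: np.ndarray | None = None,
) -> tuple[Movie, MovieGroundTruth]:
    """Render a movie of one cell moving over a planted background.

    The track is generated from ``cell`` (or supplied); the cell footprint
    is a disk whose peripheral intensity may be polarized toward the
    heading.  Per-frame ground-truth masks, centroids, the background grid
    and the heading series are returned for recovery tests.  Raises
    :class:`OutOfFieldError` naming the first frame at which the footprint
    leaves the field.
    """
    if track is None:
        track, headings = make_trajectory(cell, duration_s, dt_s, seed=seed)
    elif headings is None:
        raise InvalidArgumentError("supply headings together with a track")
    rng = np.random.default_rng(seed)
    h = w = int(field_px)
    bg_model = bg.model()
    bg_grid = bg_model.evaluate((h, w))
    # sanity: the painted interior must dominate the background
    if cell.peak_intensity * 0.5 < 3.0 * max(float(bg_grid.mean()), 0.0):
        raise InvalidArgumentError(
            "peak_intensity too low: cell interior must be >= 3x background mean"
        )
    radius_px = cell.radius_um / pixel_size_um
    n = len(track)
    frames = np.empty((n, h, w))
    masks = np.empty((n, h, w), dtype=bool)
    centroids = np.empty((n, 2))
    for i in range(n):
        # track coordinates are µm with origin at the field center, y up
        row = (h - 1) / 2.0 - track.y_um[i] / pixel_size_um
        col = (w - 1) / 2.0 + track.x_um[i] / pixel_size_um
        if (
            row - radius_px < 0
            or col - radius_px < 0
            or row + radius_px > h - 1
            or col + radius_px > w - 1
        ):
            raise OutOfFieldError(i)
        frame, mask = _paint_cell(
            bg_grid, (row, col), radius_px, cell.peak_intensity,
            cell.polarity_kappa, headings[i],
        )
        if bg.noise_sd > 0:
            frame = frame + rng.normal(0.0, bg.noise_sd, frame.shape)
        frames[i] = frame
        masks[i] = mask
        centroids[i] = (row, col)
    movie = Movie(
        frames={channel: frames},
        pixel_size_um=pixel_size_um,
        timestamps_s=track.t_s.copy(),
        meta={"channel_order": [channel], "synthetic": True},
    )
    truth = MovieGroundTruth(
        masks=masks, centroids_px=centroids, background=bg_grid,
        background_model=bg_model, headings_rad=np.asarray(headings), track=track,
    )
    return movie, truth


def simulate_adaptive_response(
    input_trace: Sequence[float],
    spec: AdaptiveResponseSpec,
    dt_s: float,
) -> np.ndarray:
    """Integrate the adaptive response ODE over a sampled input P(t).

    Fixed-step 4th-order Runge–Kutta at the input sampling interval, with
    linear interpolation of P at half steps.  Inputs must be non-negative;
    the response starts from R = I = 0.
    """
    P = np.asarray(input_trace, dtype=float)
    if dt_s <= 0:
        raise InvalidArgumentError("dt_s must be > 0")
    if np.any(P < 0):
        raise InvalidArgumentError("input trace must be non-negative")
    ga, gf = spec.gain_activation, spec.gain_feedback
    kd, fs = spec.inhibitor_decay, spec.feedback_strength

    def deriv(state, p):
        R, I = state
        dR = ga * p - kd * fs * I * R
        dI = gf * R - kd * I
        return np.array([dR, dI])

    out = np.zeros(len(P))
    state = np.zeros(2)
    for i in range(len(P) - 1):
        p0, p1 = P[i], P[i + 1]
        pm = 0.5 * (p0 + p1)
        k1 = deriv(state, p0)
        k2 = deriv(state + 0.5 * dt_s * k1, pm)
        k3 = deriv(state + 0.5 * dt_s * k2, pm)
        k4 = deriv(state + dt_s * k3, p1)
        state = state + dt_s / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
        state = np.maximum(state, 0.0)
        out[i + 1] = state[0]
    return out


@dataclass
class GuidanceCellModel:
    """Behavioral model of a guided cell for virtual assays.

    The membrane is discretized into lab-frame angular sectors around the
    centroid, each carrying a local input level P that relaxes toward its
    illumination.  The heading turns toward sectors experiencing a local
    *increase* of P, weighted by a body-frame sensitivity that is zero in a
    rear sector (default ±60° about the back), zero (saturated) in a front
    sector (default ±20°), and tapers linearly between.  All sector widths
    are configurable; the parameterization is invented and documented as
    such.
    """

    radius_um: float = 8.0
    speed_um_min: float = 10.0
    n_sectors: int = 36
    p_on_rate: float = 0.02  # 1/s, relaxation of local P toward illumination
    turn_gain: float = 7.0  # rad of turning per unit integrated drive
    rear_halfwidth_deg: float = 60.0
    front_halfwidth_deg: float = 20.0
    heading_noise_rad: float = 0.01  # SD per control step


@dataclass
class ControllerRules:
    """Closed-loop controller configuration."""

    control_dt_s: float = 1.0
    pretrack_s: float = 60.0  # motility-check window before stimulation
    frame_dt_s: float = DEFAULT_FRAME_DT_S


@dataclass
class VirtualAssayResult:
    track: Track
    headings_rad: np.ndarray  # at control resolution
    t_control_s: np.ndarray
    left_P: np.ndarray  # mean sector input, left of heading
    right_P: np.ndarray
    event_log: list
    movie: Movie | None = None
    ground_truth: MovieGroundTruth | None = None


def _sector_sensitivity(body_angles: np.ndarray, front_hw: float, rear_hw: float) -> np.ndarray:
    """Taper from the front-saturation edge (weight 0 at |θ| ≤ front) up to
    1 just outside it, down to 0 at the rear dead-zone edge."""
    a = np.abs(body_angles)
    front = np.radians(front_hw)
    rear_edge = np.pi - np.radians(rear_hw)
    w = np.zeros_like(a)
    active = (a > front) & (a < rear_edge)
    w[active] = (rear_edge - a[active]) / (rear_edge - front)
    return w


def run_virtual_assay(
    cell_model: GuidanceCellModel,
    controller_rules: ControllerRules,
    protocol: StimulusProtocol,
    duration_s: float | None = None,
    seed: int | None = None,
    render_movie: bool = False,
    bg: BackgroundSpec | None = None,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
) -> VirtualAssayResult:
    """Run a closed-loop virtual assay: controller geometry driving the
    behavioral cell model.

    The first ``pretrack_s`` establish the heading with no stimulation;
    protocol time 0 starts afterwards.  At every control step the stimulus
    pattern is recomputed from the current heading exactly as the placement
    geometry defines: ``lab``-frame spot angles are absolute bearings,
    ``initial_heading`` angles are resolved once against the heading at
    stimulation onset, and ``heading`` angles follow the instantaneous
    heading (a spot that rides the cell's edge).  An event log records each
    placement.
    """
    phases = protocol.phases
    for ph in phases:
        for sp in ph.spots:
            if sp.frame in ("heading", "initial_heading") and controller_rules.pretrack_s <= 0:
                raise UndefinedHeadingError(
                    "heading-referenced spots need a pretrack period to define "
                    "the heading; use lab-frame angles otherwise"
                )
    total = controller_rules.pretrack_s + (
        duration_s if duration_s is not None else protocol.total_duration_s
    )
    dt = controller_rules.control_dt_s
    n = int(round(total / dt)) + 1
    t = np.arange(n) * dt

    rng = np.random.default_rng(seed)
    m = cell_model
    sector_bearing = wrap_angle(
        -np.pi + (np.arange(m.n_sectors) + 0.5) * 2 * np.pi / m.n_sectors
    )
    dpsi = 2 * np.pi / m.n_sectors
    P = np.zeros(m.n_sectors)
    heading = 0.0
    initial_heading_at_stim: float | None = None
    pos = np.zeros(2)
    xs, ys, hs = [0.0], [0.0], [heading]
    left_P, right_P = [0.0], [0.0]
    log: list[dict] = []
    v = m.speed_um_min / 60.0
    spot_halfwidth = {}

    for i in range(1, n):
        ti = t[i - 1]
        t_proto = ti - controller_rules.pretrack_s
        L = np.zeros(m.n_sectors)
        phase_idx = None
        if 0.0 <= t_proto < protocol.total_duration_s:
            if initial_heading_at_stim is None:
                initial_heading_at_stim = heading
            phase_idx, phase = schedule_protocol(protocol, t_proto)
            if phase.pattern == "global":
                L[:] = phase.intensity
                log.append({"t_s": ti, "phase": phase_idx, "pattern": "global"})
            elif phase.pattern == "spots":
                for sp in phase.spots:
                    if sp.frame == "lab":
                        bearing = np.radians(sp.angle_deg)
                    elif sp.frame == "initial_heading":
                        bearing = initial_heading_at_stim + np.radians(sp.angle_deg)
                    else:  # heading: follows the instantaneous heading
                        bearing = heading + np.radians(sp.angle_deg)
                    key = id(sp)
                    if key not in spot_halfwidth:
                        spot_halfwidth[key] = np.arcsin(
                            min(1.0, sp.radius_um / m.radius_um)
                        )
                    hit = np.abs(wrap_angle(sector_bearing - bearing)) <= spot_halfwidth[key]
                    L[hit] = np.maximum(L[hit], sp.intensity)
                    log.append(
                        {
                            "t_s": ti, "phase": phase_idx, "pattern": "spot",
                            "angle_deg": sp.angle_deg, "frame": sp.frame,
                            "bearing_rad": float(wrap_angle(bearing)),
                            "heading_rad": float(wrap_angle(heading)),
                        }
                    )
        dP = m.p_on_rate * (L - P)
        drive = np.maximum(dP, 0.0)
        body = wrap_angle(sector_bearing - heading)
        w = _sector_sensitivity(body, m.front_halfwidth_deg, m.rear_halfwidth_deg)
        torque = float(np.sum(np.sign(body) * w * drive) * dpsi)
        heading = heading + m.turn_gain * torque * dt
        heading += rng.normal(0.0, m.heading_noise_rad) * np.sqrt(dt)
        P = P + dP * dt
        pos = pos + v * dt * np.array([np.cos(heading), np.sin(heading)])
        xs.append(pos[0])
        ys.append(pos[1])
        hs.append(heading)
        left = wrap_angle(sector_bearing - heading) > 0
        left_P.append(float(P[left].mean()))
        right_P.append(float(P[~left].mean()))

    track = Track(cell_id="virtual", t_s=t, x_um=np.array(xs), y_um=np.array(ys))
    result = VirtualAssayResult(
        track=track,
        headings_rad=np.array(hs),
        t_control_s=t,
        left_P=np.array(left_P),
        right_P=np.array(right_P),
        event_log=log,
    )
    if render_movie:
        frame_stride = max(1, int(round(controller_rules.frame_dt_s / dt)))
        idx = np.arange(0, n, frame_stride)
        sub = Track(
            cell_id="virtual", t_s=t[idx], x_um=np.array(xs)[idx], y_um=np.array(ys)[idx]
        )
        extent_um = max(
            np.ptp(sub.x_um), np.ptp(sub.y_um)
        ) + 6 * m.radius_um
        field_px = int(np.ceil(extent_um / pixel_size_um))
        spec = SyntheticCellSpec(radius_um=m.radius_um, speed_um_min=m.speed_um_min)
        center = Track(
            cell_id="virtual",
            t_s=sub.t_s,
            x_um=sub.x_um - (sub.x_um.min() + sub.x_um.max()) / 2,
            y_um=sub.y_um - (sub.y_um.min() + sub.y_um.max()) / 2,
        )
        movie, truth = make_cell_movie(
            spec, bg or BackgroundSpec(), field_px=field_px,
            pixel_size_um=pixel_size_um, seed=seed,
            track=center, headings=np.array(hs)[idx],
        )
        result.movie = movie
        result.ground_truth = truth
    return result
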