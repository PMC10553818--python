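"""End-to-end orchestration: config, provenance and canned synthetic workflows.

A single YAML config tree drives every stage; all analysis constants (14-px
ring contraction, 2 µm/min speed gate, 0.4-rad alignment tolerance, 20-µm
classification threshold, 100-unit baseline QC, 30-s initial-rate window,
Savitzky–Golay window 9 / order 3) are named keys with their standard
defaults, so a run is reproducible from its manifest alone.
"""

from __future__ import annotations

import copy
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__, io
from .errors import InvalidArgumentError
from .image_prep import fit_background, make_background_mask, segment_cell, subtract_background
from .kinematics import (
    angular_velocity,
    classify_two_spot,
    detect_reversal,
    heading_series,
    initial_heading,
    smooth_track,
)
from .peripheral import (
    align_winning_side,
    angular_profile,
    average_kymographs,
    build_kymograph,
    ring_mask,
)
from .stats import binomial_symmetry_test
from .stimulus import ProtocolPhase, SpotSpec, StimulusProtocol
from .synthetic import (
    ControllerRules,
    GuidanceCellModel,
    run_virtual_assay,
)

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "imaging": {
        "pixel_size_um": 3.0 / 14.0,
        "frame_dt_s": 5.0,
    },
    "prep": {
        "background_kind": "plane",
        "guard_band_px": 10,
        "baseline_threshold_units": 100.0,
        "min_area_px": 200,
    },
    "kymo": {
        "ring_contraction_px": 14,
        "n_bins": 72,
    },
    "kinematics": {
        "sg_window": 9,
        "sg_order": 3,
        "min_speed_um_min": 2.0,
        "align_tol_rad": 0.4,
        "two_spot_threshold_um": 20.0,
    },
    "regions": {
        "square_px": 20,
        "blur_sigma_px": 5.0,
        "baseline_min_s": 30.0,
    },
    "fit": {
        "initial_rate_window_s": 30.0,
    },
    "assay": {
        "preset": "two_spot_90",
        "n_cells": 6,
        "spot_angles_deg": [90.0, -90.0],
        "phase_duration_s": 300.0,
        "pretrack_s": 60.0,
        "render_movies": True,
    },
}


def default_config() -> dict:
    return copy.deepcopy(DEFAULT_CONFIG)


def load_config(path) -> dict:
    cfg = default_config()
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    for section, values in user.items():
        if isinstance(values, dict) and isinstance(cfg.get(section), dict):
            cfg[section].update(values)
        else:
            cfg[section] = values
    return cfg


def validate_config(cfg: dict) -> None:
    """Shallow schema check; raises naming the offending key path."""
    required = {
        "imaging.pixel_size_um": (int, float),
        "imaging.frame_dt_s": (int, float),
        "kymo.n_bins": int,
        "kinematics.min_speed_um_min": (int, float),
    }
    for path, types in required.items():
        node = cfg
        for part in path.split("."):
            if not isinstance(node, dict) or part not in node:
                raise InvalidArgumentError(f"config missing key {path!r}")
            node = node[part]
        if not isinstance(node, types):
            raise InvalidArgumentError(f"config key {path!r} has wrong type")
    if cfg["imaging"]["pixel_size_um"] <= 0:
        raise InvalidArgumentError("config key 'imaging.pixel_size_um' must be > 0")


@dataclass
class RunManifest:
    """Everything needed to re-run a pipeline invocation bit-identically."""

    config: dict
    seed: int
    version: str = __version__
    seeds: dict = field(default_factory=dict)
    timings_s: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2, default=str))


def _two_spot_protocol(cfg: dict) -> StimulusProtocol:
    a1, a2 = cfg["assay"]["spot_angles_deg"]
    return StimulusProtocol(
        phases=[
            ProtocolPhase(
                duration_s=cfg["assay"]["phase_duration_s"],
                pattern="spots",
                spots=[
                    SpotSpec(angle_deg=a1, frame="initial_heading"),
                    SpotSpec(angle_deg=a2, frame="initial_heading"),
                ],
            )
        ]
    )


def _kymograph_from_movie(movie, channel: str, track, cfg: dict):
    """Segment every frame, background-correct, ring-profile and stack."""
    kcfg, pcfg = cfg["kymo"], cfg["prep"]
    ref = initial_heading(track)
    profiles = []
    for i in range(movie.n_frames):
        frame = movie.channel(channel)[i]
        cm = segment_cell(frame, frame_index=i, pixel_size_um=movie.pixel_size_um)
        if cm is None:
            raise InvalidArgumentError(f"no cell found at frame {i}")
        bg_mask = make_background_mask(frame.shape, [cm.mask], pcfg["guard_band_px"])
        model = fit_background(frame, bg_mask, pcfg["background_kind"])
        corrected = subtract_background(frame, model)
        ring = ring_mask(cm.mask, kcfg["ring_contraction_px"])
        profiles.append(
            angular_profile(corrected, ring, cm.centroid_px, ref, kcfg["n_bins"])
        )
    return build_kymograph(profiles, movie.timestamps_s)


def run_pipeline(cfg: dict, out_dir, seed: int | None = None) -> RunManifest:
    """Run the canned two-spot assay workflow on a synthetic cohort.

    Simulates ``n_cells`` closed-loop virtual assays, classifies each
    outcome (frontward / rearward / nonresponder and reverser calls),
    builds the winning-side-aligned cohort-average kymograph from the
    rendered movies, and tests outcome symmetry.  All outputs are CSV/JSON/
    HDF5 under ``out_dir``; the manifest records seeds and timings.
    """
    validate_config(cfg)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"] if seed is None else seed)
    manifest = RunManifest(config=cfg, seed=seed)
    acfg = cfg["assay"]
    protocol = _two_spot_protocol(cfg)
    rules = ControllerRules(
        pretrack_s=acfg["pretrack_s"], frame_dt_s=cfg["imaging"]["frame_dt_s"]
    )
    model = GuidanceCellModel()
    kin = cfg["kinematics"]

    t0 = time.perf_counter()
    rows = []
    kymos, tracks = [], []
    rng = np.random.default_rng(seed)
    cell_seeds = rng.integers(0, 2**31 - 1, size=acfg["n_cells"])
    for k, cell_seed in enumerate(cell_seeds):
        res = run_virtual_assay(
            model, rules, protocol, seed=int(cell_seed),
            render_movie=acfg["render_movies"],
            pixel_size_um=cfg["imaging"]["pixel_size_um"],
        )
        track = res.track
        smoothed = smooth_track(track, kin["sg_window"], kin["sg_order"])
        hs = heading_series(smoothed, kin["min_speed_um_min"])
        h0 = initial_heading(track, acfg["pretrack_s"])
        angles = np.radians(acfg["spot_angles_deg"])
        axes = [
            (np.cos(h0 + angles[0]), np.sin(h0 + angles[0])),
            (np.cos(h0 + angles[1]), np.sin(h0 + angles[1])),
        ]
        outcome = classify_two_spot(
            track, axes, kin["two_spot_threshold_um"], start_time_s=acfg["pretrack_s"]
        )
        reverser = detect_reversal(
            hs,
            [h0 + angles[0], h0 + angles[1]],
            epochs=[(acfg["pretrack_s"], acfg["pretrack_s"] + acfg["phase_duration_s"])],
            tol_rad=kin["align_tol_rad"],
        )
        rows.append(
            {
                "cell_id": f"cell{k:02d}",
                "seed": int(cell_seed),
                "outcome": outcome,
                "reverser": bool(reverser),
            }
        )
        track.cell_id = f"cell{k:02d}"
        tracks.append(track)
        manifest.seeds[f"cell{k:02d}"] = int(cell_seed)
        if res.movie is not None:
            kym = _kymograph_from_movie(res.movie, "PHAkt", track, cfg)
            kymos.append(align_winning_side(kym, track))
    manifest.timings_s["simulate_and_classify"] = time.perf_counter() - t0

    import pandas as pd

    calls = pd.DataFrame(rows)
    calls_path = out_dir / "outcomes.csv"
    calls.to_csv(calls_path, index=False)
    io.write_tracks(tracks, out_dir / "tracks.csv")
    manifest.outputs["outcomes"] = str(calls_path)
    manifest.outputs["tracks"] = str(out_dir / "tracks.csv")

    if kymos:
        t0 = time.perf_counter()
        avg = average_kymographs(kymos)
        io.write_kymograph(avg, out_dir / "kymograph_avg.h5", out_dir / "kymograph_avg.csv")
        io.render_kymograph_png(avg, out_dir / "kymograph_avg.png", "cohort average")
        manifest.outputs["kymograph"] = str(out_dir / "kymograph_avg.h5")
        manifest.timings_s["kymograph"] = time.perf_counter() - t0

    responders = calls[calls["outcome"] != "nonresponder"]
    if len(responders):
        k_front = int((responders["outcome"] == "frontward").sum())
        test = binomial_symmetry_test(k_front, len(responders))
        (out_dir / "symmetry_test.json").write_text(
            json.dumps(
                {
                    "k_frontward": k_front,
                    "n_responders": int(len(responders)),
                    "p_value": test.p_value,
                    "method": test.method,
                },
                indent=2,
            )
        )
        manifest.outputs["symmetry_test"] = str(out_dir / "symmetry_test.json")

    manifest.write(out_dir / "manifest.json")
    return manifest
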