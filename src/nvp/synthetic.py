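"""Synthetic ground-truth data generation.

Every input format the pipeline consumes can be generated here with known
ground truth: vessel movies as bright ridges with analytically known
cross-sections, line-scan kymographs with streaks of known slope,
haemodynamic and calcium traces with gamma-shaped stimulus transients,
locomotion bouts, tube-network anatomy phantoms, pose-tracking tables with
known path length, and a full multi-group study bundle with planted
genotype x exercise effects.

All generators take an integer seed and are bit-reproducible: same
parameters + seed => identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtr

from nvp.core import (
    HEMO_CHANNELS,
    AnatomyStack,
    CalciumTraces,
    HemoRecording,
    Kymograph,
    LocomotionTrace,
    PericyteSet,
    StimulusSchedule,
    VesselMovie,
)


@dataclass
class GroundTruth:
    """Known truth saved alongside each generated dataset.

    Only the fields relevant to a given generator are populated.  All
    physical quantities are strictly positive; per-frame fields match the
    generated recording length.
    """

    true_diameter_trace: np.ndarray | None = None    # um per frame
    true_fwhm_trace: np.ndarray | None = None        # um per frame (box (x) PSF)
    true_velocity_trace: np.ndarray | None = None    # mm/s per line
    true_vasomotion_amp: float | None = None         # fractional oscillation
    true_vasomotion_freq: float | None = None        # Hz
    true_responsive_trials: np.ndarray | None = None  # bool per trial
    true_response_amp: dict | None = None            # per-channel % change
    true_path_length: float | None = None            # cm
    true_network_length: float | None = None         # um
    true_radii: np.ndarray | None = None             # um per skeleton point
    true_cell_classes: list | None = None            # ON/OFF/BOTH/NONE
    effect_table: dict | None = None
    seed: int | None = None
    extras: dict = field(default_factory=dict)

    def to_jsonable(self) -> dict:
        out = {}
        for k, v in self.__dict__.items():
            if v is None:
                continue
            if isinstance(v, np.ndarray):
                out[k] = v.tolist()
            else:
                out[k] = v
        return out


# ---------------------------------------------------------------------------
# vessel movies


def box_gauss_profile(distance: np.ndarray, width: float, sigma: float) -> np.ndarray:
    """Cross-section of a box of ``width`` convolved with a Gaussian PSF of
    standard deviation ``sigma`` (same units as distance), peak-normalized to
    the unblurred box height of 1."""
    if sigma <= 0:
        return (np.abs(distance) <= width / 2).astype(float)
    return ndtr((distance + width / 2) / sigma) - ndtr((distance - width / 2) / sigma)


def box_gauss_fwhm(width: float, sigma: float) -> float:
    """Analytic FWHM of the box-convolved-Gaussian profile.

    Solved numerically from the closed-form profile; exact to the solver
    tolerance.  For sigma << width this converges to ``width``.
    """
    from scipy.optimize import brentq

    peak = box_gauss_profile(np.array([0.0]), width, sigma)[0]
    half = peak / 2.0
    hi = width / 2 + 6 * sigma + 1e-9
    f = lambda d: box_gauss_profile(np.array([d]), width, sigma)[0] - half
    return 2.0 * brentq(f, 0.0, hi, xtol=1e-12)


def gen_vessel_movie(
    width_fn: Callable[[np.ndarray], np.ndarray] | float,
    pixel_size: float = 0.23,
    frame_rate: float = 7.63,
    n_frames: int = 100,
    psf_sigma: float = 0.3,
    noise_sd: float = 0.0,
    orientation: float = 0.0,
    fov: int = 128,
    amplitude: float = 100.0,
    background: float = 0.0,
    seed: int = 0,
) -> tuple[VesselMovie, GroundTruth]:
    """Generate a movie of a single straight vessel of time-varying width.

    Each frame contains one bright ridge through the field-of-view centre at
    ``orientation`` degrees (0 = horizontal vessel).  The cross-section is a
    box of the true width convolved with a Gaussian of ``psf_sigma`` (um),
    plus additive Gaussian noise of ``noise_sd`` (intensity units; the ridge
    peak is ``amplitude``).

    width_fn maps time in seconds (array over frames) to width in um; a
    scalar is treated as a constant width.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    t = np.arange(n_frames) / frame_rate
    if callable(width_fn):
        widths = np.asarray(width_fn(t), dtype=float) * np.ones_like(t)
    else:
        widths = np.full(n_frames, float(width_fn))
    limit = 2.0 * pixel_size
    if np.any(widths <= limit):
        raise ValueError(
            f"vessel width must exceed the resolvable limit of 2x pixel_size "
            f"= {limit:.3f} um at every frame"
        )

    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:fov, 0:fov].astype(float)
    cy = cx = (fov - 1) / 2.0
    theta = np.deg2rad(orientation)
    # signed perpendicular distance (um) from the centreline
    dist = ((yy - cy) * np.cos(theta) - (xx - cx) * np.sin(theta)) * pixel_size

    frames = np.empty((n_frames, fov, fov))
    for i, w in enumerate(widths):
        frames[i] = background + amplitude * box_gauss_profile(dist, w, psf_sigma)
    if noise_sd > 0:
        frames += rng.normal(0.0, noise_sd, frames.shape)

    movie = VesselMovie(data=frames, pixel_size=pixel_size, frame_rate=frame_rate)
    fwhm_trace = np.array([box_gauss_fwhm(w, psf_sigma) for w in widths])
    gt = GroundTruth(
        true_diameter_trace=widths,
        true_fwhm_trace=fwhm_trace,
        seed=seed,
        extras={"psf_sigma": psf_sigma, "orientation": orientation},
    )
    return movie, gt


# ---------------------------------------------------------------------------
# kymographs


def gen_kymograph(
    velocity_fn: Callable[[np.ndarray], np.ndarray] | float,
    line_rate: float = 1092.0,
    pixel_size: float = 0.2,
    n_lines: int = 2048,
    n_px: int = 128,
    streak_density: float = 120.0,
    streak_contrast: float = 0.6,
    streak_sigma_px: float = 1.0,
    noise_sd: float = 0.0,
    background: float = 1.0,
    seed: int = 0,
) -> tuple[Kymograph, GroundTruth]:
    """Generate a line-scan kymograph with dark streaks of known slope.

    Moving cells leave dark anti-aliased streaks: a cell at velocity v mm/s
    displaces v / (line_rate * pixel_size_mm) pixels per line, so the streak
    slope encodes the velocity.  Positive velocity = displacement toward
    increasing position index.

    velocity_fn maps time in seconds (per line) to velocity in mm/s; a
    scalar is a constant velocity.  streak_density is streaks per second.
    """
    t = np.arange(n_lines) / line_rate
    if callable(velocity_fn):
        velocities = np.asarray(velocity_fn(t), dtype=float) * np.ones_like(t)
    else:
        velocities = np.full(n_lines, float(velocity_fn))

    # px displacement per line; mm/s -> um/s -> px/s -> px/line
    u = velocities * 1000.0 / pixel_size / line_rate
    total_disp = np.abs(u).sum()
    if np.any(velocities != 0) and total_disp < 1.0:
        raise ValueError(
            "velocity implies < 1 pixel displacement over the whole window; "
            "streak slope unresolvable"
        )

    rng = np.random.default_rng(seed)
    img = np.full((n_lines, n_px), background)
    duration = n_lines / line_rate
    n_streaks = rng.poisson(max(streak_density * duration, 0.0))
    # cumulative displacement lets streaks follow a time-varying velocity
    cumdisp = np.concatenate([[0.0], np.cumsum(u)])[:n_lines]
    lines = np.arange(n_lines)
    span = np.abs(cumdisp).max() if n_lines else 0.0
    for _ in range(n_streaks):
        x0 = rng.uniform(-span - 5, n_px + span + 5)
        x = x0 + cumdisp
        inside = (x > -3 - np.abs(u)) & (x < n_px + 3 + np.abs(u))
        if not inside.any():
            continue
        xi = x[inside]
        li = lines[inside]
        ui = u[inside]
        # the cell sweeps u pixels during one line period, so the dip is
        # smeared along that interval (motion blur within the scan line);
        # deposit sub-steps along the sweep, anti-aliased across pixels
        m = max(int(np.ceil(np.abs(ui).max())), 1)
        frac = (np.arange(m) / m)[None, :]
        xs = (xi[:, None] + frac * ui[:, None]).ravel()
        ts = np.repeat(li, m)
        depth = streak_contrast * background / m
        for off in range(-2, 3):
            cols = np.round(xs).astype(int) + off
            ok = (cols >= 0) & (cols < n_px)
            d = cols[ok] - xs[ok]
            np.subtract.at(img, (ts[ok], cols[ok]),
                           depth * np.exp(-0.5 * (d / streak_sigma_px) ** 2))
    if noise_sd > 0:
        img += rng.normal(0.0, noise_sd, img.shape)

    kymo = Kymograph(data=img, line_rate=line_rate, pixel_size=pixel_size)
    gt = GroundTruth(
        true_velocity_trace=velocities,
        seed=seed,
        extras={"n_streaks": int(n_streaks), "streak_density": streak_density},
    )
    return kymo, gt


# ---------------------------------------------------------------------------
# stimulus transients


def gamma_kernel(t: np.ndarray, onset_latency: float = 0.5,
                 shape: float = 3.0, scale: float = 0.9) -> np.ndarray:
    """Gamma-variate transient, peak-normalized to 1.

    Standard single-peaked haemodynamic response shape: zero before
    ``onset_latency``, rises to its peak at onset_latency + (shape-1)*scale
    seconds, then decays.
    """
    tt = np.clip(t - onset_latency, 0.0, None)
    k = tt ** (shape - 1.0) * np.exp(-tt / scale)
    peak = ((shape - 1.0) * scale) ** (shape - 1.0) * np.exp(-(shape - 1.0))
    return k / peak


def _add_transients(trace: np.ndarray, sample_rate: float, onsets: np.ndarray,
                    amp: float, kernel_dur: float = 15.0, **kw) -> None:
    """Add ``amp``-scaled gamma transients at each onset, in place."""
    n_k = int(round(kernel_dur * sample_rate))
    tk = np.arange(n_k) / sample_rate
    k = gamma_kernel(tk, **kw) * amp
    for onset in onsets:
        i0 = int(round(onset * sample_rate))
        i1 = min(i0 + n_k, len(trace))
        if i0 < len(trace):
            trace[i0:i1] += k[: i1 - i0]


def gen_hemo_and_stim(
    baseline_levels: dict | None = None,
    response_amps: dict | None = None,
    stim_n: int = 20,
    stim_dur: float = 5.0,
    isi: float = 25.0,
    sample_rate: float = 40.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[HemoRecording, StimulusSchedule, GroundTruth]:
    """Generate an Oxy-CBF-style recording with stimulus-locked transients.

    baseline_levels / response_amps are per-channel dicts; response amps are
    % change from baseline (the gamma transient is peak-normalized, so the
    noiseless per-trial max peak equals the stated amplitude exactly).
    Hbt is constructed as Hbo + Hbd before noise, so additivity holds
    exactly in the noiseless case.
    """
    defaults = {"Flux": 200.0, "Speed": 50.0, "Hbo": 60.0, "Hbd": 40.0, "sO2": 60.0}
    levels = dict(defaults)
    if baseline_levels:
        levels.update(baseline_levels)
    amps = {c: 0.0 for c in HEMO_CHANNELS}
    if response_amps:
        amps.update(response_amps)

    schedule = StimulusSchedule.default(n_stims=stim_n, stim_dur=stim_dur, isi=isi)
    duration = schedule.onsets[-1] + stim_dur + isi
    n = int(round(duration * sample_rate))
    rng = np.random.default_rng(seed)

    raw = {}
    for ch in ("Flux", "Speed", "Hbo", "Hbd", "sO2"):
        trace = np.full(n, levels[ch])
        _add_transients(trace, sample_rate, schedule.onsets,
                        amps.get(ch, 0.0) / 100.0 * levels[ch])
        raw[ch] = trace
    hbt = raw["Hbo"] + raw["Hbd"]
    if amps.get("Hbt", 0.0) != 0.0 and amps.get("Hbo", 0.0) == 0 and amps.get("Hbd", 0.0) == 0:
        _add_transients(hbt, sample_rate, schedule.onsets,
                        amps["Hbt"] / 100.0 * hbt[0])
    raw["Hbt"] = hbt
    if noise_sd > 0:
        for ch in raw:
            scale = noise_sd / 100.0 * levels.get(ch, raw[ch][0] or 1.0)
            raw[ch] = raw[ch] + rng.normal(0.0, scale, n)
    raw["sO2"] = np.clip(raw["sO2"], 0.0, 100.0)

    rec = HemoRecording(channels=pd.DataFrame(raw), sample_rate=sample_rate)
    gt = GroundTruth(true_response_amp=dict(amps), seed=seed,
                     extras={"baseline_levels": levels})
    return rec, schedule, gt


def gen_calcium(
    classes: Sequence[str],
    amp: float = 1.0,
    decay_tau: float = 0.6,
    noise_sd: float = 0.0,
    schedule: StimulusSchedule | None = None,
    sample_rate: float = 7.63,
    seed: int = 0,
) -> tuple[CalciumTraces, GroundTruth]:
    """Generate dF/F traces for cells of stated response classes.

    ON cells rise at stimulus onset, OFF cells at offset, BOTH at both,
    NONE never.  Transients are gamma-variate with a short latency and the
    given decay time constant; amp is the dF/F peak.
    """
    if len(classes) < 1:
        raise ValueError("need at least one cell")
    bad = set(classes) - {"ON", "OFF", "BOTH", "NONE"}
    if bad:
        raise ValueError(f"unknown cell classes: {bad}")
    if schedule is None:
        schedule = StimulusSchedule.default()
    duration = schedule.onsets[-1] + schedule.stim_dur + schedule.isi
    n = int(round(duration * sample_rate))
    rng = np.random.default_rng(seed)

    kw = dict(onset_latency=0.2, shape=2.0, scale=decay_tau)
    dff = np.zeros((len(classes), n))
    for i, cls in enumerate(classes):
        if cls in ("ON", "BOTH"):
            _add_transients(dff[i], sample_rate, schedule.onsets, amp,
                            kernel_dur=10.0, **kw)
        if cls in ("OFF", "BOTH"):
            _add_transients(dff[i], sample_rate,
                            schedule.onsets + schedule.stim_dur, amp,
                            kernel_dur=10.0, **kw)
    if noise_sd > 0:
        dff += rng.normal(0.0, noise_sd, dff.shape)

    traces = CalciumTraces(dff=dff, sample_rate=sample_rate)
    gt = GroundTruth(true_cell_classes=list(classes), seed=seed)
    return traces, gt


# ---------------------------------------------------------------------------
# locomotion


def gen_locomotion(
    bouts: Sequence[tuple[float, float, float]],
    duration: float,
    sample_rate: float = 40.0,
) -> LocomotionTrace:
    """Generate a locomotion trace: speed nonzero exactly within bouts.

    bouts: (start_s, end_s, speed) tuples; must be non-overlapping and lie
    within [0, duration].
    """
    srt = sorted(bouts)
    for (s0, e0, _), (s1, _, _) in zip(srt, srt[1:]):
        if s1 < e0:
            raise ValueError("overlapping locomotion bouts")
    for s, e, _ in srt:
        if s < 0 or e > duration or e <= s:
            raise ValueError("bout outside recording or empty")
    n = int(round(duration * sample_rate))
    speed = np.zeros(n)
    for s, e, v in srt:
        i0, i1 = int(round(s * sample_rate)), int(round(e * sample_rate))
        speed[i0:i1] = v
    return LocomotionTrace(speed=speed, sample_rate=sample_rate)


# ---------------------------------------------------------------------------
# anatomy phantoms


def gen_anatomy_stack(
    segments: Sequence[tuple],
    pericytes: Sequence[tuple] = (),
    voxel_size: tuple = (1.0, 0.45, 0.45),
    shape: tuple = (40, 128, 128),
    noise_sd: float = 0.0,
    amplitude: float = 200.0,
    background: float = 10.0,
    seed: int = 0,
) -> tuple[AnatomyStack, PericyteSet, GroundTruth]:
    """Generate a 3D tube-network phantom with known centreline geometry.

    segments: ((z0,y0,x0), (z1,y1,x1), radius_um) with endpoints in um.
    pericytes: (segment_index, fraction_along, constriction_fraction,
    extent_um) — the tube radius near the soma is reduced by the stated
    fraction with a Gaussian axial profile of sigma = extent.

    Ground truth records total centreline length (um) and, per segment, the
    radius profile used.
    """
    if not segments:
        raise ValueError("need at least one segment")
    vz = np.asarray(voxel_size, dtype=float)
    segs = []
    for p0, p1, r in segments:
        p0 = np.asarray(p0, dtype=float)
        p1 = np.asarray(p1, dtype=float)
        length = np.linalg.norm(p1 - p0)
        if length == 0:
            raise ValueError("degenerate zero-length segment")
        if r < max(voxel_size):
            raise ValueError("segment radius below one voxel")
        segs.append((p0, p1, float(r), length))

    soma_info = []  # (seg_idx, position_um (3,), constriction, extent)
    for seg_idx, frac, constr, extent in pericytes:
        p0, p1, r, length = segs[seg_idx]
        pos = p0 + frac * (p1 - p0)
        soma_info.append((seg_idx, pos, float(constr), float(extent)))

    zz, yy, xx = np.meshgrid(
        np.arange(shape[0]) * vz[0],
        np.arange(shape[1]) * vz[1],
        np.arange(shape[2]) * vz[2],
        indexing="ij",
    )
    coords = np.stack([zz, yy, xx], axis=-1)  # um
    vol = np.full(shape, background)

    for seg_idx, (p0, p1, r, length) in enumerate(segs):
        d = (p1 - p0) / length
        rel = coords - p0
        s = rel @ d                               # axial position, um
        s_cl = np.clip(s, 0.0, length)
        closest = p0 + s_cl[..., None] * d
        dist = np.linalg.norm(coords - closest, axis=-1)
        r_local = np.full(shape, r)
        for sidx, pos, constr, extent in soma_info:
            if sidx != seg_idx:
                continue
            s_soma = (pos - p0) @ d
            r_local = r_local * (
                1.0 - constr * np.exp(-0.5 * ((s_cl - s_soma) / extent) ** 2)
            )
        inside = dist <= r_local
        vol = np.where(inside, background + amplitude, vol)

    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        vol = vol + rng.normal(0.0, noise_sd, shape)

    stack = AnatomyStack(data=vol, voxel_size=tuple(vz))
    soma_pos = np.array([pos for _, pos, _, _ in soma_info]).reshape(-1, 3)
    pset = PericyteSet(positions_um=soma_pos)
    total_len = float(sum(length for *_, length in segs))
    gt = GroundTruth(
        true_network_length=total_len,
        true_radii=np.array([r for _, _, r, _ in segs]),
        seed=seed,
        extras={
            "n_segments": len(segs),
            "pericytes": [
                {"segment": int(i), "constriction": c, "extent_um": e}
                for (i, _, c, e) in soma_info
            ],
        },
    )
    return stack, pset, gt


# ---------------------------------------------------------------------------
# pose tracking


def gen_tracking(
    path: Sequence[tuple[float, float]],
    wheel_rotations: float = 0.0,
    fps: float = 30.0,
    duration: float | None = None,
    px_per_cm: float = 10.0,
    dropout_rate: float = 0.0,
    wheel_center: tuple[float, float] = (300.0, 60.0),
    wheel_radius_px: float = 30.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate a pose-estimation output table following a waypoint path.

    The mouse centroid moves at constant speed along the polyline ``path``
    (waypoints in cm); the four body-part labels are placed at fixed offsets
    around the centroid.  Wheel markers rotate ``wheel_rotations`` times
    around a fixed hub.  ``dropout_rate`` of frames get likelihood < 1
    (tracking failures); all other rows have likelihood exactly 1.

    Returns a tidy table (frame, label, x, y, likelihood) and ground truth
    with the polyline path length in cm.
    """
    path = np.asarray(path, dtype=float)
    seg_len = np.linalg.norm(np.diff(path, axis=0), axis=1)
    path_length = float(seg_len.sum())
    if duration is None:
        duration = 60.0
    n_frames = int(round(duration * fps))
    rng = np.random.default_rng(seed)

    # arc-length parameterization: constant speed along the polyline
    s = np.linspace(0.0, path_length, n_frames) if path_length > 0 else np.zeros(n_frames)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    centroid = np.empty((n_frames, 2))
    for i, si in enumerate(s):
        j = min(np.searchsorted(cum, si, side="right") - 1, len(seg_len) - 1)
        if len(seg_len) == 0 or seg_len[j] == 0:
            centroid[i] = path[0]
        else:
            f = (si - cum[j]) / seg_len[j]
            centroid[i] = path[j] + f * (path[j + 1] - path[j])
    centroid_px = centroid * px_per_cm

    body_offsets = {
        "head": (8.0, 0.0),
        "left_headplate": (4.0, -5.0),
        "right_headplate": (4.0, 5.0),
        "tail": (-12.0, 0.0),
    }
    angle = np.linspace(0.0, 2 * np.pi * wheel_rotations, n_frames)
    cx, cy = wheel_center
    wheel = {
        "wheel_inner": np.stack(
            [cx + 0.6 * wheel_radius_px * np.cos(angle),
             cy + 0.6 * wheel_radius_px * np.sin(angle)], axis=1),
        "wheel_outer": np.stack(
            [cx + wheel_radius_px * np.cos(angle),
             cy + wheel_radius_px * np.sin(angle)], axis=1),
    }

    dropped = rng.random(n_frames) < dropout_rate
    rows = []
    for i in range(n_frames):
        lk = float(rng.uniform(0.2, 0.99)) if dropped[i] else 1.0
        for label, (dx, dy) in body_offsets.items():
            rows.append((i, label, centroid_px[i, 0] + dx, centroid_px[i, 1] + dy, lk))
        for label, posarr in wheel.items():
            rows.append((i, label, posarr[i, 0], posarr[i, 1], lk))
    table = pd.DataFrame(rows, columns=["frame", "label", "x", "y", "likelihood"])

    gt = GroundTruth(
        true_path_length=path_length,
        seed=seed,
        extras={
            "dropout_rate": dropout_rate,
            "n_dropped_frames": int(dropped.sum()),
            "wheel_rotations": wheel_rotations,
            "px_per_cm": px_per_cm,
            "fps": fps,
        },
    )
    return table, gt


# ---------------------------------------------------------------------------
# full cohort


GROUPS = ("E3EX", "E3NOEX", "E4EX", "E4NOEX")

#: Default planted effect structure.  Multipliers scale, per group: the
#: probability that a trial is responsive, the dilation amplitude of
#: responsive trials, and the neuronal calcium response amplitude.  The
#: qualitative pattern — a genotype deficit, an exercise benefit, a synergy
#: making the sedentary-E4 group worst, and active-E4 neuronal responses
#: slightly enhanced — mirrors the group structure the study conditions
#: describe.
DEFAULT_EFFECT_TABLE = {
    "E3EX":   {"resp_prob": 1.00, "resp_amp": 1.00, "neuro_amp": 1.00},
    "E3NOEX": {"resp_prob": 0.80, "resp_amp": 0.85, "neuro_amp": 0.90},
    "E4EX":   {"resp_prob": 0.70, "resp_amp": 0.75, "neuro_amp": 1.10},
    "E4NOEX": {"resp_prob": 0.48, "resp_amp": 0.57, "neuro_amp": 0.70},
}

BASE_RESP_PROB = 0.95        # E3EX pial responsiveness is near-ceiling
BASE_RESP_AMP = 8.0          # % peak dilation of a responsive trial
BASE_NEURO_AMP = 0.8         # dF/F peak of stimulus response


@dataclass
class VesselRecord:
    mouse: str
    group: str
    genotype: str
    exercise: str
    timepoint: int
    vessel_id: str
    baseline_diameter: float
    superficial: bool
    diameter: np.ndarray           # um per frame
    frame_rate: float


@dataclass
class MouseRecord:
    mouse: str
    group: str
    genotype: str
    exercise: str
    timepoint: int
    schedule: StimulusSchedule
    locomotion: LocomotionTrace
    calcium: CalciumTraces | None
    vessels: list


@dataclass
class CohortBundle:
    """In-memory synthetic study: one MouseRecord per mouse x timepoint,
    plus the ground-truth manifest."""

    mice: list
    manifest: dict

    def groups(self):
        return sorted({m.group for m in self.mice})


def gen_cohort(
    effect_table: dict | None = None,
    n_mice_per_group: int = 3,
    vessels_per_mouse: int = 6,
    cells_per_mouse: int = 8,
    timepoints: Sequence[int] = (1,),
    n_stims: int = 20,
    frame_rate: float = 7.63,
    noise_sd_pct: float = 1.0,
    vasomotion_amp: float = 0.02,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> CohortBundle:
    """Generate a full synthetic study bundle with planted group effects.

    Per mouse and timepoint: a stimulus schedule, a locomotion trace with a
    few bouts, calcium traces, and per-vessel diameter traces where each
    trial is responsive with probability BASE_RESP_PROB * resp_prob
    multiplier and responsive trials carry a gamma transient of amplitude
    BASE_RESP_AMP * resp_amp multiplier (% of baseline diameter, with mild
    lognormal jitter).  Diameter traces also carry a 0.1 Hz vasomotion
    oscillation and white noise.

    If ``out_dir`` is given the bundle is also written to disk in the
    pipeline's input formats (CSV/JSON) together with the ground-truth
    manifest; see :func:`write_bundle`.
    """
    table = effect_table or DEFAULT_EFFECT_TABLE
    rng = np.random.default_rng(seed)
    mice = []
    manifest: dict = {
        "seed": seed,
        "effect_table": table,
        "base": {"resp_prob": BASE_RESP_PROB, "resp_amp": BASE_RESP_AMP,
                 "neuro_amp": BASE_NEURO_AMP},
        "mice": {},
    }

    for group in table:
        genotype = "APOE4" if group.startswith("E4") else "APOE3"
        exercise = "no-wheel" if "NOEX" in group else "wheel"
        eff = table[group]
        for m in range(n_mice_per_group):
            for tp in timepoints:
                mouse_id = f"{group}_m{m}"
                sched = StimulusSchedule.default(n_stims=n_stims)
                duration = sched.onsets[-1] + sched.stim_dur + sched.isi
                # sparse bouts well clear of most stimuli
                bouts = []
                for b in range(2):
                    start = float(rng.uniform(0, duration - 4))
                    bouts.append((start, start + 2.0, 5.0))
                bouts = _merge_bouts(bouts)
                loco = gen_locomotion(bouts, duration, sample_rate=frame_rate)

                cal_amp = BASE_NEURO_AMP * eff["neuro_amp"]
                classes = ["ON"] * (cells_per_mouse // 2) + \
                          ["BOTH"] * (cells_per_mouse - cells_per_mouse // 2)
                calcium, _ = gen_calcium(
                    classes, amp=cal_amp, noise_sd=0.03, schedule=sched,
                    sample_rate=frame_rate,
                    seed=int(rng.integers(2**31)),
                )

                vessels = []
                vt = {}
                for v in range(vessels_per_mouse):
                    base_d = float(rng.uniform(14.0, 25.0))  # pial-range
                    p = min(BASE_RESP_PROB * eff["resp_prob"], 1.0)
                    responsive = rng.random(n_stims) < p
                    amp_pct = BASE_RESP_AMP * eff["resp_amp"] * \
                        rng.lognormal(0.0, 0.1, n_stims)
                    n = int(round(duration * frame_rate))
                    t = np.arange(n) / frame_rate
                    trace = np.full(n, base_d)
                    # vasomotion band, not a pure tone: per-vessel frequency
                    # in 0.08-0.12 Hz so its phase is not locked to the
                    # 30 s trial cycle
                    vm_f = rng.uniform(0.08, 0.12)
                    trace *= 1.0 + vasomotion_amp * np.sin(
                        2 * np.pi * vm_f * t + rng.uniform(0, 2 * np.pi))
                    for k, onset in enumerate(sched.onsets):
                        if responsive[k]:
                            _add_transients(trace, frame_rate,
                                            np.array([onset]),
                                            amp_pct[k] / 100.0 * base_d)
                    trace += rng.normal(0.0, noise_sd_pct / 100.0 * base_d, n)
                    vid = f"{mouse_id}_v{v}"
                    vessels.append(VesselRecord(
                        mouse=mouse_id, group=group, genotype=genotype,
                        exercise=exercise, timepoint=tp, vessel_id=vid,
                        baseline_diameter=base_d, superficial=True,
                        diameter=trace, frame_rate=frame_rate))
                    vt[vid] = {
                        "true_responsive": responsive.tolist(),
                        "true_amp_pct": amp_pct.tolist(),
                        "baseline_diameter": base_d,
                    }
                mice.append(MouseRecord(
                    mouse=mouse_id, group=group, genotype=genotype,
                    exercise=exercise, timepoint=tp, schedule=sched,
                    locomotion=loco, calcium=calcium, vessels=vessels))
                manifest["mice"][f"{mouse_id}_tp{tp}"] = {
                    "group": group, "timepoint": tp,
                    "neuro_amp": cal_amp, "vessels": vt,
                }

    bundle = CohortBundle(mice=mice, manifest=manifest)
    if out_dir is not None:
        write_bundle(bundle, out_dir)
    return bundle


def _merge_bouts(bouts):
    """Drop bouts that overlap an earlier one (keeps generation valid)."""
    out = []
    for s, e, v in sorted(bouts):
        if out and s < out[-1][1]:
            continue
        out.append((s, e, v))
    return out


def write_bundle(bundle: CohortBundle, out_dir: str | Path) -> Path:
    """Write a cohort bundle to disk in the pipeline's input formats.

    Layout: one directory per mouse x timepoint containing stimulus.json,
    locomotion.csv, calcium.csv (cells as columns) and one diameter CSV per
    vessel; ground_truth.json and cohort.csv (metadata) at the root.
    """
    root = Path(out_dir)
    root.mkdir(parents=True, exist_ok=True)
    meta_rows = []
    for m in bundle.mice:
        d = root / f"{m.mouse}_tp{m.timepoint}"
        d.mkdir(exist_ok=True)
        with open(d / "stimulus.json", "w") as fh:
            json.dump(m.schedule.to_dict(), fh)
        pd.DataFrame({
            "time_s": np.arange(len(m.locomotion.speed)) / m.locomotion.sample_rate,
            "speed": m.locomotion.speed,
        }).to_csv(d / "locomotion.csv", index=False)
        if m.calcium is not None:
            cal = pd.DataFrame(m.calcium.dff.T, columns=m.calcium.cell_ids)
            cal.insert(0, "time_s",
                       np.arange(m.calcium.dff.shape[1]) / m.calcium.sample_rate)
            cal.to_csv(d / "calcium.csv", index=False)
        for v in m.vessels:
            pd.DataFrame({
                "time_s": np.arange(len(v.diameter)) / v.frame_rate,
                "diameter_um": v.diameter,
            }).to_csv(d / f"{v.vessel_id}.csv", index=False)
            meta_rows.append({
                "mouse": m.mouse, "genotype": m.genotype,
                "exercise": m.exercise, "timepoint": m.timepoint,
                "group": m.group, "vessel_id": v.vessel_id,
                "baseline_diameter_um": v.baseline_diameter,
            })
    pd.DataFrame(meta_rows).to_csv(root / "cohort.csv", index=False)
    with open(root / "ground_truth.json", "w") as fh:
        json.dump(bundle.manifest, fh, indent=1)
    return root
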