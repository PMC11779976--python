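"""Shared data containers for the pipeline.

All physical quantities carry explicit units in their field names or
docstrings: lengths in micrometres (um), velocities in mm/s, rates in Hz,
times in seconds.  Containers validate their invariants at construction so
downstream stages can assume well-formed inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

HEMO_CHANNELS = ("Flux", "Speed", "Hbo", "Hbd", "Hbt", "sO2")


@dataclass
class VesselMovie:
    """Time series of grayscale vessel frames.

    data: intensity array, shape (time, y, x).
    pixel_size: um per pixel.
    frame_rate: frames per second.
    """

    data: np.ndarray
    pixel_size: float
    frame_rate: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3 or self.data.shape[0] < 1:
            raise ValueError("movie data must be (time, y, x) with >=1 frame")
        if self.pixel_size <= 0 or self.frame_rate <= 0:
            raise ValueError("pixel_size and frame_rate must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    def mean_image(self) -> np.ndarray:
        return self.data.mean(axis=0)


@dataclass
class Kymograph:
    """Line-scan image: rows are successive scan lines (time), columns are
    positions along the scanned line.

    line_rate: lines per second.  pixel_size: um per pixel along the line.
    """

    data: np.ndarray
    line_rate: float
    pixel_size: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("kymograph data must be 2D (time x position)")
        if self.line_rate <= 0 or self.pixel_size <= 0:
            raise ValueError("line_rate and pixel_size must be positive")


@dataclass
class SkeletonModel:
    """Vessel centreline: points (pixel or voxel coordinates, row-major
    (y, x) or (z, y, x)), unit tangents, branch-point indices, and an
    optional per-point radius in um."""

    points: np.ndarray
    tangents: np.ndarray | None = None
    branch_points: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    radius_um: np.ndarray | None = None
    total_length_um: float | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.tangents is not None:
            self.tangents = np.asarray(self.tangents, dtype=float)
            norms = np.linalg.norm(self.tangents, axis=1)
            if not np.allclose(norms[norms > 0], 1.0, atol=1e-6):
                raise ValueError("tangents must be unit-norm")

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class DiameterTrace:
    """Per-frame vessel diameter in um.

    Invalid frames hold NaN in ``values`` and a reason code in ``reasons``.
    """

    values: np.ndarray
    frame_rate: float
    n_valid_points: np.ndarray | None = None
    reasons: list | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        valid = self.values[np.isfinite(self.values)]
        if np.any(valid <= 0):
            raise ValueError("valid diameters must be positive")

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.values)) / self.frame_rate

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.values)


@dataclass
class VelocityTrace:
    """Red-blood-cell velocity per analysis window, mm/s.

    quality: normalized radon variance contrast per window; windows whose
    quality fell below the floor hold NaN and valid=False.
    """

    values: np.ndarray
    window_centers: np.ndarray
    quality: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.window_centers = np.asarray(self.window_centers, dtype=float)
        if len(self.window_centers) > 1 and np.any(np.diff(self.window_centers) <= 0):
            raise ValueError("window_centers must be strictly increasing")


@dataclass
class StimulusSchedule:
    """Visual stimulation protocol: onset times (s), stimulus duration and
    inter-stimulus interval.  Defaults follow the 5 s drifting grating / 25 s
    grey screen protocol repeated 20 times."""

    onsets: np.ndarray
    stim_dur: float = 5.0
    isi: float = 25.0

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=float)
        if np.any(np.diff(self.onsets) < self.stim_dur):
            raise ValueError("stimulus onsets closer than stim_dur")

    @property
    def n_stims(self) -> int:
        return len(self.onsets)

    @classmethod
    def default(cls, n_stims: int = 20, stim_dur: float = 5.0, isi: float = 25.0,
                first_onset: float | None = None) -> "StimulusSchedule":
        if first_onset is None:
            first_onset = stim_dur  # leave a full baseline before stim 1
        onsets = first_onset + np.arange(n_stims) * (stim_dur + isi)
        return cls(onsets=onsets, stim_dur=stim_dur, isi=isi)

    def to_dict(self) -> dict:
        return {"onsets": self.onsets.tolist(), "stim_dur": self.stim_dur,
                "isi": self.isi}

    @classmethod
    def from_dict(cls, d: dict) -> "StimulusSchedule":
        return cls(onsets=np.asarray(d["onsets"]), stim_dur=d["stim_dur"],
                   isi=d["isi"])


@dataclass
class LocomotionTrace:
    """Locomotion speed per sample (arbitrary encoder units; only the
    zero/nonzero distinction feeds trial gating)."""

    speed: np.ndarray
    sample_rate: float

    def __post_init__(self) -> None:
        self.speed = np.asarray(self.speed, dtype=float)
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")

    @property
    def duration(self) -> float:
        return len(self.speed) / self.sample_rate


@dataclass
class HemoRecording:
    """Multi-channel haemodynamic recording from a combined laser-Doppler /
    haemoglobin-spectroscopy probe, default 40 Hz.

    Channels: Flux, Speed, Hbo, Hbd, Hbt, sO2.  On construction Hbt is
    checked for consistency with Hbo + Hbd (warning beyond 5% median
    relative mismatch — real probes drift)."""

    channels: pd.DataFrame
    sample_rate: float = 40.0
    hbt_tolerance: float = 0.05

    def __post_init__(self) -> None:
        missing = [c for c in HEMO_CHANNELS if c not in self.channels.columns]
        if missing:
            raise ValueError(f"missing hemo channels: {missing}")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        so2 = self.channels["sO2"].to_numpy()
        if np.any((so2 < 0) | (so2 > 100)):
            raise ValueError("sO2 must lie in [0, 100]")
        hbt = self.channels["Hbt"].to_numpy()
        recon = self.channels["Hbo"].to_numpy() + self.channels["Hbd"].to_numpy()
        with np.errstate(divide="ignore", invalid="ignore"):
            rel = np.abs(hbt - recon) / np.where(hbt != 0, hbt, np.nan)
        if np.nanmedian(rel) > self.hbt_tolerance:
            import warnings

            warnings.warn("Hbt deviates from Hbo + Hbd beyond tolerance",
                          stacklevel=2)

    def __len__(self) -> int:
        return len(self.channels)

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.channels)) / self.sample_rate


@dataclass
class CalciumTraces:
    """Neuronal dF/F traces, shape (cell, sample)."""

    dff: np.ndarray
    sample_rate: float
    cell_ids: list | None = None

    def __post_init__(self) -> None:
        self.dff = np.atleast_2d(np.asarray(self.dff, dtype=float))
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if not np.all(np.isfinite(self.dff)):
            raise ValueError("dF/F traces must be finite")
        if self.cell_ids is None:
            self.cell_ids = [f"cell{i}" for i in range(self.dff.shape[0])]

    @property
    def n_cells(self) -> int:
        return self.dff.shape[0]


@dataclass
class TrialSet:
    """Stimulus-locked trial matrix.

    trials: shape (n_trials, n_samples), each row cut to
    baseline + stimulus + post (default 5 + 5 + 20 s).
    retained: gating flags; excluded trials keep their data but carry an
    exclusion reason and are skipped by downstream aggregation.
    """

    trials: np.ndarray
    sample_rate: float
    stim_dur: float = 5.0
    baseline_span: float = 5.0
    post_span: float = 20.0
    retained: np.ndarray | None = None
    exclusion_reasons: list | None = None
    onset_times: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.trials = np.atleast_2d(np.asarray(self.trials, dtype=float))
        if self.retained is None:
            self.retained = np.ones(self.trials.shape[0], dtype=bool)
        self.retained = np.asarray(self.retained, dtype=bool)
        if self.exclusion_reasons is None:
            self.exclusion_reasons = [None] * self.trials.shape[0]

    @property
    def n_trials(self) -> int:
        return self.trials.shape[0]

    @property
    def onset_index(self) -> int:
        """Sample index of stimulus onset within each trial row."""
        return int(round(self.baseline_span * self.sample_rate))

    @property
    def offset_index(self) -> int:
        return int(round((self.baseline_span + self.stim_dur) * self.sample_rate))


@dataclass
class AnatomyStack:
    """Post-mortem confocal z-stack.  data shape (z, y, x); voxel_size in
    um per axis, ordered (z, y, x)."""

    data: np.ndarray
    voxel_size: tuple

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("stack must be 3D (z, y, x)")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size must be 3 positive values (z, y, x)")

    @property
    def volume_mm3(self) -> float:
        nvox = self.data.size
        um3 = nvox * np.prod(self.voxel_size)
        return float(um3 / 1e9)


@dataclass
class PericyteSet:
    """Pericyte soma positions in um, (z, y, x) order, plus the index of the
    nearest skeleton point once snapped."""

    positions_um: np.ndarray
    nearest_skeleton_index: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.positions_um = np.atleast_2d(np.asarray(self.positions_um, dtype=float))

    def __len__(self) -> int:
        return len(self.positions_um)


@dataclass
class PowerSpectrum:
    """One-sided power spectral density on a common frequency grid <= 1 Hz."""

    freqs: np.ndarray
    power: np.ndarray
    source_length_s: float

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("freqs must be strictly increasing")
        if np.any(self.power < 0):
            raise ValueError("power must be non-negative")
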