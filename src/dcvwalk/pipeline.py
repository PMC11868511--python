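"""Kymograph-track ingestion, cleaning, classification, and statistics.

Consumes the tabular dialect of kymograph-tracing tools (one row per track
point: ``track_id, frame, x_px``), converts pixels/frames to µm/s, averages
duplicated time points, classifies each track as retrograde / stationary /
anterograde by its mean speed, and extracts the three observables the
heterogeneous random-walk model speaks about:

* integer displacement step counts at fixed lags (beta-binomial samples),
* ensemble mean/variance curves of displacement versus lag,
* empirical first-passage times to fixed distance thresholds.

Retrograde (dynein-driven, towards the cell body) displacement is mapped to
positive values regardless of the kymograph's drawing direction; the model is
one-sided.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .params import DEFAULT_STEP_SIZE_UM, ModelParams

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "Track",
    "FptSample",
    "EnsembleStats",
    "read_tracks",
    "dedupe_timepoints",
    "classify_track",
    "classify_tracks",
    "displacement_at_lag",
    "collect_displacements",
    "empirical_moments",
    "empirical_fpt",
    "collect_fpts",
]

RETROGRADE = "retrograde"
STATIONARY = "stationary"
ANTEROGRADE = "anterograde"
UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class PipelineConfig:
    """Physical constants and analysis choices of the track pipeline.

    ``retro_threshold_px_per_frame`` is the mean-speed cut separating directed
    from stationary tracks: a track is directed when its net displacement in
    pixels is at least threshold × frames spanned (boundary inclusive).  1.6
    px/frame suits wild-type recordings; 1.0 px/frame the slower kinesin
    light-chain mutants.  ``steps_per_frame`` links the camera frame interval
    to the model's elementary step time (``tau = frame_interval /
    steps_per_frame``).
    """

    pixel_size_um: float = DEFAULT_STEP_SIZE_UM
    frame_interval_s: float = 0.1563
    steps_per_frame: int = 10
    retro_threshold_px_per_frame: float = 1.6
    direction_sign: str = "negative_is_retrograde"
    lags_s: tuple[float, ...] = (1.563, 3.126)
    fpt_thresholds_um: tuple[float, ...] = (1.84, 3.68)

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0 or self.frame_interval_s <= 0:
            raise ValueError("pixel size and frame interval must be positive")
        if self.steps_per_frame < 1:
            raise ValueError("steps_per_frame must be >= 1")
        if self.retro_threshold_px_per_frame < 0:
            raise ValueError("speed threshold must be non-negative")
        if self.direction_sign not in (
            "negative_is_retrograde",
            "positive_is_retrograde",
        ):
            raise ValueError(f"unknown direction_sign {self.direction_sign!r}")
        if any(lag <= 0 for lag in self.lags_s):
            raise ValueError("lags must be positive")

    @property
    def step_time_s(self) -> float:
        """Elementary step time tau implied by the frame interval."""
        return self.frame_interval_s / self.steps_per_frame

    @property
    def retro_sign(self) -> int:
        """Sign of raw pixel displacement that counts as retrograde."""
        return -1 if self.direction_sign == "negative_is_retrograde" else 1

    def model_params(self, alpha: float, beta: float) -> ModelParams:
        """Model parameters on this pipeline's space/time lattice."""
        return ModelParams(
            alpha=alpha,
            beta=beta,
            step_size_um=self.pixel_size_um,
            step_time_s=self.step_time_s,
        )

    def lag_frames(self, lag_s: float, *, rtol: float = 1e-6) -> int:
        """Lag expressed in frames; errors unless an integer multiple."""
        ratio = lag_s / self.frame_interval_s
        m = round(ratio)
        if m < 1 or abs(ratio - m) > rtol * max(1.0, ratio):
            raise ValueError(
                f"lag {lag_s} s is not a positive integer multiple of the "
                f"frame interval {self.frame_interval_s} s"
            )
        return int(m)

    # -- YAML round trip ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "pixel_size_um": self.pixel_size_um,
            "frame_interval_s": self.frame_interval_s,
            "steps_per_frame": self.steps_per_frame,
            "retro_threshold_px_per_frame": self.retro_threshold_px_per_frame,
            "direction_sign": self.direction_sign,
            "lags_s": list(self.lags_s),
            "fpt_thresholds_um": list(self.fpt_thresholds_um),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        kwargs = dict(d)
        for key in ("lags_s", "fpt_thresholds_um"):
            if key in kwargs:
                kwargs[key] = tuple(float(v) for v in kwargs[key])
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class Track:
    """One particle trajectory in tracker units (frames, pixels)."""

    track_id: str
    frames: np.ndarray
    x_px: np.ndarray
    class_label: str = UNCLASSIFIED

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        self.x_px = np.asarray(self.x_px, dtype=float)
        if self.frames.shape != self.x_px.shape or self.frames.ndim != 1:
            raise ValueError("frames and x_px must be 1-d arrays of equal length")

    def __len__(self) -> int:
        return len(self.frames)

    def times_s(self, config: PipelineConfig) -> np.ndarray:
        return self.frames * config.frame_interval_s

    def x_um(self, config: PipelineConfig) -> np.ndarray:
        return self.x_px * config.pixel_size_um

    @property
    def frames_spanned(self) -> int:
        return int(self.frames[-1] - self.frames[0]) if len(self) else 0


@dataclass(frozen=True)
class FptSample:
    """Empirical first passage of one track across a distance threshold."""

    track_id: str
    threshold_um: float
    t_first_s: float  # nan when censored
    censored: bool


@dataclass(frozen=True)
class EnsembleStats:
    """Per-lag displacement mean/variance across a track ensemble."""

    lags_s: np.ndarray
    mean_um: np.ndarray
    var_um2: np.ndarray
    n_tracks: np.ndarray


# ---------------------------------------------------------------------------
# Ingestion and cleaning
# ---------------------------------------------------------------------------

REQUIRED_COLUMNS = ("track_id", "frame", "x_px")


def read_tracks(path, config: PipelineConfig | None = None) -> list[Track]:
    """Read a tracker CSV (track_id, frame, x_px) into Track objects.

    Rows with missing or non-numeric frame/position are dropped (count
    logged); tracks are grouped by id and sorted by frame.  Missing columns
    or an empty file raise ``ValueError``.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    if len(df) == 0:
        raise ValueError(f"{path}: file contains no track points")
    n_raw = len(df)
    df["frame"] = pd.to_numeric(df["frame"], errors="coerce")
    df["x_px"] = pd.to_numeric(df["x_px"], errors="coerce")
    df = df.dropna(subset=["track_id", "frame", "x_px"])
    n_bad = n_raw - len(df)
    if n_bad:
        logger.warning("%s: dropped %d malformed row(s)", path, n_bad)
    if len(df) == 0:
        raise ValueError(f"{path}: no well-formed track points")
    tracks = []
    for tid, grp in df.groupby("track_id", sort=True):
        grp = grp.sort_values("frame", kind="stable")
        tracks.append(
            Track(
                track_id=str(tid),
                frames=grp["frame"].to_numpy().astype(np.int64),
                x_px=grp["x_px"].to_numpy(dtype=float),
            )
        )
    return tracks


def dedupe_timepoints(track: Track) -> Track:
    """Average positions recorded at the same frame.

    Tracing tools can emit two x positions for one time point (two branches
    of a kymograph trace meeting); the cleaned track carries their arithmetic
    mean, leaving frames strictly increasing.
    """
    frames, inverse = np.unique(track.frames, return_inverse=True)
    if len(frames) == len(track.frames):
        return replace(track)
    sums = np.zeros(len(frames))
    counts = np.zeros(len(frames))
    np.add.at(sums, inverse, track.x_px)
    np.add.at(counts, inverse, 1.0)
    return replace(track, frames=frames, x_px=sums / counts)


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------


def classify_track(track: Track, config: PipelineConfig) -> str:
    """Label a track retrograde / stationary / anterograde by mean speed.

    Let ``d`` be the net displacement in pixels and ``F`` the frames spanned.
    The track is directed when ``|d| >= threshold * F`` (boundary inclusive);
    its direction relative to ``direction_sign`` picks retrograde vs
    anterograde.  Otherwise stationary.  Single-point tracks are
    unclassified.
    """
    if len(track) < 2:
        return UNCLASSIFIED
    d = track.x_px[-1] - track.x_px[0]
    span = track.frames_spanned
    if span <= 0:
        return UNCLASSIFIED
    if abs(d) >= config.retro_threshold_px_per_frame * span and d != 0:
        return RETROGRADE if d * config.retro_sign > 0 else ANTEROGRADE
    return STATIONARY


def classify_tracks(tracks: list[Track], config: PipelineConfig) -> list[Track]:
    """Classify every track in place; returns the same list for chaining."""
    for tr in tracks:
        tr.class_label = classify_track(tr, config)
    return tracks


# ---------------------------------------------------------------------------
# Displacement samples and moments
# ---------------------------------------------------------------------------


def _position_at_frame(track: Track, frame: float) -> float:
    """Pixel position at a frame, linearly interpolated between samples."""
    return float(np.interp(frame, track.frames, track.x_px))


def displacement_at_lag(
    track: Track, lag_s: float, config: PipelineConfig
) -> int | None:
    """Integer step count moved in ``lag_s`` from the track's first point.

    Returns ``k = clamp(round(retro_displacement / pixel), 0, n)`` where
    ``n = lag / tau`` is the number of elementary steps in the lag, or
    ``None`` when the track does not span the lag.  Small anti-retrograde
    excursions round below zero and are clamped to 0 (logged); the model is
    one-sided and reversal rates in these recordings are low.
    """
    m = config.lag_frames(lag_s)
    if track.frames_spanned < m:
        return None
    f0 = track.frames[0]
    d_px = _position_at_frame(track, f0 + m) - track.x_px[0]
    steps = d_px * config.retro_sign  # 1 step == 1 px
    n = m * config.steps_per_frame
    k = round(steps)
    if k < 0:
        logger.debug(
            "track %s: negative displacement %.2f px clamped to 0", track.track_id,
            steps,
        )
    return int(min(max(k, 0), n))


def collect_displacements(
    tracks: list[Track],
    lag_s: float,
    config: PipelineConfig,
    *,
    strain_label: str = "",
):
    """Beta-binomial sample of step counts from the retrograde tracks.

    Only retrograde-classified tracks spanning the lag contribute; the
    resulting :class:`~dcvwalk.inference.DisplacementSample` is the unit the
    likelihood consumes.
    """
    from .inference import DisplacementSample  # local import to avoid a cycle

    ks = []
    for tr in tracks:
        if tr.class_label != RETROGRADE:
            continue
        k = displacement_at_lag(tr, lag_s, config)
        if k is not None:
            ks.append(k)
    n = config.lag_frames(lag_s) * config.steps_per_frame
    return DisplacementSample(
        k_values=np.asarray(ks, dtype=np.int64),
        n_trials=n,
        t_seconds=lag_s,
        strain_label=strain_label,
    )


def empirical_moments(
    tracks: list[Track],
    config: PipelineConfig,
    lags_s: tuple[float, ...] | None = None,
) -> EnsembleStats:
    """Sample mean/variance (µm, µm²) of retrograde displacement per lag.

    Lags with fewer than two contributing tracks are omitted with a warning.
    Displacements are the signed retrograde-positive distances in µm from
    each track's first point (not integer-rounded).
    """
    lags = tuple(lags_s) if lags_s is not None else config.lags_s
    retro = [t for t in tracks if t.class_label == RETROGRADE]
    out_lags, means, variances, counts = [], [], [], []
    for lag in lags:
        m = config.lag_frames(lag)
        vals = []
        for tr in retro:
            if tr.frames_spanned < m:
                continue
            d_px = _position_at_frame(tr, tr.frames[0] + m) - tr.x_px[0]
            vals.append(d_px * config.retro_sign * config.pixel_size_um)
        if len(vals) < 2:
            logger.warning(
                "lag %.4g s: only %d track(s) span it; omitted", lag, len(vals)
            )
            continue
        v = np.asarray(vals)
        out_lags.append(lag)
        means.append(v.mean())
        variances.append(v.var(ddof=1))
        counts.append(len(v))
    return EnsembleStats(
        lags_s=np.asarray(out_lags),
        mean_um=np.asarray(means),
        var_um2=np.asarray(variances),
        n_tracks=np.asarray(counts, dtype=np.int64),
    )


# ---------------------------------------------------------------------------
# First passage times
# ---------------------------------------------------------------------------


def empirical_fpt(
    track: Track, threshold_um: float, config: PipelineConfig
) -> FptSample:
    """First time the track's retrograde displacement reaches a threshold.

    The crossing time is the first *frame* time (relative to the track start)
    at which cumulative retrograde displacement from the origin is >= the
    threshold; censored when the track ends first.
    """
    if threshold_um <= 0:
        raise ValueError("FPT threshold must be positive")
    disp_um = (
        (track.x_px - track.x_px[0]) * config.retro_sign * config.pixel_size_um
    )
    # sub-nanometre slack so px -> µm rounding cannot push an exact-threshold
    # crossing (e.g. 20 px * 0.092 µm vs 1.84 µm) one frame late
    hits = np.nonzero(disp_um >= threshold_um * (1.0 - 1e-9))[0]
    if len(hits) == 0:
        return FptSample(track.track_id, threshold_um, float("nan"), True)
    t = (track.frames[hits[0]] - track.frames[0]) * config.frame_interval_s
    return FptSample(track.track_id, threshold_um, float(t), False)


def collect_fpts(
    tracks: list[Track], threshold_um: float, config: PipelineConfig
) -> list[FptSample]:
    """Empirical FPTs of all retrograde-classified tracks (incl. censored)."""
    return [
        empirical_fpt(tr, threshold_um, config)
        for tr in tracks
        if tr.class_label == RETROGRADE
    ]
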