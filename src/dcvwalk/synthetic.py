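"""Labelled synthetic kymograph-track ensembles for end-to-end testing.

Generates track CSV files in the tracker dialect consumed by
:mod:`dcvwalk.pipeline`, mixing three behavioural classes:

* **retrograde** — heterogeneous random walks (one Beta(alpha, beta) draw of
  the movement probability per track).  Per-frame increments are drawn as
  Binomial(steps_per_frame, p), which is the exact law of the elementary walk
  observed every ``steps_per_frame`` steps;
* **stationary** — Gaussian jitter about a fixed position;
* **anterograde** — constant drift in the opposite direction, enough to
  exercise the classifier (kinesin-driven statistics are not modelled).

Optional additive Gaussian localization noise perturbs every written
position.  A JSON manifest records the configuration and each track's true
class and movement probability, so classifier and fit recovery can be scored
exactly.  Presets carry the beta-density shapes estimated for the wild-type
(``ida-1::gfp``) and kinesin-light-chain mutant (``klc-1(-)``, ``klc-2(rf)``)
C. elegans strains.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .params import ModelParams
from .pipeline import PipelineConfig

__all__ = [
    "GeneratorConfig",
    "generate_dataset",
    "strain_preset",
    "strain_pipeline_config",
    "STRAIN_PRESETS",
]

#: Per-strain beta-density shapes (MLE fits to displacement histograms at
#: t = 1.563 s and 3.126 s), expected retrograde track counts of the same
#: order as the source recordings, and the strain's mean-speed
#: classification threshold in px/frame.
STRAIN_PRESETS: dict[str, dict] = {
    "wild_type": {
        "alpha": 8.19,
        "beta": 12.95,
        "n_retrograde": 851,
        "retro_threshold_px_per_frame": 1.6,
    },
    "klc1": {
        "alpha": 3.18,
        "beta": 4.15,
        "n_retrograde": 438,
        "retro_threshold_px_per_frame": 1.0,
    },
    "klc2": {
        "alpha": 5.12,
        "beta": 12.87,
        "n_retrograde": 1118,
        "retro_threshold_px_per_frame": 1.0,
    },
}

#: Default mixture of behavioural classes (retrograde, stationary,
#: anterograde).  The recordings do not pin the stationary/anterograde
#: proportions; these are plausible placeholders.
DEFAULT_FRACTIONS = (0.5, 0.35, 0.15)

CLASSES = ("retrograde", "stationary", "anterograde")


@dataclass(frozen=True)
class GeneratorConfig:
    """Configuration of one synthetic dataset."""

    params: ModelParams
    fractions: tuple[float, float, float] = DEFAULT_FRACTIONS
    n_tracks: int = 1000
    track_length_frames: tuple[int, int] = (10, 500)
    noise_sigma_px: float = 0.5
    anterograde_speed_px_per_frame: float = 3.0
    stationary_jitter_px: float = 0.3
    steps_per_frame: int = 10
    direction_sign: str = "negative_is_retrograde"
    seed: int = 0

    def __post_init__(self) -> None:
        fr = np.asarray(self.fractions, dtype=float)
        if fr.size != 3 or np.any(fr < 0) or abs(fr.sum() - 1.0) > 1e-12:
            raise ValueError(
                "fractions must be three non-negative numbers summing to 1"
            )
        lo, hi = self.track_length_frames
        if lo < 2 or hi < lo:
            raise ValueError("track_length_frames must satisfy 2 <= min <= max")
        if self.noise_sigma_px < 0 or self.stationary_jitter_px < 0:
            raise ValueError("noise and jitter must be non-negative")
        if self.anterograde_speed_px_per_frame <= 0:
            raise ValueError("anterograde speed must be positive")
        if self.steps_per_frame < 1:
            raise ValueError("steps_per_frame must be >= 1")

    @property
    def frame_interval_s(self) -> float:
        return self.params.step_time_s * self.steps_per_frame

    def to_dict(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "fractions": list(self.fractions),
            "n_tracks": self.n_tracks,
            "track_length_frames": list(self.track_length_frames),
            "noise_sigma_px": self.noise_sigma_px,
            "anterograde_speed_px_per_frame": self.anterograde_speed_px_per_frame,
            "stationary_jitter_px": self.stationary_jitter_px,
            "steps_per_frame": self.steps_per_frame,
            "direction_sign": self.direction_sign,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        kwargs = dict(d)
        kwargs["params"] = ModelParams.from_dict(kwargs["params"])
        kwargs["fractions"] = tuple(kwargs.get("fractions", DEFAULT_FRACTIONS))
        if "track_length_frames" in kwargs:
            kwargs["track_length_frames"] = tuple(kwargs["track_length_frames"])
        return cls(**kwargs)


def strain_preset(strain: str, **overrides) -> GeneratorConfig:
    """Generator configuration mimicking one of the recorded strains.

    ``strain`` is one of ``wild_type``, ``klc1``, ``klc2``.  The preset uses
    that strain's fitted beta shapes, the 0.092 µm / 0.01563 s lattice with
    10 steps per frame, and a total track count chosen so the expected
    number of retrograde tracks matches the order observed for the strain.
    Keyword overrides replace any :class:`GeneratorConfig` field.
    """
    try:
        info = STRAIN_PRESETS[strain]
    except KeyError:
        raise ValueError(
            f"unknown strain {strain!r}; expected one of {sorted(STRAIN_PRESETS)}"
        ) from None
    params = ModelParams(alpha=info["alpha"], beta=info["beta"])
    fractions = overrides.pop("fractions", DEFAULT_FRACTIONS)
    n_tracks = overrides.pop(
        "n_tracks", int(round(info["n_retrograde"] / fractions[0]))
    )
    config = GeneratorConfig(
        params=params, fractions=tuple(fractions), n_tracks=n_tracks
    )
    return replace(config, **overrides) if overrides else config


def strain_pipeline_config(strain: str, **overrides) -> PipelineConfig:
    """Pipeline configuration matching a strain preset's speed threshold."""
    info = STRAIN_PRESETS[strain]
    kwargs = {
        "retro_threshold_px_per_frame": info["retro_threshold_px_per_frame"],
    }
    kwargs.update(overrides)
    return PipelineConfig(**kwargs)


def _class_assignment(config: GeneratorConfig, rng: np.random.Generator):
    """Deterministic largest-remainder class counts, randomly ordered."""
    fr = np.asarray(config.fractions)
    raw = fr * config.n_tracks
    counts = np.floor(raw).astype(int)
    remainder = config.n_tracks - counts.sum()
    order = np.argsort(-(raw - counts))
    counts[order[:remainder]] += 1
    labels = np.repeat(np.arange(3), counts)
    rng.shuffle(labels)
    return [CLASSES[i] for i in labels]


def generate_dataset(config: GeneratorConfig, out_path) -> dict:
    """Write a synthetic track CSV plus manifest JSON; return the manifest.

    The CSV (columns ``track_id, frame, x_px``) lands at ``out_path``; the
    manifest at ``out_path`` with a ``.manifest.json`` suffix.  The manifest
    maps every track id to its true class, latent movement probability
    (``null`` for non-retrograde tracks), and length, and embeds the full
    configuration and seed.
    """
    out_path = Path(out_path)
    root = np.random.SeedSequence(config.seed)
    assign_rng = np.random.default_rng(root.spawn(1)[0])
    labels = _class_assignment(config, assign_rng)
    streams = root.spawn(config.n_tracks)

    retro_sign = -1 if config.direction_sign == "negative_is_retrograde" else 1
    lo, hi = config.track_length_frames
    movie_frames = max(hi, 500)

    ids, frames_col, x_col = [], [], []
    manifest_tracks = {}
    for i, (label, seq) in enumerate(zip(labels, streams)):
        rng = np.random.default_rng(seq)
        n_frames = int(rng.integers(lo, hi + 1))
        start = int(rng.integers(0, max(movie_frames - n_frames, 0) + 1))
        x0 = rng.uniform(50.0, 750.0)
        frames = np.arange(start, start + n_frames)
        p_true = None
        if label == "retrograde":
            p_true = float(rng.beta(config.params.alpha, config.params.beta))
            steps = rng.binomial(config.steps_per_frame, p_true, size=n_frames - 1)
            x = x0 + retro_sign * np.concatenate(([0], np.cumsum(steps)))
        elif label == "stationary":
            x = x0 + config.stationary_jitter_px * rng.standard_normal(n_frames)
        else:  # anterograde: constant drift against the retrograde direction
            drift = config.anterograde_speed_px_per_frame * np.arange(n_frames)
            x = x0 - retro_sign * drift
        if config.noise_sigma_px > 0:
            x = x + config.noise_sigma_px * rng.standard_normal(n_frames)
        tid = f"trk{i:06d}"
        ids.append(np.full(n_frames, tid))
        frames_col.append(frames)
        x_col.append(x)
        manifest_tracks[tid] = {
            "class": label,
            "p_true": p_true,
            "n_frames": n_frames,
        }

    df = pd.DataFrame(
        {
            "track_id": np.concatenate(ids),
            "frame": np.concatenate(frames_col),
            "x_px": np.concatenate(x_col),
        }
    )
    df.to_csv(out_path, index=False)

    counts = {c: sum(1 for t in manifest_tracks.values() if t["class"] == c)
              for c in CLASSES}
    manifest = {
        "config": config.to_dict(),
        "seed": config.seed,
        "n_tracks": config.n_tracks,
        "counts": counts,
        "csv_path": out_path.name,
        "tracks": manifest_tracks,
    }
    manifest_path = out_path.with_suffix(".manifest.json")
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest
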