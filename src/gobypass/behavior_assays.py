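"""Scoring of the three personality indices from raw assay observations.

Boldness is risk tolerance after a simulated predator attack, scored as
``log(t_max) - log(latency)`` where latency is the time to first movement
after freezing and ``t_max`` the assay duration (3600 s), so that bolder
fish (shorter freezes) get higher values.  Asociability is the mean
distance (cm) kept from a stimulus pair of conspecifics over a one-hour
recording sampled at one frame per 6 s, starting at the first movement.
Activity is the count (or percentage) of inter-frame displacements longer
than one centimetre.  Fish that do not move during the first half hour are
excluded because asociability cannot be observed for long enough.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "AssayRecording",
    "TraitScores",
    "boldness_index",
    "asociability_index",
    "activity_index",
    "exclude_inactive",
    "score_recording",
    "read_frames_csv",
    "write_trait_scores_csv",
]


@dataclass(frozen=True)
class AssayRecording:
    """One fish's raw behavioural observation.

    ``frames`` is an ordered ``(n, 3)`` array of (time_s, x_px, y_px) with
    strictly increasing times; ``stimuli_point`` the pixel coordinate of
    the stimulus compartment (midpoint of the dividing wall), treated as a
    single point for the pair of stimulus fish.
    """

    fish_id: str
    latency_s: float
    frames: np.ndarray
    px_per_cm: float
    stimuli_point: tuple[float, float]
    t_max: float = 3600.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "frames",
                           np.asarray(self.frames, dtype=float).reshape(-1, 3))
        t = self.frames[:, 0]
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("frame times must be strictly increasing")
        if self.px_per_cm <= 0:
            raise ValueError("px_per_cm must be positive")
        if not (0 < self.latency_s <= self.t_max):
            raise ValueError(
                f"latency must lie in (0, {self.t_max}], got {self.latency_s}")


@dataclass
class TraitScores:
    """Scored personality indices for one fish, with exclusion bookkeeping."""

    fish_id: str
    boldness: float = math.nan
    asociability_cm: float = math.nan
    asociability_norm: float = math.nan
    activity_count: float = math.nan
    activity_pct: float = math.nan
    excluded: bool = False
    exclusion_reason: str | None = None
    log_base: str = "ten"


def boldness_index(latency_s: float, t_max: float = 3600.0,
                   log_base: str = "ten") -> float:
    """Boldness as ``log(t_max) - log(latency_s)``.

    Strictly decreasing in latency, zero when the fish never moves before
    ``t_max``.  ``log_base`` is ``"ten"`` (default) or ``"natural"``; the
    index is a bijection from latency in ``(0, t_max]`` onto ``[0, inf)``
    either way.
    """
    if not (0 < latency_s <= t_max):
        raise ValueError(f"latency must lie in (0, {t_max}], got {latency_s}")
    if log_base == "ten":
        return math.log10(t_max) - math.log10(latency_s)
    if log_base == "natural":
        return math.log(t_max) - math.log(latency_s)
    raise ValueError(f"log_base must be 'ten' or 'natural', got {log_base!r}")


def _displacements_cm(frames: np.ndarray, px_per_cm: float) -> np.ndarray:
    d_px = np.linalg.norm(np.diff(frames[:, 1:3], axis=0), axis=1)
    return d_px / px_per_cm


def _first_movement_frame(frames: np.ndarray) -> int | None:
    """Index of the first frame at which the fish has moved, else None."""
    d = np.linalg.norm(np.diff(frames[:, 1:3], axis=0), axis=1)
    moved = np.nonzero(d > 0)[0]
    if len(moved) == 0:
        return None
    return int(moved[0] + 1)


def asociability_index(rec: AssayRecording,
                       normalize_by_cm: float | None = None) -> float | None:
    """Mean distance (cm) from the fish to the stimulus point.

    Averaged over frames from the first frame with movement onward
    (scoring starts when the fish begins to swim).  Returns ``None`` when
    no frame qualifies, which callers treat as an exclusion rather than an
    error.  With ``normalize_by_cm`` (e.g. the arena width) the result is
    dimensionless.
    """
    start = _first_movement_frame(rec.frames)
    if start is None:
        return None
    sub = rec.frames[start:]
    if len(sub) == 0:
        return None
    d_px = np.linalg.norm(sub[:, 1:3] - np.asarray(rec.stimuli_point), axis=1)
    mean_cm = float(np.mean(d_px) / rec.px_per_cm)
    if normalize_by_cm is not None:
        return mean_cm / normalize_by_cm
    return mean_cm


def activity_index(rec: AssayRecording, min_move_cm: float = 1.0,
                   as_percent: bool = False) -> float:
    """Number of inter-frame moves strictly longer than ``min_move_cm``.

    The percent form divides by the number of displacement intervals and
    multiplies by 100, which makes recordings of different durations
    comparable.
    """
    if len(rec.frames) < 2:
        raise ValueError("activity needs at least two frames")
    d = _displacements_cm(rec.frames, rec.px_per_cm)
    count = int(np.sum(d > min_move_cm))
    if as_percent:
        return 100.0 * count / len(d)
    return float(count)


def exclude_inactive(rec: AssayRecording, window_s: float = 1800.0) -> bool | None:
    """True if the fish shows no movement within the first ``window_s``.

    A displacement counts as inside the window only if the later frame of
    the pair falls at or before ``window_s``.  Returns ``None``
    (indeterminate) when the recording does not cover the window.
    """
    t = rec.frames[:, 0]
    if len(t) == 0 or t[-1] < window_s:
        return None
    d = _displacements_cm(rec.frames, rec.px_per_cm)
    in_window = t[1:] <= window_s
    return not bool(np.any(d[in_window] > 0))


def score_recording(rec: AssayRecording, min_move_cm: float = 1.0,
                    window_s: float = 1800.0, log_base: str = "ten",
                    arena_width_cm: float | None = None) -> TraitScores:
    """Score all three indices, applying the inactivity exclusion rule."""
    scores = TraitScores(fish_id=rec.fish_id, log_base=log_base)
    scores.boldness = boldness_index(rec.latency_s, rec.t_max, log_base)
    inactive = exclude_inactive(rec, window_s)
    if inactive is None:
        scores.excluded = True
        scores.exclusion_reason = "recording shorter than exclusion window"
        return scores
    if inactive:
        scores.excluded = True
        scores.exclusion_reason = f"no movement in first {window_s:.0f} s"
        return scores
    asoc = asociability_index(rec)
    if asoc is None:
        scores.excluded = True
        scores.exclusion_reason = "no frames after first movement"
        return scores
    scores.asociability_cm = asoc
    if arena_width_cm is not None:
        scores.asociability_norm = asoc / arena_width_cm
    scores.activity_count = activity_index(rec, min_move_cm, as_percent=False)
    scores.activity_pct = activity_index(rec, min_move_cm, as_percent=True)
    return scores


# ---------------------------------------------------------------------------
# CSV interchange

def read_frames_csv(path: str | Path) -> np.ndarray:
    """Read a frame series CSV with columns time_s, x_px, y_px."""
    df = pd.read_csv(path)
    return df[["time_s", "x_px", "y_px"]].to_numpy(dtype=float)


def write_frames_csv(frames: np.ndarray, path: str | Path) -> None:
    pd.DataFrame(np.asarray(frames, dtype=float),
                 columns=["time_s", "x_px", "y_px"]).to_csv(path, index=False)


def write_trait_scores_csv(scores: list[TraitScores], path: str | Path) -> None:
    """Write one row per fish, including the exclusion-reason column."""
    rows = [{
        "fish_id": s.fish_id,
        "boldness": s.boldness,
        "asociability_cm": s.asociability_cm,
        "asociability_norm": s.asociability_norm,
        "activity_count": s.activity_count,
        "activity_pct": s.activity_pct,
        "excluded": s.excluded,
        "exclusion_reason": s.exclusion_reason or "",
        "log_base": s.log_base,
    } for s in scores]
    pd.DataFrame(rows).to_csv(path, index=False)
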