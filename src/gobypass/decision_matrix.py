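"""The a-priori threshold decision matrix.

Each individual fish faces three binary questions:

1. swim:        is its critical swimming speed above the barrier's maximum
                (near-bottom) flow velocity?
2. endurance:   swimming at Ucrit for its endurance time, does it cover
                more than the largest gap between two resting pools?
3. personality: are at least two of its three personality indices
                (boldness, activity, asociability) strictly above the
                invasion-front population means?

The overall outcome is the conjunction of the three.  Thresholds are set
a priori: trait thresholds are the arithmetic means of an invasion-front
reference cohort (front individuals are the "good dispersers"), the flow
and distance limits come from the barrier profile.  All comparisons are
strict: a value exactly at its threshold fails.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .barrier_profile import FlowProfile, max_pool_spacing, max_velocity
from .swim_performance import (SwimModel, endurance_minutes,
                               traversable_distance, ucrit_from_length)

__all__ = [
    "FishRecord",
    "ThresholdSet",
    "DecisionTrace",
    "compute_thresholds",
    "decision_personality",
    "run_decision_matrix",
    "summarize_traces",
    "traces_to_frame",
    "write_traces_csv",
    "write_summary_json",
]


@dataclass(frozen=True)
class FishRecord:
    """One individual: total length plus the three personality indices."""

    fish_id: str
    tl_cm: float
    boldness: float
    activity: float
    asociability: float
    population: str = "front"   # "front" or "center"

    def __post_init__(self) -> None:
        if self.tl_cm <= 0:
            raise ValueError(f"total length must be positive, got {self.tl_cm}")


@dataclass(frozen=True)
class ThresholdSet:
    """All a-priori decision thresholds.

    ``flow_limit_m_s`` / ``distance_limit_m`` may be left ``None`` and are
    then derived from the barrier profile at matrix run time (maximum
    near-bottom velocity; maximum pool spacing).  ``min_traits_above`` is
    the compensatory rule: how many of the three traits must exceed their
    mean (default 2 of 3).
    """

    boldness_mean: float
    activity_mean: float
    asociability_mean: float
    flow_limit_m_s: float | None = None
    distance_limit_m: float | None = None
    min_traits_above: int = 2

    def __post_init__(self) -> None:
        if self.min_traits_above not in (1, 2, 3):
            raise ValueError("min_traits_above must be 1, 2 or 3")
        for name in ("flow_limit_m_s", "distance_limit_m"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be positive, got {v}")


@dataclass
class DecisionTrace:
    """Per-individual audit record of the three decisions."""

    fish_id: str
    ucrit_m_s: float = math.nan
    endurance_min: float = math.nan
    distance_m: float = math.nan
    decision_swim: int = 0
    decision_endurance: int = 0
    traits_above: int = 0
    decision_personality: int = 0
    overall: int = 0
    excluded: bool = False
    exclusion_reason: str | None = None


def compute_thresholds(front_cohort: list[FishRecord],
                       flow_limit_m_s: float | None = None,
                       distance_limit_m: float | None = None,
                       min_traits_above: int = 2) -> ThresholdSet:
    """Trait thresholds as arithmetic means over an invasion-front cohort."""
    if not front_cohort:
        raise ValueError("front cohort must be nonempty")
    return ThresholdSet(
        boldness_mean=float(np.mean([f.boldness for f in front_cohort])),
        activity_mean=float(np.mean([f.activity for f in front_cohort])),
        asociability_mean=float(np.mean([f.asociability for f in front_cohort])),
        flow_limit_m_s=flow_limit_m_s,
        distance_limit_m=distance_limit_m,
        min_traits_above=min_traits_above,
    )


def decision_personality(rec: FishRecord, thr: ThresholdSet) -> tuple[int, int]:
    """Compensatory k-of-3 personality rule.

    Returns ``(decision, traits_above)`` where ``traits_above`` counts
    strict exceedances of the three trait means and the decision is 1 iff
    that count reaches ``thr.min_traits_above``.  Raises on missing (NaN)
    traits; cohort-level callers turn that into an exclusion.
    """
    traits = (rec.boldness, rec.activity, rec.asociability)
    if any(map(math.isnan, traits)):
        raise ValueError(f"fish {rec.fish_id} has a missing trait value")
    above = sum((
        rec.boldness > thr.boldness_mean,
        rec.activity > thr.activity_mean,
        rec.asociability > thr.asociability_mean,
    ))
    return (1 if above >= thr.min_traits_above else 0), above


def run_decision_matrix(cohort: list[FishRecord], profile: FlowProfile,
                        swim: SwimModel = SwimModel(),
                        thr: ThresholdSet | None = None,
                        endurance_velocity_cm_s: float | None = None,
                        ) -> list[DecisionTrace]:
    """Run all three decisions for every individual in the cohort.

    Missing trait values exclude an individual (with reason) instead of
    dropping it; exclusions carry ``overall = 0``.  The flow velocity
    entering the endurance formula defaults to the flow limit itself
    (the profile's maximum near-bottom velocity), in cm/s.
    """
    if thr is None:
        thr = compute_thresholds([f for f in cohort if f.population == "front"])
    flow_limit = thr.flow_limit_m_s
    if flow_limit is None:
        flow_limit = max_velocity(profile, "near_bottom")
    distance_limit = thr.distance_limit_m
    if distance_limit is None:
        distance_limit = max_pool_spacing(profile)
    v_cm_s = endurance_velocity_cm_s
    if v_cm_s is None:
        v_cm_s = flow_limit * 100.0

    traces: list[DecisionTrace] = []
    for rec in cohort:
        trace = DecisionTrace(fish_id=rec.fish_id)
        trace.ucrit_m_s = ucrit_from_length(rec.tl_cm, swim)
        trace.endurance_min = endurance_minutes(v_cm_s, rec.tl_cm, swim)
        trace.distance_m = traversable_distance(
            trace.ucrit_m_s, trace.endurance_min,
            flow_velocity_m_s=v_cm_s / 100.0, model=swim)
        trace.decision_swim = int(trace.ucrit_m_s > flow_limit)
        trace.decision_endurance = int(trace.distance_m > distance_limit)
        try:
            trace.decision_personality, trace.traits_above = \
                decision_personality(rec, thr)
        except ValueError as err:
            trace.excluded = True
            trace.exclusion_reason = str(err)
            trace.overall = 0
            traces.append(trace)
            continue
        trace.overall = int(trace.decision_swim and trace.decision_endurance
                            and trace.decision_personality)
        traces.append(trace)
    return traces


def summarize_traces(traces: list[DecisionTrace]) -> dict:
    """Cohort summary: counts and the fraction of successful ascents."""
    scored = [t for t in traces if not t.excluded]
    n_success = sum(t.overall for t in scored)
    return {
        "n": len(traces),
        "n_excluded": len(traces) - len(scored),
        "n_success": int(n_success),
        "fraction_success": (n_success / len(scored)) if scored else math.nan,
    }


def traces_to_frame(traces: list[DecisionTrace]) -> pd.DataFrame:
    rows = [{
        "fish_id": t.fish_id,
        "ucrit_m_s": t.ucrit_m_s,
        "endurance_min": t.endurance_min,
        "distance_m": t.distance_m,
        "decision_swim": t.decision_swim,
        "decision_endurance": t.decision_endurance,
        "traits_above": t.traits_above,
        "decision_personality": t.decision_personality,
        "overall": t.overall,
        "excluded": t.excluded,
        "exclusion_reason": t.exclusion_reason or "",
    } for t in traces]
    return pd.DataFrame(rows)


def write_traces_csv(traces: list[DecisionTrace], path: str | Path) -> None:
    traces_to_frame(traces).to_csv(path, index=False)


def write_summary_json(traces: list[DecisionTrace], path: str | Path) -> None:
    Path(path).write_text(json.dumps(summarize_traces(traces), indent=1))
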