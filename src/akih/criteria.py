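"""Creatinine-based AKI detection and staging.

The engine implements a modified KDIGO scheme that relies on serum
creatinine (SCr) only: no urine-output and no RRT-initiation criteria.
Two reference values anchor every decision at an evaluation time ``t``:

* **initial SCr** — the smaller of (a) the first SCr measured within two
  months (61 days) either side of the patient's cancer-registry
  registration date and (b) the first SCr measured after registration;
  whichever exists if only one does.
* **recent SCr** — the minimum SCr over the three weeks (21 days)
  strictly before ``t``.

AKI is detected at ``t`` when the current SCr exceeds 1.5x either
reference (strict) or exceeds it by more than 0.3 mg/dL (strict).  The
reference that triggered detection becomes the *baseline*; when both
trigger, the smaller one is used, which maximises the ratio and is
conservative toward catching severe AKI.  Staging then looks at the SCr
values from the triggering measurement through the following two weeks:

* stage 3 if any value/baseline >= 3.0 or any value >= 4.0 mg/dL,
* stage by ratio: bands [1.5, 2.0) -> 1, [2.0, 3.0) -> 2, >= 3.0 -> 3,
* stage by increment: 1 if max(value - baseline) > 0.3 mg/dL,
* final stage = max(stage by ratio, stage by increment).

All windows are half-open with the evaluation instant excluded from its
own history; "two months" = 61 days, "three weeks" = 21 days, "two
weeks" = 14 days (calendar-month arithmetic avoided for determinism).
Internally times are plain float hours, which keeps the hot path free of
datetime objects; public wrappers accept pandas timestamps.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

HOUR = 1.0
DAY = 24.0
INITIAL_WINDOW_DAYS = 61        # "two months" either side of registration
RECENT_WINDOW_DAYS = 21         # "three weeks" before the current time
STAGING_WINDOW_DAYS = 14        # "two weeks" after onset / target horizon
TARGET_START_H = 1.0            # horizon is [t + 1h, t + 14 d)

RATIO_DETECT = 1.5              # strict: current > 1.5 * reference
INCREMENT_DETECT = 0.3          # strict: current - reference > 0.3 mg/dL
STAGE1_RATIO = 1.5              # inclusive band edges for staging
STAGE2_RATIO = 2.0
STAGE3_RATIO = 3.0
STAGE3_ABSOLUTE = 4.0           # inclusive: any SCr >= 4.0 mg/dL is stage 3

# Creatinine is recorded to two decimals; comparisons carry a small guard
# so binary floats behave like by-hand decimal arithmetic (1.3 - 1.0 must
# not exceed 0.3, 2.1 / 0.7 must reach 3.0).
FLOAT_GUARD = 1e-9


def to_hours(times) -> np.ndarray:
    """Convert datetime-like input to float hours since the epoch."""
    arr = pd.to_datetime(pd.Series(np.asarray(times).ravel()))
    return (arr.astype("int64") / 3.6e12).to_numpy()


@dataclass(frozen=True)
class ScrContext:
    """The (initial, recent, baseline) SCr triple anchoring decisions at ``t``.

    ``t`` is in float hours; creatinine fields are mg/dL or ``None`` when
    the corresponding reference does not exist.  ``baseline_scr`` is set
    only after a detection and always equals one of the two references.
    """

    t: float
    scr_a: float | None = None
    scr_b: float | None = None
    initial_scr: float | None = None
    recent_scr: float | None = None
    baseline_scr: float | None = None
    baseline_source: str | None = None

    @property
    def decidable(self) -> bool:
        return self.initial_scr is not None or self.recent_scr is not None


@dataclass(frozen=True)
class AKIEpisode:
    """A detected AKI occurrence with its staging provenance."""

    patient_id: object
    onset_time: float                 # hours since epoch
    triggering_scr: float
    baseline_scr: float
    baseline_source: str
    stage: int
    stage_by_ratio: int
    stage_by_increment: int
    max_ratio: float
    max_increment: float


class UndecidableContext(ValueError):
    """Raised when neither an initial nor a recent SCr exists at ``t``."""


def initial_scr(times_h: np.ndarray, values: np.ndarray,
                registration_h: float) -> float | None:
    """Initial SCr: min of the first value within +/-61 d of registration
    (SCr_a) and the first value strictly after registration (SCr_b)."""
    half = INITIAL_WINDOW_DAYS * DAY
    scr_a = None
    in_win = (times_h >= registration_h - half) & (times_h <= registration_h + half)
    if in_win.any():
        scr_a = float(values[np.argmax(in_win)])
    scr_b = None
    after = times_h > registration_h
    if after.any():
        scr_b = float(values[np.argmax(after)])
    if scr_a is None:
        return scr_b
    if scr_b is None:
        return scr_a
    return min(scr_a, scr_b)


def recent_scr(times_h: np.ndarray, values: np.ndarray, t: float) -> float | None:
    """Minimum SCr over [t - 21 d, t); the value at ``t`` itself is excluded."""
    lo = np.searchsorted(times_h, t - RECENT_WINDOW_DAYS * DAY, side="left")
    hi = np.searchsorted(times_h, t, side="left")
    if hi <= lo:
        return None
    return float(values[lo:hi].min())


def build_context(times_h: np.ndarray, values: np.ndarray, t: float,
                  registration_h: float) -> ScrContext:
    """Assemble the ScrContext for evaluation time ``t``."""
    half = INITIAL_WINDOW_DAYS * DAY
    scr_a = None
    in_win = (times_h >= registration_h - half) & (times_h <= registration_h + half)
    if in_win.any():
        scr_a = float(values[np.argmax(in_win)])
    scr_b = None
    after = times_h > registration_h
    if after.any():
        scr_b = float(values[np.argmax(after)])
    if scr_a is not None and scr_b is not None:
        init = min(scr_a, scr_b)
    else:
        init = scr_a if scr_a is not None else scr_b
    return ScrContext(t=t, scr_a=scr_a, scr_b=scr_b, initial_scr=init,
                      recent_scr=recent_scr(times_h, values, t))


def _triggering_baseline(current: float, initial: float | None,
                         recent: float | None) -> tuple[float, str] | None:
    """Return (baseline, source) of the triggering reference, or None.

    When both references trigger, the smaller wins (severity-maximising
    tie rule)."""
    best = None
    source = None
    for c, name in ((initial, "initial"), (recent, "recent")):
        if c is None:
            continue
        if (current > RATIO_DETECT * c + FLOAT_GUARD
                or current - c > INCREMENT_DETECT + FLOAT_GUARD):
            if best is None or c < best:
                best, source = c, name
    if best is None:
        return None
    return best, source


def detect_aki(current: float, context: ScrContext) -> tuple[bool, ScrContext]:
    """Apply the detection rules at ``context.t``.

    Returns (detected, context) where a detection fixes ``baseline_scr``
    and ``baseline_source`` in the returned context.
    """
    if not context.decidable:
        raise UndecidableContext(
            "neither initial nor recent SCr available at t=%r" % (context.t,))
    hit = _triggering_baseline(current, context.initial_scr, context.recent_scr)
    if hit is None:
        return False, context
    baseline, source = hit
    return True, replace(context, baseline_scr=baseline, baseline_source=source)


def _stage_from_max(max_value: float, baseline: float) -> tuple[int, int, int, float, float]:
    """(stage, stage_by_ratio, stage_by_increment, max_ratio, max_increment).

    With a positive baseline both the maximal ratio and the maximal
    increment over a window are attained at the window maximum, so the
    maximum alone determines the stage.
    """
    max_ratio = max_value / baseline
    max_increment = max_value - baseline
    if max_ratio >= STAGE3_RATIO - FLOAT_GUARD:
        by_ratio = 3
    elif max_ratio >= STAGE2_RATIO - FLOAT_GUARD:
        by_ratio = 2
    elif max_ratio >= STAGE1_RATIO - FLOAT_GUARD:
        by_ratio = 1
    else:
        by_ratio = 0
    by_increment = 1 if max_increment > INCREMENT_DETECT + FLOAT_GUARD else 0
    if by_ratio == 3 or max_value >= STAGE3_ABSOLUTE - FLOAT_GUARD:
        stage = 3
    else:
        stage = by_ratio if by_ratio > by_increment else by_increment
    return stage, by_ratio, by_increment, max_ratio, max_increment


def stage_episode(window_values: Sequence[float], baseline: float) -> dict:
    """Stage an episode from the SCr values at onset and the next two weeks."""
    if len(window_values) == 0:
        raise ValueError("staging window must contain at least the onset value")
    if baseline <= 0:
        raise ValueError("baseline must be positive")
    stage, by_ratio, by_increment, max_ratio, max_increment = _stage_from_max(
        max(window_values), baseline)
    return {
        "stage": stage,
        "stage_by_ratio": by_ratio,
        "stage_by_increment": by_increment,
        "max_ratio": max_ratio,
        "max_increment": max_increment,
    }


def label_horizon(values: Sequence[float], initial: float | None,
                  recent: float | None) -> int:
    """Ground-truth stage over an ordered sequence of horizon SCr values.

    Walks the horizon in time order; the first value that triggers
    detection fixes the baseline, and the stage is computed from that
    value onward.  Returns 0 when nothing triggers.  Lean scalar path —
    the references are fixed at the evaluation time, not re-derived
    inside the horizon.
    """
    if initial is None and recent is None:
        raise UndecidableContext("no reference SCr available")
    for i, v in enumerate(values):
        hit = _triggering_baseline(v, initial, recent)
        if hit is not None:
            baseline = hit[0]
            return _stage_from_max(max(values[i:]), baseline)[0]
    return 0


def label_window(times_h: np.ndarray, values: np.ndarray, t: float,
                 context: ScrContext) -> int:
    """Stage label for the horizon [t + 1 h, t + 14 d) of a measurement at t."""
    lo = np.searchsorted(times_h, t + TARGET_START_H, side="left")
    hi = np.searchsorted(times_h, t + STAGING_WINDOW_DAYS * DAY, side="left")
    return label_horizon(list(values[lo:hi]), context.initial_scr, context.recent_scr)


def stage_from_predicted(max_scr_pred: float, context: ScrContext) -> int:
    """Stage implied by a predicted 14-day maximum SCr (0 when undetected)."""
    if max_scr_pred <= 0:
        raise ValueError("predicted SCr must be positive")
    return label_horizon([max_scr_pred], context.initial_scr, context.recent_scr)


def find_episodes(times_h: np.ndarray, values: np.ndarray,
                  registration_h: float, patient_id=None) -> list[AKIEpisode]:
    """Scan a patient's SCr series for AKI episodes.

    Each measurement is evaluated as "current SCr" against the references
    available at that instant.  A detection opens an episode staged over
    the following two weeks; further detections inside that window fold
    into the same episode (14-day refractory scan).
    """
    init = initial_scr(times_h, values, registration_h)
    episodes: list[AKIEpisode] = []
    next_eligible = -np.inf
    n = len(times_h)
    for i in range(n):
        t = times_h[i]
        if t < next_eligible:
            continue
        rec = recent_scr(times_h, values, t)
        if init is None and rec is None:
            continue
        hit = _triggering_baseline(float(values[i]), init, rec)
        if hit is None:
            continue
        baseline, source = hit
        hi = np.searchsorted(times_h, t + STAGING_WINDOW_DAYS * DAY, side="left")
        staged = stage_episode(list(values[i:hi]), baseline)
        episodes.append(AKIEpisode(
            patient_id=patient_id, onset_time=t, triggering_scr=float(values[i]),
            baseline_scr=baseline, baseline_source=source, **staged))
        next_eligible = t + STAGING_WINDOW_DAYS * DAY
    return episodes


def episodes_to_frame(episodes: Iterable[AKIEpisode]) -> pd.DataFrame:
    """Tabulate episodes (onset_time converted back to timestamps)."""
    rows = [{
        "patient_id": e.patient_id,
        "onset_time": pd.Timestamp(e.onset_time * 3.6e12),
        "triggering_scr": e.triggering_scr,
        "baseline_scr": e.baseline_scr,
        "baseline_source": e.baseline_source,
        "stage": e.stage,
        "max_ratio": e.max_ratio,
        "max_increment": e.max_increment,
    } for e in episodes]
    cols = ["patient_id", "onset_time", "triggering_scr", "baseline_scr",
            "baseline_source", "stage", "max_ratio", "max_increment"]
    return pd.DataFrame(rows, columns=cols)


def detect_cohort_episodes(cohort) -> pd.DataFrame:
    """Run the episode scanner over every patient in a cohort."""
    out = []
    reg_h = {pid: float(to_hours([d])[0])
             for pid, d in cohort.patients["registration_date"].items()}
    for pid, grp in cohort.scr.groupby("patient_id", sort=True):
        th = to_hours(grp["time"])
        out.extend(find_episodes(th, grp["value"].to_numpy(), reg_h[pid],
                                 patient_id=pid))
    return episodes_to_frame(out)
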