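"""Window-based feature vectors and 14-day max-SCr targets.

One feature row is built per eligible SCr measurement.  Windows are
half-open ``[start, end)`` in hours relative to the current measurement
time.  The temporal part (26 values, fixed order) is:

====================  =========================================
current SCr           the measurement the row is built for
age at measurement    years
SCr stats x 2         mean, sd, min, max, delta over
                      [-180 d, -30 d) and [-30 d, 0 d)
delta-delta           recent-window delta minus older-window delta
CT counts x 2         [-45 d, -15 d) and [-15 d, 0 d)
IV-chemo counts x 6   same two windows x nephrotoxicity class
ACEi/ARB dosed        any prescription day in [-30 d, 0 d)
diuretics dosed       same window
oral-chemo counts x3  per nephrotoxicity class over [-30 d, 0 d)
====================  =========================================

A row is skipped when either SCr history window is empty, when the
target horizon [t+1 h, t+14 d) holds no SCr, or when neither an initial
nor a recent reference SCr exists at t.  The target is the horizon
maximum SCr; under the 1/SCr transform every SCr-derived feature and
the target are computed on the inverted scale (the target becomes the
horizon minimum of 1/SCr, which equals the inverse of the maximum
exactly).  Standard deviations use the population (n) denominator.

Post-processing: per-column winsorization at the 2nd/98th percentiles
("squeezing", linear-interpolation percentiles) followed by z-scoring
to zero mean and unit (population) variance; constant columns map to
zeros.  Fitted bounds are reusable on held-out data.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.preprocessing import StandardScaler
from sklearn.utils.validation import check_is_fitted

from . import criteria
from .criteria import DAY, STAGING_WINDOW_DAYS, TARGET_START_H, to_hours
from .io import Cohort

logger = logging.getLogger(__name__)


class WindowSpec(NamedTuple):
    start_h: float
    end_h: float


SCR_WINDOWS = (WindowSpec(-180 * 24, -30 * 24), WindowSpec(-30 * 24, 0))
CT_WINDOWS = (WindowSpec(-45 * 24, -15 * 24), WindowSpec(-15 * 24, 0))
IV_WINDOWS = CT_WINDOWS
DRUG_WINDOW = WindowSpec(-30 * 24, 0)
ORAL_WINDOW = WindowSpec(-30 * 24, 0)
TARGET_WINDOW = WindowSpec(TARGET_START_H, STAGING_WINDOW_DAYS * 24)
TOX_CLASSES = ("yes", "no", "unknown")

TEMPORAL_FEATURES = (
    ["scr_current", "age_at_scr"]
    + [f"scr_w{w}_{s}" for w in (0, 1)
       for s in ("mean", "sd", "min", "max", "delta")]
    + ["scr_delta_delta"]
    + [f"ct_count_w{w}" for w in (0, 1)]
    + [f"iv_{tox}_w{w}" for w in (0, 1) for tox in TOX_CLASSES]
    + ["acei_arb_dosed", "diuretic_dosed"]
    + [f"oral_{tox}" for tox in TOX_CLASSES]
)

DEFAULT_SCR_CAP = 20.0   # mg/dL ceiling when inverting 1/SCr predictions


def window_slice(times_h: np.ndarray, t: float, w: WindowSpec) -> slice:
    """Index slice of time-sorted events with t+start <= time < t+end."""
    lo = np.searchsorted(times_h, t + w.start_h, side="left")
    hi = np.searchsorted(times_h, t + w.end_h, side="left")
    return slice(lo, hi)


def scr_window_stats(values: np.ndarray) -> tuple[float, float, float, float, float]:
    """(mean, population sd, min, max, delta=max-min) of a non-empty window."""
    if len(values) == 0:
        raise ValueError("window must be non-empty")
    mn, mx = float(values.min()), float(values.max())
    return (float(values.mean()), float(values.std(ddof=0)), mn, mx, mx - mn)


def delta_delta(delta_older: float, delta_recent: float) -> float:
    """Recent-window delta minus older-window delta (acceleration toward now)."""
    return delta_recent - delta_older


def exposure_features(streams: dict[str, np.ndarray], t: float) -> list[float]:
    """Ordered exposure counts/flags for the manifest's exposure block."""
    out: list[float] = []
    for w in CT_WINDOWS:
        s = window_slice(streams["ct"], t, w)
        out.append(float(s.stop - s.start))
    for w in IV_WINDOWS:
        for tox in TOX_CLASSES:
            s = window_slice(streams[f"iv_{tox}"], t, w)
            out.append(float(s.stop - s.start))
    for key in ("acei_arb", "diuretic"):
        s = window_slice(streams[key], t, DRUG_WINDOW)
        out.append(1.0 if s.stop > s.start else 0.0)
    for tox in TOX_CLASSES:
        s = window_slice(streams[f"oral_{tox}"], t, ORAL_WINDOW)
        out.append(float(s.stop - s.start))
    return out


def _event_streams(events: pd.DataFrame) -> dict[str, np.ndarray]:
    """Sorted per-kind event hour arrays for one patient."""
    th = to_hours(events["time"]) if len(events) else np.array([])
    kind = events["kind"].to_numpy() if len(events) else np.array([])
    tox = events["nephrotoxicity"].to_numpy() if len(events) else np.array([])
    grp = events["drug_group"].to_numpy() if len(events) else np.array([])
    streams = {"ct": th[kind == "CT"]}
    for t_ in TOX_CLASSES:
        streams[f"iv_{t_}"] = th[(kind == "IV_CHEMO") & (tox == t_)]
        streams[f"oral_{t_}"] = th[(kind == "ORAL_CHEMO") & (tox == t_)]
    streams["acei_arb"] = th[(kind == "NEPHROTOXIC") & (grp == "ACEI_ARB")]
    streams["diuretic"] = th[(kind == "NEPHROTOXIC") & (grp == "DIURETIC")]
    return streams


@dataclass
class FeatureMatrix:
    """Feature rows with per-row metadata for staging and evaluation.

    ``X`` holds the model features (non-temporal part first, temporal
    part in manifest order), ``y`` the regression target on the working
    scale (SCr, or 1/SCr under the inverse transform).  ``meta`` carries
    patient_id, t, initial/recent reference SCr, the raw SCr-scale
    target, and the ground-truth stage/occurrence labels.
    """

    X: pd.DataFrame
    y: np.ndarray
    meta: pd.DataFrame
    transform: str = "identity"
    skip_log: dict = field(default_factory=dict)

    @property
    def manifest(self) -> dict:
        return {"transform": self.transform,
                "columns": list(self.X.columns),
                "temporal_columns": TEMPORAL_FEATURES,
                "windows": {"scr": [list(w) for w in SCR_WINDOWS],
                            "ct": [list(w) for w in CT_WINDOWS],
                            "drug": list(DRUG_WINDOW),
                            "target": list(TARGET_WINDOW)}}

    def __len__(self) -> int:
        return len(self.X)

    def subset(self, idx) -> "FeatureMatrix":
        idx = np.asarray(idx)
        X = (self.X.iloc[idx].reset_index(drop=True)
             if isinstance(self.X, pd.DataFrame) else self.X[idx])
        return FeatureMatrix(X=X,
                             y=self.y[idx],
                             meta=self.meta.iloc[idx].reset_index(drop=True),
                             transform=self.transform)

    def write(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        tab = self.meta.copy()
        tab["target_working_scale"] = self.y
        tab = pd.concat([tab, self.X], axis=1)
        tab.to_csv(directory / "features.csv", index=False)
        (directory / "manifest.json").write_text(
            json.dumps(self.manifest, indent=2))


def transform_scr(values, transform: str):
    """Apply the working-scale transform to SCr values."""
    arr = np.asarray(values, dtype=float)
    if transform == "identity":
        return arr
    if transform == "inverse":
        return 1.0 / arr
    raise ValueError(f"unknown transform {transform!r}")


def invert_prediction(y_pred, transform: str,
                      scr_cap: float = DEFAULT_SCR_CAP) -> np.ndarray:
    """Map regressor output back to the SCr scale.

    Under the inverse transform, predictions are floored at
    ``1/scr_cap`` before inversion, bounding the implied SCr at the
    configured physiologic ceiling instead of letting 1/y explode (or
    flip sign); floor events are logged.
    """
    arr = np.atleast_1d(np.asarray(y_pred, dtype=float))
    if transform == "identity":
        return arr
    eps = 1.0 / scr_cap
    n_floored = int((arr < eps).sum())
    if n_floored:
        logger.info("invert_prediction: floored %d prediction(s) at %.4g",
                    n_floored, eps)
    return 1.0 / np.maximum(arr, eps)


def build_feature_row(times_h, values, i, streams, initial, age, transform):
    """Assemble the temporal part for measurement index ``i``, or None to skip.

    Returns (features, target_working, target_scr, recent, horizon_values).
    """
    t = times_h[i]
    s_old = window_slice(times_h, t, SCR_WINDOWS[0])
    s_rec = window_slice(times_h, t, SCR_WINDOWS[1])
    if s_old.stop <= s_old.start or s_rec.stop <= s_rec.start:
        return None, "empty_history_window"
    s_hor = window_slice(times_h, t, TARGET_WINDOW)
    if s_hor.stop <= s_hor.start:
        return None, "empty_horizon"
    recent = criteria.recent_scr(times_h, values, t)
    if initial is None and recent is None:
        return None, "undecidable_context"

    work = transform_scr(values, transform)
    stats_old = scr_window_stats(work[s_old])
    stats_rec = scr_window_stats(work[s_rec])
    feats = [work[i], age[i], *stats_old, *stats_rec,
             delta_delta(stats_old[4], stats_rec[4]),
             *exposure_features(streams, t)]

    horizon = values[s_hor]
    target_scr = float(horizon.max())
    if transform == "inverse":
        target_working = float(work[s_hor].min())   # min 1/SCr == 1/max SCr
    else:
        target_working = target_scr
    return (feats, target_working, target_scr, recent, horizon), None


def build_feature_matrix(cohort: Cohort, nontemporal: pd.DataFrame,
                         transform: str = "identity") -> FeatureMatrix:
    """Materialize all eligible feature rows for a cohort.

    ``nontemporal`` is the preprocessed numeric patient table (one row
    per patient); its columns form the non-temporal part of each vector.
    """
    nt_cols = list(nontemporal.columns)
    rows, nt_parts, meta_rows = [], [], []
    skips = {"empty_history_window": 0, "empty_horizon": 0,
             "undecidable_context": 0}
    ev_by_pat = {pid: g for pid, g in cohort.events.groupby("patient_id", sort=True)}
    empty_events = cohort.events.iloc[0:0]

    for pid, grp in cohort.scr.groupby("patient_id", sort=True):
        if pid not in nontemporal.index:
            continue
        times_h = to_hours(grp["time"])
        values = grp["value"].to_numpy(dtype=float)
        age = grp["age_at_measurement"].to_numpy(dtype=float)
        reg_h = float(to_hours([cohort.patients.loc[pid, "registration_date"]])[0])
        initial = criteria.initial_scr(times_h, values, reg_h)
        streams = _event_streams(ev_by_pat.get(pid, empty_events))
        nt_row = nontemporal.loc[pid, nt_cols].to_numpy(dtype=float)

        for i in range(len(times_h)):
            built, skip = build_feature_row(
                times_h, values, i, streams, initial, age, transform)
            if built is None:
                skips[skip] += 1
                continue
            feats, target_working, target_scr, recent, horizon = built
            stage = criteria.label_horizon(list(horizon), initial, recent)
            rows.append((feats, target_working))
            nt_parts.append(nt_row)
            meta_rows.append({
                "patient_id": pid,
                "t": pd.Timestamp(times_h[i] * 3.6e12),
                "scr_current": values[i],
                "initial_scr": np.nan if initial is None else initial,
                "recent_scr": np.nan if recent is None else recent,
                "target_scr": target_scr,
                "true_stage": stage,
                "true_occurrence": stage > 0,
            })

    if not rows:
        X = pd.DataFrame(columns=nt_cols + list(TEMPORAL_FEATURES))
        return FeatureMatrix(X=X, y=np.array([]), meta=pd.DataFrame(meta_rows),
                             transform=transform, skip_log=skips)
    temporal = np.array([r[0] for r in rows], dtype=float)
    X = pd.DataFrame(
        np.hstack([np.array(nt_parts, dtype=float), temporal]),
        columns=nt_cols + list(TEMPORAL_FEATURES))
    y = np.array([r[1] for r in rows], dtype=float)
    return FeatureMatrix(X=X, y=y, meta=pd.DataFrame(meta_rows),
                         transform=transform, skip_log=skips)


class Winsorizer(BaseEstimator, TransformerMixin):
    """Cap each column at its fitted lower/upper percentiles ("squeeze")."""

    def __init__(self, lower_pct: float = 2.0, upper_pct: float = 98.0):
        self.lower_pct = lower_pct
        self.upper_pct = upper_pct

    def fit(self, X, y=None):
        arr = np.asarray(X, dtype=float)
        if arr.shape[0] < 2:
            raise ValueError("winsorization needs at least 2 rows")
        self.lower_bounds_ = np.percentile(arr, self.lower_pct, axis=0)
        self.upper_bounds_ = np.percentile(arr, self.upper_pct, axis=0)
        self.n_features_in_ = arr.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self)
        arr = np.asarray(X, dtype=float)
        clipped = np.clip(arr, self.lower_bounds_, self.upper_bounds_)
        if isinstance(X, pd.DataFrame):
            return pd.DataFrame(clipped, index=X.index, columns=X.columns)
        return clipped


def squeeze(matrix, lower_pct: float = 2.0, upper_pct: float = 98.0):
    """Functional winsorization: returns (squeezed, (lower, upper) bounds)."""
    w = Winsorizer(lower_pct, upper_pct).fit(matrix)
    return w.transform(matrix), (w.lower_bounds_, w.upper_bounds_)


def zscore(matrix):
    """Z-score columns with population sd; constant columns map to zeros.

    Returns (standardized, (mean, sd)).
    """
    scaler = StandardScaler().fit(np.asarray(matrix, dtype=float))
    out = scaler.transform(np.asarray(matrix, dtype=float))
    if isinstance(matrix, pd.DataFrame):
        out = pd.DataFrame(out, index=matrix.index, columns=matrix.columns)
    return out, (scaler.mean_, scaler.scale_)


def make_postprocessor() -> "Pipeline":
    """squeeze -> z-score as a fit/transform pipeline (leakage-safe reuse)."""
    from sklearn.pipeline import Pipeline
    return Pipeline([("squeeze", Winsorizer()), ("zscore", StandardScaler())])
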