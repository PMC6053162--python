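"""Synthetic oncology-cohort generator with ground-truth AKI labels.

The generator emulates the statistical structure the prediction method
assumes, not any particular hospital's data:

* irregular creatinine sampling — dense inpatient stretches (1-3 day
  gaps) alternating with sparse outpatient follow-up (2-3 weeks to 3-6
  months between visits);
* sex-specific baseline SCr drawn from the adult normal ranges
  (0.8-1.3 mg/dL male, 0.6-1.1 mg/dL female) plus a slow drift and
  measurement noise;
* injected AKI episodes of known stage whose peak/baseline ratio sits
  inside the target staging band with a guard margin, made decidable by
  design (a measurement at the peak and one in the preceding three
  weeks);
* exposure events (CT, IV/oral chemotherapy, nephrotoxic drugs) that
  multiply the episode hazard for 30 days, giving models a learnable
  signal;
* a non-temporal table with realistic types and mild correlations,
  masked missing-at-random with per-variable rates.

Identical (config, seed) produces identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as cohort_io
from .criteria import DAY, RECENT_WINDOW_DAYS, STAGING_WINDOW_DAYS, TARGET_START_H
from .preprocess import compute_egfr_ckdepi

HOURS_PER_YEAR = 365.25 * 24.0

# peak/baseline ratio bands per intended stage; edges keep a guard margin
# inside the staging bands [1.5,2), [2,3), [3,inf) so noise cannot flip
# the recovered stage
STAGE_RATIO_BANDS = {1: (1.60, 1.80), 2: (2.10, 2.80), 3: (3.15, 3.70)}
RISE_HOURS = 48.0          # onset -> peak
RECOVERY_TAU_HOURS = 96.0  # exponential decay constant (full recovery ~2 weeks)

# default per-variable missing rates for the non-temporal table; a few sit
# above the 0.4 filtering threshold on purpose so the missing-rate drop
# rule has work to do
DEFAULT_MISSING_RATES = {
    "platelet": 0.21, "white_blood_cell": 0.21, "hemoglobin": 0.21,
    "cholesterol": 0.22, "albumin": 0.22, "total_protein": 0.22,
    "blood_urea_nitrogen": 0.24, "glucose": 0.26,
    "systolic_bp": 0.27, "diastolic_bp": 0.27, "uric_acid": 0.28,
    "sodium": 0.35, "potassium": 0.35, "chloride": 0.35,
    "smoking": 0.41, "weight": 0.42, "height": 0.42, "body_mass_index": 0.42,
    "educational_status": 0.43, "triglyceride": 0.45,
    "occupation": 0.53, "income_level": 0.77,
    "first_egfr": 0.12,
}


@dataclass
class SyntheticConfig:
    n_patients: int = 200
    seed: int = 0
    study_start: str = "2004-01-01"
    study_end: str = "2013-12-31"
    followup_years: float = 2.0
    inpatient_interval_days: tuple = (1.0, 3.0)
    outpatient_interval_days: tuple = (14.0, 180.0)
    baseline_scr_male: tuple = (0.8, 1.3)
    baseline_scr_female: tuple = (0.6, 1.1)
    male_fraction: float = 0.6
    episode_rate: float = 0.8            # expected AKI episodes / patient-year
    stage_mix: tuple = (0.5, 0.3, 0.2)   # P(stage 1), P(2), P(3)
    exposure_effect: float = 3.0         # hazard multiplier 30 d post exposure
    measurement_noise_sd: float = 0.03   # mg/dL
    drift_amplitude: float = 0.05        # mg/dL, slow sinusoidal drift
    p_inpatient_start: float = 0.4
    regime_persistence: float = 0.8
    frac_maintenance_dialysis: float = 0.02
    frac_severe_ckd: float = 0.02
    missing_rates: dict = field(default_factory=lambda: dict(DEFAULT_MISSING_RATES))

    def __post_init__(self):
        if pd.Timestamp(self.study_end) <= pd.Timestamp(self.study_start):
            raise ValueError("study_end must be after study_start")
        if abs(sum(self.stage_mix) - 1.0) > 1e-9 or min(self.stage_mix) < 0:
            raise ValueError("stage_mix must be probabilities summing to 1")
        for r in self.missing_rates.values():
            if not 0.0 <= r <= 1.0:
                raise ValueError("missing rates must be in [0, 1]")


@dataclass
class GroundTruth:
    """Injected-episode log and intended 14-day-ahead targets.

    ``episodes``: patient_id, onset_time, peak_time, stage, peak_scr,
    baseline_scr.  ``targets``: patient_id, time, intended_max_scr — the
    noise-free maximum of the underlying trajectory over the row's
    [t+1h, t+14d) horizon (NaN when the horizon holds no measurement).
    """

    episodes: pd.DataFrame
    targets: pd.DataFrame

    def write(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        ep = self.episodes.copy()
        for c in ("onset_time", "peak_time"):
            ep[c] = pd.to_datetime(ep[c]).dt.strftime("%Y-%m-%dT%H")
        ep.to_csv(directory / "episodes.csv", index=False)
        tg = self.targets.copy()
        tg["time"] = pd.to_datetime(tg["time"]).dt.strftime("%Y-%m-%dT%H")
        tg.to_csv(directory / "targets.csv", index=False)


def _bump(times_h: np.ndarray, onset_h: float, amp: float) -> np.ndarray:
    """Rise-peak-recovery excursion: linear rise over RISE_HOURS, then
    exponential decay toward baseline."""
    dt = times_h - onset_h
    rise = np.clip(dt / RISE_HOURS, 0.0, 1.0)
    decay = np.where(dt > RISE_HOURS,
                     np.exp(-(dt - RISE_HOURS) / RECOVERY_TAU_HOURS), 1.0)
    return np.where(dt <= 0, 0.0, amp * rise * decay)


def inject_episode(times_h: np.ndarray, values: np.ndarray, onset_h: float,
                   stage: int, baseline: float,
                   rng: np.random.Generator | None = None
                   ) -> tuple[np.ndarray, np.ndarray, dict]:
    """Insert an AKI excursion of the intended stage into a noiseless series.

    Guarantees a measurement at the peak and at least one in the three
    weeks before it, so the detection/staging criteria are decidable.
    Returns the augmented (times, values) and an episode record.
    """
    if stage not in (1, 2, 3):
        raise ValueError("stage must be 1, 2 or 3")
    if not (times_h.min() <= onset_h <= times_h.max()):
        raise ValueError("onset must lie inside the trajectory span")
    rng = rng or np.random.default_rng(0)
    lo, hi = STAGE_RATIO_BANDS[stage]
    ratio = float(rng.uniform(lo, hi))
    amp = (ratio - 1.0) * baseline
    peak_h = onset_h + RISE_HOURS

    extra = [onset_h, peak_h, peak_h + 3 * DAY, peak_h + 7 * DAY,
             peak_h + 12 * DAY]
    pre = (times_h >= peak_h - RECENT_WINDOW_DAYS * DAY) & (times_h < onset_h)
    if not pre.any():
        extra.append(onset_h - 10 * DAY)
    extra = np.round(np.array(extra))
    new_times = np.concatenate([times_h, extra])
    # baseline level for added points: interpolate the pre-episode signal
    new_vals = np.concatenate([
        values, np.interp(extra, times_h, values)])
    order = np.argsort(new_times, kind="stable")
    new_times, new_vals = new_times[order], new_vals[order]
    keep = np.concatenate([[True], np.diff(new_times) > 0])
    new_times, new_vals = new_times[keep], new_vals[keep]

    new_vals = new_vals + _bump(new_times, onset_h, amp)
    record = {"onset_h": onset_h, "peak_h": float(np.round(peak_h)),
              "stage": stage, "peak_scr": baseline + amp,
              "baseline_scr": baseline, "ratio": ratio}
    return new_times, new_vals, record


def mask_missing(table: pd.DataFrame, missing_rates, seed: int = 0,
                 exclude: tuple = ()) -> pd.DataFrame:
    """Null each cell independently with its variable's rate (MAR)."""
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x3A5]))
    out = table.copy()
    if not isinstance(missing_rates, dict):
        missing_rates = {c: float(missing_rates) for c in table.columns}
    for col in table.columns:
        rate = missing_rates.get(col, 0.0)
        if col in exclude or rate <= 0.0:
            continue
        mask = rng.random(len(table)) < rate
        if rate >= 1.0:
            mask[:] = True
        out.loc[mask, col] = (pd.NaT if pd.api.types.is_datetime64_any_dtype(out[col])
                              else np.nan)
    return out


def _schedule(rng: np.random.Generator, reg_h: float, followup_h: float,
              cfg: SyntheticConfig) -> np.ndarray:
    """Visit times in hours: alternating inpatient/outpatient regimes with
    gaps drawn from the configured ranges; whole-hour resolution."""
    times = [reg_h + float(rng.integers(0, 24))]
    inpatient = rng.random() < cfg.p_inpatient_start
    while True:
        rng_range = (cfg.inpatient_interval_days if inpatient
                     else cfg.outpatient_interval_days)
        gap_h = max(1.0, np.round(rng.uniform(*rng_range) * DAY))
        t = times[-1] + gap_h
        if t > reg_h + followup_h:
            break
        times.append(t)
        if rng.random() > cfg.regime_persistence:
            inpatient = not inpatient
    return np.array(times)


def _exposures(rng: np.random.Generator, reg_h: float, followup_h: float
               ) -> dict[str, list]:
    """Exposure event hours per stream (day resolution -> hour 00)."""
    span_days = followup_h / DAY
    years = followup_h / HOURS_PER_YEAR

    def days(n):
        return np.floor(reg_h / DAY + rng.uniform(0, span_days, n)) * DAY

    ev: dict[str, list] = {}
    ev["ct"] = sorted(days(rng.poisson(3.0 * years)))
    iv = []
    for _ in range(rng.poisson(2.0 * years)):
        start = days(1)[0]
        tox = rng.choice(["yes", "no", "unknown"], p=[0.4, 0.4, 0.2])
        iv.extend((start + k * 7 * DAY, tox) for k in range(3))
    ev["iv"] = sorted(iv)
    ev["oral"] = sorted(
        (days(1)[0], rng.choice(["yes", "no", "unknown"], p=[0.4, 0.4, 0.2]))
        for _ in range(rng.poisson(1.5 * years)))
    neph = []
    for _ in range(rng.poisson(1.0 * years)):
        start = days(1)[0]
        group = rng.choice(["ACEI_ARB", "DIURETIC"])
        duration = int(rng.integers(3, 15))
        neph.append((start, group, duration))
    ev["neph"] = sorted(neph)
    return ev


def _episode_onsets(rng: np.random.Generator, reg_h: float, followup_h: float,
                    exposure_hours: np.ndarray, cfg: SyntheticConfig
                    ) -> list[float]:
    """Inhomogeneous-Poisson thinning: base hazard from episode_rate,
    multiplied by exposure_effect within 30 days after any exposure;
    accepted onsets are kept >= 60 days apart."""
    if cfg.episode_rate <= 0:
        return []
    h0 = cfg.episode_rate / HOURS_PER_YEAR
    lam = h0 * max(1.0, cfg.exposure_effect)
    lo, hi = reg_h + 30 * DAY, reg_h + followup_h - 21 * DAY
    if hi <= lo:
        return []
    n_cand = rng.poisson(lam * (hi - lo))
    cand = np.sort(rng.uniform(lo, hi, n_cand))
    onsets: list[float] = []
    for t in cand:
        if exposure_hours.size and np.any(
                (exposure_hours >= t - 30 * DAY) & (exposure_hours < t)):
            h = h0 * cfg.exposure_effect
        else:
            h = h0
        if rng.random() >= h / lam:
            continue
        if onsets and t - onsets[-1] < 60 * DAY:
            continue
        onsets.append(float(np.round(t)))
    return onsets


def _nontemporal_row(rng: np.random.Generator, sex: str, age: float,
                     baseline: float, reg: pd.Timestamp,
                     cfg: SyntheticConfig, has_ct: bool, has_chemo: bool,
                     dialysis: bool) -> dict:
    male = sex == "male"
    height = rng.normal(170.0 if male else 157.0, 6.0)
    weight = rng.normal(68.0 if male else 57.0, 9.0)
    sbp = rng.normal(121.0, 15.0)
    albumin = rng.normal(4.0, 0.4)
    sodium = rng.normal(140.0, 2.5)
    hd = bool(rng.random() < 0.015) or dialysis
    ktpl = rng.random() < 0.002
    row = {
        "age_at_diagnosis": np.round(age, 1),
        "height": np.round(height, 1),
        "weight": np.round(weight, 1),
        "body_mass_index": np.round(weight / (height / 100.0) ** 2, 2),
        "systolic_bp": np.round(sbp, 0),
        "diastolic_bp": np.round(0.55 * sbp + rng.normal(10.0, 6.0), 0),
        "hemoglobin": np.round(rng.normal(14.0 if male else 12.5, 1.3), 1),
        "albumin": np.round(albumin, 1),
        "total_protein": np.round(albumin + rng.normal(3.1, 0.3), 1),
        "sodium": np.round(sodium, 0),
        "potassium": np.round(rng.normal(4.2, 0.4), 1),
        "chloride": np.round(sodium - 36.0 + rng.normal(0.0, 2.0), 0),
        "glucose": np.round(rng.normal(105.0, 20.0), 0),
        "blood_urea_nitrogen": np.round(14.0 * baseline / 1.0 + rng.normal(0, 3.0), 1),
        "cholesterol": np.round(rng.normal(170.0, 35.0), 0),
        "triglyceride": np.round(rng.normal(110.0, 40.0), 0),
        "uric_acid": np.round(rng.normal(4.7, 1.2), 1),
        "platelet": np.round(rng.normal(227.0, 80.0), 0),
        "white_blood_cell": np.round(rng.normal(6.4, 2.0), 1),
        "first_egfr": np.round(compute_egfr_ckdepi(
            max(0.1, baseline + rng.normal(0, cfg.measurement_noise_sd)),
            age, sex), 2),
        "follow_up_duration": np.round(
            cfg.followup_years * 365.25 + rng.normal(0, 30.0), 0),
        "diabetes": bool(rng.random() < 0.12),
        "hypertension": bool(rng.random() < 0.22),
        "tuberculosis": bool(rng.random() < 0.04),
        "chronic_liver_disease": bool(rng.random() < 0.11),
        "smoking": bool(rng.random() < (0.4 if male else 0.05)),
        "surgery_yn": bool(rng.random() < 0.5),
        "chemotherapy_yn": bool(has_chemo),
        "ct_scan_yn": bool(has_ct),
        "hd_yn": hd,
        "pd_yn": bool(rng.random() < 0.001),
        "crrt_yn": bool(rng.random() < 0.02),
        "ktpl_yn": bool(ktpl),
        "dialysis_yn": bool(hd or dialysis),
        "hd_date": reg + pd.Timedelta(days=int(rng.integers(30, 600))) if hd else pd.NaT,
        "ktpl_date": reg + pd.Timedelta(days=int(rng.integers(30, 600))) if ktpl else pd.NaT,
        "occupation": rng.choice(["unemployed", "homemaker", "self-employed",
                                  "company employee", "professional", "etc"]),
        "income_level": rng.choice(["low", "middle", "high", "no answer"]),
        "educational_status": rng.choice(["elementary", "middle school",
                                          "high school", "university"]),
        "cancer_code": rng.choice(
            ["respiratory", "gastrointestinal", "thymus", "hematologic",
             "breast", "genitourinary", "cns", "head_neck", "skin", "other"],
            p=[0.31, 0.20, 0.11, 0.08, 0.08, 0.10, 0.02, 0.02, 0.01, 0.07]),
    }
    return row


def generate_cohort(config: SyntheticConfig | None = None
                    ) -> tuple[cohort_io.Cohort, GroundTruth]:
    """Generate a cohort plus its ground truth; deterministic in (config, seed)."""
    cfg = config or SyntheticConfig()
    root = np.random.SeedSequence([int(cfg.seed), 0xA41])
    children = root.spawn(cfg.n_patients + 1)
    rng_global = np.random.default_rng(children[-1])

    start = pd.Timestamp(cfg.study_start)
    end = pd.Timestamp(cfg.study_end)
    followup_h = cfg.followup_years * HOURS_PER_YEAR
    reg_span_days = max(1.0, (end - start).days - cfg.followup_years * 365.25)

    width = len(str(cfg.n_patients))
    pat_rows, scr_frames, ev_rows = [], [], []
    gt_episodes, gt_targets = [], []

    for i in range(cfg.n_patients):
        rng = np.random.default_rng(children[i])
        pid = "P%0*d" % (width, i + 1)
        sex = "male" if rng.random() < cfg.male_fraction else "female"
        age_reg = rng.uniform(30.0, 80.0)
        reg = start + pd.Timedelta(days=float(np.floor(rng.uniform(0, reg_span_days))))
        reg_h = reg.value / 3.6e12
        birth = (reg - pd.Timedelta(days=age_reg * 365.25)).normalize()

        dialysis = rng.random() < cfg.frac_maintenance_dialysis
        severe = (not dialysis) and rng.random() < cfg.frac_severe_ckd
        if severe:
            baseline = rng.uniform(4.0, 6.0)
        elif sex == "male":
            baseline = rng.uniform(*cfg.baseline_scr_male)
        else:
            baseline = rng.uniform(*cfg.baseline_scr_female)

        times_h = _schedule(rng, reg_h, followup_h, cfg)
        phase = rng.uniform(0, 2 * np.pi)
        values = baseline + cfg.drift_amplitude * np.sin(
            2 * np.pi * (times_h - reg_h) / (730 * DAY) + phase)

        expo = _exposures(rng, reg_h, followup_h)
        expo_hours = np.sort(np.array(
            [h for h, *_ in expo["iv"]] + [h for h, *_ in expo["oral"]]
            + [h for h, *_ in expo["neph"]], dtype=float))

        onsets = [] if (dialysis or severe) else _episode_onsets(
            rng, reg_h, followup_h, expo_hours, cfg)
        onsets = [o for o in onsets if times_h.min() < o < times_h.max()]
        for onset_h in onsets:
            stage = int(rng.choice([1, 2, 3], p=cfg.stage_mix))
            times_h, values, rec = inject_episode(
                times_h, values, onset_h, stage, baseline, rng)
            gt_episodes.append({
                "patient_id": pid,
                "onset_time": pd.Timestamp(rec["onset_h"] * 3.6e12),
                "peak_time": pd.Timestamp(rec["peak_h"] * 3.6e12),
                "stage": stage,
                "peak_scr": rec["peak_scr"],
                "baseline_scr": baseline,
            })

        clean = values.copy()
        noisy = np.round(np.maximum(
            0.05, values + rng.normal(0, cfg.measurement_noise_sd, len(values))), 2)

        # intended 14-day-ahead max of the noise-free trajectory
        for j, t in enumerate(times_h):
            lo = np.searchsorted(times_h, t + TARGET_START_H, side="left")
            hi = np.searchsorted(times_h, t + STAGING_WINDOW_DAYS * DAY, side="left")
            gt_targets.append({
                "patient_id": pid,
                "time": pd.Timestamp(t * 3.6e12),
                "intended_max_scr": float(clean[lo:hi].max()) if hi > lo else np.nan,
            })

        scr_frames.append(pd.DataFrame({
            "patient_id": pid,
            "time": pd.to_datetime((times_h * 3.6e12).astype("int64")),
            "value": noisy,
            "age_at_measurement": np.round(
                age_reg + (times_h - reg_h) / HOURS_PER_YEAR, 2),
        }))

        for h in expo["ct"]:
            ev_rows.append((pid, h, "CT", None, None, 1))
        for h, tox in expo["iv"]:
            ev_rows.append((pid, h, "IV_CHEMO", tox, None, 1))
        for h, tox in expo["oral"]:
            ev_rows.append((pid, h, "ORAL_CHEMO", tox, None, 1))
        for h, group, duration in expo["neph"]:
            for d in range(duration):   # expanded day coverage, duration 1
                ev_rows.append((pid, h + d * DAY, "NEPHROTOXIC", None, group, 1))

        row = {"patient_id": pid, "registration_date": reg, "sex": sex,
               "birth_date": birth, "maintenance_dialysis": dialysis}
        row.update(_nontemporal_row(
            rng, sex, age_reg, baseline, reg, cfg,
            has_ct=len(expo["ct"]) > 0,
            has_chemo=len(expo["iv"]) + len(expo["oral"]) > 0,
            dialysis=dialysis))
        pat_rows.append(row)

    patients = pd.DataFrame(pat_rows).set_index("patient_id")
    for col in patients.columns:
        if patients[col].dropna().map(type).eq(bool).all() and patients[col].notna().any():
            patients[col] = patients[col].astype(object)
    scr = pd.concat(scr_frames, ignore_index=True)
    events = pd.DataFrame(
        ev_rows, columns=cohort_io.EVENT_COLUMNS)
    events["time"] = pd.to_datetime((events["time"] * 3.6e12).astype("int64"))
    events = events.sort_values(["patient_id", "time", "kind"],
                                kind="mergesort").reset_index(drop=True)

    # MAR masking of the non-temporal table (core fields never masked)
    core = ("registration_date", "sex", "birth_date", "maintenance_dialysis")
    patients = mask_missing(patients, cfg.missing_rates, seed=cfg.seed,
                            exclude=core)

    cohort = cohort_io.Cohort(patients=patients, scr=scr, events=events)
    truth = GroundTruth(
        episodes=pd.DataFrame(
            gt_episodes, columns=["patient_id", "onset_time", "peak_time",
                                  "stage", "peak_scr", "baseline_scr"]),
        targets=pd.DataFrame(
            gt_targets, columns=["patient_id", "time", "intended_max_scr"]))
    return cohort, truth
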