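"""Non-temporal table preprocessing.

Fixed pipeline order: patient exclusions -> named variable drops ->
missing-rate drop -> chained-equation imputation -> numeric encoding.

Exclusions remove patients already in severe chronic kidney disease at
registration: on maintenance dialysis, or with an initial eGFR below
15 mL/min/1.73m^2 (2009 CKD-EPI equation; either condition excludes).
Variable filtering drops three named lists (non-informative,
dialysis-linked, redundant) and then any variable whose missing rate is
strictly greater than 0.4.  Remaining gaps are filled by multiple
imputation by chained equations, averaged over repeated imputations,
and everything is finally encoded to numbers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.experimental import enable_iterative_imputer  # noqa: F401
from sklearn.impute import IterativeImputer

from .criteria import initial_scr, to_hours
from .io import Cohort

EPOCH = pd.Timestamp("1970-01-01")

DROP_NONINFORMATIVE = ("occupation", "income_level", "educational_status",
                       "follow_up_duration", "tuberculosis",
                       "chronic_liver_disease")
DROP_AKI_LINKED = ("hd_yn", "pd_yn", "crrt_yn", "ktpl_yn",
                   "hd_date", "pd_date", "crrt_date", "ktpl_date",
                   "dialysis_date")
DROP_REDUNDANT = ("surgery_yn", "chemotherapy_yn", "ct_scan_yn", "dialysis_yn")

# bookkeeping columns are pipeline plumbing, never model variables
BOOKKEEPING = ("registration_date", "maintenance_dialysis")


@dataclass
class PreprocessConfig:
    missing_rate_threshold: float = 0.4
    drop_noninformative: tuple = DROP_NONINFORMATIVE
    drop_aki_linked: tuple = DROP_AKI_LINKED
    drop_redundant: tuple = DROP_REDUNDANT
    egfr_exclusion_threshold: float = 15.0
    n_imputations: int = 100
    seed: int = 0
    use_race_coefficient: bool = False
    one_hot: bool = False

    def __post_init__(self):
        if not (0.0 < self.missing_rate_threshold < 1.0):
            raise ValueError("missing_rate_threshold must be in (0, 1)")
        if self.n_imputations < 1:
            raise ValueError("n_imputations must be >= 1")


@dataclass
class PreprocessReport:
    excluded_patients: list = field(default_factory=list)
    dropped_variables: list = field(default_factory=list)
    imputed_counts: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps({
            "excluded_patients": self.excluded_patients,
            "dropped_variables": self.dropped_variables,
            "imputed_counts": self.imputed_counts,
        }, indent=2, default=str)


def compute_egfr_ckdepi(scr, age, sex, black=False) -> np.ndarray | float:
    """2009 CKD-EPI estimated GFR in mL/min/1.73m^2.

    eGFR = 141 * min(SCr/k, 1)^a * max(SCr/k, 1)^-1.209 * 0.993^age
           * 1.018 [female] * 1.159 [black]
    with k = 0.7 / 0.9 and a = -0.329 / -0.411 for females / males.
    Strictly decreasing in SCr and in age.
    """
    scr = np.asarray(scr, dtype=float)
    age = np.asarray(age, dtype=float)
    if np.any(scr <= 0) or np.any(age <= 0):
        raise ValueError("scr and age must be positive")
    female = np.asarray(pd.Series(np.atleast_1d(sex)).map(
        {"female": True, "male": False}).to_numpy(dtype=bool))
    kappa = np.where(female, 0.7, 0.9)
    alpha = np.where(female, -0.329, -0.411)
    ratio = scr / kappa
    egfr = (141.0
            * np.minimum(ratio, 1.0) ** alpha
            * np.maximum(ratio, 1.0) ** -1.209
            * 0.993 ** age)
    egfr = np.where(female, egfr * 1.018, egfr)
    if black:
        egfr = egfr * 1.159
    egfr = np.asarray(egfr)
    return egfr.item() if egfr.size == 1 else egfr


def initial_egfr(cohort: Cohort, use_race_coefficient: bool = False) -> pd.Series:
    """Per-patient initial eGFR: recorded first_egfr when present, else
    CKD-EPI on the initial SCr with the age at that measurement."""
    out = {}
    recorded = cohort.patients.get("first_egfr")
    by_pat = dict(iter(cohort.scr.groupby("patient_id", sort=True)))
    for pid, row in cohort.patients.iterrows():
        if recorded is not None and pd.notna(recorded.get(pid, np.nan)):
            out[pid] = float(recorded[pid])
            continue
        grp = by_pat.get(pid)
        if grp is None or grp.empty:
            out[pid] = np.nan
            continue
        th = to_hours(grp["time"])
        reg_h = float(to_hours([row["registration_date"]])[0])
        init = initial_scr(th, grp["value"].to_numpy(), reg_h)
        if init is None:
            out[pid] = np.nan
            continue
        # age at the measurement that defines the initial SCr
        half = 61 * 24.0
        in_win = (th >= reg_h - half) & (th <= reg_h + half)
        after = th > reg_h
        cand = np.flatnonzero(in_win | after)
        idx = cand[np.argmin(np.abs(grp["value"].to_numpy()[cand] - init))]
        age = float(grp["age_at_measurement"].to_numpy()[idx])
        out[pid] = compute_egfr_ckdepi(init, age, row["sex"],
                                       black=use_race_coefficient)
    return pd.Series(out, name="initial_egfr")


def apply_exclusions(cohort: Cohort,
                     config: PreprocessConfig | None = None
                     ) -> tuple[Cohort, PreprocessReport]:
    """Remove maintenance-dialysis patients and those with initial
    eGFR < threshold (strict); their temporal records go with them."""
    config = config or PreprocessConfig()
    report = PreprocessReport()
    egfr = initial_egfr(cohort, config.use_race_coefficient)
    keep = []
    for pid, row in cohort.patients.iterrows():
        if bool(row.get("maintenance_dialysis", False)):
            report.excluded_patients.append(
                {"patient_id": pid, "reason": "maintenance dialysis"})
        elif pd.notna(egfr[pid]) and egfr[pid] < config.egfr_exclusion_threshold:
            report.excluded_patients.append(
                {"patient_id": pid, "reason": "initial eGFR %.1f < %.1f"
                 % (egfr[pid], config.egfr_exclusion_threshold)})
        else:
            keep.append(pid)
    return cohort.subset(keep), report


def filter_variables(table: pd.DataFrame,
                     config: PreprocessConfig | None = None,
                     report: PreprocessReport | None = None
                     ) -> tuple[pd.DataFrame, PreprocessReport]:
    """Drop the three named lists, then variables with missing rate
    strictly above the threshold (rate = nulls / patients)."""
    config = config or PreprocessConfig()
    report = report or PreprocessReport()
    table = table.copy()
    for reason, names in (("non-informative", config.drop_noninformative),
                          ("dialysis-linked", config.drop_aki_linked),
                          ("redundant", config.drop_redundant)):
        present = [c for c in names if c in table.columns]
        for c in present:
            report.dropped_variables.append(
                {"variable": c, "reason": reason,
                 "missing_rate": float(table[c].isna().mean())})
        table = table.drop(columns=present)
    rates = table.isna().mean()
    too_missing = rates.index[rates > config.missing_rate_threshold]
    for c in too_missing:
        report.dropped_variables.append(
            {"variable": c, "reason": "missing rate > %.2f" % config.missing_rate_threshold,
             "missing_rate": float(rates[c])})
    return table.drop(columns=list(too_missing)), report


def _to_numeric_frame(table: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Losslessly map every column to float with NaN for nulls; return
    the recipe needed to map imputed values back."""
    recipe = {}
    num = pd.DataFrame(index=table.index)
    for col in table.columns:
        s = table[col]
        if pd.api.types.is_datetime64_any_dtype(s):
            num[col] = (s - EPOCH).dt.total_seconds() / 86400.0
            recipe[col] = ("date", None)
        elif pd.api.types.is_bool_dtype(s) or s.dropna().isin([True, False]).all() and s.notna().any() and s.dropna().map(type).eq(bool).all():
            num[col] = s.map({True: 1.0, False: 0.0}).astype(float)
            recipe[col] = ("bool", None)
        elif pd.api.types.is_numeric_dtype(s):
            num[col] = s.astype(float)
            recipe[col] = ("numeric", None)
        else:
            labels = sorted(s.dropna().unique())
            mapping = {lab: float(i) for i, lab in enumerate(labels)}
            num[col] = s.map(mapping).astype(float)
            recipe[col] = ("category", labels)
    return num, recipe


def impute_mice(table: pd.DataFrame, n_imputations: int = 100,
                seed: int = 0) -> pd.DataFrame:
    """Chained-equation imputation averaged over ``n_imputations`` runs.

    Each run uses a distinct sub-seed with posterior sampling; the final
    value of a missing cell is the mean over runs.  Observed cells are
    never altered.  Non-numeric columns are imputed on a numeric coding
    and mapped back to the nearest valid level.
    """
    if table.shape[1] < 2:
        raise ValueError("chained-equation imputation needs >= 2 variables")
    if table.notna().sum().eq(0).any():
        bad = table.columns[table.notna().sum().eq(0)].tolist()
        raise ValueError(f"all-null columns must be filtered first: {bad}")
    num, recipe = _to_numeric_frame(table)
    mask = num.isna()
    if not mask.to_numpy().any():
        return table.copy()
    ss = np.random.SeedSequence([int(seed), 0x1CE])
    acc = np.zeros(num.shape, dtype=float)
    for child in ss.spawn(n_imputations):
        sub = int(child.generate_state(1)[0] % (2**31 - 1))
        imp = IterativeImputer(sample_posterior=True, random_state=sub,
                               max_iter=10, keep_empty_features=True)
        acc += imp.fit_transform(num.to_numpy())
    filled = pd.DataFrame(acc / n_imputations, index=num.index,
                          columns=num.columns)
    filled = num.where(~mask, filled)

    out = table.copy()
    for col, (kind, labels) in recipe.items():
        miss = mask[col]
        if not miss.any():
            continue
        vals = filled.loc[miss, col]
        if kind == "numeric":
            out.loc[miss, col] = vals
        elif kind == "bool":
            out.loc[miss, col] = (vals >= 0.5).astype(bool)
        elif kind == "date":
            out.loc[miss, col] = EPOCH + pd.to_timedelta(
                np.round(vals), unit="D")
        else:
            codes = np.clip(np.round(vals).astype(int), 0, len(labels) - 1)
            out.loc[miss, col] = [labels[c] for c in codes]
    return out


class MiceImputer(BaseEstimator, TransformerMixin):
    """sklearn-style wrapper around :func:`impute_mice` (stateless fit)."""

    def __init__(self, n_imputations: int = 100, seed: int = 0):
        self.n_imputations = n_imputations
        self.seed = seed

    def fit(self, X, y=None):
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        return impute_mice(X, self.n_imputations, self.seed)


@dataclass
class EncodingMap:
    """Serializable recipe turning a mixed table into pure numbers."""

    columns: list
    kinds: dict                    # column -> bool | category | date | numeric
    categories: dict               # column -> sorted label list

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        out = pd.DataFrame(index=table.index)
        for col in self.columns:
            s = table[col]
            kind = self.kinds[col]
            if kind == "bool":
                out[col] = s.map({True: 1.0, False: 0.0}).astype(float)
            elif kind == "date":
                out[col] = (pd.to_datetime(s) - EPOCH).dt.total_seconds() / 86400.0
            elif kind == "category":
                labels = self.categories[col]
                mapping = {lab: float(i) for i, lab in enumerate(labels)}
                enc = s.map(mapping)
                unseen = s.notna() & enc.isna()
                if unseen.any():
                    raise ValueError(
                        "unseen category for %r: %r" % (col, s[unseen].iloc[0]))
                out[col] = enc.astype(float)
            else:
                out[col] = s.astype(float)
        return out

    def to_json(self) -> str:
        return json.dumps({"columns": self.columns, "kinds": self.kinds,
                           "categories": self.categories}, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "EncodingMap":
        d = json.loads(text)
        return cls(d["columns"], d["kinds"], d["categories"])


def encode_nonnumeric(table: pd.DataFrame) -> tuple[pd.DataFrame, EncodingMap]:
    """Booleans -> {0,1}; categoricals -> stable sorted-label integer
    codes; dates -> days since 1970-01-01.  The table must be null-free."""
    if table.isna().to_numpy().any():
        raise ValueError("encode_nonnumeric requires a null-free table")
    kinds, categories = {}, {}
    for col in table.columns:
        s = table[col]
        if pd.api.types.is_datetime64_any_dtype(s):
            kinds[col] = "date"
        elif pd.api.types.is_bool_dtype(s) or s.map(type).eq(bool).all():
            kinds[col] = "bool"
        elif pd.api.types.is_numeric_dtype(s):
            kinds[col] = "numeric"
        else:
            kinds[col] = "category"
            categories[col] = sorted(s.unique())
    emap = EncodingMap(list(table.columns), kinds, categories)
    return emap.transform(table), emap


def nontemporal_table(cohort: Cohort) -> pd.DataFrame:
    """The model-variable view of the patient table (bookkeeping removed)."""
    drop = [c for c in BOOKKEEPING if c in cohort.patients.columns]
    return cohort.patients.drop(columns=drop)


def preprocess_cohort(cohort: Cohort,
                      config: PreprocessConfig | None = None
                      ) -> tuple[Cohort, pd.DataFrame, EncodingMap, PreprocessReport]:
    """Full pipeline: exclusions -> drops -> missing-rate drop -> MICE ->
    encoding.  Returns (filtered cohort, numeric table, encoding map,
    report)."""
    config = config or PreprocessConfig()
    cohort, report = apply_exclusions(cohort, config)
    table = nontemporal_table(cohort)
    table, report = filter_variables(table, config, report)
    report.imputed_counts = {c: int(n) for c, n in
                             table.isna().sum().items() if n}
    table = impute_mice(table, config.n_imputations, config.seed)
    numeric, emap = encode_nonnumeric(table)
    return cohort, numeric, emap, report
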