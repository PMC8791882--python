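"""Domain types and I/O for tooth-level periodontal cohorts.

A cohort is the nested data structure the whole pipeline operates on: teeth
(the modelling unit) clustered within patients.  Patient covariates are age,
gender, smoking status, diabetes, and the plaque control record (PCR, percent
of surfaces with visible plaque).  Tooth covariates are jaw, tooth type,
furcation class, interproximal bone loss (ordinal, as a fraction of root
length), infrabony defect depth, and abutment status.  The outcome is a
binary indicator of loss within the 10-year maintenance window.

Teeth are identified by two-digit FDI codes; third molars (codes x8) are
excluded throughout, so each patient contributes at most 28 teeth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GENDER_LEVELS",
    "SMOKING_LEVELS",
    "YESNO_LEVELS",
    "JAW_LEVELS",
    "TOOTH_TYPE_LEVELS",
    "FURCATION_LEVELS",
    "BONE_LOSS_RAW_LEVELS",
    "BONE_LOSS_CAT_LEVELS",
    "INFRABONY_LEVELS",
    "ABUTMENT_LEVELS",
    "TOOTH_COLUMNS",
    "PATIENT_COLUMNS",
    "PATIENT_VARS",
    "TOOTH_VARS",
    "DEFAULT_COMPLETE_CASE_VARS",
    "VALID_TOOTH_IDS",
    "CohortSchemaError",
    "CohortValidationError",
    "PatientRecord",
    "ToothRecord",
    "Cohort",
    "FilterReport",
    "merge_bone_loss",
    "fdi_tooth_type",
    "read_cohort_csv",
    "write_cohort_csv",
    "complete_case_filter",
    "descriptive_tables",
    "annual_loss_rate",
    "cohorts_equal",
]

GENDER_LEVELS = ("female", "male")
SMOKING_LEVELS = ("never", "former", "active")
YESNO_LEVELS = ("no", "yes")
JAW_LEVELS = ("maxilla", "mandible")
TOOTH_TYPE_LEVELS = ("anterior", "premolar", "molar")
FURCATION_LEVELS = ("single_rooted", "multi_no_fi", "multi_fi")
BONE_LOSS_RAW_LEVELS = ("<=20", "21-40", "41-60", "61-80", ">80")
BONE_LOSS_CAT_LEVELS = ("<=20", "21-40", "41-60", ">60")
INFRABONY_LEVELS = ("shallow", "moderate", "deep")
ABUTMENT_LEVELS = ("none", "fixed", "removable")

#: CSV schema, one row per tooth with the patient columns repeated.
TOOTH_COLUMNS = (
    "patient_id",
    "tooth_id",
    "age",
    "gender",
    "smoking",
    "diabetes",
    "pcr",
    "jaw",
    "tooth_type",
    "furcation_class",
    "bone_loss_raw",
    "infrabony",
    "abutment",
    "lost_by_T2",
)
PATIENT_COLUMNS = ("patient_id", "age", "gender", "smoking", "diabetes", "pcr")

PATIENT_VARS = ("age", "gender", "smoking", "diabetes", "pcr")
TOOTH_VARS = (
    "jaw",
    "tooth_type",
    "furcation_class",
    "bone_loss_raw",
    "bone_loss_cat",
    "infrabony",
    "abutment",
)

#: Complete-case default: every modelled covariate except PCR.  PCR is kept
#: optional because the study population retains all patients despite PCR
#: being recorded for only a subset.
DEFAULT_COMPLETE_CASE_VARS = (
    "age",
    "gender",
    "smoking",
    "diabetes",
    "jaw",
    "tooth_type",
    "furcation_class",
    "bone_loss_cat",
    "infrabony",
    "abutment",
)

_CATEGORICAL_LEVELS: Mapping[str, tuple[str, ...]] = {
    "gender": GENDER_LEVELS,
    "smoking": SMOKING_LEVELS,
    "diabetes": YESNO_LEVELS,
    "jaw": JAW_LEVELS,
    "tooth_type": TOOTH_TYPE_LEVELS,
    "furcation_class": FURCATION_LEVELS,
    "bone_loss_raw": BONE_LOSS_RAW_LEVELS,
    "bone_loss_cat": BONE_LOSS_CAT_LEVELS,
    "infrabony": INFRABONY_LEVELS,
    "abutment": ABUTMENT_LEVELS,
}

#: FDI two-digit codes, quadrants 1-4, positions 1-7 (x8 = third molars excluded).
VALID_TOOTH_IDS = frozenset(10 * q + p for q in (1, 2, 3, 4) for p in range(1, 8))
_THIRD_MOLARS = frozenset(10 * q + 8 for q in (1, 2, 3, 4))

_BL_MERGE = {"<=20": "<=20", "21-40": "21-40", "41-60": "41-60", "61-80": ">60", ">80": ">60"}


class CohortSchemaError(ValueError):
    """A required column is missing or the file layout is unusable."""


class CohortValidationError(ValueError):
    """One or more rows violate cohort invariants.

    ``diagnostics`` lists one human-readable message per offending row.
    """

    def __init__(self, diagnostics: Sequence[str]):
        self.diagnostics = list(diagnostics)
        preview = "; ".join(self.diagnostics[:5])
        more = "" if len(self.diagnostics) <= 5 else f" (+{len(self.diagnostics) - 5} more)"
        super().__init__(f"{len(self.diagnostics)} invalid row(s): {preview}{more}")


def merge_bone_loss(raw: str | float) -> str | float:
    """Collapse the five raw bone-loss categories to four (61-80% and >80% -> >60%)."""
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return np.nan
    return _BL_MERGE[str(raw)]


def fdi_tooth_type(tooth_id: int) -> str:
    """Tooth type implied by an FDI code: positions 1-3 anterior, 4-5 premolar, 6-7 molar."""
    pos = int(tooth_id) % 10
    if pos in (1, 2, 3):
        return "anterior"
    if pos in (4, 5):
        return "premolar"
    if pos in (6, 7):
        return "molar"
    raise ValueError(f"FDI position {pos} is not part of the analysable dentition")


@dataclass(frozen=True)
class PatientRecord:
    """One patient's baseline covariates."""

    patient_id: str
    age: float
    gender: str
    smoking: str
    diabetes: str
    pcr: float | None = None

    def __post_init__(self):
        if not np.isnan(self.age) and self.age <= 0:
            raise ValueError(f"patient {self.patient_id}: age must be positive")
        if self.pcr is not None and not np.isnan(self.pcr) and not 0 <= self.pcr <= 100:
            raise ValueError(f"patient {self.patient_id}: pcr must lie in [0, 100]")
        for fieldname in ("gender", "smoking", "diabetes"):
            val = getattr(self, fieldname)
            if not (isinstance(val, float) and np.isnan(val)) and val not in _CATEGORICAL_LEVELS[fieldname]:
                raise ValueError(
                    f"patient {self.patient_id}: unknown {fieldname} level {val!r}"
                )


@dataclass(frozen=True)
class ToothRecord:
    """One tooth's covariates and 10-year outcome, keyed to its patient."""

    patient_id: str
    tooth_id: int
    jaw: str
    tooth_type: str
    furcation_class: str
    bone_loss_raw: str
    infrabony: str
    abutment: str
    lost_by_T2: int

    @property
    def bone_loss_cat(self) -> str:
        return merge_bone_loss(self.bone_loss_raw)


@dataclass
class Cohort:
    """Nested patient/tooth collection.

    ``patients`` has one row per patient (columns :data:`PATIENT_COLUMNS`);
    ``teeth`` one row per tooth, including the derived ``bone_loss_cat``
    column.  ``provenance`` records the source and any filters applied.
    """

    patients: pd.DataFrame
    teeth: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    @property
    def n_patients(self) -> int:
        return len(self.patients)

    @property
    def n_teeth(self) -> int:
        return len(self.teeth)

    def merged(self) -> pd.DataFrame:
        """Tooth-level modelling frame: teeth joined with their patient covariates."""
        return self.teeth.merge(self.patients, on="patient_id", how="left", validate="m:1")

    def copy(self) -> "Cohort":
        return Cohort(self.patients.copy(), self.teeth.copy(), dict(self.provenance))


def _validate_frames(
    patients: pd.DataFrame, teeth: pd.DataFrame
) -> list[str]:
    """Return row-indexed diagnostics for every invariant violation (vectorised)."""
    diags: list[str] = []

    def flag(mask: pd.Series | np.ndarray, template) -> None:
        for idx in teeth.index[np.asarray(mask)]:
            diags.append(template(idx))

    tid = pd.to_numeric(teeth["tooth_id"], errors="coerce")
    bad_code = tid.isna()
    flag(bad_code, lambda i: f"row {i}: tooth_id {teeth.at[i, 'tooth_id']!r} is not an FDI code")
    tid_int = tid.fillna(0).astype(int)
    third = tid_int.isin(list(_THIRD_MOLARS))
    flag(third, lambda i: f"row {i}: tooth_id {tid_int[i]} is a third molar (excluded)")
    invalid = ~bad_code & ~third & ~tid_int.isin(list(VALID_TOOTH_IDS))
    flag(invalid, lambda i: f"row {i}: tooth_id {tid_int[i]} is not a valid FDI code")

    ok = ~(bad_code | third | invalid)
    pos = tid_int % 10
    expected = pd.Series(
        np.select([pos <= 3, pos <= 5], ["anterior", "premolar"], default="molar"),
        index=teeth.index,
    )
    ttype = teeth["tooth_type"]
    has_type = ttype.notna()
    mismatch = ok & has_type & (ttype != expected)
    flag(
        mismatch,
        lambda i: (
            f"row {i}: tooth_id {tid_int[i]} implies {expected[i]}, "
            f"got tooth_type {ttype[i]!r}"
        ),
    )
    furc = teeth["furcation_class"]
    has_furc = furc.notna()
    bad_ant = has_type & has_furc & (ttype == "anterior") & (furc != "single_rooted")
    flag(bad_ant, lambda i: f"row {i}: anterior tooth must be single_rooted, got {furc[i]!r}")
    bad_mol = has_type & has_furc & (ttype == "molar") & (furc == "single_rooted")
    flag(bad_mol, lambda i: f"row {i}: molar must be multi-rooted, got {furc[i]!r}")

    known = set(patients["patient_id"])
    orphan = ~teeth["patient_id"].isin(known)
    flag(orphan, lambda i: f"row {i}: unknown patient_id {teeth.at[i, 'patient_id']!r}")

    y = pd.to_numeric(teeth["lost_by_T2"], errors="coerce")
    bad_y = ~y.isin([0, 1])
    flag(bad_y, lambda i: f"row {i}: lost_by_T2 must be 0 or 1, got {teeth.at[i, 'lost_by_T2']!r}")

    dup = teeth.duplicated(subset=["patient_id", "tooth_id"], keep=False)
    flag(
        dup,
        lambda i: (
            f"row {i}: duplicate (patient_id, tooth_id) "
            f"({teeth.at[i, 'patient_id']}, {teeth.at[i, 'tooth_id']})"
        ),
    )
    counts = teeth.groupby("patient_id").size()
    for pid, n in counts[counts > 28].items():
        diags.append(f"patient {pid}: {n} teeth exceeds the 28-tooth dentition")

    page = pd.to_numeric(patients["age"], errors="coerce")
    for idx in patients.index[page.notna() & (page <= 0)]:
        diags.append(f"patient row {idx}: age {page[idx]} must be positive")
    ppcr = pd.to_numeric(patients["pcr"], errors="coerce")
    for idx in patients.index[ppcr.notna() & ~ppcr.between(0, 100)]:
        diags.append(f"patient row {idx}: pcr {ppcr[idx]} outside [0, 100]")
    return diags


def _check_levels(df: pd.DataFrame, columns: Iterable[str]) -> None:
    for col in columns:
        if col not in df.columns:
            continue
        levels = _CATEGORICAL_LEVELS[col]
        vals = df[col].dropna()
        bad = vals[~vals.isin(levels)]
        if len(bad):
            idx = bad.index[0]
            raise ValueError(
                f"row {idx}: unknown level {bad.iloc[0]!r} for field {col!r} "
                f"(expected one of {levels})"
            )


def build_cohort(
    patients: pd.DataFrame,
    teeth: pd.DataFrame,
    provenance: dict | None = None,
    drop_third_molars: bool = True,
) -> Cohort:
    """Assemble and validate a :class:`Cohort` from raw frames.

    Third-molar rows are dropped (with a diagnostic recorded in the
    provenance) when ``drop_third_molars`` is set, mirroring the global
    exclusion of third molars from the analysis; any other invariant
    violation raises :class:`CohortValidationError`.
    """
    patients = patients.reset_index(drop=True).copy()
    teeth = teeth.reset_index(drop=True).copy()
    provenance = dict(provenance or {})

    _check_levels(teeth, [c for c in _CATEGORICAL_LEVELS if c in teeth.columns])
    _check_levels(patients, ("gender", "smoking", "diabetes"))

    rejected: list[str] = []
    if drop_third_molars:
        tid = pd.to_numeric(teeth["tooth_id"], errors="coerce")
        mask = tid.isin(list(_THIRD_MOLARS))
        for idx in teeth.index[mask]:
            rejected.append(
                f"row {idx}: tooth_id {teeth.at[idx, 'tooth_id']} is a third molar (excluded)"
            )
        teeth = teeth[~mask].reset_index(drop=True)
    if rejected:
        provenance.setdefault("rejected_rows", []).extend(rejected)

    diags = _validate_frames(patients, teeth)
    if diags:
        raise CohortValidationError(diags)

    teeth["bone_loss_cat"] = pd.Categorical(
        teeth["bone_loss_raw"].map(_BL_MERGE), categories=BONE_LOSS_CAT_LEVELS, ordered=True
    )
    teeth["bone_loss_raw"] = pd.Categorical(
        teeth["bone_loss_raw"], categories=BONE_LOSS_RAW_LEVELS, ordered=True
    )
    teeth["infrabony"] = pd.Categorical(
        teeth["infrabony"], categories=INFRABONY_LEVELS, ordered=True
    )
    return Cohort(patients=patients, teeth=teeth, provenance=provenance)


def read_cohort_csv(
    path: str | Path,
    patient_path: str | Path | None = None,
    drop_third_molars: bool = True,
) -> Cohort:
    """Read a cohort from the documented one-row-per-tooth CSV schema.

    Empty fields and the token ``NA`` are treated as missing.  An optional
    patient-only CSV may be supplied and is joined on ``patient_id`` (its
    values take precedence for patient covariates).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str, na_values=["NA"], keep_default_na=True)
    df.columns = [c.strip().lower() if c.strip() != "lost_by_T2" else c for c in df.columns]
    df.columns = [("lost_by_T2" if c == "lost_by_t2" else c) for c in df.columns]
    # patient covariates may live in the separate file instead
    required_tooth = [c for c in TOOTH_COLUMNS if c not in ("age", "gender", "smoking", "diabetes", "pcr")]
    missing_cols = [c for c in required_tooth if c not in df.columns]
    if missing_cols:
        raise CohortSchemaError(f"missing required column(s): {missing_cols} in {path}")

    if patient_path is not None:
        pdf = pd.read_csv(patient_path, dtype=str, na_values=["NA"])
        pdf.columns = [c.strip().lower() for c in pdf.columns]
        pmissing = [c for c in PATIENT_COLUMNS if c not in pdf.columns]
        if pmissing:
            raise CohortSchemaError(f"missing required column(s): {pmissing} in {patient_path}")
        patients = pdf[list(PATIENT_COLUMNS)].copy()
    else:
        pmissing = [c for c in PATIENT_COLUMNS if c not in df.columns]
        if pmissing:
            raise CohortSchemaError(
                f"missing required column(s): {pmissing} in {path} (no patient file given)"
            )
        patients = df[list(PATIENT_COLUMNS)].drop_duplicates(subset="patient_id").copy()
        # patient covariates must be constant within patient in a denormalized file
        nun = df.groupby("patient_id")[["age", "gender", "smoking", "diabetes", "pcr"]].nunique(
            dropna=False
        )
        bad = nun[(nun > 1).any(axis=1)]
        if len(bad):
            raise CohortValidationError(
                [f"patient {pid}: inconsistent patient covariates across tooth rows" for pid in bad.index]
            )

    patients["age"] = pd.to_numeric(patients["age"], errors="coerce")
    patients["pcr"] = pd.to_numeric(patients["pcr"], errors="coerce")

    teeth = df[[c for c in TOOTH_COLUMNS if c not in ("age", "gender", "smoking", "diabetes", "pcr")]].copy()
    teeth["tooth_id"] = pd.to_numeric(teeth["tooth_id"], errors="coerce").astype("Int64")
    y = pd.to_numeric(teeth["lost_by_T2"], errors="coerce")
    if y.isna().any():
        idx = int(y.index[y.isna()][0])
        raise ValueError(f"row {idx}: lost_by_T2 must be 0 or 1")
    teeth["lost_by_T2"] = y.astype(int)
    teeth["tooth_id"] = teeth["tooth_id"].astype(int)

    return build_cohort(
        patients,
        teeth,
        provenance={"source": str(path), "filters": []},
        drop_third_molars=drop_third_molars,
    )


def write_cohort_csv(cohort: Cohort, path: str | Path) -> Path:
    """Write the cohort in the standard one-row-per-tooth schema."""
    path = Path(path)
    out = cohort.merged()
    out = out[list(TOOTH_COLUMNS)]
    out.to_csv(path, index=False, na_rep="")
    return path


def cohorts_equal(a: Cohort, b: Cohort) -> bool:
    """Order-insensitive equality of two cohorts (provenance ignored)."""

    def norm_teeth(c: Cohort) -> pd.DataFrame:
        t = c.teeth
        cols = [col for col in TOOTH_COLUMNS if col in t.columns]
        t = t[cols].copy()
        for col in cols:
            if col in _CATEGORICAL_LEVELS:
                t[col] = t[col].astype(str)
        return t.sort_values(["patient_id", "tooth_id"]).reset_index(drop=True)

    def norm_pat(c: Cohort) -> pd.DataFrame:
        p = c.patients[list(PATIENT_COLUMNS)].copy()
        return p.sort_values("patient_id").reset_index(drop=True)

    ta, tb = norm_teeth(a), norm_teeth(b)
    pa, pb = norm_pat(a), norm_pat(b)
    if ta.shape != tb.shape or pa.shape != pb.shape:
        return False
    teeth_eq = all(
        ta[c].equals(tb[c]) if ta[c].dtype == object else np.allclose(ta[c], tb[c], equal_nan=True)
        for c in ta.columns
    )
    pat_eq = all(
        pa[c].equals(pb[c])
        if pa[c].dtype == object
        else np.allclose(pa[c].astype(float), pb[c].astype(float), equal_nan=True)
        for c in pa.columns
    )
    return teeth_eq and pat_eq


@dataclass
class FilterReport:
    """Accounting of a complete-case filter pass."""

    required_vars: tuple[str, ...]
    n_teeth_before: int
    n_teeth_after: int
    n_patients_before: int
    n_patients_after: int
    removed_teeth_by_var: dict[str, int]

    @property
    def n_teeth_removed(self) -> int:
        return self.n_teeth_before - self.n_teeth_after

    @property
    def n_patients_removed(self) -> int:
        return self.n_patients_before - self.n_patients_after


def complete_case_filter(
    cohort: Cohort,
    required_vars: Sequence[str] = DEFAULT_COMPLETE_CASE_VARS,
) -> tuple[Cohort, FilterReport]:
    """Drop teeth with missing values in any required covariate.

    A missing patient-level covariate removes all of that patient's teeth.
    Patients left with no teeth are dropped.  Raises ``ValueError`` if
    nothing survives, and if ``required_vars`` contains an unknown name.
    """
    known = set(PATIENT_VARS) | set(TOOTH_VARS)
    unknown = [v for v in required_vars if v not in known]
    if unknown:
        raise ValueError(f"unknown covariate(s) in required_vars: {unknown}")

    merged = cohort.merged()
    removed_by_var: dict[str, int] = {}
    keep = pd.Series(True, index=merged.index)
    for var in required_vars:
        miss = merged[var].isna()
        removed_by_var[var] = int(miss.sum())
        keep &= ~miss

    teeth = cohort.teeth[keep.to_numpy()].reset_index(drop=True)
    if len(teeth) == 0:
        raise ValueError("complete-case filter removed every tooth; nothing to analyse")
    surviving = set(teeth["patient_id"])
    patients = cohort.patients[cohort.patients["patient_id"].isin(surviving)].reset_index(drop=True)

    report = FilterReport(
        required_vars=tuple(required_vars),
        n_teeth_before=cohort.n_teeth,
        n_teeth_after=len(teeth),
        n_patients_before=cohort.n_patients,
        n_patients_after=len(patients),
        removed_teeth_by_var=removed_by_var,
    )
    provenance = dict(cohort.provenance)
    provenance.setdefault("filters", []).append(
        {"complete_case": list(required_vars), "teeth_removed": report.n_teeth_removed}
    )
    return Cohort(patients=patients, teeth=teeth, provenance=provenance), report


def descriptive_tables(cohort: Cohort, include_chi2: bool = True) -> dict[str, pd.DataFrame]:
    """Patient- and tooth-level descriptive summaries.

    Returns ``{"patients", "patients_continuous", "teeth"}``.  The tooth
    table cross-tabulates each covariate against the 10-year outcome with
    retention/loss percentages.  ``chi2_p_naive`` is the Pearson chi-squared
    p-value per variable, computed on the flat 2-way table; it ignores the
    clustering of teeth within patients and is reported for orientation only.
    """
    if cohort.n_teeth == 0 or cohort.n_patients == 0:
        raise ValueError("descriptive_tables requires a non-empty cohort")

    pats = cohort.patients
    rows = []
    for var in ("gender", "smoking", "diabetes"):
        counts = pats[var].value_counts(dropna=True)
        total = int(counts.sum())
        for level in _CATEGORICAL_LEVELS[var]:
            n = int(counts.get(level, 0))
            if n == 0 and level not in counts.index:
                continue
            rows.append(
                {"variable": var, "level": level, "count": n, "percent": 100.0 * n / total}
            )
    patients_tab = pd.DataFrame(rows)

    cont_rows = []
    for var in ("age", "pcr"):
        vals = pd.to_numeric(pats[var], errors="coerce").dropna()
        cont_rows.append(
            {
                "variable": var,
                "n": int(len(vals)),
                "mean": float(vals.mean()) if len(vals) else np.nan,
                "sd": float(vals.std(ddof=1)) if len(vals) > 1 else np.nan,
            }
        )
    patients_cont = pd.DataFrame(cont_rows)

    teeth = cohort.teeth
    y = teeth["lost_by_T2"].to_numpy()
    trows = []
    for var in ("jaw", "tooth_type", "furcation_class", "abutment", "bone_loss_raw", "bone_loss_cat", "infrabony"):
        col = teeth[var]
        present = col.notna()
        chi2_p = np.nan
        if include_chi2:
            sub = pd.DataFrame({"level": col[present].astype(str), "lost": y[present.to_numpy()]})
            table = pd.crosstab(sub["level"], sub["lost"])
            if table.shape[0] > 1 and table.shape[1] > 1:
                chi2_p = float(stats.chi2_contingency(table.to_numpy(), correction=False)[1])
        levels = [lv for lv in _CATEGORICAL_LEVELS[var] if (col.astype(str) == lv).any()]
        for level in levels:
            mask = (col.astype(str) == level).to_numpy()
            total = int(mask.sum())
            lost = int(y[mask].sum())
            retained = total - lost
            trows.append(
                {
                    "variable": var,
                    "level": level,
                    "total": total,
                    "retained": retained,
                    "retained_pct": 100.0 * retained / total if total else np.nan,
                    "lost": lost,
                    "lost_pct": 100.0 * lost / total if total else np.nan,
                    "n_missing": int((~present).sum()),
                    "chi2_p_naive": chi2_p,
                }
            )
    teeth_tab = pd.DataFrame(trows)
    return {"patients": patients_tab, "patients_continuous": patients_cont, "teeth": teeth_tab}


def annual_loss_rate(cohort: Cohort, years: float = 10.0) -> float:
    """Teeth lost per patient per year: (total lost) / (years x patients)."""
    if years <= 0:
        raise ValueError("years must be positive")
    if cohort.n_patients == 0:
        raise ValueError("annual_loss_rate requires at least one patient")
    lost = int(cohort.teeth["lost_by_T2"].sum())
    return lost / (years * cohort.n_patients)
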