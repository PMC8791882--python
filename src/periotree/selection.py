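"""Patient-clustered bootstrap variable selection.

Robustness of the tree's automated variable selection is assessed by
refitting the model tree on bootstrap samples drawn at the *patient* level:
patients are drawn with replacement until the replicate holds the same
number of patients as the original data, each drawn copy carrying all of the
patient's teeth under a fresh cluster identifier (duplicated patients are
independent clusters, which keeps the random-intercept likelihood well
defined).  A variable "occurs" in a replicate when it appears in at least
one split of that replicate's tree.  Selection uses asymmetric inclusion
thresholds: tooth-level variables kept when selected by **more than 50%** of
replicate models, patient-level variables by **more than 25%** — looser for
patient covariates because patient-level resampling limits their
variability.  Both thresholds are strict inequalities.  The final model is
then refitted on the full data restricted to the selected variables.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, clone

from .cohort import Cohort
from .mixedlm import MixedModelError
from .tree import GLMMTreeClassifier

__all__ = [
    "DEFAULT_VARIABLE_LEVELS",
    "SelectionResult",
    "bootstrap_sample",
    "select_variables",
    "apply_thresholds",
    "final_fit",
    "BootstrapVariableSelector",
]

#: Candidate partitioning variables and the level each lives on.  PCR is not
#: offered by default because it is not part of the default complete-case
#: set (it is missing for a subset of patients that the analysis retains).
DEFAULT_VARIABLE_LEVELS: dict[str, str] = {
    "age": "patient",
    "gender": "patient",
    "smoking": "patient",
    "diabetes": "patient",
    "jaw": "tooth",
    "tooth_type": "tooth",
    "furcation_class": "tooth",
    "bone_loss_cat": "tooth",
    "infrabony": "tooth",
    "abutment": "tooth",
}

TOOTH_THRESHOLD = 0.5
PATIENT_THRESHOLD = 0.25


@dataclass
class SelectionResult:
    """Bootstrap selection frequencies and the retained variable set."""

    n_boot: int
    n_used: int  # replicates entering the denominator (fit failures excluded)
    frequency: dict[str, float]
    selected: list[str]
    variable_levels: dict[str, str]
    replicate_variables: list[list[str]] = field(default_factory=list)
    n_failed: int = 0
    seed: int = 0
    tooth_threshold: float = TOOTH_THRESHOLD
    patient_threshold: float = PATIENT_THRESHOLD

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_boot": self.n_boot,
                "n_used": self.n_used,
                "n_failed": self.n_failed,
                "seed": self.seed,
                "thresholds": {
                    "tooth": self.tooth_threshold,
                    "patient": self.patient_threshold,
                },
                "variable_levels": self.variable_levels,
                "frequency": self.frequency,
                "selected": self.selected,
                "replicate_variables": self.replicate_variables,
            },
            indent=1,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, doc: str) -> "SelectionResult":
        d = json.loads(doc)
        return cls(
            n_boot=d["n_boot"],
            n_used=d["n_used"],
            frequency=d["frequency"],
            selected=d["selected"],
            variable_levels=d["variable_levels"],
            replicate_variables=d["replicate_variables"],
            n_failed=d["n_failed"],
            seed=d["seed"],
            tooth_threshold=d["thresholds"]["tooth"],
            patient_threshold=d["thresholds"]["patient"],
        )


def bootstrap_sample(cohort: Cohort, seed: int | np.random.Generator = 0) -> Cohort:
    """One patient-level bootstrap replicate of the cohort.

    Exactly the original number of patients is drawn with replacement (by
    position, so relabelling patients cannot change the draw).  The j-th
    copy of a patient gets cluster id ``"<pid>#<j>"`` and carries all of the
    patient's teeth.
    """
    if cohort.n_patients < 1:
        raise ValueError("bootstrap_sample requires at least one patient")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = cohort.n_patients
    draw = rng.integers(0, n, size=n)

    teeth_by_pat = dict(tuple(cohort.teeth.groupby("patient_id", sort=False)))
    pat = cohort.patients.reset_index(drop=True)
    copy_count: dict[int, int] = {}
    new_pat_rows = []
    new_teeth = []
    for pos in draw:
        j = copy_count.get(int(pos), 0)
        copy_count[int(pos)] = j + 1
        row = pat.iloc[int(pos)]
        new_id = f"{row['patient_id']}#{j}"
        prow = row.to_dict()
        prow["patient_id"] = new_id
        new_pat_rows.append(prow)
        t = teeth_by_pat[row["patient_id"]].copy()
        t["patient_id"] = new_id
        new_teeth.append(t)

    patients = pd.DataFrame(new_pat_rows)
    teeth = pd.concat(new_teeth, ignore_index=True)
    provenance = dict(cohort.provenance)
    provenance.setdefault("filters", []).append({"bootstrap_sample": True})
    # frames come from an already-validated cohort; skip revalidation
    return Cohort(patients=patients, teeth=teeth, provenance=provenance)


def apply_thresholds(
    frequency: dict[str, float],
    variable_levels: dict[str, str],
    tooth_threshold: float = TOOTH_THRESHOLD,
    patient_threshold: float = PATIENT_THRESHOLD,
) -> list[str]:
    """Strict asymmetric inclusion: tooth > 50%, patient > 25% of models."""
    selected = []
    for var, freq in frequency.items():
        level = variable_levels[var]
        cut = tooth_threshold if level == "tooth" else patient_threshold
        if freq > cut:
            selected.append(var)
    return sorted(selected)


def select_variables(
    cohort: Cohort,
    variable_levels: dict[str, str] | None = None,
    n_boot: int = 200,
    estimator: GLMMTreeClassifier | None = None,
    seed: int = 0,
    max_failure_fraction: float = 0.1,
) -> SelectionResult:
    """Run the clustered-bootstrap selection.

    Fits one model tree per replicate and counts, per variable, the fraction
    of replicate models containing it in at least one split.  Replicates
    whose mixed-model fit fails are excluded from the denominator (with a
    warning); more than ``max_failure_fraction`` failures is an error.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    variable_levels = dict(variable_levels or DEFAULT_VARIABLE_LEVELS)
    base = estimator if estimator is not None else GLMMTreeClassifier()
    variables = list(variable_levels)

    merged = cohort.merged()
    missing = [v for v in variables if merged[v].isna().any()]
    if missing:
        raise ValueError(
            f"candidate variables with missing values: {missing}; "
            "apply complete_case_filter first"
        )

    rng = np.random.default_rng(seed)
    occurrences: list[list[str]] = []
    n_failed = 0
    for _ in range(n_boot):
        rep = bootstrap_sample(cohort, rng)
        m = rep.merged()
        est = clone(base)
        try:
            est.fit(m[variables], m["lost_by_T2"].to_numpy(), groups=m["patient_id"].to_numpy())
        except (MixedModelError, np.linalg.LinAlgError) as err:
            n_failed += 1
            warnings.warn(f"bootstrap replicate fit failed and was excluded: {err}")
            continue
        occurrences.append(sorted(est.partitioning_variables_))
    if n_failed > max_failure_fraction * n_boot:
        raise RuntimeError(
            f"{n_failed}/{n_boot} bootstrap replicates failed to fit; "
            "selection frequencies would be unreliable"
        )

    n_used = len(occurrences)
    frequency = {
        var: sum(var in occ for occ in occurrences) / n_used for var in variables
    }
    selected = apply_thresholds(frequency, variable_levels)
    return SelectionResult(
        n_boot=n_boot,
        n_used=n_used,
        frequency=frequency,
        selected=selected,
        variable_levels=variable_levels,
        replicate_variables=occurrences,
        n_failed=n_failed,
        seed=seed,
    )


def final_fit(
    cohort: Cohort,
    selection: SelectionResult,
    estimator: GLMMTreeClassifier | None = None,
) -> GLMMTreeClassifier:
    """Refit on the full data restricted to the selected variables."""
    if not selection.selected:
        raise ValueError(
            "bootstrap selection retained no variables; review the inclusion "
            "thresholds or the candidate set before fitting a final model"
        )
    est = clone(estimator) if estimator is not None else GLMMTreeClassifier()
    m = cohort.merged()
    est.fit(
        m[selection.selected],
        m["lost_by_T2"].to_numpy(),
        groups=m["patient_id"].to_numpy(),
    )
    return est


class BootstrapVariableSelector(BaseEstimator):
    """Estimator-style wrapper around :func:`select_variables`.

    Parameters mirror the function; after :meth:`fit` the results live in
    ``frequencies_``, ``selected_`` and ``result_`` (a
    :class:`SelectionResult`).
    """

    def __init__(
        self,
        n_boot: int = 200,
        estimator: GLMMTreeClassifier | None = None,
        variable_levels: dict[str, str] | None = None,
        random_state: int = 0,
    ):
        self.n_boot = n_boot
        self.estimator = estimator
        self.variable_levels = variable_levels
        self.random_state = random_state

    def fit(self, cohort: Cohort, y=None):
        self.result_ = select_variables(
            cohort,
            variable_levels=self.variable_levels,
            n_boot=self.n_boot,
            estimator=self.estimator,
            seed=self.random_state,
        )
        self.frequencies_ = self.result_.frequency
        self.selected_ = self.result_.selected
        return self
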