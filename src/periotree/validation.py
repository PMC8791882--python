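"""Patient-grouped cross-validation with Wilson confidence intervals.

Internal validation of the prognostic tree must respect the clustering of
teeth within patients: folds are split *by patient*, so all teeth of a
patient land in the same fold and training and test sets stay independent.
Folds hold equal numbers of patients (within one), not equal numbers of
teeth.  Per fold the model is refitted on the training patients' teeth and
marginal (new-patient) probabilities are predicted for the test patients'
teeth; AUC, sensitivity and specificity are averaged over folds.

The discrimination threshold for sensitivity/specificity is not part of the
model; the default policy maximises Youden's J (sensitivity + specificity
- 1) on the *training* fold's predictions and applies that threshold to the
test fold.  A fixed threshold can be supplied instead.

Confidence intervals are 95% Wilson score intervals computed with n equal
to the number of independent patients — deliberately conservative, and a
non-standard use of a binomial interval around a cross-validated mean that
is reproduced here because it is how the published metrics are reported.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.stats import rankdata
from sklearn.base import clone

from .cohort import Cohort
from .tree import GLMMTreeClassifier

__all__ = [
    "SingleClassError",
    "CVResult",
    "patient_kfold",
    "roc_auc",
    "youden_threshold",
    "sens_spec",
    "wilson_ci",
    "cross_validate",
    "naive_metrics",
]


class SingleClassError(ValueError):
    """Raised when a metric needs both outcome classes and only one is present."""


def patient_kfold(patient_ids, k: int = 10, seed: int = 0) -> list[np.ndarray]:
    """Shuffle patients and split them into k folds with sizes differing by <= 1."""
    ids = np.asarray(patient_ids)
    if ids.size != np.unique(ids).size:
        raise ValueError("patient_ids must be unique")
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > ids.size:
        raise ValueError(f"k={k} exceeds the number of patients ({ids.size})")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(ids.size)
    return [ids[chunk] for chunk in np.array_split(perm, k)]


def roc_auc(scores, labels) -> float:
    """Rank-based (Mann-Whitney) AUC with average ranks for ties."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise SingleClassError("AUC is undefined with a single outcome class")
    ranks = rankdata(scores, method="average")
    pos_rank_sum = float(ranks[labels == 1].sum())
    return (pos_rank_sum - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def youden_threshold(scores, labels) -> float:
    """Threshold (classify positive when score >= t) maximising Youden's J.

    Candidate thresholds are the distinct observed scores.  Ties in J are
    broken toward the larger threshold, favouring specificity — the
    clinically preferred error trade-off here (calling retention correctly).
    With all scores equal the policy returns that score, classifying
    everything positive: (sensitivity, specificity) = (1, 0).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if (labels == 1).sum() == 0 or (labels == 0).sum() == 0:
        raise SingleClassError("Youden threshold needs both classes")
    best_t, best_j = None, -np.inf
    for t in np.unique(scores):
        pred = scores >= t
        sens = float((pred & (labels == 1)).sum()) / (labels == 1).sum()
        spec = float((~pred & (labels == 0)).sum()) / (labels == 0).sum()
        j = sens + spec - 1.0
        if j > best_j or (j == best_j and (best_t is None or t > best_t)):
            best_j, best_t = j, t
    return float(best_t)


def sens_spec(scores, labels, threshold: float) -> tuple[float, float]:
    """Sensitivity and specificity at a threshold (positive when score >= t)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == 1
    neg = labels == 0
    if pos.sum() == 0 or neg.sum() == 0:
        raise SingleClassError("sensitivity/specificity need both classes")
    pred = scores >= threshold
    sens = float((pred & pos).sum() / pos.sum())
    spec = float((~pred & neg).sum() / neg.sum())
    return sens, spec


def wilson_ci(p: float, n: int, level: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a proportion-scale value with n independent units.

    Unlike the Wald interval it respects [0, 1] and behaves sensibly at the
    boundaries (p = 1 gives an upper limit of exactly 1).
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    if n < 1:
        raise ValueError("n must be >= 1")
    z = stats.norm.ppf(0.5 + level / 2.0)
    denom = 1.0 + z * z / n
    centre = (p + z * z / (2.0 * n)) / denom
    half = z * np.sqrt(p * (1.0 - p) / n + z * z / (4.0 * n * n)) / denom
    # analytically within [0, 1]; clamp float rounding at the boundaries
    return float(max(0.0, centre - half)), float(min(1.0, centre + half))


@dataclass
class CVResult:
    """Cross-validated performance with patient-based Wilson intervals."""

    k: int
    n_patients: int
    seed: int
    fold_auc: list[float]
    fold_sens: list[float]
    fold_spec: list[float]
    auc: float
    sensitivity: float
    specificity: float
    auc_ci: tuple[float, float]
    sensitivity_ci: tuple[float, float]
    specificity_ci: tuple[float, float]
    threshold_policy: str
    skipped_folds: list[int] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "k": self.k,
                "n_patients": self.n_patients,
                "seed": self.seed,
                "threshold_policy": self.threshold_policy,
                "fold_auc": self.fold_auc,
                "fold_sens": self.fold_sens,
                "fold_spec": self.fold_spec,
                "auc": self.auc,
                "sensitivity": self.sensitivity,
                "specificity": self.specificity,
                "auc_ci": list(self.auc_ci),
                "sensitivity_ci": list(self.sensitivity_ci),
                "specificity_ci": list(self.specificity_ci),
                "skipped_folds": self.skipped_folds,
            },
            indent=1,
            sort_keys=True,
        )


def _fit_on(est: GLMMTreeClassifier, merged, variables):
    est.fit(
        merged[variables],
        merged["lost_by_T2"].to_numpy(),
        groups=merged["patient_id"].to_numpy(),
    )
    return est


def cross_validate(
    cohort: Cohort,
    variables: list[str],
    estimator: GLMMTreeClassifier | None = None,
    k: int = 10,
    seed: int = 0,
    threshold: float | None = None,
    max_skipped_folds: int = 3,
) -> CVResult:
    """Patient-grouped k-fold cross-validation of the selected-variable model.

    ``threshold=None`` applies the training-fold Youden policy; a number
    applies that fixed threshold to every fold.  Folds whose test teeth
    carry a single outcome class are skipped with a warning; more than
    ``max_skipped_folds`` skipped folds is an error.
    """
    base = estimator if estimator is not None else GLMMTreeClassifier()
    merged = cohort.merged()
    y_all = merged["lost_by_T2"].to_numpy()
    if y_all.sum() in (0, len(y_all)):
        raise SingleClassError("cross-validation needs both outcome classes overall")
    folds = patient_kfold(cohort.patients["patient_id"].to_numpy(), k=k, seed=seed)

    fold_auc, fold_sens, fold_spec, skipped = [], [], [], []
    for fold_idx, test_patients in enumerate(folds):
        test_mask = merged["patient_id"].isin(test_patients).to_numpy()
        train = merged[~test_mask]
        test = merged[test_mask]
        assert not set(train["patient_id"]) & set(test["patient_id"])
        y_test = test["lost_by_T2"].to_numpy()
        if y_test.sum() in (0, len(y_test)) or train["lost_by_T2"].sum() in (0, len(train)):
            skipped.append(fold_idx)
            warnings.warn(f"fold {fold_idx}: single outcome class; metrics skipped")
            continue
        est = _fit_on(clone(base), train, variables)
        # test patients are unseen: marginal (population-averaged) predictions
        p_test = est.predict_tooth_proba(test[variables], mode="marginal")
        fold_auc.append(roc_auc(p_test, y_test))
        if threshold is None:
            p_train = est.predict_tooth_proba(train[variables], mode="marginal")
            t = youden_threshold(p_train, train["lost_by_T2"].to_numpy())
        else:
            t = float(threshold)
        se, sp = sens_spec(p_test, y_test, t)
        fold_sens.append(se)
        fold_spec.append(sp)

    if len(skipped) > max_skipped_folds:
        raise SingleClassError(
            f"{len(skipped)} folds had single-class test outcomes (max {max_skipped_folds})"
        )

    n_pat = cohort.n_patients
    auc = float(np.mean(fold_auc))
    sens = float(np.mean(fold_sens))
    spec = float(np.mean(fold_spec))
    return CVResult(
        k=k,
        n_patients=n_pat,
        seed=seed,
        fold_auc=[float(v) for v in fold_auc],
        fold_sens=[float(v) for v in fold_sens],
        fold_spec=[float(v) for v in fold_spec],
        auc=auc,
        sensitivity=sens,
        specificity=spec,
        auc_ci=wilson_ci(auc, n_pat),
        sensitivity_ci=wilson_ci(sens, n_pat),
        specificity_ci=wilson_ci(spec, n_pat),
        threshold_policy="youden_on_training_fold" if threshold is None else f"fixed:{threshold}",
        skipped_folds=skipped,
    )


def naive_metrics(
    cohort: Cohort,
    variables: list[str],
    estimator: GLMMTreeClassifier | None = None,
    threshold: float | None = None,
) -> dict[str, float]:
    """Training-set (overfit) AUC/sensitivity/specificity of the same model.

    Fit and evaluated on the full data with marginal predictions; reported
    for the contrast with the cross-validated means, which it is expected
    to exceed.
    """
    base = clone(estimator) if estimator is not None else GLMMTreeClassifier()
    merged = cohort.merged()
    est = _fit_on(base, merged, variables)
    p = est.predict_tooth_proba(merged[variables], mode="marginal")
    y = merged["lost_by_T2"].to_numpy()
    t = youden_threshold(p, y) if threshold is None else float(threshold)
    se, sp = sens_spec(p, y, t)
    return {"auc": roc_auc(p, y), "sensitivity": se, "specificity": sp, "threshold": t}
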