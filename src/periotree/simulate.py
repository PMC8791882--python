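"""Synthetic periodontal cohorts with the structure the analysis assumes.

The generator emulates the study population the pipeline was built for:
~110 periodontitis patients completing active therapy, followed for ten
years, contributing on average ~23 teeth each (third molars excluded).
It reproduces

* the published patient-level marginals (61.8% female, 8.2% diabetic,
  smoking 45.5/24.5/30.0% never/former/active, age 46.7 +/- 10.26 years,
  PCR 31.3 +/- 17.39%),
* the tooth-level marginals (jaw, tooth type, furcation within type, raw
  bone-loss category, infrabony depth, abutment status),
* the structural constraints among tooth covariates (anterior teeth are
  single-rooted, molars multi-rooted, bone-loss merge rule, valid FDI
  codes, at most 28 teeth per patient), and
* the published group-conditional 10-year loss rates, through a logistic
  mechanism with a patient random intercept:

  .. math::

     y \\sim \\mathrm{Bernoulli}\\bigl(\\mathrm{logit}^{-1}(\\eta_{g(\\text{tooth})}
     + b_{\\text{patient}})\\bigr), \\quad b \\sim N(0, \\sigma_b^2),

  where :math:`g(\\cdot)` is the published 8-group assignment and the group
  offsets :math:`\\eta_g` are calibrated so the *marginal* loss probability
  of each group matches its target rate for the chosen :math:`\\sigma_b`
  (logistic-normal integral inverted numerically).

Dentition model: each of the 28 FDI positions is present independently with
a type- and jaw-specific probability chosen so the expected tooth-type and
jaw shares equal the configured marginals and the expected dentition size
equals ``mean_teeth``; counts then concentrate in roughly 17-28 teeth.

By default only the five covariates of the published tree affect the
outcome; smoking, gender, PCR, jaw, tooth type and infrabony depth are
generated but carry no effect (they were not in the final tree).  The
``extra_effects`` hook injects additional logit-scale effects for
selection-power experiments, and ``null_rate`` produces an effect-free
cohort with a constant loss probability.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd
from numpy.polynomial.hermite import hermgauss
from scipy.optimize import brentq
from scipy.special import expit, logit

from .calculator import PUBLISHED_GROUPS, assign_group
from .cohort import Cohort, build_cohort, fdi_tooth_type

__all__ = ["SimConfig", "calibrate_offsets", "generate", "default_group_rates"]


def default_group_rates() -> dict[int, float]:
    """Exact published group proportions lost/total (not the rounded percents)."""
    return {g: rg.proportion for g, rg in PUBLISHED_GROUPS.items()}


@dataclass
class SimConfig:
    """All knobs of the generator; defaults are the study conditions."""

    n_patients: int = 110
    seed: int = 0
    mean_teeth: float = 23.2

    # patient-level marginals
    p_female: float = 0.618
    p_diabetes: float = 0.082
    p_smoking: tuple[float, float, float] = (0.455, 0.245, 0.300)  # never/former/active
    age_mean: float = 46.7
    age_sd: float = 10.26
    age_range: tuple[float, float] = (18.0, 90.0)
    pcr_mean: float = 31.3
    pcr_sd: float = 17.39
    p_pcr_missing: float = 7 / 110

    # tooth-level marginals (Table-2 totals)
    p_maxilla: float = 1215 / 2556
    p_tooth_type: tuple[float, float, float] = (1207 / 2556, 733 / 2556, 616 / 2556)
    #: per tooth type: probabilities of (single_rooted, multi_no_fi, multi_fi)
    furcation_given_type: Mapping[str, tuple[float, float, float]] = field(
        default_factory=lambda: {
            "anterior": (1.0, 0.0, 0.0),
            "premolar": (0.783, 0.096, 0.121),
            "molar": (0.0, 0.442, 0.558),
        }
    )
    p_bone_loss_raw: tuple[float, ...] = (700 / 2528, 1078 / 2528, 531 / 2528, 160 / 2528, 59 / 2528)
    p_infrabony: tuple[float, float, float] = (2260 / 2528, 266 / 2528, 2 / 2528)
    p_abutment: tuple[float, float, float] = (2243 / 2542, 232 / 2542, 67 / 2542)

    # missingness (complete-case count 2528 of 2556 implies furcation/abutment
    # missing sets are nested within the bone-loss missing set)
    p_bone_loss_missing: float = 28 / 2556
    p_furc_missing_given_bl_missing: float = 0.5
    p_abut_missing_given_bl_missing: float = 0.5

    # outcome mechanism
    group_rates: Mapping[int, float] = field(default_factory=default_group_rates)
    sigma_b: float = 0.5
    null_rate: float | None = None
    #: optional {variable: {level: logit offset}} injected additively
    extra_effects: Mapping[str, Mapping[str, float]] = field(default_factory=dict)

    def validate(self) -> None:
        def simplex(p, name):
            p = np.asarray(p, dtype=float)
            if (p < 0).any() or (p > 1).any() or abs(p.sum() - 1.0) > 1e-8:
                raise ValueError(f"{name} must be probabilities summing to 1, got {p}")

        simplex(self.p_smoking, "p_smoking")
        simplex(self.p_tooth_type, "p_tooth_type")
        simplex(self.p_bone_loss_raw, "p_bone_loss_raw")
        simplex(self.p_infrabony, "p_infrabony")
        simplex(self.p_abutment, "p_abutment")
        for t, p in self.furcation_given_type.items():
            simplex(p, f"furcation_given_type[{t}]")
        fa = self.furcation_given_type.get("anterior", (1.0, 0.0, 0.0))
        if fa[1] > 0 or fa[2] > 0:
            raise ValueError(
                "infeasible marginals: anterior teeth are single-rooted; "
                "furcation involvement probability must be 0 for them"
            )
        fm = self.furcation_given_type.get("molar", (0.0, 0.5, 0.5))
        if fm[0] > 0:
            raise ValueError("infeasible marginals: molars are multi-rooted")
        if self.sigma_b < 0:
            raise ValueError("sigma_b must be nonnegative")
        if not 0 < self.mean_teeth <= 28:
            raise ValueError("mean_teeth must lie in (0, 28]")
        for g, r in self.group_rates.items():
            if not 0 < r < 1:
                raise ValueError(f"group {g} rate must lie strictly in (0, 1)")
        # presence probabilities must be valid
        for q in self._presence_probs().values():
            if not 0 < q <= 1:
                raise ValueError(
                    "infeasible dentition: implied per-position presence probability "
                    f"{q:.3f} outside (0, 1]; lower mean_teeth or rebalance marginals"
                )

    def _presence_probs(self) -> dict[tuple[str, str], float]:
        """q[type, jaw]: presence probability of one FDI position of that kind."""
        slots = {"anterior": 12, "premolar": 8, "molar": 8}
        p_jaw = {"maxilla": self.p_maxilla, "mandible": 1.0 - self.p_maxilla}
        p_type = dict(zip(("anterior", "premolar", "molar"), self.p_tooth_type))
        out = {}
        for t in slots:
            for j in p_jaw:
                # half of each type's slots lie in each jaw
                out[(t, j)] = p_type[t] * self.mean_teeth * 2.0 * p_jaw[j] / slots[t]
        return out

    def to_flat_dict(self) -> dict:
        d = asdict(self)
        d["furcation_given_type"] = {k: list(v) for k, v in self.furcation_given_type.items()}
        d["group_rates"] = {str(k): v for k, v in self.group_rates.items()}
        d["extra_effects"] = {k: dict(v) for k, v in self.extra_effects.items()}
        return d


def _logistic_normal_mean(eta: float, sigma: float, x: np.ndarray, w: np.ndarray) -> float:
    """E[invlogit(eta + b)], b ~ N(0, sigma^2), by Gauss-Hermite quadrature."""
    if sigma == 0:
        return float(expit(eta))
    return float((w * expit(eta + np.sqrt(2.0) * sigma * x)).sum() / np.sqrt(np.pi))


def calibrate_offsets(
    group_rates: Mapping[int, float], sigma_b: float, tol: float = 1e-10
) -> dict[int, float]:
    """Logit-scale group intercepts whose marginal rates hit the targets.

    Solves :math:`\\int \\mathrm{logit}^{-1}(\\eta_g + b)\\,\\varphi(b; 0,
    \\sigma_b^2)\\,db = r_g` for each group by quadrature plus root finding.
    For ``sigma_b = 0`` this reduces to ``logit(r_g)`` exactly.
    """
    if sigma_b < 0:
        raise ValueError("sigma_b must be nonnegative")
    out: dict[int, float] = {}
    x, w = hermgauss(61)
    for g, rate in group_rates.items():
        if not 0 < rate < 1:
            raise ValueError(f"group {g}: rate must lie strictly in (0, 1), got {rate}")
        if sigma_b == 0:
            out[g] = float(logit(rate))
            continue
        f = lambda eta: _logistic_normal_mean(eta, sigma_b, x, w) - rate
        out[g] = float(brentq(f, -20.0, 20.0, xtol=tol))
    return out


_SLOT_TABLE = [
    (10 * q + p, ("maxilla" if q in (1, 2) else "mandible"), fdi_tooth_type(10 * q + p))
    for q in (1, 2, 3, 4)
    for p in range(1, 8)
]

_BL_RAW = ("<=20", "21-40", "41-60", "61-80", ">80")
_INFRA = ("shallow", "moderate", "deep")
_ABUT = ("none", "fixed", "removable")
_SMOKE = ("never", "former", "active")


def _sample_levels(rng, n: int, probs) -> np.ndarray:
    """Vectorised categorical sampling; returns integer codes."""
    cum = np.cumsum(np.asarray(probs, dtype=float))
    cum[-1] = 1.0
    return np.searchsorted(cum, rng.random(n), side="right")


def _assign_groups_vec(bl_code, fi, abut_any, age_gt61, diab) -> np.ndarray:
    """Vectorised published-tree routing (bl_code 0..3 over the merged scale)."""
    g = np.ones(bl_code.size, dtype=int)
    no8 = bl_code < 3
    g[~no8] = 8
    g[no8 & fi & (bl_code == 2)] = 7
    g[no8 & fi & (bl_code < 2)] = 6
    g[no8 & ~fi & abut_any & age_gt61] = 5
    g[no8 & ~fi & abut_any & ~age_gt61] = 4
    g[no8 & ~fi & ~abut_any & (bl_code == 2)] = 3
    g[no8 & ~fi & ~abut_any & (bl_code < 2) & diab] = 2
    return g


def generate(config: SimConfig | None = None, seed: int | None = None) -> Cohort:
    """Draw one cohort.  Reproducible: same config and seed, same cohort."""
    config = config or SimConfig()
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)

    rates = (
        {g: config.null_rate for g in range(1, 9)}
        if config.null_rate is not None
        else dict(config.group_rates)
    )
    eta = calibrate_offsets(rates, config.sigma_b)
    eta_arr = np.array([eta[g] for g in range(1, 9)])
    qpres = config._presence_probs()

    nP = config.n_patients
    lo, hi = config.age_range
    age = rng.normal(config.age_mean, config.age_sd, size=nP)
    bad = (age < lo) | (age > hi)
    while bad.any():  # truncated normal via resampling; truncation mass is tiny
        age[bad] = rng.normal(config.age_mean, config.age_sd, size=int(bad.sum()))
        bad = (age < lo) | (age > hi)
    gender = np.where(rng.random(nP) < config.p_female, "female", "male")
    smoking = np.array(_SMOKE)[_sample_levels(rng, nP, config.p_smoking)]
    diabetes = np.where(rng.random(nP) < config.p_diabetes, "yes", "no")
    pcr = np.clip(rng.normal(config.pcr_mean, config.pcr_sd, size=nP), 0.0, 100.0)
    pcr[rng.random(nP) < config.p_pcr_missing] = np.nan
    b = rng.normal(0.0, config.sigma_b, size=nP) if config.sigma_b > 0 else np.zeros(nP)
    pids = np.array([f"P{i:04d}" for i in range(nP)])

    patients = pd.DataFrame(
        {"patient_id": pids, "age": age, "gender": gender, "smoking": smoking,
         "diabetes": diabetes, "pcr": pcr}
    )

    # dentition: independent presence per FDI position
    slot_q = np.array([qpres[(t, j)] for _, j, t in _SLOT_TABLE])
    present = rng.random((nP, len(_SLOT_TABLE))) < slot_q[None, :]
    empty = ~present.any(axis=1)
    while empty.any():  # an edentulous draw is astronomically rare; redraw
        present[empty] = rng.random((int(empty.sum()), len(_SLOT_TABLE))) < slot_q[None, :]
        empty = ~present.any(axis=1)
    pat_idx, slot_idx = np.nonzero(present)
    n = pat_idx.size

    slot_ids = np.array([s[0] for s in _SLOT_TABLE])
    slot_jaw = np.array([s[1] for s in _SLOT_TABLE])
    slot_type = np.array([s[2] for s in _SLOT_TABLE])
    tooth_id = slot_ids[slot_idx]
    jaw = slot_jaw[slot_idx]
    ttype = slot_type[slot_idx]

    # furcation conditional on tooth type
    furc_code = np.zeros(n, dtype=int)
    for t in ("anterior", "premolar", "molar"):
        mask = ttype == t
        furc_code[mask] = _sample_levels(rng, int(mask.sum()), config.furcation_given_type[t])
    furc = np.array(("single_rooted", "multi_no_fi", "multi_fi"))[furc_code]

    bl_raw_code = _sample_levels(rng, n, config.p_bone_loss_raw)
    bl_raw = np.array(_BL_RAW)[bl_raw_code]
    bl_cat_code = np.minimum(bl_raw_code, 3)  # 61-80 and >80 merge to >60
    infra = np.array(_INFRA)[_sample_levels(rng, n, config.p_infrabony)]
    abut_code = _sample_levels(rng, n, config.p_abutment)
    abut = np.array(_ABUT)[abut_code]

    group = _assign_groups_vec(
        bl_cat_code,
        furc_code == 2,
        abut_code > 0,
        age[pat_idx] > 61.0,
        diabetes[pat_idx] == "yes",
    )
    lp = eta_arr[group - 1] + b[pat_idx]
    if config.extra_effects:
        bl_cat = np.array(("<=20", "21-40", "41-60", ">60"))[bl_cat_code]
        level_arrays = {
            "jaw": jaw, "tooth_type": ttype, "furcation_class": furc,
            "bone_loss_raw": bl_raw, "bone_loss_cat": bl_cat, "infrabony": infra,
            "abutment": abut, "gender": gender[pat_idx],
            "smoking": smoking[pat_idx], "diabetes": diabetes[pat_idx],
        }
        for var, effects in config.extra_effects.items():
            if var not in level_arrays:
                raise ValueError(f"extra_effects: unknown variable {var!r}")
            arr = level_arrays[var]
            for level, delta in effects.items():
                lp = lp + np.where(arr == level, float(delta), 0.0)
    lost = (rng.random(n) < expit(lp)).astype(int)

    teeth_df = pd.DataFrame(
        {"patient_id": pids[pat_idx], "tooth_id": tooth_id, "jaw": jaw,
         "tooth_type": ttype, "furcation_class": furc, "bone_loss_raw": bl_raw,
         "infrabony": infra, "abutment": abut, "lost_by_T2": lost, "_group": group}
    )
    # nested missingness: furcation/abutment missing only where bone loss is missing
    n = len(teeth_df)
    bl_missing = rng.random(n) < config.p_bone_loss_missing
    furc_missing = bl_missing & (rng.random(n) < config.p_furc_missing_given_bl_missing)
    abut_missing = bl_missing & (rng.random(n) < config.p_abut_missing_given_bl_missing)
    # molars cannot be marked single-rooted, so masking furcation keeps validity
    teeth_df.loc[bl_missing, "bone_loss_raw"] = np.nan
    teeth_df.loc[furc_missing, "furcation_class"] = np.nan
    teeth_df.loc[abut_missing, "abutment"] = np.nan

    groups = teeth_df.pop("_group")
    cohort = build_cohort(
        patients,
        teeth_df,
        provenance={
            "source": "periotree.simulate.generate",
            "seed": int(config.seed if seed is None else seed),
            "config": config.to_flat_dict(),
            "filters": [],
        },
    )
    cohort.teeth["true_group"] = groups.to_numpy()
    return cohort
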