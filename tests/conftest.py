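"""Shared fixtures: tiny hand-written cohorts and count-based builders."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from periotree.cohort import Cohort, build_cohort
from periotree.simulate import SimConfig, generate

TOOTH_DEFAULTS = dict(
    furcation_class="single_rooted",
    bone_loss_raw="21-40",
    infrabony="shallow",
    abutment="none",
)


def make_tooth(pid, tooth_id, lost=0, **kw):
    from periotree.cohort import fdi_tooth_type

    row = dict(
        patient_id=pid,
        tooth_id=tooth_id,
        jaw="maxilla" if tooth_id < 30 else "mandible",
        tooth_type=kw.get("tooth_type", fdi_tooth_type(tooth_id) if tooth_id % 10 != 8 else "molar"),
        lost_by_T2=lost,
        **TOOTH_DEFAULTS,
    )
    row.update(kw)
    return row


def make_patient(pid, age=45.0, gender="female", smoking="never", diabetes="no", pcr=30.0):
    return dict(patient_id=pid, age=age, gender=gender, smoking=smoking, diabetes=diabetes, pcr=pcr)


@pytest.fixture
def tiny_cohort() -> Cohort:
    """2 patients, 4 teeth, fully observed."""
    patients = pd.DataFrame([make_patient("A"), make_patient("B", age=66.0, diabetes="yes")])
    teeth = pd.DataFrame(
        [
            make_tooth("A", 11),
            make_tooth("A", 16, lost=1, furcation_class="multi_fi", bone_loss_raw=">80"),
            make_tooth("B", 31),
            make_tooth("B", 46, furcation_class="multi_no_fi"),
        ]
    )
    return build_cohort(patients, teeth)


def cohort_from_jaw_counts(
    maxilla_total=1215, maxilla_lost=96, mandible_total=1341, mandible_lost=70, n_patients=110
) -> Cohort:
    """Deterministic cohort reproducing a jaw x outcome contingency table.

    Teeth are dealt round-robin over patients and FDI slots; all other
    covariates are constant, so only the jaw/outcome margins are meaningful.
    """
    from periotree.cohort import fdi_tooth_type

    max_slots = [10 * q + p for q in (1, 2) for p in range(1, 8)]
    man_slots = [10 * q + p for q in (3, 4) for p in range(1, 8)]
    teeth = []
    patients = [make_patient(f"P{i:03d}") for i in range(n_patients)]

    def deal(total, lost, slots, jaw):
        # teeth for this jaw, dealt one slot per patient pass
        k = 0
        for s_i, slot in enumerate(slots):
            for p_i in range(n_patients):
                if k >= total:
                    return
                ttype = fdi_tooth_type(slot)
                teeth.append(
                    make_tooth(
                        f"P{p_i:03d}",
                        slot,
                        lost=1 if k < lost else 0,
                        jaw=jaw,
                        tooth_type=ttype,
                        furcation_class="single_rooted" if ttype != "molar" else "multi_no_fi",
                    )
                )
                k += 1

    deal(maxilla_total, maxilla_lost, max_slots, "maxilla")
    deal(mandible_total, mandible_lost, man_slots, "mandible")
    return build_cohort(pd.DataFrame(patients), pd.DataFrame(teeth))


@pytest.fixture(scope="session")
def default_cohort() -> Cohort:
    """One medium synthetic cohort at the study conditions (shared, read-only)."""
    return generate(SimConfig(n_patients=110, seed=20))


@pytest.fixture(scope="session")
def null_cohort() -> Cohort:
    """Constant loss probability 0.1, no covariate effects, no clustering."""
    return generate(
        SimConfig(n_patients=500, seed=21, null_rate=0.1, sigma_b=0.0, p_bone_loss_missing=0.0)
    )
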