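"""The published 8-group risk calculator for 10-year tooth loss.

This module encodes, as a fixed and citable classifier, the final prognostic
tree reported for periodontitis patients followed for ten years of supportive
periodontal therapy.  Five covariates route a tooth to one of eight terminal
risk groups, each carrying the published empirical 10-year loss rate:

========  ===========================================================  =============
group id  path                                                          rate (lost/n)
========  ===========================================================  =============
8         bone loss > 60%                                               22.3 (49/220)
7         bone loss 41-60% & multi-rooted with FI                       16.8 (23/137)
6         bone loss <= 40% & multi-rooted with FI                        6.3 (14/221)
5         bone loss <= 60% & no FI & abutment & age > 61                50.0 (11/22)
4         bone loss <= 60% & no FI & abutment & age <= 61                5.0 (9/179)
3         bone loss 41-60% & no FI & no abutment                         5.7 (21/366)
2         bone loss <= 40% & no FI & no abutment & diabetic              5.7 (6/105)
1         bone loss <= 40% & no FI & no abutment & non-diabetic          2.2 (28/1279)
========  ===========================================================  =============

"no FI" means single-rooted or multi-rooted without furcation involvement.
Group numbers do not order risk (group 5 has the highest printed rate).

Note a bookkeeping quirk of the published table that this module reproduces
verbatim rather than resolves: the eight group totals sum to 2529 teeth and
161 lost, while the accompanying text reports 2528 complete-case teeth and
166 lost overall.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd
from scipy.special import logit

from .cohort import (
    ABUTMENT_LEVELS,
    BONE_LOSS_CAT_LEVELS,
    FURCATION_LEVELS,
    YESNO_LEVELS,
)

__all__ = [
    "RiskGroup",
    "PUBLISHED_GROUPS",
    "AGE_CUT_YEARS",
    "assign_group",
    "assign_groups_frame",
    "group_rate_from_counts",
    "published_tree",
]

#: The data-driven age dichotomy of the published tree (<= 61 vs > 61 years).
AGE_CUT_YEARS = 61.0


@dataclass(frozen=True)
class RiskGroup:
    """One published terminal group: printed rate, counts, and routing path."""

    group_id: int
    rate: float  # printed percent, 1 decimal
    lost: int
    total: int
    path: tuple[str, ...]

    @property
    def proportion(self) -> float:
        """Exact loss proportion lost/total (not the rounded printed rate)."""
        return self.lost / self.total


def group_rate_from_counts(lost: int, total: int) -> float:
    """Percent loss rate at one decimal, rounded half-up, from raw counts."""
    if total <= 0:
        raise ValueError("total must be a positive integer")
    if not 0 <= lost <= total:
        raise ValueError("lost must lie in [0, total]")
    pct = Decimal(100 * lost) / Decimal(total)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


_RAW_GROUPS = {
    1: (28, 1279, ("BL <= 40%", "no FI", "no abutment", "non-diabetic")),
    2: (6, 105, ("BL <= 40%", "no FI", "no abutment", "diabetic")),
    3: (21, 366, ("BL 41-60%", "no FI", "no abutment")),
    4: (9, 179, ("BL <= 60%", "no FI", "abutment (fixed or removable)", "age <= 61")),
    5: (11, 22, ("BL <= 60%", "no FI", "abutment (fixed or removable)", "age > 61")),
    6: (14, 221, ("BL <= 40%", "multi-rooted with FI")),
    7: (23, 137, ("BL 41-60%", "multi-rooted with FI")),
    8: (49, 220, ("BL > 60%",)),
}

PUBLISHED_GROUPS: dict[int, RiskGroup] = {
    g: RiskGroup(g, group_rate_from_counts(lost, total), lost, total, path)
    for g, (lost, total, path) in _RAW_GROUPS.items()
}


def _check_level(value: str, levels: tuple[str, ...], name: str) -> None:
    if value not in levels:
        raise ValueError(f"{name} must be one of {levels}, got {value!r}")


def assign_group(
    bone_loss_cat: str,
    furcation_class: str,
    abutment: str,
    age_years: float,
    diabetes: str,
) -> RiskGroup:
    """Route one tooth through the published tree to its risk group.

    Routing, in the order the splits are reported:

    1. bone loss > 60%                          -> group 8
    2. multi-rooted with furcation involvement:
       bone loss 41-60% -> group 7, else        -> group 6
    3. abutment tooth (fixed or removable):
       age > 61 -> group 5, else                -> group 4
    4. no abutment, bone loss 41-60%            -> group 3
    5. no abutment, bone loss <= 40%:
       diabetic -> group 2, else                -> group 1

    Age exactly 61 follows the low-risk branch (the split reads "<= 61").
    """
    _check_level(bone_loss_cat, BONE_LOSS_CAT_LEVELS, "bone_loss_cat")
    _check_level(furcation_class, FURCATION_LEVELS, "furcation_class")
    _check_level(abutment, ABUTMENT_LEVELS, "abutment")
    _check_level(diabetes, YESNO_LEVELS, "diabetes")
    if not age_years > 0:
        raise ValueError("age_years must be positive")

    if bone_loss_cat == ">60":
        return PUBLISHED_GROUPS[8]
    if furcation_class == "multi_fi":
        return PUBLISHED_GROUPS[7 if bone_loss_cat == "41-60" else 6]
    if abutment in ("fixed", "removable"):
        return PUBLISHED_GROUPS[5 if age_years > AGE_CUT_YEARS else 4]
    if bone_loss_cat == "41-60":
        return PUBLISHED_GROUPS[3]
    return PUBLISHED_GROUPS[2 if diabetes == "yes" else 1]


def assign_groups_frame(frame: pd.DataFrame) -> pd.DataFrame:
    """Vectorised convenience wrapper over :func:`assign_group`.

    ``frame`` must carry columns ``bone_loss_cat``, ``furcation_class``,
    ``abutment``, ``age``, ``diabetes``.  Returns a copy with ``group_id``,
    ``group_rate_pct`` and ``group_path`` appended.
    """
    out = frame.copy()
    groups = [
        assign_group(
            str(r.bone_loss_cat), str(r.furcation_class), str(r.abutment), float(r.age), str(r.diabetes)
        )
        for r in frame.itertuples()
    ]
    out["group_id"] = [g.group_id for g in groups]
    out["group_rate_pct"] = [g.rate for g in groups]
    out["group_path"] = [" & ".join(g.path) for g in groups]
    return out


def published_tree():
    """The published tree as a :class:`periotree.tree.TreeNode` structure.

    Leaf intercepts are the logits of the printed empirical proportions, so
    routing a tooth through this structure and through :func:`assign_group`
    must agree everywhere.  Returns ``(root, leaf_groups)`` where
    ``leaf_groups`` maps leaf ``node_id`` to the published group id.
    """
    from .tree import SplitRule, TreeNode

    def leaf(nid: int, gid: int) -> TreeNode:
        g = PUBLISHED_GROUPS[gid]
        return TreeNode(
            node_id=nid,
            beta=float(logit(g.proportion)),
            n_teeth=g.total,
            n_lost=g.lost,
        )

    def ordinal_bl(left_levels: tuple[str, ...]) -> SplitRule:
        return SplitRule(
            variable="bone_loss_cat", kind="ordinal", left_levels=left_levels
        )

    def inner(nid: int, rule: SplitRule, left: TreeNode, right: TreeNode) -> TreeNode:
        return TreeNode(
            node_id=nid,
            split=rule,
            children=(left, right),
            n_teeth=left.n_teeth + right.n_teeth,
            n_lost=left.n_lost + right.n_lost,
        )

    # group numbering is fixed by the publication; node ids are structural
    n8, n7, n6 = leaf(2, 8), leaf(5, 7), leaf(4, 6)
    n5, n4, n3, n2, n1 = leaf(9, 5), leaf(8, 4), leaf(11, 3), leaf(14, 2), leaf(13, 1)
    fi_node = inner(3, ordinal_bl(("<=20", "21-40")), n6, n7)
    abut_node = inner(
        7, SplitRule(variable="age", kind="numeric", threshold=AGE_CUT_YEARS), n4, n5
    )
    diab_node = inner(
        12, SplitRule(variable="diabetes", kind="nominal", left_levels=("no",)), n1, n2
    )
    no_abut_node = inner(10, ordinal_bl(("<=20", "21-40")), diab_node, n3)
    nofi_node = inner(
        6,
        SplitRule(variable="abutment", kind="nominal", left_levels=("none",)),
        no_abut_node,
        abut_node,
    )
    le60_node = inner(
        1,
        SplitRule(
            variable="furcation_class",
            kind="nominal",
            left_levels=("single_rooted", "multi_no_fi"),
        ),
        nofi_node,
        fi_node,
    )
    root = inner(0, ordinal_bl(("<=20", "21-40", "41-60")), le60_node, n8)

    leaf_groups = {}
    for node, gid in ((n8, 8), (n7, 7), (n6, 6), (n5, 5), (n4, 4), (n3, 3), (n2, 2), (n1, 1)):
        leaf_groups[node.node_id] = gid
    return root, leaf_groups
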