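"""Logistic model-tree with a patient random intercept (GLMM tree).

The learner alternates two steps until the partition stabilises:

(a) **Tree growth.**  With each patient's predicted random effect held fixed
    as an offset, a binary tree is grown over the covariates.  At every node
    a score-type *instability test* is run for each candidate variable: the
    association between the working residuals :math:`y - \\hat p` and the
    candidate.  For nominal variables this is a chi-squared statistic on
    per-level residual sums (df = levels - 1); for ordinal and numeric
    variables a maximum standardised cumulative-sum statistic over cutpoints,
    with a Bonferroni correction over cutpoints.  P-values are Bonferroni
    adjusted across candidate variables; the node splits on the smallest
    adjusted p-value below ``alpha``, with the cutpoint chosen by exhaustive
    binomial-deviance search (nominal levels are first ordered by observed
    event rate, the standard exhaustive-equivalent reduction for binary
    outcomes).  ``min_node_size`` and ``max_depth`` bound the search.

(b) **Mixed-model estimation.**  With the tree fixed, a logistic model with
    one intercept per leaf and a Normal patient random intercept is fitted by
    adaptive Gauss-Hermite quadrature (:mod:`periotree.mixedlm`), yielding
    leaf log-odds, the random-intercept SD, and per-patient posterior modes
    that become the offsets of the next growth pass.

Leaves carry intercept-only models: the tree's terminal groups are risk
strata, each with a single (random-effect-adjusted) event probability, which
is what a tooth-level prognosis needs.

The estimator follows scikit-learn conventions (``fit``/``predict_proba``,
``get_params``, fitted attributes with trailing underscores) and accepts a
pandas DataFrame of covariates plus a ``groups`` vector of patient ids.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, logit
from sklearn.base import BaseEstimator, ClassifierMixin

from .mixedlm import (
    MixedFitResult,
    fit_random_intercept,
    marginal_leaf_probability,
)

__all__ = [
    "SplitRule",
    "TreeNode",
    "RoutingError",
    "GLMMTreeClassifier",
    "test_instability",
    "choose_split",
    "node_intercept",
    "model_to_json",
    "model_from_json",
]


class RoutingError(ValueError):
    """A row cannot be routed to a leaf (unknown level / missing value)."""


@dataclass
class SplitRule:
    """A binary split.  Numeric: ``x <= threshold`` goes left.  Categorical
    (ordinal or nominal): levels in ``left_levels`` go left."""

    variable: str
    kind: str  # "numeric" | "ordinal" | "nominal"
    threshold: float | None = None
    left_levels: tuple[str, ...] | None = None

    def goes_left(self, value) -> bool:
        if self.kind == "numeric":
            if value is None or (isinstance(value, float) and np.isnan(value)):
                raise RoutingError(f"missing value for numeric split on {self.variable!r}")
            return float(value) <= self.threshold
        if value is None or (isinstance(value, float) and np.isnan(value)):
            raise RoutingError(f"missing value for split on {self.variable!r}")
        return str(value) in self.left_levels

    def describe(self) -> str:
        if self.kind == "numeric":
            return f"{self.variable} <= {self.threshold:g}"
        return f"{self.variable} in {{{', '.join(self.left_levels)}}}"


@dataclass
class TreeNode:
    """Either an internal node (``split`` + two ``children``) or a leaf
    carrying the leaf log-odds ``beta`` and its tooth counts."""

    node_id: int
    split: SplitRule | None = None
    children: tuple["TreeNode", "TreeNode"] | None = None
    beta: float = 0.0
    n_teeth: int = 0
    n_lost: int = 0
    depth: int = 0
    p_value: float | None = None  # adjusted instability p-value of the split

    @property
    def is_leaf(self) -> bool:
        return self.split is None

    @property
    def probability(self) -> float:
        """Conditional (random-effect-at-zero) leaf probability."""
        return float(expit(self.beta))

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        return self.children[0].leaves() + self.children[1].leaves()

    def route(self, row: dict) -> "TreeNode":
        node = self
        while not node.is_leaf:
            var = node.split.variable
            if var not in row:
                raise RoutingError(f"covariate {var!r} required for routing")
            node = node.children[0 if node.split.goes_left(row[var]) else 1]
        return node


# ---------------------------------------------------------------------------
# node-level statistics


def node_intercept(y: np.ndarray, offset: np.ndarray, n_iter: int = 30) -> float:
    """ML intercept of a logistic model with a fixed offset (Newton).

    At the optimum the working residuals sum to zero.  Pure nodes return a
    continuity-corrected finite logit.
    """
    n = y.size
    s = float(y.sum())
    if s == 0 or s == n:
        return float(logit((s + 0.5) / (n + 1.0)) - float(np.mean(offset)))
    if np.ptp(offset) < 1e-12:
        return float(logit(s / n) - offset[0])
    beta = float(logit(s / n) - np.mean(offset))
    for _ in range(n_iter):
        mu = expit(beta + offset)
        g = s - float(mu.sum())
        h = float((mu * (1.0 - mu)).sum())
        step = g / h
        beta += step
        if abs(step) < 1e-12:
            break
    return beta


def _working_stats(y, offset, beta):
    p = expit(beta + offset)
    return y - p, p * (1.0 - p)


def test_instability(
    y: np.ndarray,
    p_hat: np.ndarray,
    x: np.ndarray,
    kind: str,
    levels: Sequence | None = None,
) -> float:
    """Score-type instability p-value for one candidate variable at a node.

    ``p_hat`` are the node's fitted probabilities (intercept + offsets), so
    the working residuals ``y - p_hat`` sum to (numerically) zero.

    * nominal: chi-squared on per-level residual sums with the efficient
      score covariance ``diag(W_l) - w w'/W`` (intercept profiled out),
      df = levels - 1;
    * ordinal / numeric: max over order-respecting cutpoints of the
      standardised cumulative residual sum, Bonferroni-corrected over the
      number of cutpoints.

    Variables with a single observed level return 1 by convention.
    """
    r = y - p_hat
    w = p_hat * (1.0 - p_hat)
    W = float(w.sum())
    if W <= 0:
        return 1.0

    if kind == "nominal":
        vals = pd.Categorical(x).codes if levels is None else x
        codes = np.asarray(vals, dtype=int)
        L = int(codes.max()) + 1
        S = np.bincount(codes, weights=r, minlength=L)
        Wl = np.bincount(codes, weights=w, minlength=L)
        present = Wl > 0
        S, Wl = S[present], Wl[present]
        L = S.size
        if L < 2:
            return 1.0
        V = np.diag(Wl[:-1]) - np.outer(Wl[:-1], Wl[:-1]) / W
        try:
            stat = float(S[:-1] @ np.linalg.solve(V, S[:-1]))
        except np.linalg.LinAlgError:
            return 1.0
        return float(stats.chi2.sf(stat, L - 1))

    # ordinal / numeric: cumulative sums in variable order
    if kind == "ordinal":
        codes = np.asarray(x, dtype=int)
        order_vals = np.unique(codes)
    else:
        xv = np.asarray(x, dtype=float)
        order_vals = np.unique(xv)
        codes = xv
    if order_vals.size < 2:
        return 1.0
    z_max = 0.0
    cum_s = 0.0
    cum_w = 0.0
    n_cut = order_vals.size - 1
    for v in order_vals[:-1]:
        mask = codes == v
        cum_s += float(r[mask].sum())
        cum_w += float(w[mask].sum())
        var = cum_w * (W - cum_w) / W
        if var <= 0:
            continue
        z = abs(cum_s) / np.sqrt(var)
        z_max = max(z_max, z)
    if z_max == 0.0:
        return 1.0
    p = 2.0 * stats.norm.sf(z_max)
    return float(min(1.0, n_cut * p))


def _binomial_deviance(y: np.ndarray, offset: np.ndarray, beta: float) -> float:
    eta = beta + offset
    return float(-2.0 * np.sum(y * eta - np.logaddexp(0.0, eta)))


def choose_split(
    y: np.ndarray,
    offset: np.ndarray,
    x: np.ndarray,
    kind: str,
    min_node_size: int,
    levels: Sequence[str] | None = None,
    max_numeric_splits: int = 64,
) -> tuple[SplitRule, np.ndarray] | None:
    """Best admissible binary partition by binomial-deviance reduction.

    Returns ``(rule, left_mask)`` or ``None`` when no partition leaves
    ``min_node_size`` observations on both sides.  Ties are broken toward
    the more balanced split, then lexicographically (lower threshold /
    earlier level order).

    Ordinal variables admit order-respecting thresholds only.  Nominal
    levels are ordered by observed event rate and thresholds are taken over
    that order - for a Bernoulli outcome this ordered search attains the
    exhaustive-subset optimum.  Numeric variables with many distinct values
    are searched over an evenly spaced quantile grid of
    ``max_numeric_splits`` candidate thresholds.
    """
    n = y.size
    parent_dev = _binomial_deviance(y, offset, node_intercept(y, offset))

    candidates: list[tuple[float, SplitRule, np.ndarray]] = []

    def try_mask(left_mask: np.ndarray, rule: SplitRule, order_key: float):
        n_left = int(left_mask.sum())
        if n_left < min_node_size or n - n_left < min_node_size:
            return
        yl, ol = y[left_mask], offset[left_mask]
        yr, orr = y[~left_mask], offset[~left_mask]
        dev = _binomial_deviance(yl, ol, node_intercept(yl, ol)) + _binomial_deviance(
            yr, orr, node_intercept(yr, orr)
        )
        reduction = parent_dev - dev
        balance = -abs(n_left - (n - n_left))
        candidates.append((reduction, rule, left_mask, balance, -order_key))

    if kind == "numeric":
        xv = np.asarray(x, dtype=float)
        uniq = np.unique(xv)
        midpoints = 0.5 * (uniq[:-1] + uniq[1:])
        if midpoints.size > max_numeric_splits:
            # evenly spaced in rank space over distinct values, plus the
            # midpoints of the widest gaps (natural cut candidates)
            ranks = np.unique(
                np.round(np.linspace(0, midpoints.size - 1, max_numeric_splits)).astype(int)
            )
            gaps = np.argsort(np.diff(uniq))[-8:]
            thresholds = np.unique(midpoints[np.union1d(ranks, gaps)])
        else:
            thresholds = midpoints
        for i, t in enumerate(thresholds):
            try_mask(xv <= t, SplitRule(variable="", kind="numeric", threshold=float(t)), float(i))
    elif kind == "ordinal":
        codes = np.asarray(x, dtype=int)
        present = np.unique(codes)
        for i in range(present.size - 1):
            left_codes = present[: i + 1]
            mask = np.isin(codes, left_codes)
            rule = SplitRule(
                variable="",
                kind="ordinal",
                left_levels=tuple(levels[c] for c in left_codes),
            )
            try_mask(mask, rule, float(i))
    else:  # nominal: order levels by observed event rate, then threshold
        codes = np.asarray(x, dtype=int)
        present = np.unique(codes)
        if present.size < 2:
            return None
        rates = np.array([y[codes == c].mean() for c in present])
        order = present[np.lexsort((present, rates))]
        for i in range(order.size - 1):
            left_codes = order[: i + 1]
            mask = np.isin(codes, left_codes)
            rule = SplitRule(
                variable="",
                kind="nominal",
                left_levels=tuple(sorted((levels[c] for c in left_codes), key=levels.index)),
            )
            try_mask(mask, rule, float(i))

    if not candidates:
        return None
    best = max(candidates, key=lambda c: (round(c[0], 10), c[3], c[4]))
    return best[1], best[2]


# ---------------------------------------------------------------------------
# estimator


class GLMMTreeClassifier(BaseEstimator, ClassifierMixin):
    """Logistic model-tree with a per-patient random intercept.

    Parameters
    ----------
    alpha : float, default 0.05
        Significance level for the node instability tests.
    bonferroni : bool, default True
        Bonferroni-adjust instability p-values across candidate variables
        (those with at least two observed levels in the node).
    min_node_size : int, default 50
        Minimum teeth on each side of any split.
    max_depth : int, default 5
        Maximum split depth (root = 0).
    max_outer_iter : int, default 100
        Cap on grow/estimate alternations.
    ll_tol : float, default 1e-4
        Marginal log-likelihood improvement below which the outer loop stops.
    quadrature_points : int, default 15
        Adaptive Gauss-Hermite nodes for the mixed-model step.
    sigma_fixed : float or None, default None
        Hold the random-intercept SD fixed (0 disables the random effect).
    feature_kinds : dict or None
        Override the inferred kind per column: ``"numeric"``, ``"nominal"``,
        ``"ordinal"`` or ``("ordinal", [levels...])``.  By default numeric
        dtypes are numeric, ordered categoricals ordinal, everything else
        nominal.
    ordinal_as_nominal : bool, default False
        Treat ordinal covariates as unordered when splitting.
    max_numeric_splits : int, default 64
        Quantile-grid size for numeric split search on high-cardinality
        variables.
    predict_mode : {"marginal", "conditional"}, default "marginal"
        Mode used by :meth:`predict_proba`/:meth:`predict`.
    random_state : int, default 0
        Reserved for stochastic tie-breaking; the default tie rules are
        deterministic, so this does not currently influence the fit.

    Attributes
    ----------
    root_ : TreeNode
    sigma_b_hat_ : float
    patient_effects_ : dict
        Patient id -> posterior-mode random effect.
    fit_info_ : dict
        Outer iterations, log-likelihood trace, convergence flag.
    partitioning_variables_ : list of str
    classes_ : ndarray of shape (2,)
    """

    def __init__(
        self,
        alpha: float = 0.05,
        bonferroni: bool = True,
        min_node_size: int = 50,
        max_depth: int = 5,
        max_outer_iter: int = 100,
        ll_tol: float = 1e-4,
        quadrature_points: int = 15,
        sigma_fixed: float | None = None,
        feature_kinds: dict | None = None,
        ordinal_as_nominal: bool = False,
        max_numeric_splits: int = 64,
        predict_mode: str = "marginal",
        random_state: int = 0,
    ):
        self.alpha = alpha
        self.bonferroni = bonferroni
        self.min_node_size = min_node_size
        self.max_depth = max_depth
        self.max_outer_iter = max_outer_iter
        self.ll_tol = ll_tol
        self.quadrature_points = quadrature_points
        self.sigma_fixed = sigma_fixed
        self.feature_kinds = feature_kinds
        self.ordinal_as_nominal = ordinal_as_nominal
        self.max_numeric_splits = max_numeric_splits
        self.predict_mode = predict_mode
        self.random_state = random_state

    # -- encoding -----------------------------------------------------------

    def _resolve_kinds(self, X: pd.DataFrame) -> dict[str, tuple[str, list | None]]:
        kinds: dict[str, tuple[str, list | None]] = {}
        overrides = self.feature_kinds or {}
        for col in X.columns:
            ov = overrides.get(col)
            if ov is not None:
                if isinstance(ov, (tuple, list)) and len(ov) == 2:
                    kinds[col] = (str(ov[0]), list(ov[1]))
                    continue
                if ov == "numeric":
                    kinds[col] = ("numeric", None)
                    continue
                if ov in ("nominal", "ordinal"):
                    cats = pd.Categorical(X[col]).categories.tolist()
                    kinds[col] = (ov, cats)
                    continue
                raise ValueError(f"bad feature_kinds entry for {col!r}: {ov!r}")
            s = X[col]
            if isinstance(s.dtype, pd.CategoricalDtype):
                kind = "ordinal" if s.dtype.ordered else "nominal"
                kinds[col] = (kind, s.dtype.categories.tolist())
            elif pd.api.types.is_numeric_dtype(s):
                kinds[col] = ("numeric", None)
            else:
                kinds[col] = ("nominal", pd.Categorical(s).categories.tolist())
        if self.ordinal_as_nominal:
            kinds = {c: ("nominal" if k == "ordinal" else k, lv) for c, (k, lv) in kinds.items()}
        return kinds

    def _encode(self, X: pd.DataFrame) -> dict[str, np.ndarray]:
        enc = {}
        for col, (kind, lv) in self.kinds_.items():
            if kind == "numeric":
                vals = pd.to_numeric(X[col], errors="coerce").to_numpy(dtype=float)
                if np.isnan(vals).any():
                    raise ValueError(
                        f"partitioning variable {col!r} has missing/non-numeric values; "
                        "apply a complete-case filter first"
                    )
                enc[col] = vals
            else:
                codes = pd.Categorical(X[col], categories=lv).codes
                if (codes < 0).any():
                    idx = int(np.argmax(codes < 0))
                    raise ValueError(
                        f"partitioning variable {col!r} has a missing or unknown level "
                        f"at row {idx}; apply a complete-case filter first"
                    )
                enc[col] = codes.astype(int)
        return enc

    # -- tree growth --------------------------------------------------------

    def _grow(self, enc, y, offset, idx, depth, counter) -> TreeNode:
        node = TreeNode(node_id=counter[0], depth=depth)
        counter[0] += 1
        ysub = y[idx]
        osub = offset[idx]
        node.n_teeth = int(idx.size)
        node.n_lost = int(ysub.sum())
        beta = node_intercept(ysub, osub)
        node.beta = beta

        if (
            depth >= self.max_depth
            or idx.size < 2 * self.min_node_size
            or node.n_lost == 0
            or node.n_lost == node.n_teeth
        ):
            return node

        p_hat = expit(beta + osub)
        tested = []
        for col, (kind, lv) in self.kinds_.items():
            x = enc[col][idx]
            n_lv = np.unique(x).size
            if n_lv < 2:
                continue
            p = test_instability(ysub, p_hat, x, kind, levels=lv)
            tested.append((p, col, kind, lv))
        if not tested:
            return node
        k = len(tested) if self.bonferroni else 1
        tested.sort(key=lambda t: (t[0], t[1]))
        best_p, best_col, best_kind, best_lv = tested[0]
        p_adj = min(1.0, best_p * k)
        if p_adj >= self.alpha:
            return node

        res = choose_split(
            ysub,
            osub,
            enc[best_col][idx],
            best_kind,
            self.min_node_size,
            levels=best_lv,
            max_numeric_splits=self.max_numeric_splits,
        )
        if res is None:
            return node
        rule, left_mask = res
        rule.variable = best_col
        node.split = rule
        node.p_value = float(p_adj)
        left = self._grow(enc, y, offset, idx[left_mask], depth + 1, counter)
        right = self._grow(enc, y, offset, idx[~left_mask], depth + 1, counter)
        node.children = (left, right)
        return node

    def _leaf_index(self, enc, root: TreeNode, n: int) -> tuple[np.ndarray, list[TreeNode]]:
        leaves = root.leaves()
        leaf_pos = {id(lf): i for i, lf in enumerate(leaves)}
        out = np.zeros(n, dtype=int)
        idx_all = np.arange(n)

        def descend(node, idx):
            if node.is_leaf:
                out[idx] = leaf_pos[id(node)]
                return
            rule = node.split
            x = enc[rule.variable][idx]
            if rule.kind == "numeric":
                mask = x <= rule.threshold
            else:
                lv = self.kinds_[rule.variable][1]
                left_codes = [lv.index(l) for l in rule.left_levels]
                mask = np.isin(x, left_codes)
            descend(node.children[0], idx[mask])
            descend(node.children[1], idx[~mask])

        descend(root, idx_all)
        return out, leaves

    # -- fit / predict ------------------------------------------------------

    def fit(self, X: pd.DataFrame, y, groups=None):
        """Fit the model tree.

        ``X`` is a tooth-level DataFrame of partitioning covariates, ``y``
        the 0/1 loss outcome, ``groups`` the per-tooth patient identifier
        (every tooth its own cluster when omitted).
        """
        if not isinstance(X, pd.DataFrame):
            raise TypeError("X must be a pandas DataFrame of named covariates")
        y = np.asarray(y, dtype=float)
        if y.shape[0] != len(X):
            raise ValueError("X and y length mismatch")
        if not np.isin(y, (0.0, 1.0)).all():
            raise ValueError("y must be binary 0/1")
        if groups is None:
            groups = np.arange(len(X))
        groups = np.asarray(groups)
        pat_ids, pat_idx = np.unique(groups, return_inverse=True)
        if pat_ids.size < 2 and self.sigma_fixed is None:
            raise ValueError("at least 2 patients are required to estimate a random intercept")

        self.kinds_ = self._resolve_kinds(X)
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        enc = self._encode(X)
        n = len(X)
        self.classes_ = np.array([0, 1])

        if y.sum() == 0 or y.sum() == n:
            warnings.warn(
                "all outcomes identical; returning a root-only model", UserWarning
            )
            root = TreeNode(node_id=0, n_teeth=n, n_lost=int(y.sum()))
            root.beta = node_intercept(y, np.zeros(n))
            self.root_ = root
            self.sigma_b_hat_ = 0.0
            self.patient_effects_ = {pid: 0.0 for pid in pat_ids}
            self.fit_info_ = {"n_outer_iter": 0, "loglik_trace": [], "converged": True}
            self.partitioning_variables_ = []
            self.n_leaves_ = 1
            return self

        # alternate growth and mixed-model estimation
        offsets_pat = np.zeros(pat_ids.size)
        prev_assign = None
        prev_ll = -np.inf
        ll_trace: list[float] = []
        converged = False
        mfit: MixedFitResult | None = None
        beta_warm = None
        sigma_warm = 0.3
        n_iter = 0
        for n_iter in range(1, self.max_outer_iter + 1):
            offset = offsets_pat[pat_idx]
            counter = [0]
            root = self._grow(enc, y, offset, np.arange(n), 0, counter)
            leaf_idx, leaves = self._leaf_index(enc, root, n)
            mfit = fit_random_intercept(
                y,
                leaf_idx,
                pat_idx,
                n_leaves=len(leaves),
                n_patients=pat_ids.size,
                quadrature_points=self.quadrature_points,
                sigma_fixed=self.sigma_fixed,
                sigma0=sigma_warm,
            )
            for lf, b in zip(leaves, mfit.betas):
                lf.beta = float(b)
            offsets_pat = mfit.blups
            sigma_warm = max(mfit.sigma_b, 0.05)
            ll_trace.append(mfit.loglik)
            same_assign = prev_assign is not None and np.array_equal(prev_assign, leaf_idx)
            if same_assign or abs(mfit.loglik - prev_ll) < self.ll_tol:
                converged = True
                break
            prev_assign = leaf_idx
            prev_ll = mfit.loglik

        self.root_ = root
        self.sigma_b_hat_ = float(mfit.sigma_b)
        self.patient_effects_ = {pid: float(b) for pid, b in zip(pat_ids, mfit.blups)}
        self.fit_info_ = {
            "n_outer_iter": n_iter,
            "loglik_trace": ll_trace,
            "converged": bool(converged),
            "mixed_trace": mfit.trace,
        }
        self.partitioning_variables_ = sorted(
            {nd.split.variable for nd in self._internal_nodes(root)}
        )
        self.n_leaves_ = len(root.leaves())
        return self

    @staticmethod
    def _internal_nodes(root: TreeNode):
        stack = [root]
        while stack:
            nd = stack.pop()
            if not nd.is_leaf:
                yield nd
                stack.extend(nd.children)

    def apply(self, X: pd.DataFrame) -> np.ndarray:
        """Leaf node_id for every row."""
        self._check_fitted()
        records = X.to_dict("records")
        return np.array([self.root_.route(rec).node_id for rec in records])

    def predict_tooth_proba(
        self, X: pd.DataFrame, groups=None, mode: str | None = None
    ) -> np.ndarray:
        """Per-tooth loss probability.

        ``marginal`` integrates over the random-intercept distribution (new
        patients, as in cross-validation); ``conditional`` uses the
        patient's fitted effect when the patient was seen in training, and
        falls back to marginal otherwise.
        """
        self._check_fitted()
        mode = mode or self.predict_mode
        if mode not in ("marginal", "conditional"):
            raise ValueError("mode must be 'marginal' or 'conditional'")
        records = X.to_dict("records")
        betas = np.empty(len(records))
        for i, rec in enumerate(records):
            try:
                betas[i] = self.root_.route(rec).beta
            except RoutingError as err:
                raise RoutingError(f"row {i}: {err}") from err
        if mode == "marginal" or groups is None:
            return np.asarray(marginal_leaf_probability(betas, self.sigma_b_hat_))
        groups = np.asarray(groups)
        out = np.empty(len(records))
        known = self.patient_effects_
        for i, g in enumerate(groups):
            if g in known:
                out[i] = expit(betas[i] + known[g])
            else:
                out[i] = marginal_leaf_probability(float(betas[i]), self.sigma_b_hat_)
        return out

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        p = self.predict_tooth_proba(X, mode=self.predict_mode)
        return np.column_stack([1.0 - p, p])

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)

    def _check_fitted(self):
        if not hasattr(self, "root_"):
            raise AttributeError("this GLMMTreeClassifier instance is not fitted yet")

    # -- serialization ------------------------------------------------------

    def to_json(self) -> str:
        self._check_fitted()
        return model_to_json(self)

    @classmethod
    def from_json(cls, doc: str) -> "GLMMTreeClassifier":
        return model_from_json(doc)


# ---------------------------------------------------------------------------
# JSON round-trip


def _node_to_dict(node: TreeNode) -> dict:
    d = {
        "node_id": node.node_id,
        "n_teeth": node.n_teeth,
        "n_lost": node.n_lost,
        "depth": node.depth,
    }
    if node.is_leaf:
        d["beta"] = node.beta
    else:
        d["split"] = {
            "variable": node.split.variable,
            "kind": node.split.kind,
            "threshold": node.split.threshold,
            "left_levels": list(node.split.left_levels) if node.split.left_levels else None,
        }
        d["p_value"] = node.p_value
        d["children"] = [_node_to_dict(c) for c in node.children]
    return d


def _node_from_dict(d: dict) -> TreeNode:
    node = TreeNode(
        node_id=d["node_id"],
        n_teeth=d["n_teeth"],
        n_lost=d["n_lost"],
        depth=d.get("depth", 0),
    )
    if "split" in d:
        s = d["split"]
        node.split = SplitRule(
            variable=s["variable"],
            kind=s["kind"],
            threshold=s["threshold"],
            left_levels=tuple(s["left_levels"]) if s["left_levels"] else None,
        )
        node.p_value = d.get("p_value")
        node.children = tuple(_node_from_dict(c) for c in d["children"])
    else:
        node.beta = d["beta"]
    return node


def model_to_json(model: GLMMTreeClassifier) -> str:
    """Serialize a fitted model; parsing back reproduces predictions exactly."""
    doc = {
        "format": "periotree-glmm-tree",
        "version": 1,
        "tree": _node_to_dict(model.root_),
        "sigma_b_hat": model.sigma_b_hat_,
        "patient_effects": {str(k): v for k, v in model.patient_effects_.items()},
        "kinds": {
            c: {"kind": k, "levels": lv} for c, (k, lv) in model.kinds_.items()
        },
        "partitioning_variables": model.partitioning_variables_,
        "fit_info": {
            "n_outer_iter": model.fit_info_["n_outer_iter"],
            "loglik_trace": model.fit_info_["loglik_trace"],
            "converged": model.fit_info_["converged"],
        },
        "config": model.get_params(),
    }
    return json.dumps(doc, indent=1, sort_keys=True)


def model_from_json(doc: str) -> GLMMTreeClassifier:
    d = json.loads(doc)
    if d.get("format") != "periotree-glmm-tree":
        raise ValueError("not a serialized GLMM tree document")
    params = d["config"]
    est = GLMMTreeClassifier(**params)
    est.root_ = _node_from_dict(d["tree"])
    est.sigma_b_hat_ = float(d["sigma_b_hat"])
    est.patient_effects_ = dict(d["patient_effects"])
    est.kinds_ = {c: (v["kind"], v["levels"]) for c, v in d["kinds"].items()}
    est.partitioning_variables_ = list(d["partitioning_variables"])
    est.fit_info_ = dict(d["fit_info"])
    est.n_leaves_ = len(est.root_.leaves())
    est.classes_ = np.array([0, 1])
    est.feature_names_in_ = np.asarray(list(est.kinds_), dtype=object)
    return est
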