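"""Plain-text rendering of fitted trees, selection results and CV metrics."""

from __future__ import annotations

from .selection import SelectionResult
from .tree import GLMMTreeClassifier, TreeNode
from .validation import CVResult


def render_tree(root: TreeNode, indent: str = "  ") -> str:
    """Indented text rendering; the left (lower-risk) child is printed first."""
    lines: list[str] = []

    def walk(node: TreeNode, depth: int, label: str):
        pad = indent * depth
        if node.is_leaf:
            rate = 100.0 * node.n_lost / node.n_teeth if node.n_teeth else float("nan")
            lines.append(
                f"{pad}{label}-> leaf [{node.node_id}]: "
                f"{rate:.1f}% lost ({node.n_lost}/{node.n_teeth}), beta={node.beta:+.3f}"
            )
            return
        lines.append(f"{pad}{label}[{node.node_id}] split on {node.split.describe()}")
        walk(node.children[0], depth + 1, "yes ")
        walk(node.children[1], depth + 1, "no  ")

    walk(root, 0, "")
    return "\n".join(lines)


def render_selection(sel: SelectionResult) -> str:
    lines = [
        f"bootstrap variable selection: {sel.n_used}/{sel.n_boot} replicates used "
        f"({sel.n_failed} failed), seed={sel.seed}",
        f"thresholds: tooth > {sel.tooth_threshold:.0%}, patient > {sel.patient_threshold:.0%}",
        "",
        f"{'variable':<18}{'level':<10}{'frequency':>10}  selected",
    ]
    for var in sorted(sel.frequency, key=lambda v: -sel.frequency[v]):
        mark = "*" if var in sel.selected else ""
        lines.append(
            f"{var:<18}{sel.variable_levels[var]:<10}{sel.frequency[var]:>10.3f}  {mark}"
        )
    return "\n".join(lines)


def render_cv(cv: CVResult) -> str:
    def fmt(name, mean, ci):
        return f"{name:<13}{mean:.2f}  (95% CI [{ci[0]:.2f}; {ci[1]:.2f}])"

    lines = [
        f"{cv.k}-fold patient-grouped cross-validation "
        f"({cv.n_patients} patients, seed={cv.seed}, threshold={cv.threshold_policy})",
        fmt("AUC", cv.auc, cv.auc_ci),
        fmt("sensitivity", cv.sensitivity, cv.sensitivity_ci),
        fmt("specificity", cv.specificity, cv.specificity_ci),
    ]
    if cv.skipped_folds:
        lines.append(f"skipped folds (single-class): {cv.skipped_folds}")
    return "\n".join(lines)


def render_report(
    selection: SelectionResult | None,
    model: GLMMTreeClassifier | None,
    cv: CVResult | None,
) -> str:
    """Combined human-readable run report."""
    parts = ["periotree run report", "=" * 21]
    if selection is not None:
        parts += ["", render_selection(selection)]
    if model is not None:
        parts += [
            "",
            "final model tree (sigma_b_hat = "
            f"{model.sigma_b_hat_:.3f}, {model.n_leaves_} leaves, "
            f"converged={model.fit_info_['converged']}):",
            render_tree(model.root_),
        ]
    if cv is not None:
        parts += ["", render_cv(cv)]
    return "\n".join(parts) + "\n"
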