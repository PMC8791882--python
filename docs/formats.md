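# File formats

## Cohort CSV (one row per tooth)

Header (case-insensitive): `patient_id, tooth_id, age, gender, smoking,
diabetes, pcr, jaw, tooth_type, furcation_class, bone_loss_raw, infrabony,
abutment, lost_by_T2`.

- Missing values: empty field or the token `NA`.
- `tooth_id`: two-digit FDI code, quadrants 1–4, positions 1–7.  Codes x8
  (third molars) are excluded at read time with a recorded diagnostic.
- Percent fields (`pcr`) as plain numbers in [0, 100]; `age` in years.
- Categorical tokens (lowercase):
  - `gender`: `female`, `male`
  - `smoking`: `never`, `former`, `active`
  - `diabetes`: `no`, `yes`
  - `jaw`: `maxilla`, `mandible`
  - `tooth_type`: `anterior`, `premolar`, `molar` (must match the FDI position)
  - `furcation_class`: `single_rooted`, `multi_no_fi`, `multi_fi`
  - `bone_loss_raw`: `<=20`, `21-40`, `41-60`, `61-80`, `>80`
  - `infrabony`: `shallow`, `moderate`, `deep`
  - `abutment`: `none`, `fixed`, `removable`
  - `lost_by_T2`: `0`, `1`
- The merged bone-loss category (`<=20`, `21-40`, `41-60`, `>60`) is always
  derived from `bone_loss_raw` and never stored.

A patient-only CSV (`patient_id, age, gender, smoking, diabetes, pcr`) may
be supplied separately and is joined on `patient_id`.

## Model JSON

`{"format": "periotree-glmm-tree", "version": 1, "tree": <node>,
"sigma_b_hat": float, "patient_effects": {pid: float}, "kinds": {...},
"partitioning_variables": [...], "fit_info": {...}, "config": {...}}`

A `<node>` is either a leaf (`node_id, beta, n_teeth, n_lost, depth`) or an
internal node with `split` (`variable`, `kind` ∈ numeric/ordinal/nominal,
`threshold` or `left_levels`), `p_value`, and two `children` (left = the
condition holds).  Parse → serialize round-trips byte-identically and
reproduces predictions bit-for-bit.

## Selection JSON

`n_boot, n_used, n_failed, seed, thresholds {tooth, patient},
variable_levels, frequency {var: fraction}, selected [var...],
replicate_variables [[var...]...]` (per-replicate audit trail).

## CV JSON

`k, n_patients, seed, threshold_policy, fold_auc/fold_sens/fold_spec,
auc/sensitivity/specificity` (fold means), `*_ci` (95% Wilson with
n = patients), `skipped_folds`.

## Prediction CSV

Published-tree mode: `patient_id, tooth_id, group_id, group_rate_pct,
group_path`.  Fitted-model mode: `patient_id, tooth_id, p_loss_10y`.

## Provenance

JSON artifacts embed a `meta` block (stage, seed, source, config echo);
CSV artifacts get a `<name>.meta.json` sidecar.  CLI config files are flat
JSON or YAML mappings; command-line flags override file values.
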