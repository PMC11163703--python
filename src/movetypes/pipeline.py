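"""End-to-end orchestration: compositions -> ilr -> outliers -> mixture fits
-> model selection -> labelled profiles -> imputation -> BCH distal models
-> report.

Children and adolescents are analysed separately (the group is a config
field).  All randomness descends deterministically from the single config
seed, so a rerun with the same config and inputs reproduces the report
byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .accelerometry import (
    CutpointSet,
    ValidityCriteria,
    aggregate_daily,
    classify_epochs,
    filter_valid_days,
    subject_compositions_table,
)
from .composition import build_basis, ilr_matrix
from .distal import (
    bch_distal_regression,
    bch_weights,
    classification_error_matrix,
    covariate_comparison,
    pool_rubin,
    school_variance_check,
)
from .imputation import ImputationConfig, littles_mcar_test, multiple_impute
from .lpa import (
    FitDiagnostics,
    class_difference_table,
    diagnostics,
    fit_lpa,
    label_profiles,
    select_model,
    vlmr_test,
    weighted_descriptives,
)
from .outliers import detect_outliers

log = logging.getLogger("movetypes")

COMP_COLS = ["mvpa_min", "lpa_min", "sb_min", "sleep_min"]
OUTCOME_SPECS = {  # outcome -> log transformed
    "bmi_z": False,
    "fm_pct": True,
    "fmi": True,
    "vat": True,
}
COVARIATES = ["sex_girl", "age_c", "birth_weight", "snacking",
              "parental_obesity", "parental_university"]


@dataclass(frozen=True)
class EMSettings:
    n_starts: int = 20
    tol: float = 1e-8
    max_iter: int = 500


@dataclass(frozen=True)
class AnalysisConfig:
    group: str = "children"
    k_min: int = 1
    k_max: int = 4
    outlier_quantile: float = 0.975
    min_class_share: float = 0.10
    use_vlmr_gate: bool = False
    vlmr_mode: str = "lmr_adjusted"
    assignment_mode: str = "proportional"
    em: EMSettings = field(default_factory=EMSettings)
    imputation: ImputationConfig = field(default_factory=ImputationConfig)
    seed: int = 0
    out_dir: str | None = None


def prepare_from_epochs(
    epochs: pd.DataFrame,
    cuts: CutpointSet | None = None,
    criteria: ValidityCriteria | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Epoch table -> per-subject compositions + validity verdicts."""
    labelled = classify_epochs(epochs, cuts)
    days = aggregate_daily(labelled)
    retained, verdicts = filter_valid_days(days, criteria)
    if retained.empty:
        return pd.DataFrame(columns=["subject_id", *COMP_COLS]), verdicts
    return subject_compositions_table(retained), verdicts


def _interactions_for(group: str, outcome: str) -> list[tuple[str, str]]:
    """Model-specific interaction terms mirroring the published adjustment:
    age x typology in every children model and the adolescent BMI-z model;
    age x sex additionally for children FM% and FMI."""
    terms: list[tuple[str, str]] = []
    if group == "children":
        terms.append(("age_c", "class"))
        if outcome in ("fm_pct", "fmi"):
            terms.append(("age_c", "sex_girl"))
    elif outcome == "bmi_z":
        terms.append(("age_c", "class"))
    return terms


def run_full(subjects: pd.DataFrame, config: AnalysisConfig) -> dict:
    """Run the complete analysis on a subject-level table.

    ``subjects`` needs the four composition columns, the covariates (possibly
    with missing parental values), school_id and the four outcomes.
    """
    rng = np.random.default_rng(config.seed)
    stage_seed = lambda: int(rng.integers(2**31 - 1))  # noqa: E731
    df = subjects.reset_index(drop=True).copy()
    n_input = len(df)
    basis = build_basis(4)
    Z = ilr_matrix(df[COMP_COLS].to_numpy(dtype=float), basis)

    outlier_seed = stage_seed()
    report_outliers = detect_outliers(Z, quantile=config.outlier_quantile,
                                      seed=outlier_seed)
    keep = ~report_outliers.flags
    log.info("outliers: %d of %d flagged", report_outliers.n_flagged, n_input)
    df = df[keep].reset_index(drop=True)
    Z = Z[keep]
    n = len(df)

    fits, diags = {}, {}
    fit_seed = stage_seed()
    for K in range(config.k_min, config.k_max + 1):
        fits[K] = fit_lpa(Z, K, n_starts=config.em.n_starts,
                          seed=fit_seed + K, tol=config.em.tol,
                          max_iter=config.em.max_iter)
        diags[K] = diagnostics(fits[K], n)
    vlmr_seed = stage_seed()
    for K in sorted(fits):
        if K - 1 in fits:
            p = vlmr_test(fits[K], fits[K - 1], n, mode=config.vlmr_mode,
                          z_matrix=Z, seed=vlmr_seed + K)
            diags[K] = FitDiagnostics(**{**asdict(diags[K]), "vlmr_p": p})

    selection = select_model(diags, min_class_share=config.min_class_share,
                             use_vlmr_gate=config.use_vlmr_gate)
    model = fits[selection.K]

    continuous = [c for c in ("age", "birth_weight", *OUTCOME_SPECS) if c in df]
    binary = [c for c in ("sex_girl", "snacking", "parental_obesity",
                          "parental_university") if c in df]
    profiles = weighted_descriptives(df, model.posteriors,
                                     continuous=continuous, binary=binary)
    # reorder classes so Workers (highest MVPA) is class 0 / reference
    order = sorted(range(selection.K),
                   key=lambda k: -profiles[k].compositional_mean.values[0])
    posteriors = model.posteriors[:, order]
    labelled = label_profiles(profiles)
    class_names = [p.label for p in labelled]
    differences = class_difference_table(labelled) if selection.K > 1 else None

    err = classification_error_matrix(posteriors, config.assignment_mode)
    weights = bch_weights(posteriors, err)

    missing_report = littles_mcar_test(
        df[[c for c in ("birth_weight", "maternal_bmi", "paternal_bmi",
                        "maternal_university", "paternal_university", "age",
                        "bmi_z") if c in df]]
    )
    imp_cfg = ImputationConfig(
        m=config.imputation.m, iterations=config.imputation.iterations,
        pmm_donors=config.imputation.pmm_donors, seed=stage_seed(),
    )
    imp_input_cols = [c for c in (
        "birth_weight", "maternal_bmi", "paternal_bmi", "maternal_university",
        "paternal_university", "sex_girl", "age", "snacking", "bmi_z",
        "fm_pct", "fmi", "vat",
    ) if c in df]
    imp_tables = multiple_impute(df[imp_input_cols], imp_cfg)
    completed = []
    for tab in imp_tables:
        full = df.copy()
        for c in tab.columns:
            full[c] = tab[c]
        if {"maternal_bmi", "paternal_bmi"} <= set(full.columns):
            full["parental_obesity"] = (
                (full["maternal_bmi"] >= 30) | (full["paternal_bmi"] >= 30)
            ).astype(float)
        if {"maternal_university", "paternal_university"} <= set(full.columns):
            full["parental_university"] = (
                (full["maternal_university"] > 0.5)
                | (full["paternal_university"] > 0.5)
            ).astype(float)
        full["age_c"] = full["age"] - full["age"].mean()
        completed.append(full)

    school = {}
    if "school_id" in df:
        for outcome, logt in OUTCOME_SPECS.items():
            if outcome not in df:
                continue
            y = df[outcome].to_numpy(dtype=float)
            school[outcome] = school_variance_check(
                np.log(y) if logt else y, df["school_id"].to_numpy()
            )

    distal_rows = []
    for outcome, logt in OUTCOME_SPECS.items():
        if outcome not in df:
            continue
        inter = _interactions_for(config.group, outcome)
        per_imp = []
        for full in completed:
            cov = full[[c for c in COVARIATES if c in full]].astype(float)
            res = bch_distal_regression(
                full[outcome].to_numpy(dtype=float), weights, cov,
                log_outcome=logt, reference=0, class_names=class_names,
                interactions=inter, outcome_name=outcome,
            )
            per_imp.append(res)
        terms = per_imp[0].terms
        for t_idx, term in enumerate(terms):
            pooled = pool_rubin(
                [r.coefficients[t_idx] for r in per_imp],
                [r.robust_se[t_idx] ** 2 for r in per_imp],
            )
            row = {
                "outcome": outcome, "term": term, "B": pooled.estimate,
                "se": pooled.se, "ci_low": pooled.estimate - 1.96 * pooled.se,
                "ci_high": pooled.estimate + 1.96 * pooled.se, "p": pooled.p,
                "pooled": 1,
            }
            if logt:
                row["exp_b"] = float(np.exp(pooled.estimate))
            distal_rows.append(row)
    distal_table = pd.DataFrame(distal_rows)

    covariate_rows = []
    if selection.K > 1:
        first = completed[0]
        for covname in ("age", "birth_weight", "sex_girl", "snacking",
                        "parental_obesity", "parental_university"):
            if covname not in first:
                continue
            res = covariate_comparison(
                first[covname].to_numpy(dtype=float), posteriors, err=None
            )
            covariate_rows.append({
                "covariate": covname,
                **{f"mean_{class_names[k]}": float(res["class_means"][k])
                   for k in range(selection.K)},
                "p": res["p"],
            })
    covariate_table = pd.DataFrame(covariate_rows)

    report = {
        "provenance": {
            "package_version": __version__,
            "seed": config.seed,
            "config_hash": hashlib.sha256(
                json.dumps(asdict(config), sort_keys=True).encode()
            ).hexdigest()[:16],
            "group": config.group,
        },
        "sample_flow": {
            "input_subjects": n_input,
            "outliers_removed": int(report_outliers.n_flagged),
            "analysed": n,
        },
        "model_selection": {
            "selected_K": selection.K,
            "rationale": list(selection.rationale),
            "table": [
                {"K": K, "loglik": d.loglik, "n_params": d.n_params,
                 "bic": d.bic, "aic": d.aic, "vlmr_p": d.vlmr_p,
                 "entropy": d.entropy, "min_class_share": d.min_class_share,
                 "selected": int(K == selection.K)}
                for K, d in sorted(diags.items())
            ],
        },
        "profiles": [
            {"label": p.label, "share": p.share,
             **{f"{name}_min": round(float(v), 1) for name, v in
                zip(p.compositional_mean.part_names, p.compositional_mean.values)}}
            for p in labelled
        ],
        "differences": (differences.to_dict(orient="records")
                        if differences is not None else []),
        "missingness": {
            "counts": {k: v for k, v in
                       sorted(missing_report.missing_counts.items())},
            "little_chi2": missing_report.little_chi2,
            "little_df": missing_report.little_df,
            "little_p": missing_report.little_p,
        },
        "school_screening": school,
        "distal": distal_table.to_dict(orient="records"),
        "covariate_comparison": covariate_table.to_dict(orient="records"),
    }

    if config.out_dir:
        _write_outputs(Path(config.out_dir), report, report_outliers, df,
                       distal_table, covariate_table, diags, selection)
    return report


def _round_floats(obj, ndigits=10):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, (np.floating,)):
        return round(float(obj), ndigits)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


def report_to_json(report: dict) -> str:
    """Canonical JSON serialisation (sorted keys, rounded floats)."""
    return json.dumps(_round_floats(report), sort_keys=True, indent=1)


def _write_outputs(out_dir, report, outlier_report, df, distal_table,
                   covariate_table, diags, selection):
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "report.json").write_text(report_to_json(report))
    pd.DataFrame({
        "subject_id": df["subject_id"] if "subject_id" in df else df.index,
        "robust_distance": outlier_report.robust_distances[~outlier_report.flags],
        "threshold": outlier_report.threshold,
        "flagged": 0,
    }).to_csv(out_dir / "outliers.csv", index=False)
    pd.DataFrame(report["model_selection"]["table"]).to_csv(
        out_dir / "model_selection.csv", index=False)
    pd.DataFrame(report["profiles"]).to_csv(out_dir / "profiles.csv", index=False)
    distal_table.to_csv(out_dir / "distal_results.csv", index=False)
    covariate_table.to_csv(out_dir / "covariate_tests.csv", index=False)
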