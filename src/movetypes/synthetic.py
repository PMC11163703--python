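"""Synthetic cohorts with the structure the typology analysis assumes.

The generator draws a latent activity typology per subject, a 4-part
24-hour composition from a logistic-normal distribution around that
typology's geometric-mean profile, covariates from the cohort's marginal
distributions, and adiposity outcomes from log-linear (or linear, for the
BMI z-score) models with typology effects.  Presets encode the two study
groups: children (n=374, two typologies mixed 80/20) and adolescents
(n=317, three typologies mixed 41/48/11).

Everything is driven by one integer seed through ``numpy.random.default_rng``
so cohorts are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .composition import DAY_MINUTES, build_basis, ilr_inverse_matrix, ilr_matrix

__all__ = [
    "OutcomeModel",
    "CovariateModel",
    "SyntheticConfig",
    "children_preset",
    "adolescents_preset",
    "generate_cohort",
    "inject_missingness",
    "DEFAULT_MISSING_RATES",
    "expand_to_days",
    "day_to_epochs",
]

#: Study-wide covariate missingness rates: reported missing counts out of the
#: 691 analysed subjects (birth weight 27, maternal BMI 46, paternal BMI 79,
#: maternal education 24, paternal education 61).
DEFAULT_MISSING_RATES: dict[str, float] = {
    "birth_weight": 27 / 691,
    "maternal_bmi": 46 / 691,
    "paternal_bmi": 79 / 691,
    "maternal_university": 24 / 691,
    "paternal_university": 61 / 691,
}

OUTCOMES: tuple[str, ...] = ("bmi_z", "fm_pct", "fmi", "vat")


@dataclass(frozen=True)
class OutcomeModel:
    """One adiposity outcome: intercept + class effects + covariate effects.

    For log-scale outcomes the linear predictor acts on ln(outcome) and the
    intercept targets the reference-class arithmetic mean (hence the
    -sigma^2/2 lognormal correction at generation time).  ``class_effects``
    has one entry per typology, reference (Workers) first, on the model scale.
    Covariate effects apply to centred covariates, so they do not shift the
    reference-class mean.
    """

    reference_mean: float
    class_effects: tuple[float, ...]
    resid_sd: float
    log_scale: bool = True
    covariate_effects: dict[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class CovariateModel:
    """Marginal covariate distributions for one study group."""

    p_girl: float
    age_range: tuple[float, float]
    birth_weight_mean: float
    birth_weight_sd: float
    p_snacking: float
    maternal_bmi_mean: float = 25.0
    maternal_bmi_sd: float = 4.0
    paternal_bmi_mean: float = 26.8
    paternal_bmi_sd: float = 3.3
    p_university_each: float = 0.314  # per parent; >=1 of 2 ~ 0.53


@dataclass(frozen=True)
class SyntheticConfig:
    n: int
    group: str  # "children" | "adolescents"
    mixing: tuple[float, ...]
    component_comps: tuple[tuple[float, ...], ...]  # minutes/day, close to 1440
    ilr_cov: np.ndarray
    covariate_model: CovariateModel
    outcome_models: dict[str, OutcomeModel]
    n_schools: int = 11
    school_sd: float = 0.0
    missing_rates: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MISSING_RATES)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "ilr_cov", np.asarray(self.ilr_cov, dtype=float))
        problems = []
        if self.n <= 0:
            problems.append("n must be positive")
        if self.group not in ("children", "adolescents"):
            problems.append("group must be 'children' or 'adolescents'")
        if abs(sum(self.mixing) - 1.0) > 1e-9 or any(p <= 0 for p in self.mixing):
            problems.append("mixing must be positive and sum to 1")
        if len(self.component_comps) != len(self.mixing):
            problems.append("one component composition per mixing weight")
        for comp in self.component_comps:
            if abs(sum(comp) - DAY_MINUTES) > 0.1:
                problems.append(f"component {comp} does not close to 1440")
        eig = np.linalg.eigvalsh(self.ilr_cov)
        if np.any(eig <= 0):
            problems.append("ilr_cov must be positive definite")
        for name, om in self.outcome_models.items():
            if om.resid_sd <= 0:
                problems.append(f"outcome {name}: resid_sd must be > 0")
            if len(om.class_effects) != len(self.mixing):
                problems.append(f"outcome {name}: one class effect per component")
        if problems:
            raise ValueError("invalid SyntheticConfig: " + "; ".join(problems))

    @property
    def K(self) -> int:
        return len(self.mixing)


def children_preset(**overrides) -> SyntheticConfig:
    """Children (8-13 y): two typologies, Workers 80% / Queens 20%.

    Component geometric-mean compositions and outcome reference means follow
    the children descriptive table; Queens-vs-Workers effects on the log
    outcomes are 0.32 (FM%), 0.36 (FMI), 0.51 (VAT) and -0.01 on the BMI
    z-score (linear scale).
    """
    cfg = SyntheticConfig(
        n=374,
        group="children",
        mixing=(0.80, 0.20),
        component_comps=(
            (63.7, 310.5, 547.6, 518.2),  # Workers
            (31.4, 259.9, 621.2, 527.5),  # Queens
        ),
        ilr_cov=0.04 * np.eye(3),
        covariate_model=CovariateModel(
            p_girl=0.570,
            age_range=(8.0, 13.0),
            birth_weight_mean=3.4,
            birth_weight_sd=0.5,
            p_snacking=0.417,
        ),
        outcome_models={
            "bmi_z": OutcomeModel(
                0.25, (0.0, -0.01), resid_sd=1.15, log_scale=False,
                covariate_effects={"parental_obesity": 0.45, "birth_weight_c": 0.20},
            ),
            "fm_pct": OutcomeModel(
                19.0, (0.0, 0.32), resid_sd=0.41,
                covariate_effects={"sex_girl_c": 0.18, "parental_obesity": 0.12,
                                   "snacking": 0.04},
            ),
            "fmi": OutcomeModel(
                3.7, (0.0, 0.36), resid_sd=0.52,
                covariate_effects={"sex_girl_c": 0.20, "parental_obesity": 0.15},
            ),
            "vat": OutcomeModel(
                41.5, (0.0, 0.51), resid_sd=0.60,
                covariate_effects={"sex_girl_c": 0.15, "parental_obesity": 0.18,
                                   "age_c": 0.03},
            ),
        },
    )
    return replace(cfg, **overrides) if overrides else cfg


def adolescents_preset(**overrides) -> SyntheticConfig:
    """Adolescents (14-18 y): Workers 41% / Drones 48% / Queens 11%."""
    cfg = SyntheticConfig(
        n=317,
        group="adolescents",
        mixing=(0.41, 0.48, 0.11),
        component_comps=(
            (56.2, 255.9, 658.6, 469.3),  # Workers
            (31.7, 248.6, 687.4, 472.3),  # Drones
            (16.6, 231.5, 734.9, 457.0),  # Queens
        ),
        ilr_cov=0.04 * np.eye(3),
        covariate_model=CovariateModel(
            p_girl=0.577,
            age_range=(14.0, 18.0),
            birth_weight_mean=3.3,
            birth_weight_sd=0.6,
            p_snacking=0.256,
        ),
        outcome_models={
            "bmi_z": OutcomeModel(
                0.16, (0.0, 0.04, 0.16), resid_sd=1.00, log_scale=False,
                covariate_effects={"parental_obesity": 0.45, "birth_weight_c": 0.20},
            ),
            "fm_pct": OutcomeModel(
                19.1, (0.0, 0.13, 0.14), resid_sd=0.42,
                covariate_effects={"sex_girl_c": 0.25, "parental_obesity": 0.12},
            ),
            "fmi": OutcomeModel(
                4.3, (0.0, 0.14, 0.16), resid_sd=0.53,
                covariate_effects={"sex_girl_c": 0.25, "parental_obesity": 0.15},
            ),
            "vat": OutcomeModel(
                49.0, (0.0, 0.14, 0.31), resid_sd=0.57,
                covariate_effects={"parental_obesity": 0.18, "age_c": 0.03},
            ),
        },
    )
    return replace(cfg, **overrides) if overrides else cfg


def generate_cohort(config: SyntheticConfig, seed: int | None = None) -> pd.DataFrame:
    """Draw one cohort as a subject-level table.

    Columns include the latent ``true_class`` (0 = Workers, ordered by
    decreasing MVPA as in the presets), which the analysis pipeline must not
    see; it exists for recovery tests.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n, K = config.n, config.K
    basis = build_basis(4)

    true_class = rng.choice(K, size=n, p=np.asarray(config.mixing))
    comp_matrix = np.asarray(config.component_comps, dtype=float)
    class_means_ilr = ilr_matrix(comp_matrix / DAY_MINUTES, basis)
    chol = np.linalg.cholesky(config.ilr_cov)
    z = class_means_ilr[true_class] + rng.standard_normal((n, 3)) @ chol.T
    minutes = ilr_inverse_matrix(z, basis, total=DAY_MINUTES)

    cm = config.covariate_model
    sex_girl = (rng.random(n) < cm.p_girl).astype(int)
    age = rng.uniform(*cm.age_range, size=n)
    birth_weight = np.clip(
        rng.normal(cm.birth_weight_mean, cm.birth_weight_sd, size=n), 0.8, 6.0
    )
    snacking = (rng.random(n) < cm.p_snacking).astype(int)
    maternal_bmi = np.clip(rng.normal(cm.maternal_bmi_mean, cm.maternal_bmi_sd, n), 15, 55)
    paternal_bmi = np.clip(rng.normal(cm.paternal_bmi_mean, cm.paternal_bmi_sd, n), 15, 55)
    maternal_university = (rng.random(n) < cm.p_university_each).astype(int)
    paternal_university = (rng.random(n) < cm.p_university_each).astype(int)
    parental_obesity = ((maternal_bmi >= 30) | (paternal_bmi >= 30)).astype(int)
    parental_university = (maternal_university | paternal_university).astype(int)
    school_id = rng.integers(0, config.n_schools, size=n)
    school_effects = rng.normal(0.0, config.school_sd, size=config.n_schools)

    centred = {
        "sex_girl_c": sex_girl - cm.p_girl,
        "age_c": age - age.mean(),
        "birth_weight_c": birth_weight - cm.birth_weight_mean,
        "snacking": snacking - cm.p_snacking,
        "parental_obesity": parental_obesity - parental_obesity.mean(),
    }

    out = {
        "subject_id": np.arange(n),
        "group": config.group,
        "true_class": true_class,
        "sex_girl": sex_girl,
        "age": age,
        "birth_weight": birth_weight,
        "snacking": snacking,
        "maternal_bmi": maternal_bmi,
        "paternal_bmi": paternal_bmi,
        "maternal_university": maternal_university,
        "paternal_university": paternal_university,
        "parental_obesity": parental_obesity,
        "parental_university": parental_university,
        "school_id": school_id,
        "mvpa_min": minutes[:, 0],
        "lpa_min": minutes[:, 1],
        "sb_min": minutes[:, 2],
        "sleep_min": minutes[:, 3],
    }

    for name, om in config.outcome_models.items():
        eta = np.full(n, 0.0)
        eta += np.asarray(om.class_effects)[true_class]
        for cov, beta in om.covariate_effects.items():
            eta += beta * centred[cov]
        eta += school_effects[school_id]
        eps = rng.normal(0.0, om.resid_sd, size=n)
        if om.log_scale:
            intercept = np.log(om.reference_mean) - om.resid_sd**2 / 2.0
            vals = np.exp(intercept + eta + eps)
            if name == "fm_pct":
                vals = np.clip(vals, 1.0, 95.0)
        else:
            vals = om.reference_mean + eta + eps
        out[name] = vals

    return pd.DataFrame(out)


def inject_missingness(
    table: pd.DataFrame,
    rates: dict[str, float] | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """MCAR Bernoulli deletion per covariate; returns (table, truth mask).

    The mask is True where a value was deleted.  Deletion is independent of
    everything, so a missing-completely-at-random test applied downstream
    should reject at its nominal size only.
    """
    rates = dict(DEFAULT_MISSING_RATES) if rates is None else rates
    bad = {k: v for k, v in rates.items() if not (0.0 <= v < 1.0)}
    if bad:
        raise ValueError(f"rates must lie in [0, 1): {bad}")
    rng = np.random.default_rng(seed)
    out = table.copy()
    mask = pd.DataFrame(False, index=table.index, columns=table.columns)
    for col, rate in rates.items():
        if col not in out.columns or rate == 0.0:
            continue
        hit = rng.random(len(out)) < rate
        out.loc[hit, col] = np.nan
        mask[col] = hit
    # derived flags are unknown whenever an ingredient is unknown
    if {"maternal_bmi", "paternal_bmi"} <= set(rates):
        und = out["maternal_bmi"].isna() | out["paternal_bmi"].isna()
        out.loc[und, "parental_obesity"] = np.nan
    if {"maternal_university", "paternal_university"} <= set(rates):
        und = out["maternal_university"].isna() | out["paternal_university"].isna()
        out.loc[und, "parental_university"] = np.nan
    return out, mask


def expand_to_days(
    cohort: pd.DataFrame,
    n_school_days: int = 4,
    n_weekend_days: int = 2,
    day_sd: float = 0.10,
    seed: int = 0,
) -> pd.DataFrame:
    """Expand subject compositions to per-day compositions.

    Day-level variation is logistic-normal around the subject composition
    (ilr noise with SD ``day_sd``), which keeps every day strictly positive.
    """
    rng = np.random.default_rng(seed)
    basis = build_basis(4)
    rows = []
    comp_cols = ["mvpa_min", "lpa_min", "sb_min", "sleep_min"]
    for _, subj in cohort.iterrows():
        z0 = ilr_matrix(subj[comp_cols].to_numpy(dtype=float)[None, :], basis)[0]
        n_days = n_school_days + n_weekend_days
        Z = z0 + rng.normal(0.0, day_sd, size=(n_days, 3))
        minutes = ilr_inverse_matrix(Z, basis, total=DAY_MINUTES)
        for d in range(n_days):
            rows.append({
                "subject_id": subj["subject_id"],
                "date": f"2018-10-{d + 1:02d}",
                "day_type": "school" if d < n_school_days else "weekend",
                "mvpa_min": minutes[d, 0],
                "lpa_min": minutes[d, 1],
                "sb_min": minutes[d, 2],
                "sleep_min": minutes[d, 3],
                "wear_hours": 24.0,
            })
    return pd.DataFrame(rows)


def day_to_epochs(
    day: dict | pd.Series,
    seed: int = 0,
    epoch_seconds: int = 5,
) -> pd.DataFrame:
    """Emit a 5-s epoch series realising one day's behaviour-minute totals.

    Sleep occupies a contiguous night block split across the start and end of
    the midnight-to-midnight day; waking behaviours are shuffled in one-minute
    runs.  ENMO values are drawn uniformly inside each behaviour's cutpoint
    band (SB < 36 mg, LPA 36-200 mg, MVPA >= 201 mg).
    """
    rng = np.random.default_rng(seed)
    per_min = 60 // epoch_seconds
    n_epochs = 1440 * per_min
    target = np.array(
        [day["mvpa_min"], day["lpa_min"], day["sb_min"], day["sleep_min"]], float
    )
    minutes = np.floor(target).astype(int)
    # distribute leftover minutes by largest remainder so the day stays full
    for idx in np.argsort(minutes - target)[: 1440 - minutes.sum()]:
        minutes[idx] += 1
    labels = np.empty(1440, dtype=object)
    sleep_n = minutes[3]
    head = sleep_n // 2
    labels[1440 - (sleep_n - head):] = "sleep"
    labels[:head] = "sleep"
    wake = np.concatenate([
        np.repeat("mvpa", minutes[0]),
        np.repeat("lpa", minutes[1]),
        np.repeat("sb", minutes[2]),
    ])
    rng.shuffle(wake)
    labels[head: head + wake.size] = wake
    lab = np.repeat(labels, per_min)
    enmo = np.where(
        lab == "sb", rng.uniform(0, 35.9, n_epochs),
        np.where(lab == "lpa", rng.uniform(36, 200.9, n_epochs),
                 np.where(lab == "mvpa", rng.uniform(201, 900, n_epochs),
                          rng.uniform(0, 20, n_epochs))),
    )
    ts = pd.date_range(
        str(day.get("date", "2018-10-01")), periods=n_epochs,
        freq=f"{epoch_seconds}s",
    )
    return pd.DataFrame({
        "subject_id": day.get("subject_id", 0),
        "timestamp": ts,
        "enmo_mg": enmo,
        "wear": 1,
        "asleep": (lab == "sleep").astype(int),
        "day_type": day.get("day_type", "school"),
    })
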