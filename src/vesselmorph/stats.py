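"""Statistical evaluation of vessel features over subject tables.

Implements the evaluation protocol around the morphological features:
OLS models of age and of cardiovascular/cognitive outcomes (with age and
sex as covariates), nested-model ANOVA between cortex-only and
cortex-plus-vessel models, pooled 10-fold cross-validated R^2, the
hypertension labelling rule (diastolic > 90 mmHg or systolic > 140 mmHg,
strictly), and logistic hypertension classifiers.

Model formulas use Patsy notation via statsmodels; the placeholders
``{vessels}`` and ``{cortex}`` expand to the 11 morphological feature
columns and to the cortical-thickness columns of the table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from sklearn.model_selection import KFold

from .features import FEATURE_NAMES

THICKNESS_PREFIX = "thickness_"

#: the nine named model formulas of the evaluation protocol
FORMULAS: dict[str, str] = {
    "age~cortex": "age ~ {cortex}",
    "age~vessels": "age ~ {vessels}",
    "age~cortex+vessels": "age ~ {cortex} + {vessels}",
    "dv~age+sex+cortex": "{dv} ~ age + C(sex) + {cortex}",
    "dv~age+sex+vessels": "{dv} ~ age + C(sex) + {vessels}",
    "dv~age+sex+cortex+vessels": "{dv} ~ age + C(sex) + {cortex} + {vessels}",
    "htn~age+sex+cortex": "hypertension ~ age + C(sex) + {cortex}",
    "htn~age+sex+vessels": "hypertension ~ age + C(sex) + {vessels}",
    "htn~age+sex+cortex+vessels": "hypertension ~ age + C(sex) + {cortex} + {vessels}",
}

LOGISTIC_FORMULAS = ("htn~age+sex+cortex", "htn~age+sex+vessels", "htn~age+sex+cortex+vessels")


class FormulaError(ValueError):
    pass


def thickness_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c.startswith(THICKNESS_PREFIX)]


def vessel_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in FEATURE_NAMES if c in table.columns]


def build_formula(formula_id: str, table: pd.DataFrame, dv: str | None = None) -> str:
    """Expand a formula id (or a raw Patsy formula) against a table."""
    template = FORMULAS.get(formula_id, formula_id)
    cortex = " + ".join(thickness_columns(table))
    vessels = " + ".join(vessel_columns(table))
    if "{cortex}" in template and not cortex:
        raise FormulaError("table has no cortical-thickness columns (prefix 'thickness_')")
    if "{vessels}" in template and not vessels:
        raise FormulaError("table has no vessel-feature columns")
    if "{dv}" in template and dv is None:
        raise FormulaError(f"formula {formula_id!r} needs a dependent variable (dv=...)")
    return template.format(cortex=cortex, vessels=vessels, dv=dv or "")


def _formula_columns(formula: str, table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c in formula.replace("C(", " ").replace(")", " ").replace("~", " ").replace("+", " ").split()]


def _check_rank(res) -> None:
    exog = res.model.exog
    rank = np.linalg.matrix_rank(exog)
    if rank < exog.shape[1]:
        names = np.asarray(res.model.exog_names)
        # columns loading on the null space are the collinear suspects
        _, s, vt = np.linalg.svd(exog, full_matrices=False)
        null = np.abs(vt[rank:]).sum(axis=0) > 1e-8
        raise FormulaError(
            f"rank-deficient design: collinear columns {list(names[null])}"
        )


def fit_linear(
    table: pd.DataFrame, formula_id: str, dv: str | None = None
) -> sm.regression.linear_model.RegressionResultsWrapper:
    """Ordinary least squares via a named formula; listwise deletion.

    The returned statsmodels results expose coefficients (``params``),
    ``rsquared_adj`` and per-subject ``resid``.
    """
    formula = build_formula(formula_id, table, dv=dv)
    cols = _formula_columns(formula, table)
    data = table.dropna(subset=cols) if cols else table
    y_name = formula.split("~")[0].strip()
    if y_name in data.columns and data[y_name].nunique() <= 1:
        raise FormulaError(f"response {y_name!r} has zero variance")
    res = smf.ols(formula, data=data).fit()
    if res.model.exog.shape[0] <= res.model.exog.shape[1]:
        raise FormulaError("fewer rows than model parameters after listwise deletion")
    _check_rank(res)
    return res


@dataclass
class ModelComparisonResult:
    """Nested-model F comparison (reduced vs full)."""

    f_statistic: float
    df_num: int
    df_den: int
    p_value: float
    adj_r2_reduced: float
    adj_r2_full: float

    def to_dict(self) -> dict:
        return {
            "f_statistic": self.f_statistic,
            "df_num": self.df_num,
            "df_den": self.df_den,
            "p_value": self.p_value,
            "adj_r2_reduced": self.adj_r2_reduced,
            "adj_r2_full": self.adj_r2_full,
        }

    def __str__(self) -> str:  # the field's conventional rendering
        return (
            f"F_{self.df_num},{self.df_den} = {self.f_statistic:.3g}, "
            f"p = {self.p_value:.3g}"
        )


def nested_anova(reduced, full) -> ModelComparisonResult:
    """F-test between nested OLS fits computed on identical rows.

    F = ((SSR_reduced - SSR_full) / df_num) / (SSR_full / df_den) with
    df_num the number of added parameters and df_den the full model's
    residual degrees of freedom.
    """
    red_names = set(reduced.model.exog_names)
    full_names = set(full.model.exog_names)
    if not red_names < full_names:
        raise FormulaError(
            "models are not nested: reduced predictors must be a strict "
            "subset of the full model's"
        )
    if reduced.nobs != full.nobs:
        raise FormulaError(
            "reduced and full models were fit on different numbers of rows; "
            "apply listwise deletion over the union of model variables first"
        )
    df_num = int(full.df_model - reduced.df_model)
    df_den = int(full.df_resid)
    num = (reduced.ssr - full.ssr) / df_num
    den = full.ssr / df_den
    f = max(num / den, 0.0)
    p = float(scipy.stats.f.sf(f, df_num, df_den)) if f > 0 else 1.0
    return ModelComparisonResult(
        f_statistic=float(f),
        df_num=df_num,
        df_den=df_den,
        p_value=p,
        adj_r2_reduced=float(reduced.rsquared_adj),
        adj_r2_full=float(full.rsquared_adj),
    )


def fit_nested_pair(
    table: pd.DataFrame, reduced_id: str, full_id: str, dv: str | None = None
) -> ModelComparisonResult:
    """Fit reduced and full models on identical complete-case rows and compare."""
    cols = sorted(
        set(_formula_columns(build_formula(reduced_id, table, dv), table))
        | set(_formula_columns(build_formula(full_id, table, dv), table))
    )
    data = table.dropna(subset=cols)
    return nested_anova(
        fit_linear(data, reduced_id, dv=dv), fit_linear(data, full_id, dv=dv)
    )


@dataclass
class CrossValResult:
    """Pooled out-of-fold coefficient of determination."""

    r2: float
    fold_assignment: np.ndarray
    seed: int
    k: int

    def to_dict(self) -> dict:
        return {"r2": self.r2, "k": self.k, "seed": self.seed}


def crossval_r2(
    table: pd.DataFrame,
    formula_id: str,
    k: int = 10,
    seed: int = 0,
    dv: str | None = None,
) -> CrossValResult:
    """k-fold cross-validated R^2 over pooled out-of-fold predictions.

    Subjects are partitioned by a seeded shuffle; each fold is predicted
    by a model fit on the remaining folds; R^2 = 1 - SS_res / SS_tot over
    the pooled predictions, so every subject is predicted exactly once
    with a model that never saw their row.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    formula = build_formula(formula_id, table, dv=dv)
    cols = _formula_columns(formula, table)
    data = table.dropna(subset=cols).reset_index(drop=True)
    if len(data) < k:
        raise ValueError(f"only {len(data)} complete rows for {k} folds")
    y_name = formula.split("~")[0].strip()
    folds = np.empty(len(data), dtype=int)
    preds = np.empty(len(data), dtype=float)
    kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    for fold, (train, test) in enumerate(kf.split(data)):
        res = smf.ols(formula, data=data.iloc[train]).fit()
        if res.model.exog.shape[0] <= res.model.exog.shape[1]:
            raise ValueError(
                f"fold {fold} leaves fewer training rows than parameters; use a smaller k"
            )
        preds[test] = res.predict(data.iloc[test])
        folds[test] = fold
    y = data[y_name].to_numpy(dtype=float)
    ss_res = float(((y - preds) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    return CrossValResult(r2=1.0 - ss_res / ss_tot, fold_assignment=folds, seed=seed, k=k)


def label_hypertension(diastolic_bp, systolic_bp):
    """Hypertension label: diastolic > 90 mmHg or systolic > 140 mmHg (strict).

    Accepts scalars or array-likes; missing values yield a missing label
    (pd.NA) that downstream model fits drop listwise.
    """
    d = pd.Series(np.atleast_1d(np.asarray(diastolic_bp, dtype=float)))
    s = pd.Series(np.atleast_1d(np.asarray(systolic_bp, dtype=float)))
    label = ((d > 90) | (s > 140)).astype("boolean")
    label[d.isna() | s.isna()] = pd.NA
    if np.isscalar(diastolic_bp) and np.isscalar(systolic_bp):
        val = label.iloc[0]
        return bool(val) if val is not pd.NA else None
    return label


@dataclass
class LogisticComparisonResult:
    """Cortex-only vs cortex-plus-vessels logistic comparison.

    The primary statistic is an analysis-of-deviance F with the same
    degree-of-freedom bookkeeping as the OLS nested ANOVA; the
    likelihood-ratio chi-square test is reported alongside as a clearly
    labelled extension.
    """

    f_statistic: float
    df_num: int
    df_den: int
    p_value: float
    lrt_chi2: float
    lrt_p_value: float
    pseudo_r2_reduced: float
    pseudo_r2_full: float
    perfectly_separated: bool = False

    def to_dict(self) -> dict:
        return self.__dict__.copy()


def fit_logistic(table: pd.DataFrame, formula_id: str):
    """Maximum-likelihood logistic regression via a named formula.

    Perfect separation is flagged with a warning on the returned results
    (``perfectly_separated`` attribute) rather than raised.
    """
    formula = build_formula(formula_id, table)
    cols = _formula_columns(formula, table)
    data = table.dropna(subset=cols).copy()
    y_name = formula.split("~")[0].strip()
    y = data[y_name].astype(float)
    if y.nunique() < 2:
        raise FormulaError(f"single-class outcome: {y_name!r} has one unique value")
    data[y_name] = y
    separated = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            res = smf.logit(formula, data=data).fit(disp=0, maxiter=200)
        except Exception:  # statsmodels raises on exact separation
            separated = True
            res = smf.logit(formula, data=data).fit(
                disp=0, method="bfgs", maxiter=500, skip_hessian=True
            )
        for w in caught:
            if "separation" in str(w.message).lower():
                separated = True
    if separated:
        warnings.warn("perfect separation detected; coefficients are unstable")
    res.perfectly_separated = separated
    return res


def compare_logistic(
    table: pd.DataFrame, reduced_id: str, full_id: str
) -> LogisticComparisonResult:
    """Nested comparison of two logistic models on identical rows."""
    cols = sorted(
        set(_formula_columns(build_formula(reduced_id, table), table))
        | set(_formula_columns(build_formula(full_id, table), table))
    )
    data = table.dropna(subset=cols)
    red = fit_logistic(data, reduced_id)
    full = fit_logistic(data, full_id)
    if not set(red.model.exog_names) < set(full.model.exog_names):
        raise FormulaError("logistic models are not nested")
    df_num = int(full.df_model - red.df_model)
    df_den = int(full.df_resid)
    dev_red = -2.0 * red.llf
    dev_full = -2.0 * full.llf
    chi2 = max(dev_red - dev_full, 0.0)
    f = (chi2 / df_num) / (dev_full / df_den) if dev_full > 0 else np.inf
    return LogisticComparisonResult(
        f_statistic=float(f),
        df_num=df_num,
        df_den=df_den,
        p_value=float(scipy.stats.f.sf(f, df_num, df_den)),
        lrt_chi2=float(chi2),
        lrt_p_value=float(scipy.stats.chi2.sf(chi2, df_num)),
        pseudo_r2_reduced=float(red.prsquared),
        pseudo_r2_full=float(full.prsquared),
        perfectly_separated=bool(
            getattr(red, "perfectly_separated", False)
            or getattr(full, "perfectly_separated", False)
        ),
    )


def split_by_age(table: pd.DataFrame, cutoff: float = 60.0):
    """Older (> cutoff years) / younger (<= cutoff) subgroup split."""
    older = table[table["age"] > cutoff]
    younger = table[table["age"] <= cutoff]
    return older, younger


def simulate_subject_table(
    n: int = 650,
    seed: int = 0,
    n_thickness: int = 6,
    vessel_age_weight: float = 0.21,
    thickness_noise_sd: float = 0.3,
    bp_noise_sd: float = 8.0,
) -> pd.DataFrame:
    """Synthetic life-span cohort for exercising the evaluation protocol.

    Ages are uniform over 18-88 years; cortical thickness declines with
    age, vessel features drift with age (vessels dilate, lengthen and
    grow more tortuous), blood pressure rises with age and MMSE mildly
    declines past midlife. The default noise scales put the age models
    in the regime typical of real life-span cohorts — a vessels-only
    model explains roughly 40% of age variance, cortex-only roughly 60%,
    and the combined model roughly 70% — and give a hypertension
    prevalence near 11%. The seed fully determines the table; effects
    are plain linear with Gaussian noise, so the table exercises the
    model plumbing, not biological realism.
    """
    rng = np.random.default_rng(seed)
    age = rng.uniform(18, 88, n)
    sex = rng.choice(["M", "F"], n)
    z = (age - 50) / 20
    tab = {"subject_id": [f"sub-{i:04d}" for i in range(n)], "age": age, "sex": sex}
    for j in range(n_thickness):
        tab[f"{THICKNESS_PREFIX}region{j}"] = (
            2.5 - 0.15 * z * rng.uniform(0.5, 1.5) + rng.normal(0, thickness_noise_sd, n)
        )
    base = {
        "total_volume_mm3": (9000, 800, 600),
        "total_length_mm": (1500, 120, 100),
        "n_segments": (120, 8, 10),
        "n_bifurcations": (55, 4, 5),
        "n_endpoints": (60, 4, 5),
        "mean_radius_mm": (1.2, 0.12, 0.08),
        "sd_radius_mm": (0.4, 0.04, 0.04),
        "max_radius_mm": (3.2, 0.25, 0.2),
        "mean_tortuosity": (1.15, 0.03, 0.02),
        "sd_tortuosity": (0.1, 0.012, 0.01),
        "mean_segment_length_mm": (12.0, 0.8, 0.9),
    }
    for name, (mu, slope, sd) in base.items():
        vals = mu + vessel_age_weight * slope * z + rng.normal(0, sd, n)
        if name.startswith("n_"):
            vals = np.round(np.clip(vals, 0, None))
        tab[name] = vals
    sex_bp = np.where(np.asarray(sex) == "M", 2.0, 0.0)
    tab["diastolic_bp"] = 73 + 4.0 * z + sex_bp + rng.normal(0, bp_noise_sd, n)
    tab["systolic_bp"] = 117 + 8.0 * z + sex_bp + rng.normal(0, 1.3 * bp_noise_sd, n)
    tab["mmse"] = np.clip(np.round(29 - 1.2 * np.clip(z, 0, None) + rng.normal(0, 1.2, n)), 0, 30)
    df = pd.DataFrame(tab)
    df["hypertension"] = label_hypertension(df["diastolic_bp"], df["systolic_bp"])
    return df
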