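"""Association models linking the PRS (or single variants) to disease
status, age at onset and CSF biomarker levels.

Models, with covariate sets fixed across traits:

* disease status   — logistic regression:
  ``status ~ PRS + age_at_last_assessment + sex + PC1 + PC2``
* age at onset     — Cox proportional hazards (Efron ties), onset as
  the event for cases, controls censored at age at last assessment:
  ``onset ~ PRS + sex + PC1 + PC2``
* CSF biomarkers   — ordinary least squares on the harmonized
  (log10, platform-centered) level:
  ``level ~ PRS + age_at_lp + sex + PC1 + PC2``

Tertile analyses compare the lowest and highest PRS thirds with a
Kaplan-Meier log-rank test and an exponentiated Cox coefficient for
the third-vs-first-tertile indicator.  Sex is coded female = 1.
Confidence intervals are Wald at 95%; no multiple-testing correction
is applied anywhere (single-variant results are nominal).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy.stats import rankdata

from .biomarkers import ANALYTES
from .qc import DosageMatrix
from .panel import ScoringPanel
from .scoring import ScoreSet

logger = logging.getLogger(__name__)

COHORT_COLUMNS = (
    "status",
    "sex",
    "age_at_onset",
    "age_at_last_assessment",
    "family_history",
    "platform",
    "pc1",
    "pc2",
)

STATUS_COVARIATES = ["age_at_last_assessment", "sex_female", "pc1", "pc2"]
SURVIVAL_COVARIATES = ["sex_female", "pc1", "pc2"]
BIOMARKER_COVARIATES = ["age_at_lp", "sex_female", "pc1", "pc2"]


@dataclass
class AssociationResult:
    """One trait ~ predictor fit: effect, 95% CI, p, provenance."""

    trait: str
    predictor: str
    beta: float
    ci_low: float
    ci_high: float
    p_value: float
    model_formula: str
    n_used: int
    converged: bool = True
    stratum: str | None = None

    def as_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class SurvivalResult:
    """Cox / Kaplan-Meier output for an age-at-onset analysis."""

    hazard_beta: float
    p_value: float
    ci_low: float = np.nan
    ci_high: float = np.nan
    tertile_effect: float | None = None
    logrank_statistic: float | None = None
    logrank_df: int | None = None
    logrank_p: float | None = None
    km_curves: dict[str, pd.DataFrame] = field(default_factory=dict)
    n_used: int = 0
    n_events: int = 0
    model_formula: str = ""
    stratum: str | None = None


# -- cohort table helpers -------------------------------------------------


def validate_cohort(cohort: pd.DataFrame) -> None:
    missing = set(COHORT_COLUMNS) - set(cohort.columns)
    if missing:
        raise ValueError(f"cohort table missing columns: {sorted(missing)}")
    if not cohort.index.is_unique:
        raise ValueError("cohort sample IDs must be unique")
    cases = cohort["status"] == "case"
    if cohort.loc[cases, "age_at_onset"].isna().any():
        bad = cohort.loc[cases & cohort["age_at_onset"].isna()].index[0]
        raise ValueError(f"case {bad} has no age at onset")
    if cohort.loc[~cases, "age_at_onset"].notna().any():
        bad = cohort.loc[~cases & cohort["age_at_onset"].notna()].index[0]
        raise ValueError(f"control {bad} has an age at onset")
    for col in ("age_at_onset", "age_at_last_assessment"):
        vals = cohort[col].dropna()
        if ((vals <= 0) | (vals >= 120)).any():
            raise ValueError(f"{col} outside (0, 120)")


def _model_frame(scores: ScoreSet, cohort: pd.DataFrame) -> pd.DataFrame:
    validate_cohort(cohort)
    shared = scores.table.index.intersection(cohort.index)
    missing = scores.table.index.difference(cohort.index)
    if len(missing) > 0:
        raise ValueError(
            f"{len(missing)} scored samples lack cohort covariates "
            f"(e.g. {list(missing[:3])})"
        )
    df = cohort.loc[shared].copy()
    df["score"] = scores.table.loc[shared, "score"]
    if "tertile" in scores.table.columns:
        df["tertile"] = scores.table.loc[shared, "tertile"]
    df["sex_female"] = (df["sex"] == "female").astype(float)
    df["is_case"] = (df["status"] == "case").astype(float)
    return df


def _check_predictor(x: pd.Series, name: str) -> None:
    if x.nunique(dropna=True) < 2:
        raise ValueError(f"predictor {name} is constant; model is degenerate")


# -- disease status -------------------------------------------------------


def _fit_logistic(
    df: pd.DataFrame,
    predictor: str,
    covariates: list[str],
    trait: str,
    predictor_label: str,
) -> AssociationResult:
    cols = [predictor] + [c for c in covariates if c in df.columns]
    data = df[["is_case"] + cols].dropna()
    if data["is_case"].nunique() < 2:
        raise ValueError("both outcome classes must be present")
    _check_predictor(data[predictor], predictor_label)
    X = sm.add_constant(data[cols], has_constant="add")
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(data["is_case"], X).fit(disp=0, maxiter=200)
            converged = bool(fit.mle_retvals.get("converged", True))
            beta = float(fit.params[predictor])
            se = float(fit.bse[predictor])
            p = float(fit.pvalues[predictor])
        except Exception as exc:  # separation and similar failures
            logger.warning("logistic fit failed (%s); flagged non-converged", exc)
            converged, beta, se, p = False, np.nan, np.nan, np.nan
    if converged and (not np.isfinite(se) or se > 1e4):
        converged = False  # quasi-separation: absurd standard error
    half = 1.959963984540054 * se
    formula = f"{trait} ~ {predictor_label} + " + " + ".join(covariates)
    return AssociationResult(
        trait=trait,
        predictor=predictor_label,
        beta=beta,
        ci_low=beta - half,
        ci_high=beta + half,
        p_value=p,
        model_formula=formula,
        n_used=len(data),
        converged=converged,
    )


def status_association(
    scores: ScoreSet,
    cohort: pd.DataFrame,
    covariates: list[str] | None = None,
) -> AssociationResult:
    """Logistic regression of case-control status on the PRS,
    adjusted for age at last assessment, sex, PC1 and PC2."""
    df = _model_frame(scores, cohort)
    covs = STATUS_COVARIATES if covariates is None else covariates
    return _fit_logistic(df, "score", covs, "PD status", "PRS")


def mann_whitney_auc(y_true: np.ndarray, y_score: np.ndarray) -> float:
    """AUC by the rank (Mann-Whitney) formulation, average ties."""
    y_true = np.asarray(y_true, dtype=float)
    y_score = np.asarray(y_score, dtype=float)
    n1 = int(y_true.sum())
    n0 = len(y_true) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC needs both outcome classes")
    ranks = rankdata(y_score)
    return float((ranks[y_true == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def roc_increment(scores: ScoreSet, cohort: pd.DataFrame) -> tuple[float, float]:
    """Apparent AUC of the covariate-only status model vs the model
    with the PRS added; returns ``(auc_base, auc_with_prs)``."""
    df = _model_frame(scores, cohort)
    data = df[["is_case", "score"] + STATUS_COVARIATES].dropna()
    if data["is_case"].nunique() < 2:
        raise ValueError("both outcome classes must be present")
    y = data["is_case"].to_numpy()
    aucs = []
    for cols in (STATUS_COVARIATES, ["score"] + STATUS_COVARIATES):
        X = sm.add_constant(data[cols], has_constant="add")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                fit = sm.Logit(data["is_case"], X).fit(disp=0, maxiter=200)
            except Exception:
                # separation breaks Newton; gradient ascent still yields a
                # monotone (rank-preserving) linear predictor for the AUC
                fit = sm.Logit(data["is_case"], X).fit(
                    disp=0, maxiter=500, method="bfgs"
                )
        aucs.append(mann_whitney_auc(y, fit.predict(X).to_numpy()))
    return aucs[0], aucs[1]


# -- age at onset (survival) ----------------------------------------------


def _survival_frame(df: pd.DataFrame, cases_only: bool) -> pd.DataFrame:
    if cases_only:
        df = df[df["is_case"] == 1.0]
    duration = df["age_at_onset"].where(
        df["is_case"] == 1.0, df["age_at_last_assessment"]
    )
    out = df.copy()
    out["duration"] = duration
    out["event"] = df["is_case"]
    if (out["duration"].dropna() <= 0).any():
        raise ValueError("non-positive event/censoring ages")
    return out


def _fit_cox(
    data: pd.DataFrame,
    predictor: str,
    trait: str,
    predictor_label: str,
) -> SurvivalResult:
    covs = [
        c
        for c in SURVIVAL_COVARIATES
        if c in data.columns and data[c].nunique(dropna=True) > 1
    ]  # constant covariates carry no information and break the fit
    frame = data[["duration", "event", predictor] + covs].dropna()
    n_events = int(frame["event"].sum())
    if n_events < 2:
        raise ValueError(f"need at least 2 events, got {n_events}")
    _check_predictor(frame[predictor], predictor_label)
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(frame, duration_col="duration", event_col="event")
    row = cph.summary.loc[predictor]
    formula = f"{trait} ~ {predictor_label} + " + " + ".join(SURVIVAL_COVARIATES)
    return SurvivalResult(
        hazard_beta=float(row["coef"]),
        p_value=float(row["p"]),
        ci_low=float(row["coef lower 95%"]),
        ci_high=float(row["coef upper 95%"]),
        n_used=len(frame),
        n_events=n_events,
        model_formula=formula,
    )


def aao_survival(
    scores: ScoreSet, cohort: pd.DataFrame, cases_only: bool = False
) -> SurvivalResult:
    """Cox proportional-hazards fit of age at onset on the PRS.

    Onset age is the event time for cases; controls are censored at
    their age at last assessment.  ``cases_only`` drops controls for
    the censoring-sensitivity analysis.
    """
    df = _survival_frame(_model_frame(scores, cohort), cases_only)
    return _fit_cox(df, "score", "age at onset", "PRS")


def kaplan_meier_curve(durations: pd.Series, events: pd.Series) -> pd.DataFrame:
    """Product-limit survival curve as an (age, survival) step table."""
    kmf = KaplanMeierFitter()
    kmf.fit(durations, events)
    sf = kmf.survival_function_
    return pd.DataFrame(
        {"age": sf.index.to_numpy(dtype=float), "survival": sf.iloc[:, 0].to_numpy()}
    )


def km_tertile_analysis(scores: ScoreSet, cohort: pd.DataFrame) -> SurvivalResult:
    """Kaplan-Meier curves per PRS tertile, log-rank test comparing
    the first and third tertiles, and the exponentiated Cox
    coefficient for T3 vs T1 (hazard-ratio scale) with the usual
    survival covariates."""
    df = _survival_frame(_model_frame(scores, cohort), cases_only=False)
    if "tertile" not in df.columns:
        raise ValueError("tertiles not assigned; call assign_tertiles first")
    curves: dict[str, pd.DataFrame] = {}
    for t in ("T1", "T2", "T3"):
        grp = df[df["tertile"] == t]
        if grp.empty:
            raise ValueError(f"empty tertile {t}")
        curves[t] = kaplan_meier_curve(grp["duration"], grp["event"])
    outer = df[df["tertile"].isin(["T1", "T3"])].copy()
    for t in ("T1", "T3"):
        if outer.loc[outer["tertile"] == t, "event"].sum() < 1:
            raise ValueError(f"no events in tertile {t}")
    if outer["event"].sum() == 0:
        raise ValueError("all subjects censored; log-rank undefined")
    lr = multivariate_logrank_test(
        outer["duration"], outer["tertile"], outer["event"]
    )
    outer["t3_vs_t1"] = (outer["tertile"] == "T3").astype(float)
    cox = _fit_cox(outer, "t3_vs_t1", "age at onset", "tertile T3 vs T1")
    return SurvivalResult(
        hazard_beta=cox.hazard_beta,
        p_value=cox.p_value,
        ci_low=cox.ci_low,
        ci_high=cox.ci_high,
        tertile_effect=float(np.exp(cox.hazard_beta)),
        logrank_statistic=float(lr.test_statistic),
        logrank_df=int(lr.degrees_of_freedom),
        logrank_p=float(lr.p_value),
        km_curves=curves,
        n_used=cox.n_used,
        n_events=cox.n_events,
        model_formula=cox.model_formula,
    )


# -- CSF biomarkers -------------------------------------------------------


def _analyte_frame(
    biomarkers: pd.DataFrame, cohort: pd.DataFrame, analyte: str
) -> pd.Series:
    if analyte not in set(biomarkers["analyte"]):
        raise ValueError(
            f"analyte {analyte!r} absent from biomarker table "
            f"(known analytes: {sorted(set(biomarkers['analyte']))})"
        )
    if "harmonized_level" not in biomarkers.columns:
        raise ValueError("biomarker table not harmonized; run harmonize() first")
    sub = biomarkers[biomarkers["analyte"] == analyte]
    return pd.Series(
        sub["harmonized_level"].to_numpy(), index=sub["sample_id"], name="level"
    )


def _fit_linear(
    df: pd.DataFrame,
    predictor: str,
    trait: str,
    predictor_label: str,
) -> AssociationResult:
    cols = [predictor] + [c for c in BIOMARKER_COVARIATES if c in df.columns]
    data = df[["level"] + cols].dropna()
    if len(data) < 10:
        raise ValueError(f"need at least 10 samples with {trait}, got {len(data)}")
    _check_predictor(data[predictor], predictor_label)
    X = sm.add_constant(data[cols], has_constant="add")
    fit = sm.OLS(data["level"], X).fit()
    ci = fit.conf_int().loc[predictor]
    formula = f"{trait} ~ {predictor_label} + " + " + ".join(BIOMARKER_COVARIATES)
    return AssociationResult(
        trait=trait,
        predictor=predictor_label,
        beta=float(fit.params[predictor]),
        ci_low=float(ci[0]),
        ci_high=float(ci[1]),
        p_value=float(fit.pvalues[predictor]),
        model_formula=formula,
        n_used=len(data),
    )


def biomarker_association(
    scores: ScoreSet,
    biomarkers: pd.DataFrame,
    cohort: pd.DataFrame,
    analyte: str,
) -> AssociationResult:
    """Linear model of the harmonized analyte level on the PRS,
    adjusted for age at lumbar puncture, sex, PC1 and PC2."""
    df = _model_frame(scores, cohort)
    level = _analyte_frame(biomarkers, cohort, analyte)
    df = df.join(level, how="inner")
    if "age_at_lp" not in df.columns:
        df["age_at_lp"] = np.nan
    return _fit_linear(df, "score", f"CSF {analyte}", "PRS")


# -- single-variant analyses ----------------------------------------------


def single_variant_tests(
    matrix: DosageMatrix,
    panel: ScoringPanel,
    cohort: pd.DataFrame,
    trait: str,
    biomarkers: pd.DataFrame | None = None,
) -> list[AssociationResult]:
    """Re-fit the trait model with each panel variant's dosage in
    place of the PRS.  One result per panel variant; monomorphic
    variants are flagged degenerate (``converged=False``) and skipped.
    Results carry no multiple-testing correction (nominal p-values).
    """
    if trait not in ("status", "onset") and trait not in ANALYTES:
        raise ValueError(f"unknown trait {trait!r}")
    validate_cohort(cohort)
    results: list[AssociationResult] = []
    for vid in panel.variant_ids:
        dosage = matrix.dosages[vid]
        fake_scores = ScoreSet(
            pd.DataFrame(
                {"score": dosage, "n_variants_used": dosage.notna().astype(int)}
            ),
            panel_id=vid,
        )
        if dosage.dropna().nunique() < 2:
            logger.warning("variant %s is monomorphic; skipped", vid)
            results.append(
                AssociationResult(
                    trait=trait,
                    predictor=vid,
                    beta=np.nan,
                    ci_low=np.nan,
                    ci_high=np.nan,
                    p_value=np.nan,
                    model_formula="degenerate (monomorphic)",
                    n_used=0,
                    converged=False,
                )
            )
            continue
        df = _model_frame(fake_scores, cohort)
        if trait == "status":
            res = _fit_logistic(df, "score", STATUS_COVARIATES, "PD status", vid)
        elif trait == "onset":
            surv = _fit_cox(_survival_frame(df, False), "score", "age at onset", vid)
            res = AssociationResult(
                trait="age at onset",
                predictor=vid,
                beta=surv.hazard_beta,
                ci_low=surv.ci_low,
                ci_high=surv.ci_high,
                p_value=surv.p_value,
                model_formula=surv.model_formula,
                n_used=surv.n_used,
            )
        else:
            if biomarkers is None:
                raise ValueError("biomarker table required for analyte traits")
            level = _analyte_frame(biomarkers, cohort, trait)
            df = df.join(level, how="inner")
            if "age_at_lp" not in df.columns:
                df["age_at_lp"] = np.nan
            res = _fit_linear(df, "score", f"CSF {trait}", vid)
        results.append(res)
    return results


# -- stratified reruns ----------------------------------------------------


def split_by_family_history(
    cohort: pd.DataFrame, stratum: str, keep_controls: bool = True
) -> pd.DataFrame:
    """Restrict cases to one family-history stratum (``yes``/``no``),
    keeping all controls unless ``keep_controls=False``."""
    cases = (cohort["status"] == "case") & (cohort["family_history"] == stratum)
    keep = cases | ((cohort["status"] == "control") if keep_controls else False)
    sub = cohort[keep]
    if (sub["status"] == "case").sum() == 0:
        raise ValueError(f"empty case stratum family_history={stratum!r}")
    return sub


def stratified_rerun(op, cohort: pd.DataFrame, stratum: str, *args, **kwargs):
    """Re-run any model op on the family-history-restricted cohort.

    ``op`` is called as ``op(*args, cohort=subset, **kwargs)``; the
    returned result is labelled with the stratum.
    """
    keep_controls = kwargs.pop("keep_controls", True)
    sub = split_by_family_history(cohort, stratum, keep_controls)

    def _restrict(obj):
        if isinstance(obj, ScoreSet):
            keep = obj.table.index.intersection(sub.index)
            return ScoreSet(obj.table.loc[keep].copy(), obj.panel_id)
        return obj

    args = tuple(_restrict(a) for a in args)
    kwargs = {k: _restrict(v) for k, v in kwargs.items()}
    result = op(*args, cohort=sub, **kwargs)
    for r in result if isinstance(result, list) else [result]:
        if hasattr(r, "stratum"):
            r.stratum = f"family_history={stratum}"
    return result


# -- demographics ---------------------------------------------------------


def summarize_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    """Demographics per (group, status): n, female n and percent
    (2 d.p.), mean ages, family-history n and percent."""
    if cohort.empty:
        return pd.DataFrame()
    validate_cohort(cohort)
    rows = []
    groups = [("combined", cohort)] + [
        (str(p), g) for p, g in cohort.groupby("platform", observed=True)
    ]
    for group, gdf in groups:
        for status, sdf in gdf.groupby("status", observed=True):
            n = len(sdf)
            n_f = int((sdf["sex"] == "female").sum())
            n_fh = int((sdf["family_history"] == "yes").sum())
            rows.append(
                {
                    "group": group,
                    "status": status,
                    "n": n,
                    "n_female": n_f,
                    "pct_female": round(100.0 * n_f / n, 2),
                    "mean_age_at_onset": sdf["age_at_onset"].mean(),
                    "mean_age_at_last_assessment": sdf[
                        "age_at_last_assessment"
                    ].mean(),
                    "mean_age_at_lp": (
                        sdf["age_at_lp"].mean() if "age_at_lp" in sdf else np.nan
                    ),
                    "n_family_history": n_fh,
                    "pct_family_history": round(100.0 * n_fh / n, 2),
                }
            )
    return pd.DataFrame(rows).set_index(["group", "status"])
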