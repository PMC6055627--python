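"""Linear mixed models for network-predicted cognitive decline.

One model per network measure x cognitive domain:

    domain_z ~ time + measure + measure:time + age + sex + education
               + total grey matter volume + scanner,  random: ~1 | subject

fit by REML.  The measure's main term is its association with baseline
cognition; the measure-by-time interaction is its association with annual
change.  Estimates are pooled over the multiply-imputed datasets with
Rubin's rules and corrected for multiple testing with a false-discovery-rate
step-up procedure (Benjamini-Yekutieli by default, Benjamini-Hochberg
available).

Network predictors are standardized (z across subjects) before entry so
coefficients are comparable across measures; this is recorded in the fit
metadata and can be disabled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import ConvergenceWarning

__all__ = [
    "ModelSpec",
    "LMMFit",
    "TermEstimate",
    "PooledEstimate",
    "fit_lmm",
    "pool_rubin",
    "fdr_adjust",
    "fit_pooled",
    "run_global_analysis",
    "run_local_analysis",
    "tabulate_global",
]

DEFAULT_COVARIATES = ("age", "sex", "education", "total_gm_vol_ml", "scanner")

BASIC_MEASURES = ("size", "degree", "connectivity_density")
HIGHER_ORDER_MEASURES = (
    "clustering",
    "path_length",
    "betweenness",
    "gamma",
    "lambda",
    "small_world",
)


@dataclass
class ModelSpec:
    """One network-measure x cognitive-domain model."""

    outcome: str
    predictor: str
    covariates: tuple[str, ...] = DEFAULT_COVARIATES
    extra_covariates: tuple[str, ...] = ()
    standardize_predictor: bool = True
    random_slope: bool = False


@dataclass
class TermEstimate:
    beta: float
    se: float


@dataclass
class LMMFit:
    """Per-imputation REML fit: every fixed term's estimate plus metadata."""

    terms: dict[str, TermEstimate]
    baseline: TermEstimate
    interaction: TermEstimate
    df_resid: float
    converged: bool
    n_obs: int
    n_subjects: int
    random_intercept_sd: float = float("nan")
    residual_sd: float = float("nan")


@dataclass
class PooledEstimate:
    """Rubin-pooled fixed effect: beta, SE, p, and later an FDR-adjusted p."""

    term: str
    beta: float
    se: float
    p: float
    df: float
    m: int
    p_fdr: float | None = None


def _standardized(values: pd.Series, by_subject: pd.Series) -> pd.Series:
    per_subject = values.groupby(by_subject).first()
    mu, sd = per_subject.mean(), per_subject.std(ddof=0)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("predictor has zero variance across subjects")
    return (values - mu) / sd


def fit_lmm(data: pd.DataFrame, spec: ModelSpec) -> LMMFit:
    """Fit one linear mixed model (REML, random subject intercept).

    Requires columns: the outcome, the predictor, ``time_years``,
    ``subject_id``, and the covariates.  Returns every fixed term's
    coefficient and SE; ``baseline`` aliases the predictor main term and
    ``interaction`` the predictor-by-time term.
    """
    needed = [spec.outcome, spec.predictor, "time_years", "subject_id"]
    needed += [c for c in spec.covariates + spec.extra_covariates]
    missing = [c for c in needed if c not in data.columns]
    if missing:
        raise ValueError(f"data lacks required columns: {missing}")
    df = data.dropna(subset=needed).copy()
    if df["subject_id"].nunique() < 3:
        raise ValueError("need at least 3 subjects with complete rows")

    pred_col = "pred_z"
    if spec.standardize_predictor:
        df[pred_col] = _standardized(df[spec.predictor], df["subject_id"])
    else:
        df[pred_col] = df[spec.predictor]

    covs = list(spec.covariates) + list(spec.extra_covariates)
    rhs = ["time_years", pred_col, f"time_years:{pred_col}"] + covs
    formula = f"Q('{spec.outcome}') ~ " + " + ".join(rhs)
    re_formula = "~time_years" if spec.random_slope else None

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        model = sm.MixedLM.from_formula(
            formula, groups="subject_id", re_formula=re_formula, data=df
        )
        result = model.fit(reml=True)

    terms = {
        name: TermEstimate(float(result.fe_params[name]), float(result.bse_fe[name]))
        for name in result.fe_params.index
    }
    re_var = float(np.asarray(result.cov_re)[0, 0])  # already in data units
    return LMMFit(
        terms=terms,
        baseline=terms[pred_col],
        interaction=terms[f"time_years:{pred_col}"],
        df_resid=float(len(df) - len(result.fe_params)),
        converged=bool(result.converged),
        n_obs=len(df),
        n_subjects=int(df["subject_id"].nunique()),
        random_intercept_sd=float(np.sqrt(max(re_var, 0.0))),
        residual_sd=float(np.sqrt(result.scale)),
    )


def pool_rubin(
    betas, ses, term: str = "", df_com: float | None = None
) -> PooledEstimate:
    """Combine per-imputation estimates with Rubin's rules.

    Pooled beta is the mean; total variance is the mean within-imputation
    variance plus (1 + 1/m) times the between-imputation variance.  Degrees
    of freedom use Rubin's formula with the Barnard-Rubin small-sample
    adjustment when a complete-data df is supplied; the p-value comes from
    the t reference.
    """
    betas = np.asarray(betas, dtype=float)
    ses = np.asarray(ses, dtype=float)
    if betas.shape != ses.shape or betas.ndim != 1:
        raise ValueError("betas and ses must be equal-length 1D sequences")
    m = len(betas)
    if m < 1:
        raise ValueError("need at least one imputation")
    if m == 1:
        warnings.warn("single imputation: pooled estimate is a passthrough")
        beta, se = float(betas[0]), float(ses[0])
        p = 2 * stats.norm.sf(abs(beta) / se) if se > 0 else float("nan")
        return PooledEstimate(term, beta, se, float(p), df=float("inf"), m=1)

    qbar = float(betas.mean())
    w = float((ses**2).mean())
    b = float(betas.var(ddof=1))
    t_var = w + (1 + 1 / m) * b
    se = float(np.sqrt(t_var))

    if b == 0 or t_var == 0:
        df = float("inf")
    else:
        r = (1 + 1 / m) * b / w if w > 0 else float("inf")
        if np.isfinite(r):
            with np.errstate(over="ignore"):
                # saturates to inf when the between-variance is negligible
                df = float((m - 1) * (1.0 + 1.0 / np.float64(r)) ** 2)
        else:
            df = float(m - 1)
        if df_com is not None and np.isfinite(df_com):
            lam = (1 + 1 / m) * b / t_var
            nu_obs = (df_com + 1) / (df_com + 3) * df_com * (1 - lam)
            df = 1.0 / (1.0 / df + 1.0 / nu_obs)
    p = 2 * stats.t.sf(abs(qbar) / se, df) if se > 0 else float("nan")
    return PooledEstimate(term, qbar, se, float(p), df=float(df), m=m)


def fdr_adjust(p_values, method: str = "by") -> np.ndarray:
    """Step-up FDR adjustment within one declared family of tests."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value family")
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    key = {"by": "fdr_by", "bh": "fdr_bh"}.get(method.lower())
    if key is None:
        raise ValueError(f"unknown FDR method '{method}' (use 'by' or 'bh')")
    return np.minimum(multipletests(p, method=key)[1], 1.0)


def fit_pooled(
    datasets: list[pd.DataFrame], spec: ModelSpec, max_failure_frac: float = 0.2
) -> dict[str, PooledEstimate]:
    """Fit the model on every imputed dataset and pool with Rubin's rules.

    Non-converged imputations are excluded with a warning as long as they
    stay under ``max_failure_frac`` of the total; beyond that the fit is
    rejected.
    """
    fits: list[LMMFit] = []
    failed = 0
    for ds in datasets:
        try:
            fit = fit_lmm(ds, spec)
        except (ValueError, np.linalg.LinAlgError):
            failed += 1
            continue
        if fit.converged:
            fits.append(fit)
        else:
            failed += 1
    if failed:
        if failed > max_failure_frac * len(datasets):
            raise RuntimeError(
                f"{failed}/{len(datasets)} imputations failed to converge for "
                f"{spec.predictor} -> {spec.outcome}"
            )
        warnings.warn(f"{failed}/{len(datasets)} imputations excluded (non-convergence)")
    df_com = float(np.median([f.df_resid for f in fits]))
    out = {}
    for key, getter in (("baseline", lambda f: f.baseline), ("interaction", lambda f: f.interaction)):
        est = [getter(f) for f in fits]
        out[key] = pool_rubin(
            [e.beta for e in est], [e.se for e in est],
            term=f"{spec.predictor}:{key}", df_com=df_com,
        )
    return out


def run_global_analysis(
    datasets: list[pd.DataFrame],
    measures: tuple[str, ...] = BASIC_MEASURES + HIGHER_ORDER_MEASURES,
    outcomes: tuple[str, ...] = ("attention", "memory", "executive", "language", "global_cognition"),
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    basic_measures: tuple[str, ...] = BASIC_MEASURES,
    fdr_method: str = "by",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Whole-brain covariate-laddered analysis over measures x domains.

    Basic network parameters (size, degree, density) are fitted first; for
    each domain, any basic parameter whose pooled baseline term is
    significant (p < alpha) is added as a covariate to that domain's
    higher-order models, since basic measures can influence higher-order
    parameters.  FDR is applied within the baseline family and within the
    annual-change family (all measures x domains).
    """
    present = [m for m in measures if m in datasets[0].columns]
    basics = [m for m in basic_measures if m in present]
    rows = []

    ladder: dict[str, list[str]] = {out: [] for out in outcomes}
    for measure in basics:
        for outcome in outcomes:
            pooled = fit_pooled(datasets, ModelSpec(outcome, measure, covariates))
            if pooled["baseline"].p < alpha:
                ladder[outcome].append(measure)
            rows += _result_rows(measure, outcome, pooled, extra=())

    for measure in present:
        if measure in basics:
            continue
        for outcome in outcomes:
            extra = tuple(b for b in ladder[outcome] if b != measure)
            pooled = fit_pooled(
                datasets, ModelSpec(outcome, measure, covariates, extra_covariates=extra)
            )
            rows += _result_rows(measure, outcome, pooled, extra=extra)

    result = pd.DataFrame(rows)
    for term in ("baseline", "annual_change"):
        mask = result["term"] == term
        result.loc[mask, "p_fdr"] = fdr_adjust(result.loc[mask, "p"], method=fdr_method)
    result["significant"] = result["p_fdr"] < alpha
    return result


def _result_rows(measure, outcome, pooled, extra):
    return [
        {
            "measure": measure,
            "outcome": outcome,
            "term": "baseline",
            "beta": pooled["baseline"].beta,
            "se": pooled["baseline"].se,
            "p": pooled["baseline"].p,
            "extra_covariates": ",".join(extra),
        },
        {
            "measure": measure,
            "outcome": outcome,
            "term": "annual_change",
            "beta": pooled["interaction"].beta,
            "se": pooled["interaction"].se,
            "p": pooled["interaction"].p,
            "extra_covariates": ",".join(extra),
        },
    ]


def run_local_analysis(
    datasets: list[pd.DataFrame],
    regional_predictors: pd.DataFrame,
    local_volumes: pd.DataFrame,
    outcome: str,
    measure_name: str = "regional_metric",
    term: str = "interaction",
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    extra_covariates: tuple[str, ...] = (),
    fdr_method: str = "by",
    alpha: float = 0.05,
    max_missing_frac: float = 0.1,
) -> pd.DataFrame:
    """Region-wise models, additionally adjusted for local grey matter volume.

    ``regional_predictors`` and ``local_volumes`` are subject-by-region
    tables (index = subject_id, one column per region).  Regions whose
    predictor is missing in more than ``max_missing_frac`` of subjects are
    dropped with a warning.  FDR runs across the retained regions; the
    tested term is the measure-by-time interaction by default.
    """
    if term not in ("interaction", "baseline"):
        raise ValueError("term must be 'interaction' or 'baseline'")
    if not regional_predictors.columns.equals(local_volumes.columns):
        raise ValueError("regional predictor and local volume tables must share regions")
    rows = []
    for region in regional_predictors.columns:
        pred = regional_predictors[region]
        if pred.isna().mean() > max_missing_frac:
            warnings.warn(f"region {region}: predictor missing in >10% of subjects; dropped")
            continue
        merged = []
        for ds in datasets:
            d = ds.copy()
            d[measure_name] = d["subject_id"].map(pred)
            d["local_gm_volume_ml"] = d["subject_id"].map(local_volumes[region])
            merged.append(d)
        spec = ModelSpec(
            outcome,
            measure_name,
            covariates,
            extra_covariates=tuple(extra_covariates) + ("local_gm_volume_ml",),
        )
        pooled = fit_pooled(merged, spec)[term]
        rows.append(
            {"region": region, "beta": pooled.beta, "se": pooled.se, "p": pooled.p}
        )
    if not rows:
        raise ValueError("no region could be analysed")
    result = pd.DataFrame(rows).set_index("region")
    result["p_fdr"] = fdr_adjust(result["p"], method=fdr_method)
    result["significant"] = result["p_fdr"] < alpha
    return result


def tabulate_global(result: pd.DataFrame, digits: int = 2) -> pd.DataFrame:
    """Reshape the long result table into the conventional wide layout:
    rows = network parameters, column pairs = baseline / annual change per
    domain, cells = "beta +/- SE" with a star for FDR significance."""

    def cell(row):
        star = "*" if row["significant"] else ""
        return f"{row['beta']:.{digits}f} ± {row['se']:.{digits}f}{star}"

    long = result.copy()
    long["cell"] = long.apply(cell, axis=1)
    wide = long.pivot(index="measure", columns=["outcome", "term"], values="cell")
    order = [m for m in BASIC_MEASURES + HIGHER_ORDER_MEASURES if m in wide.index]
    return wide.loc[order]
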