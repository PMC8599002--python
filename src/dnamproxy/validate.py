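"""Association battery for validating a projected episcore.

Implements the standard validation battery for a methylation-derived proxy of
a serum biomarker: Pearson correlations with the measured biomarker and with
estimated cell proportions; covariate-adjusted linear models against known
biomarker correlates (BMI, alcohol, deprivation); a proportional-odds ordinal
model for smoking; incremental R² of nested linear models; age trends with an
age × sex interaction; a general cognitive factor (first unrotated principal
component of the test scores) and its association with both measures; and
Benjamini–Hochberg FDR correction in a single family across all tests.

Continuous outcomes and exposures are standardized to SD 1 before model
fitting by default, so estimates are comparable across traits; binary columns
are left on their natural 0/1 coding.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from statsmodels.miscmodels.ordinal_model import OrderedModel
from statsmodels.stats.multitest import multipletests

from .pheno import log_transform

__all__ = [
    "AssociationResult",
    "ValidationReport",
    "BatteryConfig",
    "pearson_test",
    "fit_linear_assoc",
    "fit_ordinal_assoc",
    "incremental_r2",
    "fit_interaction_trend",
    "general_cognitive_factor",
    "bh_adjust",
    "run_battery",
]


class ValidationError(ValueError):
    pass


# ----------------------------------------------------------------------------
# result containers
# ----------------------------------------------------------------------------


@dataclass
class AssociationResult:
    outcome: str
    exposure: str
    model: str                  # "linear" | "ordinal-logistic" | "linear-interaction"
    estimate: float             # beta, or log-odds for the ordinal model
    se: float
    p: float
    n: int
    covariates: list[str] = field(default_factory=list)
    p_fdr: float | None = None
    converged: bool = True

    def __post_init__(self) -> None:
        if not (self.se > 0):
            raise ValidationError(
                f"{self.outcome}~{self.exposure}: SE must be positive"
            )
        if not (0.0 < self.p <= 1.0):
            raise ValidationError(
                f"{self.outcome}~{self.exposure}: p must be in (0, 1]"
            )


@dataclass
class ValidationReport:
    correlations: list[dict] = field(default_factory=list)
    associations: list[AssociationResult] = field(default_factory=list)
    incremental: list[dict] = field(default_factory=list)
    interactions: list[AssociationResult] = field(default_factory=list)

    def all_results(self) -> list[AssociationResult]:
        return list(self.associations) + list(self.interactions)

    def to_json(self, indent: int = 2) -> str:
        payload = {
            "correlations": self.correlations,
            "associations": [asdict(a) for a in self.associations],
            "incremental": self.incremental,
            "interactions": [asdict(a) for a in self.interactions],
        }
        return json.dumps(payload, indent=indent, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "ValidationReport":
        payload = json.loads(text)
        return cls(
            correlations=payload["correlations"],
            associations=[AssociationResult(**a) for a in payload["associations"]],
            incremental=payload["incremental"],
            interactions=[AssociationResult(**a) for a in payload["interactions"]],
        )


# ----------------------------------------------------------------------------
# elementary operations
# ----------------------------------------------------------------------------


def pearson_test(x, y) -> tuple[float, float, int]:
    """Product-moment correlation with a two-sided t-test p-value, on
    pairwise-complete observations."""
    xv = np.asarray(pd.Series(x), dtype=float)
    yv = np.asarray(pd.Series(y), dtype=float)
    if xv.size != yv.size:
        raise ValidationError("x and y lengths differ")
    ok = ~np.isnan(xv) & ~np.isnan(yv)
    xv, yv = xv[ok], yv[ok]
    n = xv.size
    if n < 3:
        raise ValidationError("need ≥ 3 complete pairs")
    if np.all(xv == xv[0]) or np.all(yv == yv[0]):
        raise ValidationError("constant input to correlation")
    res = scipy.stats.pearsonr(xv, yv)
    return float(res.statistic), float(res.pvalue), n


def _is_binary(v: np.ndarray) -> bool:
    vals = np.unique(v[~np.isnan(v)])
    return vals.size <= 2 and set(vals).issubset({0.0, 1.0})


def _zscore(v: np.ndarray) -> np.ndarray:
    sd = v.std(ddof=1)
    if sd == 0:
        raise ValidationError("cannot standardize a constant column")
    return (v - v.mean()) / sd


def _design(df: pd.DataFrame, cols: list[str]) -> np.ndarray:
    X = np.column_stack([np.ones(len(df))] + [df[c].to_numpy(float) for c in cols])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        collinear = []
        r_prev = 1
        for j, c in enumerate(cols):
            r_now = np.linalg.matrix_rank(X[:, : j + 2])
            if r_now == r_prev:
                collinear.append(c)
            r_prev = r_now
        raise ValidationError(f"rank-deficient design; collinear: {collinear}")
    return X


def _complete(df: pd.DataFrame) -> pd.DataFrame:
    out = df.dropna()
    if len(out) < df.shape[1] + 2:
        raise ValidationError("too few complete cases for the design")
    return out


def fit_linear_assoc(
    outcome,
    exposure,
    covariates=None,
    standardize: bool = True,
    outcome_name: str = "outcome",
    exposure_name: str = "exposure",
) -> AssociationResult:
    """OLS association of ``outcome`` on ``exposure`` adjusting for
    ``covariates``; reports the exposure estimate, SE and two-sided p.

    With ``standardize`` (default), non-binary outcome and exposure are
    scaled to SD 1 so the estimate is in SD units.
    """
    data = {"__y": pd.Series(outcome), "__x": pd.Series(exposure)}
    cov_names: list[str] = []
    if covariates is not None:
        cov_df = pd.DataFrame(covariates)
        for c in cov_df.columns:
            data[str(c)] = cov_df[c]
            cov_names.append(str(c))
    df = _complete(pd.DataFrame(data).astype(float))
    y = df["__y"].to_numpy()
    x = df["__x"].to_numpy()
    if standardize:
        if not _is_binary(y):
            y = _zscore(y)
        if not _is_binary(x):
            x = _zscore(x)
    df = df.assign(__y=y, __x=x)
    X = _design(df, ["__x"] + cov_names)
    res = sm.OLS(df["__y"].to_numpy(), X).fit()
    if res.df_resid < 1 or res.ssr <= 1e-12 * max(1.0, float(np.abs(y).max())) ** 2:
        raise ValidationError("degenerate fit: zero residual variance")
    return AssociationResult(
        outcome=outcome_name,
        exposure=exposure_name,
        model="linear",
        estimate=float(res.params[1]),
        se=float(res.bse[1]),
        p=float(res.pvalues[1]),
        n=len(df),
        covariates=cov_names,
    )


def fit_ordinal_assoc(
    outcome,
    exposure,
    covariates=None,
    standardize: bool = True,
    outcome_name: str = "outcome",
    exposure_name: str = "exposure",
) -> AssociationResult:
    """Proportional-odds (ordinal logistic) association.

    ``outcome`` must be an ordered categorical (or integer codes); every
    level must be observed.  The exposure log-odds, its SE from the observed
    information, and the Wald p-value are reported.  Non-convergence of the
    optimizer is flagged on the result rather than raising.
    """
    y = pd.Series(outcome)
    if not isinstance(y.dtype, pd.CategoricalDtype):
        codes = y.astype(float)
        y = pd.Series(
            pd.Categorical(codes, categories=sorted(codes.dropna().unique()),
                           ordered=True),
            index=y.index,
        )
    elif not y.cat.ordered:
        y = y.cat.as_ordered()

    data = {"__x": pd.Series(exposure).astype(float)}
    cov_names: list[str] = []
    if covariates is not None:
        cov_df = pd.DataFrame(covariates)
        for c in cov_df.columns:
            data[str(c)] = cov_df[c].astype(float)
            cov_names.append(str(c))
    X = pd.DataFrame(data)
    ok = y.notna() & X.notna().all(axis=1)
    y, X = y[ok], X[ok]
    counts = y.value_counts()
    empty = [str(lv) for lv in y.cat.categories if counts.get(lv, 0) == 0]
    if empty:
        raise ValidationError(f"ordinal outcome levels with zero count: {empty}")
    if len(y.cat.categories) < 2:
        raise ValidationError("ordinal outcome needs ≥ 2 levels")
    if standardize and not _is_binary(X["__x"].to_numpy()):
        X = X.assign(__x=_zscore(X["__x"].to_numpy()))

    model = OrderedModel(y, X, distr="logit")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(method="newton", maxiter=200, disp=False)
            converged = bool(res.mle_retvals.get("converged", True))
        except Exception:
            converged = False
        if not converged:
            res = model.fit(method="bfgs", maxiter=2000, gtol=1e-8, disp=False)
            converged = bool(res.mle_retvals.get("converged", True))
    j = list(X.columns).index("__x")
    return AssociationResult(
        outcome=outcome_name,
        exposure=exposure_name,
        model="ordinal-logistic",
        estimate=float(res.params.iloc[j]),
        se=float(res.bse.iloc[j]),
        p=float(res.pvalues.iloc[j]),
        n=len(y),
        covariates=cov_names,
        converged=converged,
    )


def incremental_r2(outcome, base_covariates, added_covariates):
    """R² of nested OLS models on the shared complete-case sample.

    Returns (R²_base, R²_full, ΔR²) where ΔR² = R²_full − R²_base, the
    variance uniquely attributable to the added covariates.
    """
    y = pd.Series(outcome).astype(float)
    base = pd.DataFrame(base_covariates).astype(float)
    added = pd.DataFrame(added_covariates).astype(float)
    base_cols = [f"__b{i}" for i in range(base.shape[1])]
    added_cols = [f"__a{i}" for i in range(added.shape[1])]
    base.columns, added.columns = base_cols, added_cols
    df = pd.concat([y.rename("__y"), base, added], axis=1)
    df = _complete(df)
    yv = df["__y"].to_numpy()
    Xb = _design(df, base_cols)
    Xf = _design(df, base_cols + added_cols)
    r2_base = float(sm.OLS(yv, Xb).fit().rsquared)
    r2_full = float(sm.OLS(yv, Xf).fit().rsquared)
    return r2_base, r2_full, r2_full - r2_base


def fit_interaction_trend(
    outcome, age, sex, outcome_name: str = "outcome"
) -> AssociationResult:
    """Age × sex interaction on an outcome: OLS with age (centered), sex and
    their product; reports the interaction term."""
    df = _complete(
        pd.DataFrame(
            {
                "__y": pd.Series(outcome),
                "age": pd.Series(age),
                "sex": pd.Series(sex),
            }
        ).astype(float)
    )
    age_c = df["age"].to_numpy() - df["age"].to_numpy().mean()
    sex_v = df["sex"].to_numpy()
    df = df.assign(age_c=age_c, inter=age_c * sex_v)
    X = _design(df, ["age_c", "sex", "inter"])
    res = sm.OLS(df["__y"].to_numpy(), X).fit()
    return AssociationResult(
        outcome=outcome_name,
        exposure="age:sex",
        model="linear-interaction",
        estimate=float(res.params[3]),
        se=float(res.bse[3]),
        p=float(res.pvalues[3]),
        n=len(df),
        covariates=["age", "sex"],
    )


def general_cognitive_factor(test_scores: pd.DataFrame):
    """First unrotated principal component of ≥3 cognitive test scores.

    Columns are standardized and the first eigenvector of their correlation
    matrix is taken, sign-oriented so loadings are positive where possible
    (majority-positive otherwise).  Returns (scores, loadings,
    variance_explained) with scores standardized to SD 1 on the
    complete-case samples.
    """
    df = pd.DataFrame(test_scores).astype(float)
    if df.shape[1] < 3:
        raise ValidationError("need ≥ 3 test score columns")
    df = df.dropna()
    if len(df) < df.shape[1] + 1:
        raise ValidationError("too few complete cases")
    Z = df.to_numpy()
    sds = Z.std(axis=0, ddof=1)
    if np.any(sds == 0):
        bad = df.columns[sds == 0].tolist()
        raise ValidationError(f"constant test columns: {bad}")
    Z = (Z - Z.mean(axis=0)) / sds
    C = np.corrcoef(Z, rowvar=False)
    eigvals, eigvecs = np.linalg.eigh(C)
    v = eigvecs[:, -1]
    lam1 = float(eigvals[-1])
    n_neg, n_pos = int((v < 0).sum()), int((v > 0).sum())
    if n_neg > n_pos or (n_neg == n_pos and v.sum() < 0):
        v = -v
    raw = Z @ v
    scores = pd.Series(raw / raw.std(ddof=1), index=df.index, name="g")
    loadings = pd.Series(v, index=df.columns, name="loading")
    return scores, loadings, lam1 / df.shape[1]


def bh_adjust(pvalues):
    """Benjamini–Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pd.Series(pvalues), dtype=float)
    if np.any(np.isnan(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValidationError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    _, adj, _, _ = multipletests(p, method="fdr_bh")
    return adj


# ----------------------------------------------------------------------------
# orchestration
# ----------------------------------------------------------------------------


@dataclass(frozen=True)
class BatteryConfig:
    """Column names and covariate sets for a battery run.

    ``serum_covariates`` adjust models of the measured biomarker;
    episcore models are further adjusted for the estimated cell proportions
    (and a batch/set indicator where supplied).  ``fdr_scope`` is "battery"
    (one BH family across all tests, the default) or "per-table".
    """

    serum_col: str = "serum_biomarker"
    age_col: str = "age"
    sex_col: str = "sex"
    smoking_col: str = "smoking"
    bmi_col: str = "bmi"
    alcohol_col: str = "alcohol_units"
    deprivation_col: str = "deprivation_rank"
    cognitive_cols: tuple[str, ...] = (
        "logical_memory",
        "digit_symbol",
        "verbal_fluency",
    )
    serum_covariates: tuple[str, ...] = ("age", "sex")
    standardize: bool = True
    fdr_scope: str = "battery"
    cell_covariates: tuple[str, ...] | None = None  # None → all reference types


def run_battery(
    phenotypes: pd.DataFrame,
    episcore: pd.Series,
    cell_proportions: pd.DataFrame | None = None,
    smoking_score: pd.Series | None = None,
    config: BatteryConfig | None = None,
) -> ValidationReport:
    """Run the full validation battery and return a structured report.

    Blocks: serum–episcore and episcore–cell correlations; the correlate grid
    (BMI, deprivation, log-alcohol linear; smoking proportional-odds) for
    both the serum measure and the episcore, each re-run adjusted for the
    methylation smoking score when one is supplied; incremental R² of cell
    proportions for both measures; age/sex trends with interaction; general
    cognitive factor associations; one BH family over every p-value.
    """
    cfg = config or BatteryConfig()
    ph = phenotypes

    required = [
        cfg.serum_col, cfg.age_col, cfg.sex_col, cfg.smoking_col,
        cfg.bmi_col, cfg.alcohol_col, cfg.deprivation_col,
        *cfg.cognitive_cols,
    ]
    missing = [c for c in required if c not in ph.columns]
    if missing:
        raise ValidationError(f"phenotype table missing columns: {missing}")

    episcore = episcore.reindex(ph.index)
    log_serum = log_transform(ph[cfg.serum_col].astype(float))
    log_alcohol = log_transform(ph[cfg.alcohol_col].astype(float), offset=1.0)
    age = ph[cfg.age_col].astype(float)
    sex = ph[cfg.sex_col].astype(float)
    smoking = ph[cfg.smoking_col]
    if isinstance(smoking.dtype, pd.CategoricalDtype):
        smoking = pd.Series(
            pd.Categorical(smoking, categories=smoking.cat.categories, ordered=True),
            index=ph.index,
        )

    if cell_proportions is not None:
        cells = cell_proportions.reindex(ph.index)
        cell_cols = (
            list(cfg.cell_covariates)
            if cfg.cell_covariates is not None
            else cells.columns.tolist()
        )
        cells = cells[cell_cols]
    else:
        cells = None

    def covs(base_extra: dict | None = None, with_cells: bool = False,
             with_smk: bool = False) -> pd.DataFrame:
        parts = {"age": age, "sex": sex}
        if base_extra:
            parts.update(base_extra)
        df = pd.DataFrame(parts, index=ph.index)
        if with_cells and cells is not None:
            # drop one cell type: fractions are compositional and would be
            # collinear with the intercept if all six entered
            df = pd.concat([df, cells.iloc[:, 1:]], axis=1)
        if with_smk and smoking_score is not None:
            df = pd.concat(
                [df, smoking_score.reindex(ph.index).rename("smoking_score")],
                axis=1,
            )
        return df

    report = ValidationReport()

    # -- correlation block ----------------------------------------------------
    def add_corr(x, y, name_x, name_y):
        r, p, n = pearson_test(x, y)
        report.correlations.append(
            {"x": name_x, "y": name_y, "r": r, "p": p, "r2": r * r, "n": n,
             "p_fdr": None}
        )

    add_corr(log_serum, episcore, "log_serum", "episcore")
    if cells is not None:
        for ct in cells.columns:
            add_corr(episcore, cells[ct], "episcore", f"cells:{ct}")

    # -- correlate grid (Table-2 style) ---------------------------------------
    linear_outcomes = {
        "bmi": ph[cfg.bmi_col].astype(float),
        "deprivation": ph[cfg.deprivation_col].astype(float),
        "log_alcohol": log_alcohol,
    }
    exposures = {"log_serum": (log_serum, False), "episcore": (episcore, True)}
    sens_passes = [False, True] if smoking_score is not None else [False]
    for smk_adj in sens_passes:
        tag = "+smkscore" if smk_adj else ""
        for exp_name, (exp_vals, with_cells) in exposures.items():
            C = covs(with_cells=with_cells, with_smk=smk_adj)
            for out_name, out_vals in linear_outcomes.items():
                report.associations.append(
                    fit_linear_assoc(
                        out_vals, exp_vals, C,
                        standardize=cfg.standardize,
                        outcome_name=out_name,
                        exposure_name=exp_name + tag,
                    )
                )
            report.associations.append(
                fit_ordinal_assoc(
                    smoking, exp_vals, C,
                    standardize=cfg.standardize,
                    outcome_name="smoking",
                    exposure_name=exp_name + tag,
                )
            )

    # -- incremental R² of cell proportions -----------------------------------
    if cells is not None:
        base = pd.DataFrame({"age": age, "sex": sex}, index=ph.index)
        for name, out_vals in (("log_serum", log_serum), ("episcore", episcore)):
            r2b, r2f, delta = incremental_r2(out_vals, base, cells.iloc[:, 1:])
            report.incremental.append(
                {
                    "outcome": name,
                    "base": ["age", "sex"],
                    "added": cells.columns[1:].tolist(),
                    "r2_base": r2b,
                    "r2_full": r2f,
                    "delta_r2": delta,
                }
            )

    # -- age/sex trends with interaction --------------------------------------
    for name, out_vals in (("log_serum", log_serum), ("episcore", episcore)):
        report.associations.append(
            fit_linear_assoc(
                out_vals, age, pd.DataFrame({"sex": sex}),
                standardize=cfg.standardize,
                outcome_name=name, exposure_name="age",
            )
        )
        report.associations.append(
            fit_linear_assoc(
                out_vals, sex, pd.DataFrame({"age": age}),
                standardize=cfg.standardize,
                outcome_name=name, exposure_name="sex",
            )
        )
        report.interactions.append(
            fit_interaction_trend(out_vals, age, sex, outcome_name=name)
        )

    # -- general cognitive factor ---------------------------------------------
    g, _loadings, _varexp = general_cognitive_factor(ph[list(cfg.cognitive_cols)])
    g = g.reindex(ph.index)
    for smk_adj in sens_passes:
        tag = "+smkscore" if smk_adj else ""
        for exp_name, (exp_vals, with_cells) in exposures.items():
            report.associations.append(
                fit_linear_assoc(
                    g, exp_vals, covs(with_cells=with_cells, with_smk=smk_adj),
                    standardize=cfg.standardize,
                    outcome_name="cognitive_g",
                    exposure_name=exp_name + tag,
                )
            )

    # -- FDR ------------------------------------------------------------------
    results = report.all_results()
    if cfg.fdr_scope == "battery":
        pvals = [c["p"] for c in report.correlations] + [a.p for a in results]
        adj = bh_adjust(pvals)
        k = len(report.correlations)
        for c, q in zip(report.correlations, adj[:k]):
            c["p_fdr"] = float(q)
        for a, q in zip(results, adj[k:]):
            a.p_fdr = float(q)
    else:  # per-table families
        adj = bh_adjust([c["p"] for c in report.correlations])
        for c, q in zip(report.correlations, adj):
            c["p_fdr"] = float(q)
        adj = bh_adjust([a.p for a in results])
        for a, q in zip(results, adj):
            a.p_fdr = float(q)
    return report
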