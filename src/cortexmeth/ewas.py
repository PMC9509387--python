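"""Per-probe association of methylation with neuropathology.

Models follow the cross-cortex design: methylation (beta, [0,1]) regressed
on one or more ordinal pathology measures with age, sex, batch, a residual
principal component, and two of the three estimated cell proportions as
fixed effects, and a donor random intercept when both cortical regions
contribute samples.  Effects are reported in percentage points of
methylation per unit of predictor (coefficients on the [0,1] scale x 100),
matching how methylation effect sizes are conventionally printed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2, t as t_dist

from .lmm import GroupedDesign, fit_random_intercept

DEFAULT_THRESHOLD = 9e-8  # experiment-wide significance for EPIC-scale EWAS


@dataclass
class ModelSpec:
    """Specification of one EWAS model."""
    predictors: tuple = ("braak_nft", "cerad", "thal")
    covariates: tuple = ("age", "sex", "batch")
    random_intercept: bool = True
    interaction_with_region: bool = False
    standardize_predictors: bool = False

    def __post_init__(self):
        self.predictors = tuple(self.predictors)
        self.covariates = tuple(self.covariates)
        if not self.predictors:
            raise ValueError("predictors must be nonempty")
        # the three cell proportions are collinear (they nearly sum to 1);
        # at most two may enter the model
        props = [c for c in self.covariates if c.startswith("prop_")]
        if len(props) > 2:
            raise ValueError("include at most two cell-proportion covariates")


def build_design(pheno: pd.DataFrame, spec: ModelSpec, include_region=False,
                 interaction=False) -> tuple[pd.DataFrame, list]:
    """Expand a phenotype table into a numeric design matrix.

    Returns the design (with intercept) and the list of predictor column
    names (including any interaction columns).  Categorical covariates
    (sex, batch) are dummy-coded with the first level as reference.
    """
    cols = {"Intercept": np.ones(len(pheno))}
    pred_cols = []
    for p in spec.predictors:
        x = pheno[p].astype(float)
        if spec.standardize_predictors:
            x = (x - x.mean()) / x.std(ddof=0)
        cols[p] = x.to_numpy()
        pred_cols.append(p)
    for c in spec.covariates:
        if c == "sex":
            cols["sex_M"] = (pheno["sex"].astype(str) == "M").astype(float).to_numpy()
        elif c == "batch":
            dummies = pd.get_dummies(pheno["batch"].astype("category"),
                                     prefix="batch", drop_first=True, dtype=float)
            for name in dummies.columns:
                cols[name] = dummies[name].to_numpy()
        else:
            cols[c] = pheno[c].astype(float).to_numpy()
    if include_region or interaction:
        regions = sorted(pheno["region"].unique())
        if len(regions) != 2:
            raise ValueError("both regions required")
        ind = (pheno["region"] == regions[1]).astype(float).to_numpy()
        cols[f"region_{regions[1]}"] = ind
        if interaction:
            for p in spec.predictors:
                name = f"{p}:region_{regions[1]}"
                cols[name] = cols[p] * ind
                pred_cols.append(name)
    X = pd.DataFrame(cols, index=pheno.index)
    return X, pred_cols


def _complete_cases(y: pd.Series, X: pd.DataFrame):
    ok = y.notna() & X.notna().all(axis=1)
    return y[ok], X[ok]


def _report_scale(fit, names, n_donors):
    """Coefficient table with effects/SEs rescaled to percentage points."""
    return pd.DataFrame({
        "effect": fit.beta * 100.0,
        "se": fit.se * 100.0,
        "statistic": fit.statistic,
        "p_value": fit.p_value,
    }, index=names).assign(n_samples=fit.n_obs, n_donors=n_donors,
                           ols_fallback=fit.ols_fallback)


def fit_site_lmm(y: pd.Series, pheno: pd.DataFrame, spec: ModelSpec):
    """Fit the mixed (or plain OLS) model for one probe.

    Returns a per-coefficient table (effect in percentage points, SE,
    Wald statistic, p).  Raises ``ValueError("zero variance")`` for a
    constant response; callers running many probes record the skip.
    """
    X, _ = build_design(pheno, spec)
    y, X = _complete_cases(y, X)
    donors = pheno.loc[y.index, "donor_id"]
    if spec.random_intercept and donors.duplicated().any():
        fit = fit_random_intercept(y.to_numpy(), X.to_numpy(), donors.to_numpy())
    else:
        fit = _ols_fit(y.to_numpy(), X.to_numpy())
    return _report_scale(fit, list(X.columns), donors.nunique())


def _ols_fit(y, X):
    from .lmm import LMMFit
    n, p = X.shape
    G = X.T @ X
    b = np.linalg.lstsq(X, y, rcond=None)[0]
    rss = float(np.sum((y - X @ b) ** 2))
    sigma2 = rss / (n - p)
    se = np.sqrt(np.maximum(np.diag(np.linalg.pinv(G)) * sigma2, 0.0))
    stat = np.divide(b, se, out=np.full_like(b, np.nan), where=se > 0)
    pvals = 2 * t_dist.sf(np.abs(stat), n - p)
    return LMMFit(beta=b, se=se, statistic=stat, p_value=pvals,
                  sigma2_e=rss / n, sigma2_u=0.0,
                  llf=-0.5 * (n * (np.log(rss / n) + np.log(2 * np.pi)) + n),
                  ols_fallback=True, n_obs=n, n_groups=n)


def joint_pathology_test(y: pd.Series, pheno: pd.DataFrame, spec: ModelSpec):
    """Likelihood-ratio test of all predictors jointly.

    Full and null models (the null drops every predictor) are both fit by
    maximum likelihood; the statistic is referred to chi-square with one
    degree of freedom per predictor.
    """
    full_X, pred_cols = build_design(pheno, spec)
    y2, full_X = _complete_cases(y, full_X)
    null_X = full_X.drop(columns=pred_cols)
    donors = pheno.loc[y2.index, "donor_id"].to_numpy()
    df = len(pred_cols)
    if spec.random_intercept and pd.Series(donors).duplicated().any():
        f_full = fit_random_intercept(y2.to_numpy(), full_X.to_numpy(), donors)
        f_null = fit_random_intercept(y2.to_numpy(), null_X.to_numpy(), donors)
    else:
        f_full = _ols_fit(y2.to_numpy(), full_X.to_numpy())
        f_null = _ols_fit(y2.to_numpy(), null_X.to_numpy())
    stat = max(2.0 * (f_full.llf - f_null.llf), 0.0)
    p = float(chi2.sf(stat, df)) if df > 0 else 1.0
    if df == 0:
        stat = 0.0
    return stat, df, p, f_full


def run_ewas(beta: pd.DataFrame, pheno: pd.DataFrame, spec: ModelSpec,
             threshold=DEFAULT_THRESHOLD, joint=None):
    """Apply the model at every probe.

    With multiple predictors (``joint`` defaults to True then) each probe
    gets the joint likelihood-ratio p; the reported effect/SE are the
    first predictor's Wald row from the full model.  With one predictor
    the Wald test of that coefficient is reported.  Probes whose fit
    fails are recorded with a flag and the run continues.  Rows are
    ordered by p then probe ID; returns ``(table, significant_ids)``.
    """
    if not beta.columns.equals(pheno.index):
        beta = beta.loc[:, pheno.index]
    if joint is None:
        joint = len(spec.predictors) > 1
    X_all, pred_cols = build_design(pheno, spec)
    cc = X_all.notna().all(axis=1)
    X_all, pheno_cc = X_all[cc], pheno[cc]
    donors = pheno_cc["donor_id"]
    use_lmm = spec.random_intercept and donors.duplicated().any()
    no_nan = not beta[pheno_cc.index].isna().any().any()

    # reusable group structure when every probe sees the same samples
    design_full = design_null = None
    if use_lmm and no_nan:
        design_full = GroupedDesign(X_all.to_numpy(), donors.to_numpy())
        if joint:
            design_null = GroupedDesign(
                X_all.drop(columns=pred_cols).to_numpy(), donors.to_numpy())

    rows = []
    first = spec.predictors[0]
    j_first = list(X_all.columns).index(first)
    for probe, yrow in beta[pheno_cc.index].iterrows():
        try:
            y = yrow.astype(float)
            if no_nan and use_lmm:
                yv = y.to_numpy()
                if np.var(yv) == 0:
                    raise ValueError("zero variance")
                f_full = fit_random_intercept(yv, design=design_full)
                if joint:
                    f_null = fit_random_intercept(yv, design=design_null)
                    stat = max(2.0 * (f_full.llf - f_null.llf), 0.0)
                    p = float(chi2.sf(stat, len(pred_cols)))
                else:
                    stat = float(f_full.statistic[j_first])
                    p = float(f_full.p_value[j_first])
            else:
                if joint:
                    stat, _, p, f_full = joint_pathology_test(y, pheno_cc, spec)
                else:
                    tab = fit_site_lmm(y, pheno_cc, spec)
                    stat = float(tab.loc[first, "statistic"])
                    p = float(tab.loc[first, "p_value"])
                    f_full = None
            if f_full is not None:
                eff = float(f_full.beta[j_first]) * 100.0
                se = float(f_full.se[j_first]) * 100.0
                n_obs, fallback = f_full.n_obs, f_full.ols_fallback
            else:
                eff, se = float(tab.loc[first, "effect"]), float(tab.loc[first, "se"])
                n_obs, fallback = int(tab["n_samples"].iloc[0]), bool(tab["ols_fallback"].iloc[0])
            rows.append((probe, eff, se, stat, p, n_obs, donors.nunique(),
                         "ols_fallback" if fallback else ""))
        except ValueError as exc:
            rows.append((probe, np.nan, np.nan, np.nan, np.nan, 0,
                         donors.nunique(), f"skipped: {exc}"))
    label = ("joint(" + "+".join(spec.predictors) + ")") if joint else first
    table = pd.DataFrame(rows, columns=["probe_id", "effect", "se", "statistic",
                                        "p_value", "n_samples", "n_donors",
                                        "flag"]).set_index("probe_id")
    table["model_label"] = label
    table = table.sort_values(["p_value", "probe_id"],
                              na_position="last",
                              kind="mergesort")
    significant = list(table.index[table["p_value"] < threshold])
    return table, significant


def region_interaction_test(y: pd.Series, pheno: pd.DataFrame, spec: ModelSpec):
    """Wald test of the predictor x region interaction.

    The model adds a region main effect and, per predictor, a
    predictor-by-region term to the mixed model; requires both regions
    with matched donors.  Returns the interaction rows of the coefficient
    table (single row for a single-predictor spec)."""
    if pheno["region"].nunique() < 2:
        raise ValueError("both regions required")
    both = pheno.groupby("donor_id")["region"].nunique()
    if (both == 2).sum() < 10:
        raise ValueError("need >= 10 donors observed in both regions")
    X, pred_cols = build_design(pheno, spec, include_region=True, interaction=True)
    y2, X2 = _complete_cases(y, X)
    donors = pheno.loc[y2.index, "donor_id"]
    fit = fit_random_intercept(y2.to_numpy(), X2.to_numpy(), donors.to_numpy())
    tab = _report_scale(fit, list(X2.columns), donors.nunique())
    inter = [c for c in pred_cols if ":region_" in c]
    return tab.loc[inter]


def vectorized_ols(Y: np.ndarray, X: np.ndarray):
    """OLS of many responses (rows of ``Y``) on a shared design.

    Returns (beta, se, t, p) with the unbiased residual variance and
    Student-t p-values, identical to fitting each response separately.
    """
    n, p = X.shape
    G = X.T @ X
    Ginv = np.linalg.pinv(G)
    B = Y @ X @ Ginv.T                       # probes x p
    resid = Y - B @ X.T
    rss = np.sum(resid ** 2, axis=1)
    sigma2 = rss / (n - p)
    se = np.sqrt(np.outer(sigma2, np.diag(Ginv)))
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = B / se
    pvals = 2 * t_dist.sf(np.abs(tstat), n - p)
    return B, se, tstat, pvals


def per_region_ewas(beta: pd.DataFrame, pheno: pd.DataFrame, region,
                    spec: ModelSpec, threshold=DEFAULT_THRESHOLD):
    """Single-region EWAS by ordinary least squares (one sample per donor).

    Equivalent to the mixed model's OLS path; vectorized across probes
    because every probe shares the design matrix.
    """
    sub = pheno[pheno["region"] == region]
    if len(sub) == 0:
        raise ValueError(f"no samples in region {region}")
    ospec = ModelSpec(predictors=spec.predictors, covariates=spec.covariates,
                      random_intercept=False,
                      standardize_predictors=spec.standardize_predictors)
    X, pred_cols = build_design(sub, ospec)
    cc = X.notna().all(axis=1)
    X, sub = X[cc], sub[cc]
    first = pred_cols[0]
    j = list(X.columns).index(first)
    Y = beta[sub.index]

    rows = []
    good = Y.notna().all(axis=1) & (Y.std(axis=1) > 0)
    if good.any():
        B, se, tstat, pvals = vectorized_ols(Y[good].to_numpy(dtype=float),
                                             X.to_numpy(dtype=float))
        for i, probe in enumerate(Y.index[good]):
            rows.append((probe, B[i, j] * 100, se[i, j] * 100,
                         tstat[i, j], pvals[i, j], len(sub), ""))
    for probe in Y.index[~good]:
        y = Y.loc[probe].dropna().astype(float)
        if y.var() == 0 or len(y) <= X.shape[1]:
            rows.append((probe, np.nan, np.nan, np.nan, np.nan, len(y),
                         "skipped: zero variance"))
            continue
        fit = _ols_fit(y.to_numpy(), X.loc[y.index].to_numpy(dtype=float))
        rows.append((probe, fit.beta[j] * 100, fit.se[j] * 100,
                     fit.statistic[j], fit.p_value[j], fit.n_obs, ""))
    table = pd.DataFrame(rows, columns=["probe_id", "effect", "se", "statistic",
                                        "p_value", "n_samples", "flag"]
                         ).set_index("probe_id")
    table["n_donors"] = table["n_samples"]
    table["model_label"] = f"{first}|{region}"
    return table.sort_values(["p_value", "probe_id"], na_position="last",
                             kind="mergesort")


def proportions_vs_pathology(proportions: pd.DataFrame, pheno: pd.DataFrame,
                             region=None,
                             measures=("braak_nft", "cerad", "thal"),
                             alpha=0.05, n_tests=6):
    """Regress each cell proportion on each pathology measure.

    Linear models with age and sex covariates, per region; slopes are in
    percentage points of proportion per unit of the measure.  Significance
    is Bonferroni-controlled at ``alpha / n_tests`` (default 0.05/6,
    three cell types x two regions per measure).
    """
    pheno = pheno.loc[proportions.index.intersection(pheno.index)]
    props = proportions.loc[pheno.index]
    if region is not None:
        keep = pheno["region"] == region
        pheno, props = pheno[keep], props[keep]
    rows = []
    cutoff = alpha / n_tests
    for measure in measures:
        sub = pheno[[measure, "age", "sex"]].dropna()
        X = np.column_stack([
            np.ones(len(sub)), sub[measure].astype(float),
            sub["age"].astype(float),
            (sub["sex"].astype(str) == "M").astype(float)])
        for ct in props.columns:
            y = props.loc[sub.index, ct].to_numpy(dtype=float) * 100.0
            fit = _ols_fit(y, X)
            rows.append((ct, measure, fit.beta[1], fit.se[1], fit.p_value[1],
                         fit.p_value[1] < cutoff))
    return pd.DataFrame(rows, columns=["celltype", "measure", "effect", "se",
                                       "p_value", "bonferroni_significant"])
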