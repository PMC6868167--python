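"""Follow-up single-SNP association models for the pleiotropy analysis.

Tests whether the dosage at one SNP (0/1/2 copies of the effect allele) is
associated with dichotomous and ordinal chronic-pain and depression
phenotypes, adjusting for age and sex, with optional additional adjustment
for the other phenotype to probe mediated (vertical) versus biological
(horizontal) pleiotropy.

Models: maximum-likelihood logistic regression for the dichotomous outcomes
and a proportional-odds (cumulative logit) model for the ordinal ones, with
a single slope per predictor across category thresholds.  p-values for both
come from the normal approximation to beta/SE.  Variance explained by
genotype is summarised with McFadden's pseudo-R², reported both as the full
model's R² versus the intercept-only model and as the increment over the
covariates-only (age + sex) model.  Small families of follow-up p-values are
FDR-adjusted with the Benjamini–Hochberg step-up; the family is always the
explicit set of genotype p-values passed in, never an implicit one.
Analyses are complete-case: rows with missing values are dropped listwise
per model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.miscmodels.ordinal_model import OrderedModel
from statsmodels.stats.multitest import multipletests

__all__ = [
    "FitResult",
    "fit_logistic",
    "fit_ordinal",
    "mcfadden_r2",
    "fdr_adjust",
    "attenuation_compare",
    "run_model_family",
]


@dataclass(frozen=True)
class FitResult:
    """Genotype term from one fitted model (beta on the log-odds scale)."""

    beta: float
    se: float
    or_: float
    p: float
    loglik: float
    loglik_null: float
    n: int
    converged: bool
    model: str

    @property
    def ci95(self) -> tuple[float, float]:
        return (self.beta - 1.96 * self.se, self.beta + 1.96 * self.se)


def _design(dosage, covariates: pd.DataFrame | None) -> pd.DataFrame:
    X = pd.DataFrame({"dosage": np.asarray(dosage, dtype=float)})
    if covariates is not None:
        cov = pd.DataFrame(covariates).reset_index(drop=True)
        for c in cov.columns:
            X[c] = cov[c].to_numpy(dtype=float)
    return X


def fit_logistic(outcome, dosage, covariates: pd.DataFrame | None = None) -> FitResult:
    """Logistic regression of a binary outcome on dosage (+ covariates).

    Returns the genotype coefficient with its Wald SE, odds ratio and
    two-sided normal p, plus the model and intercept-only log-likelihoods.
    Raises on non-convergence or (quasi-)separation.
    """
    y = np.asarray(outcome, dtype=float)
    classes = np.unique(y)
    if not np.isin(classes, (0.0, 1.0)).all() or classes.size < 2:
        raise ValueError("outcome must be binary with both classes present")
    X = sm.add_constant(_design(dosage, covariates), has_constant="add")
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("design matrix is rank deficient (constant predictor?)")
    res = sm.Logit(y, X).fit(disp=0, maxiter=200)
    if not res.mle_retvals.get("converged", False):
        raise RuntimeError(f"logistic fit did not converge: {res.mle_retvals}")
    beta = float(res.params["dosage"])
    se = float(res.bse["dosage"])
    if not np.isfinite(se) or se > 100:
        raise RuntimeError("unstable logistic fit (separation suspected): "
                           f"SE(dosage) = {se}")
    return FitResult(
        beta=beta,
        se=se,
        or_=float(np.exp(beta)),
        p=float(2 * stats.norm.sf(abs(beta / se))),
        loglik=float(res.llf),
        loglik_null=float(res.llnull),
        n=int(res.nobs),
        converged=True,
        model="logistic",
    )


def fit_ordinal(outcome, dosage, covariates: pd.DataFrame | None = None) -> FitResult:
    """Proportional-odds (cumulative logit) regression of an ordinal outcome.

    One slope per predictor across all thresholds; the genotype p-value is
    taken from the normal approximation to beta/SE.  Levels with no
    observations are collapsed away by construction (the model is fitted on
    the observed ordered categories).
    """
    y = pd.Series(np.asarray(outcome)).astype(int)
    if y.nunique() < 2:
        raise ValueError("ordinal outcome must have at least 2 observed levels")
    X = _design(dosage, covariates)
    if np.asarray(dosage, dtype=float).std() == 0:
        raise ValueError("dosage has zero variance")
    # standardise the nuisance covariates (not the dosage, whose scale the
    # reported beta lives on) for optimiser conditioning; the dosage slope,
    # its SE and the log-likelihood are invariant to this reparametrisation
    for c in X.columns:
        if c != "dosage" and X[c].std() > 0:
            X[c] = (X[c] - X[c].mean()) / X[c].std()
    ycat = pd.Categorical(y, categories=sorted(y.unique()), ordered=True)
    mod = OrderedModel(ycat, X, distr="logit")
    res = mod.fit(method="bfgs", maxiter=500, disp=0, gtol=1e-8)
    if not res.mle_retvals.get("converged", True):
        raise RuntimeError(f"ordinal fit did not converge: {res.mle_retvals}")
    beta = float(res.params["dosage"])
    se = float(res.bse["dosage"])
    null_llf = _ordinal_null_loglik(ycat)
    return FitResult(
        beta=beta,
        se=se,
        or_=float(np.exp(beta)),
        p=float(2 * stats.norm.sf(abs(beta / se))),
        loglik=float(res.llf),
        loglik_null=null_llf,
        n=int(res.nobs),
        converged=True,
        model="ordinal",
    )


def _ordinal_null_loglik(ycat: pd.Categorical) -> float:
    # intercepts-only cumulative-logit likelihood = multinomial at observed freqs
    counts = pd.Series(ycat).value_counts().to_numpy(dtype=float)
    probs = counts / counts.sum()
    return float((counts * np.log(probs)).sum())


def mcfadden_r2(full_loglik: float, reduced_loglik: float, null_loglik: float) -> dict:
    """McFadden pseudo-R² of the genotype term.

    ``overall`` is 1 - full/null against the intercept-only model;
    ``increment`` is the gain attributable to genotype beyond the
    covariates-only (reduced) model: (1 - full/null) - (1 - reduced/null).
    Both are returned because "adjusting for covariates" is naturally read
    as the increment while the raw overall value is often quoted too.
    """
    if null_loglik == 0:
        raise ValueError("null log-likelihood of 0: degenerate outcome")
    overall = 1.0 - full_loglik / null_loglik
    reduced_r2 = 1.0 - reduced_loglik / null_loglik
    return {"overall": overall, "increment": overall - reduced_r2}


def fdr_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if not np.all((p > 0) & (p <= 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def attenuation_compare(
    outcome,
    dosage,
    covariates: pd.DataFrame,
    adjuster_phenotype,
    alpha: float = 0.05,
) -> dict:
    """Compare the genotype effect with and without another phenotype as adjuster.

    Fits the logistic outcome model on dosage + covariates, then again adding
    ``adjuster_phenotype``; reports both genotype betas and p-values and a
    verdict: "attenuated" if genotype was significant (p <= alpha) without
    the adjuster but not with it, else "not_attenuated".
    """
    y = np.asarray(outcome, dtype=float)
    adj = np.asarray(adjuster_phenotype, dtype=float)
    if np.array_equal(y, adj):
        raise ValueError("adjuster phenotype is identical to the outcome")
    base = fit_logistic(y, dosage, covariates)
    cov_adj = pd.DataFrame(covariates).reset_index(drop=True).copy()
    cov_adj["adjuster"] = adj
    adjusted = fit_logistic(y, dosage, cov_adj)
    verdict = (
        "attenuated"
        if base.p <= alpha and adjusted.p > alpha
        else "not_attenuated"
    )
    return {
        "beta_unadjusted_model": base.beta,
        "p_unadjusted_model": base.p,
        "beta_adjusted_model": adjusted.beta,
        "p_adjusted_model": adjusted.p,
        "verdict": verdict,
    }


_MODEL_KINDS = {"logistic", "ordinal"}


def run_model_family(
    cohort: pd.DataFrame,
    models: list[tuple[str, str, str]],
    dosage_col: str = "dosage",
    covariate_cols: tuple[str, ...] = ("age", "sex"),
) -> pd.DataFrame:
    """Run a named family of models and BH-adjust their genotype p-values.

    ``models`` is a list of (label, outcome_column, kind) with kind
    "logistic" or "ordinal".  Complete cases are taken per model.  Returns a
    one-row-per-model table: model, n, beta, SE, OR, p, fdr_p.
    """
    rows = []
    for label, col, kind in models:
        if kind not in _MODEL_KINDS:
            raise ValueError(f"unknown model kind {kind!r}")
        cols = [col, dosage_col, *covariate_cols]
        data = cohort[cols].dropna()
        fit_fn = fit_logistic if kind == "logistic" else fit_ordinal
        fit = fit_fn(data[col], data[dosage_col], data[list(covariate_cols)])
        rows.append((label, fit.n, fit.beta, fit.se, fit.or_, fit.p))
    out = pd.DataFrame(rows, columns=["model", "n", "beta", "SE", "OR", "p"])
    out["fdr_p"] = fdr_adjust(out["p"])
    return out
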