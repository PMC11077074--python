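"""Covariate-adjusted genotype–phenotype association.

Two related screens over clinical code tables:

* an overrepresentation screen of codes between variant-positive and
  variant-negative donors, via logistic regression with gender, inferred
  ancestry and age as covariates, reporting OR = exp(β) with Bonferroni
  correction over the tested codes; and
* a PheWAS-lite over a phecode matrix under a dominant (binary genotype,
  logistic) or additive (allele count, linear) disease model, adjusted for
  age, sex at birth and the first five ancestry principal components.

Codes enter a screen only with at least ``min_total`` instances overall and
at least ``min_in_experimental`` instances among carriers.  Per-code
p-values are Wald tests on the genotype coefficient.  Perfect separation is
flagged rather than penalised, so small-sample estimates keep their
maximum-likelihood meaning (or lack of one).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning

__all__ = [
    "AssociationResult",
    "filter_codes",
    "fit_code_association",
    "phewas",
    "pivot_phenotypes",
]


@dataclass
class AssociationResult:
    code: str
    model: str
    beta: float
    odds_ratio: float
    p_value: float
    p_bonferroni: float
    n_cases: int
    n_total: int
    warning: str = ""


def pivot_phenotypes(phenotypes: pd.DataFrame, individuals) -> pd.DataFrame:
    """Long (individual, code, present) table → boolean code matrix."""
    mat = (
        phenotypes[phenotypes["present"]]
        .assign(value=True)
        .pivot_table(index="individual_id", columns="code", values="value",
                     aggfunc="any", fill_value=False)
    )
    return mat.reindex(list(individuals), fill_value=False).astype(bool)


def filter_codes(
    code_matrix: pd.DataFrame,
    experimental: np.ndarray,
    min_total: int = 20,
    min_in_experimental: int = 1,
) -> list[str]:
    """Codes with ≥ ``min_total`` instances, ≥ ``min_in_experimental`` of
    them in the experimental (carrier) group.  Both bounds are inclusive."""
    experimental = np.asarray(experimental, dtype=bool)
    totals = code_matrix.sum(axis=0)
    in_exp = code_matrix.loc[experimental].sum(axis=0)
    keep = (totals >= min_total) & (in_exp >= min_in_experimental)
    return list(code_matrix.columns[keep])


def _design(covariates: pd.DataFrame | None, n: int) -> tuple[np.ndarray, list[str], list[str]]:
    """Numeric design matrix from a covariate frame; drops degenerate columns.

    Categorical columns (sex, ancestry) are dummy-coded; constant or
    collinear columns are dropped with a warning.
    """
    if covariates is None or covariates.empty:
        return np.empty((n, 0)), [], []
    numeric = pd.get_dummies(covariates, drop_first=True).astype(float)
    dropped = []
    keep = []
    for col in numeric.columns:
        if numeric[col].nunique() <= 1:
            dropped.append(col)
        else:
            keep.append(col)
    X = numeric[keep].to_numpy()
    # rank check against accumulated columns
    final_cols, final = [], []
    base = np.ones((n, 1))
    for j, col in enumerate(keep):
        trial = np.column_stack(final + [X[:, j], base])
        if np.linalg.matrix_rank(trial) == trial.shape[1]:
            final.append(X[:, j])
            final_cols.append(col)
        else:
            dropped.append(col)
    if dropped:
        warnings.warn(f"dropped degenerate/collinear covariates: {dropped}")
    return (np.column_stack(final) if final else np.empty((n, 0))), final_cols, dropped


def fit_code_association(
    outcome: np.ndarray,
    genotype: np.ndarray,
    covariates: pd.DataFrame | None = None,
    code: str = "",
    model: str = "dominant_logistic",
    n_tests: int = 1,
) -> AssociationResult:
    """Fit one code's association and Wald-test the genotype coefficient.

    ``dominant_logistic`` fits a logistic model on a binary genotype;
    ``additive_linear`` an ordinary least-squares fit on allele count (the
    conventional fast PheWAS configuration, even for binary outcomes).
    Bonferroni uses ``n_tests``.  Raises on a degenerate design (constant
    genotype, or no cases/controls for the logistic model).
    """
    y = np.asarray(outcome, dtype=float)
    g = np.asarray(genotype, dtype=float)
    n = len(y)
    if np.all(g == g[0]):
        raise ValueError("genotype column is constant; nothing to fit")
    if model == "dominant_logistic" and (y.sum() == 0 or y.sum() == n):
        raise ValueError("logistic fit needs at least one case and one control")
    Xc, _, dropped = _design(covariates, n)
    X = np.column_stack([np.ones(n), g] + ([Xc] if Xc.size else []))

    warning = "; ".join(f"dropped {c}" for c in dropped)
    if model == "additive_linear":
        fit = sm.OLS(y, X).fit()
        beta = fit.params[1]
        p = fit.pvalues[1]
        oratio = float("nan")
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            try:
                fit = sm.Logit(y, X).fit(disp=0, maxiter=100, tol=1e-8)
                converged = fit.mle_retvals.get("converged", True)
            except (PerfectSeparationError, PerfectSeparationWarning, np.linalg.LinAlgError):
                fit, converged = None, False
        if fit is None or not converged or abs(fit.params[1]) > 15:
            warning = (warning + "; " if warning else "") + "perfect separation"
            beta = float("nan") if fit is None else float(fit.params[1])
            return AssociationResult(
                code, model, beta, float("nan"), float("nan"), float("nan"),
                int(y.sum()), n, warning,
            )
        beta = fit.params[1]
        p = fit.pvalues[1]
        oratio = float(np.exp(beta))
    return AssociationResult(
        code, model, float(beta), oratio, float(p),
        float(min(1.0, p * n_tests)), int(y.sum()), n, warning,
    )


def phewas(
    code_matrix: pd.DataFrame,
    genotype: np.ndarray,
    covariates: pd.DataFrame | None = None,
    model: str = "dominant",
    min_total: int = 20,
    min_in_experimental: int = 1,
) -> pd.DataFrame:
    """Association of one variant against every eligible code.

    ``model``: ``dominant`` (genotype recoded carrier/non-carrier, logistic
    regression), ``additive`` (allele count, linear regression) or
    ``additive_logistic``.  Returns one row per eligible code with beta, OR
    (logistic models), Wald p, Bonferroni-adjusted p over the tested set,
    and case counts, sorted by p.  Codes whose fit degenerates are reported
    with a warning and NA statistics.
    """
    g = np.asarray(genotype, dtype=float)
    if model == "dominant":
        g_coded, fit_model = (g > 0).astype(float), "dominant_logistic"
    elif model == "additive":
        g_coded, fit_model = g, "additive_linear"
    elif model == "additive_logistic":
        g_coded, fit_model = g, "dominant_logistic"
    else:
        raise ValueError(f"unknown model {model!r}")

    eligible = filter_codes(code_matrix, g > 0, min_total, min_in_experimental)
    m = len(eligible)
    rows = []
    for code in eligible:
        y = code_matrix[code].to_numpy(dtype=float)
        try:
            res = fit_code_association(y, g_coded, covariates, code, fit_model, n_tests=m)
        except ValueError as exc:
            res = AssociationResult(
                code, fit_model, float("nan"), float("nan"), float("nan"),
                float("nan"), int(y.sum()), len(y), str(exc),
            )
        rows.append(res.__dict__)
    out = pd.DataFrame(rows, columns=[
        "code", "model", "beta", "odds_ratio", "p_value", "p_bonferroni",
        "n_cases", "n_total", "warning",
    ])
    out["neg_log10_p"] = -np.log10(out["p_value"])
    return out.sort_values("p_value", na_position="last").reset_index(drop=True)
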