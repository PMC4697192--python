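"""Case-distribution quartiles, stratified estimates, gene-environment tests.

Quartile cutpoints come from the variable's distribution *in cases* (so the
case counts, and hence power, are balanced across strata); the same spec is
reused for the hormone analysis so the two phenotypes are directly
comparable. The interaction test is a single joint model with a 1-df
dosage x quartile-index product term.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .assoc import AssocResult, _design, _fit_logistic, linear_assoc, logistic_trend
from .containers import GenotypeMatrix

MIN_STRATUM_N = 50
QUARTILE_LABELS = ("Q1", "Q2", "Q3", "Q4")


@dataclass
class QuartileSpec:
    """Quartile boundaries of a case-distribution variable (bmi or age).

    Assignment intervals are [-inf, c1), [c1, c2), [c2, c3), [c3, inf) --
    left-closed / right-open, with the top interval closed below, matching
    the convention "<c1" ... ">=c3".
    """

    variable: str
    cutpoints: tuple[float, float, float]

    def __post_init__(self) -> None:
        c = self.cutpoints
        if not (c[0] < c[1] < c[2]):
            raise ValueError(f"cutpoints must be strictly increasing, got {c}")

    def assign(self, values: np.ndarray | pd.Series) -> np.ndarray:
        """Quartile index 0-3 per value; NaN values get -1."""
        v = np.asarray(values, float)
        idx = np.searchsorted(np.asarray(self.cutpoints), v, side="right")
        return np.where(np.isfinite(v), idx, -1)

    def label(self, value: float) -> str:
        return QUARTILE_LABELS[int(self.assign(np.array([value]))[0])]


@dataclass
class StrataResult:
    spec: QuartileSpec
    per_quartile: list[AssocResult]  # Q1..Q4
    interaction_beta: float
    interaction_se: float
    interaction_p: float


def case_quartiles(phenotypes: pd.DataFrame, variable: str) -> QuartileSpec:
    """Quartile cutpoints from the variable's distribution in cases.

    Cutpoints are the 25/50/75 empirical percentiles (linear interpolation)
    of the non-missing case values. Requires >= 4 such values.
    """
    cases = phenotypes.loc[phenotypes["status"] == 1, variable].dropna()
    if len(cases) < 4:
        raise ValueError(f"need >= 4 non-missing case values of {variable!r}, got {len(cases)}")
    c = np.percentile(cases.to_numpy(float), [25, 50, 75])
    return QuartileSpec(variable=variable, cutpoints=(float(c[0]), float(c[1]), float(c[2])))


def _per_stratum(
    genotypes: GenotypeMatrix,
    phenotypes: pd.DataFrame,
    spec: QuartileSpec,
    variant: str,
    model: str,
    covariates: list[str],
    outcome: str | None,
    min_n: int,
) -> list[AssocResult]:
    qidx = spec.assign(phenotypes[spec.variable])
    out = []
    for q in range(4):
        mask = qidx == q
        n_q = int(mask.sum())
        if n_q == 0:
            raise ValueError(f"stratum {QUARTILE_LABELS[q]} of {spec.variable} is empty")
        if n_q < min_n:
            raise ValueError(
                f"stratum {QUARTILE_LABELS[q]} of {spec.variable} has {n_q} samples (< {min_n})"
            )
        sub_ids = list(phenotypes.loc[mask, "sample_id"])
        sub_geno = genotypes.subset_samples(sub_ids)
        sub_pheno = phenotypes.loc[mask]
        if model == "logistic":
            res = logistic_trend(sub_geno, sub_pheno, covariates, variants=[variant])[0]
        else:
            res = linear_assoc(sub_geno, sub_pheno, outcome=outcome or "log_e2",
                               covariates=covariates, variants=[variant])[0]
        res.study = QUARTILE_LABELS[q]
        out.append(res)
    return out


def interaction_test(
    genotypes: GenotypeMatrix,
    phenotypes: pd.DataFrame,
    spec: QuartileSpec,
    variant: str,
    model: str = "logistic",
    covariates: list[str] | None = None,
    outcome: str | None = None,
) -> tuple[float, float, float]:
    """1-df Wald test of the dosage x quartile-index product term.

    Single joint model over all strata: outcome ~ dosage + quartile index
    (ordinal 0-3) + covariates + dosage*index. Returns (beta, se, p); the sign
    of beta gives the direction of effect modification.

    Raises
    ------
    ValueError
        If the quartile variable is missing for more than half the samples,
        or all samples fall in one quartile.
    """
    covariates = covariates or []
    aligned = phenotypes.set_index("sample_id").loc[genotypes.samples].reset_index()
    qvals = aligned[spec.variable]
    if qvals.isna().mean() > 0.5:
        raise ValueError(f"{spec.variable!r} missing for >50% of samples")
    qidx = spec.assign(qvals).astype(float)
    qidx[qidx < 0] = np.nan
    if len(np.unique(qidx[np.isfinite(qidx)])) < 2:
        raise ValueError("all samples fall in a single quartile; interaction undefined")
    dose = genotypes.column(variant)
    cov_block = _design(aligned, covariates).to_numpy(float)
    X = np.column_stack([np.ones(len(dose)), dose, qidx, dose * qidx] +
                        ([cov_block] if cov_block.size else []))
    if model == "logistic":
        y = pd.to_numeric(aligned["status"], errors="coerce").to_numpy(float)
    else:
        y = pd.to_numeric(aligned[outcome or "log_e2"], errors="coerce").to_numpy(float)
    keep = np.isfinite(y) & np.all(np.isfinite(X), axis=1)
    yk, Xk = y[keep], X[keep]
    if model == "logistic":
        params, bse, ok = _fit_logistic(yk, Xk)
        if not ok:
            return float("nan"), float("nan"), float("nan")
        beta, se = float(params[3]), float(bse[3])
    else:
        res = sm.OLS(yk, Xk).fit()
        beta, se = float(res.params[3]), float(res.bse[3])
    p = float(2 * stats.norm.sf(abs(beta / se)))
    return beta, se, p


def stratified_assoc(
    genotypes: GenotypeMatrix,
    phenotypes: pd.DataFrame,
    spec: QuartileSpec,
    variant: str,
    model: str = "logistic",
    covariates: list[str] | None = None,
    outcome: str | None = None,
    min_stratum_n: int = MIN_STRATUM_N,
) -> StrataResult:
    """Per-quartile association estimates plus the 1-df interaction test.

    For BMI strata of the disease outcome the convention is to adjust for
    age (pass it in ``covariates``); hormone analyses in strata use ln(E2)
    uncorrected for T.
    """
    covariates = list(covariates or [])
    per_q = _per_stratum(genotypes, phenotypes, spec, variant, model,
                         covariates, outcome, min_stratum_n)
    beta, se, p = interaction_test(genotypes, phenotypes, spec, variant,
                                   model, covariates, outcome)
    return StrataResult(spec=spec, per_quartile=per_q,
                        interaction_beta=beta, interaction_se=se, interaction_p=p)


def ordinal_logistic_trend(
    phenotypes: pd.DataFrame,
    exposure: str = "quartile",
    covariates: list[str] | None = None,
) -> AssocResult:
    """Logistic trend of case status on an ordinal exposure index (1 df).

    The per-level coefficient is the log-OR per quartile step -- the standard
    summary for a graded exposure such as BMI quartile.
    """
    covariates = covariates or []
    x = pd.to_numeric(phenotypes[exposure], errors="coerce").to_numpy(float)
    y = pd.to_numeric(phenotypes["status"], errors="coerce").to_numpy(float)
    cov = _design(phenotypes, covariates).to_numpy(float)
    X = np.column_stack([np.ones(x.size), x] + ([cov] if cov.size else []))
    keep = np.isfinite(y) & np.all(np.isfinite(X), axis=1)
    yk, Xk = y[keep], X[keep]
    if len(np.unique(yk)) < 2:
        raise ValueError("status has a single class")
    params, bse, ok = _fit_logistic(yk, Xk)
    if not ok:
        raise ValueError("ordinal trend fit did not converge")
    beta, se = float(params[1]), float(bse[1])
    p = float(2 * stats.norm.sf(abs(beta / se)))
    return AssocResult(variant_id=exposure, model="logistic", beta=beta, se=se,
                       p=p, n_used=int(keep.sum()), covariates=covariates)
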