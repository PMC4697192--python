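"""Per-variant association engines.

Logistic per-allele (1 df) trend tests for case-control status and ordinary
least squares for log-scale hormone outcomes, with optional cluster-robust
(sandwich) standard errors. Fits go through statsmodels (GLM/OLS); this
module owns the per-allele model construction, complete-case handling,
convergence flagging and the result schema.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .containers import GenotypeMatrix

IRLS_TOL = 1e-8
IRLS_MAXITER = 25


@dataclass
class AssocResult:
    """One variant's association summary.

    ``beta`` is the per-effect-allele log-OR (logistic) or slope (linear);
    a non-converged or separated fit carries NaN effect and ``converged=False``
    rather than raising, so region scans never abort.
    """

    variant_id: str
    model: str  # "logistic" | "linear"
    beta: float
    se: float
    p: float
    n_used: int
    freq_case: float = float("nan")
    freq_ctrl: float = float("nan")
    freq: float = float("nan")
    covariates: list[str] = field(default_factory=list)
    robust: str = "none"  # "none" | "cluster-sandwich"
    converged: bool = True
    study: str | None = None

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.beta))

    @property
    def ci(self) -> tuple[float, float]:
        """95% Wald interval on the effect scale (OR for logistic)."""
        lo, hi = self.beta - 1.96 * self.se, self.beta + 1.96 * self.se
        if self.model == "logistic":
            return float(np.exp(lo)), float(np.exp(hi))
        return float(lo), float(hi)

    @property
    def chi2(self) -> float:
        return float((self.beta / self.se) ** 2)


def _flagged(variant_id: str, model: str, n: int, covariates: list[str], robust: str = "none") -> AssocResult:
    return AssocResult(
        variant_id=variant_id, model=model, beta=float("nan"), se=float("nan"),
        p=float("nan"), n_used=n, covariates=covariates, robust=robust, converged=False,
    )


def _design(phenotypes: pd.DataFrame, covariates: list[str]) -> pd.DataFrame:
    """Covariate design block: numeric columns as-is, labels dummy-coded."""
    parts = []
    for c in covariates:
        col = phenotypes[c]
        if pd.api.types.is_numeric_dtype(col):
            parts.append(col.astype(float).rename(c))
        else:
            parts.append(pd.get_dummies(col, prefix=c, drop_first=True, dtype=float))
    if not parts:
        return pd.DataFrame(index=phenotypes.index)
    return pd.concat(parts, axis=1)


def allele_freq(genotypes: GenotypeMatrix, sample_mask: np.ndarray | None = None) -> np.ndarray:
    """Effect-allele frequency per variant, sum(dosage) / (2 * n non-missing).

    Variants with no non-missing dosage in the subset return NaN with a
    warning.
    """
    dose = genotypes.dosage.copy()
    dose[genotypes.missing_mask] = np.nan
    if sample_mask is not None:
        dose = dose[np.asarray(sample_mask, bool)]
    n_obs = np.sum(~np.isnan(dose), axis=0)
    if np.any(n_obs == 0):
        warnings.warn("variant(s) with all-missing dosage: frequency is NaN")
    with np.errstate(invalid="ignore"):
        return np.where(n_obs > 0, np.nansum(dose, axis=0) / (2 * n_obs), np.nan)


def _dosage_collinear(X: np.ndarray) -> bool:
    """True when the dosage column (index 1) is collinear with the rest."""
    others = np.delete(X, 1, axis=1)
    dose = X[:, 1]
    resid = dose - others @ np.linalg.lstsq(others, dose, rcond=None)[0]
    total = np.sum((dose - dose.mean()) ** 2)
    return total == 0 or float(np.sum(resid**2) / total) < 1e-10


def _fit_logistic(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray, bool]:
    """IRLS logistic fit; returns (params, bse, converged-and-identified)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.GLM(y, X, family=sm.families.Binomial())
        try:
            res = model.fit(maxiter=IRLS_MAXITER, tol=IRLS_TOL)
        except Exception:
            return np.full(X.shape[1], np.nan), np.full(X.shape[1], np.nan), False
    bse = np.asarray(res.bse)
    ok = bool(res.converged) and np.all(np.isfinite(bse)) and np.all(np.abs(res.params) < 30)
    return np.asarray(res.params), bse, ok


def logistic_trend(
    genotypes: GenotypeMatrix,
    phenotypes: pd.DataFrame,
    covariates: list[str] | None = None,
    variants: list[str] | None = None,
    outcome: str = "status",
) -> list[AssocResult]:
    """Per-allele logistic trend test (1 df) for each variant.

    The dosage enters as a single linear term on top of the covariate block;
    complete cases per variant. Quasi-separated or non-converged variants are
    returned flagged (NaN effect) rather than raised.

    Raises
    ------
    ValueError
        If the outcome is all-case or all-control.
    """
    covariates = covariates or []
    aligned = phenotypes.set_index("sample_id").loc[genotypes.samples].reset_index()
    y_all = pd.to_numeric(aligned[outcome], errors="coerce").to_numpy(float)
    finite_y = y_all[np.isfinite(y_all)]
    if finite_y.size and (np.all(finite_y == 1) or np.all(finite_y == 0)):
        raise ValueError(f"outcome {outcome!r} has a single class (all-case or all-control)")
    cov_block = _design(aligned, covariates)
    results = []
    for vid in variants or genotypes.variant_ids:
        dose = genotypes.column(vid)
        X = np.column_stack([np.ones(len(dose)), dose, cov_block.to_numpy(float)]) \
            if len(cov_block.columns) else np.column_stack([np.ones(len(dose)), dose])
        keep = np.isfinite(y_all) & np.all(np.isfinite(X), axis=1)
        yk, Xk = y_all[keep], X[keep]
        if yk.size == 0 or len(np.unique(yk)) < 2 or np.ptp(Xk[:, 1]) == 0 \
                or _dosage_collinear(Xk):
            results.append(_flagged(vid, "logistic", int(keep.sum()), covariates))
            continue
        params, bse, ok = _fit_logistic(yk, Xk)
        dk = Xk[:, 1]
        f_case = float(np.sum(dk[yk == 1]) / (2 * np.sum(yk == 1)))
        f_ctrl = float(np.sum(dk[yk == 0]) / (2 * np.sum(yk == 0)))
        if not ok:
            r = _flagged(vid, "logistic", int(keep.sum()), covariates)
            r.freq_case, r.freq_ctrl = f_case, f_ctrl
            results.append(r)
            continue
        beta, se = float(params[1]), float(bse[1])
        p = float(2 * stats.norm.sf(abs(beta / se)))
        results.append(
            AssocResult(
                variant_id=vid, model="logistic", beta=beta, se=se,
                p=max(p, np.nextafter(0, 1)), n_used=int(keep.sum()),
                freq_case=f_case, freq_ctrl=f_ctrl, covariates=covariates,
            )
        )
    return results


def linear_assoc(
    genotypes: GenotypeMatrix,
    phenotypes: pd.DataFrame,
    outcome: str = "log_e2",
    covariates: list[str] | None = None,
    robust: str = "none",
    variants: list[str] | None = None,
) -> list[AssocResult]:
    """OLS of a log-scale hormone outcome on dosage (+ covariates) per variant.

    ``robust="cluster"`` applies the clustered sandwich variance over
    ``cluster_id`` groups with the small-sample factor
    G/(G-1) * (n-1)/(n-k).

    Raises
    ------
    ValueError
        For a constant outcome, or fewer than 2 clusters with robust="cluster".
    """
    covariates = covariates or []
    if robust not in ("none", "cluster"):
        raise ValueError(f"robust must be 'none' or 'cluster', got {robust!r}")
    aligned = phenotypes.set_index("sample_id").loc[genotypes.samples].reset_index()
    y_all = pd.to_numeric(aligned[outcome], errors="coerce").to_numpy(float)
    cov_block = _design(aligned, covariates)
    robust_label = "cluster-sandwich" if robust == "cluster" else "none"
    results = []
    for vid in variants or genotypes.variant_ids:
        dose = genotypes.column(vid)
        X = np.column_stack([np.ones(len(dose)), dose, cov_block.to_numpy(float)]) \
            if len(cov_block.columns) else np.column_stack([np.ones(len(dose)), dose])
        keep = np.isfinite(y_all) & np.all(np.isfinite(X), axis=1)
        yk, Xk = y_all[keep], X[keep]
        if yk.size and np.ptp(yk) == 0:
            raise ValueError(f"outcome {outcome!r} is constant on complete cases")
        if yk.size < X.shape[1] + 1 or np.ptp(Xk[:, 1]) == 0 or _dosage_collinear(Xk):
            results.append(_flagged(vid, "linear", int(keep.sum()), covariates, robust_label))
            continue
        model = sm.OLS(yk, Xk)
        if robust == "cluster":
            groups = aligned.loc[keep, "cluster_id"].to_numpy()
            if len(np.unique(groups)) < 2:
                raise ValueError("cluster-robust errors need at least 2 clusters")
            res = model.fit(cov_type="cluster", cov_kwds={"groups": groups, "use_correction": True})
        else:
            res = model.fit()
        beta, se = float(res.params[1]), float(res.bse[1])
        p = float(2 * stats.norm.sf(abs(beta / se)))
        results.append(
            AssocResult(
                variant_id=vid, model="linear", beta=beta, se=se,
                p=max(p, np.nextafter(0, 1)), n_used=int(keep.sum()),
                freq=float(np.sum(Xk[:, 1]) / (2 * len(yk))),
                covariates=covariates, robust=robust_label,
            )
        )
    return results


def case_case_test(
    genotypes: GenotypeMatrix,
    phenotypes: pd.DataFrame,
    subgroup_col: str,
    covariates: list[str] | None = None,
    variants: list[str] | None = None,
) -> list[AssocResult]:
    """Case-only allele-frequency comparison between two case subgroups.

    Runs the logistic trend test among cases with subgroup membership (the
    binary ``subgroup_col``, e.g. endometrioid vs non-endometrioid) as the
    outcome. Requires both subgroups non-empty.
    """
    cases = phenotypes[phenotypes["status"] == 1]
    values = cases[subgroup_col].dropna().unique()
    if len(values) < 2:
        raise ValueError(f"subgroup {subgroup_col!r} needs 2 distinct values among cases")
    sub_geno = genotypes.subset_samples(list(cases["sample_id"]))
    recoded = cases.copy()
    lv = sorted(values)
    recoded[subgroup_col] = (recoded[subgroup_col] == lv[-1]).astype(int)
    return logistic_trend(sub_geno, recoded, covariates, variants, outcome=subgroup_col)
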