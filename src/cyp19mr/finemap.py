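"""Lead-SNP selection, conditional scans, LD r2 and the candidate causal set.

The candidate set operationalizes the rule that a variant stays a plausible
cause if its likelihood ratio against the top SNP is better than 1:100 and it
is correlated with the top SNP (r2 > 0.2). The likelihood ratio is the
asymptotic summary-statistic form exp((chi2_lead - chi2_i)/2) computed from
pooled Wald chi-squares.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .assoc import AssocResult, linear_assoc, logistic_trend
from .containers import GenotypeMatrix
from .meta import MetaResult

LR_THRESHOLD = 100.0
R2_THRESHOLD = 0.2
CONDITIONAL_P = 1e-4


@dataclass
class CandidateMember:
    variant_id: str
    chi2: float
    likelihood_ratio: float  # vs index; 1 for the index itself
    r2_with_index: float


@dataclass
class CandidateSet:
    index_variant: str
    members: list[CandidateMember]
    lr_threshold: float = LR_THRESHOLD
    r2_threshold: float = R2_THRESHOLD
    conditional_threshold_p: float = CONDITIONAL_P

    @property
    def variant_ids(self) -> list[str]:
        return [m.variant_id for m in self.members]

    def __len__(self) -> int:
        return len(self.members)


def pick_lead(meta_results: list[MetaResult]) -> str:
    """Most significantly associated retained variant.

    Smallest pooled P; ties broken by larger Wald chi-square, then by the
    order given (callers pass position-sorted results, so the lowest genomic
    position wins).
    """
    usable = [m for m in meta_results if not m.excluded_het and np.isfinite(m.p_pooled)]
    if not usable:
        raise ValueError("no retained variants to pick a lead from")
    best = usable[0]
    for m in usable[1:]:
        if (m.p_pooled, -m.chi2) < (best.p_pooled, -best.chi2):
            best = m
    return best.variant_id


def ld_r2(genotypes: GenotypeMatrix, a: str, b: str) -> float:
    """Squared Pearson correlation of non-missing paired dosages (composite LD).

    Symmetric; r2(a, a) = 1. Monomorphic pairs return NaN with a warning.
    """
    xa, xb = genotypes.column(a), genotypes.column(b)
    keep = np.isfinite(xa) & np.isfinite(xb)
    xa, xb = xa[keep], xb[keep]
    if xa.size < 2 or np.ptp(xa) == 0 or np.ptp(xb) == 0:
        warnings.warn(f"r2({a},{b}) undefined: monomorphic or too few paired dosages")
        return float("nan")
    r = np.corrcoef(xa, xb)[0, 1]
    return float(r * r)


def conditional_scan(
    genotypes: GenotypeMatrix,
    phenotypes: pd.DataFrame,
    lead: str,
    covariates: list[str] | None = None,
    model: str = "logistic",
    outcome: str | None = None,
    threshold_p: float = CONDITIONAL_P,
) -> tuple[list[AssocResult], bool]:
    """Re-run the scan adjusting for the lead SNP's dosage; flag second signals.

    The lead dosage is appended to the covariate design (genotype-level
    conditional analysis, not a summary-statistic approximation); the lead
    itself is skipped. Variants in perfect LD with the lead come back flagged
    (collinear fit) rather than raising. Returns the conditional results and
    ``second_signal = any conditional P <= threshold_p``.

    Raises
    ------
    ValueError
        If the lead dosage is collinear with an existing covariate column.
    """
    covariates = list(covariates or [])
    aligned = phenotypes.set_index("sample_id").loc[genotypes.samples].reset_index()
    lead_dose = genotypes.column(lead)
    for c in covariates:
        col = pd.to_numeric(aligned[c], errors="coerce").to_numpy(float)
        keep = np.isfinite(col) & np.isfinite(lead_dose)
        if keep.sum() > 2 and np.ptp(col[keep]) > 0 and np.ptp(lead_dose[keep]) > 0:
            if abs(np.corrcoef(col[keep], lead_dose[keep])[0, 1]) > 1 - 1e-10:
                raise ValueError(f"lead {lead!r} is collinear with covariate {c!r}")
    table = aligned.copy()
    table["_lead_dosage"] = lead_dose
    others = [v for v in genotypes.variant_ids if v != lead]
    cond_cov = covariates + ["_lead_dosage"]
    if model == "logistic":
        results = logistic_trend(genotypes, table, cond_cov, variants=others,
                                 outcome=outcome or "status")
    else:
        results = linear_assoc(genotypes, table, outcome=outcome or "log_e2",
                               covariates=cond_cov, variants=others)
    second = any(np.isfinite(r.p) and r.p <= threshold_p for r in results)
    return results, second


def candidate_set(
    meta_results: list[MetaResult],
    genotypes: GenotypeMatrix,
    index: str,
    lr_threshold: float = LR_THRESHOLD,
    r2_threshold: float = R2_THRESHOLD,
) -> CandidateSet:
    """Likelihood-ratio + LD candidate causal set around the index variant.

    Per-variant chi2 = (beta_pooled/se_pooled)^2; LR_i = exp((chi2_index -
    chi2_i)/2). Members are variants with LR_i < lr_threshold and r2 with the
    index > r2_threshold, plus the index itself (LR = 1); sorted by LR
    ascending, ties by variant order in the input.
    """
    by_id = {m.variant_id: m for m in meta_results}
    if index not in by_id:
        raise ValueError(f"index variant {index!r} not among the meta results")
    chi2_index = by_id[index].chi2
    members = [CandidateMember(index, chi2_index, 1.0, 1.0)]
    for m in meta_results:
        if m.variant_id == index or not np.isfinite(m.chi2):
            continue
        lr = float(np.exp((chi2_index - m.chi2) / 2.0))
        if lr >= lr_threshold:
            continue
        r2 = ld_r2(genotypes, m.variant_id, index)
        if np.isfinite(r2) and r2 > r2_threshold:
            members.append(CandidateMember(m.variant_id, m.chi2, lr, r2))
    members.sort(key=lambda c: c.likelihood_ratio)
    return CandidateSet(index_variant=index, members=members,
                        lr_threshold=lr_threshold, r2_threshold=r2_threshold)
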