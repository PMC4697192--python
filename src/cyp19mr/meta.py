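"""Fixed-effects inverse-variance meta-analysis with heterogeneity screening.

Pools per-study per-allele estimates with weights 1/se^2, reports Cochran's Q,
I^2 and the heterogeneity P value, and applies the exclusion rule that drops
variants with significant between-study heterogeneity (P < 0.05).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .assoc import AssocResult


@dataclass
class MetaResult:
    variant_id: str
    beta_pooled: float
    se_pooled: float
    p_pooled: float
    q_stat: float
    df: int
    p_het: float  # NaN for a single study
    i2: float  # percent in [0, 100]
    per_study: list[tuple[str, float, float]]
    excluded_het: bool = False

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.beta_pooled))

    @property
    def ci(self) -> tuple[float, float]:
        return (
            float(np.exp(self.beta_pooled - 1.96 * self.se_pooled)),
            float(np.exp(self.beta_pooled + 1.96 * self.se_pooled)),
        )

    @property
    def chi2(self) -> float:
        return float((self.beta_pooled / self.se_pooled) ** 2)


def fixed_effects(results: list[AssocResult], het_alpha: float = 0.05) -> MetaResult:
    """Inverse-variance fixed-effects pool of per-study results for one variant.

    beta_pooled = sum(w_i b_i) / sum(w_i) with w_i = 1/se_i^2;
    se_pooled = sum(w_i)^(-1/2); Q = sum(w_i (b_i - beta_pooled)^2) on k-1 df;
    I^2 = max(0, (Q - df)/Q) * 100. Studies with non-finite beta or se
    (flagged fits) are dropped. A single usable study passes through with
    Q = 0, df = 0 and undefined (NaN) p_het.
    """
    usable = [r for r in results if np.isfinite(r.beta) and np.isfinite(r.se) and r.se > 0]
    if not usable:
        raise ValueError("fixed_effects needs at least one study with finite beta/se")
    vid = usable[0].variant_id
    b = np.array([r.beta for r in usable])
    se = np.array([r.se for r in usable])
    w = 1.0 / se**2
    beta = float(np.sum(w * b) / np.sum(w))
    se_p = float(np.sum(w) ** -0.5)
    p = float(2 * stats.norm.sf(abs(beta / se_p)))
    k = len(usable)
    q = float(np.sum(w * (b - beta) ** 2))
    df = k - 1
    if df > 0:
        p_het = float(stats.chi2.sf(q, df))
        i2 = float(max(0.0, (q - df) / q) * 100.0) if q > 0 else 0.0
    else:
        p_het, i2, q = float("nan"), 0.0, 0.0
    return MetaResult(
        variant_id=vid,
        beta_pooled=beta,
        se_pooled=se_p,
        p_pooled=max(p, np.nextafter(0, 1)),
        q_stat=q,
        df=df,
        p_het=p_het,
        i2=i2,
        per_study=[(r.study or f"study{i + 1}", float(r.beta), float(r.se)) for i, r in enumerate(usable)],
        excluded_het=bool(df > 0 and p_het < het_alpha),
    )


def het_filter(
    meta_results: list[MetaResult], alpha: float = 0.05
) -> tuple[list[MetaResult], list[MetaResult]]:
    """Partition into (retained, excluded) by the heterogeneity rule P < alpha.

    Single-study results (p_het undefined) are retained with a warning:
    heterogeneity cannot be assessed, and silently dropping them would lose
    variants present in only one study's panel. Input order is preserved and
    ``excluded_het`` flags are set consistently with ``alpha``.
    """
    retained, excluded = [], []
    for m in meta_results:
        if np.isnan(m.p_het):
            warnings.warn(
                f"{m.variant_id}: single-study result, heterogeneity undefined; retained"
            )
            m.excluded_het = False
            retained.append(m)
        elif m.p_het < alpha:
            m.excluded_het = True
            excluded.append(m)
        else:
            m.excluded_het = False
            retained.append(m)
    return retained, excluded
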