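"""Core in-memory containers: variants, dosage matrices, phenotype tables.

The dosage matrix is the single genotype representation used throughout:
samples x variants effect-allele dosages in [0, 2], with an explicit missing
mask so fractional (imputed-style) dosages and hard calls share one code path.
Phenotypes live in a plain pandas DataFrame validated by ``check_phenotypes``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Columns the phenotype table may carry with fixed semantics. Anything else
#: is treated as an extra covariate (e.g. principal components).
KNOWN_PHENO_COLUMNS = (
    "sample_id",
    "status",
    "log_e2",
    "log_t",
    "log_e2t",
    "age",
    "bmi",
    "hrt",
    "menopause",
    "study",
    "batch",
    "cluster_id",
)


@dataclass(frozen=True)
class VariantRecord:
    """A biallelic variant with a declared effect allele.

    Parameters
    ----------
    id : str
        Variant identifier (rsID or synthetic label).
    position : int
        1-based bp coordinate.
    ref_allele, alt_allele : str
        Single-character nucleotide labels.
    effect_allele : str
        Which allele the dosage counts: ``"ref"`` or ``"alt"``.
    effect_freq : float
        Effect-allele frequency (population/control scale), in [0, 1].
    """

    id: str
    position: int
    ref_allele: str = "A"
    alt_allele: str = "G"
    effect_allele: str = "alt"
    effect_freq: float = float("nan")

    def __post_init__(self) -> None:
        if self.effect_allele not in ("ref", "alt"):
            raise ValueError(
                f"effect_allele must be 'ref' or 'alt', got {self.effect_allele!r}"
            )
        if np.isfinite(self.effect_freq) and not 0.0 <= self.effect_freq <= 1.0:
            raise ValueError(f"effect_freq out of [0,1]: {self.effect_freq}")


@dataclass
class GenotypeMatrix:
    """Samples x variants effect-allele dosage matrix with variant metadata.

    Invariants (enforced by :meth:`validate`): every non-missing dosage lies
    in [0, 2]; dimensions match the sample and variant lists; variant
    positions are strictly increasing.
    """

    samples: list[str]
    variants: list[VariantRecord]
    dosage: np.ndarray
    missing_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.missing_mask is None:
            self.missing_mask = ~np.isfinite(self.dosage)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        self.validate()

    def validate(self) -> None:
        n, m = self.dosage.shape
        if n != len(self.samples) or m != len(self.variants):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        if self.missing_mask.shape != self.dosage.shape:
            raise ValueError("missing_mask shape mismatch")
        obs = self.dosage[~self.missing_mask]
        if obs.size and (np.nanmin(obs) < 0 or np.nanmax(obs) > 2):
            raise ValueError("non-missing dosages must lie in [0, 2]")
        pos = [v.position for v in self.variants]
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise ValueError("variant positions must be strictly increasing")
        if len(set(v.id for v in self.variants)) != m:
            raise ValueError("duplicate variant IDs")

    # -- convenience accessors -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def variant_ids(self) -> list[str]:
        return [v.id for v in self.variants]

    def index_of(self, variant_id: str) -> int:
        try:
            return self.variant_ids.index(variant_id)
        except ValueError:
            raise KeyError(f"variant {variant_id!r} not in matrix") from None

    def column(self, variant_id: str) -> np.ndarray:
        """Dosage column for one variant with missing entries as NaN."""
        j = self.index_of(variant_id)
        col = self.dosage[:, j].astype(float).copy()
        col[self.missing_mask[:, j]] = np.nan
        return col

    def subset_samples(self, keep: np.ndarray | list[str]) -> "GenotypeMatrix":
        """Row subset by boolean mask or list of sample IDs (keeps order given)."""
        if isinstance(keep, np.ndarray) and keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            lookup = {s: i for i, s in enumerate(self.samples)}
            idx = np.array([lookup[s] for s in keep], dtype=int)
        return GenotypeMatrix(
            samples=[self.samples[i] for i in idx],
            variants=list(self.variants),
            dosage=self.dosage[idx],
            missing_mask=self.missing_mask[idx],
        )


def check_phenotypes(table: pd.DataFrame, require: tuple[str, ...] = ()) -> pd.DataFrame:
    """Validate a phenotype table and derive ``log_e2t`` where possible.

    ``sample_id`` must be present and unique. ``log_e2t`` is (re)derived as
    ``log_e2 - log_t`` wherever both components are present. Columns listed in
    ``require`` must exist.
    """
    if "sample_id" not in table.columns:
        raise ValueError("phenotype table must have a sample_id column")
    if table["sample_id"].duplicated().any():
        dup = table["sample_id"][table["sample_id"].duplicated()].iloc[0]
        raise ValueError(f"duplicate sample_id: {dup!r}")
    for col in require:
        if col not in table.columns:
            raise ValueError(f"phenotype table missing required column {col!r}")
    table = table.copy()
    if "log_e2" in table.columns and "log_t" in table.columns:
        table["log_e2t"] = table["log_e2"] - table["log_t"]
    return table


def extra_covariate_columns(table: pd.DataFrame) -> list[str]:
    """Columns carried along as extra covariates (e.g. principal components)."""
    return [c for c in table.columns if c not in KNOWN_PHENO_COLUMNS and c != "log_e2t"]
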