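"""File formats: VCF genotypes, phenotype TSV, summary TSV.

Reading uses cyvcf2; dosages come from the DS FORMAT field when present and
otherwise from GT allele counts. Writing emits minimal VCF v4.2 with GT for
hard calls plus DS (3 decimals) when fractional dosages are requested.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .containers import GenotypeMatrix, VariantRecord, check_phenotypes

log = logging.getLogger("cyp19mr")

_YESNO = {"yes": 1, "no": 0, "y": 1, "n": 0, "true": 1, "false": 0, "1": 1, "0": 0}

SUMMARY_COLUMNS = [
    "variant_id", "position", "effect_allele", "freq_case", "freq_ctrl",
    "beta", "se", "or", "ci_lower", "ci_upper", "p", "q", "i2", "p_het",
    "excluded_het", "conditional_p", "lr_vs_lead", "r2_with_lead", "in_candidate_set",
]


def read_vcf(path: str) -> GenotypeMatrix:
    """Load a biallelic-SNP VCF into a dosage matrix.

    Dosage per sample is the DS value when the record has a DS FORMAT field,
    else the GT effect(ALT)-allele count; missing GT becomes a masked entry.
    Multi-allelic records are skipped with a warning. Variants are sorted by
    position; the effect allele defaults to ALT.

    Raises
    ------
    ValueError
        On duplicate variant IDs or a dosage outside [0, 2].
    """
    vcf = VCF(path)
    samples = list(vcf.samples)
    records, columns, masks = [], [], []
    seen: set[str] = set()
    for i, rec in enumerate(vcf):
        if len(rec.ALT) != 1:
            log.warning("skipping multi-allelic record %s at line ~%d", rec.ID, i + 1)
            continue
        vid = rec.ID or f"{rec.CHROM}:{rec.POS}"
        if vid in seen:
            raise ValueError(f"duplicate variant ID {vid!r} (record {i + 1})")
        seen.add(vid)
        try:
            ds = rec.format("DS")
        except KeyError:
            ds = None
        if ds is not None:
            col = np.asarray(ds, float).reshape(-1)
            miss = ~np.isfinite(col)
        else:
            gt = np.asarray(rec.gt_types)  # 0 hom-ref, 1 het, 3 hom-alt, 2 unknown
            col = np.select([gt == 0, gt == 1, gt == 3], [0.0, 1.0, 2.0], default=np.nan)
            miss = gt == 2
        bad = np.isfinite(col) & ((col < 0) | (col > 2))
        if bad.any():
            raise ValueError(
                f"dosage out of [0,2] for variant {vid!r}: {col[bad][0]!r} (record {i + 1})"
            )
        records.append(
            VariantRecord(id=vid, position=rec.POS, ref_allele=rec.REF,
                          alt_allele=rec.ALT[0], effect_allele="alt")
        )
        col = col.copy()
        col[miss] = 0.0  # masked
        columns.append(col)
        masks.append(miss)
    order = np.argsort([r.position for r in records], kind="stable")
    return GenotypeMatrix(
        samples=samples,
        variants=[records[j] for j in order],
        dosage=np.column_stack([columns[j] for j in order]) if records else np.empty((len(samples), 0)),
        missing_mask=np.column_stack([masks[j] for j in order]) if records else np.empty((len(samples), 0), bool),
    )


def write_vcf(genotypes: GenotypeMatrix, path: str, chrom: str = "15",
              dosage_field: bool = False) -> None:
    """Write the matrix as VCF v4.2 (GT for integer calls, DS when asked)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if dosage_field:
            fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Effect-allele dosage">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(genotypes.samples) + "\n")
        fmt = "GT:DS" if dosage_field else "GT"
        for j, v in enumerate(genotypes.variants):
            col = genotypes.dosage[:, j]
            miss = genotypes.missing_mask[:, j]
            cells = []
            for d, m in zip(col, miss):
                if m:
                    cells.append("./." + (":." if dosage_field else ""))
                    continue
                k = int(round(d))
                gt = ("0/0", "0/1", "1/1")[k] if abs(d - k) < 1e-9 and 0 <= k <= 2 else "./."
                cells.append(f"{gt}:{d:.3f}" if dosage_field else gt)
            fh.write(f"{chrom}\t{v.position}\t{v.id}\t{v.ref_allele}\t{v.alt_allele}"
                     f"\t.\t.\t.\t{fmt}\t" + "\t".join(cells) + "\n")


def read_phenotypes(path: str, genotypes: GenotypeMatrix | None = None,
                    require: tuple[str, ...] = ()) -> pd.DataFrame:
    """Read the phenotype/covariate TSV.

    ``sample_id`` is mandatory and must be unique; ``hrt`` accepts yes/no
    labels and is recoded to 1/0; unknown columns ride along as extra
    covariates. When a genotype matrix is given, samples absent from it are
    dropped and the kept/dropped counts are logged.

    Raises
    ------
    ValueError
        On duplicate sample IDs or a non-numeric value in a numeric column
        (reported with its row number).
    """
    table = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "hrt" in table.columns and table["hrt"].dtype == object:
        low = table["hrt"].astype(str).str.strip().str.lower()
        unknown = ~low.isin(_YESNO)
        if unknown.any():
            row = int(np.flatnonzero(unknown)[0])
            raise ValueError(f"unrecognized hrt value {table['hrt'].iloc[row]!r} at row {row + 2}")
        table["hrt"] = low.map(_YESNO).astype(int)
    for col in ("status", "log_e2", "log_t", "age", "bmi"):
        if col in table.columns:
            coerced = pd.to_numeric(table[col], errors="coerce")
            bad = coerced.isna() & table[col].notna()
            if bad.any():
                row = int(np.flatnonzero(bad)[0])
                raise ValueError(
                    f"non-numeric value {table[col].iloc[row]!r} in column {col!r} at row {row + 2}"
                )
            table[col] = coerced
    table = check_phenotypes(table, require=require)
    if genotypes is not None:
        keep = table["sample_id"].isin(set(genotypes.samples))
        log.info("phenotype/genotype intersection: kept %d, dropped %d samples",
                 int(keep.sum()), int((~keep).sum()))
        table = table.loc[keep].reset_index(drop=True)
    return table


def _fmt(x, sci: bool = False) -> str:
    if x is None or (isinstance(x, float) and not np.isfinite(x)):
        return "NA"
    if isinstance(x, bool) or isinstance(x, np.bool_):
        return "true" if x else "false"
    if sci:
        return f"{x:.3e}"
    if isinstance(x, float):
        return f"{x:.6g}"
    return str(x)


def write_summary(rows: list[dict], path: str) -> None:
    """Write the per-variant summary TSV (deterministic order by position).

    P-type columns are rendered in scientific notation with 3 significant
    digits; an empty result set yields a header-only file.
    """
    sci = {"p", "p_het", "conditional_p"}
    rows = sorted(rows, key=lambda r: (r.get("position") or 0))
    with open(path, "w") as fh:
        fh.write("\t".join(SUMMARY_COLUMNS) + "\n")
        for r in rows:
            fh.write("\t".join(_fmt(r.get(c), sci=c in sci) for c in SUMMARY_COLUMNS) + "\n")
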