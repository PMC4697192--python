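"""Per-study per-allele scans pooled by fixed-effects meta-analysis.

Four simulated studies at the full study scale (6608 cases / 37 925
controls) share a common true per-allele OR of 1.15; the pooled estimate
recovers it and the heterogeneity statistics stay near their null values.
"""

from cyp19mr import SimulationConfig, het_filter, scan_disease, simulate_case_control, simulate_haplotypes

cfg = SimulationConfig(seed=7, n_variants=1)  # defaults: 4 studies, 6608/37925
pool = simulate_haplotypes(cfg, 20_000)
geno, pheno = simulate_case_control(pool, cfg)

meta = scan_disease(geno, pheno, [])[0]
retained, excluded = het_filter([meta])

lo, hi = meta.ci
print(f"per-study log-ORs: {[round(b, 3) for _, b, _ in meta.per_study]}")
print(f"pooled OR per effect allele: {meta.odds_ratio:.3f} (CI {lo:.3f}-{hi:.3f})")
print(f"pooled P = {meta.p_pooled:.2e}")
print(f"Cochran Q = {meta.q_stat:.2f} on {meta.df} df, I^2 = {meta.i2:.1f}%, "
      f"P_het = {meta.p_het:.2f}")
print(f"heterogeneity exclusion: {'excluded' if excluded else 'retained'}")
# A pooled OR near 1.15 with genome-wide-significant P and I^2 near zero is
# the signature of one common effect measured consistently across studies.
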