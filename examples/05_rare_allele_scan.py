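"""Rare allele scan: find a large-effect variant private to one parent.

Tests, at every map position, the additive and dominance effect of each
founder haplotype against all others.  A variant carried on a single
founder haplotype is invisible to a frequency-based GWAS but produces a
clean LOD peak here.  The selected QTL's dominance effect predicts its
contribution to inbreeding depression as 2 F p q d with F = 0.5 and
q = 1/2N.
"""

import numpy as np

from idscan import (
    QTLSpec, SimulationConfig, build_linkage_map, compute_grms,
    cross_validate, declare_initial_qtl, genomic_inbreeding, marker_pcs,
    ras_scan, simulate_population, stepwise_select,
)
from idscan.design import fixed_design
from idscan.ras import qtl_table

cfg = SimulationConfig(
    n_parents=10, n_chromosomes=2, chrom_length_cM=80, seed=5,
    selfed_family_sizes=[20] * 10,
    qtl_spec=[QTLSpec(chrom=1, cM=40.0, freq=0.05, a=-4.0, d=2.0,
                      carrier=(2, 0))],
    residual_sd_by_type_year={("outcrossed", "Y1"): 3.0,
                              ("outcrossed", "Y2"): 3.0,
                              ("selfed", "Y1"): 3.0, ("selfed", "Y2"): 3.0})
pop = simulate_population(cfg)
lmap = build_linkage_map(pop.mat_code, pop.pat_code, pop.founders.sites)
grm = compute_grms(pop.genotypes, allele_freqs=pop.founders.site_freqs)
F = genomic_inbreeding(grm)
pcs, _ = marker_pcs(pop.genotypes, 10)
X_env, _ = fixed_design(pop.phenotypes, include_type=False, extra={"F": F})
X_pc = pcs.to_numpy()
y = pop.phenotypes["trait"].to_numpy()

profile = ras_scan(y, pop.mat_code, pop.pat_code, lmap,
                   np.hstack([X_env, X_pc]))
candidates = declare_initial_qtl(profile, lmap, lod_min=4.0)
print(f"candidate peaks with LOD >= 4: {len(candidates)}")

out = pop.phenotypes.progeny_type == "outcrossed"
selected, summary = stepwise_select(
    candidates, y, pop.mat_code, pop.pat_code, lmap, X_env, X_pc,
    outcross_sd=float(y[out].std()), n_parents=10,
    outcross_mean=float(y[out].mean()))
print(f"QTL surviving stepwise BIC: {len(selected)} "
      f"(truth: one private allele, parent P002 haplotype 1, chrom 1)")
print(qtl_table(selected)[["Marker", "chrom", "cM", "LOD", "a_effect",
                           "d_effect", "r2_AD", "N_het", "N_hom",
                           "cM_start", "cM_end", "delta_pred"]]
      .to_string(index=False))
print(f"\nvariance split: QTL r2 = {summary['r2_qtl']:.3f}, "
      f"polygenic (PC) r2 = {summary['r2_pc']:.3f}")

cv = cross_validate(y, pop.mat_code, pop.pat_code, lmap, X_env, X_pc,
                    folds=5, seed=1)
print(f"cross-validation mean r: null {cv['r_null'].mean():.3f}, "
      f"+QTL {cv['r_qtl'].mean():.3f}, full {cv['r_full'].mean():.3f}")
print("\nThe planted a = -4 allele is recovered with its sign, a 2-LOD")
print("support interval, and an out-of-sample prediction gain over the")
print("covariate-only model.")
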