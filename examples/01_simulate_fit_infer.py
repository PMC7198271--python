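"""Simulate a sex-specific trait, fit the segmented Bayesian model, and
inspect SNP-level evidence for gene-by-sex interactions.

A small LD-bearing panel (1 chromosome, 300 SNPs, 1500 individuals/sex)
carries 3 causal variants, one of which affects only one sex.  The model is
fit on overlapping segments, core samples are stitched, and per-SNP
posterior probabilities are printed for the top sex-difference signals.
"""

import numpy as np

import lbr

geno = lbr.GenoSimConfig(
    n_male=1500, n_female=1500, n_chrom=1, snps_per_chrom=300,
    mean_spacing_bp=20_000.0, seed=1,
)
panel = lbr.simulate_genotypes(geno)
trait = lbr.TraitSimConfig(
    n_causal=3, causal_spacing_bp=1.5e6, per_variant_r2=1.5e-2,
    prop_gxs=0.34, gxs_scheme="one_sex_only", seed=1,
)
y, truth = lbr.simulate_trait(panel, trait)
print("true causal variants (beta on the unit-variance phenotype scale):")
print(truth.to_frame().to_string(index=False))

samples = lbr.fit_panel(
    panel, y,
    lbr.RunConfig(core_size=150, buffer_size=50, n_iter=2000, burn_in=500,
                  thin=2, seed=1),
)
snp = lbr.snp_probabilities(samples).table

print("\ntop 5 SNPs by PPDiff (posterior probability the male and female")
print("effects differ; PPM/PPF are probabilities of any effect per sex):")
print(snp.sort_values("PPDiff", ascending=False).head(5).to_string(index=False))
print("\nA PPDiff near 1 at or beside the one-sex causal SNP, and near the")
print("inclusion-prior level elsewhere, shows the interaction being mapped")
print("through local LD rather than marginal association.")
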