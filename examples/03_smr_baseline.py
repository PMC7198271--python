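"""Single-marker regression baseline: sex-stratified effects and tests.

Fits per-sex simple regressions at every SNP and prints the strongest
sex-difference signals (p_diff) next to the any-sex-effect test (p_any).
"""

import lbr

geno = lbr.GenoSimConfig(
    n_male=1500, n_female=1500, n_chrom=1, snps_per_chrom=400,
    mean_spacing_bp=20_000.0, seed=3,
)
panel = lbr.simulate_genotypes(geno)
trait = lbr.TraitSimConfig(
    n_causal=4, causal_spacing_bp=1.8e6, per_variant_r2=6e-3,
    prop_gxs=0.5, gxs_scheme="mixed", seed=3,
)
y, truth = lbr.simulate_trait(panel, trait)

scan = lbr.smr_scan(panel, y)
print("true causal variants:")
print(truth.to_frame()[["snp_id", "bp", "beta_m_true", "beta_f_true", "gxs"]]
      .to_string(index=False))
print("\ntop 5 SNPs by sex-difference p-value (z on the difference of the")
print("per-sex slopes; p_any is the 2-df joint test of any effect):")
cols = ["snp_id", "bp", "beta_hat_m", "beta_hat_f", "p_diff", "p_any"]
print(scan.sort_values("p_diff").head(5)[cols].to_string(index=False))
print("\nMarginal estimates smear causal signals over LD neighbours, which")
print("is why the segmented Bayesian fit achieves better localisation.")
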