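"""Shared fixtures: small synthetic panels and the desk-scale benchmark run.

The expensive desk-preset Monte Carlo benchmark (20 replicate fits) is
session-scoped and shared between the power/FDR tests so it runs once.
"""

from __future__ import annotations

import numpy as np
import pytest

import lbr


def make_panel(X, sex, chrom=None, bp=None):
    """GenotypePanel from a raw dosage matrix with default metadata."""
    n, p = X.shape
    return lbr.GenotypePanel(
        dosages=X,
        snp_ids=np.array([f"s{j}" for j in range(p)], dtype=object),
        chrom=np.array(chrom if chrom is not None else ["chr1"] * p, dtype=object),
        bp=np.array(bp if bp is not None else np.arange(1, p + 1) * 1000),
        individual_ids=np.array([f"i{i}" for i in range(n)], dtype=object),
        sex=np.asarray(sex, dtype=object),
    )


def random_panel(rng, n, p, maf=0.3, chrom=None, bp=None):
    """LD-free binomial dosage panel, half male / half female."""
    X = rng.binomial(2, maf, size=(n, p)).astype(float)
    sex = np.array(["male"] * (n // 2) + ["female"] * (n - n // 2), dtype=object)
    return make_panel(X, sex, chrom=chrom, bp=bp)


@pytest.fixture(scope="session")
def small_fit():
    """A quick real fit on LD-bearing data with genuine signal, reused by
    posterior-inference tests."""
    geno = lbr.GenoSimConfig(
        n_male=400, n_female=400, n_chrom=1, snps_per_chrom=150,
        mean_spacing_bp=20_000.0, seed=42,
    )
    panel = lbr.simulate_genotypes(geno)
    trait = lbr.TraitSimConfig(
        n_causal=3, causal_spacing_bp=8e5, per_variant_r2=2e-2,
        prop_gxs=0.5, gxs_scheme="one_sex_only", seed=42,
    )
    y, truth = lbr.simulate_trait(panel, trait)
    samples = lbr.gibbs_fit(
        panel, y, cfg=lbr.McmcConfig(n_iter=1200, burn_in=400, thin=1, seed=5)
    )
    return panel, y, truth, samples


DESK_MCMC = dict(n_iter=1500, burn_in=500, thin=2)
N_BENCH_REPLICATES = 20


@pytest.fixture(scope="session")
def desk_benchmark():
    """Desk-preset Monte Carlo benchmark: 20 trait replicates on one panel.

    For each replicate: simulate a trait (40% G×S), run the segmented
    Bayesian fit and the single-marker scan, and return the merged per-SNP
    table (PPDiff, PP_any, p_diff, p_any) plus causal-class flags.
    """
    geno_cfg, trait_cfg = lbr.desk_preset(seed=7)
    panel = lbr.simulate_genotypes(geno_cfg)
    run_cfg = lbr.RunConfig(seed=7, **DESK_MCMC)
    reps = []
    for r in range(N_BENCH_REPLICATES):
        trait_cfg.seed = 1000 + r
        y, truth = lbr.simulate_trait(panel, trait_cfg)
        stitched = lbr.fit_panel(panel, y, run_cfg)
        snp = lbr.snp_probabilities(stitched).table
        scan = lbr.smr_scan(panel, y)
        merged = snp.merge(scan[["snp_id", "p_diff", "p_any"]], on="snp_id")
        merged["is_causal"] = np.isin(panel.snp_ids, truth.causal_snp_ids)
        merged["is_gxs"] = np.isin(
            panel.snp_ids, truth.causal_snp_ids[truth.gxs_flags]
        )
        reps.append(merged)
    return panel, reps


@pytest.fixture(scope="session")
def null_desk_fit():
    """Desk-preset fit of a trait with NO G×S (prop_gxs=0), for calibration."""
    geno_cfg, trait_cfg = lbr.desk_preset(seed=11)
    trait_cfg.prop_gxs = 0.0
    trait_cfg.seed = 11
    panel = lbr.simulate_genotypes(geno_cfg)
    y, truth = lbr.simulate_trait(panel, trait_cfg)
    stitched = lbr.fit_panel(panel, y, lbr.RunConfig(seed=11, **DESK_MCMC))
    snp = lbr.snp_probabilities(stitched).table
    scan = lbr.smr_scan(panel, y)
    return panel, truth, snp, scan
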