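"""Synthetic genotypes and sex-specific trait architectures.

The genotype generator produces biallelic dosages with realistic local LD
from a latent-Gaussian haplotype model: per chromosome, SNP positions follow
exponential spacings, each haplotype is a stationary first-order Gaussian
process with inter-SNP correlation exp(-d/phi), and alleles are threshold
indicators at the SNP's allele frequency.  ``phi`` is calibrated so that
dosage R² between SNPs falls below 0.01 at the configured LD-decay distance
(default 1.5 Mb, matching the 1-2 Mb range over which LD vanishes in
unstructured human populations).  The genotype distribution is identical in
both sexes by construction — sex is a row label, never a confounder.

The trait generator places causal variants one per genomic stratum (default
~2 Mb), sizes each effect so its expected contribution is a fixed proportion
of phenotypic variance (default 3.3e-4), and makes a configurable fraction
of causal variants (default 40%) sex-specific under one of three schemes.
Residual noise tops total variance up to 1 before the phenotype is rescaled
to exactly unit variance.  A masked-causal mode removes causal columns so
that discovery must work through LD tagging.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import (
    FEMALE,
    MALE,
    GenotypePanel,
    PhenotypeVector,
    scale_phenotype,
    write_plink,
)

__all__ = [
    "GenoSimConfig",
    "TraitSimConfig",
    "SimulationTruth",
    "simulate_genotypes",
    "simulate_trait",
    "mask_causal",
    "desk_preset",
    "full_scale_preset",
    "write_simulation",
]


@dataclass
class GenoSimConfig:
    """Genotype generator settings.

    ``ld_decay_bp`` is the distance at which dosage R² has decayed to ~0.01;
    the latent AR correlation length is derived from it.  MAFs are uniform
    over ``maf_range``.
    """

    n_male: int = 3000
    n_female: int = 3000
    n_chrom: int = 2
    snps_per_chrom: int = 1000
    mean_spacing_bp: float = 5000.0
    ld_decay_bp: float = 1.5e6
    maf_range: tuple[float, float] = (0.05, 0.5)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.snps_per_chrom < 1:
            raise ValueError("snps_per_chrom must be >= 1")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("require 0 < maf_min <= maf_max <= 0.5")


@dataclass
class TraitSimConfig:
    """Trait architecture settings.

    ``per_variant_r2`` is the expected proportion of (pooled) phenotypic
    variance contributed by one causal variant; ``prop_gxs`` the fraction of
    causal variants whose male and female effects differ; ``gxs_scheme`` how
    those differing effects are drawn (``one_sex_only``: effect in one sex,
    alternating, zero in the other; ``independent_draw``: independent normal
    effects per sex with equal expected per-sex variance; ``mixed``: half
    each).
    """

    n_causal: int = 150
    causal_spacing_bp: float = 2e6
    per_variant_r2: float = 3.3e-4
    prop_gxs: float = 0.4
    gxs_scheme: str = "mixed"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.prop_gxs <= 1:
            raise ValueError("prop_gxs must be in [0, 1]")
        if self.per_variant_r2 * self.n_causal >= 1:
            raise ValueError("total genetic variance must be below 1")
        if self.gxs_scheme not in {"one_sex_only", "independent_draw", "mixed"}:
            raise ValueError(f"unknown gxs_scheme {self.gxs_scheme!r}")


@dataclass
class SimulationTruth:
    """Ground truth of a simulated trait, for power/FDR evaluation."""

    causal_indices: np.ndarray
    causal_snp_ids: np.ndarray
    causal_chrom: np.ndarray
    causal_bp: np.ndarray
    beta_m_true: np.ndarray
    beta_f_true: np.ndarray
    gxs_flags: np.ndarray
    realized_r2: np.ndarray  # per-causal realized variance fraction
    realized_var_g: float = 0.0
    realized_var_e: float = 0.0
    realized_cov_ge: float = 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "snp_id": self.causal_snp_ids,
                "chrom": self.causal_chrom,
                "bp": self.causal_bp,
                "beta_m_true": self.beta_m_true,
                "beta_f_true": self.beta_f_true,
                "gxs": self.gxs_flags,
                "realized_r2": self.realized_r2,
            }
        )


def _ar_phi(ld_decay_bp: float) -> float:
    # latent corr exp(-d/phi); dosage R2 <= latent R2 = exp(-2d/phi),
    # so R2 hits 0.01 no later than d where exp(-2d/phi)=0.01
    return 2.0 * ld_decay_bp / np.log(100.0)


def simulate_genotypes(cfg: GenoSimConfig) -> GenotypePanel:
    """Generate an LD-bearing dosage panel; males first, then females."""
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_male + cfg.n_female
    phi = _ar_phi(cfg.ld_decay_bp)
    p_total = cfg.n_chrom * cfg.snps_per_chrom
    dosages = np.empty((n, p_total), dtype=np.float32)
    bp = np.empty(p_total, dtype=np.int64)
    chrom = np.empty(p_total, dtype=object)
    snp_ids = np.array([f"snp{j}" for j in range(p_total)], dtype=object)

    col = 0
    for c in range(cfg.n_chrom):
        spacings = np.maximum(
            1, rng.exponential(cfg.mean_spacing_bp, cfg.snps_per_chrom).astype(np.int64)
        )
        pos = np.cumsum(spacings)
        rho = np.exp(-np.diff(pos) / phi)
        mafs = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], cfg.snps_per_chrom)
        thresholds = stats.norm.ppf(1.0 - mafs)
        # two haplotypes per individual, AR(1) latent field along the chromosome
        z = rng.standard_normal((2 * n,))
        for l in range(cfg.snps_per_chrom):
            if l > 0:
                z = rho[l - 1] * z + np.sqrt(1.0 - rho[l - 1] ** 2) * rng.standard_normal(2 * n)
            alleles = (z > thresholds[l]).astype(np.float32)
            dosages[:, col + l] = alleles[:n] + alleles[n:]
        bp[col : col + cfg.snps_per_chrom] = pos
        chrom[col : col + cfg.snps_per_chrom] = f"chr{c + 1}"
        col += cfg.snps_per_chrom

    sex = np.array([MALE] * cfg.n_male + [FEMALE] * cfg.n_female, dtype=object)
    ids = np.array([f"ind{i}" for i in range(n)], dtype=object)
    return GenotypePanel(
        dosages=dosages, snp_ids=snp_ids, chrom=chrom, bp=bp,
        individual_ids=ids, sex=sex,
    )


def _pick_causal(panel: GenotypePanel, cfg: TraitSimConfig, rng) -> np.ndarray:
    """One causal SNP per ~causal_spacing_bp stratum, n_causal strata used."""
    strata: list[np.ndarray] = []
    for c in pd.unique(panel.chrom):
        idx = np.flatnonzero(panel.chrom == c)
        pos = panel.bp[idx]
        stratum_id = ((pos - pos[0]) // int(cfg.causal_spacing_bp)).astype(int)
        for s in np.unique(stratum_id):
            strata.append(idx[stratum_id == s])
    if len(strata) < cfg.n_causal:
        raise ValueError(
            f"panel holds only {len(strata)} strata of {cfg.causal_spacing_bp:g} bp; "
            f"cannot place {cfg.n_causal} causal variants"
        )
    use = np.round(np.linspace(0, len(strata) - 1, cfg.n_causal)).astype(int)
    return np.array([rng.choice(strata[s]) for s in use])


def simulate_trait(
    panel: GenotypePanel, cfg: TraitSimConfig
) -> tuple[PhenotypeVector, SimulationTruth]:
    """Simulate a sex-specific trait on ``panel``; returns (phenotype, truth).

    Shared causal variants get identical per-sex effects sized so each
    variant's expected variance contribution is ``per_variant_r2``; G×S
    variants follow ``gxs_scheme`` with the same expected POOLED contribution.
    Residual variance is set so the pooled variance is ~1, then the phenotype
    is rescaled to exactly unit variance (truth records effects on the
    rescaled scale).
    """
    rng = np.random.default_rng(cfg.seed)
    causal = _pick_causal(panel, cfg, rng)
    k = len(causal)
    # pooled-centered causal dosages: a one-sex effect on raw dosages would
    # also shift that sex's mean, which the model's intercepts absorb — it is
    # not genetic variance, so it is excluded from the accounting here too
    Xc = panel.dosages[:, causal].astype(np.float64)
    Xc -= Xc.mean(axis=0, keepdims=True)
    var_x = Xc.var(axis=0, ddof=1)
    if (var_x == 0).any():
        # monomorphic stratum picks are resampled once; extremely rare at
        # maf >= 0.05, but a zero-variance causal SNP would be undefined
        for i in np.flatnonzero(var_x == 0):
            alt = rng.choice(np.flatnonzero(panel.dosages.var(axis=0) > 0))
            causal[i] = alt
        Xc = panel.dosages[:, causal].astype(np.float64)
        Xc -= Xc.mean(axis=0, keepdims=True)
        var_x = Xc.var(axis=0, ddof=1)

    n_gxs = int(round(cfg.prop_gxs * k))
    gxs = np.zeros(k, dtype=bool)
    gxs[rng.choice(k, size=n_gxs, replace=False)] = True

    beta_m = np.zeros(k)
    beta_f = np.zeros(k)
    shared = ~gxs
    signs = rng.choice([-1.0, 1.0], size=k)
    mag = np.sqrt(cfg.per_variant_r2 / var_x)
    beta_m[shared] = signs[shared] * mag[shared]
    beta_f[shared] = beta_m[shared]

    gxs_idx = np.flatnonzero(gxs)
    if cfg.gxs_scheme == "one_sex_only":
        one_sex = gxs_idx
        indep = np.array([], dtype=int)
    elif cfg.gxs_scheme == "independent_draw":
        one_sex = np.array([], dtype=int)
        indep = gxs_idx
    else:  # mixed
        half = len(gxs_idx) // 2
        one_sex = gxs_idx[:half]
        indep = gxs_idx[half:]
    # one-sex-only: active-sex beta^2 var(x) = 2*per_variant_r2 so the POOLED
    # contribution (half the rows active) stays per_variant_r2
    for t, j in enumerate(one_sex):
        b = signs[j] * np.sqrt(2.0 * cfg.per_variant_r2 / var_x[j])
        if t % 2 == 0:
            beta_m[j] = b
        else:
            beta_f[j] = b
    sd_ind = np.sqrt(cfg.per_variant_r2 / var_x[indep])
    beta_m[indep] = rng.standard_normal(len(indep)) * sd_ind
    beta_f[indep] = rng.standard_normal(len(indep)) * sd_ind
    # guarantee the gxs flags are literal: equal draws (prob. 0) are nudged
    clash = gxs & (beta_m == beta_f)
    beta_m[clash] += 1e-12

    male = panel.is_male
    beta_ind = np.where(male[:, None], beta_m[None, :], beta_f[None, :])
    g = (Xc * beta_ind).sum(axis=1)
    var_g = g.var(ddof=1)
    resid_var = max(1.0 - var_g, 1e-6)
    eps = rng.standard_normal(panel.n) * np.sqrt(resid_var)
    y_raw = g + eps

    var_y = y_raw.var(ddof=1)
    per_var = np.array(
        [(Xc[:, i] * beta_ind[:, i]).var(ddof=1) for i in range(k)]
    ) / var_y
    sd_y = y_raw.std(ddof=1)

    truth = SimulationTruth(
        causal_indices=causal,
        causal_snp_ids=panel.snp_ids[causal],
        causal_chrom=panel.chrom[causal],
        causal_bp=panel.bp[causal],
        beta_m_true=beta_m / sd_y,
        beta_f_true=beta_f / sd_y,
        gxs_flags=gxs,
        realized_r2=per_var,
        realized_var_g=float(var_g),
        realized_var_e=float(eps.var(ddof=1)),
        realized_cov_ge=float(np.cov(g, eps, ddof=1)[0, 1]),
    )
    return scale_phenotype(y_raw), truth


def mask_causal(panel: GenotypePanel, truth: SimulationTruth) -> GenotypePanel:
    """Panel with the causal columns removed (LD-tagging evaluation mode).

    The truth object keeps the original bp positions, which is what
    target-area evaluation needs.  Idempotent: masking an already-masked
    panel is a no-op.
    """
    keep = ~np.isin(panel.snp_ids, truth.causal_snp_ids)
    return panel.subset_snps(np.flatnonzero(keep))


def desk_preset(seed: int = 0) -> tuple[GenoSimConfig, TraitSimConfig]:
    """Small-n conditions sized for a workstation.

    3000 individuals per sex, 2 chromosomes x 1000 SNPs at 20 kb mean
    spacing (20 Mb chromosomes, so ~13 LD-decay lengths each), 10 causal
    variants (4 G×S) with per-variant R² inflated to 2e-3 so power is
    estimable at this sample size.
    """
    geno = GenoSimConfig(
        n_male=3000, n_female=3000, n_chrom=2, snps_per_chrom=1000,
        mean_spacing_bp=20_000.0, seed=seed,
    )
    trait = TraitSimConfig(
        n_causal=10, causal_spacing_bp=2e6, per_variant_r2=2e-3,
        prop_gxs=0.4, gxs_scheme="mixed", seed=seed,
    )
    return geno, trait


def full_scale_preset(seed: int = 0) -> tuple[GenoSimConfig, TraitSimConfig]:
    """Full-scale conditions (cluster-sized: ~259k individuals, 60k SNPs).

    119,190 males and 139,738 females, 10 chromosomes x 6000 SNPs at 5 kb
    spacing, 150 causal variants each explaining 3.3e-4 of phenotypic
    variance, 40% with sex-differing effects.
    """
    geno = GenoSimConfig(
        n_male=119_190, n_female=139_738, n_chrom=10, snps_per_chrom=6000,
        mean_spacing_bp=5000.0, seed=seed,
    )
    trait = TraitSimConfig(
        n_causal=150, causal_spacing_bp=2e6, per_variant_r2=3.3e-4,
        prop_gxs=0.4, gxs_scheme="mixed", seed=seed,
    )
    return geno, trait


def write_simulation(
    outdir, panel: GenotypePanel, y: PhenotypeVector, truth: SimulationTruth
) -> None:
    """Write PLINK BED/BIM/FAM, phenotype TSV and truth TSV to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_plink(panel, outdir / "genotypes")
    pd.DataFrame(
        {"individual_id": panel.individual_ids, "phenotype": y.values}
    ).to_csv(outdir / "phenotype.tsv", sep="\t", index=False)
    truth.to_frame().to_csv(outdir / "truth.tsv", sep="\t", index=False)
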