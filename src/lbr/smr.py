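"""Single-marker regression baseline with sex-stratified tests.

For each SNP, the phenotype is regressed on dosage separately within males
and within females (simple OLS with intercept).  Two tests are reported:

* ``p_diff`` — the sex-difference (heterogeneity) test,
  z = (beta_f - beta_m) / sqrt(se_f^2 + se_m^2), two-sided normal;
* ``p_any`` — an any-sex-effect test, z_m^2 + z_f^2 against chi-square(2),
  valid because the two sexes are disjoint samples.

The scan is vectorised over SNPs with the closed-form simple-regression
algebra; a SNP monomorphic within a sex gets p-values of 1 and a flag.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import GenotypePanel, PhenotypeVector

__all__ = ["smr_scan"]


def _per_sex_ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Slope, SE and a monomorphic flag for y ~ 1 + x, one SNP at a time."""
    n = X.shape[0]
    if n < 3:
        raise ValueError("need at least 3 individuals per sex for SMR")
    xc = X - X.mean(axis=0, keepdims=True)
    yc = y - y.mean()
    sxx = (xc * xc).sum(axis=0)
    mono = sxx == 0
    sxx_safe = np.where(mono, 1.0, sxx)
    beta = (xc * yc[:, None]).sum(axis=0) / sxx_safe
    rss = (yc @ yc) - beta * beta * sxx_safe
    rss = np.clip(rss, 0.0, None)
    sigma2 = rss / (n - 2)
    se = np.sqrt(np.where(mono, np.nan, sigma2 / sxx_safe))
    beta = np.where(mono, 0.0, beta)
    return beta, se, mono


def smr_scan(panel: GenotypePanel, y: PhenotypeVector) -> pd.DataFrame:
    """Genome scan of per-sex marginal effects and sex-difference tests.

    Returns one row per SNP with beta_hat_m/se_m, beta_hat_f/se_f, p_diff,
    p_any and a ``monomorphic`` flag (p-values forced to 1 where set).
    Dosages must be imputed; ``y`` must be the scaled phenotype.
    """
    if panel.has_missing():
        raise ValueError("impute missing dosages before the SMR scan")
    yv = y.values if isinstance(y, PhenotypeVector) else np.asarray(y, float)
    male = panel.is_male
    female = panel.is_female
    bm, sem, mono_m = _per_sex_ols(panel.dosages[male], yv[male])
    bf, sef, mono_f = _per_sex_ols(panel.dosages[female], yv[female])
    mono = mono_m | mono_f

    with np.errstate(invalid="ignore", divide="ignore"):
        z_diff = (bf - bm) / np.sqrt(sef**2 + sem**2)
        p_diff = 2.0 * stats.norm.sf(np.abs(z_diff))
        chi2 = (bm / sem) ** 2 + (bf / sef) ** 2
        p_any = stats.chi2.sf(chi2, df=2)
    p_diff = np.where(mono, 1.0, p_diff)
    p_any = np.where(mono, 1.0, p_any)
    # guard the open-interval invariant: a p-value of exactly 0 only occurs
    # by floating underflow
    tiny = np.finfo(float).tiny
    p_diff = np.clip(p_diff, tiny, 1.0)
    p_any = np.clip(p_any, tiny, 1.0)

    return pd.DataFrame(
        {
            "snp_id": panel.snp_ids,
            "chrom": panel.chrom,
            "bp": panel.bp,
            "beta_hat_m": bm,
            "se_m": sem,
            "beta_hat_f": bf,
            "se_f": sef,
            "p_diff": p_diff,
            "p_any": p_any,
            "monomorphic": mono,
        }
    )
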