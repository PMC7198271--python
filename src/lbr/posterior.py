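"""Postprocessing posterior samples into SNP- and window-level inferences.

Two granularities are supported, both computed from the same stitched chain:

* per SNP j: posterior means of the sex-specific effects beta_mj, beta_fj
  and the probabilities PPM (nonzero male effect), PPF (nonzero female
  effect) and PPDiff (male and female effects differ);
* per focal SNP j: an LD-defined window j* of contiguous SNPs, its
  sex-specific genetic variances sigma2_gm = var(X beta_m) and
  sigma2_gf = var(X beta_f) per draw, and the analogous probabilities
  PPMvar / PPFvar / PPDiffVar.

Because spiked-out effects are stored as EXACT zeros, "nonzero" and
"different" are indicator events on the draws, not epsilon tests: beta_mj is
nonzero iff b0j or b_mj is included, and the male/female window variances of
a draw differ iff some interaction effect inside the window is included
(otherwise beta_m = beta_f identically).  Window variances are computed on
pooled-sex centered dosages, so with a unit-variance phenotype they read as
proportions of total phenotypic variance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import GenotypePanel
from .sampler import PosteriorSamples

__all__ = [
    "SnpSummary",
    "WindowSummary",
    "sex_specific_effects",
    "snp_probabilities",
    "define_window",
    "define_all_windows",
    "window_variances",
    "window_probabilities",
    "summarize",
]


@dataclass
class SnpSummary:
    """Per-SNP posterior means and probabilities, as a DataFrame facade."""

    table: pd.DataFrame  # snp_id chrom bp mean_beta_m mean_beta_f PPM PPF PPDiff PP_any


@dataclass
class WindowSummary:
    """Per focal SNP: window extent and window-variance inferences."""

    table: pd.DataFrame  # focal snp, window bounds, mean_var_m/f, PPMvar PPFvar PPDiffVar
    windows: list  # (start_idx, end_idx) half-open per focal SNP


def sex_specific_effects(samples: PosteriorSamples) -> tuple[np.ndarray, np.ndarray]:
    """Per-draw sex-specific effects (beta_m, beta_f) = (b0+b_m, b0+b_f)."""
    return samples.beta_m(), samples.beta_f()


def snp_probabilities(samples: PosteriorSamples) -> SnpSummary:
    """SNP-level posterior summaries from the exact-zero bookkeeping.

    PPM_j is the fraction of draws in which beta_mj != 0, i.e. in which b0j
    or b_mj was included (a continuous b0 draw cannot cancel b_m exactly);
    PPDiff_j is the fraction in which the male and female effects differ,
    i.e. NOT both interaction effects spiked out.
    """
    nz0 = samples.b0 != 0
    nzm = samples.bm != 0
    nzf = samples.bf != 0
    ppm = (nz0 | nzm).mean(axis=0)
    ppf = (nz0 | nzf).mean(axis=0)
    ppdiff = (nzm | nzf).mean(axis=0)
    table = pd.DataFrame(
        {
            "snp_id": samples.snp_ids,
            "chrom": samples.chrom,
            "bp": samples.bp,
            "mean_beta_m": samples.beta_m().mean(axis=0),
            "mean_beta_f": samples.beta_f().mean(axis=0),
            "PPM": ppm,
            "PPF": ppf,
            "PPDiff": ppdiff,
            "PP_any": np.maximum(ppm, ppf),
        }
    )
    return SnpSummary(table=table)


def define_window(
    panel: GenotypePanel,
    focal_j: int,
    r2_threshold: float = 0.05,
    max_bp: int = 1_000_000,
    gap_tolerance: int = 0,
) -> tuple[int, int]:
    """LD window around a focal SNP, as a half-open index range.

    Extends left and right from ``focal_j`` while the squared Pearson
    correlation between dosages stays >= ``r2_threshold``, stopping after
    ``gap_tolerance + 1`` consecutive sub-threshold SNPs, at ``max_bp`` from
    the focal SNP, or at the chromosome end.  A monomorphic focal SNP gets a
    single-SNP window with a warning.
    """
    X = panel.dosages
    n = X.shape[0]
    xc_j = X[:, focal_j] - X[:, focal_j].mean()
    ss_j = xc_j @ xc_j
    if ss_j == 0:
        warnings.warn(f"monomorphic focal SNP {panel.snp_ids[focal_j]}; window is the SNP itself")
        return focal_j, focal_j + 1
    chrom_j = panel.chrom[focal_j]
    bp_j = panel.bp[focal_j]

    def _r2(l: int) -> float:
        xc = X[:, l] - X[:, l].mean()
        ss = xc @ xc
        if ss == 0:
            return 0.0
        r = (xc_j @ xc) / np.sqrt(ss_j * ss)
        return r * r

    lo = focal_j
    misses = 0
    l = focal_j - 1
    while l >= 0 and panel.chrom[l] == chrom_j and bp_j - panel.bp[l] <= max_bp:
        if _r2(l) >= r2_threshold:
            lo = l
            misses = 0
        else:
            misses += 1
            if misses > gap_tolerance:
                break
        l -= 1
    hi = focal_j + 1
    misses = 0
    l = focal_j + 1
    while l < panel.p and panel.chrom[l] == chrom_j and panel.bp[l] - bp_j <= max_bp:
        if _r2(l) >= r2_threshold:
            hi = l + 1
            misses = 0
        else:
            misses += 1
            if misses > gap_tolerance:
                break
        l += 1
    return lo, hi


def define_all_windows(panel: GenotypePanel, **kwargs) -> list[tuple[int, int]]:
    """One LD window per focal SNP (heavily overlapping, dynamically sized)."""
    return [define_window(panel, j, **kwargs) for j in range(panel.p)]


def window_variances(
    panel: GenotypePanel,
    windows: list[tuple[int, int]],
    beta_m: np.ndarray,
    beta_f: np.ndarray,
    sex_specific_genotypes: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-draw sex-specific window variances var(X_w beta_w).

    For each draw and window, the sample variance (denominator n-1) of the
    n-vector X_w beta_w over ALL individuals, with pooled-centered dosages.
    Computed as the quadratic form beta' C beta with C the window's dosage
    covariance matrix — algebraically identical to forming the n-vector, and
    exactly zero when the window's effects are all zero.  Returns two
    (S x n_windows) arrays (male, female).

    With ``sex_specific_genotypes`` the male (female) variance uses the
    covariance of male (female) rows only, instead of the pooled default
    that keeps both variances on the common proportion-of-total-variance
    scale.
    """
    X = panel.dosages - panel.dosages.mean(axis=0, keepdims=True)
    S = beta_m.shape[0]
    W = len(windows)
    var_m = np.zeros((S, W))
    var_f = np.zeros((S, W))
    if sex_specific_genotypes:
        rows_m, rows_f = panel.is_male, panel.is_female
    cov_cache: dict[tuple, np.ndarray] = {}

    def _cov(lo, hi, rows=None):
        key = (lo, hi, None if rows is None else rows.tobytes())
        C = cov_cache.get(key)
        if C is None:
            Xw = X[:, lo:hi] if rows is None else X[rows, lo:hi]
            Xw = Xw - Xw.mean(axis=0, keepdims=True) if rows is not None else Xw
            C = (Xw.T @ Xw) / (Xw.shape[0] - 1)
            cov_cache[key] = C
        return C

    for w, (lo, hi) in enumerate(windows):
        if sex_specific_genotypes:
            Cm, Cf = _cov(lo, hi, rows_m), _cov(lo, hi, rows_f)
        else:
            Cm = Cf = _cov(lo, hi)
        Bm = beta_m[:, lo:hi]
        Bf = beta_f[:, lo:hi]
        var_m[:, w] = np.einsum("sk,kl,sl->s", Bm, Cm, Bm)
        var_f[:, w] = np.einsum("sk,kl,sl->s", Bf, Cf, Bf)
    # quadratic forms are >= 0 up to roundoff; clip the roundoff
    np.clip(var_m, 0.0, None, out=var_m)
    np.clip(var_f, 0.0, None, out=var_f)
    return var_m, var_f


def window_probabilities(
    samples: PosteriorSamples,
    panel: GenotypePanel,
    windows: list[tuple[int, int]],
    var_m: np.ndarray | None = None,
    var_f: np.ndarray | None = None,
) -> WindowSummary:
    """Window-level posterior probabilities from exact-zero bookkeeping.

    PPMvar is the fraction of draws with any nonzero male effect (shared or
    male deviation) in the window — exactly the event sigma2_gm > 0; PPFvar
    analogous.  PPDiffVar is the fraction of draws with any included
    interaction effect in the window: when every b_m and b_f inside the
    window is zero, beta_m = beta_f = b0 identically, so the two window
    variances coincide.
    """
    if var_m is None or var_f is None:
        bm_, bf_ = sex_specific_effects(samples)
        var_m, var_f = window_variances(panel, windows, bm_, bf_)
    nz0 = samples.b0 != 0
    nzm = samples.bm != 0
    nzf = samples.bf != 0
    S, W = var_m.shape
    ppm = np.empty(W)
    ppf = np.empty(W)
    ppdiff = np.empty(W)
    for w, (lo, hi) in enumerate(windows):
        any_m = (nz0[:, lo:hi] | nzm[:, lo:hi]).any(axis=1)
        any_f = (nz0[:, lo:hi] | nzf[:, lo:hi]).any(axis=1)
        any_int = (nzm[:, lo:hi] | nzf[:, lo:hi]).any(axis=1)
        ppm[w] = any_m.mean()
        ppf[w] = any_f.mean()
        ppdiff[w] = any_int.mean()
    lows = np.array([lo for lo, _ in windows])
    highs = np.array([hi for _, hi in windows])
    table = pd.DataFrame(
        {
            "snp_id": samples.snp_ids,
            "chrom": samples.chrom,
            "bp": samples.bp,
            "window_start_bp": panel.bp[lows],
            "window_end_bp": panel.bp[highs - 1],
            "window_start_idx": lows,
            "window_end_idx": highs,
            "mean_var_m": var_m.mean(axis=0),
            "mean_var_f": var_f.mean(axis=0),
            "PPMvar": ppm,
            "PPFvar": ppf,
            "PPDiffVar": ppdiff,
        }
    )
    return WindowSummary(table=table, windows=windows)


def summarize(
    samples: PosteriorSamples,
    panel: GenotypePanel,
    r2_threshold: float = 0.05,
    max_bp: int = 1_000_000,
    gap_tolerance: int = 0,
) -> pd.DataFrame:
    """Full per-SNP output table: SNP-level and window-level inferences."""
    snp = snp_probabilities(samples).table
    windows = define_all_windows(
        panel, r2_threshold=r2_threshold, max_bp=max_bp, gap_tolerance=gap_tolerance
    )
    win = window_probabilities(samples, panel, windows).table
    return snp.merge(
        win.drop(columns=["chrom", "bp", "window_start_idx", "window_end_idx"]),
        on="snp_id",
    )
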