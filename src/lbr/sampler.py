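"""Spike-slab Gibbs sampler for the SNP-by-sex interaction model.

The model regresses a phenotype, scaled to unit variance across sexes, on
genotypes of a chromosome segment:

    y_m = 1 mu_m + X_m b0 + X_m b_m + e_m,   e_m ~ N(0, s2e_m I)
    y_f = 1 mu_f + X_f b0 + X_f b_f + e_f,   e_f ~ N(0, s2e_f I)

Each SNP effect splits into a shared component b0j and sex-specific
deviations b_mj, b_fj, so the sex-specific effects are beta_mj = b0j + b_mj
and beta_fj = b0j + b_fj.  All three effect classes k in {0, m, f} carry
independent spike-slab priors

    Pr(b_kj) = pi_k N(0, s2b_k) + (1 - pi_k) 1(b_kj = 0)

with scaled-inverse-chi-square hyperpriors on the slab variances s2b_k and
the sex-specific residual variances, and Beta hyperpriors on the inclusion
proportions pi_k.  Posterior draws keep EXACT zeros for spiked-out effects;
downstream sex-difference probabilities are indicator events on these zeros.

The per-iteration sweep (intercepts, then classes 0/m/f at each SNP in
genomic order, then variance and inclusion hyperparameters) runs in a
numba-compiled kernel; the shared-effect update is heteroskedastic because
the two sexes may have different residual variances.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from numba import njit

from .genotypes import GenotypePanel, PhenotypeVector

__all__ = [
    "LbrPrior",
    "McmcConfig",
    "FixedParams",
    "PosteriorSamples",
    "gibbs_fit",
    "log_diagnostics",
]

_CLASSES = ("shared", "male", "female")


@dataclass
class LbrPrior:
    """Hyperprior settings for the three effect classes and the residuals.

    ``slab_df``/``slab_scale`` parameterise scaled-inverse-chi-square
    hyperpriors on the slab variances (one per class 0/m/f), ``pi_a``/``pi_b``
    the Beta hyperpriors on the inclusion proportions, and
    ``residual_df``/``residual_scale`` the per-sex residual-variance
    hyperpriors (male, female).
    """

    slab_df: np.ndarray
    slab_scale: np.ndarray
    pi_a: np.ndarray
    pi_b: np.ndarray
    residual_df: np.ndarray
    residual_scale: np.ndarray

    def __post_init__(self) -> None:
        self.slab_df = np.broadcast_to(np.asarray(self.slab_df, float), (3,)).copy()
        self.slab_scale = np.broadcast_to(np.asarray(self.slab_scale, float), (3,)).copy()
        self.pi_a = np.broadcast_to(np.asarray(self.pi_a, float), (3,)).copy()
        self.pi_b = np.broadcast_to(np.asarray(self.pi_b, float), (3,)).copy()
        self.residual_df = np.broadcast_to(np.asarray(self.residual_df, float), (2,)).copy()
        self.residual_scale = np.broadcast_to(np.asarray(self.residual_scale, float), (2,)).copy()
        for name in ("slab_df", "slab_scale", "pi_a", "pi_b", "residual_df", "residual_scale"):
            if not (getattr(self, name) > 0).all():
                raise ValueError(f"{name} must be strictly positive")

    @classmethod
    def default(
        cls,
        panel: GenotypePanel | np.ndarray,
        r2: float = 0.5,
        genome_fraction: float = 1.0,
        phenotype_variance: float = 1.0,
        slab_df: float = 5.0,
        residual_df: float = 5.0,
    ) -> "LbrPrior":
        """Weakly informative defaults sized from the segment's genotypes.

        The whole-trait R² guess ``r2`` (default 0.5) is apportioned to the
        segment by ``genome_fraction`` and split equally over the three effect
        classes; the slab scale is then set so the prior-expected genetic
        variance of each class matches its share, given the prior mean of
        pi_k under Beta(1, p/50) and the summed dosage variance of the
        segment.
        """
        X = panel.dosages if isinstance(panel, GenotypePanel) else np.asarray(panel, float)
        p = X.shape[1]
        msx = float(X.var(axis=0, ddof=1).sum())
        if msx <= 0:
            raise ValueError("segment has no genotypic variance")
        pi_a, pi_b = 1.0, max(p / 50.0, 1.0)
        prior_mean_pi = pi_a / (pi_a + pi_b)
        var_target = r2 * genome_fraction * phenotype_variance / 3.0
        mean_s2b = var_target / (prior_mean_pi * msx)
        # E[scaled-inv-chi2(df, s)] = df*s/(df-2)
        slab_scale = mean_s2b * (slab_df - 2.0) / slab_df
        return cls(
            slab_df=np.full(3, slab_df),
            slab_scale=np.full(3, slab_scale),
            pi_a=np.full(3, pi_a),
            pi_b=np.full(3, pi_b),
            residual_df=np.full(2, residual_df),
            residual_scale=np.full(2, phenotype_variance),
        )


@dataclass
class McmcConfig:
    """Chain length, thinning and seed.

    (n_iter - burn_in) / thin draws are stored; at least ~100 are needed for
    stable posterior-probability estimates (the default stores 2000, giving a
    binomial SE of about 0.011 on a probability of 0.5 before autocorrelation).
    """

    n_iter: int = 12000
    burn_in: int = 2000
    thin: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.burn_in < self.n_iter):
            raise ValueError("require 0 <= burn_in < n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def n_stored(self) -> int:
        return (self.n_iter - self.burn_in + self.thin - 1) // self.thin


@dataclass
class FixedParams:
    """Optional clamps for validation runs (conjugate-limit / enumeration checks).

    Any field left None is sampled as usual.  ``pi`` and ``sigma2_b`` are
    per-class triples (shared, male, female); ``sigma2_e`` and ``intercepts``
    are per-sex pairs (male, female).
    """

    pi: Optional[np.ndarray] = None
    sigma2_b: Optional[np.ndarray] = None
    sigma2_e: Optional[np.ndarray] = None
    intercepts: Optional[np.ndarray] = None


@dataclass
class PosteriorSamples:
    """Stored MCMC draws for one segment (or a stitched genome).

    Effect arrays are draw-major (S x p) with exact zeros where the inclusion
    indicator was 0.  ``sigma2_e`` is S x 2 (male, female), ``sigma2_b`` and
    ``pi`` are S x 3 (shared, male, female).
    """

    mu_m: np.ndarray
    mu_f: np.ndarray
    b0: np.ndarray
    bm: np.ndarray
    bf: np.ndarray
    sigma2_e: np.ndarray
    sigma2_b: np.ndarray
    pi: np.ndarray
    snp_ids: np.ndarray
    chrom: np.ndarray
    bp: np.ndarray
    meta: dict = field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        return self.b0.shape[0]

    @property
    def p(self) -> int:
        return self.b0.shape[1]

    def beta_m(self) -> np.ndarray:
        """Per-draw male-specific effects beta_m = b0 + b_m."""
        return self.b0 + self.bm

    def beta_f(self) -> np.ndarray:
        """Per-draw female-specific effects beta_f = b0 + b_f."""
        return self.b0 + self.bf

    def save(self, path) -> None:
        np.savez_compressed(
            path,
            mu_m=self.mu_m, mu_f=self.mu_f, b0=self.b0, bm=self.bm, bf=self.bf,
            sigma2_e=self.sigma2_e, sigma2_b=self.sigma2_b, pi=self.pi,
            snp_ids=self.snp_ids.astype(str), chrom=self.chrom.astype(str),
            bp=self.bp, meta=np.array(repr(self.meta)),
        )

    @classmethod
    def load(cls, path) -> "PosteriorSamples":
        import ast

        with np.load(path, allow_pickle=False) as z:
            return cls(
                mu_m=z["mu_m"], mu_f=z["mu_f"], b0=z["b0"], bm=z["bm"], bf=z["bf"],
                sigma2_e=z["sigma2_e"], sigma2_b=z["sigma2_b"], pi=z["pi"],
                snp_ids=z["snp_ids"], chrom=z["chrom"], bp=z["bp"],
                meta=ast.literal_eval(str(z["meta"])),
            )


@njit(cache=True)
def _gibbs_kernel(
    XmT, XfT, ym, yf,
    slab_df, slab_scale, pi_a, pi_b, resid_df, resid_scale,
    fix_pi, fix_s2b, fix_s2e, fix_mu,
    n_iter, burn_in, thin, seed,
    mu_store, b_store, s2e_store, s2b_store, pi_store,
):  # pragma: no cover - exercised via gibbs_fit
    np.random.seed(seed)
    p, nm = XmT.shape
    nf = XfT.shape[1]

    # per-SNP sums of squares by sex (columns are centered upstream)
    cxx_m = np.empty(p)
    cxx_f = np.empty(p)
    for j in range(p):
        sm = 0.0
        for i in range(nm):
            sm += XmT[j, i] * XmT[j, i]
        cxx_m[j] = sm
        sf = 0.0
        for i in range(nf):
            sf += XfT[j, i] * XfT[j, i]
        cxx_f[j] = sf

    b = np.zeros((3, p))
    incl = np.zeros((3, p), dtype=np.uint8)
    mu = np.empty(2)
    s2e = np.empty(2)
    s2b = np.empty(3)
    pi = np.empty(3)
    for s in range(2):
        mu[s] = fix_mu[s] if np.isfinite(fix_mu[s]) else 0.0
        s2e[s] = fix_s2e[s] if np.isfinite(fix_s2e[s]) else resid_scale[s]
    for k in range(3):
        s2b[k] = fix_s2b[k] if np.isfinite(fix_s2b[k]) else slab_scale[k]
        pi[k] = fix_pi[k] if np.isfinite(fix_pi[k]) else pi_a[k] / (pi_a[k] + pi_b[k])

    em = ym - mu[0]
    ef = yf - mu[1]

    stored = 0
    for it in range(n_iter):
        # (a) intercepts, flat prior
        if not np.isfinite(fix_mu[0]):
            s = 0.0
            for i in range(nm):
                s += em[i] + mu[0]
            mnew = s / nm + np.sqrt(s2e[0] / nm) * np.random.standard_normal()
            d = mnew - mu[0]
            for i in range(nm):
                em[i] -= d
            mu[0] = mnew
        if not np.isfinite(fix_mu[1]):
            s = 0.0
            for i in range(nf):
                s += ef[i] + mu[1]
            mnew = s / nf + np.sqrt(s2e[1] / nf) * np.random.standard_normal()
            d = mnew - mu[1]
            for i in range(nf):
                ef[i] -= d
            mu[1] = mnew

        # (b) spike-slab effect updates, classes 0, m, f at each SNP
        wm = 1.0 / s2e[0]
        wf = 1.0 / s2e[1]
        for j in range(p):
            for k in range(3):
                bold = b[k, j]
                if k == 0:
                    dot_m = 0.0
                    for i in range(nm):
                        dot_m += XmT[j, i] * em[i]
                    dot_f = 0.0
                    for i in range(nf):
                        dot_f += XfT[j, i] * ef[i]
                    c = cxx_m[j] * wm + cxx_f[j] * wf
                    rhs = dot_m * wm + dot_f * wf + bold * c
                elif k == 1:
                    dot_m = 0.0
                    for i in range(nm):
                        dot_m += XmT[j, i] * em[i]
                    c = cxx_m[j] * wm
                    rhs = (dot_m + bold * cxx_m[j]) * wm
                else:
                    dot_f = 0.0
                    for i in range(nf):
                        dot_f += XfT[j, i] * ef[i]
                    c = cxx_f[j] * wf
                    rhs = (dot_f + bold * cxx_f[j]) * wf

                v = 1.0 / (c + 1.0 / s2b[k])
                mean = v * rhs
                if pi[k] >= 1.0:
                    include = True
                else:
                    log_odds = (
                        np.log(pi[k]) - np.log1p(-pi[k])
                        + 0.5 * (np.log(v) - np.log(s2b[k]))
                        + 0.5 * mean * mean / v
                    )
                    if log_odds > 35.0:
                        include = True
                    elif log_odds < -35.0:
                        include = False
                    else:
                        include = np.random.random() < 1.0 / (1.0 + np.exp(-log_odds))
                if include:
                    bnew = mean + np.sqrt(v) * np.random.standard_normal()
                    incl[k, j] = 1
                else:
                    bnew = 0.0
                    incl[k, j] = 0
                d = bnew - bold
                if d != 0.0:
                    b[k, j] = bnew
                    if k == 0:
                        for i in range(nm):
                            em[i] -= XmT[j, i] * d
                        for i in range(nf):
                            ef[i] -= XfT[j, i] * d
                    elif k == 1:
                        for i in range(nm):
                            em[i] -= XmT[j, i] * d
                    else:
                        for i in range(nf):
                            ef[i] -= XfT[j, i] * d

        # (c) slab variances, (d) inclusion proportions
        for k in range(3):
            q = 0
            ssq = 0.0
            for j in range(p):
                if incl[k, j] == 1:
                    q += 1
                    ssq += b[k, j] * b[k, j]
            if not np.isfinite(fix_s2b[k]):
                s2b[k] = (slab_df[k] * slab_scale[k] + ssq) / np.random.chisquare(
                    slab_df[k] + q
                )
            if not np.isfinite(fix_pi[k]):
                pi[k] = np.random.beta(pi_a[k] + q, pi_b[k] + p - q)

        # (e) residual variances
        if not np.isfinite(fix_s2e[0]):
            sse = 0.0
            for i in range(nm):
                sse += em[i] * em[i]
            s2e[0] = (resid_df[0] * resid_scale[0] + sse) / np.random.chisquare(
                resid_df[0] + nm
            )
        if not np.isfinite(fix_s2e[1]):
            sse = 0.0
            for i in range(nf):
                sse += ef[i] * ef[i]
            s2e[1] = (resid_df[1] * resid_scale[1] + sse) / np.random.chisquare(
                resid_df[1] + nf
            )

        if not (np.isfinite(em[0]) and np.isfinite(ef[0])):
            return -(it + 1)

        if it >= burn_in and (it - burn_in) % thin == 0:
            mu_store[stored, 0] = mu[0]
            mu_store[stored, 1] = mu[1]
            for k in range(3):
                s2b_store[stored, k] = s2b[k]
                pi_store[stored, k] = pi[k]
                for j in range(p):
                    b_store[stored, k, j] = b[k, j]
            s2e_store[stored, 0] = s2e[0]
            s2e_store[stored, 1] = s2e[1]
            stored += 1

    return stored


def gibbs_fit(
    panel_segment: GenotypePanel,
    y: PhenotypeVector,
    prior: Optional[LbrPrior] = None,
    cfg: Optional[McmcConfig] = None,
    fixed: Optional[FixedParams] = None,
    genome_fraction: float = 1.0,
) -> PosteriorSamples:
    """Draw from the joint posterior of the interaction model on one segment.

    Genotype columns are centered internally on the pooled (both-sex) mean;
    ``y`` must already be scaled to unit pooled variance and dosages imputed.
    ``fixed`` clamps chosen hyperparameters, which turns the sampler into its
    conjugate special cases used by the validation suite.
    """
    if panel_segment.p == 0:
        raise ValueError("empty segment (p=0)")
    if panel_segment.has_missing():
        raise ValueError("impute missing dosages before fitting")
    if not isinstance(y, PhenotypeVector):
        raise TypeError("y must be a PhenotypeVector (use scale_phenotype)")
    if not y.scaled:
        raise ValueError("phenotype must be scaled (pooled variance 1)")
    if len(y.values) != panel_segment.n:
        raise ValueError("phenotype length does not match panel")

    cfg = cfg or McmcConfig()
    prior = prior or LbrPrior.default(
        panel_segment, genome_fraction=genome_fraction,
        phenotype_variance=float(y.values.var(ddof=1)),
    )
    fixed = fixed or FixedParams()

    X = panel_segment.dosages - panel_segment.dosages.mean(axis=0, keepdims=True)
    male = panel_segment.is_male
    female = panel_segment.is_female
    if male.sum() == 0 or female.sum() == 0:
        raise ValueError("both sexes must be present")
    XmT = np.ascontiguousarray(X[male].T)
    XfT = np.ascontiguousarray(X[female].T)
    ym = np.ascontiguousarray(y.values[male])
    yf = np.ascontiguousarray(y.values[female])

    def _clamp(val, size):
        if val is None:
            return np.full(size, np.nan)
        return np.broadcast_to(np.asarray(val, float), (size,)).copy()

    fix_pi = _clamp(fixed.pi, 3)
    fix_s2b = _clamp(fixed.sigma2_b, 3)
    fix_s2e = _clamp(fixed.sigma2_e, 2)
    fix_mu = _clamp(fixed.intercepts, 2)

    S = cfg.n_stored
    p = panel_segment.p
    mu_store = np.empty((S, 2))
    b_store = np.empty((S, 3, p))
    s2e_store = np.empty((S, 2))
    s2b_store = np.empty((S, 3))
    pi_store = np.empty((S, 3))

    rc = _gibbs_kernel(
        XmT, XfT, ym, yf,
        prior.slab_df, prior.slab_scale, prior.pi_a, prior.pi_b,
        prior.residual_df, prior.residual_scale,
        fix_pi, fix_s2b, fix_s2e, fix_mu,
        cfg.n_iter, cfg.burn_in, cfg.thin, cfg.seed % (2**31 - 1),
        mu_store, b_store, s2e_store, s2b_store, pi_store,
    )
    if rc < 0:
        raise FloatingPointError(f"non-finite residuals at iteration {-rc - 1}")
    assert rc == S

    return PosteriorSamples(
        mu_m=mu_store[:, 0], mu_f=mu_store[:, 1],
        b0=b_store[:, 0, :], bm=b_store[:, 1, :], bf=b_store[:, 2, :],
        sigma2_e=s2e_store, sigma2_b=s2b_store, pi=pi_store,
        snp_ids=panel_segment.snp_ids, chrom=panel_segment.chrom, bp=panel_segment.bp,
        meta={
            "n_iter": cfg.n_iter, "burn_in": cfg.burn_in, "thin": cfg.thin,
            "seed": cfg.seed, "n_male": int(male.sum()), "n_female": int(female.sum()),
            "slab_df": prior.slab_df.tolist(), "slab_scale": prior.slab_scale.tolist(),
            "pi_a": prior.pi_a.tolist(), "pi_b": prior.pi_b.tolist(),
            "residual_df": prior.residual_df.tolist(),
            "residual_scale": prior.residual_scale.tolist(),
        },
    )


def _split_rhat(x: np.ndarray) -> float:
    """Split-chain potential scale reduction for a single chain of draws."""
    n = len(x) // 2
    halves = np.stack([x[:n], x[len(x) - n:]])
    within = halves.var(axis=1, ddof=1).mean()
    between = n * halves.mean(axis=1).var(ddof=1)
    if within == 0:
        return 1.0
    var_plus = (n - 1) / n * within + between / n
    return float(np.sqrt(var_plus / within))


def _mcse(x: np.ndarray, n_batches: int = 20) -> float:
    """Batch-means Monte Carlo standard error of the mean."""
    nb = min(n_batches, max(2, len(x) // 2))
    usable = (len(x) // nb) * nb
    means = x[:usable].reshape(nb, -1).mean(axis=1)
    return float(means.std(ddof=1) / np.sqrt(nb))


def log_diagnostics(samples: PosteriorSamples) -> dict:
    """Trace summaries for the global parameters of a chain.

    Returns, per parameter (sigma2_e_m, sigma2_e_f, pi_0, pi_m, pi_f): the
    posterior mean, a batch-means MC standard error, and the split-chain
    potential scale reduction (values near 1 indicate the two chain halves
    agree).
    """
    if samples.n_draws < 2:
        raise ValueError("need at least 2 stored draws for diagnostics")
    traces = {
        "sigma2_e_m": samples.sigma2_e[:, 0],
        "sigma2_e_f": samples.sigma2_e[:, 1],
        "pi_shared": samples.pi[:, 0],
        "pi_male": samples.pi[:, 1],
        "pi_female": samples.pi[:, 2],
    }
    return {
        name: {
            "mean": float(x.mean()),
            "mcse": _mcse(x),
            "split_rhat": _split_rhat(x),
        }
        for name, x in traces.items()
    }
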