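"""Power/FDR estimation against simulation truth, and enrichment testing.

Two evaluation modes mirror the two simulation designs:

* observed-causal — causal variants are on the panel; a selected SNP is a
  true discovery iff it IS a causal variant of the relevant class (G×S for
  sex-difference metrics, any-effect otherwise).
* masked-causal (target areas) — causal variants were removed; a causal
  variant is "tagged" when a selected SNP (or any SNP of a selected window)
  lies within a half-width of it (full target areas of 1 Mb, 500 kb and
  250 kb).  Power is the fraction of true variants tagged at least once; FDR
  the fraction of selections tagging none.

Conventions: selecting nothing gives FDR 0 (avoids 0/0); overlapping
selected windows are merged into distinct regions before counting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PowerFdr",
    "power_fdr_observed",
    "power_fdr_curve",
    "power_fdr_target_area",
    "merge_windows",
    "mc_aggregate",
    "hypergeom_enrichment",
]

HALF_WIDTHS_BP = (500_000, 250_000, 125_000)  # 1 Mb / 500 kb / 250 kb targets


@dataclass(frozen=True)
class PowerFdr:
    power: float
    fdr: float
    n_selected: int


def _select(scores: np.ndarray, higher_is_better: bool, top_k=None, threshold=None) -> np.ndarray:
    """Indices selected either as the best top_k or by metric threshold."""
    if (top_k is None) == (threshold is None):
        raise ValueError("give exactly one of top_k / threshold")
    s = np.asarray(scores, dtype=float)
    if top_k is not None:
        order = np.argsort(-s if higher_is_better else s, kind="stable")
        return order[: int(top_k)]
    if higher_is_better:
        return np.flatnonzero(s >= threshold)
    return np.flatnonzero(s <= threshold)


def power_fdr_observed(
    scores: np.ndarray,
    is_true: np.ndarray,
    top_k: Optional[int] = None,
    threshold: Optional[float] = None,
    higher_is_better: bool = True,
) -> PowerFdr:
    """Power/FDR when causal variants are on the panel.

    ``is_true`` flags, per scored SNP, membership in the relevant causal
    class.  Power = true selections / class size; FDR = false selections /
    selections (0 when nothing is selected).
    """
    is_true = np.asarray(is_true, dtype=bool)
    sel = _select(scores, higher_is_better, top_k, threshold)
    n_sel = len(sel)
    n_true_sel = int(is_true[sel].sum())
    n_class = int(is_true.sum())
    power = n_true_sel / n_class if n_class else 0.0
    fdr = (n_sel - n_true_sel) / n_sel if n_sel else 0.0
    return PowerFdr(power=power, fdr=fdr, n_selected=n_sel)


def power_fdr_curve(
    scores: np.ndarray,
    is_true: np.ndarray,
    ks: Sequence[int],
    higher_is_better: bool = True,
) -> pd.DataFrame:
    """Observed-causal power/FDR as a function of the number selected."""
    rows = []
    for k in ks:
        pt = power_fdr_observed(scores, is_true, top_k=k, higher_is_better=higher_is_better)
        rows.append({"k": k, "power": pt.power, "fdr": pt.fdr})
    return pd.DataFrame(rows)


def merge_windows(windows: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge half-open index windows sharing any SNP into distinct regions."""
    if not len(windows):
        return []
    ws = sorted(windows)
    merged = [list(ws[0])]
    for lo, hi in ws[1:]:
        if lo < merged[-1][1]:  # shares at least one SNP
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append([lo, hi])
    return [tuple(w) for w in merged]


def power_fdr_target_area(
    sel_chrom: np.ndarray,
    sel_start_bp: np.ndarray,
    sel_end_bp: np.ndarray,
    true_chrom: np.ndarray,
    true_bp: np.ndarray,
    half_width_bp: int,
) -> PowerFdr:
    """Masked-causal power/FDR at a target-area resolution.

    Selections are bp intervals (a single SNP has start == end; a window
    spans its SNPs).  A causal variant is tagged when a selection comes
    within ``half_width_bp`` of it on the same chromosome; a variant tagged
    by several selections counts once, and each of those selections is true.
    """
    sel_chrom = np.asarray(sel_chrom)
    sel_start = np.asarray(sel_start_bp, dtype=np.int64)
    sel_end = np.asarray(sel_end_bp, dtype=np.int64)
    true_chrom = np.asarray(true_chrom)
    true_bp = np.asarray(true_bp, dtype=np.int64)
    n_sel = len(sel_start)
    n_true = len(true_bp)
    if n_true == 0:
        return PowerFdr(power=0.0, fdr=1.0 if n_sel else 0.0, n_selected=n_sel)
    tagged = np.zeros(n_true, dtype=bool)
    sel_is_true = np.zeros(n_sel, dtype=bool)
    for c in pd.unique(true_chrom):
        t_idx = np.flatnonzero(true_chrom == c)
        s_idx = np.flatnonzero(sel_chrom == c)
        if not len(s_idx):
            continue
        pos = true_bp[t_idx]
        order = np.argsort(pos)
        pos_sorted = pos[order]
        lo = np.searchsorted(pos_sorted, sel_start[s_idx] - half_width_bp, side="left")
        hi = np.searchsorted(pos_sorted, sel_end[s_idx] + half_width_bp, side="right")
        hit = hi > lo
        sel_is_true[s_idx] = hit
        for si, l, h in zip(s_idx, lo, hi):
            if h > l:
                tagged[t_idx[order[l:h]]] = True
    power = tagged.mean()
    fdr = float((~sel_is_true).sum() / n_sel) if n_sel else 0.0
    return PowerFdr(power=float(power), fdr=fdr, n_selected=n_sel)


def mc_aggregate(values: Sequence[float]) -> dict:
    """Mean and normal-approximation 95% CI over Monte Carlo replicates."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("no replicates")
    mean = float(v.mean())
    if v.size == 1:
        return {"mean": mean, "ci_low": np.nan, "ci_high": np.nan, "n": 1, "ci_defined": False}
    se = v.std(ddof=1) / np.sqrt(v.size)
    return {
        "mean": mean,
        "ci_low": float(mean - 1.96 * se),
        "ci_high": float(mean + 1.96 * se),
        "n": int(v.size),
        "ci_defined": True,
    }


def hypergeom_enrichment(selected: set, annotated: set, universe: set) -> float:
    """Upper-tail hypergeometric enrichment p-value P(X >= overlap).

    Population ``universe``, success set ``annotated``, draws ``selected``.
    Both sets must be subsets of the universe.
    """
    selected, annotated, universe = set(selected), set(annotated), set(universe)
    if not selected <= universe:
        raise ValueError("selected set is not a subset of the universe")
    if not annotated <= universe:
        raise ValueError("annotated set is not a subset of the universe")
    M = len(universe)
    K = len(annotated)
    N = len(selected)
    k = len(selected & annotated)
    return float(stats.hypergeom.sf(k - 1, M, K, N))
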