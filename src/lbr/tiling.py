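"""Segmenting the genome into core blocks with LD buffers, and stitching.

A genome-wide joint fit is computationally out of reach at biobank scale, but
LD in unstructured human populations vanishes within 1-2 Mb, so the model is
fit on long overlapping segments instead: consecutive "core" blocks of
``core_size`` SNPs, each extended by ``buffer_size`` flanking SNPs on either
side (clipped at chromosome ends).  Only the core SNPs' posterior samples are
retained; buffer SNPs exist solely to absorb LD with neighbouring segments.

Stitching concatenates core samples across segments, treating draw t of every
segment as draw t of a genome-wide chain (segments are fit independently with
deterministic per-segment seeds, so cross-segment posterior dependence beyond
the buffer span is assumed negligible).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence

import numpy as np
import pandas as pd

from .genotypes import GenotypePanel
from .sampler import PosteriorSamples

__all__ = ["Segment", "SegmentPlan", "plan_segments", "stitch", "segment_seed"]


@dataclass(frozen=True)
class Segment:
    """One fitting unit: a core SNP interval plus its buffered fit interval.

    Indices are global SNP indices into the panel, half-open [start, end).
    """

    chrom: str
    core_start: int
    core_end: int
    fit_start: int
    fit_end: int

    @property
    def core_slice(self) -> slice:
        return slice(self.core_start, self.core_end)

    @property
    def fit_slice(self) -> slice:
        return slice(self.fit_start, self.fit_end)


@dataclass
class SegmentPlan:
    segments: List[Segment]
    p_total: int

    def __post_init__(self) -> None:
        covered = np.zeros(self.p_total, dtype=int)
        for s in self.segments:
            if not (s.fit_start <= s.core_start < s.core_end <= s.fit_end):
                raise ValueError(f"fit interval does not contain core: {s}")
            covered[s.core_slice] += 1
        if not (covered == 1).all():
            raise ValueError("core intervals must cover every SNP exactly once")

    def __len__(self) -> int:
        return len(self.segments)

    def __iter__(self):
        return iter(self.segments)

    def to_frame(self, panel: GenotypePanel) -> pd.DataFrame:
        """Plan as a table with bp coordinates, ready to write as TSV."""
        rows = []
        for i, s in enumerate(self.segments):
            rows.append(
                {
                    "segment_id": i,
                    "chrom": s.chrom,
                    "core_start_bp": int(panel.bp[s.core_start]),
                    "core_end_bp": int(panel.bp[s.core_end - 1]),
                    "fit_start_bp": int(panel.bp[s.fit_start]),
                    "fit_end_bp": int(panel.bp[s.fit_end - 1]),
                    "n_core": s.core_end - s.core_start,
                    "n_fit": s.fit_end - s.fit_start,
                }
            )
        return pd.DataFrame(rows)


def plan_segments(
    panel: GenotypePanel, core_size: int = 1500, buffer_size: int = 250
) -> SegmentPlan:
    """Partition the panel into per-chromosome cores with flanking buffers.

    Each chromosome is cut into consecutive cores of ``core_size`` SNPs (the
    last core keeps the remainder); fit windows extend cores by
    ``buffer_size`` SNPs on each side, truncated at chromosome boundaries —
    buffers never cross chromosomes.  The panel must be sorted by
    (chromosome, bp); bp order within chromosomes is enforced by the panel
    itself, but a chromosome appearing in two separate blocks is rejected.
    """
    chroms = pd.unique(panel.chrom)
    segments: List[Segment] = []
    offset = 0
    for c in chroms:
        idx = np.flatnonzero(panel.chrom == c)
        if idx[0] != offset or np.any(np.diff(idx) != 1):
            raise ValueError("panel is not sorted into contiguous chromosome blocks")
        n_c = len(idx)
        lo, hi = offset, offset + n_c
        pos = lo
        while pos < hi:
            core_end = min(pos + core_size, hi)
            segments.append(
                Segment(
                    chrom=str(c),
                    core_start=pos,
                    core_end=core_end,
                    fit_start=max(pos - buffer_size, lo),
                    fit_end=min(core_end + buffer_size, hi),
                )
            )
            pos = core_end
        offset = hi
    return SegmentPlan(segments=segments, p_total=panel.p)


def segment_seed(global_seed: int, segment_index: int) -> int:
    """Deterministic per-segment seed from the global seed (below 2**31)."""
    return int(
        np.random.SeedSequence([global_seed, segment_index]).generate_state(1)[0]
        % (2**31 - 1)
    )


def stitch(
    per_segment_samples: Sequence[PosteriorSamples], plan: SegmentPlan
) -> PosteriorSamples:
    """Concatenate core-SNP posterior samples into a genome-wide view.

    Each SNP's effect samples come from the unique segment whose CORE owns
    it; buffer copies are discarded.  Draw t of every segment is aligned as
    draw t of the result.  Global parameters (intercepts, variances, pi) are
    per-segment quantities; the stitched object carries the first segment's
    traces for interface compatibility and keeps all of them in
    ``meta["per_segment"]``.
    """
    if len(per_segment_samples) != len(plan.segments):
        raise ValueError("need exactly one sample set per planned segment")
    counts = {s.n_draws for s in per_segment_samples}
    if len(counts) != 1:
        raise ValueError(f"stored draw counts differ between segments: {sorted(counts)}")
    S = counts.pop()
    p = plan.p_total
    b0 = np.empty((S, p))
    bm = np.empty((S, p))
    bf = np.empty((S, p))
    snp_ids = np.empty(p, dtype=object)
    chrom = np.empty(p, dtype=object)
    bp = np.empty(p, dtype=np.int64)
    for seg, samp in zip(plan.segments, per_segment_samples):
        local = slice(seg.core_start - seg.fit_start, seg.core_end - seg.fit_start)
        b0[:, seg.core_slice] = samp.b0[:, local]
        bm[:, seg.core_slice] = samp.bm[:, local]
        bf[:, seg.core_slice] = samp.bf[:, local]
        snp_ids[seg.core_slice] = samp.snp_ids[local]
        chrom[seg.core_slice] = samp.chrom[local]
        bp[seg.core_slice] = samp.bp[local]
    first = per_segment_samples[0]
    return PosteriorSamples(
        mu_m=first.mu_m, mu_f=first.mu_f, b0=b0, bm=bm, bf=bf,
        sigma2_e=first.sigma2_e, sigma2_b=first.sigma2_b, pi=first.pi,
        snp_ids=snp_ids, chrom=chrom, bp=bp,
        meta={
            "stitched": True,
            "n_segments": len(plan.segments),
            "per_segment": [s.meta for s in per_segment_samples],
        },
    )
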