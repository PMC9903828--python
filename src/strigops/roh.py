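"""Runs of homozygosity: sliding-window detection, F_ROH, and the LoF-in-ROH contrast.

The detector follows the PLINK-style windowed rule: windows of a fixed SNP
count slide one SNP at a time; a SNP is "in run" when a sufficient fraction of
the windows covering it are homozygous; maximal in-run stretches are then
split at large inter-SNP gaps and filtered on SNP count, physical length,
SNP density and heterozygote count.  Only windows fully inside a chromosome
are counted, so edge SNPs overlap fewer windows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .variants import GenotypeMatrix, SiteAnnotation

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RohParams:
    """Window and segment parameters of the ROH caller.

    Defaults are the primary configuration used for kākāpō; ``strict()``
    returns the stricter sensitivity-check variant (max 1 het per segment,
    density 100 kb/SNP... gap 500 kb).
    """

    window_snp: int = 100        # SNPs per sliding window
    window_het: int = 1          # max het calls for a window to be homozygous
    window_threshold: float = 0.05  # min fraction of homozygous windows per SNP
    min_snp: int = 25            # min SNPs per segment
    min_kb: float = 100.0        # min segment length (kb)
    density_kb: float = 50.0     # max kb per SNP (mean density)
    gap_kb: float = 1000.0       # max gap between neighboring SNPs (kb)
    seg_het: int = 750           # max het calls per segment

    def __post_init__(self) -> None:
        for name in ("window_snp", "window_threshold", "min_snp", "min_kb",
                     "density_kb", "gap_kb"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.window_het < 0 or self.seg_het < 0:
            raise ValueError("het limits must be nonnegative")
        if self.min_kb > self.gap_kb:
            raise ValueError("min_kb must not exceed gap_kb")

    def strict(self) -> "RohParams":
        return replace(self, seg_het=1, density_kb=100.0, gap_kb=500.0,
                       min_kb=min(self.min_kb, 500.0))


@dataclass
class RohSegment:
    """One run of homozygosity; 1-based inclusive SNP-boundary coordinates."""

    chrom: str
    start: int
    end: int
    n_snps: int
    n_het: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def detect_roh(gm: GenotypeMatrix, individual: str,
               params: RohParams = RohParams()) -> List[RohSegment]:
    """Call ROH segments for one individual from a complete genotype matrix."""
    if not gm.is_complete:
        raise ValueError("detect_roh requires complete genotypes")
    col = gm.sample_index(individual)
    segments: List[RohSegment] = []
    for c in pd.unique(gm.chrom):
        m = gm.chrom == c
        pos = gm.pos[m]
        het = gm.dosage[m, col] == 1
        segments.extend(_detect_chrom(str(c), pos, het, params))
    return segments


def detect_roh_all(gm: GenotypeMatrix, params: RohParams = RohParams()
                   ) -> Dict[str, List[RohSegment]]:
    return {str(s): detect_roh(gm, str(s), params) for s in gm.samples}


def _detect_chrom(chrom: str, pos: np.ndarray, het: np.ndarray,
                  params: RohParams) -> List[RohSegment]:
    n = len(pos)
    W = params.window_snp
    if n < W:
        logger.warning("chromosome %s has %d < %d SNPs; no ROH calls", chrom, n, W)
        return []
    # het count per window [i, i+W)
    cs = np.concatenate([[0], np.cumsum(het)])
    win_het = cs[W:] - cs[:-W]                     # length n-W+1
    hom_win = (win_het <= params.window_het).astype(np.int64)
    # for SNP i, windows j in [max(0, i-W+1), min(i, n-W)] cover it
    hw = np.concatenate([[0], np.cumsum(hom_win)])
    i = np.arange(n)
    j_lo = np.maximum(0, i - W + 1)
    j_hi = np.minimum(i, n - W)
    n_windows = j_hi - j_lo + 1
    n_hom = hw[j_hi + 1] - hw[j_lo]
    in_run = n_hom / n_windows >= params.window_threshold

    segments: List[RohSegment] = []
    for s, e in _runs(in_run):
        for s2, e2 in _split_gaps(pos, s, e, params.gap_kb * 1000.0):
            seg = _filter_candidate(chrom, pos, het, s2, e2, params)
            if seg is not None:
                segments.append(seg)
    return segments


def _runs(mask: np.ndarray) -> List[tuple]:
    """Maximal [start, end] index runs of True."""
    idx = np.flatnonzero(mask)
    if len(idx) == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[idx[0]], idx[breaks + 1]])
    ends = np.concatenate([idx[breaks], [idx[-1]]])
    return list(zip(starts, ends))


def _split_gaps(pos: np.ndarray, s: int, e: int, max_gap_bp: float) -> List[tuple]:
    if e == s:
        return [(s, e)]
    gaps = np.diff(pos[s:e + 1])
    cut = np.flatnonzero(gaps > max_gap_bp)
    if len(cut) == 0:
        return [(s, e)]
    pieces = []
    start = s
    for k in cut:
        pieces.append((start, s + k))
        start = s + k + 1
    pieces.append((start, e))
    return pieces


def _filter_candidate(chrom: str, pos: np.ndarray, het: np.ndarray,
                      s: int, e: int, params: RohParams) -> Optional[RohSegment]:
    n_snps = e - s + 1
    length = int(pos[e] - pos[s] + 1)
    if n_snps < params.min_snp:
        return None
    if length < params.min_kb * 1000.0:
        return None
    if length / n_snps > params.density_kb * 1000.0:
        return None
    n_het = int(het[s:e + 1].sum())
    if n_het > params.seg_het:
        return None
    return RohSegment(chrom=chrom, start=int(pos[s]), end=int(pos[e]),
                      n_snps=n_snps, n_het=n_het)


# --------------------------------------------------------------------------
# F_ROH
# --------------------------------------------------------------------------

@dataclass
class FrohResult:
    """Fraction of the genome inside ROH at each minimum-length threshold."""

    froh: Dict[int, float]
    genome_length: int
    total_roh_bp: Dict[int, int]


def froh(segments: Sequence[RohSegment], genome_length: int,
         min_lengths: Sequence[int] = (100_000, 2_000_000)) -> FrohResult:
    """F_ROH = summed length of segments >= threshold / genome length."""
    if genome_length <= 0:
        raise ValueError("genome_length must be positive")
    fr, bp = {}, {}
    for t in min_lengths:
        total = sum(seg.length for seg in segments if seg.length >= t)
        bp[int(t)] = total
        fr[int(t)] = total / genome_length
    return FrohResult(froh=fr, genome_length=genome_length, total_roh_bp=bp)


def froh_table(segments_by_individual: Dict[str, List[RohSegment]],
               genome_length: int,
               min_lengths: Sequence[int] = (100_000, 2_000_000)) -> pd.DataFrame:
    rows = []
    for sample, segs in segments_by_individual.items():
        res = froh(segs, genome_length, min_lengths)
        rows.append({"sample": sample, "n_segments": len(segs),
                     **{f"froh_ge_{t}": res.froh[t] for t in res.froh}})
    return pd.DataFrame(rows)


def segments_to_bed(segments: Sequence[RohSegment]) -> pd.DataFrame:
    """BED-style frame (0-based half-open) for export."""
    return pd.DataFrame(
        [(s.chrom, s.start - 1, s.end, s.n_snps, s.n_het) for s in segments],
        columns=["chrom", "start", "end", "n_snps", "n_het"])


# --------------------------------------------------------------------------
# LoF rates inside vs outside ROH
# --------------------------------------------------------------------------

@dataclass
class LofRohContrast:
    """Per-individual LoF rates in/out of ROH, normalized by synonymous hom rates.

    rate_in  = (# HIGH-impact carrier sites inside the individual's ROH)
             / (# homozygous LOW-impact sites inside the ROH)
    rate_out is the analogue outside ROH.  The paired two-sided t test runs
    across individuals with both rates defined.
    """

    table: pd.DataFrame
    t_stat: float
    p_value: float
    n_tested: int
    excluded: List[str]


def _in_roh_mask(gm: GenotypeMatrix, segments: Sequence[RohSegment]) -> np.ndarray:
    mask = np.zeros(gm.n_sites, dtype=bool)
    by_chrom: Dict[str, list] = {}
    for seg in segments:
        by_chrom.setdefault(seg.chrom, []).append((seg.start, seg.end))
    for c, ivs in by_chrom.items():
        m = gm.chrom == c
        if not m.any():
            continue
        ivs.sort()
        starts = np.array([a for a, _ in ivs])
        ends = np.array([b for _, b in ivs])
        p = gm.pos[m]
        j = np.searchsorted(starts, p, side="right") - 1
        hit = (j >= 0) & (p <= ends[np.clip(j, 0, None)])
        mask[np.flatnonzero(m)[hit]] = True
    return mask


def lof_roh_contrast(gm: GenotypeMatrix, ann: SiteAnnotation,
                     segments_by_individual: Dict[str, List[RohSegment]],
                     lof_hom_only: bool = False) -> LofRohContrast:
    """Contrast LoF carrier rates inside vs outside ROH per individual.

    LoF sites count any site the individual carries (dosage >= 1), or only
    homozygous-derived sites with ``lof_hom_only``; the normalizer is always
    homozygous synonymous (LOW) sites in the same regions.
    """
    if not gm.is_complete:
        raise ValueError("lof_roh_contrast requires complete genotypes")
    is_high = ann.impact == "HIGH"
    is_low = ann.impact == "LOW"
    rows, excluded = [], []
    for sample, segs in segments_by_individual.items():
        col = gm.sample_index(sample)
        dos = gm.dosage[:, col]
        lof_carrier = (dos == 2) if lof_hom_only else (dos >= 1)
        syn_hom = dos == 2
        inside = _in_roh_mask(gm, segs)
        n_lof_in = int((is_high & lof_carrier & inside).sum())
        n_syn_in = int((is_low & syn_hom & inside).sum())
        n_lof_out = int((is_high & lof_carrier & ~inside).sum())
        n_syn_out = int((is_low & syn_hom & ~inside).sum())
        rate_in = n_lof_in / n_syn_in if n_syn_in > 0 else np.nan
        rate_out = n_lof_out / n_syn_out if n_syn_out > 0 else np.nan
        if not (np.isfinite(rate_in) and np.isfinite(rate_out)):
            excluded.append(sample)
        rows.append({"sample": sample, "n_lof_in": n_lof_in, "n_syn_in": n_syn_in,
                     "n_lof_out": n_lof_out, "n_syn_out": n_syn_out,
                     "rate_in": rate_in, "rate_out": rate_out,
                     "diff": rate_in - rate_out})
    table = pd.DataFrame(rows)
    ok = table.dropna(subset=["rate_in", "rate_out"])
    if len(ok) >= 2:
        res = stats.ttest_rel(ok["rate_in"], ok["rate_out"])
        t, p = float(res.statistic), float(res.pvalue)
    else:
        t, p = np.nan, np.nan
    return LofRohContrast(table=table, t_stat=t, p_value=p,
                          n_tested=len(ok), excluded=excluded)
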