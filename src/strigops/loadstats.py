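"""Mutational-load and diversity statistics on polarized genotype matrices.

Implements the per-individual GERP-weighted relative load, impact-category
counts split by het/hom state, the R_xy derived-allele frequency ratio with a
block jackknife, the D_ij genotype distance matrix with a neighbor-joining
tree, windowed nucleotide diversity and per-individual heterozygosity.

All operations require complete (no missing genotypes), polarized matrices:
dosage = derived-allele count.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .variants import GenotypeMatrix, SiteAnnotation

#: impact categories that carry counts (NONE is uncategorized filler)
COUNT_CATEGORIES = ("LOW", "MODERATE", "HIGH", "MODIFIER")


def _require_complete(gm: GenotypeMatrix, op: str) -> None:
    if not gm.is_complete:
        raise ValueError(f"{op} requires a complete matrix; run filter_complete first")


# --------------------------------------------------------------------------
# GERP-weighted relative load
# --------------------------------------------------------------------------

@dataclass
class RelativeLoadResult:
    """Per-individual GERP-weighted relative mutational load.

    load = sum over sites with GERP > threshold of (derived dosage x GERP)
           / total derived alleles over *all* sites.
    Heterozygous sites count one derived allele, homozygous-derived two.
    """

    table: pd.DataFrame  # sample, population, weighted_sum, n_derived, load
    threshold: float


def relative_load(gm: GenotypeMatrix, ann: SiteAnnotation,
                  threshold: float = 2.0) -> RelativeLoadResult:
    _require_complete(gm, "relative_load")
    gerp = np.nan_to_num(ann.gerp, nan=-np.inf)
    constrained = gerp > threshold
    dosage = gm.dosage.astype(np.float64)
    weighted = dosage[constrained].T @ ann.gerp[constrained] if constrained.any() \
        else np.zeros(gm.n_samples)
    total = dosage.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        load = np.where(total > 0, weighted / total, np.nan)
    table = pd.DataFrame({
        "sample": gm.samples, "population": gm.populations,
        "weighted_sum": weighted, "n_derived": total.astype(np.int64),
        "load": load,
    })
    return RelativeLoadResult(table=table, threshold=threshold)


# --------------------------------------------------------------------------
# Impact-category counts and Welch tests
# --------------------------------------------------------------------------

@dataclass
class ImpactCounts:
    """Het/hom derived counts per individual and impact category.

    ``tests`` holds Welch two-sample t tests between two named populations for
    each category and genotype state (empty when no populations were given).
    """

    table: pd.DataFrame  # sample, population, category, het, hom, alleles
    tests: pd.DataFrame


def _welch(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float]:
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.pvalue), float(res.df)


def significance_stars(p: float) -> str:
    """Figure-style significance marks (*** p<0.001, ** p<0.01, * p<0.05)."""
    if not np.isfinite(p):
        return ""
    return "***" if p < 0.001 else "**" if p < 0.01 else "*" if p < 0.05 else "ns"


def impact_counts(gm: GenotypeMatrix, ann: SiteAnnotation,
                  pop_x: Optional[str] = None, pop_y: Optional[str] = None
                  ) -> ImpactCounts:
    _require_complete(gm, "impact_counts")
    rows = []
    for cat in COUNT_CATEGORIES:
        sites = ann.impact == cat
        d = gm.dosage[sites]
        het = (d == 1).sum(axis=0).astype(np.int64)
        hom = (d == 2).sum(axis=0).astype(np.int64)
        for j in range(gm.n_samples):
            rows.append((gm.samples[j], gm.populations[j], cat,
                         int(het[j]), int(hom[j]), int(het[j] + 2 * hom[j])))
    table = pd.DataFrame(rows, columns=["sample", "population", "category",
                                        "het", "hom", "alleles"])

    tests = pd.DataFrame(columns=["category", "metric", "mean_x", "mean_y",
                                  "t", "df", "p", "stars"])
    if pop_x is not None and pop_y is not None:
        recs = []
        for cat in COUNT_CATEGORIES:
            sub = table[table["category"] == cat]
            for metric in ("het", "hom", "alleles"):
                a = sub.loc[sub["population"] == pop_x, metric].to_numpy(float)
                b = sub.loc[sub["population"] == pop_y, metric].to_numpy(float)
                t, p, df = _welch(a, b)
                recs.append((cat, metric, a.mean(), b.mean(), t, df, p,
                             significance_stars(p)))
        tests = pd.DataFrame(recs, columns=["category", "metric", "mean_x",
                                            "mean_y", "t", "df", "p", "stars"])
    return ImpactCounts(table=table, tests=tests)


# --------------------------------------------------------------------------
# R_xy with block jackknife
# --------------------------------------------------------------------------

@dataclass
class RxyResult:
    """R_xy = sum_i f_x(1-f_y) / sum_i f_y(1-f_x) over eligible category sites.

    A value of 1 means no frequency change between the populations; values
    above 1 mean a frequency decrease in population y relative to x, and
    values below 1 a relative deficit in population x (the orientation used
    when contrasting an island population x against a mainland reference y).
    The standard error comes from a delete-one-block jackknife over
    consecutive blocks of eligible sites in genome order.
    """

    estimate: float
    se: float
    ci_low: float
    ci_high: float
    n_sites: int
    n_blocks: int
    block_size: int
    status: str  # "ok" | "undefined" | "no_ci"
    eligibility: str


def rxy_from_freqs(fx: np.ndarray, fy: np.ndarray) -> float:
    """Point estimate of R_xy from per-site derived-allele frequencies."""
    fx = np.asarray(fx, dtype=float)
    fy = np.asarray(fy, dtype=float)
    num = float(np.sum(fx * (1.0 - fy)))
    den = float(np.sum(fy * (1.0 - fx)))
    if den == 0.0:
        return np.nan
    return num / den


def _jackknife_blocks(n: int, block: int) -> list[slice]:
    """Consecutive blocks; a final short block is kept if >= block/2 else merged."""
    if n <= 0:
        return []
    edges = list(range(0, n, block))
    blocks = [slice(s, min(s + block, n)) for s in edges]
    if len(blocks) > 1 and (blocks[-1].stop - blocks[-1].start) < block / 2:
        last = blocks.pop()
        prev = blocks.pop()
        blocks.append(slice(prev.start, last.stop))
    return blocks


def rxy(gm: GenotypeMatrix, ann: SiteAnnotation, pop_x: str, pop_y: str,
        category: str = "HIGH", block: int = 1000,
        eligibility: str = "intersection") -> RxyResult:
    """R_xy for one impact category between two populations.

    Parameters
    ----------
    eligibility : {"intersection", "union"}
        Which sites enter the sums: ``intersection`` requires at least one
        derived allele in *each* population (default); ``union`` requires at
        least one derived allele across the pooled populations.
    """
    _require_complete(gm, "rxy")
    if eligibility not in ("intersection", "union"):
        raise ValueError("eligibility must be 'intersection' or 'union'")
    sites = np.flatnonzero(ann.impact == category)
    dx, nx = gm.take_sites(sites).derived_counts(pop_x) if len(sites) else (np.array([]),) * 2
    dy, ny = gm.take_sites(sites).derived_counts(pop_y) if len(sites) else (np.array([]),) * 2
    if len(sites) == 0:
        return RxyResult(np.nan, np.nan, np.nan, np.nan, 0, 0, block,
                         "undefined", eligibility)
    if eligibility == "intersection":
        elig = (dx >= 1) & (dy >= 1)
    else:
        elig = (dx + dy) >= 1
    fx = dx[elig] / nx[elig]
    fy = dy[elig] / ny[elig]
    num_i = fx * (1.0 - fy)
    den_i = fy * (1.0 - fx)
    n_used = int(elig.sum())
    S_num, S_den = float(num_i.sum()), float(den_i.sum())
    if S_den == 0.0 or n_used == 0:
        return RxyResult(np.nan, np.nan, np.nan, np.nan, n_used, 0, block,
                         "undefined", eligibility)
    est = S_num / S_den

    blocks = _jackknife_blocks(n_used, block)
    if len(blocks) < 2:
        return RxyResult(est, np.nan, np.nan, np.nan, n_used, len(blocks),
                         block, "no_ci", eligibility)
    thetas = []
    for sl in blocks:
        num_j = S_num - float(num_i[sl].sum())
        den_j = S_den - float(den_i[sl].sum())
        thetas.append(num_j / den_j if den_j != 0 else np.nan)
    thetas = np.asarray(thetas, dtype=float)
    ok = np.isfinite(thetas)
    g = int(ok.sum())
    if g < 2:
        return RxyResult(est, np.nan, np.nan, np.nan, n_used, g, block,
                         "no_ci", eligibility)
    se = float(np.sqrt((g - 1) / g * np.sum((thetas[ok] - thetas[ok].mean()) ** 2)))
    return RxyResult(est, se, est - 1.96 * se, est + 1.96 * se,
                     n_used, g, block, "ok", eligibility)


# --------------------------------------------------------------------------
# Genotype distance matrix and NJ tree
# --------------------------------------------------------------------------

@dataclass
class DistanceMatrix:
    """Pairwise genotype distance D_ij.

    Per site: d = 0 for identical homozygotes, 0.5 when either genotype is
    heterozygous, 1 for opposite homozygotes.  D_ij is the per-site mean
    (normalization "sites"), or the sum divided by a physical region length
    (normalization "bp").
    """

    D: np.ndarray
    samples: np.ndarray
    n_sites: int
    normalization: str
    region_length: Optional[int] = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.D, index=self.samples, columns=self.samples)


def site_distance(d_i: int, d_j: int) -> float:
    """Distance between two diploid dosages at one biallelic site."""
    if d_i == 1 or d_j == 1:
        return 0.5
    return abs(d_i - d_j) / 2.0


def distance_matrix(gm: GenotypeMatrix, normalization: str = "sites",
                    region_length: Optional[int] = None) -> DistanceMatrix:
    _require_complete(gm, "distance_matrix")
    if normalization not in ("sites", "bp"):
        raise ValueError("normalization must be 'sites' or 'bp'")
    n = gm.n_samples
    M = gm.n_sites
    if normalization == "bp":
        L = region_length if region_length is not None else gm.covered_span()
    else:
        L = M
    D = np.zeros((n, n), dtype=float)
    dosage = gm.dosage
    for i in range(n):
        di = dosage[:, i]
        for j in range(i + 1, n):
            dj = dosage[:, j]
            het = (di == 1) | (dj == 1)
            d = np.where(het, 0.5, np.abs(di - dj) / 2.0).sum()
            D[i, j] = D[j, i] = d / L if L else 0.0
    return DistanceMatrix(D=D, samples=gm.samples, n_sites=M,
                          normalization=normalization,
                          region_length=(L if normalization == "bp" else None))


def nj_tree(dm: DistanceMatrix) -> str:
    """Unrooted neighbor-joining (Saitou-Nei) tree as a newick string."""
    if len(dm.samples) < 3:
        raise ValueError("neighbor joining needs at least 3 individuals")
    import skbio
    from skbio.tree import nj

    sk = skbio.DistanceMatrix(dm.D, ids=[str(s) for s in dm.samples])
    tree = nj(sk)
    buf = io.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue().strip()


# --------------------------------------------------------------------------
# Windowed nucleotide diversity and individual heterozygosity
# --------------------------------------------------------------------------

@dataclass
class DiversityResult:
    windows: pd.DataFrame      # chrom, start, end, n_sites, pi (per-site)
    heterozygosity: pd.DataFrame  # sample, population, n_het, kb, het_per_kb
    window_size: int


def diversity(gm: GenotypeMatrix, window: int = 10_000,
              population: Optional[str] = None) -> DiversityResult:
    """Windowed nucleotide diversity and per-individual heterozygosity.

    Per site the unbiased pairwise-difference estimator 2 f (1-f) n/(n-1) is
    used (n = called alleles); window pi is the site sum divided by the window
    length in bp.  Windows tile each chromosome's covered range; empty windows
    report pi = 0 with a zero site count.
    """
    _require_complete(gm, "diversity")
    cols = gm.pop_indices(population) if population else np.arange(gm.n_samples)
    dosage = gm.dosage[:, cols]
    n_alleles = 2 * len(cols)
    if n_alleles < 2:
        raise ValueError("need at least one diploid individual")
    f = dosage.sum(axis=1) / n_alleles
    per_site = 2.0 * f * (1.0 - f) * n_alleles / (n_alleles - 1)

    rows = []
    for c in pd.unique(gm.chrom):
        m = gm.chrom == c
        pos = gm.pos[m]
        vals = per_site[m]
        lo = int((pos.min() - 1) // window) * window + 1
        hi = int(pos.max())
        for start in range(lo, hi + 1, window):
            end = start + window - 1
            inw = (pos >= start) & (pos <= end)
            rows.append((c, start, end, int(inw.sum()),
                         float(vals[inw].sum()) / window))
    windows = pd.DataFrame(rows, columns=["chrom", "start", "end", "n_sites", "pi"])

    kb = gm.covered_span() / 1000.0
    het = (gm.dosage == 1).sum(axis=0).astype(np.int64)
    het_df = pd.DataFrame({
        "sample": gm.samples, "population": gm.populations, "n_het": het,
        "kb": kb, "het_per_kb": het / kb if kb > 0 else np.nan,
    })
    return DiversityResult(windows=windows, heterozygosity=het_df, window_size=window)
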