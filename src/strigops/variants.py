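"""Genotype data model: VCF ingestion, ancestral-allele polarization, filtering, masking.

All downstream statistics operate on a :class:`GenotypeMatrix` of derived-allele
dosages (0/1/2 per diploid individual) together with a 1:1 aligned
:class:`SiteAnnotation` carrying per-site GERP conservation scores, functional
impact categories and ancestral-allele calls.

Coordinate conventions: sites are 1-based inclusive (VCF dialect) internally;
BED mask intervals are 0-based half-open and converted at the boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Union

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

IMPACT_LEVELS = ("LOW", "MODERATE", "HIGH", "MODIFIER", "NONE")
#: ancestral-allele symbols treated as unknown
UNKNOWN_ANCESTRAL = {".", "", "N", "n", "-"}

MISSING = -1  # dosage sentinel before filter_complete


def _as_str_array(x) -> np.ndarray:
    return np.asarray(x, dtype=object)


@dataclass
class GenotypeMatrix:
    """Biallelic SNP dosages (sites x individuals) with positions and population labels.

    ``dosage`` counts copies of the ALT allele as read from a VCF; after
    :func:`polarize` it counts copies of the *derived* allele.  A value of -1
    marks a missing genotype and is only representable before
    :func:`filter_complete`.
    """

    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    dosage: np.ndarray
    samples: np.ndarray
    populations: np.ndarray

    def __post_init__(self) -> None:
        self.chrom = _as_str_array(self.chrom)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ref = _as_str_array(self.ref)
        self.alt = _as_str_array(self.alt)
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        self.samples = _as_str_array(self.samples)
        self.populations = _as_str_array(self.populations)
        if self.dosage.ndim != 2:
            raise ValueError("dosage must be 2-D (sites x individuals)")
        n_sites, n_samples = self.dosage.shape
        if n_samples < 2:
            raise ValueError("need at least 2 individuals")
        for arr, name in ((self.chrom, "chrom"), (self.pos, "pos"),
                          (self.ref, "ref"), (self.alt, "alt")):
            if len(arr) != n_sites:
                raise ValueError(f"{name} length {len(arr)} != {n_sites} sites")
        if len(self.samples) != n_samples or len(self.populations) != n_samples:
            raise ValueError("samples/populations must match dosage columns")
        bad = ~np.isin(self.dosage, (-1, 0, 1, 2))
        if bad.any():
            raise ValueError("dosages must be in {-1, 0, 1, 2}")
        if any(p is None or str(p) == "" for p in self.populations):
            raise ValueError("every individual needs a population label")
        self._check_sorted()

    def _check_sorted(self) -> None:
        for c in pd.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"positions not strictly increasing on {c}")

    # ---- basic accessors -------------------------------------------------
    @property
    def n_sites(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_samples(self) -> int:
        return self.dosage.shape[1]

    @property
    def is_complete(self) -> bool:
        return not (self.dosage == MISSING).any()

    def sample_index(self, sample: str) -> int:
        idx = np.flatnonzero(self.samples == sample)
        if len(idx) == 0:
            raise KeyError(f"unknown sample {sample!r}")
        return int(idx[0])

    def pop_indices(self, population: str) -> np.ndarray:
        idx = np.flatnonzero(self.populations == population)
        if len(idx) == 0:
            raise KeyError(f"no individuals in population {population!r}")
        return idx

    def take_sites(self, index: np.ndarray) -> "GenotypeMatrix":
        """New matrix restricted to the given site indices (order preserved)."""
        return GenotypeMatrix(
            chrom=self.chrom[index], pos=self.pos[index],
            ref=self.ref[index], alt=self.alt[index],
            dosage=self.dosage[index], samples=self.samples,
            populations=self.populations)

    def derived_counts(self, population: Optional[str] = None) -> tuple[np.ndarray, np.ndarray]:
        """Per-site (derived-allele count, called-allele count) for a population.

        Missing genotypes contribute to neither count.
        """
        cols = self.pop_indices(population) if population else np.arange(self.n_samples)
        d = self.dosage[:, cols]
        called = (d >= 0).sum(axis=1) * 2
        derived = np.where(d > 0, d, 0).sum(axis=1)
        return derived.astype(np.int64), called.astype(np.int64)

    def covered_span(self) -> int:
        """Total bp spanned by the analyzed sites, summed per chromosome."""
        total = 0
        for c in pd.unique(self.chrom):
            p = self.pos[self.chrom == c]
            total += int(p.max() - p.min() + 1)
        return total


@dataclass
class SiteAnnotation:
    """Per-site GERP score, SNPeff-style impact category and ancestral allele.

    Aligned 1:1 with a :class:`GenotypeMatrix` by construction (same site order).
    """

    gerp: np.ndarray
    impact: np.ndarray
    ancestral: np.ndarray

    def __post_init__(self) -> None:
        self.gerp = np.asarray(self.gerp, dtype=float)
        self.impact = _as_str_array(self.impact)
        self.ancestral = _as_str_array(self.ancestral)
        bad = set(self.impact) - set(IMPACT_LEVELS)
        if bad:
            raise ValueError(f"unknown impact categories: {sorted(bad)}")
        if not (len(self.gerp) == len(self.impact) == len(self.ancestral)):
            raise ValueError("annotation arrays must have equal length")

    def __len__(self) -> int:
        return len(self.gerp)

    def take(self, index: np.ndarray) -> "SiteAnnotation":
        return SiteAnnotation(self.gerp[index], self.impact[index], self.ancestral[index])


@dataclass
class MaskTrack:
    """Genomic intervals to exclude (e.g. CpG sites, repeats), 0-based half-open."""

    intervals: pd.DataFrame  # columns chrom, start, end

    @classmethod
    def from_bed(cls, path: Union[str, Path]) -> "MaskTrack":
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         usecols=[0, 1, 2], names=["chrom", "start", "end"])
        return cls(df).normalized()

    @classmethod
    def from_intervals(cls, intervals: Iterable[tuple]) -> "MaskTrack":
        df = pd.DataFrame(list(intervals), columns=["chrom", "start", "end"])
        return cls(df).normalized()

    def normalized(self) -> "MaskTrack":
        """Sort and merge overlapping/adjacent intervals."""
        df = self.intervals
        if (df["start"] >= df["end"]).any():
            raise ValueError("mask intervals need start < end")
        rows = []
        for c, grp in df.sort_values(["chrom", "start"]).groupby("chrom", sort=True):
            cur_s = cur_e = None
            for s, e in zip(grp["start"], grp["end"]):
                if cur_s is None:
                    cur_s, cur_e = s, e
                elif s <= cur_e:
                    cur_e = max(cur_e, e)
                else:
                    rows.append((c, cur_s, cur_e))
                    cur_s, cur_e = s, e
            if cur_s is not None:
                rows.append((c, cur_s, cur_e))
        return MaskTrack(pd.DataFrame(rows, columns=["chrom", "start", "end"]))

    def contains(self, chrom: np.ndarray, pos: np.ndarray) -> np.ndarray:
        """Boolean membership for 1-based site positions."""
        chrom = _as_str_array(chrom)
        pos0 = np.asarray(pos, dtype=np.int64) - 1  # to 0-based
        out = np.zeros(len(pos0), dtype=bool)
        for c, grp in self.intervals.groupby("chrom", sort=False):
            m = chrom == c
            if not m.any():
                continue
            starts = grp["start"].to_numpy()
            ends = grp["end"].to_numpy()
            # intervals are disjoint and sorted after normalization
            j = np.searchsorted(starts, pos0[m], side="right") - 1
            hit = (j >= 0) & (pos0[m] < ends[np.clip(j, 0, None)])
            out[np.flatnonzero(m)[hit]] = True
        return out


# --------------------------------------------------------------------------
# VCF / TSV ingestion
# --------------------------------------------------------------------------

def _load_pop_map(pop_map) -> dict:
    if isinstance(pop_map, dict):
        return dict(pop_map)
    if isinstance(pop_map, pd.DataFrame):
        df = pop_map
    else:
        df = pd.read_csv(pop_map, sep="\t", header=None, comment="#",
                         names=["sample_id", "population"], dtype=str)
    return dict(zip(df["sample_id"], df["population"]))


def read_genotypes(vcf_path, pop_map, drop_non_biallelic: bool = True
                   ) -> tuple[GenotypeMatrix, SiteAnnotation]:
    """Read a VCF into a :class:`GenotypeMatrix` plus :class:`SiteAnnotation`.

    Annotations are taken from the INFO keys ``GERP``, ``IMPACT`` and ``AA``
    when present (else NaN / NONE / unknown); a richer side TSV can be merged
    afterwards with :func:`read_annotation`.

    Parameters
    ----------
    vcf_path : str or Path
        VCF 4.x file, plain or gzipped.
    pop_map : path, DataFrame or dict
        sample_id -> population mapping (TSV with two columns).
    drop_non_biallelic : bool
        Drop records that are not biallelic SNPs; if False such records raise.
    """
    from cyvcf2 import VCF

    pops = _load_pop_map(pop_map)
    vcf = VCF(str(vcf_path), gts012=True)
    samples = list(vcf.samples)
    missing_pop = [s for s in samples if s not in pops]
    if missing_pop:
        raise ValueError(f"samples without population label: {missing_pop}")

    chrom, pos, ref, alt, rows = [], [], [], [], []
    gerp, impact, anc = [], [], []
    seen = set()
    for v in vcf:
        if len(v.ALT) != 1 or not v.is_snp:
            if drop_non_biallelic:
                continue
            raise ValueError(f"non-biallelic-SNP record at {v.CHROM}:{v.POS}")
        key = (v.CHROM, v.POS)
        if key in seen:
            raise ValueError(f"duplicated record at {v.CHROM}:{v.POS}")
        seen.add(key)
        chrom.append(v.CHROM)
        pos.append(v.POS)
        ref.append(v.REF)
        alt.append(v.ALT[0])
        # gts012: 0=hom ref, 1=het, 2=hom alt, 3=unknown
        gt = np.asarray(v.gt_types, dtype=np.int8)
        gt[gt == 3] = MISSING
        rows.append(gt)
        gerp.append(v.INFO.get("GERP", np.nan))
        impact.append(v.INFO.get("IMPACT", "NONE"))
        anc.append(v.INFO.get("AA", "."))
    vcf.close()
    if not rows:
        raise ValueError(f"no usable biallelic SNP records in {vcf_path}")

    gm = GenotypeMatrix(chrom=chrom, pos=pos, ref=ref, alt=alt,
                        dosage=np.vstack(rows), samples=samples,
                        populations=[pops[s] for s in samples])
    ann = SiteAnnotation(gerp=gerp, impact=impact, ancestral=anc)
    return gm, ann


def read_annotation(path, gm: GenotypeMatrix, allow_missing: bool = False) -> SiteAnnotation:
    """Read a per-site annotation TSV (chrom, pos, gerp, impact, ancestral).

    Sites are matched to ``gm`` by (chrom, pos); by default every site of the
    matrix must be annotated.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})
    required = {"chrom", "pos", "gerp", "impact", "ancestral"}
    if not required.issubset(df.columns):
        raise ValueError(f"annotation TSV needs columns {sorted(required)}")
    key = pd.MultiIndex.from_arrays([df["chrom"], df["pos"]])
    lookup = pd.DataFrame(
        {"gerp": df["gerp"].to_numpy(),
         "impact": df["impact"].to_numpy(),
         "ancestral": df["ancestral"].astype(str).to_numpy()}, index=key)
    want = pd.MultiIndex.from_arrays([pd.Series(gm.chrom), pd.Series(gm.pos)])
    missing = ~want.isin(lookup.index)
    if missing.any() and not allow_missing:
        raise ValueError(f"{missing.sum()} matrix sites missing from annotation")
    out = lookup.reindex(want)
    return SiteAnnotation(
        gerp=out["gerp"].to_numpy(dtype=float),
        impact=np.where(pd.isna(out["impact"]), "NONE", out["impact"]),
        ancestral=np.where(pd.isna(out["ancestral"]), ".", out["ancestral"]))


# --------------------------------------------------------------------------
# Core operations
# --------------------------------------------------------------------------

@dataclass
class PolarizeReport:
    n_kept: int = 0
    n_flipped: int = 0
    n_dropped_unknown: int = 0
    n_dropped_mismatch: int = 0


def polarize(gm: GenotypeMatrix, ann: SiteAnnotation
             ) -> tuple[GenotypeMatrix, SiteAnnotation, PolarizeReport]:
    """Re-express dosages as derived-allele counts using the ancestral allele.

    Sites where the ancestral allele is the REF are unchanged; sites where it
    is the ALT have dosages mapped 0<->2 (the REF becomes the derived allele)
    and their REF/ALT columns swapped.  Sites with an unknown ancestral allele,
    or one matching neither REF nor ALT, are dropped and tallied.
    """
    anc = ann.ancestral
    unknown = np.array([str(a) in UNKNOWN_ANCESTRAL for a in anc])
    is_ref = (anc == gm.ref) & ~unknown
    is_alt = (anc == gm.alt) & ~unknown
    mismatch = ~(is_ref | is_alt | unknown)
    keep = is_ref | is_alt

    report = PolarizeReport(
        n_kept=int(keep.sum()), n_flipped=int(is_alt.sum()),
        n_dropped_unknown=int(unknown.sum()), n_dropped_mismatch=int(mismatch.sum()))
    if report.n_dropped_mismatch:
        logger.warning("polarize: dropped %d sites with ancestral allele matching "
                       "neither REF nor ALT", report.n_dropped_mismatch)
    if report.n_dropped_unknown:
        logger.info("polarize: dropped %d sites with unknown ancestral allele",
                    report.n_dropped_unknown)

    dosage = gm.dosage.copy()
    flip = is_alt
    flipped = dosage[flip]
    present = flipped >= 0
    flipped[present] = 2 - flipped[present]
    dosage[flip] = flipped
    ref = gm.ref.copy()
    alt = gm.alt.copy()
    ref[flip], alt[flip] = gm.alt[flip], gm.ref[flip]

    idx = np.flatnonzero(keep)
    out = GenotypeMatrix(chrom=gm.chrom[idx], pos=gm.pos[idx], ref=ref[idx],
                         alt=alt[idx], dosage=dosage[idx], samples=gm.samples,
                         populations=gm.populations)
    out_ann = SiteAnnotation(ann.gerp[idx], ann.impact[idx],
                             np.asarray(out.ref, dtype=object))
    return out, out_ann, report


def filter_complete(gm: GenotypeMatrix, ann: Optional[SiteAnnotation] = None
                    ) -> tuple[GenotypeMatrix, Optional[SiteAnnotation], int]:
    """Keep only sites genotyped in every individual; returns removed-site count."""
    complete = (gm.dosage != MISSING).all(axis=1)
    n_removed = int((~complete).sum())
    idx = np.flatnonzero(complete)
    if len(idx) == 0:
        logger.warning("filter_complete: no complete sites remain")
    out = gm.take_sites(idx)
    return out, (ann.take(idx) if ann is not None else None), n_removed


def apply_mask(gm: GenotypeMatrix, mask: MaskTrack,
               ann: Optional[SiteAnnotation] = None
               ) -> tuple[GenotypeMatrix, Optional[SiteAnnotation], int]:
    """Remove sites falling inside any mask interval."""
    inside = mask.contains(gm.chrom, gm.pos)
    idx = np.flatnonzero(~inside)
    out = gm.take_sites(idx)
    return out, (ann.take(idx) if ann is not None else None), int(inside.sum())


def write_vcf(gm: GenotypeMatrix, ann: Optional[SiteAnnotation], path,
              contig_lengths: Optional[dict] = None,
              source: str = "strigops") -> None:
    """Write a matrix (plus optional annotation) as an uncompressed VCF 4.2.

    Annotations go into the INFO keys GERP/IMPACT/AA, mirroring what
    :func:`read_genotypes` consumes, so written files round-trip.
    """
    if contig_lengths is None:
        contig_lengths = {}
        for c in pd.unique(gm.chrom):
            contig_lengths[str(c)] = int(gm.pos[gm.chrom == c].max())
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source={source}\n")
        for c, length in contig_lengths.items():
            fh.write(f"##contig=<ID={c},length={length}>\n")
        if ann is not None:
            fh.write('##INFO=<ID=GERP,Number=1,Type=Float,'
                     'Description="GERP rejected-substitution score">\n')
            fh.write('##INFO=<ID=IMPACT,Number=1,Type=String,'
                     'Description="Functional impact category">\n')
            fh.write('##INFO=<ID=AA,Number=1,Type=String,'
                     'Description="Ancestral allele">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(map(str, gm.samples)) + "\n")
        for i in range(gm.n_sites):
            if ann is not None:
                info = (f"GERP={ann.gerp[i]:.4f};IMPACT={ann.impact[i]};"
                        f"AA={ann.ancestral[i]}")
            else:
                info = "."
            gts = "\t".join(gt_map[int(d)] for d in gm.dosage[i])
            fh.write(f"{gm.chrom[i]}\t{gm.pos[i]}\t.\t{gm.ref[i]}\t{gm.alt[i]}"
                     f"\t.\tPASS\t{info}\tGT\t{gts}\n")


def allele_balance_ok(ad_ref: np.ndarray, ad_alt: np.ndarray,
                      low: float = 0.2, high: float = 0.8) -> np.ndarray:
    """Optional heterozygote allele-balance predicate on FORMAT/AD counts.

    Variant calling is upstream of this package; this pass-through check is
    offered for callers that still carry read-depth fields (heterozygous calls
    with ALT fraction outside [low, high] fail).
    """
    ad_ref = np.asarray(ad_ref, dtype=float)
    ad_alt = np.asarray(ad_alt, dtype=float)
    total = ad_ref + ad_alt
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(total > 0, ad_alt / total, np.nan)
    return (frac >= low) & (frac <= high)
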