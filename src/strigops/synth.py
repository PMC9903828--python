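"""Synthetic two-population genotype datasets with known ground truth.

Emulates the statistical structure the empirical analyses assume: a
complete-coverage biallelic SNP matrix for an island and a mainland
population, per-site GERP scores and impact categories, ancestral-allele
calls, a planted per-category derived-allele frequency deficit in the island
population (for R_xy recovery), and long homozygous tracts (planted ROH) in
island individuals.  Generation is a pure function of the spec: the same spec
yields byte-identical files.

The generator has no linkage disequilibrium beyond the planted tracts and no
sequencing noise; it validates estimators, not population-genetic realism.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from .loadstats import rxy_from_freqs
from .variants import GenotypeMatrix, SiteAnnotation
from .variants import write_vcf as variants_write_vcf

NUCLEOTIDES = np.array(list("ACGT"))


@dataclass
class SynthSpec:
    """Parameters of one synthetic dataset.

    Defaults mirror the study conditions at desk scale: 35 island and 14
    mainland individuals, ~1 SNP/kb, rare-skewed frequency spectra, a GERP
    score track with a modest constrained fraction, and island individuals
    carrying about half their genome in long homozygous tracts.
    """

    n_sites: int = 20_000
    n_island: int = 35
    n_mainland: int = 14
    n_chromosomes: int = 5
    snp_per_kb: float = 1.0
    #: per-category fraction of sites (remainder is NONE)
    category_fractions: Dict[str, float] = field(default_factory=lambda: {
        "MODIFIER": 0.60, "LOW": 0.20, "MODERATE": 0.15, "HIGH": 0.02})
    #: Beta(a, b) of the shared base derived-allele frequency
    freq_beta: Tuple[float, float] = (0.5, 2.5)
    #: island-frequency multiplier per category (1 = no planted deficit)
    deficit: Dict[str, float] = field(default_factory=dict)
    #: fraction of sites with GERP > 2 (constrained)
    gerp_frac_constrained: float = 0.2
    #: fraction of island genome inside planted homozygous tracts
    roh_fraction: float = 0.5
    roh_mean_length: float = 1_000_000.0
    roh_min_length: float = 200_000.0
    #: mainland tract fraction (kept small)
    roh_fraction_mainland: float = 0.0
    #: fraction of sites whose ancestral allele is the ALT (exercises polarize)
    ancestral_alt_fraction: float = 0.0
    missing_rate: float = 0.0
    island_label: str = "island"
    mainland_label: str = "mainland"
    seed: int = 0

    @property
    def genome_length(self) -> int:
        return int(self.n_sites / self.snp_per_kb * 1000)

    @property
    def chrom_length(self) -> int:
        return self.genome_length // self.n_chromosomes

    def validate(self) -> None:
        if sum(self.category_fractions.values()) > 1.0 + 1e-9:
            raise ValueError("category fractions must sum to <= 1")
        for name, frac in (("roh_fraction", self.roh_fraction),
                           ("roh_fraction_mainland", self.roh_fraction_mainland)):
            if not 0.0 <= frac < 1.0:
                raise ValueError(f"{name} must be in [0, 1)")
        if (self.roh_fraction > 0 or self.roh_fraction_mainland > 0) \
                and self.roh_mean_length >= self.chrom_length:
            raise ValueError("tract length exceeds chromosome length")


@dataclass
class SynthTruth:
    """Ground truth of a generated dataset."""

    site_table: pd.DataFrame   # chrom, pos, category, f_island, f_mainland, gerp, ancestral
    rxy_planted: Dict[str, float]  # per category, island as population x
    roh_tracts: pd.DataFrame   # sample, chrom, start, end (1-based inclusive)


@dataclass
class SynthDataset:
    gm: GenotypeMatrix
    ann: SiteAnnotation
    truth: SynthTruth
    spec: SynthSpec


def generate(spec: SynthSpec) -> SynthDataset:
    """Generate the in-memory dataset for a spec (deterministic per seed)."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n_ind = spec.n_island + spec.n_mainland
    samples = [f"isl{i:03d}" for i in range(spec.n_island)] + \
              [f"mld{i:03d}" for i in range(spec.n_mainland)]
    populations = [spec.island_label] * spec.n_island + \
                  [spec.mainland_label] * spec.n_mainland

    # positions: uniform then sorted per chromosome, unique
    chroms, positions = [], []
    per_chrom = np.full(spec.n_chromosomes, spec.n_sites // spec.n_chromosomes)
    per_chrom[:spec.n_sites % spec.n_chromosomes] += 1
    for c in range(spec.n_chromosomes):
        pos = np.sort(rng.choice(np.arange(1, spec.chrom_length + 1),
                                 size=per_chrom[c], replace=False))
        chroms.append(np.full(per_chrom[c], f"chr{c + 1}", dtype=object))
        positions.append(pos)
    chrom = np.concatenate(chroms)
    pos = np.concatenate(positions)

    # impact categories, independent of position
    cats = list(spec.category_fractions) + ["NONE"]
    probs = list(spec.category_fractions.values())
    probs.append(max(1.0 - sum(probs), 0.0))
    impact = rng.choice(np.array(cats, dtype=object), size=spec.n_sites, p=probs)

    # derived-allele frequencies: shared base, island scaled by planted deficit
    a, b = spec.freq_beta
    f_main = rng.beta(a, b, size=spec.n_sites)
    f_isl = f_main.copy()
    for cat, factor in spec.deficit.items():
        m = impact == cat
        f_isl[m] = np.clip(f_main[m] * factor, 0.0, 1.0)

    # GERP scores: constrained fraction above 2
    constrained = rng.random(spec.n_sites) < spec.gerp_frac_constrained
    gerp = np.where(constrained, rng.uniform(2.0, 6.0, spec.n_sites),
                    rng.uniform(-4.0, 2.0, spec.n_sites))

    # genotypes: binomial by population frequency
    dosage = np.empty((spec.n_sites, n_ind), dtype=np.int8)
    dosage[:, :spec.n_island] = rng.binomial(
        2, f_isl[:, None], size=(spec.n_sites, spec.n_island))
    dosage[:, spec.n_island:] = rng.binomial(
        2, f_main[:, None], size=(spec.n_sites, spec.n_mainland))

    # planted homozygous tracts override genotypes inside them
    tract_rows = []
    for j, sample in enumerate(samples):
        frac = spec.roh_fraction if j < spec.n_island else spec.roh_fraction_mainland
        if frac <= 0:
            continue
        f_ind = f_isl if j < spec.n_island else f_main
        for c in range(spec.n_chromosomes):
            target = frac * spec.chrom_length
            placed = 0.0
            guard = 0
            intervals = []
            while placed < target and guard < 1000:
                guard += 1
                length = max(rng.exponential(spec.roh_mean_length),
                             spec.roh_min_length)
                length = min(length, spec.chrom_length / 2)
                start = int(rng.integers(1, spec.chrom_length - int(length) + 1))
                end = start + int(length) - 1
                if any(s <= end and start <= e for s, e in intervals):
                    continue
                intervals.append((start, end))
                placed += length
            for start, end in sorted(intervals):
                tract_rows.append((sample, f"chr{c + 1}", start, end))
                m = (chrom == f"chr{c + 1}") & (pos >= start) & (pos <= end)
                hom_alt = rng.random(int(m.sum())) < f_ind[m]
                dosage[m, j] = np.where(hom_alt, 2, 0).astype(np.int8)
    roh_tracts = pd.DataFrame(tract_rows,
                              columns=["sample", "chrom", "start", "end"])

    if spec.missing_rate > 0:
        miss = rng.random(dosage.shape) < spec.missing_rate
        dosage[miss] = -1

    # alleles; a configurable fraction has the ALT as ancestral so that the
    # stored VCF dosage is the complement of the derived dosage
    ref_idx = rng.integers(0, 4, size=spec.n_sites)
    alt_idx = (ref_idx + rng.integers(1, 4, size=spec.n_sites)) % 4
    ref = NUCLEOTIDES[ref_idx].astype(object)
    alt = NUCLEOTIDES[alt_idx].astype(object)
    anc_is_alt = rng.random(spec.n_sites) < spec.ancestral_alt_fraction
    ancestral = np.where(anc_is_alt, alt, ref).astype(object)
    vcf_dosage = dosage.copy()
    flip = np.flatnonzero(anc_is_alt)
    for i in flip:
        row = vcf_dosage[i]
        present = row >= 0
        row[present] = 2 - row[present]

    gm = GenotypeMatrix(chrom=chrom, pos=pos, ref=ref, alt=alt,
                        dosage=vcf_dosage, samples=samples,
                        populations=populations)
    ann = SiteAnnotation(gerp=gerp, impact=impact, ancestral=ancestral)

    site_table = pd.DataFrame({
        "chrom": chrom, "pos": pos, "category": impact,
        "f_island": f_isl, "f_mainland": f_main,
        "gerp": gerp, "ancestral": ancestral,
    })
    rxy_planted = {
        cat: rxy_from_freqs(f_isl[impact == cat], f_main[impact == cat])
        for cat in spec.category_fractions
    }
    truth = SynthTruth(site_table=site_table, rxy_planted=rxy_planted,
                       roh_tracts=roh_tracts)
    return SynthDataset(gm=gm, ann=ann, truth=truth, spec=spec)


# --------------------------------------------------------------------------
# File output
# --------------------------------------------------------------------------

def write_vcf(dataset: SynthDataset, path) -> None:
    """Write the dataset as an uncompressed VCF 4.2 with GERP/IMPACT/AA INFO."""
    spec = dataset.spec
    contigs = {f"chr{c + 1}": spec.chrom_length
               for c in range(spec.n_chromosomes)}
    variants_write_vcf(dataset.gm, dataset.ann, path,
                       contig_lengths=contigs, source="strigops-synth")


def write_dataset(dataset: SynthDataset, outdir) -> Dict[str, Path]:
    """Write VCF, population map, annotation TSV and truth tables to a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": outdir / "synthetic.vcf",
        "popmap": outdir / "popmap.tsv",
        "annotation": outdir / "annotation.tsv",
        "truth_sites": outdir / "truth_sites.tsv",
        "truth_rxy": outdir / "truth_rxy.tsv",
        "truth_roh": outdir / "truth_roh.tsv",
    }
    write_vcf(dataset, paths["vcf"])
    pd.DataFrame({"sample_id": dataset.gm.samples,
                  "population": dataset.gm.populations}) \
        .to_csv(paths["popmap"], sep="\t", header=False, index=False)
    ann_df = pd.DataFrame({
        "chrom": dataset.gm.chrom, "pos": dataset.gm.pos,
        "gerp": dataset.ann.gerp, "impact": dataset.ann.impact,
        "ancestral": dataset.ann.ancestral})
    ann_df.to_csv(paths["annotation"], sep="\t", index=False,
                  float_format="%.4f")
    dataset.truth.site_table.to_csv(paths["truth_sites"], sep="\t", index=False,
                                    float_format="%.6f")
    pd.DataFrame(sorted(dataset.truth.rxy_planted.items()),
                 columns=["category", "rxy"]) \
        .to_csv(paths["truth_rxy"], sep="\t", index=False, float_format="%.6f")
    dataset.truth.roh_tracts.to_csv(paths["truth_roh"], sep="\t", index=False)
    return paths


# --------------------------------------------------------------------------
# Truth recovery checks
# --------------------------------------------------------------------------

def truth_check(dataset: SynthDataset, detected_roh: Optional[dict] = None,
                rxy_results: Optional[dict] = None) -> dict:
    """Compare estimates against the planted truth.

    Returns a report with the maximum absolute per-site frequency error, the
    fraction of sites within 4 binomial standard deviations of truth, R_xy
    coverage of the planted value by the jackknife CI (when results are
    given), and ROH recall/precision per individual (when segments are given).
    """
    gm, truth, spec = dataset.gm, dataset.truth, dataset.spec
    report: dict = {}

    # frequencies estimated from the derived dosage of non-tract individuals
    # would be ideal; tract forcing perturbs island frequencies, so check the
    # mainland population, which is tract-free by default
    d, n = gm.derived_counts(spec.mainland_label)
    ok = n > 0
    f_hat = d[ok] / n[ok]
    f_true = truth.site_table["f_mainland"].to_numpy()[ok]
    sd = np.sqrt(np.maximum(f_true * (1 - f_true), 1e-12) / n[ok])
    report["freq_max_abs_err"] = float(np.max(np.abs(f_hat - f_true)))
    report["freq_within_4sd"] = float(
        np.mean(np.abs(f_hat - f_true) <= 4 * sd + 1e-12))

    if rxy_results:
        cover = {}
        for cat, res in rxy_results.items():
            planted = truth.rxy_planted.get(cat, np.nan)
            if res.status == "ok":
                cover[cat] = bool(res.ci_low <= planted <= res.ci_high)
            else:
                cover[cat] = None
        report["rxy_ci_covers_truth"] = cover

    if detected_roh is not None:
        recalls, precisions = [], []
        for sample, segs in detected_roh.items():
            tracts = truth.roh_tracts[truth.roh_tracts["sample"] == sample]
            if len(tracts) == 0:
                continue
            true_bp = 0
            hit_bp = 0
            det_bp = sum(s.length for s in segs)
            overlap_bp = 0
            for _, t in tracts.iterrows():
                true_bp += t.end - t.start + 1
                for s in segs:
                    if s.chrom != t.chrom:
                        continue
                    lo = max(s.start, t.start)
                    hi = min(s.end, t.end)
                    if hi >= lo:
                        overlap_bp += hi - lo + 1
            recalls.append(overlap_bp / true_bp if true_bp else np.nan)
            precisions.append(overlap_bp / det_bp if det_bp else np.nan)
        report["roh_recall"] = float(np.nanmean(recalls)) if recalls else np.nan
        report["roh_precision"] = (float(np.nanmean(precisions))
                                   if precisions else np.nan)
    return report
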