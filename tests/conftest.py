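"""Shared fixtures: small genotype matrices and synthetic datasets."""

import numpy as np
import pytest

from strigops.variants import GenotypeMatrix, SiteAnnotation


def make_matrix(dosage, pos=None, chrom=None, populations=None, samples=None):
    """Build a GenotypeMatrix around a dosage array with sensible defaults."""
    dosage = np.asarray(dosage, dtype=np.int8)
    n_sites, n_samples = dosage.shape
    if pos is None:
        pos = np.arange(1, n_sites + 1) * 100
    if chrom is None:
        chrom = np.full(n_sites, "chr1", dtype=object)
    if samples is None:
        samples = [f"s{i}" for i in range(n_samples)]
    if populations is None:
        half = n_samples // 2
        populations = ["island"] * half + ["mainland"] * (n_samples - half)
    return GenotypeMatrix(chrom=chrom, pos=pos,
                          ref=np.full(n_sites, "A", dtype=object),
                          alt=np.full(n_sites, "T", dtype=object),
                          dosage=dosage, samples=samples,
                          populations=populations)


def make_annotation(n_sites, gerp=None, impact=None, ancestral=None):
    return SiteAnnotation(
        gerp=np.zeros(n_sites) if gerp is None else np.asarray(gerp, float),
        impact=np.full(n_sites, "NONE", dtype=object) if impact is None
        else np.asarray(impact, dtype=object),
        ancestral=np.full(n_sites, "A", dtype=object) if ancestral is None
        else np.asarray(ancestral, dtype=object))


@pytest.fixture
def rng():
    return np.random.default_rng(20210908)


@pytest.fixture(scope="session")
def synth_default():
    """Default synthetic dataset (planted ROH, no planted deficit)."""
    from strigops import synth

    return synth.generate(synth.SynthSpec(seed=11))


@pytest.fixture(scope="session")
def synth_deficit():
    """Dataset with a planted 0.5x island frequency deficit for HIGH/MODERATE."""
    from strigops import synth

    spec = synth.SynthSpec(
        n_sites=50_000, roh_fraction=0.0,
        category_fractions={"MODIFIER": 0.40, "LOW": 0.20,
                            "MODERATE": 0.20, "HIGH": 0.15},
        freq_beta=(0.3, 6.0),
        deficit={"HIGH": 0.5, "MODERATE": 0.5}, seed=5)
    return synth.generate(spec)
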