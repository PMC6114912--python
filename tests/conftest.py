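import numpy as np
import pytest

from msirepeat.datamodel import (
    LengthHistogram,
    MarkerDefinition,
    MarkerObservation,
    SampleRecord,
    SnpDefinition,
    SnpObservation,
)


@pytest.fixture
def marker_8a() -> MarkerDefinition:
    """An 8 bp poly-A marker with one flanking SNP, on its own contig."""
    return MarkerDefinition(
        marker_id="LRT8",
        chromosome="ampT8",
        repeat_start=101,
        repeat_length=8,
        repeat_base="A",
        amplicon_interval=(61, 180),
        flanking_snps=(
            SnpDefinition("rsT8", position=89, ref_allele="G",
                          alt_allele="A", maf=0.35),
        ),
    )


@pytest.fixture
def marker_12a() -> MarkerDefinition:
    return MarkerDefinition(
        marker_id="LRT12",
        chromosome="ampT12",
        repeat_start=101,
        repeat_length=12,
        repeat_base="A",
        amplicon_interval=(61, 180),
        flanking_snps=(
            SnpDefinition("rsT12", position=89, ref_allele="C",
                          alt_allele="T", maf=0.40),
        ),
    )


def make_observation(
    marker_id: str,
    counts: dict[int, int],
    snp_strata: dict[str, dict[str, dict[int, int]]] | None = None,
) -> MarkerObservation:
    """Observation from a marker histogram and optional per-SNP strata."""
    obs = MarkerObservation(marker_id, LengthHistogram(dict(counts)))
    for snp_id, alleles in (snp_strata or {}).items():
        snp_obs = SnpObservation(snp_id)
        for allele, hist in alleles.items():
            snp_obs.allele_histograms[allele] = LengthHistogram(dict(hist))
        obs.snp_observations[snp_id] = snp_obs
    obs.validate()
    return obs


def make_sample(
    sample_id: str, label: str, observations: list[MarkerObservation]
) -> SampleRecord:
    return SampleRecord(
        sample_id, label, {o.marker_id: o for o in observations}
    )


def frac_observation(marker_id: str, fraction: float, depth: int = 100):
    """Observation with the requested deletion fraction at given depth."""
    k = int(round(fraction * depth))
    return make_observation(marker_id, {-1: k, 0: depth - k})


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
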