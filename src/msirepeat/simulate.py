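"""Synthetic cohorts of short-repeat amplicon read-count data.

The generator emulates the statistical structure the classifier assumes:

* per-marker read-pair depths (negative binomial);
* PCR-stutter noise whose deletion error rate grows with repeat length,
  affecting both alleles, with per-sample variability;
* in MSI-H samples, a somatic deletion component at a random mutant-cell
  fraction, confined to one allele chosen at random (the origin of the
  allelic-bias signal), optionally biallelic for stress tests;
* flanking-SNP genotypes drawn from population allele frequencies under
  Hardy-Weinberg equilibrium.

It can also emit a paired-end SAM fixture (plus a reference FASTA stub)
whose extraction reproduces a sample's histograms exactly, which is used
to validate the alignment-parsing path end to end.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .datamodel import (
    MSI_H,
    MSS,
    LengthHistogram,
    MarkerDefinition,
    MarkerObservation,
    SampleRecord,
    SnpDefinition,
    SnpObservation,
    ValidationError,
)
from .io import atomic_write

#: length deviations the stutter model distributes reads over
DEVIATIONS = (-3, -2, -1, 0, 1)


@dataclass(frozen=True)
class DepthModel:
    """Negative-binomial read-pair depth per marker.

    Defaults target amplicon sequencing at ~10,000 reads (5,000 pairs)
    per marker.
    """

    mean: float = 5000.0
    dispersion: float = 10.0
    floor: int = 0

    def draw(self, rng: np.random.Generator) -> int:
        p = self.dispersion / (self.dispersion + self.mean)
        return max(self.floor, int(rng.negative_binomial(self.dispersion, p)))


@dataclass(frozen=True)
class StutterModel:
    """PCR slippage error rates by repeat length.

    ``deletion_rate`` maps repeat length (bp) to the mean total fraction
    of error reads carrying a deletion; the rate is scaled per
    sample-marker by a log-normal factor (sigma = ``sample_sigma``) to
    mimic between-library variability.  Deletion errors are split over
    -1/-2/-3 bp by ``deletion_split``; insertions (+1) occur at a flat
    low rate.
    """

    deletion_rate: dict[int, float] = field(
        default_factory=lambda: {
            7: 0.004, 8: 0.009, 9: 0.018, 10: 0.045, 11: 0.085, 12: 0.13,
        }
    )
    deletion_split: tuple[float, float, float] = (0.80, 0.15, 0.05)
    insertion_rate: float = 0.004
    sample_sigma: float = 0.40

    def probabilities(
        self, repeat_length: int, rng: np.random.Generator
    ) -> np.ndarray:
        """Per-read probability vector over DEVIATIONS for one library."""
        rate = self.deletion_rate[repeat_length]
        if self.sample_sigma > 0:
            rate *= float(rng.lognormal(0.0, self.sample_sigma))
        rate = min(rate, 0.5)
        w1, w2, w3 = self.deletion_split
        probs = np.array(
            [rate * w3, rate * w2, rate * w1, 0.0, self.insertion_rate]
        )
        probs[3] = 1.0 - probs.sum()
        return probs


@dataclass(frozen=True)
class SomaticModel:
    """Somatic repeat-deletion events in MSI-H samples.

    An event at a marker occurs with a length-dependent probability,
    affects one allele chosen at random (both when ``biallelic``), and is
    present in a Beta-distributed fraction of the cells; mutant reads are
    shortened by 1 or 2 bp.
    """

    event_prob: dict[int, float] = field(
        default_factory=lambda: {
            7: 0.45, 8: 0.55, 9: 0.65, 10: 0.75, 11: 0.85, 12: 0.90,
        }
    )
    fraction_alpha: float = 2.5
    fraction_beta: float = 3.0
    size_probs: dict[int, float] = field(
        default_factory=lambda: {-1: 0.85, -2: 0.15}
    )
    biallelic: bool = False

    def size_vector(self) -> np.ndarray:
        probs = np.zeros(len(DEVIATIONS))
        for size, p in self.size_probs.items():
            probs[DEVIATIONS.index(size)] = p
        return probs


@dataclass(frozen=True)
class SimulationConfig:
    """Full specification of one synthetic cohort."""

    n_samples: int
    panel: tuple[MarkerDefinition, ...]
    prevalence_msi: float = 0.15
    depth: DepthModel = field(default_factory=DepthModel)
    stutter: StutterModel = field(default_factory=StutterModel)
    somatic: SomaticModel = field(default_factory=SomaticModel)
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 1:
            raise ValidationError(f"n_samples {self.n_samples} < 1")
        if not 0.0 <= self.prevalence_msi <= 1.0:
            raise ValidationError(
                f"prevalence_msi {self.prevalence_msi} outside [0, 1]"
            )
        if not self.panel:
            raise ValidationError("panel is empty")
        for marker in self.panel:
            marker.validate()
            if marker.repeat_length not in self.stutter.deletion_rate:
                raise ValidationError(
                    f"no stutter rate for repeat length {marker.repeat_length}"
                )
            if marker.repeat_length not in self.somatic.event_prob:
                raise ValidationError(
                    f"no somatic event probability for length "
                    f"{marker.repeat_length}"
                )
        if not np.isclose(sum(self.stutter.deletion_split), 1.0):
            raise ValidationError("deletion_split must sum to 1")
        if not np.isclose(sum(self.somatic.size_probs.values()), 1.0):
            raise ValidationError("somatic size_probs must sum to 1")


# ---------------------------------------------------------------------------
# default panels and presets

_PANEL_LENGTHS_A = (7, 7, 8, 8, 8, 9, 9, 9, 10, 10, 10, 11, 11, 12, 12)
_PANEL_LENGTHS_C = (8, 10)
_MAF_CYCLE = (0.22, 0.28, 0.33, 0.38, 0.44, 0.50)


def default_panel() -> list[MarkerDefinition]:
    """A 17-marker synthetic panel: 15 poly-A and 2 poly-C repeats, 7-12 bp.

    Each marker sits on its own small amplicon contig with one flanking
    SNP 12 bp upstream of the repeat.
    """
    specs = [(length, "A") for length in _PANEL_LENGTHS_A]
    specs += [(length, "C") for length in _PANEL_LENGTHS_C]
    markers = []
    for i, (length, base) in enumerate(specs, start=1):
        repeat_start = 101
        marker = MarkerDefinition(
            marker_id=f"MNR{i:02d}_{length}{base}",
            chromosome=f"amp{i:02d}",
            repeat_start=repeat_start,
            repeat_length=length,
            repeat_base=base,
            amplicon_interval=(61, 180),
            flanking_snps=(
                SnpDefinition(
                    snp_id=f"snp{i:02d}",
                    position=repeat_start - 12,
                    ref_allele="G" if base == "A" else "T",
                    alt_allele="A" if base == "A" else "G",
                    maf=_MAF_CYCLE[(i - 1) % len(_MAF_CYCLE)],
                ),
            ),
        )
        marker.validate()
        markers.append(marker)
    return markers


def preset_paper_like(
    n_samples: int, prevalence_msi: float = 0.15, seed: int = 0
) -> SimulationConfig:
    """Default study-like conditions: 17 markers, deep amplicons, moderate
    marker-to-marker separation (short repeats discriminate weakly, long
    repeats almost perfectly)."""
    return SimulationConfig(
        n_samples=n_samples,
        panel=tuple(default_panel()),
        prevalence_msi=prevalence_msi,
        seed=seed,
    )


def preset_separable(
    n_samples: int, prevalence_msi: float = 0.5, seed: int = 0
) -> SimulationConfig:
    """Strongly separable conditions for limit-of-detection studies:
    every marker mutates in every MSI-H sample at a high mutant-cell
    fraction, stutter as in the default preset."""
    return SimulationConfig(
        n_samples=n_samples,
        panel=tuple(default_panel()),
        prevalence_msi=prevalence_msi,
        somatic=SomaticModel(
            event_prob={length: 1.0 for length in range(7, 13)},
            fraction_alpha=6.0,
            fraction_beta=3.0,
        ),
        seed=seed,
    )


def small_depth(config: SimulationConfig, mean: float = 120.0) -> SimulationConfig:
    """Copy of a config at reduced depth (for fast exactness tests)."""
    return replace(config, depth=DepthModel(mean=mean, dispersion=8.0, floor=25))


# ---------------------------------------------------------------------------
# cohort generation

def _draw_genotype(
    snp: SnpDefinition, rng: np.random.Generator
) -> tuple[str, str]:
    """Phased pair of alleles for the two chromosome copies (HWE)."""
    maf = snp.maf if snp.maf is not None else 0.0
    u = rng.random(2)
    return tuple(
        snp.alt_allele if x < maf else snp.ref_allele for x in u
    )


def generate_cohort(
    config: SimulationConfig,
) -> tuple[list[SampleRecord], pd.DataFrame]:
    """Draw a labelled cohort and the per-sample-marker truth table.

    Per sample and marker, each read pair originates from one of the two
    chromosome copies with equal probability; its length deviation is
    drawn from that copy's distribution (stutter only, or the
    stutter/somatic mixture on mutated copies of MSI-H samples).  Every
    latent variable is recorded in the truth table.  Fully reproducible
    from ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    samples: list[SampleRecord] = []
    truth_rows: list[dict] = []
    width = max(3, len(str(config.n_samples)))
    for s in range(config.n_samples):
        is_msi = rng.random() < config.prevalence_msi
        sample = SampleRecord(
            f"S{s + 1:0{width}d}", MSI_H if is_msi else MSS
        )
        for marker in config.panel:
            depth = config.depth.draw(rng)
            stutter_probs = config.stutter.probabilities(
                marker.repeat_length, rng
            )
            event = bool(
                is_msi
                and rng.random()
                < config.somatic.event_prob[marker.repeat_length]
            )
            mutant_fraction = 0.0
            mutated_copies: tuple[int, ...] = ()
            if event:
                mutant_fraction = float(
                    rng.beta(
                        config.somatic.fraction_alpha,
                        config.somatic.fraction_beta,
                    )
                )
                if config.somatic.biallelic:
                    mutated_copies = (0, 1)
                else:
                    mutated_copies = (int(rng.integers(2)),)
            copy_probs = []
            for copy in (0, 1):
                if copy in mutated_copies:
                    probs = (
                        (1.0 - mutant_fraction) * stutter_probs
                        + mutant_fraction * config.somatic.size_vector()
                    )
                else:
                    probs = stutter_probs
                copy_probs.append(probs)
            n_copy0 = int(rng.binomial(depth, 0.5))
            copy_hists = []
            for copy, n_reads in ((0, n_copy0), (1, depth - n_copy0)):
                counts = rng.multinomial(n_reads, copy_probs[copy])
                copy_hists.append(
                    {
                        dev: int(c)
                        for dev, c in zip(DEVIATIONS, counts)
                        if c > 0
                    }
                )
            obs = MarkerObservation(marker.marker_id)
            for hist in copy_hists:
                for dev, c in hist.items():
                    obs.histogram.add(dev, c)
            genotypes = {}
            for snp in marker.flanking_snps:
                alleles = _draw_genotype(snp, rng)
                genotypes[snp.snp_id] = alleles
                snp_obs = SnpObservation(snp.snp_id)
                for copy in (0, 1):
                    hist = snp_obs.allele_histograms.setdefault(
                        alleles[copy], LengthHistogram()
                    )
                    for dev, c in copy_hists[copy].items():
                        hist.add(dev, c)
                obs.snp_observations[snp.snp_id] = snp_obs
            sample.observations[marker.marker_id] = obs
            truth_rows.append(
                {
                    "sample_id": sample.sample_id,
                    "label": sample.label,
                    "marker_id": marker.marker_id,
                    "depth": depth,
                    "somatic_event": event,
                    "mutant_fraction": mutant_fraction,
                    "mutated_copies": ",".join(map(str, mutated_copies)) or ".",
                    "genotypes": ";".join(
                        f"{sid}:{a}/{b}" for sid, (a, b) in genotypes.items()
                    ),
                }
            )
        samples.append(sample)
    return samples, pd.DataFrame(truth_rows)


def write_truth(truth: pd.DataFrame, path) -> None:
    with atomic_write(path) as out:
        truth.to_csv(out, sep="\t", index=False, float_format="%.8g")


# ---------------------------------------------------------------------------
# SAM fixture emission

_FLANK = "GATC"  # repeated filler pattern for reference flanks


def reference_sequence(marker: MarkerDefinition) -> str:
    """Deterministic reference contig for one marker's amplicon.

    Filler bases cycle through a fixed pattern chosen never to equal the
    repeat base at the repeat boundaries, the repeat interval is the
    homopolymer run, and each flanking SNP position carries its reference
    allele.
    """
    length = marker.amplicon_interval[1] + 10
    seq = []
    for pos in range(1, length + 1):  # 1-based
        if marker.repeat_start <= pos <= marker.repeat_end:
            seq.append(marker.repeat_base)
        else:
            base = _FLANK[pos % len(_FLANK)]
            if base == marker.repeat_base:
                base = "T" if marker.repeat_base != "T" else "G"
            seq.append(base)
    for snp in marker.flanking_snps:
        seq[snp.position - 1] = snp.ref_allele
    return "".join(seq)


def _pair_composition(
    obs: MarkerObservation, marker: MarkerDefinition
) -> list[tuple[int, str | None, int]]:
    """(deviation, SNP allele or None, count) triples covering every pair.

    Reconstructing read pairs from an observation requires the SNP
    stratification to be unambiguous, so markers with more than one
    flanking SNP are not supported here (the default panel has one).
    """
    if len(marker.flanking_snps) > 1:
        raise ValidationError(
            f"marker {marker.marker_id}: SAM emission supports at most one "
            f"flanking SNP"
        )
    if not marker.flanking_snps:
        return [(dev, None, c) for dev, c in sorted(obs.histogram.counts.items())]
    snp = marker.flanking_snps[0]
    snp_obs = obs.snp_observations.get(snp.snp_id)
    triples: list[tuple[int, str | None, int]] = []
    stratified: dict[int, int] = {}
    if snp_obs is not None:
        for allele in sorted(snp_obs.allele_histograms):
            for dev, c in sorted(snp_obs.allele_histograms[allele].counts.items()):
                triples.append((dev, allele, c))
                stratified[dev] = stratified.get(dev, 0) + c
    # pairs in the marker histogram but not covered by the SNP stratum are
    # emitted without an informative base at the SNP (mate disagreement)
    for dev, c in sorted(obs.histogram.counts.items()):
        extra = c - stratified.get(dev, 0)
        if extra < 0:
            raise ValidationError(
                f"marker {marker.marker_id}: SNP stratum exceeds histogram "
                f"at deviation {dev}"
            )
        if extra > 0:
            triples.append((dev, None, extra))
    return triples


def _read_alignment(
    marker: MarkerDefinition,
    ref: str,
    deviation: int,
    allele: str | None,
    discordant_base: str | None = None,
) -> tuple[int, str, str]:
    """(1-based POS, CIGAR, SEQ) for one mate carrying the deviation.

    The read spans from 10 bp upstream of the leftmost feature (SNP or
    repeat) to 10 bp downstream of the repeat, clamped to the amplicon.
    Deletions remove repeat bases starting at the second repeat position;
    insertions add repeat bases anchored at the first.
    """
    lo, hi = marker.amplicon_interval
    feature_lo = min(
        [marker.repeat_start] + [s.position for s in marker.flanking_snps]
    )
    start = max(lo, feature_lo - 10)  # 1-based
    end = min(hi, marker.repeat_end + 10)
    rs = marker.repeat_start
    if deviation < 0:
        d = -deviation
        a = rs - start + 1
        b = end - rs - d
        cigar = f"{a}M{d}D{b}M"
        seq = ref[start - 1 : rs] + ref[rs + d : end]
        def to_read(pos: int) -> int | None:
            if pos <= rs:
                return pos - start
            if pos <= rs + d:
                return None
            return pos - start - d
    elif deviation > 0:
        a = rs - start + 1
        cigar = f"{a}M{deviation}I{end - rs}M"
        seq = (
            ref[start - 1 : rs]
            + marker.repeat_base * deviation
            + ref[rs:end]
        )
        def to_read(pos: int) -> int | None:
            if pos <= rs:
                return pos - start
            return pos - start + deviation
    else:
        cigar = f"{end - start + 1}M"
        seq = ref[start - 1 : end]
        def to_read(pos: int) -> int | None:
            return pos - start
    seq = list(seq)
    if marker.flanking_snps:
        snp = marker.flanking_snps[0]
        idx = to_read(snp.position)
        if idx is not None:
            if discordant_base is not None:
                seq[idx] = discordant_base
            elif allele is not None:
                seq[idx] = allele
    return start, cigar, "".join(seq)


def emit_sam_fixture(
    sample: SampleRecord,
    panel: list[MarkerDefinition],
    seed: int = 0,
) -> tuple[str, str]:
    """Render a sample as SAM text plus a synthetic reference FASTA stub.

    Every read pair is concordant by construction, so running
    :func:`msirepeat.extraction.extract_observation` on the output
    reproduces the sample's marker histograms and allele strata exactly.
    """
    del seed  # emission is fully deterministic; kept for interface stability
    header = ["@HD\tVN:1.6\tSO:unsorted"]
    references = []
    body = []
    for marker in panel:
        ref = reference_sequence(marker)
        header.append(f"@SQ\tSN:{marker.chromosome}\tLN:{len(ref)}")
        references.append((marker.chromosome, ref))
        obs = sample.observations.get(marker.marker_id)
        if obs is None:
            continue
        pair_index = 0
        for deviation, allele, count in _pair_composition(obs, marker):
            for _ in range(count):
                pair_index += 1
                name = f"{sample.sample_id}:{marker.marker_id}:{pair_index}"
                if allele is None and marker.flanking_snps:
                    # mates disagree at the SNP: one carries an N there, so
                    # the pair is excluded from the stratification only
                    mates = [
                        _read_alignment(marker, ref, deviation, None),
                        _read_alignment(
                            marker, ref, deviation, None, discordant_base="N"
                        ),
                    ]
                else:
                    aln = _read_alignment(marker, ref, deviation, allele)
                    mates = [aln, aln]
                span = len(mates[0][2])
                for mate_i, (pos, cigar, seq) in enumerate(mates):
                    flag = 99 if mate_i == 0 else 147
                    tlen = span if mate_i == 0 else -span
                    body.append(
                        "\t".join(
                            [
                                name, str(flag), marker.chromosome, str(pos),
                                "60", cigar, "=", str(mates[1 - mate_i][0]),
                                str(tlen), seq, "I" * len(seq),
                            ]
                        )
                    )
    sam_text = "\n".join(header + body) + "\n"
    fasta_lines = []
    for contig, seq in references:
        fasta_lines.append(f">{contig}")
        for i in range(0, len(seq), 70):
            fasta_lines.append(seq[i : i + 70])
    return sam_text, "\n".join(fasta_lines) + "\n"


def write_sam_fixture(
    sample: SampleRecord,
    panel: list[MarkerDefinition],
    sam_path: str | os.PathLike,
    fasta_path: str | os.PathLike | None = None,
    seed: int = 0,
) -> None:
    sam_text, fasta_text = emit_sam_fixture(sample, panel, seed)
    with atomic_write(sam_path) as out:
        out.write(sam_text)
    if fasta_path is not None:
        with atomic_write(fasta_path) as out:
            out.write(fasta_text)
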