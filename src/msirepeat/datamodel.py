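"""Core domain types for short mononucleotide-repeat (MNR) MSI testing.

The package classifies tumour samples as microsatellite-instability-high
(MSI-H) or microsatellite-stable (MSS) from amplicon sequencing of short
(7-12 bp) homopolymer runs.  The types here describe the marker panel, the
per-sample read-count observations derived from aligned read pairs, the
trained naive Bayes model, and the per-sample classification result.

Coordinates in all user-facing structures are 1-based and inclusive, the
convention of panel design tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

#: minimum concordant read-pair depth for a marker observation to be usable
MIN_READ_PAIRS = 20

#: minimum minor-allele read-pair fraction to call a flanking SNP heterozygous
MIN_HET_FRACTION = 0.20

#: maximum distance (bp) between a flanking SNP and the repeat interval
MAX_SNP_DISTANCE = 30

MSI_H = "MSI-H"
MSS = "MSS"
UNKNOWN = "unknown"
NOT_ASSESSABLE = "not assessable"

VALID_LABELS = frozenset({MSI_H, MSS, UNKNOWN})


class MsirepeatError(Exception):
    """Base class for all package errors."""


class ValidationError(MsirepeatError):
    """Invalid value, configuration, or domain-rule violation."""


class DataFormatError(MsirepeatError):
    """Malformed input file (panel, counts table, model, summaries)."""


class NotComputableError(MsirepeatError):
    """Requested statistic is undefined for this observation.

    Raised e.g. for an allelic-bias table at a SNP that is not
    heterozygous, or a deletion fraction of an empty histogram.
    """


@dataclass(frozen=True)
class SnpDefinition:
    """A polymorphism flanking a repeat, used to phase reads to alleles."""

    snp_id: str
    position: int  # 1-based genomic coordinate
    ref_allele: str
    alt_allele: str
    maf: float | None = None  # population minor-allele frequency

    def validate(self) -> None:
        if self.ref_allele == self.alt_allele:
            raise ValidationError(
                f"SNP {self.snp_id}: ref and alt alleles are both "
                f"{self.ref_allele!r}"
            )
        for name, allele in (("ref", self.ref_allele), ("alt", self.alt_allele)):
            if allele not in {"A", "C", "G", "T"}:
                raise ValidationError(
                    f"SNP {self.snp_id}: {name} allele {allele!r} is not a base"
                )
        if self.maf is not None and not 0.0 <= self.maf <= 1.0:
            raise ValidationError(
                f"SNP {self.snp_id}: maf {self.maf} outside [0, 1]"
            )


@dataclass(frozen=True)
class MarkerDefinition:
    """One mononucleotide-repeat marker of the panel.

    The repeat is a homopolymer of ``repeat_base`` starting at
    ``repeat_start`` (1-based) and spanning ``repeat_length`` bases, inside
    the amplified interval ``amplicon_interval``.
    """

    marker_id: str
    chromosome: str
    repeat_start: int
    repeat_length: int
    repeat_base: str
    amplicon_interval: tuple[int, int]
    flanking_snps: tuple[SnpDefinition, ...] = ()

    @property
    def repeat_end(self) -> int:
        """1-based inclusive end of the repeat."""
        return self.repeat_start + self.repeat_length - 1

    def validate(self) -> None:
        if not 7 <= self.repeat_length <= 12:
            raise ValidationError(
                f"marker {self.marker_id}: repeat_length {self.repeat_length} "
                f"outside [7, 12]"
            )
        if self.repeat_base not in {"A", "C"}:
            raise ValidationError(
                f"marker {self.marker_id}: repeat_base {self.repeat_base!r} "
                f"must be A or C"
            )
        lo, hi = self.amplicon_interval
        if not lo <= self.repeat_start <= self.repeat_end <= hi:
            raise ValidationError(
                f"marker {self.marker_id}: repeat "
                f"[{self.repeat_start}, {self.repeat_end}] not inside "
                f"amplicon [{lo}, {hi}]"
            )
        for snp in self.flanking_snps:
            snp.validate()
            dist = max(
                self.repeat_start - snp.position,
                snp.position - self.repeat_end,
                0,
            )
            if dist > MAX_SNP_DISTANCE:
                raise ValidationError(
                    f"marker {self.marker_id}: SNP {snp.snp_id} at "
                    f"{snp.position} is {dist} bp from the repeat "
                    f"(limit {MAX_SNP_DISTANCE})"
                )


@dataclass
class LengthHistogram:
    """Read-pair counts by repeat-length deviation from the reference.

    Keys are integer base-pair deviations: negative values are deletions,
    0 is the reference length, positive values are insertions.
    """

    counts: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        cleaned: dict[int, int] = {}
        for dev, n in self.counts.items():
            if n < 0:
                raise ValidationError(f"negative count {n} at deviation {dev}")
            if n > 0:
                cleaned[int(dev)] = int(n)
        self.counts = cleaned

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def deletion_count(self) -> int:
        return sum(n for dev, n in self.counts.items() if dev < 0)

    @property
    def deletion_fraction(self) -> float:
        """Fraction of read pairs carrying any deletion.

        Insertions and reference-length reads count toward the denominator
        only.  Undefined (raises) for an empty histogram.
        """
        total = self.total
        if total == 0:
            raise NotComputableError(
                "deletion fraction undefined for an empty histogram"
            )
        return self.deletion_count / total

    def frequencies(self) -> dict[int, float]:
        total = self.total
        if total == 0:
            raise NotComputableError("empty histogram has no frequencies")
        return {dev: n / total for dev, n in sorted(self.counts.items())}

    def add(self, dev: int, n: int = 1) -> None:
        if n < 0:
            raise ValidationError(f"negative count {n} at deviation {dev}")
        if n:
            self.counts[dev] = self.counts.get(dev, 0) + n

    def copy(self) -> "LengthHistogram":
        return LengthHistogram(dict(self.counts))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LengthHistogram):
            return NotImplemented
        return self.counts == other.counts


def call_heterozygous(allele_counts: Mapping[str, int]) -> bool | None:
    """Heterozygosity call for one SNP from per-allele read-pair counts.

    The SNP is heterozygous iff the least common allele is supported by at
    least 20% of the read pairs covering the position (boundary inclusive).
    Returns ``None`` ("not assessable") when no read pairs cover the SNP,
    which is distinct from a confident homozygous call.
    """
    total = sum(allele_counts.values())
    if total == 0:
        return None
    minority = total - max(allele_counts.values())
    return minority / total >= MIN_HET_FRACTION


@dataclass
class SnpObservation:
    """Allele-stratified read-pair histograms at one flanking SNP."""

    snp_id: str
    allele_histograms: dict[str, LengthHistogram] = field(default_factory=dict)

    @property
    def allele_totals(self) -> dict[str, int]:
        return {a: h.total for a, h in self.allele_histograms.items()}

    @property
    def total(self) -> int:
        return sum(h.total for h in self.allele_histograms.values())

    @property
    def heterozygous(self) -> bool | None:
        return call_heterozygous(self.allele_totals)


@dataclass
class MarkerObservation:
    """All read-pair evidence for one marker in one sample.

    ``histogram`` aggregates every concordant read pair covering the
    repeat; the per-SNP histograms are the subset of those pairs that also
    cover the SNP concordantly with a ref or alt base.
    """

    marker_id: str
    histogram: LengthHistogram = field(default_factory=LengthHistogram)
    snp_observations: dict[str, SnpObservation] = field(default_factory=dict)

    @property
    def usable(self) -> bool:
        return self.histogram.total >= MIN_READ_PAIRS

    @property
    def heterozygous_flags(self) -> dict[str, bool | None]:
        return {sid: s.heterozygous for sid, s in self.snp_observations.items()}

    def heterozygous_snps(self) -> list[str]:
        """SNP ids called heterozygous, in stored (panel) order."""
        return [
            sid
            for sid, s in self.snp_observations.items()
            if s.heterozygous is True
        ]

    def validate(self) -> None:
        total = self.histogram.total
        for sid, snp_obs in self.snp_observations.items():
            if snp_obs.total > total:
                raise ValidationError(
                    f"marker {self.marker_id}, SNP {sid}: allele-stratified "
                    f"total {snp_obs.total} exceeds marker total {total}"
                )


@dataclass
class SampleRecord:
    """One sample's observations across the panel, with an optional label."""

    sample_id: str
    label: str = UNKNOWN
    observations: dict[str, MarkerObservation] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.label not in VALID_LABELS:
            raise ValidationError(
                f"sample {self.sample_id}: label {self.label!r} not one of "
                f"{sorted(VALID_LABELS)}"
            )


@dataclass
class MarkerParameters:
    """Trained per-marker parameters of the naive Bayes classifier.

    ``threshold`` is the deletion-frequency cutoff t_i above which the
    marker is considered mutated (D_i = 1).  The four conditional
    probabilities are Laplace-smoothed estimates; the raw training counts
    (numerator, denominator) travel with them for auditability.  Bias
    probabilities are ``None`` when no eligible training sample existed
    for that class.
    """

    marker_id: str
    threshold: float
    p_d_msi: float
    p_d_mss: float
    p_b_msi: float | None
    p_b_mss: float | None
    counts: dict[str, tuple[int, int] | None] = field(default_factory=dict)

    @property
    def bias_available(self) -> bool:
        return self.p_b_msi is not None and self.p_b_mss is not None

    def validate(self) -> None:
        if not 0.0 <= self.threshold <= 1.0:
            raise ValidationError(
                f"marker {self.marker_id}: threshold {self.threshold} "
                f"outside [0, 1]"
            )
        probs = [("p_d_msi", self.p_d_msi), ("p_d_mss", self.p_d_mss)]
        if self.p_b_msi is not None:
            probs.append(("p_b_msi", self.p_b_msi))
        if self.p_b_mss is not None:
            probs.append(("p_b_mss", self.p_b_mss))
        for name, p in probs:
            if not 0.0 < p < 1.0:
                raise ValidationError(
                    f"marker {self.marker_id}: {name} = {p} not in (0, 1); "
                    f"was the model trained with a positive pseudocount?"
                )


@dataclass
class TrainedModel:
    """Class priors plus per-marker parameters, with training provenance."""

    markers: dict[str, MarkerParameters] = field(default_factory=dict)
    prior_msi: float = 0.15
    prior_mss: float = 0.85
    bias_alpha: float = 0.05
    pseudocount: float = 1.0
    provenance: dict = field(default_factory=dict)

    @property
    def log10_prior_odds(self) -> float:
        return math.log10(self.prior_msi / self.prior_mss)

    def validate(self) -> None:
        if not math.isclose(self.prior_msi + self.prior_mss, 1.0, abs_tol=1e-9):
            raise ValidationError(
                f"priors {self.prior_msi} + {self.prior_mss} do not sum to 1"
            )
        if not 0.0 < self.prior_msi < 1.0:
            raise ValidationError(f"prior_msi {self.prior_msi} not in (0, 1)")
        if not 0.0 < self.bias_alpha < 1.0:
            raise ValidationError(
                f"bias_alpha {self.bias_alpha} not in (0, 1)"
            )
        for params in self.markers.values():
            params.validate()


@dataclass
class MarkerContribution:
    """Per-marker record attached to a classification result.

    ``d`` is the deletion-frequency exceedance indicator D_i, ``b`` the
    allelic-bias indicator B_i (``None`` when bias was not assessable or
    not applicable), ``log10_factor`` the marker's additive contribution to
    the score (``None`` when the marker was skipped).
    """

    marker_id: str
    used: bool
    d: bool | None = None
    b: bool | None = None
    snp_id: str | None = None
    bias_p: float | None = None
    log10_factor: float | None = None
    note: str = ""


@dataclass
class ClassificationResult:
    """Score and call for one sample.

    ``score`` is S = log10 of the posterior odds p(MSI|O)/p(MSS|O); a
    sample is called MSI-H iff S > 0.  The score equals the log10 prior
    odds plus the sum of the recorded per-marker factors.
    """

    sample_id: str
    score: float | None
    call: str
    contributions: list[MarkerContribution] = field(default_factory=list)
    n_markers_used: int = 0
    n_bias_assessed: int = 0
    reason: str = ""
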