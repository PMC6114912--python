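"""Candidate-repeat filtering rules for building an MNR marker panel.

The selection stage operates on per-repeat summary records computed
upstream from whole-genome data: read depths and length-variant read
fractions in an MSI-H pool and a control pool, flanking-SNP minor-allele
frequencies, and boolean annotations.  Length variants here include both
insertions and deletions.

Retention requires, in this order (the first failing rule is reported):

1. read depth >= 20 in both the MSI-H and the control group;
2. the repeat does not overlap a common SNP;
3. the combined probability of a minor allele at >= 1 flanking SNP
   (assuming linkage equilibrium) exceeds 0.20;
4. the repeat is not inside a low-complexity/repetitive region;
5. the length-stratified variant-fraction rule: 7-9 bp repeats need no
   length variation among controls and >= 10% variant reads in MSI-H;
   10-12 bp repeats need <= 5% among controls and >= 15% in MSI-H.

Poly-C repeats are rare survivors of these filters; with
``relax_for_polyC`` the depth and flanking-SNP requirements (rules 1 and
3) are waived for them.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .datamodel import DataFormatError, ValidationError
from .io import atomic_write

MIN_DEPTH = 20
MIN_COMBINED_MAF = 0.20
SHORT_MSI_MIN_VAR = 0.10  # 7-9 bp repeats
LONG_CONTROL_MAX_VAR = 0.05  # 10-12 bp repeats
LONG_MSI_MIN_VAR = 0.15


@dataclass(frozen=True)
class RepeatSummary:
    """Per-repeat summary statistics from the discovery sequencing pools."""

    repeat_id: str
    repeat_length: int
    repeat_base: str
    depth_msi: int
    depth_control: int
    var_frac_msi: float
    var_frac_control: float
    overlaps_common_snp: bool = False
    flanking_snp_mafs: tuple[float, ...] = ()
    in_low_complexity: bool = False

    def validate(self) -> None:
        if self.depth_msi < 0 or self.depth_control < 0:
            raise ValidationError(f"repeat {self.repeat_id}: negative depth")
        for name, frac in (
            ("var_frac_msi", self.var_frac_msi),
            ("var_frac_control", self.var_frac_control),
        ):
            if not 0.0 <= frac <= 1.0:
                raise ValidationError(
                    f"repeat {self.repeat_id}: {name} = {frac} outside [0, 1]"
                )


@dataclass(frozen=True)
class SelectionResult:
    repeat_id: str
    retained: bool
    reason: str | None  # first failing rule for excluded repeats


def combined_minor_allele_probability(mafs: Sequence[float]) -> float:
    """Probability of a minor allele at >= 1 flanking SNP.

    Under linkage equilibrium: 1 - prod_j (1 - maf_j).  An empty list
    gives 0.
    """
    product = 1.0
    for maf in mafs:
        if not 0.0 <= maf <= 0.5:
            raise ValidationError(f"minor allele frequency {maf} outside [0, 0.5]")
        product *= 1.0 - maf
    return 1.0 - product


def _length_rule(summary: RepeatSummary) -> str | None:
    if 7 <= summary.repeat_length <= 9:
        if summary.var_frac_control != 0.0:
            return "control_variation"
        if summary.var_frac_msi < SHORT_MSI_MIN_VAR:
            return "msi_variation"
    else:  # 10-12 bp
        if summary.var_frac_control > LONG_CONTROL_MAX_VAR:
            return "control_variation"
        if summary.var_frac_msi < LONG_MSI_MIN_VAR:
            return "msi_variation"
    return None


def select_candidates(
    summaries: Iterable[RepeatSummary], relax_for_polyC: bool = False
) -> list[SelectionResult]:
    """Apply the retention rules, recording the first failing rule."""
    results = []
    for summary in summaries:
        summary.validate()
        relaxed = relax_for_polyC and summary.repeat_base == "C"
        reason = None
        if not relaxed and (
            summary.depth_msi < MIN_DEPTH or summary.depth_control < MIN_DEPTH
        ):
            reason = "depth"
        elif summary.overlaps_common_snp:
            reason = "overlaps_common_snp"
        elif (
            not relaxed
            and combined_minor_allele_probability(summary.flanking_snp_mafs)
            <= MIN_COMBINED_MAF
        ):
            reason = "flanking_snp"
        elif summary.in_low_complexity:
            reason = "low_complexity"
        else:
            reason = _length_rule(summary)
        results.append(
            SelectionResult(summary.repeat_id, reason is None, reason)
        )
    return results


def discovery_retention(
    msi_fractions: Sequence[float], normal_fractions: Sequence[float]
) -> bool:
    """Amplicon-stage retention rule on discovery-cohort deletion fractions.

    A marker is kept iff some MSI-H sample shows a deletion frequency
    above 5% that is also more than 1.5-fold higher than the frequency in
    every normal mucosa sample.
    """
    if not normal_fractions:
        raise ValidationError(
            "discovery_retention requires >= 1 normal sample"
        )
    if not msi_fractions:
        return False
    ceiling = 1.5 * max(normal_fractions)
    return any(f > 0.05 and f > ceiling for f in msi_fractions)


_BOOL_VALUES = {"0": False, "1": True, "true": True, "false": False}


def read_repeat_summaries(path: str | os.PathLike) -> list[RepeatSummary]:
    """Read a repeat-summary TSV.

    Columns: ``repeat_id, repeat_length, repeat_base, depth_msi,
    depth_control, var_frac_msi, var_frac_control, overlaps_common_snp,
    flanking_snp_mafs, in_low_complexity``; mafs are comma-separated
    (empty or "." for none).
    """
    try:
        frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise DataFormatError(f"summaries file {path} is empty") from exc
    required = (
        "repeat_id", "repeat_length", "repeat_base", "depth_msi",
        "depth_control", "var_frac_msi", "var_frac_control",
        "overlaps_common_snp", "flanking_snp_mafs", "in_low_complexity",
    )
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise DataFormatError(
            f"summaries file {path}: missing columns {missing}"
        )
    summaries = []
    for idx, row in frame.iterrows():
        rownum = int(idx) + 2
        try:
            mafs_raw = row["flanking_snp_mafs"].strip()
            mafs = (
                tuple(float(x) for x in mafs_raw.split(",") if x)
                if mafs_raw not in ("", ".")
                else ()
            )
            summaries.append(
                RepeatSummary(
                    repeat_id=row["repeat_id"],
                    repeat_length=int(row["repeat_length"]),
                    repeat_base=row["repeat_base"],
                    depth_msi=int(row["depth_msi"]),
                    depth_control=int(row["depth_control"]),
                    var_frac_msi=float(row["var_frac_msi"]),
                    var_frac_control=float(row["var_frac_control"]),
                    overlaps_common_snp=_BOOL_VALUES[
                        row["overlaps_common_snp"].lower()
                    ],
                    flanking_snp_mafs=mafs,
                    in_low_complexity=_BOOL_VALUES[
                        row["in_low_complexity"].lower()
                    ],
                )
            )
        except (KeyError, ValueError) as exc:
            raise DataFormatError(
                f"summaries: row {rownum}: {exc}"
            ) from exc
    return summaries


def write_selection(results: Sequence[SelectionResult], path) -> None:
    with atomic_write(path) as out:
        out.write("repeat_id\tretained\treason\n")
        for r in results:
            out.write(f"{r.repeat_id}\t{int(r.retained)}\t{r.reason or '.'}\n")
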