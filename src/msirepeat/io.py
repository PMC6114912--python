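"""Readers and writers for panel, count-table, model, and result files.

All tabular files are plain tab-separated text; the trained model is a
single JSON document carrying its training counts.  Every writer goes
through an atomic write (temp file + rename) so that a failure never
leaves a partial output behind.
"""

from __future__ import annotations

import json
import os
import re
import tempfile
from contextlib import contextmanager
from typing import Iterable, Iterator, Sequence

import pandas as pd

from .datamodel import (
    ClassificationResult,
    DataFormatError,
    LengthHistogram,
    MarkerDefinition,
    MarkerObservation,
    MarkerParameters,
    SampleRecord,
    SnpDefinition,
    SnpObservation,
    TrainedModel,
    ValidationError,
)

MODEL_SCHEMA_VERSION = 1

PANEL_FIXED_COLUMNS = (
    "marker_id",
    "chrom",
    "repeat_start",
    "repeat_length",
    "repeat_base",
    "amplicon_start",
    "amplicon_end",
)

COUNTS_COLUMNS = (
    "sample_id",
    "marker_id",
    "deviation",
    "snp_id",
    "snp_allele",
    "count",
)

_SNP_ID_RE = re.compile(r"^snp(\d+)_id$")


@contextmanager
def atomic_write(path: str | os.PathLike) -> Iterator:
    """Open a temp file for writing and atomically rename it to `path`."""
    path = os.fspath(path)
    directory = os.path.dirname(path) or "."
    fd, tmp = tempfile.mkstemp(dir=directory, prefix=".tmp-", suffix="~")
    try:
        with os.fdopen(fd, "w") as handle:
            yield handle
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _read_tsv(path: str | os.PathLike, context: str) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise DataFormatError(f"{context} file {path} is empty") from exc
    except pd.errors.ParserError as exc:
        raise DataFormatError(f"cannot parse {context} file {path}: {exc}") from exc


def _field(row: pd.Series, column: str, rownum: int, kind, context: str):
    raw = row.get(column, "")
    if raw == "":
        raise DataFormatError(
            f"{context}: row {rownum}: missing value for field {column!r}"
        )
    try:
        return kind(raw)
    except (TypeError, ValueError) as exc:
        raise DataFormatError(
            f"{context}: row {rownum}: field {column!r} has invalid value "
            f"{raw!r}"
        ) from exc


def read_panel(path: str | os.PathLike) -> list[MarkerDefinition]:
    """Read a marker-panel definition table.

    Expected tab-separated columns: ``marker_id, chrom, repeat_start,
    repeat_length, repeat_base, amplicon_start, amplicon_end`` plus
    repeatable flanking-SNP groups ``snpN_id, snpN_pos, snpN_ref,
    snpN_alt[, snpN_maf]``.  Additional columns (e.g. primer sequences)
    are permitted and ignored.  Order of rows is preserved.
    """
    frame = _read_tsv(path, "panel")
    missing = [c for c in PANEL_FIXED_COLUMNS if c not in frame.columns]
    if missing:
        raise DataFormatError(
            f"panel file {path}: missing required columns {missing}"
        )
    snp_groups = sorted(
        int(m.group(1))
        for c in frame.columns
        if (m := _SNP_ID_RE.match(c)) is not None
    )
    markers: list[MarkerDefinition] = []
    seen: set[str] = set()
    for idx, row in frame.iterrows():
        rownum = int(idx) + 2  # 1-based, counting the header line
        marker_id = _field(row, "marker_id", rownum, str, "panel")
        if marker_id in seen:
            raise DataFormatError(
                f"panel: row {rownum}: duplicate marker_id {marker_id!r}"
            )
        seen.add(marker_id)
        snps = []
        for g in snp_groups:
            snp_id = str(row.get(f"snp{g}_id", "")).strip()
            if not snp_id or snp_id == ".":
                continue
            maf_raw = str(row.get(f"snp{g}_maf", "")).strip()
            snps.append(
                SnpDefinition(
                    snp_id=snp_id,
                    position=_field(row, f"snp{g}_pos", rownum, int, "panel"),
                    ref_allele=_field(row, f"snp{g}_ref", rownum, str, "panel"),
                    alt_allele=_field(row, f"snp{g}_alt", rownum, str, "panel"),
                    maf=float(maf_raw) if maf_raw and maf_raw != "." else None,
                )
            )
        marker = MarkerDefinition(
            marker_id=marker_id,
            chromosome=_field(row, "chrom", rownum, str, "panel"),
            repeat_start=_field(row, "repeat_start", rownum, int, "panel"),
            repeat_length=_field(row, "repeat_length", rownum, int, "panel"),
            repeat_base=_field(row, "repeat_base", rownum, str, "panel"),
            amplicon_interval=(
                _field(row, "amplicon_start", rownum, int, "panel"),
                _field(row, "amplicon_end", rownum, int, "panel"),
            ),
            flanking_snps=tuple(snps),
        )
        try:
            marker.validate()
        except ValidationError as exc:
            raise ValidationError(f"panel: row {rownum}: {exc}") from exc
        markers.append(marker)
    return markers


def write_panel(markers: Sequence[MarkerDefinition], path) -> None:
    n_snps = max((len(m.flanking_snps) for m in markers), default=0)
    header = list(PANEL_FIXED_COLUMNS)
    for g in range(1, n_snps + 1):
        header += [f"snp{g}_id", f"snp{g}_pos", f"snp{g}_ref", f"snp{g}_alt",
                   f"snp{g}_maf"]
    with atomic_write(path) as out:
        out.write("\t".join(header) + "\n")
        for m in markers:
            fields = [
                m.marker_id, m.chromosome, str(m.repeat_start),
                str(m.repeat_length), m.repeat_base,
                str(m.amplicon_interval[0]), str(m.amplicon_interval[1]),
            ]
            for g in range(n_snps):
                if g < len(m.flanking_snps):
                    s = m.flanking_snps[g]
                    fields += [s.snp_id, str(s.position), s.ref_allele,
                               s.alt_allele,
                               "" if s.maf is None else repr(s.maf)]
                else:
                    fields += ["", "", "", "", ""]
            out.write("\t".join(fields) + "\n")


def read_counts_table(path: str | os.PathLike) -> list[SampleRecord]:
    """Read a long-format per-sample per-marker deviation count table.

    Columns: ``sample_id, marker_id, deviation, snp_id, snp_allele,
    count``.  Rows with ``snp_id == "ALL"`` (and ``snp_allele == "."``)
    populate the marker histogram; other rows populate the allele-
    stratified histogram of the named SNP.  Duplicate keys and negative
    counts are errors.
    """
    frame = _read_tsv(path, "counts")
    missing = [c for c in COUNTS_COLUMNS if c not in frame.columns]
    if missing:
        raise DataFormatError(
            f"counts file {path}: missing required columns {missing}"
        )
    samples: dict[str, SampleRecord] = {}
    seen: set[tuple] = set()
    for idx, row in frame.iterrows():
        rownum = int(idx) + 2
        sample_id = _field(row, "sample_id", rownum, str, "counts")
        marker_id = _field(row, "marker_id", rownum, str, "counts")
        deviation = _field(row, "deviation", rownum, int, "counts")
        snp_id = _field(row, "snp_id", rownum, str, "counts")
        snp_allele = str(row.get("snp_allele", ".")) or "."
        count = _field(row, "count", rownum, int, "counts")
        if count < 0:
            raise DataFormatError(
                f"counts: row {rownum}: negative count {count}"
            )
        key = (sample_id, marker_id, deviation, snp_id, snp_allele)
        if key in seen:
            raise DataFormatError(f"counts: row {rownum}: duplicate key {key}")
        seen.add(key)
        record = samples.setdefault(sample_id, SampleRecord(sample_id))
        obs = record.observations.setdefault(
            marker_id, MarkerObservation(marker_id)
        )
        if snp_id == "ALL":
            obs.histogram.add(deviation, count)
        else:
            snp_obs = obs.snp_observations.setdefault(
                snp_id, SnpObservation(snp_id)
            )
            hist = snp_obs.allele_histograms.setdefault(
                snp_allele, LengthHistogram()
            )
            hist.add(deviation, count)
    records = list(samples.values())
    for record in records:
        for obs in record.observations.values():
            obs.validate()
    return records


def write_counts_table(samples: Iterable[SampleRecord], path) -> None:
    with atomic_write(path) as out:
        out.write("\t".join(COUNTS_COLUMNS) + "\n")
        for sample in samples:
            for marker_id in sorted(sample.observations):
                obs = sample.observations[marker_id]
                for dev, n in sorted(obs.histogram.counts.items()):
                    out.write(
                        f"{sample.sample_id}\t{marker_id}\t{dev}\tALL\t.\t{n}\n"
                    )
                for snp_id, snp_obs in obs.snp_observations.items():
                    for allele in sorted(snp_obs.allele_histograms):
                        hist = snp_obs.allele_histograms[allele]
                        for dev, n in sorted(hist.counts.items()):
                            out.write(
                                f"{sample.sample_id}\t{marker_id}\t{dev}\t"
                                f"{snp_id}\t{allele}\t{n}\n"
                            )


def read_labels(path: str | os.PathLike) -> dict[str, str]:
    """Read a two-column ``sample_id, label`` table."""
    frame = _read_tsv(path, "labels")
    for column in ("sample_id", "label"):
        if column not in frame.columns:
            raise DataFormatError(f"labels file {path}: missing column {column}")
    labels: dict[str, str] = {}
    for idx, row in frame.iterrows():
        sample_id = str(row["sample_id"])
        if sample_id in labels:
            raise DataFormatError(
                f"labels: row {int(idx) + 2}: duplicate sample_id {sample_id!r}"
            )
        labels[sample_id] = str(row["label"])
    return labels


def write_labels(labels: dict[str, str], path) -> None:
    with atomic_write(path) as out:
        out.write("sample_id\tlabel\n")
        for sample_id, label in labels.items():
            out.write(f"{sample_id}\t{label}\n")


def apply_labels(samples: Iterable[SampleRecord], labels: dict[str, str]) -> None:
    for sample in samples:
        if sample.sample_id in labels:
            label = labels[sample.sample_id]
            SampleRecord(sample.sample_id, label)  # validates the label
            sample.label = label


def _counts_to_json(counts: dict) -> dict:
    return {k: (list(v) if v is not None else None) for k, v in counts.items()}


def write_model(model: TrainedModel, path) -> None:
    model.validate()
    document = {
        "schema_version": MODEL_SCHEMA_VERSION,
        "prior_msi": model.prior_msi,
        "prior_mss": model.prior_mss,
        "bias_alpha": model.bias_alpha,
        "pseudocount": model.pseudocount,
        "provenance": model.provenance,
        "markers": [
            {
                "marker_id": p.marker_id,
                "threshold": p.threshold,
                "p_d_msi": p.p_d_msi,
                "p_d_mss": p.p_d_mss,
                "p_b_msi": p.p_b_msi,
                "p_b_mss": p.p_b_mss,
                "counts": _counts_to_json(p.counts),
            }
            for p in model.markers.values()
        ],
    }
    with atomic_write(path) as out:
        json.dump(document, out, indent=1)
        out.write("\n")


def read_model(path: str | os.PathLike) -> TrainedModel:
    try:
        with open(path) as handle:
            document = json.load(handle)
    except json.JSONDecodeError as exc:
        raise DataFormatError(f"model file {path} is not valid JSON: {exc}") from exc
    if not isinstance(document, dict):
        raise DataFormatError(f"model file {path}: top level is not an object")
    if document.get("schema_version") != MODEL_SCHEMA_VERSION:
        raise DataFormatError(
            f"model file {path}: unsupported schema_version "
            f"{document.get('schema_version')!r}"
        )
    for key in ("prior_msi", "prior_mss", "bias_alpha", "pseudocount", "markers"):
        if key not in document:
            raise DataFormatError(f"model file {path}: missing field {key!r}")
    markers: dict[str, MarkerParameters] = {}
    for entry in document["markers"]:
        for key in ("marker_id", "threshold", "p_d_msi", "p_d_mss",
                    "p_b_msi", "p_b_mss", "counts"):
            if key not in entry:
                raise DataFormatError(
                    f"model file {path}: marker entry missing field {key!r}"
                )
        counts = {
            k: (tuple(v) if v is not None else None)
            for k, v in entry["counts"].items()
        }
        params = MarkerParameters(
            marker_id=entry["marker_id"],
            threshold=entry["threshold"],
            p_d_msi=entry["p_d_msi"],
            p_d_mss=entry["p_d_mss"],
            p_b_msi=entry["p_b_msi"],
            p_b_mss=entry["p_b_mss"],
            counts=counts,
        )
        markers[params.marker_id] = params
    model = TrainedModel(
        markers=markers,
        prior_msi=document["prior_msi"],
        prior_mss=document["prior_mss"],
        bias_alpha=document["bias_alpha"],
        pseudocount=document["pseudocount"],
        provenance=document.get("provenance", {}),
    )
    model.validate()
    return model


def write_results(results: Sequence[ClassificationResult], path) -> None:
    with atomic_write(path) as out:
        out.write("sample_id\tscore\tcall\tn_markers_used\tn_bias_assessed\n")
        for r in results:
            score = "" if r.score is None else f"{r.score:.6f}"
            out.write(
                f"{r.sample_id}\t{score}\t{r.call}\t{r.n_markers_used}\t"
                f"{r.n_bias_assessed}\n"
            )


def write_result_details(results: Sequence[ClassificationResult], path) -> None:
    columns = ("sample_id", "marker_id", "used", "d", "b", "snp_id",
               "bias_p", "log10_factor", "note")
    with atomic_write(path) as out:
        out.write("\t".join(columns) + "\n")
        for r in results:
            for c in r.contributions:
                fields = [
                    r.sample_id, c.marker_id, str(int(c.used)),
                    "." if c.d is None else str(int(c.d)),
                    "." if c.b is None else str(int(c.b)),
                    c.snp_id or ".",
                    "." if c.bias_p is None else f"{c.bias_p:.6g}",
                    "." if c.log10_factor is None else f"{c.log10_factor:.6f}",
                    c.note,
                ]
                out.write("\t".join(fields) + "\n")
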