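"""Domain types and file round trips: panel, counts, model, results."""

import json

import pytest

from msirepeat.datamodel import (
    DataFormatError,
    LengthHistogram,
    MarkerParameters,
    NotComputableError,
    TrainedModel,
    ValidationError,
    call_heterozygous,
)
from msirepeat.io import (
    read_counts_table,
    read_labels,
    read_model,
    read_panel,
    write_counts_table,
    write_labels,
    write_model,
    write_panel,
)

from conftest import make_observation, make_sample

PANEL_HEADER = (
    "marker_id\tchrom\trepeat_start\trepeat_length\trepeat_base\t"
    "amplicon_start\tamplicon_end\tprimer_fwd\t"
    "snp1_id\tsnp1_pos\tsnp1_ref\tsnp1_alt\tsnp1_maf\n"
)


class TestPanelReader:
    def test_reads_markers_with_snps_and_ignores_primer_columns(self, tmp_path):
        path = tmp_path / "panel.tsv"
        path.write_text(
            PANEL_HEADER
            + "LR44\tchr20\t100\t12\tA\t61\t180\tACGTACGT\t"
            "rs1\t89\tG\tA\t0.3\n"
            + "LR46\tchr20\t500\t8\tA\t461\t580\tTTTTACGT\t"
            "rs6040079\t489\tG\tA\t0.4\n"
        )
        markers = read_panel(path)
        assert [m.marker_id for m in markers] == ["LR44", "LR46"]
        assert markers[0].repeat_length == 12
        assert markers[0].repeat_base == "A"
        assert markers[1].repeat_length == 8
        assert markers[1].flanking_snps[0].snp_id == "rs6040079"
        assert markers[1].flanking_snps[0].maf == pytest.approx(0.4)

    def test_empty_file_with_header_gives_empty_list(self, tmp_path):
        path = tmp_path / "panel.tsv"
        path.write_text(PANEL_HEADER)
        assert read_panel(path) == []

    def test_malformed_row_names_row_and_field(self, tmp_path):
        path = tmp_path / "panel.tsv"
        path.write_text(
            PANEL_HEADER + "LRX\tchr1\toops\t8\tA\t1\t200\t.\t.\t.\t.\t.\t.\n"
        )
        with pytest.raises(DataFormatError, match=r"row 2.*repeat_start"):
            read_panel(path)

    def test_repeat_length_out_of_range_rejected(self, tmp_path):
        path = tmp_path / "panel.tsv"
        path.write_text(
            PANEL_HEADER + "LRX\tchr1\t100\t15\tA\t1\t300\t.\t.\t.\t.\t.\t.\n"
        )
        with pytest.raises(ValidationError, match="repeat_length 15"):
            read_panel(path)

    def test_distant_snp_rejected(self, tmp_path):
        path = tmp_path / "panel.tsv"
        path.write_text(
            PANEL_HEADER
            + "LRX\tchr1\t100\t8\tA\t1\t300\t.\trs9\t10\tG\tA\t0.3\n"
        )
        with pytest.raises(ValidationError, match="rs9"):
            read_panel(path)

    def test_write_read_round_trip(self, tmp_path, marker_8a, marker_12a):
        path = tmp_path / "panel.tsv"
        write_panel([marker_8a, marker_12a], path)
        assert read_panel(path) == [marker_8a, marker_12a]


class TestCountsTable:
    def test_marker_histogram_assembly(self, tmp_path):
        path = tmp_path / "counts.tsv"
        path.write_text(
            "sample_id\tmarker_id\tdeviation\tsnp_id\tsnp_allele\tcount\n"
            "s1\tLR46\t-1\tALL\t.\t15\n"
            "s1\tLR46\t0\tALL\t.\t85\n"
        )
        (record,) = read_counts_table(path)
        obs = record.observations["LR46"]
        assert obs.histogram.counts == {-1: 15, 0: 85}
        assert obs.histogram.total == 100

    def test_two_markers_one_record(self, tmp_path):
        path = tmp_path / "counts.tsv"
        path.write_text(
            "sample_id\tmarker_id\tdeviation\tsnp_id\tsnp_allele\tcount\n"
            "s1\tLR46\t0\tALL\t.\t50\n"
            "s1\tLR44\t0\tALL\t.\t60\n"
        )
        (record,) = read_counts_table(path)
        assert set(record.observations) == {"LR44", "LR46"}

    def test_allele_rows_build_per_allele_histograms(self, tmp_path):
        path = tmp_path / "counts.tsv"
        path.write_text(
            "sample_id\tmarker_id\tdeviation\tsnp_id\tsnp_allele\tcount\n"
            "s1\tLR46\t-1\tALL\t.\t32\n"
            "s1\tLR46\t0\tALL\t.\t48\n"
            "s1\tLR46\t-1\trs6040079\tG\t30\n"
            "s1\tLR46\t0\trs6040079\tG\t10\n"
            "s1\tLR46\t-1\trs6040079\tA\t2\n"
            "s1\tLR46\t0\trs6040079\tA\t38\n"
        )
        (record,) = read_counts_table(path)
        snp_obs = record.observations["LR46"].snp_observations["rs6040079"]
        assert snp_obs.allele_histograms["G"].counts == {-1: 30, 0: 10}
        assert snp_obs.allele_histograms["A"].counts == {-1: 2, 0: 38}
        assert snp_obs.heterozygous is True

    def test_negative_count_rejected(self, tmp_path):
        path = tmp_path / "counts.tsv"
        path.write_text(
            "sample_id\tmarker_id\tdeviation\tsnp_id\tsnp_allele\tcount\n"
            "s1\tLR46\t0\tALL\t.\t-3\n"
        )
        with pytest.raises(DataFormatError, match="negative count"):
            read_counts_table(path)

    def test_duplicate_key_rejected(self, tmp_path):
        path = tmp_path / "counts.tsv"
        path.write_text(
            "sample_id\tmarker_id\tdeviation\tsnp_id\tsnp_allele\tcount\n"
            "s1\tLR46\t0\tALL\t.\t3\n"
            "s1\tLR46\t0\tALL\t.\t4\n"
        )
        with pytest.raises(DataFormatError, match="duplicate key"):
            read_counts_table(path)

    def test_round_trip_preserves_histograms(self, tmp_path):
        sample = make_sample(
            "s9",
            "MSI-H",
            [
                make_observation(
                    "LR46",
                    {-2: 3, -1: 20, 0: 70, 1: 7},
                    {"rs1": {"G": {-1: 18, 0: 30}, "A": {-1: 2, 0: 40}}},
                )
            ],
        )
        path = tmp_path / "counts.tsv"
        write_counts_table([sample], path)
        (reread,) = read_counts_table(path)
        orig = sample.observations["LR46"]
        got = reread.observations["LR46"]
        assert got.histogram == orig.histogram
        assert (
            got.snp_observations["rs1"].allele_histograms
            == orig.snp_observations["rs1"].allele_histograms
        )

    def test_snp_total_exceeding_marker_total_rejected(self, tmp_path):
        path = tmp_path / "counts.tsv"
        path.write_text(
            "sample_id\tmarker_id\tdeviation\tsnp_id\tsnp_allele\tcount\n"
            "s1\tLR46\t0\tALL\t.\t10\n"
            "s1\tLR46\t0\trs1\tG\t20\n"
        )
        with pytest.raises(ValidationError, match="exceeds"):
            read_counts_table(path)


def _model_with_bias_gap() -> TrainedModel:
    return TrainedModel(
        markers={
            "LR44": MarkerParameters(
                "LR44", 0.24, 59 / 68, 5 / 74, 20 / 21, 1 / 6,
                counts={"d_msi": (58, 66), "d_mss": (4, 72),
                        "b_msi": (19, 19), "b_mss": (0, 4)},
            ),
            "LR46": MarkerParameters(
                "LR46", 0.02, 31 / 56, 8 / 148, None, None,
                counts={"d_msi": (30, 54), "d_mss": (7, 146),
                        "b_msi": None, "b_mss": None},
            ),
        },
    )


class TestModelRoundTrip:
    def test_default_priors_round_trip(self, tmp_path):
        model = _model_with_bias_gap()
        path = tmp_path / "model.json"
        write_model(model, path)
        document = json.loads(path.read_text())
        assert document["prior_msi"] == 0.15
        assert document["prior_mss"] == 0.85
        reread = read_model(path)
        assert reread.markers == model.markers
        assert reread.prior_msi == model.prior_msi
        assert reread.bias_alpha == model.bias_alpha

    def test_unavailable_bias_flag_preserved(self, tmp_path):
        path = tmp_path / "model.json"
        write_model(_model_with_bias_gap(), path)
        reread = read_model(path)
        assert not reread.markers["LR46"].bias_available
        assert reread.markers["LR46"].counts["b_msi"] is None

    def test_corrupted_file_raises_without_partial_model(self, tmp_path):
        path = tmp_path / "model.json"
        path.write_text('{"schema_version": 1, "prior_msi": 0.15, ')
        with pytest.raises(DataFormatError, match="not valid JSON"):
            read_model(path)

    def test_missing_field_named(self, tmp_path):
        path = tmp_path / "model.json"
        path.write_text(
            '{"schema_version": 1, "prior_msi": 0.15, "prior_mss": 0.85, '
            '"bias_alpha": 0.05, "markers": []}'
        )
        with pytest.raises(DataFormatError, match="pseudocount"):
            read_model(path)


class TestDomainTypes:
    def test_histogram_rejects_negative_counts(self):
        with pytest.raises(ValidationError):
            LengthHistogram({-1: -5})

    def test_deletion_fraction_examples(self):
        assert LengthHistogram(
            {-2: 5, -1: 15, 0: 75, 1: 5}
        ).deletion_fraction == pytest.approx(0.20)
        assert LengthHistogram({0: 100}).deletion_fraction == 0.0
        assert LengthHistogram({-1: 100}).deletion_fraction == 1.0

    def test_deletion_fraction_undefined_for_empty(self):
        with pytest.raises(NotComputableError):
            LengthHistogram({}).deletion_fraction

    def test_heterozygosity_boundary_inclusive(self):
        assert call_heterozygous({"A": 20, "G": 80}) is True
        assert call_heterozygous({"A": 19, "G": 81}) is False
        assert call_heterozygous({"A": 0, "G": 50}) is False
        assert call_heterozygous({}) is None

    def test_usable_depth_rule(self):
        assert make_observation("m", {0: 20}).usable
        assert not make_observation("m", {0: 19}).usable


def test_labels_round_trip(tmp_path):
    path = tmp_path / "labels.tsv"
    write_labels({"s1": "MSI-H", "s2": "MSS"}, path)
    assert read_labels(path) == {"s1": "MSI-H", "s2": "MSS"}
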