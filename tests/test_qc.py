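"""Depth-table / variant parsing, coverage assessment, call classification."""

from __future__ import annotations

import pytest

from covdesign.design import DetectionDesign, evaluate_design, min_variant_reads
from covdesign.qc import (
    DepthRecord,
    ParseError,
    VariantObservation,
    assess_coverage,
    build_report,
    classify_observation,
    read_depth_table,
    read_report_json,
    read_variant_observations,
    write_failing_bed,
    write_report,
)

DESIGN = DetectionDesign(vaf=0.03, error=0.0116, alpha_fp=0.001, min_detection=0.999)


def decision_at(depth):
    k = min_variant_reads(depth, DESIGN.error, DESIGN.alpha_fp)
    return evaluate_design(depth, min(k, depth), DESIGN)


class TestReadDepthTable:
    def test_samtools_depth_rows(self, tmp_path):
        path = tmp_path / "d.tsv"
        path.write_text("chr17\t7579472\t5210\n")
        assert read_depth_table(path) == [DepthRecord("chr17", 7579472, 5210)]

    def test_bed_expansion_is_one_based(self, tmp_path):
        path = tmp_path / "d.bed"
        path.write_text("chr17\t10\t12\t100\n")
        records = read_depth_table(path, format="bed")
        assert records == [
            DepthRecord("chr17", 11, 100),
            DepthRecord("chr17", 12, 100),
        ]

    def test_empty_file_empty_list(self, tmp_path, caplog):
        path = tmp_path / "empty.tsv"
        path.write_text("")
        with caplog.at_level("WARNING"):
            assert read_depth_table(path) == []
        assert "empty" in caplog.text

    def test_malformed_row_reports_line_number(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("chr17\t100\t50\nchr17\tnot_a_pos\t60\n")
        with pytest.raises(ParseError, match="line 2"):
            read_depth_table(path)

    def test_negative_depth_rejected(self, tmp_path):
        path = tmp_path / "neg.tsv"
        path.write_text("chr17\t100\t-5\n")
        with pytest.raises(ParseError):
            read_depth_table(path)

    def test_unknown_format_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="format"):
            read_depth_table(tmp_path / "x", format="cram")


class TestReadVariants:
    def test_vcf_ad_parsing(self, variants_vcf):
        obs = read_variant_observations(variants_vcf, format="vcf")
        biallelic = obs[0]
        assert (biallelic.total_depth, biallelic.variant_reads) == (100, 5)
        # multiallelic record expands per ALT with the shared total
        multi = {(o.alt, o.variant_reads) for o in obs[1:]}
        assert multi == {("T", 6), ("G", 4)}
        assert all(o.total_depth == 100 for o in obs[1:])

    def test_tsv_parsing_and_vaf(self, variants_tsv):
        obs = read_variant_observations(variants_tsv, format="tsv")
        assert obs[0].vaf == pytest.approx(0.032)
        assert obs[1].variant_reads == 0

    def test_variant_reads_exceeding_depth_rejected(self, tmp_path):
        path = tmp_path / "v.tsv"
        path.write_text(
            "chrom\tpos\tref\talt\tdepth\tvariant_reads\nchr1\t5\tA\tG\t10\t11\n"
        )
        with pytest.raises(ParseError, match="exceeds"):
            read_variant_observations(path, format="tsv")

    def test_vcf_without_ad_or_derivable_counts_errors(self, tmp_path):
        text = (
            "##fileformat=VCFv4.2\n"
            '##contig=<ID=chr1,length=1000>\n'
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="GT">\n'
            '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="DP">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\n"
            "chr1\t100\t.\tA\tG\t.\tPASS\t.\tGT:DP\t0/1:80\n"
        )
        path = tmp_path / "noad.vcf"
        path.write_text(text)
        with pytest.raises(ParseError, match="AD"):
            read_variant_observations(path, format="vcf")


class TestAssessCoverage:
    def test_half_covered_fixture(self, depth_tsv):
        records = read_depth_table(depth_tsv)
        summary = assess_coverage(records, required_depth=1650)
        assert summary.fraction_at_depth == 0.5
        (iv,) = summary.failing_intervals
        assert iv.end - iv.start + 1 == 5
        assert iv.min_depth == 1000

    def test_full_coverage_no_intervals(self):
        records = [DepthRecord("chr1", p, 2000) for p in range(1, 11)]
        summary = assess_coverage(records, required_depth=1650)
        assert summary.fraction_at_depth == 1.0
        assert summary.failing_intervals == ()

    def test_non_adjacent_failures_stay_separate(self):
        depths = {5: 10, 6: 2000, 7: 10}
        records = [
            DepthRecord("chr1", p, depths.get(p, 2000)) for p in range(1, 11)
        ]
        summary = assess_coverage(records, required_depth=100)
        assert [(iv.start, iv.end) for iv in summary.failing_intervals] == [
            (5, 5), (7, 7),
        ]

    def test_fraction_invariant_to_order(self, depth_tsv):
        records = read_depth_table(depth_tsv)
        shuffled = list(reversed(records))
        assert (
            assess_coverage(shuffled, 1650).fraction_at_depth
            == assess_coverage(records, 1650).fraction_at_depth
        )

    def test_empty_records_error(self):
        with pytest.raises(ValueError, match="empty"):
            assess_coverage([], 100)

    def test_bed_coordinate_round_trip(self, tmp_path):
        """BED -> per-base records -> failing intervals -> BED reproduces
        the original half-open intervals."""
        src = tmp_path / "in.bed"
        src.write_text("chr17\t10\t12\t5\nchr17\t20\t25\t7\n")
        records = read_depth_table(src, format="bed")
        summary = assess_coverage(records, required_depth=100)
        out = tmp_path / "out.bed"
        write_failing_bed(summary, out)
        got = [line.split("\t")[:3] for line in out.read_text().splitlines()]
        assert got == [["chr17", "10", "12"], ["chr17", "20", "25"]]


class TestClassifyObservation:
    def test_confident_positive(self):
        obs = VariantObservation("chr17", 7578406, "C", "T", 5000, 160)
        call = classify_observation(obs, decision_at(2000), DESIGN, lod=0.01)
        assert call.status == "positive"
        assert call.observed_vaf == pytest.approx(0.032)
        assert call.threshold_used == min_variant_reads(5000, 0.0116, 0.001)

    def test_no_variant_reads_negative(self):
        obs = VariantObservation("chr17", 1, "G", "A", 100, 0)
        design = DetectionDesign(
            vaf=0.10, error=0.01, alpha_fp=0.001, min_detection=0.999
        )
        dec = evaluate_design(100, 10, design)
        assert classify_observation(obs, dec, design).status == "negative"

    def test_below_design_depth_gated(self):
        obs = VariantObservation("chr17", 1, "G", "A", 50, 10)
        assert (
            classify_observation(obs, decision_at(1650), DESIGN).status
            == "insufficient-depth"
        )

    def test_confirmation_band_flags_low_vaf_positive(self):
        obs = VariantObservation("chr17", 1, "G", "A", 5000, 100)  # VAF 2%
        call = classify_observation(
            obs, decision_at(2000), DESIGN, lod=0.01, confirmation_band=(0.01, 0.03)
        )
        assert call.status == "needs-confirmation"

    def test_positive_below_lod_labelled(self):
        obs = VariantObservation("chr17", 1, "G", "A", 5000, 100)  # VAF 2%
        call = classify_observation(
            obs, decision_at(2000), DESIGN, lod=0.03, confirmation_band=(0.001, 0.005)
        )
        assert call.status == "below-LOD"

    def test_monotone_in_variant_reads(self):
        """More variant reads never turns a call from positive to
        negative (statuses only move toward calling)."""
        dec = decision_at(2000)
        called = []
        for reads in range(0, 400, 25):
            obs = VariantObservation("chr17", 1, "G", "A", 5000, reads)
            status = classify_observation(obs, dec, DESIGN).status
            called.append(status != "negative")
        assert called == sorted(called)  # False... then True...


class TestReport:
    def test_json_round_trip(self, tmp_path, depth_tsv, variants_tsv):
        records = read_depth_table(depth_tsv)
        obs = read_variant_observations(variants_tsv, format="tsv")
        report = build_report(
            DESIGN, decision_at(2000), records, obs,
            dna_input="100 ng", dna_source="peripheral blood",
            dna_quality="high", software_version="0.1.0", seed=7,
        )
        path = tmp_path / "report.json"
        write_report(report, path, format="json")
        assert read_report_json(path) == report

    def test_tsv_carries_design_echo_and_rows(self, tmp_path, variants_tsv):
        obs = read_variant_observations(variants_tsv, format="tsv")
        report = build_report(DESIGN, decision_at(2000), (), obs)
        path = tmp_path / "report.tsv"
        write_report(report, path, format="tsv")
        text = path.read_text()
        assert "# lod=0.03" in text
        assert "# overall_error=0.0116" in text
        assert "# required_depth=2000" in text
        assert "# threshold=40" in text
        data_rows = [
            line for line in text.splitlines() if not line.startswith("#")
        ]
        assert len(data_rows) == 1 + 2  # header + two variants

    def test_minimal_report(self, tmp_path):
        report = build_report(DESIGN, decision_at(2000))
        path = tmp_path / "min.tsv"
        write_report(report, path)
        assert "# min_detection=0.999" in path.read_text()
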