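"""I/O round-trips, coverage readers agreeing across routes, GC handling."""

from __future__ import annotations

import numpy as np
import pytest

from binrefine.formats_io import (
    Bin,
    Scaffold,
    read_bins,
    read_coverage_perbase,
    read_coverage_sam,
    read_coverage_tsv,
    read_hits,
    read_taxonomy,
    read_trace,
    write_refined_bins,
    write_trace,
    TraceRecord,
)


def write_fasta(path, records):
    with open(path, "w") as fh:
        for sid, seq in records:
            fh.write(f">{sid}\n{seq}\n")


class TestScaffold:
    def test_gc_counts_gc_over_non_n(self):
        assert Scaffold("s", 8, "ACGTACGT").gc == 0.5
        assert Scaffold("s", 6, "GGGCCN").gc == pytest.approx(1.0)

    def test_gc_of_all_n_is_undefined_not_zero(self):
        assert Scaffold("s", 4, "NNNN").gc is None
        assert Scaffold("s", 4).gc is None

    def test_length_sequence_mismatch_rejected(self):
        with pytest.raises(ValueError):
            Scaffold("s", 5, "ACGT")
        with pytest.raises(ValueError):
            Scaffold("s", 0)


class TestReadBins:
    def test_single_fasta_becomes_one_bin_named_from_stem(self, tmp_path):
        p = tmp_path / "myBin.fasta"
        write_fasta(p, [("s1", "ACGT"), ("s2", "GGCC"), ("s3", "ATAT")])
        scaffolds, bins = read_bins([p])
        assert set(bins) == {"myBin"}
        assert bins["myBin"].members == {"s1", "s2", "s3"}
        assert scaffolds["s2"].sequence == "GGCC"

    def test_contig2bin_table_assigns_members(self, tmp_path):
        p = tmp_path / "all.fasta"
        write_fasta(p, [("s1", "AC"), ("s2", "GT"), ("s3", "AA")])
        table = tmp_path / "c2b.tsv"
        table.write_text("s1\tbinA\ns2\tbinA\ns3\tbinB\n")
        _, bins = read_bins([p], table)
        assert len(bins["binA"]) == 2 and len(bins["binB"]) == 1

    def test_orphan_in_table_is_error_naming_the_id(self, tmp_path):
        p = tmp_path / "all.fasta"
        write_fasta(p, [("s1", "AC")])
        table = tmp_path / "c2b.tsv"
        table.write_text("s1\tbinA\nsX\tbinA\n")
        with pytest.raises(ValueError, match="sX"):
            read_bins([p], table)

    def test_duplicate_scaffold_across_files_is_error_naming_sources(self, tmp_path):
        p1, p2 = tmp_path / "a.fasta", tmp_path / "b.fasta"
        write_fasta(p1, [("s1", "AC")])
        write_fasta(p2, [("s1", "GT")])
        with pytest.raises(ValueError, match="a.fasta"):
            read_bins([p1, p2])


class TestCoverageReaders:
    def test_depth_tsv_canonical_dialect(self, tmp_path):
        p = tmp_path / "depth.tsv"
        p.write_text(
            "contigName\tcontigLen\ttotalAvgDepth\td1\td1-var\td2\td2-var\n"
            "s1\t1000\t12.0\t10.0\t1.0\t14.0\t2.0\n"
        )
        cov = read_coverage_tsv(p)
        assert cov.datasets == ["d1", "d2"]
        assert cov.depth("s1", "d1") == 10.0
        assert cov.depth("s1", "d2") == 14.0

    def test_depth_tsv_negative_depth_rejected(self, tmp_path):
        p = tmp_path / "depth.tsv"
        p.write_text("contigName\tcontigLen\ttotalAvgDepth\td1\ns1\t10\t1\t-2\n")
        with pytest.raises(ValueError):
            read_coverage_tsv(p)

    def test_single_half_aligned_read_gives_mean_half(self, tmp_path):
        # scaffold length 100, one fully aligned 50 bp read -> mean depth 0.5
        sam = tmp_path / "a.sam"
        sam.write_text(
            "@HD\tVN:1.6\n@SQ\tSN:s1\tLN:100\n"
            "r1\t0\ts1\t1\t60\t50M\t*\t0\t0\t*\t*\n"
        )
        cov = read_coverage_sam({"d": sam}, {"s1": Scaffold("s1", 100)})
        assert cov.depth("s1", "d") == 0.5

    def test_sam_and_perbase_routes_agree_on_toy_alignment(self, tmp_path):
        """Five reads with matches, a deletion, an insertion and a soft clip:
        the SAM route and a hand-expanded per-base depth table must agree."""
        length = 100
        reads = [
            ("r1", 1, "50M"),
            ("r2", 26, "50M"),
            ("r3", 51, "20M5D25M"),
            ("r4", 1, "10M2I38M"),
            ("r5", 40, "5S45M"),
        ]
        sam = tmp_path / "toy.sam"
        with open(sam, "w") as fh:
            fh.write("@HD\tVN:1.6\n@SQ\tSN:s1\tLN:100\n")
            for rid, pos, cigar in reads:
                fh.write(f"{rid}\t0\ts1\t{pos}\t60\t{cigar}\t*\t0\t0\t*\t*\n")
        # independent expansion: walk each cigar, mark M-covered positions
        per_base = np.zeros(length + 1)
        import re
        for _, pos, cigar in reads:
            ref = pos
            for ln, op in re.findall(r"(\d+)([MIDNSHP=X])", cigar):
                ln = int(ln)
                if op in "M=X":
                    per_base[ref:ref + ln] += 1
                    ref += ln
                elif op in "DN":
                    ref += ln
        pb = tmp_path / "perbase.tsv"
        with open(pb, "w") as fh:
            for i in range(1, length + 1):
                fh.write(f"s1\t{i}\t{int(per_base[i])}\n")
        scaffolds = {"s1": Scaffold("s1", length)}
        cov_sam = read_coverage_sam({"d": sam}, scaffolds)
        cov_pb = read_coverage_perbase(pb, scaffolds, dataset="d")
        assert cov_sam.depth("s1", "d") == cov_pb.depth("s1", "d")

    def test_sam_secondary_and_supplementary_excluded(self, tmp_path):
        sam = tmp_path / "a.sam"
        sam.write_text(
            "@HD\tVN:1.6\n@SQ\tSN:s1\tLN:100\n"
            "r1\t0\ts1\t1\t60\t50M\t*\t0\t0\t*\t*\n"
            "r1\t256\ts1\t1\t60\t50M\t*\t0\t0\t*\t*\n"
            "r1\t2048\ts1\t1\t60\t50M\t*\t0\t0\t*\t*\n"
        )
        cov = read_coverage_sam({"d": sam}, {"s1": Scaffold("s1", 100)})
        assert cov.depth("s1", "d") == 0.5

    def test_sam_unknown_scaffold_skipped_with_warning(self, tmp_path):
        sam = tmp_path / "a.sam"
        sam.write_text(
            "@HD\tVN:1.6\n@SQ\tSN:s1\tLN:100\n@SQ\tSN:sX\tLN:100\n"
            "r1\t0\tsX\t1\t60\t50M\t*\t0\t0\t*\t*\n"
        )
        with pytest.warns(UserWarning, match="skipped"):
            cov = read_coverage_sam({"d": sam}, {"s1": Scaffold("s1", 100)})
        assert cov.depth("s1", "d") == 0.0


class TestHitsAndTaxonomy:
    def _tax(self, tmp_path):
        p = tmp_path / "tax.tsv"
        p.write_text("root\troot\tno rank\troot\np1\troot\tphylum\tP1\n")
        return read_taxonomy(p)

    def _hit_line(self, sid, taxid, evalue="1e-30", score="200"):
        return (f"{sid}\tsubj\t99\t100\t0\t0\t1\t100\t1\t100\t{evalue}\t{score}"
                f"\t{taxid}\n")

    def test_well_formed_lines_parsed(self, tmp_path):
        tax = self._tax(tmp_path)
        p = tmp_path / "hits.tsv"
        p.write_text("".join(self._hit_line(f"s{i}", "p1") for i in range(3)))
        table, dropped = read_hits(p, tax)
        assert len(table) == 3 and dropped == 0
        # e-value cutoff is NOT applied at read time
        p2 = tmp_path / "weak.tsv"
        p2.write_text(self._hit_line("s1", "p1", evalue="1e-5"))
        table2, _ = read_hits(p2, tax)
        assert len(table2) == 1

    def test_unresolvable_taxon_dropped_and_counted(self, tmp_path):
        tax = self._tax(tmp_path)
        p = tmp_path / "hits.tsv"
        p.write_text(
            self._hit_line("s1", "p1") + self._hit_line("s2", "p1")
            + self._hit_line("s3", "p999")
        )
        table, dropped = read_hits(p, tax)
        assert len(table) == 2 and dropped == 1

    def test_empty_file_gives_empty_table(self, tmp_path):
        tax = self._tax(tmp_path)
        p = tmp_path / "hits.tsv"
        p.write_text("")
        table, dropped = read_hits(p, tax)
        assert len(table) == 0 and dropped == 0

    def test_taxonomy_requires_single_root(self, tmp_path):
        p = tmp_path / "tax.tsv"
        p.write_text("r1\tr1\tno rank\ta\nr2\tr2\tno rank\tb\n")
        with pytest.raises(ValueError, match="root"):
            read_taxonomy(p)


class TestWriters:
    def test_bins_round_trip_preserves_members_and_sequences(self, tmp_path):
        scaffolds = {
            "s1": Scaffold("s1", 4, "ACGT"),
            "s2": Scaffold("s2", 4, "GGCC"),
            "s3": Scaffold("s3", 4, "ATAT"),
        }
        bins = {
            "binA": Bin("binA", {"s1", "s2"}),
            "binB": Bin("binB", {"s3"}),
        }
        manifest = write_refined_bins(bins, scaffolds, tmp_path / "out")
        paths = [tmp_path / "out" / manifest[b]["path"] for b in sorted(manifest)]
        scaffolds2, bins2 = read_bins(paths)
        assert {b: bins2[b].members for b in bins2} == {
            "binA": {"s1", "s2"}, "binB": {"s3"}}
        assert scaffolds2["s2"].sequence == "GGCC"

    def test_fasta_requested_without_sequences_errors_naming_scaffolds(self, tmp_path):
        scaffolds = {"s1": Scaffold("s1", 10)}
        with pytest.raises(ValueError, match="s1"):
            write_refined_bins({"b": Bin("b", {"s1"})}, scaffolds, tmp_path / "o")

    def test_existing_output_needs_overwrite_flag(self, tmp_path):
        scaffolds = {"s1": Scaffold("s1", 2, "AC")}
        bins = {"b": Bin("b", {"s1"})}
        write_refined_bins(bins, scaffolds, tmp_path / "o")
        with pytest.raises(FileExistsError):
            write_refined_bins(bins, scaffolds, tmp_path / "o")
        write_refined_bins(bins, scaffolds, tmp_path / "o", overwrite=True)

    def test_trace_round_trip_in_stage_order(self, tmp_path):
        trace = [
            TraceRecord("median_filter", "b", f"s{i}", "remove", "median_outlier",
                        3.0, "d=40>3x10")
            for i in range(4)
        ]
        path = write_trace(trace, tmp_path / "trace.tsv")
        back = read_trace(path)
        assert len(back) == 4
        assert [r.scaffold_id for r in back] == [f"s{i}" for i in range(4)]
        assert all(r.action == "remove" for r in back)
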