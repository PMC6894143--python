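"""Data model invariants, coordinate conventions, and format round-trips."""

from __future__ import annotations

import numpy as np
import pytest

from svdriver import io as svio
from svdriver.model import GenomicInterval, PhenotypeProfile, SVSet
from svdriver.position_effects import top_expressing_cell_types

from conftest import make_gene, make_junction

VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">
##INFO=<ID=END,Number=1,Type=Integer,Description="End">
##INFO=<ID=MATEID,Number=1,Type=String,Description="Mate id">
##contig=<ID=chr1,length=10000000>
##contig=<ID=chr2,length=10000000>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


class TestModel:
    def test_interval_requires_start_before_end(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 100, 100)
        with pytest.raises(ValueError):
            GenomicInterval("", 0, 10)

    def test_del_junction_requires_ordered_positions(self):
        with pytest.raises(ValueError):
            make_junction("j", "chr1", 500, "chr1", 100, "DEL")

    def test_tss_strand_convention(self):
        plus = make_gene("A", "chr1", 100, 200, "+")
        minus = make_gene("B", "chr1", 100, 200, "-")
        assert plus.tss == 100
        assert minus.tss == 199

    def test_bnd_pairs_are_not_copy_number_spans(self):
        # an intra-chromosomal BND junction must not materialize a span
        j = make_junction("j", "chr1", 100, "chr1", 5000, "BND")
        assert SVSet("P", [j]).spans() == []

    def test_complex_sv_forty_junctions_four_chromosomes(self):
        # a chromothripsis-scale rearrangement is one junction set
        rng = np.random.default_rng(0)
        junctions = [
            make_junction(
                f"j{i}", f"chr{i % 4 + 1}", int(rng.integers(0, 1_000_000)),
                f"chr{(i + 1) % 4 + 1}", int(rng.integers(0, 1_000_000)),
            )
            for i in range(40)
        ]
        svs = SVSet("P25", junctions)
        assert len(svs.junctions) == 40
        assert svs.chromosomes == {"chr1", "chr2", "chr3", "chr4"}


class TestBedpe:
    def test_three_rows_three_junctions(self, tmp_path):
        p = tmp_path / "svs.bedpe"
        rows = [
            "chr1\t100\t101\tchr1\t500\t501\tj1\t.\t+\t-\tDEL",
            "chr2\t100\t101\tchr3\t900\t901\tj2\t.\t+\t-",
            "chr1\t7000\t7001\tchr1\t9000\t9001\tj3\t.\t-\t+\tDUP",
        ]
        p.write_text("\n".join(rows) + "\n")
        svs = svio.read_sv_bedpe(p, "P1")
        assert len(svs.junctions) == 3
        assert svs.junctions[0].sv_type == "DEL"
        assert svs.junctions[1].sv_type == "BND"

    def test_round_trip(self, tmp_path):
        svs = SVSet("P1", [
            make_junction("a", "chr1", 10, "chr2", 99, "TRA", patient="P1"),
            make_junction("b", "chr1", 100, "chr1", 900, "DEL", patient="P1"),
        ])
        path = tmp_path / "rt.bedpe"
        svio.write_sv_bedpe(svs, path)
        back = svio.read_sv_bedpe(path, "P1")
        assert back.junctions == svs.junctions

    def test_malformed_orientation_is_an_error(self, tmp_path):
        p = tmp_path / "bad.bedpe"
        p.write_text("chr1\t1\t2\tchr1\t5\t6\tj\t.\t+\t?\n")
        with pytest.raises(ValueError, match="orientation"):
            svio.read_sv_bedpe(p)


class TestVcf:
    def test_del_coordinates_converted_once(self, tmp_path):
        # POS=100, END=500 (1-based) -> internal [99, 500)
        p = tmp_path / "sv.vcf"
        p.write_text(VCF_HEADER + "chr1\t100\tdel1\tN\t<DEL>\t.\tPASS\tSVTYPE=DEL;END=500\n")
        svs = svio.read_sv_vcf(p, "P1")
        (j,) = svs.junctions
        assert (j.pos_a.position, j.pos_b.position) == (99, 500)
        assert j.span() == GenomicInterval("chr1", 99, 500)

    def test_bnd_mates_paired_by_mateid(self, tmp_path):
        p = tmp_path / "bnd.vcf"
        p.write_text(
            VCF_HEADER
            + "chr1\t1000\tbnd_a\tN\tN[chr2:5000[\t.\tPASS\tSVTYPE=BND;MATEID=bnd_b\n"
            + "chr2\t5000\tbnd_b\tN\t]chr1:1000]N\t.\tPASS\tSVTYPE=BND;MATEID=bnd_a\n"
        )
        svs = svio.read_sv_vcf(p, "P1")
        (j,) = svs.junctions
        assert {j.pos_a.chrom, j.pos_b.chrom} == {"chr1", "chr2"}

    def test_unpaired_bnd_is_an_error(self, tmp_path):
        p = tmp_path / "bad.vcf"
        p.write_text(VCF_HEADER + "chr1\t1000\tbnd_x\tN\tN[chr2:5000[\t.\tPASS\tSVTYPE=BND;MATEID=bnd_y\n")
        with pytest.raises(ValueError, match="bnd_x"):
            svio.read_sv_vcf(p)


class TestResources:
    def test_bundle_reader_counts(self, tmp_path):
        for ct in ("CTA", "CTB"):
            (tmp_path / f"tads_{ct}.bed").write_text(
                "".join(f"chr1\t{i * 1000}\t{(i + 1) * 1000}\n" for i in range(5))
            )
        (tmp_path / "resources.yaml").write_text(
            "cell_types: [CTA, CTB]\n"
            "tads:\n  CTA: tads_CTA.bed\n  CTB: tads_CTB.bed\n"
        )
        bundle = svio.read_resource_bundle(tmp_path / "resources.yaml")
        assert sum(len(v["chr1"]) for v in bundle.tads.values()) == 10

    def test_duplicate_cell_type_is_an_error(self, tmp_path):
        (tmp_path / "resources.yaml").write_text("cell_types: [CTA, CTA]\n")
        with pytest.raises(ValueError, match="duplicate"):
            svio.read_resource_bundle(tmp_path / "resources.yaml")

    def test_overlapping_enhancers_kept_as_is(self, tmp_path):
        p = tmp_path / "enh.bed"
        p.write_text("chr1\t100\t300\nchr1\t200\t400\n")
        assert svio.read_bed_intervals(p)["chr1"] == [(100, 300), (200, 400)]

    def test_hic_bin_out_of_range_is_an_error(self, tmp_path):
        p = tmp_path / "hic.tsv"
        p.write_text("chr1\t0\t99\t1.5\n")
        with pytest.raises(ValueError, match="bin index"):
            svio.read_hic_triplets(p, 1000, {"chr1": 50_000})

    def test_hic_triplets_round_trip(self, tmp_path):
        rng = np.random.default_rng(5)
        m = rng.poisson(2.0, size=(12, 12)).astype(float)
        m = np.triu(m) + np.triu(m, 1).T
        path = tmp_path / "hic.tsv"
        svio.write_hic_triplets({"chr1": m}, path)
        back = svio.read_hic_triplets(path, 1000, {"chr1": 12_000})
        np.testing.assert_allclose(back["chr1"], m)

    def test_missing_gene_treated_as_not_expressed(self, tmp_path):
        (tmp_path / "expr.tsv").write_text("gene\tCTA\nGENEX\t9.0\n")
        expr = svio.read_expression_table(tmp_path / "expr.tsv")
        assert svio.gene_rpkm(expr, "ABSENT", "CTA") == 0.0
        # and downstream the gene counts as unexpressed (no top cell types)
        gene = make_gene("ABSENT", "chr1", 0, 1000)
        assert top_expressing_cell_types(gene, expr) == []


class TestReports:
    def _call(self, patient, symbol, tier, total=1.0):
        from svdriver.classify import DriverCall
        from svdriver.gene_scoring import DiseaseAssociationScore, PhenotypeAssociation
        from svdriver.phenomatch import PhenomatchResult
        from svdriver.position_effects import SVEffect

        assoc = PhenotypeAssociation(
            strength="weak",
            disease_score=DiseaseAssociationScore(1, 0, 0, 0, 0),
            phenomatch=PhenomatchResult(gene=symbol, total_score=total),
            moi_compatible=False,
        )
        return DriverCall(
            patient_id=patient, symbol=symbol, tier=tier, association=assoc,
            effect=SVEffect("weak", "position"), direct_category="adjacent",
            distance_bp=100, effect_basis="position",
        )

    def test_tier_ordering_and_determinism(self, tmp_path):
        calls = [self._call("P1", "B", "T2"), self._call("P1", "A", "T1")]
        summary = {"n_patients": 1}
        svio.write_driver_report(calls, [], summary, tmp_path / "r1")
        svio.write_driver_report(list(reversed(calls)), [], summary, tmp_path / "r2")
        lines = (tmp_path / "r1" / "drivers.tsv").read_text().splitlines()
        assert lines[1].split("\t")[1] == "A"  # T1 row precedes T2 row
        assert (tmp_path / "r1" / "drivers.tsv").read_bytes() == (
            tmp_path / "r2" / "drivers.tsv"
        ).read_bytes()

    def test_empty_report_has_header_only(self, tmp_path):
        svio.write_driver_report([], [], {"n_patients": 0}, tmp_path / "r")
        lines = (tmp_path / "r" / "drivers.tsv").read_text().splitlines()
        assert len(lines) == 1 and lines[0].startswith("patient_id\t")


class TestGeneTable:
    def test_round_trip_and_protein_coding_filter(self, tmp_path):
        genes = [
            make_gene("A", "chr1", 10, 500, "+", pLI=0.97, in_omim=True,
                      modes_of_inheritance=frozenset({"AD", "AR"})),
            make_gene("B", "chr2", 100, 900, "-", rvis_percentile=3.5,
                      clingen_hi_triplo=2),
        ]
        path = tmp_path / "genes.tsv"
        svio.write_gene_table(genes, path)
        # append a non-protein-coding row (no RefSeq id)
        with open(path, "a") as fh:
            fh.write("LINC1\tchr1\t5\t50\t+\t\t\t\t\t\t0\t0\t\n")
        back = svio.read_gene_table(path)
        assert [g.symbol for g in back] == ["A", "B"]
        assert back[0] == genes[0]
        assert back[1] == genes[1]

    def test_hpo_profile_round_trip(self, tmp_path):
        prof = PhenotypeProfile("P9", frozenset({"HP:0000001", "HP:0000002"}), "female")
        path = tmp_path / "p.hpo.tsv"
        svio.write_hpo_profile(prof, path)
        assert svio.read_hpo_profile(path) == prof
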