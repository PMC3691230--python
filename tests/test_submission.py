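"""Submission outputs: FASTA, AGP 2.0, feature table, locus_tag renumbering."""

import io

import pytest
from Bio import SeqIO

from scaffoldsmith import (
    Annotation,
    ContigRecord,
    FixtureSpec,
    Scaffold,
    SequenceEntry,
    SubmissionError,
    UnresolvedEntry,
    assemble,
    component_records,
    derive_cds,
    features_from_genes,
    generate_fixture,
    lift_all,
    reconstruct_from_agp,
    render_agp,
    render_fasta,
    render_tbl,
    renumber_locus_tags,
)


def gene(start, stop, strand="+", **attrs):
    return Annotation(
        seqid="s", source="t", ftype="gene", start=start, stop=stop,
        strand=strand, attributes=attrs,
    )


class TestRenderFasta:
    def test_short_record_is_two_lines(self):
        assert render_fasta([("r1", "ACGTA")]) == ">r1\nACGTA\n"

    def test_wrap_boundary_at_70(self):
        text = render_fasta([("r1", "A" * 71)])
        lines = text.splitlines()
        assert lines == [">r1", "A" * 70, "A"]

    def test_duplicate_id_rejected(self):
        with pytest.raises(SubmissionError, match="duplicate"):
            render_fasta([("r", "AC"), ("r", "GT")])

    def test_round_trip_via_independent_reader(self):
        # Biopython's parser is the independent FASTA oracle.
        records = [("r1", "ACGT" * 40), ("r2", "N" * 70), ("r3", "GATTACA")]
        parsed = list(SeqIO.parse(io.StringIO(render_fasta(records)), "fasta"))
        assert [(r.id, str(r.seq)) for r in parsed] == records


class TestAgp:
    @pytest.fixture()
    def simple(self):
        contigs = {
            "c1": ContigRecord("c1", "ACGTA"),
            "c2": ContigRecord("c2", "GGCC"),
        }
        sc = Scaffold(
            entries=(SequenceEntry("c1"), UnresolvedEntry(3), SequenceEntry("c2"))
        )
        return contigs, sc, assemble(sc, contigs, "scaf")

    def test_three_rows_with_gap_vocabulary(self, simple):
        _, _, asm = simple
        lines = render_agp(asm).splitlines()
        assert lines[0] == "##agp-version\t2.0"
        rows = [l.split("\t") for l in lines[1:]]
        assert len(rows) == 3
        assert rows[1] == ["scaf", "6", "8", "2", "N", "3", "scaffold", "yes", "unspecified"]
        assert [r[3] for r in rows] == ["1", "2", "3"]

    def test_single_forward_contig_row(self):
        contigs = {"c1": ContigRecord("c1", "ACGTACGT")}
        asm = assemble(Scaffold(entries=(SequenceEntry("c1"),)), contigs, "s")
        row = render_agp(asm).splitlines()[1].split("\t")
        assert row == ["s", "1", "8", "1", "W", "c1", "1", "8", "+"]

    def test_reconstruction_equals_assembly(self, simple):
        _, _, asm = simple
        agp = render_agp(asm)
        assert reconstruct_from_agp(agp, dict(component_records(asm))) == asm.seq

    def test_reconstruction_single_row_whole_contig(self):
        agp = "obj\t1\t4\t1\tW\tc1\t1\t4\t+\n"
        assert reconstruct_from_agp(agp, {"c1": "ACGT"}) == "ACGT"

    def test_minus_row_reverse_complements(self):
        agp = "obj\t1\t4\t1\tW\tc1\t1\t4\t-\n"
        assert reconstruct_from_agp(agp, {"c1": "AACC"}) == "GGTT"

    def test_one_bp_hole_is_tiling_violation(self):
        agp = "obj\t1\t4\t1\tW\tc1\t1\t4\t+\nobj\t6\t9\t2\tW\tc2\t1\t4\t+\n"
        with pytest.raises(SubmissionError, match="tiling"):
            reconstruct_from_agp(agp, {"c1": "ACGT", "c2": "ACGT"})

    def test_component_coordinate_out_of_range(self):
        agp = "obj\t1\t9\t1\tW\tc1\t1\t9\t+\n"
        with pytest.raises(SubmissionError, match="outside"):
            reconstruct_from_agp(agp, {"c1": "ACGT"})

    def test_nonsequential_part_numbers_rejected(self):
        agp = "obj\t1\t4\t2\tW\tc1\t1\t4\t+\n"
        with pytest.raises(SubmissionError, match="part_number"):
            reconstruct_from_agp(agp, {"c1": "ACGT"})

    def test_component_records_cover_trims_and_inserts(self, toy_assembled):
        # components are the placed slices, forward orientation; AGP rows
        # must address them 1..length.
        comps = dict(component_records(toy_assembled))
        for seg, (name, seq) in zip(
            toy_assembled.contig_segments(), component_records(toy_assembled)
        ):
            assert len(seq) == len(seg)
        agp = render_agp(toy_assembled)
        assert reconstruct_from_agp(agp, comps) == toy_assembled.seq

    def test_repeated_placement_gets_numbered_components(self):
        contigs = {"c1": ContigRecord("c1", "ACGTACGTAC")}
        sc = Scaffold(
            entries=(SequenceEntry("c1"), UnresolvedEntry(4), SequenceEntry("c1", reverse=True))
        )
        asm = assemble(sc, contigs, "s")
        names = [n for n, _ in component_records(asm)]
        assert names == ["c1_1", "c1_2"]
        assert reconstruct_from_agp(render_agp(asm), dict(component_records(asm))) == asm.seq

    def test_master_property_on_random_fixtures(self):
        for seed in range(1, 16):
            fx = generate_fixture(FixtureSpec(seed=seed))
            asm = assemble(fx.scaffold, fx.contigs, "s")
            agp = render_agp(asm)
            assert reconstruct_from_agp(agp, dict(component_records(asm))) == asm.seq


class TestDeriveCds:
    def test_plus_strand_gene_and_cds(self):
        feats = derive_cds(
            gene(103, 106, "+", locus_tag="X_00010", product="DNA polymerase")
        )
        assert [(f.start, f.stop, f.key) for f in feats] == [
            (103, 106, "gene"),
            (103, 106, "CDS"),
        ]
        assert ("product", "DNA polymerase") in feats[1].qualifiers
        assert ("locus_tag", "X_00010") in feats[0].qualifiers
        assert ("locus_tag", "X_00010") in feats[1].qualifiers

    def test_minus_strand_encodes_start_greater_than_stop(self):
        feats = derive_cds(gene(5, 8, "-", locus_tag="X_1"))
        assert [(f.start, f.stop) for f in feats] == [(8, 5), (8, 5)]

    def test_missing_product_defaults_to_hypothetical_protein(self):
        feats = derive_cds(gene(1, 9, "+", locus_tag="X_1"))
        assert ("product", "hypothetical protein") in feats[1].qualifiers

    def test_non_gene_feature_rejected(self):
        bad = Annotation(seqid="s", source="t", ftype="tRNA", start=1, stop=9)
        with pytest.raises(SubmissionError, match="gene"):
            derive_cds(bad)

    def test_gene_name_qualifier_from_name_attribute(self):
        feats = derive_cds(gene(1, 9, "+", locus_tag="X_1", Name="dnaA"))
        assert ("gene", "dnaA") in feats[0].qualifiers


class TestRenumberLocusTags:
    def test_step_ten_zero_padded(self):
        genes = [gene(10, 90, ID="a"), gene(200, 300, ID="b"), gene(400, 500, ID="c")]
        out = renumber_locus_tags(genes, "PFLU")
        assert [g.attributes["locus_tag"] for g in out] == [
            "PFLU_00010",
            "PFLU_00020",
            "PFLU_00030",
        ]

    def test_single_gene_gets_first_tag(self):
        out = renumber_locus_tags([gene(5000, 6000)], "ABC")
        assert out[0].attributes["locus_tag"] == "ABC_00010"

    def test_idempotent(self):
        genes = [gene(10, 90), gene(200, 300)]
        once = renumber_locus_tags(genes, "P")
        twice = renumber_locus_tags(once, "P")
        assert [g.attributes["locus_tag"] for g in once] == [
            g.attributes["locus_tag"] for g in twice
        ]

    def test_empty_prefix_rejected(self):
        with pytest.raises(SubmissionError, match="prefix"):
            renumber_locus_tags([gene(1, 9)], "")


class TestRenderTbl:
    def test_exact_tab_layout(self):
        feats = features_from_genes(
            [gene(103, 106, "+", locus_tag="X_00010", product="DNA polymerase")]
        )
        text = render_tbl("scaf1", feats)
        assert text == (
            ">Feature scaf1\n"
            "103\t106\tgene\n"
            "\t\t\tlocus_tag\tX_00010\n"
            "103\t106\tCDS\n"
            "\t\t\tproduct\tDNA polymerase\n"
            "\t\t\tlocus_tag\tX_00010\n"
        )

    def test_empty_feature_list_is_header_only(self):
        assert render_tbl("s", []) == ">Feature s\n"

    def test_minus_strand_first_column_greater(self):
        feats = features_from_genes([gene(5, 8, "-", locus_tag="L_1")])
        lines = render_tbl("s", feats).splitlines()
        start, stop, key = lines[1].split("\t")
        assert int(start) > int(stop) and key == "gene"

    def test_coordinate_outside_sequence_rejected(self):
        feats = features_from_genes([gene(5, 80, "+")])
        with pytest.raises(SubmissionError, match="outside"):
            render_tbl("s", feats, seq_length=50)
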