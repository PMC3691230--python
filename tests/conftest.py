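"""Shared toy fixture: a small hand-built finishing scenario.

Three contigs, one reversed, one trimmed, one patched with an insert, two
gaps, and a handful of genes — every coordinate transformation in one
scaffold, small enough to verify by hand.
"""

import pytest

from scaffoldsmith import (
    Annotation,
    ContigRecord,
    Insert,
    Scaffold,
    SequenceEntry,
    UnresolvedEntry,
    assemble,
)


@pytest.fixture(scope="session")
def toy_contigs():
    return {
        c.id: c
        for c in [
            # 40 bp, placed forward untouched
            ContigRecord("ctgA", "ATGGCGTACGATCGATTACGGATCTAGCATCGATTGCAAT"),
            # 40 bp, placed reverse-complemented
            ContigRecord("ctgB", "TTGACCATGGATCCGTTAACGGCATTAGCCTAGGCATGCA"),
            # 50 bp, bases 11..20 replaced by the 6 bp patch, then trimmed
            ContigRecord("ctgC", "AAAACCCCGGGGTTTTACGTAAAACCCCGGGGTTTTACGTAAAACCCCGG"),
            ContigRecord("patch1", "GGCGCC"),
        ]
    }


@pytest.fixture(scope="session")
def toy_scaffold():
    return Scaffold(
        entries=(
            SequenceEntry(source_id="ctgA"),
            UnresolvedEntry(length=10),
            SequenceEntry(source_id="ctgB", reverse=True),
            UnresolvedEntry(length=5),
            SequenceEntry(
                source_id="ctgC",
                start=3,
                stop=40,
                inserts=(Insert(source_id="patch1", open=11, close=20),),
            ),
        )
    )


@pytest.fixture(scope="session")
def toy_annotations():
    return [
        Annotation(
            seqid="ctgA", source="toy", ftype="gene", start=5, stop=16, strand="+",
            attributes={"ID": "geneA1", "locus_tag": "TOY_1", "product": "replicase"},
        ),
        Annotation(
            seqid="ctgB", source="toy", ftype="gene", start=3, stop=10, strand="+",
            attributes={"ID": "geneB1", "locus_tag": "TOY_2"},
        ),
        # entirely downstream of ctgC's replaced span [11, 20]: survives
        Annotation(
            seqid="ctgC", source="toy", ftype="gene", start=25, stop=36, strand="-",
            attributes={"ID": "geneC1", "locus_tag": "TOY_3", "product": "helicase"},
        ),
        # straddles the replaced span: dropped
        Annotation(
            seqid="ctgC", source="toy", ftype="gene", start=8, stop=14, strand="+",
            attributes={"ID": "geneC2", "locus_tag": "TOY_4"},
        ),
        # on a contig that is not placed at all
        Annotation(
            seqid="ctgZ", source="toy", ftype="gene", start=1, stop=9, strand="+",
            attributes={"ID": "geneZ1"},
        ),
    ]


@pytest.fixture(scope="session")
def toy_assembled(toy_scaffold, toy_contigs):
    return assemble(toy_scaffold, toy_contigs, identifier="toyscaf")


@pytest.fixture()
def toy_project_dir(tmp_path, toy_contigs, toy_scaffold, toy_annotations):
    """The toy scenario written out as CLI input files."""
    from scaffoldsmith import render_fasta, write_gff3, write_scaffold

    (tmp_path / "contigs.fasta").write_text(
        render_fasta([(c.id, c.seq) for c in toy_contigs.values()])
    )
    (tmp_path / "scaffold.yml").write_text(write_scaffold(toy_scaffold))
    (tmp_path / "annotations.gff3").write_text(write_gff3(toy_annotations))
    return tmp_path
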