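"""Generate the GenBank submission file set for an assembled scaffold.

Four artifacts cover a draft-genome submission: the assembled sequence as
FASTA, the placed component (contig) sequences as multi-FASTA, an AGP 2.0
file describing how components and gaps tile the scaffold, and an NCBI
5-column feature table (.tbl) consumed by tbl2asn/sequin.  The ``.asn``
submission itself is out of scope — these files are the *inputs* to the
GenBank tools.

Component records are the placed slices: each contig segment of the layout
contributes one record holding its post-insert, trimmed (but not
reverse-complemented) sequence, so AGP component coordinates (1..length,
orientation ``+``/``-``) are valid against the emitted contig FASTA.
``reconstruct_from_agp`` is the independent check that ties the three
sequence artifacts together: splicing the AGP rows back out of the contig
records must reproduce the assembled sequence byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .annotation_lift import Annotation
from .assembly import AssembledScaffold, reverse_complement
from .scaffold_format import ContigRecord

__all__ = [
    "AgpRow",
    "TblFeature",
    "SubmissionError",
    "render_fasta",
    "component_records",
    "render_agp",
    "parse_agp",
    "reconstruct_from_agp",
    "derive_cds",
    "renumber_locus_tags",
    "render_tbl",
    "features_from_genes",
]

FASTA_WIDTH = 70  # GenBank-toolchain default line wrap, pinned for determinism

LOCUS_TAG_START = 10
LOCUS_TAG_STEP = 10
LOCUS_TAG_WIDTH = 5


class SubmissionError(ValueError):
    """Raised for inconsistent submission inputs (duplicate ids, bad AGP...)."""


def render_fasta(records: list[tuple[str, str]]) -> str:
    """Render (id, sequence) pairs as FASTA, wrapped at 70 columns."""
    seen: set[str] = set()
    lines: list[str] = []
    for rec_id, seq in records:
        if not rec_id:
            raise SubmissionError("FASTA record id must be non-empty")
        if rec_id in seen:
            raise SubmissionError(f"duplicate FASTA record id {rec_id!r}")
        seen.add(rec_id)
        lines.append(f">{rec_id}")
        for i in range(0, len(seq), FASTA_WIDTH):
            lines.append(seq[i : i + FASTA_WIDTH])
    return "\n".join(lines) + "\n"


def component_records(assembled: AssembledScaffold) -> list[tuple[str, str]]:
    """The contig-FASTA records backing the AGP: one per placed segment.

    Each record is the placed slice in its forward (source) orientation.
    A contig placed more than once yields numbered components
    (``<id>_1``, ``<id>_2``, ...) so that ids stay unique.
    """
    counts: dict[str, int] = {}
    for seg in assembled.contig_segments():
        counts[seg.source_id] = counts.get(seg.source_id, 0) + 1
    seen: dict[str, int] = {}
    records: list[tuple[str, str]] = []
    for seg in assembled.contig_segments():
        rendered = assembled.entry_sequences[seg.entry_index]
        forward = reverse_complement(rendered) if seg.reversed else rendered
        if counts[seg.source_id] == 1:
            name = seg.source_id
        else:
            seen[seg.source_id] = seen.get(seg.source_id, 0) + 1
            name = f"{seg.source_id}_{seen[seg.source_id]}"
        records.append((name, forward))
    return records


@dataclass(frozen=True)
class AgpRow:
    """One AGP 2.0 line: a component (W) or gap (N/U) span of the object."""

    object: str
    object_beg: int
    object_end: int
    part_number: int
    component_type: str  # W | N | U
    # W rows
    component_id: str | None = None
    component_beg: int | None = None
    component_end: int | None = None
    orientation: str | None = None  # + | -
    # N/U rows
    gap_length: int | None = None
    gap_type: str | None = None
    linkage: str | None = None
    linkage_evidence: str | None = None

    def to_line(self) -> str:
        if self.component_type == "W":
            tail = (
                self.component_id,
                str(self.component_beg),
                str(self.component_end),
                self.orientation,
            )
        else:
            tail = (
                str(self.gap_length),
                self.gap_type,
                self.linkage,
                self.linkage_evidence,
            )
        return "\t".join(
            (
                self.object,
                str(self.object_beg),
                str(self.object_end),
                str(self.part_number),
                self.component_type,
                *tail,
            )
        )


def agp_rows(assembled: AssembledScaffold) -> list[AgpRow]:
    """Build the AGP rows for an assembled scaffold, one per layout segment."""
    components = component_records(assembled)
    rows: list[AgpRow] = []
    contig_i = 0
    for part, seg in enumerate(assembled.layout, start=1):
        if seg.kind == "gap":
            rows.append(
                AgpRow(
                    object=assembled.identifier,
                    object_beg=seg.scaffold_start,
                    object_end=seg.scaffold_stop,
                    part_number=part,
                    component_type="N",
                    gap_length=len(seg),
                    gap_type="scaffold",
                    linkage="yes",
                    linkage_evidence="unspecified",
                )
            )
        else:
            name, comp_seq = components[contig_i]
            contig_i += 1
            rows.append(
                AgpRow(
                    object=assembled.identifier,
                    object_beg=seg.scaffold_start,
                    object_end=seg.scaffold_stop,
                    part_number=part,
                    component_type="W",
                    component_id=name,
                    component_beg=1,
                    component_end=len(comp_seq),
                    orientation="-" if seg.reversed else "+",
                )
            )
    return rows


def render_agp(assembled: AssembledScaffold) -> str:
    """Render the AGP 2.0 text describing the placement of contigs."""
    lines = ["##agp-version\t2.0"]
    lines.extend(row.to_line() for row in agp_rows(assembled))
    return "\n".join(lines) + "\n"


def parse_agp(text: str) -> list[AgpRow]:
    """Parse AGP text (comment lines skipped) into :class:`AgpRow` objects."""
    rows: list[AgpRow] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 9:
            raise SubmissionError(
                f"AGP line {lineno}: expected 9 tab-separated columns, "
                f"got {len(cols)}"
            )
        ctype = cols[4]
        common = dict(
            object=cols[0],
            object_beg=int(cols[1]),
            object_end=int(cols[2]),
            part_number=int(cols[3]),
            component_type=ctype,
        )
        if ctype == "W":
            rows.append(
                AgpRow(
                    **common,
                    component_id=cols[5],
                    component_beg=int(cols[6]),
                    component_end=int(cols[7]),
                    orientation=cols[8],
                )
            )
        elif ctype in {"N", "U"}:
            rows.append(
                AgpRow(
                    **common,
                    gap_length=int(cols[5]),
                    gap_type=cols[6],
                    linkage=cols[7],
                    linkage_evidence=cols[8],
                )
            )
        else:
            raise SubmissionError(
                f"AGP line {lineno}: unsupported component type {ctype!r}"
            )
    return rows


def _as_seq_mapping(
    contigs: dict[str, ContigRecord] | dict[str, str] | list[tuple[str, str]],
) -> dict[str, str]:
    if isinstance(contigs, list):
        return dict(contigs)
    return {
        k: (v.seq if isinstance(v, ContigRecord) else v) for k, v in contigs.items()
    }


def reconstruct_from_agp(
    agp: str,
    contigs: dict[str, ContigRecord] | dict[str, str] | list[tuple[str, str]],
) -> str:
    """Rebuild the object sequence an AGP file describes.

    Splices component slices (reverse-complementing ``-`` rows) and N runs,
    verifying as it goes that rows tile the object contiguously from 1 and
    that component coordinates are in range.  This is deliberately a second,
    independent route to the assembled sequence, used to cross-check
    :func:`render_agp` against :func:`~scaffoldsmith.assembly.assemble`.
    """
    seqs = _as_seq_mapping(contigs)
    rows = parse_agp(agp)
    if not rows:
        raise SubmissionError("AGP contains no rows")
    pieces: list[str] = []
    expected_beg = 1
    for i, row in enumerate(rows):
        if row.part_number != i + 1:
            raise SubmissionError(
                f"AGP part_number {row.part_number} out of sequence "
                f"(expected {i + 1})"
            )
        if row.object_beg != expected_beg:
            raise SubmissionError(
                f"AGP tiling violation at part {row.part_number}: object_beg "
                f"{row.object_beg}, expected {expected_beg}"
            )
        span = row.object_end - row.object_beg + 1
        if span < 1:
            raise SubmissionError(
                f"AGP part {row.part_number}: object_end < object_beg"
            )
        if row.component_type == "W":
            if row.component_id not in seqs:
                raise SubmissionError(
                    f"AGP part {row.part_number}: unknown component "
                    f"{row.component_id!r}"
                )
            comp = seqs[row.component_id]
            assert row.component_beg is not None and row.component_end is not None
            if not (1 <= row.component_beg <= row.component_end <= len(comp)):
                raise SubmissionError(
                    f"AGP part {row.part_number}: component coordinates "
                    f"[{row.component_beg}, {row.component_end}] outside "
                    f"{row.component_id!r} (length {len(comp)})"
                )
            if row.component_end - row.component_beg + 1 != span:
                raise SubmissionError(
                    f"AGP part {row.part_number}: object and component spans differ"
                )
            piece = comp[row.component_beg - 1 : row.component_end]
            if row.orientation == "-":
                piece = reverse_complement(piece)
            elif row.orientation != "+":
                raise SubmissionError(
                    f"AGP part {row.part_number}: orientation must be + or -, "
                    f"got {row.orientation!r}"
                )
            pieces.append(piece)
        else:
            if row.gap_length != span:
                raise SubmissionError(
                    f"AGP part {row.part_number}: gap_length {row.gap_length} "
                    f"does not match object span {span}"
                )
            pieces.append("N" * span)
        expected_beg = row.object_end + 1
    return "".join(pieces)


@dataclass(frozen=True)
class TblFeature:
    """One feature-table entry; start > stop encodes the minus strand."""

    start: int
    stop: int
    key: str  # gene | CDS
    qualifiers: tuple[tuple[str, str], ...] = ()


def derive_cds(gene: Annotation) -> list[TblFeature]:
    """Expand a gene annotation into paired gene + CDS table features.

    Both span the same interval (single-interval features, no intron/exon
    structure).  Minus-strand genes are written with start > stop.  The CDS
    inherits the gene's ``product`` (``"hypothetical protein"`` when absent)
    and its ``locus_tag``.
    """
    if gene.ftype != "gene":
        raise SubmissionError(
            f"derive_cds expects a gene feature, got {gene.ftype!r}"
        )
    if gene.strand == "-":
        start, stop = gene.stop, gene.start
    else:
        start, stop = gene.start, gene.stop
    locus_tag = gene.attributes.get("locus_tag")
    gene_name = gene.attributes.get("gene") or gene.attributes.get("Name")
    gene_quals: list[tuple[str, str]] = []
    if locus_tag:
        gene_quals.append(("locus_tag", locus_tag))
    if gene_name:
        gene_quals.append(("gene", gene_name))
    product = gene.attributes.get("product") or "hypothetical protein"
    cds_quals: list[tuple[str, str]] = [("product", product)]
    if locus_tag:
        cds_quals.append(("locus_tag", locus_tag))
    return [
        TblFeature(start=start, stop=stop, key="gene", qualifiers=tuple(gene_quals)),
        TblFeature(start=start, stop=stop, key="CDS", qualifiers=tuple(cds_quals)),
    ]


def renumber_locus_tags(
    annotations: list[Annotation] | tuple[Annotation, ...], prefix: str
) -> list[Annotation]:
    """Assign systematic locus_tags in scaffold order.

    Tags are ``<prefix>_00010, <prefix>_00020, ...`` — numbering starts at
    the sequence origin, steps by 10 (the prokaryotic-annotation convention,
    leaving room for later insertions) and is zero-padded to 5 digits.
    Input must already be sorted by scaffold start.
    """
    if not prefix:
        raise SubmissionError("locus_tag prefix must be non-empty")
    out: list[Annotation] = []
    number = LOCUS_TAG_START
    for ann in annotations:
        attributes = dict(ann.attributes)
        attributes["locus_tag"] = f"{prefix}_{number:0{LOCUS_TAG_WIDTH}d}"
        out.append(replace(ann, attributes=attributes))
        number += LOCUS_TAG_STEP
    return out


def features_from_genes(
    genes: list[Annotation] | tuple[Annotation, ...],
) -> list[TblFeature]:
    """Derive gene + CDS table features for every gene, in input order."""
    features: list[TblFeature] = []
    for gene in genes:
        features.extend(derive_cds(gene))
    return features


def render_tbl(
    identifier: str,
    features: list[TblFeature],
    seq_length: int | None = None,
) -> str:
    """Render features as an NCBI 5-column feature table.

    Layout: a ``>Feature <identifier>`` header; per feature a
    ``start<TAB>stop<TAB>key`` line, then one ``<TAB><TAB><TAB>name<TAB>value``
    line per qualifier in stored order.  When ``seq_length`` is given,
    coordinates outside ``[1, seq_length]`` are an error.
    """
    lines = [f">Feature {identifier}"]
    for feat in features:
        for coord in (feat.start, feat.stop):
            if coord < 1 or (seq_length is not None and coord > seq_length):
                raise SubmissionError(
                    f"feature coordinate {coord} outside sequence"
                    + (f" [1, {seq_length}]" if seq_length is not None else "")
                )
        lines.append(f"{feat.start}\t{feat.stop}\t{feat.key}")
        for name, value in feat.qualifiers:
            lines.append(f"\t\t\t{name}\t{value}")
    return "\n".join(lines) + "\n"
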