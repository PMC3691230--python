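"""Lift GFF3 features from contig coordinates onto the assembled scaffold.

Given annotations in contig space and the layout of an assembled scaffold,
each feature interval is translated into scaffold space.  The translation
accounts for three transformations a placement can apply to its contig:

* **inserts** — a feature overlapping a patch-replaced span no longer has
  its original sequence and is dropped (never silently truncated);
* **trims** — a feature extending into a trimmed-off region is likewise
  dropped, with a reason recorded in the :class:`LiftReport`;
* **orientation** — on a reverse-complemented placement the interval is
  mirrored within the placed slice and the strand flips (``+`` <-> ``-``,
  ``.`` unchanged).

The defining guarantee (asserted heavily in the test suite): for every
lifted feature, the scaffold slice it now addresses is byte-identical to
the contig slice it came from — or its reverse complement on a reversed
placement.  Features on contigs placed more than once are dropped as
ambiguous rather than duplicated, since duplicated locus_tags would be
rejected at submission.  Features are single-interval (no intron/exon
structure), so phase carries through unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .assembly import AssembledScaffold
from .scaffold_format import Scaffold

__all__ = [
    "Annotation",
    "LiftReport",
    "lift_annotation",
    "lift_all",
    "parse_gff3",
    "write_gff3",
    "DROP_NOT_PLACED",
    "DROP_TRIMMED",
    "DROP_INSERT",
    "DROP_AMBIGUOUS",
]

DROP_NOT_PLACED = "contig-not-placed"
DROP_TRIMMED = "overlaps-trimmed-region"
DROP_INSERT = "overlaps-insert-region"
DROP_AMBIGUOUS = "ambiguous-multiple-placements"


@dataclass(frozen=True)
class Annotation:
    """One GFF3 feature; coordinates are 1-based inclusive.

    ``seqid`` names a contig before lifting and the scaffold after.
    ``attributes`` is an ordered mapping (``ID``, ``Name``, ``product``,
    ``locus_tag``, ... as needed).
    """

    seqid: str
    source: str
    ftype: str
    start: int
    stop: int
    score: float | None = None
    strand: str = "."
    phase: int | None = None
    attributes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"feature start must be ≥ 1, got {self.start}")
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def id(self) -> str:
        return self.attributes.get("ID", "")


@dataclass(frozen=True)
class LiftReport:
    """Outcome of a lift: every input feature is lifted or dropped, never both."""

    lifted: tuple[Annotation, ...]
    dropped: tuple[tuple[Annotation, str], ...]


_FLIP = {"+": "-", "-": "+", ".": "."}


def lift_annotation(
    annotation: Annotation,
    assembled: AssembledScaffold,
    scaffold: Scaffold,
) -> Annotation | str:
    """Translate one feature to scaffold coordinates, or return a drop reason.

    The feature interval must survive insert replacement and trimming intact
    within exactly one placement of its contig; otherwise one of
    ``contig-not-placed``, ``overlaps-insert-region``,
    ``overlaps-trimmed-region`` or ``ambiguous-multiple-placements`` is
    returned.  A malformed feature (start > stop) raises ``ValueError``.
    """
    if annotation.start > annotation.stop:
        raise ValueError(
            f"malformed feature {annotation.id or annotation.seqid!r}: "
            f"start {annotation.start} > stop {annotation.stop}"
        )
    placements = [
        seg for seg in assembled.contig_segments()
        if seg.source_id == annotation.seqid
    ]
    if not placements:
        return DROP_NOT_PLACED
    if len(placements) > 1:
        return DROP_AMBIGUOUS
    seg = placements[0]
    omap = assembled.entry_offset_maps[seg.entry_index]
    bi_start = omap.block_index(annotation.start)
    bi_stop = omap.block_index(annotation.stop)
    if bi_start is None or bi_stop is None or bi_start != bi_stop:
        # An endpoint inside a replaced span, or an insert strictly within
        # the interval: the original bases are no longer contiguous.
        return DROP_INSERT
    shift = omap.blocks[bi_start][2]
    mapped_start = annotation.start + shift
    mapped_stop = annotation.stop + shift
    assert seg.source_start is not None and seg.source_stop is not None
    if mapped_start < seg.source_start or mapped_stop > seg.source_stop:
        return DROP_TRIMMED
    if seg.reversed:
        new_start = seg.scaffold_start + (seg.source_stop - mapped_stop)
        new_stop = seg.scaffold_start + (seg.source_stop - mapped_start)
        strand = _FLIP[annotation.strand]
    else:
        new_start = seg.scaffold_start + (mapped_start - seg.source_start)
        new_stop = seg.scaffold_start + (mapped_stop - seg.source_start)
        strand = annotation.strand
    return replace(
        annotation,
        seqid=assembled.identifier,
        start=new_start,
        stop=new_stop,
        strand=strand,
        attributes=dict(annotation.attributes),
    )


def lift_all(
    annotations: list[Annotation],
    assembled: AssembledScaffold,
    scaffold: Scaffold,
) -> LiftReport:
    """Lift a feature set onto the scaffold and partition it into a report.

    Lifted features are sorted by (start, stop, ID); dropped features keep
    input order, each paired with its reason.
    """
    lifted: list[Annotation] = []
    dropped: list[tuple[Annotation, str]] = []
    for ann in annotations:
        result = lift_annotation(ann, assembled, scaffold)
        if isinstance(result, Annotation):
            lifted.append(result)
        else:
            dropped.append((ann, result))
    lifted.sort(key=lambda a: (a.start, a.stop, a.id))
    return LiftReport(lifted=tuple(lifted), dropped=tuple(dropped))


# --- GFF3 reading and writing -------------------------------------------
#
# GFF3 is simple enough to handle directly: 9 tab-separated columns, '.'
# for absent values, percent-escaping in the attribute column.  Only the
# escaping mandated by the format is applied on output.

_ESCAPES = {"%": "%25", ";": "%3B", "=": "%3D", "&": "%26", ",": "%2C",
            "\t": "%09", "\n": "%0A", "\r": "%0D"}


def _escape(value: str) -> str:
    out = value.replace("%", "%25")
    for ch, code in _ESCAPES.items():
        if ch != "%":
            out = out.replace(ch, code)
    return out


def _unescape(value: str) -> str:
    out = value
    for ch, code in _ESCAPES.items():
        if ch != "%":
            out = out.replace(code, ch).replace(code.lower(), ch)
    return out.replace("%25", "%").replace("%25".lower(), "%")


def parse_gff3(text: str) -> list[Annotation]:
    """Parse GFF3 text into a list of :class:`Annotation` (file order)."""
    annotations: list[Annotation] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 9:
            raise ValueError(
                f"GFF3 line {lineno}: expected 9 tab-separated columns, "
                f"got {len(cols)}"
            )
        seqid, source, ftype, start, stop, score, strand, phase, attrs = cols
        attributes: dict[str, str] = {}
        if attrs not in {"", "."}:
            for pair in attrs.split(";"):
                if not pair:
                    continue
                if "=" not in pair:
                    raise ValueError(
                        f"GFF3 line {lineno}: malformed attribute {pair!r}"
                    )
                key, _, value = pair.partition("=")
                attributes[_unescape(key.strip())] = _unescape(value)
        annotations.append(
            Annotation(
                seqid=seqid,
                source=source,
                ftype=ftype,
                start=int(start),
                stop=int(stop),
                score=None if score == "." else float(score),
                strand=strand,
                phase=None if phase == "." else int(phase),
                attributes=attributes,
            )
        )
    return annotations


def _format_score(score: float | None) -> str:
    if score is None:
        return "."
    if float(score).is_integer():
        return str(int(score))
    return repr(score)


def write_gff3(
    annotations: list[Annotation] | tuple[Annotation, ...],
    seqid: str | None = None,
    length: int | None = None,
) -> str:
    """Render annotations as GFF3 text.

    When ``seqid`` and ``length`` are given, a ``##sequence-region``
    directive for the (scaffold) sequence is emitted after the version line.
    """
    lines = ["##gff-version 3"]
    if seqid is not None and length is not None:
        lines.append(f"##sequence-region {seqid} 1 {length}")
    for a in annotations:
        attrs = ";".join(f"{_escape(k)}={_escape(v)}" for k, v in a.attributes.items())
        lines.append(
            "\t".join(
                (
                    a.seqid,
                    a.source,
                    a.ftype,
                    str(a.start),
                    str(a.stop),
                    _format_score(a.score),
                    a.strand,
                    "." if a.phase is None else str(a.phase),
                    attrs or ".",
                )
            )
        )
    return "\n".join(lines) + "\n"
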