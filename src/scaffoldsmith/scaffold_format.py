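"""Parse, validate and write the plain-text scaffold description file.

A scaffold plan is a hand-editable YAML document: an ordered list of
single-key maps, where each item is either a ``sequence`` entry (a contig
placement, optionally trimmed, reverse-complemented, or patched with insert
sequences) or an ``unresolved`` entry (a run of N bases of known length).
Example::

    - sequence:
        source: contig1
        reverse: true
        inserts:
          - source: pcr_patch_1
            open: 120
            close: 180
    - unresolved:
        length: 100
    - sequence:
        source: contig2
        start: 15
        stop: 900

All coordinates are 1-based inclusive.  ``start``/``stop`` trim the contig
*after* inserts have been applied (patch-then-trim), so a trim may remove
part of a patched region.  Unknown keys are a hard error: the file is meant
to be edited by hand, and a typo must fail loudly rather than be ignored.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import yaml
from Bio import SeqIO

__all__ = [
    "ContigRecord",
    "Insert",
    "SequenceEntry",
    "UnresolvedEntry",
    "Scaffold",
    "ScaffoldFormatError",
    "parse_scaffold",
    "write_scaffold",
    "validate_scaffold",
    "read_contig_fasta",
]

# IUPAC nucleotide codes (upper case; input is case-folded on ingest).
IUPAC_DNA = frozenset("ACGTNRYKMSWBDHV")


class ScaffoldFormatError(ValueError):
    """Raised for a malformed scaffold description file."""


@dataclass(frozen=True)
class ContigRecord:
    """A named DNA sequence from the input contig FASTA.

    ``id`` is the first whitespace-delimited token of the FASTA header.
    The sequence is stored upper-case and restricted to IUPAC codes.
    """

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("contig id must be non-empty")
        if not self.seq:
            raise ValueError(f"contig {self.id!r}: sequence must be non-empty")
        seq = self.seq.upper()
        bad = set(seq) - IUPAC_DNA
        if bad:
            offset = next(i for i, c in enumerate(seq) if c in bad)
            raise ValueError(
                f"contig {self.id!r}: unknown character {seq[offset]!r} "
                f"at position {offset + 1}"
            )
        object.__setattr__(self, "seq", seq)

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class Insert:
    """A patch sequence replacing host bases [open, close] (1-based inclusive).

    ``source_id`` names a record in the contig set whose whole sequence is
    spliced in place of the replaced span.  The patch need not have the same
    length as the span it replaces.
    """

    source_id: str
    open: int
    close: int


@dataclass(frozen=True)
class SequenceEntry:
    """One contig placement in the scaffold plan.

    Processing order is inserts -> trim -> orientation.  ``start``/``stop``
    are 1-based inclusive trim coordinates in the post-insert sequence;
    ``stop=None`` means "up to the post-insert end".
    """

    source_id: str
    start: int = 1
    stop: int | None = None
    reverse: bool = False
    inserts: tuple[Insert, ...] = ()


@dataclass(frozen=True)
class UnresolvedEntry:
    """An unresolved gap of known length, rendered as that many N bases."""

    length: int


@dataclass(frozen=True)
class Scaffold:
    """An ordered scaffold plan: contig placements and unresolved gaps."""

    entries: tuple[SequenceEntry | UnresolvedEntry, ...]

    def sequence_entries(self) -> list[tuple[int, SequenceEntry]]:
        return [
            (i, e) for i, e in enumerate(self.entries) if isinstance(e, SequenceEntry)
        ]


def _require_int(value: object, what: str, minimum: int = 1) -> int:
    if isinstance(value, bool) or not isinstance(value, int):
        raise ScaffoldFormatError(f"{what} must be an integer, got {value!r}")
    if value < minimum:
        raise ScaffoldFormatError(f"{what} must be ≥ {minimum}, got {value}")
    return value


_SEQUENCE_KEYS = {"source", "start", "stop", "reverse", "inserts"}
_INSERT_KEYS = {"source", "open", "close"}


def _parse_insert(raw: object, where: str) -> Insert:
    if not isinstance(raw, dict):
        raise ScaffoldFormatError(f"{where}: malformed insert block, expected a map")
    unknown = set(raw) - _INSERT_KEYS
    if unknown:
        raise ScaffoldFormatError(
            f"{where}: unknown insert key(s): {', '.join(sorted(map(str, unknown)))}"
        )
    if "source" not in raw or "open" not in raw or "close" not in raw:
        raise ScaffoldFormatError(
            f"{where}: insert requires 'source', 'open' and 'close'"
        )
    source = raw["source"]
    if not isinstance(source, str) or not source:
        raise ScaffoldFormatError(f"{where}: insert source must be a non-empty string")
    return Insert(
        source_id=source,
        open=_require_int(raw["open"], f"{where}: insert open"),
        close=_require_int(raw["close"], f"{where}: insert close"),
    )


def _parse_sequence(raw: object, where: str) -> SequenceEntry:
    if not isinstance(raw, dict):
        raise ScaffoldFormatError(f"{where}: 'sequence' value must be a map")
    unknown = set(raw) - _SEQUENCE_KEYS
    if unknown:
        raise ScaffoldFormatError(
            f"{where}: unknown key(s): {', '.join(sorted(map(str, unknown)))}"
        )
    if "source" not in raw:
        raise ScaffoldFormatError(f"{where}: sequence entry requires 'source'")
    source = raw["source"]
    if not isinstance(source, str) or not source:
        raise ScaffoldFormatError(f"{where}: source must be a non-empty string")
    start = _require_int(raw.get("start", 1), f"{where}: start")
    stop = None
    if raw.get("stop") is not None:
        stop = _require_int(raw["stop"], f"{where}: stop")
    reverse = raw.get("reverse", False)
    if not isinstance(reverse, bool):
        raise ScaffoldFormatError(f"{where}: reverse must be true or false")
    raw_inserts = raw.get("inserts", [])
    if not isinstance(raw_inserts, list):
        raise ScaffoldFormatError(f"{where}: inserts must be a list")
    inserts = tuple(_parse_insert(r, where) for r in raw_inserts)
    return SequenceEntry(
        source_id=source, start=start, stop=stop, reverse=reverse, inserts=inserts
    )


def parse_scaffold(text: str) -> Scaffold:
    """Parse a scaffold description file into a :class:`Scaffold`.

    Defaults are filled in (``start=1``, ``stop=None`` meaning post-insert
    end, ``reverse=False``, no inserts).  Raises :class:`ScaffoldFormatError`
    with a line position on YAML syntax errors, and a named diagnostic on
    unknown keys, non-positive gap lengths, or malformed insert blocks.
    """
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        mark = getattr(exc, "problem_mark", None)
        pos = f" at line {mark.line + 1}, column {mark.column + 1}" if mark else ""
        raise ScaffoldFormatError(f"scaffold file syntax error{pos}: {exc}") from exc
    if doc is None:
        raise ScaffoldFormatError("scaffold file is empty")
    if not isinstance(doc, list):
        raise ScaffoldFormatError("scaffold file must be a YAML list of entries")
    entries: list[SequenceEntry | UnresolvedEntry] = []
    for i, item in enumerate(doc):
        where = f"entry {i + 1}"
        if not isinstance(item, dict) or len(item) != 1:
            raise ScaffoldFormatError(
                f"{where}: each entry must be a single-key map "
                "('sequence' or 'unresolved')"
            )
        (key, value), = item.items()
        if key == "sequence":
            entries.append(_parse_sequence(value, where))
        elif key == "unresolved":
            if not isinstance(value, dict) or set(value) != {"length"}:
                raise ScaffoldFormatError(
                    f"{where}: 'unresolved' takes exactly one key: 'length'"
                )
            length = value["length"]
            if isinstance(length, bool) or not isinstance(length, int) or length < 1:
                raise ScaffoldFormatError(
                    f"{where}: gap length must be ≥ 1, got {length!r}"
                )
            entries.append(UnresolvedEntry(length=length))
        else:
            raise ScaffoldFormatError(
                f"{where}: unknown entry key {key!r} "
                "(expected 'sequence' or 'unresolved')"
            )
    return Scaffold(entries=tuple(entries))


def write_scaffold(scaffold: Scaffold) -> str:
    """Render a :class:`Scaffold` back to file text.

    Round-trip guarantee: ``parse_scaffold(write_scaffold(s))`` is
    structurally equal to ``s``.  Default values are omitted for brevity.
    """
    doc: list[dict] = []
    for entry in scaffold.entries:
        if isinstance(entry, UnresolvedEntry):
            doc.append({"unresolved": {"length": entry.length}})
            continue
        body: dict = {"source": entry.source_id}
        if entry.start != 1:
            body["start"] = entry.start
        if entry.stop is not None:
            body["stop"] = entry.stop
        if entry.reverse:
            body["reverse"] = True
        if entry.inserts:
            body["inserts"] = [
                {"source": ins.source_id, "open": ins.open, "close": ins.close}
                for ins in entry.inserts
            ]
        doc.append({"sequence": body})
    return yaml.safe_dump(doc, sort_keys=False, default_flow_style=False)


def validate_scaffold(
    scaffold: Scaffold, contigs: dict[str, ContigRecord]
) -> list[str]:
    """Check a scaffold plan against a contig set; return error messages.

    An empty list means the plan is internally consistent: every referenced
    ID resolves, insert spans are in range and pairwise non-overlapping,
    trims fit the post-insert sequence, and the scaffold neither starts nor
    ends with a gap.
    """
    errors: list[str] = []
    seq_entries = scaffold.sequence_entries()
    if not seq_entries:
        errors.append("scaffold must contain at least one sequence entry")
        return errors
    if not isinstance(scaffold.entries[0], SequenceEntry):
        errors.append("scaffold must not begin with an unresolved gap")
    if not isinstance(scaffold.entries[-1], SequenceEntry):
        errors.append("scaffold must not end with an unresolved gap")
    for idx, entry in seq_entries:
        where = f"entry {idx + 1} ({entry.source_id})"
        host = contigs.get(entry.source_id)
        if host is None:
            errors.append(f"{where}: unknown contig {entry.source_id!r}")
            continue
        ok = True
        spans: list[tuple[int, int]] = []
        post_len = len(host)
        for ins in entry.inserts:
            patch = contigs.get(ins.source_id)
            if patch is None:
                errors.append(f"{where}: unknown insert source {ins.source_id!r}")
                ok = False
                continue
            if ins.close < ins.open:
                errors.append(
                    f"{where}: insert [{ins.open}, {ins.close}]: close < open"
                )
                ok = False
                continue
            if not (1 <= ins.open and ins.close <= len(host)):
                errors.append(
                    f"{where}: insert [{ins.open}, {ins.close}] outside contig "
                    f"(length {len(host)})"
                )
                ok = False
                continue
            spans.append((ins.open, ins.close))
            post_len += len(patch) - (ins.close - ins.open + 1)
        spans.sort()
        for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
            if b0 <= a1:
                errors.append(
                    f"{where}: overlapping inserts [{a0}, {a1}] and [{b0}, {b1}]"
                )
                ok = False
        if not ok:
            continue
        stop = entry.stop if entry.stop is not None else post_len
        if not (1 <= entry.start <= stop <= post_len):
            errors.append(
                f"{where}: trim [{entry.start}, {stop}] outside post-insert "
                f"sequence of length {post_len}"
            )
    return errors


def read_contig_fasta(source: str) -> dict[str, ContigRecord]:
    """Read a multi-record FASTA (text or file path) into a contig set.

    Returns an insertion-ordered mapping of id -> :class:`ContigRecord`.
    Duplicate IDs are an error: scaffold entries must resolve unambiguously.
    """
    if "\n" not in source and not source.startswith(">"):
        handle: io.TextIOBase | str = source
    else:
        handle = io.StringIO(source)
    contigs: dict[str, ContigRecord] = {}
    for rec in SeqIO.parse(handle, "fasta"):
        if rec.id in contigs:
            raise ScaffoldFormatError(f"duplicate contig id {rec.id!r} in FASTA")
        contigs[rec.id] = ContigRecord(id=rec.id, seq=str(rec.seq))
    if not contigs:
        raise ScaffoldFormatError("no FASTA records found")
    return contigs
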