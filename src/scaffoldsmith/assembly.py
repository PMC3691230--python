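"""Render a scaffold plan into the draft genome sequence and its layout.

The assembly is held entirely in memory: the target scale is microbial
genomes (a few MBp), for which this is both simple and fast.  Each plan
entry is rendered independently (inserts -> trim -> orientation for contig
placements, a run of upper-case ``N`` for gaps) and the concatenation,
together with a list of :class:`LayoutSegment`, forms the
:class:`AssembledScaffold`.  The layout is the coordinate bridge used by
annotation lift-over and AGP generation: its segments tile
``[1, len(seq)]`` exactly, in entry order, with no overlaps or holes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .scaffold_format import (
    ContigRecord,
    Insert,
    Scaffold,
    SequenceEntry,
    UnresolvedEntry,
    validate_scaffold,
)

__all__ = [
    "LayoutSegment",
    "AssembledScaffold",
    "OffsetMap",
    "AssemblyError",
    "reverse_complement",
    "apply_inserts",
    "entry_sequence",
    "assemble",
]


class AssemblyError(ValueError):
    """Raised when a scaffold plan cannot be rendered into sequence."""


_COMPLEMENT = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "K": "M", "M": "K",
    "S": "S", "W": "W", "B": "V", "V": "B",
    "D": "H", "H": "D", "N": "N",
}
_REVCOMP_TABLE = str.maketrans(
    "".join(_COMPLEMENT) + "".join(_COMPLEMENT).lower(),
    "".join(_COMPLEMENT.values()) + "".join(_COMPLEMENT.values()).lower(),
)
_KNOWN = frozenset(_COMPLEMENT) | frozenset(c.lower() for c in _COMPLEMENT)


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement over the IUPAC alphabet.

    Ambiguity codes map to their complements (R<->Y, K<->M, B<->V, D<->H;
    S, W, N are self-complementary).  Case is preserved.  Unknown characters
    raise :class:`AssemblyError` naming the character and its 1-based offset.
    """
    bad = set(seq) - _KNOWN
    if bad:
        offset = next(i for i, c in enumerate(seq) if c in bad)
        raise AssemblyError(
            f"unknown character {seq[offset]!r} at position {offset + 1}"
        )
    return seq.translate(_REVCOMP_TABLE)[::-1]


@dataclass(frozen=True)
class OffsetMap:
    """Piecewise map from original host coordinates to post-insert coordinates.

    ``blocks`` is an ascending list of ``(orig_lo, orig_hi, shift)`` covering
    every original position that survives insert replacement; a position
    inside a replaced span belongs to no block.  Two positions are separated
    by replaced bases iff they fall in different blocks, even when the shift
    happens to be equal (an insert of the same length as its span).
    """

    blocks: tuple[tuple[int, int, int], ...]

    @classmethod
    def identity(cls, length: int) -> "OffsetMap":
        return cls(blocks=((1, length, 0),) if length > 0 else ())

    def block_index(self, pos: int) -> int | None:
        """Index of the block containing ``pos``, or None if replaced."""
        for i, (lo, hi, _) in enumerate(self.blocks):
            if lo <= pos <= hi:
                return i
        return None

    def map(self, pos: int) -> int | None:
        """Post-insert coordinate of original position ``pos``, or None."""
        i = self.block_index(pos)
        if i is None:
            return None
        return pos + self.blocks[i][2]


def apply_inserts(
    host: str, inserts: tuple[Insert, ...] | list[Insert],
    contigs: dict[str, ContigRecord],
) -> tuple[str, OffsetMap]:
    """Splice patch sequences into a host contig.

    Each insert replaces the host span ``[open, close]`` (1-based inclusive)
    with the full sequence of its source record.  All spans are interpreted
    in original host coordinates, so the order the file lists them in does
    not matter.  Returns the patched sequence and an :class:`OffsetMap`
    giving, for every original
    host coordinate outside the replaced spans, its post-insert coordinate.
    """
    ordered = sorted(inserts, key=lambda i: i.open)
    prev_close = 0
    for ins in ordered:
        if ins.close < ins.open:
            raise AssemblyError(f"insert [{ins.open}, {ins.close}]: close < open")
        if not (1 <= ins.open and ins.close <= len(host)):
            raise AssemblyError(
                f"insert [{ins.open}, {ins.close}] outside host of length {len(host)}"
            )
        if ins.open <= prev_close:
            raise AssemblyError(f"overlapping inserts at position {ins.open}")
        if ins.source_id not in contigs:
            raise AssemblyError(f"unknown insert source {ins.source_id!r}")
        prev_close = ins.close
    pieces: list[str] = []
    blocks: list[tuple[int, int, int]] = []
    shift = 0
    prev = 0  # last host coordinate consumed
    for ins in ordered:
        patch = contigs[ins.source_id].seq
        if ins.open > prev + 1:
            pieces.append(host[prev : ins.open - 1])
            blocks.append((prev + 1, ins.open - 1, shift))
        pieces.append(patch)
        shift += len(patch) - (ins.close - ins.open + 1)
        prev = ins.close
    if prev < len(host):
        pieces.append(host[prev:])
        blocks.append((prev + 1, len(host), shift))
    return "".join(pieces), OffsetMap(blocks=tuple(blocks))


def _resolved_trim(entry: SequenceEntry, post_len: int) -> tuple[int, int]:
    stop = entry.stop if entry.stop is not None else post_len
    if not (1 <= entry.start <= stop <= post_len):
        raise AssemblyError(
            f"entry for {entry.source_id!r}: trim [{entry.start}, {stop}] outside "
            f"post-insert sequence of length {post_len}"
        )
    return entry.start, stop


def entry_sequence(entry: SequenceEntry, contigs: dict[str, ContigRecord]) -> str:
    """Render one contig placement: inserts, then trim, then orientation."""
    host = contigs.get(entry.source_id)
    if host is None:
        raise AssemblyError(f"unknown contig {entry.source_id!r}")
    post, _ = apply_inserts(host.seq, entry.inserts, contigs)
    start, stop = _resolved_trim(entry, len(post))
    sliced = post[start - 1 : stop]
    return reverse_complement(sliced) if entry.reverse else sliced


@dataclass(frozen=True)
class LayoutSegment:
    """The resolved position of one scaffold entry in final coordinates.

    ``scaffold_start``/``scaffold_stop`` are 1-based inclusive.  For contig
    segments, ``source_start``/``source_stop`` give the placed slice in
    post-insert host coordinates, and ``reversed`` its orientation; gap
    segments carry neither.
    """

    entry_index: int
    kind: str  # "contig" | "gap"
    scaffold_start: int
    scaffold_stop: int
    source_id: str | None = None
    source_start: int | None = None
    source_stop: int | None = None
    reversed: bool = False

    def __len__(self) -> int:
        return self.scaffold_stop - self.scaffold_start + 1


@dataclass(frozen=True)
class AssembledScaffold:
    """A rendered scaffold: sequence, coordinate layout, per-entry pieces."""

    identifier: str
    seq: str
    layout: tuple[LayoutSegment, ...]
    entry_sequences: dict[int, str]
    entry_offset_maps: dict[int, OffsetMap] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.seq)

    def contig_segments(self) -> list[LayoutSegment]:
        return [s for s in self.layout if s.kind == "contig"]


def assemble(
    scaffold: Scaffold,
    contigs: dict[str, ContigRecord],
    identifier: str = "scaffold",
) -> AssembledScaffold:
    """Render a validated scaffold plan into an :class:`AssembledScaffold`.

    Deterministic: the same plan and contig set always produce byte-identical
    sequence and layout.  Raises :class:`AssemblyError` listing every
    validation failure if the plan is inconsistent with the contig set.
    """
    problems = validate_scaffold(scaffold, contigs)
    if problems:
        raise AssemblyError("invalid scaffold plan: " + "; ".join(problems))
    pieces: list[str] = []
    layout: list[LayoutSegment] = []
    entry_sequences: dict[int, str] = {}
    offset_maps: dict[int, OffsetMap] = {}
    pos = 1
    for idx, entry in enumerate(scaffold.entries):
        if isinstance(entry, UnresolvedEntry):
            rendered = "N" * entry.length
            layout.append(
                LayoutSegment(
                    entry_index=idx,
                    kind="gap",
                    scaffold_start=pos,
                    scaffold_stop=pos + entry.length - 1,
                )
            )
        else:
            host = contigs[entry.source_id]
            post, omap = apply_inserts(host.seq, entry.inserts, contigs)
            start, stop = _resolved_trim(entry, len(post))
            sliced = post[start - 1 : stop]
            rendered = reverse_complement(sliced) if entry.reverse else sliced
            offset_maps[idx] = omap
            layout.append(
                LayoutSegment(
                    entry_index=idx,
                    kind="contig",
                    scaffold_start=pos,
                    scaffold_stop=pos + len(rendered) - 1,
                    source_id=entry.source_id,
                    source_start=start,
                    source_stop=stop,
                    reversed=entry.reverse,
                )
            )
        entry_sequences[idx] = rendered
        pieces.append(rendered)
        pos += len(rendered)
    return AssembledScaffold(
        identifier=identifier,
        seq="".join(pieces),
        layout=tuple(layout),
        entry_sequences=entry_sequences,
        entry_offset_maps=offset_maps,
    )
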