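"""Synthetic contig sets, gene annotations and scaffold plans with ground truth.

Everything the pipeline consumes — a contig FASTA, a GFF3 of gene features,
and a scaffold plan exercising reversal, trimming, patch inserts and gaps —
is generated from a seed, together with an independently computed ground
truth: for every gene, the scaffold interval and strand it should land on,
or the reason it should be dropped.  The ground truth is a straight-line
cumulative-offset calculation that never touches the assembly or lift-over
code, so comparing ``lift_all`` against it is a genuine two-implementation
cross-check.

Sequences are uniform over {A,C,G,T}: the machinery under test is
coordinate arithmetic, not sequence statistics, so compositional realism
would add nothing.  Each placement carries at most one insert, which keeps
the independent calculation simple; multi-insert paths are covered by
hand-written unit cases.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .annotation_lift import Annotation, write_gff3
from .scaffold_format import (
    ContigRecord,
    Insert,
    Scaffold,
    SequenceEntry,
    UnresolvedEntry,
)
from .submission import render_fasta
from .scaffold_format import write_scaffold

__all__ = ["FixtureSpec", "GeneTruth", "Fixture", "generate_fixture", "write_fixture_dir"]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic genome-finishing scenario.

    Defaults describe a small microbial-draft-like case: a handful of
    kbp-scale contigs, a few genes each, scaffold gaps of tens to hundreds
    of bases, half the placements reversed and roughly a third trimmed or
    patched — enough to exercise every coordinate transformation at once.
    """

    n_contigs: int = 4
    contig_length_range: tuple[int, int] = (1000, 10000)
    n_genes_per_contig: int = 3
    gap_length_range: tuple[int, int] = (50, 500)
    p_reverse: float = 0.5
    p_trim: float = 0.3
    p_insert: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_contigs < 1:
            raise ValueError("n_contigs must be ≥ 1")
        if self.n_genes_per_contig < 0:
            raise ValueError("n_genes_per_contig must be ≥ 0")
        for name in ("contig_length_range", "gap_length_range"):
            lo, hi = getattr(self, name)
            if not (1 <= lo <= hi):
                raise ValueError(f"{name} must be a non-empty positive range")
        for name in ("p_reverse", "p_trim", "p_insert"):
            p = getattr(self, name)
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass(frozen=True)
class GeneTruth:
    """Expected lift-over outcome for one gene.

    ``status`` is ``"lifted"`` (with expected scaffold ``start``/``stop``/
    ``strand``) or ``"dropped"`` (with the expected ``reason``).
    """

    gene_id: str
    status: str
    start: int | None = None
    stop: int | None = None
    strand: str | None = None
    reason: str | None = None


@dataclass(frozen=True)
class Fixture:
    """One generated scenario: inputs plus per-gene expected outcomes."""

    contigs: dict[str, ContigRecord]
    annotations: tuple[Annotation, ...]
    scaffold: Scaffold
    truth: dict[str, GeneTruth]


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode("ascii")


def _place_genes(
    rng: random.Random, contig_len: int, n_genes: int
) -> list[tuple[int, int]]:
    """Non-overlapping 1-based inclusive gene intervals within a contig."""
    if n_genes == 0:
        return []
    # gene lengths 90-300 bp, capped so the requested count always fits
    max_len = min(300, contig_len // n_genes)
    if max_len < 90:
        raise ValueError(
            f"infeasible: {n_genes} genes of ≥ 90 bp cannot fit in a "
            f"{contig_len} bp contig"
        )
    lengths = [rng.randint(90, max_len) for _ in range(n_genes)]
    free = contig_len - sum(lengths)
    cuts = sorted(rng.randint(0, free) for _ in range(n_genes))
    intervals: list[tuple[int, int]] = []
    pos = 0
    prev_cut = 0
    for length, cut in zip(lengths, cuts):
        pos += cut - prev_cut
        prev_cut = cut
        start = pos + 1
        intervals.append((start, start + length - 1))
        pos += length
    return intervals


_PRODUCTS = (
    "hypothetical protein",
    "DNA polymerase III subunit alpha",
    "ABC transporter permease",
    "50S ribosomal protein L2",
    "two-component sensor histidine kinase",
)


def generate_fixture(spec: FixtureSpec) -> Fixture:
    """Generate contigs, gene annotations, a scaffold plan and ground truth.

    Deterministic: the same spec (including seed) yields an identical
    fixture.  Raises ``ValueError`` if the requested genes cannot fit.
    """
    rng = random.Random(spec.seed)
    seq_rng = np.random.default_rng(spec.seed)

    contigs: dict[str, ContigRecord] = {}
    annotations: list[Annotation] = []
    genes_by_contig: dict[str, list[Annotation]] = {}
    gene_counter = 0
    for i in range(spec.n_contigs):
        cid = f"contig{i + 1}"
        length = rng.randint(*spec.contig_length_range)
        contigs[cid] = ContigRecord(id=cid, seq=_random_seq(seq_rng, length))
        genes_by_contig[cid] = []
        for g_start, g_stop in _place_genes(rng, length, spec.n_genes_per_contig):
            gene_counter += 1
            gid = f"gene{gene_counter:04d}"
            ann = Annotation(
                seqid=cid,
                source="synthetic",
                ftype="gene",
                start=g_start,
                stop=g_stop,
                strand=rng.choice("+-"),
                attributes={
                    "ID": gid,
                    "locus_tag": f"TMP_{gene_counter:05d}",
                    "product": rng.choice(_PRODUCTS),
                },
            )
            annotations.append(ann)
            genes_by_contig[cid].append(ann)

    # Build the plan: every contig placed once, in shuffled order, with a
    # gap between consecutive placements.
    order = list(contigs)
    rng.shuffle(order)
    entries: list[SequenceEntry | UnresolvedEntry] = []
    placements: list[tuple[str, SequenceEntry, int, int, int]] = []
    # (contig id, entry, span_open, span_close, patch_len); open=0 means no insert
    gaps_between: list[int] = []  # gap length preceding placement k (0 for k=0)
    for cid in order:
        host_len = len(contigs[cid])
        inserts: tuple[Insert, ...] = ()
        span_open = span_close = patch_len = 0
        if rng.random() < spec.p_insert and host_len > 300:
            span_len = rng.randint(30, 120)
            span_open = rng.randint(1, host_len - span_len + 1)
            span_close = span_open + span_len - 1
            patch_len = rng.randint(30, 150)
            patch_id = f"{cid}_patch"
            contigs[patch_id] = ContigRecord(
                id=patch_id, seq=_random_seq(seq_rng, patch_len)
            )
            inserts = (Insert(source_id=patch_id, open=span_open, close=span_close),)
        post_len = host_len + (patch_len - (span_close - span_open + 1) if inserts else 0)
        start, stop = 1, post_len
        if rng.random() < spec.p_trim:
            start = rng.randint(1, max(1, post_len // 5))
            stop = post_len - rng.randint(0, max(0, post_len // 5))
        entry = SequenceEntry(
            source_id=cid,
            start=start,
            stop=stop,
            reverse=rng.random() < spec.p_reverse,
            inserts=inserts,
        )
        if entries:
            gap_len = rng.randint(*spec.gap_length_range)
            entries.append(UnresolvedEntry(length=gap_len))
            gaps_between.append(gap_len)
        else:
            gaps_between.append(0)
        entries.append(entry)
        placements.append((cid, entry, span_open, span_close, patch_len))

    truth = _ground_truth(placements, gaps_between, genes_by_contig)
    return Fixture(
        contigs=contigs,
        annotations=tuple(annotations),
        scaffold=Scaffold(entries=tuple(entries)),
        truth=truth,
    )


def _ground_truth(
    placements: list[tuple[str, SequenceEntry, int, int, int]],
    gaps_between: list[int],
    genes_by_contig: dict[str, list[Annotation]],
) -> dict[str, GeneTruth]:
    """Expected scaffold coordinates by straight-line cumulative arithmetic.

    Walks the plan keeping a running scaffold offset.  For each gene on the
    placed contig: drop if it touches the patched span; otherwise shift it
    past the patch if needed, drop if the trim clips it, and finally add the
    placement offset (mirroring the interval when the placement is
    reversed).  Deliberately independent of the assembly/lift-over modules.
    """
    truth: dict[str, GeneTruth] = {}
    offset = 0  # scaffold bases preceding the current placement
    for k, (cid, entry, span_open, span_close, patch_len) in enumerate(placements):
        offset += gaps_between[k]
        t_start, t_stop = entry.start, entry.stop
        assert t_stop is not None
        placed_len = t_stop - t_start + 1
        delta = patch_len - (span_close - span_open + 1) if span_open else 0
        for gene in genes_by_contig[cid]:
            gid = gene.attributes["ID"]
            if span_open and gene.start <= span_close and gene.stop >= span_open:
                truth[gid] = GeneTruth(
                    gene_id=gid, status="dropped", reason="overlaps-insert-region"
                )
                continue
            if span_open and gene.start > span_close:
                ms, mt = gene.start + delta, gene.stop + delta
            else:
                ms, mt = gene.start, gene.stop
            if ms < t_start or mt > t_stop:
                truth[gid] = GeneTruth(
                    gene_id=gid, status="dropped", reason="overlaps-trimmed-region"
                )
                continue
            if entry.reverse:
                s = offset + (t_stop - mt) + 1
                t = offset + (t_stop - ms) + 1
                strand = {"+": "-", "-": "+", ".": "."}[gene.strand]
            else:
                s = offset + (ms - t_start) + 1
                t = offset + (mt - t_start) + 1
                strand = gene.strand
            truth[gid] = GeneTruth(
                gene_id=gid, status="lifted", start=s, stop=t, strand=strand
            )
        offset += placed_len
    return truth


def write_fixture_dir(fixture: Fixture, directory: str | Path) -> dict[str, Path]:
    """Write the three input files (FASTA, GFF3, scaffold YAML) to a directory.

    Returns the paths, keyed ``contigs``/``annotations``/``scaffold`` — the
    layout the command-line interface expects for end-to-end runs.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "contigs": directory / "contigs.fasta",
        "annotations": directory / "annotations.gff3",
        "scaffold": directory / "scaffold.yml",
    }
    paths["contigs"].write_text(
        render_fasta([(c.id, c.seq) for c in fixture.contigs.values()])
    )
    paths["annotations"].write_text(write_gff3(list(fixture.annotations)))
    paths["scaffold"].write_text(write_scaffold(fixture.scaffold))
    return paths
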