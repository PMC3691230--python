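# scaffoldsmith

Finishing a microbial draft genome means repeatedly re-ordering, flipping,
trimming and patching contigs, then regenerating every downstream file each
time the scaffold changes. Doing that by editing multi-megabase FASTA and
GFF3 files by hand is slow and error-prone. `scaffoldsmith` keeps the
scaffold as a small, hand-editable plain-text plan and derives everything
else from it deterministically:

* **assembly** — the plan (contig order, orientation, trims, patch inserts,
  unresolved gaps) is rendered into the draft genome sequence, with a
  coordinate layout mapping every plan entry to its scaffold span;
* **annotation lift-over** — GFF3 gene features annotated in contig
  coordinates are translated to scaffold coordinates, so contigs can be
  annotated once and the scaffold edited freely afterwards;
* **GenBank submission files** — the assembled FASTA, the contig
  (component) FASTA, an AGP 2.0 placement file, and an NCBI 5-column
  feature table (the inputs to GenBank's `tbl2asn`/`sequin`), with
  optional systematic locus_tag renumbering from the sequence origin.

Because every output is a pure function of the input files, the tool
composes with GNU Make and git: rerun `scaffoldsmith view` after editing the
plan and every artifact updates; identical inputs give byte-identical
outputs.

## The coordinate model

A placement applies, in order: **inserts** (each replaces a host span
`[open, close]`, 1-based inclusive, with a patch sequence), a **trim**
(`[start, stop]` in post-insert coordinates), and an **orientation**
(reverse complement). A feature interval `[a, b]` on a contig placed at
scaffold span `[S, E]` from post-insert slice `[s, t]` lifts to

* forward: `[S + (a' − s), S + (b' − s)]`, strand unchanged;
* reversed: `[S + (t − b'), S + (t − a')]`, strand flipped,

where `a', b'` are the post-insert images of `a, b`. A feature whose
interval touches a replaced span or extends into a trimmed-off region is
**dropped with a reason** (`overlaps-insert-region`,
`overlaps-trimmed-region`, ...), never silently truncated — the invariant
maintained throughout is that every lifted feature still addresses exactly
its original bases (or their reverse complement).

## Worked example

A scaffold plan is a YAML list of `sequence` and `unresolved` entries:

```yaml
- sequence:
    source: contig1
- unresolved:
    length: 10
- sequence:
    source: contig2
    reverse: true
```

Running `python examples/01_assemble_scaffold.py` assembles two 32/24 bp
contigs with that plan and prints:

```
assembled draft1: 66 bp
ATGGCGTACGATCGATTACGGATCTAGCATCGNNNNNNNNNNTGCCGTTAACGGATCCATGGTCAA
  [  1,  32]  contig1
  [ 33,  42]  gap
  [ 43,  66]  contig2 (-)
```

contig1 occupies scaffold bases 1–32 unchanged, the unresolved gap renders
as ten `N`s, and contig2 is placed reverse-complemented at 43–66.
`python examples/02_lift_annotations.py` then lifts three genes through a
trimmed forward placement and a reversed one:

```
lifted:
  g1: [3, 14] strand +
  g2: [53, 64] strand -
dropped:
  g3: overlaps-trimmed-region
```

g1 shifted left by the 4 bases trimmed off its contig's start; g2 landed
mirrored on the minus strand; g3 overlapped the trimmed-off region and was
dropped with a reason rather than truncated.
`examples/03_genbank_submission.py` prints the full submission file set for
the same scaffold — including the AGP:

```
##agp-version	2.0
draft1	1	32	1	W	contig1	1	32	+
draft1	33	42	2	N	10	scaffold	yes	unspecified
draft1	43	74	3	W	contig2	1	32	-
```

and verifies `AGP reconstruction identical to assembly: True`: splicing the
AGP rows back out of the contig FASTA reproduces the assembled sequence
byte for byte.

## Command line

```sh
scaffoldsmith view fasta   --scaffold scaffold.yml --contigs contigs.fasta > genome.fasta
scaffoldsmith view agp     --scaffold scaffold.yml --contigs contigs.fasta > genome.agp
scaffoldsmith view gff     --annotations annotations.gff3 ... > genome.gff3
scaffoldsmith view table   --annotations annotations.gff3 \
                           --prefix PFLU --reset-locus-numbering > genome.tbl
```

One artifact per invocation on standard output (`fasta`, `contigs`, `gff`,
`agp`, `table`); diagnostics and the lift-over drop report go to standard
error. Exit codes: 0 success, 1 validation error, 2 usage error.

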