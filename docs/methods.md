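# Methods

## Scope and model

`scaffoldsmith` automates the manual finishing steps of a microbial genome
project: a human-edited scaffold plan is the single source of truth, and
the draft sequence, lifted annotations and GenBank submission files are
derived from it. The whole assembly is held in memory; the intended scale
is microbial drafts (up to ~10 MBp), for which a streaming mode would add
complexity without benefit.

The scaffold plan is a YAML list of single-key maps — `sequence` (contig
placement) and `unresolved` (gap) — with all coordinates 1-based inclusive,
matching GFF3 and AGP so no off-by-one conversions occur at the format
boundaries. The dialect is a re-specification of the scaffold-file idea
rather than a byte-level clone of any earlier tool's format; compatibility
with other tools' files is not claimed. Unknown keys are a hard error: a
hand-edited format must fail loudly on typos, not guess.

### Processing order within a placement

Each placement applies **inserts → trim → orientation**, in that fixed
order. `start`/`stop` are therefore interpreted in *post-insert*
coordinates: a trim can remove part of a patched region. One unambiguous
order had to be chosen; patch-then-trim is the one documented and tested
throughout. Adjacent placements with no gap between them concatenate
directly (zero-gap joins are legal and expressible in AGP). Gap bases are
upper-case `N`, the GenBank convention.

### Lift-over semantics

A feature interval is lifted only if it survives *intact* within exactly
one placement of its contig. The deliberate policy decisions:

* Features partially or wholly overlapping an insert-replaced span, or
  extending into a trimmed-off region, are **dropped with a reason** and
  reported — never truncated. Truncating a gene changes its biology
  silently; dropping is loud and auditable via the `LiftReport`.
* Features on patch (insert donor) contigs are not lifted: patches donate
  sequence, not annotation.
* If a contig is placed more than once, its features are dropped as
  `ambiguous-multiple-placements` rather than duplicated — duplicated
  locus_tags would be rejected at submission.
* Phase carries through unchanged in both orientations: features are
  single-interval with no intron/exon structure, so there is no exon
  boundary against which phase would need recomputation. Multi-exon
  (spliced) features are out of scope.

The module's defining invariant, asserted across the test suite: for every
lifted feature, `scaffold[start..stop]` equals the original contig
subsequence, or its reverse complement when the placement is reversed.

### Submission files

* **AGP**: version 2.0, the NCBI-accepted standard. Gap rows are
  `N / scaffold / yes / unspecified` — a legal linkage-evidence value when
  no specific evidence type is being asserted.
* **Components**: each contig segment of the layout contributes one
  component record holding its placed slice (post-insert, trimmed, forward
  orientation). W rows therefore address components as `1..length` with
  orientation `+`/`−`, and the emitted contig FASTA and the AGP agree
  exactly — consistency between the submitted files was chosen over
  emitting full-length original contigs. A contig placed more than once
  yields numbered component ids.
* **Feature table**: genes expand to paired `gene` + `CDS` rows spanning
  the same interval (no partial-feature `<`/`>` markup, no `codon_start`
  adjustment — consequences of the single-interval assumption). Minus
  strand is encoded as start > stop. The CDS inherits the gene's
  `product`, defaulting to `hypothetical protein`, and its `locus_tag`.
* **Locus tags**: `<prefix>_00010, _00020, ...` — start 10, step 10,
  zero-padded to 5 digits, numbered from the sequence origin. Step-10 is
  the prokaryotic-annotation convention and leaves room for later
  insertions; the exact width/step is pinned so outputs are testable
  byte-for-byte.
* **FASTA**: wrapped at 70 columns, the common GenBank-toolchain default,
  pinned for byte-exact determinism.

The `.asn` submission itself is out of scope: the outputs are the *inputs*
to GenBank's `tbl2asn`/`sequin`.

## Numerical and degenerate-input choices

* Insert spans on one placement must be pairwise non-overlapping; the
  offset map is piecewise (`(orig_lo, orig_hi, shift)` blocks), and two
  positions separated by a replaced span are recognized as such even when
  the net shift is zero (a patch the same length as its span).
* `close < open` on an insert, trims outside the post-insert bounds,
  unresolved gaps of length < 1, scaffolds that begin or end with a gap,
  and unknown contig ids are all validation errors with messages naming
  the offending entry; assembly refuses to run until the plan is clean.
* Reverse complement covers the full IUPAC alphabet (R↔Y, K↔M, B↔V, D↔H,
  S/W/N self-complementary); unknown characters are an error naming the
  character and offset, never silently passed through.
* A malformed feature (start > stop) raises an error rather than being
  "dropped": it indicates corrupt input, not a clipped gene.

## Synthetic scenarios and what they show

The fixture generator emulates a small finishing project: uniform-random
{A,C,G,T} contigs, non-overlapping single-interval genes, and a plan that
places every contig once in shuffled order with gaps between placements,
randomly reversing, trimming and patching placements. Alongside the inputs
it computes, by an independent straight-line cumulative-offset calculation
that never calls the assembly or lift-over code, each gene's expected
scaffold interval and strand (or expected drop reason) — so generator
versus `lift_all` is a genuine two-implementation cross-check.

Default study conditions, chosen once: contigs 1–10 kbp; gaps 50–500 bp
(typical short-read scaffolding gap estimates); genes 90–300 bp, capped so
the requested count always fits the contig; insert-replaced spans
30–120 bp with patches 30–150 bp (PCR-product scale, and deliberately
length-changing so shifts are exercised); trims remove at most ~20% off
each end; placement probabilities p_reverse/p_trim/p_insert =
0.5/0.3/0.3. Generated placements carry at most one insert — it keeps the
independent ground-truth arithmetic simple; multi-insert paths are covered
by hand-written unit cases.

What passing these tests does **not** show about real data: the generator
makes no attempt at compositional realism (GC content, repeats), gene
structure (operons, overlapping genes, RNA features) or imperfect inputs
(mis-assembled contigs, conflicting annotations). The machinery under test
is coordinate arithmetic and format generation; those properties transfer
to real contigs directly, but the tool will faithfully render whatever
ordering errors the plan itself contains — the plan is authoritative, and
no consensus recomputation or join-overlap detection is attempted.

## Problem sizes in the checked battery

The acceptance battery runs 500 randomized scenarios of 2–6 contigs
(1–10 kbp each, 0–5 genes per contig) — roughly 7,000,000 assembled bases
and ~5,000 gene outcomes per run — which exercises every drop reason and
both orientations many hundreds of times while completing in seconds. The
test suite additionally runs hypothesis-driven round-trip and involution
properties (200 and 100 derandomized cases respectively) and byte-exact
golden checks on a small hand-verified scaffold.

## Known limitations

* Single-sequence output: one scaffold per plan file; multi-chromosome
  projects use one plan per replicon.
* No automatic contig ordering: order and orientation come from the plan
  (alignment to a reference or paired reads are upstream concerns).
* Gene-type, single-interval features only; no mRNA/exon hierarchies,
  partial features or trans-splicing.
* No protein translation or internal-stop validation of derived CDS
  features — the feature table is generated, not biologically validated.
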