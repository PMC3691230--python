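"""Assemble a draft genome from a hand-written scaffold plan.

Builds a three-entry plan — a forward contig, a 10 bp unresolved gap, and a
reverse-complemented contig — and renders it into the draft sequence.  The
layout table shows where each plan entry landed in scaffold coordinates.
"""

from scaffoldsmith import ContigRecord, assemble, parse_scaffold

contigs = {
    c.id: c
    for c in [
        ContigRecord("contig1", "ATGGCGTACGATCGATTACGGATCTAGCATCG"),
        ContigRecord("contig2", "TTGACCATGGATCCGTTAACGGCA"),
    ]
}

plan = parse_scaffold(
    """
- sequence:
    source: contig1
- unresolved:
    length: 10
- sequence:
    source: contig2
    reverse: true
"""
)

assembled = assemble(plan, contigs, identifier="draft1")

print(f"assembled {assembled.identifier}: {len(assembled)} bp")
print(assembled.seq)
for seg in assembled.layout:
    what = seg.source_id or "gap"
    strand = " (-)" if seg.reversed else ""
    print(f"  [{seg.scaffold_start:>3}, {seg.scaffold_stop:>3}]  {what}{strand}")

# The gap renders as N bases; contig2's slice is its reverse complement, so
# the assembled sequence ends with the revcomp of contig2's start.
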