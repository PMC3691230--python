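"""Lift gene annotations from contig coordinates onto the scaffold.

One gene sits on a forward placement, one on a reversed placement (its
interval is mirrored and its strand flips), and one falls in a trimmed-off
region and is dropped with a reason — nothing is ever silently truncated.
"""

from scaffoldsmith import (
    Annotation,
    ContigRecord,
    assemble,
    lift_all,
    parse_scaffold,
    write_gff3,
)

contigs = {
    c.id: c
    for c in [
        ContigRecord("contig1", "ATGGCGTACGATCGATTACGGATCTAGCATCG"),  # 32 bp
        ContigRecord("contig2", "TTGACCATGGATCCGTTAACGGCATTAGCCTA"),  # 32 bp
    ]
}

plan = parse_scaffold(
    """
- sequence:
    source: contig1
    start: 5
    stop: 30
- unresolved:
    length: 8
- sequence:
    source: contig2
    reverse: true
"""
)

genes = [
    Annotation("contig1", "demo", "gene", 7, 18, strand="+",
               attributes={"ID": "g1", "locus_tag": "D_1"}),
    Annotation("contig2", "demo", "gene", 3, 14, strand="+",
               attributes={"ID": "g2", "locus_tag": "D_2"}),
    Annotation("contig1", "demo", "gene", 1, 9, strand="+",
               attributes={"ID": "g3", "locus_tag": "D_3"}),  # clipped by trim
]

assembled = assemble(plan, contigs, identifier="draft1")
report = lift_all(genes, assembled, plan)

print("lifted:")
for g in report.lifted:
    print(f"  {g.id}: [{g.start}, {g.stop}] strand {g.strand}")
print("dropped:")
for g, reason in report.dropped:
    print(f"  {g.id}: {reason}")
print()
print(write_gff3(list(report.lifted), seqid="draft1", length=len(assembled)), end="")

# g1 shifts left by the 4 bp trimmed off contig1's start; g2 lands mirrored
# near the scaffold end on the minus strand; g3 overlaps the trimmed region
# and is reported, not truncated.
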