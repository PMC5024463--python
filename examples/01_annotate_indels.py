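"""Annotate a handful of indels against a toy transcript.

Builds a single-exon gene in memory, runs normalization, frame
classification and protein-level naming, and prints one line per variant:
the left-aligned VCF representation, the frame call and the HGVS names.
"""

from inframe import (
    RawVariant,
    ReferenceWindow,
    TranscriptModel,
    compute_protein_change,
    normalize_indel,
    project_and_classify_frame,
)

CDS = "ATGGCCGCCAAAGTTCCAGAAGATCGCTAA"  # MAAKVPEDR*
CONTIG = "GATTACAGAT" + CDS + "CCGGAATTCC"
GENE = TranscriptModel(
    transcript_id="TOY1", chromosome="1", strand="+",
    exons=((11, 40),), cds_intervals=((11, 40),), cds_sequence=CDS,
)

variants = [
    RawVariant("1", 13, "GGCC", "G"),     # 3 nt deletion -> in-frame
    RawVariant("1", 16, "CGCC", "C"),     # equivalent, right-shifted copy
    RawVariant("1", 13, "GGCCG", "G"),    # 4 nt deletion -> frameshift
    RawVariant("1", 22, "A", "AGAT"),     # 3 nt insertion -> in-frame
]

window = ReferenceWindow(CONTIG, 1)
for v in variants:
    vn = normalize_indel(v, window)
    ci = project_and_classify_frame(vn, GENE)
    if ci.is_in_frame:
        ci = compute_protein_change(ci, GENE)
    print(
        f"{v.variant_id:<22} -> {vn.variant_id:<20} {ci.frame_status:<10}"
        f" {ci.hgvs_c or '':<16} {ci.hgvs_p or ''}"
    )

# The two equivalent deletions normalize to the same left-aligned record
# (DNA level) while the protein name follows the 3'-most convention.
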