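"""Classify the primary-sequence context of indels.

Most small indels arise by polymerase slippage in repetitive tracts; this
script plants three archetypes -- a homopolymer run, a CAG tandem array and
a repeat-free control -- and prints the detector output for each.
"""

from inframe import RawVariant, ReferenceWindow, classify_variant_context, normalize_indel

PAD_L = ("TACG" * 12)[:35]
PAD_R = ("GCAT" * 12)[:35]

cases = {
    "one A lost from AAAAAA": ("C" + "A" * 6 + "G", 3, 1),
    "one CAG lost from CAGx3": ("ACAGCAGCAGT", 2, 3),
    "3 nt lost, no repeat": ("ACGTAGCTTGA", 2, 3),
}

for name, (core, start, length) in cases.items():
    seq = PAD_L + core + PAD_R
    pos = len(PAD_L) + start
    v = RawVariant("1", pos - 1, seq[pos - 2 : pos - 1 + length], seq[pos - 2])
    w = ReferenceWindow(seq, 1)
    ctx = classify_variant_context(normalize_indel(v, w), w)
    print(
        f"{name:<26} label={ctx.label:<6} unit={ctx.repeat_unit or '-':<4}"
        f" copies={ctx.reference_copy_count} run={ctx.homopolymer_run_length}"
    )

# 'label' is HR+TR for homopolymers (a run of >= 6 identical bases is also
# a tandem repeat of a 1-mer), TR for multi-base units, 'other' otherwise.
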