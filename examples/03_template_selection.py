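"""Select a structure template for a mutated protein.

Aligns a target sequence against a small template library, applies the
E-value cutoff (1e-3) and the variant-window identity rule (> 5/11 around
the affected residue), and prints each hit with the selection outcome.
"""

from inframe import align_and_score, select_template, window_identity

target = "MTKVEIRAVDGTSQWLHNKFETPGARLIVDQ"
library = {
    "GOOD_A": "MTKVEIRAVDGTSQWLHNKFETPGARLIVDQ",      # near-identical homolog
    "PART_A": "MTKVEIRAWAWAWAWAWNKFETPGARLIVDQ",      # diverged at the variant
    "WEAK_A": "GGSSPPLLNNQQHHEERRKKDDAAVVIIMM",       # unrelated sequence
}
library_size = sum(len(s) for s in library.values())
variant_residue = 12  # 1-based position of the affected residue

hits = []
for tid, seq in library.items():
    hit = align_and_score(target, seq, library_size, template_id=tid)
    hit = window_identity(hit, variant_residue, variant_residue)
    hits.append(hit)
    print(
        f"{tid}: bits={hit.bit_score:6.1f}  E={hit.e_value:9.2e}"
        f"  window={hit.window_identity_count}/{hit.window_length}"
        f"  passes={hit.passes_window}"
    )

best = select_template(hits)
print("selected:", best.template_id if best else "none (variant not modelable)")

# A hit must be both significant overall (E <= 1e-3) and locally reliable
# around the variant; PART_A fails the 11-column window despite a good
# global alignment.
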