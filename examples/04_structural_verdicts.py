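"""Structural context and disruption verdicts on ideal-geometry fixtures.

Builds the four structural archetypes the verdict rules are designed
around -- a three-strand sheet, a coiled-coil dimer, a protein-DNA complex
and a beta-hairpin with a loop tail -- and classifies a deletion at a
diagnostic position in each.
"""

from inframe import GeometrySpec, build_geometry, classify_mechanism, parse_structure
from inframe.mechanism import annotate_structure

cases = [
    ("edge strand deletion", "beta_sheet", {"n_strands": 3}, 8, ("A", 3), 1),
    ("central strand deletion", "beta_sheet", {"n_strands": 3}, 8, ("B", 3), 7),
    ("interface helix deletion", "coiled_coil_dimer", {}, 22, ("A", 10), 1),
    ("DNA-contacting Arg deletion", "protein_dna_complex", {}, 15, ("A", 7), 1),
    ("loop next to strands", "beta_hairpin", {"tail_length": 8}, 8, ("A", 8), 1),
    ("remote surface loop", "beta_hairpin", {"tail_length": 8}, 8, ("A", 24), 1),
]

built = {}
for name, kind, params, n, affected, n_res in cases:
    key = (kind, tuple(sorted(params.items())), n)
    if key not in built:
        s = parse_structure(build_geometry(GeometrySpec(kind=kind, n_residues=n, params=params)))
        built[key] = annotate_structure(s)
    verdict = classify_mechanism([affected], built[key], n_res)
    mechs = ";".join(verdict.mechanisms)
    print(f"{name:<28} -> {verdict.category:<9} ({mechs})")

# 'probably' verdicts carry the mechanism (sheet disruption, helical
# register shift, binding-site loss); surface loops far from any secondary
# structure element are 'unlikely'; loops hugging an element are 'unclear'.
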