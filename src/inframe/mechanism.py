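"""Structural context annotation and disruption-mechanism verdicts.

Affected residues mapped onto a template structure are annotated with
secondary structure, relative accessibility, strand topology and inter-chain
contacts (including salt bridges to DNA phosphates), and the annotations are
folded into a three-level verdict on whether the indel is likely to disrupt
protein structure or function:

1. any affected residue in a beta-strand            -> probably (sheet disruption)
2. affected helix residue on an interface helix,
   with a disruptive helical register shift         -> probably (register shift)
3. affected residue contacting another chain
   (interface or salt bridge)                       -> probably (binding site)
4. all affected residues in surface loops, contact
   free and remote from any H/E element             -> unlikely
5. anything else                                    -> unclear (packing loss)

The thresholds are deliberately simple named constants; the rules encode the
qualitative structural reasoning used when triaging such variants by eye.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .secondary import assign_secondary_structure, classify_strand_position
from .structure import StructureModel
from .surface import compute_rsa

__all__ = [
    "INTERFACE_CONTACT_MAX_DIST",
    "SALT_BRIDGE_MAX_DIST",
    "LOOP_ELEMENT_MIN_SEPARATION",
    "REGISTER_SHIFT_DISRUPTIVE_DEG",
    "SaltBridge",
    "ResidueAnnotation",
    "MechanismVerdict",
    "Unassessable",
    "detect_interchain_contacts",
    "helix_register_shift",
    "annotate_structure",
    "classify_mechanism",
]

INTERFACE_CONTACT_MAX_DIST = 4.5  # heavy-atom inter-chain contact, Angstrom
SALT_BRIDGE_MAX_DIST = 4.0  # charged-group nitrogen/oxygen pair, Angstrom
LOOP_ELEMENT_MIN_SEPARATION = 3  # residues from the nearest H/E element
REGISTER_SHIFT_DISRUPTIVE_DEG = 60.0  # rotation of the helical register

# Charged side-chain atoms (plus DNA/RNA phosphate oxygens as negative).
POSITIVE_ATOMS = {
    "ARG": {"NE", "NH1", "NH2"},
    "LYS": {"NZ"},
    "HIS": {"ND1", "NE2"},
}
NEGATIVE_ATOMS = {
    "ASP": {"OD1", "OD2"},
    "GLU": {"OE1", "OE2"},
}
PHOSPHATE_OXYGENS = {"OP1", "OP2", "O1P", "O2P"}


@dataclass(frozen=True)
class SaltBridge:
    own_atom: str
    partner_chain: str
    partner_residue: str
    partner_seq_num: int
    partner_atom: str
    distance: float


@dataclass
class ResidueAnnotation:
    chain_id: str
    chain_pos: int
    seq_num: int
    residue_name: str
    ss_state: str  # H / E / C
    rsa: Optional[float]
    is_surface: bool
    strand_position: str  # edge / central / not_in_sheet
    interface_partner_chains: set[str] = field(default_factory=set)
    salt_bridges: list[SaltBridge] = field(default_factory=list)
    element_distance: Optional[int] = None  # residues to nearest H/E in chain
    helix_has_interface: bool = False  # this residue's helix touches another chain

    def __post_init__(self) -> None:
        if self.strand_position != "not_in_sheet" and self.ss_state != "E":
            raise ValueError("sheet topology implies strand state E")


@dataclass(frozen=True)
class MechanismVerdict:
    category: str  # probably / unclear / unlikely
    mechanisms: tuple[str, ...]
    evidence: dict

    def __post_init__(self) -> None:
        if self.category == "probably" and (
            not self.mechanisms or self.mechanisms == ("none",)
        ):
            raise ValueError("'probably' requires a concrete mechanism")
        if self.category == "unlikely" and self.mechanisms != ("none",):
            raise ValueError("'unlikely' implies mechanisms == ('none',)")


@dataclass(frozen=True)
class Unassessable:
    """Variant residues could not be placed on the template."""

    reason: str
    category: str = "unassessable"


def _charge_of(residue_name: str, atom_name: str, is_nucleic: bool) -> int:
    if atom_name in POSITIVE_ATOMS.get(residue_name, ()):  # guanidinium etc.
        return +1
    if atom_name in NEGATIVE_ATOMS.get(residue_name, ()):
        return -1
    if is_nucleic and atom_name in PHOSPHATE_OXYGENS:
        return -1
    return 0


def detect_interchain_contacts(
    s: StructureModel, chain_id: str, chain_pos: int
) -> tuple[set[str], list[SaltBridge]]:
    """Interface partner chains and salt bridges for one residue.

    An interface contact is any heavy-atom pair across chains within 4.5 A;
    a salt bridge is a charged side-chain atom within 4.0 A of an
    opposite-charge atom on another chain (DNA phosphate OP1/OP2 included).
    """
    chain = s.get_chain(chain_id)
    res = chain.residues[chain_pos]
    own_coords = np.array([a.xyz for a in res.atoms])

    partners: set[str] = set()
    bridges: list[SaltBridge] = []
    for other in s.chains:
        if other.chain_id == chain_id:
            continue
        other_is_nucleic = other.molecular_class == "nucleic"
        atoms = [
            (r, a)
            for r in other.residues
            for a in r.atoms
        ]
        if not atoms:
            continue
        coords = np.array([a.xyz for _, a in atoms])
        dmat = np.linalg.norm(
            own_coords[:, None, :] - coords[None, :, :], axis=-1
        )
        if (dmat <= INTERFACE_CONTACT_MAX_DIST).any():
            partners.add(other.chain_id)
        for i, own_atom in enumerate(res.atoms):
            q1 = _charge_of(res.name, own_atom.name, False)
            if q1 == 0:
                continue
            for j, (other_res, other_atom) in enumerate(atoms):
                q2 = _charge_of(other_res.name, other_atom.name, other_is_nucleic)
                if q1 * q2 >= 0:
                    continue
                d = float(dmat[i, j])
                if d <= SALT_BRIDGE_MAX_DIST:
                    bridges.append(
                        SaltBridge(
                            own_atom=own_atom.name,
                            partner_chain=other.chain_id,
                            partner_residue=other_res.name,
                            partner_seq_num=other_res.seq_num,
                            partner_atom=other_atom.name,
                            distance=round(d, 3),
                        )
                    )
    return partners, bridges


def helix_register_shift(n_deleted_or_inserted: int) -> tuple[float, bool]:
    """Rotation of the helical register caused by an n-residue indel.

    At 3.6 residues per turn each residue is 100 degrees of phase, so the
    shift is (n * 100) mod 360; it is flagged disruptive at or beyond 60
    degrees (enough to rotate an interface side chain off its interface).
    """
    if n_deleted_or_inserted < 0:
        raise ValueError("residue count must be non-negative")
    shift = float((n_deleted_or_inserted * 100) % 360)
    return shift, shift >= REGISTER_SHIFT_DISRUPTIVE_DEG


def annotate_structure(s: StructureModel) -> dict[tuple[str, int], ResidueAnnotation]:
    """Full per-residue annotation of a parsed structure (protein chains)."""
    ss = assign_secondary_structure(s)
    rsa = compute_rsa(s)
    annotations: dict[tuple[str, int], ResidueAnnotation] = {}
    for chain in s.protein_chains():
        for pos, res in enumerate(chain.residues):
            key = (chain.chain_id, pos)
            state = ss.state(*key)
            partners, bridges = detect_interchain_contacts(s, chain.chain_id, pos)
            acc = rsa.get(key, {"rsa": None, "is_surface": False})
            annotations[key] = ResidueAnnotation(
                chain_id=chain.chain_id,
                chain_pos=pos,
                seq_num=res.seq_num,
                residue_name=res.name,
                ss_state=state,
                rsa=acc["rsa"],
                is_surface=acc["is_surface"],
                strand_position=(
                    classify_strand_position(ss, *key) if state == "E" else "not_in_sheet"
                ),
                interface_partner_chains=partners,
                salt_bridges=bridges,
                element_distance=ss.element_distance(*key),
            )
    # helix segments: does the segment contain any interface residue?
    for chain in s.protein_chains():
        cid = chain.chain_id
        pos = 0
        n = len(chain.residues)
        while pos < n:
            if annotations[(cid, pos)].ss_state != "H":
                pos += 1
                continue
            seg = [pos]
            while pos + 1 < n and annotations[(cid, pos + 1)].ss_state == "H":
                pos += 1
                seg.append(pos)
            has_iface = any(
                annotations[(cid, p)].interface_partner_chains for p in seg
            )
            for p in seg:
                annotations[(cid, p)].helix_has_interface = has_iface
            pos += 1
    return annotations


def classify_mechanism(
    affected: Sequence[tuple[str, int]],
    annotations: dict[tuple[str, int], ResidueAnnotation],
    n_residue_change: int,
) -> MechanismVerdict | Unassessable:
    """Apply the mechanism rules to the affected residues, first match wins.

    ``affected`` lists ``(chain_id, chain_pos)`` keys of the residues the
    indel removes/inserts at on the template; ``n_residue_change`` is the
    unsigned residue count of the indel (for the register-shift rule).
    """
    if not affected:
        return Unassessable(reason="no affected residues mapped onto the template")
    missing = [k for k in affected if k not in annotations]
    if missing:
        return Unassessable(
            reason=f"{len(missing)}/{len(affected)} affected residues unmapped"
        )
    anns = [annotations[k] for k in affected]

    # rule 1: beta-sheet disruption
    in_sheet = [a for a in anns if a.ss_state == "E"]
    if in_sheet:
        return MechanismVerdict(
            category="probably",
            mechanisms=("beta_sheet_disruption",),
            evidence={
                "strand_positions": sorted({a.strand_position for a in in_sheet}),
                "n_strand_residues": len(in_sheet),
            },
        )

    # rule 2: helical register shift on an interface helix
    shift, disruptive = helix_register_shift(abs(n_residue_change))
    helix_iface = [a for a in anns if a.ss_state == "H" and a.helix_has_interface]
    if helix_iface and disruptive:
        return MechanismVerdict(
            category="probably",
            mechanisms=("helix_register_shift",),
            evidence={"register_shift_degrees": shift},
        )

    # rule 3: direct binding-site disruption
    contacting = [a for a in anns if a.salt_bridges or a.interface_partner_chains]
    if contacting:
        salt = [b for a in contacting for b in a.salt_bridges]
        evidence: dict = {
            "partner_chains": sorted(
                {c for a in contacting for c in a.interface_partner_chains}
            )
        }
        if salt:
            closest = min(salt, key=lambda b: b.distance)
            evidence["salt_bridge_distance"] = closest.distance
            evidence["salt_bridge_partner"] = (
                f"{closest.partner_chain}/{closest.partner_residue}"
                f"{closest.partner_seq_num}/{closest.partner_atom}"
            )
        return MechanismVerdict(
            category="probably", mechanisms=("binding_site_disruption",), evidence=evidence
        )

    # rule 4: remote surface loop
    def remote(a: ResidueAnnotation) -> bool:
        return (
            a.ss_state == "C"
            and a.is_surface
            and not a.interface_partner_chains
            and (a.element_distance is None or a.element_distance >= LOOP_ELEMENT_MIN_SEPARATION)
        )

    if all(remote(a) for a in anns):
        return MechanismVerdict(
            category="unlikely",
            mechanisms=("none",),
            evidence={
                "min_element_distance": min(
                    (a.element_distance for a in anns if a.element_distance is not None),
                    default=None,
                ),
                "min_rsa": min((a.rsa for a in anns if a.rsa is not None), default=None),
            },
        )

    # rule 5: everything else
    return MechanismVerdict(
        category="unclear",
        mechanisms=("packing_loss",),
        evidence={
            "ss_states": sorted({a.ss_state for a in anns}),
            "min_element_distance": min(
                (a.element_distance for a in anns if a.element_distance is not None),
                default=None,
            ),
        },
    )
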