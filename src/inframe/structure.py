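"""Structure model and PDB parsing.

PDB text is read through gemmi and reduced to the minimal representation the
downstream annotations need: chains of residues of heavy atoms, with each
chain classified as protein, nucleic or other.  Waters are dropped and
alternate conformations are resolved to a single conformer (highest
occupancy, ties broken toward altLoc 'A').
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "Chain",
    "StructureModel",
    "StructureParseError",
    "parse_structure",
    "chain_one_letter_sequence",
    "AA3_TO_1",
]

AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "MSE": "M", "SEC": "U", "PYL": "O",
}
NUCLEIC_NAMES = {"A", "C", "G", "U", "I", "DA", "DC", "DG", "DT", "DU", "DI"}
WATER_NAMES = {"HOH", "WAT", "DOD"}


class StructureParseError(ValueError):
    """Raised for empty or malformed PDB input."""


@dataclass
class Atom:
    name: str
    element: str
    xyz: np.ndarray  # shape (3,), Angstrom

    def distance(self, other: "Atom") -> float:
        return float(np.linalg.norm(self.xyz - other.xyz))


@dataclass
class Residue:
    name: str
    seq_num: int
    icode: str
    atoms: list[Atom] = field(default_factory=list)

    def atom(self, name: str) -> Optional[Atom]:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def is_protein(self) -> bool:
        return self.name in AA3_TO_1

    @property
    def is_nucleic(self) -> bool:
        return self.name in NUCLEIC_NAMES


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)

    @property
    def molecular_class(self) -> str:
        if not self.residues:
            return "other"
        n_prot = sum(r.is_protein for r in self.residues)
        n_nuc = sum(r.is_nucleic for r in self.residues)
        if n_prot >= n_nuc and n_prot > len(self.residues) / 2:
            return "protein"
        if n_nuc > len(self.residues) / 2:
            return "nucleic"
        return "other"

    def residue(self, seq_num: int, icode: str = "") -> Optional[Residue]:
        for r in self.residues:
            if r.seq_num == seq_num and r.icode == icode:
                return r
        return None


@dataclass
class StructureModel:
    chains: list[Chain] = field(default_factory=list)

    def get_chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(f"no chain '{chain_id}' in structure")

    def protein_chains(self) -> list[Chain]:
        return [c for c in self.chains if c.molecular_class == "protein"]

    def nucleic_chains(self) -> list[Chain]:
        return [c for c in self.chains if c.molecular_class == "nucleic"]

    def iter_residues(self):
        for c in self.chains:
            for r in c.residues:
                yield c, r


def _pick_conformer(atoms: list[gemmi.Atom]) -> gemmi.Atom:
    """Highest occupancy wins; ties resolve toward altLoc 'A' (then '')."""
    return sorted(
        atoms, key=lambda a: (-a.occ, a.altloc if a.altloc else "A")
    )[0]


def parse_structure(pdb_text: str) -> StructureModel:
    """Parse PDB v3.x text into a :class:`StructureModel`.

    Heavy atoms only; waters removed; altLoc resolved to one conformer.
    Raises :class:`StructureParseError` on empty input, missing ATOM records
    or malformed coordinates.
    """
    if not pdb_text.strip():
        raise StructureParseError("empty PDB input")
    for lineno, line in enumerate(pdb_text.splitlines(), start=1):
        if line.startswith(("ATOM", "HETATM")) and len(line) >= 54:
            for lo, hi in ((30, 38), (38, 46), (46, 54)):
                try:
                    float(line[lo:hi])
                except ValueError:
                    raise StructureParseError(
                        f"malformed coordinate field on line {lineno}: {line[lo:hi]!r}"
                    )
    try:
        st = gemmi.read_pdb_string(pdb_text)
    except (RuntimeError, ValueError) as exc:
        raise StructureParseError(f"PDB parse failure: {exc}") from exc
    if len(st) == 0:
        raise StructureParseError("no models in PDB input")
    model = st[0]

    out = StructureModel()
    n_atoms = 0
    for ch in model:
        chain = Chain(chain_id=ch.name)
        for res in ch:
            if res.name in WATER_NAMES:
                continue
            groups: dict[str, list[gemmi.Atom]] = {}
            for at in res:
                if at.element.name == "H" or at.element.name == "D":
                    continue
                groups.setdefault(at.name, []).append(at)
            residue = Residue(
                name=res.name,
                seq_num=res.seqid.num,
                icode=(res.seqid.icode or "").strip(),
            )
            for name, alts in groups.items():
                at = _pick_conformer(alts)
                pos = np.array([at.pos.x, at.pos.y, at.pos.z], dtype=float)
                if not np.all(np.isfinite(pos)):
                    raise StructureParseError(f"non-finite coordinates for atom {name}")
                residue.atoms.append(
                    Atom(name=name, element=at.element.name, xyz=pos)
                )
                n_atoms += 1
            if residue.atoms:
                chain.residues.append(residue)
        if chain.residues:
            chain.residues.sort(key=lambda r: (r.seq_num, r.icode))
            out.chains.append(chain)
    if n_atoms == 0:
        raise StructureParseError("no ATOM/HETATM records")
    return out


def chain_one_letter_sequence(chain: Chain) -> str:
    """One-letter sequence from the chain's (protein) residues; unknown
    residues become 'X'."""
    return "".join(AA3_TO_1.get(r.name, "X") for r in chain.residues)
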