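"""Backbone hydrogen-bond based secondary structure (H/E/C).

The assignment follows the Kabsch-Sander convention: an electrostatic model
of the backbone N-H...O=C hydrogen bond,

    E = 0.084 * 332 * (1/r_ON + 1/r_CH - 1/r_OH - 1/r_CN)  kcal/mol,

with a bond called at E < -0.5 kcal/mol.  Amide hydrogens are imputed 1.0 A
from N along the direction of the preceding residue's C=O bond (C minus O),
the DSSP convention.  Helices (H) require two consecutive i -> i+4 turns;
strands (E) come from parallel/antiparallel bridge ladders; everything else
is coil (C).  Residues missing backbone atoms are annotated C and flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree

from .structure import StructureModel

__all__ = [
    "HBOND_ENERGY_CUTOFF",
    "SecondaryStructure",
    "assign_secondary_structure",
    "classify_strand_position",
]

HBOND_ENERGY_CUTOFF = -0.5  # kcal/mol
_Q_FACTOR = 0.084 * 332.0
_CA_NEIGHBOR_CUTOFF = 9.0  # Kabsch-Sander CA-CA prefilter
_MIN_DIST = 0.5  # below this, clamp the energy to the strongly bonded value


@dataclass
class _BB:
    """Backbone of one residue plus its chain bookkeeping."""

    chain_id: str
    chain_pos: int  # 0-based index within the chain's residue list
    seq_num: int
    name: str
    n: np.ndarray
    ca: np.ndarray
    c: np.ndarray
    o: np.ndarray
    h: Optional[np.ndarray] = None  # imputed amide H; None for Pro/chain start


@dataclass
class SecondaryStructure:
    """Per-residue states plus the bridge topology used for sheet analysis.

    Residues are keyed by ``(chain_id, chain_pos)`` with ``chain_pos`` the
    0-based index into the chain's residue list.
    """

    states: dict[tuple[str, int], str] = field(default_factory=dict)
    bridge_partners: dict[tuple[str, int], set[tuple[str, int]]] = field(
        default_factory=dict
    )
    missing_backbone: set[tuple[str, int]] = field(default_factory=set)

    def state(self, chain_id: str, chain_pos: int) -> str:
        return self.states.get((chain_id, chain_pos), "C")

    def strands(self) -> list[list[tuple[str, int]]]:
        """Maximal runs of consecutive E residues within each chain."""
        out: list[list[tuple[str, int]]] = []
        by_chain: dict[str, list[int]] = {}
        for (cid, pos), s in self.states.items():
            if s == "E":
                by_chain.setdefault(cid, []).append(pos)
        for cid, positions in sorted(by_chain.items()):
            positions.sort()
            run: list[tuple[str, int]] = []
            prev = None
            for p in positions:
                if prev is not None and p != prev + 1:
                    out.append(run)
                    run = []
                run.append((cid, p))
                prev = p
            if run:
                out.append(run)
        return out

    def element_distance(self, chain_id: str, chain_pos: int) -> Optional[int]:
        """Residue-index distance to the nearest H/E residue in the same
        chain (0 if the residue itself is H/E); None if the chain has no
        H/E element."""
        dists = [
            abs(pos - chain_pos)
            for (cid, pos), s in self.states.items()
            if cid == chain_id and s in ("H", "E")
        ]
        return min(dists) if dists else None


def _collect_backbones(s: StructureModel) -> tuple[list[_BB], set[tuple[str, int]]]:
    bbs: list[_BB] = []
    missing: set[tuple[str, int]] = set()
    for chain in s.protein_chains():
        for pos, res in enumerate(chain.residues):
            atoms = {nm: res.atom(nm) for nm in ("N", "CA", "C", "O")}
            if any(a is None for a in atoms.values()):
                missing.add((chain.chain_id, pos))
                continue
            bbs.append(
                _BB(
                    chain_id=chain.chain_id,
                    chain_pos=pos,
                    seq_num=res.seq_num,
                    name=res.name,
                    n=atoms["N"].xyz,
                    ca=atoms["CA"].xyz,
                    c=atoms["C"].xyz,
                    o=atoms["O"].xyz,
                )
            )
    # impute amide hydrogens
    by_key = {(b.chain_id, b.chain_pos): b for b in bbs}
    for b in bbs:
        if b.name == "PRO":
            continue
        prev = by_key.get((b.chain_id, b.chain_pos - 1))
        if prev is None:
            continue
        co = prev.c - prev.o
        norm = np.linalg.norm(co)
        if norm > 0:
            b.h = b.n + co / norm
    return bbs, missing


def _hbond_energy(donor: _BB, acceptor: _BB) -> float:
    if donor.h is None:
        return 0.0
    r_on = np.linalg.norm(acceptor.o - donor.n)
    r_ch = np.linalg.norm(acceptor.c - donor.h)
    r_oh = np.linalg.norm(acceptor.o - donor.h)
    r_cn = np.linalg.norm(acceptor.c - donor.n)
    if min(r_on, r_ch, r_oh, r_cn) < _MIN_DIST:
        return -9.9
    return _Q_FACTOR * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)


def assign_secondary_structure(s: StructureModel) -> SecondaryStructure:
    """Assign H/E/C per protein residue of a structure."""
    bbs, missing = _collect_backbones(s)
    result = SecondaryStructure(missing_backbone=missing)
    for b in bbs:
        result.states[(b.chain_id, b.chain_pos)] = "C"
    for key in missing:
        result.states[key] = "C"
    if not bbs:
        return result

    index_of = {(b.chain_id, b.chain_pos): i for i, b in enumerate(bbs)}
    cas = np.array([b.ca for b in bbs])
    tree = cKDTree(cas)
    neighbor_pairs = tree.query_pairs(r=_CA_NEIGHBOR_CUTOFF)

    def sequential_gap(i: int, j: int) -> Optional[int]:
        bi, bj = bbs[i], bbs[j]
        if bi.chain_id != bj.chain_id:
            return None
        return bj.chain_pos - bi.chain_pos

    # hbonds[i] = set of acceptor indices j such that N-H(i) -> C=O(j)
    hbonds: dict[int, set[int]] = {i: set() for i in range(len(bbs))}
    for i, j in neighbor_pairs:
        for donor, acceptor in ((i, j), (j, i)):
            gap = sequential_gap(acceptor, donor)
            if gap is not None and abs(gap) < 2:
                continue  # no bond to self or sequence neighbor
            if _hbond_energy(bbs[donor], bbs[acceptor]) < HBOND_ENERGY_CUTOFF:
                hbonds[donor].add(acceptor)

    def hb(donor_key, acceptor_key) -> bool:
        di = index_of.get(donor_key)
        ai = index_of.get(acceptor_key)
        return di is not None and ai is not None and ai in hbonds[di]

    # --- helices: two consecutive i -> i+4 turns ---------------------------
    def turn4(b: _BB) -> bool:
        donor = (b.chain_id, b.chain_pos + 4)
        return hb(donor, (b.chain_id, b.chain_pos))

    for b in bbs:
        prev = (b.chain_id, b.chain_pos - 1)
        if prev in index_of and turn4(bbs[index_of[prev]]) and turn4(b):
            for k in range(b.chain_pos, b.chain_pos + 4):
                key = (b.chain_id, k)
                if key in result.states:
                    result.states[key] = "H"

    # --- bridges -----------------------------------------------------------
    def neighbors(key, delta):
        cand = (key[0], key[1] + delta)
        return cand if cand in index_of else None

    n = len(bbs)
    for idx_i, idx_j in list(neighbor_pairs):
        for i, j in ((idx_i, idx_j),):
            ki = (bbs[i].chain_id, bbs[i].chain_pos)
            kj = (bbs[j].chain_id, bbs[j].chain_pos)
            gap = sequential_gap(i, j)
            if gap is not None and abs(gap) < 3:
                continue
            im1, ip1 = neighbors(ki, -1), neighbors(ki, +1)
            jm1, jp1 = neighbors(kj, -1), neighbors(kj, +1)
            parallel = (
                (im1 and hb(im1, kj) and hb(kj, ip1))
                or (jm1 and hb(jm1, ki) and hb(ki, jp1))
            )
            antiparallel = (
                (hb(ki, kj) and hb(kj, ki))
                or (im1 and jp1 and hb(im1, jp1) and jm1 and ip1 and hb(jm1, ip1))
            )
            if parallel or antiparallel:
                for key in (ki, kj):
                    if result.states.get(key) != "H":
                        result.states[key] = "E"
                result.bridge_partners.setdefault(ki, set()).add(kj)
                result.bridge_partners.setdefault(kj, set()).add(ki)

    # residues without a full backbone stay coil, whatever their neighbours
    for key in missing:
        result.states[key] = "C"
    return result


def classify_strand_position(
    ss: SecondaryStructure, chain_id: str, chain_pos: int
) -> str:
    """edge / central / not_in_sheet for one residue.

    A strand is a maximal run of E residues in a chain.  It is central when
    it has bridge partners in at least two distinct other strands anywhere
    along its length (neighbours on both sides), edge when in exactly one.
    """
    if ss.state(chain_id, chain_pos) != "E":
        return "not_in_sheet"
    strands = ss.strands()
    strand_of: dict[tuple[str, int], int] = {}
    for sid, strand in enumerate(strands):
        for key in strand:
            strand_of[key] = sid
    own = strand_of.get((chain_id, chain_pos))
    if own is None:
        return "not_in_sheet"
    partner_strands = set()
    for key in strands[own]:
        for p in ss.bridge_partners.get(key, ()):
            pid = strand_of.get(p)
            if pid is not None and pid != own:
                partner_strands.add(pid)
    if len(partner_strands) >= 2:
        return "central"
    if len(partner_strands) == 1:
        return "edge"
    return "edge"  # bridge partner outside any strand run; one-sided contact
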