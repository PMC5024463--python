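"""Solvent accessibility by the Shrake-Rupley rolling-probe quadrature.

Each heavy atom is inflated by the probe radius (1.4 A) and sampled with a
deterministic golden-spiral point set (default 960 points); a sample point
survives if it is outside every neighbouring inflated sphere.  Residue
relative solvent accessibility (RSA) is the residue's summed atomic area
divided by the theoretical maximum for that amino acid in an extended
Gly-X-Gly context (Tien et al. theoretical values), clipped to [0, 1].
"""

from __future__ import annotations

from functools import lru_cache
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree

from .structure import StructureModel

__all__ = [
    "PROBE_RADIUS",
    "N_SPHERE_POINTS",
    "SURFACE_RSA_THRESHOLD",
    "VDW_RADII",
    "MAX_ASA",
    "atom_sasa",
    "compute_rsa",
]

PROBE_RADIUS = 1.4  # water probe, Angstrom
N_SPHERE_POINTS = 960
SURFACE_RSA_THRESHOLD = 0.25  # residues at or above are called surface

VDW_RADII = {"C": 1.7, "N": 1.55, "O": 1.52, "S": 1.8, "P": 1.8}
DEFAULT_RADIUS = 1.7

# Theoretical maximum accessible surface areas (A^2), Tien et al. 2013.
MAX_ASA = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}


@lru_cache(maxsize=4)
def _unit_sphere(n: int) -> np.ndarray:
    """Deterministic golden-spiral point set on the unit sphere."""
    k = np.arange(n, dtype=float)
    z = 1.0 - 2.0 * (k + 0.5) / n
    phi = k * np.pi * (3.0 - np.sqrt(5.0))
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack((r * np.cos(phi), r * np.sin(phi), z))


def atom_sasa(
    coords: np.ndarray,
    elements: list[str],
    probe: float = PROBE_RADIUS,
    n_points: int = N_SPHERE_POINTS,
) -> np.ndarray:
    """Per-atom solvent-accessible surface areas for a heavy-atom system."""
    coords = np.asarray(coords, dtype=float)
    radii = np.array([VDW_RADII.get(e, DEFAULT_RADIUS) for e in elements]) + probe
    sphere = _unit_sphere(n_points)
    n = len(coords)
    if n == 0:
        return np.zeros(0)
    tree = cKDTree(coords)
    max_r = radii.max()
    out = np.zeros(n)
    for i in range(n):
        pts = coords[i] + radii[i] * sphere
        neighbors = [
            j for j in tree.query_ball_point(coords[i], r=radii[i] + max_r)
            if j != i and np.linalg.norm(coords[j] - coords[i]) < radii[i] + radii[j]
        ]
        exposed = np.ones(len(pts), dtype=bool)
        for j in neighbors:
            d2 = np.einsum("ij,ij->i", pts - coords[j], pts - coords[j])
            exposed &= d2 >= radii[j] ** 2
            if not exposed.any():
                break
        out[i] = 4.0 * np.pi * radii[i] ** 2 * exposed.sum() / n_points
    return out


def compute_rsa(s: StructureModel) -> dict[tuple[str, int], dict]:
    """Residue ASA, RSA and surface flag for every residue of a structure.

    The SASA calculation sees all chains (protein and nucleic) so that
    interface burial is reflected.  RSA is reported for standard amino
    acids; other residues get ``rsa=None``.  Keyed by ``(chain_id,
    chain_pos)`` (0-based position within the chain's residue list).
    """
    coords: list[np.ndarray] = []
    elements: list[str] = []
    owner: list[tuple[str, int]] = []
    for chain in s.chains:
        for pos, res in enumerate(chain.residues):
            for atom in res.atoms:
                coords.append(atom.xyz)
                elements.append(atom.element)
                owner.append((chain.chain_id, pos))
    if not coords:
        return {}
    areas = atom_sasa(np.array(coords), elements)

    residue_area: dict[tuple[str, int], float] = {}
    for key, a in zip(owner, areas):
        residue_area[key] = residue_area.get(key, 0.0) + float(a)

    out: dict[tuple[str, int], dict] = {}
    for chain in s.chains:
        for pos, res in enumerate(chain.residues):
            key = (chain.chain_id, pos)
            asa = residue_area.get(key, 0.0)
            max_asa = MAX_ASA.get(res.name)
            rsa: Optional[float] = None
            if max_asa:
                rsa = min(1.0, max(0.0, asa / max_asa))
            out[key] = {
                "asa": asa,
                "rsa": rsa,
                "is_surface": rsa is not None and rsa >= SURFACE_RSA_THRESHOLD,
            }
    return out
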