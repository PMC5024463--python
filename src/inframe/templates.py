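"""Structure-template selection by local sequence alignment.

Candidate templates are ranked the way a protein-BLAST search would rank
them: Smith-Waterman local alignment under BLOSUM62 with affine gaps
(open 11, extend 1), bit scores from the gapped Karlin-Altschul constants
(lambda = 0.267, K = 0.041) and E = m*n*2^-bits over the searched library.
A template is usable for a given variant only when the alignment is
significant (E <= 1e-3) and locally reliable: strictly more than 5/11
identities in the window made of the variant residues plus five alignment
columns on either side.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .structure import StructureModel, chain_one_letter_sequence

__all__ = [
    "TemplateHit",
    "ResidueMap",
    "EVALUE_CUTOFF",
    "WINDOW_FLANK",
    "KA_LAMBDA",
    "KA_K",
    "align_and_score",
    "window_identity",
    "select_template",
    "map_residue_to_template",
]

EVALUE_CUTOFF = 1e-3
WINDOW_FLANK = 5  # alignment columns on each side of the variant span
WINDOW_PASS_NUM = 5  # pass requires count > 5/11 of the (possibly truncated) window
WINDOW_PASS_DEN = 11
KA_LAMBDA = 0.267  # gapped Karlin-Altschul lambda for BLOSUM62 11/1
KA_K = 0.041
GAP_OPEN = 11
GAP_EXTEND = 1


@dataclass(frozen=True)
class TemplateHit:
    template_id: str
    target_aligned: str  # gapped target sequence over the local alignment
    template_aligned: str
    target_start: int  # 1-based target index of the first aligned column
    template_start: int  # 1-based template index of the first aligned column
    raw_score: float
    bit_score: float
    e_value: float
    global_identity: float
    window_identity_count: Optional[int] = None
    window_length: Optional[int] = None
    passes_window: bool = False
    window_truncated: bool = False
    window_uncovered: bool = False

    @property
    def window_fraction(self) -> float:
        if not self.window_length:
            return 0.0
        return (self.window_identity_count or 0) / self.window_length


@dataclass(frozen=True)
class ResidueMap:
    """Monotone map from 1-based target residue indices to template residue
    identifiers (chain id, residue sequence number)."""

    pairs: tuple[tuple[int, tuple[str, int]], ...]
    unmapped: tuple[int, ...]

    def lookup(self, target_index: int) -> Optional[tuple[str, int]]:
        for t, ident in self.pairs:
            if t == target_index:
                return ident
        return None


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    # BLAST-style cost of a length-k gap is 11 + k
    aligner.open_gap_score = -(GAP_OPEN + GAP_EXTEND)
    aligner.extend_gap_score = -GAP_EXTEND
    return aligner


def align_and_score(
    target: str, template: str, library_size: int, template_id: str = ""
) -> TemplateHit:
    """Best local alignment of target vs one template with BLAST-like stats.

    ``library_size`` is the total residue count of the searched template
    library (the n of E = m*n*2^-b).  'X' residues are tolerated by the
    scoring matrix but never counted as identities.
    """
    if not target or not template:
        raise ValueError("sequences must be non-empty")
    target = target.upper()
    template = template.upper()
    aligner = _make_aligner()
    aln = aligner.align(target, template)[0]
    # For local mode, aln[i] renders only the aligned block, with gaps.
    t_sub, q_sub = str(aln[0]), str(aln[1])
    t_start = int(aln.aligned[0][0][0])  # 0-based target start of alignment
    q_start = int(aln.aligned[1][0][0])

    ident = sum(
        1 for a, b in zip(t_sub, q_sub) if a == b and a not in ("-", "X")
    )
    ncols = len(t_sub)
    raw = float(aln.score)
    bit = (KA_LAMBDA * raw - math.log(KA_K)) / math.log(2.0)
    e_value = len(target) * library_size * 2.0 ** (-bit)
    return TemplateHit(
        template_id=template_id,
        target_aligned=t_sub,
        template_aligned=q_sub,
        target_start=t_start + 1,
        template_start=q_start + 1,
        raw_score=raw,
        bit_score=bit,
        e_value=e_value,
        global_identity=ident / ncols if ncols else 0.0,
    )


def window_identity(
    hit: TemplateHit, variant_residue_start: int, variant_residue_end: int
) -> TemplateHit:
    """Score the alignment window around the variant locus.

    The window is the alignment columns holding the affected target residues
    plus ``WINDOW_FLANK`` columns each side, truncated at the alignment ends.
    Gap columns count as mismatches; 'X' never counts as identity.  Passing
    requires count > 5 * window_length / 11 (strict), the full-window case
    being the literal "more than 5 of 11".
    """
    if variant_residue_end < variant_residue_start:
        raise ValueError("variant span is empty")
    cols_for_target: dict[int, int] = {}
    ti = hit.target_start - 1
    for col, a in enumerate(hit.target_aligned):
        if a != "-":
            ti += 1
            cols_for_target[ti] = col
    span_cols = [
        cols_for_target[r]
        for r in range(variant_residue_start, variant_residue_end + 1)
        if r in cols_for_target
    ]
    if not span_cols:
        return replace(
            hit, window_identity_count=0, window_length=0,
            passes_window=False, window_uncovered=True,
        )
    lo = min(span_cols) - WINDOW_FLANK
    hi = max(span_cols) + WINDOW_FLANK
    truncated = lo < 0 or hi > len(hit.target_aligned) - 1
    lo = max(lo, 0)
    hi = min(hi, len(hit.target_aligned) - 1)
    count = sum(
        1
        for a, b in zip(hit.target_aligned[lo : hi + 1], hit.template_aligned[lo : hi + 1])
        if a == b and a not in ("-", "X")
    )
    length = hi - lo + 1
    passes = count * WINDOW_PASS_DEN > WINDOW_PASS_NUM * length
    return replace(
        hit, window_identity_count=count, window_length=length,
        passes_window=passes, window_truncated=truncated,
    )


def select_template(hits: Sequence[TemplateHit]) -> Optional[TemplateHit]:
    """Choose the most closely matching usable template.

    Candidates must be significant (E <= 1e-3) and pass the variant-window
    identity rule.  Ranking: highest window identity fraction, then highest
    global identity, then lowest E-value, then lexicographic template id.
    Returns None when no candidate survives (the variant is not modelable).
    """
    candidates = [h for h in hits if h.e_value <= EVALUE_CUTOFF and h.passes_window]
    if not candidates:
        return None
    return min(
        candidates,
        key=lambda h: (-h.window_fraction, -h.global_identity, h.e_value, h.template_id),
    )


def map_residue_to_template(hit: TemplateHit, structure: StructureModel) -> ResidueMap:
    """Walk alignment columns to map target residues onto template residues.

    The template chain is taken from the ``template_id`` suffix
    (``<pdbid>_<chain>``).  The structure's ATOM-derived one-letter sequence
    must agree with the aligned template sequence; the first mismatch raises.
    """
    chain_id = hit.template_id.rsplit("_", 1)[-1] if "_" in hit.template_id else None
    chain = structure.get_chain(chain_id) if chain_id else structure.protein_chains()[0]
    atom_seq = chain_one_letter_sequence(chain)
    residues = [r for r in chain.residues]

    aligned_template = hit.template_aligned.replace("-", "")
    offset = hit.template_start - 1
    segment = atom_seq[offset : offset + len(aligned_template)]
    for k, (a, b) in enumerate(zip(aligned_template, segment)):
        if a != b and "X" not in (a, b):
            raise ValueError(
                f"template sequence mismatch at template position {offset + k + 1}: "
                f"alignment has '{a}', ATOM records have '{b}'"
            )
    if len(segment) < len(aligned_template):
        raise ValueError("ATOM-derived sequence shorter than the aligned template region")

    pairs: list[tuple[int, tuple[str, int]]] = []
    unmapped: list[int] = []
    ti = hit.target_start - 1
    qi = offset
    for a, b in zip(hit.target_aligned, hit.template_aligned):
        if a != "-" and b != "-":
            ti += 1
            qi += 1
            res = residues[qi - 1]
            pairs.append((ti, (chain.chain_id, res.seq_num)))
        elif a != "-":
            ti += 1
            unmapped.append(ti)
        elif b != "-":
            qi += 1
    return ResidueMap(pairs=tuple(pairs), unmapped=tuple(unmapped))
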