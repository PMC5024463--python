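"""Indel normalization, transcript projection and filtering.

Coding indels are handled in VCF conventions on the DNA side (1-based
position of the first REF base, left-aligned with an anchor base) and in
HGVS conventions on the protein side (most 3'/C-terminal equivalent
representation).  Both representations are kept because they disagree by
construction whenever the indel sits in a repeat.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Optional, Sequence

from Bio.Seq import Seq
from Bio.SeqUtils import seq3

__all__ = [
    "ReferenceWindow",
    "RawVariant",
    "TranscriptModel",
    "CodingIndel",
    "FilterThresholds",
    "ProjectionKind",
    "NormalizationError",
    "normalize_indel",
    "project_and_classify_frame",
    "compute_protein_change",
    "flag_splice_proximity",
    "apply_filters",
    "assess_sample_coverage",
]


class NormalizationError(ValueError):
    """REF allele disagrees with the supplied reference sequence."""


@dataclass(frozen=True)
class ReferenceWindow:
    """A slice of reference sequence with its genomic offset.

    ``start`` is the 1-based genomic coordinate of ``seq[0]``.
    """

    seq: str
    start: int

    @property
    def end(self) -> int:
        return self.start + len(self.seq) - 1

    def base(self, pos: int) -> str:
        if not self.start <= pos <= self.end:
            raise IndexError(f"position {pos} outside window [{self.start}, {self.end}]")
        return self.seq[pos - self.start]

    def slice(self, start: int, end: int) -> str:
        """Inclusive 1-based genomic slice."""
        if not (self.start <= start and end <= self.end):
            raise IndexError(f"[{start}, {end}] outside window [{self.start}, {self.end}]")
        return self.seq[start - self.start : end - self.start + 1]


@dataclass(frozen=True)
class RawVariant:
    chromosome: str
    position: int  # 1-based genomic coordinate of the first REF base
    ref_allele: str
    alt_allele: str
    support_fraction: Optional[float] = None
    population_af: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.ref_allele or not self.alt_allele:
            raise ValueError("ref/alt alleles must be non-empty")
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt alleles are identical")

    @property
    def net_length_change(self) -> int:
        return len(self.alt_allele) - len(self.ref_allele)

    @property
    def variant_id(self) -> str:
        return f"{self.chromosome}:{self.position}:{self.ref_allele}>{self.alt_allele}"


@dataclass(frozen=True)
class TranscriptModel:
    """Single-transcript gene model with spliced, strand-corrected CDS.

    ``exons`` and ``cds_intervals`` are 1-based inclusive genomic intervals,
    sorted in transcription order (ascending for '+', descending for '-').
    ``cds_sequence`` is the spliced coding sequence read 5'->3' on the coding
    strand, expected to begin with ATG and end with a stop codon; violations
    are recorded as validation warnings rather than errors because curated
    transcript sets contain such models.
    """

    transcript_id: str
    chromosome: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds_intervals: tuple[tuple[int, int], ...]
    cds_sequence: str
    warnings: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        warn = list(self.warnings)
        genomic_sorted = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(genomic_sorted, genomic_sorted[1:]):
            if s2 <= e1:
                raise ValueError(f"{self.transcript_id}: overlapping exons")
        if len(self.cds_sequence) % 3 != 0:
            warn.append("cds_length_not_multiple_of_3")
        if not self.cds_sequence.upper().startswith("ATG"):
            warn.append("cds_missing_start_codon")
        if self.cds_sequence.upper()[-3:] not in ("TAA", "TAG", "TGA"):
            warn.append("cds_missing_stop_codon")
        object.__setattr__(self, "warnings", tuple(warn))
        object.__setattr__(self, "exons", tuple(tuple(x) for x in self.exons))
        object.__setattr__(self, "cds_intervals", tuple(tuple(x) for x in self.cds_intervals))

    # -- coordinate machinery ------------------------------------------------

    def _cds_positions(self) -> list[int]:
        """Genomic positions of CDS bases in transcription (CDS) order."""
        pos: list[int] = []
        ivals = sorted(self.cds_intervals)
        if self.strand == "+":
            for s, e in ivals:
                pos.extend(range(s, e + 1))
        else:
            for s, e in reversed(ivals):
                pos.extend(range(e, s - 1, -1))
        return pos

    def genomic_to_cds(self, pos: int) -> Optional[int]:
        """1-based CDS coordinate of a genomic position, None if non-CDS."""
        for s, e in self.cds_intervals:
            if s <= pos <= e:
                break
        else:
            return None
        c = 0
        ivals = sorted(self.cds_intervals)
        if self.strand == "+":
            for s, e in ivals:
                if pos > e:
                    c += e - s + 1
                elif pos >= s:
                    return c + pos - s + 1
        else:
            for s, e in reversed(ivals):
                if pos < s:
                    c += e - s + 1
                elif pos <= e:
                    return c + e - pos + 1
        return None

    @property
    def protein_sequence(self) -> str:
        """Translation of the CDS up to (not including) the first stop."""
        prot = str(Seq(self.cds_sequence).translate())
        stop = prot.find("*")
        return prot if stop < 0 else prot[:stop]

    def exon_boundaries(self) -> list[int]:
        out: list[int] = []
        for s, e in self.exons:
            out.extend((s, e))
        return out


class ProjectionKind(str, Enum):
    CODING = "coding"
    NON_CODING = "non_coding"
    JUNCTION_SPANNING = "junction_spanning"
    TERMINAL_CODON = "terminal_codon"


@dataclass(frozen=True)
class CodingIndel:
    variant: RawVariant
    transcript_id: str
    kind: ProjectionKind
    cds_start: Optional[int] = None
    cds_end: Optional[int] = None
    net_length_change: int = 0
    frame_status: Optional[str] = None  # in_frame | frameshift
    deleted_cds_seq: str = ""
    inserted_cds_seq: str = ""
    affected_residue_start: Optional[int] = None
    affected_residue_end: Optional[int] = None
    n_affected_residues: Optional[int] = None
    hgvs_c: Optional[str] = None
    hgvs_p: Optional[str] = None
    splice_proximal: bool = False
    in_scope: bool = True  # False when |net change| exceeds the size definition

    @property
    def is_in_frame(self) -> bool:
        return self.frame_status == "in_frame"


@dataclass(frozen=True)
class FilterThresholds:
    """Cohort QC and triage thresholds.

    Defaults follow the study design: indels supported by <0.1 of reads are
    discarded, population allele frequency >1 % is treated as benign, samples
    require >=99.5 % of the target at >=50x, the splice-proximity window is
    2 bp, and a "small" indel gains or loses at most 21 nt.
    """

    max_indel_nt: int = 21
    min_support_fraction: float = 0.1
    max_benign_af: float = 0.01
    min_depth: int = 50
    min_covered_fraction: float = 0.995
    splice_window_nt: int = 2
    # SNV-style depth/quality gates exist in the source pipeline but are not
    # documented for indels; exposed off by default.
    min_variant_depth: Optional[int] = None

    def __post_init__(self) -> None:
        if self.max_indel_nt < 1:
            raise ValueError("max_indel_nt must be >= 1")
        for name in ("min_support_fraction", "max_benign_af", "min_covered_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.min_depth < 0 or self.splice_window_nt < 0:
            raise ValueError("thresholds must be non-negative")


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def normalize_indel(v: RawVariant, window: ReferenceWindow) -> RawVariant:
    """Left-align an indel to its left-most VCF representation.

    Trims the shared suffix/prefix and shifts the event left through any
    repeat tract, keeping the VCF anchor-base convention.  Idempotent.
    Raises :class:`NormalizationError` when the REF allele does not match
    the reference window.
    """
    pos, ref, alt = v.position, v.ref_allele.upper(), v.alt_allele.upper()
    observed = window.slice(pos, pos + len(ref) - 1)
    if observed.upper() != ref:
        raise NormalizationError(
            f"{v.variant_id}: REF '{ref}' != reference '{observed}' at {v.chromosome}:{pos}"
        )
    while True:
        changed = False
        if ref and alt and ref[-1] == alt[-1] and (len(ref) > 1 or len(alt) > 1):
            if len(ref) == 1 or len(alt) == 1:
                if pos - 1 < window.start:
                    break  # cannot extend further left; keep as is
                left = window.base(pos - 1).upper()
                ref = left + ref[:-1]
                alt = left + alt[:-1]
                pos -= 1
            else:
                ref = ref[:-1]
                alt = alt[:-1]
            changed = True
        if len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
            ref = ref[1:]
            alt = alt[1:]
            pos += 1
            changed = True
        if not changed:
            break
    return replace(v, position=pos, ref_allele=ref, alt_allele=alt)


def _altered_span(v: RawVariant) -> tuple[int, int, str, str]:
    """(first, last) genomic positions of altered REF bases plus the
    deleted/inserted sequences, for a normalized variant.

    For a pure insertion the span is empty and encoded as (pos, pos) with
    ``deleted == ''``: the insertion point lies between pos and pos+1.
    """
    ref, alt = v.ref_allele, v.alt_allele
    p = 0
    while p < min(len(ref), len(alt)) and ref[p] == alt[p]:
        p += 1
    deleted = ref[p:]
    inserted = alt[p:]
    if deleted:
        return v.position + p, v.position + len(ref) - 1, deleted, inserted
    return v.position + p - 1, v.position + p - 1, "", inserted


# ---------------------------------------------------------------------------
# projection
# ---------------------------------------------------------------------------

def flag_splice_proximity(
    v: RawVariant, t: TranscriptModel, th: FilterThresholds = FilterThresholds()
) -> bool:
    """True iff any altered base lies within ``splice_window_nt`` of an exon
    boundary (boundary bases inclusive)."""
    first, last, deleted, _ = _altered_span(v)
    if deleted:
        positions: Iterable[int] = range(first, last + 1)
    else:  # insertion: consider the two flanking bases
        positions = (first, first + 1)
    bounds = t.exon_boundaries()
    return any(min(abs(p - b) for b in bounds) <= th.splice_window_nt for p in positions)


def project_and_classify_frame(
    v: RawVariant, t: TranscriptModel, th: FilterThresholds = FilterThresholds()
) -> CodingIndel:
    """Project a normalized variant onto a transcript and classify its frame.

    Returns a typed :class:`CodingIndel`; non-coding and exon/intron
    junction-spanning events carry no protein-level fields.
    """
    first, last, deleted, inserted = _altered_span(v)
    net = len(inserted) - len(deleted)
    splice = flag_splice_proximity(v, t, th)

    if deleted:
        altered = list(range(first, last + 1))
    else:
        altered = [first, first + 1]
    in_cds = [t.genomic_to_cds(p) is not None for p in altered]

    if not any(in_cds):
        return CodingIndel(
            variant=v, transcript_id=t.transcript_id, kind=ProjectionKind.NON_CODING,
            net_length_change=net, splice_proximal=splice,
        )
    if deleted and not all(in_cds):
        return CodingIndel(
            variant=v, transcript_id=t.transcript_id,
            kind=ProjectionKind.JUNCTION_SPANNING,
            net_length_change=net, splice_proximal=splice,
        )
    if not deleted and not all(in_cds):
        # insertion at the terminal CDS base: treat as junction-spanning
        return CodingIndel(
            variant=v, transcript_id=t.transcript_id,
            kind=ProjectionKind.JUNCTION_SPANNING,
            net_length_change=net, splice_proximal=splice,
        )

    cds_coords = sorted(t.genomic_to_cds(p) for p in altered)
    cds_start, cds_end = cds_coords[0], cds_coords[-1]
    if deleted and cds_end - cds_start + 1 != len(deleted):
        # CDS coordinates not contiguous: the event crosses an intron
        return CodingIndel(
            variant=v, transcript_id=t.transcript_id,
            kind=ProjectionKind.JUNCTION_SPANNING,
            net_length_change=net, splice_proximal=splice,
        )

    if t.strand == "-":
        deleted_cds = str(Seq(deleted).reverse_complement())
        inserted_cds = str(Seq(inserted).reverse_complement())
    else:
        deleted_cds, inserted_cds = deleted, inserted
    if not deleted:
        # insertion point between the two flanking CDS bases, 5'-most first
        cds_start, cds_end = cds_coords[0], cds_coords[1]

    frame_status = "in_frame" if abs(net) % 3 == 0 else "frameshift"
    in_scope = abs(net) <= th.max_indel_nt

    if deleted_cds and inserted_cds:
        hgvs_c = f"c.{cds_start}_{cds_end}delins{inserted_cds}"
    elif deleted_cds:
        hgvs_c = (
            f"c.{cds_start}del" if len(deleted_cds) == 1 else f"c.{cds_start}_{cds_end}del"
        )
    else:
        hgvs_c = f"c.{cds_start}_{cds_end}ins{inserted_cds}"

    return CodingIndel(
        variant=v, transcript_id=t.transcript_id, kind=ProjectionKind.CODING,
        cds_start=cds_start, cds_end=cds_end, net_length_change=net,
        frame_status=frame_status, deleted_cds_seq=deleted_cds,
        inserted_cds_seq=inserted_cds, hgvs_c=hgvs_c, splice_proximal=splice,
        in_scope=in_scope,
    )


# ---------------------------------------------------------------------------
# protein-level change
# ---------------------------------------------------------------------------

def _translate(cds: str) -> str:
    prot = str(Seq(cds[: len(cds) - len(cds) % 3]).translate())
    stop = prot.find("*")
    return prot if stop < 0 else prot[:stop]


def mutant_cds(ci: CodingIndel, t: TranscriptModel) -> str:
    """Apply the CDS-space edit of a coding indel to the transcript CDS."""
    cds = t.cds_sequence
    if ci.deleted_cds_seq:
        s, e = ci.cds_start, ci.cds_end
        return cds[: s - 1] + ci.inserted_cds_seq + cds[e:]
    # insertion between cds_start and cds_end (= cds_start + 1)
    return cds[: ci.cds_start] + ci.inserted_cds_seq + cds[ci.cds_start :]


def compute_protein_change(ci: CodingIndel, t: TranscriptModel) -> CodingIndel:
    """Fill in the protein-level consequence of an in-frame coding indel.

    The protein HGVS name uses the 3'-most equivalent representation: the
    shared prefix of wild-type and mutant proteins is trimmed greedily first,
    then the shared suffix, which pushes the named residues as C-terminal as
    possible.  Deletions touching the initiator methionine or removing the
    stop codon are returned as typed ``terminal_codon`` results.
    """
    if ci.kind is not ProjectionKind.CODING or not ci.is_in_frame:
        raise ValueError("protein change is defined for coding in-frame indels only")
    mut_full = str(Seq((lambda s: s[: len(s) - len(s) % 3])(mutant_cds(ci, t))).translate())
    wt = _translate(t.cds_sequence)
    mut = _translate(mutant_cds(ci, t))

    if mut and mut[0] != "M":
        return replace(ci, kind=ProjectionKind.TERMINAL_CODON)
    if "*" not in mut_full:
        return replace(ci, kind=ProjectionKind.TERMINAL_CODON)
    if ci.cds_start is not None and ci.cds_start <= 3 and ci.deleted_cds_seq:
        return replace(ci, kind=ProjectionKind.TERMINAL_CODON)
    if wt == mut:
        # silent at the protein level (can happen when the edit rearranges
        # codons without changing the translation)
        return replace(
            ci, hgvs_p="p.(=)", affected_residue_start=None,
            affected_residue_end=None, n_affected_residues=0,
        )

    # 3'-most representation: trim prefix greedily, then suffix.
    p = 0
    while p < min(len(wt), len(mut)) and wt[p] == mut[p]:
        p += 1
    s = 0
    while (
        s < min(len(wt), len(mut)) - p
        and wt[len(wt) - 1 - s] == mut[len(mut) - 1 - s]
    ):
        s += 1
    del_res = wt[p : len(wt) - s]  # residues removed, 1-based span [p+1, len(wt)-s]
    ins_res = mut[p : len(mut) - s]

    def res(i: int) -> str:  # 1-based wild-type residue label, e.g. Ala3
        return f"{seq3(wt[i - 1])}{i}"

    if del_res and not ins_res:
        start, end = p + 1, len(wt) - s
        hgvs_p = (
            f"p.({res(start)}del)" if start == end else f"p.({res(start)}_{res(end)}del)"
        )
        aff = (start, end)
    elif ins_res and not del_res:
        # insertion between wt residues p and p+1
        left, right = p, p + 1
        if left < 1 or right > len(wt):
            return replace(ci, kind=ProjectionKind.TERMINAL_CODON)
        hgvs_p = f"p.({res(left)}_{res(right)}ins{seq3(ins_res)})"
        aff = (left, right)
    else:
        start, end = p + 1, len(wt) - s
        span = res(start) if start == end else f"{res(start)}_{res(end)}"
        hgvs_p = f"p.({span}delins{seq3(ins_res)})"
        aff = (start, end)

    return replace(
        ci,
        hgvs_p=hgvs_p,
        affected_residue_start=aff[0],
        affected_residue_end=aff[1],
        n_affected_residues=aff[1] - aff[0] + 1,
    )


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------

def apply_filters(
    records: Sequence[CodingIndel], th: FilterThresholds = FilterThresholds()
) -> tuple[list[CodingIndel], list[tuple[CodingIndel, str]]]:
    """Partition records into kept and discarded-with-reason.

    Rules are applied in fixed order -- read support, then population allele
    frequency, then size -- and the first failing rule is reported.  Records
    missing a metric pass the corresponding rule.
    """
    kept: list[CodingIndel] = []
    discarded: list[tuple[CodingIndel, str]] = []
    for r in records:
        sf = r.variant.support_fraction
        af = r.variant.population_af
        if sf is not None and sf < th.min_support_fraction:
            discarded.append((r, "support"))
        elif af is not None and af > th.max_benign_af:
            discarded.append((r, "benign_af"))
        elif not r.in_scope or abs(r.net_length_change) > th.max_indel_nt:
            discarded.append((r, "size"))
        else:
            kept.append(r)
    return kept, discarded


def assess_sample_coverage(
    per_base_depths: Sequence[int], th: FilterThresholds = FilterThresholds()
) -> str:
    """'included' iff the fraction of target positions at >= min_depth is
    >= min_covered_fraction."""
    if len(per_base_depths) == 0:
        raise ValueError("empty depth vector")
    covered = sum(1 for d in per_base_depths if d >= th.min_depth)
    frac = covered / len(per_base_depths)
    return "included" if frac >= th.min_covered_fraction else "excluded"
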