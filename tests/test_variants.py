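"""Indel normalization, transcript projection, protein change and filters."""

import numpy as np
import pytest

from inframe.variants import (
    CodingIndel,
    FilterThresholds,
    NormalizationError,
    ProjectionKind,
    RawVariant,
    ReferenceWindow,
    TranscriptModel,
    apply_filters,
    assess_sample_coverage,
    compute_protein_change,
    flag_splice_proximity,
    normalize_indel,
    project_and_classify_frame,
)

# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------


def _leftmost_oracle(v: RawVariant, seq: str) -> tuple[int, str, str]:
    """Brute force: enumerate every anchor-style representation producing the
    same edited haplotype and return the left-most one."""
    pos, ref, alt = v.position, v.ref_allele, v.alt_allele
    hap = seq[: pos - 1] + alt + seq[pos - 1 + len(ref) :]
    d = len(ref) - len(alt)
    for p in range(1, len(seq) + 1):
        if d > 0:  # deletion of d bases after anchor p
            if p + d > len(seq):
                continue
            cand = seq[:p] + seq[p + d :]
            if cand == hap:
                return p, seq[p - 1 : p + d], seq[p - 1]
        else:  # insertion of -d bases after anchor p
            k = -d
            cand_ins = hap[p : p + k]
            if seq[:p] == hap[:p] and seq[p:] == hap[p + k :]:
                return p, seq[p - 1], seq[p - 1] + cand_ins
    raise AssertionError("oracle found no representation")


def test_left_shift_in_homopolymer():
    w = ReferenceWindow("GATTTTC", 1)
    v = RawVariant("1", 4, "TT", "T")
    out = normalize_indel(v, w)
    assert (out.position, out.ref_allele, out.alt_allele) == (2, "AT", "A")


def test_normalization_idempotent():
    w = ReferenceWindow("GATTTTC", 1)
    out1 = normalize_indel(RawVariant("1", 4, "TT", "T"), w)
    out2 = normalize_indel(out1, w)
    assert out1 == out2


def test_reference_mismatch_rejected():
    w = ReferenceWindow("GATTTTC", 1)
    with pytest.raises(NormalizationError):
        normalize_indel(RawVariant("1", 4, "AA", "A"), w)


def test_normalize_matches_bruteforce_oracle(rng):
    """Left-alignment equals exhaustive enumeration on random sequences."""
    for _ in range(1000):
        n = 200
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))
        p = int(rng.integers(40, n - 30))
        if rng.random() < 0.5:
            d = int(rng.integers(1, 8))
            v = RawVariant("1", p, seq[p - 1 : p + d], seq[p - 1])
        else:
            k = int(rng.integers(1, 8))
            ins = "".join("ACGT"[i] for i in rng.integers(0, 4, size=k))
            v = RawVariant("1", p, seq[p - 1], seq[p - 1] + ins)
        got = normalize_indel(v, ReferenceWindow(seq, 1))
        exp = _leftmost_oracle(v, seq)
        assert (got.position, got.ref_allele, got.alt_allele) == exp


# ---------------------------------------------------------------------------
# projection / frame
# ---------------------------------------------------------------------------

# single-exon plus-strand toy transcript: flank(10) + CDS(30) + flank(10)
_CDS = "ATGGCCGCCAAAGTTCCAGAAGATCGCTAA"  # M A A K V P E D R *
_CONTIG = "GATTACAGAT" + _CDS + "CCGGAATTCC"
_T = TranscriptModel(
    transcript_id="T1",
    chromosome="1",
    strand="+",
    exons=((11, 40),),
    cds_intervals=((11, 40),),
    cds_sequence=_CDS,
)

# two-exon transcript for junction tests: exon1 CDS 15 nt, exon2 15 nt
_CONTIG2 = "GATTACAGAT" + _CDS[:15] + "GTAAGTTTTCAG" + _CDS[15:] + "CCGGAATTCC"
_T2 = TranscriptModel(
    transcript_id="T2",
    chromosome="1",
    strand="+",
    exons=((11, 25), (38, 52)),
    cds_intervals=((11, 25), (38, 52)),
    cds_sequence=_CDS,
)


def _minus_model():
    from Bio.Seq import Seq

    contig = "GATTACAGAT" + str(Seq(_CDS).reverse_complement()) + "CCGGAATTCC"
    t = TranscriptModel(
        transcript_id="TM",
        chromosome="1",
        strand="-",
        exons=((11, 40),),
        cds_intervals=((11, 40),),
        cds_sequence=_CDS,
    )
    return contig, t


def test_inframe_deletion_classified():
    v = RawVariant("1", 13, "GGCC", "G")  # deletes CDS bases 4-6
    ci = project_and_classify_frame(v, _T)
    assert ci.kind is ProjectionKind.CODING
    assert ci.frame_status == "in_frame"
    assert ci.net_length_change == -3
    assert (ci.cds_start, ci.cds_end) == (4, 6)


def test_frameshift_deletion_classified():
    v = RawVariant("1", 13, "GGCCG", "G")
    ci = project_and_classify_frame(v, _T)
    assert ci.frame_status == "frameshift"


def test_21nt_deletion_affects_seven_residues():
    """A 21-nt in-frame deletion removes 7 residues, the size ceiling."""
    cds = "ATG" + "GCC" * 10 + "AAAGATCGC" + "TAA"
    contig = "GATTACAGAT" + cds + "CCGGAATTCC"
    t = TranscriptModel(
        transcript_id="T3", chromosome="1", strand="+",
        exons=((11, 10 + len(cds)),), cds_intervals=((11, 10 + len(cds)),),
        cds_sequence=cds,
    )
    v = RawVariant("1", 13, contig[12:34], contig[12])  # delete CDS 4..24
    ci = project_and_classify_frame(v, t)
    assert ci.frame_status == "in_frame" and ci.net_length_change == -21
    ci = compute_protein_change(ci, t)
    assert ci.n_affected_residues == 7
    assert ci.in_scope


def test_out_of_scope_marked_not_dropped():
    cds = "ATG" + "GCC" * 10 + "AAAGATCGC" + "TAA"
    contig = "GATTACAGAT" + cds + "CCGGAATTCC"
    t = TranscriptModel(
        transcript_id="T3", chromosome="1", strand="+",
        exons=((11, 10 + len(cds)),), cds_intervals=((11, 10 + len(cds)),),
        cds_sequence=cds,
    )
    v = RawVariant("1", 13, contig[12:37], contig[12])  # 24 nt deletion
    ci = project_and_classify_frame(v, t)
    assert ci.kind is ProjectionKind.CODING and not ci.in_scope
    kept, discarded = apply_filters([ci])
    assert discarded and discarded[0][1] == "size"


def test_intronic_variant_typed_non_coding():
    v = RawVariant("1", 29, _CONTIG2[28:30], _CONTIG2[28])  # deep intron of T2
    ci = project_and_classify_frame(v, _T2)
    assert ci.kind is ProjectionKind.NON_CODING


def test_junction_spanning_typed():
    # deletion spanning the exon1/intron boundary of T2 (exon ends at 25)
    v = RawVariant("1", 23, _CONTIG2[22:28], _CONTIG2[22])
    ci = project_and_classify_frame(v, _T2)
    assert ci.kind is ProjectionKind.JUNCTION_SPANNING
    assert ci.hgvs_p is None


def test_minus_strand_projection():
    contig, t = _minus_model()
    # delete the 3 genomic bases that are CDS 4..6 on the minus strand
    # CDS 4..6 ("GCC") maps to genomic 35..37 on the reverse strand
    v = RawVariant("1", 34, contig[33:37], contig[33])
    v = normalize_indel(v, ReferenceWindow(contig, 1))
    ci = project_and_classify_frame(v, t)
    assert ci.kind is ProjectionKind.CODING
    assert ci.frame_status == "in_frame"
    ci = compute_protein_change(ci, t)
    assert ci.hgvs_p == "p.(Ala3del)"


# ---------------------------------------------------------------------------
# protein change (translate-and-diff oracle)
# ---------------------------------------------------------------------------


def _mini_model(cds: str) -> tuple[str, TranscriptModel]:
    contig = "GATTACAGAT" + cds + "CCGGAATTCC"
    t = TranscriptModel(
        transcript_id="TP", chromosome="1", strand="+",
        exons=((11, 10 + len(cds)),), cds_intervals=((11, 10 + len(cds)),),
        cds_sequence=cds,
    )
    return contig, t


@pytest.mark.parametrize(
    "cds,del_start,del_len,expected",
    [
        ("ATGGCCGCCAAATAA", 4, 3, "p.(Ala3del)"),  # 3' rule on tandem Ala
        ("ATGGCCGCCAAATAA", 5, 3, "p.(Ala3del)"),  # non-codon-aligned collapse
        ("ATGAAAGCCTAA", 4, 3, "p.(Lys2del)"),  # unique codon
    ],
)
def test_protein_deletion_names(cds, del_start, del_len, expected):
    contig, t = _mini_model(cds)
    g = 10 + del_start  # genomic position of first deleted base
    v = RawVariant("1", g - 1, contig[g - 2 : g - 1 + del_len], contig[g - 2])
    v = normalize_indel(v, ReferenceWindow(contig, 1))
    ci = project_and_classify_frame(v, t)
    ci = compute_protein_change(ci, t)
    assert ci.hgvs_p == expected


def test_protein_change_matches_translation_oracle(rng):
    """The residues named in hgvs_p are exactly the wild-type/mutant
    translation difference, for random in-frame deletions."""
    from Bio.Seq import Seq

    aa_of = lambda s: str(Seq(s).translate()).split("*")[0]
    for _ in range(200):
        n_codons = int(rng.integers(10, 30))
        safe = [c for c in (a + b + d for a in "ACGT" for b in "ACGT" for d in "ACGT")
                if c not in ("TAA", "TAG", "TGA")]
        cds = "ATG" + "".join(safe[i] for i in rng.integers(0, len(safe), size=n_codons)) + "TAA"
        contig, t = _mini_model(cds)
        del_len = int(rng.integers(1, 4)) * 3
        start = int(rng.integers(4, len(cds) - 3 - del_len))  # inside CDS, not initiator
        g = 10 + start
        v = RawVariant("1", g - 1, contig[g - 2 : g - 1 + del_len], contig[g - 2])
        v = normalize_indel(v, ReferenceWindow(contig, 1))
        ci = project_and_classify_frame(v, t)
        assert ci.frame_status == "in_frame"
        ci = compute_protein_change(ci, t)
        if ci.kind is ProjectionKind.TERMINAL_CODON:
            continue
        wt = aa_of(cds)
        mut_cds = cds[: ci.cds_start - 1] + cds[ci.cds_end :]
        mut = aa_of(mut_cds)
        if ci.n_affected_residues == 0:
            assert wt == mut
            continue
        s, e = ci.affected_residue_start, ci.affected_residue_end
        if "delins" in ci.hgvs_p:
            from Bio.SeqUtils import seq1

            inserted = seq1(ci.hgvs_p.split("delins")[1].rstrip(")"))
            assert wt[: s - 1] + inserted + wt[e:] == mut
        else:
            assert wt[: s - 1] + wt[e:] == mut
        assert ci.n_affected_residues == e - s + 1


def test_initiator_deletion_typed_terminal():
    contig, t = _mini_model("ATGGCCGCCAAATAA")
    v = RawVariant("1", 10, contig[9:13], contig[9])  # removes ATG
    ci = project_and_classify_frame(v, t)
    ci = compute_protein_change(ci, t)
    assert ci.kind is ProjectionKind.TERMINAL_CODON
    assert ci.hgvs_p is None


def test_insertion_named():
    contig, t = _mini_model("ATGAAAGCCTAA")
    # insert GAT (Asp) after CDS base 6 (between Lys2 and Ala3)
    g = 16  # genomic position of CDS base 6
    v = RawVariant("1", g, contig[g - 1], contig[g - 1] + "GAT")
    v = normalize_indel(v, ReferenceWindow(contig, 1))
    ci = project_and_classify_frame(v, t)
    assert ci.frame_status == "in_frame"
    ci = compute_protein_change(ci, t)
    assert "ins" in ci.hgvs_p


# ---------------------------------------------------------------------------
# splice proximity
# ---------------------------------------------------------------------------


def test_splice_proximity_window():
    # exon1 of T2 ends at 25; a deletion of base 24 starts 1 bp inside
    th = FilterThresholds()
    near = RawVariant("1", 23, _CONTIG2[22:24], _CONTIG2[22])
    assert flag_splice_proximity(near, _T2, th)
    # center of exon1 (position 17), > 2 bp from both boundaries
    mid = RawVariant("1", 16, _CONTIG2[15:17], _CONTIG2[15])
    assert not flag_splice_proximity(mid, _T2, th)
    # altered base exactly 3 bp from the boundary -> outside the window
    v3 = RawVariant("1", 21, _CONTIG2[20:22], _CONTIG2[20])  # deletes base 22
    assert not flag_splice_proximity(v3, _T2, th)


# ---------------------------------------------------------------------------
# filters and coverage
# ---------------------------------------------------------------------------


def _ci(support=None, af=None, net=-3, in_scope=True) -> CodingIndel:
    v = RawVariant("1", 100, "AT", "A", support_fraction=support, population_af=af)
    return CodingIndel(
        variant=v, transcript_id="T", kind=ProjectionKind.CODING,
        net_length_change=net, frame_status="in_frame", in_scope=in_scope,
    )


def test_filter_order_and_thresholds():
    kept, discarded = apply_filters(
        [
            _ci(support=4 / 60),            # below 0.1 -> support
            _ci(support=0.1),               # exactly 0.1 -> kept (strict <)
            _ci(af=0.02),                   # >1 % -> benign
            _ci(support=0.05, af=0.02),     # support fires first
            _ci(),                          # metrics absent -> kept
        ]
    )
    reasons = [r for _, r in discarded]
    assert reasons == ["support", "benign_af", "support"]
    assert len(kept) == 2
    assert len(kept) + len(discarded) == 5


def test_filter_partition_exhaustive(rng):
    records = [
        _ci(
            support=float(rng.uniform(0, 0.3)) if rng.random() < 0.7 else None,
            af=float(rng.uniform(0, 0.05)) if rng.random() < 0.5 else None,
        )
        for _ in range(300)
    ]
    kept, discarded = apply_filters(records)
    assert len(kept) + len(discarded) == len(records)


def test_sample_coverage_rule():
    depths = [60] * 996 + [10] * 4
    assert assess_sample_coverage(depths) == "included"  # 0.996 >= 0.995
    depths = [60] * 994 + [10] * 6
    assert assess_sample_coverage(depths) == "excluded"
    assert assess_sample_coverage([0] * 100) == "excluded"
    with pytest.raises(ValueError):
        assess_sample_coverage([])


def test_frame_status_iff_multiple_of_three(rng):
    for _ in range(200):
        d = int(rng.integers(1, 22))
        ref = "A" + "".join("ACGT"[i] for i in rng.integers(0, 4, size=d))
        v = RawVariant("1", 13, ref, ref[0])
        contig = _CONTIG[:12] + ref[1:] + _CONTIG[12:]
        t = TranscriptModel(
            transcript_id="TF", chromosome="1", strand="+",
            exons=((11, 10 + len(_CDS) + d),),
            cds_intervals=((11, 10 + len(_CDS) + d),),
            cds_sequence=contig[10 : 10 + len(_CDS) + d],
        )
        ci = project_and_classify_frame(v, t)
        assert (ci.frame_status == "in_frame") == (abs(ci.net_length_change) % 3 == 0)
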