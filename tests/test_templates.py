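"""Template alignment statistics, variant-window rule and residue mapping."""

import math

import pytest
from Bio.Align import substitution_matrices

from inframe.geometry import GeometrySpec, build_geometry
from inframe.structure import parse_structure
from inframe.templates import (
    EVALUE_CUTOFF,
    TemplateHit,
    align_and_score,
    map_residue_to_template,
    select_template,
    window_identity,
)

BLOSUM62 = substitution_matrices.load("BLOSUM62")


def test_self_alignment_full_identity():
    seq = "MKVLAWRTCFDEQHG"
    hit = align_and_score(seq, seq, library_size=10_000, template_id="X_A")
    assert hit.global_identity == 1.0
    assert hit.target_aligned == seq


def test_evalue_closed_form():
    """bit 30, m=300, n=1e5 -> E = 3e7 * 2^-30 (Karlin-Altschul arithmetic)."""
    # invert the bit-score relation to find the raw score giving exactly b=30
    raw = (30 * math.log(2) + math.log(0.041)) / 0.267
    bit = (0.267 * raw - math.log(0.041)) / math.log(2)
    e = 300 * 100_000 * 2 ** (-bit)
    assert e == pytest.approx(3e7 * 2**-30, rel=1e-12)
    assert e == pytest.approx(0.0279, abs=2e-4)


def test_empty_sequence_rejected():
    with pytest.raises(ValueError):
        align_and_score("", "MKV", 100)


def _sw_affine_oracle(a: str, b: str, open_cost=12, extend_cost=1) -> float:
    """Exhaustive Gotoh local alignment; gap of length k costs 11 + k."""
    n, m = len(a), len(b)
    NEG = -1e9
    M = [[0.0] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (vertical)
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = BLOSUM62[a[i - 1], b[j - 1]]
            X[i][j] = max(M[i - 1][j] - open_cost, X[i - 1][j] - extend_cost)
            Y[i][j] = max(M[i][j - 1] - open_cost, Y[i][j - 1] - extend_cost)
            M[i][j] = max(0.0, M[i - 1][j - 1] + s, X[i][j], Y[i][j])
            best = max(best, M[i][j])
    return best


def test_alignment_score_matches_dp_oracle(rng):
    """Best local score equals an independent Gotoh DP for short pairs."""
    alphabet = "ARNDCQEGHK"
    for _ in range(150):
        la, lb = int(rng.integers(2, 9)), int(rng.integers(2, 9))
        a = "".join(alphabet[i] for i in rng.integers(0, len(alphabet), size=la))
        b = "".join(alphabet[i] for i in rng.integers(0, len(alphabet), size=lb))
        expected = _sw_affine_oracle(a, b)
        if expected == 0.0:
            continue  # no positive-scoring local alignment exists
        hit = align_and_score(a, b, library_size=100)
        assert hit.raw_score == pytest.approx(expected)


def _hit(target_aligned, template_aligned, target_start=1, template_start=1):
    return TemplateHit(
        template_id="X_A", target_aligned=target_aligned,
        template_aligned=template_aligned, target_start=target_start,
        template_start=template_start, raw_score=100, bit_score=40,
        e_value=1e-9, global_identity=0.5,
    )


def test_window_identity_full_window():
    seq = "MKVLAWRTCFD"
    hit = _hit(seq, seq)
    out = window_identity(hit, 6, 6)
    assert (out.window_identity_count, out.window_length) == (11, 11)
    assert out.passes_window


def test_window_boundary_strictly_greater_than_5_of_11():
    target = "MKVLAWRTCFD"
    five = "MKVLA" + "GGGGGG"  # identities only in the 5 leading columns
    out5 = window_identity(_hit(target, five), 6, 6)
    assert out5.window_identity_count == 5 and not out5.passes_window
    six = "MKVLAW" + "GGGGG"
    out6 = window_identity(_hit(target, six), 6, 6)
    assert out6.window_identity_count == 6 and out6.passes_window


def test_window_truncated_at_terminus_scales_threshold():
    target = "MKVLAW"
    out = window_identity(_hit(target, target), 1, 1)  # only 5 right flank
    assert out.window_length == 6
    assert out.window_truncated
    assert out.passes_window  # 6 > 5*6/11


def test_window_uncovered_variant():
    hit = _hit("MKVLAW", "MKVLAW", target_start=10)
    out = window_identity(hit, 2, 2)  # variant before the aligned region
    assert out.window_uncovered and not out.passes_window


def test_window_symmetric_under_pair_swap():
    a, b = "MKVLAWRTCFD", "MKVHAWRTGFD"
    o1 = window_identity(_hit(a, b), 6, 6)
    o2 = window_identity(_hit(b, a), 6, 6)
    assert o1.window_identity_count == o2.window_identity_count


def test_x_never_counts_as_identity():
    out = window_identity(_hit("MKXLAW", "MKXLAW"), 3, 3)
    assert out.window_identity_count == 5  # the X column is excluded


# ---------------------------------------------------------------------------
# selection
# ---------------------------------------------------------------------------


def _scored(tid, window_frac, global_id, e):
    count = int(round(window_frac * 11))
    return TemplateHit(
        template_id=tid, target_aligned="A", template_aligned="A",
        target_start=1, template_start=1, raw_score=50, bit_score=30,
        e_value=e, global_identity=global_id,
        window_identity_count=count, window_length=11,
        passes_window=count * 11 > 5 * 11,
    )


def test_single_passing_hit_selected():
    h = _scored("T1_A", 10 / 11, 0.9, 1e-10)
    assert select_template([h]) is h


def test_selection_ordering_and_permutation_invariance(rng):
    hits = [
        _scored("T1_A", 8 / 11, 0.40, 1e-6),
        _scored("T2_A", 8 / 11, 0.35, 1e-9),
        _scored("T3_A", 7 / 11, 0.90, 1e-12),
    ]
    assert select_template(hits).template_id == "T1_A"  # window, then global id
    for _ in range(5):
        perm = [hits[i] for i in rng.permutation(len(hits))]
        assert select_template(perm).template_id == "T1_A"


def test_no_significant_hit_returns_none():
    hits = [_scored("T1_A", 10 / 11, 0.9, 0.002), _scored("T2_A", 9 / 11, 0.8, 1.0)]
    assert select_template(hits) is None
    assert all(h.e_value > EVALUE_CUTOFF for h in hits)


def test_tie_breaks_to_lexicographic_id():
    a = _scored("TB_A", 8 / 11, 0.5, 1e-8)
    b = _scored("TA_A", 8 / 11, 0.5, 1e-8)
    assert select_template([a, b]).template_id == "TA_A"


# ---------------------------------------------------------------------------
# residue mapping
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def helix_structure():
    seq = "MKVLAWRTCFDEQHGS"
    pdb = build_geometry(
        GeometrySpec(kind="ideal_helix", n_residues=16, params={"sequence": seq})
    )
    return seq, parse_structure(pdb)


def test_gapless_mapping_is_identity_offset(helix_structure):
    seq, structure = helix_structure
    hit = align_and_score(seq, seq, 1000, template_id="HLX_A")
    rmap = map_residue_to_template(hit, structure)
    assert rmap.unmapped == ()
    assert rmap.lookup(1) == ("A", 1)
    assert rmap.lookup(16) == ("A", 16)


def test_template_gap_shifts_mapping(helix_structure):
    seq, structure = helix_structure
    # target has two extra residues inserted before position 8
    target = seq[:7] + "GG" + seq[7:]
    hit = align_and_score(target, seq, 1000, template_id="HLX_A")
    rmap = map_residue_to_template(hit, structure)
    assert rmap.lookup(10) == ("A", 8)  # shifted back by the 2-residue gap
    assert set(rmap.unmapped) == {8, 9}


def test_mapping_matches_column_walk_oracle(helix_structure, rng):
    seq, structure = helix_structure
    for _ in range(30):
        # random target: mutate/insert around the template sequence
        target = list(seq)
        if rng.random() < 0.5:
            i = int(rng.integers(2, len(seq) - 2))
            target.insert(i, "G")
        target = "".join(target)
        hit = align_and_score(target, seq, 1000, template_id="HLX_A")
        rmap = map_residue_to_template(hit, structure)
        # oracle: walk the alignment columns
        ti = hit.target_start - 1
        qi = hit.template_start - 1
        expected = {}
        for a, b in zip(hit.target_aligned, hit.template_aligned):
            if a != "-" and b != "-":
                ti += 1
                qi += 1
                expected[ti] = ("A", qi)
            elif a != "-":
                ti += 1
            else:
                qi += 1
        assert dict(rmap.pairs) == expected


def test_atom_sequence_mismatch_raises(helix_structure):
    seq, structure = helix_structure
    wrong = "W" * len(seq)
    hit = align_and_score(seq, seq, 1000, template_id="HLX_A")
    bad = hit.__class__(**{**hit.__dict__, "template_aligned": wrong})
    with pytest.raises(ValueError, match="mismatch"):
        map_residue_to_template(bad, structure)
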