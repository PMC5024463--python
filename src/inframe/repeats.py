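"""Primary-sequence context of an indel: homopolymer runs and tandem repeats.

An indel sits in a homopolymer run (HR) when its altered bases lie within --
or an insertion immediately extends -- a maximal run of six or more identical
reference bases.  It sits in a tandem repeat (TR) when some unit of 1-21 nt
occurs in at least two consecutive reference copies spanning the altered
bases and the indel is compatible with slippage of that unit.  Both flags are
kept independently (a homopolymer is also a repeat of a 1-mer) alongside a
combined label.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .variants import RawVariant, ReferenceWindow, _altered_span

__all__ = [
    "SequenceContext",
    "FLANK_NT",
    "MIN_HOMOPOLYMER_RUN",
    "MAX_REPEAT_UNIT",
    "detect_homopolymer_context",
    "detect_tandem_repeat_context",
    "classify_context",
    "classify_variant_context",
]

FLANK_NT = 30  # reference flank required on each side of the variant
MIN_HOMOPOLYMER_RUN = 6  # "run of six or more identical bases"
MAX_REPEAT_UNIT = 21  # search bound; covers every in-scope indel size


@dataclass(frozen=True)
class SequenceContext:
    is_homopolymer: bool
    homopolymer_base: Optional[str]
    homopolymer_run_length: int
    is_tandem_repeat: bool
    repeat_unit: Optional[str]
    reference_copy_count: int

    def __post_init__(self) -> None:
        if self.is_homopolymer and self.homopolymer_run_length < MIN_HOMOPOLYMER_RUN:
            raise ValueError("homopolymer flag requires a run of >= 6")
        if self.is_tandem_repeat and (
            self.reference_copy_count < 2 or not self.repeat_unit
        ):
            raise ValueError("tandem-repeat flag requires >= 2 copies of a unit")

    @property
    def label(self) -> str:
        return classify_context(self.is_homopolymer, self.is_tandem_repeat)


def _require_flank(v: RawVariant, window: ReferenceWindow) -> None:
    first, last, deleted, _ = _altered_span(v)
    left = first if deleted else first
    right = last if deleted else first + 1
    if left - window.start < FLANK_NT or window.end - right < FLANK_NT:
        raise ValueError(
            f"reference window must cover the variant with >= {FLANK_NT} nt flanks"
        )


def detect_homopolymer_context(
    v: RawVariant, window: ReferenceWindow
) -> tuple[bool, Optional[str], int]:
    """(is_HR, base, run_length) for a normalized variant.

    The run is measured on the reference.  A deletion qualifies when every
    deleted base lies inside a qualifying run; an insertion qualifies when
    its insertion point is strictly inside a run, or abuts one and inserts
    only the run base (immediately extending it).
    """
    _require_flank(v, window)
    first, last, deleted, inserted = _altered_span(v)
    seq = window.seq.upper()

    best: tuple[int, Optional[str]] = (0, None)
    i = 0
    while i < len(seq):
        j = i
        while j < len(seq) and seq[j] == seq[i]:
            j += 1
        run_len = j - i
        if run_len >= MIN_HOMOPOLYMER_RUN:
            g_start = window.start + i
            g_end = window.start + j - 1
            base = seq[i]
            ok = False
            if deleted:
                ok = g_start <= first and last <= g_end
            else:
                # insertion point between `first` and `first + 1`
                strictly_inside = g_start <= first and first + 1 <= g_end
                extends = (
                    set(inserted.upper()) == {base}
                    and (first == g_end or first + 1 == g_start)
                )
                ok = strictly_inside or extends
            if ok and run_len > best[0]:
                best = (run_len, base)
        i = j
    if best[1] is None:
        return False, None, 0
    return True, best[1], best[0]


def _is_cyclic_repeat_of(seq: str, unit: str) -> bool:
    """True iff ``seq`` is a whole number of (possibly rotated) copies of
    ``unit``."""
    L = len(unit)
    if len(seq) % L != 0:
        return False
    doubled = unit * 2
    for k in range(L):
        rot = doubled[k : k + L]
        if rot * (len(seq) // L) == seq:
            return True
    return False


def detect_tandem_repeat_context(
    v: RawVariant, window: ReferenceWindow
) -> tuple[bool, Optional[str], int]:
    """(is_TR, unit, reference_copy_count) for a normalized variant.

    Every unit length 1..21 and every anchor within the flank is examined;
    a segment of >= 2 consecutive reference copies must span the altered
    bases and the indel must be unit-compatible (net change a multiple of
    the unit length, or the changed sequence itself a cyclic repeat of the
    unit).  The smallest qualifying unit is reported with the copy count of
    its longest qualifying segment.
    """
    _require_flank(v, window)
    first, last, deleted, inserted = _altered_span(v)
    seq = window.seq.upper()
    net = len(inserted) - len(deleted)
    changed = (deleted or inserted).upper()

    for L in range(1, MAX_REPEAT_UNIT + 1):
        best_copies = 0
        best_unit: Optional[str] = None
        for i in range(0, len(seq) - 2 * L + 1):
            unit = seq[i : i + L]
            if len(set(unit)) == 0:
                continue
            # extend consecutive copies of `unit` from i
            j = i + L
            while j + L <= len(seq) and seq[j : j + L] == unit:
                j += L
            copies = (j - i) // L
            if copies < 2:
                continue
            g_start = window.start + i
            g_end = window.start + (i + copies * L) - 1
            if deleted:
                spans = g_start <= first and last <= g_end
            else:
                spans = g_start <= first and first + 1 <= g_end
            if not spans:
                continue
            if net % L != 0 and not _is_cyclic_repeat_of(changed, unit):
                continue
            if copies > best_copies:
                best_copies, best_unit = copies, unit
        if best_unit is not None:
            return True, best_unit, best_copies
    return False, None, 0


def classify_context(hr: bool, tr: bool) -> str:
    if hr and tr:
        return "HR+TR"
    if hr:
        return "HR"
    if tr:
        return "TR"
    return "other"


def classify_variant_context(v: RawVariant, window: ReferenceWindow) -> SequenceContext:
    """Run both detectors on a normalized variant and bundle the result."""
    hr, base, run = detect_homopolymer_context(v, window)
    tr, unit, copies = detect_tandem_repeat_context(v, window)
    return SequenceContext(
        is_homopolymer=hr,
        homopolymer_base=base,
        homopolymer_run_length=run,
        is_tandem_repeat=tr,
        repeat_unit=unit,
        reference_copy_count=copies,
    )
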