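"""Concordance of pathogenicity predictors with clinical assessment.

Each variant carries three sequence-based tool calls (DDIG-in, SIFT-indel,
PROVEAN; D = damaging/deleterious/disease-associated, N = neutral), a
structure-based verdict (probably / unclear / unlikely / unassessable) and a
clinical call (probably / possibly / unlikely to account for the
presentation).  Treating the clinical report as the reference standard,
"possibly" cases are excluded and confusion-matrix statistics are computed
per predictor.

Mapping convention: the structural verdict "unclear" is scored on the
damaging side (positive), in the same spirit as an inconclusive tool call
being acted on conservatively; "unassessable" variants are excluded from the
structural predictor only.  The mapping is exposed as a parameter.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

__all__ = [
    "PredictionRecord",
    "EvaluationResult",
    "CohortCounts",
    "compute_agreement",
    "evaluate_against_clinical",
    "summarize_cohort",
    "round_metric",
    "round_percent",
]

TOOL_CALLS = ("D", "N")
STRUCTURAL_CALLS = ("probably", "unclear", "unlikely", "unassessable")
CLINICAL_CALLS = ("probably", "possibly", "unlikely")
PREDICTORS = ("ddig_in", "sift_indel", "provean", "structural")


def round_metric(x: Optional[float]) -> Optional[float]:
    """Confusion-matrix metrics are reported to 2 decimals."""
    return None if x is None else round(x, 2)


def round_percent(x: Optional[float]) -> Optional[float]:
    """Rates are reported as percentages to 1 decimal."""
    return None if x is None else round(x, 1)


@dataclass(frozen=True)
class PredictionRecord:
    variant_id: str
    ddig_in: str
    sift_indel: str
    provean: str
    structural: str
    clinical: str

    def __post_init__(self) -> None:
        for f in ("ddig_in", "sift_indel", "provean"):
            if getattr(self, f) not in TOOL_CALLS:
                raise ValueError(f"{f} must be one of {TOOL_CALLS}")
        if self.structural not in STRUCTURAL_CALLS:
            raise ValueError(f"structural must be one of {STRUCTURAL_CALLS}")
        if self.clinical not in CLINICAL_CALLS:
            raise ValueError(f"clinical must be one of {CLINICAL_CALLS}")


@dataclass(frozen=True)
class EvaluationResult:
    predictor: str
    n_evaluated: int
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if self.tp + self.fp + self.tn + self.fn != self.n_evaluated:
            raise ValueError("confusion-matrix cells must sum to n_evaluated")

    @property
    def accuracy(self) -> Optional[float]:
        if self.n_evaluated == 0:
            return None
        return round_metric((self.tp + self.tn) / self.n_evaluated)

    @property
    def sensitivity(self) -> Optional[float]:
        if self.tp + self.fn == 0:
            return None
        return round_metric(self.tp / (self.tp + self.fn))

    @property
    def specificity(self) -> Optional[float]:
        """NA (None) when there are no clinical negatives."""
        if self.tn + self.fp == 0:
            return None
        return round_metric(self.tn / (self.tn + self.fp))

    def as_dict(self) -> dict:
        return {
            "predictor": self.predictor,
            "n_evaluated": self.n_evaluated,
            "TP": self.tp,
            "FP": self.fp,
            "TN": self.tn,
            "FN": self.fn,
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
        }


def compute_agreement(r: PredictionRecord) -> bool:
    """True iff the three sequence-based tools make the same binary call."""
    return r.ddig_in == r.sift_indel == r.provean


def _structural_to_binary(call: str, unclear_as: str) -> Optional[bool]:
    if call == "unassessable":
        return None
    if call == "probably":
        return True
    if call == "unlikely":
        return False
    # unclear
    if unclear_as == "positive":
        return True
    if unclear_as == "negative":
        return False
    if unclear_as == "excluded":
        return None
    raise ValueError("unclear_as must be 'positive', 'negative' or 'excluded'")


def evaluate_against_clinical(
    records: Sequence[PredictionRecord], unclear_as: str = "positive"
) -> dict[str, EvaluationResult]:
    """Per-predictor confusion-matrix statistics against the clinical call.

    Clinical "probably" counts as positive, "unlikely" as negative and
    "possibly" is excluded throughout.  Structural "unassessable" (and
    "unclear" when ``unclear_as='excluded'``) is excluded for the structural
    predictor only.
    """
    usable = [r for r in records if r.clinical != "possibly"]
    if not usable:
        raise ValueError("no evaluable records after excluding 'possibly' cases")
    out: dict[str, EvaluationResult] = {}
    for predictor in PREDICTORS:
        tp = fp = tn = fn = 0
        for r in usable:
            truth = r.clinical == "probably"
            if predictor == "structural":
                pred = _structural_to_binary(r.structural, unclear_as)
                if pred is None:
                    continue
            else:
                pred = getattr(r, predictor) == "D"
            if pred and truth:
                tp += 1
            elif pred and not truth:
                fp += 1
            elif not pred and truth:
                fn += 1
            else:
                tn += 1
        out[predictor] = EvaluationResult(
            predictor=predictor, n_evaluated=tp + fp + tn + fn,
            tp=tp, fp=fp, tn=tn, fn=fn,
        )
    return out


@dataclass(frozen=True)
class CohortCounts:
    """Count summary for one disease group (or a pooled cohort)."""

    group: str
    probands_tested: int
    probands_with_indel: int
    indels_detected: int
    indels_clinically_reported: int
    indels_modelable: int
    tool_agreement_count: int

    def __post_init__(self) -> None:
        for f in (
            "probands_tested", "probands_with_indel", "indels_detected",
            "indels_clinically_reported", "indels_modelable", "tool_agreement_count",
        ):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be non-negative")
        if self.probands_with_indel > self.probands_tested:
            raise ValueError("probands_with_indel exceeds probands_tested")
        for f in ("indels_clinically_reported", "indels_modelable", "tool_agreement_count"):
            if getattr(self, f) > self.indels_detected:
                raise ValueError(f"{f} exceeds indels_detected")


def summarize_cohort(c: CohortCounts) -> dict:
    """Headline rates for a cohort.

    carrier rate and the per-indel fractions are percentages to 1 decimal;
    the "one reported indel in every N individuals tested" figure is
    probands_tested / indels_clinically_reported rounded to the nearest
    integer.  Zero denominators yield None (NA).
    """

    def pct(num: int, den: int) -> Optional[float]:
        return round_percent(100.0 * num / den) if den else None

    reported_per_tested = (
        int(round(c.probands_tested / c.indels_clinically_reported))
        if c.indels_clinically_reported
        else None
    )
    return {
        "group": c.group,
        "carrier_rate_percent": pct(c.probands_with_indel, c.probands_tested),
        "probands_per_reported_indel": reported_per_tested,
        "modelable_fraction_percent": pct(c.indels_modelable, c.indels_detected),
        "tool_agreement_percent": pct(c.tool_agreement_count, c.indels_detected),
    }
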