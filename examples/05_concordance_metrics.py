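"""Concordance of the predictors with the clinical standard.

Loads the packaged fixture of the eight modelable indels (structural
verdict, clinical call, three tool calls each), excludes the single
'possibly' case, and prints accuracy / sensitivity / specificity per
predictor, plus the pooled cohort rates.
"""

from inframe import (
    CohortCounts,
    PredictionRecord,
    evaluate_against_clinical,
    summarize_cohort,
)
from inframe.synthetic import load_cohort_counts, make_table1_fixture

records = [
    PredictionRecord(
        variant_id=r["variant_id"], ddig_in=r["ddig_in"], sift_indel=r["sift_indel"],
        provean=r["provean"], structural=r["structural"], clinical=r["clinical"],
    )
    for r in make_table1_fixture().to_dict("records")
]
for predictor, res in evaluate_against_clinical(records).items():
    spec = "NA" if res.specificity is None else f"{res.specificity:.2f}"
    print(
        f"{predictor:<11} n={res.n_evaluated}  acc={res.accuracy:.2f}"
        f"  sens={res.sensitivity:.2f}  spec={spec}"
    )

r = load_cohort_counts().set_index("group").loc["combined"]
s = summarize_cohort(
    CohortCounts(
        group="combined", probands_tested=int(r["probands_tested"]),
        probands_with_indel=int(r["probands_with_indel"]),
        indels_detected=int(r["indels_detected"]),
        indels_clinically_reported=int(r["indels_clinically_reported"]),
        indels_modelable=int(r["indels_modelable"]),
        tool_agreement_count=int(r["tool_agreement_count"]),
    )
)
print(
    f"\ncohort: {s['carrier_rate_percent']}% probands carry an in-frame indel; "
    f"1 clinically reported indel per {s['probands_per_reported_indel']} tested; "
    f"{s['modelable_fraction_percent']}% of indels modelable; "
    f"{s['tool_agreement_percent']}% three-tool agreement"
)
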