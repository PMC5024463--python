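"""Generate a synthetic cohort and run the annotation stages end to end.

Writes a seeded cohort (genome, transcripts, VCF, truth table) to a
temporary directory, annotates it through the library pipeline, and
compares the recovered frame and context calls with the generator's truth.
"""

import tempfile
from pathlib import Path

import pandas as pd

from inframe import CohortSpec, generate_cohort
from inframe.pipeline import annotate_variants

outdir = Path(tempfile.mkdtemp(prefix="inframe-demo-"))
bundle = generate_cohort(CohortSpec(seed=1))
paths = bundle.write(outdir)
print(f"wrote cohort to {outdir} ({len(bundle.truth)} planted indels)")

annot = annotate_variants(paths["vcf"], paths["transcripts"], paths["genome"])
merged = annot.merge(
    bundle.truth[["variant_id", "frame_status", "context_label", "filter_fate"]],
    on="variant_id", suffixes=("", "_truth"),
)
frame_ok = (merged["frame_status"] == merged["frame_status_truth"]).mean()
ctx_ok = (merged["context_label"] == merged["context_label_truth"]).mean()
filt_ok = (merged["filter_outcome"] == merged["filter_fate"]).mean()
print(f"frame recovery:   {100 * frame_ok:.1f}%")
print(f"context recovery: {100 * ctx_ok:.1f}%")
print(f"filter agreement: {100 * filt_ok:.1f}%")
print(annot["context_label"].value_counts().to_string())

# All three recovery rates are 100% by construction: the generator verifies
# every planted variant against the library's own detectors before
# emitting it, so any regression in the annotation stack shows up here.
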