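"""End-to-end orchestration: annotate -> context -> template -> structure ->
evaluate, with per-stage entry points and deterministic file outputs.

Each stage is an ordinary function over in-memory objects so it can be used
from Python; :func:`run_pipeline` wires them together from a declarative
config and writes one CSV/JSON artifact per stage.  Reruns with identical
inputs and seed produce byte-identical CSV/JSON (timestamps only in the log).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__
from .evaluation import (
    CohortCounts,
    PredictionRecord,
    compute_agreement,
    evaluate_against_clinical,
    summarize_cohort,
)
from .io import (
    load_genome,
    load_transcripts,
    read_fasta,
    read_prediction_table,
    read_vcf,
    reference_window,
)
from .mechanism import Unassessable, annotate_structure, classify_mechanism
from .repeats import classify_variant_context
from .structure import parse_structure
from .templates import align_and_score, map_residue_to_template, select_template, window_identity
from .variants import (
    CodingIndel,
    FilterThresholds,
    NormalizationError,
    ProjectionKind,
    compute_protein_change,
    normalize_indel,
    project_and_classify_frame,
)

logger = logging.getLogger("inframe")

__all__ = ["PipelineConfig", "StageError", "run_pipeline", "annotate_variants",
           "search_templates", "assess_structures", "evaluate_predictions"]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and record id."""

    def __init__(self, stage: str, record: str, message: str):
        super().__init__(f"[{stage}] {record}: {message}")
        self.stage = stage
        self.record = record


@dataclass
class PipelineConfig:
    vcf: Path
    transcripts: Path
    genome: Path
    output_dir: Path
    template_fasta: Optional[Path] = None
    template_pdb_dir: Optional[Path] = None
    tool_calls: Optional[Path] = None
    clinical: Optional[Path] = None
    cohort_counts: Optional[Path] = None
    thresholds: FilterThresholds = field(default_factory=FilterThresholds)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ValueError(f"config {path} is not a mapping")
        th = FilterThresholds(**raw.pop("thresholds", {}))
        paths = {
            k: Path(v)
            for k, v in raw.items()
            if k in (
                "vcf", "transcripts", "genome", "output_dir", "template_fasta",
                "template_pdb_dir", "tool_calls", "clinical", "cohort_counts",
            )
        }
        seed = int(raw.get("seed", 0))
        cfg = cls(thresholds=th, seed=seed, **paths)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for name in ("vcf", "transcripts", "genome"):
            p = getattr(self, name)
            if p is None or not Path(p).exists():
                raise ValueError(f"config path '{name}' missing or does not exist: {p}")
        for name in (
            "template_fasta", "template_pdb_dir", "tool_calls", "clinical", "cohort_counts"
        ):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise ValueError(f"config path '{name}' does not exist: {p}")


# ---------------------------------------------------------------------------
# stage 1+2: annotation and sequence context
# ---------------------------------------------------------------------------

def annotate_variants(
    vcf_path: Path, transcripts_path: Path, genome_path: Path,
    th: FilterThresholds = FilterThresholds(),
) -> pd.DataFrame:
    """Normalize, project, classify and context-label every VCF variant
    against every transcript on its chromosome."""
    genome = load_genome(genome_path)
    transcripts = load_transcripts(transcripts_path, genome)
    by_chrom: dict[str, list] = {}
    for t in transcripts:
        by_chrom.setdefault(t.chromosome, []).append(t)

    rows: list[dict] = []
    for v in read_vcf(vcf_path):
        window = reference_window(genome, v.chromosome, v.position, len(v.ref_allele))
        try:
            vn = normalize_indel(v, window)
        except NormalizationError as exc:
            raise StageError("annotate", v.variant_id, str(exc)) from exc
        window = reference_window(genome, vn.chromosome, vn.position, len(vn.ref_allele))
        try:
            ctx = classify_variant_context(vn, window)
            ctx_label, ctx_unit = ctx.label, ctx.repeat_unit or ctx.homopolymer_base or ""
            ctx_copies, ctx_run = ctx.reference_copy_count, ctx.homopolymer_run_length
        except ValueError:
            ctx_label, ctx_unit, ctx_copies, ctx_run = "unknown", "", 0, 0

        for t in by_chrom.get(vn.chromosome, []) or [None]:
            if t is None:
                rows.append(_row(vn, None, None, ctx_label, ctx_unit, ctx_copies, ctx_run, "no_transcript"))
                continue
            ci = project_and_classify_frame(vn, t, th)
            if ci.kind is ProjectionKind.CODING and ci.is_in_frame:
                ci = compute_protein_change(ci, t)
            from .variants import apply_filters

            kept, discarded = apply_filters([ci], th)
            fate = "kept" if kept else discarded[0][1]
            rows.append(_row(vn, t, ci, ctx_label, ctx_unit, ctx_copies, ctx_run, fate))
    df = pd.DataFrame.from_records(rows)
    if not df.empty:
        df = df.sort_values(["chromosome", "position", "transcript_id"]).reset_index(drop=True)
    return df


def _row(v, t, ci: Optional[CodingIndel], label, unit, copies, run, fate) -> dict:
    base = {
        "variant_id": v.variant_id,
        "chromosome": v.chromosome,
        "position": v.position,
        "ref": v.ref_allele,
        "alt": v.alt_allele,
        "support_fraction": v.support_fraction,
        "population_af": v.population_af,
        "transcript_id": t.transcript_id if t else "",
        "context_label": label,
        "repeat_unit": unit,
        "copy_count": copies,
        "run_length": run,
        "filter_outcome": fate,
    }
    if ci is None:
        base.update(kind="no_transcript", frame_status="", hgvs_c="", hgvs_p="")
        return base
    base.update(
        kind=ci.kind.value,
        cds_start=ci.cds_start,
        cds_end=ci.cds_end,
        net_length_change=ci.net_length_change,
        frame_status=ci.frame_status or "",
        hgvs_c=ci.hgvs_c or "",
        hgvs_p=ci.hgvs_p or "",
        affected_residue_start=ci.affected_residue_start,
        affected_residue_end=ci.affected_residue_end,
        n_affected_residues=ci.n_affected_residues,
        splice_proximal=ci.splice_proximal,
        in_scope=ci.in_scope,
    )
    return base


# ---------------------------------------------------------------------------
# stage 3: template search
# ---------------------------------------------------------------------------

def search_templates(
    annot: pd.DataFrame, transcripts_path: Path, genome_path: Path,
    template_fasta: Path,
) -> pd.DataFrame:
    """Align each candidate protein against the template library and apply
    the significance and variant-window rules."""
    genome = load_genome(genome_path)
    transcripts = {t.transcript_id: t for t in load_transcripts(transcripts_path, genome)}
    library = read_fasta(template_fasta)
    library_size = sum(len(s) for s in library.values())

    mask = (
        (annot.get("kind") == "coding")
        & (annot.get("frame_status") == "in_frame")
        & (annot.get("filter_outcome") == "kept")
        & annot.get("affected_residue_start").notna()
    )
    rows = []
    align_cache: dict[tuple[str, str], object] = {}
    for _, rec in annot[mask].iterrows():
        t = transcripts[rec["transcript_id"]]
        target = t.protein_sequence
        hits = []
        for tid, seq in sorted(library.items()):
            key = (rec["transcript_id"], tid)
            if key not in align_cache:
                align_cache[key] = align_and_score(target, seq, library_size, template_id=tid)
            hit = window_identity(
                align_cache[key],
                int(rec["affected_residue_start"]),
                int(rec["affected_residue_end"]),
            )
            hits.append(hit)
            rows.append(
                {
                    "variant_id": rec["variant_id"],
                    "transcript_id": rec["transcript_id"],
                    "template_id": hit.template_id,
                    "raw_score": hit.raw_score,
                    "bit_score": round(hit.bit_score, 2),
                    "e_value": float(f"{hit.e_value:.3e}"),
                    "global_identity": round(hit.global_identity, 3),
                    "window_identity_count": hit.window_identity_count,
                    "window_length": hit.window_length,
                    "passes_window": hit.passes_window,
                    "selected": False,
                }
            )
        chosen = select_template(hits)
        if chosen is not None:
            for r in rows[::-1]:
                if r["variant_id"] == rec["variant_id"] and r["template_id"] == chosen.template_id:
                    r["selected"] = True
                    break
    return pd.DataFrame.from_records(rows)


# ---------------------------------------------------------------------------
# stage 4: structural assessment
# ---------------------------------------------------------------------------

def assess_structures(
    annot: pd.DataFrame, hits: pd.DataFrame, transcripts_path: Path,
    genome_path: Path, template_fasta: Path, template_pdb_dir: Path,
) -> pd.DataFrame:
    """Map affected residues onto selected templates and classify the
    disruption mechanism; variants without a usable template are reported
    unassessable."""
    genome = load_genome(genome_path)
    transcripts = {t.transcript_id: t for t in load_transcripts(transcripts_path, genome)}
    library = read_fasta(template_fasta)
    library_size = sum(len(s) for s in library.values())

    structure_cache: dict[str, object] = {}
    annotation_cache: dict[str, dict] = {}

    mask = (
        (annot.get("kind") == "coding")
        & (annot.get("frame_status") == "in_frame")
        & (annot.get("filter_outcome") == "kept")
        & annot.get("affected_residue_start").notna()
    )
    selected = hits[hits["selected"]] if not hits.empty else hits
    rows = []
    for _, rec in annot[mask].iterrows():
        vid = rec["variant_id"]
        sel = selected[selected["variant_id"] == vid] if not selected.empty else selected
        if sel.empty:
            rows.append(
                {
                    "variant_id": vid, "template_id": "", "category": "unassessable",
                    "mechanisms": "", "evidence": json.dumps({"reason": "no usable template"}),
                }
            )
            continue
        template_id = sel.iloc[0]["template_id"]
        pdb_name = template_id.rsplit("_", 1)[0]
        pdb_path = Path(template_pdb_dir) / f"{pdb_name}.pdb"
        if pdb_name not in structure_cache:
            try:
                structure_cache[pdb_name] = parse_structure(pdb_path.read_text())
                annotation_cache[pdb_name] = annotate_structure(structure_cache[pdb_name])
            except (OSError, ValueError) as exc:
                raise StageError("structure", vid, f"template {pdb_name}: {exc}") from exc
        structure = structure_cache[pdb_name]
        annotations = annotation_cache[pdb_name]

        t = transcripts[rec["transcript_id"]]
        hit = window_identity(
            align_and_score(t.protein_sequence, library[template_id], library_size, template_id),
            int(rec["affected_residue_start"]), int(rec["affected_residue_end"]),
        )
        rmap = map_residue_to_template(hit, structure)
        chain_id = template_id.rsplit("_", 1)[-1]
        chain = structure.get_chain(chain_id)
        pos_of_seqnum = {r.seq_num: i for i, r in enumerate(chain.residues)}
        affected_keys = []
        start, end = int(rec["affected_residue_start"]), int(rec["affected_residue_end"])
        for target_idx in range(start, end + 1):
            ident = rmap.lookup(target_idx)
            if ident is not None:
                affected_keys.append((ident[0], pos_of_seqnum[ident[1]]))
        n_res = int(rec.get("n_affected_residues") or (end - start + 1))
        verdict = classify_mechanism(affected_keys, annotations, n_res)
        if isinstance(verdict, Unassessable):
            rows.append(
                {
                    "variant_id": vid, "template_id": template_id,
                    "category": "unassessable", "mechanisms": "",
                    "evidence": json.dumps({"reason": verdict.reason}),
                }
            )
        else:
            rows.append(
                {
                    "variant_id": vid, "template_id": template_id,
                    "category": verdict.category,
                    "mechanisms": ";".join(verdict.mechanisms),
                    "evidence": json.dumps(verdict.evidence, sort_keys=True),
                }
            )
    return pd.DataFrame.from_records(rows)


# ---------------------------------------------------------------------------
# stage 5: evaluation
# ---------------------------------------------------------------------------

def evaluate_predictions(
    verdicts: pd.DataFrame, tool_calls_path: Path, clinical_path: Path,
    unclear_as: str = "positive",
) -> dict:
    tools = read_prediction_table(tool_calls_path).set_index("variant_id")
    clinical = read_prediction_table(clinical_path).set_index("variant_id")
    structural = (
        verdicts.set_index("variant_id")["category"] if not verdicts.empty else pd.Series(dtype=str)
    )
    records = []
    for vid in clinical.index:
        if vid not in tools.index:
            continue
        records.append(
            PredictionRecord(
                variant_id=vid,
                ddig_in=tools.loc[vid, "ddig_in"],
                sift_indel=tools.loc[vid, "sift_indel"],
                provean=tools.loc[vid, "provean"],
                structural=structural.get(vid, "unassessable"),
                clinical=clinical.loc[vid, "clinical"],
            )
        )
    results = evaluate_against_clinical(records, unclear_as=unclear_as)
    agreement = [compute_agreement(r) for r in records]
    return {
        "n_records": len(records),
        "tool_agreement_fraction": (
            round(sum(agreement) / len(agreement), 3) if records else None
        ),
        "metrics": {k: v.as_dict() for k, v in sorted(results.items())},
        "unclear_mapping": unclear_as,
    }


def summarize_counts(cohort_counts_path: Path) -> list[dict]:
    df = pd.read_csv(cohort_counts_path)
    out = []
    for _, r in df.iterrows():
        c = CohortCounts(
            group=r["group"],
            probands_tested=int(r["probands_tested"]),
            probands_with_indel=int(r["probands_with_indel"]),
            indels_detected=int(r["indels_detected"]),
            indels_clinically_reported=int(r["indels_clinically_reported"]),
            indels_modelable=int(r["indels_modelable"]),
            tool_agreement_count=int(r["tool_agreement_count"]),
        )
        out.append(summarize_cohort(c))
    return out


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------

def _write_json(path: Path, payload) -> None:
    path.write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")


def run_pipeline(cfg: PipelineConfig) -> dict[str, Path]:
    """Run every configured stage; returns the paths of the artifacts."""
    cfg.validate()
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    artifacts: dict[str, Path] = {}
    try:
        logger.info(
            "inframe %s seed=%s thresholds=%s", __version__, cfg.seed, asdict(cfg.thresholds)
        )
        annot = annotate_variants(cfg.vcf, cfg.transcripts, cfg.genome, cfg.thresholds)
        annot.to_csv(out / "variants.csv", index=False)
        artifacts["variants"] = out / "variants.csv"
        logger.info("annotated %d variant x transcript records", len(annot))

        if cfg.template_fasta is not None:
            hits = search_templates(annot, cfg.transcripts, cfg.genome, cfg.template_fasta)
            hits.to_csv(out / "template_hits.csv", index=False)
            artifacts["template_hits"] = out / "template_hits.csv"
            logger.info("template search: %d hit rows", len(hits))
            if cfg.template_pdb_dir is not None:
                verdicts = assess_structures(
                    annot, hits, cfg.transcripts, cfg.genome,
                    cfg.template_fasta, cfg.template_pdb_dir,
                )
                verdicts.to_csv(out / "verdicts.csv", index=False)
                artifacts["verdicts"] = out / "verdicts.csv"
                logger.info("verdicts: %s", verdicts["category"].value_counts().to_dict() if not verdicts.empty else {})
                if cfg.tool_calls is not None and cfg.clinical is not None:
                    metrics = evaluate_predictions(verdicts, cfg.tool_calls, cfg.clinical)
                    _write_json(out / "metrics.json", metrics)
                    artifacts["metrics"] = out / "metrics.json"
        if cfg.cohort_counts is not None:
            _write_json(out / "cohort_summary.json", summarize_counts(cfg.cohort_counts))
            artifacts["cohort_summary"] = out / "cohort_summary.json"
        logger.info("pipeline complete")
    finally:
        logger.removeHandler(handler)
        handler.close()
    return artifacts
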