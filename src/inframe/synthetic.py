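"""Seeded synthetic inputs: cohorts of planted indels and demo bundles.

The cohort generator emulates the output of a gene-panel indel-calling
pipeline: synthetic multi-exon genes on their own contigs, a VCF of small
(<= 21 nt) insertions/deletions planted at a configurable in-frame /
frameshift ratio, with configurable fractions placed inside homopolymer
runs and tandem repeats, per-variant read-support fractions and population
allele frequencies, and a truth table recording every planted property.
Planted contexts are verified by re-detection at generation time, so the
truth table is guaranteed consistent with the library's own definitions.

All randomness flows from a single integer seed through one generator
stream; identical seeds give byte-identical output files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .geometry import GeometrySpec, build_geometry
from .repeats import classify_variant_context
from .variants import (
    FilterThresholds,
    RawVariant,
    ReferenceWindow,
    TranscriptModel,
    apply_filters,
    normalize_indel,
    project_and_classify_frame,
)

__all__ = [
    "CohortSpec",
    "CohortBundle",
    "generate_cohort",
    "make_table1_fixture",
    "load_cohort_counts",
    "generate_structural_demo",
]

_STOPS = {"TAA", "TAG", "TGA"}
_SAFE_CODONS = [
    c
    for c in (a + b + d for a in "ACGT" for b in "ACGT" for d in "ACGT")
    if c not in _STOPS
]


@dataclass(frozen=True)
class CohortSpec:
    """Study-condition knobs for the synthetic cohort.

    Defaults mirror the study scale: 667 probands and 55 indel sites with
    63.6 % of variants in a tandem-repeat context.  The in-frame fraction
    (0.5) and homopolymer fraction (0.2) are generator choices documented in
    the methods note.  ``seed`` is mandatory.
    """

    seed: int
    n_probands: int = 667
    n_genes: int = 8
    indel_count: int = 55
    in_frame_fraction: float = 0.5
    hr_fraction: float = 0.2
    tr_fraction: float = 0.636
    in_frame_sizes: dict = field(
        default_factory=lambda: {3: 0.55, 6: 0.20, 9: 0.10, 12: 0.05, 15: 0.04, 18: 0.03, 21: 0.03}
    )
    frameshift_sizes: dict = field(
        default_factory=lambda: {1: 0.40, 2: 0.30, 4: 0.20, 5: 0.10}
    )
    low_support_fraction: float = 0.08
    benign_af_fraction: float = 0.05
    minus_strand_fraction: float = 0.25
    cds_codons: int = 500

    def __post_init__(self) -> None:
        for name in (
            "in_frame_fraction", "hr_fraction", "tr_fraction",
            "low_support_fraction", "benign_af_fraction", "minus_strand_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.hr_fraction > self.tr_fraction:
            raise ValueError(
                "hr_fraction cannot exceed tr_fraction: homopolymer runs are "
                "1-mer tandem repeats and are counted inside the TR fraction"
            )
        if self.n_genes < 1 or self.indel_count < 0 or self.n_probands < 1:
            raise ValueError("counts must be positive")


@dataclass
class CohortBundle:
    genome_fasta: str
    transcripts_json: str
    vcf: str
    truth: pd.DataFrame
    transcripts: list[TranscriptModel]

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genome": outdir / "genome.fasta",
            "transcripts": outdir / "transcripts.json",
            "vcf": outdir / "cohort.vcf",
            "truth": outdir / "truth.csv",
        }
        paths["genome"].write_text(self.genome_fasta)
        paths["transcripts"].write_text(self.transcripts_json)
        paths["vcf"].write_text(self.vcf)
        self.truth.to_csv(paths["truth"], index=False)
        return paths


# ---------------------------------------------------------------------------
# gene models
# ---------------------------------------------------------------------------

def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    idx = rng.integers(0, len(_SAFE_CODONS), size=n_codons - 2)
    body = "".join(_SAFE_CODONS[i] for i in idx)
    stop = ["TAA", "TAG", "TGA"][int(rng.integers(3))]
    return "ATG" + body + stop


def _make_gene(
    rng: np.random.Generator, name: str, chromosome: str, minus: bool, n_codons: int
) -> tuple[str, TranscriptModel]:
    """One 3-exon gene on its own contig; returns (contig sequence, model)."""
    cds = _random_cds(rng, n_codons)
    L = len(cds)
    cut1, cut2 = L // 3, 2 * L // 3
    pieces = [cds[:cut1], cds[cut1:cut2], cds[cut2:]]
    if minus:
        pieces = [str(Seq(p).reverse_complement()) for p in reversed(pieces)]
    flank = 200
    intron_len = 150
    parts: list[str] = []
    intervals: list[tuple[int, int]] = []
    cursor = 1

    def rand_seq(n: int) -> str:
        return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))

    parts.append(rand_seq(flank))
    cursor += flank
    for i, p in enumerate(pieces):
        start = cursor
        parts.append(p)
        cursor += len(p)
        intervals.append((start, cursor - 1))
        if i < len(pieces) - 1:
            parts.append(rand_seq(intron_len))
            cursor += intron_len
    parts.append(rand_seq(flank))
    contig = "".join(parts)

    strand = "-" if minus else "+"
    exons = intervals if strand == "+" else list(reversed(intervals))
    model = TranscriptModel(
        transcript_id=name,
        chromosome=chromosome,
        strand=strand,
        exons=tuple(exons),
        cds_intervals=tuple(exons),
        cds_sequence=cds,
    )
    return contig, model


def _refresh_model(model: TranscriptModel, contig: str) -> TranscriptModel:
    """Re-extract the CDS sequence after the contig was edited in place."""
    parts = []
    for s, e in sorted(model.cds_intervals):
        parts.append(contig[s - 1 : e])
    cds = "".join(parts)
    if model.strand == "-":
        cds = str(Seq(cds).reverse_complement())
    return TranscriptModel(
        transcript_id=model.transcript_id,
        chromosome=model.chromosome,
        strand=model.strand,
        exons=model.exons,
        cds_intervals=model.cds_intervals,
        cds_sequence=cds,
    )


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def _sample_sizes(rng, dist: dict, n: int) -> list[int]:
    sizes = sorted(dist)
    probs = np.array([dist[s] for s in sizes], dtype=float)
    probs /= probs.sum()
    return [int(s) for s in rng.choice(sizes, size=n, p=probs)]


def _plant_stop_safe(
    contig: list[str], model: TranscriptModel, g_start: int, replacement: str
) -> bool:
    """Overwrite contig bases, then verify no premature stop appears in the
    gene's CDS reading frame.  Returns False (and reverts) if one does."""
    old = contig[g_start - 1 : g_start - 1 + len(replacement)]
    contig[g_start - 1 : g_start - 1 + len(replacement)] = list(replacement)
    refreshed = _refresh_model(model, "".join(contig))
    cds = refreshed.cds_sequence
    codons = [cds[i : i + 3] for i in range(0, len(cds) - 3, 3)]
    if any(c in _STOPS for c in codons) or not cds.startswith("ATG"):
        contig[g_start - 1 : g_start - 1 + len(replacement)] = old
        return False
    return True


def generate_cohort(spec: CohortSpec) -> CohortBundle:
    """Build a fully specified synthetic cohort from a seed."""
    rng = np.random.default_rng(spec.seed)

    contigs: dict[str, list[str]] = {}
    models: dict[str, TranscriptModel] = {}
    gene_names = [f"GENE{i + 1}" for i in range(spec.n_genes)]
    for i, g in enumerate(gene_names):
        minus = rng.random() < spec.minus_strand_fraction
        contig, model = _make_gene(rng, g, f"chr{i + 1}", minus, spec.cds_codons)
        contigs[g] = list(contig)
        models[g] = model

    n = spec.indel_count
    n_in_frame = int(round(n * spec.in_frame_fraction))
    frames = ["in_frame"] * n_in_frame + ["frameshift"] * (n - n_in_frame)
    n_hr = int(round(n * spec.hr_fraction))
    n_tr_only = int(round(n * (spec.tr_fraction - spec.hr_fraction)))
    contexts = (
        ["HR+TR"] * n_hr + ["TR"] * n_tr_only + ["other"] * (n - n_hr - n_tr_only)
    )
    rng.shuffle(frames)
    rng.shuffle(contexts)
    if_sizes = iter(_sample_sizes(rng, spec.in_frame_sizes, n))
    fs_sizes = iter(_sample_sizes(rng, spec.frameshift_sizes, n))

    # genomic anchor slots: deep inside exons, far enough apart that one
    # variant's planted array never enters a neighbour's +-30 nt flank
    margin, spacing = 55, 100
    slots: list[tuple[str, int]] = []
    for g in gene_names:
        for s, e in sorted(models[g].cds_intervals):
            for anchor in range(s + margin, e - margin - 40, spacing):
                slots.append((g, anchor))
    if len(slots) < n:
        raise ValueError(
            f"spec infeasible: {n} indels need {n} loci but only {len(slots)} "
            f"well-separated CDS slots exist; increase n_genes or cds_codons"
        )
    slot_idx = rng.permutation(len(slots))[:n]

    records: list[dict] = []
    raw_variants: list[RawVariant] = []
    for k in range(n):
        gene, g_anchor = slots[slot_idx[k]]
        model = models[gene]
        frame = frames[k]
        ctx = contexts[k]
        size = next(if_sizes) if frame == "in_frame" else next(fs_sizes)
        planted = _plant_variant(
            rng, contigs[gene], model, g_anchor, frame, ctx, size
        )
        if planted is None:
            raise ValueError(
                f"spec infeasible: could not plant a '{ctx}' {frame} variant of "
                f"size {size} in {gene} near position {g_anchor}"
            )
        v, label_checked, unit = planted
        support = (
            float(rng.uniform(0.02, 0.095))
            if rng.random() < spec.low_support_fraction
            else float(np.clip(rng.beta(20, 20), 0.11, 0.95))
        )
        if rng.random() < spec.benign_af_fraction:
            af = float(rng.uniform(0.012, 0.05))
        elif rng.random() < 0.25:
            af = float(rng.uniform(1e-4, 9e-3))
        else:
            af = 0.0
        v = RawVariant(
            chromosome=v.chromosome, position=v.position,
            ref_allele=v.ref_allele, alt_allele=v.alt_allele,
            support_fraction=round(support, 4), population_af=round(af, 5),
        )
        carriers = 1 + int(rng.poisson(0.8))
        raw_variants.append(v)
        records.append(
            {
                "variant_id": v.variant_id,
                "chromosome": v.chromosome,
                "position": v.position,
                "ref": v.ref_allele,
                "alt": v.alt_allele,
                "gene": gene,
                "strand": model.strand,
                "net_length_change": v.net_length_change,
                "frame_status": frame,
                "context_label": label_checked,
                "planted_unit": unit or "",
                "support_fraction": round(support, 4),
                "population_af": round(af, 5),
                "carriers": carriers,
            }
        )

    # refresh models once all edits are in and compute filter fates
    final_models = {
        g: _refresh_model(models[g], "".join(contigs[g])) for g in gene_names
    }
    th = FilterThresholds()
    fates: list[str] = []
    for rec, v in zip(records, raw_variants):
        ci = project_and_classify_frame(v, final_models[rec["gene"]], th)
        _, discarded = apply_filters([ci], th)
        fates.append(discarded[0][1] if discarded else "kept")
    for rec, fate in zip(records, fates):
        rec["filter_fate"] = fate

    truth = pd.DataFrame.from_records(records)
    genome_fasta = _to_fasta(
        {final_models[g].chromosome: "".join(contigs[g]) for g in gene_names}
    )
    transcripts_json = _transcripts_to_json(
        [final_models[g] for g in gene_names], {g: g for g in gene_names}
    )
    vcf = _to_vcf(raw_variants, records)
    return CohortBundle(
        genome_fasta=genome_fasta,
        transcripts_json=transcripts_json,
        vcf=vcf,
        truth=truth,
        transcripts=[final_models[g] for g in gene_names],
    )


def _plant_variant(
    rng: np.random.Generator,
    contig: list[str],
    model: TranscriptModel,
    g_anchor: int,
    frame: str,
    ctx: str,
    size: int,
    max_tries: int = 150,
):
    """Plant one variant of the requested frame/context at a genomic slot.

    The context is planted by overwriting reference bases (run or repeat
    array) and the variant is expressed as a left-aligned VCF record.
    Returns (variant, verified label, planted unit) or None.
    """
    chromosome = model.chromosome

    for attempt in range(max_tries):
        # context-planting overwrites stay within the slot's protected zone;
        # 'other' variants overwrite nothing so they may roam a little wider
        max_shift = 8 if ctx == "other" else 4
        g = g_anchor + int(rng.integers(0, max_shift)) * 3
        if ctx == "HR+TR":
            base = "CG"[int(rng.integers(2))]
            run_len = max(6, size + 3)
            if not _plant_stop_safe(contig, model, g, base * run_len):
                continue
            # delete `size` bases from inside the run (anchor just before)
            pos = g + int(rng.integers(0, run_len - size))
            ref = "".join(contig[pos - 2 : pos - 1 + size])
            v = RawVariant(chromosome, pos - 1, ref, ref[0])
        elif ctx == "TR":
            if size % 3 == 0:
                unit_len = 3
            elif size % 2 == 0:
                unit_len = 2
            elif size == 1:
                unit_len = 1
            else:
                unit_len = size
            if unit_len == 1:
                # short run (< 6): a tandem repeat of a 1-mer, not yet a
                # homopolymer by the >= 6 rule
                base = "CG"[int(rng.integers(2))]
                run_len = 4
                if not _plant_stop_safe(contig, model, g, base * run_len):
                    continue
                pos = g + int(rng.integers(0, run_len - size))
                ref = "".join(contig[pos - 2 : pos - 1 + size])
                v = RawVariant(chromosome, pos - 1, ref, ref[0])
            else:
                unit = "".join(
                    "ACGT"[i] for i in rng.integers(0, 4, size=unit_len)
                )
                if len(set(unit)) < 2:
                    continue
                copies = max(2, size // unit_len + 1) + 1
                if not _plant_stop_safe(contig, model, g, unit * copies):
                    continue
                ref = "".join(contig[g - 2 : g - 1 + size])
                if rng.random() < 0.7:
                    v = RawVariant(chromosome, g - 1, ref, ref[0])  # deletion
                else:
                    ins = (unit * ((size // unit_len) + 1))[:size]
                    anchor = contig[g - 2]
                    v = RawVariant(chromosome, g - 1, anchor, anchor + ins)
        else:  # other
            pos = g
            if rng.random() < 0.7:
                ref = "".join(contig[pos - 2 : pos - 1 + size])
                v = RawVariant(chromosome, pos - 1, ref, ref[0])
            else:
                ins = "".join("ACGT"[i] for i in rng.integers(0, 4, size=size))
                anchor = contig[pos - 2]
                v = RawVariant(chromosome, pos - 1, anchor, anchor + ins)

        window = ReferenceWindow(
            seq="".join(contig[max(0, v.position - 60) : v.position + len(v.ref_allele) + 60]),
            start=max(1, v.position - 59),
        )
        try:
            v_norm = normalize_indel(v, window)
            context = classify_variant_context(v_norm, window)
        except (ValueError, IndexError):
            continue
        if context.label != ctx:
            # planted context not recovered as intended (e.g. flanking
            # sequence happened to extend a repeat); retry elsewhere
            continue
        unit = (
            context.homopolymer_base
            if ctx == "HR+TR"
            else (context.repeat_unit if ctx == "TR" else None)
        )
        return v_norm, context.label, unit
    return None


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def _to_fasta(seqs: dict[str, str], width: int = 70) -> str:
    lines = []
    for name, seq in seqs.items():
        lines.append(f">{name}")
        for i in range(0, len(seq), width):
            lines.append(seq[i : i + width])
    return "\n".join(lines) + "\n"


def _transcripts_to_json(models: list[TranscriptModel], genes: dict[str, str]) -> str:
    out = []
    for m in models:
        out.append(
            {
                "transcript_id": m.transcript_id,
                "gene": genes.get(m.transcript_id, m.transcript_id),
                "chromosome": m.chromosome,
                "strand": m.strand,
                "exons": [list(x) for x in m.exons],
                "cds": [list(x) for x in m.cds_intervals],
            }
        )
    return json.dumps({"transcripts": out}, indent=1, sort_keys=True) + "\n"


def _to_vcf(variants: list[RawVariant], records: list[dict]) -> str:
    contig_names = sorted(
        {v.chromosome for v in variants},
        key=lambda c: int(c.replace("chr", "")),
    )
    header = [
        "##fileformat=VCFv4.2",
        "##source=inframe-synthetic",
        *[f"##contig=<ID={c}>" for c in contig_names],
        '##INFO=<ID=SUPP,Number=1,Type=Float,Description="Fraction of reads supporting the variant">',
        '##INFO=<ID=AF,Number=A,Type=Float,Description="Population allele frequency">',
        '##INFO=<ID=GENE,Number=1,Type=String,Description="Synthetic gene name">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    body = []
    order = sorted(
        range(len(variants)),
        key=lambda i: (
            int(variants[i].chromosome.replace("chr", "")), variants[i].position
        ),
    )
    for i in order:
        v, rec = variants[i], records[i]
        info = (
            f"SUPP={rec['support_fraction']:.4f};AF={rec['population_af']:.5f};"
            f"GENE={rec['gene']}"
        )
        body.append(
            f"{v.chromosome}\t{v.position}\t.\t{v.ref_allele}\t{v.alt_allele}"
            f"\t.\tPASS\t{info}"
        )
    return "\n".join(header + body) + "\n"


# ---------------------------------------------------------------------------
# packaged fixtures
# ---------------------------------------------------------------------------

def make_table1_fixture() -> pd.DataFrame:
    """The eight modelable in-frame indels with structural verdicts,
    clinical calls and tool-call patterns, as packaged fixture data."""
    with resources.files("inframe.data").joinpath("table1.csv").open() as fh:
        return pd.read_csv(fh)


def load_cohort_counts() -> pd.DataFrame:
    """Packaged per-group and pooled cohort counts."""
    with resources.files("inframe.data").joinpath("cohort_counts.csv").open() as fh:
        return pd.read_csv(fh)


# ---------------------------------------------------------------------------
# structural demo bundle (end-to-end pipeline exercise, no downloads)
# ---------------------------------------------------------------------------

_DEMO_SHEET_A = "MTKVEIRAVDGT"  # strand chain with loop tail appended below
_DEMO_SHEET_B = "MQWESTYFHNKI"
_DEMO_SHEET_C = "MGDFNALTVRQS"
_DEMO_COIL = "MLAELKALADKLNAHLEGKLDALK"  # Leu at heptad a/d positions
_DEMO_DNA = "MSTGNAKRQEYWVDH"  # Arg at residue 8 contacts the DNA phosphate
_DEMO_HAIRPIN = "MKTAYIVSEQWGDNFTRHLAPMSCIG"


def _reverse_translate(protein: str) -> str:
    table = {
        "A": "GCT", "R": "CGT", "N": "AAT", "D": "GAT", "C": "TGT",
        "Q": "CAA", "E": "GAA", "G": "GGT", "H": "CAT", "I": "ATT",
        "L": "CTG", "K": "AAA", "M": "ATG", "F": "TTT", "P": "CCT",
        "S": "TCT", "T": "ACT", "W": "TGG", "Y": "TAT", "V": "GTT",
    }
    return "".join(table[a] for a in protein) + "TAA"


def generate_structural_demo(outdir: str | Path) -> dict[str, Path]:
    """Write a miniature end-to-end dataset: genes whose proteins equal the
    chain sequences of the ideal-geometry templates, a VCF of six in-frame
    deletions probing each structural context, template FASTA/PDB files and
    the matching tool-call and clinical CSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "templates").mkdir(exist_ok=True)

    sheet_pdb = build_geometry(
        GeometrySpec(
            kind="beta_sheet",
            n_residues=12,
            params={"sequences": [_DEMO_SHEET_A, _DEMO_SHEET_B, _DEMO_SHEET_C]},
        )
    )
    coil_pdb = build_geometry(
        GeometrySpec(kind="coiled_coil_dimer", n_residues=24, params={"sequence": _DEMO_COIL})
    )
    dna_pdb = build_geometry(
        GeometrySpec(kind="protein_dna_complex", n_residues=15, params={"sequence": _DEMO_DNA})
    )
    hairpin_pdb = build_geometry(
        GeometrySpec(kind="beta_hairpin", n_residues=8, params={"tail_length": 8, "sequence": _DEMO_HAIRPIN})
    )
    (outdir / "templates" / "SHEET.pdb").write_text(sheet_pdb)
    (outdir / "templates" / "COIL.pdb").write_text(coil_pdb)
    (outdir / "templates" / "DNAC.pdb").write_text(dna_pdb)
    (outdir / "templates" / "HAIRP.pdb").write_text(hairpin_pdb)

    templates_fasta = _to_fasta(
        {
            "SHEET_A": _DEMO_SHEET_A,
            "SHEET_B": _DEMO_SHEET_B,
            "COIL_A": _DEMO_COIL,
            "DNAC_A": _DEMO_DNA,
            "HAIRP_A": _DEMO_HAIRPIN,
        }
    )
    (outdir / "templates.fasta").write_text(templates_fasta)

    # genes: protein == template chain sequence; one deletion per context
    demo_genes = {
        "EDGE1": (_DEMO_SHEET_A, 6),       # edge-strand residue
        "CENT1": (_DEMO_SHEET_B, 6),       # central-strand residue
        "COIL1": (_DEMO_COIL, 12),         # interface helix residue
        "DNAB1": (_DEMO_DNA, 9),           # Arg8 is 1-based residue 9 in seq
        "LOOP1": (_DEMO_HAIRPIN, 10),      # hairpin turn residue
        "TAIL1": (_DEMO_HAIRPIN, 23),      # remote tail residue
    }
    # DNAB1: delete the Arg itself (residue index of R in _DEMO_DNA, 1-based)
    demo_genes["DNAB1"] = (_DEMO_DNA, _DEMO_DNA.index("R") + 1)

    contigs: dict[str, str] = {}
    models = []
    vcf_rows = []
    flank = 120
    for i, (gene, (protein, del_res)) in enumerate(demo_genes.items()):
        cds = _reverse_translate(protein)
        rng = np.random.default_rng(1000 + i)
        left = "".join("ACGT"[j] for j in rng.integers(0, 4, size=flank))
        right = "".join("ACGT"[j] for j in rng.integers(0, 4, size=flank))
        contig = left + cds + right
        chrom = f"demo{i + 1}"
        contigs[chrom] = contig
        model = TranscriptModel(
            transcript_id=gene,
            chromosome=chrom,
            strand="+",
            exons=((flank + 1, flank + len(cds)),),
            cds_intervals=((flank + 1, flank + len(cds)),),
            cds_sequence=cds,
        )
        models.append(model)
        # deletion of codon del_res, left-aligned so that every artifact
        # (VCF, tool calls, clinical labels) shares the normalized id
        g_start = flank + 1 + (del_res - 1) * 3
        ref = contig[g_start - 2 : g_start + 2]  # anchor + 3 deleted bases
        v = normalize_indel(
            RawVariant(chrom, g_start - 1, ref, ref[0]),
            ReferenceWindow(contig, 1),
        )
        vcf_rows.append((chrom, v.position, v.ref_allele, v.alt_allele, gene))

    (outdir / "genome.fasta").write_text(_to_fasta(contigs))
    (outdir / "transcripts.json").write_text(
        _transcripts_to_json(models, {m.transcript_id: m.transcript_id for m in models})
    )
    header = [
        "##fileformat=VCFv4.2",
        "##source=inframe-structural-demo",
        *[f"##contig=<ID={c}>" for c in contigs],
        '##INFO=<ID=GENE,Number=1,Type=String,Description="Synthetic gene name">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    body = [
        f"{c}\t{p}\t.\t{r}\t{a}\t.\tPASS\tGENE={g}" for c, p, r, a, g in vcf_rows
    ]
    (outdir / "cohort.vcf").write_text("\n".join(header + body) + "\n")

    ids = [
        f"{c}:{p}:{r}>{a}" for c, p, r, a, _ in vcf_rows
    ]
    tool_calls = pd.DataFrame(
        {
            "variant_id": ids,
            "ddig_in": ["D", "D", "D", "N", "D", "D"],
            "sift_indel": ["D"] * 6,
            "provean": ["D"] * 6,
        }
    )
    clinical = pd.DataFrame(
        {
            "variant_id": ids,
            "clinical": ["probably", "probably", "probably", "probably", "probably", "unlikely"],
        }
    )
    tool_calls.to_csv(outdir / "tool_calls.csv", index=False)
    clinical.to_csv(outdir / "clinical.csv", index=False)
    load_cohort_counts().to_csv(outdir / "cohort_counts.csv", index=False)

    return {
        "genome": outdir / "genome.fasta",
        "transcripts": outdir / "transcripts.json",
        "vcf": outdir / "cohort.vcf",
        "templates_fasta": outdir / "templates.fasta",
        "template_dir": outdir / "templates",
        "tool_calls": outdir / "tool_calls.csv",
        "clinical": outdir / "clinical.csv",
        "cohort_counts": outdir / "cohort_counts.csv",
    }
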