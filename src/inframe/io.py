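"""Readers and writers for the pipeline's external formats.

VCF is read through cyvcf2 (site-level fields only), transcripts come either
as GFF3 (CDS features, via gffutils) or as the documented JSON dialect::

    {"transcripts": [{"transcript_id": ..., "chromosome": ..., "strand":
     "+", "exons": [[start, end], ...], "cds": [[start, end], ...]}, ...]}

with 1-based inclusive genomic intervals; CDS sequences are extracted from
the genome FASTA (pyfaidx) and strand-corrected.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

from .variants import RawVariant, ReferenceWindow, TranscriptModel

__all__ = [
    "read_vcf",
    "load_genome",
    "load_transcripts_json",
    "load_transcripts_gff3",
    "load_transcripts",
    "read_fasta",
    "reference_window",
    "read_prediction_table",
]


class InputFormatError(ValueError):
    """Malformed input file."""


def load_genome(path: str | Path):
    """Open a FASTA as a random-access genome (pyfaidx)."""
    from pyfaidx import Fasta

    return Fasta(str(path), sequence_always_upper=True)


def reference_window(
    genome, chromosome: str, position: int, ref_len: int, flank: int = 60
) -> ReferenceWindow:
    """A reference slice around a variant with ``flank`` nt on each side."""
    contig = genome[chromosome]
    start = max(1, position - flank)
    end = min(len(contig), position + ref_len - 1 + flank)
    seq = str(contig[start - 1 : end])
    return ReferenceWindow(seq=seq, start=start)


def read_vcf(path: str | Path) -> list[RawVariant]:
    """Site-level variants from a VCF; SUPP/AF INFO fields are optional."""
    from cyvcf2 import VCF

    out: list[RawVariant] = []
    for rec in VCF(str(path)):
        for alt in rec.ALT:
            if alt in (".", "<NON_REF>") or alt.startswith("<"):
                continue
            supp = rec.INFO.get("SUPP")
            af = rec.INFO.get("AF")
            out.append(
                RawVariant(
                    chromosome=rec.CHROM,
                    position=rec.POS,
                    ref_allele=rec.REF,
                    alt_allele=alt,
                    support_fraction=float(supp) if supp is not None else None,
                    population_af=float(af) if af is not None else None,
                )
            )
    return out


def _extract_cds(genome, chromosome: str, strand: str, cds) -> str:
    parts = [str(genome[chromosome][s - 1 : e]) for s, e in sorted(map(tuple, cds))]
    seq = "".join(parts)
    return str(Seq(seq).reverse_complement()) if strand == "-" else seq


def load_transcripts_json(path: str | Path, genome) -> list[TranscriptModel]:
    try:
        payload = json.loads(Path(path).read_text())
        entries = payload["transcripts"]
    except (json.JSONDecodeError, KeyError) as exc:
        raise InputFormatError(f"bad transcript JSON {path}: {exc}") from exc
    models = []
    for e in entries:
        strand = e["strand"]
        exons = [tuple(x) for x in e["exons"]]
        cds = [tuple(x) for x in e["cds"]]
        if strand == "-":
            exons = sorted(exons, reverse=True)
            cds = sorted(cds, reverse=True)
        else:
            exons = sorted(exons)
            cds = sorted(cds)
        models.append(
            TranscriptModel(
                transcript_id=e["transcript_id"],
                chromosome=e["chromosome"],
                strand=strand,
                exons=tuple(exons),
                cds_intervals=tuple(cds),
                cds_sequence=_extract_cds(genome, e["chromosome"], strand, cds),
            )
        )
    return models


def load_transcripts_gff3(path: str | Path, genome) -> list[TranscriptModel]:
    """Transcript models from GFF3 CDS/exon features grouped by Parent."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    models = []
    for t in db.features_of_type(("mRNA", "transcript")):
        exons = [(f.start, f.end) for f in db.children(t, featuretype="exon")]
        cds = [(f.start, f.end) for f in db.children(t, featuretype="CDS")]
        if not cds:
            continue
        if not exons:
            exons = list(cds)
        strand = t.strand if t.strand in "+-" else "+"
        exons = sorted(exons, reverse=(strand == "-"))
        cds = sorted(cds, reverse=(strand == "-"))
        models.append(
            TranscriptModel(
                transcript_id=t.id,
                chromosome=t.seqid,
                strand=strand,
                exons=tuple(exons),
                cds_intervals=tuple(cds),
                cds_sequence=_extract_cds(genome, t.seqid, strand, cds),
            )
        )
    return models


def load_transcripts(path: str | Path, genome) -> list[TranscriptModel]:
    path = Path(path)
    if path.suffix.lower() == ".json":
        return load_transcripts_json(path, genome)
    return load_transcripts_gff3(path, genome)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Plain id -> sequence mapping (template libraries etc.)."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def read_prediction_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "variant_id" not in df.columns:
        raise InputFormatError(f"{path}: missing 'variant_id' column")
    return df
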