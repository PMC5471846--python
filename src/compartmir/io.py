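"""File formats: FASTA (Biopython), count TSVs, PAS BED, truth JSON.

PAS records are written BED-style with the transcript id as the chromosome
and half-open [start, end) coordinates around the 1-based cleavage
position; the score column carries the read support.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .normalize import CountTable
from .targeting import MiRNA
from .utr import PASRecord, TranscriptModel

__all__ = [
    "write_transcripts_fasta",
    "read_fasta",
    "write_mirnas_fasta",
    "read_mirnas_fasta",
    "write_counts",
    "read_counts",
    "write_pas_bed",
    "read_pas_bed",
    "write_transcript_table",
    "write_dataset",
]


def write_transcripts_fasta(transcripts: Sequence[TranscriptModel], path) -> None:
    records = [
        SeqRecord(
            Seq(t.sequence),
            id=t.id,
            description=f"gene={t.gene_id} cds={t.cds_start}-{t.cds_end}",
        )
        for t in transcripts
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    """id -> sequence for any FASTA file."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_mirnas_fasta(mirnas: Sequence[MiRNA], path) -> None:
    records = [SeqRecord(Seq(m.sequence), id=m.id, description="") for m in mirnas]
    SeqIO.write(records, str(path), "fasta")


def read_mirnas_fasta(path) -> list[MiRNA]:
    return [
        MiRNA(id=rec.id, sequence=str(rec.seq))
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_counts(table: CountTable, path) -> None:
    table.df.to_csv(path, sep="\t", index_label="id")


def read_counts(path) -> CountTable:
    df = pd.read_csv(path, sep="\t", index_col="id")
    df.index.name = None
    return CountTable(df)


def write_pas_bed(records: Iterable[PASRecord], path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f"{r.transcript_id}\t{r.position - 1}\t{r.position}\tpas\t{r.support}\n")


def read_pas_bed(path) -> list[PASRecord]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            chrom, start, end, _name, score = line.rstrip("\n").split("\t")[:5]
            out.append(PASRecord(chrom, int(end), int(score)))
    return out


def write_transcript_table(transcripts: Sequence[TranscriptModel], path) -> None:
    """Annotated transcript TSV: coordinates, UTR lengths, correction flag."""
    rows = [
        {
            "id": t.id,
            "gene_id": t.gene_id,
            "cds_start": t.cds_start,
            "cds_end": t.cds_end,
            "utr5_len": t.utr5_len,
            "utr3_len": t.utr3_len,
            "utr3_corrected": t.utr3_corrected,
        }
        for t in transcripts
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_dataset(dataset, outdir) -> dict[str, Path]:
    """Write a synthetic dataset bundle to ``outdir``; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "transcripts": outdir / "transcripts.fasta",
        "mirnas": outdir / "mirnas.fasta",
        "counts_mrna": outdir / "counts_mrna.tsv",
        "counts_sncrna": outdir / "counts_sncrna.tsv",
        "pas": outdir / "pas.bed",
        "truth": outdir / "truth.json",
    }
    write_transcripts_fasta(dataset.transcripts, paths["transcripts"])
    write_mirnas_fasta(dataset.mirnas, paths["mirnas"])
    write_counts(dataset.counts_mrna, paths["counts_mrna"])
    write_counts(dataset.counts_sncrna, paths["counts_sncrna"])
    write_pas_bed(dataset.pas, paths["pas"])
    paths["truth"].write_text(dataset.truth.to_json())
    return paths
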