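"""File-format ingestion and emission.

FASTA/FASTQ go through Biopython; tabular files (BLAST outfmt-6 hit tables,
interaction tables, truth manifests, UTR interval tables) through pandas.
All interval columns written by this package are 0-based half-open; BLAST
tabular coordinates are 1-based inclusive and are converted on ingestion by
:mod:`isomirnet.chimera`.
"""

from __future__ import annotations

import os
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import ParseError

#: Column order of BLAST tabular output (-outfmt 6).
OUTFMT6_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]

INTERACTION_COLUMNS = [
    "read_support", "mirna_id", "isomir_seq", "transcript_id",
    "site_start", "site_end", "gap_nt", "evalue", "bitscore",
]

UTR_COLUMNS = ["transcript_id", "utr_start", "utr_end"]


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Read a FASTA file into an ordered {id: sequence} dict (upper-cased)."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(records: dict[str, str] | Iterable[tuple[str, str]], path) -> None:
    items = records.items() if isinstance(records, dict) else records
    seqs = [SeqRecord(Seq(s), id=name, description="") for name, s in items]
    SeqIO.write(seqs, str(path), "fasta")


def read_fastq(path: str | os.PathLike):
    """Yield (read_id, sequence, phred_qualities) tuples from a FASTQ file."""
    for rec in SeqIO.parse(str(path), "fastq"):
        yield rec.id, str(rec.seq).upper(), rec.letter_annotations["phred_quality"]


def write_fastq(reads: Iterable[tuple[str, str, list[int]]], path) -> None:
    records = []
    for read_id, seq, quals in reads:
        rec = SeqRecord(Seq(seq), id=read_id, description="")
        rec.letter_annotations["phred_quality"] = list(quals)
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")


def read_hits(path: str | os.PathLike) -> pd.DataFrame:
    """Read a BLAST outfmt-6 TSV; malformed rows raise naming the line."""
    try:
        df = pd.read_csv(
            path, sep="\t", header=None, names=OUTFMT6_COLUMNS, comment="#",
            dtype={"qseqid": str, "sseqid": str},
        )
    except (pd.errors.ParserError, ValueError) as exc:
        raise ParseError(f"malformed hit table {path}: {exc}") from exc
    for col in ("length", "mismatch", "gapopen", "qstart", "qend", "sstart", "send"):
        bad = pd.to_numeric(df[col], errors="coerce").isna()
        if bad.any():
            line = int(bad.idxmax()) + 1
            raise ParseError(f"malformed hit table {path}: non-numeric {col} at line {line}")
        df[col] = df[col].astype(int)
    return df


def write_hits(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", header=False, index=False, columns=OUTFMT6_COLUMNS)


def read_table(path, columns: list[str] | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if columns is not None:
        missing = [c for c in columns if c not in df.columns]
        if missing:
            raise ParseError(f"{path}: missing required columns {missing}")
    return df


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)
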