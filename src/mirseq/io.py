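"""Shared sequence and table I/O.

FASTA/FASTQ go through Biopython; tables are pandas TSVs whose header
line starts with '#'. All genomic coordinates in data files are 1-based
inclusive; conversion to half-open happens only inside format writers
that require it (GFF3 is itself 1-based inclusive, BED would not be).
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

COMPLEMENT = str.maketrans("ACGTUN", "TGCAAN")


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


def to_dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


def to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def read_fasta(path) -> dict:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(records, path, description=None) -> None:
    """records: iterable of (id, seq) or mapping id->seq."""
    if isinstance(records, dict):
        records = records.items()
    recs = [SeqRecord(Seq(s), id=i, description=description.get(i, "") if description else "")
            for i, s in records]
    with open(path, "w") as fh:
        SeqIO.write(recs, fh, "fasta")


def read_fastq(path):
    """Yield (id, seq, quality-scores list) per record."""
    for rec in SeqIO.parse(str(path), "fastq"):
        yield rec.id, str(rec.seq).upper(), rec.letter_annotations["phred_quality"]


def write_fastq(reads, path) -> None:
    """reads: iterable of (id, seq, qualities as list[int]). Phred+33."""
    with open(path, "w") as fh:
        for rid, seq, quals in reads:
            qstr = "".join(chr(q + 33) for q in quals)
            fh.write(f"@{rid}\n{seq}\n+\n{qstr}\n")


def write_tsv(df: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(map(str, df.columns)) + "\n")
        df.to_csv(fh, sep="\t", header=False, index=False)


def read_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.lstrip("#") for c in df.columns]
    return df


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())
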