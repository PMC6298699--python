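"""File formats: FASTA reference, FASTQ reads, TSV tables, plasmid JSON."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .simdata import PlasmidSpec, encode

__all__ = [
    "write_plasmid",
    "read_plasmid",
    "write_fasta",
    "read_fasta",
    "read_fastq_bases",
    "write_tsv",
    "read_tsv",
]


def write_fasta(name: str, sequence: str, path) -> None:
    rec = SeqRecord(Seq(sequence), id=name, description="circular")
    SeqIO.write([rec], str(path), "fasta")


def read_fasta(path) -> tuple[str, str]:
    rec = next(SeqIO.parse(str(path), "fasta"))
    return rec.id, str(rec.seq).upper()


def write_plasmid(plasmid: PlasmidSpec, fasta_path, json_path=None) -> None:
    """Write the reference FASTA plus a JSON sidecar with the annotations."""
    write_fasta(plasmid.name, plasmid.sequence, fasta_path)
    if json_path is not None:
        with open(json_path, "w") as fh:
            json.dump(plasmid.to_dict(), fh, indent=1)


def read_plasmid(json_path) -> PlasmidSpec:
    with open(json_path) as fh:
        return PlasmidSpec.from_dict(json.load(fh))


def read_fastq_bases(path) -> np.ndarray:
    """Load equal-length FASTQ reads as an ascii uint8 matrix."""
    seqs = [str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fastq")]
    if not seqs:
        return np.empty((0, 0), dtype=np.uint8)
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValueError("reads must all have the same length")
    return np.vstack([encode(s) for s in seqs])


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(Path(path), sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(Path(path), sep="\t")
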