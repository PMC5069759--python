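"""FASTA and TSV input/output with strict round-trip guarantees."""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger(__name__)


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into an ordered {id: sequence} mapping.

    Sequences are normalised to upper case (a note is logged when the input
    was mixed-case); duplicate ids and empty records are errors; RNA (U) is
    rejected — the pipeline is DNA/protein only.
    """
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seq = str(rec.seq)
        if not seq:
            raise ValueError(f"empty FASTA record {rec.id!r} in {path}")
        if seq != seq.upper():
            log.info("normalising mixed-case sequence %s to upper case", rec.id)
            seq = seq.upper()
        if "U" in seq:
            raise ValueError(f"record {rec.id!r} contains U; RNA is not supported")
        records[rec.id] = seq
    return records


def write_fasta(records: dict[str, str], path, width: int = 80) -> None:
    """Write an {id: sequence} mapping as wrapped FASTA."""
    seqs = [SeqRecord(Seq(s), id=name, description="") for name, s in records.items()]
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqs)


def write_table(df: pd.DataFrame, path, stage: str, params: dict | None = None) -> None:
    """Write a TSV with a comment line recording the producing stage."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    param_str = " ".join(f"{k}={v}" for k, v in sorted((params or {}).items()))
    with open(path, "w") as fh:
        fh.write(f"# stage={stage} {param_str}".rstrip() + "\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
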