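"""File I/O: FASTA, narrowPeak/BED, and TSV tables.

Coordinates are 0-based half-open everywhere; narrowPeak summits are
stored as offsets from the interval start (column 10 convention).
"""

from __future__ import annotations

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

NARROWPEAK_COLS = ["chrom", "start", "end", "name", "score", "strand",
                   "signal", "pvalue", "qvalue", "summit"]


def write_fasta(path, seqs: dict):
    recs = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(recs, str(path), "fasta")


def read_fasta(path) -> dict:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_narrowpeak(path, peaks: pd.DataFrame):
    peaks[NARROWPEAK_COLS].to_csv(path, sep="\t", header=False, index=False)


def read_narrowpeak(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, names=NARROWPEAK_COLS)
    bad = df.start > df.start + df.summit
    if bad.any():
        raise ValueError("summit offset must be non-negative")
    return df


def write_tsv(path, df: pd.DataFrame):
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
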