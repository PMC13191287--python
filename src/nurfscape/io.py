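"""Readers and writers for the plain-text formats the pipeline speaks.

Conventions: all genomic intervals are 0-based half-open (BED-style) in
memory and on disk; single-base features (CAGE 5' ends, nucleosome
midpoints) are one-bp BED intervals.  Per-base signal is exchanged as
bedGraph; the toy genome as FASTA.  Tabular measurements (titrations,
arrays, particle tracks, FRAP traces) are CSV with documented headers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]

__all__ = [
    "BED6_COLUMNS",
    "CoverageTrack",
    "read_bed",
    "write_bed",
    "read_bedgraph",
    "write_bedgraph",
    "read_fasta",
    "write_fasta",
]


@dataclass
class CoverageTrack:
    """Per-base signal over ``[start, start + len(values))`` of one chromosome."""

    chrom: str
    start: int
    values: np.ndarray
    strand: str = "."

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("CoverageTrack values must be one-dimensional")
        if np.any(self.values < 0):
            raise ValueError("coverage values must be non-negative")

    @property
    def end(self) -> int:
        return self.start + len(self.values)

    def total(self) -> float:
        return float(self.values.sum())

    def slice(self, start: int, end: int) -> np.ndarray:
        """Values over genomic [start, end); out-of-track bases read as 0."""
        out = np.zeros(end - start, dtype=float)
        lo = max(start, self.start)
        hi = min(end, self.end)
        if hi > lo:
            out[lo - start : hi - start] = self.values[lo - self.start : hi - self.start]
        return out


def read_bed(path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        names=BED6_COLUMNS,
        dtype={"chrom": str, "start": np.int64, "end": np.int64, "name": str, "strand": str},
    )
    if (df["end"] <= df["start"]).any():
        bad = df[df["end"] <= df["start"]].iloc[0]
        raise ValueError(f"invalid BED interval: {bad['chrom']}:{bad['start']}-{bad['end']}")
    return df


def write_bed(df: pd.DataFrame, path) -> None:
    df.loc[:, BED6_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def write_bedgraph(track: CoverageTrack, path, header: str | None = None) -> None:
    """Run-length-encoded bedGraph; zero runs are omitted."""
    vals = track.values
    # boundaries where the value changes
    change = np.flatnonzero(np.diff(vals) != 0) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [len(vals)]))
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        for s, e in zip(starts, ends):
            v = vals[s]
            if v != 0:
                fh.write(f"{track.chrom}\t{track.start + s}\t{track.start + e}\t{v:g}\n")


def read_bedgraph(path, chrom: str | None = None, span: tuple[int, int] | None = None) -> CoverageTrack:
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#", names=["chrom", "start", "end", "value"]
    )
    if chrom is None:
        chroms = df["chrom"].unique()
        if len(chroms) != 1:
            raise ValueError("bedGraph covers multiple chromosomes; pass chrom=")
        chrom = chroms[0]
    df = df[df["chrom"] == chrom]
    if span is None:
        span = (int(df["start"].min()), int(df["end"].max())) if len(df) else (0, 0)
    start, end = span
    values = np.zeros(end - start, dtype=float)
    for s, e, v in df[["start", "end", "value"]].itertuples(index=False):
        values[max(s, start) - start : min(e, end) - start] = v
    return CoverageTrack(chrom, start, values)


def write_fasta(sequences: dict[str, str], path) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(records, path, "fasta")


def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(path, "fasta")}
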