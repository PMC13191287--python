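"""CAGE TSS calling, expression quantification and promoter classification.

CAGE tags mark capped 5' ends at base resolution.  The pipeline builds a
strand-aware per-base coverage track, defines candidate initiation
intervals as maximal runs of non-zero coverage, keeps intervals holding
more than ``min_reads`` tags (strictly greater), and calls the TSS as the
position of the per-base maximum in each retained interval.  Expression
per TSS is the tag count in a fixed window centred on the called position,
normalized to counts-per-million (CPM), and compared between genotypes as
log2 fold change with a pseudocount.

Promoters are classified two ways: by *initiation shape* — the
interquantile width of the tag distribution around the TSS, focused iff
narrow — and by *core motif* — an ordered IUPAC-consensus scan (DRE,
Ohler box 1, Ohler box 7, TATA, Inr) in class-specific windows relative
to the TSS.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CoverageTrack

__all__ = [
    "five_prime_positions",
    "compute_coverage",
    "call_tss",
    "window_counts",
    "normalize_cpm",
    "expression_log2fc",
    "classify_shape",
    "MotifClass",
    "DEFAULT_MOTIFS",
    "classify_motif",
    "aggregate_class_change",
]

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "[AG]", "Y": "[CT]", "S": "[CG]", "W": "[AT]",
    "K": "[GT]", "M": "[AC]", "B": "[CGT]", "D": "[AGT]",
    "H": "[ACT]", "V": "[ACG]", "N": "[ACGT]",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def iupac_regex(consensus: str) -> re.Pattern:
    return re.compile("".join(_IUPAC[c] for c in consensus.upper()))


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


def five_prime_positions(reads: pd.DataFrame) -> np.ndarray:
    """5' end of each BED6 read: start on '+', end - 1 on '-'."""
    pos = reads["start"].to_numpy(dtype=np.int64, copy=True)
    minus = reads["strand"].to_numpy() == "-"
    pos[minus] = reads["end"].to_numpy(dtype=np.int64)[minus] - 1
    return pos


def compute_coverage(
    reads: pd.DataFrame, chrom_length: int, chrom: str | None = None, strand: str = "."
) -> CoverageTrack:
    """Per-base count of read 5' ends over one chromosome.

    ``strand='+'``/``'-'`` restricts to that strand; ``'.'`` pools both.
    Total track mass equals the number of counted reads.  A read outside
    ``[0, chrom_length)`` raises with the offending record.
    """
    sel = reads
    if chrom is not None:
        sel = sel[sel["chrom"] == chrom]
    if strand in ("+", "-"):
        sel = sel[sel["strand"] == strand]
    pos = five_prime_positions(sel)
    if len(pos) and (pos.min() < 0 or pos.max() >= chrom_length):
        bad = sel.iloc[int(np.argmax((pos < 0) | (pos >= chrom_length)))]
        raise ValueError(f"read outside chromosome bounds: {bad.to_dict()}")
    values = np.bincount(pos, minlength=chrom_length).astype(float)
    return CoverageTrack(chrom or (sel["chrom"].iloc[0] if len(sel) else "chr"), 0, values, strand)


def call_tss(track: CoverageTrack, min_reads: int = 10) -> pd.DataFrame:
    """Call TSSs from a strand-specific coverage track.

    Maximal runs of consecutive non-zero bases form candidate intervals;
    intervals whose total tag count is strictly greater than ``min_reads``
    are retained, and the TSS is the position of the per-base maximum in
    the interval.  Ties at the maximum resolve to the 5'-most position on
    the track's strand (left-most on '+', right-most on '-').

    Returns a DataFrame with one row per retained interval:
    ``chrom, pos, strand, peak_height, interval_start, interval_end,
    interval_total`` (0-based half-open interval bounds).
    """
    columns = [
        "chrom", "pos", "strand", "peak_height",
        "interval_start", "interval_end", "interval_total",
    ]
    vals = track.values
    nonzero = vals > 0
    if not nonzero.any():
        return pd.DataFrame(columns=columns)
    boundaries = np.diff(nonzero.astype(np.int8))
    run_starts = np.flatnonzero(boundaries == 1) + 1
    run_ends = np.flatnonzero(boundaries == -1) + 1
    if nonzero[0]:
        run_starts = np.concatenate(([0], run_starts))
    if nonzero[-1]:
        run_ends = np.concatenate((run_ends, [len(vals)]))
    rows = []
    for s, e in zip(run_starts, run_ends):
        seg = vals[s:e]
        total = seg.sum()
        if not total > min_reads:
            continue
        if track.strand == "-":
            peak_idx = e - 1 - int(np.argmax(seg[::-1]))
        else:
            peak_idx = s + int(np.argmax(seg))
        rows.append(
            {
                "chrom": track.chrom,
                "pos": track.start + peak_idx,
                "strand": track.strand,
                "peak_height": float(vals[peak_idx]),
                "interval_start": track.start + int(s),
                "interval_end": track.start + int(e),
                "interval_total": float(total),
            }
        )
    return pd.DataFrame(rows, columns=columns)


def window_counts_batch(
    reads: pd.DataFrame,
    positions,
    strand: str,
    window: int = 150,
    chrom: str | None = None,
) -> np.ndarray:
    """Tag counts in ``[pos - window/2, pos + window/2)`` for many TSSs at once.

    The window is a total width centred on each TSS (must be even so the
    half-open bounds are integral); only tags on ``strand`` count unless
    ``strand='.'``.  Implemented with one sort plus binary searches, so
    quantifying thousands of TSSs against a large tag set is cheap.
    """
    if window % 2:
        raise ValueError("window width must be even")
    sel = reads
    if chrom is not None:
        sel = sel[sel["chrom"] == chrom]
    if strand in ("+", "-"):
        sel = sel[sel["strand"] == strand]
    p = np.sort(five_prime_positions(sel))
    positions = np.asarray(positions, dtype=int)
    half = window // 2
    lo = np.searchsorted(p, positions - half, side="left")
    hi = np.searchsorted(p, positions + half, side="left")
    return (hi - lo).astype(int)


def window_counts(
    reads: pd.DataFrame, pos: int, strand: str, window: int = 150, chrom: str | None = None
) -> int:
    """Tags whose 5' end falls in ``[pos - window/2, pos + window/2)`` on ``strand``."""
    return int(window_counts_batch(reads, [pos], strand, window, chrom)[0])


def normalize_cpm(count: float, library_total: float) -> float:
    """Counts-per-million normalization."""
    if library_total <= 0:
        raise ValueError("library total must be positive")
    return count * 1e6 / library_total


def expression_log2fc(cpm_wt: float, cpm_mut: float, pseudocount: float = 0.5) -> float:
    """log2((mut + p)/(wt + p)); antisymmetric under genotype swap."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    return float(np.log2((cpm_mut + pseudocount) / (cpm_wt + pseudocount)))


def classify_shape(
    track: CoverageTrack,
    pos: int,
    flank: int = 100,
    iq_low: float = 0.10,
    iq_high: float = 0.90,
    width_max: int = 15,
) -> tuple[str, int]:
    """Initiation-shape call from the tag distribution around one TSS.

    Computes the interquantile width: the smallest base span around the TSS
    (within +/- ``flank``) containing the cumulative tag-count fraction
    (``iq_low``, ``iq_high``].  Width <= ``width_max`` bp is *focused*,
    otherwise *dispersed*; zero tags in the flank yield ``("unclassifiable",
    0)``.  Returns ``(shape, width)``.  Invariant to uniform scaling of the
    tag counts.
    """
    if flank < width_max:
        raise ValueError("flank must be at least width_max")
    seg = track.slice(pos - flank, pos + flank + 1)
    total = seg.sum()
    if total <= 0:
        return "unclassifiable", 0
    cum = np.cumsum(seg)
    lo_idx = int(np.searchsorted(cum, iq_low * total, side="right"))
    hi_idx = int(np.searchsorted(cum, iq_high * total, side="left"))
    width = hi_idx - lo_idx + 1
    return ("focused" if width <= width_max else "dispersed"), width


@dataclass(frozen=True)
class MotifClass:
    """One core-promoter motif: IUPAC consensus and TSS-relative search window.

    The window ``(lo, hi)`` is in promoter-strand coordinates (negative =
    upstream of the TSS); a match anywhere whose start lies in the window
    counts.  Precedence between classes is the order they are scanned.
    """

    name: str
    consensus: str
    window: tuple[int, int]


DEFAULT_MOTIFS: tuple[MotifClass, ...] = (
    MotifClass("DRE", "TATCGATA", (-100, -20)),
    MotifClass("Ohler1", "YGGTCACACTR", (-80, 0)),
    MotifClass("Ohler7", "CAKCNCTRNY", (-60, 10)),
    MotifClass("TATA", "TATAAA", (-40, -15)),
    MotifClass("Inr", "TCAGTY", (-10, 10)),
)


def _oriented_window(seq: str, pos: int, strand: str, lo: int, hi: int) -> str:
    """Promoter-strand sequence covering TSS offsets [lo, hi] inclusive."""
    if strand == "-":
        start, end = pos - hi, pos - lo + 1
        return reverse_complement(seq[max(start, 0) : max(end, 0)])
    start, end = pos + lo, pos + hi + 1
    return seq[max(start, 0) : max(end, 0)].upper()


def classify_motif(
    seq: str, pos: int, strand: str, motifs: tuple[MotifClass, ...] = DEFAULT_MOTIFS
) -> str:
    """First motif class (by scan order) whose consensus matches near the TSS.

    Strand-aware: on '-' promoters the reverse-complement window is scanned.
    Returns the class name, or ``"none"``.
    """
    for motif in motifs:
        lo, hi = motif.window
        # extend so a match *starting* anywhere in [lo, hi] fits entirely
        window_seq = _oriented_window(seq, pos, strand, lo, hi + len(motif.consensus) - 1)
        if iupac_regex(motif.consensus).search(window_seq):
            return motif.name
    return "none"


def aggregate_class_change(
    records: pd.DataFrame, class_key: str = "motif"
) -> pd.DataFrame:
    """Per-class mean percent expression change between genotypes.

    ``records`` needs ``cpm_wt``, ``cpm_mut`` and the grouping column.
    Percent change per TSS is ``(cpm_mut / cpm_wt - 1) * 100`` (rows with
    zero WT CPM are dropped from the ratio summary); classes with no
    usable rows are omitted.  Returns one row per class with ``n``,
    ``mean_pct_change``, ``median_pct_change`` and ``sd_pct_change``.
    """
    import warnings

    needed = {class_key, "cpm_wt", "cpm_mut"}
    if not needed.issubset(records.columns):
        raise ValueError(f"records need columns {sorted(needed)}")
    rows = []
    for cls, grp in records.groupby(class_key, sort=True):
        usable = grp[grp["cpm_wt"] > 0]
        if usable.empty:
            warnings.warn(f"class {cls!r} has no usable records; omitted", stacklevel=2)
            continue
        pct = (usable["cpm_mut"] / usable["cpm_wt"] - 1.0) * 100.0
        rows.append(
            {
                class_key: cls,
                "n": len(usable),
                "mean_pct_change": float(pct.mean()),
                "median_pct_change": float(pct.median()),
                "sd_pct_change": float(pct.std(ddof=1)) if len(usable) > 1 else 0.0,
            }
        )
    return pd.DataFrame(rows)
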