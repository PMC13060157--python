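"""Per-transcript concordance of two 5'-end tracks around annotated TSSs.

For each transcript a window of 2*flank+1 positions centered on the TSS is
extracted from both tracks, read 5'->3' relative to the transcript strand.
Pearson's R is computed at single-nucleotide resolution and on 5-nt sliding
window sums, and windows where either track falls below an RPKM floor are
dropped, matching the upstream filtering of low-expressed transcripts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from annotaudit.fiveprime import FivePrimeTrack, GenomicInterval, TranscriptModel


@dataclass
class TSSWindow:
    transcript_ids: List[str]
    window: GenomicInterval
    tss: int
    flank: int

    @property
    def positions_5to3(self) -> range:
        """Genomic positions ordered 5'->3' along the transcript strand."""
        if self.window.strand == "+":
            return range(self.window.start, self.window.end)
        return range(self.window.end - 1, self.window.start - 1, -1)


@dataclass
class ConcordanceRecord:
    transcript_id: str
    counts_a: np.ndarray
    counts_b: np.ndarray
    total_a: float
    total_b: float
    rpkm_a: float
    rpkm_b: float
    r_1nt: float
    r_5nt: float
    valid: bool


def tss_windows(
    models: Sequence[TranscriptModel],
    flank: int = 500,
    chrom_sizes: Optional[Dict[str, int]] = None,
) -> List[TSSWindow]:
    """One strand-aware window per distinct (chrom, strand, tss).

    Isoforms sharing a TSS collapse into a single window carrying all their
    ids. Windows clipped by a contig edge (known from ``chrom_sizes``, or
    by the start<0 check) are excluded.
    """
    if flank <= 0:
        raise ValueError("flank must be positive")
    grouped: Dict[Tuple[str, str, int], List[str]] = {}
    for m in models:
        grouped.setdefault((m.chrom, m.strand, m.tss), []).append(m.transcript_id)
    windows = []
    for (chrom, strand, tss), ids in sorted(grouped.items()):
        start, end = tss - flank, tss + flank + 1
        if start < 0:
            continue
        if chrom_sizes is not None and end > chrom_sizes.get(chrom, math.inf):
            continue
        windows.append(
            TSSWindow(
                transcript_ids=sorted(ids),
                window=GenomicInterval(chrom, start, end, strand),
                tss=tss,
                flank=flank,
            )
        )
    return windows


def pearson_r(x: Sequence[float], y: Sequence[float]) -> Optional[float]:
    """Product-moment correlation; None when either vector has no variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    if x.size < 2:
        raise ValueError("vectors must have length >= 2")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = float(np.sqrt((xc * xc).sum()))
    sy = float(np.sqrt((yc * yc).sum()))
    if sx == 0.0 or sy == 0.0:
        return None
    return float((xc * yc).sum() / (sx * sy))


def sliding_window_sum(x: Sequence[float], k: int = 5) -> np.ndarray:
    """Valid-mode sums of k consecutive elements, step 1."""
    x = np.asarray(x, dtype=float)
    if k < 1:
        raise ValueError("k must be >= 1")
    if x.size < k:
        raise ValueError("vector shorter than window")
    return np.convolve(x, np.ones(k), mode="valid")


def rpkm(total_reads: float, window_length: int, library_size: int) -> float:
    """Reads per kilobase of window per million library reads."""
    if window_length <= 0:
        raise ValueError("window_length must be positive")
    if library_size <= 0:
        raise ValueError("library_size must be positive")
    return total_reads / ((window_length / 1e3) * (library_size / 1e6))


def concordance_table(
    track_a: FivePrimeTrack,
    track_b: FivePrimeTrack,
    models: Sequence[TranscriptModel],
    flank: int = 500,
    k: int = 5,
    min_rpkm: float = 1.0,
    chrom_sizes: Optional[Dict[str, int]] = None,
) -> List[ConcordanceRecord]:
    """Window-level concordance records, RPKM-filtered on both tracks."""
    for name, track in (("a", track_a), ("b", track_b)):
        if track.scale != "raw":
            raise ValueError(f"track_{name} must be raw-scale (library size needed)")
        if track.library_size <= 0:
            raise ValueError(f"track_{name} has zero library size")
    if not models:
        raise ValueError("no models supplied")
    records: List[ConcordanceRecord] = []
    wlen = 2 * flank + 1
    for win in tss_windows(models, flank=flank, chrom_sizes=chrom_sizes):
        chrom, strand = win.window.chrom, win.window.strand
        a = np.array(
            track_a.window_counts(chrom, strand, win.window.start, win.window.end)
        )
        b = np.array(
            track_b.window_counts(chrom, strand, win.window.start, win.window.end)
        )
        if strand == "-":
            a = a[::-1]
            b = b[::-1]
        total_a, total_b = float(a.sum()), float(b.sum())
        rpkm_a = rpkm(total_a, wlen, track_a.library_size)
        rpkm_b = rpkm(total_b, wlen, track_b.library_size)
        if min(rpkm_a, rpkm_b) < min_rpkm:
            continue
        r1 = pearson_r(a, b)
        r5 = (
            pearson_r(sliding_window_sum(a, k), sliding_window_sum(b, k))
            if wlen >= k
            else None
        )
        records.append(
            ConcordanceRecord(
                transcript_id=",".join(win.transcript_ids),
                counts_a=a,
                counts_b=b,
                total_a=total_a,
                total_b=total_b,
                rpkm_a=rpkm_a,
                rpkm_b=rpkm_b,
                r_1nt=math.nan if r1 is None else r1,
                r_5nt=math.nan if r5 is None else r5,
                valid=r1 is not None,
            )
        )
    return records


@dataclass
class ConcordanceSummary:
    bin_edges: np.ndarray
    table: pd.DataFrame  # columns: bin_low, bin_high, n, median_r, q1_r, q3_r


def summarize_by_expression(
    records: Sequence[ConcordanceRecord],
    bins: Optional[Sequence[float]] = None,
    n_bins: int = 4,
    use: str = "r_1nt",
) -> ConcordanceSummary:
    """Median and quartiles of R per expression bin (log10 window totals).

    Expression is the per-record mean of the two window totals; invalid
    records are excluded. Default bin edges are equally spaced in log10
    expression across the observed range.
    """
    valid = [r for r in records if r.valid]
    if not valid:
        raise ValueError("no valid records to summarize")
    expr = np.array([0.5 * (r.total_a + r.total_b) for r in valid])
    rvals = np.array([getattr(r, use) for r in valid])
    log_expr = np.log10(expr + 1.0)
    if bins is None:
        lo, hi = log_expr.min(), log_expr.max()
        if hi <= lo:
            hi = lo + 1e-6
        edges = np.linspace(lo, hi + 1e-9, n_bins + 1)
    else:
        edges = np.asarray(bins, dtype=float)
    rows = []
    for i in range(len(edges) - 1):
        sel = (log_expr >= edges[i]) & (
            log_expr < edges[i + 1] if i < len(edges) - 2 else log_expr <= edges[i + 1]
        )
        rs = rvals[sel]
        rows.append(
            {
                "bin_low": edges[i],
                "bin_high": edges[i + 1],
                "n": int(sel.sum()),
                "median_r": float(np.median(rs)) if rs.size else math.nan,
                "q1_r": float(np.percentile(rs, 25)) if rs.size else math.nan,
                "q3_r": float(np.percentile(rs, 75)) if rs.size else math.nan,
            }
        )
    return ConcordanceSummary(bin_edges=edges, table=pd.DataFrame(rows))


def records_to_frame(records: Sequence[ConcordanceRecord]) -> pd.DataFrame:
    """Scalar fields of each record as a tidy table."""
    return pd.DataFrame(
        [
            {
                "transcript_id": r.transcript_id,
                "total_a": r.total_a,
                "total_b": r.total_b,
                "rpkm_a": r.rpkm_a,
                "rpkm_b": r.rpkm_b,
                "r_1nt": r.r_1nt,
                "r_5nt": r.r_5nt,
                "valid": r.valid,
            }
            for r in records
        ]
    )
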