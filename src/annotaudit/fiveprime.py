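"""Strand-specific 5'-end coverage tracks and intron-chain read assignment.

Coordinates are 0-based, half-open everywhere; bedGraph output follows the
same convention. Tracks store one count per genomic base, keyed by
``(chrom, strand)``, where strand is the strand of the aligned read (reads
are assumed sense-oriented upstream).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Optional, Sequence, Tuple

import pandas as pd

STRANDS = ("+", "-")


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class Alignment:
    """A spliced alignment reduced to its aligned reference blocks.

    ``blocks`` are sorted, non-overlapping reference segments; gaps between
    consecutive blocks are introns and define ``intron_chain`` as ordered
    (donor, acceptor) = (gap start, gap end) pairs in genomic coordinates.
    """

    read_id: str
    chrom: str
    strand: str
    blocks: List[Tuple[int, int]]
    is_primary: bool = True

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValueError(f"alignment {self.read_id}: empty blocks")
        for (s, e) in self.blocks:
            if not 0 <= s < e:
                raise ValueError(f"alignment {self.read_id}: bad block {(s, e)}")
        for (_, e0), (s1, _) in zip(self.blocks, self.blocks[1:]):
            if s1 < e0:
                raise ValueError(
                    f"alignment {self.read_id}: blocks overlap or unsorted"
                )

    @property
    def intron_chain(self) -> Tuple[Tuple[int, int], ...]:
        return tuple(
            (e0, s1) for (_, e0), (s1, _) in zip(self.blocks, self.blocks[1:])
            if s1 > e0
        )

    @property
    def span(self) -> Tuple[int, int]:
        return self.blocks[0][0], self.blocks[-1][1]

    def five_prime_position(self) -> int:
        """Genomic base of the read's 5'-most aligned position."""
        if self.strand == "+":
            return self.blocks[0][0]
        return self.blocks[-1][1] - 1


@dataclass
class FivePrimeTrack:
    """Sparse per-base 5'-end counts keyed by (chrom, strand)."""

    counts: Dict[Tuple[str, str], Dict[int, float]] = field(default_factory=dict)
    library_size: int = 0
    scale: str = "raw"

    def add(self, chrom: str, strand: str, pos: int, n: float = 1.0) -> None:
        key = (chrom, strand)
        per = self.counts.setdefault(key, {})
        per[pos] = per.get(pos, 0.0) + n

    def get(self, chrom: str, strand: str, pos: int) -> float:
        return self.counts.get((chrom, strand), {}).get(pos, 0.0)

    def total(self) -> float:
        return sum(v for per in self.counts.values() for v in per.values())

    def window_counts(
        self, chrom: str, strand: str, start: int, end: int
    ) -> List[float]:
        per = self.counts.get((chrom, strand), {})
        return [per.get(p, 0.0) for p in range(start, end)]


def alignments_from_bam(
    path: str, *, primary_only: bool = True
) -> Iterator[Alignment]:
    """Stream Alignments from a BAM/SAM file (mapped reads only)."""
    import pysam

    mode = "rb" if str(path).endswith(".bam") else "r"
    with pysam.AlignmentFile(path, mode) as fh:
        for rec in fh:
            if rec.is_unmapped:
                continue
            if primary_only and (rec.is_secondary or rec.is_supplementary):
                continue
            yield Alignment(
                read_id=rec.query_name,
                chrom=rec.reference_name,
                strand="-" if rec.is_reverse else "+",
                blocks=_blocks_from_cigar(rec.reference_start, rec.cigartuples),
                is_primary=not (rec.is_secondary or rec.is_supplementary),
            )


# CIGAR ops that consume the reference: M=0, D=2, N=3, =7, X=8.
# Blocks split only on N (introns); deletions stay inside a block.
def _blocks_from_cigar(
    ref_start: int, cigartuples: Sequence[Tuple[int, int]]
) -> List[Tuple[int, int]]:
    blocks: List[Tuple[int, int]] = []
    pos = ref_start
    block_start: Optional[int] = None
    for op, length in cigartuples:
        if op in (0, 7, 8, 2):
            if block_start is None:
                block_start = pos
            pos += length
        elif op == 3:
            if block_start is not None:
                blocks.append((block_start, pos))
                block_start = None
            pos += length
    if block_start is not None:
        blocks.append((block_start, pos))
    return blocks


def five_prime_ends(
    alignments: Iterable[Alignment], *, primary_only: bool = True
) -> FivePrimeTrack:
    """Count each retained alignment's 5'-most genomic base.

    Order-independent: the resulting track is identical for any permutation
    of the input. ``library_size`` equals the number of retained alignments.
    """
    track = FivePrimeTrack(scale="raw")
    for aln in alignments:
        if primary_only and not aln.is_primary:
            continue
        track.add(aln.chrom, aln.strand, aln.five_prime_position())
        track.library_size += 1
    return track


def to_rpm(track: FivePrimeTrack) -> FivePrimeTrack:
    """Scale a raw track to reads-per-million of its own library size."""
    if track.scale != "raw":
        raise ValueError("track is already RPM-scaled")
    if track.library_size <= 0:
        raise ValueError("library_size must be positive to scale to RPM")
    factor = 1e6 / track.library_size
    scaled = FivePrimeTrack(
        counts={
            key: {pos: n * factor for pos, n in per.items()}
            for key, per in track.counts.items()
        },
        library_size=track.library_size,
        scale="RPM",
    )
    return scaled


@dataclass
class TranscriptModel:
    """Exon structure of one annotated transcript."""

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: List[Tuple[int, int]]

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: no exons")
        self.exons = sorted(self.exons)
        for (_, e0), (s1, _) in zip(self.exons, self.exons[1:]):
            if s1 < e0:
                raise ValueError(f"{self.transcript_id}: exons overlap")

    @property
    def tss(self) -> int:
        if self.strand == "+":
            return self.exons[0][0]
        return self.exons[-1][1] - 1

    @property
    def intron_chain(self) -> Tuple[Tuple[int, int], ...]:
        return tuple(
            (e0, s1) for (_, e0), (s1, _) in zip(self.exons, self.exons[1:])
            if s1 > e0
        )

    @property
    def span(self) -> Tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]


def _chain_compatible(
    read_chain: Tuple[Tuple[int, int], ...],
    model_chain: Tuple[Tuple[int, int], ...],
    tol: int,
) -> bool:
    """True iff read introns form a contiguous sub-chain of the model's,
    each junction matching within +-tol at both ends."""
    n, m = len(read_chain), len(model_chain)
    if n > m:
        return False
    for offset in range(m - n + 1):
        ok = True
        for (rd, ra), (md, ma) in zip(read_chain, model_chain[offset:offset + n]):
            if abs(rd - md) > tol or abs(ra - ma) > tol:
                ok = False
                break
        if ok:
            return True
    return False


def _assign_one(
    aln: Alignment, models: Sequence[TranscriptModel], tol: int
) -> List[str]:
    hits: List[str] = []
    rs, re = aln.span
    chain = aln.intron_chain
    for model in models:
        if model.chrom != aln.chrom or model.strand != aln.strand:
            continue
        ms, me = model.span
        if rs < ms - tol or re > me + tol:
            continue
        if chain:
            if _chain_compatible(chain, model.intron_chain, tol):
                hits.append(model.transcript_id)
        else:
            # Mono-exonic read: contained in span and overlapping no intron.
            if any(rs < ia and re > id_ for (id_, ia) in model.intron_chain):
                continue
            hits.append(model.transcript_id)
    return hits


def assign_to_models(
    alignments: Iterable[Alignment],
    models: Sequence[TranscriptModel],
    junction_tolerance: int = 0,
) -> pd.DataFrame:
    """Assign reads to transcript models by intron-chain compatibility.

    A read compatible with k models contributes 1/k to each. Returns a
    DataFrame with one row per model plus an ``__unassigned__`` row, columns
    ``model``, ``count``, ``percent`` (percent of assigned reads; NaN for
    the unassigned row).
    """
    counts: Dict[str, float] = {m.transcript_id: 0.0 for m in models}
    n_unassigned = 0
    n_reads = 0
    for aln in alignments:
        n_reads += 1
        hits = _assign_one(aln, models, junction_tolerance)
        if not hits:
            n_unassigned += 1
            continue
        w = 1.0 / len(hits)
        for tid in hits:
            counts[tid] += w
    assigned_total = n_reads - n_unassigned
    rows = []
    for m in models:
        c = counts[m.transcript_id]
        pct = 100.0 * c / assigned_total if assigned_total > 0 else math.nan
        rows.append({"model": m.transcript_id, "count": c, "percent": pct})
    rows.append(
        {"model": "__unassigned__", "count": float(n_unassigned), "percent": math.nan}
    )
    return pd.DataFrame(rows)


def write_bedgraph(track: FivePrimeTrack, prefix: str) -> Tuple[str, str]:
    """Write one 4-column bedGraph per strand: <prefix>.fwd/.rev.bedgraph."""
    paths = {}
    for strand, tag in (("+", "fwd"), ("-", "rev")):
        path = f"{prefix}.{tag}.bedgraph"
        with open(path, "w") as fh:
            items: List[Tuple[str, int, float]] = []
            for (chrom, st), per in track.counts.items():
                if st != strand:
                    continue
                items.extend((chrom, pos, n) for pos, n in per.items())
            for chrom, pos, n in sorted(items):
                val = f"{n:.6g}" if track.scale == "RPM" else f"{n:g}"
                fh.write(f"{chrom}\t{pos}\t{pos + 1}\t{val}\n")
        paths[tag] = path
    return paths["fwd"], paths["rev"]


def read_bedgraph_pair(
    fwd_path: str, rev_path: str, library_size: int, scale: str = "raw"
) -> FivePrimeTrack:
    """Load a strand pair of bedGraph files into a FivePrimeTrack."""
    track = FivePrimeTrack(library_size=library_size, scale=scale)
    for path, strand in ((fwd_path, "+"), (rev_path, "-")):
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("track", "#")):
                    continue
                chrom, start, end, value = line.split("\t")
                start_i, end_i, v = int(start), int(end), float(value)
                for pos in range(start_i, end_i):
                    track.add(chrom, strand, pos, v)
    return track


def track_from_positions(
    positions: Iterable[Tuple[str, str, int]]
) -> FivePrimeTrack:
    """Build a raw track directly from (chrom, strand, 5'-position) triples."""
    track = FivePrimeTrack(scale="raw")
    for chrom, strand, pos in positions:
        track.add(chrom, strand, pos)
        track.library_size += 1
    return track
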