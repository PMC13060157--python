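"""Full-length read selection, TSO trimming, and sense orientation.

A read is kept iff the template-switching oligo (TSO) is found, with errors
allowed, at its 5' end (sense) or its reverse complement at its 3' end
(antisense); antisense reads are reverse complemented before the TSO is
trimmed. Reads without a TSO are discarded; reads matching in both
orientations are treated as chimeric and discarded separately.

Matching model
--------------
Semi-global edit distance (substitutions and indels), anchored to the
relevant read end: the full adapter may match any span inside the first
``search_window`` nt, or an adapter suffix of length >= ``min_overlap`` may
run off the read 5' end (span anchored at position 0). A candidate is
accepted when its edit distance is <= floor(max_error_rate x matched
adapter length); the best candidate minimizes (edit distance, span start,
span end, -matched length). Antisense matching applies the same procedure
to the reverse complement of the read. N bases never match.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from typing import Iterable, Iterator, List, Optional, Tuple

import numpy as np

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


@dataclass
class AdapterSpec:
    """Parameters of TSO and polyA recognition."""

    tso_sequence: str = "CAATGAAGTCGCAGGGTTGGG"
    min_overlap: int = 15
    max_error_rate: float = 0.1
    polya_min_run: int = 8
    polya_max_mismatches: int = 1
    search_window: int = 100  # nt from the relevant read end scanned for the TSO

    def __post_init__(self) -> None:
        if len(self.tso_sequence) < self.min_overlap:
            raise ValueError("tso_sequence shorter than min_overlap")
        if not 0 <= self.max_error_rate < 0.5:
            raise ValueError("max_error_rate must be in [0, 0.5)")


@dataclass
class RawRead:
    id: str
    sequence: str
    qualities: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"read {self.id}: empty sequence")
        if set(self.sequence.upper()) - set("ACGTN"):
            raise ValueError(f"read {self.id}: invalid alphabet")


@dataclass
class TsoMatch:
    orientation: str  # "sense" | "antisense" | "none"
    span: Optional[Tuple[int, int]] = None  # read coordinates, half-open
    edit_distance: Optional[int] = None
    matched_length: Optional[int] = None


@dataclass
class OrientedRead:
    id: str
    sense_sequence: str
    was_reverse_complemented: bool
    tso_match: TsoMatch
    polya_site: Optional[int] = None
    qualities: Optional[str] = None


@dataclass
class ReadPrepReport:
    n_input: int = 0
    n_kept: int = 0
    n_discarded_no_tso: int = 0
    n_discarded_chimera: int = 0
    n_reverse_complemented: int = 0
    n_polya_detected: int = 0

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def _dp_last_row(pattern: str, seq: str, free_start: bool) -> "np.ndarray":
    """Last DP row of edit distance of ``pattern`` vs every end in ``seq``.

    ``free_start`` allows the span to start anywhere at no cost (semi-global
    pattern search); otherwise the span is anchored at position 0. N never
    matches anything.
    """
    n = len(seq)
    s_arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    idx = np.arange(n + 1, dtype=np.int32)
    prev = np.zeros(n + 1, dtype=np.int32) if free_start else idx.copy()
    n_byte = ord("N")
    for i, ch in enumerate(pattern, start=1):
        cb = ord(ch)
        cost = ((s_arr != cb) | (s_arr == n_byte) | (cb == n_byte)).astype(np.int32)
        t = np.empty(n + 1, dtype=np.int32)
        t[0] = i
        if n:
            t[1:] = np.minimum(prev[:-1] + cost, prev[1:] + 1)
        # resolve the left (insertion) dependency in one accumulate pass
        prev = np.minimum.accumulate(t - idx) + idx
    return prev


def _lev(a: str, b: str) -> int:
    """Plain global edit distance (N never matches)."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, start=1):
        cur = [i]
        for j, cb in enumerate(b, start=1):
            cost = 0 if (ca == cb and ca != "N" and cb != "N") else 1
            cur.append(min(prev[j - 1] + cost, prev[j] + 1, cur[j - 1] + 1))
        prev = cur
    return prev[-1]


def best_five_prime_match(
    seq: str, spec: AdapterSpec
) -> Optional[Tuple[int, int, int, int]]:
    """Best accepted TSO match near the 5' end of ``seq``.

    Returns (edit_distance, start, end, matched_length) or None. Candidates
    are ordered by (distance, start, end, -matched_length); start is the
    smallest span start achieving the candidate's distance for its end.
    """
    adapter = spec.tso_sequence
    L = len(adapter)
    window = seq[: min(len(seq), spec.search_window)]
    candidates: List[Tuple[int, int, int, int]] = []
    max_d_full = int(spec.max_error_rate * L)
    row = _dp_last_row(adapter, window, free_start=True)
    for e in range(1, len(window) + 1):
        d = int(row[e])
        if d > max_d_full:
            continue
        start = None
        for s in range(max(0, e - L - d), e):
            if _lev(adapter, window[s:e]) == d:
                start = s
                break
        if start is not None:
            candidates.append((d, start, e, -L))
    for k in range(1, L - spec.min_overlap + 1):
        matched = L - k
        max_d = int(spec.max_error_rate * matched)
        prefix_region = window[: matched + max_d]
        dists = _dp_last_row(adapter[k:], prefix_region, free_start=False)
        for e in range(1, len(prefix_region) + 1):
            if int(dists[e]) <= max_d:
                candidates.append((int(dists[e]), 0, e, -matched))
    if not candidates:
        return None
    d, s, e, neg = min(candidates)
    return d, s, e, -neg


def locate_tso(read: RawRead, spec: AdapterSpec) -> TsoMatch:
    """Locate the TSO in either orientation; ties favor sense."""
    sense, anti = _match_both(read.sequence, spec)
    if sense is None and anti is None:
        return TsoMatch(orientation="none")
    if anti is None or (sense is not None and sense[0] <= anti[0]):
        d, s, e, m = sense
        return TsoMatch("sense", (s, e), d, m)
    d, s, e, m = anti
    n = len(read.sequence)
    return TsoMatch("antisense", (n - e, n - s), d, m)


def _match_both(seq: str, spec: AdapterSpec):
    sense = best_five_prime_match(seq.upper(), spec)
    anti = best_five_prime_match(revcomp(seq.upper()), spec)
    return sense, anti


@dataclass
class PolyARun:
    start: int
    length: int
    n_mismatches: int


def detect_polya(
    seq: str, spec: AdapterSpec, end: str = "3prime", base: str = "A"
) -> Optional[PolyARun]:
    """Find the terminal homopolymer run (polyA at 3', or polyT at 5').

    Searches the terminal 50 nt for the 3'-most run of >= ``polya_min_run``
    bases with <= ``polya_max_mismatches`` non-matching positions; run
    endpoints must be the target base. Returns coordinates in ``seq``.
    """
    if not seq:
        raise ValueError("empty sequence")
    seq = seq.upper()
    n = len(seq)
    if end == "3prime":
        lo = max(0, n - 50)
        region = seq[lo:]
    elif end == "5prime":
        lo = 0
        region = seq[:50]
    else:
        raise ValueError(f"invalid end {end!r}")
    m = len(region)
    mm = [0] * (m + 1)  # prefix counts of non-base positions
    for i, c in enumerate(region):
        mm[i + 1] = mm[i] + (0 if c == base else 1)
    best: Optional[Tuple[int, int]] = None
    if end == "3prime":
        # 3'-most run end, then longest (smallest start)
        for j in range(m, 0, -1):
            if region[j - 1] != base:
                continue
            for i in range(0, j - spec.polya_min_run + 1):
                if region[i] != base:
                    continue
                if mm[j] - mm[i] <= spec.polya_max_mismatches:
                    best = (i, j)
                    break
            if best is not None:
                break
    else:
        # 5'-most run start, then longest (largest end)
        for i in range(0, m - spec.polya_min_run + 1):
            if region[i] != base:
                continue
            for j in range(m, i + spec.polya_min_run - 1, -1):
                if region[j - 1] != base:
                    continue
                if mm[j] - mm[i] <= spec.polya_max_mismatches:
                    best = (i, j)
                    break
            if best is not None:
                break
    if best is None:
        return None
    i, j = best
    return PolyARun(start=lo + i, length=j - i, n_mismatches=mm[j] - mm[i])


def select_full_length(
    reads: Iterable[RawRead], spec: Optional[AdapterSpec] = None
) -> Tuple[List[OrientedRead], ReadPrepReport]:
    """Select TSO-bearing reads, orient them to the sense strand, trim the
    TSO, and annotate the polyA site."""
    spec = spec or AdapterSpec()
    report = ReadPrepReport()
    kept: List[OrientedRead] = []
    for read in reads:
        report.n_input += 1
        seq = read.sequence.upper()
        sense, anti = _match_both(seq, spec)
        if sense is None and anti is None:
            report.n_discarded_no_tso += 1
            continue
        if sense is not None and anti is not None:
            report.n_discarded_chimera += 1
            continue
        if sense is not None:
            d, s, e, mlen = sense
            sense_seq = seq[e:]
            quals = read.qualities[e:] if read.qualities else None
            was_rc = False
            match = TsoMatch("sense", (s, e), d, mlen)
        else:
            d, s, e, mlen = anti
            rc = revcomp(seq)
            sense_seq = rc[e:]
            quals = read.qualities[::-1][e:] if read.qualities else None
            was_rc = True
            n = len(seq)
            match = TsoMatch("antisense", (n - e, n - s), d, mlen)
            report.n_reverse_complemented += 1
        if not sense_seq:
            report.n_discarded_no_tso += 1
            continue
        run = detect_polya(sense_seq, spec, end="3prime", base="A")
        if run is not None:
            report.n_polya_detected += 1
        kept.append(
            OrientedRead(
                id=read.id,
                sense_sequence=sense_seq,
                was_reverse_complemented=was_rc,
                tso_match=match,
                polya_site=run.start if run is not None else None,
                qualities=quals,
            )
        )
        report.n_kept += 1
    return kept, report


def read_fastx(path: str) -> Iterator[RawRead]:
    """Read FASTA or FASTQ (optionally gzipped) into RawReads."""
    from Bio import SeqIO

    opener = gzip.open if str(path).endswith(".gz") else open
    name = str(path)[:-3] if str(path).endswith(".gz") else str(path)
    fmt = "fastq" if name.endswith((".fastq", ".fq")) else "fasta"
    with opener(path, "rt") as fh:
        for rec in SeqIO.parse(fh, fmt):
            quals = None
            if "phred_quality" in rec.letter_annotations:
                quals = "".join(
                    chr(q + 33) for q in rec.letter_annotations["phred_quality"]
                )
            yield RawRead(id=rec.id, sequence=str(rec.seq).upper(), qualities=quals)


def write_fastq(reads: Iterable[OrientedRead], path: str) -> None:
    with open(path, "w") as fh:
        for r in reads:
            quals = r.qualities or "I" * len(r.sense_sequence)
            fh.write(f"@{r.id}\n{r.sense_sequence}\n+\n{quals}\n")
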