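"""Seed-deterministic generators for every input the pipeline consumes.

All generators take an explicit seed and produce identical output on rerun:
full-length cDNA reads with a truth table, multinomial 5'-end tracks,
spot-bearing fluorescence images over a nucleus mask, and qPCR CT tables
log2-linked to known abundances.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from annotaudit.fiveprime import FivePrimeTrack, TranscriptModel
from annotaudit.readprep import revcomp

DEFAULT_TSO = "CAATGAAGTCGCAGGGTTGGG"
DEFAULT_RT_PRIMER = "GTACTCTGCGTTGATACCAC"


@dataclass
class TssProfile:
    """Per-transcript distribution of transcription start positions.

    ``weights`` maps 0-based genomic positions to probability mass (sums to
    1). ``tx_end`` is the transcript's 3' boundary: half-open end on '+'
    (body = genome[tss:tx_end]) and the 3'-most base on '-' (body =
    revcomp(genome[tx_end:tss+1])). When absent, the chromosome edge is used.
    """

    transcript_id: str
    chrom: str
    strand: str
    weights: Dict[int, float]
    tx_end: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.weights:
            raise ValueError(f"{self.transcript_id}: empty weights")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.transcript_id}: bad strand")
        total = sum(self.weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"{self.transcript_id}: weights sum to {total}")

    def positions_and_probs(self) -> Tuple[np.ndarray, np.ndarray]:
        pos = np.array(sorted(self.weights), dtype=np.int64)
        p = np.array([self.weights[int(x)] for x in pos], dtype=float)
        return pos, p / p.sum()


@dataclass
class ReadSimConfig:
    n_reads: int = 1000
    truncation_fraction: float = 0.0
    truncation_geom_p: float = 0.02  # geometric shift, truncated at body length
    antisense_fraction: float = 0.0
    adapterless_fraction: float = 0.0
    polya_length: int = 30
    tso_sequence: str = DEFAULT_TSO
    rt_primer: str = DEFAULT_RT_PRIMER
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("truncation_fraction", "antisense_fraction", "adapterless_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_reads <= 0:
            raise ValueError("n_reads must be positive")
        if not 0.0 < self.truncation_geom_p <= 1.0:
            raise ValueError("truncation_geom_p must be in (0, 1]")


def _body_bounds(profile: TssProfile, tss: int, chrom_len: int) -> Tuple[int, int]:
    if profile.strand == "+":
        end = profile.tx_end if profile.tx_end is not None else chrom_len
        return tss, end
    start = profile.tx_end if profile.tx_end is not None else 0
    return start, tss + 1


def simulate_reads(
    profiles: Sequence[TssProfile],
    genome: Dict[str, str],
    cfg: ReadSimConfig,
    profile_weights: Optional[Sequence[float]] = None,
    emit_sequences: bool = True,
) -> Tuple[List[Tuple[str, str]], pd.DataFrame]:
    """Simulate full-length cDNA reads plus a per-read truth table.

    Each read is TSO + sense body (sampled TSS to transcript 3' end) +
    polyA + revcomp(rt_primer); with configured probabilities its 5' end is
    shifted 3'-ward by a geometric amount (truncation), the whole read is
    reverse complemented (antisense), or the TSO is omitted (adapterless).
    Reads whose truncation shift reaches the body length are dropped and
    logged. Returns ([(read_id, sequence), ...], truth table); sequences
    are empty strings when ``emit_sequences`` is False.
    """
    if not profiles:
        raise ValueError("empty profile list")
    for prof in profiles:
        if prof.chrom not in genome:
            raise ValueError(f"{prof.transcript_id}: chromosome not in genome")
        chrom_len = len(genome[prof.chrom])
        for pos in prof.weights:
            if not 0 <= pos < chrom_len:
                raise ValueError(f"{prof.transcript_id}: position {pos} off contig")
    rng = np.random.default_rng(cfg.seed)
    if profile_weights is None:
        pw = np.full(len(profiles), 1.0 / len(profiles))
    else:
        pw = np.asarray(profile_weights, dtype=float)
        pw = pw / pw.sum()
    prof_idx = rng.choice(len(profiles), size=cfg.n_reads, p=pw)
    reads: List[Tuple[str, str]] = []
    truth_rows = []
    for i in range(cfg.n_reads):
        prof = profiles[prof_idx[i]]
        pos_arr, p_arr = prof.positions_and_probs()
        tss = int(pos_arr[rng.choice(len(pos_arr), p=p_arr)])
        chrom_seq = genome[prof.chrom]
        b0, b1 = _body_bounds(prof, tss, len(chrom_seq))
        body_len = b1 - b0
        truncated = rng.random() < cfg.truncation_fraction
        shift = int(rng.geometric(cfg.truncation_geom_p)) if truncated else 0
        antisense = rng.random() < cfg.antisense_fraction
        adapterless = rng.random() < cfg.adapterless_fraction
        dropped = truncated and shift >= body_len
        obs_tss = tss
        if truncated and not dropped:
            obs_tss = tss + shift if prof.strand == "+" else tss - shift
        read_id = f"read{i:06d}"
        truth_rows.append(
            {
                "read_id": read_id,
                "transcript_id": prof.transcript_id,
                "chrom": prof.chrom,
                "strand": prof.strand,
                "true_tss": tss,
                "obs_tss": obs_tss if not dropped else -1,
                "truncated": truncated,
                "shift": shift,
                "antisense": antisense,
                "adapterless": adapterless,
                "dropped": dropped,
            }
        )
        if dropped:
            continue
        if emit_sequences:
            if prof.strand == "+":
                body = chrom_seq[obs_tss:b1]
            else:
                body = revcomp(chrom_seq[b0:obs_tss + 1])
            seq = (
                ("" if adapterless else cfg.tso_sequence)
                + body
                + "A" * cfg.polya_length
                + revcomp(cfg.rt_primer)
            )
            if antisense:
                seq = revcomp(seq)
        else:
            seq = ""
        reads.append((read_id, seq))
    truth = pd.DataFrame(truth_rows)
    return reads, truth


def simulate_cage_track(profile: TssProfile, n: int, seed: int = 0) -> FivePrimeTrack:
    """Multinomial sample of n 5'-end counts over one profile's weights."""
    return simulate_track([profile], n, seed=seed)


def simulate_track(
    profiles: Sequence[TssProfile],
    n: int,
    seed: int = 0,
    profile_weights: Optional[Sequence[float]] = None,
    truncation_fraction: float = 0.0,
    truncation_geom_p: float = 0.02,
) -> FivePrimeTrack:
    """Multinomial 5'-end track over several profiles at raw scale.

    Each end picks a profile (uniform or ``profile_weights``), then a TSS
    from its weights; with probability ``truncation_fraction`` the end is
    shifted 3'-ward by a geometric(``truncation_geom_p``) amount — the same
    contamination process simulate_reads applies to read 5' ends.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not profiles:
        raise ValueError("empty profile list")
    rng = np.random.default_rng(seed)
    if profile_weights is None:
        pw = np.full(len(profiles), 1.0 / len(profiles))
    else:
        pw = np.asarray(profile_weights, dtype=float)
        pw = pw / pw.sum()
    per_profile = rng.multinomial(n, pw)
    track = FivePrimeTrack(scale="raw")
    for prof, n_prof in zip(profiles, per_profile):
        if n_prof == 0:
            continue
        pos_arr, p_arr = prof.positions_and_probs()
        counts = rng.multinomial(n_prof, p_arr)
        for pos, c in zip(pos_arr, counts):
            if c == 0:
                continue
            if truncation_fraction > 0.0:
                n_trunc = rng.binomial(c, truncation_fraction)
                sign = 1 if prof.strand == "+" else -1
                for _ in range(n_trunc):
                    shift = int(rng.geometric(truncation_geom_p))
                    track.add(prof.chrom, prof.strand, max(0, int(pos) + sign * shift))
                if c - n_trunc:
                    track.add(prof.chrom, prof.strand, int(pos), float(c - n_trunc))
            else:
                track.add(prof.chrom, prof.strand, int(pos), float(c))
    track.library_size = n
    return track


def make_transcriptome(
    n_transcripts: int = 100,
    seed: int = 0,
    body_length: int = 800,
    spacing: int = 2500,
    dominant_mass: float = 0.8,
    n_satellites: int = 3,
) -> Tuple[Dict[str, str], List[TssProfile], List[TranscriptModel], np.ndarray]:
    """Toy genome with sharp-TSS transcripts, matched models and depths.

    Each transcript is mono-exonic on its own slot of one chromosome, with a
    dominant TSS carrying ``dominant_mass`` and a few satellite starts
    within +-3 nt. Returns (genome, profiles, models, lognormal expression
    weights) — the weights yield a spread of per-transcript depths.
    """
    rng = np.random.default_rng(seed)
    chrom = "chrSim"
    chrom_len = 1000 + n_transcripts * spacing + 1000
    genome = {chrom: "".join(rng.choice(list("ACGT"), size=chrom_len))}
    profiles: List[TssProfile] = []
    models: List[TranscriptModel] = []
    for i in range(n_transcripts):
        anchor = 1000 + i * spacing + 600
        strand = "+" if rng.random() < 0.5 else "-"
        offsets = rng.choice(np.arange(-3, 4), size=n_satellites, replace=False)
        sat_mass = (1.0 - dominant_mass) * rng.dirichlet(np.ones(n_satellites))
        weights = {anchor: dominant_mass}
        for off, mass in zip(offsets, sat_mass):
            if off == 0:
                weights[anchor] += mass
            else:
                weights[anchor + int(off)] = weights.get(anchor + int(off), 0.0) + mass
        total = sum(weights.values())
        weights = {p: w / total for p, w in weights.items()}
        if strand == "+":
            tx_end = anchor + body_length
            exons = [(anchor, tx_end)]
        else:
            tx_end = anchor - body_length
            exons = [(tx_end, anchor + 1)]
        tid = f"TX{i:04d}"
        profiles.append(TssProfile(tid, chrom, strand, weights, tx_end=tx_end))
        models.append(TranscriptModel(tid, f"G{i:04d}", chrom, strand, exons))
    expr = rng.lognormal(mean=0.0, sigma=1.2, size=n_transcripts)
    return genome, profiles, models, expr


@dataclass
class ImageSimConfig:
    height: int = 256
    width: int = 256
    # (center_row, center_col, radius_row, radius_col) ellipses
    nucleus_geometry: List[Tuple[float, float, float, float]] = field(
        default_factory=lambda: [(80.0, 80.0, 40.0, 50.0), (180.0, 170.0, 45.0, 40.0)]
    )
    n_spots_per_channel: Dict[str, int] = field(
        default_factory=lambda: {"red": 20, "green": 20}
    )
    nuclear_spot_fraction: Dict[str, float] = field(
        default_factory=lambda: {"red": 0.5, "green": 0.5}
    )
    spot_sigma: float = 1.2
    spot_amplitude: float = 5000.0
    background_mean: float = 100.0
    background_sd: float = 10.0
    dapi_nucleus_level: float = 2000.0
    n_chromocenters_per_nucleus: int = 0
    min_separation: float = 4.0
    border_margin: int = 6
    compartment_margin: float = 2.0  # px from the mask boundary
    seed: int = 0


def _ellipse_mask(cfg: ImageSimConfig) -> np.ndarray:
    rr, cc = np.mgrid[0:cfg.height, 0:cfg.width]
    mask = np.zeros((cfg.height, cfg.width), dtype=bool)
    for cy, cx, ry, rx in cfg.nucleus_geometry:
        mask |= ((rr - cy) / ry) ** 2 + ((cc - cx) / rx) ** 2 <= 1.0
    return mask


def _place_spots(
    rng: np.random.Generator,
    cfg: ImageSimConfig,
    mask: np.ndarray,
    n: int,
    nuclear_fraction: float,
    taken: List[Tuple[float, float]],
) -> List[Tuple[float, float, bool]]:
    from scipy import ndimage

    placed: List[Tuple[float, float, bool]] = []
    n_nuclear = int(round(n * nuclear_fraction))
    compartments = [True] * n_nuclear + [False] * (n - n_nuclear)
    # distance into each compartment's interior, to keep truth unambiguous
    depth_in = ndimage.distance_transform_edt(mask)
    depth_out = ndimage.distance_transform_edt(~mask)
    for want_nuclear in compartments:
        for _ in range(5000):
            r = rng.uniform(cfg.border_margin, cfg.height - cfg.border_margin)
            c = rng.uniform(cfg.border_margin, cfg.width - cfg.border_margin)
            ri, ci = int(round(r)), int(round(c))
            if mask[ri, ci] != want_nuclear:
                continue
            depth = depth_in[ri, ci] if want_nuclear else depth_out[ri, ci]
            if depth <= cfg.compartment_margin:
                continue
            if any(
                (r - r0) ** 2 + (c - c0) ** 2 < cfg.min_separation ** 2
                for r0, c0 in taken
            ):
                continue
            placed.append((r, c, want_nuclear))
            taken.append((r, c))
            break
        else:
            raise RuntimeError("spot placement retries exhausted")
    return placed


def simulate_image(
    cfg: ImageSimConfig,
) -> Tuple[Dict[str, np.ndarray], pd.DataFrame, np.ndarray]:
    """Render DAPI/red/green planes with planted puncta over a nucleus mask.

    Returns ({'dapi','red','green'}: uint16 planes, truth spot table with
    columns channel/row/col/nuclear, truth nucleus mask).
    """
    rng = np.random.default_rng(cfg.seed)
    mask = _ellipse_mask(cfg)
    planes: Dict[str, np.ndarray] = {}
    dapi = rng.normal(cfg.background_mean, cfg.background_sd, (cfg.height, cfg.width))
    dapi[mask] += cfg.dapi_nucleus_level
    if cfg.n_chromocenters_per_nucleus > 0:
        for cy, cx, ry, rx in cfg.nucleus_geometry:
            for _ in range(cfg.n_chromocenters_per_nucleus):
                ang = rng.uniform(0, 2 * math.pi)
                rad = rng.uniform(0, 0.6)
                r0 = cy + rad * ry * math.sin(ang)
                c0 = cx + rad * rx * math.cos(ang)
                dapi += _gaussian_punctum(
                    cfg.height, cfg.width, r0, c0, 2.0, cfg.dapi_nucleus_level
                )
    truth_rows = []
    taken: List[Tuple[float, float]] = []
    for channel in ("red", "green"):
        plane = rng.normal(
            cfg.background_mean, cfg.background_sd, (cfg.height, cfg.width)
        )
        n = cfg.n_spots_per_channel.get(channel, 0)
        frac = cfg.nuclear_spot_fraction.get(channel, 0.5)
        if n > 0:
            for r, c, nuclear in _place_spots(rng, cfg, mask, n, frac, taken):
                plane += _gaussian_punctum(
                    cfg.height, cfg.width, r, c, cfg.spot_sigma, cfg.spot_amplitude
                )
                truth_rows.append(
                    {"channel": channel, "row": r, "col": c, "nuclear": nuclear}
                )
        planes[channel] = np.clip(plane, 0, 65535).astype(np.uint16)
    planes["dapi"] = np.clip(dapi, 0, 65535).astype(np.uint16)
    truth = pd.DataFrame(truth_rows, columns=["channel", "row", "col", "nuclear"])
    return planes, truth, mask


def _gaussian_punctum(
    h: int, w: int, r0: float, c0: float, sigma: float, amplitude: float
) -> np.ndarray:
    rr, cc = np.mgrid[0:h, 0:w]
    return amplitude * np.exp(
        -((rr - r0) ** 2 + (cc - c0) ** 2) / (2.0 * sigma ** 2)
    )


@dataclass
class CtSimConfig:
    true_abundances: Dict[str, float] = field(
        default_factory=lambda: {"top": 8.0, "40S": 4.0, "60-80S": 1.0}
    )
    ct_at_unit_abundance: float = 30.0
    replicate_noise_sd: float = 0.0
    n_replicates: int = 1
    amplicon: str = "AMP1"
    seed: int = 0

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.true_abundances.values()):
            raise ValueError("abundances must be positive")
        if self.n_replicates <= 0:
            raise ValueError("n_replicates must be positive")


def simulate_ct(cfg: CtSimConfig) -> pd.DataFrame:
    """CT table with CT = ct_at_unit_abundance - log2(abundance) + noise."""
    rng = np.random.default_rng(cfg.seed)
    rows = []
    for rep in range(1, cfg.n_replicates + 1):
        for fraction, abundance in cfg.true_abundances.items():
            ct = cfg.ct_at_unit_abundance - math.log2(abundance)
            if cfg.replicate_noise_sd > 0:
                ct += rng.normal(0.0, cfg.replicate_noise_sd)
            if not 0.0 < ct <= 40.0:
                raise ValueError(
                    f"unrealistic configuration: CT {ct:.2f} outside (0, 40]"
                )
            rows.append(
                {
                    "amplicon": cfg.amplicon,
                    "fraction": fraction,
                    "replicate": rep,
                    "ct": ct,
                    "is_ntc": False,
                }
            )
    return pd.DataFrame(rows)
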