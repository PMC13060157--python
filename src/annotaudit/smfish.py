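"""Punctum detection, nuclear/cytoplasmic classification, colocalization.

Detection approximates the cited plugin settings with a transparent
pipeline: Gaussian smooth, robust background statistics (median / MAD),
threshold at mean + k*SD, 8-connected components, minimum-size filter, and
intensity-weighted centroids. The nuclear mask is an inclusive band
threshold of the DAPI plane.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage

MAD_TO_SD = 1.4826  # consistency factor for Gaussian noise


@dataclass
class SpotParams:
    min_intensity_sd: float = 20.0
    min_size_px: int = 3
    max_pair_dist_px: float = 2.0
    smoothing_sigma: float = 1.0

    def __post_init__(self) -> None:
        if (
            self.min_intensity_sd <= 0
            or self.min_size_px <= 0
            or self.max_pair_dist_px <= 0
            or self.smoothing_sigma < 0
        ):
            raise ValueError("SpotParams must be positive (smoothing_sigma >= 0)")


@dataclass
class Spot:
    centroid: Tuple[float, float]  # (row, col), sub-pixel
    area: int
    peak_intensity: float
    channel: str = ""


@dataclass
class NucleusMask:
    mask: np.ndarray
    low: float = 35.0
    high: float = 255.0


def detect_spots(
    plane: np.ndarray, params: Optional[SpotParams] = None, channel: str = ""
) -> List[Spot]:
    """Detect bright puncta in one channel plane.

    Returns spots ordered by (row, col) of centroid. A constant plane yields
    no spots (with a warning), since the SD threshold is undefined there.
    """
    params = params or SpotParams()
    img = np.asarray(plane, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a single-channel 2-D plane")
    if params.smoothing_sigma > 0:
        smooth = ndimage.gaussian_filter(img, sigma=params.smoothing_sigma)
    else:
        smooth = img
    if img.max() == img.min():
        warnings.warn("constant image: background SD is zero, no spots detected")
        return []
    background = float(np.median(smooth))
    sd = MAD_TO_SD * float(np.median(np.abs(smooth - background)))
    threshold = background + params.min_intensity_sd * sd
    binary = smooth > threshold
    labels, n = ndimage.label(binary, structure=np.ones((3, 3), dtype=int))
    spots: List[Spot] = []
    if n == 0:
        return spots
    areas = ndimage.sum_labels(binary, labels, index=range(1, n + 1))
    for lab, area in zip(range(1, n + 1), areas):
        if area < params.min_size_px:
            continue
        sel = labels == lab
        weights = np.where(sel, smooth - background, 0.0)
        total = weights.sum()
        rr, cc = np.nonzero(sel)
        r0 = float((rr * weights[rr, cc]).sum() / total)
        c0 = float((cc * weights[rr, cc]).sum() / total)
        spots.append(
            Spot(
                centroid=(r0, c0),
                area=int(area),
                peak_intensity=float(img[sel].max()),
                channel=channel,
            )
        )
    spots.sort(key=lambda s: s.centroid)
    return spots


def nucleus_mask(dapi: np.ndarray, low: float = 35.0, high: float = 255.0) -> NucleusMask:
    """Inclusive band threshold of the DAPI plane (no morphology)."""
    if low > high:
        raise ValueError("low must be <= high")
    img = np.asarray(dapi, dtype=float)
    return NucleusMask(mask=(img >= low) & (img <= high), low=low, high=high)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass
class LocalizationResult:
    labels: List[str]  # per-spot: "nuclear" | "cytoplasmic"
    n_nuclear: int
    n_cytoplasmic: int

    @property
    def fraction_nuclear(self) -> float:
        total = self.n_nuclear + self.n_cytoplasmic
        return self.n_nuclear / total if total else math.nan


def classify_localization(
    spots: Sequence[Spot], mask: NucleusMask
) -> LocalizationResult:
    """Label each spot by the mask value at its rounded centroid pixel."""
    h, w = mask.mask.shape
    labels = []
    for s in spots:
        r = _round_half_up(s.centroid[0])
        c = _round_half_up(s.centroid[1])
        if not (0 <= r < h and 0 <= c < w):
            raise ValueError(f"spot centroid {s.centroid} outside image")
        labels.append("nuclear" if mask.mask[r, c] else "cytoplasmic")
    n_nuc = labels.count("nuclear")
    return LocalizationResult(
        labels=labels, n_nuclear=n_nuc, n_cytoplasmic=len(labels) - n_nuc
    )


@dataclass
class ColocalizationResult:
    pairs: List[Tuple[int, int]]  # (index into spots_x, index into spots_y)
    matched_x: List[bool]
    per_compartment: pd.DataFrame  # compartment, n_x, n_matched, fraction_matched


def colocalize(
    spots_x: Sequence[Spot],
    spots_y: Sequence[Spot],
    max_dist: float,
    mask: Optional[NucleusMask] = None,
) -> ColocalizationResult:
    """Greedy mutual-nearest matching of x-spots to y-spots.

    Repeatedly pairs the globally closest unmatched (x, y) with centroid
    distance <= max_dist; each spot is used at most once. Per-compartment
    fractions refer to the compartment of the x-spot (requires ``mask``).
    """
    nx, ny = len(spots_x), len(spots_y)
    pairs: List[Tuple[int, int]] = []
    if nx and ny:
        cx = np.array([s.centroid for s in spots_x])
        cy = np.array([s.centroid for s in spots_y])
        dist = np.sqrt(((cx[:, None, :] - cy[None, :, :]) ** 2).sum(axis=2))
        dist = np.where(dist <= max_dist, dist, np.inf)
        used_x = np.zeros(nx, dtype=bool)
        used_y = np.zeros(ny, dtype=bool)
        while True:
            i, j = np.unravel_index(np.argmin(dist), dist.shape)
            if not np.isfinite(dist[i, j]):
                break
            pairs.append((int(i), int(j)))
            used_x[i] = used_y[j] = True
            dist[i, :] = np.inf
            dist[:, j] = np.inf
        matched_x = used_x.tolist()
    else:
        matched_x = [False] * nx
    rows = []
    if mask is not None:
        loc = classify_localization(spots_x, mask)
        for compartment in ("nuclear", "cytoplasmic"):
            idx = [i for i, lab in enumerate(loc.labels) if lab == compartment]
            n_matched = sum(1 for i in idx if matched_x[i])
            rows.append(
                {
                    "compartment": compartment,
                    "n_x": len(idx),
                    "n_matched": n_matched,
                    "fraction_matched": n_matched / len(idx) if idx else math.nan,
                }
            )
    else:
        n_matched = sum(matched_x)
        rows.append(
            {
                "compartment": "all",
                "n_x": nx,
                "n_matched": n_matched,
                "fraction_matched": n_matched / nx if nx else math.nan,
            }
        )
    return ColocalizationResult(
        pairs=pairs, matched_x=matched_x, per_compartment=pd.DataFrame(rows)
    )


def spots_to_frame(spots: Sequence[Spot], field_name: str = "") -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "field": field_name,
                "channel": s.channel,
                "row": s.centroid[0],
                "col": s.centroid[1],
                "area": s.area,
                "peak": s.peak_intensity,
            }
            for s in spots
        ]
    )


def pool_fields(results: Sequence[LocalizationResult]) -> Dict[str, float]:
    """Pool counts (not fractions) across fields of one tissue class."""
    n_nuc = sum(r.n_nuclear for r in results)
    n_cyt = sum(r.n_cytoplasmic for r in results)
    total = n_nuc + n_cyt
    return {
        "n_nuclear": n_nuc,
        "n_cytoplasmic": n_cyt,
        "fraction_nuclear": n_nuc / total if total else math.nan,
    }
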