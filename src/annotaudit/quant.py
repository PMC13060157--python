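"""qPCR delta-CT fraction profiles and dual-luciferase plate normalization.

Fraction abundances are anchored per technical replicate: with m the
maximum CT across fractions of one (amplicon, replicate), the relative
abundance of fraction f is 2**(m - CT_f), so the least abundant fraction is
exactly 1 and each fraction's share is reported as a percent of the
replicate total. No-template-control rows never contribute to m.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List

import numpy as np
import pandas as pd

CT_COLUMNS = ["amplicon", "fraction", "replicate", "ct", "is_ntc"]


def _validate_ct_table(ct: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in CT_COLUMNS if c not in ct.columns and c != "is_ntc"]
    if missing:
        raise ValueError(f"CT table missing columns: {missing}")
    ct = ct.copy()
    if "is_ntc" not in ct.columns:
        ct["is_ntc"] = False
    bad = ct[~ct["is_ntc"] & ((ct["ct"] <= 0) | (ct["ct"] > 40))]
    if len(bad):
        raise ValueError("non-NTC CT values must lie in (0, 40]")
    return ct


@dataclass
class FractionProfile:
    per_replicate: pd.DataFrame  # amplicon, replicate, fraction, rel_abundance, percent
    summary: pd.DataFrame  # amplicon, fraction, mean_percent, sd_percent, n


def fraction_abundance(ct: pd.DataFrame) -> FractionProfile:
    """Anchored 2**(max CT - CT) abundances and percent-of-total profiles."""
    ct = _validate_ct_table(ct)
    data = ct[~ct["is_ntc"]]
    if data.empty:
        raise ValueError("no non-NTC CT entries")
    rep_rows: List[dict] = []
    for (amplicon, replicate), grp in data.groupby(["amplicon", "replicate"]):
        grp = grp.dropna(subset=["ct"])
        if len(grp) < 2:
            raise ValueError(
                f"{amplicon} replicate {replicate}: need >=2 fractions with CT"
            )
        m = grp["ct"].max()
        rel = np.exp2(m - grp["ct"].to_numpy())
        pct = 100.0 * rel / rel.sum()
        for frac, r, p in zip(grp["fraction"], rel, pct):
            rep_rows.append(
                {
                    "amplicon": amplicon,
                    "replicate": replicate,
                    "fraction": frac,
                    "rel_abundance": float(r),
                    "percent": float(p),
                }
            )
    per_rep = pd.DataFrame(rep_rows)
    summary = (
        per_rep.groupby(["amplicon", "fraction"], sort=False)["percent"]
        .agg(mean_percent="mean", sd_percent="std", n="count")
        .reset_index()
    )
    return FractionProfile(per_replicate=per_rep, summary=summary)


PLATE_COLUMNS = ["condition", "replicate", "nluc", "fluc", "is_background"]


@dataclass
class ReporterResult:
    per_replicate: pd.DataFrame  # condition, replicate, ratio, excluded
    summary: pd.DataFrame  # condition, mean_ratio, sd_ratio, n


def reporter_ratios(plate: pd.DataFrame) -> ReporterResult:
    """Background-subtracted N-luc / F-luc ratios per replicate.

    Background per channel is the mean over background wells. Replicates
    whose subtracted F-luc is <= 0 are flagged excluded and dropped from
    condition means.
    """
    missing = [c for c in PLATE_COLUMNS if c not in plate.columns]
    if missing:
        raise ValueError(f"plate table missing columns: {missing}")
    if (plate[["nluc", "fluc"]] < 0).any().any():
        raise ValueError("luminescence must be non-negative")
    bg = plate[plate["is_background"]]
    if bg.empty:
        raise ValueError("no background wells")
    bg_n = float(bg["nluc"].mean())
    bg_f = float(bg["fluc"].mean())
    rows = []
    for _, well in plate[~plate["is_background"]].iterrows():
        num = well["nluc"] - bg_n
        den = well["fluc"] - bg_f
        excluded = den <= 0
        rows.append(
            {
                "condition": well["condition"],
                "replicate": well["replicate"],
                "ratio": math.nan if excluded else num / den,
                "excluded": excluded,
            }
        )
    per_rep = pd.DataFrame(rows)
    kept = per_rep[~per_rep["excluded"]]
    if kept.empty:
        raise ValueError("all replicates excluded (F-luc at or below background)")
    summary = (
        kept.groupby("condition", sort=False)["ratio"]
        .agg(mean_ratio="mean", sd_ratio="std", n="count")
        .reset_index()
    )
    return ReporterResult(per_replicate=per_rep, summary=summary)
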