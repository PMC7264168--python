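"""Immunoblot quantification: lane-total correction, WT-ratio normalization,
and 2x-SD outlier exclusion.

Band intensities are first corrected for loading differences by dividing by
the total-protein intensity of their gel lane.  Each corrected value (both
genotypes) is then expressed as a ratio to the wild-type group mean, so the
WT group averages exactly 1 and the knockout group mean reads directly as the
fold change.  Outliers deviating from their group mean by more than 2 group
SDs are excluded in a single pass.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class NormalizedBlot:
    """Per-sample normalized table plus per-group summaries."""

    table: pd.DataFrame  # sample_id, group, lane_corrected, wt_ratio, excluded
    wt_group: str = "WT"

    def group_summary(self, included_only: bool = True) -> pd.DataFrame:
        df = self.table
        if included_only:
            df = df[~df["excluded"]]
        return df.groupby("group")["wt_ratio"].agg(
            mean="mean", SD=lambda v: v.std(ddof=1), n="count"
        )


def lane_normalize(band_intensity: float, lane_total: float) -> float:
    """Band / lane-total loading correction."""
    if lane_total <= 0:
        raise ValueError("lane_total must be positive")
    return band_intensity / lane_total


def wt_ratio_normalize(table: pd.DataFrame, wt_group: str = "WT") -> NormalizedBlot:
    """Express lane-corrected intensities as ratios to the WT group mean.

    Requires at least two WT samples; scale-invariant in the raw intensities.
    """
    df = table.copy()
    for col in ("band_intensity", "lane_total", "group", "sample_id"):
        if col not in df.columns:
            raise ValueError(f"blot table missing column {col!r}")
    df["lane_corrected"] = df["band_intensity"] / df["lane_total"]
    wt = df.loc[df["group"] == wt_group, "lane_corrected"]
    if wt.size < 2:
        raise ValueError(f"need >= 2 samples in reference group {wt_group!r}")
    wt_mean = wt.mean()
    if wt_mean <= 0:
        raise ValueError("WT group mean must be positive")
    df["wt_ratio"] = df["lane_corrected"] / wt_mean
    df["excluded"] = False
    return NormalizedBlot(
        table=df[["sample_id", "group", "lane_corrected", "wt_ratio", "excluded"]],
        wt_group=wt_group,
    )


def exclude_outliers(
    normalized: NormalizedBlot,
    k_sd: float = 2.0,
    ddof: int = 1,
    renormalize: bool = True,
) -> NormalizedBlot:
    """Flag samples deviating from their group mean by more than k_sd group SDs.

    A single, non-iterative pass per group; every group must have at least
    three samples.  With ``renormalize`` (default) the WT ratios are
    recomputed from the included WT samples afterwards, so the included WT
    mean returns to exactly 1; with ``renormalize=False`` the original ratios
    are kept, which reproduces reported WT means slightly off 1.
    """
    df = normalized.table.copy()
    for group, sub in df.groupby("group"):
        if len(sub) < 3:
            raise ValueError(f"group {group!r} has n={len(sub)} < 3")
        mean = sub["wt_ratio"].mean()
        sd = sub["wt_ratio"].std(ddof=ddof)
        flag = (sub["wt_ratio"] - mean).abs() > k_sd * sd
        df.loc[sub.index, "excluded"] = flag
    if renormalize:
        wt_in = df[(df["group"] == normalized.wt_group) & (~df["excluded"])]
        wt_mean = wt_in["lane_corrected"].mean()
        if wt_mean <= 0 or wt_in.empty:
            raise ValueError("no included WT samples left to renormalize against")
        df["wt_ratio"] = df["lane_corrected"] / wt_mean
    return NormalizedBlot(table=df, wt_group=normalized.wt_group)


def normalize_blot(
    table: pd.DataFrame,
    wt_group: str = "WT",
    exclude: bool = True,
    k_sd: float = 2.0,
    renormalize: bool = True,
) -> NormalizedBlot:
    """Full chain: lane correction, WT-ratio normalization, outlier exclusion."""
    nb = wt_ratio_normalize(table, wt_group=wt_group)
    if exclude:
        nb = exclude_outliers(nb, k_sd=k_sd, renormalize=renormalize)
    return nb
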