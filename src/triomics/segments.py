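"""Segmental expression bias and read-depth CNV calling.

Differentially expressed segments: the genome is tiled in non-overlapping
500-kbp windows; a window with more than 20 DEGs (any direction, per
genotype and stage) is a candidate. The up/down bias per genotype x stage
is log2((n_up + 0.5)/(n_down + 0.5)), normalized to Z-scores within the
segment across its genotype x stage cells; a candidate is retained when the
Z range across genotypes reaches a threshold (default 1.5) in at least one
stage — an explicit, configurable replacement for visual heatmap
clustering.

CNVs: per-window read depth is aggregated to 25-kbp windows; depths above
the outlier cap (100) are excluded from the genome-wide mean/SD estimate;
windows more than one SD below/above the mean are deletions/duplications,
and adjacent same-type windows merge.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def find_segments(
    degs: pd.DataFrame,
    chrom_lengths: dict[str, int],
    window: int = 500_000,
    min_degs: int = 20,
    z_range_thresh: float = 1.5,
) -> pd.DataFrame:
    """Differentially expressed segment candidates and retention calls.

    ``degs`` needs columns chrom, pos, direction (up|down), genotype, stage.
    A partial last window on each chromosome is kept and flagged. Candidacy
    requires strictly more than ``min_degs`` DEGs in some genotype x stage
    cell of the window.
    """
    rows = []
    degs = degs.copy()
    degs["win_start"] = degs["pos"] // window * window
    cells = (
        degs.groupby(["chrom", "win_start", "genotype", "stage"], sort=True)["direction"]
        .agg(
            n_up=lambda s: int((s == "up").sum()),
            n_down=lambda s: int((s == "down").sum()),
        )
        .reset_index()
    )
    cells["n_deg"] = cells["n_up"] + cells["n_down"]
    cells["bias"] = np.log2((cells["n_up"] + 0.5) / (cells["n_down"] + 0.5))
    for (chrom, ws), seg in cells.groupby(["chrom", "win_start"], sort=True):
        end = min(ws + window, chrom_lengths.get(chrom, ws + window))
        partial = end - ws < window
        bias = seg["bias"].to_numpy(dtype=float)
        sd = bias.std(ddof=0)
        z = (bias - bias.mean()) / sd if sd > 0 else np.zeros_like(bias)
        seg = seg.assign(z=z)
        is_candidate = bool((seg["n_deg"] > min_degs).any())
        retained = False
        if is_candidate:
            for _, stage_cells in seg.groupby("stage"):
                if stage_cells["z"].max() - stage_cells["z"].min() >= z_range_thresh:
                    retained = True
                    break
        for r in seg.itertuples(index=False):
            rows.append(
                {
                    "chrom": chrom, "start": int(ws), "end": int(end),
                    "genotype": r.genotype, "stage": r.stage,
                    "n_up": r.n_up, "n_down": r.n_down, "bias": r.bias, "z": r.z,
                    "is_candidate": is_candidate, "retained": retained,
                    "partial_window": partial,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "genotype", "stage", "n_up", "n_down",
                 "bias", "z", "is_candidate", "retained", "partial_window"],
    )


def call_cnv(
    coverage: pd.DataFrame,
    window: int = 25_000,
    depth_cap: float = 100.0,
    n_sd: float = 1.0,
    min_windows: int = 10,
) -> tuple[pd.DataFrame, dict]:
    """Deletion/duplication calls from windowed depth.

    ``coverage`` has columns chrom, start, depth at any fixed sub-window
    size dividing ``window``; sub-windows are averaged per 25-kbp window.
    Returns (calls, stats) where stats carries the post-exclusion mean/SD
    used for thresholding.
    """
    cov = coverage[coverage["depth"] <= depth_cap].copy()
    cov["win_start"] = cov["start"] // window * window
    win = (
        cov.groupby(["chrom", "win_start"], sort=True)["depth"].mean().reset_index()
        .rename(columns={"depth": "mean_depth"})
    )
    if len(win) < min_windows:
        raise ValueError(
            f"only {len(win)} windows after outlier exclusion; SD estimate unstable"
        )
    mean = float(win["mean_depth"].mean())
    sd = float(win["mean_depth"].std(ddof=1))
    lo, hi = mean - n_sd * sd, mean + n_sd * sd
    win["cnv_type"] = np.where(
        win["mean_depth"] < lo, "deletion",
        np.where(win["mean_depth"] > hi, "duplication", "none"),
    )
    calls = []
    for chrom, sub in win[win["cnv_type"] != "none"].groupby("chrom", sort=True):
        sub = sub.sort_values("win_start")
        for _, row in sub.iterrows():
            if (
                calls
                and calls[-1]["chrom"] == chrom
                and calls[-1]["cnv_type"] == row["cnv_type"]
                and row["win_start"] == calls[-1]["end"]
            ):
                prev = calls[-1]
                n_prev = (prev["end"] - prev["start"]) // window
                prev["mean_depth"] = (
                    prev["mean_depth"] * n_prev + row["mean_depth"]
                ) / (n_prev + 1)
                prev["end"] = int(row["win_start"]) + window
            else:
                calls.append(
                    {"chrom": chrom, "start": int(row["win_start"]),
                     "end": int(row["win_start"]) + window,
                     "cnv_type": row["cnv_type"], "mean_depth": float(row["mean_depth"])}
                )
    stats = {"mean": mean, "sd": sd, "lower": lo, "upper": hi, "n_windows": len(win)}
    return (
        pd.DataFrame(calls, columns=["chrom", "start", "end", "cnv_type", "mean_depth"]),
        stats,
    )


def segments_vs_cnv(segments: pd.DataFrame, cnvs: pd.DataFrame) -> pd.DataFrame:
    """Annotate retained segments with overlapping CNV type.

    One row per retained segment window; ``rearrangement`` is
    'deletion-associated', 'duplication-associated', or 'no rearrangement'
    (both types overlapping gives 'deletion+duplication-associated').
    """
    seg = (
        segments[segments["retained"]][["chrom", "start", "end"]]
        .drop_duplicates()
        .reset_index(drop=True)
    )
    labels = []
    for r in seg.itertuples(index=False):
        types = set()
        if not cnvs.empty:
            hit = cnvs[
                (cnvs["chrom"] == r.chrom)
                & (cnvs["start"] < r.end)
                & (cnvs["end"] > r.start)
            ]
            types = set(hit["cnv_type"])
        if types == {"deletion"}:
            labels.append("deletion-associated")
        elif types == {"duplication"}:
            labels.append("duplication-associated")
        elif types:
            labels.append("deletion+duplication-associated")
        else:
            labels.append("no rearrangement")
    seg["rearrangement"] = labels
    return seg
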