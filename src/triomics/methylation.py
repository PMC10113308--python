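"""Methylation levels, binned score-test DMR calling, MLD, CpG islands.

Per-cytosine reports (CX dialect) are pooled per genotype into fixed-width
bins (default 1000 bp, grid anchored at coordinate 0). A bin is a DMR
candidate between two genotypes when it has >= 4 covered cytosines in each,
an absolute methylation-proportion difference >= 0.4, and a two-proportion
score-test p < 0.01; adjacent candidate bins with the same direction merge
(gap 0 means only touching bins merge) and merged regions are re-audited on
pooled counts. DMRs are called in CpG and CHG contexts by default; CHH
calling sits behind a flag. Methylation level dominance (MLD) applies the
trio dominance classifier to replicate-level DMR methylation levels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import dominance
from .io import CONTEXTS

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def _revcomp(s: str) -> str:
    return "".join(_COMP[b] for b in reversed(s))


def cytosine_contexts(seq: str, chrom: str) -> pd.DataFrame:
    """Every cytosine (both strands) with its CpG/CHG/CHH context.

    Returns columns chrom, pos (1-based), strand, context, trinucleotide.
    Cytosines whose trinucleotide runs off the chromosome end or contains N
    are skipped.
    """
    arr = np.frombuffer(seq.upper().encode(), dtype="S1")
    L = len(arr)
    is_c = arr == b"C"
    is_g = arr == b"G"
    valid = np.isin(arr, [b"A", b"C", b"G", b"T"])

    rows = []
    # plus strand: C at i, context from s[i+1], s[i+2]
    idx = np.nonzero(is_c[: L - 2] & valid[: L - 2])[0]
    idx = idx[valid[idx + 1] & valid[idx + 2]]
    if idx.size:
        nxt_g = is_g[idx + 1]
        nxt2_g = is_g[idx + 2]
        ctx = np.where(nxt_g, "CpG", np.where(nxt2_g, "CHG", "CHH"))
        tri = [seq[i : i + 3] for i in idx]
        rows.append(pd.DataFrame({"pos": idx + 1, "strand": "+", "context": ctx, "trinucleotide": tri}))
    # minus strand: G at i pairs with a C; context from s[i-1], s[i-2]
    idx = np.nonzero(is_g & valid)[0]
    idx = idx[idx >= 2]
    idx = idx[valid[idx - 1] & valid[idx - 2]]
    if idx.size:
        nxt_c = is_c[idx - 1]
        nxt2_c = is_c[idx - 2]
        ctx = np.where(nxt_c, "CpG", np.where(nxt2_c, "CHG", "CHH"))
        tri = [_revcomp(seq[i - 2 : i + 1]) for i in idx]
        rows.append(pd.DataFrame({"pos": idx + 1, "strand": "-", "context": ctx, "trinucleotide": tri}))
    if not rows:
        return pd.DataFrame(columns=["chrom", "pos", "strand", "context", "trinucleotide"])
    df = pd.concat(rows, ignore_index=True)
    df.insert(0, "chrom", chrom)
    return df.sort_values(["pos", "strand"], kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------- binning


def methylation_levels(
    cx_by_sample: dict[str, pd.DataFrame],
    genotype_of_sample: dict[str, str],
    bin_size: int = 1000,
    min_reads: int = 3,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pool cytosine reports into per-bin, per-context methylation levels.

    Cytosines whose methylation state was reported fewer than ``min_reads``
    times in a sample are dropped from that sample (the coverage >= 3 rule).
    Returns (pooled, per_replicate): pooled has one row per
    chrom/bin_start/context/genotype with n_cytosines, meth, total, level;
    per_replicate keeps samples separate. Bins with no covered cytosines are
    simply absent.
    """
    frames = []
    for sample, cx in cx_by_sample.items():
        if not cx["context"].isin(CONTEXTS).all():
            bad = cx.loc[~cx["context"].isin(CONTEXTS), "context"].iloc[0]
            raise ValueError(f"sample {sample}: context {bad!r} not in {CONTEXTS}")
        cov = cx["count_methylated"] + cx["count_unmethylated"]
        keep = cx[cov >= min_reads].copy()
        keep["bin_start"] = (keep["pos"] - 1) // bin_size * bin_size
        keep["sample"] = sample
        keep["genotype"] = genotype_of_sample[sample]
        frames.append(keep)
    allcx = pd.concat(frames, ignore_index=True)
    per_rep = (
        allcx.groupby(["chrom", "bin_start", "context", "genotype", "sample"], sort=True)
        .agg(
            n_cytosines=("pos", "size"),
            meth=("count_methylated", "sum"),
            unmeth=("count_unmethylated", "sum"),
        )
        .reset_index()
    )
    per_rep["total"] = per_rep["meth"] + per_rep["unmeth"]
    per_rep["level"] = per_rep["meth"] / per_rep["total"]
    pooled = (
        allcx.groupby(["chrom", "bin_start", "context", "genotype"], sort=True)
        .agg(
            n_cytosines=("pos", lambda s: s.nunique()),
            meth=("count_methylated", "sum"),
            unmeth=("count_unmethylated", "sum"),
        )
        .reset_index()
    )
    pooled["total"] = pooled["meth"] + pooled["unmeth"]
    pooled["level"] = pooled["meth"] / pooled["total"]
    pooled["bin_size"] = bin_size
    return pooled, per_rep


def genome_mean_levels(pooled: pd.DataFrame) -> pd.Series:
    """Read-weighted genome-wide methylation level per context."""
    g = pooled.groupby("context")[["meth", "total"]].sum()
    return g["meth"] / g["total"]


# ---------------------------------------------------------------- score test


def score_test(m1, n1, m2, n2) -> tuple[np.ndarray, np.ndarray]:
    """Two-proportion score test (pooled variance); z and two-sided p.

    z^2 equals the Pearson chi-square statistic of the 2x2 table without
    continuity correction. Degenerate pooled proportions (0 or 1) give p=1.
    """
    m1, n1, m2, n2 = (np.asarray(x, dtype=float) for x in (m1, n1, m2, n2))
    if np.any(n1 <= 0) or np.any(n2 <= 0):
        raise ValueError("total read counts must be positive")
    pooled = (m1 + m2) / (n1 + n2)
    var = pooled * (1 - pooled) * (1 / n1 + 1 / n2)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (m1 / n1 - m2 / n2) / np.sqrt(var)
    degenerate = (pooled <= 0) | (pooled >= 1)
    z = np.where(degenerate, 0.0, z)
    p = np.where(degenerate, 1.0, 2 * stats.norm.sf(np.abs(z)))
    return z, p


# ---------------------------------------------------------------- DMR calling


@dataclass
class DmrParams:
    p_thresh: float = 0.01
    min_cytosines: int = 4
    min_delta: float = 0.4
    min_gap: int = 0
    bin_size: int = 1000
    contexts: tuple[str, ...] = ("CpG", "CHG")   # CHH behind an explicit opt-in


def _audit(row: dict, par: DmrParams) -> bool:
    return (
        row["n_cyt1"] >= par.min_cytosines
        and row["n_cyt2"] >= par.min_cytosines
        and abs(row["delta"]) >= par.min_delta
        and row["pvalue"] < par.p_thresh
    )


def call_dmrs(
    pooled: pd.DataFrame,
    pair: tuple[str, str],
    params: DmrParams | None = None,
) -> pd.DataFrame:
    """Call DMRs between two genotypes from pooled bins.

    Candidate bins pass the cytosine-count, delta and p thresholds; same-
    direction candidates separated by <= min_gap bp merge, with merged
    statistics recomputed on pooled counts and re-audited (a merged region
    failing the audit falls back to its constituent bins).
    """
    par = params or DmrParams()
    g1, g2 = pair
    if "bin_size" in pooled.columns and len(pooled):
        sizes = pooled["bin_size"].unique()
        if len(sizes) > 1 or int(sizes[0]) != par.bin_size:
            raise ValueError(
                f"mismatched bin grids: bins at {sorted(sizes)} bp, caller expects {par.bin_size}"
            )
    sub = pooled[pooled["context"].isin(par.contexts)]
    a = sub[sub["genotype"] == g1]
    b = sub[sub["genotype"] == g2]
    key = ["chrom", "bin_start", "context"]
    merged = a.merge(b, on=key, suffixes=("_1", "_2"), how="inner")
    if merged.empty:
        return _empty_dmr_frame(g1, g2)
    z, p = score_test(
        merged["meth_1"], merged["total_1"], merged["meth_2"], merged["total_2"]
    )
    merged["z"] = z
    merged["pvalue"] = p
    merged["delta"] = merged["level_1"] - merged["level_2"]
    cand = merged[
        (merged["n_cytosines_1"] >= par.min_cytosines)
        & (merged["n_cytosines_2"] >= par.min_cytosines)
        & (merged["delta"].abs() >= par.min_delta)
        & (merged["pvalue"] < par.p_thresh)
    ].sort_values(["context", "chrom", "bin_start"], kind="stable")

    out_rows: list[dict] = []
    for (_, _), grp in cand.groupby(["context", "chrom"], sort=True):
        run: list[pd.Series] = []
        for _, row in grp.iterrows():
            if run and (
                row["bin_start"] - (run[-1]["bin_start"] + par.bin_size) <= par.min_gap
                and np.sign(row["delta"]) == np.sign(run[-1]["delta"])
            ):
                run.append(row)
            else:
                out_rows.extend(_emit_run(run, par, g1, g2))
                run = [row]
        out_rows.extend(_emit_run(run, par, g1, g2))
    df = pd.DataFrame(out_rows, columns=_DMR_COLUMNS + ["genotype1", "genotype2"])
    if df.empty:
        return _empty_dmr_frame(g1, g2)
    return df.sort_values(["context", "chrom", "start"], kind="stable").reset_index(drop=True)


_DMR_COLUMNS = [
    "chrom", "start", "end", "context", "n_cyt1", "n_cyt2",
    "meth1", "total1", "meth2", "total2", "p1", "p2", "delta",
    "z", "pvalue", "direction",
]


def _empty_dmr_frame(g1: str, g2: str) -> pd.DataFrame:
    df = pd.DataFrame(columns=_DMR_COLUMNS + ["genotype1", "genotype2"])
    return df


def _row_to_region(rows: list[pd.Series], par: DmrParams, g1: str, g2: str) -> dict:
    m1 = float(sum(r["meth_1"] for r in rows))
    t1 = float(sum(r["total_1"] for r in rows))
    m2 = float(sum(r["meth_2"] for r in rows))
    t2 = float(sum(r["total_2"] for r in rows))
    z, p = score_test(m1, t1, m2, t2)
    p1, p2 = m1 / t1, m2 / t2
    return {
        "chrom": rows[0]["chrom"],
        "start": int(rows[0]["bin_start"]),
        "end": int(rows[-1]["bin_start"]) + par.bin_size,
        "context": rows[0]["context"],
        "n_cyt1": int(sum(r["n_cytosines_1"] for r in rows)),
        "n_cyt2": int(sum(r["n_cytosines_2"] for r in rows)),
        "meth1": m1, "total1": t1, "meth2": m2, "total2": t2,
        "p1": p1, "p2": p2, "delta": p1 - p2,
        "z": float(z), "pvalue": float(p),
        "direction": "hyper" if p1 > p2 else "hypo",
        "genotype1": g1, "genotype2": g2,
    }


def _emit_run(run: list[pd.Series], par: DmrParams, g1: str, g2: str) -> list[dict]:
    if not run:
        return []
    region = _row_to_region(run, par, g1, g2)
    if len(run) == 1 or _audit(region, par):
        return [region]
    # pathological weighting flipped the merged statistics: emit bins singly
    return [_row_to_region([r], par, g1, g2) for r in run]


# ---------------------------------------------------------------- MLD


def dmr_replicate_levels(
    dmrs: pd.DataFrame, per_rep: pd.DataFrame, genotype: str
) -> np.ndarray:
    """(n_dmrs, n_replicates) methylation levels inside each DMR.

    Levels pool reads over the DMR's constituent bins per sample. A sample
    with no covered cytosines in the DMR contributes NaN.
    """
    sub = per_rep[per_rep["genotype"] == genotype]
    samples = sorted(sub["sample"].unique())
    out = np.full((len(dmrs), len(samples)), np.nan)
    grouped = {k: v for k, v in sub.groupby(["chrom", "context", "sample"], sort=False)}
    for i, row in enumerate(dmrs.itertuples(index=False)):
        for j, s in enumerate(samples):
            g = grouped.get((row.chrom, row.context, s))
            if g is None:
                continue
            inside = g[(g["bin_start"] >= row.start) & (g["bin_start"] < row.end)]
            tot = inside["total"].sum()
            if tot > 0:
                out[i, j] = inside["meth"].sum() / tot
    return out


def classify_mld(
    dmrs: pd.DataFrame,
    per_rep: pd.DataFrame,
    roles: dict[str, str],
    stage: str = "",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Methylation level dominance per DMR (same taxonomy as ELD).

    ``roles`` maps dominance roles to genotype labels, e.g.
    {"maternal": "E", "paternal": "G", "hybrid": "F"}. Transgressive groups
    read as hyper-/hypomethylation for DMRs.
    """
    if dmrs.empty:
        return pd.DataFrame(
            columns=["feature_id", "stage", "omic", "vFE", "vFG", "vEG",
                     "category", "group", "mean_E", "mean_F", "mean_G"]
        )
    e = dmr_replicate_levels(dmrs, per_rep, roles["maternal"])
    f = dmr_replicate_levels(dmrs, per_rep, roles["hybrid"])
    g = dmr_replicate_levels(dmrs, per_rep, roles["paternal"])
    ok = ~(np.isnan(e).any(axis=1) | np.isnan(f).any(axis=1) | np.isnan(g).any(axis=1))
    ids = [
        f"{r.context}:{r.chrom}:{r.start}-{r.end}" for r in dmrs.itertuples(index=False)
    ]
    calls = dominance.classify_trio(
        np.array(ids)[ok], e[ok], f[ok], g[ok], stage=stage, omic="DMR", alpha=alpha
    )
    if (~ok).any():
        missing = pd.DataFrame(
            {
                "feature_id": np.array(ids)[~ok], "stage": stage, "omic": "DMR",
                "vFE": "=", "vFG": "=", "vEG": "=",
                "category": "unclassified", "group": "unclassified",
                "mean_E": np.nan, "mean_F": np.nan, "mean_G": np.nan,
            }
        )
        calls = pd.concat([calls, missing], ignore_index=True)
    return calls


# ---------------------------------------------------------------- CpG islands


def find_cpg_islands(
    seqs: dict[str, str],
    min_gc: float = 0.5,
    min_len: int = 201,
    min_obs_exp: float = 0.6,
    window: int = 100,
) -> pd.DataFrame:
    """CpG islands by sliding-window scan (step 1) with full-span re-audit.

    A window passes when GC fraction >= min_gc and observed/expected CpG
    ratio = CpG_count * L / (C_count * G_count) >= min_obs_exp (windows with
    zero C or G fail; windows containing N are skipped). Overlapping passing
    windows merge; the merged span is re-evaluated on its full length and
    kept only if it passes all three criteria with length >= min_len.
    """
    rows = []
    for chrom in sorted(seqs):
        seq = seqs[chrom].upper()
        L = len(seq)
        if L < window:
            continue
        arr = np.frombuffer(seq.encode(), dtype="S1")
        is_c = (arr == b"C").astype(np.int64)
        is_g = (arr == b"G").astype(np.int64)
        is_n = (~np.isin(arr, [b"A", b"C", b"G", b"T"])).astype(np.int64)
        is_cpg = np.zeros(L, dtype=np.int64)
        is_cpg[:-1] = (arr[:-1] == b"C") & (arr[1:] == b"G")

        def wsum(x, w):
            cs = np.concatenate([[0], np.cumsum(x)])
            return cs[w:] - cs[:-w]

        c_w = wsum(is_c, window)
        g_w = wsum(is_g, window)
        n_w = wsum(is_n, window)
        cpg_w = wsum(is_cpg, window)  # counts CpGs starting in the window
        gc_ok = (c_w + g_w) >= min_gc * window
        with np.errstate(divide="ignore", invalid="ignore"):
            oe = cpg_w * window / (c_w * g_w)
        oe_ok = (c_w > 0) & (g_w > 0) & (oe >= min_obs_exp)
        passing = gc_ok & oe_ok & (n_w == 0)
        starts = np.nonzero(passing)[0]
        if starts.size == 0:
            continue
        # merge windows that overlap or touch
        breaks = np.nonzero(np.diff(starts) > window)[0]
        run_bounds = np.split(starts, breaks + 1)
        for run in run_bounds:
            s, e = int(run[0]), int(run[-1]) + window
            span = e - s
            c_t = int(is_c[s:e].sum())
            g_t = int(is_g[s:e].sum())
            cpg_t = int(is_cpg[s : e - 1].sum())
            gc = (c_t + g_t) / span
            oe_t = cpg_t * span / (c_t * g_t) if c_t and g_t else 0.0
            if span >= min_len and gc >= min_gc and oe_t >= min_obs_exp:
                rows.append(
                    {"chrom": chrom, "start": s, "end": e, "length": span,
                     "gc": gc, "obs_exp": oe_t, "n_cpg": cpg_t}
                )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "length", "gc", "obs_exp", "n_cpg"])
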