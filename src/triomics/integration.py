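"""Joint analysis of expression and methylation layers.

Putative epialleles are differentially expressed genes with an additive or
parent-dominant expression pattern and at least one DMR overlapping their
gene body or 1-kbp promoter whose methylation dominance group matches the
expression group (matching is on the group label; direction concordance is
not additionally required, since both proportional and inverse couplings
occur). Proximity association tests whether differential features sit
inside 5-kbp gene (or DEG) flanks more often than their non-differential
counterparts, with a chi-square test per feature class and BH adjustment
across the family. Methylation-expression coupling is measured with
tie-corrected Kendall tau-b.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust
from .intervals import GeneModel, GenomicInterval, flanks, nearest_gene_distance, overlaps_any

DOMINANT_GROUPS = ("additive", "maternal_dominant", "paternal_dominant")


def _dmr_intervals(dmrs: pd.DataFrame) -> list[GenomicInterval]:
    return [GenomicInterval(r.chrom, int(r.start), int(r.end)) for r in dmrs.itertuples(index=False)]


def find_epialleles(
    eld_calls: pd.DataFrame,
    dmrs: pd.DataFrame,
    mld_calls: pd.DataFrame,
    genes: list[GeneModel],
) -> pd.DataFrame:
    """Genes whose ELD group matches an overlapping DMR's MLD group.

    ``eld_calls``/``mld_calls`` are DominanceCall tables from one stage;
    ``mld_calls.feature_id`` must be the "context:chrom:start-end" DMR key.
    The DMR must overlap the gene body or its 1-kbp promoter; the location
    class records which (gene_body, promoter, or both).
    """
    mld_group = dict(zip(mld_calls["feature_id"], mld_calls["group"]))
    eligible = eld_calls[eld_calls["group"].isin(DOMINANT_GROUPS)]
    gene_of = {g.gene_id: g for g in genes}
    rows = []
    for call in eligible.itertuples(index=False):
        gene = gene_of.get(call.feature_id)
        if gene is None:
            continue
        body = gene.interval
        prom = gene.promoter
        in_body = False
        in_prom = False
        for dmr in dmrs.itertuples(index=False):
            key = f"{dmr.context}:{dmr.chrom}:{dmr.start}-{dmr.end}"
            if mld_group.get(key) != call.group:
                continue
            iv = GenomicInterval(dmr.chrom, int(dmr.start), int(dmr.end))
            if iv.overlaps(body):
                in_body = True
            if prom is not None and iv.overlaps(prom):
                in_prom = True
        if in_body or in_prom:
            loc = "both" if (in_body and in_prom) else ("gene_body" if in_body else "promoter")
            rows.append(
                {"gene_id": call.feature_id, "stage": call.stage,
                 "eld_group": call.group, "mld_group": call.group, "dmr_location": loc}
            )
    return pd.DataFrame(rows, columns=["gene_id", "stage", "eld_group", "mld_group", "dmr_location"])


def proximity_association(
    feature_sets: dict[str, tuple[list[GenomicInterval], list[GenomicInterval]]],
    genes: list[GeneModel],
    deg_ids: set[str],
    flank_bp: int = 5000,
    chrom_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Chi-square association of feature classes with gene/DEG flanks.

    ``feature_sets`` maps a class name to (differential, non-differential)
    interval lists (e.g. DMRs vs matched non-differential regions). For each
    class and each flank universe (all genes; DEGs only), a 2x2 table of
    within-flank x differential is tested with Pearson chi-square (no
    continuity correction); BH adjustment runs across all performed tests.
    Tests with any expected cell below 1 are skipped with a note.
    """
    flank_sets = {"gene": [], "deg": []}
    for g in genes:
        fl = flanks(
            g.interval, flank_bp,
            chrom_lengths.get(g.interval.chrom) if chrom_lengths else None,
        )
        flank_sets["gene"].extend(fl)
        if g.gene_id in deg_ids:
            flank_sets["deg"].extend(fl)
    rows = []
    for cls, (diff_ivs, nondiff_ivs) in sorted(feature_sets.items()):
        for universe, fset in flank_sets.items():
            in_diff = int(overlaps_any(diff_ivs, fset).sum()) if diff_ivs else 0
            in_non = int(overlaps_any(nondiff_ivs, fset).sum()) if nondiff_ivs else 0
            table = np.array(
                [[in_diff, len(diff_ivs) - in_diff], [in_non, len(nondiff_ivs) - in_non]]
            )
            row = {
                "feature_class": cls, "flank_universe": universe,
                "diff_in_flank": in_diff, "diff_out": int(table[0, 1]),
                "nondiff_in_flank": in_non, "nondiff_out": int(table[1, 1]),
                "frac_diff_in_flank": in_diff / len(diff_ivs) if diff_ivs else np.nan,
                "frac_nondiff_in_flank": in_non / len(nondiff_ivs) if nondiff_ivs else np.nan,
            }
            expected = stats.contingency.expected_freq(table) if table.sum() else np.zeros((2, 2))
            if table.sum() == 0 or (expected < 1).any():
                row.update({"chi2": np.nan, "pvalue": np.nan, "skipped": True})
            else:
                chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
                row.update({"chi2": chi2, "pvalue": p, "skipped": False})
            rows.append(row)
    out = pd.DataFrame(rows)
    tested = ~out["skipped"]
    out["padj"] = np.nan
    if tested.any():
        out.loc[tested, "padj"] = bh_adjust(out.loc[tested, "pvalue"].to_numpy())
    return out


def methylation_expression_correlation(
    expression: np.ndarray, methylation: np.ndarray, min_pairs: int = 10
) -> dict:
    """Kendall tau-b between paired expression and methylation values.

    Observations are gene x genotype pairs from one stage. Constant input
    yields tau = NaN (reported as missing rather than raising).
    """
    x = np.asarray(expression, dtype=float)
    y = np.asarray(methylation, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if x.size < min_pairs:
        raise ValueError(f"need >= {min_pairs} paired observations, got {x.size}")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return {"tau": np.nan, "pvalue": np.nan, "n": int(x.size)}
    res = stats.kendalltau(x, y, variant="b", method="asymptotic")
    return {"tau": float(res.statistic), "pvalue": float(res.pvalue), "n": int(x.size)}


def gene_methylation_levels(
    pooled_bins: pd.DataFrame, genes: list[GeneModel], region: str = "gene_body",
    context: str = "CpG",
) -> pd.DataFrame:
    """Read-weighted methylation level per gene x genotype over a region.

    ``region`` is gene_body or promoter. Bins overlapping the region
    contribute their full pooled counts (bin resolution is the unit of
    analysis throughout).
    """
    sub = pooled_bins[pooled_bins["context"] == context]
    bin_size = int(sub["bin_size"].iloc[0]) if "bin_size" in sub and len(sub) else 1000
    rows = []
    for g in genes:
        iv = g.interval if region == "gene_body" else g.promoter
        if iv is None:
            continue
        hit = sub[
            (sub["chrom"] == iv.chrom)
            & (sub["bin_start"] < iv.end)
            & (sub["bin_start"] + bin_size > iv.start)
        ]
        for genotype, grp in hit.groupby("genotype"):
            tot = grp["total"].sum()
            if tot > 0:
                rows.append(
                    {"gene_id": g.gene_id, "genotype": genotype,
                     "level": grp["meth"].sum() / tot}
                )
    return pd.DataFrame(rows, columns=["gene_id", "genotype", "level"])


def dmr_feature_composition(
    dmrs: pd.DataFrame,
    genes: list[GeneModel],
    repeats: list[GenomicInterval],
    flank_bp: int = 5000,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fraction of DMRs in promoters/exons/introns/repeats + gene distances.

    Classes are not mutually exclusive: a DMR inside both an exon and a
    repeat counts in both. Returns (composition, per_dmr) where per_dmr
    carries each DMR's class flags, distance to the nearest gene and
    whether it lies within ``flank_bp`` of one (overlap counts as distance 0).
    """
    ivs = _dmr_intervals(dmrs)
    promoters = [g.promoter for g in genes if g.promoter is not None]
    exons = [e for g in genes for e in g.exons]
    introns = [i for g in genes for i in g.introns]
    per = pd.DataFrame(
        {
            "chrom": dmrs["chrom"].to_numpy(),
            "start": dmrs["start"].to_numpy(),
            "end": dmrs["end"].to_numpy(),
            "in_promoter": overlaps_any(ivs, promoters),
            "in_exon": overlaps_any(ivs, exons),
            "in_intron": overlaps_any(ivs, introns),
            "in_repeat": overlaps_any(ivs, repeats),
        }
    )
    dist = nearest_gene_distance(ivs, genes)
    per["distance_to_gene"] = [d for d, _ in dist]
    per["nearest_gene"] = [gid for _, gid in dist]
    # gap strictly below flank_bp <=> overlap with the half-open flank interval
    per["within_flank"] = [d is not None and d < flank_bp for d, _ in dist]
    n = len(per)
    comp = pd.DataFrame(
        {
            "feature_class": ["promoter", "exon", "intron", "repeat", f"within_{flank_bp}bp_of_gene"],
            "fraction": [
                per["in_promoter"].mean() if n else np.nan,
                per["in_exon"].mean() if n else np.nan,
                per["in_intron"].mean() if n else np.nan,
                per["in_repeat"].mean() if n else np.nan,
                per["within_flank"].mean() if n else np.nan,
            ],
        }
    )
    return comp, per
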