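"""Small-RNA cluster classification.

Clusters are classified from their primary-read length histogram and
upstream-provided secondary-structure evidence: miRNA candidates need >=80%
of primary reads at 20-24 nt, fewer than 5 unpaired bases and a hairpin
flag in {Y, N15, N14, N13}; putative 24-nt siRNA clusters need >=80% of
primary reads at exactly 24 nt and no miRNA selection flags (the miRNA rule
is applied first). Everything else is "other". Clusters with zero coverage
in all samples are dropped before classification.
"""

from __future__ import annotations

import pandas as pd

MIRNA_FLAGS = {"Y", "N15", "N14", "N13"}
MIRNA_CLASS = "miRNA_candidate"
SIRNA_CLASS = "putative_siRNA"
OTHER_CLASS = "other"


def parse_length_histogram(text: str) -> dict[int, int]:
    """Parse 'len:count,len:count' histogram strings."""
    out: dict[int, int] = {}
    for part in str(text).split(","):
        if not part:
            continue
        length, count = part.split(":")
        out[int(length)] = int(count)
    return out


def format_length_histogram(hist: dict[int, int]) -> str:
    return ",".join(f"{k}:{v}" for k, v in sorted(hist.items()))


def classify_cluster(
    length_histogram: dict[int, int],
    unpaired_bases: int | None,
    hairpin_flag: str,
    mirna_min_frac: float = 0.80,
    sirna_min_frac: float = 0.80,
    max_unpaired: int = 5,
) -> str:
    """Classify one cluster; raises on an empty histogram."""
    total = sum(length_histogram.values())
    if total <= 0:
        raise ValueError("empty primary-read length histogram")
    frac_20_24 = sum(c for l, c in length_histogram.items() if 20 <= l <= 24) / total
    frac_24 = length_histogram.get(24, 0) / total
    is_mirna = (
        frac_20_24 >= mirna_min_frac
        and unpaired_bases is not None
        and unpaired_bases < max_unpaired
        and hairpin_flag in MIRNA_FLAGS
    )
    if is_mirna:
        return MIRNA_CLASS
    if frac_24 >= sirna_min_frac:
        return SIRNA_CLASS
    return OTHER_CLASS


def classify_clusters(clusters: pd.DataFrame, count_columns: list[str]) -> pd.DataFrame:
    """Classify a cluster table; drops clusters with zero total coverage.

    Expects columns ``length_histogram`` (string dialect), ``unpaired_bases``
    and ``hairpin_flag`` plus the per-sample count columns.
    """
    kept = clusters[clusters[count_columns].sum(axis=1) > 0].copy()
    kept["srna_class"] = [
        classify_cluster(
            parse_length_histogram(row.length_histogram),
            None if pd.isna(row.unpaired_bases) else int(row.unpaired_bases),
            str(row.hairpin_flag),
        )
        for row in kept.itertuples(index=False)
    ]
    return kept
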