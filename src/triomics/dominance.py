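"""Expression/methylation level dominance classification in trios.

A differential feature (gene, miRNA cluster, siRNA cluster or DMR) is
classified by how the hybrid's level F relates to the maternal parent E and
the paternal parent G, into twelve categories collapsed into five groups:

* additive {I, XII} — all three genotypes differ, F between the parents;
* paternal dominant {II, XI} — F indistinguishable from G, both differ from E;
* maternal dominant {IV, IX} — F indistinguishable from E, both differ from G;
* transgressive up {III, VII, X} — F above both parents;
* transgressive down {V, VI, VIII} — F below both parents.

A genotype pair counts as different only when BOTH a two-sample Student
t-test and a three-group Tukey HSD separate it at alpha = 0.05 (conservative
conjunction of the two tests). Any verdict combination outside the decision
table (e.g. a non-transitive Tukey outcome) is reported as unclassified.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats

GROUP_OF_CATEGORY = {
    "I": "additive", "XII": "additive",
    "II": "paternal_dominant", "XI": "paternal_dominant",
    "IV": "maternal_dominant", "IX": "maternal_dominant",
    "III": "transgressive_up", "VII": "transgressive_up", "X": "transgressive_up",
    "V": "transgressive_down", "VI": "transgressive_down", "VIII": "transgressive_down",
}
CATEGORIES = tuple(GROUP_OF_CATEGORY)
GROUPS = (
    "additive", "maternal_dominant", "paternal_dominant",
    "transgressive_up", "transgressive_down",
)
VERDICT_SYMBOL = {-1: "<", 0: "=", 1: ">"}


@dataclass(frozen=True)
class DominanceCall:
    feature_id: str
    stage: str
    omic: str
    v_fe: str   # hybrid vs maternal
    v_fg: str   # hybrid vs paternal
    v_eg: str   # maternal vs paternal
    category: str
    group: str
    mean_e: float
    mean_f: float
    mean_g: float


@lru_cache(maxsize=None)
def _t_crit(df: int, alpha: float) -> float:
    return float(stats.t.ppf(1 - alpha / 2, df))


@lru_cache(maxsize=None)
def _q_crit(k: int, df: int, alpha: float) -> float:
    return float(stats.studentized_range.ppf(1 - alpha, k, df))


def _pair_t_sig(m1, v1, n1, m2, v2, n2, alpha, equal_var):
    """Vectorized two-sample t significance (arrays over features)."""
    if equal_var:
        df = n1 + n2 - 2
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
        se = np.sqrt(sp2 * (1 / n1 + 1 / n2))
        crit = _t_crit(df, alpha)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.abs(m1 - m2) / se
        # zero pooled variance: different means separate perfectly
        return np.where(se == 0, m1 != m2, t > crit)
    se2 = v1 / n1 + v2 / n2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.abs(m1 - m2) / np.sqrt(se2)
        df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    sig = np.zeros_like(t, dtype=bool)
    ok = se2 > 0
    if np.any(ok):
        sig[ok] = t[ok] > stats.t.ppf(1 - alpha / 2, df[ok])
    return np.where(se2 == 0, m1 != m2, sig)


def trio_verdicts(
    e: np.ndarray, f: np.ndarray, g: np.ndarray,
    alpha: float = 0.05, equal_var: bool = True,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Verdict codes (-1/0/+1) for v(F,E), v(F,G), v(E,G) per feature.

    ``e``, ``f``, ``g`` are (n_features, n_replicates) arrays of replicate-
    level values (normalized counts for ELD, DMR methylation levels for
    MLD). Replicate counts may differ between genotypes. A pair's verdict is
    nonzero only when both the Student t-test and Tukey HSD (3 groups,
    df = N - 3, studentized-range distribution) reject at ``alpha``.
    """
    e, f, g = (np.atleast_2d(np.asarray(x, dtype=float)) for x in (e, f, g))
    ns = [x.shape[1] for x in (e, f, g)]
    if min(ns) < 2:
        raise ValueError("need >=2 replicates per genotype")
    means = [x.mean(axis=1) for x in (e, f, g)]
    varis = [x.var(axis=1, ddof=1) for x in (e, f, g)]
    n_tot = sum(ns)
    df_tukey = n_tot - 3
    mse = sum((n - 1) * v for n, v in zip(ns, varis)) / df_tukey
    qc = _q_crit(3, df_tukey, alpha)

    def verdict(i: int, j: int) -> np.ndarray:
        mi, mj = means[i], means[j]
        t_sig = _pair_t_sig(mi, varis[i], ns[i], mj, varis[j], ns[j], alpha, equal_var)
        se = np.sqrt(mse / 2 * (1 / ns[i] + 1 / ns[j]))
        with np.errstate(divide="ignore", invalid="ignore"):
            q = np.abs(mi - mj) / se
        tukey_sig = np.where(se == 0, mi != mj, q > qc)
        return np.sign(mi - mj).astype(int) * (t_sig & tukey_sig)

    # index order: 0=E, 1=F, 2=G
    return verdict(1, 0), verdict(1, 2), verdict(0, 2)


def pairwise_tests(
    e, f, g, alpha: float = 0.05, equal_var: bool = True
) -> tuple[str, str, str]:
    """Single-feature convenience wrapper returning '<'/'='/'>' verdicts."""
    vfe, vfg, veg = trio_verdicts(
        np.asarray(e)[None, :], np.asarray(f)[None, :], np.asarray(g)[None, :],
        alpha=alpha, equal_var=equal_var,
    )
    return tuple(VERDICT_SYMBOL[int(v[0])] for v in (vfe, vfg, veg))


def classify_verdicts(v_fe: int, v_fg: int, v_eg: int) -> tuple[str, str]:
    """Map one verdict triple to (category, group) by the decision table."""
    if v_fe > 0 and v_fg > 0:
        if v_eg == 0:
            return "III", "transgressive_up"
        return ("VII" if v_eg < 0 else "X"), "transgressive_up"
    if v_fe < 0 and v_fg < 0:
        if v_eg == 0:
            return "VI", "transgressive_down"
        return ("V" if v_eg < 0 else "VIII"), "transgressive_down"
    if v_fg == 0 and v_fe != 0 and v_eg != 0:
        return ("II" if v_fe > 0 else "XI"), "paternal_dominant"
    if v_fe == 0 and v_fg != 0 and v_eg != 0:
        return ("IV" if v_fg > 0 else "IX"), "maternal_dominant"
    if v_fe != 0 and v_fg != 0 and v_eg != 0 and v_fe * v_fg < 0:
        # hybrid strictly between the parents by both tests and means
        return ("I" if v_eg < 0 else "XII"), "additive"
    return "unclassified", "unclassified"


def classify(
    verdicts: tuple[str, str, str], means: tuple[float, float, float]
) -> tuple[str, str]:
    """Classify symbolic verdicts (v_FE, v_FG, v_EG) with means (E, F, G)."""
    code = {"<": -1, "=": 0, ">": 1}
    return classify_verdicts(code[verdicts[0]], code[verdicts[1]], code[verdicts[2]])


def classify_trio(
    feature_ids,
    e: np.ndarray, f: np.ndarray, g: np.ndarray,
    stage: str, omic: str,
    is_differential: np.ndarray | None = None,
    alpha: float = 0.05, equal_var: bool = True,
    log_transform: bool = False,
) -> pd.DataFrame:
    """Classify a block of features; non-differential features are unclassified.

    ``log_transform`` applies log2(x + 1) before testing — the variance-
    stabilizing choice for normalized counts, whose variance grows with the
    mean and would otherwise dominate the pooled Tukey MSE; methylation
    proportions are bounded and are tested untransformed. Reported means
    are always on the original scale. Returns the DominanceCall table.
    """
    e, f, g = (np.atleast_2d(np.asarray(x, dtype=float)) for x in (e, f, g))
    n = e.shape[0]
    if is_differential is None:
        is_differential = np.ones(n, dtype=bool)
    if log_transform:
        te, tf, tg = (np.log2(x + 1.0) for x in (e, f, g))
    else:
        te, tf, tg = e, f, g
    v_fe, v_fg, v_eg = trio_verdicts(te, tf, tg, alpha=alpha, equal_var=equal_var)
    me, mf, mg = e.mean(axis=1), f.mean(axis=1), g.mean(axis=1)
    cats, groups = [], []
    for i in range(n):
        if not is_differential[i]:
            cats.append("unclassified")
            groups.append("unclassified")
            continue
        cat, grp = classify_verdicts(int(v_fe[i]), int(v_fg[i]), int(v_eg[i]))
        cats.append(cat)
        groups.append(grp)
    return pd.DataFrame(
        {
            "feature_id": list(feature_ids),
            "stage": stage,
            "omic": omic,
            "vFE": [VERDICT_SYMBOL[int(v)] for v in v_fe],
            "vFG": [VERDICT_SYMBOL[int(v)] for v in v_fg],
            "vEG": [VERDICT_SYMBOL[int(v)] for v in v_eg],
            "category": cats,
            "group": groups,
            "mean_E": me,
            "mean_F": mf,
            "mean_G": mg,
        }
    )


def dominance_summary(calls: pd.DataFrame, by=("stage", "omic")) -> pd.DataFrame:
    """Percentage of each collapsed group among classified features.

    One row per combination of ``by``; columns are the five groups plus the
    count of classified features.
    """
    rows = []
    for key, sub in calls.groupby(list(by), sort=True):
        classified = sub[sub["group"] != "unclassified"]
        total = len(classified)
        row = dict(zip(by, key if isinstance(key, tuple) else (key,)))
        row["n_classified"] = total
        for grp in GROUPS:
            row[grp] = 100.0 * (classified["group"] == grp).sum() / total if total else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def shared_across_stages(calls: pd.DataFrame) -> pd.DataFrame:
    """Features keeping one identical (non-unclassified) group in all stages."""
    n_stages = calls["stage"].nunique()
    out = []
    for (omic, fid), sub in calls.groupby(["omic", "feature_id"], sort=True):
        groups = set(sub["group"])
        if len(sub) == n_stages and len(groups) == 1 and "unclassified" not in groups:
            out.append({"omic": omic, "feature_id": fid, "group": sub["group"].iloc[0]})
    return pd.DataFrame(out, columns=["omic", "feature_id", "group"])
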