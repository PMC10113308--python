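"""Trio dataset simulator with machine-readable planted truth.

Generates everything the downstream stages consume — replicate count
matrices with planted 12-category dominance structure, per-cytosine
methylation reports with planted DMRs, a genome FASTA with planted CpG
islands, gene/TE/centromere annotation, windowed coverage with planted
deletions/duplications, and sRNA cluster tables — from one
:class:`SimulationConfig` and one seed. Every planted feature is emitted in
a TSV truth sidecar so recovery can be measured exactly.

Counts are negative binomial via a gamma-Poisson mixture with a constant
dispersion across features (variance mu + alpha * mu^2). Methylated read
counts are Binomial(depth, p) with Poisson per-cytosine depth; contexts are
derived from the generated genome sequence, so the CpG-island scanner and
the methylome share one genome. Genotype labels follow the trio notation:
E = maternal parent, G = paternal parent, F = hybrid.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import methylation
from .diffexpr import TrioCountMatrix
from .dominance import CATEGORIES, GROUP_OF_CATEGORY
from .intervals import GeneModel, GenomicInterval
from .srna import MIRNA_CLASS, OTHER_CLASS, SIRNA_CLASS, format_length_histogram

GENOTYPES = {"maternal": "E", "paternal": "G", "hybrid": "F"}
CLASS_LABELS = CATEGORIES + ("null",)

# per-context background methylation proportions (CpG highest, CHH lowest)
CONTEXT_BASE_P = {"CpG": 0.8, "CHG": 0.5, "CHH": 0.2}


class ConfigurationError(ValueError):
    pass


@dataclass
class SimulationConfig:
    seed: int = 0
    n_chromosomes: int = 2
    chrom_length_bp: int = 300_000
    n_genes: int = 120
    gc_content: float = 0.36
    stage: str = "OS15"
    # counts
    n_features_per_class: dict = field(
        default_factory=lambda: {c: 25 for c in CLASS_LABELS}
    )
    base_mean: float = 50.0
    base_mean_log_sd: float = 0.4
    fold_change: float = 4.0
    nb_dispersion: float = 0.05
    n_replicates: int = 3
    # methylation
    n_meth_replicates: int = 2
    meth_depth: float = 30.0
    dmr_delta: float = 0.5
    dmr_base_low: float = 0.3
    n_dmrs_per_class: dict = field(
        default_factory=lambda: {c: 3 for c in CATEGORIES}
    )
    dmr_context: str = "CpG"
    meth_bin_size: int = 1000
    # coverage / CNV: list of (chrom, start, end, multiplier)
    cnv_spec: list = field(default_factory=list)
    coverage_window_bp: int = 1000
    coverage_mean: float = 30.0
    # islands: list of (chrom, start, end)
    island_spec: list = field(default_factory=list)
    # sRNA
    n_srna_per_class: dict = field(
        default_factory=lambda: {MIRNA_CLASS: 20, SIRNA_CLASS: 20, OTHER_CLASS: 10}
    )
    # annotation
    gene_length_bp: int = 2000
    n_tes: int = 40
    te_length_bp: int = 800

    def __post_init__(self) -> None:
        for label in self.n_features_per_class:
            if label not in CLASS_LABELS:
                raise ConfigurationError(f"unknown dominance category {label!r}")
        for label in self.n_dmrs_per_class:
            if label not in CLASS_LABELS:
                raise ConfigurationError(f"unknown dominance category {label!r}")
        if self.fold_change <= 1:
            raise ConfigurationError("fold_change must exceed 1")
        if self.n_replicates < 2 or self.n_meth_replicates < 2:
            raise ConfigurationError("need >=2 replicates per genotype")
        if self.meth_depth <= 0:
            raise ConfigurationError("meth_depth must be positive")
        if not 0 <= self.dmr_delta <= 1:
            raise ConfigurationError("dmr_delta must lie in [0, 1]")
        if self.dmr_base_low + self.dmr_delta > 1 or self.dmr_base_low < 0:
            raise ConfigurationError(
                f"planted proportions {self.dmr_base_low} + {self.dmr_delta} leave [0, 1]"
            )
        for chrom, start, end, _ in self.cnv_spec:
            self._check_interval(chrom, start, end, "cnv_spec")
        for chrom, start, end in self.island_spec:
            self._check_interval(chrom, start, end, "island_spec")

    def _check_interval(self, chrom, start, end, what) -> None:
        if not (0 <= start < end <= self.chrom_length_bp):
            raise ConfigurationError(
                f"{what} interval {chrom}:{start}-{end} outside chromosome bounds"
            )
        if chrom not in self.chrom_names:
            raise ConfigurationError(f"{what} names unknown chromosome {chrom!r}")

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: self.chrom_length_bp for c in self.chrom_names}

    def config_hash(self) -> str:
        payload = repr(sorted(asdict(self).items())).encode()
        return hashlib.md5(payload).hexdigest()[:12]

    def rng(self, stream: str) -> np.random.Generator:
        """Independent deterministic substream per generation stage."""
        digest = hashlib.sha256(f"{self.seed}:{stream}".encode()).digest()
        return np.random.default_rng(int.from_bytes(digest[:4], "big"))


def class_mean_multipliers(category: str, fold_change: float) -> tuple[float, float, float]:
    """(E, F, G) mean multipliers planting the given dominance pattern.

    Every pair of distinct planted levels is separated by the full
    fold-change (levels come from {1, f, f^2}), so the effect size of each
    detectable contrast is the configured one.
    """
    f = fold_change
    table = {
        "null": (1, 1, 1),
        "I": (1, f, f * f), "XII": (f * f, f, 1),
        "II": (1, f, f), "XI": (f, 1, 1),
        "IV": (f, f, 1), "IX": (1, 1, f),
        "III": (1, f, 1), "VI": (f, 1, f),
        "VII": (1, f * f, f), "X": (f, f * f, 1),
        "V": (f, 1, f * f), "VIII": (f * f, 1, f),
    }
    if category not in table:
        raise ConfigurationError(f"unknown dominance category {category!r}")
    return table[category]


def _nb_counts(rng, mean: np.ndarray, dispersion: float, n_reps: int) -> np.ndarray:
    """Gamma-Poisson draws, shape (len(mean), n_reps)."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(np.repeat(mean[:, None], n_reps, axis=1))
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean[:, None] * dispersion, size=(mean.size, n_reps))
    return rng.poisson(lam)


def simulate_trio_counts(
    config: SimulationConfig, prefix: str = "gene"
) -> tuple[TrioCountMatrix, pd.DataFrame]:
    """Counts with planted dominance categories + truth sidecar table."""
    rng = config.rng(f"counts:{prefix}")
    cats = [c for c in CLASS_LABELS for _ in range(config.n_features_per_class.get(c, 0))]
    n = len(cats)
    ids = [f"{prefix}_{i:05d}" for i in range(n)]
    if config.base_mean_log_sd > 0:
        base = config.base_mean * np.exp(
            rng.normal(0.0, config.base_mean_log_sd, size=n)
        )
    else:
        base = np.full(n, config.base_mean)
    mult = np.array([class_mean_multipliers(c, config.fold_change) for c in cats])
    means = base[:, None] * mult  # columns E, F, G
    blocks, samples, design_rows = [], [], []
    for role, label in GENOTYPES.items():
        col = {"E": 0, "F": 1, "G": 2}[label]
        blocks.append(_nb_counts(rng, means[:, col], config.nb_dispersion, config.n_replicates))
        for rep in range(1, config.n_replicates + 1):
            samples.append(f"{label}_rep{rep}")
            design_rows.append((f"{label}_rep{rep}", role, config.stage, rep))
    counts = pd.DataFrame(np.hstack(blocks), index=pd.Index(ids, name="feature_id"), columns=samples)
    design = pd.DataFrame(
        design_rows, columns=["sample_id", "genotype_role", "stage", "replicate"]
    ).set_index("sample_id")
    truth = pd.DataFrame(
        {
            "feature_id": ids,
            "category": cats,
            "group": [GROUP_OF_CATEGORY.get(c, "null") for c in cats],
            "mean_E": means[:, 0], "mean_F": means[:, 1], "mean_G": means[:, 2],
        }
    )
    return TrioCountMatrix(counts, design), truth


# ---------------------------------------------------------------- genome


def simulate_genome(config: SimulationConfig) -> dict:
    """FASTA sequences, gene models, TE/centromere tracks, island truth."""
    rng = config.rng("genome")
    bases = np.array(list("ACGT"))
    p_gc = config.gc_content / 2
    probs = [(1 - config.gc_content) / 2, p_gc, p_gc, (1 - config.gc_content) / 2]
    seqs: dict[str, str] = {}
    for chrom in config.chrom_names:
        seq = rng.choice(bases, size=config.chrom_length_bp, p=probs)
        seqs[chrom] = "".join(seq)
    # plant CpG-rich islands as CG dinucleotide repeats
    for chrom, start, end in config.island_spec:
        block = "CG" * ((end - start + 1) // 2)
        seqs[chrom] = seqs[chrom][:start] + block[: end - start] + seqs[chrom][end:]

    genes: list[GeneModel] = []
    per_chrom = int(np.ceil(config.n_genes / config.n_chromosomes))
    spacing = config.chrom_length_bp // (per_chrom + 1)
    gi = 0
    for chrom in config.chrom_names:
        for k in range(per_chrom):
            if gi >= config.n_genes:
                break
            start = (k + 1) * spacing
            end = start + config.gene_length_bp
            if end > config.chrom_length_bp:
                break
            strand = "+" if gi % 2 == 0 else "-"
            iv = GenomicInterval(chrom, start, end, strand)
            third = config.gene_length_bp // 3
            exons = (
                GenomicInterval(chrom, start, start + third, strand),
                GenomicInterval(chrom, end - third, end, strand),
            )
            genes.append(GeneModel(f"gene_{gi:05d}", iv, exons))
            gi += 1
    seen = set()
    for g in genes:
        if g.gene_id in seen:
            raise ConfigurationError(f"duplicate gene ID {g.gene_id}")
        seen.add(g.gene_id)

    tes = []
    for _ in range(config.n_tes):
        chrom = config.chrom_names[int(rng.integers(config.n_chromosomes))]
        start = int(rng.integers(0, config.chrom_length_bp - config.te_length_bp))
        tes.append(GenomicInterval(chrom, start, start + config.te_length_bp))
    tes.sort()
    centromeres = [
        GenomicInterval(c, config.chrom_length_bp // 2 - 5000, config.chrom_length_bp // 2 + 5000)
        for c in config.chrom_names
    ]
    island_truth = pd.DataFrame(
        [{"chrom": c, "start": s, "end": e} for c, s, e in config.island_spec],
        columns=["chrom", "start", "end"],
    )
    return {"seqs": seqs, "genes": genes, "tes": tes, "centromeres": centromeres,
            "island_truth": island_truth}


# ---------------------------------------------------------------- methylome


def _mld_proportions(category: str, low: float, delta: float) -> tuple[float, float, float]:
    """(pE, pF, pG) planting the dominance pattern on methylation levels."""
    lo, hi, mid = low, low + delta, low + delta / 2
    table = {
        "null": (lo, lo, lo),
        "I": (lo, mid, hi), "XII": (hi, mid, lo),
        "II": (lo, hi, hi), "XI": (hi, lo, lo),
        "IV": (hi, hi, lo), "IX": (lo, lo, hi),
        "III": (lo, hi, lo), "VI": (hi, lo, hi),
        "VII": (lo, hi, mid), "X": (mid, hi, lo),
        "V": (mid, lo, hi), "VIII": (hi, lo, mid),
    }
    if category not in table:
        raise ConfigurationError(f"unknown dominance category {category!r}")
    return table[category]


def simulate_methylome(
    config: SimulationConfig, seqs: dict[str, str]
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame, pd.DataFrame]:
    """Per-sample CX reports with planted DMR/MLD structure.

    Returns (cx_by_sample, design, truth). Planted regions occupy whole
    bins of ``meth_bin_size`` in the configured context, chosen away from
    planted islands and chromosome ends; the truth table carries the
    planted proportions and per-pair differences.
    """
    rng = config.rng("methylome")
    contexts = {c: methylation.cytosine_contexts(seqs[c], c) for c in sorted(seqs)}
    bin_size = config.meth_bin_size
    island_bins = {
        (c, b)
        for c, s, e in config.island_spec
        for b in range(s // bin_size, (e - 1) // bin_size + 1)
    }
    usable = [
        (chrom, b * bin_size)
        for chrom in sorted(seqs)
        for b in range(1, len(seqs[chrom]) // bin_size - 1)
        if (chrom, b) not in island_bins
    ]
    wanted = [
        (cat, i)
        for cat in CLASS_LABELS
        for i in range(config.n_dmrs_per_class.get(cat, 0))
    ]
    if len(wanted) > len(usable):
        raise ConfigurationError("more planted DMRs than usable bins")
    order = rng.permutation(len(usable))
    planted = {}
    truth_rows = []
    for j, (cat, _) in enumerate(wanted):
        chrom, start = usable[order[j]]
        p_e, p_f, p_g = _mld_proportions(cat, config.dmr_base_low, config.dmr_delta)
        planted[(chrom, start)] = (p_e, p_f, p_g)
        truth_rows.append(
            {
                "chrom": chrom, "start": start, "end": start + bin_size,
                "context": config.dmr_context, "category": cat,
                "group": GROUP_OF_CATEGORY.get(cat, "null"),
                "p_E": p_e, "p_F": p_f, "p_G": p_g,
                "delta_EG": p_e - p_g, "delta_EF": p_e - p_f, "delta_FG": p_f - p_g,
            }
        )
    truth = pd.DataFrame(
        truth_rows,
        columns=["chrom", "start", "end", "context", "category", "group",
                 "p_E", "p_F", "p_G", "delta_EG", "delta_EF", "delta_FG"],
    )

    cx_by_sample: dict[str, pd.DataFrame] = {}
    design_rows = []
    for role, label in GENOTYPES.items():
        col = {"E": 0, "F": 1, "G": 2}[label]
        for rep in range(1, config.n_meth_replicates + 1):
            sample = f"{label}_meth{rep}"
            frames = []
            for chrom in sorted(seqs):
                ctx = contexts[chrom]
                p = ctx["context"].map(CONTEXT_BASE_P).to_numpy(dtype=float)
                bin_start = (ctx["pos"].to_numpy() - 1) // bin_size * bin_size
                in_target_ctx = (ctx["context"] == config.dmr_context).to_numpy()
                for (pchrom, pstart), props in planted.items():
                    if pchrom != chrom:
                        continue
                    mask = (bin_start == pstart) & in_target_ctx
                    p[mask] = props[col]
                depth = rng.poisson(config.meth_depth, size=len(ctx))
                meth = rng.binomial(depth, p)
                frames.append(
                    pd.DataFrame(
                        {
                            "chrom": chrom,
                            "pos": ctx["pos"].to_numpy(),
                            "strand": ctx["strand"].to_numpy(),
                            "count_methylated": meth,
                            "count_unmethylated": depth - meth,
                            "context": ctx["context"].to_numpy(),
                            "trinucleotide": ctx["trinucleotide"].to_numpy(),
                        }
                    )
                )
            cx_by_sample[sample] = pd.concat(frames, ignore_index=True)
            design_rows.append((sample, role, config.stage, rep))
    design = pd.DataFrame(
        design_rows, columns=["sample_id", "genotype_role", "stage", "replicate"]
    ).set_index("sample_id")
    return cx_by_sample, design, truth


# ---------------------------------------------------------------- coverage


def simulate_coverage(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Windowed depth with planted CNVs; truth from cnv_spec multipliers."""
    rng = config.rng("coverage")
    w = config.coverage_window_bp
    rows = []
    for chrom in config.chrom_names:
        starts = np.arange(0, config.chrom_length_bp, w)
        mean = np.full(starts.size, config.coverage_mean)
        for c, s, e, mult in config.cnv_spec:
            if c == chrom:
                inside = (starts >= s) & (starts < e)
                mean[inside] = config.coverage_mean * mult
        depth = rng.poisson(mean)
        rows.append(pd.DataFrame({"chrom": chrom, "start": starts, "depth": depth}))
    truth = pd.DataFrame(
        [
            {"chrom": c, "start": s, "end": e,
             "cnv_type": "deletion" if m < 1 else "duplication"}
            for c, s, e, m in config.cnv_spec
            if m != 1
        ],
        columns=["chrom", "start", "end", "cnv_type"],
    )
    return pd.concat(rows, ignore_index=True), truth


# ---------------------------------------------------------------- sRNA


def simulate_srna_clusters(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, TrioCountMatrix, pd.DataFrame]:
    """Cluster table with planted sRNA classes and planted count structure."""
    rng = config.rng("srna")
    classes = [
        cls for cls in (MIRNA_CLASS, SIRNA_CLASS, OTHER_CLASS)
        for _ in range(config.n_srna_per_class.get(cls, 0))
    ]
    n = len(classes)
    # expression categories cycle through the taxonomy so sRNA dominance is testable
    expr_cats = [CLASS_LABELS[i % len(CLASS_LABELS)] for i in range(n)]
    counts_cfg = SimulationConfig(
        seed=config.seed + 1,
        n_chromosomes=config.n_chromosomes,
        chrom_length_bp=config.chrom_length_bp,
        n_features_per_class={},
        fold_change=config.fold_change,
        nb_dispersion=config.nb_dispersion,
        n_replicates=config.n_replicates,
        stage=config.stage,
    )
    # plant counts directly (categories here follow expr_cats, not a per-class map)
    base = counts_cfg.base_mean * np.exp(rng.normal(0, counts_cfg.base_mean_log_sd, size=n))
    mult = np.array([class_mean_multipliers(c, config.fold_change) for c in expr_cats])
    means = base[:, None] * mult
    blocks, samples, design_rows = [], [], []
    for role, label in GENOTYPES.items():
        col = {"E": 0, "F": 1, "G": 2}[label]
        blocks.append(_nb_counts(rng, means[:, col], config.nb_dispersion, config.n_replicates))
        for rep in range(1, config.n_replicates + 1):
            samples.append(f"{label}_srna{rep}")
            design_rows.append((f"{label}_srna{rep}", role, config.stage, rep))
    ids = [f"cluster_{i:05d}" for i in range(n)]
    counts = pd.DataFrame(np.hstack(blocks), index=pd.Index(ids, name="feature_id"), columns=samples)
    design = pd.DataFrame(
        design_rows, columns=["sample_id", "genotype_role", "stage", "replicate"]
    ).set_index("sample_id")

    width = 500
    spacing = max(config.chrom_length_bp // (n // config.n_chromosomes + 2), width + 1)
    rows = []
    for i, cls in enumerate(classes):
        chrom = config.chrom_names[i % config.n_chromosomes]
        start = (i // config.n_chromosomes + 1) * spacing
        total = int(rng.integers(50, 200))
        if cls == MIRNA_CLASS:
            n21 = int(round(total * 0.9))
            hist = {21: n21, 24: total - n21}
            unpaired, flag = int(rng.integers(0, 5)), "Y"
        elif cls == SIRNA_CLASS:
            hist = {24: total}
            unpaired, flag = int(rng.integers(5, 30)), "N"
        else:
            n18 = int(round(total * 0.6))
            hist = {18: n18, 24: total - n18}
            unpaired, flag = int(rng.integers(5, 30)), "N"
        rows.append(
            {
                "cluster_id": ids[i], "chrom": chrom, "start": start, "end": start + width,
                "length_histogram": format_length_histogram(hist),
                "unpaired_bases": unpaired, "hairpin_flag": flag,
            }
        )
    clusters = pd.DataFrame(rows)
    truth = pd.DataFrame(
        {"cluster_id": ids, "srna_class": classes, "category": expr_cats,
         "group": [GROUP_OF_CATEGORY.get(c, "null") for c in expr_cats]}
    )
    return clusters, TrioCountMatrix(counts, design), truth
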