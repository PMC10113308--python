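import numpy as np
import pandas as pd
import pytest

from triomics import methylation, simulate
from triomics.simulate import ConfigurationError, SimulationConfig, class_mean_multipliers


class TestConfigValidation:
    def test_unknown_category_rejected(self):
        with pytest.raises(ConfigurationError, match="category"):
            SimulationConfig(n_features_per_class={"XIII": 5})

    def test_dmr_delta_outside_unit_interval_rejected(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(dmr_delta=1.5)
        with pytest.raises(ConfigurationError, match=r"\[0, 1\]"):
            SimulationConfig(dmr_delta=0.9, dmr_base_low=0.3)

    def test_cnv_outside_chromosome_rejected(self):
        with pytest.raises(ConfigurationError, match="bounds"):
            SimulationConfig(chrom_length_bp=1000, cnv_spec=[("chr1", 0, 5000, 0.1)])

    def test_fold_change_must_exceed_one(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(fold_change=1.0)


class TestTrioCounts:
    def test_category_ii_plants_expected_means(self):
        cfg = SimulationConfig(
            seed=1, n_features_per_class={"II": 400}, base_mean=50,
            base_mean_log_sd=0.0, fold_change=4,
        )
        matrix, truth = simulate.simulate_trio_counts(cfg)
        assert (truth["mean_E"] == 50).all()
        assert (truth["mean_F"] == 200).all()
        assert (truth["mean_G"] == 200).all()
        emp_e = matrix.counts[matrix.samples("maternal")].to_numpy().mean()
        emp_f = matrix.counts[matrix.samples("hybrid")].to_numpy().mean()
        assert emp_e == pytest.approx(50, rel=0.05)
        assert emp_f == pytest.approx(200, rel=0.05)

    def test_null_config_has_no_expected_differences(self):
        cfg = SimulationConfig(seed=2, n_features_per_class={"null": 2000},
                               base_mean_log_sd=0.0)
        matrix, truth = simulate.simulate_trio_counts(cfg)
        assert (truth[["mean_E", "mean_F", "mean_G"]].nunique(axis=1) == 1).all()
        means = {
            role: matrix.counts[matrix.samples(role)].to_numpy().mean()
            for role in ("maternal", "paternal", "hybrid")
        }
        vals = list(means.values())
        assert max(vals) - min(vals) < 0.05 * np.mean(vals)

    def test_same_seed_reproduces_identical_matrices(self):
        cfg = SimulationConfig(seed=7)
        m1, t1 = simulate.simulate_trio_counts(cfg)
        m2, t2 = simulate.simulate_trio_counts(SimulationConfig(seed=7))
        pd.testing.assert_frame_equal(m1.counts, m2.counts)
        pd.testing.assert_frame_equal(t1, t2)

    def test_planted_class_frequencies_exact(self, small_trio):
        cfg, _, truth = small_trio
        counts = truth["category"].value_counts()
        for cat, n in cfg.n_features_per_class.items():
            assert counts.get(cat, 0) == n

    def test_nb_mean_variance_relation(self):
        cfg = SimulationConfig(
            seed=9, n_features_per_class={"null": 12_000}, base_mean=100,
            base_mean_log_sd=0.0, nb_dispersion=0.05, n_replicates=3,
        )
        matrix, _ = simulate.simulate_trio_counts(cfg)
        x = matrix.counts.to_numpy(dtype=float)  # 9 iid draws per feature
        mu = x.mean()
        # pooled variance across features at a common mean
        var = x.var(ddof=1, axis=1).mean()
        assert mu == pytest.approx(100, rel=0.05)
        assert var == pytest.approx(100 + 0.05 * 100**2, rel=0.05)

    def test_all_multipliers_respect_category_semantics(self):
        f = 4.0
        for cat in simulate.CATEGORIES:
            e, fh, g = class_mean_multipliers(cat, f)
            group = simulate.GROUP_OF_CATEGORY[cat]
            if group == "transgressive_up":
                assert fh > max(e, g)
            elif group == "transgressive_down":
                assert fh < min(e, g)
            elif group == "maternal_dominant":
                assert fh == e and e != g
            elif group == "paternal_dominant":
                assert fh == g and e != g
            else:  # additive
                assert min(e, g) < fh < max(e, g)


class TestGenomeAndMethylome:
    def test_contexts_recomputed_from_fasta_match_emitted(self, small_methylome):
        cfg, genome, cx, design, _ = small_methylome
        sample = next(iter(cx))
        frame = cx[sample]
        for chrom in cfg.chrom_names:
            expected = methylation.cytosine_contexts(genome["seqs"][chrom], chrom)
            got = frame[frame["chrom"] == chrom]
            merged = got.merge(
                expected, on=["chrom", "pos", "strand"], suffixes=("", "_ref")
            )
            assert len(merged) == len(got)
            assert (merged["context"] == merged["context_ref"]).all()
            assert (merged["trinucleotide"] == merged["trinucleotide_ref"]).all()

    def test_methylome_deterministic_under_seed(self):
        cfg = SimulationConfig(seed=11, n_chromosomes=1, chrom_length_bp=30_000,
                               n_dmrs_per_class={"II": 2})
        g1 = simulate.simulate_genome(cfg)
        g2 = simulate.simulate_genome(SimulationConfig(seed=11, n_chromosomes=1,
                                                       chrom_length_bp=30_000,
                                                       n_dmrs_per_class={"II": 2}))
        assert g1["seqs"] == g2["seqs"]
        cx1, _, t1 = simulate.simulate_methylome(cfg, g1["seqs"])
        cx2, _, t2 = simulate.simulate_methylome(cfg, g2["seqs"])
        for s in cx1:
            pd.testing.assert_frame_equal(cx1[s], cx2[s])
        pd.testing.assert_frame_equal(t1, t2)

    def test_planted_dmr_bin_proportions_approach_truth(self, small_methylome):
        cfg, genome, cx, design, truth = small_methylome
        genotype_of = {
            s: simulate.GENOTYPES[design.loc[s, "genotype_role"]] for s in design.index
        }
        pooled, _ = methylation.methylation_levels(cx, genotype_of)
        row = truth[truth["category"] == "II"].iloc[0]
        for genotype, col in (("E", "p_E"), ("G", "p_G")):
            sub = pooled[
                (pooled["chrom"] == row["chrom"]) & (pooled["bin_start"] == row["start"])
                & (pooled["context"] == row["context"]) & (pooled["genotype"] == genotype)
            ]
            assert sub["level"].iloc[0] == pytest.approx(row[col], abs=0.05)

    def test_no_planted_dmrs_means_no_genotype_differences(self):
        cfg = SimulationConfig(seed=13, n_chromosomes=1, chrom_length_bp=40_000,
                               n_dmrs_per_class={})
        genome = simulate.simulate_genome(cfg)
        cx, design, truth = simulate.simulate_methylome(cfg, genome["seqs"])
        assert truth.empty
        genotype_of = {
            s: simulate.GENOTYPES[design.loc[s, "genotype_role"]] for s in design.index
        }
        pooled, _ = methylation.methylation_levels(cx, genotype_of)
        piv = pooled.pivot_table(
            index=["chrom", "bin_start", "context"], columns="genotype", values="level"
        ).dropna()
        assert (piv["E"] - piv["G"]).abs().mean() < 0.05

    def test_planted_island_satisfies_gardiner_garden_criteria(self):
        # 300 bp of CG repeats: GC = 100%, obs/exp = 150*300/(150*150) = 2
        block = "CG" * 150
        c = block.count("C")
        g = block.count("G")
        cpg = sum(block[i : i + 2] == "CG" for i in range(len(block) - 1))
        assert (c + g) / len(block) == 1.0
        assert cpg * len(block) / (c * g) == pytest.approx(2.0)


class TestCoverage:
    def test_deletion_multiplier_construction(self):
        cfg = SimulationConfig(
            seed=3, n_chromosomes=1, chrom_length_bp=500_000,
            cnv_spec=[("chr1", 100_000, 150_000, 0.1)],
        )
        cov, truth = simulate.simulate_coverage(cfg)
        inside = cov[(cov["start"] >= 100_000) & (cov["start"] < 150_000)]
        outside = cov[(cov["start"] < 100_000) | (cov["start"] >= 150_000)]
        assert inside["depth"].mean() == pytest.approx(3, rel=0.3)
        assert outside["depth"].mean() == pytest.approx(30, rel=0.05)
        assert truth.iloc[0]["cnv_type"] == "deletion"

    def test_neutral_multiplier_yields_empty_truth(self):
        cfg = SimulationConfig(seed=3, n_chromosomes=1, chrom_length_bp=100_000,
                               cnv_spec=[("chr1", 0, 50_000, 1.0)])
        _, truth = simulate.simulate_coverage(cfg)
        assert truth.empty


class TestSrna:
    def test_planted_class_counts_and_determinism(self):
        cfg = SimulationConfig(seed=21)
        clusters, matrix, truth = simulate.simulate_srna_clusters(cfg)
        assert (truth["srna_class"].value_counts().sort_index()
                == pd.Series({"miRNA_candidate": 20, "other": 10, "putative_siRNA": 20})
                .sort_index()).all()
        clusters2, matrix2, _ = simulate.simulate_srna_clusters(SimulationConfig(seed=21))
        pd.testing.assert_frame_equal(clusters, clusters2)
        pd.testing.assert_frame_equal(matrix.counts, matrix2.counts)
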