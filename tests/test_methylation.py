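import numpy as np
import pandas as pd
import pytest
from scipy import stats

from triomics import methylation, simulate
from triomics.methylation import (
    DmrParams,
    call_dmrs,
    classify_mld,
    cytosine_contexts,
    find_cpg_islands,
    genome_mean_levels,
    methylation_levels,
    score_test,
)


def cx_frame(rows):
    return pd.DataFrame(
        rows,
        columns=["chrom", "pos", "strand", "count_methylated", "count_unmethylated",
                 "context", "trinucleotide"],
    )


class TestContexts:
    def test_known_sequence_contexts(self):
        #        123456789
        seq = "ACGTACAGTT"
        ctx = cytosine_contexts(seq, "c")
        plus = ctx[ctx["strand"] == "+"].set_index("pos")
        # C at pos 2 followed by G -> CpG; C at pos 6 then A,G -> CHG
        assert plus.loc[2, "context"] == "CpG"
        assert plus.loc[6, "context"] == "CHG"
        minus = ctx[ctx["strand"] == "-"].set_index("pos")
        # G at pos 3 pairs with C; preceding C at pos 2 -> CpG on minus strand
        assert minus.loc[3, "context"] == "CpG"
        assert minus.loc[3, "trinucleotide"].startswith("C")

    def test_n_containing_trinucleotides_skipped(self):
        ctx = cytosine_contexts("CNGCGT", "c")
        assert 1 not in set(ctx["pos"])  # C followed by N

    def test_strand_counts_match_c_and_g_content(self):
        seq = "ACGTGCCA"
        ctx = cytosine_contexts(seq, "c")
        # every reported position is a C (+) or G (-) in the sequence
        for r in ctx.itertuples(index=False):
            base = seq[r.pos - 1]
            assert base == ("C" if r.strand == "+" else "G")


class TestMethylationLevels:
    def test_single_cytosine_level(self):
        cx = {"s1": cx_frame([("chr1", 42, "+", 3, 7, "CpG", "CGA")])}
        pooled, per_rep = methylation_levels(cx, {"s1": "E"})
        assert pooled["level"].iloc[0] == pytest.approx(0.3)
        assert pooled["bin_start"].iloc[0] == 0
        assert per_rep["n_cytosines"].iloc[0] == 1

    def test_coverage_below_three_excluded(self):
        cx = {"s1": cx_frame([("chr1", 10, "+", 1, 1, "CpG", "CGA"),
                              ("chr1", 20, "+", 2, 1, "CpG", "CGT")])}
        pooled, _ = methylation_levels(cx, {"s1": "E"})
        assert pooled["n_cytosines"].sum() == 1  # only the thrice-covered one

    def test_bin_sums_match_position_oracle(self, rng):
        rows = []
        for pos in rng.choice(5000, size=300, replace=False):
            m, u = int(rng.integers(0, 20)), int(rng.integers(0, 20))
            rows.append(("chr1", int(pos) + 1, "+", m, u, "CpG", "CGA"))
        cx = {"s1": cx_frame(rows)}
        pooled, _ = methylation_levels(cx, {"s1": "E"}, bin_size=1000)
        for r in pooled.itertuples(index=False):
            manual_m = sum(
                m for (_, p, _, m, u, _, _) in rows
                if r.bin_start < p <= r.bin_start + 1000 and m + u >= 3
            )
            assert r.meth == manual_m

    def test_unknown_context_raises(self):
        cx = {"s1": cx_frame([("chr1", 5, "+", 3, 3, "CWW", "CAA")])}
        with pytest.raises(ValueError, match="context"):
            methylation_levels(cx, {"s1": "E"})


class TestScoreTest:
    def test_equal_proportions_give_null(self):
        z, p = score_test(5, 10, 50, 100)
        assert z == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_z_squared_equals_pearson_chi_square(self, rng):
        for _ in range(10_000):
            n1, n2 = rng.integers(2, 200, size=2)
            m1 = rng.integers(0, n1 + 1)
            m2 = rng.integers(0, n2 + 1)
            z, _ = score_test(m1, n1, m2, n2)
            table = np.array([[m1, n1 - m1], [m2, n2 - m2]])
            if table.sum(axis=0).min() == 0:  # degenerate pooled proportion
                assert z == 0.0
                continue
            chi2 = stats.chi2_contingency(table, correction=False).statistic
            assert z**2 == pytest.approx(chi2, abs=1e-10)

    def test_antisymmetric_in_group_order(self):
        z1, p1 = score_test(40, 100, 10, 100)
        z2, p2 = score_test(10, 100, 40, 100)
        assert z1 == pytest.approx(-z2)
        assert p1 == pytest.approx(p2)

    def test_degenerate_pooled_proportion_gives_p_one(self):
        _, p = score_test(0, 50, 0, 80)
        assert p == 1.0
        _, p = score_test(50, 50, 80, 80)
        assert p == 1.0


def pooled_bins(rows):
    df = pd.DataFrame(
        rows,
        columns=["chrom", "bin_start", "context", "genotype", "n_cytosines",
                 "meth", "unmeth"],
    )
    df["total"] = df["meth"] + df["unmeth"]
    df["level"] = df["meth"] / df["total"]
    df["bin_size"] = 1000
    return df


class TestCallDmrs:
    def test_adjacent_same_direction_bins_merge(self):
        rows = []
        for b in (0, 1000):
            rows.append(("chr1", b, "CpG", "E", 10, 270, 30))   # level 0.9
            rows.append(("chr1", b, "CpG", "G", 10, 30, 270))   # level 0.1
        dmrs = call_dmrs(pooled_bins(rows), ("E", "G"))
        assert len(dmrs) == 1
        assert (dmrs.iloc[0]["start"], dmrs.iloc[0]["end"]) == (0, 2000)
        assert dmrs.iloc[0]["direction"] == "hyper"

    def test_opposite_direction_bins_do_not_merge(self):
        rows = [
            ("chr1", 0, "CpG", "E", 10, 270, 30), ("chr1", 0, "CpG", "G", 10, 30, 270),
            ("chr1", 1000, "CpG", "E", 10, 30, 270), ("chr1", 1000, "CpG", "G", 10, 270, 30),
        ]
        dmrs = call_dmrs(pooled_bins(rows), ("E", "G"))
        assert len(dmrs) == 2
        assert set(dmrs["direction"]) == {"hyper", "hypo"}

    def test_min_cytosines_threshold_enforced(self):
        rows = [("chr1", 0, "CpG", "E", 3, 270, 30), ("chr1", 0, "CpG", "G", 10, 30, 270)]
        assert call_dmrs(pooled_bins(rows), ("E", "G")).empty

    def test_genotype_swap_flips_direction_keeps_regions(self, small_methylome):
        cfg, genome, cx, design, _ = small_methylome
        genotype_of = {
            s: simulate.GENOTYPES[design.loc[s, "genotype_role"]] for s in design.index
        }
        pooled, _ = methylation_levels(cx, genotype_of)
        a = call_dmrs(pooled, ("E", "G"))
        b = call_dmrs(pooled, ("G", "E"))
        key = ["chrom", "start", "end", "context"]
        pd.testing.assert_frame_equal(
            a[key].reset_index(drop=True), b[key].reset_index(drop=True)
        )
        flip = {"hyper": "hypo", "hypo": "hyper"}
        assert list(b["direction"]) == [flip[d] for d in a["direction"]]

    def test_every_emitted_dmr_satisfies_thresholds(self, small_methylome):
        cfg, genome, cx, design, _ = small_methylome
        genotype_of = {
            s: simulate.GENOTYPES[design.loc[s, "genotype_role"]] for s in design.index
        }
        pooled, _ = methylation_levels(cx, genotype_of)
        par = DmrParams()
        for pair in (("E", "G"), ("E", "F"), ("F", "G")):
            dmrs = call_dmrs(pooled, pair, par)
            assert (dmrs["pvalue"] < par.p_thresh).all()
            assert (dmrs["delta"].abs() >= par.min_delta).all()
            assert (dmrs["n_cyt1"] >= par.min_cytosines).all()
            assert (dmrs["n_cyt2"] >= par.min_cytosines).all()
            assert set(dmrs["context"]) <= {"CpG", "CHG"}  # CHH off by default

    def test_mismatched_bin_grid_rejected(self):
        rows = [("chr1", 0, "CpG", "E", 10, 9, 1), ("chr1", 0, "CpG", "G", 10, 1, 9)]
        bins = pooled_bins(rows)
        with pytest.raises(ValueError, match="grid"):
            call_dmrs(bins, ("E", "G"), DmrParams(bin_size=500))


class TestMld:
    def test_planted_maternal_hypermethylation_recovered(self, rng):
        # pE = pF = 0.8, pG = 0.3 at high coverage -> maternal dominant
        per_rep_rows = []
        for genotype, p in (("E", 0.8), ("F", 0.8), ("G", 0.3)):
            for rep in (1, 2):
                meth = int(rng.binomial(600, p))
                per_rep_rows.append(
                    {"chrom": "chr1", "bin_start": 0, "context": "CpG",
                     "genotype": genotype, "sample": f"{genotype}_m{rep}",
                     "n_cytosines": 20, "meth": meth, "unmeth": 600 - meth,
                     "total": 600, "level": meth / 600}
                )
        per_rep = pd.DataFrame(per_rep_rows)
        dmrs = pd.DataFrame([{"chrom": "chr1", "start": 0, "end": 1000, "context": "CpG"}])
        calls = classify_mld(
            dmrs, per_rep, {"maternal": "E", "paternal": "G", "hybrid": "F"}
        )
        assert calls.iloc[0]["group"] == "maternal_dominant"

    def test_equal_genotypes_unclassified(self):
        per_rep_rows = [
            {"chrom": "chr1", "bin_start": 0, "context": "CpG", "genotype": g,
             "sample": f"{g}_m{r}", "n_cytosines": 10, "meth": 300, "unmeth": 300,
             "total": 600, "level": 0.5}
            for g in "EFG" for r in (1, 2)
        ]
        dmrs = pd.DataFrame([{"chrom": "chr1", "start": 0, "end": 1000, "context": "CpG"}])
        calls = classify_mld(
            dmrs, pd.DataFrame(per_rep_rows),
            {"maternal": "E", "paternal": "G", "hybrid": "F"},
        )
        assert calls.iloc[0]["group"] == "unclassified"


class TestCpgIslands:
    def test_planted_cg_island_recovered_with_window_slack(self):
        seq = "AT" * 500 + "CG" * 150 + "AT" * 500
        islands = find_cpg_islands({"chr1": seq})
        assert len(islands) == 1
        row = islands.iloc[0]
        assert row["start"] <= 1000 and row["end"] >= 1300
        assert abs(row["start"] - 1000) < 100 and abs(row["end"] - 1300) < 100

    def test_at_only_genome_has_no_islands(self):
        assert find_cpg_islands({"chr1": "AT" * 2000}).empty

    def test_every_emitted_island_passes_criteria(self):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGT"), p=[0.2, 0.3, 0.3, 0.2], size=30_000))
        islands = find_cpg_islands({"chr1": seq})
        for r in islands.itertuples(index=False):
            assert r.length > 200
            assert r.gc >= 0.5
            assert r.obs_exp >= 0.6
            span = seq[r.start : r.end]
            assert (span.count("C") + span.count("G")) / len(span) == pytest.approx(r.gc)

    def test_gc_rich_but_cpg_poor_fails_obs_exp(self):
        # alternating GGCC blocks have GC=100% but almost no CpG dinucleotides
        seq = "A" * 500 + "GGGGGCCCCC" * 40 + "A" * 500
        islands = find_cpg_islands({"chr1": seq})
        assert islands.empty


def test_genome_mean_level_ordering(small_methylome):
    cfg, genome, cx, design, _ = small_methylome
    genotype_of = {
        s: simulate.GENOTYPES[design.loc[s, "genotype_role"]] for s in design.index
    }
    pooled, _ = methylation_levels(cx, genotype_of)
    levels = genome_mean_levels(pooled)
    assert levels["CpG"] > levels["CHG"] > levels["CHH"]
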