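"""Genotype-class ANOVA/LSD, superior genotypes, population uniqueness."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from growmark.assoc import (
    MarkerCall,
    anova_lsd,
    associate_candidates,
    call_superior_genotype,
    classify_population_unique,
    genotype_freqs_by_population,
    genotype_label,
    report_markers,
)
from growmark.simdata import SimulationConfig, simulate_genotypes
from growmark.variants import VariantTable


class TestAnovaLsd:
    def test_two_classes_equal_pooled_t_test(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, 12)
        b = rng.normal(0.8, 1, 15)
        w = np.concatenate([a, b])
        cls = np.array(["AA"] * 12 + ["AG"] * 15)
        f, p, lsd, means, testable = anova_lsd(w, cls)
        t_stat, t_p = stats.ttest_ind(a, b, equal_var=True)
        assert testable
        assert f == pytest.approx(t_stat**2, rel=1e-10)
        assert p == pytest.approx(t_p, rel=1e-10)
        assert lsd.loc["AA", "AG"] == pytest.approx(t_p, rel=1e-10)

    def test_identical_means_give_f_near_zero(self):
        base = np.array([1.0, 2.0, 3.0, 4.0])
        w = np.concatenate([base, base, base])
        cls = np.repeat(["AA", "AG", "GG"], 4)
        f, p, *_ = anova_lsd(w, cls)
        assert f == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_three_class_sums_of_squares_oracle(self):
        # planted mean shifts, n = 5/8/6; oracle is the from-scratch
        # between/within decomposition
        rng = np.random.default_rng(1)
        groups = [
            rng.normal(10.0, 1.0, 5),
            rng.normal(11.5, 1.0, 8),
            rng.normal(9.0, 1.0, 6),
        ]
        labels = ["AA", "AG", "GG"]
        w = np.concatenate(groups)
        cls = np.repeat(labels, [5, 8, 6])
        f, p, lsd, means, _ = anova_lsd(w, cls)
        N, k = 19, 3
        grand = w.mean()
        ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
        ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
        f_oracle = (ssb / (k - 1)) / (ssw / (N - k))
        assert f == pytest.approx(f_oracle, abs=1e-10)
        assert p == pytest.approx(stats.f.sf(f_oracle, k - 1, N - k), abs=1e-10)
        mse = ssw / (N - k)
        for (i, a), (j, b) in [((0, "AA"), (1, "AG")), ((0, "AA"), (2, "GG")), ((1, "AG"), (2, "GG"))]:
            ga, gb = groups[i], groups[j]
            t = (ga.mean() - gb.mean()) / np.sqrt(mse * (1 / len(ga) + 1 / len(gb)))
            assert lsd.loc[a, b] == pytest.approx(
                2 * stats.t.sf(abs(t), N - k), abs=1e-10
            )

    def test_small_classes_dropped_then_untestable(self):
        w = np.arange(6, dtype=float)
        cls = np.array(["AA"] * 4 + ["AG"] * 2)
        f, p, lsd, means, testable = anova_lsd(w, cls, min_class_n=3)
        assert not testable and np.isnan(f)

    def test_shift_invariance(self):
        rng = np.random.default_rng(2)
        w = rng.normal(size=20)
        cls = np.repeat(["AA", "AG"], 10)
        _, p1, *_ = anova_lsd(w, cls)
        _, p2, *_ = anova_lsd(w + 1234.5, cls)
        assert p1 == pytest.approx(p2, rel=1e-9)


class TestSuperiorGenotype:
    def test_argmax_of_class_means(self):
        got = call_superior_genotype(
            {"AA": 5.0, "AG": 7.0, "GG": 6.0}, {"AA": 10, "AG": 9, "GG": 8}, 0.01
        )
        assert got == "AG"

    def test_not_significant_returns_none(self):
        assert (
            call_superior_genotype({"AA": 5.0, "AG": 7.0}, {"AA": 3, "AG": 3}, 0.20)
            is None
        )

    def test_tie_breaks_by_n_then_lexicographic(self):
        assert (
            call_superior_genotype({"AA": 5.0, "GG": 5.0}, {"AA": 3, "GG": 9}, 0.01)
            == "GG"
        )
        assert (
            call_superior_genotype({"AA": 5.0, "GG": 5.0}, {"AA": 5, "GG": 5}, 0.01)
            == "AA"
        )


class TestGenotypeFreqs:
    def test_single_population_tally(self):
        freqs = genotype_freqs_by_population(
            np.array([0.0, 0.0, 1.0, 2.0]), ["P"] * 4, "G", "C"
        )
        assert freqs.loc["P", "GG"] == pytest.approx(0.5)
        assert freqs.loc["P", "GC"] == pytest.approx(0.25)
        assert freqs.loc["P", "CC"] == pytest.approx(0.25)

    def test_all_missing_population_is_zero_row(self):
        freqs = genotype_freqs_by_population(
            np.array([np.nan, np.nan, 1.0, 1.0]), ["A", "A", "B", "B"], "A", "G"
        )
        assert freqs.loc["A"].sum() == 0.0
        assert freqs.loc["B", "AG"] == 1.0

    def test_rows_sum_to_one_over_observed_classes(self):
        rng = np.random.default_rng(3)
        d = rng.integers(0, 3, 60).astype(float)
        pops = rng.choice(["A", "B", "C"], 60)
        freqs = genotype_freqs_by_population(d, list(pops), "T", "C")
        np.testing.assert_allclose(freqs.sum(axis=1), 1.0)


class TestPopulationUnique:
    def _call(self, freqs: pd.DataFrame, superior="CC") -> MarkerCall:
        return MarkerCall(
            snp="chr1_10_C_T",
            chrom="chr1",
            pos=10,
            classes={"CC": 5, "CT": 5},
            class_means={"CC": 9.0, "CT": 7.0},
            anova_f=8.0,
            anova_p=0.001,
            lsd_p=None,
            testable=True,
            growth_related=True,
            superior_genotype=superior,
            population_freqs=freqs,
        )

    def test_exclusive_presence_flags_unique(self):
        freqs = pd.DataFrame(
            {"CC": [0.3, 0.0, 0.0], "CT": [0.5, 0.6, 0.4], "TT": [0.2, 0.4, 0.6]},
            index=["HLJ", "AH", "HN"],
        )
        call = classify_population_unique(self._call(freqs))
        assert call.population_unique and call.unique_population == "HLJ"

    def test_presence_in_two_populations_not_unique(self):
        freqs = pd.DataFrame(
            {"CC": [0.3, 0.1], "CT": [0.5, 0.5], "TT": [0.2, 0.4]},
            index=["HLJ", "AH"],
        )
        call = classify_population_unique(self._call(freqs))
        assert not call.population_unique and call.unique_population is None

    def test_superior_genotype_absent_everywhere_is_inconsistent(self):
        freqs = pd.DataFrame(
            {"CC": [0.0, 0.0], "CT": [0.6, 0.5], "TT": [0.4, 0.5]},
            index=["A", "B"],
        )
        with pytest.raises(ValueError, match="absent"):
            classify_population_unique(self._call(freqs))


class TestPipelineLevel:
    def test_genotype_labels(self):
        assert genotype_label("G", "C", 0) == "GG"
        assert genotype_label("G", "C", 1) == "GC"
        assert genotype_label("G", "C", 2) == "CC"
        with pytest.raises(ValueError):
            genotype_label("G", "C", 3)

    def test_null_calibration_of_growth_related_rate(self):
        # under no genetic effect the per-test level is the nominal alpha
        n_tested = 0
        n_called = 0
        for seed in range(50):
            cfg = SimulationConfig(
                n_chromosomes=1,
                loci_per_chromosome=40,
                heritability=0.0,
                population_means=(50.0, 50.0, 50.0, 50.0),
                population_sds=(5.0, 5.0, 5.0, 5.0),
                missing_rate=0.0,
                seed=1000 + seed,
            )
            t = simulate_genotypes(cfg)
            rng = np.random.default_rng(2000 + seed)
            w = rng.normal(size=t.n_samples)
            cand = pd.DataFrame({"snp": t.ids})
            calls = associate_candidates(cand, t, w, alpha=0.05)
            n_tested += sum(c.testable for c in calls)
            n_called += sum(c.growth_related for c in calls)
        rate = n_called / n_tested
        assert abs(rate - 0.05) < 0.02

    def test_planted_effect_superior_is_alt_homozygote(self):
        hits, sig = 0, 0
        for seed in range(20):
            cfg = SimulationConfig(
                n_per_population=(100, 100, 100, 100),
                n_chromosomes=1,
                loci_per_chromosome=30,
                causal_spec=((15, 0.8),),
                heritability=0.3,
                population_means=(50.0,) * 4,
                population_sds=(5.0,) * 4,
                missing_rate=0.0,
                seed=seed,
            )
            t = simulate_genotypes(cfg)
            from growmark.simdata import simulate_phenotypes

            ph = simulate_phenotypes(t, cfg)
            w = ph["weight_g"].to_numpy() - ph["weight_g"].mean()
            calls = associate_candidates(
                pd.DataFrame({"snp": [t.ids.iloc[15]]}), t, w
            )
            c = calls[0]
            if c.growth_related:
                sig += 1
                locus = t.loci.iloc[15]
                if c.superior_genotype == locus["alt"] * 2:
                    hits += 1
        assert sig > 0
        assert hits / sig >= 0.9

    def test_report_files_and_set_containments(self, tmp_path, small_table):
        rng = np.random.default_rng(7)
        w = rng.normal(size=small_table.n_samples)
        cand = pd.DataFrame({"snp": small_table.ids.iloc[:100]})
        calls = associate_candidates(cand, small_table, w)
        paths = report_markers(calls, tmp_path / "r1")
        full = pd.read_csv(paths["candidates"], sep="\t")
        growth = pd.read_csv(paths["growth_related"], sep="\t")
        unique = pd.read_csv(paths["population_unique"], sep="\t")
        assert set(unique["snp"]) <= set(growth["snp"]) <= set(full["snp"])
        assert len(full) == len(calls)
        assert len(growth) == sum(c.growth_related for c in calls)
        # determinism: a second run is byte-identical
        paths2 = report_markers(calls, tmp_path / "r2")
        for k in paths:
            assert (
                open(paths[k], "rb").read() == open(paths2[k], "rb").read()
            )

    def test_empty_call_list_writes_headers(self, tmp_path):
        paths = report_markers([], tmp_path)
        for p in paths.values():
            df = pd.read_csv(p, sep="\t")
            assert len(df) == 0 and "snp" in df.columns
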