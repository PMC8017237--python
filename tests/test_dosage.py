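import numpy as np
import pandas as pd
import pytest

from finchdev import ExpressionMatrix, SimulationConfig, default_design
from finchdev import dosage as do
from finchdev import expression as ex
from finchdev.core import GeneAnnotation
from finchdev.simulate import simulate_expression, simulate_genes


def _genes(chroms):
    table = pd.DataFrame(
        {
            "chrom": chroms,
            "start": 0,
            "end": 100,
            "strand": "+",
            "tss": 0,
        },
        index=pd.Index([f"g{i}" for i in range(len(chroms))], name="gene_id"),
    )
    return GeneAnnotation(table)


def _expr(cpm_rows, design, lib=1_000_000):
    counts = pd.DataFrame(
        (np.asarray(cpm_rows, dtype=float) * lib / 1e6).astype(int),
        index=[f"g{i}" for i in range(len(cpm_rows))],
        columns=design.sample_ids,
    )
    return ExpressionMatrix(counts=counts, lib_size=pd.Series(float(lib), index=counts.columns))


class TestMfRatios:
    def test_double_male_expression_gives_ratio_two(self, design):
        sex = design.table["sex"].to_numpy()
        row = np.where(sex == "M", 20.0, 10.0)
        x = _expr([row], design)
        genes = _genes(["Z"])
        r = do.mf_ratios(x, design, genes)
        for age in ("d1", "d20", "d65", "adult"):
            assert r[f"ratio_{age}"].iloc[0] == pytest.approx(2.0, rel=1e-5)

    def test_equal_means_give_ratio_one(self, design):
        x = _expr([[10.0] * 24], design)
        r = do.mf_ratios(x, design, _genes(["1"]))
        assert r["ratio_adult"].iloc[0] == pytest.approx(1.0, rel=1e-5)

    def test_zero_female_mean_guarded_and_flagged(self, design):
        sex = design.table["sex"].to_numpy()
        row = np.where(sex == "M", 20.0, 0.0)
        x = _expr([row], design)
        r = do.mf_ratios(x, design, _genes(["Z"]))
        assert np.isfinite(r["ratio_d1"].iloc[0])
        assert r["ratio_d1"].iloc[0] > 1e4
        assert bool(r["zero_female_mean"].iloc[0])

    def test_random_fragments_fold_into_parent_class(self, design):
        x = _expr([[10.0] * 24, [10.0] * 24], design)
        r = do.mf_ratios(x, design, _genes(["Z_random", "1_random"]))
        assert r["chrom_class"].tolist() == ["Z", "autosome"]

    def test_ratios_scale_invariant(self, design, small_dataset):
        x = small_dataset.expression
        genes = small_dataset.genes
        r1 = do.mf_ratios(x, design, genes)
        x2 = ExpressionMatrix(counts=x.counts * 3, lib_size=x.lib_size * 3,
                              norm_factor=x.norm_factor)
        r2 = do.mf_ratios(x2, design, genes)
        pd.testing.assert_frame_equal(r1, r2, rtol=1e-9)


class TestClassification:
    def _ratios(self, auto_ratios, z_d1, z_adult):
        n_a, n_z = len(auto_ratios), len(z_d1)
        return pd.DataFrame(
            {
                "ratio_d1": list(auto_ratios) + list(z_d1),
                "ratio_d20": 1.0,
                "ratio_d65": 1.0,
                "ratio_adult": list(auto_ratios) + list(z_adult),
                "chrom_class": ["autosome"] * n_a + ["Z"] * n_z,
                "zero_female_mean": False,
            },
            index=[f"g{i}" for i in range(n_a + n_z)],
        )

    def test_quantile_matches_hand_computed_interpolation(self):
        ratios = self._ratios([1.0] * 19 + [2.0], [1.5], [1.5])
        cls = do.classify_dosage(ratios)
        # 95% quantile of 19 x 1.0 and 1 x 2.0 by linear interpolation
        assert cls.cutoff["d1"] == pytest.approx(1.05)
        assert cls.cutoff["adult"] == pytest.approx(1.05)

    def test_three_way_rule(self):
        # autosomal quantile 1 + 0.05 * 8 = 1.4 separates 1.0/1.1 from 1.8
        cfg = do.DosageConfig(per_age_cutoff=False)
        cls = do.classify_dosage(self._ratios([1.0] * 19 + [9.0], z_d1=[1.8, 1.8, 1.0],
                                              z_adult=[1.1, 1.8, 1.0]), cfg)
        assert cls.cutoff["d1"] == pytest.approx(1.4)
        assert cls.table["dosage_class"].tolist() == ["acquired", "never", "from_birth"]

    def test_cutoff_monotone_in_quantile(self, design, small_dataset):
        x = ex.normalize_counts(small_dataset.expression)
        r = do.mf_ratios(x, design, small_dataset.genes)
        cuts = [
            do.classify_dosage(r, do.DosageConfig(quantile=q)).cutoff["adult"]
            for q in (0.5, 0.8, 0.95)
        ]
        assert cuts == sorted(cuts)

    def test_too_few_autosomal_genes_rejected(self):
        ratios = self._ratios([1.0] * 5, [1.5], [1.5])
        with pytest.raises(ValueError, match="autosomal"):
            do.classify_dosage(ratios)

    def test_planted_classes_recovered(self, design):
        # pooled over several independent studies so the measured accuracy
        # reflects the classifier's operating characteristic, not one draw
        n_correct = n_total = 0
        for seed in range(101, 107):
            cfg = SimulationConfig(n_genes=1000, seed=seed)
            genes, gtruth = simulate_genes(cfg)
            x, truth = simulate_expression(cfg, design, genes, gtruth)
            xn = ex.normalize_counts(ex.filter_low_expression(x))
            r = do.mf_ratios(xn, design, genes)
            cls = do.classify_dosage(r)
            pred = cls.table["dosage_class"]
            true = truth.loc[pred.index, "dosage_class"]
            n_correct += (pred == true).sum()
            n_total += len(pred)
        assert n_correct / n_total >= 0.9

    def test_complete_compensation_rarely_labelled_never(self, design):
        cfg = SimulationConfig(
            n_genes=600,
            seed=23,
            dosage_class_fractions={
                "from_birth": 0.15, "acquired": 0.0, "never": 0.0, "autosomal_null": 0.85
            },
        )
        genes, gtruth = simulate_genes(cfg)
        x, _ = simulate_expression(cfg, design, genes, gtruth)
        r = do.mf_ratios(ex.normalize_counts(x), design, genes)
        cls = do.classify_dosage(r)
        frac_never = (cls.table["dosage_class"] == "never").mean()
        assert frac_never <= (1 - 0.95) + 0.05


class TestRatioDistribution:
    def test_identical_ratios_occupy_single_bin(self):
        ratios = pd.DataFrame(
            {
                **{f"ratio_{a}": 1.0 for a in ("d1", "d20", "d65", "adult")},
                "chrom_class": ["autosome"] * 30,
            },
            index=[f"g{i}" for i in range(30)],
        )
        dist = do.ratio_distribution(ratios)
        sub = dist[(dist["age"] == "d1")]
        assert sub["pct"].max() == pytest.approx(100.0)
        assert (sub["pct"] > 0).sum() == 1

    def test_bin_percentages_sum_to_hundred(self, design, small_dataset):
        r = do.mf_ratios(small_dataset.expression, design, small_dataset.genes)
        dist = do.ratio_distribution(r)
        sums = dist.groupby(["age", "chrom_class"])["pct"].sum()
        assert np.allclose(sums, 100.0)

    def test_smoothed_mass_close_to_raw(self, design, small_dataset):
        r = do.mf_ratios(small_dataset.expression, design, small_dataset.genes)
        dist = do.ratio_distribution(r)
        sub = dist[(dist["age"] == "adult") & (dist["chrom_class"] == "autosome")]
        assert sub["pct_smooth"].sum() == pytest.approx(sub["pct"].sum(), rel=0.01)


class TestGroupStats:
    def _classification(self, design, seed=19):
        cfg = SimulationConfig(
            n_genes=800, seed=seed,
            dosage_class_fractions={
                "from_birth": 0.05, "acquired": 0.10, "never": 0.05, "autosomal_null": 0.80
            },
        )
        genes, gtruth = simulate_genes(cfg)
        x, truth = simulate_expression(cfg, design, genes, gtruth)
        xn = ex.normalize_counts(x)
        r = do.mf_ratios(xn, design, genes)
        return xn, do.classify_dosage(r)

    def test_identical_class_means_give_null_anova(self, design, rng):
        xn, cls = self._classification(design)
        # replace expression by exchangeable noise: no class differences
        lc = pd.DataFrame(
            rng.standard_normal((len(xn.counts), 24)),
            index=xn.counts.index, columns=xn.counts.columns,
        )
        res = do.dosage_group_stats(lc, cls)
        assert res.anova_p > 0.05
        assert (pd.to_numeric(res.tukey["p-adj"]) > 0.05).all()

    def test_planted_class_offsets_detected(self, design, rng):
        xn, cls = self._classification(design)
        lc = pd.DataFrame(
            0.1 * rng.standard_normal((len(xn.counts), 24)),
            index=xn.counts.index, columns=xn.counts.columns,
        )
        offset = {"from_birth": 0.0, "acquired": 1.0, "never": 2.0}
        for c, dv in offset.items():
            lc.loc[cls.genes_in_class(c)] += dv
        res = do.dosage_group_stats(lc, cls)
        assert res.anova_p < 1e-6
        assert (pd.to_numeric(res.tukey["p-adj"]) < 0.01).all()

    def test_z_fraction_pairwise_tests_bonferroni(self, design):
        xn, cls = self._classification(design)
        gene_classes = pd.Series("autosome", index=xn.counts.index)
        gene_classes.iloc[:100] = "Z"
        sex_de = {
            "d1": xn.counts.index[:80],        # mostly Z
            "d20": xn.counts.index[60:140],
            "d65": xn.counts.index[90:170],    # mostly autosomal
            "adult": xn.counts.index[100:180],  # all autosomal
        }
        lc = pd.DataFrame(
            np.random.default_rng(2).standard_normal((len(xn.counts), 24)),
            index=xn.counts.index, columns=xn.counts.columns,
        )
        res = do.dosage_group_stats(
            lc, cls, sex_de_by_age=sex_de, gene_classes=gene_classes
        )
        t = res.z_fraction_tests
        assert len(t) == 6
        assert (t["p_bonferroni"] >= t["p"].fillna(0)).all()
        extreme = t[(t["age_1"] == "d1") & (t["age_2"] == "adult")]
        assert extreme["p_bonferroni"].iloc[0] < 0.05
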