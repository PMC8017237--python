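import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from finchdev import MethylationMatrix, SimulationConfig, default_design
from finchdev import methylation as me
from finchdev.core import GeneAnnotation
from finchdev.simulate import simulate_methylation, simulate_genes


def _matrix(meth, total, samples=None, assay="rrbs"):
    meth = np.atleast_2d(meth)
    total = np.atleast_2d(total)
    cols = samples or [f"s{i}" for i in range(meth.shape[1])]
    idx = pd.MultiIndex.from_tuples(
        [("chr1", 100 + 10 * i, "+", "CpG") for i in range(meth.shape[0])],
        names=MethylationMatrix.INDEX_NAMES,
    )
    return MethylationMatrix(
        pd.DataFrame(meth, index=idx, columns=cols),
        pd.DataFrame(total, index=idx, columns=cols),
        assay,
    )


class TestMValues:
    def test_half_methylated_gives_zero(self):
        beta, m = me.compute_m_values(_matrix([[5]], [[10]]))
        assert beta.iloc[0, 0] == 0.5
        assert m.iloc[0, 0] == 0.0

    def test_unmethylated_value_from_offset(self):
        # M(0) = log2(0.01 / 1.01)
        _, m = me.compute_m_values(_matrix([[0]], [[10]]))
        assert m.iloc[0, 0] == pytest.approx(-6.6582, abs=1e-4)

    def test_fully_methylated_is_mirror_image(self):
        _, m0 = me.compute_m_values(_matrix([[0]], [[10]]))
        _, m1 = me.compute_m_values(_matrix([[10]], [[10]]))
        assert m1.iloc[0, 0] == pytest.approx(-m0.iloc[0, 0])

    def test_zero_coverage_is_missing_not_zero(self):
        beta, m = me.compute_m_values(_matrix([[0, 5]], [[0, 10]]))
        assert np.isnan(beta.iloc[0, 0]) and np.isnan(m.iloc[0, 0])
        assert beta.iloc[0, 1] == 0.5

    @given(
        meth=st.integers(min_value=0, max_value=30),
        total=st.integers(min_value=1, max_value=30),
    )
    @settings(deadline=None, max_examples=60, derandomize=True)
    def test_symmetry_and_monotonicity(self, meth, total):
        meth = min(meth, total)
        _, m = me.compute_m_values(_matrix([[meth]], [[total]]))
        _, m_flip = me.compute_m_values(_matrix([[total - meth]], [[total]]))
        assert m.iloc[0, 0] == pytest.approx(-m_flip.iloc[0, 0], abs=1e-12)
        if meth < total:
            _, m_up = me.compute_m_values(_matrix([[meth + 1]], [[total]]))
            assert m_up.iloc[0, 0] > m.iloc[0, 0]


class TestFilters:
    def test_exact_boundary_retained(self):
        n = 24
        meth = np.zeros((1, n), dtype=int)
        meth[0, :6] = 1
        total = np.full((1, n), 5)
        m = _matrix(meth, total)
        assert me.filter_cytosines(m).n_sites == 1

    def test_mean_coverage_just_below_removed(self):
        n = 24
        total = np.full((1, n), 5)
        total[0, 0] = 4  # sum 119, mean 4.958
        meth = np.minimum(1, total)
        meth[0, :6] = 1
        m = _matrix(meth, total)
        assert me.filter_cytosines(m).n_sites == 0

    def test_five_methylated_reads_removed(self):
        n = 24
        meth = np.zeros((1, n), dtype=int)
        meth[0, :5] = 1
        total = np.full((1, n), 50)
        m = _matrix(meth, total)
        assert me.filter_cytosines(m).n_sites == 0

    def test_filter_invariant_under_sample_permutation(self, small_dataset, rng):
        m = small_dataset.rrbs
        perm = rng.permutation(m.meth.columns)
        m_perm = MethylationMatrix(m.meth[perm], m.total[perm], m.assay)
        kept = me.filter_cytosines(m).sites
        kept_perm = me.filter_cytosines(m_perm).sites
        assert kept.equals(kept_perm)


class TestModeratedDM:
    def test_zero_prior_df_reduces_to_ordinary_t(self, design, small_dataset):
        m = me.filter_cytosines(small_dataset.rrbs)
        plain = me.fit_moderated_dm(m, design, me.MethylConfig(prior_df=0.0))
        # ordinary OLS t-test p-value for the age contrast at one site
        from finchdev.expression import contrast_matrix, group_design
        from scipy import stats as ss

        X, groups = group_design(design)
        C, names = contrast_matrix(groups)
        _, m_df = me.compute_m_values(m)
        y = m_df.loc[plain.table.index].to_numpy()[0]
        XtX_inv = np.linalg.inv(X.T @ X)
        b = XtX_inv @ X.T @ y
        resid = y - X @ b
        s2 = resid @ resid / (len(y) - X.shape[1])
        tval = (C[0] @ b) / np.sqrt(s2 * C[0] @ XtX_inv @ C[0])
        p = 2 * ss.t.sf(abs(tval), len(y) - X.shape[1])
        assert plain.table["t_p_age"].iloc[0] == pytest.approx(p, rel=1e-10)

    def test_shrinkage_is_convex_combination(self, design, small_dataset):
        m = me.filter_cytosines(small_dataset.rrbs)
        res = me.fit_moderated_dm(m, design)
        lo = np.minimum(res.table["s2"], res.prior_var) - 1e-12
        hi = np.maximum(res.table["s2"], res.prior_var) + 1e-12
        assert ((res.table["s2_post"] >= lo) & (res.table["s2_post"] <= hi)).all()

    def test_null_simulation_controls_fdr(self, design):
        cfg = SimulationConfig(n_genes=250, n_cpg_per_gene=8, n_cph_per_gene=0,
                               seed=31, meth_age_slope=0.0)
        genes, _ = simulate_genes(cfg)
        rrbs, _, truth = simulate_methylation(cfg, design, genes)
        res = me.fit_moderated_dm(me.filter_cytosines(rrbs), design)
        frac = (res.table["omnibus_fdr"] < 0.05).mean()
        se = np.sqrt(0.05 * 0.95 / len(res.table))
        assert frac <= 0.05 + 2 * se

    def test_planted_age_trend_recovered(self, design):
        # mid-range baseline; slope 1.25 logits/step is a methylation
        # change of about 0.3 per age step at these levels
        cfg = SimulationConfig(
            n_genes=150, n_cpg_per_gene=8, n_cph_per_gene=0, seed=17,
            meth_age_slope=1.25, dm_fraction=0.3, cpg_beta_params=(4.0, 6.0),
        )
        genes, _ = simulate_genes(cfg)
        rrbs, _, truth = simulate_methylation(cfg, design, genes)
        res = me.fit_moderated_dm(me.filter_cytosines(rrbs), design)
        truth = truth.loc[res.table.index]
        step = (truth["true_beta_d20"] - truth["true_beta_d1"])[truth["dm_flag"]]
        assert step.mean() == pytest.approx(0.3, abs=0.05)
        called = (res.table["omnibus_fdr"] < 0.05) & (res.table["stage2_p_age"] < 0.05)
        sens = (called & truth["dm_flag"]).sum() / truth["dm_flag"].sum()
        assert sens >= 0.9

    def test_subset_fdr_on_full_set_equals_original(self, design, small_dataset):
        m = me.filter_cytosines(small_dataset.rrbs)
        res = me.fit_moderated_dm(m, design)
        q = res.subset_fdr(res.table.index)
        assert np.allclose(q.to_numpy(), res.table["omnibus_fdr"].to_numpy())


class TestHydroxymethylation:
    def test_simple_subtraction(self):
        r = _matrix([[5]], [[10]], assay="rrbs")
        o = _matrix([[3]], [[10]], assay="oxrrbs")
        h, clipped, dropped = me.subtract_hydroxymethylation(r, o)
        assert h.iloc[0, 0] == pytest.approx(0.2)
        assert not clipped.iloc[0, 0]
        assert dropped == 0

    def test_negative_estimate_clipped_and_flagged(self):
        r = _matrix([[2]], [[10]], assay="rrbs")
        o = _matrix([[3]], [[10]], assay="oxrrbs")
        h, clipped, _ = me.subtract_hydroxymethylation(r, o)
        assert h.iloc[0, 0] == 0.0
        assert bool(clipped.iloc[0, 0])

    def test_disjoint_site_sets_rejected(self):
        r = _matrix([[5]], [[10]], assay="rrbs")
        o = me.MethylationMatrix(
            r.meth.rename(index={100: 999}, level="pos"),
            r.total.rename(index={100: 999}, level="pos"),
            "oxrrbs",
        )
        with pytest.raises(ValueError, match="no overlapping"):
            me.subtract_hydroxymethylation(r, o)

    def test_estimates_bounded_and_centered_near_truth(self, small_dataset):
        h, clipped, _ = me.subtract_hydroxymethylation(
            me.filter_cytosines(small_dataset.rrbs),
            me.filter_cytosines(small_dataset.oxrrbs),
        )
        arr = h.to_numpy()
        assert np.nanmin(arr) >= 0.0 and np.nanmax(arr) <= 1.0


class TestAnnotation:
    @pytest.fixture
    def genes(self):
        table = pd.DataFrame(
            {
                "chrom": ["chr1", "chr1"],
                "start": [10000, 14500],
                "end": [13000, 30000],
                "strand": ["+", "+"],
                "tss": [10000, 14500],
                "chrom_class": ["autosome", "autosome"],
                "is_tf": [False, False],
            },
            index=pd.Index(["gA", "gB"], name="gene_id"),
        )
        return GeneAnnotation(table)

    def _annotate(self, genes, pos):
        sites = pd.MultiIndex.from_tuples(
            [("chr1", p, "+", "CpG") for p in pos], names=MethylationMatrix.INDEX_NAMES
        )
        return me.annotate_cytosines(sites, genes)

    def test_upstream_site_is_promoter(self, genes):
        ann = self._annotate(genes, [9900])  # 100 bp upstream of gA TSS
        assert ann["region"].iloc[0] == "promoter"
        assert ann["gene_ids"].iloc[0] == "gA"

    def test_mid_gene_site_is_genic(self, genes):
        ann = self._annotate(genes, [24500])  # 10 kb past gB TSS
        assert ann["region"].iloc[0] == "genic"

    def test_promoter_takes_priority_over_other_genes_body(self, genes):
        # 12,600 is inside gA's body and inside gB's promoter window
        ann = self._annotate(genes, [12600])
        assert ann["region"].iloc[0] == "promoter"
        assert ann["gene_ids"].iloc[0] == "gA,gB"
        assert not ann["unique_gene"].iloc[0]

    def test_far_site_is_intergenic(self, genes):
        ann = self._annotate(genes, [500])
        assert ann["region"].iloc[0] == "intergenic"
        assert ann["gene_ids"].iloc[0] == ""
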