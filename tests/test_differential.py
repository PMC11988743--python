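import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

from editlens.annotation import annotate_sites
from editlens.differential import (
    DISPERSION_FLOOR,
    aggregate_gene_editing,
    bh_adjust,
    estimate_dispersion,
    nb_wald_test,
    size_factors,
)
from editlens.discovery import discover_sites
from editlens.simulate import SimulationConfig, simulate_study


def nb_counts(rng, mu, alpha, size):
    if alpha <= 0:
        return rng.poisson(mu, size)
    return rng.negative_binomial(1.0 / alpha, 1.0 / (1.0 + alpha * mu), size)


class TestSizeFactors:
    def test_identical_samples_give_unit_factors(self):
        counts = pd.DataFrame({"a": [10, 20, 5], "b": [10, 20, 5]})
        sf = size_factors(counts)
        assert np.allclose(sf, 1.0)

    def test_doubled_sample_ratio_two(self):
        rng = np.random.default_rng(0)
        a = rng.integers(5, 100, 50)
        counts = pd.DataFrame({"a": a, "b": 2 * a})
        sf = size_factors(counts)
        assert sf["b"] / sf["a"] == pytest.approx(2.0)
        assert np.exp(np.mean(np.log(sf))) == pytest.approx(1.0)

    def test_scale_invariance_property(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            counts = pd.DataFrame(rng.integers(1, 200, (40, 4)),
                                  columns=list("abcd"))
            sf = size_factors(counts)
            scaled = counts.copy()
            scaled["c"] *= 5
            sf2 = size_factors(scaled)
            # c's factor x5 relative to the others (up to the geo-mean rescale)
            ratio = (sf2 / sf).to_numpy()
            assert ratio[2] / ratio[0] == pytest.approx(5.0, rel=1e-9)

    def test_fallback_warns_without_all_positive_feature(self):
        counts = pd.DataFrame({"a": [0, 10], "b": [10, 0]})
        with pytest.warns(RuntimeWarning):
            sf = size_factors(counts)
        assert np.all(sf > 0)


class TestEstimateDispersion:
    def test_poisson_limit_alpha_near_zero(self):
        rng = np.random.default_rng(2)
        counts = pd.DataFrame(rng.poisson(1000.0, (200, 50)))
        sf = pd.Series(1.0, index=counts.columns)
        alpha = estimate_dispersion(counts, sf)
        assert alpha.mean() == pytest.approx(0.0, abs=0.05)

    def test_nb_parameter_recovery(self):
        rng = np.random.default_rng(3)
        counts = pd.DataFrame(nb_counts(rng, 1000.0, 0.2, (200, 50)))
        sf = pd.Series(1.0, index=counts.columns)
        alpha = estimate_dispersion(counts, sf)
        assert 0.1 <= alpha.mean() <= 0.3

    def test_constant_counts_hit_floor(self):
        counts = pd.DataFrame({"a": [50, 50], "b": [50, 50], "c": [50, 50]})
        sf = pd.Series(1.0, index=counts.columns)
        alpha = estimate_dispersion(counts, sf)
        assert np.allclose(alpha, DISPERSION_FLOOR)

    def test_zero_mean_feature_flagged_untestable(self):
        counts = pd.DataFrame({"a": [0, 100], "b": [0, 100], "c": [0, 100]})
        sf = pd.Series(1.0, index=counts.columns)
        alpha = estimate_dispersion(counts, sf)
        assert np.isnan(alpha.iloc[0])


class TestBHAdjust:
    def test_single_p(self):
        assert bh_adjust([0.04])[0] == pytest.approx(0.04)

    def test_hand_computed_step_up(self):
        out = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(size=100)
        perm = rng.permutation(100)
        assert np.allclose(bh_adjust(p)[perm], bh_adjust(p[perm]))

    def test_empty(self):
        assert bh_adjust([]).size == 0

    def test_nan_passthrough(self):
        out = bh_adjust([0.01, np.nan, 0.5])
        assert np.isnan(out[1])
        # m excludes the NaN entry
        assert out[0] == pytest.approx(0.02)

    def test_matches_statsmodels_on_random_vectors(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            p = rng.uniform(size=rng.integers(1, 200))
            expect = multipletests(p, method="fdr_bh")[1]
            assert np.allclose(bh_adjust(p), expect)

    def test_adjusted_geq_raw(self):
        rng = np.random.default_rng(6)
        p = rng.uniform(size=500)
        adj = bh_adjust(p)
        assert np.all(adj >= p - 1e-12)
        assert np.all(adj <= 1.0)


@pytest.fixture(scope="module")
def null_fit():
    rng = np.random.default_rng(10)
    mu = rng.lognormal(5, 1, 600)
    counts = pd.DataFrame(
        nb_counts(rng, mu[:, None], 0.1, (600, 6)),
        columns=[f"s{i}" for i in range(6)],
    )
    design = pd.Series(["A"] * 3 + ["B"] * 3, index=counts.columns)
    return counts, design, nb_wald_test(counts, design)


class TestNBWaldTest:
    def test_identical_groups_null(self):
        counts = pd.DataFrame(
            {"a1": [40, 7], "a2": [50, 9], "b1": [40, 7], "b2": [50, 9]},
            index=["g1", "g2"],
        )
        design = pd.Series(["A", "A", "B", "B"], index=counts.columns)
        res = nb_wald_test(counts, design)
        assert np.allclose(res["log2FC"], 0.0, atol=1e-6)
        assert np.all(res["pvalue"] > 0.95)

    def test_all_zero_feature_excluded(self):
        counts = pd.DataFrame(
            {"a1": [0, 10], "a2": [0, 12], "b1": [0, 9], "b2": [0, 11]},
            index=["gz", "g"],
        )
        design = pd.Series(["A", "A", "B", "B"], index=counts.columns)
        res = nb_wald_test(counts, design)
        assert np.isnan(res.loc["gz", "pvalue"])
        assert np.isfinite(res.loc["g", "pvalue"])

    def test_true_lfc_recovery(self):
        # shift a 10% subset so median-of-ratios normalization stays anchored
        rng = np.random.default_rng(11)
        n, n_shift = 1000, 100
        mu = rng.lognormal(5, 0.5, n)
        fold = np.ones(n)
        fold[:n_shift] = 4.0
        a = nb_counts(rng, mu[:, None], 0.05, (n, 3))
        b = nb_counts(rng, (fold * mu)[:, None], 0.05, (n, 3))
        counts = pd.DataFrame(
            np.hstack([a, b]), columns=[f"a{i}" for i in range(3)] + [f"b{i}" for i in range(3)]
        )
        design = pd.Series(["A"] * 3 + ["B"] * 3, index=counts.columns)
        res = nb_wald_test(counts, design)
        assert res["log2FC"].iloc[:n_shift].mean() == pytest.approx(2.0, abs=0.3)

    def test_group_label_swap_negates_lfc_preserves_p(self, null_fit):
        counts, design, res = null_fit
        swapped = design.map({"A": "B", "B": "A"})
        res2 = nb_wald_test(counts, swapped, control="A", treatment="B")
        ok = np.isfinite(res["log2FC"]) & np.isfinite(res2["log2FC"])
        assert np.allclose(res.loc[ok, "log2FC"], -res2.loc[ok, "log2FC"], atol=1e-4)
        assert np.allclose(res.loc[ok, "pvalue"], res2.loc[ok, "pvalue"], atol=1e-6)

    def test_uniform_count_scaling_leaves_results_unchanged(self, null_fit):
        counts, design, res = null_fit
        res2 = nb_wald_test(counts * 3, design)
        ok = np.isfinite(res["log2FC"])
        # near-exact for log2FC (size factors absorb the scale) ...
        assert np.allclose(res.loc[ok, "log2FC"], res2.loc[ok, "log2FC"], atol=1e-2)
        # ... approximate for p (the Poisson noise share shrinks slightly)
        assert np.corrcoef(res.loc[ok, "pvalue"], res2.loc[ok, "pvalue"])[0, 1] > 0.99

    def test_requires_two_groups_and_replicates(self):
        counts = pd.DataFrame({"a": [1], "b": [2], "c": [3]})
        with pytest.raises(ValueError):
            nb_wald_test(counts, pd.Series(["A", "A", "A"], index=counts.columns))
        with pytest.raises(ValueError):
            nb_wald_test(counts, pd.Series(["A", "A", "B"], index=counts.columns))

    def test_padj_monotone_with_p(self, null_fit):
        _, _, res = null_fit
        ok = res.dropna(subset=["pvalue"]).sort_values("pvalue")
        assert ok["padj"].is_monotonic_increasing
        assert np.all(ok["padj"] >= ok["pvalue"] - 1e-12)


class TestAggregateGeneEditing:
    def test_two_sites_sum(self, small_study, small_design):
        st = small_study
        sites, _ = discover_sites(st.candidates)
        ann = annotate_sites(sites, st.genes, st.sequences)
        mat = aggregate_gene_editing(ann, st.genes, st.config.samples)
        # brute-force double loop oracle
        expected = {}
        for a in ann:
            if a.gene_id is None:
                continue
            gene = next(g for g in st.genes if g.gene_id == a.gene_id)
            if not gene.contains(a.site.pos):
                continue
            for s in st.config.samples:
                if a.site.frequency.get(s) is not None:
                    key = (a.gene_id, s)
                    expected[key] = expected.get(key, 0) + a.site.alt_depth[s]
        for (gid, s), v in expected.items():
            assert mat.loc[gid, s] == v
        assert int(mat.to_numpy().sum()) == sum(expected.values())

    def test_simple_sum_and_absent_gene(self):
        from editlens.annotation import AnnotatedSite
        from editlens.models import EditingSite, Gene

        g = Gene("g1", "c", 100, 200, "+", exons=((100, 200),), cds=())
        mk = lambda pos, alt: AnnotatedSite(
            site=EditingSite("c", pos, "A", "G", {"s": 50}, {"s": alt},
                             {"s": alt / 50}),
            gene_id="g1", gene_strand="+", mismatch_type="A>G",
            collapsed_type="A-to-I", region="exonic", consequence="noncoding",
        )
        mat = aggregate_gene_editing([mk(110, 3), mk(120, 5)], [g], ["s"])
        assert mat.loc["g1", "s"] == 8
        assert list(mat.index) == ["g1"]

    def test_invalid_measurement_contributes_zero(self):
        from editlens.annotation import AnnotatedSite
        from editlens.models import EditingSite, Gene

        g = Gene("g1", "c", 100, 200, "+", exons=((100, 200),), cds=())
        a = AnnotatedSite(
            site=EditingSite("c", 110, "A", "G", {"s": 50, "t": 4},
                             {"s": 10, "t": 2}, {"s": 0.2, "t": None}),
            gene_id="g1", gene_strand="+", mismatch_type="A>G",
            collapsed_type="A-to-I", region="exonic", consequence="noncoding",
        )
        mat = aggregate_gene_editing([a], [g], ["s", "t"])
        assert mat.loc["g1", "s"] == 10
        assert mat.loc["g1", "t"] == 0
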