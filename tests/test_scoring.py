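"""PCA score model, TMB, strata, frequency summaries and rank statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from m6ascore import (
    M6AScoreModel,
    cnv_frequency,
    combine_strata,
    correlate,
    fit_score_model,
    group_compare,
    m6a_score,
    mutation_frequency,
    stratify_score,
    tmb_per_sample,
)
from m6ascore.io import CopyNumberCalls, MutationTable
from m6ascore.scoring import PCAModel


def _frame(rng, n_genes=10, n_samples=30):
    return pd.DataFrame(
        rng.normal(8, 2, (n_genes, n_samples)),
        index=[f"G{i}" for i in range(n_genes)],
        columns=[f"s{j}" for j in range(n_samples)],
    )


class TestScoreModel:
    def test_rank_one_data_loads_on_pc1(self, rng):
        factor = rng.normal(size=40)
        loadings = rng.normal(size=8)
        x = pd.DataFrame(
            np.outer(loadings, factor) + rng.normal(0, 0.01, (8, 40)),
            index=[f"G{i}" for i in range(8)],
            columns=[f"s{j}" for j in range(40)],
        )
        res = M6AScoreModel(x, list(x.index)).fit()
        assert res.model.explained_variance_ratio[0] > 0.99

    def test_loadings_match_eigendecomposition_oracle(self, rng):
        """SVD loadings agree (up to sign) with an independent eigendecomposition
        of the gene-gene correlation matrix on a small instance."""
        x = _frame(rng, n_genes=6, n_samples=20)
        model = fit_score_model(x, list(x.index))
        z = ((x.T - x.mean(axis=1)) / x.std(axis=1, ddof=1)).to_numpy()
        corr = z.T @ z / (z.shape[0] - 1)
        w, v = np.linalg.eigh(corr)
        for j, eig_idx in enumerate((-1, -2)):
            ref = v[:, eig_idx]
            got = model.loadings[:, j]
            assert min(np.abs(got - ref).max(), np.abs(got + ref).max()) < 1e-8

    def test_sign_convention_positive_loading_sum(self, rng):
        model = fit_score_model(_frame(rng), [f"G{i}" for i in range(10)])
        assert model.loadings[:, 0].sum() >= 0
        assert model.loadings[:, 1].sum() >= 0

    def test_sample_at_training_mean_scores_zero(self, rng):
        x = _frame(rng)
        model = fit_score_model(x, list(x.index))
        mean_sample = x.mean(axis=1).to_frame("mean_sample")
        assert m6a_score(model, mean_sample)["mean_sample"] == pytest.approx(0.0, abs=1e-10)

    def test_score_invariant_to_gene_constant_shift(self, rng):
        x = _frame(rng)
        model = fit_score_model(x, list(x.index))
        s1 = m6a_score(model, x)
        shifted = x.copy()
        shifted.loc["G0"] += 123.0
        model2 = fit_score_model(shifted, list(x.index))
        s2 = m6a_score(model2, shifted)
        np.testing.assert_allclose(s1, s2, atol=1e-8)

    def test_missing_model_genes_listed(self, rng):
        x = _frame(rng)
        model = fit_score_model(x, list(x.index))
        with pytest.raises(KeyError, match="G0"):
            m6a_score(model, x.drop(index="G0"))

    def test_fewer_than_three_genes_errors(self, rng):
        with pytest.raises(ValueError, match=">=3"):
            M6AScoreModel(_frame(rng), ["G0", "G1"])

    def test_model_json_roundtrip(self, rng):
        x = _frame(rng)
        model = fit_score_model(x, list(x.index))
        back = PCAModel.from_json(model.to_json())
        np.testing.assert_allclose(model.loadings, back.loadings)
        np.testing.assert_allclose(
            m6a_score(model, x), m6a_score(back, x), atol=1e-12
        )

    def test_split_half_stability(self, default_bundle):
        """Scores from models fit on disjoint training halves correlate
        strongly on held-out samples."""
        b = default_bundle
        sig = b.truth["marker_genes"]
        x = b.expression.values
        cols = x.columns.to_numpy()
        rng = np.random.default_rng(1)
        held = rng.choice(cols, 60, replace=False)
        rest = np.setdiff1d(cols, held)
        half1, half2 = rest[::2], rest[1::2]
        s1 = m6a_score(fit_score_model(x[half1], sig), x[held])
        s2 = m6a_score(fit_score_model(x[half2], sig), x[held])
        assert np.corrcoef(s1, s2)[0, 1] > 0.95

    def test_cluster_b_scores_highest(self, default_bundle):
        b = default_bundle
        clusters = b.truth["cluster"]
        res = M6AScoreModel(b.expression, b.truth["marker_genes"]).fit()
        means = res.scores.groupby(clusters).mean()
        assert means.idxmax() == "B" and means.idxmin() == "A"
        stat, p = group_compare(res.scores, clusters.to_numpy(), test="kruskal")
        assert p < 0.001


class TestTmbAndStrata:
    def test_nonsilent_count(self):
        mt = MutationTable(pd.DataFrame({
            "sample_id": ["S1", "S1", "S1"],
            "gene_symbol": ["A", "B", "C"],
            "variant_class": ["missense", "missense", "silent"],
        }))
        assert tmb_per_sample(mt)["S1"] == 2
        assert tmb_per_sample(mt, nonsilent_only=False)["S1"] == 3
        assert tmb_per_sample(mt, per_mb=38.0)["S1"] == pytest.approx(2 / 38)

    def test_absent_sample_scores_zero(self):
        mt = MutationTable(pd.DataFrame({
            "sample_id": ["S1"], "gene_symbol": ["A"], "variant_class": ["missense"],
        }))
        out = tmb_per_sample(mt, samples=["S1", "S2"])
        assert out["S2"] == 0

    def test_tmb_group_difference_on_default_bundle(self, default_bundle):
        b = default_bundle
        tmb = tmb_per_sample(b.mutations, samples=b.expression.samples)
        latent = b.truth["latent_score"]
        low = latent <= latent.median()
        stat, p = group_compare(tmb.to_numpy(), np.where(low, "low", "high"))
        assert p < 0.01
        assert tmb[low.to_numpy()].mean() > tmb[~low.to_numpy()].mean()

    def test_combine_strata_worst_group(self, rng):
        n = 400
        score_group = pd.Series(np.repeat(["high", "low"], n // 2),
                                index=[f"s{i}" for i in range(n)])
        tmb_group = pd.Series(np.tile(np.repeat(["high", "low"], n // 4), 2),
                              index=score_group.index)
        protect = (score_group == "high").astype(float) + (tmb_group == "high").astype(float)
        rates = 0.03 * np.exp(-0.8 * protect.to_numpy())
        t = rng.exponential(1 / rates)
        c = rng.uniform(0, 120, n)
        time, event = np.minimum(t, c), (t <= c).astype(int)
        stratum, (chi2, df, p), pairwise = combine_strata(score_group, tmb_group, time, event)
        assert p < 0.001 and df == 3
        from m6ascore import km_fit

        curves = km_fit(time, event, stratum.to_numpy())
        five_year = {g: c_.survival_at(60) for g, c_ in curves.items()}
        assert min(five_year, key=five_year.get) == "L/L"

    def test_empty_stratum_dropped_with_three_group_test(self, rng):
        idx = [f"s{i}" for i in range(90)]
        score_group = pd.Series(np.repeat(["high", "low", "low"], 30), index=idx)
        tmb_group = pd.Series(np.repeat(["high", "high", "low"], 30), index=idx)
        t = rng.exponential(30, 90)
        stratum, (chi2, df, p), _ = combine_strata(
            score_group, tmb_group, t, np.ones(90, dtype=int)
        )
        assert stratum.nunique() == 3 and df == 2

    def test_stratify_score_records_cutpoint(self, rng):
        n = 100
        scores = pd.Series(rng.normal(size=n), index=[f"s{i}" for i in range(n)])
        t = rng.exponential(30, n)
        groups, cut = stratify_score(scores, t, np.ones(n, dtype=int))
        assert set(groups.unique()) == {"high", "low"}
        assert (scores[groups == "high"] > cut.cutpoint).all()


class TestFrequencies:
    def test_mutation_frequency_percentages(self):
        # 151 altered samples of 567 -> 26.63% overall
        rows = [(f"S{i}", "ZC3H13", "missense") for i in range(151)]
        mt = MutationTable(pd.DataFrame(rows, columns=["sample_id", "gene_symbol", "variant_class"]))
        out = mutation_frequency(mt, ["ZC3H13", "CBLL1"], n_samples=567)
        assert out.attrs["overall_percent"] == 26.63
        assert out.loc["ZC3H13", "count"] == 151
        assert out.loc["CBLL1", "count"] == 0

    def test_multiple_hits_count_once(self):
        mt = MutationTable(pd.DataFrame({
            "sample_id": ["S1", "S1"], "gene_symbol": ["A", "A"],
            "variant_class": ["missense", "nonsense"],
        }))
        out = mutation_frequency(mt, ["A"], n_samples=4)
        assert out.loc["A", "count"] == 1 and out.loc["A", "percent"] == 25.0

    def test_cnv_gain_loss_fractions(self):
        cnv = CopyNumberCalls(pd.DataFrame([[1, -1, 0, 2]], index=["G1"],
                                           columns=list("abcd")))
        out = cnv_frequency(cnv)
        assert out.loc["G1", "gain_freq"] == 0.5
        assert out.loc["G1", "loss_freq"] == 0.25

    def test_frequencies_sample_order_invariant(self, default_bundle):
        cnv = default_bundle.cnv
        shuffled = CopyNumberCalls(cnv.calls.sample(frac=1, axis=1, random_state=0))
        pd.testing.assert_frame_equal(cnv_frequency(cnv), cnv_frequency(shuffled))


class TestCorrelateAndCompare:
    def test_monotone_pairs(self):
        a = pd.DataFrame([[1.0, 2, 3, 4, 5]], index=["up"], columns=list("abcde"))
        b = pd.DataFrame([[2.0, 4, 6, 8, 10], [5.0, 4, 3, 2, 1]],
                         index=["mono", "anti"], columns=list("abcde"))
        rho, p, p_adj = correlate(a, b)
        assert rho.loc["up", "mono"] == pytest.approx(1.0)
        assert rho.loc["up", "anti"] == pytest.approx(-1.0)

    def test_null_calibration(self, rng):
        a = pd.DataFrame(rng.normal(size=(40, 50)), columns=[f"s{i}" for i in range(50)])
        b = pd.DataFrame(rng.normal(size=(25, 50)), columns=a.columns)
        rho, p, _ = correlate(a, b)
        assert abs(rho.to_numpy().mean()) < 0.02
        rate = (p.to_numpy() < 0.05).mean()
        assert 0.02 <= rate <= 0.08

    def test_constant_vector_yields_missing(self, rng):
        a = pd.DataFrame([[1.0, 1, 1, 1]], index=["flat"], columns=list("abcd"))
        b = pd.DataFrame([[1.0, 2, 3, 4]], index=["x"], columns=list("abcd"))
        rho, p, _ = correlate(a, b)
        assert np.isnan(rho.loc["flat", "x"])

    def test_kruskal_two_groups_equals_wilcoxon_chi2(self, rng):
        v = rng.normal(size=60)
        labels = np.repeat(["a", "b"], 30)
        kw_stat, kw_p = group_compare(v, labels, test="kruskal")
        ref = stats.kruskal(v[:30], v[30:])
        assert kw_stat == pytest.approx(ref.statistic)
        # wilcoxon on the same data agrees in p-value up to the normal/chi2 link
        _, w_p = group_compare(v, labels, test="wilcoxon")
        assert kw_p == pytest.approx(w_p, rel=0.05)

    def test_shifted_groups_detected(self, rng):
        v = np.concatenate([rng.normal(0, 1, 50), rng.normal(1, 1, 50)])
        labels = np.repeat(["a", "b"], 50)
        _, p = group_compare(v, labels)
        assert p < 0.01

    def test_empty_group_errors(self):
        with pytest.raises(ValueError):
            group_compare([1.0, 2.0], np.array(["a", "a"]), test="wilcoxon")
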