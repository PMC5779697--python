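"""Factorial model fits, clustering, fold changes — against hand oracles."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import make_table
from lipiddiff.ingest import log2_transform, to_mole_percent
from lipiddiff.species_differential import (
    classify_significant,
    cluster_regulation_groups,
    design_2x2,
    fit_species_linear_model,
    per_genotype_fold_changes,
    row_zscores,
    run_three_test_families,
)


def mouse_annotation(n=7):
    rows = []
    for geno in ("wt", "atATGL-KO"):
        for interv in ("sham", "TAC"):
            for i in range(n):
                rows.append({"sample": f"{geno}-{interv}-{i}",
                             "genotype": geno, "intervention": interv})
    return pd.DataFrame(rows).set_index("sample")


def ols_oracle(y, X):
    """Textbook least squares: beta = (X'X)^-1 X'y, classical t and F."""
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ y
    resid = y - X @ beta
    n, p = X.shape
    df = n - p
    s2 = resid @ resid / df
    se = np.sqrt(np.diag(XtX_inv) * s2)
    t = beta / se
    p_t = 2 * stats.t.sf(np.abs(t), df)
    tss = np.sum((y - y.mean()) ** 2)
    rss = resid @ resid
    F = ((tss - rss) / (p - 1)) / (rss / df)
    p_F = stats.f.sf(F, p - 1, df)
    return beta, t, p_t, F, p_F


class TestFit:
    def test_noise_free_cell_means_reproduced_by_coefficients(self):
        ann = mouse_annotation(2)
        X = design_2x2(ann)
        cell_value = {("wt", "sham"): 1.0, ("wt", "TAC"): 2.0,
                      ("atATGL-KO", "sham"): 1.0, ("atATGL-KO", "TAC"): 1.0}
        y = np.array([cell_value[(g, i)] + 1e-6 * k  # tiny jitter: estimable
                      for k, (g, i) in enumerate(
                          zip(ann["genotype"], ann["intervention"]))])
        r = fit_species_linear_model(y, X)
        assert r.beta[2] == pytest.approx(1.0, abs=1e-5)   # intervention
        assert r.beta[3] == pytest.approx(-1.0, abs=1e-5)  # interaction
        assert r.beta[0] == pytest.approx(1.0, abs=1e-5)   # wt-sham mean

    def test_constant_response_is_inestimable_not_zero_p(self):
        ann = mouse_annotation(2)
        r = fit_species_linear_model(np.full(8, 3.0), design_2x2(ann))
        assert not r.estimable
        assert np.isnan(r.p_F)
        np.testing.assert_allclose(r.beta[1:], 0.0, atol=1e-12)

    def test_matches_normal_equations_oracle_on_random_designs(self, rng):
        """1000 random 2x2 instances: coefficients, t, F agree to 1e-10."""
        for _ in range(1000):
            n = int(rng.integers(2, 5))
            ann = mouse_annotation(n)
            X = design_2x2(ann)
            y = rng.normal(size=len(ann))
            r = fit_species_linear_model(y, X)
            beta, t, p_t, F, p_F = ols_oracle(y, X.to_numpy())
            np.testing.assert_allclose(r.beta, beta, atol=1e-10)
            np.testing.assert_allclose([r.t_genotype, r.t_intervention],
                                       t[1:3], atol=1e-10)
            np.testing.assert_allclose([r.p_genotype, r.p_intervention],
                                       p_t[1:3], atol=1e-10)
            assert r.F == pytest.approx(F, abs=1e-8)
            assert r.p_F == pytest.approx(p_F, abs=1e-12)

    def test_casewise_deletion_and_minimum_support(self):
        ann = mouse_annotation(2)
        y = np.full(8, np.nan)
        y[:4] = [1.0, 2.0, 3.0, 4.0]  # only two cells observed
        r = fit_species_linear_model(y, design_2x2(ann))
        assert not r.estimable

    def test_wt_intervention_t_equals_two_sample_t(self, rng):
        """On balanced wt-only data the model's intervention t is the
        classical equal-variance two-sample t statistic."""
        n = 6
        sham = rng.normal(0, 1, n)
        tac = rng.normal(0.8, 1, n)
        ann = pd.DataFrame({
            "genotype": ["wt"] * (2 * n),
            "intervention": ["sham"] * n + ["TAC"] * n,
        }, index=[f"s{i}" for i in range(2 * n)])
        X = pd.DataFrame({"const": 1.0,
                          "intervention": (ann["intervention"] == "TAC").astype(float)})
        y = np.concatenate([sham, tac])
        XtX_inv = np.linalg.inv(X.T @ X)
        beta = XtX_inv @ X.T.to_numpy() @ y
        resid = y - X.to_numpy() @ beta
        s2 = resid @ resid / (2 * n - 2)
        t_model = beta[1] / np.sqrt(s2 * XtX_inv[1, 1])
        t_classic = stats.ttest_ind(tac, sham, equal_var=True).statistic
        assert t_model == pytest.approx(t_classic, abs=1e-10)


class TestFamilies:
    def test_planted_intervention_effects_retained_via_intervention_family(self, rng):
        ann = mouse_annotation(7)
        cols = {}
        truth = []
        for i in range(40):
            name = f"PC {14 + i % 10}:{i % 4}-{15 + (i * 3) % 9}:{i % 3}"
            y = rng.normal(0, 0.3, len(ann))
            if i < 8:
                y[(ann["intervention"] == "TAC").to_numpy()] += 2.0
                truth.append(name)
            cols[name] = y
        table = make_table(pd.DataFrame(cols, index=ann.index), "log2_mole_percent")
        res = run_three_test_families(table, ann)
        assert set(truth) <= set(res.index[res["retained"]])
        assert res.loc[truth, "adj_p_intervention"].lt(0.1).all()

    def test_retained_set_invariant_under_species_permutation(self, mouse_prepared, rng):
        _, _, log2t, annotation, _, _ = mouse_prepared
        res = run_three_test_families(log2t, annotation)
        perm = rng.permutation(log2t.species)
        shuffled = replace(log2t, data=log2t.data[perm])
        res_p = run_three_test_families(shuffled, annotation)
        assert set(res.index[res["retained"]]) == set(res_p.index[res_p["retained"]])

    def test_inestimable_species_do_not_abort_the_run(self):
        ann = mouse_annotation(3)
        df = pd.DataFrame({
            "PE 16:0-18:2": np.arange(12, dtype=float) / 7.0,
            "PC 16:0-18:1": np.full(12, 2.0),  # zero variance
        }, index=ann.index)
        res = run_three_test_families(make_table(df, "log2_mole_percent"), ann)
        assert res.loc["PE 16:0-18:2", "estimable"]
        assert not res.loc["PC 16:0-18:1", "estimable"]
        assert not res.loc["PC 16:0-18:1", "retained"]


class TestClustering:
    def _results_frame(self, tvecs, names):
        df = pd.DataFrame(tvecs, columns=["t_genotype", "t_intervention", "F"])
        df["F"] = df["F"].abs()
        df.index = names
        df["beta_genotype"] = df["t_genotype"]
        df["beta_intervention"] = df["t_intervention"]
        df["beta_interaction"] = 0.0
        df["p_genotype"] = df["p_intervention"] = df["p_F"] = 0.01
        df["adj_p_genotype"] = df["adj_p_intervention"] = df["adj_p_F"] = 0.01
        df["retained"] = True
        df["estimable"] = True
        df.index.name = "species"
        return df

    def _table_for(self, names, ann, rng):
        return make_table(pd.DataFrame(rng.normal(size=(len(ann), len(names))),
                                       index=ann.index, columns=names),
                          "log2_mole_percent")

    def test_two_planted_profiles_separate_perfectly(self, rng):
        ann = mouse_annotation(2)
        names = [f"PE 16:0-18:{i}" for i in range(3)] + [f"PC 16:0-18:{i}" for i in range(3)]
        tvecs = [[5.0 + rng.normal(0, 0.01), 0.0, 25.0] for _ in range(3)] + [
            [0.0, 5.0 + rng.normal(0, 0.01), 25.0] for _ in range(3)]
        res = self._results_frame(tvecs, names)
        groups = cluster_regulation_groups(res, self._table_for(names, ann, rng),
                                           ann, k=2)
        labels = groups.labels
        assert labels[names[:3]].nunique() == 1
        assert labels[names[3:]].nunique() == 1
        assert labels[names[0]] != labels[names[3]]

    def test_labels_invariant_to_input_order(self, rng):
        ann = mouse_annotation(2)
        names = [f"PE 16:0-{18 + i}:{i % 4}" for i in range(8)]
        tvecs = rng.normal(size=(8, 3)).tolist()
        res = self._results_frame(tvecs, names)
        table = self._table_for(names, ann, rng)
        g1 = cluster_regulation_groups(res, table, ann, k=3)
        shuffled = res.sample(frac=1.0, random_state=0)
        g2 = cluster_regulation_groups(shuffled, table, ann, k=3)
        pd.testing.assert_series_equal(g1.labels, g2.labels)

    def test_k_larger_than_retained_errors(self, rng):
        ann = mouse_annotation(2)
        names = ["PE 16:0-18:1", "PE 16:0-18:2"]
        res = self._results_frame([[1, 0, 1], [0, 1, 1]], names)
        with pytest.raises(Exception, match="retained"):
            cluster_regulation_groups(res, self._table_for(names, ann, rng), ann, k=4)

    def test_zscore_rows_have_zero_mean_unit_sd(self, rng):
        means = pd.DataFrame(rng.normal(size=(10, 4)))
        z = row_zscores(means)
        np.testing.assert_allclose(z.mean(axis=1), 0.0, atol=1e-12)
        np.testing.assert_allclose(z.std(axis=1, ddof=0), 1.0, atol=1e-12)

    def test_zscore_constant_row_is_zero(self):
        z = row_zscores(pd.DataFrame([[2.0, 2.0, 2.0, 2.0]]))
        assert z.iloc[0].tolist() == [0.0, 0.0, 0.0, 0.0]


class TestFoldChanges:
    def test_noise_free_doubling_gives_log2fc_one(self):
        ann = mouse_annotation(2)
        pct = {"PE 16:0-18:2": [], "PC 16:0-18:1": []}
        for g, i in zip(ann["genotype"], ann["intervention"]):
            pe = 2.0 if (i == "TAC") else 1.0
            pct["PE 16:0-18:2"].append(pe)
            pct["PC 16:0-18:1"].append(10.0)
        mp = make_table(pd.DataFrame(pct, index=ann.index), "mole_percent")
        l2 = log2_transform(mp)
        fc = per_genotype_fold_changes(l2, mp, ann)
        wt_pe = fc[(fc["genotype"] == "wt") & (fc["species"] == "PE 16:0-18:2")]
        assert wt_pe["log2fc"].iloc[0] == pytest.approx(1.0)
        assert wt_pe["mean_mole_percent"].iloc[0] == pytest.approx(1.5)

    def test_families_are_per_genotype(self, mouse_prepared):
        _, molepct, log2t, annotation, _, _ = mouse_prepared
        fc = per_genotype_fold_changes(log2t, molepct, annotation)
        assert set(fc["genotype"]) == {"wt", "atATGL-KO"}
        n_species = len(log2t.species)
        assert (fc.groupby("genotype").size() == n_species).all()

    def test_missing_group_is_an_error(self):
        ann = mouse_annotation(2)
        ann = ann[~((ann["genotype"] == "wt") & (ann["intervention"] == "TAC"))]
        mp = make_table(pd.DataFrame({"PE 16:0-18:2": np.ones(len(ann))},
                                     index=ann.index), "mole_percent")
        with pytest.raises(Exception, match="sham or TAC"):
            per_genotype_fold_changes(log2_transform(mp), mp, ann)


@pytest.mark.parametrize(
    "adj_p, lfc, expected",
    [(0.05, 0.6, True), (0.05, 0.4, False), (0.2, 1.0, False),
     (0.05, -0.6, True), (np.nan, 1.0, False)],
)
def test_dual_threshold_rule(adj_p, lfc, expected):
    assert classify_significant(adj_p, lfc) is expected
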