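"""Residual-randomization MANCOVA, model reduction, and pairwise tests."""

import numpy as np
import pandas as pd
import pytest

from craniomorph.rrpp import (CollinearDesignError, MANCOVAResults, ShapeMANCOVA,
                              build_design, reduce_model)


def _design(rng, n_per=8, sizes=True):
    rows = []
    for g in ("control", "LOF", "GOF"):
        for i in range(n_per):
            rows.append({"genotype": g, "sex": "F" if i % 2 else "M",
                         "log_size": float(rng.normal(0, 0.05))})
    return pd.DataFrame(rows)


def _null_scores(rng, n, p=3):
    return rng.normal(size=(n, p))


class TestDesignBuilding:
    def test_sum_contrasts_and_interactions(self, rng):
        df = _design(rng)
        x, spans = build_design(df, ["genotype", "sex", "genotype:sex", "log_size"],
                                ["log_size"])
        assert x.shape[1] == 1 + 2 + 1 + 2 + 1
        assert spans["genotype"] == slice(1, 3)
        # covariate centered
        assert abs(x[:, spans["log_size"].start].mean()) < 1e-12

    def test_interaction_requires_main_effects_first(self, rng):
        with pytest.raises(ValueError, match="main-effect"):
            build_design(_design(rng), ["genotype:sex"], [])

    def test_collinear_design_names_aliased_terms(self, rng):
        df = _design(rng)
        df["individual"] = df.index.astype(str)  # one level per row: aliases all
        y = _null_scores(rng, len(df))
        with pytest.raises(CollinearDesignError, match="individual"):
            ShapeMANCOVA(y, df, ["genotype", "individual"])


class TestRrppFit:
    def test_planted_effect_saturates_p(self, rng):
        df = _design(rng)
        y = _null_scores(rng, len(df)) * 0.01
        y[df["genotype"] == "GOF"] += 5.0
        res = ShapeMANCOVA(y, df, ["genotype", "log_size"], ["log_size"]).fit(
            iterations=499, seed=1)
        assert res.table.loc["genotype", "p"] == pytest.approx(1 / 500)

    def test_p_bounded_below_by_iteration_count(self, rng):
        df = _design(rng)
        y = _null_scores(rng, len(df))
        res = ShapeMANCOVA(y, df, ["genotype"], []).fit(iterations=99, seed=0)
        assert 1 / 100 <= res.table.loc["genotype", "p"] <= 1.0

    def test_observation_order_invariance_with_matched_permutations(self, rng):
        """Relabeling rows and conjugating the permutation set leaves every
        statistic and p-value unchanged."""
        df = _design(rng)
        n = len(df)
        y = _null_scores(rng, n)
        perms = [rng.permutation(n) for _ in range(200)]
        res1 = ShapeMANCOVA(y, df, ["genotype", "log_size"], ["log_size"]).fit(
            permutations=perms)
        order = rng.permutation(n)
        inv = np.argsort(order)
        perms2 = [inv[p[order]] for p in perms]
        res2 = ShapeMANCOVA(y[order], df.iloc[order], ["genotype", "log_size"],
                            ["log_size"]).fit(permutations=perms2)
        pd.testing.assert_frame_equal(res1.table, res2.table, rtol=1e-9)

    def test_summary_mentions_terms(self, rng):
        df = _design(rng)
        y = _null_scores(rng, len(df))
        res = ShapeMANCOVA(y, df, ["genotype", "log_size"], ["log_size"]).fit(
            iterations=49, seed=0)
        text = res.summary()
        assert "genotype" in text and "log_size" in text and "iterations: 49" in text

    def test_type3_ss_matches_reduced_vs_full_rss(self, rng):
        df = _design(rng)
        y = _null_scores(rng, len(df))
        model = ShapeMANCOVA(y, df, ["genotype", "sex"], [])
        res = model.fit(iterations=9, seed=0)

        def rss(terms):
            x, _ = build_design(df, terms, [])
            beta, *_ = np.linalg.lstsq(x, y, rcond=None)
            return float(((y - x @ beta) ** 2).sum())

        expected = rss(["sex"]) - rss(["genotype", "sex"])
        assert res.table.loc["genotype", "SS"] == pytest.approx(expected, rel=1e-9)


class TestPairwise:
    def test_identical_group_means_not_significant(self, rng):
        df = _design(rng)
        y = np.zeros((len(df), 2))
        model = ShapeMANCOVA(y, df, ["genotype"], [])
        pw = model.pairwise_means("genotype", iterations=199, seed=0)
        assert (pw["distance"] < 1e-9).all()
        assert (pw["p"] == 1.0).all()

    def test_single_group_effect_isolated(self, rng):
        df = _design(rng)
        y = _null_scores(rng, len(df), 2) * 0.05
        y[df["genotype"] == "GOF"] += 2.0
        model = ShapeMANCOVA(y, df, ["genotype"], [])
        pw = model.pairwise_means("genotype", iterations=499, seed=2)
        pw = pw.set_index(["group_a", "group_b"])
        assert pw.loc[("GOF", "LOF"), "p"] <= 0.01
        assert pw.loc[("GOF", "control"), "p"] <= 0.01
        assert pw.loc[("LOF", "control"), "p"] > 0.05

    def test_distances_satisfy_triangle_inequality(self, rng):
        df = _design(rng)
        y = _null_scores(rng, len(df), 4)
        model = ShapeMANCOVA(y, df, ["genotype"], [])
        pw = model.pairwise_means("genotype", iterations=9, seed=0)
        d = {(r.group_a, r.group_b): r.distance for r in pw.itertuples()}
        d.update({(b, a): v for (a, b), v in d.items()})
        groups = sorted({g for pair in d for g in pair})
        for a in groups:
            for b in groups:
                for c in groups:
                    if len({a, b, c}) == 3:
                        assert d[(a, b)] <= d[(a, c)] + d[(c, b)] + 1e-12

    def test_common_slope_not_flagged(self, rng):
        """An exactly shared slope gives zero pairwise differences, p = 1."""
        df = _design(rng)
        slope = np.array([1.0, -0.5])
        y = np.outer(df["log_size"] - df["log_size"].mean(), slope)
        model = ShapeMANCOVA(y, df, ["genotype", "log_size", "genotype:log_size"],
                             ["log_size"])
        pw = model.pairwise_slopes("genotype", "log_size", iterations=199, seed=0)
        np.testing.assert_allclose(pw["length_diff"], 0.0, atol=1e-9)
        assert (pw["p_length"] == 1.0).all()

    def test_steep_slope_in_one_group_detected(self, rng):
        df = _design(rng, n_per=12)
        c = (df["log_size"] - df["log_size"].mean()).to_numpy()
        y = 0.01 * rng.normal(size=(len(df), 2))
        mask = (df["genotype"] == "GOF").to_numpy()
        y[mask] += np.outer(c[mask], [8.0, 4.0])
        model = ShapeMANCOVA(y, df, ["genotype", "log_size", "genotype:log_size"],
                             ["log_size"])
        pw = model.pairwise_slopes("genotype", "log_size", iterations=499, seed=3)
        pw = pw.set_index(["group_a", "group_b"])
        assert pw.loc[("GOF", "LOF"), "p_length"] <= 0.05
        assert pw.loc[("GOF", "control"), "p_length"] <= 0.05
        assert pw.loc[("LOF", "control"), "p_length"] > 0.05

    def test_angle_between_identical_slopes_is_zero(self, rng):
        df = _design(rng)
        slope = np.array([2.0, 1.0])
        y = np.outer(df["log_size"] - df["log_size"].mean(), slope)
        model = ShapeMANCOVA(y, df, ["genotype", "log_size"], ["log_size"])
        pw = model.pairwise_slopes("genotype", "log_size", iterations=9, seed=0)
        np.testing.assert_allclose(pw["angle_deg"], 0.0, atol=1e-4)

    def test_group_without_size_variation_rejected(self, rng):
        df = _design(rng)
        df.loc[df["genotype"] == "LOF", "log_size"] = 0.0
        y = _null_scores(rng, len(df), 2)
        model = ShapeMANCOVA(y, df, ["genotype", "log_size"], ["log_size"])
        with pytest.raises(ValueError, match="size variation"):
            model.pairwise_slopes("genotype", "log_size", iterations=9, seed=0)


class TestReduceModel:
    def test_all_null_terms_reduce_to_covariate_only(self, rng):
        df = _design(rng, n_per=10)
        y = _null_scores(rng, len(df), 2)
        final, res = reduce_model(y, df, ["genotype", "sex", "log_size"],
                                  covariates=["log_size"], protected=["log_size"],
                                  alpha=0.01, iterations=199, seed=4)
        assert "log_size" in final
        assert final == ["log_size"] or set(final) <= {"log_size"}

    def test_planted_genotype_effect_retained_with_covariate(self, rng):
        df = _design(rng, n_per=10)
        y = _null_scores(rng, len(df), 2) * 0.1
        y[df["genotype"] == "GOF"] += 1.5
        final, _ = reduce_model(
            y, df, ["genotype", "sex", "log_size", "genotype:sex"],
            covariates=["log_size"], protected=["log_size"],
            alpha=0.01, iterations=199, seed=4)
        assert sorted(final) == ["genotype", "log_size"]

    def test_planted_sex_effect_retained(self, rng):
        df = _design(rng, n_per=10)
        y = _null_scores(rng, len(df), 2) * 0.1
        y[(df["sex"] == "F").to_numpy()] += 1.5
        final, _ = reduce_model(
            y, df, ["genotype", "sex", "log_size", "genotype:sex"],
            covariates=["log_size"], protected=["log_size"],
            alpha=0.01, iterations=199, seed=4)
        assert "sex" in final and "log_size" in final

    def test_interactions_removed_before_main_effects(self, rng):
        """A main effect is never dropped while its interaction remains."""
        df = _design(rng, n_per=10)
        y = _null_scores(rng, len(df), 2)
        seen = []
        from craniomorph import rrpp as rrpp_mod

        orig = rrpp_mod.ShapeMANCOVA.fit

        def spy(self, **kw):
            seen.append(list(self.terms))
            return orig(self, **kw)

        rrpp_mod.ShapeMANCOVA.fit = spy
        try:
            reduce_model(y, df, ["genotype", "sex", "log_size", "genotype:sex"],
                         covariates=["log_size"], protected=["log_size"],
                         alpha=0.5, iterations=99, seed=0)
        finally:
            rrpp_mod.ShapeMANCOVA.fit = orig
        for terms in seen:
            if "genotype:sex" in terms:
                assert "genotype" in terms and "sex" in terms
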