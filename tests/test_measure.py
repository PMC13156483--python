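"""Measurement primitives, the panel, asymmetry grading, and eruption scoring."""

import numpy as np
import pandas as pd
import pytest

from craniomorph.io import LandmarkConfiguration
from craniomorph.measure import (MeasurementDefinition, align_canonical,
                                 angle_at_vertex, bilateral_mean,
                                 classify_asymmetry, compute_panel, default_panel,
                                 eruption_score, linear_distance,
                                 normalize_by_size, panel_frame,
                                 penetrance_summary, polygon_area,
                                 projected_distance, root_centroid_size,
                                 snout_deviation, MeasurementValue)
from craniomorph.schemes import CRANIUM_SCHEME
from craniomorph.simulate import make_template


def _cfg(points, **kw):
    return LandmarkConfiguration("s", np.asarray(points, float), **kw)


class TestRootCentroidSize:
    def test_single_point_is_zero(self):
        assert root_centroid_size(np.array([[3.0, -1.0, 7.0]])) == 0.0

    def test_symmetric_square(self):
        pts = [[0.5, 0.5, 0], [0.5, -0.5, 0], [-0.5, 0.5, 0], [-0.5, -0.5, 0]]
        assert root_centroid_size(np.array(pts)) == pytest.approx(np.sqrt(2), abs=1e-12)

    def test_hand_evaluated_formula(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [0, 2, 0]], float)
        assert root_centroid_size(pts) == pytest.approx(np.sqrt(10 / 3), abs=1e-12)

    def test_rigid_invariance_and_linear_scaling(self, rng):
        pts = rng.normal(size=(9, 3))
        base = root_centroid_size(pts)
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        moved = pts @ q + rng.normal(size=3)
        assert root_centroid_size(moved) == pytest.approx(base, rel=1e-12)
        assert root_centroid_size(pts * 2.5) == pytest.approx(2.5 * base, rel=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            root_centroid_size(np.empty((0, 3)))


class TestDistancesAndAngles:
    def _abc(self, a, b, c=None):
        pts = [a, b] + ([c] if c is not None else [])
        cfg = _cfg(pts)
        # ad-hoc scheme-free access via indices
        return cfg

    def test_linear_3_4_5(self):
        cfg = _cfg([[0, 0, 0], [3, 4, 0]])
        cfg.scheme_ref = None
        d = np.linalg.norm(cfg.points[0] - cfg.points[1])
        assert d == 5.0

    def test_linear_matches_coordinatewise_oracle(self, rng):
        from craniomorph.simulate import make_mandible_template

        cfg = make_mandible_template("right")
        names = cfg.scheme.landmark_names
        for _ in range(50):
            a, b = rng.choice(len(names), size=2, replace=False)
            expected = np.sqrt(sum((cfg.points[a][k] - cfg.points[b][k]) ** 2
                                   for k in range(3)))
            assert linear_distance(cfg, names[a], names[b]) == pytest.approx(
                expected, abs=1e-12)

    def test_projected_axis_components(self):
        t = make_template("cranium")
        t.points[CRANIUM_SCHEME.index("nasion")] = [0, 0, 0]
        t.points[CRANIUM_SCHEME.index("bregma")] = [3, 4, 12]
        assert projected_distance(t, "nasion", "bregma", "z") == 12
        assert projected_distance(t, "nasion", "bregma", "x") == 3

    def test_projected_never_exceeds_euclidean(self, rng):
        t = make_template("cranium")
        names = CRANIUM_SCHEME.landmark_names
        t.points = rng.normal(size=t.points.shape)
        for _ in range(1000):
            a, b = rng.choice(len(names), size=2, replace=False)
            axis = rng.choice(["x", "y", "z"])
            assert projected_distance(t, names[a], names[b], axis) <= \
                linear_distance(t, names[a], names[b]) + 1e-12

    def test_right_angle_and_collinear(self):
        t = make_template("cranium")
        i = CRANIUM_SCHEME.index
        t.points[i("nasion")] = [0, 0, 0]
        t.points[i("bregma")] = [1, 0, 0]
        t.points[i("lambda")] = [0, 1, 0]
        angle, flag = angle_at_vertex(t, "bregma", "nasion", "lambda")
        assert angle == pytest.approx(90.0, abs=1e-12) and not flag
        t.points[i("lambda")] = [-2, 0, 0]
        angle, _ = angle_at_vertex(t, "bregma", "nasion", "lambda")
        assert angle == pytest.approx(180.0, abs=1e-9)

    def test_angle_matches_extended_precision_oracle(self, rng):
        import mpmath  # bundled with sympy

        t = make_template("cranium")
        i = CRANIUM_SCHEME.index
        for _ in range(25):
            pts = rng.normal(size=(3, 3))
            t.points[i("bregma")], t.points[i("nasion")], t.points[i("lambda")] = pts
            angle, _ = angle_at_vertex(t, "bregma", "nasion", "lambda")
            u = [mpmath.mpf(float(v)) for v in pts[0] - pts[1]]
            v = [mpmath.mpf(float(v)) for v in pts[2] - pts[1]]
            dot = sum(a * b for a, b in zip(u, v))
            nu = mpmath.sqrt(sum(a * a for a in u))
            nv = mpmath.sqrt(sum(b * b for b in v))
            expected = float(mpmath.degrees(mpmath.acos(dot / (nu * nv))))
            assert angle == pytest.approx(expected, abs=1e-9)

    def test_degenerate_arm_policy(self):
        t = make_template("cranium")
        i = CRANIUM_SCHEME.index
        t.points[i("bregma")] = t.points[i("nasion")]
        angle, flag = angle_at_vertex(t, "bregma", "nasion", "lambda")
        assert angle == 0.0 and flag
        with pytest.raises(ValueError):
            angle_at_vertex(t, "bregma", "nasion", "lambda", on_degenerate="raise")


class TestSnoutDeviation:
    def test_midline_anterior_point_gives_zero(self):
        assert snout_deviation(make_template("cranium")) == pytest.approx(0.0, abs=1e-9)

    def test_arctangent_oracle(self):
        t = make_template("cranium")
        i = CRANIUM_SCHEME.index
        t.points[i("nasion")] = [0, 0, 0]
        t.points[i("internasal_anterior")] = [0, 10, 0]
        t.points[i("nasal_anterior")] = [1, 10, 0]
        expected = np.degrees(np.arctan(1 / 10))
        assert snout_deviation(t) == pytest.approx(expected, abs=1e-4)
        assert snout_deviation(t) == pytest.approx(5.7106, abs=1e-3)

    def test_mirroring_flips_sign(self):
        t = make_template("cranium")
        i = CRANIUM_SCHEME.index
        t.points[i("nasal_anterior")] += [0.4, 0, 0]
        d = snout_deviation(t)
        mirrored = t.copy()
        mirrored.points[:, 0] *= -1
        assert snout_deviation(mirrored) == pytest.approx(-d, abs=1e-12)
        assert d > 0  # rightward is positive


class TestAsymmetryGrading:
    CONTROLS = {"c1": 0.5, "c2": -1.0, "c3": 2.0}

    @pytest.mark.parametrize("value, grade", [
        (1.5, "none"), (-1.5, "none"), (2.0, "none"),      # inside control range
        (3.0, "mild"), (-3.9, "mild"),                     # (m, 2m)
        (4.0, "pronounced"), (5.0, "pronounced"),          # >= 2m
    ])
    def test_rule_table(self, value, grade):
        devs = dict(self.CONTROLS, case=value)
        grades = {g.specimen_id: g.grade
                  for g in classify_asymmetry(devs, list(self.CONTROLS))}
        assert grades["case"] == grade
        assert all(grades[c] == "none" for c in self.CONTROLS)

    def test_boundary_policy_configurable(self):
        devs = dict(self.CONTROLS, case=4.0)
        grades = classify_asymmetry(devs, list(self.CONTROLS),
                                    boundary_pronounced_inclusive=False)
        assert {g.specimen_id: g.grade for g in grades}["case"] == "mild"

    def test_controls_never_graded_asymmetric(self, rng):
        devs = {f"c{i}": float(v) for i, v in enumerate(rng.normal(0, 2, 30))}
        grades = classify_asymmetry(devs, list(devs))
        assert all(g.grade == "none" for g in grades)

    def test_empty_controls_rejected(self):
        with pytest.raises(ValueError):
            classify_asymmetry({"a": 1.0}, [])

    def test_penetrance_counts(self):
        devs = dict(self.CONTROLS, m1=3.0, p1=9.0, n1=0.2)
        genos = {k: "control" for k in self.CONTROLS} | \
            {"m1": "LOF", "p1": "LOF", "n1": "LOF"}
        summary = penetrance_summary(
            classify_asymmetry(devs, list(self.CONTROLS), genos))
        row = summary.set_index("genotype").loc["LOF"]
        assert (row["mild"], row["pronounced"], row["none"]) == (1, 1, 1)
        assert row["penetrance"] == pytest.approx(2 / 3)


class TestBilateralMeanAndNormalization:
    def _value(self, raw, side):
        return MeasurementValue("s1", "m", raw, None, side)

    def test_arithmetic_mean_then_normalize(self):
        out = bilateral_mean(self._value(10.0, "left"), self._value(12.0, "right"),
                             rcs=2.0, kind="linear")
        assert out.raw == 11.0 and out.normalized == 5.5
        assert out.side == "bilateral-mean"

    def test_single_side_flagged(self):
        out = bilateral_mean(self._value(10.0, "left"), None, rcs=2.0, kind="linear")
        assert out.raw == 10.0 and out.side == "single-left"

    def test_normalization_rules(self):
        assert normalize_by_size(5.0, 10.0, "linear") == 0.5
        assert normalize_by_size(5.0, 10.0, "area") == 0.05
        assert normalize_by_size(90.0, 10.0, "angular") is None
        with pytest.raises(ValueError):
            normalize_by_size(5.0, 0.0, "linear")

    def test_uniform_scaling_leaves_normalized_panel_unchanged(self, clean_cohort):
        cohort, _ = clean_cohort
        base = panel_frame(compute_panel(cohort, default_panel()))
        scaled = cohort
        import copy

        scaled_configs = []
        for c in cohort.configurations:
            c2 = c.copy()
            c2.points = c2.points * 1.7
            scaled_configs.append(c2)
        from craniomorph.io import CohortTable

        scaled = CohortTable(scaled_configs, cohort.metadata)
        after = panel_frame(compute_panel(scaled, default_panel()))
        merged = base.merge(after, on=["specimen_id", "measurement"],
                            suffixes=("_a", "_b"))
        mask = merged["normalized_a"].notna()
        np.testing.assert_allclose(merged.loc[mask, "normalized_b"],
                                   merged.loc[mask, "normalized_a"], rtol=1e-9)


class TestEruptionScore:
    def _table(self, counts, n_cusps=13, jaw="mandibular"):
        rows = []
        for spec_id, c in counts.items():
            for k in range(n_cusps):
                rows.append({"specimen_id": spec_id, "jaw": jaw, "cusp_id": f"c{k}",
                             "state": "fully_unobstructed" if k < c else "covered"})
        return pd.DataFrame(rows)

    def test_identical_groups_zero_percent_difference(self):
        table = self._table({"a": 5, "b": 5, "x": 5, "y": 5})
        genos = {"a": "control", "b": "control", "x": "LOF", "y": "LOF"}
        out = eruption_score(table, genos).set_index("genotype")
        assert out.loc["LOF", "percent_diff_vs_control"] == 0.0

    def test_published_magnitude_from_planted_counts(self):
        # control mean 8.0 vs experimental mean 4.28 -> -46.5%
        ctrl = {f"c{i}": c for i, c in enumerate([8, 8, 8, 8, 8, 8])}
        lof_counts = [4, 4, 5, 4, 4, 4, 5]  # mean 4.2857
        lof = {f"l{i}": c for i, c in enumerate(lof_counts)}
        table = self._table(ctrl | lof)
        genos = {k: "control" for k in ctrl} | {k: "LOF" for k in lof}
        out = eruption_score(table, genos).set_index("genotype")
        assert out.loc["LOF", "percent_diff_vs_control"] == pytest.approx(-46.5, abs=0.1)

    def test_counting_matches_indicator_sum(self, rng):
        counts = {f"s{i}": int(v) for i, v in enumerate(rng.integers(0, 13, 10))}
        table = self._table(counts)
        genos = {k: "control" for k in counts}
        out = (table.assign(u=table["state"] == "fully_unobstructed")
               .groupby("specimen_id")["u"].sum())
        for k, v in counts.items():
            assert out[k] == v
        summary = eruption_score(table, genos).set_index("genotype")
        assert summary.loc["control", "mean_count"] == pytest.approx(
            np.mean(list(counts.values())))

    def test_unknown_state_rejected(self):
        table = self._table({"a": 2})
        table.loc[0, "state"] = "exploded"
        with pytest.raises(ValueError, match="exploded"):
            eruption_score(table, {"a": "control"})


class TestPanel:
    def test_empty_definitions_give_empty_panel(self, clean_cohort):
        cohort, _ = clean_cohort
        assert compute_panel(cohort, []) == []

    def test_symmetric_cohort_has_zero_snout_deviation(self, clean_cohort):
        cohort, _ = clean_cohort
        panel = panel_frame(compute_panel(cohort, default_panel()))
        devs = panel[panel["measurement"] == "snout_deviation"]["raw"]
        np.testing.assert_allclose(devs, 0.0, atol=1e-9)

    def test_rigid_motion_invariance(self, clean_cohort, rng):
        """Rotating and translating every configuration of a specimen jointly
        leaves all raw panel values unchanged (projected ones via the fitted
        canonical frame)."""
        from craniomorph.io import CohortTable

        cohort, _ = clean_cohort
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        shift = rng.normal(size=3) * 5
        moved = []
        for c in cohort.configurations:
            c2 = c.copy()
            if c2.dimension == 3:
                c2.points = c2.points @ q.T + shift
            moved.append(c2)
        base = panel_frame(compute_panel(cohort, default_panel()))
        after = panel_frame(compute_panel(CohortTable(moved, cohort.metadata),
                                          default_panel()))
        merged = base.merge(after, on=["specimen_id", "measurement"],
                            suffixes=("_a", "_b"))
        skip = merged["measurement"] == "snout_deviation"  # zero +- sign flip
        np.testing.assert_allclose(merged.loc[~skip, "raw_b"],
                                   merged.loc[~skip, "raw_a"], rtol=1e-8, atol=1e-9)

    def test_specimen_order_independence(self, noisy_cohort):
        from craniomorph.io import CohortTable

        cohort, _ = noisy_cohort
        reordered = CohortTable(list(reversed(cohort.configurations)), cohort.metadata)
        a = panel_frame(compute_panel(cohort, default_panel()))
        b = panel_frame(compute_panel(reordered, default_panel()))
        a = a.sort_values(["specimen_id", "measurement"]).reset_index(drop=True)
        b = b.sort_values(["specimen_id", "measurement"]).reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)

    def test_count_kind_directed_to_eruption(self, clean_cohort):
        cohort, _ = clean_cohort
        bad = MeasurementDefinition("cusps", "count", ("nasion", "bregma", "lambda"))
        with pytest.raises(ValueError, match="eruption_score"):
            compute_panel(cohort, [bad])
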