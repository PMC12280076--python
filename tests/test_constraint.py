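import math

import numpy as np
import pandas as pd
import pytest

from smd_scorecard.constraint import (
    ConstraintSpec,
    evaluate_constraints,
    metric_boundary_distance,
    metric_nearest_invalid,
    metric_violation_rate,
)
from smd_scorecard.data_model import DataModelError, FeatureMatrix, TabularDataset
from smd_scorecard.fixtures import gen_toy_images, measure_lesion_features


def fm(values, names):
    return FeatureMatrix(np.asarray(values, dtype=float), feature_names=names)


class TestEvaluateConstraints:
    def test_interior_point_satisfied(self):
        vm = evaluate_constraints(
            fm([[5.0]], ["x"]),
            [ConstraintSpec(id="c", target="x", kind="interval", lo=0, hi=10)],
        )
        assert not vm.flags[0, 0]
        assert vm.depths[0, 0] == 0.0

    def test_interval_depth_arithmetic(self):
        vm = evaluate_constraints(
            fm([[12.0]], ["x"]),
            [ConstraintSpec(id="c", target="x", kind="interval", lo=0, hi=10)],
        )
        assert vm.flags[0, 0]
        assert vm.depths[0, 0] == pytest.approx(2.0)

    def test_implication_anemia_hemoglobin(self):
        # "if condition = anemia then hemoglobin in [0, 12]"
        data = TabularDataset(frame=pd.DataFrame(
            {"condition": ["anemia", "anemia", "normal"],
             "hemoglobin": [14.0, 11.0, 15.0]}))
        spec = ConstraintSpec(
            id="anemia_hb", target="hemoglobin", kind="implication",
            antecedent=("condition", "anemia"),
            consequent=("hemoglobin", (0.0, 12.0)),
        )
        vm = evaluate_constraints(data, [spec])
        assert vm.flags[:, 0].tolist() == [True, False, False]

    def test_missing_value_fails_closed(self):
        data = TabularDataset(frame=pd.DataFrame({"x": [5.0, np.nan]}))
        vm = evaluate_constraints(
            data, [ConstraintSpec(id="c", target="x", kind="interval", lo=0, hi=10)])
        assert vm.flags[:, 0].tolist() == [False, True]
        assert vm.missing_driven[:, 0].tolist() == [False, True]

    def test_unresolvable_target_rejected(self):
        with pytest.raises(DataModelError, match="not found"):
            evaluate_constraints(
                fm([[1.0]], ["x"]),
                [ConstraintSpec(id="c", target="y", kind="interval", lo=0, hi=1)],
            )

    def test_agrees_with_direct_predicate_oracle(self):
        rng = np.random.default_rng(13)
        categories = ["a", "b", "c", "d"]
        for _ in range(10):
            n = 20
            df = pd.DataFrame({
                "num": rng.normal(0, 2, n),
                "cat": rng.choice(categories, n),
            })
            lo, hi = sorted(rng.normal(0, 2, 2))
            allowed = list(rng.choice(categories, 2, replace=False))
            specs = [
                ConstraintSpec(id="i", target="num", kind="interval", lo=lo, hi=hi),
                ConstraintSpec(id="s", target="cat", kind="category_set",
                               allowed=allowed),
                ConstraintSpec(id="imp", target="num", kind="implication",
                               antecedent=("cat", allowed[0]),
                               consequent=("num", (lo, None))),
            ]
            vm = evaluate_constraints(TabularDataset(frame=df), specs)
            for i in range(n):
                x, c = df.loc[i, "num"], df.loc[i, "cat"]
                assert vm.flags[i, 0] == (not (lo <= x <= hi))
                assert vm.flags[i, 1] == (c not in allowed)
                assert vm.flags[i, 2] == (c == allowed[0] and not (x >= lo))


class TestViolationRate:
    def test_zero_constraints_vacuous(self):
        vm = evaluate_constraints(fm([[1.0]], ["x"]), [])
        assert metric_violation_rate(vm).raw_value == 0.0

    def test_manual_count(self):
        vm = evaluate_constraints(
            fm([[12.0], [5.0], [11.0], [3.0], [2.0]], ["x"]),
            [ConstraintSpec(id="c", target="x", kind="interval", lo=0, hi=10)],
        )
        assert metric_violation_rate(vm).raw_value == pytest.approx(0.4)

    def test_all_violating(self):
        vm = evaluate_constraints(
            fm([[20.0], [30.0]], ["x"]),
            [ConstraintSpec(id="c", target="x", kind="interval", lo=0, hi=10)],
        )
        assert metric_violation_rate(vm).raw_value == 1.0


class TestBoundaryDistance:
    def test_all_satisfied_zero_depth(self):
        vm = evaluate_constraints(
            fm([[5.0], [7.0]], ["x"]),
            [ConstraintSpec(id="c", target="x", kind="interval", lo=0, hi=10)],
        )
        res = metric_boundary_distance(vm)
        assert res.raw_value == 0.0
        assert res.params["mean_satisfied_margin"] == pytest.approx(4.0)

    def test_mean_depth_arithmetic(self):
        vm = evaluate_constraints(
            fm([[12.0], [5.0]], ["x"]),
            [ConstraintSpec(id="c", target="x", kind="interval", lo=0, hi=10)],
        )
        assert metric_boundary_distance(vm).raw_value == pytest.approx(1.0)

    def test_boundary_point_zero_depth_zero_margin(self):
        vm = evaluate_constraints(
            fm([[10.0]], ["x"]),
            [ConstraintSpec(id="c", target="x", kind="interval", lo=0, hi=10)],
        )
        res = metric_boundary_distance(vm)
        assert res.raw_value == 0.0
        assert res.params["mean_satisfied_margin"] == 0.0

    def test_translation_equivariance(self, rng):
        x = rng.normal(5, 3, 30)
        shift = 17.3
        vm1 = evaluate_constraints(
            fm(x[:, None], ["x"]),
            [ConstraintSpec(id="c", target="x", kind="interval", lo=0, hi=10)])
        vm2 = evaluate_constraints(
            fm((x + shift)[:, None], ["x"]),
            [ConstraintSpec(id="c", target="x", kind="interval",
                            lo=0 + shift, hi=10 + shift)])
        np.testing.assert_allclose(vm1.depths, vm2.depths, atol=1e-12)

    def test_no_interval_constraints_rejected(self):
        vm = evaluate_constraints(
            TabularDataset(frame=pd.DataFrame({"c": ["a"]})),
            [ConstraintSpec(id="s", target="c", kind="category_set", allowed=["a"])])
        with pytest.raises(DataModelError, match="interval"):
            metric_boundary_distance(vm)


class TestNearestInvalid:
    def test_coincident_point_distance_zero(self):
        syn = fm([[1.0, 2.0]], ["a", "b"])
        inv = fm([[1.0, 2.0]], ["a", "b"])
        res = metric_nearest_invalid(syn, inv)
        assert res.raw_value == 0.0 and res.params["min_distance"] == 0.0

    def test_euclidean_arithmetic(self):
        assert metric_nearest_invalid(
            fm([[3.0, 4.0]], ["a", "b"]), fm([[0.0, 0.0]], ["a", "b"])
        ).raw_value == pytest.approx(5.0)

    def test_matches_exhaustive_pairwise_minimum(self, rng):
        syn = rng.normal(size=(12, 3))
        inv = rng.normal(size=(5, 3))
        expected = np.mean([
            min(np.linalg.norm(s - v) for v in inv) for s in syn
        ])
        got = metric_nearest_invalid(
            FeatureMatrix(syn), FeatureMatrix(inv)).raw_value
        assert got == pytest.approx(expected)


class TestPlantedViolationRecovery:
    @pytest.mark.parametrize("f", [0.0, 0.2, 0.5])
    def test_violation_rate_recovers_planted_fraction(self, f):
        diameter_range = (10.0, 20.0)
        images, truth = gen_toy_images(
            n=10, size=64, diameter_range=diameter_range,
            violation_fraction=f, seed=31)
        measured = measure_lesion_features(images)
        specs = [
            ConstraintSpec(id="one_lesion", target="lesion_count",
                           kind="interval", lo=1, hi=1),
            ConstraintSpec(id="diameter", target="lesion_diameter",
                           kind="interval", lo=diameter_range[0],
                           hi=diameter_range[1]),
        ]
        vm = evaluate_constraints(measured, specs)
        rate = metric_violation_rate(vm).raw_value
        assert rate == pytest.approx(math.floor(f * 10) / 10)
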