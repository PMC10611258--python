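"""2D mechanism-of-action integration and pairwise MANOVA."""

import numpy as np
import pytest
from scipy import stats as sps

from somaxon.errors import PairingError, UsageError
from somaxon.moa import (MoAPoint, classify_moa, make_moa_points,
                         make_replicate_points, manova_pairwise)
from somaxon.scoring import (CompoundSummary, ToxicityLine,
                             ToxicityProbability)
from somaxon.stats import wilks_manova


def _summary(compound, conc, kind, mean):
    return CompoundSummary(compound, conc, kind, mean, 1.0, 8)


class TestMakeMoaPoints:
    def test_pairs_compartment_means(self):
        soma = [_summary("oxaliplatin", "10 uM", "soma", 32.5)]
        axon = [_summary("oxaliplatin", "10 uM", "axon", 28.5)]
        (pt,) = make_moa_points(soma, axon)
        assert (pt.axon_percent, pt.soma_percent) == (28.5, 32.5)

    def test_vehicle_at_origin(self):
        (pt,) = make_moa_points([_summary("DMSO", "0.1%", "soma", 0.0)],
                                [_summary("DMSO", "0.1%", "axon", 0.0)])
        assert (pt.axon_percent, pt.soma_percent) == (0.0, 0.0)

    def test_unmatched_condition_rejected(self):
        with pytest.raises(PairingError):
            make_moa_points([_summary("a", "1 uM", "soma", 1.0)], [])
        with pytest.raises(PairingError):
            make_moa_points([], [_summary("a", "1 uM", "axon", 1.0)])


class TestReplicatePairing:
    def _probs(self, kind, compound, values):
        return [ToxicityProbability(f"{compound}_{kind}_{i}", kind, 100,
                                    int(v), compound=compound,
                                    concentration="1 uM")
                for i, v in enumerate(values)]

    def test_truncates_to_smaller_compartment(self):
        soma = self._probs("soma", "pac", [10, 20, 30, 40])
        axon = self._probs("axon", "pac", [5, 15])
        points = make_replicate_points(soma, axon)
        assert len(points) == 2
        assert all(p.mode == "replicate" for p in points)

    def test_condition_mismatch_rejected(self):
        with pytest.raises(PairingError):
            make_replicate_points(self._probs("soma", "pac", [1, 2]),
                                  self._probs("axon", "vin", [1, 2]))


class TestClassifyMoa:
    SOMA_LINE = ToxicityLine("soma", 3.3, 0, 0, ())
    AXON_LINE = ToxicityLine("axon", 21.1, 0, 0, ())

    @pytest.mark.parametrize("axon,soma,expected", [
        (1.0, 0.5, "none"),
        (5.0, 30.0, "soma-dominant"),
        (50.0, 40.0, "mixed"),
        (50.0, 2.0, "axon-dominant"),
        (21.1, 3.3, "none"),            # exactly on both lines: ties don't exceed
    ])
    def test_quadrant_reading(self, axon, soma, expected):
        pt = MoAPoint("x", "1 uM", axon_percent=axon, soma_percent=soma)
        call = classify_moa(pt, self.SOMA_LINE, self.AXON_LINE)
        assert call.category == expected

    def test_swapped_lines_rejected(self):
        pt = MoAPoint("x", "1 uM", axon_percent=1, soma_percent=1)
        with pytest.raises(UsageError):
            classify_moa(pt, self.AXON_LINE, self.SOMA_LINE)


def _hotelling_two_sample_p(x, y):
    """Independent oracle: two-sample Hotelling's T^2 via pooled covariance."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n1, n2 = len(x), len(y)
    p = x.shape[1]
    d = x.mean(axis=0) - y.mean(axis=0)
    s = (((x - x.mean(axis=0)).T @ (x - x.mean(axis=0))) +
         ((y - y.mean(axis=0)).T @ (y - y.mean(axis=0)))) / (n1 + n2 - 2)
    t2 = (n1 * n2) / (n1 + n2) * d @ np.linalg.solve(s, d)
    f = (n1 + n2 - p - 1) / ((n1 + n2 - 2) * p) * t2
    return sps.f.sf(f, p, n1 + n2 - p - 1)


class TestWilksManova:
    def test_two_group_equals_hotelling(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            x = rng.normal(0, 1, size=(10, 2))
            y = rng.normal(0.5, 1, size=(12, 2))
            res = wilks_manova([x, y])
            assert res.p_value == pytest.approx(
                _hotelling_two_sample_p(x, y), abs=1e-9)

    def test_agrees_with_statsmodels(self):
        from statsmodels.multivariate.manova import MANOVA

        rng = np.random.default_rng(4)
        x = rng.normal(0, 1, size=(9, 2))
        y = rng.normal(1, 1, size=(11, 2))
        res = wilks_manova([x, y])
        data = np.vstack([x, y])
        groups = np.array(["a"] * 9 + ["b"] * 11)
        sm = MANOVA(data, np.column_stack(
            [np.ones(20), (groups == "b").astype(float)]))
        table = sm.mv_test().results["x1"]["stat"]
        assert res.wilks_lambda == pytest.approx(
            float(table.loc["Wilks' lambda", "Value"]), abs=1e-10)
        assert res.p_value == pytest.approx(
            float(table.loc["Wilks' lambda", "Pr > F"]), abs=1e-8)

    def test_strong_separation_detected(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, size=(10, 2))
        y = rng.normal([10, 0], 1, size=(10, 2))  # 10 pooled SDs on one axis
        assert wilks_manova([x, y]).p_value < 0.01


class TestManovaPairwise:
    def _points(self, cond, xy, n, rng):
        return [MoAPoint(cond, "", *np.clip(rng.normal(xy, 1), 0, 100),
                         mode="replicate", replicate=i) for i in range(n)]

    def test_symmetric_matrix_and_label_permutation(self):
        rng = np.random.default_rng(2)
        pts = (self._points("a", [5, 5], 6, rng) +
               self._points("b", [40, 5], 6, rng) +
               self._points("c", [5, 40], 6, rng))
        labels, mat, results = manova_pairwise(pts)
        assert set(labels) == {"a", "b", "c"}
        assert np.allclose(mat.values, mat.values.T, equal_nan=True)
        # same points presented in reversed order: same p for each pair
        labels2, mat2, _ = manova_pairwise(list(reversed(pts)))
        for x in labels:
            for y in labels:
                if x != y:
                    assert mat.loc[x, y] == pytest.approx(mat2.loc[x, y],
                                                          abs=1e-12)

    def test_small_groups_excluded_with_warning(self):
        rng = np.random.default_rng(3)
        pts = (self._points("big", [10, 10], 6, rng) +
               self._points("big2", [30, 10], 6, rng) +
               self._points("tiny", [5, 5], 2, rng))
        with pytest.warns(UserWarning, match="tiny"):
            labels, mat, _ = manova_pairwise(pts)
        assert "tiny" not in labels

    def test_mean_mode_points_rejected(self):
        pt = MoAPoint("a", "", 1.0, 1.0, mode="mean")
        with pytest.raises(UsageError):
            manova_pairwise([pt, pt])


def test_moa_point_range_validated():
    with pytest.raises(UsageError):
        MoAPoint("a", "", axon_percent=101.0, soma_percent=0.0)
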