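"""Toxicity probability, decision line and Dunnett statistics."""

import numpy as np
import pytest
from scipy import stats as sps

from somaxon.classifier import TilePrediction
from somaxon.errors import InsufficientDataError, UsageError
from somaxon.scoring import (CompoundSummary, ToxicityLine,
                             ToxicityProbability, anova_dunnett, exceeds_line,
                             summarize, toxicity_line, toxicity_probability)
from somaxon.stats import (DunnettQuadrature, dunnett_critical_value,
                           dunnett_from_samples)


def _preds(n, n_pos, parent="img"):
    return [TilePrediction(parent_id=parent, origin_x=0, origin_y=48 * i,
                           positive_probability=0.9 if i < n_pos else 0.1,
                           positive_call=i < n_pos) for i in range(n)]


class TestToxicityProbability:
    @pytest.mark.parametrize("n,pos,expected", [
        (36, 0, 0.0), (16, 16, 100.0), (36, 9, 25.0), (144, 36, 25.0),
    ])
    def test_percent_positive(self, n, pos, expected):
        assert toxicity_probability(_preds(n, pos)).percent_positive == expected

    def test_empty_rejected(self):
        with pytest.raises(UsageError):
            toxicity_probability([])

    def test_mixed_parents_rejected(self):
        preds = _preds(4, 2, "a") + _preds(4, 2, "b")
        with pytest.raises(UsageError):
            toxicity_probability(preds)

    def test_counts_reported(self):
        tp = toxicity_probability(_preds(36, 7))
        assert (tp.n_tiles, tp.n_positive) == (36, 7)


def _tox(percent, image_id="x", kind="soma", compound="", conc=""):
    # express a percentage exactly as counts out of 1000
    return ToxicityProbability(image_id=image_id, area_kind=kind,
                               n_tiles=1000, n_positive=int(round(10 * percent)),
                               compound=compound, concentration=conc)


class TestToxicityLine:
    def test_hand_checkable_case(self):
        probs = [_tox(v, f"i{k}") for k, v in enumerate([0, 0, 0, 4])]
        line = toxicity_line(probs)
        assert line.negative_mean == pytest.approx(1.0)
        assert line.negative_sd == pytest.approx(2.0)
        assert line.threshold_percent == pytest.approx(5.0)

    def test_all_zero_inputs_give_zero_line(self):
        line = toxicity_line([_tox(0, f"i{k}") for k in range(6)])
        assert line.threshold_percent == 0.0

    def test_matches_streaming_oracle(self):
        """Two-pass numpy line equals an independent Welford accumulator."""
        rng = np.random.default_rng(42)
        vals = rng.uniform(0, 50, size=200)
        probs = [_tox(v, f"i{k}") for k, v in enumerate(vals)]
        line = toxicity_line(probs)
        # Welford online mean/variance
        mean, m2 = 0.0, 0.0
        for i, p in enumerate(probs, start=1):
            x = p.percent_positive
            d = x - mean
            mean += d / i
            m2 += d * (x - mean)
        sd = (m2 / (len(probs) - 1)) ** 0.5
        assert line.threshold_percent == pytest.approx(mean + 2 * sd, abs=1e-9)

    def test_order_invariance_and_scaling(self):
        rng = np.random.default_rng(1)
        vals = rng.integers(0, 500, size=30)  # tenths of a percent
        probs = [ToxicityProbability(f"i{k}", "soma", 1000, int(v))
                 for k, v in enumerate(vals)]
        shuffled = [probs[i] for i in rng.permutation(len(probs))]
        assert toxicity_line(probs).threshold_percent == pytest.approx(
            toxicity_line(shuffled).threshold_percent, abs=1e-12)
        halved = [ToxicityProbability(f"i{k}", "soma", 2000, int(v))
                  for k, v in enumerate(vals)]
        line, hline = toxicity_line(probs), toxicity_line(halved)
        assert hline.threshold_percent == pytest.approx(
            line.threshold_percent / 2, abs=1e-9)
        assert hline.negative_mean == pytest.approx(line.negative_mean / 2)
        assert hline.negative_sd == pytest.approx(line.negative_sd / 2)

    def test_insufficient_data(self):
        with pytest.raises(InsufficientDataError):
            toxicity_line([_tox(0)])

    def test_mixed_kinds_rejected(self):
        with pytest.raises(UsageError):
            toxicity_line([_tox(0, "a", "soma"), _tox(0, "b", "axon")])


class TestExceedsLine:
    LINE = ToxicityLine("soma", 3.3, 0.3, 1.5, ())

    def test_clearly_above(self):
        assert exceeds_line(_tox(24.6), self.LINE)

    def test_zero_below(self):
        assert not exceeds_line(_tox(0.0), self.LINE)

    def test_tie_does_not_exceed(self):
        line = ToxicityLine("soma", 25.0, 0, 0, ())
        assert not exceeds_line(_tox(25.0), line)

    def test_summary_and_kind_mismatch(self):
        s = CompoundSummary("x", "1 uM", "axon", 50.0, 1.0, 5)
        with pytest.raises(UsageError):
            exceeds_line(s, self.LINE)
        s2 = CompoundSummary("x", "1 uM", "soma", 50.0, 1.0, 5)
        assert exceeds_line(s2, self.LINE)


class TestSummarize:
    def test_mean_and_sem(self):
        probs = [_tox(v, f"i{k}", compound="pac", conc="1 uM")
                 for k, v in enumerate([10.0, 20.0, 30.0])]
        (s,) = summarize(probs)
        assert s.mean_percent == pytest.approx(20.0)
        assert s.sem_percent == pytest.approx(10.0 / np.sqrt(3))
        assert s.n_images == 3


class TestDunnett:
    def test_single_treatment_reduces_to_t_test(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            a = rng.normal(0, 1, size=int(rng.integers(4, 25)))
            b = rng.normal(0.3, 1, size=int(rng.integers(4, 25)))
            _, p = dunnett_from_samples([b], a)
            t = sps.ttest_ind(b, a, equal_var=True)
            assert p[0] == pytest.approx(t.pvalue, abs=1e-6)

    def test_critical_value_matches_published_table(self):
        """Two-sided 5% point for 3 treatments, balanced n, 20 df.

        Reference value 2.540347 computed with the multivariate-t
        quantile routine of R's mvtnorm (abseps 1e-8); classical Dunnett
        tables print 2.54.
        """
        q = dunnett_critical_value(0.05, [6, 6, 6], 6)
        assert q == pytest.approx(2.540347, abs=5e-4)

    def test_large_shift_is_significant(self):
        rng = np.random.default_rng(0)
        ctrl = rng.normal(0, 1, 10)
        shifted = rng.normal(5, 1, 10)  # 5 pooled SDs away
        other = rng.normal(0, 1, 10)
        _, p = dunnett_from_samples([shifted, other], ctrl)
        assert p[0] < 0.001

    def test_agrees_with_scipy_dunnett(self):
        rng = np.random.default_rng(7)
        groups = [rng.normal(0.4 * i, 1, 12) for i in range(3)]
        ctrl = rng.normal(0, 1, 15)
        _, mine = dunnett_from_samples(groups, ctrl)
        ref = sps.dunnett(*groups, control=ctrl, rng=1).pvalue
        assert np.allclose(mine, ref, atol=2e-3)

    def test_anova_dunnett_interface(self):
        rng = np.random.default_rng(5)
        groups = {
            "DMSO": list(rng.normal(0, 1, 8)),
            "drugA": list(rng.normal(4, 1, 8)),
            "drugB": list(rng.normal(0, 1, 8)),
        }
        results = anova_dunnett(groups, control="DMSO", alpha=0.05)
        assert results[0].comparison == "ANOVA"
        by_name = {r.comparison: r for r in results[1:]}
        assert by_name["drugA vs DMSO"].significant
        assert not by_name["drugB vs DMSO"].significant

    def test_missing_control_rejected(self):
        with pytest.raises(UsageError):
            anova_dunnett({"a": [1, 2], "b": [2, 3]}, control="DMSO")

    def test_small_group_rejected(self):
        with pytest.raises(InsufficientDataError):
            anova_dunnett({"DMSO": [1.0], "a": [1, 2]}, control="DMSO")

    def test_quadrature_cdf_is_monotone(self):
        quad = DunnettQuadrature([8, 8], 8)
        ts = np.linspace(0.1, 6, 25)
        cdf = quad.cdf_max_abs(ts)
        assert np.all(np.diff(cdf) > 0)
        assert 0 < cdf[0] < cdf[-1] < 1
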