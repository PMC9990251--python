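import dataclasses

import numpy as np
import pytest

from nhrs_barometer import (
    DomainError,
    PerformanceBand,
    classify_band,
    function_score,
    minmax_index,
    overall_score,
    performance_gap,
    score_country,
)
from nhrs_barometer.schema import IndicatorKind, Scaling

from .conftest import random_observation


class TestMinmaxIndex:
    @pytest.mark.parametrize(
        "actual, lo, hi, expected",
        [
            (3.157, 0.0, 5.39, 0.586),   # university density index
            (0.328, 0.0, 2.0, 0.164),    # budget share index
            (3.157, 0.0, 100.0, 0.0316),  # staffing index
            (0.0, 0.0, 5.39, 0.0),
            (5.39, 0.0, 5.39, 1.0),
        ],
    )
    def test_worked_examples_and_boundaries(self, actual, lo, hi, expected):
        sfi = minmax_index(actual, lo, hi)
        assert sfi.index == pytest.approx(expected, abs=5e-4)
        assert not sfi.clamped

    def test_clamps_above_goalpost_with_flag(self):
        sfi = minmax_index(15.0, 0.0, 12.514)  # out-publishing the benchmark
        assert sfi.index == 1.0
        assert sfi.clamped

    def test_clamps_below_goalpost_with_flag(self):
        sfi = minmax_index(1.0, 2.0, 5.0)
        assert sfi.index == 0.0
        assert sfi.clamped

    def test_degenerate_goalposts_raise(self):
        with pytest.raises(DomainError):
            minmax_index(1.0, 2.0, 2.0)


class TestAggregation:
    def test_leadership_function_score(self):
        assert function_score([0, 1, 0, 1, 1, 0]) == 50.0

    def test_developing_function_score_from_printed_indices(self):
        assert function_score([1, 0.0316, 1, 1, 0.586, 1]) == pytest.approx(76.96, abs=5e-3)

    def test_financing_function_score(self):
        assert function_score([1, 0.164]) == pytest.approx(58.2, abs=1e-9)

    def test_empty_function_raises(self):
        with pytest.raises(DomainError):
            function_score([])

    def test_overall_extremes(self):
        assert overall_score([1.0] * 17) == 100.0
        assert overall_score([0.0] * 17) == 0.0
        with pytest.raises(DomainError):
            overall_score([])


class TestBandsAndGaps:
    @pytest.mark.parametrize(
        "score, band",
        [
            (0.0, PerformanceBand.nonexistent),
            (1e-12, PerformanceBand.nonexistent),   # within tolerance of 0
            (0.5, PerformanceBand.below_average),
            (49.999, PerformanceBand.below_average),
            (50.0, PerformanceBand.average),
            (50.0 + 5e-10, PerformanceBand.average),  # tolerance at the knot
            (50.001, PerformanceBand.above_average),
            (60.84, PerformanceBand.above_average),
            (99.999, PerformanceBand.above_average),
            (100.0, PerformanceBand.optimal),
        ],
    )
    def test_classification(self, score, band):
        assert classify_band(score) is band

    def test_out_of_range_rejected(self):
        for score in (-0.1, 100.1):
            with pytest.raises(DomainError):
                classify_band(score)
            with pytest.raises(DomainError):
                performance_gap(score)

    @pytest.mark.parametrize("score, gap", [(60.84, 39.16), (77.0, 23.0), (100.0, 0.0)])
    def test_gap_is_shortfall_from_optimal(self, score, gap):
        assert performance_gap(score) == pytest.approx(gap, abs=1e-9)


class TestScoreCountryMauritius:
    def test_headline_scores(self, schema, mauritius):
        card = score_country(schema, mauritius)
        assert round(card.overall_score, 2) == 60.84
        assert card.band is PerformanceBand.above_average
        expected = {
            "leadership_governance": 50.0,
            "developing_resources": 77.0,
            "producing_utilizing": 52.0,
            "financing": 58.2,
        }
        for fid, want in expected.items():
            assert card.function_scores[fid] == pytest.approx(want, abs=0.05)

    def test_gaps(self, schema, mauritius):
        card = score_country(schema, mauritius)
        assert card.gaps["overall"] == pytest.approx(39.16, abs=0.01)
        assert card.gaps["developing_resources"] == pytest.approx(23.0, abs=0.05)
        assert card.gaps["producing_utilizing"] == pytest.approx(48.0, abs=0.05)
        assert card.gaps["financing"] == pytest.approx(41.8, abs=0.05)

    def test_as_printed_mode_reproduces_printed_intermediates(self, schema, mauritius):
        card = score_country(schema, mauritius, precision="as_printed")
        assert card.index_sum == pytest.approx(10.3426, abs=1e-12)
        assert round(card.overall_score, 2) == 60.84

    def test_exact_mode_index_sum(self, schema, mauritius):
        card = score_country(schema, mauritius)
        assert round(card.index_sum, 4) == 10.3427

    def test_pure_function_of_inputs(self, schema, mauritius):
        assert score_country(schema, mauritius) == score_country(schema, mauritius)


class TestScoreCardProperties:
    def test_oracle_equivalence_on_random_observations(self, schema):
        """ScoreCard aggregation matches a flat independent recomputation."""
        rng = np.random.default_rng(7)
        scale = {Scaling.per_100k_population: 100_000, Scaling.per_million_population: 1_000_000}
        for trial in range(200):
            obs = random_observation(schema, rng)
            card = score_country(schema, obs)
            indices = []
            for ind in schema.ordered_indicators():
                if ind.kind is IndicatorKind.binary:
                    a = float(obs.binary_flags[ind.id])
                elif ind.scaling is Scaling.percent_of_total_budget:
                    a = obs.r4h_budget / obs.total_health_budget * 100.0
                else:
                    a = obs.counts[ind.id] / obs.population * scale[ind.scaling]
                raw = (a - ind.goalpost_min) / (ind.goalpost_max - ind.goalpost_min)
                indices.append(min(1.0, max(0.0, raw)))
            assert card.overall_score == pytest.approx(
                sum(indices) / 17 * 100.0, rel=1e-12, abs=1e-12
            )
            assert all(0.0 <= s.index <= 1.0 for s in card.sub_indices)
            assert 0.0 <= card.overall_score <= 100.0
            assert all(0.0 <= v <= 100.0 for v in card.function_scores.values())

    def test_invariants_tie_scores_together(self, schema, mauritius):
        card = score_country(schema, mauritius)
        assert card.overall_score == pytest.approx(
            sum(s.index for s in card.sub_indices) / 17 * 100, abs=1e-9
        )
        by_id = {s.indicator_id: s for s in card.sub_indices}
        for fn in schema.functions:
            own = [by_id[i].index for i in fn.indicator_ids]
            assert card.function_scores[fn.id] == pytest.approx(
                sum(own) / len(own) * 100, abs=1e-9
            )
        for label, gap in card.gaps.items():
            score = card.overall_score if label == "overall" else card.function_scores[label]
            assert gap == pytest.approx(100 - score, abs=1e-9)

    def test_overall_is_count_weighted_mean_of_function_scores(self, schema, mauritius):
        card = score_country(schema, mauritius)
        weights = {fn.id: len(fn.indicator_ids) for fn in schema.functions}
        weighted = sum(card.function_scores[f] * w for f, w in weights.items()) / 17
        assert card.overall_score == pytest.approx(weighted, abs=1e-9)
        unweighted = sum(card.function_scores.values()) / 4
        assert unweighted == pytest.approx(59.3, abs=0.05)
        assert abs(unweighted - card.overall_score) > 1.0  # genuinely different

    def test_monotone_under_single_indicator_improvement(self, schema):
        rng = np.random.default_rng(11)
        for trial in range(50):
            obs = random_observation(schema, rng)
            base = score_country(schema, obs)
            ind = schema.indicators[int(rng.integers(0, 17))]
            improved = dataclasses.replace(
                obs,
                binary_flags=dict(obs.binary_flags),
                counts=dict(obs.counts),
            )
            if ind.kind is IndicatorKind.binary:
                improved.binary_flags[ind.id] = 1
            elif ind.scaling is Scaling.percent_of_total_budget:
                improved.r4h_budget = min(
                    obs.r4h_budget * 1.5 + 1.0, obs.total_health_budget
                )
            else:
                improved.counts[ind.id] = obs.counts[ind.id] + 1
            bumped = score_country(schema, improved)
            assert bumped.overall_score >= base.overall_score - 1e-12
            fid = ind.function_id
            assert bumped.function_scores[fid] >= base.function_scores[fid] - 1e-12

    def test_clamped_indicator_reported_on_card(self, schema, mauritius):
        hot = dataclasses.replace(mauritius, counts=dict(mauritius.counts))
        hot.counts["pubs_per_100k"] = 500  # out-publishes the benchmark rate
        card = score_country(schema, hot)
        sfi = {s.indicator_id: s for s in card.sub_indices}["pubs_per_100k"]
        assert sfi.index == 1.0
        assert sfi.clamped
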