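"""Attention trajectories, the hybrid model, and sleeping-beauty calls."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import mse
from mse.prediction import (
    AttentionTrajectory,
    HybridAttentionModel,
    HybridAttentionResults,
    awakening_year,
    discrimination_report,
    focus_labels,
)


def traj(sid, year, values):
    return AttentionTrajectory(sid, year, dict(enumerate(values, start=1)))


def synthetic_training_set(rng, n=120, separation=True):
    """Linear-ish ratio trajectories; focus samples end with high ratios."""
    trajs, labels = [], []
    for i in range(n):
        focus = i % 3 == 0
        peak = rng.uniform(15, 25) if focus else rng.uniform(1, 8)
        shape = np.clip(np.array([0.25, 0.5, 0.75, 1.0]) + rng.normal(0, 0.05, 4), 0.01, 1)
        shape = np.sort(shape)
        values = peak * shape if separation else rng.uniform(0, 10, 4)
        trajs.append(traj(f"s{i}", 2010, np.sort(values)))
        labels.append(focus)
    return trajs, labels


class TestTrajectories:
    def test_never_followed_samples_have_flat_zero_trajectories(self, default_sim, default_db, default_panels):
        trajs = {
            t.sample_id: t
            for t in mse.trajectories(default_db, panels=default_panels, birth_years=(2016, 2016), max_db_year=2017)
        }
        for sid in default_sim.truth.never_followed_novel:
            assert trajs[sid].mas_by_offset == {1: 0.0}
            assert trajs[sid].ratios == {1: 0.0}  # 0/0 defined as 0
            assert trajs[sid].max_mas == 0.0

    def test_planted_followed_samples_gain_attention(self, default_sim, default_db, default_panels):
        trajs = {
            t.sample_id: t
            for t in mse.trajectories(default_db, panels=default_panels, birth_years=(2016, 2016), max_db_year=2017)
        }
        for sid in default_sim.truth.expected_focus:
            assert trajs[sid].mas_by_offset[1] > 5.0

    def test_training_trajectories_grow_on_average(self, default_db, default_panels):
        # a growing database adds connections but can also displace a sample
        # from an observer's top list, so growth is a cohort-level property
        trajs = mse.trajectories(default_db, panels=default_panels, birth_years=(2010, 2013))
        matrix = np.array([[t.mas_by_offset[i] for i in (1, 2, 3, 4)] for t in trajs])
        means = matrix.mean(axis=0)
        assert all(a <= b + 1e-9 for a, b in zip(means, means[1:]))
        steps = np.diff(matrix, axis=1)
        assert (steps >= -1e-9).mean() > 0.5  # displacement is the exception

    def test_only_novel_samples_are_tracked(self, default_db, default_panels):
        novel = {p.sample_id for p in default_panels if p.is_novel}
        trajs = mse.trajectories(default_db, panels=default_panels)
        assert {t.sample_id for t in trajs} <= novel


class TestAwakening:
    def test_first_crossing_is_reported(self):
        assert awakening_year(traj("x", 2010, [2, 15, 20, 21]), 14) == 2

    def test_never_crossing_reports_none(self):
        assert awakening_year(traj("x", 2010, [1, 2, 3, 4]), 14) is None

    def test_planted_schedule_awakens_when_followers_suffice(self):
        # a dedicated corpus whose follow-up wave stays at full strength:
        # pioneers cross the threshold once ~16 connections accumulate
        sim = mse.simulate_database(
            mse.SimulationConfig(
                seed=5,
                years=(2010, 2015),
                emergent_habitat_year=2012,
                follow_up_per_year=13,
                follow_up_decay=1.0,
                n_planted_duplicates=0,
                qc_fail_fraction=0.0,
            )
        )
        db = mse.ReferenceDatabase.build(sim.profiles, sim.phylogeny)
        panels = mse.score_panel(db)
        trajs = mse.trajectories(db, panels=panels, birth_years=(2012, 2012))
        offsets = {
            t.sample_id: awakening_year(t, 14.0)
            for t in trajs
            if t.sample_id in set(sim.truth.expected_focus)
        }
        assert len(offsets) == len(sim.truth.expected_focus)
        # ~12 connections arrive per wave year, so the threshold falls in year 2
        assert set(offsets.values()) == {2}


class TestHybridModel:
    def test_perfect_line_is_recovered(self):
        trajs = [
            traj(f"s{i}", 2010, np.array([0.25, 0.5, 0.75, 1.0]) * (10 + i % 5))
            for i in range(40)
        ]
        labels = [i % 2 == 0 for i in range(40)]
        model = HybridAttentionModel(trajs, labels).fit(seed=0)
        for i, expected in zip((1, 2, 3, 4), (0.25, 0.5, 0.75, 1.0)):
            assert model.reg[i] == pytest.approx(expected, abs=1e-9)

    def test_importances_are_normalized(self):
        rng = np.random.default_rng(0)
        trajs, labels = synthetic_training_set(rng)
        model = HybridAttentionModel(trajs, labels).fit(seed=0)
        assert sum(model.rf_importance.values()) == pytest.approx(1.0, abs=1e-9)
        assert all(v >= 0 for v in model.rf_importance.values())
        assert all(0.05 <= v <= 1.0 for v in model.reg.values())

    def test_separable_classes_are_classified_accurately(self):
        rng = np.random.default_rng(1)
        trajs, labels = synthetic_training_set(rng, separation=True)
        model = HybridAttentionModel(trajs, labels, use_ratios=False).fit(seed=1)
        assert model.rf_accuracy >= 0.95

    def test_single_class_labels_are_rejected(self):
        trajs = [traj(f"s{i}", 2010, [1, 2, 3, 4]) for i in range(10)]
        with pytest.raises(mse.ValidationError, match="both focus and nonfocus"):
            HybridAttentionModel(trajs, [True] * 10)

    def test_round_trips_through_json(self):
        rng = np.random.default_rng(2)
        trajs, labels = synthetic_training_set(rng)
        model = HybridAttentionModel(trajs, labels).fit(seed=2)
        again = HybridAttentionResults.from_json(model.to_json())
        assert again == model

    def test_summary_mentions_the_fitted_numbers(self):
        rng = np.random.default_rng(3)
        trajs, labels = synthetic_training_set(rng)
        model = HybridAttentionModel(trajs, labels).fit(seed=3)
        text = model.summary()
        assert "RF" in text and f"{model.rf_accuracy:.4f}" in text


class TestMaxMasEstimator:
    MODEL = HybridAttentionResults(
        reg={1: 0.4, 2: 0.7, 3: 0.9, 4: 1.0},
        rf_importance={1: 0.5, 2: 0.3, 3: 0.2, 4: 0.0},
        rf_accuracy=1.0,
        horizon=4,
        theta_mas=14.0,
        n_trajectories=0,
        n_focus=0,
    )

    def test_worked_three_offset_example(self):
        partial = traj("x", 2015, [2.0, 5.0, 9.0])
        # (2*0.5/0.4 + 5*0.3/0.7 + 9*0.2/0.9) / 1.0
        assert self.MODEL.predict_max_mas(partial) == pytest.approx(6.642857, abs=1e-6)

    def test_zero_attention_predicts_zero(self):
        assert self.MODEL.predict_max_mas(traj("x", 2015, [0.0, 0.0])) == 0.0

    @given(
        st.lists(st.floats(min_value=1e-3, max_value=1.0), min_size=4, max_size=4),
        st.floats(min_value=0.0, max_value=50.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_single_offset_reduces_to_mas_over_reg(self, rf, mas1):
        total = sum(rf)
        model = HybridAttentionResults(
            reg={1: 0.4, 2: 0.7, 3: 0.9, 4: 1.0},
            rf_importance={i + 1: w / total for i, w in enumerate(rf)},
            rf_accuracy=1.0,
            horizon=4,
            theta_mas=14.0,
            n_trajectories=0,
            n_focus=0,
        )
        partial = AttentionTrajectory("x", 2016, {1: mas1})
        assert model.predict_max_mas(partial) == pytest.approx(mas1 / 0.4, rel=1e-9)

    def test_estimates_scale_linearly_in_attention(self):
        base = self.MODEL.predict_max_mas(traj("x", 2015, [2.0, 5.0, 9.0]))
        doubled = self.MODEL.predict_max_mas(traj("x", 2015, [4.0, 10.0, 18.0]))
        assert doubled == pytest.approx(2 * base, rel=1e-12)
        assert base >= 0

    def test_no_observed_offsets_is_an_error(self):
        with pytest.raises(mse.ValidationError):
            self.MODEL.predict_max_mas(AttentionTrajectory("x", 2015, {}))


class TestSleepingBeauties:
    def test_recovers_planted_beauties_without_orphan_false_positives(
        self, default_sim, default_db, default_panels
    ):
        config = mse.ScoreConfig()
        trajs = mse.trajectories(
            default_db, config, panels=default_panels, birth_years=(2010, 2014)
        )
        model = HybridAttentionModel(
            trajs, focus_labels(trajs, config.theta_mas)
        ).fit(seed=7)
        beauties = set(
            mse.sleeping_beauties(
                default_db, model, config, panels=default_panels, birth_years=(2015, 2017)
            )
        )
        planted = set(default_sim.truth.expected_focus)
        orphans = set(default_sim.truth.never_followed_novel)
        assert len(planted & beauties) / len(planted) >= 0.8
        assert len(orphans & beauties) / len(orphans) <= 0.2

    def test_already_awake_samples_are_excluded(self, default_db, default_panels):
        config = mse.ScoreConfig()
        trajs = mse.trajectories(
            default_db, config, panels=default_panels, birth_years=(2010, 2014)
        )
        model = HybridAttentionModel(trajs, focus_labels(trajs, config.theta_mas)).fit(seed=7)
        beauties = mse.sleeping_beauties(
            default_db, model, config, panels=default_panels, birth_years=(2015, 2017)
        )
        mas_by_id = {p.sample_id: p.mas for p in default_panels}
        novel = {p.sample_id for p in default_panels if p.is_novel}
        for sid in beauties:
            assert mas_by_id[sid] < config.theta_mas
            assert sid in novel  # non-novel samples are never candidates


class TestDiscrimination:
    def test_identical_class_distributions_give_chance_accuracy(self):
        rng = np.random.default_rng(6)
        trajs = [traj(f"s{i}", 2010, np.sort(rng.uniform(0, 10, 4))) for i in range(200)]
        labels = [i % 2 == 0 for i in range(200)]
        report = discrimination_report(trajs, labels, seed=6)
        assert abs(report.accuracy - 0.5) <= 0.1

    def test_separated_classes_are_discriminated(self):
        rng = np.random.default_rng(7)
        trajs, labels = synthetic_training_set(rng, separation=True)
        report = discrimination_report(trajs, labels, seed=7, use_ratios=False)
        assert report.accuracy >= 0.95

    def test_projection_orders_components_by_variance(self):
        rng = np.random.default_rng(8)
        trajs, labels = synthetic_training_set(rng)
        report = discrimination_report(trajs, labels, seed=8)
        assert report.projection.shape == (len(trajs), 2)
        assert report.explained_variance[0] >= report.explained_variance[1]
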