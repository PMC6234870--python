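"""Novelty, attention and focus scoring plus duplicate curation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import mse
from mse.scores import ScoreConfig, _mas_from_matrix, mns_from_similarities

from conftest import oracle_mas


class TestNoveltyFormula:
    def test_constant_similarities_give_one_minus_s(self):
        # ten matches at 0.85 land exactly on the novelty threshold
        assert mns_from_similarities([0.85] * 10) == pytest.approx(0.15, abs=1e-12)
        for s in (0.0, 0.3, 1.0):
            assert mns_from_similarities([s] * 10) == pytest.approx(1 - s, abs=1e-12)

    def test_descending_ladder_hand_value(self):
        sims = [1.0, 0.9, 0.8, 0.7, 0.6, 0.5, 0.4, 0.3, 0.2, 0.1]
        # weights (9..0)/45 give 1 - 33/45
        assert mns_from_similarities(sims) == pytest.approx(1 - 33.0 / 45.0, abs=1e-12)
        assert mns_from_similarities(sims) == pytest.approx(0.26667, abs=1e-5)

    def test_tenth_match_carries_zero_weight(self):
        sims = [1.0, 0.9, 0.8, 0.7, 0.6, 0.5, 0.4, 0.3, 0.2, 0.1]
        perturbed = sims[:9] + [0.0]
        assert mns_from_similarities(sims) == mns_from_similarities(perturbed)

    def test_missing_matches_count_as_zero_similarity(self):
        assert mns_from_similarities([]) == pytest.approx(1.0)
        assert mns_from_similarities([1.0]) == pytest.approx(1 - 9 / 45)

    def test_depth_below_two_is_rejected(self):
        with pytest.raises(mse.ValidationError):
            mns_from_similarities([0.5], n_top=1)

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=0, max_size=15))
    @settings(max_examples=200, deadline=None)
    def test_range_and_monotonicity(self, sims):
        value = mns_from_similarities(sims)
        assert 0.0 <= value <= 1.0
        # raising any contributing similarity can only lower novelty
        bumped = [min(1.0, s + 0.05) for s in sims]
        assert mns_from_similarities(bumped) <= value + 1e-12

    def test_zero_only_when_all_weighted_matches_are_perfect(self):
        assert mns_from_similarities([1.0] * 10) == pytest.approx(0.0, abs=1e-12)
        assert mns_from_similarities([1.0] * 9 + [0.0]) == pytest.approx(0.0, abs=1e-12)
        assert mns_from_similarities([1.0] * 8 + [0.999, 0.0]) > 0.0


class TestNoveltyOnDatabase:
    def test_birth_novelty_uses_strictly_earlier_samples(self, db300):
        meta = db300.metadata
        sid = meta.index[meta["year"] == 2011][0]
        profile = mse.MicrobiomeProfile(
            sid,
            {
                db300.phylogeny.leaf_order[i]: v
                for i, v in enumerate(db300.vector(sid))
                if v > 0
            },
            year=2011,
        )
        matrix = mse.all_pairs_similarity(db300)
        pos = {s: i for i, s in enumerate(db300.sample_ids)}
        earlier = [s for s in db300.sample_ids if meta.at[s, "year"] <= 2010]
        top = sorted((matrix[pos[sid], pos[s]] for s in earlier), reverse=True)[:10]
        assert mse.mns(profile, db300) == pytest.approx(
            mns_from_similarities(top), abs=1e-12
        )

    def test_empty_eligible_database_is_maximally_novel(self, db300):
        sid = db300.sample_ids[0]
        profile = mse.MicrobiomeProfile(
            sid,
            {
                db300.phylogeny.leaf_order[i]: v
                for i, v in enumerate(db300.vector(sid))
                if v > 0
            },
            year=2010,  # no samples strictly before the first year
        )
        assert mse.mns(profile, db300) == 1.0


class TestAttention:
    def test_hand_built_connectivity_sum(self):
        # three other-study observers rank m in their top lists at 0.90/0.88/0.86
        ids = ["m", "o1", "o2", "o3", "x"]
        studies = ["sm", "s1", "s2", "s3", "sx"]
        sims = np.array(
            [
                [1.00, 0.90, 0.88, 0.86, 0.10],
                [0.90, 1.00, 0.20, 0.20, 0.10],
                [0.88, 0.20, 1.00, 0.20, 0.10],
                [0.86, 0.20, 0.20, 1.00, 0.10],
                [0.10, 0.10, 0.10, 0.10, 1.00],
            ]
        )
        mas = _mas_from_matrix(sims, studies, ids, n_top=3, theta_connect=0.85)
        assert mas[0] == pytest.approx(0.90 + 0.88 + 0.86)

    def test_connections_below_threshold_do_not_count(self):
        ids = ["m", "o1"]
        sims = np.array([[1.0, 0.8499], [0.8499, 1.0]])
        mas = _mas_from_matrix(sims, ["a", "b"], ids, n_top=5, theta_connect=0.85)
        assert mas[0] == 0.0
        boundary = np.array([[1.0, 0.85], [0.85, 1.0]])
        assert _mas_from_matrix(boundary, ["a", "b"], ids, 5, 0.85)[0] == pytest.approx(0.85)

    def test_same_study_connections_are_excluded(self):
        ids = ["m", "peer"]
        sims = np.array([[1.0, 0.95], [0.95, 1.0]])
        mas = _mas_from_matrix(sims, ["sA", "sA"], ids, n_top=5, theta_connect=0.85)
        assert mas[0] == 0.0

    def test_absent_sample_has_no_attention_score(self, toy_db):
        with pytest.raises(mse.ValidationError, match="not in the database"):
            mse.mas("ghost", toy_db)

    def test_matches_bruteforce_oracle_with_year_cutoff(self, db200):
        config = ScoreConfig()
        panel = mse.mas_panel(db200, config, max_year=2010)
        expected = oracle_mas(db200, config, max_year=2010)
        for sid, value in expected.items():
            assert panel[sid] == pytest.approx(value, abs=1e-9)


class TestPanelAndThresholds:
    def test_focus_requires_both_flags_and_boundary_is_inclusive(self):
        config = ScoreConfig()
        frame = pd.DataFrame(
            {"mns": [0.0, 0.15, 0.15], "mas": [20.0, 14.0, 13.99]}
        )
        novel = frame["mns"] >= config.theta_novel
        attended = frame["mas"] >= config.theta_mas
        assert list(novel & attended) == [False, True, False]
        assert (frame["mns"] * frame["mas"])[1] == pytest.approx(2.1)

    def test_panel_mfi_is_the_exact_product(self, db300):
        for record in mse.score_panel(db300)[:50]:
            assert record.mfi == record.mns * record.mas
            assert record.is_focus == (record.is_novel and record.is_high_attention)

    def test_indexed_panel_equals_exhaustive_panel(self, db200):
        exhaustive = mse.score_panel(db200, method="exhaustive")
        indexed = mse.score_panel(db200, method="indexed")
        for a, b in zip(exhaustive, indexed):
            assert a.sample_id == b.sample_id
            assert a.mns == pytest.approx(b.mns, abs=1e-9)
            assert a.mas == pytest.approx(b.mas, abs=1e-9)
            assert (a.is_novel, a.is_high_attention) == (b.is_novel, b.is_high_attention)

    def test_quantile_threshold_examples(self):
        assert mse.mas_quantile_threshold([3.0] * 7) == 3.0
        assert mse.mas_quantile_threshold(list(range(10)), q=0.2) == 8
        values = np.random.default_rng(1).gamma(2.0, 5.0, 500)
        threshold = mse.mas_quantile_threshold(values, q=0.2)
        assert (values >= threshold).mean() >= 0.2


class TestDeduplication:
    def _db_with_pair(self, toy, year_a, year_b):
        profiles, phylo, _ = toy
        a = mse.MicrobiomeProfile(
            "dupA", {"leafA": 0.5, "leafC": 0.5}, study_id="s1",
            year=year_a, date=f"{year_a}-01-01", read_count=1000,
        )
        b = mse.MicrobiomeProfile(
            "dupB", {"leafA": 0.5, "leafC": 0.5}, study_id="s2",
            year=year_b, date=f"{year_b}-01-01", read_count=1000,
        )
        return mse.ReferenceDatabase.build([a, b] + profiles[:2], phylo)

    def test_later_dated_member_is_dropped(self, toy):
        db = self._db_with_pair(toy, 2015, 2016)
        kept, pairs = mse.deduplicate(db)
        assert pairs == [("dupA", "dupB", pytest.approx(1.0))]
        assert "dupB" not in kept and "dupA" in kept

    def test_similarity_just_below_threshold_keeps_both(self, toy):
        profiles, phylo, _ = toy
        a = mse.MicrobiomeProfile("a", {"leafA": 1.0}, year=2015, read_count=10)
        b = mse.MicrobiomeProfile(
            "b", {"leafA": 0.9998, "leafB": 0.0002}, year=2016, read_count=10
        )
        db = mse.ReferenceDatabase.build([a, b], phylo)
        sim = mse.similarity(db.vector("a"), db.vector("b"), phylo)
        assert sim < 0.9999
        kept, pairs = mse.deduplicate(db)
        assert pairs == [] and len(kept) == 2

    def test_date_tie_drops_the_larger_id(self, toy):
        db = self._db_with_pair(toy, 2015, 2015)
        kept, pairs = mse.deduplicate(db)
        assert pairs[0][1] == "dupB"

    def test_planted_duplicates_are_recovered_exactly(self, default_sim, default_db):
        # default_db is already deduplicated; recompute on the raw corpus
        profiles, _ = mse.quality_filter(default_sim.profiles)
        db = mse.ReferenceDatabase.build(profiles, default_sim.phylogeny)
        _, pairs = mse.deduplicate(db)
        dropped = {d for _, d, _ in pairs}
        assert dropped == {d for _, d in default_sim.truth.duplicate_pairs}
        for kept_id, dropped_id, _ in pairs:
            assert (kept_id, dropped_id) in set(default_sim.truth.duplicate_pairs)
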