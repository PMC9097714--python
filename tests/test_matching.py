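"""Exposed-group construction, propensity scores and exact+NN matching."""

import numpy as np
import pandas as pd
import pytest

import trajscan.matching as tm
from trajscan.io import SequencePanel
from trajscan.params import StudyParams
from trajscan.synthetic import planted_rr_dataset
from trajscan.io import build_panel


def make_panel(rows, concepts):
    """rows: (person_id, gender, birth_year, {concept: date})."""
    units = pd.DataFrame(
        {
            "unit_id": range(len(rows)),
            "person_id": [r[0] for r in rows],
            "gender": [r[1] for r in rows],
            "birth_year": [r[2] for r in rows],
            "window_start": pd.Timestamp("2000-01-01"),
            "window_end": pd.Timestamp("2029-12-31"),
        }
    )
    D = np.full((len(rows), len(concepts)), np.nan)
    cidx = {c: i for i, c in enumerate(concepts)}
    for i, r in enumerate(rows):
        for c, d in r[3].items():
            D[i, cidx[c]] = np.datetime64(d, "D").astype(float)
    return SequencePanel(units, np.array(concepts), D)


class TestBuildExposed:
    def test_each_carrier_becomes_one_unit(self):
        panel = make_panel(
            [
                ("a", "female", 1960, {1: "2015-06-01"}),
                ("b", "female", 1960, {1: "2016-06-01", 2: "2016-07-01"}),
                ("c", "male", 1950, {1: "2017-06-01"}),
                ("d", "male", 1950, {2: "2017-06-01"}),
            ],
            [1, 2],
        )
        exp = tm.build_exposed(panel, 1, StudyParams())
        assert len(exp.unit_rows) == 3

    def test_age_at_index_arithmetic(self):
        panel = make_panel([("a", "female", 1960, {1: "2015-06-01"})], [1])
        exp = tm.build_exposed(panel, 1, StudyParams())
        assert exp.age_at_index.tolist() == [55]
        assert exp.index_year.tolist() == [2015]

    def test_event_on_window_start_included(self):
        panel = make_panel([("a", "female", 1960, {1: "2000-01-01"})], [1])
        exp = tm.build_exposed(panel, 1, StudyParams())
        assert len(exp.unit_rows) == 1
        assert exp.index_days[0] == np.datetime64("2000-01-01", "D").astype(float)


class TestComputePropensity:
    def test_identical_features_give_equal_scores(self):
        X = np.ones((10, 3))
        y = np.array([1] * 5 + [0] * 5)
        ps = tm.compute_propensity(X, y)
        assert np.allclose(ps, ps[0])
        assert np.all((ps > 0) & (ps < 1))

    def test_separating_feature_orders_scores(self):
        X = np.zeros((20, 2))
        X[:10, 0] = 1.0
        y = np.array([1] * 10 + [0] * 10)
        ps = tm.compute_propensity(X, y)
        assert np.isfinite(ps).all()
        assert ps[:10].min() > ps[10:].max()

    def test_random_features_scores_in_unit_interval(self):
        rng = np.random.default_rng(5)
        X = rng.random((200, 8))
        y = (rng.random(200) < 0.3).astype(int)
        ps = tm.compute_propensity(X, y)
        assert np.all((ps > 0) & (ps < 1))
        assert 0 < ps.mean() < 1

    def test_single_class_rejected(self):
        with pytest.raises(tm.MatchingError, match="propensity"):
            tm.compute_propensity(np.ones((5, 2)), np.ones(5))


class TestMatchBackground:
    params = StudyParams(seed=1)

    def test_single_eligible_candidate_matched_one_to_one(self):
        panel = make_panel(
            [
                ("a", "female", 1962, {1: "2015-03-01"}),
                ("b", "female", 1963, {2: "2014-01-01"}),
            ],
            [1, 2],
        )
        mg = tm.match_background(panel, 1, 2, self.params, np.random.default_rng(0))
        assert mg.n_exposed == 1 and mg.n_background == 1
        assert mg.n_unmatched_exposed == 0
        assert mg.background_index_days[0] == mg.exposed_index_days[0]

    def test_gender_mismatch_leaves_exposed_unmatched(self):
        panel = make_panel(
            [
                ("a", "female", 1962, {1: "2015-03-01"}),
                ("b", "male", 1963, {2: "2014-01-01"}),
            ],
            [1, 2],
        )
        mg = tm.match_background(panel, 1, 2, self.params, np.random.default_rng(0))
        assert mg.n_exposed == 0
        assert mg.n_unmatched_exposed == 1

    def test_nearest_neighbor_prefers_closer_score(self, monkeypatch):
        panel = make_panel(
            [
                ("a", "female", 1962, {1: "2015-03-01"}),
                ("b", "female", 1962, {2: "2014-01-01"}),
                ("c", "female", 1962, {2: "2014-02-01"}),
            ],
            [1, 2],
        )
        monkeypatch.setattr(
            tm, "compute_propensity", lambda X, y, seed=0: np.array([0.39, 0.40, 0.41])
        )
        mg = tm.match_background(panel, 1, 2, self.params, np.random.default_rng(0))
        assert mg.n_background == 1
        assert panel.units["person_id"].iloc[mg.background_rows[0]] == "b"

    def test_score_tie_broken_by_lower_person_id(self, monkeypatch):
        panel = make_panel(
            [
                ("a", "female", 1962, {1: "2015-03-01"}),
                ("d", "female", 1962, {2: "2014-01-01"}),
                ("b", "female", 1962, {2: "2014-02-01"}),
            ],
            [1, 2],
        )
        monkeypatch.setattr(
            tm, "compute_propensity", lambda X, y, seed=0: np.array([0.40, 0.40, 0.40])
        )
        mg = tm.match_background(panel, 1, 2, self.params, np.random.default_rng(0))
        assert panel.units["person_id"].iloc[mg.background_rows[0]] == "b"

    def test_empty_background_pool_raises(self):
        panel = make_panel([("a", "female", 1962, {1: "2015-03-01"})], [1])
        with pytest.raises(tm.MatchingError, match="pool"):
            tm.match_background(panel, 1, 2, self.params, np.random.default_rng(0))


@pytest.fixture(scope="module")
def matched():
    persons, events, pair = planted_rr_dataset(
        n_persons=400, n_carriers=60, p_e2_given_e1=0.5, design_rr=2.0, seed=9
    )
    panel = build_panel(events, persons)
    params = StudyParams(seed=9)
    mg = tm.match_background(panel, pair.e1, pair.e2, params, np.random.default_rng(9))
    return panel, params, mg


class TestMatchingInvariants:

    def test_exact_balance_of_strata(self, matched):
        panel, params, mg = matched
        cache = tm._panel_cache(panel)

        def strata(rows, index_days):
            years = tm._years_of_days(np.asarray(index_days))
            age = years - cache["birth_year"][rows]
            return sorted(
                zip(cache["gender"][rows].tolist(),
                    (age // params.age_bin_years).tolist(),
                    years.tolist())
            )

        assert strata(mg.exposed_rows, mg.exposed_index_days) == strata(
            mg.background_rows, mg.background_index_days
        )

    def test_no_contamination(self, matched):
        panel, _, mg = matched
        e1_dates = panel.col(mg.e1)[mg.background_rows]
        before = np.isfinite(e1_dates) & (e1_dates <= mg.background_index_days)
        assert not before.any()

    def test_without_replacement(self, matched):
        _, _, mg = matched
        assert len(mg.background_rows) == len(set(mg.background_rows.tolist()))
        assert not set(mg.background_rows.tolist()) & set(mg.exposed_rows.tolist())

    def test_background_under_observation_at_assigned_date(self, matched):
        panel, _, mg = matched
        cache = tm._panel_cache(panel)
        ws = cache["win_start"][mg.background_rows]
        we = cache["win_end"][mg.background_rows]
        assert ((ws <= mg.background_index_days) & (mg.background_index_days <= we)).all()

    def test_matched_prevalence_tracks_population_when_unconfounded(self, matched):
        # exposure independent of covariates: matched background E2 prevalence
        # should approximate the planted baseline within binomial error
        panel, params, mg = matched
        e2_dates = panel.col(mg.e2)[mg.background_rows]
        hit = np.isfinite(e2_dates) & (
            e2_dates >= mg.background_index_days + params.min_gap_days
        )
        p_hat = hit.mean()
        p0 = 0.25  # q / design_rr
        se = np.sqrt(p0 * (1 - p0) / mg.n_background)
        assert abs(p_hat - p0) < 4 * se
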