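"""End-to-end detection pipeline and its estimator front-end.

``test_pair`` runs matching + statistics for one candidate pair;
``run_discovery`` / ``run_validation`` execute the whole framework on a
:class:`~trajscan.io.SequencePanel`; :class:`TrajectoryDetector` wraps the
pipeline as a scikit-learn style estimator (``fit`` + fitted attributes).
"""

from __future__ import annotations

import logging
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from . import graph as tg
from . import stats
from .io import SequencePanel, build_panel
from .matching import MatchingError, match_background
from .pairs import enumerate_pairs, filter_pairs, pair_count_matrix
from .params import StudyParams

logger = logging.getLogger(__name__)

RESULT_COLUMNS = [
    "e1", "e2", "e1_name", "e2_name", "status",
    "n_pair", "n_reverse", "n_exposed", "n_background", "n_unmatched_exposed",
    "k_exposed_e2", "k_background_e2",
    "rr", "rr_ci_low", "rr_ci_high",
    "fisher_p", "fisher_p_adj", "binom_p", "binom_p_adj",
    "significant_assoc", "significant_direction",
    "smd_before", "smd_after",
]


def _count_after_index(col: np.ndarray, rows: np.ndarray, index_days: np.ndarray,
                       params: StudyParams) -> int:
    """Units among ``rows`` whose E2 falls in [index+min_gap, index+max_gap]."""
    d = col[rows]
    with np.errstate(invalid="ignore"):
        hit = (d >= index_days + params.min_gap_days) & (
            d <= index_days + params.gap_upper
        )
    return int(hit.sum())


class _MatchCache:
    """Per-E1 cache of matched groups.

    Matching depends on the pair only through E1 (exposed definition, pool,
    exact covariates and propensity features are all E1-specific), so every
    pair sharing an E1 reuses the same matched groups.
    """

    def __init__(self, panel: SequencePanel, params: StudyParams,
                 rng: np.random.Generator):
        self.panel, self.params, self.rng = panel, params, rng
        self._cache: dict[int, object] = {}

    def get(self, e1: int):
        """MatchedGroups for E1, or the MatchingError it raised."""
        key = int(e1)
        if key not in self._cache:
            try:
                self._cache[key] = match_background(
                    self.panel, key, -1, self.params, self.rng
                )
            except MatchingError as exc:
                self._cache[key] = exc
        return self._cache[key]


def test_pair(
    panel: SequencePanel,
    e1: int,
    e2: int,
    n_pair: int,
    n_reverse: int,
    params: StudyParams,
    rng: np.random.Generator,
    _cache: Optional[_MatchCache] = None,
) -> dict:
    """Matched-group statistics for one ordered pair (p-values unadjusted)."""
    row = {
        "e1": int(e1), "e2": int(e2),
        "e1_name": panel.name_of(e1), "e2_name": panel.name_of(e2),
        "n_pair": int(n_pair), "n_reverse": int(n_reverse),
        "status": "tested",
    }
    if _cache is not None:
        mg = _cache.get(e1)
        if isinstance(mg, MatchingError):
            logger.debug("pair %s->%s untestable: %s", e1, e2, mg)
            row["status"] = "untestable"
            return row
    else:
        try:
            mg = match_background(panel, e1, e2, params, rng)
        except MatchingError as exc:
            logger.debug("pair %s->%s untestable: %s", e1, e2, exc)
            row["status"] = "untestable"
            return row
    if mg.n_exposed == 0 or mg.n_background == 0:
        row["status"] = "untestable"
        row["n_unmatched_exposed"] = mg.n_unmatched_exposed
        return row
    e2_col = panel.col(e2)
    k_exp = _count_after_index(e2_col, mg.exposed_rows, mg.exposed_index_days, params)
    k_bg = _count_after_index(
        e2_col, mg.background_rows, mg.background_index_days, params
    )
    rr, lo, hi = stats.relative_risk(k_exp, mg.n_exposed, k_bg, mg.n_background)
    row.update(
        n_exposed=mg.n_exposed,
        n_background=mg.n_background,
        n_unmatched_exposed=mg.n_unmatched_exposed,
        k_exposed_e2=k_exp,
        k_background_e2=k_bg,
        rr=rr, rr_ci_low=lo, rr_ci_high=hi,
        fisher_p=stats.fisher_association(k_exp, mg.n_exposed, k_bg, mg.n_background),
        binom_p=stats.binomial_direction(n_pair, n_reverse),
        smd_before=mg.smd_before,
        smd_after=mg.smd_after,
    )
    return row


def _finalize(rows: list[dict], params: StudyParams) -> pd.DataFrame:
    """Adjust both p-value families across all tested pairs and classify."""
    df = pd.DataFrame(rows)
    for c in RESULT_COLUMNS:
        if c not in df.columns:
            df[c] = np.nan
    df = df[RESULT_COLUMNS]
    tested = df["status"] == "tested"
    df["significant_assoc"] = False
    df["significant_direction"] = False
    if tested.any():
        df.loc[tested, "fisher_p_adj"] = stats.adjust_pvalues(
            df.loc[tested, "fisher_p"], params.correction
        )
        df.loc[tested, "binom_p_adj"] = stats.adjust_pvalues(
            df.loc[tested, "binom_p"], params.correction
        )
        for i in df.index[tested]:
            assoc, direction = stats.classify_pair(
                df.at[i, "fisher_p_adj"],
                df.at[i, "binom_p_adj"],
                df.at[i, "rr"],
                df.at[i, "n_pair"],
                df.at[i, "n_reverse"],
                params.alpha,
                params.rr_min_of_interest,
            )
            df.at[i, "significant_assoc"] = assoc
            df.at[i, "significant_direction"] = direction
    return df


def run_discovery(
    panel: SequencePanel, params: StudyParams, attrition: Optional[dict] = None
) -> tuple[pd.DataFrame, "tg.nx.DiGraph", pd.DataFrame]:
    """Steps 2-4 of the framework on an already-built panel.

    Returns ``(pair_results, graph, trajectory_counts)``.
    """
    rng = np.random.default_rng(params.seed)
    pairs = enumerate_pairs(panel, params)
    candidates = filter_pairs(pairs, params, panel.n_units)
    if attrition is not None:
        attrition["pairs_enumerated"] = len(pairs)
        attrition["pairs_candidate"] = len(candidates)
    cache = _MatchCache(panel, params, rng)
    rows = [
        test_pair(panel, r.e1, r.e2, r.n_pair, r.n_reverse, params, rng, cache)
        for r in candidates.itertuples()
    ]
    results = _finalize(rows, params) if rows else pd.DataFrame(columns=RESULT_COLUMNS)
    graph = tg.build_graph(results, panel) if len(results) else tg.nx.DiGraph()
    trajectories = tg.count_all_trajectories(graph, panel, params)
    if attrition is not None:
        attrition["pairs_tested"] = int((results["status"] == "tested").sum()) if len(results) else 0
        attrition["pairs_untestable"] = int((results["status"] != "tested").sum()) if len(results) else 0
        attrition["pairs_significant_assoc"] = int(results["significant_assoc"].sum()) if len(results) else 0
        attrition["pairs_directional"] = int(results["significant_direction"].sum()) if len(results) else 0
        attrition["trajectories_counted"] = len(trajectories)
    return results, graph, trajectories


def run_validation(
    panel: SequencePanel,
    params: StudyParams,
    pair_list: pd.DataFrame,
    attrition: Optional[dict] = None,
) -> tuple[pd.DataFrame, "tg.nx.DiGraph", pd.DataFrame]:
    """Test only the supplied pairs (validation mode).

    Listed pairs never realized in the data are reported with status
    ``absent``. Significant pairs whose dominant order or risk direction
    contradicts the listed expectation are flagged ``opposite_direction`` /
    ``opposite_effect``.
    """
    if len(pair_list) == 0:
        raise ValueError("validation mode requires a non-empty pair list")
    rng = np.random.default_rng(params.seed)
    M = pair_count_matrix(panel, params)
    cindex = {int(c): i for i, c in enumerate(panel.concepts)}
    cache = _MatchCache(panel, params, rng)
    rows = []
    for r in pair_list.itertuples():
        e1, e2 = int(r.e1), int(r.e2)
        i, j = cindex.get(e1), cindex.get(e2)
        n_fwd = int(M[i, j]) if i is not None and j is not None else 0
        n_rev = int(M[j, i]) if i is not None and j is not None else 0
        if n_fwd == 0 and n_rev == 0:
            rows.append(
                {"e1": e1, "e2": e2, "e1_name": panel.name_of(e1),
                 "e2_name": panel.name_of(e2), "status": "absent",
                 "n_pair": 0, "n_reverse": 0}
            )
            continue
        rows.append(test_pair(panel, e1, e2, n_fwd, n_rev, params, rng, cache))
    results = _finalize(rows, params)
    tested = results["status"] == "tested"
    results["opposite_direction"] = (
        tested
        & (results["fisher_p_adj"] < params.alpha)
        & (results["binom_p_adj"] < params.alpha)
        & (results["n_reverse"] > results["n_pair"])
    )
    results["opposite_effect"] = (
        tested & (results["fisher_p_adj"] < params.alpha) & (results["rr"] < 1.0)
    )
    graph = tg.build_graph(results, panel)
    trajectories = tg.count_all_trajectories(graph, panel, params)
    if attrition is not None:
        attrition["pairs_listed"] = len(pair_list)
        attrition["pairs_absent"] = int((results["status"] == "absent").sum())
        attrition["pairs_tested"] = int(tested.sum())
        attrition["pairs_directional"] = int(results["significant_direction"].sum())
    return results, graph, trajectories


class TrajectoryDetector(BaseEstimator):
    """Detector of directed clinical event pairs and trajectories.

    A scikit-learn style estimator: construction stores study parameters,
    :meth:`fit` consumes a long event table plus a person table and exposes
    the detected pairs, graph and trajectory counts as fitted attributes.

    Parameters mirror :class:`~trajscan.params.StudyParams`.

    Attributes
    ----------
    panel_ : SequencePanel
        First-occurrence date panel of the analysed cohort.
    pair_results_ : pd.DataFrame
        One row per tested pair with counts, RR and CI, raw and adjusted
        p-values, and significance flags.
    graph_ : networkx.DiGraph
        Directed graph of significant directional pairs.
    trajectories_ : pd.DataFrame
        Ranked trajectory counts.
    attrition_ : dict
        Row counts at each pipeline stage.
    """

    def __init__(
        self,
        min_gap_days: int = 1,
        max_gap_days: Optional[int] = None,
        min_pair_count: Optional[int] = None,
        min_pair_prevalence: Optional[float] = 0.01,
        rr_min_of_interest: float = 1.2,
        alpha: float = 0.05,
        correction: str = "fdr",
        mode: str = "discovery",
        age_bin_years: int = 5,
        match_ratio: int = 1,
        propensity_top_k: int = 100,
        privacy_min_count: int = 20,
        max_trajectory_len: int = 5,
        seed: int = 0,
    ):
        self.min_gap_days = min_gap_days
        self.max_gap_days = max_gap_days
        self.min_pair_count = min_pair_count
        self.min_pair_prevalence = min_pair_prevalence
        self.rr_min_of_interest = rr_min_of_interest
        self.alpha = alpha
        self.correction = correction
        self.mode = mode
        self.age_bin_years = age_bin_years
        self.match_ratio = match_ratio
        self.propensity_top_k = propensity_top_k
        self.privacy_min_count = privacy_min_count
        self.max_trajectory_len = max_trajectory_len
        self.seed = seed

    def _study_params(self) -> StudyParams:
        return StudyParams(**self.get_params())

    def fit(
        self,
        X: pd.DataFrame,
        y=None,
        *,
        persons: pd.DataFrame,
        cohort: Optional[pd.DataFrame] = None,
        pair_list: Optional[pd.DataFrame] = None,
    ) -> "TrajectoryDetector":
        """Run the full framework.

        Parameters
        ----------
        X : pd.DataFrame
            Long event table (person_id, concept_id, concept_name, domain,
            event_date).
        persons : pd.DataFrame
            Person table as returned by :func:`trajscan.io.read_person_table`.
        cohort : pd.DataFrame, optional
            Cohort windows; omitted = whole-database cohort.
        pair_list : pd.DataFrame, optional
            Pairs to test; required in validation mode.
        """
        params = self._study_params()
        attrition: dict = {}
        self.panel_ = build_panel(X, persons, cohort, attrition)
        self.n_units_ = self.panel_.n_units
        if params.mode == "validation":
            if pair_list is None:
                raise ValueError("validation mode requires pair_list")
            out = run_validation(self.panel_, params, pair_list, attrition)
        else:
            out = run_discovery(self.panel_, params, attrition)
        self.pair_results_, self.graph_, self.trajectories_ = out
        self.attrition_ = attrition
        return self

    def fit_from_panel(
        self, panel: SequencePanel, pair_list: Optional[pd.DataFrame] = None
    ) -> "TrajectoryDetector":
        """Like :meth:`fit` but starting from an already-built panel."""
        params = self._study_params()
        attrition: dict = {"sequence_units": panel.n_units}
        self.panel_ = panel
        self.n_units_ = panel.n_units
        if params.mode == "validation":
            if pair_list is None:
                raise ValueError("validation mode requires pair_list")
            out = run_validation(panel, params, pair_list, attrition)
        else:
            out = run_discovery(panel, params, attrition)
        self.pair_results_, self.graph_, self.trajectories_ = out
        self.attrition_ = attrition
        return self
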