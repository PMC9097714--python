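"""Exposed / background group construction for one event pair.

For a candidate pair E1 -> E2 the exposed group holds every sequence unit
whose history contains E1, indexed at the first E1 date. Background members
are drawn from units without E1, exact-matched on gender, age bin and
calendar year of the index date, and nearest-neighbour matched on a
propensity score within each exact stratum. A background member inherits the
index date of the exposed unit it is matched to, and must be under
observation on that date.

The propensity score is the fitted probability of exposure from an
L2-regularized logistic regression on the unit's pre-index history:
indicators of the K most prevalent concepts occurring strictly before the
index date, plus the total pre-index event count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import LogisticRegression

from .io import SequencePanel
from .params import StudyParams

logger = logging.getLogger(__name__)


class MatchingError(RuntimeError):
    """Raised when a pair cannot be matched (empty pool, degenerate model)."""


@dataclass
class ExposedGroup:
    """Units exposed to E1 with their index dates and exact covariates."""

    unit_rows: np.ndarray      # row indices into the panel
    index_days: np.ndarray     # first E1 date, days since epoch
    gender: np.ndarray         # integer gender codes
    age_at_index: np.ndarray
    index_year: np.ndarray


@dataclass
class MatchedGroups:
    """Result of matching one pair's exposed group against the pool."""

    e1: int
    e2: int
    exposed_rows: np.ndarray          # matched exposed units
    exposed_index_days: np.ndarray
    background_rows: np.ndarray       # matched background units
    background_index_days: np.ndarray  # assigned (= matched exposed's) dates
    n_unmatched_exposed: int
    ps_exposed: np.ndarray = field(default_factory=lambda: np.empty(0))
    ps_background: np.ndarray = field(default_factory=lambda: np.empty(0))
    smd_before: float = float("nan")
    smd_after: float = float("nan")

    @property
    def n_exposed(self) -> int:
        return len(self.exposed_rows)

    @property
    def n_background(self) -> int:
        return len(self.background_rows)


def _panel_cache(panel: SequencePanel) -> dict:
    """Demographics and prevalence arrays shared by all pairs of one panel."""
    cache = getattr(panel, "_match_cache", None)
    if cache is not None:
        return cache
    units = panel.units
    gender_codes, _ = units["gender"].factorize(sort=True)
    prevalence = np.isfinite(panel.dates).sum(axis=0)
    # most prevalent concepts first; ties by ascending concept id
    top_order = np.lexsort((panel.concepts, -prevalence))
    cache = {
        "gender": gender_codes.astype(np.int64),
        "birth_year": units["birth_year"].to_numpy(dtype=np.int64),
        "win_start": units["window_start"].to_numpy(dtype="datetime64[D]").astype(float),
        "win_end": units["window_end"].to_numpy(dtype="datetime64[D]").astype(float),
        "person_order": np.argsort(units["person_id"].to_numpy()).argsort(),
        "top_order": top_order,
    }
    panel._match_cache = cache
    return cache


def _years_of_days(days: np.ndarray) -> np.ndarray:
    return (
        days.astype("datetime64[D]").astype("datetime64[Y]").astype(int) + 1970
    )


def build_exposed(panel: SequencePanel, e1: int, params: StudyParams) -> ExposedGroup:
    """All units containing E1, indexed at the first E1 occurrence."""
    cache = _panel_cache(panel)
    a = panel.col(e1)
    rows = np.flatnonzero(np.isfinite(a))
    days = a[rows]
    years = _years_of_days(days)
    age = years - cache["birth_year"][rows]
    return ExposedGroup(rows, days, cache["gender"][rows], age, years)


def prior_feature_matrix(
    panel: SequencePanel, unit_rows: np.ndarray, index_days: np.ndarray, top_k: int
) -> np.ndarray:
    """Pre-index history features: top-K concept indicators + prior count."""
    cache = _panel_cache(panel)
    D = panel.dates[unit_rows]
    with np.errstate(invalid="ignore"):
        prior = D < index_days[:, None]
    cols = cache["top_order"][: min(top_k, panel.n_concepts)]
    X = np.empty((len(unit_rows), len(cols) + 1))
    X[:, :-1] = prior[:, cols]
    X[:, -1] = prior.sum(axis=1) / 10.0  # keep the count on the indicators' scale
    return X


def compute_propensity(X: np.ndarray, exposed_flag: np.ndarray, seed: int = 0) -> np.ndarray:
    """Propensity of exposure per unit, in (0, 1), deterministic given seed."""
    y = np.asarray(exposed_flag, dtype=int)
    if len(np.unique(y)) < 2 or min((y == 0).sum(), (y == 1).sum()) < 1:
        raise MatchingError("cannot fit propensity model: single-class input")
    model = LogisticRegression(
        C=1.0, solver="lbfgs", max_iter=200, tol=1e-4, random_state=seed,
    )
    model.fit(X, y)
    return model.predict_proba(X)[:, 1]


def _smd(a: np.ndarray, b: np.ndarray) -> float:
    if len(a) == 0 or len(b) == 0:
        return float("nan")
    pooled = np.sqrt((a.var(ddof=1) if len(a) > 1 else 0.0) / 2
                     + (b.var(ddof=1) if len(b) > 1 else 0.0) / 2)
    if pooled == 0:
        return 0.0
    return float((a.mean() - b.mean()) / pooled)


def match_background(
    panel: SequencePanel,
    e1: int,
    e2: int,
    params: StudyParams,
    rng: np.random.Generator,
) -> MatchedGroups:
    """Match each exposed unit to ``match_ratio`` background units.

    Exact strata are (gender, age bin, index calendar year); within a
    stratum, greedy nearest-neighbour matching on the propensity score
    without replacement, exposed units processed in ascending person order,
    distance ties broken by lower person order. Exposed units with no
    eligible candidate are counted in ``n_unmatched_exposed``.
    """
    cache = _panel_cache(panel)
    exp = build_exposed(panel, e1, params)
    if len(exp.unit_rows) == 0:
        raise MatchingError(f"pair {e1}->{e2}: no exposed units")
    a = panel.col(e1)
    pool = np.flatnonzero(~np.isfinite(a))  # units never exposed to E1
    if len(pool) == 0:
        raise MatchingError(f"pair {e1}->{e2}: empty background pool")

    bin_w = params.age_bin_years
    exp_stratum = np.stack(
        [exp.gender, exp.age_at_index // bin_w, exp.index_year], axis=1
    )
    strata, exp_labels = np.unique(exp_stratum, axis=0, return_inverse=True)

    pool_gender = cache["gender"][pool]
    pool_by = cache["birth_year"][pool]
    ws, we = cache["win_start"][pool], cache["win_end"][pool]
    porder_pool = cache["person_order"][pool]
    porder_exp = cache["person_order"][exp.unit_rows]

    # Stage 1: collect eligible candidates per stratum, with a provisional
    # index date sampled from the stratum's exposed index dates (used only to
    # evaluate pre-index propensity features).
    cand_rows_per_stratum: list[np.ndarray] = []
    cand_prov_days: list[np.ndarray] = []
    for s, (g, ab, yr) in enumerate(strata):
        in_s = np.flatnonzero(
            (pool_gender == g) & ((yr - pool_by) // bin_w == ab)
        )
        if len(in_s) == 0:
            cand_rows_per_stratum.append(np.empty(0, dtype=int))
            cand_prov_days.append(np.empty(0))
            continue
        exp_days_s = exp.index_days[exp_labels == s]
        prov = rng.choice(exp_days_s, size=len(in_s), replace=True)
        covered = (ws[in_s] <= prov) & (prov <= we[in_s])
        in_s, prov = in_s[covered], prov[covered]
        cand_rows_per_stratum.append(pool[in_s])
        cand_prov_days.append(prov)

    all_cand_rows = np.concatenate([c for c in cand_rows_per_stratum]) if cand_rows_per_stratum else np.empty(0, dtype=int)
    if len(all_cand_rows) == 0:
        return MatchedGroups(
            e1, e2,
            np.empty(0, dtype=int), np.empty(0),
            np.empty(0, dtype=int), np.empty(0),
            n_unmatched_exposed=len(exp.unit_rows),
        )

    # Stage 2: one propensity model per pair over exposed + candidates.
    all_prov = np.concatenate(cand_prov_days)
    rows_fit = np.concatenate([exp.unit_rows, all_cand_rows])
    days_fit = np.concatenate([exp.index_days, all_prov])
    flag = np.concatenate(
        [np.ones(len(exp.unit_rows), dtype=int), np.zeros(len(all_cand_rows), dtype=int)]
    )
    X = prior_feature_matrix(panel, rows_fit, days_fit, params.propensity_top_k)
    ps = compute_propensity(X, flag, seed=params.seed)
    ps_exp_all = ps[: len(exp.unit_rows)]
    ps_cand = ps[len(exp.unit_rows):]

    # Stage 3: greedy nearest-neighbour matching within each stratum.
    matched_exp, matched_exp_days, matched_exp_ps = [], [], []
    matched_bg, matched_bg_days, matched_bg_ps = [], [], []
    n_unmatched = 0
    offset = 0
    for s in range(len(strata)):
        cand_rows = cand_rows_per_stratum[s]
        n_c = len(cand_rows)
        cand_ps = ps_cand[offset: offset + n_c]
        offset += n_c
        e_local = np.flatnonzero(exp_labels == s)
        if n_c == 0:
            n_unmatched += len(e_local)
            continue
        cand_win_lo = cache["win_start"][cand_rows]
        cand_win_hi = cache["win_end"][cand_rows]
        cand_order = cache["person_order"][cand_rows]
        available = np.ones(n_c, dtype=bool)
        # process exposed in ascending person order for determinism
        for ei in e_local[np.argsort(porder_exp[e_local], kind="stable")]:
            idx_day = exp.index_days[ei]
            elig = available & (cand_win_lo <= idx_day) & (idx_day <= cand_win_hi)
            n_elig = int(elig.sum())
            if n_elig < params.match_ratio:
                n_unmatched += 1
                continue
            elig_idx = np.flatnonzero(elig)
            dist = np.abs(cand_ps[elig_idx] - ps_exp_all[ei])
            # nearest first; ties by lower person order
            pick = elig_idx[np.lexsort((cand_order[elig_idx], dist))[: params.match_ratio]]
            available[pick] = False
            matched_exp.append(exp.unit_rows[ei])
            matched_exp_days.append(idx_day)
            matched_exp_ps.append(ps_exp_all[ei])
            matched_bg.extend(cand_rows[pick])
            matched_bg_days.extend([idx_day] * len(pick))
            matched_bg_ps.extend(cand_ps[pick])

    mg = MatchedGroups(
        e1=e1,
        e2=e2,
        exposed_rows=np.asarray(matched_exp, dtype=int),
        exposed_index_days=np.asarray(matched_exp_days, dtype=float),
        background_rows=np.asarray(matched_bg, dtype=int),
        background_index_days=np.asarray(matched_bg_days, dtype=float),
        n_unmatched_exposed=n_unmatched,
        ps_exposed=np.asarray(matched_exp_ps, dtype=float),
        ps_background=np.asarray(matched_bg_ps, dtype=float),
        smd_before=_smd(ps_exp_all, ps_cand),
        smd_after=_smd(np.asarray(matched_exp_ps), np.asarray(matched_bg_ps)),
    )
    return mg
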