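"""Synthetic longitudinal event data with plantable signal.

Generates random person/event tables in the exact schema the pipeline
consumes, and injects (a) event pairs where E2 follows E1 with a chosen
conditional probability and (b) full multi-event trajectories carried by an
exact number of persons. Injected concept ids are disjoint from the random
background concepts, so planted structure can be recovered and counted
exactly.

The default experimental conditions mirror the framework's internal
validation: cohorts of a few hundred to a thousand persons, 1-30 random
background events per person drawn uniformly from 100 background concepts,
and a planted pair with P(E2 after E1) = 50%.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

DOMAINS = np.array(["condition", "observation", "drug_era", "procedure"])
DEFAULT_GAP = (30, 365)  # uniform integer days between injected events


@dataclass
class InjectedPair:
    e1: int
    e2: int
    n_carriers: int
    p_e2_given_e1: float = 0.5
    gap_days: tuple[int, int] = DEFAULT_GAP
    p_e2_baseline: float = 0.0       # E2 probability among non-carriers
    e1_window_days: Optional[int] = None  # restrict E1 to the first k days


@dataclass
class InjectedTrajectory:
    concepts: tuple[int, ...]
    n_carriers: int
    gap_days: tuple[int, int] = DEFAULT_GAP


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic dataset."""

    n_persons: int = 1000
    events_per_person: tuple[int, int] = (1, 30)
    n_background_concepts: int = 100
    date_range: tuple[str, str] = ("2010-01-01", "2019-12-31")
    birth_year_range: tuple[int, int] = (1940, 1999)
    background_concept_base: int = 1000
    injected_pairs: list[InjectedPair] = field(default_factory=list)
    injected_trajectories: list[InjectedTrajectory] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.events_per_person
        if lo < 0 or hi < lo:
            raise ValueError("invalid events_per_person range")
        bg = set(
            range(
                self.background_concept_base,
                self.background_concept_base + self.n_background_concepts,
            )
        )
        injected: set[int] = set()
        for p in self.injected_pairs:
            injected |= {p.e1, p.e2}
            if not 0 <= p.p_e2_given_e1 <= 1 or not 0 <= p.p_e2_baseline <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
            if p.n_carriers > self.n_persons:
                raise ValueError("n_carriers exceeds n_persons")
        for t in self.injected_trajectories:
            if len(t.concepts) < 2:
                raise ValueError("an injected trajectory needs >= 2 concepts")
            injected |= set(t.concepts)
            if t.n_carriers > self.n_persons:
                raise ValueError("n_carriers exceeds n_persons")
        if bg & injected:
            raise ValueError("injected concept ids must be disjoint from background")


def _day_bounds(spec: SyntheticSpec) -> tuple[int, int]:
    start = np.datetime64(spec.date_range[0], "D").astype(int)
    end = np.datetime64(spec.date_range[1], "D").astype(int)
    if end < start:
        raise ValueError("date_range end before start")
    return int(start), int(end)


def _to_dates(days: np.ndarray) -> pd.Series:
    return pd.Series(days.astype("datetime64[D]"))


def generate_random_events(spec: SyntheticSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Random persons and background events, deterministic given the seed.

    Every person is observed over the full ``date_range``; event counts are
    uniform in ``events_per_person``, concepts uniform over the background
    concepts, and dates uniform over the window.
    """
    rng = np.random.default_rng(spec.seed)
    d0, d1 = _day_bounds(spec)
    n = spec.n_persons
    persons = pd.DataFrame(
        {
            "person_id": [f"p{i:06d}" for i in range(n)],
            "gender": rng.choice(["female", "male"], size=n),
            "birth_year": rng.integers(
                spec.birth_year_range[0], spec.birth_year_range[1] + 1, size=n
            ),
            "obs_start": _to_dates(np.full(n, d0)),
            "obs_end": _to_dates(np.full(n, d1)),
        }
    )
    lo, hi = spec.events_per_person
    counts = rng.integers(lo, hi + 1, size=n)
    pid = np.repeat(persons["person_id"].to_numpy(), counts)
    total = int(counts.sum())
    concepts = spec.background_concept_base + rng.integers(
        0, spec.n_background_concepts, size=total
    )
    events = pd.DataFrame(
        {
            "person_id": pid,
            "concept_id": concepts.astype(np.int64),
            "concept_name": [f"background concept {c}" for c in concepts],
            "domain": rng.choice(DOMAINS, size=total),
            "event_date": _to_dates(rng.integers(d0, d1 + 1, size=total)),
        }
    )
    return persons, events


def _new_events(person_ids, concept_ids, days, label: str) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "person_id": person_ids,
            "concept_id": np.asarray(concept_ids, dtype=np.int64),
            "concept_name": [f"{label} {c}" for c in concept_ids],
            "domain": "condition",
            "event_date": _to_dates(np.asarray(days)),
        }
    )


def inject_pair(
    persons: pd.DataFrame,
    events: pd.DataFrame,
    pair: InjectedPair,
    spec: SyntheticSpec,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, int]:
    """Plant an E1 -> E2 pair; returns the events plus the realized E2 count.

    ``pair.n_carriers`` persons (drawn without replacement) receive E1 at a
    random in-window date and, independently with probability
    ``p_e2_given_e1``, E2 at E1 + gap. Non-carriers receive E2 at a uniform
    date with probability ``p_e2_baseline`` (background risk channel). E1
    dates are resampled (bounded retries) when the gap would pass the end of
    observation.
    """
    d0, d1 = _day_bounds(spec)
    glo, ghi = pair.gap_days
    n = len(persons)
    carriers = rng.choice(n, size=pair.n_carriers, replace=False)
    e1_hi = d0 + pair.e1_window_days if pair.e1_window_days is not None else d1
    e1_hi = min(e1_hi, d1)

    e1_days = np.empty(pair.n_carriers, dtype=int)
    gaps = np.empty(pair.n_carriers, dtype=int)
    for k in range(pair.n_carriers):
        for _ in range(100):
            day = int(rng.integers(d0, e1_hi + 1))
            gap = int(rng.integers(glo, ghi + 1))
            if day + gap <= d1:
                break
        else:
            raise ValueError("cannot place E1 + gap inside the observation window")
        e1_days[k], gaps[k] = day, gap
    has_e2 = rng.random(pair.n_carriers) < pair.p_e2_given_e1
    pid = persons["person_id"].to_numpy()
    parts = [events, _new_events(pid[carriers], [pair.e1] * pair.n_carriers, e1_days, "injected concept")]
    if has_e2.any():
        parts.append(
            _new_events(
                pid[carriers[has_e2]],
                [pair.e2] * int(has_e2.sum()),
                e1_days[has_e2] + gaps[has_e2],
                "injected concept",
            )
        )
    if pair.p_e2_baseline > 0:
        non_carriers = np.setdiff1d(np.arange(n), carriers)
        base = non_carriers[rng.random(len(non_carriers)) < pair.p_e2_baseline]
        if len(base):
            parts.append(
                _new_events(
                    pid[base],
                    [pair.e2] * len(base),
                    rng.integers(d0, d1 + 1, size=len(base)),
                    "injected concept",
                )
            )
    out = pd.concat(parts, ignore_index=True)
    return out, int(has_e2.sum())


def inject_trajectory(
    persons: pd.DataFrame,
    events: pd.DataFrame,
    traj: InjectedTrajectory,
    spec: SyntheticSpec,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Plant a full ordered event chain into exactly ``n_carriers`` persons,
    with strictly positive adjacent gaps."""
    if traj.n_carriers == 0:
        return events
    d0, d1 = _day_bounds(spec)
    glo, ghi = traj.gap_days
    k = len(traj.concepts)
    n = len(persons)
    carriers = rng.choice(n, size=traj.n_carriers, replace=False)
    pid = persons["person_id"].to_numpy()
    rows_pid, rows_cid, rows_day = [], [], []
    for c in carriers:
        for _ in range(100):
            start = int(rng.integers(d0, d1 + 1))
            gaps = rng.integers(max(1, glo), ghi + 1, size=k - 1)
            days = start + np.concatenate([[0], np.cumsum(gaps)])
            if days[-1] <= d1:
                break
        else:
            raise ValueError("cannot place trajectory inside the observation window")
        rows_pid.extend([pid[c]] * k)
        rows_cid.extend(traj.concepts)
        rows_day.extend(days.tolist())
    return pd.concat(
        [events, _new_events(rows_pid, rows_cid, rows_day, "injected concept")],
        ignore_index=True,
    )


def generate(spec: SyntheticSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Random tables plus every injection of the spec, deterministic."""
    persons, events = generate_random_events(spec)
    rng = np.random.default_rng(spec.seed + 1)
    for pair in spec.injected_pairs:
        events, _ = inject_pair(persons, events, pair, spec, rng)
    for traj in spec.injected_trajectories:
        events = inject_trajectory(persons, events, traj, spec, rng)
    events = events.sort_values(
        ["person_id", "event_date", "concept_id"], kind="mergesort"
    ).reset_index(drop=True)
    return persons, events


def planted_rr_dataset(
    n_persons: int,
    n_carriers: int,
    p_e2_given_e1: float,
    design_rr: float,
    seed: int,
    events_per_person: tuple[int, int] = (1, 30),
    e1: int = 9001,
    e2: int = 9002,
) -> tuple[pd.DataFrame, pd.DataFrame, InjectedPair]:
    """Dataset whose planted pair has a calibrated design relative risk.

    Carriers receive E1 near the start of the observation window and E2 only
    through the conditional channel (probability ``p_e2_given_e1``), so the
    exposed-group E2 prevalence equals that probability. Non-carriers receive
    E2 at a uniform date with probability ``p_e2_given_e1 / design_rr``; with
    index dates at the window start, the matched background prevalence equals
    that baseline, giving RR = ``design_rr`` by construction.
    """
    if design_rr <= 0:
        raise ValueError("design_rr must be positive")
    p0 = p_e2_given_e1 / design_rr
    if not 0 <= p0 <= 1:
        raise ValueError("p_e2_given_e1 / design_rr must be a probability")
    pair = InjectedPair(
        e1=e1,
        e2=e2,
        n_carriers=n_carriers,
        p_e2_given_e1=p_e2_given_e1,
        p_e2_baseline=p0,
        e1_window_days=30,
    )
    spec = SyntheticSpec(
        n_persons=n_persons,
        events_per_person=events_per_person,
        injected_pairs=[pair],
        seed=seed,
    )
    persons, events = generate(spec)
    return persons, events, pair


def write_tables(persons: pd.DataFrame, events: pd.DataFrame, person_path, event_path) -> None:
    """Write tables in the file schema the readers consume."""
    pout = persons.rename(
        columns={
            "gender": "gender_concept",
            "birth_year": "year_of_birth",
            "obs_start": "observation_period_start_date",
            "obs_end": "observation_period_end_date",
        }
    )
    for c in ("observation_period_start_date", "observation_period_end_date"):
        pout[c] = pd.to_datetime(pout[c]).dt.strftime("%Y-%m-%d")
    eout = events.copy()
    eout["event_date"] = pd.to_datetime(eout["event_date"]).dt.strftime("%Y-%m-%d")
    sep = "\t" if str(person_path).endswith((".tsv", ".tab", ".txt")) else ","
    pout.to_csv(person_path, sep=sep, index=False)
    sep = "\t" if str(event_path).endswith((".tsv", ".tab", ".txt")) else ","
    eout.to_csv(event_path, sep=sep, index=False)
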