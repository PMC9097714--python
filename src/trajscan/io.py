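"""Reading and validation of person / event / cohort tables.

The input schema is a flattened OMOP-CDM subset carried in delimited text
(comma- or tab-separated, auto-detected from the extension) or Parquet:

* person table: ``person_id, gender_concept, year_of_birth,
  observation_period_start_date, observation_period_end_date``
* event table: ``person_id, concept_id, concept_name, domain, event_date``
* cohort table: ``person_id, cohort_start_date, cohort_end_date``

Dates are ISO-8601 calendar dates (day precision). All filters conserve
counts: kept + dropped = input, and both are logged.
"""

from __future__ import annotations

import logging
from typing import Iterable, Optional

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ALLOWED_DOMAINS = frozenset({"condition", "observation", "drug_era", "procedure"})
ALLOWED_GENDERS = frozenset({"male", "female", "unknown"})

PERSON_COLUMNS = [
    "person_id",
    "gender_concept",
    "year_of_birth",
    "observation_period_start_date",
    "observation_period_end_date",
]
EVENT_COLUMNS = ["person_id", "concept_id", "concept_name", "domain", "event_date"]
COHORT_COLUMNS = ["person_id", "cohort_start_date", "cohort_end_date"]


class TableSchemaError(ValueError):
    """A required column is missing or the file cannot be read."""


class TableContentError(ValueError):
    """Row-level validation failed; the message lists offending rows."""


def _read_table(path, columns: list[str]) -> pd.DataFrame:
    p = str(path)
    if p.endswith(".parquet"):
        df = pd.read_parquet(p)
    elif p.endswith((".tsv", ".tab", ".txt")):
        df = pd.read_csv(p, sep="\t", dtype=str)
    else:
        df = pd.read_csv(p, sep=",", dtype=str)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise TableSchemaError(f"{p}: missing required columns {missing}")
    return df


def _parse_dates(df: pd.DataFrame, col: str, label: str) -> pd.Series:
    parsed = pd.to_datetime(df[col], format="ISO8601", errors="coerce")
    bad = parsed.isna() & df[col].notna()
    if bad.any():
        rows = (df.index[bad] + 2).tolist()[:10]  # +2: header + 1-based
        raise TableContentError(
            f"{label}: {int(bad.sum())} unparseable dates in column '{col}' "
            f"(file lines {rows}{'...' if bad.sum() > 10 else ''})"
        )
    if parsed.isna().any():
        rows = (df.index[parsed.isna()] + 2).tolist()[:10]
        raise TableContentError(
            f"{label}: {int(parsed.isna().sum())} empty dates in column '{col}' "
            f"(file lines {rows})"
        )
    return parsed


def read_person_table(path) -> pd.DataFrame:
    """Read and validate the person table.

    Returns a DataFrame with columns ``person_id`` (str), ``gender``
    (``male``/``female``/``unknown``), ``birth_year`` (int), ``obs_start`` and
    ``obs_end`` (datetime64). Raises :class:`TableContentError` naming the
    offending file lines when invariants are violated.
    """
    raw = _read_table(path, PERSON_COLUMNS)
    label = f"person table {path}"
    out = pd.DataFrame(
        {
            "person_id": raw["person_id"].astype(str),
            "gender": raw["gender_concept"].astype(str).str.lower(),
            "birth_year": pd.to_numeric(raw["year_of_birth"], errors="coerce"),
            "obs_start": _parse_dates(raw, "observation_period_start_date", label),
            "obs_end": _parse_dates(raw, "observation_period_end_date", label),
        }
    )
    problems = []
    dup = out["person_id"].duplicated(keep=False)
    if dup.any():
        problems.append(
            f"duplicate person_id on file lines {(out.index[dup] + 2).tolist()[:10]}"
        )
    bad_gender = ~out["gender"].isin(ALLOWED_GENDERS)
    if bad_gender.any():
        problems.append(
            f"unknown gender values on file lines "
            f"{(out.index[bad_gender] + 2).tolist()[:10]}"
        )
    bad_year = out["birth_year"].isna()
    if bad_year.any():
        problems.append(
            f"non-integer year_of_birth on file lines "
            f"{(out.index[bad_year] + 2).tolist()[:10]}"
        )
    bad_window = out["obs_end"] < out["obs_start"]
    if bad_window.any():
        problems.append(
            f"obs_end before obs_start on file lines "
            f"{(out.index[bad_window] + 2).tolist()[:10]}"
        )
    if not bad_year.any():
        bad_by = out["birth_year"] > out["obs_start"].dt.year
        if bad_by.any():
            problems.append(
                f"birth_year after observation start on file lines "
                f"{(out.index[bad_by] + 2).tolist()[:10]}"
            )
    if problems:
        raise TableContentError(f"{label}: " + "; ".join(problems))
    out["birth_year"] = out["birth_year"].astype(int)
    logger.info("%s: %d persons read", label, len(out))
    return out


def read_event_table(
    path,
    included_domains: Iterable[str] = ALLOWED_DOMAINS,
    persons: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Read the event table, keeping only the requested domains.

    Rows whose domain is outside ``included_domains`` are dropped (count
    logged). When ``persons`` is given, events dated outside the person's
    observation window are likewise dropped and counted, and events for
    unknown persons raise an error.
    """
    included = set(included_domains)
    if not included <= ALLOWED_DOMAINS:
        raise ValueError(
            f"included_domains must be a subset of {sorted(ALLOWED_DOMAINS)}"
        )
    raw = _read_table(path, EVENT_COLUMNS)
    label = f"event table {path}"
    out = pd.DataFrame(
        {
            "person_id": raw["person_id"].astype(str),
            "concept_id": pd.to_numeric(raw["concept_id"], errors="coerce"),
            "concept_name": raw["concept_name"].astype(str),
            "domain": raw["domain"].astype(str).str.lower(),
            "event_date": _parse_dates(raw, "event_date", label),
        }
    )
    bad_cid = out["concept_id"].isna()
    if bad_cid.any():
        raise TableContentError(
            f"{label}: non-integer concept_id on file lines "
            f"{(out.index[bad_cid] + 2).tolist()[:10]}"
        )
    out["concept_id"] = out["concept_id"].astype(np.int64)
    unknown_domain = ~out["domain"].isin(ALLOWED_DOMAINS)
    if unknown_domain.any():
        raise TableContentError(
            f"{label}: unknown domain values on file lines "
            f"{(out.index[unknown_domain] + 2).tolist()[:10]}"
        )
    n_in = len(out)
    out = out[out["domain"].isin(included)].reset_index(drop=True)
    logger.info(
        "%s: %d rows read, %d kept after domain filter, %d dropped",
        label,
        n_in,
        len(out),
        n_in - len(out),
    )
    if persons is not None:
        unknown = ~out["person_id"].isin(persons["person_id"])
        if unknown.any():
            ids = sorted(out.loc[unknown, "person_id"].unique())[:10]
            raise TableContentError(f"{label}: events for unknown persons {ids}")
        merged = out.merge(
            persons[["person_id", "obs_start", "obs_end"]], on="person_id", how="left"
        )
        in_window = (merged["event_date"] >= merged["obs_start"]) & (
            merged["event_date"] <= merged["obs_end"]
        )
        n_out = int((~in_window).sum())
        if n_out:
            logger.info("%s: %d events outside observation windows dropped", label, n_out)
        out = out[in_window.to_numpy()].reset_index(drop=True)
    return out


def read_cohort_table(path) -> pd.DataFrame:
    """Read a cohort table of per-person entry/exit windows."""
    raw = _read_table(path, COHORT_COLUMNS)
    label = f"cohort table {path}"
    out = pd.DataFrame(
        {
            "person_id": raw["person_id"].astype(str),
            "entry_date": _parse_dates(raw, "cohort_start_date", label),
            "exit_date": _parse_dates(raw, "cohort_end_date", label),
        }
    )
    bad = out["exit_date"] < out["entry_date"]
    if bad.any():
        raise TableContentError(
            f"{label}: exit before entry on file lines "
            f"{(out.index[bad] + 2).tolist()[:10]}"
        )
    # windows of one person must not overlap
    s = out.sort_values(["person_id", "entry_date"])
    overlap = (s["person_id"] == s["person_id"].shift()) & (
        s["entry_date"] <= s["exit_date"].shift()
    )
    if overlap.any():
        ids = sorted(s.loc[overlap, "person_id"].unique())[:10]
        raise TableContentError(f"{label}: overlapping windows for persons {ids}")
    return out


def read_pair_list(path) -> pd.DataFrame:
    """Read a validation-mode pair list with columns ``e1_concept_id``,
    ``e2_concept_id`` (names optional)."""
    df = _read_table(path, ["e1_concept_id", "e2_concept_id"])
    out = pd.DataFrame(
        {
            "e1": pd.to_numeric(df["e1_concept_id"]).astype(np.int64),
            "e2": pd.to_numeric(df["e2_concept_id"]).astype(np.int64),
        }
    )
    if len(out) == 0:
        raise TableContentError(f"pair list {path}: empty")
    return out


def apply_cohort(
    events: pd.DataFrame,
    persons: pd.DataFrame,
    cohort: Optional[pd.DataFrame] = None,
    attrition: Optional[dict] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Restrict events to cohort windows and build sequence units.

    With ``cohort=None`` (whole-database mode) every person forms one unit
    whose window equals the observation period. Otherwise each cohort window
    becomes an independent sequence unit; a person with several windows is
    represented several times, and events outside every window are dropped.

    Returns ``(events, units)`` where ``events`` gains a ``unit_id`` column
    and ``units`` has one row per sequence unit with demographics and the
    window bounds.
    """
    if cohort is None:
        units = persons.rename(
            columns={"obs_start": "window_start", "obs_end": "window_end"}
        ).copy()
        units["unit_id"] = np.arange(len(units))
    else:
        unknown = set(cohort["person_id"]) - set(persons["person_id"])
        if unknown:
            raise TableContentError(
                f"cohort persons not in person table: {sorted(unknown)[:10]}"
            )
        units = cohort.merge(persons, on="person_id", how="left")
        # clamp cohort windows to the observation period
        units["window_start"] = units[["entry_date", "obs_start"]].max(axis=1)
        units["window_end"] = units[["exit_date", "obs_end"]].min(axis=1)
        units = units[units["window_start"] <= units["window_end"]].reset_index(
            drop=True
        )
        units["unit_id"] = np.arange(len(units))
        units = units[
            ["unit_id", "person_id", "gender", "birth_year", "window_start", "window_end"]
        ]
    n_in = len(events)
    merged = events.merge(
        units[["unit_id", "person_id", "window_start", "window_end"]],
        on="person_id",
        how="inner",
    )
    keep = (merged["event_date"] >= merged["window_start"]) & (
        merged["event_date"] <= merged["window_end"]
    )
    out = merged[keep.to_numpy()].drop(columns=["window_start", "window_end"])
    out = out.reset_index(drop=True)
    logger.info(
        "cohort restriction: %d events in, %d kept, %d dropped; %d sequence units",
        n_in,
        len(out),
        n_in - len(out),
        len(units),
    )
    if attrition is not None:
        attrition["events_in"] = n_in
        attrition["events_in_cohort"] = len(out)
        attrition["sequence_units"] = len(units)
    return out, units


def first_occurrences(events: pd.DataFrame) -> pd.DataFrame:
    """Reduce events to per-unit first occurrences of each distinct concept.

    Requires a ``unit_id`` column (from :func:`apply_cohort`). Within a unit
    only the earliest date of each concept is kept; output is sorted by date
    and, for same-date ties, by ascending concept_id, so sequences are
    deterministic.
    """
    if "unit_id" not in events.columns:
        raise ValueError("events must carry unit_id; run apply_cohort first")
    firsts = (
        events.groupby(["unit_id", "concept_id"], as_index=False)
        .agg(event_date=("event_date", "min"))
        .sort_values(["unit_id", "event_date", "concept_id"], kind="mergesort")
        .reset_index(drop=True)
    )
    return firsts


class SequencePanel:
    """Dense first-occurrence date matrix of a cohort.

    Attributes
    ----------
    units : pd.DataFrame
        One row per sequence unit: ``unit_id, person_id, gender, birth_year,
        window_start, window_end``.
    concepts : np.ndarray
        Sorted distinct concept ids.
    dates : np.ndarray, shape (n_units, n_concepts)
        First-occurrence date of each concept per unit, as days since the
        Unix epoch; NaN where the concept never occurs in the unit.
    concept_names : dict
        concept_id -> display name.
    """

    def __init__(self, units, concepts, dates, concept_names=None):
        self.units = units.reset_index(drop=True)
        self.concepts = np.asarray(concepts, dtype=np.int64)
        self.dates = dates
        self.concept_names = concept_names or {}
        self._index = {int(c): i for i, c in enumerate(self.concepts)}

    @classmethod
    def from_events(
        cls,
        firsts: pd.DataFrame,
        units: pd.DataFrame,
        concept_names: Optional[dict] = None,
    ) -> "SequencePanel":
        concepts = np.sort(firsts["concept_id"].unique()).astype(np.int64)
        cindex = {int(c): i for i, c in enumerate(concepts)}
        uindex = {u: i for i, u in enumerate(units["unit_id"])}
        D = np.full((len(units), len(concepts)), np.nan)
        rows = firsts["unit_id"].map(uindex).to_numpy()
        cols = firsts["concept_id"].map(cindex).to_numpy()
        days = firsts["event_date"].to_numpy(dtype="datetime64[D]").astype(float)
        D[rows, cols] = days
        return cls(units, concepts, D, concept_names)

    @property
    def n_units(self) -> int:
        return self.dates.shape[0]

    @property
    def n_concepts(self) -> int:
        return self.dates.shape[1]

    def col(self, concept_id: int) -> np.ndarray:
        """First-occurrence day vector of one concept (NaN = absent)."""
        try:
            return self.dates[:, self._index[int(concept_id)]]
        except KeyError:
            return np.full(self.n_units, np.nan)

    def has_concept(self, concept_id: int) -> bool:
        return int(concept_id) in self._index

    def patient_count(self, concept_id: int) -> int:
        """Number of units whose sequence contains the concept."""
        return int(np.isfinite(self.col(concept_id)).sum())

    def name_of(self, concept_id: int) -> str:
        return self.concept_names.get(int(concept_id), str(concept_id))

    def sequences(self) -> dict[int, list[tuple[int, float]]]:
        """Per-unit ordered (concept_id, day) lists; ties by concept_id."""
        out = {}
        for u in range(self.n_units):
            row = self.dates[u]
            present = np.flatnonzero(np.isfinite(row))
            order = present[np.lexsort((self.concepts[present], row[present]))]
            out[int(self.units["unit_id"].iloc[u])] = [
                (int(self.concepts[i]), float(row[i])) for i in order
            ]
        return out


def build_panel(
    events: pd.DataFrame,
    persons: pd.DataFrame,
    cohort: Optional[pd.DataFrame] = None,
    attrition: Optional[dict] = None,
) -> SequencePanel:
    """Cohort restriction + first occurrences + dense panel, in one call."""
    ev, units = apply_cohort(events, persons, cohort, attrition)
    firsts = first_occurrences(ev)
    names = (
        events.drop_duplicates("concept_id").set_index("concept_id")["concept_name"]
        if "concept_name" in events.columns
        else pd.Series(dtype=str)
    )
    return SequencePanel.from_events(firsts, units, concept_names=names.to_dict())
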