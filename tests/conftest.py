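import numpy as np
import pandas as pd
import pytest

from trajscan.io import SequencePanel


def make_persons(rows):
    """rows: list of (person_id, gender, birth_year, obs_start, obs_end)."""
    df = pd.DataFrame(
        rows, columns=["person_id", "gender", "birth_year", "obs_start", "obs_end"]
    )
    df["obs_start"] = pd.to_datetime(df["obs_start"])
    df["obs_end"] = pd.to_datetime(df["obs_end"])
    return df


def make_events(rows):
    """rows: list of (person_id, concept_id, event_date)."""
    df = pd.DataFrame(rows, columns=["person_id", "concept_id", "event_date"])
    df["concept_name"] = "c" + df["concept_id"].astype(str)
    df["domain"] = "condition"
    df["event_date"] = pd.to_datetime(df["event_date"])
    return df[["person_id", "concept_id", "concept_name", "domain", "event_date"]]


def panel_from_day_offsets(day_map, base="2015-01-01"):
    """Build a SequencePanel from {unit: {concept: day_offset}}.

    Units get identical demographics so matching strata are trivial.
    """
    base_day = np.datetime64(base, "D").astype(float)
    concepts = sorted({c for d in day_map.values() for c in d})
    units = pd.DataFrame(
        {
            "unit_id": list(range(len(day_map))),
            "person_id": [f"p{u}" for u in day_map],
            "gender": "female",
            "birth_year": 1970,
            "window_start": pd.Timestamp("2010-01-01"),
            "window_end": pd.Timestamp("2029-12-31"),
        }
    )
    D = np.full((len(day_map), len(concepts)), np.nan)
    cidx = {c: i for i, c in enumerate(concepts)}
    for r, (_, cmap) in enumerate(day_map.items()):
        for c, off in cmap.items():
            D[r, cidx[c]] = base_day + off
    return SequencePanel(units, np.array(concepts), D)


@pytest.fixture
def three_event_panel():
    """One unit with A(day 0), B(day 10), C(day 20)."""
    return panel_from_day_offsets({0: {1: 0, 2: 10, 3: 20}})
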