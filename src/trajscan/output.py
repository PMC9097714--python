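"""Result-file writers with privacy masking.

Patient counts below the study's ``privacy_min_count`` are written as
``<k`` in every exported table, mirroring the convention of hiding small
event counts in published trajectory studies.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .graph import mask_count
from .params import StudyParams

COUNT_COLUMNS = [
    "n_pair", "n_reverse", "n_exposed", "n_background",
    "k_exposed_e2", "k_background_e2", "n_patients",
]


def _masked(df: pd.DataFrame, k: int) -> pd.DataFrame:
    out = df.copy()
    for c in COUNT_COLUMNS:
        if c in out.columns:
            out[c] = out[c].map(
                lambda v: "" if pd.isna(v) else mask_count(int(v), k)
            )
    return out


def write_results_tsv(results: pd.DataFrame, path, params: StudyParams) -> None:
    """Per-pair test results, tab-separated, counts privacy-masked."""
    _masked(results, params.privacy_min_count).to_csv(
        path, sep="\t", index=False, float_format="%.6g"
    )


def write_trajectories_tsv(trajectories: pd.DataFrame, path, params: StudyParams) -> None:
    df = trajectories.copy()
    if len(df):
        df["trajectory"] = df["trajectory"].map(
            lambda t: "->".join(str(c) for c in t)
        )
    _masked(df, params.privacy_min_count).to_csv(path, sep="\t", index=False)


def write_manifest(path, params: StudyParams, attrition: dict) -> None:
    payload = {"study_params": params.to_dict(), "attrition": attrition}
    Path(path).write_text(json.dumps(payload, indent=2, default=str) + "\n")
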