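"""Enumeration of ordered event pairs under temporal-gap constraints.

An event pair E1 -> E2 is realized by a sequence unit when the first
occurrence of E2 falls between ``min_gap_days`` and ``max_gap_days`` (both
inclusive) after the first occurrence of E1. Intermediate events between the
two do not block a pair.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .io import SequencePanel
from .params import StudyParams

logger = logging.getLogger(__name__)


def pair_count_matrix(panel: SequencePanel, params: StudyParams) -> np.ndarray:
    """Dense matrix ``M[i, j]`` = number of units realizing
    ``concepts[i] -> concepts[j]`` within the gap window."""
    D = panel.dates
    lo, hi = float(params.min_gap_days), params.gap_upper
    m = panel.n_concepts
    M = np.zeros((m, m), dtype=np.int64)
    with np.errstate(invalid="ignore"):
        for i in range(m):
            gap = D - D[:, i][:, None]  # (units, concepts): date(b) - date(a)
            M[i] = ((gap >= lo) & (gap <= hi)).sum(axis=0)
    np.fill_diagonal(M, 0)
    return M


def enumerate_pairs(panel: SequencePanel, params: StudyParams) -> pd.DataFrame:
    """All ordered concept pairs with a positive realization count.

    Returns a DataFrame with columns ``e1, e2, n_pair, n_reverse`` where
    ``n_reverse`` is the count of the opposite order (used later by the
    direction test). Pairs with ``n_pair == 0`` are omitted.
    """
    M = pair_count_matrix(panel, params)
    i, j = np.nonzero(M)
    df = pd.DataFrame(
        {
            "e1": panel.concepts[i],
            "e2": panel.concepts[j],
            "n_pair": M[i, j],
            "n_reverse": M[j, i],
        }
    )
    df = df.sort_values(["e1", "e2"], kind="mergesort").reset_index(drop=True)
    logger.info("enumerated %d ordered pairs with n_pair >= 1", len(df))
    return df


def filter_pairs(
    pairs: pd.DataFrame, params: StudyParams, n_units: int
) -> pd.DataFrame:
    """Keep pairs meeting the minimum count / prevalence floor."""
    if n_units < 1:
        raise ValueError("n_units must be >= 1")
    threshold = params.pair_count_threshold(n_units)
    kept = pairs[pairs["n_pair"] >= threshold].reset_index(drop=True)
    logger.info(
        "pair floor %d (of %d units): %d pairs kept, %d dropped",
        threshold,
        n_units,
        len(kept),
        len(pairs) - len(kept),
    )
    return kept
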