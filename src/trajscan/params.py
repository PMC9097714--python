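"""Study parameters controlling pair detection, matching and testing.

A single :class:`StudyParams` instance travels through the whole pipeline so
that every stage (pair enumeration, matching, testing, trajectory counting)
applies the same temporal-gap window, thresholds and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

VALID_CORRECTIONS = ("fdr", "bonferroni")
VALID_MODES = ("discovery", "validation")


@dataclass
class StudyParams:
    """Parameters of a trajectory study.

    Parameters
    ----------
    min_gap_days : int
        Minimum temporal distance (days) between the first occurrences of the
        two events of a pair. The default of 1 enforces strict temporal order
        and excludes same-day co-recording.
    max_gap_days : int or None
        Maximum temporal distance in days; ``None`` means unbounded.
    min_pair_count : int or None
        Absolute floor on the number of sequence units realizing a pair.
        Exactly one of ``min_pair_count`` / ``min_pair_prevalence`` is set.
    min_pair_prevalence : float or None
        Pair-count floor expressed as a fraction of the cohort; converted to
        a count with ceiling semantics ("at least this share of the cohort").
    rr_min_of_interest : float
        Lower bound of the relative-risk range of interest; associated pairs
        with smaller RR are not flagged significant.
    alpha : float
        Significance level applied to multiple-testing-corrected p-values.
    correction : {"fdr", "bonferroni"}
        Multiple-testing correction. Discovery runs default to
        Benjamini-Hochberg FDR, validation runs to Bonferroni.
    mode : {"discovery", "validation"}
        Whether pairs are discovered from the data or a supplied pair list is
        validated.
    age_bin_years : int
        Width of the age bins used for exact matching.
    match_ratio : int
        Background members matched per exposed unit.
    propensity_top_k : int
        Number of most prevalent concepts whose prior-occurrence indicators
        enter the propensity model (plus the total prior-event count).
    privacy_min_count : int
        Counts below this value are masked as ``<k`` in written outputs.
    max_trajectory_len : int
        Maximum number of concepts in a composed trajectory.
    seed : int
        Governs every stochastic step (candidate index-date assignment and
        tie-breaking).
    """

    min_gap_days: int = 1
    max_gap_days: Optional[int] = None
    min_pair_count: Optional[int] = None
    min_pair_prevalence: Optional[float] = 0.01
    rr_min_of_interest: float = 1.2
    alpha: float = 0.05
    correction: str = "fdr"
    mode: str = "discovery"
    age_bin_years: int = 5
    match_ratio: int = 1
    propensity_top_k: int = 100
    privacy_min_count: int = 20
    max_trajectory_len: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_gap_days < 0:
            raise ValueError("min_gap_days must be >= 0")
        if self.max_gap_days is not None and self.max_gap_days < self.min_gap_days:
            raise ValueError("min_gap_days must not exceed max_gap_days")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie strictly between 0 and 1")
        if (self.min_pair_count is None) == (self.min_pair_prevalence is None):
            raise ValueError(
                "exactly one of min_pair_count / min_pair_prevalence must be set"
            )
        if self.min_pair_count is not None and self.min_pair_count < 1:
            raise ValueError("min_pair_count must be >= 1")
        if self.min_pair_prevalence is not None and not (
            0.0 < self.min_pair_prevalence <= 1.0
        ):
            raise ValueError("min_pair_prevalence must be in (0, 1]")
        if self.correction not in VALID_CORRECTIONS:
            raise ValueError(f"correction must be one of {VALID_CORRECTIONS}")
        if self.mode not in VALID_MODES:
            raise ValueError(f"mode must be one of {VALID_MODES}")
        if self.rr_min_of_interest <= 0:
            raise ValueError("rr_min_of_interest must be positive")
        if self.age_bin_years < 1:
            raise ValueError("age_bin_years must be >= 1")
        if self.match_ratio < 1:
            raise ValueError("match_ratio must be >= 1")
        if self.max_trajectory_len < 2:
            raise ValueError("max_trajectory_len must be >= 2")

    @property
    def gap_upper(self) -> float:
        """Upper gap bound as a float (``inf`` when unbounded)."""
        return float("inf") if self.max_gap_days is None else float(self.max_gap_days)

    def pair_count_threshold(self, n_units: int) -> int:
        """Minimum pair count implied by the parameters for ``n_units`` units.

        A prevalence floor is converted with ceiling semantics so that the
        kept pairs cover *at least* the requested share of the cohort.
        """
        import math

        if self.min_pair_count is not None:
            return int(self.min_pair_count)
        return max(1, math.ceil(self.min_pair_prevalence * n_units))

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "StudyParams":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown study parameters: {sorted(unknown)}")
        return cls(**d)
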