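"""Statistical tests for matched event pairs.

Association of E1 with future E2 is tested by Fisher's exact test on the
2x2 table of E2 occurrence in the matched exposed and background groups,
and quantified as the relative risk

    RR = Pr(E2 with prior E1) / Pr(E2 without prior E1)

with a 95% CI from the Katz log-normal approximation. Temporal direction is
tested with an exact two-sided binomial test at p = 1/2 on the numbers of
patients carrying both events in either order. Multiple-testing correction
(Benjamini-Hochberg FDR or Bonferroni) is applied separately to the Fisher
and binomial p-value families across all tested pairs of a run.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

Z975 = 1.959963984540054  # standard normal 97.5% quantile


def relative_risk(
    k_exp: int, n_exp: int, k_bg: int, n_bg: int, continuity: bool = True
) -> tuple[float, float, float]:
    """Relative risk of E2 with a 95% Katz log-normal CI.

    ``rr = (k_exp/n_exp) / (k_bg/n_bg)``. When any cell of the implied 2x2
    table is zero, the Haldane-Anscombe correction (0.5 added to all four
    cells) is used for the CI, and for the point estimate as well when
    ``k_bg == 0``; with ``continuity=False`` a zero ``k_bg`` yields
    ``rr = inf`` and no finite CI.
    """
    if n_exp <= 0 or n_bg <= 0:
        raise ValueError("empty group")
    if min(k_exp, k_bg) < 0 or k_exp > n_exp or k_bg > n_bg:
        raise ValueError("invalid counts")
    any_zero = 0 in (k_exp, n_exp - k_exp, k_bg, n_bg - k_bg)
    if k_bg == 0 and not continuity:
        return float("inf"), float("nan"), float("nan")
    if k_bg == 0:
        rr = ((k_exp + 0.5) / (n_exp + 1)) / ((k_bg + 0.5) / (n_bg + 1))
    else:
        rr = (k_exp / n_exp) / (k_bg / n_bg)
    if any_zero and continuity:
        a, n1, c, n2 = k_exp + 0.5, n_exp + 1.0, k_bg + 0.5, n_bg + 1.0
    else:
        a, n1, c, n2 = float(k_exp), float(n_exp), float(k_bg), float(n_bg)
    if a == 0 or c == 0:
        return float(rr), float("nan"), float("nan")
    log_rr = np.log((a / n1) / (c / n2))
    se = np.sqrt(1.0 / a - 1.0 / n1 + 1.0 / c - 1.0 / n2)
    return float(rr), float(np.exp(log_rr - Z975 * se)), float(np.exp(log_rr + Z975 * se))


def fisher_association(k_exp: int, n_exp: int, k_bg: int, n_bg: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table
    ``[[k_exp, n_exp - k_exp], [k_bg, n_bg - k_bg]]`` (probability-mass
    method: tables as or less probable than the observed one)."""
    cells = (k_exp, n_exp - k_exp, k_bg, n_bg - k_bg)
    if any(c < 0 for c in cells):
        raise ValueError("negative cell in 2x2 table")
    table = [[cells[0], cells[1]], [cells[2], cells[3]]]
    return float(sps.fisher_exact(table, alternative="two-sided")[1])


def binomial_direction(n_e1_first: int, n_e2_first: int) -> float:
    """Exact two-sided binomial p at success probability 1/2 for the
    observed split of patients carrying both events in either order."""
    if n_e1_first < 0 or n_e2_first < 0:
        raise ValueError("negative count")
    n = n_e1_first + n_e2_first
    if n == 0:
        raise ValueError("no ordered co-occurrences")
    return float(sps.binomtest(n_e1_first, n, p=0.5, alternative="two-sided").pvalue)


def adjust_pvalues(pvals, method: str = "fdr") -> np.ndarray:
    """Multiple-testing-adjusted p-values, order-preserving with the input.

    ``bonferroni``: min(1, m*p). ``fdr``: Benjamini-Hochberg step-up.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    name = {"fdr": "fdr_bh", "bonferroni": "bonferroni"}.get(method)
    if name is None:
        raise ValueError(f"unknown correction method {method!r}")
    return multipletests(p, method=name)[1]


def classify_pair(
    fisher_p_adj: float,
    binom_p_adj: float,
    rr: float,
    n_e1_first: int,
    n_e2_first: int,
    alpha: float,
    rr_min_of_interest: float,
) -> tuple[bool, bool]:
    """Significance flags for one pair.

    ``significant_assoc``: corrected Fisher p below alpha and RR within the
    range of interest. ``significant_direction``: additionally, the
    corrected binomial p below alpha with E1-before-E2 the dominant order.
    """
    assoc = bool(fisher_p_adj < alpha and rr >= rr_min_of_interest)
    direction = bool(
        assoc and binom_p_adj < alpha and n_e1_first > n_e2_first
    )
    return assoc, direction
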