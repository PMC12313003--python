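"""Group summaries and two-group comparisons for cohort endpoints.

Endpoints are per-cell scalars (RVD %, peak FRET change, decay constants,
membrane properties).  Groups are summarized as mean ± SEM with both cell
(n) and animal (N) counts carried through.  Two-group tests mirror common
slice-physiology practice: an unpaired t-test (Welch by default) or a
two-sided Mann–Whitney U-test, computed exactly by full enumeration of
rank assignments for small samples (pooled n ≤ 14) and by the tie-corrected
normal approximation otherwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
from scipy import stats as sstats

__all__ = [
    "GroupSummary",
    "ComparisonResult",
    "summarize_group",
    "mann_whitney_exact",
    "compare_two_groups",
    "EXACT_MW_MAX_POOLED_N",
]

EXACT_MW_MAX_POOLED_N = 14


@dataclass
class GroupSummary:
    """Mean ± SEM summary of one genotype/condition group."""

    label: str
    n_cells: int
    n_animals: int | None
    mean: float
    sd: float
    sem: float
    values: np.ndarray


@dataclass
class ComparisonResult:
    """Two-sided two-group test result."""

    test_name: str
    statistic: float
    p_value: float
    group_labels: tuple[str, str]

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")


def summarize_group(
    values, label: str = "", n_animals: int | None = None
) -> GroupSummary:
    """Summarize per-cell values as mean ± SEM (SEM = sd/√n, sd with ddof 1)."""
    vals = np.asarray(values, dtype=float)
    if vals.size == 0:
        raise ValueError("empty group")
    if vals.size == 1:
        warnings.warn("single-value group: SEM undefined, reported as 0")
        sd = sem = 0.0
    else:
        sd = float(np.std(vals, ddof=1))
        sem = sd / np.sqrt(vals.size)
    return GroupSummary(
        label=label,
        n_cells=int(vals.size),
        n_animals=n_animals,
        mean=float(vals.mean()),
        sd=sd,
        sem=sem,
        values=vals,
    )


def _u_statistic_from_ranks(rank_sum: float, n_a: int) -> float:
    return rank_sum - n_a * (n_a + 1) / 2.0


def mann_whitney_exact(a, b) -> tuple[float, float]:
    """Exact two-sided Mann–Whitney U test by full enumeration.

    Pools both samples, assigns midranks (ties supported), and enumerates
    all C(n, n_a) assignments of ranks to group a.  The two-sided p-value
    counts assignments at least as extreme as the observed U on either tail
    (u ≤ min(U, U′) or u ≥ max(U, U′)), capped at 1.
    Returns (U of group a, p_two_sided).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    if np.unique(pooled).size == 1:
        raise ValueError("all pooled values identical; U test degenerate")
    n_a, n = a.size, pooled.size
    if comb(n, n_a) > 2_000_000:
        raise ValueError("sample too large for exact enumeration")
    ranks = sstats.rankdata(pooled)
    u_obs = _u_statistic_from_ranks(ranks[:n_a].sum(), n_a)
    u_max = n_a * b.size
    lo = min(u_obs, u_max - u_obs)
    hi = u_max - lo
    count = 0
    total = 0
    for idx in combinations(range(n), n_a):
        u = _u_statistic_from_ranks(ranks[list(idx)].sum(), n_a)
        total += 1
        if u <= lo + 1e-9 or u >= hi - 1e-9:
            count += 1
    return float(u_obs), min(1.0, count / total)


def compare_two_groups(
    a,
    b,
    test: str = "welch_t",
    labels: tuple[str, str] = ("a", "b"),
) -> ComparisonResult:
    """Two-sided comparison of two independent groups.

    ``test``: "welch_t" (default), "student_t" (pooled variance), or
    "mann_whitney" (exact enumeration when pooled n ≤ 14, tie-corrected
    normal approximation otherwise).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if test in ("welch_t", "student_t"):
        res = sstats.ttest_ind(a, b, equal_var=(test == "student_t"))
        return ComparisonResult(
            test_name=test,
            statistic=float(res.statistic),
            p_value=float(res.pvalue),
            group_labels=labels,
        )
    if test == "mann_whitney":
        if a.size + b.size <= EXACT_MW_MAX_POOLED_N:
            u, p = mann_whitney_exact(a, b)
            name = "mann_whitney_exact"
        else:
            res = sstats.mannwhitneyu(a, b, alternative="two-sided",
                                      method="asymptotic")
            u, p = float(res.statistic), float(res.pvalue)
            name = "mann_whitney_normal"
        return ComparisonResult(
            test_name=name, statistic=u, p_value=p, group_labels=labels
        )
    raise ValueError(f"unknown test {test!r}")
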