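"""Nonparametric group comparison of SLA parameters.

Groups (strain x age cohorts) are compared with the two-tailed
Mann-Whitney U test and summarized as mean ± SEM.  The test is implemented
here rather than delegated: the exact null distribution of U is computed by
the standard counting recurrence for small tie-free samples, and a normal
approximation with midrank tie correction and continuity correction is used
otherwise, so every p value is auditable.  Significance is reported in the
conventional tiers p < 0.05 (1), p < 0.01 (2), p < 0.001 (3).

No multiple-testing correction is applied by default (cross-sectional
per-parameter comparisons); Holm or Bonferroni adjustment is available as
an option.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "SampleGroup",
    "TestResult",
    "mann_whitney_u",
    "summarize_group",
    "significance_tier",
    "build_comparison_table",
]


@dataclass(frozen=True)
class SampleGroup:
    """One cohort's values of one SLA parameter."""

    label: str
    values: Tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.values) == 0:
            raise ValueError(f"group {self.label!r} is empty")

    @property
    def n(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class TestResult:
    """Mann-Whitney outcome: U of the first group, two-tailed p, tier."""

    U: float
    p_two_tailed: float
    method: str  # "exact" or "normal_approximation"
    tier: int
    n1: int
    n2: int


def significance_tier(p: float) -> int:
    """Conventional tiers: 3 if p < 0.001, 2 if p < 0.01, 1 if p < 0.05, else 0."""
    if p < 0.001:
        return 3
    if p < 0.01:
        return 2
    if p < 0.05:
        return 1
    return 0


@lru_cache(maxsize=None)
def _u_counts(n1: int, n2: int) -> Tuple[int, ...]:
    """Number of rank assignments giving each U value, tie-free null.

    ``_u_counts(n1, n2)[u]`` counts the subsets of ranks {1..n1+n2} of size
    n1 whose U statistic equals u; classic recurrence
    f(n1, n2, u) = f(n1-1, n2, u-n2) + f(n1, n2-1, u).
    """
    max_u = n1 * n2
    # table[i][j] = counts over u for i-of-first, j-of-second sample
    prev = [np.zeros(max_u + 1, dtype=object) for _ in range(n2 + 1)]
    for j in range(n2 + 1):
        prev[j][0] = 1  # i = 0: only u = 0
    for i in range(1, n1 + 1):
        cur = [None] * (n2 + 1)
        col = np.zeros(max_u + 1, dtype=object)
        col[0] = 1
        cur[0] = col
        for j in range(1, n2 + 1):
            c = np.zeros(max_u + 1, dtype=object)
            # add an element of sample 1 larger than all j of sample 2: u += j
            c[j:] += prev[j][: max_u + 1 - j]
            # add an element of sample 2 larger than all i of sample 1
            c += cur[j - 1]
            cur[j] = c
        prev = cur
    return tuple(int(v) for v in prev[n2])


def _exact_two_tailed_p(u_min: float, n1: int, n2: int) -> float:
    counts = _u_counts(n1, n2)
    total = math.comb(n1 + n2, n1)
    k = int(math.floor(u_min + 1e-9))
    p_one = sum(counts[: k + 1]) / total
    return min(1.0, 2.0 * p_one)


def mann_whitney_u(a, b, continuity: bool = True, method: str = "auto") -> TestResult:
    """Two-tailed Mann-Whitney U test between two samples.

    U is computed from rank sums with midranks for ties.  With
    ``method="auto"`` the exact two-tailed p (full enumeration of the null
    distribution of U) is used when ``n1 + n2 <= 20`` and there are no
    ties; otherwise the normal approximation with tie correction and
    (optionally) continuity correction.  The two-tailed p is twice the
    smaller one-tailed p, capped at 1.
    """
    av = np.asarray(getattr(a, "values", a), dtype=float)
    bv = np.asarray(getattr(b, "values", b), dtype=float)
    n1, n2 = av.size, bv.size
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    combined = np.concatenate([av, bv])
    ranks = rankdata(combined)
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0
    u2 = n1 * n2 - u1
    u_min = min(u1, u2)
    has_ties = np.unique(combined).size < combined.size

    if method == "auto":
        method = "exact" if (n1 + n2 <= 20 and not has_ties) else "normal_approximation"
    if method == "exact":
        if has_ties:
            raise ValueError("exact method requires tie-free samples")
        p = _exact_two_tailed_p(u_min, n1, n2)
    elif method == "normal_approximation":
        n = n1 + n2
        mu = n1 * n2 / 2.0
        _, tie_counts = np.unique(combined, return_counts=True)
        tie_term = float(np.sum(tie_counts ** 3 - tie_counts))
        var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
        if var <= 0:
            p = 1.0
        else:
            cc = 0.5 if continuity else 0.0
            z = (u_min - mu + cc) / math.sqrt(var)
            p = min(1.0, 2.0 * 0.5 * math.erfc(-z / math.sqrt(2.0)))
    else:
        raise ValueError(f"unknown method {method!r}")
    return TestResult(U=float(u1), p_two_tailed=float(p), method=method,
                      tier=significance_tier(p), n1=n1, n2=n2)


def summarize_group(g) -> Tuple[float, Optional[float], int]:
    """Mean, SEM (sample SD / sqrt(n); ``None`` for n = 1) and n."""
    v = np.asarray(getattr(g, "values", g), dtype=float)
    if v.size == 0:
        raise ValueError("empty group")
    mean = float(v.mean())
    sem = float(v.std(ddof=1) / math.sqrt(v.size)) if v.size > 1 else None
    return mean, sem, int(v.size)


def build_comparison_table(profiles: pd.DataFrame, parameters: Sequence[str],
                           strain_col: str = "strain", age_col: str = "age",
                           baseline_age: Optional[float] = None,
                           correction: Optional[str] = None,
                           **test_kwargs) -> pd.DataFrame:
    """All between-strain (matched ages) and within-strain vs-baseline tests.

    Returns a long-format table (parameter, comparison, group_a, group_b,
    n_a, n_b, U, p, tier).  ``correction`` may be ``"holm"`` or
    ``"bonferroni"`` (applied per parameter); the default is no adjustment.
    """
    missing = [p for p in parameters if p not in profiles.columns]
    if missing:
        raise ValueError(f"parameters not in profile table: {missing}")
    strains = list(dict.fromkeys(profiles[strain_col]))
    ages = sorted(set(profiles[age_col]))
    if baseline_age is None:
        baseline_age = ages[0]
    rows = []
    for param in parameters:
        param_rows = []

        def values(strain, age):
            sel = (profiles[strain_col] == strain) & (profiles[age_col] == age)
            return profiles.loc[sel, param].dropna().to_numpy()

        for age in ages:
            for i in range(len(strains)):
                for j in range(i + 1, len(strains)):
                    va, vb = values(strains[i], age), values(strains[j], age)
                    if va.size and vb.size:
                        res = mann_whitney_u(va, vb, **test_kwargs)
                        param_rows.append((param, "between_strain",
                                           f"{strains[i]}@{age}", f"{strains[j]}@{age}",
                                           res))
        for strain in strains:
            base = values(strain, baseline_age)
            if not base.size:
                continue
            for age in ages:
                if age == baseline_age:
                    continue
                va = values(strain, age)
                if va.size:
                    res = mann_whitney_u(base, va, **test_kwargs)
                    param_rows.append((param, "vs_baseline_age",
                                       f"{strain}@{baseline_age}", f"{strain}@{age}",
                                       res))
        pvals = [r[4].p_two_tailed for r in param_rows]
        if correction is not None and pvals:
            from statsmodels.stats.multitest import multipletests
            pvals = list(multipletests(pvals, method=correction)[1])
        for (param_, kind, ga, gb, res), p in zip(param_rows, pvals):
            rows.append({
                "parameter": param_, "comparison": kind,
                "group_a": ga, "group_b": gb,
                "n_a": res.n1, "n_b": res.n2,
                "U": res.U, "p": p, "tier": significance_tier(p),
                "method": res.method,
            })
    if not rows:
        raise ValueError("no overlapping groups to compare")
    return pd.DataFrame(rows)


def summary_table(profiles: pd.DataFrame, parameters: Sequence[str],
                  strain_col: str = "strain", age_col: str = "age") -> pd.DataFrame:
    """Mean ± SEM per (strain, age) cohort for each parameter."""
    rows = []
    for (strain, age), sub in profiles.groupby([strain_col, age_col], sort=True):
        for param in parameters:
            v = sub[param].dropna().to_numpy()
            if not v.size:
                continue
            mean, sem, n = summarize_group(v)
            rows.append({"strain": strain, "age": age, "parameter": param,
                         "mean": mean, "sem": sem, "n": n})
    return pd.DataFrame(rows)
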