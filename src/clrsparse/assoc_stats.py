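"""Two-group and correlation statistics used throughout the analyses.

Every comparison in the reanalysis chain is one of two tests: a two-sided
Mann-Whitney U for a continuous value against a binary phenotype, or a
Pearson correlation between two continuous values.  Group summaries are
reported as median [min-max], matching how microbiome comparisons of this
kind are usually printed.

The Mann-Whitney implementation has two routes.  For pooled sample sizes
above 16 it uses the normal approximation with midrank ties, tie-corrected
variance and a continuity correction (delegated to scipy).  At or below 16
it enumerates all C(n_a+n_b, n_a) group assignments exactly; the exact
enumerator is also exported on its own (`exact_mann_whitney`) so it can
serve as an independent oracle for the asymptotic route.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Literal, Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .errors import DegenerateDataError, ValidationError

EXACT_MAX_POOLED = 16


@dataclass(frozen=True)
class PhenotypeLabels:
    """Binary phenotype: sample ID -> group, with a designated positive group."""

    assignments: Mapping[str, str]
    positive: str
    negative: str

    def __post_init__(self) -> None:
        levels = set(self.assignments.values())
        if levels != {self.positive, self.negative}:
            raise ValidationError(
                f"labels must take exactly the two levels "
                f"{self.positive!r}/{self.negative!r}; saw {sorted(levels)}"
            )

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(self.assignments)

    def positive_mask(self, sample_ids: Sequence[str]) -> np.ndarray:
        missing = [s for s in sample_ids if s not in self.assignments]
        if missing:
            raise ValidationError(f"samples missing from labels: {missing}")
        return np.array(
            [self.assignments[s] == self.positive for s in sample_ids], dtype=bool
        )

    def split(
        self, values: np.ndarray, sample_ids: Sequence[str]
    ) -> tuple[np.ndarray, np.ndarray]:
        """Return (positive-group values, negative-group values)."""
        mask = self.positive_mask(sample_ids)
        values = np.asarray(values, dtype=float)
        return values[mask], values[~mask]

    def subset(self, sample_ids: Sequence[str]) -> "PhenotypeLabels":
        return PhenotypeLabels(
            assignments={s: self.assignments[s] for s in sample_ids},
            positive=self.positive,
            negative=self.negative,
        )

    def permuted(self, rng: np.random.Generator) -> "PhenotypeLabels":
        ids = list(self.assignments)
        vals = list(self.assignments.values())
        rng.shuffle(vals)
        return PhenotypeLabels(
            assignments=dict(zip(ids, vals)),
            positive=self.positive,
            negative=self.negative,
        )


@dataclass(frozen=True)
class GroupSummary:
    median: float
    min: float
    max: float


@dataclass(frozen=True)
class AssociationResult:
    """One statistical comparison: test, statistic, two-sided p, summaries."""

    test: Literal["mann_whitney_u", "pearson"]
    statistic: float
    p_value: float
    n_a: int
    n_b: int
    group_summaries: dict[str, GroupSummary]
    direction: int  # sign of the effect (a vs b, or sign of R)


def _summary(values: np.ndarray) -> GroupSummary:
    return GroupSummary(
        median=float(np.median(values)),
        min=float(np.min(values)),
        max=float(np.max(values)),
    )


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """U for group a via midranks (handles ties)."""
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    return float(ranks[: a.size].sum() - a.size * (a.size + 1) / 2.0)


def exact_mann_whitney(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney by full enumeration.

    Enumerates every way of assigning the pooled values to groups of sizes
    (n_a, n_b) and returns (U, p) with p = P(|U - n_a n_b / 2| >= |U_obs -
    n_a n_b / 2|) under that uniform permutation null.  Ties are handled by
    midranks, which the enumeration inherits for free.  Cost is
    C(n_a+n_b, n_a); intended for pooled sizes up to ~16.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n_a, n_b = a.size, b.size
    if n_a == 0 or n_b == 0:
        raise ValidationError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    u_obs = float(ranks[:n_a].sum() - n_a * (n_a + 1) / 2.0)
    mu = n_a * n_b / 2.0
    dev_obs = abs(u_obs - mu)
    hits = 0
    offset = n_a * (n_a + 1) / 2.0
    for idx in combinations(range(n_a + n_b), n_a):
        u = ranks[list(idx)].sum() - offset
        if abs(u - mu) >= dev_obs - 1e-12:
            hits += 1
    p = hits / comb(n_a + n_b, n_a)
    return u_obs, p


def mann_whitney_u(
    a: Sequence[float],
    b: Sequence[float],
    *,
    method: Literal["auto", "exact", "asymptotic"] = "auto",
    group_names: tuple[str, str] = ("a", "b"),
) -> AssociationResult:
    """Two-sided Mann-Whitney U comparing two independent groups.

    Exact enumeration for pooled n <= 16 (or on request); otherwise the
    tie-corrected normal approximation with continuity correction.  All-tied
    pooled data yields p = 1 with a warning rather than an error, so sweep
    and reanalysis chains survive a feature that is constant (e.g. all-zero)
    across every sample.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both groups must be non-empty")
    summaries = {group_names[0]: _summary(a), group_names[1]: _summary(b)}
    u = _u_statistic(a, b)
    direction = int(np.sign(u - a.size * b.size / 2.0))
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        warnings.warn(
            "all pooled values identical; Mann-Whitney is degenerate, p = 1",
            stacklevel=2,
        )
        return AssociationResult(
            test="mann_whitney_u",
            statistic=u,
            p_value=1.0,
            n_a=int(a.size),
            n_b=int(b.size),
            group_summaries=summaries,
            direction=0,
        )
    if method == "auto":
        method = "exact" if a.size + b.size <= EXACT_MAX_POOLED else "asymptotic"
    if method == "exact":
        u, p = exact_mann_whitney(a, b)
    else:
        res = sps.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=True
        )
        u, p = float(res.statistic), float(res.pvalue)
    return AssociationResult(
        test="mann_whitney_u",
        statistic=u,
        p_value=min(1.0, float(p)),
        n_a=int(a.size),
        n_b=int(b.size),
        group_summaries=summaries,
        direction=direction,
    )


def pearson_r(x: Sequence[float], y: Sequence[float]) -> AssociationResult:
    """Pearson correlation with the two-sided t-transform p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValidationError("x and y must have equal length")
    if x.size < 3:
        raise ValidationError("Pearson correlation needs at least 3 pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise DegenerateDataError("Pearson correlation undefined for a constant vector")
    res = sps.pearsonr(x, y)
    r, p = float(res.statistic), float(res.pvalue)
    return AssociationResult(
        test="pearson",
        statistic=r,
        p_value=p,
        n_a=int(x.size),
        n_b=int(x.size),
        group_summaries={"x": _summary(x), "y": _summary(y)},
        direction=int(np.sign(r)),
    )


def group_summary(
    values: Sequence[float],
    labels: PhenotypeLabels,
    sample_ids: Sequence[str],
) -> dict[str, GroupSummary]:
    """Median/min/max per phenotype group (median: midpoint convention)."""
    pos, neg = labels.split(np.asarray(values, dtype=float), sample_ids)
    if pos.size == 0 or neg.size == 0:
        raise ValidationError("both phenotype groups must be non-empty")
    return {labels.positive: _summary(pos), labels.negative: _summary(neg)}
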