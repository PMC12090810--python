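"""Compositional mathematics for microbiome abundance tables.

Sequencing read counts carry an arbitrary per-sample total, so a sample is
interpreted as a composition: only the relative abundances of its taxa are
meaningful.  The centered log-ratio (CLR) transform maps a strictly positive
composition ``x`` to ``ln(x_j / g(x))`` where ``g`` is the sample geometric
mean.  Because logarithms are undefined at zero, a small pseudocount is added
first, either in relative-abundance space or in raw-count space.

The consequence this package studies falls straight out of the algebra: a
feature that equals the pseudocount ``c`` in every sample is transformed to
``ln c - ln g_i``, a pure function of the sample geometric mean.  Since the
geometric mean is tied to Shannon alpha diversity (H equals the negative log
of the abundance-weighted geometric mean), any phenotype that tracks
diversity will appear "associated" with such an originally-empty feature —
with no information leakage anywhere.

All logarithms here are natural logs, so the Shannon / weighted-geometric-
mean identity holds exactly.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ValidationError

logger = logging.getLogger(__name__)

Unit = Literal["counts", "relative"]
PseudocountMode = Literal["relative_space", "count_space"]

#: tolerance on row sums of a relative-abundance table
RELATIVE_ROW_TOL = 1e-9


def _check_ids(ids: Sequence[str], what: str, n: int) -> tuple[str, ...]:
    ids = tuple(str(i) for i in ids)
    if len(ids) != n:
        raise ValidationError(
            f"{what}: expected {n} identifiers, got {len(ids)}"
        )
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        dup = next(i for i in ids if i in seen or seen.add(i))
        raise ValidationError(f"duplicate {what} identifier: {dup!r}")
    return ids


@dataclass(frozen=True)
class AbundanceTable:
    """Samples x features matrix of raw counts or relative abundances.

    Rows are samples, columns are features (taxa).  ``unit`` records whether
    the entries are raw counts (any nonnegative reals with arbitrary row
    totals) or relative abundances (each row sums to one).
    """

    values: np.ndarray
    sample_ids: tuple[str, ...]
    feature_ids: tuple[str, ...]
    unit: Unit

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ValidationError("values must be a 2-D samples x features matrix")
        if not np.all(np.isfinite(values)):
            raise ValidationError("values contain NaN or infinite entries")
        if np.any(values < 0):
            i, j = np.argwhere(values < 0)[0]
            raise ValidationError(
                f"negative abundance at sample index {i}, feature index {j}"
            )
        object.__setattr__(self, "values", values)
        object.__setattr__(
            self, "sample_ids", _check_ids(self.sample_ids, "sample", values.shape[0])
        )
        object.__setattr__(
            self, "feature_ids", _check_ids(self.feature_ids, "feature", values.shape[1])
        )
        if self.unit not in ("counts", "relative"):
            raise ValidationError(f"unknown unit {self.unit!r}")
        if self.unit == "relative":
            sums = values.sum(axis=1)
            bad = np.flatnonzero(np.abs(sums - 1.0) > RELATIVE_ROW_TOL)
            if bad.size:
                raise ValidationError(
                    f"relative-abundance row {self.sample_ids[bad[0]]!r} "
                    f"sums to {sums[bad[0]]!r}, not 1"
                )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def feature_column(self, feature_id: str) -> np.ndarray:
        try:
            j = self.feature_ids.index(feature_id)
        except ValueError:
            raise ValidationError(f"feature {feature_id!r} not in table") from None
        return self.values[:, j].copy()

    def select_features(self, keep: Iterable[str]) -> "AbundanceTable":
        keep = list(keep)
        idx = [self.feature_ids.index(f) for f in keep]
        return replace(
            self, values=self.values[:, idx], feature_ids=tuple(keep)
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.sample_ids), columns=list(self.feature_ids)
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, unit: Unit) -> "AbundanceTable":
        return cls(
            values=df.to_numpy(dtype=float),
            sample_ids=tuple(str(i) for i in df.index),
            feature_ids=tuple(str(c) for c in df.columns),
            unit=unit,
        )


@dataclass(frozen=True)
class PositiveCompositionTable:
    """Post-pseudocount table: strictly positive, ready for the CLR."""

    values: np.ndarray
    sample_ids: tuple[str, ...]
    feature_ids: tuple[str, ...]
    pseudocount: float
    pseudocount_mode: PseudocountMode

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2 or not np.all(np.isfinite(values)):
            raise ValidationError("values must be a finite 2-D matrix")
        if np.any(values <= 0):
            i, j = np.argwhere(values <= 0)[0]
            raise ValidationError(
                f"non-positive entry after pseudocount at sample "
                f"{self.sample_ids[i]!r}, feature {self.feature_ids[j]!r}"
            )
        if not self.pseudocount > 0:
            raise ValidationError("pseudocount must be > 0")
        object.__setattr__(self, "values", values)
        object.__setattr__(
            self, "sample_ids", _check_ids(self.sample_ids, "sample", values.shape[0])
        )
        object.__setattr__(
            self, "feature_ids", _check_ids(self.feature_ids, "feature", values.shape[1])
        )


@dataclass(frozen=True)
class ClrTable:
    """CLR-transformed table; every row sums to zero (closure)."""

    values: np.ndarray
    sample_ids: tuple[str, ...]
    feature_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        sums = np.abs(values.sum(axis=1))
        if np.any(sums > 1e-8):
            i = int(np.argmax(sums))
            raise ValidationError(
                f"CLR row {self.sample_ids[i]!r} sums to {values.sum(axis=1)[i]!r}"
            )
        object.__setattr__(self, "values", values)
        object.__setattr__(
            self, "sample_ids", _check_ids(self.sample_ids, "sample", values.shape[0])
        )
        object.__setattr__(
            self, "feature_ids", _check_ids(self.feature_ids, "feature", values.shape[1])
        )

    def feature_column(self, feature_id: str) -> np.ndarray:
        try:
            j = self.feature_ids.index(feature_id)
        except ValueError:
            raise ValidationError(f"feature {feature_id!r} not in table") from None
        return self.values[:, j].copy()

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.sample_ids), columns=list(self.feature_ids)
        )


@dataclass(frozen=True)
class SampleSummary:
    """Per-sample scalars: geometric mean (post-pseudocount), Shannon H and
    the abundance-weighted geometric mean (both on the pre-pseudocount
    relative abundances)."""

    sample_id: str
    geometric_mean: float
    shannon: float
    weighted_geometric_mean: float


def to_relative_abundance(table: AbundanceTable) -> AbundanceTable:
    """Normalize each sample (row) to sum to one.

    Idempotent on tables already in relative units.  A row of all zeros has
    no defined composition and raises, naming the sample.
    """
    sums = table.values.sum(axis=1)
    empty = np.flatnonzero(sums <= 0)
    if empty.size:
        raise ValidationError(
            f"sample {table.sample_ids[empty[0]]!r} has zero total abundance; "
            "cannot normalize"
        )
    return AbundanceTable(
        values=table.values / sums[:, None],
        sample_ids=table.sample_ids,
        feature_ids=table.feature_ids,
        unit="relative",
    )


def default_pseudocount(table: AbundanceTable) -> float:
    """Largest power of 10 strictly below the smallest positive entry.

    The convention keeps the pseudocount under the data's resolution: for a
    minimum observed relative abundance m, returns max{10^k : 10^k < m}.
    Strict inequality, so m = 1e-3 exactly yields 1e-4.
    """
    positive = table.values[table.values > 0]
    if positive.size == 0:
        raise ValidationError("table has no positive entries")
    m = float(positive.min())
    k = math.floor(math.log10(m))
    while 10.0 ** k >= m:
        k -= 1
    return 10.0 ** k


def add_pseudocount(
    table: AbundanceTable, c: float, mode: PseudocountMode
) -> PositiveCompositionTable:
    """Replace zeros by adding the constant ``c`` to every entry.

    ``relative_space``: c is added to an already-normalized table and the
    rows are *not* renormalized — the CLR is invariant to row rescaling, so
    renormalization would change nothing downstream.
    ``count_space``: c is added to raw counts, which are then normalized; in
    this mode zero counts become ``c / (total + D*c)`` and therefore vary
    with sequencing depth.
    """
    if not c > 0:
        raise ValidationError(f"pseudocount must be > 0, got {c!r}")
    if mode == "relative_space":
        if table.unit != "relative":
            raise ValidationError(
                "relative_space pseudocount requires a relative-abundance table"
            )
        values = table.values + c
    elif mode == "count_space":
        if table.unit != "counts":
            raise ValidationError("count_space pseudocount requires a counts table")
        shifted = AbundanceTable(
            values=table.values + c,
            sample_ids=table.sample_ids,
            feature_ids=table.feature_ids,
            unit="counts",
        )
        values = to_relative_abundance(shifted).values
    else:
        raise ValidationError(f"unknown pseudocount mode {mode!r}")
    return PositiveCompositionTable(
        values=values,
        sample_ids=table.sample_ids,
        feature_ids=table.feature_ids,
        pseudocount=float(c),
        pseudocount_mode=mode,
    )


def clr_transform(table: PositiveCompositionTable) -> ClrTable:
    """Centered log-ratio: clr_ij = ln(x_ij) - mean_k ln(x_ik).

    Scale-invariant per row and closed (rows sum to zero).  A feature stuck
    at the constant pseudocount c maps to ln(c) - ln(g_i), which is the
    mechanism by which empty features acquire sample-dependent values.
    """
    if table.values.shape[1] == 1:
        logger.warning(
            "CLR of a single-feature composition is identically zero "
            "(%d samples, 1 feature)", table.values.shape[0]
        )
    logs = np.log(table.values)
    clr = logs - logs.mean(axis=1, keepdims=True)
    return ClrTable(
        values=clr, sample_ids=table.sample_ids, feature_ids=table.feature_ids
    )


def geometric_mean(row: np.ndarray) -> float:
    """Geometric mean over *all* entries of a strictly positive vector.

    Computed after pseudocount addition, pseudocount-filled entries
    included — this is what the CLR divides by.
    """
    row = np.asarray(row, dtype=float)
    if row.ndim != 1 or row.size == 0:
        raise ValidationError("geometric_mean expects a non-empty 1-D vector")
    if np.any(row <= 0):
        raise ValidationError("geometric_mean requires strictly positive entries")
    return float(sps.gmean(row))


def _check_relative_row(row: np.ndarray) -> np.ndarray:
    row = np.asarray(row, dtype=float)
    if row.ndim != 1 or row.size == 0:
        raise ValidationError("expected a non-empty 1-D relative-abundance vector")
    if np.any(row < 0):
        raise ValidationError("relative abundances must be nonnegative")
    total = row.sum()
    if abs(total - 1.0) > 1e-6:
        raise ValidationError(f"relative-abundance row sums to {total!r}, not 1")
    return row


def shannon_diversity(row: np.ndarray) -> float:
    """Shannon alpha diversity H = -sum p ln p (natural log, 0 ln 0 = 0)."""
    row = _check_relative_row(row)
    return float(sps.entropy(row))


def weighted_geometric_mean(row: np.ndarray) -> float:
    """Abundance-weighted geometric mean: prod p_i^{p_i} over positive p_i.

    Its negative natural log is exactly the Shannon diversity, which is the
    bridge between alpha diversity and the CLR's geometric-mean reference.
    """
    row = _check_relative_row(row)
    p = row[row > 0]
    return float(np.prod(p ** p))


def summarize_samples(
    relative: AbundanceTable, positive: PositiveCompositionTable
) -> list[SampleSummary]:
    """Per-sample geometric mean (post-pseudocount) and diversity summaries."""
    if relative.sample_ids != positive.sample_ids:
        raise ValidationError("tables describe different samples")
    out = []
    for i, sid in enumerate(relative.sample_ids):
        out.append(
            SampleSummary(
                sample_id=sid,
                geometric_mean=geometric_mean(positive.values[i]),
                shannon=shannon_diversity(relative.values[i]),
                weighted_geometric_mean=weighted_geometric_mean(relative.values[i]),
            )
        )
    return out
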