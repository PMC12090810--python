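"""Synthetic datasets with a diversity-phenotype association and sparse taxa.

Two generators:

``simulate_counterexample`` builds the two-group dataset in which an
entirely empty feature becomes perfectly phenotype-separating after
pseudocount + CLR.  Positive samples draw 30 features i.i.d. Uniform(0,1)
(31st empty); negative samples draw 20 features with the remaining 11 empty.
After row normalization the groups differ strongly in geometric mean, so the
CLR value of the empty feature, ln(c) - ln(g_i), separates them — although
no step ever looks at a label.

``simulate_cohort`` emulates the statistical structure of real case/control
microbiome tables: one group's compositions come from a low-concentration
symmetric Dirichlet (dominated, low Shannon diversity), the other from a
high-concentration one (even, high diversity); reads are multinomial at a
fixed depth; optionally one extra taxon receives a single read in exactly
one sample, mimicking a singleton OTU.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Union

import numpy as np

from .assoc_stats import PhenotypeLabels
from .comp_core import AbundanceTable, default_pseudocount, to_relative_abundance
from .errors import ValidationError

SparseVariant = Literal["empty", "nonzero", "partial"]

POSITIVE_LABEL = "positive"
NEGATIVE_LABEL = "negative"


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the empty-feature counterexample generator.

    The default pseudocount is the fixed value 1e-6 used throughout the
    headline analysis; ``pseudocount="auto"`` instead applies the
    power-of-ten rule to the realized table (which can resolve one power up
    or down depending on the realized minimum).
    """

    n_positive: int = 50
    n_negative: int = 50
    n_features_positive: int = 30
    n_features_negative: int = 20
    total_features: int = 31
    sparse_variant: SparseVariant = "empty"
    partial_fraction: float = 0.2
    pseudocount: Union[float, str] = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_positive", "n_negative", "n_features_positive",
                     "n_features_negative", "total_features"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.n_features_positive >= self.total_features:
            raise ValidationError("n_features_positive must be < total_features")
        if self.n_features_negative >= self.total_features:
            raise ValidationError("n_features_negative must be < total_features")
        if self.sparse_variant not in ("empty", "nonzero", "partial"):
            raise ValidationError(f"unknown sparse_variant {self.sparse_variant!r}")
        if not (0.0 < self.partial_fraction < 1.0):
            raise ValidationError("partial_fraction must lie in (0, 1)")
        if self.pseudocount != "auto" and not (
            isinstance(self.pseudocount, (int, float)) and self.pseudocount > 0
        ):
            raise ValidationError("pseudocount must be a positive number or 'auto'")


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of the Dirichlet-multinomial case/control emulator."""

    n_per_group: int = 20
    n_taxa: int = 50
    depth: int = 10_000
    concentration_low_diversity: float = 0.1
    concentration_high_diversity: float = 10.0
    singleton_taxon: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group <= 0:
            raise ValidationError("n_per_group must be positive")
        if self.n_taxa < 3:
            raise ValidationError("n_taxa must be >= 3")
        if self.depth < 1:
            raise ValidationError("depth must be >= 1")
        if self.concentration_low_diversity <= 0 or self.concentration_high_diversity <= 0:
            raise ValidationError("Dirichlet concentrations must be positive")


@dataclass(frozen=True)
class LabeledDataset:
    """A table with its binary phenotype and (optionally) a designated
    sparse feature of interest."""

    table: AbundanceTable
    labels: PhenotypeLabels
    sparse_feature_id: Optional[str] = None

    def __post_init__(self) -> None:
        if set(self.labels.assignments) != set(self.table.sample_ids):
            raise ValidationError("labels must cover exactly the table's samples")
        if (
            self.sparse_feature_id is not None
            and self.sparse_feature_id not in self.table.feature_ids
        ):
            raise ValidationError(
                f"sparse_feature_id {self.sparse_feature_id!r} not in table"
            )


def simulate_counterexample(config: SimulationConfig) -> LabeledDataset:
    """Generate the empty-feature counterexample dataset.

    Rows are normalized to relative abundances; the returned
    ``sparse_feature_id`` names the final feature, whose content depends on
    ``sparse_variant``:

    - ``empty``   — zero in every sample (the headline case);
    - ``nonzero`` — i.i.d. Uniform(0,1) in every sample, identically
      distributed in both groups, so any post-CLR association is driven
      solely by the geometric-mean mechanism;
    - ``partial`` — Uniform(0,1) in a label-blind random ``partial_fraction``
      of samples, zero elsewhere.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_positive + config.n_negative
    d = config.total_features
    raw = np.zeros((n, d))
    raw[: config.n_positive, : config.n_features_positive] = rng.uniform(
        size=(config.n_positive, config.n_features_positive)
    )
    raw[config.n_positive :, : config.n_features_negative] = rng.uniform(
        size=(config.n_negative, config.n_features_negative)
    )
    if config.sparse_variant == "nonzero":
        raw[:, d - 1] = rng.uniform(size=n)
    elif config.sparse_variant == "partial":
        k = round(config.partial_fraction * n)
        chosen = rng.choice(n, size=k, replace=False)
        raw[chosen, d - 1] = rng.uniform(size=k)

    sample_ids = tuple(
        f"pos_{i:03d}" for i in range(config.n_positive)
    ) + tuple(f"neg_{i:03d}" for i in range(config.n_negative))
    feature_ids = tuple(f"feature_{j + 1:02d}" for j in range(d))
    table = to_relative_abundance(
        AbundanceTable(
            values=raw, sample_ids=sample_ids, feature_ids=feature_ids, unit="counts"
        )
    )
    labels = PhenotypeLabels(
        assignments={
            s: (POSITIVE_LABEL if i < config.n_positive else NEGATIVE_LABEL)
            for i, s in enumerate(sample_ids)
        },
        positive=POSITIVE_LABEL,
        negative=NEGATIVE_LABEL,
    )
    return LabeledDataset(
        table=table, labels=labels, sparse_feature_id=feature_ids[-1]
    )


def resolve_pseudocount(config: SimulationConfig, table: AbundanceTable) -> float:
    """Turn a config's pseudocount spec into a number for a realized table."""
    if config.pseudocount == "auto":
        return default_pseudocount(table)
    return float(config.pseudocount)


def simulate_cohort(config: CohortConfig) -> LabeledDataset:
    """Dirichlet-multinomial cohort with a diversity gap between groups.

    Group ``low_diversity`` (the positive phenotype) uses the small
    concentration, giving dominated compositions; ``high_diversity`` uses
    the large one, giving even compositions.  Counts are multinomial at a
    uniform depth.  With ``singleton_taxon`` an extra column holds exactly
    one read in one uniformly chosen sample — the sparse feature whose
    post-CLR behavior the reanalysis chain studies.
    """
    rng = np.random.default_rng(config.seed)
    n = 2 * config.n_per_group
    comps = np.vstack(
        [
            rng.dirichlet(
                np.full(config.n_taxa, config.concentration_low_diversity),
                size=config.n_per_group,
            ),
            rng.dirichlet(
                np.full(config.n_taxa, config.concentration_high_diversity),
                size=config.n_per_group,
            ),
        ]
    )
    counts = np.vstack([rng.multinomial(config.depth, p) for p in comps]).astype(float)
    feature_ids = [f"taxon_{j + 1:03d}" for j in range(config.n_taxa)]
    sparse_id = None
    if config.singleton_taxon:
        singleton = np.zeros((n, 1))
        singleton[rng.integers(n), 0] = 1.0
        counts = np.hstack([counts, singleton])
        sparse_id = "taxon_singleton"
        feature_ids.append(sparse_id)
    sample_ids = tuple(f"case_{i:03d}" for i in range(config.n_per_group)) + tuple(
        f"ctrl_{i:03d}" for i in range(config.n_per_group)
    )
    table = AbundanceTable(
        values=counts,
        sample_ids=sample_ids,
        feature_ids=tuple(feature_ids),
        unit="counts",
    )
    labels = PhenotypeLabels(
        assignments={
            s: ("low_diversity" if i < config.n_per_group else "high_diversity")
            for i, s in enumerate(sample_ids)
        },
        positive="low_diversity",
        negative="high_diversity",
    )
    return LabeledDataset(table=table, labels=labels, sparse_feature_id=sparse_id)
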