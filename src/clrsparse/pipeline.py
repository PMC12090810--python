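"""The experiments, end to end.

Four reproducible stages built from the core pieces:

- ``run_counterexample_experiment`` — simulate the two-group dataset with an
  empty feature, add a pseudocount, CLR-transform, and test both the
  per-sample geometric means and the CLR of the empty feature against the
  labels.
- ``run_pseudocount_sweep`` — repeat the CLR + Mann-Whitney step of a fixed
  dataset over a grid of pseudocounts, isolating the pseudocount's effect.
- ``run_sparse_feature_reanalysis`` — the full real-data-style chain on a
  counts table: contaminant removal, relative abundances, Shannon diversity
  vs phenotype, raw relative abundance of a chosen sparse taxon vs
  phenotype, then pseudocount + CLR and the taxon's CLR against both the
  diversity (Pearson) and the phenotype (Mann-Whitney).
- ``permutation_leakage_test`` — the recommended audit for any pipeline
  suspected of leakage: shuffle phenotype labels *before* the pipeline sees
  anything (normalization included) and compare the observed score to the
  permutation distribution.

None of the normalization stages receives labels; labels enter only at the
association steps.  That is the structural point of the whole exercise: a
sample-wise transform cannot leak what it never sees.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Literal, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .assoc_stats import (
    AssociationResult,
    GroupSummary,
    PhenotypeLabels,
    group_summary,
    mann_whitney_u,
    pearson_r,
)
from .comp_core import (
    AbundanceTable,
    add_pseudocount,
    clr_transform,
    default_pseudocount,
    geometric_mean,
    shannon_diversity,
    to_relative_abundance,
)
from .errors import ValidationError
from .synthetic_data import (
    LabeledDataset,
    SimulationConfig,
    resolve_pseudocount,
    simulate_counterexample,
)

logger = logging.getLogger(__name__)

LEAKAGE_ALPHA = 0.05


@dataclass(frozen=True)
class CounterexampleReport:
    geometric_mean_summary: dict[str, GroupSummary]
    clr_sparse_summary: dict[str, GroupSummary]
    mw_geomean: AssociationResult
    mw_clr_sparse: AssociationResult
    config: SimulationConfig
    pseudocount_used: float


@dataclass(frozen=True)
class SweepRow:
    pseudocount: float
    statistic: float
    p_value: float
    exceeds_data_scale: bool


@dataclass(frozen=True)
class SweepReport:
    rows: tuple[SweepRow, ...]
    target_feature: str


@dataclass(frozen=True)
class ReanalysisReport:
    diversity_vs_label: AssociationResult
    raw_ra_vs_label: AssociationResult
    clr_vs_diversity: AssociationResult
    clr_vs_label: AssociationResult
    taxon_id: str
    n_samples: int
    n_features_after_filter: int
    pseudocount_used: float


@dataclass(frozen=True)
class LeakageAuditReport:
    observed_score: float
    permuted_scores: tuple[float, ...]
    empirical_p: float
    n_permutations: int
    verdict: Literal["no_evidence_of_leakage", "leakage_suspected"]


def run_counterexample_experiment(config: SimulationConfig) -> CounterexampleReport:
    """Simulate, transform and test the empty-feature counterexample.

    Geometric means are computed after pseudocount addition over all
    features (this is the quantity the CLR divides by), and the sparse
    feature's CLR column is compared between the label groups.
    """
    dataset = simulate_counterexample(config)
    c = resolve_pseudocount(config, dataset.table)
    positive = add_pseudocount(dataset.table, c, "relative_space")
    g = np.array([geometric_mean(row) for row in positive.values])
    clr = clr_transform(positive)
    sparse = clr.feature_column(dataset.sparse_feature_id)
    ids = dataset.table.sample_ids
    labels = dataset.labels

    g_pos, g_neg = labels.split(g, ids)
    s_pos, s_neg = labels.split(sparse, ids)
    names = (labels.positive, labels.negative)
    return CounterexampleReport(
        geometric_mean_summary=group_summary(g, labels, ids),
        clr_sparse_summary=group_summary(sparse, labels, ids),
        mw_geomean=mann_whitney_u(g_pos, g_neg, group_names=names),
        mw_clr_sparse=mann_whitney_u(s_pos, s_neg, group_names=names),
        config=config,
        pseudocount_used=c,
    )


def run_pseudocount_sweep(
    dataset: LabeledDataset,
    target_feature: str,
    pseudocounts: Sequence[float],
) -> SweepReport:
    """Re-run pseudocount + CLR + Mann-Whitney over a pseudocount grid.

    The dataset is fixed across the grid so that rows differ only in the
    pseudocount.  A pseudocount at or above the table's smallest positive
    relative abundance is flagged (it exceeds the data's scale) but still
    computed, as in the reported sensitivity analysis.
    """
    if dataset.table.unit != "relative":
        raise ValidationError("sweep expects a relative-abundance dataset")
    if target_feature not in dataset.table.feature_ids:
        raise ValidationError(f"target feature {target_feature!r} not in table")
    cs = [float(c) for c in pseudocounts]
    if any(c2 <= c1 for c1, c2 in zip(cs, cs[1:])):
        raise ValidationError("pseudocounts must be strictly increasing")
    positive_entries = dataset.table.values[dataset.table.values > 0]
    m = float(positive_entries.min()) if positive_entries.size else np.inf
    ids = dataset.table.sample_ids
    rows = []
    for c in cs:
        exceeds = c >= m
        if exceeds:
            logger.warning(
                "pseudocount %.3g is not below the smallest positive relative "
                "abundance %.3g; computed anyway", c, m
            )
        clr = clr_transform(add_pseudocount(dataset.table, c, "relative_space"))
        col = clr.feature_column(target_feature)
        a, b = dataset.labels.split(col, ids)
        res = mann_whitney_u(
            a, b, group_names=(dataset.labels.positive, dataset.labels.negative)
        )
        rows.append(
            SweepRow(
                pseudocount=c,
                statistic=res.statistic,
                p_value=res.p_value,
                exceeds_data_scale=exceeds,
            )
        )
    return SweepReport(rows=tuple(rows), target_feature=target_feature)


def filter_first_timepoint(
    metadata: pd.DataFrame,
    *,
    sample_col: str = "sample_id",
    subject_col: str = "subject",
    timepoint_col: str = "timepoint",
) -> list[str]:
    """Keep one sample per subject: the earliest timepoint.

    Ties on the minimal timepoint are broken by lexicographically smallest
    sample ID, so the selection is deterministic.
    """
    for col in (sample_col, subject_col, timepoint_col):
        if col not in metadata.columns:
            raise ValidationError(f"metadata lacks required column {col!r}")
    df = metadata[[sample_col, subject_col, timepoint_col]].copy()
    df[sample_col] = df[sample_col].astype(str)
    df = df.sort_values([subject_col, timepoint_col, sample_col], kind="stable")
    first = df.groupby(subject_col, sort=False).head(1)
    return first[sample_col].tolist()


def filter_observed_taxa(table: AbundanceTable) -> AbundanceTable:
    """Drop features with zero reads in every sample, preserving order."""
    observed = np.flatnonzero(table.values.sum(axis=0) > 0)
    keep = [table.feature_ids[j] for j in observed]
    logger.info(
        "filter_observed_taxa: kept %d of %d features", len(keep), table.n_features
    )
    return table.select_features(keep)


def remove_contaminants(
    table: AbundanceTable, contaminant_ids: Iterable[str]
) -> AbundanceTable:
    """Drop features flagged as contaminants; unknown IDs are logged, not fatal."""
    contaminants = set(contaminant_ids)
    unknown = contaminants - set(table.feature_ids)
    if unknown:
        logger.warning(
            "remove_contaminants: %d listed IDs not in table (e.g. %r)",
            len(unknown), sorted(unknown)[0],
        )
    keep = [f for f in table.feature_ids if f not in contaminants]
    if not keep:
        raise ValidationError("contaminant removal would drop every feature")
    logger.info(
        "remove_contaminants: dropped %d features, %d remain",
        table.n_features - len(keep), len(keep),
    )
    return table.select_features(keep)


def run_sparse_feature_reanalysis(
    table: AbundanceTable,
    labels: PhenotypeLabels,
    taxon_id: str,
    *,
    contaminant_ids: Iterable[str] = (),
    pseudocount_mode: Literal["relative_space", "count_space"] = "relative_space",
    pseudocount: Union[float, str] = "auto",
) -> ReanalysisReport:
    """The full sparse-taxon chain on a labeled abundance table.

    Stage order: contaminant removal -> relative abundances -> per-sample
    Shannon diversity (pre-pseudocount) -> Mann-Whitney of diversity vs
    phenotype -> Mann-Whitney of the taxon's raw relative abundance vs
    phenotype -> pseudocount (``auto`` resolves to the power-of-ten rule in
    relative space and to 1 in count space) -> CLR -> Pearson of the taxon's
    CLR vs diversity -> Mann-Whitney of the taxon's CLR vs phenotype.

    Labels are consumed only by the association steps, never by any
    transformation.
    """
    filtered = remove_contaminants(table, contaminant_ids)
    if taxon_id not in filtered.feature_ids:
        raise ValidationError(
            f"taxon {taxon_id!r} absent after contaminant removal"
        )
    rel = (
        to_relative_abundance(filtered) if filtered.unit == "counts" else filtered
    )
    ids = rel.sample_ids
    names = (labels.positive, labels.negative)

    shannon = np.array([shannon_diversity(row) for row in rel.values])
    div_pos, div_neg = labels.split(shannon, ids)
    if div_pos.size == 0 or div_neg.size == 0:
        raise ValidationError("both phenotype groups must be non-empty")
    diversity_vs_label = mann_whitney_u(div_pos, div_neg, group_names=names)

    raw = rel.feature_column(taxon_id)
    raw_vs_label = mann_whitney_u(*labels.split(raw, ids), group_names=names)

    if pseudocount_mode == "relative_space":
        c = default_pseudocount(rel) if pseudocount == "auto" else float(pseudocount)
        positive = add_pseudocount(rel, c, "relative_space")
    else:
        if filtered.unit != "counts":
            raise ValidationError("count_space pseudocount requires a counts table")
        c = 1.0 if pseudocount == "auto" else float(pseudocount)
        positive = add_pseudocount(filtered, c, "count_space")
    logger.info(
        "reanalysis: %d samples, %d features, pseudocount %.3g (%s)",
        rel.n_samples, rel.n_features, c, pseudocount_mode,
    )

    clr = clr_transform(positive)
    clr_taxon = clr.feature_column(taxon_id)
    clr_vs_diversity = pearson_r(clr_taxon, shannon)
    clr_vs_label = mann_whitney_u(*labels.split(clr_taxon, ids), group_names=names)

    return ReanalysisReport(
        diversity_vs_label=diversity_vs_label,
        raw_ra_vs_label=raw_vs_label,
        clr_vs_diversity=clr_vs_diversity,
        clr_vs_label=clr_vs_label,
        taxon_id=taxon_id,
        n_samples=rel.n_samples,
        n_features_after_filter=rel.n_features,
        pseudocount_used=c,
    )


def permutation_leakage_test(
    pipeline_fn: Callable[[AbundanceTable, PhenotypeLabels], float],
    table: AbundanceTable,
    labels: PhenotypeLabels,
    n_permutations: int = 99,
    seed: int = 0,
) -> LeakageAuditReport:
    """Label-permutation audit of an arbitrary scoring pipeline.

    The labels are shuffled *before* ``pipeline_fn`` runs, so every stage of
    the audited pipeline — normalization included — sees only permuted
    labels.  The empirical p uses the standard +1 correction:
    (1 + #{permuted >= observed}) / (1 + n_permutations).

    A small empirical p means the pipeline scores genuinely higher on the
    true labels.  On data where the labels are known to be independent of
    the features, that is evidence of leakage; on data with a real
    label-feature association it simply reflects the signal, so the verdict
    is advisory, never fatal.
    """
    if n_permutations < 19:
        raise ValidationError("need at least 19 permutations")
    if len(set(labels.assignments.values())) < 2:
        raise ValidationError("labels must contain two groups")
    rng = np.random.default_rng(seed)
    observed = float(pipeline_fn(table, labels))
    permuted = [
        float(pipeline_fn(table, labels.permuted(rng)))
        for _ in range(n_permutations)
    ]
    hits = sum(1 for s in permuted if s >= observed)
    p = (1 + hits) / (1 + n_permutations)
    return LeakageAuditReport(
        observed_score=observed,
        permuted_scores=tuple(permuted),
        empirical_p=p,
        n_permutations=n_permutations,
        verdict=(
            "leakage_suspected" if p <= LEAKAGE_ALPHA else "no_evidence_of_leakage"
        ),
    )
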