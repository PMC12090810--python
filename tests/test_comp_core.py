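"""Compositional core: normalization, pseudocounts, CLR, diversity identities."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from clrsparse import (
    AbundanceTable,
    PositiveCompositionTable,
    ValidationError,
    add_pseudocount,
    clr_transform,
    default_pseudocount,
    geometric_mean,
    shannon_diversity,
    summarize_samples,
    to_relative_abundance,
    weighted_geometric_mean,
)


def make_table(values, unit="counts"):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    return AbundanceTable(
        values=values,
        sample_ids=tuple(f"s{i}" for i in range(values.shape[0])),
        feature_ids=tuple(f"f{j}" for j in range(values.shape[1])),
        unit=unit,
    )


positive_rows = arrays(
    float,
    st.integers(2, 12),
    elements=st.floats(1e-6, 1e6, allow_nan=False, allow_infinity=False),
)


class TestToRelativeAbundance:
    @pytest.mark.parametrize(
        "row, expected",
        [
            ([2, 2, 4], [0.25, 0.25, 0.5]),
            ([1, 0, 0], [1, 0, 0]),
        ],
    )
    def test_rows_normalized(self, row, expected):
        rel = to_relative_abundance(make_table(row))
        assert rel.unit == "relative"
        np.testing.assert_allclose(rel.values[0], expected, atol=1e-12)

    def test_empty_sample_names_offender(self):
        table = make_table([[1, 2, 3], [0, 0, 0]])
        with pytest.raises(ValidationError, match="s1"):
            to_relative_abundance(table)

    def test_idempotent_on_relative(self):
        rel = to_relative_abundance(make_table([3, 1, 4, 1, 5]))
        again = to_relative_abundance(rel)
        np.testing.assert_allclose(again.values, rel.values)


class TestDefaultPseudocount:
    @pytest.mark.parametrize(
        "minimum, expected",
        [
            (3.2e-4, 1e-4),
            (1e-3, 1e-4),  # strict "below": a power of 10 maps one power down
            (3.2e-6, 1e-6),
            (0.05, 0.01),
        ],
    )
    def test_printed_anchors(self, minimum, expected):
        rel = to_relative_abundance(make_table([minimum, 1 - minimum]))
        # the row's smallest positive entry is exactly `minimum`
        assert default_pseudocount(rel) == pytest.approx(expected, rel=1e-12)

    def test_all_zero_table_rejected(self):
        table = make_table([[0, 0], [0, 0]])
        with pytest.raises(ValidationError):
            default_pseudocount(table)

    @given(
        st.floats(1e-8, 0.5, allow_nan=False, exclude_min=True),
    )
    def test_power_of_ten_strictly_below_minimum(self, m):
        rel = to_relative_abundance(make_table([m, 1.0]))
        c = default_pseudocount(rel)
        k = round(np.log10(c))
        assert c == pytest.approx(10.0 ** k, rel=1e-12)  # exact power of 10
        m_realized = rel.values[rel.values > 0].min()
        assert c < m_realized
        assert 10.0 * c >= m_realized * (1 - 1e-12)  # largest such power


class TestAddPseudocount:
    def test_relative_space_adds_without_renormalizing(self):
        rel = make_table([0, 0.5, 0.5], unit="relative")
        out = add_pseudocount(rel, 1e-6, "relative_space")
        np.testing.assert_allclose(out.values[0], [1e-6, 0.500001, 0.500001])

    def test_count_space_normalizes_after_shift(self):
        counts = make_table([0, 1, 3])
        out = add_pseudocount(counts, 1.0, "count_space")
        np.testing.assert_allclose(out.values[0], [1 / 7, 2 / 7, 4 / 7])

    @pytest.mark.parametrize("c", [0.0, -1e-6])
    def test_nonpositive_pseudocount_rejected(self, c):
        rel = make_table([0.5, 0.5], unit="relative")
        with pytest.raises(ValidationError):
            add_pseudocount(rel, c, "relative_space")

    def test_mode_unit_mismatch_rejected(self):
        counts = make_table([1, 2, 3])
        with pytest.raises(ValidationError):
            add_pseudocount(counts, 1e-6, "relative_space")
        rel = to_relative_abundance(counts)
        with pytest.raises(ValidationError):
            add_pseudocount(rel, 1, "count_space")


def positive_table(values, c=1e-6):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    return PositiveCompositionTable(
        values=values,
        sample_ids=tuple(f"s{i}" for i in range(values.shape[0])),
        feature_ids=tuple(f"f{j}" for j in range(values.shape[1])),
        pseudocount=c,
        pseudocount_mode="relative_space",
    )


class TestClr:
    @pytest.mark.parametrize(
        "row, expected",
        [
            ([0.5, 0.5], [0.0, 0.0]),
            ([np.e, 1.0], [0.5, -0.5]),
        ],
    )
    def test_known_rows(self, row, expected):
        clr = clr_transform(positive_table(row))
        np.testing.assert_allclose(clr.values[0], expected, atol=1e-12)

    def test_constant_feature_equals_log_ratio_to_geometric_mean(self):
        # the central mechanism: a pseudocount-valued feature maps to
        # ln(c) - ln(g_i), a pure function of the sample geometric mean
        c = 1e-6
        row = np.array([0.3, 0.2, 0.5, c])
        clr = clr_transform(positive_table(row, c))
        g = geometric_mean(row)
        assert clr.values[0, -1] == pytest.approx(np.log(c) - np.log(g), abs=1e-10)

    @given(positive_rows)
    def test_closure_rows_sum_to_zero(self, row):
        clr = clr_transform(positive_table(row))
        assert abs(clr.values.sum()) < 1e-8

    @given(positive_rows, st.floats(1e-6, 1e6))
    def test_scale_invariance(self, row, lam):
        base = clr_transform(positive_table(row)).values
        scaled = clr_transform(positive_table(lam * row)).values
        np.testing.assert_allclose(scaled, base, atol=1e-9)

    def test_nonpositive_entry_names_sample_and_feature(self):
        with pytest.raises(ValidationError, match="s0.*f1"):
            positive_table([0.5, 0.0, 0.5])

    def test_matches_reference_implementation(self):
        from skbio.stats.composition import clr as skbio_clr

        rng = np.random.default_rng(0)
        x = rng.uniform(0.01, 1.0, size=(20, 8))
        ours = clr_transform(positive_table(x)).values
        np.testing.assert_allclose(ours, skbio_clr(x), atol=1e-10)


class TestPerSampleScalars:
    @pytest.mark.parametrize(
        "row, expected",
        [
            ([0.25, 0.25, 0.25, 0.25], 0.25),
            ([4, 1], 2.0),
        ],
    )
    def test_geometric_mean_known_values(self, row, expected):
        assert geometric_mean(np.array(row, float)) == pytest.approx(expected)

    def test_geometric_mean_lowered_by_pseudocount_entry(self):
        base = np.array([0.4, 0.6])
        with_pc = np.array([1e-6, 0.4, 0.6])
        assert geometric_mean(with_pc) < geometric_mean(base)

    def test_geometric_mean_rejects_nonpositive(self):
        with pytest.raises(ValidationError):
            geometric_mean(np.array([0.0, 1.0]))

    @pytest.mark.parametrize(
        "row, expected",
        [
            ([0.25] * 4, np.log(4)),
            ([1.0, 0.0, 0.0], 0.0),
            ([0.5, 0.25, 0.25], 1.5 * np.log(2)),
        ],
    )
    def test_shannon_known_values(self, row, expected):
        assert shannon_diversity(np.array(row)) == pytest.approx(expected, abs=1e-12)

    def test_shannon_rejects_unnormalized_row(self):
        with pytest.raises(ValidationError):
            shannon_diversity(np.array([0.5, 0.6]))

    @pytest.mark.parametrize(
        "row, expected",
        [
            ([1.0], 1.0),
            ([0.2] * 5, 0.2),
        ],
    )
    def test_weighted_geometric_mean_known_values(self, row, expected):
        assert weighted_geometric_mean(np.array(row)) == pytest.approx(expected)

    def test_shannon_equals_neg_log_weighted_geometric_mean(self, rng):
        # the diversity / geometric-mean bridge, over 1000 random compositions
        for _ in range(1000):
            k = rng.integers(2, 30)
            p = rng.dirichlet(np.full(k, rng.uniform(0.1, 5.0)))
            h = shannon_diversity(p)
            wgm = weighted_geometric_mean(p)
            assert abs(h + np.log(wgm)) < 1e-10


def test_clr_of_zero_feature_monotone_in_pseudocount():
    # larger pseudocount -> larger CLR value at the originally-zero feature
    rel = make_table([0.0, 0.3, 0.7], unit="relative")
    grid = [10.0 ** k for k in range(-8, -1)]
    vals = [
        clr_transform(add_pseudocount(rel, c, "relative_space")).values[0, 0]
        for c in grid
    ]
    assert all(b > a for a, b in zip(vals, vals[1:]))


def test_summarize_samples_consistent(counterexample_dataset):
    rel = counterexample_dataset.table
    pos = add_pseudocount(rel, 1e-6, "relative_space")
    summaries = summarize_samples(rel, pos)
    assert len(summaries) == rel.n_samples
    s = summaries[0]
    assert s.shannon == pytest.approx(-np.log(s.weighted_geometric_mean), abs=1e-10)
    assert s.geometric_mean == pytest.approx(geometric_mean(pos.values[0]))


def test_table_validation_rejects_bad_inputs():
    with pytest.raises(ValidationError, match="duplicate"):
        AbundanceTable(
            values=np.ones((2, 2)),
            sample_ids=("a", "a"),
            feature_ids=("f0", "f1"),
            unit="counts",
        )
    with pytest.raises(ValidationError, match="negative"):
        make_table([[1, -1]])
    with pytest.raises(ValidationError, match="sums to"):
        make_table([[0.5, 0.6]], unit="relative")
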