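"""Probe collapsing, QC filters and interval assignment boundaries."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import devcoex as dx
from devcoex.preprocess import DEFAULT_SCHEME, age_to_years


def _probe_matrix():
    return pd.DataFrame(
        {
            "s1": [7.0, 6.0, 5.0, 9.0],
            "s2": [7.2, 6.4, 5.2, 9.2],
        },
        index=["p1", "p2", "p3", "p4"],
    )


class TestCollapseProbes:
    def test_max_mean_probe_represents_multiprobe_gene(self):
        # p1 mean 7.1 beats p2 mean 6.2 for gene A
        out = dx.collapse_probes(_probe_matrix(), {"p1": "A", "p2": "A", "p4": "B"})
        assert list(out.index) == ["A", "B"]
        np.testing.assert_array_equal(out.loc["A"], _probe_matrix().loc["p1"])

    def test_single_probe_gene_passthrough(self):
        out = dx.collapse_probes(_probe_matrix(), {"p3": "C"})
        np.testing.assert_array_equal(out.loc["C"], _probe_matrix().loc["p3"])

    def test_unmapped_probe_absent_from_output(self):
        out = dx.collapse_probes(_probe_matrix(), {"p1": "A"})
        assert out.shape[0] == 1

    def test_empty_mapping_errors(self):
        with pytest.raises(ValueError):
            dx.collapse_probes(_probe_matrix(), {})

    def test_gene_count_equals_distinct_mapped_genes(self):
        mapping = {"p1": "A", "p2": "A", "p3": "B", "p4": "C"}
        out = dx.collapse_probes(_probe_matrix(), mapping)
        assert out.shape[0] == len(set(mapping.values()))


class TestFilterSamples:
    def _samples(self, rins):
        return pd.DataFrame(
            {"RIN": rins}, index=[f"s{i}" for i in range(len(rins))]
        )

    def test_rin_boundary_is_inclusive(self):
        kept = dx.filter_samples(self._samples([8.0, 7.9, 9.5]), dx.FilterConfig())
        assert list(kept.index) == ["s0", "s2"]

    def test_empty_table_passes_through(self):
        kept = dx.filter_samples(self._samples([]), dx.FilterConfig())
        assert len(kept) == 0

    def test_missing_rin_errors(self):
        with pytest.raises(ValueError, match="RIN"):
            dx.filter_samples(self._samples([8.0, np.nan]), dx.FilterConfig())


class TestAssignIntervals:
    def _table(self, pairs):
        return pd.DataFrame(
            {
                "age_value": [v for v, _ in pairs],
                "age_unit": [u for _, u in pairs],
            },
            index=[f"s{i}" for i in range(len(pairs))],
        )

    @pytest.mark.parametrize(
        "age,unit,expected",
        [
            (10.0, "weeks_postconception", "I-1"),  # earliest prenatal age
            (37.9, "weeks_postconception", "I-1"),
            (38.0, "weeks_postconception", "I-2"),  # birth opens I-2
            (5.0, "years", "I-2"),
            (6.0, "years", "I-3"),  # >= 6 is I-3
            (39.99, "years", "I-3"),
            (40.0, "years", "I-4"),  # >= 40 is I-4
            (95.0, "years", "I-4"),
        ],
    )
    def test_boundaries(self, age, unit, expected):
        out = dx.assign_intervals(self._table([(age, unit)]), DEFAULT_SCHEME)
        assert out.iloc[0] == expected

    def test_pre_scheme_age_flagged_not_dropped(self):
        out = dx.assign_intervals(
            self._table([(8.0, "weeks_postconception")]), DEFAULT_SCHEME
        )
        assert len(out) == 1 and pd.isna(out.iloc[0])

    def test_negative_age_errors(self):
        with pytest.raises(ValueError, match="negative"):
            dx.assign_intervals(self._table([(-1.0, "years")]), DEFAULT_SCHEME)

    def test_partition_of_in_scheme_cohort(self):
        rng = np.random.default_rng(0)
        ages = np.concatenate([rng.uniform(10, 38, 20), rng.uniform(0, 90, 40)])
        units = ["weeks_postconception"] * 20 + ["years"] * 40
        out = dx.assign_intervals(self._table(list(zip(ages, units))), DEFAULT_SCHEME)
        assert out.notna().all()


class TestIntervalScheme:
    def test_overlapping_intervals_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            dx.IntervalScheme((("a", 0, 5), ("b", 4, 10)))

    def test_inverted_bounds_rejected(self):
        with pytest.raises(ValueError):
            dx.IntervalScheme((("a", 5, 5),))

    def test_roundtrip_dict(self):
        scheme = dx.IntervalScheme.from_dict(DEFAULT_SCHEME.to_dict())
        assert scheme == DEFAULT_SCHEME

    def test_unit_conversion_birth_is_zero(self):
        assert age_to_years(38.0, "weeks_postconception") == 0.0
        assert age_to_years(12.5, "years") == 12.5


class TestFilterGenes:
    def _study(self):
        # 2 regions x 2 intervals, 2 samples per cell
        samples = pd.DataFrame(
            {
                "age_value": [1, 1, 10, 10, 1, 1, 10, 10],
                "age_unit": ["years"] * 8,
                "region": ["A", "A", "A", "A", "B", "B", "B", "B"],
            },
            index=[f"s{i}" for i in range(8)],
        )
        scheme = dx.IntervalScheme((("young", 0, 6), ("old", 6, 100)))
        return samples, scheme

    def test_group_mean_boundary_inclusive(self):
        samples, scheme = self._study()
        # gene g1: every group mean exactly 6.0 -> kept; g2 has one 5.99 group
        matrix = pd.DataFrame(
            [[5.9, 6.1] * 4, [5.98, 6.0] * 4, [9.0] * 8],
            index=["g1", "g2", "g3"],
            columns=samples.index,
        )
        out = dx.filter_genes(matrix, samples, dx.FilterConfig(), scheme)
        assert list(out.index) == ["g1", "g3"]

    def test_identity_when_everything_expressed(self):
        samples, scheme = self._study()
        matrix = pd.DataFrame(
            np.full((4, 8), 7.5), index=list("wxyz"), columns=samples.index
        )
        out = dx.filter_genes(matrix, samples, dx.FilterConfig(), scheme)
        pd.testing.assert_frame_equal(out, matrix)

    def test_idempotent(self):
        samples, scheme = self._study()
        rng = np.random.default_rng(1)
        matrix = pd.DataFrame(
            rng.uniform(5, 9, (20, 8)),
            index=[f"g{i}" for i in range(20)],
            columns=samples.index,
        )
        once = dx.filter_genes(matrix, samples, dx.FilterConfig(), scheme)
        twice = dx.filter_genes(once, samples, dx.FilterConfig(), scheme)
        pd.testing.assert_frame_equal(once, twice)

    def test_empty_group_errors_naming_the_group(self):
        samples, scheme = self._study()
        samples = samples.iloc[:6]  # region B loses its 'old' cell
        matrix = pd.DataFrame(
            np.full((2, 6), 7.0), index=["g1", "g2"], columns=samples.index
        )
        with pytest.raises(ValueError, match="region='B', interval='old'"):
            dx.filter_genes(matrix, samples, dx.FilterConfig(), scheme)

    def test_per_sample_min_mode_is_stricter(self):
        samples, scheme = self._study()
        matrix = pd.DataFrame(
            [[5.9, 6.1] * 4, [7.0] * 8], index=["g1", "g2"], columns=samples.index
        )
        strict = dx.filter_genes(
            matrix, samples, dx.FilterConfig(summary="per_sample_min"), scheme
        )
        assert list(strict.index) == ["g2"]

    def test_row_order_preserved(self):
        samples, scheme = self._study()
        rng = np.random.default_rng(2)
        matrix = pd.DataFrame(
            rng.uniform(6.5, 9, (10, 8)),
            index=[f"g{i}" for i in (5, 3, 8, 1, 9, 0, 2, 7, 4, 6)],
            columns=samples.index,
        )
        out = dx.filter_genes(matrix, samples, dx.FilterConfig(), scheme)
        assert list(out.index) == list(matrix.index)
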