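"""Collection model: grid intersection, trim/mask, summaries, grouping."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import proxispec as px
from proxispec.errors import (
    EmptyRangeError,
    IncompatibleGridsError,
    InsufficientSamplesError,
    KeyCollisionError,
    UnknownNameError,
    UsageError,
)


def _spec(sid, lo, hi, value=0.3):
    wl = np.arange(lo, hi + 1, dtype=float)
    return px.Spectrum(sid, wl, np.full(wl.size, value))


class TestBuildCollection:
    def test_identical_grids_identity(self):
        c = px.build_collection([_spec("a", 400, 500), _spec("b", 400, 500)])
        assert np.array_equal(c.grid, np.arange(400, 501))

    def test_intersection_of_grids(self):
        c = px.build_collection([_spec("a", 339, 1100), _spec("b", 400, 1000)])
        assert c.grid[0] == 400 and c.grid[-1] == 1000

    def test_empty_intersection_error_lists_ranges(self):
        with pytest.raises(IncompatibleGridsError, match="400–700"):
            px.build_collection([_spec("a", 400, 700), _spec("b", 800, 1000)])

    def test_duplicate_ids_error(self):
        with pytest.raises(KeyCollisionError):
            px.build_collection([_spec("a", 400, 500), _spec("a", 400, 500)])

    def test_values_never_interpolated(self):
        # the narrower sample keeps its own measured values on shared points
        a = px.Spectrum("a", np.arange(400.0, 411.0), np.linspace(0.1, 0.2, 11))
        b = px.Spectrum("b", np.arange(405.0, 416.0), np.linspace(0.5, 0.6, 11))
        c = px.build_collection([a, b])
        assert np.array_equal(c.grid, np.arange(405, 411))
        assert np.array_equal(c.values[0], a.reflectance[5:])
        assert np.array_equal(c.values[1], b.reflectance[:6])


class TestTrimMask:
    @pytest.fixture
    def collection(self):
        return px.build_collection([_spec("a", 339, 1100), _spec("b", 339, 1100)])

    def test_documented_analysis_trim(self, collection):
        t = collection.trim(*px.ANALYSIS_RANGE_NM)
        assert t.grid[0] == 400 and t.grid[-1] == 1000

    def test_trim_full_range_is_identity(self, collection):
        t = collection.trim(339, 1100)
        assert np.array_equal(t.grid, collection.grid)
        assert np.array_equal(t.values, collection.values)

    def test_closed_interval_boundaries(self):
        wl = np.array([399.0, 400.0, 1000.0, 1001.0])
        c = px.build_collection([px.Spectrum("a", wl, np.full(4, 0.2))])
        t = c.trim(400, 1000)
        assert np.array_equal(t.grid, [400, 1000])

    def test_trim_empty_result_error(self, collection):
        with pytest.raises(EmptyRangeError):
            collection.trim(2000, 3000)

    def test_trim_bad_interval(self, collection):
        with pytest.raises(UsageError):
            collection.trim(800, 400)

    def test_mask_nothing_is_identity(self, collection):
        m = collection.mask([])
        assert np.array_equal(m.grid, collection.grid)

    def test_mask_noisy_edges(self):
        c = px.build_collection([_spec("a", 300, 1200)])
        m = c.mask([[300, 399], [1001, 1200]])
        assert m.grid[0] == 400 and m.grid[-1] == 1000

    def test_overlapping_masks_union(self, collection):
        m1 = collection.mask([[350, 500], [450, 600]])
        m2 = collection.mask([[350, 600]])
        assert np.array_equal(m1.grid, m2.grid)

    def test_mask_everything_error(self, collection):
        with pytest.raises(EmptyRangeError):
            collection.mask([[0, 2000]])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        lo=st.integers(min_value=350, max_value=700),
        span=st.integers(min_value=1, max_value=300),
    )
    def test_trim_equals_mask_of_complement(self, lo, span):
        hi = lo + span
        c = px.build_collection([_spec("a", 339, 1100, 0.4)])
        trimmed = c.trim(lo, hi)
        masked = c.mask([[c.grid[0], lo - 1], [hi + 1, c.grid[-1]]])
        assert np.array_equal(trimmed.grid, masked.grid)
        assert np.array_equal(trimmed.values, masked.values)

    def test_trim_preserves_retained_values(self, trial):
        collection, _, _ = trial
        t = collection.trim(400, 1000)
        keep = (collection.grid >= 400) & (collection.grid <= 1000)
        assert np.array_equal(t.values, collection.values[:, keep])


class TestSummaries:
    def test_identical_samples_mean_and_zero_variance(self):
        c = px.build_collection([_spec("a", 400, 500, 0.3), _spec("b", 400, 500, 0.3)])
        assert np.allclose(c.summarize("mean").reflectance, 0.3)
        assert np.allclose(c.summarize("variance").reflectance, 0.0)

    def test_hand_computed_mean_and_variance(self):
        c = px.build_collection([_spec("a", 400, 500, 0.2), _spec("b", 400, 500, 0.4)])
        assert np.allclose(c.summarize("mean").reflectance, 0.3)
        # unbiased: ((0.1)^2 + (0.1)^2) / (2-1) = 0.02
        assert np.allclose(c.summarize("variance").reflectance, 0.02)

    @pytest.mark.parametrize("stat,fn", [
        ("mean", lambda m: m.mean(axis=0)),
        ("median", lambda m: np.median(m, axis=0)),
        ("variance", lambda m: m.var(axis=0, ddof=1)),
    ])
    def test_matches_brute_force_per_column(self, trial, stat, fn):
        collection, _, _ = trial
        got = collection.summarize(stat).reflectance
        assert np.allclose(got, fn(collection.values), atol=1e-12, rtol=0)

    def test_variance_needs_two_samples(self):
        c = px.build_collection([_spec("a", 400, 500)])
        with pytest.raises(InsufficientSamplesError):
            c.summarize("variance")


class TestGrouping:
    def test_two_treatment_partition(self, trial):
        collection, _, _ = trial
        groups = collection.group_by_attribute("treatment")
        assert set(groups) == {"140", "180"}
        assert all(g.n_samples == 20 for g in groups.values())

    def test_single_level_group_is_input(self):
        collection, _, _ = px.generate_trial(px.TrialDesign(treatments=("140",), seed=1))
        groups = collection.group_by_attribute("treatment")
        assert list(groups) == ["140"]
        assert groups["140"].sample_ids == collection.sample_ids

    def test_union_of_groups_is_sample_set(self, trial_with_outlier):
        collection, _, _ = trial_with_outlier
        groups = collection.group_by_attribute("treatment")
        union = [sid for g in groups.values() for sid in g.sample_ids]
        assert sorted(union) == sorted(collection.sample_ids)
        assert "unassigned" in groups  # the dry-leaf control has no treatment

    def test_continuous_attribute_rejected(self, trial):
        collection, attributes, _ = trial
        attributes.types["fake"] = "continuous"
        attributes.data["fake"] = 1.0
        try:
            with pytest.raises(UsageError):
                collection.group_by_attribute("fake")
        finally:
            del attributes.types["fake"], attributes.data["fake"]

    def test_unknown_attribute_rejected(self, trial):
        collection, _, _ = trial
        with pytest.raises(UnknownNameError):
            collection.group_by_attribute("no_such_trait")


class TestRemoveSamples:
    def test_remove_nothing_identity(self, trial):
        collection, _, _ = trial
        out = collection.remove_samples([])
        assert out.sample_ids == collection.sample_ids

    def test_remove_one(self, trial):
        collection, _, _ = trial
        out = collection.remove_samples([collection.sample_ids[0]])
        assert out.n_samples == collection.n_samples - 1
        assert np.array_equal(out.grid, collection.grid)

    def test_remove_all_error(self):
        c = px.build_collection([_spec("a", 400, 500)])
        with pytest.raises(InsufficientSamplesError):
            c.remove_samples(["a"])

    def test_remove_unknown_error(self, trial):
        collection, _, _ = trial
        with pytest.raises(UnknownNameError):
            collection.remove_samples(["nope"])
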