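"""Threshold selection, Z-standardization, tag combination, purging."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq
from scipy.stats import norm

import poolfit as pf
from poolfit import tagstats
from poolfit.errors import ConsistencyError, PoolfitError, StandardizationError


class TestThresholdFpr:
    def test_enumerated_example(self):
        # oracle: enumerate the fraction strictly above every candidate
        a = np.arange(1, 101, dtype=float)
        fracs = {t: (a > t).mean() for t in a}
        expected = min(t for t, f in fracs.items() if f <= 0.05)
        assert expected == 95.0
        assert tagstats.select_threshold_fpr(a, 0.05) == 95.0

    def test_constant_values(self):
        assert tagstats.select_threshold_fpr(np.full(30, 7.0)) == 7.0

    def test_target_zero_gives_max(self):
        a = np.arange(1, 51, dtype=float)
        assert tagstats.select_threshold_fpr(a, 0.0) == 50.0

    def test_too_few_values_rejected(self):
        with pytest.raises(PoolfitError):
            tagstats.select_threshold_fpr(np.arange(10.0))
        with pytest.raises(PoolfitError):
            tagstats.select_threshold_fpr(np.array([]))

    @given(st.integers(min_value=0, max_value=10**6))
    @settings(max_examples=25, deadline=None)
    def test_achieved_fpr_bounded(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=100)
        t = tagstats.select_threshold_fpr(a, 0.05)
        assert (a > t).mean() <= 0.05


class TestThresholdBimodal:
    def test_well_separated_mixture(self):
        rng = np.random.default_rng(1)
        a = np.concatenate([rng.normal(6, 0.5, 5000), rng.normal(12, 1.0, 5000)])
        thr = tagstats.select_threshold_bimodal(a)
        assert 7.5 <= thr <= 9.5
        # oracle: equal-posterior crossing of the true densities
        exact = brentq(
            lambda x: norm.pdf(x, 6, 0.5) - norm.pdf(x, 12, 1.0), 6, 12
        )
        assert abs(thr - exact) < 1.0

    def test_symmetric_mixture_splits_at_center(self):
        rng = np.random.default_rng(2)
        a = np.concatenate([rng.normal(7, 0.8, 4000), rng.normal(11, 0.8, 4000)])
        thr = tagstats.select_threshold_bimodal(a)
        assert abs(thr - 9.0) < 0.2

    def test_unimodal_falls_back_to_percentile(self):
        rng = np.random.default_rng(3)
        a = rng.normal(10, 1.0, 3000)
        with pytest.warns(UserWarning):
            thr = tagstats.select_threshold_bimodal(a)
        assert thr == pytest.approx(np.percentile(a, 1.0), abs=0.3)

    def test_too_few_values_rejected(self):
        with pytest.raises(PoolfitError):
            tagstats.select_threshold_bimodal(np.arange(50.0))


class TestZscore:
    def test_hand_computed_triplet(self):
        z = tagstats.zscore_per_tag_array([1.0, 2.0, 3.0])
        np.testing.assert_allclose(z, [-1.224744871, 0.0, 1.224744871], atol=1e-8)

    def test_idempotent_on_standardized_input(self):
        v = np.array([-1.5, -0.5, 0.5, 1.5]) / np.std([-1.5, -0.5, 0.5, 1.5])
        np.testing.assert_allclose(tagstats.zscore_per_tag_array(v), v, atol=1e-12)

    def test_pair_with_unit_population_sd(self):
        np.testing.assert_allclose(
            tagstats.zscore_per_tag_array([-1.0, 1.0]), [-1.0, 1.0], atol=1e-12
        )

    def test_constant_input_rejected(self):
        with pytest.raises(StandardizationError):
            tagstats.zscore_per_tag_array([2.0, 2.0, 2.0])

    @given(st.integers(min_value=0, max_value=10**6))
    @settings(max_examples=25, deadline=None)
    def test_population_moments_exact(self, seed):
        rng = np.random.default_rng(seed)
        z = tagstats.zscore_per_tag_array(rng.normal(3, 2, 50))
        assert abs(z.mean()) < 1e-9
        assert abs(z.std() - 1.0) < 1e-9


class TestCombineAndAverage:
    @pytest.mark.parametrize(
        "up,dn,expected",
        [(-2.0, -1.0, -1.5), (-2.0, None, -2.0), (None, None, float("nan"))],
    )
    def test_combine_tags(self, up, dn, expected):
        got = tagstats.combine_tags(up, dn)
        if np.isnan(expected):
            assert np.isnan(got)
        else:
            assert got == expected

    @pytest.mark.parametrize(
        "cells,expected",
        [
            ([1.0, 1.0, 1.0, 1.0], 1.0),
            ([2.0, float("nan"), 0.0], 1.0),
            ([], float("nan")),
        ],
    )
    def test_average_replicates(self, cells, expected):
        got = tagstats.average_replicates(cells)
        if np.isnan(expected):
            assert np.isnan(got)
        else:
            assert got == expected


def spot_frame(frac_significant: dict) -> pd.DataFrame:
    """10 spots per (strain, tag), the given fraction marked significant."""
    rows = []
    for (strain, kind), frac in frac_significant.items():
        n_sig = int(round(10 * frac))
        for i in range(10):
            rows.append(
                {
                    "strain_id": strain,
                    "tag_kind": kind,
                    "significant": i < n_sig,
                }
            )
    return pd.DataFrame(rows)


class TestDropSparseTags:
    def test_strict_inequality_at_forty_percent(self):
        spots = spot_frame({("s1", "UP"): 0.3, ("s2", "UP"): 0.4, ("s3", "UP"): 1.0})
        kept = tagstats.drop_sparse_tags(spots)
        kept_tags = set(zip(kept["strain_id"], kept["tag_kind"]))
        assert kept_tags == {("s2", "UP"), ("s3", "UP")}

    def test_monotone_in_min_fraction(self):
        rng = np.random.default_rng(0)
        spots = spot_frame(
            {(f"s{i}", k): rng.integers(0, 11) / 10 for i in range(20) for k in ("UP", "DN")}
        )
        prev = None
        for frac in (0.2, 0.4, 0.6, 0.8):
            kept = set(
                zip(*tagstats.drop_sparse_tags(spots, frac)[["strain_id", "tag_kind"]].T.values)
            )
            if prev is not None:
                assert kept <= prev
            prev = kept


class TestPurgeFalseBarcodes:
    def make_key(self):
        return pd.DataFrame(
            {
                "strain_id": ["s1", "s2", "s3", "s4", "s5"],
                "gene": list("abcde"),
                "in_pool": [True, True, True, False, False],
            }
        )

    def test_out_of_pool_rows_removed(self):
        matrix = pd.DataFrame(np.ones((5, 2)), index=["s1", "s2", "s3", "s4", "s5"])
        out = tagstats.purge_false_barcodes(matrix, self.make_key())
        assert list(out.index) == ["s1", "s2", "s3"]

    def test_all_in_pool_unchanged(self):
        matrix = pd.DataFrame(np.ones((3, 2)), index=["s1", "s2", "s3"])
        out = tagstats.purge_false_barcodes(matrix, self.make_key())
        pd.testing.assert_frame_equal(out, matrix)

    def test_unknown_strain_rejected(self):
        matrix = pd.DataFrame(np.ones((2, 2)), index=["s1", "sX"])
        with pytest.raises(ConsistencyError, match="sX"):
            tagstats.purge_false_barcodes(matrix, self.make_key())


class TestSimulatedRunInvariants:
    def test_z_moments_per_array_and_tag(self, small_matrix):
        _, tag_matrix = small_matrix
        spots = tag_matrix.spots
        groups = spots[spots["significant"] & spots["in_pool"]].groupby(
            ["array_id", "tag_kind"]
        )
        assert groups.ngroups == 12  # 6 arrays x 2 tag kinds
        for _, sub in groups:
            assert abs(sub["z"].mean()) < 1e-9
            assert abs(sub["z"].std(ddof=0) - 1.0) < 1e-9

    def test_false_barcode_leakage_bounded(self, small_matrix):
        _, tag_matrix = small_matrix
        fb = tag_matrix.prefilter_spots.query("~in_pool")
        assert fb["significant"].mean() <= 0.06

    def test_matrix_has_no_false_barcode_rows(self, small_matrix, small_experiment):
        matrix, _ = small_matrix
        out_of_pool = set(
            small_experiment.truth.loc[~small_experiment.truth["in_pool"], "strain_id"]
        )
        assert not (set(matrix.index) & out_of_pool)

    def test_spot_order_does_not_change_results(self, small_experiment):
        from tests.conftest import make_key

        key = make_key(small_experiment.truth)
        normalized = pf.normalize.normalize_all(small_experiment.scans, key=key)
        m1, _ = tagstats.build_fitness_matrix(normalized, key)
        shuffled = {
            day: df.sample(frac=1.0, random_state=99).reset_index(drop=True)
            for day, df in normalized.items()
        }
        m2, _ = tagstats.build_fitness_matrix(shuffled, key)
        pd.testing.assert_frame_equal(m1, m2)
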