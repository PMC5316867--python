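"""Label-swap combining, batch correction, imputation and the outlier test."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pwaskit as pk
from pwaskit.simulate import ALT_HEAVY, REF_HEAVY, PulldownPair


def _pair(fwd, rev, snp="snp_x", intensity=1e7):
    """Build a pair from stored heavy/light log-ratios (fwd=REF_HEAVY)."""
    ids = [f"p{i}" for i in range(len(fwd))]
    reps = tuple(
        pd.DataFrame(
            {
                "protein_id": ids,
                "log2_ratio": vals,
                "intensity": intensity,
                "orientation": orientation,
            }
        )
        for vals, orientation in ((fwd, REF_HEAVY), (rev, ALT_HEAVY))
    )
    return PulldownPair(snp, "G", "A", reps)


class TestCombineLabelSwap:
    def test_symmetric_swap_cancels(self):
        # Alt-heavy replicate measuring the same Alt/Ref ratio cancels exactly.
        out = pk.combine_label_swap(_pair([1.0], [1.0]))
        assert out["log2fc_ref_over_alt"].iloc[0] == pytest.approx(0.0)

    def test_consistent_preference_is_preserved(self):
        out = pk.combine_label_swap(_pair([1.0], [-1.0]))
        assert out["log2fc_ref_over_alt"].iloc[0] == pytest.approx(1.0)

    def test_single_replicate_value_carried_and_flagged(self):
        out = pk.combine_label_swap(_pair([2.0], [np.nan]))
        row = out.iloc[0]
        assert row["log2fc_ref_over_alt"] == pytest.approx(2.0)
        assert row["single_replicate"] and row["n_observed"] == 1

    def test_same_orientation_is_a_bookkeeping_fault(self):
        pair = _pair([1.0], [1.0])
        bad = PulldownPair(
            pair.snp_id, "G", "A",
            (pair.replicates[0], pair.replicates[0].copy()),
        )
        with pytest.raises(ValueError, match="orientation"):
            pk.combine_label_swap(bad)

    def test_replicate_storage_order_is_irrelevant(self):
        rng = np.random.default_rng(0)
        pair = _pair(rng.normal(size=20), rng.normal(size=20))
        flipped = PulldownPair(
            pair.snp_id, "G", "A", (pair.replicates[1], pair.replicates[0])
        )
        pd.testing.assert_frame_equal(
            pk.combine_label_swap(pair), pk.combine_label_swap(flipped)
        )

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.lists(st.floats(-5, 5), min_size=3, max_size=30), st.integers(0, 2**31 - 1))
    def test_allele_swap_flips_preference_but_not_magnitude(self, fwd, seed):
        """Exchanging Ref and Alt (ratios negated under fixed labels, or
        labels flipped under fixed ratios) flips the sign of every combined
        fold change and preserves its magnitude and p-value."""
        rng = np.random.default_rng(seed)
        rev = list(rng.normal(size=len(fwd)))
        pair = _pair(fwd, rev)
        a = pk.combine_label_swap(pair)["log2fc_ref_over_alt"]
        negated = _pair([-v for v in fwd], [-v for v in rev])
        b = pk.combine_label_swap(negated)["log2fc_ref_over_alt"]
        relabelled = _pair(rev, fwd)  # same stored ratios, labels exchanged
        c = pk.combine_label_swap(relabelled)["log2fc_ref_over_alt"]
        for flipped in (b, c):
            np.testing.assert_allclose(a.abs(), flipped.abs(), atol=1e-12)
            np.testing.assert_allclose(a, -flipped, atol=1e-12)
        if len(set(map(float, a.dropna()))) > 2:
            pa = pk.significance_outlier_test(a, mode="A")
            pb = pk.significance_outlier_test(b, mode="A")
            np.testing.assert_allclose(pa, pb, atol=1e-9)


class TestSignificanceOutlierTest:
    def test_median_point_has_p_one(self):
        x = [-2.0, -1.0, 0.0, 1.0, 2.0]
        p = pk.significance_outlier_test(x, mode="A")
        assert p[2] == pytest.approx(1.0)

    def test_one_sigma_percentile_point_has_standard_normal_tail(self):
        # On the grid 0.00..100.00 the 84.13th percentile is itself a point,
        # so its robust z is exactly 1 and p = erfc(1/sqrt(2)).
        x = np.arange(10001) / 100.0
        p = pk.significance_outlier_test(x, mode="A")
        idx = int(round(84.13 * 100))
        assert x[idx] == pytest.approx(84.13)
        assert p[idx] == pytest.approx(math.erfc(1 / math.sqrt(2)), abs=1e-6)
        assert p[idx] == pytest.approx(0.3173, abs=1e-3)

    def test_null_pvalues_are_uniform(self):
        from scipy.stats import kstest

        rng = np.random.default_rng(42)
        x = rng.normal(size=500)
        p = pk.significance_outlier_test(x, mode="A")
        assert kstest(p, "uniform").statistic < 0.08

    def test_mode_b_single_bin_equals_mode_a_exactly(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=120)
        li = rng.normal(7, 1, size=120)
        pa = pk.significance_outlier_test(x, li, mode="A")
        pb = pk.significance_outlier_test(x, li, mode="B", min_bin_size=300)
        np.testing.assert_array_equal(pa, pb)

    def test_mode_b_bins_by_intensity(self):
        rng = np.random.default_rng(2)
        # low-intensity half is noisy, high-intensity half is tight
        x = np.concatenate([rng.normal(0, 2, 300), rng.normal(0, 0.2, 300)])
        li = np.concatenate([np.full(300, 5.0), np.full(300, 9.0)])
        pb = pk.significance_outlier_test(x, li, mode="B", min_bin_size=300)
        x_out = x.copy()
        x_out[550] = 1.5  # 7.5 sigma within its bin, < 1 sigma globally
        pb = pk.significance_outlier_test(x_out, li, mode="B", min_bin_size=300)
        pa = pk.significance_outlier_test(x_out, li, mode="A")
        assert pb[550] < 1e-6 < pa[550]

    def test_zero_spread_names_degenerate_side(self):
        x = [0.0] * 10 + [1.0]
        with pytest.raises(ValueError, match="right"):
            pk.significance_outlier_test(x, mode="A")
        with pytest.raises(ValueError, match="left"):
            pk.significance_outlier_test([-v for v in x], mode="A")

    def test_monotone_in_distance_from_median_within_bin(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=200)
        p = pk.significance_outlier_test(x, mode="A")
        r0 = np.percentile(x, 50)
        order = np.argsort(np.abs(x - r0))
        upper = x >= r0
        for side in (upper, ~upper):
            d = np.abs(x[side] - r0)
            idx = np.argsort(d)
            assert (np.diff(p[side][idx]) <= 1e-12).all()

    def test_nan_ratios_get_nan_pvalues(self):
        x = np.array([0.0, 1.0, np.nan, -1.0, 0.5])
        p = pk.significance_outlier_test(x, mode="A")
        assert np.isnan(p[2]) and np.isfinite(p[[0, 1, 3, 4]]).all()


class TestCorrectBatch:
    def test_single_batch_is_identity(self):
        m = pd.DataFrame(np.random.default_rng(0).normal(size=(20, 4)))
        out, flags = pk.correct_batch(m, ["b"] * 4)
        pd.testing.assert_frame_equal(out, m)
        assert not flags.any()

    def test_pure_location_shift_is_removed(self):
        rng = np.random.default_rng(1)
        base = np.tile(rng.normal(size=(30, 1)), (1, 6))
        m = pd.DataFrame(base)
        m.iloc[:, 3:] += 0.9
        out, _ = pk.correct_batch(m, ["a"] * 3 + ["b"] * 3)
        gap = out.iloc[:, :3].mean(axis=1) - out.iloc[:, 3:].mean(axis=1)
        assert np.abs(gap).max() < 1e-8

    def test_known_offsets_variance_reduction(self):
        """Between-batch variance of protein means drops to <= 5% of input."""
        rng = np.random.default_rng(2)
        n, per = 300, 10
        batches = ["a"] * per + ["b"] * per
        m = pd.DataFrame(rng.normal(0, 0.2, size=(n, 2 * per)))
        m.iloc[:, per:] += 2.0

        def between_var(df):
            # per-protein variance across the two batch means, averaged
            batch_means = np.stack(
                [df.iloc[:, :per].mean(axis=1), df.iloc[:, per:].mean(axis=1)]
            )
            return float(np.var(batch_means, axis=0, ddof=1).mean())

        out, _ = pk.correct_batch(m, batches)
        assert between_var(out) <= 0.05 * between_var(m)

    def test_matches_reference_combat(self):
        """Agrees with scanpy's parametric ComBat on a complete matrix."""
        anndata = pytest.importorskip("anndata")
        sc = pytest.importorskip("scanpy")
        rng = np.random.default_rng(3)
        batches = ["a"] * 6 + ["b"] * 5 + ["c"] * 7
        m = pd.DataFrame(rng.normal(0, 0.5, size=(150, 18)))
        for label, shift, scale in (("b", 0.6, 1.4), ("c", -0.4, 0.7)):
            cols = [i for i, b in enumerate(batches) if b == label]
            m.iloc[:, cols] = m.iloc[:, cols] * scale + shift
        out, _ = pk.correct_batch(m, batches)
        ad = anndata.AnnData(X=m.T.to_numpy())
        ad.obs["batch"] = batches
        sc.pp.combat(ad, key="batch")
        np.testing.assert_allclose(out.to_numpy(), ad.X.T, atol=5e-3)

    def test_sparse_rows_passed_through_and_flagged(self):
        rng = np.random.default_rng(4)
        m = pd.DataFrame(rng.normal(size=(10, 6)))
        m.iloc[0, 3:] = np.nan  # row 0 has 0 observed values in batch b
        m.iloc[1, 4:] = np.nan  # row 1 has 1 observed value in batch b
        out, flags = pk.correct_batch(m, ["a"] * 3 + ["b"] * 3)
        assert flags.iloc[0] and flags.iloc[1] and not flags.iloc[2:].any()
        pd.testing.assert_series_equal(out.iloc[0], m.iloc[0], check_names=False)
        pd.testing.assert_series_equal(out.iloc[1], m.iloc[1], check_names=False)

    def test_batch_vector_length_mismatch_rejected(self):
        m = pd.DataFrame(np.zeros((5, 4)))
        with pytest.raises(ValueError, match="length"):
            pk.correct_batch(m, ["a", "b"])


class TestImputeMissing:
    def test_no_missing_is_identity_with_empty_mask(self):
        m = pd.DataFrame(np.random.default_rng(0).normal(size=(30, 3)))
        filled, mask = pk.impute_missing(m, seed=1)
        pd.testing.assert_frame_equal(filled, m)
        assert not mask.to_numpy().any()

    def test_imputed_values_center_on_downshifted_mean(self):
        """Imputed sample mean converges on mean - 1.8 sd of the observed."""
        rng = np.random.default_rng(1)
        observed = rng.normal(0, 1, 5000)
        col = np.concatenate([observed, np.full(10_000, np.nan)])
        m = pd.DataFrame({"c": col})
        filled, mask = pk.impute_missing(m, width_factor=0.3, downshift_factor=1.8, seed=2)
        imputed = filled.loc[mask["c"], "c"]
        mu, sd = observed.mean(), observed.std(ddof=1)
        sem = 0.3 * sd / np.sqrt(len(imputed))
        assert abs(imputed.mean() - (mu - 1.8 * sd)) < 3 * sem

    def test_same_seed_identical_imputations(self):
        rng = np.random.default_rng(2)
        m = pd.DataFrame(rng.normal(size=(50, 2)))
        m[m > 1.0] = np.nan
        a, _ = pk.impute_missing(m, seed=5)
        b, _ = pk.impute_missing(m, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_column_with_too_few_observed_values_rejected(self):
        m = pd.DataFrame({"c": [1.0, 2.0, np.nan, np.nan]})
        with pytest.raises(ValueError, match="observed"):
            pk.impute_missing(m)


class TestCallInteractors:
    def _table(self, rows):
        return pd.DataFrame(
            rows, columns=["snp_id", "protein_id", "log2fc_ref_over_alt", "p_value"]
        )

    def test_empty_input_empty_output(self):
        out = pk.call_interactors(self._table([]))
        assert len(out) == 0

    def test_alt_preference_from_negative_fold_change(self):
        out = pk.call_interactors(self._table([("s1", "p1", -2.0, 0.005)]))
        assert len(out) == 1
        assert out["allele_preference"].iloc[0] == "ALT"

    def test_threshold_is_strict(self):
        out = pk.call_interactors(self._table([("s1", "p1", 2.0, 0.01)]), alpha=0.01)
        assert len(out) == 0

    def test_replicate_support_filters_unconfirmed_outliers(self):
        combined = self._table(
            [("s1", "p1", 2.0, 0.004), ("s1", "p2", 2.0, 0.004)]
        )
        reps = pd.DataFrame(
            {
                "snp_id": ["s1"] * 4,
                "protein_id": ["p1", "p1", "p2", "p2"],
                "p_value": [0.001, 0.002, 0.001, 0.5],
            }
        )
        out = pk.call_interactors(combined, alpha=0.01, replicate_pvalues=reps)
        assert out["protein_id"].tolist() == ["p1"]

    def test_call_set_matches_direct_formula_reimplementation(self):
        """Synthetic screen: calls equal an independent percentile-formula rerun."""
        spec = pk.ScreenSpec(
            n_loci=3, n_background_proteins=400, n_spiked_binders=6,
            missing_rate_low_intensity=0.0, seed=21,
        )
        pairs, _ = pk.generate_pulldown_tables(spec)
        expected = set()
        for pair in pairs:
            combined = pk.combine_label_swap(pair)
            x = combined["log2fc_ref_over_alt"].to_numpy()
            r0 = np.percentile(x, 50)
            right = np.percentile(x, 84.13) - r0
            left = r0 - np.percentile(x, 15.87)
            z = np.where(x > r0, (x - r0) / right, (r0 - x) / left)
            p = np.array([math.erfc(v / math.sqrt(2)) for v in z])
            for pid in combined["protein_id"][p < 0.01]:
                expected.add((pair.snp_id, pid))
        combined_all = []
        for pair in pairs:
            df = pk.combine_label_swap(pair)
            df["p_value"] = pk.significance_outlier_test(
                df["log2fc_ref_over_alt"], df["mean_log10_intensity"], mode="A"
            )
            combined_all.append(df)
        calls = pk.call_interactors(pd.concat(combined_all), alpha=0.01)
        got = set(zip(calls["snp_id"], calls["protein_id"]))
        assert got == expected
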