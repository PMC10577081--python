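"""Filters, enrichment ratios, score anchoring, errors, and map combination."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from varmap.errors import CalibrationError, ParameterError
from varmap.scoring import (
    adjust_and_enrich,
    combine_maps,
    combine_scores,
    compute_scales,
    estimate_error,
    filter_counts,
    functional_score,
    preference_transforms,
    quality_filter,
    rescale_isoform,
)
from varmap.variants import VariantKey

from conftest import make_count_table

K = VariantKey  # shorthand: K(pos, ref, alt)


def _tables(sel_counts, ns_counts, wt_sel=None, wt_ns=None, depth=100_000):
    sel = make_count_table(sel_counts, depth=depth, condition="selective")
    ns = make_count_table(ns_counts, depth=depth, condition="nonselective")
    wt_s = make_count_table(wt_sel or {}, depth=depth, condition="wt_selective")
    wt_n = make_count_table(wt_ns or {}, depth=depth, condition="wt_nonselective")
    return sel, ns, wt_s, wt_n


class TestFilterCounts:
    def test_count_below_threshold_removed(self):
        key = K(1, "M", "A")
        sel, ns, wt_s, wt_n = _tables({key: 50}, {key: 9})
        kept, log = filter_counts(sel, ns, wt_s, wt_n)
        assert kept == set()
        assert "low_count_nonselective" in log["reasons"].iloc[0]

    def test_zero_wt_frequencies_remove_nothing(self):
        key = K(1, "M", "A")
        sel, ns, wt_s, wt_n = _tables(
            {key: 50}, {key: 50}, wt_sel={K(2, "A", "C"): 0}, wt_ns={K(2, "A", "C"): 0}
        )
        kept, _ = filter_counts(sel, ns, wt_s, wt_n)
        assert kept == {key}

    def test_empty_wt_table_is_calibration_error(self):
        key = K(1, "M", "A")
        sel = make_count_table({key: 50})
        ns = make_count_table({key: 50})
        empty_wt = make_count_table({}, depth=0, n_tiles=0)
        with pytest.raises(CalibrationError):
            filter_counts(sel, ns, empty_wt, empty_wt)

    def test_survivors_match_bruteforce_rules(self):
        # oracle: re-apply both published rules by direct enumeration
        rng = np.random.default_rng(17)
        keys = [K(int(p), "M", a) for p, a in zip(range(1, 41), "ACDEFGHIKLMNPQRSTVWY" * 2)]
        sel_counts = {k: int(rng.integers(0, 40)) for k in keys}
        ns_counts = {k: int(rng.integers(0, 40)) for k in keys}
        wt_counts = {k: int(rng.integers(0, 8)) for k in keys[::3]}
        depth = 1_000
        sel, ns, wt_s, wt_n = _tables(
            sel_counts, ns_counts, wt_sel=wt_counts, wt_ns=wt_counts, depth=depth
        )
        kept, _ = filter_counts(sel, ns, wt_s, wt_n, min_count=10, wt_percentile=90)
        thr = np.percentile([c / depth for c in wt_counts.values()], 90)
        expected = {
            k
            for k in keys
            if sel_counts[k] >= 10
            and ns_counts[k] >= 10
            and sel_counts[k] / depth >= thr
            and ns_counts[k] / depth >= thr
        }
        assert kept == expected


class TestAdjustAndEnrich:
    def test_no_background_gives_plain_ratio(self):
        key = K(1, "M", "A")
        sel, ns, wt_s, wt_n = _tables({key: 200}, {key: 400})
        rec = adjust_and_enrich(sel, ns, wt_s, wt_n)
        assert rec.loc[key, "phi"] == pytest.approx(0.5)

    def test_selective_floor_applied(self):
        key = K(1, "M", "A")
        depth = 100_000
        sel, ns, wt_s, wt_n = _tables(
            {key: 5}, {key: 400}, wt_sel={key: 5}, depth=depth
        )
        rec = adjust_and_enrich(sel, ns, wt_s, wt_n)
        # f_s_adj floored at half a read over depth -> phi strictly positive
        assert rec.loc[key, "floored_selective"]
        assert rec.loc[key, "phi"] == pytest.approx(
            (0.5 / depth) / (400 / depth)
        )

    def test_nonpositive_nonselective_marks_unusable(self):
        key = K(1, "M", "A")
        sel, ns, wt_s, wt_n = _tables({key: 100}, {key: 10}, wt_ns={key: 10})
        rec = adjust_and_enrich(sel, ns, wt_s, wt_n)
        assert not rec.loc[key, "usable"]
        assert math.isnan(rec.loc[key, "phi"])

    def test_depth_invariance(self):
        key = K(1, "M", "A")
        phis = []
        for depth in (50_000, 100_000):
            sel, ns, wt_s, wt_n = _tables(
                {key: depth // 100}, {key: depth // 50}, depth=depth
            )
            rec = adjust_and_enrich(sel, ns, wt_s, wt_n)
            phis.append(rec.loc[key, "phi"])
        assert phis[0] == pytest.approx(phis[1])

    def test_variant_missing_from_nonselective_is_unusable(self):
        key = K(1, "M", "A")
        sel, ns, wt_s, wt_n = _tables({key: 100}, {})
        rec = adjust_and_enrich(sel, ns, wt_s, wt_n)
        assert not rec.loc[key, "usable"]


def _records(phis: dict[VariantKey, float]) -> pd.DataFrame:
    idx = pd.MultiIndex.from_tuples(phis, names=["pos", "ref", "alt"])
    return pd.DataFrame(
        {"phi": list(phis.values()), "usable": True, "f_ns": 1e-3}, index=idx
    )


class TestScales:
    def test_median_of_nonsense_ratios(self):
        phis = {
            K(1, "M", "*"): 0.1,
            K(2, "A", "*"): 0.2,
            K(3, "A", "*"): 0.3,
            K(1, "M", "M"): 1.0,
            K(2, "A", "A"): 1.1,
            K(3, "A", "A"): 0.9,
        }
        classes = {k: k.variant_class for k in phis}
        scales = compute_scales(_records(phis), classes, protein_length=100)
        assert scales[0] == (pytest.approx(0.2), pytest.approx(1.0))

    def test_c_terminal_nonsense_excluded(self):
        L = 100
        phis = {
            K(1, "M", "*"): 0.1,
            K(2, "A", "*"): 0.2,
            K(3, "A", "*"): 0.3,
            K(L - 5, "A", "*"): 5.0,  # within the last 14 residues: ignored
            K(1, "M", "M"): 1.0,
            K(2, "A", "A"): 1.1,
            K(3, "A", "A"): 0.9,
        }
        classes = {k: k.variant_class for k in phis}
        scales = compute_scales(_records(phis), classes, protein_length=L)
        assert scales[0][0] == pytest.approx(0.2)

    def test_unseparated_classes_raise(self):
        phis = {
            K(1, "M", "*"): 1.0,
            K(2, "A", "*"): 1.0,
            K(3, "A", "*"): 1.0,
            K(1, "M", "M"): 0.5,
            K(2, "A", "A"): 0.5,
            K(3, "A", "A"): 0.5,
        }
        classes = {k: k.variant_class for k in phis}
        with pytest.raises(CalibrationError):
            compute_scales(_records(phis), classes, protein_length=100)

    def test_scale_separation_grows_with_selection_gap(self, small_truth):
        """Harder selection widens the synonymous/nonsense ratio."""
        from varmap.synthetic import (
            LibraryModel,
            SelectionModel,
            SequencingModel,
            simulate_clone_pool,
            simulate_selection,
            simulate_tile_counts,
        )

        lib = LibraryModel(n_clones=30_000)
        pool = simulate_clone_pool(small_truth, lib, seed=2, region=(1, 41))
        seqm = SequencingModel(
            depth_per_tile=100_000, tile_length=30, per_base_error=0.0
        )
        ns = simulate_tile_counts(pool, seqm, seed=3)
        ratios = []
        for gap in (0.3, 0.8):
            sel_model = SelectionModel(
                generations=3.0, stop_syn_growth_gap=gap, noise_sd=0.0
            )
            selected = simulate_selection(pool, small_truth, sel_model, seed=4)
            sel = simulate_tile_counts(selected, seqm, seed=5, condition="selective")
            rec = adjust_and_enrich(sel, ns, *_empty_wt_pair())
            scales = compute_scales(
                rec, small_truth.variant_class, small_truth.protein_length
            )
            phi_stop, phi_syn = scales[0]
            ratios.append(phi_syn / phi_stop)
        assert ratios[1] > ratios[0]


def _empty_wt_pair():
    wt_s = make_count_table({}, condition="wt_selective")
    wt_n = make_count_table({}, condition="wt_nonselective")
    return wt_s, wt_n


class TestFunctionalScore:
    SCALES = (0.2, 4.0)

    def test_anchors(self):
        assert functional_score(4.0, self.SCALES) == pytest.approx(1.0)
        assert functional_score(0.2, self.SCALES) == pytest.approx(0.0)

    def test_geometric_midpoint_scores_half(self):
        mid = math.sqrt(0.2 * 4.0)
        assert functional_score(mid, self.SCALES) == pytest.approx(0.5)

    def test_hyper_and_negative_scores_permitted(self):
        assert functional_score(8.0, self.SCALES) > 1.0
        assert functional_score(0.1, self.SCALES) < 0.0

    def test_nonpositive_phi_is_nan(self):
        assert math.isnan(functional_score(0.0, self.SCALES))

    def test_invalid_scales_rejected(self):
        with pytest.raises(CalibrationError):
            functional_score(1.0, (2.0, 1.0))


class TestEstimateError:
    def _frame(self, values: np.ndarray) -> tuple[pd.DataFrame, pd.Series]:
        idx = pd.MultiIndex.from_tuples(
            [(i, "A", "C") for i in range(1, len(values) + 1)],
            names=["pos", "ref", "alt"],
        )
        fs = pd.DataFrame(values, index=idx)
        f_ns = pd.Series(np.linspace(1e-4, 1e-3, len(values)), index=idx)
        return fs, f_ns

    def test_zero_prior_reproduces_empirical_standard_error(self):
        rng = np.random.default_rng(3)
        values = rng.normal(0.5, 0.1, size=(40, 3))
        fs, f_ns = self._frame(values)
        out = estimate_error(fs, f_ns, m=0.0, bias_correct=False)
        expected = values.std(axis=1, ddof=1) / np.sqrt(3)
        np.testing.assert_allclose(out["sigma"].to_numpy(), expected)

    def test_identical_replicates_blend_toward_trend(self):
        rng = np.random.default_rng(4)
        values = rng.normal(0.5, 0.05, size=(60, 2))
        values[30] = (0.5, 0.5)  # identical replicates for one variant
        fs, f_ns = self._frame(values)
        m = 2.0
        out = estimate_error(fs, f_ns, m=m, bias_correct=False)
        row = out.iloc[30]
        t = row["trend"]
        assert t > 0
        # blend of sd 0 (weight n) and trend t (weight m), as standard error
        assert row["sigma"] == pytest.approx((m * t) / (m + 2) / np.sqrt(2))

    def test_blend_formula_holds_for_every_variant(self):
        rng = np.random.default_rng(5)
        values = rng.normal(0.0, 0.2, size=(50, 2))
        fs, f_ns = self._frame(values)
        out = estimate_error(fs, f_ns, m=3.0, bias_correct=False)
        sd = values.std(axis=1, ddof=1)
        expected = (3.0 * out["trend"].to_numpy() + 2 * sd) / 5.0 / np.sqrt(2)
        np.testing.assert_allclose(out["sigma"].to_numpy(), expected)

    def test_single_replicate_takes_trend_and_flag(self):
        rng = np.random.default_rng(6)
        values = rng.normal(0.0, 0.1, size=(30, 2))
        fs, f_ns = self._frame(values)
        fs.iloc[10, 1] = np.nan
        out = estimate_error(fs, f_ns, m=2.0, bias_correct=False)
        assert out["single_replicate"].iloc[10]
        assert out["sigma"].iloc[10] == pytest.approx(out["trend"].iloc[10])

    def test_negative_prior_rejected(self):
        fs, f_ns = self._frame(np.zeros((10, 2)))
        with pytest.raises(ParameterError):
            estimate_error(fs, f_ns, m=-1.0)


class TestQualityFilter:
    def _scores(self, sigma, f_ns):
        idx = pd.MultiIndex.from_tuples([(1, "A", "C")], names=["pos", "ref", "alt"])
        return pd.DataFrame({"fs": [0.5], "sigma": [sigma], "f_ns": [f_ns]}, index=idx)

    @pytest.mark.parametrize(
        "sigma,f_ns,passes",
        [
            (0.31, 1e-3, False),  # sigma above 0.3 fails
            (0.30, 1e-3, True),  # boundary passes (strict reading)
            (0.1, 0.004e-2, False),  # frequency below 0.005% fails
            (0.1, 0.005e-2, True),  # boundary passes
        ],
    )
    def test_boundaries(self, sigma, f_ns, passes):
        out = quality_filter(self._scores(sigma, f_ns))
        assert bool(out["passed_filters"].iloc[0]) is passes


class TestRescaleAndCombine:
    def test_identity_transform(self):
        s = pd.Series(np.linspace(0, 1, 60))
        rescaled, (a, b) = rescale_isoform(s, s)
        assert a == pytest.approx(1.0) and b == pytest.approx(0.0, abs=1e-12)

    def test_halving_slope_recovered(self):
        rng = np.random.default_rng(8)
        base = pd.Series(rng.uniform(0, 1, 80))
        rescaled, (a, b) = rescale_isoform(2 * base, base)
        assert a == pytest.approx(0.5) and b == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(rescaled.to_numpy(), base.to_numpy())

    def test_rank_correlation_preserved(self):
        from scipy.stats import spearmanr

        rng = np.random.default_rng(9)
        a = pd.Series(rng.normal(size=70))
        b = a + pd.Series(rng.normal(scale=0.3, size=70))
        rescaled, _ = rescale_isoform(a, b)
        assert spearmanr(a, rescaled).statistic == pytest.approx(1.0)
        assert spearmanr(rescaled, b).statistic == pytest.approx(
            spearmanr(a, b).statistic
        )

    def test_too_few_shared_variants_rejected(self):
        s = pd.Series(np.arange(10, dtype=float))
        with pytest.raises(ParameterError):
            rescale_isoform(s, s)

    def test_degenerate_shared_set_rejected(self):
        s = pd.Series(np.ones(60))
        with pytest.raises(CalibrationError):
            rescale_isoform(s, s)

    def test_inverse_variance_worked_example(self):
        # weights 1/0.01=100 and 1/0.04=25 -> (0.8*100+0.4*25)/125 = 0.72
        fs, sigma = combine_scores(0.8, 0.1, 0.4, 0.2)
        assert fs == pytest.approx(0.72)
        assert sigma == pytest.approx(math.sqrt(1 / 125))

    def test_equal_sigmas_give_simple_mean(self):
        fs, _ = combine_scores(0.2, 0.1, 0.6, 0.1)
        assert fs == pytest.approx(0.4)

    def test_single_score_passes_through(self):
        fs, sigma = combine_scores(None, None, 0.3, 0.05)
        assert (fs, sigma) == (0.3, 0.05)

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ParameterError):
            combine_scores(0.5, 0.0, 0.5, 0.1)

    @given(
        fs1=st.floats(-1, 2),
        fs2=st.floats(-1, 2),
        s1=st.floats(0.01, 0.5),
        s2=st.floats(0.01, 0.5),
    )
    @settings(max_examples=50, deadline=None)
    def test_combination_contracts(self, fs1, fs2, s1, s2):
        fs, sigma = combine_scores(fs1, s1, fs2, s2)
        assert min(fs1, fs2) - 1e-12 <= fs <= max(fs1, fs2) + 1e-12
        assert sigma <= min(s1, s2) + 1e-12

    def test_combine_maps_delta_and_sources(self):
        idx1 = pd.MultiIndex.from_tuples(
            [(1, "A", "C"), (2, "A", "C")], names=["pos", "ref", "alt"]
        )
        idx2 = pd.MultiIndex.from_tuples(
            [(1, "A", "C"), (3, "A", "C")], names=["pos", "ref", "alt"]
        )
        m1 = pd.DataFrame({"fs": [0.8, 0.2], "sigma": [0.1, 0.1]}, index=idx1)
        m2 = pd.DataFrame({"fs": [0.4, 0.6], "sigma": [0.2, 0.1]}, index=idx2)
        out = combine_maps(m1, m2)
        both = out.loc[(1, "A", "C")]
        assert both["fs_combined"] == pytest.approx(0.72)
        assert both["delta"] == pytest.approx(0.4)
        only1 = out.loc[(2, "A", "C")]
        assert only1["fs_combined"] == pytest.approx(0.2)
        assert math.isnan(only1["delta"])
        assert out.loc[(3, "A", "C"), "sources"] == "map_2"


class TestPreferenceTransforms:
    def test_uniform_row_gives_uniform_preferences(self):
        cols = list("ACDEFGHIKLMNPQRSTVWY")
        scores = pd.DataFrame([[0.7] * 20], columns=cols, index=[1])
        prefs = preference_transforms(scores)
        for mat in prefs.values():
            np.testing.assert_allclose(mat.loc[1].to_numpy(), 1 / 20)

    def test_damaging_model_inverts_above_one(self):
        scores = pd.DataFrame([[2.0, 1.0]], columns=["A", "C"], index=[1])
        prefs = preference_transforms(scores)
        np.testing.assert_allclose(
            prefs["damaging"].loc[1].to_numpy(), [1 / 3, 2 / 3]
        )
        np.testing.assert_allclose(prefs["neutral"].loc[1].to_numpy(), [0.5, 0.5])
        np.testing.assert_allclose(
            prefs["advantageous"].loc[1].to_numpy(), [2 / 3, 1 / 3]
        )

    def test_models_coincide_when_nothing_exceeds_one(self):
        rng = np.random.default_rng(10)
        cols = list("ACDEFGHIKLMNPQRSTVWY")
        scores = pd.DataFrame(
            rng.uniform(0.05, 1.0, size=(5, 20)), columns=cols, index=range(1, 6)
        )
        prefs = preference_transforms(scores)
        pd.testing.assert_frame_equal(prefs["advantageous"], prefs["neutral"])
        pd.testing.assert_frame_equal(prefs["advantageous"], prefs["damaging"])

    def test_rows_sum_to_one_with_nonpositive_scores(self):
        scores = pd.DataFrame([[0.0, -0.5, 1.5]], columns=["A", "C", "D"], index=[1])
        prefs = preference_transforms(scores)
        for mat in prefs.values():
            assert mat.loc[1].sum() == pytest.approx(1.0)
            assert (mat.loc[1] > 0).all()
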