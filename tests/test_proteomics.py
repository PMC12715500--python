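"""Partition proteomics: filtering, normalization, statistics, native MS."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from pchscaffold import proteomics as prot
from pchscaffold import synthio

ids = st.sets(st.sampled_from([f"P{i:03d}" for i in range(30)]),
              max_size=25)


def _matrix(values: np.ndarray, fractions, scale="raw") -> synthio.IntensityMatrix:
    cols, meta = [], []
    for fr, n in fractions:
        for r in range(1, n + 1):
            cols.append(f"{fr}.r{r}")
            meta.append({"sample_id": cols[-1], "fraction": fr,
                         "replicate": r})
    idx = [f"P{i}" for i in range(values.shape[0])]
    return synthio.IntensityMatrix(
        pd.DataFrame(values, index=idx, columns=cols),
        pd.DataFrame(meta), scale=scale)


class TestDetectionFilter:
    def test_sparse_protein_dropped_full_kept(self):
        vals = np.full((2, 12), 100.0)
        vals[0, 2:] = np.nan  # present in only 2 of 12 samples
        m = _matrix(vals, [("HC", 12)])
        out = prot.detection_filter(m, 3)
        assert out.proteins == ["P1"]

    def test_matches_row_count_oracle(self, rng):
        vals = np.exp2(rng.normal(16, 2, (50, 9)))
        mask = rng.random((50, 9)) < 0.5
        vals[mask] = np.nan
        m = _matrix(vals, [("HC", 9)])
        out = prot.detection_filter(m, 4)
        oracle = [f"P{i}" for i in range(50)
                  if (~np.isnan(vals[i])).sum() >= 4]
        assert out.proteins == oracle


class TestReplicatePresence:
    def test_two_of_three_in_one_of_three_out(self):
        vals = np.array([[100.0, 100.0, np.nan],
                         [100.0, np.nan, np.nan]])
        m = _matrix(vals, [("HC_P", 3)])
        assert prot.replicate_presence(m, "HC_P", 2) == {"P0"}

    def test_unknown_group_rejected(self, dia_matrix):
        with pytest.raises(KeyError):
            prot.replicate_presence(dia_matrix, "no_such_fraction")

    def test_order_insensitive_with_detection_filter(self, dia_matrix):
        a = prot.replicate_presence(prot.detection_filter(dia_matrix, 3),
                                    "HC_P", 2)
        survivors = set(prot.detection_filter(dia_matrix, 3).proteins)
        b = prot.replicate_presence(dia_matrix, "HC_P", 2) & survivors
        assert a == b


class TestNormalization:
    def test_worked_column_example(self):
        m = _matrix(np.array([[1.0], [4.0], [16.0]]), [("HC", 1)])
        out = prot.log2_median_normalize(m)
        np.testing.assert_allclose(out.values.to_numpy().ravel(),
                                   [-2.0, 0.0, 2.0])

    def test_constant_column_maps_to_zero(self):
        m = _matrix(np.full((5, 2), 8.0), [("HC", 2)])
        out = prot.log2_median_normalize(m)
        assert np.allclose(out.values.to_numpy(), 0.0)

    def test_column_medians_exactly_zero(self, dia_matrix):
        out = prot.log2_median_normalize(dia_matrix)
        med = np.nanmedian(out.values.to_numpy(), axis=0)
        np.testing.assert_allclose(med, 0.0, atol=1e-12)

    def test_median_step_idempotent(self, dia_matrix):
        out = prot.log2_median_normalize(dia_matrix)
        vals = out.values.to_numpy()
        again = vals - np.nanmedian(vals, axis=0)
        np.testing.assert_allclose(again, vals, atol=1e-12,
                                   equal_nan=True)

    def test_nonpositive_values_rejected(self):
        with pytest.raises(ValueError):
            m = _matrix(np.array([[4.0], [8.0]]), [("HC", 1)])
            m.values.iloc[0, 0] = -1.0
            prot.log2_median_normalize(m)


class TestImputation:
    def test_complete_matrix_unchanged(self):
        m = _matrix(np.full((4, 3), 10.0), [("HC", 3)], scale="log2")
        out = prot.impute_downshift(m, seed=1)
        np.testing.assert_array_equal(out.values.to_numpy(),
                                      m.values.to_numpy())

    def test_imputed_mean_is_downshifted(self, rng):
        n = 20000
        vals = rng.normal(20.0, 2.0, (n, 1))
        vals[rng.random(n) < 0.5, 0] = np.nan
        m = _matrix(vals, [("HC", 1)], scale="log2")
        obs = vals[~np.isnan(vals)]
        mu, sd = obs.mean(), obs.std(ddof=1)
        out = prot.impute_downshift(m, width=0.3, shift=1.8, seed=5)
        imputed = out.values.to_numpy()[np.isnan(vals)]
        se = 0.3 * sd / np.sqrt(len(imputed))
        assert abs(imputed.mean() - (mu - 1.8 * sd)) < 3 * se

    def test_deterministic_per_seed(self, dia_matrix):
        log2 = prot.log2_median_normalize(
            prot.detection_filter(dia_matrix, 3))
        a = prot.impute_downshift(log2, seed=7)
        b = prot.impute_downshift(log2, seed=7)
        pd.testing.assert_frame_equal(a.values, b.values)

    def test_underobserved_column_raises_with_name(self):
        vals = np.array([[1.0, np.nan], [np.nan, np.nan], [np.nan, 2.0]])
        m = _matrix(vals, [("HC", 2)], scale="log2")
        with pytest.raises(ValueError, match="HC.r1"):
            prot.impute_downshift(m, seed=1)


class TestSetClassification:
    @settings(max_examples=100, derandomize=True)
    @given(s=ids, p=ids)
    def test_partition_is_a_partition(self, s, p):
        res = prot.partition_classify(s | p, s, p)
        assert res.universe == s | p
        assert res.p_and_s == s & p
        assert res.p_only == p - s and res.s_only == s - p

    @settings(max_examples=100, derandomize=True)
    @given(a=ids, b=ids)
    def test_composition_shift_set_algebra(self, a, b):
        shift = prot.composition_shift(a, b)
        assert shift.retained == a & b
        assert shift.excluded == a - b and shift.recruited == b - a
        assert (shift.retained | shift.excluded | shift.recruited) == a | b

    def test_shift_worked_example(self):
        shift = prot.composition_shift({"x", "y"}, {"y", "z"})
        assert shift.retained == {"y"}
        assert shift.excluded == {"x"} and shift.recruited == {"z"}

    def test_identical_pellets_shift_nothing(self):
        shift = prot.composition_shift({"a", "b"}, {"a", "b"})
        assert shift.excluded == set() == shift.recruited


class TestDomainFractionAndSummary:
    def test_fraction_counting(self, annotations):
        flags = annotations.df.set_index("protein_id")["has_cc"]
        some = set(annotations.ids[:40])
        frac = prot.domain_fraction(some, annotations, "cc")
        assert frac == pytest.approx(flags.loc[sorted(some)].mean())
        with pytest.raises(ValueError):
            prot.domain_fraction(set(), annotations, "cc")

    def test_printed_ratio_examples(self):
        # class of 25 detected, 14 excluded -> 56.0%;
        # class of 34 detected, 25 retained -> 73.5% (~74%)
        pellet = {f"a{i}" for i in range(25)} | {f"d{i}" for i in range(34)}
        shift = prot.CompositionShift(
            retained=({f"a{i}" for i in range(14, 25)}
                      | {f"d{i}" for i in range(25)}),
            excluded=({f"a{i}" for i in range(14)}
                      | {f"d{i}" for i in range(25, 34)}),
            recruited=set())
        ac = prot.functional_partition_summary(
            {f"a{i}" for i in range(25)}, pellet, shift)
        assert ac["pct_excluded"] == 56.0
        assert ac["n_excluded"] == 14 and ac["n_class_detected"] == 25
        de = prot.functional_partition_summary(
            {f"d{i}" for i in range(34)}, pellet, shift)
        assert de["pct_retained"] == 73.5
        assert de["pct_retained_approx"] == 74

    def test_empty_class_flagged_undefined(self):
        shift = prot.composition_shift({"a"}, {"a"})
        out = prot.functional_partition_summary(set(), {"a"}, shift)
        assert out["undefined"] is True


def _pooled_t_pvalue(a, b):
    """Textbook pooled-variance two-sided t-test."""
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * np.var(a, ddof=1) + (nb - 1) * np.var(b, ddof=1)) \
        / (na + nb - 2)
    t = (np.mean(a) - np.mean(b)) / np.sqrt(sp2 * (1 / na + 1 / nb))
    return 2 * stats.t.sf(abs(t), na + nb - 2)


class TestGroupStatistics:
    def test_identical_groups_zero_difference(self, annotations):
        g = set(annotations.ids[:20])
        out = prot.compare_group_metric(g, g, annotations,
                                        "disorder_fraction")
        assert out["mean_a"] == out["mean_b"]

    def test_closed_form_t_agreement(self, annotations, rng):
        a = set(rng.choice(annotations.ids, 30, replace=False))
        b = set(annotations.ids) - a
        out = prot.compare_group_metric(a, b, annotations,
                                        "disorder_fraction")
        series = annotations.df.set_index("protein_id")["disorder_fraction"]
        expect = _pooled_t_pvalue(series.loc[sorted(a)].to_numpy(),
                                  series.loc[sorted(b)].to_numpy())
        assert out["p_two_sided"] == pytest.approx(expect, abs=1e-10)

    def test_unit_shift_detected_with_high_power(self, rng):
        hits = 0
        for _ in range(100):
            a = rng.normal(0, 1, 100)
            b = rng.normal(1, 1, 100)
            if stats.ttest_ind(a, b, equal_var=True).pvalue < 0.01:
                hits += 1
        assert hits >= 95

    def test_differential_abundance_recovers_and_matches_closed_form(
            self, rng):
        vals = np.concatenate([rng.normal(0, 0.3, (30, 3)),
                               rng.normal(2, 0.3, (30, 3))], axis=1)
        m = _matrix(vals, [("A", 3), ("B", 3)], scale="log2")
        out = prot.differential_abundance(m, "A", "B")
        assert out["log2_fc"].mean() == pytest.approx(2.0, abs=0.2)
        row = out.iloc[0]
        expect = _pooled_t_pvalue(vals[0, 3:], vals[0, :3])
        assert row["p"] == pytest.approx(expect, abs=1e-10)

    def test_zero_fold_change_for_duplicated_group(self):
        vals = np.tile(np.array([[1.0, 2.0, 3.0]]), (4, 2))
        m = _matrix(vals, [("A", 3), ("B", 3)], scale="log2")
        out = prot.differential_abundance(m, "A", "B")
        assert np.allclose(out["log2_fc"], 0.0)

    def test_degenerate_variance_flagged(self):
        vals = np.full((1, 6), 5.0)
        m = _matrix(vals, [("A", 3), ("B", 3)], scale="log2")
        out = prot.differential_abundance(m, "A", "B")
        assert bool(out["flagged"].iloc[0]) and np.isnan(out["p"].iloc[0])


class TestNativeMS:
    def test_small_mass_roundtrip(self):
        peaks = prot.synthesize_charge_peaks(10000.0, 11, 3)
        series = prot.mass_from_charge_series(peaks)
        assert series.mass == pytest.approx(10000.0, abs=1e-3)
        assert set(series.charges) == {9, 10, 11}

    def test_467kda_series_near_mz_10000(self):
        mass = 467000.0
        z_top = 48  # places the envelope around m/z 10 000
        peaks = prot.synthesize_charge_peaks(mass, z_top, 6)
        assert 9000 < peaks.mean() < 11000
        series = prot.mass_from_charge_series(peaks)
        assert abs(series.mass - mass) / mass < 1e-4

    def test_jittered_peaks_recover_within_a_tenth_percent(self, rng):
        mass = 120000.0
        for _ in range(30):
            peaks = prot.synthesize_charge_peaks(mass, 25, 5)
            noisy = np.sort(peaks * (1 + rng.normal(0, 5e-4, 5) * 0.5))
            series = prot.mass_from_charge_series(noisy)
            assert abs(series.mass - mass) / mass < 1e-3

    @pytest.mark.parametrize("mass,z_top,n", [
        (5e3, 8, 3), (5e4, 20, 10), (5e5, 60, 20), (1e6, 90, 12)])
    def test_roundtrip_identity_across_mass_range(self, mass, z_top, n):
        peaks = prot.synthesize_charge_peaks(mass, z_top, n)
        series = prot.mass_from_charge_series(peaks)
        assert abs(series.mass - mass) / mass < 1e-4

    def test_unassignable_peaks_rejected(self):
        with pytest.raises(ValueError):
            prot.mass_from_charge_series([100.0, 5000.0, 5001.0])

    def test_oligomer_order_cases(self):
        assert prot.oligomer_order(300.0, 100.0)[:2] == (3, 3.0)
        order, ratio, ambiguous = prot.oligomer_order(467000.0, 66714.0)
        assert order == 7 and ambiguous is False
        _, _, ambiguous = prot.oligomer_order(250.0, 100.0)
        assert ambiguous is True
        with pytest.raises(ValueError):
            prot.oligomer_order(-1.0, 100.0)
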