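"""Generator contracts: planted signal, reproducibility, on-disk round trips."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pchscaffold import frap, proteomics, screen, synthio


class TestGenAnnotations:
    def test_pure_pch_mix_plants_a_keyword_in_every_record(self):
        ann = synthio.gen_annotations(
            10, {"pericentric": 1.0}, seed=1)
        classes = screen.keyword_classes(ann)
        assert classes["pericentric_heterochromatin"] == set(ann.ids)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            synthio.gen_annotations(0, {}, seed=1)

    def test_overfull_mix_rejected(self):
        with pytest.raises(ValueError):
            synthio.gen_annotations(10, {"pericentric": 0.7,
                                         "nucleolus": 0.5}, seed=1)

    def test_pch_fraction_within_binomial_bounds(self):
        # 99% two-sided binomial bounds for n=1000, p=0.05
        ann = synthio.gen_annotations(1000, {"pericentric": 0.05}, seed=7)
        n_pch = len(ann.ids_with_compartment("pericentric_heterochromatin"))
        lo = stats.binom.ppf(0.005, 1000, 0.05)
        hi = stats.binom.ppf(0.995, 1000, 0.05)
        assert lo <= n_pch <= hi

    def test_reproducible_and_provenance_recorded(self):
        a = synthio.gen_annotations(40, {"nucleolus": 0.2}, seed=5)
        b = synthio.gen_annotations(40, {"nucleolus": 0.2}, seed=5)
        pd.testing.assert_frame_equal(a.df, b.df)
        assert a.provenance["seed"] == 5
        assert a.provenance["params"]["n_proteins"] == 40

    def test_tsv_round_trip(self, annotations, tmp_path):
        p = tmp_path / "ann.tsv"
        annotations.to_tsv(p)
        back = synthio.AnnotationTable.from_tsv(p)
        assert back.ids == annotations.ids
        assert list(back.df["has_cc"]) == list(annotations.df["has_cc"])


class TestGenPredictorScores:
    def test_unknown_planted_id_rejected(self, annotations):
        with pytest.raises(KeyError):
            synthio.gen_predictor_scores(annotations, {"nope"}, 1.0, seed=1)

    def test_large_effect_puts_planted_on_top_of_every_predictor(self):
        ann = synthio.gen_annotations(1000, {}, seed=3)
        planted = set(ann.ids[::20])  # 50 planted
        preds = synthio.gen_predictor_scores(ann, planted, 10.0, seed=3)
        for ps in preds:
            assert planted <= screen.top_n_candidates(ps, 50)

    def test_consensus_recall_matches_monte_carlo_oracle(self):
        # the package route and a direct numpy re-simulation estimate the
        # same recall of planted scaffolds by the >=2-predictor vote
        n, k, n_planted, effect = 400, 60, 30, 1.5
        ann = synthio.gen_annotations(n, {}, seed=4)
        planted = set(ann.ids[:n_planted])

        def package_recall(seed):
            preds = synthio.gen_predictor_scores(ann, planted, effect,
                                                 seed=seed)
            sets = [screen.top_n_candidates(p, k) for p in preds[:2]]
            sets.append(screen.top_n_candidates(preds[2], k)
                        | screen.top_n_candidates(preds[3], k))
            hits = screen.consensus_vote(sets, 2) & planted
            return len(hits) / n_planted

        rng = np.random.default_rng(2024)

        def oracle_recall():
            counts = np.zeros(n)
            for two_scores in (False, False, True):
                s = rng.standard_normal(n)
                s[:n_planted] += effect
                member = np.zeros(n, bool)
                member[np.argsort(-s)[:k]] = True
                if two_scores:
                    s2 = rng.standard_normal(n)
                    s2[:n_planted] += effect
                    member[np.argsort(-s2)[:k]] = True
                counts += member
            return (counts[:n_planted] >= 2).mean()

        r_pkg = np.array([package_recall(s) for s in range(60)])
        r_mc = np.array([oracle_recall() for _ in range(200)])
        se = np.sqrt(r_pkg.var(ddof=1) / len(r_pkg)
                     + r_mc.var(ddof=1) / len(r_mc))
        assert abs(r_pkg.mean() - r_mc.mean()) < 3 * se


class TestGenDiaExperiment:
    def test_zero_slope_gives_half_missingness(self, annotations):
        m = synthio.gen_dia_experiment(
            annotations, [("HC", 3)],
            params={"dropout_slope": 0.0}, seed=2)
        n_cells = m.values.size
        n_missing = int(m.values.isna().sum().sum())
        lo = stats.binom.ppf(0.005, n_cells, 0.5)
        hi = stats.binom.ppf(0.995, n_cells, 0.5)
        assert lo <= n_missing <= hi

    def test_truth_shifts_recorded_and_raw_positive(self, dia_matrix):
        shifts = dia_matrix.truth["shifts"]["HC_P"]
        assert any(v == 2.0 for v in shifts.values())
        vals = dia_matrix.values.to_numpy()
        assert np.nanmin(vals) > 0

    def test_column_medians_agree_across_replicates(self, annotations):
        # without enrichment the per-replicate log2 medians coincide in
        # expectation; check a loose tolerance at n=300 proteins
        m = synthio.gen_dia_experiment(annotations, [("HC", 3)],
                                       params={"dropout_midpoint": 10.0},
                                       seed=9)
        med = np.nanmedian(np.log2(m.values.to_numpy()), axis=0)
        assert np.ptp(med) < 0.5

    def test_bad_params_rejected(self, annotations):
        with pytest.raises(ValueError):
            synthio.gen_dia_experiment(annotations, [("HC", 3)],
                                       params={"base_sd": -1}, seed=1)
        with pytest.raises(KeyError):
            synthio.gen_dia_experiment(
                annotations, [("HC", 3)],
                params={"enrichment_effects": {("no_such_class", "HC"): 1}},
                seed=1)

    def test_tsv_round_trip(self, dia_matrix, tmp_path):
        p = tmp_path / "m.tsv"
        dia_matrix.to_tsv(p)
        back = synthio.IntensityMatrix.from_tsv(p)
        assert back.fractions == dia_matrix.fractions
        np.testing.assert_allclose(back.values.to_numpy(),
                                   dia_matrix.values.to_numpy(),
                                   rtol=1e-6, equal_nan=True)


class TestGenFrapTraces:
    def test_no_bleach_no_noise_is_constant(self):
        ts = synthio.gen_frap_traces({"bleach_depth": 0.0, "noise_sd": 0.0,
                                      "n_post": 40}, seed=1)
        tr = ts.traces[0]
        assert np.allclose(tr.bleached, tr.bleached[0], atol=1e-9)
        assert np.allclose(tr.nonbleached, tr.nonbleached[0], atol=1e-9)

    def test_closed_compartment_equilibrates_to_half_depth(self):
        # k_boundary = 0: the two halves mix only with each other, so the
        # nonbleached half decays toward their common mean 1 - depth/2
        ts = synthio.gen_frap_traces({"k_boundary": 0.0, "k_intra": 1.0,
                                      "bleach_depth": 0.6, "noise_sd": 0.0,
                                      "n_post": 200, "dt": 0.5,
                                      "base_intensity": 1.0}, seed=1)
        tr = ts.traces[0]
        assert np.isclose(tr.nonbleached[-1], 1 - 0.3, atol=1e-4)
        assert np.isclose(tr.bleached[-1], 1 - 0.3, atol=1e-4)

    def test_dip_matches_matrix_exponential_oracle(self):
        params = {"k_intra": 0.4, "k_boundary": 0.03, "bleach_depth": 0.8,
                  "noise_sd": 0.0, "base_intensity": 1.0}
        ts = synthio.gen_frap_traces(params, seed=1)
        dip_gen = frap.compute_dip(frap.normalize_halves(ts.traces[0])).dip
        oracle = frap.simulate_two_compartment(0.4, 0.03, 0.8)
        dip_ode = frap.compute_dip(oracle.traces[0]).dip
        assert abs(dip_gen - dip_ode) < 1e-6

    def test_negative_dt_rejected(self):
        with pytest.raises(ValueError):
            synthio.gen_frap_traces({"dt": -1.0}, seed=1)

    def test_csv_round_trip(self, tmp_path):
        ts = synthio.gen_frap_traces({"n_traces": 2, "n_post": 20}, seed=8)
        p = tmp_path / "frap.csv"
        ts.to_csv(p)
        back = synthio.FrapTraceSet.from_csv(p)
        assert len(back.traces) == 2
        np.testing.assert_allclose(back.traces[0].nonbleached,
                                   ts.traces[0].nonbleached)
        assert back.traces[0].n_pre == ts.traces[0].n_pre


class TestGenNucleusImage:
    def test_zero_foci_gives_empty_truth(self):
        img = synthio.gen_nucleus_image({"n_foci": 0}, seed=1)
        assert img.truth["focus_labels"].max() == 0

    def test_unit_contrast_percent_equals_area_fraction(self):
        # foci at nucleus intensity: percent-in-PCH is the pure area ratio
        img = synthio.gen_nucleus_image({"focus_contrast": 1.0,
                                         "noise_sd": 0.0, "n_foci": 4},
                                        seed=2)
        from pchscaffold import imaging
        mask = img.truth["nucleus_mask"]
        labels = img.truth["focus_labels"]
        pct = imaging.percent_in_compartment(img.channels["dapi"],
                                             labels, mask)
        area_frac = 100.0 * (labels > 0).sum() / mask.sum()
        assert abs(pct - area_frac) < 1e-9

    def test_impossible_packing_raises(self):
        with pytest.raises((RuntimeError, ValueError)):
            synthio.gen_nucleus_image({"shape": (32, 32), "n_foci": 50,
                                       "focus_radius": 6.0}, seed=1)

    def test_tiff_round_trip(self, tmp_path):
        img = synthio.gen_nucleus_image({"shape": (48, 48), "n_foci": 2,
                                         "focus_radius": 4.0}, seed=3)
        img.to_tiff(tmp_path / "n.tiff")
        back = synthio.NucleusImage.from_tiff(tmp_path / "n.tiff")
        np.testing.assert_allclose(back.channels["dapi"],
                                   img.channels["dapi"], rtol=1e-6)


class TestGenStandardCurve:
    def test_noiseless_fit_is_exact(self):
        from pchscaffold import imaging
        c = synthio.gen_standard_curve(2.0, 1.0, [1, 2, 5, 10], 0.0, seed=1)
        fit = imaging.fit_standard_curve(c)
        assert fit.slope == pytest.approx(2.0, abs=1e-12)
        assert fit.intercept == pytest.approx(1.0, abs=1e-12)
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)

    def test_flat_curve_inversion_errors_downstream(self):
        from pchscaffold import imaging
        c = synthio.gen_standard_curve(0.0, 3.0, [1, 2, 3], 0.0, seed=1)
        fit = imaging.fit_standard_curve(c)
        with pytest.raises(ZeroDivisionError):
            imaging.invert_to_quantity(fit, 5.0)

    def test_fitted_slope_unbiased_over_seeds(self):
        from pchscaffold import imaging
        slopes = []
        for s in range(60):
            c = synthio.gen_standard_curve(2.0, 1.0, [1, 5, 10, 20, 30],
                                           1.0, seed=s)
            slopes.append(imaging.fit_standard_curve(c).slope)
        slopes = np.asarray(slopes)
        se = slopes.std(ddof=1) / np.sqrt(len(slopes))
        assert abs(slopes.mean() - 2.0) < 3 * se

    def test_too_few_levels_rejected(self):
        with pytest.raises(ValueError):
            synthio.gen_standard_curve(1.0, 0.0, [3, 3, 3], 0.1, seed=1)


def test_generators_use_independent_streams(annotations):
    """Adding one generator call must not shift another's output."""
    a1 = synthio.gen_annotations(20, {}, seed=42)
    _ = synthio.gen_standard_curve(1.0, 0.0, [1, 2], 0.5, seed=42)
    a2 = synthio.gen_annotations(20, {}, seed=42)
    pd.testing.assert_frame_equal(a1.df, a2.df)
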