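"""Mann-Whitney U, Holm correction, peak detection/matching, panel selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

import ftir_sputum as fs
from ftir_sputum.spectra import GRID_STEP


class TestMannWhitney:
    @pytest.mark.parametrize("x,y,u,p", [
        # exact two-sided p from enumerating all C(4,2)=6 group assignments
        ([1, 2], [3, 4], 0.0, 1 / 3),
        ([1, 3], [2, 4], 1.0, 2 / 3),
    ])
    def test_small_sample_exact_enumeration(self, x, y, u, p):
        res = fs.mann_whitney_u(x, y)
        assert res.mode == "exact"
        assert res.u == u
        assert res.p == pytest.approx(p)

    @settings(derandomize=True, max_examples=30)
    @given(st.lists(st.floats(-10, 10), min_size=2, max_size=5, unique=True),
           st.lists(st.floats(-10, 10), min_size=2, max_size=5, unique=True))
    def test_swap_symmetry(self, x, y):
        """Swapping samples maps U to n1*n2 - U and leaves p unchanged."""
        a = fs.mann_whitney_u(x, y)
        b = fs.mann_whitney_u(y, x)
        assert a.u + b.u == pytest.approx(len(x) * len(y))
        assert a.p == pytest.approx(b.p)

    @pytest.mark.parametrize("seed", range(5))
    def test_exact_agrees_with_scipy(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=5)
        y = rng.normal(0.8, size=6)
        ours = fs.mann_whitney_u(x, y, mode="exact")
        ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        assert ours.u == pytest.approx(ref.statistic)
        assert ours.p == pytest.approx(ref.pvalue, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_normal_approx_agrees_with_scipy_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        x = np.round(rng.normal(size=25), 1)  # rounding induces ties
        y = np.round(rng.normal(0.5, size=25), 1)
        ours = fs.mann_whitney_u(x, y, mode="normal_approx")
        ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert ours.u == pytest.approx(ref.statistic)
        assert ours.p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            fs.mann_whitney_u([], [1.0])


class TestHolm:
    def test_hand_worked_step_down(self):
        # m=3: adjusted = cummax(min(1, (m-i+1) p_(i))) = [.03, .04, .04]
        adj, rej = fs.holm_adjust([0.01, 0.02, 0.04], alpha=0.05)
        assert np.allclose(adj, [0.03, 0.04, 0.04])
        assert rej.all()

    def test_single_p_unchanged(self):
        adj, rej = fs.holm_adjust([0.04], alpha=0.05)
        assert adj[0] == pytest.approx(0.04)
        assert rej[0]
        assert not fs.holm_adjust([0.06], alpha=0.05)[1][0]

    def test_step_down_stops_at_first_failure(self):
        adj, rej = fs.holm_adjust([0.001, 0.5, 0.9], alpha=0.05)
        assert np.allclose(adj, [0.003, 1.0, 1.0])
        assert rej.tolist() == [True, False, False]

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_statsmodels(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(size=40) ** 2
        adj, rej = fs.holm_adjust(p, alpha=0.05)
        ref_rej, ref_adj, _, _ = multipletests(p, alpha=0.05, method="holm")
        assert np.allclose(adj, ref_adj)
        assert np.array_equal(rej, ref_rej)

    @settings(derandomize=True, max_examples=30)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=20))
    def test_adjusted_dominates_raw_and_subsets_unadjusted(self, p):
        adj, rej = fs.holm_adjust(p, alpha=0.05)
        assert np.all(adj >= np.asarray(p) - 1e-15)
        # Holm rejections are a subset of unadjusted alpha-level rejections
        assert np.all(~rej | (np.asarray(p) <= 0.05))

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValueError, match="index 1"):
            fs.holm_adjust([0.1, 1.5], alpha=0.05)


class TestShapiroScreen:
    def test_gaussian_samples_mostly_pass(self):
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            _, p = sps.shapiro(rng.normal(size=25))
            hits += p > 0.05
        assert hits >= 90

    def test_heavy_skew_mostly_fails(self):
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            _, p = sps.shapiro(rng.uniform(-1, 1, size=25) ** 4)
            hits += p < 0.01
        assert hits >= 90

    def test_constant_sample_flagged_not_fatal(self):
        grid = fs.WavenumberGrid([1000.0, 1010.0])
        matrix = np.array([[1.0, 0.1], [1.0, 0.2], [1.0, 0.3],
                           [1.0, 0.4], [1.0, 0.5], [1.0, 0.6]])
        meta = pd.DataFrame({"sample_id": [f"S{i}" for i in range(6)],
                             "replicate": [1] * 6,
                             "class": ["cancer"] * 3 + ["normal"] * 3})
        out = fs.shapiro_wilk_screen(fs.SpectrumCohort(grid, matrix, meta))
        assert bool(out.loc[0, "undefined"])
        assert np.isnan(out.loc[0, "shapiro_p"])


class TestScreenTable:
    def test_single_class_cohort_rejected(self, tiny_cohort):
        sub = tiny_cohort.subset(tiny_cohort.class_labels == "cancer")
        with pytest.raises(ValueError):
            fs.screen_wavenumbers(sub)

    def test_table_invariants(self, default_screen):
        _, table = default_screen
        assert len(table) == 442
        assert np.all(table["p_holm"] >= table["p_raw"] - 1e-15)
        assert table["p_raw"].between(0, 1).all()
        ranks = table.loc[table["reject"], "rank"].to_numpy()
        assert sorted(ranks) == list(range(1, len(ranks) + 1))
        # ranks follow ascending raw p
        ordered = table.loc[table["reject"]].sort_values("rank")
        assert ordered["p_raw"].is_monotonic_increasing

    def test_rank_invariant_to_monotone_rescaling(self, default_screen):
        """A common monotone transform of all samples' values at one
        wavenumber leaves that wavenumber's test untouched (rank test)."""
        per_sample, table = default_screen
        j = 100
        warped = per_sample.matrix.copy()
        warped[:, j] = np.exp(5 * warped[:, j])
        cohort = fs.SpectrumCohort(per_sample.grid, warped, per_sample.meta,
                                   kind="second_derivative")
        table2 = fs.screen_wavenumbers(cohort)
        assert table2.loc[j, "u_statistic"] == table.loc[j, "u_statistic"]
        assert table2.loc[j, "p_raw"] == pytest.approx(table.loc[j, "p_raw"])


class TestPeakDetection:
    def _second_deriv_of_bands(self, centres, fwhm=12.0, amps=None):
        grid = fs.fingerprint_grid()
        amps = amps or [0.2] * len(centres)
        total = np.zeros(len(grid))
        for c, a in zip(centres, amps):
            total += fs.band_profile(c, fwhm, a, grid)
        spec = fs.Spectrum(grid, total, kind="raw")
        return fs.sg_second_derivative(spec)

    def test_flat_spectrum_gives_empty_table(self):
        spec = fs.Spectrum(fs.fingerprint_grid(), np.zeros(442),
                           kind="second_derivative")
        assert fs.detect_band_centres(spec).empty

    def test_single_band_centre_recovered(self):
        d2 = self._second_deriv_of_bands([1100.0])
        peaks = fs.detect_band_centres(d2, min_prominence=1e-5)
        deepest = peaks.loc[peaks["depth"].idxmax(), "centre"]
        assert abs(deepest - 1100.0) <= GRID_STEP

    def test_two_close_glycogen_bands_resolved(self):
        d2 = self._second_deriv_of_bands([1024.0, 1049.0])
        peaks = fs.detect_band_centres(d2, min_prominence=1e-5)
        for c in (1024.0, 1049.0):
            assert np.min(np.abs(peaks["centre"] - c)) <= GRID_STEP

    def test_sign_flip_swaps_minima_and_maxima(self):
        d2 = self._second_deriv_of_bands([1100.0, 1300.0])
        flipped = fs.Spectrum(d2.grid, -d2.absorbance, kind="second_derivative")
        peaks = fs.detect_band_centres(d2, min_prominence=1e-5)
        anti = fs.detect_band_centres(flipped, min_prominence=1e-5)
        # no centre of the flipped spectrum coincides with an original centre
        for c in anti["centre"]:
            assert np.min(np.abs(peaks["centre"] - c)) > GRID_STEP / 2

    def test_wrong_kind_rejected(self):
        spec = fs.Spectrum(fs.fingerprint_grid(), np.zeros(442), kind="raw")
        with pytest.raises(ValueError):
            fs.detect_band_centres(spec)


class TestMatchingAndPanel:
    def _sig_table(self, rejected_wavenumbers, ranks):
        v = fs.fingerprint_grid().values
        table = pd.DataFrame({"wavenumber": v, "reject": False, "rank": np.nan})
        for w, r in zip(rejected_wavenumbers, ranks):
            j = int(np.argmin(np.abs(v - w)))
            table.loc[j, ["reject", "rank"]] = True, float(r)
        return table

    def _peaks(self, centres):
        return pd.DataFrame({"centre": centres, "depth": 1.0, "prominence": 1.0,
                             "matched_rank": np.nan, "annotation": ""})

    def test_no_rejections_matches_nothing(self):
        table = self._sig_table([], [])
        matched = fs.match_significant_to_peaks(table, self._peaks([1024.0]))
        assert matched.empty

    def test_tolerance_shrink_never_grows_match(self):
        table = self._sig_table([1024.0, 1055.0], [1, 2])
        peaks = self._peaks([1024.0, 1051.0])
        wide = fs.match_significant_to_peaks(table, peaks, tolerance=2 * GRID_STEP)
        narrow = fs.match_significant_to_peaks(table, peaks, tolerance=GRID_STEP / 2)
        assert len(narrow) <= len(wide)
        assert set(narrow["centre"]) <= set(wide["centre"])

    def test_matched_rank_is_best_nearby_rank(self):
        table = self._sig_table([1023.0, 1025.0], [5, 2])
        matched = fs.match_significant_to_peaks(table, self._peaks([1024.0]))
        assert matched.loc[0, "matched_rank"] == 2

    def test_merge_collapses_shifted_band_pair(self):
        a = self._peaks([1049.0, 1656.0])
        b = self._peaks([1051.0, 1654.0])
        merged = fs.merge_peak_tables(a, b)
        assert len(merged) == 2
        assert merged["centre"].tolist() == [1050.0, 1655.0]

    def test_paper_panel_from_six_prominent_peaks(self):
        """The six reported band centres minus the mucin-confounded glycogen
        band 1049 leave the five-wavenumber multivariate panel."""
        matched = self._peaks([964.0, 1024.0, 1049.0, 1411.0, 1577.0, 1656.0])
        matched["matched_rank"] = range(1, 7)
        panel = fs.select_mva_panel(matched)
        assert panel == [964.0, 1024.0, 1411.0, 1577.0, 1656.0]

    def test_no_mucin_refs_or_zero_window_is_identity(self):
        matched = self._peaks([964.0, 1024.0, 1049.0, 1411.0, 1577.0, 1656.0])
        matched["matched_rank"] = range(1, 7)
        assert len(fs.select_mva_panel(matched, mucin_refs=())) == 6
        assert len(fs.select_mva_panel(matched, exclusion_window=0.0)) == 6

    def test_all_excluded_raises_with_diagnostic(self):
        matched = self._peaks([1040.0, 1076.0])
        matched["matched_rank"] = [1, 2]
        with pytest.raises(ValueError, match="mucin"):
            fs.select_mva_panel(matched)
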