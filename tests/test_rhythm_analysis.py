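"""Tests for biharmonic rhythm detection, qPCR normalization and
circular phase statistics."""

import math

import numpy as np
import pandas as pd
import pytest

from circatissue import (
    ExpressionDataset,
    SyntheticSpec,
    biharmonic_fit,
    biharmonic_fit_matrix,
    circular_mode,
    circular_phase_histogram,
    classify_rhythmic,
    generate_expression_matrix,
    normalize_qpcr,
    set_overlap,
    top_by_amplitude,
)

W = 2 * math.pi / 24.0
TIMES_2H = np.arange(0.0, 24.0, 2.0)


class TestBiharmonicFit:
    def test_noiseless_cosine_recovered_exactly(self):
        y = 1.0 + 0.5 * np.cos(W * (TIMES_2H - 4.0))
        fit = biharmonic_fit(TIMES_2H, y)
        assert fit.mean == pytest.approx(1.0, abs=1e-9)
        assert fit.amplitude24 == pytest.approx(0.5, abs=1e-9)
        assert fit.a2 == pytest.approx(0.0, abs=1e-9)
        assert fit.p_value == pytest.approx(0.0, abs=1e-12)
        assert fit.phase == pytest.approx(4.0, abs=0.011)
        assert fit.relative_amplitude == pytest.approx(0.5, abs=1e-3)

    def test_pure_12h_cosine_loads_on_second_harmonic(self):
        y = 2.0 + 0.8 * np.cos(2 * W * TIMES_2H)
        fit = biharmonic_fit(TIMES_2H, y)
        # 24 h terms vanish by orthogonality on the regular grid
        assert abs(fit.a1) < 1e-9 and abs(fit.b1) < 1e-9
        assert fit.a2 == pytest.approx(0.8, abs=1e-9)

    def test_statsmodels_cross_check(self):
        """Coefficients and F-test agree with an independent OLS fit."""
        import statsmodels.api as sm

        rng = np.random.default_rng(3)
        t = np.repeat(TIMES_2H, 2)
        y = 5 + np.cos(W * t) + 0.3 * np.sin(2 * W * t) \
            + rng.normal(0, 0.2, t.size)
        fit = biharmonic_fit(t, y)
        X = sm.add_constant(np.column_stack([
            np.cos(W * t), np.sin(W * t),
            np.cos(2 * W * t), np.sin(2 * W * t)]))
        res = sm.OLS(y, X).fit()
        assert np.allclose([fit.mean, fit.a1, fit.b1, fit.a2, fit.b2],
                           res.params, atol=1e-9)
        assert fit.f_statistic == pytest.approx(res.fvalue, rel=1e-9)
        assert fit.p_value == pytest.approx(res.f_pvalue, rel=1e-6)

    def test_insufficient_samples_rejected(self):
        with pytest.raises(ValueError):
            biharmonic_fit(np.arange(5.0), np.ones(5))

    def test_type_one_error_calibrated_on_null(self):
        """White-noise probes trigger p<0.01 at roughly the nominal rate."""
        rng = np.random.default_rng(12)
        n = 2000
        times = np.repeat(TIMES_2H, 4)
        ds = ExpressionDataset(
            [f"p{i}" for i in range(n)], times,
            np.abs(rng.normal(100, 10, (n, times.size))))
        fits = biharmonic_fit_matrix(ds)
        rate = float((fits["p_value"] < 0.01).mean())
        assert abs(rate - 0.01) < 3 * math.sqrt(0.01 * 0.99 / n)

    def test_planted_rhythm_recovery(self):
        """Planted cosines at 10% CV: high recall, accurate phases."""
        spec = SyntheticSpec(seed=4, n_probes=1000, rhythmic_fraction=0.1,
                             relamp_range=(0.5, 0.5), harmonic_fraction=0.0,
                             noise_cv=0.10)
        ds, truth = generate_expression_matrix(spec)
        fits = biharmonic_fit_matrix(ds)
        rhythmic = set(classify_rhythmic(fits, expression_cutoff=0.0))
        planted = set(truth.index[truth["rhythmic"]])
        recall = len(rhythmic & planted) / len(planted)
        assert recall >= 0.95
        # fundamental phase accuracy at SNR = relamp/CV = 5 on the 2 h grid
        err = []
        for probe in planted:
            diff = (fits.loc[probe, "phase24"]
                    - truth.loc[probe, "phase"] + 12) % 24 - 12
            err.append(abs(diff))
        assert np.median(err) < 0.25


class TestFiltersAndRanking:
    @staticmethod
    def _fits(rows):
        return pd.DataFrame(rows, columns=["p_value", "relative_amplitude",
                                           "max_expression"],
                            index=[f"p{i}" for i in range(len(rows))])

    def test_all_cutoffs_strict(self):
        fits = self._fits([
            (0.005, 0.5, 700.0),   # passes all
            (0.005, 0.3, 700.0),   # relamp at the boundary -> excluded
            (0.005, 0.5, 600.0),   # expression at the boundary -> excluded
            (0.010, 0.5, 700.0),   # p at the boundary -> excluded
        ])
        assert classify_rhythmic(fits) == ["p0"]

    def test_top_by_amplitude_edges_and_order(self):
        rng = np.random.default_rng(0)
        amp = rng.uniform(0, 1, 50)
        fits = pd.DataFrame({"relative_amplitude": amp},
                            index=[f"p{i:02d}" for i in range(50)])
        ids = list(fits.index)
        assert top_by_amplitude(fits, ids, k=0) == []
        assert set(top_by_amplitude(fits, ids, k=100)) == set(ids)
        top10 = top_by_amplitude(fits, ids, k=10)
        expected = list(fits["relative_amplitude"]
                        .sort_values(ascending=False).index[:10])
        assert top10 == expected

    def test_top_by_amplitude_tie_break_lexicographic(self):
        fits = pd.DataFrame({"relative_amplitude": [0.5, 0.5, 0.5]},
                            index=["b", "a", "c"])
        assert top_by_amplitude(fits, list(fits.index), k=2) == ["a", "b"]

    def test_set_overlap(self):
        assert set_overlap(["a", "b"], ["c"]) == []
        assert set_overlap(["a", "b"], ["b", "a"]) == ["a", "b"]
        # planted shared fraction between two synthetic "tissues"
        rng = np.random.default_rng(1)
        probes = [f"p{i}" for i in range(1000)]
        shared = list(rng.choice(probes, 150, replace=False))
        rest = [p for p in probes if p not in shared]
        set_a = shared + rest[:350]
        set_b = shared + rest[350:700]
        assert len(set_overlap(set_a, set_b)) == 150


class TestCircularHistogram:
    def test_single_phase_occupies_four_bins(self):
        hist = circular_phase_histogram([0.0])
        nz = hist[hist["count"] > 0]
        assert len(nz) == 4
        assert hist["count"].sum() == 4
        assert set(nz["bin_center_CT"]) == {23.0, 0.0, 1.0, 2.0}

    def test_uniform_phases_fill_bins_evenly(self):
        phases = np.arange(0, 24, 0.125)
        hist = circular_phase_histogram(phases)
        assert hist["count"].nunique() == 1

    def test_mass_conservation(self):
        rng = np.random.default_rng(8)
        phases = rng.uniform(0, 24, 537)
        hist = circular_phase_histogram(phases)
        assert hist["count"].sum() == 4 * len(phases)

    def test_wraparound_membership_matches_brute_force(self):
        rng = np.random.default_rng(9)
        phases = np.concatenate([rng.uniform(0, 24, 200), [23.9, 0.05]])
        hist = circular_phase_histogram(phases)
        for center, count in zip(hist["bin_center_CT"], hist["count"]):
            # independent membership rule: circular distance from the bin
            # start, half-open interval of length 4
            members = sum(
                1 for ph in phases
                if ((ph - (center - 2.0)) % 24.0) < 4.0)
            assert count == members
        # the 23.9 phase must be counted in the bin centered at CT 0
        c0 = int(hist.loc[hist["bin_center_CT"] == 0.0, "count"].iloc[0])
        assert c0 >= sum(1 for p in phases if p >= 22.0 or p < 2.0)

    def test_mode_earliest_tie(self):
        # phase 6.0 falls in the four half-open bins centered 5..8;
        # ties resolve to the earliest center
        assert circular_mode([6.0]) == 5.0


class TestQPCRNormalization:
    REFS = ["Hmbs", "Eif2a", "Ppib"]

    def _table(self, genes, samples, cp):
        return pd.DataFrame(cp, index=genes, columns=samples)

    def test_identical_cp_gives_identical_quantities(self):
        genes = ["g1"] + self.REFS
        cp = self._table(genes, ["s1", "s2", "s3"],
                         np.full((4, 3), 25.0))
        eff = {g: 2.0 for g in genes}
        out = normalize_qpcr(cp, eff, self.REFS)
        assert np.allclose(out.loc["g1"], out.loc["g1"].iloc[0])

    def test_one_cycle_doubles_quantity(self):
        genes = ["g1"] + self.REFS
        cp = np.full((4, 2), 25.0)
        cp[0, 1] = 24.0          # one cycle fewer in sample 2
        out = normalize_qpcr(self._table(genes, ["s1", "s2"], cp),
                             {g: 2.0 for g in genes}, self.REFS,
                             rescale="none")
        assert out.loc["g1", "s2"] / out.loc["g1", "s1"] == pytest.approx(2.0)

    def test_reference_drift_removed(self):
        """Per-sample loading drift cancels through the reference genes."""
        from circatissue import generate_qpcr_dataset

        rng = np.random.default_rng(2)
        samples = [f"s{i}" for i in range(12)]
        t = np.arange(0, 24, 2.0)
        true = pd.DataFrame(
            {s: [1 + 0.5 * math.cos(W * (ti - 6)),
                 1 + 0.3 * math.cos(W * (ti - 15))]
             for s, ti in zip(samples, t)},
            index=["gA", "gB"])
        eff = {g: 1.95 for g in ["gA", "gB"] + self.REFS}
        drift = rng.uniform(0.5, 2.0, len(samples))
        cp = generate_qpcr_dataset(true, eff, self.REFS,
                                   reference_drift=drift, seed=0)
        out = normalize_qpcr(cp, eff, self.REFS, rescale="none")
        for g in ["gA", "gB"]:
            assert np.corrcoef(out.loc[g], true.loc[g])[0, 1] > 0.9999

    def test_sample_missing_reference_dropped_with_warning(self):
        genes = ["g1"] + self.REFS
        cp = self._table(genes, ["s1", "s2"], np.full((4, 2), 20.0))
        cp.loc["Hmbs", "s2"] = np.nan
        with pytest.warns(UserWarning):
            out = normalize_qpcr(cp, {g: 2.0 for g in genes}, self.REFS)
        assert list(out.columns) == ["s1"]

    def test_invalid_efficiency_rejected(self):
        genes = ["g1"] + self.REFS
        cp = self._table(genes, ["s1"], np.full((4, 1), 20.0))
        with pytest.raises(ValueError):
            normalize_qpcr(cp, {g: 2.5 for g in genes}, self.REFS)
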