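"""Tests for clock-controlled gene simulation and harmonics generation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from circatissue import (
    CCGParameters,
    DboxDrive,
    EboxDrive,
    GENES,
    HarmonicSpec,
    RREDrive,
    Trajectory,
    ccg_peak_phase,
    dominant_period,
    fit_ccg_to_target,
    harmonic_expansion,
    harmonic_product,
    sample_ccg_population,
    simulate_ccg,
)
from circatissue.ccg_simulator import _drive_linear

W = 2 * math.pi / 24.0


def _flat_clock(rev_level=0.5, t_end=480.0, dt=0.05):
    t = np.arange(0, t_end + dt / 2, dt)
    values = np.ones((t.size, 5))
    values[:, GENES.index("Rev-erba")] = rev_level
    return Trajectory(t, values, GENES, dt, {"transient": 240.0})


class TestLinearDrive:
    def test_relaxation_to_constant_matches_closed_form(self):
        dt, d = 0.05, 0.3
        t = np.arange(0, 40 + dt / 2, dt)
        m = np.full(t.size, 2.0)
        c = _drive_linear(m, d, dt, c0=0.0)
        assert np.allclose(c, 2.0 * (1 - np.exp(-d * t)), atol=1e-9)

    @pytest.mark.parametrize("d", [0.1, 0.2, 0.4, 0.6, 1.0])
    def test_linear_response_lag_matches_arctan_formula(self, d):
        """Peak of the response lags the drive by arctan(w/d)/w."""
        dt = 0.01
        t = np.arange(0, 480 + dt / 2, dt)
        m = 1.0 + 0.5 * np.cos(W * (t - 10.0))
        c = _drive_linear(m, d, dt)
        tail = t >= 240
        tt, cc = t[tail], c[tail]
        from circatissue.core_model import _gene_peaks
        pk_t, _ = _gene_peaks(tt, cc, dt)
        lag = (pk_t[-1] - 10.0) % 24.0
        expected = math.atan(W / d) / W
        assert lag == pytest.approx(expected, abs=0.1)


class TestSimulateCCG:
    def test_constant_repressor_gives_steady_state(self):
        clock = _flat_clock(rev_level=0.8)
        ccg = CCGParameters(d_ccg=0.4,
                            rre=RREDrive(strength=3.0, site_count=2,
                                         delay=2.0))
        traj = simulate_ccg(clock, ccg)
        expected = (1 + 3.0 * 0.8) ** (-2)
        assert traj.values[-1, 0] == pytest.approx(expected, rel=1e-6)
        # flat output is flagged by a NaN phase
        assert math.isnan(ccg_peak_phase(traj, _FakeDesc()))

    def test_missing_driver_species_rejected(self):
        t = np.arange(0, 480.05, 0.05)
        traj = Trajectory(t, np.ones((t.size, 2)), ("Bmal1", "Dbp"), 0.05)
        with pytest.raises(ValueError):
            simulate_ccg(traj, CCGParameters(rre=RREDrive()))

    def test_increasing_degradation_advances_peak(
            self, default_clock, default_descriptors):
        """Faster mRNA turnover means less decay lag, earlier peaks."""
        phases = []
        for d in (0.2, 0.3, 0.4, 0.5, 0.6):
            ccg = CCGParameters(d_ccg=d, rre=RREDrive(strength=5.0,
                                                      delay=2.0))
            ph = ccg_peak_phase(simulate_ccg(default_clock, ccg),
                                default_descriptors)
            phases.append(ph)
        diffs = [(a - b) % 24 for a, b in zip(phases[:-1], phases[1:])]
        assert all(0 < d < 12 for d in diffs)
        # the 0.2 -> 0.6 advance approximates the linear-response lag gap
        lag_gap = (math.atan(W / 0.2) - math.atan(W / 0.6)) / W
        assert (phases[0] - phases[-1]) % 24 == pytest.approx(lag_gap,
                                                              abs=1.0)


class _FakeDesc:
    period = 24.0
    anchor_time = 0.0

    def ct(self, t):
        return np.asarray(t, float) % 24.0


class TestPopulations:
    def test_seed_reproducibility(self, default_clock, default_descriptors):
        a = sample_ccg_population(default_clock, default_descriptors,
                                  driver="rre", n=40, seed=5)
        b = sample_ccg_population(default_clock, default_descriptors,
                                  driver="rre", n=40, seed=5)
        assert np.array_equal(a.phases, b.phases)

    def test_mode_stable_between_seeds(self, default_clock,
                                       default_descriptors):
        a = sample_ccg_population(default_clock, default_descriptors,
                                  driver="rre", n=250, seed=1)
        b = sample_ccg_population(default_clock, default_descriptors,
                                  driver="rre", n=250, seed=2)
        diff = abs((a.mode() - b.mode() + 12) % 24 - 12)
        assert diff <= 1.0

    def test_rre_and_ebox_modes_well_separated(self, default_clock,
                                               default_descriptors):
        rre = sample_ccg_population(default_clock, default_descriptors,
                                    driver="rre", n=120, seed=3)
        ebox = sample_ccg_population(default_clock, default_descriptors,
                                     driver="ebox", n=120, seed=3)
        diff = abs((rre.mode() - ebox.mode() + 12) % 24 - 12)
        assert diff > 6.0

    def test_excluded_flat_genes_are_counted(self, default_clock,
                                             default_descriptors):
        pop = sample_ccg_population(default_clock, default_descriptors,
                                    driver="rre", n=30, seed=4,
                                    strength_range=(1e-3, 2e-3))
        assert pop.n_excluded + len(pop.phases) == 30


class TestCCGTargetFitting:
    def test_self_consistency_recovers_phase(self, default_clock,
                                             default_descriptors):
        # a gene drawn from within the default sampling scheme
        known = CCGParameters(d_ccg=0.35,
                              rre=RREDrive(strength=0.08, delay=2.2))
        traj = simulate_ccg(default_clock, known)
        target_phase = ccg_peak_phase(traj, default_descriptors)
        from circatissue.ccg_simulator import ccg_relative_amplitude
        target_relamp = ccg_relative_amplitude(traj, default_descriptors)
        res = fit_ccg_to_target(default_clock, default_descriptors,
                                target_phase, target_relamp,
                                drivers=("rre",), n_candidates=250, seed=8)
        assert res
        err = abs((res.phase - target_phase + 12) % 24 - 12)
        assert err < 0.5

    def test_rre_cannot_reach_midday_but_ebox_can(self, default_clock,
                                                  default_descriptors):
        """An RRE-only promoter cannot produce a mid-day peak; adding an
        E-box makes the same target reachable."""
        rre_mode = sample_ccg_population(
            default_clock, default_descriptors, "rre", n=60,
            seed=0).mode()
        target = (rre_mode + 8.0) % 24.0     # far from anything RRE can do
        res = fit_ccg_to_target(default_clock, default_descriptors, target,
                                0.5, drivers=("rre",), n_candidates=150,
                                seed=9)
        assert not res
        res2 = fit_ccg_to_target(default_clock, default_descriptors, target,
                                 0.5, drivers=("ebox", "rre"),
                                 n_candidates=300, seed=9)
        assert res2


class TestHarmonics:
    @given(A=st.floats(0, 1), alpha=st.floats(0, 360))
    @settings(deadline=None, max_examples=100, derandomize=True)
    def test_product_equals_expansion(self, A, alpha):
        spec = HarmonicSpec(amplitude=A, phase_shift_deg=alpha)
        t = np.linspace(0, 96, 777)
        assert np.allclose(harmonic_product(spec, t),
                           harmonic_expansion(spec, t), atol=1e-12)

    def test_out_of_phase_unit_amplitude_gives_12h(self):
        spec = HarmonicSpec(amplitude=1.0, phase_shift_deg=180.0)
        t = np.arange(0, 96.05, 0.1)
        assert dominant_period((t, harmonic_product(spec, t))) == 12.0

    def test_no_second_regulator_gives_24h(self):
        spec = HarmonicSpec(amplitude=0.0)
        t = np.arange(0, 96.05, 0.1)
        assert dominant_period((t, harmonic_product(spec, t))) == 24.0

    def test_flat_signal_has_undefined_period(self):
        t = np.arange(0, 96.05, 0.1)
        assert math.isnan(dominant_period((t, np.ones_like(t))))

    def test_short_series_rejected(self):
        t = np.arange(0, 48, 0.1)
        with pytest.raises(ValueError):
            dominant_period((t, np.sin(W * t)))

    def test_out_of_phase_dbox_ebox_ccg_generates_harmonic(
            self, default_clock, default_descriptors):
        """A CCG with matched-strength antiphase drivers shows a dominant
        12 h component (combinatorial-harmonics regime located by a scan
        over relative strength; see the grid in this test)."""
        from circatissue import ClockParameters

        p = ClockParameters()
        best = None
        for s_e, f_e in ((0.5, 6.0), (1.0, 6.0), (2.0, 3.0)):
            for s_d, f_d in ((0.5, 3.0), (1.0, 6.0), (2.0, 6.0)):
                for delay in (9.5, 10.5):
                    ccg = CCGParameters(
                        d_ccg=2.0,
                        ebox=EboxDrive(activator_strength=s_e,
                                       per_strength=0.5, cry_strength=2.0,
                                       fold=f_e, site_count=1,
                                       delay_bmal1=p.tau_bmal1,
                                       delay_per2=p.tau_per2,
                                       delay_cry1=p.tau_cry1),
                        dbox=DboxDrive(strength=s_d, fold=f_d, site_count=1,
                                       delay=delay))
                    traj = simulate_ccg(default_clock, ccg)
                    sub = traj.after(traj.transient)
                    period = dominant_period((sub.time, sub.values[:, 0]))
                    if period == 12.0:
                        best = (s_e, s_d, delay)
        assert best is not None
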