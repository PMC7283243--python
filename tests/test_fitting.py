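"""Estimators: round trips, cross-checks against simpler oracles, flags."""

import math
import warnings

import numpy as np
import pytest

from tnfkin.errors import FitError, FlatTraceError, IdentifiabilityWarning
from tnfkin.fitting import (
    fit_biexp_global,
    fit_dissociation_single,
    fit_monomerization,
    fit_titration,
    global_fit_association,
    global_fit_dissociation,
    kinetics_report,
    normalize_trace,
    select_decay_model,
)
from tnfkin.models import BiExpFit, Phase, Trace
from tnfkin.synthdata import (
    NoiseModel,
    gen_biexp_trace,
    gen_kinetic_series,
    gen_mono_trace,
    gen_titration,
)

CONCS = [1e-9, 2e-9, 4e-9, 8e-9]


def _split(traces):
    assoc = [t for t in traces if t.phase is Phase.ASSOCIATION]
    dissoc = [t for t in traces if t.phase is Phase.DISSOCIATION]
    return assoc, dissoc


class TestNormalize:
    def _tr(self, y):
        t = np.linspace(0, 10, len(y))
        return Trace(t=t, y=np.asarray(y, float), phase=Phase.DISSOCIATION)

    def test_initial_value_mode_and_idempotence(self):
        tr = self._tr([2.0, 1.0, 0.5, 0.25])
        n1 = normalize_trace(tr, "initial_value")
        assert n1.y[0] == 1.0
        n2 = normalize_trace(n1, "initial_value")
        np.testing.assert_array_equal(n1.y, n2.y)

    def test_scale_invariance(self):
        y = np.array([2.0, 1.5, 1.0, 0.8])
        a = normalize_trace(self._tr(y), "baseline")
        b = normalize_trace(self._tr(5 * y), "baseline")
        np.testing.assert_allclose(a.y, b.y, rtol=1e-14)

    def test_zero_trace_raises(self):
        with pytest.raises(FlatTraceError):
            normalize_trace(self._tr([0.0, 0.0, 0.0, 0.0]), "initial_value")

    def test_baseline_window_selection(self):
        tr = self._tr([2.0, 2.0, 4.0, 4.0])
        n = normalize_trace(tr, "baseline", baseline_window=(0.0, 3.5))
        assert n.y[0] == pytest.approx(1.0)
        with pytest.raises(ValueError):
            normalize_trace(tr, "baseline", baseline_window=(100.0, 101.0))

    def test_unknown_mode(self):
        with pytest.raises(ValueError):
            normalize_trace(self._tr([1, 2, 3.0]), "zscore")


class TestMonomerizationFit:
    def test_noiseless_roundtrip(self, mono_grid):
        tr = gen_mono_trace(1.66e-3, 1.0, 1.0, mono_grid)
        fit = fit_monomerization(tr)
        assert fit.k == pytest.approx(1.66e-3, rel=1e-3)
        assert fit.A == pytest.approx(1.0, rel=1e-3)
        assert fit.y0 == pytest.approx(1.0, rel=1e-3)

    def test_tetraplicate_sem_matches_hand_formula(self, mono_grid):
        ks = []
        for seed in range(4):
            tr = gen_mono_trace(1.66e-3, 1.0, 1.0, mono_grid,
                                NoiseModel(0.01, seed))
            ks.append(fit_monomerization(tr).k)
        ks = np.array(ks)
        sem = ks.std(ddof=1) / math.sqrt(4)
        # the hand formula sd/√n on the same numbers
        sd = math.sqrt(((ks - ks.mean()) ** 2).sum() / 3)
        assert sem == pytest.approx(sd / 2, rel=1e-12)

    def test_flat_trace_raises_not_tiny_rate(self, mono_grid):
        flat = Trace(t=mono_grid, y=np.full_like(mono_grid, 0.7),
                     phase=Phase.MONOMERIZATION)
        with pytest.raises(FlatTraceError):
            fit_monomerization(flat)
        noisy_flat = Trace(
            t=mono_grid,
            y=0.7 + np.random.default_rng(0).normal(0, 0.01, mono_grid.size),
            phase=Phase.MONOMERIZATION,
        )
        with pytest.raises(FlatTraceError):
            fit_monomerization(noisy_flat)

    def test_wrong_phase_rejected(self, mono_grid):
        tr = Trace(t=mono_grid, y=np.exp(-1e-3 * mono_grid),
                   phase=Phase.DISSOCIATION)
        with pytest.raises(ValueError):
            fit_monomerization(tr)


class TestGlobalDissociation:
    def test_noiseless_roundtrip(self):
        _, dissoc = _split(gen_kinetic_series(CONCS, 2.82e6, 8.52e-5))
        fit = global_fit_dissociation(dissoc)
        assert fit.k_off == pytest.approx(8.52e-5, rel=1e-3)

    def test_global_equals_per_curve_on_identical_traces(self, dissoc_grid):
        tr = gen_mono_trace(8.52e-5, -0.8, 0.0, dissoc_grid,
                            phase=Phase.DISSOCIATION)
        copies = [
            Trace(t=tr.t, y=tr.y, phase=tr.phase, replicate_id=f"r{i}")
            for i in range(3)
        ]
        glob = global_fit_dissociation(copies)
        single = fit_dissociation_single(copies[0])
        assert glob.k_off == pytest.approx(single.k, rel=1e-6)
        for k in glob.per_trace_k_off:
            assert k == pytest.approx(single.k, rel=1e-9)

    def test_single_trace_warns(self, dissoc_grid):
        tr = gen_mono_trace(8.52e-5, -0.8, 0.0, dissoc_grid,
                            phase=Phase.DISSOCIATION)
        with pytest.warns(IdentifiabilityWarning):
            global_fit_dissociation([tr])

    def test_low_bias_at_one_percent_noise(self):
        # bias of the pooled k_off over seeds stays well under 2%
        koffs = []
        for seed in range(30):
            _, dissoc = _split(
                gen_kinetic_series(CONCS, 2.82e6, 8.52e-5,
                                   noise=NoiseModel(0.01, seed))
            )
            koffs.append(global_fit_dissociation(dissoc).k_off)
        bias = abs(np.mean(koffs) / 8.52e-5 - 1)
        assert bias < 0.02


class TestGlobalAssociation:
    def test_noiseless_roundtrip(self):
        assoc, _ = _split(gen_kinetic_series(CONCS, 8.22e6, 7.96e-5))
        fit = global_fit_association(assoc, 7.96e-5)
        assert fit.k_on == pytest.approx(8.22e6, rel=1e-3)

    def test_kobs_regression_cross_check(self):
        # slope of k_obs vs c must match k_on; intercept ≈ k_off
        assoc, _ = _split(
            gen_kinetic_series(CONCS, 2.82e6, 8.52e-5,
                               noise=NoiseModel(0.005, 11))
        )
        fit = global_fit_association(assoc, 8.52e-5)
        slope, intercept = np.polyfit(CONCS, fit.k_obs, 1)
        assert slope == pytest.approx(fit.k_on, rel=1e-9)
        assert intercept == pytest.approx(8.52e-5, rel=1e-6)

    def test_zero_concentration_rejected(self, mono_grid):
        tr = Trace(t=mono_grid, y=np.zeros_like(mono_grid),
                   phase=Phase.ASSOCIATION, conc=0.0)
        with pytest.raises(ValueError):
            global_fit_association([tr], 8.52e-5)

    def test_equal_concentrations_warn(self):
        t = np.arange(0.0, 260.1, 1.0)
        trs = [
            Trace(t=t, y=1 - np.exp(-3e-3 * t), phase=Phase.ASSOCIATION,
                  conc=1e-9, replicate_id=f"r{i}")
            for i in range(2)
        ]
        with pytest.warns(IdentifiabilityWarning):
            global_fit_association(trs, 8.52e-5)


class TestBiexpGlobal:
    P = BiExpFit(1.42e-3, 8.52e-5, 0.5, 0.5, 1.0)

    def test_noiseless_two_trace_roundtrip(self, dissoc_grid):
        trs = [
            gen_biexp_trace(self.P, f, dissoc_grid, replicate_id=f"r{f}")
            for f in (0.4, 0.6)
        ]
        fit = fit_biexp_global(trs)
        assert fit.k_fast == pytest.approx(1.42e-3, rel=5e-3)
        assert fit.k_slow == pytest.approx(8.52e-5, rel=5e-3)
        assert not fit.effective_mono

    def test_pure_slow_flagged_mono(self, dissoc_grid):
        tr = gen_biexp_trace(self.P, 1.0, dissoc_grid,
                             noise=NoiseModel(0.005, 3))
        fit = fit_biexp_global([tr])
        assert fit.effective_mono
        assert fit.k_slow == pytest.approx(8.52e-5, rel=0.05)

    def test_recovery_within_printed_uncertainty_at_noise(self, dissoc_grid):
        # k_fast 1.42±0.39e-3, k_slow 8.52±0.28e-5: 1% noise keeps both inside
        tr = gen_biexp_trace(self.P, 0.5, dissoc_grid, noise=NoiseModel(0.01, 5))
        fit = fit_biexp_global([tr])
        assert abs(fit.k_fast - 1.42e-3) < 0.39e-3
        assert abs(fit.k_slow - 8.52e-5) < 0.28e-5


class TestModelSelection:
    def test_pure_mono_selected(self, dissoc_grid):
        tr = gen_mono_trace(8.52e-5, -0.8, 0.0, dissoc_grid,
                            phase=Phase.DISSOCIATION)
        sel = select_decay_model(tr)
        assert sel.decision == "mono"

    def test_mono_preferred_under_noise(self):
        # false-positive rate of the combined AICc+F criterion on mono data
        t = np.arange(0.0, 18_000.1, 30.0)
        hits = 0
        for seed in range(100):
            tr = gen_mono_trace(8.52e-5, -0.8, 0.0, t,
                                noise=NoiseModel(0.01, seed),
                                phase=Phase.DISSOCIATION)
            if select_decay_model(tr).decision == "mono":
                hits += 1
        assert hits >= 95

    def test_well_separated_biexp_detected(self, dissoc_grid):
        # rate ratio ≈ 16.7 with equal amplitudes is clearly biphasic
        p = BiExpFit(1.42e-3, 8.52e-5, 0.5, 0.5, 1.0)
        tr = gen_biexp_trace(p, 0.5, dissoc_grid, noise=NoiseModel(0.01, 2))
        assert select_decay_model(tr).decision == "bi"

    def test_rate_ratio_near_one_collapses_to_mono(self, dissoc_grid):
        p = BiExpFit(9.0e-5, 8.52e-5, 0.5, 0.5, 1.0)
        tr = gen_biexp_trace(p, 0.5, dissoc_grid, noise=NoiseModel(0.01, 9))
        assert select_decay_model(tr).decision == "mono"

    def test_too_short_rejected(self):
        tr = Trace(t=np.arange(5.0), y=np.exp(-np.arange(5.0)),
                   phase=Phase.DISSOCIATION)
        with pytest.raises(ValueError):
            select_decay_model(tr)


class TestTitrationFit:
    def test_noiseless_roundtrip(self, titration_grid):
        tab = gen_titration(100e-12, 53.6e-12, titration_grid)
        res = fit_titration(tab, 100e-12, n_boot=50, seed=0)
        assert res.kd == pytest.approx(53.6e-12, rel=0.01)
        assert not res.is_bound

    def test_order_invariance(self, titration_grid):
        tab = gen_titration(100e-12, 53.6e-12, titration_grid,
                            noise=NoiseModel(0.01, 4))
        shuffled = tab.sample(frac=1.0, random_state=1).reset_index(drop=True)
        a = fit_titration(tab, 100e-12, n_boot=50, seed=0)
        b = fit_titration(shuffled, 100e-12, n_boot=50, seed=0)
        assert a.kd == pytest.approx(b.kd, rel=1e-9)

    def test_uniform_rescaling_absorbed_by_amplitude(self, titration_grid):
        tab = gen_titration(100e-12, 53.6e-12, titration_grid,
                            noise=NoiseModel(0.01, 4))
        scaled = tab.assign(response=3.0 * tab["response"])
        a = fit_titration(tab, 100e-12, n_boot=50, seed=0)
        b = fit_titration(scaled, 100e-12, n_boot=50, seed=0)
        assert b.kd == pytest.approx(a.kd, rel=1e-6)
        assert b.amplitude == pytest.approx(3.0 * a.amplitude, rel=1e-6)

    def test_depletion_limited_reports_upper_bound(self, titration_grid):
        # kd far below rt: only "K_D < x" is supportable
        tab = gen_titration(500e-12, 10e-12, titration_grid,
                            noise=NoiseModel(0.01, 6))
        res = fit_titration(tab, 500e-12, n_boot=100, seed=0)
        assert res.is_bound
        assert res.kd_upper < 0.2 * 500e-12

    def test_input_validation(self, titration_grid):
        tab = gen_titration(100e-12, 53.6e-12, titration_grid)
        with pytest.raises(ValueError):
            fit_titration(tab.iloc[:0], 100e-12)
        with pytest.raises(ValueError):
            fit_titration(tab.iloc[:4], 100e-12)
        with pytest.raises(ValueError):
            fit_titration(tab, 0.0)


class TestKineticsReport:
    def test_table_style_assembly(self):
        traces = gen_kinetic_series(CONCS, 2.82e6, 8.52e-5)
        assoc, dissoc = _split(traces)
        d = global_fit_dissociation(dissoc)
        a = global_fit_association(assoc, d.k_off)
        rep = kinetics_report(a, d)
        assert rep.kd * 1e12 == pytest.approx(30.2, abs=0.1)
        assert rep.kd * rep.k_on == pytest.approx(rep.k_off, rel=1e-12)

    def test_sem_of_per_trace_koff_hand_computed(self):
        from tnfkin.fitting import AssociationFit, DissociationFit

        d = DissociationFit(k_off=4.6e-5, se_k_off=0.0, amplitudes=(1,),
                            offsets=(0,), per_trace_k_off=(4.0e-5, 5.0e-5, 4.8e-5))
        a = AssociationFit(k_on=1e6, se_k_on=0.0, amplitudes=(1,), offsets=(0,))
        rep = kinetics_report(a, d)
        mean = (4.0e-5 + 5.0e-5 + 4.8e-5) / 3
        sd = math.sqrt(
            sum((x - mean) ** 2 for x in (4.0e-5, 5.0e-5, 4.8e-5)) / 2
        )
        assert rep.se_k_off == pytest.approx(sd / math.sqrt(3), rel=1e-12)
        assert rep.se_k_off == pytest.approx(3.06e-6, rel=0.01)

    def test_single_trace_sem_absent(self):
        from tnfkin.fitting import AssociationFit, DissociationFit

        d = DissociationFit(k_off=4.6e-5, se_k_off=1e-6, amplitudes=(1,),
                            offsets=(0,), per_trace_k_off=(4.6e-5,))
        a = AssociationFit(k_on=1e6, se_k_on=0.0, amplitudes=(1,), offsets=(0,))
        assert kinetics_report(a, d).se_k_off == 0.0
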