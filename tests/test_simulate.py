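"""Forward-simulator behavior: quenching law, compartment kinetics, waveform
construction, whole-tubule series and axial uptake."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lysoscan.scenarios import (CompartmentSpec, KineticPhase, LabelingSpec,
                                Scenario, healthy_s1, e64_inhibited, ocrl_like,
                                separable_scenario)
from lysoscan.simulate import (compartment_time_course, degraded_brightness,
                               ideal_waveform, intact_brightness,
                               s1_degradation_component, simulate_axial_uptake,
                               simulate_profiles, simulate_tubule_series,
                               simulate_waveform, unquench_gain)


class TestUnquenchGain:
    def test_single_fluorophore_cannot_self_quench(self):
        assert unquench_gain(LabelingSpec(n_labels=1, quench_q=0.6)) == 1.0

    def test_no_quenching_at_q_one(self):
        assert unquench_gain(LabelingSpec(n_labels=4, quench_q=1.0)) == 1.0

    def test_gain_is_q_to_one_minus_n(self):
        gain = unquench_gain(LabelingSpec(n_labels=4, quench_q=0.6))
        assert gain == pytest.approx(0.6 ** -3, rel=1e-12)

    def test_brightness_ratio_is_gain(self):
        lab = LabelingSpec(n_labels=5, quench_q=0.7)
        assert degraded_brightness(lab) / intact_brightness(lab) == pytest.approx(
            unquench_gain(lab))

    @given(q=st.floats(0.05, 0.95))
    @settings(deadline=None, derandomize=True)
    def test_gain_strictly_increases_with_labeling_density(self, q):
        gains = [unquench_gain(LabelingSpec(n_labels=n, quench_q=q))
                 for n in range(1, 8)]
        assert all(b > a for a, b in zip(gains, gains[1:]))


class TestCompartmentTimeCourse:
    lab = LabelingSpec(n_labels=1)  # brightness 1: raw phase amplitudes

    def comp(self, **phase_kw):
        defaults = dict(onset=10.0, rise_tau=2.0, decay_tau=math.inf,
                        amplitude=1.0)
        defaults.update(phase_kw)
        return CompartmentSpec("C", 0.5, 0.1, (KineticPhase(**defaults),))

    def test_zero_amplitude_gives_zero_vector(self):
        t = np.linspace(0, 60, 61)
        tc = compartment_time_course(self.comp(amplitude=0.0), t, self.lab)
        assert np.all(tc == 0)

    def test_causality_before_onset(self):
        t = np.linspace(0, 9, 10)
        tc = compartment_time_course(self.comp(onset=10.0), t, self.lab)
        assert np.all(tc == 0)

    def test_saturating_rise_closed_form(self):
        # onset 10, rise 2, plateau: value at t=12 is 1 - 1/e
        t = np.array([0.0, 12.0])
        tc = compartment_time_course(self.comp(), t, self.lab)
        assert tc[1] == pytest.approx(1 - math.exp(-1), rel=1e-12)

    def test_nonincreasing_times_rejected(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            compartment_time_course(self.comp(), np.array([0.0, 5.0, 5.0]),
                                    self.lab)

    def test_gated_phase_zeroed_under_inhibition(self):
        spec = self.comp(gated_by_unquenching=True)
        t = np.linspace(0, 60, 61)
        assert np.all(compartment_time_course(spec, t, self.lab,
                                              cathepsin_inhibited=True) == 0)
        assert compartment_time_course(spec, t, self.lab).max() > 0

    def test_gated_to_intact_amplitude_ratio_is_unquench_gain(self):
        lab = LabelingSpec(n_labels=4, quench_q=0.6)
        t = np.linspace(0, 60, 61)
        gated = compartment_time_course(self.comp(gated_by_unquenching=True),
                                        t, lab)
        intact = compartment_time_course(self.comp(), t, lab)
        ratio = gated[t > 10] / intact[t > 10]
        assert ratio == pytest.approx(unquench_gain(lab), rel=1e-12)


class TestWaveform:
    def test_single_compartment_is_outer_product(self):
        scen = separable_scenario(rank=1)
        wf = simulate_waveform(scen)
        s = np.linalg.svd(wf.values, compute_uv=False)
        assert s[1] == pytest.approx(0.0, abs=1e-10 * s[0])

    def test_same_seed_bit_identical(self):
        a = simulate_waveform(healthy_s1(seed=7))
        b = simulate_waveform(healthy_s1(seed=7))
        assert np.array_equal(a.values, b.values)

    def test_linearity_of_noiseless_mixture(self):
        scen2 = separable_scenario(rank=2)
        both = ideal_waveform(scen2)
        parts = [ideal_waveform(scen2.replace(compartments=(c,)))
                 for c in scen2.compartments]
        assert np.allclose(both, parts[0] + parts[1], atol=1e-12)

    @pytest.mark.parametrize("rank", [1, 2, 3, 4])
    def test_noiseless_rank_matches_eigendecomposition_oracle(self, rank):
        A = ideal_waveform(separable_scenario(rank=rank))
        ev = np.linalg.eigvalsh(A.T @ A)[::-1]
        numerical_rank = int(np.sum(ev > ev[0] * 1e-10))
        assert numerical_rank == rank

    def test_healthy_noiseless_rank_equals_three_compartments(self):
        A = ideal_waveform(healthy_s1().replace(noise_sigma=0.0))
        ev = np.linalg.eigvalsh(A.T @ A)[::-1]
        assert int(np.sum(ev > ev[0] * 1e-10)) == 3

    def test_inhibitor_removes_lysosome_energy(self):
        # with cathepsin inhibited the lysosome compartment contributes nothing
        scen = e64_inhibited().replace(noise_sigma=0.0)
        lys = [c for c in scen.compartments if c.name == "LYS"]
        contribution = ideal_waveform(scen.replace(compartments=tuple(lys)))
        assert np.all(contribution == 0)

    def test_empty_compartments_rejected(self):
        with pytest.raises(ValueError, match="at least one compartment"):
            Scenario(compartments=())

    def test_profiles_deterministic_and_bounded(self):
        scen = healthy_s1(seed=3).replace(n_timepoints=5, n_profiles=4)
        p1 = simulate_profiles(scen)
        p2 = simulate_profiles(scen)
        assert len(p1) == 5 * 4
        assert all(np.array_equal(a.intensities, b.intensities)
                   for a, b in zip(p1, p2))
        assert all(a.intensities.min() >= 0 for a in p1)


class TestTubuleSeries:
    def test_zero_uptake_gives_zero_tubular_signals(self):
        series = simulate_tubule_series(healthy_s1(seed=2).replace(uptake_scale=0.0))
        for seg in ("S1", "S2", "DT_lumen"):
            assert np.all(series[seg].intensities == 0)

    def test_inhibitor_suppresses_downstream_signals(self):
        ctrl = simulate_tubule_series(healthy_s1(seed=4))
        inhib = simulate_tubule_series(e64_inhibited(seed=4))
        for seg in ("S2", "DT_lumen"):
            assert inhib[seg].intensities.max() < 0.1 * ctrl[seg].intensities.max()

    def test_degradation_onset_matches_configured_delay(self):
        from lysoscan.kinetics import onset_time
        scen = healthy_s1(seed=5)
        onset = onset_time(simulate_tubule_series(scen)["S1"], fraction=0.5)
        step = scen.duration / (scen.n_timepoints - 1)
        assert abs(onset - 10.0) <= step

    def test_same_seed_reproducible(self):
        a = simulate_tubule_series(healthy_s1(seed=9))
        b = simulate_tubule_series(healthy_s1(seed=9))
        assert all(np.array_equal(a[k].intensities, b[k].intensities) for k in a)


class TestAxialUptake:
    def test_reduced_uptake_redistributes_distally(self):
        wt = simulate_axial_uptake(healthy_s1(seed=1))
        ko = simulate_axial_uptake(ocrl_like(seed=1))
        # uptake amplitude reduced, but decline along the axis is shallower
        assert ko.signal_intensity[0] < wt.signal_intensity[0]
        half = len(wt.positions) // 2
        wt_tail = wt.signal_intensity[half:].sum() / wt.signal_intensity.sum()
        ko_tail = ko.signal_intensity[half:].sum() / ko.signal_intensity.sum()
        assert ko_tail > wt_tail

    def test_dispersion_gradient_flattens_with_reduced_uptake(self):
        wt = simulate_axial_uptake(healthy_s1(seed=1))
        ko = simulate_axial_uptake(ocrl_like(seed=1))
        wt_slope = np.polyfit(wt.positions, wt.dispersion, 1)[0]
        ko_slope = np.polyfit(ko.positions, ko.dispersion, 1)[0]
        assert abs(ko_slope) < abs(wt_slope)
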