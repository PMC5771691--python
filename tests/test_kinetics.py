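"""Growth/degeneration kinetics: rates, coefficients, counterfactuals,
forward simulation, and atrophy percentages."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from braintraj.kinetics import (
    ModelVariant,
    fit_baseline,
    fit_counterfactual,
    interval_rate,
    net_coefficient,
    percent_decrease,
    simulate_trajectory,
)
from braintraj.records import SummaryCell


class TestIntervalRate:
    def test_first_month_cerebellar_growth(self):
        # (0.2188 - 0.0316) / 1
        assert interval_rate(0.0316, 0.2188, 0, 1) == pytest.approx(0.1872)

    def test_constant_area_zero_rate(self):
        assert interval_rate(0.42, 0.42, 0, 5) == 0.0

    def test_decline_phase_sign_preserved(self):
        assert interval_rate(0.3006, 0.2483, 6, 23) == pytest.approx(-0.0030765, rel=1e-4)

    def test_degenerate_interval_rejected(self):
        with pytest.raises(ValueError):
            interval_rate(1.0, 2.0, 3.0, 3.0)


class TestNetCoefficient:
    def test_closed_form(self):
        # (2-1)/(1*2) = 0.5
        assert net_coefficient(1.0, 2.0, 0.0, 1.0) == pytest.approx(0.5)

    def test_end_anchored_vs_log_convention(self):
        k_end = net_coefficient(1.0, 2.0, 0.0, 1.0)
        k_log = net_coefficient(1.0, 2.0, 0.0, 1.0, convention="log")
        assert k_end == pytest.approx(0.5)
        assert k_log == pytest.approx(math.log(2.0))

    def test_nonpositive_end_area_rejected(self):
        with pytest.raises(ValueError):
            net_coefficient(1.0, 0.0, 0.0, 1.0)


class TestFitBaseline:
    CORTEX_WT = [(0, 0.244), (1, 0.7527), (2, 0.908), (6, 0.949), (23, 0.7723)]

    def test_wildtype_cortex_coefficients(self):
        fit = fit_baseline(self.CORTEX_WT, region="cortex")
        g = [ph.G for ph in fit.phases]
        d = [ph.D for ph in fit.phases]
        # frozen from the end-anchored rule: k = (dA/dt) / A(t_end)
        assert g == pytest.approx([0.5087 / 0.7527, 0.1553 / 0.908, 0.01025 / 0.949, 0.0])
        assert d[:3] == [0.0, 0.0, 0.0]
        assert d[3] == pytest.approx((0.949 - 0.7723) / 17 / 0.7723)
        assert fit.feasible

    def test_constant_anchors_all_zero(self):
        fit = fit_baseline([(0, 1.0), (1, 1.0), (2, 1.0), (6, 1.0), (23, 1.0)])
        assert all(ph.G == 0.0 and ph.D == 0.0 for ph in fit.phases)

    def test_straddling_interval_rejected(self):
        with pytest.raises(ValueError, match="straddles"):
            fit_baseline([(0, 0.2), (5, 0.3), (8, 0.29)], growth_phase_end=6.0)

    def test_too_few_anchors_rejected(self):
        with pytest.raises(ValueError):
            fit_baseline([(0, 0.2)])


@st.composite
def feasible_fits(draw):
    """Random feasible piecewise trajectories on the study's age grid."""
    # keep k*dt < 1 on every interval so the discrete rule stays invertible
    g = [draw(st.floats(0.0, 0.8)), draw(st.floats(0.0, 0.8)), draw(st.floats(0.0, 0.2))]
    d = draw(st.floats(0.0, 0.04))
    anchors = [(0.0, 1.0)]
    a = 1.0
    for k, (t0, t1) in zip(g + [-d], [(0, 1), (1, 2), (2, 6), (6, 23)]):
        a = a / (1 - k * (t1 - t0))
        anchors.append((float(t1), a))
    return anchors, g, d


class TestFitCounterfactual:
    CORTEX_WT = [(0, 0.244), (1, 0.7527), (2, 0.908), (6, 0.949), (23, 0.7723)]
    CORTEX_MUT = [(0, 0.2499), (1, 0.766), (2, 0.808), (6, 0.907), (23, 0.7501)]

    def test_mutant_identical_to_control_recovers_control(self):
        base = fit_baseline(self.CORTEX_WT)
        for variant in ("undergrowth_only", "degeneration_only"):
            cf = fit_counterfactual(self.CORTEX_WT, base, variant, genotype="MUT")
            for ph, ctrl in zip(cf.phases, base.phases):
                assert ph.G == pytest.approx(ctrl.G, abs=1e-12)
                assert ph.D == pytest.approx(ctrl.D, abs=1e-12)

    def test_degeneration_only_cortex_flags_negative_coefficient(self):
        base = fit_baseline(self.CORTEX_WT)
        cf = fit_counterfactual(self.CORTEX_MUT, base, "degeneration_only")
        ph = cf.phase_at(2.0)
        assert ph.D < 0  # growth at control levels cannot explain 2-6 mo catch-up
        assert not ph.feasible
        assert not cf.feasible

    def test_decline_phase_shared_between_variants(self):
        # after the growth phase G is pinned to the control value 0 and D
        # is refit, so both variants agree there
        base = fit_baseline(self.CORTEX_WT)
        ug = fit_counterfactual(self.CORTEX_MUT, base, "undergrowth_only")
        do = fit_counterfactual(self.CORTEX_MUT, base, "degeneration_only")
        assert ug.phase_at(6.0).G == do.phase_at(6.0).G == 0.0
        assert ug.phase_at(6.0).D == pytest.approx(do.phase_at(6.0).D, abs=1e-15)

    def test_misaligned_anchors_rejected(self):
        base = fit_baseline(self.CORTEX_WT)
        with pytest.raises(ValueError, match="align"):
            fit_counterfactual([(0, 0.25), (1, 0.76), (3, 0.8), (6, 0.9), (23, 0.75)],
                               base, "undergrowth_only")

    @settings(derandomize=True, max_examples=30)
    @given(data=feasible_fits(), mut_scale=st.floats(0.5, 1.0))
    def test_conservation_across_variants(self, data, mut_scale):
        """Every variant repartitions, never changes, the interval's net
        coefficient: G - D equals the data's net coefficient."""
        anchors, _, _ = data
        mut = [(t, a * mut_scale) for t, a in anchors]
        base = fit_baseline(anchors)
        for variant in ("undergrowth_only", "degeneration_only"):
            cf = fit_counterfactual(mut, base, variant)
            for ph, (t0, a0), (t1, a1) in zip(cf.phases, mut, mut[1:]):
                k = net_coefficient(a0, a1, t0, t1)
                assert ph.G - ph.D == pytest.approx(k, rel=1e-9, abs=1e-12)


class TestSimulateTrajectory:
    def test_zero_coefficient_constant_both_modes(self):
        fit = fit_baseline([(0, 1.0), (1, 1.0)])
        for mode in ("discrete", "continuous"):
            anchors = simulate_trajectory(fit, mode=mode)
            assert anchors == [(0.0, 1.0), (1.0, 1.0)]

    def test_modes_disagree_by_closed_forms(self):
        # k = 0.5 over 1 mo: exp(0.5) = 1.6487 vs 1/(1 - 0.5) = 2.0
        anchors = [(0.0, 1.0), (1.0, 2.0)]
        fit = fit_baseline(anchors)
        assert fit.phases[0].G == pytest.approx(0.5)
        disc = simulate_trajectory(fit, mode="discrete")[-1][1]
        cont = simulate_trajectory(fit, mode="continuous")[-1][1]
        assert disc == pytest.approx(2.0)
        assert cont == pytest.approx(math.exp(0.5))

    def test_singular_inversion_rejected(self):
        from braintraj.kinetics import PhaseFit, TrajectoryFit

        ph = PhaseFit(0.0, 2.0, 0.5, 0.6, 0.0)
        fit = TrajectoryFit("cortex", "WT", (ph,), ((0.0, 1.0), (2.0, 5.0)), 6.0)
        with pytest.raises(ValueError, match="singular"):
            simulate_trajectory(fit, mode="discrete")  # k*dt = 1.2

    @settings(derandomize=True, max_examples=40)
    @given(data=feasible_fits())
    def test_simulate_then_fit_round_trip(self, data):
        """Discrete simulation inverts the end-anchored fit exactly."""
        anchors, g_true, d_true = data
        base = fit_baseline(anchors)
        refit = fit_baseline(simulate_trajectory(base, mode="discrete"))
        for ph, ref in zip(refit.phases, base.phases):
            assert ph.G == pytest.approx(ref.G, rel=1e-9, abs=1e-12)
            assert ph.D == pytest.approx(ref.D, rel=1e-9, abs=1e-12)
        # and the generating coefficients are themselves recovered
        assert [ph.G for ph in base.phases[:3]] == pytest.approx(g_true, rel=1e-9, abs=1e-9)
        assert base.phases[3].D == pytest.approx(d_true, rel=1e-9, abs=1e-9)


class TestPercentDecrease:
    def _cell(self, mean, sem, n, genotype="WT"):
        return SummaryCell(genotype, 22.0, "cerebellum", "tissue_area", mean, sem, n)

    def test_cerebellar_atrophy(self):
        est = percent_decrease(self._cell(7.128, 0.014, 2), self._cell(4.586, 0.089, 4, "MUT"))
        assert est.percent_decrease == pytest.approx(35.66, abs=0.01)
        assert est.uncertainty == pytest.approx(100 * 0.089 / 7.128, abs=1e-6)

    def test_spinal_cord_atrophy(self):
        est = percent_decrease(self._cell(1.890, 0.073, 2), self._cell(1.491, 0.073, 2, "MUT"))
        assert est.percent_decrease == pytest.approx(21.11, abs=0.01)
        assert est.uncertainty == pytest.approx(3.86, abs=0.01)

    def test_identical_cells_zero(self):
        c = self._cell(5.0, 0.1, 3)
        assert percent_decrease(c, c).percent_decrease == 0.0

    def test_strictly_decreasing_in_test_mean(self):
        ref = self._cell(5.0, 0.1, 3)
        values = [
            percent_decrease(ref, self._cell(m, 0.1, 3, "MUT")).percent_decrease
            for m in (3.0, 4.0, 5.0, 6.0)
        ]
        assert values == sorted(values, reverse=True)
        assert len(set(values)) == 4

    def test_delta_method_option(self):
        est = percent_decrease(
            self._cell(7.128, 0.014, 2), self._cell(4.586, 0.089, 4, "MUT"),
            uncertainty="delta",
        )
        assert est.uncertainty > 0

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValueError):
            percent_decrease(self._cell(0.0, 0.0, 2), self._cell(1.0, 0.1, 3, "MUT"))
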