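"""Dosimetry calculators and GCA/IA/HQ mixture responses."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mixrisk.datamodel import Config
from mixrisk.dose_response import HillCurve, hill_forward
from mixrisk.mixture import (MixtureInput, calc_gca, calc_hazard_quotient,
                             calc_independent_action, calc_internal_dose,
                             calc_invitro_concentration, calc_response)


def random_mixture(rng, n_chem, gw_one=True):
    tps = rng.uniform(20, 120, n_chem)
    gas = 10.0 ** rng.uniform(-1, 1, n_chem)
    gws = np.ones(n_chem) if gw_one else rng.uniform(0.5, 3, n_chem)
    c = rng.uniform(0, 5, n_chem)
    curves = [HillCurve(tp, ga, gw) for tp, ga, gw in zip(tps, gas, gws)]
    return MixtureInput(c, curves)


class TestDosimetry:
    def test_internal_dose_arithmetic(self):
        assert calc_internal_dose(1000.0, 0.25) == pytest.approx(0.25, abs=1e-12)

    def test_internal_dose_annihilator_and_linearity(self):
        assert calc_internal_dose(0.0, 0.25) == 0.0
        assert calc_internal_dose(3.0, 0.0) == 0.0
        d1 = calc_internal_dose(2.0, 0.2)
        assert calc_internal_dose(2.0, 0.4) == pytest.approx(2 * d1, rel=1e-12)

    def test_internal_dose_rejects_negative(self):
        with pytest.raises(ValueError):
            calc_internal_dose(-1.0, 0.25)

    def test_invitro_concentration(self):
        assert calc_invitro_concentration(0.5, 2.0) == pytest.approx(1.0, abs=1e-12)
        assert calc_invitro_concentration(0.5, 0.0) == 0.0

    def test_invitro_matrix_matches_scalar(self):
        d = np.array([[0.1, 0.2], [0.3, 0.4]])
        css = np.array([[2.0, 3.0], [4.0, 5.0]])
        out = calc_invitro_concentration(d, css)
        for i in range(2):
            for j in range(2):
                assert out[i, j] == calc_invitro_concentration(d[i, j], css[i, j])


class TestIndependentAction:
    def test_single_chemical_reduces_to_hill(self):
        curve = HillCurve(80, 2, 1.3)
        mix = MixtureInput([1.5], [curve])
        assert calc_independent_action(mix) == pytest.approx(
            hill_forward(1.5, curve), abs=1e-12)

    def test_two_chemicals_half_effect(self):
        # f1 = f2 = 50 with Emax = 100 -> 100 * (1 - 0.25) = 75
        curves = [HillCurve(100, 10, 1), HillCurve(100, 10, 1)]
        mix = MixtureInput([10.0, 10.0], curves, emax=100.0)
        assert calc_independent_action(mix) == pytest.approx(75.0, abs=1e-12)

    def test_zero_mixture(self):
        mix = MixtureInput([0.0, 0.0], [HillCurve(100, 1), HillCurve(50, 2)])
        assert calc_independent_action(mix) == 0.0

    @given(st.integers(0, 2 ** 31 - 1), st.integers(2, 10))
    @settings(derandomize=True, max_examples=50, deadline=None)
    def test_ia_union_bounds(self, seed, n_chem):
        """max individual effect <= IA <= Emax (probabilistic union)."""
        rng = np.random.default_rng(seed)
        mix = random_mixture(rng, n_chem, gw_one=False)
        effs = [hill_forward(c, cv) for c, cv in zip(mix.c_invitro, mix.curves)]
        ia = calc_independent_action(mix)
        assert ia >= max(effs) - 1e-9
        assert ia <= mix.emax + 1e-9


class TestGCA:
    def test_closed_form_arithmetic(self):
        # (tp,ga,C) = (100,10,10) and (50,5,5): E = (100+50)/(1+1+1) = 50
        mix = MixtureInput([10.0, 5.0], [HillCurve(100, 10, 1), HillCurve(50, 5, 1)])
        assert calc_gca(mix) == pytest.approx(50.0, abs=1e-12)

    def test_all_zero_concentration(self):
        mix = MixtureInput([0.0, 0.0], [HillCurve(100, 1, 2), HillCurve(50, 2, 1.5)])
        assert calc_gca(mix) == 0.0

    @pytest.mark.parametrize("gw", [1.0, 0.7, 2.5])
    def test_single_chemical_matches_hill(self, gw):
        curve = HillCurve(90, 3, gw)
        mix = MixtureInput([4.0], [curve])
        assert calc_gca(mix) == pytest.approx(hill_forward(4.0, curve), abs=1e-8)
        assert calc_gca(mix) == pytest.approx(calc_independent_action(mix), abs=1e-8)

    @pytest.mark.parametrize("gw", [1.0, 1.6])
    def test_sham_mixture_invariance(self, gw):
        """Splitting one chemical's dose across identical curves changes
        nothing — the defining property of concentration addition."""
        curve = HillCurve(100, 2, gw)
        whole = calc_gca(MixtureInput([3.0], [curve]))
        split = calc_gca(MixtureInput([1.2, 1.8], [curve, curve]))
        assert split == pytest.approx(whole, abs=1e-8)
        assert whole == pytest.approx(hill_forward(3.0, curve), abs=1e-8)

    def test_numeric_solver_matches_closed_form(self):
        """Force the numeric path with a negligible slope perturbation."""
        rng = np.random.default_rng(11)
        for _ in range(50):
            n = rng.integers(2, 8)
            mix = random_mixture(rng, n, gw_one=True)
            perturbed = [HillCurve(cv.tp, cv.ga, 1.0 + 2e-9) for cv in mix.curves]
            num = calc_gca(MixtureInput(mix.c_invitro, perturbed))
            closed = calc_gca(mix)
            if closed < min(cv.tp for cv in mix.curves):  # inside restricted bracket
                assert num == pytest.approx(closed, abs=1e-6)

    def test_bracket_limited_flag(self):
        # a potent full agonist pushes E to the weaker top: flagged, no raise
        curves = [HillCurve(100, 0.01, 2.0), HillCurve(20, 10, 1.5)]
        res = calc_gca(MixtureInput([50.0, 0.1], curves), full=True)
        assert res.bracket_limited
        assert res.value == pytest.approx(20.0, rel=1e-6)

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(derandomize=True, max_examples=40, deadline=None)
    def test_monotone_in_each_concentration(self, seed):
        """IA is monotone in every concentration; GCA is monotone in a
        chemical's concentration whenever that chemical's top is at or above
        the current mixture response (a partial agonist below it dilutes —
        the classical concentration-addition result)."""
        rng = np.random.default_rng(seed)
        mix = random_mixture(rng, 3, gw_one=bool(seed % 2))
        base_gca = calc_gca(mix)
        base_ia = calc_independent_action(mix)
        for j in range(3):
            c = mix.c_invitro.copy()
            c[j] += 0.5
            bumped = MixtureInput(c, mix.curves, emax=mix.emax)
            assert calc_independent_action(bumped) >= base_ia - 1e-9
            if mix.curves[j].tp >= base_gca:
                assert calc_gca(bumped) >= base_gca - 1e-6

    def test_partial_agonist_dilutes_gca(self):
        """Raising a weak partial agonist's dose pulls the GCA response down
        toward its own top — the slope-1 closed form makes this exact:
        dE/dC_j has the sign of (tp_j - E)."""
        strong, weak = HillCurve(100, 1, 1), HillCurve(30, 1, 1)
        base = calc_gca(MixtureInput([5.0, 1.0], [strong, weak]))
        diluted = calc_gca(MixtureInput([5.0, 20.0], [strong, weak]))
        assert base > diluted > 30


class TestHazardQuotient:
    def test_single_chemical_closed_form(self):
        # EC10 = 10*10/90 = 1.111..., HQ = 5 / 1.111... = 4.5
        mix = MixtureInput([5.0], [HillCurve(100, 10, 1)])
        assert calc_hazard_quotient(mix, "GCA", 0.10) == pytest.approx(4.5, rel=1e-9)

    def test_hq_is_one_at_benchmark(self):
        mix = MixtureInput([10.0 * 10.0 / 90.0], [HillCurve(100, 10, 1)])
        assert calc_hazard_quotient(mix, "GCA", 0.10) == pytest.approx(1.0, rel=1e-9)

    def test_homogeneity(self):
        rng = np.random.default_rng(2)
        mix = random_mixture(rng, 4)
        hq1 = calc_hazard_quotient(mix, "GCA")
        hq2 = calc_hazard_quotient(
            MixtureInput(2 * mix.c_invitro, mix.curves, emax=mix.emax), "GCA")
        assert hq2 == pytest.approx(2 * hq1, rel=1e-8)

    def test_zero_mixture_is_zero(self):
        mix = MixtureInput([0.0, 0.0], [HillCurve(100, 1), HillCurve(50, 2)])
        assert calc_hazard_quotient(mix, "GCA") == 0.0
        assert calc_hazard_quotient(mix, "IA") == 0.0

    def test_relabeling_and_merging_invariance(self):
        a, b = HillCurve(100, 2, 1), HillCurve(60, 5, 1)
        hq = calc_hazard_quotient(MixtureInput([1.0, 3.0], [a, b]), "GCA")
        hq_swapped = calc_hazard_quotient(MixtureInput([3.0, 1.0], [b, a]), "GCA")
        assert hq_swapped == pytest.approx(hq, rel=1e-10)
        hq_split = calc_hazard_quotient(
            MixtureInput([0.4, 0.6, 3.0], [a, a, b]), "GCA")
        assert hq_split == pytest.approx(hq, rel=1e-8)

    def test_ia_method(self):
        mix = MixtureInput([5.0], [HillCurve(100, 10, 1)])
        # single chemical: IA response == GCA response, so HQs agree
        assert calc_hazard_quotient(mix, "IA", 0.10) == pytest.approx(4.5, rel=1e-8)


class TestCalcResponse:
    def _population(self, c_invitro, casrns):
        from mixrisk.datamodel import PopulationDraw
        n = c_invitro.shape[0]
        return PopulationDraw(region_id="R1", age=np.full(n, 30),
                              obese=np.zeros(n, bool), ir=np.full(n, 0.25),
                              casrns=casrns, c_ext=np.zeros_like(c_invitro),
                              c_invitro=c_invitro)

    def _params(self, casrns, assay="A1"):
        from mixrisk.datamodel import HillParams
        return [HillParams(casrn=c, assay=assay, tp=100.0, log10_ga=1.0,
                           gw=1.0, sigma=1.0, n_params=2) for c in casrns]

    def test_single_individual_single_chemical_consistency(self):
        pop = self._population(np.array([[5.0]]), ["X"])
        res = calc_response(pop, self._params(["X"]), Config())
        curve = HillCurve(100, 10, 1)
        assert res.gca_eff[0] == pytest.approx(hill_forward(5.0, curve), abs=1e-10)
        assert res.ia_eff[0] == pytest.approx(res.gca_eff[0], abs=1e-10)
        assert res.gca_hq[0] == pytest.approx(4.5, rel=1e-9)
        assert res.ia_hq[0] == pytest.approx(4.5, rel=1e-8)

    def test_zero_exposure_individual(self):
        pop = self._population(np.array([[0.0, 0.0]]), ["X", "Y"])
        res = calc_response(pop, self._params(["X", "Y"]), Config())
        assert res.gca_eff[0] == res.ia_eff[0] == 0.0
        assert res.gca_hq[0] == res.ia_hq[0] == 0.0

    def test_chemicals_without_fits_dropped(self, caplog):
        pop = self._population(np.array([[1.0, 2.0]]), ["X", "Y"])
        res = calc_response(pop, self._params(["X"]), Config())
        assert res.gca_eff[0] == pytest.approx(
            hill_forward(1.0, HillCurve(100, 10, 1)), abs=1e-10)

    def test_empty_intersection_errors(self):
        pop = self._population(np.array([[1.0]]), ["X"])
        with pytest.raises(ValueError, match="joinable"):
            calc_response(pop, self._params(["Z"]), Config())

    def test_repeated_calls_identical(self):
        rng = np.random.default_rng(8)
        pop = self._population(rng.uniform(0, 3, (20, 3)), ["X", "Y", "Z"])
        params = self._params(["X", "Y", "Z"])
        r1 = calc_response(pop, params, Config())
        r2 = calc_response(pop, params, Config())
        assert np.array_equal(r1.gca_eff, r2.gca_eff)
        assert np.array_equal(r1.ia_hq, r2.ia_hq)
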