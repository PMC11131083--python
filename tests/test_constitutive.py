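"""Constitutive laws: scaling relations, stresses, gas thermodynamics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gelpore.constitutive import (
    CavityState,
    GelParams,
    LayerSpec,
    LocalState,
    activity_to_mu,
    cauchy_stress,
    cavity_from_pressure,
    chemical_potential,
    osmotic_pressure_mix,
    p_sat_tetens,
    piola_stress,
    saturated_cavity,
    skin_phi_ref,
    water_activity,
)

P0 = 101325.0


class TestGelParams:
    def test_defaults_encode_free_swelling(self, gel):
        assert gel.lambda0**3 == pytest.approx(1.5, rel=1e-15)
        # alpha is the unique value making the free-swollen state stationary
        assert gel.alpha == pytest.approx(gel.lambda0 ** (23 / 4), rel=1e-15)
        assert gel.alpha == pytest.approx(2.17525, abs=1e-5)

    @pytest.mark.parametrize("bad", [dict(alpha=0.9), dict(T=-1.0), dict(nu_w=0.0)])
    def test_invalid_parameters_rejected(self, bad):
        with pytest.raises(ValueError):
            GelParams(**bad)


class TestSkinPhiRef:
    def test_equal_moduli_leave_density_unchanged(self):
        assert skin_phi_ref(1e5, 1e5, 0.05) == pytest.approx(0.05)

    @pytest.mark.parametrize(
        "ratio,expected", [(20.0, 0.18928), (10.0, 0.13913)]
    )
    def test_c_star_scaling(self, ratio, expected):
        # phi_core * ratio**(4/9), evaluated independently
        assert skin_phi_ref(1e5, ratio * 1e5, 0.05) == pytest.approx(
            expected, abs=1e-4
        )

    def test_overdense_skin_rejected(self):
        with pytest.raises(ValueError, match="modulus ratio too large"):
            skin_phi_ref(1e5, 1e9, 0.05)

    def test_softer_skin_rejected(self):
        with pytest.raises(ValueError):
            skin_phi_ref(1e5, 5e4, 0.05)


class TestOsmoticPressure:
    def test_reference_state_gives_alpha_G(self, gel):
        layer = LayerSpec(G=1e5, phi_ref=0.05)
        assert osmotic_pressure_mix(0.05, layer, gel) == pytest.approx(
            gel.alpha * 1e5
        )

    def test_initial_state_gives_G_over_lambda0(self, gel):
        # phi = phi0 means phi_tilde = 2/3; with the default alpha the
        # closed form is G * (3/2)**(-1/3) ~ 0.87358 G
        layer = LayerSpec(G=1e5, phi_ref=0.05)
        phi0 = layer.phi0(gel)
        assert osmotic_pressure_mix(phi0, layer, gel) == pytest.approx(
            1e5 / gel.lambda0, rel=1e-12
        )
        assert osmotic_pressure_mix(phi0, layer, gel) == pytest.approx(
            0.87358 * 1e5, rel=1e-4
        )

    def test_strictly_increasing_and_vanishing(self, gel):
        layer = LayerSpec(G=1e5, phi_ref=0.05)
        phis = np.linspace(1e-4, 0.6, 50)
        pis = osmotic_pressure_mix(phis, layer, gel)
        assert np.all(np.diff(pis) > 0)
        assert pis[0] < 1.0  # Pi -> 0 with phi -> 0

    def test_domain_checked(self, gel):
        layer = LayerSpec(G=1e5, phi_ref=0.05)
        with pytest.raises(ValueError):
            osmotic_pressure_mix(0.0, layer, gel)


stretches = st.floats(min_value=0.3, max_value=3.0)
pressures = st.floats(min_value=-5e5, max_value=5e6)


class TestStresses:
    @given(lam_r=stretches, lam_t=stretches, p=pressures)
    @settings(max_examples=250, derandomize=True, deadline=None)
    def test_stress_difference_identity(self, lam_r, lam_t, p):
        """sigma_rr - sigma_tt = phi_hat G (lam_r^2 - lam_t^2) exactly."""
        gel = GelParams()
        layer = LayerSpec(G=2e5, phi_ref=0.05)
        state = LocalState.from_stretches(lam_r, lam_t, layer, gel, p_liq=p)
        s_rr, s_tt = cauchy_stress(state, layer, gel)
        phi_hat = state.phi / (layer.phi0(gel) * gel.lambda0)
        expected = phi_hat * layer.G * (lam_r**2 - lam_t**2)
        assert s_rr - s_tt == pytest.approx(expected, rel=1e-12, abs=1e-7)

    @given(lam_r=stretches, lam_t=stretches, p=pressures)
    @settings(max_examples=250, derandomize=True, deadline=None)
    def test_piola_push_forward(self, lam_r, lam_t, p):
        """S_RR = sigma_rr lam_t^2 and S_tt = sigma_tt lam_t lam_r."""
        gel = GelParams()
        layer = LayerSpec(G=2e5, phi_ref=0.05)
        state = LocalState.from_stretches(lam_r, lam_t, layer, gel, p_liq=p)
        s_rr, s_tt = cauchy_stress(state, layer, gel)
        S_RR, S_tt = piola_stress(state, layer, gel)
        assert S_RR == pytest.approx(s_rr * lam_t**2, rel=1e-12, abs=1e-7)
        assert S_tt == pytest.approx(s_tt * lam_t * lam_r, rel=1e-12, abs=1e-7)

    def test_initial_state_is_ambient(self, gel):
        """lam = 1 with p = G/lambda0 + p0 carries pure ambient traction."""
        layer = LayerSpec(G=3e5, phi_ref=0.05)
        p = layer.G / gel.lambda0 + gel.p0
        state = LocalState.from_stretches(1.0, 1.0, layer, gel, p_liq=p)
        s_rr, s_tt = cauchy_stress(state, layer, gel)
        assert s_rr == pytest.approx(-gel.p0, rel=1e-12)
        assert s_tt == pytest.approx(-gel.p0, rel=1e-12)
        S_RR, _ = piola_stress(state, layer, gel)
        assert S_RR == pytest.approx(-gel.p0, rel=1e-12)

    def test_isotropic_swelling_isotropic_stress(self, gel):
        layer = LayerSpec(G=3e5, phi_ref=0.05)
        lam = 1.3
        state = LocalState.from_stretches(lam, lam, layer, gel, p_liq=0.0)
        s_rr, s_tt = cauchy_stress(state, layer, gel)
        assert s_rr == pytest.approx(s_tt, rel=1e-14)
        assert s_rr == pytest.approx(layer.G / (lam * gel.lambda0), rel=1e-12)
        S_RR, _ = piola_stress(state, layer, gel)
        assert S_RR == pytest.approx(layer.G * lam / gel.lambda0, rel=1e-12)


class TestChemicalPotential:
    def test_free_swollen_state_in_equilibrium_with_water(self, gel):
        """With the default alpha, mu_w = p0 in both layers simultaneously."""
        for G in (1.89e5, 20 * 1.89e5):
            layer = LayerSpec(G=G, phi_ref=skin_phi_ref(1.89e5, G, 0.05))
            p_liq = G / gel.lambda0 + gel.p0
            mu = chemical_potential(layer.phi0(gel), p_liq, layer, gel)
            assert mu == pytest.approx(gel.p0, rel=1e-12)

    def test_balanced_pressure_zeroes_mu(self, gel):
        layer = LayerSpec(G=1e5, phi_ref=0.05)
        pi = osmotic_pressure_mix(0.1, layer, gel)
        assert chemical_potential(0.1, pi, layer, gel) == pytest.approx(0.0, abs=1e-8)

    def test_drier_gel_lower_mu(self, gel):
        layer = LayerSpec(G=1e5, phi_ref=0.05)
        mus = [chemical_potential(phi, 0.0, layer, gel) for phi in (0.05, 0.1, 0.2)]
        assert mus[0] > mus[1] > mus[2]


class TestGasPhase:
    def test_tetens_anchor_points(self):
        assert p_sat_tetens(273.15) == pytest.approx(610.78)
        assert p_sat_tetens(308.15) == pytest.approx(5622.7, rel=1e-3)
        assert p_sat_tetens(338.15) == pytest.approx(25.0e3, rel=2e-3)

    def test_tetens_domain(self):
        with pytest.raises(ValueError):
            p_sat_tetens(250.0)

    def test_activity_roundtrip_and_anchors(self, gel):
        assert water_activity(0.0, gel) == pytest.approx(1.0)
        gel308 = GelParams(T=308.15)
        assert water_activity(-3.783e8, gel308) == pytest.approx(0.070, abs=2e-3)
        for a in (0.07, 0.5, 0.999):
            assert water_activity(activity_to_mu(a, gel), gel) == pytest.approx(
                a, rel=1e-12
            )

    def test_supersaturation_warns(self, gel):
        with pytest.warns(UserWarning, match="supersaturated"):
            water_activity(1e7, gel)

    def test_saturated_cavity_initialisation(self):
        gel = GelParams(T=308.15)
        V0 = 4 / 3 * math.pi * (3e-3) ** 3
        cav = saturated_cavity(V0, gel)
        assert cav.p_gas == pytest.approx(P0)
        assert cav.p_vap == pytest.approx(p_sat_tetens(308.15))
        assert cav.p_air == pytest.approx(95.7e3, rel=1e-3)
        assert cav.N_air == pytest.approx(cav.p_air * V0 / gel.RT, rel=1e-12)
        cav.check(gel)

    def test_cavity_update_fixed_point_at_equilibrium(self):
        gel = GelParams(T=308.15)
        V0 = 4 / 3 * math.pi * (3e-3) ** 3
        cav = saturated_cavity(V0, gel)
        new = cavity_from_pressure(-gel.p0, gel.p0, cav, gel)
        assert new.V_gas == pytest.approx(cav.V_gas, rel=1e-12)
        assert new.N_vap == pytest.approx(cav.N_vap, rel=1e-12)

    def test_cavity_gay_lussac(self):
        """Doubling the air partial pressure halves the gas volume."""
        gel = GelParams(T=308.15)
        V0 = 4 / 3 * math.pi * (3e-3) ** 3
        cav = saturated_cavity(V0, gel)
        # sigma chosen so that p_gas - p_vap = 2 p_air0, with a_w = 1 held
        p_gas = 2 * cav.p_air + cav.p_vap
        new = cavity_from_pressure(-p_gas, p_gas, cav, gel)
        assert new.V_gas == pytest.approx(cav.V_gas / 2, rel=1e-12)
        assert new.N_air == cav.N_air

    def test_cavity_rejects_vapour_above_total(self):
        gel = GelParams(T=308.15)
        cav = saturated_cavity(1e-7, gel)
        with pytest.raises(ValueError, match="nonphysical"):
            cavity_from_pressure(-10.0, gel.p0, cav, gel)


class TestKinematicRoundTrip:
    @given(lam_r=stretches, lam_t=stretches)
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_volume_ratio_consistency(self, lam_r, lam_t):
        """J = lam_r lam_t^2 = phi0/phi round-trips with J = phi0 + nu_w c."""
        gel = GelParams()
        layer = LayerSpec(G=1e5, phi_ref=0.05)
        state = LocalState.from_stretches(lam_r, lam_t, layer, gel)
        J = state.J()
        phi0 = layer.phi0(gel)
        assert J == pytest.approx(phi0 / state.phi, rel=1e-12)
        c = (J - phi0) / gel.nu_w  # water concentration per initial volume
        assert phi0 + gel.nu_w * c == pytest.approx(J, rel=1e-12)
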