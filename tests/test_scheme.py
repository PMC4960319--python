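"""Reaction-network construction, integration and channel projection."""

import numpy as np
import pytest

from redoxswitch import (
    SchemeParams, build_scheme, build_displacement_scheme, simulate, observe,
    fit_exponential,
)
from redoxswitch.scheme import SchemeError


def holo_kobs(p, r0):
    return p.kon_holo * r0 + p.koff_holo


class TestBuildScheme:
    def test_minimal_scheme_has_two_reversible_bindings(self, params):
        sc = build_scheme(params, include_oxidation=False, include_par=False)
        assert len(sc.reactions) == 4  # 2 forward + 2 reverse
        assert set(sc.species) == {"RZn", "R", "S", "RZnS", "RS"}
        assert {m[0] for m in sc.conserved_moieties} == {
            "total_R", "total_S", "total_Zn"}

    def test_full_scheme_conserves_sensor_moiety(self, params):
        sc = build_scheme(params)
        (_, weights), = [m for m in sc.conserved_moieties if m[0] == "total_R"]
        assert set(weights) == {"RZn", "R", "Rox", "RZnS", "RS", "I", "IC", "RoxS"}
        assert all(w == 1.0 for w in weights.values())
        # constructor itself verifies weighted stoichiometry sums to zero

    def test_zinc_removal_accelerates_dissociation_400_fold(self, params):
        # the zinc-free complex falls apart 400x faster; association barely moves
        assert params.koff_apo / params.koff_holo == pytest.approx(400.0)
        assert params.kon_apo == pytest.approx(params.kon_holo, rel=0.5)

    def test_invalid_params_rejected(self):
        with pytest.raises(SchemeError):
            SchemeParams(kon_holo=-1.0)
        with pytest.raises(SchemeError):
            SchemeParams(K1_ox=0.0)
        with pytest.raises(SchemeError):
            SchemeParams(koff_holo=1.0, koff_apo=0.1)  # zinc must slow koff

    def test_par_without_oxidation_rejected(self, params):
        with pytest.raises(SchemeError):
            build_scheme(params, include_oxidation=False, include_par=True)


class TestSimulate:
    def test_all_zero_init_stays_zero(self, params):
        sc = build_scheme(params)
        traj = simulate(sc, {}, np.linspace(0, 10, 20))
        assert all(np.all(v == 0) for v in traj.concentrations.values())

    def test_negative_init_rejected(self, params):
        sc = build_scheme(params)
        with pytest.raises(ValueError):
            simulate(sc, {"RZn": -1e-6}, np.linspace(0, 1, 10))

    def test_unknown_species_rejected(self, params):
        sc = build_scheme(params, include_oxidation=False, include_par=False)
        with pytest.raises(SchemeError):
            simulate(sc, {"Ox": 1e-3}, np.linspace(0, 1, 10))

    def test_pseudo_first_order_relaxation_rate(self, params):
        # closed-form limit: with sensor in 100-fold excess the sigma decay is
        # single-exponential at kon*[RZn] + koff within 1%
        sc = build_scheme(params, include_oxidation=False, include_par=False)
        r0, s0 = 1.25e-6, 1.25e-8
        kobs = holo_kobs(params, r0)
        t = np.linspace(0, 7 * np.log(2) / kobs, 200)
        traj = simulate(sc, {"RZn": r0, "S": s0}, t)
        fit = fit_exponential((t, traj.concentrations["S"]))
        assert fit.kobs == pytest.approx(kobs, rel=0.01)

    def test_moiety_conservation_during_oxidation(self, params):
        sc = build_scheme(params)
        t = np.linspace(0, 60, 200)
        traj = simulate(sc, {"RZnS": 2e-6, "Ox": 1e-3, "S": 1e-7}, t)
        for name, tot in traj.moiety_totals(sc).items():
            drift = (tot.max() - tot.min()) / tot.max()
            assert drift < 1e-6, name

    def test_detailed_balance_equilibrium(self, params):
        # with oxidation off both binding reactions settle at Kd = koff/kon
        sc = build_scheme(params, include_oxidation=False, include_par=False)
        t = np.geomspace(1e-3, 5e4, 60)
        traj = simulate(sc, {"RZn": 1e-6, "R": 1e-6, "S": 1.5e-6},
                        np.concatenate([[0.0], t]))
        c = {k: v[-1] for k, v in traj.concentrations.items()}
        kd_holo = c["RZn"] * c["S"] / c["RZnS"]
        kd_apo = c["R"] * c["S"] / c["RS"]
        assert kd_holo == pytest.approx(params.koff_holo / params.kon_holo, rel=1e-4)
        assert kd_apo == pytest.approx(params.koff_apo / params.kon_apo, rel=1e-4)

    @pytest.mark.parametrize("ox0", [25e-6, 200e-6, 1e-3, 5e-3, 20e-3])
    def test_rapid_equilibrium_zinc_release_rate(self, params, ox0):
        # two-step rapid-equilibrium closed form kobs = k2[Ox]/(K1+[Ox]);
        # catalytic sensor concentration keeps the oxidant undepleted
        sc = build_scheme(params)
        kobs_th = params.k2_ox * ox0 / (params.K1_ox + ox0)
        t = np.linspace(0, 7 * np.log(2) / kobs_th, 300)
        traj = simulate(sc, {"RZnS": 5e-8, "Ox": ox0}, t)
        trace = observe(traj, "absorbance_500", {"ZnPAR": 6.6e4})
        fit = fit_exponential(trace)
        assert fit.kobs == pytest.approx(kobs_th, rel=0.02)

    def test_oxidized_sensor_releases_sigma(self, params):
        # oxidation of the complex must liberate free sigma (Rox cannot rebind)
        sc = build_scheme(params)
        t = np.linspace(0, 600, 300)
        traj = simulate(sc, {"RZnS": 2e-6, "Ox": 20e-3}, t)
        assert traj.concentrations["S"][-1] > 0.95 * 2e-6
        assert traj.concentrations["ZnPAR"][-1] > 0.95 * 2e-6


class TestDisplacement:
    def test_exchange_rate_is_koff_times_pool_correction(self, params):
        # the QSS exchange eigenvalue is koff*(1 + Rtot/(Stot+Xtot-Rtot));
        # at the 10x design that is exactly 1.10*koff
        sc = build_displacement_scheme(params)
        c0, x0 = 2.5e-6, 25e-6
        t = np.linspace(0, 7 * np.log(2) / params.koff_holo, 400)
        traj = simulate(sc, {"RZnS": c0, "Sx": x0}, t)
        trace = observe(traj, "fluorescence_343", {"S": 1.0, "RZnS": 0.35},
                        offset=0.1)
        fit = fit_exponential(trace)
        expected = params.koff_holo * (1.0 + c0 / x0)
        assert fit.kobs == pytest.approx(expected, rel=0.01)

    def test_bias_vanishes_with_larger_excess(self, params):
        sc = build_displacement_scheme(params)
        c0 = 2.5e-6
        devs = []
        for excess in (10, 100):
            t = np.linspace(0, 7 * np.log(2) / params.koff_holo, 300)
            traj = simulate(sc, {"RZnS": c0, "Sx": excess * c0}, t)
            fit = fit_exponential((t, traj.concentrations["S"]))
            devs.append(abs(fit.kobs / params.koff_holo - 1.0))
        assert devs[1] < devs[0] / 5


class TestObserve:
    def test_par_channel_tracks_cumulative_zinc_release(self, params):
        sc = build_scheme(params)
        t = np.linspace(0, 60, 100)
        traj = simulate(sc, {"RZnS": 2e-6, "Ox": 1e-3}, t)
        trace = observe(traj, "absorbance_500", {"ZnPAR": 6.6e4})
        assert np.all(np.diff(trace.signal) >= -1e-12)
        np.testing.assert_allclose(
            trace.signal, 6.6e4 * traj.concentrations["ZnPAR"])

    def test_oxidant_channel_decreases_during_oxidation(self, params):
        sc = build_scheme(params)
        t = np.linspace(0, 600, 100)
        traj = simulate(sc, {"RZnS": 20e-6, "Ox": 25e-6}, t)
        trace = observe(traj, "absorbance_320", {"Ox": 3.1e3})
        assert trace.signal[-1] < trace.signal[0]
        assert np.all(np.diff(trace.signal) <= 1e-12)

    def test_binding_changes_fluorescence_in_one_direction(self, params):
        # complex formation quenches sigma tryptophan emission, so the
        # association trace must fall monotonically toward its plateau
        sc = build_scheme(params, include_oxidation=False, include_par=False)
        t = np.linspace(0, 10, 100)
        traj = simulate(sc, {"RZn": 2e-6, "S": 1e-6}, t)
        trace = observe(traj, "fluorescence_343", {"S": 1.0, "RZnS": 0.35},
                        offset=0.1)
        assert trace.signal[-1] < trace.signal[0]

    def test_unknown_channel_and_species_rejected(self, params):
        sc = build_scheme(params)
        traj = simulate(sc, {"RZn": 1e-6}, np.linspace(0, 1, 10))
        with pytest.raises(ValueError):
            observe(traj, "absorbance_999", {"RZn": 1.0})
        with pytest.raises(ValueError):
            observe(traj, "absorbance_500", {"NotASpecies": 1.0})
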