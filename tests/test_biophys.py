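"""Isotherm model vs mass-action oracle, fit round trips, NMR ratios, RMSD."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import brute_force_rmsd_oracle, itc_equilibrium_heats_oracle
from nerupture import synthetic
from nerupture.biophys import (
    BindingParams,
    FitError,
    InjectionSchedule,
    ItcExperiment,
    R_KCAL,
    fit_itc,
    itc_model_heats,
    kabsch_rmsd,
    kabsch_superpose,
    kd_to_thermo,
    load_ca_coordinates,
    nmr_intensity_ratios,
)

WT = dict(cell=20e-6, syringe=100e-6)
A12T = dict(cell=40e-6, syringe=200e-6)


class TestItcModel:
    def test_zero_enthalpy_zero_heats(self):
        p = BindingParams(kd_M=1e-6, dh_kcal=0.0)
        heats = itc_model_heats(p, InjectionSchedule(), **{
            "cell_concentration_M": 20e-6, "syringe_concentration_M": 100e-6})
        np.testing.assert_array_equal(heats, 0.0)

    def test_weak_binding_limit_suppresses_heats(self):
        schedule = InjectionSchedule()
        tight = itc_model_heats(
            BindingParams(kd_M=1e-12, dh_kcal=-5.0), schedule, 20e-6, 100e-6
        )
        weak = itc_model_heats(
            BindingParams(kd_M=1e3 * 100e-6, dh_kcal=-5.0), schedule, 20e-6, 100e-6
        )
        assert np.all(np.abs(weak) <= 0.01 * abs(tight[0]))

    @pytest.mark.parametrize("geom", [WT, A12T])
    def test_matches_mass_action_oracle(self, geom):
        p = BindingParams(kd_M=33e-6, dh_kcal=-5.0, n=0.5)
        schedule = InjectionSchedule()
        closed = itc_model_heats(p, schedule, geom["cell"], geom["syringe"])
        numeric = itc_equilibrium_heats_oracle(p, schedule, geom["cell"], geom["syringe"])
        np.testing.assert_allclose(closed, numeric, rtol=1e-6)

    def test_heat_conservation_at_saturation(self):
        """Total heat approaches n·M0·V0·ΔH once the titration saturates."""
        schedule = InjectionSchedule(n_injections=29)
        m0, xs, dh, n = 20e-6, 400e-6, -5.0, 0.5
        kd = n * m0 / 50.0  # c-value 50
        heats = itc_model_heats(BindingParams(kd_M=kd, dh_kcal=dh, n=n),
                                schedule, m0, xs)
        expected = n * m0 * schedule.cell_volume_ul * 1e-6 * dh * 1e9
        assert heats.sum() == pytest.approx(expected, rel=0.02)


class TestFitItc:
    @pytest.mark.parametrize("kd_uM", [1.0, 3.0, 10.0, 33.0, 100.0])
    def test_noiseless_round_trip(self, kd_uM):
        p = BindingParams(kd_M=kd_uM * 1e-6, dh_kcal=-5.0)
        exp, _ = synthetic.generate_itc_experiment(
            p, InjectionSchedule(), 40e-6, 200e-6, noise_sd_ucal=0.0
        )
        res = fit_itc(exp)
        assert res.kd_M == pytest.approx(p.kd_M, rel=0.01)
        assert res.dh_kcal == pytest.approx(-5.0, rel=0.01)

    def test_thermo_identities(self):
        p = BindingParams(kd_M=10e-6, dh_kcal=-5.0)
        exp, _ = synthetic.generate_itc_experiment(
            p, InjectionSchedule(), 20e-6, 100e-6
        )
        res = fit_itc(exp)
        assert res.dg_kcal == pytest.approx(R_KCAL * 288.0 * math.log(res.kd_M))
        assert res.tds_kcal == pytest.approx(res.dh_kcal - res.dg_kcal)

    def test_too_few_injections_rejected(self):
        schedule = InjectionSchedule(n_injections=3)
        exp = ItcExperiment(schedule, 20e-6, 100e-6, np.zeros(3))
        with pytest.raises(FitError):
            fit_itc(exp)

    def test_low_c_fit_warns(self):
        p = BindingParams(kd_M=2e-3, dh_kcal=-5.0)  # c ~ 0.005
        exp, _ = synthetic.generate_itc_experiment(
            p, InjectionSchedule(), 20e-6, 100e-6
        )
        res = fit_itc(exp)
        assert res.c_warning


class TestKdToThermo:
    def test_reference_values(self):
        assert kd_to_thermo(1.0, 288.0) == pytest.approx(0.0)
        assert kd_to_thermo(2.7e-6, 288.0) == pytest.approx(-7.34, abs=0.01)
        assert kd_to_thermo(33e-6, 288.0) == pytest.approx(-5.91, abs=0.01)

    def test_entropy_term(self):
        dg, tds = kd_to_thermo(2.7e-6, 288.0, dh_kcal=-5.0)
        assert tds == pytest.approx(-5.0 - dg)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            kd_to_thermo(-1.0, 288.0)


class TestNmrRatios:
    def test_identical_spectra_full_retention(self):
        res = np.arange(1, 11)
        profile, pct = nmr_intensity_ratios(res, np.ones(10), np.ones(10))
        assert np.allclose(profile.ratio, 1.0)
        assert pct == pytest.approx(100.0)

    def test_neighbour_interpolation(self):
        res = [1, 2, 3]
        vol = [0.4, np.nan, 0.6]
        ref = [1.0, 1.0, 1.0]
        profile, _ = nmr_intensity_ratios(res, vol, ref, assigned=[True, False, True])
        assert profile.ratio.iloc[1] == pytest.approx(0.5)
        assert profile.interpolated.iloc[1]

    def test_mean_retained_fraction(self):
        rng = np.random.default_rng(0)
        ref = rng.uniform(0.5, 2.0, 40)
        ratios = np.full(40, 0.27)
        _, pct = nmr_intensity_ratios(np.arange(40), ratios * ref, ref)
        assert pct == pytest.approx(27.0)

    def test_terminal_unassigned_left_missing(self):
        profile, _ = nmr_intensity_ratios(
            [1, 2, 3], [np.nan, 0.5, 0.7], [1, 1, 1],
            assigned=[False, True, True],
        )
        assert np.isnan(profile.ratio.iloc[0]) and not profile.interpolated.iloc[0]

    @given(st.lists(st.booleans(), min_size=5, max_size=30))
    @settings(deadline=None, max_examples=60)
    def test_interpolation_stays_in_neighbour_hull(self, assigned):
        if sum(assigned) < 2:
            return
        n = len(assigned)
        rng = np.random.default_rng(42)
        vol = rng.uniform(0.1, 2.0, n)
        profile, _ = nmr_intensity_ratios(
            np.arange(n), vol, np.ones(n), assigned=assigned
        )
        assigned_idx = [i for i, a in enumerate(assigned) if a]
        for i, row in profile.iterrows():
            if row.interpolated:
                prev = max(j for j in assigned_idx if j < i)
                nxt = min(j for j in assigned_idx if j > i)
                lo = min(vol[prev], vol[nxt])
                hi = max(vol[prev], vol[nxt])
                assert lo - 1e-12 <= row.ratio <= hi + 1e-12


def random_rigid(rng):
    from scipy.spatial.transform import Rotation

    rot = Rotation.random(random_state=rng).as_matrix()
    t = rng.uniform(-20, 20, 3)
    return rot, t


class TestKabsch:
    def test_self_rmsd_zero(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(10, 3))
        _, _, rmsd = kabsch_superpose(pts, pts)
        assert rmsd == pytest.approx(0.0, abs=1e-12)

    def test_rigid_transform_invariance(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=(25, 3)) * 10
        for _ in range(5):
            rot, t = random_rigid(rng)
            b = a @ rot.T + t
            _, _, rmsd = kabsch_superpose(a, b)
            assert rmsd < 1e-10

    def test_toy_sets_match_brute_force_optimizer(self):
        a = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0.2, 0.3, 1.1]])
        b = np.array([[0.1, 0, 0], [1.1, 0.2, 0], [0, 0.9, 0.1], [0.1, 0.4, 1.0]])
        _, _, rmsd = kabsch_superpose(a, b)
        assert rmsd == pytest.approx(brute_force_rmsd_oracle(a, b), abs=1e-6)

    def test_symmetry(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=(12, 3))
        b = rng.normal(size=(12, 3))
        assert kabsch_superpose(a, b)[2] == pytest.approx(
            kabsch_superpose(b, a)[2], abs=1e-10
        )

    def test_degenerate_inputs_rejected(self):
        line = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]], float)
        with pytest.raises(ValueError):
            kabsch_superpose(line, line + 1.0)
        with pytest.raises(ValueError):
            kabsch_rmsd({("A", 1): np.zeros(3)}, {("A", 1): np.ones(3)})

    def test_keyed_pairing_and_chain_map(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(8, 3)) * 5
        a = {("A", i + 1): p for i, p in enumerate(pts)}
        rot, t = random_rigid(rng)
        b = {("X", i + 1): p @ rot.T + t for i, p in enumerate(pts)}
        b[("X", 99)] = np.zeros(3)  # unpaired residue is ignored
        res = kabsch_rmsd(a, b, chain_map={"X": "A"})
        assert res.n_pairs == 8
        assert res.rmsd < 1e-10


SYNTHETIC_PDB = """\
CRYST1   50.000   50.000   50.000  90.00  90.00  90.00 P 1           1
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00 10.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00 10.00           C
ATOM      3  CA AGLY A   2      12.685   7.156  -4.889  0.40 10.00           C
ATOM      4  CA BGLY A   2      12.000   7.000  -4.000  0.60 10.00           C
ATOM      5  CA  SER A   3      13.500   8.500  -3.000  1.00 10.00           C
ATOM      6  O   HOH A 101      20.000  20.000  20.000  1.00 10.00           O
END
"""


class TestPdbLoading:
    def test_ca_extraction_with_altloc_resolution(self, tmp_path):
        path = tmp_path / "synthetic_toy.pdb"
        path.write_text(SYNTHETIC_PDB)
        coords = load_ca_coordinates(path)
        assert set(coords) == {("A", 1), ("A", 2), ("A", 3)}
        # highest-occupancy altloc (B, 0.60) wins for residue 2
        np.testing.assert_allclose(coords[("A", 2)], [12.0, 7.0, -4.0])
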