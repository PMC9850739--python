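"""EVB ground state, coupling calibration, state identification, Morse fits."""

import numpy as np
import pytest

from pesscan import kg, synth
from pesscan.ffeval import HarmonicBond, MorseBond
from pesscan.fitting import (
    CalibrationInfeasibleError,
    CouplingModel,
    EnergyProfile,
    EVBCouplingModel,
    EVBInput,
    MorseModel,
    MorseParams,
    NoWellError,
    StateIdentificationError,
    align_state,
    calibrate,
    evb_ground,
    fit_morse,
    identify_states,
    pointwise_coupling,
    to_fitting_record,
)

from conftest import make_diatomic_scan


def profile_of(energies, r=None):
    r = r if r is not None else list(range(len(energies)))
    return EnergyProfile.from_arrays(r, energies)


class TestEvbGround:
    @pytest.mark.parametrize(
        "e1, e2, h, expected",
        [(0.0, 50.0, 0.0, 0.0), (10.0, 10.0, 3.0, 7.0), (0.0, 30.0, 20.0, -10.0)],
    )
    def test_pinned_examples(self, e1, e2, h, expected):
        assert evb_ground(e1, e2, h) == pytest.approx(expected, abs=1e-12)

    def test_matches_symmetric_eigensolver_oracle(self, rng):
        vals = rng.uniform(-500.0, 500.0, size=(2000, 3))
        for e1, e2, h in vals:
            lo = np.linalg.eigvalsh(np.array([[e1, h], [h, e2]]))[0]
            assert abs(evb_ground(e1, e2, h) - lo) < 1e-10

    def test_symmetry_evenness_bound(self, rng):
        vals = rng.uniform(-500.0, 500.0, size=(500, 3))
        for e1, e2, h in vals:
            g = evb_ground(e1, e2, h)
            assert g == pytest.approx(evb_ground(e2, e1, h), abs=1e-12)
            assert g == pytest.approx(evb_ground(e1, e2, -h), abs=1e-12)
            assert g <= min(e1, e2) + 1e-12

    def test_nonincreasing_in_coupling_magnitude(self, rng):
        for e1, e2 in rng.uniform(-100.0, 100.0, size=(100, 2)):
            hs = np.linspace(0.0, 50.0, 20)
            gs = [evb_ground(e1, e2, h) for h in hs]
            assert all(a >= b - 1e-12 for a, b in zip(gs, gs[1:]))


class TestPointwiseCoupling:
    @pytest.mark.parametrize(
        "e1, e2, eref, expected",
        [(9.0, 4.0, 0.0, 6.0), (5.0, 2.0, 2.0, 0.0)],
    )
    def test_pinned_examples(self, e1, e2, eref, expected):
        assert pointwise_coupling(e1, e2, eref) == pytest.approx(expected, abs=1e-12)

    def test_unreachable_reference_is_undefined(self):
        assert np.isnan(pointwise_coupling(5.0, 7.0, 6.0))

    def test_inversion_identity(self, rng):
        e1 = rng.uniform(-200.0, 200.0, size=2000)
        e2 = rng.uniform(-200.0, 200.0, size=2000)
        eref = np.minimum(e1, e2) - rng.uniform(0.0, 100.0, size=2000)
        h = pointwise_coupling(e1, e2, eref)
        assert np.all(np.isfinite(h))
        back = evb_ground(e1, e2, h)
        assert np.max(np.abs(back - eref)) < 1e-9


class TestIdentifyStates:
    def test_single_well_distance_scan_uses_last_point(self):
        prof = profile_of([-5.0, -3.0, -1.0, -0.2, 0.0])
        assert identify_states(prof, "distance") == (0, 4)

    def test_double_well_picks_two_lowest_minima(self):
        prof = profile_of([0.0, -4.0, 2.0, -3.0, 1.0])
        assert identify_states(prof, "distance") == (1, 3)

    def test_monotone_profile_on_angle_scan_fails(self):
        prof = profile_of([0.0, 1.0, 2.0, 3.0])
        with pytest.raises(StateIdentificationError):
            identify_states(prof, "angle")

    def test_matches_brute_force_rule_on_random_profiles(self, rng):
        def brute(e, kind):
            n = len(e)
            mins = [i for i in range(n)
                    if (i == 0 and e[0] < e[1])
                    or (i == n - 1 and e[-1] < e[-2])
                    or (0 < i < n - 1 and e[i] < e[i - 1] and e[i] < e[i + 1])]
            if not mins:
                return None
            mins = sorted(mins, key=lambda i: (e[i], i))
            if kind == "distance" and len(mins) == 1:
                return (mins[0], n - 1) if mins[0] != n - 1 else None
            if len(mins) >= 2:
                return (mins[0], mins[1])
            return None

        for trial in range(300):
            n = int(rng.integers(3, 30))
            e = np.cumsum(rng.normal(size=n))
            kind = "distance" if trial % 2 == 0 else "dihedral"
            expected = brute(list(e), kind)
            prof = profile_of(e)
            if expected is None:
                with pytest.raises(StateIdentificationError):
                    identify_states(prof, kind)
            else:
                assert identify_states(prof, kind) == expected


class TestAlignState:
    def test_arithmetic(self):
        e = profile_of([10.0, 12.0])
        eref = profile_of([0.0, 5.0])
        shifted, shift = align_state(e, 0, eref)
        assert shift == -10.0
        assert list(shifted.e) == [0.0, 2.0]

    def test_identity_when_matching(self):
        e = profile_of([3.0, 4.0])
        _, shift = align_state(e, 0, profile_of([3.0, 9.0]))
        assert shift == 0.0

    def test_zero_of_energy_at_last_point(self):
        e = profile_of([50.0, 20.0, 7.0])
        eref = profile_of([43.0, 13.0, 0.0])
        shifted, _ = align_state(e, 2, eref)
        assert shifted.e[2] == 0.0


class TestCalibrate:
    def test_constant_coupling_recovery(self, two_state_const):
        data, truth = two_state_const
        res = calibrate(data, "constant", optimize_shifts=True)
        assert res.converged
        assert res.coupling.A == pytest.approx(truth.coupling.A, abs=1e-6)
        assert res.max_abs_residual < 1e-6
        assert res.s1 == pytest.approx(truth.s1, abs=1e-6)
        assert res.s2 == pytest.approx(truth.s2, abs=1e-6)

    def test_gaussian_coupling_recovery(self):
        spec = synth.TwoStateSpec(
            grid=tuple(np.linspace(1.2, 4.0, 40)),
            state1=HarmonicBond(1, 2, k=900.0, r0=1.5),
            state2=HarmonicBond(1, 2, k=350.0, r0=3.0),
            coupling=CouplingModel("gaussian", 40.0, 2.2, 0.3),
            s2=40.0,
        )
        data, truth = synth.make_two_state_system(spec)
        res = calibrate(data, "gaussian", optimize_shifts=True)
        assert res.coupling.A == pytest.approx(40.0, rel=1e-4)
        assert res.coupling.r0 == pytest.approx(2.2, rel=1e-4)
        assert res.coupling.w == pytest.approx(0.3, rel=1e-4)

    def test_identical_profiles_need_no_coupling(self):
        r = np.linspace(1.0, 4.0, 25)
        well = 200.0 * (r - 1.6) ** 2  # single-well distance profile
        p = EnergyProfile.from_arrays(r, well)
        res = calibrate(EVBInput(p, p, p), "constant")
        assert res.coupling.A == pytest.approx(0.0, abs=1e-9)
        assert res.max_abs_residual == pytest.approx(0.0, abs=1e-9)

    def test_infeasible_when_no_point_admits_real_coupling(self):
        # even after anchoring, the other state undercuts the reference at
        # each anchor and the barrier towers above both states in between
        r = [1.0, 2.0, 3.0]
        e1 = EnergyProfile.from_arrays(r, [0.0, -200.0, -200.0])
        e2 = EnergyProfile.from_arrays(r, [-200.0, -200.0, 0.0])
        eref = EnergyProfile.from_arrays(r, [0.0, 100.0, 0.0])
        with pytest.raises(CalibrationInfeasibleError):
            calibrate(EVBInput(e1, e2, eref), "constant", anchors=(0, 2))

    def test_max_abs_residual_matches_brute_force(self, two_state_const):
        data, _ = two_state_const
        for kind in ("constant", "gaussian"):
            res = calibrate(data, kind, optimize_shifts=True)
            brute = max(abs(a - b) for a, b in zip(res.e_evb.e, data.eref.e))
            assert res.max_abs_residual == brute

    def test_noisy_constant_estimate_is_unbiased_and_near_the_crlb(self):
        # Coupling is identifiable only near the state-crossing seam, so the
        # information bound for A under these conditions is sd ≈ 0.84 kJ/mol
        # at σ = 1 (Cramér–Rao with jointly estimated shifts).  Check the
        # estimator is unbiased and its spread is of that order, i.e. the
        # calibration loses little of the available information.
        truth_a, sigma = 25.0, 1.0
        errs = []
        for seed in range(30):
            spec = synth.default_two_state_spec(seed=seed, noise_sigma=sigma)
            data, _ = synth.make_two_state_system(spec)
            res = calibrate(data, "constant", optimize_shifts=True)
            errs.append(res.coupling.A - truth_a)
        errs = np.asarray(errs)
        assert abs(errs.mean()) < 0.6  # ≈3 standard errors of the mean
        assert np.sum(np.abs(errs) <= 3.0) >= 28  # ~3.5× the CRLB sd

    def test_summary_reports_parameters(self, two_state_const):
        data, _ = two_state_const
        res = EVBCouplingModel(data, "constant").fit()
        text = res.summary()
        assert "constant" in text and "max |residual|" in text


class TestMorse:
    def test_parameter_recovery(self):
        r = np.linspace(1.1, 5.0, 60)
        truth = MorseParams(350.0, 1.53, 1.9)
        prof = EnergyProfile.from_arrays(r, truth(r))
        params, residuals = fit_morse(prof)
        assert params.De == pytest.approx(350.0, rel=1e-6)
        assert params.re == pytest.approx(1.53, rel=1e-6)
        assert params.a == pytest.approx(1.9, rel=1e-6)
        assert max(abs(x) for x in residuals) < 1e-6

    def test_recovery_with_offset(self):
        r = np.linspace(1.1, 5.0, 60)
        prof = EnergyProfile.from_arrays(r, MorseParams(350.0, 1.53, 1.9)(r, v0=-120.0))
        res = MorseModel(prof).fit()
        assert res.v0 == pytest.approx(-120.0, rel=1e-6)
        assert res.params.De == pytest.approx(350.0, rel=1e-6)

    def test_constant_profile_has_no_well(self):
        with pytest.raises(NoWellError):
            fit_morse(profile_of([5.0, 5.0, 5.0, 5.0]))

    def test_monotone_profile_has_no_well(self):
        with pytest.raises(NoWellError):
            fit_morse(profile_of([0.0, 1.0, 2.0, 3.0]))

    def test_residual_at_minimum_bounded_by_max(self):
        r = np.linspace(1.1, 5.0, 60)
        rng = np.random.default_rng(3)
        e = MorseParams(350.0, 1.53, 1.9)(r) + rng.normal(0, 0.5, size=r.size)
        res = MorseModel(EnergyProfile.from_arrays(r, e)).fit()
        i0 = int(np.argmin(e))
        assert abs(res.residuals[i0]) <= res.max_abs_residual


class TestFittingRecords:
    def test_constant_record_schema(self, two_state_const):
        data, _ = two_state_const
        res = calibrate(data, "constant", optimize_shifts=True)
        rec = to_fitting_record(res, "local calibration")
        assert rec.method_name == "EVB-2state-constant"
        assert [n for n, _v, _u in rec.parameters] == ["A", "s1", "s2"]
        assert rec.get("A") == res.coupling.A

    def test_morse_record_schema(self):
        rec = to_fitting_record(MorseParams(350.0, 1.53, 1.9), "textbook")
        assert rec.method_name == "MorsePotential"
        assert [n for n, _v, _u in rec.parameters] == ["De", "re", "a", "V0"]

    def test_record_round_trips_through_graph(self, two_state_const):
        data, _ = two_state_const
        res = calibrate(data, "gaussian", optimize_shifts=True)
        rec = to_fitting_record(res, "local calibration")
        scan = make_diatomic_scan([1.5, 1.6])
        g = kg.to_graph(scan)
        kg.attach_fitting(g, scan.iri, rec)
        back = kg.from_graph(g, scan.iri)
        assert back.fittings == (rec,)
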