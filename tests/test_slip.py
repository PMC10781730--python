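"""Simulator unit and property tests: leg forces, event handling, energy
conservation, noise injection, serialization."""

import numpy as np
import pytest

from templatesig import (GaitFailureError, InitialState, LegParams,
                         SlipParams, Trial, add_noise, canonical_params,
                         canonical_initial_state, mechanical_energy, simulate,
                         slip_acceleration, symmetric_params)
from templatesig.slip import leg_geometry, touchdown_direction, LEG_SIGN

G = 9.81


def _single_leg(k_L=10_000.0, L_0=1.0, **kw):
    leg = LegParams(k_L=k_L, L_0=L_0, **kw)
    return symmetric_params(M=70.0, g=G, L_bio=1.0, leg=leg)


class TestSlipAcceleration:
    def test_ballistic_limit_no_active_legs(self):
        p = _single_leg()
        acc = slip_acceleration({}, {}, set(), p)
        assert np.allclose(acc, [0, -G, 0])

    def test_vanishing_gains_any_state(self):
        # k_L cannot be exactly zero (invariant), but the force scales to zero
        p = _single_leg(k_L=1e-12)
        q = {"R": np.array([0.3, 0.8, 0.1])}
        v = {"R": np.array([1.0, -0.2, 0.05])}
        acc = slip_acceleration(q, v, {"R"}, p)
        assert np.allclose(acc, [0, -G, 0], atol=1e-10)

    def test_unloaded_spring_at_rest_length(self):
        p = _single_leg(k_L=10_000.0, L_0=1.0)
        acc = slip_acceleration({"R": np.array([0.0, 1.0, 0.0])},
                                {"R": np.zeros(3)}, {"R"}, p)
        assert np.allclose(acc, [0, -G, 0])

    def test_compressed_vertical_spring_hand_value(self):
        # k_L*(compression)/M - g = 10000*0.05/70 - 9.81
        p = _single_leg(k_L=10_000.0, L_0=1.0)
        acc = slip_acceleration({"R": np.array([0.0, 0.95, 0.0])},
                                {"R": np.zeros(3)}, {"R"}, p)
        assert acc[1] == pytest.approx(10_000 * 0.05 / 70 - G, rel=1e-12)
        assert acc[0] == acc[2] == 0.0

    def test_zero_leg_length_raises(self):
        p = _single_leg()
        with pytest.raises(ValueError, match="zero leg length"):
            slip_acceleration({"R": np.zeros(3)}, {"R": np.zeros(3)},
                              {"R"}, p)

    def test_zero_projection_with_rotary_gains_raises(self):
        p = _single_leg(k_s=100.0)
        # q in the ML axis only: sagittal projection length is zero
        with pytest.raises(ValueError, match="sagittal projection"):
            slip_acceleration({"R": np.array([0.0, 0.0, 0.5])},
                              {"R": np.zeros(3)}, {"R"}, p)

    def test_unknown_leg_rejected(self):
        with pytest.raises(ValueError):
            slip_acceleration({}, {}, {"X"}, _single_leg())


class TestSimulate:
    def test_energy_conserved_without_damping(self, params, canonical_trial):
        tr = canonical_trial
        E = mechanical_energy(params, tr.com, tr.com_vel,
                              {"R": tr.foot_r, "L": tr.foot_l},
                              {"R": tr.contact_r, "L": tr.contact_l})
        assert np.ptp(E) / E.mean() < 1e-7

    def test_stride_cycle_contact_pattern(self, canonical_trial):
        """Contact flags recomputed from postconditions: the gait cycles
        DS -> SS -> DS -> SS and someone is always on the ground."""
        cr = canonical_trial.contact_r
        cl = canonical_trial.contact_l
        assert not np.any(~cr & ~cl)
        labels = np.where(cr & cl, "DS", np.where(cr, "SS_R", "SS_L"))
        runs = [labels[0]]
        for x in labels[1:]:
            if x != runs[-1]:
                runs.append(x)
        # strip boundary partials, then the pattern must alternate DS/SS
        for a, b in zip(runs[1:-1], runs[2:-1]):
            if a == "DS":
                assert b in ("SS_R", "SS_L")
            else:
                assert b == "DS"

    def test_contact_flags_match_event_postconditions(self, params,
                                                      canonical_trial):
        """In-contact feet are at ground height; stance springs are short of
        resting length except at the transition instants."""
        tr = canonical_trial
        for leg, foot, contact in (("R", tr.foot_r, tr.contact_r),
                                   ("L", tr.foot_l, tr.contact_l)):
            assert np.allclose(foot[1, contact], 0.0, atol=1e-12)
            L = np.linalg.norm(tr.com - foot, axis=0)
            assert np.all(L[contact] <= params.leg(leg).L_0 + 1e-6)

    def test_double_support_fraction_plausible(self, canonical_trial):
        """Each double-support phase occupies a plausible fraction of the
        stride (humans: ~10-12%; a conservative SLIP runs a bit longer)."""
        ds = (canonical_trial.contact_r & canonical_trial.contact_l).mean()
        assert 0.10 < ds / 2.0 < 0.25

    def test_feet_fixed_while_in_contact(self, canonical_trial):
        for foot, contact in ((canonical_trial.foot_r,
                               canonical_trial.contact_r),
                              (canonical_trial.foot_l,
                               canonical_trial.contact_l)):
            idx = np.flatnonzero(contact)
            runs = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
            for run in runs:
                assert np.ptp(foot[:, run], axis=1).max() == 0.0

    def test_walks_at_nominal_speed(self, canonical_trial):
        speed = ((canonical_trial.com[0, -1] - canonical_trial.com[0, 0])
                 / (canonical_trial.t[-1] - canonical_trial.t[0]))
        assert speed == pytest.approx(1.2, abs=0.1)

    def test_mediolateral_mirror_symmetry(self, params):
        """Mirroring the initial state in the frontal plane mirrors the whole
        trajectory (ML states are genuinely dynamic, not clamped)."""
        init = canonical_initial_state(params)
        mirror = np.array([1.0, 1.0, -1.0])
        vel = init.vel + np.array([0.0, 0.0, 0.05])
        i1 = InitialState(init.com, vel, init.foot_r, init.foot_l)
        i2 = InitialState(init.com * mirror, vel * mirror,
                          init.foot_r * mirror, init.foot_l * mirror)

        def run(i):
            try:
                return simulate(params, i, n_strides=3)
            except GaitFailureError as e:
                return e.trial

        t1, t2 = run(i1), run(i2)
        n = min(t1.n_samples, t2.n_samples)
        assert np.allclose(t1.com[:, :n], t2.com[:, :n] * mirror[:, None],
                           atol=1e-9)

    def test_gait_failure_carries_partial_trajectory(self):
        leg = LegParams(k_L=5_000.0, L_0=0.98, theta_td=-0.1)
        p = symmetric_params(M=70.0, g=G, L_bio=1.0, leg=leg)
        with pytest.raises(GaitFailureError, match="gait failed") as exc:
            simulate(p, canonical_initial_state(p), n_strides=30)
        assert exc.value.stride < 30
        if exc.value.trial is not None:
            assert exc.value.trial.n_samples > 0

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            symmetric_params(M=-1.0, g=G, L_bio=1.0,
                             leg=LegParams(k_L=1.0, L_0=1.0))
        with pytest.raises(ValueError):
            symmetric_params(M=70.0, g=G, L_bio=1.0,
                             leg=LegParams(k_L=1.0, L_0=1.3))
        with pytest.raises(ValueError):
            symmetric_params(M=70.0, g=G, L_bio=1.0,
                             leg=LegParams(k_L=1.0, L_0=1.0, c_L=-0.1))


class TestAddNoise:
    def test_zero_sd_is_identity(self, canonical_trial):
        out = add_noise(canonical_trial, 0.0, seed=3)
        assert np.array_equal(out.com, canonical_trial.com)

    def test_deterministic_under_seed(self, canonical_trial):
        a = add_noise(canonical_trial, 1e-3, seed=11)
        b = add_noise(canonical_trial, 1e-3, seed=11)
        assert np.array_equal(a.com, b.com)
        assert np.array_equal(a.foot_r, b.foot_r)

    def test_sample_sd_matches_requested(self, canonical_trial):
        sd = 1e-3
        out = add_noise(canonical_trial, sd, seed=5)
        resid = np.concatenate([
            (out.com - canonical_trial.com).ravel(),
            (out.foot_r - canonical_trial.foot_r).ravel(),
            (out.foot_l - canonical_trial.foot_l).ravel(),
        ])
        assert resid.size >= 10_000
        assert np.std(resid) == pytest.approx(sd, rel=0.05)

    def test_contacts_untouched(self, canonical_trial):
        out = add_noise(canonical_trial, 1e-3, seed=5)
        assert np.array_equal(out.contact_r, canonical_trial.contact_r)

    def test_negative_sd_rejected(self, canonical_trial):
        with pytest.raises(ValueError):
            add_noise(canonical_trial, -1e-3, seed=0)


class TestSerialization:
    def test_csv_roundtrip(self, canonical_trial, tmp_path):
        path = tmp_path / "trial.csv"
        canonical_trial.to_csv(path)
        back = Trial.from_csv(path)
        assert np.allclose(back.com, canonical_trial.com)
        assert np.array_equal(back.contact_l, canonical_trial.contact_l)
        assert back.M == canonical_trial.M
        assert back.provenance == "synthetic"


def test_touchdown_direction_matches_planar_angles():
    for th, ph, leg in ((-0.44, 0.0, "R"), (-0.3, 0.1, "R"), (-0.3, 0.1, "L")):
        u = touchdown_direction(th, ph, LEG_SIGN[leg])
        assert np.linalg.norm(u) == pytest.approx(1.0)
        L, theta, phi, _, _ = leg_geometry(u, LEG_SIGN[leg])
        assert theta == pytest.approx(th)
        assert phi == pytest.approx(ph)
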