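"""Bipedal spring-loaded-inverted-pendulum (SLIP) walking simulator.

Forward-simulates a 3D point-mass biped whose massless legs generate force
through a radial spring + damper and sagittal/frontal rotary spring–dampers,
with event-driven touchdown/liftoff transitions.  Serves as the ground-truth
generator for the template-signature identification pipeline: every mechanism
the function library can select is present here with a known constant, so
recovered coefficients can be checked against truth.

World axes are (anterior–posterior, vertical, mediolateral); the ground plane
is at height 0 and gravity acts along -y.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

Leg = Literal["R", "L"]
LEGS: tuple[Leg, Leg] = ("R", "L")

#: Sign convention for the frontal-plane leg angle: positive when the CoM is
#: displaced toward the contralateral side.  With the ML axis positive to the
#: left, that means +q_z for the right leg and -q_z for the left.
LEG_SIGN = {"R": +1.0, "L": -1.0}

DEFAULT_FALL_FRACTION = 0.4  # gait "fails" when vertical CoM < 0.4 * L_bio
DEFAULT_SWING_CLEARANCE = 0.05  # peak swing-foot height above ground (m)


# ---------------------------------------------------------------------------
# parameters and trial container
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LegParams:
    """Mechanism constants of one leg (SI units).

    k_L : radial (leg) stiffness, N/m
    L_0 : leg resting length, m
    c_L : radial damping, N*s/m
    k_s, c_s : sagittal-plane rotary stiffness (N*m/rad) and damping
    k_f, c_f : frontal-plane rotary stiffness and damping
    theta_td, phi_td : touchdown leg angles from vertical (rad); theta_td < 0
        places the foot anterior to the CoM, phi_td > 0 lateral (toward the
        leg's own side after mirroring).
    """

    k_L: float
    L_0: float
    c_L: float = 0.0
    k_s: float = 0.0
    c_s: float = 0.0
    k_f: float = 0.0
    c_f: float = 0.0
    theta_td: float = -0.35
    phi_td: float = 0.0


@dataclass(frozen=True)
class SlipParams:
    """Full parameter set of the bipedal SLIP walker."""

    M: float
    g: float
    L_bio: float
    right: LegParams
    left: LegParams
    speed: float = 1.2  # nominal forward speed (m/s), metadata only

    def __post_init__(self) -> None:
        if self.M <= 0 or self.g <= 0 or self.L_bio <= 0:
            raise ValueError("M, g and L_bio must all be positive")
        for leg in (self.right, self.left):
            if leg.k_L <= 0:
                raise ValueError("leg stiffness k_L must be positive")
            if not 0.0 < leg.L_0 <= 1.2 * self.L_bio:
                raise ValueError("resting length must satisfy 0 < L_0 <= 1.2*L_bio")
            for c in (leg.c_L, leg.c_s, leg.c_f):
                if c < 0:
                    raise ValueError("damping values must be non-negative")

    def leg(self, leg: Leg) -> LegParams:
        return self.right if leg == "R" else self.left


def symmetric_params(
    M: float,
    g: float,
    L_bio: float,
    leg: LegParams,
    speed: float = 1.2,
) -> SlipParams:
    """Walker with identical right and left legs."""
    return SlipParams(M=M, g=g, L_bio=L_bio, right=leg, left=leg, speed=speed)


@dataclass
class Trial:
    """One walking trial: uniformly sampled CoM and foot trajectories.

    Arrays are shaped (3, m) with axes (AP, vertical, ML).  Contact flags are
    per-sample booleans.  ``com_vel`` is an optional simulator-side extra
    (exact velocities from the integrator's dense output) used by oracle
    tests; it is not part of the serialized format and measured data will not
    have it.
    """

    t: np.ndarray
    com: np.ndarray
    foot_r: np.ndarray
    foot_l: np.ndarray
    contact_r: np.ndarray
    contact_l: np.ndarray
    M: float
    L_bio: float
    g: float = 9.81
    provenance: str = "synthetic"
    noise_seed: int | None = None
    noise_sd: float = 0.0
    com_vel: np.ndarray | None = None

    def __post_init__(self) -> None:
        m = self.t.size
        for name in ("com", "foot_r", "foot_l"):
            arr = getattr(self, name)
            if arr.shape != (3, m):
                raise ValueError(f"{name} must have shape (3, {m})")
        if self.contact_r.shape != (m,) or self.contact_l.shape != (m,):
            raise ValueError("contact flags must match the time vector")
        if m >= 3:
            dt = np.diff(self.t)
            if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
                raise ValueError("time vector must be uniformly spaced")

    @property
    def n_samples(self) -> int:
        return self.t.size

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    def foot(self, leg: Leg) -> np.ndarray:
        return self.foot_r if leg == "R" else self.foot_l

    def contact(self, leg: Leg) -> np.ndarray:
        return self.contact_r if leg == "R" else self.contact_l

    # -- serialization: tidy CSV + JSON sidecar ----------------------------

    def to_csv(self, path: str | Path) -> None:
        path = Path(path)
        cols = {
            "t": self.t,
            "com_x": self.com[0], "com_y": self.com[1], "com_z": self.com[2],
            "footR_x": self.foot_r[0], "footR_y": self.foot_r[1], "footR_z": self.foot_r[2],
            "footL_x": self.foot_l[0], "footL_y": self.foot_l[1], "footL_z": self.foot_l[2],
            "contactR": self.contact_r.astype(int),
            "contactL": self.contact_l.astype(int),
        }
        pd.DataFrame(cols).to_csv(path, index=False)
        sidecar = {
            "M": self.M, "L_bio": self.L_bio, "g": self.g,
            "provenance": self.provenance,
            "noise_seed": self.noise_seed, "noise_sd": self.noise_sd,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def from_csv(cls, path: str | Path) -> "Trial":
        path = Path(path)
        df = pd.read_csv(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        return cls(
            t=df["t"].to_numpy(),
            com=df[["com_x", "com_y", "com_z"]].to_numpy().T,
            foot_r=df[["footR_x", "footR_y", "footR_z"]].to_numpy().T,
            foot_l=df[["footL_x", "footL_y", "footL_z"]].to_numpy().T,
            contact_r=df["contactR"].to_numpy().astype(bool),
            contact_l=df["contactL"].to_numpy().astype(bool),
            M=float(meta["M"]), L_bio=float(meta["L_bio"]), g=float(meta["g"]),
            provenance=str(meta.get("provenance", "measured")),
            noise_seed=meta.get("noise_seed"),
            noise_sd=float(meta.get("noise_sd", 0.0)),
        )


class GaitFailureError(RuntimeError):
    """Raised when the walker falls or loses ground contact before completing
    the requested number of strides.  Carries the partial trajectory."""

    def __init__(self, message: str, stride: int, trial: Trial | None = None):
        super().__init__(message)
        self.stride = stride
        self.trial = trial


# ---------------------------------------------------------------------------
# leg geometry (shared with the state-computation module)
# ---------------------------------------------------------------------------


def leg_geometry(q_rel: np.ndarray, sign: float):
    """Planar-projection leg geometry from a CoM-minus-foot vector.

    Returns (L, theta, phi, L_s, L_f) where theta is the sagittal-plane angle
    from vertical (positive CoM-anterior), phi the frontal-plane angle from
    vertical (positive toward the contralateral side; ``sign`` mirrors the
    two legs), and L_s, L_f the in-plane projection lengths.  Works on (3,)
    vectors or (3, m) arrays.
    """
    qx, qy, qz = q_rel[0], q_rel[1], q_rel[2]
    L = np.sqrt(qx**2 + qy**2 + qz**2)
    L_s = np.sqrt(qx**2 + qy**2)
    L_f = np.sqrt(qz**2 + qy**2)
    theta = np.arctan2(qx, qy)
    phi = np.arctan2(sign * qz, qy)
    return L, theta, phi, L_s, L_f


def touchdown_direction(theta_td: float, phi_td: float, sign: float) -> np.ndarray:
    """Unit vector u such that a leg with q_rel = L_0 * u has the given
    planar touchdown angles (foot at com - L_0*u)."""
    ts, tf = np.tan(theta_td), np.tan(phi_td)
    uy = 1.0 / np.sqrt(1.0 + ts**2 + tf**2)
    return np.array([uy * ts, uy, sign * uy * tf])


# ---------------------------------------------------------------------------
# leg force / CoM acceleration
# ---------------------------------------------------------------------------


def _leg_force(
    q: np.ndarray,
    v: np.ndarray,
    p: LegParams,
    sign: float,
    rotary_transverse: bool,
) -> np.ndarray:
    L, theta, phi, L_s, L_f = leg_geometry(q, sign)
    if L == 0:
        raise ValueError("zero leg length: force direction undefined")
    L_dot = float(q @ v) / L
    force = -(p.k_L * (L - p.L_0) + p.c_L * L_dot) * q / L

    if p.k_s != 0.0 or p.c_s != 0.0:
        if L_s == 0:
            raise ValueError("zero sagittal projection with nonzero rotary gains")
        theta_dot = (v[0] * q[1] - q[0] * v[1]) / L_s**2
        mag = p.k_s * theta + p.c_s * theta_dot
        if rotary_transverse:
            # force transverse to the leg in the sagittal plane (the gradient
            # of the rotary spring energy), magnitude torque / L_s
            e_t = np.array([q[1], -q[0], 0.0]) / L_s
            force += -(mag / L_s) * e_t
        else:
            force += -mag * q / L_s**2

    if p.k_f != 0.0 or p.c_f != 0.0:
        if L_f == 0:
            raise ValueError("zero frontal projection with nonzero rotary gains")
        phi_dot = sign * (v[2] * q[1] - q[2] * v[1]) / L_f**2
        mag = p.k_f * phi + p.c_f * phi_dot
        if rotary_transverse:
            e_t = np.array([0.0, -sign * q[2], sign * q[1]]) / L_f
            force += -(mag / L_f) * e_t
        else:
            force += -mag * q / L_f**2

    return force


def slip_acceleration(
    q_rel: dict[Leg, np.ndarray],
    v_rel: dict[Leg, np.ndarray],
    active_legs: set[Leg] | frozenset[Leg],
    params: SlipParams,
    rotary_transverse: bool = False,
) -> np.ndarray:
    """CoM acceleration (m/s^2) given per-leg relative states and the set of
    legs in ground contact.  Legs not in contact contribute zero force."""
    if not set(active_legs) <= {"R", "L"}:
        raise ValueError(f"unknown legs in {active_legs!r}")
    total = np.zeros(3)
    for leg in active_legs:
        total += _leg_force(
            np.asarray(q_rel[leg], dtype=float),
            np.asarray(v_rel[leg], dtype=float),
            params.leg(leg),
            LEG_SIGN[leg],
            rotary_transverse,
        )
    return np.array([0.0, -params.g, 0.0]) + total / params.M


# ---------------------------------------------------------------------------
# hybrid forward simulation
# ---------------------------------------------------------------------------


@dataclass
class InitialState:
    """State at a right-leg touchdown instant: CoM position/velocity and both
    foot positions, with both feet in contact (start of first double support).
    """

    com: np.ndarray
    vel: np.ndarray
    foot_r: np.ndarray
    foot_l: np.ndarray


@dataclass
class _Segment:
    t0: float
    t1: float
    sol: object  # OdeSolution
    feet: dict[Leg, np.ndarray]
    contacts: frozenset


def _sample_swing_path(
    t: np.ndarray, t0: float, t1: float, p0: np.ndarray, p1: np.ndarray,
    clearance: float,
) -> np.ndarray:
    """Smooth massless-foot path from liftoff (t0, p0) to touchdown (t1, p1):
    minimum-jerk horizontal profile plus a C1 vertical clearance bump."""
    tau = np.clip((t - t0) / max(t1 - t0, 1e-12), 0.0, 1.0)
    s = 10 * tau**3 - 15 * tau**4 + 6 * tau**5
    path = p0[:, None] + (p1 - p0)[:, None] * s[None, :]
    path[1] += clearance * 16 * tau**2 * (1 - tau) ** 2
    return path


def simulate(
    params: SlipParams,
    initial_state: InitialState,
    n_strides: int,
    dt: float = 1.0 / 120.0,
    seed: int | None = None,
    rotary_transverse: bool = False,
    fall_fraction: float = DEFAULT_FALL_FRACTION,
    swing_clearance: float = DEFAULT_SWING_CLEARANCE,
    rtol: float = 1e-9,
    atol: float = 1e-10,
    max_time_per_stride: float = 5.0,
) -> Trial:
    """Integrate the hybrid walking dynamics for ``n_strides`` strides.

    A stride runs from one right-foot touchdown to the next.  Touchdown fires
    when the swing foot, virtually placed at the touchdown angles with length
    L_0 from the CoM, reaches ground height; liftoff fires when a stance
    spring returns to its resting length.  Raises :class:`GaitFailureError`
    (carrying the partial trajectory) if the CoM drops below
    ``fall_fraction * L_bio`` or ground contact is lost before completion.

    ``seed`` is recorded as trial provenance only; the dynamics are
    deterministic.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    feet: dict[Leg, np.ndarray] = {
        "R": np.asarray(initial_state.foot_r, dtype=float).copy(),
        "L": np.asarray(initial_state.foot_l, dtype=float).copy(),
    }
    contacts: set[Leg] = {"R", "L"}
    y = np.concatenate([initial_state.com, initial_state.vel])
    if y[1] <= 0:
        raise ValueError("initial vertical CoM must be positive")

    segments: list[_Segment] = []
    # swing intervals with exact event endpoints, for path reconstruction
    swing_records: list[dict] = []
    touchdown_times: list[float] = []
    t_now = 0.0
    strides = 0
    fall_height = fall_fraction * params.L_bio
    t_max = max_time_per_stride * (n_strides + 2)

    def rhs(t, y):
        com, vel = y[:3], y[3:]
        q = {leg: com - feet[leg] for leg in contacts}
        v = {leg: vel for leg in contacts}
        acc = slip_acceleration(q, v, contacts, params, rotary_transverse)
        return np.concatenate([vel, acc])

    def make_events():
        events = []
        kinds = []

        def fall(t, y):
            return y[1] - fall_height
        fall.terminal = True
        fall.direction = -1
        events.append(fall)
        kinds.append(("fall", None))

        for leg in sorted(contacts):
            p = params.leg(leg)

            def liftoff_ev(t, y, leg=leg, L0=p.L_0):
                return np.linalg.norm(y[:3] - feet[leg]) - L0
            liftoff_ev.terminal = True
            liftoff_ev.direction = +1
            events.append(liftoff_ev)
            kinds.append(("liftoff", leg))

        for leg in sorted(set(LEGS) - contacts):
            p = params.leg(leg)
            u = touchdown_direction(p.theta_td, p.phi_td, LEG_SIGN[leg])

            def touchdown_ev(t, y, L0=p.L_0, uy=u[1]):
                return y[1] - L0 * uy
            touchdown_ev.terminal = True
            touchdown_ev.direction = -1
            events.append(touchdown_ev)
            kinds.append(("touchdown", leg))

        return events, kinds

    def build_trial(t_end: float) -> Trial | None:
        if t_end <= dt:
            return None
        m = int(np.floor(t_end / dt)) + 1
        t_grid = np.arange(m) * dt
        com = np.empty((3, m))
        vel = np.empty((3, m))
        foot = {leg: np.empty((3, m)) for leg in LEGS}
        contact = {leg: np.zeros(m, dtype=bool) for leg in LEGS}
        # CoM from dense outputs
        for seg in segments:
            mask = (t_grid >= seg.t0 - 1e-12) & (t_grid <= seg.t1 + 1e-12)
            if not mask.any():
                continue
            ys = seg.sol(np.clip(t_grid[mask], seg.sol.t_min, seg.sol.t_max))
            com[:, mask] = ys[:3]
            vel[:, mask] = ys[3:]
            for leg in LEGS:
                if leg in seg.contacts:
                    foot[leg][:, mask] = seg.feet[leg][:, None]
                    contact[leg][mask] = True
        # swing-foot paths between (liftoff, touchdown) event pairs
        for leg in LEGS:
            in_swing = ~contact[leg]
            if not in_swing.any():
                continue
            filled = np.zeros(m, dtype=bool)
            for rec in swing_records:
                if rec["leg"] != leg:
                    continue
                sel = in_swing & (t_grid >= rec["t0"]) & (t_grid <= rec.get("t1", np.inf))
                if not sel.any():
                    continue
                if "t1" in rec:
                    foot[leg][:, sel] = _sample_swing_path(
                        t_grid[sel], rec["t0"], rec["t1"], rec["p0"],
                        rec["p1"], swing_clearance)
                else:
                    # swing unfinished (gait failure): hold the liftoff pose
                    foot[leg][:, sel] = rec["p0"][:, None]
                filled |= sel
            # swing samples before the first recorded liftoff (none in a
            # normal run, which starts in double support)
            rest = in_swing & ~filled
            if rest.any():
                ref = np.flatnonzero(~in_swing)
                nearest = ref[np.searchsorted(ref, np.flatnonzero(rest)).clip(0, ref.size - 1)]
                foot[leg][:, rest] = foot[leg][:, nearest]
        return Trial(
            t=t_grid, com=com, foot_r=foot["R"], foot_l=foot["L"],
            contact_r=contact["R"], contact_l=contact["L"],
            M=params.M, L_bio=params.L_bio, g=params.g,
            provenance="synthetic", noise_seed=seed, com_vel=vel,
        )

    while strides < n_strides:
        events, kinds = make_events()
        sol = solve_ivp(
            rhs, (t_now, t_max), y, method="RK45", dense_output=True,
            events=events, rtol=rtol, atol=atol, max_step=0.05,
        )
        if sol.status != 1:
            raise GaitFailureError(
                f"gait failed at stride {strides}: no transition found "
                f"(integrator status {sol.status})",
                stride=strides, trial=build_trial(sol.t[-1]),
            )
        t_event = sol.t[-1]
        segments.append(_Segment(t_now, t_event, sol.sol, dict(feet), frozenset(contacts)))
        # which event fired
        fired = [i for i, te in enumerate(sol.t_events) if te.size > 0]
        kind, leg = kinds[fired[0]]
        y = sol.y[:, -1].copy()
        t_now = t_event

        if kind == "fall":
            raise GaitFailureError(
                f"gait failed at stride {strides}: CoM fell below "
                f"{fall_height:.3f} m at t = {t_now:.3f} s",
                stride=strides, trial=build_trial(t_now),
            )
        if kind == "liftoff":
            contacts.discard(leg)
            swing_records.append({"leg": leg, "t0": t_now,
                                  "p0": feet[leg].copy()})
            if not contacts:
                raise GaitFailureError(
                    f"gait failed at stride {strides}: both feet left the "
                    "ground (flight phase, not walking)",
                    stride=strides, trial=build_trial(t_now),
                )
        else:  # touchdown
            p = params.leg(leg)
            u = touchdown_direction(p.theta_td, p.phi_td, LEG_SIGN[leg])
            new_foot = y[:3] - p.L_0 * u
            new_foot[1] = 0.0
            feet[leg] = new_foot
            for rec in reversed(swing_records):
                if rec["leg"] == leg and "t1" not in rec:
                    rec["t1"] = t_now
                    rec["p1"] = new_foot.copy()
                    break
            contacts.add(leg)
            touchdown_times.append(t_now)
            if leg == "R":
                strides += 1

    trial = build_trial(touchdown_times[-1] if touchdown_times else t_now)
    assert trial is not None
    return trial


def add_noise(trial: Trial, sd_pos: float, seed: int) -> Trial:
    """Additive i.i.d. zero-mean Gaussian noise (sd in metres) on CoM and
    foot positions, emulating marker-based motion-capture error.  Contact
    flags and time are untouched; deterministic under a fixed seed."""
    if sd_pos < 0:
        raise ValueError("sd_pos must be non-negative")
    if sd_pos == 0:
        return replace(trial)
    rng = np.random.default_rng(seed)
    m = trial.n_samples
    return replace(
        trial,
        com=trial.com + rng.normal(0.0, sd_pos, (3, m)),
        foot_r=trial.foot_r + rng.normal(0.0, sd_pos, (3, m)),
        foot_l=trial.foot_l + rng.normal(0.0, sd_pos, (3, m)),
        noise_seed=seed,
        noise_sd=sd_pos,
        com_vel=None,
    )


def mechanical_energy(
    params: SlipParams,
    com: np.ndarray,
    vel: np.ndarray,
    feet: dict[Leg, np.ndarray],
    contacts: dict[Leg, np.ndarray],
) -> np.ndarray:
    """Total mechanical energy per sample: kinetic + gravitational + elastic
    (radial and rotary springs of legs in contact).  Only meaningful as a
    conserved quantity when all damping is zero and rotary terms vanish or
    the transverse rotary variant is used."""
    E = 0.5 * params.M * np.sum(vel**2, axis=0) + params.M * params.g * com[1]
    for leg in LEGS:
        p = params.leg(leg)
        q = com - feet[leg]
        L, theta, phi, _, _ = leg_geometry(q, LEG_SIGN[leg])
        on = contacts[leg]
        E = E + on * (
            0.5 * p.k_L * (L - p.L_0) ** 2
            + 0.5 * p.k_s * theta**2
            + 0.5 * p.k_f * phi**2
        )
    return E
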