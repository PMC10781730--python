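"""Template state variables from raw CoM/foot trajectories.

Turns a :class:`~templatesig.slip.Trial` into the per-leg kinematic states the
mechanism library is built from (leg lengths, planar-projection angles and
their velocities), CoM accelerations, a continuous kinematic phase variable
psi in [0, 100)% of a stride, and per-sample gait-phase labels defined by
foot-contact configuration.

Angles are planar-projection angles (sagittal: AP–vertical plane, positive
with the CoM anterior to the foot; frontal: ML–vertical plane, positive
toward the contralateral side and mirrored between legs), not spherical
coordinates.  Derivatives come from Savitzky–Golay smoothing differentiation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .slip import LEG_SIGN, LEGS, Leg, Trial, leg_geometry

#: gait phases in stride order: first double support (after a right heel
#: strike), right single support, second double support (after a left heel
#: strike), left single support
GAIT_PHASES = ("DS1", "SS_R", "DS2", "SS_L")

#: per-leg role within each system gait phase, used when reporting signatures
#: per (leg, phase)
LEG_ROLES = {
    ("R", "DS1"): "leading_DS", ("L", "DS1"): "trailing_DS",
    ("R", "SS_R"): "single_support", ("L", "SS_R"): "swing",
    ("R", "DS2"): "trailing_DS", ("L", "DS2"): "leading_DS",
    ("R", "SS_L"): "swing", ("L", "SS_L"): "single_support",
}


@dataclass
class LegStates:
    """Kinematic states of one leg, per sample."""

    q_rel: np.ndarray  # (3, m) CoM minus foot
    v_rel: np.ndarray  # (3, m) smoothed d/dt of q_rel
    L: np.ndarray
    L_dot: np.ndarray
    theta: np.ndarray
    theta_dot: np.ndarray
    phi: np.ndarray
    phi_dot: np.ndarray
    L_s: np.ndarray
    L_f: np.ndarray


@dataclass
class TemplateStates:
    """All per-sample state variables of a trial."""

    t: np.ndarray
    legs: dict[Leg, LegStates]
    com_acc: np.ndarray  # (3, m)
    psi: np.ndarray  # (m,) continuous phase, % stride in [0, 100)
    gait_phase: np.ndarray  # (m,) strings from GAIT_PHASES
    trial: Trial

    @property
    def n_samples(self) -> int:
        return self.t.size

    def phase_mask(self, phase: str) -> np.ndarray:
        return self.gait_phase == phase

    def to_frame(self) -> pd.DataFrame:
        """One row per sample with documented column names."""
        cols: dict[str, np.ndarray] = {"t": self.t, "psi": self.psi,
                                       "gait_phase": self.gait_phase}
        for leg in LEGS:
            s = self.legs[leg]
            lo = leg.lower()
            cols.update({
                f"L_{lo}": s.L, f"Ldot_{lo}": s.L_dot,
                f"theta_{lo}": s.theta, f"thetadot_{lo}": s.theta_dot,
                f"phi_{lo}": s.phi, f"phidot_{lo}": s.phi_dot,
                f"Ls_{lo}": s.L_s, f"Lf_{lo}": s.L_f,
            })
        for i, ax in enumerate(("x", "y", "z")):
            cols[f"com_acc_{ax}"] = self.com_acc[i]
        return pd.DataFrame(cols)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(Path(path), index=False)


# ---------------------------------------------------------------------------
# smoothed differentiation
# ---------------------------------------------------------------------------


def _sg_derivative(x: np.ndarray, dt: float, deriv: int, window: int,
                   polyorder: int) -> np.ndarray:
    """Savitzky–Golay derivative along the last axis."""
    window = min(window, x.shape[-1] if x.shape[-1] % 2 else x.shape[-1] - 1)
    if window <= polyorder:
        raise ValueError("trial too short for the smoothing window")
    return savgol_filter(x, window_length=window, polyorder=polyorder,
                         deriv=deriv, delta=dt, axis=-1, mode="interp")


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def estimate_position_noise(trial: Trial) -> float:
    """Robust estimate of additive position-noise SD (metres).

    Uses the median absolute deviation of 4th-order differences, which
    annihilate the smooth trajectory (4th-derivative content is microns at
    gait frequencies) and have variance 70*sigma^2 for white noise.  The
    median over all nine position signals guards against impact transients.
    """
    sigmas = []
    for arr in (trial.com, trial.foot_r, trial.foot_l):
        d4 = np.diff(arr, n=4, axis=-1)
        mad = np.median(np.abs(d4 - np.median(d4, axis=-1, keepdims=True)),
                        axis=-1)
        sigmas.extend(1.4826 * mad / np.sqrt(70.0))
    return float(np.median(sigmas))


def resolve_smoothing(trial: Trial, smoothing) -> tuple[int, int]:
    """Concrete (window, polyorder), auto-selected from the noise level when
    the config leaves them unset."""
    if smoothing.window is not None:
        return smoothing.window, smoothing.polyorder or 3
    sigma = estimate_position_noise(trial)
    return (smoothing.clean_filter if sigma < smoothing.noise_switch
            else smoothing.noisy_filter)


def compute_states(trial: Trial, smoothing=None,
                   reference_leg: Leg = "R") -> TemplateStates:
    """Full state computation: per-leg geometry, velocities, CoM
    acceleration, continuous phase (anchored at the reference leg's heel
    strikes) and gait-phase labels."""
    from .config import SmoothingConfig

    smoothing = smoothing or SmoothingConfig()
    window, polyorder = resolve_smoothing(trial, smoothing)
    if np.isnan(trial.com).any() or np.isnan(trial.foot_r).any() \
            or np.isnan(trial.foot_l).any():
        raise ValueError("NaNs in trial positions")
    dt = trial.dt

    legs: dict[Leg, LegStates] = {}
    for leg in LEGS:
        q = trial.com - trial.foot(leg)
        v = _sg_derivative(q, dt, 1, window, polyorder)
        # geometry from smoothed positions (position smoothing = 0th-order SG)
        q_s = _sg_derivative(q, dt, 0, window, polyorder)
        sign = LEG_SIGN[leg]
        L, theta, phi, L_s, L_f = leg_geometry(q_s, sign)
        if np.any(L <= 0):
            raise ValueError(f"non-positive leg length for leg {leg}")
        L_dot = np.einsum("im,im->m", q_s, v) / L
        theta_dot = (v[0] * q_s[1] - q_s[0] * v[1]) / L_s**2
        phi_dot = sign * (v[2] * q_s[1] - q_s[2] * v[1]) / L_f**2
        legs[leg] = LegStates(q_rel=q_s, v_rel=v, L=L, L_dot=L_dot,
                              theta=theta, theta_dot=theta_dot,
                              phi=phi, phi_dot=phi_dot, L_s=L_s, L_f=L_f)

    com_acc = _sg_derivative(trial.com, dt, 2, window, polyorder)

    gait_phase = label_gait_phases(trial.contact_r, trial.contact_l)
    ref = legs[reference_leg]
    heelstrikes = rising_edges(trial.contact(reference_leg))
    psi = compute_phase(ref.theta, ref.theta_dot, heelstrikes)

    return TemplateStates(t=trial.t, legs=legs, com_acc=com_acc, psi=psi,
                          gait_phase=gait_phase, trial=trial)


def rising_edges(contact: np.ndarray) -> np.ndarray:
    """Sample indices where a contact flag turns on (heel strikes)."""
    c = contact.astype(bool)
    return np.flatnonzero(~c[:-1] & c[1:]) + 1


def compute_phase(theta: np.ndarray, theta_dot: np.ndarray,
                  heelstrike_idx: np.ndarray | None = None) -> np.ndarray:
    """Continuous kinematic phase from the reference leg's phase portrait.

    Each portrait coordinate is centered and scaled to unit amplitude; the
    wrapped angle of (theta_hat, thetadot_hat) advances by 100% per stride.
    If heel-strike indices are given, the phase is shifted so psi = 0 at the
    (circular-mean) heel-strike phase.
    """
    amp_th = 0.5 * float(np.ptp(theta))
    amp_thd = 0.5 * float(np.ptp(theta_dot))
    if amp_th < 1e-9 or amp_thd < 1e-9:
        raise ValueError("phase undefined: reference leg angle does not oscillate")
    th_hat = (theta - np.mean(theta)) / amp_th
    thd_hat = (theta_dot - np.mean(theta_dot)) / amp_thd
    ang = np.arctan2(-thd_hat, th_hat)  # advances with time for a gait loop
    psi = np.mod(ang, 2 * np.pi) / (2 * np.pi) * 100.0
    if heelstrike_idx is not None and len(heelstrike_idx) > 0:
        hs = psi[np.asarray(heelstrike_idx)]
        mean_ang = np.angle(np.mean(np.exp(1j * hs / 100.0 * 2 * np.pi)))
        psi = np.mod(psi - mean_ang / (2 * np.pi) * 100.0, 100.0)
    return psi


def circular_phase_distance(a, b) -> np.ndarray:
    """Shortest distance between phases on the 0–100 circle."""
    d = np.abs(np.asarray(a) - np.asarray(b)) % 100.0
    return np.minimum(d, 100.0 - d)


def label_gait_phases(contact_r: np.ndarray,
                      contact_l: np.ndarray) -> np.ndarray:
    """Per-sample gait-phase labels from contact configuration.

    Double-support intervals following a right heel strike are DS1, those
    following a left heel strike are DS2; single-contact intervals are SS_R /
    SS_L.  Raises if any sample has neither foot in contact (the walking
    assumption).
    """
    cr = contact_r.astype(bool)
    cl = contact_l.astype(bool)
    if np.any(~cr & ~cl):
        raise ValueError("neither foot in contact: not walking data")
    m = cr.size
    labels = np.empty(m, dtype=object)
    labels[cr & ~cl] = "SS_R"
    labels[~cr & cl] = "SS_L"

    both = cr & cl
    idx = np.flatnonzero(both)
    if idx.size:
        splits = np.flatnonzero(np.diff(idx) > 1)
        runs = np.split(idx, splits + 1)
        for run in runs:
            i0 = run[0]
            if i0 > 0:
                # which leg just struck? the one not in contact before the run
                label = "DS1" if not cr[i0 - 1] else "DS2"
            else:
                # trial starts mid-DS: infer from the phase that follows
                after = run[-1] + 1
                label = "DS1" if after < m and labels[after] == "SS_R" else "DS2"
            labels[run] = label
    return labels.astype(str)


def detect_contacts(trial: Trial, height_frac: float = 0.01,
                    speed_threshold: float = 0.05,
                    smoothing=None) -> tuple[np.ndarray, np.ndarray]:
    """Fallback contact detection from foot kinematics, for trials without
    contact flags: a foot is in contact when below ``height_frac * L_bio``
    and slower than ``speed_threshold`` (m/s)."""
    from .config import SmoothingConfig

    smoothing = smoothing or SmoothingConfig()
    out = []
    for leg in LEGS:
        foot = trial.foot(leg)
        window, polyorder = resolve_smoothing(trial, smoothing)
        v = _sg_derivative(foot, trial.dt, 1, window, polyorder)
        speed = np.linalg.norm(v, axis=0)
        out.append((foot[1] < height_frac * trial.L_bio)
                   & (speed < speed_threshold))
    return out[0], out[1]
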