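"""Mechanism function library for template-signature regression.

Builds the 14-column (7 per leg) library Theta(q, qdot) and the regression
target M*(acc - g)/(M*g) so that a least-squares fit returns dimensionless
mechanism coefficients directly.  Per leg the columns multiply, in order:

    kappa_L        = k_L * L_bio / (M g)           leg stiffness
    kappa_L*L0~    = k_L * L_0 / (M g)             stiffness x resting length
    cL~            = c_L / (M sqrt(g / L_bio))     leg damping surrogate
    kappa_s        = k_s / (M g L_bio)             sagittal rotary stiffness
    cs~            = c_s / (M L_bio sqrt(g L_bio)) sagittal damping surrogate
    kappa_f        = k_f / (M g L_bio)             frontal rotary stiffness
    cf~            = c_f / (M L_bio sqrt(g L_bio)) frontal damping surrogate

The damping surrogates are linear-scale dimensionless constants; conversion
to the conventional damping ratios (zeta) happens after estimation because
the ratio definitions are nonlinear in the estimated stiffnesses.  Gravity is
handled on the target side, never as a library column, and one coefficient is
shared across the three spatial directions (rows stacked), because each
mechanism is a single physical constant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .slip import LEG_SIGN, LEGS, Leg, LegParams, SlipParams
from .states import TemplateStates

MECHANISMS = ("kappa_L", "kappa_L_L0", "cL_tilde", "kappa_s", "cs_tilde",
              "kappa_f", "cf_tilde")

#: ordered (leg, mechanism) metadata for the 14 columns
COLUMNS: tuple[tuple[Leg, str], ...] = tuple(
    (leg, mech) for leg in LEGS for mech in MECHANISMS
)
N_COLUMNS = len(COLUMNS)


def column_index(leg: Leg, mechanism: str) -> int:
    return COLUMNS.index((leg, mechanism))


@dataclass
class LibraryMatrix:
    """Stacked 3-direction regression system.

    ``theta`` has one row per (sample, direction) in sample-major order;
    ``sample_idx`` maps block i (rows 3i..3i+2) back to the trial sample.
    """

    theta: np.ndarray  # (3*m', 14)
    target: np.ndarray  # (3*m',)
    sample_idx: np.ndarray  # (m',)
    M: float
    g: float
    L_bio: float
    rotary_transverse: bool = False

    def __post_init__(self) -> None:
        if self.theta.shape != (3 * self.sample_idx.size, N_COLUMNS):
            raise ValueError("theta shape inconsistent with sample index")
        if not np.all(np.isfinite(self.theta)) or not np.all(np.isfinite(self.target)):
            raise ValueError("non-finite library entries")
        self._pos = {int(s): i for i, s in enumerate(self.sample_idx)}

    @property
    def n_samples(self) -> int:
        return self.sample_idx.size

    def rows_for_samples(self, samples: np.ndarray) -> np.ndarray:
        """Row indices (all three directions) for the given trial samples."""
        pos = np.fromiter((self._pos[int(s)] for s in samples), dtype=int,
                          count=len(samples))
        return (3 * pos[:, None] + np.arange(3)[None, :]).ravel()

    def predict_target(self, xi: np.ndarray) -> np.ndarray:
        return self.theta @ xi

    def predict_acceleration(self, xi: np.ndarray) -> np.ndarray:
        """CoM accelerations (3, m') implied by a coefficient vector."""
        acc = (self.theta @ xi).reshape(-1, 3).T * self.g
        acc[1] -= self.g
        return acc

    def measured_acceleration(self) -> np.ndarray:
        acc = self.target.reshape(-1, 3).T * self.g
        acc[1] -= self.g
        return acc


def build_library(
    states: TemplateStates,
    sample_mask: np.ndarray | None = None,
    rotary_transverse: bool = False,
    min_projection_frac: float = 1e-6,
) -> LibraryMatrix:
    """Build Theta and the nondimensional target from template states.

    Both legs' columns are always present regardless of contact: sparsity
    decides which mechanisms survive, which is how swing-leg coefficients are
    obtained.  Raises if any in-plane projection length falls below
    ``min_projection_frac * L_bio`` within the mask (rotary columns would
    blow up).
    """
    trial = states.trial
    M, g, L_bio = trial.M, trial.g, trial.L_bio
    m = states.n_samples
    if sample_mask is None:
        samples = np.arange(m)
    else:
        sample_mask = np.asarray(sample_mask)
        samples = (np.flatnonzero(sample_mask) if sample_mask.dtype == bool
                   else sample_mask.astype(int))

    cols = []
    for leg in LEGS:
        s = states.legs[leg]
        sign = LEG_SIGN[leg]
        q = s.q_rel[:, samples]
        L = s.L[samples]
        L_s, L_f = s.L_s[samples], s.L_f[samples]
        for name, proj in (("sagittal", L_s), ("frontal", L_f)):
            bad = np.flatnonzero(np.abs(proj) < min_projection_frac * L_bio)
            if bad.size:
                raise ValueError(
                    f"{name} projection length below threshold for leg {leg} "
                    f"at samples {samples[bad[:10]].tolist()}"
                )
        theta_ang, phi_ang = s.theta[samples], s.phi[samples]
        theta_dot, phi_dot = s.theta_dot[samples], s.phi_dot[samples]
        L_dot = s.L_dot[samples]

        if rotary_transverse:
            # transverse-to-the-leg force directions (per-plane tangents)
            dir_s = np.stack([q[1], -q[0], np.zeros_like(q[0])])
            dir_f = np.stack([np.zeros_like(q[0]), -sign * q[2], sign * q[1]])
        else:
            # default convention: rotary terms force along the leg axis
            dir_s = q
            dir_f = q

        tau = np.sqrt(L_bio / g)  # time scale for damping surrogates
        cols.extend([
            -q / L_bio,                                   # kappa_L
            q / L,                                        # kappa_L * L0~
            -(L_dot * tau) * q / L,                       # cL~
            -(theta_ang * L_bio / L_s**2) * dir_s,        # kappa_s
            -(theta_dot * tau * L_bio / L_s**2) * dir_s,  # cs~
            -(phi_ang * L_bio / L_f**2) * dir_f,          # kappa_f
            -(phi_dot * tau * L_bio / L_f**2) * dir_f,    # cf~
        ])

    theta = np.stack(cols, axis=-1)  # (3, m', 14)
    theta = np.transpose(theta, (1, 0, 2)).reshape(3 * samples.size, N_COLUMNS)

    acc = states.com_acc[:, samples]
    target = acc.copy()
    target[1] += g
    target = (target / g).T.reshape(-1)

    return LibraryMatrix(theta=theta, target=target, sample_idx=samples,
                         M=M, g=g, L_bio=L_bio,
                         rotary_transverse=rotary_transverse)


# ---------------------------------------------------------------------------
# library-scale <-> raw mechanism constants
# ---------------------------------------------------------------------------


def library_scale_from_raw(p: LegParams, M: float, g: float,
                           L_bio: float) -> np.ndarray:
    """The 7 library-scale coefficients of one leg from raw constants."""
    return np.array([
        p.k_L * L_bio / (M * g),
        p.k_L * p.L_0 / (M * g),
        p.c_L / (M * np.sqrt(g / L_bio)),
        p.k_s / (M * g * L_bio),
        p.c_s / (M * L_bio * np.sqrt(g * L_bio)),
        p.k_f / (M * g * L_bio),
        p.c_f / (M * L_bio * np.sqrt(g * L_bio)),
    ])


def raw_from_library_scale(xi7: np.ndarray, M: float, g: float,
                           L_bio: float) -> dict[str, float]:
    """Invert :func:`library_scale_from_raw` (L_0 requires k_L != 0)."""
    kL = xi7[0] * M * g / L_bio
    out = {
        "k_L": kL,
        "L_0": (xi7[1] * M * g / kL) if kL != 0 else np.nan,
        "c_L": xi7[2] * M * np.sqrt(g / L_bio),
        "k_s": xi7[3] * M * g * L_bio,
        "c_s": xi7[4] * M * L_bio * np.sqrt(g * L_bio),
        "k_f": xi7[5] * M * g * L_bio,
        "c_f": xi7[6] * M * L_bio * np.sqrt(g * L_bio),
    }
    return out


def true_coefficients(params: SlipParams,
                      active_legs: set[Leg] | frozenset[Leg]) -> np.ndarray:
    """Ground-truth 14-vector for a contact regime: library-scale constants
    for legs in contact, zeros for legs in swing."""
    xi = np.zeros(N_COLUMNS)
    for i, leg in enumerate(LEGS):
        if leg in active_legs:
            xi[7 * i: 7 * i + 7] = library_scale_from_raw(
                params.leg(leg), params.M, params.g, params.L_bio
            )
    return xi


TRUE_ACTIVE_LEGS = {
    "DS1": {"R", "L"}, "DS2": {"R", "L"}, "SS_R": {"R"}, "SS_L": {"L"},
}
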