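"""Coefficient normalization, bootstrap uncertainty, and constrained refits.

Normalized template-signature coefficients (dimensionless, comparable across
body sizes):

    kappa_L  = k_L * L_bio / (M g)        leg stiffness
    L0~      = L_0 / L_bio                leg resting length
    zeta_L   = c_L / (2 sqrt(k_L M))      leg damping ratio
    kappa_s  = k_s / (M g L_bio)          sagittal rotary stiffness
    zeta_s   = c_s / sqrt(kappa_s M L_bio^2)
    kappa_f, zeta_f analogously in the frontal plane

Note zeta_s/zeta_f use the *normalized* stiffness inside the radical — the
conventional definition adopted here — so they carry residual dimensions of
sqrt(N); they are reported as-is.  A damping ratio is undefined (reported
missing, not 0) when the corresponding stiffness is not positive.

The bootstrap refits a fixed support structure on resampled training data
(with replacement) within each gait phase and summarizes each normalized
coefficient by its mean, SD and coefficient of variation (CV).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import BootstrapConfig, PipelineConfig
from .library import LibraryMatrix, MECHANISMS, N_COLUMNS
from .selection import aicc_score, refit_support, residual_ss
from .slip import LEGS, Leg
from .states import LEG_ROLES, TemplateStates

logger = logging.getLogger(__name__)

#: names of the normalized per-leg coefficients
NORMALIZED_NAMES = ("kappa_L", "L0_tilde", "zeta_L", "kappa_s", "zeta_s",
                    "kappa_f", "zeta_f")


# ---------------------------------------------------------------------------
# Table-style normalization of raw mechanism constants
# ---------------------------------------------------------------------------


def normalize(k_L: float, L_0: float, c_L: float, k_s: float, c_s: float,
              k_f: float, c_f: float, M: float, g: float,
              L_bio: float) -> dict[str, float]:
    """Raw mechanism constants (SI) -> normalized signature coefficients."""
    if min(M, g, L_bio) <= 0:
        raise ValueError("M, g, L_bio must be positive")
    kappa_s = k_s / (M * g * L_bio)
    kappa_f = k_f / (M * g * L_bio)
    out = {
        "kappa_L": k_L * L_bio / (M * g),
        "L0_tilde": L_0 / L_bio if k_L != 0 else np.nan,
        "zeta_L": c_L / (2 * np.sqrt(k_L * M)) if k_L > 0 else np.nan,
        "kappa_s": kappa_s,
        "zeta_s": c_s / np.sqrt(kappa_s * M * L_bio**2) if kappa_s > 0 else np.nan,
        "kappa_f": kappa_f,
        "zeta_f": c_f / np.sqrt(kappa_f * M * L_bio**2) if kappa_f > 0 else np.nan,
    }
    return out


def denormalize(coeffs: dict[str, float], M: float, g: float,
                L_bio: float) -> dict[str, float]:
    """Inverse of :func:`normalize`; round-trips to machine precision."""
    k_L = coeffs["kappa_L"] * M * g / L_bio
    kappa_s, kappa_f = coeffs["kappa_s"], coeffs["kappa_f"]
    z = {k: coeffs.get(k, np.nan) for k in ("zeta_L", "zeta_s", "zeta_f")}
    return {
        "k_L": k_L,
        "L_0": coeffs["L0_tilde"] * L_bio,
        "c_L": z["zeta_L"] * 2 * np.sqrt(k_L * M) if k_L > 0 and np.isfinite(z["zeta_L"]) else 0.0,
        "k_s": kappa_s * M * g * L_bio,
        "c_s": z["zeta_s"] * np.sqrt(kappa_s * M * L_bio**2) if kappa_s > 0 and np.isfinite(z["zeta_s"]) else 0.0,
        "k_f": kappa_f * M * g * L_bio,
        "c_f": z["zeta_f"] * np.sqrt(kappa_f * M * L_bio**2) if kappa_f > 0 and np.isfinite(z["zeta_f"]) else 0.0,
    }


def normalized_from_library_scale(xi7: np.ndarray, M: float, g: float,
                                  L_bio: float) -> dict[str, float]:
    """One leg's library-scale coefficients -> normalized signature values.

    The resting length is recovered from the product term (L0~ = xi2 / xi1);
    when the stiffness is thresholded to zero the product term is meaningless
    and both are reported zero / missing.  Damping surrogates convert to
    ratios via the estimated stiffnesses.
    """
    kappa_L, prod, cL_t, kappa_s, cs_t, kappa_f, cf_t = xi7
    out = {"kappa_L": float(kappa_L), "kappa_s": float(kappa_s),
           "kappa_f": float(kappa_f)}
    out["L0_tilde"] = float(prod / kappa_L) if kappa_L != 0 else np.nan
    out["zeta_L"] = float(cL_t / (2 * np.sqrt(kappa_L))) if kappa_L > 0 else np.nan
    scale = np.sqrt(M * g * L_bio)  # converts c~ to Table-style zeta
    out["zeta_s"] = float(cs_t * scale / np.sqrt(kappa_s)) if kappa_s > 0 else np.nan
    out["zeta_f"] = float(cf_t * scale / np.sqrt(kappa_f)) if kappa_f > 0 else np.nan
    return out


def signature_table(xi: np.ndarray, gait_phase: str, M: float, g: float,
                    L_bio: float) -> pd.DataFrame:
    """Tidy per-(leg, role) normalized coefficients from a 14-vector."""
    rows = []
    for i, leg in enumerate(LEGS):
        norm = normalized_from_library_scale(xi[7 * i: 7 * i + 7], M, g, L_bio)
        role = LEG_ROLES[(leg, gait_phase)]
        for name in NORMALIZED_NAMES:
            rows.append({"gait_phase": gait_phase, "leg": leg, "role": role,
                         "coefficient": name, "value": norm[name]})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------


@dataclass
class BootstrapResult:
    """Per-coefficient bootstrap summary for one gait phase."""

    gait_phase: str
    support: np.ndarray
    draws: np.ndarray  # (n_boot, 14) library-scale coefficient draws
    seed: int
    n_redrawn: int
    mean: np.ndarray = field(init=False)  # (14,)
    sd: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.mean = self.draws.mean(axis=0)
        self.sd = self.draws.std(axis=0, ddof=1)

    @property
    def cv(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(self.mean != 0, self.sd / np.abs(self.mean), 0.0)

    def normalized_summary(self, M: float, g: float,
                           L_bio: float) -> pd.DataFrame:
        """Mean/SD/CV of the normalized coefficients across draws."""
        per_draw = {leg: {n: [] for n in NORMALIZED_NAMES} for leg in LEGS}
        for draw in self.draws:
            for i, leg in enumerate(LEGS):
                norm = normalized_from_library_scale(draw[7 * i: 7 * i + 7],
                                                     M, g, L_bio)
                for n in NORMALIZED_NAMES:
                    per_draw[leg][n].append(norm[n])
        rows = []
        for leg in LEGS:
            role = LEG_ROLES[(leg, self.gait_phase)]
            for n in NORMALIZED_NAMES:
                vals = np.asarray(per_draw[leg][n], dtype=float)
                finite = vals[np.isfinite(vals)]
                if finite.size == 0:
                    mean = sd = cv = np.nan
                else:
                    mean = float(finite.mean())
                    sd = float(finite.std(ddof=1)) if finite.size > 1 else 0.0
                    cv = sd / abs(mean) if mean != 0 else np.nan
                rows.append({"gait_phase": self.gait_phase, "leg": leg,
                             "role": role, "coefficient": n, "mean": mean,
                             "sd": sd, "cv": cv})
        return pd.DataFrame(rows)


def bootstrap_signature(
    library: LibraryMatrix,
    phase_train_samples: np.ndarray,
    support: np.ndarray,
    gait_phase: str,
    seed: int,
    config: BootstrapConfig | None = None,
    trial_pool_size: int | None = None,
) -> BootstrapResult:
    """Bootstrap coefficient estimates for a fixed structure in one phase.

    Each of ``n_boot`` iterations draws samples with replacement from the
    phase's training pool (the phase's occupancy share of ``resample_size``
    when ``trial_pool_size`` is given and proportional resampling is on) and
    refits the support by least squares.  Rank-deficient resamples are
    redrawn (logged); more than ``max_redraw_frac`` redraws is an error.
    """
    config = config or BootstrapConfig()
    rng = np.random.default_rng(seed)
    cols = np.flatnonzero(support)
    if config.proportional and trial_pool_size is not None:
        n_draw = max(int(round(config.resample_size
                               * phase_train_samples.size
                               / trial_pool_size)), 10 * max(cols.size, 1))
    else:
        n_draw = config.resample_size
    draws = np.zeros((config.n_boot, N_COLUMNS))
    n_redrawn = 0
    max_redraws = int(np.ceil(config.max_redraw_frac * config.n_boot))
    i = 0
    while i < config.n_boot:
        idx = rng.choice(phase_train_samples, size=n_draw, replace=True)
        rows = library.rows_for_samples(idx)
        A = library.theta[np.ix_(rows, cols)]
        sol, _, rank, _ = np.linalg.lstsq(A, library.target[rows], rcond=None)
        if rank < cols.size:
            n_redrawn += 1
            if n_redrawn > max_redraws:
                raise ValueError(
                    f"bootstrap unstable: {n_redrawn} rank-deficient "
                    f"resamples (> {config.max_redraw_frac:.0%} of "
                    f"{config.n_boot})"
                )
            logger.debug("rank-deficient bootstrap resample redrawn")
            continue
        draws[i, cols] = sol
        i += 1
    return BootstrapResult(gait_phase=gait_phase, support=support.copy(),
                           draws=draws, seed=seed, n_redrawn=n_redrawn)


# ---------------------------------------------------------------------------
# constrained (fixed-structure) refits across conditions
# ---------------------------------------------------------------------------


@dataclass
class ConstrainedRefit:
    gait_phase: str
    support: np.ndarray
    coefficients: np.ndarray  # (14,)
    aic: float
    aicc: float
    rho: int
    rss: float


def constrained_refit(
    support: np.ndarray,
    library: LibraryMatrix,
    states: TemplateStates,
    gait_phase: str,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    config: PipelineConfig | None = None,
) -> ConstrainedRefit:
    """Fit a fixed signature structure (e.g. from another walking condition)
    to this trial's data and score it on this trial's held-out samples, for
    AICc comparison against the trial's own selected structures."""
    config = config or PipelineConfig()
    phase_mask = states.gait_phase == gait_phase
    train_phase = train_idx[phase_mask[train_idx]]
    test_phase = (test_idx[phase_mask[test_idx]] if config.heldout_per_phase
                  else test_idx)
    if train_phase.size == 0 or test_phase.size == 0:
        raise ValueError(f"no samples in gait phase {gait_phase}")
    train_rows = library.rows_for_samples(train_phase)
    test_rows = library.rows_for_samples(test_phase)
    xi = refit_support(library, train_rows, support)
    rss = max(residual_ss(library, test_rows, xi), 1e-300)
    k = int(support.sum())
    aic, aicc = aicc_score(k, test_phase.size, rss)
    return ConstrainedRefit(gait_phase=gait_phase, support=support.copy(),
                            coefficients=xi, aic=aic, aicc=aicc,
                            rho=test_phase.size, rss=rss)
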