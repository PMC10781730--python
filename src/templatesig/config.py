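"""Defaults and configuration for the template-signature pipeline.

The canonical ground-truth walker is a conservative planar bipedal SLIP limit
cycle embedded in 3D, found by a stride-map fixed-point search at ~1.2 m/s
with dimensionless leg stiffness kappa_L = 16.7 (a representative human
single-support value).  It walks > 130 strides under the default integrator
tolerances, which covers the full-scale trial length (14,400 samples at
120 Hz).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .slip import InitialState, LegParams, SlipParams, symmetric_params, touchdown_direction, LEG_SIGN

#: sampling rate of the emulated motion-capture system (Hz)
SAMPLE_RATE = 120.0

#: canonical walker constants (SI units)
CANONICAL_M = 70.0
CANONICAL_G = 9.81
CANONICAL_L_BIO = 1.0
CANONICAL_KAPPA_L = 16.7
CANONICAL_L0_TILDE = 0.98
CANONICAL_THETA_TD = -0.44

#: stride-map fixed point at a right-foot touchdown:
#: (CoM minus trailing-foot AP offset, forward velocity, vertical velocity)
CANONICAL_FIXED_POINT = (0.20601746, 1.28120399, -0.56761239)

#: default measurement-noise level: 1 mm, a standard marker-based
#: motion-capture error magnitude
DEFAULT_NOISE_SD = 1e-3


def canonical_params() -> SlipParams:
    """The canonical conservative bipedal SLIP parameter set."""
    k_L = CANONICAL_KAPPA_L * CANONICAL_M * CANONICAL_G / CANONICAL_L_BIO
    leg = LegParams(
        k_L=k_L,
        L_0=CANONICAL_L0_TILDE * CANONICAL_L_BIO,
        theta_td=CANONICAL_THETA_TD,
    )
    return symmetric_params(
        M=CANONICAL_M, g=CANONICAL_G, L_bio=CANONICAL_L_BIO, leg=leg, speed=1.2
    )


def canonical_initial_state(params: SlipParams | None = None) -> InitialState:
    """Initial state on the canonical limit cycle (right-foot touchdown)."""
    params = params or canonical_params()
    d_trail, vx, vy = CANONICAL_FIXED_POINT
    p = params.right
    com = np.array([0.0, p.L_0 * np.cos(p.theta_td), 0.0])
    u = touchdown_direction(p.theta_td, p.phi_td, LEG_SIGN["R"])
    foot_r = com - p.L_0 * u
    foot_r[1] = 0.0
    foot_l = np.array([-d_trail, 0.0, 0.0])
    return InitialState(com=com, vel=np.array([vx, vy, 0.0]),
                        foot_r=foot_r, foot_l=foot_l)


@dataclass(frozen=True)
class SmoothingConfig:
    """Savitzky–Golay differentiation settings (window in samples).

    With ``window=None`` the filter is chosen from the data: a robust
    position-noise estimate (high-order differences) selects minimal
    smoothing for numerically clean signals, where differentiation bias
    dominates, or a wide window at motion-capture noise levels, where
    second-derivative noise amplification dominates.
    """

    window: int | None = None
    polyorder: int | None = None

    #: (window, polyorder) used when the noise estimate falls below / above
    #: ``noise_switch`` (metres)
    clean_filter: tuple[int, int] = (5, 4)
    noisy_filter: tuple[int, int] = (21, 7)
    noise_switch: float = 1e-4


@dataclass(frozen=True)
class ClusterConfig:
    """Phase-neighborhood clustering: seeds are the first
    ``n_train_centroids`` samples of the clustering pool; each cluster holds
    the seed's ``k`` nearest pool samples in circular phase."""

    n_train_centroids: int = 3600
    k: int = 800
    n_test: int = 3600


@dataclass(frozen=True)
class SweepConfig:
    """Sparsity sweep: ``n_lambdas`` log-spaced thresholds from
    ``lam_min_frac`` to ``lam_max_frac`` of the largest-magnitude coefficient
    of the cluster's unthresholded fit."""

    n_lambdas: int = 40
    lam_min_frac: float = 0.01
    lam_max_frac: float = 1.0


@dataclass(frozen=True)
class BootstrapConfig:
    """``resample_size`` is the trial-level draw count; with ``proportional``
    (the default) each gait phase receives its occupancy share of the draw,
    which is what drawing 3600 samples from the whole trial and splitting by
    phase produces on average.  Phases with fewer samples therefore get
    proportionally smaller resamples and wider bootstrap distributions."""

    n_boot: int = 200
    resample_size: int = 3600
    proportional: bool = True
    max_redraw_frac: float = 0.1


@dataclass(frozen=True)
class PipelineConfig:
    """End-to-end configuration for signature identification."""

    smoothing: SmoothingConfig = field(default_factory=SmoothingConfig)
    clustering: ClusterConfig = field(default_factory=ClusterConfig)
    sweep: SweepConfig = field(default_factory=SweepConfig)
    bootstrap: BootstrapConfig = field(default_factory=BootstrapConfig)
    frequency_threshold: float = 0.01
    delta_aicc_threshold: float = 3.0
    rotary_transverse: bool = False
    #: score held-out samples within the candidate's gait phase (the
    #: alternative, scoring the full cycle, is available for comparison)
    heldout_per_phase: bool = True
    #: structure handed to the bootstrap: the selected (delta-AICc = 0)
    #: structure, or the union of all plausible structures
    bootstrap_structure: str = "best"  # "best" | "union"

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        kwargs = dict(d)
        for key, sub in (
            ("smoothing", SmoothingConfig),
            ("clustering", ClusterConfig),
            ("sweep", SweepConfig),
            ("bootstrap", BootstrapConfig),
        ):
            if key in kwargs and isinstance(kwargs[key], dict):
                kwargs[key] = sub(**kwargs[key])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)


def reduced_config(n_train_centroids: int = 600, k: int = 400,
                   n_test: int = 3600) -> PipelineConfig:
    """A scaled-down configuration for desk-scale runs: fewer cluster seeds
    and a proportionally smaller neighborhood, same held-out size."""
    return PipelineConfig(
        clustering=ClusterConfig(n_train_centroids=n_train_centroids, k=k,
                                 n_test=n_test)
    )
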