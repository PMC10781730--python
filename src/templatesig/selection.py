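"""Model evaluation, AICc-based selection, and multi-model inference.

Pipeline steps 3–5 up to averaging: candidate structures are refit per gait
phase on the training samples of that phase (scoring is structure-driven,
not cluster-driven), scored on held-out data with the small-sample-corrected
Akaike information criterion, filtered at a relative-AICc plausibility
threshold, and combined into one signature per gait phase with Akaike
weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import PipelineConfig
from .library import LibraryMatrix, N_COLUMNS
from .sindy import CandidateSignature
from .states import GAIT_PHASES, TemplateStates


# ---------------------------------------------------------------------------
# information criteria
# ---------------------------------------------------------------------------


def aicc_score(k: int, rho: int, rss: float) -> tuple[float, float]:
    """AIC and small-sample-corrected AICc from a residual sum of squares.

    AIC = 2k + rho*ln(rss/rho), with rss pooled over the three spatial
    directions; AICc adds 2(k+1)(k+2)/(rho-k-2).  ``rho`` is the number of
    held-out samples scored.
    """
    if rho <= k + 2:
        raise ValueError(f"AICc undefined: rho={rho} must exceed k+2={k + 2}")
    if rss <= 0:
        raise ValueError("rss must be positive")
    aic = 2 * k + rho * np.log(rss / rho)
    aicc = aic + 2 * (k + 1) * (k + 2) / (rho - k - 2)
    return float(aic), float(aicc)


def rank_and_filter(aiccs: np.ndarray, threshold: float = 3.0
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Relative AICc scores and plausibility flags (delta <= threshold)."""
    aiccs = np.asarray(aiccs, dtype=float)
    if aiccs.size == 0:
        raise ValueError("no scored candidates")
    delta = aiccs - aiccs.min()
    return delta, delta <= threshold


def akaike_weights(delta_aicc) -> np.ndarray:
    """Normalized relative likelihoods exp(-delta/2) / sum."""
    delta = np.asarray(delta_aicc, dtype=float)
    if delta.size == 0:
        raise ValueError("empty delta-AICc list")
    w = np.exp(-delta / 2.0)
    return w / w.sum()


# ---------------------------------------------------------------------------
# held-out evaluation
# ---------------------------------------------------------------------------


def heldout_error_curve(xi: np.ndarray, library: LibraryMatrix,
                        psi: np.ndarray, n_bins: int = 100
                        ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Average absolute reconstruction error binned over the gait cycle.

    Returns (bin_centers, per-direction error (3, n_bins), pooled error
    (n_bins,)); empty bins are NaN, not zero.  ``psi`` gives the phase of
    each library sample.
    """
    resid = np.abs(library.theta @ xi - library.target).reshape(-1, 3)
    bins = np.clip((psi / (100.0 / n_bins)).astype(int), 0, n_bins - 1)
    per_dir = np.full((3, n_bins), np.nan)
    pooled = np.full(n_bins, np.nan)
    for b in range(n_bins):
        mask = bins == b
        if mask.any():
            per_dir[:, b] = resid[mask].mean(axis=0)
            pooled[b] = resid[mask].mean()
    centers = (np.arange(n_bins) + 0.5) * (100.0 / n_bins)
    return centers, per_dir, pooled


def refit_support(library: LibraryMatrix, rows: np.ndarray,
                  support: np.ndarray) -> np.ndarray:
    """Least-squares coefficients on a fixed support over the given rows."""
    xi = np.zeros(N_COLUMNS)
    if support.any():
        sol, *_ = np.linalg.lstsq(library.theta[np.ix_(rows, np.flatnonzero(support))],
                                  library.target[rows], rcond=None)
        xi[np.flatnonzero(support)] = sol
    return xi


def residual_ss(library: LibraryMatrix, rows: np.ndarray,
                xi: np.ndarray) -> float:
    r = library.theta[rows] @ xi - library.target[rows]
    return float(r @ r)


# ---------------------------------------------------------------------------
# per-phase scoring and averaging
# ---------------------------------------------------------------------------


@dataclass
class ScoredSignature:
    candidate: CandidateSignature
    gait_phase: str
    coefficients: np.ndarray  # (14,) refit on the phase's training samples
    k: int
    rho: int
    rss: float
    aic: float
    aicc: float
    delta_aicc: float = np.nan
    plausible: bool = False
    weight: float = 0.0


@dataclass
class PhaseSelection:
    """Selection outcome in one gait phase."""

    gait_phase: str
    scored: list[ScoredSignature]
    averaged_xi: np.ndarray  # (14,) Akaike-weighted average
    union_support: np.ndarray  # bool (14,)
    term_weight: np.ndarray  # (14,) total plausible weight carrying each term

    @property
    def best(self) -> ScoredSignature:
        return min(self.scored, key=lambda s: s.aicc)

    @property
    def plausible(self) -> list[ScoredSignature]:
        return [s for s in self.scored if s.plausible]


def score_candidates_in_phase(
    candidates: list[CandidateSignature],
    library: LibraryMatrix,
    states: TemplateStates,
    phase: str,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    config: PipelineConfig,
) -> list[ScoredSignature]:
    """Refit each candidate on the phase's training samples and score it on
    the phase's held-out samples (or the whole held-out set if configured)."""
    phase_mask = states.gait_phase == phase
    train_phase = train_idx[phase_mask[train_idx]]
    if config.heldout_per_phase:
        test_phase = test_idx[phase_mask[test_idx]]
    else:
        test_phase = test_idx
    if train_phase.size == 0 or test_phase.size == 0:
        raise ValueError(f"no samples available in gait phase {phase}")
    train_rows = library.rows_for_samples(train_phase)
    test_rows = library.rows_for_samples(test_phase)
    rho = test_phase.size
    scored = []
    for cand in candidates:
        xi = refit_support(library, train_rows, cand.support)
        rss = residual_ss(library, test_rows, xi)
        rss = max(rss, 1e-300)  # exact-model guard: log needs rss > 0
        aic, aicc = aicc_score(cand.k, rho, rss)
        scored.append(ScoredSignature(candidate=cand, gait_phase=phase,
                                      coefficients=xi, k=cand.k, rho=rho,
                                      rss=rss, aic=aic, aicc=aicc))
    return scored


def multimodel_average(scored: list[ScoredSignature],
                       weights: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Akaike-weighted coefficient average over the plausible set.

    Terms absent from a model contribute zero; the union support is retained
    together with the total weight of the models carrying each term.
    """
    if not scored:
        raise ValueError("empty plausible set")
    xi = np.zeros(N_COLUMNS)
    term_weight = np.zeros(N_COLUMNS)
    union = np.zeros(N_COLUMNS, dtype=bool)
    for s, w in zip(scored, weights):
        xi += w * s.coefficients
        term_weight += w * s.candidate.support
        union |= s.candidate.support
    return xi, union, term_weight


def select_signatures(
    candidates: list[CandidateSignature],
    library: LibraryMatrix,
    states: TemplateStates,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    config: PipelineConfig | None = None,
) -> dict[str, PhaseSelection]:
    """Steps 3–5 for every gait phase present in the trial.

    A candidate competes in a gait phase when that phase appears among its
    source-cluster centroid labels.
    """
    config = config or PipelineConfig()
    out: dict[str, PhaseSelection] = {}
    for phase in GAIT_PHASES:
        in_phase = [c for c in candidates if c.gait_phases.get(phase, 0) > 0]
        if not in_phase:
            continue
        scored = score_candidates_in_phase(in_phase, library, states, phase,
                                           train_idx, test_idx, config)
        delta, plaus = rank_and_filter([s.aicc for s in scored],
                                       config.delta_aicc_threshold)
        for s, d, p in zip(scored, delta, plaus):
            s.delta_aicc = float(d)
            s.plausible = bool(p)
        plausible = [s for s in scored if s.plausible]
        w = akaike_weights([s.delta_aicc for s in plausible])
        for s, wi in zip(plausible, w):
            s.weight = float(wi)
        xi, union, term_w = multimodel_average(plausible, w)
        out[phase] = PhaseSelection(gait_phase=phase, scored=scored,
                                    averaged_xi=xi, union_support=union,
                                    term_weight=term_w)
    return out
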