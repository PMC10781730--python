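"""End-to-end template-signature identification for one trial.

Glues the stages together: state computation -> function library ->
train/test split -> phase clustering -> sparsity sweep -> candidate pool ->
AICc selection and multi-model averaging -> bootstrap uncertainty.  Returns
a :class:`SignatureReport` that serializes to JSON and tidy CSV tables.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__ as _version
from .coefficients import (BootstrapResult, bootstrap_signature,
                           signature_table)
from .config import PipelineConfig
from .library import COLUMNS, LibraryMatrix, build_library
from .selection import PhaseSelection, select_signatures
from .sindy import (CandidateSignature, cluster_by_phase, collect_candidates,
                    fit_clusters, split_train_test)
from .states import GAIT_PHASES, TemplateStates, compute_states
from .slip import Trial


@dataclass
class SignatureReport:
    """Identified template signatures and their bookkeeping for one trial."""

    condition: str
    config: PipelineConfig
    selections: dict[str, PhaseSelection]
    bootstraps: dict[str, BootstrapResult]
    candidates: list[CandidateSignature]
    states: TemplateStates
    library: LibraryMatrix
    train_idx: np.ndarray
    test_idx: np.ndarray
    seed: int | None = None

    def signature_frame(self) -> pd.DataFrame:
        """Tidy table of final per-(leg, role) normalized coefficients with
        bootstrap mean/sd/CV, all gait phases."""
        frames = []
        tr = self.states.trial
        for phase, boot in self.bootstraps.items():
            frames.append(boot.normalized_summary(tr.M, tr.g, tr.L_bio)
                          .assign(condition=self.condition))
        return pd.concat(frames, ignore_index=True)

    def averaged_signature_frame(self) -> pd.DataFrame:
        """Akaike-weighted (pre-bootstrap) signatures per gait phase."""
        tr = self.states.trial
        frames = [signature_table(sel.averaged_xi, phase, tr.M, tr.g,
                                  tr.L_bio).assign(condition=self.condition)
                  for phase, sel in self.selections.items()]
        return pd.concat(frames, ignore_index=True)

    def candidate_table(self) -> pd.DataFrame:
        rows = []
        for phase, sel in self.selections.items():
            for s in sel.scored:
                rows.append({
                    "condition": self.condition, "gait_phase": phase,
                    "support": "+".join(f"{leg}:{m}" for (leg, m), on
                                        in zip(COLUMNS, s.candidate.support)
                                        if on),
                    "frequency": s.candidate.frequency, "k": s.k,
                    "rho": s.rho, "aicc": s.aicc,
                    "delta_aicc": s.delta_aicc, "plausible": s.plausible,
                    "weight": s.weight,
                })
        return pd.DataFrame(rows)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "version": _version,
            "condition": self.condition,
            "seed": self.seed,
            "config": self.config.to_dict(),
            "candidates": self.candidate_table().to_dict(orient="records"),
            "signatures": json.loads(
                self.signature_frame().to_json(orient="records")),
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def identify_signatures(
    trial: Trial,
    config: PipelineConfig | None = None,
    seed: int = 0,
    condition: str = "trial",
    fixed_structures: dict[str, np.ndarray] | None = None,
) -> SignatureReport:
    """Run the full identification pipeline on one trial.

    ``seed`` drives the bootstrap resampling only; clustering and model
    selection are deterministic.  If ``fixed_structures`` maps gait phases to
    support masks (e.g. structures selected in a reference condition), those
    structures replace the trial's own selected structures before the
    bootstrap, which is how coefficients are compared across conditions.
    """
    config = config or PipelineConfig()
    states = compute_states(trial, config.smoothing)
    library = build_library(states, rotary_transverse=config.rotary_transverse)
    pool_idx, test_idx = split_train_test(states, config.clustering)
    clusters = cluster_by_phase(states.psi, states.gait_phase, pool_idx,
                                config.clustering.n_train_centroids,
                                config.clustering.k)
    per_cluster = fit_clusters(library, clusters, config.sweep)
    candidates = collect_candidates(per_cluster, clusters,
                                    config.frequency_threshold)
    selections = select_signatures(candidates, library, states, pool_idx,
                                   test_idx, config)

    bootstraps: dict[str, BootstrapResult] = {}
    rng = np.random.default_rng(seed)
    for phase in GAIT_PHASES:
        if phase not in selections and (fixed_structures is None
                                        or phase not in fixed_structures):
            continue
        if fixed_structures is not None and phase in fixed_structures:
            support = np.asarray(fixed_structures[phase], dtype=bool)
        elif config.bootstrap_structure == "union":
            support = selections[phase].union_support
        else:
            support = selections[phase].best.candidate.support
        phase_train = pool_idx[states.gait_phase[pool_idx] == phase]
        boot_seed = int(rng.integers(2**31 - 1))
        bootstraps[phase] = bootstrap_signature(
            library, phase_train, support, phase, boot_seed, config.bootstrap,
            trial_pool_size=pool_idx.size,
        )

    return SignatureReport(condition=condition, config=config,
                           selections=selections, bootstraps=bootstraps,
                           candidates=candidates, states=states,
                           library=library, train_idx=pool_idx,
                           test_idx=test_idx, seed=seed)
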