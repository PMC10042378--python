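"""The shipped fall-risk study: banks of walker conditions and the
standard analyses over them.

A *condition* is a walker preset combined with a perturbation timing; the
shipped study uses 20 training presets and 6 validation presets, each under
the three timings (60 training and 18 validation conditions).  This module
wires the pipeline stages together:

1. for each condition, build the deterministic mesh, the absorbing chain,
   its first-passage statistics and the chain metric vector;
2. validate the chain metrics against brute-force 50-step segments
   (the agreement study) and quantify metric convergence with the number of
   steps (the convergence study);
3. fit the combined fall-risk model on the training conditions and evaluate
   it on brute-force segments from the held-out validation conditions.

The agreement and convergence studies use the eight training presets whose
step-to-step correlation length is short relative to a 50-step segment
(contraction 0.30-0.84); for more persistent walkers the brute-force
segment statistics are themselves unreliable at that segment length (see
docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .chain import (AbsorbingChain, ChainStatistics, build_chain,
                    chain_statistics)
from .chain_metrics import chain_metric_vector
from .metrics import (MetricVector, NON_LYAPUNOV_METRICS, NormalizationRecord,
                      apply_normalization, fit_normalization, metric_table,
                      metric_vector_from_steps, spatiotemporal_stats)
from .model import FallRiskModel, FallRiskResults, goodness_of_fit
from .validation import (DEFAULT_STEP_COUNTS, compare_methods, convergence_fit,
                         segment_trials)
from .walker import (DeterministicMesh, WalkerConfig, build_deterministic_mesh,
                     load_preset, preset_names, simulate_brute, TIMINGS)

__all__ = [
    "AGREEMENT_PRESETS",
    "Condition",
    "build_condition",
    "condition_bank",
    "metric_frame",
    "training_normalization",
    "agreement_study",
    "convergence_study",
    "fit_study_model",
    "validation_predictions",
]

#: Training presets used for the chain-vs-brute agreement and convergence
#: studies (contraction 0.30-0.84).
AGREEMENT_PRESETS = ["train_01", "train_03", "train_05", "train_07",
                     "train_09", "train_11", "train_12", "train_13"]


@dataclass
class Condition:
    """One walker condition with its chain-side artifacts."""

    name: str
    timing: str
    config: WalkerConfig
    mesh: DeterministicMesh
    chain: AbsorbingChain
    stats: ChainStatistics
    metrics: MetricVector

    @property
    def label(self) -> str:
        return f"{self.name}:{self.timing}"

    @property
    def log_mfpt(self) -> float:
        return float(np.log(self.stats.mfpt))


def build_condition(name: str, timing: str = "DS0",
                    lyapunov: bool = False, rng=None,
                    **lyap_kwargs) -> Condition:
    """Mesh, chain, first-passage statistics and chain metric vector for one
    preset x timing condition."""
    config = load_preset(name, timing=timing)
    mesh = build_deterministic_mesh(config)
    chain = build_chain(mesh)
    stats = chain_statistics(chain)
    vec = chain_metric_vector(chain, mesh, lyapunov=lyapunov, rng=rng,
                              stats=stats, **(lyap_kwargs or {}))
    return Condition(name=name, timing=timing, config=config, mesh=mesh,
                     chain=chain, stats=stats, metrics=vec)


def condition_bank(role: str = "train", timings: Sequence[str] = TIMINGS,
                   lyapunov: bool = False) -> List[Condition]:
    """All conditions for the presets of a role ('train' or 'val')."""
    return [build_condition(name, timing, lyapunov=lyapunov)
            for name in preset_names(role) for timing in timings]


def metric_frame(conditions: Sequence[Condition]):
    """Stack conditions into (metric table, ln MFPT, preset groups)."""
    table = metric_table([c.metrics for c in conditions],
                         index=[c.label for c in conditions])
    y = pd.Series([c.log_mfpt for c in conditions],
                  index=[c.label for c in conditions])
    groups = [c.name for c in conditions]
    return table, y, groups


def training_normalization(conditions: Sequence[Condition]
                           ) -> NormalizationRecord:
    """Normalization record over the non-Lyapunov chain metrics of the
    training conditions."""
    table, _, _ = metric_frame(conditions)
    return fit_normalization(table[NON_LYAPUNOV_METRICS])


def _condition_rng(seed: int, config: WalkerConfig) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), int(config.seed)]))


def agreement_study(conditions: Sequence[Condition],
                    record: NormalizationRecord,
                    presets: Sequence[str] = AGREEMENT_PRESETS,
                    timing: str = "DS0",
                    n_segments: int = 200, seg_len: int = 50,
                    seed: int = 0):
    """Chain-vs-brute comparison on 50-step segments, per preset.

    Returns ``(results, trials_by_preset)`` where ``results`` maps preset
    name to a :class:`~gaitrisk.validation.ComparisonResult` and the trials
    are returned for reuse (e.g. by the convergence study).
    """
    by_label = {c.label: c for c in conditions}
    results = {}
    trials_by_preset = {}
    for name in presets:
        cond = by_label[f"{name}:{timing}"]
        rng = _condition_rng(seed, cond.config)
        trials = simulate_brute(cond.config, n_steps=1000, rng=rng,
                                ensure_segments=(n_segments, seg_len))
        segs = segment_trials(trials, seg_len)[:n_segments]
        brute = [metric_vector_from_steps(s, lyapunov=False) for s in segs]
        results[name] = compare_methods(cond.metrics, brute, record=record)
        trials_by_preset[name] = trials
    return results, trials_by_preset


def pooled_match_rate(results: dict) -> float:
    """% of non-Lyapunov chain metrics within one brute-force SD, pooled
    over presets."""
    flags = pd.concat([r.rows["match"].dropna() for r in results.values()])
    return 100.0 * float(flags.mean())


def convergence_study(conditions: Sequence[Condition],
                      record: NormalizationRecord,
                      trials_by_preset: dict,
                      timing: str = "DS0",
                      ns: Sequence[int] = DEFAULT_STEP_COUNTS,
                      thresholds: Sequence[float] = (0.1, 0.5)):
    """Pooled spatiotemporal accuracy vs number of steps.

    For each segment length ``n``, every trial is cut into disjoint n-step
    segments, the six spatiotemporal metrics are computed per segment, and
    the percentage of (segment, metric) errors below each normalized
    threshold -- pooled over presets and metrics -- is recorded.  Returns a
    DataFrame indexed by ``n`` with one column per threshold, plus the
    log-linear :class:`~gaitrisk.validation.ConvergenceFit` per threshold.
    """
    by_label = {c.label: c for c in conditions}
    st_names = ["speed_mean", "speed_sd", "step_length_mean",
                "step_length_sd", "step_duration_mean", "step_duration_sd"]
    center = record.center[st_names]
    scale = record.scale[st_names]
    pcts = {thr: {} for thr in thresholds}
    for n in ns:
        errs = []
        for name, trials in trials_by_preset.items():
            cond = by_label[f"{name}:{timing}"]
            zc = (cond.metrics.values[st_names] - center) / scale
            for seg in segment_trials(trials, n):
                z = (pd.Series(spatiotemporal_stats(seg))[st_names]
                     - center) / scale
                errs.append((z - zc).abs())
        err = pd.DataFrame(errs)
        for thr in thresholds:
            pcts[thr][n] = 100.0 * float((err < thr).to_numpy().mean())
    table = pd.DataFrame(pcts)
    fits = {thr: convergence_fit(table.index, table[thr])
            for thr in thresholds}
    return table, fits


def fit_study_model(conditions: Sequence[Condition], seed: int = 0,
                    variant: str = "no_lyap") -> FallRiskResults:
    """Fit the combined fall-risk model on the training conditions, with
    whole presets as the consensus-reduction groups."""
    table, y, groups = metric_frame(conditions)
    model = FallRiskModel(table, y, variant=variant, groups=groups)
    return model.fit(seed=seed)


def validation_predictions(results: FallRiskResults,
                           conditions: Sequence[Condition],
                           n_steps: int, seed: int = 0,
                           segments_per_condition: int = 10):
    """Predict ln(MFPT) from brute-force segments of held-out conditions.

    Returns ``(yhat, y_true, groups)`` over all segments of all conditions
    (conditions whose trials never survive ``n_steps`` contribute none).
    """
    yhat, y, groups = [], [], []
    for cond in conditions:
        rng = _condition_rng(seed, cond.config)
        trials = simulate_brute(cond.config, n_steps=1000, rng=rng)
        for seg in segment_trials(trials, n_steps)[:segments_per_condition]:
            vec = metric_vector_from_steps(seg, lyapunov=False)
            yhat.append(float(results.predict(vec)))
            y.append(cond.log_mfpt)
            groups.append(cond.label)
    return np.asarray(yhat), np.asarray(y), groups
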