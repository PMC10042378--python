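"""Fall-risk metrics estimated directly from the absorbing Markov chain.

Instead of simulating thousands of steps, each metric is computed from the
chain's one-step catalog.  For a step-level quantity ``rho_ij`` (its value
when transitioning from state i to state j), the per-state mean and SD are
probability-weighted over the surviving transitions,

    mu_i      = sum_j P(s_ij) rho_ij / sum_j P(s_ij)
    sigma_i^2 = sum_j P(s_ij) (rho_ij - mu_i)^2 / sum_j P(s_ij),

and the overall mean and SD pool the per-state moments with the expected
visit counts ``n_1i`` (row 1 of the fundamental matrix) as frequency weights,

    mu      = sum_i n_1i mu_i / sum_i n_1i
    sigma^2 = sum_i n_1i (sigma_i^2 + (mu_i - mu)^2) / sum_i n_1i .

This is exactly the mean/variance of the visit-weighted mixture of per-state
step distributions (law of total variance).  Failed transitions are excluded
from both numerator and denominator: a falling biped takes no complete step.

Lyapunov exponents need step *sequences*, so they are instead estimated from
random trajectories through the chain: starting from the states with the
largest ``n_1i``, several fixed-length trajectories are sampled, the
divergence-curve slopes computed per trajectory, and the results averaged
with weights proportional to ``n_1i`` times the (uniform) probability of the
perturbation vector.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Union

import numpy as np
import pandas as pd

from .chain import (AbsorbingChain, ChainStatistics, chain_statistics,
                    gaussian_cell_masses, sample_chain_trajectory)
from .exceptions import StructuralError
from .metrics import (CH, EmbeddingConfig, LYAP_CHANNELS, METRIC_NAMES,
                      MetricVector, VARIABILITY_CHANNELS, divergence_curve,
                      fri_series, lyapunov_exponents, xcom_series)
from .walker import DeterministicMesh, synthesize_steps

__all__ = [
    "WeightedStepStats",
    "ChainLyapunovResult",
    "weighted_step_stats",
    "chain_metric",
    "chain_lyapunov",
    "chain_metric_vector",
]


@dataclass
class WeightedStepStats:
    """Per-state probability-weighted moments of a step-level quantity."""

    states: np.ndarray    # included transient state indices
    mu: np.ndarray        # (n_incl, ...) per-state weighted means
    sigma: np.ndarray     # (n_incl, ...) per-state weighted SDs
    mass: np.ndarray      # (n_incl,) total surviving perturbation mass


def _transition_catalog(mesh: DeterministicMesh, chain: AbsorbingChain):
    """Surviving transitions (i, j) with median perturbations and Gaussian
    masses."""
    ii, jj, s_med = mesh.unique_transitions()
    w = gaussian_cell_masses(mesh.perturbation_grid,
                             chain.noise_sd or mesh.config.noise_sd)
    mass = np.empty(ii.size)
    for k in range(ii.size):
        mass[k] = w[mesh.transitions[ii[k]] == jj[k]].sum()
    return ii, jj, s_med, mass


def _grouped_weighted_stats(ii: np.ndarray, rho: np.ndarray,
                            mass: np.ndarray, n_states: int):
    """Vectorized per-state weighted mean/SD over transitions grouped by
    start state; ``rho`` may be (P,) or (P, ...)."""
    extra = rho.shape[1:]
    tot = np.zeros(n_states)
    np.add.at(tot, ii, mass)
    included = tot > 0
    m = mass.reshape((-1,) + (1,) * len(extra))
    s1 = np.zeros((n_states,) + extra)
    np.add.at(s1, ii, m * rho)
    with np.errstate(invalid="ignore", divide="ignore"):
        mu = s1 / tot.reshape((-1,) + (1,) * len(extra))
    s2 = np.zeros((n_states,) + extra)
    np.add.at(s2, ii, m * (rho - mu[ii]) ** 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        var = s2 / tot.reshape((-1,) + (1,) * len(extra))
    idx = np.flatnonzero(included)
    return WeightedStepStats(states=idx, mu=mu[idx],
                             sigma=np.sqrt(np.maximum(var[idx], 0.0)),
                             mass=tot[idx]), included


def weighted_step_stats(mesh: DeterministicMesh, chain: AbsorbingChain,
                        quantity_extractor: Callable) -> WeightedStepStats:
    """Per-state weighted mean/SD of ``quantity_extractor(trajectory)``.

    The extractor maps each surviving transition's stored step trajectory to
    a scalar (or array).  States whose entire perturbation mass is absorbed
    are excluded with a warning.
    """
    ii, jj, _, mass = _transition_catalog(mesh, chain)
    if ii.size == 0:
        raise StructuralError("mesh has no surviving transitions")
    rho = np.asarray([np.asarray(quantity_extractor(mesh.trajectory(i, j)),
                                 dtype=float)
                      for i, j in zip(ii, jj)])
    stats, included = _grouped_weighted_stats(ii, rho, mass, mesh.n_states)
    if not included.all():
        warnings.warn(
            f"states {list(np.flatnonzero(~included))} have zero surviving "
            "mass and were excluded", stacklevel=2)
    return stats


def chain_metric(stats: WeightedStepStats, n1: np.ndarray) -> tuple:
    """Pool per-state moments into the overall (mu, sigma) using expected
    visit counts as frequency weights."""
    n1 = np.asarray(n1, dtype=float)
    w = n1[stats.states]
    wsum = w.sum()
    if wsum <= 0:
        raise ValueError("total visit weight is zero")
    shape = (-1,) + (1,) * (stats.mu.ndim - 1)
    wr = w.reshape(shape)
    mu = (wr * stats.mu).sum(axis=0) / wsum
    var = (wr * (stats.sigma ** 2 + (stats.mu - mu) ** 2)).sum(axis=0) / wsum
    return mu, np.sqrt(np.maximum(var, 0.0))


@dataclass
class ChainLyapunovResult:
    """Chain-sampled Lyapunov estimates: the weighted means plus the
    per-trajectory values and weights behind them."""

    values: pd.Series                  # 24 entries (lyap_short_*, lyap_long_*)
    per_trajectory: pd.DataFrame       # one row per retained trajectory
    weights: np.ndarray                # normalized, sums to 1
    n_dropped: int = 0


def chain_lyapunov(
    chain: AbsorbingChain,
    mesh: Optional[DeterministicMesh] = None,
    cfg: Optional[EmbeddingConfig] = None,
    rng: Union[np.random.Generator, int, None] = None,
    n_start_states: int = 20,
    n_vectors: int = 20,
    n_steps: int = 50,
    retry_cap: int = 5,
) -> ChainLyapunovResult:
    """Estimate the 24 Lyapunov metrics from random chain trajectories.

    From each of the ``n_start_states`` most visited states (largest
    ``n_1i``), ``n_vectors`` random ``n_steps``-step trajectories are
    sampled.  Each trajectory's divergence-curve slopes are computed per
    coordinate with distances floored at ``cfg.d_floor`` (repeated steps give
    exactly zero distance otherwise).  The overall value is the weighted mean
    with weight ``n_1i * (1 / n_vectors)``, normalized to sum to one.
    Trajectories absorbed before ``n_steps`` are redrawn up to ``retry_cap``
    times, then dropped with a warning and the weights renormalized.
    """
    mesh = mesh or chain.mesh
    if mesh is None:
        raise ValueError("a mesh is required for chain-sampled trajectories")
    cfg = cfg or EmbeddingConfig()
    rng = np.random.default_rng(rng)
    stats = chain_statistics(chain)
    t = chain.n_states
    m = min(n_start_states, t)
    if t < n_start_states:
        warnings.warn(
            f"chain has only {t} transient states; using all of them",
            stacklevel=2)
    top = np.argsort(stats.n1)[::-1][:m]

    rows = []
    weights = []
    labels = []
    n_dropped = 0
    cols = ([f"lyap_short_{c}" for c in LYAP_CHANNELS]
            + [f"lyap_long_{c}" for c in LYAP_CHANNELS])
    for i in top:
        for vec in range(n_vectors):
            seq = None
            for _attempt in range(retry_cap + 1):
                cand, _ = sample_chain_trajectory(
                    chain, mesh, start_state=int(i), n_steps=n_steps, rng=rng)
                if len(cand) == n_steps:
                    seq = cand
                    break
            if seq is None:
                n_dropped += 1
                continue
            samples = seq.samples()
            vals = np.empty(24)
            for ci, c in enumerate(LYAP_CHANNELS):
                curve = divergence_curve(samples[:, :, CH[c]].ravel(), cfg)
                lam_s, lam_l = lyapunov_exponents(curve, cfg)
                vals[ci] = lam_s
                vals[12 + ci] = lam_l
            rows.append(vals)
            weights.append(stats.n1[i] / n_vectors)
            labels.append((int(i), vec))
    if n_dropped:
        warnings.warn(
            f"{n_dropped} chain trajectories absorbed before {n_steps} steps "
            "were dropped; weights renormalized", stacklevel=2)
    if not rows:
        raise StructuralError(
            "no chain trajectory survived long enough for Lyapunov "
            "estimation")
    per = pd.DataFrame(rows, columns=cols,
                       index=pd.MultiIndex.from_tuples(
                           labels, names=["state", "vector"]))
    w = np.asarray(weights)
    w = w / w.sum()
    values = pd.Series(per.to_numpy().T @ w, index=cols)
    return ChainLyapunovResult(values=values, per_trajectory=per, weights=w,
                               n_dropped=n_dropped)


def chain_metric_vector(
    chain: AbsorbingChain,
    mesh: Optional[DeterministicMesh] = None,
    cfg: Optional[EmbeddingConfig] = None,
    lyapunov: bool = False,
    rng: Union[np.random.Generator, int, None] = None,
    stats: Optional[ChainStatistics] = None,
    **lyap_kwargs,
) -> MetricVector:
    """Assemble the 49-metric vector from the chain.

    Non-Lyapunov entries use the weighted-moment route; joint variability is
    computed per time point (the two-stage weighted SD at each of the 100
    samples, then log and time-average, mirroring the brute-force
    definition).  Lyapunov entries are filled via :func:`chain_lyapunov`
    when ``lyapunov=True`` and flagged missing otherwise.
    """
    mesh = mesh or chain.mesh
    if mesh is None:
        raise ValueError("a mesh is required to synthesize step trajectories")
    cfg = cfg or EmbeddingConfig()
    if stats is None:
        stats = chain_statistics(chain)
    config = mesh.config

    ii, jj, s_med, mass = _transition_catalog(mesh, chain)
    if ii.size == 0:
        raise StructuralError("mesh has no surviving transitions")
    samples, T, L, v = synthesize_steps(config, mesh.states[ii], s_med)

    vals = pd.Series(np.nan, index=METRIC_NAMES)
    scalar_rhos = {
        "xcom": xcom_series(samples, config.g).max(axis=-1),
        "fri": fri_series(samples).max(axis=-1),
        "speed": v,
        "step_length": L,
        "step_duration": T,
    }
    warned = False
    for key, rho in scalar_rhos.items():
        st, included = _grouped_weighted_stats(ii, rho, mass, mesh.n_states)
        if not included.all() and not warned:
            warnings.warn(
                f"states {list(np.flatnonzero(~included))} have zero "
                "surviving mass and were excluded", stacklevel=2)
            warned = True
        mu, sigma = chain_metric(st, stats.n1)
        vals[f"{key}_mean"] = mu
        vals[f"{key}_sd"] = sigma

    # joint variability: two-stage weighted SD per time point, then log/mean
    idx = [CH[c] for c in VARIABILITY_CHANNELS]
    coord = samples[:, :, idx]                      # (P, 100, 15)
    st, _ = _grouped_weighted_stats(ii, coord, mass, mesh.n_states)
    _, sigma_t = chain_metric(st, stats.n1)         # (100, 15)
    jv = np.log(np.maximum(sigma_t, cfg.d_floor)).mean(axis=0)
    for c, val in zip(VARIABILITY_CHANNELS, jv):
        vals[f"var_{c}"] = val

    if lyapunov:
        lyap = chain_lyapunov(chain, mesh, cfg, rng=rng, **lyap_kwargs)
        vals[lyap.values.index] = lyap.values

    return MetricVector(vals, provenance="chain", n_steps=None)
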