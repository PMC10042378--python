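"""Mechanics-based fall-risk metrics computed from sequences of steps.

The inventory contains 49 named metrics per condition:

* mean and SD over steps of the per-step maximum extrapolated center of mass
  (XCoM) and foot rotation index (FRI);
* mean and SD of walking speed, step length and step duration;
* short- and long-term Lyapunov exponents (divergence-curve slopes over
  0-1 and 4-10 strides) for the six joint angles and their velocities;
* average log joint variability for fifteen coordinates (the six joint
  angles, the vertical hip position and all eight coordinate velocities --
  the horizontal hip position is excluded because it is not cyclic).

The XCoM of a sample is ``(x7 - xst) + dx7 * sqrt(l / g)`` with ``l`` the
hip-to-stance-contact distance; the FRI is the ground point where the net
reaction force would have to act to keep the stance foot from rotating,

    FRI = ([OG x Fg - OA x Fa]_z - tau_a) / Fn - xst .

Lyapunov exponents follow the divergence-of-nearest-neighbours recipe: a
5-dimensional delay embedding (delay 15 samples), nearest neighbour outside a
+-50-sample exclusion window, mean log divergence curve, least-squares slopes
over fixed index ranges.  All standard deviations over steps use the sample
(n-1) convention; standard deviations are floored at ``d_floor`` before logs
so that perfectly periodic synthetic gaits stay finite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, List, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .exceptions import (DegenerateGeometryError, FailedStepError,
                         InsufficientDataError)
from .walker import CH, N_SAMPLES, StepSequence, StepTrajectory

__all__ = [
    "EmbeddingConfig",
    "MetricVector",
    "NormalizationRecord",
    "METRIC_NAMES",
    "METRIC_GROUPS",
    "LYAP_CHANNELS",
    "VARIABILITY_CHANNELS",
    "SPATIOTEMPORAL_METRICS",
    "NON_LYAPUNOV_METRICS",
    "xcom_series",
    "xcom_step_max",
    "fri_series",
    "fri_step_max",
    "spatiotemporal_stats",
    "joint_variability",
    "divergence_curve",
    "lyapunov_exponents",
    "metric_vector_from_steps",
    "metric_table",
    "fit_normalization",
    "apply_normalization",
]

#: Coordinates entering the Lyapunov metrics (joint angles and velocities).
LYAP_CHANNELS = ["q1", "q2", "q3", "q4", "q5", "q6",
                 "dq1", "dq2", "dq3", "dq4", "dq5", "dq6"]
#: Coordinates entering the joint-variability metrics (q7 excluded: the
#: walker moves forward, so the horizontal hip position is not cyclic).
VARIABILITY_CHANNELS = ["q1", "q2", "q3", "q4", "q5", "q6", "q8",
                        "dq1", "dq2", "dq3", "dq4", "dq5", "dq6", "dq7",
                        "dq8"]

METRIC_NAMES: List[str] = (
    ["xcom_mean", "xcom_sd", "fri_mean", "fri_sd",
     "speed_mean", "speed_sd", "step_length_mean", "step_length_sd",
     "step_duration_mean", "step_duration_sd"]
    + [f"lyap_short_{c}" for c in LYAP_CHANNELS]
    + [f"lyap_long_{c}" for c in LYAP_CHANNELS]
    + [f"var_{c}" for c in VARIABILITY_CHANNELS]
)
assert len(METRIC_NAMES) == 49

#: Metric-type groups used when pooling validation statistics ("the results
#: for all coordinates were combined" for variability and Lyapunov metrics).
METRIC_GROUPS = {}
for _n in METRIC_NAMES:
    if _n.startswith("lyap_short"):
        METRIC_GROUPS[_n] = "lyap_short"
    elif _n.startswith("lyap_long"):
        METRIC_GROUPS[_n] = "lyap_long"
    elif _n.startswith("var_dq"):
        METRIC_GROUPS[_n] = "var_velocity"
    elif _n.startswith("var_"):
        METRIC_GROUPS[_n] = "var_angle"
    else:
        METRIC_GROUPS[_n] = _n

SPATIOTEMPORAL_METRICS = ["speed_mean", "speed_sd", "step_length_mean",
                          "step_length_sd", "step_duration_mean",
                          "step_duration_sd"]
NON_LYAPUNOV_METRICS = [n for n in METRIC_NAMES if not n.startswith("lyap")]


@dataclass(frozen=True)
class EmbeddingConfig:
    """Parameters of the divergence-curve Lyapunov estimator.

    ``dt`` is the sample interval in stride-normalized time (each step is
    resampled to 100 samples; ``dt`` defaults to one hundredth of a stride,
    so exponents are in units of 1/(dt * sample)).
    """

    delay: int = 15                 # tau, samples
    dim: int = 5                    # embedding dimension
    exclusion: int = 50             # Theiler half-window, samples
    short_range: tuple = (1, 200)   # 0-1 strides
    long_range: tuple = (801, 2000)  # 4-10 strides
    dt: float = 0.01                # stride-normalized sample interval
    d_floor: float = 1e-7           # numerical floor for distances and SDs
    min_lyap_steps: int = 50        # pilot rule: >= 50 steps for lambda

    def __post_init__(self) -> None:
        if self.delay < 1:
            raise ValueError("delay must be >= 1")
        if self.d_floor <= 0:
            raise ValueError("d_floor must be positive")

    def replace(self, **kw) -> "EmbeddingConfig":
        return replace(self, **kw)


@dataclass
class MetricVector:
    """The 49 named metrics for one condition plus provenance."""

    values: pd.Series
    provenance: str = "brute"       # "chain" or "brute"
    n_steps: Optional[int] = None

    def __post_init__(self) -> None:
        self.values = pd.Series(self.values, dtype=float)
        if list(self.values.index) != METRIC_NAMES:
            self.values = self.values.reindex(METRIC_NAMES)
        if len(self.values) != 49:
            raise ValueError("metric vector must have exactly 49 entries")

    def __len__(self) -> int:
        return 49

    def __getitem__(self, name: str) -> float:
        return float(self.values[name])


@dataclass
class NormalizationRecord:
    """Per-metric centers and scales (chain metrics define them; the same
    record is then reused for brute-force metrics)."""

    center: pd.Series
    scale: pd.Series

    def __post_init__(self) -> None:
        self.center = pd.Series(self.center, dtype=float)
        self.scale = pd.Series(self.scale, dtype=float)
        if list(self.center.index) != list(self.scale.index):
            raise ValueError("center and scale must share an index")
        if (self.scale.dropna() <= 0).any():
            raise ValueError("normalization scales must be positive")

    @property
    def metrics(self) -> list:
        return list(self.center.index)


# ---------------------------------------------------------------------------
# Per-step metrics
# ---------------------------------------------------------------------------

def _as_stack(steps) -> tuple:
    """Coerce a StepSequence / list of StepTrajectory / raw stack into
    ``(samples, T, L, v, g)``."""
    if isinstance(steps, StepSequence):
        T, L, v = steps.scalars()
        return steps.samples(), T, L, v, steps.config.g
    if isinstance(steps, StepTrajectory):
        steps = [steps]
    if isinstance(steps, (list, tuple)) and steps and isinstance(
            steps[0], StepTrajectory):
        samples = np.stack([t.samples for t in steps])
        T = np.array([t.T for t in steps])
        L = np.array([t.L for t in steps])
        v = np.array([t.v for t in steps])
        return samples, T, L, v, 9.81
    samples = np.asarray(steps, dtype=float)
    if samples.ndim == 2:
        samples = samples[None]
    return samples, None, None, None, 9.81


def xcom_series(samples: np.ndarray, g: float = 9.81) -> np.ndarray:
    """Per-sample extrapolated center of mass for a (n, 100, C) stack."""
    samples = np.asarray(samples, dtype=float)
    if samples.ndim == 2:
        samples = samples[None]
    rel_x = samples[..., CH["q7"]] - samples[..., CH["xst"]]
    rel_y = samples[..., CH["q8"]] - samples[..., CH["yst"]]
    ell = np.hypot(rel_x, rel_y)
    if np.any(ell == 0):
        raise DegenerateGeometryError(
            "hip coincides with the stance contact (l = 0)")
    return rel_x + samples[..., CH["dq7"]] * np.sqrt(ell / g)


def xcom_step_max(traj, g: float = 9.81) -> Union[float, np.ndarray]:
    """Maximum XCoM over the 100 samples of each step."""
    if isinstance(traj, StepTrajectory):
        return float(xcom_series(traj.samples[None], g).max())
    samples, *_ , g_cfg = _as_stack(traj)
    if isinstance(traj, StepSequence):
        g = g_cfg
    out = xcom_series(samples, g).max(axis=-1)
    return out if out.size > 1 else float(out[0])


def fri_series(samples: np.ndarray) -> np.ndarray:
    """Per-sample foot rotation index for a (n, 100, C) stack.

    Moment balance about the stationary origin: the planar (z) component of
    ``OG x Fg - OA x Fa`` minus the ankle torque, divided by the normal
    ground reaction force, relative to the stance contact.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.ndim == 2:
        samples = samples[None]
    Fn = samples[..., CH["Fn"]]
    if np.any(Fn <= 0):
        raise FailedStepError(
            "non-positive normal GRF: FRI is defined for supported steps only")
    m_g = (samples[..., CH["Gx"]] * samples[..., CH["Fgy"]]
           - samples[..., CH["Gy"]] * samples[..., CH["Fgx"]])
    m_a = (samples[..., CH["Ax"]] * samples[..., CH["Fay"]]
           - samples[..., CH["Ay"]] * samples[..., CH["Fax"]])
    return (m_g - m_a - samples[..., CH["tau_a"]]) / Fn - samples[..., CH["xst"]]


def fri_step_max(traj) -> Union[float, np.ndarray]:
    """Maximum FRI over the 100 samples of each step."""
    if isinstance(traj, StepTrajectory):
        return float(fri_series(traj.samples[None]).max())
    samples, *_ = _as_stack(traj)
    out = fri_series(samples).max(axis=-1)
    return out if out.size > 1 else float(out[0])


def spatiotemporal_stats(steps) -> dict:
    """Mean and sample SD of speed, step length and step duration."""
    if isinstance(steps, StepSequence):
        # scalars are cheap; no need to synthesize full trajectories
        T, L, v = steps.scalars()
    else:
        _, T, L, v, _ = _as_stack(steps)
    if T is None or T.size < 2:
        raise InsufficientDataError(
            "at least 2 steps are required for spatiotemporal statistics")
    return {
        "speed_mean": float(np.mean(v)),
        "speed_sd": float(np.std(v, ddof=1)),
        "step_length_mean": float(np.mean(L)),
        "step_length_sd": float(np.std(L, ddof=1)),
        "step_duration_mean": float(np.mean(T)),
        "step_duration_sd": float(np.std(T, ddof=1)),
    }


def joint_variability(steps, d_floor: float = 1e-7) -> pd.Series:
    """Average log variability for the 15 cyclic coordinates.

    For each coordinate: the sample SD across steps at each of the 100 time
    points, the natural log of each SD (floored at ``d_floor``), averaged
    over the step.
    """
    samples, *_ = _as_stack(steps)
    if samples.shape[0] < 2:
        raise InsufficientDataError(
            "at least 2 steps are required for joint variability")
    idx = [CH[c] for c in VARIABILITY_CHANNELS]
    sd = np.std(samples[:, :, idx], axis=0, ddof=1)   # (100, 15)
    vals = np.log(np.maximum(sd, d_floor)).mean(axis=0)
    return pd.Series(vals, index=[f"var_{c}" for c in VARIABILITY_CHANNELS])


# ---------------------------------------------------------------------------
# Lyapunov exponents
# ---------------------------------------------------------------------------

def _embed(series: np.ndarray, cfg: EmbeddingConfig) -> np.ndarray:
    span = (cfg.dim - 1) * cfg.delay
    n_emb = series.size - span
    if n_emb < 2:
        raise InsufficientDataError(
            f"series of {series.size} samples is too short for a "
            f"{cfg.dim}-dimensional embedding with delay {cfg.delay}")
    window = np.lib.stride_tricks.sliding_window_view(series, span + 1)
    return np.ascontiguousarray(window[:, ::cfg.delay])


def _nearest_neighbors(X: np.ndarray, exclusion: int) -> tuple:
    """Index pairs (j, k): for each j the nearest point outside the
    +-exclusion window, ties broken toward the smaller index."""
    n = X.shape[0]
    if n < exclusion + 2:
        raise InsufficientDataError(
            "embedded series too short for the exclusion window")
    k_query = min(n, 2 * exclusion + 3)
    tree = cKDTree(X)
    dist, idx = tree.query(X, k=k_query)
    rows = np.arange(n)
    valid = np.abs(idx - rows[:, None]) > exclusion
    found = valid.any(axis=1)
    first = valid.argmax(axis=1)
    best = dist[rows, first]
    # exact-distance ties (duplicated points) break toward the smaller index
    tie_idx = np.where(valid & (dist == best[:, None]), idx, n)
    kk = tie_idx.min(axis=1)
    jj = rows[found]
    kk = kk[found]
    missing = rows[~found]
    if missing.size:
        # brute-force fallback for points whose k nearest all fell inside
        # the exclusion window
        mj, mk = [], []
        for j in missing:
            d2 = np.einsum("ij,ij->i", X - X[j], X - X[j])
            lo = max(0, j - exclusion)
            hi = min(n, j + exclusion + 1)
            d2[lo:hi] = np.inf
            k = int(np.argmin(d2))
            if np.isfinite(d2[k]):
                mj.append(j)
                mk.append(k)
        jj = np.concatenate([jj, np.asarray(mj, dtype=int)])
        kk = np.concatenate([kk, np.asarray(mk, dtype=int)])
        order = np.argsort(jj)
        jj, kk = jj[order], kk[order]
    return jj, kk


def divergence_curve(series: np.ndarray, cfg: Optional[EmbeddingConfig] = None,
                     i_max: Optional[int] = None) -> np.ndarray:
    """Mean logarithmic divergence curve ``y(i)`` of nearest neighbours.

    ``y(i) = (1/dt) <ln d_j(i)>`` where ``d_j(i)`` is the distance between
    the delay-embedded point ``j`` and its nearest neighbour (outside the
    exclusion window) ``i`` samples later, floored at ``cfg.d_floor``, and
    the average runs over all pairs still inside the series at lag ``i``.
    """
    cfg = cfg or EmbeddingConfig()
    series = np.asarray(series, dtype=float).ravel()
    if i_max is None:
        i_max = cfg.long_range[1]
    X = _embed(series, cfg)
    n = X.shape[0]
    jj, kk = _nearest_neighbors(X, cfg.exclusion)
    if jj.size == 0:
        raise InsufficientDataError("no valid nearest-neighbour pairs")
    horizon = n - np.maximum(jj, kk)   # pair (j,k) is usable for i < horizon
    i_top = min(i_max, int(horizon.max()) - 1)

    # d_jk(i)^2 = sum_d (s[j+i+d*tau] - s[k+i+d*tau])^2: gather the squared
    # difference series once per pair, then sum its dim shifted copies.
    span = (cfg.dim - 1) * cfg.delay
    win = i_top + span + 1
    lags = np.arange(i_top + 1)
    floor2 = cfg.d_floor ** 2
    padded = np.concatenate([series, np.zeros(win)])
    W = np.lib.stride_tricks.sliding_window_view(padded, win)
    sums = np.zeros(i_top + 1)
    counts = np.zeros(i_top + 1, dtype=np.int64)
    # process pairs in blocks ordered by horizon so each block only touches
    # the lags it can still reach
    order = np.argsort(horizon)[::-1]
    jj, kk, horizon = jj[order], kk[order], horizon[order]
    for p0 in range(0, jj.size, 1024):
        jb = jj[p0:p0 + 1024]
        kb = kk[p0:p0 + 1024]
        hb = horizon[p0:p0 + 1024]
        i_blk = min(i_top, int(hb.max()) - 1)
        wb = i_blk + span + 1
        D = W[jb, :wb] - W[kb, :wb]
        E = D * D
        d2 = E[:, :i_blk + 1].copy()
        for d in range(1, cfg.dim):
            d2 += E[:, d * cfg.delay:d * cfg.delay + i_blk + 1]
        lnd = 0.5 * np.log(np.maximum(d2, floor2))
        valid = hb[:, None] > lags[None, :i_blk + 1]
        sums[:i_blk + 1] += np.where(valid, lnd, 0.0).sum(axis=0)
        counts[:i_blk + 1] += valid.sum(axis=0)
    with np.errstate(invalid="ignore"):
        y = np.where(counts > 0, sums / counts, np.nan) / cfg.dt
    return y


def lyapunov_exponents(curve: np.ndarray,
                       cfg: Optional[EmbeddingConfig] = None) -> tuple:
    """Least-squares slopes of the divergence curve over the short (0-1
    stride) and long (4-10 stride) index ranges."""
    cfg = cfg or EmbeddingConfig()
    curve = np.asarray(curve, dtype=float)
    out = []
    for label, (lo, hi) in (("short", cfg.short_range),
                            ("long", cfg.long_range)):
        if curve.size <= hi or np.isnan(curve[lo:hi + 1]).any():
            raise InsufficientDataError(
                f"divergence curve too short for the {label} fit range "
                f"({lo}..{hi})")
        i = np.arange(lo, hi + 1)
        out.append(float(np.polyfit(i, curve[lo:hi + 1], 1)[0]))
    return tuple(out)


def _lyapunov_from_stack(samples: np.ndarray,
                         cfg: EmbeddingConfig) -> pd.Series:
    """Short/long Lyapunov exponents for each of the 12 joint coordinates of
    a (n, 100, C) stack; series are the concatenated resampled steps."""
    vals = {}
    for c in LYAP_CHANNELS:
        series = samples[:, :, CH[c]].ravel()
        curve = divergence_curve(series, cfg)
        lam_s, lam_l = lyapunov_exponents(curve, cfg)
        vals[f"lyap_short_{c}"] = lam_s
        vals[f"lyap_long_{c}"] = lam_l
    return pd.Series(vals)


# ---------------------------------------------------------------------------
# Assembly and normalization
# ---------------------------------------------------------------------------

def metric_vector_from_steps(steps, cfg: Optional[EmbeddingConfig] = None,
                             lyapunov: bool = True) -> MetricVector:
    """Assemble all 49 metrics from a sequence of steps.

    Lyapunov entries require at least ``cfg.min_lyap_steps`` steps; with
    fewer (or with ``lyapunov=False``) they are flagged missing (NaN).
    """
    cfg = cfg or EmbeddingConfig()
    samples, T, L, v, g = _as_stack(steps)
    n = samples.shape[0]
    vals = pd.Series(np.nan, index=METRIC_NAMES)

    xc = xcom_series(samples, g).max(axis=-1)
    fr = fri_series(samples).max(axis=-1)
    if n < 2:
        raise InsufficientDataError("at least 2 steps are required")
    vals["xcom_mean"] = xc.mean()
    vals["xcom_sd"] = xc.std(ddof=1)
    vals["fri_mean"] = fr.mean()
    vals["fri_sd"] = fr.std(ddof=1)
    for k, val in spatiotemporal_stats(steps).items():
        vals[k] = val
    jv = joint_variability(steps, cfg.d_floor)
    vals[jv.index] = jv

    if lyapunov:
        if n < cfg.min_lyap_steps:
            warnings.warn(
                f"{n} steps < {cfg.min_lyap_steps}: Lyapunov metrics flagged "
                "missing", stacklevel=2)
        else:
            lam = _lyapunov_from_stack(samples, cfg)
            vals[lam.index] = lam
    return MetricVector(vals, provenance="brute", n_steps=n)


def metric_table(vectors: Sequence[MetricVector],
                 index: Optional[Iterable] = None) -> pd.DataFrame:
    """Stack metric vectors into a (conditions x 49) DataFrame."""
    df = pd.DataFrame([v.values for v in vectors])
    if index is not None:
        df.index = list(index)
    return df


def fit_normalization(vectors) -> NormalizationRecord:
    """Fit per-metric centers (means) and scales (sample SDs).

    Zero-variance metrics get scale 1 with a warning so that constant
    columns normalize to exact zeros instead of blowing up.
    """
    if isinstance(vectors, pd.DataFrame):
        df = vectors
    else:
        df = metric_table(list(vectors))
    if df.shape[0] < 2:
        raise InsufficientDataError(
            "at least 2 vectors are required to fit a normalization")
    center = df.mean(axis=0)
    scale = df.std(axis=0, ddof=1)
    bad = ~(scale > 0)
    if bad.any():
        warnings.warn(
            f"zero-variance metrics {list(scale.index[bad])}: scale set to 1",
            stacklevel=2)
        scale[bad] = 1.0
    return NormalizationRecord(center, scale)


def apply_normalization(record: NormalizationRecord, data):
    """Center/scale a MetricVector, Series or DataFrame with a fitted
    record."""
    idx = record.center.index
    if isinstance(data, MetricVector):
        vals = data.values.copy()
        vals[idx] = (vals[idx] - record.center) / record.scale
        return MetricVector(vals, provenance=data.provenance,
                            n_steps=data.n_steps)
    if isinstance(data, pd.DataFrame):
        return (data[idx] - record.center) / record.scale
    data = pd.Series(data, dtype=float)
    return (data[idx] - record.center) / record.scale
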