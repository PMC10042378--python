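"""Validation of chain-derived metrics against brute-force simulation.

Three stages:

* :func:`segment_trials` cuts long perturbed trials into disjoint n-step
  segments (the paper-style step-count grid is ``DEFAULT_STEP_COUNTS``);
* :func:`compare_methods` checks, per metric, whether the single chain value
  lies within one standard deviation of the distribution of brute-force
  segment values, and aggregates match rates and median errors by metric
  type;
* :func:`convergence_fit` fits  ``p = alpha_1 ln(n) + alpha_0``  to the
  percentage of segments within a normalized-error threshold of the chain
  value, and inverts the fit for the number of steps at which 90% of
  segments would comply (rounded up, floored at 10).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import InsufficientDataError
from .metrics import (METRIC_GROUPS, METRIC_NAMES, MetricVector,
                      NormalizationRecord, apply_normalization)
from .walker import StepSequence

__all__ = [
    "DEFAULT_STEP_COUNTS",
    "ComparisonResult",
    "ConvergenceFit",
    "segment_trials",
    "compare_methods",
    "error_percentages",
    "convergence_fit",
]

#: Segment lengths used when quantifying metric convergence.
DEFAULT_STEP_COUNTS = (10, 20, 30, 40, 50, 60, 70, 80, 90, 100,
                       200, 300, 500, 1000)


def segment_trials(trials: Sequence[StepSequence], n: int) -> List[StepSequence]:
    """Cut each trial into consecutive disjoint ``n``-step segments.

    Trailing remainders are discarded.  Trials contain only completed steps,
    so segments never span a fall; a trial that fell before ``n`` steps
    contributes none.
    """
    if n < 1:
        raise ValueError("segment length must be >= 1")
    segments: List[StepSequence] = []
    for trial in trials:
        for k in range(len(trial) // n):
            segments.append(trial[k * n:(k + 1) * n])
    if not segments:
        warnings.warn(f"no trial is {n} steps long; empty segmentation",
                      stacklevel=2)
    return segments


@dataclass
class ComparisonResult:
    """Per-metric and aggregated chain-vs-brute comparison.

    ``rows`` has one line per metric: the (normalized) chain value, the mean
    and sample SD of the brute-force values, the one-SD match flag and the
    absolute difference.  ``aggregates`` pools metrics by type (coordinates
    combined for variability and Lyapunov entries) into % match, median
    absolute error and median brute-force SD.
    """

    rows: pd.DataFrame
    aggregates: pd.DataFrame

    @property
    def percent_match(self) -> float:
        """Overall % of metrics whose chain value is within one SD."""
        flags = self.rows["match"].dropna()
        return 100.0 * flags.mean() if len(flags) else float("nan")


def compare_methods(chain_vec: MetricVector,
                    brute_vecs: Sequence[MetricVector],
                    record: Optional[NormalizationRecord] = None
                    ) -> ComparisonResult:
    """Compare the chain metric vector against the brute-force distribution.

    When ``record`` is given, both sides are normalized with it first (the
    intended use: a record fitted on the chain metrics of all conditions).
    Metrics missing (NaN) on either side are kept in ``rows`` but excluded
    from the aggregates.
    """
    if len(brute_vecs) < 2:
        raise InsufficientDataError(
            "at least 2 brute-force vectors are required")
    if record is not None:
        chain_vec = apply_normalization(record, chain_vec)
        brute_vecs = [apply_normalization(record, v) for v in brute_vecs]
    brute = pd.DataFrame([v.values for v in brute_vecs])
    if list(brute.columns) != METRIC_NAMES:
        raise ValueError("brute vectors do not share the metric schema")
    bmean = brute.mean(axis=0)
    bsd = brute.std(axis=0, ddof=1)
    diff = (chain_vec.values - bmean).abs()
    match = diff <= bsd
    match = match.where(~(diff.isna() | bsd.isna()))
    rows = pd.DataFrame({
        "chain": chain_vec.values,
        "brute_mean": bmean,
        "brute_sd": bsd,
        "match": match,
        "abs_diff": diff,
        "group": pd.Series(METRIC_GROUPS),
    })

    ok = rows.dropna(subset=["match"])
    agg = ok.groupby("group").agg(
        percent_match=("match", lambda s: 100.0 * s.mean()),
        median_abs_err=("abs_diff", "median"),
        median_brute_sd=("brute_sd", "median"),
        n_metrics=("match", "size"),
    )
    return ComparisonResult(rows=rows, aggregates=agg)


def error_percentages(
    normalized_errors: pd.DataFrame,
    thresholds: Sequence[float] = (0.1, 0.5),
    metrics: Optional[Sequence[str]] = None,
    pool: bool = True,
):
    """Percentage of segment errors below each threshold.

    ``normalized_errors``: rows = segments (any number of conditions pooled),
    columns = metric names, values = |brute - chain| in normalized units.
    With ``pool=True`` the requested metrics are pooled into one percentage
    per threshold (as when coordinates and conditions are combined);
    otherwise one percentage per metric is returned.
    """
    df = normalized_errors if metrics is None else normalized_errors[list(metrics)]
    out = {}
    for thr in thresholds:
        below = (df.abs() < thr)
        valid = df.notna()
        if pool:
            out[thr] = 100.0 * below.values.sum() / valid.values.sum()
        else:
            out[thr] = 100.0 * below.sum() / valid.sum()
    return out if len(out) > 1 else out[thresholds[0]]


@dataclass
class ConvergenceFit:
    """Log-linear accuracy-vs-steps fit ``p = alpha1 ln(n) + alpha0``."""

    alpha0: float
    alpha1: float
    r_squared: float
    steps_to_90: Optional[int]      # None when alpha1 <= 0 (unattainable)
    extrapolated: bool = False      # steps_to_90 > 10x the largest n observed

    def predict(self, n) -> np.ndarray:
        return self.alpha1 * np.log(np.asarray(n, dtype=float)) + self.alpha0


def convergence_fit(ns: Iterable[float], pcts: Iterable[float]
                    ) -> ConvergenceFit:
    """Fit the percentage-within-threshold curve against ln(n).

    ``steps_to_90 = exp((90 - alpha0) / alpha1)`` rounded up to an integer
    and floored at 10; reported as unattainable (None) when the fitted slope
    is not positive.
    """
    ns = np.asarray(list(ns), dtype=float)
    pcts = np.asarray(list(pcts), dtype=float)
    if ns.size < 3:
        raise InsufficientDataError("at least 3 (n, p) points are required")
    if np.unique(ns).size < 2:
        raise ValueError("degenerate fit: all n values identical")
    x = np.log(ns)
    alpha1, alpha0 = np.polyfit(x, pcts, 1)
    resid = pcts - (alpha1 * x + alpha0)
    ss_tot = np.sum((pcts - pcts.mean()) ** 2)
    r2 = 1.0 - np.sum(resid ** 2) / ss_tot if ss_tot > 0 else 1.0
    if alpha1 > 0:
        raw = math.exp((90.0 - alpha0) / alpha1)
        steps = max(int(math.ceil(raw)), 10)
        extrapolated = steps > 10 * ns.max()
    else:
        steps = None
        extrapolated = False
    return ConvergenceFit(alpha0=float(alpha0), alpha1=float(alpha1),
                          r_squared=float(r2), steps_to_90=steps,
                          extrapolated=extrapolated)
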