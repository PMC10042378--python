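"""Quadratic fall-risk prediction models.

The target is the natural log of the mean first passage time (steps to
fall); raw MFPTs span many orders of magnitude, so the log condenses the
range into something a regression can work with.  Two model families are
provided, both in the Model / Results idiom: construct a model object from
data, call ``fit()``, get a results object carrying estimates,
uncertainties, diagnostics and ``summary()``.

* :class:`IndividualMetricModel` -- one metric at a time,
  ``yhat = b0 + b1 rho + b2 rho^2``.
* :class:`FallRiskModel` -- the combined model: metrics are centered/scaled,
  projected onto the first 15 principal components, and a quadratic form in
  the scores

      yhat = b_00 + sum_k (b_k1 X_PCA,k + b_k2 X_PCA,k^2)

  is selected by consensus stepwise regression: the training conditions are
  reduced by removing three whole conditions, a bidirectional stepwise pass
  selects terms, this is repeated ten times, terms appearing in at least
  three reduced models are pooled, and a final stepwise pass over the pool
  fixes the model.  Two variants exist: ``no_lyap`` (no Lyapunov exponents)
  and ``with_lyap`` (adds the long-term exponents).  Short-term exponents
  are used by neither -- they are not reliably computable from the chain.

Goodness of fit is summarized by RMSE, MAE, MAPE, RAAE (mean absolute error
scaled by the SD of the predictions), maximum absolute error, the share of
predictions within a +-3.3 band on ln(MFPT) (10% of the log-range the bank
is designed to span), and the calibration line ``yhat = a1 y + a0`` with its
R^2 (written Re^2 to distinguish it from the model's own fit).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, Union

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.decomposition import PCA

from .exceptions import InsufficientDataError
from .metrics import (METRIC_NAMES, NON_LYAPUNOV_METRICS, MetricVector,
                      NormalizationRecord, apply_normalization,
                      fit_normalization, metric_table)

__all__ = [
    "VARIANTS",
    "variant_metrics",
    "GoodnessOfFit",
    "goodness_of_fit",
    "IndividualMetricModel",
    "IndividualMetricResults",
    "PCATransform",
    "fit_pca",
    "apply_pca",
    "stepwise_select",
    "consensus_stepwise",
    "FallRiskModel",
    "FallRiskResults",
]

VARIANTS = ("no_lyap", "with_lyap")

#: Default tolerance on ln(MFPT): 10% of the designed log-range.
DEFAULT_TOLERANCE = 3.3


def variant_metrics(variant: str) -> List[str]:
    """Metric columns used by a combined-model variant."""
    if variant == "no_lyap":
        return list(NON_LYAPUNOV_METRICS)
    if variant == "with_lyap":
        return list(NON_LYAPUNOV_METRICS) + [
            n for n in METRIC_NAMES if n.startswith("lyap_long")]
    raise ValueError(f"variant must be one of {VARIANTS}, got {variant!r}")


# ---------------------------------------------------------------------------
# Goodness of fit
# ---------------------------------------------------------------------------

@dataclass
class GoodnessOfFit:
    """Error summaries relating predicted and true ln(MFPT)."""

    rmse: float
    mae: float
    mape: float                   # percent; y == 0 cases excluded
    raae: float                   # mean |err| / SD of predictions
    max_abs_err: float
    pct_in_tolerance: float
    tolerance: float
    slope: float                  # a1 of yhat = a1 y + a0
    intercept: float              # a0
    re2: float                    # R^2 of the calibration line
    mean_group_sd: Optional[float]
    n: int
    n_mape_excluded: int = 0
    r2_adj: Optional[float] = None   # adjusted R^2 of the fitted model

    def to_dict(self) -> dict:
        return {k: (None if v is None else float(v) if np.isscalar(v) else v)
                for k, v in self.__dict__.items()}


def goodness_of_fit(yhat, y, groups: Optional[Sequence] = None,
                    tolerance: float = DEFAULT_TOLERANCE,
                    r2_adj: Optional[float] = None) -> GoodnessOfFit:
    """Compute all goodness-of-fit measures for predictions ``yhat`` against
    true values ``y`` (both on the ln(MFPT) scale).

    ``groups`` optionally labels conditions; the SD of the error within each
    group is averaged into ``mean_group_sd`` (the trial-to-trial precision of
    the prediction for one condition).
    """
    yhat = np.asarray(yhat, dtype=float)
    y = np.asarray(y, dtype=float)
    if yhat.shape != y.shape or yhat.ndim != 1:
        raise ValueError("yhat and y must be 1-D arrays of equal length")
    if yhat.size < 2:
        raise InsufficientDataError("at least 2 predictions are required")
    err = yhat - y
    nonzero = y != 0
    n_excl = int((~nonzero).sum())
    if n_excl:
        warnings.warn(f"{n_excl} cases with y = 0 excluded from MAPE",
                      stacklevel=2)
    mape = 100.0 * float(np.mean(np.abs(err[nonzero] / y[nonzero]))) \
        if nonzero.any() else float("nan")
    sd_pred = float(np.std(yhat, ddof=1))
    raae = float(np.mean(np.abs(err))) / sd_pred if sd_pred > 0 \
        else float("inf")
    # calibration line yhat = a1 y + a0
    if np.ptp(y) > 0:
        a1, a0 = np.polyfit(y, yhat, 1)
        resid = yhat - (a1 * y + a0)
        ss_tot = np.sum((yhat - yhat.mean()) ** 2)
        re2 = 1.0 - np.sum(resid ** 2) / ss_tot if ss_tot > 0 else 1.0
    else:
        a1, a0, re2 = float("nan"), float("nan"), float("nan")
    mean_group_sd = None
    if groups is not None:
        s = pd.Series(err).groupby(list(groups)).std(ddof=1).dropna()
        mean_group_sd = float(s.mean()) if len(s) else None
    return GoodnessOfFit(
        rmse=float(np.sqrt(np.mean(err ** 2))),
        mae=float(np.mean(np.abs(err))),
        mape=mape,
        raae=raae,
        max_abs_err=float(np.max(np.abs(err))),
        pct_in_tolerance=100.0 * float(np.mean(np.abs(err) <= tolerance)),
        tolerance=tolerance,
        slope=float(a1), intercept=float(a0), re2=float(re2),
        mean_group_sd=mean_group_sd,
        n=int(y.size), n_mape_excluded=n_excl, r2_adj=r2_adj)


# ---------------------------------------------------------------------------
# Individual metric models
# ---------------------------------------------------------------------------

class IndividualMetricModel:
    """Quadratic regression of ln(MFPT) on a single metric."""

    def __init__(self, endog, metric_values, name: str = "metric"):
        self.endog = np.asarray(endog, dtype=float)
        self.rho = np.asarray(metric_values, dtype=float)
        self.name = name
        if self.endog.shape != self.rho.shape or self.endog.ndim != 1:
            raise ValueError("endog and metric_values must be 1-D and equal "
                             "length")
        if self.endog.size < 4:
            raise InsufficientDataError(
                "at least 4 conditions are required for a quadratic fit")

    def fit(self) -> "IndividualMetricResults":
        X = np.column_stack([np.ones_like(self.rho), self.rho, self.rho ** 2])
        if np.linalg.matrix_rank(X) < 3:
            raise np.linalg.LinAlgError(
                f"degenerate quadratic design for metric {self.name!r} "
                "(constant values?)")
        res = sm.OLS(self.endog, X).fit()
        return IndividualMetricResults(self, res)


class IndividualMetricResults:
    """OLS results for one metric's quadratic model."""

    def __init__(self, model: IndividualMetricModel, ols_results):
        self.model = model
        self.ols_results = ols_results
        self.params = pd.Series(ols_results.params,
                                index=["beta0", "beta1", "beta2"])
        self.bse = pd.Series(ols_results.bse,
                             index=["beta0", "beta1", "beta2"])
        self.rsquared = float(ols_results.rsquared)
        self.rsquared_adj = float(ols_results.rsquared_adj)

    def predict(self, rho) -> np.ndarray:
        rho = np.asarray(rho, dtype=float)
        b = self.params.to_numpy()
        out = b[0] + b[1] * rho + b[2] * rho ** 2
        return out if out.ndim else float(out)

    def predict_mfpt(self, rho) -> np.ndarray:
        """Predicted MFPT in steps, exp of the log-scale prediction."""
        return np.exp(self.predict(rho))

    def summary(self) -> str:
        head = (f"Quadratic fall-risk model for metric "
                f"{self.model.name!r}\n"
                f"adj. R^2 = {self.rsquared_adj:.4f}\n")
        return head + str(self.ols_results.summary())


# ---------------------------------------------------------------------------
# PCA transform
# ---------------------------------------------------------------------------

@dataclass
class PCATransform:
    """Frozen principal-component transform of the normalized metrics."""

    loadings: pd.DataFrame          # (metrics x components)
    mean: pd.Series                 # column means removed before projection
    explained_variance: np.ndarray

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]


def fit_pca(normalized: pd.DataFrame, n_components: int = 15) -> PCATransform:
    """PCA of the normalized metric matrix via SVD.

    Components are ordered by non-increasing explained variance; each
    component's sign is fixed so its largest-magnitude loading is positive.
    Fewer components than requested are returned (with a warning) when the
    data cannot support 15.
    """
    if normalized.size == 0:
        raise ValueError("empty metric matrix")
    if normalized.isna().any().any():
        bad = normalized.columns[normalized.isna().any()].tolist()
        raise ValueError(f"metric matrix contains NaNs in {bad}")
    k = min(n_components, normalized.shape[0] - 1, normalized.shape[1])
    if k < n_components:
        warnings.warn(
            f"only {k} principal components supported by "
            f"{normalized.shape[0]} conditions", stacklevel=2)
    pca = PCA(n_components=k, svd_solver="full")
    pca.fit(normalized.to_numpy())
    comps = pca.components_            # (k, p)
    for r in range(comps.shape[0]):
        j = np.argmax(np.abs(comps[r]))
        if comps[r, j] < 0:
            comps[r] *= -1.0
    loadings = pd.DataFrame(comps.T, index=normalized.columns,
                            columns=[f"pc{r + 1}" for r in range(k)])
    return PCATransform(loadings=loadings,
                        mean=pd.Series(pca.mean_, index=normalized.columns),
                        explained_variance=pca.explained_variance_.copy())


def apply_pca(transform: PCATransform, data):
    """Project normalized metrics onto the frozen components."""
    if isinstance(data, pd.DataFrame):
        centered = data[transform.loadings.index] - transform.mean
        return centered @ transform.loadings
    data = pd.Series(data, dtype=float)
    centered = data[transform.loadings.index] - transform.mean
    return pd.Series(centered @ transform.loadings,
                     index=transform.loadings.columns)


# ---------------------------------------------------------------------------
# Stepwise selection
# ---------------------------------------------------------------------------

def stepwise_select(X: pd.DataFrame, y, entry: float = 0.05,
                    stay: float = 0.10, max_iter: int = 200) -> List[str]:
    """Bidirectional stepwise term selection on t-test p-values.

    Forward: add the candidate with the smallest p-value, if that p-value
    survives a Bonferroni correction for the number of candidates scanned
    (``p_min * n_candidates < entry``) -- the forward step is a
    best-of-many selection, so the raw threshold alone would admit a noise
    term with high probability.  Backward: drop the selected term with the
    largest p-value above ``stay``.  Iterate until stable.  The intercept
    is always included and never a candidate.
    """
    y = np.asarray(y, dtype=float)
    selected: List[str] = []
    remaining = list(X.columns)
    n = len(y)
    for _ in range(max_iter):
        changed = False
        if remaining and len(selected) + 2 < n:
            best, bestp = None, np.inf
            for c in remaining:
                cols = selected + [c]
                res = sm.OLS(y, sm.add_constant(X[cols], has_constant="add")
                             ).fit()
                p = float(res.pvalues.get(c, 1.0))
                if p < bestp:
                    best, bestp = c, p
            if best is not None and bestp * len(remaining) < entry:
                selected.append(best)
                remaining.remove(best)
                changed = True
            else:
                best = None
        while selected:
            res = sm.OLS(y, sm.add_constant(X[selected], has_constant="add")
                         ).fit()
            pv = res.pvalues.drop("const", errors="ignore")
            worst = pv.idxmax()
            if float(pv[worst]) > stay:
                selected.remove(worst)
                remaining.append(worst)
                changed = True
            else:
                break
        if not changed:
            break
    return selected


# ---------------------------------------------------------------------------
# Combined model
# ---------------------------------------------------------------------------

def _score_terms(scores: pd.DataFrame) -> pd.DataFrame:
    """Candidate design: linear and squared terms of each PCA score."""
    out = {}
    for c in scores.columns:
        out[c] = scores[c]
        out[f"{c}^2"] = scores[c] ** 2
    return pd.DataFrame(out, index=scores.index)


def consensus_stepwise(terms: pd.DataFrame, y, groups: Sequence,
                       seed: int = 0, n_repeats: int = 10, n_remove: int = 3,
                       min_votes: int = 3, entry: float = 0.05,
                       stay: float = 0.10) -> tuple:
    """Consensus term selection over reduced training sets.

    ``n_repeats`` times, ``n_remove`` whole condition groups are removed at
    random and a stepwise pass selects terms on the remainder.  Terms
    selected in at least ``min_votes`` reduced models are pooled, and a
    final stepwise pass over the pool (on the full data) fixes the model.
    Returns ``(selected_terms, votes)``; deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    y = np.asarray(y, dtype=float)
    groups = pd.Series(list(groups), index=terms.index)
    unique_groups = pd.unique(groups)
    if len(unique_groups) <= n_remove:
        raise InsufficientDataError(
            f"need more than {n_remove} condition groups to reduce the "
            "training set")
    votes: dict = {}
    for _ in range(n_repeats):
        removed = rng.choice(unique_groups, size=n_remove, replace=False)
        keep = ~groups.isin(removed).to_numpy()
        sel = stepwise_select(terms.loc[keep], y[keep],
                              entry=entry, stay=stay)
        for term in sel:
            votes[term] = votes.get(term, 0) + 1
    pool = [t for t in terms.columns if votes.get(t, 0) >= min_votes]
    final = stepwise_select(terms[pool], y, entry=entry, stay=stay) \
        if pool else []
    return final, votes


class FallRiskModel:
    """Combined quadratic fall-risk model over PCA scores of the metrics.

    Parameters
    ----------
    metrics
        Raw (un-normalized) chain metric table, one row per training
        condition, columns at least the variant's metric set (a list of
        :class:`MetricVector` is also accepted).
    endog
        ln(MFPT) per condition.
    variant
        ``"no_lyap"`` (default) or ``"with_lyap"``.
    groups
        Condition labels used when reducing the training set; defaults to
        the row index (each row its own condition).
    """

    def __init__(self, metrics, endog, variant: str = "no_lyap",
                 groups: Optional[Sequence] = None):
        if not isinstance(metrics, pd.DataFrame):
            metrics = metric_table(list(metrics))
        cols = variant_metrics(variant)
        missing = [c for c in cols if c not in metrics.columns]
        if missing:
            raise ValueError(f"metrics table lacks columns {missing}")
        self.metrics = metrics[cols].copy()
        if self.metrics.isna().any().any():
            bad = self.metrics.columns[self.metrics.isna().any()].tolist()
            raise ValueError(
                f"variant {variant!r} requires metrics {bad}, which contain "
                "missing values")
        self.endog = pd.Series(np.asarray(endog, dtype=float),
                               index=metrics.index)
        if len(self.endog) != len(self.metrics):
            raise ValueError("endog length does not match the metric table")
        self.variant = variant
        self.groups = pd.Series(
            list(groups) if groups is not None else list(metrics.index),
            index=metrics.index)
        if len(self.endog) < 10:
            raise InsufficientDataError(
                "at least 10 training conditions are required")

    def fit(self, seed: int = 0, n_components: int = 15,
            n_repeats: int = 10, n_remove: int = 3, min_votes: int = 3,
            entry: float = 0.05, stay: float = 0.10) -> "FallRiskResults":
        """Consensus stepwise fit; deterministic given ``seed``."""
        record = fit_normalization(self.metrics)
        Z = apply_normalization(record, self.metrics)
        pca = fit_pca(Z, n_components=n_components)
        scores = apply_pca(pca, Z)
        terms = _score_terms(scores)
        y = self.endog
        final, votes = consensus_stepwise(
            terms, y.to_numpy(), self.groups, seed=seed,
            n_repeats=n_repeats, n_remove=n_remove, min_votes=min_votes,
            entry=entry, stay=stay)
        if not final:
            warnings.warn("no term survived consensus selection; "
                          "intercept-only model", stacklevel=2)
        design = sm.add_constant(terms[final], has_constant="add")
        ols = sm.OLS(y.to_numpy(), design).fit()
        return FallRiskResults(
            model=self, normalization=record, pca=pca, terms=final,
            params=pd.Series(ols.params, index=design.columns),
            ols_results=ols, seed=seed, votes=votes)


class FallRiskResults:
    """Fitted combined fall-risk model.

    Carries the frozen normalization, PCA loadings, selected quadratic
    terms and coefficients; ``predict`` maps a raw metric vector (or table)
    to predicted ln(MFPT).
    """

    def __init__(self, model: Optional[FallRiskModel],
                 normalization: NormalizationRecord, pca: PCATransform,
                 terms: List[str], params: pd.Series,
                 ols_results=None, seed: Optional[int] = None,
                 votes: Optional[dict] = None,
                 variant: Optional[str] = None):
        self.model = model
        self.normalization = normalization
        self.pca = pca
        self.terms = list(terms)
        self.params = pd.Series(params, dtype=float)
        self.ols_results = ols_results
        self.seed = seed
        self.votes = votes or {}
        self.variant = variant or (model.variant if model else "no_lyap")

    # -- diagnostics --------------------------------------------------------

    @property
    def rsquared_adj(self) -> Optional[float]:
        return float(self.ols_results.rsquared_adj) if self.ols_results \
            is not None else None

    @property
    def bse(self) -> Optional[pd.Series]:
        if self.ols_results is None:
            return None
        return pd.Series(self.ols_results.bse, index=self.params.index)

    @property
    def fittedvalues(self) -> Optional[np.ndarray]:
        return None if self.ols_results is None \
            else np.asarray(self.ols_results.fittedvalues)

    # -- prediction ---------------------------------------------------------

    def _required_metrics(self) -> List[str]:
        return variant_metrics(self.variant)

    def predict(self, metrics) -> Union[float, pd.Series]:
        """Predicted ln(MFPT) for a metric vector, Series or table."""
        single = False
        if isinstance(metrics, MetricVector):
            metrics = metrics.values.to_frame().T
            single = True
        elif isinstance(metrics, pd.Series):
            metrics = metrics.to_frame().T
            single = True
        elif not isinstance(metrics, pd.DataFrame):
            metrics = metric_table(list(metrics))
        req = self._required_metrics()
        for c in req:
            if c not in metrics.columns or metrics[c].isna().any():
                raise ValueError(
                    f"prediction requires metric {c!r} (variant "
                    f"{self.variant!r})")
        Z = apply_normalization(self.normalization, metrics)
        scores = apply_pca(self.pca, Z)
        terms = _score_terms(scores)
        yhat = pd.Series(np.full(len(metrics), self.params.get("const", 0.0)),
                         index=metrics.index)
        for t in self.terms:
            yhat += self.params[t] * terms[t]
        return float(yhat.iloc[0]) if single else yhat

    def predict_mfpt(self, metrics):
        """Predicted MFPT in steps (exp of the log-scale prediction)."""
        out = self.predict(metrics)
        return np.exp(out) if not isinstance(out, pd.Series) else np.exp(out)

    def evaluate(self, metrics, y, groups=None,
                 tolerance: float = DEFAULT_TOLERANCE) -> GoodnessOfFit:
        """Goodness of fit of this model on a labelled metric table."""
        yhat = self.predict(metrics)
        yhat = np.asarray(yhat, dtype=float).ravel()
        return goodness_of_fit(yhat, np.asarray(y, dtype=float),
                               groups=groups, tolerance=tolerance,
                               r2_adj=self.rsquared_adj)

    # -- reporting ----------------------------------------------------------

    def summary(self) -> str:
        lines = [
            "Combined quadratic fall-risk model",
            f"variant: {self.variant}   seed: {self.seed}",
            f"PCA components available: {self.pca.n_components}",
            f"selected terms ({len(self.terms)}): "
            + (", ".join(self.terms) if self.terms else "(intercept only)"),
        ]
        if self.ols_results is not None:
            lines.append(f"adj. R^2 = {self.rsquared_adj:.4f}")
            lines.append(str(self.ols_results.summary()))
        else:
            lines.append("coefficients:")
            lines.append(self.params.to_string())
        return "\n".join(lines)

    def plot_calibration(self, y, yhat=None, ax=None):
        """Scatter of predicted vs true ln(MFPT) with the calibration
        line."""
        import matplotlib.pyplot as plt

        if yhat is None:
            yhat = self.fittedvalues
        y = np.asarray(y, dtype=float)
        yhat = np.asarray(yhat, dtype=float)
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(y, yhat, "o", alpha=0.6, label="conditions")
        a1, a0 = np.polyfit(y, yhat, 1)
        xs = np.linspace(y.min(), y.max(), 2)
        ax.plot(xs, a1 * xs + a0, "-",
                label=f"fit: slope {a1:.2f}, intercept {a0:.2f}")
        ax.plot(xs, xs, "k--", alpha=0.5, label="ideal")
        ax.set_xlabel("true ln(MFPT)")
        ax.set_ylabel("predicted ln(MFPT)")
        ax.legend()
        return ax

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "schema": "gaitrisk.fall_risk_model/1",
            "variant": self.variant,
            "seed": self.seed,
            "terms": self.terms,
            "params": {k: float(v) for k, v in self.params.items()},
            "normalization": {
                "metrics": list(self.normalization.center.index),
                "center": [float(x) for x in self.normalization.center],
                "scale": [float(x) for x in self.normalization.scale],
            },
            "pca": {
                "metrics": list(self.pca.loadings.index),
                "components": list(self.pca.loadings.columns),
                "loadings": self.pca.loadings.to_numpy().tolist(),
                "mean": [float(x) for x in self.pca.mean],
                "explained_variance":
                    [float(x) for x in self.pca.explained_variance],
            },
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, d: dict) -> "FallRiskResults":
        from .exceptions import SchemaError

        if d.get("schema") != "gaitrisk.fall_risk_model/1":
            raise SchemaError(f"unexpected schema {d.get('schema')!r}")
        norm = NormalizationRecord(
            pd.Series(d["normalization"]["center"],
                      index=d["normalization"]["metrics"]),
            pd.Series(d["normalization"]["scale"],
                      index=d["normalization"]["metrics"]))
        pca = PCATransform(
            loadings=pd.DataFrame(np.asarray(d["pca"]["loadings"]),
                                  index=d["pca"]["metrics"],
                                  columns=d["pca"]["components"]),
            mean=pd.Series(d["pca"]["mean"], index=d["pca"]["metrics"]),
            explained_variance=np.asarray(d["pca"]["explained_variance"]))
        return cls(model=None, normalization=norm, pca=pca,
                   terms=list(d["terms"]),
                   params=pd.Series(d["params"]), seed=d.get("seed"),
                   variant=d.get("variant"))

    @classmethod
    def from_json(cls, path) -> "FallRiskResults":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))
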