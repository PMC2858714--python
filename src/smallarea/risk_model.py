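"""Logistic disclosure-risk models on (POP, MaxCombs) observations.

One observation is an (area x quasi-identifier model) pair: the area's
population size ``POP``, the model's ``MaxCombs``, and binary responses
``I05`` / ``I20`` marking estimated population uniqueness above 5% / 20%.
The risk model is a logit with an interaction term,

    logit pi = b0 + b1*POP_cs + b2*MaxCombs_cs + b3*POP_cs*MaxCombs_cs,

where both predictors are centered (to avoid collinearity with the
interaction) and scaled by 10,000 (to avoid overflow in the interaction).
An area is flagged high risk when pi exceeds 0.5.

High-uniqueness observations are rare, so two unbalanced-data corrections
are provided: down-sampling the majority class with an analytic prior
correction of the intercept, and the King-Zeng finite-sample bias
correction on the full data.  Published coefficient sets for the 5% and
20% thresholds fitted on 2001 Canadian census data are shipped as
ready-to-use decision rules; their original centering constants are not
recoverable, so a user-supplied scaler is required before prediction.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import ConfigurationError, FittingError, ParameterError
from scipy.special import expit

__all__ = [
    "RiskObservation",
    "CenteredScaler",
    "LogitRiskModel",
    "PUBLISHED_COEFFICIENTS",
    "published_model",
    "center_scale",
    "predict_probability",
    "flag_small_area",
    "prior_correction",
    "fit_downsampled",
    "fit_kz",
    "kz_bias",
    "remove_influential",
    "save_model",
    "load_model",
]

#: Published down-sampling coefficients (intercept, POP, MaxCombs, interaction)
#: for the 5% and 20% uniqueness thresholds.
PUBLISHED_COEFFICIENTS = {
    "5%": (779.1, -37.35, 137.8, -6.5),
    "20%": (63.3, -6.0, 11.8, -1.0),
}


@dataclass(frozen=True)
class RiskObservation:
    """One (area x qid-model) row: population size and MaxCombs plus flags."""

    pop: int
    max_combs: int
    I05: int = 0
    I20: int = 0

    def __post_init__(self) -> None:
        if self.pop < 1:
            raise ParameterError(f"pop must be >= 1, got {self.pop}")
        if self.max_combs < 2:
            raise ParameterError(f"max_combs must be >= 2, got {self.max_combs}")
        if self.I20 and not self.I05:
            raise ParameterError("I20 = 1 requires I05 = 1")


@dataclass(frozen=True)
class CenteredScaler:
    """Centering constants and common scale for the two predictors."""

    pop_center: float
    maxcombs_center: float
    scale: float = 10_000.0

    def __post_init__(self) -> None:
        if not (self.scale > 0):
            raise ParameterError(f"scale must be > 0, got {self.scale}")

    def transform(self, pop, max_combs):
        pop_cs = (np.asarray(pop, dtype=float) - self.pop_center) / self.scale
        mc_cs = (np.asarray(max_combs, dtype=float) - self.maxcombs_center) / self.scale
        return pop_cs, mc_cs


def center_scale(pop, max_combs, scaler: CenteredScaler):
    """Centered/scaled predictor pair ``((x - center) / scale)``."""
    return scaler.transform(pop, max_combs)


@dataclass
class LogitRiskModel:
    """A fitted or published threshold model.

    ``b0..b3`` are intercept, POP, MaxCombs and interaction coefficients on
    the centered/scaled predictors.  ``conf_int`` holds per-coefficient 95%
    confidence intervals (rows b0..b3) when the model was fitted in-package.
    """

    threshold_label: str
    b0: float
    b1: float
    b2: float
    b3: float
    scaler: CenteredScaler | None
    provenance: str = "fitted"
    seed: int | None = None
    warning: str | None = None
    conf_int: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.threshold_label not in ("5%", "20%"):
            raise ParameterError(
                f"threshold_label must be '5%' or '20%', got {self.threshold_label!r}"
            )
        for name in ("b0", "b1", "b2", "b3"):
            if not math.isfinite(getattr(self, name)):
                raise ParameterError(f"coefficient {name} is not finite")

    @property
    def coefficients(self) -> tuple[float, float, float, float]:
        return (self.b0, self.b1, self.b2, self.b3)

    def _require_scaler(self) -> CenteredScaler:
        if self.scaler is None:
            raise ConfigurationError(
                f"the {self.provenance} {self.threshold_label} model has no centering "
                "constants: the original study's centers are not published. Supply a "
                "CenteredScaler (pop_center, maxcombs_center, scale=10000) computed "
                "from your own data before predicting."
            )
        return self.scaler

    def logit(self, pop, max_combs) -> np.ndarray:
        pop_cs, mc_cs = self._require_scaler().transform(pop, max_combs)
        return self.b0 + self.b1 * pop_cs + self.b2 * mc_cs + self.b3 * pop_cs * mc_cs

    def predict_probability(self, pop, max_combs) -> np.ndarray:
        """pi = logistic(logit); numerically stable for very large |logit|."""
        return expit(self.logit(pop, max_combs))


def published_model(
    threshold_label: str, scaler: CenteredScaler | None = None
) -> LogitRiskModel:
    """The published down-sampling model for a threshold.

    Without ``scaler`` the model is constructed but refuses to predict: the
    centering constants used in the original fit were never published and are
    not fabricated here.
    """
    if threshold_label not in PUBLISHED_COEFFICIENTS:
        raise ParameterError(f"no published model for threshold {threshold_label!r}")
    if scaler is None:
        warnings.warn(
            f"published {threshold_label} model created without centering constants; "
            "prediction will fail until a CenteredScaler is attached",
            UserWarning,
            stacklevel=2,
        )
    b0, b1, b2, b3 = PUBLISHED_COEFFICIENTS[threshold_label]
    return LogitRiskModel(
        threshold_label=threshold_label,
        b0=b0, b1=b1, b2=b2, b3=b3,
        scaler=scaler,
        provenance="published",
    )


def predict_probability(model: LogitRiskModel, pop, max_combs) -> np.ndarray:
    return model.predict_probability(pop, max_combs)


def flag_small_area(model: LogitRiskModel, pop, max_combs, cutoff: float = 0.5):
    """True iff predicted probability strictly exceeds ``cutoff`` (default 0.5)."""
    if not (0.0 < cutoff < 1.0):
        raise ParameterError(f"cutoff must be in (0, 1), got {cutoff}")
    return model.predict_probability(pop, max_combs) > cutoff


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def _as_arrays(data, response: str):
    """Accept a DataFrame (pop/max_combs/I05/I20 columns) or RiskObservations."""
    if isinstance(data, pd.DataFrame):
        pop = data["pop"].to_numpy(dtype=float)
        mc = data["max_combs"].to_numpy(dtype=float)
        y = data[response].to_numpy(dtype=float)
    else:
        obs = list(data)
        pop = np.array([o.pop for o in obs], dtype=float)
        mc = np.array([o.max_combs for o in obs], dtype=float)
        y = np.array([getattr(o, response) for o in obs], dtype=float)
    if response not in ("I05", "I20"):
        raise ParameterError(f"response must be 'I05' or 'I20', got {response!r}")
    return pop, mc, y


def _design(pop, mc, scaler: CenteredScaler) -> np.ndarray:
    pop_cs, mc_cs = scaler.transform(pop, mc)
    return np.column_stack([np.ones_like(pop_cs), pop_cs, mc_cs, pop_cs * mc_cs])


_LABEL_FOR_RESPONSE = {"I05": "5%", "I20": "20%"}


def prior_correction(tau: float, ybar: float) -> float:
    """Intercept offset induced by re-balancing: ln[((1-tau)/tau)(ybar/(1-ybar))].

    ``tau`` is the response prevalence in the full data and ``ybar`` the
    prevalence in the balanced sample; subtracting this from the balanced
    fit's intercept restores predictions on the original prevalence scale.
    Zero when the data were already balanced (tau == ybar).
    """
    if not (0.0 < tau < 1.0 and 0.0 < ybar < 1.0):
        raise ParameterError("prevalences must lie strictly between 0 and 1")
    return math.log(((1.0 - tau) / tau) * (ybar / (1.0 - ybar)))


def _ml_fit(X: np.ndarray, y: np.ndarray):
    """Maximum-likelihood logit; returns (params, conf_int, warning-or-None).

    (Quasi-)separated data drive the MLE towards infinity and make the
    Newton Hessian singular; in that case the fit falls back to BFGS and the
    result carries a warning status instead of failing, since saturated
    probabilities still order and flag observations correctly.
    """
    warning = None
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        model = sm.Logit(y, X)
        try:
            res = model.fit(disp=0, maxiter=200)
        except Exception:
            try:
                res = model.fit(method="bfgs", disp=0, maxiter=500, gtol=1e-6)
                warning = "possible separation: Newton failed, BFGS fallback used"
            except Exception as exc:
                raise FittingError(f"logit fit failed: {exc}") from exc
    for w in caught:
        msg = str(w.message).lower()
        if "separat" in msg or "converge" in msg:
            warning = warning or str(w.message)
            break
    params = np.asarray(res.params)
    try:
        ci = np.asarray(res.conf_int())
        if not np.isfinite(ci).all():
            warning = warning or "non-finite confidence intervals (possible separation)"
    except Exception:
        ci = np.full((len(params), 2), np.nan)
        warning = warning or "singular covariance (possible separation)"
    return params, ci, warning


def fit_downsampled(
    data,
    response: str,
    seed: int,
    *,
    scaler: CenteredScaler | None = None,
) -> LogitRiskModel:
    """Down-sampling fit with analytic prior correction of the intercept.

    All minority-class rows are kept and an equal-size simple random
    subsample of the majority class is drawn without replacement.  After the
    maximum-likelihood fit on the balanced data, the intercept is corrected
    for the induced prevalence shift by subtracting

        ln[ ((1 - tau) / tau) * (ybar / (1 - ybar)) ],

    where ``tau`` is the full-data prevalence of the response and ``ybar``
    the balanced-sample prevalence.  Slopes are unaffected.  The scaler is
    computed from the *full* training data (unless supplied) and stored with
    the model.
    """
    pop, mc, y = _as_arrays(data, response)
    n1 = int(y.sum())
    n0 = int(len(y) - n1)
    if n1 == 0 or n0 == 0:
        raise FittingError(f"both classes must be present (n1={n1}, n0={n0})")
    if scaler is None:
        scaler = CenteredScaler(float(pop.mean()), float(mc.mean()))

    tau = y.mean()
    rng = np.random.default_rng(seed)
    minority = 1 if n1 <= n0 else 0
    keep_min = np.flatnonzero(y == minority)
    maj_idx = np.flatnonzero(y != minority)
    keep_maj = rng.choice(maj_idx, size=len(keep_min), replace=False)
    idx = np.concatenate([keep_min, keep_maj])

    X = _design(pop[idx], mc[idx], scaler)
    yb = y[idx]
    params, ci, warning = _ml_fit(X, yb)

    ybar = yb.mean()
    correction = prior_correction(tau, ybar)
    params = params.copy()
    params[0] -= correction
    ci = ci.copy()
    ci[0, :] -= correction

    return LogitRiskModel(
        threshold_label=_LABEL_FOR_RESPONSE[response],
        b0=float(params[0]), b1=float(params[1]),
        b2=float(params[2]), b3=float(params[3]),
        scaler=scaler,
        provenance="fitted",
        seed=int(seed),
        warning=warning,
        conf_int=ci,
    )


def kz_bias(X: np.ndarray, params: np.ndarray) -> np.ndarray:
    """King-Zeng small-sample bias term of a fitted logit.

    With ``W = diag(pi_i (1 - pi_i))``, ``Q = X (X'WX)^{-1} X'`` and
    ``xi_i = 0.5 * Q_ii * (2 pi_i - 1)``, the bias is
    ``(X'WX)^{-1} X'W xi``; the corrected estimate is ``params - bias``.
    """
    pi = expit(X @ params)
    w = pi * (1.0 - pi)
    A = X.T @ (X * w[:, None])
    try:
        A_inv = np.linalg.inv(A)
    except np.linalg.LinAlgError as exc:
        raise FittingError(f"singular information matrix: {exc}") from exc
    Q_ii = np.einsum("ij,jk,ik->i", X, A_inv, X)
    xi = 0.5 * Q_ii * (2.0 * pi - 1.0)
    return A_inv @ (X.T @ (w * xi))


def fit_kz(
    data,
    response: str,
    *,
    scaler: CenteredScaler | None = None,
) -> LogitRiskModel:
    """Full-data maximum-likelihood fit with the King-Zeng bias correction.

    Unlike down-sampling this uses every observation; the correction removes
    the finite-sample bias that is most severe when positives are rare.
    """
    pop, mc, y = _as_arrays(data, response)
    if y.sum() == 0 or y.sum() == len(y):
        raise FittingError("both classes must be present")
    if scaler is None:
        scaler = CenteredScaler(float(pop.mean()), float(mc.mean()))
    X = _design(pop, mc, scaler)
    params, ci, warning = _ml_fit(X, y)
    bias = kz_bias(X, params)
    params = params - bias
    ci = ci - bias[:, None]
    return LogitRiskModel(
        threshold_label=_LABEL_FOR_RESPONSE[response],
        b0=float(params[0]), b1=float(params[1]),
        b2=float(params[2]), b3=float(params[3]),
        scaler=scaler,
        provenance="fitted",
        warning=warning,
        conf_int=ci,
    )


def remove_influential(
    data,
    response: str,
    *,
    cutoff: float | None = None,
    scaler: CenteredScaler | None = None,
):
    """Single-pass influential-observation removal via dfbetas.

    Fits a preliminary maximum-likelihood logit, computes the standardized
    leave-one-out coefficient changes (dfbetas) and drops every row whose
    largest absolute dfbeta exceeds ``cutoff`` (default ``2 / sqrt(n)``).

    Returns ``(kept_mask, removed_fraction)``.  Aborts if removal would
    empty a response class.
    """
    pop, mc, y = _as_arrays(data, response)
    n = len(y)
    if y.sum() == 0 or y.sum() == n:
        raise FittingError("both classes must be present")
    if scaler is None:
        scaler = CenteredScaler(float(pop.mean()), float(mc.mean()))
    if cutoff is None:
        cutoff = 2.0 / math.sqrt(n)
    X = _design(pop, mc, scaler)
    if math.isinf(cutoff):
        return np.ones(n, dtype=bool), 0.0
    res = sm.GLM(y, X, family=sm.families.Binomial()).fit()
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        dfbetas = np.abs(res.get_influence(observed=False).dfbetas)
    kept = dfbetas.max(axis=1) <= cutoff
    if y[kept].sum() == 0 or y[kept].sum() == kept.sum():
        raise FittingError(
            "influence-based removal would empty a response class; "
            f"cutoff={cutoff:.4g} removes {int((~kept).sum())}/{n} rows"
        )
    return kept, float((~kept).mean())


# ---------------------------------------------------------------------------
# serialization (structured text model files)
# ---------------------------------------------------------------------------


def save_model(model: LogitRiskModel, path) -> None:
    payload = {
        "threshold_label": model.threshold_label,
        "coefficients": {
            "intercept": model.b0, "pop": model.b1,
            "maxcombs": model.b2, "interaction": model.b3,
        },
        "scaler": None if model.scaler is None else asdict(model.scaler),
        "provenance": model.provenance,
        "seed": model.seed,
        "warning": model.warning,
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")


def load_model(path) -> LogitRiskModel:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    coef = payload["coefficients"]
    scaler = payload.get("scaler")
    return LogitRiskModel(
        threshold_label=payload["threshold_label"],
        b0=float(coef["intercept"]), b1=float(coef["pop"]),
        b2=float(coef["maxcombs"]), b3=float(coef["interaction"]),
        scaler=None if scaler is None else CenteredScaler(**scaler),
        provenance=payload.get("provenance", "fitted"),
        seed=payload.get("seed"),
        warning=payload.get("warning"),
    )
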