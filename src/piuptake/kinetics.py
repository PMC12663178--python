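"""First-order propidium-iodide uptake kinetics.

After a cavitation event compromises the membrane, the fluorescence of a
single cell rises as a saturating exponential

    I(t) = I_final * (1 - exp(-k * t)),

where ``I_final`` (AU) is the plateau intensity reached at the end of the
observation window and ``k`` (1/s) is the first-order uptake rate constant.
The initial uptake rate is the model derivative at the moment of collapse,
dI/dt|_{t=0} = k * I_final, so across a cohort the initial rate is linear in
the plateau with slope ``k``.  Across space the plateau follows an
inverse-distance law

    I_final(gamma) = a + b / gamma,

with ``gamma`` the distance from the cavitation center normalised by the
maximum bubble radius.

The two regressions are exposed as scikit-learn estimators
(:class:`SaturationCurve`, :class:`RadialIntensityLaw`); cohort-level helpers
(:func:`fit_traces`, :func:`population_k_stats`, :func:`initial_rate_vs_final`)
operate on trace tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "SaturationCurve",
    "RadialIntensityLaw",
    "GoodnessOfFit",
    "PopulationKStats",
    "InitialRateFit",
    "goodness",
    "fit_traces",
    "population_k_stats",
    "initial_rate_vs_final",
]

logger = logging.getLogger(__name__)


def _as_time_vector(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 2 and X.shape[1] == 1:
        X = X[:, 0]
    if X.ndim != 1:
        raise ValueError(f"expected a 1-d time axis, got shape {X.shape}")
    return X


@dataclass
class GoodnessOfFit:
    """R^2 = 1 - SS_res/SS_tot, RMSE = sqrt(mean squared residual)."""

    r_squared: float
    rmse: float
    residuals: np.ndarray = field(repr=False)


def goodness(observed, predicted) -> GoodnessOfFit:
    """Fit diagnostics for a model prediction.

    ``r_squared`` is NaN (flagged, not raised) when the observed values have
    zero variance, in which case SS_tot = 0 and the ratio is undefined.
    """
    y = np.asarray(observed, dtype=float)
    Y = np.asarray(predicted, dtype=float)
    if y.shape != Y.shape or y.ndim != 1:
        raise ValueError("observed and predicted must be 1-d of equal length")
    if y.size < 2:
        raise ValueError("need at least two points")
    residuals = y - Y
    ss_res = float(np.sum(residuals**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = np.nan if ss_tot == 0.0 else 1.0 - ss_res / ss_tot
    rmse = float(np.sqrt(np.mean(residuals**2)))
    return GoodnessOfFit(r_squared=r2, rmse=rmse, residuals=residuals)


class SaturationCurve(RegressorMixin, BaseEstimator):
    """Nonlinear least-squares fit of I(t) = I_final (1 - exp(-k t)).

    Parameters
    ----------
    initial_rate_guess : float, default 0.01
        Starting value for ``k`` (1/s).  The starting value for ``I_final``
        is the maximum of the trace.
    max_nfev : int or None
        Cap on function evaluations passed to :func:`scipy.optimize.curve_fit`.

    Attributes
    ----------
    I_final_ : float
        Fitted plateau intensity (AU), constrained nonnegative.
    k_ : float
        Fitted uptake rate constant (1/s), constrained positive.
    r_squared_, rmse_, residuals_ : fit diagnostics.
    converged_ : bool
        False when the optimiser failed or returned a degenerate solution
        (all-zero trace, nonfinite covariance); such fits are excluded from
        population summaries.
    """

    def __init__(self, initial_rate_guess: float = 0.01, max_nfev: int | None = None):
        self.initial_rate_guess = initial_rate_guess
        self.max_nfev = max_nfev

    @staticmethod
    def _model(t, i_final, k):
        return i_final * (1.0 - np.exp(-k * t))

    @staticmethod
    def _jacobian(t, i_final, k):
        decay = np.exp(-k * t)
        return np.stack([1.0 - decay, i_final * t * decay], axis=1)

    def fit(self, X, y):
        t = _as_time_vector(X)
        y = np.asarray(y, dtype=float)
        if y.shape != t.shape:
            raise ValueError("time axis and trace must have equal length")
        if t.size < 3:
            raise ValueError("need at least 3 frames to fit two parameters")
        if np.any(t < 0):
            raise ValueError("time axis must be measured from the cavitation event (t >= 0)")

        self.n_features_in_ = 1
        self.converged_ = True
        peak = float(np.max(y))
        if peak <= 0.0:
            # an unstained cell carries no kinetic information
            self.I_final_, self.k_ = np.nan, np.nan
            self.converged_ = False
        else:
            try:
                popt, pcov = curve_fit(
                    self._model,
                    t,
                    y,
                    p0=(peak, self.initial_rate_guess),
                    jac=self._jacobian,
                    bounds=([0.0, 1e-12], [np.inf, np.inf]),
                    max_nfev=self.max_nfev,
                )
                self.I_final_, self.k_ = float(popt[0]), float(popt[1])
                self.covariance_ = pcov
                if not np.all(np.isfinite(popt)):
                    self.converged_ = False
            except RuntimeError:
                self.I_final_, self.k_ = np.nan, np.nan
                self.converged_ = False

        if self.converged_:
            gof = goodness(y, self._model(t, self.I_final_, self.k_))
            self.r_squared_ = gof.r_squared
            self.rmse_ = gof.rmse
            self.residuals_ = gof.residuals
        else:
            self.r_squared_ = np.nan
            self.rmse_ = np.nan
            self.residuals_ = np.full_like(y, np.nan)
        return self

    def predict(self, X):
        check_is_fitted(self, "I_final_")
        t = _as_time_vector(X)
        return self._model(t, self.I_final_, self.k_)

    def initial_rate(self) -> float:
        """Analytic model derivative at t = 0: k * I_final (AU/s)."""
        check_is_fitted(self, "I_final_")
        return self.k_ * self.I_final_


class RadialIntensityLaw(RegressorMixin, BaseEstimator):
    """Least-squares fit of the inverse-distance plateau law a + b/gamma.

    The model is linear in 1/gamma, so the fit is solved in closed form
    (ordinary least squares on the design matrix [1, 1/gamma]).

    Attributes
    ----------
    intercept_ : float
        ``a`` (AU), the far-field plateau intensity.
    coef_ : float
        ``b`` (AU), the inverse-distance coefficient.
    r_squared_, rmse_ : fit diagnostics.
    """

    def fit(self, X, y):
        gamma = _as_time_vector(X)
        y = np.asarray(y, dtype=float)
        if y.shape != gamma.shape:
            raise ValueError("gamma and intensity must have equal length")
        if gamma.size < 2:
            raise ValueError("need at least 2 cells")
        if np.any(gamma <= 0):
            raise ValueError("gamma must be positive")
        if np.unique(gamma).size < 2:
            raise ValueError("all gamma equal: the design matrix is rank deficient")

        design = np.column_stack([np.ones_like(gamma), 1.0 / gamma])
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        self.intercept_ = float(coef[0])
        self.coef_ = float(coef[1])
        self.n_features_in_ = 1
        gof = goodness(y, design @ coef)
        self.r_squared_ = gof.r_squared
        self.rmse_ = gof.rmse
        return self

    def predict(self, X):
        check_is_fitted(self, "intercept_")
        gamma = np.asarray(X, dtype=float)
        if gamma.ndim == 2 and gamma.shape[1] == 1:
            gamma = gamma[:, 0]
        if np.any(gamma <= 0):
            raise ValueError("gamma must be positive")
        return self.intercept_ + self.coef_ / gamma

    @classmethod
    def from_coefficients(cls, intercept: float, coef: float) -> "RadialIntensityLaw":
        """A law with known coefficients (e.g. a generator's ground truth)."""
        law = cls()
        law.intercept_ = float(intercept)
        law.coef_ = float(coef)
        law.n_features_in_ = 1
        law.r_squared_ = np.nan
        law.rmse_ = np.nan
        return law


@dataclass
class PopulationKStats:
    """Cohort summary of fitted uptake rate constants."""

    mean_k: float  # 1/s
    sd_k: float  # 1/s
    n_used: int
    n_excluded: int

    @property
    def tau_char(self) -> float:
        """Characteristic saturation time 1/mean_k (s)."""
        return 1.0 / self.mean_k


@dataclass
class InitialRateFit:
    """Zero-intercept regression of initial uptake rate on plateau intensity."""

    slope: float  # 1/s
    r_squared: float
    n_cells: int


def fit_traces(
    intensities: np.ndarray,
    time_s: np.ndarray,
    cell_ids=None,
    gamma=None,
    initial_rate_guess: float = 0.01,
) -> pd.DataFrame:
    """Fit the saturation model to every trace in a cohort.

    Parameters
    ----------
    intensities : (n_cells, n_frames) array of AU values.
    time_s : (n_frames,) time axis in seconds from the cavitation event.
    cell_ids, gamma : optional per-cell metadata copied into the output.

    Returns a table with columns cell_id, gamma, I_final, k, r_squared,
    rmse, converged.  Non-converged fits are logged and retained with
    ``converged=False`` so callers can exclude them explicitly.
    """
    intensities = np.atleast_2d(np.asarray(intensities, dtype=float))
    n_cells = intensities.shape[0]
    if cell_ids is None:
        cell_ids = np.arange(n_cells)
    rows = []
    n_failed = 0
    est = SaturationCurve(initial_rate_guess=initial_rate_guess)
    for i in range(n_cells):
        est.fit(time_s, intensities[i])
        if not est.converged_:
            n_failed += 1
            logger.debug("saturation fit did not converge for cell %s", cell_ids[i])
        rows.append(
            {
                "cell_id": cell_ids[i],
                "gamma": np.nan if gamma is None else float(np.asarray(gamma)[i]),
                "I_final": est.I_final_,
                "k": est.k_,
                "r_squared": est.r_squared_,
                "rmse": est.rmse_,
                "converged": est.converged_,
            }
        )
    if n_failed:
        logger.warning("%d of %d saturation fits did not converge (excluded downstream)",
                       n_failed, n_cells)
    return pd.DataFrame(rows)


def population_k_stats(fits: pd.DataFrame, n_sigma: float = 3.0) -> PopulationKStats:
    """Mean and spread of the uptake constant with single-pass outlier removal.

    Rate constants farther than ``n_sigma`` standard deviations from the
    initial mean are excluded once, then mean and standard deviation are
    recomputed on the retained set.
    """
    k = fits.loc[fits["converged"], "k"].to_numpy(dtype=float)
    if k.size < 2:
        raise ValueError("need at least 2 converged fits")
    m0, s0 = k.mean(), k.std(ddof=1)
    # zero spread: every value is an inlier regardless of rounding noise
    keep = np.abs(k - m0) <= n_sigma * s0 if s0 > 0 else np.ones_like(k, bool)
    if not np.any(keep):
        raise ValueError("outlier exclusion removed every fit")
    kept = k[keep]
    sd = kept.std(ddof=1) if kept.size > 1 else 0.0
    return PopulationKStats(
        mean_k=float(kept.mean()),
        sd_k=float(sd),
        n_used=int(kept.size),
        n_excluded=int(k.size - kept.size),
    )


def initial_rate_vs_final(fits: pd.DataFrame) -> InitialRateFit:
    """Regress the model-derivative initial rate k*I_final on I_final.

    The regression has no intercept (the model forces I(0) = 0), so the
    slope is sum(I_final * rate) / sum(I_final^2) — the I_final^2-weighted
    mean of the per-cell rate constants.  For a cohort sharing a single k
    the slope equals that k exactly.
    """
    sub = fits.loc[fits["converged"]]
    if len(sub) < 1:
        raise ValueError("no converged fits")
    i_final = sub["I_final"].to_numpy(dtype=float)
    rate = sub["k"].to_numpy(dtype=float) * i_final
    denom = float(np.sum(i_final**2))
    if denom == 0.0:
        raise ValueError("all plateau intensities are zero; slope undefined")
    slope = float(np.sum(i_final * rate) / denom)
    predicted = slope * i_final
    if len(sub) > 1:
        r2 = goodness(rate, predicted).r_squared
    else:
        r2 = np.nan
    return InitialRateFit(slope=slope, r_squared=r2, n_cells=int(len(sub)))
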