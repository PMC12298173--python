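"""Linear calibrations: tracer concentration vs L*, feeder and pump lines.

Three straight-line calibrations back the measurement pipeline:

* tracer mass fraction C (wt%) against sample lightness L* — negative
  slope, since dye darkens the granules;
* volumetric-feeder mass flow (g/min) against opening percentage;
* peristaltic-pump liquid flow (g/min) against rotational speed (r/min).

All three share one estimator, :class:`LinearCalibration`, written in the
scikit-learn idiom (``fit``/``predict``, fitted attributes with trailing
underscores) so it drops into sklearn pipelines and model selection.
"""

from __future__ import annotations

import warnings

import numpy as np
import yaml
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "LinearCalibration",
    "fit_linear",
    "predict",
    "lstar_to_concentration",
    "ExtrapolationWarning",
]


class ExtrapolationWarning(UserWarning):
    """Prediction requested outside the fitted predictor domain."""


class LinearCalibration(RegressorMixin, BaseEstimator):
    """Ordinary-least-squares straight line ``y = slope * x + intercept``.

    Attributes
    ----------
    slope_ : float
        Response units per predictor unit.
    intercept_ : float
        Response at zero predictor.
    r_squared_ : float
        Coefficient of determination, ``1 - SS_res / SS_tot``.
    domain_ : tuple of float
        ``(min x, max x)`` of the fitted data; predictions outside it
        raise :class:`ExtrapolationWarning`.
    """

    def fit(self, X, y):
        x = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        if x.size != y.size:
            raise ValueError("x and y lengths differ")
        if x.size < 2 or np.unique(x).size < 2:
            raise ValueError("need at least 2 points with 2 distinct x values")
        A = np.stack([x, np.ones_like(x)], axis=1)
        (slope, intercept), *_ = np.linalg.lstsq(A, y, rcond=None)
        resid = y - (slope * x + intercept)
        ss_res = float(resid @ resid)
        ss_tot = float(((y - y.mean()) ** 2).sum())
        self.slope_ = float(slope)
        self.intercept_ = float(intercept)
        self.r_squared_ = 1.0 if ss_tot == 0.0 else 1.0 - ss_res / ss_tot
        self.domain_ = (float(x.min()), float(x.max()))
        return self

    @classmethod
    def from_coefficients(cls, slope, intercept, r_squared=None, domain=None):
        """Build a fitted calibration from known (e.g. published) coefficients."""
        cal = cls()
        cal.slope_ = float(slope)
        cal.intercept_ = float(intercept)
        cal.r_squared_ = float(r_squared) if r_squared is not None else float("nan")
        cal.domain_ = tuple(domain) if domain is not None else (-np.inf, np.inf)
        return cal

    def predict(self, X):
        check_is_fitted(self, "slope_")
        x = np.asarray(X, dtype=float)
        scalar = x.ndim == 0
        x = x.reshape(-1)
        lo, hi = self.domain_
        if np.any(x < lo) or np.any(x > hi):
            warnings.warn(
                f"predicting outside calibration domain [{lo}, {hi}]",
                ExtrapolationWarning,
                stacklevel=2,
            )
        y = self.slope_ * x + self.intercept_
        if np.any(y < 0):
            warnings.warn("calibration predicts a negative response", UserWarning,
                          stacklevel=2)
        return float(y[0]) if scalar else y

    # -- serialization --------------------------------------------------
    def to_dict(self) -> dict:
        check_is_fitted(self, "slope_")
        return {
            "slope": self.slope_,
            "intercept": self.intercept_,
            "r_squared": self.r_squared_,
            "domain": list(self.domain_),
        }

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh)

    @classmethod
    def from_yaml(cls, path) -> "LinearCalibration":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls.from_coefficients(d["slope"], d["intercept"],
                                     d.get("r_squared"), d.get("domain"))


def fit_linear(points) -> LinearCalibration:
    """Fit a calibration line to an iterable of ``(x, y)`` pairs."""
    pts = np.asarray(list(points), dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be (x, y) pairs")
    return LinearCalibration().fit(pts[:, 0], pts[:, 1])


def predict(cal: LinearCalibration, x):
    """Evaluate a calibration line at ``x`` (warns on extrapolation)."""
    return cal.predict(x)


def lstar_to_concentration(cal: LinearCalibration, l_star):
    """Tracer mass fraction (wt%) from lightness via a concentration line.

    Requires a negative slope (darkness increases with concentration);
    negative predictions are clipped to zero.
    """
    check_is_fitted(cal, "slope_")
    if cal.slope_ >= 0:
        raise ValueError(
            "concentration calibration must have a negative slope in L*"
        )
    l_star = np.asarray(l_star, dtype=float)
    scalar = l_star.ndim == 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        c = cal.slope_ * l_star + cal.intercept_
    c = np.clip(c, 0.0, None)
    return float(c) if scalar else c
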