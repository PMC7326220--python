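"""Speed/accuracy performance models for PSSM-based secondary structure
prediction, with evaluation and refitting.

Two families of empirical models relate the PSSM target dataset to predictor
performance:

**Size-dependent models** (dataset sampled at a fixed ~90% identity level,
n_t = number of proteins in the target dataset):

    TC(n_t) = slope * n_t + intercept                       (seconds)
    Q3(n_t) = A / (1 + exp((M - log2 n_t) / s))**g + B      (fraction)
    Q8(n_t) = A / (1 + exp((M - log2 n_t) / s)) + B         (fraction)

Time cost is linear in dataset size (PSI-BLAST search dominates and is
O(n_t)); accuracy follows a sigmoid in log2 dataset size with baseline B,
amplitude A, midpoint M, scale s and, for Q3, an asymmetry exponent g.

**Homology-dependent models** (dataset built at identity cutoff c_t percent,
size changing passively):

    TC_h(n_t) = a2*n_t^2 + a1*n_t + a0                      (seconds)
    Q3_h(c_t), Q8_h(c_t) = cubic polynomials in c_t         (fraction)

The default coefficients reproduce published benchmark fits for a 115-protein
query set on a specific hardware/software setup; absolute times do not
transfer to other machines (the trends do), which is flagged in the model
metadata.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "SizePerformanceModel",
    "HomologyPerformanceModel",
    "FitResult",
    "eval_size_model",
    "eval_homology_model",
    "fit_size_models",
    "fit_homology_models",
    "ExtrapolationWarning",
]


class ExtrapolationWarning(UserWarning):
    """Model evaluated outside the range its coefficients were fitted on."""


@dataclass(frozen=True)
class SigmoidParams:
    """Generalized-logistic accuracy curve over log2 dataset size."""

    amplitude: float
    midpoint: float
    scale: float
    baseline: float
    asymmetry: float = 1.0

    def __call__(self, n_t) -> np.ndarray | float:
        log_n = np.log2(n_t)
        core = 1.0 + np.exp((self.midpoint - log_n) / self.scale)
        return self.amplitude / core ** self.asymmetry + self.baseline


@dataclass(frozen=True)
class SizePerformanceModel:
    """Time-cost and accuracy as functions of target dataset size n_t.

    Defaults are the published fits for a standard UniRef90-style target
    dataset; ``tc_slope`` is seconds per protein in the dataset and
    ``tc_intercept`` seconds of fixed overhead.
    """

    tc_slope: float = 2.8658e-5
    tc_intercept: float = 5.8248
    q3: SigmoidParams = field(default_factory=lambda: SigmoidParams(
        amplitude=0.1363, midpoint=17.0963, scale=2.1447,
        baseline=0.6716, asymmetry=0.6205))
    q8: SigmoidParams = field(default_factory=lambda: SigmoidParams(
        amplitude=0.1281, midpoint=15.6095, scale=2.5405,
        baseline=0.5621, asymmetry=1.0))
    hardware_note: str = (
        "time-cost constants are specific to the benchmark machine "
        "(3.33 GHz CPU, single search thread); only the trend transfers"
    )

    def time_cost(self, n_t) -> np.ndarray | float:
        return self.tc_slope * np.asarray(n_t, dtype=float) + self.tc_intercept

    def q3_accuracy(self, n_t) -> np.ndarray | float:
        return self.q3(n_t)

    def q8_accuracy(self, n_t) -> np.ndarray | float:
        return self.q8(n_t)


#: Alternative linear time-cost coefficient sets fitted on the CASP12/CASP13
#: query sets (same functional form as the default model).
CASP12_TC = (2.8980e-5, 6.4610)
CASP13_TC = (3.2020e-5, 5.5190)


@dataclass(frozen=True)
class HomologyPerformanceModel:
    """Time-cost and accuracy of homology-reduced target datasets.

    ``tc_coeffs`` is a quadratic in the dataset size n_t (highest degree
    first); ``q3_coeffs`` and ``q8_coeffs`` are cubics in the identity
    cutoff c_t (percent).
    """

    tc_coeffs: tuple[float, ...] = (-4.0386e-14, 3.2338e-05, -73.9573)
    q3_coeffs: tuple[float, ...] = (-1.0552e-7, 1.4931e-5, -0.0006, 0.8152)
    q8_coeffs: tuple[float, ...] = (-9.3552e-8, 1.5515e-5, -0.0008, 0.7000)

    def time_cost(self, n_t) -> np.ndarray | float:
        if np.any(np.asarray(n_t) < 1):
            warnings.warn("TC_h evaluated at n_t < 1 (extrapolation)",
                          ExtrapolationWarning, stacklevel=2)
        return np.polyval(self.tc_coeffs, np.asarray(n_t, dtype=float))

    def q3_accuracy(self, c_t) -> np.ndarray | float:
        self._check_cutoff(c_t)
        return np.polyval(self.q3_coeffs, np.asarray(c_t, dtype=float))

    def q8_accuracy(self, c_t) -> np.ndarray | float:
        self._check_cutoff(c_t)
        return np.polyval(self.q8_coeffs, np.asarray(c_t, dtype=float))

    @staticmethod
    def _check_cutoff(c_t) -> None:
        c = np.asarray(c_t)
        if np.any(c < 20) or np.any(c > 100):
            warnings.warn(
                "identity cutoff outside the fitted range [20, 100] "
                "(extrapolation)", ExtrapolationWarning, stacklevel=3)


def eval_size_model(
    model: SizePerformanceModel,
    quantity: Literal["TC", "Q3", "Q8"],
    n_t,
) -> float:
    """Evaluate a size-dependent model at dataset size n_t (proteins)."""
    if np.any(np.asarray(n_t) < 1):
        raise ValueError("dataset size n_t must be >= 1")
    fn = {"TC": model.time_cost, "Q3": model.q3_accuracy,
          "Q8": model.q8_accuracy}.get(quantity)
    if fn is None:
        raise ValueError(f"unknown quantity: {quantity!r}")
    return float(fn(n_t))


def eval_homology_model(
    model: HomologyPerformanceModel,
    quantity: Literal["TC_h", "Q3_h", "Q8_h"],
    x,
) -> float:
    """Evaluate a homology-series model: TC_h at n_t, Q3_h/Q8_h at c_t."""
    fn = {"TC_h": model.time_cost, "Q3_h": model.q3_accuracy,
          "Q8_h": model.q8_accuracy}.get(quantity)
    if fn is None:
        raise ValueError(f"unknown quantity: {quantity!r}")
    return float(fn(x))


@dataclass
class FitResult:
    """Parameters and residuals of a least-squares model fit."""

    params: dict[str, float]
    rss: float
    residuals: np.ndarray

    def __post_init__(self) -> None:
        self.residuals = np.asarray(self.residuals, dtype=float)


def _linear_fit(x: np.ndarray, y: np.ndarray) -> FitResult:
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    return FitResult({"slope": float(slope), "intercept": float(intercept)},
                     float(np.sum(resid ** 2)), resid)


def _sigmoid_fit(
    n: np.ndarray, q: np.ndarray, *, asymmetric: bool
) -> FitResult:
    """Fit the generalized-logistic accuracy curve over log2 dataset size.

    Initialization: baseline = min(q), amplitude = max(q) - min(q),
    midpoint = log2 size nearest the half-rise, scale = 2, asymmetry = 1;
    bounded trust-region least squares with tolerance 1e-10 — deterministic
    given the points.
    """
    log_n = np.log2(n)
    q_min, q_max = float(q.min()), float(q.max())
    half = (q_min + q_max) / 2
    mid0 = float(log_n[np.argmin(np.abs(q - half))])

    if asymmetric:
        def f(ln, A, M, s, B, g):
            return A / (1 + np.exp((M - ln) / s)) ** g + B
        p0 = [q_max - q_min, mid0, 2.0, q_min, 1.0]
        lower = [1e-6, log_n.min() - 10, 1e-3, 0.0, 1e-3]
        upper = [1.0, log_n.max() + 10, 50.0, 1.0, 20.0]
        names = ["amplitude", "midpoint", "scale", "baseline", "asymmetry"]
    else:
        def f(ln, A, M, s, B):
            return A / (1 + np.exp((M - ln) / s)) + B
        p0 = [q_max - q_min, mid0, 2.0, q_min]
        lower = [1e-6, log_n.min() - 10, 1e-3, 0.0]
        upper = [1.0, log_n.max() + 10, 50.0, 1.0]
        names = ["amplitude", "midpoint", "scale", "baseline"]

    popt, _ = curve_fit(
        f, log_n, q, p0=p0, bounds=(lower, upper),
        ftol=1e-10, xtol=1e-10, gtol=1e-10, maxfev=100_000,
    )
    resid = q - f(log_n, *popt)
    return FitResult(dict(zip(names, map(float, popt))),
                     float(np.sum(resid ** 2)), resid)


def fit_size_models(
    points: Sequence[tuple[float, float]],
    form: Literal["tc-linear", "q3-sigmoid", "q8-sigmoid"],
) -> FitResult:
    """Refit a size-dependent model form to (n_t, y) points.

    ``tc-linear`` needs >= 2 points; the sigmoid forms need >= 5 (asymmetric
    Q3) or >= 4 (Q8) points spanning enough of the rise to constrain the
    midpoint.  Fitting is deterministic given the points.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be (x, y) pairs")
    x, y = pts[:, 0], pts[:, 1]
    if form == "tc-linear":
        if len(pts) < 2:
            raise ValueError("linear fit needs at least 2 points")
        return _linear_fit(x, y)
    if form == "q3-sigmoid":
        if len(pts) < 5:
            raise ValueError("asymmetric sigmoid fit needs at least 5 points")
        return _sigmoid_fit(x, y, asymmetric=True)
    if form == "q8-sigmoid":
        if len(pts) < 4:
            raise ValueError("sigmoid fit needs at least 4 points")
        return _sigmoid_fit(x, y, asymmetric=False)
    raise ValueError(f"unknown form: {form!r}")


def fit_homology_models(
    points: Sequence[tuple[float, float]],
    form: Literal["tc-quadratic", "q-cubic"],
) -> FitResult:
    """Refit a homology-series polynomial to (x, y) points.

    ``tc-quadratic`` (x = n_t) needs >= 3 points; ``q-cubic`` (x = c_t)
    needs >= 4.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be (x, y) pairs")
    degree = {"tc-quadratic": 2, "q-cubic": 3}.get(form)
    if degree is None:
        raise ValueError(f"unknown form: {form!r}")
    if len(pts) < degree + 1:
        raise ValueError(f"{form} fit needs at least {degree + 1} points")
    x, y = pts[:, 0], pts[:, 1]
    coeffs = np.polyfit(x, y, degree)
    resid = y - np.polyval(coeffs, x)
    names = [f"c{degree - i}" for i in range(degree + 1)]
    return FitResult(dict(zip(names, map(float, coeffs))),
                     float(np.sum(resid ** 2)), resid)
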