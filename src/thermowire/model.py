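"""Semi-empirical model of RF-induced heating near an implanted wire.

The heat source at the wire tip is approximated by a spatially Gaussian
deposition at constant power P0 applied between t0 and t1.  The resulting
temperature rise at the hottest point is piecewise logarithmic:

    T(t) = 0                                   for t <= t0
    T(t) = a*P0*tau*ln((t - t0 + tau)/tau)     for t0 <= t <= t1
    T(t) = a*P0*tau*ln((t - t0 + tau)/(t - t1 + tau))   for t >= t1

where ``a`` (alpha) is an absorption coefficient in °C·W⁻¹·s⁻¹ and ``tau``
a time constant in seconds.  Fitting (alpha, tau) to heating curves
acquired at several calibration powers, then describing alpha(P) and
tau(P) with second-order polynomials, yields a predictor of the maximal
temperature rise of *any* sequence from its effective emitted power
(total energy / duration) and its duration.

The module also provides the simple calibration-curve fits of the maximal
temperature rise against flip angle (quadratic), B1+rms (quadratic) and
emitted energy (linear) — the naive energy estimator is shown to be
inadequate for wires, which is the point of the piecewise-log model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "HeatingWindow",
    "EqOneParams",
    "CalibrationPoint",
    "CalibrationSet",
    "SequenceSpec",
    "BetaFitResult",
    "IsothermGrid",
    "PredictionResult",
    "FitFailureError",
    "OutOfDomainError",
    "LogHeatSource",
    "WireHeatingCalibration",
    "PowerLawRegressor",
    "eq1_eval",
    "eq1_peak",
    "fit_eq1",
    "fit_power_polynomials",
    "predict_for_sequence",
    "isotherm_grid",
    "fit_beta",
    "energy_estimate",
]


class FitFailureError(RuntimeError):
    """Nonlinear fit failed to converge after restarts."""


class OutOfDomainError(ValueError):
    """Calibration polynomials give nonphysical parameters at this power."""


@dataclass(frozen=True)
class HeatingWindow:
    """Energy-deposition interval (seconds)."""

    t0: float
    t1: float

    def __post_init__(self) -> None:
        if not self.t1 > self.t0:
            raise ValueError(f"t1 ({self.t1}) must exceed t0 ({self.t0})")

    @property
    def duration(self) -> float:
        return self.t1 - self.t0


@dataclass
class EqOneParams:
    """Absorption coefficient and time constant of the log heating model."""

    alpha: float  # °C · W⁻¹ · s⁻¹
    tau: float  # s
    p0: float  # W
    alpha_se: float = np.nan
    tau_se: float = np.nan
    rmse: float = np.nan
    low_signal: bool = False

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.tau <= 0:
            raise ValueError("tau must be > 0")
        if self.p0 < 0:
            raise ValueError("p0 must be >= 0")


@dataclass(frozen=True)
class SequenceSpec:
    """An MRI sequence reduced to effective emitted power and duration."""

    power: float  # W
    duration: float  # s
    label: str = ""

    def __post_init__(self) -> None:
        if self.power < 0:
            raise ValueError("power must be >= 0")
        if self.duration <= 0:
            raise ValueError("duration must be > 0")


@dataclass
class CalibrationPoint:
    """One row of a calibration table."""

    fa_hm: float  # degrees
    b1rms: float  # μT
    energy: float  # J
    power: float  # W
    tmax: float  # °C (mean over the end-of-heating window)
    tmax_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.tmax_sd < 0:
            raise ValueError("tmax_sd must be >= 0")


@dataclass
class CalibrationSet:
    """Heating curves and fitted model parameters across powers."""

    points: list[CalibrationPoint] = field(default_factory=list)
    curves: dict[float, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)
    fitted: list[EqOneParams] = field(default_factory=list)
    alpha_poly: np.ndarray | None = None  # np.polyfit order (descending)
    tau_poly: np.ndarray | None = None
    power_range: tuple[float, float] | None = None
    window: HeatingWindow | None = None


@dataclass
class BetaFitResult:
    beta: float
    beta_se: float
    r_squared: float
    model: str
    intercept: float = 0.0


@dataclass
class IsothermGrid:
    """Predicted maximal temperature rise over a (power, duration) grid."""

    powers: np.ndarray  # W
    durations: np.ndarray  # s
    tmax: np.ndarray  # °C, shape (n_powers, n_durations); NaN where undefined


@dataclass
class PredictionResult:
    times: np.ndarray
    curve: np.ndarray
    tmax: float
    extrapolated: bool
    params: EqOneParams


def eq1_eval(
    t, alpha: float, p0: float, tau: float, window: HeatingWindow
) -> np.ndarray:
    """Piecewise-logarithmic temperature response to constant-power heating.

    Continuous at both window edges; 0 before heating starts and → 0 as
    t → ∞ after the power is switched off.
    """
    if tau <= 0:
        raise ValueError(f"tau must be > 0, got {tau}")
    t = np.asarray(t, dtype=float)
    scalar = t.ndim == 0
    t = np.atleast_1d(t)
    out = np.zeros_like(t)
    amp = alpha * p0 * tau
    heat = (t >= window.t0) & (t <= window.t1)
    cool = t > window.t1
    out[heat] = amp * np.log((t[heat] - window.t0 + tau) / tau)
    out[cool] = amp * np.log(
        (t[cool] - window.t0 + tau) / (t[cool] - window.t1 + tau)
    )
    return float(out[0]) if scalar else out


def eq1_peak(alpha: float, p0: float, tau: float, window: HeatingWindow) -> float:
    """Maximal temperature rise, reached at the end of heating (t = t1)."""
    if tau <= 0:
        raise ValueError(f"tau must be > 0, got {tau}")
    return float(alpha * p0 * tau * np.log((window.duration + tau) / tau))


class LogHeatSource(BaseEstimator, RegressorMixin):
    """Nonlinear least-squares fit of the log heating model to one curve.

    Parameters
    ----------
    p0 : float
        Constant applied power (W) during the heating window.
    window : HeatingWindow
        Heating start/stop times (s).
    max_restarts : int
        Multi-start attempts with log-spaced tau initialisations on
        non-convergence.
    seed : int or None
        Unused randomness hook kept for API symmetry; the fit is
        deterministic (restarts are on a fixed log grid).

    Attributes
    ----------
    alpha_, tau_ : float
        Fitted parameters (alpha bounded >= 0, tau > 0).
    alpha_se_, tau_se_ : float
        Asymptotic standard errors from the Jacobian.
    rmse_ : float
        Residual root-mean-square error, °C.
    low_signal_ : bool
        True when alpha is within 2 standard errors of 0 (or p0 == 0),
        i.e. no detectable heating.
    """

    def __init__(
        self,
        p0: float = 1.0,
        window: HeatingWindow = HeatingWindow(10.0, 90.0),
        max_restarts: int = 5,
        seed: int | None = None,
    ):
        self.p0 = p0
        self.window = window
        self.max_restarts = max_restarts
        self.seed = seed

    def fit(self, t, dT) -> "LogHeatSource":
        t = np.asarray(t, dtype=float)
        dT = np.asarray(dT, dtype=float)
        if t.shape != dT.shape or t.ndim != 1:
            raise ValueError("t and dT must be 1-D arrays of equal length")
        w = self.window
        dur = w.duration
        tau0_default = 0.1 * dur

        if self.p0 == 0:
            # model is identically zero whatever alpha: no signal to fit
            self.alpha_, self.tau_ = 0.0, tau0_default
            self.alpha_se_ = np.nan
            self.tau_se_ = np.nan
            self.rmse_ = float(np.sqrt(np.mean(dT**2)))
            self.low_signal_ = True
            return self

        def f(tt, alpha, tau):
            return eq1_eval(tt, alpha, self.p0, tau, w)

        # alpha start from the observed end-of-heating level via the
        # closed-form peak at the starting tau
        peak_obs = max(float(np.max(dT)), 1e-9)

        def alpha0(tau0: float) -> float:
            return peak_obs / (self.p0 * tau0 * np.log((dur + tau0) / tau0))

        tau_starts = [tau0_default] + list(
            np.logspace(np.log10(0.01 * dur), np.log10(dur), self.max_restarts)
        )
        last_err: Exception | None = None
        for tau0 in tau_starts:
            try:
                popt, pcov = curve_fit(
                    f,
                    t,
                    dT,
                    p0=[alpha0(tau0), tau0],
                    bounds=([0.0, 1e-9], [np.inf, np.inf]),
                    maxfev=20000,
                )
            except (RuntimeError, ValueError) as err:  # no convergence
                last_err = err
                continue
            self.alpha_, self.tau_ = float(popt[0]), float(popt[1])
            perr = np.sqrt(np.diag(pcov))
            self.alpha_se_, self.tau_se_ = float(perr[0]), float(perr[1])
            resid = dT - f(t, *popt)
            self.rmse_ = float(np.sqrt(np.mean(resid**2)))
            self.low_signal_ = bool(
                not np.isfinite(self.alpha_se_)
                or self.alpha_ < 2.0 * self.alpha_se_
            )
            return self
        raise FitFailureError(
            f"log heating model fit did not converge after "
            f"{len(tau_starts)} starts (p0={self.p0} W, last error: {last_err})"
        )

    def predict(self, t) -> np.ndarray:
        return eq1_eval(t, self.alpha_, self.p0, self.tau_, self.window)

    def params_(self) -> EqOneParams:
        return EqOneParams(
            alpha=self.alpha_,
            tau=self.tau_,
            p0=self.p0,
            alpha_se=self.alpha_se_,
            tau_se=self.tau_se_,
            rmse=self.rmse_,
            low_signal=self.low_signal_,
        )


def fit_eq1(
    t,
    dT,
    window: HeatingWindow,
    p0: float,
    max_restarts: int = 5,
    seed: int | None = None,
) -> EqOneParams:
    """Fit (alpha, tau) of the log heating model to one heating curve.

    Thin wrapper over :class:`LogHeatSource`.  Curves with no detectable
    heating are returned with ``low_signal=True`` rather than rejected.
    """
    est = LogHeatSource(p0=p0, window=window, max_restarts=max_restarts, seed=seed)
    est.fit(t, dT)
    return est.params_()


def fit_power_polynomials(
    fits: list[EqOneParams], degree: int = 2
) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares polynomials alpha(P) and tau(P) across calibration fits.

    Coefficients are in descending order (``np.polyfit`` convention).
    Requires at least ``degree + 1`` distinct powers.
    """
    powers = np.array([f.p0 for f in fits], dtype=float)
    if len(np.unique(powers)) < degree + 1:
        raise ValueError(
            f"need >= {degree + 1} distinct powers, got {len(np.unique(powers))}"
        )
    alphas = np.array([f.alpha for f in fits], dtype=float)
    taus = np.array([f.tau for f in fits], dtype=float)
    return np.polyfit(powers, alphas, degree), np.polyfit(powers, taus, degree)


class WireHeatingCalibration(BaseEstimator):
    """Calibration of the heating model across powers and sequence prediction.

    ``fit`` takes one hottest-pixel heating curve per calibration power,
    fits (alpha, tau) per power and describes both as second-order
    polynomials of power.  ``predict`` returns the maximal temperature rise
    for a sequence given its effective emitted power and duration, with
    heating over (0, duration).

    Parameters
    ----------
    window : HeatingWindow
        Heating interval of the *calibration* acquisitions.
    degree : int
        Polynomial degree of alpha(P) and tau(P) (default 2).
    min_curves : int
        Minimum number of usable (non-low-signal) curves.

    Attributes
    ----------
    fits_ : list of EqOneParams
    alpha_poly_, tau_poly_ : ndarray, descending coefficients
    power_range_ : (float, float)
        Power range of the calibration; predictions outside it are
        flagged ``extrapolated`` (the polynomials behave poorly far
        outside the fit range).
    """

    def __init__(
        self,
        window: HeatingWindow = HeatingWindow(10.0, 90.0),
        degree: int = 2,
        min_curves: int = 3,
    ):
        self.window = window
        self.degree = degree
        self.min_curves = min_curves

    def fit(self, curves: dict[float, tuple[np.ndarray, np.ndarray]], y=None):
        """Fit from ``{power_W: (t_s, dT_C)}`` heating curves."""
        fits: list[EqOneParams] = []
        for p0 in sorted(curves):
            t, dT = curves[p0]
            fits.append(fit_eq1(t, dT, self.window, p0))
        usable = [f for f in fits if not f.low_signal]
        if len({f.p0 for f in usable}) < max(self.min_curves, self.degree + 1):
            raise ValueError(
                f"need >= {max(self.min_curves, self.degree + 1)} usable "
                f"calibration curves at distinct powers, got {len(usable)}"
            )
        self.fits_ = fits
        self.alpha_poly_, self.tau_poly_ = fit_power_polynomials(
            usable, degree=self.degree
        )
        ps = [f.p0 for f in usable]
        self.power_range_ = (min(ps), max(ps))
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "alpha_poly_"):
            raise RuntimeError("WireHeatingCalibration is not fitted")

    def params_at(self, power: float) -> tuple[float, float]:
        """Evaluate alpha(P), tau(P); raises OutOfDomainError when nonphysical."""
        self._check_fitted()
        alpha = float(np.polyval(self.alpha_poly_, power))
        tau = float(np.polyval(self.tau_poly_, power))
        if alpha < 0 or tau <= 0:
            raise OutOfDomainError(
                f"calibration polynomials give alpha={alpha:.4g}, "
                f"tau={tau:.4g} at P={power} W; refusing to predict"
            )
        return alpha, tau

    def predict_sequence(self, spec: SequenceSpec, dt: float = 1.0) -> PredictionResult:
        """Predicted heating curve and peak for one sequence."""
        self._check_fitted()
        w = HeatingWindow(0.0, spec.duration)
        times = np.arange(0.0, spec.duration + dt / 2, min(dt, spec.duration / 10))
        if spec.power == 0:
            params = EqOneParams(alpha=0.0, tau=1.0, p0=0.0)
            return PredictionResult(times, np.zeros_like(times), 0.0, False, params)
        alpha, tau = self.params_at(spec.power)
        extrap = not (self.power_range_[0] <= spec.power <= self.power_range_[1])
        curve = eq1_eval(times, alpha, spec.power, tau, w)
        tmax = eq1_peak(alpha, spec.power, tau, w)
        params = EqOneParams(alpha=alpha, tau=tau, p0=spec.power)
        return PredictionResult(times, curve, tmax, extrap, params)

    def predict(self, X) -> np.ndarray:
        """Peak temperature rise (°C) for rows of (power_W, duration_s)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        out = np.empty(X.shape[0])
        for i, (p, d) in enumerate(X):
            out[i] = self.predict_sequence(SequenceSpec(power=p, duration=d)).tmax
        return out

    def isotherm_grid(self, powers, durations) -> IsothermGrid:
        """Peak-rise chart over a power × duration grid (NaN = not predictable)."""
        self._check_fitted()
        powers = np.asarray(powers, dtype=float)
        durations = np.asarray(durations, dtype=float)
        tmax = np.full((len(powers), len(durations)), np.nan)
        for i, p in enumerate(powers):
            for j, d in enumerate(durations):
                try:
                    tmax[i, j] = self.predict_sequence(
                        SequenceSpec(power=p, duration=d)
                    ).tmax
                except OutOfDomainError:
                    pass
        return IsothermGrid(powers=powers, durations=durations, tmax=tmax)

    def to_calibration_set(self) -> CalibrationSet:
        self._check_fitted()
        return CalibrationSet(
            fitted=list(self.fits_),
            alpha_poly=self.alpha_poly_,
            tau_poly=self.tau_poly_,
            power_range=self.power_range_,
            window=self.window,
        )


def predict_for_sequence(
    calib: WireHeatingCalibration | CalibrationSet, spec: SequenceSpec
) -> PredictionResult:
    """Predict the heating curve and peak for a sequence from a calibration."""
    est = _as_estimator(calib)
    return est.predict_sequence(spec)


def isotherm_grid(
    calib: WireHeatingCalibration | CalibrationSet, powers, durations
) -> IsothermGrid:
    return _as_estimator(calib).isotherm_grid(powers, durations)


def _as_estimator(calib) -> WireHeatingCalibration:
    if isinstance(calib, WireHeatingCalibration):
        calib._check_fitted()
        return calib
    if isinstance(calib, CalibrationSet):
        if calib.alpha_poly is None or calib.tau_poly is None:
            raise ValueError("CalibrationSet has no fitted polynomials")
        est = WireHeatingCalibration(window=calib.window or HeatingWindow(10, 90))
        est.fits_ = list(calib.fitted)
        est.alpha_poly_ = np.asarray(calib.alpha_poly, dtype=float)
        est.tau_poly_ = np.asarray(calib.tau_poly, dtype=float)
        est.power_range_ = calib.power_range or (0.0, np.inf)
        return est
    raise TypeError(f"unsupported calibration object {type(calib)!r}")


class PowerLawRegressor(BaseEstimator, RegressorMixin):
    """Least-squares fit of T = beta·x² (quadratic) or T = beta·x (linear).

    Both models pass through the origin by default (no heating at zero
    exposure); set ``intercept=True`` for an unconstrained fit.

    Attributes
    ----------
    beta_ : float           primary coefficient
    beta_se_ : float        its standard error
    intercept_ : float      0 unless ``intercept=True``
    r_squared_ : float      coefficient of determination (about the mean)
    """

    def __init__(self, model: str = "quadratic", intercept: bool = False):
        self.model = model
        self.intercept = intercept

    def _basis(self, x: np.ndarray) -> np.ndarray:
        if self.model == "quadratic":
            cols = [x**2]
        elif self.model == "linear":
            cols = [x]
        else:
            raise ValueError(f"model must be 'quadratic' or 'linear', got {self.model!r}")
        if self.intercept:
            cols.append(np.ones_like(x))
        return np.column_stack(cols)

    def fit(self, x, y) -> "PowerLawRegressor":
        x = np.asarray(x, dtype=float).ravel()
        y = np.asarray(y, dtype=float).ravel()
        if x.size < 2:
            raise ValueError("need at least 2 points")
        if np.all(x == 0):
            raise ValueError("degenerate predictor: all values are zero")
        X = self._basis(x)
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ coef
        dof = max(len(y) - X.shape[1], 1)
        sigma2 = float(resid @ resid) / dof
        cov = sigma2 * np.linalg.inv(X.T @ X)
        self.beta_ = float(coef[0])
        self.beta_se_ = float(np.sqrt(cov[0, 0]))
        self.intercept_ = float(coef[1]) if self.intercept else 0.0
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        self.r_squared_ = 1.0 - float(resid @ resid) / ss_tot if ss_tot > 0 else 1.0
        return self

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.model == "quadratic":
            return self.beta_ * x**2 + self.intercept_
        return self.beta_ * x + self.intercept_


def fit_beta(
    x, tmax, model: str = "quadratic", intercept: bool = False
) -> BetaFitResult:
    """Calibration-curve coefficient (beta) of peak rise vs an exposure metric.

    ``model='quadratic'`` for flip angle or B1+rms (T = beta·x²),
    ``model='linear'`` for emitted energy (T = beta·x).
    """
    est = PowerLawRegressor(model=model, intercept=intercept).fit(x, tmax)
    return BetaFitResult(
        beta=est.beta_,
        beta_se=est.beta_se_,
        r_squared=est.r_squared_,
        model=model,
        intercept=est.intercept_,
    )


def energy_estimate(beta3: float, energy: float) -> float:
    """Naive peak-rise estimate beta3·E from total emitted energy.

    Linear in energy by construction.  For heating localised at a wire tip
    this estimator ignores the power/duration trade-off and badly
    mispredicts short high-power sequences — which is why the
    piecewise-logarithmic model exists.
    """
    if beta3 < 0 or energy < 0:
        raise ValueError("beta3 and energy must be >= 0")
    return float(beta3 * energy)
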