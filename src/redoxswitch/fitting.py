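"""Trace- and rate-level fitting for stopped-flow kinetics.

Implements the reduced models the individual experiments are analysed with:

* single-exponential relaxation fits of instrument traces,
* pseudo-first-order analysis (kobs vs concentration) giving kon and koff,
* hyperbolic (Michaelis–Menten-form) saturation fits of zinc-release rates
  giving the oxidant pre-equilibrium constant K1 and the zinc-release rate
  k2 (and the low-concentration bimolecular constant k2/K1),
* second-order linearization of equal-concentration oxidant consumption
  (1/[oxidant] vs time),
* the standard inner-filter correction for fluorescence titrations.

All nonlinear fits use trust-region least squares with deterministic
initial guesses derived from linearized transforms of the data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from scipy.stats import t as t_dist

from .scheme import Trace

__all__ = [
    "FitError",
    "FitWarning",
    "ExpFit",
    "PFOFit",
    "SatFit",
    "SecondOrderFit",
    "fit_exponential",
    "fit_pseudo_first_order",
    "fit_saturation",
    "second_order_rate",
    "inner_filter_correct",
    "ci95",
]


class FitError(RuntimeError):
    """Fit could not be performed or did not converge."""


class FitWarning(UserWarning):
    """Non-fatal fit diagnostics (identifiability, data span)."""


@dataclass
class ExpFit:
    """Single-exponential fit  signal = amplitude * exp(-kobs*t) + offset."""

    amplitude: float
    kobs: float
    offset: float
    residual_rms: float
    stderr: dict = field(default_factory=dict)
    dof: int = 0

    @property
    def kobs_stderr(self) -> float:
        return self.stderr.get("kobs", np.nan)


@dataclass
class PFOFit:
    """Pseudo-first-order line  kobs = kon * [conc] + koff."""

    kon: float
    koff_intercept: float
    kobs: list
    concentrations: list
    stderr: dict = field(default_factory=dict)
    r_squared: float = np.nan
    dof: int = 0


@dataclass
class SatFit:
    """Hyperbolic saturation fit  kobs = k2 * [Ox] / (K1 + [Ox])."""

    K1: float
    k2: float
    stderr: dict = field(default_factory=dict)
    extrapolated: bool = False
    dof: int = 0

    @property
    def bimolecular(self) -> float:
        """Low-concentration second-order constant k2/K1 (M^-1 s^-1)."""
        return self.k2 / self.K1


@dataclass
class SecondOrderFit:
    """Equal-concentration second-order fit: slope of 1/C vs t."""

    k2nd: float
    intercept: float
    r_squared: float
    stderr: dict = field(default_factory=dict)
    intercept_consistent: bool = True
    monotone: bool = True
    dof: int = 0


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float, float]:
    """Least-squares line y = a*x + b; returns a, b, se_a, se_b, R^2."""
    n = x.size
    A = np.column_stack([x, np.ones(n)])
    coef, res, *_ = np.linalg.lstsq(A, y, rcond=None)
    a, b = coef
    yhat = A @ coef
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    if n > 2:
        s2 = ss_res / (n - 2)
        cov = s2 * np.linalg.inv(A.T @ A)
        se_a, se_b = np.sqrt(np.diag(cov))
    else:
        se_a = se_b = np.nan
    return float(a), float(b), float(se_a), float(se_b), r2


def fit_exponential(trace: Trace | tuple, n_phases: int = 1) -> ExpFit:
    """Fit ``A*exp(-k*t) + c`` to a trace by nonlinear least squares.

    Accepts a :class:`~redoxswitch.scheme.Trace` or a ``(times, signal)``
    pair.  Standard errors come from the covariance of the fit.  Warns when
    the trace spans fewer than three relaxation times of the fitted rate.
    """
    if n_phases != 1:
        raise NotImplementedError("only single-phase fits are supported")
    if isinstance(trace, Trace):
        t, y = trace.times, trace.signal
    else:
        t, y = (np.asarray(v, dtype=float) for v in trace)
    if t.size < 10:
        raise FitError(f"need >= 10 points for an exponential fit, got {t.size}")

    y_range = float(y.max() - y.min())
    if y_range == 0 or y_range < 1e-12 * max(1.0, abs(float(y.mean()))):
        raise FitError("constant trace: exponential amplitude not identifiable")

    # fit on unit-normalized signal so the trust region is well conditioned
    # regardless of instrument units
    y_min = float(y.min())
    yn = (y - y_min) / y_range

    # deterministic starts: offset from the trace tail, rate from the
    # log-slope of the baseline-subtracted early points
    c0 = float(np.mean(yn[-max(3, t.size // 10):]))
    a0 = float(yn[0] - c0)
    if a0 == 0:
        a0 = 1.0 if yn[0] > yn.mean() else -1.0
    resid = (yn - c0) / a0
    early = (resid > 0.05) & (resid < 1.5)
    if early.sum() >= 3:
        k0 = max(-_ols(t[early], np.log(resid[early]))[0], 1e-12)
    else:
        k0 = 1.0 / max(t[-1] - t[0], 1e-12)

    def model(tt, a, k, c):
        return a * np.exp(-k * tt) + c

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, pcov = curve_fit(
                model, t, yn, p0=[a0, k0, c0], maxfev=20000,
                bounds=([-np.inf, 0.0, -np.inf], np.inf), xtol=1e-14, ftol=1e-14,
                gtol=1e-14,
            )
    except RuntimeError as exc:  # pragma: no cover - non-convergence path
        raise FitError(f"exponential fit did not converge: {exc}") from exc
    a, k, c = popt
    # undo normalization
    a = a * y_range
    c = c * y_range + y_min
    pcov = pcov * np.outer([y_range, 1.0, y_range], [y_range, 1.0, y_range])
    if k <= 0 or not np.isfinite(k):
        raise FitError(f"fitted rate at parameter bound (k={k})")
    if abs(a) < 1e-6 * y_range:
        raise FitError("fitted amplitude vanishes: rate not identifiable")
    perr = np.sqrt(np.diag(pcov))
    rms = float(np.sqrt(np.mean((y - model(t, a, k, c)) ** 2)))
    span = (t[-1] - t[0]) * k
    if span < 3:
        warnings.warn(
            f"trace spans only {span:.2f} relaxation times (< 3); "
            "rate and offset may be correlated",
            FitWarning, stacklevel=2,
        )
    return ExpFit(
        amplitude=float(a), kobs=float(k), offset=float(c), residual_rms=rms,
        stderr={"amplitude": float(perr[0]), "kobs": float(perr[1]),
                "offset": float(perr[2])},
        dof=int(t.size - 3),
    )


def fit_pseudo_first_order(points) -> PFOFit:
    """Ordinary least-squares line through (concentration, kobs) points.

    The slope is the bimolecular association rate constant kon and the
    intercept estimates koff.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an iterable of (conc_M, kobs_per_s) pairs")
    if pts.shape[0] < 3:
        raise FitError(f"need >= 3 concentration points, got {pts.shape[0]}")
    conc, kobs = pts[:, 0], pts[:, 1]
    if np.unique(conc).size != conc.size:
        raise FitError("concentrations must be distinct")
    kon, koff, se_kon, se_koff, r2 = _ols(conc, kobs)
    if kon <= 0:
        raise FitError(f"fitted slope (kon) is non-positive: {kon:.3e}")
    return PFOFit(
        kon=kon, koff_intercept=koff, kobs=list(kobs), concentrations=list(conc),
        stderr={"kon": se_kon, "koff_intercept": se_koff}, r_squared=r2,
        dof=int(conc.size - 2),
    )


def fit_saturation(points) -> SatFit:
    """Fit the hyperbola kobs = k2*[Ox]/(K1+[Ox]) to (oxidant, kobs) points.

    Initial guesses come from the double-reciprocal line.  If the fitted K1
    exceeds the largest oxidant concentration the result is flagged
    ``extrapolated`` (the data never leave the linear regime).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an iterable of (oxidant_M, kobs_per_s) pairs")
    if pts.shape[0] < 4:
        raise FitError(f"need >= 4 points for a saturation fit, got {pts.shape[0]}")
    ox, kobs = pts[:, 0], pts[:, 1]
    if np.any(ox <= 0) or np.any(kobs <= 0):
        raise FitError("oxidant concentrations and rates must be positive")

    # double-reciprocal start: 1/k = (K1/k2)(1/[Ox]) + 1/k2
    slope, icpt, *_ = _ols(1.0 / ox, 1.0 / kobs)
    if icpt > 0 and slope > 0:
        k2_0, K1_0 = 1.0 / icpt, slope / icpt
    else:
        k2_0, K1_0 = float(kobs.max()), float(np.median(ox))

    def model(x, K1, k2):
        return k2 * x / (K1 + x)

    try:
        popt, pcov = curve_fit(
            model, ox, kobs, p0=[K1_0, k2_0], maxfev=20000,
            bounds=(0.0, np.inf), xtol=1e-12, ftol=1e-12,
        )
    except RuntimeError as exc:  # pragma: no cover
        raise FitError(f"saturation fit did not converge: {exc}") from exc
    K1, k2 = (float(v) for v in popt)
    if K1 <= 0 or k2 <= 0:
        raise FitError("saturation fit collapsed to a boundary")
    perr = np.sqrt(np.diag(pcov))
    extrapolated = K1 > ox.max()
    if extrapolated:
        warnings.warn(
            f"fitted K1 = {K1:.3g} M exceeds the largest oxidant concentration "
            f"({ox.max():.3g} M): K1 is extrapolated",
            FitWarning, stacklevel=2,
        )
    return SatFit(K1=K1, k2=k2,
                  stderr={"K1": float(perr[0]), "k2": float(perr[1])},
                  extrapolated=extrapolated, dof=int(ox.size - 2))


def second_order_rate(times, conc) -> SecondOrderFit:
    """Second-order rate from equal-concentration consumption data.

    For A + A-type (here oxidant + sensor at equal concentration) kinetics,
    1/C(t) = 1/C0 + k*t, so the slope of 1/C vs t is the second-order rate
    constant.  The fitted intercept is checked against 1/C0 (within 5%).
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(conc, dtype=float)
    if t.size != c.size or t.size < 3:
        raise ValueError("need matched time/concentration arrays with >= 3 points")
    if np.any(c <= 0):
        raise FitError("non-positive concentrations cannot be linearized")
    monotone = bool(np.all(np.diff(c) <= 1e-12 * c[0]))
    if not monotone:
        warnings.warn("concentration series is not monotonically decreasing",
                      FitWarning, stacklevel=2)
    slope, icpt, se_a, se_b, r2 = _ols(t, 1.0 / c)
    if slope <= 0:
        warnings.warn(f"non-positive second-order slope ({slope:.3e} M^-1 s^-1): "
                      "no consumption detected", FitWarning, stacklevel=2)
    consistent = bool(abs(icpt - 1.0 / c[0]) <= 0.05 * (1.0 / c[0]))
    if not consistent:
        warnings.warn(
            "fitted intercept deviates > 5% from 1/C0; data may not be "
            "equal-concentration second order", FitWarning, stacklevel=2,
        )
    return SecondOrderFit(k2nd=slope, intercept=icpt, r_squared=r2,
                          stderr={"k2nd": se_a, "intercept": se_b},
                          intercept_consistent=consistent, monotone=monotone,
                          dof=int(t.size - 2))


def inner_filter_correct(observed, A_ex, A_em):
    """Standard inner-filter correction: observed * 10**((A_ex + A_em)/2)."""
    A_ex = np.asarray(A_ex, dtype=float)
    A_em = np.asarray(A_em, dtype=float)
    if np.any(A_ex < 0) or np.any(A_em < 0):
        raise ValueError("absorbances must be >= 0")
    return np.asarray(observed, dtype=float) * 10.0 ** ((A_ex + A_em) / 2.0)


def ci95(fit, param: str) -> float:
    """Half-width of the nominal 95% confidence interval for a fitted
    parameter, using the Student-t quantile at the fit's residual degrees
    of freedom (the proper small-sample calibration for least squares)."""
    se = fit.stderr[param]
    dof = getattr(fit, "dof", 0)
    if dof < 1 or not np.isfinite(se):
        raise FitError(f"no finite CI available for {param!r}")
    return float(t_dist.ppf(0.975, dof) * se)
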