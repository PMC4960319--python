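"""Equilibrium thermodynamics: glutathione-couple redox titration, tight
binding, and isothermal titration calorimetry (ITC).

Redox titration.  A two-electron dithiol/disulfide centre equilibrated
against a GSH/GSSG couple satisfies

    R = X / (Keq + X),        X = [GSH]^2 / [GSSG]  (M),

where R is the reduced fraction and Keq (M) the equilibrium constant of the
thiol-disulfide exchange.  The standard potential follows from the Nernst
relation at the glutathione reference potential:

    E0 = E0_ref - (R_gas * T / (n * F)) * ln(Keq),   n = 2.

ITC.  Per-injection heats are modelled from exact equilibrium compositions
(quadratic solution for a single site; bracketed scalar root for the
three-species competitive case) with stepwise displacement dilution of the
cell contents.  A sub-nanomolar site is outside the directly fittable
c-value window at accessible cell concentrations, which is why the tight
interaction is measured by competitive displacement against a weak binder.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import brentq, curve_fit, least_squares

__all__ = [
    "R_GAS_J", "F_CONST_J_MV", "R_KCAL",
    "RedoxCoupleParams", "RedoxTitration",
    "fraction_reduced", "nernst_potential", "keq_from_potential",
    "fit_redox_titration", "bound_fraction_quadratic",
    "ITCExperiment", "ITCFitResult", "itc_model_heats", "fit_itc",
    "thermo_convert", "kd_from_thermo", "ThermoError",
]

R_GAS_J = 8.314          # J K^-1 mol^-1
F_CONST_J_MV = 96.485    # J mV^-1 mol^-1
R_KCAL = 1.987204e-3     # kcal K^-1 mol^-1


class ThermoError(ValueError):
    """Invalid thermodynamic input or non-identifiable data."""


@dataclass(frozen=True)
class RedoxCoupleParams:
    """Glutathione reference couple and physical constants.

    ``E0_ref`` is the standard potential of GSH/GSSG at 25 degC, pH 7.5
    (-240 mV); the exchange is two-electron.
    """

    E0_ref: float = -240.0
    n_electrons: int = 2
    R_gas: float = R_GAS_J
    F_const: float = F_CONST_J_MV
    temperature: float = 298.15

    def __post_init__(self) -> None:
        if self.n_electrons != 2:
            raise ThermoError("the dithiol/GSSG exchange is a two-electron couple")
        if self.temperature <= 0:
            raise ThermoError("temperature must be > 0 K")

    @property
    def prefactor_mV(self) -> float:
        """RT/nF in mV."""
        return self.R_gas * self.temperature / (self.n_electrons * self.F_const)


@dataclass
class RedoxTitration:
    """Points of a glutathione-couple titration and (after fitting) Keq/E0.

    ``fraction_reduced`` may be supplied directly or derived from control
    signals: positive/negative controls bracket the full signal change and
    the experimental signal is read as
    ``R = (signal_exp - signal_neg) / (signal_pos - signal_neg)``.
    """

    gsh: np.ndarray
    gssg: np.ndarray
    fraction_reduced: np.ndarray | None = None
    signal_exp: np.ndarray | None = None
    signal_pos: np.ndarray | None = None
    signal_neg: np.ndarray | None = None
    Keq: float | None = None
    Keq_stderr: float | None = None
    E0: float | None = None

    def __post_init__(self) -> None:
        self.gsh = np.asarray(self.gsh, dtype=float)
        self.gssg = np.asarray(self.gssg, dtype=float)
        if self.gsh.shape != self.gssg.shape:
            raise ThermoError("gsh and gssg grids must have equal length")
        if np.any(self.gsh <= 0) or np.any(self.gssg <= 0):
            raise ThermoError("glutathione concentrations must be > 0")
        if self.fraction_reduced is not None:
            self.fraction_reduced = np.asarray(self.fraction_reduced, dtype=float)

    @property
    def X(self) -> np.ndarray:
        """[GSH]^2/[GSSG] in M."""
        return self.gsh ** 2 / self.gssg

    def resolve_fractions(self) -> np.ndarray:
        if self.fraction_reduced is not None:
            return self.fraction_reduced
        if self.signal_exp is None or self.signal_pos is None or self.signal_neg is None:
            raise ThermoError(
                "fraction_reduced absent and control signals incomplete"
            )
        pos = np.asarray(self.signal_pos, dtype=float)
        neg = np.asarray(self.signal_neg, dtype=float)
        exp = np.asarray(self.signal_exp, dtype=float)
        total = pos - neg
        if np.any(total == 0):
            raise ThermoError("degenerate controls: zero total signal change")
        return (exp - neg) / total


def fraction_reduced(Keq, gsh, gssg):
    """Reduced fraction R = X/(Keq+X) with X = [GSH]^2/[GSSG] (all in M)."""
    Keq = np.asarray(Keq, dtype=float)
    gsh = np.asarray(gsh, dtype=float)
    gssg = np.asarray(gssg, dtype=float)
    if np.any(Keq <= 0) or np.any(gsh <= 0) or np.any(gssg <= 0):
        raise ThermoError("Keq, [GSH] and [GSSG] must all be > 0")
    X = gsh ** 2 / gssg
    out = X / (Keq + X)
    return float(out) if out.ndim == 0 else out


def nernst_potential(Keq, couple: RedoxCoupleParams | None = None) -> float:
    """Standard potential (mV) from the exchange constant Keq (M)."""
    couple = couple or RedoxCoupleParams()
    Keq = np.asarray(Keq, dtype=float)
    if np.any(Keq <= 0):
        raise ThermoError("Keq must be > 0")
    out = couple.E0_ref - couple.prefactor_mV * np.log(Keq)
    return float(out) if out.ndim == 0 else out


def keq_from_potential(E0, couple: RedoxCoupleParams | None = None) -> float:
    """Exact inverse of :func:`nernst_potential`."""
    couple = couple or RedoxCoupleParams()
    E0 = np.asarray(E0, dtype=float)
    out = np.exp((couple.E0_ref - E0) / couple.prefactor_mV)
    return float(out) if out.ndim == 0 else out


def fit_redox_titration(
    titration: RedoxTitration,
    couple: RedoxCoupleParams | None = None,
) -> RedoxTitration:
    """Fit Keq from (X, R) points and convert to a standard potential.

    Requires at least five points and an identifiable transition: the
    observed reduced fractions must leave both plateaus (some R < 0.95 and
    some R > 0.05), otherwise Keq is unbounded on one side.
    """
    couple = couple or RedoxCoupleParams()
    R = titration.resolve_fractions()
    X = titration.X
    if X.size < 5:
        raise ThermoError(f"need >= 5 titration points, got {X.size}")
    if np.all(R > 0.95) or np.all(R < 0.05):
        raise ThermoError(
            "titration is non-identifiable: all points on one plateau "
            f"(R in [{R.min():.3f}, {R.max():.3f}])"
        )
    def model(x, logK):
        return x / (np.exp(logK) + x)

    logK0 = float(np.log(np.median(X)))
    popt, pcov = curve_fit(model, X, R, p0=[logK0], maxfev=20000,
                           xtol=1e-14, ftol=1e-14)
    Keq = float(np.exp(popt[0]))
    Keq_se = float(np.sqrt(pcov[0, 0]) * Keq)  # delta method on log-scale fit
    titration.Keq = Keq
    titration.Keq_stderr = Keq_se
    titration.E0 = nernst_potential(Keq, couple)
    if titration.fraction_reduced is None:
        titration.fraction_reduced = R
    return titration


def bound_fraction_quadratic(P0: float, L0: float, Kd: float) -> float:
    """Fraction of P bound at totals P0, L0 (M) via the tight-binding quadratic.

    Valid at any affinity; in the stoichiometric limit (Kd << P0) the curve
    rises linearly to saturation at L0 = P0.
    """
    if P0 < 0 or L0 < 0:
        raise ThermoError("total concentrations must be >= 0")
    if Kd <= 0:
        raise ThermoError("Kd must be > 0")
    if P0 == 0:
        return 0.0
    b = P0 + L0 + Kd
    complex_conc = (b - np.sqrt(b * b - 4.0 * P0 * L0)) / 2.0
    return float(complex_conc / P0)


# --------------------------------------------------------------------------
# ITC


@dataclass
class ITCExperiment:
    """An ITC titration: cell composition, injection schedule and heats.

    ``cell`` maps ``"receptor"`` (and optionally ``"competitor"``) to molar
    cell concentrations; ``syringe`` is the titrant concentration.  Heats
    are integrated per-injection values in kcal.  Default geometry is a
    200 uL cell with 20 x 2 uL injections; default temperature 308.15 K
    (35 degC — at 25 degC the binding heats are undetectable).
    """

    cell: dict
    syringe: float
    injections: Sequence[float] = field(
        default_factory=lambda: [2e-6] * 20)
    heats: np.ndarray | None = None
    model: str = "single_site"
    cell_volume: float = 200e-6
    temperature: float = 308.15
    competitor_Kd: float | None = None

    def __post_init__(self) -> None:
        if self.model not in ("single_site", "competitive"):
            raise ThermoError(f"unknown ITC model {self.model!r}")
        if self.cell_volume <= 0 or any(v <= 0 for v in self.injections):
            raise ThermoError("volumes must be > 0")
        if "receptor" not in self.cell:
            raise ThermoError("cell must contain a receptor concentration")
        if self.model == "competitive" and "competitor" not in self.cell:
            raise ThermoError("competitive model requires a cell competitor")
        self.injections = list(self.injections)
        if self.heats is not None:
            self.heats = np.asarray(self.heats, dtype=float)
            if self.heats.size != len(self.injections):
                raise ThermoError("heats length must match injections length")


@dataclass
class ITCFitResult:
    """Fitted ITC parameters with derived, self-consistent state functions.

    ``dG = R*T*ln(Kd)`` (kcal/mol, R in kcal units) and
    ``dS = (dH - dG) * 1000 / T`` (cal/mol/K) hold exactly by construction.
    """

    N: float
    Kd: float
    dH: float
    temperature: float
    dG: float = field(init=False)
    dS: float = field(init=False)
    competitor_Kd: float | None = None
    competitor_dH: float | None = None
    stderr: dict = field(default_factory=dict)
    c_value: float | None = None
    c_flag: str | None = None
    residual_rms: float | None = None

    def __post_init__(self) -> None:
        if self.Kd <= 0:
            raise ThermoError("Kd must be > 0")
        self.dG, self.dS = thermo_convert(self.Kd, self.dH, self.temperature)


def thermo_convert(Kd: float, dH: float, T: float) -> tuple[float, float]:
    """(dG kcal/mol, dS cal/mol/K) from Kd (M) and dH (kcal/mol) at T (K)."""
    if Kd <= 0 or T <= 0:
        raise ThermoError("Kd and T must be > 0")
    dG = R_KCAL * T * np.log(Kd)
    dS = (dH - dG) * 1000.0 / T
    return float(dG), float(dS)


def kd_from_thermo(dH: float, dS: float, T: float) -> float:
    """Inverse of :func:`thermo_convert`: Kd from dH (kcal/mol), dS (cal/mol/K)."""
    if T <= 0:
        raise ThermoError("T must be > 0")
    dG = dH - T * dS / 1000.0
    return float(np.exp(dG / (R_KCAL * T)))


def _free_receptor(Pt: float, At: float, Bt: float,
                   KdA: float, KdB: float) -> float:
    """Free receptor from totals for receptor + titrant (A) + competitor (B).

    Solves P + At*P/(KdA+P) + Bt*P/(KdB+P) = Pt by bracketed root finding;
    the left side is strictly increasing in P so the root is unique.
    """
    if Pt <= 0:
        return 0.0

    def g(P):
        return P + At * P / (KdA + P) + Bt * P / (KdB + P) - Pt

    return brentq(g, 0.0, Pt, xtol=1e-300, rtol=1e-15, maxiter=200)


def _cell_compositions(exp: ITCExperiment):
    """Stepwise totals (M) in the cell after each injection.

    Each injection of volume dV displaces a fraction dV/V0 of the current
    cell contents and delivers syringe titrant at dV/V0; all cell totals
    dilute by (1 - dV/V0) per injection.
    """
    V0 = exp.cell_volume
    rec = exp.cell["receptor"]
    comp = exp.cell.get("competitor", 0.0)
    tit = 0.0
    rows = []
    for dV in exp.injections:
        f = dV / V0
        rec *= (1.0 - f)
        comp *= (1.0 - f)
        tit = tit * (1.0 - f) + exp.syringe * f
        rows.append((rec, comp, tit, f))
    return rows


def itc_model_heats(
    exp: ITCExperiment,
    N: float,
    Kd: float,
    dH: float,
    competitor_Kd: float | None = None,
    competitor_dH: float = 0.0,
) -> np.ndarray:
    """Per-injection heats (kcal) for the single-site or competitive model.

    The heat of injection i is V0 * sum_k dH_k * (B_k,i - B_k,i-1*(1-f_i)),
    i.e. newly formed complex corrected for bound material displaced from
    the overfilled cell during the injection.
    """
    if Kd <= 0 or N <= 0:
        raise ThermoError("N and Kd must be > 0")
    if exp.model == "competitive":
        competitor_Kd = competitor_Kd if competitor_Kd is not None else exp.competitor_Kd
        if competitor_Kd is None or competitor_Kd <= 0:
            raise ThermoError("competitive model requires a positive competitor Kd")
    V0 = exp.cell_volume
    heats = np.empty(len(exp.injections))
    BA_prev = 0.0
    BB_prev = 0.0
    for i, (rec, comp, tit, f) in enumerate(_cell_compositions(exp)):
        Pt = N * rec
        if exp.model == "single_site":
            b = Pt + tit + Kd
            BA = (b - np.sqrt(b * b - 4.0 * Pt * tit)) / 2.0
            BB = 0.0
        else:
            P = _free_receptor(Pt, tit, comp, Kd, competitor_Kd)
            BA = tit * P / (Kd + P)
            BB = comp * P / (competitor_Kd + P)
        q = V0 * (dH * (BA - BA_prev * (1.0 - f))
                  + competitor_dH * (BB - BB_prev * (1.0 - f)))
        heats[i] = q
        BA_prev, BB_prev = BA, BB
    return heats


def _c_flag(c: float) -> str | None:
    if c > 1000:
        return "c_too_high"
    if c < 1:
        return "c_too_low"
    return None


def fit_itc(
    exp: ITCExperiment,
    competitor_Kd: float | None = None,
    p0: dict | None = None,
) -> ITCFitResult:
    """Least-squares fit of N, Kd, dH (and competitor dH if competitive).

    The competitor Kd is fixed at its independently measured value (passed
    here or stored on the experiment); the competitor enthalpy is co-fitted.
    Kd is fitted on a log scale.  A Wiseman c-value outside [1, 1000] is
    flagged: such a site is not directly fittable and should be measured by
    competition.
    """
    if exp.heats is None:
        raise ThermoError("experiment carries no heats to fit")
    heats = exp.heats
    informative = np.abs(heats) > 1e-3 * np.abs(heats).max()
    if informative.sum() < 10:
        raise ThermoError(
            f"need >= 10 informative injections, got {int(informative.sum())}"
        )
    competitive = exp.model == "competitive"
    if competitive:
        competitor_Kd = competitor_Kd if competitor_Kd is not None else exp.competitor_Kd
        if competitor_Kd is None:
            raise ThermoError("competitive fit requires the competitor Kd")

    scale = np.abs(heats).max()
    dH0 = (p0 or {}).get("dH", heats[0] / (exp.cell_volume * exp.cell["receptor"]))
    dHc0 = (p0 or {}).get("competitor_dH", dH0 / 2.0)
    N0 = (p0 or {}).get("N", 1.0)
    Kd_starts = ([(p0 or {})["Kd"]] if p0 and "Kd" in p0 else
                 [1e-6, 1e-7, 1e-8, 1e-9, 1e-10])

    def residuals(theta):
        if competitive:
            N, logKd, dH, dHc = theta
        else:
            N, logKd, dH = theta
            dHc = 0.0
        try:
            model = itc_model_heats(
                exp, N, np.exp(logKd), dH,
                competitor_Kd=competitor_Kd, competitor_dH=dHc)
        except (ThermoError, ValueError):
            return np.full(heats.size, 1e3 * scale)
        return (model - heats) / scale

    best = None
    for Kd0 in Kd_starts:
        theta0 = [N0, np.log(Kd0), dH0] + ([dHc0] if competitive else [])
        lo = [1e-3, np.log(1e-15), -np.inf] + ([-np.inf] if competitive else [])
        hi = [10.0, np.log(1.0), np.inf] + ([np.inf] if competitive else [])
        sol = least_squares(residuals, theta0, bounds=(lo, hi),
                            xtol=1e-15, ftol=1e-15, gtol=1e-15)
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not best.success and best.cost > 1e-6:  # pragma: no cover
        raise ThermoError("ITC fit did not converge")

    if competitive:
        N, logKd, dH, dHc = best.x
    else:
        N, logKd, dH = best.x
        dHc = None
    Kd = float(np.exp(logKd))

    # standard errors from the Gauss-Newton covariance
    stderr = {}
    try:
        J = best.jac
        dof = max(heats.size - best.x.size, 1)
        s2 = 2.0 * best.cost / dof
        cov = s2 * np.linalg.inv(J.T @ J)
        se = np.sqrt(np.diag(cov)) * scale / scale
        names = ["N", "logKd", "dH"] + (["competitor_dH"] if competitive else [])
        stderr = dict(zip(names, (float(v) for v in se)))
        stderr["Kd"] = stderr.pop("logKd") * Kd
    except np.linalg.LinAlgError:  # pragma: no cover
        pass

    c = float(N * exp.cell["receptor"] / Kd)
    flag = _c_flag(c) if not competitive else None
    if flag:
        warnings.warn(
            f"Wiseman c-value {c:.3g} outside the directly fittable range "
            "[1, 1000]; Kd is unreliable — use a competition design",
            UserWarning, stacklevel=2,
        )
    rms = float(np.sqrt(np.mean((residuals(best.x) * scale) ** 2)))
    return ITCFitResult(
        N=float(N), Kd=Kd, dH=float(dH), temperature=exp.temperature,
        competitor_Kd=competitor_Kd if competitive else None,
        competitor_dH=float(dHc) if competitive else None,
        stderr=stderr, c_value=c, c_flag=flag, residual_rms=rms,
    )
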