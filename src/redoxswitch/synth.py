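"""Synthetic instrument data with the statistical structure the analyses assume.

The generators emulate the study's experimental designs:

* stopped-flow association under pseudo-first-order conditions (sigma at
  125 nM, anti-sigma varied 1.25–2.5 uM in 250 nM steps),
* competition displacement with a 10-fold excess of a non-fluorescent
  sigma variant,
* oxidation kinetics: pseudo-first-order zinc release (PAR, 500 nm) over a
  25 uM – 20 mM diamide grid, and equal-concentration (25 uM + 25 uM)
  second-order oxidant consumption at 320 nm,
* glutathione-couple redox titrations with positive/negative control pairs,
* single-site and competitive ITC thermograms.

Noise is additive Gaussian on the observed signal (default 1% of the
dynamic range).  Every generator takes an explicit seed and is bit-for-bit
reproducible under it.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import scheme as sch
from . import thermo as th

__all__ = [
    "NoiseSpec", "GeneratorSpec",
    "gen_kinetic_dataset", "gen_redox_titration", "gen_itc_thermogram",
    "DESIGNS",
]

# Methods-style default designs (concentrations in M, times in s)
DESIGNS = {
    "association": {
        "sigma_conc": 125e-9,
        "antisigma_grid": [1.25e-6 + 0.25e-6 * i for i in range(6)],
        "n_points": 200,
    },
    "displacement": {
        "complex_conc": 2.5e-6,
        "competitor_conc": 25e-6,
        "n_points": 400,
    },
    "oxidation": {
        "complex_conc": 2e-6,
        "oxidant_grid": [25e-6, 50e-6, 100e-6, 200e-6, 500e-6,
                         1e-3, 2e-3, 5e-3, 10e-3, 20e-3],
        "n_points": 300,
    },
    "second_order": {
        "conc0": 25e-6,
        "duration": 1200.0,
        "n_points": 300,
    },
    "redox_titration": {
        # Methods GSSG span; GSH raised so X=[GSH]^2/[GSSG] brackets the
        # midpoint implied by the measured potential (see docs/methods.md)
        "gsh": 10e-3,
        "gssg_grid": list(np.geomspace(100e-6, 100e-3, 12)),
    },
    "itc": {
        "cell_receptor": 10e-6,
        "syringe": 100e-6,
        "competitor": 50e-6,
        "n_injections": 20,
        "injection_vol": 2e-6,
    },
}


@dataclass(frozen=True)
class NoiseSpec:
    """Additive Gaussian noise; sigma relative to the signal's dynamic range
    when ``relative`` is true, absolute otherwise."""

    sigma: float = 0.01
    relative: bool = True
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")

    def apply(self, signal: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        if self.sigma == 0:
            return signal
        scale = self.sigma
        if self.relative:
            rng_span = float(signal.max() - signal.min())
            scale = self.sigma * (rng_span if rng_span > 0 else 1.0)
        return signal + rng.normal(0.0, scale, size=signal.shape)


@dataclass
class GeneratorSpec:
    """What to simulate: experiment kind, truth parameters, design, noise.

    ``design`` entries override the Methods-style defaults in ``DESIGNS``.
    If ``seed`` is None it is derived from a hash of the spec itself (and
    recorded in the outputs).
    """

    kind: str
    truth: dict = field(default_factory=dict)
    design: dict = field(default_factory=dict)
    noise: NoiseSpec = field(default_factory=lambda: NoiseSpec(sigma=0.0))
    seed: int | None = None

    def __post_init__(self) -> None:
        known = ("association", "displacement", "oxidation", "second_order",
                 "redox_titration", "itc")
        if self.kind not in known:
            raise ValueError(f"unknown experiment kind {self.kind!r}")

    def resolved_seed(self) -> int:
        if self.seed is not None:
            return int(self.seed)
        blob = json.dumps(
            {"kind": self.kind, "truth": self.truth, "design": self.design,
             "noise": asdict(self.noise)},
            sort_keys=True, default=str).encode()
        return int.from_bytes(hashlib.sha256(blob).digest()[:4], "big") % (2**31)

    def resolved_design(self) -> dict:
        base = dict(DESIGNS.get(self.kind, {}))
        base.update(self.design)
        return base

    def scheme_params(self) -> sch.SchemeParams:
        fields = {k: v for k, v in self.truth.items()
                  if k in sch.SchemeParams.__dataclass_fields__}
        return sch.SchemeParams(**fields)


def _truth_sidecar(spec: GeneratorSpec, seed: int, extra: dict | None = None) -> dict:
    side = {"kind": spec.kind, "seed": seed, "truth": dict(spec.truth),
            "design": spec.resolved_design(), "noise": asdict(spec.noise)}
    if extra:
        side.update(extra)
    return side


def gen_kinetic_dataset(spec: GeneratorSpec) -> tuple[list[sch.Trace], dict]:
    """Simulate a set of stopped-flow traces for the requested design.

    Returns (traces, truth_sidecar).  Traces are produced by integrating
    the mass-action scheme and projecting onto the appropriate channel;
    noise is added post hoc.
    """
    seed = spec.resolved_seed()
    rng = np.random.default_rng(seed)
    design = spec.resolved_design()
    params = spec.scheme_params()

    if spec.kind == "association":
        traces = _gen_association(spec, params, design, rng)
    elif spec.kind == "displacement":
        traces = _gen_displacement(spec, params, design, rng)
    elif spec.kind == "oxidation":
        traces = _gen_oxidation(spec, params, design, rng)
    elif spec.kind == "second_order":
        traces = _gen_second_order(spec, params, design, rng)
    else:
        raise ValueError(f"{spec.kind!r} is not a kinetic trace experiment")
    return traces, _truth_sidecar(spec, seed, {"params": params.to_dict()})


def _time_grid(rate: float, n: int, n_halflives: float = 7.0) -> np.ndarray:
    span = n_halflives * np.log(2.0) / rate
    return np.linspace(0.0, span, n)


def _gen_association(spec, params, design, rng):
    scheme = sch.build_scheme(params, include_oxidation=False, include_par=False)
    s0 = design["sigma_conc"]
    coeffs = {"S": 1.0, "RZnS": 0.35, "RS": 0.35}  # complex quenches sigma Trp
    traces = []
    for r0 in design["antisigma_grid"]:
        kobs = params.kon_holo * r0 + params.koff_holo
        times = _time_grid(kobs, design["n_points"])
        traj = sch.simulate(scheme, {"RZn": r0, "S": s0}, times)
        tr = sch.observe(traj, "fluorescence_343", coeffs, offset=0.1,
                         meta={"antisigma_conc": r0, "sigma_conc": s0, "seed": spec.seed})
        tr.signal = spec.noise.apply(tr.signal, rng)
        traces.append(tr)
    return traces


def _gen_displacement(spec, params, design, rng):
    if design["competitor_conc"] <= design["complex_conc"]:
        raise ValueError("displacement requires an excess of dark competitor")
    scheme = sch.build_displacement_scheme(params)
    c0 = design["complex_conc"]
    times = _time_grid(params.koff_holo, design["n_points"])
    traj = sch.simulate(
        scheme, {"RZnS": c0, "Sx": design["competitor_conc"]}, times)
    tr = sch.observe(traj, "fluorescence_343", {"S": 1.0, "RZnS": 0.35},
                     offset=0.1, meta={"complex_conc": c0, "seed": spec.seed})
    tr.signal = spec.noise.apply(tr.signal, rng)
    return [tr]


def _gen_oxidation(spec, params, design, rng):
    """Pseudo-first-order zinc release over the oxidant grid (PAR, 500 nm)."""
    c0 = design["complex_conc"]
    eps500 = design.get("eps500", 6.6e4)  # Zn-PAR extinction x 1 cm path
    traces = []
    for ox0 in design["oxidant_grid"]:
        scheme = sch.build_scheme(params, include_oxidation=True, include_par=True)
        kobs = params.k2_ox * ox0 / (params.K1_ox + ox0)
        times = _time_grid(kobs, design["n_points"])
        traj = sch.simulate(scheme, {"RZnS": c0, "Ox": ox0}, times)
        tr = sch.observe(traj, "absorbance_500", {"ZnPAR": eps500},
                         meta={"oxidant_conc": ox0, "complex_conc": c0,
                               "seed": spec.seed})
        tr.signal = spec.noise.apply(tr.signal, rng)
        traces.append(tr)
    return traces


def _gen_second_order(spec, params, design, rng):
    """Equal-concentration diamide consumption followed at 320 nm."""
    c0 = design["conc0"]
    eps320 = design.get("eps320", 3.1e3)
    k2nd = spec.truth.get("k2nd", params.k2_ox / params.K1_ox)
    times = np.linspace(0.0, design["duration"], design["n_points"])
    conc = c0 / (1.0 + k2nd * c0 * times)
    signal = spec.noise.apply(eps320 * conc, rng)
    tr = sch.Trace(times=times, signal=signal, channel="absorbance_320",
                   meta={"conc0": c0, "eps320": eps320, "k2nd": k2nd,
                         "seed": spec.seed})
    return [tr]


def gen_redox_titration(spec: GeneratorSpec) -> tuple[th.RedoxTitration, dict]:
    """Glutathione-couple titration with control-pair synthesis.

    Truth is ``Keq`` (M) or ``E0`` (mV).  Experimental signal is
    ``neg + R*(pos - neg)`` with Gaussian noise; positive/negative controls
    set the full-signal bracket per point.  Warns if the X grid does not
    bracket Keq (the fit would extrapolate the midpoint).
    """
    if spec.kind != "redox_titration":
        raise ValueError("spec.kind must be 'redox_titration'")
    seed = spec.resolved_seed()
    rng = np.random.default_rng(seed)
    design = spec.resolved_design()
    couple = th.RedoxCoupleParams(
        temperature=spec.truth.get("temperature", 298.15))
    if "Keq" in spec.truth:
        Keq = float(spec.truth["Keq"])
    elif "E0" in spec.truth:
        Keq = th.keq_from_potential(spec.truth["E0"], couple)
    else:
        raise ValueError("truth must provide Keq or E0")

    gssg = np.asarray(design["gssg_grid"], dtype=float)
    gsh = np.full_like(gssg, float(design["gsh"]))
    X = gsh ** 2 / gssg
    if not (X.min() < Keq < X.max()):
        import warnings
        warnings.warn(
            "titration grid does not bracket the midpoint: Keq "
            f"{Keq:.3g} M outside X range [{X.min():.3g}, {X.max():.3g}] M",
            UserWarning, stacklevel=2)
    R = th.fraction_reduced(Keq, gsh, gssg)
    pos = np.full_like(X, design.get("signal_pos", 1.0))
    neg = np.full_like(X, design.get("signal_neg", 0.05))
    exp_signal = spec.noise.apply(neg + R * (pos - neg), rng)
    titr = th.RedoxTitration(gsh=gsh, gssg=gssg, signal_exp=exp_signal,
                             signal_pos=pos, signal_neg=neg)
    side = _truth_sidecar(spec, seed, {"Keq": Keq,
                                       "E0": th.nernst_potential(Keq, couple)})
    return titr, side


def gen_itc_thermogram(spec: GeneratorSpec) -> tuple[th.ITCExperiment, dict]:
    """Synthetic single-site or competitive thermogram.

    Truth keys: ``N``, ``Kd`` (M), ``dH`` (kcal/mol) and, for the
    competitive design, ``competitor_Kd`` and ``competitor_dH``.
    """
    if spec.kind != "itc":
        raise ValueError("spec.kind must be 'itc'")
    seed = spec.resolved_seed()
    rng = np.random.default_rng(seed)
    design = spec.resolved_design()
    model = spec.truth.get("model", "single_site")
    cell = {"receptor": design["cell_receptor"]}
    if model == "competitive":
        cell["competitor"] = design["competitor"]
    exp = th.ITCExperiment(
        cell=cell, syringe=design["syringe"],
        injections=[design["injection_vol"]] * design["n_injections"],
        model=model,
        temperature=spec.truth.get("temperature", 308.15),
        competitor_Kd=spec.truth.get("competitor_Kd"),
    )
    heats = th.itc_model_heats(
        exp, N=spec.truth.get("N", 1.0), Kd=spec.truth["Kd"],
        dH=spec.truth["dH"],
        competitor_Kd=spec.truth.get("competitor_Kd"),
        competitor_dH=spec.truth.get("competitor_dH", 0.0),
    )
    exp.heats = spec.noise.apply(heats, rng)
    return exp, _truth_sidecar(spec, seed)
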