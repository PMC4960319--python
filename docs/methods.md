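# Methods

## The kinetic model

The package models a zinc-gated anti-sigma-factor redox switch as a
mass-action reaction network. The reduced, zinc-bound sensor (`RZn`)
binds its sigma factor (`S`) reversibly, as does the zinc-free form
(`R`):

    RZn + S ⇌ RZnS      kon_holo / koff_holo
    R   + S ⇌ RS        kon_apo  / koff_apo

Zinc acts almost entirely on the off-rate: the defaults encode a 400-fold
acceleration of complex dissociation when zinc is removed
(`koff_holo = 7.5e-4 s⁻¹`, `koff_apo = 0.3 s⁻¹`) with association rates
left equal (`1e6 M⁻¹s⁻¹`, a typical stopped-flow magnitude). These
defaults give a holo-complex Kd of 0.75 nM and an apo Kd of 300 nM at
mass-action equilibrium; they are package choices consistent with the
measured rate ratios, since individual rate constants for the wild-type
pair are not published in an accessible form.

Oxidation proceeds through a weak, rapidly equilibrating oxidant adduct
whose decomposition releases zinc and forms the trigger disulfide:

    RZn + Ox ⇌ I        rapid equilibrium, K1 (default 0.7 mM)
    I → Rox + Zn + OxRed            k2 (default 0.15 s⁻¹)

with the identical path for the sigma-bound sensor (`RZnS + Ox ⇌ IC`,
`IC → RoxS + Zn + OxRed`, `RoxS → Rox + S` at `koff_apo`) — free and
complexed sensor oxidize identically, and the oxidized sensor cannot
rebind sigma. Released zinc is captured by the PAR chromophore,
modelled as irreversible and pseudo-first-order (`k_par·[PAR]`, PAR in
excess at 100 µM and not tracked). Under this scheme the observed
zinc-release rate follows the two-step rapid-equilibrium closed form
`kobs = k2·[Ox]/(K1+[Ox])`, and its low-concentration limit `k2/K1` is
the second-order oxidation rate.

The scheme topology is a reconstruction from the measured behaviour of
the system (rate-limiting zinc release; a weak saturable oxidant adduct;
identical oxidation of free and bound sensor; no sigma binding by the
oxidized form); the network builder validates every reaction against the
declared conserved moieties (total sensor, total sigma, total zinc, total
oxidant) at construction time.

**Rapid pre-equilibrium encoding.** K1 is realized as explicit
forward/reverse mass action with `k1f = 1e5 M⁻¹s⁻¹` and `k1r = k1f·K1`.
At these defaults `k1r = 70 s⁻¹ ≫ k2 = 0.15 s⁻¹`, so the pre-equilibrium
approximation holds to better than 2% across the experimental oxidant
range (validated against the closed form in the test suite, using a
catalytic 50 nM sensor so the oxidant is not depleted; at the
experimental 2 µM sensor the lowest oxidant point, 25 µM, is itself
depleted ~8% during the reaction and its kobs is biased low by a few
percent — a feature of the experiment, not the integrator).

**Integration.** `scipy.integrate.solve_ivp` with LSODA (stiff-capable),
`rtol = 1e-8`, `atol = 1e-12 M`. Small negative excursions (below
100·atol) are clipped to zero with a logged warning; larger ones raise.
Conserved-moiety totals drift < 1e-6 relative over every tested
trajectory.

**Displacement kinetics.** Mixing preformed complex with an excess of a
non-fluorescent sigma variant yields a clean single-exponential exchange
whose eigenvalue is `koff·(1 + Rtot/(Stot+Xtot−Rtot))` under the
quasi-steady-state for free sensor — i.e. `1.10·koff` at the standard
design (2.5 µM complex + 25 µM competitor). The fitted "koff" from such
an experiment therefore carries a systematic +10% at 10-fold excess,
shrinking as 1/excess. The simulator reproduces this exactly and the
test suite asserts the closed-form eigenvalue rather than pretending the
bias away.

## Fitting

All nonlinear fits use trust-region least squares (`scipy.optimize`)
with deterministic initial guesses from linearized transforms
(log-slope of the baseline-subtracted early points for exponentials; the
double-reciprocal line for saturation). The exponential fit normalizes
the signal to unit range internally so convergence is independent of
instrument units (molar traces and fluorescence volts condition
identically). Standard errors come from the Gauss–Newton covariance;
95% intervals use the Student-t quantile at the residual degrees of
freedom (`fitting.ci95`), which is what makes the Monte-Carlo coverage
test calibrate correctly at 6–10 data points. Fits on fewer than the
minimum informative points raise errors rather than warn; identifiability
problems that leave a usable estimate (fitted K1 beyond the data range,
inconsistent second-order intercept, sub-3-relaxation-time traces) warn
and set flags.

The second-order analysis assumes equal initial concentrations of
oxidant and sensor thiols, for which `1/C(t) = 1/C0 + k·t`; the fitted
intercept is checked against 1/C0 within 5% as a design self-check. The
inner-filter correction is the standard
`observed · 10^((A_ex+A_em)/2)`.

## Redox titration and the Nernst conversion

For a two-electron dithiol/disulfide centre equilibrated against
GSH/GSSG, the reduced fraction follows `R = X/(Keq+X)` with
`X = [GSH]²/[GSSG]` (M). Keq is fitted on a log scale; the standard
potential is `E0 = −240 mV − (RT/2F)·ln Keq` with R = 8.314 J K⁻¹ mol⁻¹,
F = 96.485 J mV⁻¹ mol⁻¹, T = 298.15 K. The orientation of both
equations is fixed by requiring that fitting a synthetic titration
generated at any potential returns that potential (asserted to 1e-6 mV
noiseless). Raw titrations carry positive/negative control signals per
point; the reduced fraction is `(signal_exp − signal_neg)/(signal_pos −
signal_neg)`. Degenerate titrations (all points on one plateau) are
rejected as non-identifiable.

The generator's default design keeps the experimental GSSG span
(100 µM – 100 mM) but fixes GSH at 10 mM: with GSH in the sub-µM range
the X grid could not reach the measured midpoint (Keq ≈ 0.026 M implied
by −193.04 mV), which points to a unit inconsistency in the published
protocol. Concentrations remain free parameters of the generator; the
default simply brackets the midpoint (X/Keq from 0.04 to 39) as any
workable titration must.

## ITC

Per-injection heats are modelled from exact equilibrium compositions.
Cell bookkeeping uses exact stepwise displacement for an overfilled
cell: injection *i* of volume dV dilutes all cell totals by
`1 − dV/V0` and delivers syringe titrant at `dV/V0`; the heat is
`q_i = V0 · Σ_k ΔH_k · (B_k,i − B_k,i−1·(1−dV/V0))`, subtracting bound
material expelled during the injection. Defaults: 200 µL cell, 20 × 2 µL
injections, 308.15 K (heats at 25 °C are undetectable for this system;
35 °C is the working temperature).

Single-site compositions come from the tight-binding quadratic with the
effective site concentration `N·[receptor]`. Competitive compositions
solve the free-receptor balance
`P + At·P/(KdA+P) + Bt·P/(KdB+P) = Pt` — strictly increasing in P, so a
bracketed scalar root on [0, Pt] is exact (relative tolerance 1e-15);
the tests cross-check it against the closed-form cubic root to 1e-8 over
randomized compositions spanning Kd 10 pM – 1 µM.

Fits estimate N, Kd (log-scale) and ΔH, plus the competitor ΔH in the
competitive model; the competitor Kd is held at its independently
measured value (185 nM for the weak-binding variant used as competitor).
ΔG = RT·ln Kd and ΔS = (ΔH−ΔG)·1000/T are derived, so results are
self-consistent by construction. The Wiseman c-value `N·[cell]/Kd` is
computed for every direct fit and flagged outside [1, 1000]: a
sub-nanomolar site at 10 µM cell concentration (c ≈ 13,000) is reported
but flagged unreliable, which is the quantitative rationale for the
competition design.

## Synthetic data

Generators mirror the experimental designs: association at 125 nM sigma
with sensor 1.25–2.5 µM in 250 nM steps; displacement at 2.5 µM complex
with 25 µM dark competitor; pseudo-first-order zinc release over a
25 µM – 20 mM oxidant grid at 2 µM complex; equal-concentration
(25 µM + 25 µM) second-order consumption over 1200 s; the glutathione
titration above; and the two ITC designs. Time grids span 7 half-lives
of the expected rate at 200–400 points. Noise is additive Gaussian on
the observed signal, default σ = 1% of the trace's dynamic range —
adequate for these analyses; photon-counting statistics and stopped-flow
dead-time artefacts are not modelled. Seeds are explicit; an unseeded
spec derives a stable seed from its own hash. Truth sidecars always
contain enough to re-run recovery.

What passing recovery tests shows — and does not. Because the generator
and the fitted reduced models share the same functional forms, noiseless
round trips validate correctness of the estimators and solvers, not the
adequacy of those forms for real instrument data (baseline drift,
dead time, mixing artefacts are out of scope). The scheme-based tests
(PFO slope from simulated traces, second-order rate from simulated
absorbance, zinc-release saturation) are the stronger checks: there the
data come from the full network, not from the reduced model being
fitted.

## Structure metrics

Coordinates are parsed with gemmi (PDB/mmCIF); all models of an ensemble
are kept, alternate locations resolve to the first conformer, and
heteroatoms are retained but flagged. "Lowest-energy model" follows the
deposition convention of MODEL 1.

SASA uses Shrake–Rupley point sampling on a golden-spiral sphere
lattice: probe 1.4 Å, 960 points per atom by default, Bondi-type van der
Waals radii (C 1.70, N 1.55, O 1.52, S 1.80, Zn 1.39 Å …). The
implementation is validated against the closed form for isolated atoms,
additivity, burial, 4× point-count convergence (< 0.5%) and an
independent Shrake–Rupley implementation (biotite) on matched radii.
Absolute values for a protein ensemble depend on the radius set and
hydrogen treatment, so cross-program agreement should only be expected
to ~10%; relative comparisons between states computed with the same
settings (e.g. the ~13% compaction of the oxidized sensor) are robust.

Crosslink checks report Cα–Cα (and, where present, Lys NZ–NZ) distances
per restraint against linker-specific cutoffs — 26 Å for BS2G (7.7 Å
spacer) and 30 Å for BS3 (11.4 Å spacer), the community-standard
modelling limits, both configurable since no universal cutoff exists.
Links with missing residues or atoms are marked unevaluable, never
silently dropped. Both MODEL-1 and ensemble-averaged quantities are
accessible, since conventions differ between studies.

The deposited sensor ensembles (PDB 5frf reduced/zinc-bound, 5frh
oxidized) are analysed with the same calls via `fetch_pdb` where a
network is available; the test suite runs entirely on synthetic
fixtures.

## Pipeline and reproducibility

A YAML config lists ordered stages (generate / fit operations with
parameters and input references). Units are explicit strings validated
against a fixed vocabulary (M, s, per_s, per_M_per_s, mV, kcal_per_mol,
cal_per_mol_K, angstrom, …). Every report records the config hash, the
global seed and the package version; re-running an identical config and
seed reproduces byte-identical result tables. Stage failures halt the
run with the stage name in the diagnostic.

## Problem sizes

Simulations in the test suite use 200–400 time points per trace, 6–10
grid points per titration, 500-replicate Monte-Carlo calibrations and
100-composition solver cross-checks; the full suite and the
reproduction script each complete in well under a minute on one CPU.
These sizes were chosen to keep every estimator in its asymptotic
regime while remaining desk-scale.

## Known limitations

* No global fitting of full trajectories to the complete scheme; each
  experiment is analysed by its standard reduced model, as in practice.
* No multi-exponential model selection; `fit_exponential` is
  single-phase.
* Zinc rebinding to the apo sensor is treated as negligible on the
  experimental timescale (release is committed once PAR captures the
  ion).
* ITC heats are integrated per-injection values; raw power traces and
  baseline integration are out of scope.
* Thermodynamic-cycle closure between the kinetic and calorimetric
  parameter sets is reported, not enforced.
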