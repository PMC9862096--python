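# Methods

## The physical model

The system is an amphiphilic ligand equilibrating among three media in a
suspension of native membrane vesicles containing P-glycoprotein: the aqueous
phase (W), the lipid bilayer (Lb), and the protein binding pocket (P). All
species concentrations are expressed as amount per total solution volume;
partition coefficients are dimensionless concentration ratios on a volume
basis, with the convention that a medium of volume fraction `V` holding
`KP·V/(Σ KP·V)` of the ligand in the dilute limit.

### Membrane composition

A preparation is characterised by the total protein mass concentration and
five composition constants with the defaults used throughout:
phospholipid:protein mass ratio 0.57 w/w, mean phospholipid molar mass
750 g/mol, lipid molar volume 0.8 dm³/mol, protein density 1.2 g/mL, and a
P-gp molar volume of 142 dm³/mol (from its molar mass at 1.2 g/mL). At the
two standard assay dilutions (0.107 and 1.0 mg protein/mL) the membrane
volume fractions are ~1.5e-4 and ~1.5e-3, which justifies the default
approximation V_W = 1; the exact option V_W = 1 − V_Lb − V_P is available on
every entry point and changes results by <0.2%.

Because a "whole membrane" can mean lipid+P-gp or lipid+all proteins, every
`PartitionCoefficientSet` carries a scenario tag (`pgp_only` /
`all_proteins`) and operations refuse to mix scenarios; the whole-membrane
coefficient is only meaningful together with the protein volume used to
reduce the raw titration.

### Partition titrations

The fluorescence of the NBD fluorophore increases on transfer into a
membrane, so titrating membrane into a fixed amount of amphiphile follows the
two-state isotherm F(v) = (F_W + F_M·KP·v)/(1 + KP·v) with v the volume
fraction of the partitioning phase. KP is parameterised as Log10(KP): this
enforces positivity and matches the LogNormal convention used to average
replicates (the mean of Log KP is reported). The covariance-based 75%
interval on Log KP uses a Student-t factor. When the largest sampled KP·v is
below 0.1 the amplitude F_M (and hence KP) is weakly identified; the fit
warns and flags the result rather than failing. Scatter correction of raw
plate-reader signals is out of scope — input tables are assumed corrected.

### Cycle closure

KP(W→M)·(V_Lb+V_P) = KP(W→P)·V_P + KP(W→Lb)·V_Lb is solved for KP(W→P), and
KP(Lb→P) = KP(W→P)/KP(W→Lb) closes the thermodynamic cycle. The subtraction
amplifies input rounding when KP(W→M)·V_M ≈ KP(W→Lb)·V_Lb (lipophilic
ligands, all-proteins scenario); with 2-significant-figure inputs the
recovered KP(W→P) can carry ~25% error even though the inputs are ~2%
rounded. A negative numerator (whole-membrane affinity below the
bilayer-only prediction) is clipped to KP(W→P)=0 and flagged, not raised,
since it is an ordinary consequence of measurement noise.

### Binding polynomial and speciation

The pocket is n equal and independent sites of microscopic constant
K_b = 1/K_d: K_i = ((n−i+1)/i)K_b, β_i = C(n,i)K_b^i, β_1 = nK_b =
KP(W→P)·V̄_P. The apparent site-count estimate `#` = KP(W→P)·V̄_P·K_d is
exposed as a plain formula; it inherits the equal-sites approximation and is
real-valued by design.

The free aqueous ligand solves
g(L_W) = L_W(1 + KP·V_Lb/V_W) + Σ i·β_i·P(L_W)·L_W^i − L_T = 0 with
P(L_W) = P_T/(1 + Σ β_i L_W^i). Each term of g is non-decreasing in L_W and
g(0) = −L_T < 0 ≤ g(L_T), so the root is unique in [0, L_T]; it is found with
Brent's method at machine-precision relative tolerance (returned states
satisfy both mass balances to <1e-12 relative in practice; the contract is
1e-9). L_T = 0 returns the all-zero state rather than an error. No
excess-ligand assumption is made anywhere: although the amphiphile totals
(µM) dwarf the protein (nM), bilayer sequestration can push the *aqueous*
concentration down to the protein scale, which is exactly the regime where
total-concentration models go wrong. An independent algebraic route — the
cleared-denominator degree-(n+1) polynomial solved by a companion-matrix
root finder — exists only for cross-checks in the tests; the production path
is the bracketed scalar root.

Cooperative microscopic models, binding kinetics, aqueous aggregates as mass-
balance species, and slow inter-leaflet translocation (relevant to charged
lysolipids on assay timescales) are out of scope. Aggregation is only
*flagged*, by comparing the computed aqueous concentration with the 25 °C
critical aggregation concentration (assays run at 37 °C, where the CAC is
higher, so the flag is conservative; no temperature correction is applied).

### Observables

ATPase: the printed occupancy-weighted form mixes units if read literally,
so the implementation uses saturation-fraction weighting,
V = V₀·(P/P_T) + Σ (PL_i/P_T)·V_i, which returns exactly V₀ at zero ligand
and keeps every value inside [min(V₀,V_i), max(V₀,V_i)]. The V_i are free
parameters (no monotonicity constraint by default; one can be imposed).

IAAP: the tracer (5 nM) is below the protein (59 nM), so the bound fraction
uses the exact 1:1 quadratic with depletion, applied to the protein still
available given amphiphile occupancy. Three availability rules are
implemented: any bound amphiphile blocks (P* = P), only the saturated pocket
blocks (P* = P + Σ_{i<n} PL_i), or i ≥ n−1 blocks. For n < 2 the
intermediate rule is undefined and falls back to `any_bound` with an
explicit warning. Displacement is 100·(I_P0 − I_P)/I_P0, clipped to [0, 100]
with a 1e-9 overshoot tolerance.

Apparent baselines (total-concentration models) are the standard two-site
rational ATPase curve — with activation-only and full-inhibition variants —
and competitive displacement with the tracer-occupancy correction
Ki·(1 + I_T/Kd_IAAP). In the excess-ligand, no-bilayer, single-site limit
the full model collapses onto the competitive curve once Ki absorbs that
correction factor; this equivalence is verified numerically to <1% over
three decades.

## Fitting and uncertainty

Residuals are unweighted by default (per-point 1/sd weighting is optional).
Kd is fitted as Log10(Kd) with bounds [1e-10, 1] M; for ATPase data the
V_1..V_n are free with V₀ fixed at 100%. Each fit is restarted from 8
log-spaced Kd values (10 nM–1 mM, deterministic grid) and the lowest-χ²
solution kept. χ² is the plain residual sum of squares. Non-convergence is
reported via a flag with the best iterate.

Profile confidence intervals: the parameter is stepped outward from the
estimate, all other parameters re-optimised at each value, and the interval
is where χ²(θ) ≤ χ²_min·(1 + F(1, ν; level)/ν), ν = N − p, located by
bisection to 1e-3 of the bracket. Profiles that never cross (flat
directions, parameters at bounds) give open one-sided intervals. On an
exactly quadratic χ² surface this reproduces the closed-form t-based
interval, which is the oracle test. The default level is 75%, matching the
sensitivity analyses this type of assay usually reports; levels are
qualitative anchors, not calibrated frequentist guarantees, for the strongly
nonlinear models.

The site-count scan fits each n independently and reports (n, χ², Kd,
KP-from-β₁). χ² is not assumed monotone in n. For IAAP data the parameter
count is the same for every n, so the χ² minimum is a meaningful selector;
for ATPase data larger n adds V_i parameters and the scan is read as
"improvement then plateau", with the β₁-implied partition coefficient
against the measured one as the tiebreaker.

## Synthetic data

The generators produce the three assay types from known ground truth through
the *same* forward-model code the fitting uses (no duplicated math), with
Gaussian noise: a relative (heteroscedastic) component, default 2% of the
response — consistent with the replicate scatter of these assays — plus an
optional additive floor; negative responses are clipped at zero and flagged.
Default grids mirror the study conditions: modulator 0–60 µM (ATPase,
10 points) and 0.5–50 µM (IAAP, 8 points), membrane 0–1.2 mg protein/mL
(titrations, 1% noise). Presets for the NBD-C4/C8/LysoMPE amphiphiles carry
the published bilayer partition coefficients, Kd = 5 µM (inside the 2–9 µM
consensus of the intrinsic analysis), and per-occupancy activity profiles
encoding the qualitative behaviour of each compound (progressive activation;
activation-then-inhibition; mostly inhibition), since per-occupancy
activities are not tabulated anywhere.

What the generators do *not* emulate: raw spectra and wavelength shifts,
scatter artifacts at high membrane concentration, radiolabel counting
statistics, aqueous aggregation above the CAC, and leaflet asymmetry. A
passing recovery study therefore demonstrates the statistical identifiability
of (n, Kd, V_i) under the model's own assumptions at realistic noise — not
robustness to those unmodelled features of real data.

## Validation problem sizes

The recovery studies use 20 seeded replicates per assay type: ATPase with
n = 2, Kd = 5 µM, (V₁, V₂) = (500, 100)% at the 0.107 mg/mL condition; IAAP
with n = 3, Kd = 5 µM, the i ≥ n−1 availability rule at the 1.0 mg/mL
condition, scanning n = 1..5. These sizes keep the full suite at a few
minutes on one core while giving stable medians; observed performance is
~3% median Kd error (ATPase), 75–80% coverage of the 75% profile interval,
and 20/20 correct site-count selections at these settings. The
solver-vs-polynomial-oracle check runs 1000 random parameter draws with
n ≤ 5 and agrees to <1e-10 relative.

## Known limitations

- The equal-and-independent-sites pocket is an idealisation; the `#`
  estimate and the β₁ comparison inherit it.
- Profile-CI levels are approximate for these nonlinear models (see above).
- The apparent-model baselines are conventions, not derivations; they exist
  to quantify how far total-concentration analyses drift, not as competing
  physical models.
- Cycle closure is numerically ill-conditioned for ligands whose membrane
  association is bilayer-dominated; report and propagate the Log-scale
  uncertainty rather than trusting point values there.
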