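# Methods

## Transport model

The transwell monolayer is modelled as a one-dimensional chain of
resistances at steady state. In the apical→basolateral (A→B) direction the
chain is: donor aqueous boundary layer (ABL) → apical membrane → cytosol →
basolateral membrane → support filter + basolateral ABL → acceptor; the
B→A chain is the mirror image. The acceptor is a perfect sink, matching
assays run under sink conditions. A paracellular route acts in parallel and
is added directly to the transcellular apparent permeability, so `P_app`
never falls below `P_para`.

Aqueous elements act on the total dissolved concentration:
`P_ABL = D_w/δ`, `P_filter = (π r² ρ_pores) · D_w/δ_filter`,
`P_cyt = f_cyt · D_w/δ_cyt`. Membranes pass only the neutral microspecies,
with compartment-specific neutral fractions on each face:
`J_mem = P₀ (f_n,out · C_out − f_n,in · C_in)`. This makes ion trapping an
emergent property rather than a correction: a weak base accumulates in the
(more acidic) cytosol, lowering the effective cytosolic resistance, while
passive `ER` remains exactly 1 (the chain is reciprocal).

The apical membrane's folded microvilli are represented by a surface-area
multiplier `SA` on its passive permeability only. Active transport:

- an apical efflux pump moving compound unidirectionally cytosol→apical
  with apparent permeability `p_pgp` (per nominal insert area), giving a
  flux `p_pgp · C_cyt,a`;
- an optional basolateral uptake transporter (`p_b`, basolateral→cytosol),
  off by default — with bidirectional data of usual quality only the A→B
  inversion is well posed, so basolateral transport is assumed
  insignificant unless the user enables it.

With fixed pump permeability the four internal node concentrations solve a
linear 4×4 system (exact, with a backward-error flux-balance check at
1 × 10⁻⁹ of the dominant term scale). In saturable mode
`p_pgp = J_max/(K_m + C_cyt,a)` with `K_m` on the intracellular axis; the
self-consistent `C_cyt,a` is found by Brent's method on
`g(C) = C_cyt,a(p_pgp(C)) − C`. Because the pump only removes mass from the
cytosol, the passive solution bounds `C_cyt,a` from above and the bracket
`[0, C_passive]` always contains the root.

Units: concentrations in µM, permeabilities in cm/s, fluxes in
µmol·cm⁻²·s⁻¹ (1 µM = 10⁻³ µmol·cm⁻³, so `J = P·C·10⁻³`).

## Speciation and passive permeability

Ionisable sites follow independent Henderson–Hasselbalch equilibria; the
neutral fraction is the probability of the fully uncharged microspecies.
For zwitterions the 2ⁿ protonation microstates are enumerated explicitly
(log-space partition function) and only the uncharged — not the
net-neutral zwitterionic — state counts. Multi-site coupling (macro-pKa
shifts) is not modelled; pKa values are inputs, and values outside
[−2, 16] are accepted but logged as suspicious.

Cytosolic pH defaults to a damped linear homeostasis map
`pH_cyt = 7.2 + 0.3 (pH_ext − 7.4)` — anchored at the observed 7.2 for an
external 7.4, monotone, and deliberately flat because cells buffer their
interior. Any callable can replace it.

Intrinsic permeability `P₀` resolution, in decreasing reliability:
experimental (MDCK-extracted) values; then hexadecane–water partition
coefficients through the solubility–diffusion model
`P₀,SDM = D_hex · K_hex/w / x_m` and the empirical MDCK calibration
`log₁₀ P₀,MDCK = 0.84 · log₁₀ P₀,SDM − 1.85`, preferring PAMPA-measured
over experimental-descriptor over calculated-descriptor `K_hex/w`.
Quantum-chemical (COSMO) `K_hex/w` is accepted only for zwitterions and
compounds above 1000 g/mol, where descriptor methods are unreliable.

Numerical choices:

- Aqueous diffusivity: drug-like power law
  `log₁₀ D_w = −4.113 − 0.4609 log₁₀ MW` (cm²/s at 25 °C), rescaled to
  assay temperature by the Stokes–Einstein factor `(T/T₀)(η₀/η(T))` with
  the Vogel water-viscosity equation. `D_hex = D_w/10`.
- Membrane hydrocarbon-core thickness `x_m = 3 nm` (configurable).
- Geometry defaults (12-well MDCKII inserts): ABL 100 µm per side (orbital
  shaking), filter 11.5 µm thick with 0.4 µm pores at 10⁸ cm⁻²
  (open-area fraction 0.126), `SA = 7.5` (presets 1 and 24 bracket the
  plausible range), cytosolic path 5 µm at half the aqueous diffusivity,
  `P_para = 1×10⁻⁶ cm/s`. The paracellular value is a configurable
  constant representative of tight MDCKII monolayers; a mechanistic
  size/charge model of the tight junction is out of scope.

## Assay inversion

`P_app` from acceptor time courses uses consecutive-interval slopes
`(ΔQ/Δt)/(A·C₀)`, each divided by the mass-balance recovery fraction
(losses to binding/degradation scale the whole accumulation curve, so
dividing the slope by recovery is unbiased); the A→B direction drops the
first interval, which absorbs the lag time. Inserts failing the Lucifer
yellow integrity cutoff (1.5×10⁻⁶ cm/s) are masked out.

Per concentration, `p_pgp` is fitted by a bracketed root solve so the
model reproduces the observed A→B `P_app`; `P_app` is strictly decreasing
in `p_pgp` from the passive value down to the paracellular floor, so the
fit is unique, returns 0 when the observation is at or above the passive
prediction, and raises when the observation is below the floor. The active
flux `J = p_pgp · C_cyt,a` is then regressed on `C_cyt,a` with a
Michaelis–Menten law by multi-start nonlinear least squares (five
log-spaced `K_m` starts, flux normalised to its maximum so optimiser
tolerances act on O(1) residuals).

Weighting: the inversion amplifies noise enormously near saturation, where
the observed `P_app` approaches the passive value. Per-point flux
uncertainties are therefore propagated by finite differences using a
single pooled relative error (median sd/`P_app` across the series) —
replicate SDs at n = 3 are too noisy to weight by individually — and used
as `σ` in the fit. A fitted `K_m` beyond 3× the largest sampled
concentration marks the linear-regime degenerate case: the fit is flagged
non-identifiable and `J_max` is only a lower bound.

## Threshold construction

`pm_at_energy_limit` solves, for a given pump strength, the membrane
permeability at which the steady-state active flux equals `J_max`
(bracketed on `log₁₀ P₀ ∈ [−9, 3]`; the flux is monotone in `P₀`).
`threshold_curve` sweeps the pump over `J_max/(10⁻³·C_ext)` × 10⁻¹…10⁶
(71 log-spaced points; infeasible low-pump samples are skipped), pairs
each limiting `P_m` with the efflux ratio of that configuration, and
reports the plateau as the median `log₁₀(P_m·C_ext)` over samples with
`ER ≥ 10`. The template compound is neutral with MW 400 (representative
drug-like; configurable) at `C_ext = 1 µM`.

In the strong-pump limit the balance reduces to
`SA · P_m · f_n · C_ext · 10⁻³ ≈ J_max`, so the plateau is linear in
`log J_max` with slope 1, inversely proportional to `SA` at fixed `J_max`,
and invariant when `SA` and `J_max` scale together. The
concentration-normalisation (`P_m·C_ext` invariant to `C_ext`) is exact
only asymptotically: aqueous-side resistances (cytosol, filter, ABLs) do
not scale with `P_m`, leaving residuals of order `escape/p_pgp` that decay
as 1/pump-strength. Measured at the plateau statistic, a hundredfold
`C_ext` change moves the plateau by ~3×10⁻⁵ log units — negligible for
screening but not identically zero.

Classification uses the borderline band [−2, −1] on `log₁₀(P_m·C_ext)`
(below → effluxable, inside → borderline, above → non-effluxable) and the
single threshold −1.7 for the outlier rule: a compound with `ER ≥ 2.5` and
`log₁₀(P_m·C_ext)` above the threshold contradicts the energy limit and is
flagged for re-examination. Band, threshold and the `ER` significance
cutoff are all configurable. Screening excludes permanently charged
compounds (declared by an input flag — no structure-based detection) and
keeps conflicting literature `ER` values as separate datapoints.

## Synthetic data

The generator produces exactly the structures the inversion consumes, with
known truth: compound panels whose `log₁₀(P_m·C_ext)` is uniform over a
requested range (permeability back-computed from sampled MW, ionisation
and concentration), bidirectional concentration series from the forward
model with saturable efflux, and acceptor time courses with recovery
losses and lag. Noise is multiplicative lognormal on `P_app` with a unit
median and default CV 5% — assay scatter scales with the measured value —
averaged over 3 simulated replicate inserts. The default saturable truth is
`J_max = 1.6×10⁻⁴ µmol·cm⁻²·s⁻¹`, `K_m = 5 µM`.

The canonical borderline panel spans membrane permeabilities
`log₁₀ P_m ∈ [−3.5, −3.05]`, chosen from the forward model's `ER`
profiles so that the efflux ratio declines from roughly 12 to 2 over
1.5–150 µM while the pump's effect on `P_app` stays well above the noise
floor at every concentration — the regime in which saturation assays are
informative. All generators are pure functions of configuration and seed.

What the generator does *not* emulate: inter-passage biological
variability, concentration-dependent recovery, solubility/DMSO ceilings,
LC-MS quantification limits, TEER drift, or multiple co-expressed
transporters. Passing recovery tests therefore demonstrate the inversion
machinery under the stated noise model, not robustness to every failure
mode of real assays.

## Numerical sizes used in tests

Test and acceptance runs use desk-scale problems chosen for tight
turnaround: 4 synthetic borderline compounds × 8 concentrations × 3
replicates for parameter recovery; 100-compound panels for screening; a
71-point pump sweep per threshold curve; 20 random draws for the
finite-difference cross-check; 100 replicates for estimator-bias checks.

## Known limitations

- The energy limit is cell-system specific; the default `J_max` and the
  −1.7 plateau apply to MDCKII-MDR1-like monolayers. Other systems (BBB
  endothelium, cancer lines) need their own `J_max`; only the parameter is
  exposed, not a predictive energy-budget model.
- The paracellular route is a constant permeability, not a size/charge
  model, and bypasses the ABLs.
- Multi-site pKa coupling and temperature dependence of pKa are not
  modelled.
- The basolateral uptake pathway is implemented but not fitted by default;
  enabling it requires externally supplied `p_b`.
- Time-dependent (pre-steady-state) behaviour is outside the model; time
  courses are evaluated as quasi-steady interval slopes.
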