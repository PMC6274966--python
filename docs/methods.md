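# Methods

## The physical model

### Condensing-effect stoichiometry

A gramicidin dimer spans the bilayer and condenses neighbouring DMPC acyl
chains onto its side surface. Given a radial distribution g(r) of lipid
around the dimer axis, the cumulative condensed count per leaflet is

    N(R) = rho_bulk * integral_{R_g}^{R} g(r) 2 pi r dr,

with `rho_bulk = 1/62 A^-2` (the inverse cross-section of a fluid DMPC)
and peptide radius `R_g = 7.5 A`. The integral is evaluated by composite
trapezoid on the tabulated grid, with linear interpolation at both
endpoints; no adaptive quadrature is used because profiles are tabulated
data and grid-reproducibility matters more than formal order. Inverting
N(R) by bisection (|dN| < 1e-9) gives the rigid-cluster radius for M
condensed chains per leaflet (M/2 lipids, each contributing two chains;
fractional lipid counts such as 5.5 at M = 11 are kept as reals
throughout). The cluster area A_M = pi R^2 defines the lattice unit; the
cross-section of one condensed lipid is (A_M - pi R_g^2)/(M/2). The
critical mole fraction at which the cluster stoichiometry is exactly
satisfied membrane-wide is X_cr(M) = 1/(1 + M/2), with exact inverse
M(x) = 2(1-x)/x.

The centrosymmetry assumption behind N(R) degrades at small N; no
correction is applied.

### Lattice free energy

The bilayer is a lattice of units of area A_M, each either a rigid
cluster (s state: one dimer + M chains per leaflet) or fluid phase
(u state: fluid lipid plus 0-2 monomers). Writing everything per leaflet
for N_tot molecules with overall peptide fraction X_g and cluster
fraction X_gs:

* `N_s = X_gs * N_tot`, and the fluid-unit count follows from area
  bookkeeping,
  `N_u = N_tot[(X_g - X_gs) A_g + (1 - X_g - X_gs M/2) A_pf] / A_M`,
  which vanishes identically at the stoichiometric point
  X_gs = X_g = X_cr(M).
* The free energy is a mean-field (Bragg-Williams) reconstruction:

      F(X_gs) = N_s (delta_cluster + eps_gs-gu)
              + (z / 2N)(N_s^2 e_ss + 2 N_s N_u e_us + N_u^2 e_uu)
              + RT [N_s ln(N_s/N) + N_u ln(N_u/N)]
              + RT [n_gf ln x_gf + L_f ln x_lf]

  with N = N_s + N_u, fluid monomer count n_gf = (X_g - X_gs) N_tot,
  fluid lipid count L_f = (1 - X_g - X_gs M/2) N_tot and their fluid-phase
  mole fractions x_gf, x_lf. The internal energies and entropies of the
  two unit types are folded into the single condensation free energy
  `delta_cluster` (per cluster per leaflet); any independent temperature
  dependence of those internal terms is absorbed there as well. The
  convention 0·ln 0 = 0 makes F finite on the closed admissible interval
  X_gs in [0, min(X_g, 2(1 - X_g)/M)].

* Equilibrium is the maximum-term approximation: the minimizer of F over
  the admissible interval, located by a 2001-point coarse scan followed by
  bounded scalar refinement to 1e-8 in X_gs. A boundary minimum is
  legitimate and reported. The regular-area fraction is
  A_reg = N_s/(N_s + N_u).

The interaction term depends on (z, eps) only through the products z·eps,
so coordination number is a pure reparameterization (verified to 1e-9
relative in the tests); z defaults to 4 with the per-contact
`eps_us = 484.1 cal/mol`. The cooperativity energies w of cluster
aggregation are not recomputed from first principles; they are shipped as
a reference table per M (9..25, two gramicidin state-energy variants,
tabulated at z = 4 and scaled by 2/3 at z = 6).

Parameter defaults and units:

| parameter | default | units | meaning |
|---|---|---|---|
| z | 4 | – | lattice coordination number |
| eps_ss, eps_uu | 0 | cal/mol | like-unit contact energies |
| eps_us | 484.1 | cal/mol | rigid-fluid contact energy |
| delta_cluster | -3000 | cal/mol per cluster | condensation free energy |
| eps_gs_minus_gu | 0 (alt. -1000) | cal/mol | peptide state energy difference |
| temperature | 310.15 | K | 37 °C |
| n_tot | 1e4 | molecules/leaflet | system size |
| R (gas constant) | 1.98720 | cal/(mol·K) | |

`delta_cluster = -3000 cal/mol` was fixed once so that condensation
dominates the mixing entropy at 310 K, leaving A_reg ≥ 0.98 at the
critical fraction (the physically expected near-complete dimerization);
it is the main tunable of the model. With these defaults A_reg(X_g) is
biphasic with its local maximum at X_cr(M), the two eps_gs_minus_gu
variants differ by < 0.02 in A_reg, and below X_cr(12) = 0.143 the
separate linear regime A_reg = X_g/0.143 applies (each dimer still binds
12 lipids; only the aggregate area shrinks). Above the solubility limit
X = 0.154 the peptide precipitates and the model is flagged inapplicable.

Units hidden in the leaflet convention: the model works per leaflet
(one cluster = 1 gramicidin + M/2 lipids), whereas the explicit
configuration accounting and the fluid-unit occupancies count whole
bilayer units (2·A_M of lipid area, dimers worth 2 gramicidins); the two
conventions meet only in dimensionless outputs (X_g, A_reg, dimer
fraction).

## Phasor analysis

Phase phi (stored in degrees in files, radians internally) and
demodulation M at modulation frequency f map to G = M cos phi,
S = M sin phi. The omega–tau bridge is omega·tau = 2·pi·f_MHz·tau_ns·1e-3.
First-order propagation gives

    dG = G sqrt(s_Mr^2 + (phi s_phir tan phi)^2)
    dS = S sqrt(s_Mr^2 + (phi s_phir cot phi)^2)

with phi in radians (so phi·s_phir is the absolute phase error); this
matches Monte-Carlo propagation of independent relative Gaussian errors
to within 5% for errors up to ~1%, and is singular at 0 and 90 degrees.

Calibration against a lifetime standard (PPO in ethanol, tau = 1.46 ns)
subtracts the reference's measured phase and divides by its measured
modulation, then applies the standard's exact single-exponential
response; instrument phase offsets and modulation factors cancel.

Replicates are aggregated phasor-first: the phasor of each replicate is
computed, then G and S are averaged (not the phases/modulations), which
shrinks scatter by ~1/sqrt(n).

The biphasic scan operationalizes the "~0.01 movement is significant"
rule as the Euclidean distance between the candidate fraction's phasor
dot and the centroid of all other fractions at one frequency (an
axis-wise variant is available by flag); the biphasic flag additionally
requires the shift to be leftward (lower G = longer lifetime). The
multi-exponential lifetime fit is deliberately auxiliary — the phasor
representation itself is model-independent — and uses error-weighted
least squares on phase/modulation residuals with a fixed-seed multi-start
to stay deterministic.

## Laurdan GP

GP = (I435 - I500)/(I435 + I500), with band intensities linearly
interpolated on the wavelength grid and blanks subtracted point-wise.
The series dip test — (neighbour mean − candidate mean)/pooled replicate
SD > 2 — is plumbing for automated screening; it is deliberately crude
because the scientific claim it checks here is a *flat* series
(gramicidin, unlike cholesterol, produces no GP dip at critical
fractions).

## Synthetic data

The generators define the study conditions and are deterministic under a
fixed seed:

* **Phasor sweeps**: a two-exponential baseline decay
  (tau = 1.2/4.5 ns, fractions 0.45/0.55 — a plausible two-lifetime
  summary of multi-tryptophan emission) on the 15-frequency 2–200 MHz
  grid; mole fractions 0.139–0.147 in steps of 0.002, three replicates.
  At critical fractions (default {0.143, 0.154}) intensity weight is
  transferred from the short- to the long-lifetime component, solved by
  bisection so the phasor at 200 MHz is displaced by exactly 0.013 —
  just above the 0.01 significance rule, keeping detection non-trivial.
  Phase and modulation carry independent multiplicative Gaussian noise of
  relative SD 0.002 (the instrument's stated 0.2% maximum standard
  error); modulation is truncated to (0, 1], which slightly deflates the
  realized noise at near-unity modulation (lowest frequencies).
* **Radial profile**: g(r) = 1 + A[peak Gaussian at 10.5 A −
  0.5·depletion Gaussian at the peptide surface], 7.5–30 A in 0.05 A
  steps; the amplitude A is solved in closed form (the integral is linear
  in A) so that N(r) = 6 lipids/leaflet exactly at the radius of a
  520.1 A^2 cluster, reproducing the M = 12 geometry to well within the
  0.5% calibration tolerance. The shape emulates the depletion-then-peak
  packing seen next to a dimer; it is a calibrated stand-in, not a
  simulation output.
* **Laurdan spectra**: two Gaussian bands at 435/500 nm (widths 22/32 nm)
  whose amplitudes invert the GP formula exactly for the target GP
  (default 0.05, flat across fractions — fluid-phase DMPC has near-zero
  GP and gramicidin does not raise it); optional planted dip; additive
  noise at 0.2% of peak; constant-plus-noise blanks.

What the generators do **not** emulate: tryptophan rotamer photophysics,
instrument response functions, frequency-correlated noise, scattering
backgrounds, or any real non-monotonicity of lipid order beyond the
single depletion/peak feature. Passing tests therefore demonstrate the
correctness and sensitivity of the analysis chain under the stated noise
model, not its robustness to instrument artifacts.

## Numerical choices

* Trapezoid quadrature on the native grid; bisection root-finding
  (tolerances 1e-9 in N, 1e-8 in X_gs).
* 0·ln 0 = 0 at all entropy boundaries; N_u clipped at 0 against float
  round-off at the stoichiometric point.
* Temperatures in Celsius are converted by +273.15; R = 1.98720
  cal/(mol·K).
* Text I/O is comma-separated with '#' comments; floats are written at
  %.17g and parsed with round-trip precision so write/read cycles are
  bit-exact.
* Problem sizes used by the tests and the acceptance script: N_tot = 1e4
  molecules per leaflet, 2001-point minimizer scans (1e5-point grids as
  the independent oracle), 1e5-draw Monte-Carlo error propagation,
  200-seed detection and 1000-seed null batteries — sizes at which all
  reported statistics are stable to well under their tolerances.

## Known limitations

* The free-energy reconstruction folds all internal unit energies and
  entropies into one parameter; only the structure of the mixing terms
  and the z·eps invariance are constrained by the model's published
  behaviour, so absolute free energies (as opposed to minimizer locations
  and A_reg) should not be over-interpreted.
* One cluster size M per run: coexistence of cluster sizes between
  critical fractions is out of scope, so the model is meaningful only
  near X_cr(M).
* The cooperativity table is reference data, not a computation.
* The biphasic significance rule is a fixed-threshold heuristic, not a
  calibrated hypothesis test.
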