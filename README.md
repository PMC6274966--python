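# gramlattice

Statistical-mechanical modelling and fluorescence analysis of
gramicidin/DMPC membranes.

Gramicidin is a 15-residue channel peptide whose dimers span a
phospholipid bilayer and condense the surrounding
dimyristoylphosphatidylcholine (DMPC) acyl chains into "rigid clusters".
At particular peptide mole fractions the cluster stoichiometry is exactly
satisfied membrane-wide and the clusters aggregate into regularly packed
(superlattice) domains. `gramlattice` implements, as a tested and fully
synthetic-data-driven pipeline:

* **condensation** — condensed-lipid counts from a radial distribution
  g(r), via N(R) = ρ ∫ g(r) 2πr dr; cluster radius/area; the critical mole
  fractions X<sub>cr</sub>(M) = 1/(1 + M/2); lattice-unit occupancies.
* **lattice_model** — a mean-field (Bragg–Williams) lattice free energy
  F(X<sub>gs</sub>) of rigid-cluster vs. fluid units, minimized by the
  maximum-term method; the regular-area fraction
  A<sub>reg</sub> = ⟨N<sub>s</sub>⟩/(⟨N<sub>s</sub>⟩+⟨N<sub>u</sub>⟩),
  which peaks biphasically at X<sub>cr</sub>(M); explicit worked lattice
  configurations; the sub-critical linear regime; tabulated aggregation
  cooperativity energies.
* **phasor** — frequency-domain lifetime analysis: G = M·cosφ,
  S = M·sinφ phasor coordinates with first-order error propagation,
  multi-exponential phasor prediction, calibration against a
  single-exponential lifetime standard (PPO, τ = 1.46 ns), least-squares
  lifetime fitting, and a biphasic-shift scan across a mole-fraction
  series (significant = displacement ≥ 0.01, leftward = longer lifetime).
* **laurdan** — generalized polarization
  GP = (I₄₃₅ − I₅₀₀)/(I₄₃₅ + I₅₀₀) from emission spectra, plus a dip test
  over a mole-fraction series.
* **synthetic_data** — seeded generators for all of the above (decay
  sweeps with planted critical-fraction shifts, a calibrated radial
  profile, two-band Laurdan spectra).
* **io / cli** — delimited-text readers/writers and a `gramlattice`
  command-line tool (`simulate`, `phasor`, `biphasic`, `model`,
  `condense`, `gp`).

## Worked example

```python
from gramlattice import (
    cluster_geometry, LatticeConfiguration, configuration_stats,
    MixtureComposition, equilibrium,
)
from gramlattice.condensation import fluid_unit_occupancy
from gramlattice.synthetic_data import simulate_radial_profile

profile = simulate_radial_profile()          # calibrated g(r)
geom = cluster_geometry(12, profile)         # M = 12 rigid cluster
print(round(geom.area, 1), round(geom.a_condensed, 2), round(geom.x_cr, 3))
# 520.1 57.23 0.143

print(round(fluid_unit_occupancy(geom, 1), 2))
# 13.93

config = LatticeConfiguration(12, n_rigid=386, n_fluid2=12, n_fluid1=2)
x_g, a_reg, dimer = configuration_stats(config, geom)
print(round(x_g, 4), a_reg, round(dimer, 2))
# 0.1427 0.965 96.74

state = equilibrium(MixtureComposition(geom.x_cr), geom)
print(round(state.a_reg, 3), round(state.dimer_fraction, 3))
# 0.993 0.994
```

The first block says that a dimer with 12 condensed chains per leaflet
occupies 520.1 Å², each condensed lipid 57.23 Å², and that the cluster
stoichiometry is exact at a 0.143 peptide mole fraction. The explicit
400-unit configuration has composition 0.1427, 96.5% of its area
regularly packed and 96.74% of its gramicidin dimeric. The equilibrium
free-energy minimum at the critical fraction leaves 99.3% of the membrane
area in the regular phase with 99.4% of the peptide in dimers.

End-to-end from the shell:

```sh
gramlattice simulate --seed 1 --out data/
gramlattice biphasic --sweeps data/sweeps.csv --at 0.143
# candidate=0.143 displacement=0.01358 leftward=True biphasic=True
```

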