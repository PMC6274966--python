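"""Sludge-like superlattice lattice model of peptide/lipid membranes.

The bilayer is a lattice of units of area A_M (the rigid-cluster
cross-section).  A unit is either a rigid cluster -- a gramicidin dimer with
M hydrocarbon chains per leaflet condensed to it (the low-energy, low-entropy
s state) -- or a patch of fluid phase holding 0-2 freely diffusing monomers
(u state).  Written per leaflet for N_tot molecules, with X_gs the mole
fraction of gramicidins sitting in rigid clusters:

* fluid-unit count       N_u = N_tot[(X_g - X_gs) A_g + (1 - X_g - X_gs M/2) A_pf] / A_M
* free energy            F(X_gs) = N_s (delta_cluster + eps_gs-gu)
                                   + (z/2N)(N_s^2 e_ss + 2 N_s N_u e_us + N_u^2 e_uu)
                                   - T (S_mix,units + S_mix,fluid)
* regular-area fraction  A_reg = N_s / (N_s + N_u)

The minimum of F over the admissible interval [0, min(X_g, 2(1-X_g)/M)]
(maximum-term method) gives the equilibrium state.  Results depend on the
interaction energies only through the products z*eps, and A_reg peaks at the
critical mole fraction X_cr(M) = 1/(1 + M/2).

Internal cluster energies and entropies are folded into the single
condensation free energy ``delta_cluster`` (cal/mol per cluster); the
cooperativity energies w for cluster aggregation are shipped as tabulated
reference data per chain count M.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import xlogy

from .condensation import ClusterGeometry, fluid_unit_occupancy

__all__ = [
    "GAS_CONSTANT_CAL",
    "SOLUBILITY_LIMIT",
    "EnergyParams",
    "MixtureComposition",
    "EquilibriumState",
    "LatticeConfiguration",
    "n_fluid_units",
    "free_energy",
    "equilibrium",
    "area_fraction",
    "areg_curve",
    "subcritical_areg",
    "configuration_stats",
    "w_reference",
    "solubility_check",
]

#: gas constant, cal / (mol K)
GAS_CONSTANT_CAL = 1.98720
#: gramicidin solubility limit in DMPC (mole fraction); X_cr at M = 11
SOLUBILITY_LIMIT = 0.154
#: junction of the sub-critical linear regime, X_cr at M = 12 (printed value)
_XCR12 = 0.143


@dataclass(frozen=True)
class EnergyParams:
    """Thermodynamic parameters of the lattice model (cal/mol, K).

    ``eps_ss``, ``eps_us``, ``eps_uu`` are per-contact unit-unit interaction
    energies on a lattice of coordination number ``z``; only the products
    z*eps matter.  ``delta_cluster`` is the free energy of assembling one
    rigid cluster from one fluid gramicidin and M/2 fluid lipids (per
    leaflet); ``eps_gs_minus_gu`` is the energy difference of a gramicidin
    in the cluster vs. fluid state.
    """

    z: int = 4
    eps_ss: float = 0.0
    eps_us: float = 484.1
    eps_uu: float = 0.0
    delta_cluster: float = -3000.0
    eps_gs_minus_gu: float = 0.0
    temperature: float = 310.15

    def __post_init__(self) -> None:
        if self.z < 3:
            raise ValueError("coordination number z must be >= 3")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive (K)")


@dataclass(frozen=True)
class MixtureComposition:
    """Overall composition of one leaflet: peptide mole fraction and size."""

    x_g: float
    n_tot: float = 1e4

    def __post_init__(self) -> None:
        if not 0.0 < self.x_g < 1.0:
            raise ValueError("x_g must lie in (0, 1)")
        if self.n_tot <= 0:
            raise ValueError("n_tot must be positive")

    @property
    def n_gramicidin(self) -> float:
        return self.x_g * self.n_tot

    @property
    def n_lipid(self) -> float:
        return (1.0 - self.x_g) * self.n_tot


@dataclass(frozen=True)
class EquilibriumState:
    """Free-energy-minimizing state of the lattice."""

    x_gs: float
    n_s: float
    n_u: float
    free_energy: float
    a_reg: float
    dimer_fraction: float


@dataclass(frozen=True)
class LatticeConfiguration:
    """Explicit unit counts of a hand-built lattice configuration."""

    m_chains: int
    n_rigid: int
    n_fluid2: int = 0
    n_fluid1: int = 0
    n_fluid0: int = 0
    lipids_per_rigid: float | None = None  # bilayer total; default M

    def __post_init__(self) -> None:
        for name in ("n_rigid", "n_fluid2", "n_fluid1", "n_fluid0"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.lipids_per_rigid is None:
            object.__setattr__(self, "lipids_per_rigid", float(self.m_chains))

    @property
    def total_units(self) -> int:
        return self.n_rigid + self.n_fluid2 + self.n_fluid1 + self.n_fluid0


def _x_gs_bound(x_g: float, m_chains: int) -> float:
    """Upper end of the admissible interval for x_gs."""
    return min(x_g, 2.0 * (1.0 - x_g) / m_chains)


def n_fluid_units(
    comp: MixtureComposition, x_gs: float, geometry: ClusterGeometry
) -> float:
    """Number of fluid lattice units per leaflet at cluster fraction x_gs.

    Fluid area = area of the (X_g - X_gs)N_tot monomers plus the
    uncondensed lipids, divided by the unit area A_M.  Vanishes exactly at
    the stoichiometric point x_gs = x_g = X_cr(M).
    """
    m = geometry.m_chains
    hi = _x_gs_bound(comp.x_g, m)
    if not -1e-12 <= x_gs <= hi + 1e-12:
        raise ValueError(f"x_gs={x_gs} outside admissible [0, {hi:.6g}]")
    bracket = (comp.x_g - x_gs) * geometry.a_gram + (
        1.0 - comp.x_g - x_gs * m / 2.0
    ) * geometry.a_fluid_lipid
    return max(comp.n_tot * bracket / geometry.area, 0.0)


def free_energy(
    x_gs,
    comp: MixtureComposition,
    geometry: ClusterGeometry,
    params: EnergyParams,
):
    """Leaflet free energy F(x_gs) in cal/mol (per N_tot molecules).

    Accepts a scalar or an array of x_gs values; finite on the closed
    admissible interval with the convention 0*log(0) = 0.
    """
    x_gs_arr = np.atleast_1d(np.asarray(x_gs, dtype=float))
    m = geometry.m_chains
    n_tot = comp.n_tot
    rt = GAS_CONSTANT_CAL * params.temperature

    n_s = x_gs_arr * n_tot
    bracket = (comp.x_g - x_gs_arr) * geometry.a_gram + (
        1.0 - comp.x_g - x_gs_arr * m / 2.0
    ) * geometry.a_fluid_lipid
    n_u = np.maximum(n_tot * bracket / geometry.area, 0.0)
    n_units = n_s + n_u

    # cluster formation + gramicidin state energy
    f = n_s * (params.delta_cluster + params.eps_gs_minus_gu)

    # Bragg-Williams nearest-neighbour interaction between lattice units
    with np.errstate(divide="ignore", invalid="ignore"):
        e_i = np.where(
            n_units > 0,
            (params.z / (2.0 * np.maximum(n_units, 1e-300)))
            * (
                n_s**2 * params.eps_ss
                + 2.0 * n_s * n_u * params.eps_us
                + n_u**2 * params.eps_uu
            ),
            0.0,
        )
    f = f + e_i

    # -T * mixing entropy of s and u units on the lattice
    frac_s = np.where(n_units > 0, n_s / np.maximum(n_units, 1e-300), 0.0)
    frac_u = np.where(n_units > 0, n_u / np.maximum(n_units, 1e-300), 0.0)
    f = f + rt * (xlogy(n_s, frac_s) + xlogy(n_u, frac_u))

    # -T * mixing entropy of monomers and lipids within the fluid phase
    n_gf = np.maximum((comp.x_g - x_gs_arr) * n_tot, 0.0)
    l_f = np.maximum((1.0 - comp.x_g - x_gs_arr * m / 2.0) * n_tot, 0.0)
    fluid = n_gf + l_f
    x_gf = np.where(fluid > 0, n_gf / np.maximum(fluid, 1e-300), 0.0)
    x_lf = np.where(fluid > 0, l_f / np.maximum(fluid, 1e-300), 0.0)
    f = f + rt * (xlogy(n_gf, x_gf) + xlogy(l_f, x_lf))

    return float(f[0]) if np.isscalar(x_gs) or np.asarray(x_gs).ndim == 0 else f


def area_fraction(n_s: float, n_u: float) -> float:
    """Regular-area fraction A_reg = N_s / (N_s + N_u)."""
    if n_s < 0 or n_u < 0:
        raise ValueError("unit counts must be non-negative")
    total = n_s + n_u
    if total == 0:
        raise ValueError("A_reg undefined when there are no lattice units")
    return n_s / total


def equilibrium(
    comp: MixtureComposition,
    geometry: ClusterGeometry,
    params: EnergyParams | None = None,
) -> EquilibriumState:
    """Minimize F over the admissible x_gs interval (maximum-term method).

    A 2001-point coarse scan brackets the minimum, then bounded
    golden-section/Brent refinement narrows it to 1e-8 in x_gs.  A boundary
    minimum is legitimate and reported as found.
    """
    params = params or EnergyParams()
    x_cr = geometry.x_cr
    if not 0.8 * x_cr <= comp.x_g <= 1.2 * x_cr:
        warnings.warn(
            f"x_g={comp.x_g:.4g} is far from X_cr(M={geometry.m_chains})="
            f"{x_cr:.4g}; the single-cluster-type model may not apply",
            stacklevel=2,
        )
    hi = _x_gs_bound(comp.x_g, geometry.m_chains)
    grid = np.linspace(0.0, hi, 2001)
    f_grid = free_energy(grid, comp, geometry, params)
    i = int(np.argmin(f_grid))
    lo_b = grid[max(i - 1, 0)]
    hi_b = grid[min(i + 1, grid.size - 1)]
    if lo_b == hi_b:
        x_opt = grid[i]
    else:
        res = minimize_scalar(
            lambda x: float(free_energy(np.array([x]), comp, geometry, params)[0]),
            bounds=(lo_b, hi_b),
            method="bounded",
            options={"xatol": 1e-8},
        )
        x_opt = float(res.x)
        if free_energy(grid[i], comp, geometry, params) < free_energy(
            x_opt, comp, geometry, params
        ):
            x_opt = float(grid[i])
    n_s = x_opt * comp.n_tot
    n_u = n_fluid_units(comp, min(x_opt, hi), geometry)
    return EquilibriumState(
        x_gs=x_opt,
        n_s=n_s,
        n_u=n_u,
        free_energy=float(free_energy(x_opt, comp, geometry, params)),
        a_reg=area_fraction(n_s, n_u),
        dimer_fraction=x_opt / comp.x_g,
    )


def areg_curve(
    geometry: ClusterGeometry,
    params: EnergyParams | None = None,
    x_g_grid=None,
    n_tot: float = 1e4,
) -> list[tuple[float, float]]:
    """A_reg versus X_g on a grid around the critical mole fraction.

    With default parameters the curve is biphasic: a single local maximum at
    the grid point nearest X_cr(M), decreasing on both sides.
    """
    if x_g_grid is None:
        x_cr = geometry.x_cr
        x_g_grid = np.linspace(0.95 * x_cr, 1.05 * x_cr, 21)
    out = []
    for x_g in np.asarray(x_g_grid, dtype=float):
        state = equilibrium(MixtureComposition(float(x_g), n_tot), geometry, params)
        out.append((float(x_g), state.a_reg))
    return out


def subcritical_areg(x_g: float) -> float:
    """Linear A_reg regime below the lowest critical mole fraction.

    Below X_cr(12) = 0.143 every dimer still condenses 12 lipids, so the
    aggregate area shrinks linearly: A_reg = x_g / 0.143, clipped to [0, 1].
    """
    if x_g < 0:
        raise ValueError("x_g must be non-negative")
    if x_g > _XCR12:
        raise ValueError(
            f"x_g={x_g} above the linear regime bound {_XCR12}; use equilibrium()"
        )
    return min(max(x_g / _XCR12, 0.0), 1.0)


def configuration_stats(
    config: LatticeConfiguration, geometry: ClusterGeometry
) -> tuple[float, float, float]:
    """(x_g, a_reg, dimer_percent) of an explicit bilayer configuration.

    Gramicidins: 2 per rigid cluster (dimer) plus the fluid monomers.
    Lipids: the condensed lipids of each cluster (bilayer total) plus the
    fluid-unit occupancies from the cluster geometry.
    """
    if config.total_units == 0:
        raise ValueError("configuration has no lattice units")
    gram = 2.0 * config.n_rigid + 2.0 * config.n_fluid2 + config.n_fluid1
    lipids = config.n_rigid * config.lipids_per_rigid
    for n_mono, count in ((2, config.n_fluid2), (1, config.n_fluid1), (0, config.n_fluid0)):
        if count:
            lipids += count * fluid_unit_occupancy(geometry, n_mono)
    if gram + lipids == 0:
        raise ValueError("empty configuration")
    x_g = gram / (gram + lipids)
    a_reg = config.n_rigid / config.total_units
    dimer_percent = 100.0 * 2.0 * config.n_rigid / gram if gram else 0.0
    return x_g, a_reg, dimer_percent


# Cooperativity energy w (cal/mol) of rigid-cluster aggregation at z = 4,
# tabulated per chain count M for the two gramicidin state-energy variants.
_W_TABLE: dict[int, tuple[float, float]] = {
    9: (489.2, 447.0),
    10: (486.8, 444.1),
    11: (485.2, 442.3),
    12: (484.1, 441.5),
    13: (483.7, 441.4),
    14: (483.8, 442.0),
    15: (484.3, 443.2),
    16: (485.3, 444.9),
    17: (486.6, 447.0),
    18: (488.3, 450.0),
    19: (490.2, 452.4),
    20: (492.4, 455.5),
    21: (494.8, 459.0),
    22: (497.4, 462.5),
    23: (500.3, 466.4),
    24: (503.3, 470.4),
    25: (506.4, 474.5),
}


def w_reference(m_chains: int, variant: int = 0, z: int = 4) -> float:
    """Tabulated cooperativity energy w for chain count M, cal/mol.

    ``variant`` selects the gramicidin state-energy difference the table was
    computed at (0 or -1000 cal/mol).  Values are tabulated at z = 4; at
    z = 6 they scale by 2/3 (fixed z*w product).
    """
    if m_chains not in _W_TABLE:
        raise ValueError(f"w not tabulated for M={m_chains} (range 9..25)")
    if variant not in (0, -1000):
        raise ValueError("variant must be 0 or -1000 (cal/mol)")
    if z not in (4, 6):
        raise ValueError("w is defined for z in {4, 6}")
    w4 = _W_TABLE[m_chains][0 if variant == 0 else 1]
    return w4 * (2.0 / 3.0) if z == 6 else w4


def solubility_check(x_g: float) -> bool:
    """Flag (and warn) when x_g exceeds the 0.154 solubility limit.

    Above X_cr(11) = 0.154 gramicidin precipitates from the DMPC matrix as
    fiber-like material; the lattice model no longer applies.  The boundary
    itself is soluble.  Returns True when flagged.
    """
    if not 0.0 <= x_g < 1.0:
        raise ValueError("x_g must lie in [0, 1)")
    if x_g > SOLUBILITY_LIMIT:
        warnings.warn(
            f"x_g={x_g:.4g} exceeds the solubility limit {SOLUBILITY_LIMIT}: "
            "precipitation regime",
            stacklevel=2,
        )
        return True
    return False
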