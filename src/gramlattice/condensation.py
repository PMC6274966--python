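"""Condensing-effect stoichiometry of gramicidin dimers in a DMPC bilayer.

A gramicidin dimer condenses the acyl chains of neighbouring DMPC molecules
onto its side surface.  Given the radial distribution g(r) of lipids around
a dimer, the cumulative number of condensed lipids per leaflet within radius
R is

    N(R) = rho_bulk * \\int_{R_g}^{R} g(r) 2 pi r dr

where ``rho_bulk`` is the areal lipid density far from the peptide and
``R_g`` the peptide radius.  Inverting N(R) gives the radius, area and
lipid cross-section of a "rigid cluster" of M condensed hydrocarbon chains
per leaflet, and the critical mole fraction X_cr(M) = 1/(1 + M/2) at which
the cluster stoichiometry is exactly satisfied membrane-wide.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RadialProfile",
    "ClusterGeometry",
    "cumulative_condensed",
    "cluster_radius",
    "cluster_geometry",
    "critical_mole_fraction",
    "chains_for",
    "fluid_unit_occupancy",
    "side_surface_ratio",
    "DEFAULT_A_FLUID_LIPID",
    "DEFAULT_R_GRAM",
]

#: cross-sectional area of one fluid-phase DMPC, A^2
DEFAULT_A_FLUID_LIPID = 62.0
#: gramicidin radius, A
DEFAULT_R_GRAM = 7.5


@dataclass(frozen=True)
class RadialProfile:
    """Tabulated radial distribution g(r) of lipid around a peptide dimer.

    Parameters
    ----------
    r_grid : array-like
        Radial distances in Angstrom, strictly increasing; the first point
        must not lie below ``r_gram``.
    g_values : array-like
        Dimensionless radial distribution, same length as ``r_grid``,
        non-negative.
    rho_bulk : float
        Areal lipid density far from the peptide, A^-2.
    r_gram : float
        Peptide (gramicidin) radius in Angstrom; lower integration limit.
    """

    r_grid: np.ndarray
    g_values: np.ndarray
    rho_bulk: float = 1.0 / DEFAULT_A_FLUID_LIPID
    r_gram: float = DEFAULT_R_GRAM

    def __post_init__(self) -> None:
        r = np.asarray(self.r_grid, dtype=float)
        g = np.asarray(self.g_values, dtype=float)
        if r.ndim != 1 or g.shape != r.shape:
            raise ValueError("r_grid and g_values must be 1-D and equally long")
        if r.size < 2:
            raise ValueError("need at least two grid points")
        if not np.all(np.diff(r) > 0):
            raise ValueError("r_grid must be strictly increasing")
        if np.any(g < 0):
            raise ValueError("g_values must be non-negative")
        if r[0] < self.r_gram - 1e-9:
            raise ValueError(
                f"first grid point {r[0]} lies below r_gram={self.r_gram}"
            )
        if self.rho_bulk <= 0:
            raise ValueError("rho_bulk must be positive")
        object.__setattr__(self, "r_grid", r)
        object.__setattr__(self, "g_values", g)

    def is_bulk_terminated(self, tol: float = 0.05) -> bool:
        """Whether g approaches its bulk value 1 at the largest radius."""
        return abs(float(self.g_values[-1]) - 1.0) <= tol


@dataclass(frozen=True)
class ClusterGeometry:
    """Geometry of a rigid cluster of M condensed chains around a dimer."""

    m_chains: int
    radius: float  # A
    area: float  # A^2, pi R^2
    x_cr: float  # critical mole fraction 1/(1+M/2)
    a_condensed: float  # cross-section of one condensed lipid, A^2
    a_gram: float  # pi r_gram^2, A^2
    a_fluid_lipid: float = DEFAULT_A_FLUID_LIPID

    def __post_init__(self) -> None:
        if self.m_chains < 1:
            raise ValueError("m_chains must be >= 1")
        if not np.isclose(self.area, np.pi * self.radius**2, rtol=1e-9):
            raise ValueError("area must equal pi * radius^2")
        if self.a_condensed <= 0:
            raise ValueError("condensed-lipid cross-section must be positive")


def _interp_g(profile: RadialProfile, r: float) -> float:
    return float(np.interp(r, profile.r_grid, profile.g_values))


def cumulative_condensed(profile: RadialProfile, r: float) -> float:
    """Cumulative condensed-lipid count per leaflet within radius ``r``.

    Composite trapezoid on the tabulated grid with linear interpolation at
    both endpoints.  Non-negative and non-decreasing in ``r``.
    """
    r = float(r)
    lo = profile.r_gram
    grid, g = profile.r_grid, profile.g_values
    if r < lo - 1e-12:
        raise ValueError(f"r={r} below the peptide radius {lo}")
    if r > grid[-1] + 1e-12:
        raise ValueError(f"r={r} beyond the tabulated grid end {grid[-1]}")
    r = min(max(r, lo), float(grid[-1]))
    if r <= lo:
        return 0.0
    # assemble integration nodes: lo, interior grid points, r
    interior = grid[(grid > lo) & (grid < r)]
    nodes = np.concatenate(([lo], interior, [r]))
    vals = np.interp(nodes, grid, g)
    integrand = vals * 2.0 * np.pi * nodes
    return float(profile.rho_bulk * np.trapezoid(integrand, nodes))


def cluster_radius(profile: RadialProfile, n_lipids_per_layer: float) -> float:
    """Radius enclosing ``n_lipids_per_layer`` condensed lipids (per leaflet).

    Monotone bisection solve of ``cumulative_condensed(r) = n`` to
    |dN| < 1e-9.  Raises if ``n`` exceeds the count at the grid end.
    """
    n = float(n_lipids_per_layer)
    if n < 0:
        raise ValueError("lipid count must be non-negative")
    if n == 0.0:
        return profile.r_gram
    lo, hi = profile.r_gram, float(profile.r_grid[-1])
    n_max = cumulative_condensed(profile, hi)
    if n > n_max + 1e-9:
        raise ValueError(
            f"n={n} not achievable on this profile (max {n_max:.6g} at grid end)"
        )
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        val = cumulative_condensed(profile, mid)
        if abs(val - n) < 1e-9:
            return mid
        if val < n:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-13:
            break
    return 0.5 * (lo + hi)


def critical_mole_fraction(m_chains: int) -> float:
    """Critical peptide mole fraction X_cr(M) = 1/(1 + M/2)."""
    if m_chains < 1:
        raise ValueError("m_chains must be >= 1")
    return 1.0 / (1.0 + m_chains / 2.0)


def chains_for(x: float) -> float:
    """Chain count M achieving critical mole fraction ``x``: M = 2(1-x)/x."""
    if not 0.0 < x < 1.0:
        raise ValueError("mole fraction must lie in (0, 1)")
    return 2.0 * (1.0 - x) / x


def cluster_geometry(
    m_chains: int,
    profile: RadialProfile,
    a_fluid_lipid: float = DEFAULT_A_FLUID_LIPID,
) -> ClusterGeometry:
    """Full geometry of the rigid cluster with ``m_chains`` chains per leaflet.

    ``m_chains/2`` lipids per leaflet are condensed (each lipid has two
    chains); the condensed-lipid cross-section follows from the annulus
    between the peptide and the cluster edge.
    """
    if m_chains < 1:
        raise ValueError("m_chains must be >= 1")
    n_per_layer = m_chains / 2.0
    radius = cluster_radius(profile, n_per_layer)
    area = np.pi * radius**2
    a_gram = np.pi * profile.r_gram**2
    a_condensed = (area - a_gram) / n_per_layer
    return ClusterGeometry(
        m_chains=m_chains,
        radius=radius,
        area=area,
        x_cr=critical_mole_fraction(m_chains),
        a_condensed=a_condensed,
        a_gram=a_gram,
        a_fluid_lipid=a_fluid_lipid,
    )


def fluid_unit_occupancy(geometry: ClusterGeometry, n_monomers: int) -> float:
    """DMPC molecules in a bilayer fluid lattice unit with 0-2 monomers.

    The unit spans both leaflets (area 2*A_M); each peptide monomer occupies
    one leaflet, displacing lipid area ``a_gram``.
    """
    if n_monomers not in (0, 1, 2):
        raise ValueError("a fluid unit holds 0, 1 or 2 monomers")
    return (2.0 * geometry.area - n_monomers * geometry.a_gram) / geometry.a_fluid_lipid


def side_surface_ratio(len_a: float, r_a: float, len_b: float, r_b: float) -> float:
    """Ratio of lateral (side) surface areas of two cylindrical molecules."""
    if min(len_a, r_a, len_b, r_b) <= 0:
        raise ValueError("lengths and radii must be positive")
    return (r_a * len_a) / (r_b * len_b)
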