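"""Frequency-domain fluorescence lifetime analysis on the phasor plot.

Phase delay phi and demodulation M measured at modulation frequency f map to
the phasor coordinates G = M cos(phi), S = M sin(phi).  Single-exponential
decays lie on the "universal circle" (G - 1/2)^2 + S^2 = 1/4; multi-
exponential decays fall strictly inside it, at the intensity-weighted convex
combination of their components:

    G = sum_i f_i / (1 + (w tau_i)^2),   S = sum_i f_i w tau_i / (1 + (w tau_i)^2)

with w = 2 pi f.  A leftward (lower-G) displacement of a sample's phasor dot
means a longer average lifetime.  Uncertainties on G and S follow from the
relative errors of M and phi by first-order propagation:

    dG = G sqrt(s_Mr^2 + (phi s_phir tan phi)^2)
    dS = S sqrt(s_Mr^2 + (phi s_phir cot phi)^2)

The biphasic scan flags a candidate mole fraction whose phasor dot moves
significantly (>= 0.01) and leftward relative to its neighbours -- the
signature of a critical superlattice composition.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "STANDARD_FREQUENCIES_MHZ",
    "SIGNIFICANT_SHIFT",
    "PPO_LIFETIME_NS",
    "FrequencySweep",
    "PhasorPoint",
    "DecayModel",
    "BiphasicReport",
    "to_phasor",
    "phasor_uncertainty",
    "decay_to_phasor",
    "reference_calibration",
    "fit_lifetimes",
    "biphasic_scan",
    "average_phasors",
]

#: standard 15-point modulation frequency grid, MHz
STANDARD_FREQUENCIES_MHZ = (
    200.00, 143.94, 103.59, 74.55, 53.65, 38.61, 27.79, 20.00,
    14.39, 10.36, 7.46, 5.37, 3.86, 2.78, 2.00,
)
#: movement of a phasor dot on the G or S axis that counts as significant
SIGNIFICANT_SHIFT = 0.01
#: lifetime of the PPO-in-ethanol reference standard, ns
PPO_LIFETIME_NS = 1.46


def _omega(frequency_mhz: float) -> float:
    """Angular frequency in rad/ns for a modulation frequency in MHz."""
    return 2.0 * math.pi * frequency_mhz * 1e-3


@dataclass(frozen=True)
class PhasorPoint:
    """A point (G, S) on the phasor plot with propagated uncertainties."""

    g: float
    s: float
    dg: float = 0.0
    ds: float = 0.0
    frequency: float = float("nan")  # MHz

    def inside_universal_circle(self, tol: float = 0.0) -> bool:
        return (self.g - 0.5) ** 2 + self.s**2 <= 0.25 + tol

    def __post_init__(self) -> None:
        if self.dg < 0 or self.ds < 0:
            raise ValueError("uncertainties must be non-negative")
        if self.g**2 + self.s**2 > 1.0 + 1e-9:
            warnings.warn(
                f"phasor ({self.g:.4g}, {self.s:.4g}) lies outside the unit "
                "circle; unphysical for single-detector data",
                stacklevel=2,
            )


@dataclass(frozen=True)
class DecayModel:
    """Multi-exponential intensity decay: (lifetime ns, fractional intensity)."""

    components: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        comps = tuple((float(t), float(f)) for t, f in self.components)
        if not comps:
            raise ValueError("at least one decay component required")
        if any(t <= 0 for t, _ in comps):
            raise ValueError("lifetimes must be positive (ns)")
        if any(f < 0 for _, f in comps):
            raise ValueError("fractional intensities must be non-negative")
        total = sum(f for _, f in comps)
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"fractional intensities sum to {total}, not 1")
        object.__setattr__(self, "components", comps)

    @property
    def mean_lifetime(self) -> float:
        """Intensity-weighted mean lifetime, ns."""
        return sum(t * f for t, f in self.components)


@dataclass
class FrequencySweep:
    """Phase/modulation measurements of one sample over a frequency sweep.

    Phase is stored in degrees (file convention) and converted to radians
    internally wherever trigonometry is involved.
    """

    frequency_mhz: np.ndarray
    phase_deg: np.ndarray
    modulation: np.ndarray
    rel_err_phase: np.ndarray = field(default=None)  # type: ignore[assignment]
    rel_err_mod: np.ndarray = field(default=None)  # type: ignore[assignment]
    mole_fraction: float = float("nan")
    replicate: int = 0

    def __post_init__(self) -> None:
        f = np.asarray(self.frequency_mhz, dtype=float)
        p = np.asarray(self.phase_deg, dtype=float)
        m = np.asarray(self.modulation, dtype=float)
        if f.shape != p.shape or f.shape != m.shape:
            raise ValueError("frequency, phase and modulation lengths differ")
        if np.any(f <= 0):
            raise ValueError("frequencies must be positive (MHz)")
        if np.unique(f).size != f.size:
            raise ValueError("frequencies must be unique")
        if np.any((p < 0) | (p > 90)):
            raise ValueError("phase delays must lie in [0, 90] degrees")
        if np.any((m <= 0) | (m > 1 + 1e-9)):
            raise ValueError("modulation ratios must lie in (0, 1]")
        ep = self.rel_err_phase
        em = self.rel_err_mod
        ep = np.zeros_like(f) if ep is None else np.asarray(ep, dtype=float)
        em = np.zeros_like(f) if em is None else np.asarray(em, dtype=float)
        if np.any(ep < 0) or np.any(em < 0):
            raise ValueError("relative errors must be non-negative")
        # physical decays: phase rises and modulation falls with frequency
        order = np.argsort(f)
        if f.size >= 3 and (
            np.any(np.diff(p[order]) < -1e-9) or np.any(np.diff(m[order]) > 1e-9)
        ):
            warnings.warn(
                "phase not increasing / modulation not decreasing with "
                "frequency; sweep may be unphysical",
                stacklevel=2,
            )
        self.frequency_mhz, self.phase_deg, self.modulation = f, p, m
        self.rel_err_phase, self.rel_err_mod = ep, em

    def __len__(self) -> int:
        return self.frequency_mhz.size

    def phasors(self) -> list[PhasorPoint]:
        """Phasor point at every frequency, with propagated uncertainties."""
        out = []
        for i in range(len(self)):
            pt = to_phasor(self.phase_deg[i], self.modulation[i], self.frequency_mhz[i])
            phi = math.radians(self.phase_deg[i])
            if 0.0 < phi < math.pi / 2 and (
                self.rel_err_mod[i] > 0 or self.rel_err_phase[i] > 0
            ):
                dg, ds = phasor_uncertainty(
                    pt, phi, self.rel_err_mod[i], self.rel_err_phase[i]
                )
                pt = PhasorPoint(pt.g, pt.s, dg, ds, pt.frequency)
            out.append(pt)
        return out


def to_phasor(phase_deg: float, modulation: float, frequency_mhz: float = float("nan")) -> PhasorPoint:
    """Map (phase delay, demodulation) to phasor coordinates G, S."""
    if not 0.0 <= phase_deg <= 90.0:
        raise ValueError("phase must lie in [0, 90] degrees")
    if not 0.0 < modulation <= 1.0 + 1e-12:
        raise ValueError("modulation must lie in (0, 1]")
    phi = math.radians(phase_deg)
    return PhasorPoint(
        g=modulation * math.cos(phi),
        s=modulation * math.sin(phi),
        frequency=frequency_mhz,
    )


def phasor_uncertainty(
    point: PhasorPoint, phase_rad: float, rel_err_mod: float, rel_err_phase: float
) -> tuple[float, float]:
    """First-order propagated absolute errors (dG, dS).

    ``phase_rad`` is the phase delay in radians, so phi * s_phir is the
    absolute phase error.  Singular at phi = 0 or pi/2 where tan/cot blow up.
    """
    if not 0.0 < phase_rad < math.pi / 2:
        raise ValueError("phase must lie strictly inside (0, pi/2) radians")
    if rel_err_mod < 0 or rel_err_phase < 0:
        raise ValueError("relative errors must be non-negative")
    tan, cot = math.tan(phase_rad), 1.0 / math.tan(phase_rad)
    dphi = phase_rad * rel_err_phase
    dg = abs(point.g) * math.sqrt(rel_err_mod**2 + (dphi * tan) ** 2)
    ds = abs(point.s) * math.sqrt(rel_err_mod**2 + (dphi * cot) ** 2)
    return dg, ds


def decay_to_phasor(model: DecayModel, frequency_mhz: float) -> PhasorPoint:
    """Theoretical phasor of a multi-exponential decay at one frequency."""
    w = _omega(frequency_mhz)
    g = sum(f / (1.0 + (w * t) ** 2) for t, f in model.components)
    s = sum(f * w * t / (1.0 + (w * t) ** 2) for t, f in model.components)
    return PhasorPoint(g=g, s=s, frequency=frequency_mhz)


def _decay_phase_mod(model: DecayModel, freqs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free phase (deg) and modulation of a decay over a frequency grid."""
    phase = np.empty_like(freqs)
    mod = np.empty_like(freqs)
    for i, f in enumerate(freqs):
        pt = decay_to_phasor(model, float(f))
        phase[i] = math.degrees(math.atan2(pt.s, pt.g))
        mod[i] = math.hypot(pt.g, pt.s)
    return phase, mod


def reference_calibration(
    raw: FrequencySweep,
    reference_raw: FrequencySweep,
    tau_ref: float = PPO_LIFETIME_NS,
) -> FrequencySweep:
    """Correct a raw sweep against a single-exponential lifetime standard.

    The reference's true response at each frequency is phase arctan(w tau)
    and modulation 1/sqrt(1 + (w tau)^2); instrument phase offsets and
    modulation factors cancel in the ratio.
    """
    if raw.frequency_mhz.shape != reference_raw.frequency_mhz.shape or not np.allclose(
        raw.frequency_mhz, reference_raw.frequency_mhz
    ):
        raise ValueError("sample and reference frequency grids do not match")
    w = 2.0 * np.pi * raw.frequency_mhz * 1e-3
    phase_true_ref = np.degrees(np.arctan(w * tau_ref))
    mod_true_ref = 1.0 / np.sqrt(1.0 + (w * tau_ref) ** 2)
    phase = raw.phase_deg - reference_raw.phase_deg + phase_true_ref
    mod = raw.modulation / reference_raw.modulation * mod_true_ref
    return FrequencySweep(
        frequency_mhz=raw.frequency_mhz.copy(),
        phase_deg=phase,
        modulation=np.clip(mod, 1e-12, 1.0),
        rel_err_phase=raw.rel_err_phase.copy(),
        rel_err_mod=raw.rel_err_mod.copy(),
        mole_fraction=raw.mole_fraction,
        replicate=raw.replicate,
    )


def fit_lifetimes(sweep: FrequencySweep, n_components: int, n_starts: int = 8) -> DecayModel:
    """Weighted least-squares multi-exponential fit of a calibrated sweep.

    Residuals are phase (deg) and modulation differences, each weighted by
    the stated relative errors (floored to avoid zero weights).  Multi-start
    from a fixed seeded set of initial lifetime spreads keeps the fit
    deterministic.
    """
    if n_components < 1:
        raise ValueError("need at least one component")
    if len(sweep) < 2 * n_components:
        raise ValueError("need at least 2 frequencies per decay component")
    freqs = sweep.frequency_mhz
    w_phase = np.maximum(np.abs(sweep.phase_deg) * sweep.rel_err_phase, 1e-4)
    w_mod = np.maximum(sweep.modulation * sweep.rel_err_mod, 1e-4)

    def unpack(theta: np.ndarray) -> DecayModel:
        taus = np.exp(theta[:n_components])
        if n_components == 1:
            fracs = np.array([1.0])
        else:
            raw = np.concatenate([np.exp(theta[n_components:]), [1.0]])
            fracs = raw / raw.sum()
        return DecayModel(tuple(zip(taus.tolist(), fracs.tolist())))

    def residuals(theta: np.ndarray) -> np.ndarray:
        model = unpack(theta)
        phase, mod = _decay_phase_mod(model, freqs)
        return np.concatenate(
            [(phase - sweep.phase_deg) / w_phase, (mod - sweep.modulation) / w_mod]
        )

    rng = np.random.default_rng(20180137)
    n_params = n_components + max(n_components - 1, 0)
    best, best_cost = None, np.inf
    for start in range(n_starts):
        tau0 = np.sort(np.exp(rng.uniform(np.log(0.1), np.log(20.0), n_components)))
        theta0 = np.concatenate([np.log(tau0), np.zeros(n_params - n_components)])
        try:
            res = least_squares(residuals, theta0, method="lm", max_nfev=2000)
        except Exception:
            continue
        if res.cost < best_cost:
            best, best_cost = res, res.cost
    if best is None:
        raise RuntimeError("lifetime fit failed to converge from any start")
    model = unpack(best.x)
    # report components sorted by lifetime
    comps = tuple(sorted(model.components))
    return DecayModel(comps)


def average_phasors(points: list[PhasorPoint]) -> PhasorPoint:
    """Mean of replicate phasor points (mean of G and S separately)."""
    if not points:
        raise ValueError("no phasor points to average")
    g = float(np.mean([p.g for p in points]))
    s = float(np.mean([p.s for p in points]))
    dg = float(np.sqrt(np.sum([p.dg**2 for p in points])) / len(points))
    ds = float(np.sqrt(np.sum([p.ds**2 for p in points])) / len(points))
    return PhasorPoint(g, s, dg, ds, points[0].frequency)


@dataclass(frozen=True)
class BiphasicReport:
    """Outcome of a biphasic-shift scan at one candidate mole fraction."""

    candidate: float
    displacement: float
    axis_shift_g: float
    axis_shift_s: float
    significant: bool
    leftward: bool
    biphasic: bool
    centroid: tuple[float, float]


def biphasic_scan(
    series: dict[float, PhasorPoint],
    candidate: float,
    threshold: float = SIGNIFICANT_SHIFT,
    axis_wise: bool = False,
) -> BiphasicReport:
    """Test whether the candidate mole fraction shows a biphasic phasor shift.

    The candidate's phasor dot is compared with the centroid of all other
    mole fractions in the series (one frequency).  ``significant`` means the
    Euclidean displacement reaches ``threshold`` (or, with ``axis_wise``,
    either axis displacement does); ``leftward`` means lower G, i.e. a
    longer lifetime; the biphasic flag requires both.
    """
    if candidate not in series:
        raise KeyError(f"candidate mole fraction {candidate} not in series")
    others = [p for x, p in series.items() if x != candidate]
    if len(others) < 2:
        raise ValueError("need at least 3 mole fractions including the candidate")
    cand = series[candidate]
    cg = float(np.mean([p.g for p in others]))
    cs = float(np.mean([p.s for p in others]))
    dx, dy = cand.g - cg, cand.s - cs
    displacement = math.hypot(dx, dy)
    if axis_wise:
        significant = max(abs(dx), abs(dy)) >= threshold
    else:
        significant = displacement >= threshold
    leftward = cand.g < cg
    return BiphasicReport(
        candidate=candidate,
        displacement=displacement,
        axis_shift_g=dx,
        axis_shift_s=dy,
        significant=significant,
        leftward=leftward,
        biphasic=significant and leftward,
        centroid=(cg, cs),
    )
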