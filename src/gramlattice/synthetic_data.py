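"""Seeded generators for every input the analysis pipeline consumes.

The generators emulate the statistical structure of the study's
measurements so that each stage of the pipeline can be exercised and
validated without external data:

* frequency-domain sweeps of a multi-exponential tryptophan/tyrosine decay,
  with a longer-lifetime component planted at critical mole fractions
  (leftward phasor displacement just above the 0.01 significance threshold)
  and multiplicative Gaussian noise at the instrument's 0.2% standard-error
  level;
* a radial lipid distribution g(r) around a peptide dimer with a
  depletion-then-peak feature, auto-calibrated so that the M = 12 rigid
  cluster has a cross-section of 520.1 A^2;
* two-band Laurdan emission spectra whose band amplitudes invert the target
  GP, flat across mole fraction unless a dip is planted.

Every generator draws from ``numpy.random.default_rng(seed)`` only, so the
outputs are bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .condensation import RadialProfile, cumulative_condensed
from .laurdan import BLUE_NM, RED_NM, EmissionSpectrum
from .phasor import (
    STANDARD_FREQUENCIES_MHZ,
    DecayModel,
    FrequencySweep,
    _decay_phase_mod,
    decay_to_phasor,
)

__all__ = [
    "SimConfig",
    "simulate_phasor_experiment",
    "simulate_raw_with_reference",
    "simulate_radial_profile",
    "simulate_laurdan_spectra",
    "shifted_decay",
]

#: printed M = 12 rigid-cluster cross-section the radial profile reproduces
TARGET_A12 = 520.1


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic study.

    Defaults mirror the study conditions: the 0.139-0.147 mole-fraction
    scan bracketing the critical fraction 0.143, triplicate samples, the
    15-point frequency grid, 0.2% relative noise, and a planted phasor
    displacement of 0.013 (just above the 0.01 significance rule) at the
    critical fractions.
    """

    seed: int = 0
    mole_fractions: tuple[float, ...] = (0.139, 0.141, 0.143, 0.145, 0.147)
    critical_fractions: frozenset[float] = frozenset({0.143, 0.154})
    frequencies: tuple[float, ...] = STANDARD_FREQUENCIES_MHZ
    n_replicates: int = 3
    rel_noise: float = 0.002
    baseline_decay: DecayModel = field(
        default_factory=lambda: DecayModel(((1.2, 0.45), (4.5, 0.55)))
    )
    critical_shift: float = 0.013  # phasor displacement at the top frequency
    # Laurdan spectrum parameters
    gp_target: float = 0.05
    gp_dip: float = 0.0  # GP reduction planted at critical fractions
    band_width_blue: float = 22.0  # nm (Gaussian sigma-like width)
    band_width_red: float = 32.0
    spectrum_grid: tuple[float, float, float] = (400.0, 560.0, 1.0)
    spectrum_noise: float = 0.002  # additive, relative to peak intensity
    # radial profile shape parameters
    r_max: float = 30.0
    r_step: float = 0.05
    peak_center: float = 10.5
    peak_width: float = 1.2
    depletion_depth: float = 0.5  # relative to the peak amplitude
    depletion_width: float = 1.5

    def __post_init__(self) -> None:
        if self.rel_noise < 0:
            raise ValueError("rel_noise must be non-negative")
        fr = tuple(sorted(set(self.mole_fractions)))
        if fr != tuple(self.mole_fractions):
            object.__setattr__(self, "mole_fractions", fr)
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")


def shifted_decay(config: SimConfig) -> tuple[DecayModel, float]:
    """Decay at a critical fraction: weight moved to the longest lifetime.

    Solves for the intensity-fraction transfer from the shortest- to the
    longest-lifetime component that displaces the phasor at the highest
    modulation frequency by ``config.critical_shift`` (leftward).  Returns
    the shifted model and the transferred fraction.
    """
    base = config.baseline_decay
    comps = sorted(base.components)  # by lifetime
    f_top = max(config.frequencies)
    p0 = decay_to_phasor(base, f_top)

    def displaced(delta: float) -> float:
        model = _transfer(base, delta)
        p = decay_to_phasor(model, f_top)
        return math.hypot(p.g - p0.g, p.s - p0.s)

    lo, hi = 0.0, comps[0][1]  # can move at most the short component's weight
    if displaced(hi) < config.critical_shift:
        raise ValueError("critical_shift not reachable with this baseline decay")
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        if displaced(mid) < config.critical_shift:
            lo = mid
        else:
            hi = mid
    delta = 0.5 * (lo + hi)
    return _transfer(base, delta), delta


def _transfer(base: DecayModel, delta: float) -> DecayModel:
    comps = sorted(base.components)
    if len(comps) == 1:
        return base
    (t_short, f_short), *mid, (t_long, f_long) = comps
    new = [(t_short, f_short - delta), *mid, (t_long, f_long + delta)]
    return DecayModel(tuple(new))


def simulate_phasor_experiment(
    config: SimConfig,
) -> tuple[list[FrequencySweep], dict]:
    """Generate one calibrated sweep per (mole fraction, replicate).

    Phase and modulation carry independent multiplicative Gaussian noise of
    relative SD ``config.rel_noise``; modulation is truncated to (0, 1].
    Returns the sweeps and a ground-truth record.
    """
    rng = np.random.default_rng(config.seed)
    freqs = np.asarray(config.frequencies, dtype=float)
    base_phase, base_mod = _decay_phase_mod(config.baseline_decay, freqs)
    crit_model, delta = shifted_decay(config)
    crit_phase, crit_mod = _decay_phase_mod(crit_model, freqs)

    sweeps: list[FrequencySweep] = []
    for x in config.mole_fractions:
        is_crit = any(abs(x - c) < 1e-9 for c in config.critical_fractions)
        phase0, mod0 = (crit_phase, crit_mod) if is_crit else (base_phase, base_mod)
        for rep in range(config.n_replicates):
            if config.rel_noise > 0:
                phase = phase0 * (1.0 + config.rel_noise * rng.standard_normal(freqs.size))
                mod = mod0 * (1.0 + config.rel_noise * rng.standard_normal(freqs.size))
            else:
                phase, mod = phase0.copy(), mod0.copy()
            sweeps.append(
                FrequencySweep(
                    frequency_mhz=freqs.copy(),
                    phase_deg=np.clip(phase, 0.0, 90.0),
                    modulation=np.clip(mod, 1e-9, 1.0),
                    rel_err_phase=np.full(freqs.size, config.rel_noise),
                    rel_err_mod=np.full(freqs.size, config.rel_noise),
                    mole_fraction=x,
                    replicate=rep,
                )
            )
    truth = {
        "seed": config.seed,
        "critical_fractions": sorted(
            x
            for x in config.mole_fractions
            if any(abs(x - c) < 1e-9 for c in config.critical_fractions)
        ),
        "baseline_decay": list(config.baseline_decay.components),
        "critical_decay": list(crit_model.components),
        "transferred_fraction": delta,
        "planted_displacement": config.critical_shift,
        "rel_noise": config.rel_noise,
    }
    return sweeps, truth


def simulate_raw_with_reference(
    model: DecayModel,
    config: SimConfig,
    tau_ref: float = 1.46,
) -> tuple[FrequencySweep, FrequencySweep]:
    """Raw sample and PPO-reference sweeps sharing an instrument response.

    A deterministic per-frequency phase offset and modulation factor (drawn
    from the config seed) distort both sweeps identically, so reference
    calibration must recover the sample's true response exactly.
    """
    rng = np.random.default_rng(config.seed + 7)
    freqs = np.asarray(config.frequencies, dtype=float)
    w = 2.0 * np.pi * freqs * 1e-3
    phase_offset = rng.uniform(1.0, 8.0, freqs.size)  # degrees
    mod_factor = rng.uniform(0.85, 0.99, freqs.size)

    true_phase, true_mod = _decay_phase_mod(model, freqs)
    ref_phase = np.degrees(np.arctan(w * tau_ref))
    ref_mod = 1.0 / np.sqrt(1.0 + (w * tau_ref) ** 2)

    raw_sample = FrequencySweep(
        frequency_mhz=freqs.copy(),
        phase_deg=np.clip(true_phase + phase_offset, 0.0, 90.0),
        modulation=np.clip(true_mod * mod_factor, 1e-9, 1.0),
    )
    raw_reference = FrequencySweep(
        frequency_mhz=freqs.copy(),
        phase_deg=np.clip(ref_phase + phase_offset, 0.0, 90.0),
        modulation=np.clip(ref_mod * mod_factor, 1e-9, 1.0),
    )
    return raw_sample, raw_reference


def simulate_radial_profile(config: SimConfig | None = None) -> RadialProfile:
    """Radial lipid distribution with a depletion-then-peak condensing shell.

    g(r) = 1 + A [exp(-((r - r_peak)/w_peak)^2)
                  - d exp(-((r - r_gram)/w_dep)^2)]

    The single amplitude A is calibrated (the profile integral is linear in
    A) so that the cumulative condensed count reaches 6 lipids per leaflet
    at the radius implied by a 520.1 A^2 cluster cross-section, i.e. the
    M = 12 geometry reproduces the printed cluster area.
    """
    config = config or SimConfig()
    r_gram = 7.5
    grid = np.arange(r_gram, config.r_max + 0.5 * config.r_step, config.r_step)
    shape = np.exp(-(((grid - config.peak_center) / config.peak_width) ** 2)) - (
        config.depletion_depth
        * np.exp(-(((grid - r_gram) / config.depletion_width) ** 2))
    )
    r_star = math.sqrt(TARGET_A12 / math.pi)
    target_n = 6.0

    def n_at(amp: float) -> float:
        profile = RadialProfile(grid, np.maximum(1.0 + amp * shape, 0.0), r_gram=r_gram)
        return cumulative_condensed(profile, r_star)

    n0, n1 = n_at(0.0), n_at(1.0)
    if abs(n1 - n0) < 1e-12:
        raise ValueError("radial shape has no net condensing contribution")
    amp = (target_n - n0) / (n1 - n0)  # integral is linear in the amplitude
    g = 1.0 + amp * shape
    if np.any(g < 0):
        raise ValueError("calibrated profile went negative; adjust shape params")
    profile = RadialProfile(grid, g, r_gram=r_gram)
    achieved = cumulative_condensed(profile, r_star)
    if abs(achieved - target_n) > 0.005 * target_n:
        raise ValueError(f"calibration failed: N(r*)={achieved:.4f} != {target_n}")
    return profile


def _band_amplitudes(gp: float, w_blue: float, w_red: float) -> tuple[float, float]:
    """Blue/red Gaussian band amplitudes realizing a target GP exactly."""
    if not -1.0 < gp < 1.0:
        raise ValueError("target GP must lie in (-1, 1)")
    sep = RED_NM - BLUE_NM
    cross_red = math.exp(-((sep / w_red) ** 2))  # red band evaluated at 435
    cross_blue = math.exp(-((sep / w_blue) ** 2))  # blue band evaluated at 500
    ratio = (1.0 + gp) / (1.0 - gp)  # I435 / I500
    q = 1.0
    p = (ratio - cross_red) / (1.0 - ratio * cross_blue)
    if p <= 0:
        raise ValueError("target GP not realizable with these band widths")
    return p, q


def simulate_laurdan_spectra(
    config: SimConfig | None = None,
) -> tuple[dict[float, list[EmissionSpectrum]], dict]:
    """Two-band Laurdan emission spectra per (mole fraction, replicate).

    Band amplitudes invert the GP formula for the target GP (reduced by
    ``gp_dip`` at critical fractions); additive Gaussian noise scales with
    the peak intensity; matching blank spectra are generated and attached.
    """
    config = config or SimConfig()
    rng = np.random.default_rng(config.seed + 13)
    lo, hi, step = config.spectrum_grid
    wl = np.arange(lo, hi + 0.5 * step, step)
    scale = 1000.0

    spectra: dict[float, list[EmissionSpectrum]] = {}
    truth_gp: dict[float, float] = {}
    for x in config.mole_fractions:
        is_crit = any(abs(x - c) < 1e-9 for c in config.critical_fractions)
        gp = config.gp_target - (config.gp_dip if is_crit else 0.0)
        p, q = _band_amplitudes(gp, config.band_width_blue, config.band_width_red)
        clean = scale * (
            p * np.exp(-(((wl - BLUE_NM) / config.band_width_blue) ** 2))
            + q * np.exp(-(((wl - RED_NM) / config.band_width_red) ** 2))
        )
        baseline = 0.01 * scale
        truth_gp[x] = gp
        reps = []
        for _ in range(config.n_replicates):
            noise_sd = config.spectrum_noise * clean.max()
            blank = baseline + noise_sd * rng.standard_normal(wl.size)
            sample = clean + baseline + noise_sd * rng.standard_normal(wl.size)
            reps.append(EmissionSpectrum(wl.copy(), sample, blank=blank))
        spectra[x] = reps
    truth = {
        "seed": config.seed,
        "gp_by_fraction": truth_gp,
        "gp_target": config.gp_target,
        "gp_dip": config.gp_dip,
    }
    return spectra, truth
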