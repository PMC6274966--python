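"""Laurdan generalized polarization (GP) from emission spectra.

Laurdan's emission is a blue band (~435 nm, ordered/dehydrated lipid
environment) and a red-shifted band (~500 nm, fluid/hydrated environment).
The excitation generalized polarization

    GP = (I_435 - I_500) / (I_435 + I_500)

summarizes membrane packing in one number in [-1, 1].  A GP dip at a
critical peptide mole fraction would mirror the sterol-superlattice
signature; gramicidin/DMPC mixtures show a flat GP series instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "BLUE_NM",
    "RED_NM",
    "EmissionSpectrum",
    "generalized_polarization",
    "gp_series_test",
    "GPSeriesReport",
]

BLUE_NM = 435.0
RED_NM = 500.0


@dataclass(frozen=True)
class EmissionSpectrum:
    """Emission spectrum on a strictly increasing wavelength grid (nm)."""

    wavelength: np.ndarray
    intensity: np.ndarray
    blank: np.ndarray | None = None

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelength, dtype=float)
        it = np.asarray(self.intensity, dtype=float)
        if wl.ndim != 1 or it.shape != wl.shape:
            raise ValueError("wavelength and intensity must be 1-D, same length")
        if not np.all(np.diff(wl) > 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if not (wl[0] <= BLUE_NM and wl[-1] >= RED_NM):
            raise ValueError(f"grid must cover [{BLUE_NM}, {RED_NM}] nm")
        if not np.all(np.isfinite(it)):
            raise ValueError("intensities must be finite")
        blank = self.blank
        if blank is not None:
            blank = np.asarray(blank, dtype=float)
            if blank.shape != wl.shape:
                raise ValueError("blank must share the sample grid")
        object.__setattr__(self, "wavelength", wl)
        object.__setattr__(self, "intensity", it)
        object.__setattr__(self, "blank", blank)

    def corrected(self) -> np.ndarray:
        """Intensity after point-wise blank subtraction (if a blank exists)."""
        if self.blank is None:
            return self.intensity
        return self.intensity - self.blank


def generalized_polarization(spectrum: EmissionSpectrum) -> float:
    """GP = (I_435 - I_500)/(I_435 + I_500) after blank subtraction.

    Band intensities are read off by linear interpolation on the grid.
    """
    corrected = spectrum.corrected()
    i_blue = float(np.interp(BLUE_NM, spectrum.wavelength, corrected))
    i_red = float(np.interp(RED_NM, spectrum.wavelength, corrected))
    denom = i_blue + i_red
    if denom <= 0:
        raise ValueError("I_435 + I_500 must be positive after blank subtraction")
    return (i_blue - i_red) / denom


@dataclass(frozen=True)
class GPSeriesReport:
    candidate: float
    candidate_mean: float
    neighbor_mean: float
    pooled_sd: float
    dip_statistic: float
    biphasic: bool


def gp_series_test(
    series: dict[float, list[float]],
    candidate: float,
    threshold: float = 2.0,
) -> GPSeriesReport:
    """Test a GP-vs-mole-fraction series for a dip at the candidate fraction.

    dip statistic = (mean GP of the other fractions - mean GP at the
    candidate) / pooled replicate SD; the series is flagged biphasic when
    the statistic exceeds ``threshold`` (default 2 SD).
    """
    if candidate not in series:
        raise KeyError(f"candidate mole fraction {candidate} not in series")
    if len(series) < 3:
        raise ValueError("need at least 3 mole fractions")
    if any(len(v) < 2 for v in series.values()):
        raise ValueError("need at least 2 replicates per mole fraction")
    cand_vals = np.asarray(series[candidate], dtype=float)
    other_vals = [np.asarray(v, dtype=float) for x, v in series.items() if x != candidate]
    neighbor_mean = float(np.mean([v.mean() for v in other_vals]))
    cand_mean = float(cand_vals.mean())
    # pooled within-fraction replicate SD
    groups = [cand_vals] + other_vals
    ss = sum(((v - v.mean()) ** 2).sum() for v in groups)
    dof = sum(v.size - 1 for v in groups)
    pooled_sd = float(np.sqrt(ss / dof)) if dof > 0 else 0.0
    if pooled_sd == 0.0:
        stat = 0.0 if neighbor_mean == cand_mean else float("inf")
    else:
        stat = (neighbor_mean - cand_mean) / pooled_sd
    return GPSeriesReport(
        candidate=candidate,
        candidate_mean=cand_mean,
        neighbor_mean=neighbor_mean,
        pooled_sd=pooled_sd,
        dip_statistic=stat,
        biphasic=stat > threshold,
    )
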