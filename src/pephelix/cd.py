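"""Circular-dichroism helicity analysis.

Far-UV CD of a peptide reports secondary structure through the shape of the
190-260 nm band: a single minimum near 197 nm is the signature of a random
coil, while an alpha-helix shows a positive band below 195 nm and the double
minimum at 208 and 222 nm.  After normalizing the raw ellipticity (mdeg) to
mean-residue molar ellipticity [theta] (deg cm^2 dmol^-1), the helix content
of a free peptide is estimated from the single-wavelength value at 222 nm:

    % helix = 100 * (3000 - [theta]_222) / 39000

i.e. an affine interpolation between a coil limit of +3000 and a full-helix
limit of -36000 deg cm^2 dmol^-1 at 222 nm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.signal import find_peaks, savgol_filter

#: [theta]_222 of a fully helical peptide, deg cm^2 dmol^-1 (per residue).
THETA222_HELIX = -36000.0
#: [theta]_222 of a fully random-coil peptide, deg cm^2 dmol^-1 (per residue).
THETA222_COIL = 3000.0

MILLIDEGREES = "millidegrees"
MOLAR_ELLIPTICITY = "molar_ellipticity_deg_cm2_dmol"


class CDError(ValueError):
    pass


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero (0.5 -> 1, -0.5 -> -1)."""
    return int(math.floor(abs(x) + 0.5) * (1 if x >= 0 else -1))


@dataclass(frozen=True)
class CDSampleInfo:
    """Sample parameters needed to normalize raw ellipticity.

    concentration_molar : peptide concentration in mol/L
    path_length_cm      : cuvette path length in cm
    n_residues          : number of residues (mean-residue normalization)
    """

    concentration_molar: float
    path_length_cm: float
    n_residues: int

    def __post_init__(self) -> None:
        if self.concentration_molar <= 0:
            raise CDError("concentration must be > 0")
        if self.path_length_cm <= 0:
            raise CDError("path length must be > 0")
        if self.n_residues <= 0:
            raise CDError("residue count must be > 0")


@dataclass(frozen=True)
class CDSpectrum:
    wavelengths: np.ndarray
    ellipticity: np.ndarray
    units: str = MILLIDEGREES
    temperature_C: float = 25.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        el = np.asarray(self.ellipticity, dtype=float)
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "ellipticity", el)
        if wl.shape != el.shape or wl.ndim != 1:
            raise CDError("wavelength and ellipticity arrays must match 1:1")
        d = np.diff(wl)
        if wl.size >= 2 and not (np.all(d > 0) or np.all(d < 0)):
            raise CDError("wavelengths must be strictly monotonic")

    def value_at(self, wavelength: float) -> float:
        """Ellipticity at ``wavelength`` (linear interpolation on the grid)."""
        wl, el = self.wavelengths, self.ellipticity
        if wl[0] > wl[-1]:
            wl, el = wl[::-1], el[::-1]
        if not (wl[0] <= wavelength <= wl[-1]):
            raise CDError(f"{wavelength} nm outside measured range")
        return float(np.interp(wavelength, wl, el))


def to_mean_residue_ellipticity(
    spec: CDSpectrum, info: CDSampleInfo
) -> CDSpectrum:
    """Convert raw ellipticity (mdeg) to mean-residue [theta].

    [theta](lam) = theta_mdeg(lam) / (10 * c * l * n_residues), with c in
    mol/L and l in cm, yielding deg cm^2 dmol^-1 per residue.
    """
    if spec.units != MILLIDEGREES:
        raise CDError(f"expected millidegrees input, got {spec.units}")
    scale = 10.0 * info.concentration_molar * info.path_length_cm * info.n_residues
    return replace(
        spec, ellipticity=spec.ellipticity / scale, units=MOLAR_ELLIPTICITY
    )


def smooth_spectrum(spec: CDSpectrum, window: int = 11, order: int = 3) -> CDSpectrum:
    """Polynomial moving-window (Savitzky-Golay) smoothing.

    Endpoints are handled by polynomial extrapolation of the edge fits, so
    constants and straight lines pass through unchanged.
    """
    if window % 2 == 0:
        raise CDError("window must be odd")
    if window <= order:
        raise CDError("window must exceed polynomial order")
    if window >= spec.wavelengths.size:
        raise CDError("window must be smaller than the spectrum")
    sm = savgol_filter(spec.ellipticity, window, order, mode="interp")
    return replace(spec, ellipticity=sm)


@dataclass(frozen=True)
class HelixFraction:
    """Helix percentage from [theta]_222 with the table-rounding convention."""

    percent: float
    percent_rounded: int
    theta222: float
    in_range: bool


def helix_fraction_from_ellipticity(theta222: float) -> HelixFraction:
    """Helix percentage from the mean-residue ellipticity at 222 nm.

    Affine and strictly decreasing in [theta]_222; values outside [0, 100]
    are returned as-is with ``in_range=False`` rather than clamped.
    """
    if not np.isfinite(theta222):
        raise CDError("non-finite [theta]222")
    percent = 100.0 * (THETA222_COIL - theta222) / (THETA222_COIL - THETA222_HELIX)
    return HelixFraction(
        percent=percent,
        percent_rounded=round_half_away(percent),
        theta222=float(theta222),
        in_range=0.0 <= percent <= 100.0,
    )


def classify_spectrum(spec: CDSpectrum) -> str:
    """Classify a far-UV spectrum as ``random_coil``, ``helical`` or ``other``.

    helical     : local minima within 208+-3 and 222+-3 nm and a positive
                  band below 195 nm
    random_coil : global minimum in 195-200 nm without the double minimum
    other       : anything else (including a flat spectrum)
    """
    wl = spec.wavelengths
    el = spec.ellipticity
    if wl[0] > wl[-1]:
        wl, el = wl[::-1], el[::-1]
    if wl[0] > 191.0 or wl[-1] < 250.0:
        raise CDError("spectrum must cover the 190-260 nm far-UV range")

    span = float(np.ptp(el))
    if span == 0.0:
        return "other"
    # prominence floor suppresses noise-induced wiggles
    minima, _ = find_peaks(-el, prominence=0.01 * span)
    min_wl = wl[minima]

    has_208 = np.any(np.abs(min_wl - 208.0) <= 3.0)
    has_222 = np.any(np.abs(min_wl - 222.0) <= 3.0)
    below_195 = el[wl < 195.0]
    positive_band = below_195.size > 0 and np.any(below_195 > 0.05 * span)
    if has_208 and has_222 and positive_band:
        return "helical"

    gmin_wl = float(wl[np.argmin(el)])
    if 195.0 <= gmin_wl <= 200.0 and not (has_208 and has_222):
        return "random_coil"
    return "other"


def write_cd_csv(spec: CDSpectrum, path: str | Path) -> None:
    """Two-column delimited text with a units header line."""
    lines = [f"# units: {spec.units}", "wavelength_nm,ellipticity"]
    for w, e in zip(spec.wavelengths, spec.ellipticity):
        lines.append(f"{w:.4f},{e:.6f}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_cd_csv(path: str | Path) -> CDSpectrum:
    text = Path(path).read_text().splitlines()
    units = MILLIDEGREES
    rows: list[tuple[float, float]] = []
    for line in text:
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            if "units:" in line:
                units = line.split("units:", 1)[1].strip()
            continue
        if line.lower().startswith("wavelength"):
            continue
        w, e = line.split(",")
        rows.append((float(w), float(e)))
    if not rows:
        raise CDError(f"no data rows in {path}")
    wl, el = zip(*rows)
    return CDSpectrum(np.array(wl), np.array(el), units=units)
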