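"""ASCII spectrum reading and fixed-window peak quantification.

MALDI-TOF spectra are exchanged as plain two-column text (m/z, intensity).
Isotopic peaks are quantified by the trapezoidal area in a window of
+/- half_width (default 0.3 Da) around each theoretical peak position;
linear-mode peptides whose isotopes are not resolved are summarized by the
intensity-weighted average mass instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .chem import IsotopicEnvelope, PeptideFragment

__all__ = [
    "Spectrum",
    "PeakVector",
    "read_ascii_spectrum",
    "peak_area",
    "extract_peak_vector",
    "average_mass",
    "write_ascii_spectrum",
]

logger = logging.getLogger(__name__)

DEFAULT_HALF_WIDTH = 0.3  # Da; window is theoretical mass +/- this


@dataclass
class Spectrum:
    """A profile (or stick) mass spectrum with strictly increasing m/z."""

    mz: np.ndarray
    intensity: np.ndarray
    source_path: str = ""
    label: str = ""

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape or self.mz.ndim != 1:
            raise ValueError("mz and intensity must be equal-length 1-D arrays")
        if len(self.mz) < 2:
            raise ValueError("spectrum needs at least 2 points")
        if np.any(np.diff(self.mz) <= 0):
            raise ValueError("mz must be strictly increasing")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensities must be finite")


@dataclass
class PeakVector:
    """Peak areas measured at the theoretical isotopic peak positions."""

    fragment: PeptideFragment | None
    centers: np.ndarray
    areas: np.ndarray
    half_width: float = DEFAULT_HALF_WIDTH
    components: np.ndarray | None = None  # per-component rows, for fitted vectors

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float)
        self.areas = np.asarray(self.areas, dtype=float)
        if self.centers.shape != self.areas.shape:
            raise ValueError("centers and areas must have equal length")
        if np.any(np.diff(self.centers) <= 0):
            raise ValueError("centers must be strictly increasing")
        if np.any(self.areas < -1e-12):
            raise ValueError("areas must be non-negative")


def read_ascii_spectrum(path: str | Path, label: str = "") -> Spectrum:
    """Read a two-column ASCII spectrum (whitespace or comma delimited).

    Lines starting with ``#`` and blank lines are skipped.  Rows are sorted
    by m/z; a malformed line raises ``ValueError`` naming its line number.
    """
    path = Path(path)
    mzs: list[float] = []
    ints: list[float] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", " ").split()
            if len(parts) != 2:
                raise ValueError(
                    f"{path}:{lineno}: expected two numeric columns, got {raw!r}"
                )
            try:
                mzs.append(float(parts[0]))
                ints.append(float(parts[1]))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric value in {raw!r}") from exc
    if not mzs:
        raise ValueError(f"{path}: no data rows")
    order = np.argsort(mzs, kind="stable")
    return Spectrum(
        mz=np.asarray(mzs)[order],
        intensity=np.asarray(ints)[order],
        source_path=str(path),
        label=label or path.stem,
    )


def write_ascii_spectrum(path: str | Path, spectrum: Spectrum, header: str = "") -> None:
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        for m, i in zip(spectrum.mz, spectrum.intensity):
            fh.write(f"{m:.6f}\t{i:.8g}\n")


def peak_area(
    spectrum: Spectrum, center: float, half_width: float = DEFAULT_HALF_WIDTH
) -> float:
    """Trapezoidal integral of intensity over [center - hw, center + hw].

    The signal is treated as piecewise linear; window edges are interpolated.
    Returns 0 (with a logged warning) when the window lies outside the data.
    """
    if half_width <= 0:
        raise ValueError("half_width must be positive")
    lo, hi = center - half_width, center + half_width
    mz, inten = spectrum.mz, spectrum.intensity
    if hi <= mz[0] or lo >= mz[-1]:
        logger.warning(
            "integration window [%.4f, %.4f] outside spectrum range", lo, hi
        )
        return 0.0
    lo_c, hi_c = max(lo, mz[0]), min(hi, mz[-1])
    inside = (mz > lo_c) & (mz < hi_c)
    xs = np.concatenate(([lo_c], mz[inside], [hi_c]))
    ys = np.concatenate(
        ([np.interp(lo_c, mz, inten)], inten[inside], [np.interp(hi_c, mz, inten)])
    )
    return float(np.trapezoid(ys, xs))


def extract_peak_vector(
    spectrum: Spectrum,
    fragment: PeptideFragment | None,
    basis: list[IsotopicEnvelope],
    half_width: float = DEFAULT_HALF_WIDTH,
) -> PeakVector:
    """Measure one peak area per theoretical peak of the basis grid."""
    if not basis:
        raise ValueError("basis must be non-empty")
    centers = basis[0].mz
    spacing = np.diff(centers)
    if spacing.size and spacing.min() < 2 * half_width:
        logger.warning(
            "peak windows overlap: min spacing %.3f Da < 2 x half_width %.3f Da",
            spacing.min(),
            half_width,
        )
    areas = np.array([peak_area(spectrum, c, half_width) for c in centers])
    # noise can drive a near-empty window slightly negative; areas are >= 0
    np.clip(areas, 0.0, None, out=areas)
    return PeakVector(
        fragment=fragment, centers=centers, areas=areas, half_width=half_width
    )


def average_mass(spectrum: Spectrum, window_lo: float, window_hi: float) -> float:
    """Intensity-weighted mean m/z (centroid) over a window.

    Used for linear-mode peptides whose isotopic peaks are not resolved.
    """
    if window_lo >= window_hi:
        raise ValueError("window_lo must be < window_hi")
    sel = (spectrum.mz >= window_lo) & (spectrum.mz <= window_hi)
    total = spectrum.intensity[sel].sum()
    if total <= 0:
        raise ValueError("no intensity in the requested window")
    return float(
        np.dot(spectrum.mz[sel], spectrum.intensity[sel]) / total
    )
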