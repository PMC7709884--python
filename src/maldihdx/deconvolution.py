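"""Non-negative least-squares deconvolution of HDX isotopic envelopes.

An observed peak-area vector y (scaled to unit sum) is modelled as a convex
mixture of the theoretical basis envelopes A_k for k = 0..N incorporated
backbone deuteriums:

    minimize  || A f - y ||^2   subject to  f >= 0,

solved by active-set NNLS; the solution is renormalized to a composition
profile summing to 1.  Zeros in the profile arise naturally from the
non-negativity active set.  Summary outputs are the average number of
exchanged atoms (sum k f_k) and the average deuteration ratio
(100 x average / N).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .chem import IsotopicEnvelope, PeptideFragment, basis_envelopes, count_exchange_sites
from .spectrum import (
    DEFAULT_HALF_WIDTH,
    PeakVector,
    Spectrum,
    extract_peak_vector,
    read_ascii_spectrum,
)

__all__ = [
    "CompositionProfile",
    "HDXResult",
    "fit_composition",
    "average_exchanged",
    "deuteration_ratio",
    "fitted_peak_vector",
    "deconvolute_spectrum",
    "batch_process",
    "read_fragment_table",
    "results_to_dataframe",
]

logger = logging.getLogger(__name__)


@dataclass
class CompositionProfile:
    """Fractions f_k of molecules carrying exactly k amide deuteriums."""

    fractions: np.ndarray
    n_amide: int
    degenerate: bool = False  # True when the basis was rank-deficient

    def __post_init__(self) -> None:
        self.fractions = np.asarray(self.fractions, dtype=float)
        if len(self.fractions) != self.n_amide + 1:
            raise ValueError("profile must have n_amide + 1 fractions")
        if np.any(self.fractions < -1e-12):
            raise ValueError("fractions must be non-negative")
        if abs(self.fractions.sum() - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1 within 1e-9")


@dataclass
class HDXResult:
    """Per-spectrum deconvolution output for one fragment."""

    profile: CompositionProfile
    avg_exchanged: float
    deuteration_ratio: float
    residual_norm: float
    fitted: PeakVector
    spectrum_label: str = ""
    fragment_name: str = ""
    time_point: float = float("nan")


def fit_composition(
    observed: PeakVector, basis: list[IsotopicEnvelope]
) -> CompositionProfile:
    """Fit the observed areas as a non-negative mixture of basis envelopes.

    The observed vector is scaled to unit sum before the fit (removing the
    intensity scale); the NNLS solution is renormalized to sum to 1.
    """
    y = np.asarray(observed.areas, dtype=float)
    if y.sum() <= 0:
        raise ValueError("observation has no signal (all peak areas zero)")
    A = np.column_stack([env.abundance for env in basis])
    if A.shape[0] != len(y):
        raise ValueError("observed vector and basis are on different grids")
    y = y / y.sum()
    f, _ = nnls(A, y)
    total = f.sum()
    if total <= 0:
        raise ValueError("NNLS returned an all-zero profile")
    degenerate = np.linalg.matrix_rank(A) < A.shape[1]
    if degenerate:
        logger.warning("rank-deficient basis: composition profile is not unique")
    return CompositionProfile(
        fractions=f / total, n_amide=len(basis) - 1, degenerate=degenerate
    )


def average_exchanged(profile: CompositionProfile) -> float:
    """Average number of exchanged (incorporated) deuterium atoms, sum k f_k."""
    k = np.arange(len(profile.fractions))
    return float(np.dot(k, profile.fractions))


def deuteration_ratio(profile: CompositionProfile) -> float:
    """Average deuteration ratio in percent: 100 x average_exchanged / n_amide."""
    if profile.n_amide < 1:
        raise ValueError("deuteration ratio undefined for a peptide with no amides")
    return 100.0 * average_exchanged(profile) / profile.n_amide


def fitted_peak_vector(
    profile: CompositionProfile,
    basis: list[IsotopicEnvelope],
    scale: float,
    half_width: float = DEFAULT_HALF_WIDTH,
) -> PeakVector:
    """Predicted peak vector A f, rescaled to the observed total area.

    Per-component contributions (rows of ``components``) sum exactly to the
    fitted vector.
    """
    A = np.column_stack([env.abundance for env in basis])
    components = (A * profile.fractions).T * scale
    return PeakVector(
        fragment=None,
        centers=basis[0].mz,
        areas=components.sum(axis=0),
        half_width=half_width,
        components=components,
    )


def deconvolute_spectrum(
    spectrum: Spectrum,
    fragment: PeptideFragment,
    basis: list[IsotopicEnvelope] | None = None,
    solvent_D_fraction: float = 0.9,
    half_width: float = DEFAULT_HALF_WIDTH,
    time_point: float = float("nan"),
) -> HDXResult:
    """Full per-spectrum pipeline: peak extraction, NNLS fit, summaries."""
    if basis is None:
        basis = basis_envelopes(fragment, solvent_D_fraction)
    observed = extract_peak_vector(spectrum, fragment, basis, half_width)
    profile = fit_composition(observed, basis)
    total = observed.areas.sum()
    fitted = fitted_peak_vector(profile, basis, scale=total, half_width=half_width)
    resid = np.linalg.norm(fitted.areas / total - observed.areas / total)
    return HDXResult(
        profile=profile,
        avg_exchanged=average_exchanged(profile),
        deuteration_ratio=deuteration_ratio(profile),
        residual_norm=float(resid),
        fitted=fitted,
        spectrum_label=spectrum.label,
        fragment_name=fragment.name,
        time_point=time_point,
    )


def read_fragment_table(path: str | Path) -> list[PeptideFragment]:
    """Read a fragment table CSV/TSV with columns name, sequence, start, end."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep)
    df.columns = [c.strip().lower() for c in df.columns]
    required = {"name", "sequence"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"fragment table {path} must have columns name, sequence "
            "(and optionally start, end)"
        )
    fragments = []
    for _, row in df.iterrows():
        start = int(row["start"]) if "start" in df.columns and pd.notna(row.get("start")) else None
        end = int(row["end"]) if "end" in df.columns and pd.notna(row.get("end")) else None
        fragments.append(
            PeptideFragment(
                sequence=str(row["sequence"]).strip(),
                name=str(row["name"]).strip(),
                range_start=start,
                range_end=end,
            )
        )
    if not fragments:
        raise ValueError(f"fragment table {path} is empty")
    return fragments


_TIME_TOKEN = re.compile(r"(?:^|[_\-.])t?(\d+(?:\.\d+)?)\s*min(?:$|[_\-.])")


def _time_from_name(stem: str) -> float:
    m = _TIME_TOKEN.search(stem)
    return float(m.group(1)) if m else float("nan")


def batch_process(
    folder: str | Path,
    fragments: list[PeptideFragment],
    solvent_D_fraction: float = 0.9,
    half_width: float = DEFAULT_HALF_WIDTH,
    pattern: str = "*.txt",
) -> tuple[list[HDXResult], list[tuple[str, str, str]]]:
    """Deconvolute every (spectrum, fragment) pair in a folder.

    Spectra are processed in sorted path order, fragments in table order, so
    reruns are byte-identical.  A failure on one pair is logged and recorded
    without aborting the batch.  A time point in minutes is parsed from a
    ``t<minutes>min`` token in the file name when present.

    Returns (results, failures) where failures are (spectrum, fragment, error).
    """
    folder = Path(folder)
    paths = sorted(folder.glob(pattern))
    if not paths:
        raise ValueError(f"no spectra matching {pattern!r} in {folder}")
    bases = {
        f.name: basis_envelopes(f, solvent_D_fraction) for f in fragments
    }
    results: list[HDXResult] = []
    failures: list[tuple[str, str, str]] = []
    for path in paths:
        try:
            spec = read_ascii_spectrum(path)
        except ValueError as exc:
            for frag in fragments:
                logger.error("failed to read %s: %s", path, exc)
                failures.append((str(path), frag.name, str(exc)))
            continue
        t = _time_from_name(path.stem)
        for frag in fragments:
            try:
                results.append(
                    deconvolute_spectrum(
                        spec,
                        frag,
                        basis=bases[frag.name],
                        half_width=half_width,
                        time_point=t,
                    )
                )
            except ValueError as exc:
                logger.error("failed %s / %s: %s", path.name, frag.name, exc)
                failures.append((str(path), frag.name, str(exc)))
    return results, failures


def results_to_dataframe(results: list[HDXResult]) -> pd.DataFrame:
    """Tabulate results: one row per (spectrum, fragment), fractions in percent."""
    max_n = max((r.profile.n_amide for r in results), default=0)
    rows = []
    for r in results:
        row: dict[str, object] = {
            "spectrum": r.spectrum_label,
            "fragment": r.fragment_name,
            "time_min": r.time_point,
            "n_amide": r.profile.n_amide,
        }
        for k in range(max_n + 1):
            f = r.profile.fractions
            row[f"f_{k}_pct"] = round(100.0 * f[k], 4) if k < len(f) else np.nan
        row["avg_exchanged"] = round(r.avg_exchanged, 6)
        row["deut_ratio_pct"] = round(r.deuteration_ratio, 6)
        row["residual_norm"] = round(r.residual_norm, 8)
        rows.append(row)
    return pd.DataFrame(rows)
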