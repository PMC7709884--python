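"""Synthetic MALDI HDX spectra and uptake time courses with known truth.

Spectra are rendered as sums of Gaussian peaks: each basis envelope k is
weighted by the true composition fraction f_k, every isotopic peak becomes a
Gaussian of FWHM = m/z / resolution whose integrated area equals its weight,
and seeded additive Gaussian noise (a fraction of the maximum intensity) is
superimposed.  Defaults mirror the measurement conditions the package
targets: 90% solvent deuterium, reflectron-TOF resolution 10000, and the
seven sampling times 1, 3, 5, 7, 10, 20 and 40 min for kinetics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chem import IsotopicEnvelope, PeptideFragment, basis_envelopes
from .deconvolution import CompositionProfile
from .kinetics import UptakeTimeSeries
from .spectrum import Spectrum

__all__ = [
    "SimulationConfig",
    "render_spectrum",
    "render_time_series",
    "DEFAULT_TIMES_MIN",
]

#: standard HDX sampling schedule, minutes
DEFAULT_TIMES_MIN = (1.0, 3.0, 5.0, 7.0, 10.0, 20.0, 40.0)

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class SimulationConfig:
    """Ground-truth description of one synthetic spectrum.

    resolution is m/dm at FWHM (default 10000, reflectron TOF); noise_sd is
    the additive Gaussian noise standard deviation as a fraction of the
    maximum signal intensity; mz_step the sampling interval in Da.
    """

    fragment: PeptideFragment
    true_profile: CompositionProfile
    resolution: float = 10000.0
    noise_sd: float = 0.0
    solvent_D_fraction: float = 0.9
    mz_step: float = 0.01
    seed: int = 0
    pad: float = 2.0  # Da of baseline kept on each side

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not 0 < self.solvent_D_fraction <= 1:
            raise ValueError("solvent_D_fraction must be in (0, 1]")
        if self.mz_step <= 0:
            raise ValueError("mz_step must be positive")


def render_spectrum(
    config: SimulationConfig,
    basis: list[IsotopicEnvelope] | None = None,
) -> Spectrum:
    """Render the mixture spectrum implied by the true composition profile."""
    if basis is None:
        basis = basis_envelopes(config.fragment, config.solvent_D_fraction)
    f = config.true_profile.fractions
    if len(f) != len(basis):
        raise ValueError("true_profile length does not match the basis")
    grid_mz = basis[0].mz
    lo = grid_mz[0] - config.pad
    hi = grid_mz[-1] + config.pad
    mz = np.arange(lo, hi + config.mz_step, config.mz_step)
    intensity = np.zeros_like(mz)
    for fk, env in zip(f, basis):
        if fk == 0:
            continue
        for center, ab in zip(env.mz, env.abundance):
            weight = fk * ab
            if weight <= 0:
                continue
            sigma = (center / config.resolution) * _FWHM_TO_SIGMA
            intensity += (
                weight
                / (sigma * np.sqrt(2 * np.pi))
                * np.exp(-0.5 * ((mz - center) / sigma) ** 2)
            )
    if config.noise_sd > 0:
        # additive detector noise around the baseline; left untruncated so
        # that integrated peak areas stay unbiased
        rng = np.random.default_rng(config.seed)
        intensity = intensity + rng.normal(
            0.0, config.noise_sd * intensity.max(), size=intensity.shape
        )
    return Spectrum(
        mz=mz,
        intensity=intensity,
        label=f"sim:{config.fragment.name}:seed{config.seed}",
    )


def render_time_series(
    fragment: str,
    d_inf: float,
    a: float,
    k_obs: float,
    times: np.ndarray | tuple[float, ...] = DEFAULT_TIMES_MIN,
    noise_sd: float = 0.0,
    seed: int = 0,
    state: str = "sim",
) -> UptakeTimeSeries:
    """Uptake series D(t) = D_inf - A exp(-k_obs t) with seeded Gaussian noise."""
    times = np.asarray(times, dtype=float)
    d = d_inf - a * np.exp(-k_obs * times)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        d = d + rng.normal(0.0, noise_sd, size=d.shape)
    d = np.clip(d, 0.0, 100.0)
    sd = np.full_like(times, noise_sd) if noise_sd > 0 else None
    return UptakeTimeSeries(fragment=fragment, state=state, times=times, d_t=d, sd=sd)
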