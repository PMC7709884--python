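"""HDX uptake kinetics: single-exponential time-course fitting.

The deuteration ratio D(t) of a peptic fragment is modelled as

    D(t) = D_inf - A * exp(-k_obs * t)

where D_inf is the asymptotic uptake (percent), A the amplitude of the
exchangeable fraction resolved within the observation window, k_obs the
apparent first-order rate constant (per minute; an average over the amide
sites of the fragment), and D_0 = D_inf - A the zero-time uptake, dominated
by sites that exchange faster than the first sampled time.  Flat time courses
are reported as A = 0 with k_obs undefined.

Region-specific uptake for a sub-region covered by two nested peptic
fragments is obtained by amide-weighted subtraction of the child series from
the parent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "UptakeTimeSeries",
    "KineticsFit",
    "fit_hdx_kinetics",
    "d0",
    "subtract_nested_fragment",
]

logger = logging.getLogger(__name__)

#: below this amplitude (percent) a fit is reported as flat (A = 0, k undefined)
_FLAT_AMPLITUDE = 1e-6


@dataclass
class UptakeTimeSeries:
    """Percent deuteration of one fragment/state at increasing times (min)."""

    fragment: str
    state: str
    times: np.ndarray
    d_t: np.ndarray
    sd: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.d_t = np.asarray(self.d_t, dtype=float)
        if self.times.shape != self.d_t.shape:
            raise ValueError("times and d_t must have equal length")
        if np.any(np.diff(self.times) <= 0) or np.any(self.times <= 0):
            raise ValueError("times must be strictly increasing and positive")
        if np.any((self.d_t < -1e-9) | (self.d_t > 100 + 1e-9)):
            raise ValueError("d_t must lie in [0, 100] percent")
        if self.sd is not None:
            self.sd = np.asarray(self.sd, dtype=float)
            if self.sd.shape != self.times.shape or np.any(self.sd <= 0):
                raise ValueError("sd must be positive and match times in length")


@dataclass
class KineticsFit:
    """Fitted uptake parameters; uncertainties are 1-sigma from the covariance."""

    d_inf: float
    a: float
    k_obs: float
    d_inf_sd: float = float("nan")
    a_sd: float = float("nan")
    k_obs_sd: float = float("nan")
    d0_sd: float = float("nan")
    converged: bool = True

    @property
    def d0(self) -> float:
        """Zero-time uptake D_0 = D_inf - A, percent."""
        return self.d_inf - self.a

    def predict(self, t: np.ndarray) -> np.ndarray:
        k = 0.0 if np.isnan(self.k_obs) else self.k_obs
        return self.d_inf - self.a * np.exp(-k * np.asarray(t, dtype=float))


def _model(t: np.ndarray, d_inf: float, a: float, k: float) -> np.ndarray:
    return d_inf - a * np.exp(-k * t)


def fit_hdx_kinetics(series: UptakeTimeSeries, seed: int = 0) -> KineticsFit:
    """Weighted nonlinear least-squares fit of the single-exponential model.

    Multi-start: one data-driven initialization (D_inf = max D, A = range,
    k = 1/median t) plus 10 jittered restarts from a seeded generator; the
    lowest-SSR converged fit wins.  When the amplitude collapses to zero the
    series is flat and k_obs is unidentifiable: A = 0 and k_obs = NaN are
    reported, with D_inf the (weighted) mean.
    """
    t, y = series.times, series.d_t
    if len(t) < 4:
        raise ValueError("need at least 4 time points to fit 3 parameters")
    sigma = series.sd
    w = 1.0 / sigma**2 if sigma is not None else np.ones_like(y)

    d0_init = float(np.max(y))
    a_init = max(float(np.max(y) - np.min(y)), 1e-3)
    k_init = 1.0 / float(np.median(t))
    starts = [(d0_init, a_init, k_init)]
    rng = np.random.default_rng(seed)
    for _ in range(10):
        starts.append(
            (
                min(100.0, d0_init * rng.uniform(0.8, 1.2)),
                a_init * rng.uniform(0.3, 3.0),
                k_init * rng.uniform(0.1, 10.0),
            )
        )

    bounds = ([0.0, 0.0, 0.0], [100.0, np.inf, np.inf])
    best = None
    for p0 in starts:
        try:
            popt, pcov = curve_fit(
                _model,
                t,
                y,
                p0=p0,
                sigma=sigma,
                absolute_sigma=sigma is not None,
                bounds=bounds,
                maxfev=20000,
                xtol=1e-14,
                ftol=1e-14,
                gtol=1e-14,
            )
        except RuntimeError:
            continue
        ssr = float(np.sum(w * (_model(t, *popt) - y) ** 2))
        if best is None or ssr < best[0]:
            best = (ssr, popt, pcov)

    # flat model: D_inf = weighted mean, A = 0
    mean = float(np.sum(w * y) / np.sum(w))
    flat_ssr = float(np.sum(w * (y - mean) ** 2))
    flat_sd = float(np.sqrt(1.0 / np.sum(w))) if sigma is not None else float(
        np.std(y, ddof=1) / np.sqrt(len(y))
    )

    if best is None:
        logger.warning("kinetics fit failed for %s/%s from all starts",
                       series.fragment, series.state)
        return KineticsFit(
            d_inf=mean, a=0.0, k_obs=float("nan"),
            d_inf_sd=flat_sd, a_sd=0.0, d0_sd=flat_sd, converged=False,
        )

    ssr, popt, pcov = best
    d_inf, a, k = (float(v) for v in popt)
    if a < _FLAT_AMPLITUDE or flat_ssr <= ssr * (1 + 1e-12):
        return KineticsFit(
            d_inf=mean, a=0.0, k_obs=float("nan"),
            d_inf_sd=flat_sd, a_sd=0.0, k_obs_sd=float("nan"),
            d0_sd=flat_sd, converged=True,
        )
    perr = np.sqrt(np.clip(np.diag(pcov), 0, np.inf))
    var_d0 = pcov[0, 0] + pcov[1, 1] - 2 * pcov[0, 1]
    return KineticsFit(
        d_inf=d_inf,
        a=a,
        k_obs=k,
        d_inf_sd=float(perr[0]),
        a_sd=float(perr[1]),
        k_obs_sd=float(perr[2]),
        d0_sd=float(np.sqrt(max(var_d0, 0.0))),
        converged=True,
    )


def d0(fit: KineticsFit) -> float:
    """Zero-time uptake D_0 = D_inf - A, percent."""
    return fit.d0


def subtract_nested_fragment(
    parent: UptakeTimeSeries,
    child: UptakeTimeSeries,
    n_parent: int,
    n_child: int,
) -> UptakeTimeSeries:
    """Uptake of the region covered by the parent but not the nested child.

    With n amides carrying the signal, the region deuteration at each time is
    the amide-weighted difference

        D_region = (D_parent * n_parent - D_child * n_child) / (n_parent - n_child)

    with per-point standard deviations propagated in quadrature when present.
    Points outside [-5, 105] percent (possible under noise) are kept but
    flagged with a warning; clamp only for display.
    """
    if n_child <= 0:
        raise ValueError("child fragment must contribute at least one amide")
    if n_parent <= n_child:
        raise ValueError("parent must have more amides than the nested child")
    if len(parent.times) != len(child.times) or np.any(
        np.abs(parent.times - child.times) > 1e-9
    ):
        raise ValueError("parent and child series must share the same time points")
    n_region = n_parent - n_child
    d_region = (parent.d_t * n_parent - child.d_t * n_child) / n_region
    out_of_range = (d_region < -5) | (d_region > 105)
    if out_of_range.any():
        logger.warning(
            "%d region uptake point(s) outside [-5, 105]%% for %s minus %s",
            int(out_of_range.sum()), parent.fragment, child.fragment,
        )
    sd = None
    if parent.sd is not None and child.sd is not None:
        sd = np.sqrt(
            (parent.sd * n_parent) ** 2 + (child.sd * n_child) ** 2
        ) / n_region
    series = UptakeTimeSeries.__new__(UptakeTimeSeries)
    # bypass the [0, 100] range check: noise can push region values past it
    series.fragment = f"{parent.fragment}-minus-{child.fragment}"
    series.state = parent.state
    series.times = parent.times.copy()
    series.d_t = d_region
    series.sd = sd
    return series
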