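"""Derived per-cell quantities.

Covers the measurement layer of the analysis: the allometric map from
cell area to nuclear area, nuclear SPCH concentration, exponential decay
constants of SPCH intensity after birth, the post-birth intensity nadir
("dip"), photobleaching-rate estimation, and perimeter contact fractions.

Units
-----
Areas are µm², perimeters µm, times minutes, intensities arbitrary units.
Decay constants λ are **per hour** (negative = decline); conversion from
trajectory minutes happens inside :func:`fit_decay`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .data_model import Trajectory

__all__ = [
    "AllometryFit",
    "DecayFit",
    "DipResult",
    "DEFAULT_ALLOMETRY",
    "fit_nuclear_allometry",
    "estimate_nuclear_area",
    "spch_concentration",
    "fit_decay",
    "pct_decline_per_hour",
    "find_dip",
    "estimate_bleaching_rate",
    "contact_fraction",
    "InsufficientDataError",
]


class InsufficientDataError(ValueError):
    """Too few usable observations for a fit."""


@dataclass(frozen=True)
class AllometryFit:
    """ln(nuclear area) = beta * ln(cell area) + alpha + eps, eps ~ N(0, sigma_eps).

    ``sigma_eps`` is the residual standard deviation (n - 2 denominator).
    """

    alpha: float
    beta: float
    sigma_eps: float
    se_alpha: float = float("nan")
    se_beta: float = float("nan")
    n: int = 0


#: Built-in calibration of the nuclear-size allometry for the 3-dpg
#: Arabidopsis cotyledon epidermis (ln-ln slope 0.19, intercept 1.82,
#: Gaussian residual scale 0.027).  Used wherever a nuclear area must be
#: imputed from a cell area.
DEFAULT_ALLOMETRY = AllometryFit(alpha=1.82, beta=0.19, sigma_eps=0.027)


@dataclass(frozen=True)
class DecayFit:
    """Fitted exponential decay N(t) = N0 * exp(lambda * t)."""

    n0: float
    lambda_per_h: float
    window_min: tuple[float, float]
    r_squared: float
    n_points: int
    n_dropped: int = 0  # zero-intensity samples dropped before the log fit

    @property
    def rising(self) -> bool:
        """True when SPCH increased over the fit window (lambda > 0)."""
        return self.lambda_per_h > 0


@dataclass(frozen=True)
class DipResult:
    """Location and level of the post-birth SPCH intensity nadir."""

    t_dip_min: float
    intensity_at_dip: float
    concentration_at_dip: float | None = None


def fit_nuclear_allometry(cell_areas, nuclear_areas) -> AllometryFit:
    """OLS of ln(nuclear area) on ln(cell area).

    Parameters are estimated on the natural-log scale.  Standard errors
    come from the usual OLS formulae; ``sigma_eps`` uses the n - 2
    denominator.
    """
    x = np.asarray(cell_areas, dtype=float)
    y = np.asarray(nuclear_areas, dtype=float)
    if x.size != y.size:
        raise ValueError("cell_areas and nuclear_areas must have equal length")
    if x.size < 3:
        raise InsufficientDataError("allometry fit requires at least 3 pairs")
    if np.any(x <= 0) or np.any(y <= 0):
        raise ValueError("areas must be strictly positive")
    lx, ly = np.log(x), np.log(y)
    sxx = np.sum((lx - lx.mean()) ** 2)
    if sxx == 0:
        raise ValueError("cell areas have zero variance on the log scale")
    beta = np.sum((lx - lx.mean()) * (ly - ly.mean())) / sxx
    alpha = ly.mean() - beta * lx.mean()
    resid = ly - (alpha + beta * lx)
    n = x.size
    sigma_eps = float(np.sqrt(np.sum(resid**2) / (n - 2)))
    se_beta = sigma_eps / np.sqrt(sxx)
    se_alpha = sigma_eps * np.sqrt(1.0 / n + lx.mean() ** 2 / sxx)
    return AllometryFit(
        alpha=float(alpha),
        beta=float(beta),
        sigma_eps=sigma_eps,
        se_alpha=float(se_alpha),
        se_beta=float(se_beta),
        n=int(n),
    )


def estimate_nuclear_area(
    cell_area: float,
    fit: AllometryFit = DEFAULT_ALLOMETRY,
    noise: str = "off",
    rng: np.random.Generator | None = None,
) -> float:
    """Impute nuclear area (µm²) from cell area through the allometric map.

    With ``noise="draw"`` a Gaussian residual of scale ``fit.sigma_eps`` is
    added on the log scale (requires ``rng``); with ``noise="off"`` the
    conditional median is returned.
    """
    if cell_area <= 0:
        raise ValueError("cell_area must be > 0")
    eps = 0.0
    if noise == "draw":
        if rng is None:
            raise ValueError("noise='draw' requires an rng")
        eps = rng.normal(0.0, fit.sigma_eps)
    elif noise != "off":
        raise ValueError("noise must be 'off' or 'draw'")
    return float(np.exp(fit.beta * np.log(cell_area) + fit.alpha + eps))


def spch_concentration(intensity: float, nuclear_area: float) -> float:
    """Nuclear concentration: intensity divided by nuclear area."""
    if nuclear_area <= 0:
        raise ValueError("nuclear_area must be > 0")
    if intensity < 0:
        raise ValueError("intensity must be >= 0")
    return intensity / nuclear_area


def fit_decay(traj: Trajectory, window_min: tuple[float, float] = (0.0, 200.0)) -> DecayFit:
    """Fit N(t) = N0 * exp(lambda t) by log-linear OLS inside a time window.

    The regression is ln(intensity) on time in **hours**, so ``lambda`` is
    per hour and ``N0 = exp(intercept)``.  Zero-intensity samples cannot
    enter the log fit; they are dropped and counted in ``n_dropped``.
    Rising cells (lambda > 0) are retained and flagged, not excluded —
    filtering decisions belong to callers.
    """
    t0, t1 = window_min
    in_window = (traj.times >= t0) & (traj.times <= t1)
    t = traj.times[in_window]
    y = traj.intensities[in_window]
    positive = y > 0
    n_dropped = int(np.sum(~positive))
    if n_dropped:
        warnings.warn(
            f"{traj.cell_id}: dropped {n_dropped} zero-intensity sample(s) "
            "before log-linear decay fit",
            stacklevel=2,
        )
    t, y = t[positive], y[positive]
    if t.size < 2:
        raise InsufficientDataError(
            f"{traj.cell_id}: need >= 2 positive samples in window {window_min}"
        )
    th = t / 60.0
    ly = np.log(y)
    slope, intercept = np.polyfit(th, ly, 1)
    fitted = intercept + slope * th
    ss_res = float(np.sum((ly - fitted) ** 2))
    ss_tot = float(np.sum((ly - ly.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return DecayFit(
        n0=float(np.exp(intercept)),
        lambda_per_h=float(slope),
        window_min=(float(t0), float(t1)),
        r_squared=r2,
        n_points=int(t.size),
        n_dropped=n_dropped,
    )


def pct_decline_per_hour(lambda_per_h: float) -> float:
    """Overall rate of decline, % of SPCH lost per hour: 100 * (1 - e^lambda).

    Negative output (a gain) is permitted when lambda > 0.
    """
    if not np.isfinite(lambda_per_h):
        raise ValueError("lambda must be finite")
    return float(100.0 * (1.0 - np.exp(lambda_per_h)))


def find_dip(
    traj: Trajectory,
    search_window_min: tuple[float, float] = (0.0, 400.0),
    smooth_k: int = 3,
) -> DipResult:
    """Locate the post-birth intensity nadir ("dip").

    The series is smoothed by a centred moving average of width
    ``smooth_k`` (shrinking at the edges), and the dip is the global
    minimum of the smoothed series inside the search window.  Ties go to
    the earliest time.  ``concentration_at_dip`` is filled when the
    trajectory carries nuclear areas.
    """
    if smooth_k < 1 or smooth_k % 2 == 0:
        raise ValueError("smooth_k must be a positive odd integer")
    if traj.n_samples < smooth_k:
        raise InsufficientDataError(
            f"{traj.cell_id}: need >= {smooth_k} samples for smoothing"
        )
    half = smooth_k // 2
    n = traj.n_samples
    smoothed = np.empty(n)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        smoothed[i] = traj.intensities[lo:hi].mean()
    t0, t1 = search_window_min
    in_window = (traj.times >= t0) & (traj.times <= t1)
    if not in_window.any():
        raise ValueError(f"{traj.cell_id}: search window {search_window_min} excludes all samples")
    idx_window = np.flatnonzero(in_window)
    # argmin returns the first minimum -> earliest-time tie-break for free
    idx = idx_window[np.argmin(smoothed[idx_window])]
    conc = None
    if traj.nuclear_area_um2 is not None:
        conc = spch_concentration(
            float(traj.intensities[idx]), float(traj.nuclear_area_um2[idx])
        )
    return DipResult(
        t_dip_min=float(traj.times[idx]),
        intensity_at_dip=float(traj.intensities[idx]),
        concentration_at_dip=conc,
    )


def estimate_bleaching_rate(tracks) -> float:
    """Photobleaching rate in % per hour from pooled nuclear tracks.

    Intensity is regressed on time in hours over all samples of all
    nuclei; the rate is minus the slope over the intercept, times 100
    (positive = signal loss).
    """
    t = np.concatenate([tr.times for tr in tracks]) / 60.0
    y = np.concatenate([tr.intensities for tr in tracks])
    if t.size < 3:
        raise InsufficientDataError("bleaching estimate requires >= 3 pooled samples")
    slope, intercept = np.polyfit(t, y, 1)
    if abs(intercept) < 1e-9 * max(abs(y.mean()), 1e-300):
        raise ValueError("degenerate bleaching fit: intercept is ~0")
    return float(-100.0 * slope / intercept)


def contact_fraction(p_slgc: float, p_neighbour: float, p_union: float) -> float:
    """Fraction of an SLGC's perimeter in contact with one neighbour.

    Computed as ``0.5 * (P_slgc + P_neighbour - P_union) / P_slgc`` from
    the two cell perimeters and the perimeter of their union (all µm).
    A value outside [0, 1] by more than 1e-9 — possible with inconsistent
    segmentations — is clamped with a warning, never silently.
    """
    if p_slgc <= 0 or p_neighbour <= 0 or p_union <= 0:
        raise ValueError("perimeters must be > 0")
    if p_union > p_slgc + p_neighbour:
        raise ValueError(
            "impossible geometry: union perimeter exceeds the sum of the parts"
        )
    frac = 0.5 * (p_slgc + p_neighbour - p_union) / p_slgc
    if frac < -1e-9 or frac > 1.0 + 1e-9:
        warnings.warn(
            f"contact fraction {frac:.6g} outside [0, 1]; clamping", stacklevel=2
        )
        frac = min(max(frac, 0.0), 1.0)
    return float(frac)
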