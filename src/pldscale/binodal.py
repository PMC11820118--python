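"""Coexistence extraction and critical-point fitting for slab simulations.

A direct-coexistence (slab) simulation produces a mass-density profile
along the elongated box axis with a dense plateau flanked by dilute
plateaus. The coexisting densities are read off by least-squares fitting a
symmetric double hyperbolic tangent

    rho(z) = rho_low + (rho_high - rho_low)/2
             * [tanh((z - z1)/w) - tanh((z - z2)/w)]

after circularly re-centring the profile so the dense slab sits mid-box
(the geometry is periodic).

Coexistence points (T, rho_low, rho_high) are then fitted simultaneously
to the law of coexisting densities with the 3.06 3D-Ising empirical
exponent and the law of rectilinear diameters:

    (rho_high - rho_low)^3.06 = d * (1 - T/Tc)
    (rho_high + rho_low)/2    = rho_c + A*(T - Tc)

by weighted nonlinear least squares over (Tc, rho_c, d, A); the reported
Tc uncertainty is the square root of the corresponding diagonal element of
the parameter covariance of the fit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit, least_squares

__all__ = [
    "COEXISTENCE_EXPONENT",
    "FitError",
    "DensityProfile",
    "PhaseDensities",
    "CoexistencePoint",
    "CriticalPoint",
    "DeltaTc",
    "recenter_profile",
    "extract_coexisting_densities",
    "fit_critical_point",
    "predict_binodal",
    "delta_tc",
    "read_profile_csv",
    "read_coexistence_csv",
    "write_coexistence_csv",
    "critical_point_to_json",
]

#: Dimensionless empirical exponent from 3D Ising simulations; a fixed
#: constant of the coexistence law, never a free fit parameter.
COEXISTENCE_EXPONENT = 3.06


class FitError(RuntimeError):
    """A nonlinear fit failed or the input is unusable for fitting."""


@dataclass(frozen=True)
class DensityProfile:
    """Binned density along the slab axis: z in A, rho in g/cm^3."""

    z: np.ndarray
    rho: np.ndarray
    err: np.ndarray | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "z", np.asarray(self.z, dtype=float))
        object.__setattr__(self, "rho", np.asarray(self.rho, dtype=float))
        if self.err is not None:
            object.__setattr__(self, "err", np.asarray(self.err, dtype=float))
        if self.z.ndim != 1 or self.z.shape != self.rho.shape:
            raise ValueError("z and rho must be equal-length 1-D arrays")
        if not np.all(np.diff(self.z) > 0):
            raise ValueError("z bin centers must be strictly increasing")
        if np.any(self.rho < 0):
            raise ValueError("densities must be non-negative")


@dataclass(frozen=True)
class PhaseDensities:
    """Extracted plateau densities with standard errors.

    ``coexistence`` is False when the fitted plateaus differ by less than
    three times their joint standard error (single-phase profile).
    """

    rho_low: float
    rho_high: float
    err_low: float
    err_high: float
    coexistence: bool


@dataclass(frozen=True)
class CoexistencePoint:
    """One binodal observation: temperature plus coexisting densities."""

    T: float
    rho_low: float
    rho_high: float
    err_low: float = 0.0
    err_high: float = 0.0

    def __post_init__(self) -> None:
        if not (self.rho_high > self.rho_low > 0):
            raise ValueError(
                f"coexistence requires rho_high > rho_low > 0, got "
                f"({self.rho_low}, {self.rho_high}) at T={self.T}"
            )


@dataclass(frozen=True)
class CriticalPoint:
    """Fitted critical parameters with covariance.

    Tc in K; rho_c in g/cm^3; d the coexistence amplitude
    ((g/cm^3)^3.06); A the rectilinear-diameter slope (g cm^-3 K^-1).
    """

    Tc: float
    rho_c: float
    d: float
    A: float
    covariance: np.ndarray = field(default_factory=lambda: np.zeros((4, 4)))

    @property
    def Tc_err(self) -> float:
        return float(np.sqrt(self.covariance[0, 0]))


@dataclass(frozen=True)
class DeltaTc:
    """Critical-temperature shift (variant minus reference), in K."""

    value: float
    error: float

    def __post_init__(self) -> None:
        if self.error < 0:
            raise ValueError("error must be non-negative")


# ---------------------------------------------------------------------------
# Profile extraction
# ---------------------------------------------------------------------------

def _double_tanh(z, rho_low, rho_high, z1, z2, w):
    return rho_low + 0.5 * (rho_high - rho_low) * (
        np.tanh((z - z1) / w) - np.tanh((z - z2) / w)
    )


def recenter_profile(profile: DensityProfile) -> DensityProfile:
    """Circularly shift bins so the density-weighted mean sits at box center.

    Profiles from periodic boxes can have the dense slab wrapped across
    the boundary; the slab is made contiguous via the circular
    (angle-averaged) center of mass of the density.
    """
    z, rho = profile.z, profile.rho
    n = z.size
    span = z[-1] - z[0] + (z[1] - z[0])  # box length assuming uniform bins
    theta = 2.0 * np.pi * (z - z[0]) / span
    weight = rho.sum()
    if weight == 0:
        return profile
    mean_angle = np.arctan2((rho * np.sin(theta)).sum(), (rho * np.cos(theta)).sum())
    center_bin = int(round((mean_angle % (2.0 * np.pi)) / (2.0 * np.pi) * n)) % n
    shift = n // 2 - center_bin
    err = None if profile.err is None else np.roll(profile.err, shift)
    return DensityProfile(z=z, rho=np.roll(rho, shift), err=err)


def extract_coexisting_densities(
    profile: DensityProfile, recenter: bool = True
) -> PhaseDensities:
    """Fit the double-tanh slab model and return plateau densities.

    Initial guesses: 10th/90th density percentiles for the plateaus and
    the half-maximum crossings for the interface positions. Requires at
    least 20 bins. A flat profile yields ``coexistence=False``.
    """
    if profile.z.size < 20:
        raise FitError(f"need >= 20 bins to extract coexistence, got {profile.z.size}")
    if recenter:
        profile = recenter_profile(profile)
    z, rho = profile.z, profile.rho

    lo0 = float(np.percentile(rho, 10))
    hi0 = float(np.percentile(rho, 90))
    half = 0.5 * (lo0 + hi0)
    above = np.nonzero(rho > half)[0]
    if above.size == 0 or hi0 - lo0 < 1e-12 * max(hi0, 1.0):
        # Flat (or effectively flat) profile: single phase.
        mean = float(rho.mean())
        sd = float(rho.std(ddof=1) / np.sqrt(rho.size)) if rho.size > 1 else 0.0
        return PhaseDensities(mean, mean, sd, sd, coexistence=False)
    z1_0, z2_0 = float(z[above[0]]), float(z[above[-1]])
    w0 = max((z2_0 - z1_0) / 10.0, float(z[1] - z[0]))
    p0 = [lo0, hi0, z1_0, z2_0, w0]

    sigma = profile.err if profile.err is not None else None
    try:
        popt, pcov = curve_fit(
            _double_tanh, z, rho, p0=p0, sigma=sigma,
            absolute_sigma=False, maxfev=20000,
        )
    except RuntimeError as exc:
        raise FitError(
            f"double-tanh fit did not converge (initial guess rho_low={lo0:.4g}, "
            f"rho_high={hi0:.4g}, z1={z1_0:.4g}, z2={z2_0:.4g}, w={w0:.4g}): {exc}"
        ) from exc
    perr = np.sqrt(np.clip(np.diag(pcov), 0, None))
    rho_low, rho_high = float(popt[0]), float(popt[1])
    err_low, err_high = float(perr[0]), float(perr[1])
    joint = float(np.hypot(err_low, err_high))
    separated = (rho_high - rho_low) > 3.0 * joint
    if rho_high < rho_low:  # degenerate orientation; report sorted
        rho_low, rho_high = rho_high, rho_low
        err_low, err_high = err_high, err_low
    return PhaseDensities(rho_low, rho_high, err_low, err_high, coexistence=separated)


# ---------------------------------------------------------------------------
# Critical-point fit
# ---------------------------------------------------------------------------

def _binodal_model(T, Tc, rho_c, d, A):
    delta = (d * (1.0 - T / Tc)) ** (1.0 / COEXISTENCE_EXPONENT)
    mean = rho_c + A * (T - Tc)
    return mean - 0.5 * delta, mean + 0.5 * delta


def _initial_critical_guess(points: Sequence[CoexistencePoint]):
    T = np.array([p.T for p in points])
    gap = np.array([p.rho_high - p.rho_low for p in points])
    mean = np.array([0.5 * (p.rho_high + p.rho_low) for p in points])
    # (gap)^3.06 is linear in T: slope -d/Tc, intercept d.
    y = gap ** COEXISTENCE_EXPONENT
    slope, intercept = np.polyfit(T, y, 1)
    if slope >= 0 or intercept <= 0:
        Tc0 = float(T.max()) + 0.2 * (float(T.max()) - float(T.min()) + 1.0)
        d0 = float(y.max()) / max(1.0 - T.min() / Tc0, 1e-6)
    else:
        Tc0 = float(-intercept / slope)
        d0 = float(intercept)
        if Tc0 <= T.max():
            Tc0 = float(T.max()) + 0.2 * (float(T.max()) - float(T.min()) + 1.0)
    a0, b0 = np.polyfit(T, mean, 1)
    return Tc0, float(a0 * Tc0 + b0), d0, float(a0)


def fit_critical_point(
    points: Sequence[CoexistencePoint],
    weighted: bool = True,
    tmax_frac: float | None = None,
) -> CriticalPoint:
    """Simultaneous weighted fit of both coexistence laws.

    Parameters
    ----------
    points:
        At least three coexistence observations below the critical point.
    weighted:
        Use per-point density errors as weights when all are positive;
        otherwise the fit is unweighted.
    tmax_frac:
        Optional truncation: drop points with T > tmax_frac * max(T). No
        truncation by default.
    """
    pts = list(points)
    if tmax_frac is not None:
        tmax = max(p.T for p in pts)
        pts = [p for p in pts if p.T <= tmax_frac * tmax]
    if len(pts) < 3:
        raise FitError(f"need >= 3 coexistence points, got {len(pts)}")

    T = np.array([p.T for p in pts])
    rho_lo = np.array([p.rho_low for p in pts])
    rho_hi = np.array([p.rho_high for p in pts])
    errs = np.array([[p.err_low, p.err_high] for p in pts])
    if weighted and np.all(errs > 0):
        w_lo, w_hi = 1.0 / errs[:, 0], 1.0 / errs[:, 1]
    else:
        w_lo = w_hi = np.ones_like(T)

    Tc0, rc0, d0, A0 = _initial_critical_guess(pts)

    def residuals(theta):
        Tc, rho_c, d, A = theta
        lo, hi = _binodal_model(T, Tc, rho_c, d, A)
        return np.concatenate([(lo - rho_lo) * w_lo, (hi - rho_hi) * w_hi])

    tmax = float(T.max())
    result = least_squares(
        residuals, x0=[Tc0, rc0, d0, A0],
        bounds=([tmax * (1 + 1e-9), 0.0, 1e-12, -np.inf], [np.inf] * 4),
        xtol=1e-14, ftol=1e-14, gtol=1e-14,
    )
    if not result.success:
        raise FitError(f"critical-point fit failed: {result.message}")

    dof = 2 * len(pts) - 4
    jtj = result.jac.T @ result.jac
    cond = np.linalg.cond(jtj)
    if cond > 1e12:
        import warnings

        warnings.warn(
            f"ill-conditioned critical-point fit (cond(JtJ) = {cond:.3g})",
            RuntimeWarning, stacklevel=2,
        )
    try:
        cov = np.linalg.inv(jtj)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(jtj)
    if dof > 0:
        cov = cov * (2.0 * result.cost / dof)

    Tc, rho_c, d, A = (float(v) for v in result.x)
    return CriticalPoint(Tc=Tc, rho_c=rho_c, d=d, A=A, covariance=cov)


def predict_binodal(cp: CriticalPoint, temps: Iterable[float]) -> list[CoexistencePoint]:
    """Closed-form coexisting densities below Tc.

    rho_high/low(T) = rho_c + A (T - Tc) +/- 0.5 [d (1 - T/Tc)]^(1/3.06)
    """
    out = []
    for T in temps:
        if T >= cp.Tc:
            raise ValueError(f"T = {T} K is not below Tc = {cp.Tc} K")
        lo, hi = _binodal_model(np.asarray(T, dtype=float), cp.Tc, cp.rho_c, cp.d, cp.A)
        out.append(CoexistencePoint(T=float(T), rho_low=float(lo), rho_high=float(hi)))
    return out


def delta_tc(variant: CriticalPoint, wt: CriticalPoint) -> DeltaTc:
    """Tc(variant) - Tc(reference) with errors summed in quadrature."""
    return DeltaTc(
        value=variant.Tc - wt.Tc,
        error=float(np.hypot(variant.Tc_err, wt.Tc_err)),
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_profile_csv(path: str | Path) -> DensityProfile:
    """Read a two/three-column CSV: z_A, rho_g_cm3[, err]."""
    df = pd.read_csv(path)
    cols = list(df.columns)
    if len(cols) < 2:
        raise ValueError(f"profile CSV {path} needs columns z_A, rho_g_cm3[, err]")
    err = df[cols[2]].to_numpy() if len(cols) > 2 else None
    return DensityProfile(z=df[cols[0]].to_numpy(), rho=df[cols[1]].to_numpy(), err=err)


def read_coexistence_csv(path: str | Path) -> list[CoexistencePoint]:
    """Read a coexistence table CSV: T_K, rho_low, rho_high[, err_low, err_high]."""
    df = pd.read_csv(path)
    needed = {"T_K", "rho_low", "rho_high"}
    if not needed <= set(df.columns):
        raise ValueError(f"coexistence CSV {path} missing columns {needed - set(df.columns)}")
    points = []
    for _, row in df.iterrows():
        points.append(CoexistencePoint(
            T=float(row["T_K"]), rho_low=float(row["rho_low"]),
            rho_high=float(row["rho_high"]),
            err_low=float(row.get("err_low", 0.0) or 0.0),
            err_high=float(row.get("err_high", 0.0) or 0.0),
        ))
    return points


def write_coexistence_csv(points: Iterable[CoexistencePoint], path: str | Path) -> None:
    pd.DataFrame(
        [
            {"T_K": p.T, "rho_low": p.rho_low, "rho_high": p.rho_high,
             "err_low": p.err_low, "err_high": p.err_high}
            for p in points
        ]
    ).to_csv(path, index=False)


def critical_point_to_json(cp: CriticalPoint) -> str:
    """Serialise a fit as JSON {Tc, Tc_err, rho_c, d, A, covariance}."""
    return json.dumps({
        "Tc": cp.Tc, "Tc_err": cp.Tc_err, "rho_c": cp.rho_c,
        "d": cp.d, "A": cp.A, "covariance": cp.covariance.tolist(),
    }, indent=2)
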