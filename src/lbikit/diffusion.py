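"""Steady-state diffusion model of spatially-resolved diffuse reflectance.

Forward model
-------------
For a semi-infinite turbid medium with absorption coefficient ``mu_a`` and
reduced scattering coefficient ``mu_s_prime`` (both cm^-1), the diffusion
approximation with a single isotropic point source buried at depth
``z0 = 1/mu_t'`` and an extrapolated boundary at ``-zb`` gives the radial
diffuse reflectance

    R(r) = (a'/4pi) * [ z0 (mu_eff + 1/r1) exp(-mu_eff r1)/r1^2
                      + (z0 + 2 zb)(mu_eff + 1/r2) exp(-mu_eff r2)/r2^2 ]

with ``mu_t' = mu_a + mu_s'``, transport albedo ``a' = mu_s'/mu_t'``,
``mu_eff = sqrt(3 mu_a mu_t')``, ``r1 = sqrt(z0^2 + r^2)``,
``r2 = sqrt((z0 + 2 zb)^2 + r^2)``.  The boundary offset is ``zb = 2 A D``
with diffusion constant ``D = 1/(3 mu_t')`` and internal-reflection parameter
``A = (1 + r_d)/(1 - r_d)`` from the Groenhuis empirical polynomial
``r_d = -1.440 n^-2 + 0.710 n^-1 + 0.668 + 0.0636 n`` for relative refractive
index ``n``.

Inverse problem
---------------
:func:`fit_optical_properties` recovers ``(mu_a, mu_s')`` from a measured
radial profile by bounded trust-region least squares on log intensities, with
a free multiplicative amplitude concentrated out analytically and a small
multi-start over the bound box.  Bounds may come from a pre-classification
step (see :mod:`lbikit.fda`), which is what makes the narrow-range inversion
well behaved on real tissue.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import (
    ConvergenceError,
    FitUnderdeterminedError,
    InvalidInputError,
    InvalidParameterError,
)

#: Absorption floor: the inverse model requires mu_a > 0.
MU_A_FLOOR = 1e-10

#: Default open-range fitting box (cm^-1), generously covering fruit tissue
#: and the calibration phantoms.
OPEN_MU_A_RANGE = (MU_A_FLOOR, 5.0)
OPEN_MU_S_RANGE = (0.05, 30.0)

#: Default relative refractive indices.
N_REL_PHANTOM = 1.33
N_REL_FRUIT = 1.35


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OpticalProperties:
    """A (mu_a, mu_s') pair in cm^-1."""

    mu_a: float
    mu_s_prime: float

    def __post_init__(self):
        if not np.isfinite(self.mu_a) or self.mu_a < MU_A_FLOOR:
            raise InvalidParameterError(
                f"mu_a must be >= {MU_A_FLOOR:g} cm^-1, got {self.mu_a!r}"
            )
        if not np.isfinite(self.mu_s_prime) or self.mu_s_prime <= 0:
            raise InvalidParameterError(
                f"mu_s_prime must be > 0 cm^-1, got {self.mu_s_prime!r}"
            )


@dataclass(frozen=True)
class FarrellParams:
    """Internal parameters of the diffusion reflectance model."""

    mu_t_prime: float  # cm^-1
    albedo: float
    z0: float  # cm
    mu_eff: float  # cm^-1
    zb: float  # cm
    n_rel: float


@dataclass
class DiffusionProfile:
    """Radial intensity profile: distance from the incident point vs intensity."""

    radii: np.ndarray  # cm, strictly increasing
    intensities: np.ndarray  # arbitrary units, >= 0
    amplitude: float = 1.0

    def __post_init__(self):
        self.radii = np.asarray(self.radii, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.radii.size == 0:
            raise InvalidInputError("profile has no points")
        if self.radii.shape != self.intensities.shape:
            raise InvalidInputError("radii and intensities must have equal length")
        if np.any(np.diff(self.radii) <= 0):
            raise InvalidInputError("radii must be strictly increasing")
        if np.any(self.intensities < 0):
            raise InvalidInputError("intensities must be >= 0")

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"radius_cm": self.radii, "intensity": self.intensities}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "DiffusionProfile":
        df = pd.read_csv(path)
        return cls(df["radius_cm"].to_numpy(), df["intensity"].to_numpy())


@dataclass
class FitResult:
    """Outcome of an inverse diffusion-model fit."""

    properties: OpticalProperties
    amplitude: float
    residual: float  # sum of squared log-intensity errors
    bounds_used: dict  # {"mu_a": (lo, hi), "mu_s_prime": (lo, hi)}
    at_bound: dict = field(default_factory=dict)  # {"mu_a": bool, "mu_s_prime": bool}
    converged: bool = True

    def to_json(self, path=None) -> str:
        payload = {
            "mu_a": self.properties.mu_a,
            "mu_s_prime": self.properties.mu_s_prime,
            "amplitude": self.amplitude,
            "residual": self.residual,
            "bounds": self.bounds_used,
            "at_bound": self.at_bound,
            "converged": self.converged,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


# ---------------------------------------------------------------------------
# Forward model
# ---------------------------------------------------------------------------

def derive_farrell_params(props: OpticalProperties, n_rel: float = N_REL_PHANTOM) -> FarrellParams:
    """Compute the internal diffusion-model parameters for a coefficient pair.

    ``n_rel`` is the refractive index of the sample relative to the ambient
    medium and must lie in [1.0, 1.6] (water ~1.33, fruit flesh ~1.35).
    """
    if not (1.0 <= n_rel <= 1.6):
        raise InvalidParameterError(f"n_rel must be in [1.0, 1.6], got {n_rel!r}")
    mu_t = props.mu_a + props.mu_s_prime
    albedo = props.mu_s_prime / mu_t
    z0 = 1.0 / mu_t
    mu_eff = np.sqrt(3.0 * props.mu_a * mu_t)
    diffusion_const = 1.0 / (3.0 * mu_t)
    r_d = -1.440 * n_rel**-2 + 0.710 / n_rel + 0.668 + 0.0636 * n_rel
    boundary_a = (1.0 + r_d) / (1.0 - r_d)
    zb = 2.0 * boundary_a * diffusion_const
    return FarrellParams(
        mu_t_prime=mu_t, albedo=albedo, z0=z0, mu_eff=float(mu_eff), zb=zb, n_rel=n_rel
    )


def farrell_reflectance(r, props: OpticalProperties, n_rel: float = N_REL_PHANTOM):
    """Relative diffuse reflectance R(r) at radial distance ``r`` (cm).

    Accepts a scalar or array of radii; returns the same shape.  Strictly
    decreasing in r for r > 0.
    """
    p = derive_farrell_params(props, n_rel)
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise InvalidInputError("radii must be >= 0")
    r1 = np.sqrt(p.z0**2 + r**2)
    z2 = p.z0 + 2.0 * p.zb
    r2 = np.sqrt(z2**2 + r**2)
    term1 = p.z0 * (p.mu_eff + 1.0 / r1) * np.exp(-p.mu_eff * r1) / r1**2
    term2 = z2 * (p.mu_eff + 1.0 / r2) * np.exp(-p.mu_eff * r2) / r2**2
    out = (p.albedo / (4.0 * np.pi)) * (term1 + term2)
    return out if out.ndim else float(out)


def simulate_profile(
    props: OpticalProperties,
    radii: Sequence[float],
    amplitude: float = 1.0,
    n_rel: float = N_REL_PHANTOM,
) -> DiffusionProfile:
    """Noise-free forward profile: ``amplitude * R(r)`` at each radius."""
    radii = np.asarray(radii, dtype=float)
    if radii.size == 0:
        raise InvalidInputError("radii must be non-empty")
    if np.any(np.diff(radii) <= 0):
        raise InvalidInputError("radii must be strictly increasing")
    vals = amplitude * farrell_reflectance(radii, props, n_rel)
    return DiffusionProfile(radii=radii, intensities=vals, amplitude=amplitude)


# ---------------------------------------------------------------------------
# Inverse fit
# ---------------------------------------------------------------------------

def _log_residuals(log_i, radii, mu_a, mu_s, n_rel):
    """Log residuals with the amplitude concentrated out analytically."""
    model = farrell_reflectance(radii, OpticalProperties(mu_a, mu_s), n_rel)
    log_m = np.log(model)
    log_amp = float(np.mean(log_i - log_m))
    return log_i - (log_amp + log_m), log_amp


def fit_optical_properties(
    profile: DiffusionProfile,
    bounds: dict | None = None,
    fixed_mu_a: float | None = None,
    n_rel: float = N_REL_PHANTOM,
    min_points: int = 8,
) -> FitResult:
    """Estimate (mu_a, mu_s') from a radial profile.

    Parameters
    ----------
    profile
        Radial profile; only strictly positive intensities are used (the log
        loss is undefined at zero).
    bounds
        Optional ``{"mu_a": (lo, hi), "mu_s_prime": (lo, hi)}``; missing axes
        default to the open ranges.  Typically supplied by the
        pre-classification step.
    fixed_mu_a
        If given, mu_a is held constant (the known-absorber mode used when the
        absorber concentration of a phantom is measured independently) and
        only mu_s' and the amplitude are fitted.  Incompatible with an
        explicit mu_a bound range.

    The cost is the sum of squared differences between log measured intensity
    and log of amplitude * R(r); the amplitude has a closed-form optimum at
    fixed coefficients and is concentrated out.  Three starts (box center and
    the two diagonal corners) guard against local minima; ties are broken by
    lowest residual, then lowest mu_a.
    """
    bounds = dict(bounds or {})
    if fixed_mu_a is not None and "mu_a" in bounds:
        raise InvalidParameterError(
            "fixed_mu_a and an explicit mu_a bound range are mutually exclusive"
        )
    mu_a_rng = tuple(bounds.get("mu_a", OPEN_MU_A_RANGE))
    mu_s_rng = tuple(bounds.get("mu_s_prime", OPEN_MU_S_RANGE))
    for lo, hi in (mu_a_rng, mu_s_rng):
        if not (lo < hi):
            raise InvalidParameterError(f"empty bound range ({lo}, {hi})")
    mu_a_rng = (max(mu_a_rng[0], MU_A_FLOOR), mu_a_rng[1])

    mask = profile.intensities > 0
    radii = profile.radii[mask]
    log_i = np.log(profile.intensities[mask])
    if radii.size < min_points:
        raise FitUnderdeterminedError(
            f"fit needs >= {min_points} positive-intensity points, got {radii.size}"
        )

    if fixed_mu_a is not None:
        fixed_mu_a = max(float(fixed_mu_a), MU_A_FLOOR)

        def cost(x):
            return _log_residuals(log_i, radii, fixed_mu_a, x[0], n_rel)[0]

        lo = np.array([mu_s_rng[0]])
        hi = np.array([mu_s_rng[1]])
    else:

        def cost(x):
            return _log_residuals(log_i, radii, x[0], x[1], n_rel)[0]

        lo = np.array([mu_a_rng[0], mu_s_rng[0]])
        hi = np.array([mu_a_rng[1], mu_s_rng[1]])

    center = 0.5 * (lo + hi)
    eps = 1e-3 * (hi - lo)
    starts = [center, lo + eps, hi - eps]

    candidates = []
    any_success = False
    for x0 in starts:
        try:
            sol = least_squares(
                cost, x0, bounds=(lo, hi), method="trf",
                xtol=1e-12, ftol=1e-12, gtol=1e-12,
            )
        except Exception:  # numerical failure from one start is tolerable
            continue
        any_success = any_success or sol.success
        candidates.append((2.0 * sol.cost, sol))
    if not candidates:
        raise ConvergenceError("all fit starts failed")
    # lowest residual wins; residual ties (within 1e-10 cost tolerance) broken
    # by lowest mu_a
    min_res = min(c[0] for c in candidates)
    tied = [c for c in candidates if c[0] <= min_res + 1e-10]
    residual, sol = min(tied, key=lambda c: c[1].x[0])

    if fixed_mu_a is not None:
        mu_a, mu_s = fixed_mu_a, float(sol.x[0])
    else:
        mu_a, mu_s = float(sol.x[0]), float(sol.x[1])
    _, log_amp = _log_residuals(log_i, radii, mu_a, mu_s, n_rel)

    def near(x, rng):
        tol = 1e-6 * (rng[1] - rng[0])
        return bool(abs(x - rng[0]) <= tol or abs(x - rng[1]) <= tol)

    result = FitResult(
        properties=OpticalProperties(mu_a, mu_s),
        amplitude=float(np.exp(log_amp)),
        residual=float(residual),
        bounds_used={"mu_a": mu_a_rng, "mu_s_prime": mu_s_rng},
        at_bound={
            "mu_a": False if fixed_mu_a is not None else near(mu_a, mu_a_rng),
            "mu_s_prime": near(mu_s, mu_s_rng),
        },
        converged=any_success,
    )
    if not any_success:
        raise ConvergenceError("optimizer did not converge from any start", best=result)
    return result
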