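"""First-order optics of the liquid-lens continuous-zoom objective.

The zoom objective is built from an electrowetting liquid lens (Young-Lippmann
focusing) and a two-group zoom relay.  This module implements the two governing
relations:

* the voltage -> focal-length law of an electrowetting liquid lens,
  ``f = -D (n_c - n_n) / [cos(theta0) + eps*eps0*U^2 / (2*H*gamma)]``, and
* the two-group system magnification with fixed object/image conjugates,
  ``beta = (1 - Phi_f*u)^-1 * [1 + Phi_c/(Phi_f + 1/u) - Phi_f*d]^-1``,

together with the inverse problem (solve group powers for a target
magnification) used to lay out zoom trajectories.  SI units are used
internally; optical powers at the API boundary are in diopters (m^-1).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
import math

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "LiquidLensParams",
    "ZoomConfiguration",
    "SingularFocusError",
    "SingularConfigurationError",
    "InfeasibleMagnificationError",
    "focal_length",
    "optical_power",
    "system_magnification",
    "solve_powers",
    "magnification_grid",
    "front_power_schedule",
    "stitched_range",
    "VACUUM_PERMITTIVITY",
    "DEFAULT_POWER_BOUNDS",
]

VACUUM_PERMITTIVITY = 8.8541878128e-12  # F/m

#: Tunable optical power range of the Corning Arctic-58N0 lens, diopters.
DEFAULT_POWER_BOUNDS = (-5.0, 10.0)


class SingularFocusError(ValueError):
    """Raised when the Young-Lippmann denominator vanishes (zero optical power)."""


class SingularConfigurationError(ValueError):
    """Raised when a zoom configuration hits a singular denominator."""


class InfeasibleMagnificationError(ValueError):
    """Raised when a target magnification is outside the achievable range."""

    def __init__(self, target: float, achievable: tuple[float, float]):
        self.target = target
        self.achievable = achievable
        super().__init__(
            f"target magnification {target:g} outside achievable range "
            f"[{achievable[0]:g}, {achievable[1]:g}]"
        )


@dataclass(frozen=True)
class LiquidLensParams:
    """Physical parameters of an electrowetting liquid lens.

    Parameters
    ----------
    aperture_D : float
        Effective aperture diameter (m).
    n_conductive, n_nonconductive : float
        Refractive indices of the conductive and non-conductive liquids.
    theta0 : float
        Contact angle at zero applied voltage (rad).
    eps_rel : float
        Relative dielectric constant of the insulating layer.
    thickness_H : float
        Dielectric layer thickness (m).
    tension_gamma : float
        Liquid-liquid interfacial tension (N/m).
    eps0 : float
        Vacuum permittivity (F/m).
    """

    aperture_D: float
    n_conductive: float
    n_nonconductive: float
    theta0: float
    eps_rel: float
    thickness_H: float
    tension_gamma: float
    eps0: float = VACUUM_PERMITTIVITY

    def __post_init__(self) -> None:
        if self.aperture_D <= 0:
            raise ValueError("aperture_D must be positive")
        if self.thickness_H <= 0:
            raise ValueError("thickness_H must be positive")
        if self.tension_gamma <= 0:
            raise ValueError("tension_gamma must be positive")
        if self.n_conductive <= 1 or self.n_nonconductive <= 1:
            raise ValueError("refractive indices must exceed 1")
        if self.n_conductive == self.n_nonconductive:
            raise ValueError("liquid refractive indices must differ")

    @property
    def electrowetting_coeff(self) -> float:
        """eps*eps0 / (2*H*gamma), the V^-2 coefficient of the contact-angle term."""
        return self.eps_rel * self.eps0 / (2.0 * self.thickness_H * self.tension_gamma)


@dataclass(frozen=True)
class ZoomConfiguration:
    """A two-group zoom state.

    ``power_front``/``power_rear`` are the front/rear group optical powers in
    diopters, ``working_distance_u`` the object-side working distance (m) and
    ``separation_d`` the distance between group centers (m).  ``relay_offset``
    (m, signed) records the relay image-plane shift; it does not enter the
    magnification formula (u and d are held constant during zooming) but is
    carried as metadata for the aberration schedule of the PSF simulator.
    """

    power_front: float
    power_rear: float
    working_distance_u: float
    separation_d: float
    relay_offset: float = 0.0

    def __post_init__(self) -> None:
        if self.working_distance_u <= 0:
            raise ValueError("working_distance_u must be positive")
        if self.separation_d <= 0:
            raise ValueError("separation_d must be positive")


def focal_length(lens: LiquidLensParams, voltage: float) -> float:
    """Focal length (m) of the electrowetting lens at an applied voltage.

    Evaluates ``f = -D (n_c - n_n) / [cos(theta0) + eps*eps0*U^2/(2*H*gamma)]``.
    The sign of f is carried through: a negative numerator/denominator ratio is
    a diverging state.
    """
    if voltage < 0:
        raise ValueError("voltage must be non-negative")
    denom = math.cos(lens.theta0) + lens.electrowetting_coeff * voltage**2
    if abs(denom) < 1e-15:
        raise SingularFocusError(
            f"optical power is zero at U = {voltage:g} V "
            "(cos(theta0) cancels the electrowetting term)"
        )
    return -lens.aperture_D * (lens.n_conductive - lens.n_nonconductive) / denom


def optical_power(lens: LiquidLensParams, voltage: float) -> float:
    """Optical power 1/f (diopters) at an applied voltage.

    Affine in U^2: ``1/f = [cos(theta0) + eps*eps0*U^2/(2*H*gamma)] / (-D*(n_c-n_n))``.
    """
    return 1.0 / focal_length(lens, voltage)


def system_magnification(config: ZoomConfiguration) -> float:
    """Overall magnification beta of the two-group zoom system.

    ``beta = (1 - Phi_f*u)^-1 * [1 + Phi_c*(Phi_f + 1/u)^-1 - Phi_f*d]^-1``
    with powers in diopters and distances in meters.
    """
    phi_f = config.power_front
    phi_c = config.power_rear
    u = config.working_distance_u
    d = config.separation_d

    front = 1.0 - phi_f * u
    if abs(front) < 1e-12:
        raise SingularConfigurationError("singular factor: 1 - Phi_f*u = 0")
    mid = phi_f + 1.0 / u
    if abs(mid) < 1e-12:
        raise SingularConfigurationError("singular factor: Phi_f + 1/u = 0")
    bracket = 1.0 + phi_c / mid - phi_f * d
    if abs(bracket) < 1e-12:
        raise SingularConfigurationError(
            "singular factor: 1 + Phi_c/(Phi_f + 1/u) - Phi_f*d = 0"
        )
    return (1.0 / front) * (1.0 / bracket)


def front_power_schedule(
    beta: float,
    working_distance_u: float = 0.12,
    beta_range: tuple[float, float] = (10.0, 100.0),
    power_bounds: tuple[float, float] = DEFAULT_POWER_BOUNDS,
    split: float = 0.45,
) -> float:
    """Front-group power for a target magnification.

    The two-group magnification under-determines the (Phi_f, Phi_c) pair, so
    the front power follows a fixed schedule, linear in log(beta) between
    endpoint values chosen so the front group contributes ~sqrt(beta) of the
    total magnification (``Phi_f = (1 - split/sqrt(beta)) / u`` at the range
    endpoints).  The rear power is then solved from the magnification.
    """
    u = working_distance_u
    b0, b1 = beta_range
    p_lo = (1.0 - split / math.sqrt(b0)) / u
    p_hi = (1.0 - split / math.sqrt(b1)) / u
    t = (math.log(beta) - math.log(b0)) / (math.log(b1) - math.log(b0))
    t = min(1.0, max(0.0, t))
    phi = p_lo + t * (p_hi - p_lo)
    return min(power_bounds[1], max(power_bounds[0], phi))


def _beta_of_rear(phi_c: float, template: ZoomConfiguration) -> float:
    return system_magnification(replace(template, power_rear=phi_c))


def solve_powers(
    target_beta: float,
    config_template: ZoomConfiguration,
    power_bounds: tuple[float, float] = DEFAULT_POWER_BOUNDS,
    front_schedule=None,
    rtol: float = 1e-9,
) -> ZoomConfiguration:
    """Solve the rear-group power for a target magnification.

    The front power is taken from ``front_schedule(target_beta)`` if given,
    otherwise from ``config_template.power_front``.  The rear power is found by
    bracketed scalar root finding on the magnification residual within
    ``power_bounds``; the returned configuration round-trips through
    :func:`system_magnification` within 1e-6 relative tolerance.
    """
    if target_beta == 0:
        raise InfeasibleMagnificationError(target_beta, (np.nan, np.nan))
    phi_f = (
        front_schedule(target_beta)
        if front_schedule is not None
        else config_template.power_front
    )
    template = replace(config_template, power_front=phi_f)

    lo, hi = power_bounds
    # beta is hyperbolic in Phi_c: monotone on each side of the pole of the
    # bracketed factor.  Sample, and only accept sign changes of the residual
    # that do not straddle that pole.
    grid = np.linspace(lo, hi, 513)
    vals = np.full(grid.shape, np.nan)
    branch = np.zeros(grid.shape)
    mid = template.power_front + 1.0 / template.working_distance_u
    for i, p in enumerate(grid):
        try:
            vals[i] = _beta_of_rear(float(p), template)
            branch[i] = np.sign(1.0 + p / mid
                                - template.power_front * template.separation_d)
        except SingularConfigurationError:
            pass
    resid = vals - target_beta
    ok = np.isfinite(resid)
    bracket = None
    for i in range(len(grid) - 1):
        if (ok[i] and ok[i + 1] and branch[i] == branch[i + 1]
                and resid[i] * resid[i + 1] <= 0):
            bracket = (float(grid[i]), float(grid[i + 1]))
            break
    if bracket is None:
        finite = vals[ok]
        achievable = (
            (float(np.nanmin(finite)), float(np.nanmax(finite)))
            if finite.size
            else (np.nan, np.nan)
        )
        raise InfeasibleMagnificationError(target_beta, achievable)

    if resid[ok][0] == 0:
        phi_c = float(grid[ok][0])
    else:
        phi_c = brentq(
            lambda p: _beta_of_rear(p, template) - target_beta,
            bracket[0],
            bracket[1],
            xtol=1e-13,
            rtol=8.9e-16,
        )
    config = replace(template, power_rear=float(phi_c))
    achieved = system_magnification(config)
    if abs(achieved - target_beta) > 1e-6 * abs(target_beta):
        raise InfeasibleMagnificationError(
            target_beta, (achieved, achieved)
        )
    return config


def magnification_grid(
    beta_min: float,
    beta_max: float,
    n_levels: int,
    config_template: ZoomConfiguration | None = None,
    power_bounds: tuple[float, float] = DEFAULT_POWER_BOUNDS,
) -> list[ZoomConfiguration]:
    """Geometrically spaced zoom configurations from beta_min to beta_max.

    Endpoints are exact; each level is solved via :func:`solve_powers` with the
    log-linear front-power schedule.
    """
    if not beta_min < beta_max:
        raise ValueError("beta_min must be smaller than beta_max")
    if n_levels < 2:
        raise ValueError("n_levels must be at least 2")
    if config_template is None:
        config_template = ZoomConfiguration(
            power_front=0.0, power_rear=0.0,
            working_distance_u=0.12, separation_d=0.1,
        )
    betas = np.geomspace(beta_min, beta_max, n_levels)
    betas[0], betas[-1] = beta_min, beta_max

    def schedule(b: float) -> float:
        return front_power_schedule(
            b, working_distance_u=config_template.working_distance_u,
            beta_range=(beta_min, beta_max), power_bounds=power_bounds)

    return [
        solve_powers(float(b), config_template, power_bounds=power_bounds,
                     front_schedule=schedule)
        for b in betas
    ]


def stitched_range(
    front_range: tuple[float, float] = (2.0, 8.0),
    rear_range: tuple[float, float] = (5.0, 12.5),
) -> tuple[float, float]:
    """Magnification range of the stitched two-group objective.

    The front and rear zoom groups are designed independently and stitched;
    the stitched system's magnification range is the product of the group
    ranges (defaults: front 2x-8x, rear 5x-12.5x -> 10x-100x).
    """
    return (front_range[0] * rear_range[0], front_range[1] * rear_range[1])
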