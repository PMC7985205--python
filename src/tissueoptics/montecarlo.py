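"""Time-resolved Monte Carlo photon transport in a homogeneous slab.

The model is the classic weighted-photon random walk used throughout tissue
optics: step lengths are drawn from the exponential scattering distribution
``rho(d) = mu_s * exp(-mu_s * d)``, deflection angles from the
Henyey-Greenstein phase function, absorption is applied continuously along
every traversed path segment through a Beer-Lambert factor, and refractive
boundaries are resolved stochastically with unpolarized Fresnel
reflectances. Photons whose weight falls below a threshold enter a Russian
roulette that either kills them or boosts the survivors so the expected
weight is conserved.

Every photon that leaves the slab is logged with its exit position,
direction, weight and arrival time; the specular reflection of the incident
beam is deducted deterministically at launch and logged as a single record
at ``r = 0``, ``t = 0``.

Conventions: the illuminated face is ``z = 0`` with ``z`` increasing into
the slab; photons launched at the origin along ``+z``; units are mm, ps and
mm^-1; "reflection" means exit through the illuminated face.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Tuple, Union

import numpy as np
import pandas as pd

from ._kernel import C_VACUUM, _run_photons

__all__ = [
    "C_VACUUM",
    "InvalidParameterError",
    "OpticalProperties",
    "SlabGeometry",
    "SimulationConfig",
    "ExitRecord",
    "SimulationResult",
    "sample_free_path",
    "sample_scatter_cosine",
    "new_direction",
    "attenuate_weight",
    "fresnel_reflectance",
    "specular_reflectance",
    "russian_roulette",
    "propagate_photon",
    "run_simulation",
]

REFLECTION = "reflection"
TRANSMISSION = "transmission"


class InvalidParameterError(ValueError):
    """A physical or configuration parameter is outside its valid domain."""


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OpticalProperties:
    """Optical properties of one homogeneous slab realization.

    Parameters
    ----------
    n : float
        Refractive index of the medium (>= 1).
    g : float
        Scattering anisotropy, the mean cosine of the single-scattering
        deflection angle; must lie strictly inside (-1, 1).
    mu_s : float
        Scattering coefficient in mm^-1 (> 0); 1/mu_s is the scattering
        mean free path.
    mu_a : float
        Absorption coefficient in mm^-1 (>= 0).
    """

    n: float
    g: float
    mu_s: float
    mu_a: float

    def __post_init__(self) -> None:
        if not self.n >= 1.0:
            raise InvalidParameterError(f"refractive index must be >= 1, got {self.n}")
        if not -1.0 < self.g < 1.0:
            raise InvalidParameterError(f"anisotropy must satisfy |g| < 1, got {self.g}")
        if not self.mu_s > 0.0:
            raise InvalidParameterError(f"mu_s must be positive, got {self.mu_s}")
        if not self.mu_a >= 0.0:
            raise InvalidParameterError(f"mu_a must be non-negative, got {self.mu_a}")

    @property
    def mu_s_prime(self) -> float:
        """Reduced scattering coefficient (1 - g) * mu_s in mm^-1."""
        return (1.0 - self.g) * self.mu_s

    @classmethod
    def from_reduced(cls, n: float, g: float, mu_s_prime: float, mu_a: float) -> "OpticalProperties":
        """Build from the reduced scattering coefficient instead of mu_s."""
        if not -1.0 < g < 1.0:
            raise InvalidParameterError(f"anisotropy must satisfy |g| < 1, got {g}")
        return cls(n=n, g=g, mu_s=mu_s_prime / (1.0 - g), mu_a=mu_a)


@dataclass(frozen=True)
class SlabGeometry:
    """Single slab: finite thickness along z, unbounded transversely."""

    thickness: float = 10.0
    n_ambient_top: float = 1.0
    n_ambient_bottom: float = 1.0

    def __post_init__(self) -> None:
        if not self.thickness > 0.0:
            raise InvalidParameterError(f"thickness must be positive, got {self.thickness}")
        if self.n_ambient_top < 1.0 or self.n_ambient_bottom < 1.0:
            raise InvalidParameterError("ambient refractive indices must be >= 1")


@dataclass(frozen=True)
class SimulationConfig:
    """Run-level knobs: photon budget, roulette, seed and termination cap.

    ``roulette_threshold <= 0`` disables Russian roulette entirely.
    """

    n_photons: int = 250_000
    roulette_threshold: float = 1e-6
    roulette_m: int = 10
    seed: int = 0
    c_vacuum: float = C_VACUUM
    max_events: int = 1_000_000
    tally_absorption: bool = True

    def __post_init__(self) -> None:
        if self.n_photons < 1:
            raise InvalidParameterError("n_photons must be >= 1")
        if self.roulette_threshold >= 1.0:
            raise InvalidParameterError("roulette_threshold must be < 1")
        if self.roulette_m < 2:
            raise InvalidParameterError("roulette_m must be >= 2")
        if self.max_events < 1:
            raise InvalidParameterError("max_events must be >= 1")


@dataclass(frozen=True)
class PhotonState:
    """Instantaneous state of one photon during its random walk."""

    position: Tuple[float, float, float]
    direction: Tuple[float, float, float]
    weight: float
    time: float
    alive: bool = True

    def __post_init__(self) -> None:
        norm = float(np.linalg.norm(self.direction))
        if abs(norm - 1.0) > 1e-12:
            raise InvalidParameterError(f"direction must be a unit vector, |d| = {norm}")
        if self.alive and not self.weight > 0.0:
            raise InvalidParameterError("a live photon must carry positive weight")


@dataclass(frozen=True)
class ExitRecord:
    """One detected photon leaving the slab."""

    side: str
    x: float
    y: float
    direction: Tuple[float, float, float]
    weight: float
    time: float

    def __post_init__(self) -> None:
        if self.side not in (REFLECTION, TRANSMISSION):
            raise InvalidParameterError(f"side must be reflection|transmission, got {self.side!r}")
        if not self.weight > 0.0:
            raise InvalidParameterError("exit weight must be positive")
        if self.time < 0.0:
            raise InvalidParameterError("arrival time must be non-negative")

    @property
    def r(self) -> float:
        """Radial exit distance sqrt(x^2 + y^2) in mm."""
        return float(np.hypot(self.x, self.y))


# ---------------------------------------------------------------------------
# elementary sampling operations
# ---------------------------------------------------------------------------


def sample_free_path(mu_s, u):
    """Invert the exponential free-path CDF: ``d = -ln(u) / mu_s``.

    The sample mean over many uniform deviates converges to the scattering
    mean free path 1/mu_s.
    """
    mu_s = np.asarray(mu_s, dtype=float)
    u = np.asarray(u, dtype=float)
    if np.any(mu_s <= 0.0):
        raise InvalidParameterError("mu_s must be positive")
    if np.any((u <= 0.0) | (u >= 1.0)):
        raise InvalidParameterError("uniform deviate must lie in (0, 1)")
    out = -np.log(u) / mu_s
    return float(out) if out.ndim == 0 else out

def sample_scatter_cosine(g, u):
    """Henyey-Greenstein deflection cosine via the closed-form inverse CDF.

    For ``g = 0`` the distribution degenerates to isotropic scattering and
    the draw is ``2u - 1``.
    """
    g = np.asarray(g, dtype=float)
    u = np.asarray(u, dtype=float)
    if np.any(np.abs(g) >= 1.0):
        raise InvalidParameterError("anisotropy must satisfy |g| < 1")
    if np.any((u < 0.0) | (u > 1.0)):
        raise InvalidParameterError("uniform deviate must lie in [0, 1]")
    g_safe = np.where(g == 0.0, 1.0, g)
    tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
    aniso = (1.0 + g * g - tmp * tmp) / (2.0 * g_safe)
    out = np.where(g == 0.0, 2.0 * u - 1.0, aniso)
    out = np.clip(out, -1.0, 1.0)
    return float(out) if out.ndim == 0 else out


def new_direction(direction, cos_theta: float, phi: float):
    """Deflect a unit vector by angle ``acos(cos_theta)`` at azimuth ``phi``.

    Uses the standard local-frame rotation; directions within 1e-6 of the
    z-axis take the dedicated axial special case to avoid the singular
    denominator.
    """
    d = np.asarray(direction, dtype=float)
    if abs(float(np.linalg.norm(d)) - 1.0) > 1e-9:
        raise InvalidParameterError("input direction must be a unit vector")
    if abs(cos_theta) > 1.0:
        raise InvalidParameterError("|cos_theta| must be <= 1")
    ux, uy, uz = (float(d[0]), float(d[1]), float(d[2]))
    st = np.sqrt(max(0.0, 1.0 - cos_theta * cos_theta))
    cphi, sphi = np.cos(phi), np.sin(phi)
    if abs(uz) > 1.0 - 1e-6:
        out = np.array([st * cphi, st * sphi, cos_theta if uz > 0 else -cos_theta])
    else:
        den = np.sqrt(1.0 - uz * uz)
        out = np.array(
            [
                st * (ux * uz * cphi - uy * sphi) / den + ux * cos_theta,
                st * (uy * uz * cphi + ux * sphi) / den + uy * cos_theta,
                -den * st * cphi + uz * cos_theta,
            ]
        )
    return out / np.linalg.norm(out)


def attenuate_weight(w, mu_a, d):
    """Beer-Lambert attenuation: ``w * exp(-mu_a * d)``."""
    w = np.asarray(w, dtype=float)
    mu_a = np.asarray(mu_a, dtype=float)
    d = np.asarray(d, dtype=float)
    if np.any(w <= 0.0) or np.any(mu_a < 0.0) or np.any(d < 0.0):
        raise InvalidParameterError("require w > 0, mu_a >= 0, d >= 0")
    out = w * np.exp(-mu_a * d)
    return float(out) if out.ndim == 0 else out


def fresnel_reflectance(n_i, n_t, cos_theta_i):
    """Unpolarized Fresnel reflectance R = (R_s + R_p) / 2.

    Snell's law supplies the refraction angle; incidence beyond the critical
    angle returns exactly 1 (total internal reflection).
    """
    n_i = np.asarray(n_i, dtype=float)
    n_t = np.asarray(n_t, dtype=float)
    ci = np.asarray(cos_theta_i, dtype=float)
    if np.any(n_i < 1.0) or np.any(n_t < 1.0):
        raise InvalidParameterError("refractive indices must be >= 1")
    if np.any((ci <= 0.0) | (ci > 1.0)):
        raise InvalidParameterError("cos_theta_i must lie in (0, 1]")
    sin2_t = (n_i / n_t) ** 2 * (1.0 - ci * ci)
    with np.errstate(invalid="ignore"):
        ct = np.sqrt(1.0 - sin2_t)
        r_s = (n_i * ci - n_t * ct) / (n_i * ci + n_t * ct)
        r_p = (n_i * ct - n_t * ci) / (n_i * ct + n_t * ci)
        out = 0.5 * (r_s * r_s + r_p * r_p)
    out = np.where(sin2_t >= 1.0, 1.0, out)
    out = np.where(n_i == n_t, 0.0, out)
    return float(out) if out.ndim == 0 else out


def specular_reflectance(n_ambient: float, n_medium: float) -> float:
    """Normal-incidence Fresnel reflectance of the entry face."""
    return float(((n_ambient - n_medium) / (n_ambient + n_medium)) ** 2)


def russian_roulette(w, threshold, m, u):
    """Unbiased roulette: below threshold, survive with probability 1/m.

    Survivors are boosted to ``m * w`` so the expectation of the returned
    weight equals ``w``; weights at or above the threshold pass unchanged.
    """
    w = np.asarray(w, dtype=float)
    u = np.asarray(u, dtype=float)
    if np.any(w <= 0.0):
        raise InvalidParameterError("weight must be positive")
    if m < 2:
        raise InvalidParameterError("roulette divisor must be >= 2")
    survived = np.where(u < 1.0 / m, m * w, 0.0)
    out = np.where(w >= threshold, w, survived)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# full simulation
# ---------------------------------------------------------------------------


@dataclass
class SimulationResult:
    """Exit log plus weight tallies for one simulation run.

    The exit log is stored columnar (one entry per detected photon):
    ``side`` codes 0 for reflection and 1 for transmission. Weights are in
    photon units (a launched photon carries weight 1 before the specular
    deduction), so tallies are comparable to ``config.n_photons``.
    """

    side: np.ndarray
    x: np.ndarray
    y: np.ndarray
    ux: np.ndarray
    uy: np.ndarray
    uz: np.ndarray
    weight: np.ndarray
    time: np.ndarray
    specular_weight: float
    absorbed_weight: float
    lost_weight: float
    n_cap_terminations: int
    properties: OpticalProperties
    geometry: SlabGeometry
    config: SimulationConfig

    @property
    def n_exit(self) -> int:
        return int(self.side.size)

    @property
    def r(self) -> np.ndarray:
        """Radial exit distances sqrt(x^2 + y^2)."""
        return np.hypot(self.x, self.y)

    @property
    def reflected(self) -> np.ndarray:
        """Boolean mask of diffusely reflected photons."""
        return self.side == 0

    @property
    def reflected_weight(self) -> float:
        """Total diffusely reflected weight (excludes the specular record)."""
        return float(self.weight[self.reflected].sum())

    @property
    def transmitted_weight(self) -> float:
        return float(self.weight[~self.reflected].sum())

    @property
    def launched_weight(self) -> float:
        """Total launched weight including the specular deduction."""
        return float(self.config.n_photons)

    @property
    def specular_record(self) -> Optional[ExitRecord]:
        if self.specular_weight <= 0.0:
            return None
        return ExitRecord(
            side=REFLECTION,
            x=0.0,
            y=0.0,
            direction=(0.0, 0.0, -1.0),
            weight=self.specular_weight,
            time=0.0,
        )

    def energy_balance(self) -> dict:
        """Weight budget of the run; terms sum to ``launched + boosted``."""
        return {
            "launched": self.launched_weight,
            "specular": self.specular_weight,
            "reflected": self.reflected_weight,
            "transmitted": self.transmitted_weight,
            "absorbed": self.absorbed_weight,
            "lost": self.lost_weight,
        }

    def to_dataframe(self, include_specular: bool = True) -> pd.DataFrame:
        """Exit log as a table with columns side, x, y, r, ux, uy, uz, weight, time."""
        side = np.where(self.reflected, REFLECTION, TRANSMISSION)
        frame = pd.DataFrame(
            {
                "side": side,
                "x": self.x,
                "y": self.y,
                "r": self.r,
                "ux": self.ux,
                "uy": self.uy,
                "uz": self.uz,
                "weight": self.weight,
                "time": self.time,
            }
        )
        if include_specular and self.specular_weight > 0.0:
            spec = pd.DataFrame(
                {
                    "side": [REFLECTION],
                    "x": [0.0],
                    "y": [0.0],
                    "r": [0.0],
                    "ux": [0.0],
                    "uy": [0.0],
                    "uz": [-1.0],
                    "weight": [self.specular_weight],
                    "time": [0.0],
                }
            )
            frame = pd.concat([spec, frame], ignore_index=True)
        return frame

    def time_histogram(
        self,
        bins: Union[int, np.ndarray] = 50,
        side: str = REFLECTION,
        t_max: Optional[float] = None,
        include_specular: bool = False,
    ) -> Tuple[np.ndarray, np.ndarray]:
        """Weighted arrival-time histogram; returns (bin_edges, weights)."""
        mask = self.reflected if side == REFLECTION else ~self.reflected
        t = self.time[mask]
        w = self.weight[mask]
        if include_specular and side == REFLECTION and self.specular_weight > 0:
            t = np.concatenate([[0.0], t])
            w = np.concatenate([[self.specular_weight], w])
        if t_max is None:
            t_max = float(t.max()) if t.size else 1.0
        hist, edges = np.histogram(t, bins=bins, range=(0.0, t_max), weights=w)
        return edges, hist

    def radial_histogram(
        self,
        bins: Union[int, np.ndarray] = 50,
        side: str = REFLECTION,
        r_max: Optional[float] = None,
    ) -> Tuple[np.ndarray, np.ndarray]:
        """Weighted radial exit histogram; returns (bin_edges, weights)."""
        mask = self.reflected if side == REFLECTION else ~self.reflected
        r = self.r[mask]
        w = self.weight[mask]
        if r_max is None:
            r_max = float(r.max()) if r.size else 1.0
        hist, edges = np.histogram(r, bins=bins, range=(0.0, r_max), weights=w)
        return edges, hist


def _kernel_args(
    properties: OpticalProperties,
    geometry: SlabGeometry,
    config: SimulationConfig,
    w_launch: float,
) -> tuple:
    log_threshold = (
        np.log(config.roulette_threshold) if config.roulette_threshold > 0.0 else -np.inf
    )
    return (
        w_launch,
        properties.mu_s,
        properties.mu_a,
        properties.n,
        properties.g,
        geometry.thickness,
        geometry.n_ambient_top,
        geometry.n_ambient_bottom,
        log_threshold,
        float(config.roulette_m),
        config.max_events,
        config.seed,
    )


def propagate_photon(
    properties: OpticalProperties,
    geometry: Optional[SlabGeometry] = None,
    config: Optional[SimulationConfig] = None,
    photon_index: int = 0,
) -> Tuple[Optional[ExitRecord], dict]:
    """Trace a single photon of a run (the one at ``photon_index``).

    Returns the exit record (None if the photon was terminated inside the
    slab) and the photon's weight tallies. Tracing photon ``i`` here is
    bit-identical to what the same photon does inside
    :func:`run_simulation`, because every photon owns an independent random
    substream keyed on (seed, index).
    """
    geometry = geometry or SlabGeometry()
    config = config or SimulationConfig()
    r_sp = specular_reflectance(geometry.n_ambient_top, properties.n)
    args = _kernel_args(properties, geometry, config, 1.0 - r_sp)
    (n_exit, side, xs, ys, uxs, uys, uzs, ws, ts, lost_r, lost_c, boost, n_cap) = _run_photons(
        1, *args, photon_index
    )
    tallies = {
        "lost_roulette": lost_r,
        "lost_cap": lost_c,
        "boost_added": boost,
        "absorbed": (1.0 - r_sp) + boost - ws[:n_exit].sum() - lost_r - lost_c,
    }
    if n_exit == 0:
        return None, tallies
    record = ExitRecord(
        side=REFLECTION if side[0] == 0 else TRANSMISSION,
        x=float(xs[0]),
        y=float(ys[0]),
        direction=(float(uxs[0]), float(uys[0]), float(uzs[0])),
        weight=float(ws[0]),
        time=float(ts[0]),
    )
    return record, tallies


def run_simulation(
    properties: OpticalProperties,
    geometry: Optional[SlabGeometry] = None,
    config: Optional[SimulationConfig] = None,
) -> SimulationResult:
    """Launch ``config.n_photons`` photons into the slab and log every exit.

    The normal-incidence specular reflection is deducted deterministically
    at launch (each photon starts with weight ``1 - R_sp``) and reported as
    a single aggregate record at r = 0, t = 0. Identical inputs (including
    the seed) reproduce bit-identical results.
    """
    geometry = geometry or SlabGeometry()
    config = config or SimulationConfig()
    r_sp = specular_reflectance(geometry.n_ambient_top, properties.n)
    w_launch = 1.0 - r_sp
    args = _kernel_args(properties, geometry, config, w_launch)
    (n_exit, side, xs, ys, uxs, uys, uzs, ws, ts, lost_r, lost_c, boost, n_cap) = _run_photons(
        config.n_photons, *args, 0
    )
    sl = slice(0, n_exit)
    exited = float(ws[sl].sum())
    launched = config.n_photons * w_launch
    absorbed = launched + boost - exited - lost_r - lost_c
    lost = lost_r + lost_c
    if lost > 1e-3 * launched:
        warnings.warn(
            f"lost weight {lost:.4g} exceeds 1e-3 of launched weight {launched:.4g}"
            f" ({n_cap} event-cap terminations)",
            RuntimeWarning,
            stacklevel=2,
        )
    return SimulationResult(
        side=side[sl].copy(),
        x=xs[sl].copy(),
        y=ys[sl].copy(),
        ux=uxs[sl].copy(),
        uy=uys[sl].copy(),
        uz=uzs[sl].copy(),
        weight=ws[sl].copy(),
        time=ts[sl].copy(),
        specular_weight=config.n_photons * r_sp,
        absorbed_weight=absorbed if config.tally_absorption else float("nan"),
        lost_weight=lost,
        n_cap_terminations=int(n_cap),
        properties=properties,
        geometry=geometry,
        config=config,
    )
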