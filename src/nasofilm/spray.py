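"""Spray source: dose -> droplet ensemble at the nozzle exit.

The device is characterised by a dose volume, a droplet size (either a
single monodisperse diameter or laser-diffraction Dv10/Dv50/Dv90
percentiles), an exit speed, and the full opening angle of the spray
cone.  A dose is represented by statistical parcels, each carrying an
equal aliquot of liquid volume, so that volume bookkeeping is exact no
matter how many parcels stand for the physical droplet count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import datasets

__all__ = [
    "SprayConfig",
    "DropletEnsemble",
    "droplet_count",
    "fit_size_distribution",
    "sample_droplets",
]

#: z-scores of the 10th and 90th percentiles of a standard normal.
_Z10 = -1.2815515655446004
_Z90 = +1.2815515655446004


def droplet_count(
    dose_mL: float, diameter_um: float, reference_dose_mL: float = 0.25
) -> int:
    """Number of physical droplets in a dose of monodisperse spray.

    The count for the reference actuation volume (0.25 mL) is the dose
    volume divided by the volume of one droplet (pi d^3 / 6), rounded
    to the nearest integer — 1,660,770 droplets at 66 um; other doses
    scale that count proportionately, so a doubled dose carries exactly
    twice the droplets.
    """
    if dose_mL <= 0 or diameter_um <= 0 or reference_dose_mL <= 0:
        raise ValueError("dose and diameter must be positive")
    droplet_volume_um3 = np.pi * diameter_um**3 / 6.0
    base = round(reference_dose_mL * 1e12 / droplet_volume_um3)
    return int(round(base * dose_mL / reference_dose_mL))


def fit_size_distribution(dv10: float, dv50: float, dv90: float):
    """Median-anchored lognormal fit to volume-based size percentiles.

    The volume-weighted diameter distribution is modelled as lognormal
    with its median fixed exactly at Dv50; the log-slope sigma is the
    least-squares fit of ln(d) against the percentile z-scores
    (-1.2816, 0, +1.2816).  Three arbitrary percentiles cannot all be
    matched exactly by a two-parameter lognormal; anchoring the median
    keeps the headline Dv50 exact.

    Returns
    -------
    (median_um, gsd) : the volume-median diameter and the geometric
        standard deviation exp(sigma).
    """
    if not dv10 < dv50 < dv90:
        raise ValueError("percentiles must be strictly increasing")
    # slope through the origin of (z, ln d - ln dv50)
    z = np.array([_Z10, 0.0, _Z90])
    y = np.log(np.array([dv10, dv50, dv90]) / dv50)
    sigma = float(z @ y / (z @ z))
    return float(dv50), float(np.exp(sigma))


@dataclass(frozen=True)
class SprayConfig:
    """Device and administration parameters of one actuation."""

    dose_volume_mL: float = datasets.STANDARD_DOSE_ML
    droplet_diameter_um: float | None = 66.0
    size_distribution: tuple[float, float, float] | None = None
    exit_speed_m_s: float = datasets.SPRAY_EXIT_SPEED_M_S
    plume_full_angle_deg: float = datasets.SPRAY_PLUME_FULL_ANGLE_DEG
    nozzle_position_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    nozzle_axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    insertion_depth_mm: float = 2.0
    nozzle_angle_deg: float = 45.0
    speed_jitter_m_s: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.dose_volume_mL <= 0:
            raise ValueError("dose_volume_mL must be positive")
        if not 0.0 <= self.plume_full_angle_deg < 180.0:
            raise ValueError("plume_full_angle_deg must lie in [0, 180)")
        if self.exit_speed_m_s <= 0:
            raise ValueError("exit_speed_m_s must be positive")
        if self.size_distribution is not None:
            d10, d50, d90 = self.size_distribution
            if not d10 < d50 < d90:
                raise ValueError("size_distribution percentiles must increase")
        elif self.droplet_diameter_um is None or self.droplet_diameter_um <= 0:
            raise ValueError("either a positive diameter or a distribution is required")


@dataclass
class DropletEnsemble:
    """Statistical parcels representing one actuated dose.

    Each parcel carries ``total_volume_mL / n`` of liquid; ``diameter``
    only sets the aerodynamics of the parcel's droplets.
    """

    position_mm: np.ndarray      # (n, 3)
    velocity_m_s: np.ndarray     # (n, 3)
    diameter_um: np.ndarray      # (n,)
    parcel_volume_nL: np.ndarray  # (n,)
    metadata: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.diameter_um)

    @property
    def total_volume_mL(self) -> float:
        return float(self.parcel_volume_nL.sum() * 1e-6)


def _cone_directions(rng, axis, full_angle_deg, n):
    """Directions uniform in solid angle within a cone about ``axis``."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    cos_half = np.cos(np.radians(full_angle_deg) / 2.0)
    u = rng.uniform(cos_half, 1.0, size=n)          # cos(theta)
    phi = rng.uniform(0.0, 2 * np.pi, size=n)
    s = np.sqrt(1.0 - u**2)
    local = np.column_stack([s * np.cos(phi), s * np.sin(phi), u])
    # orthonormal basis with e3 = axis
    helper = np.array([1.0, 0.0, 0.0])
    if abs(axis @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(axis, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    return local @ np.vstack([e1, e2, axis])


def sample_droplets(config: SprayConfig, n_represented: int = 50_000) -> DropletEnsemble:
    """Draw a parcel ensemble at the nozzle exit.

    Directions are uniform in solid angle within the plume cone about
    the nozzle axis; speeds equal the exit speed (optionally jittered);
    diameters are monodisperse by default or drawn volume-weighted from
    the median-anchored lognormal when percentiles are configured.
    Reproducible for a fixed config seed.
    """
    if n_represented < 1:
        raise ValueError("n_represented must be >= 1")
    rng = np.random.default_rng(config.seed)
    n = int(n_represented)

    directions = _cone_directions(
        rng, config.nozzle_axis, config.plume_full_angle_deg, n
    )
    speeds = np.full(n, config.exit_speed_m_s)
    if config.speed_jitter_m_s > 0:
        speeds = np.maximum(
            0.1, speeds + rng.normal(0.0, config.speed_jitter_m_s, size=n)
        )

    if config.size_distribution is not None:
        med, gsd = fit_size_distribution(*config.size_distribution)
        diameters = med * np.exp(np.log(gsd) * rng.standard_normal(n))
    else:
        diameters = np.full(n, float(config.droplet_diameter_um))

    parcel_volume_nL = np.full(n, config.dose_volume_mL * 1e6 / n)
    return DropletEnsemble(
        position_mm=np.tile(np.asarray(config.nozzle_position_mm, dtype=float), (n, 1)),
        velocity_m_s=speeds[:, None] * directions,
        diameter_um=diameters,
        parcel_volume_nL=parcel_volume_nL,
        metadata={"config": config},
    )


def volume_median_diameter(diameter_um, volume_weights=None) -> float:
    """Empirical Dv50: diameter below which half the liquid volume lies."""
    d = np.asarray(diameter_um, dtype=float)
    w = (
        np.ones_like(d)
        if volume_weights is None
        else np.asarray(volume_weights, dtype=float)
    )
    order = np.argsort(d)
    d, w = d[order], w[order]
    cum = np.cumsum(w)
    return float(np.interp(0.5 * cum[-1], cum, d))
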