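"""Synthetic assay trials and spray-size samples.

The generator emulates the statistical structure of the ex vivo
retention experiment so the analysis pipeline can be exercised without
the laboratory raw data: a true angle-dependent retained-thickness
curve anchored at the measured holding capacities, Gaussian measurement
noise at the observed relative standard deviations, and the linear
thickness gradient seen along tilted coupons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import PchipInterpolator

from . import datasets
from .assay import AssayTrial
from .spray import fit_size_distribution

__all__ = [
    "AssayGeneratorConfig",
    "generate_assay_trials",
    "generate_spray_sample",
    "default_hmax_curve",
]

#: Measured anchors of retained film thickness (um) against tilt angle.
#: The 0-degree value is the full applied dose spread over the coupon
#: (no runoff on a horizontal sample); the others are the measured
#: holding capacities.
_DEFAULT_CURVE_ANCHORS = (
    # horizontal coupon retains the whole dose: 0.25 mL / 4 cm^2 = 625 um
    (0.0, 1e4 * datasets.STANDARD_DOSE_ML / datasets.MUCOSA_AREA_CM2),
    (45.0, 1e3 * datasets.HMAX_45_MM),
    (60.0, 1e3 * datasets.HMAX_60_MM),
    (90.0, 1e3 * datasets.HMAX_90_MM),
)


def default_hmax_curve():
    """Monotone interpolant of retained thickness (um) on [0, 90] degrees."""
    angles, thick = zip(*_DEFAULT_CURVE_ANCHORS)
    return PchipInterpolator(np.asarray(angles), np.asarray(thick))


@dataclass
class AssayGeneratorConfig:
    """Study conditions of the emulated retention experiment.

    Relative standard deviations default to the values observed across
    the ten 60-degree trials: 0.8% on the applied mass, 3.9% on the
    runoff mass, and 4.3% on the optical thickness measurement.  The
    five-point profile has a linear gradient of about -5 um/mm toward
    the upper edge, consistent with the measured profiles.
    """

    tilt_angles: tuple = (60.0,)
    true_thickness_curve: object = None          # angle -> um; default anchors
    applied_mass_mean_g: float = 0.246
    applied_mass_rsd: float = 0.008
    runoff_rsd: float = 0.039
    thickness_gradient_um_per_mm: float = -5.0
    measurement_rsd: float = 0.043
    mucosa_area_cm2: float = datasets.MUCOSA_AREA_CM2
    liquid_density_g_cm3: float = datasets.LIQUID_DENSITY_G_CM3
    seed: int = 0
    regenerated_trials: int = field(default=0, init=False)

    def __post_init__(self):
        for name in ("applied_mass_rsd", "runoff_rsd", "measurement_rsd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.true_thickness_curve is None:
            self.true_thickness_curve = default_hmax_curve()


def generate_assay_trials(config: AssayGeneratorConfig, n_per_angle: int) -> list:
    """Draw synthetic retention trials, reproducible under the config seed.

    For each tilt angle the applied mass is drawn around its mean, the
    true deposited mass follows from the true retained thickness
    (area x density x thickness), and the runoff is the noised
    difference; syringe and cardboard before/after masses are then
    constructed so that the analysis recovers these quantities by mass
    balance.  The five-point profile is linear in distance from the
    bottom edge with multiplicative measurement noise.  In the
    noise-free limit the analysis recovers the true thickness exactly.
    """
    if n_per_angle < 1:
        raise ValueError("n_per_angle must be >= 1")
    rng = np.random.default_rng(config.seed)
    positions = np.asarray(datasets.THICKNESS_POINT_POSITIONS_MM)
    trials = []
    config.regenerated_trials = 0
    for angle in config.tilt_angles:
        true_um = float(config.true_thickness_curve(angle))
        deposited = (
            config.mucosa_area_cm2
            * config.liquid_density_g_cm3
            * true_um
            * 1e-4
        )
        for _ in range(n_per_angle):
            for _attempt in range(100):
                applied = config.applied_mass_mean_g * (
                    1.0 + config.applied_mass_rsd * rng.standard_normal()
                )
                runoff = (applied - deposited) * (
                    1.0 + config.runoff_rsd * rng.standard_normal()
                )
                if 0.0 <= runoff < applied:
                    break
                config.regenerated_trials += 1
            else:
                raise RuntimeError(
                    "configuration implies negative runoff; lower the true "
                    "thickness or raise the applied mass"
                )
            realized_um = 1e4 * (applied - runoff) / (
                config.mucosa_area_cm2 * config.liquid_density_g_cm3
            )
            profile = realized_um + config.thickness_gradient_um_per_mm * (
                positions - positions.mean()
            )
            profile = profile * (
                1.0 + config.measurement_rsd * rng.standard_normal(len(positions))
            )
            profile = np.maximum(profile, 1.0)
            syringe_before = 12.0
            cardboard_before = 2.35
            trials.append(
                AssayTrial(
                    tilt_angle=float(angle),
                    syringe_before=syringe_before,
                    syringe_after=syringe_before - applied,
                    cardboard_before=cardboard_before,
                    cardboard_after=cardboard_before + runoff,
                    point_thicknesses=tuple(profile),
                    mucosa_area_cm2=config.mucosa_area_cm2,
                    liquid_density_g_cm3=config.liquid_density_g_cm3,
                )
            )
    return trials


def generate_spray_sample(
    dv=datasets.SPRAY_DV_PERCENTILES_UM, n: int = 100_000, seed: int = 0
) -> np.ndarray:
    """Volume-weighted diameter draws (um) from the fitted lognormal.

    Each draw represents an equal aliquot of spray volume, so empirical
    volume percentiles are plain percentiles of the sample.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    median, gsd = fit_size_distribution(*dv)
    rng = np.random.default_rng(seed)
    return median * np.exp(np.log(gsd) * rng.standard_normal(int(n)))
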