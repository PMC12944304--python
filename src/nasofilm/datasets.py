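"""Reference measurements shipped with the package.

Two experimental datasets drive the models:

* a gravimetric/optical liquid-retention experiment on ex vivo porcine
  nasal mucosa (20 mm x 20 mm coupons, 0.25 mL naloxone HCl spray,
  tilted supports), which anchors the mucosal holding capacity
  ``h_max`` used by the wall-film model; and
* device and airway characterisation numbers: laser-diffraction spray
  percentiles, PIV exit speed and plume angle, formulation fluid
  properties, and the per-region dimensions of a 10-day-old infant
  nasal airway used to calibrate the surrogate geometry.
"""

from __future__ import annotations

# ---------------------------------------------------------------------------
# Formulation fluid properties (naloxone HCl solution)
# ---------------------------------------------------------------------------

LIQUID_DENSITY_G_CM3 = 1.0088
"""Formulation density, g/cm^3."""

LIQUID_VISCOSITY_PA_S = 0.711e-3
"""Dynamic viscosity, Pa*s."""

LIQUID_SURFACE_TENSION_N_M = 52.86e-3
"""Liquid-air surface tension, N/m."""

# Maximum film height (mucosal holding capacity) measured on tilted
# porcine mucosa, mm.  0.324 mm on a 45 degree wall is the average-case
# bound; 0.220 mm on a vertical wall is the conservative worst case.
HMAX_45_MM = 0.324
HMAX_60_MM = 0.293   # mean retained (theoretical) thickness at 60 degrees
HMAX_90_MM = 0.220

# ---------------------------------------------------------------------------
# Spray device characterisation
# ---------------------------------------------------------------------------

SPRAY_DV_PERCENTILES_UM = (28.1, 66.0, 145.3)
"""Volume-based size percentiles (Dv10, Dv50, Dv90), micrometres."""

SPRAY_EXIT_SPEED_M_S = 8.5
"""Mean droplet exit speed from PIV, m/s (measured range 5-12 m/s)."""

SPRAY_PLUME_FULL_ANGLE_DEG = 45.0
"""Full opening angle of the spray cone."""

STANDARD_DOSE_ML = 0.25
"""Single-actuation dose volume, mL."""

# ---------------------------------------------------------------------------
# Infant (10-day-old female) nasal airway dimensions
# ---------------------------------------------------------------------------

#: Per-region volume (cm^3), surface area (cm^2) and effective diameter
#: (cm, 4*V/A) of the bilateral airway, anterior regions counted for
#: both passages.
NASAL_DIMENSIONS = {
    "vestibule": {"volume_cm3": 0.58, "area_cm2": 3.85, "diameter_cm": 0.60},
    "valve": {"volume_cm3": 0.21, "area_cm2": 3.60, "diameter_cm": 0.23},
    "turbinate": {"volume_cm3": 1.57, "area_cm2": 21.09, "diameter_cm": 0.30},
    "nasopharynx": {"volume_cm3": 0.48, "area_cm2": 3.72, "diameter_cm": 0.52},
    "pharynx": {"volume_cm3": 0.31, "area_cm2": 2.96, "diameter_cm": 0.42},
    "larynx": {"volume_cm3": 0.36, "area_cm2": 2.87, "diameter_cm": 0.50},
}

NOSTRIL_AREA_CM2 = 0.166
NOSTRIL_HYDRAULIC_DIAMETER_CM = 0.46


def unilateral_dims() -> dict:
    """Region dimensions for a single (right) nasal passage.

    The vestibule, valve and turbinate are paired structures, so their
    areas and volumes are halved; the nasopharynx, pharynx and larynx
    are shared and enter at full size.
    """
    halved = {"vestibule", "valve", "turbinate"}
    out = {}
    for region, d in NASAL_DIMENSIONS.items():
        f = 0.5 if region in halved else 1.0
        out[region] = {
            "volume_cm3": f * d["volume_cm3"],
            "area_cm2": f * d["area_cm2"],
            "diameter_cm": d["diameter_cm"],
        }
    return out


# ---------------------------------------------------------------------------
# Porcine-mucosa retention trials at a 60 degree tilt
# ---------------------------------------------------------------------------

#: Raw measurements for the ten retention trials at a 60 degree tilt:
#: syringe mass before/after dispensing (g), absorbent-cardboard mass
#: before/after (g), and optical film thickness (um) at five points
#: located 2, 6, 10, 14 and 18 mm from the lower coupon edge.
PORCINE_TRIALS_60_TILT = (
    # (syr_before, syr_after, card_before, card_after, (t2, t6, t10, t14, t18))
    (12.032, 11.789, 2.363, 2.490, (330, 305, 283, 263, 246)),
    (12.050, 11.803, 2.362, 2.490, (325, 316, 272, 251, 239)),
    (12.025, 11.776, 2.365, 2.493, (347, 316, 287, 263, 240)),
    (12.098, 11.850, 2.313, 2.435, (332, 310, 311, 276, 242)),
    (12.060, 11.819, 2.360, 2.484, (311, 293, 276, 256, 241)),
    (12.035, 11.790, 2.347, 2.475, (330, 305, 278, 256, 237)),
    (12.012, 11.765, 2.326, 2.464, (293, 283, 260, 246, 231)),
    (12.037, 11.792, 2.315, 2.444, (318, 307, 262, 252, 237)),
    (12.008, 11.762, 2.322, 2.442, (344, 328, 308, 282, 248)),
    (12.079, 11.833, 2.338, 2.470, (317, 296, 264, 257, 227)),
)

#: Published derived columns for the same ten trials: applied mass (g),
#: runoff mass (g), deposited mass (g), theoretical thickness (um),
#: five-point measured thickness (um), variation (%).  Trials 4, 6 and
#: 10 contain cells that disagree with their own raw masses; the
#: analysis recomputes everything from raw data and reports both.
PRINTED_SUMMARY_60_TILT = (
    (0.243, 0.127, 0.116, 287, 285, -0.7),
    (0.247, 0.128, 0.119, 295, 281, -4.9),
    (0.249, 0.128, 0.121, 300, 291, -3.1),
    (0.248, 0.122, 0.126, 310, 294, -5.8),
    (0.241, 0.124, 0.117, 290, 275, -5.0),
    (0.245, 0.123, 0.117, 290, 281, -3.0),
    (0.247, 0.138, 0.109, 270, 263, -2.8),
    (0.245, 0.129, 0.116, 287, 275, -4.3),
    (0.246, 0.120, 0.126, 312, 302, -3.3),
    (0.246, 0.132, 0.116, 300, 291, -3.7),
)

MUCOSA_AREA_CM2 = 4.0
"""Mucosa coupon area used in the retention assay, cm^2 (20 mm x 20 mm)."""

THICKNESS_POINT_POSITIONS_MM = (2.0, 6.0, 10.0, 14.0, 18.0)
"""Distance of the five optical measurement points from the lower edge."""


def porcine_trials_60deg():
    """The ten 60-degree-tilt retention trials as :class:`AssayTrial` objects."""
    from .assay import AssayTrial

    return [
        AssayTrial(
            tilt_angle=60.0,
            syringe_before=sb,
            syringe_after=sa,
            cardboard_before=cb,
            cardboard_after=ca,
            point_thicknesses=tuple(float(t) for t in pts),
        )
        for sb, sa, cb, ca, pts in PORCINE_TRIALS_60_TILT
    ]
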