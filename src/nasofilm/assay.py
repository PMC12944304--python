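"""Ex vivo mucosa liquid-retention assay analysis.

Each trial sprays a fixed dose onto a tilted 20 mm x 20 mm porcine
nasal mucosa coupon mounted on absorbent cardboard.  The applied mass
is the syringe mass loss, the runoff mass is the cardboard mass gain,
and their difference is the mass retained on the mucosa.  Dividing the
retained mass by the coupon area and formulation density gives the
theoretical (mass-balance) film thickness, which is compared with the
mean of five optical point thicknesses measured 2-18 mm from the lower
edge.  The per-trial variation is the relative difference of the
five-point mean from the theoretical thickness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import datasets

__all__ = [
    "AssayTrial",
    "AssaySummary",
    "theoretical_thickness",
    "analyze_trial",
    "summarize_trials",
    "thickness_gradient_check",
    "trials_to_frame",
    "trials_from_frame",
    "compare_with_printed",
]


@dataclass(frozen=True)
class AssayTrial:
    """Raw measurements of one retention trial."""

    tilt_angle: float
    syringe_before: float
    syringe_after: float
    cardboard_before: float
    cardboard_after: float
    point_thicknesses: tuple  # um, ordered 2/6/10/14/18 mm from the bottom edge
    mucosa_area_cm2: float = datasets.MUCOSA_AREA_CM2
    liquid_density_g_cm3: float = datasets.LIQUID_DENSITY_G_CM3

    def __post_init__(self):
        if self.syringe_before <= self.syringe_after:
            raise ValueError("syringe must lose mass when dispensing")
        if self.cardboard_after < self.cardboard_before:
            raise ValueError("cardboard cannot lose mass")
        if len(self.point_thicknesses) != 5:
            raise ValueError("exactly five point thicknesses are required")
        if any(t <= 0 for t in self.point_thicknesses):
            raise ValueError("point thicknesses must be positive")


@dataclass(frozen=True)
class AssaySummary:
    """Derived mass-balance quantities of one trial (full precision)."""

    tilt_angle: float
    applied_mass_g: float
    runoff_mass_g: float
    deposited_mass_g: float
    theoretical_thickness_um: float
    five_point_mean_um: float
    variation_percent: float
    valid: bool = True

    def rounded(self) -> dict:
        """Values at the reporting precision: 0.001 g, 1 um, 0.1 %."""
        return {
            "applied_mass_g": round(self.applied_mass_g, 3),
            "runoff_mass_g": round(self.runoff_mass_g, 3),
            "deposited_mass_g": round(self.deposited_mass_g, 3),
            "theoretical_thickness_um": round(self.theoretical_thickness_um),
            "five_point_mean_um": round(self.five_point_mean_um),
            "variation_percent": round(self.variation_percent, 1),
        }


def theoretical_thickness(
    deposited_mass_g: float,
    area_cm2: float = datasets.MUCOSA_AREA_CM2,
    density_g_cm3: float = datasets.LIQUID_DENSITY_G_CM3,
) -> float:
    """Uniform-film thickness (um) implied by a retained mass.

    thickness = mass / (area * density), converted from cm to um.
    """
    if area_cm2 <= 0 or density_g_cm3 <= 0:
        raise ValueError("area and density must be positive")
    if deposited_mass_g < 0:
        raise ValueError("deposited mass cannot be negative")
    return 1e4 * deposited_mass_g / (area_cm2 * density_g_cm3)


def analyze_trial(trial: AssayTrial) -> AssaySummary:
    """Mass balance and thickness comparison for one trial.

    A trial whose runoff exceeds its applied mass is flagged invalid
    (``valid=False``) rather than raising, so batch analyses can report
    it.
    """
    applied = trial.syringe_before - trial.syringe_after
    runoff = trial.cardboard_after - trial.cardboard_before
    deposited = applied - runoff
    valid = deposited > 0
    theo = (
        theoretical_thickness(
            deposited, trial.mucosa_area_cm2, trial.liquid_density_g_cm3
        )
        if valid
        else float("nan")
    )
    mean5 = float(np.mean(trial.point_thicknesses))
    variation = 100.0 * (mean5 - theo) / theo if valid else float("nan")
    return AssaySummary(
        tilt_angle=trial.tilt_angle,
        applied_mass_g=applied,
        runoff_mass_g=runoff,
        deposited_mass_g=deposited,
        theoretical_thickness_um=theo,
        five_point_mean_um=mean5,
        variation_percent=variation,
        valid=bool(valid),
    )


_COLUMNS = [
    "applied_mass_g",
    "runoff_mass_g",
    "deposited_mass_g",
    "theoretical_thickness_um",
    "five_point_mean_um",
    "variation_percent",
]


def summarize_trials(trials) -> pd.DataFrame:
    """Per-angle mean, standard deviation and RSD of the derived columns.

    Returns a tidy frame indexed by (tilt_angle, statistic) with the
    derived columns; angles with a single trial carry NaN SD/RSD and a
    ``single_trial`` flag.  RSD is the sample SD as a percent of the
    mean (not reported for the signed variation column).
    """
    rows = []
    for t in trials:
        s = analyze_trial(t)
        if not s.valid:
            continue
        rows.append({"tilt_angle": s.tilt_angle, **{c: getattr(s, c) for c in _COLUMNS}})
    if not rows:
        raise ValueError("no valid trials to summarize")
    df = pd.DataFrame(rows)

    out = []
    for angle, grp in df.groupby("tilt_angle"):
        mean = grp[_COLUMNS].mean()
        sd = grp[_COLUMNS].std(ddof=1)
        rsd = 100.0 * sd / mean
        rsd["variation_percent"] = np.nan
        single = len(grp) == 1
        for stat, vals in (("mean", mean), ("sd", sd), ("rsd_percent", rsd)):
            out.append(
                {
                    "tilt_angle": angle,
                    "statistic": stat,
                    "n_trials": len(grp),
                    "single_trial": single,
                    **vals.to_dict(),
                }
            )
    summary = pd.DataFrame(out).set_index(["tilt_angle", "statistic"])

    # monotonicity of retained thickness against tilt angle
    means = summary.xs("mean", level="statistic")["theoretical_thickness_um"]
    summary.attrs["thickness_decreases_with_angle"] = bool(
        means.sort_index().is_monotonic_decreasing
    )
    return summary


def thickness_gradient_check(trial: AssayTrial):
    """Check that the film thickens toward the lower edge of a tilted coupon.

    Returns ``(decreasing, slope_um_per_mm)`` where ``decreasing`` is
    True when the Spearman rank correlation of thickness against
    distance from the bottom edge is non-positive, and the slope is the
    least-squares gradient in um/mm (negative for the expected profile).
    """
    x = np.asarray(datasets.THICKNESS_POINT_POSITIONS_MM)
    y = np.asarray(trial.point_thicknesses, dtype=float)
    if np.ptp(y) == 0:  # flat profile: rank correlation undefined, treat as 0
        rho = 0.0
    else:
        rho = stats.spearmanr(x, y).statistic
    slope = float(np.polyfit(x, y, 1)[0])
    return bool(rho <= 0), slope


# ---------------------------------------------------------------------------
# CSV interchange and reference comparison
# ---------------------------------------------------------------------------

_TRIAL_COLS = [
    "tilt_angle",
    "syringe_before",
    "syringe_after",
    "cardboard_before",
    "cardboard_after",
    "t_2mm",
    "t_6mm",
    "t_10mm",
    "t_14mm",
    "t_18mm",
]


def trials_to_frame(trials) -> pd.DataFrame:
    """Trials as a flat table (one row per trial, thicknesses widened)."""
    rows = []
    for t in trials:
        rows.append(
            [
                t.tilt_angle,
                t.syringe_before,
                t.syringe_after,
                t.cardboard_before,
                t.cardboard_after,
                *t.point_thicknesses,
            ]
        )
    return pd.DataFrame(rows, columns=_TRIAL_COLS)


def trials_from_frame(df: pd.DataFrame):
    return [
        AssayTrial(
            tilt_angle=float(r.tilt_angle),
            syringe_before=float(r.syringe_before),
            syringe_after=float(r.syringe_after),
            cardboard_before=float(r.cardboard_before),
            cardboard_after=float(r.cardboard_after),
            point_thicknesses=(
                float(r.t_2mm),
                float(r.t_6mm),
                float(r.t_10mm),
                float(r.t_14mm),
                float(r.t_18mm),
            ),
        )
        for r in df.itertuples()
    ]


def compare_with_printed(trials=None, printed=None) -> pd.DataFrame:
    """Side-by-side of recomputed-from-raw and published derived values.

    Recomputed values take precedence when the two disagree (a few
    published cells are inconsistent with their own raw masses); the
    returned frame marks every disagreement at reporting precision.
    """
    if trials is None:
        trials = datasets.porcine_trials_60deg()
    if printed is None:
        printed = datasets.PRINTED_SUMMARY_60_TILT
    rows = []
    for k, (t, p) in enumerate(zip(trials, printed), start=1):
        r = analyze_trial(t).rounded()
        printed_vals = dict(zip(_COLUMNS, p))
        row = {"trial": k}
        for c in _COLUMNS:
            row[f"{c}_recomputed"] = r[c]
            row[f"{c}_printed"] = printed_vals[c]
            row[f"{c}_agrees"] = np.isclose(r[c], printed_vals[c], atol=1e-9)
        rows.append(row)
    return pd.DataFrame(rows).set_index("trial")
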