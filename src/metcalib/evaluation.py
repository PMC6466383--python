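"""Validation machinery: calorimetric MET derivation and agreement statistics.

MET values are derived from indirect calorimetry: energy expenditure from
oxygen consumption and carbon dioxide production via Weir's protein-free
equation (EE [kcal/min] = 3.941 VO2 + 1.106 VCO2, gas rates in L/min), and
METs as activity EE divided by the measured resting metabolic rate EE.
Agreement between predicted and measured METs is summarised per activity
(mean +/- SD of absolute and percent differences, predicted minus measured)
and overall by Bland-Altman statistics with +/- 2 SD limits of agreement.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CalorimetryRecord",
    "AgreementStats",
    "weir_energy_expenditure",
    "met_from_ee",
    "bland_altman",
    "activity_error_table",
    "bland_altman_plot",
]

WEIR_KCAL_PER_L_O2 = 3.941
WEIR_KCAL_PER_L_CO2 = 1.106
KCAL_TO_KJ = 4.184

#: Physiological plausibility band for the respiratory quotient VCO2/VO2.
RQ_RANGE = (0.6, 1.3)


@dataclass(frozen=True)
class CalorimetryRecord:
    """One steady-state expired-gas measurement (Douglas bag)."""

    vo2_l_min: float
    vco2_l_min: float
    activity_label: Optional[str] = None
    subject_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.vo2_l_min <= 0 or self.vco2_l_min <= 0:
            raise ValueError(
                f"gas exchange rates must be positive, got VO2={self.vo2_l_min}, "
                f"VCO2={self.vco2_l_min}"
            )

    @property
    def respiratory_quotient(self) -> float:
        return self.vco2_l_min / self.vo2_l_min

    @property
    def rq_plausible(self) -> bool:
        lo, hi = RQ_RANGE
        return lo < self.respiratory_quotient < hi


def weir_energy_expenditure(record: CalorimetryRecord) -> float:
    """Energy expenditure in kJ/min from a calorimetry record (Weir equation)."""
    kcal_min = WEIR_KCAL_PER_L_O2 * record.vo2_l_min + WEIR_KCAL_PER_L_CO2 * record.vco2_l_min
    return kcal_min * KCAL_TO_KJ


def met_from_ee(activity_ee_kj_min: float, rmr_ee_kj_min: float) -> float:
    """MET value: activity energy expenditure over resting energy expenditure."""
    if rmr_ee_kj_min <= 0:
        raise ValueError(f"resting EE must be positive, got {rmr_ee_kj_min}")
    return activity_ee_kj_min / rmr_ee_kj_min


@dataclass(frozen=True)
class AgreementStats:
    """Bland-Altman summary of paired predicted/measured values."""

    mean_difference: float
    sd_difference: float
    loa_lower: float
    loa_upper: float
    n: int

    def to_dict(self) -> dict:
        return {
            "mean_diff": self.mean_difference,
            "sd_diff": self.sd_difference,
            "loa": [self.loa_lower, self.loa_upper],
            "n": self.n,
        }


def bland_altman(
    y_pred: Sequence[float], y_meas: Sequence[float], loa_multiplier: float = 2.0
) -> AgreementStats:
    """Mean difference and limits of agreement of predicted minus measured.

    Limits are mean +/- ``loa_multiplier`` * SD; the SD uses the n-1
    denominator. The default multiplier is 2 (not 1.96), the convention used
    for the published plots.
    """
    yp = np.asarray(y_pred, dtype=float)
    ym = np.asarray(y_meas, dtype=float)
    if yp.shape != ym.shape:
        raise ValueError(f"length mismatch: {yp.shape} vs {ym.shape}")
    if yp.size < 2:
        raise ValueError("need at least 2 pairs")
    d = yp - ym
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    return AgreementStats(
        mean_difference=mean,
        sd_difference=sd,
        loa_lower=mean - loa_multiplier * sd,
        loa_upper=mean + loa_multiplier * sd,
        n=int(d.size),
    )


def activity_error_table(
    y_pred: Sequence[float],
    y_meas: Sequence[float],
    labels: Sequence[str],
) -> pd.DataFrame:
    """Per-activity prediction error: mean +/- SD of absolute and % differences.

    Differences are predicted minus measured, so negative means
    underestimation. Percent differences use the measured value as
    denominator and are computed per pair before aggregating. Pairs with a
    measured value of exactly zero are excluded from the percent columns only
    and flagged in ``n_pct_excluded``.
    """
    yp = np.asarray(y_pred, dtype=float)
    ym = np.asarray(y_meas, dtype=float)
    lab = np.asarray(labels, dtype=object)
    if not (yp.shape == ym.shape == lab.shape):
        raise ValueError("y_pred, y_meas and labels must be aligned")
    rows = []
    for label in pd.unique(lab):
        sel = lab == label
        d = yp[sel] - ym[sel]
        ok = ym[sel] != 0
        pct = 100.0 * d[ok] / ym[sel][ok]
        rows.append(
            {
                "activity_label": label,
                "n": int(sel.sum()),
                "mean_abs_diff": float(d.mean()),
                "sd_abs_diff": float(d.std(ddof=1)) if d.size > 1 else 0.0,
                "mean_pct_diff": float(pct.mean()) if pct.size else np.nan,
                "sd_pct_diff": float(pct.std(ddof=1)) if pct.size > 1 else 0.0,
                "n_pct_excluded": int((~ok).sum()),
            }
        )
    return pd.DataFrame(rows)


def bland_altman_plot(y_pred, y_meas, loa_multiplier: float = 2.0, ax=None):
    """Scatter of differences against pair means with mean and LoA lines.

    Requires matplotlib (optional dependency); returns the axes.
    """
    import matplotlib.pyplot as plt

    stats = bland_altman(y_pred, y_meas, loa_multiplier)
    yp = np.asarray(y_pred, dtype=float)
    ym = np.asarray(y_meas, dtype=float)
    if ax is None:
        _, ax = plt.subplots()
    ax.scatter((yp + ym) / 2.0, yp - ym, s=12, alpha=0.6)
    ax.axhline(stats.mean_difference, color="k", lw=1)
    for y in (stats.loa_lower, stats.loa_upper):
        ax.axhline(y, color="k", lw=1, ls="--")
    ax.set_xlabel("Mean of predicted and measured METs")
    ax.set_ylabel("Predicted − measured METs")
    return ax
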