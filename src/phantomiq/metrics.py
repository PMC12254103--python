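"""Image-quality endpoints: recovery coefficient, contrast-to-noise ratio,
with/without-correction ratios, and the background-noise change.

Definitions (all activities in kBq/mL):

* ``RC = (T_observed / B_mean) / (T_in / B_in)`` — the measured target-to-
  background ratio divided by the true filled ratio.  With ``T_observed``
  the VOI maximum this is ``RC_max``; with the VOI mean, ``RC_mean``.
* ``CNR = (T_observed - B_mean) / sigma_B`` — contrast in units of the
  background noise; negative when the target reads below background.
* ``Ratio(s, a) = value_with / value_without`` per sphere and amplitude,
  averaged over TBRs (or over spheres per TBR).  A TBR cell is excluded from
  the average when its with- or without-correction value is negative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

PARAMETERS = ("rc_max", "rc_mean", "cnr_max", "cnr_mean")


def recovery_coefficient(t_observed: float, b_mean: float,
                         t_in: float, b_in: float) -> float:
    if b_mean <= 0:
        raise ValueError(f"b_mean must be > 0, got {b_mean}")
    if t_in <= 0 or b_in <= 0:
        raise ValueError(f"true activities must be > 0, got t_in={t_in}, b_in={b_in}")
    return (t_observed / b_mean) / (t_in / b_in)


def contrast_to_noise(t_observed: float, b_mean: float, sigma_b: float) -> float:
    if sigma_b <= 0:
        raise ValueError(f"sigma_b must be > 0, got {sigma_b}")
    return (t_observed - b_mean) / sigma_b


def ddmc_ratio(value_with: float, value_without: float) -> float:
    """With/without-correction ratio; NaN flags an undefined (zero) denominator."""
    if value_without == 0:
        return math.nan
    return value_with / value_without


@dataclass
class MeasurementRecord:
    """One (sphere, amplitude, TBR, corrected-flag) cell of the design."""

    sphere_id: int
    sphere_diameter_mm: float
    sphere_volume_ml: float
    amplitude: float
    tbr: float
    corrected: bool
    t_max: float
    t_mean: float
    b_mean: float
    sigma_b: float
    t_in: float
    b_in: float
    rc_max: float = field(init=False)
    rc_mean: float = field(init=False)
    cnr_max: float = field(init=False)
    cnr_mean: float = field(init=False)

    def __post_init__(self):
        self.rc_max = recovery_coefficient(self.t_max, self.b_mean, self.t_in, self.b_in)
        self.rc_mean = recovery_coefficient(self.t_mean, self.b_mean, self.t_in, self.b_in)
        if self.sigma_b > 0:
            self.cnr_max = contrast_to_noise(self.t_max, self.b_mean, self.sigma_b)
            self.cnr_mean = contrast_to_noise(self.t_mean, self.b_mean, self.sigma_b)
        else:
            # noise-free image: background SD vanishes and CNR is undefined;
            # flag with NaN so RC-only analyses still run
            self.cnr_max = math.nan
            self.cnr_mean = math.nan


def records_to_frame(records: list[MeasurementRecord]) -> pd.DataFrame:
    return pd.DataFrame([asdict(r) for r in records])


def _ratio_table(df: pd.DataFrame, parameter: str, cell_keys: list[str],
                 average_over: str) -> pd.DataFrame:
    wide = df.pivot_table(index=cell_keys + [average_over], columns="corrected",
                          values=parameter, aggfunc="first")
    if True not in wide.columns or False not in wide.columns:
        raise ValueError("records must contain both corrected and uncorrected cells")
    rows = []
    for keys, grp in wide.groupby(level=cell_keys, sort=True):
        if not isinstance(keys, tuple):
            keys = (keys,)
        ratios, excluded = [], []
        for idx, row in grp.iterrows():
            level = idx[-1]
            v_with, v_without = row[True], row[False]
            if v_with < 0 or v_without < 0:
                excluded.append(level)
                continue
            r = ddmc_ratio(v_with, v_without)
            if math.isnan(r):
                excluded.append(level)
                continue
            ratios.append(r)
        rows.append(dict(zip(cell_keys, keys),
                         parameter=parameter,
                         ratio=float(np.mean(ratios)) if ratios else math.nan,
                         n_included=len(ratios),
                         excluded=tuple(excluded)))
    return pd.DataFrame(rows)


def aggregate_ratios(records: pd.DataFrame | list[MeasurementRecord],
                     group_axes: str = "over_tbr",
                     parameters: tuple[str, ...] = PARAMETERS) -> pd.DataFrame:
    """Per-cell with/without ratios averaged over TBRs or over sphere sizes.

    ``over_tbr`` yields one row per (sphere, amplitude, parameter) with the
    mean of the per-TBR ratios; ``over_sphere`` yields one row per
    (TBR, amplitude, parameter) averaged over the six spheres.  Cells whose
    with- or without-correction value is negative are excluded from the mean
    and listed in the ``excluded`` column; a cell with nothing left to
    average carries a NaN ratio and ``n_included == 0``.

    The average is a mean of per-cell ratios, not a ratio of averaged values.
    """
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    if group_axes == "over_tbr":
        cell_keys, average_over = ["sphere_volume_ml", "amplitude"], "tbr"
    elif group_axes == "over_sphere":
        cell_keys, average_over = ["tbr", "amplitude"], "sphere_volume_ml"
    else:
        raise ValueError(f"group_axes must be 'over_tbr' or 'over_sphere', "
                         f"got {group_axes!r}")
    tables = [_ratio_table(df, p, cell_keys, average_over) for p in parameters]
    return pd.concat(tables, ignore_index=True)


def noise_change(records: pd.DataFrame | list[MeasurementRecord]) -> dict:
    """Relative change (%) of the background SD with correction.

    Per (TBR, amplitude): ``100 * (sigma_with - sigma_without) / sigma_without``.
    Per TBR the changes are averaged over amplitudes; two overall summaries
    are reported — the mean of the per-TBR means and the plain mean over all
    cells — because the aggregation order changes the value slightly.
    """
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    sigma = df.pivot_table(index=["tbr", "amplitude"], columns="corrected",
                           values="sigma_b", aggfunc="first")
    if sigma.isna().any().any() or True not in sigma.columns or False not in sigma.columns:
        missing = sigma[sigma.isna().any(axis=1)].index.tolist()
        raise ValueError(f"missing corrected/uncorrected pair for cells {missing}")
    change = 100.0 * (sigma[True] - sigma[False]) / sigma[False]
    per_cell = change.rename("sigma_b_change_pct").reset_index()
    per_tbr = change.groupby(level="tbr").mean()
    return {
        "per_cell": per_cell,
        "per_tbr_mean": per_tbr.to_dict(),
        "overall_mean_of_tbr_means": float(per_tbr.mean()),
        "overall_mean_of_cells": float(change.mean()),
    }
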