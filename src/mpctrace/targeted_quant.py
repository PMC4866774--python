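"""Targeted LC-MS/MS quantification.

Peak areas are converted to concentrations in three composed steps, in
this order:

1. internal-standard normalisation — the analyte peak area is divided by
   the co-eluting signal of the matching uniformly-¹³C-labeled internal
   standard (an E. coli extract spiked into every sample; derivatized
   pyruvate uses a [U-¹³C]pyruvate standard but the same arithmetic),
2. external calibration — the response ratio is mapped to a
   concentration through a least-squares line fitted on standards of
   known concentration,
3. protein normalisation — concentrations are divided by the sample's
   total protein to remove cell-amount effects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

logger = logging.getLogger(__name__)

__all__ = [
    "CalibrationCurve",
    "is_normalize",
    "calibrate",
    "protein_normalize",
    "TargetedQuantifier",
]


def is_normalize(area: float, is_area: float) -> float:
    """Response ratio: analyte peak area over internal-standard area."""
    if is_area <= 0:
        raise ValueError("internal-standard area must be > 0")
    if area < 0:
        raise ValueError("peak area must be >= 0")
    return area / is_area


@dataclass
class CalibrationCurve:
    """Least-squares line mapping response ratio to concentration."""

    metabolite_id: str
    concentrations: np.ndarray = field(default_factory=lambda: np.array([]))
    ratios: np.ndarray = field(default_factory=lambda: np.array([]))
    slope: float | None = None
    intercept: float | None = None

    def fit(self) -> "CalibrationCurve":
        conc = np.asarray(self.concentrations, dtype=float)
        ratio = np.asarray(self.ratios, dtype=float)
        if conc.size < 2:
            raise ValueError(f"{self.metabolite_id}: need >= 2 calibration points")
        self.slope, self.intercept = np.polyfit(conc, ratio, 1)
        if self.slope <= 0:
            raise ValueError(
                f"{self.metabolite_id}: calibration slope must be positive "
                f"(got {self.slope:.3g})"
            )
        return self

    @property
    def fitted(self) -> bool:
        return self.slope is not None


def calibrate(ratio: float, curve: CalibrationCurve) -> tuple[float, bool]:
    """Concentration from a response ratio: (ratio - intercept) / slope.

    Returns ``(concentration, floored)``; values that would be negative
    are reported as 0 with ``floored=True``.
    """
    if not curve.fitted:
        raise ValueError(f"{curve.metabolite_id}: calibration curve not fitted")
    conc = (ratio - curve.intercept) / curve.slope
    if conc < 0:
        return 0.0, True
    return float(conc), False


def protein_normalize(concentration: float, protein_mg: float) -> float:
    """Concentration per mg of cellular protein."""
    if protein_mg <= 0:
        raise ValueError("protein amount must be > 0 mg")
    if concentration < 0:
        raise ValueError("concentration must be >= 0")
    return concentration / protein_mg


class TargetedQuantifier(BaseEstimator, TransformerMixin):
    """Estimator turning peak tables into protein-normalised concentrations.

    ``fit`` learns per-metabolite calibration lines from a standards
    table (columns: metabolite_id, concentration, ratio); ``transform``
    consumes a peak table (columns: sample_id, metabolite_id, peak_area,
    internal_standard_area, protein_mg) and returns a tidy frame with
    columns sample_id, metabolite_id, concentration_per_mg, floored.

    Rows with a zero internal-standard signal are dropped with a logged
    warning; samples with non-positive protein are rejected.
    """

    def __init__(self, calibrate_output: bool = True):
        self.calibrate_output = calibrate_output

    def fit(self, standards: pd.DataFrame, y=None):
        curves: dict[str, CalibrationCurve] = {}
        for met, grp in standards.groupby("metabolite_id"):
            curves[met] = CalibrationCurve(
                met,
                grp["concentration"].to_numpy(),
                grp["ratio"].to_numpy(),
            ).fit()
        self.curves_ = curves
        return self

    def transform(self, peaks: pd.DataFrame) -> pd.DataFrame:
        if self.calibrate_output and not hasattr(self, "curves_"):
            raise ValueError("TargetedQuantifier must be fitted before transform")
        records = []
        for row in peaks.itertuples(index=False):
            if row.internal_standard_area <= 0:
                logger.warning(
                    "dropping %s/%s: internal-standard area is zero",
                    row.sample_id, row.metabolite_id,
                )
                continue
            if row.protein_mg <= 0:
                raise ValueError(f"sample {row.sample_id}: protein_mg must be > 0")
            ratio = is_normalize(row.peak_area, row.internal_standard_area)
            floored = False
            if self.calibrate_output:
                curve = self.curves_.get(row.metabolite_id)
                if curve is None:
                    raise KeyError(f"no calibration curve for {row.metabolite_id}")
                value, floored = calibrate(ratio, curve)
            else:
                value = ratio
            records.append(
                {
                    "sample_id": row.sample_id,
                    "metabolite_id": row.metabolite_id,
                    "concentration_per_mg": protein_normalize(value, row.protein_mg),
                    "floored": floored,
                }
            )
        return pd.DataFrame.from_records(
            records,
            columns=["sample_id", "metabolite_id", "concentration_per_mg", "floored"],
        )
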