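"""Per-vine aggregation and the cluster-area -> yield regression.

The yield estimate rests on a single linear model: total 2-D cluster
surface per vine, S (cm^2), against harvested grape mass per vine, y (g),

    y = beta1 * S + beta0 + eps,

fitted by ordinary least squares on a training season and applied to a
later season (season transfer).  The model is exposed statsmodels-style:
``AreaYieldModel`` holds the data, ``fit()`` returns an
``AreaYieldResults`` carrying estimates, standard errors, R^2,
``predict`` and ``summary``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .particles import ParticleSet

__all__ = [
    "VineRecord",
    "AreaYieldModel",
    "AreaYieldResults",
    "aggregate_vine",
    "fit_area_weight_regression",
    "predict_yield",
]


@dataclass
class VineRecord:
    """One vine: detected cluster totals plus optional ground truth."""

    vine_id: str
    vigor_zone: str = ""  # "HV" / "LV"
    condition: str = ""  # "B" / "W"
    total_cluster_area_cm2: float = 0.0
    detected_count: int = 0
    adjusted_count: int = 0
    observed_count: Optional[int] = None
    green_count: Optional[int] = None
    measured_yield_g: Optional[float] = None
    estimated_yield_g: Optional[float] = None

    def __post_init__(self):
        if self.total_cluster_area_cm2 < 0:
            raise ValueError("total cluster area cannot be negative")
        if (
            self.green_count is not None
            and self.observed_count is not None
            and self.green_count > self.observed_count
        ):
            raise ValueError("green clusters cannot exceed total observed clusters")


def aggregate_vine(
    particles: ParticleSet,
    vine_id: str,
    vigor_zone: str = "",
    condition: str = "",
) -> VineRecord:
    """Sum the retained, calibrated cluster areas of one vine's image."""
    if particles.calibration is None:
        raise ValueError(
            "cannot aggregate an uncalibrated particle set; set the pixel scale first"
        )
    total = particles.total_area_cm2() if particles.particles else 0.0
    adjusted = (
        particles.adjusted_count
        if particles.adjusted_count is not None
        else particles.raw_count
    )
    return VineRecord(
        vine_id=vine_id,
        vigor_zone=vigor_zone,
        condition=condition,
        total_cluster_area_cm2=total,
        detected_count=particles.raw_count,
        adjusted_count=adjusted,
    )


def _records_to_frame(records: Iterable[VineRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])


class AreaYieldModel:
    """OLS of measured vine yield (g) on total cluster area (cm^2).

    Parameters
    ----------
    data : DataFrame with columns ``total_cluster_area_cm2`` and
        ``measured_yield_g`` (rows with missing yield are dropped at fit).
    through_origin : force a zero intercept (area 0 => yield 0).
    """

    def __init__(self, data: pd.DataFrame, through_origin: bool = False):
        if "total_cluster_area_cm2" not in data or "measured_yield_g" not in data:
            missing = {"total_cluster_area_cm2", "measured_yield_g"} - set(data.columns)
            raise ValueError(f"missing required columns: {sorted(missing)}")
        self.data = data
        self.through_origin = bool(through_origin)

    @classmethod
    def from_records(
        cls, records: Sequence[VineRecord], through_origin: bool = False
    ) -> "AreaYieldModel":
        return cls(_records_to_frame(records), through_origin=through_origin)

    def fit(self) -> "AreaYieldResults":
        df = self.data.dropna(subset=["total_cluster_area_cm2", "measured_yield_g"])
        if len(df) < 2:
            raise ValueError(
                f"need at least 2 vines with both area and yield, got {len(df)}"
            )
        x = df["total_cluster_area_cm2"].to_numpy(dtype=np.float64)
        y = df["measured_yield_g"].to_numpy(dtype=np.float64)
        if np.ptp(x) == 0:
            raise ValueError("cluster areas have zero variance; regression degenerate")
        exog = x[:, None] if self.through_origin else sm.add_constant(x)
        res = sm.OLS(y, exog).fit()
        if self.through_origin:
            slope, intercept = float(res.params[0]), 0.0
        else:
            intercept, slope = (float(v) for v in res.params)
        return AreaYieldResults(
            slope=slope,
            intercept=intercept,
            r_squared=float(res.rsquared),
            n_train=int(len(df)),
            slope_se=float(res.bse[-1]),
            through_origin=self.through_origin,
            fit_meta={},
            _sm_results=res,
        )


@dataclass
class AreaYieldResults:
    """Fitted area->weight line; predicts grams from cm^2."""

    slope: float  # g per cm^2
    intercept: float  # g
    r_squared: float
    n_train: int
    slope_se: float = float("nan")
    through_origin: bool = False
    fit_meta: dict = field(default_factory=dict)
    _sm_results: object = None

    def predict(self, area_cm2) -> np.ndarray:
        """Predicted yield in grams; negative predictions clamp to 0."""
        area = np.asarray(area_cm2, dtype=np.float64)
        pred = self.slope * area + self.intercept
        neg = pred < 0
        if np.any(neg):
            import warnings

            warnings.warn(
                "negative yield prediction clamped to 0 g", stacklevel=2
            )
            pred = np.where(neg, 0.0, pred)
        return pred if pred.ndim else float(pred)

    def predict_record(self, record: VineRecord) -> float:
        return float(self.predict(record.total_cluster_area_cm2))

    def apply(self, records: Sequence[VineRecord]) -> List[VineRecord]:
        """Season transfer: fill ``estimated_yield_g`` on new vines."""
        out = []
        for r in records:
            est = self.predict_record(r)
            out.append(
                VineRecord(**{**r.__dict__, "estimated_yield_g": est})
            )
        return out

    def summary(self) -> str:
        lines = [
            "Area -> yield linear regression (OLS)",
            "-------------------------------------",
            f"  n vines (train) : {self.n_train}",
            f"  slope           : {self.slope:.4f} g/cm^2  (se {self.slope_se:.4f})",
            f"  intercept       : {self.intercept:.4f} g"
            + ("  [forced 0]" if self.through_origin else ""),
            f"  R^2             : {self.r_squared:.4f}",
        ]
        if self.fit_meta:
            lines.append(f"  fit meta        : {self.fit_meta}")
        return "\n".join(lines)

    # persistence -------------------------------------------------------
    def to_json(self, path=None) -> str:
        payload = {
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "n_train": self.n_train,
            "slope_se": self.slope_se,
            "through_origin": self.through_origin,
            "fit_meta": self.fit_meta,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "AreaYieldResults":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        return cls(**payload)


def fit_area_weight_regression(
    records: Sequence[VineRecord], through_origin: bool = False
) -> AreaYieldResults:
    """Convenience wrapper: build the model from records and fit."""
    return AreaYieldModel.from_records(records, through_origin=through_origin).fit()


def predict_yield(results: AreaYieldResults, record: VineRecord) -> float:
    """Estimated grams for one vine from its total cluster area."""
    return results.predict_record(record)
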