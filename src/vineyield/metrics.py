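"""Detection and yield evaluation statistics, plus NDVI.

TPR here is a count ratio, not a pixel-level classifier rate: the
percentage of ground-observed clusters that the automatic method finds,

    TPR       = detected / observed_total * 100
    TPR_Ripe  = detected / (observed_total - observed_green) * 100,

where the ripe variant drops unripe (green) bunches from the
denominator — green clusters are nearly invisible against foliage and
are deliberately out of the method's reach.  Neither is clamped: a
method that over-counts can exceed 100%.

Yield accuracy is the complement of the absolute percent error of the
estimate against the ground-measured mass:

    percent_error = (measured - estimated) / measured * 100   (signed)
    accuracy      = 100 - |percent_error|.

Both single-vine and mean-of-vines use are supported: every function
broadcasts over array inputs, and ``mean_tpr``-style aggregation is a
plain numpy mean over per-vine values.
"""

from __future__ import annotations

import numpy as np

__all__ = ["tpr", "tpr_ripe", "percent_error", "accuracy_pct", "ndvi"]


def _as_float(x):
    arr = np.asarray(x, dtype=np.float64)
    return arr


def tpr(detected_adjusted, observed_total):
    """Percent of observed clusters detected (may exceed 100)."""
    det, obs = _as_float(detected_adjusted), _as_float(observed_total)
    if np.any(obs <= 0):
        raise ValueError("observed_total must be positive")
    out = det / obs * 100.0
    return out if out.ndim else float(out)


def tpr_ripe(detected_adjusted, observed_total, observed_green):
    """Percent of observed *ripe* clusters detected."""
    det = _as_float(detected_adjusted)
    obs = _as_float(observed_total)
    green = _as_float(observed_green)
    if np.any(green > obs):
        raise ValueError("green clusters cannot exceed total observed")
    ripe = obs - green
    if np.any(ripe <= 0):
        raise ValueError("no ripe clusters observed; TPR_Ripe undefined")
    out = det / ripe * 100.0
    return out if out.ndim else float(out)


def percent_error(measured_g, estimated_g):
    """Signed percent error of the yield estimate: positive means
    under-estimation."""
    meas, est = _as_float(measured_g), _as_float(estimated_g)
    if np.any(meas <= 0):
        raise ValueError("measured yield must be positive")
    out = (meas - est) / meas * 100.0
    return out if out.ndim else float(out)


def accuracy_pct(measured_g, estimated_g):
    """100 minus the absolute percent error; negative for gross
    overestimation (error beyond 100%)."""
    err = np.abs(_as_float(percent_error(measured_g, estimated_g)))
    out = 100.0 - err
    return out if out.ndim else float(out)


def ndvi(r_nir, r_red):
    """Normalized difference vegetation index, (Rnir - Rred)/(Rnir + Rred)."""
    nir, red = _as_float(r_nir), _as_float(r_red)
    if np.any(nir < 0) or np.any(red < 0) or np.any(nir > 1) or np.any(red > 1):
        raise ValueError("reflectances must lie in [0, 1]")
    denom = nir + red
    if np.any(denom == 0):
        raise ValueError("NDVI undefined for zero total reflectance")
    out = (nir - red) / denom
    return out if out.ndim else float(out)
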