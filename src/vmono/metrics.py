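"""Quantitative evaluation: percentage error, MAE, UNAAD uniformity.

The percentage-error metric compares predicted to reference line-integral
images pixel-wise, 100 * |pred - ref| / ref, excluding air trajectories
(pixels whose reference line integral is at or below a small threshold,
0.01 by default -- pixels with a tiny positive reference would otherwise
produce unbounded percentages).

UNAAD (uniform normalized absolute average deviation) scores the uniformity
of a reconstructed region of interest::

    UNAAD = 100 - 100 / (N * Ybar) * sum_i |Y_i - Ybar|

and equals 100 exactly for a constant region; larger is more uniform.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "ErrorSummary",
    "percentage_error",
    "mae",
    "unaad",
    "reconstruction_difference_map",
    "path_length_error_report",
]

AIR_THRESHOLD = 0.01  #: default reference line integral at/below which a pixel is air


@dataclass
class ErrorSummary:
    """Mean/SD percentage error over non-excluded pixels plus the error map."""

    mean: float                 # %
    std: float                  # %
    error_map: np.ndarray       # %, NaN where excluded
    excluded_mask: np.ndarray   # True where excluded
    n_excluded: int

    @property
    def n_used(self) -> int:
        return int(self.error_map.size - self.n_excluded)


def percentage_error(predicted: np.ndarray, reference: np.ndarray,
                     air_threshold: float = AIR_THRESHOLD) -> ErrorSummary:
    """Air-excluded per-pixel percentage error 100*|pred - ref|/ref."""
    predicted = np.asarray(predicted, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if predicted.shape != reference.shape:
        raise ValueError("shape mismatch between predicted and reference")
    if air_threshold < 0:
        raise ValueError("air_threshold must be >= 0")
    excluded = reference <= air_threshold
    if excluded.all():
        raise ValueError("all pixels excluded as air; nothing to evaluate")
    err = np.full(predicted.shape, np.nan)
    sel = ~excluded
    err[sel] = 100.0 * np.abs(predicted[sel] - reference[sel]) / reference[sel]
    vals = err[sel]
    return ErrorSummary(float(vals.mean()), float(vals.std()), err, excluded,
                        int(excluded.sum()))


def mae(predicted: np.ndarray, reference: np.ndarray) -> float:
    """Mean absolute error over all pixels (no air exclusion)."""
    predicted = np.asarray(predicted, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if predicted.shape != reference.shape:
        raise ValueError("shape mismatch between predicted and reference")
    return float(np.abs(predicted - reference).mean())


def unaad(values: np.ndarray, roi_mask: np.ndarray | None = None) -> float:
    """Uniform normalized absolute average deviation of an ROI; <= 100."""
    values = np.asarray(values, dtype=float)
    if roi_mask is not None:
        roi_mask = np.asarray(roi_mask, dtype=bool)
        if roi_mask.shape != values.shape:
            raise ValueError("ROI mask shape mismatch")
        values = values[roi_mask]
    values = values.ravel()
    if values.size == 0:
        raise ValueError("empty ROI")
    ybar = values.mean()
    if ybar == 0:
        raise ValueError("zero-mean ROI: UNAAD undefined")
    return float(100.0 - 100.0 / (values.size * ybar) *
                 np.abs(values - ybar).sum())


def reconstruction_difference_map(raw: np.ndarray, corrected: np.ndarray,
                                  body_threshold: float = 0.05):
    """Per-voxel percentage difference map between raw and corrected volumes.

    The map is 100 * (raw - corrected) / raw, so a region whose corrected
    value is 15 % below the raw value reads +15.  Returns (map %, body mask);
    statistics should be read off the masked voxels (|corrected| above
    ``body_threshold``); the map is NaN outside.
    """
    raw = np.asarray(raw, dtype=float)
    corrected = np.asarray(corrected, dtype=float)
    if raw.shape != corrected.shape:
        raise ValueError("volume grids do not match")
    mask = (np.abs(corrected) > body_threshold) & (raw != 0)
    out = np.full(raw.shape, np.nan)
    out[mask] = 100.0 * (raw[mask] - corrected[mask]) / raw[mask]
    return out, mask


def path_length_error_report(errors_long: np.ndarray, errors_short: np.ndarray):
    """Wilcoxon signed-ranks comparison of paired per-projection errors.

    Convenience wrapper for checking that prediction loss does not depend on
    whether the beam crossed the long or the short axis of the animal.
    Returns (statistic, p_value).
    """
    res = stats.wilcoxon(np.asarray(errors_long, float),
                         np.asarray(errors_short, float))
    return float(res.statistic), float(res.pvalue)
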