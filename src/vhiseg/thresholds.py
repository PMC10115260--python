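"""Adaptive STIR intensity thresholds from the normal-bone reference region.

Two thresholds are estimated from the intensity distribution of manually
segmented normal sacral marrow:

* the **conservative** threshold ``L_upper``, the maximum intensity ``I_max``
  of the reference distribution, and
* the **sensitive** threshold ``L_lower = Q_U + n * IQR``, where ``Q_U`` is
  the upper quartile and ``IQR`` the inter-quartile range.

The multiple ``n`` adapts per scan: it starts at 1.5 and is incremented in
exact steps of 0.05 until the gap between the two thresholds satisfies
``0 < L_upper - L_lower < IQR / 2``. If the condition already holds at
n = 1.5 no incrementation is performed. Because raising ``n`` only lowers
the gap, a non-positive gap at the first ``n`` meeting ``gap < IQR/2`` can
never recover; such inputs (as well as zero-IQR samples and runaway loops)
are flagged *degenerate* and collapse both thresholds onto ``L_upper``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ImageVolume, RegionMask, ValidationError, ensure_aligned

__all__ = [
    "ThresholdEstimate",
    "estimate_thresholds",
    "extract_region_intensities",
    "N_START",
    "N_STEP",
    "MAX_INCREMENTS",
]

N_START = 1.5
N_STEP = 0.05
MAX_INCREMENTS = 2000


@dataclass(frozen=True)
class ThresholdEstimate:
    """Sensitive / conservative thresholds for one scan.

    Attributes
    ----------
    q_upper : upper quartile of the reference intensities.
    iqr : inter-quartile range (>= 0).
    i_max : maximum reference intensity; always equals ``l_upper``.
    n_multiple : the adapted multiple n (1.5 + k * 0.05 for integer k).
    l_lower : sensitive threshold; equals ``l_upper`` when degenerate.
    l_upper : conservative threshold.
    degenerate : True when no valid sensitive threshold exists (zero IQR,
        non-positive threshold gap, or increment cap reached).
    """

    q_upper: float
    iqr: float
    i_max: float
    n_multiple: float
    l_lower: float
    l_upper: float
    degenerate: bool

    def __post_init__(self) -> None:
        if self.l_upper != self.i_max:
            raise ValidationError("l_upper must equal i_max")
        if self.degenerate and self.l_lower != self.l_upper:
            raise ValidationError("degenerate estimate must have l_lower == l_upper")


def estimate_thresholds(
    normal_intensities, min_samples: int = 8
) -> ThresholdEstimate:
    """Estimate sensitive and conservative thresholds from reference intensities.

    Parameters
    ----------
    normal_intensities : sequence of float
        STIR intensities of the normal-bone reference voxels.
    min_samples : int
        Minimum acceptable sample size (default 8).

    Returns
    -------
    ThresholdEstimate

    Raises
    ------
    ValidationError
        On fewer than ``min_samples`` values or non-finite values.
    """
    x = np.asarray(normal_intensities, dtype=np.float64).ravel()
    if x.size < min_samples:
        raise ValidationError(
            f"need at least {min_samples} reference samples, got {x.size}"
        )
    if not np.all(np.isfinite(x)):
        raise ValidationError("reference intensities must be finite")

    # Quartiles by linear interpolation between order statistics.
    q_lower, q_upper = np.percentile(x, [25.0, 75.0])
    iqr = float(q_upper - q_lower)
    i_max = float(x.max())
    q_upper = float(q_upper)

    if iqr == 0.0:
        return ThresholdEstimate(q_upper, iqr, i_max, N_START, i_max, i_max, True)

    # Loop over the exact n grid 1.5 + k*0.05 (integer k avoids float drift).
    half_iqr = iqr / 2.0
    for k in range(MAX_INCREMENTS + 1):
        n = N_START + k * N_STEP
        l_lower = q_upper + n * iqr
        gap = i_max - l_lower
        if gap < half_iqr:
            if gap <= 0.0:
                return ThresholdEstimate(q_upper, iqr, i_max, n, i_max, i_max, True)
            return ThresholdEstimate(q_upper, iqr, i_max, n, float(l_lower), i_max, False)
    n = N_START + MAX_INCREMENTS * N_STEP
    return ThresholdEstimate(q_upper, iqr, i_max, n, i_max, i_max, True)


def extract_region_intensities(volume: ImageVolume, mask: RegionMask) -> np.ndarray:
    """Intensities of exactly the voxels covered by ``mask``.

    Order follows the C-order raster scan of the grid (deterministic).
    """
    ensure_aligned(volume, mask, context="extract_region_intensities")
    if mask.is_empty():
        raise ValidationError("reference mask is empty")
    return volume.data[mask.data]
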