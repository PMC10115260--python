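"""Agreement and response statistics for segmentation biomarkers.

Covers the comparison machinery used to evaluate a volumetric inflammation
biomarker against visual scoring: Dice overlap, a >=3-of-4 composite
reference standard, Bland-Altman limits of agreement (optionally after a
log(x+1) transform that leaves zeros unaltered), ordinary least-squares
regression with t-based confidence intervals, a strict-decrease responder
rule, and flagging of inter-observer discrepancies beyond k standard
deviations from zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .core import RegionMask, ValidationError, ensure_aligned

__all__ = [
    "AgreementStats",
    "ResponseRecord",
    "dice",
    "composite_reference",
    "bland_altman",
    "linear_fit",
    "LinearFit",
    "classify_response",
    "flag_discrepancies",
    "bland_altman_plot",
]

logger = logging.getLogger(__name__)

LOA_MULTIPLIER = 1.96


@dataclass(frozen=True)
class AgreementStats:
    """Bland-Altman bias and 95% limits of agreement for paired scores."""

    bias: float
    loa_low: float
    loa_high: float
    n: int
    transform: str  # "raw" | "log1p"


@dataclass(frozen=True)
class ResponseRecord:
    subject: str
    baseline: float
    followup: float

    @property
    def delta(self) -> float:
        return self.followup - self.baseline

    @property
    def responder(self) -> bool:
        """Any improvement (strict decrease) counts as a response."""
        return self.delta < 0


def dice(a: RegionMask, b: RegionMask) -> float:
    """Dice overlap 2|A∩B| / (|A| + |B|) between two binary masks.

    Two empty masks agree vacuously and score 1.0 (with a warning).
    """
    ensure_aligned(a, b, context="dice")
    na, nb = a.count(), b.count()
    if na == 0 and nb == 0:
        logger.warning("dice: both masks empty; returning 1.0 (vacuous agreement)")
        return 1.0
    inter = int(np.count_nonzero(a.data & b.data))
    return 2.0 * inter / (na + nb)


def composite_reference(masks: list[RegionMask], min_votes: int = 3) -> RegionMask:
    """Majority-vote composite: voxels inflamed in at least ``min_votes`` masks.

    The canonical use is two manual and two semi-automated segmentation
    trials with a >=3-of-4 vote defining "truly inflamed" voxels.
    """
    if min_votes < 1:
        raise ValidationError("min_votes must be >= 1")
    if len(masks) < min_votes:
        raise ValidationError(
            f"need at least min_votes={min_votes} masks, got {len(masks)}"
        )
    ensure_aligned(*masks, context="composite_reference")
    votes = np.zeros(masks[0].shape, dtype=np.int32)
    for m in masks:
        votes += m.data
    return RegionMask(votes >= min_votes, masks[0].spacing_mm, "composite_reference")


def _log1p_checked(values: np.ndarray) -> np.ndarray:
    if np.any(values < 0):
        raise ValidationError("log1p transform requires non-negative values")
    return np.log1p(values)


def bland_altman(x, y, transform: str = "raw") -> AgreementStats:
    """Bland-Altman bias and 95% limits of agreement for paired measurements.

    Differences are ``x - y`` after an optional ``log(x+1)`` transform of
    both sides (zeros are unaltered by the transform). The limits are
    ``bias ± 1.96 * SD`` with the sample (n-1) standard deviation.
    """
    x = np.asarray(x, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    if x.size != y.size:
        raise ValidationError(f"length mismatch: {x.size} vs {y.size}")
    if x.size < 3:
        raise ValidationError(f"need at least 3 pairs, got {x.size}")
    if transform == "log1p":
        x, y = _log1p_checked(x), _log1p_checked(y)
    elif transform != "raw":
        raise ValidationError(f"unknown transform {transform!r}")
    d = x - y
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return AgreementStats(
        bias=bias,
        loa_low=bias - LOA_MULTIPLIER * sd,
        loa_high=bias + LOA_MULTIPLIER * sd,
        n=int(d.size),
        transform=transform,
    )


@dataclass(frozen=True)
class LinearFit:
    slope: float
    intercept: float
    slope_ci: tuple[float, float]
    intercept_ci: tuple[float, float]
    r_squared: float
    n: int


def linear_fit(x, y) -> LinearFit:
    """OLS fit of y on x with 95% CIs from the t distribution (n-2 dof)."""
    x = np.asarray(x, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    if x.size != y.size:
        raise ValidationError(f"length mismatch: {x.size} vs {y.size}")
    if x.size < 3:
        raise ValidationError(f"need at least 3 points, got {x.size}")
    if np.ptp(x) == 0:
        raise ValidationError("x is constant; slope undefined")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    ci = model.conf_int(alpha=0.05)
    return LinearFit(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        slope_ci=(float(ci[1, 0]), float(ci[1, 1])),
        intercept_ci=(float(ci[0, 0]), float(ci[0, 1])),
        r_squared=float(model.rsquared),
        n=int(x.size),
    )


def classify_response(
    scores: pd.DataFrame, external_labels: dict[str, bool] | None = None
):
    """Strict-decrease responder classification, optionally vs external labels.

    Parameters
    ----------
    scores : DataFrame with columns ``subject``, ``baseline``, ``followup``.
        Rows with a missing baseline or follow-up are skipped with a warning.
    external_labels : optional mapping subject -> bool (e.g. clinical response).

    Returns
    -------
    (records, concordance) where ``records`` is a list of
    :class:`ResponseRecord` and ``concordance`` is None or a dict with
    ``agree``, ``disagree``, ``n`` and the 2x2 ``table``
    (rows: biomarker responder yes/no; columns: external yes/no).
    """
    required = {"subject", "baseline", "followup"}
    if not required.issubset(scores.columns):
        raise ValidationError(f"scores must have columns {sorted(required)}")
    records: list[ResponseRecord] = []
    for row in scores.itertuples(index=False):
        if pd.isna(row.baseline) or pd.isna(row.followup):
            logger.warning("classify_response: subject %s missing a score; skipped", row.subject)
            continue
        records.append(
            ResponseRecord(str(row.subject), float(row.baseline), float(row.followup))
        )
    concordance = None
    if external_labels is not None:
        table = np.zeros((2, 2), dtype=int)
        agree = 0
        n = 0
        for rec in records:
            if rec.subject not in external_labels:
                logger.warning(
                    "classify_response: subject %s has no external label; skipped", rec.subject
                )
                continue
            ext = bool(external_labels[rec.subject])
            table[0 if rec.responder else 1, 0 if ext else 1] += 1
            agree += int(rec.responder == ext)
            n += 1
        concordance = {"agree": agree, "disagree": n - agree, "n": n, "table": table}
    return records, concordance


def flag_discrepancies(diffs, k_sd: float = 2.0, about_zero: bool = True) -> np.ndarray:
    """Indices of inter-observer differences more than ``k_sd`` SD from zero.

    With ``about_zero`` (default) deviations are measured from 0 and the
    standard deviation is the root mean square of the differences about 0.
    With ``about_zero=False`` both the deviations and the sample (n-1) SD
    are taken about the mean difference instead. The comparison is strict (>).
    """
    d = np.asarray(diffs, dtype=np.float64).ravel()
    if d.size < 3:
        raise ValidationError(f"need at least 3 differences, got {d.size}")
    if about_zero:
        sd = float(np.sqrt(np.mean(d**2)))
        deviations = np.abs(d)
    else:
        sd = float(d.std(ddof=1))
        deviations = np.abs(d - d.mean())
    return np.flatnonzero(deviations > k_sd * sd)


def bland_altman_plot(x, y, transform: str = "raw", ax=None, title: str | None = None):
    """Scatter of differences vs means with bias and 95% LoA lines."""
    import matplotlib.pyplot as plt

    stats = bland_altman(x, y, transform=transform)
    x = np.asarray(x, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    if transform == "log1p":
        x, y = np.log1p(x), np.log1p(y)
    if ax is None:
        _, ax = plt.subplots()
    ax.scatter((x + y) / 2.0, x - y, s=14)
    ax.axhline(stats.bias, color="k", label=f"bias {stats.bias:.3g}")
    for v in (stats.loa_low, stats.loa_high):
        ax.axhline(v, color="k", linestyle="--")
    ax.set_xlabel("mean of readers")
    ax.set_ylabel("difference between readers")
    if title:
        ax.set_title(title)
    ax.legend()
    return ax, stats
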