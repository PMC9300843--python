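"""Volumetric ROI biomarkers and measurement repeatability.

Two oxygen-saturation summaries are computed over a tumor ROI:

* **StO2 average** — mean StO2 over the ROI voxels that carry signal
  (the valid-mask voxels);
* **StO2 total** — mean over *all* ROI voxels, with signal-free voxels
  contributing zero.

The total is therefore never larger than the average, with equality
exactly when every ROI voxel carries signal.  HbT average/total follow
the same convention.  Tumor volume comes either from the ROI voxel count
or from the ellipsoid caliper formula V = L*W*H*pi/6.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import EmptyROIError, InsufficientDataError, ValidationError
from .unmix import ChromophoreMaps

__all__ = [
    "ROIMetrics",
    "CaliperMeasurement",
    "roi_statistics",
    "caliper_volume",
    "repeatability_variance",
]


@dataclass(frozen=True)
class ROIMetrics:
    """Volumetric biomarkers of one ROI in one acquisition.

    ``sto2_avg`` is NaN (and ``sto2_avg_defined`` False) when no ROI voxel
    carries signal; ``sto2_tot`` is 0 in that case.
    """

    sto2_avg: float
    sto2_tot: float
    hbt_avg: float
    hbt_tot: float
    n_voxels_roi: int
    n_voxels_signal: int
    volume_mm3: float

    @property
    def sto2_avg_defined(self) -> bool:
        return not math.isnan(self.sto2_avg)


@dataclass(frozen=True)
class CaliperMeasurement:
    """Caliper length, width and height of a tumor, in mm."""

    L: float
    W: float
    H: float

    def __post_init__(self) -> None:
        if min(self.L, self.W, self.H) <= 0:
            raise ValidationError("caliper dimensions must be positive")


def caliper_volume(m: CaliperMeasurement) -> float:
    """Ellipsoid tumor volume from caliper dimensions: L*W*H*pi/6 (mm^3)."""
    return m.L * m.W * m.H * math.pi / 6.0


def roi_statistics(
    maps: ChromophoreMaps,
    mask: np.ndarray,
    voxel_spacing: Sequence[float] | None = None,
) -> ROIMetrics:
    """Compute the ROI biomarkers from chromophore maps and a mask.

    ``voxel_spacing`` defaults to the spacing carried by ``maps``.
    """
    mask = np.asarray(mask).astype(bool)
    if mask.shape != maps.shape:
        raise ValidationError("mask shape must match the maps")
    if not mask.any():
        raise EmptyROIError("ROI mask selects no voxels")
    spacing = tuple(voxel_spacing) if voxel_spacing is not None else maps.voxel_spacing

    n_roi = int(mask.sum())
    signal = mask & maps.valid_mask
    n_sig = int(signal.sum())

    if n_sig:
        sto2_avg = float(maps.sto2[signal].mean())
        hbt_avg = float(maps.hbt[signal].mean())
        # invalid voxels contribute 0 to the numerator, full ROI to the denominator
        sto2_tot = float(maps.sto2[signal].sum() / n_roi)
        hbt_tot = float(maps.hbt[signal].sum() / n_roi)
    else:
        sto2_avg = float("nan")
        hbt_avg = float("nan")
        sto2_tot = 0.0
        hbt_tot = 0.0

    return ROIMetrics(
        sto2_avg=sto2_avg,
        sto2_tot=sto2_tot,
        hbt_avg=hbt_avg,
        hbt_tot=hbt_tot,
        n_voxels_roi=n_roi,
        n_voxels_signal=n_sig,
        volume_mm3=float(n_roi * np.prod(spacing)),
    )


_METRIC_FIELDS = ("sto2_avg", "sto2_tot", "hbt_avg", "hbt_tot", "volume_mm3")


def repeatability_variance(
    replicate_metrics: Sequence[Sequence[ROIMetrics]] | Sequence[ROIMetrics],
) -> pd.DataFrame:
    """Session-to-session sample variance of each ROI biomarker.

    Parameters
    ----------
    replicate_metrics : sequence
        Either one subject's replicate-session metrics (a flat sequence of
        :class:`ROIMetrics`, >= 2 entries) or a sequence of such sequences,
        one per subject.

    Returns
    -------
    DataFrame
        One row per metric with the per-subject variances, their mean and
        (for >= 2 subjects) SD across subjects — the "mean +/- SD of the
        replicate variance" summary used for repeatability reporting.
    """
    if replicate_metrics and isinstance(replicate_metrics[0], ROIMetrics):
        subjects = [list(replicate_metrics)]
    else:
        subjects = [list(s) for s in replicate_metrics]
    for reps in subjects:
        if len(reps) < 2:
            raise InsufficientDataError(
                "repeatability needs >= 2 replicate sessions per subject"
            )

    records = {}
    for name in _METRIC_FIELDS:
        per_subject = [
            float(np.var([getattr(m, name) for m in reps], ddof=1))
            for reps in subjects
        ]
        records[name] = dict(
            variances=per_subject,
            mean_variance=float(np.mean(per_subject)),
            sd_variance=float(np.std(per_subject, ddof=1))
            if len(per_subject) > 1
            else float("nan"),
        )
    out = pd.DataFrame.from_dict(records, orient="index")
    out.index.name = "metric"
    return out
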