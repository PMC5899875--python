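"""Tissue volume change across freezing from paired CT volumes.

For fixed tissue composition the CT number tracks density, and mass is
conserved across freezing, so the local after/before volume ratio is
(1000 + CT_before) / (1000 + CT_after).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .metrics import BinaryMask
from .volume_io import Volume

__all__ = ["HUVolume", "volume_ratio", "roi_volume_change"]


@dataclass
class HUVolume(Volume):
    """A CT volume in Hounsfield units (water = 0, air = -1000)."""


def _hu_array(v):
    if isinstance(v, Volume):
        return np.asarray(v.data, dtype=float)
    return np.asarray(v, dtype=float)


def volume_ratio(hu_before, hu_after):
    """V_after / V_before = (1000 + CT_before) / (1000 + CT_after).

    Accepts scalars or volumes (elementwise map).  Exactly reciprocal when
    the arguments are swapped.
    """
    before = _hu_array(hu_before)
    after = _hu_array(hu_after)
    denom = 1000.0 + after
    if np.any(denom <= 0):
        raise ValueError("nonphysical CT value: 1000 + CT_after <= 0")
    ratio = (1000.0 + before) / denom
    if np.isscalar(hu_before) or (ratio.ndim == 0):
        return float(ratio)
    if isinstance(hu_before, Volume):
        return Volume(ratio, hu_before.spacing, hu_before.origin)
    return ratio


def roi_volume_change(before: Volume, after: Volume, roi: BinaryMask):
    """Percent volume change over an ROI of rigidly aligned CT pairs.

    Returns ``(percent_change, sd_percent, report)`` where the change is
    100 * (mean voxelwise ratio - 1) and sd is the population sd of the
    voxelwise ratios * 100.  Nonphysical voxels (HU <= -1000) are excluded
    and counted in the report instead of failing the ROI.
    """
    if tuple(before.shape) != tuple(after.shape):
        raise ValueError("CT pair must be on a common (aligned) grid")
    if roi.data.shape != tuple(before.shape):
        raise ValueError("ROI must share the CT grid")
    if not roi.data.any():
        raise ValueError("empty ROI")
    hb = np.asarray(before.data, dtype=float)[roi.data]
    ha = np.asarray(after.data, dtype=float)[roi.data]
    physical = (hb > -1000.0) & (ha > -1000.0)
    n_excluded = int((~physical).sum())
    if not physical.any():
        raise ValueError("no physical voxels in ROI")
    ratios = (1000.0 + hb[physical]) / (1000.0 + ha[physical])
    percent = 100.0 * (ratios.mean() - 1.0)
    sd = 100.0 * ratios.std()
    report = {"n_voxels": int(physical.sum()), "n_excluded_nonphysical": n_excluded}
    return float(percent), float(sd), report
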