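"""Background-calibrated marker (Egr3) intensity quantification.

The background level is calibrated from a *primary negative* image (a
control stain omitting the primary antibody): the threshold is the
smallest integer grey level that removes at least 99% of the positive
pixel coverage (pixels with grey value above 0).  Background subtraction
is masking, not shifting -- pixels at or below the threshold are zeroed,
pixels above keep their original value -- because every downstream
quantity (coverage, summed intensity per nucleus, per-myotube mean)
counts or sums signal *above background*.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .micrograph import Micrograph


@dataclass(frozen=True)
class IntensityCalibration:
    background_threshold: int
    source: str
    removed_fraction: float
    dtype: str

    def to_dict(self) -> dict:
        return {
            "background_threshold": int(self.background_threshold),
            "source": self.source,
            "removed_fraction": float(self.removed_fraction),
            "dtype": self.dtype,
        }


@dataclass
class IntensityReport:
    coverage_pct: float
    total_intensity_above_bg: float
    intensity_per_nucleus: float | None
    fold_vs_control: float | None = None
    per_myotube_mean_intensity: dict | None = None
    positive_nuclei_pct: float | None = None


def _as_marker_array(image: Micrograph | np.ndarray) -> np.ndarray:
    if isinstance(image, Micrograph):
        return image.channel("marker")
    return np.asarray(image)


def calibrate_background(primary_negative: Micrograph | np.ndarray
                         ) -> IntensityCalibration:
    """Smallest integer grey level T such that at most 1% of the initially
    positive pixels (value > 0) remain above T.

    An all-zero image calibrates to T = 0.  Minimality: counts of pixels
    above a threshold are non-increasing in T, so T is found directly from
    the sorted positive values; T - 1 always leaves more than 1%.
    """
    img = _as_marker_array(primary_negative)
    if not np.issubdtype(img.dtype, np.integer):
        raise TypeError("calibration expects an integer grey-level image")
    positives = np.sort(img[img > 0].ravel())
    n_pos = positives.size
    if n_pos == 0:
        threshold, removed = 0, 1.0
    else:
        allowed = int(np.floor(0.01 * n_pos))
        # keep at most `allowed` pixels strictly above T: T is the value of
        # the (allowed + 1)-th largest positive pixel
        threshold = int(positives[n_pos - allowed - 1])
        removed = float(np.count_nonzero(positives <= threshold) / n_pos)
    source = (primary_negative.provenance
              if isinstance(primary_negative, Micrograph) else "array")
    return IntensityCalibration(background_threshold=threshold, source=source,
                                removed_fraction=removed, dtype=str(img.dtype))


def subtract_background(image: Micrograph | np.ndarray,
                        calibration: IntensityCalibration) -> np.ndarray:
    """Zero pixels at or below the calibrated threshold; keep the rest."""
    img = _as_marker_array(image)
    if str(img.dtype) != calibration.dtype:
        raise ValueError(
            f"bit-depth mismatch: image {img.dtype} vs calibration "
            f"{calibration.dtype}")
    corrected = img.copy()
    corrected[corrected <= calibration.background_threshold] = 0
    return corrected


def coverage(corrected: np.ndarray) -> float:
    """Percent of image pixels expressing above background (non-zero)."""
    corrected = np.asarray(corrected)
    return 100.0 * np.count_nonzero(corrected) / corrected.size


def intensity_per_nucleus(corrected: np.ndarray, nuclei_count: int,
                          control_mean: float | None = None
                          ) -> tuple[float | None, float | None]:
    """Total corrected pixel intensity divided by the nucleus count; the
    optional fold is taken against a control-group mean.  Undefined (None)
    when the field has no nuclei."""
    if nuclei_count <= 0:
        return None, None
    value = float(np.asarray(corrected, dtype=np.float64).sum()) / nuclei_count
    fold = value / control_mean if control_mean else None
    return value, fold


def myotube_mean_intensity(corrected: np.ndarray, mask: np.ndarray) -> float:
    """Mean corrected grey level over one myotube mask."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty myotube mask")
    return float(np.asarray(corrected, dtype=np.float64)[mask].mean())


def positive_nuclei_pct(corrected: np.ndarray,
                        nucleus_masks: Sequence[np.ndarray]
                        | Sequence[tuple[np.ndarray, np.ndarray]],
                        positive_fraction: float = 0.5) -> float:
    """Percent of nuclei overlapping the corrected marker image.

    A nucleus is positive iff at least ``positive_fraction`` of its pixels
    are non-zero after background subtraction.  Nucleus masks may be given
    as boolean arrays or ``(rows, cols)`` index tuples.
    """
    if not 0.0 <= positive_fraction <= 1.0:
        raise ValueError("positive_fraction must be in [0, 1]")
    if len(nucleus_masks) == 0:
        raise ValueError("need at least one nucleus")
    corrected = np.asarray(corrected)
    positives = 0
    for m in nucleus_masks:
        if isinstance(m, tuple):
            values = corrected[m[0], m[1]]
        else:
            values = corrected[np.asarray(m, dtype=bool)]
        if values.size and np.count_nonzero(values) / values.size >= positive_fraction:
            positives += 1
    return 100.0 * positives / len(nucleus_masks)


def nucleus_masks_from_centroids(centroids: np.ndarray, radius_px: float,
                                 shape: tuple[int, int]
                                 ) -> list[tuple[np.ndarray, np.ndarray]]:
    """Disc index masks around detected nucleus centroids."""
    import math
    masks = []
    rad = int(math.ceil(radius_px))
    for r, c in np.asarray(centroids, dtype=float):
        r0, r1 = max(0, int(r) - rad), min(shape[0], int(r) + rad + 1)
        c0, c1 = max(0, int(c) - rad), min(shape[1], int(c) + rad + 1)
        yy, xx = np.mgrid[r0:r1, c0:c1]
        inside = (yy - r) ** 2 + (xx - c) ** 2 <= radius_px ** 2
        masks.append((yy[inside], xx[inside]))
    return masks
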