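"""Myotube morphometry: segmentation, nuclei, width profiles, DDR and
field-level myogenic metrics.

The classification statistic is the diameter difference ratio (DDR), the
largest local diameter of a fibre divided by its smallest.  Widths are
measured along the medial axis: at each skeleton point the local diameter
is twice the Euclidean distance to the fibre boundary.  Training the
classifier on linear and bag exemplars yields one cutoff per class --
``linear_mean + linear_sd`` and ``bag_mean - bag_sd`` -- with the open
interval between them left unassigned.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.ndimage import distance_transform_edt
from skimage.feature import peak_local_max
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import label as sk_label
from skimage.morphology import skeletonize

from .micrograph import Micrograph

UNASSIGNED = "unassigned"
LINEAR = "linear"
BAG = "bag"


class ThresholdsNotSeparableError(ValueError):
    """Training populations overlap: linear cutoff >= bag cutoff."""


class UnmeasurableInstanceError(ValueError):
    """Mask degenerate (skeleton too short or zero minimum width)."""


# --------------------------------------------------------------------------
# data types
# --------------------------------------------------------------------------

@dataclass
class Candidate:
    """A connected actin component before the myotube filter."""
    id: int
    mask: np.ndarray          # boolean, full frame
    area_um2: float
    nuclei_count: int | None = None


@dataclass
class MyotubeInstance:
    id: int
    mask: np.ndarray
    pixel_size: float
    nuclei_count: int
    area_um2: float
    skeleton: np.ndarray | None = None       # (N, 2) ordered row/col path
    width_profile: np.ndarray | None = None  # um, per retained path point
    d_max: float | None = None
    d_min: float | None = None
    ddr: float | None = None
    assigned_class: str | None = None
    measurable: bool = True


@dataclass(frozen=True)
class DdrThresholds:
    linear_mean: float
    linear_sd: float
    bag_mean: float
    bag_sd: float

    def __post_init__(self) -> None:
        if min(self.linear_mean, self.linear_sd, self.bag_mean, self.bag_sd) <= 0:
            raise ValueError("threshold summary values must be positive")
        if self.linear_cutoff >= self.bag_cutoff:
            raise ThresholdsNotSeparableError(
                f"populations not separable: linear cutoff {self.linear_cutoff:.3f}"
                f" >= bag cutoff {self.bag_cutoff:.3f}")

    @property
    def linear_cutoff(self) -> float:
        return self.linear_mean + self.linear_sd

    @property
    def bag_cutoff(self) -> float:
        return self.bag_mean - self.bag_sd

    @classmethod
    def from_summary(cls, linear_mean: float, linear_sd: float,
                     bag_mean: float, bag_sd: float) -> "DdrThresholds":
        return cls(linear_mean, linear_sd, bag_mean, bag_sd)

    def to_dict(self) -> dict:
        return {
            "linear_mean": self.linear_mean, "linear_sd": self.linear_sd,
            "bag_mean": self.bag_mean, "bag_sd": self.bag_sd,
            "linear_cutoff": self.linear_cutoff, "bag_cutoff": self.bag_cutoff,
        }


#: Cutoffs from the published training summary (linear 1.81 +- 0.37,
#: bag 4.03 +- 1.32): linear <= 2.18, bag >= 2.71.
PUBLISHED_THRESHOLDS = DdrThresholds(1.81, 0.37, 4.03, 1.32)


@dataclass
class FieldSummary:
    n_myotubes: int
    bag_pct: float
    linear_pct: float
    unassigned_pct: float
    nuclei_per_fov: int
    fusion_efficiency_pct: float | None
    mean_area_per_nucleus: float | None
    nuclei_per_myotube: dict = field(default_factory=dict)
    denominator: str = "all"


# --------------------------------------------------------------------------
# segmentation and nuclei
# --------------------------------------------------------------------------

def segment_myotubes(micrograph: Micrograph, min_area_um2: float = 100.0,
                     actin_threshold: str | float = "otsu") -> list[Candidate]:
    """Connected components of the thresholded actin channel above a
    minimum area.  Deterministic for fixed inputs."""
    actin = micrograph.channel("actin")
    if actin.max() == actin.min():
        return []
    if actin_threshold == "otsu":
        thr = threshold_otsu(actin)
    else:
        thr = float(actin_threshold)
    binary = actin > thr
    labels = sk_label(binary, connectivity=2)
    px_area = micrograph.pixel_size ** 2
    min_px = min_area_um2 / px_area
    out: list[Candidate] = []
    next_id = 0
    for lab in range(1, labels.max() + 1):
        mask = labels == lab
        n_px = int(mask.sum())
        if n_px < min_px:
            continue
        out.append(Candidate(id=next_id, mask=mask, area_um2=n_px * px_area))
        next_id += 1
    return out


def detect_nuclei(micrograph: Micrograph, min_diameter_um: float = 7.0
                  ) -> np.ndarray:
    """Nucleus centroids from the DAPI channel.

    Blob detection by local maxima of the Gaussian-smoothed channel; two
    blobs whose maxima merge (closer than about half the minimum diameter)
    are counted as one -- the documented declumping behaviour.
    Returns an (N, 2) float array of row/col coordinates.
    """
    dapi = micrograph.channel("dapi").astype(float)
    if dapi.max() == dapi.min():
        return np.empty((0, 2), dtype=float)
    d_px = min_diameter_um / micrograph.pixel_size
    smooth = gaussian(dapi, sigma=max(1.0, d_px / 5.0), preserve_range=True)
    thr = threshold_otsu(smooth)
    if (smooth > thr).mean() > 0.5:   # no sparse blob structure present
        return np.empty((0, 2), dtype=float)
    peaks = peak_local_max(smooth, min_distance=max(1, int(round(0.45 * d_px))),
                           threshold_abs=thr, exclude_border=False)
    return peaks.astype(float)


def assign_nuclei(masks: Sequence[np.ndarray] | Sequence[Candidate],
                  centroids: np.ndarray
                  ) -> tuple[np.ndarray, np.ndarray, int]:
    """Assign each nucleus centroid to at most one mask.

    A nucleus belongs to a mask iff its (rounded) centroid pixel lies inside
    the mask; mask pixels are inclusive of the boundary.  A centroid inside
    two or more overlapping masks is assigned to none and counted as
    ambiguous.  Returns ``(counts, assignment, n_ambiguous)`` where
    ``assignment[i]`` is the mask index or -1.
    """
    mask_arrays = [m.mask if isinstance(m, Candidate) else m for m in masks]
    counts = np.zeros(len(mask_arrays), dtype=int)
    assignment = np.full(len(centroids), -1, dtype=int)
    n_ambiguous = 0
    if len(centroids) == 0 or not mask_arrays:
        return counts, assignment, 0
    shape = mask_arrays[0].shape
    for i, (r, c) in enumerate(np.asarray(centroids, dtype=float)):
        ri, ci = int(round(r)), int(round(c))
        if not (0 <= ri < shape[0] and 0 <= ci < shape[1]):
            continue
        hits = [j for j, m in enumerate(mask_arrays) if m[ri, ci]]
        if len(hits) == 1:
            assignment[i] = hits[0]
            counts[hits[0]] += 1
        elif len(hits) > 1:
            n_ambiguous += 1
    return counts, assignment, n_ambiguous


def filter_myotubes(candidates: Sequence[Candidate], counts: Sequence[int],
                    pixel_size: float, min_nuclei: int = 3
                    ) -> tuple[list[MyotubeInstance], list[tuple[Candidate, str]]]:
    """Retain candidates with at least ``min_nuclei`` nuclei (a myotube is a
    single actin fibre containing three or more nuclei); the rest are
    returned with the reason for exclusion."""
    retained: list[MyotubeInstance] = []
    excluded: list[tuple[Candidate, str]] = []
    for cand, n in zip(candidates, counts):
        cand.nuclei_count = int(n)
        if n >= min_nuclei:
            retained.append(MyotubeInstance(
                id=cand.id, mask=cand.mask, pixel_size=pixel_size,
                nuclei_count=int(n), area_um2=cand.area_um2))
        else:
            excluded.append((cand, f"nuclei_count {n} < {min_nuclei}"))
    return retained, excluded


# --------------------------------------------------------------------------
# medial-axis width profile
# --------------------------------------------------------------------------

def _skeleton_longest_path(skel: np.ndarray) -> np.ndarray:
    """Ordered pixel path between the two farthest skeleton endpoints
    (double-BFS graph diameter on the 8-connected skeleton graph)."""
    pts = np.argwhere(skel)
    if len(pts) == 0:
        return pts
    index = {tuple(p): i for i, p in enumerate(map(tuple, pts))}
    offs = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    adj: list[list[int]] = [[] for _ in pts]
    for (r, c), i in index.items():
        for dr, dc in offs:
            j = index.get((r + dr, c + dc))
            if j is not None:
                adj[i].append(j)

    def bfs(start: int) -> tuple[np.ndarray, np.ndarray]:
        dist = np.full(len(pts), -1, dtype=int)
        prev = np.full(len(pts), -1, dtype=int)
        dist[start] = 0
        queue = [start]
        for u in queue:
            for v in adj[u]:
                if dist[v] < 0:
                    dist[v] = dist[u] + 1
                    prev[v] = u
                    queue.append(v)
        return dist, prev

    dist, _ = bfs(0)
    e1 = int(np.argmax(dist))
    dist, prev = bfs(e1)
    e2 = int(np.argmax(dist))
    path = [e2]
    while prev[path[-1]] >= 0:
        path.append(int(prev[path[-1]]))
    return pts[np.array(path[::-1])]


def _smooth_profile(values: np.ndarray, window: int) -> np.ndarray:
    """Running median: suppresses single-pixel rasterisation dips without
    biasing monotone stretches of the profile."""
    if window <= 1 or len(values) < window:
        return values
    from scipy.signal import medfilt
    return medfilt(values, kernel_size=window | 1)


def width_profile(instance: MyotubeInstance,
                  others_mask: np.ndarray | None = None,
                  end_trim_frac: float = 0.02,
                  end_radius_factor: float = 1.5,
                  smooth_window: int = 9) -> np.ndarray:
    """Per-medial-axis-point local width in micrometres.

    Width = 2 x Euclidean distance transform at each point of the longest
    medial-axis path x pixel size.  Points near the fibre tips are excluded
    two ways: a fractional arc-length trim at each end, and removal of any
    point closer to a path end than ``end_radius_factor`` times its own
    inscribed radius (tip points systematically under-report the diameter;
    the radius rule also discards skeleton corner spurs).  Points whose
    inscribed disc touches another instance's mask are excluded, matching
    the manual convention of only measuring diameters not interfered with
    by an overlapping myotube.

    Fills ``skeleton``, ``width_profile``, ``d_max``, ``d_min`` and ``ddr``
    on the instance and returns the width array.
    """
    mask = instance.mask
    rr, cc = np.nonzero(mask)
    if len(rr) == 0:
        raise UnmeasurableInstanceError("empty mask")
    pad = 2
    r0, r1 = max(0, rr.min() - pad), min(mask.shape[0], rr.max() + pad + 1)
    c0, c1 = max(0, cc.min() - pad), min(mask.shape[1], cc.max() + pad + 1)
    crop = mask[r0:r1, c0:c1]
    skel = skeletonize(crop)
    path = _skeleton_longest_path(skel)
    if len(path) < 3:
        instance.measurable = False
        raise UnmeasurableInstanceError("skeleton shorter than 3 points")

    dt = distance_transform_edt(crop)
    # a rasterised skeleton can sit half a pixel off the true medial axis
    # (and kink diagonally); the local maximum of the distance transform
    # recovers the inscribed radius despite the offset
    from scipy.ndimage import maximum_filter
    dt_max = maximum_filter(dt, size=3)
    radii = dt_max[path[:, 0], path[:, 1]]

    steps = np.sqrt((np.diff(path, axis=0) ** 2).sum(axis=1))
    arc = np.concatenate([[0.0], np.cumsum(steps)])
    total = arc[-1]
    from_end = total - arc

    # Euclidean distance to the path endpoints: tip regions closer to a
    # fibre end than ~1.5 inscribed radii under-report the diameter (and
    # skeleton corner spurs live entirely inside that zone)
    d_start = np.sqrt(((path - path[0]) ** 2).sum(axis=1))
    d_end = np.sqrt(((path - path[-1]) ** 2).sum(axis=1))
    keep = (arc >= end_trim_frac * total) & (from_end >= end_trim_frac * total)
    keep &= np.minimum(d_start, d_end) >= end_radius_factor * radii

    if others_mask is not None and others_mask.any():
        dist_other = distance_transform_edt(~others_mask)[
            path[:, 0] + r0, path[:, 1] + c0]
        keep &= dist_other > radii + 1.0

    if keep.sum() < 2:
        instance.measurable = False
        raise UnmeasurableInstanceError("fewer than 2 retained profile points")

    # 2*EDT reports w for even and w+1 for odd pixel widths; the half-pixel
    # correction centres the discretisation error at +-0.5 px
    widths_px = _smooth_profile(2.0 * radii - 0.5, smooth_window)[keep]
    widths = widths_px * instance.pixel_size
    instance.skeleton = path[keep] + np.array([r0, c0])
    instance.width_profile = widths
    instance.d_max = float(widths.max())
    instance.d_min = float(widths.min())
    if instance.d_min <= 0:
        raise UnmeasurableInstanceError("degenerate mask: zero minimum width")
    instance.ddr = instance.d_max / instance.d_min
    return widths


def compute_ddr(instance: MyotubeInstance) -> float:
    """DDR = max(width profile) / min(width profile); always >= 1."""
    if instance.width_profile is None:
        width_profile(instance)
    assert instance.width_profile is not None
    if len(instance.width_profile) < 2:
        raise UnmeasurableInstanceError("width profile has fewer than 2 points")
    d_min = float(instance.width_profile.min())
    if d_min <= 0:
        raise UnmeasurableInstanceError("degenerate mask: zero minimum width")
    instance.d_max = float(instance.width_profile.max())
    instance.d_min = d_min
    instance.ddr = instance.d_max / d_min
    return instance.ddr


# --------------------------------------------------------------------------
# thresholds and classification
# --------------------------------------------------------------------------

def derive_thresholds(linear_ddrs: Sequence[float],
                      bag_ddrs: Sequence[float]) -> DdrThresholds:
    """Per-class mean and sample SD (n-1 denominator) of training DDRs;
    cutoffs are mean + SD (linear) and mean - SD (bag).  Raises
    :class:`ThresholdsNotSeparableError` when the cutoffs cross."""
    linear = np.asarray(linear_ddrs, dtype=float)
    bag = np.asarray(bag_ddrs, dtype=float)
    if len(linear) < 2 or len(bag) < 2:
        raise ValueError("need at least 2 training DDR values per class")
    return DdrThresholds(
        linear_mean=float(linear.mean()), linear_sd=float(linear.std(ddof=1)),
        bag_mean=float(bag.mean()), bag_sd=float(bag.std(ddof=1)))


def classify(ddr: float, thresholds: DdrThresholds) -> str:
    """Assign a class from a DDR value; both boundaries are inclusive to
    their named class (to within floating-point round-off) and the open
    interval between them is unassigned."""
    if ddr < 1.0:
        raise ValueError(f"DDR must be >= 1, got {ddr}")
    eps = 1e-9 * max(1.0, abs(ddr))
    if ddr <= thresholds.linear_cutoff + eps:
        return LINEAR
    if ddr >= thresholds.bag_cutoff - eps:
        return BAG
    return UNASSIGNED


def summarise_field(instances: Sequence[MyotubeInstance], total_nuclei: int,
                    denominator: str = "all") -> FieldSummary:
    """Field-level myogenic metrics over retained myotubes.

    ``denominator="all"`` (default) computes class percentages over all
    retained myotubes including unassigned ones, so the three percentages
    sum to 100; ``"assigned"`` restricts the bag/linear percentages to the
    assigned subset (unassigned_pct stays on the full denominator).
    """
    if denominator not in ("all", "assigned"):
        raise ValueError("denominator must be 'all' or 'assigned'")
    n = len(instances)
    counts = {LINEAR: 0, BAG: 0, UNASSIGNED: 0}
    for inst in instances:
        if inst.assigned_class is None:
            raise ValueError("all instances must be classified first")
        counts[inst.assigned_class] += 1
    nuclei_in = sum(inst.nuclei_count for inst in instances)
    if total_nuclei and total_nuclei < nuclei_in:
        raise ValueError("total_nuclei below the nuclei inside myotubes")

    if n == 0:
        bag_pct = linear_pct = unassigned_pct = 0.0
    else:
        unassigned_pct = 100.0 * counts[UNASSIGNED] / n
        denom = n if denominator == "all" else counts[LINEAR] + counts[BAG]
        if denom == 0:
            bag_pct = linear_pct = 0.0
        else:
            bag_pct = 100.0 * counts[BAG] / denom
            linear_pct = 100.0 * counts[LINEAR] / denom

    fusion = None
    if total_nuclei > 0:
        fusion = 100.0 * nuclei_in / total_nuclei

    apn_values = [inst.area_um2 / inst.nuclei_count
                  for inst in instances if inst.nuclei_count > 0]
    apn = float(np.mean(apn_values)) if apn_values else None

    npm = {}
    for cls in (LINEAR, BAG, UNASSIGNED):
        vals = [inst.nuclei_count for inst in instances
                if inst.assigned_class == cls]
        if vals:
            npm[cls] = float(np.mean(vals))
    return FieldSummary(
        n_myotubes=n, bag_pct=bag_pct, linear_pct=linear_pct,
        unassigned_pct=unassigned_pct, nuclei_per_fov=int(total_nuclei),
        fusion_efficiency_pct=fusion, mean_area_per_nucleus=apn,
        nuclei_per_myotube=npm, denominator=denominator)


# --------------------------------------------------------------------------
# field-level driver
# --------------------------------------------------------------------------

def measure_instances(instances: Sequence[MyotubeInstance],
                      exclude_overlap: bool = True) -> list[MyotubeInstance]:
    """Measure width profiles for a set of instances from one field,
    excluding profile points interfered with by any other instance."""
    if not instances:
        return []
    all_mask = np.zeros_like(instances[0].mask, dtype=bool)
    for inst in instances:
        all_mask |= inst.mask
    measured = []
    for inst in instances:
        others = (all_mask & ~inst.mask) if exclude_overlap else None
        try:
            width_profile(inst, others_mask=others)
            compute_ddr(inst)
            measured.append(inst)
        except UnmeasurableInstanceError:
            inst.measurable = False
    return measured


def analyze_field(micrograph: Micrograph, thresholds: DdrThresholds,
                  min_area_um2: float = 100.0, min_nuclei: int = 3,
                  min_nucleus_diameter_um: float = 7.0,
                  denominator: str = "all"
                  ) -> tuple[list[MyotubeInstance], FieldSummary, np.ndarray]:
    """Segment, count, measure and classify one field end to end."""
    candidates = segment_myotubes(micrograph, min_area_um2=min_area_um2)
    centroids = detect_nuclei(micrograph, min_diameter_um=min_nucleus_diameter_um)
    counts, _, _ = assign_nuclei(candidates, centroids)
    retained, _ = filter_myotubes(candidates, counts, micrograph.pixel_size,
                                  min_nuclei=min_nuclei)
    measured = measure_instances(retained)
    for inst in measured:
        inst.assigned_class = classify(inst.ddr, thresholds)
    summary = summarise_field(measured, total_nuclei=len(centroids),
                              denominator=denominator)
    return measured, summary, centroids
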