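"""Synthetic micrographs and assay tables with the statistical structure of
Nrg-1 treated vs control C2C12 myotube cultures.

The generator renders two myotube phenotypes into multi-channel 16-bit
fields of view:

* **linear** myotubes — gently tapered tubes whose maximum/minimum width
  ratio (the diameter difference ratio, DDR) is drawn from the linear
  training distribution, with nuclei spaced along the axis;
* **bag** myotubes — fusiform tubes with a Gaussian equatorial bulge whose
  DDR is drawn from the bag training distribution, with nuclei clustered
  at the equator.

Unfused mononuclear cells fill the remainder of the field so that the
fraction of nuclei residing inside myotubes matches the configured fusion
efficiency in expectation.  A marker channel (emulating Egr3 staining) is
scaled per condition and true class; additive Gaussian camera noise is
applied last.  Ground truth (class, DDR, nuclei, area, marker level) is
recorded before rendering so every downstream measurement can be checked
against it.

Ct, western-blot and viability tables are generated by inverting the exact
arithmetic the expression module applies, so zero-noise tables round-trip
to the requested fold changes to machine precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .micrograph import Micrograph

LINEAR = "linear"
BAG = "bag"
CLASSES = (LINEAR, BAG)

_U16_MAX = 65535


# --------------------------------------------------------------------------
# condition parameters
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ConditionParams:
    """Field-level generative settings for one culture condition.

    Defaults for the two study arms live in :data:`CONTROL` and
    :data:`NRG1`; all rates are per field of view (FOV).
    """

    name: str
    bag_fraction: float          # P(myotube is bag)
    myotubes_per_fov: float      # Poisson mean
    nuclei_per_fov_mean: float   # expected total nuclei per FOV
    fusion_efficiency: float     # expected fraction of nuclei inside myotubes
    linear_ddr_mean: float = 1.81
    linear_ddr_sd: float = 0.37
    bag_ddr_mean: float = 4.03
    bag_ddr_sd: float = 1.32
    nuclei_per_linear_mean: float = 5.48
    nuclei_per_bag_mean: float = 8.09
    nb_dispersion: float = 0.17   # var = mu + nb_dispersion * mu^2
    area_per_nucleus_mean: float = 645.3  # um^2
    marker_intensity_by_type: Mapping[str, float] = field(
        default_factory=lambda: {LINEAR: 0.88, BAG: 1.85})
    positive_nuclei_fraction_by_type: Mapping[str, float] = field(
        default_factory=lambda: {LINEAR: 0.486, BAG: 0.55})

    def __post_init__(self) -> None:
        for prop in ("bag_fraction", "fusion_efficiency"):
            v = getattr(self, prop)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{prop} must be in [0, 1], got {v}")
        for prop in ("linear_ddr_sd", "bag_ddr_sd", "nb_dispersion",
                     "myotubes_per_fov", "nuclei_per_fov_mean",
                     "nuclei_per_linear_mean", "nuclei_per_bag_mean",
                     "area_per_nucleus_mean"):
            if getattr(self, prop) <= 0:
                raise ValueError(f"{prop} must be positive")
        if self.linear_ddr_mean >= self.bag_ddr_mean:
            raise ValueError("linear_ddr_mean must be below bag_ddr_mean")
        for mapping in (self.marker_intensity_by_type,
                        self.positive_nuclei_fraction_by_type):
            for cls in CLASSES:
                if cls not in mapping:
                    raise ValueError(f"per-type mapping missing {cls!r}")
        for cls, frac in self.positive_nuclei_fraction_by_type.items():
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"positive fraction for {cls!r} not in [0, 1]")


#: Untreated (control) arm: 8.52% bag myotubes, 104.8 nuclei/FOV, 46.88%
#: fusion efficiency, 645.3 um^2 per myonucleus, Egr3 intensity 0.88
#: (linear) / 1.85 (bag) relative to the control per-nucleus mean.
CONTROL = ConditionParams(
    name="control",
    bag_fraction=0.0852,
    myotubes_per_fov=8.33,
    nuclei_per_fov_mean=104.8,
    fusion_efficiency=0.4688,
    nuclei_per_linear_mean=5.48,
    nuclei_per_bag_mean=8.09,
    area_per_nucleus_mean=645.3,
    marker_intensity_by_type={LINEAR: 0.88, BAG: 1.85},
    positive_nuclei_fraction_by_type={LINEAR: 0.486, BAG: 0.55},
)

#: Nrg-1 treated arm: 41.61% bag myotubes, 136.3 nuclei/FOV, 47.41% fusion,
#: 537.9 um^2 per myonucleus, Egr3 intensity 2.50 (linear) / 6.13 (bag).
NRG1 = ConditionParams(
    name="nrg1",
    bag_fraction=0.4161,
    myotubes_per_fov=9.22,
    nuclei_per_fov_mean=136.3,
    fusion_efficiency=0.4741,
    nuclei_per_linear_mean=6.10,
    nuclei_per_bag_mean=8.33,
    area_per_nucleus_mean=537.9,
    marker_intensity_by_type={LINEAR: 2.50, BAG: 6.13},
    positive_nuclei_fraction_by_type={LINEAR: 0.58, BAG: 0.7212},
)

CONDITIONS: dict[str, ConditionParams] = {"control": CONTROL, "nrg1": NRG1}


@dataclass(frozen=True)
class RenderSettings:
    """Rendering constants shared by both arms.

    Grey-level scales were fixed once so that the marker channel, after the
    99%-rule background calibration, reproduces the study's field-level
    intensity-per-nucleus contrast (see docs/methods.md); they are not per-
    condition knobs.
    """

    pixel_size: float = 0.65          # um / px
    nucleus_diameter: float = 10.0    # um
    noise_sd_frac: float = 0.02       # additive Gaussian SD, fraction of 16-bit range
    actin_level: float = 25000.0
    dapi_amplitude: float = 30000.0
    marker_scale: float = 8000.0      # grey levels per unit relative intensity
    marker_texture_shape: float = 4.0  # gamma shape of cytoplasmic texture
    nuclear_marker_scale: float = 8000.0
    nuclear_suppression: float = 0.05  # cytoplasm factor inside marker-negative nuclei
    marker_between_cv: float = 0.9     # between-myotube lognormal CV of marker level
    width_min_range: tuple[float, float] = (8.0, 12.0)  # um
    max_width: float = 50.0           # um, cap on rendered w_max
    min_nucleus_separation: float = 7.5  # um between nucleus centres
    instance_margin_px: int = 3       # clearance enforced between instances
    unfused_cell_radius: float = 8.0  # um, actin blob of a mononuclear cell
    allow_overlap: bool = False

    @property
    def noise_sd(self) -> float:
        return self.noise_sd_frac * _U16_MAX


DEFAULT_RENDER = RenderSettings()
NOISELESS_RENDER = replace(DEFAULT_RENDER, noise_sd_frac=0.0)


@dataclass
class SyntheticField:
    """One rendered field of view plus its generative ground truth."""

    micrograph: Micrograph
    ground_truth: pd.DataFrame     # one row per rendered myotube
    nuclei_truth: pd.DataFrame     # one row per rendered nucleus
    params: ConditionParams
    seed: int

    @property
    def pixel_size(self) -> float:
        return self.micrograph.pixel_size


# --------------------------------------------------------------------------
# geometry helpers
# --------------------------------------------------------------------------

_BAG_SIGMA_FRAC = 1.0 / 7.0   # bulge sigma as a fraction of length (FWHM ~ L/3)


def _linear_caps(length: float, w_min: float, w_max: float
                 ) -> tuple[float, float]:
    """Plateau cap lengths at the thin and thick end of a tapered fibre.

    The caps hold the profile flat at w_min / w_max near the tips so the
    true extrema lie in the measurable interior of the medial axis (tip
    regions within ~1.5 local radii of a fibre end cannot report a correct
    diameter and are excluded by the morphometry).
    """
    c1 = 0.9 * w_min + 0.03 * length
    c2 = 0.9 * w_max + 0.03 * length
    if c1 + c2 > 0.6 * length:
        scale = 0.6 * length / (c1 + c2)
        c1, c2 = c1 * scale, c2 * scale
    return c1, c2


def _half_width_um(s_um: np.ndarray, kind: str, length: float,
                   w_min: float, w_max: float) -> np.ndarray:
    """Local half-width (um) at axial position ``s`` along a fibre.

    Linear fibres ramp from w_min to w_max between flat plateau caps; bag
    fibres carry a Gaussian equatorial bulge with sigma = L/7, whose full
    width at half maximum spans roughly the central third of the fibre and
    whose tails return to within ~1% of w_min at the poles.
    """
    s = np.asarray(s_um, dtype=float)
    if kind == LINEAR:
        c1, c2 = _linear_caps(length, w_min, w_max)
        t = np.clip((s - c1) / max(length - c1 - c2, 1e-9), 0.0, 1.0)
        w = w_min + (w_max - w_min) * t
    elif kind == BAG:
        sigma = length * _BAG_SIGMA_FRAC
        w = w_min + (w_max - w_min) * np.exp(
            -((s - length / 2.0) ** 2) / (2.0 * sigma ** 2))
    else:  # pragma: no cover - guarded upstream
        raise ValueError(f"unknown fibre kind {kind!r}")
    return w / 2.0


def _length_from_area(kind: str, area: float, w_min: float, w_max: float) -> float:
    """Invert the profile integral to get fibre length from target area."""
    if kind == BAG:
        return area / (w_min + (w_max - w_min)
                       * math.sqrt(2 * math.pi) * _BAG_SIGMA_FRAC)
    w_bar = (w_min + w_max) / 2.0
    length = area / w_bar
    for _ in range(4):  # cap lengths depend weakly on L; fixed point
        c1, c2 = _linear_caps(length, w_min, w_max)
        length = (area - c1 * w_min - c2 * w_max) / w_bar + c1 + c2
    return length


def fibre_mask(shape: tuple[int, int], centre: tuple[float, float],
               theta: float, kind: str, length_um: float, w_min_um: float,
               w_max_um: float, pixel_size: float) -> np.ndarray:
    """Rasterise one fibre as a boolean mask (full-frame)."""
    h, w = shape
    ux, uy = math.cos(theta), math.sin(theta)  # (col, row) direction
    length_px = length_um / pixel_size
    half_len = length_px / 2.0
    half_wmax = w_max_um / 2.0 / pixel_size
    cy, cx = centre
    x0, y0 = cx - ux * half_len, cy - uy * half_len

    pad = int(math.ceil(half_wmax)) + 2
    r0 = max(0, int(min(y0, y0 + uy * length_px)) - pad)
    r1 = min(h, int(max(y0, y0 + uy * length_px)) + pad + 1)
    c0 = max(0, int(min(x0, x0 + ux * length_px)) - pad)
    c1 = min(w, int(max(x0, x0 + ux * length_px)) + pad + 1)
    if r0 >= r1 or c0 >= c1:
        return np.zeros(shape, dtype=bool)

    yy, xx = np.mgrid[r0:r1, c0:c1]
    dx, dy = xx - x0, yy - y0
    s = dx * ux + dy * uy                  # along-axis, px
    d = -dx * uy + dy * ux                 # perpendicular, px
    s_um = s * pixel_size
    hw = _half_width_um(s_um, kind, length_um, w_min_um, w_max_um) / pixel_size
    sub = (s >= 0) & (s <= length_px) & (np.abs(d) <= hw)
    mask = np.zeros(shape, dtype=bool)
    mask[r0:r1, c0:c1] = sub
    return mask


def render_single_fibre(kind: str, ddr: float, *, w_min_um: float = 10.0,
                        length_um: float = 250.0, theta: float = 0.0,
                        fov_shape: tuple[int, int] = (256, 640),
                        pixel_size: float = 0.65,
                        actin_level: float = 25000.0) -> tuple[Micrograph, np.ndarray]:
    """Render one isolated fibre; returns the micrograph and its true mask.

    Used for threshold training, width-oracle checks and DDR-fidelity tests.
    """
    if ddr < 1.0:
        raise ValueError("ddr must be >= 1")
    centre = (fov_shape[0] / 2.0, fov_shape[1] / 2.0)
    mask = fibre_mask(fov_shape, centre, theta, kind, length_um,
                      w_min_um, w_min_um * ddr, pixel_size)
    actin = np.zeros(fov_shape, dtype=float)
    actin[mask] = actin_level
    mg = Micrograph(channels={"actin": actin.astype(np.uint16)},
                    pixel_size=pixel_size,
                    provenance=f"synthetic single {kind} fibre ddr={ddr}")
    return mg, mask


# --------------------------------------------------------------------------
# sampling helpers
# --------------------------------------------------------------------------

def _draw_truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                           low: float = 1.0) -> float:
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if x > low:
            return float(x)
    return low + abs(rng.normal(0.0, sd))  # pathological parameters


def _draw_nuclei_count(rng: np.random.Generator, mean: float,
                       dispersion: float, min_count: int = 3) -> int:
    """Negative-binomial draw conditioned on >= min_count.

    Parameterised so var = mean + dispersion * mean^2; a myotube is by
    definition a fibre with >= 3 nuclei, so counts are resampled until the
    floor is met (mild upward shift of the mean, documented).
    """
    r = 1.0 / dispersion
    p = r / (r + mean)
    for _ in range(1000):
        n = int(rng.negative_binomial(r, p))
        if n >= min_count:
            return n
    return min_count


def _place_points(rng: np.random.Generator, n: int, sampler, existing: list,
                  min_sep_px: float, max_tries: int = 60) -> list[tuple[float, float]]:
    """Rejection-sample ``n`` points with pairwise separation; relaxes the
    separation by 10% whenever a point cannot be placed."""
    placed: list[tuple[float, float]] = []
    sep = min_sep_px
    for _ in range(n):
        ok = None
        for attempt in range(max_tries):
            cand = sampler()
            if cand is None:
                continue
            all_pts = existing + placed
            if all_pts:
                d2 = min((cand[0] - p[0]) ** 2 + (cand[1] - p[1]) ** 2
                         for p in all_pts)
                if d2 < sep ** 2:
                    continue
            ok = cand
            break
        if ok is None:
            sep *= 0.9
            ok = sampler()
            if ok is None:
                continue
        placed.append(ok)
    return placed


def _stamp_gaussian(canvas: np.ndarray, row: float, col: float,
                    amplitude: float, sigma_px: float) -> None:
    rad = int(math.ceil(3.0 * sigma_px))
    r0, r1 = max(0, int(row) - rad), min(canvas.shape[0], int(row) + rad + 1)
    c0, c1 = max(0, int(col) - rad), min(canvas.shape[1], int(col) + rad + 1)
    if r0 >= r1 or c0 >= c1:
        return
    yy, xx = np.mgrid[r0:r1, c0:c1]
    canvas[r0:r1, c0:c1] += amplitude * np.exp(
        -((yy - row) ** 2 + (xx - col) ** 2) / (2.0 * sigma_px ** 2))


def _disc_indices(shape: tuple[int, int], row: float, col: float,
                  radius_px: float) -> tuple[np.ndarray, np.ndarray]:
    rad = int(math.ceil(radius_px))
    r0, r1 = max(0, int(row) - rad), min(shape[0], int(row) + rad + 1)
    c0, c1 = max(0, int(col) - rad), min(shape[1], int(col) + rad + 1)
    if r0 >= r1 or c0 >= c1:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    yy, xx = np.mgrid[r0:r1, c0:c1]
    inside = (yy - row) ** 2 + (xx - col) ** 2 <= radius_px ** 2
    return yy[inside], xx[inside]


# --------------------------------------------------------------------------
# field generation
# --------------------------------------------------------------------------

def generate_field(params: ConditionParams, seed: int,
                   fov_shape: tuple[int, int] = (1024, 1024),
                   settings: RenderSettings = DEFAULT_RENDER) -> SyntheticField:
    """Render one two-condition-style field of view.

    Deterministic for fixed ``(params, seed, fov_shape, settings)``:
    regenerating yields byte-identical channels and identical ground truth.
    """
    if params.myotubes_per_fov <= 0:
        raise ValueError("degenerate params: myotubes_per_fov must be > 0")
    px = settings.pixel_size
    h, w = fov_shape
    min_dim_um = min(h, w) * px
    if min_dim_um < 60.0:
        raise ValueError("fov_shape too small to hold a fibre")

    rng = np.random.default_rng(seed)
    actin = np.zeros(fov_shape, dtype=float)
    dapi = np.zeros(fov_shape, dtype=float)
    marker = np.zeros(fov_shape, dtype=float)
    occupancy = np.zeros(fov_shape, dtype=bool)

    n_myo = int(rng.poisson(params.myotubes_per_fov))
    gt_rows = []
    nuc_rows = []
    all_nuclei_px: list[tuple[float, float]] = []
    sep_px = settings.min_nucleus_separation / px
    nuc_sigma_px = settings.nucleus_diameter / 4.0 / px
    nuc_rad_px = settings.nucleus_diameter / 2.0 / px

    instance_id = 0
    for _ in range(n_myo):
        is_bag = rng.random() < params.bag_fraction
        kind = BAG if is_bag else LINEAR
        ddr = _draw_truncated_normal(
            rng,
            params.bag_ddr_mean if is_bag else params.linear_ddr_mean,
            params.bag_ddr_sd if is_bag else params.linear_ddr_sd,
            low=1.0,
        )
        w_min = rng.uniform(*settings.width_min_range)
        if w_min * ddr > settings.max_width:
            w_min = settings.max_width / ddr

        n_nuclei = _draw_nuclei_count(
            rng,
            params.nuclei_per_bag_mean if is_bag else params.nuclei_per_linear_mean,
            params.nb_dispersion,
        )
        target_area = params.area_per_nucleus_mean * n_nuclei * rng.uniform(0.85, 1.15)
        if kind == BAG:
            # keep the fusiform shape fibre-like (L >= 4 w_max): a bulge
            # wider than it is long has no line-like medial axis; small
            # bags are therefore rendered proportionally thinner
            c = 1.0 + (ddr - 1.0) * math.sqrt(2 * math.pi) * _BAG_SIGMA_FRAC
            w_cap = math.sqrt(target_area / (4.0 * ddr * c))
            w_min = max(min(w_min, w_cap), 6.0)
        w_max = w_min * ddr
        length = _length_from_area(kind, target_area, w_min, w_max)
        if kind == BAG:
            length = max(length, 4.0 * w_max)
        length = float(np.clip(length, 60.0, 0.85 * min_dim_um))

        # placement with margin; skip the fibre if the field is too crowded
        mask = None
        for _attempt in range(40):
            theta = rng.uniform(0.0, math.pi)
            half_len_px = length / px / 2.0
            margin_r = abs(math.sin(theta)) * half_len_px + w_max / px / 2.0 + 2
            margin_c = abs(math.cos(theta)) * half_len_px + w_max / px / 2.0 + 2
            if 2 * margin_r >= h or 2 * margin_c >= w:
                length *= 0.8
                continue
            centre = (rng.uniform(margin_r, h - margin_r),
                      rng.uniform(margin_c, w - margin_c))
            cand = fibre_mask(fov_shape, centre, theta, kind, length,
                              w_min, w_max, px)
            if settings.allow_overlap:
                mask = cand
                break
            m = settings.instance_margin_px
            rr, cc = np.nonzero(cand)
            r0, r1 = max(0, rr.min() - m), min(h, rr.max() + m + 1)
            c0, c1 = max(0, cc.min() - m), min(w, cc.max() + m + 1)
            from scipy.ndimage import binary_dilation
            dil = binary_dilation(cand[r0:r1, c0:c1], iterations=m)
            if not (dil & occupancy[r0:r1, c0:c1]).any():
                mask = cand
                break
        if mask is None:
            continue
        occupancy |= mask
        ux, uy = math.cos(theta), math.sin(theta)
        x0 = centre[1] - ux * length / px / 2.0
        y0 = centre[0] - uy * length / px / 2.0

        # nuclei inside the fibre
        def sample_nucleus(kind=kind, length=length, w_min=w_min, w_max=w_max,
                           x0=x0, y0=y0, ux=ux, uy=uy):
            if kind == LINEAR:
                s = rng.uniform(0.08, 0.92) * length
            else:
                s = float(np.clip(rng.normal(length / 2.0, length / 8.0),
                                  0.08 * length, 0.92 * length))
            hw = float(_half_width_um(np.array([s]), kind, length, w_min, w_max)[0])
            max_off = max(hw - settings.nucleus_diameter / 2.0 - px, 0.0)
            d = rng.uniform(-max_off, max_off)
            col = x0 + (s / px) * ux - (d / px) * uy
            row = y0 + (s / px) * uy + (d / px) * ux
            if not (0 <= row < h and 0 <= col < w):
                return None
            return (row, col)

        pts = _place_points(rng, n_nuclei, sample_nucleus, all_nuclei_px, sep_px)
        n_placed = len(pts)
        all_nuclei_px.extend(pts)

        rel_intensity = params.marker_intensity_by_type[kind]
        if settings.marker_between_cv > 0:
            # between-myotube biological variability, mean-preserving
            s2 = math.log(1.0 + settings.marker_between_cv ** 2)
            rel_intensity *= float(rng.lognormal(-s2 / 2.0, math.sqrt(s2)))
        pos_frac = params.positive_nuclei_fraction_by_type[kind]

        # actin + marker cytoplasm
        lvl = settings.actin_level * rng.uniform(0.85, 1.15)
        actin[mask] = np.maximum(actin[mask], lvl)
        n_px = int(mask.sum())
        shape_k = settings.marker_texture_shape
        texture = rng.gamma(shape_k, 1.0 / shape_k, size=n_px)
        marker[mask] = rel_intensity * settings.marker_scale * texture

        # nuclei: DAPI blobs; marker channel shows nuclear accumulation in
        # positive nuclei and nuclear exclusion (dim) in negative ones
        n_pos = 0
        for row, col in pts:
            _stamp_gaussian(dapi, row, col, settings.dapi_amplitude, nuc_sigma_px)
            positive = bool(rng.random() < pos_frac)
            yy, xx = _disc_indices(fov_shape, row, col, nuc_rad_px)
            if positive:
                n_pos += 1
                marker[yy, xx] = rel_intensity * settings.nuclear_marker_scale
            else:
                marker[yy, xx] = (rel_intensity * settings.marker_scale
                                  * settings.nuclear_suppression)
            nuc_rows.append({"row": row, "col": col, "instance_id": instance_id,
                             "marker_positive": positive})

        gt_rows.append({
            "instance_id": instance_id,
            "true_class": kind,
            "true_ddr": ddr,
            "true_nuclei": n_placed,
            "true_area_um2": n_px * px * px,
            "true_marker_intensity": rel_intensity,
            "true_marker_positive_nuclei": n_pos,
            "length_um": length,
            "w_min_um": w_min,
            "w_max_um": w_max,
        })
        instance_id += 1

    # unfused mononuclear cells fill the remainder of the nuclei budget
    n_unfused = int(rng.poisson(
        params.nuclei_per_fov_mean * (1.0 - params.fusion_efficiency)))
    cell_rad_px = settings.unfused_cell_radius / px
    clearance = occupancy.copy()

    def sample_unfused():
        row = rng.uniform(cell_rad_px, h - cell_rad_px)
        col = rng.uniform(cell_rad_px, w - cell_rad_px)
        yy, xx = _disc_indices(fov_shape, row, col, cell_rad_px + 2)
        if clearance[yy, xx].any():
            return None
        return (row, col)

    pts = _place_points(rng, n_unfused, sample_unfused, all_nuclei_px, sep_px)
    for row, col in pts:
        yy, xx = _disc_indices(fov_shape, row, col, cell_rad_px)
        actin[yy, xx] = np.maximum(actin[yy, xx],
                                   settings.actin_level * rng.uniform(0.7, 1.0))
        clearance[yy, xx] = True
        _stamp_gaussian(dapi, row, col, settings.dapi_amplitude, nuc_sigma_px)
        nuc_rows.append({"row": row, "col": col, "instance_id": -1,
                         "marker_positive": False})

    channels = {}
    for name, canvas in (("actin", actin), ("dapi", dapi), ("marker", marker)):
        if settings.noise_sd > 0:
            canvas = canvas + rng.normal(0.0, settings.noise_sd, size=fov_shape)
        channels[name] = np.clip(np.rint(canvas), 0, _U16_MAX).astype(np.uint16)

    gt_cols = ["instance_id", "true_class", "true_ddr", "true_nuclei",
               "true_area_um2", "true_marker_intensity",
               "true_marker_positive_nuclei", "length_um", "w_min_um", "w_max_um"]
    ground_truth = pd.DataFrame(gt_rows, columns=gt_cols)
    nuclei_truth = pd.DataFrame(
        nuc_rows, columns=["row", "col", "instance_id", "marker_positive"])
    mg = Micrograph(channels=channels, pixel_size=px,
                    provenance=f"synthetic:{params.name}:seed={seed}")
    return SyntheticField(micrograph=mg, ground_truth=ground_truth,
                          nuclei_truth=nuclei_truth, params=params, seed=seed)


def generate_primary_negative(seed: int, fov_shape: tuple[int, int] = (512, 512),
                              noise_scale: float = DEFAULT_RENDER.noise_sd,
                              distribution: str = "gaussian") -> Micrograph:
    """Pure background image emulating a primary-negative control stain.

    ``gaussian``: additive zero-mean Gaussian read noise of SD ``noise_scale``
    grey levels, clipped to [0, 65535] (about half the pixels positive).
    ``uniform``: integer grey levels drawn uniformly from 0..noise_scale.
    """
    if noise_scale < 0:
        raise ValueError("noise_scale must be >= 0")
    rng = np.random.default_rng(seed)
    if noise_scale == 0:
        img = np.zeros(fov_shape, dtype=np.uint16)
    elif distribution == "gaussian":
        img = np.clip(np.rint(rng.normal(0.0, noise_scale, size=fov_shape)),
                      0, _U16_MAX).astype(np.uint16)
    elif distribution == "uniform":
        img = rng.integers(0, int(noise_scale) + 1, size=fov_shape,
                           dtype=np.uint16)
    else:
        raise ValueError(f"unknown distribution {distribution!r}")
    return Micrograph(channels={"marker": img},
                      pixel_size=DEFAULT_RENDER.pixel_size,
                      provenance=f"synthetic primary negative seed={seed}")


# --------------------------------------------------------------------------
# assay tables
# --------------------------------------------------------------------------

def generate_ct_table(fold_changes: Mapping[str, float],
                      reference_gene: str = "Csnk2a2",
                      n_samples: int = 9,
                      ct_noise_sd: float = 0.0,
                      seed: int = 0,
                      reference_ct: float = 18.0,
                      control_delta_ct: Mapping[str, float] | None = None,
                      plate: str = "P1") -> pd.DataFrame:
    """Triplicate Ct table whose expected 2^-ddCt equals the requested folds.

    For each gene a control dCt (gene Ct minus reference Ct) is fixed; the
    treated dCt is shifted by -log2(fold).  Replicate noise is Gaussian with
    SD ``ct_noise_sd`` cycles, so a zero-noise table round-trips exactly
    through :func:`spindlemorph.expression.relative_expression`.
    """
    if reference_gene in fold_changes:
        raise ValueError("reference gene cannot carry a fold change")
    for gene, fold in fold_changes.items():
        if fold <= 0:
            raise ValueError(f"fold for {gene!r} must be positive")
    rng = np.random.default_rng(seed)
    control_delta_ct = dict(control_delta_ct or {})
    for gene in fold_changes:
        control_delta_ct.setdefault(gene, float(rng.uniform(3.0, 9.0)))

    rows = []
    for condition, shift in (("control", 0.0), ("treated", 1.0)):
        for i in range(n_samples):
            sample = f"{condition}_{i + 1}"
            reps = reference_ct + rng.normal(0.0, ct_noise_sd, size=3) \
                if ct_noise_sd > 0 else np.full(3, reference_ct)
            rows.append({"sample": sample, "condition": condition,
                         "plate": plate, "gene": reference_gene,
                         "ct1": reps[0], "ct2": reps[1], "ct3": reps[2]})
            for gene, fold in fold_changes.items():
                dct = control_delta_ct[gene] - shift * math.log2(fold)
                reps = reference_ct + dct + (
                    rng.normal(0.0, ct_noise_sd, size=3) if ct_noise_sd > 0
                    else np.zeros(3))
                rows.append({"sample": sample, "condition": condition,
                             "plate": plate, "gene": gene,
                             "ct1": reps[0], "ct2": reps[1], "ct3": reps[2]})
    return pd.DataFrame(rows)


def generate_blot_table(adjusted_folds: Mapping[str, float],
                        n_repeats: int = 3, seed: int = 0,
                        noise_cv: float = 0.0) -> pd.DataFrame:
    """Band / loading-control densities whose adjusted relative density
    recovers the requested folds in expectation (exactly at zero noise)."""
    for target, fold in adjusted_folds.items():
        if fold <= 0:
            raise ValueError(f"fold for {target!r} must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    for target, fold in adjusted_folds.items():
        base_ratio = rng.uniform(0.5, 2.0)
        for condition, f in (("control", 1.0), ("treated", fold)):
            for i in range(n_repeats):
                loading = rng.uniform(800.0, 1200.0)
                ratio = base_ratio * f
                if noise_cv > 0:
                    ratio *= 1.0 + rng.normal(0.0, noise_cv)
                rows.append({"lane": f"{target}_{condition}_{i + 1}",
                             "condition": condition, "target": target,
                             "band_density": max(ratio, 1e-9) * loading,
                             "loading_density": loading})
    return pd.DataFrame(rows)


def generate_assay_table(fold: float = 1.15, n_wells: int = 9,
                         control_mean: float = 1000.0,
                         blank_mean: float = 50.0,
                         noise_cv: float = 0.0, seed: int = 0) -> pd.DataFrame:
    """PrestoBlue-style Rfu readings with media-only blank wells."""
    if fold <= 0:
        raise ValueError("fold must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    for condition, mean in (("media", blank_mean),
                            ("control", blank_mean + control_mean),
                            ("treated", blank_mean + control_mean * fold)):
        n = 3 if condition == "media" else n_wells
        for i in range(n):
            rfu = mean * (1.0 + (rng.normal(0.0, noise_cv) if noise_cv > 0 else 0.0))
            rows.append({"well": f"{condition}_{i + 1}", "condition": condition,
                         "rfu": rfu})
    return pd.DataFrame(rows)
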