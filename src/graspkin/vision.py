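"""Catadioptric grasp imaging: panoramic unwrapping and skin segmentation.

The instrumented glass carries a hyperbolic mirror above a transparent
cylinder; a camera below sees the grasping hand reflected as a bright
annulus.  This module maps that annulus to a *metric* panoramic image of
the cylinder surface (azimuth around × height along the cylinder, in
mm), clusters the panorama's colors in CIELAB chroma with K-means
(k = 3, Euclidean distance), selects the skin cluster nearest a
configurable reference skin chroma, and measures the grasp contact area
in mm².

The default device geometry images a 140 mm circumference; of the
100 mm cylinder length the bottom 30 mm are rejected (the mirror
compresses them into too few pixels), leaving a 140 × 70 mm surface.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates
from skimage import color as skcolor
from skimage.measure import label as cc_label
from skimage.morphology import remove_small_objects
from sklearn.cluster import KMeans

from .errors import (
    AmbiguousClusterError,
    CalibrationError,
    DegenerateClusterError,
    FormatError,
    ParameterError,
    ValidationError,
)

#: default mid-tone skin locus in CIELAB chroma (a*, b*); calibrate per
#: cohort from one labeled frame — skin tones vary.
DEFAULT_SKIN_AB = (14.0, 17.0)


@dataclass
class MirrorModel:
    """Catadioptric geometry and metric calibration.

    ``center_px`` is the annulus principal point as (row, col).  The
    radius↔height calibration defaults to linear interpolation between
    (r_inner → cylinder top) and (r_outer → rejected-band boundary); a
    measured calibration table (strictly monotone) can be supplied when
    the true single-viewpoint mirror mapping is known.
    """

    center_px: tuple[float, float] = (480.0, 640.0)
    r_inner_px: float = 120.0
    r_outer_px: float = 400.0
    cylinder_circumference_mm: float = 140.0
    cylinder_length_mm: float = 100.0
    reject_bottom_mm: float = 30.0
    calibration_table: np.ndarray | None = None   # (m, 2): radius_px, height_mm

    def __post_init__(self):
        if not (0 < self.r_inner_px < self.r_outer_px):
            raise ValidationError("need 0 < r_inner_px < r_outer_px")
        if not (0 <= self.reject_bottom_mm < self.cylinder_length_mm):
            raise ValidationError("need 0 <= reject_bottom_mm < cylinder_length_mm")
        if self.calibration_table is not None:
            tab = np.asarray(self.calibration_table, dtype=float)
            if tab.ndim != 2 or tab.shape[1] != 2 or tab.shape[0] < 2:
                raise ValidationError("calibration table must be (m, 2) with m >= 2")
            if np.any(np.diff(tab[:, 0]) <= 0):
                raise ValidationError("calibration radii must be strictly increasing")
            dh = np.diff(tab[:, 1])
            if not (np.all(dh > 0) or np.all(dh < 0)):
                raise ValidationError("calibration heights must be strictly monotone")
            self.calibration_table = tab

    @property
    def band_height_mm(self) -> float:
        return self.cylinder_length_mm - self.reject_bottom_mm

    def _table(self) -> tuple[np.ndarray, np.ndarray]:
        if self.calibration_table is not None:
            return self.calibration_table[:, 0], self.calibration_table[:, 1]
        radii = np.array([self.r_inner_px, self.r_outer_px])
        heights = np.array([self.cylinder_length_mm, self.reject_bottom_mm])
        return radii, heights

    def height_of_radius(self, r) -> np.ndarray:
        """Cylinder height (mm) imaged at radius ``r`` (px)."""
        radii, heights = self._table()
        return np.interp(r, radii, heights)

    def radius_of_height(self, h) -> np.ndarray:
        """Image radius (px) at which cylinder height ``h`` (mm) appears."""
        radii, heights = self._table()
        if heights[0] > heights[-1]:
            heights, radii = heights[::-1], radii[::-1]
        return np.interp(h, heights, radii)


@dataclass
class PanoramicImage:
    """Unwrapped metric image of the cylinder surface.

    Column axis is azimuth (column 0 and column W−1 are adjacent on the
    cylinder, wrapping 360°); row axis is height above the rejected
    band.  ``valid`` flags pixels whose source radius lay inside the
    annulus.
    """

    pixels: np.ndarray
    width_mm: float
    height_mm: float
    mm_per_px_x: float
    mm_per_px_y: float
    valid: np.ndarray | None = None
    azimuth_origin_deg: float = 0.0

    @property
    def shape(self):
        return self.pixels.shape

    @property
    def pixel_area_mm2(self) -> float:
        return self.mm_per_px_x * self.mm_per_px_y


@dataclass
class SkinSegmentation:
    """K-means chroma partition of a panorama and its skin mask."""

    labels: np.ndarray          # per-pixel cluster index in {0..k-1}
    centroids: np.ndarray       # (k, 3) cluster centers in L*a*b*
    skin_cluster: int
    mask: np.ndarray            # binary skin map (small components removed)
    grasp_area_mm2: float


# ---------------------------------------------------------------------------
# unwrapping

def unwrap(omni: np.ndarray, model: MirrorModel,
           out_w: int = 360, out_h: int = 140) -> PanoramicImage:
    """Transform the annular mirror image into a metric panorama.

    Output pixel (row, col) samples azimuth θ = 360°·col/out_w and
    height h = reject + (length − reject)·row/out_h; the source radius
    is the inverse radius↔height calibration, sampled bilinearly.
    Pixels whose radius falls outside the annulus are flagged invalid,
    never extrapolated.
    """
    if out_w < 8 or out_h < 8:
        raise ParameterError("panorama must be at least 8x8 pixels")
    omni = np.asarray(omni)
    cy, cx = model.center_px
    rows = np.arange(out_h)
    cols = np.arange(out_w)
    h = model.reject_bottom_mm + model.band_height_mm * rows / out_h
    theta = 2.0 * np.pi * cols / out_w
    r = np.asarray(model.radius_of_height(h))
    yy = cy + r[:, None] * np.sin(theta)[None, :]
    xx = cx + r[:, None] * np.cos(theta)[None, :]
    valid = ((r >= model.r_inner_px - 1e-9) & (r <= model.r_outer_px + 1e-9))
    valid = np.broadcast_to(valid[:, None], (out_h, out_w)).copy()
    valid &= (yy >= 0) & (yy <= omni.shape[0] - 1) & \
             (xx >= 0) & (xx <= omni.shape[1] - 1)
    coords = np.stack([yy, xx])
    if omni.ndim == 2:
        pix = map_coordinates(omni.astype(float), coords, order=1, mode="nearest")
    else:
        pix = np.dstack([
            map_coordinates(omni[..., c].astype(float), coords, order=1,
                            mode="nearest")
            for c in range(omni.shape[2])])
    if np.issubdtype(np.asarray(omni).dtype, np.integer):
        pix = np.clip(np.rint(pix), 0, 255).astype(np.uint8)
    return PanoramicImage(
        pixels=pix,
        width_mm=model.cylinder_circumference_mm,
        height_mm=model.band_height_mm,
        mm_per_px_x=model.cylinder_circumference_mm / out_w,
        mm_per_px_y=model.band_height_mm / out_h,
        valid=valid,
    )


# ---------------------------------------------------------------------------
# color clustering

def to_lab(rgb: np.ndarray) -> np.ndarray:
    """sRGB → CIELAB (D65); accepts uint8 or float images."""
    rgb = np.asarray(rgb)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise FormatError(f"expected an (H, W, 3) RGB image, got shape {rgb.shape}")
    if np.issubdtype(rgb.dtype, np.integer):
        rgb = rgb.astype(float) / 255.0
    return skcolor.rgb2lab(rgb)


def kmeans_lab(lab: np.ndarray, k: int = 3, seed: int = 0, restarts: int = 10,
               chroma_only: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Lloyd K-means on CIELAB chroma with Euclidean distance.

    By default clusters on (a*, b*) only, dropping L*, so lighting and
    sheen variations do not split a material into multiple clusters;
    ``chroma_only=False`` clusters the full L*a*b* vector.  Returns the
    label image and the (k, 3) centroids in full L*a*b* (the L* of a
    chroma-only centroid is the mean L* of its members).
    """
    lab = np.asarray(lab, dtype=float)
    feats = lab.reshape(-1, 3)[:, 1:] if chroma_only else lab.reshape(-1, 3)
    if np.unique(np.round(feats, 6), axis=0).shape[0] < k:
        raise DegenerateClusterError(
            f"fewer than {k} distinct colors in the image")
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed)
    labels = km.fit_predict(feats)
    flat = lab.reshape(-1, 3)
    centroids = np.vstack([flat[labels == j].mean(axis=0) for j in range(k)])
    return labels.reshape(lab.shape[:2]), centroids


def select_skin_cluster(centroids: np.ndarray,
                        reference_skin_ab=DEFAULT_SKIN_AB) -> int:
    """Index of the centroid nearest the reference skin chroma (a*, b*).

    An exact tie (within 1e-6) raises :class:`AmbiguousClusterError` so
    the choice can be made manually.
    """
    centroids = np.asarray(centroids, dtype=float)
    ref = np.asarray(reference_skin_ab, dtype=float)
    d = np.linalg.norm(centroids[:, 1:3] - ref, axis=1)
    order = np.argsort(d)
    if d.size > 1 and abs(d[order[0]] - d[order[1]]) < 1e-6:
        raise AmbiguousClusterError(
            "two centroids are equidistant from the reference skin chroma")
    return int(order[0])


def grasp_area(mask: np.ndarray, pano: PanoramicImage,
               min_component_px: int = 25) -> tuple[float, np.ndarray]:
    """Skin contact area in mm² after removing small speckle components.

    Returns ``(area_mm2, cleaned_mask)``.  An empty mask yields 0.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.any() and min_component_px > 1:
        cleaned = remove_small_objects(cc_label(mask, connectivity=2) > 0,
                                       max_size=min_component_px - 1)
    else:
        cleaned = mask
    return float(cleaned.sum() * pano.pixel_area_mm2), cleaned


def segment_skin(pano: PanoramicImage, k: int = 3, seed: int = 0,
                 restarts: int = 10, reference_skin_ab=DEFAULT_SKIN_AB,
                 min_component_px: int = 25, chroma_only: bool = True,
                 max_skin_distance: float | None = 12.0) -> SkinSegmentation:
    """Full color-segmentation chain on an RGB panorama.

    When no centroid lies within ``max_skin_distance`` CIELAB chroma
    units of the reference, no hand is considered present and the mask
    is empty (``skin_cluster`` is −1); set it to None to always accept
    the nearest centroid.
    """
    lab = to_lab(pano.pixels)
    labels, centroids = kmeans_lab(lab, k=k, seed=seed, restarts=restarts,
                                   chroma_only=chroma_only)
    skin = select_skin_cluster(centroids, reference_skin_ab)
    if max_skin_distance is not None:
        d = np.linalg.norm(centroids[skin, 1:3]
                           - np.asarray(reference_skin_ab, float))
        if d > max_skin_distance:
            skin = -1
    mask = labels == skin
    if pano.valid is not None:
        mask &= pano.valid
    area, cleaned = grasp_area(mask, pano, min_component_px)
    return SkinSegmentation(labels=labels, centroids=centroids,
                            skin_cluster=skin, mask=cleaned,
                            grasp_area_mm2=area)


# ---------------------------------------------------------------------------
# annulus calibration

def detect_annulus(omni: np.ndarray) -> tuple[tuple[float, float], float, float]:
    """Estimate the mirror annulus center and radii from one frame.

    The bright annulus is segmented by Otsu threshold; its centroid
    gives the center (the annulus is rotationally symmetric), and the
    radial mean-intensity profile's half-maximum edges give the radii.
    Raises :class:`CalibrationError` when the image has no annular
    contrast.  Results are meant to seed a :class:`MirrorModel` and can
    be overridden by configuration.
    """
    omni = np.asarray(omni)
    gray = skcolor.rgb2gray(omni) if omni.ndim == 3 else omni.astype(float)
    gmin, gmax = float(gray.min()), float(gray.max())
    if gmax - gmin < 0.05 * max(gmax, 1e-12):
        raise CalibrationError("image has no contrast; annulus not found")
    from skimage.filters import threshold_otsu
    thr = threshold_otsu(gray)
    bright = gray > thr
    if bright.sum() < 16:
        raise CalibrationError("no bright annular region found")
    ys, xs = np.nonzero(bright)
    cy, cx = float(ys.mean()), float(xs.mean())
    yy, xx = np.indices(gray.shape)
    rr = np.hypot(yy - cy, xx - cx).ravel()
    vals = gray.ravel()
    nbins = int(rr.max()) + 1
    ridx = rr.astype(int)
    prof = np.bincount(ridx, weights=vals, minlength=nbins)
    cnt = np.bincount(ridx, minlength=nbins)
    prof = np.where(cnt > 0, prof / np.maximum(cnt, 1), 0.0)
    half = 0.5 * prof.max()
    above = prof >= half
    if not above.any():
        raise CalibrationError("radial profile has no annular band")
    # contiguous band containing the profile peak
    peak = int(np.argmax(prof))
    lo = peak
    while lo > 0 and above[lo - 1]:
        lo -= 1
    hi = peak
    while hi < nbins - 1 and above[hi + 1]:
        hi += 1
    if hi - lo < 2:
        raise CalibrationError("annular band too narrow to calibrate")

    def edge(i, j):
        # sub-bin half-max crossing between radius bins i and j
        if prof[j] == prof[i]:
            return float(j)
        return i + (half - prof[i]) / (prof[j] - prof[i]) * (j - i)

    r_in = edge(lo - 1, lo) if lo > 0 else float(lo)
    r_out = edge(hi + 1, hi) if hi < nbins - 1 else float(hi)
    if r_out < r_in:
        r_in, r_out = r_out, r_in
    return (cy, cx), float(r_in), float(r_out)


# ---------------------------------------------------------------------------
# key-instant postures

def posture_at_events(frames, events, model: MirrorModel,
                      out_w: int = 360, out_h: int = 140,
                      seed: int = 0, **segment_kwargs) -> dict:
    """Unwrap and segment the frame nearest each task event.

    ``frames`` is a sequence of ``(timestamp_s, rgb_image)`` pairs.  An
    event whose nearest frame is farther than two median frame periods
    away is skipped with a warning.  Returns a dict keyed by event label
    ("A".."E") of ``(frame_time, PanoramicImage, SkinSegmentation)``.
    """
    frames = sorted(frames, key=lambda p: p[0])
    if len(frames) < 1:
        raise ParameterError("no frames supplied")
    times = np.array([p[0] for p in frames], dtype=float)
    period = float(np.median(np.diff(times))) if len(times) > 1 else np.inf
    out = {}
    ev = events.as_dict() if hasattr(events, "as_dict") else dict(events)
    for name in ("A", "B", "C", "D", "E"):
        t_ev = ev.get(name)
        if t_ev is None:
            continue
        i = int(np.argmin(np.abs(times - t_ev)))
        if np.isfinite(period) and abs(times[i] - t_ev) > 2 * period:
            warnings.warn(
                f"event {name} at {t_ev:.3f}s has no frame within two "
                f"periods; skipped", stacklevel=2)
            continue
        pano = unwrap(frames[i][1], model, out_w=out_w, out_h=out_h)
        seg = segment_skin(pano, seed=seed, **segment_kwargs)
        out[name] = (float(times[i]), pano, seg)
    return out
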