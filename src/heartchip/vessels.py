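"""Microvascular network morphometry from fluorescence projections.

Reimplements the standard ImageJ-style vessel quantification chain on a
maximum-intensity projection of a CD31 z-stack: Gaussian blur (σ = 2 px),
triangle thresholding, binary erosion, despeckling, 2-D skeletonization,
and skeleton statistics.  Derived metrics are the vessel area fraction of
the field, total network length, mean vessel diameter (total area divided
by total skeleton length), and connectivity (junctions / endpoints).

Conventions: 8-connectivity throughout; 8-adjacent junction pixels are
merged so an X-crossing counts as one junction; diagonal skeleton steps
count √2 pixels so diagonal vessels are not over-weighted; all lengths are
converted to µm via an explicit pixel size — there is no implicit default.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import gaussian
from skimage.morphology import diamond, dilation, disk, erosion, skeletonize

from .calcium import InvalidParameterError

__all__ = [
    "VesselMask",
    "SkeletonStats",
    "VesselMetrics",
    "max_projection",
    "triangle_threshold",
    "preprocess_mask",
    "skeletonize_2d",
    "skeleton_stats",
    "vessel_metrics",
    "analyze_vessel_image",
    "extravascular_fraction",
    "roi_mean_intensity",
]


@dataclass
class VesselMask:
    """Binary vessel image with pixel size and processing provenance."""

    mask: np.ndarray
    pixel_size: float  # µm/px
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask)
        if self.mask.dtype != bool:
            uniq = np.unique(self.mask)
            if not np.all(np.isin(uniq, (0, 1))):
                raise InvalidParameterError("mask must be strictly binary")
            self.mask = self.mask.astype(bool)
        if self.pixel_size <= 0:
            raise InvalidParameterError("pixel_size must be positive")

    @property
    def area_fraction(self) -> float:
        return float(self.mask.mean())


@dataclass
class SkeletonStats:
    total_length: float  # µm
    n_junctions: int
    n_endpoints: int
    n_branches: int

    def __post_init__(self) -> None:
        if self.total_length < 0 or min(self.n_junctions, self.n_endpoints, self.n_branches) < 0:
            raise InvalidParameterError("skeleton statistics must be non-negative")


@dataclass
class VesselMetrics:
    """Field-level morphometrics; ``connectivity`` is ``None`` when there
    are no endpoints, and ``degenerate`` flags a mask with area but no
    measurable skeleton length."""

    area_fraction: float
    total_length: float  # µm
    mean_diameter: float | None  # µm
    connectivity: float | None
    degenerate: bool = False


def max_projection(zstack: np.ndarray) -> np.ndarray:
    """Per-pixel maximum across the slices of a ``(Z, H, W)`` stack."""
    zstack = np.asarray(zstack)
    if zstack.ndim == 2:
        return zstack.copy()
    if zstack.ndim != 3 or zstack.shape[0] < 1:
        raise InvalidParameterError("z-stack must be (Z, H, W) with >= 1 slice")
    return zstack.max(axis=0)


def triangle_threshold(image: np.ndarray, nbins: int = 256):
    """Triangle-algorithm threshold on an ``nbins``-bin histogram.

    A line is drawn from the histogram peak to the farthest empty tail
    bin; the threshold sits at the bin of maximum perpendicular distance
    between that line and the histogram.  Returns ``(threshold, tail)``
    where ``tail`` is ``"right"`` or ``"left"`` depending on which side of
    the peak carried the longer tail.  Pixels strictly above the threshold
    are foreground.
    """
    image = np.asarray(image, dtype=float)
    lo, hi = float(image.min()), float(image.max())
    if lo == hi:
        raise InvalidParameterError("constant image has no threshold")
    hist, edges = np.histogram(image, bins=nbins, range=(lo, hi))
    peak = int(np.argmax(hist))
    nz = np.flatnonzero(hist)
    first, last = int(nz[0]), int(nz[-1])
    # farthest empty bin beyond each tail (clamped to histogram range)
    left_end = max(first - 1, 0)
    right_end = min(last + 1, nbins - 1)
    if (peak - left_end) > (right_end - peak):
        tail = "left"
        span = np.arange(left_end, peak + 1)
    else:
        tail = "right"
        span = np.arange(peak, right_end + 1)
    if span.size < 2:
        raise InvalidParameterError("degenerate histogram; no tail to search")
    h_peak = float(hist[peak])
    end = span[0] if tail == "left" else span[-1]
    # height of the peak->tail-end line at each bin of the span
    line = h_peak * (np.abs(end - span) / max(abs(end - peak), 1))
    gap = line - hist[span]
    interior = span[(span != peak)]
    gaps = gap[(span != peak)]
    b = int(interior[np.argmax(gaps)])
    centers = (edges[:-1] + edges[1:]) / 2.0
    return float(centers[b]), tail


def preprocess_mask(
    projection: np.ndarray,
    pixel_size: float,
    blur_sigma: float = 2.0,
    erode_iters: int = 2,
    outlier_radius: int = 2,
) -> VesselMask:
    """Projection → blur → triangle threshold → erode → despeckle.

    The Gaussian blur uses σ = 2 px by default; erosion uses a 3×3 cross
    (two iterations by default, calibrated so the halo admitted by the
    triangle threshold is cancelled and the mask boundary is recovered to
    sub-pixel accuracy on rendered networks); despeckling is a binary median filter of
    radius ``outlier_radius``, which removes bright specks smaller than
    their neighborhood median support.  Every parameter and the realized
    threshold are recorded in the mask's provenance.  An empty result is
    flagged, never returned silently.
    """
    projection = np.asarray(projection, dtype=float)
    blurred = gaussian(projection, sigma=blur_sigma, preserve_range=True)
    thr, tail = triangle_threshold(blurred)
    mask = blurred > thr
    selem = diamond(1)
    for _ in range(erode_iters):
        mask = erosion(mask, selem)
    if outlier_radius > 0:
        foot = disk(outlier_radius)
        counts = ndi.convolve(mask.astype(np.uint8), foot, mode="constant")
        mask = counts > foot.sum() / 2.0
    prov = {
        "blur_sigma": blur_sigma,
        "threshold": thr,
        "threshold_tail": tail,
        "erode_iters": erode_iters,
        "outlier_radius": outlier_radius,
        "empty": not bool(mask.any()),
    }
    if prov["empty"]:
        warnings.warn("vessel mask is empty after preprocessing", stacklevel=2)
    return VesselMask(mask=mask, pixel_size=pixel_size, provenance=prov)


def skeletonize_2d(mask: VesselMask | np.ndarray, prune_px: int = 0) -> np.ndarray:
    """1-px-wide medial skeleton by morphological thinning.

    Thinning preserves topology: the skeleton has the same number of
    8-connected components as the input mask.  ``prune_px > 0`` removes
    terminal spur branches shorter than that many pixels — thinning of
    tubes wider than a few pixels grows short spurs at junctions, which
    would otherwise inflate endpoint and junction counts.
    """
    m = mask.mask if isinstance(mask, VesselMask) else np.asarray(mask, dtype=bool)
    sk = skeletonize(m)
    if prune_px > 0:
        sk = prune_spurs(sk, prune_px)
    return sk


# ring of 8 neighbors in circular order (consecutive entries are 8-adjacent)
_RING = [(-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1)]


def _arm_count_lut() -> np.ndarray:
    """Arms per 8-neighborhood bitmask: connected groups of foreground
    neighbors in circular ring order.  A bend pixel whose three neighbors
    form two contiguous ring groups has 2 arms, not 3 — neighbor *count*
    alone misclassifies bends as junctions."""
    lut = np.zeros(256, dtype=np.uint8)
    for m in range(256):
        bits = [(m >> i) & 1 for i in range(8)]
        transitions = sum(
            1 for i in range(8) if bits[i] and not bits[(i - 1) % 8]
        )
        lut[m] = transitions
    return lut


_ARM_LUT = _arm_count_lut()


def _neighbor_arms(sk: np.ndarray) -> np.ndarray:
    """Number of skeleton arms leaving each pixel (0 for isolated)."""
    pad = np.pad(sk.astype(np.uint8), 1)
    code = np.zeros(sk.shape, dtype=np.uint8)
    for bit, (dr, dc) in enumerate(_RING):
        code |= pad[1 + dr : 1 + dr + sk.shape[0], 1 + dc : 1 + dc + sk.shape[1]] << bit
    return _ARM_LUT[code]


def prune_spurs(skeleton: np.ndarray, min_length_px: int) -> np.ndarray:
    """Remove terminal branches shorter than ``min_length_px`` pixels.

    A terminal branch is a connected run of non-junction skeleton pixels
    that contains an endpoint and touches a junction; branches smaller
    than ``min_length_px`` pixels are deleted (junction pixels stay) and
    the pass repeats until stable.  Isolated short components are left
    untouched — they are vessels, not spurs.
    """
    sk = np.asarray(skeleton, dtype=bool).copy()
    eight = np.ones((3, 3), dtype=bool)
    while True:
        arms = _neighbor_arms(sk)
        junction_px = sk & (arms >= 3)
        endpoints = sk & (arms == 1)
        # dilate junction pixels so branches that skirt a thick junction
        # attachment by redundant diagonal adjacency are still separated
        zone = ndi.binary_dilation(junction_px, structure=disk(2))
        branches, n_branches = ndi.label(sk & ~zone, structure=eight)
        if n_branches == 0:
            return sk
        sizes = np.bincount(branches.ravel(), minlength=n_branches + 1)
        has_endpoint = np.zeros(n_branches + 1, dtype=bool)
        has_endpoint[np.unique(branches[endpoints])] = True
        near_junction = np.zeros(n_branches + 1, dtype=bool)
        jz = ndi.binary_dilation(zone, structure=eight)
        near_junction[np.unique(branches[jz & (branches > 0)])] = True
        doomed = has_endpoint & near_junction & (sizes < min_length_px)
        doomed[0] = False
        if not doomed.any():
            return sk
        sk[doomed[branches]] = False


def skeleton_stats(
    skeleton: np.ndarray,
    pixel_size: float,
    junction_merge_radius_px: float = 0.0,
) -> SkeletonStats:
    """Endpoint/junction counts and total length of a thin skeleton.

    Arms are counted as connected groups of foreground neighbors in the
    circular 8-neighborhood: endpoints have exactly one arm, junction
    pixels three or more, with 8-adjacent junction pixels merged into a
    single junction.
    ``junction_merge_radius_px`` switches to a graph-contraction count
    for tubes much wider than one pixel, whose thinning splits an
    X-crossing into two nearby Y-junctions and grows local thickenings at
    bends: junction pixels are dilated into zones of that radius, and a
    zone counts as one junction only if at least three distinct skeleton
    branches leave it (a thickened bend has only two).  A radius of about
    half the tube diameter restores the centerline-graph count.  Total
    length sums all adjacent skeleton-pixel pairs: 1 px for orthogonal
    and √2 px for diagonal steps, scaled by ``pixel_size``.
    """
    if pixel_size <= 0:
        raise InvalidParameterError("pixel_size must be positive")
    sk = np.asarray(skeleton, dtype=bool)
    arms = _neighbor_arms(sk)
    n_endpoints = int(np.sum(sk & (arms == 1)))
    junction_px = sk & (arms >= 3)
    eight = np.ones((3, 3))
    if junction_merge_radius_px > 0 and junction_px.any():
        zones = dilation(junction_px, disk(junction_merge_radius_px / 2.0))
        # tips inside a junction zone are thinning debris, not vessel ends
        n_endpoints = int(np.sum(sk & (arms == 1) & ~zones))
        zone_lab, _ = ndi.label(zones, structure=eight)
        branch_lab, _ = ndi.label(sk & ~zones, structure=eight)
        # incidences: zone pixels 8-adjacent to branch pixels
        grown = ndi.grey_dilation(branch_lab, footprint=eight)
        pairs = set(
            zip(
                zone_lab[(zone_lab > 0) & (grown > 0) & sk].tolist(),
                grown[(zone_lab > 0) & (grown > 0) & sk].tolist(),
            )
        )
        deg = np.bincount([z for z, _ in pairs])
        n_junctions = int(np.sum(deg >= 3))
    else:
        _, n_junctions = ndi.label(junction_px, structure=eight)
    # branches: connected runs of non-junction skeleton pixels
    _, n_branches = ndi.label(sk & ~junction_px, structure=np.ones((3, 3)))
    horiz = int(np.sum(sk[:, :-1] & sk[:, 1:]))
    vert = int(np.sum(sk[:-1, :] & sk[1:, :]))
    diag1 = int(np.sum(sk[:-1, :-1] & sk[1:, 1:]))
    diag2 = int(np.sum(sk[:-1, 1:] & sk[1:, :-1]))
    total = (horiz + vert + math.sqrt(2.0) * (diag1 + diag2)) * pixel_size
    return SkeletonStats(
        total_length=float(total),
        n_junctions=int(n_junctions),
        n_endpoints=n_endpoints,
        n_branches=int(n_branches),
    )


def vessel_metrics(mask: VesselMask, stats: SkeletonStats) -> VesselMetrics:
    """Area fraction, mean diameter (area/length) and connectivity.

    ``mean_diameter`` divides the foreground area in µm² by the total
    skeleton length in µm; ``connectivity`` is junctions/endpoints and is
    ``None`` (undefined) when there are no endpoints.
    """
    area_px = int(mask.mask.sum())
    area_um2 = area_px * mask.pixel_size**2
    degenerate = stats.total_length == 0 and area_px > 0
    mean_d = None if stats.total_length == 0 else area_um2 / stats.total_length
    conn = None if stats.n_endpoints == 0 else stats.n_junctions / stats.n_endpoints
    return VesselMetrics(
        area_fraction=mask.area_fraction,
        total_length=stats.total_length,
        mean_diameter=mean_d,
        connectivity=conn,
        degenerate=degenerate,
    )


def analyze_vessel_image(
    zstack_or_projection: np.ndarray,
    pixel_size: float,
    blur_sigma: float = 2.0,
    erode_iters: int = 2,
    outlier_radius: int = 2,
    spur_prune_px: int = 0,
    junction_merge_radius_px: float = 0.0,
) -> tuple[VesselMask, SkeletonStats, VesselMetrics]:
    """Full morphometry pipeline from a z-stack or projection.

    The default of two erosion iterations cancels the foreground halo the
    triangle threshold admits on blurred images (the threshold sits near
    the foot of the background peak); see the methods note.  Topology
    cleanup (``spur_prune_px``, ``junction_merge_radius_px``) is off by
    default and is typically set to about half the expected vessel
    diameter in pixels when junction/endpoint counts are of interest.
    """
    proj = max_projection(zstack_or_projection)
    vm = preprocess_mask(proj, pixel_size, blur_sigma, erode_iters, outlier_radius)
    sk = skeletonize_2d(vm, prune_px=spur_prune_px)
    stats = skeleton_stats(sk, pixel_size, junction_merge_radius_px)
    return vm, stats, vessel_metrics(vm, stats)


def extravascular_fraction(
    liposome_image: np.ndarray,
    vessel_mask: np.ndarray | VesselMask,
    positive_threshold: float | str = "triangle",
    dilation_px: int = 1,
) -> float:
    """Fraction of liposome-positive pixels outside the (dilated) vessels.

    ``positive_threshold`` is either a number, ``"triangle"`` (threshold
    the liposome channel with the triangle algorithm), or ignored when the
    image is already boolean.  Returns NaN (with a warning) when there are
    no positive pixels.
    """
    vm = vessel_mask.mask if isinstance(vessel_mask, VesselMask) else np.asarray(vessel_mask, dtype=bool)
    img = np.asarray(liposome_image)
    if img.shape != vm.shape:
        raise InvalidParameterError("liposome image and vessel mask shapes differ")
    if img.dtype == bool:
        positive = img
    elif positive_threshold == "triangle":
        thr, _ = triangle_threshold(img)
        positive = img > thr
    else:
        positive = img > float(positive_threshold)
    n_pos = int(positive.sum())
    if n_pos == 0:
        warnings.warn("no liposome-positive pixels; fraction undefined", stacklevel=2)
        return float("nan")
    dilated = vm
    for _ in range(int(dilation_px)):
        dilated = dilation(dilated, diamond(1))
    outside = positive & ~dilated
    return float(outside.sum() / n_pos)


def save_qc_overlay(projection: np.ndarray, mask: "VesselMask", skeleton: np.ndarray, path) -> None:
    """Write a PNG overlay of projection, mask boundary and skeleton."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 6))
    ax.imshow(projection, cmap="gray")
    m = mask.mask if isinstance(mask, VesselMask) else mask
    ax.contour(m, levels=[0.5], colors="cyan", linewidths=0.5)
    ys, xs = np.where(skeleton)
    ax.plot(xs, ys, ".", color="red", markersize=0.3)
    ax.set_axis_off()
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)


def roi_mean_intensity(image: np.ndarray, roi: tuple[int, int, int, int]) -> float:
    """Mean pixel value in a rectangular ROI (stacks are max-projected)."""
    img = max_projection(np.asarray(image))
    r0, c0, r1, c1 = roi
    patch = img[r0:r1, c0:c1]
    if patch.size == 0:
        raise InvalidParameterError("empty ROI")
    return float(patch.mean())
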