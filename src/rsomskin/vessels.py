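"""Dermal vessel segmentation and microvascular biomarkers.

Vessel analysis runs on 2D coronal maximum-intensity projections of the
dermis slab, one per frequency band: a multi-scale, multi-orientation matched
filter (zero-mean elongated Gaussian kernels) highlights tubes, Otsu
thresholding of the positive response gives the vascular mask, topological
thinning gives 1-pixel centerlines, and skeleton pixels with ≥ 3 neighbours
are the junctions whose count is the vessel number.  Junctions are classified
small/large by the length-weighted mean diameter (2 × distance transform at
the centerline) of their incident segments, with the 40 µm arteriole/venule
cutoff.  Total blood volume alone is computed in 3D over the
4 × 2 × 1.5 mm³ dermis slab.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import disk, skeletonize

from .layers import DermisSlab
from .volio import VolumeGrid

logger = logging.getLogger(__name__)

#: defaults: matched-filter scales (µm), orientations over 180°, small/large
#: cutoff (µm), isolated-skeleton prune length (px), TBV relative threshold
SCALES_UM = (15.0, 30.0, 45.0, 60.0, 90.0)
N_ORIENTATIONS = 12
CUTOFF_UM = 40.0
MIN_SKELETON_PX = 5
TBV_THRESHOLD_FRACTION = 0.20


# ---------------------------------------------------------------------------
# projections
# ---------------------------------------------------------------------------

def dermis_mip(grid: VolumeGrid, slab: DermisSlab) -> np.ndarray:
    """Coronal MIP of the dermis slab: per (fast, slow) position the maximum
    intensity over the slab's depth interval."""
    vals = np.asarray(grid.values)
    nz, nf, ns = vals.shape
    rows = np.arange(nz)[:, None, None]
    inside = (rows >= slab.start_index[None]) & (rows < slab.stop_index[None])
    masked = np.where(inside, vals, -np.inf)
    out = masked.max(axis=0)
    out[~np.isfinite(out)] = 0.0  # columns with empty (clipped) slab
    return out


# ---------------------------------------------------------------------------
# matched filtering
# ---------------------------------------------------------------------------

def line_kernel(scale_um: float, theta: float, pixel_um: float) -> np.ndarray:
    """Zero-mean Gaussian-profile line kernel at one scale and orientation.

    Cross-section standard deviation ``scale/2.355/2`` (so the Gaussian FWHM
    is half the nominal vessel diameter), length ``3 × scale``, rotated by
    ``theta`` radians; the mean over the rectangular support is subtracted so
    flat regions respond exactly zero, and the kernel is scaled so its
    positive lobe sums to 1 — responses are then comparable across scales
    (≈ the tube's intensity at a matched vessel center).
    """
    sigma_px = scale_um / 2.355 / 2.0 / pixel_um
    half_len_px = 1.5 * scale_um / pixel_um
    half = int(np.ceil(max(half_len_px, 3 * sigma_px, 1.0)))
    y, x = np.mgrid[-half:half + 1, -half:half + 1].astype(float)
    u = x * np.cos(theta) + y * np.sin(theta)       # along the line
    v = -x * np.sin(theta) + y * np.cos(theta)      # across the line
    k = np.exp(-(v ** 2) / (2 * sigma_px ** 2)) * (np.abs(u) <= half_len_px)
    k -= k.mean()
    return k / k[k > 0].sum()


def matched_filter_response(image: np.ndarray, scales_um=SCALES_UM,
                            n_orientations: int = N_ORIENTATIONS,
                            pixel_um: float = 12.0) -> np.ndarray:
    """Maximum matched-filter correlation over all scales and orientations."""
    img = np.asarray(image, dtype=float)
    if len(scales_um) < 1:
        raise ValueError("need at least one scale")
    response = np.full(img.shape, -np.inf)
    for s in scales_um:
        for theta in np.arange(n_orientations) * np.pi / n_orientations:
            k = line_kernel(s, theta, pixel_um)
            if k.shape[0] > img.shape[0] or k.shape[1] > img.shape[1]:
                raise ValueError(
                    f"kernel {k.shape} larger than image {img.shape} at scale {s} µm"
                )
            np.maximum(response, ndimage.correlate(img, k, mode="nearest"),
                       out=response)
    return response


def segment_vessels(response: np.ndarray, image: np.ndarray | None = None,
                    absolute_threshold: float | None = None,
                    refine_fraction: float = 0.5) -> np.ndarray:
    """Binary vascular mask from the matched-filter response.

    Detection threshold is Otsu on the positive responses (or a configured
    absolute override).  When the intensity ``image`` is supplied, each
    detected component's boundary is then refined at the image's local
    half-maximum — ``background + refine_fraction × (component peak −
    background)`` within a 2-pixel dilation of the component — because the
    intensity profile of a blurred tube crosses half-max at the tube edge,
    which keeps distance-transform diameters accurate; the zero-mean response
    decays faster than the intensity near edges and would bias widths low.
    A 1-pixel-radius closing follows; components touching the border are
    retained.
    """
    resp = np.asarray(response, dtype=float)
    if not np.all(np.isfinite(resp)):
        raise ValueError("non-finite matched-filter response")
    pos = resp[resp > 0]
    if pos.size == 0:
        return np.zeros(resp.shape, dtype=bool)
    if absolute_threshold is not None:
        thr = absolute_threshold
    elif np.ptp(pos) == 0:
        thr = pos[0] / 2.0
    else:
        thr = threshold_otsu(pos)
    mask = resp > thr
    if image is not None and refine_fraction:
        img = np.asarray(image, dtype=float)
        background = float(np.median(img[~mask])) if (~mask).any() else 0.0
        labels, n = ndimage.label(mask, structure=np.ones((3, 3)))
        refined = np.zeros_like(mask)
        for i in range(1, n + 1):
            comp = labels == i
            region = ndimage.binary_dilation(comp, structure=np.ones((3, 3)),
                                             iterations=2)
            peak = float(img[comp].max())
            local_thr = background + refine_fraction * (peak - background)
            refined |= region & (img >= local_thr)
        mask = refined
    # close through an edge-replicating pad so border components are retained
    padded = np.pad(mask, 1, mode="edge")
    closed = ndimage.binary_closing(padded, structure=disk(1))
    return closed[1:-1, 1:-1]


# ---------------------------------------------------------------------------
# skeleton, junctions, segments
# ---------------------------------------------------------------------------

_NEIGHBOR_KERNEL = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]])
_EIGHT = np.ones((3, 3), dtype=int)


def _neighbor_count(skel: np.ndarray) -> np.ndarray:
    return ndimage.convolve(skel.astype(int), _NEIGHBOR_KERNEL, mode="constant")


def skeletonize_and_prune(mask: np.ndarray,
                          min_skeleton_px: int = MIN_SKELETON_PX) -> np.ndarray:
    """1-pixel centerlines of the mask, with *isolated* short pieces removed.

    A connected skeleton component is deleted when its total length is under
    ``min_skeleton_px`` pixels and it contains no junction — short spurs that
    hang off a larger structure are kept (the rule targets isolated
    noise/artifact specks only).

    Thinning uses Lee's method; Zhang–Suen can collapse stair-stepped
    diagonal bands to a point on this kind of rasterized tube mask."""
    skel = skeletonize(np.asarray(mask, bool), method="lee").astype(bool)
    junction = skel & (_neighbor_count(skel) >= 3)
    labels, n = ndimage.label(skel, structure=_EIGHT)
    if n == 0:
        return skel
    sizes = ndimage.sum_labels(skel, labels, index=np.arange(1, n + 1))
    has_junction = ndimage.sum_labels(junction, labels, index=np.arange(1, n + 1)) > 0
    drop = (sizes < min_skeleton_px) & ~has_junction
    if drop.any():
        skel = skel & ~np.isin(labels, np.flatnonzero(drop) + 1)
    return skel


@dataclass
class Junction:
    """One merged junction: the centroid of an 8-connected cluster of
    skeleton pixels with ≥ 3 neighbours."""

    centroid: tuple[float, float]
    pixels: np.ndarray  # (k, 2) row/col indices


def find_junctions(skeleton: np.ndarray) -> list[Junction]:
    """Junction points: skeleton pixels with ≥ 3 skeleton neighbours
    (8-connectivity); adjacent junction pixels merge into one junction."""
    skel = np.asarray(skeleton, bool)
    jmask = skel & (_neighbor_count(skel) >= 3)
    labels, n = ndimage.label(jmask, structure=_EIGHT)
    out = []
    for i in range(1, n + 1):
        pix = np.argwhere(labels == i)
        out.append(Junction(centroid=tuple(pix.mean(axis=0)), pixels=pix))
    return out


@dataclass
class VesselSegment:
    """A junction-free centerline piece of the skeleton."""

    pixels: np.ndarray          # (k, 2) row/col
    length_px: int
    diameter_um: float
    incident_junctions: list[int] = field(default_factory=list)

    @property
    def length_um(self) -> float:
        return self.length_px * self._pixel_um

    _pixel_um: float = 12.0


def centerline_diameters(mask: np.ndarray, pixels: np.ndarray,
                         pixel_um: float = 12.0,
                         edt: np.ndarray | None = None) -> np.ndarray:
    """Per-centerline-pixel vessel diameter: twice the Euclidean distance to
    the nearest background pixel, in µm.  The convention over- or under-reads
    by up to half a pixel per side depending on local orientation; with 12 µm
    lateral pixels that keeps single-vessel estimates within one pixel."""
    if edt is None:
        edt = ndimage.distance_transform_edt(np.asarray(mask, bool))
    return 2.0 * edt[pixels[:, 0], pixels[:, 1]] * pixel_um


def extract_segments(skeleton: np.ndarray, junctions: list[Junction],
                     mask: np.ndarray, pixel_um: float = 12.0
                     ) -> list[VesselSegment]:
    """Partition the skeleton minus junction pixels into connected segments,
    attach per-segment diameters (mean of :func:`centerline_diameters` over
    the segment) and incident junction indices."""
    skel = np.asarray(skeleton, bool)
    jmask = np.zeros_like(skel)
    for j in junctions:
        jmask[j.pixels[:, 0], j.pixels[:, 1]] = True
    seg_mask = skel & ~jmask
    labels, n = ndimage.label(seg_mask, structure=_EIGHT)
    edt = ndimage.distance_transform_edt(np.asarray(mask, bool))

    # junction adjacency: a segment is incident if any of its pixels 8-touches
    # a junction cluster
    jlabel = np.zeros(skel.shape, dtype=int)
    for idx, j in enumerate(junctions, start=1):
        jlabel[j.pixels[:, 0], j.pixels[:, 1]] = idx
    jdilated = ndimage.grey_dilation(jlabel, footprint=_EIGHT)

    segments = []
    for i in range(1, n + 1):
        pix = np.argwhere(labels == i)
        diam = centerline_diameters(mask, pix, pixel_um, edt=edt).mean()
        touching = np.unique(jdilated[pix[:, 0], pix[:, 1]])
        incident = [int(t) - 1 for t in touching if t > 0]
        segments.append(VesselSegment(
            pixels=pix, length_px=len(pix), diameter_um=float(diam),
            incident_junctions=incident, _pixel_um=pixel_um,
        ))
    return segments


@dataclass
class VesselNetwork:
    """Vascular mask, skeleton, junctions and segments of one band's dermis MIP."""

    mask: np.ndarray
    skeleton: np.ndarray
    junctions: list[Junction]
    segments: list[VesselSegment]
    pixel_um: float
    band: str = "full"

    @property
    def n_junctions(self) -> int:
        return len(self.junctions)


def build_network(image: np.ndarray, pixel_um: float = 12.0,
                  scales_um=SCALES_UM, n_orientations: int = N_ORIENTATIONS,
                  absolute_threshold: float | None = None,
                  min_skeleton_px: int = MIN_SKELETON_PX,
                  band: str = "full") -> VesselNetwork:
    """Full 2D vessel analysis of a dermis MIP."""
    response = matched_filter_response(image, scales_um=scales_um,
                                       n_orientations=n_orientations,
                                       pixel_um=pixel_um)
    mask = segment_vessels(response, image=image,
                           absolute_threshold=absolute_threshold)
    skeleton = skeletonize_and_prune(mask, min_skeleton_px=min_skeleton_px)
    junctions = find_junctions(skeleton)
    segments = extract_segments(skeleton, junctions, mask, pixel_um=pixel_um)
    return VesselNetwork(mask=mask, skeleton=skeleton, junctions=junctions,
                         segments=segments, pixel_um=pixel_um, band=band)


# ---------------------------------------------------------------------------
# biomarkers
# ---------------------------------------------------------------------------

def junction_diameters(network: VesselNetwork) -> np.ndarray:
    """Length-weighted mean diameter (µm) of the segments incident to each
    junction; junctions with no incident segment fall back to the network-wide
    mean segment diameter (degenerate thinning artifact)."""
    sums = np.zeros(network.n_junctions)
    weights = np.zeros(network.n_junctions)
    for seg in network.segments:
        for j in seg.incident_junctions:
            sums[j] += seg.diameter_um * seg.length_px
            weights[j] += seg.length_px
    out = np.full(network.n_junctions, np.nan)
    nz = weights > 0
    out[nz] = sums[nz] / weights[nz]
    if np.any(~nz) and network.segments:
        out[~nz] = np.mean([s.diameter_um for s in network.segments])
    return out


def count_vessels(network: VesselNetwork, cutoff_um: float = CUTOFF_UM
                  ) -> tuple[int, int, int]:
    """(svn, lvn, tvn) of one network: every junction counts toward the total;
    a junction is *small* when the length-weighted mean diameter of its
    incident vessels is below the cutoff, else *large*.  svn + lvn = tvn."""
    if network.n_junctions == 0:
        return 0, 0, 0
    diam = junction_diameters(network)
    diam = np.where(np.isnan(diam), cutoff_um, diam)  # undecidable → large
    svn = int(np.sum(diam < cutoff_um))
    tvn = network.n_junctions
    return svn, tvn - svn, tvn


def combined_counts(network_low: VesselNetwork, network_high: VesselNetwork,
                    cutoff_um: float = CUTOFF_UM,
                    network_full: VesselNetwork | None = None,
                    ) -> tuple[int, int, int]:
    """Cohort-level counts mirroring the band-to-size mapping: small vessels
    from the high-band network, large from the low-band network; the total is
    their sum (or the full-band junction count when ``network_full`` given)."""
    svn, _, _ = count_vessels(network_high, cutoff_um)
    _, lvn, _ = count_vessels(network_low, cutoff_um)
    if network_full is not None:
        return svn, lvn, network_full.n_junctions
    return svn, lvn, svn + lvn


def total_blood_volume(grid: VolumeGrid, slab: DermisSlab,
                       threshold_fraction: float = TBV_THRESHOLD_FRACTION) -> float:
    """Total blood volume (%) = 100·N/T with N the dermis voxels above
    ``threshold_fraction`` of the dermis maximum and T all slab voxels.
    Invariant to global intensity scaling."""
    inside = slab.mask(grid.shape)
    t = int(inside.sum())
    if t == 0:
        raise ValueError("empty dermis slab")
    vals = np.asarray(grid.values)[inside]
    vmax = float(vals.max())
    if vmax <= 0:
        import warnings

        warnings.warn("all-zero dermis slab; TBV set to 0")
        return 0.0
    n = int(np.sum(vals > threshold_fraction * vmax))
    return 100.0 * n / t


def diameter_histogram(diameters_um, min_um: float = 10.0, bin_um: float = 10.0,
                       n_bins: int = 10) -> np.ndarray:
    """10-bin vessel-size histogram: [10,20), …, [90,100), [100,∞) µm;
    diameters below 10 µm are excluded (logged)."""
    d = np.asarray(list(diameters_um), dtype=float)
    n_small = int(np.sum(d < min_um))
    if n_small:
        logger.info("excluded %d segment(s) below %.0f µm from the histogram",
                    n_small, min_um)
    d = d[d >= min_um]
    idx = np.minimum(((d - min_um) // bin_um).astype(int), n_bins - 1)
    return np.bincount(idx, minlength=n_bins) if d.size else np.zeros(n_bins, int)
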