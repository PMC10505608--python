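"""Synthetic RSOM phantoms and synthetic cohorts with known ground truth.

The study this package reimplements deposited no patient scans, so everything
downstream is exercised on two synthetic stand-ins:

* **Skin phantoms** — dual-band volumes containing a bright superficial
  epidermis slab (with cosmetic ridge texture) over a dermis holding tubular
  vessels of prescribed diameters, split across the low (10–40 MHz, large
  vessels) and high (40–120 MHz, small vessels) bands, blurred by the system
  PSF and corrupted by additive Gaussian noise.  A :class:`PhantomTruth`
  companion carries the analytic ground truth (boundary surfaces, per-band
  vessel masks, branch-point count, true total blood volume) computed from
  the rasterization *before* blur and noise.

* **Cohort tables** — per-subject biomarker rows drawn from per-group normal
  distributions.  The healthy and pooled-diabetic parameters are the printed
  study values (e.g. small-vessel number 9.78 ± 3.41 healthy vs 3.45 ± 2.62
  diabetic); the severity-subgroup parameters are fixed by an a-priori power
  calculation documented in the methods note.

Both generators are bit-reproducible given a seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .volio import DEFAULT_SPACING_UM, BandPair, VolumeGrid

# system resolutions (FWHM): ~4.5 µm axial, ~18.4 µm lateral
FWHM_TO_SIGMA = 1.0 / 2.355
DEFAULT_PSF_SIGMA_UM = (4.5 * FWHM_TO_SIGMA, 18.4 * FWHM_TO_SIGMA, 18.4 * FWHM_TO_SIGMA)

DERMIS_DEPTH_UM = 1500.0


@dataclass
class VesselSpec:
    """One tubular vessel: a polyline centerline swept by a circular cross-section.

    ``control_points_um`` is an (n, 3) array of (depth, fast, slow) coordinates
    in µm, n >= 2; consecutive points are joined by straight segments.
    """

    control_points_um: np.ndarray
    diameter_um: float
    band: str = "high"
    intensity: float = 1.0

    def __post_init__(self) -> None:
        self.control_points_um = np.atleast_2d(np.asarray(self.control_points_um, dtype=float))
        if self.control_points_um.shape[0] < 2 or self.control_points_um.shape[1] != 3:
            raise ValueError("control_points_um must be an (n>=2, 3) array")
        if self.diameter_um <= 0:
            raise ValueError("diameter must be positive")
        if self.band not in ("low", "high"):
            raise ValueError(f"vessel band must be 'low' or 'high', got {self.band!r}")

    @property
    def length_um(self) -> float:
        return float(np.linalg.norm(np.diff(self.control_points_um, axis=0), axis=1).sum())


@dataclass
class PhantomSpec:
    """Geometry and imaging parameters of a synthetic skin volume.

    Defaults reproduce the nominal system: 3 × 12 × 12 µm voxels over a
    4 × 2 mm² field of view, 1.8 mm deep; epidermis thickness defaults to the
    printed healthy mean (105 µm).
    """

    grid_shape: tuple[int, int, int] = (600, 333, 167)
    voxel_spacing_um: tuple[float, float, float] = DEFAULT_SPACING_UM
    surface_depth_um: float | Callable[[np.ndarray, np.ndarray], np.ndarray] = 120.0
    ep_thickness_um: float = 105.0
    ep_intensity: float = 1.0
    ridge_period_um: float = 150.0
    ridge_amplitude: float = 0.2  # relative intensity modulation of the EP slab
    vessels: Sequence[VesselSpec] = field(default_factory=list)
    noise_sigma: float = 0.0
    psf_sigma_um: tuple[float, float, float] = DEFAULT_PSF_SIGMA_UM
    high_band_scale: float = 1.0  # relative intensity of the high band (unknown in real data)
    seed: int = 0

    def __post_init__(self) -> None:
        self.grid_shape = tuple(int(n) for n in self.grid_shape)
        self.voxel_spacing_um = tuple(float(s) for s in self.voxel_spacing_um)
        if any(n <= 0 for n in self.grid_shape):
            raise ValueError("grid_shape must be positive")
        if any(s <= 0 for s in self.voxel_spacing_um):
            raise ValueError("voxel spacing must be positive")
        if self.ep_thickness_um <= 0:
            raise ValueError("ep_thickness_um must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")

    def surface_map(self) -> np.ndarray:
        """Skin-surface depth (µm) per lateral (fast, slow) position."""
        _, nf, ns = self.grid_shape
        dz, df, ds = self.voxel_spacing_um
        fast_um, slow_um = np.meshgrid(
            np.arange(nf) * df, np.arange(ns) * ds, indexing="ij"
        )
        if callable(self.surface_depth_um):
            surf = np.asarray(self.surface_depth_um(fast_um, slow_um), dtype=float)
            surf = np.broadcast_to(surf, (nf, ns)).copy()
        else:
            surf = np.full((nf, ns), float(self.surface_depth_um))
        max_depth = (self.grid_shape[0] - 1) * dz
        if surf.min() < 0 or surf.max() > max_depth:
            raise ValueError("surface depth map leaves the grid depth range")
        return surf


@dataclass
class PhantomTruth:
    """Analytic ground truth of a phantom, from the pre-blur rasterization."""

    ep_top_um: np.ndarray            # (fast, slow) maps, µm
    ep_bottom_um: np.ndarray
    vessel_mask_low: np.ndarray      # boolean, full grid
    vessel_mask_high: np.ndarray
    vessels: pd.DataFrame            # per-vessel: band, diameter_um, length_um, n_voxels
    n_branch_points: int
    tbv_pct: float                   # rasterized vessel voxels / dermis voxels × 100
    dermis_mask: np.ndarray


def rasterize_tube(vessel: VesselSpec, grid_shape: tuple[int, int, int],
                   spacing_um: tuple[float, float, float]) -> np.ndarray:
    """Boolean mask of voxels whose centers lie within ``diameter/2`` of the
    vessel centerline (distance to the polyline, in physical µm)."""
    mask = np.zeros(grid_shape, dtype=bool)
    r = vessel.diameter_um / 2.0
    spacing = np.asarray(spacing_um)
    pts = vessel.control_points_um
    lo_all = pts.min(axis=0) - r
    hi_all = pts.max(axis=0) + r
    grid_hi = (np.asarray(grid_shape) - 1) * spacing
    if np.any(lo_all > grid_hi) or np.any(hi_all < 0):
        raise ValueError("vessel lies entirely outside the grid")
    if np.any(pts < -r) or np.any(pts > grid_hi + r):
        raise ValueError("vessel control points leave the grid")

    for a, b in zip(pts[:-1], pts[1:]):
        lo_idx = np.maximum(np.floor((np.minimum(a, b) - r) / spacing).astype(int), 0)
        hi_idx = np.minimum(
            np.ceil((np.maximum(a, b) + r) / spacing).astype(int) + 1,
            np.asarray(grid_shape),
        )
        if np.any(lo_idx >= hi_idx):
            continue
        axes = [np.arange(lo_idx[k], hi_idx[k]) * spacing[k] for k in range(3)]
        zz, ff, ss = np.meshgrid(*axes, indexing="ij")
        p = np.stack([zz, ff, ss], axis=-1)
        ab = b - a
        denom = float(ab @ ab)
        if denom == 0:
            d2 = ((p - a) ** 2).sum(axis=-1)
        else:
            t = np.clip(((p - a) @ ab) / denom, 0.0, 1.0)
            closest = a + t[..., None] * ab
            d2 = ((p - closest) ** 2).sum(axis=-1)
        sub = d2 <= r * r
        mask[lo_idx[0]:hi_idx[0], lo_idx[1]:hi_idx[1], lo_idx[2]:hi_idx[2]] |= sub
    return mask


def count_branch_points(vessels: Sequence[VesselSpec], tol_um: float = 1e-6) -> int:
    """Branch points of the combined centerline graph: polyline vertices where
    >= 3 segments meet (shared endpoints across vessels are merged)."""
    from collections import defaultdict

    degree: dict[tuple, int] = defaultdict(int)
    for v in vessels:
        pts = np.round(v.control_points_um / tol_um).astype(np.int64)
        for a, b in zip(pts[:-1], pts[1:]):
            ka, kb = tuple(a), tuple(b)
            if ka == kb:
                continue
            degree[ka] += 1
            degree[kb] += 1
    return int(sum(1 for d in degree.values() if d >= 3))


def make_skin_phantom(spec: PhantomSpec) -> tuple[BandPair, PhantomTruth]:
    """Render a dual-band skin phantom and its analytic ground truth.

    The epidermis slab and each vessel are rasterized on the grid, the truth
    fields are frozen, and only then are the volumes blurred by the
    band-independent Gaussian PSF and corrupted with additive noise (negative
    noise excursions are clipped at zero, as reconstructed intensities are
    nonnegative).
    """
    nz, nf, ns = spec.grid_shape
    dz, df, ds = spec.voxel_spacing_um
    rng = np.random.default_rng(spec.seed)

    surf = spec.surface_map()
    ep_bottom = surf + spec.ep_thickness_um
    depth_extent = nz * dz
    if ep_bottom.max() + DERMIS_DEPTH_UM > depth_extent:
        warnings.warn(
            f"grid depth {depth_extent:.0f} µm covers less than 1.5 mm below the "
            f"deepest epidermis bottom ({ep_bottom.max():.0f} µm); dermis truth is clipped"
        )

    depth_um = (np.arange(nz) * dz)[:, None, None]
    in_ep = (depth_um >= surf[None]) & (depth_um < ep_bottom[None])

    fast_um = (np.arange(nf) * df)[None, :, None]
    ridge = 1.0 + spec.ridge_amplitude * np.sin(2 * np.pi * fast_um / spec.ridge_period_um)
    ep_field = (spec.ep_intensity * ridge * in_ep).astype(np.float32)

    vol = {"low": ep_field.copy(), "high": (spec.high_band_scale * ep_field).astype(np.float32)}
    band_mask = {
        "low": np.zeros(spec.grid_shape, dtype=bool),
        "high": np.zeros(spec.grid_shape, dtype=bool),
    }
    rows = []
    for i, v in enumerate(spec.vessels):
        m = rasterize_tube(v, spec.grid_shape, spec.voxel_spacing_um)
        band_mask[v.band] |= m
        np.maximum(vol[v.band], (v.intensity * m).astype(np.float32), out=vol[v.band])
        rows.append({
            "vessel_id": i, "band": v.band, "diameter_um": v.diameter_um,
            "length_um": v.length_um, "n_voxels": int(m.sum()),
        })
    vessel_table = pd.DataFrame(
        rows, columns=["vessel_id", "band", "diameter_um", "length_um", "n_voxels"]
    )

    # analytic dermis slab: [EP bottom, EP bottom + 1.5 mm) per lateral position
    dermis = (depth_um >= ep_bottom[None]) & (depth_um < ep_bottom[None] + DERMIS_DEPTH_UM)
    union = (band_mask["low"] | band_mask["high"]) & dermis
    n_dermis = int(dermis.sum())
    tbv = 100.0 * union.sum() / n_dermis if n_dermis else 0.0

    truth = PhantomTruth(
        ep_top_um=surf,
        ep_bottom_um=ep_bottom,
        vessel_mask_low=band_mask["low"],
        vessel_mask_high=band_mask["high"],
        vessels=vessel_table,
        n_branch_points=count_branch_points(spec.vessels),
        tbv_pct=float(tbv),
        dermis_mask=dermis,
    )

    sigma_vox = tuple(s / sp for s, sp in zip(spec.psf_sigma_um, spec.voxel_spacing_um))
    from scipy.ndimage import gaussian_filter

    grids = {}
    for band in ("low", "high"):
        v = vol[band]
        if any(s > 0 for s in sigma_vox):
            v = gaussian_filter(v, sigma=sigma_vox, mode="constant")
        if spec.noise_sigma > 0:
            v = v + rng.normal(0.0, spec.noise_sigma, size=v.shape).astype(np.float32)
            np.clip(v, 0.0, None, out=v)
        grids[band] = VolumeGrid(
            np.ascontiguousarray(v, dtype=np.float32),
            spacing_um=spec.voxel_spacing_um, band=band,
        )
    return BandPair(low=grids["low"], high=grids["high"]), truth


# ---------------------------------------------------------------------------
# synthetic cohorts
# ---------------------------------------------------------------------------

BIOMARKER_COLUMNS = ("svn", "lvn", "tvn", "tbv_pct", "ep_thickness_um", "ep_density")

COHORT_COLUMNS = (
    "subject_id", "group", "age", "sex", "bmi", "dm_type", "duration_y",
    "nds", "nss", "hba1c", "ascvd",
) + BIOMARKER_COLUMNS

#: per-group biomarker (mean, SD).  healthy and diabetic rows are the printed
#: study values; NC/LN/HN/NA rows are the package's power-calculated defaults
#: (see docs/methods.md); NnA is the LN∪HN mixture for direct draws.
DEFAULT_GROUP_BIOMARKERS: dict[str, dict[str, tuple[float, float]]] = {
    "healthy": {"svn": (9.78, 3.41), "lvn": (20.34, 8.32), "tvn": (30.12, 9.87),
                "tbv_pct": (4.21, 1.10), "ep_thickness_um": (105.27, 17.04),
                "ep_density": (1.00, 0.22)},
    "diabetic": {"svn": (3.45, 2.62), "lvn": (13.39, 11.30), "tvn": (16.87, 9.30),
                 "tbv_pct": (1.58, 0.90), "ep_thickness_um": (81.03, 23.06),
                 "ep_density": (0.78, 0.22)},
    "NC": {"svn": (5.2, 2.8), "lvn": (14.5, 11.3), "tvn": (19.9, 10.0),
           "tbv_pct": (2.4, 1.0), "ep_thickness_um": (113.0, 16.0),
           "ep_density": (0.82, 0.20)},
    "LN": {"svn": (2.4, 1.2), "lvn": (13.5, 11.0), "tvn": (16.0, 9.5),
           "tbv_pct": (1.4, 0.7), "ep_thickness_um": (95.0, 18.0),
           "ep_density": (0.78, 0.20)},
    "HN": {"svn": (0.35, 0.35), "lvn": (12.5, 11.0), "tvn": (7.0, 5.0),
           "tbv_pct": (0.35, 0.25), "ep_thickness_um": (78.0, 18.0),
           "ep_density": (0.72, 0.20)},
    "NA": {"svn": (0.3, 0.5), "lvn": (7.0, 6.0), "tvn": (7.5, 6.0),
           "tbv_pct": (0.4, 0.4), "ep_thickness_um": (80.0, 20.0),
           "ep_density": (0.75, 0.20)},
    "NnA": {"svn": (1.42, 1.3), "lvn": (13.0, 11.0), "tvn": (11.7, 9.0),
            "tbv_pct": (0.9, 0.8), "ep_thickness_um": (86.8, 19.0),
            "ep_density": (0.75, 0.20)},
}

#: covariate distributions per group, following Table-1-style summaries.
#: healthy HbA1c is synthetic (normal clinical range) — not recorded in the study.
DEFAULT_GROUP_COVARIATES: dict[str, dict] = {
    "healthy": {"age": (64, 13), "duration_y": (0, 0), "bmi": (26, 7),
                "hba1c": (5.4, 0.4), "male_frac": 27 / 48, "type1_frac": 0.0,
                "nds": (0, 0), "nss": (0, 0), "ascvd": False},
    "diabetic": {"age": (68, 12), "duration_y": (20, 16), "bmi": (27, 8),
                 "hba1c": (7.1, 1.1), "male_frac": 42 / 98, "type1_frac": 21 / 95,
                 "nds": (0, 10), "nss": (0, 10), "ascvd": False},
    "NC": {"age": (63, 19), "duration_y": (12, 11), "bmi": (27, 6),
           "hba1c": (7.1, 1.6), "male_frac": 24 / 43, "type1_frac": 7 / 43,
           "nds": (0, 0), "nss": (0, 0), "ascvd": False},
    "LN": {"age": (70, 10), "duration_y": (27, 17), "bmi": (30, 8),
           "hba1c": (7.2, 0.7), "male_frac": 9 / 27, "type1_frac": 11 / 25,
           "nds": (1, 5), "nss": (1, 5), "ascvd": False},
    "HN": {"age": (70, 10), "duration_y": (27, 17), "bmi": (30, 8),
           "hba1c": (7.2, 0.7), "male_frac": 9 / 27, "type1_frac": 11 / 25,
           "nds": (6, 10), "nss": (6, 10), "ascvd": False},
    "NA": {"age": (76, 7), "duration_y": (23, 16), "bmi": (28, 4),
           "hba1c": (6.9, 0.9), "male_frac": 6 / 25, "type1_frac": 3 / 25,
           "nds": (1, 10), "nss": (1, 10), "ascvd": True},
    "NnA": {"age": (70, 10), "duration_y": (27, 17), "bmi": (30, 8),
            "hba1c": (7.2, 0.7), "male_frac": 9 / 27, "type1_frac": 11 / 25,
            "nds": (1, 10), "nss": (1, 10), "ascvd": False},
}

#: study group sizes: 48 healthy, 45 no-complication, 13 low-score and 12
#: high-score neuropathy (without ASCVD), 25 neuropathy with ASCVD/PAD.
DEFAULT_GROUP_SIZES = {"healthy": 48, "NC": 45, "LN": 13, "HN": 12, "NA": 25}


@dataclass
class CohortSpec:
    """Parameters of a synthetic biomarker cohort."""

    group_sizes: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    group_biomarkers: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=lambda: {g: dict(v) for g, v in DEFAULT_GROUP_BIOMARKERS.items()}
    )
    group_covariates: dict[str, dict] = field(
        default_factory=lambda: {g: dict(v) for g, v in DEFAULT_GROUP_COVARIATES.items()}
    )
    clip_at_zero: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for g, n in self.group_sizes.items():
            if g not in self.group_biomarkers:
                raise ValueError(f"unknown group {g!r}")
            if n <= 0:
                raise ValueError(f"group {g!r} size must be positive, got {n}")
            for bm, (_, sd) in self.group_biomarkers[g].items():
                if sd < 0:
                    raise ValueError(f"negative SD for {g}/{bm}")


def make_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a synthetic subject table: one row per subject, group label,
    covariates, and the six biomarkers drawn from that group's normals
    (untruncated unless ``clip_at_zero``)."""
    rng = np.random.default_rng(spec.seed)
    frames = []
    next_id = 0
    for group in spec.group_sizes:
        n = spec.group_sizes[group]
        cov = spec.group_covariates[group]
        bio = spec.group_biomarkers[group]
        rec: dict[str, np.ndarray | list] = {}
        rec["subject_id"] = [f"S{j:04d}" for j in range(next_id, next_id + n)]
        next_id += n
        rec["group"] = [group] * n
        rec["age"] = np.round(rng.normal(*cov["age"], size=n)).clip(18, 100)
        rec["sex"] = np.where(rng.random(n) < cov["male_frac"], "M", "F")
        rec["bmi"] = np.round(rng.normal(*cov["bmi"], size=n).clip(15, 60), 1)
        if group == "healthy":
            rec["dm_type"] = ["none"] * n
            rec["duration_y"] = np.zeros(n)
        else:
            rec["dm_type"] = np.where(rng.random(n) < cov["type1_frac"], 1, 2)
            rec["duration_y"] = np.round(
                rng.normal(*cov["duration_y"], size=n).clip(0.5, 70), 1
            )
        for score in ("nds", "nss"):
            lo, hi = cov[score]
            rec[score] = lo if lo == hi else rng.integers(lo, hi + 1, size=n)
            rec[score] = np.broadcast_to(rec[score], (n,)).astype(int)
        rec["hba1c"] = np.round(rng.normal(*cov["hba1c"], size=n).clip(4.0, 15.0), 1)
        rec["ascvd"] = [bool(cov["ascvd"])] * n
        for bm in BIOMARKER_COLUMNS:
            mean, sd = bio[bm]
            draws = rng.normal(mean, sd, size=n)
            if spec.clip_at_zero:
                draws = draws.clip(0.0, None)
            rec[bm] = draws
        frames.append(pd.DataFrame(rec))
    table = pd.concat(frames, ignore_index=True)
    return table[list(COHORT_COLUMNS)]
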