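"""Volume I/O and the canonical in-memory grid model.

RSOM reconstructions are 3D scalar intensity fields on a regular grid with
strongly anisotropic voxels (nominally 3 µm axially, 12 µm laterally).  Every
module in this package works on :class:`VolumeGrid` (one frequency band) or
:class:`BandPair` (co-registered low 10–40 MHz and high 40–120 MHz band
volumes).  Supported on-disk formats: multi-page TIFF (one page per depth
slice), NIfTI-1, and raw float32 with a JSON sidecar.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace
from pathlib import Path

import nibabel as nib
import numpy as np
import tifffile

logger = logging.getLogger(__name__)

#: nominal reconstruction-grid voxel spacing (depth, fast, slow) in µm
DEFAULT_SPACING_UM = (3.0, 12.0, 12.0)

_BANDS = ("low", "high", "full")


@dataclass
class VolumeGrid:
    """One band's 3D intensity field.

    Axis convention is (depth, fast, slow): index 0 increases with depth into
    the skin, indices 1 and 2 are the fast and slow scan axes.

    Parameters
    ----------
    values
        Nonnegative finite intensities, arbitrary units.
    spacing_um
        Voxel spacing (depth, fast, slow) in µm; all positive.
    band
        One of ``"low"``, ``"high"``, ``"full"``.
    origin_depth_um
        Physical depth of the first depth index, µm.
    """

    values: np.ndarray
    spacing_um: tuple[float, float, float] = DEFAULT_SPACING_UM
    band: str = "full"
    origin_depth_um: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3D volume, got ndim={self.values.ndim}")
        self.spacing_um = tuple(float(s) for s in self.spacing_um)
        if len(self.spacing_um) != 3 or any(s <= 0 for s in self.spacing_um):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing_um}")
        if self.band not in _BANDS:
            raise ValueError(f"band must be one of {_BANDS}, got {self.band!r}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("volume contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def extent_mm(self) -> tuple[float, float, float]:
        """Physical span (depth, fast, slow) in mm."""
        return tuple(n * s / 1000.0 for n, s in zip(self.shape, self.spacing_um))

    def depth_coords_um(self) -> np.ndarray:
        """Depth coordinate of every depth index, µm."""
        return self.origin_depth_um + np.arange(self.shape[0]) * self.spacing_um[0]

    def copy(self) -> "VolumeGrid":
        return replace(self, values=self.values.copy())


@dataclass
class BandPair:
    """Co-registered low/high band volumes plus the high-band display weight.

    The weight modulates the high band in the red/green fused composite only;
    biomarker computation never uses it.
    """

    low: VolumeGrid
    high: VolumeGrid
    weight: float | None = None

    def __post_init__(self) -> None:
        if self.low.shape != self.high.shape:
            raise ValueError(
                f"band shapes differ: low {self.low.shape} vs high {self.high.shape}"
            )
        if self.low.spacing_um != self.high.spacing_um:
            raise ValueError("band spacings differ")
        if self.weight is None:
            self.weight = default_weight(self.low.values, self.high.values)
        if self.weight < 0:
            raise ValueError("weight must be >= 0")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.low.shape

    @property
    def spacing_um(self) -> tuple[float, float, float]:
        return self.low.spacing_um

    def full(self) -> VolumeGrid:
        """Unweighted sum of both bands, standing in for a full-band (10–120 MHz)
        reconstruction."""
        return VolumeGrid(
            self.low.values + self.high.values,
            spacing_um=self.low.spacing_um,
            band="full",
            origin_depth_um=self.low.origin_depth_um,
        )


def default_weight(low: np.ndarray, high: np.ndarray) -> float:
    """High-band weight matching the two bands' 95th percentiles.

    The reconstruction papers introduce a weighting factor for the
    high-frequency band without stating a value; matching upper percentiles
    gives both bands comparable brightness in the composite.
    """
    p_low = float(np.percentile(low, 95))
    p_high = float(np.percentile(high, 95))
    if p_high <= 0:
        return 1.0
    return p_low / p_high if p_low > 0 else 1.0


# ---------------------------------------------------------------------------
# file formats
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def _read_sidecar(path: Path) -> dict | None:
    sc = _sidecar_path(path)
    if sc.exists():
        with open(sc) as fh:
            return json.load(fh)
    return None


def write_volume(grid: VolumeGrid, path: str | Path) -> Path:
    """Write a volume as TIFF stack, NIfTI, or raw float32, with JSON sidecar.

    Format chosen by extension: ``.tif``/``.tiff``, ``.nii``/``.nii.gz``,
    anything else is raw float32 (C order).  Round trip through
    :func:`read_volume` is lossless for float32 data.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    values = np.ascontiguousarray(grid.values, dtype=np.float32)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        tifffile.imwrite(path, values)
    elif suffix == ".nii" or path.name.lower().endswith(".nii.gz"):
        # store (depth, fast, slow) directly; sidecar is authoritative for metadata
        affine = np.diag([grid.spacing_um[0], grid.spacing_um[1], grid.spacing_um[2], 1.0])
        nib.save(nib.Nifti1Image(values, affine), str(path))
    else:
        values.tofile(path)
    meta = {
        "shape": list(grid.shape),
        "spacing_um": list(grid.spacing_um),
        "band": grid.band,
        "origin_depth_um": grid.origin_depth_um,
    }
    with open(_sidecar_path(path), "w") as fh:
        json.dump(meta, fh, indent=1)
    return path


def read_volume(path: str | Path, metadata: dict | None = None) -> VolumeGrid:
    """Read a volume, normalizing to the (depth, fast, slow) axis order.

    Metadata precedence: explicit ``metadata`` argument, then JSON sidecar,
    then defaults (with a logged warning).  Raises ``ValueError`` on empty or
    inconsistent files.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    meta = dict(metadata) if metadata is not None else None
    if meta is None:
        meta = _read_sidecar(path)
    if meta is None:
        logger.warning("no metadata for %s; assuming default spacing %s", path, DEFAULT_SPACING_UM)
        meta = {}

    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        if path.stat().st_size == 0:
            raise ValueError(f"empty TIFF file: {path}")
        values = np.asarray(tifffile.imread(path))
        if values.ndim == 2:
            values = values[None]
    elif suffix == ".nii" or path.name.lower().endswith(".nii.gz"):
        values = np.asanyarray(nib.load(str(path)).dataobj)
    else:
        shape = meta.get("shape")
        if shape is None:
            raise ValueError(f"raw volume {path} requires a shape in metadata/sidecar")
        values = np.fromfile(path, dtype=np.float32)
        if values.size != int(np.prod(shape)):
            raise ValueError(
                f"raw file {path} has {values.size} values, metadata shape {shape} "
                f"needs {int(np.prod(shape))}"
            )
        values = values.reshape(shape)
    if values.size == 0:
        raise ValueError(f"empty volume in {path}")

    if "shape" in meta and tuple(meta["shape"]) != values.shape:
        raise ValueError(
            f"metadata shape {tuple(meta['shape'])} does not match file shape {values.shape}"
        )
    spacing = tuple(meta.get("spacing_um", DEFAULT_SPACING_UM))
    return VolumeGrid(
        values.astype(np.float32),
        spacing_um=spacing,
        band=meta.get("band", "full"),
        origin_depth_um=float(meta.get("origin_depth_um", 0.0)),
    )


def read_band_pair(low_path: str | Path, high_path: str | Path,
                   weight: float | None = None) -> BandPair:
    low = read_volume(low_path)
    high = read_volume(high_path)
    if low.band == "full":
        low = replace(low, band="low")
    if high.band == "full":
        high = replace(high, band="high")
    return BandPair(low=low, high=high, weight=weight)


# ---------------------------------------------------------------------------
# display fusion
# ---------------------------------------------------------------------------

def fuse_composite(pair: BandPair) -> np.ndarray:
    """Red/green composite: red = normalized low band, green = weight × normalized
    high band, blue = 0, clipped to [0, 1].

    Visualization only — large vessels appear red (low band), fine vasculature
    green (high band).  Never feeds biomarker computation.
    """
    def _norm(v: np.ndarray) -> np.ndarray:
        m = float(v.max())
        return v / m if m > 0 else np.zeros_like(v, dtype=float)

    red = _norm(np.asarray(pair.low.values, dtype=float))
    green = pair.weight * _norm(np.asarray(pair.high.values, dtype=float))
    rgb = np.stack([red, green, np.zeros_like(red)], axis=-1)
    return np.clip(rgb, 0.0, 1.0)


def save_mip_png(grid: VolumeGrid, path: str | Path, axis: int = 2) -> Path:
    """8-bit grayscale PNG of a maximum intensity projection along ``axis``."""
    import matplotlib.image  # lazy; only needed for figure export

    mip = np.asarray(grid.values, dtype=float).max(axis=axis)
    m = mip.max()
    img = mip / m if m > 0 else mip
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    matplotlib.image.imsave(path, img, cmap="gray", vmin=0.0, vmax=1.0)
    return path
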