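"""Band splitting, skin-surface detection, and volume flattening.

Real acquisitions split the detected ultrasound signals into a low (10–40 MHz)
and a high (40–120 MHz) band before reconstruction; :func:`bandpass_split`
exercises that definition on synthetic time series.  Reconstructed volumes are
then *flattened* — each A-line shifted so the detected skin surface lies at a
common depth — before layer segmentation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal

from .volio import VolumeGrid

LOW_BAND_HZ = (10e6, 40e6)
HIGH_BAND_HZ = (40e6, 120e6)

#: surface detector defaults: fraction of the per-column max after depth
#: smoothing, depth-smoothing window (voxels), lateral median-filter window
SURFACE_THRESHOLD_FRACTION = 0.5
SURFACE_SMOOTH_VOXELS = 5
SURFACE_MEDIAN_WINDOW = 3


def bandpass_split(signals: np.ndarray, fs: float, order: int = 4
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Zero-phase split of time-domain signals into the 10–40 and 40–120 MHz bands.

    Parameters
    ----------
    signals
        Array with time along the last axis (any number of leading axes).
    fs
        Sampling rate in Hz; must exceed 240 MHz (Nyquist for the high band).

    Returns
    -------
    (low, high) : filtered copies, same shape as the input.
    """
    if fs <= 2 * HIGH_BAND_HZ[1]:
        raise ValueError(
            f"sampling rate {fs:.3g} Hz too low; need > {2 * HIGH_BAND_HZ[1]:.3g} Hz"
        )
    signals = np.asarray(signals, dtype=float)
    out = []
    for lo, hi in (LOW_BAND_HZ, HIGH_BAND_HZ):
        sos = signal.butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")
        out.append(signal.sosfiltfilt(sos, signals, axis=-1))
    return out[0], out[1]


@dataclass
class SurfaceMap:
    """Skin-surface depth per lateral (fast, slow) position, µm."""

    depth_um: np.ndarray
    spacing_um: tuple[float, float, float]

    def depth_index(self) -> np.ndarray:
        return np.round(self.depth_um / self.spacing_um[0]).astype(int)


def detect_surface(grid: VolumeGrid,
                   threshold_fraction: float = SURFACE_THRESHOLD_FRACTION,
                   smooth_voxels: int = SURFACE_SMOOTH_VOXELS,
                   median_window: int = SURFACE_MEDIAN_WINDOW) -> SurfaceMap:
    """Per A-line first-crossing surface detector.

    Each A-line is smoothed along depth (uniform filter), and the surface is
    the first depth where the smoothed line exceeds ``threshold_fraction`` of
    its own maximum.  The lateral map is then median filtered to suppress
    outlier columns.  All-zero columns are filled from the lateral median.
    """
    vals = np.asarray(grid.values, dtype=float)
    if not np.any(vals > 0):
        raise ValueError("cannot detect a surface in an all-zero volume")
    sm = ndimage.uniform_filter1d(vals, size=smooth_voxels, axis=0, mode="nearest")
    colmax = sm.max(axis=0)
    ok = colmax > 0
    above = sm >= threshold_fraction * np.where(ok, colmax, np.inf)[None]
    first = np.argmax(above, axis=0).astype(float)
    first[~ok] = np.nan
    if np.any(~ok):
        fill = np.nanmedian(first)
        first = np.where(ok, first, fill)
    first = ndimage.median_filter(first, size=median_window, mode="nearest")
    return SurfaceMap(depth_um=grid.origin_depth_um + first * grid.spacing_um[0],
                      spacing_um=grid.spacing_um)


def flatten(grid: VolumeGrid, surface: SurfaceMap,
            reference_index: int | None = None) -> tuple[VolumeGrid, np.ndarray]:
    """Shift every A-line by an integer number of depth voxels so the surface
    sits at a common depth index.

    Integer shifts keep intensities exact (no interpolation), so downstream
    relative-intensity thresholds are unaffected.  Out-of-range voxels are
    zero-filled.  Returns the flattened grid and the per-column shift applied
    (positive = moved up), allowing inverse mapping.
    """
    idx = surface.depth_index()
    if reference_index is None:
        reference_index = int(idx.min())
    shifts = idx - reference_index  # voxels removed from the top of each column
    vals = np.asarray(grid.values)
    out = np.zeros_like(vals)
    nz = vals.shape[0]
    for s in np.unique(shifts):
        cols = shifts == s
        if s >= 0:
            out[: nz - s, cols] = vals[s:, cols]
        else:
            out[-s:, cols] = vals[: nz + s, cols]
    flat = VolumeGrid(out, spacing_um=grid.spacing_um, band=grid.band,
                      origin_depth_um=grid.origin_depth_um)
    return flat, shifts
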