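"""Epidermis segmentation by dynamic programming and layer-derived biomarkers.

The low-band volume is split into four 0.5 mm stacks along the slow axis; the
sagittal maximum-intensity projection of each stack is segmented with a
shortest-path (graph / dynamic programming) boundary finder for the epidermis
top (dark→bright) and bottom (bright→dark) edges; the four boundary pairs are
smoothed and merged.  From the merged boundaries come epidermal thickness,
epidermal signal density, and the dermis slab (1.5 mm below the epidermis
bottom) used by the vessel analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volio import VolumeGrid

N_STACKS = 4
JUMP_LIMIT = 1           # max row change between adjacent columns
EDGE_EPSILON = 1e-5      # strictly positive edge cost floor
SMOOTH_WINDOW = 11       # boundary moving-average window, columns
MIN_SEPARATION = 2       # bottom path starts this many rows below the top path
DERMIS_DEPTH_UM = 1500.0


# ---------------------------------------------------------------------------
# stacks and projections
# ---------------------------------------------------------------------------

def split_stacks(grid: VolumeGrid, n_stacks: int = N_STACKS) -> list[VolumeGrid]:
    """Partition the slow axis into ``n_stacks`` contiguous slabs.

    The nominal 2 mm slow extent gives four 0.5 mm stacks; slow extents that
    do not divide evenly are split into equal voxel counts with the remainder
    going to the last stack (warning if the extent is under 2 mm).
    """
    ns = grid.shape[2]
    if grid.extent_mm()[2] < 2.0 - 1e-9:
        warnings.warn(
            f"slow extent {grid.extent_mm()[2]:.2f} mm < 2 mm; splitting proportionally"
        )
    ranges = stack_slices(ns, n_stacks)
    return [VolumeGrid(
        grid.values[:, :, s0:s1],
        spacing_um=grid.spacing_um, band=grid.band,
        origin_depth_um=grid.origin_depth_um,
    ) for s0, s1 in ranges]


def stack_slices(n_slow: int, n_stacks: int = N_STACKS) -> list[tuple[int, int]]:
    """Slow-index ranges of :func:`split_stacks` (half-open): equal counts of
    ⌈n/4⌉ slices with the remainder shortening the last stack (167 → 42, 42,
    42, 41)."""
    base = -(-n_slow // n_stacks)
    if n_slow - (n_stacks - 1) * base < 1:
        raise ValueError(
            f"cannot split {n_slow} slow slices into {n_stacks} non-empty stacks"
        )
    return [(k * base, min((k + 1) * base, n_slow)) for k in range(n_stacks)]


def stack_mip(stack: VolumeGrid) -> np.ndarray:
    """Sagittal MIP of a stack: per-pixel maximum over the slow axis,
    returning a (depth, fast) image."""
    if stack.values.size == 0:
        raise ValueError("empty stack")
    return np.asarray(stack.values).max(axis=2)


# ---------------------------------------------------------------------------
# dynamic-programming boundary search
# ---------------------------------------------------------------------------

def _column_normalize(g: np.ndarray) -> np.ndarray:
    """Scale each column to [0, 1]; constant columns map to 0."""
    lo = g.min(axis=0, keepdims=True)
    hi = g.max(axis=0, keepdims=True)
    rng = hi - lo
    out = np.zeros_like(g, dtype=float)
    np.divide(g - lo, rng, out=out, where=rng > 0)
    return out


def dp_min_path(node_weight: np.ndarray, jump_limit: int = JUMP_LIMIT,
                eps: float = EDGE_EPSILON,
                allowed: np.ndarray | None = None) -> tuple[np.ndarray, float]:
    """Exact minimal-cost left-to-right monotone-column path.

    One node per pixel; directed edges from each pixel to pixels in the next
    column within ``±jump_limit`` rows; edge cost ``2 − (w(a)+w(b)) + eps``
    where ``w`` is the node weight (normalized gradient).  Virtual zero-cost
    start/end columns leave the endpoints free, so the total cost is the sum
    over the ``ncols − 1`` internal edges.

    Parameters
    ----------
    allowed
        Optional boolean mask of permitted nodes (used to force the bottom
        boundary below the top one).

    Returns
    -------
    (rows, cost) : row index per column, and the exact minimal path cost.
    """
    w = np.asarray(node_weight, dtype=float)
    nrows, ncols = w.shape
    if ncols < 3:
        raise ValueError("need at least 3 columns")
    big = np.inf
    node_ok = np.ones_like(w, dtype=bool) if allowed is None else np.asarray(allowed, bool)
    if not node_ok.any(axis=0).all():
        raise ValueError("some column has no allowed rows")

    dist = np.where(node_ok[:, 0], 0.0, big)
    prev = np.full((nrows, ncols), -1, dtype=np.int32)
    shifts = range(-jump_limit, jump_limit + 1)
    for j in range(1, ncols):
        # candidate predecessor total including the predecessor's weight term
        base = dist - w[:, j - 1]
        cand = np.full((len(shifts), nrows), big)
        for i, s in enumerate(shifts):
            # predecessor at row r+s feeds row r
            if s >= 0:
                cand[i, : nrows - s] = base[s:]
            else:
                cand[i, -s:] = base[: nrows + s]
        best = np.argmin(cand, axis=0)
        dist_new = cand[best, np.arange(nrows)] + 2.0 + eps - w[:, j]
        dist_new[~node_ok[:, j]] = big
        prev[:, j] = np.arange(nrows) + np.array(list(shifts))[best]
        dist = dist_new
    end = int(np.argmin(dist))
    if not np.isfinite(dist[end]):
        raise ValueError("no feasible path")
    rows = np.empty(ncols, dtype=int)
    rows[-1] = end
    for j in range(ncols - 1, 0, -1):
        rows[j - 1] = prev[rows[j], j]
    return rows, float(dist[end])


def brute_force_min_path(node_weight: np.ndarray, jump_limit: int = JUMP_LIMIT,
                         eps: float = EDGE_EPSILON) -> tuple[np.ndarray, float]:
    """Exhaustive enumeration of all monotone-column paths (oracle; tiny images)."""
    from itertools import product

    w = np.asarray(node_weight, dtype=float)
    nrows, ncols = w.shape
    best_cost, best_path = np.inf, None
    for start in range(nrows):
        for moves in product(range(-jump_limit, jump_limit + 1), repeat=ncols - 1):
            rows = [start]
            ok = True
            for m in moves:
                r = rows[-1] + m
                if not 0 <= r < nrows:
                    ok = False
                    break
                rows.append(r)
            if not ok:
                continue
            cost = sum(2.0 + eps - w[rows[j], j] - w[rows[j + 1], j + 1]
                       for j in range(ncols - 1))
            if cost < best_cost:
                best_cost, best_path = cost, rows
    return np.asarray(best_path), float(best_cost)


def segment_epidermis_2d(image: np.ndarray, jump_limit: int = JUMP_LIMIT,
                         min_separation: int = MIN_SEPARATION,
                         eps: float = EDGE_EPSILON, stack_label: str = "",
                         ) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Segment the epidermis top and bottom boundaries in a (depth, fast) MIP.

    The top boundary follows the dark→bright vertical gradient, the bottom the
    bright→dark gradient, each as an exact shortest path; the bottom search is
    restricted to ``min_separation`` rows below the found top path.

    Returns (top rows, bottom rows, top cost, bottom cost).
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2 or img.shape[1] < 3:
        raise ValueError("need a 2D image with at least 3 columns")
    # backward difference: the dark→bright peak sits on the first bright row and
    # the bright→dark peak on the first dark row, so the epidermis is exactly
    # the half-open row interval [top, bottom)
    grad = np.diff(img, axis=0, prepend=img[:1])
    g_top = _column_normalize(grad)
    g_bot = _column_normalize(-grad)

    top, cost_top = dp_min_path(g_top, jump_limit=jump_limit, eps=eps)
    rows = np.arange(img.shape[0])[:, None]
    allowed = rows >= (top[None, :] + min_separation)
    try:
        bottom, cost_bot = dp_min_path(g_bot, jump_limit=jump_limit, eps=eps,
                                       allowed=allowed)
    except ValueError as exc:
        raise ValueError(
            f"no feasible epidermis bottom boundary below the top boundary"
            f"{' in stack ' + stack_label if stack_label else ''}"
        ) from exc
    return top, bottom, cost_top, cost_bot


# ---------------------------------------------------------------------------
# merged boundaries and layer biomarkers
# ---------------------------------------------------------------------------

@dataclass
class LayerBoundaries:
    """Per-stack epidermis top/bottom boundary curves (µm depth vs fast axis).

    ``top_um``/``bottom_um`` have shape (4, n_fast); ``stack_ranges`` are the
    half-open slow-index spans of the four 0.5 mm stacks.
    """

    top_um: np.ndarray
    bottom_um: np.ndarray
    stack_ranges: list[tuple[int, int]]
    spacing_um: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.top_um = np.atleast_2d(np.asarray(self.top_um, dtype=float))
        self.bottom_um = np.atleast_2d(np.asarray(self.bottom_um, dtype=float))
        if self.top_um.shape != self.bottom_um.shape:
            raise ValueError("top/bottom shapes differ")
        if np.any(self.bottom_um < self.top_um):
            raise ValueError("bottom boundary above top boundary")

    def top_index(self) -> np.ndarray:
        return np.round(self.top_um / self.spacing_um[0]).astype(int)

    def bottom_index(self) -> np.ndarray:
        return np.round(self.bottom_um / self.spacing_um[0]).astype(int)


def smooth_boundaries(pairs: list[tuple[np.ndarray, np.ndarray]],
                      grid: VolumeGrid,
                      window: int = SMOOTH_WINDOW) -> LayerBoundaries:
    """Moving-average smoothing of the four stack boundary pairs along the
    fast axis, re-enforcing bottom ≥ top afterwards."""
    if len(pairs) != N_STACKS:
        raise ValueError(f"expected {N_STACKS} boundary pairs, got {len(pairs)}")
    dz = grid.spacing_um[0]
    tops, bottoms = [], []
    for top, bottom in pairs:
        t = ndimage.uniform_filter1d(np.asarray(top, float), size=window, mode="nearest")
        b = ndimage.uniform_filter1d(np.asarray(bottom, float), size=window, mode="nearest")
        b = np.maximum(b, t)  # clamp: smoothing must not cross the boundaries
        tops.append(t * dz)
        bottoms.append(b * dz)
    return LayerBoundaries(
        top_um=np.stack(tops), bottom_um=np.stack(bottoms),
        stack_ranges=stack_slices(grid.shape[2]),
        spacing_um=grid.spacing_um,
    )


def segment_epidermis(grid: VolumeGrid, jump_limit: int = JUMP_LIMIT,
                      min_separation: int = MIN_SEPARATION,
                      smooth_window: int = SMOOTH_WINDOW) -> LayerBoundaries:
    """Full stack-wise epidermis segmentation of a (flattened) low-band volume."""
    pairs = []
    for k, stack in enumerate(split_stacks(grid)):
        mip = stack_mip(stack)
        top, bottom, _, _ = segment_epidermis_2d(
            mip, jump_limit=jump_limit, min_separation=min_separation,
            stack_label=str(k + 1),
        )
        pairs.append((top, bottom))
    return smooth_boundaries(pairs, grid, window=smooth_window)


def ep_thickness(boundaries: LayerBoundaries) -> float:
    """Epidermal thickness (µm): the mean over the four stacks of the mean
    per-column boundary separation."""
    per_stack = (boundaries.bottom_um - boundaries.top_um).mean(axis=1)
    return float(per_stack.mean())


def _ep_mask(grid: VolumeGrid, boundaries: LayerBoundaries) -> np.ndarray:
    nz = grid.shape[0]
    rows = np.arange(nz)[:, None, None]
    mask = np.zeros(grid.shape, dtype=bool)
    top_idx = boundaries.top_index()
    bot_idx = boundaries.bottom_index()
    for k, (s0, s1) in enumerate(boundaries.stack_ranges):
        sub = (rows >= top_idx[k][None, :, None]) & (rows < bot_idx[k][None, :, None])
        mask[:, :, s0:s1] = np.broadcast_to(sub, (nz, grid.shape[1], s1 - s0))
    return mask


def ep_signal_density(grid: VolumeGrid, boundaries: LayerBoundaries) -> float:
    """Mean intensity per voxel inside the segmented epidermis: the summed
    epidermis intensity divided by the epidermis voxel count over the full
    scanning region."""
    mask = _ep_mask(grid, boundaries)
    n = int(mask.sum())
    if n == 0:
        raise ValueError("empty epidermis region")
    return float(np.asarray(grid.values, dtype=float)[mask].sum() / n)


@dataclass
class DermisSlab:
    """Per-lateral-position dermis depth interval [EP bottom, EP bottom + 1.5 mm)."""

    start_index: np.ndarray   # (fast, slow) first dermis depth index
    stop_index: np.ndarray    # exclusive
    spacing_um: tuple[float, float, float]

    def mask(self, shape: tuple[int, int, int]) -> np.ndarray:
        rows = np.arange(shape[0])[:, None, None]
        return (rows >= self.start_index[None]) & (rows < self.stop_index[None])

    def n_voxels(self) -> int:
        return int((self.stop_index - self.start_index).sum())


def dermis_mask(boundaries: LayerBoundaries, grid: VolumeGrid) -> DermisSlab:
    """Dermis slab starting at the epidermis bottom and extending 1.5 mm deep,
    clipped (with a warning) where the grid is shallower."""
    nz, nf, ns = grid.shape
    dz = grid.spacing_um[0]
    n_depth = int(round(DERMIS_DEPTH_UM / dz))
    start = np.zeros((nf, ns), dtype=int)
    for k, (s0, s1) in enumerate(boundaries.stack_ranges):
        start[:, s0:s1] = boundaries.bottom_index()[k][:, None]
    stop = start + n_depth
    if np.any(stop > nz):
        warnings.warn(
            f"grid depth ({nz * dz / 1000:.2f} mm) clips the 1.5 mm dermis slab"
        )
        stop = np.minimum(stop, nz)
    start = np.minimum(start, stop)
    return DermisSlab(start_index=start, stop_index=stop, spacing_um=grid.spacing_um)


def boundaries_to_frame(boundaries: LayerBoundaries):
    """Boundary export: one row per (stack, fast column) with depths in µm."""
    import pandas as pd

    n_stacks, nf = boundaries.top_um.shape
    stack = np.repeat(np.arange(1, n_stacks + 1), nf)
    col = np.tile(np.arange(nf), n_stacks)
    return pd.DataFrame({
        "stack": stack, "column": col,
        "top_um": boundaries.top_um.ravel(),
        "bottom_um": boundaries.bottom_um.ravel(),
    })
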