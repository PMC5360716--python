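"""Density volumes on regular cubic grids and the preprocessing pipeline.

A :class:`DensityMap` is a scalar field sampled at the centers of the voxels
of an axis-aligned cubic grid (equal spacing along all three axes).  Before
fitting, experimental maps are prepared in four steps:

1. **threshold-shift** — clip at a user-supplied density threshold
   ``rho_min`` and shift so the background is exactly zero,
2. **autocrop** — remove bordering layers that contain only zero voxels,
3. **downsample** — block-mean decimation so the voxel spacing is comparable
   to the blur bandwidth (about ``2 * sigma``), which keeps voxel errors
   approximately independent,
4. **mask** — restrict the likelihood to voxels likely to carry signal.

Each step reduces the number of voxels that enter the likelihood, which is
essential for a realistic estimate of the map precision: zero-density border
voxels inflate the apparent precision without adding information.

Conventions: the values array is indexed ``[i, j, k]`` with x fastest
(axis 0 = x); the world position of voxel ``(i, j, k)`` is
``origin + spacing * (i, j, k)``; grids are 0-based and ``origin`` is the
center of the first voxel.
"""

from __future__ import annotations

import dataclasses
import os

import numpy as np

import gemmi

__all__ = [
    "DensityMap",
    "read_map",
    "write_map",
    "threshold_shift",
    "autocrop",
    "downsample",
    "build_mask",
    "preprocess",
]

#: Relative tolerance for accepting a voxel size as cubic.
CUBIC_TOLERANCE = 1e-3


@dataclasses.dataclass
class DensityMap:
    """Scalar density on a regular cubic grid.

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
        Density value at each voxel center (arbitrary density units).
    origin : ndarray, shape (3,)
        World position (Å) of the center of voxel (0, 0, 0).
    spacing : float
        Voxel edge length (Å), identical along all three axes.
    mask : ndarray of bool, shape (nx, ny, nz), optional
        Signal indicator per voxel; all-ones unless :func:`build_mask` has
        been applied.
    """

    values: np.ndarray
    origin: np.ndarray
    spacing: float
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError("values must be a 3-D array")
        self.origin = np.asarray(self.origin, dtype=np.float64).reshape(3)
        self.spacing = float(self.spacing)
        if not self.spacing > 0:
            raise ValueError("spacing must be positive")
        if self.mask is None:
            self.mask = np.ones(self.values.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.values.shape:
                raise ValueError("mask shape must match values shape")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def n_voxels(self) -> int:
        """Total voxel count N."""
        return int(self.values.size)

    @property
    def n_signal(self) -> int:
        """Number of masked-in (signal) voxels N1."""
        return int(self.mask.sum())

    def voxel_centers(self) -> np.ndarray:
        """World coordinates of all voxel centers, shape (nx, ny, nz, 3)."""
        nx, ny, nz = self.shape
        grid = np.stack(
            np.meshgrid(
                np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
            ),
            axis=-1,
        )
        return self.origin + self.spacing * grid

    def box_corners(self) -> tuple[np.ndarray, np.ndarray]:
        """Lower-left and upper-right corner of the grid bounding box (Å).

        The lower corner is the origin (center of the first voxel) and the
        upper corner the center of the last voxel, matching the box used by
        the soft confinement prior.
        """
        lower = self.origin.copy()
        upper = self.origin + self.spacing * (np.array(self.shape) - 1)
        return lower, upper

    def copy(self) -> "DensityMap":
        return DensityMap(
            self.values.copy(), self.origin.copy(), self.spacing, self.mask.copy()
        )


def read_map(path: str | os.PathLike) -> DensityMap:
    """Read an MRC/CCP4 volume into a :class:`DensityMap`.

    The grid is normalized to x-fastest axis order regardless of the axis
    permutation stored in the file header.  The origin is taken from the
    MRC2014 ORIGIN record when set, otherwise from the start-index words
    times the voxel size.

    Raises
    ------
    ValueError
        If the voxel sizes along the three axes differ by more than 0.1%.
    """
    m = gemmi.read_ccp4_map(str(path))
    m.setup(float("nan"))  # reorder axes to x-fastest, fill missing with NaN
    values = np.array(m.grid, copy=True).astype(np.float64)
    cell = m.grid.unit_cell
    nx, ny, nz = values.shape
    spac = np.array([cell.a / nx, cell.b / ny, cell.c / nz])
    mean_spacing = float(spac.mean())
    if np.any(np.abs(spac - mean_spacing) > CUBIC_TOLERANCE * mean_spacing):
        raise ValueError(
            f"anisotropic voxel sizes {tuple(spac)} (tolerance 0.1%); "
            "only cubic-voxel maps are supported"
        )
    origin = np.array([m.header_float(w) for w in (50, 51, 52)], dtype=np.float64)
    if np.all(origin == 0.0):
        # fall back to the CCP4 start-index convention
        start = np.array([m.header_i32(w) for w in (5, 6, 7)], dtype=np.float64)
        origin = start * mean_spacing
    return DensityMap(values, origin, mean_spacing)


def write_map(dmap: DensityMap, path: str | os.PathLike) -> None:
    """Write a :class:`DensityMap` as a mode-2 (float32) MRC/CCP4 volume.

    Values are stored in float32; reading the file back reproduces
    ``dmap.values.astype(float32)`` bit-exactly.  The mask is not stored.
    """
    m = gemmi.Ccp4Map()
    m.grid = gemmi.FloatGrid(np.ascontiguousarray(dmap.values, dtype=np.float32))
    nx, ny, nz = dmap.shape
    s = dmap.spacing
    m.grid.unit_cell = gemmi.UnitCell(nx * s, ny * s, nz * s, 90.0, 90.0, 90.0)
    m.grid.spacegroup = gemmi.find_spacegroup_by_name("P1")
    m.update_ccp4_header()
    for w, v in zip((50, 51, 52), dmap.origin):
        m.set_header_float(w, float(v))
    m.write_ccp4_map(str(path))


def threshold_shift(dmap: DensityMap, rho_min: float) -> DensityMap:
    """Clip the density at ``rho_min`` and shift the background to zero.

    Every voxel with density at or above the threshold is shifted down by
    ``rho_min``; voxels below the threshold are set to zero::

        rho_n <- rho_n - rho_min   if rho_n >= rho_min
                 0                 otherwise

    so the minimum of the output is exactly 0.
    """
    rho_min = float(rho_min)
    if not np.isfinite(rho_min):
        raise ValueError("rho_min must be finite")
    out = np.where(dmap.values >= rho_min, dmap.values - rho_min, 0.0)
    return DensityMap(out, dmap.origin.copy(), dmap.spacing, dmap.mask.copy())


def autocrop(dmap: DensityMap) -> DensityMap:
    """Crop away bordering layers that contain only zero-density voxels.

    Returns the minimal axis-aligned subgrid containing every strictly
    positive voxel.  The origin is updated so world coordinates of retained
    voxel centers are unchanged.  The input must already be
    threshold-shifted (all values >= 0).

    Raises
    ------
    ValueError
        If the map contains no positive voxel (nothing to fit).
    """
    positive = dmap.values > 0
    if not positive.any():
        raise ValueError("map has no positive density; nothing to crop to")
    lo = np.empty(3, dtype=int)
    hi = np.empty(3, dtype=int)
    for axis in range(3):
        proj = positive.any(axis=tuple(a for a in range(3) if a != axis))
        idx = np.nonzero(proj)[0]
        lo[axis], hi[axis] = idx[0], idx[-1] + 1
    sl = tuple(slice(l, h) for l, h in zip(lo, hi))
    return DensityMap(
        dmap.values[sl].copy(),
        dmap.origin + dmap.spacing * lo,
        dmap.spacing,
        dmap.mask[sl].copy(),
    )


def downsample(dmap: DensityMap, target_spacing: float) -> DensityMap:
    """Decimate the grid by block averaging to reach ``target_spacing``.

    The decimation factor is the smallest integer ``k`` with
    ``k * spacing >= target_spacing``; each output voxel is the mean of its
    ``k**3`` source block (edge blocks are averaged over the voxels that
    exist).  The output grid is regular: its origin is placed at the center
    of the first full block, ``origin + spacing * (k - 1) / 2``, and its
    spacing is ``k * spacing``.

    Raises
    ------
    ValueError
        If ``target_spacing`` is smaller than the current spacing.
    """
    target_spacing = float(target_spacing)
    if target_spacing < dmap.spacing:
        raise ValueError(
            f"target spacing {target_spacing} is finer than current "
            f"spacing {dmap.spacing}"
        )
    k = int(np.ceil(target_spacing / dmap.spacing - 1e-12))
    if k == 1:
        return dmap.copy()

    def block_reduce(a: np.ndarray) -> np.ndarray:
        # mean over k-blocks along each axis, edge blocks over what exists
        for axis in range(3):
            n = a.shape[axis]
            edges = np.arange(0, n, k)
            sums = np.add.reduceat(a, edges, axis=axis)
            counts = np.diff(np.append(edges, n))
            shape = [1, 1, 1]
            shape[axis] = len(counts)
            a = sums / counts.reshape(shape)
        return a

    values = block_reduce(dmap.values)
    new_origin = dmap.origin + dmap.spacing * (k - 1) / 2.0
    return DensityMap(values, new_origin, dmap.spacing * k)


def build_mask(dmap: DensityMap, mask_level: float = 0.0) -> DensityMap:
    """Mark voxels with density above ``mask_level`` as signal.

    The values are unchanged; only the binary mask is set.  Masked-out
    voxels are excluded from the likelihood sum, the map restraint energy
    and the cross-correlation, preventing low-density background voxels
    from inflating the estimated precision.

    Raises
    ------
    ValueError
        If no voxel survives (empty mask).
    """
    mask = dmap.values > float(mask_level)
    if not mask.any():
        raise ValueError("mask level excludes every voxel")
    return DensityMap(dmap.values.copy(), dmap.origin.copy(), dmap.spacing, mask)


def preprocess(
    dmap: DensityMap,
    rho_min: float,
    spacing_factor: float | None = None,
    sigma: float | None = None,
    mask_level: float = 0.0,
) -> tuple[DensityMap, dict]:
    """Full preparation pipeline: threshold -> crop -> downsample -> mask.

    Downsampling targets ``spacing_factor * sigma`` (the conventional choice
    is a spacing of roughly twice the blur bandwidth) and is skipped when
    ``sigma`` is not given or the target does not exceed the current
    spacing.  Masking is applied last.  Returns the prepared map and a
    report dict with voxel counts and the crop box.
    """
    report: dict = {"n_input": dmap.n_voxels, "input_shape": dmap.shape}
    out = threshold_shift(dmap, rho_min)
    out = autocrop(out)
    report["crop_shape"] = out.shape
    report["n_cropped"] = out.n_voxels
    report["crop_fraction"] = out.n_voxels / dmap.n_voxels
    lower, upper = out.box_corners()
    report["crop_box_angstrom"] = tuple(
        float(x) for x in (upper - lower + out.spacing)
    )
    if sigma is not None and spacing_factor is not None:
        target = spacing_factor * sigma
        if target > out.spacing:
            out = downsample(out, target)
    report["spacing"] = out.spacing
    report["decimated_shape"] = out.shape
    out = build_mask(out, mask_level)
    report["n_voxels"] = out.n_voxels
    report["n_signal"] = out.n_signal
    return out, report
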