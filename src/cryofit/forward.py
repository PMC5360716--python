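"""Gaussian-kernel forward model: render a theoretical map from atoms.

Each atom contributes a spherical, normalized Gaussian of bandwidth
``sigma`` (equal size and weight for all atoms):

    rho(x) = sum_k (2 pi sigma^2)^(-3/2) exp(-|x - x_k|^2 / (2 sigma^2))

evaluated at voxel centers.  This is the map-blurring view of a density at
intermediate-to-low resolution: the rendered map equals an infinitely sharp
atomic map convolved with a Gaussian blur kernel.  Atom-wise weights,
scattering factors and temperature factors are intentionally absent — the
model targets maps where a single bandwidth per map is adequate.

The bandwidth is conventionally tied to the nominal map resolution as
``sigma = 0.225 * resolution`` (the Chimera default).

For efficiency each atom's Gaussian is evaluated only inside a cube of
half-width ``cutoff * sigma`` voxels around the atom (default 5 sigma, where
the neglected tail is below 4e-6 of the peak); the kernel is separable, so
the local cube is built from three 1-D Gaussians.
"""

from __future__ import annotations

import numpy as np

from cryofit.maps import DensityMap

__all__ = ["default_bandwidth", "render_density", "render_gradient"]

#: Default kernel truncation radius in units of sigma.
DEFAULT_CUTOFF = 5.0


def default_bandwidth(resolution: float) -> float:
    """Blur bandwidth sigma (Å) for a map of the given nominal resolution.

    Uses the conventional proportionality ``sigma = 0.225 * resolution``.
    """
    resolution = float(resolution)
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    return 0.225 * resolution


def _atom_window(
    x: float, origin: float, spacing: float, n: int, radius: float
) -> tuple[int, int]:
    """Index range [lo, hi) of voxels within ``radius`` of coordinate x."""
    lo = int(np.ceil((x - radius - origin) / spacing))
    hi = int(np.floor((x + radius - origin) / spacing)) + 1
    return max(lo, 0), min(hi, n)


def render_density(
    coords: np.ndarray,
    grid: DensityMap,
    sigma: float,
    cutoff: float = DEFAULT_CUTOFF,
) -> np.ndarray:
    """Evaluate the Gaussian-mixture density at every voxel center.

    Parameters
    ----------
    coords : ndarray, shape (K, 3)
        Atom positions (Å).
    grid : DensityMap
        Supplies the grid geometry (shape, origin, spacing); its values are
        ignored.
    sigma : float
        Gaussian bandwidth (Å), > 0.
    cutoff : float
        Truncation radius in units of sigma.

    Returns
    -------
    ndarray with the grid's shape; all entries >= 0.
    """
    coords = np.asarray(coords, dtype=np.float64)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise ValueError("coords must have shape (K, 3)")
    sigma = float(sigma)
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    out = np.zeros(grid.shape, dtype=np.float64)
    norm = (2.0 * np.pi * sigma**2) ** -1.5
    radius = cutoff * sigma
    inv2s2 = 1.0 / (2.0 * sigma**2)
    for xk in coords:
        wins = [
            _atom_window(xk[a], grid.origin[a], grid.spacing, grid.shape[a], radius)
            for a in range(3)
        ]
        if any(lo >= hi for lo, hi in wins):
            continue
        g1d = []
        for a, (lo, hi) in enumerate(wins):
            pos = grid.origin[a] + grid.spacing * np.arange(lo, hi)
            g1d.append(np.exp(-inv2s2 * (pos - xk[a]) ** 2))
        block = norm * g1d[0][:, None, None] * g1d[1][None, :, None] * g1d[2][None, None, :]
        out[wins[0][0]:wins[0][1], wins[1][0]:wins[1][1], wins[2][0]:wins[2][1]] += block
    return out


def render_gradient(
    coords: np.ndarray,
    grid: DensityMap,
    sigma: float,
    voxel_weights: np.ndarray,
    cutoff: float = DEFAULT_CUTOFF,
) -> np.ndarray:
    """Gradient of ``sum_n w_n * rho(x_n)`` with respect to atom positions.

    ``voxel_weights`` are the partial derivatives of a scalar objective with
    respect to the model density at each voxel (supplied by the likelihood);
    the returned array has shape (K, 3).  Uses the same kernel truncation as
    :func:`render_density`.
    """
    coords = np.asarray(coords, dtype=np.float64)
    weights = np.asarray(voxel_weights, dtype=np.float64)
    if weights.shape != grid.shape:
        raise ValueError("voxel_weights shape must match the grid")
    sigma = float(sigma)
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    grad = np.zeros_like(coords)
    norm = (2.0 * np.pi * sigma**2) ** -1.5
    radius = cutoff * sigma
    inv2s2 = 1.0 / (2.0 * sigma**2)
    inv_s2 = 1.0 / sigma**2
    for k, xk in enumerate(coords):
        wins = [
            _atom_window(xk[a], grid.origin[a], grid.spacing, grid.shape[a], radius)
            for a in range(3)
        ]
        if any(lo >= hi for lo, hi in wins):
            continue
        g1d, d1d = [], []
        for a, (lo, hi) in enumerate(wins):
            pos = grid.origin[a] + grid.spacing * np.arange(lo, hi)
            dx = pos - xk[a]
            g1d.append(np.exp(-inv2s2 * dx**2))
            d1d.append(dx)
        w = weights[wins[0][0]:wins[0][1], wins[1][0]:wins[1][1], wins[2][0]:wins[2][1]]
        block = norm * g1d[0][:, None, None] * g1d[1][None, :, None] * g1d[2][None, None, :]
        wp = w * block
        # d rho / d x_k = rho_nk * (x_n - x_k) / sigma^2
        grad[k, 0] = inv_s2 * np.einsum("ijk,i->", wp, d1d[0])
        grad[k, 1] = inv_s2 * np.einsum("ijk,j->", wp, d1d[1])
        grad[k, 2] = inv_s2 * np.einsum("ijk,k->", wp, d1d[2])
    return grad
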