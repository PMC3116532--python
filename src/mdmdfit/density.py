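"""Density maps: synthesis from coordinates, cross-correlation, MRC/CCP4 I/O.

The simulated density places a Gaussian g(r) = exp[-(3 / (2 sigma^2)) *
|r - r_n|^2] on every atom n and integrates it over each voxel.  Because
the kernel is separable the voxel integral is computed exactly as a
product of one-dimensional Gaussian-integral (erf) differences, not by
sampling the voxel center.  An atom contributes only to voxels whose
centers lie within ``cutoff_radius`` (default 2 sigma) of the atom; the
2-sigma truncation approximates the nominal map resolution.

Grid convention (used everywhere): voxel values are indexed ``[i, j, k]``
along x, y, z; the Cartesian center of voxel (i, j, k) is
``origin + (i + 1/2, j + 1/2, k + 1/2) * spacing``.

The cross-correlation is the unnormalized cosine similarity

    CC = sum(rho_a * rho_b) / sqrt(sum(rho_a^2) * sum(rho_b^2))

with no mean subtraction, so for non-negative maps CC is in [0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import map_coordinates
from scipy.special import erf

import gemmi

from .model_io import Structure


class GridMismatchError(ValueError):
    """Grids differ in origin, spacing or shape; resample one map first."""


@dataclass
class DensityMap:
    """3-D voxel grid of non-negative density values.

    Attributes
    ----------
    origin : (3,) array, Angstrom — Cartesian position of the grid corner
        (the corner of voxel (0,0,0), not its center).
    spacing : (3,) array, Angstrom — voxel edge lengths.  Maps synthesized
        by this package are isotropic; anisotropic files are accepted on
        read and carried through.
    values : (nx, ny, nz) array — voxel densities, all >= 0.
    """

    origin: np.ndarray
    spacing: np.ndarray
    values: np.ndarray
    annotation: dict = field(default_factory=dict)

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=np.float64).reshape(3)
        spacing = np.asarray(self.spacing, dtype=np.float64).reshape(-1)
        if spacing.size == 1:
            spacing = np.repeat(spacing, 3)
        self.spacing = spacing.reshape(3)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3 or min(self.values.shape) < 1:
            raise ValueError("values must be a 3-D array with shape >= 1 per axis")
        if np.any(self.spacing <= 0):
            raise ValueError("spacing must be positive")
        if np.any(self.values < 0):
            raise ValueError("density values must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def is_isotropic(self) -> bool:
        return bool(np.allclose(self.spacing, self.spacing[0]))

    def geometry(self) -> "DensityMap":
        """Same grid geometry with zeroed values (a synthesis template)."""
        return DensityMap(self.origin.copy(), self.spacing.copy(),
                          np.zeros(self.shape))

    def voxel_centers_1d(self, axis: int) -> np.ndarray:
        n = self.shape[axis]
        return self.origin[axis] + (np.arange(n) + 0.5) * self.spacing[axis]

    def same_geometry(self, other: "DensityMap", tol: float = 1e-6) -> bool:
        return (self.shape == other.shape
                and np.allclose(self.origin, other.origin, atol=tol)
                and np.allclose(self.spacing, other.spacing, atol=tol))

    def total_mass(self) -> float:
        return float(self.values.sum())


@dataclass
class KernelParams:
    """Per-atom Gaussian kernel: width sigma (A) and truncation radius (A).

    ``cutoff_radius`` defaults to 2 sigma.  With the resolution convention
    sigma = resolution / 2 the truncation sphere has diameter equal to the
    nominal resolution.
    """

    sigma: float
    cutoff_radius: float | None = None

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.cutoff_radius is None:
            self.cutoff_radius = 2.0 * self.sigma
        if self.cutoff_radius <= 0:
            raise ValueError("cutoff_radius must be positive")

    @classmethod
    def from_resolution(cls, resolution: float,
                        cutoff_radius: float | None = None) -> "KernelParams":
        """sigma = resolution / 2, so the 2-sigma cutoff equals the resolution."""
        if resolution <= 0:
            raise ValueError("resolution must be positive")
        return cls(sigma=resolution / 2.0, cutoff_radius=cutoff_radius)

    @property
    def alpha(self) -> float:
        """Gaussian exponent coefficient: g(r) = exp(-alpha r^2)."""
        return 3.0 / (2.0 * self.sigma ** 2)


def default_grid(structure: Structure, kernel: KernelParams,
                 spacing: float | None = None,
                 pad: float | None = None) -> DensityMap:
    """Grid template: structure bounding box padded by the cutoff radius.

    Default spacing is ``(2 * kernel.cutoff_radius) / 6`` = resolution/3
    under the sigma = resolution/2 convention.
    """
    if spacing is None:
        spacing = 2.0 * kernel.cutoff_radius / 6.0
    if pad is None:
        pad = kernel.cutoff_radius
    lo = structure.coords.min(axis=0) - pad
    hi = structure.coords.max(axis=0) + pad
    shape = np.maximum(np.ceil((hi - lo) / spacing).astype(int), 1)
    return DensityMap(lo, np.repeat(spacing, 3), np.zeros(tuple(shape)))


def simulate_density(structure: Structure, grid: DensityMap,
                     kernel: KernelParams) -> DensityMap:
    """Synthesize a density map from atomic coordinates.

    Each voxel receives the exact integral of every atom's truncated
    Gaussian over the voxel volume (separable erf products); atoms
    contribute only to voxels whose centers are within the cutoff sphere.
    """
    if not grid.is_isotropic and not grid.annotation.get("allow_anisotropic"):
        raise ValueError(
            "simulate_density requires an isotropic grid "
            "(set annotation['allow_anisotropic'] to override)")
    out = np.zeros(grid.shape)
    xyz = structure.coords
    if len(xyz) == 0:
        return DensityMap(grid.origin.copy(), grid.spacing.copy(), out)
    lo_ok = np.all(xyz + kernel.cutoff_radius >= grid.origin, axis=1)
    hi = grid.origin + np.array(grid.shape) * grid.spacing
    hi_ok = np.all(xyz - kernel.cutoff_radius <= hi, axis=1)
    inside = lo_ok & hi_ok
    if not np.any(inside):
        warnings.warn("structure lies entirely outside the grid; map is zero")
        return DensityMap(grid.origin.copy(), grid.spacing.copy(), out)
    xyz = xyz[inside]

    s = grid.spacing
    c = kernel.cutoff_radius
    sqrt_a = np.sqrt(kernel.alpha)
    norm = np.sqrt(np.pi) / (2.0 * sqrt_a)  # per-axis integral prefactor
    nx, ny, nz = grid.shape
    # fixed-size index box around each atom covering the cutoff sphere
    nb = [int(np.ceil(2 * c / s[d])) + 2 for d in range(3)]

    axes = []   # per-axis: (indices (N,nb), weights (N,nb), center offsets)
    for d in range(3):
        rel = (xyz[:, d] - grid.origin[d]) / s[d]          # in voxel units
        i0 = np.floor(rel - c / s[d] - 0.5).astype(int)
        idx = i0[:, None] + np.arange(nb[d])[None, :]       # (N, nb)
        lo_edge = grid.origin[d] + idx * s[d]
        w = norm * (erf(sqrt_a * (lo_edge + s[d] - xyz[:, [d]]))
                    - erf(sqrt_a * (lo_edge - xyz[:, [d]])))
        centers = lo_edge + 0.5 * s[d]
        off = centers - xyz[:, [d]]
        valid = (idx >= 0) & (idx < grid.shape[d])
        w = np.where(valid, w, 0.0)
        idx = np.clip(idx, 0, grid.shape[d] - 1)
        axes.append((idx, w, off))

    (ix, wx, ox), (iy, wy, oy), (iz, wz, oz) = axes
    vals = (wx[:, :, None, None] * wy[:, None, :, None] * wz[:, None, None, :])
    dist2 = (ox[:, :, None, None] ** 2 + oy[:, None, :, None] ** 2
             + oz[:, None, None, :] ** 2)
    vals = np.where(dist2 <= c * c, vals, 0.0)
    flat_idx = (ix[:, :, None, None] * (ny * nz)
                + iy[:, None, :, None] * nz
                + iz[:, None, None, :])
    out = np.bincount(flat_idx.ravel(), weights=vals.ravel(),
                      minlength=nx * ny * nz).reshape(nx, ny, nz)
    return DensityMap(grid.origin.copy(), grid.spacing.copy(), out)


def cross_correlation(map_a: DensityMap, map_b: DensityMap,
                      mean_subtract: bool = False) -> float:
    """Cross-correlation coefficient between two maps on a common grid.

    CC = sum(a*b) / sqrt(sum(a^2) sum(b^2)); in [0, 1] for non-negative
    maps (1 iff the maps are proportional, Cauchy-Schwarz).  With
    ``mean_subtract=True`` the voxel means are removed first (a Pearson
    coefficient, in [-1, 1]); the plain cosine form is the default.
    """
    if not map_a.same_geometry(map_b):
        raise GridMismatchError(
            "maps are on different grids (origin/spacing/shape); "
            "use resample() to bring one onto the other's geometry")
    a, b = map_a.values, map_b.values
    if mean_subtract:
        a = a - a.mean()
        b = b - b.mean()
    na, nb = float(np.sum(a * a)), float(np.sum(b * b))
    if na == 0.0 or nb == 0.0:
        raise ValueError("cross-correlation undefined for an all-zero map")
    return float(np.sum(a * b) / np.sqrt(na * nb))


def resample(source: DensityMap, target: DensityMap) -> DensityMap:
    """Trilinear resampling of ``source`` onto ``target``'s grid geometry.

    Points outside the source extent evaluate to 0; the result is clipped
    at 0 so interpolation cannot introduce negative density.
    """
    if source.same_geometry(target):
        return DensityMap(source.origin.copy(), source.spacing.copy(),
                          source.values.copy())
    coords = np.meshgrid(*(target.voxel_centers_1d(d) for d in range(3)),
                         indexing="ij")
    # fractional voxel-index coordinates into the source grid
    frac = [(coords[d] - source.origin[d]) / source.spacing[d] - 0.5
            for d in range(3)]
    vals = map_coordinates(source.values, np.stack(frac), order=1,
                           mode="constant", cval=0.0)
    return DensityMap(target.origin.copy(), target.spacing.copy(),
                      np.clip(vals, 0.0, None))


# ---------------------------------------------------------------------------
# MRC / CCP4 I/O (gemmi behind the scenes)
# ---------------------------------------------------------------------------

def write_map(density: DensityMap, dest) -> None:
    """Write a DensityMap as a CCP4/MRC 2014 mode-2 (float32) file."""
    nx, ny, nz = density.shape
    grid = gemmi.FloatGrid(nx, ny, nz)
    cell = gemmi.UnitCell(nx * density.spacing[0], ny * density.spacing[1],
                          nz * density.spacing[2], 90.0, 90.0, 90.0)
    grid.set_unit_cell(cell)
    np.asarray(grid)[:] = density.values.astype(np.float32)
    ccp4 = gemmi.Ccp4Map()
    ccp4.grid = grid
    ccp4.update_ccp4_header()
    for word, val in zip((50, 51, 52), density.origin):
        ccp4.set_header_float(word, float(val))
    ccp4.write_ccp4_map(str(dest))


def read_map(source) -> DensityMap:
    """Read an MRC/CCP4 map, normalizing axis order to x-fastest-index.

    The ORIGIN header (MRC2014) is honored; if absent/zero, the start
    indices (NCSTART...) define the origin.  Negative values (possible in
    experimental maps) are clipped at 0 with a warning, preserving the
    non-negativity invariant.
    """
    path = str(source)
    if not Path(path).exists():
        raise FileNotFoundError(path)
    ccp4 = gemmi.read_ccp4_map(path)
    mode = ccp4.header_i32(4)
    if mode not in (0, 1, 2):
        raise ValueError(f"unsupported MRC mode {mode}; modes 0/1/2 supported")
    ccp4.setup(0.0)  # reorder axes to standard X, Y, Z
    values = np.array(ccp4.grid, dtype=np.float64)
    cell = ccp4.grid.unit_cell
    spacing = np.array([cell.a / values.shape[0], cell.b / values.shape[1],
                        cell.c / values.shape[2]])
    origin = np.array([ccp4.header_float(w) for w in (50, 51, 52)])
    if np.allclose(origin, 0.0):
        nstart = np.array([ccp4.header_i32(w) for w in (5, 6, 7)], dtype=float)
        origin = nstart * spacing
    if np.any(values < 0):
        warnings.warn("map contains negative values; clipping at 0")
        values = np.clip(values, 0.0, None)
    return DensityMap(origin, spacing, values)
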