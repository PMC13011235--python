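"""Binary pore-space geometries: container type, benchmark generators,
analytic references, voxel coarsening, sub-volume extraction and TIFF I/O.

Conventions
-----------
Masks are boolean arrays indexed ``[x, y]`` (2D) or ``[x, y, z]`` (3D) with
``True`` = solid.  On disk (8-bit TIFF/PNG) the convention is inverted to
match the imaging pipeline: 255 (white) = pore, 0 (black) = solid.  The
voxel edge length is stored in metres.

Voxelization uses a node-centre rule (a node is solid iff its centre lies
inside the solid), with node centres at half-integer positions
``(i + 0.5) * dx``; this matches the staircase wall treatment of half-way
bounce-back and produces first-order geometric convergence.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "DomainGeometry",
    "make_channel",
    "make_hexagonal_array",
    "make_fcc",
    "fcc_porosity_analytic",
    "gebart_reference",
    "gebart_touching_porosity",
    "poiseuille_reference",
    "poiseuille_umax",
    "coarsen",
    "extract_rev",
    "save_geometry",
    "load_geometry",
]


@dataclass
class DomainGeometry:
    """A binary solid/pore image with a physical voxel size.

    Parameters
    ----------
    solid : bool array, ``True`` where the voxel is solid.
    voxel_size : voxel edge length in metres (default 1.0 = lattice units).
    meta : free-form provenance (generator parameters, seed, ...).
    """

    solid: np.ndarray
    voxel_size: float = 1.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.solid = np.asarray(self.solid, dtype=bool)
        if self.solid.ndim not in (2, 3):
            raise ValueError("solid mask must be 2D or 3D")
        if not (~self.solid).any():
            raise ValueError("geometry has no fluid node")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")

    @property
    def dimension(self) -> int:
        return self.solid.ndim

    @property
    def shape(self) -> tuple:
        return self.solid.shape

    @property
    def porosity(self) -> float:
        return float((~self.solid).mean())


# ------------------------------------------------------------ benchmarks

def make_channel(nx: int, ny: int, nz: int | None = None) -> DomainGeometry:
    """Plane channel: one-node solid walls on the last axis, open along x.

    The fluid gap is ``ny - 2`` nodes wide; with half-way bounce-back the
    effective wall-to-wall width is ``H = ny - 2`` lattice units (walls sit
    half a link beyond the outermost fluid nodes).
    """
    if nx < 3 or ny < 3 or (nz is not None and nz < 3):
        raise ValueError("channel needs at least 3 nodes per axis")
    if nz is None:
        solid = np.zeros((nx, ny), dtype=bool)
        solid[:, 0] = solid[:, -1] = True
    else:
        solid = np.zeros((nx, ny, nz), dtype=bool)
        solid[:, :, 0] = solid[:, :, -1] = True
    return DomainGeometry(solid, meta={"kind": "channel"})


def make_hexagonal_array(nx: int = 440, ny: int = 254, R: float = 60.0) -> DomainGeometry:
    """Periodic hexagonal array of solid disks in a 2D cell.

    Quarter disks at the four corners plus a full disk at the centre; under
    full periodicity this tiles into the hexagonal packing.  The default
    cell 440 x 254 has the ~sqrt(3) aspect ratio of the hexagonal lattice.
    ``R`` is the disk *radius* in lattice units.
    """
    if R <= 0:
        raise ValueError("R must be positive")
    if 2 * R > min(nx, ny):
        raise ValueError("disks overlap inconsistently with the cell size")
    x = np.arange(nx)[:, None] + 0.5
    y = np.arange(ny)[None, :] + 0.5
    centers = [(0.0, 0.0), (nx, 0.0), (0.0, ny), (nx, ny), (nx / 2.0, ny / 2.0)]
    solid = np.zeros((nx, ny), dtype=bool)
    for cx, cy in centers:
        solid |= (x - cx) ** 2 + (y - cy) ** 2 < R ** 2
    return DomainGeometry(solid, meta={"kind": "hexagonal", "R": R})


def fcc_porosity_analytic() -> float:
    """Void fraction of the touching face-centred-cubic sphere packing.

    Spheres at the 8 corners and 6 face centres of a cube of side L touch
    along the half face diagonal, so D = L/sqrt(2) and the solid fraction
    is pi/(3*sqrt(2)) ~ 0.74048, i.e. porosity 0.25952.
    """
    return 1.0 - np.pi / (3.0 * np.sqrt(2.0))


def make_fcc(L: int) -> DomainGeometry:
    """Voxelized FCC unit cell of side ``L`` with touching spheres.

    Sphere radius sqrt(2)*L/4 (diameter D = L/sqrt(2)); centres at the cube
    corners and face centres; fully periodic.  A node is solid iff its
    centre (half-integer coordinates) lies inside a sphere, with periodic
    minimum-image distances.
    """
    if L < 16 or L % 2:
        raise ValueError("L must be an even integer >= 16")
    r = np.sqrt(2.0) * L / 4.0
    coords = np.arange(L) + 0.5
    x = coords[:, None, None]
    y = coords[None, :, None]
    z = coords[None, None, :]
    centers = [(0, 0, 0)]
    h = L / 2.0
    centers += [(h, h, 0), (h, 0, h), (0, h, h)]
    solid = np.zeros((L, L, L), dtype=bool)

    def _pdist2(a, c):
        d = np.abs(a - c)
        return np.minimum(d, L - d) ** 2

    for cx, cy, cz in centers:
        solid |= _pdist2(x, cx) + _pdist2(y, cy) + _pdist2(z, cz) < r ** 2
    return DomainGeometry(solid, meta={"kind": "fcc", "L": L, "D": 2 * r})


# ------------------------------------------------------ analytic references

def gebart_touching_porosity() -> float:
    """Porosity at which hexagonally packed disks touch, 1 - pi/(2*sqrt(3))."""
    return 1.0 - np.pi / (2.0 * np.sqrt(3.0))


def gebart_reference(phi: float) -> float:
    """Gebart's closed-form transverse permeability of a hexagonal fibre
    array, normalised by the fibre radius squared:

        k/R^2 = 16/(9*pi*sqrt(6)) * (sqrt(pi/(2*sqrt(3)*(1-phi))) - 1)^(5/2)

    Valid for porosities above the touching limit (~0.0931), where the
    bracket is non-negative.
    """
    bracket = np.sqrt(np.pi / (2.0 * np.sqrt(3.0) * (1.0 - phi))) - 1.0
    if np.any(bracket < 0):
        raise ValueError("porosity below the touching-disk limit")
    return 16.0 / (9.0 * np.pi * np.sqrt(6.0)) * bracket ** 2.5


def poiseuille_reference(x, umax: float, L: float):
    """Parabolic plane-Poiseuille profile u(x) = 4 umax x (L - x) / L^2."""
    x = np.asarray(x, dtype=np.float64)
    return 4.0 * umax * x * (L - x) / L ** 2


def poiseuille_umax(F: float, H: float, nu: float) -> float:
    """Centreline velocity of force-driven plane Poiseuille flow, F H^2/(8 nu)."""
    return F * H * H / (8.0 * nu)


# ------------------------------------------------------------- operations

def coarsen(geom: DomainGeometry, factor: int) -> DomainGeometry:
    """Block-coarsen by ``factor`` using the >50%-solid rule.

    Each coarse cell is solid iff strictly more than half of its fine
    voxels are solid (exact ties are fluid); the voxel size is multiplied
    by ``factor``.  Dimensions not divisible by ``factor`` are zero-padded
    with fluid.
    """
    if factor < 1 or int(factor) != factor:
        raise ValueError("factor must be a positive integer")
    solid = geom.solid
    pad = [(0, (-s) % factor) for s in solid.shape]
    if any(p[1] for p in pad):
        solid = np.pad(solid, pad, constant_values=False)
    shape = []
    for s in solid.shape:
        shape += [s // factor, factor]
    blocks = solid.reshape(shape)
    axes = tuple(range(1, 2 * solid.ndim, 2))
    frac = blocks.mean(axis=axes)
    coarse = frac > 0.5
    meta = dict(geom.meta, coarsened_by=factor)
    return DomainGeometry(coarse, voxel_size=geom.voxel_size * factor, meta=meta)


def extract_rev(geom: DomainGeometry, size: int | tuple) -> DomainGeometry:
    """Centred square/cubic crop of extent ``size`` along every axis.

    Nested crops share their centre, as in REV convergence studies that
    grow a subdomain outward from the sample centre.
    """
    if np.isscalar(size):
        size = (int(size),) * geom.dimension
    if len(size) != geom.dimension:
        raise ValueError("size rank does not match geometry dimension")
    slices = []
    for s, full in zip(size, geom.shape):
        if s > full or s < 1:
            raise ValueError(f"crop size {s} invalid for extent {full}")
        lo = (full - s) // 2
        slices.append(slice(lo, lo + s))
    return DomainGeometry(
        geom.solid[tuple(slices)], voxel_size=geom.voxel_size,
        meta=dict(geom.meta, rev_size=tuple(int(s) for s in size)),
    )


# -------------------------------------------------------------------- I/O

def save_geometry(geom: DomainGeometry, path) -> None:
    """Write an 8-bit TIFF (255 = pore, 0 = solid) plus a JSON sidecar.

    3D masks are written as a stack with the first axis as pages.
    """
    import tifffile

    path = Path(path)
    img = np.where(geom.solid, 0, 255).astype(np.uint8)
    tifffile.imwrite(path, img)
    sidecar = {
        "voxel_size_um": geom.voxel_size * 1e6,
        "shape": list(geom.shape),
        "meta": {k: _jsonable(v) for k, v in geom.meta.items()},
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def load_geometry(path, voxel_size: float | None = None) -> DomainGeometry:
    """Read a TIFF/PNG stack; intensity > 127 is pore, else solid.

    The voxel size is taken from the JSON sidecar when present (µm),
    unless overridden.
    """
    import tifffile

    path = Path(path)
    if path.suffix.lower() in (".png",):
        import imageio.v3 as iio

        img = np.asarray(iio.imread(path))
    else:
        img = tifffile.imread(path)
    if img.ndim > 3:
        img = img[..., 0]  # drop colour channel
    solid = img <= 127
    vs = voxel_size
    meta = {}
    sc = path.with_suffix(path.suffix + ".json")
    if sc.exists():
        info = json.loads(sc.read_text())
        meta = info.get("meta", {})
        if vs is None:
            vs = info.get("voxel_size_um", 1e6) * 1e-6
    return DomainGeometry(solid, voxel_size=1.0 if vs is None else vs, meta=meta)


def _jsonable(v):
    import dataclasses

    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return float(v)
    if isinstance(v, np.ndarray):
        return v.tolist()
    if dataclasses.is_dataclass(v) and not isinstance(v, type):
        return {k: _jsonable(x) for k, x in dataclasses.asdict(v).items()}
    if isinstance(v, dict):
        return {str(k): _jsonable(x) for k, x in v.items()}
    if isinstance(v, (list, tuple)):
        return [_jsonable(x) for x in v]
    if isinstance(v, (str, int, float, bool)) or v is None:
        return v
    return str(v)
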