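"""Grid-based 3D mathematical morphology for molecular surface extraction.

The antigen is discretized as a binary occupancy field f over Z^3: the object is
X = {v : f(v)=1} and the background its complement.  Dilation by a small digital
ball B1 fills narrow crevices; erosion of the dilated set by a larger ball B2
removes the interior; the set difference XD - XE is a surface shell a few
voxels thick.  An atom's surface rate AR(r) is the fraction of its own occupied
voxels (voxel centers within its van der Waals radius) lying inside that shell.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .structure_io import Atom, Structure

DEFAULT_SPACING = 1.0  # Angstrom
DEFAULT_B1_RADIUS = 1.5  # Angstrom, fundamental ball element
# B2 must be strictly larger than B1; smallest ball that guarantees a
# non-degenerate shell at the default spacing.
def default_b2_radius(b1_radius: float = DEFAULT_B1_RADIUS,
                      spacing: float = DEFAULT_SPACING) -> float:
    return b1_radius + 2.0 * spacing


@dataclass(frozen=True)
class StructuringElement:
    """Digital ball: integer offsets d with ||d|| * spacing <= radius."""

    radius: float
    spacing: float
    offsets: np.ndarray  # (k, 3) int

    def __post_init__(self):
        assert (self.offsets == 0).all(axis=1).any(), "element must contain the origin"

    @property
    def half_width(self) -> int:
        return int(np.abs(self.offsets).max())

    def mask(self) -> np.ndarray:
        """Boolean (2m+1)^3 footprint centered at the origin."""
        m = self.half_width
        out = np.zeros((2 * m + 1,) * 3, dtype=bool)
        idx = self.offsets + m
        out[idx[:, 0], idx[:, 1], idx[:, 2]] = True
        return out


@dataclass
class VoxelGrid:
    origin: np.ndarray  # (3,) coordinates of voxel (0,0,0) center, Angstrom
    spacing: float
    occupancy: np.ndarray  # bool array, shape (nx, ny, nz)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.occupancy.shape

    def voxel_center(self, index: np.ndarray) -> np.ndarray:
        return self.origin + np.asarray(index, dtype=float) * self.spacing

    def count(self) -> int:
        return int(self.occupancy.sum())

    def like(self, occupancy: np.ndarray) -> "VoxelGrid":
        return VoxelGrid(self.origin.copy(), self.spacing, occupancy)


def ball_element(radius: float, spacing: float) -> StructuringElement:
    """All integer offsets within ``radius`` of the origin at the given spacing."""
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if radius < 0:
        raise ValueError("radius must be non-negative")
    m = int(np.floor(radius / spacing))
    rng = np.arange(-m, m + 1)
    dx, dy, dz = np.meshgrid(rng, rng, rng, indexing="ij")
    d = np.stack([dx.ravel(), dy.ravel(), dz.ravel()], axis=1)
    keep = (d ** 2).sum(axis=1) * spacing ** 2 <= radius ** 2 + 1e-9
    return StructuringElement(radius=radius, spacing=spacing, offsets=d[keep])


def _atom_ball_indices(pos: np.ndarray, radius: float, origin: np.ndarray,
                       spacing: float, shape: tuple[int, int, int]) -> np.ndarray:
    """Voxel indices whose centers lie within ``radius`` of ``pos`` (clipped to grid)."""
    lo = np.maximum(np.ceil((pos - radius - origin) / spacing).astype(int), 0)
    hi = np.minimum(np.floor((pos + radius - origin) / spacing).astype(int),
                    np.asarray(shape) - 1)
    if (lo > hi).any():
        return np.empty((0, 3), dtype=int)
    ax = [np.arange(lo[k], hi[k] + 1) for k in range(3)]
    gx, gy, gz = np.meshgrid(*ax, indexing="ij")
    idx = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)
    centers = origin + idx * spacing
    keep = ((centers - pos) ** 2).sum(axis=1) <= radius ** 2 + 1e-9
    return idx[keep]


def voxelize(structure: Structure, spacing: float = DEFAULT_SPACING,
             padding: float | None = None) -> VoxelGrid:
    """Discretize the union of heavy-atom van der Waals balls onto a grid.

    A voxel is occupied iff its center lies within some heavy atom's van der
    Waals radius.  Padding defaults to b2 + max vdw radius + 2*spacing so that
    later dilation cannot clip at the grid boundary.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    atoms = structure.heavy_atoms()
    if not atoms:
        raise ValueError("structure has no heavy atoms")
    positions = np.array([a.position for a in atoms])
    radii = np.array([a.vdw_radius for a in atoms])
    if padding is None:
        padding = default_b2_radius(spacing=spacing) + radii.max() + 2 * spacing
    # snap the origin to the global lattice so voxel centers are
    # translation-consistent across grids built from different extents
    origin = np.floor((positions.min(axis=0) - padding) / spacing) * spacing
    top = positions.max(axis=0) + padding
    shape = tuple(np.ceil((top - origin) / spacing).astype(int) + 1)
    occ = np.zeros(shape, dtype=bool)
    for pos, r in zip(positions, radii):
        idx = _atom_ball_indices(pos, r, origin, spacing, shape)
        occ[idx[:, 0], idx[:, 1], idx[:, 2]] = True
    return VoxelGrid(origin=origin, spacing=spacing, occupancy=occ)


def _check_spacing(grid: VoxelGrid, element: StructuringElement) -> None:
    if not np.isclose(grid.spacing, element.spacing):
        raise ValueError("grid and structuring element spacings differ")


def _check_border(occ: np.ndarray, half_width: int, op: str) -> None:
    """Object voxels within the element's reach of the boundary mean the grid
    was built with insufficient padding and the operation would be clipped."""
    m = half_width
    if m == 0:
        return
    interior = np.zeros_like(occ)
    interior[m:-m or None, m:-m or None, m:-m or None] = True
    if (occ & ~interior).any():
        raise ValueError(f"padding insufficient for {op} with this element")


def dilate(grid: VoxelGrid, element: StructuringElement) -> VoxelGrid:
    """Minkowski dilation: occupied where the translated element meets X."""
    _check_spacing(grid, element)
    _check_border(grid.occupancy, element.half_width, "dilation")
    out = ndimage.binary_dilation(grid.occupancy, structure=element.mask())
    return grid.like(out)


def erode(grid: VoxelGrid, element: StructuringElement) -> VoxelGrid:
    """Minkowski erosion: occupied where every element translate stays inside X."""
    _check_spacing(grid, element)
    _check_border(grid.occupancy, element.half_width, "erosion")
    out = ndimage.binary_erosion(grid.occupancy, structure=element.mask(),
                                 border_value=0)
    return grid.like(out)


@dataclass
class MorphologyResult:
    occupied: VoxelGrid   # X
    dilated: VoxelGrid    # XD = X (+) B1
    eroded: VoxelGrid     # XE = XD (-) B2
    shell: VoxelGrid      # XD - XE


def morphological_surface(structure: Structure, spacing: float = DEFAULT_SPACING,
                          b1_radius: float = DEFAULT_B1_RADIUS,
                          b2_radius: float | None = None) -> MorphologyResult:
    """Run the full dilation/erosion/difference construction for a structure."""
    if b2_radius is None:
        b2_radius = default_b2_radius(b1_radius, spacing)
    if b2_radius <= b1_radius:
        raise ValueError("b2_radius must exceed b1_radius")
    max_vdw = max(a.vdw_radius for a in structure.heavy_atoms())
    padding = b2_radius + max_vdw + 2 * spacing
    grid = voxelize(structure, spacing=spacing, padding=padding)
    b1 = ball_element(b1_radius, spacing)
    b2 = ball_element(b2_radius, spacing)
    xd = dilate(grid, b1)
    xe = erode(xd, b2)
    shell = xd.like(xd.occupancy & ~xe.occupancy)
    return MorphologyResult(occupied=grid, dilated=xd, eroded=xe, shell=shell)


def surface_shell(structure: Structure, spacing: float = DEFAULT_SPACING,
                  b1_radius: float = DEFAULT_B1_RADIUS,
                  b2_radius: float | None = None) -> VoxelGrid:
    """Surface shell XD - XE of a structure (see :func:`morphological_surface`)."""
    return morphological_surface(structure, spacing, b1_radius, b2_radius).shell


def atom_surface_rate(atom: Atom, shell: VoxelGrid, occupied: VoxelGrid) -> float:
    """Fraction of the atom's own occupied voxels lying in the surface shell.

    An atom's own voxels are those whose centers fall within its van der Waals
    radius.  Returns 0 (with a warning) if the spacing is too coarse for the
    atom to own any voxel.
    """
    if not np.allclose(shell.origin, occupied.origin) or not np.isclose(
        shell.spacing, occupied.spacing
    ):
        raise ValueError("shell and occupancy grids are not aligned")
    idx = _atom_ball_indices(atom.position, atom.vdw_radius, occupied.origin,
                             occupied.spacing, occupied.shape)
    if len(idx) == 0:
        warnings.warn(
            f"atom {atom.name} at {atom.position} owns no voxels at spacing "
            f"{occupied.spacing}; AR treated as 0"
        )
        return 0.0
    in_shell = shell.occupancy[idx[:, 0], idx[:, 1], idx[:, 2]]
    return float(in_shell.sum()) / float(len(idx))


def shell_to_pdb(shell: VoxelGrid) -> str:
    """Debug writer: shell voxels as HETATM pseudo-atoms for visual inspection."""
    lines = []
    idx = np.argwhere(shell.occupancy)
    for i, v in enumerate(idx, start=1):
        x, y, z = shell.voxel_center(v)
        lines.append(
            f"HETATM{i % 100000:5d}  C   VOX X{i % 10000:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
        )
    lines.append("END")
    return "\n".join(lines) + "\n"
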