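"""Shared grid and field types for the macroscopic tumour state.

The macroscopic model lives on a regular cell-centred Cartesian lattice
covering a tissue cube.  The tumour occupies an evolving subregion
``Omega(t)`` represented by a binary indicator; its lattice boundary and
outward normals are extracted here.  The macroscopic state is the vector
``u = (c, l, F)`` — cancer-cell density, non-fibre ECM density and fibre
ECM magnitude — plus the nutrient level ``sigma``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage


class GridMismatchError(ValueError):
    """Fields that must share a grid do not."""


class GeometryError(ValueError):
    """Invalid domain geometry (empty indicator, frame contact, ...)."""


@dataclass(frozen=True)
class Grid3D:
    """Regular cell-centred 3D lattice.

    Physical coordinate of voxel ``(i, j, k)`` is
    ``origin + (index + 0.5) * spacing`` (0-based indices).
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(n) < 4 for n in self.shape):
            raise ValueError(f"grid shape must have 3 components >= 4, got {self.shape}")
        if any(h <= 0 for h in self.spacing):
            raise ValueError(f"grid spacings must be positive, got {self.spacing}")
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "spacing", tuple(float(h) for h in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    def coords(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Cell-centre physical coordinates as three broadcastable axes."""
        axes = []
        for n, h, o in zip(self.shape, self.spacing, self.origin):
            axes.append(o + (np.arange(n) + 0.5) * h)
        return tuple(np.meshgrid(*axes, indexing="ij", sparse=True))

    def zeros(self, dtype=np.float64) -> np.ndarray:
        return np.zeros(self.shape, dtype=dtype)

    def validate_field(self, f: np.ndarray, name: str = "field") -> np.ndarray:
        f = np.asarray(f)
        if f.shape != self.shape:
            raise GridMismatchError(
                f"{name} has shape {f.shape}, expected grid shape {self.shape}"
            )
        return f


@dataclass
class TissueState:
    """Macroscopic tumour state ``u = (c, l, F)`` plus nutrients ``sigma``.

    All four scalar fields share one :class:`Grid3D`; densities are
    nondimensional volume fractions, so the total occupied space is
    ``rho(u) = c + l + F``.
    """

    grid: Grid3D
    c: np.ndarray
    l: np.ndarray
    F: np.ndarray
    sigma: np.ndarray

    def __post_init__(self) -> None:
        for name in ("c", "l", "F", "sigma"):
            arr = self.grid.validate_field(getattr(self, name), name)
            if np.any(arr < 0):
                raise ValueError(f"{name} must be nonnegative everywhere")
            setattr(self, name, np.asarray(arr, dtype=np.float64))

    @classmethod
    def zeros(cls, grid: Grid3D) -> "TissueState":
        return cls(grid, grid.zeros(), grid.zeros(), grid.zeros(), grid.zeros())

    def copy(self) -> "TissueState":
        return TissueState(
            self.grid, self.c.copy(), self.l.copy(), self.F.copy(), self.sigma.copy()
        )


def total_density(state: TissueState) -> np.ndarray:
    """Total occupied volume fraction ``rho(u) = c + l + F`` (pointwise)."""
    return state.c + state.l + state.F


def weight_w(c: np.ndarray, F: np.ndarray) -> np.ndarray:
    """Mediating weight ``w = c / (c + F)`` used in fibre rearrangement.

    Returns 0 where ``c + F = 0`` (no cells and no fibres means the weight
    is irrelevant; the continuum definition leaves 0/0 open).
    """
    c = np.asarray(c, dtype=np.float64)
    F = np.asarray(F, dtype=np.float64)
    if np.any(c < 0) or np.any(F < 0):
        raise ValueError("weight_w requires nonnegative c and F")
    denom = c + F
    out = np.zeros(np.broadcast_shapes(c.shape, F.shape))
    np.divide(c, denom, out=out, where=denom > 0)
    return out if out.ndim else float(out)


@dataclass
class TumourDomain:
    """Evolving tumour region ``Omega(t)`` on the lattice.

    ``boundary_points`` are voxel indices that lie inside Omega with at
    least one outside 6-neighbour; ``normals`` are unit outward vectors per
    boundary point; ``outer_interface`` is the set of outside voxels
    adjacent to Omega (the outer interface where the nutrient Dirichlet
    condition applies).
    """

    grid: Grid3D
    indicator: np.ndarray
    boundary_points: np.ndarray  # (nb, 3) int voxel indices
    normals: np.ndarray  # (nb, 3) float unit vectors
    outer_interface: np.ndarray  # (no, 3) int voxel indices
    degenerate: bool = False

    @property
    def volume_voxels(self) -> int:
        return int(self.indicator.sum())

    def boundary_coords(self) -> np.ndarray:
        """Physical coordinates of the boundary voxel centres."""
        h = np.asarray(self.grid.spacing)
        o = np.asarray(self.grid.origin)
        return o + (self.boundary_points + 0.5) * h


_FACE_STRUCT = ndimage.generate_binary_structure(3, 1)  # 6-connectivity


def extract_boundary(indicator: np.ndarray, grid: Grid3D) -> TumourDomain:
    """Realise ``Omega(t)``'s lattice boundary, normals and outer interface.

    Boundary voxels are inside voxels with an outside 6-neighbour.  Normals
    are the negative normalised gradient of a Gaussian-smoothed signed
    distance transform of the indicator (smoothing width one voxel), which
    is far less noisy than raw lattice normals.
    """
    indicator = grid.validate_field(indicator, "indicator").astype(bool)
    if not indicator.any():
        raise GeometryError("empty tumour indicator")
    frame = np.zeros_like(indicator)
    frame[0, :, :] = frame[-1, :, :] = True
    frame[:, 0, :] = frame[:, -1, :] = True
    frame[:, :, 0] = frame[:, :, -1] = True
    if (indicator & frame).any():
        raise GeometryError("tumour indicator touches the grid frame")

    eroded = ndimage.binary_erosion(indicator, structure=_FACE_STRUCT, border_value=0)
    boundary_mask = indicator & ~eroded
    boundary_points = np.argwhere(boundary_mask)

    dilated = ndimage.binary_dilation(indicator, structure=_FACE_STRUCT, border_value=0)
    outer = np.argwhere(dilated & ~indicator)

    # Signed distance: negative inside, positive outside.
    inside = ndimage.distance_transform_edt(indicator, sampling=grid.spacing)
    outside = ndimage.distance_transform_edt(~indicator, sampling=grid.spacing)
    sdist = outside - inside
    smoothed = ndimage.gaussian_filter(sdist, sigma=1.0)
    grads = np.gradient(smoothed, *grid.spacing)

    idx = tuple(boundary_points.T)
    g = np.stack([gr[idx] for gr in grads], axis=1)
    norms = np.linalg.norm(g, axis=1)
    degenerate = bool(np.any(norms < 1e-12)) or indicator.sum() == 1
    safe = np.where(norms < 1e-12, 1.0, norms)
    normals = g / safe[:, None]
    normals[norms < 1e-12] = 0.0

    return TumourDomain(
        grid=grid,
        indicator=indicator,
        boundary_points=boundary_points,
        normals=normals,
        outer_interface=outer,
        degenerate=degenerate,
    )


def ball_indicator(grid: Grid3D, centre, radius: float) -> np.ndarray:
    """Digitised ball: voxels whose centre lies within ``radius`` of ``centre``."""
    X, Y, Z = grid.coords()
    cx, cy, cz = centre
    return ((X - cx) ** 2 + (Y - cy) ** 2 + (Z - cz) ** 2) <= radius**2
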