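"""Voxel-grid geometry shared by the acquisition simulator and the resampler.

Axes follow a right-handed patient frame with components ordered
(right-left, anterior-posterior, foot-head); positive foot-head points from
feet toward head.  Grids store world coordinates in millimetres via a NIfTI
affine; the flow physics works in metres, so helpers convert explicitly.

Voxels are half-open axis-aligned boxes centred on integer indices: voxel
(i, j, k) spans index space [i-0.5, i+0.5) × ... and maps to world space
through the affine.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MM_PER_M = 1000.0

# axis order inside all lattices
AX_RL, AX_AP, AX_FH = 0, 1, 2
COMPONENTS = ("RL", "AP", "FH")


@dataclass(frozen=True)
class GridGeometry:
    """Shape + affine of a voxel lattice (world units mm, NIfTI convention)."""

    shape: tuple[int, int, int]
    affine: np.ndarray  # 4x4, index -> mm

    def __post_init__(self) -> None:
        object.__setattr__(self, "affine", np.asarray(self.affine, dtype=float))
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if len(self.shape) != 3 or any(n < 1 for n in self.shape):
            raise ValueError("shape must be three positive integers")

    @property
    def voxel_size_mm(self) -> np.ndarray:
        """Per-axis voxel edge lengths, mm."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def index_to_mm(self, ijk: np.ndarray) -> np.ndarray:
        """Map (N,3) fractional indices to (N,3) world mm."""
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def voxel_centers_mm(self) -> np.ndarray:
        """World coordinates of all voxel centres, shape ``(*shape, 3)``, mm."""
        idx = np.stack(
            np.meshgrid(*[np.arange(n) for n in self.shape], indexing="ij"), axis=-1
        )
        flat = self.index_to_mm(idx.reshape(-1, 3))
        return flat.reshape(*self.shape, 3)

    def supersample_points_mm(self, subdiv: tuple[int, int, int]) -> np.ndarray:
        """Midpoint-rule sample points inside every voxel.

        Returns an array of shape ``(*shape, prod(subdiv), 3)`` in world mm.
        ``subdiv`` gives the number of equally weighted samples per axis.
        """
        if any(s < 1 for s in subdiv):
            raise ValueError("subdivision counts must be >= 1")
        offs = [
            (np.arange(s) + 0.5) / s - 0.5 for s in subdiv
        ]  # index-space offsets in [-0.5, 0.5)
        cell = np.stack(np.meshgrid(*offs, indexing="ij"), axis=-1).reshape(-1, 3)
        idx = np.stack(
            np.meshgrid(*[np.arange(n) for n in self.shape], indexing="ij"), axis=-1
        ).reshape(-1, 1, 3)
        pts = idx + cell[None, :, :]
        world = self.index_to_mm(pts.reshape(-1, 3)).reshape(
            *self.shape, cell.shape[0], 3
        )
        return world


def sagittal_slab_grid(
    fov_ap_mm: float,
    fov_fh_mm: float,
    in_plane_mm: float = 1.25,
    slab_mm: float = 10.0,
    center_mm: tuple[float, float, float] = (0.0, 0.0, 0.0),
    n_slabs: int = 1,
) -> GridGeometry:
    """Build a sagittal PC-MRI grid: thick slab along RL, fine in-plane (AP, FH).

    Mirrors the anisotropic acquisition geometry: ~1.25-1.5 mm in plane and a
    10-12.5 mm slab through-plane.
    """
    n_ap = max(1, int(round(fov_ap_mm / in_plane_mm)))
    n_fh = max(1, int(round(fov_fh_mm / in_plane_mm)))
    shape = (n_slabs, n_ap, n_fh)
    affine = np.diag([slab_mm, in_plane_mm, in_plane_mm, 1.0])
    # place grid so that its centre sits at center_mm
    for ax, n in enumerate(shape):
        affine[ax, 3] = center_mm[ax] - affine[ax, ax] * (n - 1) / 2.0
    return GridGeometry(shape=shape, affine=affine)


@dataclass
class DynamicWindow:
    """Half-open acquisition interval [start, start + duration), seconds."""

    start: float
    duration: float

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("dynamic duration must be positive")

    def time_points(self, n: int = 11) -> np.ndarray:
        """Midpoint-rule time samples spanning the window."""
        return self.start + (np.arange(n) + 0.5) / n * self.duration
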