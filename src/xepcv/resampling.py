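"""Resampling a fine velocity field onto coarse anisotropic MRI voxels.

This is the reference-side half of the comparison pipeline: the continuous
(or finely simulated) velocity field is averaged over each anisotropic MRI
voxel — including the full slab thickness in the right-left direction — and
over the multi-second acquisition window of each dynamic image, producing a
map directly comparable to the PC-MRI data.  The module also provides the two
robustness operations applied before the statistics: in-plane morphological
erosion of the lumen mask by one voxel (removing the partial-volume-biased
boundary layer) and 3×3 in-plane block down-sampling.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

from .grids import AX_AP, AX_FH, AX_RL, COMPONENTS, MM_PER_M, DynamicWindow, GridGeometry
from .phantom import AnalyticFlowField

__all__ = [
    "VoxelVelocityMap",
    "EmptyMaskError",
    "voxel_average_field",
    "resample_to_voxels",
    "erode_mask",
    "downsample_blocks",
]

# in-plane 4-connectivity for a sagittal stack: no coupling across the slab axis
_CROSS_IN_PLANE = np.array([[[0, 1, 0], [1, 1, 1], [0, 1, 0]]], dtype=bool).transpose(
    0, 1, 2
)


class EmptyMaskError(ValueError):
    """The voxel grid does not overlap the phantom lumen."""


@dataclass
class VoxelVelocityMap:
    """Per-component voxel velocity lattices (cm·s⁻¹) with lumen mask and window."""

    grid: GridGeometry
    velocity: dict[str, np.ndarray]  # component -> lattice, cm/s, NaN outside mask
    mask: np.ndarray  # bool lattice
    window: DynamicWindow
    lumen_fraction: np.ndarray | None = None

    def __post_init__(self) -> None:
        for comp, lat in self.velocity.items():
            if lat.shape != tuple(self.grid.shape):
                raise ValueError(f"{comp} lattice shape does not match grid")
        if self.mask.shape != tuple(self.grid.shape):
            raise ValueError("mask shape does not match grid")

    def masked(self, comp: str) -> np.ndarray:
        """Values of one component inside the mask (1-D)."""
        return self.velocity[comp][self.mask]

    def with_mask(self, mask: np.ndarray) -> "VoxelVelocityMap":
        return VoxelVelocityMap(
            grid=self.grid,
            velocity=self.velocity,
            mask=mask & self.mask,
            window=self.window,
            lumen_fraction=self.lumen_fraction,
        )

    def to_nifti(self, stem: str | Path) -> None:
        """Write one NIfTI per component plus the mask and a JSON sidecar."""
        stem = Path(stem)
        for comp, lat in self.velocity.items():
            nib.save(
                nib.Nifti1Image(np.nan_to_num(lat), self.grid.affine),
                f"{stem}_v{comp}.nii",
            )
        nib.save(
            nib.Nifti1Image(self.mask.astype(np.uint8), self.grid.affine),
            f"{stem}_mask.nii",
        )
        meta = {
            "window_start_s": self.window.start,
            "window_duration_s": self.window.duration,
            "components": sorted(self.velocity),
        }
        Path(f"{stem}.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def from_nifti(cls, stem: str | Path) -> "VoxelVelocityMap":
        stem = Path(stem)
        meta = json.loads(Path(f"{stem}.json").read_text())
        mask_img = nib.load(f"{stem}_mask.nii")
        mask = np.asarray(mask_img.dataobj).astype(bool)
        velocity = {}
        for comp in meta["components"]:
            velocity[comp] = np.asarray(nib.load(f"{stem}_v{comp}.nii").dataobj).astype(
                float
            )
        grid = GridGeometry(shape=mask.shape, affine=mask_img.affine)
        return cls(
            grid=grid,
            velocity=velocity,
            mask=mask,
            window=DynamicWindow(meta["window_start_s"], meta["window_duration_s"]),
        )


def voxel_average_field(
    field: AnalyticFlowField,
    grid: GridGeometry,
    window: DynamicWindow,
    subdiv: tuple[int, int, int],
    n_time: int = 11,
    concentration=None,
    signal_weighted: bool = False,
    chunk_voxels: int = 512,
):
    """Core spatio-temporal voxel averaging shared by resampler and simulator.

    Returns ``(vel, lumen_fraction, mean_signal)`` where ``vel`` is an array
    of shape ``(*grid.shape, 3)`` in m·s⁻¹.

    * plain mode (``signal_weighted=False``): per voxel, the unweighted mean
      of the field over a regular supersample of the voxel volume and over
      ``n_time`` window time points; points outside the lumen contribute
      zero velocity, exactly as a volume average of the true field does.
    * signal-weighted mode: per time point, velocities are averaged with
      weight lumen-membership × local xenon concentration (the MR
      signal-formation weighting causing the partial-volume and slow-flow
      biases), then averaged evenly over time points; ``mean_signal`` is the
      mean weight per voxel (before relaxation losses).
    """
    pts_mm = grid.supersample_points_mm(subdiv)  # (*shape, P, 3)
    n_vox = int(np.prod(grid.shape))
    P = pts_mm.shape[-2]
    pts_m = pts_mm.reshape(n_vox, P, 3) / MM_PER_M
    times = window.time_points(n_time)
    T = len(times)

    vel = np.zeros((n_vox, 3))
    frac = np.zeros(n_vox)
    sig = np.zeros(n_vox)
    phantom = field.phantom
    # keep chunks near ~10^5 sample points regardless of supersampling density
    chunk_voxels = max(1, min(chunk_voxels, -(-100_000 // P), n_vox))
    buf = np.zeros((T, chunk_voxels * P, 3))  # reused across chunks
    for lo in range(0, n_vox, chunk_voxels):
        hi = min(lo + chunk_voxels, n_vox)
        chunk = pts_m[lo:hi].reshape(-1, 3)
        inside = phantom.contains(chunk).reshape(hi - lo, P)
        frac[lo:hi] = inside.mean(axis=1)
        n_pts = (hi - lo) * P
        v_series = field.velocity_series(chunk, times, out=buf[:, :n_pts]).reshape(
            T, hi - lo, P, 3
        )
        if not signal_weighted:
            vel[lo:hi] = v_series.mean(axis=(0, 2))
            sig[lo:hi] = frac[lo:hi]
            continue
        v_acc = np.zeros((hi - lo, 3))
        n_acc = np.zeros(hi - lo)
        w_acc = np.zeros(hi - lo)
        for ti, t in enumerate(times):
            if concentration is not None:
                conc = np.asarray(concentration.at_world(chunk, float(t))).reshape(
                    hi - lo, P
                )
            else:
                conc = np.ones((hi - lo, P))
            w = inside * conc
            wsum = w.sum(axis=1)
            ok = wsum > 0
            num = np.einsum("vp,vpc->vc", w, v_series[ti])
            v_acc[ok] += num[ok] / wsum[ok, None]
            n_acc[ok] += 1
            w_acc += w.mean(axis=1)
        ok = n_acc > 0
        vel[lo:hi][ok] = v_acc[ok] / n_acc[ok, None]
        vel[lo:hi][~ok] = np.nan
        sig[lo:hi] = w_acc / T
    shape = tuple(grid.shape)
    if not np.any(frac > 0):
        raise EmptyMaskError("voxel grid does not overlap the phantom lumen")
    return (
        vel.reshape(*shape, 3),
        frac.reshape(shape),
        sig.reshape(shape),
    )


def resample_to_voxels(
    field: AnalyticFlowField,
    grid: GridGeometry,
    window: DynamicWindow,
    supersampling: int = 4,
    slab_supersampling: int = 9,
    n_time: int = 11,
    mask_threshold: float = 0.5,
) -> VoxelVelocityMap:
    """Average the fine field into MRI voxels over one dynamic window.

    Each voxel value is the plain volume mean of the field over a regular
    ``slab_supersampling × supersampling × supersampling`` supersample
    (slab axis right-left) and over ``n_time`` time points spanning the
    window — the reference-side counterpart of the PC-MRI measurement.
    Voxels whose lumen volume fraction is at least ``mask_threshold`` form
    the mask.
    """
    if supersampling < 2:
        raise ValueError("supersampling must be >= 2")
    if n_time < 10:
        raise ValueError("use at least 10 time points per dynamic window")
    subdiv = (slab_supersampling, supersampling, supersampling)
    vel, frac, _ = voxel_average_field(
        field, grid, window, subdiv, n_time=n_time, signal_weighted=False
    )
    mask = frac >= mask_threshold
    vel_cms = vel * 100.0
    velocity = {comp: vel_cms[..., i] for i, comp in enumerate(COMPONENTS)}
    return VoxelVelocityMap(
        grid=grid, velocity=velocity, mask=mask, window=window, lumen_fraction=frac
    )


def erode_mask(mask: np.ndarray, iterations: int = 1) -> np.ndarray:
    """In-plane morphological erosion (4-connectivity per sagittal slice).

    Removes the boundary layer of voxels at the lumen edge, where
    partial-volume mixing, delayed xenon arrival and longer signal decay bias
    the PC-MRI velocities.  Lattice edges count as background.  The result is
    always a subset of the input and may be empty.
    """
    mask = np.asarray(mask).astype(bool)
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    if iterations == 0:
        return mask.copy()
    if mask.ndim == 2:  # convenience for single-slice maps
        return ndimage.binary_erosion(
            mask, structure=_CROSS_IN_PLANE[0], iterations=iterations, border_value=0
        )
    if mask.ndim != 3:
        raise ValueError("mask must be 2-D or 3-D")
    return ndimage.binary_erosion(
        mask, structure=_CROSS_IN_PLANE, iterations=iterations, border_value=0
    )


def _block_reduce(
    values: np.ndarray, mask: np.ndarray, block: tuple[int, int], min_count: int
):
    """Non-overlapping in-plane block means; returns (means, out_mask, shape)."""
    nb_ap = values.shape[AX_AP] // block[0]
    nb_fh = values.shape[AX_FH] // block[1]
    if nb_ap == 0 or nb_fh == 0:
        raise ValueError("map smaller than one block")
    v = values[:, : nb_ap * block[0], : nb_fh * block[1]]
    m = mask[:, : nb_ap * block[0], : nb_fh * block[1]]
    v = np.where(m, np.nan_to_num(v), 0.0)
    v = v.reshape(v.shape[0], nb_ap, block[0], nb_fh, block[1])
    m = m.reshape(m.shape[0], nb_ap, block[0], nb_fh, block[1])
    counts = m.sum(axis=(2, 4))
    sums = v.sum(axis=(2, 4))
    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(counts > 0, sums / counts, np.nan)
    return means, counts >= min_count


def downsample_blocks(
    vmap: VoxelVelocityMap,
    block: tuple[int, int] = (3, 3),
    min_count: int = 5,
    overlapping: bool = False,
) -> VoxelVelocityMap:
    """3×3 in-plane down-sampling of a velocity map.

    Default behaviour partitions the in-plane (AP, FH) grid into
    non-overlapping ``block`` windows, replacing each with the mean over its
    in-mask pixels; the output pixel is in-mask only when at least
    ``min_count`` of the inputs were (default 5 of 9).  Trailing partial
    blocks are dropped.  ``overlapping=True`` instead applies a sliding-window
    moving average at the original resolution (sensitivity variant).
    """
    if min(block) < 2:
        raise ValueError("block must be >= 2 per axis")
    if overlapping:
        return _downsample_sliding(vmap, block, min_count)
    velocity = {}
    out_mask = None
    for comp, lat in vmap.velocity.items():
        means, bmask = _block_reduce(lat, vmap.mask, block, min_count)
        velocity[comp] = np.where(bmask, means, np.nan)
        out_mask = bmask if out_mask is None else out_mask
    # output voxel (i, j', k') is centred on input voxel (i, b j'+ (b-1)/2, ...)
    new_affine = vmap.grid.affine.copy()
    for ax, b in zip((AX_AP, AX_FH), block):
        new_affine[:3, ax] *= b
    center0 = np.array([0.0, (block[0] - 1) / 2.0, (block[1] - 1) / 2.0])
    new_affine[:3, 3] = vmap.grid.index_to_mm(center0)[0]
    new_grid = GridGeometry(shape=out_mask.shape, affine=new_affine)
    return VoxelVelocityMap(
        grid=new_grid, velocity=velocity, mask=out_mask, window=vmap.window
    )


def _downsample_sliding(
    vmap: VoxelVelocityMap, block: tuple[int, int], min_count: int
) -> VoxelVelocityMap:
    """Overlapping moving-average variant: same grid, smoothed values."""
    kernel = np.ones((1, block[0], block[1]))
    m = vmap.mask.astype(float)
    counts = ndimage.convolve(m, kernel, mode="constant", cval=0.0)
    velocity = {}
    for comp, lat in vmap.velocity.items():
        v = np.where(vmap.mask, np.nan_to_num(lat), 0.0)
        sums = ndimage.convolve(v, kernel, mode="constant", cval=0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            velocity[comp] = np.where(counts > 0, sums / counts, np.nan)
    out_mask = counts >= min_count
    return VoxelVelocityMap(
        grid=vmap.grid, velocity=velocity, mask=out_mask, window=vmap.window
    )
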