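"""Voxel-wise agreement statistics between PC-MRI and reference velocity maps.

The comparison follows the standard method-agreement toolkit: voxel-wise
Pearson correlation with an ordinary-least-squares best-fit line, velocity
histograms, voxel-wise difference maps, and Bland-Altman analysis (bias =
mean difference, limits of agreement = bias ± 1.96·SD of the differences).
Differences are signed PC-MRI minus reference, so a positive bias means the
MRI measurement reads higher.  A velocity-cutoff sensitivity sweep recomputes
the correlation after discarding pairs whose reference speed falls below a
threshold, probing how much low-velocity voxels drive the statistics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .acquisition import PCMRISeries
from .resampling import VoxelVelocityMap, downsample_blocks, erode_mask

__all__ = [
    "PairedVoxels",
    "CorrelationResult",
    "BlandAltmanResult",
    "ComparisonReport",
    "pearson_voxelwise",
    "bland_altman",
    "cutoff_sensitivity",
    "build_report",
]


@dataclass(frozen=True)
class PairedVoxels:
    """Paired (v_mri, v_ref) samples for one velocity component, cm·s⁻¹."""

    v_mri: np.ndarray
    v_ref: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        a = np.asarray(self.v_mri, dtype=float)
        b = np.asarray(self.v_ref, dtype=float)
        if a.shape != b.shape or a.ndim != 1:
            raise ValueError("paired lists must be 1-D and equal length")
        if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
            raise ValueError("paired values must be finite")
        object.__setattr__(self, "v_mri", a)
        object.__setattr__(self, "v_ref", b)

    @property
    def n(self) -> int:
        return len(self.v_mri)


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p_value: float
    slope: float
    intercept: float
    n: int


@dataclass(frozen=True)
class BlandAltmanResult:
    """Bias and 95% limits of agreement of the pairwise differences, cm·s⁻¹."""

    bias: float
    loa_lower: float
    loa_upper: float
    sd_diff: float
    n: int

    def __post_init__(self) -> None:
        assert self.loa_lower <= self.bias <= self.loa_upper


def _degenerate(v: np.ndarray) -> bool:
    """True when a sample is (numerically) constant, so r is undefined."""
    if np.ptp(v) == 0:
        return True
    return np.std(v) <= 1e-9 * max(1.0, float(np.max(np.abs(v))))


def pearson_voxelwise(pairs: PairedVoxels) -> CorrelationResult:
    """Pearson r (two-sided p from the exact t transform) plus OLS fit line.

    Requires at least 3 pairs and non-degenerate variance in both lists.
    """
    if pairs.n < 3:
        raise ValueError("need at least 3 pairs for a correlation")
    if _degenerate(pairs.v_mri) or _degenerate(pairs.v_ref):
        raise ValueError("zero variance: correlation undefined")
    r, p = sps.pearsonr(pairs.v_ref, pairs.v_mri)
    fit = sps.linregress(pairs.v_ref, pairs.v_mri)
    return CorrelationResult(
        r=float(r),
        p_value=float(p),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        n=pairs.n,
    )


def bland_altman(pairs: PairedVoxels, loa_factor: float = 1.96) -> BlandAltmanResult:
    """Bland-Altman bias and limits of agreement (MRI − reference)."""
    if pairs.n < 2:
        raise ValueError("need at least 2 pairs")
    diff = pairs.v_mri - pairs.v_ref
    bias = float(np.mean(diff))
    sd = float(np.std(diff, ddof=1))
    return BlandAltmanResult(
        bias=bias,
        loa_lower=bias - loa_factor * sd,
        loa_upper=bias + loa_factor * sd,
        sd_diff=sd,
        n=pairs.n,
    )


def cutoff_sensitivity(
    pairs: PairedVoxels, cutoffs: np.ndarray
) -> list[dict]:
    """Correlation after excluding pairs with |v_ref| below each cutoff (cm/s).

    For each cutoff returns ``{"cutoff", "r", "p_value", "n"}``; when fewer
    than 3 pairs survive, ``r`` and ``p_value`` are NaN rather than raising.
    """
    out = []
    for cut in np.asarray(cutoffs, dtype=float):
        if cut < 0:
            raise ValueError("cutoffs must be non-negative")
        keep = np.abs(pairs.v_ref) >= cut
        n = int(keep.sum())
        if n < 3 or _degenerate(pairs.v_ref[keep]) or _degenerate(pairs.v_mri[keep]):
            out.append({"cutoff": float(cut), "r": float("nan"), "p_value": float("nan"), "n": n})
            continue
        r, p = sps.pearsonr(pairs.v_ref[keep], pairs.v_mri[keep])
        out.append({"cutoff": float(cut), "r": float(r), "p_value": float(p), "n": n})
    return out


@dataclass
class ComparisonReport:
    """Full agreement report: per-component statistics plus difference maps."""

    correlation: dict[str, CorrelationResult]
    agreement: dict[str, BlandAltmanResult]
    per_dynamic: list[dict]  # one entry per retained dynamic and component
    histograms: dict[str, dict]  # component -> {bin_edges, mri_counts, ref_counts}
    difference_maps: dict[str, list[np.ndarray]]  # component -> per-dynamic lattice
    pairs: dict[str, PairedVoxels]
    retained_dynamics: list[int]

    def to_dict(self) -> dict:
        d = {
            "correlation": {c: asdict(v) for c, v in self.correlation.items()},
            "agreement": {c: asdict(v) for c, v in self.agreement.items()},
            "per_dynamic": self.per_dynamic,
            "retained_dynamics": self.retained_dynamics,
            "histograms": {
                c: {k: np.asarray(v).tolist() for k, v in h.items()}
                for c, h in self.histograms.items()
            },
        }
        return d

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.per_dynamic).to_csv(path, index=False)


def _histogram_pair(
    v_mri: np.ndarray, v_ref: np.ndarray, n_bins: int = 50
) -> dict:
    lo = min(v_mri.min(), v_ref.min())
    hi = max(v_mri.max(), v_ref.max())
    if lo == hi:
        lo, hi = lo - 0.5, hi + 0.5
    edges = np.linspace(lo, hi, n_bins + 1)
    return {
        "bin_edges": edges,
        "mri_counts": np.histogram(v_mri, bins=edges)[0],
        "ref_counts": np.histogram(v_ref, bins=edges)[0],
    }


def build_report(
    mri: PCMRISeries,
    refs: dict[int, VoxelVelocityMap],
    erosion_iterations: int = 0,
    downsample: bool = False,
    block: tuple[int, int] = (3, 3),
    min_count: int = 5,
    n_bins: int = 50,
    components: tuple[str, ...] | None = None,
) -> ComparisonReport:
    """Compare a simulated/measured PC-MRI series against reference maps.

    ``refs`` maps dynamic index → reference :class:`VoxelVelocityMap` on the
    same grid; only those dynamics are compared (exhalation dynamics should
    already be absent).  The common mask (MRI lumen ∧ reference mask) is
    optionally eroded in-plane and both sides optionally 3×3 down-sampled
    before statistics.  Statistics are pooled across dynamics per component;
    per-dynamic values are also reported.
    """
    if not refs:
        raise ValueError("need at least one retained dynamic to compare")
    comps = components or tuple(mri.velocity)
    pooled_mri: dict[str, list[np.ndarray]] = {c: [] for c in comps}
    pooled_ref: dict[str, list[np.ndarray]] = {c: [] for c in comps}
    per_dynamic: list[dict] = []
    diff_maps: dict[str, list[np.ndarray]] = {c: [] for c in comps}

    for k, ref in sorted(refs.items()):
        if ref.grid.shape != mri.grid.shape or not np.allclose(
            ref.grid.affine, mri.grid.affine
        ):
            raise ValueError(
                "grid mismatch between MRI and reference:\n"
                f"MRI affine:\n{mri.grid.affine}\nreference affine:\n{ref.grid.affine}"
            )
        mask = mri.mask & ref.mask
        if erosion_iterations:
            mask = erode_mask(mask, erosion_iterations)
        mri_map = VoxelVelocityMap(
            grid=mri.grid,
            velocity={c: mri.velocity[c][k] for c in comps},
            mask=mask & np.all([np.isfinite(mri.velocity[c][k]) for c in comps], axis=0),
            window=mri.window(k),
        )
        ref_map = VoxelVelocityMap(
            grid=ref.grid,
            velocity={c: ref.velocity[c] for c in comps},
            mask=mri_map.mask,
            window=ref.window,
        )
        if downsample:
            mri_map = downsample_blocks(mri_map, block=block, min_count=min_count)
            ref_map = downsample_blocks(ref_map, block=block, min_count=min_count)
        common = mri_map.mask & ref_map.mask
        for c in comps:
            a = mri_map.velocity[c]
            b = ref_map.velocity[c]
            diff = np.where(common, a - b, np.nan)
            diff_maps[c].append(diff)
            va, vb = a[common], b[common]
            pooled_mri[c].append(va)
            pooled_ref[c].append(vb)
            entry = {"dynamic": k, "component": c, "n": int(common.sum())}
            if entry["n"] >= 3 and not (_degenerate(va) or _degenerate(vb)):
                pv = PairedVoxels(va, vb, label=f"dyn{k}/{c}")
                corr = pearson_voxelwise(pv)
                ba = bland_altman(pv)
                entry.update(
                    r=corr.r,
                    p_value=corr.p_value,
                    slope=corr.slope,
                    intercept=corr.intercept,
                    bias=ba.bias,
                    loa_lower=ba.loa_lower,
                    loa_upper=ba.loa_upper,
                )
            per_dynamic.append(entry)

    correlation, agreement, histograms, pairs = {}, {}, {}, {}
    for c in comps:
        va = np.concatenate(pooled_mri[c]) if pooled_mri[c] else np.empty(0)
        vb = np.concatenate(pooled_ref[c]) if pooled_ref[c] else np.empty(0)
        if len(va) < 3:
            continue
        pv = PairedVoxels(va, vb, label=c)
        pairs[c] = pv
        if not (_degenerate(va) or _degenerate(vb)):
            correlation[c] = pearson_voxelwise(pv)
        agreement[c] = bland_altman(pv)
        histograms[c] = _histogram_pair(va, vb, n_bins=n_bins)
    return ComparisonReport(
        correlation=correlation,
        agreement=agreement,
        per_dynamic=per_dynamic,
        histograms=histograms,
        difference_maps=diff_maps,
        pairs=pairs,
        retained_dynamics=sorted(refs),
    )
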