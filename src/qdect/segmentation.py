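"""Interface segmentation, VOI extraction, crack masking and depth profiling.

Volumes are (nz, ny, nx) attenuation stacks with the bath above the tissue
along axis 0.  Each (y, x) column is segmented independently into
bath / cartilage / bone (plus crack and excluded), and every included
cartilage voxel is assigned a normalised depth
``(z - surface) / (bone - surface)`` so that 0 is the articulating surface
and 1 the cartilage-bone interface regardless of surface tilt or local
thickness.

Surface detection is mixture-dependent: with the triple bath the
nanoparticle-bright bath sits far above any tissue attenuation, so the
surface is the steepest sustained bath-to-tissue drop per column; with the
dual bath the interface contrast at 2 h is weak and detection falls back to
a bimodal-histogram (Otsu) threshold crossing, which is intrinsically less
accurate — that contrast deficit is the rationale for the triple mixture.
An import path accepts externally drawn label volumes (the stand-in for
manual segmentation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .errors import SegmentationError
from .synthetic import LABEL_BATH, LABEL_BONE, LABEL_CARTILAGE, LABEL_CRACK, LABEL_EXCLUDED

LABEL_NAMES = {
    LABEL_BATH: "bath",
    LABEL_CARTILAGE: "cartilage",
    LABEL_BONE: "bone",
    LABEL_CRACK: "crack",
    LABEL_EXCLUDED: "excluded",
}

#: consecutive voxels required beyond a threshold (noise resistance)
SUSTAINED_RUN = 3


@dataclass
class SegmentationResult:
    """Label volume plus per-column interface index maps.

    ``surface_map`` / ``bone_map`` hold the first cartilage voxel and the
    first bone voxel of each column; ``column_ok`` flags columns where both
    interfaces were found.
    """

    labels: np.ndarray
    surface_map: np.ndarray
    bone_map: np.ndarray
    column_ok: np.ndarray

    @property
    def excluded_fraction(self) -> float:
        return float(1.0 - self.column_ok.mean())


@dataclass
class DepthProfile:
    """Depth-binned profile on [0, 1] with per-bin voxel counts."""

    depth: np.ndarray  # bin centers
    value: np.ndarray
    n_voxels: np.ndarray

    def __post_init__(self):
        self.depth = np.asarray(self.depth, float)
        self.value = np.asarray(self.value, float)
        self.n_voxels = np.asarray(self.n_voxels)
        if not (self.depth.shape == self.value.shape == self.n_voxels.shape):
            raise ValueError("profile arrays must share one length")

    def _check_binning(self, other: "DepthProfile"):
        if self.depth.shape != other.depth.shape or not np.allclose(self.depth, other.depth):
            raise ValueError("depth profiles have mismatched binning")


def _finalize(volume, surface, bone, ok):
    nz = volume.shape[0]
    zz = np.arange(nz)[:, None, None]
    s = surface[None]
    b = bone[None]
    labels = np.full(volume.shape, LABEL_BATH, dtype=np.uint8)
    labels[(zz >= s) & (zz < b)] = LABEL_CARTILAGE
    labels[zz >= b] = LABEL_BONE
    labels[:, ~ok] = LABEL_EXCLUDED
    return SegmentationResult(labels, surface.copy(), bone.copy(), ok.copy())


def _detect_bone(cols, surface, ok, nz):
    """First bone voxel per column: largest sustained attenuation rise below the surface."""
    n_cols = cols.shape[1]
    bone = np.full(n_cols, nz - 1, dtype=int)
    d = np.diff(cols, axis=0)
    for j in range(n_cols):
        if not ok[j]:
            continue
        lo = surface[j] + SUSTAINED_RUN
        if lo >= nz - 1:
            ok[j] = False
            continue
        jmp = int(np.argmax(d[lo:, j])) + lo
        bone[j] = jmp + 1
        if bone[j] <= surface[j] + 1:
            ok[j] = False
    return bone


def segment_interfaces(volume: np.ndarray, mixture: str) -> SegmentationResult:
    """Locate the articulating surface and bone-cartilage interface per column.

    Raises :class:`SegmentationError` when more than 20% of columns lack a
    detectable interface (e.g. a pure-bath volume), or when the histogram
    shows no bath/tissue separation in dual mode.
    """
    if mixture not in ("dual", "triple"):
        raise ValueError(f"unknown mixture {mixture!r}")
    nz, ny, nx = volume.shape
    cols = volume.reshape(nz, -1)
    n_cols = cols.shape[1]
    ok = np.ones(n_cols, dtype=bool)
    surface = np.zeros(n_cols, dtype=int)

    noise_sigma = 1.4826 * np.median(np.abs(np.diff(cols[: max(3, nz // 8)], axis=0))) / np.sqrt(2)
    min_drop = max(6.0 * noise_sigma, 1e-6)

    if mixture == "triple":
        smooth = ndimage.uniform_filter1d(cols, SUSTAINED_RUN, axis=0)
        d = np.diff(smooth, axis=0)
        for j in range(n_cols):
            jmin = int(np.argmin(d[: nz - SUSTAINED_RUN, j]))
            lo = max(jmin - 2, 0)
            hi = min(jmin + 3, nz - 1)
            step = np.diff(cols[lo : hi + 1, j])
            k = lo + int(np.argmin(step))
            before = cols[max(k - SUSTAINED_RUN + 1, 0) : k + 1, j].mean()
            after = cols[k + 1 : k + 1 + SUSTAINED_RUN, j].mean()
            if before - after < min_drop:
                ok[j] = False
                continue
            surface[j] = k + 1
    else:
        tau = threshold_otsu(volume)
        below = volume < tau
        lo_mean, hi_mean = volume[below].mean(), volume[~below].mean()
        pooled = np.sqrt((np.var(volume[below]) + np.var(volume[~below])) / 2.0)
        if hi_mean - lo_mean < 4.0 * pooled:
            raise SegmentationError("no bath/tissue separation in attenuation histogram")
        cross = below.reshape(nz, -1)
        run = np.zeros(n_cols, dtype=int)
        surface[:] = -1
        for i in range(nz):
            run = np.where(cross[i], run + 1, 0)
            hit = (run == SUSTAINED_RUN) & (surface < 0)
            surface[hit] = i - SUSTAINED_RUN + 1
        ok &= surface >= 0
        surface = np.maximum(surface, 0)

    bone = _detect_bone(cols, surface, ok, nz)
    if 1.0 - ok.mean() > 0.20:
        raise SegmentationError(
            f"interface not found in {100 * (1 - ok.mean()):.0f}% of columns (> 20%)"
        )
    return _finalize(volume, surface.reshape(ny, nx), bone.reshape(ny, nx), ok.reshape(ny, nx))


def segmentation_from_labels(labels: np.ndarray) -> SegmentationResult:
    """Import an external label volume (bath/cartilage/bone/crack code book).

    Reconstructs per-column surface and bone maps; columns without any
    cartilage voxel are excluded.  This is the entry point for externally
    drawn (e.g. manual) segmentations.
    """
    nz, ny, nx = labels.shape
    cart = labels == LABEL_CARTILAGE
    any_cart = cart.any(axis=0)
    surface = np.where(any_cart, cart.argmax(axis=0), 0)
    is_bone = labels == LABEL_BONE
    bone = np.where(is_bone.any(axis=0), is_bone.argmax(axis=0), nz)
    res = SegmentationResult(labels.copy(), surface, bone, any_cart)
    res.labels[:, ~any_cart] = LABEL_EXCLUDED
    return res


def extract_voi(
    seg: SegmentationResult,
    voxel_um: float,
    diameter_um: float = 1313.0,
    center: tuple | None = None,
) -> SegmentationResult:
    """Restrict the mask to a cylindrical volume of interest.

    The cylinder axis is the depth axis through ``center`` (default: grid
    center); its height spans surface to bone per column.  Voxels outside
    are relabelled ``excluded``.  Raises ``ValueError`` if the cylinder
    does not fit the cross-section.
    """
    nz, ny, nx = seg.labels.shape
    radius_vox = 0.5 * diameter_um / voxel_um
    cy, cx = center if center is not None else ((ny - 1) / 2.0, (nx - 1) / 2.0)
    if (cy - radius_vox < -0.5 or cy + radius_vox > ny - 0.5
            or cx - radius_vox < -0.5 or cx + radius_vox > nx - 0.5):
        raise ValueError(
            f"VOI cylinder (r = {radius_vox:.1f} vox) exceeds the {ny}x{nx} cross-section"
        )
    yy, xx = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
    inside = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius_vox**2
    labels = seg.labels.copy()
    labels[:, ~inside] = LABEL_EXCLUDED
    return SegmentationResult(labels, seg.surface_map, seg.bone_map, seg.column_ok & inside)


def mask_cracks(
    volume: np.ndarray,
    seg: SegmentationResult,
    threshold: float | None = None,
    envelope_margin: int = 2,
    depth_guard: int = 3,
) -> SegmentationResult:
    """Relabel bath-filled cracks by thresholding.

    Two complementary rules:

    1. *Surface envelope*: columns whose detected surface lies more than
       ``envelope_margin`` voxels below the median-filtered surface of
       their neighbourhood are crack columns — the bath-level voxels
       between the envelope and the detected surface are the fissure.
    2. *Attenuation threshold*: cartilage voxels brighter than ``threshold``
       (default: midpoint of the bath and cartilage attenuation levels) and
       at least ``depth_guard`` voxels below the local surface are crack
       remnants.  The depth guard keeps legitimately bright superficial
       tissue from being excluded.

    If the mask offers no bath reference (or no voxel qualifies) the call
    is a no-op.
    """
    labels = seg.labels.copy()
    bath_sel = labels == LABEL_BATH
    cart_sel = labels == LABEL_CARTILAGE
    if not bath_sel.any() or not cart_sel.any():
        return SegmentationResult(labels, seg.surface_map, seg.bone_map, seg.column_ok)
    if threshold is None:
        threshold = 0.5 * (np.median(volume[bath_sel]) + np.median(volume[cart_sel]))

    nz = volume.shape[0]
    zz = np.arange(nz)[:, None, None]
    # window wide enough that a fissure a few columns wide cannot drag the
    # median surface down with it
    envelope = ndimage.median_filter(seg.surface_map, size=7)
    crack_cols = (seg.surface_map - envelope) > envelope_margin
    fissure = (
        crack_cols[None]
        & bath_sel
        & (zz >= envelope[None])
        & (zz < seg.surface_map[None])
        & (volume > threshold)
    )
    remnant = cart_sel & (volume > threshold) & (zz >= (seg.surface_map + depth_guard)[None])
    labels[fissure | remnant] = LABEL_CRACK
    return SegmentationResult(labels, seg.surface_map, seg.bone_map, seg.column_ok)


def depth_profile(volume: np.ndarray, seg: SegmentationResult, n_bins: int = 100) -> DepthProfile:
    """Depth-normalised mean attenuation profile over included cartilage voxels.

    Each cartilage voxel of an included column contributes at fraction
    ``(z - surface) / (bone - surface)`` of its own column; crack and
    excluded voxels never contribute.  Columns of zero cartilage thickness
    are dropped.
    """
    if n_bins < 3:
        raise ValueError("need at least 3 depth bins")
    nz = volume.shape[0]
    zz = np.arange(nz)[:, None, None]
    thick = (seg.bone_map - seg.surface_map)[None]
    valid_col = (seg.column_ok & (seg.bone_map > seg.surface_map))[None]
    sel = (seg.labels == LABEL_CARTILAGE) & valid_col
    frac = (zz - seg.surface_map[None]) / np.where(thick > 0, thick, 1)
    bins = np.clip((frac * n_bins).astype(int), 0, n_bins - 1)
    counts = np.bincount(bins[sel], minlength=n_bins)
    sums = np.bincount(bins[sel], weights=volume[sel], minlength=n_bins)
    with np.errstate(invalid="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    centers = (np.arange(n_bins) + 0.5) / n_bins
    return DepthProfile(centers, mean, counts)


def average_34kev(profile_a: DepthProfile, profile_b: DepthProfile) -> DepthProfile:
    """Average the two 34 keV profiles to cancel ongoing-diffusion drift."""
    profile_a._check_binning(profile_b)
    return DepthProfile(
        profile_a.depth,
        0.5 * (profile_a.value + profile_b.value),
        np.minimum(profile_a.n_voxels, profile_b.n_voxels),
    )


def subtract_baseline(contrast: DepthProfile, native: DepthProfile) -> DepthProfile:
    """Remove the tissue's native attenuation; negatives are kept (noise)."""
    contrast._check_binning(native)
    return DepthProfile(
        contrast.depth,
        contrast.value - native.value,
        np.minimum(contrast.n_voxels, native.n_voxels),
    )
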