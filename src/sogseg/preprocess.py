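"""Pre-processing applied before visualisation and segmentation.

Covers the filters used on the labelled volumes — non-local means
denoising, Gaussian smoothing, 3×3×1 binning — plus the observed "true
range" whose width parameterises seed-trial steps. All operations are
deterministic and record themselves in the volume's provenance.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi
from skimage.restoration import denoise_nl_means

from .volume import IntensityRange, VolumeGrid

__all__ = [
    "denoise_nlm",
    "gaussian_smooth",
    "sharpen",
    "bin_volume",
    "true_range",
    "preprocess_pipeline",
]

# Fixed NLM neighbourhood defaults, recorded in provenance: 3^3 patches
# compared within a 7^3 search window.
_NLM_PATCH_SIZE = 3
_NLM_PATCH_DISTANCE = 3


def denoise_nlm(volume: VolumeGrid, sigma: float) -> VolumeGrid:
    """Non-local means denoising with noise standard deviation ``sigma``.

    ``sigma`` is in intensity units of the working bit depth (the labelled
    SBEM volume was denoised with sigma = 5 on 8-bit data). ``sigma=0`` is
    the identity.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return volume.evolve(volume.values.copy(), "nlm", sigma=0.0,
                             patch_size=_NLM_PATCH_SIZE, patch_distance=_NLM_PATCH_DISTANCE)
    out = denoise_nl_means(
        volume.values.astype(np.float64),
        h=0.8 * sigma,
        sigma=sigma,
        patch_size=_NLM_PATCH_SIZE,
        patch_distance=_NLM_PATCH_DISTANCE,
        fast_mode=True,
    )
    out = np.clip(out, 0, volume.domain_max).astype(np.float32)
    return volume.evolve(out, "nlm", sigma=float(sigma),
                         patch_size=_NLM_PATCH_SIZE, patch_distance=_NLM_PATCH_DISTANCE)


def gaussian_smooth(volume: VolumeGrid, sigma_nm) -> VolumeGrid:
    """Gaussian blur with a physical smoothing scale.

    ``sigma_nm`` is a scalar or per-axis (z, y, x) scale in nanometres,
    converted to voxel units through the voxel size, so anisotropic stacks
    are smoothed isotropically in physical space. Boundary mode is reflect,
    which conserves total intensity.
    """
    sig = np.broadcast_to(np.asarray(sigma_nm, dtype=float), (3,))
    if np.any(sig < 0):
        raise ValueError("sigma_nm must be >= 0")
    if np.all(sig == 0):
        return volume.evolve(volume.values.copy(), "gaussian", sigma_nm=tuple(sig), mode="reflect")
    vs = volume.require_voxel_size()
    sigma_vox = [s / v for s, v in zip(sig, vs)]
    out = ndi.gaussian_filter(volume.values.astype(np.float64), sigma=sigma_vox, mode="reflect")
    out = np.clip(out, 0, volume.domain_max).astype(np.float32)
    return volume.evolve(out, "gaussian", sigma_nm=tuple(float(s) for s in sig), mode="reflect")


def sharpen(volume: VolumeGrid, radius_nm: float = 50.0, amount: float = 0.5) -> VolumeGrid:
    """Unsharp masking. Exposed for presentation parity; OFF by default and
    not part of the segmentation pipeline."""
    blurred = gaussian_smooth(volume, radius_nm)
    out = volume.values + amount * (volume.values - blurred.values)
    out = np.clip(out, 0, volume.domain_max).astype(np.float32)
    return volume.evolve(out, "sharpen", radius_nm=float(radius_nm), amount=float(amount))


def bin_volume(volume: VolumeGrid, factors: tuple[int, int, int]) -> VolumeGrid:
    """Downsample by integer block-averaging.

    ``factors`` are in (z, y, x) order; the 3×3×1 in-plane binning used on
    the SBEM datasets (stated in (x, y, z) display order) is ``(1, 3, 3)``
    here. Each output voxel is the mean of its factor block, so intensity
    ranges stay comparable before and after binning; trailing voxels that do
    not fill a block are dropped, and the voxel size is multiplied by the
    factors.
    """
    fz, fy, fx = (int(f) for f in factors)
    if min(fz, fy, fx) < 1:
        raise ValueError(f"factors must be >= 1; got {factors}")
    nz, ny, nx = volume.shape
    if fz > nz or fy > ny or fx > nx:
        raise ValueError(f"factors {factors} exceed grid extents {volume.shape}")
    mz, my, mx = nz // fz, ny // fy, nx // fx
    v = volume.values[: mz * fz, : my * fy, : mx * fx].astype(np.float64)
    out = v.reshape(mz, fz, my, fy, mx, fx).mean(axis=(1, 3, 5)).astype(np.float32)
    new_vs = None
    if volume.voxel_size is not None:
        new_vs = tuple(s * f for s, f in zip(volume.voxel_size, (fz, fy, fx)))
    return volume.evolve(out, "bin", voxel_size=new_vs, factors=(fz, fy, fx))


def true_range(volume: VolumeGrid, nominal: bool = False) -> IntensityRange:
    """The "true range" of a volume: its observed minimum and maximum.

    This is the data-driven span whose width parameterises seed-trial steps
    (each trial step is a fixed 0.2-0.4% fraction of it). With
    ``nominal=True`` the full bit-depth domain is returned instead.
    """
    if volume.values.size == 0:
        raise ValueError("cannot take the range of an empty volume")
    if nominal:
        return IntensityRange(0.0, volume.domain_max)
    return IntensityRange(float(volume.values.min()), float(volume.values.max()))


def preprocess_pipeline(
    volume: VolumeGrid,
    nlm_sigma: float = 0.0,
    bin_factors: tuple[int, int, int] = (1, 1, 1),
    gaussian_sigma_nm: float = 0.0,
    order: str = "nlm-bin",
) -> VolumeGrid:
    """Compose the standard pre-processing: NLM, then binning (default order).

    ``order`` is ``"nlm-bin"`` or ``"bin-nlm"``; Gaussian smoothing, when
    requested, always runs last on the working volume.
    """
    if order not in ("nlm-bin", "bin-nlm"):
        raise ValueError(f"unknown order {order!r}")
    steps = [
        ("nlm", lambda v: denoise_nlm(v, nlm_sigma) if nlm_sigma > 0 else v),
        ("bin", lambda v: bin_volume(v, bin_factors) if tuple(bin_factors) != (1, 1, 1) else v),
    ]
    if order == "bin-nlm":
        steps.reverse()
    out = volume
    for _name, f in steps:
        out = f(out)
    if np.any(np.asarray(gaussian_sigma_nm) > 0):
        out = gaussian_smooth(out, gaussian_sigma_nm)
    return out
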