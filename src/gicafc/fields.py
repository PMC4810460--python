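"""Smoothed Gaussian random fields on voxel grids.

Shared by the synthetic-data generator (subject noise maps) and the
Monte-Carlo cluster-extent calibration, which must assume the same
spatial noise model.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import gaussian_filter

FWHM_TO_SIGMA = 1.0 / np.sqrt(8.0 * np.log(2.0))  # sigma = FWHM / 2.3548


def fwhm_to_sigma_voxels(fwhm_mm: float, voxel_size_mm: float) -> float:
    if voxel_size_mm <= 0:
        raise ValueError("voxel size must be positive")
    return fwhm_mm * FWHM_TO_SIGMA / voxel_size_mm


def smooth_field(field: np.ndarray, fwhm_mm: float, voxel_size_mm: float) -> np.ndarray:
    """Gaussian-smooth a 3D field; FWHM = 0 is the identity."""
    if fwhm_mm == 0:
        return field
    return gaussian_filter(field, sigma=fwhm_to_sigma_voxels(fwhm_mm, voxel_size_mm))


def standardized_noise_field(shape: tuple[int, int, int], fwhm_mm: float,
                             voxel_size_mm: float, mask: np.ndarray,
                             rng: np.random.Generator) -> np.ndarray:
    """White noise, smoothed, then re-standardized to unit SD within the mask.

    Re-standardizing after smoothing makes per-voxel thresholds calibrated
    on unit-variance values applicable regardless of the smoothing kernel.
    """
    f = smooth_field(rng.standard_normal(shape), fwhm_mm, voxel_size_mm)
    vals = f[mask]
    sd = vals.std()
    if sd == 0:
        raise ValueError("degenerate field")
    return (f - vals.mean()) / sd
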