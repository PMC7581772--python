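"""Image preprocessing: bias-field correction, percentile normalization, crop.

The pipeline order used throughout the package is bias -> normalize -> crop,
and each step records itself in the volume's provenance.  Normalization maps
each volume to [0, 1] using its own 2.5th and 97.5th intensity percentiles
with clipping, so inference on a single new scan is self-contained.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volume import Volume

__all__ = [
    "NormalizationSpec",
    "correct_bias",
    "normalize_percentile",
    "crop_to_input",
]


@dataclass(frozen=True)
class NormalizationSpec:
    """Percentile window for intensity normalization (per volume)."""

    lo_percentile: float = 2.5
    hi_percentile: float = 97.5

    def __post_init__(self) -> None:
        if not (0.0 <= self.lo_percentile < self.hi_percentile <= 100.0):
            raise ValueError("need 0 <= lo < hi <= 100")


def _polynomial_design(shape, mask, order: int) -> np.ndarray:
    coords = [np.linspace(-1.0, 1.0, n) for n in shape]
    x, y, z = np.meshgrid(*coords, indexing="ij")
    cols = []
    for total in range(order + 1):
        for i in range(total + 1):
            for j in range(total - i + 1):
                k = total - i - j
                cols.append((x**i * y**j * z**k)[mask])
    return np.stack(cols, axis=1)


def correct_bias(
    volume: Volume,
    method: str = "surrogate_polynomial",
    poly_order: int = 3,
    shift: float | str | None = None,
) -> Volume:
    """Remove a smooth multiplicative intensity inhomogeneity.

    ``surrogate_polynomial`` (default) fits a low-order polynomial to the
    log-intensities of the bright foreground voxels and divides it out; the
    mean over the foreground is re-anchored so the overall gain is unchanged.
    Restricting the fit to the brighter half of the foreground keeps the dark
    fibroglandular compartment from dragging the estimate — the bias is read
    off the dominant (fat) tissue class, whose intensity is spatially flat
    apart from the field itself.

    ``external_n4`` delegates to SimpleITK's N4 implementation and records it
    in the provenance.

    Intensities must be strictly positive for the log-domain fit; pass a
    numeric ``shift`` to offset a volume that touches zero, or
    ``shift="auto"`` to offset just above zero (the shift is removed again
    after correction).
    """
    if poly_order < 0:
        raise ValueError("poly_order must be >= 0")
    values = np.asarray(volume.values, dtype=np.float64)
    applied_shift = 0.0
    if shift == "auto":
        lo = values.min()
        applied_shift = max(0.0, -lo) + 1e-3 * max(np.ptp(values), 1e-12)
    elif shift is not None:
        applied_shift = float(shift)
    values = values + applied_shift
    if method == "external_n4":
        import SimpleITK as sitk

        img = sitk.GetImageFromArray(values)
        img.SetSpacing((volume.voxel_size_mm,) * 3)
        corrected = sitk.GetArrayFromImage(sitk.N4BiasFieldCorrection(img))
        return volume.with_values(corrected, "bias:n4")
    if method != "surrogate_polynomial":
        raise ValueError(f"unknown bias-correction method: {method!r}")
    if values.min() <= 0:
        raise ValueError(
            "non-positive intensities: pass shift= to offset before the log-domain fit"
        )
    # foreground = clearly-above-air voxels; fit on its brighter half
    threshold = 0.25 * np.percentile(values, 97.5)
    foreground = values > threshold
    if not foreground.any():
        raise ValueError("no foreground voxels above the air threshold")
    bright = values >= np.median(values[foreground])
    fit_mask = foreground & bright
    if not fit_mask.any():
        fit_mask = foreground
    design = _polynomial_design(values.shape, fit_mask, poly_order)
    logv = np.log(values[fit_mask])
    coeffs, *_ = np.linalg.lstsq(design, logv, rcond=None)
    full = _polynomial_design(values.shape, np.ones(values.shape, dtype=bool), poly_order)
    log_bias = (full @ coeffs).reshape(values.shape)
    bias = np.exp(log_bias - log_bias[foreground].mean())  # unit gain on foreground
    corrected = values / bias
    corrected *= values[foreground].mean() / corrected[foreground].mean()
    corrected -= applied_shift
    return volume.with_values(corrected, f"bias:poly{poly_order}")


def normalize_percentile(volume: Volume, spec: NormalizationSpec = NormalizationSpec()) -> Volume:
    """Clip-and-rescale intensities to [0, 1] by per-volume percentiles.

    Output = clip((x - p_lo) / (p_hi - p_lo), 0, 1) with p_lo, p_hi the
    per-volume percentiles under the linear-interpolation quantile
    convention.  A constant volume has p_lo == p_hi and is rejected.
    """
    values = np.asarray(volume.values, dtype=np.float64)
    p_lo, p_hi = np.percentile(values, [spec.lo_percentile, spec.hi_percentile])
    if p_hi == p_lo:
        raise ValueError("degenerate volume: percentile window has zero width")
    out = np.clip((values - p_lo) / (p_hi - p_lo), 0.0, 1.0)
    return volume.with_values(
        out, f"normalize:p[{spec.lo_percentile},{spec.hi_percentile}]"
    )


def crop_to_input(
    volume: Volume,
    breast_box: tuple[tuple[int, int, int], tuple[int, int, int]],
    target_shape: tuple[int, int, int] = (128, 128, 128),
    fill_value: float = 0.0,
    mask: np.ndarray | None = None,
):
    """Extract the model-input box and fit it to ``target_shape``.

    The box (corner, shape) is cut out of the grid, then zero-padded or
    center-cropped to the target shape.  When ``mask`` is given it is cropped
    identically and returned alongside.
    """
    corner, shape = breast_box
    values = np.asarray(volume.values)
    for c, s, n in zip(corner, shape, values.shape):
        if c < 0 or c + s > n:
            raise ValueError(f"breast box [{c}, {c + s}) outside grid of extent {n}")
    sl = tuple(slice(c, c + s) for c, s in zip(corner, shape))
    box = values[sl]
    out = np.full(target_shape, fill_value, dtype=box.dtype)
    mask_box = mask[sl] if mask is not None else None
    mask_out = np.zeros(target_shape, dtype=bool) if mask is not None else None
    src_slices, dst_slices = [], []
    for s, t in zip(box.shape, target_shape):
        if s <= t:
            off = (t - s) // 2
            src_slices.append(slice(0, s))
            dst_slices.append(slice(off, off + s))
        else:
            off = (s - t) // 2
            src_slices.append(slice(off, off + t))
            dst_slices.append(slice(0, t))
    out[tuple(dst_slices)] = box[tuple(src_slices)]
    cropped = volume.with_values(out, f"crop:corner={tuple(corner)},target={tuple(target_shape)}")
    if mask is not None:
        mask_out[tuple(dst_slices)] = mask_box[tuple(src_slices)]
        return cropped, mask_out
    return cropped
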