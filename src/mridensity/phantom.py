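"""Synthetic 3D breast-MRI phantoms with exactly known volumetric density.

Each phantom emulates a non-fat-suppressed T1-weighted precontrast breast
volume: bright fat, dark fibroglandular tissue (FGT), a pectoral-muscle slab
and an optional heart-like ellipsoid as confounders, a smooth multiplicative
bias field and additive Gaussian noise.  The FGT compartment is carved out of
the breast by thresholding a smoothed Gaussian random field, which makes the
true volumetric density — 100 * |FGT| / |breast| — exact by construction.

Axis convention (0-based): axis 0 = left-right, axis 1 = anterior->posterior
(increasing index is more posterior), axis 2 = superior->inferior.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .volume import Volume, write_mask, write_volume

__all__ = [
    "PhantomSpec",
    "Phantom",
    "make_breast_geometry",
    "sample_fgt_mask",
    "render_intensities",
    "generate_cohort",
    "default_breast_box",
    "write_cohort",
]

DEFAULT_TISSUE_MEANS = {
    "air": 0.05,
    "fat": 0.85,
    "fgt": 0.30,
    "muscle": 0.35,
    "heart": 0.40,
}


@dataclass(frozen=True)
class PhantomSpec:
    """Recipe for one phantom.

    ``tissue_means`` are arbitrary intensity units encoding the
    non-fat-suppressed T1 contrast (fat bright, FGT dark).  ``bias_amplitude``
    is the maximal fractional deviation of the multiplicative bias field, so
    the field spans exactly [1-A, 1+A].  ``breast_semi_axes`` (voxels) may be
    None, in which case sizes are derived from the grid.
    """

    grid_shape: tuple[int, int, int] = (48, 48, 48)
    voxel_size_mm: float = 1.35
    target_density: float = 15.0
    fgt_correlation_length_mm: float = 5.0
    tissue_means: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TISSUE_MEANS)
    )
    bias_amplitude: float = 0.2
    noise_sigma: float = 0.05
    include_heart: bool = True
    breast_semi_axes: tuple[float, float, float] | None = None
    muscle_thickness_frac: float = 0.08
    heart_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.target_density <= 100.0):
            raise ValueError("target_density must be in [0, 100]")
        if any(int(d) < 8 for d in self.grid_shape):
            raise ValueError("all grid dimensions must be >= 8")
        missing = set(DEFAULT_TISSUE_MEANS) - set(self.tissue_means)
        if missing:
            raise ValueError(f"tissue_means missing compartments: {sorted(missing)}")
        if not self.tissue_means["fat"] > self.tissue_means["fgt"]:
            raise ValueError("fat must be brighter than FGT (non-fat-suppressed T1)")
        if not (0.0 <= self.bias_amplitude < 1.0):
            raise ValueError("bias_amplitude must be in [0, 1)")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if not (0.0 < self.muscle_thickness_frac < 0.4):
            raise ValueError("muscle_thickness_frac must be in (0, 0.4)")
        if self.heart_scale <= 0:
            raise ValueError("heart_scale must be positive")


@dataclass
class Phantom:
    """A rendered phantom plus its exact construction masks and label."""

    volume: Volume
    breast_mask: np.ndarray
    fgt_mask: np.ndarray
    muscle_mask: np.ndarray
    heart_mask: np.ndarray
    true_density: float
    sternum_plane_index: int
    spec: PhantomSpec

    def __post_init__(self) -> None:
        if self.volume.shape != self.breast_mask.shape:
            raise ValueError("volume and masks must share the grid")
        if np.any(self.fgt_mask & ~self.breast_mask):
            raise ValueError("fgt_mask must be a subset of breast_mask")
        if np.any(self.breast_mask & self.muscle_mask):
            raise ValueError("breast and muscle masks must be disjoint")
        n_breast = int(self.breast_mask.sum())
        expected = 100.0 * int(self.fgt_mask.sum()) / n_breast
        if abs(expected - self.true_density) > 1e-9:
            raise ValueError("true_density inconsistent with mask counts")


def _ellipsoid(shape, center, semi_axes) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    acc = np.zeros(shape, dtype=float)
    for g, c, a in zip(grids, center, semi_axes):
        acc = acc + ((g - c) / a) ** 2
    return acc <= 1.0


def _default_semi_axes(grid_shape) -> tuple[float, float, float]:
    n0, n1, n2 = grid_shape
    return (round(0.29 * n0), round(0.27 * n1), round(0.29 * n2))


def make_breast_geometry(spec: PhantomSpec) -> dict:
    """Lay out the anatomy surrogate on the voxel grid.

    The breast is a half-ellipsoid strictly anterior of the chest-wall plane
    (the sternum plane); the pectoral-muscle slab sits immediately posterior
    of that plane; the heart-like ellipsoid lies in the posterior-inferior
    chest.  Returns breast/muscle/heart/body masks (pairwise disjoint apart
    from body containing muscle and heart) and the sternum plane index.
    """
    n0, n1, n2 = (int(d) for d in spec.grid_shape)
    chest_wall = int(round(0.58 * n1))
    muscle_thickness = max(2, int(round(spec.muscle_thickness_frac * n1)))
    semi = spec.breast_semi_axes or _default_semi_axes(spec.grid_shape)
    a, b, c = (float(s) for s in semi)
    center = (0.5 * (n0 - 1), float(chest_wall), 0.5 * (n2 - 1))
    if min(a, b, c) < 1:
        raise ValueError("breast semi-axes must each be >= 1 voxel")
    if b > chest_wall:
        raise ValueError(
            f"breast semi-axis {b} does not fit anterior of chest wall at {chest_wall}"
        )
    if chest_wall + muscle_thickness >= n1:
        raise ValueError("grid too small to contain the pectoral muscle slab")

    y = np.arange(n1)
    breast = _ellipsoid((n0, n1, n2), center, (a, b, c)) & (y < chest_wall)[None, :, None]
    if not breast.any():
        raise ValueError("grid too small: breast mask is empty")

    muscle = np.zeros((n0, n1, n2), dtype=bool)
    muscle[:, chest_wall : chest_wall + muscle_thickness, :] = True

    body = np.zeros((n0, n1, n2), dtype=bool)
    body[:, chest_wall:, :] = True

    heart = np.zeros((n0, n1, n2), dtype=bool)
    if spec.include_heart:
        post_extent = n1 - (chest_wall + muscle_thickness)
        if post_extent < 4:
            raise ValueError("grid too small to contain the heart posterior of muscle")
        h_center = (
            round(0.42 * n0),
            chest_wall + muscle_thickness + post_extent / 2.0,
            round(0.62 * n2),
        )
        h_semi = (
            max(1.0, 0.15 * n0 * spec.heart_scale),
            max(1.0, 0.35 * post_extent * spec.heart_scale),
            max(1.0, 0.15 * n2 * spec.heart_scale),
        )
        heart = _ellipsoid((n0, n1, n2), h_center, h_semi)
        heart &= (y >= chest_wall + muscle_thickness)[None, :, None]

    return {
        "breast_mask": breast,
        "muscle_mask": muscle,
        "heart_mask": heart,
        "body_mask": body,
        "sternum_plane_index": chest_wall,
    }


def sample_fgt_mask(
    breast_mask: np.ndarray,
    target_density: float,
    correlation_length_mm: float,
    voxel_size_mm: float,
    seed: int,
) -> np.ndarray:
    """Carve a fibroglandular compartment of prescribed volume fraction.

    A white-noise Gaussian field is smoothed to the stated correlation length
    and the top ``target_density`` percent of its values inside the breast
    become FGT — i.e. the field is thresholded at its empirical
    (1 - d/100) quantile, which pins the realized density to the target up to
    the integer voxel count.
    """
    if not breast_mask.any():
        raise ValueError("breast_mask is empty")
    if not (0.0 <= target_density <= 100.0):
        raise ValueError("target_density must be in [0, 100]")
    n_breast = int(breast_mask.sum())
    k = int(round(n_breast * target_density / 100.0))
    fgt = np.zeros_like(breast_mask, dtype=bool)
    if k == 0:
        return fgt
    if k >= n_breast:
        return breast_mask.copy()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0]))
    field_ = rng.standard_normal(breast_mask.shape)
    sigma_vox = max(correlation_length_mm / voxel_size_mm, 1e-6)
    field_ = ndimage.gaussian_filter(field_, sigma=sigma_vox)
    inside = field_[breast_mask]
    # top-k selection == empirical-quantile threshold, exact even with ties
    order = np.argsort(inside, kind="stable")
    chosen = np.zeros(n_breast, dtype=bool)
    chosen[order[n_breast - k :]] = True
    fgt[breast_mask] = chosen
    return fgt


def _bias_field(shape, amplitude: float, seed: int) -> np.ndarray:
    """Smooth multiplicative field spanning exactly [1-A, 1+A].

    A random cubic polynomial in normalized coordinates, rescaled so its
    extrema hit the nominal amplitude — smooth, differentiable, cheap.
    """
    if amplitude == 0.0:
        return np.ones(shape)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    coords = [np.linspace(-1.0, 1.0, n) for n in shape]
    x, y, z = np.meshgrid(*coords, indexing="ij")
    poly = np.zeros(shape)
    for powers in _monomial_powers(max_order=3):
        coeff = rng.normal()
        poly = poly + coeff * x ** powers[0] * y ** powers[1] * z ** powers[2]
    lo, hi = poly.min(), poly.max()
    mid, half = 0.5 * (hi + lo), 0.5 * (hi - lo)
    if half == 0:
        return np.ones(shape)
    return 1.0 + amplitude * (poly - mid) / half


def _monomial_powers(max_order: int):
    """Monomial exponent triples with total degree in 1..max_order."""
    for total in range(1, max_order + 1):
        for i in range(total + 1):
            for j in range(total - i + 1):
                yield (i, j, total - i - j)


def render_intensities(masks: dict, fgt_mask: np.ndarray, spec: PhantomSpec) -> Volume:
    """Render the piecewise-constant tissue map, then corrupt it.

    Voxel value = tissue mean of its compartment, multiplied by the bias
    field and plus zero-mean Gaussian noise; deterministic given the spec
    seed.  The chest bulk renders at the fat mean (subcutaneous fat), with
    muscle and heart overwriting it.
    """
    tm = spec.tissue_means
    values = np.full(spec.grid_shape, tm["air"], dtype=np.float64)
    values[masks["body_mask"]] = tm["fat"]
    values[masks["muscle_mask"]] = tm["muscle"]
    values[masks["heart_mask"]] = tm["heart"]
    values[masks["breast_mask"]] = tm["fat"]
    values[fgt_mask] = tm["fgt"]
    values *= _bias_field(spec.grid_shape, spec.bias_amplitude, spec.seed)
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 2]))
        values = values + rng.normal(0.0, spec.noise_sigma, spec.grid_shape)
    return Volume(
        values=values,
        voxel_size_mm=spec.voxel_size_mm,
        provenance=[f"phantom:seed={spec.seed}"],
    )


def make_phantom(spec: PhantomSpec) -> Phantom:
    """Generate one phantom end to end from its spec."""
    geo = make_breast_geometry(spec)
    fgt = sample_fgt_mask(
        geo["breast_mask"],
        spec.target_density,
        spec.fgt_correlation_length_mm,
        spec.voxel_size_mm,
        spec.seed,
    )
    volume = render_intensities(geo, fgt, spec)
    n_breast = int(geo["breast_mask"].sum())
    true_density = 100.0 * int(fgt.sum()) / n_breast
    return Phantom(
        volume=volume,
        breast_mask=geo["breast_mask"],
        fgt_mask=fgt,
        muscle_mask=geo["muscle_mask"],
        heart_mask=geo["heart_mask"],
        true_density=true_density,
        sternum_plane_index=geo["sternum_plane_index"],
        spec=spec,
    )


def default_breast_box(phantom: Phantom, target_shape=(32, 32, 32)):
    """Model-input box: breast centered in the anterior half, chest posterior.

    The box is centered on the breast left-right and superior-inferior, and
    on the sternum plane along the anterior-posterior axis, so that roughly
    the anterior half contains the breast and the posterior half the
    confounders.  Clamped to the grid; returns (corner, shape).
    """
    grid = phantom.volume.shape
    idx = np.argwhere(phantom.breast_mask)
    c0 = 0.5 * (idx[:, 0].min() + idx[:, 0].max())
    c2 = 0.5 * (idx[:, 2].min() + idx[:, 2].max())
    center = (c0, float(phantom.sternum_plane_index), c2)
    corner = []
    shape = []
    for ctr, t, n in zip(center, target_shape, grid):
        t = min(int(t), int(n))
        lo = int(round(ctr - t / 2))
        lo = max(0, min(lo, n - t))
        corner.append(lo)
        shape.append(t)
    return tuple(corner), tuple(shape)


def generate_cohort(
    n: int,
    density_range: tuple[float, float],
    template: PhantomSpec,
    seed: int,
) -> tuple[list[Phantom], pd.DataFrame]:
    """Generate a cohort of phantoms with uniformly drawn target densities.

    Target densities are uniform in ``density_range``; breast semi-axes vary
    phantom-to-phantom (factors 0.85-1.05 of the template's); every phantom
    gets an independent seed derived from the master seed.  Returns the
    phantoms and a labels table with one row per phantom (id, true_density),
    ids ranked by generation order.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    lo, hi = density_range
    if not (0.0 <= lo <= hi <= 100.0):
        raise ValueError("density_range must satisfy 0 <= lo <= hi <= 100")
    rng = np.random.default_rng(seed)
    base_semi = template.breast_semi_axes or _default_semi_axes(template.grid_shape)
    phantoms: list[Phantom] = []
    rows = []
    for i in range(n):
        target = float(rng.uniform(lo, hi))
        factors = rng.uniform(0.85, 1.05, size=3)
        semi = tuple(float(s * f) for s, f in zip(base_semi, factors))
        child_seed = int(rng.integers(0, 2**31))
        spec = replace(
            template,
            target_density=target,
            breast_semi_axes=semi,
            seed=child_seed,
        )
        ph = make_phantom(spec)
        phantoms.append(ph)
        rows.append({"id": f"p{i:04d}", "true_density": ph.true_density})
    return phantoms, pd.DataFrame(rows)


def write_cohort(phantoms: list[Phantom], labels: pd.DataFrame, outdir, master_seed: int) -> None:
    """Persist a cohort: NIfTI volumes+masks, labels CSV, JSON manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for pid, ph in zip(labels["id"], phantoms):
        write_volume(ph.volume, outdir / f"{pid}.nii.gz")
        write_mask(ph.breast_mask, ph.spec.voxel_size_mm, outdir / f"{pid}_breast.nii.gz")
        write_mask(ph.fgt_mask, ph.spec.voxel_size_mm, outdir / f"{pid}_fgt.nii.gz")
    labels.to_csv(outdir / "labels.csv", index=False)
    spec0 = phantoms[0].spec
    manifest = {
        "master_seed": master_seed,
        "n": len(phantoms),
        "grid_shape": list(spec0.grid_shape),
        "voxel_size_mm": spec0.voxel_size_mm,
        "tissue_means": spec0.tissue_means,
        "bias_amplitude": spec0.bias_amplitude,
        "noise_sigma": spec0.noise_sigma,
        "ids": list(labels["id"]),
        "sternum_plane_index": [ph.sternum_plane_index for ph in phantoms],
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
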