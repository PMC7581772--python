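"""Voxel-wise Shapley-additive explanations of a density estimate.

Contributions are computed by DeepLIFT rescale-rule backpropagation against
a background input and averaged over a background set sampled from the
training cohort (the Deep-SHAP estimator).  Per background pair the
contributions satisfy summation-to-delta (local accuracy): they add up to
model(x) - model(b).  The sign convention follows the regression head:
positive attribution on a voxel means it pushed the density estimate up.

The QC operation turns the qualitative reading of attribution overlays into
a statistic: the fraction of total absolute attribution that falls inside
the breast mask, flagging estimates that lean on confounders such as the
pectoral muscle or the heart.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .density_cnn import TrainedModel
from .volume import Volume

__all__ = [
    "AttributionMap",
    "BackgroundSet",
    "QCReport",
    "deeplift_contributions",
    "shap_map",
    "sample_backgrounds",
    "attribution_qc",
    "render_overlay",
]


@dataclass
class AttributionMap:
    shap_values: np.ndarray        # signed, on the model-input grid
    base_value: float              # mean model output over backgrounds
    prediction: float              # model output on the explained volume
    n_backgrounds: int
    completeness_residual: float   # |sum(shap) - (prediction - base_value)|


@dataclass
class BackgroundSet:
    volumes: list[np.ndarray]
    ids: list[str]
    seed: int

    def __post_init__(self) -> None:
        if len(self.volumes) < 1:
            raise ValueError("background set must contain at least one volume")


@dataclass
class QCReport:
    inside_fraction: float
    flagged: bool
    threshold: float
    degenerate: bool = False


def _as_input(model: TrainedModel, v) -> np.ndarray:
    values = np.asarray(v.values if isinstance(v, Volume) else v, dtype=np.float64)
    if tuple(values.shape) != tuple(model.config.input_shape):
        raise ValueError(
            f"shape {tuple(values.shape)} does not match model input "
            f"{tuple(model.config.input_shape)}"
        )
    return values


def deeplift_contributions(model: TrainedModel, x, b) -> np.ndarray:
    """Per-voxel contributions of x relative to background b.

    Rescale-rule backpropagation: linear/conv layers pass multipliers through
    their weights; each nonlinearity multiplies by the secant slope between
    its pre-activations on x and on b (derivative fallback when the two are
    nearly equal).  The returned grid satisfies
    sum(C) = model(x) - model(b) up to floating-point error.
    """
    xv = _as_input(model, x)
    bv = _as_input(model, b)
    net = model.network
    out_x, caches_x = net.forward_with_caches(xv[None, None])
    out_b, caches_b = net.forward_with_caches(bv[None, None])
    if not (np.all(np.isfinite(out_x)) and np.all(np.isfinite(out_b))):
        raise FloatingPointError("non-finite activations during attribution")
    m = np.ones((1, 1))
    m_in = net.backprop_multipliers(m, caches_x, caches_b)
    return m_in[0, 0] * (xv - bv)


def shap_map(model: TrainedModel, x, backgrounds: BackgroundSet) -> AttributionMap:
    """Deep-SHAP map: mean of per-background DeepLIFT contributions.

    ``base_value`` is the mean model output over the background set, so the
    map's voxels sum to prediction - base_value up to the stored
    completeness residual.
    """
    xv = _as_input(model, x)
    contribs = np.zeros_like(xv)
    base = 0.0
    net = model.network
    out_x, caches_x = net.forward_with_caches(xv[None, None])
    prediction = float(out_x[0, 0])
    for bv in backgrounds.volumes:
        bvv = _as_input(model, bv)
        out_b, caches_b = net.forward_with_caches(bvv[None, None])
        base += float(out_b[0, 0])
        m_in = net.backprop_multipliers(np.ones((1, 1)), caches_x, caches_b)
        contribs += m_in[0, 0] * (xv - bvv)
    n = len(backgrounds.volumes)
    contribs /= n
    base /= n
    residual = abs(float(contribs.sum()) - (prediction - base))
    return AttributionMap(
        shap_values=contribs,
        base_value=base,
        prediction=prediction,
        n_backgrounds=n,
        completeness_residual=residual,
    )


def sample_backgrounds(
    volumes: dict[str, np.ndarray], train_ids, n: int = 15, seed: int = 0
) -> BackgroundSet:
    """Sample n distinct training volumes (without replacement) as the
    background signal for Deep SHAP."""
    train_ids = list(train_ids)
    if n > len(train_ids):
        raise ValueError(f"cannot sample {n} backgrounds from {len(train_ids)} training volumes")
    rng = np.random.default_rng(seed)
    chosen = [train_ids[i] for i in rng.choice(len(train_ids), size=n, replace=False)]
    return BackgroundSet(volumes=[volumes[i] for i in chosen], ids=chosen, seed=seed)


def attribution_qc(amap: AttributionMap, breast_mask: np.ndarray, threshold: float = 0.8) -> QCReport:
    """Fraction of absolute attribution inside the breast; flag if low.

    An estimate whose attribution mass sits largely outside the breast —
    on the pectoral muscle or the heart — is flagged so those regions can be
    reviewed or excluded.  An all-zero map makes the fraction undefined and
    is reported as degenerate (and flagged).
    """
    if breast_mask.shape != amap.shap_values.shape:
        raise ValueError("breast mask must live on the attribution grid")
    total = float(np.abs(amap.shap_values).sum())
    if total == 0.0:
        return QCReport(inside_fraction=float("nan"), flagged=True, threshold=threshold, degenerate=True)
    inside = float(np.abs(amap.shap_values[breast_mask]).sum())
    frac = inside / total
    return QCReport(inside_fraction=frac, flagged=frac < threshold, threshold=threshold)


def render_overlay(volume_values: np.ndarray, amap: AttributionMap, path, sagittal_index: int | None = None) -> None:
    """Sagittal slice with the signed attribution map superimposed (PNG)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    i = sagittal_index if sagittal_index is not None else volume_values.shape[0] // 2
    img = volume_values[i].T
    shap_slice = amap.shap_values[i].T
    vmax = np.abs(shap_slice).max() or 1.0
    fig, axes = plt.subplots(1, 3, figsize=(12, 4))
    axes[0].imshow(img, cmap="gray")
    axes[0].set_title("precontrast (sagittal)")
    axes[1].imshow(img, cmap="gray")
    axes[1].imshow(shap_slice, cmap="seismic", vmin=-vmax, vmax=vmax, alpha=0.5)
    axes[1].set_title("overlay")
    im = axes[2].imshow(shap_slice, cmap="seismic", vmin=-vmax, vmax=vmax)
    axes[2].set_title("SHAP values")
    fig.colorbar(im, ax=axes[2], shrink=0.8)
    for ax in axes:
        ax.axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
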