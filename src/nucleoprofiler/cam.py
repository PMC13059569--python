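"""Score-CAM heatmaps and their nuclear quantification.

Score-CAM is a gradient-free class-activation mapping: each spatial
activation map of a target convolutional layer is upsampled to input size,
min-max normalized, used to mask the input, and the masked input's forward
pass supplies the map's class score; the heatmap is the ReLU of the
score-softmax-weighted sum of the normalized maps.

Heatmaps are quantified with two nucleus-referenced metrics:

* nuclear intensity — the mean heatmap score over the nonzero pixels of the
  nucleus mask, ``(1/|M|) * sum_{p in M} S(p)`` with
  ``M = {p in mask : S(p) > 0}``;
* nuclear periphery enrichment — the mean score over *all* pixels of the
  outermost concentric zone (part5, the periphery), divided by the nuclear
  intensity. The numerator includes zero-score pixels while the denominator
  excludes them; the asymmetry is part of the metric's definition and is
  implemented verbatim.

Group-average heatmaps are built by rotating and anisotropically rescaling
each heatmap so its fitted nucleus ellipse lands on a canonical
axis-aligned ellipse, then averaging pixel-wise. Alignment is used for
visualization only; per-cell metrics are computed in original coordinates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.feature import canny
from skimage.filters import sobel
from skimage.measure import regionprops, shannon_entropy
from skimage.transform import resize

from . import nn
from .geometry import EllipseFit, ZonePartition, fit_ellipse, roundness
from .classifier import ResidualCNN

__all__ = [
    "CamHeatmap",
    "score_cam",
    "nuclear_intensity",
    "periphery_enrichment",
    "align_and_average",
    "cam_feature_battery",
    "FEATURE_CATEGORIES",
    "BATTERY_VERSION",
]

# canonical semi-axes for group-average alignment, px
CANONICAL_AXES = (150.0, 100.0)
BATTERY_VERSION = "1.0"


@dataclass
class CamHeatmap:
    """Nonnegative per-pixel Score-CAM scores tied to a nucleus mask."""

    scores: np.ndarray
    mask: np.ndarray
    ellipse: EllipseFit | None = None

    def __post_init__(self) -> None:
        if self.scores.shape != self.mask.shape:
            raise ValueError("scores and mask shapes differ")
        if (self.scores < 0).any():
            raise ValueError("Score-CAM scores must be nonnegative (post-ReLU)")

    def with_ellipse(self) -> "CamHeatmap":
        if self.ellipse is None:
            self.ellipse = fit_ellipse(self.mask)
        return self


def score_cam(model: ResidualCNN, image: np.ndarray, mask: np.ndarray,
              target_class: int = 1, batch_size: int = 32) -> CamHeatmap:
    """Compute the Score-CAM heatmap of a (3, H, W) input.

    The target layer is the model's last convolutional block output (its K
    spatial activation maps). For a binary single-logit model the class
    score of a masked forward pass is ``sigmoid(logit)`` for class 1 and
    ``sigmoid(-logit)`` for class 0. Constant (zero-range) activation maps
    carry no spatial information and are skipped with a warning.
    """
    image = np.asarray(image, dtype=np.float32)
    if image.ndim != 3:
        raise ValueError("expected a (C, H, W) input image")
    _, h, w = image.shape
    _, acts = model.forward(image[None], train=False, return_activations=True)
    maps = acts[0]  # (K, h', w')
    k = maps.shape[0]
    norm_maps = np.zeros((k, h, w), dtype=np.float32)
    keep = []
    for i in range(k):
        m = maps[i]
        rng_ = m.max() - m.min()
        if rng_ <= 0:
            warnings.warn(f"activation map {i} is constant; skipped",
                          stacklevel=2)
            continue
        up = resize(m.astype(np.float64), (h, w), order=1, mode="reflect",
                    anti_aliasing=False)
        norm_maps[i] = ((up - up.min()) / (up.max() - up.min())).astype(np.float32)
        keep.append(i)
    if not keep:
        return CamHeatmap(scores=np.zeros((h, w)), mask=np.asarray(mask, bool))

    scores = np.empty(len(keep), dtype=np.float64)
    for start in range(0, len(keep), batch_size):
        chunk = keep[start:start + batch_size]
        masked = image[None] * norm_maps[chunk][:, None, :, :]
        logits = model.forward(masked, train=False)
        probs = nn.sigmoid(logits if target_class == 1 else -logits)
        scores[start:start + len(chunk)] = probs
    weights = np.exp(scores - scores.max())
    weights /= weights.sum()
    heat = np.tensordot(weights, norm_maps[keep], axes=(0, 0))
    heat = np.maximum(heat, 0.0)
    return CamHeatmap(scores=heat, mask=np.asarray(mask, bool))


def nuclear_intensity(heatmap: CamHeatmap) -> float | None:
    """Mean score over nonzero mask pixels; None when no pixel qualifies."""
    if not heatmap.mask.any():
        raise ValueError("empty nucleus mask")
    inside = heatmap.scores[heatmap.mask]
    nz = inside[inside > 0]
    if nz.size == 0:
        return None
    return float(nz.mean())


def periphery_enrichment(heatmap: CamHeatmap,
                         partition: ZonePartition) -> float | None:
    """Mean score over all part5 pixels divided by the nuclear intensity."""
    denom = nuclear_intensity(heatmap)
    if denom is None:
        return None
    r5 = partition.zone_mask(5)
    if not r5.any():
        raise ValueError("empty periphery zone in partition")
    return float(heatmap.scores[r5].mean() / denom)


def _alignment_coords(ellipse: EllipseFit, out_shape: tuple[int, int],
                      canonical: tuple[float, float]) -> np.ndarray:
    a0, b0 = canonical
    rc, cc = out_shape[0] / 2.0, out_shape[1] / 2.0
    rr, cols = np.meshgrid(np.arange(out_shape[0]), np.arange(out_shape[1]),
                           indexing="ij")
    # canonical frame: major axis along columns
    u = (cols - cc) / a0   # normalized major-axis coordinate
    v = (rr - rc) / b0     # normalized minor-axis coordinate
    ct, st = np.cos(ellipse.orientation), np.sin(ellipse.orientation)
    # major unit vector (row, col) = (cos t, sin t); minor = (-sin t, cos t)
    src_r = ellipse.center[0] + u * ellipse.semi_major * ct \
        - v * ellipse.semi_minor * st
    src_c = ellipse.center[1] + u * ellipse.semi_major * st \
        + v * ellipse.semi_minor * ct
    return np.stack([src_r, src_c])


def align_heatmap(heatmap: CamHeatmap,
                  canonical: tuple[float, float] = CANONICAL_AXES,
                  out_shape: tuple[int, int] | None = None
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Resample one heatmap onto the canonical ellipse frame.

    Returns (aligned scores, aligned mask). Scores are interpolated
    bilinearly, the mask with nearest neighbor.
    """
    hm = heatmap.with_ellipse()
    if out_shape is None:
        side = int(2 * max(canonical) + 41)
        out_shape = (side, side)
    coords = _alignment_coords(hm.ellipse, out_shape, canonical)
    scores = ndimage.map_coordinates(hm.scores, coords, order=1,
                                     mode="constant", cval=0.0)
    mask = ndimage.map_coordinates(hm.mask.astype(np.uint8), coords, order=0,
                                   mode="constant", cval=0)
    return scores, mask.astype(bool)


def align_and_average(heatmaps: list[CamHeatmap],
                      canonical: tuple[float, float] = CANONICAL_AXES
                      ) -> np.ndarray:
    """Pixel-wise mean of ellipse-aligned heatmaps (group-level average)."""
    if not heatmaps:
        raise ValueError("empty heatmap list")
    acc = None
    for hm in heatmaps:
        aligned, _ = align_heatmap(hm, canonical)
        acc = aligned if acc is None else acc + aligned
    return acc / len(heatmaps)


FEATURE_CATEGORIES: dict[str, str] = {
    # Size
    "area": "Size", "major_axis_length": "Size", "minor_axis_length": "Size",
    "equivalent_diameter": "Size", "perimeter": "Size",
    # Shape
    "roundness": "Shape", "eccentricity": "Shape", "solidity": "Shape",
    "extent": "Shape",
    # Intensity
    "intensity_mean": "Intensity", "intensity_sd": "Intensity",
    "intensity_median": "Intensity", "intensity_p10": "Intensity",
    "intensity_p90": "Intensity", "intensity_max": "Intensity",
    # Edge
    "canny_edge_count": "Edge", "edge_density": "Edge",
    "gradient_mean": "Edge", "gradient_sd": "Edge",
    # Texture
    "haralick_contrast": "Texture", "haralick_correlation": "Texture",
    "haralick_energy": "Texture", "haralick_homogeneity": "Texture",
    "entropy": "Texture",
}


def cam_feature_battery(heatmap: CamHeatmap) -> dict[str, float]:
    """A frozen, versioned battery of standard image features of a heatmap.

    Features span five categories (Size, Shape, Intensity, Edge, Texture)
    computed over the nucleus mask region of the heatmap; see
    ``FEATURE_CATEGORIES`` for the name -> category map and
    ``BATTERY_VERSION`` for the battery version. Texture descriptors use a
    32-level gray-level co-occurrence matrix (distance 1, 4 directions
    averaged) plus Shannon entropy.
    """
    from skimage.feature import graycomatrix, graycoprops

    mask = heatmap.mask
    if not mask.any():
        raise ValueError("empty nucleus mask")
    scores = heatmap.scores
    inside = scores[mask]

    rp = regionprops(mask.astype(np.uint8))[0]
    feats: dict[str, float] = {
        "area": float(rp.area),
        "major_axis_length": float(rp.axis_major_length),
        "minor_axis_length": float(rp.axis_minor_length),
        "equivalent_diameter": float(rp.equivalent_diameter_area),
        "perimeter": float(rp.perimeter),
        "roundness": roundness(mask),
        "eccentricity": float(rp.eccentricity),
        "solidity": float(rp.solidity),
        "extent": float(rp.extent),
        "intensity_mean": float(inside.mean()),
        "intensity_sd": float(inside.std()),
        "intensity_median": float(np.median(inside)),
        "intensity_p10": float(np.percentile(inside, 10)),
        "intensity_p90": float(np.percentile(inside, 90)),
        "intensity_max": float(inside.max()),
    }

    # normalize scores to [0, 1] for edge/texture operators
    rng_ = inside.max() - inside.min()
    norm = np.zeros_like(scores)
    if rng_ > 0:
        norm[mask] = (inside - inside.min()) / rng_
    edges = canny(norm, sigma=1.0) & mask
    grad = sobel(norm)[mask]
    feats["canny_edge_count"] = float(edges.sum())
    feats["edge_density"] = float(edges.sum() / rp.area)
    feats["gradient_mean"] = float(grad.mean())
    feats["gradient_sd"] = float(grad.std())

    levels = 32
    quant = np.zeros(scores.shape, dtype=np.uint8)
    quant[mask] = np.clip((norm[mask] * (levels - 1)).astype(int), 0,
                          levels - 1) + 1
    glcm = graycomatrix(quant, distances=[1],
                        angles=[0, np.pi / 4, np.pi / 2, 3 * np.pi / 4],
                        levels=levels + 1, symmetric=True, normed=False)
    glcm = glcm[1:, 1:, :, :].astype(np.float64)  # drop background level
    total = glcm.sum(axis=(0, 1), keepdims=True)
    total[total == 0] = 1.0
    glcm = glcm / total
    def _prop(name: str) -> float:
        vals = graycoprops(glcm, name)
        return float(np.mean(vals))
    feats["haralick_contrast"] = _prop("contrast")
    feats["haralick_correlation"] = _prop("correlation")
    feats["haralick_energy"] = _prop("energy")
    feats["haralick_homogeneity"] = _prop("homogeneity")
    feats["entropy"] = float(shannon_entropy(quant[mask]))
    return feats
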