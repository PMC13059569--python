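"""Synthetic single-nucleus image generator with known ground truth.

Emulates single-nucleus crops from high-speed spinning-disk super-resolution
(SoRa-class) imaging of nuclei stained for two punctate chromatin markers
(H3K27ac, CTCF) plus a DNA channel: an elliptical nucleus containing bright
diffraction-limited foci, with controllable puncta count, size, brightness,
radial placement over five concentric zones, inter-channel colocalization,
background and noise. Every generated image carries a :class:`GroundTruth`
record of the sampled ellipse and puncta parameters, so segmentation,
colocalization and classification stages can be scored against truth.

All generators are pure functions of (config, seed): the same pair yields
bit-identical output.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

from .geometry import EllipseFit, elliptical_radius, partition_zones

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "NucleusImage",
    "generate_nucleus",
    "generate_dataset",
    "generate_multicell_field",
    "write_nucleus_tiff",
    "match_puncta",
]

CHANNELS = ("H3K27ac", "CTCF", "DNA")


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic nucleus model.

    Defaults emulate a single-nucleus super-resolution crop: a 600x600 px
    canvas at 50 nm/px, a nucleus of ~10-14 um extent, and a few tens of
    sub-diffraction foci per marker channel.

    Attributes
    ----------
    canvas_size : int
        Side of the square canvas in pixels.
    pixel_pitch_nm : float
        Physical pixel size in nm (reported pitch of the source data ranges
        from ~20 to ~50 nm depending on acquisition; configurable, never
        hard-coded downstream).
    ellipse_semi_axes : ((float, float), (float, float))
        Uniform sampling ranges (lo, hi) for the semi-major and semi-minor
        axis in pixels.
    puncta_count : ((float, float), (float, float))
        Per-channel (mean, dispersion) of the puncta count for the two
        marker channels. The dispersion is a Fano factor (variance / mean):
        0 gives a fixed count of round(mean), 1 gives Poisson, > 1 gives a
        negative binomial with that variance inflation. A mean of 0 gives
        an empty channel.
    puncta_radius : (float, float)
        Uniform range of punctum effective radius in px; the rendered focus
        is an isotropic 2D Gaussian with sigma = radius / 2 (a PSF-smoothed
        spot rather than a hard disc).
    puncta_peak : (float, float)
        Uniform range of punctum peak amplitude in image units.
    zone_weights : tuple of 5 floats
        Radial placement probabilities over the five concentric elliptical
        zones part1..part5 (must sum to 1); position is uniform within the
        chosen zone.
    coloc_fraction : float
        Share rho of channel-2 (CTCF) puncta placed at channel-1 centroids.
    coloc_jitter : float
        Isotropic Gaussian jitter (px std) applied to colocalized placements.
    background_level, noise_sigma : float
        Additive background and Gaussian read-noise std, image units.
    min_separation : float
        Minimum centroid separation enforced within each channel by
        rejection sampling (0 disables).
    noise_model : str
        "gaussian" (default) or "poisson" (shot noise on the noiseless
        signal, then Gaussian read noise).
    orientation_range : (float, float)
        Uniform sampling range of the ellipse orientation in radians
        (default the full [0, pi); a zero-width range pins the orientation,
        e.g. for spatially structured class signals).
    extra_puncta : (float, int | None)
        (count, quadrant): extra channel-1 puncta appended after the base
        sampling. With a quadrant index 0..3 their angular position is
        confined to that quarter of the ellipse frame (0 starts at the
        positive minor-axis direction); None places them anywhere. Used to
        build classes whose discriminative signal has a known location.
    """

    canvas_size: int = 600
    pixel_pitch_nm: float = 50.0
    ellipse_semi_axes: tuple[tuple[float, float], tuple[float, float]] = (
        (180.0, 230.0),
        (120.0, 170.0),
    )
    puncta_count: tuple[tuple[float, float], tuple[float, float]] = (
        (40.0, 0.0),
        (40.0, 0.0),
    )
    puncta_radius: tuple[float, float] = (2.0, 5.0)
    puncta_peak: tuple[float, float] = (600.0, 1200.0)
    zone_weights: tuple[float, float, float, float, float] = (
        0.04, 0.12, 0.20, 0.28, 0.36)
    coloc_fraction: float = 0.2
    coloc_jitter: float = 1.0
    background_level: float = 100.0
    noise_sigma: float = 20.0
    min_separation: float = 0.0
    noise_model: str = "gaussian"
    orientation_range: tuple[float, float] = (0.0, float(np.pi))
    extra_puncta: tuple[float, int | None] = (0.0, None)

    def __post_init__(self) -> None:
        w = np.asarray(self.zone_weights, dtype=float)
        if w.shape != (5,) or (w < 0).any() or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("zone_weights must be 5 nonnegative reals summing to 1")
        if not 0.0 <= self.coloc_fraction <= 1.0:
            raise ValueError("coloc_fraction must lie in [0, 1]")
        for mean, disp in self.puncta_count:
            if mean < 0 or (disp != 0 and disp < 1):
                raise ValueError("puncta_count dispersion (Fano factor) must "
                                 "be 0 (fixed) or >= 1")
        for lo, hi in (*self.ellipse_semi_axes, self.puncta_radius, self.puncta_peak):
            if lo < 0 or hi < lo:
                raise ValueError("ranges must be nonnegative with lo <= hi")
        a_hi = self.ellipse_semi_axes[0][1]
        if 2 * a_hi >= self.canvas_size:
            raise ValueError("canvas cannot accommodate the largest ellipse")
        b_lo = self.ellipse_semi_axes[1][0]
        if self.puncta_radius[1] > b_lo:
            raise ValueError("puncta radius exceeds the ellipse minor semi-axis")
        if self.noise_model not in ("gaussian", "poisson"):
            raise ValueError(f"unknown noise_model {self.noise_model!r}")
        if self.orientation_range[1] < self.orientation_range[0]:
            raise ValueError("orientation_range must be (lo, hi) with lo <= hi")
        n_extra, quadrant = self.extra_puncta
        if n_extra < 0 or (quadrant is not None and quadrant not in range(4)):
            raise ValueError("extra_puncta must be (count >= 0, quadrant in "
                             "0..3 or None)")

    def replace(self, **kw) -> "SynthConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class GroundTruth:
    """True generative parameters of one synthetic nucleus."""

    ellipse: EllipseFit
    centroids: dict[str, np.ndarray]        # channel -> (n, 2) row/col
    radii: dict[str, np.ndarray]            # channel -> (n,)
    peaks: dict[str, np.ndarray]            # channel -> (n,)
    class_label: int = 0

    def __post_init__(self) -> None:
        for ch, cen in self.centroids.items():
            n = len(cen)
            if len(self.radii[ch]) != n or len(self.peaks[ch]) != n:
                raise ValueError(f"inconsistent ground-truth lengths for {ch}")


@dataclass
class NucleusImage:
    """A single-nucleus multi-channel 2D image plus its nucleus mask.

    ``channels`` maps channel name -> 2D float array; ``mask`` is the binary
    nucleus footprint; ``pixel_pitch_nm`` the physical pixel size.
    """

    channels: dict[str, np.ndarray]
    mask: np.ndarray
    pixel_pitch_nm: float
    meta: dict = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape


def _sample_count(rng: np.random.Generator, mean: float, dispersion: float) -> int:
    if mean <= 0:
        return 0
    if dispersion <= 0:
        return int(round(mean))
    if dispersion == 1.0:
        return int(rng.poisson(mean))
    # negative binomial with variance = dispersion * mean (Fano factor)
    p = 1.0 / dispersion
    r = mean * p / (1.0 - p)
    return int(rng.negative_binomial(r, p))


def _sample_positions(rng: np.random.Generator, ellipse: EllipseFit,
                      weights: np.ndarray, n: int,
                      min_sep: float, max_tries: int = 200,
                      quadrant: int | None = None) -> np.ndarray:
    """Sample puncta centroids: zone by ``weights``, uniform within the zone.

    Uniform-within-zone is achieved by drawing the squared normalized radius
    uniformly over the zone's annulus [( (j-1)/5 )^2, (j/5)^2] and the angle
    uniformly, which is area-uniform in the ellipse frame. A ``quadrant``
    restricts the angle to one quarter turn.
    """
    out = np.empty((n, 2))
    ct, st = np.cos(ellipse.orientation), np.sin(ellipse.orientation)
    k = 0
    tries = 0
    while k < n:
        j = rng.choice(5, p=weights) + 1
        rho2 = rng.uniform(((j - 1) / 5) ** 2, (j / 5) ** 2)
        rho = np.sqrt(rho2)
        if quadrant is None:
            phi = rng.uniform(0, 2 * np.pi)
        else:
            phi = rng.uniform(quadrant * np.pi / 2, (quadrant + 1) * np.pi / 2)
        u = rho * ellipse.semi_major * np.cos(phi)
        v = rho * ellipse.semi_minor * np.sin(phi)
        r = ellipse.center[0] + u * ct - v * st
        c = ellipse.center[1] + u * st + v * ct
        cand = np.array([r, c])
        if min_sep > 0 and k > 0:
            if np.min(np.linalg.norm(out[:k] - cand, axis=1)) < min_sep:
                tries += 1
                if tries > max_tries * n:
                    raise RuntimeError(
                        "could not place puncta with the requested min_separation")
                continue
        out[k] = cand
        k += 1
    return out


def _render_puncta(shape: tuple[int, int], centroids: np.ndarray,
                   radii: np.ndarray, peaks: np.ndarray) -> np.ndarray:
    """Sum of isotropic 2D Gaussians (sigma = radius/2), rendered locally."""
    img = np.zeros(shape, dtype=np.float64)
    for (r0, c0), rad, peak in zip(centroids, radii, peaks):
        sigma = rad / 2.0
        ext = int(np.ceil(4 * sigma)) + 1
        rlo, rhi = int(np.floor(r0)) - ext, int(np.floor(r0)) + ext + 1
        clo, chi = int(np.floor(c0)) - ext, int(np.floor(c0)) + ext + 1
        rlo, clo = max(rlo, 0), max(clo, 0)
        rhi, chi = min(rhi, shape[0]), min(chi, shape[1])
        if rlo >= rhi or clo >= chi:
            continue
        rr = np.arange(rlo, rhi)[:, None] - r0
        cc = np.arange(clo, chi)[None, :] - c0
        img[rlo:rhi, clo:chi] += peak * np.exp(-(rr**2 + cc**2) / (2 * sigma**2))
    return img


def generate_nucleus(config: SynthConfig, seed: int,
                     class_label: int = 0) -> tuple[NucleusImage, GroundTruth]:
    """Generate one synthetic nucleus crop and its ground truth.

    The DNA channel is a filled ellipse with a smoothed edge plus noise; the
    two marker channels are background plus Gaussian foci at the sampled
    positions plus noise. Deterministic in (config, seed).
    """
    rng = np.random.default_rng(seed)
    size = config.canvas_size
    shape = (size, size)
    (a_lo, a_hi), (b_lo, b_hi) = config.ellipse_semi_axes
    a = rng.uniform(a_lo, a_hi)
    b = rng.uniform(b_lo, b_hi)
    if b > a:
        a, b = b, a
    theta = rng.uniform(*config.orientation_range) % np.pi
    center = (size / 2.0 + rng.uniform(-5, 5), size / 2.0 + rng.uniform(-5, 5))
    ellipse = EllipseFit(center=center, semi_major=a, semi_minor=b,
                         orientation=theta)
    rho = elliptical_radius(ellipse, shape)
    mask = rho <= 1.0
    # soft-edged DNA signal: sigmoid falloff across ~2 px at the boundary
    dna_amp = 0.6 * np.mean(config.puncta_peak) if config.puncta_peak[1] > 0 else 500.0
    edge_soft = 2.0 / max(b, 1.0)
    dna = dna_amp / (1.0 + np.exp((rho - 1.0) / max(edge_soft, 1e-6)))

    weights = np.asarray(config.zone_weights, dtype=float)
    centroids: dict[str, np.ndarray] = {}
    radii: dict[str, np.ndarray] = {}
    peaks: dict[str, np.ndarray] = {}

    # channel 1 (H3K27ac): fully sampled from the radial law
    n1 = _sample_count(rng, *config.puncta_count[0])
    pos1 = _sample_positions(rng, ellipse, weights, n1, config.min_separation)
    n_extra, quadrant = config.extra_puncta
    n_extra = int(round(n_extra))
    if n_extra > 0:
        pos_extra = _sample_positions(rng, ellipse, weights, n_extra,
                                      config.min_separation, quadrant=quadrant)
        pos1 = np.vstack([pos1, pos_extra]) if n1 else pos_extra
        n1 += n_extra
    centroids["H3K27ac"] = pos1
    radii["H3K27ac"] = rng.uniform(*config.puncta_radius, size=n1)
    peaks["H3K27ac"] = rng.uniform(*config.puncta_peak, size=n1)

    # channel 2 (CTCF): a coloc_fraction share re-uses channel-1 centroids
    n2 = _sample_count(rng, *config.puncta_count[1])
    n_co = min(int(round(config.coloc_fraction * n2)), n1)
    idx = (np.sort(rng.choice(n1, size=n_co, replace=False))
           if n_co > 0 else np.empty(0, int))
    pos_co = pos1[idx].copy()
    if config.coloc_jitter > 0 and n_co > 0:
        pos_co += rng.normal(0, config.coloc_jitter, size=pos_co.shape)
    pos_free = _sample_positions(rng, ellipse, weights, n2 - n_co,
                                 config.min_separation)
    pos2 = np.vstack([pos_co, pos_free]) if n2 > 0 else np.empty((0, 2))
    centroids["CTCF"] = pos2
    radii["CTCF"] = rng.uniform(*config.puncta_radius, size=n2)
    peaks["CTCF"] = rng.uniform(*config.puncta_peak, size=n2)

    channels: dict[str, np.ndarray] = {}
    for ch in ("H3K27ac", "CTCF"):
        clean = (config.background_level * mask
                 + _render_puncta(shape, centroids[ch], radii[ch], peaks[ch]))
        channels[ch] = _add_noise(rng, clean, config)
    channels["DNA"] = _add_noise(rng, dna, config)

    img = NucleusImage(channels=channels, mask=mask,
                       pixel_pitch_nm=config.pixel_pitch_nm,
                       meta={"seed": int(seed)})
    gt = GroundTruth(ellipse=ellipse, centroids=centroids, radii=radii,
                     peaks=peaks, class_label=class_label)
    return img, gt


def _add_noise(rng: np.random.Generator, clean: np.ndarray,
               config: SynthConfig) -> np.ndarray:
    img = clean
    if config.noise_model == "poisson":
        img = rng.poisson(np.clip(clean, 0, None)).astype(np.float64)
    if config.noise_sigma > 0:
        img = img + rng.normal(0, config.noise_sigma, size=clean.shape)
    return np.clip(img, 0, None)


def generate_dataset(cfg_class0: SynthConfig, cfg_class1: SynthConfig,
                     n_per_class: int, seed: int
                     ) -> list[tuple[NucleusImage, GroundTruth]]:
    """Generate a two-class labeled collection of synthetic nuclei.

    Per-image seeds are derived deterministically from the master seed via
    numpy's SeedSequence spawning, so the collection is reproducible and
    individual images can be regenerated independently.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(2 * n_per_class)
    out = []
    for i, child in enumerate(children):
        label = i % 2
        cfg = cfg_class1 if label else cfg_class0
        sub_seed = int(child.generate_state(1)[0] % (2**31))
        img, gt = generate_nucleus(cfg, sub_seed, class_label=label)
        out.append((img, gt))
    return out


def generate_multicell_field(n_nuclei: int, field_size: int, min_gap: float,
                             config: SynthConfig, seed: int,
                             max_attempts: int = 2000
                             ) -> tuple[dict[str, np.ndarray], np.ndarray,
                                        list[GroundTruth]]:
    """Place ``n_nuclei`` synthetic nuclei on a larger field without overlap.

    Nucleus centers are rejection-sampled so that bounding circles separated
    by ``min_gap`` never intersect. Returns the multi-channel field, an
    instance label mask (1..n), and the per-nucleus ground truths with
    centroids mapped to field coordinates.
    """
    rng = np.random.default_rng(seed)
    a_hi = config.ellipse_semi_axes[0][1]
    margin = a_hi + 2
    if field_size - 2 * margin <= 0:
        raise ValueError("field too small for the configured ellipse size")
    centers = []
    attempts = 0
    while len(centers) < n_nuclei:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                f"placement failed: {len(centers)}/{n_nuclei} nuclei placed "
                f"after {max_attempts} attempts (field too crowded for min_gap)")
        cand = rng.uniform(margin, field_size - margin, size=2)
        if all(np.linalg.norm(cand - c) >= 2 * a_hi + min_gap for c in centers):
            centers.append(cand)

    field = {ch: np.zeros((field_size, field_size)) for ch in CHANNELS}
    inst = np.zeros((field_size, field_size), dtype=np.int32)
    truths: list[GroundTruth] = []
    sub_seeds = np.random.SeedSequence(seed).spawn(n_nuclei)
    for i, (center, child) in enumerate(zip(centers, sub_seeds), start=1):
        sub_seed = int(child.generate_state(1)[0] % (2**31))
        img, gt = generate_nucleus(config, sub_seed)
        size = config.canvas_size
        r0 = int(round(center[0])) - size // 2
        c0 = int(round(center[1])) - size // 2
        # clip the paste window to the field (the ellipse itself always fits)
        rlo, rhi = max(r0, 0), min(r0 + size, field_size)
        clo, chi = max(c0, 0), min(c0 + size, field_size)
        src = (slice(rlo - r0, rhi - r0), slice(clo - c0, chi - c0))
        dst = (slice(rlo, rhi), slice(clo, chi))
        for ch in CHANNELS:
            field[ch][dst] += img.channels[ch][src]
        inst[dst][img.mask[src]] = i
        offset = np.array([r0, c0], dtype=float)
        shifted = GroundTruth(
            ellipse=EllipseFit(
                center=(gt.ellipse.center[0] + r0, gt.ellipse.center[1] + c0),
                semi_major=gt.ellipse.semi_major,
                semi_minor=gt.ellipse.semi_minor,
                orientation=gt.ellipse.orientation),
            centroids={ch: gt.centroids[ch] + offset for ch in gt.centroids},
            radii=gt.radii, peaks=gt.peaks, class_label=gt.class_label)
        truths.append(shifted)
    return field, inst, truths


def match_puncta(true_centroids: np.ndarray, found_centroids: np.ndarray,
                 max_dist: float = 4.0) -> tuple[np.ndarray, np.ndarray, float]:
    """Greedy one-to-one matching of detected to planted puncta.

    Pairs are matched in order of increasing distance until ``max_dist`` is
    exceeded. Returns (matched true indices, matched found indices, RMSE of
    matched centroid distances; NaN if nothing matched).
    """
    true_centroids = np.asarray(true_centroids, dtype=float)
    found_centroids = np.asarray(found_centroids, dtype=float)
    if len(true_centroids) == 0 or len(found_centroids) == 0:
        return np.empty(0, int), np.empty(0, int), float("nan")
    d = np.linalg.norm(true_centroids[:, None, :] - found_centroids[None, :, :],
                       axis=2)
    ti, fi = np.unravel_index(np.argsort(d, axis=None), d.shape)
    used_t: set[int] = set()
    used_f: set[int] = set()
    mt, mf, dists = [], [], []
    for t, f in zip(ti, fi):
        if d[t, f] > max_dist:
            break
        if t in used_t or f in used_f:
            continue
        used_t.add(t)
        used_f.add(f)
        mt.append(t)
        mf.append(f)
        dists.append(d[t, f])
    rmse = float(np.sqrt(np.mean(np.square(dists)))) if dists else float("nan")
    return np.array(mt, int), np.array(mf, int), rmse


# ---------------------------------------------------------------------------
# Preset study conditions. These define, in one place, the synthetic datasets
# used by the package's own validation experiments; tests and scripts share
# them rather than re-declaring parameters.

def recovery_config() -> SynthConfig:
    """Puncta-recovery conditions: full-size nucleus, 50 homogeneous-brightness
    puncta per marker channel at SNR 5 (peak 1000, noise sigma 200), radii
    2-5 px, centroids at least 8 px apart."""
    return SynthConfig(
        canvas_size=600,
        puncta_count=((50.0, 0.0), (50.0, 0.0)),
        puncta_radius=(2.0, 5.0),
        puncta_peak=(1000.0, 1000.0),
        background_level=300.0,
        noise_sigma=200.0,
        min_separation=8.0,
    )


def dense_lowres_config(canvas: int = 300) -> SynthConfig:
    """Dense-foci conditions for resolution-degradation experiments.

    Many well-separated homogeneous-brightness puncta with radii spanning
    1.5-3 px, so a sub-population sits at or below 2 px — below the width of
    the simulated conventional-resolution blur kernel."""
    s = canvas / 600.0
    return SynthConfig(
        canvas_size=canvas,
        ellipse_semi_axes=((180.0 * s, 230.0 * s), (120.0 * s, 170.0 * s)),
        puncta_count=((60.0, 0.0), (60.0, 0.0)),
        puncta_radius=(1.5, 3.0),
        puncta_peak=(1000.0, 1000.0),
        background_level=100.0,
        noise_sigma=10.0,
        min_separation=5.0,
    )


def desk_base_config(canvas: int = 128) -> SynthConfig:
    """Desk-scale nucleus (geometry scaled ~128/600 from the default)."""
    s = canvas / 600.0
    return SynthConfig(
        canvas_size=canvas,
        ellipse_semi_axes=((180.0 * s, 230.0 * s), (120.0 * s, 170.0 * s)),
        puncta_count=((20.0, 0.0), (20.0, 0.0)),
        puncta_radius=(1.5, 3.0),
        puncta_peak=(500.0, 800.0),
        background_level=100.0,
        noise_sigma=20.0,
    )


def desk_separable_config(canvas: int = 128) -> SynthConfig:
    """Desk-scale class 1: puncta count and peak intensity doubled."""
    return desk_base_config(canvas).replace(
        puncta_count=((40.0, 0.0), (40.0, 0.0)),
        puncta_peak=(1000.0, 1600.0),
    )


def desk_quadrant_configs(canvas: int = 128, quadrant: int = 0
                          ) -> tuple[SynthConfig, SynthConfig]:
    """Class pair whose only difference is extra puncta in one quadrant.

    Orientation is pinned to 0 (axis-aligned ellipse) so the discriminative
    quadrant occupies a fixed region of the image frame, which lets heatmap
    localization be scored against the known signal location.
    """
    base = desk_base_config(canvas).replace(orientation_range=(0.0, 0.0))
    signal = base.replace(extra_puncta=(20.0, quadrant))
    return base, signal


def quadrant_mask(ellipse: EllipseFit, shape: tuple[int, int],
                  quadrant: int) -> np.ndarray:
    """Image-frame mask of one ellipse quadrant (for an axis-aligned ellipse).

    Quadrant q covers ellipse-frame angles [q*pi/2, (q+1)*pi/2): q=0 is
    dr >= 0 and dc >= 0 from the ellipse center, and so on counterclockwise
    in the (row, col) frame used by the position sampler.
    """
    rr, cc = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]),
                         indexing="ij")
    dr = rr - ellipse.center[0]
    dc = cc - ellipse.center[1]
    quads = [(dr >= 0) & (dc >= 0), (dr < 0) & (dc >= 0),
             (dr < 0) & (dc < 0), (dr >= 0) & (dc < 0)]
    return quads[quadrant]


def write_nucleus_tiff(img: NucleusImage, gt: GroundTruth | None,
                       path: str | Path) -> None:
    """Write a multi-page 16-bit TIFF (one page per channel, order
    H3K27ac/CTCF/DNA) plus a JSON ground-truth sidecar and a mask page."""
    path = Path(path)
    stack = np.stack([np.clip(img.channels[ch], 0, 65535).astype(np.uint16)
                      for ch in CHANNELS])
    tifffile.imwrite(path, stack, metadata={
        "axes": "CYX", "channels": list(CHANNELS),
        "pixel_pitch_nm": img.pixel_pitch_nm})
    tifffile.imwrite(path.with_suffix(".mask.tif"),
                     img.mask.astype(np.uint8) * 255)
    if gt is not None:
        side = {
            "ellipse": {
                "center": list(gt.ellipse.center),
                "semi_major": gt.ellipse.semi_major,
                "semi_minor": gt.ellipse.semi_minor,
                "orientation": gt.ellipse.orientation,
            },
            "class_label": gt.class_label,
            "channels": {
                ch: {
                    "centroids": gt.centroids[ch].tolist(),
                    "radii": gt.radii[ch].tolist(),
                    "peaks": gt.peaks[ch].tolist(),
                } for ch in gt.centroids
            },
        }
        path.with_suffix(".json").write_text(json.dumps(side, indent=1))
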