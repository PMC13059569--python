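import numpy as np
import pytest

from nucleoprofiler.geometry import EllipseFit, elliptical_radius
from nucleoprofiler.puncta import PunctaSet, PunctumProps


def rasterize_ellipse(a: float, b: float, theta: float = 0.0,
                      center=None, shape=None) -> np.ndarray:
    """Binary mask of a filled ellipse, used as the geometry oracle."""
    if shape is None:
        side = int(2 * a + 21)
        shape = (side, side)
    if center is None:
        center = (shape[0] / 2.0, shape[1] / 2.0)
    ell = EllipseFit(center=center, semi_major=a, semi_minor=b,
                     orientation=theta % np.pi)
    return elliptical_radius(ell, shape) <= 1.0


def make_puncta_set(centroids, l_major=None, l_minor=None,
                    areas=None, intensities=None) -> PunctaSet:
    """Assemble a PunctaSet from explicit per-punctum values (no image)."""
    centroids = np.atleast_2d(np.asarray(centroids, dtype=float))
    n = len(centroids)
    l_major = np.full(n, 4.0) if l_major is None else np.asarray(l_major, float)
    l_minor = np.full(n, 4.0) if l_minor is None else np.asarray(l_minor, float)
    areas = np.full(n, 10) if areas is None else np.asarray(areas)
    intensities = (np.full(n, 100.0) if intensities is None
                   else np.asarray(intensities, float))
    props = [PunctumProps(label=i + 1, centroid=tuple(c), area=int(a),
                          mean_intensity=float(it), l_major=float(lm),
                          l_minor=float(ln))
             for i, (c, a, it, lm, ln)
             in enumerate(zip(centroids, areas, intensities, l_major, l_minor))]
    return PunctaSet(labels=np.zeros((1, 1), dtype=np.int32), props=props)


@pytest.fixture(scope="session")
def small_nucleus():
    """One deterministic small synthetic nucleus shared across tests."""
    from nucleoprofiler.synthgen import SynthConfig, generate_nucleus
    cfg = SynthConfig(canvas_size=200,
                      ellipse_semi_axes=((60.0, 70.0), (40.0, 50.0)),
                      puncta_count=((15.0, 0.0), (15.0, 0.0)),
                      puncta_radius=(2.0, 4.0),
                      puncta_peak=(900.0, 1100.0),
                      noise_sigma=15.0)
    return generate_nucleus(cfg, seed=7)
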