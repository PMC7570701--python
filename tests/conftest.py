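import numpy as np
import pytest

from aosize.echogram import Echogram
from aosize.geometry import TunaModelParams, render_silhouette
from aosize.vision import detect_edges, extract_blobs


def make_params(**overrides) -> TunaModelParams:
    base = dict(
        sx=200.0, sy=240.0, l=150.0, alpha_deg=15.0, theta_b_deg=8.0,
        w=30.0 * np.array([1.0, 0.85, 0.68, 0.50, 0.33, 0.18]),
        lp=12.0, sp=0.1,
    )
    base.update(overrides)
    return TunaModelParams(**base)


def random_params(rng, image_size=(480, 640)) -> TunaModelParams:
    """Randomized silhouette guaranteed to fit well inside the image."""
    h, w_img = image_size
    l = rng.uniform(70, 200)
    w0 = l * rng.uniform(0.16, 0.26)
    ratios = rng.uniform(0.55, 0.95, size=5)
    return TunaModelParams(
        sx=w_img / 2 + rng.uniform(-30, 30),
        sy=h / 2 + rng.uniform(-30, 30),
        l=l,
        alpha_deg=rng.uniform(-180, 180),
        theta_b_deg=rng.uniform(-15, 15),
        w=w0 * np.concatenate([[1.0], np.cumprod(ratios)]),
        lp=rng.uniform(0.3, 0.6) * w0,
        sp=rng.uniform(-0.3, 0.3),
    )


def edges_of(params, image_size=(480, 640), subpixel=True):
    mask, clipped = render_silhouette(params, image_size)
    assert not clipped
    blob = max(extract_blobs(mask), key=lambda b: len(b.pixels))
    edges, truncated = detect_edges(mask, blob, subpixel=subpixel)
    assert not truncated
    return edges


def make_echogram(values, ping_dt=0.05, dr=0.02, r0=0.02):
    values = np.asarray(values, dtype=float)
    n_p, n_s = values.shape
    return Echogram(
        values_db=values,
        ping_times_s=np.arange(n_p) * ping_dt,
        sample_ranges_m=r0 + np.arange(n_s) * dr,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
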