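import numpy as np
import pytest

from pvgradient.phantom import PhantomSpec, generate_phantom

# compact geometry that fits a 48^3 grid: fast enough for per-test generation
SMALL_KWARGS = dict(
    grid_shape=(48, 48, 48),
    ventricle_halfwidths_mm=(3.0, 7.0, 4.0),
    ventricle_offset_mm=5.0,
    wm_shell_thickness_mm=12.0,
    cortex_thickness_mm=2.0,
    chp_volume_ml=0.03,
    lesion_count=2,
    lesion_radius_mm=2.5,
)


def small_spec(**overrides) -> PhantomSpec:
    kw = dict(SMALL_KWARGS)
    kw.update(overrides)
    return PhantomSpec(**kw)


@pytest.fixture(scope="session")
def noise_free_phantom():
    """One noise-free small phantom with a 10 mm gradient, shared across tests."""
    spec = small_spec(noise_sd=0.0, gradient_slope=-0.01, gradient_range_mm=10.0, seed=11)
    return spec, *generate_phantom(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def bh_bruteforce(p: np.ndarray) -> np.ndarray:
    """Step-up Benjamini-Hochberg by the textbook formula: q(i) = min over
    j >= i of p(j)*m/j (on the sorted scale), capped at 1."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj_sorted = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum.accumulate(adj_sorted[::-1])[::-1]
    adj_sorted = np.minimum(adj_sorted, 1.0)
    out = np.empty(m)
    out[order] = adj_sorted
    return out


def dilate_bruteforce(mask: np.ndarray, connectivity: int) -> np.ndarray:
    """Reference dilation: explicit scan over all neighbor offsets."""
    out = mask.copy()
    for dz in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                if dz == dy == dx == 0:
                    continue
                if connectivity == 6 and abs(dz) + abs(dy) + abs(dx) != 1:
                    continue
                shifted = np.zeros_like(mask)
                src = [slice(None)] * 3
                dst = [slice(None)] * 3
                for ax, d in enumerate((dz, dy, dx)):
                    if d == 1:
                        src[ax], dst[ax] = slice(0, -1), slice(1, None)
                    elif d == -1:
                        src[ax], dst[ax] = slice(1, None), slice(0, -1)
                shifted[tuple(dst)] = mask[tuple(src)]
                out |= shifted
    return out
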