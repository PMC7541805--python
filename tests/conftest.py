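import numpy as np
import pytest

from petdna import FeatureConfig, PhantomSpec, SuvVolume, extract_all, generate_phantom


def ball_mask(radius_mm: float, spacing: float, margin: int = 3) -> np.ndarray:
    """Digital ball: voxel centres within radius of the grid centre."""
    n = int(np.ceil(2 * radius_mm / spacing)) + 2 * margin
    ax = (np.arange(n) - n / 2 + 0.5) * spacing
    x, y, z = np.meshgrid(ax, ax, ax, indexing="ij")
    return x**2 + y**2 + z**2 <= radius_mm**2


def cube_mask(side_vox: int, margin: int = 2) -> np.ndarray:
    n = side_vox + 2 * margin
    m = np.zeros((n, n, n), bool)
    m[margin : margin + side_vox, margin : margin + side_vox, margin : margin + side_vox] = True
    return m


def uniform_suv(mask: np.ndarray, level: float = 10.0, spacing=(1.0, 1.0, 1.0)) -> SuvVolume:
    return SuvVolume(mask.astype(np.float32) * level, spacing)


@pytest.fixture(scope="session")
def sphere_features_1mm():
    """Twelve features of a digital r = 20 mm ball at 1 mm spacing."""
    mask = ball_mask(20.0, 1.0)
    return extract_all(uniform_suv(mask), mask)


@pytest.fixture(scope="session")
def small_cohort():
    """A 30-patient synthetic cohort at coarse resolution (shared, seeded)."""
    from petdna import generate_cohort

    spec = PhantomSpec(spacing_mm=(5.0, 5.0, 5.0), body_box_mm=(300, 300, 400),
                       lesion_count_lambda=5.0)
    cohort, mutations, truth = generate_cohort(spec, n_patients=30, seed=42)
    return cohort, mutations, truth
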