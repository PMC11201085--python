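import numpy as np
import pytest

from archform.geometry import DentalMesh
from archform.synthetic_data import (
    MeshParams,
    SyntheticCohortConfig,
    default_alveolar_templates,
    default_dental_templates,
    generate_synthetic_cast,
)


@pytest.fixture(scope="session")
def dental_templates():
    return default_dental_templates()


@pytest.fixture(scope="session")
def alveolar_templates():
    return default_alveolar_templates()


@pytest.fixture(scope="session")
def zero_noise_cast(dental_templates, alveolar_templates):
    cfg = SyntheticCohortConfig(shape_noise_sd=0.0)
    return generate_synthetic_cast(
        dental_templates[2], alveolar_templates[2], config=cfg, seed=1
    )


@pytest.fixture(scope="session")
def noisy_cast(dental_templates, alveolar_templates):
    cfg = SyntheticCohortConfig(shape_noise_sd=0.02)
    return generate_synthetic_cast(
        dental_templates[1], alveolar_templates[1], config=cfg, seed=42
    )


@pytest.fixture(scope="session")
def zero_noise_extraction(zero_noise_cast):
    from archform.arch_extraction import extract_arch_forms

    return extract_arch_forms(zero_noise_cast.mesh)


@pytest.fixture(scope="session")
def noisy_extraction(noisy_cast):
    from archform.arch_extraction import extract_arch_forms

    return extract_arch_forms(noisy_cast.mesh)


def grid_surface(x, y_of_xz, z_levels, jaw="mandible"):
    """Structured open surface from y = f(x, z) rows (test helper)."""
    rows = [np.column_stack([x, y_of_xz(x, z), np.full_like(x, z)]) for z in z_levels]
    v = np.vstack(rows)
    ncol = len(x)
    faces = []
    for r in range(len(z_levels) - 1):
        a = r * ncol + np.arange(ncol - 1)
        faces.append(np.column_stack([a, a + 1, a + 1 + ncol]))
        faces.append(np.column_stack([a, a + 1 + ncol, a + ncol]))
    return DentalMesh(vertices=v, faces=np.vstack(faces), jaw=jaw)


def tube_surface(radius_of_z, z_levels, n_theta=64, jaw="mandible"):
    """Closed tube around the z-axis with per-level radius (test helper)."""
    theta = np.linspace(0, 2 * np.pi, n_theta, endpoint=False)
    rows = []
    for z in z_levels:
        r = radius_of_z(z)
        rows.append(np.column_stack([r * np.cos(theta), r * np.sin(theta), np.full_like(theta, z)]))
    v = np.vstack(rows)
    faces = []
    for k in range(len(z_levels) - 1):
        a = k * n_theta + np.arange(n_theta)
        b = k * n_theta + (np.arange(n_theta) + 1) % n_theta
        faces.append(np.column_stack([a, b, b + n_theta]))
        faces.append(np.column_stack([a, b + n_theta, a + n_theta]))
    return DentalMesh(vertices=v, faces=np.vstack(faces), jaw=jaw)
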