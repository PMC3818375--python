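import numpy as np
import pytest


def stripes_image(beta_deg, shape=(128, 128), period=8, width=4):
    """Binary [z, x] stripe image; struts run at (beta_deg + 90) from +x."""
    z, x = np.mgrid[0 : shape[0], 0 : shape[1]]
    n = np.radians(beta_deg)
    return ((x * np.cos(n) + z * np.sin(n)) % period) < width


def axis_error_deg(a, b):
    """Angle in degrees between two axes (antipodally symmetric)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    a = a / np.linalg.norm(a)
    b = b / np.linalg.norm(b)
    return float(np.degrees(np.arccos(min(1.0, abs(float(np.dot(a, b)))))))


def sagittal_axis(alpha_deg):
    """Unit axis in the sagittal (x-z) plane at alpha degrees from +x."""
    t = np.radians(alpha_deg)
    return np.array([np.cos(t), 0.0, np.sin(t)])


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def rod_lattice_z():
    """64^3 rod lattice along +z, shared across tests (read-only)."""
    from fabricgait import synthetic_data as sd

    spec = sd.RodLatticeSpec(
        shape=(64, 64, 64), rod_radius=2, spacing=12, primary_axis=(0, 0, 1), seed=11
    )
    return sd.make_rod_lattice(spec)
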