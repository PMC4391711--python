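import numpy as np
import pytest

from plaquesim.geometry import Contour, CrossSection, PlaqueModel3D


def circle(r, n=96, center=(0.0, 0.0)):
    th = 2 * np.pi * np.arange(n) / n
    return Contour(np.column_stack([center[0] + r * np.cos(th),
                                    center[1] + r * np.sin(th)]))


def annulus_section(a, b, z=0.0, lrncs=(), n=96):
    return CrossSection(z, circle(a, n), circle(b, n), tuple(lrncs))


def uniform_model(section):
    """Three identical stacked sections: no axial variation."""
    secs = [CrossSection(z, section.lumen, section.outer_wall, section.lrncs)
            for z in (0.0, 1.0, 2.0)]
    return PlaqueModel3D.from_sections(secs)


@pytest.fixture
def annulus_cs():
    return annulus_section(3.0, 5.0)


@pytest.fixture
def cone_model():
    """Lumen radius 1 -> 2 mm linearly over z in [0, 2]; outer wall r + 2."""
    secs = [annulus_section(1.0 + z / 2.0, 3.0 + z / 2.0, z=z)
            for z in (0.0, 1.0, 2.0)]
    return PlaqueModel3D.from_sections(secs)


@pytest.fixture
def plaque_with_core():
    """Ring a=2, b=5 with one off-axis disk core (gap 0.4 mm), axially uniform."""
    sec = annulus_section(2.0, 5.0, lrncs=[circle(0.8, center=(3.2, 0.0))])
    return uniform_model(sec)


@pytest.fixture(scope="session")
def tissue_params():
    from plaquesim.mri import TissueParams
    return TissueParams()
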