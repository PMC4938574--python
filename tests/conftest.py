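import numpy as np
import pytest

from capmorph.core_io import CapillaryAnnotation, Polygon


def rect(x0: float, y0: float, x1: float, y1: float) -> Polygon:
    return Polygon(np.array([[x0, y0], [x1, y0], [x1, y1], [x0, y1]], float))


def regular_polygon(cx: float, cy: float, radius: float, n: int) -> Polygon:
    t = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    return Polygon(np.column_stack([cx + radius * np.cos(t), cy + radius * np.sin(t)]))


@pytest.fixture
def square_annotation() -> CapillaryAnnotation:
    """Vessel 100×50 px, lumen 50×40 px, nucleus 25×40 px (disjoint rectangles).

    At 100 nm/px: total 50 µm², lumen 20 µm², nucleus 10 µm², cytoplasm 20 µm².
    """
    return CapillaryAnnotation(
        vessel_outer=rect(0, 0, 100, 50),
        lumen=rect(5, 5, 55, 45),
        nuclei=[rect(60, 5, 85, 45)],
        capillary_id="square",
    )


@pytest.fixture(scope="session")
def ir_infarct_preset():
    from capmorph.synthetic import get_preset

    return get_preset("IR30-60.infarct")
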