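import numpy as np
import pytest
from skimage import draw as skdraw

import nucmorph as nm


@pytest.fixture(scope="session")
def table1() -> nm.Cohort:
    return nm.load_table1()


@pytest.fixture(scope="session")
def draw_disc():
    def _disc(radius: float, pad: int = 12) -> np.ndarray:
        size = int(2 * radius) + 2 * pad
        img = np.zeros((size, size), dtype=np.uint8)
        rr, cc = skdraw.disk((size / 2, size / 2), radius)
        img[rr, cc] = 1
        return img

    return _disc


@pytest.fixture(scope="session")
def draw_ellipse():
    def _ellipse(a: float, b: float, rotation: float = 0.0, pad: int = 12) -> np.ndarray:
        size = int(2 * max(a, b)) + 2 * pad
        img = np.zeros((size, size), dtype=np.uint8)
        rr, cc = skdraw.ellipse(size / 2, size / 2, a, b, rotation=rotation)
        img[rr, cc] = 1
        return img

    return _ellipse


def cohort_from_2x2(a: int, b: int, c: int, d: int, cutoff: float = 100.0) -> nm.Cohort:
    """Cohort realizing the 2x2 table [[a, b], [c, d]]: rows pN-/pN+,
    columns (area <= cutoff)/(area > cutoff)."""
    records = []
    case = 0
    for status, below, above in ((0, a, b), (1, c, d)):
        for area in [cutoff - 50.0] * below + [cutoff + 50.0] * above:
            case += 1
            records.append(
                nm.PatientRecord(
                    case_id=case, age=60.0, sex="M", site="tongue",
                    differentiation="well", neoadjuvant="C", t_class="2",
                    n_class_clinical="0", m_class="0", dissection="RND",
                    pn_status=status, pn_class="1" if status else "0",
                    n_positive_nodes=status, node_levels=("II",) if status else (),
                    mean_nuclear_area=area, mean_perimeter=35.0,
                    circular_rate=0.8, aspect_ratio=1.4, nacv=30.0,
                )
            )
    return nm.Cohort(records, provenance="constructed 2x2")
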