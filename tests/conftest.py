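import numpy as np
import pandas as pd
import pytest

from tmepipe.io import CellMap


def make_cell_map(points, types, width=2000, height=2000, slide="S1", patient="P1"):
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    cells = pd.DataFrame(
        {
            "cell_id": pd.Series([f"c{i:04d}" for i in range(len(pts))], dtype=object),
            "x": pd.Series(pts[:, 0], dtype=float),
            "y": pd.Series(pts[:, 1], dtype=float),
            "cell_type": pd.Series(list(types), dtype=object),
        }
    )
    return CellMap(
        slide_id=slide, patient_id=patient, width_px=width, height_px=height, cells=cells
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240115)


@pytest.fixture
def small_cell_map(rng):
    """One 2000x2000 slide: a dense tumor blob plus scattered other types."""
    n_t, n_s, n_l = 120, 40, 20
    tumor = rng.uniform(500, 1100, size=(n_t, 2))
    stroma = rng.uniform(0, 2000, size=(n_s, 2))
    lymph = rng.uniform(0, 2000, size=(n_l, 2))
    pts = np.vstack([tumor, stroma, lymph])
    types = ["tumor"] * n_t + ["stroma"] * n_s + ["lymphocyte"] * n_l
    return make_cell_map(pts, types)


@pytest.fixture
def clinical_frame():
    n = 8
    return pd.DataFrame(
        {
            "patient_id": [f"P{i}" for i in range(n)],
            "os_months": [12.0, 30.5, 8.2, 44.0, 20.1, 5.5, 60.0, 15.3],
            "event": [1, 0, 1, 0, 1, 1, 0, 1],
            "tki_treated": [1, 1, 0, 1, 0, 1, 0, 1],
            "egfr_class": ["sensitizing"] * 6 + ["other"] * 2,
            "age": [61.0, 55.2, 70.1, 48.9, 66.0, 59.3, 72.8, 50.0],
            "sex": ["female", "male"] * 4,
            "smoking_status": ["never", "former", "current", "never"] * 2,
            "surgery": [0, 1, 0, 0, 1, 1, 0, 1],
        }
    )
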