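import numpy as np
import pandas as pd
import pytest

import allomorph as al
from allomorph.shift_analysis import ReporterLibrary


@pytest.fixture(scope="session")
def reference_model():
    """Noise-free open synthetic two-domain structure (angles 0,0,0)."""
    model, _ = al.make_two_domain_structure()
    return model


@pytest.fixture(scope="session")
def canonical_reference(reference_model):
    return al.canonicalize_reference(reference_model)


@pytest.fixture(scope="session")
def synthetic_library():
    """Synthetic full-coordinate reporter library for simulation tests.

    The bundled library carries only published reporter coordinates; this
    synthetic stand-in supplies complete 2-D cluster points for every
    reporter/state so classification and generation can be exercised end
    to end.  The I84 NAC III / NAC IIIt proton coordinates keep the
    published 7.00 / 7.17 ppm values.
    """
    rows = [
        ("A143", 143, "cis", 8.60, 123.0, np.nan),
        ("A143", 143, "trans", 7.90, 126.5, np.nan),
        ("D180", 180, "cis", 8.05, 118.0, np.nan),
        ("D180", 180, "trans", 8.55, 121.5, np.nan),
        ("I84", 84, "open", 7.60, 120.5, np.nan),
        ("I84", 84, "NAC_I", 7.40, 121.0, np.nan),
        ("I84", 84, "NAC_III", 7.00, 121.8, np.nan),
        ("I84", 84, "NAC_III_t", 7.17, 122.3, np.nan),
        ("I84", 84, "closed", 6.80, 123.0, np.nan),
        ("S88", 88, "open", 8.90, 115.5, np.nan),
        ("S88", 88, "NAC_I", 8.70, 116.2, np.nan),
        ("S88", 88, "NAC_III", 8.45, 117.0, np.nan),
        ("S88", 88, "NAC_III_t", 8.30, 117.5, np.nan),
        ("S88", 88, "closed", 8.10, 118.4, np.nan),
        ("P146", 146, "cis", np.nan, np.nan, 35.0),
        ("P146", 146, "trans", np.nan, np.nan, 32.0),
    ]
    return ReporterLibrary(pd.DataFrame(rows, columns=ReporterLibrary.COLUMNS))


@pytest.fixture(scope="session")
def conformer_centroids():
    """Well-separated synthetic (pitch, roll, yaw) class centroids (deg)."""
    return {
        "open": (0.0, 0.0, 0.0),
        "NAC_I": (26.0, 4.0, -2.0),
        "NAC_III": (35.0, 10.0, -4.0),
        "closed": (44.0, 16.0, -8.0),
    }
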