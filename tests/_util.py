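"""Shared helpers for building small in-memory test series."""

import numpy as np
import pandas as pd

from eelvkit.study_data import PairedSeries


def series_from_md(m, d, animals=None):
    """Build a PairedSeries directly from Bland-Altman coordinates."""
    m = np.asarray(m, dtype=float)
    d = np.asarray(d, dtype=float)
    if animals is None:
        animals = ["a"] * len(m)
    frame = pd.DataFrame(
        {
            "animal_id": animals,
            "stage": "peep_trial",
            "order_index": np.arange(len(m)),
            "peep_cmH2O": 10.0,
            "vt_mL": 168.0,
            "eelv_ct_mL": m - d / 2,
            "eelv_wiwo_mL": m + d / 2,
            "m_mL": m,
            "d_mL": d,
        }
    )
    return PairedSeries(frame)
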