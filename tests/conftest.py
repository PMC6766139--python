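import logging

import numpy as np
import pandas as pd
import pytest

from sermir.datamodel import CtMatrix

logging.getLogger("sermir").setLevel(logging.ERROR)


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def ct_csv(tmp_path):
    """Write a long-format CT CSV from a list of row dicts and return its path."""

    def _write(rows, name="ct.csv"):
        path = tmp_path / name
        frame = pd.DataFrame(rows)
        for col, default in (("phase", "TRAINING"), ("replicate", 1)):
            if col not in frame.columns:
                frame[col] = default
        frame.to_csv(path, index=False)
        return path

    return _write


def make_ct_matrix(values: dict, max_cycles=40.0) -> CtMatrix:
    """CtMatrix from {sample: {assay: ct-or-None}}; None means censored."""
    samples = list(values)
    assays = sorted({a for row in values.values() for a in row})
    ct = pd.DataFrame(np.nan, index=samples, columns=assays)
    cen = pd.DataFrame(False, index=samples, columns=assays)
    nrep = pd.DataFrame(0, index=samples, columns=assays)
    for s, row in values.items():
        for a, v in row.items():
            nrep.at[s, a] = 1
            if v is None:
                cen.at[s, a] = True
            else:
                ct.at[s, a] = v
    return CtMatrix(ct, cen, nrep, max_cycles=max_cycles)
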