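import numpy as np
import pandas as pd
import pytest

import neemscreen as ns


@pytest.fixture(scope="session")
def tiny_library():
    """Six shRNAs over two genes, distance-3 barcodes."""
    return ns.generate_shrna_library(2, 3, 18, seed=7)


@pytest.fixture(scope="session")
def small_library():
    """100 genes x 5 shRNAs — big enough for sampling checks, still fast."""
    return ns.generate_shrna_library(100, 5, 18, seed=11)


@pytest.fixture(scope="session")
def full_library():
    """The full-scale 27,500-shRNA library (shared across tests: ~1.5 s to build)."""
    return ns.generate_shrna_library(5500, 5, 18, seed=1)


def make_matrix(values: dict, sheet_rows: list[tuple], scale="log2"):
    """Build an ExpressionMatrix from a column dict and sample-sheet rows
    (sample_id, condition, time_min, batch[, dose])."""
    rows = [r if len(r) == 5 else (*r, "200ug/ml") for r in sheet_rows]
    sheet = pd.DataFrame(rows, columns=["sample_id", "condition", "time_min",
                                        "batch", "dose"])
    first = next(iter(values.values()))
    index = [f"G{i}" for i in range(len(first))]
    return ns.ExpressionMatrix(values=pd.DataFrame(values, index=index),
                               samples=sheet, scale=scale)


@pytest.fixture
def profile_factory():
    def make(fc_treatment, fc_rescue=(), gene="G1"):
        return ns.TimecourseProfile(gene=gene,
                                    fc_treatment=np.asarray(fc_treatment, float),
                                    fc_rescue=np.asarray(fc_rescue, float))
    return make
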