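import numpy as np
import pandas as pd
import pytest

from hybridkit import simdata
from hybridkit.markers import BandMatrix


def make_band_matrix(rows, locus_to_primer, mother_id="M", father_id="F"):
    """Build a BandMatrix from {individual: [calls...]} (None = missing)."""
    loci = list(locus_to_primer)
    calls = pd.DataFrame(
        {ind: [np.nan if v is None else float(v) for v in vals] for ind, vals in rows.items()},
        index=loci,
    ).T
    mapping = pd.Series(locus_to_primer)
    return BandMatrix(calls, mapping, mother_id, father_id)


@pytest.fixture
def toy_matrix():
    """Mother (1,0,1), father (1,1,0) plus three offspring."""
    return make_band_matrix(
        {
            "M": [1, 0, 1],
            "F": [1, 1, 0],
            "O1": [1, 1, 1],  # carries the paternal band
            "O2": [1, 0, 1],  # maternal type
            "O3": [1, None, 1],  # paternal locus missing -> unresolved
        },
        {"a": "P1", "b": "P1", "c": "P1"},
    )


@pytest.fixture(scope="session")
def tiny_fixture_dir(tmp_path_factory):
    out = tmp_path_factory.mktemp("fixtures") / "tiny"
    simdata.write_fixture_set(out, "tiny", seed=11)
    return out


@pytest.fixture(scope="session")
def f1_fixture_dir(tmp_path_factory):
    out = tmp_path_factory.mktemp("fixtures") / "f1"
    simdata.write_fixture_set(out, "paper-like-F1", seed=5)
    return out
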