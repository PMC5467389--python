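import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from coipquant.count_interactome import CountMatrix
from coipquant.synthetic_data import synthetic_nfm, synthetic_spinophilin


@pytest.fixture(scope="session")
def nfm():
    return synthetic_nfm()


@pytest.fixture(scope="session")
def spino():
    return synthetic_spinophilin()


def make_count_matrix(count_rows: dict, n_animals: int = 6, bait: str = "Bait") -> CountMatrix:
    """Build a 24-sample CountMatrix from per-protein per-stratum counts.

    ``count_rows`` maps protein -> {(fraction, hemisphere): per-replicate
    count or list of per-replicate counts}.
    """
    animals = [f"a{i + 1}" for i in range(n_animals)]
    meta_rows, columns = [], []
    for frac in ("S2", "S3"):
        for hemi in ("intact", "lesion"):
            for i, animal in enumerate(animals):
                sid = f"{frac}_{hemi}_{animal}"
                columns.append((sid, frac, hemi, i))
                meta_rows.append(
                    {
                        "sample_id": sid,
                        "animal_id": animal,
                        "hemisphere": hemi,
                        "fraction": frac,
                        "replicate_day": 1 if i < 3 else 2,
                    }
                )
    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    data = {}
    for sid, frac, hemi, i in columns:
        col = []
        for protein, strata in count_rows.items():
            value = strata.get((frac, hemi), 0)
            col.append(value[i] if isinstance(value, (list, tuple)) else value)
        data[sid] = col
    counts = pd.DataFrame(data, index=list(count_rows))
    return CountMatrix(counts=counts, meta=meta, bait=bait)


@pytest.fixture
def simple_matrix():
    """Bait at 100/replicate everywhere; one prey with a planted S3 decrease."""
    return make_count_matrix(
        {
            "Bait": {(f, h): 100 for f in ("S2", "S3") for h in ("intact", "lesion")},
            "PreyDown": {
                ("S2", "intact"): 10,
                ("S2", "lesion"): 10,
                ("S3", "intact"): 10,
                ("S3", "lesion"): 8,  # ratio 0.8 in S3
            },
        }
    )
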