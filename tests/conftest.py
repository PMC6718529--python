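import numpy as np
import pandas as pd
import pytest

from methdmr.datamodel import BetaMatrix, ProbeManifest, SampleSheet
from methdmr import synthetic


@pytest.fixture
def tiny_manifest() -> ProbeManifest:
    """Ten hand-placed probes on two chromosomes."""
    rows = []
    positions = [100, 200, 1500, 1600, 5000, 5100, 5200, 9000, 9100, 9200]
    for i, pos in enumerate(positions):
        rows.append({
            "probe_id": f"cg{i:03d}",
            "chrom": "chr1" if i < 7 else "chr2",
            "pos": pos,
            "genes": [f"G{i // 3}"],
            "gene_region": ["Body"],
            "island_relation": "Island",
            "snp_overlap": False,
            "sex_chrom": False,
        })
    return ProbeManifest(pd.DataFrame(rows).set_index("probe_id"))


@pytest.fixture
def small_sheet() -> SampleSheet:
    return synthetic.generate_cohort(6, 6, seed=11)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_matrix(values, probe_ids=None, sample_ids=None) -> BetaMatrix:
    arr = np.asarray(values, dtype=float)
    probe_ids = probe_ids or [f"cg{i:03d}" for i in range(arr.shape[0])]
    sample_ids = sample_ids or [f"S{j}" for j in range(arr.shape[1])]
    return BetaMatrix(pd.DataFrame(arr, index=probe_ids, columns=sample_ids))
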