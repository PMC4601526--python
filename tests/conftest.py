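import numpy as np
import pandas as pd
import pytest

from mirddr.ingest import CountTable, MatureMiRNA


@pytest.fixture
def tiny_reference() -> list[MatureMiRNA]:
    """Five matures incl. an arm pair and an identical-sequence pair."""
    return [
        MatureMiRNA("mirX-5p", "ACGTACGTACGTACGTACGTAC", "mirX", "5p"),
        MatureMiRNA("mirX-3p", "TTGCAGGCAGTGCAAGTCTAG", "mirX", "3p"),
        MatureMiRNA("mirYa-3p", "GGATTCCAGGCTTACGATCCA", "mirYa", "3p"),
        MatureMiRNA("mirYb-3p", "GGATTCCAGGCTTACGATCCA", "mirYb", "3p"),
        MatureMiRNA("mirZ-5p", "CAGTTGACCTAGGACTTGCAT", "mirZ", "5p"),
    ]


def make_table(counts: dict[str, list[int]], mirnas: list[str],
               meta_rows: list[dict]) -> CountTable:
    frame = pd.DataFrame(counts, index=mirnas)
    meta = pd.DataFrame(meta_rows).set_index("sample")
    return CountTable(counts=frame, sample_meta=meta,
                      library_sizes=frame.sum(axis=0).astype(float))


@pytest.fixture
def small_raw_table() -> CountTable:
    """Two replicates x two time points, one cell line, 4 miRNAs."""
    mirnas = ["m1", "m2", "m3", "m4"]
    counts = {
        "s_t0_r1": [100, 40, 0, 30],
        "s_t0_r2": [110, 36, 2, 34],
        "s_t4_r1": [95, 160, 1, 33],
        "s_t4_r2": [105, 150, 0, 29],
    }
    meta = [
        {"sample": "s_t0_r1", "cell_line": "CL", "genotype": "WT", "time_h": 0, "replicate": 1},
        {"sample": "s_t0_r2", "cell_line": "CL", "genotype": "WT", "time_h": 0, "replicate": 2},
        {"sample": "s_t4_r1", "cell_line": "CL", "genotype": "WT", "time_h": 4, "replicate": 1},
        {"sample": "s_t4_r2", "cell_line": "CL", "genotype": "WT", "time_h": 4, "replicate": 2},
    ]
    return make_table(counts, mirnas, meta)
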