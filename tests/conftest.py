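import numpy as np
import pandas as pd
import pytest

import stqc


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_panel():
    return stqc.ProbePanel.from_genes(
        targets=["GENE_A", "GENE_B", "GENE_C"],
        backgrounds=["Blank-1", "Blank-2"],
        background_class="blank",
    )


@pytest.fixture
def two_cell_mask():
    """4x6 mask (pixel size 2 µm) with cell 7 on the left, cell 9 on the right."""
    labels = np.zeros((4, 6), dtype=np.int32)
    labels[1:3, 1:3] = 7
    labels[1:3, 4:6] = 9
    return stqc.SegmentationMask(labels, pixel_size=2.0)


@pytest.fixture
def small_tissue():
    """Small two-compartment simulation shared across tests."""
    cfg = stqc.TissueSimConfig(
        field_size=(400.0, 400.0),
        cell_density=1200.0,
        nodules=((120.0, 120.0, 90.0),),
        detection_efficiency=0.35,
        background_rates={"Blank-1": 150.0, "Blank-2": 250.0},
    )
    return stqc.simulate_tissue(cfg, seed=7)
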