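import numpy as np
import pandas as pd
import pytest

from methyldiag.io import MethylationMatrix, SampleMetadataTable


@pytest.fixture
def tiny_matrix() -> MethylationMatrix:
    """2 samples x 3 sites with known values."""
    return MethylationMatrix(
        ["s1", "s2"],
        ["cg000", "cg001", "cg002"],
        np.array([[0.1, 0.2, 0.3], [0.4, 0.5, 0.6]]),
    )


@pytest.fixture
def two_tissue_cohort():
    """Deterministic 40-sample, 30-site cohort: site cg000 separates status
    perfectly in brain; sites are otherwise uniform noise.  Kidney samples
    are all healthy (single-status tissue)."""
    rng = np.random.default_rng(42)
    n = 40
    sample_ids = [f"s{i:02d}" for i in range(n)]
    status = np.array([0, 1] * (n // 4) + [0] * (n // 2))
    tissue = ["brain"] * (n // 2) + ["kidney"] * (n // 2)
    betas = rng.uniform(0.2, 0.8, (n, 30))
    # perfect separator in brain: healthy < 0.2, disease > 0.8
    for i in range(n // 2):
        betas[i, 0] = 0.1 if status[i] == 0 else 0.9
    matrix = MethylationMatrix(sample_ids, [f"cg{j:03d}" for j in range(30)], betas)
    meta = SampleMetadataTable(
        pd.DataFrame({"sample_id": sample_ids, "tissue": tissue, "status": status}),
        tissue_vocabulary=("brain", "kidney"),
    )
    return matrix, meta
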