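import numpy as np
import pandas as pd
import pytest

from hybqc.core_io import Alignment, RecoveryMatrix


@pytest.fixture
def worked_alignment() -> Alignment:
    """4 taxa x 4 columns: [AACC], [AA--], [ACAC], [---A] column-wise."""
    return Alignment(
        "worked",
        ["s1", "s2", "s3", "s4"],
        ["AAA-", "AAC-", "C-A-", "C-CA"],
    )


@pytest.fixture
def uniform_matrix() -> RecoveryMatrix:
    """4 accessions x 4 loci, uniform 100 bp targets."""
    rec = pd.DataFrame(
        {
            "l1": [100.0, 50.0, 0.0, 100.0],
            "l2": [100.0, 50.0, 0.0, 0.0],
            "l3": [100.0, 0.0, 0.0, 60.0],
            "l4": [100.0, 0.0, 0.0, 40.0],
        },
        index=["full", "half", "none", "mixed"],
    )
    targets = pd.Series({f"l{i}": 100.0 for i in range(1, 5)})
    return RecoveryMatrix(rec, targets)


def random_alignment(rng: np.random.Generator, max_taxa: int = 10,
                     max_cols: int = 50, min_taxa: int = 2) -> Alignment:
    """Random gapped DNA alignment (shared helper for oracle tests)."""
    n = int(rng.integers(min_taxa, max_taxa + 1))
    m = int(rng.integers(1, max_cols + 1))
    chars = np.array(list("ACGT-?NRY"))
    probs = np.array([0.2, 0.2, 0.2, 0.2, 0.1, 0.03, 0.03, 0.02, 0.02])
    rows = [
        "".join(rng.choice(chars, size=m, p=probs)) for _ in range(n)
    ]
    return Alignment("rand", [f"t{i}" for i in range(n)], rows)
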