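from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from dartsex import PaMatrix, Sex, SexRegistry, SnpGenotypeMatrix


def make_registry(n_males: int, n_females: int) -> SexRegistry:
    ids = {f"M{i+1:02d}": Sex.MALE for i in range(n_males)}
    ids.update({f"F{i+1:02d}": Sex.FEMALE for i in range(n_females)})
    return SexRegistry(ids)


def make_pa(rows, individuals=None, locus_ids=None) -> PaMatrix:
    """PA matrix from a list of row-lists using codes 1/0/-1."""
    arr = np.asarray(rows, dtype=np.int8)
    individuals = individuals or [f"I{j+1:02d}" for j in range(arr.shape[1])]
    locus_ids = locus_ids or [f"L{i+1:03d}" for i in range(arr.shape[0])]
    return PaMatrix(pd.DataFrame(arr, index=locus_ids, columns=individuals))


def make_snp(rows, individuals=None, locus_ids=None) -> SnpGenotypeMatrix:
    arr = np.asarray(rows, dtype=np.int8)
    individuals = individuals or [f"I{j+1:02d}" for j in range(arr.shape[1])]
    locus_ids = locus_ids or [f"L{i+1:03d}" for i in range(arr.shape[0])]
    return SnpGenotypeMatrix(pd.DataFrame(arr, index=locus_ids, columns=individuals))


def random_calls(
    rng: np.random.Generator,
    n_loci: int,
    n_ind: int,
    marker_type: str,
    missing_rate: float = 0.15,
) -> np.ndarray:
    if marker_type == "PA":
        calls = rng.integers(0, 2, size=(n_loci, n_ind))
    else:
        calls = rng.integers(0, 3, size=(n_loci, n_ind))
    calls = calls.astype(np.int8)
    calls[rng.random((n_loci, n_ind)) < missing_rate] = -1
    return calls


@pytest.fixture
def registry_3m3f() -> SexRegistry:
    return make_registry(3, 3)


@pytest.fixture
def registry_15m15f() -> SexRegistry:
    return make_registry(15, 15)
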