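import numpy as np
import pandas as pd
import pytest

from refstab.core import CtMatrix
from refstab.synthetic import paper_shape_preset, simulate_ct


def make_ct(values, genes=None, samples=None, annotations=None):
    """Small helper to build a CtMatrix from a nested list."""
    arr = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    samples = samples or [f"s{j}" for j in range(arr.shape[1])]
    ann = None
    if annotations is not None:
        ann = pd.DataFrame(annotations, index=samples)
    return CtMatrix(
        pd.DataFrame(arr, index=genes, columns=samples),
        ann if ann is not None else pd.DataFrame(index=pd.Index(samples)),
    )


@pytest.fixture
def small_ct():
    """4 genes x 6 samples, two organs, no missing values."""
    rng = np.random.default_rng(42)
    base = np.array([[20.0], [22.0], [25.0], [23.0]])
    noise = rng.normal(0, [[0.1], [0.15], [0.2], [1.0]], size=(4, 6))
    values = base + noise
    return make_ct(
        values,
        genes=["stableA", "stableB", "stableC", "noisy"],
        samples=[f"s{j}" for j in range(6)],
        annotations={
            "organ": ["leaf", "leaf", "leaf", "flower", "flower", "flower"],
            "species": ["X", "X", "Y", "X", "X", "Y"],
        },
    )


@pytest.fixture
def preset_ct():
    """One draw of the default study-shaped simulation (seed 7)."""
    ct, truth = simulate_ct(paper_shape_preset(seed=7))
    return ct, truth


@pytest.fixture
def preset_refs(preset_ct):
    """Reference candidates only (targets removed)."""
    ct, truth = preset_ct
    refs = ct.select(genes=[g for g in ct.genes if g not in ("PAL", "CHS")])
    return refs, truth
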