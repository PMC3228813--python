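import numpy as np
import pytest

import pclouds as pc


@pytest.fixture(scope="session")
def small_planted():
    """A 500-kb genome with one 300-bp family at 10% divergence (fast fixture)."""
    fam = pc.RepeatFamilySpec(master_length=300, copies=120, divergence=0.10, name="famA")
    return pc.plant_genome(500_000, [fam], seed=101)


@pytest.fixture(scope="session")
def esp_family():
    """Training/test split of a synthetic diverged SINE-like family."""
    fam = pc.RepeatFamilySpec(master_length=260, copies=210, divergence=0.05, name="mirlike")
    g = pc.plant_genome(2_000_000, [fam], seed=202)
    copies = g.families["mirlike"]["copies"]
    train = [(f"train{i}", s) for i, s in enumerate(copies[:200])]
    test = [(f"test{i}", s) for i, s in enumerate(copies[200:])]
    return train, test


def coverage_mask(n, regions):
    m = np.zeros(n, dtype=bool)
    for r in regions:
        m[r.start : r.end] = True
    return m
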